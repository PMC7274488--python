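"""Summary-statistic estimators: closed forms, degeneracies, pleiotropy behaviour."""

import numpy as np
import pandas as pd
import pytest

from thyromr import mr_two_sample as mr2
from thyromr.synthetic_cohort import default_variant_panel, simulate_summary_stats


def rows_from(bx, by, se_out, se_exp=None, ids=None):
    bx = np.asarray(bx, dtype=float)
    k = len(bx)
    return pd.DataFrame(
        {
            "variant_id": ids or [f"rs{i}" for i in range(k)],
            "effect_allele": ["A"] * k,
            "other_allele": ["G"] * k,
            "beta_exp": bx,
            "se_exp": se_exp if se_exp is not None else np.full(k, 0.01),
            "beta_out": np.asarray(by, dtype=float),
            "se_out": np.asarray(se_out, dtype=float),
        }
    )


class TestHarmonize:
    def test_sign_flip_preserves_ratio(self):
        rows = rows_from([-0.1], [-0.05], [0.01])
        out = mr2.harmonize(rows)
        assert out.loc[0, "beta_exp"] == pytest.approx(0.1)
        assert out.loc[0, "beta_out"] == pytest.approx(0.05)
        assert out.loc[0, "effect_allele"] == "G"
        assert out.loc[0, "other_allele"] == "A"

    def test_palindromic_drop_policy(self):
        rows = rows_from([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        rows.loc[1, ["effect_allele", "other_allele"]] = ["A", "T"]
        out = mr2.harmonize(rows, palindromic="drop")
        assert list(out["variant_id"]) == ["rs0"]

    def test_allele_mismatch_listed(self):
        exp = rows_from([0.1], [0.05], [0.01])[
            ["variant_id", "effect_allele", "other_allele", "beta_exp", "se_exp"]
        ]
        out = pd.DataFrame(
            {
                "variant_id": ["rs0"],
                "effect_allele": ["C"],
                "other_allele": ["T"],
                "beta_out": [0.05],
                "se_out": [0.01],
            }
        )
        with pytest.raises(ValueError, match="rs0"):
            mr2.merge_exposure_outcome(exp, out, allow_strand_flip=False)

    def test_swapped_alleles_flip_outcome_beta(self):
        exp = rows_from([0.1], [0.0], [0.01])[
            ["variant_id", "effect_allele", "other_allele", "beta_exp", "se_exp"]
        ]
        out = pd.DataFrame(
            {
                "variant_id": ["rs0"],
                "effect_allele": ["G"],
                "other_allele": ["A"],
                "beta_out": [0.05],
                "se_out": [0.01],
            }
        )
        merged = mr2.merge_exposure_outcome(exp, out)
        assert merged.loc[0, "beta_out"] == pytest.approx(-0.05)


class TestWaldRatio:
    def test_first_order_delta(self):
        ratio, se = mr2.wald_ratio(0.1, 0.05, 0.01, 0.01)
        assert ratio == pytest.approx(0.5)
        assert se == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        ratio, _ = mr2.wald_ratio(0.1, 0.0, 0.01, 0.01)
        assert ratio == 0.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mr2.wald_ratio(0.0, 0.1, 0.01, 0.01)

    def test_second_order_reduces_to_first_order_as_se_exp_vanishes(self):
        r1, se1 = mr2.wald_ratio(0.1, 0.05, 0.0, 0.01, second_order=True)
        r2, se2 = mr2.wald_ratio(0.1, 0.05, 0.0, 0.01, second_order=False)
        assert (r1, se1) == (r2, se2)


class TestIVW:
    def test_closed_form(self):
        rows = rows_from([0.1, 0.2], [0.05, 0.04], [0.01, 0.01])
        est = mr2.ivw(rows)
        assert est.beta == pytest.approx(0.26)
        assert est.se == pytest.approx(1 / np.sqrt((0.01 + 0.04) / 0.0001))

    def test_single_instrument_equals_wald_ratio(self):
        rows = rows_from([0.13], [0.071], [0.017])
        est = mr2.ivw(rows)
        ratio, se = mr2.wald_ratio(0.13, 0.071, 0.0, 0.017)
        assert est.beta == pytest.approx(ratio, abs=1e-14)
        assert est.se == pytest.approx(se, abs=1e-14)

    def test_consistency_on_valid_instruments(self):
        panel = default_variant_panel("BMI", n_variants=50, seed=1)
        rows = mr2.harmonize(
            simulate_summary_stats(panel, 0.2, 300_000, 400_000, seed=2)
        )
        est = mr2.ivw(rows)
        assert abs(est.beta - 0.2) < 3 * est.se

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least 1"):
            mr2.ivw(rows_from([], [], []))

    def test_random_effects_never_shrinks_se(self):
        rows = rows_from([0.1, 0.2, 0.15], [0.09, 0.01, 0.12], [0.01, 0.01, 0.01])
        assert mr2.ivw(rows, random_effects=True).se >= mr2.ivw(rows).se


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.05, 0.1, 0.2])
        rows = rows_from(bx, 0.01 + 0.4 * bx, [0.01, 0.01, 0.01])
        est = mr2.egger(rows)
        assert est.beta == pytest.approx(0.4, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.01, abs=1e-10)

    def test_fewer_than_three_rows_refused(self):
        with pytest.raises(ValueError, match="at least 3"):
            mr2.egger(rows_from([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_directional_pleiotropy_recovered(self):
        panel = default_variant_panel("BMI", n_variants=200, seed=3)
        rows = mr2.harmonize(
            simulate_summary_stats(
                panel,
                0.2,
                300_000,
                400_000,
                pleiotropy_mode="directional",
                pleiotropy_mean=0.05,
                pleiotropy_sd=0.005,
                seed=4,
            )
        )
        est = mr2.egger(rows)
        ivw_est = mr2.ivw(rows)
        assert est.egger_intercept == pytest.approx(0.05, abs=0.01)
        assert abs(est.beta - 0.2) < 0.15
        assert ivw_est.beta - 0.2 > 0.5  # IVW displaced by the directional offset


class TestMedians:
    def test_plain_median_with_equal_weights(self):
        rows = rows_from([1.0, 1.0, 1.0], [0.2, 0.5, 0.9], [0.01, 0.01, 0.01])
        est = mr2.weighted_median(rows, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_cumulative_weight_interpolation(self):
        # ratios 0.1/0.4/0.7 with ratio-scale weights 0.2/0.3/0.5
        se_out = 1.0 / np.sqrt([0.2, 0.3, 0.5])
        rows = rows_from([1.0, 1.0, 1.0], [0.1, 0.4, 0.7], se_out)
        est = mr2.weighted_median(rows, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5125)

    def test_pwm_equals_wm_on_homogeneous_data(self):
        # ratios tightly clustered: every Q_j far below the penalization
        # threshold, so no weight is shrunk and the two estimates coincide
        k = 15
        bx = np.full(k, 0.1)
        by = 0.1 * (0.2 + np.linspace(-0.001, 0.001, k))
        rows = rows_from(bx, by, np.full(k, 0.01))
        wm = mr2.weighted_median(rows, n_boot=50, seed=7)
        pwm = mr2.penalized_weighted_median(rows, n_boot=50, seed=7)
        assert pwm.beta == pytest.approx(wm.beta, abs=1e-12)

    def test_gross_outlier_weight_crushed(self):
        bx = np.full(21, 0.1)
        by = 0.2 * bx
        by[0] = 0.5  # ratio 5 vs 0.2 elsewhere
        rows = rows_from(bx, by, np.full(21, 0.002))
        ratios, w = mr2._ratio_inputs(rows)
        wm = mr2._weighted_median(ratios, w)
        q = w * (ratios - wm) ** 2
        from scipy import stats

        penalized = w * np.minimum(1.0, 20 * stats.chi2.sf(q, df=1))
        assert penalized[0] < 0.01 * w[0]
        est = mr2.penalized_weighted_median(rows, n_boot=50, seed=8)
        assert est.beta == pytest.approx(0.2, abs=1e-6)


class TestInvariants:
    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_scale_equivariance(self, k):
        panel = default_variant_panel("BMI", n_variants=25, seed=9)
        rows = mr2.harmonize(
            simulate_summary_stats(panel, 0.2, 300_000, 400_000, seed=10)
        )
        scaled = rows.copy()
        scaled["beta_exp"] *= k
        scaled["se_exp"] *= k
        assert mr2.ivw(scaled).beta == pytest.approx(mr2.ivw(rows).beta / k)
        assert mr2.egger(scaled).beta == pytest.approx(mr2.egger(rows).beta / k)
        wm0 = mr2.weighted_median(rows, n_boot=10, seed=1).beta
        wmk = mr2.weighted_median(scaled, n_boot=10, seed=1).beta
        assert wmk == pytest.approx(wm0 / k)

    def test_ivw_equals_meta_analysis_of_wald_ratios(self):
        panel = default_variant_panel("BMI", n_variants=40, seed=11)
        rows = mr2.harmonize(
            simulate_summary_stats(panel, 0.1, 300_000, 400_000, seed=12)
        )
        ratios = rows["beta_out"] / rows["beta_exp"]
        w = (np.abs(rows["beta_exp"]) / rows["se_out"]) ** 2
        meta = float(np.sum(w * ratios) / np.sum(w))
        est = mr2.ivw(rows)
        assert est.beta == pytest.approx(meta, abs=1e-10)
        assert est.se == pytest.approx(1 / np.sqrt(np.sum(w)), abs=1e-10)

    def test_estimators_agree_without_pleiotropy(self):
        panel = default_variant_panel("BMI", n_variants=100, seed=13)
        rows = mr2.harmonize(
            simulate_summary_stats(panel, 0.15, 10**7, 10**7, seed=14)
        )
        betas = [e.beta for e in mr2.all_methods(rows, n_boot=100, seed=15)]
        assert max(betas) - min(betas) < 0.02
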