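"""Publication-style rendering of association and MR results.

Conventions: odds ratios and CI bounds to two decimals, intervals printed as
"(low-high)", p-values to two significant figures with scientific notation
("1.2 x 10^-5") below 0.001.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Sequence

import pandas as pd

from .types import AssocResult, MREstimate


def format_or_ci(odds_ratio: float, ci_low: float, ci_high: float) -> str:
    return f"{odds_ratio:.2f} ({ci_low:.2f}-{ci_high:.2f})"


def format_p(p: float) -> str:
    if not (0 <= p <= 1):
        raise ValueError(f"p-value out of range: {p}")
    if p >= 0.001:
        return f"{p:.2g}"
    if p == 0:
        return "<1 x 10^-300"
    exponent = math.floor(math.log10(p))
    mantissa = p / 10**exponent
    return f"{mantissa:.1f} x 10^{exponent}"


def parse_or_ci(cell: str) -> tuple[float, float, float]:
    """Inverse of :func:`format_or_ci`, for round-trip checks."""
    m = re.match(r"^([\d.]+) \(([\d.]+)-([\d.]+)\)$", cell)
    if not m:
        raise ValueError(f"cannot parse OR cell: {cell!r}")
    return tuple(float(g) for g in m.groups())  # type: ignore[return-value]


def _mr_cell(est: MREstimate | None) -> tuple[str, str]:
    if est is None:
        return "", ""
    return format_or_ci(est.odds_ratio, est.ci95_low, est.ci95_high), format_p(est.p)


def format_observational_table(results: Iterable[AssocResult]) -> pd.DataFrame:
    """One row per trait: OR (95% CI) and p per outcome, observational layout."""
    rows: dict[str, dict[str, str]] = {}
    for r in results:
        cell = rows.setdefault(r.trait, {"trait": r.trait})
        cell[f"or_{r.outcome}"] = format_or_ci(r.odds_ratio, r.ci95_low, r.ci95_high)
        cell[f"p_{r.outcome}"] = format_p(r.p_value)
    return pd.DataFrame(list(rows.values()))


def format_two_sample_table(
    results_by_trait: dict[str, Sequence[MREstimate]]
) -> pd.DataFrame:
    """Per trait: OR (95% CI) and p for IVW / Egger / WM / PWM + Egger intercept p."""
    short = {
        "ivw": "ivw",
        "egger": "egger",
        "weighted_median": "wm",
        "penalized_weighted_median": "pwm",
    }
    out = []
    for trait, results in results_by_trait.items():
        row: dict[str, str] = {"trait": trait}
        seen = {e.method: e for e in results}
        for method, tag in short.items():
            est = seen.get(method)
            if est is None:
                import warnings

                warnings.warn(f"{trait}: no {method} estimate; cell left empty")
                row[f"{tag}_or_ci"], row[f"{tag}_p"] = "", ""
                continue
            row[f"{tag}_or_ci"], row[f"{tag}_p"] = _mr_cell(est)
            if method == "egger":
                row["egger_int_p"] = format_p(est.intercept_p)
        out.append(row)
    return pd.DataFrame(out)


def format_quartile_table(
    counts: pd.DataFrame, adjusted: Sequence[MREstimate]
) -> pd.DataFrame:
    """Quartile layout: counts (%), adjusted OR (95% CI), p; quartile 1 = 1.00."""
    total_cases = counts["cases"].sum()
    total_controls = counts["controls"].sum()
    rows = []
    adj = {int(e.notes[0].split()[1]): e for e in adjusted}  # "quartile q vs 1"
    for _, r in counts.sort_values("quartile").iterrows():
        q = int(r["quartile"])
        row = {
            "quartile": q,
            "cases": f"{r['cases']} ({100 * r['cases'] / total_cases:.1f})",
            "controls": f"{r['controls']} ({100 * r['controls'] / total_controls:.1f})",
        }
        if q == counts["quartile"].min():
            row["or_ci"], row["p"] = "1.00", ""
        elif q in adj:
            row["or_ci"], row["p"] = _mr_cell(adj[q])
        else:
            row["or_ci"], row["p"] = "", ""
        rows.append(row)
    return pd.DataFrame(rows)
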