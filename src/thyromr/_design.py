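"""Design-matrix assembly shared by the regression-based modules."""

from __future__ import annotations

import pandas as pd


def build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design block: categoricals one-hot encoded (first level dropped).

    Object/category/boolean columns become reference-coded dummies; numeric
    columns pass through as float. Low-cardinality integer identifiers
    (assessment centre, platform ids) should be passed as strings or
    categoricals by the caller when they are nominal.
    """
    blocks = []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            blocks.append(dummies)
        else:
            blocks.append(s.astype(float).to_frame(col))
    if not blocks:
        return pd.DataFrame(index=covariates.index)
    return pd.concat(blocks, axis=1)
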