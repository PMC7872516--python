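"""Lipidomic matrix preparation.

Rank-based inverse-normal transformation of each marker (the scale on which
all downstream associations and mediation models operate), the duplicate-QC
coefficient-of-variation summary, and principal components of the full
transformed panel for joint-mediation analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

#: Blom rank offset — the common epidemiological convention; any fixed
#: offset in (0, 1) preserves ranks and yields mean ~0, SD ~1.
BLOM_C = 0.375


def inverse_normal_transform(column: np.ndarray | pd.Series, c: float = BLOM_C) -> np.ndarray:
    """Map a variable to normal quantiles (mean 0, SD = 1).

    Uses ``Phi^-1((r - c) / (n - 2c + 1))`` with Blom's ``c = 3/8`` and
    average fractional ranks for ties, so duplicated concentrations map to
    equal transformed values and any strictly monotone re-expression of the
    input gives identical output.  The normal scores are rescaled by their
    sample SD so every transformed column has SD exactly 1 (the raw Blom
    scores fall slightly short of unit variance at finite n).
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d column")
    n = x.size
    if n < 3:
        raise ValueError("inverse-normal transform needs n >= 3")
    if np.isnan(x).any():
        raise ValueError("missing values in metabolite column")
    if np.ptp(x) == 0:
        raise ValueError("constant column cannot be inverse-normal transformed")
    ranks = stats.rankdata(x, method="average")
    scores = stats.norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))
    return scores / scores.std(ddof=1)


def transform_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Inverse-normal transform every marker column of a participants x markers table."""
    out = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    for col in values.columns:
        out[col] = inverse_normal_transform(values[col].to_numpy())
    return out


def duplicate_cv(pairs: dict[str, list[tuple[float, float]]]) -> dict[str, float]:
    """Duplicate-measurement QC summary.

    For each marker, the CV of a replicate pair is SD/mean of the two values
    (so a pair (90, 110) gives 10*sqrt(2)/100 ~ 14.14%); the marker CV is the
    mean over its pairs, and the returned summary is the median and IQR of
    marker CVs, in percent.  Pairs with mean 0 are excluded with a warning.
    """
    marker_cvs = []
    for marker, marker_pairs in pairs.items():
        if not marker_pairs:
            raise ValueError(f"no duplicate pairs for marker {marker!r}")
        cvs = []
        for v1, v2 in marker_pairs:
            m = (v1 + v2) / 2.0
            if m == 0:
                warnings.warn(f"duplicate pair with zero mean for {marker!r} excluded")
                continue
            sd = abs(v1 - v2) / np.sqrt(2.0)  # two-point sample SD
            cvs.append(sd / abs(m))
        if not cvs:
            raise ValueError(f"all duplicate pairs for {marker!r} had zero mean")
        marker_cvs.append(float(np.mean(cvs)))
    arr = 100.0 * np.asarray(marker_cvs)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {"median_cv_pct": float(med), "iqr_low_pct": float(q1), "iqr_high_pct": float(q3)}


def top_principal_components(
    transformed: pd.DataFrame, k: int = 5, variance_floor: float = 0.95
) -> tuple[pd.DataFrame, np.ndarray]:
    """Scores of the first ``k`` principal components of the transformed panel.

    Returns ``(pc_scores, variance_explained)`` where ``pc_scores`` has
    columns ``PC1..PCk``.  Warns when the top-``k`` cumulative variance falls
    below ``variance_floor`` (the joint-mediation analysis expects the five
    leading components to carry >=95% of total variation).
    """
    x = transformed.to_numpy(dtype=float)
    n, p = x.shape
    if k < 1 or k > min(n, p):
        raise ValueError(f"k = {k} exceeds the rank bound min(n, p) = {min(n, p)}")
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / (n - 1)
    frac = var / var.sum()
    if frac[:k].sum() < variance_floor:
        warnings.warn(
            f"top {k} components explain {frac[:k].sum():.1%} of variance, "
            f"below the {variance_floor:.0%} floor"
        )
    scores = u[:, :k] * s[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=transformed.index, columns=cols), frac[:k]
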