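"""Association layers: lifestyle -> metabolites, metabolites -> CHD.

Linear models relate the combined HLF exposure (categorical 0-1 / 2-3 / 4-5
groups, or the count itself) to each inverse-normal-transformed marker;
logistic models relate each marker to incident CHD (cases vs controls,
stroke cases excluded).  Both layers adjust for the design covariates
(age, sex, fasting time, 10 study areas, education; plus case/control
status or smoking status depending on the layer), report Wald 95% CIs, and
control the false discovery rate across markers with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

Z95 = stats.norm.ppf(0.975)


@dataclass
class AssociationResult:
    """One estimated contrast: an SD-difference or a log odds ratio."""

    marker: str
    contrast: str
    estimate: float
    se: float
    p: float
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)
    p_fdr: float = field(default=np.nan)
    n: int = field(default=0)

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            self.ci_low = self.estimate - Z95 * self.se
        if np.isnan(self.ci_high):
            self.ci_high = self.estimate + Z95 * self.se


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# design matrices

_AREA_LEVELS = [f"area{i}" for i in range(1, 11)]


def _dummies(series: pd.Series, prefix: str, reference: str) -> pd.DataFrame:
    d = pd.get_dummies(series, prefix=prefix, dtype=float)
    ref_col = f"{prefix}_{reference}"
    if ref_col in d.columns:
        d = d.drop(columns=[ref_col])
    return d


def design_matrix(df: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    """Covariate design (no intercept) for the requested adjustment terms.

    Recognised terms: ``age`` (years, continuous), ``sex`` (male indicator),
    ``fasting`` (>=8 h indicator), ``area`` (9 indicators for 10 areas),
    ``education`` (2 indicators for 3 levels), ``case_status`` (indicators
    vs control), ``smoking`` (indicators vs never), ``ancestry_pcs``
    (10 genotype PCs).
    """
    parts: list[pd.DataFrame | pd.Series] = []
    for term in terms:
        if term == "age":
            parts.append(df["age"].astype(float).rename("age"))
        elif term == "sex":
            parts.append((df["sex"] == "male").astype(float).rename("sex_male"))
        elif term == "fasting":
            parts.append(df["fasting_ge_8h"].astype(float).rename("fasting_ge_8h"))
        elif term == "area":
            parts.append(_dummies(df["area"], "area", reference=df["area"].iloc[0]))
        elif term == "education":
            parts.append(_dummies(df["education"], "edu", reference="primary_or_less"))
        elif term == "case_status":
            parts.append(_dummies(df["status"], "status", reference="control"))
        elif term == "smoking":
            parts.append(_dummies(df["smoking_status"], "smoke", reference="never"))
        elif term == "ancestry_pcs":
            cols = [c for c in df.columns if c.startswith("apc")]
            if len(cols) == 0:
                raise ValueError("no ancestry PC columns (apc1..apcK) in input")
            parts.append(df[cols].astype(float))
        else:
            raise ValueError(f"unknown covariate term {term!r}")
    out = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)
    return out.astype(float)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the aliased columns by QR pivoting
        _, r = np.linalg.qr(arr)
        aliased = [X.columns[j] for j in range(arr.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def fit_ols(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    _check_full_rank(Xc)
    return sm.OLS(np.asarray(y, dtype=float), Xc).fit()


def fit_logit(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    _check_full_rank(Xc)
    y = np.asarray(y, dtype=float)
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge")
    return res


# ---------------------------------------------------------------------------
# layers


def fit_hlf_metabolite(
    metabolite: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame,
    marker: str = "",
) -> list[AssociationResult]:
    """SD differences in a transformed marker by combined-HLF exposure.

    ``exposure`` may be the categorical group (reference "0-1") or the HLF
    count (then a single per-+1-HLF slope is returned).
    """
    y = metabolite.to_numpy(dtype=float)
    results = []
    if exposure.dtype == object or isinstance(exposure.dtype, pd.CategoricalDtype):
        dummies = _dummies(exposure.astype(str), "hlf", reference="0-1")
        X = pd.concat([dummies, covariates], axis=1)
        res = fit_ols(y, X)
        for col in dummies.columns:
            level = col.split("_", 1)[1]
            results.append(
                AssociationResult(
                    marker=marker,
                    contrast=f"{level} vs 0-1 HLFs",
                    estimate=float(res.params[col]),
                    se=float(res.bse[col]),
                    p=float(res.pvalues[col]),
                    n=len(y),
                )
            )
    else:
        X = pd.concat([exposure.astype(float).rename("hlf_count"), covariates], axis=1)
        res = fit_ols(y, X)
        results.append(
            AssociationResult(
                marker=marker,
                contrast="per +1 HLF",
                estimate=float(res.params["hlf_count"]),
                se=float(res.bse["hlf_count"]),
                p=float(res.pvalues["hlf_count"]),
                n=len(y),
            )
        )
    return results


def fit_metabolite_chd(
    status: pd.Series,
    metabolite: pd.Series,
    covariates: pd.DataFrame,
    marker: str = "",
) -> AssociationResult:
    """Log odds ratio of CHD per 1-SD higher transformed marker level.

    The input must contain only CHD cases and controls (stroke cases are
    excluded upstream).
    """
    levels = set(status.unique())
    if not levels <= {"control", "chd_case"}:
        raise ValueError(f"expected only controls and CHD cases, got {sorted(levels)}")
    y = (status == "chd_case").astype(float).to_numpy()
    X = pd.concat([metabolite.astype(float).rename("marker"), covariates], axis=1)
    res = fit_logit(y, X)
    return AssociationResult(
        marker=marker,
        contrast="per 1-SD marker (log-OR)",
        estimate=float(res.params["marker"]),
        se=float(res.bse["marker"]),
        p=float(res.pvalues["marker"]),
        n=len(y),
    )


def bh_fdr(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(results: list[AssociationResult]) -> list[AssociationResult]:
    adj = bh_fdr([r.p for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
    return results


def joint_group_analysis(
    metabolite: pd.Series,
    hlf_group2: pd.Series,
    score_group: pd.Series,
    covariates: pd.DataFrame,
    marker: str = "",
) -> list[AssociationResult]:
    """Four-group cross-classification of genetic score (median split) and HLFs.

    Reference: higher genetic risk (low protective score) with 0-2 HLFs.
    Returns one result per group, with the reference estimate fixed at 0.
    """
    combo = score_group.astype(str) + " score & " + hlf_group2.astype(str) + " HLFs"
    reference = "high_risk score & 0-2 HLFs"
    levels = sorted(combo.unique())
    if reference not in levels:
        raise ValueError(f"empty reference cell {reference!r}; cells present: {levels}")
    counts = combo.value_counts()
    expected = [
        f"{s} score & {h} HLFs" for s in ("high_risk", "low_risk") for h in ("0-2", "3-5")
    ]
    empty = [c for c in expected if counts.get(c, 0) == 0]
    if empty:
        raise ValueError(f"empty joint cell(s): {empty}")
    dummies = _dummies(combo.rename("group"), "g", reference=reference)
    X = pd.concat([dummies, covariates], axis=1)
    res = fit_ols(metabolite.to_numpy(dtype=float), X)
    out = [
        AssociationResult(
            marker=marker, contrast=f"{reference} (reference)", estimate=0.0, se=0.0, p=1.0, n=len(combo)
        )
    ]
    out[0].ci_low = out[0].ci_high = 0.0
    for col in dummies.columns:
        level = col.split("_", 1)[1]
        out.append(
            AssociationResult(
                marker=marker,
                contrast=f"{level} vs {reference}",
                estimate=float(res.params[col]),
                se=float(res.bse[col]),
                p=float(res.pvalues[col]),
                n=len(combo),
            )
        )
    return out


def interaction_lrt(
    y: pd.Series | np.ndarray,
    exposure: pd.Series,
    modifier: pd.Series,
    covariates: pd.DataFrame,
    family: str = "linear",
) -> tuple[float, int, float]:
    """Likelihood-ratio test for an exposure x modifier cross-product term.

    Fits the model with and without the product term and returns
    ``(statistic, df, p)`` with the statistic 2*(ll_full - ll_reduced)
    referred to chi-square.  ``family`` is ``"linear"`` for a continuous
    outcome or ``"logistic"`` for a binary one.
    """
    e = np.asarray(exposure, dtype=float)
    m = np.asarray(modifier, dtype=float)
    base = pd.DataFrame({"exposure": e, "modifier": m}, index=covariates.index)
    Xr = pd.concat([base, covariates], axis=1)
    Xf = Xr.copy()
    Xf["exposure_x_modifier"] = e * m
    if family == "linear":
        full = fit_ols(np.asarray(y, dtype=float), Xf)
        red = fit_ols(np.asarray(y, dtype=float), Xr)
    elif family == "logistic":
        full = fit_logit(np.asarray(y, dtype=float), Xf)
        red = fit_logit(np.asarray(y, dtype=float), Xr)
    else:
        raise ValueError(f"unknown family {family!r}")
    stat = max(0.0, 2.0 * (full.llf - red.llf))
    df = 1
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return float(stat), df, p
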