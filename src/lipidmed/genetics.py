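"""Conditional-selection genetic scores for LDL-C-lowering drug-target genes.

Mimics pharmacological inhibition of a target (statins at HMGCR, bempedoic
acid at ACLY) with a weighted allele score built from variants in a +-500 kb
window around the gene: variants are selected by an iterative conditional
regression on LDL-C (smallest p first, LD partners with r^2 > 0.3 removed,
stop when no remaining variant reaches p < 0.05 conditionally), oriented so
the exposure allele lowers LDL-C, and weighted by their conditional effects
(mmol/l per exposure allele) in the final joint model.  Scores are
inverse-normal transformed, reported per 2-SD, and combined or median-split
for the joint and stratified lifestyle analyses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .associations import AssociationResult, fit_ols, interaction_lrt
from .metabolites import inverse_normal_transform


def ld_r2(dosages: pd.DataFrame, i: str, j: str) -> float:
    """Squared Pearson correlation between two dosage columns."""
    x = dosages[i].to_numpy(dtype=float)
    y = dosages[j].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"constant dosage column among ({i!r}, {j!r})")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


@dataclass
class GeneticScore:
    """A selected-variant score definition plus (optionally) participant scores."""

    gene: str
    variants: list[str]
    exposure_alleles: list[str]
    weights: list[float]  # conditional |effect| in mmol/l per exposure allele
    conditional_p: list[float]
    raw_effects: list[float]  # signed conditional effect per alt allele
    raw_scores: pd.Series | None = field(default=None, repr=False)
    standardized_scores: pd.Series | None = field(default=None, repr=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene": self.gene,
                "variants": self.variants,
                "exposure_alleles": self.exposure_alleles,
                "weights": self.weights,
                "conditional_p": self.conditional_p,
                "raw_effects": self.raw_effects,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GeneticScore":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# fast OLS helpers (the selection loop fits many small models)


def _ols_stats(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficients, SEs and two-sided p-values for y ~ X (X includes a constant)."""
    n, p = X.shape
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), n - p)
    return beta, se, pvals


def conditional_select_variants(
    dosages: pd.DataFrame,
    variant_meta: pd.DataFrame,
    ldlc: pd.Series,
    covariates: pd.DataFrame,
    gene_window: str,
    r2_threshold: float = 0.3,
    p_stop: float = 0.05,
) -> GeneticScore:
    """Iterative conditional selection of score variants within a gene window.

    At each step every remaining candidate is tested for association with
    LDL-C adjusted for the covariates and all previously selected variants;
    the smallest-p candidate is selected if its p-value is below ``p_stop``
    (ties broken by genomic position), and remaining candidates with
    ``r^2 > r2_threshold`` to it are removed.  Weights are the conditional
    effects from the final joint model; the exposure allele is the one whose
    dosage lowers LDL-C.  Monomorphic variants are excluded up front.
    """
    meta = variant_meta.set_index("variant_id") if "variant_id" in variant_meta.columns else variant_meta
    in_window = [v for v in dosages.columns if meta.loc[v, "gene_window"] == gene_window]
    if not in_window:
        warnings.warn(f"no variants in gene window {gene_window!r}: empty score")
        return GeneticScore(gene_window, [], [], [], [], [])
    candidates = [v for v in in_window if np.ptp(dosages[v].to_numpy()) > 0]

    y = ldlc.to_numpy(dtype=float)
    n = y.size
    base = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    selected: list[str] = []

    while candidates:
        sel_mat = dosages[selected].to_numpy(dtype=float) if selected else np.empty((n, 0))
        best = None  # (p, pos, variant)
        for v in candidates:
            X = np.column_stack([base, sel_mat, dosages[v].to_numpy(dtype=float)])
            _, _, pvals = _ols_stats(X, y)
            key = (pvals[-1], int(meta.loc[v, "pos"]), v)
            if best is None or key < best:
                best = key
        p_best, _, v_best = best
        if p_best >= p_stop:
            break
        selected.append(v_best)
        keep = []
        for v in candidates:
            if v == v_best:
                continue
            if ld_r2(dosages, v, v_best) > r2_threshold:
                continue
            keep.append(v)
        candidates = keep

    if not selected:
        warnings.warn(f"no variant reached p < {p_stop} in window {gene_window!r}: empty score")
        return GeneticScore(gene_window, [], [], [], [], [])

    X = np.column_stack([base, dosages[selected].to_numpy(dtype=float)])
    beta, _, pvals = _ols_stats(X, y)
    k0 = base.shape[1]
    effects = beta[k0:]
    final_p = pvals[k0:]
    exposure_alleles = []
    weights = []
    for v, eff in zip(selected, effects):
        if eff < 0:  # alt allele lowers LDL-C
            exposure_alleles.append(str(meta.loc[v, "alt"]))
        else:
            exposure_alleles.append(str(meta.loc[v, "ref"]))
        weights.append(abs(float(eff)))
    return GeneticScore(
        gene=gene_window,
        variants=selected,
        exposure_alleles=exposure_alleles,
        weights=weights,
        conditional_p=[float(p) for p in final_p],
        raw_effects=[float(e) for e in effects],
    )


def exposure_dosage(dosages: pd.DataFrame, variant_meta: pd.DataFrame, score: GeneticScore) -> pd.DataFrame:
    """Per-variant count of exposure (LDL-C-lowering) alleles."""
    meta = variant_meta.set_index("variant_id") if "variant_id" in variant_meta.columns else variant_meta
    out = {}
    for v, allele in zip(score.variants, score.exposure_alleles):
        if v not in dosages.columns:
            raise KeyError(f"variant {v!r} in score definition missing from genotypes")
        d = dosages[v].astype(float)
        out[v] = d if str(meta.loc[v, "alt"]) == allele else 2.0 - d
    return pd.DataFrame(out, index=dosages.index)


def build_score(
    dosages: pd.DataFrame, variant_meta: pd.DataFrame, score: GeneticScore
) -> GeneticScore:
    """Weighted sum of exposure-allele dosages, inverse-normal standardized."""
    if not score.variants:
        raise ValueError("empty score definition")
    ed = exposure_dosage(dosages, variant_meta, score)
    raw = ed @ np.asarray(score.weights)
    score.raw_scores = pd.Series(raw, index=dosages.index, name=f"{score.gene}_raw")
    score.standardized_scores = pd.Series(
        _standardize(raw.to_numpy(), score.gene), index=dosages.index, name=f"{score.gene}_std"
    )
    return score


def _standardize(raw: np.ndarray, gene: str) -> np.ndarray:
    if np.ptp(raw) == 0:  # degenerate (e.g. all weights zero): no information
        warnings.warn(f"score {gene!r} is constant across participants")
        return np.zeros_like(raw)
    return inverse_normal_transform(raw)


def sum_scores(score_a: GeneticScore, score_b: GeneticScore, gene: str = "combined") -> GeneticScore:
    """Element-wise sum of two raw scores over the same participants, restandardized."""
    if score_a.raw_scores is None or score_b.raw_scores is None:
        raise ValueError("build_score must be called on both scores first")
    if not score_a.raw_scores.index.equals(score_b.raw_scores.index):
        raise ValueError("participant mismatch between scores")
    raw = score_a.raw_scores + score_b.raw_scores
    out = GeneticScore(
        gene=gene,
        variants=score_a.variants + score_b.variants,
        exposure_alleles=score_a.exposure_alleles + score_b.exposure_alleles,
        weights=score_a.weights + score_b.weights,
        conditional_p=score_a.conditional_p + score_b.conditional_p,
        raw_effects=score_a.raw_effects + score_b.raw_effects,
    )
    out.raw_scores = raw.rename(f"{gene}_raw")
    out.standardized_scores = pd.Series(
        _standardize(raw.to_numpy(), gene), index=raw.index, name=f"{gene}_std"
    )
    return out


def score_association(
    score_std: pd.Series,
    metabolite: pd.Series,
    covariates: pd.DataFrame,
    marker: str = "",
    scale: float = 2.0,
) -> AssociationResult:
    """Association of a ``scale``-SD (default 2-SD) score increase with a marker."""
    X = pd.concat([score_std.astype(float).rename("score"), covariates], axis=1)
    res = fit_ols(metabolite.to_numpy(dtype=float), X)
    return AssociationResult(
        marker=marker,
        contrast=f"per {scale:g}-SD score",
        estimate=scale * float(res.params["score"]),
        se=scale * float(res.bse["score"]),
        p=float(res.pvalues["score"]),
        n=len(score_std),
    )


def median_risk_group(score_std: pd.Series) -> pd.Series:
    """Median split of a protective (LDL-C-lowering) score.

    Scores at or above the median are the genetically 'low risk' stratum.
    """
    med = float(score_std.median())
    return pd.Series(
        np.where(score_std >= med, "low_risk", "high_risk"), index=score_std.index, name="score_group"
    )


def stratified_hlf_analysis(
    metabolite: pd.Series,
    hlf_count: pd.Series,
    score_std: pd.Series,
    covariates: pd.DataFrame,
    marker: str = "",
) -> dict:
    """HLF-metabolite association within genetic-score strata + interaction LRT."""
    group = median_risk_group(score_std)
    out: dict = {"strata": {}}
    for level in ("high_risk", "low_risk"):
        mask = (group == level).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"empty score stratum {level!r}")
        X = pd.concat(
            [hlf_count[mask].astype(float).rename("hlf_count"), covariates.loc[mask]], axis=1
        )
        res = fit_ols(metabolite[mask].to_numpy(dtype=float), X)
        out["strata"][level] = AssociationResult(
            marker=marker,
            contrast=f"per +1 HLF ({level} stratum)",
            estimate=float(res.params["hlf_count"]),
            se=float(res.bse["hlf_count"]),
            p=float(res.pvalues["hlf_count"]),
            n=int(mask.sum()),
        )
    _, _, p_int = interaction_lrt(
        metabolite,
        hlf_count.astype(float),
        (group == "low_risk").astype(float),
        covariates,
        family="linear",
    )
    out["p_interaction"] = p_int
    return out
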