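"""Synthetic nested case-control generator with known mediation ground truth.

Emulates the statistical structure the analysis assumes: a source cohort
aged 30-79 with five correlated healthy-lifestyle factors (HLFs) whose raw
questionnaire fields are generated consistently with the scoring rules; a
correlated ~61-marker lipidome driven by latent factors, the HLFs, and an
LDL-C genetic liability; LD-structured genotype dosages in +-500 kb
gene-window analogues; a rare logistic CHD outcome with direct and
metabolite-mediated lifestyle effects (plus stroke outcomes that are carried
but not modelled); and frequency-matched control sampling by age, sex and
study area.  Every dataset ships with the analytically known natural
direct/indirect effects per marker, so parameter recovery is testable
without any external data.

Randomness is a single seed expanded into independent per-stage substreams,
so stages can be regenerated in isolation and outputs are byte-identical
for identical parameters and seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .markers import MARKER_CLASSES, MARKER_NAMES

EDUCATION_LEVELS = ["primary_or_less", "middle_high", "college"]
AREAS = [f"area{i}" for i in range(1, 11)]

#: six diet components with Table-1-like popularity used when drawing which
#: components make up a given diet score
_DIET_POPULARITY = {
    "diet_veg_daily": 0.93,
    "diet_fruit_daily": 0.12,
    "diet_red_meat_lt7": 0.72,
    "diet_soybean_ge4": 0.08,
    "diet_fish_ge1": 0.32,
    "diet_grains_ge4": 0.22,
}

HLF_TRUE_COLS = [
    "true_never_smoking",
    "true_moderate_alcohol",
    "true_healthy_diet",
    "true_physically_active",
    "true_healthy_adiposity",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class VariantSpec:
    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    allele_freq: float
    ldl_effect: float  # mmol/l per alt allele
    ld_block_id: str
    gene_window: str

    def __post_init__(self) -> None:
        if not 0.01 < self.allele_freq < 0.99:
            raise ValueError(f"allele_freq {self.allele_freq} outside (0.01, 0.99)")


@dataclass
class OutcomeParams:
    """Logistic CHD model: logit p = intercept + d*count + t'M + covariate terms.

    ``intercept=None`` means: calibrate on the realized cohort so the
    marginal risk equals ``target_marginal_risk`` (rare-outcome regime).
    """

    direct_hlf_log_or: float
    metabolite_log_ors: np.ndarray
    covariate_log_ors: dict[str, float] = field(default_factory=dict)
    intercept: float | None = None
    target_marginal_risk: float = 0.02


@dataclass
class GenerativeParams:
    n_source: int
    hlf_prevalences: np.ndarray
    lifestyle_covariate_effects: np.ndarray  # 5 x 3: per (age_std, female, edu_std)
    hlf_latent_corr: float
    marker_names: list[str]
    metabolite_loading_matrix: np.ndarray  # n_markers x n_factors
    lifestyle_effect_matrix: np.ndarray  # n_markers x 5, SD units per HLF
    metabolite_genetic_effects: np.ndarray  # n_markers, SD per 1-SD LDL genetic liability
    variant_spec: list[VariantSpec]
    outcome_model: OutcomeParams
    n_cases_chd: int
    n_cases_is: int
    n_cases_ich: int
    n_controls: int
    n_selection: int
    seed: int
    ld_adjacent_r: float = 0.8
    stroke_marginal_risk: float = 0.025
    female_frac: float = 0.55

    def __post_init__(self) -> None:
        self.hlf_prevalences = np.asarray(self.hlf_prevalences, dtype=float)
        if np.any((self.hlf_prevalences <= 0) | (self.hlf_prevalences >= 1)):
            raise ValueError("hlf_prevalences must lie in (0, 1)")
        B = np.asarray(self.lifestyle_effect_matrix, dtype=float)
        if B.shape != (len(self.marker_names), 5):
            raise ValueError(
                f"lifestyle_effect_matrix has shape {B.shape}, "
                f"expected {(len(self.marker_names), 5)}"
            )
        if len(self.outcome_model.metabolite_log_ors) != len(self.marker_names):
            raise ValueError("metabolite_log_ors length must match marker panel")

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)


@dataclass
class SimulationTruth:
    """Analytically known per-marker mediation effects (oracle for recovery tests)."""

    marker_names: list[str]
    true_nie_log_or: np.ndarray
    true_nde_log_or: np.ndarray
    true_te_log_or: float
    true_pm: np.ndarray
    causal_variant_ids: list[str]
    method: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "marker_names": self.marker_names,
                "true_nie_log_or": list(map(float, self.true_nie_log_or)),
                "true_nde_log_or": list(map(float, self.true_nde_log_or)),
                "true_te_log_or": float(self.true_te_log_or),
                "true_pm": list(map(float, self.true_pm)),
                "causal_variant_ids": self.causal_variant_ids,
                "method": self.method,
            },
            indent=2,
        )


@dataclass
class StudyData:
    """One generated study: nested case-control set + genetic selection cohort."""

    analysis: pd.DataFrame  # cases + frequency-matched controls
    metabolites_raw: pd.DataFrame  # aligned to analysis index
    dosages_analysis: pd.DataFrame
    selection: pd.DataFrame  # age/sex/ancestry PCs/LDL-C for score selection
    dosages_selection: pd.DataFrame
    variant_meta: pd.DataFrame
    truth: SimulationTruth
    activity_thresholds: dict[str, float] | None = None  # source-cohort sex medians
    source: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# defaults


def default_variant_spec() -> list[VariantSpec]:
    """Two drug-target gene-window analogues (statin / ACLY-inhibitor targets),
    five LD blocks of five variants each; three causal variants per window."""
    freqs = [0.12, 0.2, 0.3, 0.4, 0.25]
    out: list[VariantSpec] = []
    for window, chrom, base in (("HMGCR", "5", 74_000_000), ("ACLY", "17", 41_800_000)):
        causal = {(0, 2): -0.09, (2, 1): 0.07, (4, 3): -0.12}  # (block, idx) -> effect
        for b in range(5):
            for j in range(5):
                out.append(
                    VariantSpec(
                        variant_id=f"{window.lower()}_b{b}v{j}",
                        chrom=chrom,
                        pos=base + b * 100_000 + j * 15_000,
                        ref="A",
                        alt="G",
                        allele_freq=freqs[(b + j) % 5],
                        ldl_effect=causal.get((b, j), 0.0),
                        ld_block_id=f"{window}_block{b}",
                        gene_window=window,
                    )
                )
    return out


def default_lifestyle_effects(marker_names: list[str]) -> np.ndarray:
    """Per-HLF marker effects (SD units), equal across the five factors so the
    mediator is exactly linear in the HLF count."""
    per_hlf = []
    for m in marker_names:
        cls = MARKER_CLASSES[m]
        per_hlf.append({"vldl": -0.12, "idl": -0.05, "ldl": -0.05, "hdl": 0.10, "size": -0.06}[cls])
    return np.tile(np.asarray(per_hlf)[:, None], (1, 5))


def default_loadings(marker_names: list[str], n_factors: int = 5) -> np.ndarray:
    """Class-structured factor loadings: one dominant factor per lipoprotein
    class plus a small shared lipid factor, giving a realistic correlated panel."""
    fac = {"vldl": 0, "idl": 1, "ldl": 1, "hdl": 2, "size": 3}
    L = np.zeros((len(marker_names), n_factors))
    for i, m in enumerate(marker_names):
        L[i, fac[MARKER_CLASSES[m]]] = 0.93
        L[i, 4] = 0.32  # shared lipid factor
        if m.endswith("-TG") or m in ("Total-TG",):
            L[i, 3] += 0.20
    return L


def default_metabolite_log_ors(marker_names: list[str]) -> np.ndarray:
    """Outcome log-ORs per marker SD: a handful of causal markers (apoB-like
    atherogenic particles positive, large-HDL protective)."""
    t = np.zeros(len(marker_names))
    causal = {"ApoB": 0.25, "S-VLDL-TG": 0.18, "L-HDL-C": -0.18, "LDL-C": 0.15, "M-VLDL-P": 0.15}
    for name, val in causal.items():
        t[marker_names.index(name)] = val
    return t


def default_params(
    n_source: int = 80_000,
    seed: int = 0,
    n_cases_chd: int = 927,
    n_cases_is: int = 1114,
    n_cases_ich: int = 1127,
    n_controls: int = 1513,
    n_selection: int = 13_060,
) -> GenerativeParams:
    names = list(MARKER_NAMES)
    cov_eff = np.array(
        [
            [-0.02, 0.35, 0.02],  # never smoking: younger, strongly female, educated
            [0.00, -0.08, 0.02],  # moderate alcohol: less common in women
            [-0.03, 0.05, 0.06],  # healthy diet
            [-0.04, 0.02, 0.01],  # physically active
            [-0.04, 0.03, 0.01],  # healthy adiposity
        ]
    )
    return GenerativeParams(
        n_source=n_source,
        hlf_prevalences=np.array([0.60, 0.12, 0.45, 0.50, 0.55]),
        lifestyle_covariate_effects=cov_eff,
        hlf_latent_corr=0.10,
        marker_names=names,
        metabolite_loading_matrix=default_loadings(names),
        lifestyle_effect_matrix=default_lifestyle_effects(names),
        metabolite_genetic_effects=_default_genetic_effects(names),
        variant_spec=default_variant_spec(),
        outcome_model=OutcomeParams(
            direct_hlf_log_or=-0.10,
            metabolite_log_ors=default_metabolite_log_ors(names),
            covariate_log_ors={"age_std": 0.45, "sex_male": 0.50},
        ),
        n_cases_chd=n_cases_chd,
        n_cases_is=n_cases_is,
        n_cases_ich=n_cases_ich,
        n_controls=n_controls,
        n_selection=n_selection,
        seed=seed,
    )


def _default_genetic_effects(marker_names: list[str]) -> np.ndarray:
    g = np.zeros(len(marker_names))
    for name, val in {"LDL-C": 0.35, "ApoB": 0.28, "Total-C": 0.25, "non-HDL-C": 0.30,
                      "M-LDL-C": 0.25, "S-LDL-C": 0.22, "IDL-C": 0.18}.items():
        g[marker_names.index(name)] = val
    return g


def recovery_params(true_pm: float, seed: int, n_source: int = 60_000) -> GenerativeParams:
    """Single-marker fixture with exactly known proportion mediated.

    Fixes TE = -0.5 per +1 HLF and theta2 = 0.4, so beta1 = pm * TE / theta2
    and the direct effect absorbs the remainder; the strong total effect keeps
    the O(1/n) ratio bias of pm = NIE/TE well below its Monte-Carlo noise at
    the fixture's case-control size.
    """
    te = -0.5
    theta2 = 0.4
    beta1 = true_pm * te / theta2
    base = default_params(seed=seed)
    return GenerativeParams(
        n_source=n_source,
        hlf_prevalences=base.hlf_prevalences,
        lifestyle_covariate_effects=base.lifestyle_covariate_effects,
        hlf_latent_corr=base.hlf_latent_corr,
        marker_names=["marker1"],
        metabolite_loading_matrix=np.array([[0.6, 0.0, 0.0, 0.0, 0.0]]),
        lifestyle_effect_matrix=np.full((1, 5), beta1),
        metabolite_genetic_effects=np.zeros(1),
        variant_spec=default_variant_spec()[:5],  # genotypes unused downstream here
        outcome_model=OutcomeParams(
            direct_hlf_log_or=te - theta2 * beta1,
            metabolite_log_ors=np.array([theta2]),
            covariate_log_ors={"age_std": 0.45, "sex_male": 0.50},
        ),
        n_cases_chd=900,
        n_cases_is=50,
        n_cases_ich=50,
        n_controls=1500,
        n_selection=100,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# stage generators


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _simulate_covariates(n: int, rng: np.random.Generator, female_frac: float) -> pd.DataFrame:
    age = np.clip(rng.normal(50.5, 10.5, n), 30.0, 79.0)
    sex = np.where(rng.random(n) < female_frac, "female", "male")
    area = rng.choice(AREAS, size=n)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=[0.45, 0.40, 0.15])
    age_std = (age - age.mean()) / age.std()
    df = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "area": area,
            "education": education,
            "married": rng.random(n) < 0.94,
            "fasting_ge_8h": rng.random(n) < 0.35,
            "prevalent_hypertension": rng.random(n) < expit(-0.3 + 0.8 * age_std),
            "prevalent_diabetes": rng.random(n) < expit(-2.8 + 0.7 * age_std),
            "statin_use": rng.random(n) < 0.03,
            "prior_cvd_cancer": rng.random(n) < 0.04,
        }
    )
    df.index = pd.Index([f"P{i:07d}" for i in range(n)], name="participant_id")
    return df


def _covariate_design_for_hlf(cov: pd.DataFrame) -> np.ndarray:
    age_std = (cov["age"] - cov["age"].mean()) / cov["age"].std()
    female = (cov["sex"] == "female").astype(float)
    female = female - female.mean()
    edu = cov["education"].map({l: i for i, l in enumerate(EDUCATION_LEVELS)}).astype(float)
    edu = (edu - edu.mean()) / edu.std()
    return np.column_stack([age_std, female, edu])


def _simulate_lifestyle(
    cov: pd.DataFrame, params: GenerativeParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate HLF truth flags via a Gaussian copula, then raw questionnaire
    fields consistent with the scoring definitions."""
    n = len(cov)
    rho = params.hlf_latent_corr
    R = np.full((5, 5), rho) + (1 - rho) * np.eye(5)
    Z = rng.multivariate_normal(np.zeros(5), R, size=n, method="cholesky")
    X = _covariate_design_for_hlf(cov)
    shifts = X @ params.lifestyle_covariate_effects.T  # n x 5, probability scale
    from scipy.stats import norm

    out = pd.DataFrame(index=cov.index)
    flags = {}
    for k, name in enumerate(HLF_TRUE_COLS):
        if k == 3:
            continue  # activity handled below via its realized median
        p_k = np.clip(params.hlf_prevalences[k] + shifts[:, k], 0.02, 0.98)
        flags[name] = Z[:, k] < norm.ppf(p_k)

    # physical activity: continuous MET-h/day; truth flag = sex-specific median split
    female = (cov["sex"] == "female").to_numpy()
    mu_log = np.where(female, 2.85, 3.00)
    log_act = mu_log + 0.55 * (Z[:, 3] + 3.0 * shifts[:, 3])
    activity = np.round(np.exp(log_act), 2)  # rounded before the median split
    active = np.zeros(n, dtype=bool)
    for mask in (female, ~female):
        med = np.median(activity[mask])
        active[mask] = activity[mask] >= med
    flags["true_physically_active"] = active

    # --- raw fields consistent with the flags ---
    smoke = np.where(
        flags["true_never_smoking"], "never", np.where(rng.random(n) < 0.3, "former", "current")
    )

    mod = flags["true_moderate_alcohol"]
    freq = np.empty(n, dtype=object)
    grams = np.zeros(n)
    weekly = rng.random(n) < 0.7
    freq[mod & weekly] = "weekly"
    grams[mod & weekly] = rng.uniform(5, 40, (mod & weekly).sum())
    freq[mod & ~weekly] = "daily"
    grams[mod & ~weekly] = rng.uniform(5, 29.5, (mod & ~weekly).sum())
    u = rng.random(n)
    nm = ~mod
    freq[nm & (u < 0.55)] = "never"
    freq[nm & (u >= 0.55) & (u < 0.75)] = "monthly"
    grams[nm & (u >= 0.55) & (u < 0.75)] = rng.uniform(1, 15, ((u >= 0.55) & (u < 0.75) & nm).sum())
    heavy = nm & (u >= 0.75)
    freq[heavy] = "daily"
    grams[heavy] = rng.uniform(30, 80, heavy.sum())

    healthy_diet = flags["true_healthy_diet"]
    score = np.where(
        healthy_diet,
        rng.choice([4, 5, 6], size=n, p=[0.62, 0.30, 0.08]),
        rng.choice([0, 1, 2, 3], size=n, p=[0.08, 0.20, 0.34, 0.38]),
    )
    comp_names = list(_DIET_POPULARITY)
    logw = np.log(np.array([_DIET_POPULARITY[c] for c in comp_names]))
    gumbel = rng.gumbel(size=(n, 6))
    order = np.argsort(-(logw[None, :] + gumbel), axis=1)
    diet = np.zeros((n, 6), dtype=bool)
    rows = np.arange(n)
    for j in range(6):
        diet[rows, order[:, j]] |= j < score
    diet_df = pd.DataFrame(diet, columns=comp_names, index=cov.index)

    healthy_adip = flags["true_healthy_adiposity"]
    wc_cut = np.where(female, 85.0, 90.0)
    bmi = np.empty(n)
    wc = np.empty(n)
    h = healthy_adip
    bmi[h] = np.clip(rng.normal(23.5, 2.2, h.sum()), 18.6, 27.85)
    wc[h] = np.minimum(rng.normal(np.where(female, 74, 79)[h], 6.0), wc_cut[h] - 0.2)
    uh = ~h
    mode = rng.random(n)
    under = uh & (mode < 0.10)
    obese = uh & (mode >= 0.10) & (mode < 0.60)
    bigwc = uh & (mode >= 0.60)
    bmi[under] = rng.uniform(15.5, 18.4, under.sum())
    wc[under] = rng.normal(68, 5, under.sum())
    bmi[obese] = 28.0 + rng.exponential(2.5, obese.sum())
    wc[obese] = wc_cut[obese] + rng.normal(5, 6, obese.sum())
    bmi[bigwc] = np.clip(rng.normal(25.5, 1.8, bigwc.sum()), 18.6, 27.85)
    wc[bigwc] = wc_cut[bigwc] + np.abs(rng.normal(0, 6, bigwc.sum())) + 0.1

    out["smoking_status"] = smoke
    out["alcohol_freq"] = freq
    out["alcohol_g_per_day"] = np.round(grams, 1)
    for c in comp_names:
        out[c] = diet_df[c]
    out["activity_met_h"] = activity
    out["bmi"] = np.round(bmi, 1)
    out["wc"] = np.round(wc, 1)
    for name in HLF_TRUE_COLS:
        out[name] = flags[name]
    out["hlf_count_true"] = out[HLF_TRUE_COLS].sum(axis=1).astype(int)
    return out


def simulate_genotypes(
    n: int,
    variant_spec: list[VariantSpec],
    seed: int | np.random.Generator,
    ld_adjacent_r: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosages in {0,1,2} with block LD structure, plus variant metadata.

    Haplotypes are latent multivariate Gaussians per LD block (correlation
    ``ld_adjacent_r^|i-j|`` between block positions) thresholded at each
    variant's allele frequency, so margins are Hardy-Weinberg and
    cross-block variants are independent.
    """
    if not variant_spec:
        raise ValueError("variant_spec is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from scipy.stats import norm

    cols = {}
    blocks: dict[str, list[VariantSpec]] = {}
    for v in variant_spec:
        blocks.setdefault(v.ld_block_id, []).append(v)
    for block_variants in blocks.values():
        k = len(block_variants)
        idx = np.arange(k)
        R = ld_adjacent_r ** np.abs(idx[:, None] - idx[None, :])
        L = np.linalg.cholesky(R + 1e-10 * np.eye(k))
        thr = norm.ppf([v.allele_freq for v in block_variants])
        dos = np.zeros((n, k), dtype=np.int8)
        for _hap in range(2):
            Z = rng.standard_normal((n, k)) @ L.T
            dos += Z < thr
        for j, v in enumerate(block_variants):
            cols[v.variant_id] = dos[:, j]
    dosages = pd.DataFrame(cols)
    dosages.index = pd.Index([f"P{i:07d}" for i in range(n)], name="participant_id")
    meta = pd.DataFrame(
        [
            {
                "variant_id": v.variant_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "allele_freq": v.allele_freq,
                "ldl_effect": v.ldl_effect,
                "ld_block_id": v.ld_block_id,
                "gene_window": v.gene_window,
            }
            for v in variant_spec
        ]
    )
    return dosages[[v.variant_id for v in variant_spec]], meta


def _simulate_metabolites(
    lifestyle: pd.DataFrame,
    cov: pd.DataFrame,
    genetic_liability: np.ndarray,
    params: GenerativeParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Markers = factor structure + HLF effects + genetic liability + noise,
    calibrated to ~unit total variance so effects are on the SD scale."""
    n = len(lifestyle)
    L = np.asarray(params.metabolite_loading_matrix, dtype=float)
    B = np.asarray(params.lifestyle_effect_matrix, dtype=float)
    gam = np.asarray(params.metabolite_genetic_effects, dtype=float)
    factors = rng.standard_normal((n, L.shape[1]))
    flags = lifestyle[HLF_TRUE_COLS].to_numpy(dtype=float)
    g = genetic_liability
    g_std = (g - g.mean()) / g.std() if g.std() > 0 else np.zeros_like(g)
    age_std = ((cov["age"] - cov["age"].mean()) / cov["age"].std()).to_numpy()
    male = (cov["sex"] == "male").to_numpy(dtype=float)
    systematic = (
        factors @ L.T
        + flags @ B.T
        + g_std[:, None] * gam[None, :]
        + age_std[:, None] * 0.08
        + (male - male.mean())[:, None] * 0.05
    )
    noise_var = np.clip(1.0 - systematic.var(axis=0), 0.04, None)
    values = systematic + rng.standard_normal((n, len(params.marker_names))) * np.sqrt(noise_var)
    return pd.DataFrame(values, columns=params.marker_names, index=lifestyle.index)


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    return brentq(lambda t: expit(t + lp).mean() - target, -25.0, 5.0, xtol=1e-10)


def _simulate_outcome(
    cov: pd.DataFrame,
    lifestyle: pd.DataFrame,
    metabolites: pd.DataFrame,
    params: GenerativeParams,
    rng: np.random.Generator,
) -> pd.Series:
    n = len(cov)
    om = params.outcome_model
    age_std = ((cov["age"] - cov["age"].mean()) / cov["age"].std()).to_numpy()
    male = (cov["sex"] == "male").to_numpy(dtype=float)
    covterm = om.covariate_log_ors.get("age_std", 0.0) * age_std + om.covariate_log_ors.get(
        "sex_male", 0.0
    ) * male
    lp = (
        om.direct_hlf_log_or * lifestyle["hlf_count_true"].to_numpy(dtype=float)
        + metabolites.to_numpy() @ np.asarray(om.metabolite_log_ors, dtype=float)
        + covterm
    )
    theta0 = om.intercept if om.intercept is not None else _calibrate_intercept(lp, om.target_marginal_risk)
    p_chd = expit(theta0 + lp)

    lp_stroke = 0.5 * age_std + 0.3 * male
    t_is = _calibrate_intercept(lp_stroke, params.stroke_marginal_risk)
    t_ich = _calibrate_intercept(lp_stroke, params.stroke_marginal_risk)
    p_is = expit(t_is + lp_stroke)
    p_ich = expit(t_ich + lp_stroke)

    u = rng.random(n)
    status = np.full(n, "control", dtype=object)
    status[u < p_chd] = "chd_case"
    status[(u >= p_chd) & (u < p_chd + p_is)] = "ischemic_stroke_case"
    status[(u >= p_chd + p_is) & (u < p_chd + p_is + p_ich)] = "ich_case"
    return pd.Series(status, index=cov.index, name="status")


# ---------------------------------------------------------------------------
# nested case-control sampling


def age_bins(age: pd.Series, width: float = 5.0) -> pd.Series:
    """Five-year age bins used for frequency matching."""
    lo = 30.0
    b = (np.floor((age - lo) / width)).astype(int)
    return pd.Series([f"[{lo + width * i:.0f},{lo + width * (i + 1):.0f})" for i in b], index=age.index)


def sample_nested_case_control(
    source: pd.DataFrame,
    n_cases_by_type: dict[str, int],
    n_controls: int,
    rng: np.random.Generator | int = 0,
    matching_vars: tuple[str, ...] = ("age_bin", "sex", "area"),
) -> pd.DataFrame:
    """Cases plus controls frequency-matched to the combined cases.

    Eligibility mirrors the design: no prior cardiovascular disease or
    cancer and no statin use at baseline.  Controls are drawn without
    replacement so their joint (5-year age bin, sex, area) distribution
    matches the combined-case distribution in frequency; a stratum with too
    few eligible controls raises an error naming the stratum.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    elig = source[~source["statin_use"] & ~source["prior_cvd_cancer"]].copy()
    elig["age_bin"] = age_bins(elig["age"])

    case_parts = []
    for status, n_req in n_cases_by_type.items():
        pool = elig[elig["status"] == status]
        if len(pool) < n_req:
            raise ValueError(
                f"requested {n_req} cases of type {status!r} but only {len(pool)} "
                f"eligible are available (shortfall {n_req - len(pool)})"
            )
        take = rng.choice(len(pool), size=n_req, replace=False)
        case_parts.append(pool.iloc[np.sort(take)])
    cases = pd.concat(case_parts)

    strata = cases.groupby(list(matching_vars), observed=True).size()
    shares = strata / strata.sum()
    alloc = np.floor(shares * n_controls).astype(int)
    remainder = n_controls - int(alloc.sum())
    if remainder > 0:
        frac = shares * n_controls - alloc
        for key in frac.sort_values(ascending=False).index[:remainder]:
            alloc[key] += 1

    ctrl_pool = elig[elig["status"] == "control"]
    grouped = ctrl_pool.groupby(list(matching_vars), observed=True)
    ctrl_parts = []
    for key, n_req in alloc.items():
        if n_req == 0:
            continue
        try:
            pool = grouped.get_group(key)
        except KeyError:
            raise ValueError(f"no eligible controls in matching stratum {key}") from None
        if len(pool) < n_req:
            raise ValueError(
                f"matching stratum {key} exhausted: need {n_req} controls, have {len(pool)}"
            )
        take = rng.choice(len(pool), size=n_req, replace=False)
        ctrl_parts.append(pool.iloc[np.sort(take)])
    out = pd.concat([cases] + ctrl_parts).drop(columns=["age_bin"])
    return out


# ---------------------------------------------------------------------------
# ground truth


def true_mediation_effects(
    params: GenerativeParams,
    method: str = "closed_form",
    n_mc: int = 1_000_000,
    seed: int = 12345,
) -> SimulationTruth:
    """True per-marker NDE/NIE/TE log-ORs for the +1-HLF-count contrast.

    ``closed_form`` integrates the Gaussian mediator analytically (exact for
    the generative model, which is linear in the HLF count with no
    exposure-mediator interaction): NIE_m = theta2_m * beta1_m, the total
    effect is shared across markers (direct effect + all mediated paths),
    and NDE_m = TE - NIE_m, i.e. other markers' paths count as not-through-
    this-marker.  ``mc`` recomputes the same quantities by counterfactual
    Monte-Carlo over the generative distribution (factor, genetic and noise
    randomness; covariates at reference) as an independent check.
    """
    if params.outcome_model.target_marginal_risk >= 0.05 and params.outcome_model.intercept is None:
        warnings.warn("marginal risk >= 5%: OR does not approximate RR; truth values are RR-scale")
    B = np.asarray(params.lifestyle_effect_matrix, dtype=float)
    if not np.allclose(B, B[:, [0]]):
        warnings.warn(
            "lifestyle_effect_matrix columns differ across HLFs: the mediator is "
            "not exactly linear in the count; using the column mean for beta1"
        )
    beta1 = B.mean(axis=1)
    t = np.asarray(params.outcome_model.metabolite_log_ors, dtype=float)
    d = params.outcome_model.direct_hlf_log_or
    nie = t * beta1
    te = d + float(t @ beta1)
    if method == "mc":
        nie_mc, te_mc = _mc_truth(params, n_mc, seed)
        nie, te = nie_mc, te_mc
    elif method != "closed_form":
        raise ValueError(f"unknown method {method!r}")
    nde = te - nie
    with np.errstate(divide="ignore", invalid="ignore"):
        pm = np.where(te != 0, nie / te, np.nan)
    causal = [v.variant_id for v in params.variant_spec if v.ldl_effect != 0]
    return SimulationTruth(
        marker_names=list(params.marker_names),
        true_nie_log_or=nie,
        true_nde_log_or=nde,
        true_te_log_or=float(te),
        true_pm=pm,
        causal_variant_ids=causal,
        method=method,
    )


def _mc_truth(params: GenerativeParams, n_mc: int, seed: int) -> tuple[np.ndarray, float]:
    """Counterfactual MC integration of NIE/TE under the generative model.

    Exposure set to a* = mean count and a = a* + 1 with mediators responding
    per the structural equations; log-linear (rare-outcome) risk contrasts.
    """
    rng = np.random.default_rng(seed)
    L = np.asarray(params.metabolite_loading_matrix, dtype=float)
    B = np.asarray(params.lifestyle_effect_matrix, dtype=float)
    beta1 = B.mean(axis=1)
    t = np.asarray(params.outcome_model.metabolite_log_ors, dtype=float)
    d = params.outcome_model.direct_hlf_log_or
    n_markers = len(params.marker_names)
    factors = rng.standard_normal((n_mc, L.shape[1]))
    noise = rng.standard_normal((n_mc, n_markers))
    noise_sd = np.sqrt(np.clip(1.0 - (L**2).sum(axis=1), 0.05, None))
    base = factors @ L.T + noise * noise_sd
    a_star, a = 0.0, 1.0  # only the contrast matters under log-linearity

    def log_mean_risk(a_y: float, a_m: float, marker: int | None) -> float:
        m_all = base + a_m * beta1[None, :]
        if marker is not None:  # counterfactual shift in one marker only
            m_all = base + a_star * beta1[None, :]
            m_all[:, marker] = base[:, marker] + a_m * beta1[marker]
        lp = d * a_y + m_all @ t
        return float(np.log(np.exp(lp).mean()))

    te = log_mean_risk(a, a, None) - log_mean_risk(a_star, a_star, None)
    nie = np.array(
        [
            log_mean_risk(a, a, m) - log_mean_risk(a, a_star, m) if t[m] != 0 else 0.0
            for m in range(n_markers)
        ]
    )
    return nie, te


# ---------------------------------------------------------------------------
# top-level generation


def simulate_cohort(
    params: GenerativeParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate the full source cohort.

    Returns ``(cohort, metabolites, dosages, variant_meta, truth)`` with all
    tables indexed by participant id.  Deterministic given ``params.seed``.
    """
    rngs = _substreams(params.seed, 6)
    cov = _simulate_covariates(params.n_source, rngs[0], params.female_frac)
    lifestyle = _simulate_lifestyle(cov, params, rngs[1])
    dosages, meta = simulate_genotypes(
        params.n_source, params.variant_spec, rngs[2], params.ld_adjacent_r
    )
    effects = meta.set_index("variant_id")["ldl_effect"]
    liability = dosages.to_numpy(dtype=float) @ effects.loc[dosages.columns].to_numpy()
    metabolites = _simulate_metabolites(lifestyle, cov, liability, params, rngs[3])
    status = _simulate_outcome(cov, lifestyle, metabolites, params, rngs[4])

    # ancestry PCs and LDL-C for the genetic-score stages
    n = params.n_source
    apcs = rngs[5].standard_normal((n, 10))
    age_std = ((cov["age"] - cov["age"].mean()) / cov["age"].std()).to_numpy()
    female = (cov["sex"] == "female").to_numpy(dtype=float)
    ldlc = (
        2.30
        + liability
        + 0.10 * age_std
        - 0.10 * female
        + 0.05 * apcs[:, 0]
        - 0.04 * apcs[:, 1]
        + rngs[5].normal(0.0, 0.55, n)
    )
    cohort = pd.concat([cov, lifestyle], axis=1)
    cohort["status"] = status
    cohort["ldlc"] = np.round(ldlc, 4)
    for j in range(10):
        cohort[f"apc{j + 1}"] = np.round(apcs[:, j], 4)
    truth = true_mediation_effects(params)
    return cohort, metabolites, dosages, meta, truth


def simulate_study(params: GenerativeParams, keep_source: bool = False) -> StudyData:
    """Source cohort -> nested case-control analysis set + disjoint selection cohort."""
    cohort, metabolites, dosages, meta, truth = simulate_cohort(params)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(7)[6])
    analysis = sample_nested_case_control(
        cohort,
        {
            "chd_case": params.n_cases_chd,
            "ischemic_stroke_case": params.n_cases_is,
            "ich_case": params.n_cases_ich,
        },
        params.n_controls,
        rng=rng,
    )
    remaining = cohort.drop(index=analysis.index)
    elig = remaining[~remaining["statin_use"] & ~remaining["prior_cvd_cancer"]]
    if len(elig) < params.n_selection:
        raise ValueError(
            f"selection cohort needs {params.n_selection} participants, "
            f"only {len(elig)} eligible remain"
        )
    take = rng.choice(len(elig), size=params.n_selection, replace=False)
    selection = elig.iloc[np.sort(take)]
    from .lifestyle import activity_threshold

    return StudyData(
        analysis=analysis,
        metabolites_raw=metabolites.loc[analysis.index],
        dosages_analysis=dosages.loc[analysis.index],
        selection=selection[["age", "sex", "ldlc"] + [f"apc{j + 1}" for j in range(10)]],
        dosages_selection=dosages.loc[selection.index],
        variant_meta=meta,
        truth=truth,
        activity_thresholds=activity_threshold(cohort),
        source=cohort if keep_source else None,
    )
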