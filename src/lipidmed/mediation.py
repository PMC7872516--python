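"""Parametric causal mediation for a continuous mediator and rare binary outcome.

The estimand chain: a linear model for the mediator given the exposure (the
HLF count, continuous) and covariates, fitted in controls only; a logistic
model for CHD given exposure, mediator, their optional product, and
covariates, fitted in CHD cases + controls.  Under the rare-outcome
approximation the natural direct and indirect effects on the log odds-ratio
scale have closed forms:

    NIE = (theta2 * beta1 + theta3 * beta1 * a) * (a - a*)
    NDE = [theta1 + theta3 * (beta0 + beta1 a* + beta2'c + theta2 sigma^2)]
          * (a - a*) + 0.5 * theta3^2 sigma^2 (a^2 - a*^2)
    TE  = NDE + NIE

with the mediator model M = beta0 + beta1 A + beta2'C + eps, eps ~ N(0,
sigma^2), and the outcome model logit P(Y=1) = theta0 + theta1 A + theta2 M
+ theta3 A M + theta4'C.  Standard errors come from the delta method over
the stacked (beta, sigma^2, theta) parameter vector with a block-diagonal
covariance (the two fits treated as independent), and the proportion
mediated is NIE / TE on the log-odds scale.

The four-way decomposition splits the total effect, on the excess relative
risk scale, into a controlled direct effect, reference interaction,
mediated interaction, and pure indirect effect; under the same
approximation each component is an explicit function of the two model fits
(Gaussian moment-generating function in the mediator), and the four
components sum to the total excess relative risk as an algebraic identity.
When the outcome model contains no product term the decomposition is
reported in its degenerate form (interaction components exactly zero, the
natural-effect split carried to the excess-RR scale), since the fitted
model structurally excludes interaction.

A Monte-Carlo counterfactual oracle (exact logistic risks, Bernoulli
outcomes, no rarity approximation) is provided for cross-checking the
closed forms, together with a nonparametric bootstrap for the delta-method
standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .associations import bh_fdr, fit_logit, fit_ols, interaction_lrt

Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# model containers


@dataclass
class MediatorModel:
    """OLS fit of the mediator on exposure + covariates (controls only)."""

    beta0: float
    beta1: float
    beta2: np.ndarray  # covariate effects, aligned with cov_names
    sigma2: float
    vcov: np.ndarray  # covariance of (beta0, beta1, beta2...)
    n: int
    n_params: int
    cov_names: list[str]

    @property
    def sigma2_var(self) -> float:
        """Sampling variance of the residual-variance estimate, 2 sigma^4 / (n - p)."""
        return 2.0 * self.sigma2**2 / (self.n - self.n_params)

    def mean(self, a: float, c: np.ndarray) -> float:
        """Model mean of the mediator at exposure ``a`` and covariates ``c``."""
        return self.beta0 + self.beta1 * a + float(self.beta2 @ c)


@dataclass
class OutcomeModel:
    """Logistic fit of CHD on exposure, mediator, optional product, covariates."""

    theta0: float
    theta1: float
    theta2: float
    theta3: float  # 0.0 when the product term is disabled
    theta4: np.ndarray
    vcov: np.ndarray  # covariance of (theta0, theta1, theta2[, theta3], theta4...)
    interaction: bool
    n: int
    cov_names: list[str]


@dataclass
class MediationResult:
    marker: str
    a: float
    a_star: float
    nde: float
    nie: float
    te: float
    nde_se: float
    nie_se: float
    te_se: float
    pm: float
    pm_se: float
    p_nie: float
    cde: float
    int_ref: float
    int_med: float
    pie: float
    prop_cde: float
    prop_int_ref: float
    prop_int_med: float
    prop_pie: float
    interaction: bool
    p_interaction: float = field(default=np.nan)
    p_fdr: float = field(default=np.nan)
    inconsistent: bool = field(default=False)

    @property
    def pm_pct(self) -> float:
        return 100.0 * self.pm

    def ci(self, which: str) -> tuple[float, float]:
        est = getattr(self, which)
        se = getattr(self, f"{which}_se")
        return est - Z95 * se, est + Z95 * se


def results_to_frame(results: list[MediationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = vars(r).copy()
        d["pm_pct"] = r.pm_pct
        for which in ("nde", "nie", "te"):
            lo, hi = r.ci(which)
            d[f"{which}_ci_low"], d[f"{which}_ci_high"] = lo, hi
            d[f"or_{which}"] = float(np.exp(getattr(r, which)))
        rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model fitting


def fit_mediator_model(
    mediator: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame,
    status: pd.Series,
) -> MediatorModel:
    """Linear mediator model, estimated in control participants only.

    ``status`` is required so the controls-only contract is enforced rather
    than assumed.
    """
    if (status != "control").any():
        bad = sorted(set(status.unique()) - {"control"})
        raise ValueError(f"mediator model must be fitted on controls only; found {bad}")
    X = pd.concat([exposure.astype(float).rename("exposure"), covariates], axis=1)
    res = fit_ols(mediator.to_numpy(dtype=float), X)
    params = res.params
    cov_names = list(covariates.columns)
    beta2 = np.array([params[c] for c in cov_names])
    # reorder vcov to (const, exposure, covariates...)
    order = ["const", "exposure"] + cov_names
    vcov = res.cov_params().loc[order, order].to_numpy()
    return MediatorModel(
        beta0=float(params["const"]),
        beta1=float(params["exposure"]),
        beta2=beta2,
        sigma2=float(res.mse_resid),
        vcov=vcov,
        n=int(res.nobs),
        n_params=len(order),
        cov_names=cov_names,
    )


def fit_outcome_model(
    status: pd.Series,
    mediator: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame,
    interaction: bool = False,
) -> OutcomeModel:
    """Logistic CHD model on cases + controls (stroke cases excluded upstream)."""
    levels = set(status.unique())
    if not levels <= {"control", "chd_case"}:
        raise ValueError(f"outcome model expects controls and CHD cases only, got {sorted(levels)}")
    y = (status == "chd_case").astype(float).to_numpy()
    cols = {
        "exposure": exposure.astype(float),
        "mediator": mediator.astype(float),
    }
    if interaction:
        cols["exp_x_med"] = cols["exposure"] * cols["mediator"]
    X = pd.concat([pd.DataFrame(cols, index=covariates.index), covariates], axis=1)
    res = fit_logit(y, X)
    params = res.params
    cov_names = list(covariates.columns)
    order = ["const", "exposure", "mediator"] + (["exp_x_med"] if interaction else []) + cov_names
    vcov = res.cov_params().loc[order, order].to_numpy()
    return OutcomeModel(
        theta0=float(params["const"]),
        theta1=float(params["exposure"]),
        theta2=float(params["mediator"]),
        theta3=float(params["exp_x_med"]) if interaction else 0.0,
        theta4=np.array([params[c] for c in cov_names]),
        vcov=vcov,
        interaction=interaction,
        n=int(res.nobs),
        cov_names=cov_names,
    )


def covariate_reference(covariates: pd.DataFrame) -> np.ndarray:
    """Reference covariate vector: means for continuous, modes for indicators."""
    c = []
    for col in covariates.columns:
        vals = covariates[col].to_numpy(dtype=float)
        uniq = np.unique(vals)
        if uniq.size <= 2 and set(uniq) <= {0.0, 1.0}:
            c.append(float(stats.mode(vals, keepdims=False).mode))
        else:
            c.append(float(vals.mean()))
    return np.asarray(c)


# ---------------------------------------------------------------------------
# closed-form effects


def natural_effects(
    mm: MediatorModel, om: OutcomeModel, a: float, a_star: float, c: np.ndarray
) -> dict[str, float]:
    """Closed-form NDE / NIE / TE on the log odds-ratio scale (rare outcome)."""
    if a == a_star:
        raise ValueError("exposure contrast requires a != a*")
    c = np.asarray(c, dtype=float)
    d = a - a_star
    bc = mm.beta0 + mm.beta1 * a_star + float(mm.beta2 @ c)
    nie = (om.theta2 * mm.beta1 + om.theta3 * mm.beta1 * a) * d
    nde = (om.theta1 + om.theta3 * (bc + om.theta2 * mm.sigma2)) * d + 0.5 * om.theta3**2 * mm.sigma2 * (
        a**2 - a_star**2
    )
    return {"nde": float(nde), "nie": float(nie), "te": float(nde + nie)}


def proportion_mediated(nde: float, nie: float) -> tuple[float, bool]:
    """NIE / TE on the log-odds scale; flags the inconsistent-signs case.

    Returns ``(pm, inconsistent)``; 0 indicates no mediation.  Raises when
    TE = 0 (proportion undefined).
    """
    te = nde + nie
    if te == 0:
        raise ZeroDivisionError("total effect is zero: proportion mediated undefined")
    inconsistent = (nde != 0) and (nie != 0) and (np.sign(nde) != np.sign(nie))
    return nie / te, inconsistent


def _log_mean_risk(om: OutcomeModel, mm: MediatorModel, a_y: float, a_m: float, c: np.ndarray) -> float:
    """log E[exp(linear predictor)] with M ~ N(mu(a_m), sigma^2): Gaussian MGF."""
    s = om.theta2 + om.theta3 * a_y
    mu = mm.mean(a_m, c)
    return om.theta0 + om.theta1 * a_y + float(om.theta4 @ c) + s * mu + 0.5 * s**2 * mm.sigma2


def _log_risk_at(om: OutcomeModel, a_y: float, m: float, c: np.ndarray) -> float:
    return om.theta0 + om.theta1 * a_y + om.theta2 * m + om.theta3 * a_y * m + float(om.theta4 @ c)


def four_way_decomposition(
    mm: MediatorModel,
    om: OutcomeModel,
    a: float,
    a_star: float,
    c: np.ndarray,
    m_star: float | None = None,
) -> dict[str, float]:
    """Four-way decomposition on the excess relative risk scale.

    Components (``cde``, ``int_ref``, ``int_med``, ``pie``) are normalized by
    the counterfactual baseline risk at ``a*`` and sum exactly to the total
    excess RR; ``proportions`` divide by the total.  ``m_star`` defaults to
    the fitted mediator mean at ``a*``.  When the outcome model has no
    product term the interaction components are structurally zero and the
    natural-effect split is carried to the excess-RR scale.
    """
    c = np.asarray(c, dtype=float)
    if m_star is None:
        m_star = mm.mean(a_star, c)
    kappa = np.exp(_log_mean_risk(om, mm, a_star, a_star, c))
    w = lambda ay, am: np.exp(_log_mean_risk(om, mm, ay, am, c)) / kappa
    if om.theta3 == 0.0:
        cde = w(a, a_star) - 1.0
        int_ref = 0.0
        int_med = 0.0
        pie = w(a, a) - w(a, a_star)
    else:
        v = lambda ay, m: np.exp(_log_risk_at(om, ay, m, c)) / kappa
        cde = v(a, m_star) - v(a_star, m_star)
        int_ref = w(a, a_star) - 1.0 - cde
        int_med = w(a, a) - w(a, a_star) - w(a_star, a) + 1.0
        pie = w(a_star, a) - 1.0
    total = w(a, a) - 1.0
    out = {
        "cde": float(cde),
        "int_ref": float(int_ref),
        "int_med": float(int_med),
        "pie": float(pie),
        "total_err": float(total),
        "m_star": float(m_star),
    }
    if abs(total) < 1e-12:
        warnings.warn("total excess RR ~ 0: four-way proportions undefined")
        for k in ("cde", "int_ref", "int_med", "pie"):
            out[f"prop_{k}"] = np.nan
    else:
        for k in ("cde", "int_ref", "int_med", "pie"):
            out[f"prop_{k}"] = float(out[k] / total)
    return out


# ---------------------------------------------------------------------------
# delta-method uncertainty


def stack_params(mm: MediatorModel, om: OutcomeModel) -> tuple[np.ndarray, np.ndarray, dict]:
    """Stacked parameter vector (beta, sigma2, theta) and block-diagonal covariance."""
    k = len(mm.beta2)
    beta = np.concatenate([[mm.beta0, mm.beta1], mm.beta2])
    theta_core = [om.theta0, om.theta1, om.theta2] + ([om.theta3] if om.interaction else [])
    theta = np.concatenate([theta_core, om.theta4])
    phi = np.concatenate([beta, [mm.sigma2], theta])
    n_b, n_t = beta.size, theta.size
    sigma = np.zeros((phi.size, phi.size))
    sigma[:n_b, :n_b] = mm.vcov
    sigma[n_b, n_b] = mm.sigma2_var
    sigma[n_b + 1 :, n_b + 1 :] = om.vcov
    layout = {
        "b0": 0,
        "b1": 1,
        "b2": np.arange(2, 2 + k),
        "sigma2": n_b,
        "t0": n_b + 1,
        "t1": n_b + 2,
        "t2": n_b + 3,
        "t3": n_b + 4 if om.interaction else None,
        "t4": np.arange(n_b + (5 if om.interaction else 4), n_b + 1 + n_t),
        "size": phi.size,
    }
    return phi, sigma, layout


def _effect_gradients(
    mm: MediatorModel, om: OutcomeModel, a: float, a_star: float, c: np.ndarray
) -> dict[str, np.ndarray]:
    """Analytic gradients of NDE / NIE / TE w.r.t. the stacked parameters."""
    _, _, L = stack_params(mm, om)
    c = np.asarray(c, dtype=float)
    d = a - a_star
    t2, t3 = om.theta2, om.theta3
    b1, s2 = mm.beta1, mm.sigma2
    bc = mm.beta0 + mm.beta1 * a_star + float(mm.beta2 @ c)

    g_nie = np.zeros(L["size"])
    g_nie[L["b1"]] = (t2 + t3 * a) * d
    g_nie[L["t2"]] = b1 * d
    if L["t3"] is not None:
        g_nie[L["t3"]] = a * b1 * d

    g_nde = np.zeros(L["size"])
    g_nde[L["t1"]] = d
    g_nde[L["t2"]] = d * t3 * s2
    g_nde[L["b0"]] = d * t3
    g_nde[L["b1"]] = d * t3 * a_star
    g_nde[L["b2"]] = d * t3 * c
    g_nde[L["sigma2"]] = d * t3 * t2 + 0.5 * t3**2 * (a**2 - a_star**2)
    if L["t3"] is not None:
        g_nde[L["t3"]] = d * (bc + t2 * s2) + t3 * s2 * (a**2 - a_star**2)

    return {"nie": g_nie, "nde": g_nde, "te": g_nie + g_nde}


def delta_method_ci(
    mm: MediatorModel,
    om: OutcomeModel,
    a: float,
    a_star: float,
    c: np.ndarray,
) -> dict[str, dict[str, float]]:
    """Delta-method SEs, Wald CIs and p-values for NDE, NIE, TE and pm.

    The variance of each estimand is ``g' Sigma g`` with ``Sigma``
    block-diagonal across the two model fits (including the sampling
    variance of sigma^2).
    """
    _, sigma, _ = stack_params(mm, om)
    eff = natural_effects(mm, om, a, a_star, c)
    grads = _effect_gradients(mm, om, a, a_star, c)
    te = eff["te"]
    if te != 0:
        grads["pm"] = (grads["nie"] * te - eff["nie"] * grads["te"]) / te**2
        eff = dict(eff, pm=eff["nie"] / te)
    out: dict[str, dict[str, float]] = {}
    for name, g in grads.items():
        var = float(g @ sigma @ g)
        if var < 0:
            raise ValueError("negative delta-method variance: singular covariance")
        se = float(np.sqrt(var))
        est = eff[name]
        z = est / se if se > 0 else np.inf * np.sign(est)
        out[name] = {
            "estimate": float(est),
            "se": se,
            "ci_low": est - Z95 * se,
            "ci_high": est + Z95 * se,
            "p": float(2 * stats.norm.sf(abs(z))) if se > 0 else 0.0,
        }
    return out


def numerical_gradient(f, phi: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of the stacked parameters."""
    g = np.zeros_like(phi)
    for i in range(phi.size):
        h = eps * max(1.0, abs(phi[i]))
        up, dn = phi.copy(), phi.copy()
        up[i] += h
        dn[i] -= h
        g[i] = (f(up) - f(dn)) / (2 * h)
    return g


def effects_from_stacked(
    phi: np.ndarray, mm: MediatorModel, om: OutcomeModel, a: float, a_star: float, c: np.ndarray
) -> dict[str, float]:
    """Natural effects evaluated at an arbitrary stacked parameter vector.

    Used by the finite-difference cross-check of the analytic gradients.
    """
    _, _, L = stack_params(mm, om)
    mm2 = MediatorModel(
        beta0=phi[L["b0"]],
        beta1=phi[L["b1"]],
        beta2=phi[L["b2"]],
        sigma2=phi[L["sigma2"]],
        vcov=mm.vcov,
        n=mm.n,
        n_params=mm.n_params,
        cov_names=mm.cov_names,
    )
    om2 = OutcomeModel(
        theta0=phi[L["t0"]],
        theta1=phi[L["t1"]],
        theta2=phi[L["t2"]],
        theta3=phi[L["t3"]] if L["t3"] is not None else 0.0,
        theta4=phi[L["t4"]],
        vcov=om.vcov,
        interaction=om.interaction,
        n=om.n,
        cov_names=om.cov_names,
    )
    return natural_effects(mm2, om2, a, a_star, c)


# ---------------------------------------------------------------------------
# Monte-Carlo counterfactual oracle


def mc_counterfactuals(
    mm: MediatorModel,
    om: OutcomeModel,
    a: float,
    a_star: float,
    c: np.ndarray,
    n_draws: int = 1_000_000,
    seed: int = 0,
    m_star: float | None = None,
    risk_model: str = "loglinear",
) -> dict[str, dict[str, float]]:
    """Simulation-based natural effects and four-way components with MC SEs.

    Draws the mediator from the fitted normal model under each exposure
    level, draws Bernoulli outcomes from the outcome model's risk, and forms
    the effect contrasts from the simulated counterfactual arms: the
    independent oracle for the closed forms.

    ``risk_model="loglinear"`` (default) simulates the rare-outcome risk
    ``exp(lp)`` whose Gaussian integral the closed forms evaluate, so any
    disagreement beyond MC noise indicates an integration error.
    ``risk_model="logistic"`` simulates the exact logistic risk ``expit(lp)``
    and forms odds ratios; its deviation from the closed forms additionally
    measures the rare-outcome approximation itself (of order the baseline
    risk).
    """
    if risk_model not in ("loglinear", "logistic"):
        raise ValueError(f"unknown risk_model {risk_model!r}")
    rng = np.random.default_rng(seed)
    c = np.asarray(c, dtype=float)
    if m_star is None:
        m_star = mm.mean(a_star, c)
    sd = np.sqrt(mm.sigma2)

    def arm(a_y: float, m_vals: np.ndarray) -> tuple[float, float]:
        lp = (
            om.theta0
            + om.theta1 * a_y
            + (om.theta2 + om.theta3 * a_y) * m_vals
            + float(om.theta4 @ c)
        )
        p = np.minimum(np.exp(lp), 1.0) if risk_model == "loglinear" else 1.0 / (1.0 + np.exp(-lp))
        y = rng.random(m_vals.size) < p
        k = max(int(y.sum()), 1)  # continuity guard for empty cells
        phat = k / m_vals.size
        return phat, k

    m_a = mm.mean(a, c) + sd * rng.standard_normal(n_draws)
    m_as = mm.mean(a_star, c) + sd * rng.standard_normal(n_draws)
    arms = {
        "aa": arm(a, m_a),  # Y_{a, M_a}
        "aas": arm(a, m_as),  # Y_{a, M_a*}
        "asa": arm(a_star, m_a),  # Y_{a*, M_a}
        "asas": arm(a_star, m_as),  # Y_{a*, M_a*}
        "am": arm(a, np.full(n_draws, m_star)),  # Y_{a, m*}
        "asm": arm(a_star, np.full(n_draws, m_star)),  # Y_{a*, m*}
    }
    p = {k: v[0] for k, v in arms.items()}
    cnt = {k: v[1] for k, v in arms.items()}

    def log_ratio(k1: str, k0: str) -> tuple[float, float]:
        if risk_model == "logistic":  # odds ratio, the reporting scale of the analysis
            o1 = p[k1] / (1 - p[k1])
            o0 = p[k0] / (1 - p[k0])
            est = np.log(o1 / o0)
            se = np.sqrt(
                1 / cnt[k1] + 1 / (n_draws - cnt[k1]) + 1 / cnt[k0] + 1 / (n_draws - cnt[k0])
            )
        else:  # risk ratio, exactly what the closed forms compute
            est = np.log(p[k1] / p[k0])
            se = np.sqrt((1 - p[k1]) / cnt[k1] + (1 - p[k0]) / cnt[k0])
        return float(est), float(se)

    out: dict[str, dict[str, float]] = {}
    for name, (k1, k0) in {"nde": ("aas", "asas"), "nie": ("aa", "aas"), "te": ("aa", "asas")}.items():
        est, se = log_ratio(k1, k0)
        out[name] = {"estimate": est, "se": se}

    # excess-RR components; SEs via independent-arm binomial variances
    kap = p["asas"]
    var_p = {k: p[k] * (1 - p[k]) / n_draws for k in p}

    def comp(terms: list[tuple[str, float]]) -> dict[str, float]:
        est = sum(w * p[k] for k, w in terms) / kap
        var = sum((w / kap) ** 2 * var_p[k] for k, w in terms if k != "asas")
        # baseline in the denominator: first-order contribution
        dk = -est / kap
        var += dk**2 * var_p["asas"]
        return {"estimate": float(est), "se": float(np.sqrt(var))}

    out["cde"] = comp([("am", 1.0), ("asm", -1.0)])
    out["int_ref"] = comp([("aas", 1.0), ("asas", -1.0), ("am", -1.0), ("asm", 1.0)])
    out["int_med"] = comp([("aa", 1.0), ("aas", -1.0), ("asa", -1.0), ("asas", 1.0)])
    out["pie"] = comp([("asa", 1.0), ("asas", -1.0)])
    out["total_err"] = comp([("aa", 1.0), ("asas", -1.0)])
    return out


# ---------------------------------------------------------------------------
# high-level per-marker analysis


def mediate_one(
    data: pd.DataFrame,
    mediator_col: str,
    exposure_col: str,
    covariates: pd.DataFrame,
    a: float | None = None,
    a_star: float | None = None,
    interaction: str = "auto",
    c: np.ndarray | None = None,
) -> MediationResult:
    """Full mediation analysis for one marker on a CHD-cases + controls table.

    ``interaction`` is ``"on"``, ``"off"``, or ``"auto"`` (screen with the
    likelihood-ratio test at 0.05, mirroring the reported screen where no
    marker retained an interaction); the exposure contrast defaults to one
    additional HLF around the sample mean.
    """
    status = data["status"]
    controls = status == "control"
    exposure = data[exposure_col].astype(float)
    if a_star is None:
        a_star = float(exposure.mean())
    if a is None:
        a = a_star + 1.0

    mm = fit_mediator_model(
        data.loc[controls, mediator_col],
        exposure[controls],
        covariates.loc[controls],
        status[controls],
    )
    p_int = np.nan
    if interaction == "auto":
        _, _, p_int = interaction_lrt(
            (status == "chd_case").astype(float),
            exposure,
            data[mediator_col],
            covariates,
            family="logistic",
        )
        use_interaction = p_int < 0.05
    elif interaction in ("on", "off"):
        use_interaction = interaction == "on"
    else:
        raise ValueError(f"interaction policy must be auto|on|off, got {interaction!r}")

    om = fit_outcome_model(status, data[mediator_col], exposure, covariates, use_interaction)
    if c is None:
        c = covariate_reference(covariates.loc[controls])
    stats_out = delta_method_ci(mm, om, a, a_star, c)
    eff = natural_effects(mm, om, a, a_star, c)
    pm, inconsistent = proportion_mediated(eff["nde"], eff["nie"])
    fw = four_way_decomposition(mm, om, a, a_star, c)
    return MediationResult(
        marker=mediator_col,
        a=a,
        a_star=a_star,
        nde=eff["nde"],
        nie=eff["nie"],
        te=eff["te"],
        nde_se=stats_out["nde"]["se"],
        nie_se=stats_out["nie"]["se"],
        te_se=stats_out["te"]["se"],
        pm=pm,
        pm_se=stats_out.get("pm", {}).get("se", np.nan),
        p_nie=stats_out["nie"]["p"],
        cde=fw["cde"],
        int_ref=fw["int_ref"],
        int_med=fw["int_med"],
        pie=fw["pie"],
        prop_cde=fw["prop_cde"],
        prop_int_ref=fw["prop_int_ref"],
        prop_int_med=fw["prop_int_med"],
        prop_pie=fw["prop_pie"],
        interaction=use_interaction,
        p_interaction=p_int,
        inconsistent=inconsistent,
    )


def mediate_all(
    data: pd.DataFrame,
    marker_cols: list[str],
    exposure_col: str,
    covariates: pd.DataFrame,
    interaction: str = "auto",
) -> list[MediationResult]:
    """Per-marker mediation across the panel, with BH-FDR over the NIE p-values."""
    results = [
        mediate_one(data, m, exposure_col, covariates, interaction=interaction)
        for m in marker_cols
    ]
    adj = bh_fdr([r.p_nie for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
    return results


def joint_mediation_via_pcs(
    data: pd.DataFrame,
    pc_cols: list[str],
    exposure_col: str,
    covariates: pd.DataFrame,
    a: float | None = None,
    a_star: float | None = None,
) -> dict[str, float]:
    """Joint mediated proportion through the top principal components.

    One mediator model per PC (controls only) and a single outcome model
    containing all PCs (no interactions); the joint NIE is the sum over
    components of theta2_k * beta1_k * (a - a*), and the joint pm divides by
    the common total effect.
    """
    status = data["status"]
    controls = status == "control"
    exposure = data[exposure_col].astype(float)
    if a_star is None:
        a_star = float(exposure.mean())
    if a is None:
        a = a_star + 1.0
    d = a - a_star

    beta1 = {}
    for pc in pc_cols:
        mmk = fit_mediator_model(
            data.loc[controls, pc], exposure[controls], covariates.loc[controls], status[controls]
        )
        beta1[pc] = mmk.beta1

    y = (status == "chd_case").astype(float).to_numpy()
    X = pd.concat(
        [exposure.rename("exposure"), data[pc_cols].astype(float), covariates], axis=1
    )
    res = fit_logit(y, X)
    joint_nie = sum(float(res.params[pc]) * beta1[pc] for pc in pc_cols) * d
    nde = float(res.params["exposure"]) * d
    te = nde + joint_nie
    if te == 0:
        raise ZeroDivisionError("total effect is zero: joint pm undefined")
    return {
        "joint_nie": float(joint_nie),
        "nde": float(nde),
        "te": float(te),
        "joint_pm": float(joint_nie / te),
        "per_pc_nie": {pc: float(res.params[pc]) * beta1[pc] * d for pc in pc_cols},
    }


# ---------------------------------------------------------------------------
# bootstrap cross-check


def bootstrap_effects(
    data: pd.DataFrame,
    mediator_col: str,
    exposure_col: str,
    covariate_terms_builder,
    n_boot: int = 500,
    seed: int = 0,
    interaction: str = "off",
) -> pd.DataFrame:
    """Nonparametric bootstrap of NDE / NIE / TE (resampling cases and
    controls separately to preserve the case-control design).

    ``covariate_terms_builder`` maps a resampled table to its covariate
    design, so factor levels are re-derived per resample.
    """
    rng = np.random.default_rng(seed)
    cases = data[data["status"] == "chd_case"]
    ctrls = data[data["status"] == "control"]
    rows = []
    for _ in range(n_boot):
        bs = pd.concat(
            [
                cases.sample(len(cases), replace=True, random_state=rng.integers(2**31)),
                ctrls.sample(len(ctrls), replace=True, random_state=rng.integers(2**31)),
            ]
        ).reset_index(drop=True)
        cov = covariate_terms_builder(bs)
        r = mediate_one(bs, mediator_col, exposure_col, cov, interaction=interaction)
        rows.append({"nde": r.nde, "nie": r.nie, "te": r.te})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dichotomization-bias experiment


def dichotomization_bias_experiment(
    beta1_grid: list[float],
    n: int = 3000,
    n_sim: int = 200,
    seed: int = 0,
    theta1: float = -0.5,
    theta2: float = -0.4,
    theta0: float = -2.5,
) -> pd.DataFrame:
    """Bias in the proportion mediated when a continuous exposure is median-split.

    For each exposure->mediator effect size beta1 in the grid, simulates a
    continuous standard-normal exposure, mediator M = beta1*A + N(0,1), and a
    rare logistic outcome, then estimates pm using the continuous exposure
    and its median dichotomization.  Reports the mean pm under each coding
    and the Monte-Carlo SE of the bias (their difference).
    """
    if theta1 != 0 and theta2 != 0 and np.sign(theta1) != np.sign(theta2):
        warnings.warn("direct and mediated paths have opposite signs: the total "
                      "effect may cross zero over the grid and pm become unstable")
    rng = np.random.default_rng(seed)
    records = []
    empty_cov = lambda idx: pd.DataFrame(index=idx)
    for b1 in beta1_grid:
        pm_cont, pm_dich = [], []
        for _ in range(n_sim):
            a_vals = rng.standard_normal(n)
            m = b1 * a_vals + rng.standard_normal(n)
            lp = theta0 + theta1 * a_vals + theta2 * m
            y = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))
            df = pd.DataFrame(
                {
                    "exposure": a_vals,
                    "exposure_dich": (a_vals >= np.median(a_vals)).astype(float),
                    "marker": m,
                    "status": np.where(y, "chd_case", "control"),
                }
            )
            cov = empty_cov(df.index)
            try:
                r_c = mediate_one(df, "marker", "exposure", cov, interaction="off")
                r_d = mediate_one(
                    df, "marker", "exposure_dich", cov, a=1.0, a_star=0.0, interaction="off"
                )
            except (ValueError, ZeroDivisionError):
                continue
            pm_cont.append(r_c.pm)
            pm_dich.append(r_d.pm)
        pm_cont, pm_dich = np.asarray(pm_cont), np.asarray(pm_dich)
        bias = pm_dich - pm_cont
        records.append(
            {
                "beta1": b1,
                "n_ok": len(bias),
                "mean_pm_continuous": float(pm_cont.mean()),
                "mean_pm_dichotomized": float(pm_dich.mean()),
                "mean_bias": float(bias.mean()),
                "bias_mc_se": float(bias.std(ddof=1) / np.sqrt(len(bias))),
            }
        )
    return pd.DataFrame(records)
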