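# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `lipidmed`.

## Estimands and models

The exposure is the number of adopted healthy-lifestyle factors (HLFs),
treated as continuous; the default contrast is one additional factor around
the sample mean (a\* = mean HLF count, a = a\* + 1). Each lipidomic marker
is analysed in turn as the mediator on its inverse-normal (SD = 1) scale.

Two regression models are fitted per marker:

1. **Mediator model** (linear, controls only): M = β₀ + β₁A + β₂′C + ε,
   ε ~ N(0, σ²). Controls stand in for the source population under the
   rare-outcome assumption; fitting in cases would distort β because case
   status depends on M.
2. **Outcome model** (logistic, CHD cases + controls; stroke cases are
   carried in the data but excluded from every CHD model):
   logit P(Y=1) = θ₀ + θ₁A + θ₂M + θ₃AM + θ₄′C.

Covariates C are age (years), sex, fasting time (≥8 h), 10 study areas and
3 education levels in both models; the HLF→marker layer additionally
adjusts for case/control status, the marker→CHD layer for smoking status.

### Natural effects (rare outcome)

With a Gaussian mediator, the marginal odds ratios over M have closed
forms when the outcome is rare (the exponential-risk integral is the
Gaussian moment-generating function):

- log OR^NIE = (θ₂β₁ + θ₃β₁a)(a − a\*)
- log OR^NDE = [θ₁ + θ₃(β₀ + β₁a\* + β₂′c + θ₂σ²)](a − a\*)
  + ½θ₃²σ²(a² − a\*²)
- log OR^TE = NDE + NIE (identity), pm = NIE/TE on the log-odds scale,
  reported as a percentage and flagged "inconsistent" when NDE and NIE
  have opposite signs.

The covariate reference c is the control-sample mean for continuous
covariates and the mode for indicators; c only enters through the
interaction term, so it is irrelevant when θ₃ = 0.

### Four-way decomposition

On the excess relative-risk scale, relative to the counterfactual baseline
E[Y(a\*, M(a\*))], the total effect splits into a controlled direct effect
at mediator level m\* (default: the fitted mediator mean at a\*), a
reference interaction, a mediated interaction, and a pure indirect effect.
All four components are evaluated from the same Gaussian-MGF expressions,
so they sum to the total excess RR exactly (tested to 1e-10). When the
outcome model contains no product term the decomposition is reported in
its degenerate form — interaction components exactly zero and the
natural-effect split carried to the excess-RR scale — because the fitted
model structurally excludes interaction; the definitional components would
otherwise retain second-order terms of size ≈ ½θ₂²σ² · NDE that reflect
scale non-collapsibility, not interaction.

### Uncertainty

Standard errors come from the delta method on the stacked parameter vector
(β, σ², θ) with a block-diagonal covariance: the two fits are treated as
independent (the standard parametric-mediation construction; a
nonparametric bootstrap resampling cases and controls separately is
provided as the cross-check and agrees within a few percent at n = 2000).
The sampling variance of σ̂² (2σ⁴/(n−p)) is included. Gradients of
NDE/NIE/TE/pm are analytic and verified against central finite differences
to 1e-6; four-way component SEs use numerical gradients of the same
stacked parameterization. CIs are Wald (±1.96 SE) throughout, matching the
95% intervals the analyses report.

### Interaction policy

Per marker, an exposure×mediator likelihood-ratio test (1 df) screens for
interaction; under the default `auto` policy the product term is retained
only at p < 0.05, mirroring the analysis regime in which no marker retains
an interaction. Because the lipidomic panel is strongly correlated (whole
lipoprotein classes share a latent factor), these 61 screens behave like a
handful of effective tests: in a typical simulated study no marker flags,
but with probability roughly equal to the per-factor level an entire class
flags together in one dataset. This is multiplicity across correlated
tests, not a defect of the LRT, whose null p-values are uniform
(Kolmogorov–Smirnov check over 500 independent simulations).

### Joint mediation via principal components

The top five principal components of the transformed panel (≥95% of total
variance under the default generator) serve as a joint mediator set: one
linear mediator model per component (controls only), a single logistic
outcome model containing all five, joint NIE = Σₖ θ₂ₖβ₁ₖ(a − a\*) with no
interactions, and joint pm = joint NIE / TE. Summed per-component NIEs
equal the joint NIE by construction.

### Monte-Carlo counterfactual oracle

`mc_counterfactuals` simulates the mediator from the fitted normal model
under each exposure level and draws Bernoulli outcomes, forming the effect
contrasts from the simulated arms. Its default risk model is the
rare-outcome (log-linear) risk exp(lp), making it the exact independent
check of the closed forms' Gaussian integration: disagreement beyond
Monte-Carlo noise indicates an implementation error, and the acceptance
check requires |z| < 3 at 1e6 draws over randomized fixtures. The
exact-logistic mode (odds ratios from expit risks) is also provided; its
deviation from the closed forms measures the rare-outcome approximation
itself, of the order of the baseline risk (~2% here), and is checked
against a correspondingly looser tolerance.

## Transform, FDR, genetic scores

**Inverse-normal transform.** Φ⁻¹((r − 3/8)/(n + 1/4)) with Blom's offset
(any fixed offset preserves ranks; Blom is the common epidemiological
choice), average fractional ranks for ties, and a final rescaling by the
sample SD so every transformed column has SD exactly 1. Transformation is
computed on the pooled analysis sample (cases + controls), since the
association models adjust for case status. Constant columns and missing
values are errors.

**FDR.** Benjamini–Hochberg step-up over the marker panel, per contrast;
significance at 0.05. Verified against the direct min-over-ranks formula
and for false-discovery control on null correlated panels.

**Conditional variant selection.** Within a gene window: test every
candidate variant's association with LDL-C (linear model; age, sex, 10
ancestry PCs, plus all previously selected variants), select the smallest
p if below 0.05 (ties broken by genomic position — the procedure is
otherwise order-dependent), prune remaining candidates with r² > 0.3 to
the selection, iterate. Monomorphic variants are excluded up front.
Weights are conditional effects from the final joint model; the exposure
allele is whichever allele lowers LDL-C, so weights are positive and the
score is protective by construction. Scores are inverse-normal
standardized, reported per 2 SD, summed on the raw scale before
restandardization, and median-split for the joint and stratified analyses.
A degenerate (constant) score standardizes to zeros with a warning.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, with these
study conditions as defaults:

- **Source cohort** of 80,000 (60,000 in the analysis drivers, which
  comfortably supplies the case counts): age ~ N(50.5, 10.5²) truncated to
  30–79, 55% female, 10 equal study areas, 3 education levels, plus
  anthropometry, fasting, comorbidity, statin-use and prior-disease flags.
- **Five HLFs** from a Gaussian copula (exchangeable latent correlation
  0.10) with per-factor prevalences (0.60, 0.12, 0.45, ~0.50, 0.55) and
  age/sex/education effects on the probability scale chosen to reproduce
  the tabulated gradients (younger, female, more educated → healthier).
  Physical activity is generated as a continuous MET-h/day variable
  (per-sex log-normal); its truth flag is the realized sex-specific median
  split — its "prevalence" parameter only shapes the copula margin. Raw
  questionnaire fields (smoking status, drinking frequency and grams/day,
  six diet components, BMI, WC) are drawn conditionally on the truth flags
  so the scoring rules recover the flags exactly.
- **Lipidome**: 61 markers = class-structured factor loadings (VLDL, IDL/
  LDL, HDL, TG, shared-lipid factors; top-5 PCs ≈ 96% of variance) + equal
  per-HLF lifestyle effects (so the mediator is exactly linear in the HLF
  count) + an LDL-C genetic liability loading on LDL/IDL-class markers +
  small age/sex effects + noise calibrated so each marker has ~unit
  variance, putting all generative effects on the SD scale the analysis
  estimates.
- **Genotypes**: latent multivariate-Gaussian haplotypes per LD block,
  thresholded at each allele frequency (Hardy–Weinberg margins, adjacent
  latent correlation 0.8 decaying geometrically, independence across
  blocks); two gene windows of 25 variants with three causal LDL-C
  variants each.
- **Outcome**: logistic CHD risk with a direct HLF-count effect (−0.10 per
  factor), marker effects on a handful of causal markers, and age/sex
  terms; the intercept is calibrated on the realized cohort to a 2%
  marginal risk so the OR≈RR approximation underlying the closed forms
  holds. Stroke outcomes (2.5% each) are generated and carried but never
  modelled. Statuses are mutually exclusive by construction.
- **Sampling**: cases drawn from eligible participants (no statins, no
  prior cardiovascular disease/cancer); controls frequency-matched to the
  combined cases on 5-year age bin × sex × area by largest-remainder
  quota, without replacement, failing loudly when a stratum is exhausted.
  A disjoint selection cohort (default 13,060) is drawn for the genetic
  scores. One seed feeds independent per-stage substreams, so outputs are
  byte-identical given (params, seed).

**Ground truth.** With equal lifestyle-effect columns and no generative
interaction, the true per-marker NIE is θ₂ₘβ₁ₘ per +1 HLF; the total
effect (direct + all mediated paths) is shared across markers and the
per-marker NDE is TE − NIEₘ — i.e. other markers' paths count as "not
through this marker", which is what a per-marker proportion mediated
means. The closed form is the exact Gaussian integral of the generative
model; an independent Monte-Carlo integration mode cross-checks it.

**What the generator does not emulate:** real joint distributions beyond
the tabulated marginals; survival time (case status only, as in the nested
design); measurement error in the markers beyond the duplicate-CV summary;
population stratification beyond independent ancestry PCs; true
exposure–mediator interaction (θ₃ = 0 generatively, so interaction
machinery is validated on parametric fixtures instead). Passing tests
therefore demonstrate correctness of the estimators under the stated
parametric structure, not robustness to violations of it.

## Validation experiments and their problem sizes

- **Oracle equivalence**: 10 randomized rare-outcome fixtures (half with
  interaction), 1e6 draws; closed forms within 3 MC SEs.
- **Parameter recovery**: 200 nested case–control replicates per true pm ∈
  {0, 0.10, 0.25}; fixture TE = −0.5 per +1 HLF, θ₂ = 0.4, 900 CHD cases +
  1500 controls from a 60,000 source at 2% risk. The mean estimated pm is
  compared to truth within three empirical SEs of the estimator (the
  replicate SD). Two small intrinsic biases of the estimator, each of
  order 0.005 here, are visible at finer resolution and are properties of
  the method, not the implementation: conditioning the mediator model on
  controls (Y = 0) induces a collider association between exposure and
  mediator proportional to disease risk times the effect sizes, and
  pm = NIE/TE carries an O(1/n) ratio bias ≈ pm·var(TE)/TE². Replicates
  whose frequency matching is infeasible (a rare old-age stratum with more
  cases than eligible controls) are redrawn from a derived seed. The
  null-pm false-positive criterion (FDR-significant NIE) is ≤7%; observed
  ≈5%.
- **Delta vs bootstrap**: one n = 2000 fixture, 500 resamples; SE ratios
  within 15% (observed 1.02–1.04).
- **Genetic-score benchmark**: 50 seeds, 50 variants in 10 LD blocks,
  3 causal, n = 13,060; every causal block tagged in ≥90% of seeds
  (observed 100%), selected pairwise r² ≤ 0.3 always, and conditional
  weights calibrated (≥97% of z-scores within 3 SE).
- **Null calibration**: 500 interaction-LRT null simulations (KS
  uniformity); 100 null 61-marker panels with a shared latent factor for
  BH false-discovery control at 0.05 (observed FDP ≤ 0.07; under the
  global null the FDP equals the probability of any discovery).
- **Dichotomization bias**: median-splitting a continuous exposure leaves
  pm essentially unbiased when the exposure–mediator association is null,
  shifts it by ~0.01 at β₁ = 0.2, and distorts it substantially only at
  associations (β₁ ≥ 0.5 SD per SD) far stronger than lifestyle scores
  show against single metabolites; the bias is monotone in |β₁|.

## Numerical choices and degenerate inputs

- OLS via statsmodels (QR), logistic via Newton ML; rank-deficient designs
  fail listing the aliased columns; separation or non-convergence fails
  with the statsmodels diagnostic.
- LRT statistics are clipped at 0 (full and reduced models are nested).
- TE = 0 makes pm undefined (explicit error); total excess RR ≈ 0 makes
  four-way proportions NaN with a warning.
- Tie-breaks: equal selection p-values go to the smaller genomic position;
  BH adjustment is order-invariant.
- The frequency-matching quota uses the largest-remainder method, so
  control counts sum exactly to the requested total.

## Limitations

- All mediation estimands assume no unmeasured exposure–outcome,
  mediator–outcome or exposure–mediator confounding and no
  exposure-induced mediator–outcome confounding; no sensitivity analysis
  for these is provided.
- The rare-outcome approximation (2% default) contributes bias of the
  order of the baseline risk to the OR-scale effects.
- Per-marker proportions mediated over a correlated panel do not sum to a
  joint proportion; the PC-based joint estimate is the supported summary.
- The controls-only mediator model and the pm ratio carry the small-sample
  biases quantified above; at the default study size they are an order of
  magnitude below the estimator's SE.
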