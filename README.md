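# lipidmed

Combined healthy-lifestyle factors (HLFs) protect against coronary heart
disease (CHD), and a large part of that protection plausibly runs through
the blood lipidome. `lipidmed` implements the full analytic chain for
quantifying that pathway in a nested case–control study with an NMR-style
lipoprotein panel:

- **Lifestyle scoring** — five binary HLFs (never smoking; moderate alcohol
  use, i.e. weekly-but-not-daily drinking or daily drinking of <30 g pure
  alcohol; a healthy-diet score ≥4 of 6 components; physical activity at or
  above the sex-specific median; BMI 18.5–27.9 kg/m² with waist
  circumference <90 cm in men / <85 cm in women), their count (0–5) and the
  0–1 / 2–3 / 4–5 grouping, plus the sensitivity variants (strict adiposity
  cut-offs; alcohol dropped from the score).
- **Metabolite preparation** — rank-based inverse-normal transformation of
  each of ~61 lipoprotein/lipid measures (SD = 1), duplicate-QC
  coefficient-of-variation summaries, and principal components of the panel.
- **Association layers** — linear models for HLF groups → markers and
  logistic models for markers → CHD (per 1 SD), with the study's covariate
  sets and Benjamini–Hochberg FDR across markers.
- **Causal mediation** — the package's core: parametric natural-effect
  estimation for a continuous mediator and rare binary outcome, with
  optional exposure–mediator interaction, the four-way effect decomposition,
  delta-method standard errors, the proportion mediated (NIE/TE on the
  log-odds scale), and joint mediation through the top five principal
  components.
- **Genetic scores** — the iterative conditional variant-selection
  algorithm (smallest p first, LD pruning at r² > 0.3, stop at p ≥ 0.05)
  for drug-target gene windows (HMGCR/ACLY analogues mimicking statins and
  ACLY inhibitors), exposure-allele orientation toward lower LDL-C,
  conditional-effect weights, 2-SD score associations, score sums, and the
  joint/stratified score × lifestyle analyses.
- **Synthetic cohort generator** — a first-class module that emulates the
  nested case–control design (cases of CHD, ischemic stroke and
  intracerebral hemorrhage; controls frequency-matched by 5-year age bin,
  sex and study area) with known ground-truth mediation effects, so every
  stage is testable end to end without any restricted data.

## The model

For marker $M$, exposure $A$ (the HLF count, continuous) and covariates
$C$, two models are fitted:

$$M = \beta_0 + \beta_1 A + \beta_2' C + \varepsilon,\quad
\varepsilon \sim N(0,\sigma^2) \qquad \text{(controls only)}$$

$$\operatorname{logit} P(Y{=}1) = \theta_0 + \theta_1 A + \theta_2 M +
\theta_3 A M + \theta_4' C \qquad \text{(CHD cases + controls)}$$

Under the rare-outcome approximation the natural effects on the log-OR
scale are

$$\text{NIE} = (\theta_2\beta_1 + \theta_3\beta_1 a)(a-a^*), \qquad
\text{NDE} = \big[\theta_1 + \theta_3(\beta_0 + \beta_1 a^* + \beta_2'c +
\theta_2\sigma^2)\big](a-a^*) + \tfrac12\theta_3^2\sigma^2(a^2-a^{*2})$$

with TE = NDE + NIE and proportion mediated pm = NIE/TE. Standard errors
use the delta method over the stacked $(\beta,\sigma^2,\theta)$ vector. The
four-way decomposition (controlled direct effect, reference interaction,
mediated interaction, pure indirect effect) is computed on the excess
relative-risk scale, where the components sum to the total excess RR as an
algebraic identity. See `docs/methods.md` for assumptions, defaults, and
known limitations.

## Worked example

```bash
python analysis/02_full_pipeline.py 1      # seed 1
```

simulates a source cohort of 60,000, draws 927 CHD cases, 1114 ischemic
strokes, 1127 intracerebral hemorrhages and 1513 frequency-matched controls
(4681 participants), and runs every stage. It prints:

```
== lipidomic mediation analysis summary ==
markers analysed: 61
markers with FDR<0.05 mediation: 22
top mediators by proportion mediated:
  XL-VLDL-TG     pm =  20.30%  NIE = -0.0459 (p_fdr = 0.000336)
  M-VLDL-TG      pm =  20.25%  NIE = -0.0457 (p_fdr = 0.000336)
  Total-TG       pm =  19.98%  NIE = -0.0450 (p_fdr = 0.000336)
  ...
joint mediation via top PCs: 30.36% of the total effect
joint genetic-score x HLF groups (selected markers):
  ...
  LDL-C    low_risk score & 3-5 HLFs vs high_risk score & 0-2 HLFs: -0.503
conservation check: max |TE - (NDE+NIE)| = 1.39e-17
```

Reading this: 22 markers carry an FDR-significant share of the
lifestyle→CHD effect; VLDL-triglyceride measures are the strongest single
mediators (each ~20% of the total log-odds effect, reflecting the
generative truth for this synthetic study); jointly, the top five principal
components of the panel mediate 30% of the effect; and participants with a
protective (LDL-C-lowering) genetic score *and* 3–5 HLFs show the most
favourable lipid profile (−0.50 SD LDL-C vs the high-risk/0–2-HLF group).
The conservation line verifies the TE = NDE + NIE identity to machine
precision.

The numbered scripts under `analysis/` step through the same work:
`01_simulate_study.py` (generation), `02_full_pipeline.py` (all stages),
`03_mediation_validation.py` (closed form vs Monte-Carlo counterfactual
oracle; delta method vs bootstrap; pm parameter recovery),
`04_genetic_score_benchmark.py` (conditional-selection recovery),
`05_null_calibration.py` (interaction-LRT uniformity, FDR control),
`06_dichotomization_bias.py` (bias from median-splitting a continuous
exposure). A `lipidmed` console script exposes the stages as subcommands
(`lipidmed run-all --seed 1 --out results/run`).

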