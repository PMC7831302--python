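# Methods notes

This note records the statistical model behind the package, the defaults
and why they are what they are, and the design choices made where more than
one defensible convention exists. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The monitoring problem

A community nutrition program enrolls every household child under five
(rolling entry; exit at 60 months) and aims for monthly contact: growth
monitoring (length/height measured, giving a length/height-for-age z-score,
LAZ, with stunting = LAZ < −2) and micronutrient delivery. Program data is
visit-level and unbalanced: the same child appears at many time points,
children enter and leave continuously, and a quarter's subgroup is whatever
children happened to be measured. The analysis has two layers:

1. **Control charts** treat each quarter as a rational subgroup and ask
   whether the plotted statistic departs from a frozen baseline period by
   more than common-cause variation, via the four classic run rules.
2. **GEE regression** asks the same pre/post question while explicitly
   modeling the intra-child correlation that quarterly subgroups ignore —
   the sensitivity analysis for autocorrelation.

## Quarterly reduction

* Calendar quarters (Q1 = Jan–Mar). When a child has several measurements
  in one quarter, the one closest to the quarter midpoint is kept. The
  midpoint is defined as first day + ⌊(last − first)/2⌋ days (e.g. Q1 →
  Feb 14), and equidistant ties go to the earlier visit. Neither detail is
  standardized anywhere; both are fixed here so the reduction is
  deterministic and auditable.
* Subgroup SD uses the n−1 denominator — required for the S chart, whose
  c₄/B₃/B₄ constants are derived for the sample SD.
* Process indicators are child-month proportions: the denominator for a
  month is every child enrolled during that month (enrollment month and
  exit month count as full months — the simplest auditable rule), the
  numerator is children with the flag documented; the quarter's value is
  the mean of its three monthly proportions. A visit row with a missing
  LAZ still counts here; it is only excluded from anthropometric subgroups.
* Each child's birth month (needed for the under-60-months exit in the
  denominators) is inferred as the per-child median of visit month minus
  age in months, so the reduction runs on the visit file alone.

## Control charts

* **Baseline freezing.** Centerlines, P̄/X̄, and the process-SD estimate σ̂
  come from the baseline quarters only (default 2014Q4–2017Q4) and never
  change as monitoring quarters accrue. Limits do vary point by point
  through nᵢ.
* **p-chart.** P̄ is count-weighted (Σxᵢ/Σnᵢ). Limits P̄ ± 3√(P̄(1−P̄)/nᵢ),
  clipped to [0, 1]. A degenerate P̄ of 0 or 1 yields a warning, not an
  error.
* **X̄/S charts.** σ̂ defaults to the *pooled* baseline SD,
  σ̂ = √(Σ(nᵢ−1)sᵢ²/ν)/c₄(ν+1) with ν = Σ(nᵢ−1), because subgroup sizes
  vary considerably across quarters; the classic mean-of-s estimator
  (σ̂ = Σsᵢ/Σc₄(nᵢ)) is available as `sigma_method="mean-s"` for
  cross-checking against software that averages. The S chart's centerline
  is per-point, c₄(nᵢ)σ̂, with B₃/B₄ scaling, so its limits also respect
  the subgroup size.
* **Run charts** use the median of all plotted points (mean-of-middle-two
  for even counts). Process-indicator run charts start at the intervention
  quarter by default, since delivery documentation typically begins with
  the improvement work; the enrollment run chart spans the whole program.
* **Rule semantics.** Rule 2 ("either above or below") is read as a run on
  one side; Rule 3 ("going up or down") as strictly monotone; equal
  successive values break Rule 3/4 runs, points exactly on the centerline
  break Rule 2 runs, and gap quarters (no data) reset every counter.
  Runs are tracked over the entire series, but by default a signal is only
  *reported* if it includes at least one post-baseline point: a process
  shift beginning in the late baseline can legitimately complete a
  nine-point run shortly after monitoring starts, and with an eight-quarter
  monitoring window a wholly post-baseline nine-point run is impossible.
  `scope="all"` reports everything (diagnostics on the baseline itself).

## GEE sensitivity analysis

The panel is the deduplicated child-quarter series; the design is an
intercept plus a post-period indicator; clusters are children. Families:
binomial/logit for the stunting flag, Gaussian/identity for LAZ. The
solver alternates Fisher scoring on β with moment updates of the
exchangeable correlation α and stops at max|Δβ| < 1e−8 (cap 100
iterations). Software differs in small-sample corrections, so the exact
conventions are: Pearson dispersion φ̂ = Σe²/(N−p); α̂ = (Σ within-cluster
cross-products / φ̂)/(Σnᵢ(nᵢ−1)/2 − p); working covariance without the
dispersion factor (it cancels from the score and the sandwich); naive
covariance B⁻¹φ̂ with φ fixed at 1 for the binomial family. The
exchangeable inverse is applied in closed form (Woodbury), so fits are
linear in the number of observations. Degenerate cases: all-singleton
clusters give α = 0 and the independence GLM; non-convergence sets
`converged=False` rather than raising; likely separation (|η| > 30) warns.

**The marginal period effect.** For the Gaussian family the identity link
makes the post coefficient itself the marginal mean difference (robust
Wald 95% CI). For the binomial family a "stunting declined by x%" summary
cannot be the raw logit coefficient; it is computed by g-computation —
average predicted probability with the indicator set to 1 versus 0 over
all rows — and reported both as an absolute risk difference and as a
relative decline 100·(p₀−p₁)/p₀, each with a delta-method CI on the robust
covariance. The relative-decline reading is an interpretive choice and is
reported alongside the absolute difference so either contrast is available.

`exclude_first_quarter` implements the standard robustness check against a
start-up-artifact first quarter; it is deliberately not idempotent.

## The synthetic cohort

The generator emulates the study conditions the analysis is designed for:

* **Scale and span:** 125 households with 1–3 under-5 children each
  (categorical {1: 0.70, 2: 0.28, 3: 0.02}, mean 1.32 → ≈165 children at
  start), quarters 2014Q4–2019Q4, intervention 2018Q1, Poisson(12) new
  children per quarter thereafter (roughly balancing exits at 60 months
  given uniform 0–48-month entry ages), exit at 60 months.
* **Latent LAZ:** Z = −1.77 + bᵢ + (age slope)·age + effect(t) + ε, with
  bᵢ ~ N(0, 0.95²) between children and ε ~ N(0, 0.55²) within — an
  exchangeable intra-child correlation of 0.75 (LAZ tracks strongly within
  a child) and a marginal SD of 1.10, so the marginal baseline stunting
  probability Φ((−2+1.77)/1.10) ≈ 0.42. The age slope defaults to 0 so
  that the baseline marginal mean equals −1.77 exactly; growth faltering
  with age remains available as a knob.
* **Intervention effect:** a step of +0.10 Z at 2018Q1 plus +0.055 Z per
  quarter, capped at +0.50 — a gradual drift rather than a jump, which is
  how delivery-fidelity improvements plausibly act; averaged over the
  eight monitoring quarters this is ≈ +0.29 Z, moving the marginal mean
  to ≈ −1.48 and stunting to ≈ 0.32. The linear-in-Z step-plus-ramp form
  is a modeling choice, not an empirical claim.
* **Stunting is always derived** from the latent Z, never simulated
  separately, so the p-chart and X̄ chart are automatically coherent.
* **Contacts and delivery:** monthly contact with probability 0.80 pre /
  0.90 post; given a contact, growth monitoring (and hence a LAZ value)
  with probability 0.60 pre / 0.85 post and micronutrient delivery 0.55
  pre / 0.85 post. No visit-frequency or documentation rates are published
  for such programs at this granularity; these are free parameters chosen
  once as plausible for a CHW program tightening its delivery, and they
  are config fields, not constants.

What the generator does **not** emulate: seasonality, measurement error
spikes, informative missingness (sicker children measured more or less
often), household-level clustering of growth, covariates (diet, illness,
food insecurity), or secular trends. Passing tests therefore demonstrate
that the chain is correct under its stated statistical assumptions — not
that those assumptions hold in any particular field data set.

## Numerical and validation choices

* c₄ is computed via log-gamma for stability at large ν; B₃ is clipped at
  zero.
* The rule detector is validated against a brute-force window-scanning
  oracle (independent code path) on random sequences containing ties,
  exact centerline hits, and gaps.
* The in-control Rule-1 false-alarm measurement uses simulated charts with
  400-subgroup baselines: with short baselines the estimated limits
  themselves wander enough to inflate the observed rate (a convexity
  effect of order 3φ(3)/n_base per point), which would conflate detector
  calibration with limit-estimation noise.
* The GEE is validated against statsmodels' GEE (never used as the
  implementation) at a 1e−4 relative tolerance on coefficients and robust
  SEs; because both solvers target identical estimating equations, the
  observed agreement is ~1e−10.
* Parameter-recovery measurements use a −0.3 Z step at the default cohort
  scale over 21 quarters: CI coverage of the Gaussian GEE and
  Rule-1-or-2 detection power of the p-chart over 50 seeded replicates.
  Problem sizes throughout (10⁵ chart points, 50 panels, 50 replicates)
  were chosen to make Monte-Carlo error small relative to the quantities
  being checked.

## Known limitations

* The stunting cutoff is strict (Z < −2); a boundary value of exactly −2
  counts as not stunted. Conventions differ across published material on
  this boundary; it is measure-zero in practice but documented here.
* The biological-plausibility screen (|Z| ≤ 6, the WHO data-cleaning
  convention) is on by default and configurable; cleaned values are
  masked, not dropped, so enrollment and process denominators are
  unaffected.
* The poverty lookup consumes a bracket table (only brackets the user
  supplies); it does not implement any scorecard's internal scoring.
* WHO LMS reference tables are not bundled (they are licensed data and
  heavy); the LMS math accepts any table in the documented CSV schema.
  Pipelines that already record z-scores from field software skip this
  path entirely — the visit schema takes `laz` directly.
* Quarters with zero measured children appear as gaps; no imputation of
  missed visits is attempted anywhere.
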