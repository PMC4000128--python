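# Methods

## Scope and model

`progsig` evaluates continuous risk scores from multi-gene breast-cancer
signatures against a right-censored survival endpoint
(distant-metastasis-free survival, years from diagnosis). The working
assumptions are:

* expression is log2 scale, genes × samples, already normalized
  (probe-level processing, RMA and batch correction are out of scope);
* each signature is pure data — a JSON document naming an archetype,
  genes with parameters, a risk direction and calibration proportions —
  and the engine implements the archetypes, not any vendor's exact
  coefficients;
* prognostic effects need not be proportional over time: the central
  output is the standardized hazard ratio per follow-up interval and
  per ER stratum, not a single whole-follow-up HR.

## Scoring archetypes

* `centroid_subtype` — correlation of a sample's signature-gene profile
  with each class centroid; the subtype call is the argmax
  (deterministic tie-break: first class in declared order, ties within
  1e-8 flagged ambiguous); the continuous risk score is a linear
  combination of the centroid correlations (ROR-S).
* `centroid_risk` — correlation to one reference (good-prognosis)
  centroid times `risk_direction`; with direction −1 a sample identical
  to the good-prognosis profile gets the minimum score.
* `weighted_sum` — Σ w·x over the gene set, with separate gene sets per
  patient stratum when declared (ER-specific panels). When genes are
  missing for a sample, the observed sum is rescaled by
  (total |w|)/(observed |w|); an all-zero weight vector scores 0.
* `difference_of_means` — mean(up-set) − mean(down-set), then linearly
  mapped so the cohort's raw range becomes [−1, +1] around the cohort
  midpoint (an invariant scale; the offset/scale is recorded in the
  result's metadata). A degenerate zero-range cohort maps to 0.
* `grouped_threshold` — optional reference-gene mean subtracted per
  sample, per-group gene means clipped to declared bounds, then
  intercept + Σ group-weight · group value (unscaled recurrence-score
  construction). With clipping off and no reference genes this is
  algebraically a weighted sum with weights w_g/|group| — asserted to
  1e-12 in tests.

Correlation defaults: Spearman for subtype calling, Pearson for ROR and
reference-centroid scores; both are configurable per signature. A
sample sharing fewer than 3 genes with a centroid gets a missing score.
Coverage: scoring requires ≥ 50% of a signature's genes in the matrix
(published panels commonly lose 25–50% of genes across platforms), with
a warning below 80%. Duplicate gene rows collapse to the
highest-variance row (configurable mean), preserving dynamic range.

## Calibration

Risk groups use nearest-rank (type-1) empirical quantiles so that group
counts are exact integers: with proportions (0.51, 0.22, 0.27) on 100
distinct scores the groups have exactly 51/22/27 members. Ties at a
cutoff go to the lower-risk group. Cutoffs are computed per stratum
when per-stratum proportions are declared. Standardization always uses
the ddof-1 SD over exactly the sample set entering the subsequent model
fit (e.g. the ER+ subjects at risk within one interval), never a global
SD — per-stratum standardized HRs would otherwise be on distorted
scales.

## Survival methodology

* Cox fits: lifelines `CoxPHFitter` (Efron ties, the default; optional
  cohort stratification gives each cohort its own baseline hazard
  without forcing proportional cohort effects). `ties="breslow"` uses
  statsmodels `PHReg`. Constant covariates, zero events and
  non-convergence raise explicit errors.
* Interval analysis: the sub-experiment of `[a, b)` keeps subjects
  still at risk at `a` with their original times, censoring survivors
  at `b`; intervals are half-open, so an event exactly at `b` belongs
  to the next interval and tiling intervals count every event exactly
  once. Cells with zero events are reported with a missing HR and a
  reason rather than dropped.
* Concordance: Harrell's C with a pair usable when censoring still
  reveals the ordering (earlier time is an event, or tied times with
  exactly one event); score ties credit 1/2. CI: normal approximation
  on the usable-pair proportion, clipped to [0, 1]; this is a crude SE
  and is labeled as such — bootstrap over subjects is the alternative
  when precise uncertainty matters.
* Explained variation: `PVE = 1 − exp(−G/n)` from the partial
  likelihood-ratio statistic. This is a declared, documented estimator
  choice (several PVE variants exist in the literature); the result
  object stores the log-likelihoods so any other transform can be
  recomputed.
* PH diagnostics: scaled Schoenfeld residuals; ρ is their Pearson
  correlation with transformed event time (default transform:
  1 − KM(t−); identity/rank/log available), p from the
  Grambsch–Therneau score test (lifelines). A decaying effect gives
  ρ < 0. Calibration is verified by simulation: type-I error within
  [0.03, 0.07] at α = 0.05 over 1000 null replicates.
* Aalen additive model: at each event time the increment is the
  least-squares solution (XᵀX)⁻¹XᵀdN over the risk set with design
  [1, z]; variances accumulate the squared increments; 95% pointwise
  CIs are normal. If the design loses rank (covariate constant in the
  shrinking risk set) accumulation stops and the truncation time is
  recorded. A time-constant additive effect appears as a line of the
  true slope; the recovery test uses the median slope of five n = 2000
  replicates because a single replicate's slope has ~8% sampling SD.
* Multivariate models: signature + tumor size (pT1 reference), node
  (negative reference), grade (grade-1 reference) in the combinations
  signature / +size / +grade / +size+node+grade; subjects with unknown
  levels of a used factor are dropped per model, and dummy columns for
  levels absent from an estimation sample are omitted.

## The synthetic cohort

The generator produces the structure the evaluation assumes, with full
ground truth, and is the package's test substrate:

* n = 912 tumors, 76% ER-positive (meta-cohort scale); per-sample
  latent proliferation factor P and an independent hypoxia factor H,
  both N(0, 1).
* Nine signature definitions covering all archetypes. Sum-type
  signature s has true score l·F + σ·U (F its driving factor, U
  signature-specific, defaults l ≈ 0.8–0.9, σ = 0.45), written into its
  genes plus N(0, 0.5) measurement noise; two scores with loadings
  l₁, l₂ on the same factor then correlate as
  l₁l₂/√((l₁²+σ²)(l₂²+σ²)) ≈ 0.8 — the tight agreement block real
  signatures show. A 60-gene centroid pool defines five subtype
  centroids; samples sit at their subtype's centroid shifted along the
  LumA→LumB axis by 0.8·P per gene, so subtype calls and ROR scores
  also read the proliferation axis. ESR1/ERBB2 marker genes are bimodal
  by ER/HER2 status for the imputation path.
* Survival: piecewise-exponential inversion sampling per ER stratum.
  The log-hazard adds β(t)·z, z the within-stratum standardized driver
  (P for ER+, H for ER−). Defaults: β = log 2 on [0, 5) then 0 in ER+;
  β = log 1.5 on [0, 5) then 0 in ER− — a strong early effect that
  vanishes, which is the time-decay phenomenon under study. Baseline
  hazards are piecewise (ER+ 0.035/0.015/0.005, ER− 0.065/0.012/0.008
  per year over 0–5/5–10/>10 y) with exponential random censoring at
  0.015/yr and administrative censoring at 15 y; these rates were
  chosen so the per-interval at-risk/event pattern matches a ~900-tumor
  meta-cohort (≈120/30/10 ER+ and ≈60/7/5 ER− events per interval).
* Grade and size are quantile cuts of noisy copies of P (grade tracks
  proliferation strongly, size weakly), so adjusting for grade
  attenuates signature effects — giving the multivariate module a real
  mediation structure to detect. Node status and treatment are
  independent.
* `expected_event_count` gives the closed-form expected number of
  observed events (per-sample given the simulated drivers, or by
  Gauss–Hermite quadrature over a standard-normal driver), used as a
  binomial sanity check on every simulation.
* All randomness flows from one `SeedSequence` through four named
  sub-streams (expression, survival, censoring, clinical), so the same
  seed reproduces the cohort byte-for-byte and components are
  independently reproducible.

What the generator does **not** emulate: platform/batch effects,
probe-level noise, missing expression values, informative censoring,
competing risks, or the outcome contamination of cohorts that define
the endpoint as metastasis-or-death. Passing tests therefore
demonstrate that the statistical machinery is correct and calibrated
under the assumed generating model — not that any particular published
signature is valid on real data.

## Numerical and design choices

* Half-open interval convention `[a, b)` everywhere; determinism over
  boundary ambiguity.
* Nearest-rank quantiles (exact integer group sizes) rather than
  interpolated quantiles.
* The receptor-status mixture is a quartile-initialized equal-variance
  two-component EM: deterministic without a seed and exactly
  equivariant under positive affine transforms of the marker values;
  collapsed fits fall back to a median split with a warning flag.
* Scores are oriented at scoring time (risk_direction applied), so
  every score column is increasing-in-risk before any survival model
  sees it.
* Pipeline outputs are pure functions of (inputs, config, seed); the
  run-metadata record stores the config hash and library versions.

## Known limitations

* The concordance CI underestimates uncertainty because usable pairs
  are not independent; it is a screening interval.
* PVE on the partial likelihood is one of several inequivalent
  definitions; comparisons across packages require matching the
  transform.
* The Breslow backend (statsmodels) does not expose the PH diagnostic;
  `ph_test` requires the Efron (lifelines) fit.
* Aalen CIs are pointwise, not simultaneous bands.
* Interval HRs from very sparse cells (a handful of events, as in
  late ER-negative follow-up) are reported with their wide CIs; they
  are not suppressed, and should be read accordingly.
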