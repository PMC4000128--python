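# progsig

Scoring and survival evaluation of multi-gene prognostic signatures for
breast cancer expression cohorts.

Multi-gene expression signatures (intrinsic-subtype classifiers with
risk-of-relapse scores, 70/76-gene panels, genomic grade, recurrence
scores, hypoxia and wound-response modules) are widely used to predict
distant-metastasis-free survival (DMFS), but their prognostic power is
not constant: it depends strongly on estrogen-receptor (ER) status and
decays with follow-up time. `progsig` is a toolkit for quantifying
exactly that: it computes continuous risk scores from declarative
signature definitions, recalibrates risk groups on the studied
population, and measures how each score's hazard ratio behaves across
follow-up intervals and ER strata.

It is written for biostatisticians and computational biologists who
have a log2 expression matrix and a clinical follow-up table and want a
reproducible, fully tested pipeline from scores to time-resolved hazard
ratios — plus a synthetic-cohort generator with complete ground truth,
so the whole stack is testable without any data download.

## The statistics at the core

For each signature score `x` and each follow-up window `[a, b)` within
an ER stratum, the cohort is restricted to subjects still at risk at
`a` (earlier failures excluded, survivors past `b` censored at `b`),
the score is standardized to unit SD over exactly that restricted
sample, and a univariate Cox model

&nbsp;&nbsp;&nbsp;&nbsp;`h(t | z) = h0(t) · exp(β z)`,&nbsp; `z = (x − x̄)/SD(x)`

is fitted, so `HR = exp(β)` reads as hazard per one standard deviation
of the score. Whole-follow-up discrimination is summarized by Harrell's
concordance index C over usable (orderable-under-censoring) pairs and
by the explained variation `PVE = 1 − exp(−G/n)` with `G` the
likelihood-ratio statistic. Time-dependence is diagnosed by the
correlation ρ of scaled Schoenfeld residuals with (KM-transformed)
event time and the Grambsch–Therneau test, and visualized through
Aalen additive cumulative regression `B(t) = ∫ β(s) ds`, whose slope is
the instantaneous additive effect. Cross-signature agreement uses
pairwise-complete Pearson correlations and Cohen's κ on subtype calls.

Scoring archetypes: nearest-centroid subtyping + ROR-S linear
combination of centroid correlations; single-reference-centroid risk;
(stratified) weighted gene sums; up-minus-down mean contrasts on an
invariant scale; reference-normalized grouped threshold scores.
Risk groups are assigned by nearest-rank population quantiles (fixed
proportion of the cohort per group, optionally per ER stratum).

## Worked example

```python
import progsig as ps

# a 912-tumor synthetic cohort (~76% ER+, 15-year follow-up) with nine
# signature definitions covering every scoring archetype
sim = ps.simulate_cohort(ps.SimulationConfig(seed=1))
table = ps.score_all(sim.expression, sim.signatures, sim.clinical)

model = ps.SignatureSurvivalModel(table.scores, sim.clinical)
res = model.fit()
row = res.intervals.cell("proliferation_sum", "positive", "0-5 yr")
print(f"ER+ 0-5 yr HR/SD: {row['hr']:.2f} [{row['ci_low']:.2f}, {row['ci_high']:.2f}]")
row = res.intervals.cell("proliferation_sum", "positive", "5-10 yr")
print(f"ER+ 5-10 yr HR/SD: {row['hr']:.2f} [{row['ci_low']:.2f}, {row['ci_high']:.2f}]")
row = res.intervals.cell("hypoxia_sum", "negative", "0-5 yr")
print(f"ER- 0-5 yr HR/SD (hypoxia): {row['hr']:.2f} [{row['ci_low']:.2f}, {row['ci_high']:.2f}]")
```

prints

```
ER+ 0-5 yr HR/SD: 1.65 [1.42, 1.92]
ER+ 5-10 yr HR/SD: 0.97 [0.67, 1.41]
ER- 0-5 yr HR/SD (hypoxia): 1.46 [1.14, 1.88]
```

i.e. the proliferation-coupled score roughly multiplies the early
ER-positive metastasis hazard by 1.65 per standard deviation, has no
effect after year five, and the hypoxia-like score is prognostic only
in ER-negative disease — the time- and ER-dependence pattern the
package exists to measure. `res.summary()` renders the full tables
(C-index/PVE per signature, Schoenfeld ρ, all interval × stratum HRs).

The same analysis from the shell:

```bash
progsig simulate --seed 1 --n 912 --outdir sim/
progsig run --expression sim/expression.tsv --clinical sim/clinical.tsv \
            --signatures sim/signatures --outdir out/ --seed 1
```

writes `scores.tsv`, `risk_groups.tsv`, `km_curves.tsv`,
`score_correlations.tsv`, `performance.tsv`, `interval_effects.tsv`,
`aalen_curves.tsv`, `multivariate_models.tsv` and a
`run_metadata.json` with config hash, seed and library versions.

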