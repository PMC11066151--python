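# Methods

## Model and pipeline

The package implements a two-stage prognostic classifier for binary
relapse outcome from log-scale gene expression.

**Per-gene statistics.** The discriminative value of a gene is the
Mann–Whitney AUC of the rule "higher expression ⇒ early relapse",
computed by rank statistics with tied pairs counted 1/2. The direction
d_g is the sign of the mean difference (early − no relapse); an exact
tie leaves the direction undefined. Stability screening draws b = 50
bootstrap resamples of the training samples, stratified by outcome group
(each group resampled at its own size), so both classes are present in
every resample and the per-resample AUC is always defined. All genes
share the same resample indices — the bootstrap is at the sample level.
A gene is *stable* when its direction is defined and identical in all b
resamples; its reported AUC is the bootstrap average. Whether the
original procedure stratified its bootstraps is unknown; stratification
was chosen because it makes the per-resample statistics well-defined at
these group sizes (19/20).

**Signed modules.** A module is an ordered list of n_g distinct genes
from one gene set with their directions; its value per sample is
n_g⁻¹ Σ d_g·x_g. Candidate modules for a set are found by (1) keeping
the set's stable genes present in the matrix, (2) ranking them by
*direction-adjusted* AUC — the AUC of the signed gene d_g·x_g, i.e.
1 − AUC for negatively-directed genes — and (3) exhaustively scoring all
n_g-subsets of the top `pool_size` (default 8) ranked genes by the
training AUC of the subset's module value. The best `top_k` (default 5)
subsets become candidates. The enumeration space is a design choice: the
bounded pool keeps the search exhaustive yet small (C(8,4) = 70 subsets)
while honoring "top subsets by AUC". Ranking by raw (unadjusted) AUC
would discard strongly protective genes and cannot produce mixed-sign
modules. Ties among equal-AUC subsets break toward the larger sum of
member adjusted AUCs, then lexicographic gene order — fully
deterministic. Modules are named `<set>_<rank>`.

**Classifier.** The n_f candidates with the highest training AUC
(across all sets; gene reuse and multiple modules per set allowed) feed
an ElasticNet-penalized logistic regression (scikit-learn, saga solver)
on standardized module values. The L1 ratio ∈ {0.1, 0.55, 1.0} and
inverse penalty C ∈ {0.1, 1, 10} are tuned by internal stratified
k-fold cross-validation (k = 5, reduced to the minority-class count when
smaller) maximizing pooled out-of-fold AUC; ties resolve to the first
grid point in iteration order. The grid over (n_g, n_f) ∈ {3,4,5}² is
selected the same way — the choice rule for the published models was not
recorded, so internal-CV AUC inside the training fold is used, which
keeps selection leakage-free. If every feature is constant the fit
degenerates to the closed-form intercept-only model (class-prior
log-odds); the saga solver cannot reach that limit exactly because it
treats the intercept as a decaying pseudo-feature.

**External leave-one-out loop.** Performance is estimated by removing
one sample, re-running *everything* (screening, module construction,
selection, tuning, fitting) on the rest, and scoring the held-out
sample. The same base seed drives every fold, so the random stream never
depends on the held-out sample; perturbing a held-out label provably
cannot change its score, and the test suite asserts this bit-exactly.
In signal-free data a fold can end with no gene set retaining n_g stable
genes; `loocv(on_empty=...)` either propagates the error (default) or
assigns the neutral score 0.5. The neutral value was chosen over a
class-prior fallback because the leave-one-out prior is anti-correlated
with the held-out label and would bias null AUC below 0.5.

**Reported statistics.** AUC confidence intervals use the DeLong
structural-components variance with a normal 95% interval truncated to
[0, 1]. Sensitivity and specificity at cutoff 0.5 (a score exactly at
the cutoff counts as a negative call) carry Clopper–Pearson exact
binomial intervals — the only method consistent with the published
intervals for 14/19 and 16/20. The two-sided Fisher exact test uses the
"probability at most that of the observed table" summation with relative
tolerance 1e-7, which reproduces the published p = 0.487 for the
19-vs-20 grade table exactly; the t test is the pooled-variance Student
variant with df = n_x + n_y − 2. Matched bulk/invasion-front scores are
combined by arithmetic mean over samples present in both sets; agreement
is Pearson/Spearman correlation on scores and Cohen's κ on class calls.

## Synthetic cohort generator

`SimulationConfig` defaults encode the emulated study design: 19
early-relapse and 20 no-relapse patients, 4 of whom lack an
invasion-front profile (39 bulk / 35 front columns, dropped alternately
from the two groups); 2,000 genes; 30 gene sets of 25 distinct genes each, drawn
independently from the universe so sets may overlap.
Expression is additive Gaussian on the log scale: per-gene baselines
uniform on [4, 12] (log2-intensity-like) with residual SD 1.0, the
simplest model matching RMA-style normalized intensities. Planted genes
— the union of the configured planted sets — receive a between-group
mean shift of ±`effect_size` (default 1.0 noise-SD, a realistic modest
single-gene effect for this setting), with 25% of planted genes shifted
*down* in the early-relapse group so mixed-sign modules arise. Bulk and
invasion-front values of the same gene and patient share a latent draw:
x_region = μ + √ρ·L + √(1−ρ)·ε_region, giving between-region correlation
ρ (default 0.5, producing the modest score agreement the paired design
assumes). Fixed seeds give bit-identical cohorts.

The generator does **not** model probe-level effects, cross-platform
batch structure, survival times, heavy-tailed noise, or gene–gene
correlation beyond the planted shifts and the shared regional factor.
Passing tests therefore demonstrate correctness of the pipeline's
statistics and its calibration/recovery behaviour under the assumed
noise model — not clinical performance on real cohorts.

## Frozen published signatures

Three fixed models ship as JSON data (`baseline`: 5 modules × 4 genes;
`bulk`: 3 × 5; `invasion_front`: 3 × 4) with module genes, signs and
coefficients exactly as published. No intercept or score cutoff was
published, so `apply_signature` returns the uncalibrated linear score
Σ coef_m · module-value_m: valid for within-cohort ranking only. Whether
the published coefficients assume raw log expression or standardized
values is unstated; a `standardize` flag z-scores each gene across
samples for cross-cohort use. Strict mode requires every signature gene;
relaxed mode drops missing genes and renormalizes each affected module
by its remaining size — a documented approximation for cross-platform
application, not a published behaviour.

## Problem sizes and tolerances

Study-scale simulation runs (calibration, signal recovery, the
acceptance script) use the single grid point n_g = n_f = 4 — the
published baseline model's shape — with the full b = 50 bootstrap
screening and default ElasticNet tuning; the 3×3 grid search itself is
exercised on smaller cohorts. Null calibration averages 10 seeds; the
paired-region study uses 3 seeds and reports medians. Printed-precision
comparisons against published three-decimal table values use an absolute
tolerance of 1e-3 because those values are truncated, not rounded
(e.g. 0.74753 printed as 0.747).

## Known limitations

- The subset-enumeration rule behind module construction and the
  original "_up"/"_dn" gene-set splitting were not fully specified for
  the published models; this implementation's bounded-pool enumeration
  is one defensible reading and will not bit-reproduce the published
  module lists from the original data.
- Frozen signatures cannot be validated here against external cohorts;
  applying them yields ranks, not probabilities.
- At a 1-SD planted effect the top-ranked candidate module frequently
  swaps a planted gene for a correlated noise gene (in-sample selection
  over 70 subsets); whole-pipeline discrimination is robust to this, but
  exact gene-list recovery needs ≈2-SD effects at n = 39.
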