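# frontsig

Discovery and evaluation of prognostic gene-expression signatures from
**paired tumor regions** — conventional bulk-tumor sampling and the
**invasion front**, the contact border between tumor and host tissue.
The target setting is early-relapse prediction in low-risk (stage
IIA/pT3N0, microsatellite-stable) colon cancer, where most patients are
spared adjuvant chemotherapy yet a minority relapse within five years.

The package is for computational biologists who want to build, evaluate,
or apply small signed gene-module classifiers on log-scale expression
matrices (microarray or RNA-seq after suitable normalization), with
honest, leakage-free performance estimation at small sample sizes.

## Method

Given a genes × samples log-expression matrix `X`, a binary outcome
(`early_relapse` vs `no_relapse`) and a gene-set collection (e.g. MSigDB
hallmark sets in GMT format):

1. **Gene screening.** Each gene *g* is scored by its Mann–Whitney AUC
   for "higher expression ⇒ early relapse" and its direction
   *d<sub>g</sub>* = +1 if mean expression is higher in the early-relapse
   group, −1 otherwise. Over *b* = 50 stratified bootstrap resamples of
   the training samples, a gene is **stable** when its direction never
   flips; its AUC is the bootstrap average.
2. **Signed modules.** For each gene set, the stable member genes are
   ranked by direction-adjusted AUC and the top five *n<sub>g</sub>*-gene
   subsets (by the training AUC of the module value) become candidate
   modules. A module's value for a sample is the direction-weighted mean
   *n<sub>g</sub>*<sup>−1</sup> Σ *d<sub>g</sub>x<sub>g</sub>*.
3. **Classifier.** An ElasticNet-penalized logistic regression is fitted
   on the *n<sub>f</sub>* modules with the highest training AUC;
   *n<sub>g</sub>*, *n<sub>f</sub>* ∈ {3, 4, 5} and the penalty are tuned
   by internal stratified cross-validation.
4. **Evaluation.** The whole pipeline (screening → modules → selection →
   fitting) is re-run from scratch inside an **external leave-one-out
   loop**; out-of-fold scores yield the AUC (DeLong 95% CI) and
   sensitivity/specificity (Clopper–Pearson 95% CIs) at cutoff 0.5.
5. **Region combination.** Scores from matched bulk and invasion-front
   classifiers can be averaged into a combined predictor; their agreement
   is quantified by Pearson/Spearman correlation and Cohen's κ.

Because the original cohort is not bundled, the package ships a
**synthetic paired-cohort generator** that emulates the study design (19
early-relapse vs 20 no-relapse bulk profiles, 35 matched invasion-front
profiles, planted signed differential signal in chosen gene sets, tunable
bulk/front correlation), plus the three **published signatures**
(baseline, bulk, invasion front) as frozen JSON models that can be
applied to any expression matrix as uncalibrated linear risk scores.

## Worked example

```python
from frontsig import SimulationConfig, simulate_study, loocv, evaluate_scores

config = SimulationConfig(planted_sets=("SET01",), effect_size=0.8, seed=7)
bulk, front, pheno, sets = simulate_study(config)
scores = loocv(bulk, pheno, sets, n_g_grid=(4,), n_f_grid=(4,), seed=7)
report = evaluate_scores(scores, pheno)
print(f"LOO AUC = {report.auc:.3f} "
      f"(95% CI {report.auc_ci[0]:.3f}-{report.auc_ci[1]:.3f})")
print(f"Se = {report.sensitivity:.3f}, Sp = {report.specificity:.3f} at cutoff 0.5")
```

Output:

```
LOO AUC = 0.918 (95% CI 0.833-1.000)
Se = 0.947, Sp = 0.800 at cutoff 0.5
```

The simulated cohort plants a 0.8-SD signed expression shift in the genes
of one of 30 gene sets. The leave-one-out loop rebuilds the signature 39
times without the held-out patient and still ranks patients nearly
perfectly (AUC 0.918): the pipeline finds the planted module signal. At
the default probability cutoff 0.5, 18 of 19 early-relapse patients and
16 of 20 no-relapse patients are called correctly.

Applying a published signature to your own cohort:

```python
import frontsig as fs

expr = fs.read_expression_matrix("expr.tsv")     # genes x samples, log scale
sig = fs.load_published_signature("invasion_front")
risk = fs.apply_signature(sig, expr)             # higher = higher risk
```

The same steps are available from the shell: `frontsig simulate`,
`frontsig train`, `frontsig loocv`, `frontsig combine`, `frontsig apply`,
`frontsig table1` (see `frontsig --help`).

## Limitations

The published signatures ship without intercepts, so they produce
rank-valid linear scores, not calibrated probabilities. The synthetic
generator models additive Gaussian noise on the log scale with a single
shared latent factor per gene/patient pair; see `docs/methods.md` for
what that does and does not establish about real cohorts.
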