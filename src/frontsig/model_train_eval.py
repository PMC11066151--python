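"""ElasticNet signature training and external leave-one-out evaluation.

A signature model is a penalized logistic regression (mixed L1/L2,
"ElasticNet") fitted on the values of a handful of signed gene modules.
Hyperparameters — the module size n_g, the number of modules n_f, and the
ElasticNet mixing/strength — are tuned by internal stratified k-fold
cross-validation on AUC.  Honest performance estimation wraps the entire
pipeline (bootstrap gene screening, module construction, module selection,
classifier fitting) in an external leave-one-out loop so the held-out
sample never influences feature generation.

Scores from classifiers trained on matched sampling regions (tumor bulk and
invasion front) can be averaged into a combined predictor, and their
agreement quantified by Pearson/Spearman correlations and Cohen's kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import StratifiedKFold

from .cohort_stats import clopper_pearson
from .gene_stats import auc_mann_whitney, bootstrap_gene_stability, _class_masks
from .io_formats import EARLY_RELAPSE, NO_RELAPSE
from .module_builder import (
    DEFAULT_POOL_SIZE,
    DEFAULT_TOP_K,
    GeneModule,
    candidate_modules,
    module_score,
    select_top_modules,
)

DEFAULT_GRID = (3, 4, 5)


@dataclass
class TuningConfig:
    """Internal cross-validation settings for the ElasticNet classifier."""

    l1_ratios: tuple[float, ...] = (0.1, 0.55, 1.0)
    cs: tuple[float, ...] = (0.1, 1.0, 10.0)
    n_splits: int = 5
    max_iter: int = 5000


@dataclass
class SignatureModel:
    """A fitted module-based classifier.

    ``standardization`` holds the per-feature (mean, sd) applied to module
    values before the linear predictor; ``intercept`` may be ``None`` for
    published signatures that ship as uncalibrated linear scores.
    """

    modules: list[GeneModule]
    module_coefficients: np.ndarray
    intercept: Optional[float]
    n_g: int
    n_f: int
    region: str = "bulk"
    standardization: Optional[tuple[np.ndarray, np.ndarray]] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.modules) != len(self.module_coefficients):
            raise ValueError("one coefficient per module required")

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.modules]


def signature_features(expr: pd.DataFrame,
                       modules: Sequence[GeneModule]) -> pd.DataFrame:
    """samples x modules matrix of module values."""
    return pd.DataFrame({m.name: module_score(expr, m) for m in modules})


def _encode_labels(phenotype, index) -> np.ndarray:
    labels = pd.Series(phenotype).reindex(index)
    if labels.isna().any():
        missing = list(pd.Index(index)[labels.isna()])
        raise ValueError(f"samples without phenotype: {missing}")
    pos, _ = _class_masks(labels.values)
    return pos.astype(int)


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (x - mean) / sd, mean, sd


def fit_elasticnet(features: pd.DataFrame, phenotype: pd.Series,
                   seed: int = 0,
                   tuning: Optional[TuningConfig] = None):
    """Fit a penalized logistic model on module values.

    Features are standardized; the L1 mixing ratio and inverse penalty
    strength are chosen by stratified k-fold cross-validation maximizing
    the pooled out-of-fold AUC.  Deterministic for a fixed seed.

    Returns ``(coef, intercept, (mean, sd), cv_auc, params)`` where
    ``coef`` is on the standardized feature scale.
    """
    tuning = tuning or TuningConfig()
    y = _encode_labels(phenotype, features.index)
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("need at least 2 samples per outcome group")
    x, mean, sd = _standardize(features.to_numpy(dtype=float))
    if np.all(x == 0.0):
        # degenerate: every feature constant; the penalized fit reduces to
        # the intercept-only model, solved in closed form (prior log-odds)
        prior = y.mean()
        intercept = float(np.log(prior / (1.0 - prior)))
        return (np.zeros(x.shape[1]), intercept, (mean, sd), 0.5,
                {"l1_ratio": tuning.l1_ratios[0], "C": tuning.cs[0],
                 "n_splits": 0})

    n_splits = min(tuning.n_splits, int(y.sum()), int(len(y) - y.sum()))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(cv.split(x, y))

    def make_clf(l1_ratio, c):
        return LogisticRegression(
            solver="saga", l1_ratio=l1_ratio, C=c,
            max_iter=tuning.max_iter, tol=1e-4, random_state=seed,
        )

    best = None
    for l1_ratio in tuning.l1_ratios:
        for c in tuning.cs:
            oof = np.full(len(y), np.nan)
            for train_idx, test_idx in splits:
                clf = make_clf(l1_ratio, c)
                clf.fit(x[train_idx], y[train_idx])
                oof[test_idx] = clf.predict_proba(x[test_idx])[:, 1]
            labels = np.where(y == 1, EARLY_RELAPSE, NO_RELAPSE)
            cv_auc = auc_mann_whitney(oof, labels)
            if best is None or cv_auc > best[0]:
                best = (cv_auc, l1_ratio, c)
    cv_auc, l1_ratio, c = best
    clf = make_clf(l1_ratio, c)
    clf.fit(x, y)
    coef = clf.coef_.ravel().astype(float)
    intercept = float(clf.intercept_[0])
    return coef, intercept, (mean, sd), float(cv_auc), {
        "l1_ratio": l1_ratio, "C": c, "n_splits": n_splits,
    }


def predict_score(model: SignatureModel, features: pd.DataFrame) -> pd.Series:
    """Posterior probability of early relapse per sample.

    Requires an intercept (i.e. a model fitted by this package, not an
    uncalibrated published signature).
    """
    missing = [n for n in model.feature_names if n not in features.columns]
    if missing:
        raise KeyError(f"features missing from input: {missing}")
    if model.intercept is None:
        raise ValueError("model has no intercept; use "
                         "frozen_signatures.apply_signature for linear scores")
    x = features[model.feature_names].to_numpy(dtype=float)
    if model.standardization is not None:
        mean, sd = model.standardization
        x = (x - mean) / sd
    eta = x @ np.asarray(model.module_coefficients, dtype=float) + model.intercept
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=features.index,
                     name="score")


def predict_from_expression(model: SignatureModel,
                            expr: pd.DataFrame) -> pd.Series:
    """Convenience: compute module values from ``expr`` then score."""
    return predict_score(model, signature_features(expr, model.modules))


def train_signature_model(expr: pd.DataFrame, phenotype: pd.Series,
                          gene_sets: dict[str, list[str]],
                          n_g_grid: Sequence[int] = DEFAULT_GRID,
                          n_f_grid: Sequence[int] = DEFAULT_GRID,
                          b: int = 50,
                          pool_size: int = DEFAULT_POOL_SIZE,
                          top_k: int = DEFAULT_TOP_K,
                          seed: int = 0,
                          tuning: Optional[TuningConfig] = None,
                          region: str = "bulk") -> SignatureModel:
    """Run the full feature-generation + classifier pipeline.

    For every (n_g, n_f) pair in the grid: screen genes by bootstrap
    stability, build candidate modules per gene set, keep the n_f modules
    with highest training AUC, and fit the ElasticNet.  The grid point
    with the best internal-CV AUC wins (ties go to the smaller n_g, then
    smaller n_f, via iteration order).  Only the provided samples are
    used anywhere in the pipeline.
    """
    stats = bootstrap_gene_stability(expr, phenotype, b=b, seed=seed)
    best = None
    for n_g in n_g_grid:
        candidates: list[GeneModule] = []
        for set_name in gene_sets:
            candidates.extend(candidate_modules(
                set_name, gene_sets, stats, expr, phenotype, n_g,
                top_k=top_k, pool_size=pool_size,
            ))
        if not candidates:
            continue
        for n_f in n_f_grid:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                selected = select_top_modules(candidates, n_f)
            features = signature_features(expr, selected)
            coef, intercept, std, cv_auc, params = fit_elasticnet(
                features, phenotype, seed=seed, tuning=tuning)
            if best is None or cv_auc > best[0]:
                best = (cv_auc, n_g, n_f, selected, coef, intercept, std,
                        params)
    if best is None:
        raise ValueError("no candidate modules at any grid point; "
                         "not enough stable genes")
    cv_auc, n_g, n_f, selected, coef, intercept, std, params = best
    return SignatureModel(
        modules=list(selected),
        module_coefficients=np.asarray(coef, dtype=float),
        intercept=intercept,
        n_g=n_g,
        n_f=len(selected),
        region=region,
        standardization=std,
        metadata={"cv_auc": cv_auc, "seed": seed, "n_g": n_g, "n_f": n_f,
                  **params},
    )


def loocv(expr: pd.DataFrame, phenotype: pd.Series,
          gene_sets: dict[str, list[str]],
          n_g_grid: Sequence[int] = DEFAULT_GRID,
          n_f_grid: Sequence[int] = DEFAULT_GRID,
          b: int = 50,
          pool_size: int = DEFAULT_POOL_SIZE,
          top_k: int = DEFAULT_TOP_K,
          seed: int = 0,
          tuning: Optional[TuningConfig] = None,
          on_empty: str = "error",
          return_details: bool = False):
    """External leave-one-out evaluation of the whole pipeline.

    For every sample the full pipeline — gene screening, module building,
    module selection, hyperparameter tuning, classifier fitting — is
    re-run from scratch on the remaining samples, and the held-out sample
    is scored by the resulting model.  Returns one out-of-fold score per
    sample (plus the per-fold models when ``return_details``).

    ``on_empty`` controls folds in which no gene set yields a candidate
    module (possible in signal-free data, where few genes are stable):
    ``"error"`` propagates the training error, ``"neutral"`` assigns the
    uninformative score 0.5 to the held-out sample.
    """
    if on_empty not in ("error", "neutral"):
        raise ValueError("on_empty must be 'error' or 'neutral'")
    _encode_labels(phenotype, expr.columns)  # validate labels up front
    scores = {}
    details = {}
    for sample in expr.columns:
        rest = expr.drop(columns=[sample])
        try:
            model = train_signature_model(
                rest, phenotype, gene_sets,
                n_g_grid=n_g_grid, n_f_grid=n_f_grid, b=b,
                pool_size=pool_size, top_k=top_k, seed=seed, tuning=tuning,
            )
        except ValueError as exc:
            if on_empty == "error" or "no candidate modules" not in str(exc):
                raise
            scores[sample] = 0.5
            if return_details:
                details[sample] = None
            continue
        features = signature_features(expr[[sample]], model.modules)
        scores[sample] = float(predict_score(model, features).iloc[0])
        if return_details:
            details[sample] = model
    out = pd.Series(scores, name="score").reindex(expr.columns)
    return (out, details) if return_details else out


# ---------------------------------------------------------------------------
# performance and agreement statistics
# ---------------------------------------------------------------------------

def roc_auc_ci(scores: pd.Series, phenotype: pd.Series,
               conf: float = 0.95) -> tuple[float, float, float]:
    """Mann-Whitney AUC with a DeLong confidence interval, clipped to [0, 1]."""
    labels = pd.Series(phenotype).reindex(scores.index)
    pos, neg = _class_masks(labels.values)
    x = np.asarray(scores, dtype=float)[pos]   # early relapse
    y = np.asarray(scores, dtype=float)[neg]
    m, n = len(x), len(y)
    # psi(x, y) = 1[x > y] + 0.5 * 1[x == y], structural components
    cmp = (x[:, None] > y[None, :]).astype(float) \
        + 0.5 * (x[:, None] == y[None, :])
    auc = cmp.mean()
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    z = sps.norm.ppf(0.5 + conf / 2.0)
    half = z * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def confusion_at_cutoff(scores: pd.Series, phenotype: pd.Series,
                        cutoff: float = 0.5, conf: float = 0.95) -> dict:
    """Sensitivity/specificity at a cutoff with Clopper-Pearson intervals.

    A sample is called early relapse when its score is strictly above the
    cutoff (a score exactly at the cutoff counts as no relapse).
    """
    labels = pd.Series(phenotype).reindex(scores.index)
    pos, neg = _class_masks(labels.values)
    s = np.asarray(scores, dtype=float)
    pred_pos = s > cutoff
    tp = int((pred_pos & pos).sum())
    tn = int((~pred_pos & neg).sum())
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    return {
        "sensitivity": tp / n_pos,
        "sensitivity_ci": clopper_pearson(tp, n_pos, conf),
        "specificity": tn / n_neg,
        "specificity_ci": clopper_pearson(tn, n_neg, conf),
        "tp": tp, "tn": tn, "n_early": n_pos, "n_no": n_neg,
        "cutoff": cutoff,
    }


@dataclass
class EvaluationReport:
    """Out-of-fold scores with the headline performance statistics."""

    scores: pd.Series
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    n_early: int
    n_no: int
    cutoff: float = 0.5

    def to_dict(self) -> dict:
        return {
            "scores": {k: float(v) for k, v in self.scores.items()},
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "n_early": self.n_early,
            "n_no": self.n_no,
            "cutoff": self.cutoff,
        }


def evaluate_scores(scores: pd.Series, phenotype: pd.Series,
                    cutoff: float = 0.5) -> EvaluationReport:
    """Bundle AUC (DeLong CI) and Se/Sp (exact CIs) into a report."""
    auc, lo, hi = roc_auc_ci(scores, phenotype)
    conf = confusion_at_cutoff(scores, phenotype, cutoff=cutoff)
    return EvaluationReport(
        scores=scores,
        auc=auc, auc_ci=(lo, hi),
        sensitivity=conf["sensitivity"],
        sensitivity_ci=conf["sensitivity_ci"],
        specificity=conf["specificity"],
        specificity_ci=conf["specificity_ci"],
        n_early=conf["n_early"], n_no=conf["n_no"], cutoff=cutoff,
    )


def combine_scores(scores_a: pd.Series, scores_b: pd.Series) -> pd.Series:
    """Average two score sets over the samples present in both.

    Samples present in only one set are excluded and reported in a
    warning; an empty intersection is an error.
    """
    common = [s for s in scores_a.index if s in scores_b.index]
    if not common:
        raise ValueError("no samples shared between the two score sets")
    excluded = sorted(set(scores_a.index).symmetric_difference(scores_b.index))
    if excluded:
        warnings.warn(f"samples excluded from the combined score "
                      f"(missing in one set): {excluded}", stacklevel=2)
    return ((scores_a.loc[common] + scores_b.loc[common]) / 2.0).rename("score")


def score_agreement(scores_a: pd.Series, scores_b: pd.Series,
                    cutoff: float = 0.5) -> tuple[float, float, float]:
    """(Pearson, Spearman, Cohen's kappa) agreement of two score sets.

    Correlations are computed on the scores of shared samples; kappa on
    the binary class assignments at the cutoff.  Zero-variance scores
    make the correlations undefined: a warning is emitted and NaN
    returned rather than a silent 0.
    """
    common = [s for s in scores_a.index if s in scores_b.index]
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    a = np.asarray(scores_a.loc[common], dtype=float)
    bvals = np.asarray(scores_b.loc[common], dtype=float)
    if a.std() == 0 or bvals.std() == 0:
        warnings.warn("zero-variance scores: correlations undefined",
                      stacklevel=2)
        pearson = spearman = float("nan")
    else:
        pearson = float(sps.pearsonr(a, bvals).statistic)
        spearman = float(sps.spearmanr(a, bvals).statistic)
    kappa = float(cohen_kappa_score(a > cutoff, bvals > cutoff))
    return pearson, spearman, kappa
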