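"""Per-gene discriminative statistics.

Each gene is scored by the Mann-Whitney AUC of the rule "higher expression
implies early relapse" and assigned a direction d_g: +1 when its mean
expression is higher in the early-relapse group, -1 when lower.  Stability
is assessed over b bootstrap resamples of the training samples: a gene is
stable when its direction is defined and identical in every resample, and
its reported AUC is the average over the resamples.

Bootstraps are stratified by outcome group (each group resampled at its own
size) so both classes are always present, and all genes share the same
bootstrap sample indices — the resampling is at the sample level, not per
gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import EARLY_RELAPSE, NO_RELAPSE


def _class_masks(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == EARLY_RELAPSE
    neg = labels == NO_RELAPSE
    unknown = ~(pos | neg)
    if unknown.any():
        raise ValueError(f"unknown labels: {sorted(set(labels[unknown]))}")
    if not pos.any() or not neg.any():
        raise ValueError("both outcome groups must be present")
    return pos, neg


def auc_mann_whitney(values, labels) -> float:
    """AUC of "higher value => early relapse", ties counted 1/2.

    Equals the fraction of (early, no-relapse) sample pairs in which the
    early-relapse sample has the larger value, counting tied pairs 0.5.
    """
    pos, neg = _class_masks(labels)
    values = np.asarray(values, dtype=float)
    ranks = rankdata(values)
    n_pos, n_neg = pos.sum(), neg.sum()
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _auc_matrix(values: np.ndarray, pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUC for a genes x samples array."""
    ranks = rankdata(values, axis=1)
    n_pos, n_neg = pos.sum(), neg.sum()
    u = ranks[:, pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def gene_direction(values, labels):
    """Direction of association: +1, -1, or None on an exact mean tie."""
    pos, neg = _class_masks(labels)
    values = np.asarray(values, dtype=float)
    diff = values[pos].mean() - values[neg].mean()
    if diff > 0:
        return 1
    if diff < 0:
        return -1
    return None


def bootstrap_gene_stability(expr: pd.DataFrame, phenotype: pd.Series,
                             b: int = 50, seed: int = 0) -> pd.DataFrame:
    """Bootstrap AUC and direction stability for every gene.

    Parameters
    ----------
    expr:
        genes x samples matrix; columns must be covered by ``phenotype``.
    phenotype:
        group label per sample.
    b:
        number of bootstrap resamples of the sample set (default 50).
    seed:
        seed of the single generator producing the shared resamples.

    Returns
    -------
    DataFrame indexed by gene with columns ``mean_auc`` (average bootstrap
    AUC), ``adjusted_auc`` (AUC of the signed gene d_g * x_g),
    ``direction`` (+1/-1, 0 when undefined), ``stable`` (bool) and
    ``n_bootstraps``.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    labels = phenotype.reindex(expr.columns)
    if labels.isna().any():
        missing = list(expr.columns[labels.isna()])
        raise ValueError(f"samples without phenotype: {missing}")
    pos, neg = _class_masks(labels.values)
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("need at least 2 samples per outcome group")

    values = expr.to_numpy(dtype=float)
    pos_idx = np.flatnonzero(pos)
    neg_idx = np.flatnonzero(neg)
    n_pos, n_neg = len(pos_idx), len(neg_idx)
    boot_pos = np.ones(n_pos + n_neg, dtype=bool)
    boot_pos[n_pos:] = False

    rng = np.random.default_rng(seed)
    n_genes = values.shape[0]
    auc_sum = np.zeros(n_genes)
    sign_ref = np.zeros(n_genes)
    consistent = np.ones(n_genes, dtype=bool)
    for k in range(b):
        cols = np.concatenate([rng.choice(pos_idx, size=n_pos, replace=True),
                               rng.choice(neg_idx, size=n_neg, replace=True)])
        boot = values[:, cols]
        auc_sum += _auc_matrix(boot, boot_pos, ~boot_pos)
        diff = boot[:, :n_pos].mean(axis=1) - boot[:, n_pos:].mean(axis=1)
        sign = np.sign(diff)
        if k == 0:
            sign_ref = sign
        consistent &= (sign == sign_ref) & (sign != 0)

    direction = np.where(consistent, sign_ref, 0).astype(int)
    mean_auc = auc_sum / b
    # discriminative power of the signed gene d_g * x_g: a gene with
    # direction -1 and AUC near 0 is as predictive as one near 1
    adjusted = np.where(direction < 0, 1.0 - mean_auc,
                        np.where(direction > 0, mean_auc,
                                 np.maximum(mean_auc, 1.0 - mean_auc)))
    return pd.DataFrame(
        {
            "mean_auc": mean_auc,
            "adjusted_auc": adjusted,
            "direction": direction,
            "stable": consistent,
            "n_bootstraps": b,
        },
        index=expr.index,
    )
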