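"""Signed gene modules built from gene-set collections.

A gene module is a small ordered list of genes from a single gene set,
each carrying its direction of association d_g with the outcome.  Its
value for a sample is the direction-weighted mean of the member genes'
log expression, (1/n_g) * sum_g d_g * x_g, so a module behaves as a
one-dimensional signed meta-gene.

Candidate modules for a set are found by restricting the set to its
stable genes, ranking those by mean bootstrap AUC, and exhaustively
scoring every n_g-subset of the top ``pool_size`` genes by the training
AUC of the module value; the best ``top_k`` subsets become candidates.
The search space is bounded (C(8, 4) = 70 subsets at the defaults) while
still selecting the top subsets by AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .gene_stats import _class_masks

DEFAULT_POOL_SIZE = 8
DEFAULT_TOP_K = 5


@dataclass(frozen=True)
class GeneModule:
    """An ordered, signed gene list from one source gene set."""

    name: str
    genes: tuple[str, ...]
    directions: tuple[int, ...]
    source_set: str
    train_auc: Optional[float] = None

    def __post_init__(self):
        if len(self.genes) != len(self.directions):
            raise ValueError("genes and directions must have equal length")
        if len(self.genes) == 0:
            raise ValueError("a module needs at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("module genes must be distinct")
        if any(d not in (-1, 1) for d in self.directions):
            raise ValueError("directions must be +1 or -1")

    @property
    def n_g(self) -> int:
        return len(self.genes)


def module_score(expr: pd.DataFrame, module: GeneModule) -> pd.Series:
    """Per-sample module value (1/n_g) * sum_g d_g * x_g."""
    missing = [g for g in module.genes if g not in expr.index]
    if missing:
        raise KeyError(f"module {module.name!r}: genes missing from the "
                       f"expression matrix: {missing}")
    x = expr.loc[list(module.genes)].to_numpy(dtype=float)
    d = np.asarray(module.directions, dtype=float)
    return pd.Series(d @ x / module.n_g, index=expr.columns, name=module.name)


def candidate_modules(set_name: str, gene_sets: dict[str, list[str]],
                      stats: pd.DataFrame, expr: pd.DataFrame,
                      phenotype: pd.Series, n_g: int,
                      top_k: int = DEFAULT_TOP_K,
                      pool_size: int = DEFAULT_POOL_SIZE) -> list[GeneModule]:
    """Best ``top_k`` n_g-gene modules from one gene set.

    The set's genes are intersected with the stable genes of ``stats``
    that are present in ``expr``, ranked by direction-adjusted bootstrap
    AUC, and all
    n_g-subsets of the ``pool_size`` top-ranked genes are scored by the
    training AUC of their module value.  Returns modules in
    non-increasing train-AUC order (ties broken by the larger sum of
    member gene AUCs, then lexicographic gene order); an empty list when
    fewer than n_g stable genes remain.
    """
    if n_g < 1:
        raise ValueError("n_g must be >= 1")
    members = gene_sets[set_name]
    stable = stats.index[stats["stable"]]
    pool = [g for g in members if g in stable and g in expr.index]
    if len(pool) < n_g:
        return []
    # rank the stable members by direction-adjusted bootstrap AUC, so a
    # gene with d = -1 and AUC near 0 ranks as high as one near 1
    pool = sorted(pool, key=lambda g: (-stats.at[g, "adjusted_auc"], g))[:pool_size]

    labels = phenotype.reindex(expr.columns).values
    pos, neg = _class_masks(labels)
    signed = (expr.loc[pool].to_numpy(dtype=float)
              * stats.loc[pool, "direction"].to_numpy(dtype=float)[:, None])

    combos = list(combinations(range(len(pool)), n_g))
    combo_idx = np.array(combos)
    scores = signed[combo_idx].mean(axis=1)          # (n_combos, n_samples)
    ranks = rankdata(scores, axis=1)
    n_pos, n_neg = pos.sum(), neg.sum()
    aucs = (ranks[:, pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    member_auc = stats.loc[pool, "adjusted_auc"].to_numpy(dtype=float)
    order = sorted(
        range(len(combos)),
        key=lambda i: (-aucs[i], -member_auc[combo_idx[i]].sum(),
                       tuple(pool[j] for j in combos[i])),
    )
    modules = []
    for rank, i in enumerate(order[:top_k], start=1):
        genes = tuple(pool[j] for j in combos[i])
        modules.append(GeneModule(
            name=f"{set_name}_{rank}",
            genes=genes,
            directions=tuple(int(stats.at[g, "direction"]) for g in genes),
            source_set=set_name,
            train_auc=float(aucs[i]),
        ))
    return modules


def select_top_modules(modules: Sequence[GeneModule], n_f: int) -> list[GeneModule]:
    """The ``n_f`` modules with the highest training AUC across all sets.

    Genes may recur across modules and several modules may come from one
    gene set.  Returns fewer than ``n_f`` (with a warning) when fewer
    candidates exist; raises on an empty candidate list.
    """
    if not modules:
        raise ValueError("no candidate modules to select from")
    if n_f < 1:
        raise ValueError("n_f must be >= 1")
    ranked = sorted(modules, key=lambda m: (-(m.train_auc or 0.0), m.name))
    if len(ranked) < n_f:
        warnings.warn(
            f"only {len(ranked)} candidate modules for n_f={n_f}",
            stacklevel=2,
        )
    return ranked[:n_f]
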