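"""Published early-relapse signatures, shipped as fixed data files.

Three frozen models are packaged: a ``baseline`` signature (bulk profiles
restricted to a cross-platform gene intersection; 5 modules of 4 genes), a
``bulk`` tumor signature (3 modules of 5 genes) and an ``invasion_front``
signature (3 modules of 4 genes).  No intercept or cutoff was published
with them, so applying a frozen signature yields an *uncalibrated linear
risk score* — valid for ranking samples within a cohort (higher score =
higher early-relapse risk), not a posterior probability.

The published coefficients' expression scale is unstated; the signatures
assume log-scale within-cohort values, and an optional per-gene
standardization flag is provided.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .io_formats import read_signature
from .model_train_eval import SignatureModel

PUBLISHED_SIGNATURES = ("baseline", "bulk", "invasion_front")


def load_published_signature(name: str) -> SignatureModel:
    """Load one of the packaged signatures by region name."""
    if name not in PUBLISHED_SIGNATURES:
        raise ValueError(
            f"unknown signature {name!r}; available: {PUBLISHED_SIGNATURES}"
        )
    path = resources.files("frontsig.data").joinpath(f"{name}.json")
    with resources.as_file(path) as p:
        return read_signature(p)


def apply_signature(sig: SignatureModel, expr: pd.DataFrame,
                    strict: bool = True,
                    standardize: bool = False) -> pd.Series:
    """Linear risk score of a frozen signature for every sample.

    score(sample) = sum_m coefficient_m * module_value_m, with each module
    value the direction-weighted mean of its genes' expression.

    Parameters
    ----------
    strict:
        When True (default) all signature genes must be present; missing
        genes raise an error listing them.  When False, missing genes are
        dropped and each affected module is renormalized by its remaining
        size, with a warning (a module losing all its genes is an error).
    standardize:
        Z-score each gene across samples first, for use when the cohort's
        expression scale differs from log intensities.
    """
    if standardize:
        values = expr.to_numpy(dtype=float)
        sd = values.std(axis=1, ddof=0, keepdims=True)
        sd = np.where(sd == 0.0, 1.0, sd)
        expr = pd.DataFrame((values - values.mean(axis=1, keepdims=True)) / sd,
                            index=expr.index, columns=expr.columns)

    all_missing = sorted({g for m in sig.modules for g in m.genes
                          if g not in expr.index})
    if all_missing:
        if strict:
            raise KeyError(
                f"signature genes missing from the expression matrix: "
                f"{all_missing}"
            )
        warnings.warn(
            f"missing genes dropped; affected modules renormalized: "
            f"{all_missing}", stacklevel=2,
        )

    score = np.zeros(expr.shape[1])
    for module, coef in zip(sig.modules, sig.module_coefficients):
        keep = [(g, d) for g, d in zip(module.genes, module.directions)
                if g in expr.index]
        if not keep:
            raise KeyError(
                f"module {module.name!r} has no genes left in the matrix"
            )
        genes, dirs = zip(*keep)
        x = expr.loc[list(genes)].to_numpy(dtype=float)
        value = np.asarray(dirs, dtype=float) @ x / len(genes)
        score += float(coef) * value
    return pd.Series(score, index=expr.columns, name="risk_score")
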