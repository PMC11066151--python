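"""Cohort-description statistics: exact tests and binomial intervals.

Implements the two-sided Fisher exact test with the
"probability-at-most-observed" summation convention, the pooled-variance
Student t test, and the Clopper-Pearson exact binomial confidence
interval used for sensitivity and specificity.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

# relative tolerance when comparing table probabilities to the observed
# one, guarding against floating-point noise in the hypergeometric pmf
_FISHER_RELTOL = 1e-7


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Conditional on the margins, sums the hypergeometric probabilities of
    every table whose probability does not exceed that of the observed
    table (within relative tolerance 1e-7).  Returns a p-value in (0, 1].
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)):
            raise ValueError("cell counts must be integers")
        t = t.astype(int)
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n < 1:
        raise ValueError("table total must be >= 1")
    row1, col1 = a + b, a + c
    dist = sps.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = pmf[pmf <= p_obs * (1.0 + _FISHER_RELTOL)].sum()
    return float(min(p, 1.0))


def two_sample_t(x, y, pooled: bool = True) -> tuple[float, float, float]:
    """Two-sided two-sample t test; returns ``(t, df, p)``.

    Pooled (Student) variance by default, with df = n_x + n_y - 2;
    ``pooled=False`` gives the Welch variant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if pooled and x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)


def clopper_pearson(successes: int, trials: int,
                    conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles.

    The lower bound is 0 when ``successes == 0`` and the upper bound 1
    when ``successes == trials``.
    """
    k, n = int(successes), int(trials)
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    if not 0 < conf < 1:
        raise ValueError("conf must lie in (0, 1)")
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high
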