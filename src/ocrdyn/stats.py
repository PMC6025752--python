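"""Shared exact statistics: two-sided Fisher, BH FDR, exact binomial.

The Fisher test here is the single implementation used by every module
that needs a 2x2 test (motif enrichment, concordance, TF stage
specificity). Two-sidedness follows the classical definition: the sum of
the probabilities of all tables, with the observed margins fixed, whose
probability does not exceed that of the observed table.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

# relative slack when comparing discrete probability masses, so that
# tables tied with the observed one up to float error are included
_TIE_SLACK = 1e-12


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    Parameters
    ----------
    table : 2x2 array-like of non-negative ints, rows are groups,
        columns are outcomes.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer cells")
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    if n == 0:
        return 1.0
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = sps.hypergeom.logpmf(support, n, c1, r1)
    pmf = np.exp(logpmf)
    obs = pmf[a - lo]
    p = float(pmf[pmf <= obs * (1.0 + _TIE_SLACK)].sum())
    return min(1.0, p)


def fisher_fold(table: Sequence[Sequence[int]]) -> float:
    """Ratio of row-wise success fractions: (a/(a+b)) / (c/(c+d)).

    Returns ``inf`` when only the first row has successes and ``nan``
    when neither does.
    """
    t = np.asarray(table, dtype=float)
    f1 = t[0, 0] / t[0].sum() if t[0].sum() > 0 else np.nan
    f2 = t[1, 0] / t[1].sum() if t[1].sum() > 0 else np.nan
    if np.isnan(f1) or np.isnan(f2):
        return float("nan")
    if f2 == 0:
        return float("inf") if f1 > 0 else float("nan")
    return float(f1 / f2)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def binomial_test_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test (minimum-likelihood definition)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)


def log_nb_conditional_weights(T: int, r_a: float, r_b: float) -> np.ndarray:
    """Unnormalised log-weights of the conditional distribution of ``A``
    given ``A + B = T`` for independent ``A ~ NB(r_a, p)``,
    ``B ~ NB(r_b, p)`` with a common success probability.

    The common ``p`` cancels, leaving a beta-negative-binomial shape that
    depends only on the dispersions (shape parameters).
    """
    a = np.arange(T + 1, dtype=float)
    return (
        gammaln(a + r_a)
        - gammaln(a + 1.0)
        + gammaln(T - a + r_b)
        - gammaln(T - a + 1.0)
    )


def conditional_two_sided_p(log_weights: np.ndarray, observed: int) -> float:
    """Two-sided p from unnormalised log-weights over splits 0..T: total
    mass of splits no more probable than the observed one."""
    lw = np.asarray(log_weights, dtype=float)
    w = np.exp(lw - lw.max())
    total = w.sum()
    obs = w[observed]
    p = w[w <= obs * (1.0 + _TIE_SLACK)].sum() / total
    return float(min(1.0, p))
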