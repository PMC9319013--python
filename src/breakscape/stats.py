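"""In-repo statistical primitives: two-sided Fisher's exact test and
Benjamini-Hochberg FDR.

Both are deliberately implemented here rather than delegated: the exact
test's two-sided definition (minimum-likelihood) and the step-up FDR are
load-bearing for the enrichment and differential-expression results, and
the tests cross-check them against independent implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp


def _log_hypergeom_pmf(x: np.ndarray, n: int, K: int, N: int) -> np.ndarray:
    """log P(X = x) for X ~ Hypergeometric(population n, successes K,
    draws N)."""
    x = np.asarray(x)
    return (
        gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
        + gammaln(n - K + 1) - gammaln(N - x + 1) - gammaln(n - K - (N - x) + 1)
        - (gammaln(n + 1) - gammaln(N + 1) - gammaln(n - N + 1))
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     alternative: str = "two-sided") -> float:
    """Fisher's exact p for the table [[a, b], [c, d]].

    The default two-sided p uses the minimum-likelihood definition: the
    sum, over all tables with the observed margins, of hypergeometric
    probabilities no larger than that of the observed table, computed in
    log space with a relative tolerance of 1e-7 on the probability
    comparison (guards against floating-point ties, the convention used
    by standard software). ``alternative="greater"`` gives the one-sided
    upper tail P(X >= a) - the value some published analyses report.
    """
    cells = (a, b, c, d)
    if any(int(v) != v for v in cells):
        raise ValueError("cells must be integers")
    a, b, c, d = (int(v) for v in cells)
    if min(a, b, c, d) < 0:
        raise ValueError("cells must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    K = a + c          # column-1 margin
    N = a + b          # row-1 margin
    lo = max(0, N - (n - K))
    hi = min(N, K)
    support = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(support, n, K, N)
    log_obs = _log_hypergeom_pmf(np.array([a]), n, K, N)[0]
    if alternative == "two-sided":
        keep = logpmf <= log_obs + np.log1p(1e-7)
    elif alternative == "greater":
        keep = support >= a
    elif alternative == "less":
        keep = support <= a
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = float(np.exp(logsumexp(logpmf[keep])))
    return min(p, 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforced.

    q_(i) = min over j >= i of p_(j) * m / j, clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
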