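"""Independent brute-force oracles used by multiple test modules."""

from __future__ import annotations

from scipy.stats import binom


def clopper_pearson_by_bisection(
    k: int, n: int, alpha: float = 0.05, tol: float = 1e-12
) -> tuple[float, float]:
    """Invert the binomial tail probabilities by plain bisection.

    Independent of the beta-quantile route used by the implementation: the
    lower bound is the p with upper-tail probability P(X >= k | p) = alpha/2,
    the upper bound the p with lower-tail probability P(X <= k | p) = alpha/2.
    """

    def bisect(f, target, lo=0.0, hi=1.0, increasing=True):
        for _ in range(200):
            mid = (lo + hi) / 2
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    if k == 0:
        low = 0.0
    else:
        # P(X >= k | p) increases in p
        low = bisect(lambda p: binom.sf(k - 1, n, p), alpha / 2, increasing=True)
    if k == n:
        high = 1.0
    else:
        # P(X <= k | p) decreases in p
        high = bisect(lambda p: binom.cdf(k, n, p), alpha / 2, increasing=False)
    return low, high
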