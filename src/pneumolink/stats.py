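"""Exact binomial proportion estimation, table rounding, and small-count censoring.

Every headline number produced by this package is a proportion ``k/n`` of
record counts, reported as a percentage with a 95% confidence interval.
The default interval is Clopper–Pearson ("exact"), obtained by inverting
the binomial tail probabilities; a Wald (normal-approximation) interval is
available for comparison because published tables in this literature are
sometimes only reproducible under the approximation at one-decimal rounding.

Rendered counts between 1 and 4 are suppressed as ``"< 5"`` following the
usual statistical-disclosure rule for small cells in EHR research outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy.stats import beta as _beta
from scipy.stats import norm as _norm

__all__ = [
    "ProportionEstimate",
    "exact_binomial_ci",
    "wald_ci",
    "proportion_percent",
    "censor_count",
]


def _check_counts(k: int, n: int) -> None:
    if n < 1:
        raise ValueError(f"denominator must be >= 1, got n={n}")
    if not 0 <= k <= n:
        raise ValueError(f"numerator must satisfy 0 <= k <= n, got k={k}, n={n}")


def exact_binomial_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper–Pearson interval for a binomial proportion, on the [0, 1] scale.

    The lower bound solves ``P(X >= k | p) = alpha/2`` (0 when ``k == 0``) and
    the upper bound solves ``P(X <= k | p) = alpha/2`` (1 when ``k == n``),
    computed through the beta-quantile representation of the binomial tails.
    """
    _check_counts(k, n)
    low = 0.0 if k == 0 else float(_beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(_beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def wald_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Normal-approximation interval, clipped to [0, 1]."""
    _check_counts(k, n)
    p = k / n
    z = float(_norm.ppf(1 - alpha / 2))
    half = z * (p * (1 - p) / n) ** 0.5
    return max(0.0, p - half), min(1.0, p + half)


def proportion_percent(k: int, n: int, decimals: int = 1) -> float:
    """``100 * k / n`` rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding is used so that boundary cases render the
    way they are conventionally printed in clinical tables.
    """
    _check_counts(k, n)
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(k) * 100 / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP)
    return float(value)


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def censor_count(k: int, threshold: int = 5) -> str:
    """Render a count with small-cell suppression: 0 -> "0", 1..4 -> "< 5"."""
    if k < 0:
        raise ValueError(f"count must be >= 0, got {k}")
    if k == 0:
        return "0"
    if k < threshold:
        return f"< {threshold}"
    return str(k)


@dataclass(frozen=True)
class ProportionEstimate:
    """A reported proportion: counts, percentage, and confidence interval.

    ``percent``, ``ci_low`` and ``ci_high`` are on the percentage scale and
    rounded half-up to one decimal, matching how the estimates are rendered.
    """

    k: int
    n: int
    percent: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    method: str = "clopper_pearson"

    @classmethod
    def from_counts(
        cls, k: int, n: int, alpha: float = 0.05, method: str = "clopper_pearson"
    ) -> "ProportionEstimate":
        if method == "clopper_pearson":
            low, high = exact_binomial_ci(k, n, alpha)
        elif method == "wald":
            low, high = wald_ci(k, n, alpha)
        else:
            raise ValueError(f"unknown CI method: {method!r}")
        return cls(
            k=k,
            n=n,
            percent=proportion_percent(k, n),
            ci_low=_round_half_up(low * 100),
            ci_high=_round_half_up(high * 100),
            alpha=alpha,
            method=method,
        )

    def render(self, threshold: int = 5) -> str:
        """Censored display string, e.g. ``"57.7 (55.6-59.8)"`` or ``"< 5"``."""
        if 0 < self.k < threshold:
            return f"{censor_count(self.k, threshold)} ({self.percent:.1f}%)"
        return f"{self.percent:.1f} ({self.ci_low:.1f}-{self.ci_high:.1f})"
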