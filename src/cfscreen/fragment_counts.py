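"""Sampling distribution of the observed mutant-fragment percentage.

Counting ``n`` deduplicated plasma DNA fragments at one mutation site, each
carrying the mutation independently with probability ``m/100``, the observed
percentage is a scaled binomial.  The screening model uses its Gaussian
approximation, mean ``m`` and standard deviation ``sqrt(m (100 - m) / n)``
(in percent); the exact binomial tail is kept alongside as an independent
oracle for that approximation.

A screening result is *positive* when the observed percentage is equal to or
greater than the cut-off — the boundary is inclusive, which matters: a
distribution whose mean sits exactly on the cut-off has tail probability
exactly one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binom, norm

__all__ = [
    "SiteDistribution",
    "percent_sd",
    "tail_prob_gaussian",
    "tail_prob_binomial",
]


@dataclass(frozen=True)
class SiteDistribution:
    """Observed-percentage distribution at one site: mean ``m``, count ``n``."""

    m: float  # expected mutant percentage, 0..100
    n: int  # deduplicated fragments covering the site

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 100.0:
            raise ValueError(f"mean percent must be in [0, 100], got {self.m}")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError(f"fragment count must be a positive integer, got {self.n}")

    @property
    def sd(self) -> float:
        return percent_sd(self.m, self.n)


def percent_sd(m: float, n: int) -> float:
    """Standard deviation (percent) of the observed percentage: √(m(100−m)/n)."""
    if not 0.0 <= m <= 100.0:
        raise ValueError(f"mean percent must be in [0, 100], got {m}")
    if n < 1:
        raise ValueError(f"fragment count must be >= 1, got {n}")
    return math.sqrt(m * (100.0 - m) / n)


def tail_prob_gaussian(m: float, n: int, cutoff: float) -> float:
    """P(observed percent ≥ cutoff) under the Gaussian approximation.

    Degenerate means (``m`` = 0 or 100) have zero sd and are treated as a
    point mass: tail 1 if ``m >= cutoff`` else 0.  No continuity correction
    is applied.
    """
    sd = percent_sd(m, n)
    if sd == 0.0:
        return 1.0 if m >= cutoff else 0.0
    return float(norm.sf((cutoff - m) / sd))


def tail_prob_binomial(m: float, n: int, cutoff: float) -> float:
    """Exact P(K ≥ ⌈cutoff·n/100⌉) for K ~ Binomial(n, m/100).

    The inclusive threshold count is ``k = ceil(cutoff * n / 100)``: the
    smallest fragment count whose percentage is ≥ the cut-off.
    """
    if int(n) != n or n < 1:
        raise ValueError(f"fragment count must be a positive integer, got {n}")
    if not 0.0 <= m <= 100.0:
        raise ValueError(f"mean percent must be in [0, 100], got {m}")
    k = math.ceil(cutoff * n / 100.0)
    if k <= 0:
        return 1.0
    return float(binom.sf(k - 1, n, m / 100.0))
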