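"""Shared elementary statistics: Poisson tails, summary stats, read fractions."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


def poisson_upper_tail(k: int, mu: float) -> float:
    """P(X >= k) for X ~ Poisson(mu), via the survival function (stable for
    small tails; never computed as 1 - CDF)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(sps.poisson.sf(k - 1, mu))


@dataclass(frozen=True)
class ReadFraction:
    percent: float
    rounded: int


def variant_read_fraction(variant_reads: int, total_reads: int) -> ReadFraction:
    """Percentage of reads carrying a variant, with round-half-away-from-zero
    integer rounding (so 54.05% prints as 54%, 23.68% as 24%)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if variant_reads < 0 or variant_reads > total_reads:
        raise ValueError("variant_reads must be in [0, total_reads]")
    pct = 100.0 * variant_reads / total_reads
    rounded = int(math.floor(pct + 0.5)) if pct >= 0 else -int(math.floor(-pct + 0.5))
    return ReadFraction(percent=pct, rounded=rounded)


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    sem: float
    n: int
    degenerate: bool = False  # n == 1: sd and sem reported as 0


def mean_sd_sem(values: Sequence[float]) -> SummaryStats:
    """Mean, sample standard deviation (n-1 denominator) and standard error."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("mean_sd_sem requires at least one value")
    if vals.size == 1:
        return SummaryStats(mean=float(vals[0]), sd=0.0, sem=0.0, n=1, degenerate=True)
    sd = float(np.std(vals, ddof=1))
    return SummaryStats(
        mean=float(np.mean(vals)),
        sd=sd,
        sem=sd / math.sqrt(vals.size),
        n=int(vals.size),
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()
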