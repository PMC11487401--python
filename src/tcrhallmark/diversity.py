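"""Clonality (1 − normalized Shannon–Wiener entropy) and V-segment usage."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import Clonotype, Repertoire
from .preprocess import PooledCloneset


@dataclass(frozen=True)
class DiversityReport:
    sample_id: str
    n_clonotypes: int
    shannon: float            # H = -sum f_i ln f_i (nats)
    normalized_shannon: float  # H / ln N
    clonality: float           # 1 - H / ln N


def clonality(repertoire: Repertoire) -> DiversityReport:
    """Clonality of a repertoire: 0 for a perfectly even repertoire, 1 for a
    monoclonal one. Entropy uses the natural log over clones with f > 0; a
    single-clone repertoire is maximally clonal by convention."""
    total = repertoire.frequency_sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(
            f"repertoire {repertoire.sample_id}: frequencies sum to {total:.6g}, "
            "expected 1 (normalize first)"
        )
    freqs = np.array([c.frequency for c in repertoire.clonotypes if c.frequency > 0])
    n = freqs.size
    if n == 0:
        raise ValueError(f"repertoire {repertoire.sample_id} has no positive-frequency clones")
    h = float(-np.sum(freqs * np.log(freqs)))
    if n == 1:
        return DiversityReport(repertoire.sample_id, 1, 0.0, 0.0, 1.0)
    norm = h / math.log(n)
    return DiversityReport(repertoire.sample_id, n, h, norm, 1.0 - norm)


def _usage_items(items) -> list[tuple[str, float]]:
    """Extract (v_segment, frequency) pairs from a Repertoire, PooledCloneset,
    or iterable of objects carrying V calls."""
    if isinstance(items, Repertoire):
        pairs = [(c.v_segment, c.frequency) for c in items.clonotypes]
    elif isinstance(items, PooledCloneset):
        pairs = [
            (e.representative_v, e.cumulative_frequency) for e in items.entries.values()
        ]
    else:
        pairs = []
        for it in items:
            if isinstance(it, Clonotype):
                pairs.append((it.v_segment, it.frequency))
            else:  # convergence hits and similar records
                v = getattr(it, "v", None) or getattr(it, "v_segment", None)
                f = getattr(it, "cumulative_frequency", None)
                if f is None:
                    f = getattr(it, "frequency", None)
                pairs.append((v, f if f is not None else 0.0))
    return pairs


def v_usage(items, weighting: str = "clonotype_count") -> dict[str, float]:
    """V-segment usage as fractions summing to 1.

    ``clonotype_count`` weighting counts clonotypes per segment (the convention
    behind statements like "TRBV17 was in 24.4% of clonotypes");
    ``frequency`` weighting sums clone frequencies per segment.
    """
    if weighting not in ("frequency", "clonotype_count"):
        raise ValueError("weighting must be 'frequency' or 'clonotype_count'")
    pairs = _usage_items(items)
    if not pairs:
        raise ValueError("v_usage on empty input")
    missing = [v for v, _ in pairs if not v]
    if missing:
        raise ValueError(f"{len(missing)} item(s) lack a V call")
    usage: dict[str, float] = {}
    for v, f in pairs:
        usage[v] = usage.get(v, 0.0) + (f if weighting == "frequency" else 1.0)
    total = sum(usage.values())
    if total <= 0:
        raise ValueError("total usage weight is zero")
    return {v: w / total for v, w in sorted(usage.items())}
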