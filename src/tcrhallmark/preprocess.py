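"""Frequency filtering, sample-consistency checks, pooling and unique clonesets.

The per-sample chain mirrors standard repertoire hygiene for sorted-cell
TCR-seq: clones below a detection threshold (default 2.5e-5, i.e. the smallest
frequency a single cell can plausibly produce at the sorted depth) are dropped
and the remainder rescaled to sum to one. Samples of one vaccine group are then
pooled by CDR3 amino acid; clonotypes whose cumulative (summed-across-samples)
frequency stays at or below 5e-5 are discarded. Clonotypes shared between two
vaccine groups are removed from both to obtain group-unique clonesets.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Hashable, Sequence

import pandas as pd

from .io import Clonotype, Repertoire

DEFAULT_FREQUENCY_THRESHOLD = 2.5e-5
DEFAULT_MIN_CUMULATIVE = 5e-5

#: clonotype identity keys for amino-acid level analyses
KEY_MODES = ("cdr3aa", "cdr3aa_vj")


def clone_key(clonotype: Clonotype, key: str = "cdr3aa") -> Hashable:
    if key == "cdr3aa":
        return clonotype.cdr3aa
    if key == "cdr3aa_vj":
        return (clonotype.cdr3aa, clonotype.v_segment, clonotype.j_segment)
    raise ValueError(f"key must be one of {KEY_MODES}, got {key!r}")


@dataclass
class PoolEntry:
    """One pooled clonotype: cumulative frequency plus per-sample breakdown."""

    cdr3aa: str
    cumulative_frequency: float
    per_sample_frequencies: dict[str, float]
    representative_v: str | None = None
    representative_j: str | None = None


@dataclass
class PooledCloneset:
    """Per-group pooled cloneset keyed by clonotype identity."""

    group: str
    key_mode: str
    entries: dict[Hashable, PoolEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: Hashable) -> bool:
        return key in self.entries

    def to_frame(self) -> pd.DataFrame:
        samples = sorted({s for e in self.entries.values() for s in e.per_sample_frequencies})
        rows = []
        for key, e in self.entries.items():
            row = {
                "key": key if isinstance(key, str) else "|".join(str(k) for k in key),
                "cdr3aa": e.cdr3aa,
                "v": e.representative_v,
                "j": e.representative_j,
                "cumulative_frequency": e.cumulative_frequency,
            }
            for s in samples:
                row[s] = e.per_sample_frequencies.get(s, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


def filter_and_rescale(
    repertoire: Repertoire, threshold: float = DEFAULT_FREQUENCY_THRESHOLD
) -> Repertoire:
    """Drop clones with frequency <= threshold (strictly-above survive) and
    rescale the survivors' frequencies to sum to one. Read counts untouched."""
    if not repertoire.is_normalized():
        raise ValueError(
            f"repertoire {repertoire.sample_id} frequencies sum to "
            f"{repertoire.frequency_sum():.6g}; normalize before filtering"
        )
    kept = [c for c in repertoire.clonotypes if c.frequency > threshold]
    if not kept:
        raise ValueError(
            f"threshold {threshold} removes entire repertoire {repertoire.sample_id}"
        )
    mass = sum(c.frequency for c in kept)
    rescaled = [replace(c, frequency=c.frequency / mass) for c in kept]
    return Repertoire(
        sample_id=repertoire.sample_id,
        clonotypes=rescaled,
        total_reads=repertoire.total_reads,
        cell_count=repertoire.cell_count,
        meta=repertoire.meta,
    )


@dataclass(frozen=True)
class ConsistencyResult:
    ratio: float
    passes: bool


def consistency_ratio(repertoire: Repertoire) -> ConsistencyResult:
    """Total reads divided by the smallest positive clone's reads.

    The smallest clone is presumed to come from a single cell, so the ratio
    estimates the number of cells the reads could represent; the sample is
    consistent when it stays below the sorted cell count.
    """
    if repertoire.cell_count is None:
        raise ValueError(
            f"sample {repertoire.sample_id}: cell_count missing; "
            "provide it via the sample sheet"
        )
    positive = [c.read_count for c in repertoire.clonotypes if c.read_count > 0]
    if not positive:
        raise ValueError(f"sample {repertoire.sample_id}: no clone with positive reads")
    ratio = repertoire.total_reads / min(positive)
    return ConsistencyResult(ratio=ratio, passes=ratio < repertoire.cell_count)


def choose_threshold(
    repertoire: Repertoire,
    grid: Sequence[float] | None = None,
) -> float:
    """Smallest frequency threshold on a k×1e-6 grid whose filtered repertoire
    passes the cell-count consistency rule; 0 if it passes unfiltered."""
    if consistency_ratio(repertoire).passes:
        return 0.0
    if grid is None:
        grid = [k * 1e-6 for k in range(1, 1001)]
    for t in sorted(grid):
        try:
            filtered = filter_and_rescale(repertoire, t)
        except ValueError:
            break
        if consistency_ratio(filtered).passes:
            return t
    raise ValueError(
        f"sample {repertoire.sample_id}: no grid threshold satisfies the "
        "consistency rule"
    )


def pool_repertoires(
    repertoires: Sequence[Repertoire],
    key: str = "cdr3aa",
    min_cumulative: float = DEFAULT_MIN_CUMULATIVE,
) -> PooledCloneset:
    """Pool same-group samples by clonotype identity.

    Cumulative frequency of a key is the *sum* of its per-sample frequencies;
    keys with cumulative frequency <= ``min_cumulative`` are dropped.
    """
    if not repertoires:
        raise ValueError("pool_repertoires requires at least one repertoire")
    groups = {r.meta.group for r in repertoires}
    if len(groups) > 1:
        raise ValueError(f"cannot pool mixed groups {sorted(groups)}")
    if key not in KEY_MODES:
        raise ValueError(f"key must be one of {KEY_MODES}, got {key!r}")

    per_sample: dict[Hashable, dict[str, float]] = defaultdict(dict)
    v_votes: dict[Hashable, Counter] = defaultdict(Counter)
    j_votes: dict[Hashable, Counter] = defaultdict(Counter)
    aa_of: dict[Hashable, str] = {}
    for rep in repertoires:
        for c in rep.clonotypes:
            k = clone_key(c, key)
            aa_of[k] = c.cdr3aa
            per_sample[k][rep.sample_id] = per_sample[k].get(rep.sample_id, 0.0) + c.frequency
            if c.v_segment:
                # weight the modal-V vote by frequency contributed
                v_votes[k][c.v_segment] += c.frequency
            if c.j_segment:
                j_votes[k][c.j_segment] += c.frequency

    entries: dict[Hashable, PoolEntry] = {}
    for k, samples in per_sample.items():
        cumulative = sum(samples.values())
        if cumulative <= min_cumulative:
            continue
        entries[k] = PoolEntry(
            cdr3aa=aa_of[k],
            cumulative_frequency=cumulative,
            per_sample_frequencies=dict(samples),
            representative_v=v_votes[k].most_common(1)[0][0] if v_votes[k] else None,
            representative_j=j_votes[k].most_common(1)[0][0] if j_votes[k] else None,
        )
    return PooledCloneset(group=groups.pop(), key_mode=key, entries=entries)


@dataclass
class UniqueClonesets:
    unique_a: PooledCloneset
    unique_b: PooledCloneset
    overlap_fraction_a: float
    overlap_fraction_b: float
    n_overlap: int


def unique_clonesets(pool_a: PooledCloneset, pool_b: PooledCloneset) -> UniqueClonesets:
    """Remove clonotypes shared by both pools from each (cross-group exclusion).

    Overlap fractions are clone-count based: shared keys / keys in that pool
    before exclusion.
    """
    if pool_a.key_mode != pool_b.key_mode:
        raise ValueError(
            f"pools keyed differently: {pool_a.key_mode!r} vs {pool_b.key_mode!r}"
        )
    shared = set(pool_a.entries) & set(pool_b.entries)
    ua = PooledCloneset(
        group=pool_a.group,
        key_mode=pool_a.key_mode,
        entries={k: v for k, v in pool_a.entries.items() if k not in shared},
    )
    ub = PooledCloneset(
        group=pool_b.group,
        key_mode=pool_b.key_mode,
        entries={k: v for k, v in pool_b.entries.items() if k not in shared},
    )
    return UniqueClonesets(
        unique_a=ua,
        unique_b=ub,
        overlap_fraction_a=len(shared) / len(pool_a.entries) if pool_a.entries else 0.0,
        overlap_fraction_b=len(shared) / len(pool_b.entries) if pool_b.entries else 0.0,
        n_overlap=len(shared),
    )


def top_group_clones(
    pool: PooledCloneset, n: int, sample_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Rank pooled clonotypes by cumulative frequency (ties lexicographic on
    CDR3aa) and tabulate per-sample frequencies; absent samples render 0."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not pool.entries:
        raise ValueError("pool is empty")
    if sample_ids is None:
        sample_ids = sorted({s for e in pool.entries.values() for s in e.per_sample_frequencies})
    ranked = sorted(
        pool.entries.items(),
        key=lambda kv: (-kv[1].cumulative_frequency, kv[1].cdr3aa),
    )[:n]
    rows = []
    for key, e in ranked:
        row = {
            "group": pool.group,
            "v": e.representative_v,
            "cdr3aa": e.cdr3aa,
            "cumulative_frequency": e.cumulative_frequency,
        }
        for s in sample_ids:
            row[s] = e.per_sample_frequencies.get(s, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
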