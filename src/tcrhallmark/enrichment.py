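"""Draining- vs non-draining-lymph-node enrichment ratios.

For an entity (clone, cluster, or specificity group) the enrichment ratio is

    ratio = dLN_frequency / ndLN_frequency

where each side is the frequency summed over that side's samples. A side
summing to zero is replaced by a floor (default 2.5e-5, the smallest
retainable frequency at the default detection threshold) before division,
and the record is flagged as floored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import pandas as pd

from .clustering import Cluster, ClusterSet
from .io import Repertoire
from .preprocess import clone_key
from .stats import SummaryStats, mean_sd_sem

DEFAULT_FLOOR = 2.5e-5


@dataclass(frozen=True)
class EnrichmentRecord:
    entity_id: str
    dln_frequency: float
    ndln_frequency: float
    ratio: float
    floored: bool


def ln_side_map(samples: Sequence[Repertoire] | Mapping[str, str]) -> dict[str, str]:
    """sample_id -> lymph-node side, from repertoires or a ready mapping."""
    if isinstance(samples, Mapping):
        return dict(samples)
    return {r.sample_id: r.meta.ln_side for r in samples}


def _ratio(entity_id: str, dln: float, ndln: float, floor: float) -> EnrichmentRecord:
    floored = False
    if dln == 0.0:
        dln, floored = floor, True
    if ndln == 0.0:
        ndln, floored = floor, True
    return EnrichmentRecord(
        entity_id=entity_id,
        dln_frequency=dln,
        ndln_frequency=ndln,
        ratio=dln / ndln,
        floored=floored,
    )


def _split_sides(sides: Mapping[str, str]) -> tuple[list[str], list[str]]:
    dln = [s for s, side in sides.items() if side == "dLN"]
    ndln = [s for s, side in sides.items() if side == "ndLN"]
    if not dln or not ndln:
        raise ValueError("need at least one dLN and one ndLN sample")
    return dln, ndln


def clone_ln_ratio(
    key: Hashable,
    samples: Sequence[Repertoire],
    floor: float = DEFAULT_FLOOR,
    key_mode: str = "cdr3aa",
) -> EnrichmentRecord:
    """dLN/ndLN frequency ratio of one clonotype across annotated samples."""
    sides = ln_side_map(samples)
    dln_ids, ndln_ids = _split_sides(sides)
    freq = {r.sample_id: 0.0 for r in samples}
    for r in samples:
        for c in r.clonotypes:
            if clone_key(c, key_mode) == key:
                freq[r.sample_id] += c.frequency
    dln = sum(freq[s] for s in dln_ids)
    ndln = sum(freq[s] for s in ndln_ids)
    return _ratio(str(key), dln, ndln, floor)


def frequencies_ln_ratio(
    entity_id: str,
    per_sample_frequencies: Mapping[str, float],
    sides: Mapping[str, str],
    floor: float = DEFAULT_FLOOR,
) -> EnrichmentRecord:
    """Ratio from an already-tabulated per-sample frequency breakdown."""
    dln_ids, ndln_ids = _split_sides(sides)
    dln = sum(per_sample_frequencies.get(s, 0.0) for s in dln_ids)
    ndln = sum(per_sample_frequencies.get(s, 0.0) for s in ndln_ids)
    return _ratio(entity_id, dln, ndln, floor)


def cluster_ln_ratio(
    cluster: Cluster,
    samples: Sequence[Repertoire] | Mapping[str, str],
    floor: float = DEFAULT_FLOOR,
) -> EnrichmentRecord:
    """Summed member frequencies in dLN vs ndLN samples for one cluster."""
    sides = ln_side_map(samples)
    dln_ids, ndln_ids = _split_sides(sides)
    dln = sum(
        m.per_sample_frequencies.get(s, 0.0)
        for m in cluster.members
        for s in dln_ids
    )
    ndln = sum(
        m.per_sample_frequencies.get(s, 0.0)
        for m in cluster.members
        for s in ndln_ids
    )
    return _ratio(f"cluster_{cluster.cluster_id}", dln, ndln, floor)


def top_cluster_ratio_summary(
    clusters: ClusterSet | Sequence[Cluster],
    samples: Sequence[Repertoire] | Mapping[str, str],
    k: int = 30,
    floor: float = DEFAULT_FLOOR,
) -> SummaryStats:
    """Mean/SD/SEM of dLN-to-ndLN ratios over the top-k clusters (clusters
    ranked by size, then cumulative frequency)."""
    members = list(clusters.clusters if isinstance(clusters, ClusterSet) else clusters)
    if not members:
        raise ValueError("no clusters to summarize")
    ranked = sorted(members, key=lambda c: (-c.size, -c.cumulative_frequency, c.consensus))
    top = ranked[: max(1, k)]
    ratios = [cluster_ln_ratio(c, samples, floor).ratio for c in top]
    return mean_sd_sem(ratios)


def specificity_group_ratio(
    matches: pd.DataFrame,
    label: str,
    samples: Sequence[Repertoire] | Mapping[str, str],
    floor: float = DEFAULT_FLOOR,
) -> tuple[SummaryStats, list[EnrichmentRecord]]:
    """Per-clone dLN/ndLN ratios for all clones matching one specificity
    label, summarized as mean +/- SD (n-1) with SEM.

    ``matches`` is the per-clone match table from
    :func:`tcrhallmark.dbmatch.annotate_repertoires` (columns sample_id,
    cdr3aa, v, frequency, label).
    """
    sides = ln_side_map(samples)
    sub = matches[matches["label"] == label]
    if sub.empty:
        available = sorted(matches["label"].unique())
        raise ValueError(f"no clone matches label {label!r}; available: {available}")
    # one row per clone occurrence: drop duplicate matches of the same clone
    # against several records of this label
    if "clone_index" in sub.columns:
        sub = sub.drop_duplicates(subset=["sample_id", "clone_index"])
    records = []
    for (cdr3aa, v), grp in sub.groupby(["cdr3aa", "v"], dropna=False):
        per_sample = grp.groupby("sample_id")["frequency"].sum().to_dict()
        records.append(
            frequencies_ln_ratio(f"{cdr3aa}|{v}", per_sample, sides, floor)
        )
    return mean_sd_sem([r.ratio for r in records]), records


def enrichment_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "entity": r.entity_id,
                "dln_freq": r.dln_frequency,
                "ndln_freq": r.ndln_frequency,
                "ratio": r.ratio,
                "floored": r.floored,
            }
            for r in records
        ]
    )
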