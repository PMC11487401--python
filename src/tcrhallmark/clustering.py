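"""Assemble neighbor-enriched clonotypes into similarity clusters.

Clusters are connected components of the Hamming-1 graph over significant
clonotypes (edges additionally require matching V and J in linked mode).
Every member of a component therefore shares one CDR3 length. Components of
size >= 2 are reported as clusters, ranked by member count (ties: cumulative
frequency, then consensus string); singletons are kept separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .convergence import ConvergenceHit
from .io import SampleMeta


@dataclass
class Cluster:
    cluster_id: int
    members: list[ConvergenceHit]
    edges: list[tuple]  # canonical (min, max) key pairs at Hamming distance 1
    consensus: str
    size: int
    cumulative_frequency: float

    def member_cdr3s(self) -> set[str]:
        return {m.cdr3aa for m in self.members}


@dataclass
class ClusterSet:
    """Size->=2 components plus retained singletons; together they partition
    the input hit set."""

    clusters: list[Cluster]
    singletons: list[ConvergenceHit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)


def _hit_linkage(hit: ConvergenceHit) -> tuple:
    return (hit.v, hit.j)


def _hamming1_edges(hits: Sequence[ConvergenceHit], link_vj: bool) -> list[tuple]:
    """All Hamming-1 pairs among hits, via positional mask buckets."""
    buckets: dict[tuple, list[int]] = {}
    for idx, h in enumerate(hits):
        link = _hit_linkage(h) if link_vj else ()
        for i in range(len(h.cdr3aa)):
            pat = (i, h.cdr3aa[:i], h.cdr3aa[i + 1:], link)
            buckets.setdefault(pat, []).append(idx)
    edges: set[tuple[int, int]] = set()
    for members in buckets.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                if hits[i].cdr3aa != hits[j].cdr3aa:
                    edges.add((min(i, j), max(i, j)))
    return sorted(edges)


def consensus_sequence(
    members: Sequence[ConvergenceHit] | "Cluster",
    member_weights: str = "uniform",
) -> tuple[str, pd.DataFrame]:
    """Per-position majority letter plus the position-frequency matrix.

    ``uniform`` weights every member equally; ``frequency`` weights members by
    cumulative frequency. Ties go to the lexicographically smallest letter.
    The matrix (positions x letters) rows sum to 1 and suffice to regenerate
    a sequence logo externally.
    """
    if isinstance(members, Cluster):
        members = members.members
    if not members:
        raise ValueError("consensus of an empty member list")
    if member_weights not in ("uniform", "frequency"):
        raise ValueError("member_weights must be 'uniform' or 'frequency'")
    lengths = {len(m.cdr3aa) for m in members}
    if len(lengths) > 1:
        raise ValueError(f"mixed CDR3 lengths {sorted(lengths)} in one cluster")
    L = lengths.pop()
    cols: list[Counter] = [Counter() for _ in range(L)]
    for m in members:
        w = 1.0 if member_weights == "uniform" else m.cumulative_frequency
        for i, aa in enumerate(m.cdr3aa):
            cols[i][aa] += w
    letters = sorted({aa for c in cols for aa in c})
    matrix = pd.DataFrame(0.0, index=range(L), columns=letters)
    consensus = []
    for i, c in enumerate(cols):
        total = sum(c.values())
        for aa, w in c.items():
            matrix.loc[i, aa] = w / total if total > 0 else 0.0
        best = sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        consensus.append(best)
    return "".join(consensus), matrix


def build_clusters(hits: Sequence[ConvergenceHit], link_vj: bool = True) -> ClusterSet:
    """Connected components of the Hamming-1 (optionally V/J-linked) graph."""
    hits = list(hits)
    if not hits:
        return ClusterSet(clusters=[], singletons=[])
    edges = _hamming1_edges(hits, link_vj)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(hits)))
    graph.add_edges_from(edges)

    raw: list[tuple[list[int], list[tuple[int, int]]]] = []
    singles: list[ConvergenceHit] = []
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        if len(comp) == 1:
            singles.append(hits[comp[0]])
            continue
        comp_edges = [(a, b) for a, b in edges if a in comp and b in comp]
        raw.append((comp, comp_edges))

    clusters = []
    for comp, comp_edges in raw:
        members = [hits[i] for i in comp]
        cons, _ = consensus_sequence(members)
        clusters.append(
            Cluster(
                cluster_id=-1,
                members=members,
                edges=[
                    tuple(sorted((hits[a].key, hits[b].key), key=str))
                    for a, b in comp_edges
                ],
                consensus=cons,
                size=len(members),
                cumulative_frequency=sum(m.cumulative_frequency for m in members),
            )
        )
    clusters.sort(key=lambda c: (-c.size, -c.cumulative_frequency, c.consensus))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = i
    singles.sort(key=lambda h: h.cdr3aa)
    return ClusterSet(clusters=clusters, singletons=singles)


def export_graph(
    clusters: ClusterSet | Sequence[Cluster],
    path: str | Path,
    fmt: str = "edge_list_tsv",
    sample_meta: Mapping[str, SampleMeta] | None = None,
) -> Path:
    """Export clusters for external viewers (e.g. Cytoscape).

    One node per (clonotype, sample) occurrence, carrying mouse, lymph-node
    side, per-sample frequency and cluster id; a clonotype seen in several
    samples is therefore drawn as several nodes, tied together by
    same-clonotype edges. ``edge_list_tsv`` writes the edge list plus a
    ``<path>.nodes.tsv`` attribute table; ``graphml`` writes one GraphML file.
    """
    members = list(clusters.clusters if isinstance(clusters, ClusterSet) else clusters)
    path = Path(path)

    def node_id(key, sample: str) -> str:
        base = key if isinstance(key, str) else "|".join(map(str, key))
        return f"{base}@{sample}"

    nodes: list[dict] = []
    edges: list[tuple[str, str, int]] = []
    for cluster in members:
        occ: dict = {}
        for m in cluster.members:
            samples = sorted(m.per_sample_frequencies) or ["pooled"]
            occ[m.key] = samples
            for s in samples:
                meta = sample_meta.get(s) if sample_meta else None
                nodes.append(
                    {
                        "node": node_id(m.key, s),
                        "cdr3aa": m.cdr3aa,
                        "v": m.v or "",
                        "sample": s,
                        "mouse": meta.mouse_id if meta else "",
                        "ln_side": meta.ln_side if meta else "",
                        "frequency": m.per_sample_frequencies.get(s, m.cumulative_frequency),
                        "cluster_id": cluster.cluster_id,
                    }
                )
            # same-clonotype occurrences form a chain, keeping them connected
            for a, b in zip(samples, samples[1:]):
                edges.append((node_id(m.key, a), node_id(m.key, b), cluster.cluster_id))
        for ka, kb in cluster.edges:
            for sa in occ.get(ka, []):
                for sb in occ.get(kb, []):
                    edges.append((node_id(ka, sa), node_id(kb, sb), cluster.cluster_id))

    nodes.sort(key=lambda n: n["node"])
    edges.sort()
    if fmt == "edge_list_tsv":
        pd.DataFrame(edges, columns=["source", "target", "cluster_id"]).to_csv(
            path, sep="\t", index=False
        )
        pd.DataFrame(nodes).to_csv(
            path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t", index=False
        )
    elif fmt == "graphml":
        g = nx.Graph()
        for n in nodes:
            g.add_node(n["node"], **{k: v for k, v in n.items() if k != "node"})
        for s, t, cid in edges:
            g.add_edge(s, t, cluster_id=cid)
        nx.write_graphml(g, path)
    else:
        raise ValueError("fmt must be 'edge_list_tsv' or 'graphml'")
    return path
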