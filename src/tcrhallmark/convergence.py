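"""Neighbor-enrichment detection of convergent clonotypes (ALICE-style).

A clonotype is convergent when its pooled cloneset contains more
single-substitution CDR3 variants ("neighbors") than expected if every
clonotype were an independent draw from the generative background. For each
scanned clonotype the expected number of distinct neighbors present in a
cloneset of N clonotypes is

    E = sum over neighbor sequences s of  1 - (1 - pgen(s))^N

with the linear shortcut N * sum(pgen) when N * max(pgen) < 1e-3. The
observed count is tested against a Poisson upper tail with mean E (neighbor
presences are rare, nearly independent Bernoulli events), and the family of
p-values over all scanned clonotypes is Benjamini–Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy import stats as sps

from .background import GenerativeModel
from .io import AA_ALPHABET, validate_cdr3aa
from .preprocess import DEFAULT_MIN_CUMULATIVE, PooledCloneset
from .stats import bh_adjust

DEFAULT_ALPHA = 5e-5          # BH-adjusted significance, V/J-linked mode
REPLICATION_ALPHA = 1e-4      # alternative published threshold, unlinked mode
_LINEAR_REGIME = 1e-3


def neighbors(cdr3aa: str, alphabet: str = AA_ALPHABET) -> set[str]:
    """All sequences at Hamming distance exactly 1 (same length, self
    excluded); size (|alphabet| - 1) * L."""
    seq = validate_cdr3aa(cdr3aa)
    out: set[str] = set()
    for i, aa in enumerate(seq):
        prefix, suffix = seq[:i], seq[i + 1:]
        for a in alphabet:
            if a != aa:
                out.add(prefix + a + suffix)
    return out


def _linkage(entry) -> tuple:
    return (entry.representative_v, entry.representative_j)


def _neighbor_counts(pool: PooledCloneset, link_vj: bool) -> dict[Hashable, int]:
    """Observed distinct-neighbor counts for every pooled key, via positional
    mask buckets (two sequences are Hamming-1 iff they share exactly one
    masked pattern and are not identical)."""
    buckets: Counter = Counter()
    identical: Counter = Counter()
    masks: dict[Hashable, list[tuple]] = {}
    for key, e in pool.entries.items():
        seq = e.cdr3aa
        link = _linkage(e) if link_vj else ()
        identical[(seq, link)] += 1
        row = []
        for i in range(len(seq)):
            pat = (i, seq[:i], seq[i + 1:], link)
            row.append(pat)
            buckets[pat] += 1
        masks[key] = row
    counts: dict[Hashable, int] = {}
    for key, e in pool.entries.items():
        seq = e.cdr3aa
        link = _linkage(e) if link_vj else ()
        same = identical[(seq, link)]  # self + identical-CDR3 keys (Hamming 0)
        counts[key] = sum(buckets[pat] for pat in masks[key]) - len(seq) * same
    return counts


def observed_neighbor_count(
    key: Hashable, pool: PooledCloneset, link_vj: bool = False
) -> int:
    """Distinct pooled keys whose CDR3 is a single-substitution variant of
    ``key``'s CDR3 (same V, and same J when available, if ``link_vj``)."""
    if key not in pool.entries:
        raise KeyError(f"key {key!r} absent from pooled cloneset")
    entry = pool.entries[key]
    count = 0
    for other_key, other in pool.entries.items():
        if other_key == key:
            continue
        if link_vj and _linkage(other) != _linkage(entry):
            continue
        a, b = entry.cdr3aa, other.cdr3aa
        if len(a) == len(b) and sum(x != y for x, y in zip(a, b)) == 1:
            count += 1
    return count


def expected_neighbor_count(
    cdr3aa: str,
    model: GenerativeModel,
    n_clonotypes: int,
    v: str | None = None,
    j: str | None = None,
) -> float:
    """Expected number of distinct neighbors present among ``n_clonotypes``
    background draws.

    When the scan links V (and J), an observed neighbor must also carry the
    same segments, so each neighbor's presence probability is multiplied by
    the background probability of that V (and J); pass the scanned key's
    segments via ``v``/``j`` to apply the correction. Segments unknown to the
    model contribute no reduction (conservative).
    """
    if n_clonotypes < 0:
        raise ValueError("n_clonotypes must be non-negative")
    if n_clonotypes == 0:
        return 0.0
    if model.pgen(cdr3aa) == 0.0 and model.length_dist.get(len(cdr3aa), 0.0) == 0.0:
        warnings.warn(
            f"CDR3 length {len(cdr3aa)} carries no mass in the background model"
        )
        return 0.0
    seg_factor = 1.0
    if v is not None:
        seg_factor *= model.v_dist.get(v, 1.0)
    if j is not None and model.j_dist:
        seg_factor *= model.j_dist.get(j, 1.0)
    if n_clonotypes * seg_factor * model.neighbor_pgen_max(cdr3aa) < _LINEAR_REGIME:
        return n_clonotypes * seg_factor * model.neighbor_pgen_sum(cdr3aa)
    return float(
        sum(
            1.0 - (1.0 - seg_factor * model.pgen(s)) ** n_clonotypes
            for s in neighbors(cdr3aa, model.alphabet)
        )
    )


@dataclass
class ConvergenceHit:
    """Per-clonotype scan record; ``is_hit`` marks significance."""

    key: Hashable
    cdr3aa: str
    v: str | None
    j: str | None
    observed: int
    expected: float
    p_value: float
    adjusted_p: float
    is_hit: bool
    cumulative_frequency: float
    per_sample_frequencies: dict[str, float]


def alice_scan(
    pool: PooledCloneset,
    model: GenerativeModel,
    link_vj: bool = True,
    alpha: float = DEFAULT_ALPHA,
    min_cumulative_freq: float = DEFAULT_MIN_CUMULATIVE,
) -> list[ConvergenceHit]:
    """Scan a pooled cloneset for neighbor-enriched clonotypes.

    Returns one record per scanned key, sorted by adjusted p ascending (ties
    by CDR3). A key is a hit when it has at least one observed neighbor and
    its BH-adjusted Poisson tail p-value falls below ``alpha``. The BH family
    is the full set of scanned keys.
    """
    if not pool.entries:
        raise ValueError("alice_scan on empty pooled cloneset")
    keys = [
        k for k, e in pool.entries.items()
        if e.cumulative_frequency > min_cumulative_freq
    ]
    if not keys:
        raise ValueError("min_cumulative_freq leaves no clonotype to scan")
    scan_pool = pool
    if len(keys) != len(pool.entries):
        scan_pool = PooledCloneset(
            group=pool.group,
            key_mode=pool.key_mode,
            entries={k: pool.entries[k] for k in keys},
        )
    observed = _neighbor_counts(scan_pool, link_vj)
    n = len(keys)
    expected = {}
    for k in keys:
        e = scan_pool.entries[k]
        expected[k] = expected_neighbor_count(
            e.cdr3aa, model, n,
            v=e.representative_v if link_vj else None,
            j=e.representative_j if link_vj else None,
        )

    obs = np.array([observed[k] for k in keys])
    exp = np.array([expected[k] for k in keys])
    p = np.ones(n)
    pos = obs >= 1
    # sf(k-1, mu) = P(X >= k); mu == 0 with observed > 0 degenerates to p = 0
    p[pos] = sps.poisson.sf(obs[pos] - 1, exp[pos])
    degenerate = pos & (exp == 0.0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} clonotype(s) with observed neighbors but "
            "zero expectation; background model may be mis-specified"
        )
    adj = np.array(bh_adjust(p.tolist()))

    records = [
        ConvergenceHit(
            key=k,
            cdr3aa=scan_pool.entries[k].cdr3aa,
            v=scan_pool.entries[k].representative_v,
            j=scan_pool.entries[k].representative_j,
            observed=int(obs[i]),
            expected=float(exp[i]),
            p_value=float(p[i]),
            adjusted_p=float(adj[i]),
            is_hit=bool(obs[i] >= 1 and adj[i] < alpha),
            cumulative_frequency=scan_pool.entries[k].cumulative_frequency,
            per_sample_frequencies=dict(scan_pool.entries[k].per_sample_frequencies),
        )
        for i, k in enumerate(keys)
    ]
    records.sort(key=lambda h: (h.adjusted_p, h.cdr3aa))
    return records


def significant_hits(records: Sequence[ConvergenceHit]) -> list[ConvergenceHit]:
    return [h for h in records if h.is_hit]


def hits_to_frame(records: Sequence[ConvergenceHit]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "key": h.key if isinstance(h.key, str) else "|".join(map(str, h.key)),
                "cdr3aa": h.cdr3aa,
                "v": h.v,
                "j": h.j,
                "observed": h.observed,
                "expected": h.expected,
                "p": h.p_value,
                "adjusted_p": h.adjusted_p,
                "is_hit": h.is_hit,
            }
            for h in records
        ]
    )
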