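"""Fuzzy matching of repertoire clonotypes against known antigen-specific TCRs.

A repertoire clonotype matches a database TCR when the gene-level TRBV calls
are identical and the CDR3 amino-acid sequences are alignable within the
allowed edit budget. Two budgets are provided:

``combined`` (default)
    at most one substitution AND at most one indel may co-occur: equal
    lengths with Hamming distance <= 1, or lengths differing by exactly one
    where deleting a single position from the longer sequence leaves Hamming
    distance <= 1.
``strict``
    one substitution XOR one indel: equal lengths with Hamming distance <= 1,
    or a single indel with the remaining positions identical.

Length differences of two or more never match. Indels may sit anywhere,
termini included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import Repertoire, SpecificityRecord, validate_cdr3aa, _strip_allele

MATCH_MODES = ("combined", "strict")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _deletion_hamming_min(longer: str, shorter: str) -> int:
    """Minimum Hamming distance between ``shorter`` and any single-deletion
    variant of ``longer`` (len(longer) == len(shorter) + 1).

    A deletion at position i leaves longer[:i] + longer[i+1:]; the minimum
    over i equals prefix_mismatches(i) + suffix_mismatches(i), computable in
    O(L) with prefix/suffix mismatch arrays.
    """
    n = len(shorter)
    prefix = [0] * (n + 1)  # mismatches of longer[:i] vs shorter[:i]
    for i in range(n):
        prefix[i + 1] = prefix[i] + (longer[i] != shorter[i])
    suffix = [0] * (n + 1)  # mismatches of longer[i+1:] vs shorter[i:]
    for i in range(n - 1, -1, -1):
        suffix[i] = suffix[i + 1] + (longer[i + 1] != shorter[i])
    return min(prefix[i] + suffix[i] for i in range(n + 1))


def cdr3_fuzzy_equal(a: str, b: str, mode: str = "combined") -> bool:
    """Sequence part of the fuzzy rule (no V comparison)."""
    if mode not in MATCH_MODES:
        raise ValueError(f"mode must be one of {MATCH_MODES}")
    a = validate_cdr3aa(a)
    b = validate_cdr3aa(b)
    if abs(len(a) - len(b)) >= 2:
        return False
    if len(a) == len(b):
        return _hamming(a, b) <= 1
    longer, shorter = (a, b) if len(a) > len(b) else (b, a)
    budget = 1 if mode == "combined" else 0
    return _deletion_hamming_min(longer, shorter) <= budget


def fuzzy_match(
    query_cdr3: str,
    db_cdr3: str,
    query_v: str | None,
    db_v: str | None,
    mode: str = "combined",
) -> bool:
    """True when gene-level TRBV calls are equal and the CDR3s are within the
    fuzzy edit budget."""
    qv = _strip_allele(query_v) if query_v else None
    dv = _strip_allele(db_v) if db_v else None
    if qv is None or dv is None or qv != dv:
        return False
    return cdr3_fuzzy_equal(query_cdr3, db_cdr3, mode)


@dataclass
class Annotation:
    """Per-(sample, label) cumulative matched frequencies plus per-clone
    match provenance."""

    matrix: pd.DataFrame   # rows = labels, columns = sample_ids
    matches: pd.DataFrame  # sample_id, cdr3aa, v, frequency, label, db_cdr3aa, db_v

    def label_maxima(self) -> pd.Series:
        if self.matrix.empty:
            return pd.Series(dtype=float)
        return self.matrix.max(axis=1)


def annotate_repertoires(
    repertoires: Sequence[Repertoire],
    db: Sequence[SpecificityRecord],
    mode: str = "combined",
) -> Annotation:
    """Cumulative frequency of database-matching clonotypes per sample and
    specificity label.

    A clone matching several records of one label is counted once for that
    label (it may still count toward other labels).
    """
    if not db:
        raise ValueError("specificity database is empty")
    labels = sorted({r.label for r in db})
    sample_ids = [r.sample_id for r in repertoires]
    matrix = pd.DataFrame(0.0, index=labels, columns=sample_ids)

    # index db by (v, length bucket) to skip impossible comparisons
    by_v: dict[str, list[SpecificityRecord]] = {}
    for rec in db:
        by_v.setdefault(rec.trbv, []).append(rec)

    rows = []
    for rep in repertoires:
        for clone_index, clone in enumerate(rep.clonotypes):
            if not clone.v_segment:
                continue
            candidates = by_v.get(clone.v_segment, ())
            hit_labels: set[str] = set()
            for rec in candidates:
                if abs(len(rec.cdr3aa) - len(clone.cdr3aa)) >= 2:
                    continue
                if cdr3_fuzzy_equal(clone.cdr3aa, rec.cdr3aa, mode):
                    rows.append(
                        {
                            "sample_id": rep.sample_id,
                            "clone_index": clone_index,
                            "cdr3aa": clone.cdr3aa,
                            "v": clone.v_segment,
                            "frequency": clone.frequency,
                            "label": rec.label,
                            "db_cdr3aa": rec.cdr3aa,
                            "db_v": rec.trbv,
                        }
                    )
                    if rec.label not in hit_labels:
                        hit_labels.add(rec.label)
                        matrix.loc[rec.label, rep.sample_id] += clone.frequency
    matches = pd.DataFrame(
        rows,
        columns=["sample_id", "clone_index", "cdr3aa", "v", "frequency", "label",
                 "db_cdr3aa", "db_v"],
    )
    return Annotation(matrix=matrix, matches=matches)


def matched_cumulative_ceiling_check(annotation: Annotation) -> pd.DataFrame:
    """Per-label maxima of matched cumulative frequency across samples — the
    sanity report mirroring the scale of matched fractions in real data."""
    maxima = annotation.label_maxima()
    out = pd.DataFrame({"label": maxima.index, "max_cumulative_frequency": maxima.values})
    if not annotation.matrix.empty:
        out["argmax_sample"] = annotation.matrix.idxmax(axis=1).values
    return out
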