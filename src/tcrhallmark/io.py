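"""Reading and writing clonotype tables, sample sheets and specificity databases.

Clonotype tables are tab-separated text in one of three dialects:

``vdjtools``
    VDJTools-style columns ``count, freq, cdr3nt, cdr3aa, v, d, j``.
``mixcr``
    MiXCR export columns ``cloneCount, cloneFraction, nSeqCDR3, aaSeqCDR3,
    allVHitsWithScore, allDHitsWithScore, allJHitsWithScore`` (``bestVHit`` /
    ``bestJHit`` are accepted as fallbacks).
``minimal``
    Four columns ``count, freq, cdr3aa, v`` — the compact format used for
    synthetic fixtures.

Segment calls are stripped to gene level on read: allele suffixes
(``TRBV17*01`` -> ``TRBV17``) and MiXCR alignment-score decorations
(``TRBV17*00(123.4)`` -> ``TRBV17``) are removed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

GROUP_LABELS = ("adjuvant", "p20", "p30")
LN_SIDES = ("dLN", "ndLN", "NA")
SUBSETS = ("CTL", "Treg", "other")


class FormatError(ValueError):
    """A table does not conform to the declared dialect."""


def _strip_allele(segment: str | None) -> str | None:
    """Reduce a segment call to gene level (drop alleles, scores, multi-hits)."""
    if segment is None:
        return None
    segment = segment.strip()
    if not segment or segment in {".", "-", "NA", "*"}:
        return None
    # MiXCR multi-hit strings: keep the best (first) hit.
    segment = segment.split(",")[0]
    segment = re.sub(r"\(.*?\)", "", segment)  # alignment scores
    segment = segment.split("*")[0]  # allele suffix
    return segment or None


def validate_cdr3aa(cdr3aa: str) -> str:
    seq = cdr3aa.strip().upper()
    if not seq:
        raise ValueError("empty CDR3 amino-acid sequence")
    bad = set(seq) - _AA_SET
    if bad:
        raise ValueError(
            f"non-canonical amino-acid letter(s) {sorted(bad)} in CDR3 {cdr3aa!r}"
        )
    return seq


@dataclass(frozen=True)
class Clonotype:
    """One TCRβ clone: CDR3 plus segment calls and abundance."""

    cdr3aa: str
    read_count: int
    frequency: float
    v_segment: str | None = None
    j_segment: str | None = None
    cdr3nt: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cdr3aa", validate_cdr3aa(self.cdr3aa))
        object.__setattr__(self, "read_count", int(self.read_count))
        object.__setattr__(self, "frequency", float(self.frequency))
        if self.read_count < 0:
            raise ValueError(f"negative read count for {self.cdr3aa}")
        if self.frequency < 0:
            raise ValueError(f"negative frequency for {self.cdr3aa}")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation from the sample sheet."""

    mouse_id: str = "NA"
    group: str = "adjuvant"
    ln_side: str = "NA"
    subset: str = "CTL"

    def __post_init__(self) -> None:
        if self.ln_side not in LN_SIDES:
            raise ValueError(f"ln_side must be one of {LN_SIDES}, got {self.ln_side!r}")
        if self.subset not in SUBSETS:
            raise ValueError(f"subset must be one of {SUBSETS}, got {self.subset!r}")


@dataclass
class Repertoire:
    """One sample's clonotype list plus metadata.

    ``total_reads`` counts on-target TCR reads; it may exceed the sum of
    clonotype read counts but never be below the largest single clone.
    """

    sample_id: str
    clonotypes: list[Clonotype]
    total_reads: int = 0
    cell_count: int | None = None
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        if self.total_reads == 0 and self.clonotypes:
            self.total_reads = sum(c.read_count for c in self.clonotypes)
        if self.clonotypes:
            biggest = max(c.read_count for c in self.clonotypes)
            if self.total_reads < biggest:
                raise ValueError(
                    f"total_reads {self.total_reads} below largest clone ({biggest})"
                )

    def __len__(self) -> int:
        return len(self.clonotypes)

    def frequency_sum(self) -> float:
        return float(sum(c.frequency for c in self.clonotypes))

    def is_normalized(self, tol: float = 1e-6) -> bool:
        return abs(self.frequency_sum() - 1.0) <= tol


@dataclass(frozen=True)
class SpecificityRecord:
    """A known antigen-specific TCRβ: CDR3aa + TRBV + specificity label."""

    cdr3aa: str
    trbv: str
    label: str
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cdr3aa", validate_cdr3aa(self.cdr3aa))
        trbv = _strip_allele(self.trbv)
        if not trbv:
            raise ValueError("specificity record with empty TRBV")
        object.__setattr__(self, "trbv", trbv)
        if not self.label:
            raise ValueError("specificity record with empty label")


# ---------------------------------------------------------------------------
# Dialects
# ---------------------------------------------------------------------------

#: column mapping per dialect: canonical name -> acceptable column names, in order
_DIALECTS: dict[str, dict[str, tuple[str, ...]]] = {
    "vdjtools": {
        "count": ("count", "#count"),
        "freq": ("freq", "frequency"),
        "cdr3nt": ("cdr3nt",),
        "cdr3aa": ("cdr3aa",),
        "v": ("v",),
        "d": ("d",),
        "j": ("j",),
    },
    "mixcr": {
        "count": ("cloneCount",),
        "freq": ("cloneFraction",),
        "cdr3nt": ("nSeqCDR3",),
        "cdr3aa": ("aaSeqCDR3",),
        "v": ("allVHitsWithScore", "bestVHit"),
        "d": ("allDHitsWithScore", "bestDHit"),
        "j": ("allJHitsWithScore", "bestJHit"),
    },
    "minimal": {
        "count": ("count",),
        "freq": ("freq",),
        "cdr3aa": ("cdr3aa",),
        "v": ("v",),
    },
}

_REQUIRED = {
    "vdjtools": ("count", "cdr3aa", "v"),
    "mixcr": ("count", "cdr3aa", "v"),
    "minimal": ("count", "cdr3aa", "v"),
}


def _resolve_columns(columns: Sequence[str], dialect: str) -> dict[str, str]:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    lower = {c.lower().lstrip("#"): c for c in columns}
    resolved: dict[str, str] = {}
    for canon, options in _DIALECTS[dialect].items():
        for opt in options:
            if opt.lower().lstrip("#") in lower:
                resolved[canon] = lower[opt.lower().lstrip("#")]
                break
    missing = [c for c in _REQUIRED[dialect] if c not in resolved]
    if missing:
        raise FormatError(
            f"dialect {dialect!r}: missing required column(s) {missing}; "
            f"found columns {list(columns)}"
        )
    return resolved


def read_clonotype_table(
    path: str | Path,
    dialect: str = "vdjtools",
    sample_id: str | None = None,
    total_reads: int | None = None,
    cell_count: int | None = None,
    meta: SampleMeta | None = None,
) -> Repertoire:
    """Read a tab-separated clonotype table into a :class:`Repertoire`.

    Frequencies are taken from the file when the frequency column is present,
    otherwise computed as ``read_count / sum(read_counts)``. Row order is
    preserved; duplicate CDR3aa rows are kept as distinct clonotypes.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns, dialect)

    counts: list[int] = []
    for i, val in enumerate(df[cols["count"]], start=2):  # header = line 1
        try:
            counts.append(int(float(val)))
        except ValueError as exc:
            raise FormatError(f"{path.name} line {i}: non-numeric count {val!r}") from exc

    if "freq" in cols:
        freqs: list[float] = []
        for i, val in enumerate(df[cols["freq"]], start=2):
            try:
                freqs.append(float(val))
            except ValueError as exc:
                raise FormatError(
                    f"{path.name} line {i}: non-numeric frequency {val!r}"
                ) from exc
    else:
        total = sum(counts)
        freqs = [c / total if total > 0 else 0.0 for c in counts]

    aa = df[cols["cdr3aa"]].tolist()
    vs = df[cols["v"]].tolist() if "v" in cols else [None] * len(df)
    js = df[cols["j"]].tolist() if "j" in cols else [None] * len(df)
    nts = df[cols["cdr3nt"]].tolist() if "cdr3nt" in cols else [None] * len(df)
    clonotypes = [
        Clonotype(
            cdr3aa=aa[idx],
            read_count=counts[idx],
            frequency=freqs[idx],
            v_segment=_strip_allele(vs[idx]) if vs[idx] is not None else None,
            j_segment=_strip_allele(js[idx]) if js[idx] is not None else None,
            cdr3nt=nts[idx] or None,
        )
        for idx in range(len(df))
    ]

    return Repertoire(
        sample_id=sample_id or path.stem,
        clonotypes=clonotypes,
        total_reads=total_reads or 0,
        cell_count=cell_count,
        meta=meta or SampleMeta(),
    )


def write_clonotype_table(
    repertoire: Repertoire, path: str | Path, dialect: str = "vdjtools"
) -> Path:
    """Write a repertoire as a tab-separated table; inverse of the reader."""
    path = Path(path)
    if dialect == "vdjtools":
        cols = ["count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j"]
        rows = [
            [c.read_count, repr(c.frequency), c.cdr3nt or ".", c.cdr3aa,
             c.v_segment or ".", ".", c.j_segment or "."]
            for c in repertoire.clonotypes
        ]
    elif dialect == "mixcr":
        cols = ["cloneCount", "cloneFraction", "nSeqCDR3", "aaSeqCDR3",
                "allVHitsWithScore", "allDHitsWithScore", "allJHitsWithScore"]
        rows = [
            [c.read_count, repr(c.frequency), c.cdr3nt or "", c.cdr3aa,
             c.v_segment or "", "", c.j_segment or ""]
            for c in repertoire.clonotypes
        ]
    elif dialect == "minimal":
        cols = ["count", "freq", "cdr3aa", "v"]
        rows = [
            [c.read_count, repr(c.frequency), c.cdr3aa, c.v_segment or "."]
            for c in repertoire.clonotypes
        ]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet (sample_id, mouse_id, group, ln_side, subset,
    cell_count, path) as a DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "mouse_id", "group", "ln_side", "subset"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing column(s) {sorted(missing)}")
    return df


def load_study(sheet_path: str | Path, dialect: str = "vdjtools") -> list[Repertoire]:
    """Load every repertoire listed in a sample sheet (paths relative to it)."""
    sheet_path = Path(sheet_path)
    sheet = read_sample_sheet(sheet_path)
    reps = []
    for _, row in sheet.iterrows():
        table = Path(row["path"])
        if not table.is_absolute():
            table = sheet_path.parent / table
        cell_count = int(float(row["cell_count"])) if row.get("cell_count") else None
        reps.append(
            read_clonotype_table(
                table,
                dialect=dialect,
                sample_id=row["sample_id"],
                cell_count=cell_count,
                meta=SampleMeta(
                    mouse_id=row["mouse_id"],
                    group=row["group"],
                    ln_side=row["ln_side"],
                    subset=row["subset"],
                ),
            )
        )
    return reps


def read_specificity_db(path: str | Path) -> list[SpecificityRecord]:
    """Read a specificity database TSV (cdr3aa, trbv, label[, source]).

    Lowercase CDR3s are uppercased with a warning; rows identical on
    (cdr3aa, trbv, label) are deduplicated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"cdr3aa", "trbv", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"specificity DB missing column(s) {sorted(missing)}")
    if df.empty:
        warnings.warn(f"specificity database {path} is empty")
        return []
    records: list[SpecificityRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for _, row in df.iterrows():
        if row["cdr3aa"] != row["cdr3aa"].upper():
            warnings.warn(f"lowercase CDR3 {row['cdr3aa']!r} uppercased")
        rec = SpecificityRecord(
            cdr3aa=row["cdr3aa"],
            trbv=row["trbv"],
            label=row["label"],
            source=row.get("source", ""),
        )
        key = (rec.cdr3aa, rec.trbv, rec.label)
        if key in seen:
            continue
        seen.add(key)
        records.append(rec)
    return records


def write_specificity_db(records: Iterable[SpecificityRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [[r.cdr3aa, r.trbv, r.label, r.source] for r in records],
        columns=["cdr3aa", "trbv", "label", "source"],
    ).to_csv(path, sep="\t", index=False)
    return path
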