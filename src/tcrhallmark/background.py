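"""Factorized generative background model for CDR3β amino-acid sequences.

The null model for neighbor-enrichment scanning factorizes the generation
probability of a CDR3 into a length term and independent per-position
emission terms:

    Pgen(s) = P(L = len(s)) * prod_i  P(s_i | bin(i, L))

Positions are binned relative to the conserved termini: the first three
positions (the C-A-S anchor region) and the last two (the ...F/W-motif
region) each own a bin; all interior positions share one pooled bin. The
bins are anchored to both sequence ends, so one emission table serves every
length. This deliberately ignores nucleotide-level V(D)J recombination
mechanics (insertion profiles, gene usage correlations); all downstream uses
need only a self-consistent pgen/sampler pair — expected neighbor counts and
null sampling. A pgen table computed by an external recombination model can
be plugged in through :class:`TabularPgen`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AA_ALPHABET, Repertoire, validate_cdr3aa

#: emission bins, in left-to-right order of precedence
BINS = ("p0", "p1", "p2", "mid", "m2", "m1")


def position_bin(i: int, length: int) -> str:
    """Bin of position ``i`` (0-based) in a sequence of ``length``.

    The right-end anchors take precedence for very short sequences (the
    terminal F/W position is the strongest conservation signal).
    """
    if i == length - 1:
        return "m1"
    if i == length - 2:
        return "m2"
    if i < 3:
        return f"p{i}"
    return "mid"


def _normalize(d: Mapping, label: str) -> dict:
    total = float(sum(d.values()))
    if total <= 0:
        raise ValueError(f"{label}: distribution has no mass")
    return {k: v / total for k, v in d.items()}


@dataclass
class GenerativeModel:
    """Length × position-binned emission model with V-segment usage."""

    length_dist: dict[int, float]
    emissions: dict[str, dict[str, float]]  # bin -> letter -> probability
    v_dist: dict[str, float]
    j_dist: dict[str, float] | None = None
    alphabet: str = AA_ALPHABET

    def __post_init__(self) -> None:
        self.length_dist = _normalize(self.length_dist, "length_dist")
        self.v_dist = _normalize(self.v_dist, "v_dist")
        if self.j_dist:
            self.j_dist = _normalize(self.j_dist, "j_dist")
        for b in BINS:
            if b not in self.emissions:
                raise ValueError(f"emissions missing bin {b!r}")
            em = _normalize(self.emissions[b], f"emissions[{b}]")
            missing = set(self.alphabet) - set(em)
            if missing:
                raise ValueError(f"emissions[{b}] missing letters {sorted(missing)}")
            if min(em.values()) <= 0:
                raise ValueError(f"emissions[{b}] contains a zero-probability letter")
            self.emissions[b] = em

    # -- scoring -----------------------------------------------------------

    def pgen(self, cdr3aa: str) -> float:
        """Generation probability of an amino-acid CDR3; 0 for lengths the
        model has never seen."""
        seq = validate_cdr3aa(cdr3aa)
        bad = set(seq) - set(self.alphabet)
        if bad:
            raise ValueError(f"letter(s) {sorted(bad)} outside model alphabet")
        L = len(seq)
        p = self.length_dist.get(L, 0.0)
        if p == 0.0:
            return 0.0
        for i, aa in enumerate(seq):
            p *= self.emissions[position_bin(i, L)][aa]
        return p

    def neighbor_pgen_sum(self, cdr3aa: str) -> float:
        """Sum of pgen over all same-length single-substitution variants.

        Equals pgen(s) * sum_i (1 - e_i) / e_i where e_i is the emission
        probability of the residue actually present at position i.
        """
        base = self.pgen(cdr3aa)
        if base == 0.0:
            return 0.0
        L = len(cdr3aa)
        acc = 0.0
        for i, aa in enumerate(cdr3aa):
            e = self.emissions[position_bin(i, L)][aa]
            acc += (1.0 - e) / e
        return base * acc

    def neighbor_pgen_max(self, cdr3aa: str) -> float:
        """Largest pgen among the single-substitution variants."""
        base = self.pgen(cdr3aa)
        if base == 0.0:
            return 0.0
        L = len(cdr3aa)
        best = 0.0
        for i, aa in enumerate(cdr3aa):
            em = self.emissions[position_bin(i, L)]
            e = em[aa]
            alt = max(p for a, p in em.items() if a != aa)
            best = max(best, alt / e)
        return base * best

    def entropy(self) -> float:
        """Model entropy in nats: H(length) + E_L[ per-position emission H ]."""
        lengths = np.array(list(self.length_dist.keys()))
        pl = np.array(list(self.length_dist.values()))
        h_len = float(-np.sum(np.where(pl > 0, pl * np.log(np.maximum(pl, 1e-300)), 0.0)))
        h_bin = {
            b: float(-sum(p * np.log(p) for p in em.values()))
            for b, em in self.emissions.items()
        }
        h_seq = sum(
            w * sum(h_bin[position_bin(i, int(L))] for i in range(int(L)))
            for L, w in zip(lengths, pl)
        )
        return h_len + h_seq

    # -- sampling ----------------------------------------------------------

    def sample(self, n: int, seed: int | np.random.Generator) -> list[tuple[str, str]]:
        """Draw ``n`` i.i.d. (cdr3aa, v_segment) pairs; same seed, same draws."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        lengths = np.array(sorted(self.length_dist))
        pl = np.array([self.length_dist[L] for L in lengths])
        vs = sorted(self.v_dist)
        pv = np.array([self.v_dist[v] for v in vs])
        letters = {b: (list(em.keys()), np.array(list(em.values())))
                   for b, em in self.emissions.items()}
        drawn_L = rng.choice(lengths, size=n, p=pl)
        drawn_v = rng.choice(vs, size=n, p=pv)
        seqs: list[str] = [""] * n
        # vectorized per length class: one categorical draw per position column
        for L in lengths:
            idx = np.flatnonzero(drawn_L == L)
            if idx.size == 0:
                continue
            cols = []
            for i in range(int(L)):
                abc, probs = letters[position_bin(i, int(L))]
                draws = rng.choice(len(abc), size=idx.size, p=probs)
                cols.append([abc[d] for d in draws])
            for row, j in enumerate(idx):
                seqs[j] = "".join(col[row] for col in cols)
        return [(seqs[i], drawn_v[i]) for i in range(n)]

    def sample_j(self, n: int, seed: int | np.random.Generator) -> list[str]:
        """Draw J segments when the model carries a J distribution."""
        if not self.j_dist:
            return [None] * n  # type: ignore[list-item]
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        js = sorted(self.j_dist)
        pj = np.array([self.j_dist[j] for j in js])
        return [js[i] for i in rng.choice(len(js), size=n, p=pj)]

    # -- serialization -----------------------------------------------------

    def to_tsv_dir(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            sorted(self.length_dist.items()), columns=["length", "probability"]
        ).to_csv(directory / "length_dist.tsv", sep="\t", index=False)
        rows = [
            (b, aa, p)
            for b in BINS
            for aa, p in sorted(self.emissions[b].items())
        ]
        pd.DataFrame(rows, columns=["bin", "letter", "probability"]).to_csv(
            directory / "emissions.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            sorted(self.v_dist.items()), columns=["segment", "probability"]
        ).to_csv(directory / "v_dist.tsv", sep="\t", index=False)
        if self.j_dist:
            pd.DataFrame(
                sorted(self.j_dist.items()), columns=["segment", "probability"]
            ).to_csv(directory / "j_dist.tsv", sep="\t", index=False)
        return directory

    @classmethod
    def from_tsv_dir(cls, directory: str | Path) -> "GenerativeModel":
        directory = Path(directory)
        ld = pd.read_csv(directory / "length_dist.tsv", sep="\t")
        em = pd.read_csv(directory / "emissions.tsv", sep="\t")
        vd = pd.read_csv(directory / "v_dist.tsv", sep="\t")
        emissions: dict[str, dict[str, float]] = {}
        for b, sub in em.groupby("bin"):
            emissions[b] = dict(zip(sub["letter"], sub["probability"]))
        j_dist = None
        jpath = directory / "j_dist.tsv"
        if jpath.exists():
            jd = pd.read_csv(jpath, sep="\t")
            j_dist = dict(zip(jd["segment"], jd["probability"]))
        alphabet = "".join(sorted(emissions["mid"]))
        return cls(
            length_dist=dict(zip(ld["length"].astype(int), ld["probability"])),
            emissions=emissions,
            v_dist=dict(zip(vd["segment"], vd["probability"])),
            j_dist=j_dist,
            alphabet=alphabet,
        )


def fit_background(
    repertoires: Sequence[Repertoire] | Repertoire,
    pseudocount: float = 1.0,
    alphabet: str = AA_ALPHABET,
) -> GenerativeModel:
    """Fit the factorized model from one or more repertoires by counting.

    Lengths and V usage are empirical (clonotype-count weighted); emissions
    are position-binned counts with an additive pseudocount per (bin, letter),
    which keeps every variant's pgen strictly positive.
    """
    if isinstance(repertoires, Repertoire):
        repertoires = [repertoires]
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    clones = [c for r in repertoires for c in r.clonotypes]
    if not clones:
        raise ValueError("fit_background on empty input")

    length_counts: dict[int, float] = {}
    v_counts: dict[str, float] = {}
    j_counts: dict[str, float] = {}
    bin_counts: dict[str, dict[str, float]] = {
        b: {a: pseudocount for a in alphabet} for b in BINS
    }
    for c in clones:
        L = len(c.cdr3aa)
        length_counts[L] = length_counts.get(L, 0.0) + 1.0
        if c.v_segment:
            v_counts[c.v_segment] = v_counts.get(c.v_segment, 0.0) + 1.0
        if c.j_segment:
            j_counts[c.j_segment] = j_counts.get(c.j_segment, 0.0) + 1.0
        for i, aa in enumerate(c.cdr3aa):
            bin_counts[position_bin(i, L)][aa] += 1.0
    if not v_counts:
        v_counts = {"TRBV?": 1.0}
    return GenerativeModel(
        length_dist=length_counts,
        emissions=bin_counts,
        v_dist=v_counts,
        j_dist=j_counts or None,
        alphabet=alphabet,
    )


class TabularPgen:
    """Pgen lookup backed by an externally computed table (cdr3aa -> pgen).

    Sequences absent from the table score 0; sampling is unsupported.
    """

    def __init__(self, table: Mapping[str, float]):
        self.table = {validate_cdr3aa(k): float(v) for k, v in table.items()}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TabularPgen":
        df = pd.read_csv(path, sep="\t")
        missing = {"cdr3aa", "pgen"} - set(df.columns)
        if missing:
            raise ValueError(f"pgen table missing column(s) {sorted(missing)}")
        return cls(dict(zip(df["cdr3aa"], df["pgen"])))

    def pgen(self, cdr3aa: str) -> float:
        return self.table.get(validate_cdr3aa(cdr3aa), 0.0)


# ---------------------------------------------------------------------------
# Default mouse-like background
# ---------------------------------------------------------------------------

def _spread(named: dict[str, float], alphabet: str = AA_ALPHABET) -> dict[str, float]:
    """Distribute the probability not claimed by ``named`` uniformly over the
    remaining letters."""
    rest = [a for a in alphabet if a not in named]
    leftover = 1.0 - sum(named.values())
    out = dict(named)
    out.update({a: leftover / len(rest) for a in rest})
    return out


#: interior-position tilt: mild over-representation of the residues common in
#: CDR3 loops (G/S-rich junctions), otherwise near-uniform
_MID_WEIGHTS = {
    "G": 1.6, "S": 1.5, "L": 1.4, "A": 1.3, "R": 1.3, "E": 1.2, "T": 1.2,
    "Q": 1.1, "D": 1.1, "N": 1.05, "P": 1.0, "V": 1.0, "Y": 0.95, "F": 0.9,
    "K": 0.9, "I": 0.85, "H": 0.8, "W": 0.7, "M": 0.7, "C": 0.6,
}

#: mouse TRBV usage, order-of-magnitude realistic (TRBV17 rare, ~2%)
_TRBV_WEIGHTS = {
    "TRBV1": 4, "TRBV2": 5, "TRBV3": 3, "TRBV4": 5, "TRBV5": 8,
    "TRBV12-1": 5, "TRBV12-2": 5, "TRBV13-1": 7, "TRBV13-2": 9,
    "TRBV13-3": 7, "TRBV14": 4, "TRBV15": 3, "TRBV16": 5, "TRBV17": 2,
    "TRBV19": 9, "TRBV20": 3, "TRBV23": 2, "TRBV24": 3, "TRBV26": 4,
    "TRBV29": 5, "TRBV31": 2,
}

_TRBJ_WEIGHTS = {
    "TRBJ1-1": 8, "TRBJ1-2": 6, "TRBJ1-4": 5, "TRBJ1-5": 7, "TRBJ2-1": 10,
    "TRBJ2-2": 6, "TRBJ2-3": 7, "TRBJ2-4": 4, "TRBJ2-5": 9, "TRBJ2-7": 12,
}


def default_model() -> GenerativeModel:
    """Deterministic mouse-like CDR3β background.

    Lengths 12–17 amino acids peaking at 14 (C-to-F/W inclusive), conserved
    C/A/S left anchor and F/W-dominated right anchor, near-uniform interior.
    """
    return GenerativeModel(
        length_dist={12: 0.10, 13: 0.22, 14: 0.27, 15: 0.21, 16: 0.13, 17: 0.07},
        emissions={
            "p0": _spread({"C": 0.98}),
            "p1": _spread({"A": 0.55, "S": 0.15, "G": 0.06, "T": 0.06}),
            "p2": _spread({"S": 0.50, "A": 0.12, "G": 0.08, "R": 0.06}),
            "mid": _normalize(_MID_WEIGHTS, "mid"),
            "m2": _spread({"Q": 0.25, "T": 0.15, "L": 0.12, "Y": 0.10, "E": 0.08, "V": 0.06}),
            "m1": _spread({"F": 0.72, "W": 0.08, "Y": 0.08}),
        },
        v_dist={k: float(v) for k, v in _TRBV_WEIGHTS.items()},
        j_dist={k: float(v) for k, v in _TRBJ_WEIGHTS.items()},
    )
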