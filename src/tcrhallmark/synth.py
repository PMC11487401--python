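"""Seeded generator of complete synthetic vaccination studies.

Each study comprises one or more vaccine groups, each with several mice and
a draining/non-draining lymph-node CTL repertoire pair per mouse. Into a
heavy-tailed (log-normal) background drawn from the generative model the
generator plants:

* **convergent clusters** — a seed CDR3 plus distinct single-substitution
  variants sharing one V/J, every member enriched in the draining node by a
  factor rho (intended dLN frequency = rho x intended ndLN frequency);
* **bystanders** — expanded single clonotypes without sequence neighbors,
  with their own (typically milder) dLN enrichment;
* **public database clones** — clonotypes planted at equal frequency on
  both sides that exactly match an emitted specificity database.

Planted clonotypes keep their intended frequencies in every sample of their
group; the background fills the remaining mass. Reads are multinomial at the
configured depth, so realized frequencies carry binomial sampling noise
around the intended values. The same seed reproduces the study bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from .background import GenerativeModel, default_model
from .clustering import ClusterSet
from .io import Clonotype, Repertoire, SampleMeta, SpecificityRecord
from .preprocess import PooledCloneset, PoolEntry

SPECIFICITY_LABELS = ("TRP-2", "gp100", "GVHD", "Influenza", "VSV", "MCMV", "MLV")


@dataclass
class StudyConfig:
    """Study-level simulation parameters.

    Defaults mirror the sequencing scale of sorted lymph-node CTL samples:
    1.4e4 clonotypes and 1e6 on-target reads per sample from 7.5e4 sorted
    cells, with a log-normal clone-size distribution (sigma 1.5).
    """

    groups: tuple[str, ...] = ("p20", "p30")
    mice_per_group: int = 2
    clonotypes_per_sample: int = 14_000
    reads_per_sample: int = 1_000_000
    cell_count: int = 75_000
    lognormal_sigma: float = 1.5
    lognormal_mu: float = 0.0
    n_planted_clusters: int = 10
    cluster_size: int = 8            # seed + (cluster_size - 1) variants
    cluster_frequency_mass: float = 0.024  # summed dLN-side intended mass
    seed_dominance: float = 0.4      # fraction of a cluster's mass on its seed
    dln_enrichment: float = 3.0      # rho
    n_bystanders: int = 20
    bystander_frequency_mass: float = 0.02
    bystander_enrichment: float = 2.0
    n_public_clones: int = 10
    public_frequency_mass: float = 0.002
    member_jitter_sigma: float = 0.3  # log-normal jitter on planted frequencies
    overdispersion: float = 0.0       # Dirichlet-multinomial concentration^-1; 0 = multinomial
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_size < 2:
            raise ValueError("cluster_size must be >= 2 (seed + variants)")
        for name in (
            "mice_per_group", "clonotypes_per_sample", "reads_per_sample",
            "n_planted_clusters", "n_bystanders", "n_public_clones",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dln_enrichment <= 0:
            raise ValueError("dln_enrichment must be positive")
        planted = (
            self.cluster_frequency_mass
            + self.bystander_frequency_mass
            + self.public_frequency_mass
        )
        if planted >= 1.0:
            raise ValueError("planted frequency masses must sum below 1")


@dataclass
class PlantedClone:
    group: str
    cdr3aa: str
    v: str
    j: str | None
    dln_frequency: float
    ndln_frequency: float
    label: str | None = None


@dataclass
class PlantedCluster:
    group: str
    cluster_index: int
    seed_cdr3: str
    v: str
    j: str | None
    members: list[PlantedClone]

    def member_cdr3s(self) -> set[str]:
        return {m.cdr3aa for m in self.members}


@dataclass
class GroundTruth:
    clusters: list[PlantedCluster] = field(default_factory=list)
    bystanders: list[PlantedClone] = field(default_factory=list)
    public_clones: list[PlantedClone] = field(default_factory=list)
    sample_depths: dict[str, int] = field(default_factory=dict)

    def clusters_for(self, group: str) -> list[PlantedCluster]:
        return [c for c in self.clusters if c.group == group]


@dataclass
class SimulatedStudy:
    config: StudyConfig
    samples: list[Repertoire]
    truth: GroundTruth
    specificity_db: list[SpecificityRecord]
    model: GenerativeModel

    def group_samples(self, group: str) -> list[Repertoire]:
        return [s for s in self.samples if s.meta.group == group]


def _jitter(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Mean-one log-normal jitter vector."""
    if sigma <= 0 or n == 0:
        return np.ones(n)
    j = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return j / j.mean()


def _sample_distinct(
    model: GenerativeModel, n: int, rng: np.random.Generator, taken: set[str]
) -> list[tuple[str, str]]:
    """Draw n (cdr3aa, v) pairs with CDR3s distinct from each other and from
    ``taken``; raises if rejection exceeds 100n draws."""
    out: list[tuple[str, str]] = []
    attempts = 0
    while len(out) < n:
        if attempts >= 100 * max(n, 1):
            raise RuntimeError(
                "duplicate rejection budget exceeded; background model too concentrated"
            )
        batch = model.sample(min(n, n - len(out) + 16), rng)
        for seq, v in batch:
            attempts += 1
            if seq in taken:
                continue
            taken.add(seq)
            out.append((seq, v))
            if len(out) == n:
                break
    return out


def _plant_variants(
    seed_cdr3: str, k: int, rng: np.random.Generator, alphabet: str
) -> list[str]:
    """k distinct single-substitution variants, uniform without replacement
    over the (|alphabet|-1) * L substitution space."""
    L = len(seed_cdr3)
    space = (len(alphabet) - 1) * L
    if k > space:
        raise ValueError(
            f"cannot plant {k} distinct variants of a length-{L} CDR3 "
            f"(space size {space})"
        )
    picks = rng.choice(space, size=k, replace=False)
    variants = []
    for p in picks:
        pos, slot = divmod(int(p), len(alphabet) - 1)
        others = [a for a in alphabet if a != seed_cdr3[pos]]
        variants.append(seed_cdr3[:pos] + others[slot] + seed_cdr3[pos + 1:])
    return variants


def _draw_counts(
    rng: np.random.Generator, freqs: np.ndarray, depth: int, overdispersion: float
) -> np.ndarray:
    if overdispersion > 0:
        freqs = rng.dirichlet(freqs / overdispersion)
    return rng.multinomial(depth, freqs)


def simulate_study(
    config: StudyConfig | None = None,
    model: GenerativeModel | None = None,
) -> SimulatedStudy:
    """Generate a complete study: repertoires, ground truth, specificity DB."""
    config = config or StudyConfig()
    model = model or default_model()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    db: list[SpecificityRecord] = []
    samples: list[Repertoire] = []

    rho = config.dln_enrichment
    for group in config.groups:
        taken: set[str] = set()

        # -- planted convergent clusters ----------------------------------
        planted_clusters: list[PlantedCluster] = []
        n_members = config.n_planted_clusters * config.cluster_size
        if config.n_planted_clusters > 0:
            seeds = _sample_distinct(model, config.n_planted_clusters, rng, taken)
            jit = _jitter(rng, n_members, config.member_jitter_sigma)
            # each cluster mirrors a real convergent response: one dominant
            # (expanded) clone plus low-frequency single-substitution variants
            per_cluster = config.cluster_frequency_mass / config.n_planted_clusters
            seed_freq = per_cluster * config.seed_dominance
            variant_freq = per_cluster * (1.0 - config.seed_dominance) / max(
                config.cluster_size - 1, 1
            )
            js = model.sample_j(config.n_planted_clusters, rng)
            mi = 0
            for ci, ((seed_cdr3, v), j) in enumerate(zip(seeds, js)):
                variants = _plant_variants(
                    seed_cdr3, config.cluster_size - 1, rng, model.alphabet
                )
                taken.update(variants)
                members = []
                for cdr3 in [seed_cdr3, *variants]:
                    base = seed_freq if cdr3 == seed_cdr3 else variant_freq
                    f_d = base * jit[mi]
                    members.append(
                        PlantedClone(
                            group=group, cdr3aa=cdr3, v=v, j=j,
                            dln_frequency=f_d, ndln_frequency=f_d / rho,
                        )
                    )
                    mi += 1
                planted_clusters.append(
                    PlantedCluster(
                        group=group, cluster_index=ci, seed_cdr3=seed_cdr3,
                        v=v, j=j, members=members,
                    )
                )
        truth.clusters.extend(planted_clusters)

        # -- bystanders (expanded, non-convergent) ------------------------
        bystanders: list[PlantedClone] = []
        if config.n_bystanders > 0:
            pairs = _sample_distinct(model, config.n_bystanders, rng, taken)
            js = model.sample_j(config.n_bystanders, rng)
            jit = _jitter(rng, config.n_bystanders, config.member_jitter_sigma)
            per_dln = config.bystander_frequency_mass / config.n_bystanders
            for (cdr3, v), j, w in zip(pairs, js, jit):
                f_d = per_dln * w
                bystanders.append(
                    PlantedClone(
                        group=group, cdr3aa=cdr3, v=v, j=j,
                        dln_frequency=f_d,
                        ndln_frequency=f_d / config.bystander_enrichment,
                    )
                )
        truth.bystanders.extend(bystanders)

        # -- public, database-matching clones (no LN asymmetry) -----------
        publics: list[PlantedClone] = []
        if config.n_public_clones > 0:
            pairs = _sample_distinct(model, config.n_public_clones, rng, taken)
            js = model.sample_j(config.n_public_clones, rng)
            per_f = config.public_frequency_mass / config.n_public_clones
            for pi, ((cdr3, v), j) in enumerate(zip(pairs, js)):
                label = SPECIFICITY_LABELS[pi % len(SPECIFICITY_LABELS)]
                publics.append(
                    PlantedClone(
                        group=group, cdr3aa=cdr3, v=v, j=j,
                        dln_frequency=per_f, ndln_frequency=per_f, label=label,
                    )
                )
                db.append(
                    SpecificityRecord(
                        cdr3aa=cdr3, trbv=v, label=label, source="synthetic"
                    )
                )
        truth.public_clones.extend(publics)

        planted = [m for c in planted_clusters for m in c.members] + bystanders + publics

        # -- per-sample assembly ------------------------------------------
        # the background pool (sequences and log-normal clone weights) is
        # drawn once per mouse and shared by that mouse's dLN and ndLN: both
        # nodes sample the same animal's T-cell compartment, which is what
        # makes the within-mouse dLN-vs-ndLN comparison paired
        for mouse in range(1, config.mice_per_group + 1):
            mouse_id = f"{group}_m{mouse}"
            bg_taken = set(m.cdr3aa for m in planted)
            bg = _sample_distinct(model, config.clonotypes_per_sample, rng, bg_taken)
            bg_js = model.sample_j(len(bg), rng)
            weights = rng.lognormal(
                mean=config.lognormal_mu,
                sigma=config.lognormal_sigma,
                size=len(bg),
            )
            for side in ("dLN", "ndLN"):
                sample_id = f"{mouse_id}_{side}"
                planted_freqs = np.array(
                    [
                        m.dln_frequency if side == "dLN" else m.ndln_frequency
                        for m in planted
                    ]
                )
                bg_mass = 1.0 - planted_freqs.sum()
                bg_freqs = bg_mass * weights / weights.sum()

                freqs = np.concatenate([planted_freqs, bg_freqs])
                counts = _draw_counts(
                    rng, freqs, config.reads_per_sample, config.overdispersion
                )
                seqs = [(m.cdr3aa, m.v, m.j) for m in planted] + [
                    (s, v, j) for (s, v), j in zip(bg, bg_js)
                ]
                clonotypes = [
                    Clonotype(
                        cdr3aa=s, read_count=int(c),
                        frequency=c / config.reads_per_sample,
                        v_segment=v, j_segment=j,
                    )
                    for (s, v, j), c in zip(seqs, counts)
                    if c > 0
                ]
                samples.append(
                    Repertoire(
                        sample_id=sample_id,
                        clonotypes=clonotypes,
                        total_reads=config.reads_per_sample,
                        cell_count=config.cell_count,
                        meta=SampleMeta(
                            mouse_id=mouse_id, group=group, ln_side=side, subset="CTL"
                        ),
                    )
                )
                truth.sample_depths[sample_id] = config.reads_per_sample

    return SimulatedStudy(
        config=config, samples=samples, truth=truth,
        specificity_db=db, model=model,
    )


def simulate_null_cloneset(
    model: GenerativeModel, n: int, seed: int | np.random.Generator
) -> PooledCloneset:
    """n distinct background sequences at uniform frequency — the type-I
    error harness for the convergence scan."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = _sample_distinct(model, n, rng, set())
    js = model.sample_j(n, rng)
    entries = {}
    for (seq, v), j in zip(pairs, js):
        entries[seq] = PoolEntry(
            cdr3aa=seq,
            cumulative_frequency=1.0 / n,
            per_sample_frequencies={"null": 1.0 / n},
            representative_v=v,
            representative_j=j,
        )
    return PooledCloneset(group="null", key_mode="cdr3aa", entries=entries)


@dataclass
class RecoveryReport:
    n_planted: int
    n_recovered: int
    n_spurious: int
    recovered_indices: list[int]

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else float("nan")


def evaluate_recovery(
    truth: GroundTruth, clusters: ClusterSet, group: str
) -> RecoveryReport:
    """Compare reported clusters against planted ground truth.

    A planted cluster is recovered when some reported cluster contains at
    least half of its members; a reported cluster containing no planted
    member of any cluster is spurious.
    """
    planted = truth.clusters_for(group)
    planted_sets = [c.member_cdr3s() for c in planted]
    all_planted = set().union(*planted_sets) if planted_sets else set()
    recovered: set[int] = set()
    spurious = 0
    for cluster in clusters.clusters:
        members = cluster.member_cdr3s()
        if not members & all_planted:
            spurious += 1
            continue
        for i, pset in enumerate(planted_sets):
            if len(members & pset) * 2 >= len(pset):
                recovered.add(i)
    return RecoveryReport(
        n_planted=len(planted),
        n_recovered=len(recovered),
        n_spurious=spurious,
        recovered_indices=sorted(recovered),
    )
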