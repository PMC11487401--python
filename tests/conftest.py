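import numpy as np
import pytest

from tcrhallmark import GenerativeModel, Repertoire, SampleMeta, StudyConfig, simulate_study
from tcrhallmark.background import BINS
from tcrhallmark.io import Clonotype


def make_repertoire(
    freqs,
    cdr3s=None,
    vs=None,
    js=None,
    counts=None,
    sample_id="s1",
    total_reads=0,
    cell_count=None,
    **meta,
):
    """Build a repertoire from parallel lists; CDR3s default to CASSA-style
    distinct sequences."""
    n = len(freqs)
    if cdr3s is None:
        letters = "ACDEFGHIKLMNPQRSTVWY"
        cdr3s = ["CASS" + letters[i % 20] + letters[(i // 20) % 20] for i in range(n)]
    if vs is None:
        vs = ["TRBV17"] * n
    if js is None:
        js = [None] * n
    if counts is None:
        counts = [max(1, round(f * 1_000_000)) for f in freqs]
    clones = [
        Clonotype(cdr3aa=c, read_count=rc, frequency=f, v_segment=v, j_segment=j)
        for c, rc, f, v, j in zip(cdr3s, counts, freqs, vs, js)
    ]
    return Repertoire(
        sample_id=sample_id,
        clonotypes=clones,
        total_reads=total_reads,
        cell_count=cell_count,
        meta=SampleMeta(**meta) if meta else SampleMeta(),
    )


def uniform_model(alphabet="ACDF", length_dist=None):
    """Reduced-alphabet model with uniform emissions in every bin — pgen of
    any length-L sequence is |alphabet|^-L * P(L)."""
    p = 1.0 / len(alphabet)
    return GenerativeModel(
        length_dist=length_dist or {2: 0.4, 3: 0.6},
        emissions={b: {a: p for a in alphabet} for b in BINS},
        v_dist={"TRBV1": 0.5, "TRBV2": 0.5},
        j_dist={"TRBJ1-1": 0.5, "TRBJ2-7": 0.5},
        alphabet=alphabet,
    )


@pytest.fixture(scope="session")
def tiny4_model():
    return uniform_model()


@pytest.fixture(scope="session")
def mouse_model():
    from tcrhallmark import default_model

    return default_model()


SMALL_STUDY_CONFIG = dict(
    groups=("p30",),
    mice_per_group=2,
    clonotypes_per_sample=2_000,
    reads_per_sample=200_000,
    n_planted_clusters=4,
    cluster_size=6,
    cluster_frequency_mass=0.012,
    n_bystanders=8,
    bystander_frequency_mass=0.006,
    n_public_clones=6,
    public_frequency_mass=0.0018,
)


@pytest.fixture(scope="session")
def small_study():
    """One-group, 4-sample study at reduced depth with planted structure."""
    return simulate_study(StudyConfig(seed=11, **SMALL_STUDY_CONFIG))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
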