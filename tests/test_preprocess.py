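import math

import numpy as np
import pytest

from tcrhallmark import (
    choose_threshold,
    consistency_ratio,
    filter_and_rescale,
    pool_repertoires,
    top_group_clones,
    unique_clonesets,
)
from tcrhallmark.preprocess import PoolEntry, PooledCloneset

from conftest import make_repertoire


def random_normalized(rng, n=500):
    w = rng.lognormal(sigma=1.5, size=n)
    return list(w / w.sum())


class TestFilterAndRescale:
    def test_strict_threshold_and_rescale(self):
        rep = make_repertoire([0.5, 0.49985, 1e-4, 2.5e-5, 2.5e-5])
        out = filter_and_rescale(rep, 2.5e-5)
        assert len(out) == 3  # the two clones exactly at the threshold drop
        mass = 0.5 + 0.49985 + 1e-4
        expect = [0.5 / mass, 0.49985 / mass, 1e-4 / mass]
        for c, e in zip(out.clonotypes, expect):
            assert math.isclose(c.frequency, e, rel_tol=1e-12)
        assert math.isclose(out.frequency_sum(), 1.0, abs_tol=1e-9)

    def test_zero_threshold_is_identity(self):
        rep = make_repertoire([0.6, 0.4])
        out = filter_and_rescale(rep, 0.0)
        assert [c.frequency for c in out.clonotypes] == [0.6, 0.4]
        assert [c.read_count for c in out.clonotypes] == [
            c.read_count for c in rep.clonotypes
        ]

    def test_rescaling_matches_direct_recomputation(self, rng):
        freqs = random_normalized(rng)
        rep = make_repertoire(freqs)
        out = filter_and_rescale(rep, 2.5e-5)
        kept = [f for f in freqs if f > 2.5e-5]
        mass = sum(kept)
        assert math.isclose(out.frequency_sum(), 1.0, abs_tol=1e-9)
        for c, f in zip(out.clonotypes, kept):
            assert math.isclose(c.frequency, f / mass, rel_tol=1e-12)

    def test_idempotent_at_same_threshold(self, rng):
        rep = make_repertoire(random_normalized(rng))
        once = filter_and_rescale(rep, 2.5e-5)
        twice = filter_and_rescale(once, 2.5e-5)
        assert len(once) == len(twice)
        for a, b in zip(once.clonotypes, twice.clonotypes):
            assert math.isclose(a.frequency, b.frequency, rel_tol=1e-12)

    def test_threshold_removing_everything_errors(self):
        rep = make_repertoire([0.5, 0.5])
        with pytest.raises(ValueError, match="entire repertoire"):
            filter_and_rescale(rep, 0.6)


class TestConsistencyRatio:
    def test_sorted_sample_arithmetic(self):
        rep = make_repertoire(
            [0.9, 0.1], counts=[999_975, 25], total_reads=1_000_000, cell_count=75_000
        )
        res = consistency_ratio(rep)
        assert res.ratio == pytest.approx(4.0e4)
        assert res.passes

    def test_single_clone(self):
        rep = make_repertoire([1.0], counts=[100], total_reads=100, cell_count=2)
        res = consistency_ratio(rep)
        assert res.ratio == 1.0 and res.passes
        rep1 = make_repertoire([1.0], counts=[100], total_reads=100, cell_count=1)
        assert not consistency_ratio(rep1).passes

    def test_singleton_read_fails(self):
        rep = make_repertoire(
            [1 - 1e-6, 1e-6], counts=[999_999, 1], total_reads=1_000_000, cell_count=75_000
        )
        assert not consistency_ratio(rep).passes

    def test_missing_cell_count_errors(self):
        rep = make_repertoire([1.0], counts=[10])
        with pytest.raises(ValueError, match="cell_count"):
            consistency_ratio(rep)


class TestChooseThreshold:
    def _failing_singleton_rep(self):
        counts = [999_990] + [1] * 10
        freqs = [999_990 / 1e6] + [1e-6] * 10
        return make_repertoire(freqs, counts=counts, total_reads=1_000_000, cell_count=75_000)

    def test_passing_repertoire_returns_zero(self):
        rep = make_repertoire([0.9, 0.1], counts=[900, 100], total_reads=1000, cell_count=500)
        assert choose_threshold(rep) == 0.0

    def test_singleton_failure_picks_smallest_grid_value(self):
        rep = self._failing_singleton_rep()
        # singletons sit at 1e-6; the smallest grid value at/above that drops them
        assert choose_threshold(rep) == pytest.approx(1e-6)

    def test_grid_monotonicity(self):
        rep = self._failing_singleton_rep()
        t = choose_threshold(rep)
        for t2 in [2e-6, 5e-6, 1e-5]:
            assert t2 > t
            assert consistency_ratio(filter_and_rescale(rep, t2)).passes


def entry(aa, cum, per=None, v="TRBV1"):
    return PoolEntry(
        cdr3aa=aa,
        cumulative_frequency=cum,
        per_sample_frequencies=per or {"s1": cum},
        representative_v=v,
    )


class TestPooling:
    def _reps(self, freq_maps):
        reps = []
        for i, fm in enumerate(freq_maps):
            cdr3s = list(fm)
            reps.append(
                make_repertoire(
                    list(fm.values()), cdr3s=cdr3s, sample_id=f"s{i}", group="p30"
                )
            )
        return reps

    def test_cumulative_threshold_drops_and_keeps(self):
        base = {"CASSAAAAAF": 1 - 3e-5, "CASSDDDDDF": 3e-5}
        other = {"CASSAAAAAF": 1.0}
        with_two = {"CASSAAAAAF": 1 - 3e-5, "CASSCCCCCF": 3e-5}
        # clone at 3e-5 in one of three samples -> cumulative 3e-5 -> dropped
        pool = pool_repertoires(self._reps([base, other, with_two]))
        keys = set(pool.entries)
        assert "CASSDDDDDF" not in keys and "CASSCCCCCF" not in keys
        # the same clone in two samples -> cumulative 6e-5 -> kept
        pool2 = pool_repertoires(self._reps([base, base]))
        assert "CASSDDDDDF" in pool2.entries
        assert pool2.entries["CASSDDDDDF"].cumulative_frequency == pytest.approx(6e-5)

    def test_single_repertoire_identity(self):
        fm = {"CASSAAAAAF": 0.7, "CASSDDDDDF": 0.3}
        pool = pool_repertoires(self._reps([fm]), min_cumulative=0.0)
        assert {k: e.cumulative_frequency for k, e in pool.entries.items()} == fm

    def test_mass_conservation(self, rng):
        reps = []
        for i in range(4):
            freqs = random_normalized(rng, 200)
            cdr3s = [
                "C" + "".join(rng.choice(list("ASTGLRE"), size=8)) + "F" for _ in freqs
            ]
            reps.append(make_repertoire(freqs, cdr3s=cdr3s, sample_id=f"s{i}", group="p30"))
        pool = pool_repertoires(reps, min_cumulative=0.0)
        total = sum(e.cumulative_frequency for e in pool.entries.values())
        assert math.isclose(total, 4.0, abs_tol=1e-9)
        for e in pool.entries.values():
            assert math.isclose(
                e.cumulative_frequency, sum(e.per_sample_frequencies.values()),
                abs_tol=1e-12,
            )

    def test_mixed_groups_error(self):
        a = make_repertoire([1.0], sample_id="a", group="p20")
        b = make_repertoire([1.0], sample_id="b", group="p30")
        with pytest.raises(ValueError, match="mixed"):
            pool_repertoires([a, b])


class TestUniqueClonesets:
    def _pool(self, group, aas):
        return PooledCloneset(
            group=group, key_mode="cdr3aa", entries={aa: entry(aa, 0.01) for aa in aas}
        )

    def test_disjoint_pools_unchanged(self):
        res = unique_clonesets(self._pool("p20", ["CASSA"]), self._pool("p30", ["CASSD"]))
        assert res.overlap_fraction_a == 0 and res.overlap_fraction_b == 0
        assert len(res.unique_a) == 1 and len(res.unique_b) == 1

    def test_identical_pools_empty(self):
        res = unique_clonesets(self._pool("p20", ["CASSA"]), self._pool("p30", ["CASSA"]))
        assert res.overlap_fraction_a == 1 and res.overlap_fraction_b == 1
        assert len(res.unique_a) == 0 and len(res.unique_b) == 0

    def test_counts_match_set_arithmetic(self):
        letters = "ACDEFGHIKLMNPQRSTVWY"
        a_keys = ["CASS" + letters[i % 20] + letters[i // 20] for i in range(100)]
        b_keys = a_keys[:2] + ["CTSS" + letters[i % 20] + letters[i // 20] for i in range(48)]
        res = unique_clonesets(self._pool("p20", a_keys), self._pool("p30", b_keys))
        assert res.overlap_fraction_a == pytest.approx(0.02)
        assert res.overlap_fraction_b == pytest.approx(0.04)
        assert len(res.unique_a) == 98 and len(res.unique_b) == 48
        assert set(res.unique_a.entries).isdisjoint(res.unique_b.entries)


class TestTopGroupClones:
    def _pool(self):
        entries = {
            "CASSRRNYAEQFF": entry(
                "CASSRRNYAEQFF", 0.0136, {"dLN1": 7.2e-3, "ndLN1": 6.4e-3}, v="TRBV17"
            ),
            "CASSAAAAAF": entry("CASSAAAAAF", 0.001),
            "CASSDDDDDF": entry("CASSDDDDDF", 0.001),
        }
        return PooledCloneset(group="p30", key_mode="cdr3aa", entries=entries)

    def test_largest_cumulative_first(self):
        table = top_group_clones(self._pool(), 1)
        assert table.iloc[0]["cdr3aa"] == "CASSRRNYAEQFF"
        assert table.iloc[0]["v"] == "TRBV17"
        assert table.iloc[0]["dLN1"] == pytest.approx(7.2e-3)

    def test_n_larger_than_pool(self):
        assert len(top_group_clones(self._pool(), 100)) == 3

    def test_ties_break_lexicographically(self):
        table = top_group_clones(self._pool(), 3)
        assert list(table["cdr3aa"][1:]) == ["CASSAAAAAF", "CASSDDDDDF"]

    def test_nonpositive_n_errors(self):
        with pytest.raises(ValueError):
            top_group_clones(self._pool(), 0)
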