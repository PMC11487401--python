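import math

import pandas as pd
import pytest

from tcrhallmark import clone_ln_ratio, cluster_ln_ratio, top_cluster_ratio_summary
from tcrhallmark.clustering import Cluster
from tcrhallmark.convergence import ConvergenceHit
from tcrhallmark.enrichment import frequencies_ln_ratio, specificity_group_ratio

from conftest import make_repertoire


def member(aa, per, cum=None):
    cum = cum if cum is not None else sum(per.values())
    return ConvergenceHit(
        key=aa, cdr3aa=aa, v="TRBV1", j=None, observed=1, expected=1e-6,
        p_value=1e-8, adjusted_p=1e-6, is_hit=True,
        cumulative_frequency=cum, per_sample_frequencies=per,
    )


def cluster_of(cid, members):
    return Cluster(
        cluster_id=cid, members=members, edges=[], consensus=members[0].cdr3aa,
        size=len(members),
        cumulative_frequency=sum(m.cumulative_frequency for m in members),
    )


def four_samples(freq_by_sample, key="CASSPGQANTEVFF"):
    sides = {"dLN1": "dLN", "ndLN1": "ndLN", "dLN2": "dLN", "ndLN2": "ndLN"}
    reps = []
    for sid, side in sides.items():
        f = freq_by_sample.get(sid, 0.0)
        freqs = [f, 1 - f] if f > 0 else [1.0]
        cdr3s = [key, "CASSFILLERGNTLYF"][: len(freqs)] if f > 0 else ["CASSFILLERGNTLYF"]
        reps.append(
            make_repertoire(
                freqs, cdr3s=cdr3s, sample_id=sid,
                mouse_id=sid[-1], group="p30", ln_side=side,
            )
        )
    return reps


class TestCloneRatio:
    def test_reported_clone_arithmetic(self):
        # frequencies (x1e-3): dLN 8.5 + 0.3, ndLN 3.3 + 0.01 -> ratio 2.659
        samples = four_samples(
            {"dLN1": 8.5e-3, "ndLN1": 3.3e-3, "dLN2": 0.3e-3, "ndLN2": 0.01e-3}
        )
        rec = clone_ln_ratio("CASSPGQANTEVFF", samples)
        assert rec.ratio == pytest.approx(8.8 / 3.31, abs=1e-3)
        assert not rec.floored

    def test_equal_sides_give_one(self):
        samples = four_samples(
            {"dLN1": 2e-3, "ndLN1": 2e-3, "dLN2": 1e-3, "ndLN2": 1e-3}
        )
        assert clone_ln_ratio("CASSPGQANTEVFF", samples).ratio == pytest.approx(1.0)

    def test_absent_side_floored(self):
        samples = four_samples({"dLN1": 2e-3, "dLN2": 1e-3})
        rec = clone_ln_ratio("CASSPGQANTEVFF", samples, floor=2.5e-5)
        assert rec.floored
        assert rec.ratio == pytest.approx(3e-3 / 2.5e-5)

    def test_missing_side_errors(self):
        reps = [
            make_repertoire([1.0], sample_id="a", ln_side="dLN"),
            make_repertoire([1.0], sample_id="b", ln_side="dLN"),
        ]
        with pytest.raises(ValueError, match="ndLN"):
            clone_ln_ratio("CASSA", reps)


SIDES = {"dLN1": "dLN", "ndLN1": "ndLN", "dLN2": "dLN", "ndLN2": "ndLN"}


class TestClusterRatio:
    def test_single_member_reduces_to_clone_ratio(self):
        per = {"dLN1": 8.5e-3, "ndLN1": 3.3e-3, "dLN2": 0.3e-3, "ndLN2": 0.01e-3}
        c = cluster_of(1, [member("CASSPGQANTEVFF", per)])
        samples = four_samples(per)
        assert cluster_ln_ratio(c, samples).ratio == pytest.approx(
            clone_ln_ratio("CASSPGQANTEVFF", samples).ratio, abs=1e-9
        )

    def test_two_member_sums(self):
        c = cluster_of(
            1,
            [
                member("CASSA", {"dLN1": 4e-3, "ndLN1": 5e-3}),
                member("CASSD", {"dLN1": 6e-3, "ndLN1": 5e-3}),
            ],
        )
        assert cluster_ln_ratio(c, SIDES).ratio == pytest.approx(1.0)

    def test_antisymmetry_under_side_swap(self):
        per = {"dLN1": 4e-3, "ndLN1": 1e-3, "dLN2": 2e-3, "ndLN2": 3e-3}
        c = cluster_of(1, [member("CASSA", per)])
        r = cluster_ln_ratio(c, SIDES).ratio
        swapped = {s: ("dLN" if side == "ndLN" else "ndLN") for s, side in SIDES.items()}
        assert cluster_ln_ratio(c, swapped).ratio == pytest.approx(1 / r)

    def test_scale_invariance(self):
        per = {"dLN1": 4e-3, "ndLN1": 1e-3}
        scaled = {s: f * 0.1 for s, f in per.items()}
        r1 = cluster_ln_ratio(cluster_of(1, [member("CASSA", per)]), SIDES).ratio
        r2 = cluster_ln_ratio(cluster_of(1, [member("CASSA", scaled)]), SIDES).ratio
        assert r1 == pytest.approx(r2)


class TestTopClusterSummary:
    def test_identical_ratios(self):
        clusters = [
            cluster_of(i, [member(f"CASS{c}", {"dLN1": 2e-3, "ndLN1": 1e-3})])
            for i, c in enumerate("ABC")
        ]
        s = top_cluster_ratio_summary(clusters, SIDES, k=3)
        assert s.mean == pytest.approx(2.0) and s.sd == 0.0 and s.sem == 0.0

    def test_known_spread(self):
        pers = [
            {"dLN1": 1e-3, "ndLN1": 1e-3},
            {"dLN1": 2e-3, "ndLN1": 1e-3},
            {"dLN1": 3e-3, "ndLN1": 1e-3},
        ]
        clusters = [
            cluster_of(i, [member(f"CASS{c}", per)])
            for i, (c, per) in enumerate(zip("ABC", pers))
        ]
        s = top_cluster_ratio_summary(clusters, SIDES, k=3)
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)
        assert s.sem == pytest.approx(0.5774, abs=1e-4)

    def test_k_exceeding_cluster_count(self):
        clusters = [cluster_of(1, [member("CASSA", {"dLN1": 1e-3, "ndLN1": 1e-3})])]
        s = top_cluster_ratio_summary(clusters, SIDES, k=30)
        assert s.n == 1


class TestSpecificityGroupRatio:
    def _matches(self, rows):
        return pd.DataFrame(
            rows,
            columns=["sample_id", "clone_index", "cdr3aa", "v", "frequency",
                     "label", "db_cdr3aa", "db_v"],
        )

    def test_single_clone(self):
        m = self._matches(
            [("dLN1", 0, "CASSA", "TRBV1", 2e-3, "TRP-2", "CASSA", "TRBV1"),
             ("ndLN1", 0, "CASSA", "TRBV1", 1e-3, "TRP-2", "CASSA", "TRBV1")]
        )
        stats, records = specificity_group_ratio(m, "TRP-2", SIDES)
        assert stats.mean == pytest.approx(2.0) and stats.sd == 0.0

    def test_two_clone_spread(self):
        m = self._matches(
            [("dLN1", 0, "CASSA", "TRBV1", 1e-3, "GVHD", "CASSA", "TRBV1"),
             ("ndLN1", 0, "CASSA", "TRBV1", 1e-3, "GVHD", "CASSA", "TRBV1"),
             ("dLN1", 1, "CASSD", "TRBV1", 3e-3, "GVHD", "CASSD", "TRBV1"),
             ("ndLN1", 1, "CASSD", "TRBV1", 1e-3, "GVHD", "CASSD", "TRBV1")]
        )
        stats, _ = specificity_group_ratio(m, "GVHD", SIDES)
        assert stats.mean == pytest.approx(2.0)
        assert stats.sd == pytest.approx(math.sqrt(2), abs=1e-3)

    def test_unknown_label_lists_available(self):
        m = self._matches(
            [("dLN1", 0, "CASSA", "TRBV1", 1e-3, "TRP-2", "CASSA", "TRBV1")]
        )
        with pytest.raises(ValueError, match="TRP-2"):
            specificity_group_ratio(m, "gp100", SIDES)


class TestFrequenciesRatio:
    def test_sample_order_invariance(self):
        per = {"dLN1": 3e-3, "ndLN1": 1e-3, "dLN2": 1e-3, "ndLN2": 2e-3}
        r1 = frequencies_ln_ratio("x", per, SIDES).ratio
        r2 = frequencies_ln_ratio("x", dict(reversed(per.items())), SIDES).ratio
        assert r1 == pytest.approx(r2)
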