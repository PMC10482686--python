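"""Province classification, ridgelines, overlap/exclusivity, dominance."""

import numpy as np
import pytest

from abyssal.beta_diversity import bray_curtis
from abyssal.zonation import (
    ProvinceScheme,
    boundary_sweep,
    classify_province,
    dominance,
    overlap_counts,
    ridgeline,
)

from conftest import bd_sample, make_table


class TestClassifyProvince:
    @pytest.mark.parametrize(
        "depth,expected",
        [
            (4299.0, "shallow"),
            (4300.0, "transition"),  # half-open boundary
            (4799.0, "transition"),
            (4800.0, "deep"),
            (4850.0, "deep"),
            (5300.0, "deep"),
        ],
    )
    def test_boundaries(self, depth, expected):
        assert classify_province(depth) == expected

    def test_partition_is_total(self):
        rng = np.random.default_rng(0)
        labels = {classify_province(float(d)) for d in rng.uniform(100, 9000, 500)}
        assert labels <= {"shallow", "transition", "deep"}

    def test_invalid_scheme(self):
        with pytest.raises(ValueError):
            ProvinceScheme(b1=5000, b2=4000)


class TestRidgeline:
    def make_table_for(self, group_depths):
        rows = []
        i = 0
        for group, depths in group_depths.items():
            for d in depths:
                rows.append(
                    (f"s{i}", f"i{i}", "A", 12.0, -140.0, float(d), f"M{i}", group)
                )
                i += 1
        return make_table(rows)

    def test_frequencies(self):
        t = self.make_table_for({"Act": [4000] * 3 + [5000]})
        (r,) = ridgeline(t, min_occurrences=3)
        assert r.frequencies.sum() == pytest.approx(1.0)
        by_bin = dict(zip(r.bin_edges[:-1], r.frequencies))
        assert by_bin[4000.0] == pytest.approx(0.75)
        assert by_bin[5000.0] == pytest.approx(0.25)

    def test_threshold_is_strict(self):
        t = self.make_table_for({"Act": [4000] * 50, "Hol": [4000] * 51})
        groups = {r.group for r in ridgeline(t, min_occurrences=50)}
        assert groups == {"Hol"}

    def test_random_fixture_normalized(self):
        rng = np.random.default_rng(1)
        t = self.make_table_for(
            {g: rng.uniform(3900, 5300, 80) for g in ("Act", "Hol", "Oph")}
        )
        for r in ridgeline(t):
            assert r.frequencies.sum() == pytest.approx(1.0)


class TestOverlapCounts:
    def test_exclusive_and_shared(self):
        samples = [
            bd_sample({"A": 10, "B": 5}, sample_id="s1", depth=4000.0),
            bd_sample({"B": 7, "C": 8}, sample_id="s2", depth=5000.0),
        ]
        oc = overlap_counts(samples)
        assert oc.per_province["shallow"]["exclusive"] == 1  # A
        assert oc.per_province["deep"]["exclusive"] == 1  # C
        assert oc.shared_shallow_deep == 1  # B

    def test_rare_threshold(self):
        samples = [
            bd_sample({"A": 4, "B": 100}, sample_id="s1", depth=4000.0),
        ]
        oc = overlap_counts(samples)
        assert oc.per_province["shallow"]["rare_exclusive"] == 1  # A only

    def test_transition_does_not_void_sharing(self):
        samples = [
            bd_sample({"X": 5}, sample_id="s1", depth=4000.0),
            bd_sample({"X": 5}, sample_id="s2", depth=4500.0),
            bd_sample({"X": 5}, sample_id="s3", depth=5000.0),
        ]
        oc = overlap_counts(samples)
        assert oc.shared_shallow_deep == 1
        assert oc.per_province["transition"]["exclusive"] == 0

    def test_totals_bound_exclusives(self):
        rng = np.random.default_rng(2)
        samples = [
            bd_sample(
                {f"m{k}": int(rng.integers(1, 9)) for k in rng.choice(30, 10, replace=False)},
                sample_id=f"s{i}",
                depth=float(rng.choice([4000, 4500, 5000])),
            )
            for i in range(12)
        ]
        oc = overlap_counts(samples)
        for p, c in oc.per_province.items():
            assert c["exclusive"] <= c["total"]
            assert c["rare_exclusive"] <= c["exclusive"]
        assert oc.shared_shallow_deep <= min(
            oc.per_province["shallow"]["total"], oc.per_province["deep"]["total"]
        )


class TestDominance:
    def test_top10_share(self):
        ab = {f"big{i}": 6 for i in range(10)}
        ab.update({f"rare{i}": 1 for i in range(40)})
        dom = dominance([bd_sample(ab, sample_id="s1", depth=4000.0)], k=10)
        assert dom.topk_share["shallow"] == pytest.approx(0.6)

    def test_single_taxon_share_is_one(self):
        dom = dominance([bd_sample({"only": 200}, sample_id="s1", depth=4900.0)])
        assert dom.topk_share["deep"] == pytest.approx(1.0)

    def test_ties_broken_by_label(self):
        samples = [bd_sample({"b": 5, "a": 5, "c": 5}, sample_id="s1", depth=4000.0)]
        dom = dominance(samples, k=3)
        assert list(dom.tables["shallow"]["taxon"]) == ["a", "b", "c"]
        dom2 = dominance(samples, k=3)
        assert list(dom2.tables["shallow"]["taxon"]) == ["a", "b", "c"]

    def test_group_level_requires_mapping(self):
        s = [bd_sample({"a": 10}, sample_id="s1")]
        with pytest.raises(ValueError, match="mapping"):
            dominance(s, level="group")
        dom = dominance(s, level="group", groups={"a": "Act"})
        assert list(dom.tables["shallow"]["taxon"]) == ["Act"]
        assert dom.k == 4


class TestSyntheticRecovery:
    def test_calcifiers_absent_below_ccd(self, default_run):
        """The programmed hard CCD cut-off is exact in the raw records."""
        table, truth = default_run["table"], default_run["truth"]
        calcifiers = set(
            truth.community.loc[
                truth.community["response"] == "ccd_restricted", "morphotype"
            ]
        )
        rec = table.records
        below = rec[rec["depth"] > truth.ccd_depth]
        assert not set(below["morphotype"].dropna()) & calcifiers

    def test_calcifiers_never_in_deep_province_samples(self, default_run):
        """With CCD <= deep boundary, overlap counting places every
        calcifier morphotype outside the deep province."""
        truth = default_run["truth"]
        assert truth.ccd_depth <= truth.province_boundaries[1]
        calcifiers = set(
            truth.community.loc[
                truth.community["response"] == "ccd_restricted", "morphotype"
            ]
        )
        for s in default_run["bd"]:
            if classify_province(s.mean_depth) == "deep":
                assert not set(s.abundances) & calcifiers

    def test_boundary_sweep_recovers_ccd(self, default_run):
        bd = default_run["bd"]
        truth = default_run["truth"]
        sweep = boundary_sweep(bd, bray_curtis(bd))
        best = sweep.loc[sweep["score"].idxmax(), "boundary_m"]
        assert abs(best - truth.ccd_depth) <= 100.0
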