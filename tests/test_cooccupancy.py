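"""Summit intersection, MARE rules, differential calls, gene annotation."""

import numpy as np
import pytest

from chromare.cooccupancy import (
    DifferentialOccupancy,
    annotate_genes,
    call_mares,
    classify_combinations,
    deg_overlap,
    differential_occupancy,
    intersect_summits,
    overlap_fraction,
)
from chromare.io import DegTable, GenomicInterval, IntervalSet, TssRecord
from chromare.matrices import SignalMatrix
from chromare.peaks import PairedPeakCall, Summit


def sites_at(*positions, chrom="chr1", name_prefix="s"):
    ivs = []
    for i, pos in enumerate(positions):
        ivs.append(
            GenomicInterval(chrom, max(0, pos - 100), pos + 100,
                            name=f"{name_prefix}{i}", summit=min(pos, 100))
        )
    return IntervalSet(tuple(ivs))


class TestIntersectSummits:
    def test_within_threshold_cooccupied(self):
        df = intersect_summits(sites_at(1000), sites_at(1100), max_dist=250)
        assert bool(df.loc[0, "cooccupied"])
        assert df.loc[0, "offset"] == 100

    def test_boundary_is_inclusive_then_exclusive(self):
        assert bool(
            intersect_summits(sites_at(1000), sites_at(1250), 250)
            .loc[0, "cooccupied"]
        )
        assert not bool(
            intersect_summits(sites_at(1000), sites_at(1251), 250)
            .loc[0, "cooccupied"]
        )

    def test_nearest_b_summit_chosen(self):
        df = intersect_summits(sites_at(1000), sites_at(760, 1260), 250)
        assert df.loc[0, "offset"] == -240  # -240 nearer than +260

    def test_equidistant_resolves_leftmost(self):
        df = intersect_summits(sites_at(1000), sites_at(900, 1100), 250)
        assert df.loc[0, "offset"] == -100

    def test_symmetric_match_counts(self):
        a, b = sites_at(1000, 5000), sites_at(1100, 9000)
        ab = intersect_summits(a, b, 250)["cooccupied"].sum()
        ba = intersect_summits(b, a, 250)["cooccupied"].sum()
        assert ab == ba == 1

    def test_negative_max_dist_rejected(self):
        with pytest.raises(ValueError):
            intersect_summits(sites_at(0), sites_at(0), -1)

    def test_shift_invariance(self):
        df1 = intersect_summits(sites_at(1000), sites_at(1100), 250)
        df2 = intersect_summits(sites_at(31000), sites_at(31100), 250)
        assert df1.loc[0, "offset"] == df2.loc[0, "offset"]


class TestClassifyCombinations:
    def test_exact_combination_codes(self):
        sites = sites_at(1000, 5000, 9000)
        factors = {
            "MITF": sites_at(1000, 5000),
            "SOX10": sites_at(1020),
        }
        records, table = classify_combinations(sites, factors, 250)
        codes = {r.site_id: r.code for r in records}
        assert codes == {"s0": "MITF+SOX10", "s1": "MITF", "s2": "none"}
        assert dict(zip(table["combination"], table["n_sites"])) == {
            "MITF+SOX10": 1, "MITF": 1, "none": 1,
        }

    def test_single_factor_two_classes(self):
        sites = sites_at(1000, 9000)
        _, table = classify_combinations(sites, {"F": sites_at(1000)}, 250)
        assert set(table["combination"]) == {"F", "none"}

    def test_empty_site_set_empty_table(self):
        _, table = classify_combinations(IntervalSet(), {"F": sites_at(0)},
                                         250)
        assert len(table) == 0


def paired_call(site_id, p1=-250.0, p2=250.0):
    return PairedPeakCall(site_id, (Summit(p1, 5), Summit(p2, 5)), "paired",
                          p1, p2, p2 - p1, "left")


class TestCallMares:
    def setup_method(self):
        self.sites = sites_at(1000, name_prefix="m")
        self.acetyl_both = sites_at(750, 1250, name_prefix="ac")

    def call(self, tf_pos=1000, calls=None, acetyl=None, **kw):
        calls = calls if calls is not None else {"m0": paired_call("m0")}
        acetyl = acetyl if acetyl is not None else self.acetyl_both
        return call_mares(self.sites, calls, {"MITF": sites_at(tf_pos)},
                          acetyl, **kw)

    def test_canonical_architecture_is_mare(self):
        (rec,) = self.call()
        assert rec.is_mare and rec.strictly_between
        assert rec.acetyl_left and rec.acetyl_right

    def test_tf_outside_pair_is_not_mare(self):
        # TF present at the site (within max_dist) but right of the pair
        (rec,) = self.call(tf_pos=1300, max_dist=400)
        assert not rec.strictly_between and not rec.is_mare

    def test_tf_at_flank_summit_is_not_between(self):
        (rec,) = self.call(tf_pos=750)
        assert not rec.is_mare  # strict inequality: p1 < s

    def test_single_flank_acetyl_flagged_not_mare(self):
        (rec,) = self.call(acetyl=sites_at(750, name_prefix="ac"))
        assert rec.strictly_between and not rec.is_mare
        assert rec.acetyl_left and not rec.acetyl_right

    def test_either_rule_accepts_single_flank(self):
        (rec,) = self.call(acetyl=sites_at(750, name_prefix="ac"),
                           acetyl_rule="either")
        assert rec.is_mare

    def test_unpaired_site_not_reported(self):
        calls = {"m0": PairedPeakCall("m0", (Summit(0, 5),), "single")}
        assert self.call(calls=calls) == []

    def test_mare_subset_of_cooccupied(self):
        records = self.call()
        assert {r.site_id for r in records} <= set(self.sites.ids())


class TestDifferential:
    def mat(self, values):
        values = np.asarray(values, dtype=float)
        return SignalMatrix(values,
                            tuple(f"s{i}" for i in range(values.shape[0])),
                            flank=values.shape[1] * 5, bin_size=10)

    def test_identical_matrices_all_unchanged(self, rng):
        m = self.mat(rng.random((5, 10)) + 1)
        calls = differential_occupancy(m, m, 1.0)
        assert all(c.label == "unchanged" and c.log2_ratio == 0 for c in calls)

    def test_quartered_signal_is_loss(self, rng):
        x = rng.random((5, 10)) + 4
        calls = differential_occupancy(self.mat(x), self.mat(0.25 * x), 1.0,
                                       pseudocount=1e-9)
        assert all(c.label == "loss" for c in calls)
        assert calls[0].log2_ratio == pytest.approx(-2, abs=1e-6)

    def test_gain_symmetry(self, rng):
        x = rng.random((5, 10)) + 4
        calls = differential_occupancy(self.mat(x), self.mat(4 * x), 1.0,
                                       pseudocount=1e-9)
        assert all(c.label == "gain" for c in calls)

    def test_misaligned_matrices_rejected(self, rng):
        m1 = self.mat(rng.random((5, 10)))
        m2 = SignalMatrix(rng.random((5, 10)), tuple("abcde"), 50, 10)
        with pytest.raises(ValueError, match="share anchors"):
            differential_occupancy(m1, m2)

    def test_estimator_params_round_trip(self):
        est = DifferentialOccupancy(log2_threshold=2.0)
        assert est.get_params()["log2_threshold"] == 2.0
        est.set_params(log2_threshold=0.5)
        assert est.log2_threshold == 0.5


class TestAnnotateGenes:
    def tss(self, pos=100_000):
        return [TssRecord("g1", "chr1", pos, "+")]

    def site(self, summit_pos):
        return IntervalSet((
            GenomicInterval("chr1", summit_pos - 50, summit_pos + 50,
                            name="s0", summit=50),
        ))

    @pytest.mark.parametrize(
        "offset,window,linked",
        [
            (9_999, 10_000, True),
            (10_000, 10_000, False),  # half-open upper bound
            (-10_000, 10_000, True),  # closed lower bound
            (-10_001, 10_000, False),
            (29_999, 30_000, True),
            (30_000, 30_000, False),
        ],
    )
    def test_window_boundaries_half_open(self, offset, window, linked):
        gene_map, _ = annotate_genes(self.site(100_000 + offset), self.tss(),
                                     window)
        assert ("g1" in gene_map) is linked

    def test_both_directions_of_map(self):
        gene_map, site_map = annotate_genes(self.site(101_000), self.tss(),
                                            10_000)
        assert gene_map == {"g1": ["s0"]}
        assert site_map == {"s0": ["g1"]}


class TestOverlapFraction:
    def test_planted_fraction_recovered(self):
        deg = DegTable({f"d{i}": "down" for i in range(100)})
        annotated = {f"d{i}" for i in range(34)}
        out = overlap_fraction(annotated, deg)
        assert out["down"]["fraction"] == pytest.approx(0.34)
        assert out["down"]["n_annotated"] == 34

    def test_all_annotated_gives_one(self):
        deg = DegTable({"a": "up", "b": "down"})
        out = overlap_fraction({"a", "b"}, deg)
        assert out["up"]["fraction"] == 1.0 and out["down"]["fraction"] == 1.0

    def test_empty_status_is_undefined(self):
        out = overlap_fraction(set(), DegTable({"a": "up"}))
        assert out["down"]["fraction"] is None

    def test_disjoint_ids_warn_and_give_zero(self):
        deg = DegTable({"a": "down"})
        with pytest.warns(UserWarning, match="disjoint"):
            out = overlap_fraction({"zzz"}, deg)
        assert out["down"]["fraction"] == 0.0

    def test_pairwise_deg_overlap(self):
        a = DegTable({"x": "down", "y": "down", "z": "up"})
        b = DegTable({"y": "down", "w": "down"})
        df = deg_overlap(a, b).set_index("status")
        assert df.loc["down", "both"] == 1
        assert df.loc["down", "a_only"] == 1
        assert df.loc["down", "b_only"] == 1
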