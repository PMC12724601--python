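import itertools

import numpy as np
import pandas as pd
import pytest

from xsc.regulatory import (
    annotate_min_overlap,
    classify_region_orthology,
    evolutionary_distance,
    group_jaccard,
    node_branch_lengths,
    promoter_windows,
    regions_from_bed,
)

TOY_TREE = "((A:1,B:1)AB:1,C:2)root;"


def make_regions(rows):
    df = pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])
    df["region_id"] = (df["Chromosome"] + ":" + df["Start"].astype(str)
                       + "-" + df["End"].astype(str))
    return df


class TestRegionOrthology:
    def lift(self, pairs):
        return pd.DataFrame({"region_id": [p[0] for p in pairs],
                             "aligned_bp": [p[1] for p in pairs]})

    @pytest.mark.parametrize("bp1, bp2, expected", [
        (250, 300, "orthologous"),       # both clear the 250/500 rule
        (249, 0, "species_specific"),    # both below
        (400, 100, "partial"),           # exactly one passes
    ])
    def test_three_classes(self, bp1, bp2, expected):
        regions = make_regions([("chr1", 0, 500)])
        rid = regions["region_id"].iloc[0]
        out = classify_region_orthology(
            regions, {"mac": self.lift([(rid, bp1)]), "mar": self.lift([(rid, bp2)])},
            min_frac=0.5)
        assert out["orthology_class"].iloc[0] == expected

    def test_unknown_region_in_liftover_rejected(self):
        regions = make_regions([("chr1", 0, 500)])
        with pytest.raises(KeyError, match="ghost"):
            classify_region_orthology(regions, {"mac": self.lift([("ghost", 10)])})

    def test_min_frac_limits(self):
        regions = make_regions([("chr1", 0, 500)])
        rid = regions["region_id"].iloc[0]
        lift = {"mac": self.lift([(rid, 1)])}
        tiny = classify_region_orthology(regions, lift, min_frac=1e-9)
        assert tiny["matched_mac"].iloc[0]
        full = classify_region_orthology(regions, lift, min_frac=1.0)
        assert not full["matched_mac"].iloc[0]
        exact = classify_region_orthology(
            regions, {"mac": self.lift([(rid, 500)])}, min_frac=1.0)
        assert exact["matched_mac"].iloc[0]

    def test_best_record_per_region_used(self):
        regions = make_regions([("chr1", 0, 500)])
        rid = regions["region_id"].iloc[0]
        out = classify_region_orthology(
            regions, {"mac": self.lift([(rid, 10), (rid, 400)])}, min_frac=0.5)
        assert out["matched_mac"].iloc[0]


class TestEvolutionaryDistance:
    def frac(self, values, nodes=("A", "B", "AB", "C")):
        return pd.DataFrame([values], index=["r1"], columns=list(nodes))

    def test_toy_tree_partial_clade(self):
        # branches A=1, B=1, AB=1, C=2; total 5; aligned {A, B, AB} -> 3/5
        out = evolutionary_distance(TOY_TREE, self.frac([0.95, 0.99, 0.92, 0.1]))
        assert out.iloc[0] == pytest.approx(0.6)

    def test_full_and_empty_alignment(self):
        assert evolutionary_distance(TOY_TREE, self.frac([1, 1, 1, 1])).iloc[0] == 1.0
        assert evolutionary_distance(TOY_TREE, self.frac([0, 0, 0, 0])).iloc[0] == 0.0

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError, match="ghost"):
            evolutionary_distance(TOY_TREE, self.frac([1, 1, 1, 1],
                                                      nodes=("A", "B", "AB", "ghost")))

    def test_monotone_in_threshold_and_alignment(self, rng):
        F = pd.DataFrame(rng.uniform(size=(20, 4)), columns=["A", "B", "AB", "C"])
        d_loose = evolutionary_distance(TOY_TREE, F, align_thr=0.5)
        d_tight = evolutionary_distance(TOY_TREE, F, align_thr=0.95)
        assert (d_loose >= d_tight - 1e-12).all()
        F2 = F.copy()
        F2["C"] = 1.0  # add a node to every region's aligned set
        assert (evolutionary_distance(TOY_TREE, F2, 0.9)
                >= evolutionary_distance(TOY_TREE, F, 0.9) - 1e-12).all()

    def test_leaves_mode_excludes_internal_branches(self):
        w = node_branch_lengths(TOY_TREE, mode="leaves")
        assert set(w.index) == {"A", "B", "C"}
        assert w.sum() == pytest.approx(1.0)


class TestPromoterWindows:
    def test_strand_aware_windows(self):
        gm = pd.DataFrame({
            "gene_id": ["gp", "gm"],
            "Chromosome": ["chr1", "chr1"],
            "Strand": ["+", "-"],
            "tss": [10_000, 10_000],
        })
        out = promoter_windows(gm).set_index("gene_id")
        assert (out.loc["gp", "Start"], out.loc["gp", "End"]) == (9000, 10500)
        assert (out.loc["gm", "Start"], out.loc["gm", "End"]) == (9500, 11000)

    def test_clipped_at_chromosome_start(self):
        gm = pd.DataFrame({"gene_id": ["g"], "Chromosome": ["chr1"],
                           "Strand": ["+"], "tss": [300]})
        out = promoter_windows(gm)
        assert (out["Start"].iloc[0], out["End"].iloc[0]) == (0, 800)

    def test_same_gene_overlapping_windows_merged(self):
        gm = pd.DataFrame({"gene_id": ["g", "g"], "Chromosome": ["chr1"] * 2,
                           "Strand": ["+", "+"], "tss": [10_000, 10_400]})
        out = promoter_windows(gm)
        assert len(out) == 1
        assert (out["Start"].iloc[0], out["End"].iloc[0]) == (9000, 10900)

    def test_unknown_strand_rejected(self):
        gm = pd.DataFrame({"gene_id": ["g"], "Chromosome": ["chr1"],
                           "Strand": ["."], "tss": [5000]})
        with pytest.raises(ValueError, match="strand"):
            promoter_windows(gm)


class TestAnnotateMinOverlap:
    def features(self, rows):
        return pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "name"])

    def test_min_overlap_rule(self):
        regions = make_regions([("chr1", 0, 500)])
        hits = annotate_min_overlap(regions, self.features([("chr1", 250, 800, "te1")]),
                                    min_bp=250)
        assert hits.loc[0, "feature"] == "te1" and hits.loc[0, "hit"]

    def test_below_threshold_gets_sentinel(self):
        regions = make_regions([("chr1", 0, 500)])
        hits = annotate_min_overlap(regions, self.features([("chr1", 251, 800, "te1")]),
                                    min_bp=250)
        assert hits.loc[0, "feature"] == "False"
        assert hits.loc[0, "overlap_bp"] == -1
        assert not hits.loc[0, "hit"]

    def test_abutting_half_open_intervals_never_annotate(self):
        regions = make_regions([("chr1", 0, 100)])
        hits = annotate_min_overlap(regions, self.features([("chr1", 100, 200, "f")]),
                                    min_bp=0)
        assert not hits["hit"].any()

    def test_multiple_qualifying_features_all_reported(self):
        regions = make_regions([("chr1", 0, 500)])
        hits = annotate_min_overlap(
            regions, self.features([("chr1", 0, 300, "f1"), ("chr1", 100, 500, "f2")]),
            min_bp=250)
        assert set(hits.loc[hits["hit"], "feature"]) == {"f1", "f2"}


class TestGroupJaccard:
    def test_known_values(self):
        m = pd.DataFrame({"a": [1, 1, 0, 0], "b": [1, 0, 1, 0], "c": [1, 1, 0, 0]})
        J = group_jaccard(m)
        assert J.loc["a", "b"] == pytest.approx(1 / 3)
        assert J.loc["a", "c"] == pytest.approx(1.0)
        assert J.loc["a", "a"] == 1.0

    def test_disjoint_columns(self):
        m = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        assert group_jaccard(m).loc["a", "b"] == 0.0

    def test_empty_group_warns_nan(self):
        m = pd.DataFrame({"a": [1, 0], "b": [0, 0]})
        with pytest.warns(UserWarning, match="empty"):
            J = group_jaccard(m)
        assert np.isnan(J.loc["a", "b"])

    def test_oracle_set_arithmetic_and_metric(self, rng):
        m = pd.DataFrame(rng.integers(0, 2, size=(30, 5)) | np.eye(30, 5, dtype=int),
                         columns=list("abcde"))
        J = group_jaccard(m)
        D = group_jaccard(m, distance=True)
        sets = {c: set(np.flatnonzero(m[c])) for c in m}
        for x, y in itertools.combinations(m.columns, 2):
            expect = len(sets[x] & sets[y]) / len(sets[x] | sets[y])
            assert J.loc[x, y] == pytest.approx(expect)
            assert J.loc[x, y] == J.loc[y, x]
        for x, y, z in itertools.permutations(m.columns, 3):
            assert D.loc[x, z] <= D.loc[x, y] + D.loc[y, z] + 1e-12

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            group_jaccard(pd.DataFrame({"a": [2, 0]}))


def test_regions_from_bed_round_trip(tmp_path):
    bed = tmp_path / "r.bed"
    bed.write_text("chr1\t0\t500\nchr2\t100\t900\n")
    df = regions_from_bed(bed)
    assert df["region_id"].tolist() == ["chr1:0-500", "chr2:100-900"]
    aliased = regions_from_bed(bed, alias={"chr2": "2"})
    assert aliased["region_id"].tolist()[1] == "2:100-900"
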