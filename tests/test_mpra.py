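"""MPRA quantification: counting, normalization, QC, scan, tests vs WT."""

import numpy as np
import pandas as pd
import pytest

from titinreg import mpra
from titinreg.mpra import (ActivityTable, BarcodeCountMatrix, ConstructDesign,
                           activity_ratio, assign_barcodes, mutagenesis_scan,
                           normalize_counts, qc_filter)
from titinreg.mpra import test_vs_wt as compare_vs_wt


def make_activity_table(ratio: pd.DataFrame, dna_cpm: pd.DataFrame | None = None,
                        n_libraries: int = 1) -> ActivityTable:
    if dna_cpm is None:
        dna_cpm = pd.DataFrame(1000.0, index=ratio.index, columns=ratio.columns)
    n_wells = ratio.shape[1] // n_libraries
    reps = pd.DataFrame(
        {"library": np.repeat(np.arange(1, n_libraries + 1), n_wells),
         "well": np.tile(np.arange(1, n_wells + 1), n_libraries)},
        index=ratio.columns)
    return ActivityTable(ratio=ratio, dna_cpm=dna_cpm, rna_cpm=ratio * dna_cpm,
                         included=pd.DataFrame(True, index=ratio.index,
                                               columns=ratio.columns),
                         reasons=pd.DataFrame("", index=ratio.index,
                                              columns=ratio.columns),
                         replicates=reps)


class TestAssignBarcodes:
    DESIGN = [
        ConstructDesign("A", "wt", None, "", frozenset({"b1", "b2"})),
        ConstructDesign("B", "tf_deletion", (5, 9), "m1", frozenset({"b3"})),
    ]

    def test_sums_and_unmatched(self):
        m = assign_barcodes([("b1", 10), ("b2", 5), ("bX", 7)], self.DESIGN, "DNA")
        assert m.counts.loc["A"].iloc[0] == 15
        assert m.counts.loc["B"].iloc[0] == 0
        assert m.unmatched.iloc[0] == 7

    def test_empty_stream_all_zero(self):
        m = assign_barcodes([], self.DESIGN, "RNA")
        assert (m.counts == 0).all().all()

    def test_duplicate_barcode_rejected(self):
        bad = self.DESIGN + [ConstructDesign("C", "wt", None, "",
                                             frozenset({"b1"}))]
        with pytest.raises(ValueError, match="b1"):
            assign_barcodes([], bad, "DNA")

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(11)
        design = [ConstructDesign(f"c{i}", "wt", None, "",
                                  frozenset({f"bc{i}_{j}" for j in range(3)}))
                  for i in range(100)]
        pool = [bc for c in design for bc in sorted(c.barcode_ids)] + \
               [f"junk{i}" for i in range(30)]
        reads = [(pool[i], int(n)) for i, n in
                 zip(rng.integers(0, len(pool), 500), rng.integers(0, 50, 500))]
        m = assign_barcodes(reads, design, "DNA")
        # oracle: per-read linear scan over the design list
        expected = {c.construct_id: 0 for c in design}
        junk = 0
        for bc, n in reads:
            for c in design:
                if bc in c.barcode_ids:
                    expected[c.construct_id] += n
                    break
            else:
                junk += n
        for cid, total in expected.items():
            assert m.counts.loc[cid].iloc[0] == total
        assert m.unmatched.iloc[0] == junk


class TestNormalize:
    def test_counts_per_million(self):
        m = BarcodeCountMatrix(
            "DNA", pd.DataFrame({"r1": [10, 30, 60]}, index=["a", "b", "c"]),
            pd.DataFrame({"library": [1], "well": [1]}, index=["r1"]))
        norm = normalize_counts(m)
        np.testing.assert_allclose(norm["r1"], [1e5, 3e5, 6e5])

    def test_single_construct_gets_million(self):
        m = BarcodeCountMatrix(
            "DNA", pd.DataFrame({"r1": [42]}, index=["a"]),
            pd.DataFrame({"library": [1], "well": [1]}, index=["r1"]))
        assert normalize_counts(m)["r1"].iloc[0] == pytest.approx(1e6)

    def test_column_sums_conserved(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 1000, size=(50, 8)),
                              index=[f"c{i}" for i in range(50)],
                              columns=[f"r{j}" for j in range(8)])
        m = BarcodeCountMatrix("RNA", counts,
                               pd.DataFrame({"library": 1, "well": range(8)},
                                            index=counts.columns))
        sums = normalize_counts(m).sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-9)

    def test_zero_total_replicate_flagged(self):
        m = BarcodeCountMatrix(
            "DNA", pd.DataFrame({"r1": [10], "r2": [0]}, index=["a"]),
            pd.DataFrame({"library": [1, 1], "well": [1, 2]}, index=["r1", "r2"]))
        with pytest.warns(UserWarning, match="zero total"):
            norm = normalize_counts(m)
        assert np.isnan(norm["r2"]).all()


class TestActivityRatio:
    def test_ratio_and_zero_dna_cell(self):
        idx = ["WT", "mut"]
        rna = pd.DataFrame({"r1": [200.0, 300.0]}, index=idx)
        dna = pd.DataFrame({"r1": [100.0, 0.0]}, index=idx)
        act = activity_ratio(rna, dna)
        assert act.ratio.loc["WT", "r1"] == pytest.approx(2.0)
        assert not act.included.loc["mut", "r1"]
        assert act.reasons.loc["mut", "r1"] == mpra.REASON_ZERO_DNA

    def test_key_mismatch_rejected(self):
        rna = pd.DataFrame({"r1": [1.0]}, index=["a"])
        dna = pd.DataFrame({"r1": [1.0]}, index=["b"])
        with pytest.raises(ValueError):
            activity_ratio(rna, dna)


class TestQcFilter:
    def test_low_dna_boundary_is_strict(self):
        ratio = pd.DataFrame({"r1": [1.0, 1.0], "r2": [1.0, 1.0]},
                             index=["WT", "m"])
        dna = pd.DataFrame({"r1": [500.0, 99.9], "r2": [500.0, 100.0]},
                           index=["WT", "m"])
        act = make_activity_table(ratio, dna)
        out, report = qc_filter(act)
        assert not out.included.loc["m", "r1"]          # 99.9 < 100 excluded
        assert out.included.loc["m", "r2"]              # 100.0 retained
        assert report["n_low_dna"] == 1

    def test_wt_outlier_replicate_dropped(self):
        # WT activities [1, 1, 1, 2]: mean 1.25, SD 0.5, |2 - 1.25| >= 0.5
        ratio = pd.DataFrame([[1.0, 1.0, 1.0, 2.0], [0.5, 0.5, 0.5, 0.5]],
                             index=["WT", "m"],
                             columns=["r1", "r2", "r3", "r4"])
        act = make_activity_table(ratio)
        out, report = qc_filter(act)
        assert report["excluded_replicates"] == ["r4"]
        assert not out.included["r4"].any()
        assert out.included[["r1", "r2", "r3"]].all().all()
        assert (out.reasons.loc["m", "r4"] == mpra.REASON_WT_REPLICATE)

    def test_equal_wt_activities_keep_all(self):
        ratio = pd.DataFrame([[1.0, 1.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0]],
                             index=["WT", "m"],
                             columns=["r1", "r2", "r3", "r4"])
        out, report = qc_filter(make_activity_table(ratio))
        assert out.included.all().all()
        assert report["n_wt_replicate_excluded"] == 0

    def test_wt_rule_is_within_library(self):
        # same WT pattern in two libraries; outlier well dropped in each
        ratio = pd.DataFrame([[1.0, 1.0, 1.0, 2.0] * 2, [1.0] * 8],
                             index=["WT", "m"],
                             columns=[f"r{i}" for i in range(8)])
        out, report = qc_filter(make_activity_table(ratio, n_libraries=2))
        assert report["excluded_replicates"] == ["r3", "r7"]

    def test_no_wt_survivors_aborts(self):
        ratio = pd.DataFrame({"r1": [1.0, 1.0]}, index=["WT", "m"])
        dna = pd.DataFrame({"r1": [10.0, 500.0]}, index=["WT", "m"])
        with pytest.raises(ValueError, match="WT"):
            qc_filter(make_activity_table(ratio, dna))

    def test_filter_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        ratio = pd.DataFrame(rng.uniform(0.5, 1.5, (20, 4)),
                             index=[f"c{i}" for i in range(19)] + ["WT"],
                             columns=["r1", "r2", "r3", "r4"])
        dna = pd.DataFrame(rng.uniform(0, 400, (20, 4)), index=ratio.index,
                           columns=ratio.columns)
        dna.loc["WT"] = 500.0
        act = make_activity_table(ratio, dna)
        loose, _ = qc_filter(act, min_norm_count=50)
        strict, _ = qc_filter(act, min_norm_count=150)
        assert (loose.included | ~strict.included).all().all()


class TestMutagenesisScan:
    DESIGN = [
        ConstructDesign("WT", "wt"),
        ConstructDesign("d1", "tf_deletion", (10, 15), "m1"),
        ConstructDesign("d2", "tf_deletion", (14, 20), "m2"),
        ConstructDesign("p1", "point_mutation", (12, 12), "m1"),
    ]

    def table(self, vals):
        ratio = pd.DataFrame({"r1": vals, "r2": vals},
                             index=["WT", "d1", "d2", "p1"], dtype=float)
        return make_activity_table(ratio)

    def test_profile_values_and_tracks(self):
        act = self.table([1.0, 0.4, 0.8, 0.4])
        prof = mutagenesis_scan(act, self.DESIGN)
        dele = prof[prof["track"] == "deletion"].set_index("position")
        assert sorted(dele.index) == list(range(10, 21))
        assert dele.loc[10, "mean_activity"] == pytest.approx(0.4)
        # overlap of d1 (0.4) and d2 (0.8) on 14-15 -> mean 0.6
        assert dele.loc[14, "mean_activity"] == pytest.approx(0.6)
        assert dele.loc[18, "mean_activity"] == pytest.approx(0.8)
        pm = prof[prof["track"] == "point_mutation"].set_index("position")
        assert list(pm.index) == [12]
        assert pm.loc[12, "mean_activity"] == pytest.approx(0.4)

    def test_uncovered_positions_are_gaps(self):
        prof = mutagenesis_scan(self.table([1.0, 0.4, 0.8, 0.4]), self.DESIGN)
        assert 9 not in set(prof["position"])
        assert 21 not in set(prof["position"])

    def test_wt_only_empty_profile(self):
        act = make_activity_table(pd.DataFrame({"r1": [1.0]}, index=["WT"]))
        prof = mutagenesis_scan(act, [ConstructDesign("WT", "wt")])
        assert prof.empty

    def test_matches_per_position_enumeration(self):
        rng = np.random.default_rng(9)
        design = [ConstructDesign("WT", "wt")]
        for i in range(15):
            s = int(rng.integers(1, 90))
            design.append(ConstructDesign(
                f"d{i}", "tf_deletion", (s, s + int(rng.integers(0, 12))), ""))
        vals = rng.uniform(0.2, 1.5, len(design))
        ratio = pd.DataFrame({"r1": vals},
                             index=[c.construct_id for c in design])
        act = make_activity_table(ratio)
        prof = mutagenesis_scan(act, design).set_index("position")
        for pos in range(1, 110):
            covering = [c for c in design if c.mutated_interval
                        and c.mutated_interval[0] <= pos <= c.mutated_interval[1]]
            if not covering:
                assert pos not in prof.index
            else:
                expected = np.mean([ratio.loc[c.construct_id, "r1"]
                                    for c in covering])
                assert prof.loc[pos, "mean_activity"] == pytest.approx(expected)


class TestVsWt:
    def test_group_identical_to_wt(self):
        ratio = pd.DataFrame([[1.0, 1.2, 0.8, 1.0]] * 2, index=["WT", "m"],
                             columns=["r1", "r2", "r3", "r4"])
        design = [ConstructDesign("WT", "wt"),
                  ConstructDesign("m", "tf_deletion", (1, 5), "")]
        out = compare_vs_wt(make_activity_table(ratio), design)
        assert out.loc[0, "t"] == pytest.approx(0.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)
        # single group: BH adjustment is the identity
        assert out.loc[0, "p_adj"] == pytest.approx(out.loc[0, "p"])

    def test_large_effect_is_significant_after_bh(self):
        rng = np.random.default_rng(21)
        wt = rng.normal(1.0, 0.05, 12)
        lo = rng.normal(0.4, 0.05, 12)
        ratio = pd.DataFrame(np.vstack([wt, lo]), index=["WT", "m"],
                             columns=[f"r{i}" for i in range(12)])
        design = [ConstructDesign("WT", "wt"),
                  ConstructDesign("m", "tf_deletion", (1, 5), "")]
        out = compare_vs_wt(make_activity_table(ratio), design)
        assert out.loc[0, "p_adj"] < 1e-6

    def test_motif_grouping_pools_constructs(self):
        ratio = pd.DataFrame(
            [[1.0, 1.1], [0.5, 0.6], [0.4, 0.5], [0.9, 1.0]],
            index=["WT", "a", "b", "c"], columns=["r1", "r2"])
        design = [ConstructDesign("WT", "wt"),
                  ConstructDesign("a", "tf_deletion", (1, 5), "mot1"),
                  ConstructDesign("b", "point_mutation", (3, 3), "mot1"),
                  ConstructDesign("c", "tf_deletion", (8, 12), "mot2")]
        out = compare_vs_wt(make_activity_table(ratio), design,
                         grouping="motif_label")
        assert set(out["group"]) == {"mot1", "mot2"}
        assert out.set_index("group").loc["mot1", "n"] == 4
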