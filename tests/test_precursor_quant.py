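"""Precursor identification, normalization and fold-change arithmetic."""

import numpy as np
import pandas as pd
import pytest

from pirnaterm import precursor_quant as pq
from pirnaterm.annotation_io import AlignedRead, PiRNALocus


@pytest.fixture
def locus():
    return PiRNALocus("p1", "chrIV", "+", 1000)  # tss at 998


class TestIdentifyPrecursors:
    def test_28mer_at_tss_is_precursor(self, locus):
        read = AlignedRead("chrIV", "+", 998, 1026)
        (rec,) = pq.identify_precursors([read], [locus])
        assert rec.locus_id == "p1" and rec.length == 28

    def test_read_at_u5_is_not_precursor(self, locus):
        # 5' end exactly 2 nt downstream of the TSS (at the 5'U) does not count
        read = AlignedRead("chrIV", "+", 1000, 1028)
        assert pq.identify_precursors([read], [locus]) == []

    def test_17mer_dropped(self, locus):
        read = AlignedRead("chrIV", "+", 998, 1015)
        assert pq.identify_precursors([read], [locus]) == []

    def test_shared_tss_is_annotation_error(self, locus):
        clash = PiRNALocus("p2", "chrIV", "+", 1000)
        with pytest.raises(ValueError, match="share TSS"):
            pq.identify_precursors([], [locus, clash])

    def test_multiplicity_split_invariance(self, locus):
        merged = [AlignedRead("chrIV", "+", 998, 1026, count=3)]
        split = [AlignedRead("chrIV", "+", 998, 1026, count=1)] * 3
        total = lambda recs: sum(r.count for r in recs)
        assert total(pq.identify_precursors(merged, [locus])) == total(
            pq.identify_precursors(split, [locus])
        )

    def test_order_invariance(self, locus):
        reads = [
            AlignedRead("chrIV", "+", 998, 998 + n, count=c)
            for n, c in [(28, 5), (48, 2), (30, 1)]
        ]
        fwd = pq.identify_precursors(reads, [locus])
        rev = pq.identify_precursors(reads[::-1], [locus])
        assert sorted((r.length, r.count) for r in fwd) == sorted((r.length, r.count) for r in rev)


class TestTssLibrarySize:
    def test_no_reads_at_tss(self):
        reads = [AlignedRead("c", "+", 50, 80)]
        assert pq.tss_library_size(reads, [("c", "+", 10)]) == 0

    def test_multiplicity_summed(self):
        reads = [AlignedRead("c", "+", 10, 40, count=2) for _ in range(3)]
        assert pq.tss_library_size(reads, [("c", "+", 10)]) == 6

    def test_membership_semantics(self):
        reads = [AlignedRead("c", "+", 10, 40), AlignedRead("c", "+", 20, 50)]
        assert pq.tss_library_size(reads, [("c", "+", 10)]) == 1
        assert pq.tss_library_size(reads, [("c", "+", 10), ("c", "+", 20)]) == 2

    def test_empty_tss_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pq.tss_library_size([], [])


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        table = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = pq.size_factors_median_of_ratios(table)
        assert sf["a"] == pytest.approx(0.7071, abs=1e-4)
        assert sf["b"] == pytest.approx(1.4142, abs=1e-4)

    def test_identical_samples_unit_factors(self):
        table = pd.DataFrame({"a": [5, 7, 9], "b": [5, 7, 9]})
        assert pq.size_factors_median_of_ratios(table).to_numpy() == pytest.approx([1.0, 1.0])

    def test_single_sample_unit_factor(self):
        table = pd.DataFrame({"a": [5, 7, 9]})
        assert pq.size_factors_median_of_ratios(table).tolist() == [1.0]

    def test_scalar_multiples_recovered(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 500, size=40)
        scalars = np.array([0.5, 1.0, 2.0, 4.0])
        table = pd.DataFrame(
            {f"s{i}": np.round(base * c).astype(int) for i, c in enumerate(scalars)}
        )
        sf = pq.size_factors_median_of_ratios(table).to_numpy()
        ratio = sf / scalars
        assert np.allclose(ratio, ratio[0], rtol=0.02)

    def test_no_common_nonzero_feature_errors(self):
        table = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(ValueError, match="nonzero"):
            pq.size_factors_median_of_ratios(table)


class TestFoldChanges:
    def _tables(self):
        a = pd.DataFrame({"a1": [10, 0, 4]}, index=["L1", "L2", "L3"])
        b = pd.DataFrame({"b1": [10, 15, 4]}, index=["L1", "L2", "L3"])
        sf = {"a1": 1.0, "b1": 1.0}
        return a, b, sf

    def test_equal_counts_give_zero(self):
        a, b, sf = self._tables()
        fc = pq.per_locus_log2fc(a, b, sf)
        assert fc["L1"] == 0.0

    def test_pseudocount_arithmetic(self):
        a, b, sf = self._tables()
        fc = pq.per_locus_log2fc(a, b, sf)
        assert fc["L2"] == pytest.approx(np.log2(16.0))

    def test_low_mean_locus_excluded(self):
        a, b, sf = self._tables()
        fc = pq.per_locus_log2fc(a, b, sf)
        assert "L3" not in fc.index

    def test_self_comparison_identically_zero(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame({"x": rng.integers(0, 100, 30)})
        fc = pq.per_locus_log2fc(a, a.rename(columns={"x": "y"}), {"x": 1.0, "y": 1.0})
        assert (fc == 0.0).all()

    def test_mismatched_features_error(self):
        a = pd.DataFrame({"a1": [1]}, index=["L1"])
        b = pd.DataFrame({"b1": [1]}, index=["L2"])
        with pytest.raises(ValueError, match="mismatched"):
            pq.per_locus_log2fc(a, b, {"a1": 1.0, "b1": 1.0})


class TestTotalAbundance:
    def test_identical_pairs_ratio_one(self):
        table = pd.DataFrame({"c1": [5, 5], "t1": [5, 5]})
        out = pq.total_abundance_relative(table, [("c1", "t1")])
        assert out["t1"] == 1.0

    def test_halved_treatment(self):
        table = pd.DataFrame({"c1": [10, 30], "t1": [5, 15]})
        out = pq.total_abundance_relative(table, [("c1", "t1")])
        assert out["t1"] == 0.5

    def test_unpaired_sample_errors(self):
        table = pd.DataFrame({"c1": [1]})
        with pytest.raises(ValueError, match="unpaired"):
            pq.total_abundance_relative(table, [("c1", "t1")])

    def test_ints11_vs_wildtype_total_below_one(self, config, loci):
        from pirnaterm import synthetic_data as sd

        recs_wt = pq.identify_precursors(
            sd.simulate_capped_reads(loci, config, "wild_type", "chromatin"),
            loci,
            sample_id="wt",
        )
        recs_kd = pq.identify_precursors(
            sd.simulate_capped_reads(loci, config, "ints11_kd", "chromatin"),
            loci,
            sample_id="kd",
        )
        table = pq.count_table(list(recs_wt) + list(recs_kd), loci)
        out = pq.total_abundance_relative(table, [("wt", "kd")])
        assert out["kd"] < 1.0


class TestNonstructuralTotal:
    def test_structural_overlaps_excluded(self):
        reads = [
            AlignedRead("c", "+", 0, 20, count=3),
            AlignedRead("c", "+", 100, 120, count=2),
        ]
        total = pq.nonstructural_total(reads, [("c", "+", 10, 15)])
        assert total == 2
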