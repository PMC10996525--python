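"""SV merging/filtering, variant assignment, folded spectra and their comparison."""

import numpy as np
import pytest

from oracles import single_linkage_clusters
from tecompartment.compartmentalization import CompartmentCallSet
from tecompartment.io_formats import VariantRecord
from tecompartment.popgen import (
    FoldedAFS,
    assign_variants,
    compare_afs_chi2,
    filter_te_svs,
    folded_afs,
    merge_sv_calls,
)


def sv(vid, pos, vtype="TE_SV_INS", length=100, cov=0.9, sample=None, chrom="chr1", n=50):
    return VariantRecord(vid, chrom, pos, vtype, 1 if sample else 0, n,
                         length=length, te_coverage=cov, sample_id=sample)


class TestMerge:
    def test_nearby_same_type_calls_merge_with_sample_count(self):
        merged = merge_sv_calls([sv("a", 1000, sample="s1"), sv("b", 1300, sample="s2")])
        assert len(merged) == 1
        assert merged[0].alt_count == 2
        assert merged[0].pos == 1000  # leftmost representative

    def test_insertion_and_deletion_never_merge(self):
        merged = merge_sv_calls(
            [sv("a", 1000, "TE_SV_INS", sample="s1"), sv("b", 1000, "TE_SV_DEL", sample="s2")]
        )
        assert len(merged) == 2

    def test_single_linkage_chains_transitively(self):
        # a-b within 500, b-c within 500, a-c at 900: one cluster of three
        calls = [sv("a", 0, sample="s1"), sv("b", 450, sample="s2"), sv("c", 900, sample="s3")]
        merged = merge_sv_calls(calls)
        assert len(merged) == 1 and merged[0].alt_count == 3

    def test_both_breakpoints_must_be_near(self):
        # deletions share start proximity but ends differ by > 500
        a = sv("a", 1000, "TE_SV_DEL", length=100, sample="s1")
        b = sv("b", 1100, "TE_SV_DEL", length=2000, sample="s2")
        assert len(merge_sv_calls([a, b])) == 2

    def test_matches_exhaustive_clustering_oracle(self, rng):
        for _ in range(150):
            n = int(rng.integers(1, 12))
            calls = [
                sv(f"v{i}", int(rng.integers(0, 3000)), "TE_SV_DEL",
                   length=int(rng.integers(60, 1500)), sample=f"s{i}")
                for i in range(n)
            ]
            merged = merge_sv_calls(calls)
            linked = lambda x, y: abs(x.pos - y.pos) <= 500 and abs(x.end - y.end) <= 500
            clusters = single_linkage_clusters(calls, linked)
            assert len(merged) == len(clusters)
            expect_counts = sorted(len(c) for c in clusters)
            assert sorted(v.alt_count for v in merged) == expect_counts


class TestFilter:
    @pytest.mark.parametrize(
        "length,cov,kept",
        [(49, 0.9, False), (50, 0.9, False), (51, 0.9, True),
         (200, 0.50, True), (200, 0.49, False), (5000, 1.0, True)],
    )
    def test_length_strict_coverage_inclusive(self, length, cov, kept):
        out = filter_te_svs([sv("a", 100, length=length, cov=cov)])
        assert (len(out) == 1) is kept

    def test_toy_callset_exact_survivors(self, rng):
        lengths = [20, 49, 50, 51, 80, 120, 300, 45, 600, 1000,
                   70, 55, 52, 30, 49, 500, 51, 50, 200, 90]
        covs = [0.9, 0.9, 0.9, 0.9, 0.4, 0.5, 0.49, 0.8, 0.51, 1.0,
                0.5, 0.3, 0.5, 0.9, 0.5, 0.95, 0.49, 0.5, 0.5, 0.7]
        calls = [sv(f"v{i}", 100 * i, length=l, cov=c) for i, (l, c) in enumerate(zip(lengths, covs))]
        survivors = filter_te_svs(calls)
        expect = {f"v{i}" for i, (l, c) in enumerate(zip(lengths, covs)) if l > 50 and c >= 0.5}
        assert {v.variant_id for v in survivors} == expect
        assert len(survivors) == 9

    def test_ambiguous_sequence_dropped_first(self):
        v = sv("a", 100, length=200, cov=0.9)
        v.ambiguous = True
        assert filter_te_svs([v]) == []

    def test_missing_coverage_is_hard_error(self):
        v = VariantRecord("a", "chr1", 100, "TE_SV_INS", 0, 50, length=100)
        with pytest.raises(ValueError):
            filter_te_svs([v])


class TestAssignment:
    def setup_method(self):
        self.flanks = {"gc": [(0, 1000)], "go": [(2000, 3000)], "go2": [(2500, 3500)]}
        self.cds = {"gc": [(1200, 1400)], "go": [(4000, 4200)]}
        self.calls = CompartmentCallSet("sp", "ALL", 90, 0.1, {"gc"}, {"go", "go2"})
        self.chrom_of = {"gc": "chr1", "go": "chr1", "go2": "chr1"}

    def assign(self, variants):
        return assign_variants(variants, self.flanks, self.cds, self.calls, self.chrom_of)

    def test_te_sv_in_called_flank(self):
        out = self.assign([sv("a", 500)])
        assert out["a"] == ("called", "flank")

    def test_snv_in_other_cds(self):
        v = VariantRecord("s", "chr1", 4100, "SNV_SYN", 3, 50)
        assert self.assign([v])["s"] == ("other", "cds")

    def test_called_priority_on_overlapping_flanks(self):
        self.flanks["go"] = [(500, 1500)]  # overlaps called gene's flank
        assert self.assign([sv("a", 700)])["a"] == ("called", "flank")

    def test_unassigned_variants_dropped_and_partition_holds(self):
        vs = [sv("a", 500), sv("b", 99_999), VariantRecord("c", "chr1", 1300, "SNV_SYN", 1, 50)]
        out = self.assign(vs)
        assert set(out) == {"a", "c"}
        assert len(out) == len(set(out))  # one cell per retained variant


class TestFoldedAFS:
    def test_fold_arithmetic(self):
        vs = [VariantRecord(f"v{i}", "chr1", i, "SNV_SYN", c, 4) for i, c in enumerate([1, 3, 2])]
        afs = folded_afs(vs, 4)
        assert list(afs.bins) == [2, 1]

    def test_empty_input_zero_bins(self):
        afs = folded_afs([], 50)
        assert afs.bins.sum() == 0 and len(afs.bins) == 25

    def test_half_n_boundary(self):
        v = VariantRecord("v", "chr1", 0, "SNV_SYN", 25, 50)
        afs = folded_afs([v], 50)
        assert afs.bins[24] == 1

    def test_monomorphic_excluded(self):
        vs = [
            VariantRecord("v0", "chr1", 0, "SNV_SYN", 0, 10),
            VariantRecord("v1", "chr1", 1, "SNV_SYN", 10, 10),
            VariantRecord("v2", "chr1", 2, "SNV_SYN", 4, 10),
        ]
        assert folded_afs(vs, 10).n_variants == 1

    def test_folding_is_involutive(self, rng):
        n = 50
        counts = rng.integers(1, n, size=200)
        vs = [VariantRecord(f"v{i}", "chr1", i, "SNV_SYN", int(c), n) for i, c in enumerate(counts)]
        once = folded_afs(vs, n)
        refolded_counts = [min(int(c), n - int(c)) for c in counts]
        vs2 = [VariantRecord(f"w{i}", "chr1", i, "SNV_SYN", c, n) for i, c in enumerate(refolded_counts)]
        assert np.array_equal(folded_afs(vs2, n).bins, once.bins)


class TestAfsComparison:
    def test_identical_spectra_chi2_zero_p_one(self):
        bins = np.array([100, 60, 40, 30, 20] + [10] * 20)
        a, b = FoldedAFS(50, bins), FoldedAFS(50, bins.copy())
        chi2, df, p = compare_afs_chi2(a, b)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_bin_totals_conserved_through_pooling(self):
        rngl = np.random.default_rng(4)
        a = FoldedAFS(50, rngl.integers(0, 30, size=25))
        b = FoldedAFS(50, rngl.integers(0, 30, size=25))
        chi2, df, p = compare_afs_chi2(a, b)
        assert df < 25  # pooling happened but the test still ran
        assert 0 <= p <= 1

    def test_different_sample_sizes_rejected(self):
        with pytest.raises(ValueError):
            compare_afs_chi2(FoldedAFS(50, np.ones(25)), FoldedAFS(40, np.ones(20)))

    def test_too_few_variants_is_error(self):
        a = FoldedAFS(50, np.zeros(25, dtype=int))
        b = FoldedAFS(50, np.ones(25, dtype=int))
        with pytest.raises(ValueError):
            compare_afs_chi2(a, b)

    def test_strong_skew_detected(self):
        rngl = np.random.default_rng(9)
        i = np.arange(1, 50)
        p_neutral = (1 / i) / (1 / i).sum()
        neutral = rngl.choice(i, size=500, p=p_neutral)
        skewed = np.where(rngl.random(500) < 0.5, rngl.integers(26, 50, size=500), neutral)
        def make(counts):
            minor = np.minimum(counts, 50 - counts)
            return FoldedAFS(50, np.bincount(minor, minlength=26)[1:])
        chi2, df, p = compare_afs_chi2(make(skewed), make(neutral))
        assert p < 0.01
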