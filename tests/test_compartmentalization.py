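"""Flank extraction, overlap resolution, TE coverage and percentile calls."""

import numpy as np
import pytest

from oracles import (
    brute_force_coverage,
    brute_force_noncoding_flanks,
    brute_force_resolve,
    percentile_linear,
)
from tecompartment.compartmentalization import (
    FlankProfile,
    RepeatCoverage,
    call_compartmentalized,
    compute_te_density,
    extract_noncoding_flanks,
    resolve_repeat_overlaps,
)
from tecompartment.io_formats import GeneRecord, RepeatRecord


def make_gene(start, end, cds=None, gene_id="g", chrom="chr1"):
    return GeneRecord(gene_id, chrom, start, end, "+", cds or [])


class TestFlankExtraction:
    def test_full_50kb_flanks_when_nothing_interferes(self):
        g = make_gene(100_000, 101_000)
        flanks = extract_noncoding_flanks(g, {}, 50_000, 1_000_000)
        assert flanks == [(50_000, 100_000), (101_000, 151_000)]
        assert sum(e - s for s, e in flanks) == 100_000

    def test_chromosome_start_truncates_left_flank(self):
        g = make_gene(0, 1000)
        flanks = extract_noncoding_flanks(g, {}, 50_000, 1_000_000)
        assert flanks == [(1000, 51_000)]

    def test_neighbor_cds_is_subtracted(self):
        g = make_gene(100_000, 101_000)
        cds = {"chr1": [(99_000, 100_000)]}
        flanks = extract_noncoding_flanks(g, cds, 50_000, 1_000_000)
        assert flanks == [(50_000, 99_000), (101_000, 151_000)]

    def test_matches_per_base_oracle_on_random_instances(self, rng):
        for _ in range(200):
            chrom_len = int(rng.integers(500, 10_000))
            start = int(rng.integers(0, chrom_len - 10))
            end = int(start + rng.integers(5, min(400, chrom_len - start)))
            n_cds = int(rng.integers(0, 6))
            cds = []
            for _ in range(n_cds):
                s = int(rng.integers(0, chrom_len - 1))
                cds.append((s, min(chrom_len, s + int(rng.integers(1, 300)))))
            flank = int(rng.integers(1, 2000))
            got = extract_noncoding_flanks(
                make_gene(start, end), {"chr1": cds}, flank, chrom_len
            )
            assert got == brute_force_noncoding_flanks(start, end, cds, flank, chrom_len)


class TestOverlapResolution:
    def r(self, start, end, score, chrom="chr1"):
        return RepeatRecord(chrom, start, end, "LINE", score=score)

    def test_higher_score_survives_intact(self):
        kept = resolve_repeat_overlaps([self.r(10, 30, 250), self.r(20, 40, 100)])
        assert [(k.start, k.end) for k in kept] == [(10, 30)]

    def test_non_overlapping_unchanged(self):
        rs = [self.r(0, 10, 1), self.r(20, 30, 2)]
        assert resolve_repeat_overlaps(rs) == rs

    def test_chain_keeps_ends(self):
        # A(3) overlaps B(2) overlaps C(1), but A and C are disjoint
        a, b, c = self.r(0, 15, 3), self.r(10, 25, 2), self.r(20, 35, 1)
        kept = resolve_repeat_overlaps([a, b, c])
        assert [(k.start, k.end) for k in kept] == [(0, 15), (20, 35)]

    def test_matches_greedy_oracle_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 12))
            recs = []
            for _ in range(n):
                s = int(rng.integers(0, 200))
                recs.append(self.r(s, s + int(rng.integers(1, 50)), float(rng.integers(1, 1000))))
            got = [(k.start, k.end, k.score) for k in resolve_repeat_overlaps(recs)]
            assert got == brute_force_resolve([(r.start, r.end, r.score) for r in recs])


class TestCoverage:
    def test_two_repeats_in_flank(self):
        cov = RepeatCoverage(
            [RepeatRecord("chr1", 10, 20, "LINE"), RepeatRecord("chr1", 50, 80, "LTR")]
        )
        prof = compute_te_density("g", "chr1", [(0, 100)], cov)
        assert prof.te_covered_len["ALL"] == 40
        assert prof.density["ALL"] == pytest.approx(0.4)
        assert prof.density["LINE"] == pytest.approx(0.1)

    def test_no_repeats_density_zero(self):
        prof = compute_te_density("g", "chr1", [(0, 100)], RepeatCoverage([]))
        assert prof.density["ALL"] == 0.0

    def test_repeat_clipped_at_flank_edge(self):
        cov = RepeatCoverage([RepeatRecord("chr1", 90, 200, "DNA")])
        prof = compute_te_density("g", "chr1", [(0, 100)], cov)
        assert prof.te_covered_len["ALL"] == 10

    def test_simple_repeats_do_not_count(self):
        cov = RepeatCoverage([RepeatRecord("chr1", 0, 50, "Simple")])
        prof = compute_te_density("g", "chr1", [(0, 100)], cov)
        assert prof.te_covered_len["ALL"] == 0

    def test_unresolved_overlapping_input_is_hard_error(self):
        with pytest.raises(ValueError, match="resolve"):
            RepeatCoverage(
                [RepeatRecord("chr1", 0, 30, "LINE"), RepeatRecord("chr1", 20, 50, "LINE")]
            )

    def test_matches_per_base_oracle_and_classes_sum_to_all(self, rng):
        classes = ["LINE", "SINE", "LTR", "DNA", "Other"]
        for _ in range(200):
            chrom_len = int(rng.integers(200, 10_000))
            raw = []
            for _ in range(int(rng.integers(0, 10))):
                s = int(rng.integers(0, chrom_len - 1))
                raw.append(
                    RepeatRecord(
                        "chr1", s, min(chrom_len, s + int(rng.integers(1, 200))),
                        classes[int(rng.integers(len(classes)))],
                        score=float(rng.integers(1, 100)),
                    )
                )
            resolved = resolve_repeat_overlaps(raw)
            flanks = []
            for _ in range(int(rng.integers(1, 4))):
                s = int(rng.integers(0, chrom_len - 1))
                flanks.append((s, min(chrom_len, s + int(rng.integers(1, 500)))))
            from tecompartment.intervals import merge_intervals

            flanks = merge_intervals(flanks)
            prof = compute_te_density("g", "chr1", flanks, RepeatCoverage(resolved))
            expect = brute_force_coverage(
                flanks, [(r.start, r.end) for r in resolved], chrom_len
            )
            assert prof.te_covered_len["ALL"] == expect
            # resolved classes are disjoint, so per-class coverage sums exactly
            assert sum(prof.te_covered_len[c] for c in classes) == prof.te_covered_len["ALL"]


def profiles_from_densities(densities, noncoding=10_000):
    return [
        FlankProfile(
            gene_id=f"g{i}",
            flank_intervals=[(0, noncoding)],
            noncoding_len=noncoding,
            te_covered_len={"ALL": int(d * noncoding)},
            density={"ALL": d},
        )
        for i, d in enumerate(densities)
    ]


class TestPercentileCalls:
    def test_ten_distinct_densities_call_exactly_the_top_gene(self):
        profiles = profiles_from_densities([i / 100 for i in range(1, 11)])
        calls = call_compartmentalized(profiles, "ALL", 90)
        assert calls.called_gene_ids == {"g9"}
        assert calls.cutoff_value == pytest.approx(percentile_linear([i / 100 for i in range(1, 11)], 90))

    def test_hundred_distinct_densities_at_95_call_five(self):
        densities = list(np.linspace(0.01, 0.99, 100))
        calls = call_compartmentalized(profiles_from_densities(densities), "ALL", 95)
        assert len(calls.called_gene_ids) == 5

    def test_all_equal_densities_saturate(self):
        calls = call_compartmentalized(profiles_from_densities([0.3] * 20), "ALL", 90)
        assert len(calls.called_gene_ids) == 20
        assert calls.background_gene_ids == set()

    def test_called_and_background_partition_eligible(self):
        densities = list(np.linspace(0, 0.5, 50))
        calls = call_compartmentalized(profiles_from_densities(densities), "ALL", 90)
        assert not calls.called_gene_ids & calls.background_gene_ids
        assert len(calls.called_gene_ids | calls.background_gene_ids) == 50

    def test_zero_noncoding_genes_are_ineligible(self):
        profiles = profiles_from_densities(list(np.linspace(0.01, 0.5, 12)))
        dead = FlankProfile("dead", [], 0, {"ALL": 0}, {})
        calls = call_compartmentalized(profiles + [dead], "ALL", 90)
        assert "dead" not in calls.called_gene_ids | calls.background_gene_ids

    def test_fewer_than_ten_eligible_is_hard_error(self):
        with pytest.raises(ValueError, match="percentile"):
            call_compartmentalized(profiles_from_densities([0.1] * 9), "ALL", 90)
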