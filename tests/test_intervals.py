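"""Interval arithmetic: consensus, merging, overlap counting, annotation."""

import numpy as np
import pandas as pd
import pytest

from cryptic_cre.intervals import (
    GenomicInterval,
    RegionSet,
    annotate_regions,
    consensus_peaks,
    intersect_footprint,
    merge_within,
    overlap_counts,
)

from conftest import brute_force_overlap, make_regions


class TestGenomicInterval:
    def test_rejects_inverted_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 10)

    def test_summit_must_lie_inside(self):
        GenomicInterval("chr1", 0, 100, summit=99)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 100, summit=100)

    def test_duplicate_names_rejected(self):
        df = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 50], "end": [10, 60],
             "name": ["a", "a"]}
        )
        with pytest.raises(ValueError):
            RegionSet(df)


class TestConsensusPeaks:
    def test_identical_replicates_return_merged_input(self):
        reps = [make_regions([("chr1", 100, 200), ("chr1", 400, 500)]) for _ in range(3)]
        out = consensus_peaks(reps, min_support=2)
        assert out.df[["chrom", "start", "end"]].values.tolist() == [
            ["chr1", 100, 200],
            ["chr1", 400, 500],
        ]

    def test_singleton_peak_absent(self):
        reps = [
            make_regions([("chr1", 100, 200)]),
            make_regions([("chr1", 100, 200)]),
            make_regions([("chr1", 100, 200), ("chr2", 0, 50)]),
        ]
        out = consensus_peaks(reps, min_support=2)
        assert "chr2" not in set(out.df["chrom"])

    def test_union_footprint_of_supporting_peaks(self):
        # A:[100,200) B:[150,250) C:[400,500): per-bp support >=2 on
        # [150,200) only, but the output extends to the union footprint
        # of the supporting peaks A and B -> [100,250)
        reps = [
            make_regions([("chr1", 100, 200)]),
            make_regions([("chr1", 150, 250)]),
            make_regions([("chr1", 400, 500)]),
        ]
        out = consensus_peaks(reps, min_support=2)
        assert out.df[["start", "end"]].values.tolist() == [[100, 250]]

    def test_min_support_exceeding_sets_is_an_error(self):
        with pytest.raises(ValueError):
            consensus_peaks([make_regions([("chr1", 0, 10)])], min_support=2)

    def test_min_support_one_equals_merged_union(self):
        rng = np.random.default_rng(0)
        reps = []
        for _ in range(3):
            starts = np.sort(rng.integers(0, 10_000, size=30))
            reps.append(
                make_regions([("chr1", int(s), int(s + rng.integers(10, 400))) for s in starts])
            )
        out = consensus_peaks(reps, min_support=1)
        pooled = RegionSet(pd.concat([r.df for r in reps], ignore_index=True))
        merged = merge_within(pooled, gap=0)
        # merged union uses strict-overlap merge; bookended intervals merge
        # in both, so compare covered-bp footprints
        assert out.total_bp() == intersect_footprint(out, merged).total_bp()
        assert merged.total_bp() == intersect_footprint(out, merged).total_bp()


class TestMergeWithin:
    def test_gap_boundary_is_inclusive(self):
        out = merge_within(make_regions([("chr1", 0, 100), ("chr1", 600, 700)]), gap=500)
        assert out.df[["start", "end"]].values.tolist() == [[0, 700]]

    def test_gap_just_over_boundary_not_merged(self):
        out = merge_within(make_regions([("chr1", 0, 100), ("chr1", 601, 700)]), gap=500)
        assert len(out) == 2

    def test_transitive_chain_collapses(self):
        # five 100 bp intervals spaced 400 bp apart merge transitively
        ivs = [("chr1", i * 500, i * 500 + 100) for i in range(5)]
        out = merge_within(make_regions(ivs), gap=500)
        assert out.df[["start", "end"]].values.tolist() == [[0, 2100]]

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_within(make_regions([("chr1", 0, 10)]), gap=-1)

    def test_idempotent_and_coverage_monotone(self):
        rng = np.random.default_rng(1)
        starts = np.sort(rng.integers(0, 50_000, size=200))
        s = make_regions(
            [("chr1", int(a), int(a + rng.integers(5, 600))) for a in starts]
        )
        once = merge_within(s, gap=500)
        twice = merge_within(once, gap=500)
        assert once.df[["start", "end"]].values.tolist() == twice.df[
            ["start", "end"]
        ].values.tolist()
        # covered bp never decreases relative to the strict-overlap merge
        assert once.total_bp() >= merge_within(s, gap=0).total_bp()


class TestOverlapCounts:
    def test_empty_subject(self):
        q = make_regions([("chr1", 0, 100), ("chr1", 200, 300)])
        assert overlap_counts(q, make_regions([])) == (0, 2)

    def test_size_filter_drops_small_subjects(self):
        q = make_regions([("chr1", 0, 100)])
        s = make_regions([("chr1", 50, 60)])
        assert overlap_counts(q, s, min_subject_size=500) == (0, 1)
        assert overlap_counts(q, s) == (1, 1)

    def test_hand_placed_seven_of_twenty(self):
        queries = make_regions([("chr1", i * 1000, i * 1000 + 200) for i in range(20)])
        # subjects hitting queries 0..6 only
        subjects = make_regions([("chr1", i * 1000 + 100, i * 1000 + 150) for i in range(7)])
        assert overlap_counts(queries, subjects) == (7, 20)

    def test_each_query_counted_once(self):
        q = make_regions([("chr1", 0, 1000)])
        s = make_regions([("chr1", i * 100, i * 100 + 50) for i in range(10)])
        assert overlap_counts(q, s) == (1, 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        def random_set(n):
            rows = []
            for _ in range(n):
                chrom = f"chr{rng.integers(1, 3)}"
                s = int(rng.integers(0, 100_000))
                rows.append((chrom, s, s + int(rng.integers(1, 2000))))
            return make_regions(rows)

        q, s = random_set(300), random_set(300)
        for min_size in (0, 500):
            assert overlap_counts(q, s, min_size) == brute_force_overlap(q, s, min_size)


class TestAnnotateRegions:
    @pytest.fixture()
    def toy_genes(self):
        return pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chrom": ["chr1", "chr1"],
                "start": [10_000, 23_000],
                "end": [20_000, 30_000],
                "strand": ["+", "+"],
                "tss": [10_000, 23_000],
                "exon_starts": ["10000,18000", "23000,28000"],
                "exon_ends": ["11000,20000", "24000,30000"],
                "biotype": ["protein_coding", "protein_coding"],
            }
        )

    def test_upstream_promoter(self, toy_genes):
        r = make_regions([("chr1", 8400, 8600)])  # midpoint 8500, 1.5 kb from TSS
        assert annotate_regions(r, toy_genes).tolist() == ["promoter"]

    def test_promoter_priority_over_intron(self, toy_genes):
        # midpoint 21500 in no gene; make one inside gA's intron and within
        # 2 kb of gB's TSS: 12000..16999 is gA intron; gB TSS at 23000 ->
        # region midpoint 21500 is intergenic but within 2 kb of gB TSS
        r = make_regions([("chr1", 21_400, 21_600)])
        assert annotate_regions(r, toy_genes).tolist() == ["promoter"]
        # inside gA intron AND within 2 kb of a TSS is promoter by priority
        r2 = make_regions([("chr1", 15_000, 15_200)])  # pure intron
        assert annotate_regions(r2, toy_genes).tolist() == ["intron"]

    def test_exon_and_utr_classes(self, toy_genes):
        utr5 = make_regions([("chr1", 10_050, 10_150)])  # first 200 bp of exon 1... but promoter wins
        assert annotate_regions(utr5, toy_genes).tolist() == ["promoter"]
        exon = make_regions([("chr1", 18_500, 18_700)])  # exon 2 of gA, >2 kb from TSSs
        assert annotate_regions(exon, toy_genes).tolist() == ["exon"]
        utr3 = make_regions([("chr1", 19_800, 19_990)])  # last 300 bp of gA
        assert annotate_regions(utr3, toy_genes).tolist() == ["3'UTR"]

    def test_gene_free_chromosome_is_distal_with_warning(self, toy_genes):
        r = make_regions([("chr9", 0, 100)])
        with pytest.warns(UserWarning):
            assert annotate_regions(r, toy_genes).tolist() == ["distal intergenic"]


class TestIntersectFootprint:
    def test_piecewise_intersection(self):
        a = make_regions([("chr1", 0, 100), ("chr1", 200, 300)])
        b = make_regions([("chr1", 50, 250)])
        out = intersect_footprint(a, b)
        assert out.df[["start", "end"]].values.tolist() == [[50, 100], [200, 250]]
        assert out.total_bp() == 100
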