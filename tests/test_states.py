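"""Chromatin-state procedures: clustering, bivalent calls, spreading, strata."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cryptic_cre.states import (
    call_bivalent_promoters,
    classify_erv_groups,
    kmeans_cluster_regions,
    spreading_analysis,
    stratify_enhancers,
)
from cryptic_cre.synth import mean_track, simulate_tracks
from cryptic_cre.tracks import BinnedTrack, SignalMatrix, signal_matrix

from conftest import make_regions


def mat(values, ids=None):
    v = np.asarray(values, dtype=float)
    return SignalMatrix(v, ids or [f"r{i}" for i in range(len(v))], 250, 5000)


class TestKmeansClusterRegions:
    def test_two_loss_classes_recovered(self):
        rng = np.random.default_rng(0)
        n = 150
        ctrl = rng.normal(8, 0.5, size=(2 * n, 40))
        mut = np.vstack(
            [rng.normal(0.5, 0.3, size=(n, 40)), rng.normal(4, 0.5, size=(n, 40))]
        )
        out = kmeans_cluster_regions(mat(ctrl), mat(mut), seed=0)
        truth = ["Cluster1"] * n + ["Cluster2"] * n
        agree = (out["label"].to_numpy() == np.array(truth)).mean()
        assert agree > 0.95
        # naming rule: Cluster1 always the lower mutant/control ratio
        r1 = out.loc[out["label"] == "Cluster1", "ratio"].mean()
        r2 = out.loc[out["label"] == "Cluster2", "ratio"].mean()
        assert r1 < r2

    def test_six_points_match_exhaustive_best_partition(self):
        pts = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [9.0]])
        out = kmeans_cluster_regions(mat(pts), mat(pts), restarts=20, seed=1)
        labels = out["label"].to_numpy()

        def wss(split):
            total = 0.0
            for grp in (pts[list(split)], pts[[i for i in range(6) if i not in split]]):
                if len(grp):
                    total += ((grp - grp.mean(axis=0)) ** 2).sum()
            return total

        best = min(
            (
                frozenset(c)
                for k in range(1, 6)
                for c in itertools.combinations(range(6), k)
            ),
            key=wss,
        )
        got = frozenset(np.flatnonzero(labels == labels[0]))
        assert got in (best, frozenset(range(6)) - best)

    def test_identical_rows_report_degeneracy(self):
        x = np.ones((5, 10))
        with pytest.warns(UserWarning):
            out = kmeans_cluster_regions(mat(x), mat(x), seed=0)
        assert out.attrs["degenerate"]
        assert out["label"].nunique() == 1

    def test_k_exceeding_rows_rejected(self):
        x = np.ones((3, 4))
        with pytest.raises(ValueError):
            kmeans_cluster_regions(mat(x), mat(x), k=5)


class TestBivalentCalling:
    def make_gene_table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "chrom", "start", "end", "strand", "tss",
                     "exon_starts", "exon_ends", "biotype"],
        )

    def reps(self, intervals):
        return [make_regions(intervals) for _ in range(2)]

    def test_three_gene_walkthrough(self):
        # A: both marks at TSS + SUZ12; B: both marks, no SUZ12; C: K4me3 only
        genes = self.make_gene_table(
            [
                ("A", "chr1", 10_000, 14_000, "+", 10_000, "10000", "14000", "protein_coding"),
                ("B", "chr1", 30_000, 34_000, "+", 30_000, "30000", "34000", "protein_coding"),
                ("C", "chr1", 50_000, 54_000, "+", 50_000, "50000", "54000", "protein_coding"),
            ]
        )
        k4 = self.reps([("chr1", 9500, 10_500), ("chr1", 29_500, 30_500),
                        ("chr1", 49_500, 50_500)])
        k27 = self.reps([("chr1", 9400, 10_600), ("chr1", 29_400, 30_600)])
        suz = make_regions([("chr1", 9800, 10_200)], names=["suz1"])
        calls = call_bivalent_promoters(k4, k27, genes, prc2_peaks=suz)
        got = calls.set_index("gene_id")["bivalent"]
        assert got["A"] and not got["B"] and not got["C"]
        a = calls.set_index("gene_id").loc["A"]
        assert a["region_id"] is not None and a["prc2_id"] == "suz1"

    def test_no_k27me3_means_no_bivalent_genes(self):
        genes = self.make_gene_table(
            [("A", "chr1", 10_000, 14_000, "+", 10_000, "10000", "14000", "protein_coding")]
        )
        k4 = self.reps([("chr1", 9500, 10_500)])
        k27 = self.reps([])
        calls = call_bivalent_promoters(k4, k27, genes, prc2_peaks=make_regions([]))
        assert not calls["bivalent"].any()

    def test_marks_far_from_tss_do_not_call(self):
        genes = self.make_gene_table(
            [("A", "chr1", 10_000, 14_000, "+", 10_000, "10000", "14000", "protein_coding")]
        )
        k4 = self.reps([("chr1", 15_000, 16_000)])  # 5 kb away from TSS
        k27 = self.reps([("chr1", 15_000, 16_000)])
        calls = call_bivalent_promoters(
            k4, k27, genes, prc2_peaks=make_regions([("chr1", 15_000, 16_000)])
        )
        assert not calls["bivalent"].any()

    def test_missing_prc2_set_flags_unrefined(self):
        genes = self.make_gene_table(
            [("A", "chr1", 10_000, 14_000, "+", 10_000, "10000", "14000", "protein_coding")]
        )
        k4 = self.reps([("chr1", 9500, 10_500)])
        k27 = self.reps([("chr1", 9500, 10_500)])
        with pytest.warns(UserWarning):
            calls = call_bivalent_promoters(k4, k27, genes, prc2_peaks=None)
        assert calls["bivalent"].all()
        assert not calls["refined"].any()


class TestSpreadingAnalysis:
    def test_identical_tracks_give_unit_ratios(self):
        t = BinnedTrack(250, {"chr1": np.full(200, 2.0)})
        suz = make_regions([("chr1", 10_000, 12_000)], names=["p1"])
        summ = spreading_analysis(suz, {"control": [t], "K27A": [t]})
        assert all(v == pytest.approx(1.0) for v in summ.zone_ratios.values())

    def test_noise_free_recovery_is_exact(self, default_truth):
        cfg = default_truth.config
        suz = default_truth.suz12_peaks()
        tracks = {
            g: [mean_track(default_truth, "H3K27me3", g)] for g in cfg.groups
        }
        summ = spreading_analysis(suz, tracks, flank=cfg.suz12_flank)
        assert summ.zone_ratios[("K27A", "within")] == pytest.approx(cfg.f_in, abs=1e-9)
        assert summ.flank_ratio("K27A") == pytest.approx(cfg.f_flank, abs=1e-9)
        # uniform loss in K9A: flank ratio equals within ratio
        assert summ.flank_ratio("K9A") == pytest.approx(
            summ.zone_ratios[("K9A", "within")], abs=1e-9
        )

    def test_short_peak_uses_single_bin_and_flags(self):
        t = BinnedTrack(250, {"chr1": np.arange(100, dtype=float)})
        suz = make_regions([("chr1", 10_000, 10_100)], names=["tiny"])
        with pytest.warns(UserWarning):
            summ = spreading_analysis(suz, {"control": [t], "K27A": [t]})
        assert summ.flagged_short_peaks == ["tiny"]
        assert summ.per_peak["control_within"][0] == pytest.approx(40.0)

    def test_missing_control_condition_rejected(self):
        t = BinnedTrack(250, {"chr1": np.ones(10)})
        with pytest.raises(ValueError):
            spreading_analysis(make_regions([("chr1", 0, 500)]), {"K27A": [t]})


class TestStratifyEnhancers:
    def test_ten_enhancers_split_1_3_6(self):
        out = stratify_enhancers([f"e{i}" for i in range(10)], np.arange(1.0, 11.0))
        counts = out["stratum"].value_counts()
        assert counts["weak"] == 1 and counts["medium"] == 3 and counts["strong"] == 6

    def test_all_equal_collapse_to_strong_with_warning(self):
        with pytest.warns(UserWarning):
            out = stratify_enhancers(list("abc"), [2.0, 2.0, 2.0])
        assert (out["stratum"] == "strong").all()

    def test_stratum_is_monotone_in_rpkm(self):
        rng = np.random.default_rng(0)
        rpkm = rng.random(30) * 10
        base = stratify_enhancers([f"e{i}" for i in range(30)], rpkm)
        order = {"weak": 0, "medium": 1, "strong": 2}
        idx = np.argsort(rpkm)
        ranks = base["stratum"].map(order).to_numpy()[idx]
        assert (np.diff(ranks) >= 0).all()
        # raising one enhancer's RPKM never demotes it (absolute boundaries)
        q = np.quantile(rpkm, (0.10, 0.40))
        bumped = rpkm.copy()
        bumped[5] += 3.0
        after = stratify_enhancers(
            [f"e{i}" for i in range(30)], bumped, boundaries=tuple(q), absolute=True
        )
        assert order[after["stratum"][5]] >= order[base["stratum"][5]]


class TestClassifyErvGroups:
    def test_rule_set(self):
        out = classify_erv_groups(
            ["a", "b", "c", "d"],
            control_k27ac=[5.0, 5.0, 0.0, 0.0],
            control_k9me3=[0.0, 6.0, 6.0, 6.0],
            mutant_k27ac=[5.0, 8.0, 4.0, 0.5],
            thresholds=(2.0, 3.0, 1.0),
        )
        assert out.set_index("subfamily")["group"].tolist() == ["i", "ii", "iii", "unclassified"]

    def test_median_defaults(self):
        out = classify_erv_groups(
            ["a", "b"], [4.0, 0.0], [0.0, 4.0], [4.0, 3.0]
        )
        # a: K27ac >= median(2), K9me3 < median(2) -> group i
        assert out["group"][0] == "i"
        # b: K27ac < a-threshold, mutant K27ac above it -> group iii
        assert out["group"][1] == "iii"
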