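"""Chromatin-state procedures on differential regions and promoters.

k-means partitioning of differential H3K9me3 regions into a fully-lost
and a partially-lost cluster, bivalent-promoter calling from replicate
H3K4me3/H3K27me3 peak sets refined by PRC2 occupancy, the H3K27me3
spreading analysis around SUZ12-bound intervals, nascent-transcription
strength strata for enhancers, and the three-way ERV activity grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import (
    RegionSet,
    consensus_peaks,
    intersect_footprint,
    merge_within,
    overlap_flags,
)
from .tracks import BinnedTrack, SignalMatrix

__all__ = [
    "kmeans_cluster_regions",
    "call_bivalent_promoters",
    "spreading_analysis",
    "stratify_enhancers",
    "classify_erv_groups",
    "SpreadingSummary",
]


# ---------------------------------------------------------------------------
# k-means clustering of differential regions
# ---------------------------------------------------------------------------

def kmeans_cluster_regions(
    control_matrix: SignalMatrix,
    mutant_matrix: SignalMatrix,
    k: int = 2,
    restarts: int = 10,
    seed: int = 0,
    control_only: bool = False,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Cluster differential regions by their window signal profiles.

    Features are the row-wise concatenation of control and mutant window
    vectors (both conditions are needed to separate degrees of loss;
    ``control_only`` restricts to the control profile), log1p-transformed
    by default so that fold-level differences rather than absolute signal
    dominate the Euclidean distances.  Cluster labels are renamed so that
    "Cluster1" is the cluster with the lower mean mutant/control signal
    ratio -- the fully-lost class.  All-identical rows are reported as
    degenerate rather than arbitrarily split.
    """
    if control_matrix.values.shape[0] != mutant_matrix.values.shape[0]:
        raise ValueError("matrices must be row-aligned on the same region set")
    n = control_matrix.values.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of regions ({n})")
    ctrl = np.nan_to_num(control_matrix.values, nan=0.0)
    mut = np.nan_to_num(mutant_matrix.values, nan=0.0)
    X = ctrl if control_only else np.hstack([ctrl, mut])
    if log_scale:
        X = np.log1p(np.clip(X, 0.0, None))

    ctrl_mean = ctrl.mean(axis=1)
    mut_mean = mut.mean(axis=1)
    eps = 1e-9
    ratio = (mut_mean + eps) / (ctrl_mean + eps)

    out = pd.DataFrame(
        {
            "region_id": control_matrix.region_ids,
            "control_mean": ctrl_mean,
            "mutant_mean": mut_mean,
            "ratio": ratio,
        }
    )
    if np.allclose(X, X[0][None, :]):
        warnings.warn("all region profiles identical; clustering is degenerate")
        out["label"] = "Cluster1"
        out.attrs["degenerate"] = True
        return out
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(X)
    # order clusters by mean mutant/control ratio: lowest -> Cluster1
    means = [ratio[raw == c].mean() for c in range(k)]
    order = np.argsort(means)
    rename = {c: f"Cluster{i + 1}" for i, c in enumerate(order)}
    out["label"] = [rename[c] for c in raw]
    out.attrs["degenerate"] = False
    out.attrs["inertia"] = float(km.inertia_)
    return out


# ---------------------------------------------------------------------------
# bivalent promoter calling
# ---------------------------------------------------------------------------

def call_bivalent_promoters(
    k4_replicates: list[RegionSet],
    k27_replicates: list[RegionSet],
    genes: pd.DataFrame,
    prc2_peaks: RegionSet | None = None,
    tss_flank: int = 1000,
    merge_gap: int = 500,
    min_support: int = 2,
) -> pd.DataFrame:
    """Bivalent promoters: consensus(K4me3) n consensus(K27me3), merged,
    kept at TSS +- ``tss_flank`` of protein-coding genes and refined by
    PRC2 (e.g. SUZ12) occupancy.

    Returns one row per gene with the bivalent flag and the supporting
    evidence (overlapping dual-mark region, PRC2 peak).  Without a PRC2
    set the refinement is skipped and calls are flagged unrefined.
    """
    k4 = consensus_peaks(k4_replicates, min_support=min_support)
    k27 = consensus_peaks(k27_replicates, min_support=min_support)
    dual = merge_within(intersect_footprint(k4, k27), gap=merge_gap)
    dual.df["name"] = [f"dual_{i:05d}" for i in range(len(dual.df))]

    coding = genes[genes["biotype"] == "protein_coding"]
    refined = prc2_peaks is not None
    if not refined:
        warnings.warn("no PRC2 peak set supplied; bivalent calls are unrefined")

    # per dual-mark region: does it carry PRC2 occupancy?
    if refined and len(dual):
        dual_prc2 = overlap_flags(dual, prc2_peaks)
        prc2_names = prc2_peaks.names
        prc2_hit_id = []
        for i in range(len(dual)):
            reg = RegionSet(dual.df.iloc[[i]][["chrom", "start", "end"]])
            hits = overlap_flags(prc2_peaks, reg)
            prc2_hit_id.append(
                prc2_names[int(np.flatnonzero(hits)[0])] if hits.any() else None
            )
    else:
        dual_prc2 = np.ones(len(dual), dtype=bool)
        prc2_hit_id = [None] * len(dual)

    by_chrom = {c: sub for c, sub in dual.df.reset_index().groupby("chrom")}
    rows = []
    for g in coding.itertuples(index=False):
        tss = int(g.tss)
        lo, hi = max(tss - tss_flank, 0), tss + tss_flank
        sub = by_chrom.get(g.chrom)
        region_id = prc2_id = None
        bivalent = False
        if sub is not None:
            hit = sub[(sub["start"] < hi) & (sub["end"] > lo)]
            for _, reg in hit.iterrows():
                i = int(reg["index"])
                if not refined or dual_prc2[i]:
                    bivalent = True
                    region_id = reg["name"]
                    prc2_id = prc2_hit_id[i]
                    break
        rows.append((g.gene_id, tss, bivalent, region_id, prc2_id, refined))
    return pd.DataFrame(
        rows, columns=["gene_id", "tss", "bivalent", "region_id", "prc2_id", "refined"]
    )


# ---------------------------------------------------------------------------
# H3K27me3 spreading around SUZ12 peaks
# ---------------------------------------------------------------------------

@dataclass
class SpreadingSummary:
    """Zone means per peak and mutant/control zone ratios.

    Zones per SUZ12 peak: within [start, end), upstream [start-flank, start),
    downstream [end, end+flank); ratios are mean(mutant)/mean(control) over
    all peaks, per zone.
    """

    per_peak: pd.DataFrame
    zone_ratios: dict  # (condition, zone) -> ratio vs control
    flank: int
    flagged_short_peaks: list = field(default_factory=list)

    def flank_ratio(self, condition: str) -> float:
        return 0.5 * (
            self.zone_ratios[(condition, "upstream")]
            + self.zone_ratios[(condition, "downstream")]
        )


def _zone_mean(tracks: list[BinnedTrack], chrom: str, start: int, end: int) -> float:
    vals = [t.region_mean(chrom, start, end) for t in tracks if chrom in t.data]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else np.nan


def spreading_analysis(
    suz12: RegionSet,
    tracks_by_condition: dict[str, list[BinnedTrack]],
    flank: int = 1500,
    control: str = "control",
) -> SpreadingSummary:
    """Replicate-averaged H3K27me3 per zone around each SUZ12 peak.

    Flank zones are clipped at chromosome ends; peaks shorter than one
    track bin use the single covering bin and are flagged.
    """
    if control not in tracks_by_condition:
        raise ValueError(f"control condition {control!r} missing from tracks")
    bin_size = next(iter(tracks_by_condition.values()))[0].bin_size
    rows = []
    short = []
    for i, row in enumerate(suz12.df.itertuples(index=False)):
        chrom, s, e = row.chrom, int(row.start), int(row.end)
        name = getattr(row, "name", f"peak_{i}")
        if e - s < bin_size:
            short.append(name)
        rec = {"peak": name}
        for cond, tracks in tracks_by_condition.items():
            rec[f"{cond}_within"] = _zone_mean(tracks, chrom, s, e)
            rec[f"{cond}_upstream"] = _zone_mean(tracks, chrom, max(s - flank, 0), s)
            rec[f"{cond}_downstream"] = _zone_mean(tracks, chrom, e, e + flank)
        rows.append(rec)
    per_peak = pd.DataFrame(rows)
    ratios = {}
    for cond in tracks_by_condition:
        if cond == control:
            continue
        for zone in ("within", "upstream", "downstream"):
            num = np.nanmean(per_peak[f"{cond}_{zone}"].to_numpy())
            den = np.nanmean(per_peak[f"{control}_{zone}"].to_numpy())
            ratios[(cond, zone)] = float(num / den)
    if short:
        warnings.warn(f"{len(short)} SUZ12 peaks shorter than one bin; flagged")
    return SpreadingSummary(per_peak, ratios, flank, flagged_short_peaks=short)


# ---------------------------------------------------------------------------
# enhancer strength strata
# ---------------------------------------------------------------------------

def stratify_enhancers(
    enhancer_ids,
    control_rpkm,
    boundaries: tuple[float, float] = (0.10, 0.40),
    absolute: bool = False,
) -> pd.DataFrame:
    """Three strata (weak/medium/strong) by control nascent-transcription RPKM.

    ``boundaries`` are quantiles by default (weak <= q1 < medium <= q2 <
    strong) or absolute RPKM thresholds with ``absolute=True``.  Ties are
    broken deterministically by enhancer id; an all-equal input collapses
    to a single "strong" stratum with a warning.
    """
    rpkm = np.asarray(control_rpkm, dtype=float)
    ids = list(enhancer_ids)
    if len(ids) != len(rpkm):
        raise ValueError("ids and RPKM must align")
    if len(ids) < 3:
        raise ValueError("need at least 3 enhancers to stratify")
    if not np.isfinite(rpkm).all():
        raise ValueError("RPKM values must be finite")
    if np.ptp(rpkm) == 0:
        warnings.warn("all enhancers have equal RPKM; single 'strong' stratum")
        strata = np.array(["strong"] * len(ids))
    else:
        if absolute:
            q1, q2 = boundaries
        else:
            q1, q2 = np.quantile(rpkm, boundaries)
        strata = np.where(rpkm <= q1, "weak", np.where(rpkm <= q2, "medium", "strong"))
    return pd.DataFrame({"enhancer_id": ids, "control_rpkm": rpkm, "stratum": strata})


def classify_erv_groups(
    subfamilies,
    control_k27ac,
    control_k9me3,
    mutant_k27ac,
    thresholds: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Three ERV activity groups from control/mutant H3K27ac and H3K9me3.

    i   constitutively active: control K27ac >= a, control K9me3 < m
    ii  dual-marked, further activated: control K27ac >= a and K9me3 >= m,
        with mutant K27ac gain >= d
    iii mutant-only activated: control K27ac < a, mutant K27ac >= a

    Defaults: a, m are the per-mark medians over subfamilies; d = 1 (log2).
    """
    ac = np.asarray(control_k27ac, dtype=float)
    me = np.asarray(control_k9me3, dtype=float)
    mac = np.asarray(mutant_k27ac, dtype=float)
    if thresholds is None:
        a, m, d = float(np.median(ac)), float(np.median(me)), 1.0
    else:
        a, m, d = thresholds
    group = np.full(len(ac), "unclassified", dtype=object)
    group[(ac >= a) & (me < m)] = "i"
    group[(ac >= a) & (me >= m) & (mac - ac >= d)] = "ii"
    group[(ac < a) & (mac >= a)] = "iii"
    return pd.DataFrame(
        {
            "subfamily": list(subfamilies),
            "control_k27ac": ac,
            "control_k9me3": me,
            "mutant_k27ac": mac,
            "group": group,
        }
    )
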