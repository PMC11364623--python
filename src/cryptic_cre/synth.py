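"""Synthetic miniature epigenome with implanted ground truth.

The generator emulates the statistical structure the downstream stages
assume, at desk scale: a two-chromosome genome with gene models, ERV
instances grouped into subfamilies and families, three classes of distal
H3K9me3 regions (Cluster1 = full signal loss in the K9A mutant, Cluster2 =
partial loss, nonDA = unchanged), bivalent promoters carrying
H3K4me3 + H3K27me3 + SUZ12 with flank-specific H3K27me3 loss in the K27A
mutant, dREG-like enhancers with graded nascent transcription, binned
signal tracks per (mark, genotype, replicate), and negative-binomial count
matrices in which genes linked to de-repressed regions are upregulated.

Everything is driven by one root seed; per-(mark, genotype, replicate)
substreams are derived by stable hashing so adding one track never
perturbs another.  Tracks are emitted directly as binned values
(bedGraph-equivalent); no read-level simulation.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import RegionSet, overlap_flags

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SimCounts",
    "build_genome",
    "simulate_tracks",
    "mean_track",
    "make_peak_calls",
    "simulate_counts",
    "write_dataset",
]

MARKS = ("H3.3", "H3K9me3", "H3K27ac", "H3K9ac", "H3K4me3", "H3K27me3", "SUZ12", "PROseq")
REGION_CLASSES = ("Cluster1", "Cluster2", "nonDA")

DEFAULT_SUBFAMILIES = (
    ("IAPEz-int", "ERVK"),
    ("IAPLTR1_Mm", "ERVK"),
    ("MMERVK10C-int", "ERVK"),
    ("RLTR1B", "ERV1"),
    ("RLTR4_Mm", "ERV1"),
    ("MERVL-int", "ERVL"),
    ("ORR1A2", "MaLR"),
    ("MTA_Mm", "MaLR"),
)


class SizingError(ValueError):
    """Genome too small for the requested feature load."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the miniature study design.

    Region-class effect sizes are expressed as mean bin amplitudes over a
    lognormal background of mean 1 (RPGC-like); the mutant/control ratio of
    amplitudes is the implanted fold change the recovery tests measure.
    """

    # genome layout
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    bin_size: int = 250
    n_genes: int = 400
    gene_length: tuple[int, int] = (2000, 3500)
    n_exons: tuple[int, int] = (2, 4)
    # ERVs
    erv_subfamilies: tuple[tuple[str, str], ...] = DEFAULT_SUBFAMILIES
    n_erv_instances: int = 75  # per subfamily
    erv_frac_ge500: float = 0.7
    # regions
    n_cluster1_regions: int = 200
    n_cluster2_regions: int = 200
    n_nonda_regions: int = 200
    # H3K9me3 forms broad heterochromatin domains; widths are drawn so the
    # summit +- 5 kb heatmap span lies mostly inside the domain
    region_length: tuple[int, int] = (6000, 12000)
    erv_overlap_fractions: tuple[float, float, float] = (0.60, 0.40, 0.22)
    tss_exclusion: int = 2000
    # promoters / enhancers
    n_bivalent_promoters: int = 60
    tss_flank: int = 1000
    suz12_flank: int = 1500
    n_enhancers: int = 120
    enhancer_length: tuple[int, int] = (500, 1000)
    enhancer_strata_fracs: tuple[float, float] = (0.10, 0.30)  # weak, medium
    # design
    replicates_per_group: int = 3
    groups: tuple[str, ...] = ("control", "K9A", "K27A")
    # track amplitudes (mean bin signal; background = 1)
    h3k9me3_amp: float = 8.0
    h3k9me3_k9a_amp: tuple[float, float] = (1.0, 4.0)  # Cluster1, Cluster2
    h33_amp: tuple[float, float, float] = (6.0, 6.0, 2.0)  # Cl1, Cl2, nonDA
    h3k27ac_ctrl_amp: tuple[float, float] = (3.0, 1.5)
    h3k27ac_k9a_amp: tuple[float, float] = (8.0, 3.0)
    proseq_k9a_amp: tuple[float, float] = (6.0, 2.0)
    k4me3_amp: float = 6.0
    suz12_amp: float = 5.0
    k27me3_amp_in: float = 6.0
    k27me3_amp_flank: float = 3.0
    f_in: float = 0.7       # K27A within-SUZ12-peak retention
    f_flank: float = 0.4    # K27A flank retention (< f_in: spreading defect)
    k9a_k27me3_factor: float = 0.7  # K9A uniform loss (no flank specificity)
    enhancer_k9a_factor: tuple[float, float, float] = (1.5, 0.9, 0.6)
    noise_sd: float = 0.25
    # counts
    dispersion: float = 0.1  # NB alpha; variance = mu + alpha*mu^2
    depth_sd: float = 0.15
    base_log_mean: float = 5.0
    base_log_sd: float = 1.0
    n_links: int = 80
    link_max_dist: int = 200_000
    de_log2fc: float = 2.0
    de_up_fraction: float = 0.82
    n_k27a_bivalent_up: int = 30
    te_log2fc: float = 2.0
    te_base_log_mean: float = 6.0
    # peak (H3K27ac-like) per-sample signal for linkage
    peak_base_log2: float = 3.0
    peak_base_sd: float = 0.5
    peak_k9a_shift: tuple[float, float] = (2.0, 1.0)  # log2, Cl1/Cl2
    activity_sd: float = 0.5   # within-group chromatin variability (log2)
    link_coupling: float = 0.6  # propagation of peak activity into linked gene
    peak_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.chrom_length <= 0 or self.bin_size <= 0 or self.n_chroms <= 0:
            raise ValueError("lengths and counts must be positive")
        if self.chrom_length % self.bin_size != 0:
            raise ValueError("bin_size must divide chrom_length")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not (0 < self.f_flank <= self.f_in <= 1):
            raise ValueError("need 0 < f_flank <= f_in <= 1")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)

    @property
    def samples(self) -> list[tuple[str, str, int]]:
        return [
            (f"{g}_r{i + 1}", g, i + 1)
            for g in self.groups
            for i in range(self.replicates_per_group)
        ]


@dataclass
class GroundTruth:
    """Record of every implanted effect; the acceptance surface."""

    config: SynthConfig
    genes: pd.DataFrame
    regions: pd.DataFrame       # name, class, chrom, start, end, summit
    ervs: pd.DataFrame          # name, subfamily, family, chrom, start, end
    enhancers: pd.DataFrame     # name, chrom, start, end, stratum, ctrl_amp
    bivalent_genes: list[str]
    links: pd.DataFrame         # region_id, gene_id, distance
    gene_direction: dict        # gene_id -> {genotype: log2fc}
    te_direction: dict          # subfamily -> {genotype: log2fc}
    region_erv_overlap: dict    # region name -> list of ERV names (>=500 bp)
    warnings: list[str] = field(default_factory=list)

    # -- convenience views --------------------------------------------------
    def region_set(self, cls: str | None = None) -> RegionSet:
        df = self.regions if cls is None else self.regions[self.regions["class"] == cls]
        return RegionSet(df[["chrom", "start", "end", "name", "summit"]], label=cls or "regions")

    def erv_set(self) -> RegionSet:
        return RegionSet(self.ervs[["chrom", "start", "end", "name"]], label="ERV")

    def suz12_peaks(self) -> RegionSet:
        """SUZ12-bound intervals: TSS +- tss_flank at bivalent promoters."""
        sub = self.genes[self.genes["gene_id"].isin(self.bivalent_genes)]
        df = pd.DataFrame(
            {
                "chrom": sub["chrom"],
                "start": sub["tss"] - self.config.tss_flank,
                "end": sub["tss"] + self.config.tss_flank,
                "name": ["SUZ12_" + g for g in sub["gene_id"]],
            }
        )
        return RegionSet(df, label="SUZ12")

    def class_ratio(self, mark: str, genotype: str) -> dict[str, float]:
        """Implanted mutant/control amplitude ratio per region class."""
        cfg = self.config
        out = {}
        for i, cls in enumerate(REGION_CLASSES):
            a_ctrl = _class_amp(cfg, mark, "control", cls)
            a_mut = _class_amp(cfg, mark, genotype, cls)
            out[cls] = a_mut / a_ctrl if a_ctrl else np.nan
        return out

    def chrom_sizes(self) -> dict[str, int]:
        return {
            f"chr{i + 1}": self.config.chrom_length for i in range(self.config.n_chroms)
        }


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Stable substream: root seed + CRC32 of the tag string."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(tag.encode())])
    )


def _snap(x: int, bs: int) -> int:
    return (int(x) // bs) * bs


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def build_genome(config: SynthConfig) -> GroundTruth:
    """Place genes, regions, enhancers and ERVs; record the ground truth.

    Features occupy disjoint slots with a margin wide enough that distal
    regions are always >= ``tss_exclusion`` bp from every TSS and that
    SUZ12 flank zones never collide with a neighbouring feature.  A
    configured, exact (rounded) count of regions per class receives an
    implanted ERV instance >= 500 bp; remaining ERV copies are placed away
    from the study regions so the realized overlap fractions equal the
    configured ones up to rounding.
    """
    cfg = config
    rng = _rng(cfg.seed, "genome")
    bs = cfg.bin_size
    # margin keeps regions >= tss_exclusion from any TSS (features sit >= margin
    # inside their slot, so cross-slot distances are >= 2*margin) and keeps
    # SUZ12 flank zones (tss_flank + suz12_flank from the TSS) off neighbours
    margin = max(cfg.tss_exclusion, cfg.tss_flank + cfg.suz12_flank)

    n_regions = cfg.n_cluster1_regions + cfg.n_cluster2_regions + cfg.n_nonda_regions
    n_features = cfg.n_genes + n_regions + cfg.n_enhancers
    per_chrom = -(-n_features // cfg.n_chroms)
    slot_width = cfg.chrom_length // per_chrom
    usable = slot_width - 2 * margin
    max_len = max(cfg.gene_length[1], cfg.region_length[1], cfg.enhancer_length[1])
    if usable < max_len + bs:
        raise SizingError(
            f"slot width {slot_width} bp (chrom_length {cfg.chrom_length} / "
            f"{per_chrom} features per chromosome) leaves {usable} bp after "
            f"2 x {margin} bp margins, below the largest feature length "
            f"{max_len} bp; enlarge chrom_length or reduce feature counts"
        )

    types = (
        ["gene"] * cfg.n_genes
        + ["Cluster1"] * cfg.n_cluster1_regions
        + ["Cluster2"] * cfg.n_cluster2_regions
        + ["nonDA"] * cfg.n_nonda_regions
        + ["enhancer"] * cfg.n_enhancers
    )
    rng.shuffle(types)

    genes_rows, region_rows, enh_rows = [], [], []
    counters = {t: 0 for t in ("gene", "Cluster1", "Cluster2", "nonDA", "enhancer")}
    for idx, ftype in enumerate(types):
        chrom = f"chr{idx % cfg.n_chroms + 1}"
        slot_idx = idx // cfg.n_chroms
        slot_start = slot_idx * slot_width
        if ftype == "gene":
            lo, hi = cfg.gene_length
        elif ftype == "enhancer":
            lo, hi = cfg.enhancer_length
        else:
            lo, hi = cfg.region_length
        length = _snap(rng.integers(lo, hi + 1), bs)
        length = max(length, bs)
        start = slot_start + margin + int(rng.integers(0, usable - length + 1))
        start = _snap(start, bs)
        end = start + length
        counters[ftype] += 1
        if ftype == "gene":
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            n_ex = int(rng.integers(cfg.n_exons[0], cfg.n_exons[1] + 1))
            parts = rng.random(2 * n_ex - 1) + 0.2
            parts = np.cumsum(parts / parts.sum() * length).astype(int)
            bounds = [start] + [start + int(p) for p in parts[:-1]] + [end]
            ex_s = [bounds[2 * i] for i in range(n_ex)]
            ex_e = [bounds[2 * i + 1] for i in range(n_ex)]
            genes_rows.append(
                (
                    f"gene{counters['gene']:04d}",
                    chrom,
                    start,
                    end,
                    strand,
                    tss,
                    ",".join(map(str, ex_s)),
                    ",".join(map(str, ex_e)),
                    "protein_coding",
                )
            )
        elif ftype == "enhancer":
            enh_rows.append((f"enh{counters['enhancer']:04d}", chrom, start, end))
        else:
            summit = length // 2
            region_rows.append(
                (f"{ftype}_{counters[ftype]:04d}", ftype, chrom, start, end, summit)
            )

    genes = pd.DataFrame(
        genes_rows,
        columns=[
            "gene_id", "chrom", "start", "end", "strand", "tss",
            "exon_starts", "exon_ends", "biotype",
        ],
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    regions = pd.DataFrame(
        region_rows, columns=["name", "class", "chrom", "start", "end", "summit"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    enhancers = pd.DataFrame(enh_rows, columns=["name", "chrom", "start", "end"])

    warnings_list: list[str] = []

    # ---- ERV instances ----------------------------------------------------
    subfams = list(cfg.erv_subfamilies)
    # implanted (region-overlapping) instances are drawn from the K9A-
    # responsive families (ERVK, ERV1); other families stay background-only
    implant_slots = [
        sf for sf in subfams if sf[1] in ("ERVK", "ERV1")
        for _ in range(cfg.n_erv_instances)
    ]
    bg_slots = [
        sf for sf in subfams if sf[1] not in ("ERVK", "ERV1")
        for _ in range(cfg.n_erv_instances)
    ]
    rng.shuffle(implant_slots)
    rng.shuffle(bg_slots)
    fracs = dict(zip(REGION_CLASSES, cfg.erv_overlap_fractions))
    implant_targets: list[str] = []  # region names receiving an ERV
    if cfg.n_erv_instances > 0:
        for cls in REGION_CLASSES:
            names = regions.loc[regions["class"] == cls, "name"].to_numpy()
            k = int(round(fracs[cls] * len(names)))
            implant_targets.extend(rng.choice(names, size=k, replace=False))
        if len(implant_slots) < len(implant_targets):
            raise SizingError(
                f"{len(implant_slots)} ERVK/ERV1 instances cannot cover "
                f"{len(implant_targets)} implanted region overlaps; raise "
                "n_erv_instances"
            )
    else:
        warnings_list.append("n_erv_instances = 0: all ERV-overlap fractions are 0")
        warnings.warn(warnings_list[-1])
    slots = implant_slots + bg_slots

    region_lookup = regions.set_index("name")
    erv_rows = []
    occupied = regions[["chrom", "start", "end"]].copy()
    occ_by_chrom = {
        c: sub[["start", "end"]].to_numpy() for c, sub in occupied.groupby("chrom")
    }
    for i, (subfam, family) in enumerate(slots):
        if i < len(implant_targets):
            reg = region_lookup.loc[implant_targets[i]]
            length = int(rng.integers(500, 2501))
            lo = max(int(reg["start"]) - length + 50, 0)
            hi = max(int(reg["end"]) - 50, lo + 1)
            start = int(rng.integers(lo, hi))
            chrom = reg["chrom"]
        else:
            # background copy, placed away from every study region
            length = (
                int(rng.integers(500, 2501))
                if rng.random() < cfg.erv_frac_ge500
                else int(rng.integers(80, 500))
            )
            for _ in range(1000):
                chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
                start = int(rng.integers(0, cfg.chrom_length - length))
                arr = occ_by_chrom.get(chrom)
                if arr is None or not np.any(
                    (arr[:, 0] < start + length) & (arr[:, 1] > start)
                ):
                    break
            else:
                raise SizingError(
                    "could not place a background ERV away from study regions "
                    "after 1000 tries; genome too crowded"
                )
        end = min(start + length, cfg.chrom_length)
        erv_rows.append((f"{subfam}|{family}|{i:04d}", subfam, family, chrom, start, end))
    ervs = pd.DataFrame(
        erv_rows, columns=["name", "subfamily", "family", "chrom", "start", "end"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    # realized region -> ERV (>=500 bp) overlaps
    region_erv: dict[str, list[str]] = {n: [] for n in regions["name"]}
    if len(ervs):
        big = ervs[(ervs["end"] - ervs["start"]) >= 500]
        for _, erv in big.iterrows():
            hits = regions[
                (regions["chrom"] == erv["chrom"])
                & (regions["start"] < erv["end"])
                & (regions["end"] > erv["start"])
            ]
            for name in hits["name"]:
                region_erv[name].append(erv["name"])

    # ---- bivalent promoters ----------------------------------------------
    n_biv = min(cfg.n_bivalent_promoters, len(genes))
    bivalent = sorted(rng.choice(genes["gene_id"].to_numpy(), size=n_biv, replace=False))

    # ---- enhancer strata --------------------------------------------------
    amp = np.exp(rng.normal(np.log(4.0), 0.9, size=len(enhancers)))
    order = np.argsort(np.argsort(amp, kind="mergesort"), kind="mergesort")
    q = (order + 0.5) / max(len(enhancers), 1)
    w, m = cfg.enhancer_strata_fracs
    stratum = np.where(q < w, "weak", np.where(q < w + m, "medium", "strong"))
    enhancers = enhancers.assign(ctrl_amp=amp, stratum=stratum)

    # ---- peak-gene links --------------------------------------------------
    linkable = regions[regions["class"].isin(["Cluster1", "Cluster2"])]
    links_rows = []
    used_genes: set[str] = set()
    if len(linkable) and cfg.n_links > 0:
        chosen = rng.choice(
            linkable["name"].to_numpy(),
            size=min(cfg.n_links, len(linkable)),
            replace=False,
        )
        tss = genes["tss"].to_numpy()
        gchrom = genes["chrom"].to_numpy()
        gids = genes["gene_id"].to_numpy()
        for rname in chosen:
            reg = region_lookup.loc[rname]
            center = int(reg["start"]) + int(reg["summit"])
            cand = np.where(
                (gchrom == reg["chrom"])
                & (np.abs(tss - center) <= cfg.link_max_dist)
            )[0]
            cand = [j for j in cand if gids[j] not in used_genes]
            if not cand:
                warnings_list.append(f"no linkable gene near {rname}; link skipped")
                continue
            j = cand[int(rng.integers(0, len(cand)))]
            used_genes.add(gids[j])
            links_rows.append((rname, gids[j], int(tss[j]) - center))
    links = pd.DataFrame(links_rows, columns=["region_id", "gene_id", "distance"])

    gene_direction: dict[str, dict[str, float]] = {}
    if len(links):
        n_up = int(round(cfg.de_up_fraction * len(links)))
        up_idx = rng.choice(len(links), size=n_up, replace=False)
        for i, gid in enumerate(links["gene_id"]):
            gene_direction[gid] = {"K9A": cfg.de_log2fc if i in set(up_idx) else 0.0}
    # K27A: a subset of bivalent genes de-represses
    k27_up = rng.choice(
        np.array(bivalent), size=min(cfg.n_k27a_bivalent_up, len(bivalent)), replace=False
    )
    for gid in k27_up:
        gene_direction.setdefault(gid, {})["K27A"] = cfg.de_log2fc

    # TE subfamilies overlapping de-repressed regions go up in K9A
    responsive = set()
    for cls in ("Cluster1", "Cluster2"):
        for rname in regions.loc[regions["class"] == cls, "name"]:
            for ename in region_erv[rname]:
                responsive.add(ename.split("|")[0])
    te_direction = {
        sf: ({"K9A": cfg.te_log2fc} if sf in responsive else {})
        for sf, _ in cfg.erv_subfamilies
    }

    return GroundTruth(
        config=cfg,
        genes=genes,
        regions=regions,
        ervs=ervs,
        enhancers=enhancers,
        bivalent_genes=[str(g) for g in bivalent],
        links=links,
        gene_direction=gene_direction,
        te_direction=te_direction,
        region_erv_overlap=region_erv,
        warnings=warnings_list,
    )


# ---------------------------------------------------------------------------
# track simulation
# ---------------------------------------------------------------------------

def _class_amp(cfg: SynthConfig, mark: str, genotype: str, cls: str) -> float:
    """Mean bin amplitude of a region class for one mark and genotype."""
    i = REGION_CLASSES.index(cls)
    if mark == "H3K9me3":
        if genotype == "K9A":
            return (*cfg.h3k9me3_k9a_amp, cfg.h3k9me3_amp)[i]
        return cfg.h3k9me3_amp
    if mark == "H3.3":
        return cfg.h33_amp[i]
    if mark in ("H3K27ac", "H3K9ac"):
        scale = 1.0 if mark == "H3K27ac" else 0.5
        if cls == "nonDA":
            return 1.0
        base = cfg.h3k27ac_k9a_amp if genotype == "K9A" else cfg.h3k27ac_ctrl_amp
        return max(1.0, base[i] * scale)
    if mark == "PROseq":
        if genotype == "K9A" and cls != "nonDA":
            return cfg.proseq_k9a_amp[i]
        return 1.0
    return 1.0


def _feature_amplitudes(truth: GroundTruth, mark: str, genotype: str):
    """All (chrom, start, end, amplitude) features of the mean surface."""
    cfg = truth.config
    feats: list[tuple[str, int, int, float]] = []
    reg = truth.regions
    for chrom, start, end, cls in zip(
        reg["chrom"], reg["start"], reg["end"], reg["class"]
    ):
        a = _class_amp(cfg, mark, genotype, cls)
        if a != 1.0:
            feats.append((chrom, int(start), int(end), a))
    if mark == "H3K4me3":
        for g in truth.genes.itertuples(index=False):
            feats.append(
                (g.chrom, int(g.tss) - cfg.tss_flank, int(g.tss) + cfg.tss_flank, cfg.k4me3_amp)
            )
    if mark in ("H3K27me3", "SUZ12", "H3.3"):
        biv = truth.genes[truth.genes["gene_id"].isin(truth.bivalent_genes)]
        for g in biv.itertuples(index=False):
            s, e = int(g.tss) - cfg.tss_flank, int(g.tss) + cfg.tss_flank
            if mark == "SUZ12":
                feats.append((g.chrom, s, e, cfg.suz12_amp))
            elif mark == "H3.3":
                feats.append((g.chrom, s, e, 4.0))
            else:
                f_in = f_fl = 1.0
                if genotype == "K27A":
                    f_in, f_fl = cfg.f_in, cfg.f_flank
                elif genotype == "K9A":
                    f_in = f_fl = cfg.k9a_k27me3_factor
                feats.append((g.chrom, s, e, max(1.0, cfg.k27me3_amp_in * f_in)))
                for fs, fe in ((s - cfg.suz12_flank, s), (e, e + cfg.suz12_flank)):
                    feats.append((g.chrom, fs, fe, max(1.0, cfg.k27me3_amp_flank * f_fl)))
    if mark in ("H3K27ac", "H3K9ac", "PROseq", "H3.3"):
        scale = {"H3K27ac": 1.0, "H3K9ac": 0.5, "PROseq": 1.0, "H3.3": 0.0}[mark]
        factors = dict(zip(("weak", "medium", "strong"), cfg.enhancer_k9a_factor))
        for e in truth.enhancers.itertuples(index=False):
            if mark == "H3.3":
                amp = 3.0
            else:
                amp = max(1.0, e.ctrl_amp * scale)
                if genotype == "K9A" and mark == "PROseq":
                    amp = max(1.0, e.ctrl_amp * factors[e.stratum])
                elif genotype == "K27A" and mark in ("H3K27ac", "H3K9ac"):
                    amp = max(1.0, amp * 0.6)
            feats.append((e.chrom, int(e.start), int(e.end), amp))
    if mark == "PROseq":
        for g in truth.genes.itertuples(index=False):
            feats.append((g.chrom, int(g.start), int(g.end), 2.0))
    return feats


def _validate(cfg: SynthConfig, mark: str, genotype: str) -> None:
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; choose from {MARKS}")
    if genotype not in cfg.groups:
        raise ValueError(f"unknown genotype {genotype!r}; choose from {cfg.groups}")


def mean_track(truth: GroundTruth, mark: str, genotype: str):
    """Deterministic mean surface (the noise-free expectation) as BinnedTrack."""
    from .tracks import BinnedTrack

    cfg = truth.config
    _validate(cfg, mark, genotype)
    bs = cfg.bin_size
    nbins = cfg.chrom_length // bs
    data = {f"chr{i + 1}": np.ones(nbins) for i in range(cfg.n_chroms)}
    for chrom, s, e, amp in _feature_amplitudes(truth, mark, genotype):
        if chrom not in data:
            continue
        b0 = max(s // bs, 0)
        b1 = min(-(-e // bs), nbins)
        if b1 > b0:
            data[chrom][b0:b1] = amp
    return BinnedTrack(bs, data, normalization="RPGC")


def simulate_tracks(truth: GroundTruth, mark: str, genotype: str, replicate: int):
    """One replicate track: mean surface x mean-one lognormal bin noise."""
    cfg = truth.config
    _validate(cfg, mark, genotype)
    track = mean_track(truth, mark, genotype)
    sd = cfg.noise_sd
    if sd > 0:
        rng = _rng(cfg.seed, f"track|{mark}|{genotype}|{replicate}")
        for chrom in sorted(track.data):
            z = rng.standard_normal(len(track.data[chrom]))
            track.data[chrom] *= np.exp(sd * z - sd * sd / 2.0)
    return track


def make_peak_calls(
    truth: GroundTruth,
    mark: str,
    genotype: str,
    replicate: int,
    dropout: float = 0.08,
    jitter: int = 100,
    min_amp: float = 2.0,
) -> RegionSet:
    """Replicate-level peak calls: true features with jittered boundaries
    and random dropout, emulating MACS2-style per-replicate variability."""
    cfg = truth.config
    _validate(cfg, mark, genotype)
    rng = _rng(cfg.seed, f"peaks|{mark}|{genotype}|{replicate}")
    rows = []
    i = 0
    for chrom, s, e, amp in _feature_amplitudes(truth, mark, genotype):
        if amp < min_amp:
            continue
        if rng.random() < dropout:
            continue
        js = max(0, s - int(rng.integers(0, jitter + 1)))
        je = min(cfg.chrom_length, e + int(rng.integers(0, jitter + 1)))
        rows.append((chrom, js, je, f"{mark}_{genotype}_r{replicate}_{i:05d}"))
        i += 1
    return RegionSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]),
        label=f"{mark}:{genotype}:r{replicate}",
    )


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

@dataclass
class SimCounts:
    gene_counts: pd.DataFrame   # genes x samples, integers
    te_counts: pd.DataFrame     # TE subfamilies x samples, integers
    peak_signal: pd.DataFrame   # regions x samples, log2 normalized signal
    sample_sheet: pd.DataFrame  # sample, genotype, replicate, batch
    size_factors: pd.Series


def _nb_draw(rng, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return np.rint(mu).astype(np.int64)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.int64)


def simulate_counts(truth: GroundTruth) -> SimCounts:
    """NB gene and TE-subfamily counts plus a per-region signal matrix.

    Genes carry their implanted log2 fold changes in the relevant mutant;
    linked genes additionally inherit a ``link_coupling``-scaled share of
    their region's per-sample chromatin activity (the within-group
    deviation), which is what the correlation linker detects.  TE
    subfamilies overlapping de-repressed regions are upregulated in K9A.
    """
    cfg = truth.config
    if cfg.dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = _rng(cfg.seed, "counts")
    samples = cfg.samples
    sample_ids = [s[0] for s in samples]
    genotypes = np.array([s[1] for s in samples])
    sheet = pd.DataFrame(
        {
            "sample": sample_ids,
            "genotype": [s[1] for s in samples],
            "replicate": [s[2] for s in samples],
            "batch": "b1",
        }
    )
    sf = (
        np.exp(rng.normal(0.0, cfg.depth_sd, size=len(samples)))
        if cfg.depth_sd > 0
        else np.ones(len(samples))
    )
    sf = sf / np.exp(np.mean(np.log(sf)))

    # ---- per-region activity (log2), shared with linked genes -------------
    regions = truth.regions
    shift = {"Cluster1": cfg.peak_k9a_shift[0], "Cluster2": cfg.peak_k9a_shift[1], "nonDA": 0.0}
    base = rng.normal(cfg.peak_base_log2, cfg.peak_base_sd, size=len(regions))
    eps = rng.normal(0.0, cfg.activity_sd, size=(len(regions), len(samples)))
    group_shift = np.array(
        [[shift[c] if g == "K9A" else 0.0 for g in genotypes] for c in regions["class"]]
    )
    activity = group_shift + eps
    peak_signal = pd.DataFrame(
        base[:, None]
        + activity
        + rng.normal(0.0, cfg.peak_noise_sd, size=activity.shape),
        index=regions["name"].to_numpy(),
        columns=sample_ids,
    )
    region_row = {n: i for i, n in enumerate(regions["name"])}
    gene_eps = {
        gid: eps[region_row[rid]]
        for rid, gid in zip(truth.links["region_id"], truth.links["gene_id"])
    }

    # ---- gene counts ------------------------------------------------------
    genes = truth.genes["gene_id"].to_numpy()
    base_mu = np.exp(rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=len(genes)))
    log2_mult = np.zeros((len(genes), len(samples)))
    for i, gid in enumerate(genes):
        for geno, lfc in truth.gene_direction.get(gid, {}).items():
            log2_mult[i, genotypes == geno] += lfc
        if cfg.link_coupling != 0 and gid in gene_eps:
            log2_mult[i] += cfg.link_coupling * gene_eps[gid]
    mu = base_mu[:, None] * np.exp2(log2_mult) * sf[None, :]
    gene_counts = pd.DataFrame(
        _nb_draw(rng, mu, cfg.dispersion), index=genes, columns=sample_ids
    )

    # ---- TE subfamily counts ---------------------------------------------
    subfams = [sf_ for sf_, _ in cfg.erv_subfamilies]
    te_mu = np.exp(rng.normal(cfg.te_base_log_mean, 0.8, size=len(subfams)))
    te_mult = np.zeros((len(subfams), len(samples)))
    for i, sub in enumerate(subfams):
        for geno, lfc in truth.te_direction.get(sub, {}).items():
            te_mult[i, genotypes == geno] += lfc
    te_counts = pd.DataFrame(
        _nb_draw(rng, te_mu[:, None] * np.exp2(te_mult) * sf[None, :], cfg.dispersion),
        index=subfams,
        columns=sample_ids,
    )
    return SimCounts(
        gene_counts=gene_counts,
        te_counts=te_counts,
        peak_signal=peak_signal,
        sample_sheet=sheet,
        size_factors=pd.Series(sf, index=sample_ids, name="size_factor"),
    )


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def write_dataset(truth: GroundTruth, outdir, tracks: bool = False) -> dict:
    """Write the annotation, counts and ground truth as plain-text files."""
    from pathlib import Path

    from .intervals import write_gene_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    write_gene_table(truth.genes, out / "genes.tsv")
    truth.regions.to_csv(out / "regions.tsv", sep="\t", index=False)
    truth.region_set().to_bed(out / "regions.bed", summit_column=True)
    truth.ervs.to_csv(out / "ervs.tsv", sep="\t", index=False)
    truth.erv_set().to_bed(out / "ervs.bed")
    truth.enhancers.to_csv(out / "enhancers.tsv", sep="\t", index=False)
    truth.suz12_peaks().to_bed(out / "suz12_peaks.bed")
    (out / "bivalent_genes.txt").write_text("\n".join(truth.bivalent_genes) + "\n")
    sims = simulate_counts(truth)
    sims.gene_counts.to_csv(out / "gene_counts.tsv", sep="\t")
    sims.te_counts.to_csv(out / "te_counts.tsv", sep="\t")
    sims.peak_signal.to_csv(out / "peak_signal.tsv", sep="\t", float_format="%.6g")
    sims.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    ground = {
        "links": truth.links.to_dict(orient="records"),
        "gene_direction": truth.gene_direction,
        "te_direction": truth.te_direction,
        "bivalent_genes": truth.bivalent_genes,
        "region_class": dict(zip(truth.regions["name"], truth.regions["class"])),
        "region_erv_overlap": truth.region_erv_overlap,
        "warnings": truth.warnings,
    }
    (out / "ground_truth.json").write_text(json.dumps(ground, indent=1, sort_keys=True))
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=1, sort_keys=True, default=list)
    )
    written = {p.name: p for p in sorted(out.iterdir())}
    if tracks:
        tdir = out / "tracks"
        tdir.mkdir(exist_ok=True)
        for mark in MARKS:
            for geno in cfg.groups:
                for rep in range(1, cfg.replicates_per_group + 1):
                    trk = simulate_tracks(truth, mark, geno, rep)
                    trk.to_bedgraph(tdir / f"{mark}_{geno}_r{rep}.bedgraph")
    return written
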