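"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes the stages in dependency order on a simulated
dataset: simulate -> differential (genes, TE subfamilies, regions) ->
k-means clustering -> ERV overlap/enrichment -> TE shuffle enrichment ->
peak-gene linkage -> bivalent promoter calling -> H3K27me3 spreading ->
report.  Every run is fully determined by (config, seed); the JSON report
records per-stage outputs, checksums, counts and warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, linkage, states, synth
from .enrich import format_percent, te_shuffle_enrichment, two_proportion_z
from .intervals import RegionSet, annotate_regions, consensus_peaks, overlap_counts
from .tracks import signal_matrix

log = logging.getLogger("cryptic_cre")

STAGES = (
    "simulate",
    "differential",
    "cluster",
    "enrich",
    "te_enrich",
    "link",
    "bivalent",
    "spreading",
)

DEPENDENCIES = {
    "differential": [("simulate", "counts table")],
    "cluster": [("differential", "DA-region table")],
    "enrich": [("cluster", "cluster assignment")],
    "te_enrich": [("simulate", "region and ERV annotation")],
    "link": [("differential", "differential gene table"), ("cluster", "cluster assignment")],
    "bivalent": [("simulate", "replicate peak calls")],
    "spreading": [("simulate", "H3K27me3 tracks")],
}

_KNOWN_KEYS = {
    "outdir",
    "seed",
    "stages",
    "synth",
    "region_lfc_cut",
    "gene_lfc_cut",
    "te_lfc_cut",
    "padj_cut",
    "link_max_dist",
    "link_fdr_cut",
    "te_iterations",
    "te_p_cut",
    "te_lfc_enrich_cut",
    "kmeans_restarts",
}


@dataclass
class RunConfig:
    """All stage parameters with their module defaults; unknown keys rejected."""

    outdir: str = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    synth: dict = field(default_factory=dict)
    region_lfc_cut: float = 0.8
    gene_lfc_cut: float = 1.0
    te_lfc_cut: float = 1.5
    padj_cut: float = 0.05
    link_max_dist: int = 50_000
    link_fdr_cut: float = 0.2
    te_iterations: int = 20
    te_p_cut: float = 0.01
    te_lfc_enrich_cut: float = 1.0
    kmeans_restarts: int = 10

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "stages" in d:
            bad = set(d["stages"]) - set(STAGES)
            if bad:
                raise ValueError(f"unknown stages: {sorted(bad)}")
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _check_deps(stage: str, done: set[str], enabled: set[str]) -> None:
    for dep, artifact in DEPENDENCIES.get(stage, []):
        if dep not in done:
            raise RuntimeError(
                f"stage '{stage}' requires the {artifact} from stage '{dep}', "
                "which did not run"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the run report dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    done: set[str] = set()
    ctx: dict = {}
    caught: list[str] = []

    def finish(stage: str, outputs: list[Path], counts: dict) -> None:
        report["stages"][stage] = {
            "outputs": {p.name: _sha(p) for p in outputs},
            "counts": counts,
            "warnings": list(caught),
        }
        caught.clear()
        done.add(stage)
        log.info("stage %s done: %s", stage, counts)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        for stage in STAGES:
            if stage not in enabled:
                continue
            _check_deps(stage, done, enabled)
            caught.extend(str(w.message) for w in wlist)
            del wlist[:]
            fn = globals()[f"_stage_{stage}"]
            outputs, counts = fn(config, ctx, out)
            caught.extend(str(w.message) for w in wlist)
            del wlist[:]
            finish(stage, outputs, counts)

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, ctx: dict, out: Path):
    scfg = synth.SynthConfig(**{**config.synth, "seed": config.seed})
    truth = synth.build_genome(scfg)
    sims = synth.simulate_counts(truth)
    simdir = out / "sim"
    synth.write_dataset(truth, simdir)
    ctx["truth"] = truth
    ctx["sims"] = sims
    return sorted(simdir.iterdir()), {
        "genes": len(truth.genes),
        "regions": len(truth.regions),
        "ervs": len(truth.ervs),
        "samples": len(sims.sample_sheet),
    }


def _stage_differential(config: RunConfig, ctx: dict, out: Path):
    truth: synth.GroundTruth = ctx["truth"]
    sims: synth.SimCounts = ctx["sims"]
    sheet = sims.sample_sheet
    outputs = []
    counts = {}
    mutants = [g for g in truth.config.groups if g != "control"]
    ctx["diff_genes"] = {}
    for mut in mutants:
        res = diffexpr.run_differential(
            sims.gene_counts, sheet, (mut, "control"),
            padj_cut=config.padj_cut, lfc_cut=config.gene_lfc_cut, seed=config.seed,
        )
        p = out / f"diff_genes_{mut}.tsv"
        res.to_csv(p, sep="\t")
        outputs.append(p)
        ctx["diff_genes"][mut] = res
        counts[f"deg_{mut}"] = int((res["status"] != "ns").sum())
    # TE matrices are small and mostly responsive; normalize with the
    # gene-derived factors instead of the TE matrix's own ratios
    gene_factors = diffexpr.size_factors(sims.gene_counts)
    te = diffexpr.run_differential(
        sims.te_counts, sheet, ("K9A", "control"),
        padj_cut=config.padj_cut, lfc_cut=config.te_lfc_cut, seed=config.seed,
        factors=gene_factors,
    )
    p = out / "diff_te_K9A.tsv"
    te.to_csv(p, sep="\t")
    outputs.append(p)
    ctx["diff_te"] = te
    counts["te_up_K9A"] = int((te["status"] == "up").sum())

    # region-level differential on per-region H3K9me3 signal
    regions = truth.region_set()
    sig = {}
    for geno in ("control", "K9A"):
        for rep in range(1, truth.config.replicates_per_group + 1):
            trk = synth.simulate_tracks(truth, "H3K9me3", geno, rep)
            sig[f"{geno}_r{rep}"] = [
                trk.region_sum(r.chrom, int(r.start), int(r.end))
                for r in regions.df.itertuples(index=False)
            ]
    region_mat = pd.DataFrame(sig, index=regions.names)
    rsheet = sheet[sheet["sample"].isin(region_mat.columns)]
    # tracks are RPGC-normalized, so region signal needs no size factoring
    da = diffexpr.run_differential(
        region_mat, rsheet, ("K9A", "control"),
        padj_cut=config.padj_cut, lfc_cut=config.region_lfc_cut, seed=config.seed,
        factors=pd.Series(1.0, index=region_mat.columns),
    )
    p = out / "diff_regions_H3K9me3.tsv"
    da.to_csv(p, sep="\t")
    outputs.append(p)
    ctx["da_regions"] = da
    counts["da_regions"] = int((da["status"] != "ns").sum())
    return outputs, counts


def _stage_cluster(config: RunConfig, ctx: dict, out: Path):
    truth: synth.GroundTruth = ctx["truth"]
    da = ctx["da_regions"]
    da_ids = da.index[da["status"] == "down"]
    regions = truth.region_set()
    sub = RegionSet(
        regions.df[regions.df["name"].isin(da_ids)], label="DA-H3K9me3"
    )
    reps = range(1, truth.config.replicates_per_group + 1)
    mats = {}
    for geno in ("control", "K9A"):
        rep_mats = [
            signal_matrix(synth.simulate_tracks(truth, "H3K9me3", geno, r), sub)
            for r in reps
        ]
        avg = rep_mats[0]
        avg.values = np.nanmean(np.stack([m.values for m in rep_mats]), axis=0)
        mats[geno] = avg
    assign = states.kmeans_cluster_regions(
        mats["control"], mats["K9A"], restarts=config.kmeans_restarts, seed=config.seed
    )
    p = out / "region_clusters.tsv"
    assign.to_csv(p, sep="\t", index=False)
    ctx["clusters"] = assign
    ctx["da_set"] = sub
    n1 = int((assign["label"] == "Cluster1").sum())
    return [p], {"da_clustered": len(assign), "cluster1": n1, "cluster2": len(assign) - n1}


def _stage_enrich(config: RunConfig, ctx: dict, out: Path):
    truth: synth.GroundTruth = ctx["truth"]
    assign = ctx["clusters"]
    ervs = truth.erv_set()
    genes = truth.genes
    rows = []
    sets = {}
    for cls in ("Cluster1", "Cluster2"):
        ids = assign.loc[assign["label"] == cls, "region_id"]
        sets[cls] = RegionSet(
            truth.regions[truth.regions["name"].isin(ids)][
                ["chrom", "start", "end", "name", "summit"]
            ],
            label=cls,
        )
    sets["nonDA"] = truth.region_set("nonDA")
    counts = {}
    overlap = {}
    for cls, rs in sets.items():
        k, n = overlap_counts(rs, ervs, min_subject_size=500)
        overlap[cls] = (k, n)
        cats = annotate_regions(rs, genes)
        rows.append(
            {
                "class": cls,
                "n": n,
                "erv_overlap_k": k,
                "erv_overlap_pct": format_percent(k, n),
                "pct_distal": format_percent(int((cats == "distal intergenic").sum()), n),
            }
        )
        counts[f"{cls}_erv_pct"] = round(100 * k / n, 1) if n else np.nan
    for cls in ("Cluster1", "Cluster2"):
        z, pv = two_proportion_z(*overlap[cls], *overlap["nonDA"])
        counts[f"p_{cls}_vs_nonDA"] = pv
    tab = pd.DataFrame(rows)
    p = out / "erv_overlap.tsv"
    tab.to_csv(p, sep="\t", index=False)
    ctx["erv_overlap"] = overlap
    return [p], counts


def _stage_te_enrich(config: RunConfig, ctx: dict, out: Path):
    truth: synth.GroundTruth = ctx["truth"]
    signal = truth.region_set("Cluster1")
    te_by_sub = {
        sub: (fam, RegionSet(g[["chrom", "start", "end", "name"]]))
        for (sub, fam), g in truth.ervs.groupby(["subfamily", "family"])
    }
    res = te_shuffle_enrichment(
        signal,
        te_by_sub,
        truth.chrom_sizes(),
        iterations=config.te_iterations,
        seed=config.seed,
        p_cut=config.te_p_cut,
        lfc_cut=config.te_lfc_enrich_cut,
    )
    tab = pd.DataFrame([dataclasses.asdict(r) for r in res])
    p = out / "te_enrichment.tsv"
    tab.to_csv(p, sep="\t", index=False)
    ctx["te_enrichment"] = tab
    return [p], {"subfamilies": len(tab), "enriched": int(tab["enriched"].sum())}


def _stage_link(config: RunConfig, ctx: dict, out: Path):
    truth: synth.GroundTruth = ctx["truth"]
    sims: synth.SimCounts = ctx["sims"]
    assign = ctx["clusters"]
    da_set: RegionSet = ctx["da_set"]
    pairs = linkage.candidate_pairs(da_set, truth.genes, max_dist=config.link_max_dist)
    expr = np.log2(
        diffexpr.normalize(sims.gene_counts, diffexpr.size_factors(sims.gene_counts)) + 1
    )
    links = linkage.correlate_links(
        pairs, sims.peak_signal, expr, fdr_cut=config.link_fdr_cut
    )
    summary = linkage.link_summary(links, ctx["diff_genes"]["K9A"], assign)
    p1 = out / "links.tsv"
    p2 = out / "link_summary.tsv"
    links.to_csv(p1, sep="\t", index=False)
    summary.to_csv(p2, sep="\t", index=False)
    ctx["links"] = links
    any_row = summary[summary["class"] == "any"].iloc[0]
    return [p1, p2], {
        "candidates": len(pairs),
        "retained": int(links["retained"].sum()),
        "linked_genes": int(any_row["n_linked_genes"]),
        "fraction_up": float(any_row["fraction_up"])
        if np.isfinite(any_row["fraction_up"])
        else None,
    }


def _stage_bivalent(config: RunConfig, ctx: dict, out: Path):
    truth: synth.GroundTruth = ctx["truth"]
    reps = range(1, truth.config.replicates_per_group + 1)
    k4 = [synth.make_peak_calls(truth, "H3K4me3", "control", r) for r in reps]
    k27 = [synth.make_peak_calls(truth, "H3K27me3", "control", r) for r in reps]
    suz = consensus_peaks(
        [synth.make_peak_calls(truth, "SUZ12", "control", r) for r in reps]
    )
    suz.df["name"] = [f"SUZ12_{i:05d}" for i in range(len(suz.df))]
    calls = states.call_bivalent_promoters(
        k4, k27, truth.genes, prc2_peaks=suz, tss_flank=truth.config.tss_flank
    )
    p = out / "bivalent_calls.tsv"
    calls.to_csv(p, sep="\t", index=False)
    ctx["bivalent"] = calls
    return [p], {"bivalent_genes": int(calls["bivalent"].sum())}


def _stage_spreading(config: RunConfig, ctx: dict, out: Path):
    truth: synth.GroundTruth = ctx["truth"]
    suz = truth.suz12_peaks()
    reps = range(1, truth.config.replicates_per_group + 1)
    tracks = {
        geno: [synth.simulate_tracks(truth, "H3K27me3", geno, r) for r in reps]
        for geno in truth.config.groups
    }
    summ = states.spreading_analysis(suz, tracks, flank=truth.config.suz12_flank)
    p1 = out / "spreading_per_peak.tsv"
    summ.per_peak.to_csv(p1, sep="\t", index=False)
    ratios = {f"{c}_{z}": v for (c, z), v in summ.zone_ratios.items()}
    p2 = out / "spreading_ratios.json"
    p2.write_text(json.dumps(ratios, indent=1, sort_keys=True))
    ctx["spreading"] = summ
    return [p1, p2], {k: round(v, 4) for k, v in ratios.items()}
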