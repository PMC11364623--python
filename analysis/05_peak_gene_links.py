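"""Peak-gene linkage and the expression of linked genes.

Two runs of the distance-window + correlation linker (FDR 0.2, positive
correlations only):

1. Link-recovery validation in the 12-sample co-variation design
   (genotype effects off, per-region chromatin activity shared with the
   linked gene): precision and recall against the implanted links.
2. Linked-gene expression in a 6-replicate control/K9A design: of the
   genes linked to de-repressed regions, the fraction called upregulated,
   recovering the implanted 82% up-fraction.
"""

import argparse
from pathlib import Path

import numpy as np

from cryptic_cre import diffexpr
from cryptic_cre.enrich import format_percent
from cryptic_cre.intervals import RegionSet
from cryptic_cre.linkage import candidate_pairs, correlate_links, link_summary
from cryptic_cre.synth import SynthConfig, build_genome, simulate_counts


def cluster_regions(truth):
    return RegionSet(
        truth.regions[truth.regions["class"].isin(["Cluster1", "Cluster2"])][
            ["chrom", "start", "end", "name", "summit"]
        ]
    )


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    # 1. recovery under strong per-sample co-variation (12 samples)
    vcfg = SynthConfig(
        seed=args.seed, replicates_per_group=4, groups=("control", "K9A", "K27A"),
        de_log2fc=0.0, te_log2fc=0.0, peak_k9a_shift=(0.0, 0.0),
        activity_sd=1.0, link_coupling=1.0, dispersion=0.05,
        n_links=50, link_max_dist=80_000,
    )
    truth = build_genome(vcfg)
    sims = simulate_counts(truth)
    pairs = candidate_pairs(cluster_regions(truth), truth.genes, max_dist=100_000)
    expr = np.log2(diffexpr.normalize(sims.gene_counts) + 1)
    links = correlate_links(pairs, sims.peak_signal, expr, fdr_cut=0.2)
    links.to_csv(args.outdir / "links_validation.tsv", sep="\t", index=False)
    retained = set(zip(links.loc[links["retained"], "peak_id"],
                       links.loc[links["retained"], "gene_id"]))
    implanted = set(zip(truth.links["region_id"], truth.links["gene_id"]))
    recall = len(retained & implanted) / len(implanted)
    precision = len(retained & implanted) / max(len(retained), 1)
    print(f"link recovery (12 samples, {len(pairs)} candidates, FDR 0.2): "
          f"precision {precision:.2f}, recall {recall:.2f} "
          f"of {len(implanted)} implanted links")

    # 2. linked-gene expression at the 6-replicate scale
    ecfg = SynthConfig(
        seed=args.seed + 1, replicates_per_group=6, groups=("control", "K9A"),
        n_k27a_bivalent_up=0,
    )
    etruth = build_genome(ecfg)
    esims = simulate_counts(etruth)
    diff = diffexpr.run_differential(
        esims.gene_counts, esims.sample_sheet, ("K9A", "control"), seed=args.seed
    )
    classes = dict(zip(etruth.regions["name"], etruth.regions["class"]))
    summary = link_summary(
        etruth.links.rename(columns={"region_id": "peak_id"}), diff, classes
    )
    summary.to_csv(args.outdir / "link_summary.tsv", sep="\t", index=False)
    row = summary.set_index("class").loc["any"]
    print(f"linked genes: {int(row['n_linked_genes'])}, of which "
          f"{int(row['n_up'])} up in K9A -> "
          f"{format_percent(int(row['n_up']), int(row['n_linked_genes']))} "
          f"(implanted up-fraction {ecfg.de_up_fraction:.0%}); "
          f"mean |peak-gene distance| {row['mean_abs_distance']/1e3:.0f} kb")


if __name__ == "__main__":
    main()
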