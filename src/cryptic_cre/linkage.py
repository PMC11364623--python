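"""Distance-window + correlation peak-gene linker.

A simplified enhancer-gene network: candidate (peak, gene) pairs within a
distance window of the TSS, Pearson correlation of per-sample peak signal
with per-sample expression, BH control of the false-discovery rate across
all pairs (FDR 0.2 by default, positive correlations only), and summaries
of the differential expression of linked genes per region class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .intervals import RegionSet

__all__ = ["candidate_pairs", "correlate_links", "link_summary"]


def candidate_pairs(
    peaks: RegionSet, genes: pd.DataFrame, max_dist: int = 250_000
) -> pd.DataFrame:
    """All (peak, gene) pairs with |peak center - TSS| <= max_dist.

    The peak center is the summit when present, else the midpoint.
    Distances are signed by gene strand (positive = downstream of the
    TSS in the direction of transcription).  No uniqueness constraint: a
    peak equidistant from two TSSs in range yields two pairs.
    """
    centers = peaks.centers()
    names = peaks.names
    chroms = peaks.df["chrom"].to_numpy()
    rows = []
    for chrom, sub in genes.groupby("chrom"):
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        tss = sub["tss"].to_numpy()
        strand = sub["strand"].to_numpy()
        gid = sub["gene_id"].to_numpy()
        for i in sel:
            d = centers[i] - tss
            hit = np.abs(d) <= max_dist
            for j in np.flatnonzero(hit):
                signed = int(d[j]) if strand[j] == "+" else -int(d[j])
                rows.append((names[i], gid[j], signed))
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"])


def correlate_links(
    pairs: pd.DataFrame,
    peak_signal: pd.DataFrame,
    expression: pd.DataFrame,
    fdr_cut: float = 0.2,
    positive_only: bool = True,
) -> pd.DataFrame:
    """Pearson correlation per candidate pair with BH-controlled retention.

    ``peak_signal`` (peaks x samples) and ``expression`` (genes x samples)
    must share >= 4 sample columns and be normalized/log-transformed
    upstream.  p comes from the t-transform of r with n-2 df; retained
    links satisfy padj < ``fdr_cut`` and (by default) r > 0, treating
    peaks as activating elements.  Zero-variance pairs are dropped and
    counted in ``.attrs['n_dropped']``.
    """
    shared = [c for c in peak_signal.columns if c in set(expression.columns)]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples between signal and expression")
    n = len(shared)
    X = peak_signal[shared]
    Y = expression[shared]
    out = pairs.copy().reset_index(drop=True)
    rs = np.full(len(out), np.nan)
    dropped = 0
    for i, (pid, gid) in enumerate(zip(out["peak_id"], out["gene_id"])):
        if pid not in X.index or gid not in Y.index:
            dropped += 1
            continue
        x = X.loc[pid].to_numpy(dtype=float)
        y = Y.loc[gid].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            dropped += 1
            continue
        rs[i] = np.corrcoef(x, y)[0, 1]
    valid = ~np.isnan(rs)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rs * np.sqrt(n - 2) / np.sqrt(np.clip(1 - rs**2, 1e-300, None))
    p = np.where(valid, 2 * stats.t.sf(np.abs(t), n - 2), np.nan)
    out["r"] = rs
    out["p"] = p
    out["padj"] = np.nan
    if valid.any():
        out.loc[valid, "padj"] = bh_adjust(pd.Series(p[valid])).to_numpy()
    out["retained"] = valid & (out["padj"] < fdr_cut)
    if positive_only:
        out["retained"] &= out["r"] > 0
    out = out[valid].reset_index(drop=True)
    out.attrs["n_dropped"] = dropped
    return out


def link_summary(
    links: pd.DataFrame,
    diff: pd.DataFrame,
    region_classes: pd.DataFrame | dict,
) -> pd.DataFrame:
    """Per-class counts of linked genes by differential status.

    ``links`` needs peak_id/gene_id (plus optional ``retained`` flag and
    ``distance``); ``diff`` is indexed by gene with a ``status`` column;
    ``region_classes`` maps region id -> class label.  A gene linked to
    >= 1 region of a class counts once for that class, so duplicate links
    to the same gene do not inflate the counts.
    """
    if isinstance(region_classes, pd.DataFrame):
        cls_map = dict(zip(region_classes["region_id"], region_classes["label"]))
    else:
        cls_map = dict(region_classes)
    use = links[links["retained"]] if "retained" in links.columns else links
    peak_col = "peak_id" if "peak_id" in use.columns else "region_id"
    rows = []
    classes = sorted(set(cls_map.values()))
    for cls in classes + ["any"]:
        if cls == "any":
            sub = use[use[peak_col].map(cls_map).notna()]
        else:
            sub = use[use[peak_col].map(cls_map) == cls]
        genes = sorted(set(sub["gene_id"]))
        status = diff.loc[[g for g in genes if g in diff.index], "status"]
        n_up = int((status == "up").sum())
        n_down = int((status == "down").sum())
        rows.append(
            {
                "class": cls,
                "n_linked_genes": len(genes),
                "n_up": n_up,
                "n_down": n_down,
                "n_ns": len(genes) - n_up - n_down,
                "fraction_up": n_up / len(genes) if genes else np.nan,
                "mean_abs_distance": float(np.abs(sub["distance"]).mean())
                if "distance" in sub.columns and len(sub)
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
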