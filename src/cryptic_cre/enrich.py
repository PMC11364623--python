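"""Overlap-proportion and factor-enrichment statistics.

One-sided two-proportion Z-tests for overlap percentages, Fisher's exact
test with the dual-selection rule for factor occupancy (significant both
against the background region set and against the other cluster),
shuffle-based empirical enrichment of signal regions at TE subfamilies,
and the truncating percentage formatter used for printed fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import RegionSet, overlap_bp
from .diffexpr import bh_adjust

__all__ = [
    "two_proportion_z",
    "fisher_exact",
    "dual_enrichment_select",
    "te_shuffle_enrichment",
    "format_percent",
    "TEEnrichment",
]


def two_proportion_z(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "greater"
) -> tuple[float, float]:
    """Pooled two-proportion Z-test without continuity correction.

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with
    phat = (k1 + k2)/(n1 + n2); the one-sided p comes from the upper
    normal tail for ``alternative='greater'``.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("need 0 <= k <= n and n > 0")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        # both proportions at the boundary: no evidence either way
        if p1 == p2:
            return 0.0, 0.5 if alternative != "two-sided" else 1.0
        z = np.inf if p1 > p2 else -np.inf
    else:
        z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    elif alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), float(p)


def fisher_exact(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Conditional hypergeometric exact test on a 2x2 table.

    Two-sided p sums all tables with fixed margins whose probability does
    not exceed the observed one.  A zero row or column gives p = 1 and an
    undefined odds ratio reported as NaN.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(t, alternative=alternative)
    if t[0, 1] == 0 or t[1, 0] == 0:
        odds = float("nan") if (t[0, 0] == 0 or t[1, 1] == 0) else float("inf")
    return float(odds), float(p)


def dual_enrichment_select(
    tables: pd.DataFrame, alpha: float = 0.05, alternative: str = "greater"
) -> pd.DataFrame:
    """Per-factor dual Fisher selection.

    ``tables`` carries one row per factor with the two 2x2 tables as
    columns (a_bg, b_bg, c_bg, d_bg) for cluster-vs-background and
    (a_cl, b_cl, c_cl, d_cl) for cluster-vs-other-cluster.  p-values are
    BH-adjusted within each comparison family; a factor is selected iff
    both adjusted p < alpha.
    """
    res = tables.copy()
    for fam in ("bg", "cl"):
        ors, ps = [], []
        for _, r in tables.iterrows():
            o, p = fisher_exact(
                [[r[f"a_{fam}"], r[f"b_{fam}"]], [r[f"c_{fam}"], r[f"d_{fam}"]]],
                alternative=alternative,
            )
            ors.append(o)
            ps.append(p)
        res[f"odds_{fam}"] = ors
        res[f"p_{fam}"] = ps
        res[f"padj_{fam}"] = bh_adjust(pd.Series(ps, index=tables.index))
    res["selected"] = (res["padj_bg"] < alpha) & (res["padj_cl"] < alpha)
    return res


@dataclass
class TEEnrichment:
    subfamily: str
    family: str
    observed_bp: float
    background_mean_bp: float
    log2_fold_change: float
    p: float
    iterations: int
    enriched: bool
    flagged: bool = False


def te_shuffle_enrichment(
    signal_regions: RegionSet,
    te_by_subfamily: dict[str, tuple[str, RegionSet]],
    chrom_sizes: dict[str, int],
    iterations: int = 20,
    seed: int = 0,
    p_cut: float = 0.01,
    lfc_cut: float = 1.0,
    eps: float = 1.0,
) -> list[TEEnrichment]:
    """Empirical per-subfamily enrichment of signal regions at TE instances.

    Observed statistic: bp overlap of the signal regions with the
    subfamily's instances.  Background: per iteration the signal regions
    are uniformly re-placed within their chromosome (length-preserving)
    and the overlap recomputed.  log2FC uses an epsilon guard; the
    empirical p uses the add-one convention, so its floor is
    1/(1+iterations).  "Enriched" requires both p < p_cut and
    log2FC > lfc_cut.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    for chrom in signal_regions.df["chrom"].unique():
        if chrom not in chrom_sizes:
            raise ValueError(f"chromosome {chrom} missing from chrom_sizes")
    rng = np.random.default_rng(seed)
    shuffles = []
    df = signal_regions.df
    lengths = (df["end"] - df["start"]).to_numpy()
    for _ in range(iterations):
        starts = np.array(
            [
                rng.integers(0, max(chrom_sizes[c] - l, 1))
                for c, l in zip(df["chrom"], lengths)
            ]
        )
        shuffles.append(
            RegionSet(
                pd.DataFrame(
                    {"chrom": df["chrom"], "start": starts, "end": starts + lengths}
                )
            )
        )
    out = []
    for subfam, (family, tes) in sorted(te_by_subfamily.items()):
        if len(tes) == 0:
            out.append(
                TEEnrichment(subfam, family, 0.0, 0.0, 0.0, 1.0, iterations, False, True)
            )
            continue
        obs = overlap_bp(signal_regions, tes)
        bg = np.array([overlap_bp(sh, tes) for sh in shuffles], dtype=float)
        lfc = float(np.log2((obs + eps) / (bg.mean() + eps)))
        p = float((1 + (bg >= obs).sum()) / (1 + iterations))
        out.append(
            TEEnrichment(
                subfam,
                family,
                float(obs),
                float(bg.mean()),
                lfc,
                p,
                iterations,
                enriched=(p < p_cut and lfc > lfc_cut),
            )
        )
    return out


def format_percent(k: int, n: int, decimals: int = 0) -> str:
    """Truncating (floor) percentage formatter, e.g. (31, 37, 1) -> '83.7%'.

    Integer arithmetic keeps the floor exact; the value printed, read back
    and multiplied out never exceeds 100*k/n.
    """
    if n <= 0 or k < 0 or k > n:
        raise ValueError("need 0 <= k <= n and n > 0")
    scaled = (k * 100 * 10**decimals) // n
    if decimals == 0:
        return f"{scaled}%"
    s = str(scaled).rjust(decimals + 1, "0")
    return f"{s[:-decimals]}.{s[-decimals:]}%"
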