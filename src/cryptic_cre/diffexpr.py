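"""Self-contained differential analysis for count matrices.

Median-of-ratios normalization, pseudocounted log2 fold changes, a
moderated-t statistic with permutation (or small-sample t-reference)
p-values, Benjamini-Hochberg adjustment, and thresholded up/down/ns
calls.  The same pipeline serves gene counts, TE-subfamily counts and
per-region summed track signal; the standard thresholds are padj < 0.05
with |log2FC| >= 1 (genes, regions) or >= 1.5 (ERV subfamilies).
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "normalize",
    "log2_fold_change",
    "permutation_test",
    "bh_adjust",
    "call_differential",
    "run_differential",
]

MIN_PERMUTATION_ASSIGNMENTS = 100
MAX_EXACT_ASSIGNMENTS = 2000


def _group_columns(sheet: pd.DataFrame, genotype: str) -> list[str]:
    cols = sheet.loc[sheet["genotype"] == genotype, "sample"].tolist()
    if not cols:
        raise ValueError(f"no samples with genotype {genotype!r} in sample sheet")
    return cols


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    factor_s = median over all-positive features of count_fs / geomean_f.
    Falls back to library-size ratios (with a warning) when no feature is
    positive in every sample.
    """
    counts = matrix.to_numpy(dtype=float)
    allpos = (counts > 0).all(axis=1)
    if allpos.any():
        sub = counts[allpos]
        geo = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / geo[:, None], axis=0)
    else:
        warnings.warn(
            "no feature has positive counts in every sample; "
            "falling back to library-size ratios"
        )
        lib = counts.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("library sizes must be positive")
        factors = lib
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def normalize(matrix: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(matrix)
    return matrix / factors


def log2_fold_change(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    contrast: tuple[str, str],
    pseudocount: float = 1.0,
    factors: pd.Series | None = None,
) -> pd.Series:
    """log2((mean normalized mutant + pc) / (mean normalized control + pc))."""
    mutant, control = contrast
    norm = normalize(matrix, factors)
    m = norm[_group_columns(sheet, mutant)].mean(axis=1)
    c = norm[_group_columns(sheet, control)].mean(axis=1)
    return pd.Series(
        np.log2((m + pseudocount) / (c + pseudocount)), index=matrix.index, name="log2FC"
    )


def _moderated_t(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise moderated t on a (features x samples) log matrix.

    t_f = (mean1 - mean2) / sqrt((s2_f + s0sq) * (1/n1 + 1/n2)), with
    s0sq the median pooled variance over features (variance moderation).
    Degenerate all-constant rows give t = 0.
    """
    g1 = x[:, labels]
    g2 = x[:, ~labels]
    n1, n2 = g1.shape[1], g2.shape[1]
    d = g1.mean(axis=1) - g2.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    s0sq = float(np.median(s2))
    denom = np.sqrt((s2 + s0sq) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        # zero pooled and prior variance: infinite evidence unless d is 0 too
        t = np.where(
            denom > 0, d / np.where(denom > 0, denom, 1.0),
            np.where(d == 0, 0.0, np.sign(d) * np.inf),
        )
    return t


def permutation_test(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    contrast: tuple[str, str],
    n_permutations: int = 999,
    seed: int = 0,
    factors: pd.Series | None = None,
) -> pd.Series:
    """Two-sided p-values for the moderated t on log2(normalized + 1).

    When the number of distinct label assignments C(n1+n2, n1) is at least
    100 the p-value is empirical over label permutations with the add-one
    convention p = (1 + #{|t_perm| >= |t_obs|}) / (1 + #perms), so p is
    never below 1/(1+#perms); up to 2000 assignments the permutation
    distribution is enumerated exactly (tightest attainable floor),
    otherwise ``n_permutations`` random draws are used.  Smaller designs
    fall back to a t reference with n1+n2-2 degrees of freedom.  Features
    constant across all samples get p = 1.
    """
    mutant, control = contrast
    cols1 = _group_columns(sheet, mutant)
    cols2 = _group_columns(sheet, control)
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("need >= 2 replicates per group")
    sub = matrix[cols1 + cols2]
    norm = normalize(sub, factors[cols1 + cols2] if factors is not None else None)
    x = np.log2(norm.to_numpy(dtype=float) + 1.0)
    n1, n2 = len(cols1), len(cols2)
    labels = np.zeros(n1 + n2, dtype=bool)
    labels[:n1] = True
    t_obs = _moderated_t(x, labels)
    # degeneracy is judged on the raw counts: a feature identical across
    # all samples carries no evidence even if size factors differ
    constant = np.ptp(sub.to_numpy(dtype=float), axis=1) == 0

    n_assign = math.comb(n1 + n2, n1)
    if n_assign >= MIN_PERMUTATION_ASSIGNMENTS:
        exceed = np.ones(x.shape[0])  # the +1 of the add-one convention
        if n_assign <= MAX_EXACT_ASSIGNMENTS:
            # exact test: every distinct assignment except the observed one
            n_used = 0
            for combo in itertools.combinations(range(n1 + n2), n1):
                lab = np.zeros(n1 + n2, dtype=bool)
                lab[list(combo)] = True
                if np.array_equal(lab, labels):
                    continue
                exceed += np.abs(_moderated_t(x, lab)) >= np.abs(t_obs)
                n_used += 1
            p = exceed / (1.0 + n_used)
        else:
            rng = np.random.default_rng(seed)
            for _ in range(n_permutations):
                perm = rng.permutation(n1 + n2)
                exceed += np.abs(_moderated_t(x[:, perm], labels)) >= np.abs(t_obs)
            p = exceed / (1.0 + n_permutations)
    else:
        df = n1 + n2 - 2
        p = 2.0 * stats.t.sf(np.abs(t_obs), df)
    p = np.clip(p, 0.0, 1.0)
    p[constant] = 1.0
    return pd.Series(p, index=matrix.index, name="p")


def bh_adjust(p) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; padj in [p, 1]."""
    ser = pd.Series(p)
    padj = multipletests(ser.to_numpy(), method="fdr_bh")[1]
    return pd.Series(padj, index=ser.index, name="padj")


def call_differential(
    results: pd.DataFrame, padj_cut: float = 0.05, lfc_cut: float = 1.0
) -> pd.DataFrame:
    """Attach status: up / down when padj < padj_cut and |log2FC| >= lfc_cut."""
    out = results.copy()
    sig = out["padj"] < padj_cut
    out["status"] = np.where(
        sig & (out["log2FC"] >= lfc_cut),
        "up",
        np.where(sig & (out["log2FC"] <= -lfc_cut), "down", "ns"),
    )
    return out


def run_differential(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    contrast: tuple[str, str],
    padj_cut: float = 0.05,
    lfc_cut: float = 1.0,
    pseudocount: float = 1.0,
    n_permutations: int = 999,
    seed: int = 0,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Full pipeline: normalize, log2FC, test, adjust, call.

    Pass explicit ``factors`` (e.g. all ones) when the matrix is already
    normalized, as for per-region signal from coverage-normalized tracks;
    median-of-ratios assumes most features are unchanged and misbehaves
    when a large fraction shifts in one direction.
    """
    if factors is None:
        factors = size_factors(matrix)
    lfc = log2_fold_change(matrix, sheet, contrast, pseudocount, factors)
    p = permutation_test(matrix, sheet, contrast, n_permutations, seed, factors)
    res = pd.DataFrame(
        {
            "base_mean": normalize(matrix, factors).mean(axis=1),
            "log2FC": lfc,
            "p": p,
            "padj": bh_adjust(p),
        }
    )
    return call_differential(res, padj_cut, lfc_cut)
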