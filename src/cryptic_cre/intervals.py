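"""Genomic interval arithmetic on BED-convention coordinates.

All coordinates are 0-based, half-open ``[start, end)`` throughout.  A
:class:`RegionSet` is a thin, sorted wrapper around a pandas DataFrame and is
the substrate for every overlap, merge and consensus operation in the
package: consensus peak sets across replicates, gap-merging, size-filtered
overlap counting, and the genomic annotation of regions relative to gene
models (promoter / UTR / exon / intron / distal intergenic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "consensus_peaks",
    "merge_within",
    "overlap_counts",
    "intersect_footprint",
    "annotate_regions",
    "read_bed",
    "read_gene_table",
    "write_gene_table",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A single half-open genomic interval.

    ``summit``, when set, is an offset from ``start`` and must lie inside
    the interval.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None
    summit: int | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValueError("summit offset outside interval")

    def __len__(self) -> int:
        return self.end - self.start


class RegionSet:
    """An ordered, normalized collection of genomic intervals.

    The backing frame always carries ``chrom``, ``start``, ``end`` and
    optionally ``strand``, ``name``, ``score``, ``summit``.  Construction
    sorts by (chrom, start, end) and validates coordinates; names, when
    present, must be unique within the set.
    """

    def __init__(self, df: pd.DataFrame, label: str = "", validate: bool = True):
        df = df.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"RegionSet requires a '{col}' column")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if validate and len(df):
            bad = (df["start"] < 0) | (df["start"] >= df["end"])
            if bad.any():
                row = df[bad].iloc[0]
                raise ValueError(
                    f"invalid interval {row['chrom']}:{row['start']}-{row['end']}"
                )
            if "name" in df.columns and df["name"].notna().all():
                if df["name"].duplicated().any():
                    raise ValueError("interval names must be unique within a set")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )
        self.df = df
        self.label = label

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=getattr(row, "strand", "."),
                name=getattr(row, "name", None),
                summit=int(row.summit)
                if "summit" in self.df.columns and not pd.isna(getattr(row, "summit"))
                else None,
            )

    @property
    def names(self) -> list:
        if "name" in self.df.columns:
            return list(self.df["name"])
        return [f"region_{i}" for i in range(len(self.df))]

    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    # -- construction helpers ----------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[tuple], label: str = "", columns: Sequence[str] | None = None
    ) -> "RegionSet":
        cols = list(columns) if columns is not None else ["chrom", "start", "end"]
        return cls(pd.DataFrame.from_records(list(records), columns=cols), label=label)

    def centers(self) -> np.ndarray:
        """Per-interval center: summit position if present, else midpoint."""
        mid = (self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2
        if "summit" in self.df.columns:
            summit = self.df["summit"].to_numpy(dtype=float)
            abs_summit = self.df["start"].to_numpy() + summit
            return np.where(np.isnan(summit), mid, abs_summit).astype(np.int64)
        return mid.astype(np.int64)

    # -- IO ------------------------------------------------------------------
    def to_bed(self, path, summit_column: bool = False) -> None:
        df = self.df
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": df["name"] if "name" in df.columns else self.names,
                "score": df["score"] if "score" in df.columns else 0,
                "strand": df["strand"] if "strand" in df.columns else ".",
            }
        )
        if summit_column and "summit" in df.columns:
            out["summit"] = df["summit"]
        out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, label: str = "") -> RegionSet:
    """Read BED3/BED6 (+ optional 7th summit column), tab-separated."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    cols = BED_COLUMNS[: min(ncol, 6)]
    if ncol > 6:
        cols = cols + ["summit"] + [f"extra{i}" for i in range(ncol - 7)]
    df.columns = cols
    return RegionSet(df, label=label)


# ---------------------------------------------------------------------------
# footprints and sweeps
# ---------------------------------------------------------------------------

def _merged_footprint(df: pd.DataFrame, gap: int = 0) -> dict[str, np.ndarray]:
    """Merge intervals per chromosome; returns chrom -> (n, 2) start/end array.

    Intervals whose gap (next.start - prev.end) <= ``gap`` are merged
    transitively.  ``gap=0`` merges overlapping and book-ended intervals,
    ``gap=-1`` merges strictly overlapping intervals only.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        starts, ends = starts[order], ends[order]
        merged_s, merged_e = [starts[0]], [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged_e[-1] <= gap:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        out[chrom] = np.column_stack([merged_s, merged_e])
    return out


def _footprint_to_regionset(fp: dict[str, np.ndarray], label: str = "") -> RegionSet:
    rows = []
    for chrom in sorted(fp):
        for s, e in fp[chrom]:
            rows.append((chrom, int(s), int(e)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return RegionSet(df, label=label)


def merge_within(regions: RegionSet, gap: int = 500) -> RegionSet:
    """Merge intervals transitively whenever their gap is <= ``gap`` bp.

    The boundary is inclusive: two intervals exactly ``gap`` bp apart merge.
    Total covered bp never decreases.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    if len(regions) == 0:
        return RegionSet(regions.df.copy(), label=regions.label)
    return _footprint_to_regionset(
        _merged_footprint(regions.df, gap=gap), label=regions.label
    )


def consensus_peaks(
    replicate_sets: Sequence[RegionSet], min_support: int = 2
) -> RegionSet:
    """Peaks supported by at least ``min_support`` replicates.

    A base pair is "supported" when >= ``min_support`` distinct replicate
    sets each contribute an overlapping interval there.  The output is the
    union footprint of all replicate peaks that touch a supported run, so
    a consensus peak extends to the outermost boundaries of its supporting
    evidence (occupancy-style consensus), not just the >=k-coverage core.
    """
    if min_support > len(replicate_sets):
        raise ValueError(
            f"min_support={min_support} exceeds number of replicate sets "
            f"({len(replicate_sets)})"
        )
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    # merge each replicate internally so per-replicate depth is 0/1
    rep_fps = [
        _merged_footprint(rs.df, gap=-1) if len(rs) else {} for rs in replicate_sets
    ]
    all_chroms = sorted({c for fp in rep_fps for c in fp})
    out_rows: list[tuple[str, int, int]] = []
    for chrom in all_chroms:
        events: list[tuple[int, int]] = []  # position, +1/-1
        intervals: list[tuple[int, int]] = []
        for fp in rep_fps:
            arr = fp.get(chrom)
            if arr is None:
                continue
            for s, e in arr:
                events.append((int(s), 1))
                events.append((int(e), -1))
                intervals.append((int(s), int(e)))
        if not events:
            continue
        events.sort()
        # supported runs where replicate depth >= min_support
        cores: list[tuple[int, int]] = []
        depth = 0
        run_start = None
        i = 0
        while i < len(events):
            pos = events[i][0]
            while i < len(events) and events[i][0] == pos:
                depth += events[i][1]
                i += 1
            if depth >= min_support and run_start is None:
                run_start = pos
            elif depth < min_support and run_start is not None:
                cores.append((run_start, pos))
                run_start = None
        if not cores:
            continue
        core_starts = np.array([c[0] for c in cores])
        core_ends = np.array([c[1] for c in cores])
        # union footprint of replicate peaks overlapping any core
        supported = []
        for s, e in intervals:
            i0 = np.searchsorted(core_ends, s, side="right")
            i1 = np.searchsorted(core_starts, e, side="left")
            if i0 < i1:
                supported.append((s, e))
        fp = _merged_footprint(
            pd.DataFrame(supported, columns=["start", "end"]).assign(chrom=chrom),
            gap=-1,
        )
        for s, e in fp[chrom]:
            out_rows.append((chrom, int(s), int(e)))
    df = pd.DataFrame(out_rows, columns=["chrom", "start", "end"])
    return RegionSet(df, label="consensus")


def _any_overlap_flags(
    query: RegionSet, subject_fp: dict[str, np.ndarray]
) -> np.ndarray:
    """Boolean per query interval: shares >=1 bp with the subject footprint."""
    flags = np.zeros(len(query), dtype=bool)
    for chrom, sub in query.df.groupby("chrom", sort=False):
        arr = subject_fp.get(chrom)
        if arr is None or not len(arr):
            continue
        starts, ends = arr[:, 0], arr[:, 1]
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        i0 = np.searchsorted(ends, qs, side="right")
        i1 = np.searchsorted(starts, qe, side="left")
        flags[sub.index.to_numpy()] = i0 < i1
    return flags


def overlap_counts(
    query: RegionSet, subject: RegionSet, min_subject_size: int = 0
) -> tuple[int, int]:
    """(k, n): queries with >=1 bp overlap with a size-filtered subject.

    Subject intervals shorter than ``min_subject_size`` bp are ignored
    (the size filter used for ERV instances).  Each query counts once no
    matter how many subjects hit it.
    """
    n = len(query)
    if len(subject) == 0:
        return 0, n
    sub_df = subject.df
    if min_subject_size > 0:
        sub_df = sub_df[(sub_df["end"] - sub_df["start"]) >= min_subject_size]
    if len(sub_df) == 0 or n == 0:
        return 0, n
    fp = _merged_footprint(sub_df, gap=-1)
    return int(_any_overlap_flags(query, fp).sum()), n


def overlap_flags(
    query: RegionSet, subject: RegionSet, min_subject_size: int = 0
) -> np.ndarray:
    """Per-query boolean overlap indicator (same rules as overlap_counts)."""
    if len(subject) == 0 or len(query) == 0:
        return np.zeros(len(query), dtype=bool)
    sub_df = subject.df
    if min_subject_size > 0:
        sub_df = sub_df[(sub_df["end"] - sub_df["start"]) >= min_subject_size]
    if len(sub_df) == 0:
        return np.zeros(len(query), dtype=bool)
    return _any_overlap_flags(query, _merged_footprint(sub_df, gap=-1))


def intersect_footprint(a: RegionSet, b: RegionSet) -> RegionSet:
    """Piecewise intersection of the two sets' merged footprints."""
    fa = _merged_footprint(a.df, gap=-1) if len(a) else {}
    fb = _merged_footprint(b.df, gap=-1) if len(b) else {}
    rows = []
    for chrom in sorted(set(fa) & set(fb)):
        xa, xb = fa[chrom], fb[chrom]
        i = j = 0
        while i < len(xa) and j < len(xb):
            s = max(xa[i, 0], xb[j, 0])
            e = min(xa[i, 1], xb[j, 1])
            if s < e:
                rows.append((chrom, int(s), int(e)))
            if xa[i, 1] < xb[j, 1]:
                i += 1
            else:
                j += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return RegionSet(df)


def overlap_bp(a: RegionSet, b: RegionSet) -> int:
    """Total base pairs shared between the footprints of two sets."""
    return intersect_footprint(a, b).total_bp()


# ---------------------------------------------------------------------------
# gene models and annotation
# ---------------------------------------------------------------------------

GENE_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "tss",
    "exon_starts",
    "exon_ends",
    "biotype",
]

ANNOT_CATEGORIES = [
    "promoter",
    "5'UTR",
    "3'UTR",
    "exon",
    "intron",
    "distal intergenic",
]


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"exon_starts": str, "exon_ends": str})
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def _exon_blocks(row) -> list[tuple[int, int]]:
    starts = [int(x) for x in str(row.exon_starts).split(",") if x != ""]
    ends = [int(x) for x in str(row.exon_ends).split(",") if x != ""]
    return list(zip(starts, ends))


def annotate_regions(
    regions: RegionSet,
    genes: pd.DataFrame,
    promoter_flank: int = 2000,
    utr5_len: int = 200,
    utr3_len: int = 300,
) -> pd.Series:
    """Assign one genomic category to each region by its midpoint.

    Priority: promoter (midpoint within ``promoter_flank`` of a TSS) >
    5'UTR > 3'UTR > exon > intron > distal intergenic.  The midpoint rule
    guarantees exactly one category per region, so category percentages
    sum to 100.  Regions on chromosomes absent from the annotation are
    distal intergenic (with a warning).
    """
    cats = []
    genes_by_chrom = {c: sub for c, sub in genes.groupby("chrom")}
    unknown_chroms = set()
    for row in regions.df.itertuples(index=False):
        mid = (int(row.start) + int(row.end)) // 2
        sub = genes_by_chrom.get(row.chrom)
        if sub is None:
            unknown_chroms.add(row.chrom)
            cats.append("distal intergenic")
            continue
        best = "distal intergenic"
        rank = {c: i for i, c in enumerate(ANNOT_CATEGORIES)}
        for g in sub.itertuples(index=False):
            cat = None
            if abs(mid - int(g.tss)) <= promoter_flank:
                cat = "promoter"
            elif g.start <= mid < g.end:
                exons = _exon_blocks(g)
                in_exon = any(s <= mid < e for s, e in exons)
                if g.strand == "+":
                    utr5 = (exons[0][0], min(exons[0][0] + utr5_len, exons[0][1]))
                    utr3 = (max(exons[-1][1] - utr3_len, exons[-1][0]), exons[-1][1])
                else:
                    utr5 = (max(exons[-1][1] - utr5_len, exons[-1][0]), exons[-1][1])
                    utr3 = (exons[0][0], min(exons[0][0] + utr3_len, exons[0][1]))
                if utr5[0] <= mid < utr5[1]:
                    cat = "5'UTR"
                elif utr3[0] <= mid < utr3[1]:
                    cat = "3'UTR"
                elif in_exon:
                    cat = "exon"
                else:
                    cat = "intron"
            if cat is not None and rank[cat] < rank[best]:
                best = cat
        cats.append(best)
    if unknown_chroms:
        warnings.warn(
            f"regions on chromosomes absent from annotation treated as distal: "
            f"{sorted(unknown_chroms)}"
        )
    return pd.Series(cats, index=regions.df.index, name="category")
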