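"""Binned coverage tracks, normalization and region signal summaries.

A :class:`BinnedTrack` holds one mark x one sample as fixed-width bin
vectors per chromosome (bedGraph-equivalent).  On top of it sit the
normalizations used for ChIP-seq coverage (RPGC 1x scaling, exogenous
spike-in factors), the 40-window signal matrices behind heatmaps and
metaprofiles, and RPKM for nascent-transcription quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import RegionSet

__all__ = [
    "BinnedTrack",
    "SignalMatrix",
    "rpgc_normalize",
    "spike_in_factors",
    "signal_matrix",
    "metaprofile",
    "region_rpkm",
    "read_bedgraph",
]


@dataclass
class BinnedTrack:
    """Fixed-width binned signal, one vector per chromosome.

    ``normalization`` is a provenance tag in {"raw", "RPGC", "spike-scaled"}.
    """

    bin_size: int
    data: dict[str, np.ndarray]
    normalization: str = "raw"

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_size

    def genome_mean(self) -> float:
        total = sum(v.sum() for v in self.data.values())
        nbins = sum(len(v) for v in self.data.values())
        return total / nbins

    def scale(self, factor: float, tag: str | None = None) -> "BinnedTrack":
        return BinnedTrack(
            self.bin_size,
            {c: v * factor for c, v in self.data.items()},
            normalization=tag or self.normalization,
        )

    def region_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Bin values overlapping [start, end); partial bins weighted by
        their covered fraction is *not* applied here -- see region_sum."""
        vec = self.data[chrom]
        b0 = max(start // self.bin_size, 0)
        b1 = min(-(-end // self.bin_size), len(vec))
        return vec[b0:b1]

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Signal integrated over [start, end), weighting partial bins by
        the fraction of the bin covered."""
        vec = self.data[chrom]
        bs = self.bin_size
        start = max(start, 0)
        end = min(end, len(vec) * bs)
        if end <= start:
            return 0.0
        b0, b1 = start // bs, (end - 1) // bs
        if b0 == b1:
            return float(vec[b0] * (end - start) / bs)
        total = vec[b0] * ((b0 + 1) * bs - start) / bs
        total += vec[b1] * (end - b1 * bs) / bs
        if b1 > b0 + 1:
            total += vec[b0 + 1 : b1].sum()
        return float(total)

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        span = min(end, len(self.data[chrom]) * self.bin_size) - max(start, 0)
        if span <= 0:
            return np.nan
        return self.region_sum(chrom, start, end) / (span / self.bin_size)

    # -- IO -----------------------------------------------------------------
    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                vec = self.data[chrom]
                for i, v in enumerate(vec):
                    fh.write(
                        f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{v:.6g}\n"
                    )


def read_bedgraph(path, bin_size: int, normalization: str = "raw") -> BinnedTrack:
    """Read a fixed-step bedGraph whose records tile ``bin_size`` bins."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    data: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom"):
        if ((sub["start"] % bin_size) != 0).any() or (
            (sub["end"] - sub["start"]) != bin_size
        ).any():
            raise ValueError(
                f"bedGraph records on {chrom} are not aligned to {bin_size} bp bins"
            )
        nbins = int(sub["end"].max() // bin_size)
        vec = np.zeros(nbins)
        vec[(sub["start"] // bin_size).to_numpy()] = sub["value"].to_numpy()
        data[chrom] = vec
    return BinnedTrack(bin_size, data, normalization=normalization)


def rpgc_normalize(
    raw: BinnedTrack,
    total_reads: int,
    genome_size: int,
    fragment_length: int = 150,
) -> BinnedTrack:
    """Reads-per-genomic-content (1x coverage) scaling.

    Bin sums are multiplied by ``genome_size / (total_reads x
    fragment_length)`` so that the genome-wide mean bin value is 1x
    coverage when the raw track holds per-bin read counts.
    """
    if total_reads <= 0 or genome_size <= 0 or fragment_length <= 0:
        raise ValueError("totals must be positive")
    factor = genome_size / (total_reads * fragment_length)
    return raw.scale(factor, tag="RPGC")


def spike_in_factors(fly_reads) -> np.ndarray:
    """Exogenous spike-in (ChIP-Rx) scale factors: mean(fly) / fly_s.

    The factors average to 1, so scaling preserves the overall signal
    level while equalizing immunoprecipitation efficiency across samples.
    """
    fly = np.asarray(fly_reads, dtype=float)
    if np.any(fly <= 0):
        raise ValueError("spike-in read counts must be positive")
    f = fly.mean() / fly
    return f / f.mean()


@dataclass
class SignalMatrix:
    """Regions x fixed windows of mean signal around region centers."""

    values: np.ndarray  # (n_regions, n_windows), NaN where off-chromosome
    region_ids: list
    window: int
    flank: int
    oriented: bool = False  # True when minus-strand rows were flipped

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def row_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=1)

    def flip(self, strands) -> "SignalMatrix":
        """Reverse rows on the minus strand; an involution."""
        vals = self.values.copy()
        strands = np.asarray(list(strands))
        vals[strands == "-"] = vals[strands == "-", ::-1]
        return SignalMatrix(
            vals, self.region_ids, self.window, self.flank, oriented=not self.oriented
        )


def signal_matrix(
    track: BinnedTrack,
    centers: RegionSet,
    flank: int = 5000,
    window: int = 250,
    orient_by_strand: bool = False,
) -> SignalMatrix:
    """Mean signal in fixed windows across center +- flank for each region.

    The center is the summit when present, else the midpoint (for TSS sets
    pass 1-bp intervals at the TSS).  Windows truncated by chromosome ends
    become NaN cells, excluded from any downstream averaging.  With
    ``orient_by_strand`` rows of minus-strand regions are reversed so that
    transcription runs left to right.
    """
    if window % track.bin_size != 0:
        raise ValueError(
            f"window ({window}) must be a multiple of the track bin size "
            f"({track.bin_size})"
        )
    if (2 * flank) % window != 0:
        raise ValueError("2*flank must be a multiple of the window width")
    n_win = 2 * flank // window
    bins_per_win = window // track.bin_size
    pts = centers.centers()
    vals = np.full((len(centers), n_win), np.nan)
    chroms = centers.df["chrom"].to_numpy()
    for i, (chrom, center) in enumerate(zip(chroms, pts)):
        if chrom not in track.data:
            continue
        vec = track.data[chrom]
        start_bin = (int(center) - flank) // track.bin_size
        for w in range(n_win):
            b0 = start_bin + w * bins_per_win
            b1 = b0 + bins_per_win
            if b0 < 0 or b1 > len(vec):
                continue
            vals[i, w] = vec[b0:b1].mean()
    mat = SignalMatrix(vals, centers.names, window, flank)
    if orient_by_strand and "strand" in centers.df.columns:
        mat = mat.flip(centers.df["strand"].to_numpy())
    return mat


def metaprofile(matrices: list[SignalMatrix]) -> np.ndarray:
    """Per-window mean profile: regions averaged, then replicates averaged.

    Missing (NaN) cells are excluded at both stages.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    shape = matrices[0].values.shape
    for m in matrices[1:]:
        if m.values.shape != shape or m.oriented != matrices[0].oriented:
            raise ValueError("replicate matrices must share shape and orientation")
    with np.errstate(invalid="ignore"):
        profiles = [np.nanmean(m.values, axis=0) for m in matrices]
        return np.nanmean(np.vstack(profiles), axis=0)


def region_rpkm(
    track: BinnedTrack, regions: RegionSet, total_signal: float
) -> np.ndarray:
    """RPKM_r = signal_in_r x 1e9 / (length_r x total_signal)."""
    if total_signal <= 0:
        raise ValueError("total_signal must be positive")
    out = np.empty(len(regions))
    for i, row in enumerate(regions.df.itertuples(index=False)):
        sig = (
            track.region_sum(row.chrom, int(row.start), int(row.end))
            if row.chrom in track.data
            else 0.0
        )
        out[i] = sig * 1e9 / ((int(row.end) - int(row.start)) * total_signal)
    return out
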