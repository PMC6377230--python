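"""Reference-point signal matrices and replicate correlation.

``reference_point_matrix`` tabulates mean signal in fixed-width bins
around region centers (the figure-style signal metaprofiles);
``pairwise_pearson`` computes replicate correlation on binned read
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gatc import AlignedReadSet
from .intervals import StepSignal, _as_signal
from .peaks import PeakSet

__all__ = [
    "ProfileMatrix",
    "BinnedSignal",
    "CorrelationMatrix",
    "reference_point_matrix",
    "mean_profile",
    "bin_reads",
    "pairwise_pearson",
]

DEFAULT_PROFILE_BIN = 50
DEFAULT_CORR_BIN = 1000


@dataclass
class ProfileMatrix:
    """Regions x bins matrix of mean signal around region centers.

    Bins that extend beyond a chromosome end are absent (NaN) and are
    excluded from column means.
    """

    values: np.ndarray          # regions x bins, NaN = absent
    region_chrom: np.ndarray
    region_center: np.ndarray
    half_width: int
    bin_width: int

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_offsets(self) -> np.ndarray:
        """Left edge of each bin relative to the region center."""
        return -self.half_width + self.bin_width * np.arange(self.n_bins)

    @property
    def n_absent(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass
class BinnedSignal:
    """Per-sample read 5'-end counts in fixed-width genome bins."""

    counts: np.ndarray          # bins x samples
    sample_names: list[str]
    bin_width: int
    bin_chrom: np.ndarray
    bin_start: np.ndarray


@dataclass
class CorrelationMatrix:
    """Sample x sample Pearson r on binned counts."""

    r: np.ndarray
    sample_names: list[str]
    bin_width: int
    n_bins_used: int
    undefined: np.ndarray       # samples with zero variance


def reference_point_matrix(
    signal,
    regions: PeakSet,
    half_width: int,
    bin_width: int = DEFAULT_PROFILE_BIN,
) -> ProfileMatrix:
    """Mean signal per bin over [center - W, center + W) for each region.

    W must be divisible by the bin width.  Each cell is the
    length-weighted mean of the signal over its bin, with uncovered bases
    inside the chromosome counting as 0; bins reaching past either
    chromosome end are absent.
    """
    if half_width % bin_width != 0:
        raise ValueError("half_width must be divisible by bin_width")
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    sig = _as_signal(signal)
    n_bins = 2 * half_width // bin_width
    values = np.full((len(regions), n_bins), np.nan)
    centers = regions.centers
    offsets = -half_width + bin_width * np.arange(n_bins + 1)
    for chrom in np.unique(regions.chrom.astype(str)):
        sel = np.flatnonzero(regions.chrom == chrom)
        clen = sig.chrom_lengths.get(chrom)
        if clen is None:
            raise ValueError(f"regions on chromosome {chrom!r} absent from signal")
        edges = centers[sel][:, None] + offsets[None, :]   # regions x (bins+1)
        lo = edges[:, :-1]
        hi = edges[:, 1:]
        ok = (lo >= 0) & (hi <= clen)
        means = sig.window_means(
            chrom, np.maximum(lo, 0).ravel(), np.minimum(hi, clen).ravel()
        ).reshape(lo.shape)
        values[sel] = np.where(ok, means, np.nan)
    return ProfileMatrix(
        values=values,
        region_chrom=regions.chrom.copy(),
        region_center=centers,
        half_width=half_width,
        bin_width=bin_width,
    )


def mean_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Per-bin mean over present cells; all-absent columns are NaN."""
    if matrix.values.size == 0:
        raise ValueError("empty profile matrix")
    with np.errstate(invalid="ignore"):
        return np.nanmean(matrix.values, axis=0)


def bin_reads(
    read_sets: list[AlignedReadSet],
    chrom_lengths: dict[str, int],
    bin_width: int = DEFAULT_CORR_BIN,
) -> BinnedSignal:
    """Count read 5' ends per fixed-width bin (last bin truncated).

    5'-end assignment conserves library size: the bin counts of one
    sample sum to its read count.
    """
    chrom_names = list(chrom_lengths)
    bins_per_chrom = {
        c: int(np.ceil(chrom_lengths[c] / bin_width)) for c in chrom_names
    }
    offsets = {}
    total_bins = 0
    for c in chrom_names:
        offsets[c] = total_bins
        total_bins += bins_per_chrom[c]
    counts = np.zeros((total_bins, len(read_sets)), dtype=np.int64)
    for j, reads in enumerate(read_sets):
        for chrom in np.unique(reads.chrom.astype(str)):
            if chrom not in offsets:
                raise ValueError(f"reads on unknown chromosome {chrom!r}")
            sel = reads.chrom == chrom
            plus = sel & (reads.strand == "+")
            minus = sel & (reads.strand == "-")
            five = np.concatenate(
                [reads.start[plus], reads.end[minus] - 1]
            )
            idx = offsets[chrom] + np.minimum(
                five // bin_width, bins_per_chrom[chrom] - 1
            )
            np.add.at(counts[:, j], idx, 1)
    bin_chrom = np.concatenate(
        [np.full(bins_per_chrom[c], c, dtype=object) for c in chrom_names]
    )
    bin_start = np.concatenate(
        [np.arange(bins_per_chrom[c], dtype=np.int64) * bin_width for c in chrom_names]
    )
    return BinnedSignal(
        counts=counts,
        sample_names=[r.label or f"sample{j}" for j, r in enumerate(read_sets)],
        bin_width=bin_width,
        bin_chrom=bin_chrom,
        bin_start=bin_start,
    )


def pairwise_pearson(
    read_sets: list[AlignedReadSet],
    chrom_lengths: dict[str, int],
    bin_width: int = DEFAULT_CORR_BIN,
) -> CorrelationMatrix:
    """Pearson correlation between samples on binned 5'-end counts.

    Bins that are zero across every sample are excluded.  Samples with
    zero variance over the used bins get undefined (NaN) off-diagonal
    entries and are flagged.
    """
    if len(read_sets) < 2:
        raise ValueError("need >= 2 samples")
    binned = bin_reads(read_sets, chrom_lengths, bin_width)
    used = binned.counts[np.any(binned.counts > 0, axis=1)]
    n_samples = len(read_sets)
    r = np.full((n_samples, n_samples), np.nan)
    np.fill_diagonal(r, 1.0)
    sd = used.std(axis=0) if used.size else np.zeros(n_samples)
    undefined = sd == 0
    if used.shape[0] >= 2:
        x = used.astype(np.float64)
        for i in range(n_samples):
            for j in range(i + 1, n_samples):
                if undefined[i] or undefined[j]:
                    continue
                rij = np.corrcoef(x[:, i], x[:, j])[0, 1]
                r[i, j] = r[j, i] = rij
    return CorrelationMatrix(
        r=r,
        sample_names=binned.sample_names,
        bin_width=bin_width,
        n_bins_used=int(used.shape[0]),
        undefined=undefined,
    )
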