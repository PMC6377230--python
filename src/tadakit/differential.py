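"""Consensus peaks, binding-affinity matrix, and differential occupancy.

Replicate peaksets from two lineages are merged into consensus regions,
extended reads are counted per region into a binding-affinity matrix, and
per-region differential occupancy is tested with a common-dispersion
negative-binomial Wald test (median-of-ratios size factors, method-of-
moments dispersion pooled across regions).  Loci are classified as
A-enriched, B-enriched or not differential at FDR <= 0.01 and >= 2-fold
change by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gatc import AlignedReadSet, ConsistencyError
from .peaks import PeakSet

__all__ = [
    "ConsensusPeakSet",
    "AffinityMatrix",
    "DifferentialResult",
    "build_consensus",
    "count_affinity",
    "test_differential",
]

DEFAULT_FDR_MAX = 0.01
DEFAULT_MIN_FOLD = 2.0
MIN_DISPERSION = 1e-6
_LOG2FC_PSEUDO = 0.5  # applied to group means only when one of them is 0


class InvalidDesignError(ValueError):
    """Experimental design cannot support the requested test."""


@dataclass
class ConsensusPeakSet:
    """Merged intervals supported by >= min_samples replicate peaksets."""

    peaks: PeakSet
    membership: np.ndarray      # regions x peaksets boolean
    set_names: list[str]
    min_samples: int

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def support(self) -> np.ndarray:
        return self.membership.sum(axis=1)


@dataclass
class AffinityMatrix:
    """Consensus regions x samples read-count matrix ("binding affinity")."""

    counts: np.ndarray           # regions x samples, int
    sample_names: list[str]
    groups: np.ndarray           # per-sample group label, e.g. "A"/"B"
    consensus: ConsensusPeakSet
    library_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.groups = np.asarray(self.groups, dtype=object)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape[1] != len(self.sample_names):
            raise ValueError("sample_names/counts shape mismatch")


@dataclass
class DifferentialResult:
    """Per-region differential occupancy calls between groups A and B."""

    table: pd.DataFrame          # chrom,start,end,mean_a,mean_b,log2fc,pvalue,fdr,class
    group_a: str
    group_b: str
    fdr_max: float
    min_fold: float
    size_factors: np.ndarray
    dispersion: float

    def class_peaks(self, cls: str, name: str | None = None) -> PeakSet:
        """Regions of one class ('enriched_A' / 'enriched_B' / ...) as a PeakSet."""
        sub = self.table[self.table["class"] == cls]
        return PeakSet(
            name=name or cls,
            chrom=sub["chrom"].to_numpy(dtype=object),
            start=sub["start"].to_numpy(),
            end=sub["end"].to_numpy(),
            score=-np.log10(np.maximum(sub["fdr"].to_numpy(), 1e-300)),
            qvalue=sub["fdr"].to_numpy(),
            provenance=f"differential:{cls}",
        )


def build_consensus(
    peaksets: list[PeakSet],
    min_samples: int = 2,
) -> ConsensusPeakSet:
    """Merge peaks across replicate sets into consensus intervals.

    Peaks from all sets are chained by >=1-bp overlap into maximal
    connected intervals; an interval is kept when >= min_samples distinct
    peaksets contribute at least one peak to it.
    """
    if not peaksets:
        raise ValueError("need at least one peakset")
    rows = []
    for si, ps in enumerate(peaksets):
        for i in range(len(ps)):
            rows.append((str(ps.chrom[i]), int(ps.start[i]), int(ps.end[i]), si))
    if not rows:
        return ConsensusPeakSet(
            peaks=PeakSet(
                name="consensus",
                chrom=np.empty(0, dtype=object),
                start=np.empty(0, dtype=np.int64),
                end=np.empty(0, dtype=np.int64),
            ),
            membership=np.zeros((0, len(peaksets)), dtype=bool),
            set_names=[ps.name for ps in peaksets],
            min_samples=min_samples,
        )
    rows.sort()
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    members: list[np.ndarray] = []

    cur_chrom, cur_start, cur_end, si = rows[0]
    cur_members = np.zeros(len(peaksets), dtype=bool)
    cur_members[si] = True

    def flush() -> None:
        if cur_members.sum() >= min_samples:
            chroms.append(cur_chrom)
            starts.append(cur_start)
            ends.append(cur_end)
            members.append(cur_members.copy())

    for chrom, s, e, si in rows[1:]:
        if chrom == cur_chrom and s < cur_end:     # >=1 bp overlap chains
            cur_end = max(cur_end, e)
            cur_members[si] = True
        else:
            flush()
            cur_chrom, cur_start, cur_end = chrom, s, e
            cur_members = np.zeros(len(peaksets), dtype=bool)
            cur_members[si] = True
    flush()

    peaks = PeakSet(
        name="consensus",
        chrom=np.asarray(chroms, dtype=object),
        start=np.asarray(starts, dtype=np.int64),
        end=np.asarray(ends, dtype=np.int64),
        provenance=f"consensus(min_samples={min_samples})",
    )
    return ConsensusPeakSet(
        peaks=peaks,
        membership=np.asarray(members, dtype=bool).reshape(len(chroms), len(peaksets)),
        set_names=[ps.name for ps in peaksets],
        min_samples=min_samples,
    )


def count_affinity(
    consensus: ConsensusPeakSet,
    read_sets: list[AlignedReadSet],
    groups: list[str],
    sample_names: list[str] | None = None,
) -> AffinityMatrix:
    """Count extended reads overlapping (>=1 bp) each consensus region."""
    if len(consensus) == 0:
        raise ValueError("consensus peakset is empty")
    if len(read_sets) != len(groups):
        raise ValueError("one group label per read set required")
    peaks = consensus.peaks
    n_regions = len(peaks)
    counts = np.zeros((n_regions, len(read_sets)), dtype=np.int64)
    region_idx_by_chrom: dict[str, np.ndarray] = {}
    for chrom in np.unique(peaks.chrom.astype(str)):
        region_idx_by_chrom[chrom] = np.flatnonzero(peaks.chrom == chrom)
    for j, reads in enumerate(read_sets):
        for chrom, ridx in region_idx_by_chrom.items():
            sel = reads.chrom == chrom
            if not np.any(sel):
                continue
            rs = peaks.start[ridx]
            re_ = peaks.end[ridx]
            s = reads.start[sel]
            e = reads.end[sel]
            # consensus regions are sorted and non-overlapping per chrom
            lo = np.searchsorted(re_, s, side="right")
            hi = np.searchsorted(rs, e, side="left")
            diff = np.zeros(ridx.size + 1, dtype=np.int64)
            valid = hi > lo
            np.add.at(diff, lo[valid], 1)
            np.add.at(diff, hi[valid], -1)
            counts[ridx, j] += np.cumsum(diff[:-1])
    return AffinityMatrix(
        counts=counts,
        sample_names=sample_names or [r.label or f"sample{j}" for j, r in enumerate(read_sets)],
        groups=np.asarray(groups, dtype=object),
        consensus=consensus,
        library_sizes=np.asarray([len(r) for r in read_sets], dtype=np.int64),
    )


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference).

    Only regions with all-positive counts contribute; falls back to
    library-size ratios if no such region exists.
    """
    all_pos = np.all(counts > 0, axis=1)
    if not np.any(all_pos):
        totals = counts.sum(axis=0).astype(np.float64)
        return totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    sub = counts[all_pos].astype(np.float64)
    log_ref = np.mean(np.log(sub), axis=1)
    return np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))


def _pooled_dispersion(norm: np.ndarray, group_masks: list[np.ndarray]) -> float:
    """Method-of-moments NB dispersion pooled across regions and groups.

    For each region and group with positive mean, phi = (var - mean)/mean^2;
    the pooled estimate is the median over all such values, floored at
    MIN_DISPERSION.
    """
    cands = []
    for mask in group_masks:
        sub = norm[:, mask]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        ok = mean > 0
        cands.append(((var[ok] - mean[ok]) / mean[ok] ** 2))
    all_c = np.concatenate(cands) if cands else np.empty(0)
    if all_c.size == 0:
        return MIN_DISPERSION
    return float(max(np.median(all_c), MIN_DISPERSION))


def test_differential(
    matrix: AffinityMatrix,
    group_a: str | None = None,
    group_b: str | None = None,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> DifferentialResult:
    """Common-dispersion NB Wald test of per-region occupancy, A over B.

    Counts are normalized by median-of-ratios size factors; a single NB
    dispersion is estimated by method of moments pooled across regions;
    the Wald statistic tests log2(mean_A/mean_B) with delta-method NB
    variance.  BH FDR across regions; classification uses inclusive
    thresholds (FDR <= fdr_max and |log2FC| >= log2(min_fold)).
    """
    labels = list(dict.fromkeys(matrix.groups))
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise InvalidDesignError("exactly two groups required")
        group_a, group_b = labels[0], labels[1]
    mask_a = matrix.groups == group_a
    mask_b = matrix.groups == group_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise InvalidDesignError("each group needs >= 2 replicates")

    counts = matrix.counts
    sf = _size_factors(counts)
    norm = counts / sf[None, :]

    phi = _pooled_dispersion(norm, [mask_a, mask_b])
    n_a = int(mask_a.sum())
    n_b = int(mask_b.sum())
    mu_a = norm[:, mask_a].mean(axis=1)
    mu_b = norm[:, mask_b].mean(axis=1)

    zero_row = (mu_a == 0) & (mu_b == 0)
    needs_pseudo = (mu_a == 0) | (mu_b == 0)
    eff_a = np.where(needs_pseudo, mu_a + _LOG2FC_PSEUDO, mu_a)
    eff_b = np.where(needs_pseudo, mu_b + _LOG2FC_PSEUDO, mu_b)
    log2fc = np.log2(eff_a / eff_b)

    # delta-method variance of log2 of an NB group mean
    var_a = (eff_a + phi * eff_a**2) / n_a
    var_b = (eff_b + phi * eff_b**2) / n_b
    se = np.sqrt(var_a / eff_a**2 + var_b / eff_b**2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    pvals[zero_row] = 1.0
    fdr = stats.false_discovery_control(pvals, method="bh")

    min_lfc = np.log2(min_fold)
    cls = np.full(counts.shape[0], "not_differential", dtype=object)
    hit = (fdr <= fdr_max) & (np.abs(log2fc) >= min_lfc) & ~zero_row
    cls[hit & (log2fc > 0)] = "enriched_A"
    cls[hit & (log2fc < 0)] = "enriched_B"

    peaks = matrix.consensus.peaks
    table = pd.DataFrame(
        {
            "chrom": peaks.chrom.astype(str),
            "start": peaks.start,
            "end": peaks.end,
            "mean_a": mu_a,
            "mean_b": mu_b,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "class": cls,
        }
    )
    return DifferentialResult(
        table=table,
        group_a=group_a,
        group_b=group_b,
        fdr_max=fdr_max,
        min_fold=min_fold,
        size_factors=sf,
        dispersion=phi,
    )
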