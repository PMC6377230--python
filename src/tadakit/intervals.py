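"""Interval overlap and Monte Carlo enrichment statistics.

The lineage comparisons rest on a small family of custom interval
statistics: >=1-bp overlap counting between peaksets, random peaksets that
preserve each chromosome's peak count and length multiset, Monte Carlo
overlap and signal-ratio tests (Z score, one-sided normal-tail p, and an
empirical p), and a closest-peak-within-distance comparison tested with
Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gatc import RatioTrack
from .peaks import PeakSet

__all__ = [
    "OverlapResult",
    "MonteCarloResult",
    "ClosestResult",
    "StepSignal",
    "overlap",
    "random_peakset",
    "mc_overlap",
    "mean_signal_at",
    "mc_signal_ratio",
    "closest_fisher",
]

DEFAULT_HALF_WIDTH = 2000
DEFAULT_CLOSEST_DIST = 2000


@dataclass
class OverlapResult:
    """Two-way >=1-bp overlap counts between peaksets A and B."""

    n_a: int
    n_b: int
    a_overlapping_b: int
    b_overlapping_a: int

    @property
    def frac_a(self) -> float:
        return self.a_overlapping_b / self.n_a if self.n_a else 0.0

    @property
    def frac_b(self) -> float:
        return self.b_overlapping_a / self.n_b if self.n_b else 0.0


@dataclass
class MonteCarloResult:
    """Observed statistic against a permutation null.

    ``parametric_p`` is the one-sided normal upper-tail probability of the
    observed value under N(null_mean, null_sd); ``empirical_p`` is
    (r + 1)/(n_iter + 1) with r = null draws >= observed.  When the null
    is degenerate (sd = 0) only the empirical p is defined.
    """

    observed: float
    null_mean: float
    null_sd: float
    n_iter: int
    seed: int
    statistic: str = ""
    extra: dict = None  # type: ignore[assignment]

    zscore: float = None        # type: ignore[assignment]
    parametric_p: float = None  # type: ignore[assignment]
    empirical_p: float = None   # type: ignore[assignment]
    degenerate: bool = False

    def to_dict(self) -> dict:
        out = {
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "zscore": self.zscore,
            "parametric_p": self.parametric_p,
            "empirical_p": self.empirical_p,
            "degenerate": self.degenerate,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }
        if self.extra:
            out.update(self.extra)
        return out


def _finalize_mc(
    observed: float,
    null: np.ndarray,
    n_iter: int,
    seed: int,
    statistic: str,
    extra: dict | None = None,
) -> MonteCarloResult:
    null = np.asarray(null, dtype=np.float64)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    r = int(np.sum(null >= observed))
    res = MonteCarloResult(
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        n_iter=n_iter,
        seed=seed,
        statistic=statistic,
        extra=extra or {},
    )
    res.empirical_p = (r + 1) / (n_iter + 1)
    if sd > 0:
        res.zscore = (observed - mean) / sd
        res.parametric_p = float(stats.norm.sf(res.zscore))
    else:
        res.degenerate = True
    return res


@dataclass
class ClosestResult:
    """Distance from query-peak centers to the nearest reference peak edge."""

    distances_a: np.ndarray
    distances_b: np.ndarray
    within_a: int
    within_b: int
    n_a: int
    n_b: int
    distance: int
    table: tuple[tuple[int, int], tuple[int, int]]
    fisher_p: float


def _sorted_by_chrom(peaks: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(peaks.chrom.astype(str)):
        sel = peaks.chrom == chrom
        out[chrom] = (peaks.start[sel], peaks.end[sel])
    return out


def _overlap_flags(query: PeakSet, target: PeakSet) -> np.ndarray:
    """Boolean per query peak: does it overlap any target peak by >=1 bp?"""
    flags = np.zeros(len(query), dtype=bool)
    by_chrom = _sorted_by_chrom(target)
    for chrom, (t_start, t_end) in by_chrom.items():
        sel = np.flatnonzero(query.chrom == chrom)
        if sel.size == 0:
            continue
        qs = query.start[sel]
        qe = query.end[sel]
        # targets are start-sorted but may mutually overlap (randomized
        # sets); the running max of ends answers "does any interval with
        # start < qe reach past qs" exactly
        t_end_cummax = np.maximum.accumulate(t_end)
        hi = np.searchsorted(t_start, qe, side="left")
        has = hi > 0
        has &= np.where(hi > 0, t_end_cummax[np.maximum(hi - 1, 0)] > qs, False)
        flags[sel] = has
    return flags


def overlap(a: PeakSet, b: PeakSet) -> OverlapResult:
    """Count peaks of A overlapping >=1 peak of B (>=1 bp), and vice versa."""
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        a_overlapping_b=int(_overlap_flags(a, b).sum()),
        b_overlapping_a=int(_overlap_flags(b, a).sum()),
    )


def random_peakset(
    reference: PeakSet,
    chrom_lengths: dict[str, int],
    seed: int,
    rng: np.random.Generator | None = None,
) -> PeakSet:
    """Random peaks preserving each chromosome's peak count and lengths.

    Every reference peak is re-placed uniformly on its own chromosome;
    placements are independent, so mutual overlaps are permitted.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    starts = np.empty(len(reference), dtype=np.int64)
    lengths = reference.end - reference.start
    for chrom in np.unique(reference.chrom.astype(str)):
        sel = np.flatnonzero(reference.chrom == chrom)
        clen = chrom_lengths[chrom]
        lens = lengths[sel]
        if np.any(lens > clen):
            raise ValueError(f"peak longer than chromosome {chrom}")
        span = (clen - lens + 1).astype(np.float64)
        starts[sel] = (rng.random(sel.size) * span).astype(np.int64)
    return PeakSet(
        name=f"random:{reference.name}",
        chrom=reference.chrom.copy(),
        start=starts,
        end=starts + lengths,
        provenance=f"random_peakset(seed={seed})",
    )


def mc_overlap(
    a: PeakSet,
    b: PeakSet,
    chrom_lengths: dict[str, int],
    n_iter: int = 100,
    seed: int = 0,
) -> MonteCarloResult:
    """Monte Carlo overlap test: randomize A, keep B fixed.

    Statistic = fraction of A peaks overlapping >=1 B peak.  The null is
    built from ``n_iter`` chromosome-structure-preserving randomizations
    of A.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("peaksets must be non-empty")
    observed = _overlap_flags(a, b).mean()
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        rand_a = random_peakset(a, chrom_lengths, seed=0, rng=rng)
        null[i] = _overlap_flags(rand_a, b).mean()
    return _finalize_mc(
        observed, null, n_iter, seed, statistic="overlap_fraction"
    )


class StepSignal:
    """Piecewise-constant genomic signal supporting fast window means.

    Backed by per-chromosome sorted non-overlapping intervals with a
    cumulative value*length mass, so the mean over any window is two
    interpolated lookups.  Bases not covered by any interval contribute 0.
    """

    def __init__(
        self,
        intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        chrom_lengths: dict[str, int],
    ):
        self.chrom_lengths = dict(chrom_lengths)
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if np.any(ends <= starts):
                raise ValueError("signal intervals must have end > start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"signal intervals overlap on {chrom}")
            cmass = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._data[chrom] = (starts, ends, values, cmass)

    @classmethod
    def from_track(cls, track: RatioTrack) -> "StepSignal":
        frags = track.fragments
        intervals = {}
        lengths = {}
        for chrom in frags.chrom_names:
            lo, hi = frags.chrom_slices[chrom]
            intervals[chrom] = (
                frags.starts[lo:hi], frags.ends[lo:hi], track.values[lo:hi]
            )
            lengths[chrom] = int(frags.boundaries[chrom][-1])
        return cls(intervals, lengths)

    @classmethod
    def from_bedgraph_frame(cls, df, chrom_lengths: dict[str, int]) -> "StepSignal":
        intervals = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            grp = grp.sort_values("start")
            intervals[str(chrom)] = (
                grp["start"].to_numpy(),
                grp["end"].to_numpy(),
                grp["value"].to_numpy(),
            )
        return cls(intervals, chrom_lengths)

    def _mass_at(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the signal over [0, x) per element of x."""
        if chrom not in self._data:
            return np.zeros(np.asarray(x).shape, dtype=np.float64)
        starts, ends, values, cmass = self._data[chrom]
        x = np.asarray(x, dtype=np.float64)
        idx = np.searchsorted(starts, x, side="right") - 1
        idx_c = np.clip(idx, 0, starts.size - 1)
        inside = np.clip(x - starts[idx_c], 0, ends[idx_c] - starts[idx_c])
        mass = cmass[idx_c] + values[idx_c] * inside
        return np.where(idx < 0, 0.0, mass)

    def window_means(
        self, chrom: str, win_start: np.ndarray, win_end: np.ndarray
    ) -> np.ndarray:
        """Length-weighted mean signal over [win_start, win_end), absent=0."""
        win_start = np.asarray(win_start, dtype=np.float64)
        win_end = np.asarray(win_end, dtype=np.float64)
        width = win_end - win_start
        mass = self._mass_at(chrom, win_end) - self._mass_at(chrom, win_start)
        return np.divide(mass, width, out=np.zeros_like(mass), where=width > 0)


def _as_signal(signal) -> StepSignal:
    if isinstance(signal, StepSignal):
        return signal
    if isinstance(signal, RatioTrack):
        return StepSignal.from_track(signal)
    raise TypeError(f"unsupported signal type {type(signal)!r}")


def mean_signal_at(
    regions: PeakSet,
    signal,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> tuple[np.ndarray, float]:
    """Mean signal over each region's center +- half_width, and grand mean.

    Windows are clipped to the chromosome; uncovered bases count as signal
    0.  The grand mean is the unweighted mean of the per-region means,
    matching "average signal at each peak" then averaged over peaks.
    """
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    sig = _as_signal(signal)
    means = np.empty(len(regions))
    centers = regions.centers
    for chrom in np.unique(regions.chrom.astype(str)):
        sel = np.flatnonzero(regions.chrom == chrom)
        clen = sig.chrom_lengths.get(chrom)
        if clen is None:
            raise ValueError(f"regions on chromosome {chrom!r} absent from signal")
        ws = np.clip(centers[sel] - half_width, 0, clen)
        we = np.clip(centers[sel] + half_width, 0, clen)
        means[sel] = sig.window_means(chrom, ws, we)
    return means, float(means.mean())


def mc_signal_ratio(
    signal,
    a: PeakSet,
    b: PeakSet,
    n_iter: int = 1000,
    seed: int = 0,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> MonteCarloResult:
    """Monte Carlo test of the A/B ratio of mean signal around peak centers.

    Observed statistic = (grand mean signal over A windows) / (grand mean
    over B windows); each null draw re-randomizes both peaksets with the
    chromosome-preserving placement and recomputes the ratio.  The raw
    difference (A - B) and its null moments are reported alongside; when
    the B grand mean is exactly 0 the result is difference-only.
    """
    sig = _as_signal(signal)
    chrom_lengths = sig.chrom_lengths
    _, gm_a = mean_signal_at(a, sig, half_width)
    _, gm_b = mean_signal_at(b, sig, half_width)
    rng = np.random.default_rng(seed)
    null_ratio = np.empty(n_iter)
    null_diff = np.empty(n_iter)
    for i in range(n_iter):
        ra = random_peakset(a, chrom_lengths, seed=0, rng=rng)
        rb = random_peakset(b, chrom_lengths, seed=0, rng=rng)
        _, na = mean_signal_at(ra, sig, half_width)
        _, nb = mean_signal_at(rb, sig, half_width)
        null_diff[i] = na - nb
        null_ratio[i] = na / nb if nb != 0 else np.nan

    diff_res = _finalize_mc(
        gm_a - gm_b, null_diff, n_iter, seed, statistic="signal_difference"
    )
    extra = {
        "difference": diff_res.observed,
        "difference_null_mean": diff_res.null_mean,
        "difference_null_sd": diff_res.null_sd,
        "difference_zscore": diff_res.zscore,
        "difference_parametric_p": diff_res.parametric_p,
        "difference_empirical_p": diff_res.empirical_p,
        "grand_mean_a": gm_a,
        "grand_mean_b": gm_b,
        "half_width": half_width,
    }
    valid = np.isfinite(null_ratio)
    if gm_b == 0 or valid.sum() < 2:
        res = MonteCarloResult(
            observed=np.nan, null_mean=np.nan, null_sd=np.nan,
            n_iter=n_iter, seed=seed, statistic="signal_ratio",
            extra=extra, degenerate=True,
        )
        return res
    extra["n_ratio_draws"] = int(valid.sum())
    return _finalize_mc(
        gm_a / gm_b, null_ratio[valid], n_iter, seed,
        statistic="signal_ratio", extra=extra,
    )


def _center_distances(query: PeakSet, reference: PeakSet) -> np.ndarray:
    """Distance from each query center to the nearest reference edge.

    0 when the center lies inside a reference interval.
    """
    dist = np.full(len(query), np.iinfo(np.int64).max, dtype=np.int64)
    by_chrom = _sorted_by_chrom(reference)
    centers = query.centers
    for chrom, (r_start, r_end) in by_chrom.items():
        sel = np.flatnonzero(query.chrom == chrom)
        if sel.size == 0:
            continue
        p = centers[sel]
        # nearest interval at-or-before, and first interval after
        idx = np.searchsorted(r_start, p, side="right") - 1
        idx_c = np.clip(idx, 0, r_start.size - 1)
        end_cummax = np.maximum.accumulate(r_end)
        inside = (idx >= 0) & (p < end_cummax[idx_c])
        d_prev = np.where(idx >= 0, p - (end_cummax[idx_c] - 1), np.iinfo(np.int64).max)
        nxt = np.clip(idx + 1, 0, r_start.size - 1)
        d_next = np.where(idx + 1 < r_start.size, r_start[nxt] - p,
                          np.iinfo(np.int64).max)
        d = np.minimum(np.maximum(d_prev, 0), np.maximum(d_next, 0))
        dist[sel] = np.where(inside, 0, d)
    return dist


def closest_fisher(
    a: PeakSet,
    b: PeakSet,
    reference: PeakSet,
    distance: int = DEFAULT_CLOSEST_DIST,
) -> ClosestResult:
    """Compare how many A vs B peak centers lie within `distance` of a
    reference peak, with a two-sided Fisher exact test on the 2x2 table
    [[within_A, rest_A], [within_B, rest_B]].
    """
    if len(a) == 0 or len(b) == 0 or len(reference) == 0:
        raise ValueError("peaksets must be non-empty")
    da = _center_distances(a, reference)
    db = _center_distances(b, reference)
    wa = int(np.sum(da <= distance))
    wb = int(np.sum(db <= distance))
    table = ((wa, len(a) - wa), (wb, len(b) - wb))
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return ClosestResult(
        distances_a=da,
        distances_b=db,
        within_a=wa,
        within_b=wb,
        n_a=len(a),
        n_b=len(b),
        distance=distance,
        table=table,
        fisher_p=float(p),
    )
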