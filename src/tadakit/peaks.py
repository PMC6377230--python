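"""Fragment-resolution peak calling for TaDa binding and CaTaDa accessibility.

A transparent Poisson caller at GATC-fragment resolution: each fragment's
read count is tested one-sided against an expectation derived either from
a Dam-only control (binding mode) or from the larger of the global and
local read densities (control-free accessibility mode).  Benjamini-
Hochberg FDR is applied genome-wide; runs of significant fragments are
merged into peaks.  This is deliberately a simplified caller: the
downstream lineage comparisons need "significantly bound/open regions",
not any particular caller's internals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gatc import ConsistencyError, FragmentCounts, GATCFragmentTable

__all__ = ["PeakCallConfig", "PeakSet", "call_peaks_ratio", "call_peaks_accessibility"]

MIN_EXPECTATION = 0.25  # global floor on the Poisson expectation


@dataclass
class PeakCallConfig:
    q_threshold: float = 0.05
    merge_gap: int = 1            # fragments of tolerated gap inside a peak
    min_fragments: int = 2        # significant fragments required per peak
    local_lambda_windows: tuple[int, ...] = (5000, 10000)

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if any(w <= 0 for w in self.local_lambda_windows):
            raise ValueError("local-lambda windows must be positive")


@dataclass
class PeakSet:
    """Scored intervals from one sample, sorted by (chrom, start).

    Caller and consensus outputs are non-overlapping within a set;
    randomized sets (interval statistics) may mutually overlap.
    """

    name: str
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    summit: np.ndarray = None       # type: ignore[assignment]
    score: np.ndarray = None        # type: ignore[assignment]
    qvalue: np.ndarray = None       # type: ignore[assignment]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if np.any(self.end <= self.start):
            raise ValueError("peaks must have end > start")
        n = self.start.size
        if self.summit is None:
            self.summit = (self.start + self.end) // 2
        if self.score is None:
            self.score = np.zeros(n)
        if self.qvalue is None:
            self.qvalue = np.full(n, np.nan)
        self.summit = np.asarray(self.summit, dtype=np.int64)
        self.score = np.asarray(self.score, dtype=np.float64)
        self.qvalue = np.asarray(self.qvalue, dtype=np.float64)
        order = np.lexsort((self.start, self.chrom.astype(str)))
        for attr in ("chrom", "start", "end", "summit", "score", "qvalue"):
            setattr(self, attr, getattr(self, attr)[order])

    def __len__(self) -> int:
        return self.start.size

    @property
    def centers(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom.astype(str),
                "start": self.start,
                "end": self.end,
                "summit": self.summit,
                "score": self.score,
                "qvalue": self.qvalue,
            }
        )


def _merge_significant(
    fragments: GATCFragmentTable,
    significant: np.ndarray,
    qvalues: np.ndarray,
    enrichment: np.ndarray,
    cfg: PeakCallConfig,
    name: str,
    provenance: str,
) -> PeakSet:
    """Merge runs of significant fragments (gap <= merge_gap) into peaks."""
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    summits: list[int] = []
    scores: list[float] = []
    qbest: list[float] = []
    for chrom in fragments.chrom_names:
        lo, hi = fragments.chrom_slices[chrom]
        sig_local = np.flatnonzero(significant[lo:hi])
        if sig_local.size == 0:
            continue
        # split where the run of non-significant fragments exceeds merge_gap
        breaks = np.flatnonzero(np.diff(sig_local) > cfg.merge_gap + 1)
        groups = np.split(sig_local, breaks + 1)
        for g in groups:
            if g.size < cfg.min_fragments:
                continue
            gi = g + lo
            best = gi[np.argmin(qvalues[gi])]
            q = qvalues[best]
            chroms.append(chrom)
            starts.append(int(fragments.starts[gi[0]]))
            ends.append(int(fragments.ends[gi[-1]]))
            peak_best = gi[np.argmax(enrichment[gi])]
            summits.append(
                int((fragments.starts[peak_best] + fragments.ends[peak_best]) // 2)
            )
            scores.append(float(-np.log10(max(q, 1e-300))))
            qbest.append(float(q))
    return PeakSet(
        name=name,
        chrom=np.asarray(chroms, dtype=object),
        start=np.asarray(starts, dtype=np.int64),
        end=np.asarray(ends, dtype=np.int64),
        summit=np.asarray(summits, dtype=np.int64),
        score=np.asarray(scores),
        qvalue=np.asarray(qbest),
        provenance=provenance,
    )


def _empty_peakset(name: str, provenance: str) -> PeakSet:
    z = np.empty(0, dtype=np.int64)
    return PeakSet(
        name=name, chrom=np.empty(0, dtype=object), start=z, end=z,
        summit=z.copy(), score=np.empty(0), qvalue=np.empty(0),
        provenance=provenance,
    )


def _call(
    obs: np.ndarray,
    lam: np.ndarray,
    fragments: GATCFragmentTable,
    cfg: PeakCallConfig,
    name: str,
    provenance: str,
) -> PeakSet:
    lam = np.maximum(lam, MIN_EXPECTATION)
    pvals = stats.poisson.sf(obs - 1, lam)  # one-sided upper tail, P(X >= obs)
    qvals = stats.false_discovery_control(pvals, method="bh")
    significant = qvals <= cfg.q_threshold
    if not np.any(significant):
        return _empty_peakset(name, provenance)
    enrichment = obs / lam
    return _merge_significant(
        fragments, significant, qvals, enrichment, cfg, name, provenance
    )


def call_peaks_ratio(
    fusion: FragmentCounts,
    dam: FragmentCounts,
    fragments: GATCFragmentTable,
    cfg: PeakCallConfig | None = None,
    name: str = "tada",
) -> PeakSet:
    """Call binding peaks: fusion counts tested against scaled Dam control.

    Expectation per fragment = dam count x (fusion library / dam library),
    floored at the control's genome-wide density (so zero-control
    fragments are tested against the global background, as narrow-peak
    callers do) and at a hard minimum of 0.25.
    """
    cfg = cfg or PeakCallConfig()
    if fusion.counts.size != dam.counts.size or fusion.counts.size != fragments.n_fragments:
        raise ConsistencyError("fusion/dam/fragment tables do not match")
    if fusion.library_size <= 0 or dam.library_size <= 0:
        raise ValueError("library sizes must be > 0")
    scale = fusion.library_size / dam.library_size
    genome_bp = sum(int(fragments.boundaries[c][-1]) for c in fragments.chrom_names)
    global_lam = dam.counts.sum() / genome_bp * fragments.lengths * scale
    lam = np.maximum(dam.counts * scale, global_lam)
    return _call(
        fusion.counts.astype(np.float64), lam, fragments, cfg, name,
        provenance=f"mode=tada q<={cfg.q_threshold}",
    )


def _interval_mass(boundaries: np.ndarray, density_cum: np.ndarray,
                   lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Integral of a piecewise-constant per-bp density over [lo, hi).

    ``density_cum`` is the cumulative mass at each boundary; inside a
    fragment mass accrues linearly.
    """
    def mass_at(x: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(boundaries, x, side="right") - 1, 0,
                      boundaries.size - 2)
        frac = (x - boundaries[idx]) / (boundaries[idx + 1] - boundaries[idx])
        frac = np.clip(frac, 0.0, 1.0)
        seg = density_cum[idx + 1] - density_cum[idx]
        return density_cum[idx] + frac * seg

    return mass_at(hi) - mass_at(lo)


def call_peaks_accessibility(
    dam: FragmentCounts,
    fragments: GATCFragmentTable,
    cfg: PeakCallConfig | None = None,
    name: str = "catada",
) -> PeakSet:
    """Call open-chromatin peaks from Dam-only counts without a control.

    Per fragment the Poisson expectation is fragment_length x the largest
    of the global read density and the local densities over the configured
    windows centred on the fragment (a local-lambda background, so broad
    enrichment does not inflate its own expectation unchecked).
    """
    cfg = cfg or PeakCallConfig()
    if dam.counts.size != fragments.n_fragments:
        raise ConsistencyError("counts/fragment table do not match")
    if dam.library_size <= 0:
        raise ValueError("library size must be > 0")
    if dam.counts.sum() == 0:
        return _empty_peakset(name, f"mode=catada q<={cfg.q_threshold}")

    genome_bp = sum(
        int(fragments.boundaries[c][-1]) for c in fragments.chrom_names
    )
    global_rate = dam.counts.sum() / genome_bp
    flen = fragments.lengths.astype(np.float64)
    lam = np.full(fragments.n_fragments, global_rate) * flen

    for chrom in fragments.chrom_names:
        lo, hi = fragments.chrom_slices[chrom]
        b = fragments.boundaries[chrom].astype(np.float64)
        clen = b[-1]
        cum = np.concatenate([[0.0], np.cumsum(dam.counts[lo:hi])])
        centers = (fragments.starts[lo:hi] + fragments.ends[lo:hi]) / 2.0
        for w in cfg.local_lambda_windows:
            w_lo = np.clip(centers - w / 2.0, 0.0, clen)
            w_hi = np.clip(centers + w / 2.0, 0.0, clen)
            width = w_hi - w_lo
            mass = _interval_mass(b, cum, w_lo, w_hi)
            local_rate = np.divide(
                mass, width, out=np.zeros_like(mass), where=width > 0
            )
            lam[lo:hi] = np.maximum(lam[lo:hi], local_rate * flen[lo:hi])

    return _call(
        dam.counts.astype(np.float64), lam, fragments, cfg, name,
        provenance=f"mode=catada q<={cfg.q_threshold}",
    )
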