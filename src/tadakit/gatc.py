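"""GATC-fragment coordinate system and normalized DamID ratio tracks.

DamID signal lives at the resolution of *GATC fragments*: the intervals
between successive DpnI cut points (DpnI cuts the methylated GA^TC motif
between A and T, leaving blunt ends).  This module builds that coordinate
system from a genome, extends aligned reads toward their flanking GATC
sites, counts reads per fragment, and computes the normalized
log2(Dam-fusion / Dam-only) ratio track with decile-exclusion
normalization.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeAssembly",
    "GATCMap",
    "GATCFragmentTable",
    "AlignedReadSet",
    "FragmentCounts",
    "RatioTrack",
    "scan_gatc",
    "build_fragments",
    "extend_reads",
    "count_fragments",
    "normalize_decile",
    "coverage_track",
]

DEFAULT_EXTENSION = 300
DEFAULT_PSEUDOCOUNT = 0.5

_VALID_BASES = frozenset("ACGTN")


class ConsistencyError(ValueError):
    """Inputs refer to different genomes / fragment tables."""


class NormalizationError(ValueError):
    """Decile-exclusion normalization could not retain any fragment."""


@dataclass
class GenomeAssembly:
    """Ordered chromosome names, lengths and sequences."""

    names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name in self.names:
            if len(self.sequences[name]) == 0:
                raise ValueError(f"chromosome {name!r} has zero length")

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(self.sequences[n]) for n in self.names}

    @property
    def total_length(self) -> int:
        return sum(len(self.sequences[n]) for n in self.names)


@dataclass
class GATCMap:
    """Per-chromosome sorted DpnI cut coordinates (motif_start + 2)."""

    cuts: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, c in self.cuts.items():
            c = np.asarray(c, dtype=np.int64)
            self.cuts[chrom] = c
            if c.size and (np.any(np.diff(c) <= 0)):
                raise ValueError(f"cuts not strictly increasing on {chrom}")
            if c.size and (c[0] <= 0 or c[-1] >= self.chrom_lengths[chrom]):
                raise ValueError(f"cut outside (0, length) on {chrom}")


@dataclass
class GATCFragmentTable:
    """Fragments tiling each chromosome between successive GATC cuts.

    Fragment ids are global, ordered by chromosome then coordinate.
    ``chrom_slices`` maps each chromosome to its (lo, hi) id range and
    ``boundaries`` holds the fragment edge coordinates per chromosome
    (length = number of local fragments + 1).
    """

    chrom_names: list[str]
    chrom_slices: dict[str, tuple[int, int]]
    boundaries: dict[str, np.ndarray]
    chroms: np.ndarray = field(repr=False)   # per-fragment chromosome name
    starts: np.ndarray = field(repr=False)
    ends: np.ndarray = field(repr=False)

    @property
    def n_fragments(self) -> int:
        return self.starts.size

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def fragment_at(self, chrom: str, pos: int) -> int:
        """Global fragment id containing base ``pos`` of ``chrom``."""
        lo, _ = self.chrom_slices[chrom]
        b = self.boundaries[chrom]
        local = int(np.searchsorted(b, pos, side="right")) - 1
        if local < 0 or local >= b.size - 1:
            raise IndexError(f"position {pos} outside {chrom}")
        return lo + local


@dataclass
class AlignedReadSet:
    """Aligned single-end reads: one (chrom, start, end, strand) per read."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype=object)
        if np.any(self.end <= self.start):
            raise ValueError("reads must have end > start")
        if np.any(self.start < 0):
            raise ValueError("reads must have start >= 0")

    def __len__(self) -> int:
        return self.start.size

    @property
    def library_size(self) -> int:
        return len(self)


@dataclass
class FragmentCounts:
    """Per-fragment read counts for one sample/channel."""

    counts: np.ndarray
    library_size: int
    label: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def cpm(self) -> np.ndarray:
        if self.library_size <= 0:
            raise ValueError("library size must be > 0")
        return self.counts * (1e6 / self.library_size)


@dataclass
class RatioTrack:
    """Per-fragment normalized log2(fusion/Dam) signal — the 'ratio file'.

    value_f = log2((fusion_cpm_f + c) / (dam_cpm_f + c)) − f where f is the
    decile-exclusion normalization factor.
    """

    values: np.ndarray
    factor: float
    pseudocount: float
    fragments: GATCFragmentTable
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratio track must be finite everywhere")


def scan_gatc(genome: GenomeAssembly) -> GATCMap:
    """Locate every GATC motif; cut point at motif_start + 2 (GA^TC).

    Case-insensitive.  Raises on characters outside A/C/G/T/N.
    """
    cuts: dict[str, np.ndarray] = {}
    for name in genome.names:
        seq = genome.sequences[name].upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            pos = min(seq.index(b) for b in bad)
            raise ValueError(
                f"invalid character {seq[pos]!r} at {name}:{pos}"
            )
        found = []
        i = seq.find("GATC")
        while i != -1:
            found.append(i + 2)
            i = seq.find("GATC", i + 1)
        cuts[name] = np.asarray(found, dtype=np.int64)
    return GATCMap(cuts=cuts, chrom_lengths=genome.lengths)


def build_fragments(gatc: GATCMap, genome: GenomeAssembly) -> GATCFragmentTable:
    """Tile each chromosome into fragments between successive cuts."""
    chrom_slices: dict[str, tuple[int, int]] = {}
    boundaries: dict[str, np.ndarray] = {}
    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    offset = 0
    for name in genome.names:
        length = len(genome.sequences[name])
        c = gatc.cuts.get(name, np.empty(0, dtype=np.int64))
        if c.size and c[-1] >= length:
            raise ConsistencyError(f"cut {int(c[-1])} beyond end of {name}")
        b = np.concatenate([[0], c, [length]]).astype(np.int64)
        boundaries[name] = b
        n = b.size - 1
        chrom_slices[name] = (offset, offset + n)
        chroms.append(np.full(n, name, dtype=object))
        starts.append(b[:-1])
        ends.append(b[1:])
        offset += n
    return GATCFragmentTable(
        chrom_names=list(genome.names),
        chrom_slices=chrom_slices,
        boundaries=boundaries,
        chroms=np.concatenate(chroms),
        starts=np.concatenate(starts).astype(np.int64),
        ends=np.concatenate(ends).astype(np.int64),
    )


def extend_reads(
    reads: AlignedReadSet,
    gatc: GATCMap,
    L: int = DEFAULT_EXTENSION,
) -> AlignedReadSet:
    """Extend each read from its 5' end to min(L bp, first GATC cut).

    The read grows in its strand direction until its total length reaches
    ``L`` or it hits the first cut strictly beyond its original 3' end,
    whichever comes first; it is never shortened.  Clipped silently at
    chromosome bounds.
    """
    new_start = reads.start.copy()
    new_end = reads.end.copy()
    for chrom in np.unique(reads.chrom.astype(str)):
        if chrom not in gatc.chrom_lengths:
            raise ConsistencyError(f"read on unknown chromosome {chrom!r}")
        sel = reads.chrom == chrom
        cuts = gatc.cuts.get(chrom, np.empty(0, dtype=np.int64))
        clen = gatc.chrom_lengths[chrom]

        plus = sel & (reads.strand == "+")
        if np.any(plus):
            s = reads.start[plus]
            e = reads.end[plus]
            if cuts.size:
                idx = np.searchsorted(cuts, e, side="right")
                cand = np.where(
                    idx < cuts.size, cuts[np.minimum(idx, cuts.size - 1)], clen + L
                )
            else:
                cand = np.full(s.size, clen + L, dtype=np.int64)
            ne = np.minimum(s + L, cand)
            ne = np.maximum(ne, e)            # never shorter than the read
            new_end[plus] = np.minimum(ne, clen)

        minus = sel & (reads.strand == "-")
        if np.any(minus):
            s = reads.start[minus]
            e = reads.end[minus]
            if cuts.size:
                idx = np.searchsorted(cuts, s, side="left") - 1
                cand = np.where(idx >= 0, cuts[np.maximum(idx, 0)], -L - 1)
            else:
                cand = np.full(s.size, -L - 1, dtype=np.int64)
            ns = np.maximum(e - L, cand)
            ns = np.minimum(ns, s)            # never shorter than the read
            new_start[minus] = np.maximum(ns, 0)
    return AlignedReadSet(
        chrom=reads.chrom.copy(),
        start=new_start,
        end=new_end,
        strand=reads.strand.copy(),
        label=reads.label,
    )


def count_fragments(
    extended: AlignedReadSet,
    fragments: GATCFragmentTable,
    channel: str = "",
) -> FragmentCounts:
    """Count, per fragment, the extended reads overlapping it by >= 1 bp.

    Each read increments every fragment it touches, so the column sum can
    exceed the library size (= the number of reads).
    """
    counts = np.zeros(fragments.n_fragments, dtype=np.int64)
    for chrom in np.unique(extended.chrom.astype(str)):
        if chrom not in fragments.chrom_slices:
            raise ConsistencyError(f"read on unknown chromosome {chrom!r}")
        sel = extended.chrom == chrom
        b = fragments.boundaries[chrom]
        lo, hi = fragments.chrom_slices[chrom]
        s = extended.start[sel]
        e = extended.end[sel]
        first = np.searchsorted(b, s, side="right") - 1
        last = np.searchsorted(b, e - 1, side="right") - 1
        first = np.clip(first, 0, hi - lo - 1)
        last = np.clip(last, 0, hi - lo - 1)
        # difference-array trick: +1 at first, -1 after last, then cumsum
        diff = np.zeros(hi - lo + 1, dtype=np.int64)
        np.add.at(diff, first, 1)
        np.add.at(diff, last + 1, -1)
        counts[lo:hi] += np.cumsum(diff[:-1])
    return FragmentCounts(
        counts=counts,
        library_size=len(extended),
        label=extended.label,
        channel=channel,
    )


def _decile_bins(values: np.ndarray) -> np.ndarray:
    """Equal-frequency decile index (0..9) per element.

    Stable sort: ties are broken by position (fragment id), ascending.
    """
    n = values.size
    order = np.argsort(values, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    return (rank * 10) // n


def normalize_decile(
    fusion: FragmentCounts,
    dam: FragmentCounts,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[float, RatioTrack]:
    """Decile-exclusion normalization of the fusion/Dam log2 ratio.

    Fragments are ranked into equal-frequency deciles independently by
    fusion cpm and by Dam cpm.  The fusion *top* decile (true signal) and
    the Dam *bottom three* deciles (noise) are excluded, as are fragments
    with a zero raw count in either channel.  The normalization factor f
    is the median of log2((fusion_cpm+c)/(dam_cpm+c)) over the retained
    fragments and is subtracted from the track, so the retained-set median
    of the returned track is exactly 0.
    """
    if fusion.counts.size != dam.counts.size:
        raise ConsistencyError("fusion and dam counts on different fragment tables")
    fus_cpm = fusion.cpm()
    dam_cpm = dam.cpm()
    fus_dec = _decile_bins(fus_cpm)
    dam_dec = _decile_bins(dam_cpm)
    retained = (
        (fus_dec != 9)
        & (dam_dec > 2)
        & (fusion.counts > 0)
        & (dam.counts > 0)
    )
    if not np.any(retained):
        raise NormalizationError(
            "no fragments retained by decile exclusion; "
            "review pseudocount / count thresholds"
        )
    ratio = np.log2((fus_cpm + pseudocount) / (dam_cpm + pseudocount))
    factor = float(np.median(ratio[retained]))
    return factor, RatioTrack(
        values=ratio - factor,
        factor=factor,
        pseudocount=pseudocount,
        fragments=None,  # type: ignore[arg-type]  # attached by caller when available
        provenance=f"{fusion.label}/{dam.label}",
    )


def normalize_decile_track(
    fusion: FragmentCounts,
    dam: FragmentCounts,
    fragments: GATCFragmentTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> RatioTrack:
    """Convenience wrapper attaching the fragment table to the track."""
    factor, track = normalize_decile(fusion, dam, pseudocount)
    track.fragments = fragments
    return track


def coverage_track(
    counts: FragmentCounts,
    fragments: GATCFragmentTable,
    log2: bool = False,
) -> RatioTrack:
    """Per-fragment cpm coverage as a signal track (accessibility signal).

    Dam-only coverage is itself the chromatin-accessibility readout; this
    packs it into the same track container the ratio pipeline uses.  With
    ``log2`` the values are log2(cpm + 0.5).
    """
    vals = counts.cpm()
    if log2:
        vals = np.log2(vals + 0.5)
    return RatioTrack(
        values=vals,
        factor=0.0,
        pseudocount=0.0,
        fragments=fragments,
        provenance=f"coverage:{counts.label}",
    )
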