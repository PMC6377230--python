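"""Synthetic DamID experiments encoding the open-chromatin-gates-binding model.

Two neural-stem-cell lineages (A and B) share one genome.  Each lineage has
its own open-chromatin domains plus a shared set; transcription-factor
occupancy is confined to open domains of the matching class.  Dam-only read
counts are proportional to accessibility (untethered Dam methylates open
chromatin); Dam-fusion counts are proportional to accessibility x occupancy.
Replicate counts carry negative-binomial overdispersion.

Reads are emitted as already-aligned intervals (BED6-style records), the
pipeline's true input boundary; alignment itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gatc import (
    AlignedReadSet,
    GATCFragmentTable,
    GenomeAssembly,
    build_fragments,
    scan_gatc,
)

__all__ = [
    "SimConfig",
    "TruthModel",
    "SimulatedExperiment",
    "generate_genome",
    "build_truth",
    "expected_counts",
    "simulate_reads",
    "simulate_experiment",
]

LINEAGES = ("A", "B")
CHANNELS = ("dam_only", "dam_fusion")

DOMAIN_LABELS = ("open_shared", "open_A", "open_B")
BOUND_LABELS = ("bound_shared", "bound_A", "bound_B")


class PlacementError(RuntimeError):
    """Domain placement failed within the retry budget."""


@dataclass
class SimConfig:
    """Study conditions of the default synthetic experiment.

    Defaults emulate a desk-scale version of an embryonic-lineage DamID
    study: a 3 Mb genome at GC 0.5 (mean GATC fragment ~256 bp), hundreds
    of open-chromatin domains per class, bound loci only inside open
    domains of the matching class, four-fold accessibility and occupancy
    effects, 250k reads per sample (about the depth-per-bp of ~10^7 reads
    on a ~140 Mb fly genome) and three replicates per lineage/channel.
    """

    n_chroms: int = 2
    chrom_length: int = 1_500_000
    gc_fraction: float = 0.5
    n_open_shared: int = 60
    n_open_A: int = 120
    n_open_B: int = 120
    open_domain_len: int = 10       # fragments per open domain
    n_bound_shared: int = 40
    n_bound_A: int = 100
    n_bound_B: int = 100
    bound_locus_len: int = 2        # fragments per bound locus
    accessibility_fold: float = 4.0
    occupancy_fold: float = 4.0
    reads_per_sample: int = 250_000
    read_length: int = 75
    nb_dispersion: float = 0.05     # variance = mu + phi * mu^2
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length < 10 * self.read_length:
            raise ValueError(
                "chrom_length must be at least 10 x read_length"
            )
        if not 0 <= self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in [0, 1)")
        for cls in ("shared", "A", "B"):
            if getattr(self, f"n_bound_{cls}") > getattr(self, f"n_open_{cls}"):
                raise ValueError(f"n_bound_{cls} exceeds n_open_{cls}")
        if self.accessibility_fold < 1 or self.occupancy_fold < 1:
            raise ValueError("folds must be >= 1")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 1 <= self.bound_locus_len <= self.open_domain_len:
            raise ValueError("bound_locus_len must be in [1, open_domain_len]")


@dataclass
class TruthModel:
    """Ground-truth accessibility/occupancy per fragment and lineage."""

    accessibility: dict[str, np.ndarray]   # lineage -> per-fragment factor
    occupancy: dict[str, np.ndarray]       # lineage -> per-fragment factor
    domains: pd.DataFrame                  # label, chrom, start, end, frag_lo, frag_hi

    def intervals(self, label: str) -> pd.DataFrame:
        return self.domains[self.domains["label"] == label].reset_index(drop=True)


@dataclass
class SimulatedExperiment:
    genome: GenomeAssembly
    fragments: GATCFragmentTable
    truth: TruthModel
    reads: dict[tuple[str, str, int], AlignedReadSet]
    config: SimConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _derive_seed(seed: int, *tokens) -> int:
    """Stable sub-seed from a global seed and string/int tokens (< 2^31)."""
    import hashlib

    h = hashlib.sha256(repr((int(seed),) + tuple(tokens)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def generate_genome(config: SimConfig) -> GenomeAssembly:
    """I.i.d. nucleotides at the configured GC fraction, per chromosome.

    GATC motifs occur naturally: at GC 0.5 the expected spacing is
    4^4 = 256 bp.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, "genome"))
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sequences = {}
    for name in names:
        draws = rng.choice(4, size=config.chrom_length, p=probs)
        sequences[name] = alphabet[draws].tobytes().decode("ascii")
    return GenomeAssembly(names=names, sequences=sequences)


def _place_domains(
    n_domains: int,
    domain_len: int,
    fragments: GATCFragmentTable,
    occupied: np.ndarray,
    rng: np.random.Generator,
    label: str,
    max_tries: int = 10_000,
) -> list[tuple[int, int]]:
    """Place ``n_domains`` runs of ``domain_len`` whole fragments, no overlap.

    Domains never span chromosome boundaries.  Raises PlacementError when a
    placement cannot be found within the retry budget.
    """
    placed: list[tuple[int, int]] = []
    starts_per_chrom = {
        c: (lo, hi - domain_len)
        for c, (lo, hi) in fragments.chrom_slices.items()
        if hi - lo >= domain_len
    }
    if not starts_per_chrom and n_domains > 0:
        raise PlacementError(
            f"{label}: no chromosome holds {domain_len} fragments"
        )
    chrom_keys = list(starts_per_chrom)
    weights = np.array(
        [starts_per_chrom[c][1] - starts_per_chrom[c][0] + 1 for c in chrom_keys],
        dtype=np.float64,
    )
    weights /= weights.sum()
    for _ in range(n_domains):
        for attempt in range(max_tries):
            c = chrom_keys[rng.choice(len(chrom_keys), p=weights)]
            lo, hi_start = starts_per_chrom[c]
            s = int(rng.integers(lo, hi_start + 1))
            if not occupied[s : s + domain_len].any():
                occupied[s : s + domain_len] = True
                placed.append((s, s + domain_len))
                break
        else:
            raise PlacementError(
                f"could not place {label} domain {len(placed) + 1}/{n_domains} "
                f"of {domain_len} fragments after {max_tries} tries; "
                "genome capacity exceeded"
            )
    return placed


def build_truth(config: SimConfig, fragments: GATCFragmentTable) -> TruthModel:
    """Place open domains and bound loci; assign fold factors per fragment.

    Accessibility is 1 everywhere, x accessibility_fold inside a lineage's
    open domains (shared domains are open in both lineages).  Occupancy is
    1 everywhere, x occupancy_fold at bound loci of the matching lineage.
    Bound loci are sampled only from open domains of the matching class,
    at most one per domain, so binding is open-chromatin-gated by
    construction.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, "truth"))
    n = fragments.n_fragments
    occupied = np.zeros(n, dtype=bool)

    open_counts = {
        "open_shared": config.n_open_shared,
        "open_A": config.n_open_A,
        "open_B": config.n_open_B,
    }
    open_domains: dict[str, list[tuple[int, int]]] = {}
    for label, count in open_counts.items():
        open_domains[label] = _place_domains(
            count, config.open_domain_len, fragments, occupied, rng, label
        )

    bound_counts = {
        "bound_shared": ("open_shared", config.n_bound_shared),
        "bound_A": ("open_A", config.n_bound_A),
        "bound_B": ("open_B", config.n_bound_B),
    }
    bound_loci: dict[str, list[tuple[int, int]]] = {}
    for label, (open_label, count) in bound_counts.items():
        hosts = open_domains[open_label]
        if count > len(hosts):
            raise PlacementError(f"{label}: more loci than {open_label} domains")
        chosen = rng.choice(len(hosts), size=count, replace=False)
        loci = []
        for i in sorted(int(j) for j in chosen):
            lo, hi = hosts[i]
            s = int(rng.integers(lo, hi - config.bound_locus_len + 1))
            loci.append((s, s + config.bound_locus_len))
        bound_loci[label] = loci

    acc = {lin: np.ones(n) for lin in LINEAGES}
    occ = {lin: np.ones(n) for lin in LINEAGES}
    for label, spans in open_domains.items():
        lineages = LINEAGES if label == "open_shared" else (label[-1],)
        for lo, hi in spans:
            for lin in lineages:
                acc[lin][lo:hi] = config.accessibility_fold
    for label, spans in bound_loci.items():
        lineages = LINEAGES if label == "bound_shared" else (label[-1],)
        for lo, hi in spans:
            for lin in lineages:
                occ[lin][lo:hi] = config.occupancy_fold

    rows = []
    for label, spans in {**open_domains, **bound_loci}.items():
        for lo, hi in spans:
            rows.append(
                {
                    "label": label,
                    "chrom": str(fragments.chroms[lo]),
                    "start": int(fragments.starts[lo]),
                    "end": int(fragments.ends[hi - 1]),
                    "frag_lo": lo,
                    "frag_hi": hi,
                }
            )
    domains = pd.DataFrame(
        rows, columns=["label", "chrom", "start", "end", "frag_lo", "frag_hi"]
    ).sort_values(["label", "chrom", "start"], ignore_index=True)
    return TruthModel(accessibility=acc, occupancy=occ, domains=domains)


def expected_counts(
    truth: TruthModel,
    fragments: GATCFragmentTable,
    lineage: str,
    channel: str,
    reads_per_sample: int,
) -> np.ndarray:
    """Per-fragment expected read count mu_f; sums exactly to reads_per_sample.

    mu_f is proportional to fragment length x accessibility (dam_only) or
    length x accessibility x occupancy (dam_fusion).
    """
    w = fragments.lengths * truth.accessibility[lineage]
    if channel == "dam_fusion":
        w = w * truth.occupancy[lineage]
    elif channel != "dam_only":
        raise ValueError(f"unknown channel {channel!r}")
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate truth model: zero total weight")
    return reads_per_sample * (w / total)


def simulate_reads(
    truth: TruthModel,
    fragments: GATCFragmentTable,
    lineage: str,
    channel: str,
    config: SimConfig,
    replicate_seed: int,
    label: str = "",
) -> AlignedReadSet:
    """Draw one replicate's reads.

    Counts per fragment are negative binomial with variance mu + phi*mu^2
    (Poisson when phi = 0), realised as a gamma-Poisson mixture; the total
    equals reads_per_sample in expectation.  Read 5' starts are uniform
    within the fragment, strands Bernoulli(0.5); reads are truncated, not
    discarded, at chromosome ends.
    """
    rng = np.random.default_rng(replicate_seed)
    mu = expected_counts(truth, fragments, lineage, channel, config.reads_per_sample)
    phi = config.nb_dispersion
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        counts = rng.poisson(lam)

    frag_idx = np.repeat(np.arange(fragments.n_fragments), counts)
    total = frag_idx.size
    fs = fragments.starts[frag_idx]
    fl = fragments.lengths[frag_idx]
    five_prime = fs + (rng.random(total) * fl).astype(np.int64)
    minus = rng.random(total) < 0.5

    chrom_len = {c: int(fragments.boundaries[c][-1]) for c in fragments.chrom_names}
    clen_per_frag = np.empty(fragments.n_fragments, dtype=np.int64)
    for c, (lo, hi) in fragments.chrom_slices.items():
        clen_per_frag[lo:hi] = chrom_len[c]
    clen = clen_per_frag[frag_idx]
    start = np.where(minus, np.maximum(five_prime + 1 - config.read_length, 0),
                     five_prime)
    end = np.where(minus, five_prime + 1,
                   np.minimum(five_prime + config.read_length, clen))
    strand = np.where(minus, "-", "+").astype(object)
    return AlignedReadSet(
        chrom=fragments.chroms[frag_idx].copy(),
        start=start,
        end=end,
        strand=strand,
        label=label or f"{lineage}_{channel}",
    )


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Full deterministic experiment: genome, truth, and all replicate reads."""
    genome = generate_genome(config)
    fragments = build_fragments(scan_gatc(genome), genome)
    truth = build_truth(config, fragments)
    reads: dict[tuple[str, str, int], AlignedReadSet] = {}
    for lineage in LINEAGES:
        for channel in CHANNELS:
            for rep in range(1, config.n_replicates + 1):
                seed = _derive_seed(config.seed, "reads", lineage, channel, rep)
                reads[(lineage, channel, rep)] = simulate_reads(
                    truth, fragments, lineage, channel, config, seed,
                    label=f"{lineage}_{channel}_rep{rep}",
                )
    return SimulatedExperiment(
        genome=genome, fragments=fragments, truth=truth, reads=reads, config=config
    )
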