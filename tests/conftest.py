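from __future__ import annotations

import numpy as np
import pytest

from tadakit.gatc import GenomeAssembly, build_fragments, scan_gatc
from tadakit.peaks import PeakSet


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def make_genome(seed: int = 7, lengths: tuple[int, ...] = (30_000, 20_000)) -> GenomeAssembly:
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(len(lengths))]
    return GenomeAssembly(
        names=names,
        sequences={n: random_sequence(rng, L) for n, L in zip(names, lengths)},
    )


def make_peakset(
    rng: np.random.Generator,
    n: int,
    chrom_lengths: dict[str, int],
    min_len: int = 200,
    max_len: int = 2000,
    name: str = "peaks",
) -> PeakSet:
    chroms = list(chrom_lengths)
    ci = rng.integers(0, len(chroms), n)
    lengths = rng.integers(min_len, max_len, n)
    starts = np.array(
        [rng.integers(0, chrom_lengths[chroms[c]] - L) for c, L in zip(ci, lengths)],
        dtype=np.int64,
    )
    return PeakSet(
        name=name,
        chrom=np.array([chroms[c] for c in ci], dtype=object),
        start=starts,
        end=starts + lengths,
    )


@pytest.fixture(scope="session")
def genome() -> GenomeAssembly:
    return make_genome()


@pytest.fixture(scope="session")
def gatc_map(genome):
    return scan_gatc(genome)


@pytest.fixture(scope="session")
def fragments(genome, gatc_map):
    return build_fragments(gatc_map, genome)
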