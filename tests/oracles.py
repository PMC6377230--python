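"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — per-element python loops, quadratic
all-pairs scans, base-resolution averaging, a different sorting route for
the decile normalization — so the oracles share no code path with the
package.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


def naive_scan_gatc(seq: str) -> list[int]:
    """Sliding-window motif scan; cut at motif_start + 2."""
    s = seq.upper()
    return [i + 2 for i in range(len(s) - 3) if s[i : i + 4] == "GATC"]


def naive_extend_read(
    start: int, end: int, strand: str, cuts: list[int], chrom_len: int, L: int
) -> tuple[int, int]:
    """Per-read linear scan for the first cut strictly beyond the 3' end."""
    if strand == "+":
        cand = None
        for c in cuts:
            if c > end:
                cand = c
                break
        new_end = start + L if cand is None else min(start + L, cand)
        new_end = max(new_end, end)
        return start, min(new_end, chrom_len)
    cand = None
    for c in reversed(cuts):
        if c < start:
            cand = c
            break
    new_start = end - L if cand is None else max(end - L, cand)
    new_start = min(new_start, start)
    return max(new_start, 0), end


def naive_fragment_counts(
    reads: list[tuple[int, int]], frag_bounds: list[tuple[int, int]]
) -> list[int]:
    """Quadratic all-pairs >=1-bp overlap counting (one chromosome)."""
    counts = [0] * len(frag_bounds)
    for s, e in reads:
        for i, (fs, fe) in enumerate(frag_bounds):
            if fs < e and fe > s:
                counts[i] += 1
    return counts


def naive_overlap_flags(
    query: list[tuple[str, int, int]], target: list[tuple[str, int, int]]
) -> list[bool]:
    """Quadratic >=1-bp any-overlap flags per query interval."""
    out = []
    for qc, qs, qe in query:
        out.append(
            any(tc == qc and ts < qe and te > qs for tc, ts, te in target)
        )
    return out


def base_array_signal(
    starts: np.ndarray, ends: np.ndarray, values: np.ndarray, chrom_len: int
) -> np.ndarray:
    """Expand a step signal to one value per base (absent = 0)."""
    arr = np.zeros(chrom_len)
    for s, e, v in zip(starts, ends, values):
        arr[s:e] = v
    return arr


def naive_window_mean(base: np.ndarray, start: int, end: int) -> float:
    """Per-base average over a clipped window."""
    start = max(0, start)
    end = min(base.size, end)
    if end <= start:
        return 0.0
    return float(base[start:end].mean())


def naive_decile_normalize(
    fusion_counts: np.ndarray,
    dam_counts: np.ndarray,
    fusion_lib: int,
    dam_lib: int,
    pseudocount: float,
) -> tuple[float, np.ndarray]:
    """Decile-exclusion normalization via an explicit sort-and-slice route.

    Deciles are equal-frequency chunks of the (cpm, fragment_id)-sorted
    list: chunk d covers sorted ranks [ceil(d*n/10), ceil((d+1)*n/10)).
    """
    n = len(fusion_counts)
    fus_cpm = [c * 1e6 / fusion_lib for c in fusion_counts]
    dam_cpm = [c * 1e6 / dam_lib for c in dam_counts]

    def decile_of(cpm: list[float]) -> list[int]:
        order = sorted(range(n), key=lambda i: (cpm[i], i))
        dec = [0] * n
        for d in range(10):
            lo = math.ceil(d * n / 10)
            hi = math.ceil((d + 1) * n / 10)
            for r in range(lo, hi):
                dec[order[r]] = d
        return dec

    fus_dec = decile_of(fus_cpm)
    dam_dec = decile_of(dam_cpm)
    retained = [
        i
        for i in range(n)
        if fus_dec[i] != 9
        and dam_dec[i] >= 3
        and fusion_counts[i] > 0
        and dam_counts[i] > 0
    ]
    ratios = [
        math.log2((fus_cpm[i] + pseudocount) / (dam_cpm[i] + pseudocount))
        for i in range(n)
    ]
    factor = statistics.median(ratios[i] for i in retained)
    return factor, np.array([r - factor for r in ratios])


def poisson_sf(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam), by direct series summation."""
    if k <= 0:
        return 1.0
    # sum P(X < k) then complement
    term = math.exp(-lam)
    total = term
    for i in range(1, k):
        term *= lam / i
        total += term
    return max(0.0, 1.0 - total)


def fisher_two_sided(table: tuple[tuple[int, int], tuple[int, int]]) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed the observed table's (with a tiny relative
    slack for float ties).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def naive_profile_matrix(
    base_by_chrom: dict[str, np.ndarray],
    regions: list[tuple[str, int]],
    half_width: int,
    bin_width: int,
) -> np.ndarray:
    """Base-resolution reference-point matrix; NaN for out-of-chromosome bins."""
    n_bins = 2 * half_width // bin_width
    out = np.full((len(regions), n_bins), np.nan)
    for r, (chrom, center) in enumerate(regions):
        base = base_by_chrom[chrom]
        for k in range(n_bins):
            lo = center - half_width + k * bin_width
            hi = lo + bin_width
            if lo < 0 or hi > base.size:
                continue
            out[r, k] = base[lo:hi].mean()
    return out
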