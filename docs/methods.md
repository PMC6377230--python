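# Methods

This note documents the statistical models, parameter defaults and design
choices behind `tadakit`, and what its synthetic-data tests do and do not
demonstrate about real data.

## Coordinate system

All signal lives on **GATC fragments**: the tiling of each chromosome into
intervals between successive DpnI cut points. The cut coordinate is
`motif_start + 2` (DpnI cuts GA^TC, leaving blunt ends); a chromosome with
k motifs yields k+1 fragments covering it exactly. All coordinates are
0-based half-open, in memory and in every emitted BED/bedGraph/narrowPeak
file.

## Ratio profiling

Reads arrive as aligned intervals (BED6). Each read is extended from its
5' end in its strand direction to a total length of min(300 bp, distance
to the first GATC cut strictly beyond its original 3' end), never
shortened, and clipped at chromosome ends. Extension exists to let a read
reach the flanking cut sites of the methylated fragment it came from,
which is why counting is overlap-based: an extended read increments every
fragment it touches by ≥ 1 bp. Library size is the read count, not the
count sum.

Normalization is by decile exclusion. Counts are converted to cpm;
fragments are ranked into ten equal-frequency bins separately by fusion
cpm and Dam cpm (ties broken by fragment id, stable). Retained fragments
are those **not** in the fusion top decile, **not** in the Dam bottom
three deciles, and with a nonzero raw count in both channels; excluding
the fusion top decile avoids normalizing away true signal and excluding
the Dam bottom deciles suppresses noise-dominated fragments. The
normalization factor is the **median** (robust against residual signal)
of log2((fusion_cpm + c)/(dam_cpm + c)) over the retained set, with
pseudocount c = 0.5 cpm applied after cpm scaling so zero-count fragments
stay finite. By construction the retained-set median of the normalized
track is exactly 0. Deciles are computed on cpm rather than raw counts
for library-size robustness. Note that published DamID pipelines offer
several normalization variants (including kernel-density methods); this
package implements the decile-exclusion procedure only.

## Peak calling

A deliberately transparent stand-in for a narrow-peak caller, operating
at fragment resolution with one-sided (enrichment-only) Poisson tests:

- **Binding (TaDa) mode**: per fragment, P(X ≥ obs) for X ~
  Poisson(λ), λ = Dam count × (fusion library / Dam library), floored at
  the Dam channel's genome-wide density × fragment length (so fragments
  with an empty control are tested against the global background, as
  narrow-peak callers do) and at a hard minimum of 0.25.
- **Accessibility (CaTaDa) mode**, control-free: λ = fragment length ×
  max(global read density, local densities over 5 kb and 10 kb windows
  centred on the fragment). The local-λ background protects against
  regional density fluctuations.

Benjamini–Hochberg FDR is applied across all fragments genome-wide
(q ≤ 0.05 by default). Significant fragments separated by at most one
non-significant fragment are merged; merged runs with fewer than two
significant fragments are dropped. Peak intervals therefore always align
to fragment boundaries and never overlap; the summit is the centre of the
most enriched fragment and the score is −log10 of the best q. Broad-peak
and summit-extension variants are not implemented.

## Differential binding

Replicate peaksets from both lineages are chained by ≥ 1-bp overlap into
maximal connected intervals; intervals supported by at least
`min_samples` (default 2) distinct peaksets form the consensus. Extended
reads are counted per consensus region into the binding-affinity matrix.

The test is a common-dispersion negative-binomial Wald test, a
transparent substitute for shrinkage-based differential packages (whose
numerical replication is explicitly out of scope — the downstream claims
need thresholded classification, not a particular shrinkage estimator):

- size factors by median-of-ratios against a geometric-mean reference
  over all-positive rows (size factors are identified up to a common
  scale; fold changes are invariant);
- one pooled dispersion φ by method of moments, φ = median over
  region × group of (var − mean)/mean², floored at 1e-6;
- per region, log2FC = log2(mean_A/mean_B) of normalized counts (a 0.5
  pseudocount enters only when a group mean is zero), Wald statistic with
  delta-method variance Var(log2 mean) = (μ + φμ²)/(n μ² ln²2), two-sided
  normal p, BH FDR. All-zero rows get p = 1.

Classification is inclusive: enriched_A/enriched_B iff FDR ≤ 0.01 and
|log2FC| ≥ 1 (2-fold), with the sign giving the side.

## Interval statistics

- **Overlap**: ≥ 1 bp counts in both directions, computed by sweep.
- **Random peaksets**: every reference peak is re-placed uniformly on its
  own chromosome, preserving per-chromosome peak counts and length
  multisets exactly; placements are independent, so mutual overlaps are
  permitted.
- **Monte Carlo overlap test**: statistic = fraction of A peaks
  overlapping B; A is randomized (default 100 iterations), B stays
  fixed. Reported: null mean/sd, Z, one-sided normal-tail p, and the
  empirical p = (r+1)/(n+1). The parametric tail is reported because
  overlap enrichments can be far beyond anything 100 draws can resolve
  empirically; when the null is degenerate (sd = 0) only the empirical p
  is defined.
- **Signal-ratio test**: per region, the length-weighted mean signal over
  centre ± 2 kb (uncovered bases count 0); grand mean = unweighted mean
  of the per-region means. The statistic is the A/B ratio of grand means
  (the raw difference is reported alongside); both peaksets are
  re-randomized each of 1000 iterations. If the B grand mean is 0 the
  result is difference-only.
- **Closest + Fisher**: distance from each query-peak centre to the
  nearest reference-peak edge (0 inside); counts within 2 kb for two
  query sets against one reference enter a 2×2 table tested two-sided
  with Fisher's exact test (hypergeometric). The genome-background
  interval Fisher variant is out of scope.

## Metaprofiles and correlation

Reference-point matrices tabulate the length-weighted mean signal in
50-bp bins over centre ± W (W = 5 or 10 kb typical); bins that extend at
all beyond a chromosome end are marked absent and excluded from column
means rather than zero-filled, avoiding edge artefacts. Replicate
correlation is Pearson r on read 5'-end counts in 1-kb bins (5'-end
assignment conserves library size); bins all-zero across every sample are
excluded; raw counts are used.

## Synthetic experiments

The generator encodes the causal model under study — spatial factors
establish lineage-specific open chromatin, and the temporal factor binds
only within it:

- genome: i.i.d. nucleotides at GC 0.5 (mean fragment ≈ 256 bp since a
  4-mer is GATC with probability 4⁻⁴), 2 chromosomes × 1.5 Mb by default;
- truth: open domains of 10 fragments placed uniformly without overlap
  (60 shared, 120 per lineage); bound loci of 2 fragments, at most one
  per open domain of the *matching* class (40 shared, 100 per lineage);
  accessibility ×4 inside a lineage's open domains, occupancy ×4 at its
  bound loci — four-fold effects are an assumption for testability, as no
  effect-size estimates exist for the real data;
- reads: per-fragment expected counts ∝ length × accessibility (Dam-only)
  or length × accessibility × occupancy (fusion), scaled to 250,000 reads
  per sample (≈ the depth-per-bp of ~10⁷ reads on a ~140 Mb genome);
  realized counts are gamma-Poisson (negative binomial, variance
  μ + φμ², φ = 0.05; Poisson at φ = 0), so totals equal the target in
  expectation; read 5' starts uniform within the fragment, strand fair,
  fixed 75-bp length truncated (never discarded) at chromosome ends;
- 3 replicates per lineage × channel; everything derived deterministically
  from one seed via hashed stage/replicate sub-seeds.

What the generator does **not** emulate: sequence composition bias and
mappability, PCR duplicates, sequencing error, GATC-site methylation
saturation, copy-number variation, and continuous (rather than two-level)
accessibility/occupancy. Passing tests therefore demonstrate that the
pipeline's inference is correct *when its model assumptions hold*, not
that those assumptions hold in any particular real dataset.

## Numerical choices and edge cases

- Decile ties broken by fragment id (stable sort); decile of rank r among
  n is ⌊10r/n⌋.
- Empty retained set in normalization raises with advice rather than
  returning NaNs.
- Poisson tails via `scipy.stats.poisson.sf`, BH via
  `scipy.stats.false_discovery_control`, Fisher via
  `scipy.stats.fisher_exact`.
- Monte Carlo null sd uses ddof = 1; Z and the parametric p are omitted
  (flagged degenerate) when sd = 0.
- Peaks/regions are sorted by (chromosome, start) on construction;
  randomized peaksets are the one place mutual overlap is allowed.
- bedGraph values are written at 6 significant digits; canonical-form
  interval files round-trip byte-identically.
- The full pipeline writes a JSON manifest with per-stage summaries and
  SHA-256 hashes of all outputs; repeat runs with one seed are
  hash-identical.

## Default problem sizes

The default configuration (3 Mb genome, ~11,700 fragments, 12 samples ×
250k reads) was chosen so a complete run, including the 1000-iteration
signal test, finishes in well under a minute on a single CPU while
keeping per-fragment counts in the regime of real experiments (tens of
reads per fragment). The acceptance script and test suite run the same
configuration.

## Known limitations

- The peak caller and differential test are simplified stand-ins; they
  reproduce the *role* of narrow-peak calling and shrinkage-based
  differential analysis, not their numerics.
- Chromosome-preserving randomization ignores GC content, assembly gaps
  and mappability; enrichment p-values against this null are
  correspondingly liberal on real genomes.
- The two-query-set Fisher comparison tests A-vs-B proximity counts; it
  does not model genome-wide co-occurrence of query and reference.
- Read QC, alignment, duplicate marking and genome-build liftover are out
  of scope; inputs are assumed aligned and clean.
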