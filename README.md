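# tadakit

Lineage-resolved **Targeted DamID (TaDa)** and **chromatin-accessibility
(CaTaDa)** analysis as a tested, reusable Python pipeline.

DamID maps protein–DNA interactions by expressing a Dam
methyltransferase–transcription factor fusion: Dam methylates adenines in
GATC motifs near the factor's binding sites, and methylated fragments cut
by DpnI (GA^TC) are sequenced. Untethered Dam preferentially methylates
open chromatin, so the Dam-only channel doubles as an accessibility
readout (CaTaDa). `tadakit` implements the full downstream analysis at
**GATC-fragment resolution** — the intervals between successive DpnI cut
points, the natural coordinate system of DamID signal — for the
two-lineage comparison design: which loci does a factor occupy in lineage
A but not lineage B, and is that occupancy gated by lineage-specific open
chromatin?

It is aimed at researchers analysing cell-type-resolved DamID of scarce
cell populations (e.g. individually identifiable neural stem cell
lineages in the fly embryo), where the central claims rest on
differential binding, differential accessibility, and interval-overlap
statistics between the two.

## What it computes

1. **Ratio profiling** (`tadakit.gatc`). Reads are extended from their 5'
   end to 300 bp or the first downstream GATC cut, whichever comes first;
   counted per fragment (≥ 1 bp overlap); and the per-fragment signal

   `value_f = log2((fusion_cpm_f + c) / (dam_cpm_f + c)) − f`

   is normalized by decile exclusion: fragments are ranked into
   equal-frequency deciles by each channel's cpm, the fusion **top decile**
   (true signal) and the Dam **bottom three deciles** (noise) are excluded,
   and `f` is the median log2 ratio of the retained fragments.
2. **Peak calling** (`tadakit.peaks`). A transparent fragment-level
   Poisson caller: one-sided upper-tail tests against a scaled Dam
   control (TaDa binding) or a max(global, local-window) background
   density (CaTaDa accessibility, control-free), Benjamini–Hochberg FDR
   genome-wide, significant fragments merged into peaks.
3. **Differential binding** (`tadakit.differential`). Consensus peaks
   across replicates of both lineages (≥ 1 bp overlap chains, minimum
   support), a consensus-region × sample **binding-affinity matrix** of
   extended-read counts, and a common-dispersion negative-binomial Wald
   test with median-of-ratios size factors. Loci are classified
   A-enriched / B-enriched / not-differential at FDR ≤ 0.01 and ≥ 2-fold.
4. **Interval statistics** (`tadakit.intervals`). ≥ 1-bp overlap
   fractions; Monte Carlo overlap and signal-ratio tests against random
   peaksets that preserve each chromosome's peak count and length
   multiset (Z score, one-sided normal-tail p, empirical p); and a
   closest-peak-within-2-kb comparison tested with Fisher's exact test.
5. **Metaprofiles & QC** (`tadakit.metaprofile`). Reference-point signal
   matrices around peak centers and replicate Pearson correlation on
   binned read counts.
6. **Synthetic experiments** (`tadakit.synthetic`). A generator encoding
   the "open chromatin gates TF binding" model: two lineages share a
   genome; each has specific and shared open-chromatin domains over GATC
   fragments; occupancy is confined to open domains of the matching
   lineage; Dam-only counts follow accessibility, fusion counts follow
   accessibility × occupancy, with negative-binomial replicate noise
   (variance = μ + φμ²). Every downstream stage is testable against this
   known truth with no download.

## Worked example

Run the full pipeline on the default synthetic experiment (3 Mb genome,
100 A-specific + 100 B-specific bound loci inside lineage-specific open
domains, 3 replicates per lineage and channel):

```bash
tadakit run --outdir out/ --seed 1
```

which ends by printing the truth-recovery summary (also in
`out/manifest.json`):

```json
{
  "binding_enriched_A": {"recall": 0.99, "precision": 1.0,
                         "n_predicted": 99, "n_truth": 100},
  "binding_enriched_B": {"recall": 0.97, "precision": 1.0,
                         "n_predicted": 97, "n_truth": 100}
}
```

Reading the rest of `out/`: of the 99 A-enriched binding loci, 93.9%
overlap A-enriched open chromatin (random expectation 12.3%; Monte Carlo
Z = 24.9, p ≈ 6e-137; `mc_overlap_A.json`); the accessibility signal of
lineage A is 2.78× higher around A-enriched than B-enriched binding loci
(random ratio 1.02, p ≈ 1e-72; `signal_ratio.json`); and 97/99 A-enriched
loci have an A-enriched open-chromatin peak within 2 kb of their center
versus 5/97 for B (Fisher p ≈ 9e-47; `closest_fisher.json`). That is the
expected answer: in this synthetic world binding *is* gated by
lineage-specific accessibility by construction, and the pipeline recovers
it.

Individual stages are available as subcommands (`simulate`, `profile`,
`callpeaks`, `diff`, `overlap-test`, `signal-test`, `closest-test`,
`metaprofile`, `correlate`) and as plain library functions.

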