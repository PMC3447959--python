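# Methods

This note records the models, parameter defaults, and numerical choices
behind each pipeline stage, what the synthetic-data generator does and does
not emulate, and the design decisions taken where the method left genuine
freedom. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and domain types

All internal coordinates are 0-based, half-open; GFF3 (1-based inclusive)
is converted at the I/O boundary. Strand `.` orients like `+` wherever a
TSS-relative window is needed, so unstranded annotation behaves
deterministically. Interval-valued track records (bedGraph) map to a point
probe at the floored interval midpoint; fixedStep/variableStep WIG uses the
declared start coordinate — array probes are treated as point measurements.
Genes are assigned to exactly one domain (euchromatin, pericentric
heterochromatin, chr4, chr4-proximal) by the location of their TSS; an
uncovered TSS gets an explicit `unassigned` label rather than being
dropped.

## Enrichment tracks

**Smoothing.** A centered moving average over probes within ± window/2
(default window 500 bp). The probe set is unchanged; the operator preserves
constants and is shift-equivariant. The simplest smoother consistent with
working on "smoothed M-value profiles"; nothing downstream depends on the
choice beyond its bandwidth.

**Region calling.** The null is a Gaussian fitted robustly to the bulk of
the (smoothed) M distribution: the location is the half-sample mode
(recursive shorth), the scale comes from the median absolute deviation of
values *below* the mode (divided by Φ⁻¹(0.75) ≈ 0.6745), so the enriched
right tail cannot inflate it. One-sided p-values feed Benjamini–Hochberg
step-up control at the calling FDR (default 1e-3); significant probes
within a merge gap (default 1,000 bp) are joined and regions with fewer
than 3 significant probes are dropped. Degenerate tracks (zero robust
scale) call nothing; tracks with fewer than 10 probes are rejected. A
caveat that matters in practice: the "bulk" must actually be the unenriched
background — if enriched sequence dominates the genome analysed, the mode
lands in the enriched mass and calls are conservative. The calibration
check in the benchmark (mean false regions per 10,000-probe null track, and
recall / per-base false calls on planted +3σ blocks) quantifies the
operating point.

**Replicate consistency.** Two rules, either sufficient: symmetric target
overlap (fraction of regions in either list overlapping the other) above
75%, or above-80% agreement of the top 40% of targets by score. Overlap is
target-count based by default, with a base-pair variant behind a flag,
since the original rule's units are ambiguous.

**Scaling-factor normalization.** The factor is the ratio of the median
absolute deviations of lagged probe differences (WT over mutant); lagged
differencing cancels additive offsets and any slowly varying enrichment
component, leaving the probe-level noise scale, so a multiplicative
distortion of the mutant track is inverted exactly in the noiseless limit.
A constant mutant track (zero MAD) and mismatched probe grids are hard
errors.

**Quantile normalization.** The reference is the mean of the sorted value
vectors; ties within a track receive the average of the reference values
over the tied ranks. With continuous data (no ties) the sorted output
vectors are bit-identical across tracks and the operation is idempotent;
with ties the averaging necessarily perturbs the sorted vector — true of
any tie-averaging implementation — which is why the exactness benchmark
uses tie-free data and the tie rule is unit-tested against a hand-computed
example.

## Chromatin states

Bins with any missing mark are excluded; marks are z-scored (they have
different dynamic ranges). K-means runs with `k_initial = 10` clusters and
10 restarts under a fixed seed; clusters are then merged iteratively, most
similar pair first, until no pair qualifies. Two merge conditions:

1. centroid Pearson correlation > `merge_threshold` (default 0.8) — same
   combinatorial signature at different amplitude;
2. a two-means split ratio (centroid separation divided by the pooled
   within-cluster spread projected onto the inter-centroid axis) below 4.0
   — the pair is not separated beyond its own noise.

The second rule exists because correlation alone can never collapse
fragments of a single homogeneous population: complementary K-means
fragments of one blob have *anti-correlated* centroids. The 4.0 cut sits
between the ratios K-means fragmentation produces on homogeneous data
(≈ 2.5–3.5, weakly dependent on dimension) and the ratio of genuinely
separated clusters at the ≥ 3 SD planted separation used in the benchmark
(≈ 5). Final states are renamed A, B, C, … by decreasing mean of the
silencing-mark centroid components (marks matching `H3K9*`/`HP1*`, or all
marks when none match), so the labels are reproducible; their biological
identity is reported, never assumed.

## Metagene profiles

Active/silent calls: log10(RPKM+1) > 0.6 (cell-line context) or > 0.4
(larval context); log2(FPKM+1) > 1.4 for FPKM tables. Profiles scale each
gene body onto 60 bins (50 bp at the 3-kb display scale) and sample ±2-kb
flanks at fixed 50-bp steps; bins take the mean of their probes, and empty
bins are filled by linear interpolation between neighbours (arrays are
sparse relative to 50-bp bins). Minus-strand genes are reversed so profiles
read 5′→3′. The mean and SEM are taken across genes at each position (SEM 0
for a single gene, by convention). Genes whose bodies contain fewer than
two probes are skipped with a log message. Heatmaps keep genes ≥ 1 kb and
use unscaled ± 500-bp anchors at the TSS and TES with a scaled interior;
no aggregation. Feature-class means (active TSS ± 500 bp, active gene body
beyond the TSS window, silent-gene bodies) average probes within each gene
first, then across genes, so the SEM is over genes.

## Pausing statistics

Eligibility: genes ≥ 500 bp that overlap no other gene (any bp, either
strand; both parties of an overlap are removed).

`PI_groseq` = mean per-bp read density over the first 500 bp from the TSS,
divided by the density over the first ⌈0.25·(L−500)⌉ bp of the remaining
gene, using reads on the gene's strand only (run-on signal is stranded;
antisense reads are ignored). A zero denominator with signal upstream gives
+∞ (paused at any threshold); 0/0 marks the gene as not
polymerase-associated and removes it from paused-fraction denominators.
Default threshold 10.

`PI_chip` = max Pol II enrichment in TSS ± 300 bp over the median across
the gene body (600 bp downstream of the TSS to the gene end), computed on
linear intensities (2ᴹ) by default — log-scale ratios can be negative and
are ill-defined as an index; the raw-M variant is available behind a flag.
"Median" is the reading adopted for the body summary (a mean variant is
available). At least 1 TSS probe and 2 body probes are required; otherwise
the gene is skipped with a log message. Default threshold 4.

The domain contrast shuffles domain labels across polymerase-associated
genes; the statistic is the paused-fraction difference and the two-sided
p-value uses the +1 correction, p = (1 + #{|null| ≥ |obs|})/(1 + n_perm),
which keeps it valid (conservative) at any n_perm. TSS-peak offsets take
the argmax probe in TSS ± 500 bp, strand-oriented, ties to the smallest
offset, flat windows flagged low-confidence; the condition comparison is
the difference of mean offsets. Cross-method overlap reduces
transcript-level results to genes by max PI and intersects top-N lists
(ties broken by gene id).

## Promoter sequence features

Motif scanning is forward-strand-only over TSS-oriented windows, with exact
IUPAC character classes (N in the sequence never matches); inverted motifs
are separate patterns, not reverse-complement scans, so forward and
inverted counts stay distinct. Defaults: pause button `KCGRWCG` in
TSS ± 60 bp; `GAGAG` / `CTCTC` (GAGA factor and inversion) and `TCAGTY`
(Inr) in TSS ± 200 bp — the exact GAGA/Inr consensus is configuration, and
the patterns used are recorded in output metadata. Domain contrasts use
the same +1-corrected label-shuffling permutation test on the per-promoter
hit indicators.

Melting temperatures use nearest-neighbor thermodynamics over the unified
published parameter table (the `DNA_NN3` table), 50 mM Na⁺, 25 nM per
strand, entropy-based salt correction; these conditions are fixed in
`seqfeat.TM_PARAMS` and echoed into resolved configs. Absolute T_m values
are model-dependent; every comparative statement (profile shapes, GC
ordering, domain contrasts) is invariant to the admissible table choice.
Profiles slide a 9-mer window over the first 100 bp downstream of the TSS
(92 offsets); windows containing N are skipped, sequences that are not
exactly 100 bp are skipped with a log message, and the per-set
min/median/mean/max summary pools all computed windows.

## Mutant comparisons

All comparisons consume a mutant track rescaled by the scaling-factor
normalization, which makes them invariant to multiplicative distortions of
the raw mutant data. A WT peak counts as "reduced" when no mutant region —
called by the same FDR machinery on the rescaled mutant track — covers at
least 50% of it; this reuses the calibrated caller instead of inventing a
second test. Level changes come from feature-class means; extent changes
from enriched-bp totals per domain at the calling FDR (base pairs, with a
region-count column alongside, since the original units are ambiguous).

The distance-to-repeat null places the observed peaks (identical lengths
and count, non-overlapping) uniformly in the domain and compares median
nearest-repeat distances, one-sided with the +1 correction. The statistic
saturates when peaks are long or repeats are dense and finely interspersed
(most placements touch a repeat and the median pins to zero); it is
informative when peaks are narrow relative to repeat spacing — e.g. with
clustered repeats — which the benchmark's power construction uses.

Expression contrasts use log2 fold changes with a pseudocount of 1 and a
paired Wilcoxon signed-rank test per domain or per supplied gene set;
zero-difference pairs drop out of the signed-rank statistic, and a group
with no nonzero differences reports p = 1. Groups under 6 paired genes are
flagged unreliable. Swapping conditions negates fold changes and preserves
the p-value.

## Synthetic-data generator

The generator is the package's study design. Defaults:

- **Domains**: a euchromatin-like arm (2 Mb, 500 genes, median length
  1,907 bp, median 3 exons, 5% repeats), a pericentric-like region
  (0.4 Mb, 60 genes, 1,844 bp, 2 exons, 35% repeats), a chr4-like arm
  (1.2 Mb, 80 genes, median 8,001 bp, 6 exons, 30% repeats) and a
  repeat-rich 70-kb proximal block on the same chromosome. Gene lengths
  are log-normal around the configured median (σ = 0.45 in natural log);
  exon counts are 1 + Poisson(median − 1); genes pack sequentially with
  exponential-profile gaps; repeats fill intergenic space first, then
  introns, until the configured density is met.
- **Mark architecture**: per (mark, domain, feature class) mean M with
  Gaussian probe noise, SD 0.3 (a free parameter — probe noise is
  platform-dependent; 0.3 gives per-probe z ≈ 6 for the strongest planted
  classes, a realistic array regime). HP1a/H3K9me3/POF sit on active
  chr4-like gene bodies (means 2.0/1.8/2.0) with TSS depletion (0.2);
  pericentric heterochromatin carries HP1a/H3K9me2/me3 but no POF; the
  euchromatin-like arm carries only Pol II architecture. Probe spacing
  100 bp (dense enough for ±300-bp windows at desk scale).
- **Mutants**: multiplicative retention of the class mean. The HP1a-null
  condition retains 11.1% of H3K9me2 and 33.3% of H3K9me3 on the chr4-like
  arm, 4% of HP1a everywhere heterochromatic, and half of gene-body Pol II
  on chr4; the pof condition removes chr4 HP1a except at repeats
  (retention 1.0 there) — residual repeat-proximal HP1a is the planted
  structure behind the distance-to-repeat analysis.
- **Read density**: active genes carry λ = 0.5 reads/bp on their strand;
  planted paused genes add λ × 150 over a 50-bp window starting 25 bp
  downstream of the TSS, so the expected GRO-seq PI of a paused gene is
  1 + 150·50/500 = 16 (safely above threshold 10) while non-paused genes
  sit at PI ≈ 1. The off-gene background rate defaults to 0, which makes
  the 0/0 rule the polymerase-association call — real GRO-seq association
  calls threshold on signal; the generator reproduces the *outcome* of
  that call, not read-level noise. Planted paused fractions: 15%
  (euchromatin-like), 12.5% (pericentric-like), 1.6% (chr4-like), set on
  active, PI-eligible genes.
- **Sequences**: promoters are i.i.d. at the domain GC (0.43 euchromatin,
  0.36 chr4-like, so T_m profiles are depressed on the chr4-like set) with
  motifs planted independently at domain-specific rates (GAGA 24% vs 11%,
  inversion 25% vs 13%, PB and Inr equal across domains) at uniform
  positions inside each motif's scan window. Note that short degenerate
  patterns also occur in the background at combinatorial rates, so
  observed hit fractions exceed planting rates.
- **Expression**: log-normal, with planted-active genes drawn above the
  expressed threshold and silent genes below it; the mutant table
  down-scales 80% of chr4-like genes by a per-gene factor in [0.2, 0.6],
  leaves other genes untouched by default, and can add symmetric log-scale
  noise to every gene (used for null calibrations).
- **Determinism**: one master seed; every generator draws from a labelled
  sub-stream (`default_rng([seed, crc32(label)])`), so adding a stage never
  perturbs another and all outputs are bit-reproducible.

What the generator does **not** emulate: read-level sequencing noise,
probe-specific affinity and GC bias, transposon sequence content,
copy-number structure, antibody cross-reactivity, and biological coupling
between expression level and mark strength. Passing the planted-recovery
benchmarks therefore demonstrates that the *estimators* are correct and
calibrated under the assumed signal model — not that the model captures
every property of real arrays or GRO-seq libraries.

## Benchmark problem sizes

The benchmark (`scripts/acceptance.py`, mirrored by
`tests/test_acceptance.py`) uses: 200 genes for the PI oracle equivalence;
10 runs of 2,000 + 80 genes for pausing recovery (with every gene
polymerase-associated, so the stated sample sizes are the test
denominators); 500 replicates at 199 permutations for the type-I
calibrations; 100 null tracks of 10,000 probes plus 20 planted tracks for
the region caller; 10 seeds of 1,000 bins × 5 marks for state recovery;
1,000 random sequences and 200 random 9-mers for the motif and T_m
oracles. These sizes make every run complete in about a minute on one CPU
while keeping Monte-Carlo error well inside the stated tolerances.

## Known limitations

- The region caller assumes the unenriched background dominates the track;
  genomes consisting mostly of enriched sequence push the robust null into
  the enriched mass and make calls conservative.
- The distance-to-repeat median statistic has no power against dense,
  finely interspersed repeat annotations (see above).
- `PI_chip` on the linear scale is sensitive to the smoothing bandwidth of
  the Pol II track; comparisons across conditions should use identically
  processed tracks (the pipeline driver does).
- Quantile normalization with heavy ties cannot keep sorted vectors
  bit-identical across tracks; ties are averaged deterministically instead.
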