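# hetdomain

Analysis toolkit for the chromatin biology of small heterochromatic
chromosome arms — the *Drosophila melanogaster* fourth chromosome being the
motivating case: a gene-dense, ~1.2 Mb arm that is packaged with
heterochromatin marks (HP1a, H3K9me2/3, POF) over *active* gene bodies while
keeping transcription start sites depleted, and that shows strikingly little
RNA polymerase II promoter-proximal pausing compared with euchromatin and
pericentric heterochromatin.

The package implements the full analysis pipeline around that biology:

- **Enrichment tracks** (`hetdomain.enrichment`) — probe-level M-values
  (M = log2 ChIP/input), moving-average smoothing, enrichment-region calling
  against a robust Gaussian null with Benjamini–Hochberg FDR control
  (default FDR = 1e-3), replicate-consistency rules (>75% target overlap, or
  >80% agreement of the top 40% by score), 500-bp binning, per-domain mark
  correlations, and two cross-condition normalizations: a scaling factor
  from the ratio of median absolute deviations of lagged probe differences,

      factor = median|d_i^WT − median(d^WT)| / median|d_i^Mut − median(d^Mut)|,
      d_i = x_{i+1} − x_i,

  and quantile normalization with deterministic tie averaging.
- **Chromatin states** (`hetdomain.states`) — K-means over z-scored bin ×
  mark matrices with a generous initial k (default 10), followed by merging
  of redundant clusters (centroid correlation > 0.8 or a low two-means
  split ratio) down to a small state set named A, B, C, … by decreasing
  silencing-mark signature.
- **Metagene profiles** (`hetdomain.metagene`) — active/silent calls
  (active iff log10(RPKM+1) > 0.6 for cell lines, > 0.4 for larvae, or
  log2(FPKM+1) > 1.4), scaled gene-body profiles (3-kb body, ±2-kb flanks),
  per-gene heatmaps, and feature-class means (active TSS / active body /
  silent) with SEM across genes.
- **Pausing statistics** (`hetdomain.pausing`) — both pausing-index
  definitions:
  `PI_groseq` = read density over the first 500 bp from the TSS / density
  over the first 25% of the remaining gene length (paused if PI > 10);
  `PI_chip` = max Pol II enrichment in TSS ± 300 bp / median over the gene
  body from 600 bp downstream of the TSS (paused if PI > 4, linear scale).
  Gene filters (≥ 500 bp, non-overlapping), per-domain paused fractions,
  label-shuffling permutation tests with the +1 correction, mutant/WT PI
  ratios, TSS-peak-shift estimation, and top-N cross-method overlap.
- **Promoter sequence features** (`hetdomain.seqfeat`) — IUPAC motif
  scanning (pause button `KCGRWCG` in TSS ± 60 bp; GAGA-factor `GAGAG`,
  its inversion, and Inr in TSS ± 200 bp) with permutation contrasts
  between domains, and sliding-window 9-mer melting-temperature profiles
  (nearest-neighbor thermodynamics) over the first 100 bp downstream of
  the TSS.
- **Mutant comparisons** (`hetdomain.mutant`) — peak retention under the
  mutant's own region call, level/extent change summaries per feature class
  and domain, a distance-to-nearest-repeat permutation test for residual
  peaks, paired Wilcoxon expression contrasts, and PI-change/mark-enrichment
  correlations.
- **Synthetic data** (`hetdomain.simulate`) — a fully deterministic
  generator that emulates the genomic structure the analysis assumes
  (domain layout, gene-size/exon distributions, ~30% interspersed repeats,
  mark architecture, planted paused genes, motif planting rates, GC
  composition, mutant retention factors, expression down-scaling), so every
  stage is testable against known ground truth without any downloads.

## Worked example

```python
from hetdomain import simulate, pausing, metagene

cfg = simulate.SimConfig(seed=0)                 # chr4-like defaults
ann = simulate.generate_annotation(cfg)
density = simulate.generate_readdensity(cfg, ann)

results = pausing.compute_pausing(ann.genes, ann.partition, "groseq",
                                  density=density)
for domain, (n, frac) in sorted(pausing.paused_fraction(results).items()):
    print(f"{domain:<28s} associated={n:<5d} paused={100*frac:.1f}%")

obs, p = pausing.pausing_domain_test(results, "euchromatin", "chr4",
                                     n_perm=999, seed=0)
print(f"euchromatin vs chr4: diff={obs:+.3f}, permutation p={p:.3f}")
```

prints

```
chr4                         associated=43    paused=2.3%
chr4_proximal                associated=1     paused=0.0%
euchromatin                  associated=259   paused=15.1%
pericentric_heterochromatin  associated=32    paused=12.5%
euchromatin vs chr4: diff=+0.127, permutation p=0.030
```

— the generator plants a 15% paused fraction on the euchromatin-like arm
and ~2% on the chr4-like arm among polymerase-associated genes; the
pipeline recovers both and the permutation test flags the contrast (with
only 80 chr4-like genes at the default association rate the p-value sits
around a few percent; it drops below 0.01 at the benchmark sample sizes).
Feature-class means on the same simulation recover the planted HP1a
architecture (active gene body 2.0, active TSS 0.2, silent 1.0):

```
               mean    sem   n
active_body    1.995  0.007  43
active_tss     0.192  0.015  43
silent         1.009  0.005  37
```

A command-line interface mirrors the library:

```sh
hetdomain simulate --seed 1 --out sim/
hetdomain callregions --track sim/tracks/HP1a.WT.bedGraph --fdr 1e-3 --out hp1a.bed
hetdomain pause --method groseq --genes sim/genes.gff3 --domains-bed sim/domains.bed \
    --plus sim/groseq.plus.bedGraph --minus sim/groseq.minus.bedGraph --out pausing.tsv
hetdomain run --seed 1 --out full/        # end-to-end with a checksum manifest
```

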