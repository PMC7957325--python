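# germfate

Analyses of zebrafish primordial germ cell (PGC) versus somatic cell
divergence during the first day of development, packaged as a tested,
reusable library with an end-to-end synthetic-data driver.

Zebrafish PGCs inherit maternal germ plasm, yet they activate their
zygotic genome together with the soma; their identity diverges later,
during migration, through selective transcript stabilization and a
PGC-specific chromatin accessibility program. Testing those claims
requires a set of interlocking computations that are not shipped by any
one tool:

* **Zygotic-gene classification** — a gene is called zygotic when its
  expression is below **2 TPM** at the 256-cell stage (before zygotic
  transcription starts) and rises at the next stage.
* **ERCC absolute quantification** — spike-in RPKM values below 1 are
  discarded and the rest fit by ordinary least squares in log–log
  space, *y = a + bX* with *X* = log10 concentration (attomoles/µL),
  inverted to estimate absolute RNA amounts.
* **Intron retention (IR)** — for each intron,
  `IR = D / (max(SS5, SS3) + D)` with intronic depth *D* and 5′/3′
  splice-site reads; because splicing is co-transcriptional, an IR rise
  marks nascent transcription. A gene subgroup's IR shift between
  stages is tested against **10,000 random gene subsets** of the same
  size (two-sided, add-one corrected), alongside a Welch *t* test.
* **Tn5-corrected accessibility** — ATAC fragment ends are shifted
  **+5 bp / −4 bp** to recover transposase cut sites, extended by 25 bp
  (two 51-bp windows per pair; 5 bp for matrix analyses), with mapping
  quality < 10, non-numbered contigs and the mitochondrial chromosome
  removed and duplicates kept. Peaks are scored by a global-background
  Poisson scan.
* **Candidate-enhancer cascade** — replicate peaks pass a Gaussian
  copula mixture **IDR at 5%**, lose anything within **500 bp** of a
  TSS or wider than **1 kb**, and are union-merged across conditions
  with a final width filter; every step's survivor count is logged.
* **PCA / SOM** — per-element signal in **601-bp** windows, library
  normalized, log transformed, column (sample) centered for PCA and
  additionally row centered for a **3×3 self-organizing map** (nine
  clusters) operating on log-fold-change profiles.
* **Differential accessibility / expression** — negative-binomial Wald
  tests with a shared moment-matched dispersion and BH correction
  (significance at |logFC| > 1, padj < 0.05, and for peaks fold
  enrichment > 4).
* **CpG methylation** — bismark-coverage tables filtered at **6 reads**,
  coverage-weighted region summaries, and per-CpG Fisher exact tests of
  pooled groups with a differential fraction readout.
* **Germ-granule geometry** — per granule, the boundary length lying
  against the nucleus divided by the cell's total granule area; a
  condition's ratios are compared against control by a Wilcoxon
  rank-sum test.

A seeded synthetic-data module (`germfate.synthdata`) emulates the study
design — two cell types × five stages (256-cell, high, dome, 10-somites,
prim-5) × two replicates, with maternal/zygotic/germ-plasm-stabilized
transcript classes, reproducible and irreproducible ATAC elements,
soma-only enhancer demethylation and granule-contact geometry — so every
stage is testable against known ground truth without any downloads.

## Worked example

```python
import pandas as pd
from germfate.expression import tpm, classify_zygotic, ercc_calibrate, rpkm
from germfate.introns import ir_ratio, gene_ir, ir_permutation_test
from germfate.synthdata import SimConfig, gen_expression, gen_introns

cfg = SimConfig(seed=7)                      # the default study design
counts, truth = gen_expression(cfg)          # genes x (2 x 5 x 2) samples

t = tpm(counts)
pgc = counts.samples[counts.samples.cell_type == "PGC"]
stage_tpm = pd.DataFrame({s: t[pgc.index[pgc.stage == s]].mean(axis=1)
                          for s in cfg.stages})
calls = classify_zygotic(stage_tpm, list(cfg.stages))
print((calls == "zygotic").sum())            # -> 383 genes called zygotic

introns = gen_introns(cfg, truth)
pre = gene_ir(introns, sample="soma_256-cell")
post = gene_ir(introns, sample="soma_high")
zygotic = truth.gene_class.index[truth.gene_class == "zygotic"]
res = ir_permutation_test(pre, post, zygotic, n_perm=10_000, seed=7)
print(res.observed, res.pvalue)              # -> 0.479  1.00e-04
print(res.null_interval)                     # -> (0.1932, 0.2270)
```

The classifier recovers 94% of the planted zygotic genes with no false
positives among maternal or housekeeping genes. The IR shift of the
zygotic subgroup in *somatic* cells (+0.479) lies far outside the
(0.193, 0.227) interval of 10,000 random gene subsets — the synthetic
counterpart of germ-cell transcripts being actively transcribed
throughout the embryo at genome activation, with their background
elevated too because most of the transcriptome is newly made after
activation. `ir_ratio(10, 30, 20)` evaluates to `0.25` exactly.

The full pipeline, from simulation through granule scoring, runs from
the shell:

```bash
germfate run --outdir out/ --seed 7        # writes out/report.json
germfate simulate --outdir sim/ --seed 7   # just the synthetic dataset
germfate atac cascade --help               # per-assay operations
```

`out/report.json` records every stage's status, the analysis constants
in force (TPM 2; 500 bp; 1 kb; 601 bp; IDR 0.05; 10,000 permutations),
the enhancer-cascade audit log and the truth-recovery metrics.

## Layout

```
src/germfate/
  synthdata.py     seeded generators + ground-truth labels
  expression.py    size factors, TPM, zygotic rule, ERCC, NB Wald test
  introns.py       IR ratio, gene aggregation, permutation test
  chromatin/       cut sites, peaks, IDR, cascade, signal, PCA/SOM,
                   differential accessibility, annotation
  methylation.py   CpG filtering, region summaries, Fisher differential
  granules.py      mask measurement, contact ratio, group comparison
  pipeline.py      end-to-end driver and report
  cli.py           `germfate` command group
docs/methods.md    model and design notes
```
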