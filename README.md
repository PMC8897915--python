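# exondepth

Rare copy-number-variant (CNV) detection from whole-exome sequencing read
depth. The distinguishing idea: instead of normalizing a whole chromosome of
capture regions at once, **every region is normalized independently** together
with its *k* most-correlated background regions (Pearson correlation of
coverage profiles across samples), under a Poisson log-linear latent-factor
model. Deviations of raw counts from the fitted expectation are then segmented
per sample with circular binary segmentation (CBS) and turned into merged
DEL/DUP calls. Small background sets sharpen rare-CNV precision because each
subgroup's systematic artifacts are low-rank and easy to remove; `k = n-1`
reproduces the classical single global normalization exactly.

## Layout

| module | role |
| --- | --- |
| `exondepth.io_coverage` | BED targets, per-region read counting from BAM ("events" overlap counting), coverage-matrix TSV I/O (the counting module is replaceable by a precomputed TSV) |
| `exondepth.qc` | GC / mappability / length / median-depth annotation and the four boundary-inclusive quality filters |
| `exondepth.background` | background-set selection: pearson (primary), random, GC / length / mean-depth similarity |
| `exondepth.normalization` | Poisson log-linear latent-factor fit (block-coordinate MLE: exact β and N updates, LOESS GC curve, SVD latent factors); fork-join independent per-region normalization and the global baseline |
| `exondepth.segmentation` | ratio tracks, permutation-tested CBS, copy-number calling, call merging |
| `exondepth.synthetic` | coverage simulator with known biases and spiked CNVs, tiny-BAM fixture writer, stratified truth-based evaluation (rare/common × short/long) |
| `exondepth.cli` | `exondepth` command: per-stage subcommands plus the end-to-end pipeline |

## CLI

Full pipeline from a precomputed coverage matrix (regions × samples TSV) and
a region annotation table:

```sh
exondepth pipeline --coverage coverage.tsv --targets targets.bed \
    --annotations annotations.tsv --mode pearson --k 100 --out-dir results/
```

or from BAMs + BED + FASTA:

```sh
exondepth pipeline --bam s1.bam --bam s2.bam --targets targets.bed \
    --fasta ref.fa --out-dir results/
```

Every intermediate is persisted (`coverage.tsv`, `qc.tsv`, `qc_report.tsv`,
`neighbors.tsv`, `normalized.tsv`, `calls.tsv`, `calls.bed`,
`manifest.json`), so each stage can be re-run in isolation via the
`coverage`, `qc`, `neighbors`, `normalize`, `call` subcommands. Re-running
with identical inputs, config and seed is byte-identical, independent of
`--workers`. Config files are flat YAML (`--config run.yaml`); unknown keys
are rejected.

Synthetic data and evaluation:

```sh
exondepth simulate --spec spec.yaml --out-dir sim/
exondepth evaluate --calls results/calls.tsv --truth sim/truth.tsv \
    --n-samples 50 --out report.tsv
```

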