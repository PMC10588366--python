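# dashbench

Benchmarking CRISPR/Cas9-based depletion (DASH — Depletion of Abundant
Sequences by Hybridization) of a single overwhelming contaminant
transcript from droplet single-cell RNA-seq libraries.

## The problem

In some organisms a single transcript escapes poly(A) selection and
dominates 3' droplet scRNA-seq libraries — the canonical case is the
planarian mitochondrial 16S rRNA, which can account for well over half of
all UMIs in a cell and ~95% of ambient RNA. The contamination wastes
sequencing reads, inflates empty-droplet totals until cell callers
misclassify ambient barcodes as cells, and raises dropout rates for
informative genes. DASH removes the contaminant cDNA *physically*:
Cas9 complexed with a tiling pool of sgRNAs digests it after reverse
transcription, before fragmentation and indexing.

`dashbench` is for computational groups who want to quantify what such a
depletion buys — before or after doing it at the bench. It provides:

* a **read-level simulator** of paired untreated/DASHed libraries: cells
  and empty droplets with log-normal library sizes, a Beta-distributed
  per-cell contaminant fraction, an ambient profile dominated by the
  contaminant, PCR amplification noise that grows with cycle number, and
  multinomial read allocation whose zero-read molecules are the dropout
  mechanism;
* a **depletion operator**: per-molecule Bernoulli removal with cut
  probability ε, a post-amplification bottleneck, and resequencing at the
  same read budget so both arms are compared at matched depth;
* the **analyses** that turn a paired experiment into conclusions:
  ordmag barcode-rank cell calling and the untreated/shared/DASHed-only
  partition, per-cell complexity metrics, exact hypergeometric read
  downsampling and rarefaction curves, paired per-cell regression and
  binned fold changes, pseudobulk Wilcoxon rank-sum DE with Bonferroni
  correction, and SNN-graph clustering evaluated against simulated truth;
* a **guide designer**: both-strand NGG protospacer scanning, greedy
  non-overlapping tiling, T7 in-vitro-transcription templates, and the
  poly(A)/polyadenylation-motif diagnostics used to reason about why a
  transcript is captured at all.

## The model in brief

Depletion acts on molecules, not reads: each contaminant molecule is cut
independently with probability ε, so if a fraction *p* of molecules is
contaminant, the residual contaminant fraction after depletion is

&nbsp;&nbsp;&nbsp;&nbsp;*p*(1 − ε) / (1 − *p*ε),

and ε is recoverable from a paired experiment as 1 minus the ratio of
contaminant odds (depleted over untreated). At the benchmark operating
point (*p* ≈ 0.60, ε = 0.999) the residual is ≈ 0.15% of UMIs. Reads
freed from the contaminant are reallocated to real transcripts, which
raises genes and non-contaminant UMIs per cell uniformly across the
library-size range — a paired OLS of depleted on untreated per-cell genes
has slope > 1 at R² > 0.97.

The cell caller thresholds at one tenth of the 99th percentile of the top
*N*-expected barcode totals; an ambient pool at ~95% contaminant pushes
empty droplets over that threshold in the untreated arm only, which is
the aberrant-calling phenomenon the partition analysis measures.

## Worked example

```python
import dashbench as db

cfg = db.load_scenario("bench-default").replace(seed=1)
truth, base, unt, dsh = db.simulate_paired(cfg)  # 2,000 cells, 5,000 empties,
                                                 # 6M reads per arm
feats = truth.features_frame()
mu, md = db.collapse_umis(unt, feats), db.collapse_umis(dsh, feats)

calls_u = db.call_cells(mu, cfg.n_cells)
calls_d = db.call_cells(md, cfg.n_cells)
part = db.partition_barcodes(calls_u, calls_d)
print(calls_u.n_called, calls_d.n_called, len(part.untreated_only))
# 4151 2001 2150

shared = sorted(part.shared)
pm_u = db.per_cell_metrics(mu, "16S", shared)
pm_d = db.per_cell_metrics(md, "16S", shared)
print(pm_u["pct_contaminant"].median(), pm_d["pct_contaminant"].median())
# 59.80551053484603 0.0

print(db.paired_regression(pm_u, pm_d, "genes_detected"))
# (1.1494062051488785, 18.731885378814667, 0.9841305326498407)

print(db.estimate_depletion(mu, md, "16S", shared))
# 0.9990114866163087
```

Read the output as: the
untreated arm calls 4,151 barcodes — 2,150 more than the depleted arm's
2,001, and those extra barcodes are ambient droplets full of contaminant;
shared cells drop from ~60% to 0% median contaminant UMIs; genes per cell
rise ~15% uniformly (slope 1.149, R² 0.984); and the configured cut
probability 0.999 is recovered to four decimals from counts alone.

The same pipeline is scriptable from a shell:

```
dashbench simulate --config bench-default --outdir sim
dashbench report --untreated-dir sim/untreated --dashed-dir sim/dashed \
    --expected-cells 2000 --out report.json
dashbench design-guides --fasta target.fasta --report guides.tsv
```

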