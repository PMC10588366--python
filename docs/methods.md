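# Methods

## Generative model

One simulated experiment is a single underlying cDNA library sequenced
twice: once untreated and once after depletion, at the same total read
budget. The library is built in three layers.

**Truth.** `n_genes` genes (default 1,000) share one log-normal baseline
abundance vector (σ = 1). Each of K cell types (default 8, one rare type
at proportion 0.02) upregulates its own disjoint set of m = 25 marker
genes by fold f = 8; each type's expression program is renormalized to sum
to 1 over the genes. One designated gene is a stem-cell marker
("piwi-1") holding a fixed 5% share of the program in stem types and
absent from non-stem types (default: one non-stem type), so the standard
marker-based cell filter has something real to act on. The contaminant
("16S") is a separate feature outside every program. The ambient profile
is a mixture: weight `ambient_contaminant` (default 0.95) on the
contaminant, the rest proportional to the type-proportion-weighted mean
program.

**Molecules.** Each of `n_cells` cells (default 2,000) draws a molecule
count from a log-normal with median 2,000 and σ_log = 0.35; a per-cell
contaminant fraction is drawn from a Beta with mean `p_contaminant` = 0.60
and concentration 200 (per-cell spread matching the few-percent
inter-cell variation seen in real shared barcodes), and that fraction of
its molecules is contaminant, the rest i.i.d. from the type program
(equivalently multinomial). Each of `n_empty` droplets (default 5,000)
draws a log-normal molecule count (median 400, σ_log = 0.6) i.i.d. from
the ambient profile. Empty droplets carry no cell-type signal and
doublets are not modeled.

**Reads.** Every molecule gets a log-normal amplification weight with
σ_amp = σ₀·√(cycles), σ₀ = 0.15, and the total read budget R (default
6,000,000) is allocated multinomially in proportion to the weights.
Molecules receiving zero reads are dropped — this is the only dropout
mechanism, and it is why the simulator is read-level: saturation,
rarefaction and the value of freeing reads from a contaminant are
unobservable in a UMI-level simulation. Totals are exact by construction:
reads always sum to R.

## Depletion operator

`apply_dash(molecules, epsilon, post_cycles)`:

1. each contaminant molecule is removed independently with probability ε
   (default 0.999); non-contaminant molecules are never removed or
   relabelled. Partial cutting that destroys an amplifiable template is
   collapsed into the same Bernoulli event, since only full-length cDNA
   survives re-amplification;
2. survivors pass a bottleneck of size min(N, N·2^(post−pre) ) — the
   minimal mechanism by which too few post-depletion PCR cycles reduce
   library complexity; at the default post = pre = 10 cycles there is no
   bottleneck. Cycle-number distortion beyond that is expressed only
   through σ_amp growth, not a separate jackpot mechanism;
3. fresh amplification weights with σ_amp = σ₀·√(pre+post) reallocate the
   same read budget R.

The untreated arm is produced by the identical resequencing step with
ε = 0, so the two arms differ only in the depletion event and are
comparable at matched depth. Under this model the residual contaminant
molecule fraction is p(1−ε)/(1−pε), and ε is identified from paired
counts as one minus the ratio of contaminant odds — the package's
`estimate_depletion` recovers the configured 0.999 to ~10⁻⁵ at benchmark
scale.

The fragment-length helper adds the fixed 3' chemistry overhead — an
82-base poly(dT) capture primer plus a 30-base template-switching oligo,
112 bases total — to an insert length.

## Analyses

**Cell calling** is the ordmag heuristic: threshold = (99th percentile of
the top `expected_cells` totals, linear interpolation) / 10; ties at the
threshold are called (≥). It is invariant to positive scaling and
barcode permutation. It deliberately replaces droplet-caliber empty-drop
testing: the phenomenon under study — ambient totals crossing a rank
threshold — is expressed by the simple caller, and it is exactly
specifiable.

**Downsampling** draws exactly `depth` reads without replacement
(multivariate hypergeometric over molecules) and re-deduplicates, so a
downsampled library is distributed like a library sequenced at that depth;
chained downsampling agrees with one-step downsampling in distribution.

**Per-cell metrics** count total, contaminant and non-contaminant UMIs
and genes detected (≥ 1 UMI; the contaminant counts as one gene when
present — a naive-counting convention, stated because it is a choice).
Percentages are 0 by convention for zero-UMI barcodes.

**Paired regression** is OLS with intercept (the unconstrained line) of
the depleted on the untreated per-cell value; binned fold changes use
quintiles of the untreated distribution by default, excluding and
counting zero-untreated cells.

**Differential expression** normalizes to log(count/total·10⁴ + 1) —
natural log for testing, log10 for the marker-filter threshold, which is
quoted on the log10 scale (threshold 2.5 ⇔ cp10k ≈ 315.2). The rank-sum
test enumerates the exact null (midranks for ties) when the pooled sample
is ≤ 12 and otherwise uses the normal approximation with tie-corrected
variance and continuity correction; the split at 12 keeps the exact path
testable by brute force. Bonferroni m is the number of features passing a
minimal prevalence prefilter (≥ 3 cells overall), and the prefilter is
reported per run. The average log2 fold change is
log2((mean cp10k + 1)/(mean cp10k + 1)) with a fixed pseudocount of 1.
Marker detection requires adjusted p < 0.05, expression in ≥ 25% of the
cluster's cells (boundary inclusive) and log2FC > 0.25.

**Clustering** filters to cells with more than 200 genes and marker
log10-cp10k ≥ 2.5 — applied to the contaminant-removed matrices, since
in-silico removal precedes clustering in the workflow being modeled — with
union-of-failures elimination across the pair so both arms cluster the
same cells. Embedding is PCA on log-normalized, per-gene standardized
(clipped ±10) expression; components are sign-fixed (largest-magnitude
loading positive) so the embedding is deterministic. Synthetic replicates
are single-batch, so no batch-integration step sits between scaling and
PCA; a batch hook is reserved for real data. Clustering builds a k = 20
nearest-neighbour graph on the first 20 components, converts to shared-
nearest-neighbour Jaccard weights pruned below 1/15 (the dominant
community convention), and optimizes RB-configuration modularity at
resolution 0.5 with a fixed seed; labels are renumbered by decreasing
cluster size, ties broken by lowest member index.

Because both arms cluster essentially perfectly at the full benchmark
depth, the paired clustering evaluation compares the arms at a matched,
deliberately limited depth (1M reads, cell set fixed at full depth) where
library complexity is the binding constraint — that is the regime in
which depletion is claimed to make clustering more sensitive, and the
depleted arm's agreement with truth dominates there.

## What the generator does and does not emulate

It emulates: one contaminant at ~60% of cell UMIs and ~95% of ambient
UMIs; log-normal cell and empty-droplet library sizes; multiple cell
types with one rare type; amplification noise growing with PCR cycles;
per-molecule depletion; matched-depth paired sequencing. It does not
emulate: sequence-level reads or barcode errors, doublets, batch effects,
cell-type-dependent contamination, more than one contaminant, or
empty-droplet cell-type leakage. Tests passing on this simulation
therefore demonstrate that the analysis code measures what it claims
under the stated model — not that real libraries behave this way; the
magnitudes (e.g. per-cell gene gains) are tied to the chosen operating
point and scale.

## Problem sizes and numerical choices

The benchmark scenario runs ~6.6M molecules and 6M reads per arm,
completing a full paired simulation in ~15 s and the whole analysis in
well under a minute; unit tests use a scaled-down scenario (60 cells, 150
droplets, 120 genes, 60k reads) that exercises identical code paths.
All randomness flows from the single scenario seed through named
`SeedSequence` streams, so equal configurations give byte-identical
outputs. Degenerate inputs are defined, not special-cased: zero-UMI
barcodes report 0% contaminant and are excluded from normalization with a
warning; empty partition categories report n = 0; sequences shorter than
23 bases yield no guides; identical pooled samples give p = 1.

## Known limitations

The ordmag caller matches the aberrant-calling *direction* and category
contaminant profiles, not any particular commercial caller's partition
sizes. Guide selection guarantees count and non-overlap of cut sites, not
identity with any external design tool's ranked picks, and no on/off-
target activity scoring is attempted. The shipped 905-nt guide-design
target is a synthetic stand-in sequence with the documented diagnostic
features planted (poly(A) stretches mid-sequence, an AATAAT signal at
position 808, TTTTT at 856); real targets should be supplied as FASTA.
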