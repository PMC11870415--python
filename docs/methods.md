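# Methods

This note documents the statistical models implemented in `clonmem`, the
assumptions behind them, the synthetic-data generator that exercises them,
and the numerical conventions fixed where the underlying procedures leave
choices open.

## Clone calling from expressed barcodes

Reads from the barcode library contain a 7-bp anchor (`TAGACAT`) followed by
a 48-bp barcode built as eight blocks of four random bases, each closed by
an invariant dinucleotide (CT, AC, TC, GT, TG, CA, AT, GC at 0-based offsets
4, 10, ..., 46), leaving 32 informative positions. Parsing scans left to
right for the first 7-mer within Hamming distance 1 of the anchor, trims
everything through it, takes the next 48 bp, rejects all-G UMIs (reverse-
transcription artifacts) and any read whose invariant dinucleotides mismatch
(off-target PCR products). Cell-UMI-barcode triples with fewer than 5
supporting reads are discarded — note that with *r* reads per UMI and
per-base error rate *p*, a triple survives essentially only when all of its
reads are error-free, with probability `(1 − p)^{48·r}` per read; recovery
therefore requires enough UMIs per cell that at least one survives.

Consensus calling operates on the Levenshtein distance matrix of the
retained 48-mers (computed with edlib): each sequence joins the most
abundant sequence within distance 4 of it (its own neighborhood includes
itself, so isolated barcodes self-assign), and the surviving assigned-to set
is collapsed once more at distance 2 toward the more abundant member,
processed in descending abundance so chains resolve globally. Abundance is
total read count; ties break toward the lexicographically smaller sequence,
which makes the whole procedure order-independent. Cells take the clone
supported by a plurality of their UMIs (ties → unassigned); clones attach to
the sample contributing most member cells, cross-sample cells are dropped
(split-pool transcript mixing), and clones below 5 cells are removed.

*Well-posedness.* The generator enforces pairwise Levenshtein distance ≥ 9
between planted consensus barcodes, so distance-4 clustering cannot merge
two clones: any read within distance 4 of two consensus sequences would
imply consensus distance ≤ 8.

## Background-normalized deviation scores

For a feature set *a* with weights *w* over features (binary motif
membership, or topic-gene probabilities for expression programs), and the
rank-one expectation `e_if = depth_i · total_f / grand_total`, the raw
deviation of cell *i* is

    Y_i = (Σ_f w_f x_if − Σ_f w_f e_if) / (Σ_f w_f e_if).

Background replicates substitute every annotated feature by a random
feature from the same mean-abundance bin (features ranked by mean count,
split into `n_bins = 20` equal-size bins; `n_background = 250` replicates;
drawn without replacement within a bin when possible, with replacement when
the bin is too small). The reported score is the z-score of `Y_i` against
the background replicates (SD with `ddof=1`). This controls for sequencing
depth and feature abundance; under the expectation model the score has mean
approximately 0 per cell.

Conventions: a constant-background cell/family resolves to 0 when the raw
deviation equals the background mean (the exact-null case) and to missing
otherwise; GC matching for peak backgrounds is not built in — callers with
sequence-aware bins pass them via `bin_assignments`. Condition summaries
average scores over the target cells of each sample, report change as
sample mean minus the mean of control-sample means, test conditions against
control by two-sample t-test on sample means, and BH-adjust across the 50
most variable families (per-cell score variance); samples under 200 target
cells are excluded. Activated cells are those with score strictly above 1.5.

## Clonal-variance permutation test

For each feature, within-clone SDs (`ddof=1`) are computed across the cells
of every clone; the observed clonal variance is the square of the median of
those SDs. Cell-to-clone labels are permuted uniformly over all
clone-assigned cells (a true permutation, preserving clone sizes; cells
without clones never enter), the statistic is recomputed `n_perm = 1000`
times (200 in the test suite), and

    Z = (V_obs − mean(V_null)) / sd(V_null),   p = 2·Φ(−|Z|),

with BH FDR across features. Heritability means *less* within-clone
variance than chance, i.e. negative Z; the two-sided p is retained, and
`ClonalVarianceTest.heritable_features` additionally requires Z < 0.
Both observed and shuffled statistics are squared (the test operates on
clonal-variance quantities throughout). Permutation is global across
samples by design: sample-level differences (e.g. the position along the
colon an organoid derives from) then legitimately register as clonal
structure, which is the behavior needed to attribute HOX/HHEX/SOX-type
signals to positional origin. Features constant across all cells are
flagged and excluded from the FDR. The statistic is invariant to adding a
constant per feature, and a fixed seed reproduces Z exactly.

Clone-level comparisons summarize each clone by median and SD per feature;
conditions are compared by a KS test on the SDs and by differences of
median-of-medians and median-of-SDs; high-memory clones are those with
median score > 1.25. Motif-program coupling is the Pearson correlation of
clone-mean motif scores against clone-mean program scores across clones.

## k-NN condition enrichment

Euclidean k = 100 nearest neighbors (self excluded — including self would
inflate own-condition enrichment by 1/k) in an externally supplied
embedding; observed per-condition neighbor fractions minus the global
condition fractions (the expectation under random assignment). Enrichments
are exactly zero-sum per cell and bounded in [−1, 1].

## Footprint memory and co-binding

Sites are 10-bp bins inside peaks with per-condition footprint scores in
[0, 1] (quantile-transformed upstream; bins never reaching 0.2 in any
condition are assumed pre-filtered). A memory footprint gains at least 0.2
over control (inclusive threshold, "minimum change of 0.2"); inhibitor
responses use the loss direction (≤ −0.2). For each family pair, peaks are
cross-tabulated (both / first-only / second-only / neither — the universe
must be the full analyzed peak set, not just site-bearing peaks) and the
log2 odds ratio reported, with a Haldane +0.5 correction on every cell when
any cell is zero. Normalization maps positive log-ORs linearly between
their pooled 10th and 90th percentiles onto [0, 1] (clipped) and negative
values onto [−1, 0]; the pooling set (all pairs × all timepoints of one
experiment) is an explicit argument; percentiles use linear interpolation;
a degenerate percentile range maps to 0 with a warning. Distances to the
nearest AP-1 memory site use bin midpoints within the same peak, with
adjacency defined as < 20 bp. The performance sweep collapses each peak's
reference-family sites to the change of largest magnitude, predicts
"differential" at |Δ| ≥ t, and reports sensitivity, specificity and
accuracy over a threshold grid (monotone by construction).

## Spatial tumor identification

Bins below 300 reads are removed; the rest are scaled to the mean depth,
log2(x+1)-transformed, reduced to 20 PCs, and smoothed by averaging each
bin with its 20 nearest bins in PC space (self included). Tumor cells are
bins whose smoothed, Z-scored Axin2 reaches 1 (inclusive; a constant field
gives Z ≡ 0 and no calls). Tumors are individualized on the k = 5 spatial
NN graph over called bins (directed edges symmetrized) by seeded Louvain at
resolution 1.0, **with connected communities merged**: modularity's
resolution limit otherwise splits a single contiguous lesion into a number
of pieces that grows with graph size, making counts depend on total tumor
burden; after merging, a tumor is a maximal connected group of called bins,
and Louvain supplies determinism and sub-tumor granularity where wanted
(`merge_connected=False`). Tumor pseudobulks (summed member-bin counts) are
scored with the deviation statistic, treating pseudobulks as cells, with
backgrounds binned on pseudobulk mean expression; high-AP-1 tumors exceed
score 1.5 (strictly; an alternative cutoff of 3 can be passed for
exceptional-tumor contrasts).

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions for the test suite.

**Latent model.** Per cell and family,
`s = clone_effect + condition_shift·exposed + noise` with
`Var(clone_effect) = icc`, unit total variance, so intraclass correlation is
a direct parameter. A configured fraction of exposed-condition clones gains
`delta_high` (default 2.0) on designated AP-1-like families — the
high-memory subpopulation. Counts are conditional Poisson: each cell draws
a lognormal depth (median 2000 fragments) and distributes it multinomially
over features whose rates are tilted by `exp(0.25 · s)` through the
feature-family annotation; conditioning on the total keeps column sums
exactly equal to sampled depths while preserving the Poisson null that the
deviation scores assume. Defaults mirror a six-line organoid experiment
(3 control / 3 colitis), 30 clones and 500 cells per line.

**Barcode reads.** 80 UMIs per cell, 5 reads per UMI, i.i.d. per-base
substitutions at rate 0.01 across the 48 barcode positions. The UMI count
follows from the triple filter arithmetic above: at 5 reads/UMI a UMI
survives with probability ≈ 0.09, so ≈ 80 UMIs bound the per-cell failure
probability at ≈ 5×10⁻⁴ — a realistic capture count for a highly expressed
barcode transcript. Junk reads (broken anchor, all-G UMI) are interleaved
at a configurable fraction.

**Footprints.** AP-1 memory sites (Δ drawn from [0.25, 0.5], control scores
from [0.2, 0.5], so calls are exact by construction) occupy a configurable
fraction of peaks; partner families co-occur with probability
`footprint_cooccurrence` in AP-1-memory peaks and `footprint_base_rate`
elsewhere — setting the two equal yields independence (odds ratio 1).
Co-occurring sites sit within ±1 bin of the AP-1 site.

**Spatial grids.** Circular tumors (radius 4 bins) are placed with an edge
gap of at least 6 bins between discs — the spatial analogue of the minimum
barcode distance: a k = 5 NN graph over called bins then cannot link two
planted tumors. Three structural features emulate what real sections
provide and the smoothing model relies on: a baseline Axin2 read share of
4% (a WNT target is well detected in normal crypts, so the adenoma fold
change rides on a well-measured baseline), smooth latent tissue programs
across the section (PC-space smoothing averages tissue structure, not
single-gene Poisson noise), and a broad adenoma expression program (APC
loss rewires expression globally, which is what places tumor bins in their
own PC-space region). A designated tumor subset additionally elevates
program probes (the high-AP-1 tumors).

**Reproducibility.** Each output artifact uses its own RNG stream derived
from the master seed, so regenerating one artifact never perturbs another;
identical configurations reproduce outputs exactly.

## What the generator does not emulate

No doublets or cell clumps, no GC composition or chromatin-accessibility
sequence biases, no batch effects, no zero-inflation beyond what the
multinomial induces, no spatial platform artifacts (bleed-over, tissue
folds), and no raw sequencing reads for alignment. Passing tests therefore
demonstrate correctness of the statistics under their own model
assumptions and recoverability of planted structure — not robustness to
the full noise structure of real experiments.

## Problem sizes in the test suite

The suite runs the pipeline at reduced scale chosen for comfortable
iteration: heritability calibration uses 30 clones × 20 cells, 1000 null
features and 200 permutations; clone-recovery uses 30 clones over 300
cells; spatial recovery uses 70×70-bin grids over 20 seeds per
configuration; deviation-score oracles use 10×20 matrices. These sizes are
the package's own choices; all statistics scale to full experiments
unchanged.
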