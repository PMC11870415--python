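# clonmem

Analysis toolkit for **clonal epigenetic memory** in single-cell multiome
(ATAC + RNA) experiments with expressed lineage barcodes, plus the companion
footprint and spatial-transcriptomics analyses used to follow that memory
into transcription-factor networks and tumors.

The package targets the analysis pattern of colitis-memory studies in the
colonic epithelium: stem cells retain heritable accessibility changes at
AP-1 (Fos/Jun) binding sites after inflammation resolves, a subpopulation of
clones carries exceptionally strong memory, and the same signal re-appears
in adenomas. Every stage can be exercised without any external data through
a synthetic generator that plants known clonal structure, condition effects,
footprint co-occurrence and Axin2-high tumors.

## What it computes

* **Clone calling** (`clonmem.clonotyping`). Barcode reads carry a `TAGACAT`
  anchor followed by a 48-bp barcode (eight blocks of four random bases,
  each closed by an invariant dinucleotide: CT, AC, TC, GT, TG, CA, AT, GC
  at offsets 4, 10, ..., 46). Reads are anchor-parsed (≤1 mismatch),
  validated, counted per cell-UMI-barcode triple (≥5 reads), and clustered
  on the Levenshtein distance matrix: assignment to the most abundant
  sequence within distance 4, then collapse of the survivors within
  distance 2. Clones need ≥5 cells and are attached to the sample
  contributing most member cells.
* **Deviation scores** (`clonmem.scoring`). chromVAR-style background-
  normalized scores: for a feature set with weights *w*,
  `Y_i = (Σ w x_if − Σ w e_if) / Σ w e_if` with `e_if = depth_i ·
  total_f / grand_total`, z-scored against 250 abundance-matched background
  feature sets drawn from 20 equal-size bins. Works for motif families over
  peaks and LDA gene programs over genes; includes motif-family bagging,
  per-sample condition summaries with t-tests and BH FDR, activated-cell
  fractions (score > 1.5) and downsampled KS tests.
* **Clonal heritability** (`clonmem.heritability`). The clonal-variance
  permutation test: observed clonal variance = (median over clones of the
  within-clone SD)², compared against cell-to-clone label permutations;
  `Z = (V_obs − μ₀)/σ₀`, `p = 2·Φ(−|Z|)`, BH FDR. Heritable features have
  negative Z. Plus clone-level condition comparisons (KS on SDs, Δ medians,
  high-clone fractions at median score > 1.25) and clone-mean motif↔program
  Pearson correlations.
* **k-NN condition enrichment** (`clonmem.enrichment`). Observed minus
  expected condition fractions among each cell's k = 100 nearest neighbors
  in a latent embedding (exactly zero-sum per cell).
* **Footprint co-binding** (`clonmem.footprints`). Memory-footprint calls at
  |Δscore| ≥ 0.2 per 10-bp bin, peak-level 2×2 co-occurrence log2 odds
  ratios against AP-1, 10th–90th percentile normalization onto [−1, 1],
  nearest-AP-1 distances (adjacency < 20 bp), and the
  sensitivity/specificity sweep of footprint changes against orthogonal
  differential-binding labels.
* **Spatial tumors** (`clonmem.spatial`). 16-µm bins: QC (≥300 reads),
  depth normalization, log2(x+1), top-20-PC k = 20 smoothing; tumor-cell
  calls at smoothed Axin2 Z ≥ 1; tumor individualization by seeded Louvain
  on the k = 5 spatial NN graph (connected communities merged); pseudobulk
  program scoring with the same deviation statistic, high-AP-1 tumors at
  score > 1.5.

The fit/transform-shaped stages are scikit-learn estimators
(`CloneCaller`, `DeviationScorer`, `ClonalVarianceTest`,
`KNNConditionEnrichment`, `TumorSegmenter`); module-level functions wrap
them for one-off use.

## Worked example

```python
import numpy as np
from clonmem import CloneCaller, ClonalVarianceTest, DeviationScorer
from clonmem.simulate import SimulationConfig, simulate_multiome, simulate_barcode_reads

cfg = SimulationConfig(seed=7, n_samples=2, conditions=("control", "colitis"),
                       n_cells_per_sample=150, n_clones_per_sample=15,
                       icc_per_family=0.5, barcode_error_rate=0.01)
cells, peak_counts, gene_counts, ann, truth = simulate_multiome(cfg)

reads, consensus = simulate_barcode_reads(
    cells.assign(clone_id=truth["clone_of_cell"]), cfg)
caller = CloneCaller().fit(reads, cells.set_index("cell_id")["sample"])
print(len(caller.consensus_barcodes_), "clones recovered")

scorer = DeviationScorer(annotation=ann["peak_families"], n_background=100,
                         n_bins=10, family_names=ann["family_ids"], random_state=0)
scores = scorer.fit(peak_counts).transform(peak_counts)
assigned = cells["cell_id"].map(caller.cell_to_clone_)
keep = assigned.notna().to_numpy()
test = ClonalVarianceTest(n_permutations=200, random_state=0)
test.fit(scores[keep], assigned[keep].to_numpy())
print(test.results_[["Z", "p_value", "FDR"]].round(3).head(4))
```

Output:

```
30 clones recovered
                Z  p_value  FDR
feature_id
family_0   -6.204      0.0  0.0
family_1   -6.230      0.0  0.0
family_2   -5.232      0.0  0.0
family_3   -3.620      0.0  0.0
```

All 30 planted clones are recovered from the error-bearing barcode reads,
and every motif family is called heritable (strongly negative Z: cells
within a clone vary far less than under permuted clone labels), as expected
for data generated with intraclass correlation 0.5.

A command-line surface mirrors the library:
`clonmem simulate | clones | score | heritability | knn-enrich | cobind |
spatial` (see `clonmem --help`).

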