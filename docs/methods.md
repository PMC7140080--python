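# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations behind `scaffoldomics`. It states nothing that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. Imaging arm

### Stack model

An `ImageStack` is a pair of `(z, y, x)` arrays of unsigned intensities
(channels `DiO`, the membrane dye marking whole cells, and `DAPI`, the
nuclear stain) with a physical voxel size, default `(2, 1, 1)` µm — a 2 µm
confocal step with ~1 µm lateral sampling.

### Glass/scaffold separation

Cultures grown in a scaffold chamber produce two signal regimes: cells
adhering to the coverslip (a dense quasi-2D sheet) and cells suspended in
the 3D matrix. The separation rule is purely intensity-profile based:

1. Sum every slice's intensities per channel (exact int64 accumulation).
2. Compute Tukey inner fences `Q1 − 1.5·IQR, Q3 + 1.5·IQR` per channel.
   Quartiles use linear interpolation between order statistics (numpy's
   default, the "type 7" rule); this convention is declared because the
   fences of small slice counts depend on it. At least 4 slices are
   required.
3. Find, per channel, the **highest** z-index containing a voxel at the
   channel's global maximum; the reference slice is the maximum of the two
   channel indices. (For a constant channel every slice attains the
   maximum, so the reference is the last slice and nothing is removed.)
4. Remove a slice iff its index is strictly above the reference **and**
   its sum is outside the fences in **either** channel (the union rule is
   the conservative reading; sums below the lower fence also count as
   outlying). Fences are computed once from all slices — removal is a
   single pass, not iterative re-fencing.

The lowest removed index is recorded as the dividing slice. Cropping is
idempotent in the tested regime (a second pass finds no new outliers above
the reference). The rule removes only high-z outliers; a bright sheet at
low z would not be removed — the recorded dividing index is reported
without interpreting orientation.

### Segmentation

* **Otsu threshold**: exhaustive maximization of the between-class variance
  over the intensity histogram. For 8-bit data the candidates are the 256
  integer levels; for wider dtypes, 256 equal-width bins over the observed
  range (configurable), candidate = upper bin edge. Foreground is
  *strictly above* the threshold, and variance ties resolve to the lowest
  threshold. A constant image is an error ("degenerate histogram").
* **Components**: 26-connectivity by default (faces + edges + vertices),
  configurable to 18 or 6; labeling and region statistics are delegated to
  `skimage.measure`.
* **Filters**: minimum object size 10 voxels ("ten pixels" read as voxels,
  since the counter operates on 3D objects); objects whose bounding box
  touches any of the six volume faces can be excluded (the stricter
  all-faces rule; configurable).
* **Masked stacks** carry the object id per voxel and round-trip to the
  same object table.

### Clustering quantification

Density histograms of object volumes are normalized so bar area integrates
to 1; the default bin width is Freedman–Diaconis on the pooled sample.
"Peak region" histograms restrict the domain to `[0, x̄ + 2σ]` with mean
and standard deviation from the input sample and re-normalize within that
domain.

The scalar metrics are an artifact-defined operationalization of a
qualitative clustered/non-clustered comparison, and outputs flag them as
such in this sense: a calibrated single-cell unit volume `v₁` (default:
the mode of the volume histogram, on the assumption that single cells are
the most common object; configurable and best supplied explicitly when
known) defines singletons as objects with volume `< 2·v₁`. Reported per
condition/day: singleton and cluster fractions, mean cluster volume,
estimated total cells (`round(v/v₁)`, at least 1 per object). Condition
comparisons are descriptive (differences against the first condition); no
inferential statistic is attached.

## 2. Expression arm

Counts live in an `AnnData` (cells × genes, sparse CSR). Conventions:

* **QC trim**: cells with total molecules strictly above 40,000 are
  removed (a cell at exactly 40,000 is retained). The default emulates a
  droplet-capture upper trim against doublets/over-sequencing.
* **Percent mtRNA** is computed from the count matrix
  (`100 × mito/total`), an approximation of per-read percentages that
  would require raw alignments; a zero-total cell is an error.
* **Size-factor normalization**: `sf_c = total_c / median(totals)`;
  dividing by `sf_c` leaves every cell at the median raw total (checked to
  1e-9). Raw counts are preserved in `layers["counts"]`.
* **Wilcoxon DE**: LFC is natural-log with pseudocount 1 on group means of
  normalized values (the 0.25 default threshold is a natural-log
  convention). Genes are pre-filtered to `|LFC| > 0.25` *before* testing,
  so the Bonferroni multiplier counts only tested genes. The p-value is
  two-sided rank-sum: exact enumeration when both groups have ≤ 10 cells
  and the gene is tie-free, otherwise the tie-corrected normal
  approximation (scipy's `mannwhitneyu`, continuity-corrected). Whether
  significance is called on raw or adjusted p is a parameter; the default
  is adjusted p < 0.01, with both always reported. Groups must be disjoint
  with ≥ 3 cells each.
* **Dot-plot statistics**: per cluster per gene, mean normalized expression
  and percent of cells with raw count > 0; unknown genes go to a
  skipped-genes report rather than failing.
* **Population fractions**: fraction of cells with a metric strictly below
  a threshold per group (default: percent mtRNA < 10), plus cluster × 
  sample composition tables.

Graph-based clustering, embedding, and dataset integration are inputs
(cell metadata), not computed here.

## 3. Network arm

* **DEG selection**: adjusted p strictly below 0.05.
* **First-order networks**: seeds plus direct interactors from one level's
  edge table, with all induced edges among included nodes; isolated seeds
  remain as singleton components; the largest component is flagged. All
  graphs are undirected — TF→gene and miRNA→gene directionality is
  collapsed so levels merge cleanly.
* **Trimming**: degree and exact unnormalized shortest-path betweenness
  are computed on the *untrimmed* network; non-seed nodes failing the
  thresholds are removed (both thresholds conjunctively by default; a flag
  switches to either-passes). Seeds are never trimmed — the query genes
  define the network. Defaults per level: ppi 10 degree; gene-TF 25;
  gene-miRNA 25; co-expression 2 degree + 4 betweenness. Results outside
  the declared 200–600 node budget raise a warning, not an error.
* **Merging**: union by node id; replicate nodes are ids in more than one
  input, replicate edges are unordered level-agnostic pairs in more than
  one input; merged edges carry their level provenance.
* **MCODE**: vertex weight = (highest k-core number of the closed
  neighborhood) × (density of that core); complexes grow greedily from the
  top-weighted unvisited vertex, including neighbors whose weight exceeds
  `(1 − node_score_cutoff) ×` seed weight, breadth-first with a depth
  limit; visited vertices join one complex only, so regions are disjoint.
  Post-processing drops complexes with no 2-core and iteratively shaves
  singly connected vertices (haircut). Complexes are ranked by
  density × size. Defaults are the algorithm's published ones: degree
  cutoff 2, node score cutoff 0.2, k-core 2, max depth 100, haircut on,
  fluff off.
* **ORA**: upper hypergeometric tail `P(X ≥ k)` via `scipy.stats
  .hypergeom.sf`, BH-FDR within each run via statsmodels. The universe is
  a declared choice because p-values depend on it: for a per-network run,
  the annotation collection's genes intersected with the network's nodes
  (the study set being the seed genes in the network); for a plain gene
  list, the measured genes. Both are parameters.
* **Consensus**: a term is significant in a level at `q < 0.1`; terms
  significant in ≥ 3 levels are kept. The inclusive-3 default is chosen
  over "more than three" because the two conventions disagree in the
  source workflow's own description; both are reachable via
  `min_networks`. Dismissal of isolated terms is a manual curation step —
  the table surfaces term families (an optional user-supplied mapping,
  never inferred) instead of automating the dismissal.

Interaction knowledge always arrives as user-supplied edge tables; nothing
is fetched from live interaction databases, so results are a function of
the provided tables alone (recorded in the level tag).

## 4. Synthetic data: what it emulates, what it does not

* **Stacks**: cells are filled digital spheres (voxel included iff center
  distance ≤ radius) — the simplest shape with an exact analytic voxel
  count for oracles. Clusters are a seed center plus members displaced by
  an isotropic Gaussian (scale `cluster_spread_vox`); overlapping members
  merge into one rendered object, and the truth records both the intended
  membership and the glass z-range. Scaffold groups are placed with
  minimum separation and away from the volume faces, so the intended group
  count equals the rendered component count. The glass layer is rendered
  clipped to its z-range at reduced intensity (default 0.6× gain): dense
  enough that its slice sums are outlying, dim enough that the global
  intensity maximum stays in the scaffold — the regime in which the
  cropping rule is well-posed. Noise is additive Gaussian clipped to
  8-bit; no PSF/optics model, no intensity attenuation with depth, no
  touching-cell splitting scenarios. Passing tests therefore show the
  pipeline recovers geometry under idealized optics, not that Otsu
  segmentation is robust to real confocal artifacts.
* **Counts**: gamma-Poisson (negative binomial) with constant base mean
  per gene (default mean 2, dispersion 2 — typical sparse droplet data);
  mitochondrial gene means are set per cell so the expected mito fraction
  equals the condition target exactly (defaults 5% control vs 30% treated,
  matching the direction of a damaged treated population); a 10%
  subpopulation overexpresses 7 stem-marker-like genes 4-fold; an optional
  tail of cells is scaled to exceed the 40,000-molecule trim threshold.
  No batch effects, doublets, gene-gene correlation, or dropout model
  beyond NB sparsity.
* **Networks**: per-level Erdős–Rényi-like edge tables with half the
  endpoints biased to DEGs so first-order networks are non-trivial; one
  planted clique among the planted term's DEGs in one level; one planted
  term drawn mostly (90%) from the 50 DEGs plus uniform background terms.
  Interactor ids at every level live in the same annotated gene universe
  (defensible — TFs are genes — and necessary for a well-defined
  per-network ORA universe at every level). Real interactomes' degree
  distributions and annotation structure are not modeled.

Defaults for the generators are fixed study conditions, not tuning knobs;
the acceptance script runs them as stated (e.g. 1,000 cells, 10% stem
subpopulation, 4-fold markers; 1,000-gene universe, 50 DEGs, size-20
planted term, size-8 clique).

## 5. Numerical choices and degenerate inputs

* Quartiles: type-7 (linear interpolation); fences need ≥ 4 values.
* Otsu: ties toward the lowest threshold; constant images are errors.
* Histogram densities integrate to 1 within 1e-9; single-valued samples
  fall back to a single bin.
* Wilcoxon: exact only when tie-free and both groups ≤ 10; genes constant
  across both groups get p = 1.
* BH q-values are monotone by construction (step-up with enforcement).
* Empty structures error early with specific messages (empty stack, empty
  study set, empty seed set, all-cells-trimmed, all-nodes-trimmed).
* Determinism: every generator draws from a single `numpy` Generator
  seeded by its spec; pipeline stages derive per-stage seeds from the one
  config seed; two runs with identical config + seed produce byte-identical
  artifacts (verified by checksum).

## 6. Problem sizes

Tests and the acceptance script run deliberately small instances chosen as
the package's own test conditions: stacks of 24–30 slices at 96–128²
pixels, 1,000-cell count matrices with 300 genes, 1,000-gene network
universes with ~600 edges per level, 20-replicate null calibrations of 150
genes at 100 cells per group. These sizes keep the full suite in seconds
while leaving every statistic in its asymptotically valid regime; all
thresholds scale to production-size data unchanged.

## 7. Known limitations

* The clustering metrics depend on the unit-volume calibration; the
  default histogram-mode calibration can misclassify tight clusters whose
  merged volume falls under 2×unit (visible in the worked example: 4/15
  vs the planted 5/15).
* The cropping rule assumes the glass layer is above the brightest
  scaffold slice and brighter in sum but dimmer in peak; stacks violating
  that geometry keep their glass slices.
* Percent mtRNA from counts differs from per-read percentages when reads
  per molecule vary by gene class.
* MCODE's greedy, disjoint expansion means a vertex bridging two dense
  regions joins only the first-ranked one.
* The ORA universe choice materially changes p-values; cross-study
  comparisons must hold it fixed.
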