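# Methods

## Problem and model

`topomet` integrates several targeted metabolomics blocks measured on the
same tissues (here: engineered heart tissues under doxorubicin treatment)
with per-sample functional and design metadata, using the Mapper construction
from topological data analysis.

Let `X_i ∈ R^{n×D_i}` be the Z-scored intensity matrix of block *i* (n
samples shared across blocks, D_i metabolites). The pipeline is:

1. **Preprocessing.** Raw peak areas are divided by each sample's total
   dsDNA content (extract + residual tissue, ng) to correct for tissue
   amount, then each metabolite is Z-scored across samples with the
   population standard deviation (divisor *n*). Missing cells are excluded
   pairwise from all statistics and never imputed; zero-variance columns
   map to all-zero Z scores and are flagged.
2. **Lens.** Each block is embedded to 2D (`f_i : X_i → Y_i ∈ R^{n×2}`)
   with UMAP on the correlation distance `d(s, t) = 1 − r(x_s, x_t)`
   between sample Z-score profiles. The per-block lenses are horizontally
   concatenated into the composite filtered space `Y = [Y_1 | … | Y_B] ∈
   R^{n×2B}` (6 columns for 3 blocks) and each column is min-max rescaled
   to [0, 1].
3. **Cover.** Every composite axis gets K equal-length intervals with
   fractional overlap p (defaults K = 3, p = 0.30): interval length
   L = R / (K − p(K − 1)) for axis range R, interval *i* starting at
   min + i·L·(1 − p). Hypercubes are products of per-axis intervals;
   containment is closed on both ends, so boundary points belong to every
   covering interval.
4. **Mapper / nerve.** Samples in each hypercube are clustered on the
   correlation distance of the concatenated Z-score matrix; each cluster
   becomes a node of the topological connectivity network (TCN), and two
   nodes are joined iff they share at least one sample (edge weight = size
   of the intersection). Connected components are labeled A, B, … by
   decreasing node count, ties broken by lexicographically smallest sample
   id.
5. **Topological node enrichment (TNE).** Per-sample variables are mapped
   to per-node values: arithmetic mean for numeric variables (metabolite Z
   scores, force of contraction), within-node fraction for categorical
   ones. Condition labels (treatment@timepoint) are expanded to one
   indicator per condition, so per-node fractions over the condition set
   sum to 1. Samples appearing in several nodes count in each node
   independently (node-as-cluster semantics).
6. **Inference.** Spearman rank correlations (average-rank ties) between
   metabolite node values and targets (FoC, condition indicators), with
   two-sided p-values from the t approximation at n = number of nodes. The
   screen retains metabolites with, in at least one condition, p < 0.05
   **and** |rho| > 0.60 (strict inequalities; the joint per-condition
   reading — the marginal reading is selectable), zeroes remaining
   sub-threshold cells, hierarchically clusters the retained correlation
   profiles (average linkage, Euclidean, name-sorted input for
   deterministic leaf order), emits chord records for |rho| > 0.60, and
   flags a *switch of association sign* (SAS) when a metabolite passes the
   chord threshold against both FoC and a condition with opposite signs.

Because FoC never enters the Mapper construction, the sample-level Spearman
of each metabolite with FoC is an independent ground truth; the benchmark
reports, per block, the Pearson correlation between the node-level and
sample-level coefficient vectors.

## Parameters that matter

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `n_intervals` (K) | 3 | intervals per composite axis |
| `overlap_frac` (p) | 0.30 | overlap as a fraction of interval length (not of step) |
| `metric` | correlation | 1 − Pearson between sample rows; nan-aware (pairwise complete) |
| `embed_method` | umap | `mds` = classical scaling of the same distance matrix, fully deterministic |
| `n_neighbors` | 15, clamped to n − 1 | UMAP neighborhood; an explicit value ≥ n errors |
| `min_dist` | 0.1 | UMAP minimum embedding distance |
| `cluster_method` | single_gap | single linkage cut at the largest merge-distance gap |
| `gap_frac` | 0.5 | a gap only counts if it exceeds this fraction of the merge-distance spread (and 1e−12 absolute); below that the preimage stays one cluster |
| `contract` | True | drop nodes whose sample set is contained in another node's |
| `p_thresh`, `rho_thresh`, `chord_thresh` | 0.05, 0.60, 0.60 | screen thresholds, strict |

**Node contraction.** The overlapping cover multiplies nodes with identical
or nested sample sets (60–90 nodes from 21 samples at the defaults).
Contraction keeps only maximal distinct sample sets — the same
post-processing the reference Mapper implementation offers — leaving the
covered sample set unchanged while bringing the node count to the scale of
the sample count, which the node-count t-test implicitly assumes. It is the
default; `contract=False` restores one node per (hypercube, cluster).

**Lens rescaling.** Membership in the uniform cover is invariant under
per-axis affine maps, so rescaling to [0, 1] is presentational: it makes
cover geometry comparable across axes and export plots stable.

**Z-scoring scope.** Z scores are computed jointly across all samples (not
within batches); this is the natural choice when all samples form one
design and is what the enrichment benchmark assumes.

## Synthetic data

The generator reproduces the statistical skeleton of the dose–time study:
21 samples = 3 replicates × 7 (treatment, timepoint) conditions (untreated
0 h; DMSO / 1 µM DOXO / 5 µM DOXO at 24 h and 48 h), 48 metabolites in 3
blocks of 16. Exposure = dose level (0, 0, 1, 2) × hours/24 ∈ {0…4}. Per
block, the first quarter of metabolites rises and the second quarter falls
with exposure (log-intensity shift `effect_size × noise_sd` per exposure
unit, defaults 1.5 and 1.0); a per-block per-sample batch factor
(log-sd 0.2) and a lognormal dsDNA factor (removed exactly by
normalization) complete the model. FoC = 100 µN × condition multiplier ×
lognormal noise (sd 0.08), with vehicle controls gaining ≈10 %/day and
DOXO declining with dose and time (strongest at 5 µM/48 h). Baseline peak
areas are drawn log-uniformly in 10⁴–10⁶ to mimic targeted LC-MS
magnitudes.

What the generator does **not** emulate: metabolite-specific pathway
correlation structure, condition-specific (non-monotone) responses,
instrument drift, censoring at the detection limit, or missingness.
Passing tests therefore demonstrate correctness and calibration of the
machinery under a clean monotone dose–time response, not performance on
real LC-MS data.

Micro fixtures (≤12 samples, ≤6 metabolites): `two_cluster` (two groups
separated by a 6-residual-sd shift), `singleton_limit` (run with
`n_intervals=1` and the `singleton` clusterer so each sample is its own
node), `null` (2 replicates × six 24/48 h conditions, no planted effects).

## Numerical choices and degenerate inputs

- Population (divisor n) standard deviation for Z scores; zero-variance
  columns → all zeros + flag.
- Zero-range lens axis → a single interval covering the point (warning).
- The last cover interval's upper bound is clamped to the axis maximum so
  floating-point rounding cannot exclude the extreme sample.
- Preimages of size 1 or 2 are never split (a gap needs ≥ 2 merge
  distances); equidistant point sets stay together.
- Spearman on a zero-variance vector → rho 0, p 1, flagged; fewer than 4
  nodes is an error.
- In the exact singleton limit the benchmark agreement is 1 bit-exactly;
  identical coefficient vectors short-circuit the Pearson computation.
- The classical-MDS fallback fixes reflections by making the
  largest-magnitude loading of each axis positive, so it is a pure
  function of the distance matrix.

## Known limitations

- **Condition-arm ceiling.** A single condition indicator marks 3 of 21
  samples; with mostly condition-pure nodes its rank vector is
  tie-dominated and the attainable |Spearman| is ≈0.65 even for a perfect
  monotone response. With exposure-linear effects, typical condition-arm
  values sit near 0.55, so SAS detection at the strict 0.60 threshold is
  all-or-nothing across simulation replicates. Condition-specific (rather
  than exposure-linear) responses, or graded mixed nodes, raise the
  ceiling.
- **Anticonservative null p-values.** Node values share samples through
  the overlapping cover, so the t test at n = number of nodes overstates
  the effective sample size; on null data the 3-step filter retains a
  metabolite in a substantial fraction of replicates. Contraction
  mitigates but does not remove this; the raw p < 0.05 screen should be
  read as a ranking device, not a calibrated error rate (a
  Benjamini–Hochberg option is available, off by default to match the
  screen's definition).
- The t approximation for Spearman p-values is poor below n ≈ 6 (beyond
  2× the exact permutation p at n = 5).
- UMAP lenses are seed-sensitive at n = 21; the seed is recorded in every
  manifest and the `mds` embedder gives a fully deterministic alternative
  on the same distances.

## Problem sizes used in tests and the acceptance script

The simulation studies run at the native study scale (21 samples, 48
metabolites, 3 blocks): 10 seeds for the enrichment-fidelity and
planted-signal checks, 20 seeds for the null screen, and 50 random
instances (≤50 samples) for the cover/nerve brute-force oracles.
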