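# Methods

## Overview

`plurimap` reconstructs cell-state trajectories from single-cell RNA-seq by
ensemble connectivity: many k-medoids clusterings of a 2-D embedding, a
minimum spanning tree (MST) per clustering, and an average over the
ensemble of each cell's cluster connectivity.  The package also implements
the two upstream steps such pooled experiments need — hashtag
demultiplexing and distribution-based background correction — and a
synthetic-data generator that produces branching pluripotency-state data
with ground truth, so the whole chain is testable without external data.

## Demultiplexing model

Hashtag counts are hashtags × cells.  Libraries are normalised linearly to
the smallest library total, which preserves within-hashtag ranking and is
idempotent.  Assignment is by argmax with fold-change
`fc = (first + 1)/(second + 1)`; the pseudocount keeps `fc` finite when the
second-most hashtag has zero reads and preserves ordering.  Exact
first/second ties are labelled ambiguous.  Doublet removal sorts cells
ascending by `fc` and relabels the first `floor(n · fraction)` as doublets
(a doublet carries two hashtags, so its fold-change is close to 1); ties at
the cut are broken by barcode so the result is deterministic.  The default
removal fraction 0.0382 follows the reference workflow; it is a parameter,
not a derived quantity, because the well count needed to derive it from
Poisson loading is generally not known.  The Poisson estimator returns the
doublet fraction *among occupied wells*, `P(≥2 | ≥1)`, since the filter is
applied to captured cells.

Cell calling from barcode totals finds the knee of the log₁₀(total) versus
log₁₀(rank) curve: the curve is smoothed with a centred moving average
(window 5), the steepest negative smoothed slope is located, and the
threshold is placed at the largest raw single-rank drop within one window
of that point (geometric mean of the totals on either side).  Using the raw
drop for placement avoids the rank bias that smoothing introduces at a
plateau edge.  A monotone curve without negative slope warns and retains
all barcodes.

## Background correction

For each gene with any `log2(x+1)` value above 8, the positive log values
are decomposed into two equal-variance 1-D Gaussian components by EM
(means initialised at the data minimum and maximum, weights ½, shared
variance at the sample variance, ≤100 iterations, tolerance 1e−6 on the
log-likelihood, variance floor 1e−6).  When the lower component's mean is
≤ 5.5 and the separation of means is ≥ 5, counts of cells with posterior
≥ ½ for the lower component are zeroed.  The three gates are the normative
content of the procedure; the equal-variance mixture is the simplest model
consistent with them.  Correction is monotone (never increases a count) and
idempotent in practice: after zeroing, the remaining positive values are
unimodal-high, so the gap gate fails on a second pass.  Genes with fewer
than four positive values or degenerate spread fall back to a single
component and are left untouched.

## Embedding and clustering

Preprocessing removes cells below a minimum total (default 200, synthetic
scale) and genes detected in fewer than 3 cells, scales cells to the median
total, applies log1p, and keeps the top 500 genes by variance of the logged
values (ties broken by gene order).  Classical (Torgerson) MDS
double-centers −D²/2 and takes the top-2 eigenpairs (Lanczos with a fixed
start vector above n = 200, dense otherwise); each axis's sign is fixed so
its first non-negligible loading is positive.  Negative eigenvalues are
clamped to zero.

CLARA draws 5 subsamples of size 40 + 2k, solves each with PAM, assigns all
cells to the nearest medoid, and keeps the sampling with the lowest
full-data cost; with a subsample as large as the data it reduces exactly to
PAM.  PAM is greedy BUILD plus steepest-descent single-swap passes; because
single-swap descent can stall in a local optimum even on toy instances,
four additional seeded random starts are swapped to convergence and the
best solution kept.  All tie-breaks are by lowest index, so every run is
deterministic given its seed.  The ensemble runs CLARA `n_runs` times with
k cycling evenly over [k_min, k_max] (defaults 3–20) and seeds
`base_seed + r`.  The desk-scale default is 1,000 runs; the reference
workflow used 10,000, and the larger ensemble only narrows the Monte-Carlo
spread of the per-cell score.

## Connectivity, selection, trajectory

Inter-cluster distances are the Mahalanobis-like form
`d²(i,j) = Δᵀ[(Σᵢ+Σⱼ)/2 + εI]⁻¹Δ` with ridge `ε = 1e−6 ×` the mean
embedding variance (singletons contribute the ridge alone).  This form
makes broad, diffuse clusters "closer" to everything — which is exactly
what lets a heterogeneous starting population act as the hub of the tree.
The MST is Prim's algorithm with lexicographic tie-breaks; cluster
connectivity is MST degree divided by k, so the per-run mean is exactly
2(k−1)/k².  The per-cell score averages the cell's cluster connectivity
over all runs with equal weight (the alternative of weighting runs by k has
no support in the reference description).

Candidate clusterings are ranked by the Calinski–Harabasz variance ratio on
the 1-D connectivity vector; zero within-cluster variance returns an
infinite sentinel so ranking still works.  The reference workflow examined
the top twenty by eye and chose the one resolving three differentiation
routes; the automated stand-in picks the first of the top twenty whose
final MST has ≥ 3 root-to-leaf lineages and at least one route of ≥ 3
clusters, falling back to top-1.  The root is the cluster with the highest
mean connectivity, restricted to clusters whose mean marker score is above
the across-cluster median when a marker score (e.g., mean expression of
user-supplied pluripotency genes) is given.

Lineages are the unique root→leaf paths of the final MST.  Pseudotime
simplifies iterative simultaneous principal curves to fixed
piecewise-linear curves through each lineage's ordered cluster centroids:
each cell is assigned to every lineage containing its cluster (weight
1/number of such lineages) and its pseudotime is the arc length of its
orthogonal projection onto the curve, clamped to the curve.  This is
deterministic and adequate for ordering; it does not iterate curve
re-fitting, so curves do not bend inside clusters.  The connectivity
landscape linearly interpolates per-cell scores on a regular grid over the
embedding's bounding box (5% margin), with nearest-neighbour fill outside
the convex hull.

## Synthetic data generator

The generator emulates a pooled naive-conversion experiment at desk scale:
3,000 cells, 2,000 genes, seven states on the trajectory tree

    primed → bridge → intermediate_A → naive
    primed → intermediate_B → ectoderm
    primed → mesoderm

with seven 50-gene programs (pluripotency, naive-related, metallothionein,
differentiation-suppressive, neural, mesodermal, housekeeping).  Counts are
negative binomial with log-mean `log(base) + Σ logFC_p · activation_p`,
dispersion 2, baseline mean 0.5.  Activations are piecewise-linear in the
position along each lineage and continuous across state boundaries:

- The primed population is a broad cloud: pluripotency at a constant
  mid-level, *lineage priming* ramps (each primed cell ramps the leading
  program of its own fate up to amplitude 0.35), and a stochastic leak of
  up to 0.35 of the off-route programs.  The breadth is deliberate — it is
  what places the primed population at the centre of the Mahalanobis
  distance structure, as the starting population is in the real data.
- The bridge is a narrow spur: a transient pluripotency peak (the
  Oct4⁺/Nanog⁺ subpopulation) that the MST tends to bypass, reproducing its
  observed low connectivity.
- The two intermediate halves share one naive-inducer corridor and diverge
  only late and in few programs (metallothionein and a transient
  differentiation-suppressive pulse for the naive-fated half, neural for
  the neural-fated half) — the "similar profiles, few critical genes"
  property of the plastic hub.
- Termini complete their ramps; the mesoderm offshoot leaves the primed
  cloud directly.

The bridge sits on the naive route only, matching the reconstructed
trajectory of the reference data (the ectoderm route leaves the primed/hub
region without an Oct4/Nanog peak).  State sizes default to primed 1000,
bridge 150, intermediates 250 + 300 each side, naive 350, ectoderm 350,
mesoderm 550.  `branch_noise_sd` (default 0.05) jitters each cell's
position along its trajectory; `discrete_states` flattens every gradient to
the state midpoint, giving separable blobs for clustering-recovery tests.
Doublets are formed by over-generating `floor(rate · n)` extra singlets and
summing each into a resident cell, so the configured cell total is
preserved; the standalone doublet injector merges pairs within a given
matrix and therefore returns fewer cells.  Hashtags model one sample per
tag with deliberately unequal depths (500–2,000) and a background fraction
spread uniformly over the other tags; doublets mix two tags at half weight.

What the generator does *not* model: UMI chemistry or read-level artifacts,
ambient RNA with a realistic soup profile (ambient injection for testing is
explicit and position-tracked), batch effects, cell-cycle structure, or
dropout beyond what the negative binomial induces.  Passing tests therefore
show that the pipeline recovers the intended structure under its own
generative assumptions, not that it is robust to all properties of real
data.

## Problem sizes and numerical choices

Analyses and tests run at 3,000 cells with 100–1,000-run ensembles; the
lineage-recovery experiment uses 20 seeds at 200 runs each.  These sizes
were chosen so the whole study executes on a laptop-class single CPU in
minutes while leaving the Monte-Carlo margins of its claims intact.
Floating-point tie-breaks in PAM and the MST are by lowest index; the EM
variance floor is 1e−6; the landscape interpolation falls back to
nearest-neighbour when all cells are collinear.  QC percentages round
half-up to one decimal to match conventional reporting.

## Known limitations

- Pseudotime curves are polylines through centroids; within-cluster
  ordering along a direction orthogonal to the curve is unresolvable, and
  sharp trajectory folds (like the bridge spur) locally scramble the
  projection.
- The VRC selects clusterings by connectivity contrast, not biological
  resolution; the structural top-20 filter is a stand-in for expert
  inspection and is exposed as a parameter.
- The equal-variance two-component model under-corrects genes whose
  background and signal variances differ strongly.
- With fewer than two hashtags, demultiplexing degenerates to a single
  assignment with infinite fold-change.
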