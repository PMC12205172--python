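# Methods

This package diagnoses *ambiguous mappings* in diagonal integration of
multimodal single-cell data: situations where two regions of a data
manifold are geometrically interchangeable, so an anchor-free integration
method can map either region onto the other modality's counterpart with
near-identical cost. The resulting "artificial" integrations are
mathematically plausible and biologically wrong, and they are invisible to
the integration method's own objective. The diagnosis below never claims
to know the biological truth; it reports whether alternatives exist and
what they are.

## Model and procedure

### Manifold approximation

Each modality is a cell x feature matrix whose cells are assumed to lie
near a low-dimensional manifold. The manifold is approximated Isomap
style: a weighted k-nearest-neighbor graph (union symmetrization,
Euclidean feature distances) is built, and all-pairs shortest-path lengths
serve as geodesic distances. If the k-NN graph is disconnected, k is
incremented until it connects; the value used is recorded. Note that
graph-geodesic distances are blind to extrinsic geometry such as the
angles between branches of a tree-shaped manifold — only path lengths and
sampling densities matter. This has real consequences for what counts as
"congruent" (see the simulated benchmarks below).

### Self-alignment with Gromov-Wasserstein transport

Ambiguity within one modality is exposed by aligning the modality to
perturbed copies of itself. A *variational replicate* adds Gaussian noise
with standard deviation `noise_sd * sd_f` per feature f (relative scaling
keeps perturbations comparable across features) and rebuilds the geodesics
with a neighbor count drawn from a ladder of 5%, 10% and 20% of the cell
count, cycled across replicates. The replicate is aligned to the source by
entropically regularized Gromov-Wasserstein (GW) optimal transport over
the two geodesic metric spaces, with uniform marginals and the quadratic
loss L(a, b) = (a - b)^2 / 2. Because the noise breaks exact
self-identification, the transport cannot collapse onto the trivial
identity; wherever distant regions are congruent, different replicates
(and the entropic smoothing itself) distribute mass across the identity
and the region-exchanging isometries.

The default ensemble uses 20 replicates. Smaller ensembles under-sample
the isometry group of richly symmetric manifolds: the X-shaped benchmark's
geodesic space has an 8-element dihedral symmetry group, and an arm pair
is only covered when some replicate's alignment lands in a basin whose
isometry moves that pair. The *consensus* coupling is the elementwise mean
of the replicate couplings, symmetrized as (G + G^T)/2 since cell-cell
ambiguity is a symmetric relation.

### The GW solver

No transport library is used; the solver is part of the package:

* Outer loop: the standard quadratic-loss tensor factorization
  (the four-index cost never materializes; each linearization costs two
  matrix products), re-projected each iteration by a log-stabilized
  Sinkhorn loop with warm-started dual potentials.
* Distance matrices are max-normalized before solving so the entropic
  regularization `epsilon` (default 5e-3) transfers across datasets.
* Epsilon annealing: the first ten outer iterations tighten epsilon
  geometrically from 0.05 to its target, a graduated-non-convexity scheme
  that flattens spurious basins early.
* Restarts: the problem is non-convex; for small instances
  (n*m <= 10,000) the solve restarts from ten spiky random couplings
  (Gamma(0.5) entries, normalized). Restart selection scores each
  candidate by the objective of its *hardened* (row-argmax, row-marginal
  mass) assignment, not the blurred coupling: at finite epsilon the
  entropic blur can make the wrong basin's continuous objective lower
  than the right basin's.
* Discrete refinement: for square uniform-marginal problems with
  n <= 12, every restart is rounded to a permutation by Hungarian
  assignment and improved by pairwise-swap plus 3-cycle local search on
  the exact vertex objective, with additional random-permutation
  multistarts (cheap at this size). The returned coupling is a feasible
  mixture concentrated on the winning vertex. This makes small instances
  reliably globally optimal (validated against exhaustive permutation
  search), without touching the large-instance path.
* Only iterates whose inner projection reached feasibility (marginal
  error < 1e-7) are eligible to be returned; the reported objective
  history is the running best and is non-increasing by construction.

Scaling note: multiplying both metrics by c (with epsilon scaled by c^2)
leaves the coupling pattern unchanged and scales the quadratic objective
by exactly c^2.

### Calling ambiguous cell pairs

The null hypothesis is that correspondence probability can only decay
with geodesic distance. Two fits operationalize it:

* A **reporting null**: a cubic smoothing spline (generalized
  cross-validation) fit to 100 equal-count distance-bin means of the
  consensus, projected through pool-adjacent-violators onto the monotone
  non-increasing cone and clamped at zero. This is the `expected` column
  in the output and is guaranteed antitonic on a dense grid.
* A **testing null**: consensus mass spans many orders of magnitude
  across distances, so a single global scale would be set by the far-pair
  noise floor and is useless. Instead an antitonic curve through the
  per-bin *medians* (robust: the ambiguous pairs themselves cannot drag
  it) is interpolated across bin centers and subtracted; the residuals
  are standardized per bin by median and 1.4826*MAD, and one-sided
  upper-tail p-values come from the standard normal. Interpolating the
  median curve also removes the within-bin distance trend that would
  otherwise inflate the scale estimate; under a synthetic null
  (monotone f(K) plus Gaussian noise) the p <= alpha rate is calibrated
  to within binomial error.

A pair is called **significant** iff all three hold:

1. p <= alpha (default 0.01);
2. its geodesic distance exceeds the 20th percentile of off-diagonal
   distances — nearby cells legitimately share correspondence mass, and
   only far-apart look-alikes indicate ambiguity;
3. its mass is at least 2x the same-distance typical mass, measured on a
   pseudo-counted scale (pseudo-count = 1% of the uniform coupling value
   1/n^2). This minimum-effect-size clause encodes that ambiguity means a
   distant pair couples like a neighbor: planted-ambiguity folds on the
   benchmarks run 5-200x, while density fluctuations along an unambiguous
   trajectory stay in the few-percent range, and mass far below 1/n^2 is
   physically negligible however locally "outlying" it is.

No multiple-testing correction is applied (the raw 1% cutoff is the
intended operating point); Benjamini-Hochberg can be bolted on downstream
from the returned p-values if desired.

A dataset is **flagged ambiguous** when the significant fraction exceeds
`2 * alpha`: below that, the calls are indistinguishable from the test's
false-positive budget.

### Aggregating pairs into substitutable groups

Significant pairs become cannot-link constraints (confused cells must
land in different groups, because groups are the units that substitute
for one another). Constraints whose fold change is below 10% of the 90th
percentile fold of all significant pairs are dropped first: folds in a
diagnosis often split into a headline regime (full-region congruence) and
a much weaker regime caused by *partial* congruences — any two equal
arc-length segments of a trajectory look locally alike — and the weak
regime would otherwise manufacture spurious extra groups. The cut is
relative, so it is inert when all folds are comparable.

Constrained cells are embedded by 2-D classical (Torgerson) MDS of their
geodesic submatrix and clustered COP-k-means style: greedy
constraint-respecting nearest-centroid assignment, best of ten restarts
by (violations, then inertia), for k = 1..8. The group count is chosen
from the violations-vs-k curve: the smallest k resolving at least 95% of
the k = 1 violations (the plateau), falling back to the point of maximal
vertical distance below the endpoint chord when no k qualifies. Cells in
no (strong) significant pair are labeled unambiguous (-1).

### Alternative integration solutions

For each pair of groups (Gs, Gt) whose mean inter-group consensus mass
exceeds the spline-expected mass at the corresponding distances, a soft
permutation P is assembled: rows in Gs carry the consensus mass toward Gt
(renormalized to sum to one, so P stays row-stochastic and the
alternative remains transport-like) and vice versa; all other rows are
identity. The alternative integration is exactly `P @ gamma_xy`. The
original coupling is always returned alongside, and candidates are
unranked unless ground truth is supplied: geometry cannot decide which
solution is biologically true. When the swapped block is a hard
permutation, P is an involution (applying it twice recovers the
original).

### Evaluation metrics

* **FOSCTTM**: for each cell, the fraction of the other modality's
  non-match cells strictly closer than its true match (ties count as not
  closer), averaged over both directions; 0 is perfect, 0.5 is the
  random-pairing expectation. Couplings are scored after barycentric
  projection (each x cell placed at its coupling-weighted mean partner
  position).
* **Label transfer accuracy**: k-NN majority vote (default k = 5) from
  source to destination in the aligned space, majority ties broken by
  summed inverse distance; both directions are available, the headline is
  their mean.

## Simulated benchmarks

Four two-modality designs, each with 300 cells on a shared 2-D latent
manifold, lifted to 1000 and 2000 feature dimensions by independent
random linear maps with orthonormalized columns, then i.i.d. Gaussian
feature noise with sigma = 0.1:

* **t_branch** — two collinear unit arms (exact mirror images, sharing
  one draw of arc-length parameters, so the mirror is an exact isometry
  of the sampled point set) plus a stem. The stem is 1.5x longer than the
  arms: because geodesic distances ignore arm angles, three equal-length
  arms would be mutually congruent *in the geodesic metric* no matter the
  angles, and the design intends exactly one congruent pair.
* **y_branch** — three unit arms at 120 degrees, all congruent.
* **x_branch** — four unit arms at 90 degrees, all congruent.
* **decay_path** — a hook (straight segment of length 2 plus a
  semicircular hook of radius 0.5) sampled with exponentially decaying
  density, rate chosen so the first-to-last arc-length-quartile count
  ratio is ~4. The straight and curved parts are incongruent; nothing is
  ambiguous. This is the negative control.

The lift is scaled by sqrt(p) so individual features have unit-order
magnitude; without that scaling, sigma = 0.1 noise across 1000+ features
would swamp the manifold geometry entirely and no method could recover
the branches. Identity correspondence and branch labels are returned as
ground truth.

What these benchmarks do *not* emulate: count-like sparsity and
overdispersion, batch effects, uneven cell-type abundances, and
modality-specific feature noise structure. Passing them shows the
geometry-driven machinery works under exact planted congruence; on real
data, ambiguity is approximate and the fold-change and flagging margins
will be narrower.

## Defaults at a glance

| parameter | default | meaning |
| --- | --- | --- |
| `n_replicates` | 20 | variational copies in the self-alignment ensemble |
| `noise_sd` | 0.1 | per-feature relative noise of a replicate |
| k ladder | 5/10/20% of n | replicate neighbor counts (cycled); source graph uses 10% |
| `epsilon` | 5e-3 | entropic regularization (max-normalized distances) |
| `alpha` | 0.01 | one-sided significance cutoff |
| `local_quantile` | 0.20 | geodesic quantile below which pairs are never called |
| `min_fold_change` | 2.0 | minimum mass ratio vs same-distance typical mass |
| flag threshold | 2 * alpha | significant fraction above which a dataset is flagged |
| `Kmax` | 8 | largest group count tried by the elbow |
| `strength_frac` | 0.1 | constraint cut relative to the 90th-percentile fold |

All randomness (noise draws, solver restarts, clustering restarts) is
driven by one integer seed expanded through numpy generators; identical
seeds give bit-identical runs.

## Numerical choices and degenerate inputs

* Duplicate cells produce zero-weight k-NN edges; weights are replaced by
  the smallest positive float with a warning.
* Fewer than ten distinct geodesic distances: the null spline falls back
  to an antitonic step function (warning).
* Zero deviation spread: all p-values are set to 0.5 (warning); nothing
  is significant.
* A cell with no cross-group consensus mass is mapped to the opposite
  group's highest-mass cell during swap construction (warning).
* Couplings are validated to marginal error 1e-6; the solver targets
  1e-9 internally.

## Known limitations

* Group swaps are pairwise; chained or simultaneous multi-group
  permutations are not composed.
* The diagnosis is per-modality; it does not fuse evidence across both
  modalities of a pair.
* Runtime is dominated by the GW ensemble (~10 s for 300 cells and 20
  replicates on one core; the solve is O(n^2) memory and roughly O(n^3)
  time per replicate), so very large datasets need subsampling.
* The significance machinery assumes enough cell pairs (hundreds) to
  estimate per-bin robust scales; tiny datasets fall back to coarser
  binning automatically but lose power.
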