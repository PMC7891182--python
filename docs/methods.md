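# Methods

## Scope and model

`wmnet` implements the standard analysis chain for FA-weighted structural
brain networks built from diffusion-MRI deterministic tractography:

1. **Network construction** (toy scale): FACT streamline tracking on a voxel
   grid carrying per-voxel fractional anisotropy (FA), principal fiber
   direction, and a parcel label; streamline endpoints define edges between
   parcels, gated by a minimum fiber count, weighted by mean FA.
2. **Graph metrics** over a sparsity band, normalized against
   degree-preserving random networks, summarized as areas under the
   metric-vs-sparsity curve (AUC), plus per-region efficiency/betweenness
   and hub identification.
3. **Network-based statistic (NBS)**: permutation inference on connected
   components of edge-wise suprathreshold group differences.
4. **Group statistics**: covariate-adjusted ANOVA of AUC metrics, gatekept
   post-hoc contrasts, FDR across regions, Spearman brain-behavior
   correlations.
5. **Synthetic cohorts**: a generator producing three-group cohorts with
   known planted effects so that every stage is testable without MRI data.

## Tractography conventions

FACT is implemented in its simplest voxel-hop form: nearest-neighbor steps
of one voxel along the local principal direction, bidirectional launch from
every voxel with FA >= `fa_seed_min` (default 0.2), and termination on grid
exit, on a sub-threshold FA at the *next* voxel (that voxel is not
entered), on a turning angle above `angle_max_deg` (default 45 deg; the
turning voxel is kept and propagation stops there), or at a step cap.
Principal directions are sign-ambiguous eigenvector surrogates, so each
step re-orients the local vector to agree with the current heading.
Sub-voxel (trilinear) interpolation is deliberately not implemented: the
voxel-hop variant keeps every tracking example exactly checkable by hand.

Edges require at least `min_fibers = 3` streamlines between two parcels.
The edge weight pools mean FA over *all voxels of all connecting
streamlines* (not the mean of per-streamline means); the two conventions
agree when streamlines have equal length. Duplicate trajectories from
collinear seeds count as distinct fibers, since fiber counts, not unique
paths, gate the edge.

## Graph-metric conventions

Weighted-network analysis requires fixing several conventions; `wmnet` uses
the ones dominant in connectome toolboxes, and validates each against an
independent brute-force oracle in the test suite rather than against any
published table:

* distance on an edge: `d_ij = 1 / w_ij`;
* `Lp`: arithmetic mean of shortest-path distances over *connected* ordered
  pairs (disconnected pairs are excluded, not imputed);
* `Eglob` and nodal efficiency: Latora-Marchiori mean inverse distance,
  disconnected pairs contributing 0;
* `Cp`: Onnela geometric-mean triangle weights, normalized by the matrix
  maximum, averaged over all nodes (degree < 2 contributes 0);
* `Eloc`: mean over nodes of `Eglob` of the neighbor-induced weighted
  subgraph;
* betweenness: Brandes on reciprocal-weight distances, unnormalized, each
  unordered pair counted once.

Consequences worth knowing: multiplying all weights by c > 0 multiplies
`Eglob` and nodal efficiency by c, divides `Lp` by c, and leaves `Cp` and
the hub set unchanged.

**Sparsity thresholding** keeps the `K = round(s * N(N-1)/2)` strongest
edges (round half away from zero), breaking weight ties by ascending
`(i, j)` order so that output is deterministic. Surviving edges keep their
weights. The default band is 0.10-0.15 in steps of 0.01 — the range in
which global metrics of 90-region FA networks are stable — with a wider
screening band available through `SparsityGrid`.

**Random normalization** builds surrogates by attempted double-edge swaps
on the binarized topology (10 x edge-count attempts per surrogate; binary
degrees preserved exactly) followed by random permutation of the original
weight multiset onto the rewired edges. `gamma = Cp/<Cp_rand>`,
`lambda = Lp/<Lp_rand>`, `sigma = gamma/lambda`. Graphs that admit no swap
(e.g. stars) yield surrogates with the original topology, logged. The
default ensemble is 1000 surrogates; the validation suite and the
acceptance script use 100, which changes gamma/lambda estimates by well
under the margin of any of the checks.

**Hubs** are nodes whose betweenness is >= mean + one sample SD (ddof=1) of
the network's betweenness. When all values coincide the SD is 0 and all
nodes are flagged; the degenerate case is kept rather than special-cased.
Group-level hubs are computed on the group-mean connectivity matrix
(per-subject hub sets remain available by calling `identify_hubs` on any
subject's betweenness vector).

**AUC** uses trapezoidal integration over the sparsity axis; a missing
metric value at any grid point makes that AUC missing.

## NBS

Edge-wise statistics are one-way ANOVA F (omnibus) or pooled-variance
two-tailed t (pairwise). Only edges present in at least 50% of subjects
are tested; never-present edges would produce degenerate statistics. Edges
with uncorrected p below `primary_p = 0.01` are grouped into components by
shared nodes; the component size is its edge count. The null distribution
records the maximal component size under `n_perm` full relabelings of the
subjects in the contrast. The corrected p-value is
`(1 + #{max >= M}) / (n_perm + 1)` — the +1 smoothing keeps p-values valid
and strictly positive; the unsmoothed strict-inequality proportion is
available via `strict_greater=True`. Inside the permutation loop the
threshold is applied on the statistic scale (|t| or F beyond the critical
value for `primary_p`), which is equivalent to thresholding p and avoids
500,000 distribution-function calls. Covariate residualization before the
edge-wise test is not applied by default (the group + covariate design is
handled at the AUC/nodal level).

## Group statistics

The ANCOVA fits `y ~ group + age + sex` by OLS and tests the group
indicators with the extra-sum-of-squares F against `y ~ age + sex`.
Constant covariates are dropped (with a warning) so informationless
covariates reproduce the plain ANOVA exactly; genuinely collinear designs
raise `DesignError`. Post-hoc pairwise contrasts come from the same fitted
model and are gatekept by the omnibus test at 0.05 (configurable off for
power studies); correction is Bonferroni or Benjamini-Hochberg. FDR for
nodal metrics is applied across the 90-region family separately per metric
and contrast — the most common convention where the scope is ambiguous.
Spearman correlations use average ranks for ties and the two-sided
t-approximation, reported uncorrected.

## Synthetic cohort generator

The generator's defaults define the simulated study conditions: three
groups (HC, NC, MCI) of 30 subjects, 90 regions, template edge density
0.25, FA weights ~ N(0.45, 0.10) clipped to (0, 1].

* **Template topology**: nodes at uniform random positions in the unit
  cube; four spatially coherent modules (nearest of four random
  centroids); connection probability proportional to
  `exp(-d/0.25) * (2 if same module)`, scaled to the target density, and
  stray components joined through their closest node pairs. Geometric
  proximity plus modularity produces the high clustering and short paths
  (sigma > 1) characteristic of structural brain networks, which an
  Erdos-Renyi template would not.
* **Subject variation**: per-edge lognormal noise (sigma = 0.15) times a
  per-subject global lognormal factor (sigma = 0.03). The global factor
  sets the between-subject spread of whole-network efficiency at a few
  percent, a realistic scale for FA-weighted networks; the per-edge term
  makes edge-wise tests non-degenerate.
* **Group effect**: multiplicative attenuation of all edge weights by
  `eglob_effect = 0.93` per group step, lowering Eglob and raising Lp
  smoothly without changing density.
* **Planted subnetwork**: 8 template edges grown breadth-first from a
  well-connected node (hence 9 nodes, 8 edges, always connected); MCI
  subjects lose `planted_delta = 0.2` of FA on those edges, floored at 0.
* **Cognition**: DST-forwards (positively) and TMT-A/TMT-B (negatively,
  they are completion times) linked to the subject's true whole-matrix
  Eglob via a standardized linear model with slope 0.5 and unit noise,
  giving latent correlations near 0.45 and within-group rank correlations
  in the 0.25-0.45 range typical of brain-behavior tables. Scores have
  realistic bases/spreads and plausibility floors.
* **Reproducibility**: one root seed; template, planted-edge selection,
  each subject, phenotypes, and cognition noise each use independent
  counter-offset substreams (`default_rng([seed, offset])`), so outputs do
  not depend on generation order.

What the generator does **not** emulate: scanner physics and acquisition
noise, head motion, white-matter lesions, atlas misregistration,
tractography biases (crossing fibers, gyral bias), distance-dependent FA
profiles, or realistic covariate confounding (age/sex are generated
independently of the matrices). Passing the simulation-based checks
therefore demonstrates that the *analysis chain* is correct and calibrated
— not that it would detect effects of this size in real MRI data, where
all of the above inflate variance.

## Validation design and problem sizes

Every deterministic operation is pinned by hand-computed examples, and the
metric kernels are checked to 1e-9 against brute-force oracles (explicit
Floyd-Warshall, exhaustive shortest-path counting, hand union-find, ranked
Pearson, sum-of-squares ANOVA) on random graphs with N <= 12. The
statistical machinery is validated by calibration and recovery at the
package's chosen desk-scale problem sizes: 200 null cohorts (2 x 15
subjects, 500 permutations) for NBS type-I error; 50 planted-deficit
cohorts (30/group) for NBS power and localization; 50 graded-attenuation
cohorts plus 100 null cohorts for the ANCOVA recovery and its nominal 5%
rejection rate; and one full-size cohort with 100-surrogate normalization
for the small-world bound. These sizes give binomial standard errors of
1.5-4 percentage points on the estimated rates, adequate for the
pass-bands used in the tests.

## Known limitations

* The toy tracker is voxel-hop only; no sub-voxel interpolation, no
  multi-direction voxels, no curvature-radius constraints.
* `Eloc` costs roughly an order of magnitude more than the other global
  metrics (one efficiency computation per node); `metric_curves` therefore
  accepts a metric subset for simulation loops.
* The NBS implements group contrasts only (no general linear model
  contrasts, no threshold-free cluster enhancement).
* Region labels default to a synthetic `R001...R090` naming; the packaged
  AAL-90 abbreviation list can be attached for readability, but no atlas
  geometry is shipped.
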