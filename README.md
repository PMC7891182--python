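# wmnet

Analysis of **FA-weighted white-matter structural connectomes**: network
construction from deterministic tractography, sparsity-thresholded
graph-theory metrics with random-network normalization, network-based
statistics (NBS), and covariate-adjusted group comparison — with a
synthetic-cohort generator so the whole chain runs and validates without
any MRI data.

The package targets the study design common in clinical diffusion-MRI
work: three groups (healthy controls, patients with normal cognition,
patients with mild cognitive impairment), one 90-region FA-weighted
adjacency matrix per subject, and the question of where and how strongly
the white-matter network differs between groups and how those differences
relate to cognitive scores.

## The analysis in brief

* **Edges and weights.** Streamlines are tracked with FACT (seed wherever
  FA >= 0.2; stop when FA < 0.2 or the turning angle exceeds 45 deg). Two
  regions are connected when >= 3 fibers run between them; the edge weight
  is the mean FA along the connecting bundles, giving a symmetric
  `N x N` matrix per subject.
* **Metrics.** With edge distance `d_ij = 1/w_ij`: clustering coefficient
  `Cp` (Onnela, max-normalized), characteristic path length `Lp`, global
  and local efficiency `Eglob`, `Eloc`, nodal efficiency, and betweenness
  centrality. Each is evaluated at sparsity thresholds 10-15% (step 1%)
  and summarized by the area under the curve (AUC). Normalized quantities
  `gamma = Cp/Cp_rand`, `lambda = Lp/Lp_rand` and the small-world index
  `sigma = gamma/lambda` use degree-preserving rewired surrogates;
  `sigma > 1` indicates small-world organization. Hubs are nodes with
  betweenness >= mean + SD.
* **NBS.** Edge-wise ANOVA/t statistics, a primary component-forming
  threshold (p < 0.01 uncorrected), and a permutation null (default 5000
  relabelings) of the maximal suprathreshold component size give
  family-wise corrected p-values for impaired subnetworks.
* **Group statistics.** One-way ANOVA of AUC metrics adjusted for age and
  sex, gatekept post-hoc contrasts with Bonferroni/FDR correction, FDR
  across regions for nodal metrics, and Spearman correlations with
  cognitive scores.

See `docs/methods.md` for every convention and the generator's design.

## Worked example

```python
import numpy as np
from wmnet import (CohortConfig, NBSParams, RandomReferenceParams,
                   SparsityGrid, generate_cohort, metric_curves, nbs_test)

# a three-group cohort: 30 subjects/group, 90 regions, graded efficiency
# loss (7% per group step) plus a planted 8-edge deficit in the MCI group
cohort = generate_cohort(CohortConfig(seed=7))

# small-world profile of the first subject
curve = metric_curves(cohort.matrices[0], SparsityGrid(),
                      random_params=RandomReferenceParams(n_random=100, seed=0),
                      metrics=("cp", "lp"))
print(curve.table[["cp", "lp", "sigma"]].round(4))

# NBS: which subnetwork is impaired in MCI vs HC?
res = nbs_test(cohort.stack, cohort.groups,
               NBSParams(n_perm=500, seed=0), contrast=("HC", "MCI"))
top = res.significant[0]
print(f"component of {top.size} edges, corrected p = {top.p_corrected:.4f}")
```

Output:

```
              cp      lp   sigma
sparsity
0.10      0.0991  3.7568  1.4339
0.11      0.1078  3.6829  1.4061
0.12      0.1087  3.6199  1.3757
0.13      0.1202  3.5657  1.4151
0.14      0.1328  3.5216  1.4748
0.15      0.1430  3.4868  1.4906
component of 751 edges, corrected p = 0.0020
```

`sigma > 1` at every sparsity says the subject's network is small-world
(clustered like a lattice, short paths like a random graph). The NBS
component is large here because the default cohort carries a *global*
efficiency deficit on top of the focal one; with only the planted 8-edge
deficit (`CohortConfig(eglob_effect=1.0, planted_delta=0.2)`) the
recovered component closely matches the planted edges.

A command-line interface mirrors the library:

```bash
wmnet simulate --out cohort/ --seed 7
wmnet run --cohort cohort/ --out results/ --n-random 100 --n-perm 500
```

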