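"""Synthetic cohorts of FA-weighted structural connectomes with phenotypes.

The generator emulates a three-group diffusion-MRI study design -- healthy
controls (HC), diabetic patients with normal cognition (NC), and diabetic
patients with mild cognitive impairment (MCI), 30 subjects each by default --
on a shared 90-region template:

* **Template topology** is a random geometric graph on uniformly sampled 3-D
  coordinates with four spatially coherent modules (connection probability
  decays with inter-node distance and is boosted within modules).  This
  yields high clustering with short paths, i.e. small-world organization,
  which a plain Erdos-Renyi template would not.
* **Group effect**: per group step (HC -> NC -> MCI) every edge weight is
  attenuated multiplicatively (default 0.93 per step), lowering global
  efficiency and raising path length smoothly without changing density.
* **Planted subnetwork**: MCI subjects additionally lose ``planted_delta``
  of FA weight on a connected set of ~8 template edges (9 nodes), emulating
  a focal impaired subnetwork for the network-based statistic to recover.
* **Cognition**: each subject's cognitive scores are affine in their true
  global efficiency plus Gaussian noise, signed so that higher efficiency
  means better performance (and *lower* completion time on the timed
  trail-making tests).

Reproducibility: one root seed; the template, each subject, the phenotype
table, and the cognition noise each draw from an independent counter-offset
substream, so results do not depend on generation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .matrix import ConnectivityMatrix, default_labels
from .metrics import _eglob

__all__ = [
    "GROUPS",
    "CohortConfig",
    "Cohort",
    "CohortConfigError",
    "PlantedEdgeError",
    "generate_cohort",
    "plant_subnetwork_effect",
    "null_config",
]

logger = logging.getLogger(__name__)

GROUPS = ("HC", "NC", "MCI")

# (base score, score SD, sign of the efficiency link, floor): DST counts
# digits (higher = better); TMT-A/TMT-B are completion times in seconds
# (higher = worse).  Bases/SDs sit in the realistic adult clinical range;
# the floor keeps extreme noise draws physically plausible.
_COGNITIVE_TESTS: dict[str, tuple[float, float, int, float]] = {
    "DST_forwards": (9.1, 1.1, +1, 2.0),
    "TMT_A": (55.0, 18.0, -1, 12.0),
    "TMT_B": (70.0, 25.0, -1, 15.0),
}


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


class PlantedEdgeError(ValueError):
    """A planted edge does not exist in the template topology."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a simulated cohort.

    ``eglob_effect`` is the multiplicative edge-weight attenuation applied
    once per group step (HC=1, NC=effect, MCI=effect^2); 1.0 disables the
    graded group difference.  ``planted_delta`` is the absolute FA reduction
    on ``planted_edges`` in MCI subjects; 0 disables the focal deficit.
    """

    n_per_group: int = 30
    n_regions: int = 90
    base_density: float = 0.25
    fa_mean: float = 0.45
    fa_sd: float = 0.10
    eglob_effect: float = 0.93
    planted_edges: tuple[tuple[int, int], ...] | None = None
    n_planted: int = 8
    planted_delta: float = 0.2
    edge_noise_sd: float = 0.15
    subject_sd: float = 0.03
    cognition_slope: float = 0.5
    cognition_noise_sd: float = 1.0
    age_range: tuple[float, float] = (45.0, 66.0)
    sex_ratio: float = 0.5
    education_mean: float = 11.5
    education_sd: float = 3.0
    # template shape parameters: distance decay length (unit cube) and the
    # within-module connection-probability multiplier
    distance_decay: float = 0.25
    module_bonus: float = 2.0
    n_modules: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise CohortConfigError("n_per_group must be >= 2")
        if self.n_regions < 2:
            raise CohortConfigError("n_regions must be >= 2")
        if not (0 < self.base_density <= 1):
            raise CohortConfigError("base_density must be in (0, 1]")
        if not (0 < self.eglob_effect <= 1):
            raise CohortConfigError("eglob_effect must be in (0, 1]")
        if self.planted_delta < 0:
            raise CohortConfigError("planted_delta must be >= 0")
        if not (0 < self.fa_mean < 1):
            raise CohortConfigError("fa_mean must be in (0, 1)")
        if not (0 <= self.sex_ratio <= 1):
            raise CohortConfigError("sex_ratio must be in [0, 1]")


@dataclass(frozen=True)
class Cohort:
    """Matrices, phenotypes, and the planted ground truth of one simulation."""

    matrices: tuple[ConnectivityMatrix, ...]
    phenotypes: pd.DataFrame
    ground_truth: dict
    template: np.ndarray
    coords: np.ndarray

    @property
    def stack(self) -> np.ndarray:
        """Subject-major array of shape (n_subjects, N, N)."""
        return np.stack([m.weights for m in self.matrices])

    @property
    def groups(self) -> np.ndarray:
        return self.phenotypes["group"].to_numpy()

    @property
    def subject_ids(self) -> list[str]:
        return self.phenotypes["subject_id"].tolist()


def null_config(**overrides) -> CohortConfig:
    """A configuration with every planted effect switched off."""
    base = dict(eglob_effect=1.0, planted_delta=0.0)
    base.update(overrides)
    return CohortConfig(**base)


# ---------------------------------------------------------------------------
# template


def _make_template(
    cfg: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Geometric-modular template: weights, coordinates, module assignment."""
    n = cfg.n_regions
    coords = rng.random((n, 3))
    centroids = rng.random((min(cfg.n_modules, n), 3))
    d_cent = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    module = d_cent.argmin(axis=1)
    dist = squareform(pdist(coords))
    score = np.exp(-dist / cfg.distance_decay)
    same = module[:, None] == module[None, :]
    score = score * np.where(same, cfg.module_bonus, 1.0)
    iu, ju = np.triu_indices(n, k=1)
    s = score[iu, ju]
    p = np.clip(s * (cfg.base_density * s.size / s.sum()), 0.0, 1.0)
    edge = rng.random(s.size) < p
    A = np.zeros((n, n), dtype=bool)
    A[iu[edge], ju[edge]] = True
    A |= A.T
    # join stray components so path-based metrics are defined cohort-wide
    n_comp, labels = connected_components(A, directed=False)
    while n_comp > 1:
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                if labels[i] != labels[j]:
                    if best is None or dist[i, j] < dist[best]:
                        best = (i, j)
        A[best] = A[best[::-1]] = True
        n_comp, labels = connected_components(A, directed=False)
    w = np.clip(
        rng.normal(cfg.fa_mean, cfg.fa_sd, size=(n, n)), 1e-3, 1.0
    )
    w = np.triu(w, k=1)
    w = w + w.T
    W = np.where(A, w, 0.0)
    np.fill_diagonal(W, 0.0)
    return W, coords, module


def _default_planted(
    template: np.ndarray, n_planted: int, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    """A connected set of ``n_planted`` template edges grown breadth-first."""
    n = template.shape[0]
    degrees = np.count_nonzero(template, axis=1)
    start = int(rng.choice(np.flatnonzero(degrees >= 3)))
    edges: list[tuple[int, int]] = []
    visited = {start}
    frontier = [start]
    while frontier and len(edges) < n_planted:
        node = frontier.pop(0)
        for nbr in np.flatnonzero(template[node]):
            nbr = int(nbr)
            if nbr not in visited:
                visited.add(nbr)
                frontier.append(nbr)
                edges.append((min(node, nbr), max(node, nbr)))
                if len(edges) == n_planted:
                    break
    return tuple(edges)


# ---------------------------------------------------------------------------
# operations


def plant_subnetwork_effect(
    matrices: np.ndarray,
    group_labels: np.ndarray,
    edges: tuple[tuple[int, int], ...],
    delta: float,
    target_label: str = "MCI",
) -> np.ndarray:
    """Reduce the listed edge weights by ``delta`` in targeted subjects only.

    Weights are floored at 0 (with a logged warning if flooring occurred);
    symmetry is preserved; non-targeted subjects and unlisted edges are
    untouched.  Returns a new array.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    stack = np.array(matrices, dtype=float, copy=True)
    group_labels = np.asarray(group_labels)
    n = stack.shape[1]
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise PlantedEdgeError(f"invalid node pair ({i}, {j})")
    targeted = np.flatnonzero(group_labels == target_label)
    floored = False
    for s in targeted:
        for i, j in edges:
            v = stack[s, i, j] - delta
            if v < 0:
                v = 0.0
                floored = True
            stack[s, i, j] = stack[s, j, i] = v
    if floored:
        logger.warning("planted deficit floored some edge weights at 0")
    return stack


def generate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a full three-group cohort (deterministic given the seed)."""
    cfg = config
    rng_template = np.random.default_rng([cfg.seed, 0])
    template, coords, module = _make_template(cfg, rng_template)

    iu, ju = np.triu_indices(cfg.n_regions, k=1)
    template_edges = {
        (int(i), int(j)) for i, j in zip(iu, ju) if template[i, j] > 0
    }
    if cfg.planted_edges is not None:
        planted = tuple(
            (min(i, j), max(i, j)) for i, j in cfg.planted_edges
        )
        for e in planted:
            if e not in template_edges:
                raise PlantedEdgeError(f"planted edge {e} not in template")
    else:
        planted = _default_planted(
            template, cfg.n_planted, np.random.default_rng([cfg.seed, 1])
        )

    n_subj = 3 * cfg.n_per_group
    groups = np.repeat(GROUPS, cfg.n_per_group)
    step = np.repeat(np.arange(3), cfg.n_per_group)
    tw = template[iu, ju]
    nz = tw > 0
    stack = np.zeros((n_subj, cfg.n_regions, cfg.n_regions))
    for s in range(n_subj):
        rng_s = np.random.default_rng([cfg.seed, 100 + s])
        global_factor = float(np.exp(rng_s.normal(0.0, cfg.subject_sd)))
        edge_noise = np.exp(rng_s.normal(0.0, cfg.edge_noise_sd, size=nz.sum()))
        w = np.zeros_like(tw)
        w[nz] = np.minimum(
            tw[nz] * cfg.eglob_effect ** step[s] * global_factor * edge_noise,
            1.0,
        )
        W = np.zeros((cfg.n_regions, cfg.n_regions))
        W[iu, ju] = w
        W += W.T
        stack[s] = W

    if cfg.planted_delta > 0:
        stack = plant_subnetwork_effect(
            stack, groups, planted, cfg.planted_delta, target_label="MCI"
        )

    labels = default_labels(cfg.n_regions)
    matrices = tuple(ConnectivityMatrix(W, labels) for W in stack)

    # phenotypes
    rng_p = np.random.default_rng([cfg.seed, 2])
    age = rng_p.uniform(*cfg.age_range, size=n_subj).round(1)
    sex = np.where(rng_p.random(n_subj) < cfg.sex_ratio, "M", "F")
    education = np.clip(
        rng_p.normal(cfg.education_mean, cfg.education_sd, size=n_subj), 6, 20
    ).round(1)
    pheno = pd.DataFrame(
        {
            "subject_id": [f"sub-{s + 1:03d}" for s in range(n_subj)],
            "group": groups,
            "age": age,
            "sex": sex,
            "education": education,
        }
    )

    # cognition: affine in each subject's true (whole-matrix) global efficiency
    eglob = np.array([_eglob(W) for W in stack])
    sd = eglob.std()
    z = (eglob - eglob.mean()) / sd if sd > 0 else np.zeros(n_subj)
    rng_c = np.random.default_rng([cfg.seed, 3])
    norm = np.sqrt(cfg.cognition_slope**2 + cfg.cognition_noise_sd**2)
    for test, (base, scale, sign, floor) in _COGNITIVE_TESTS.items():
        eps = rng_c.normal(0.0, 1.0, size=n_subj)
        u = (cfg.cognition_slope * z + cfg.cognition_noise_sd * eps) / norm
        pheno[test] = np.maximum(base + sign * scale * u, floor).round(2)

    ground_truth = {
        "planted_edges": [list(e) for e in planted],
        "planted_delta": cfg.planted_delta,
        "eglob_effect": cfg.eglob_effect,
        "expected_ordering": list(GROUPS) if cfg.eglob_effect < 1 else None,
        "true_eglob": eglob.tolist(),
        "modules": module.tolist(),
    }
    return Cohort(
        matrices=matrices,
        phenotypes=pheno,
        ground_truth=ground_truth,
        template=template,
        coords=coords,
    )
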