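"""Network-based statistic: edge-wise tests, components, permutation null.

The NBS controls family-wise error over *connected components* of
suprathreshold edges rather than over individual edges:

1. an edge-wise statistic (one-way ANOVA F across groups, or a two-sample
   two-tailed t for a pairwise contrast) is computed at every tested edge;
2. edges with uncorrected ``p < primary_p`` are kept and partitioned into
   components (edges are connected when they share a node);
3. group labels are randomly permuted ``n_perm`` times and the *maximum*
   component size (in edges) under each permutation forms the empirical
   null;
4. a component of observed size M receives the corrected p-value
   ``(1 + #{permutation max >= M}) / (n_perm + 1)``.

The +1 smoothing guarantees valid p-values bounded below by
``1/(n_perm + 1)``; the strict "proportion of permutations with max size
larger than M" reading is available via ``strict_greater``.

Only edges present (nonzero) in at least half of the subjects are tested by
default; never-present edges would otherwise produce degenerate statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .matrix import ConnectivityMatrix

__all__ = [
    "NBSParams",
    "NBSComponent",
    "NBSResult",
    "edge_statistics",
    "suprathreshold_components",
    "nbs_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NBSParams:
    primary_p: float = 0.01
    n_perm: int = 5000
    alpha: float = 0.05
    min_presence: float = 0.5  # fraction of subjects in which an edge must be nonzero
    strict_greater: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.primary_p < 1):
            raise ValueError("primary_p must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class NBSComponent:
    edges: tuple[tuple[int, int], ...]
    nodes: tuple[int, ...]
    p_corrected: float

    @property
    def size(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class NBSResult:
    components: tuple[NBSComponent, ...]  # sorted largest first
    null_max_sizes: np.ndarray
    stat_matrix: np.ndarray
    p_matrix: np.ndarray
    mask: np.ndarray
    alpha: float
    labels: tuple[str, ...] = field(default=())

    @property
    def max_component_size(self) -> int:
        return self.components[0].size if self.components else 0

    @property
    def significant(self) -> tuple[NBSComponent, ...]:
        return tuple(c for c in self.components if c.p_corrected < self.alpha)


# ---------------------------------------------------------------------------
# helpers


def _coerce_stack(stack) -> np.ndarray:
    if isinstance(stack, np.ndarray):
        arr = stack
    else:
        arr = np.stack(
            [m.weights if isinstance(m, ConnectivityMatrix) else np.asarray(m) for m in stack]
        )
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError("stack must be (n_subjects, N, N)")
    return arr


def _edge_mask(arr: np.ndarray, min_presence: float) -> np.ndarray:
    """Boolean upper-triangle mask of edges present in enough subjects."""
    n = arr.shape[1]
    presence = (arr > 0).mean(axis=0)
    mask = presence >= min_presence
    mask &= np.triu(np.ones((n, n), dtype=bool), k=1)
    return mask


def _group_stats_vectorized(
    X: np.ndarray, labels: np.ndarray, groups: list
) -> np.ndarray:
    """One-way ANOVA F (>=3 groups) or two-sample t (2 groups) per column.

    Columns with zero pooled within-group variance yield NaN.
    """
    n = X.shape[0]
    k = len(groups)
    total = X.sum(axis=0)
    sumsq = (X**2).sum(axis=0)
    ss_between = np.zeros(X.shape[1])
    means = []
    sizes = []
    for g in groups:
        sel = labels == g
        ng = int(sel.sum())
        sg = X[sel].sum(axis=0)
        sizes.append(ng)
        means.append(sg / ng)
        ss_between += sg**2 / ng
    ss_within = np.maximum(sumsq - ss_between, 0.0)
    ss_between -= total**2 / n
    dfw = n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        if k == 2:
            sp2 = ss_within / dfw
            se = np.sqrt(sp2 * (1.0 / sizes[0] + 1.0 / sizes[1]))
            stat = (means[0] - means[1]) / se
        else:
            stat = (ss_between / (k - 1)) / (ss_within / dfw)
    stat[~np.isfinite(stat)] = np.nan
    return stat


def _stat_pvalues(stat: np.ndarray, n: int, k: int) -> np.ndarray:
    if k == 2:
        return 2 * stats.t.sf(np.abs(stat), df=n - k)
    return stats.f.sf(stat, k - 1, n - k)


def _critical_value(primary_p: float, n: int, k: int) -> float:
    if k == 2:
        return float(stats.t.isf(primary_p / 2, df=n - k))
    return float(stats.f.isf(primary_p, k - 1, n - k))


def _largest_component_size(iu: np.ndarray, ju: np.ndarray, n_nodes: int) -> int:
    """Max component size, in edges, of the graph on the given edge list."""
    if iu.size == 0:
        return 0
    adj = sparse.coo_matrix(
        (np.ones(iu.size), (iu, ju)), shape=(n_nodes, n_nodes)
    )
    _, comp = connected_components(adj, directed=False)
    edge_comp = comp[iu]  # both endpoints share a component
    return int(np.bincount(edge_comp).max())


def _subset_contrast(labels: np.ndarray, contrast) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    if contrast == "omnibus":
        groups = sorted(set(labels.tolist()))
        return np.ones(labels.size, dtype=bool), groups
    g1, g2 = contrast
    sel = (labels == g1) | (labels == g2)
    if not sel.any():
        raise ValueError(f"no subjects in contrast {contrast}")
    return sel, [g1, g2]


# ---------------------------------------------------------------------------
# operations


def edge_statistics(
    stack,
    labels,
    contrast="omnibus",
    min_presence: float = 0.5,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edge-wise group statistic and p-value matrices.

    ``contrast="omnibus"`` gives one-way ANOVA F across all groups; a pair
    of group labels gives the two-sample two-tailed pooled-variance t.
    Untested edges (outside the presence mask) are NaN in both outputs,
    which are symmetric N x N matrices.  The third return value is the
    upper-triangle boolean mask of tested edges.
    """
    arr = _coerce_stack(stack)
    labels = np.asarray(labels)
    if labels.size != arr.shape[0]:
        raise ValueError("one label per subject required")
    sel, groups = _subset_contrast(labels, contrast)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels[sel] == g).sum() < 2:
            raise ValueError(f"need >= 2 subjects in group {g!r}")
    arr = arr[sel]
    sub_labels = labels[sel]
    if mask is None:
        mask = _edge_mask(arr, min_presence)
    iu, ju = np.nonzero(mask)
    X = arr[:, iu, ju]
    stat = _group_stats_vectorized(X, sub_labels, groups)
    if np.isnan(stat).any():
        warnings.warn(
            "zero within-group variance at some edges; statistics set to NaN",
            stacklevel=2,
        )
    p = _stat_pvalues(stat, X.shape[0], len(groups))
    n = arr.shape[1]
    stat_m = np.full((n, n), np.nan)
    p_m = np.full((n, n), np.nan)
    stat_m[iu, ju] = stat_m[ju, iu] = stat
    p_m[iu, ju] = p_m[ju, iu] = p
    return stat_m, p_m, mask


def suprathreshold_components(
    p_matrix: np.ndarray,
    primary_p: float,
    mask: np.ndarray | None = None,
) -> list[list[tuple[int, int]]]:
    """Connected components of edges with ``p < primary_p`` (strict).

    Components are lists of ``(i, j)`` edges (i < j), ordered largest first;
    edges belong to one component when linked through shared nodes.
    """
    p_matrix = np.asarray(p_matrix, dtype=float)
    n = p_matrix.shape[0]
    tri = np.triu(np.ones((n, n), dtype=bool), k=1)
    if mask is not None:
        tri &= mask
    with np.errstate(invalid="ignore"):
        supra = tri & (p_matrix < primary_p)
    iu, ju = np.nonzero(supra)
    if iu.size == 0:
        return []
    adj = sparse.coo_matrix((np.ones(iu.size), (iu, ju)), shape=(n, n))
    _, comp = connected_components(adj, directed=False)
    comps: dict[int, list[tuple[int, int]]] = {}
    for i, j in zip(iu, ju):
        comps.setdefault(int(comp[i]), []).append((int(i), int(j)))
    return sorted(comps.values(), key=lambda c: (-len(c), c))


def nbs_test(
    stack,
    labels,
    params: NBSParams,
    contrast="omnibus",
) -> NBSResult:
    """Full NBS procedure with a permutation null of max component sizes.

    Permutations relabel all subjects entering the contrast (for pairwise
    contrasts, only the two groups involved are shuffled).  Deterministic
    given ``params.seed``.
    """
    if params.n_perm < 100:
        warnings.warn(
            f"n_perm={params.n_perm} gives coarse p-value resolution "
            f"(minimum {1 / (params.n_perm + 1):.3f})",
            stacklevel=2,
        )
    arr = _coerce_stack(stack)
    labels = np.asarray(labels)
    sel, groups = _subset_contrast(labels, contrast)
    sub = arr[sel]
    sub_labels = labels[sel]
    stat_m, p_m, mask = edge_statistics(
        sub, sub_labels, "omnibus" if contrast == "omnibus" else tuple(groups),
        min_presence=params.min_presence,
    )
    comps = suprathreshold_components(p_m, params.primary_p, mask)

    n_nodes = sub.shape[1]
    iu, ju = np.nonzero(mask)
    X = sub[:, iu, ju]
    k = len(groups)
    n = X.shape[0]
    crit = _critical_value(params.primary_p, n, k)
    rng = np.random.default_rng(params.seed)
    null_max = np.zeros(params.n_perm, dtype=int)
    for b in range(params.n_perm):
        perm_labels = sub_labels[rng.permutation(n)]
        stat = _group_stats_vectorized(X, perm_labels, groups)
        with np.errstate(invalid="ignore"):
            supra = (np.abs(stat) > crit) if k == 2 else (stat > crit)
        supra &= np.isfinite(stat)
        null_max[b] = _largest_component_size(iu[supra], ju[supra], n_nodes)

    out = []
    for edges in comps:
        m_size = len(edges)
        if params.strict_greater:
            p_corr = float((null_max > m_size).sum() / params.n_perm)
        else:
            p_corr = float((1 + (null_max >= m_size).sum()) / (params.n_perm + 1))
        nodes = tuple(sorted({v for e in edges for v in e}))
        out.append(
            NBSComponent(edges=tuple(edges), nodes=nodes, p_corrected=p_corr)
        )
    first = next(
        (m for m in (stack if not isinstance(stack, np.ndarray) else []) if isinstance(m, ConnectivityMatrix)),
        None,
    )
    return NBSResult(
        components=tuple(out),
        null_max_sizes=null_max,
        stat_matrix=stat_m,
        p_matrix=p_m,
        mask=mask,
        alpha=params.alpha,
        labels=first.labels if first is not None else (),
    )
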