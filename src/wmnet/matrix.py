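"""The central container: a symmetric FA-weighted connectivity matrix.

Edge weight ``w_ij`` is the mean fractional anisotropy (FA) along the fiber
bundles connecting regions ``i`` and ``j``; FA lives on ``[0, 1]``, so valid
edge weights do too.  A zero entry means "no edge".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConnectivityMatrix", "default_labels"]


def default_labels(n: int) -> tuple[str, ...]:
    """Region labels ``R001 ... RNNN`` used when no atlas naming is supplied."""
    return tuple(f"R{i + 1:03d}" for i in range(n))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric, non-negative N x N adjacency with region labels.

    Invariants enforced at construction: square shape, exact symmetry, zero
    diagonal, weights in ``[0, 1]``, one label per region.
    """

    weights: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"non-square matrix: shape {w.shape}")
        if np.isnan(w).any():
            raise ValueError("matrix contains NaN entries")
        if (w < 0).any():
            raise ValueError("matrix contains negative weights")
        if (w > 1).any():
            raise ValueError("matrix contains weights above 1 (FA scale)")
        if not np.array_equal(w, w.T):
            raise ValueError("matrix is not symmetric")
        if np.diagonal(w).any():
            raise ValueError("matrix has nonzero diagonal entries")
        object.__setattr__(self, "weights", w)
        labels = tuple(self.labels) if self.labels else default_labels(w.shape[0])
        if len(labels) != w.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {w.shape[0]} regions"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of undirected edges (nonzero upper-triangle entries)."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu, ju]))

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Undirected edges as ``(i, j, weight)`` with ``i < j``."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        w = self.weights[iu, ju]
        nz = w > 0
        return [
            (int(i), int(j), float(x))
            for i, j, x in zip(iu[nz], ju[nz], w[nz])
        ]

    def with_weights(self, weights: np.ndarray) -> "ConnectivityMatrix":
        """A copy carrying the same labels but new weights."""
        return ConnectivityMatrix(weights, self.labels)
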