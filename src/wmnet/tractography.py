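"""Deterministic streamline tracking (FACT) on toy voxel grids.

Fiber assignment by continuous tracking, in its simplest voxel-hop form:
from every voxel whose fractional anisotropy (FA) meets the seed threshold,
a streamline is launched in both directions along the local principal fiber
direction.  Propagation moves one voxel at a time to the nearest neighbor
along the (sign-aligned) local direction and terminates when

* the next voxel would lie outside the grid,
* the next voxel's FA falls below the threshold (that voxel is *not*
  entered),
* the turning angle between the directions of two adjacent voxels exceeds
  the angle limit (the turning voxel *is* kept, propagation stops there), or
* a safety cap on steps is reached.

Streamline endpoints are mapped to parcellation labels; two regions are
connected when at least ``min_fibers`` streamlines run between them, and the
edge weight is the mean FA pooled over every voxel of every connecting
streamline.  Collinear seeds produce duplicate trajectories which are
counted as distinct fibers, matching fiber-count (not unique-trajectory)
conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matrix import ConnectivityMatrix, default_labels

__all__ = [
    "OrientationField",
    "TrackingParams",
    "NetworkBuildParams",
    "Streamline",
    "StreamlineSet",
    "track_fact",
    "build_matrix",
    "save_field",
    "load_field",
    "save_streamlines",
    "load_streamlines",
]


@dataclass(frozen=True)
class OrientationField:
    """Per-voxel FA, principal direction, and parcel label on a 3-D grid.

    ``label`` 0 is background; 1..N_regions index parcels.  Directions must
    be unit-norm wherever FA is positive.
    """

    fa: np.ndarray  # (X, Y, Z)
    direction: np.ndarray  # (X, Y, Z, 3)
    label: np.ndarray  # (X, Y, Z) ints

    def __post_init__(self) -> None:
        fa = np.asarray(self.fa, dtype=float)
        di = np.asarray(self.direction, dtype=float)
        la = np.asarray(self.label, dtype=int)
        if fa.ndim != 3:
            raise ValueError("fa must be a 3-D array")
        if di.shape != fa.shape + (3,):
            raise ValueError("direction must have shape fa.shape + (3,)")
        if la.shape != fa.shape:
            raise ValueError("label must match the fa grid shape")
        if (fa < 0).any() or (fa > 1).any():
            raise ValueError("fa values must lie in [0, 1]")
        norms = np.linalg.norm(di, axis=-1)
        active = fa > 0
        if active.any() and not np.allclose(norms[active], 1.0, atol=1e-6):
            raise ValueError("directions must be unit-norm where fa > 0")
        object.__setattr__(self, "fa", fa)
        object.__setattr__(self, "direction", di)
        object.__setattr__(self, "label", la)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fa.shape


@dataclass(frozen=True)
class TrackingParams:
    fa_seed_min: float = 0.2
    angle_max_deg: float = 45.0
    step: float = 1.0
    max_steps: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.fa_seed_min < 1):
            raise ValueError("fa_seed_min must be in (0, 1)")
        if not (0 < self.angle_max_deg < 90):
            raise ValueError("angle_max_deg must be in (0, 90)")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass(frozen=True)
class NetworkBuildParams:
    """``min_fibers`` streamlines are required before an edge is accepted."""

    min_fibers: int = 3

    def __post_init__(self) -> None:
        if self.min_fibers < 1:
            raise ValueError("min_fibers must be >= 1")


@dataclass(frozen=True)
class Streamline:
    voxels: tuple[tuple[int, int, int], ...]
    fa: tuple[float, ...]
    endpoint_labels: tuple[int, int]

    def __len__(self) -> int:
        return len(self.voxels)


@dataclass(frozen=True)
class StreamlineSet:
    streamlines: tuple[Streamline, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.streamlines)


def _aligned_direction(
    field_dir: np.ndarray, voxel: tuple[int, int, int], heading: np.ndarray
) -> np.ndarray:
    """Local direction, sign-flipped to continue along the current heading.

    Principal eigenvectors are sign-ambiguous, so the tracker always picks
    the orientation that agrees with the direction of travel.
    """
    d = field_dir[voxel]
    if heading is not None and float(d @ heading) < 0:
        d = -d
    return d


def _half_track(
    f: OrientationField, seed: tuple[int, int, int], sign: float, p: TrackingParams
) -> list[tuple[int, int, int]]:
    """Voxels visited walking from the seed in one direction (seed excluded)."""
    cos_max = np.cos(np.deg2rad(p.angle_max_deg))
    shape = f.shape
    voxel = seed
    heading = sign * f.direction[seed]
    path: list[tuple[int, int, int]] = []
    for _ in range(p.max_steps):
        offset = [int(x) for x in np.rint(p.step * heading)]
        if not any(offset):
            break
        nxt = (voxel[0] + offset[0], voxel[1] + offset[1], voxel[2] + offset[2])
        if not all(0 <= c < s for c, s in zip(nxt, shape)):
            break
        if f.fa[nxt] < p.fa_seed_min:
            break
        path.append(nxt)
        nxt_dir = _aligned_direction(f.direction, nxt, heading)
        # turning-angle rule: stop at (but keep) the voxel where the fiber
        # direction bends by more than the limit
        if float(heading @ nxt_dir) < cos_max - 1e-12:
            break
        voxel = nxt
        heading = nxt_dir
    return path


def track_fact(f: OrientationField, params: TrackingParams) -> StreamlineSet:
    """Seed every voxel with FA >= threshold and track bidirectionally.

    The two half-tracks from a seed are concatenated into one streamline.
    Streamlines with fewer than 2 voxels (isolated seeds) are dropped.
    Output order follows C-order seed iteration, so tracking is fully
    deterministic.
    """
    seeds = np.argwhere(f.fa >= params.fa_seed_min)
    streamlines: list[Streamline] = []
    for seed in (tuple(int(c) for c in s) for s in seeds):
        backward = _half_track(f, seed, -1.0, params)
        forward = _half_track(f, seed, +1.0, params)
        voxels = list(reversed(backward)) + [seed] + forward
        if len(voxels) < 2:
            continue
        fa_along = tuple(float(f.fa[v]) for v in voxels)
        labels = (int(f.label[voxels[0]]), int(f.label[voxels[-1]]))
        streamlines.append(
            Streamline(voxels=tuple(voxels), fa=fa_along, endpoint_labels=labels)
        )
    return StreamlineSet(streamlines=tuple(streamlines))


def build_matrix(
    streams: StreamlineSet, params: NetworkBuildParams, n_regions: int
) -> ConnectivityMatrix:
    """Streamline counts and pooled mean FA -> FA-weighted adjacency.

    A streamline contributes to entry (i, j) when its endpoints lie in two
    distinct non-background regions.  Entries backed by fewer than
    ``min_fibers`` streamlines are zeroed; surviving entries carry the mean
    FA over all voxels of all connecting streamlines.
    """
    fa_sums = np.zeros((n_regions + 1, n_regions + 1))
    fa_counts = np.zeros((n_regions + 1, n_regions + 1), dtype=int)
    fibers = np.zeros((n_regions + 1, n_regions + 1), dtype=int)
    for sl in streams.streamlines:
        a, b = sl.endpoint_labels
        if not (0 <= a <= n_regions and 0 <= b <= n_regions):
            raise ValueError(f"endpoint label outside 0..{n_regions}: {(a, b)}")
        if a == 0 or b == 0 or a == b:
            continue
        i, j = min(a, b), max(a, b)
        fibers[i, j] += 1
        fa_sums[i, j] += sum(sl.fa)
        fa_counts[i, j] += len(sl.fa)
    W = np.zeros((n_regions, n_regions))
    for i, j in zip(*np.nonzero(fibers >= params.min_fibers)):
        w = fa_sums[i, j] / fa_counts[i, j]
        W[i - 1, j - 1] = W[j - 1, i - 1] = w
    return ConnectivityMatrix(W, default_labels(n_regions))


# ---------------------------------------------------------------------------
# plain-text serialization


def save_field(f: OrientationField, path: str | Path) -> None:
    """JSON with the grid shape and flattened fa / direction / label arrays."""
    payload = {
        "shape": list(f.shape),
        "fa": f.fa.ravel().tolist(),
        "direction": f.direction.ravel().tolist(),
        "label": f.label.ravel().tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_field(path: str | Path) -> OrientationField:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["shape"])
    return OrientationField(
        fa=np.array(payload["fa"]).reshape(shape),
        direction=np.array(payload["direction"]).reshape(shape + (3,)),
        label=np.array(payload["label"], dtype=int).reshape(shape),
    )


def save_streamlines(streams: StreamlineSet, path: str | Path) -> None:
    """JSON-lines: one streamline per line (voxels, fa, endpoint labels)."""
    with open(path, "w") as fh:
        for sl in streams.streamlines:
            fh.write(
                json.dumps(
                    {
                        "voxels": [list(v) for v in sl.voxels],
                        "fa": list(sl.fa),
                        "endpoint_labels": list(sl.endpoint_labels),
                    }
                )
                + "\n"
            )


def load_streamlines(path: str | Path) -> StreamlineSet:
    streamlines = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            streamlines.append(
                Streamline(
                    voxels=tuple(tuple(v) for v in d["voxels"]),
                    fa=tuple(d["fa"]),
                    endpoint_labels=tuple(d["endpoint_labels"]),
                )
            )
    return StreamlineSet(streamlines=tuple(streamlines))
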