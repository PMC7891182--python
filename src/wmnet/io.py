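"""File formats: TSV matrices, phenotype CSVs, cohort folders, BrainNet export.

Connectivity matrices travel as TSV with a shared header row/column of
region labels.  A full simulated cohort is laid out as::

    <dir>/matrices/<subject_id>.tsv
    <dir>/phenotypes.csv
    <dir>/ground_truth.json

BrainNet-viewer hand-off writes ``.node`` (x y z color size label per row)
and ``.edge`` (N x N whitespace-separated matrix) files for visualization in
external tools; nothing is rendered here.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .matrix import ConnectivityMatrix

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "save_cohort",
    "load_cohort_dir",
    "write_brainnet",
]

logger = logging.getLogger(__name__)

_SYMMETRY_ATOL = 1e-8


def write_matrix_tsv(m: ConnectivityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.weights, index=list(m.labels), columns=list(m.labels))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path: str | Path) -> ConnectivityMatrix:
    """Read and validate a labeled TSV matrix.

    Near-symmetric input (within 1e-8) is symmetrized by averaging with a
    logged warning; non-square bodies, NaN, or negative entries are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    w = df.to_numpy(dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"non-square matrix in {path}: shape {w.shape}")
    if np.isnan(w).any():
        raise ValueError(f"NaN entries in {path}")
    if (w < 0).any():
        raise ValueError(f"negative weights in {path}")
    if not np.array_equal(w, w.T):
        if not np.allclose(w, w.T, atol=_SYMMETRY_ATOL, rtol=0):
            raise ValueError(f"matrix in {path} is asymmetric beyond tolerance")
        logger.warning("symmetrized near-symmetric matrix from %s", path)
        w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, tuple(str(c) for c in df.columns))


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write matrices, phenotypes, and the ground-truth sidecar to a folder."""
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    for sid, m in zip(cohort.subject_ids, cohort.matrices):
        write_matrix_tsv(m, out / "matrices" / f"{sid}.tsv")
    cohort.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(cohort.ground_truth, indent=1, sort_keys=True)
    )
    np.savetxt(out / "node_coordinates.txt", cohort.coords, fmt="%.8f")
    return out


def load_cohort_dir(
    in_dir: str | Path,
) -> tuple[list[ConnectivityMatrix], pd.DataFrame]:
    """Load a cohort folder; matrices are aligned to the phenotype rows.

    Raises a named error listing offending subjects when matrix files and
    phenotype rows disagree.
    """
    in_dir = Path(in_dir)
    pheno = pd.read_csv(in_dir / "phenotypes.csv")
    mat_dir = in_dir / "matrices"
    available = {p.stem for p in mat_dir.glob("*.tsv")}
    wanted = set(pheno["subject_id"])
    missing = sorted(wanted - available)
    extra = sorted(available - wanted)
    if missing or extra:
        raise ValueError(
            f"subject mismatch between matrices and phenotypes: "
            f"missing matrices {missing}; unmatched files {extra}"
        )
    matrices = [
        read_matrix_tsv(mat_dir / f"{sid}.tsv") for sid in pheno["subject_id"]
    ]
    return matrices, pheno


def write_brainnet(
    node_path: str | Path,
    edge_path: str | Path,
    coords: np.ndarray,
    matrix: np.ndarray,
    color: np.ndarray | None = None,
    size: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> None:
    """BrainNet-viewer ``.node`` and ``.edge`` files for a network snapshot."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    color = np.ones(n) if color is None else np.asarray(color, dtype=float)
    size = np.ones(n) if size is None else np.asarray(size, dtype=float)
    labels = [f"R{i + 1:03d}" for i in range(n)] if labels is None else list(labels)
    with open(node_path, "w") as fh:
        for i in range(n):
            x, y, z = coords[i]
            fh.write(
                f"{x:.6f}\t{y:.6f}\t{z:.6f}\t{color[i]:.6f}\t{size[i]:.6f}\t{labels[i]}\n"
            )
    np.savetxt(edge_path, np.asarray(matrix, dtype=float), fmt="%.8f")
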