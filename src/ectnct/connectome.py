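"""Reading, validating, binarizing, and summarizing structural connectomes.

A structural connectome is an undirected, weighted graph over parcellated
brain regions: nodes are regions, edge weights are tractography-derived
quantities (number of streamlines, fractional anisotropy, mean diffusivity).
This module handles the plain-matrix on-disk representation (square TSV/CSV,
optionally with region labels) and the basic graph bookkeeping the analyses
need: binarization of streamline counts into an adjacency matrix and the
undirected edge count used as a nuisance covariate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "read_connectome",
    "write_connectome",
    "binarize",
    "edge_count",
]

#: Tolerance for symmetry checks on weighted matrices.
SYMMETRY_ATOL = 1e-9


@dataclass(frozen=True)
class Connectome:
    """A validated undirected connectivity matrix with node labels.

    Parameters
    ----------
    node_labels
        Region identifiers, in matrix row/column order. All downstream
        per-node vectors (controllability profiles) align to this order.
    weights
        N x N matrix of nonnegative reals; symmetric, zero diagonal.
    is_binary
        True when every entry is exactly 0 or 1.
    """

    node_labels: tuple[str, ...]
    weights: np.ndarray = field(repr=False)
    is_binary: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"non-square matrix with shape {w.shape}")
        if len(self.node_labels) != w.shape[0]:
            raise ValueError(
                f"{len(self.node_labels)} labels for {w.shape[0]} nodes"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite entries in connectivity matrix")
        if np.any(w < 0):
            raise ValueError("negative entries in connectivity matrix")
        if np.any(np.diag(w) != 0):
            raise ValueError("nonzero diagonal (self-connections not allowed)")
        if not np.allclose(w, w.T, rtol=0.0, atol=SYMMETRY_ATOL):
            raise ValueError(
                "asymmetric matrix (pass symmetrize=True to read_connectome "
                "to average with the transpose)"
            )
        binary = bool(np.all((w == 0) | (w == 1)))
        if self.is_binary and not binary:
            raise ValueError("is_binary set but entries outside {0, 1}")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_labels", tuple(str(x) for x in self.node_labels))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_matrix(
        cls, weights: np.ndarray, node_labels: list[str] | None = None
    ) -> "Connectome":
        """Build a Connectome from a raw matrix, defaulting labels to node_i."""
        weights = np.asarray(weights, dtype=float)
        if node_labels is None:
            node_labels = default_labels(weights.shape[0])
        binary = bool(np.all((weights == 0) | (weights == 1)))
        return cls(tuple(node_labels), weights, is_binary=binary)


def default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"node_{i}" for i in range(n))


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_connectome(
    path: str | Path,
    delimiter: str | None = None,
    symmetrize: bool = False,
) -> Connectome:
    """Read a square connectivity matrix from a delimited text file.

    The file may carry a header row and a leading label column; when both are
    present they must agree in order. Without labels, nodes are named
    ``node_0 .. node_{N-1}``.

    Parameters
    ----------
    path
        TSV/CSV file holding an N x N numeric matrix.
    delimiter
        Field separator; inferred from the suffix when omitted
        (.tsv/.txt -> tab, otherwise comma).
    symmetrize
        Average the matrix with its transpose before validation. Off by
        default: tractography outputs are often *near*-symmetric and silent
        symmetrization would hide genuine file corruption.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    first = pd.read_csv(path, sep=sep, header=None, nrows=1).iloc[0]
    # a label header has every non-corner cell non-numeric
    labels_row = [
        isinstance(v, str) and not _is_number(v) for v in first.tolist()[1:]
    ]
    has_header = len(labels_row) > 0 and all(labels_row)
    if has_header:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0)
        labels = [str(c) for c in df.columns]
    else:
        df = pd.read_csv(path, sep=sep, header=None)
        labels = None
    try:
        weights = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from None
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise ValueError(f"non-square matrix in {path}: shape {weights.shape}")
    if symmetrize:
        weights = 0.5 * (weights + weights.T)
    if labels is None:
        labels = list(default_labels(weights.shape[0]))
    return Connectome.from_matrix(weights, labels)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def write_connectome(
    c: Connectome, path: str | Path, delimiter: str | None = None
) -> Path:
    """Write a connectome as a labeled square matrix in the same dialect."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.DataFrame(c.weights, index=c.node_labels, columns=c.node_labels)
    # %.17g round-trips float64 exactly; binary matrices serialize as 0/1.
    fmt = "%g" if c.is_binary else "%.17g"
    df.to_csv(path, sep=sep, float_format=fmt)
    return path


def binarize(counts: Connectome, threshold: float = 0.0) -> Connectome:
    """Threshold a streamline-count matrix into a binary adjacency matrix.

    An edge is present where the count strictly exceeds ``threshold``; the
    default 0 keeps any nonzero streamline count as an edge.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    adj = (counts.weights > threshold).astype(float)
    return Connectome(counts.node_labels, adj, is_binary=True)


def edge_count(c: Connectome) -> int:
    """Number of undirected edges: strictly positive strict-upper-triangle entries."""
    iu = np.triu_indices(c.n_nodes, k=1)
    return int(np.count_nonzero(c.weights[iu] > 0))
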