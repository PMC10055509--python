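"""Structural connectome handling.

The spectral graph model operates on a fixed anatomical substrate: a matrix
``C`` of inter-regional connection weights (streamline counts or similar,
arbitrary units) and a matrix ``D`` of fiber distances in millimetres, both
over an ordered set of cortical regions (by default the 68 regions of the
Desikan–Killiany parcellation).  This module loads, validates, normalizes and
writes those matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_N_REGIONS = 68


class ConnectomeValidationError(ValueError):
    """Raised when a connectivity or distance matrix violates an invariant."""


@dataclass
class ConnectomeGraph:
    """Structural connectivity substrate of the network model.

    Parameters
    ----------
    C : ndarray, shape (N, N)
        Non-negative connection weights.  The diagonal is zeroed on
        construction: the network term models inter-regional coupling only.
    D : ndarray, shape (N, N)
        Symmetric inter-regional fiber distances in millimetres, zero
        diagonal.
    labels : list of str
        Ordered, unique region names.  Region order is significant and must
        be shared by every matrix and spectrum paired with this graph.
    """

    C: np.ndarray
    D: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        _check_square(self.C, "C")
        _check_square(self.D, "D")
        if self.C.shape != self.D.shape:
            raise ConnectomeValidationError(
                f"C is {self.C.shape} but D is {self.D.shape}; "
                "connectivity and distance matrices must match"
            )
        _check_nonnegative(self.C, "C")
        _check_nonnegative(self.D, "D")
        if not np.allclose(np.diag(self.D), 0.0):
            raise ConnectomeValidationError("D must have a zero diagonal")
        if not np.allclose(self.D, self.D.T):
            raise ConnectomeValidationError("D must be symmetric")
        if np.any(np.diag(self.C) != 0):
            logger.warning(
                "C has nonzero self-connections; zeroing the diagonal "
                "(the network term models inter-region coupling)"
            )
            self.C = self.C.copy()
            np.fill_diagonal(self.C, 0.0)
        if not self.labels:
            self.labels = [f"region_{i + 1:04d}" for i in range(self.N)]
        if len(self.labels) != self.N:
            raise ConnectomeValidationError(
                f"{len(self.labels)} labels for {self.N} regions"
            )
        if len(set(self.labels)) != self.N:
            raise ConnectomeValidationError("region labels must be unique")

    @property
    def N(self) -> int:
        return self.C.shape[0]

    def permuted(self, order: np.ndarray) -> "ConnectomeGraph":
        """Return a copy with regions reordered by index array ``order``."""
        order = np.asarray(order)
        return ConnectomeGraph(
            C=self.C[np.ix_(order, order)],
            D=self.D[np.ix_(order, order)],
            labels=[self.labels[i] for i in order],
        )


def _check_square(M: np.ndarray, name: str) -> None:
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ConnectomeValidationError(f"{name} must be square, got shape {M.shape}")


def _check_nonnegative(M: np.ndarray, name: str) -> None:
    if np.any(M < 0):
        i, j = np.argwhere(M < 0)[0]
        raise ConnectomeValidationError(
            f"{name} has a negative entry {M[i, j]!r} at row {i}, column {j}"
        )


def _load_matrix(path: str | Path) -> np.ndarray:
    """Load a dense numeric matrix from delimited text (CSV or whitespace)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        return np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ConnectomeValidationError(f"could not parse {path}: {exc}") from exc


def load_connectome(
    conn_path: str | Path,
    dist_path: str | Path,
    labels_path: str | Path | None = None,
) -> ConnectomeGraph:
    """Load connectivity and distance matrices from delimited text files.

    Labels are read one-per-line from ``labels_path`` when given, otherwise
    generated as ``region_0001`` ... in file row order.
    """
    C = _load_matrix(conn_path)
    D = _load_matrix(dist_path)
    if C.shape != D.shape:
        raise ConnectomeValidationError(
            f"{conn_path} is {C.shape} but {dist_path} is {D.shape}"
        )
    labels: list[str] = []
    if labels_path is not None:
        labels = [
            line.strip()
            for line in Path(labels_path).read_text().splitlines()
            if line.strip()
        ]
    try:
        return ConnectomeGraph(C=C, D=D, labels=labels)
    except ConnectomeValidationError as exc:
        raise ConnectomeValidationError(
            f"validation failed for {conn_path} / {dist_path}: {exc}"
        ) from exc


def save_connectome(graph: ConnectomeGraph, conn_path: str | Path,
                    dist_path: str | Path,
                    labels_path: str | Path | None = None) -> None:
    """Write the graph back to delimited text at fixed (%.12g) precision."""
    np.savetxt(conn_path, graph.C, fmt="%.12g", delimiter=",")
    np.savetxt(dist_path, graph.D, fmt="%.12g", delimiter=",")
    if labels_path is not None:
        Path(labels_path).write_text("\n".join(graph.labels) + "\n")


def degree_normalize(C: np.ndarray) -> np.ndarray:
    """Row-degree normalization: each row is divided by its sum.

    Rows with zero sum (isolated regions) are left as zero rather than
    raising, so sparse synthetic graphs remain usable.
    """
    C = np.asarray(C, dtype=float)
    _check_square(C, "C")
    _check_nonnegative(C, "C")
    rowsum = C.sum(axis=1, keepdims=True)
    out = np.divide(C, rowsum, out=np.zeros_like(C), where=rowsum > 0)
    return out


def smoothing_operator(C_norm: np.ndarray, w: float) -> np.ndarray:
    """Row-normalized (C_norm + w·I), the network smoother of the spatial
    correlation objective.

    With a row-normalized ``C_norm`` every row sums to 1 + w before
    renormalization, so diagonal entries become w/(1+w) and off-diagonal
    entries are scaled by 1/(1+w).  With ``C_norm = 0`` the result is the
    identity and the smoothed correlation reduces to plain Pearson r.
    """
    if w <= 0:
        raise ValueError(f"smoothing weight must be positive, got {w}")
    C_norm = np.asarray(C_norm, dtype=float)
    M = C_norm + w * np.eye(C_norm.shape[0])
    return degree_normalize(M)
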