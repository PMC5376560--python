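"""Weighted functional-connectivity network construction.

Edges are Pearson correlations between regional mean time series, mapped
through Fisher's r-to-z transform and taken in absolute value, so the edge
weight ``|atanh(r)|`` is a nonnegative strength that treats correlated and
anticorrelated node pairs alike.  Degree centrality (DC) of a node is the sum
of its incident edge weights; high-DC nodes are the network's hubs.

The default parcellation is 12 bilateral regions implicated in motor control
and mastication (24 nodes, 276 unique edges): primary/secondary motor and
somatosensory cortices, superior parietal lobe, anterior insula, dorsal
anterior cingulate, caudate, thalamus, and three cerebellar subdivisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .preprocess import ROITimeSeries

__all__ = [
    "ROI_ORDER",
    "default_node_labels",
    "ConnectivityMatrix",
    "DegreeCentralityVector",
    "Edge",
    "fisher_z_weight",
    "compute_connectivity",
    "degree_centrality",
    "flatten_edges",
]

#: canonical ROI order (each expanded left-before-right)
ROI_ORDER = (
    "M1", "PMC", "S1", "S2", "SPL", "aINS",
    "dACC", "CaN", "THA", "CAnt", "CPost67", "CPost8",
)

CLIP_LIMIT = 1.0 - 1e-7


def default_node_labels() -> tuple[str, ...]:
    """The 24 node labels in canonical order, e.g. ``M1_L, M1_R, PMC_L, ...``"""
    return tuple(f"{roi}_{side}" for roi in ROI_ORDER for side in ("L", "R"))


def fisher_z_weight(r, clip: bool = False):
    """Edge weight ``|atanh(r)|`` for a correlation coefficient.

    Parameters
    ----------
    r
        Scalar or array of correlations, each with ``|r| < 1``.
    clip
        If true, correlations at or beyond +/-1 are clipped to
        ``+/-(1 - 1e-7)`` instead of raising.
    """
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -CLIP_LIMIT, CLIP_LIMIT)
    elif np.any(np.abs(r) >= 1.0):
        bad = float(np.asarray(r).flat[int(np.argmax(np.abs(r) >= 1.0))])
        raise ValueError(
            f"|r| >= 1 gives an infinite Fisher z weight (got r={bad}); "
            "enable clip=True to truncate at 1 - 1e-7"
        )
    out = np.abs(np.arctanh(r))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric node x node correlations and their |Fisher z| edge weights.

    The diagonal is defined as 0 in both matrices and excluded from every
    edge enumeration (no self-loops), so an n-node network has
    ``n (n - 1) / 2`` unique edges -- 276 for the default 24 nodes.
    """

    r: np.ndarray
    weight: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        w = np.asarray(self.weight, dtype=float)
        n = r.shape[0]
        if r.shape != (n, n) or w.shape != (n, n):
            raise ValueError("r and weight must be square matrices of equal shape")
        if len(self.node_labels) != n:
            raise ValueError(f"{len(self.node_labels)} labels for {n} nodes")
        if len(set(self.node_labels)) != n:
            raise ValueError("node labels must be distinct")
        if not (np.allclose(r, r.T) and np.allclose(w, w.T)):
            raise ValueError("connectivity matrices must be symmetric")
        if np.any(np.abs(r) > 1.0) or np.any(w < 0):
            raise ValueError("r must lie in [-1, 1] and weights must be nonnegative")
        if np.any(np.diag(r) != 0) or np.any(np.diag(w) != 0):
            raise ValueError("diagonals must be stored as 0 (no self-loops)")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(w[off], np.abs(np.arctanh(r[off]))):
            raise ValueError("weight must equal |atanh(r)| off-diagonal")
        r = r.copy(); r.setflags(write=False)
        w = w.copy(); w.setflags(write=False)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "weight", w)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))

    @classmethod
    def from_r(cls, r: np.ndarray, node_labels) -> "ConnectivityMatrix":
        """Build from a correlation matrix, deriving weights and zeroed diagonal."""
        r = np.asarray(r, dtype=float).copy()
        np.fill_diagonal(r, 0.0)
        w = np.abs(np.arctanh(r))
        np.fill_diagonal(w, 0.0)
        return cls(r=r, weight=w, node_labels=tuple(node_labels))

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2


@dataclass(frozen=True)
class DegreeCentralityVector:
    """Per-node sum of incident edge weights."""

    dc: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        dc = np.asarray(self.dc, dtype=float)
        if dc.ndim != 1 or len(self.node_labels) != dc.size:
            raise ValueError("dc must be 1-D with one entry per label")
        if np.any(dc < 0):
            raise ValueError("degree centrality must be nonnegative")
        dc = dc.copy(); dc.setflags(write=False)
        object.__setattr__(self, "dc", dc)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))


class Edge(NamedTuple):
    node_i: str
    node_j: str
    r: float
    weight: float


def compute_connectivity(series: ROITimeSeries, clip: bool = False) -> ConnectivityMatrix:
    """Pearson correlation between every node pair, Fisher-z weighted.

    Raises if any node signal has zero variance, or if a perfect correlation
    appears between distinct nodes (unless ``clip`` truncates it).
    """
    if series.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlations")
    spread = np.ptp(series.data, axis=0)
    if np.any(spread == 0):
        bad = series.node_labels[int(np.argmax(spread == 0))]
        raise ValueError(f"node {bad!r} has zero variance; correlation undefined")
    r = np.corrcoef(series.data, rowvar=False)
    r = np.clip(r, -1.0, 1.0)  # guard fp overshoot only
    np.fill_diagonal(r, 0.0)
    if clip:
        r = np.clip(r, -CLIP_LIMIT, CLIP_LIMIT)
    elif np.any(np.abs(r) >= 1.0):
        i, j = np.unravel_index(int(np.argmax(np.abs(r) >= 1.0)), r.shape)
        raise ValueError(
            f"perfect correlation between {series.node_labels[i]!r} and "
            f"{series.node_labels[j]!r}; enable clip=True to truncate"
        )
    return ConnectivityMatrix.from_r(r, series.node_labels)


def degree_centrality(cm: ConnectivityMatrix) -> DegreeCentralityVector:
    """DC_k = sum of node k's incident edge weights (diagonal excluded)."""
    return DegreeCentralityVector(dc=cm.weight.sum(axis=1), node_labels=cm.node_labels)


def flatten_edges(cm: ConnectivityMatrix) -> list[Edge]:
    """Deterministic upper-triangle edge list, i < j in node order."""
    out = []
    n = cm.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            out.append(
                Edge(
                    node_i=cm.node_labels[i],
                    node_j=cm.node_labels[j],
                    r=float(cm.r[i, j]),
                    weight=float(cm.weight[i, j]),
                )
            )
    return out
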