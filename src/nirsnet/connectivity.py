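"""Weighted Pearson correlation networks and sparsity-controlled binarization.

Each fNIRS channel is a node; the edge weight between channels i and j is
the Pearson correlation r_ij of their time series.  The weighted matrix is
binarized by a threshold T on |r_ij| (an edge exists iff |r_ij| >= T).  T is
usually not set directly: instead a *sparsity* S — the fraction of realised
edges over the M = C(C-1)/2 possible ones — is requested, and T is the k-th
largest |r| with k = round(S*M).  At S = 0.5 (M even) this makes T the upper
median of the correlation magnitudes.

Ties at T are all kept (deterministic, order-independent), so the achieved
sparsity can exceed the requested one by at most the tie-group size / M.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .dataio import Recording

__all__ = [
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "correlation_matrix",
    "sparsity_to_threshold",
    "binarize",
    "threshold_sweep",
    "default_sparsity_grid",
]


def default_sparsity_grid() -> np.ndarray:
    """Sparsity levels 0.01, 0.02, ..., 0.50 (50 levels)."""
    return np.round(np.arange(1, 51) * 0.01, 2)


@dataclass
class CorrelationMatrix:
    """Symmetric C x C Pearson matrix with unit diagonal."""

    values: np.ndarray
    channel_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(v).max() > 1 + 1e-12:
            raise ValueError("correlation values must lie in [-1, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("correlation diagonal must be exactly 1")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_possible_edges(self) -> int:
        c = self.n_channels
        return c * (c - 1) // 2

    def upper_triangle_abs(self) -> np.ndarray:
        iu = np.triu_indices(self.n_channels, k=1)
        return np.abs(self.values[iu])


@dataclass
class AdjacencyMatrix:
    """Binary undirected network at one threshold.

    ``sparsity`` is the *achieved* edge density edge_count / M, which can
    exceed the requested level when |r| values tie at the threshold.
    """

    edges: np.ndarray
    threshold: float
    channel_labels: list[str] = field(default_factory=list)
    requested_sparsity: float | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.edges)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("adjacency matrix must be square")
        e = (e != 0).astype(np.uint8)
        if not np.array_equal(e, e.T):
            raise ValueError("adjacency matrix must be symmetric")
        np.fill_diagonal(e, 0)
        self.edges = e
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1:02d}" for i in range(e.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.edges.shape[0]

    @property
    def n_possible_edges(self) -> int:
        c = self.n_nodes
        return c * (c - 1) // 2

    @property
    def edge_count(self) -> int:
        return int(self.edges.sum()) // 2

    @property
    def sparsity(self) -> float:
        return self.edge_count / self.n_possible_edges


def correlation_matrix(rec: Recording) -> CorrelationMatrix:
    """Pearson correlation between every unordered pair of channels.

    r_ij = cov(X_i, X_j) / (sigma_i * sigma_j); the diagonal is set to
    exactly 1.  Channels with zero variance have undefined correlation and
    raise an error naming the channel.
    """
    if rec.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    stds = rec.data.std(axis=1)
    dead = np.flatnonzero(stds == 0)
    if dead.size:
        names = [rec.channel_labels[i] for i in dead]
        raise ValueError(
            f"zero-variance channel(s) {names}: Pearson correlation undefined"
        )
    r = np.corrcoef(rec.data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, list(rec.channel_labels))


def sparsity_to_threshold(
    corr: CorrelationMatrix,
    sparsity: float,
    *,
    rounding: Literal["round", "floor"] = "round",
) -> float:
    """Threshold T realising a requested edge density.

    T is the k-th largest |r_ij| over the M unordered pairs, with
    k = round(S*M) (configurable to floor); k is clamped to at least 1 so a
    positive requested sparsity always yields a well-defined threshold.
    """
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    tri = np.sort(corr.upper_triangle_abs())[::-1]
    m = tri.size
    if rounding == "round":
        k = int(np.floor(sparsity * m + 0.5))
    elif rounding == "floor":
        k = int(np.floor(sparsity * m))
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    k = min(max(k, 1), m)
    return float(tri[k - 1])


def binarize(
    corr: CorrelationMatrix,
    threshold: float,
    *,
    requested_sparsity: float | None = None,
) -> AdjacencyMatrix:
    """Edge rule: e_ij = 1 iff |r_ij| >= T and i != j."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    edges = (np.abs(corr.values) >= threshold).astype(np.uint8)
    np.fill_diagonal(edges, 0)
    return AdjacencyMatrix(
        edges=edges,
        threshold=float(threshold),
        channel_labels=list(corr.channel_labels),
        requested_sparsity=requested_sparsity,
    )


def threshold_sweep(
    corr: CorrelationMatrix,
    grid: Sequence[float] | None = None,
    *,
    mode: Literal["sparsity", "raw"] = "sparsity",
    rounding: Literal["round", "floor"] = "round",
) -> list[AdjacencyMatrix]:
    """One binary network per grid level.

    In ``sparsity`` mode (default) each grid value is an edge-density level
    converted to a threshold via :func:`sparsity_to_threshold`; in ``raw``
    mode the grid values are applied directly as |r| cuts.  The default grid
    is 0.01..0.50 in steps of 0.01 (50 networks), whose edge sets are nested
    as the level grows (up to tie groups).
    """
    levels = default_sparsity_grid() if grid is None else np.asarray(grid, dtype=float)
    if levels.size == 0:
        raise ValueError("empty threshold grid")
    nets = []
    for s in levels:
        if mode == "sparsity":
            t = sparsity_to_threshold(corr, float(s), rounding=rounding)
            nets.append(binarize(corr, t, requested_sparsity=float(s)))
        elif mode == "raw":
            nets.append(binarize(corr, float(s)))
        else:
            raise ValueError(f"unknown threshold mode {mode!r}")
    return nets
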