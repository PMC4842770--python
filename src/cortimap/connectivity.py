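"""Threshold correlation matrices into displayable networks.

A loaded n x n correlation measure (e.g. a band-wise phase-locking-value
matrix) becomes an edge set by keeping pairs whose value is *strictly*
above a threshold tau.  Tau is chosen either manually or automatically at
a target sparsity (fraction of the n(n-1)/2 possible pairs kept).  Node
importance is summarized by strength, the sum of incident edge weights,
which drives the "replot nodes" highlighting of network hubs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ShapeError
from .surface_mapping import DEFAULT_CMAP, value_colors

log = logging.getLogger(__name__)

DEFAULT_SPARSITY = 0.1


def _offdiag_upper(c: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = c.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju, c[iu, ju]


def _as_matrix(c) -> np.ndarray:
    m = c.values if hasattr(c, "values") else np.asarray(c, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ShapeError(f"correlation matrix must be square, got {m.shape}")
    return 0.5 * (m + m.T)


@dataclass(frozen=True)
class EdgeSet:
    """Edges surviving a threshold: (i, j, weight) with i < j, no
    self-edges, no duplicates; ``mode`` is 'binary' or 'weighted'."""

    i: np.ndarray
    j: np.ndarray
    weights: np.ndarray
    threshold: float
    mode: str = "weighted"

    def __len__(self) -> int:
        return len(self.weights)

    def as_list(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(w))
                for a, b, w in zip(self.i, self.j, self.weights)]


def auto_threshold(c, sparsity: float = DEFAULT_SPARSITY) -> float:
    """Threshold keeping the top ``ceil(sparsity * P)`` of the P = n(n-1)/2
    off-diagonal pairs.

    Returns the k-th largest upper-triangle value nudged down by one ulp so
    a strict ``> tau`` comparison keeps exactly those k pairs.  When values
    tie at the cut, every tied pair survives (logged).
    """
    m = _as_matrix(c)
    n = m.shape[0]
    if n < 2:
        raise DomainError(f"need at least 2 channels, got {n}")
    if not 0 < sparsity <= 1:
        raise DomainError(f"sparsity must be in (0, 1], got {sparsity}")
    _, _, vals = _offdiag_upper(m)
    p = len(vals)
    k = math.ceil(sparsity * p)
    kth = np.sort(vals)[::-1][k - 1]
    tau = float(np.nextafter(kth, -np.inf))
    kept = int((vals > tau).sum())
    if kept != k:
        log.info("auto_threshold: ties at the cut keep %d edges "
                 "(target %d)", kept, k)
    return tau


def threshold_edges(c, tau: float, mode: str = "weighted",
                    use_abs: bool = False) -> EdgeSet:
    """Edges with correlation strictly greater than ``tau``.

    ``use_abs`` compares |C| instead of signed values (correlation
    matrices may be signed; synchronization measures are nonnegative).
    A tau at or above the off-diagonal maximum hides every connection.
    """
    if mode not in ("binary", "weighted"):
        raise DomainError(f"mode must be 'binary' or 'weighted', got {mode!r}")
    m = _as_matrix(c)
    iu, ju, vals = _offdiag_upper(m)
    cmp = np.abs(vals) if use_abs else vals
    keep = cmp > tau
    return EdgeSet(i=iu[keep], j=ju[keep], weights=vals[keep],
                   threshold=float(tau), mode=mode)


def node_strength(edge_set: EdgeSet, n: int) -> np.ndarray:
    """Summed connection strength of each node (binary mode counts
    degree); isolated nodes score 0."""
    if len(edge_set) and max(edge_set.i.max(), edge_set.j.max()) >= n:
        raise IndexError(f"edge endpoint out of range for n={n}")
    w = (np.ones_like(edge_set.weights) if edge_set.mode == "binary"
         else edge_set.weights)
    s = np.zeros(n)
    np.add.at(s, edge_set.i, w)
    np.add.at(s, edge_set.j, w)
    return s


def edge_styles(edge_set: EdgeSet, color_mode: str = "scaled",
                scale_mode: str = "auto", lo: float | None = None,
                hi: float | None = None,
                single_color=(0.2, 0.2, 0.8),
                cmap: str = DEFAULT_CMAP) -> tuple[np.ndarray,
                                                   tuple[float, float]]:
    """Stick colors for the surviving edges.

    ``single`` paints every stick one color (binary networks); ``scaled``
    maps weights through a colormap over (lo, hi) — automatically the
    (min, max) of the surviving weights, or a manual pair that clamps
    weights outside it to the end colors.  Returns (k, 3) RGB and the
    range used.
    """
    k = len(edge_set)
    if color_mode == "single":
        return np.tile(np.asarray(single_color, float), (k, 1)), (0.0, 1.0)
    if color_mode != "scaled":
        raise DomainError(f"color_mode must be 'single' or 'scaled', "
                          f"got {color_mode!r}")
    if scale_mode == "manual":
        if lo is None or hi is None or lo >= hi:
            raise DomainError(f"manual scale requires lo < hi, "
                              f"got ({lo}, {hi})")
        vrange = (float(lo), float(hi))
    elif scale_mode == "auto":
        if k == 0:
            vrange = (0.0, 1.0)
        else:
            wmin, wmax = float(edge_set.weights.min()), \
                float(edge_set.weights.max())
            vrange = (wmin, wmax if wmax > wmin else wmin + 1e-9)
    else:
        raise DomainError(f"scale_mode must be 'auto' or 'manual', "
                          f"got {scale_mode!r}")
    return value_colors(edge_set.weights, vrange, cmap), vrange
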