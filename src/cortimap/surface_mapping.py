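"""Interpolate per-electrode functional parameters onto the brain surface.

Two interpolants are provided, mirroring the two map styles of interactive
function-mapping viewers:

* **Gaussian** — every vertex takes the kernel-weighted mean of all
  electrode values, ``w_i = exp(-d_i^2 / (2 sigma^2))`` with Euclidean
  distance ``d_i`` to contact *i*.  The "Gauss extend" parameter is sigma
  in millimetres.  All vertices are covered and the field is a convex
  combination of the electrode values.
* **Linear** — hat weights ``w_i = max(0, 1 - d_i / R)``; vertices farther
  than ``R`` from every contact are marked uncovered and excluded from
  display-range computation.

Color ranges can be chosen automatically (data min/max) or manually, with
out-of-range values clamped by the downstream color mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import Normalize
from scipy.spatial.distance import cdist

from .errors import DomainError, ShapeError, ValidationError
from .mesh_model import TriMesh
from .registration import ElectrodeSet

DEFAULT_SIGMA_MM = 10.0
DEFAULT_LINEAR_RADIUS_MM = 15.0
DEFAULT_CMAP = "coolwarm"  # blue -> red diverging


@dataclass(frozen=True)
class ScalarField:
    """Per-vertex mapped values with a coverage mask and display range."""

    values: np.ndarray   # (V,) parameter units
    covered: np.ndarray  # (V,) bool
    range: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.range
        if lo > hi:
            raise DomainError(f"display range lo > hi: ({lo}, {hi})")
        if not np.all(np.isfinite(self.values[self.covered])):
            raise ValidationError("covered vertices must have finite values")


def _check_inputs(eset: ElectrodeSet, row_values) -> np.ndarray:
    if len(eset) == 0:
        raise ValidationError("cannot map with an empty montage")
    x = np.asarray(row_values, dtype=np.float64).ravel()
    if len(x) != len(eset):
        raise ShapeError(f"{len(x)} values for {len(eset)} electrodes")
    return x


def gaussian_map(mesh: TriMesh, eset: ElectrodeSet, row_values,
                 extend_sigma_mm: float = DEFAULT_SIGMA_MM) -> ScalarField:
    """Gaussian-kernel interpolation of electrode values onto vertices.

    Weights are normalized per vertex, so the field is a convex
    combination of the inputs; as sigma -> 0 it tends to the
    nearest-electrode (Voronoi) assignment and as sigma -> inf to the
    global mean.  Numerically stable for tiny sigma (weights are shifted
    by the nearest-contact distance before exponentiation).
    """
    x = _check_inputs(eset, row_values)
    if extend_sigma_mm <= 0:
        raise DomainError(f"sigma must be > 0, got {extend_sigma_mm}")
    d2 = cdist(mesh.vertices, eset.positions) ** 2
    # shift by the per-vertex minimum so at least one weight is exp(0)=1
    d2s = d2 - d2.min(axis=1, keepdims=True)
    w = np.exp(-d2s / (2.0 * extend_sigma_mm ** 2))
    vals = (w @ x) / w.sum(axis=1)
    covered = np.ones(mesh.n_vertices, dtype=bool)
    return ScalarField(values=vals, covered=covered,
                       range=scale_range(x, "auto"))


def linear_map(mesh: TriMesh, eset: ElectrodeSet, row_values,
               radius_mm: float = DEFAULT_LINEAR_RADIUS_MM) -> ScalarField:
    """Linear (hat-kernel) interpolation with support radius ``radius_mm``.

    Vertices outside every contact's support are uncovered; their value is
    NaN and they are ignored by range computation and rendering.
    """
    x = _check_inputs(eset, row_values)
    if radius_mm <= 0:
        raise DomainError(f"radius must be > 0, got {radius_mm}")
    d = cdist(mesh.vertices, eset.positions)
    w = np.maximum(0.0, 1.0 - d / radius_mm)
    wsum = w.sum(axis=1)
    covered = wsum > 0
    vals = np.full(mesh.n_vertices, np.nan)
    vals[covered] = (w[covered] @ x) / wsum[covered]
    return ScalarField(values=vals, covered=covered,
                       range=scale_range(x, "auto"))


def scale_range(values, mode: str = "auto", manual_lo: float | None = None,
                manual_hi: float | None = None) -> tuple[float, float]:
    """Display range for a row of electrode values.

    ``auto`` takes (min, max) of the plotted row, widening a degenerate
    all-equal range by 1e-9; ``manual`` takes the given pair (lo < hi)
    and downstream color mapping clamps values outside it.
    """
    if mode == "manual":
        if manual_lo is None or manual_hi is None or manual_lo >= manual_hi:
            raise DomainError(f"manual range requires lo < hi, "
                              f"got ({manual_lo}, {manual_hi})")
        return float(manual_lo), float(manual_hi)
    if mode != "auto":
        raise DomainError(f"mode must be 'auto' or 'manual', got {mode!r}")
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise DomainError("cannot auto-scale an empty/all-NaN value set")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        lo, hi = lo - 1e-9, hi + 1e-9
    return lo, hi


def value_colors(values, vrange: tuple[float, float],
                 cmap: str = DEFAULT_CMAP) -> np.ndarray:
    """Map values through a named colormap over ``vrange`` (clamped);
    returns (k, 3) RGB in [0, 1].  NaN maps to mid-gray."""
    lo, hi = vrange
    norm = Normalize(vmin=lo, vmax=hi, clip=True)
    cm = colormaps[cmap]
    x = np.asarray(values, dtype=np.float64)
    rgba = cm(norm(np.where(np.isfinite(x), x, (lo + hi) / 2.0)))
    rgb = rgba[..., :3]
    rgb[~np.isfinite(x)] = 0.5
    return rgb


def replot_nodes(eset: ElectrodeSet, node_values,
                 vrange: tuple[float, float] | None = None,
                 cmap: str = DEFAULT_CMAP) -> ElectrodeSet:
    """Recolor the electrode balls by per-node values (e.g. summed
    connection strength) to highlight important locations.  Positions are
    untouched."""
    x = np.asarray(node_values, dtype=np.float64).ravel()
    if len(x) != len(eset):
        raise ShapeError(f"{len(x)} node values for {len(eset)} electrodes")
    if vrange is None:
        vrange = scale_range(x, "auto")
    rgb = value_colors(x, vrange, cmap)
    elecs = tuple(_dc_replace(e, color=tuple(rgb[i]))
                  for i, e in enumerate(eset.electrodes))
    return _dc_replace(eset, electrodes=elecs)
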