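"""Electrode registration on the brain surface.

Contacts are placed the way a user would in an interactive viewer: a 2D
viewport pixel is turned into a 3D ray through the camera ("ray casting")
and the nearest intersection of that ray with the brain surface becomes
the electrode position.  The module also provides the list-editing
operations (append / insert-after / remove) and sub-millimetre tuning of
registered coordinates.  Tuned contacts may leave the surface on purpose:
implantation can deform the brain, so corrections must not be re-projected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .camera import Camera
from .errors import CameraError, DomainError, ValidationError
from .mesh_model import TriMesh

DEFAULT_COLOR = (1.0, 0.0, 0.0)  # red
DEFAULT_RADIUS_MM = 2.0


@dataclass(frozen=True)
class Electrode:
    """A single contact: 1-based ordinal, label, position (mm), ball style."""

    index: int
    label: str
    position: np.ndarray
    color: tuple[float, float, float] = DEFAULT_COLOR
    radius: float = DEFAULT_RADIUS_MM

    def __post_init__(self):
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=np.float64))
        if self.radius <= 0:
            raise ValidationError(f"electrode radius must be > 0, "
                                  f"got {self.radius}")
        if not np.all(np.isfinite(self.position)):
            raise ValidationError("electrode position must be finite")


@dataclass(frozen=True)
class ElectrodeSet:
    """Ordered montage of contacts; indices are contiguous 1..k."""

    electrodes: tuple[Electrode, ...] = ()
    coordinate_space: str = "native"

    def __post_init__(self):
        object.__setattr__(self, "electrodes", tuple(self.electrodes))
        got = [e.index for e in self.electrodes]
        if got != list(range(1, len(got) + 1)):
            raise ValidationError(
                f"electrode indices must be contiguous 1..k, got {got}")

    def __len__(self) -> int:
        return len(self.electrodes)

    def __iter__(self):
        return iter(self.electrodes)

    def __getitem__(self, index: int) -> Electrode:
        """Look up a contact by its 1-based index."""
        if not 1 <= index <= len(self):
            raise IndexError(f"no electrode with index {index}")
        return self.electrodes[index - 1]

    @property
    def positions(self) -> np.ndarray:
        """(k, 3) array of contact positions."""
        if not self.electrodes:
            return np.zeros((0, 3))
        return np.array([e.position for e in self.electrodes])

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.electrodes]


def _reindexed(electrodes) -> tuple[Electrode, ...]:
    return tuple(replace(e, index=i + 1) for i, e in enumerate(electrodes))


@dataclass(frozen=True)
class Ray:
    origin: np.ndarray
    direction: np.ndarray  # unit norm


@dataclass(frozen=True)
class RayHit:
    point: np.ndarray
    face_index: int
    t: float  # ray parameter, mm


def cast_ray(camera: Camera, viewport_wh: tuple[int, int],
             pixel_xy: tuple[float, float]) -> Ray:
    """Project a viewport pixel through the camera into the scene.

    Pixel coordinates are continuous, origin at the top-left corner, x to
    the right and y downward; the viewport centre (w/2, h/2) maps exactly
    onto the view axis.  The vertical field of view is ``view_angle``; the
    horizontal one follows from the aspect ratio.
    """
    w, h = viewport_wh
    px, py = pixel_xy
    if w <= 0 or h <= 0:
        raise CameraError("viewport must have positive size")
    if not (0 <= px <= w and 0 <= py <= h):
        raise DomainError(f"pixel ({px}, {py}) outside viewport {w}x{h}")
    right, up, fwd = camera.basis()
    t = np.tan(np.deg2rad(camera.view_angle) / 2.0)
    u = (px - w / 2.0) / (h / 2.0) * t
    v = (h / 2.0 - py) / (h / 2.0) * t
    d = fwd + u * right + v * up
    d = d / np.linalg.norm(d)
    return Ray(origin=camera.position.copy(), direction=d)


def intersect(ray: Ray, mesh: TriMesh, eps: float = 1e-9) -> RayHit | None:
    """Nearest ray/mesh intersection (smallest positive parameter).

    Vectorized Moeller-Trumbore over every face.  Exact parameter ties
    (a ray grazing a shared edge) resolve to the lowest face index.
    Returns ``None`` on a miss.
    """
    o = np.asarray(ray.origin, dtype=np.float64)
    d = np.asarray(ray.direction, dtype=np.float64)
    tri = mesh.triangles
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / det
        s = o - v0
        u = np.einsum("ij,ij->i", s, pvec) * inv
        qvec = np.cross(s, e1)
        v = np.einsum("j,ij->i", d, qvec) * inv
        t = np.einsum("ij,ij->i", e2, qvec) * inv
        bary_tol = 1e-12
        hit = ((np.abs(det) > 1e-14) & (u >= -bary_tol) & (v >= -bary_tol)
               & (u + v <= 1 + bary_tol) & (t > eps))
    if not hit.any():
        return None
    t = np.where(hit, t, np.inf)
    fi = int(np.argmin(t))  # argmin returns the lowest index on exact ties
    return RayHit(point=o + t[fi] * d, face_index=fi, t=float(t[fi]))


def pick_surface_point(camera: Camera, mesh: TriMesh,
                       viewport_wh: tuple[int, int],
                       pixel_xy: tuple[float, float]) -> RayHit | None:
    """Ray-cast a viewport click onto the brain surface."""
    return intersect(cast_ray(camera, viewport_wh, pixel_xy), mesh)


def place(eset: ElectrodeSet, point, label: str | None = None,
          color=DEFAULT_COLOR, radius: float = DEFAULT_RADIUS_MM,
          insert_after: int | None = None) -> ElectrodeSet:
    """Add a contact; ``insert_after=j`` inserts after ordinal j (0 prepends,
    ``None`` appends).  Subsequent indices shift up by one."""
    k = len(eset)
    if insert_after is None:
        insert_after = k
    if not 0 <= insert_after <= k:
        raise IndexError(f"insert_after must be in [0, {k}], "
                         f"got {insert_after}")
    new = Electrode(index=1, label=label if label is not None else "",
                    position=np.asarray(point, dtype=np.float64),
                    color=tuple(color), radius=radius)
    elecs = list(eset.electrodes)
    elecs.insert(insert_after, new)
    elecs = _reindexed(elecs)
    if label is None:
        elecs = tuple(e if e.label else replace(e, label=str(e.index))
                      for e in elecs)
    return replace(eset, electrodes=elecs)


def remove(eset: ElectrodeSet, index: int) -> ElectrodeSet:
    """Remove contact ``index`` (the interactive tool's second click);
    remaining indices close ranks to stay contiguous."""
    if not 1 <= index <= len(eset):
        raise IndexError(f"no electrode with index {index}")
    elecs = [e for e in eset.electrodes if e.index != index]
    return replace(eset, electrodes=_reindexed(elecs))


def tune(eset: ElectrodeSet, index: int, delta_xyz,
         step: float = 0.1) -> ElectrodeSet:
    """Nudge a contact by ``delta_xyz`` snapped to integer multiples of
    ``step`` (default 0.1 mm).  No re-projection onto the surface."""
    if step <= 0:
        raise DomainError(f"tuning step must be > 0, got {step}")
    if not 1 <= index <= len(eset):
        raise IndexError(f"no electrode with index {index}")
    delta = np.asarray(delta_xyz, dtype=np.float64)
    delta = np.round(delta / step) * step
    elecs = [replace(e, position=e.position + delta) if e.index == index
             else e for e in eset.electrodes]
    return replace(eset, electrodes=tuple(elecs))
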