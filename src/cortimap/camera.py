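"""Perspective camera model and the standard anatomical view presets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CameraError

DEFAULT_VIEW_ANGLE = 30.0  # vertical field of view, degrees


@dataclass
class Camera:
    """Perspective pinhole camera.

    ``rotation`` is a roll about the view axis in degrees; ``view_angle``
    is the vertical field of view.  The view distance is derived from
    ``position``/``focal_point`` and kept consistent on file round trips.
    """

    position: np.ndarray
    focal_point: np.ndarray
    view_up: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    view_angle: float = DEFAULT_VIEW_ANGLE
    rotation: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64)
        self.focal_point = np.asarray(self.focal_point, dtype=np.float64)
        up = np.asarray(self.view_up, dtype=np.float64)
        n = np.linalg.norm(up)
        if n == 0:
            raise CameraError("view_up has zero norm")
        self.view_up = up / n
        if not 0 < self.view_angle < 180:
            raise CameraError(f"view_angle must be in (0, 180) degrees, "
                              f"got {self.view_angle}")
        if np.linalg.norm(self.focal_point - self.position) == 0:
            raise CameraError("camera position coincides with focal point")

    @property
    def distance(self) -> float:
        return float(np.linalg.norm(self.position - self.focal_point))

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (right, up, forward) with roll applied.

        ``forward`` points from the camera toward the focal point.
        """
        fwd = self.focal_point - self.position
        fwd = fwd / np.linalg.norm(fwd)
        right = np.cross(fwd, self.view_up)
        n = np.linalg.norm(right)
        if n < 1e-12:
            raise CameraError("view_up is parallel to the view direction")
        right = right / n
        up = np.cross(right, fwd)
        th = np.deg2rad(self.rotation)
        c, s = np.cos(th), np.sin(th)
        right_r = c * right + s * up
        up_r = -s * right + c * up
        return right_r, up_r, fwd


#: anatomical view presets: (unit direction from focal point to camera, up)
_PRESETS = {
    "left": ((-1, 0, 0), (0, 0, 1)),
    "right": ((1, 0, 0), (0, 0, 1)),
    "anterior": ((0, 1, 0), (0, 0, 1)),
    "posterior": ((0, -1, 0), (0, 0, 1)),
    "superior": ((0, 0, 1), (0, 1, 0)),
    "inferior": ((0, 0, -1), (0, 1, 0)),
}


def preset_camera(name: str, focal_point=(0.0, 0.0, 0.0),
                  distance: float = 400.0) -> Camera:
    """One of the quick anatomical perspectives (left, right, anterior,
    posterior, superior, inferior)."""
    try:
        direction, up = _PRESETS[name]
    except KeyError:
        raise CameraError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    fp = np.asarray(focal_point, dtype=np.float64)
    pos = fp + distance * np.asarray(direction, dtype=np.float64)
    return Camera(position=pos, focal_point=fp, view_up=np.array(up, float))
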