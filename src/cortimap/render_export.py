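"""Deterministic headless scene assembly and image export.

Scenes combine the brain surface, electrode balls, connection sticks, an
optional surface scalar map, a colorbar and axis/label annotations, viewed
through a :class:`~cortimap.camera.Camera`.  Rendering uses a software
painter's algorithm on the matplotlib Agg canvas: every primitive (face,
ball, stick) is projected through the pinhole camera, depth-sorted and
drawn far-to-near.  With a translucent brain (opacity < 1) interior
electrodes show through the surface; at opacity 1 they are hidden by
nearer faces — matching what an interactive viewer shows.  Identical
scenes render to byte-identical pixel buffers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.cm import ScalarMappable
from matplotlib.colors import Normalize
from matplotlib.figure import Figure
from matplotlib.lines import Line2D
from matplotlib.patches import Circle, Polygon

from PIL import Image

from .camera import Camera
from .connectivity import EdgeSet
from .errors import DomainError
from .formats import ParamTable
from .mesh_model import TriMesh
from .registration import ElectrodeSet
from .surface_mapping import (DEFAULT_CMAP, DEFAULT_SIGMA_MM, ScalarField,
                              gaussian_map, value_colors)

_NEAR_MM = 1.0
MESH_BASE_COLOR = (0.78, 0.78, 0.80)


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to render one view, with the interactive tool's
    toggles (axes, colorbar, electrodes, labels) as booleans."""

    mesh: TriMesh
    camera: Camera
    electrodes: ElectrodeSet | None = None
    edge_set: EdgeSet | None = None
    edge_colors: np.ndarray | None = None  # (k, 3) RGB per stick
    scalar_field: ScalarField | None = None
    mesh_opacity: float = 1.0
    background: str = "white"
    cmap: str = DEFAULT_CMAP
    show_axes: bool = False
    show_colorbar: bool = True
    show_electrodes: bool = True
    show_labels: bool = False

    def __post_init__(self):
        if not 0.0 <= self.mesh_opacity <= 1.0:
            raise DomainError(f"mesh opacity must be in [0, 1], "
                              f"got {self.mesh_opacity}")
        if self.background not in ("white", "black"):
            raise DomainError("background must be 'white' or 'black'")


def _project(points: np.ndarray, camera: Camera, width: int, height: int):
    """World -> (pixel x, pixel y, view depth); matches cast_ray exactly."""
    right, up, fwd = camera.basis()
    rel = points - camera.position
    x = rel @ right
    y = rel @ up
    z = rel @ fwd
    t = np.tan(np.deg2rad(camera.view_angle) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        px = width / 2.0 + (x / z) / t * (height / 2.0)
        py = height / 2.0 - (y / z) / t * (height / 2.0)
    return px, py, z


def render(scene: SceneSpec, width: int = 640,
           height: int = 480) -> np.ndarray:
    """Render the scene to an (height, width, 3) uint8 RGB buffer.

    Deterministic: the same scene and size always produce the same bytes
    on the same platform.  Inputs are never mutated.
    """
    if width <= 0 or height <= 0:
        raise DomainError("image size must be positive")
    cam = scene.camera
    mesh = scene.mesh
    prims: list[tuple[float, int, object]] = []  # (depth, seq, artist spec)
    seq = 0

    # --- brain surface faces
    vx, vy, vz = _project(mesh.vertices, cam, width, height)
    tri_px = np.stack([vx[mesh.faces], vy[mesh.faces]], axis=-1)  # (F,3,2)
    tri_z = vz[mesh.faces]
    normals = mesh.face_normals()
    _, _, fwd = cam.basis()
    shade = 0.25 + 0.75 * np.abs(normals @ fwd)
    if scene.scalar_field is not None:
        sf = scene.scalar_field
        face_vals = np.nanmean(sf.values[mesh.faces], axis=1)
        base = value_colors(face_vals, sf.range, scene.cmap)
        face_cov = sf.covered[mesh.faces].any(axis=1)
        base[~face_cov] = MESH_BASE_COLOR
    else:
        base = np.tile(np.asarray(MESH_BASE_COLOR), (mesh.n_faces, 1))
    face_rgb = base * shade[:, None]
    if scene.mesh_opacity > 0:
        visible = tri_z.min(axis=1) > _NEAR_MM
        for fi in np.nonzero(visible)[0]:
            prims.append((float(tri_z[fi].mean()), seq,
                          ("poly", tri_px[fi],
                           (*face_rgb[fi], scene.mesh_opacity))))
            seq += 1

    # --- connection sticks
    if scene.edge_set is not None and scene.electrodes is not None \
            and len(scene.edge_set):
        pos = scene.electrodes.positions
        ex, ey, ez = _project(pos, cam, width, height)
        colors = scene.edge_colors
        if colors is None:
            colors = np.tile([0.2, 0.2, 0.8], (len(scene.edge_set), 1))
        for k, (a, b, w) in enumerate(scene.edge_set.as_list()):
            if ez[a] <= _NEAR_MM or ez[b] <= _NEAR_MM:
                continue
            depth = float((ez[a] + ez[b]) / 2.0)
            lw = 2.5 if scene.edge_set.mode == "binary" else 1.0 + 2.5 * abs(w)
            prims.append((depth, seq,
                          ("line", ((ex[a], ey[a]), (ex[b], ey[b])),
                           tuple(colors[k]), lw)))
            seq += 1

    # --- electrode balls (+ labels)
    if scene.electrodes is not None and scene.show_electrodes \
            and len(scene.electrodes):
        pos = scene.electrodes.positions
        ex, ey, ez = _project(pos, cam, width, height)
        t = np.tan(np.deg2rad(cam.view_angle) / 2.0)
        for i, e in enumerate(scene.electrodes):
            if ez[i] <= _NEAR_MM:
                continue
            r_px = (e.radius / ez[i]) / t * (height / 2.0)
            prims.append((float(ez[i]), seq,
                          ("disc", (ex[i], ey[i]), max(r_px, 0.5), e.color)))
            seq += 1
            if scene.show_labels:
                prims.append((float(ez[i]) - 1e-6, seq,
                              ("text", (ex[i], ey[i] - 1.2 * r_px),
                               e.label)))
                seq += 1

    # --- assemble the figure
    dpi = 100.0
    fig = Figure(figsize=(width / dpi, height / dpi), dpi=dpi)
    FigureCanvasAgg(fig)
    fig.patch.set_facecolor(scene.background)
    ax = fig.add_axes([0.0, 0.0, 1.0, 1.0])
    ax.set_facecolor(scene.background)
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)  # pixel y grows downward
    ax.set_axis_off()
    fg = "black" if scene.background == "white" else "white"

    for depth, _, spec in sorted(prims, key=lambda p: (-p[0], p[1])):
        kind = spec[0]
        if kind == "poly":
            # stroking opaque faces with their own color closes the
            # antialiasing seams between adjacent triangles
            edge = spec[2] if spec[2][3] >= 1.0 else "none"
            ax.add_patch(Polygon(spec[1], closed=True, facecolor=spec[2],
                                 edgecolor=edge, linewidth=0.4))
        elif kind == "line":
            (x0, y0), (x1, y1) = spec[1]
            ax.add_line(Line2D([x0, x1], [y0, y1], color=spec[2],
                               linewidth=spec[3], solid_capstyle="round"))
        elif kind == "disc":
            ax.add_patch(Circle(spec[1], radius=spec[2], facecolor=spec[3],
                                edgecolor="none"))
        elif kind == "text":
            ax.text(spec[1][0], spec[1][1], spec[2], color=fg, fontsize=6,
                    ha="center", va="bottom")

    if scene.show_axes:
        ox, oy, oz = _project(np.vstack([np.zeros(3),
                                         np.eye(3) * 50.0]), cam,
                              width, height)
        for k, col in enumerate(("r", "g", "b")):
            if oz[0] > _NEAR_MM and oz[k + 1] > _NEAR_MM:
                ax.add_line(Line2D([ox[0], ox[k + 1]], [oy[0], oy[k + 1]],
                                   color=col, linewidth=1.0))

    if scene.show_colorbar and scene.scalar_field is not None:
        cax = fig.add_axes([0.92, 0.15, 0.025, 0.7])
        lo, hi = scene.scalar_field.range
        sm = ScalarMappable(norm=Normalize(lo, hi), cmap=scene.cmap)
        cb = fig.colorbar(sm, cax=cax)
        cb.ax.tick_params(labelsize=6, colors=fg)
        cb.outline.set_edgecolor(fg)

    fig.canvas.draw()
    buf = np.asarray(fig.canvas.buffer_rgba())[:, :, :3].copy()
    return buf


def save_image(buffer: np.ndarray, path) -> None:
    """Write an RGB buffer as PNG or BMP (chosen by extension)."""
    Image.fromarray(buffer).save(str(path))


def export_images(scene: SceneSpec, params: ParamTable, out_prefix,
                  fmt: str = "png", width: int = 640, height: int = 480,
                  method: str = "gauss",
                  sigma_mm: float = DEFAULT_SIGMA_MM) -> list[Path]:
    """Export one surface-map image per parameter row.

    Row ``r`` (1-based in filenames) is interpolated onto the surface and
    rendered with the scene's camera/toggles; files are named
    ``<prefix>_001.<fmt>`` .. ``<prefix>_m.<fmt>``.  Re-exporting the
    same inputs rewrites identical files.
    """
    if fmt not in ("png", "bmp"):
        raise DomainError(f"format must be 'png' or 'bmp', got {fmt!r}")
    if scene.electrodes is None or len(scene.electrodes) == 0:
        raise DomainError("export needs a montage in the scene")
    from .surface_mapping import linear_map  # local to avoid cycle noise
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in range(params.m):
        row = params.values[r]
        if method == "gauss":
            sf = gaussian_map(scene.mesh, scene.electrodes, row, sigma_mm)
        elif method == "linear":
            sf = linear_map(scene.mesh, scene.electrodes, row)
        else:
            raise DomainError(f"method must be 'gauss' or 'linear', "
                              f"got {method!r}")
        frame = replace(scene, scalar_field=sf)
        buf = render(frame, width=width, height=height)
        path = Path(f"{out_prefix}_{r + 1:03d}.{fmt}")
        save_image(buf, path)
        paths.append(path)
    return paths
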