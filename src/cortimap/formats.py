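"""Readers and writers for the five cortimap file types.

==========  =========  =====================================================
extension   payload    contents
==========  =========  =====================================================
``.mof``    binary     brain model: vertices + triangle faces
``.epf``    ASCII      electrode positions (one contact per line)
``.cpf``    ASCII      camera view (position, focal point, up, angle, roll)
``.txt``    ASCII      functional-parameter table (m x n, tab-separated)
``.txt``    ASCII      correlation matrix (n x n, tab-separated)
==========  =========  =====================================================

The model file is the only binary format: an 8-byte magic ``CORTIMOF``,
little-endian ``uint32`` vertex and face counts, a ``float32`` V x 3 vertex
block and a ``uint32`` F x 3 face block (0-based indices).  Standard mesh
files (OFF/PLY/STL via trimesh, GIfTI via nibabel) can be converted in.

All ASCII formats use the tab as the only field delimiter and a
locale-independent decimal point; the writers are canonical so
write(read(f)) reproduces f byte for byte (modulo trailing newline).
Electrode files are deliberately hand-editable: whatever coordinate is in
the file is the truth on re-read.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .camera import Camera
from .errors import (DomainError, FormatError, ParseError, ShapeError,
                     ValidationError)
from .mesh_model import TriMesh, import_mesh
from .registration import (DEFAULT_COLOR, DEFAULT_RADIUS_MM, Electrode,
                           ElectrodeSet)

log = logging.getLogger(__name__)

MODEL_MAGIC = b"CORTIMOF"
_FLOAT_FMT = "%.10g"
#: |C - C.T| above this triggers symmetrization with a warning
MATRIX_ASYMMETRY_TOL = 1e-6


@dataclass(frozen=True)
class ParamTable:
    """m x n functional-parameter values: m rows (time stages or indexes),
    n channels."""

    values: np.ndarray

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if v.ndim != 2 or v.shape[0] < 1:
            raise ShapeError(f"parameter table must be m x n, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("parameter table contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CorrTable:
    """n x n symmetric matrix of a pairwise correlation measure.

    The diagonal is ignored by every consumer (no self-connections)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeError(f"correlation matrix must be square, "
                             f"got {v.shape}")
        asym = np.abs(v - v.T).max() if v.size else 0.0
        if asym > MATRIX_ASYMMETRY_TOL:
            log.warning("correlation matrix asymmetric by %.3g; "
                        "symmetrizing with (C + C.T)/2", asym)
            v = 0.5 * (v + v.T)
        else:
            v = 0.5 * (v + v.T)  # idempotent; removes sub-tol noise
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------- model .mof

def write_model(path, mesh: TriMesh) -> None:
    """Write a brain model file (.mof)."""
    path = Path(path)
    mesh = import_mesh(mesh.vertices, mesh.faces)  # enforce invariants
    with open(path, "wb") as fh:
        fh.write(MODEL_MAGIC)
        fh.write(struct.pack("<II", mesh.n_vertices, mesh.n_faces))
        fh.write(np.ascontiguousarray(mesh.vertices,
                                      dtype="<f4").tobytes())
        fh.write(np.ascontiguousarray(mesh.faces, dtype="<u4").tobytes())


def read_model(path) -> TriMesh:
    """Read a brain model file (.mof)."""
    path = Path(path)
    raw = path.read_bytes()
    if raw[:8] != MODEL_MAGIC:
        raise FormatError(f"{path}: bad magic at byte offset 0 "
                          f"(expected {MODEL_MAGIC!r}, got {raw[:8]!r})")
    if len(raw) < 16:
        raise FormatError(f"{path}: truncated header at byte offset 8")
    nv, nf = struct.unpack_from("<II", raw, 8)
    need = 16 + nv * 12 + nf * 12
    if len(raw) < need:
        raise FormatError(f"{path}: truncated payload at byte offset "
                          f"{len(raw)} (expected {need} bytes)")
    verts = np.frombuffer(raw, dtype="<f4", count=nv * 3,
                          offset=16).reshape(nv, 3).astype(np.float64)
    faces = np.frombuffer(raw, dtype="<u4", count=nf * 3,
                          offset=16 + nv * 12).reshape(nf, 3)
    if faces.size and faces.max() >= nv:
        bad = np.where((faces >= nv).any(axis=1))[0]
        raise ValidationError(
            f"{path}: dangling face index (faces {bad[:10].tolist()} "
            f"reference vertices >= {nv})")
    return import_mesh(verts, faces.astype(np.int64))


def convert_mesh(path) -> TriMesh:
    """Load a standard mesh file (OFF/PLY/STL/GIfTI/.mof) as a TriMesh."""
    path = Path(path)
    if path.suffix.lower() == ".mof":
        return read_model(path)
    if path.suffix.lower() == ".gii":
        import nibabel as nib
        img = nib.load(str(path))
        verts = img.agg_data("pointset")
        faces = img.agg_data("triangle")
        return import_mesh(np.asarray(verts), np.asarray(faces))
    import trimesh as _tm
    tm = _tm.load_mesh(str(path), process=False)
    return import_mesh(np.asarray(tm.vertices), np.asarray(tm.faces))


# ----------------------------------------------------------- electrodes .epf

def write_electrodes(path, eset: ElectrodeSet) -> None:
    """Write an electrode position file (.epf)."""
    lines = [f"# cortimap electrodes v1\tspace={eset.coordinate_space}"]
    for e in eset:
        coords = "\t".join(_FLOAT_FMT % c for c in e.position)
        style = "\t".join(_FLOAT_FMT % c for c in (*e.color, e.radius))
        lines.append(f"{e.index}\t{e.label}\t{coords}\t{style}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_electrodes(path) -> ElectrodeSet:
    """Read an electrode position file (.epf).

    The file is the source of truth: coordinates edited by hand are
    honoured verbatim.  An empty file yields an empty montage.
    """
    space = "native"
    electrodes: list[Electrode] = []
    seen: set[int] = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if "space=" in line:
                space = line.split("space=", 1)[1].split()[0].strip()
            continue
        parts = line.split("\t")
        if len(parts) not in (5, 9):
            raise ParseError(f"expected 5 or 9 tab-separated fields, "
                             f"got {len(parts)}", line=ln)
        try:
            idx = int(parts[0])
            xyz = [float(p) for p in parts[2:5]]
        except ValueError as exc:
            raise ParseError(f"non-numeric field: {exc}", line=ln) from None
        if idx in seen:
            raise ValidationError(f"duplicate electrode index {idx} "
                                  f"at line {ln}")
        seen.add(idx)
        color, radius = DEFAULT_COLOR, DEFAULT_RADIUS_MM
        if len(parts) == 9:
            try:
                color = tuple(float(p) for p in parts[5:8])
                radius = float(parts[8])
            except ValueError as exc:
                raise ParseError(f"non-numeric style field: {exc}",
                                 line=ln) from None
        electrodes.append(Electrode(index=idx, label=parts[1],
                                    position=np.array(xyz), color=color,
                                    radius=radius))
    electrodes.sort(key=lambda e: e.index)
    got = [e.index for e in electrodes]
    if got != list(range(1, len(got) + 1)):
        raise ValidationError(f"electrode indices not contiguous 1..k: {got}")
    return ElectrodeSet(electrodes=tuple(electrodes),
                        coordinate_space=space)


# --------------------------------------------------------------- camera .cpf

_CAMERA_KEYS = ("position", "focal_point", "view_up", "view_angle",
                "distance", "rotation")


def write_camera(path, camera: Camera) -> None:
    """Write a camera position file (.cpf)."""
    lines = ["# cortimap camera v1"]
    for key, vals in (
            ("position", camera.position),
            ("focal_point", camera.focal_point),
            ("view_up", camera.view_up),
            ("view_angle", [camera.view_angle]),
            ("distance", [camera.distance]),
            ("rotation", [camera.rotation % 360.0])):
        lines.append(key + "\t" + "\t".join(_FLOAT_FMT % v for v in vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_camera(path) -> Camera:
    """Read a camera position file (.cpf).

    The stored distance must agree with ``|position - focal_point|``
    (tolerance 1e-3 mm); the roll angle is normalized into [0, 360).
    """
    fields: dict[str, list[float]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            fields[parts[0]] = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise ParseError(f"non-numeric value for key {parts[0]!r}: "
                             f"{exc}", line=ln) from None
    for key in _CAMERA_KEYS:
        if key not in fields:
            raise ParseError(f"camera file missing required key {key!r}")
    cam = Camera(position=np.array(fields["position"]),
                 focal_point=np.array(fields["focal_point"]),
                 view_up=np.array(fields["view_up"]),
                 view_angle=fields["view_angle"][0],
                 rotation=fields["rotation"][0] % 360.0)
    stored = fields["distance"][0]
    if abs(stored - cam.distance) > 1e-3:
        raise ValidationError(
            f"stored camera distance {stored:g} inconsistent with "
            f"|position - focal_point| = {cam.distance:g}")
    return cam


# ------------------------------------------------------------- tables (.txt)

def write_table(path, table: ParamTable | CorrTable | np.ndarray) -> None:
    """Write a tab-separated parameter table or correlation matrix."""
    values = table.values if hasattr(table, "values") else np.atleast_2d(table)
    lines = ["\t".join(_FLOAT_FMT % v for v in row) for row in values]
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path, kind: str = "params") -> ParamTable | CorrTable:
    """Read a tab-separated table as ``kind='params'`` (m x n) or
    ``kind='matrix'`` (n x n correlation measure)."""
    if kind not in ("params", "matrix"):
        raise DomainError(f"kind must be 'params' or 'matrix', got {kind!r}")
    rows: list[list[float]] = []
    width = None
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            row = [float(p) for p in parts]
        except ValueError as exc:
            raise ParseError(f"non-numeric value: {exc}", line=ln) from None
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ParseError(f"ragged row: expected {width} values, "
                             f"got {len(row)}", line=ln)
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: empty table")
    values = np.array(rows, dtype=np.float64)
    if kind == "matrix":
        if values.shape[0] != values.shape[1]:
            raise ShapeError(f"correlation matrix must be square, "
                             f"got {values.shape}")
        return CorrTable(values=values)
    return ParamTable(values=values)


# ----------------------------------------------------- coordinate import

def import_coordinates(table, transform=None, source_space: str = "native",
                       labels=None) -> ElectrodeSet:
    """Build a montage from an external k x 3(+) coordinate table.

    ``transform`` is an affine 4x4 (identity when omitted) mapping the
    source coordinates into model space, for positions exported by
    stereotactic devices, CT/X-ray reconstructions etc.  Labels default
    to "1".."k".
    """
    arr = np.atleast_2d(np.asarray(table, dtype=np.float64))
    if arr.shape[1] < 3:
        raise ShapeError(f"coordinate table needs >= 3 numeric columns, "
                         f"got {arr.shape[1]}")
    xyz = arr[:, :3]
    if transform is not None:
        tr = np.asarray(transform, dtype=np.float64)
        if tr.shape != (4, 4):
            raise ShapeError(f"transform must be 4x4, got {tr.shape}")
        if abs(np.linalg.det(tr)) < 1e-12:
            raise ValidationError("singular affine transform")
        homo = np.hstack([xyz, np.ones((len(xyz), 1))])
        xyz = (homo @ tr.T)[:, :3]
    if labels is None:
        labels = [str(i + 1) for i in range(len(xyz))]
    electrodes = tuple(
        Electrode(index=i + 1, label=str(labels[i]), position=xyz[i])
        for i in range(len(xyz)))
    return ElectrodeSet(electrodes=electrodes, coordinate_space=source_space)
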