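"""Brain-surface triangle mesh: container, validation and fineness control.

The surface model used throughout cortimap is a plain triangle mesh in
millimetres (RAS orientation, matching MNI/Talairach conventions): a V x 3
float array of vertex coordinates and an F x 3 integer array of 0-based
vertex indices.  Meshes typically come from an MRI reconstruction exported
by other software; cortimap never extracts surfaces itself.

``decimate`` reduces mesh fineness by quadric edge collapse (Garland &
Heckbert error quadrics), deterministically given the input vertex/face
order, so that coarse display meshes can be derived from dense
reconstructions.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError

log = logging.getLogger(__name__)

#: faces with area below this (mm^2) are considered degenerate
DEGENERATE_AREA_MM2 = 1e-12


@dataclass(frozen=True)
class TriMesh:
    """A validated triangle surface.

    Attributes
    ----------
    vertices : (V, 3) float64 array, millimetres
    faces : (F, 3) int64 array of vertex indices (0-based)
    """

    vertices: np.ndarray
    faces: np.ndarray

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        """Unit per-face normals, (F, 3)."""
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / norm

    def face_areas(self) -> np.ndarray:
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def edges_unique(self) -> np.ndarray:
        """Undirected unique edges, (E, 2) with e[0] < e[1]."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        """V - E + F; equals 2 for a closed surface of genus 0."""
        return self.n_vertices - len(self.edges_unique()) + self.n_faces

    def bbox_diagonal(self) -> float:
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


def import_mesh(vertices: np.ndarray, faces: np.ndarray) -> TriMesh:
    """Validate raw vertex/face arrays into a :class:`TriMesh`.

    Degenerate faces (repeated vertex index or area < 1e-12 mm^2) are
    dropped with a logged count; out-of-bounds indices raise.
    """
    vertices = np.ascontiguousarray(vertices, dtype=np.float64)
    faces = np.ascontiguousarray(faces, dtype=np.int64)
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise ValidationError(f"vertices must be V x 3, got {vertices.shape}")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise ValidationError(f"faces must be F x 3, got {faces.shape}")
    if vertices.shape[0] < 4:
        raise ValidationError(
            f"a surface needs at least 4 vertices, got {vertices.shape[0]}")
    if not np.all(np.isfinite(vertices)):
        raise ValidationError("non-finite vertex coordinate")
    if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
        bad = np.where((faces < 0) | (faces >= len(vertices)))[0]
        raise ValidationError(
            f"face indices out of range [0, {len(vertices)}): "
            f"faces {bad[:10].tolist()}")

    # drop repeated-index and zero-area faces
    repeated = ((faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2])
                | (faces[:, 0] == faces[:, 2]))
    tri = vertices[faces]
    area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    keep = ~repeated & (area >= DEGENERATE_AREA_MM2)
    dropped = int((~keep).sum())
    if dropped:
        log.info("import_mesh: dropped %d degenerate face(s)", dropped)
        faces = faces[keep]
    return TriMesh(vertices=vertices, faces=faces)


def _vertex_quadrics(mesh: TriMesh) -> np.ndarray:
    """Per-vertex 4x4 error quadrics: sum of face plane quadrics."""
    tri = mesh.triangles
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = n / norm
    d = -np.einsum("ij,ij->i", n, tri[:, 0])
    p = np.hstack([n, d[:, None]])                      # (F, 4) plane coeffs
    kp = p[:, :, None] * p[:, None, :]                  # (F, 4, 4)
    quadrics = np.zeros((mesh.n_vertices, 4, 4))
    for c in range(3):
        np.add.at(quadrics, mesh.faces[:, c], kp)
    return quadrics


def _collapse_target(q: np.ndarray, p1: np.ndarray, p2: np.ndarray):
    """Optimal collapse position for quadric q, falling back to the best of
    the endpoints and midpoint when the quadric is singular."""
    a = q[:3, :3]
    b = -q[:3, 3]
    try:
        v = np.linalg.solve(a, b)
        if np.all(np.isfinite(v)) and np.linalg.cond(a) < 1e7:
            h = np.append(v, 1.0)
            return v, float(h @ q @ h)
    except np.linalg.LinAlgError:
        pass
    best_v, best_c = None, np.inf
    for cand in (p1, p2, 0.5 * (p1 + p2)):
        h = np.append(cand, 1.0)
        c = float(h @ q @ h)
        if c < best_c:
            best_v, best_c = cand, c
    return best_v, best_c


def decimate(mesh: TriMesh, target_fraction: float | None = None,
             target_faces: int | None = None) -> TriMesh:
    """Reduce face count by quadric edge collapse.

    Exactly one of ``target_fraction`` (0 < f <= 1, fraction of current
    faces kept) or ``target_faces`` may be given.  Boundary vertices are
    frozen so open edges are preserved.  Deterministic for a given input.
    """
    if (target_fraction is None) == (target_faces is None):
        raise DomainError("give exactly one of target_fraction/target_faces")
    if target_fraction is not None:
        if not 0 < target_fraction <= 1:
            raise DomainError(f"target_fraction must be in (0, 1], "
                              f"got {target_fraction}")
        target_faces = int(round(target_fraction * mesh.n_faces))
    if target_faces >= mesh.n_faces:
        return mesh

    verts = mesh.vertices.copy()
    quadrics = _vertex_quadrics(mesh)
    faces = [tuple(f) for f in mesh.faces]
    face_alive = [True] * len(faces)
    n_alive = len(faces)
    vert_faces: list[set[int]] = [set() for _ in range(len(verts))]
    for fi, f in enumerate(faces):
        for v in f:
            vert_faces[v].add(fi)

    # boundary vertices: incident edge with a single adjacent face
    edge_count: dict[tuple[int, int], int] = {}
    for f in faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            e = (a, b) if a < b else (b, a)
            edge_count[e] = edge_count.get(e, 0) + 1
    boundary = np.zeros(len(verts), dtype=bool)
    for (a, b), c in edge_count.items():
        if c == 1:
            boundary[a] = boundary[b] = True

    version = [0] * len(verts)
    alive = [True] * len(verts)

    def push(heap, i, j):
        if boundary[i] or boundary[j]:
            return
        q = quadrics[i] + quadrics[j]
        v, cost = _collapse_target(q, verts[i], verts[j])
        heapq.heappush(heap, (cost, i, j, version[i], version[j],
                              tuple(v)))

    heap: list = []
    for (a, b) in sorted(edge_count):
        push(heap, a, b)

    while n_alive > target_faces and heap:
        cost, i, j, vi, vj, vbar = heapq.heappop(heap)
        if not (alive[i] and alive[j]):
            continue
        if version[i] != vi or version[j] != vj:
            continue
        shared = vert_faces[i] & vert_faces[j]
        if not shared:
            continue  # no longer an edge
        vbar = np.asarray(vbar)

        # reject collapses that flip a surviving face's normal
        ok = True
        for fi in (vert_faces[i] | vert_faces[j]) - shared:
            f = faces[fi]
            old = [verts[v] for v in f]
            new = [vbar if v in (i, j) else verts[v] for v in f]
            n_old = np.cross(old[1] - old[0], old[2] - old[0])
            n_new = np.cross(new[1] - new[0], new[2] - new[0])
            if np.dot(n_old, n_new) <= 0:
                ok = False
                break
        if not ok:
            continue

        verts[i] = vbar
        quadrics[i] = quadrics[i] + quadrics[j]
        for fi in shared:
            if face_alive[fi]:
                face_alive[fi] = False
                n_alive -= 1
            for v in faces[fi]:
                vert_faces[v].discard(fi)
        for fi in list(vert_faces[j]):
            f = faces[fi]
            faces[fi] = tuple(i if v == j else v for v in f)
            vert_faces[j].discard(fi)
            vert_faces[i].add(fi)
        alive[j] = False
        version[i] += 1
        version[j] += 1

        neighbours = sorted({v for fi in vert_faces[i]
                             for v in faces[fi] if v != i and alive[v]})
        for nb in neighbours:
            push(heap, min(i, nb), max(i, nb))

    kept = [faces[fi] for fi in range(len(faces)) if face_alive[fi]]
    used = sorted({v for f in kept for v in f})
    remap = {v: k for k, v in enumerate(used)}
    new_faces = np.array([[remap[v] for v in f] for f in kept], dtype=np.int64)
    new_verts = verts[used]
    return import_mesh(new_verts, new_faces)
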