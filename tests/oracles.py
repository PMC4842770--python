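"""Independent reference implementations used only as test oracles.

Deliberately scalar and loop-based so they share no code path with the
vectorized library routines they check.
"""

import numpy as np


def moller_trumbore_one(origin, direction, v0, v1, v2, eps=1e-9):
    """Ray/triangle intersection parameter t, or None (scalar version)."""
    e1 = v1 - v0
    e2 = v2 - v0
    p = np.cross(direction, e2)
    det = float(np.dot(e1, p))
    if abs(det) < 1e-14:
        return None
    inv = 1.0 / det
    s = origin - v0
    u = float(np.dot(s, p)) * inv
    if u < -1e-12:
        return None
    q = np.cross(s, e1)
    v = float(np.dot(direction, q)) * inv
    if v < -1e-12 or u + v > 1 + 1e-12:
        return None
    t = float(np.dot(e2, q)) * inv
    return t if t > eps else None


def brute_force_nearest_hit(origin, direction, mesh):
    """Nearest positive ray/mesh hit by testing every triangle in a loop."""
    best_t, best_face = None, None
    for fi, f in enumerate(mesh.faces):
        t = moller_trumbore_one(origin, direction, mesh.vertices[f[0]],
                                mesh.vertices[f[1]], mesh.vertices[f[2]])
        if t is not None and (best_t is None or t < best_t):
            best_t, best_face = t, fi
    if best_t is None:
        return None
    return origin + best_t * direction, best_face, best_t


def point_triangle_distance(p, a, b, c):
    """Euclidean distance from a point to a triangle (clamped barycentric
    projection onto the plane, edges and vertices)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.dot(ab, ap)
    d2 = np.dot(ac, ap)
    if d1 <= 0 and d2 <= 0:
        return float(np.linalg.norm(p - a))
    bp = p - b
    d3 = np.dot(ab, bp)
    d4 = np.dot(ac, bp)
    if d3 >= 0 and d4 <= d3:
        return float(np.linalg.norm(p - b))
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return float(np.linalg.norm(p - (a + v * ab)))
    cp = p - c
    d5 = np.dot(ab, cp)
    d6 = np.dot(ac, cp)
    if d6 >= 0 and d5 <= d6:
        return float(np.linalg.norm(p - c))
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return float(np.linalg.norm(p - (a + w * ac)))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return float(np.linalg.norm(p - (b + w * (c - b))))
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return float(np.linalg.norm(p - (a + v * ab + w * ac)))


def distance_to_mesh(p, mesh):
    """Distance from a point to the nearest triangle of a mesh."""
    return min(point_triangle_distance(p, *mesh.vertices[f])
               for f in mesh.faces)
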