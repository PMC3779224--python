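"""Icosphere tessellations used as the discrete support of ODFs.

The icosahedron is centrally symmetric, and midpoint subdivision preserves
that symmetry, so every vertex has an exact antipode in the mesh — the
property ODF symmetrization and axial peak merging rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["SphereTess", "icosphere"]


@dataclass(frozen=True)
class SphereTess:
    vertices: np.ndarray  # (V, 3), unit norm
    faces: np.ndarray  # (F, 3) int
    neighbors: tuple  # tuple of int arrays, per-vertex 1-ring
    antipode: np.ndarray  # (V,) index of -v for each v

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edge_angle_deg(self) -> float:
        """Largest 1-ring edge angle (an upper bound on angular resolution)."""
        worst = 0.0
        for i, nb in enumerate(self.neighbors):
            dots = self.vertices[nb] @ self.vertices[i]
            worst = max(worst, float(np.degrees(np.arccos(np.clip(dots.min(), -1, 1)))))
        return worst


def _icosahedron():
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    return v, f


@lru_cache(maxsize=8)
def icosphere(subdivisions: int = 3) -> SphereTess:
    """Subdivided icosahedron; order 3 gives 642 vertices (~8 deg edges)."""
    verts, faces = _icosahedron()
    verts = [tuple(v) for v in verts]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        new_faces = []

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = np.asarray(verts[i]) + np.asarray(verts[j])
                m /= np.linalg.norm(m)
                verts.append(tuple(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        faces = np.asarray(new_faces, dtype=int)
    v = np.asarray(verts, dtype=float)
    v /= np.linalg.norm(v, axis=1, keepdims=True)

    # neighbor lists from face edges
    nb: list[set[int]] = [set() for _ in range(len(v))]
    for a, b, c in faces:
        nb[a].update((b, c))
        nb[b].update((a, c))
        nb[c].update((a, b))
    neighbors = tuple(np.array(sorted(s), dtype=int) for s in nb)

    # exact antipode lookup (mesh is centrally symmetric)
    order = np.lexsort(np.round(v.T, 9))
    lookup = {tuple(np.round(v[i], 9)): i for i in order}
    anti = np.empty(len(v), dtype=int)
    for i in range(len(v)):
        key = tuple(np.round(-v[i], 9))
        if key not in lookup:
            raise RuntimeError("tessellation lost antipodal symmetry")
        anti[i] = lookup[key]
    return SphereTess(v, faces, neighbors, anti)
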