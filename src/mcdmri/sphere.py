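"""Unit-sphere point sets and orientation helpers.

Provides the cached symmetric tessellations used for numerical spherical
integration, FOD positivity constraint grids, and brute-force orientation
searches, plus conversions between Cartesian unit vectors and the
(theta, phi) Euler-angle convention used by all anisotropic models
(theta in [0, pi] polar, phi in [-pi, pi] azimuth; antipodal symmetry is
handled by canonicalizing to the upper hemisphere).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "icosphere",
    "symmetric_sphere",
    "hemisphere",
    "golden_spiral_directions",
    "unit_vector_to_angles",
    "angles_to_unit_vector",
]


def _icosahedron():
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    return verts, faces


@lru_cache(maxsize=8)
def icosphere(subdivisions: int = 4) -> np.ndarray:
    """Vertices of a subdivided icosahedron (12, 42, 162, 642, 2562, ... points).

    The vertex set is exactly antipodally symmetric, which makes it suitable
    for integrating antipodally symmetric spherical functions.
    """
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        edge_mid = {}
        new_faces = []
        verts_list = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in edge_mid:
                m = verts_list[i] + verts_list[j]
                m = m / np.linalg.norm(m)
                edge_mid[key] = len(verts_list)
                verts_list.append(m)
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces)
    return verts


def golden_spiral_directions(n: int, hemisphere_only: bool = False) -> np.ndarray:
    """Deterministic near-uniform directions via the golden-ratio spiral."""
    i = np.arange(n) + 0.5
    if hemisphere_only:
        cos_theta = i / n  # z in (0, 1)
    else:
        cos_theta = 1.0 - 2.0 * i / n
    theta = np.arccos(np.clip(cos_theta, -1, 1))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


@lru_cache(maxsize=8)
def symmetric_sphere(n_half: int = 362) -> np.ndarray:
    """Antipodally symmetric set of 2*n_half points (default 724)."""
    half = golden_spiral_directions(n_half, hemisphere_only=True)
    return np.vstack([half, -half])


@lru_cache(maxsize=8)
def hemisphere(n: int = 30) -> np.ndarray:
    """n upper-hemisphere directions for brute-force orientation grids."""
    return golden_spiral_directions(n, hemisphere_only=True)


def unit_vector_to_angles(v: np.ndarray) -> np.ndarray:
    """Cartesian unit vector(s) -> (theta, phi), canonicalized to z >= 0."""
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    v = np.where((v[:, 2:3] < 0), -v, v)  # antipodal symmetry
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])
    ang = np.column_stack([theta, phi])
    return ang[0] if single else ang


def angles_to_unit_vector(angles: np.ndarray) -> np.ndarray:
    """(theta, phi) pair(s) -> Cartesian unit vector(s)."""
    angles = np.asarray(angles, dtype=float)
    single = angles.ndim == 1
    angles = np.atleast_2d(angles)
    theta, phi = angles[:, 0], angles[:, 1]
    v = np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    return v[0] if single else v
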