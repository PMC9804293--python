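"""Shared numerical helpers: direction sampling, structuring elements, RNG."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "fibonacci_directions",
    "ball_offsets",
    "ball_struct",
    "rng_from",
    "farthest_point_indices",
]


def rng_from(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the hemisphere (antipodes are redundant
    for line probes), shape (n, 3)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    # sample z in (0, 1): upper hemisphere only
    z = i / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    d = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def ball_struct(radius: int) -> np.ndarray:
    """Boolean ball structuring element of the given voxel radius."""
    if radius < 1:
        raise ValueError("radius must be >= 1 voxel")
    ax = np.arange(-radius, radius + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (x**2 + y**2 + z**2) <= radius**2


def ball_offsets(radius_vox: float) -> np.ndarray:
    """Integer offsets (N, 3) of voxels whose centres lie within a sphere of
    the given radius (in voxels)."""
    r = int(np.ceil(radius_vox))
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = (x**2 + y**2 + z**2) <= radius_vox**2
    return np.stack([x[inside], y[inside], z[inside]], axis=1)


def binary_dilate(mask: np.ndarray, radius: int, iterations: int = 1) -> np.ndarray:
    out = mask
    for _ in range(iterations):
        out = ndi.binary_dilation(out, structure=ball_struct(radius))
    return out


def binary_erode(mask: np.ndarray, radius: int, iterations: int = 1) -> np.ndarray:
    out = mask
    for _ in range(iterations):
        out = ndi.binary_erosion(out, structure=ball_struct(radius))
    return out


def closest_on_surface(mesh, points: np.ndarray):
    """Closest points on a trimesh surface.

    Returns (points_on_surface, distances, face_indices).  Uses the rtree-
    accelerated query when available, otherwise the exact naive search.
    """
    import trimesh.proximity as prox

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    try:
        return mesh.nearest.on_surface(pts)
    except BaseException:
        surface, dist, tid = prox.closest_point_naive(mesh, pts)
        return surface, dist, tid


def points_inside_mesh(mesh, points: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Ray-crossing-parity inside test for a closed triangulated mesh.

    Casts one ray per point along a fixed oblique direction (chosen to avoid
    edge/vertex grazing on lattice-aligned inputs) and counts Möller-Trumbore
    intersections against every face; odd parity = inside.  Pure numpy, no
    spatial index required.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = np.asarray(mesh.triangles, dtype=float)  # (F, 3, 3)
    d = np.array([0.2408325, 0.4571233, 0.8562107])
    d /= np.linalg.norm(d)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(d, e2)  # (F, 3)
    det = np.einsum("fj,fj->f", e1, pvec)
    ok_f = np.abs(det) > 1e-12
    inv_det = np.where(ok_f, 1.0 / np.where(ok_f, det, 1.0), 0.0)
    inside = np.zeros(len(pts), dtype=bool)
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk]
        tvec = p[:, None, :] - v0[None, :, :]  # (P, F, 3)
        u = np.einsum("pfj,fj->pf", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("pfj,j->pf", qvec, d) * inv_det
        t = np.einsum("pfj,fj->pf", qvec, e2) * inv_det
        hit = (
            ok_f[None, :]
            & (u >= 0.0)
            & (v >= 0.0)
            & (u + v <= 1.0)
            & (t > 1e-10)
        )
        inside[lo : lo + chunk] = (hit.sum(axis=1) % 2) == 1
    return inside


def farthest_point_indices(points: np.ndarray, k: int, start: int = 0) -> np.ndarray:
    """Greedy farthest-point subsampling of a point set.

    Deterministic given ``start``; O(k * N). Returns indices into ``points``.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if k > n:
        raise ValueError(f"cannot sample {k} points from {n}")
    chosen = np.empty(k, dtype=int)
    chosen[0] = start
    d = np.linalg.norm(pts - pts[start], axis=1)
    for i in range(1, k):
        nxt = int(np.argmax(d))
        chosen[i] = nxt
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return chosen
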