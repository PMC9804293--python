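"""Tetrahedral meshing of the trabecular region and scalar interpolation.

A Delaunay-based volumetric mesh is built from the inner-mask voxel
geometry: interior lattice points at the target edge length plus boundary
vertices from a marching-cubes surface, tetrahedralized and clipped to the
mask.  Grid-sampled scalars (BV/TV, DA) are carried to element centroids by
barycentric interpolation over the Delaunay triangulation of the sample
nodes, with nearest-node fallback (flagged) outside the sample hull — the
visualization carrier of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import Delaunay
from skimage.measure import marching_cubes

from ._utils import farthest_point_indices
from .core import Volume

__all__ = ["TetMesh", "tet_mesh", "interp_to_centroids"]


@dataclass
class TetMesh:
    """Tetrahedral mesh with optional per-element scalars.

    All tetrahedra are positively oriented with volume > 0; ``cell_data``
    maps scalar names to per-element arrays.
    """

    vertices: np.ndarray
    tetrahedra: np.ndarray
    cell_data: dict[str, np.ndarray] = field(default_factory=dict)
    extrapolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.tetrahedra = np.asarray(self.tetrahedra, dtype=int)
        if self.tetrahedra.max() >= len(self.vertices):
            raise ValueError("tetrahedron index out of range")

    @property
    def n_elements(self) -> int:
        return len(self.tetrahedra)

    def element_volumes(self) -> np.ndarray:
        v = self.vertices
        t = self.tetrahedra
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        c = v[t[:, 3]] - v[t[:, 0]]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def centroids(self) -> np.ndarray:
        return self.vertices[self.tetrahedra].mean(axis=1)

    def total_volume(self) -> float:
        return float(self.element_volumes().sum())


def tet_mesh(inner_mask: Volume, target_edge: float | None = None) -> TetMesh:
    """Delaunay mesh of a voxel mask (largest component; warns if several).

    Vertices are an interior lattice at ``target_edge`` spacing plus the
    marching-cubes boundary vertices downsampled to the same density; the
    Delaunay tetrahedra are clipped to those whose centroid lies inside the
    mask (nearest-voxel test).  Mesh volume tracks the voxel volume to a
    few percent at the default edge length.
    """
    if not inner_mask.data.any():
        raise ValueError("empty mask")
    vs = inner_mask.voxel_size
    if target_edge is None:
        target_edge = 4.0 * vs
    lbl, n = ndi.label(inner_mask.data)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        warnings.warn(f"mask has {n} components; meshing the largest", stacklevel=2)
        mask = lbl == keep
    else:
        mask = inner_mask.data

    step = max(1, int(round(target_edge / vs)))
    interior = np.zeros_like(mask)
    interior[::step, ::step, ::step] = True
    interior &= ndi.binary_erosion(mask, iterations=1)
    pts_in = (np.argwhere(interior) + 0.5) * vs

    verts, faces, _, _ = marching_cubes(mask.astype(np.float32), level=0.5)
    surf = (verts + 0.5) * vs
    n_surf = max(64, int(4.0 * mask.sum() * vs**3 / target_edge**3) // 4)
    if len(surf) > n_surf:
        surf = surf[farthest_point_indices(surf, n_surf, start=0)]

    points = np.vstack([pts_in, surf]) if len(pts_in) else surf
    tri = Delaunay(points)
    cent = points[tri.simplices].mean(axis=1)
    ci = inner_mask.indices(cent)
    inside = mask[ci[:, 0], ci[:, 1], ci[:, 2]]
    tets = tri.simplices[inside]

    # enforce positive orientation
    a = points[tets[:, 1]] - points[tets[:, 0]]
    b = points[tets[:, 2]] - points[tets[:, 0]]
    c = points[tets[:, 3]] - points[tets[:, 0]]
    vol6 = np.einsum("ij,ij->i", np.cross(a, b), c)
    flip = vol6 < 0
    tets[flip, 1], tets[flip, 2] = tets[flip, 2].copy(), tets[flip, 1].copy()
    tets = tets[np.abs(vol6) > 1e-12]
    return TetMesh(vertices=points, tetrahedra=tets)


def interp_to_centroids(
    node_positions: np.ndarray,
    node_values: dict[str, np.ndarray] | np.ndarray,
    mesh: TetMesh,
) -> TetMesh:
    """Linear (barycentric) interpolation of node scalars to element
    centroids.

    Values are interpolated over the Delaunay triangulation of the sample
    nodes; centroids outside the sample hull take the nearest node's value
    and are flagged in ``mesh.extrapolated``.  Requires >= 4 non-coplanar
    defined nodes.
    """
    pos = np.asarray(node_positions, dtype=float)
    if isinstance(node_values, np.ndarray):
        node_values = {"value": node_values}
    finite = np.ones(len(pos), dtype=bool)
    for v in node_values.values():
        finite &= np.isfinite(np.asarray(v, dtype=float))
    pos = pos[finite]
    if len(pos) < 4 or np.linalg.matrix_rank(pos - pos.mean(axis=0), tol=1e-9) < 3:
        raise ValueError("need >= 4 non-coplanar defined sample nodes")
    cents = mesh.centroids()
    out = TetMesh(
        vertices=mesh.vertices.copy(),
        tetrahedra=mesh.tetrahedra.copy(),
        cell_data=dict(mesh.cell_data),
    )
    flags = None
    for name, vals in node_values.items():
        vals = np.asarray(vals, dtype=float)[finite]
        lin = LinearNDInterpolator(pos, vals)
        near = NearestNDInterpolator(pos, vals)
        interp = lin(cents)
        nan = ~np.isfinite(interp)
        if nan.any():
            interp[nan] = near(cents[nan])
        out.cell_data[name] = interp
        flags = nan if flags is None else (flags | nan)
    out.extrapolated = flags
    return out
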