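"""Pointcloud correspondence, registration and scalar transfer."""

import numpy as np
import pytest
import trimesh

from bonemorph.gmm import gpa
from bonemorph.pointcloud import (
    CoherentPointDrift,
    canonical_cloud,
    closest_to_mean,
    cpd_register,
    match_pseudolandmarks,
    sample_pseudolandmarks,
    transfer_scalars,
    warp_to_mean,
)


@pytest.fixture(scope="module")
def sphere_mesh():
    return trimesh.creation.icosphere(subdivisions=3, radius=10.0)


def rotation(deg, axis=2):
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    R = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    R[i, i] = R[j, j] = c
    R[i, j], R[j, i] = -s, s
    return R


class TestPseudolandmarks:
    def test_even_coverage_on_sphere(self, sphere_mesh):
        pls = sample_pseudolandmarks(sphere_mesh, k=300, seed=0)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pls.points).query(pls.points, k=2)
        nn = d[:, 1]
        assert nn.std() / nn.mean() <= 0.15

    def test_seed_reproducible(self, sphere_mesh):
        a = sample_pseudolandmarks(sphere_mesh, k=200, seed=3)
        b = sample_pseudolandmarks(sphere_mesh, k=200, seed=3)
        np.testing.assert_array_equal(a.points, b.points)

    def test_matching_rotated_copy_recovers_correspondence(self):
        # asymmetric shape: a rotation search is only identifiable when the
        # surface has no rotational symmetry
        base = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        v = base.vertices * np.array([1.3, 1.0, 0.8])
        bump = 1.0 + 0.15 * np.tanh(v[:, 0] / 4.0) + 0.1 * np.tanh((v[:, 1] + v[:, 2]) / 5.0)
        mesh = trimesh.Trimesh(vertices=v * bump[:, None], faces=base.faces)
        ref = sample_pseudolandmarks(mesh, k=150, seed=0)
        rot = trimesh.Trimesh(vertices=mesh.vertices @ rotation(40).T, faces=mesh.faces)
        # same seeded sampling of the rotated mesh yields the rotated set
        tgt = sample_pseudolandmarks(rot, k=150, seed=0)
        matched = match_pseudolandmarks(ref, tgt)
        # matched points, rotated back, coincide with the reference set
        back = matched.points @ rotation(40)
        err = np.linalg.norm(back - ref.points, axis=1)
        assert np.median(err) < 0.5

    def test_too_small_mesh_rejected(self):
        tiny = trimesh.creation.icosphere(subdivisions=0)
        with pytest.raises(ValueError):
            sample_pseudolandmarks(tiny, k=10**6, oversample=1)


class TestClosestToMean:
    def test_ensemble_containing_its_mean(self, rng):
        base = rng.standard_normal((30, 3))
        coords = [base + 0.1 * rng.standard_normal((30, 3)) for _ in range(4)]
        coords.append(np.mean(coords, axis=0))
        pe = gpa(np.stack(coords))
        # the appended mean shape is closest to the consensus
        assert closest_to_mean(pe) == 4

    def test_central_specimen_beats_symmetric_outliers(self, rng):
        base = rng.standard_normal((30, 3))
        delta = rng.standard_normal((30, 3))
        pe = gpa(np.stack([base + delta, base - delta, base]))
        assert closest_to_mean(pe) == 2

    def test_order_invariance(self, rng):
        coords = np.stack([rng.standard_normal((20, 3)) for _ in range(5)])
        i = closest_to_mean(gpa(coords))
        perm = [4, 3, 2, 1, 0]
        j = closest_to_mean(gpa(coords[perm]))
        assert perm[j] == i


class TestWarpToMean:
    def test_identity_correspondence(self, sphere_mesh, rng):
        lms = sample_pseudolandmarks(sphere_mesh, k=60, seed=1).points
        out = warp_to_mean(sphere_mesh, lms, lms.copy())
        np.testing.assert_allclose(out.vertices, sphere_mesh.vertices, atol=1e-8)

    def test_affine_correspondence_exact(self, sphere_mesh, rng):
        A = np.diag([1.2, 0.9, 1.1])
        lms = sample_pseudolandmarks(sphere_mesh, k=60, seed=1).points
        out = warp_to_mean(sphere_mesh, lms, lms @ A)
        np.testing.assert_allclose(out.vertices, sphere_mesh.vertices @ A, atol=1e-8)

    def test_sphere_scale_recovered(self, sphere_mesh):
        lms = sample_pseudolandmarks(sphere_mesh, k=80, seed=2).points
        out = warp_to_mean(sphere_mesh, lms, 1.5 * lms)
        radii = np.linalg.norm(out.vertices, axis=1)
        assert radii.mean() == pytest.approx(15.0, rel=1e-6)


class TestCanonicalCloud:
    def test_cube_lattice_count(self):
        box = trimesh.creation.box(extents=(10.0, 10.0, 10.0))
        cloud = canonical_cloud(box, spacing=2.0)
        assert cloud.n_points == pytest.approx(216, rel=0.3)

    def test_points_inside_and_spacing(self, sphere_mesh):
        cloud = canonical_cloud(sphere_mesh, spacing=1.75)
        from bonemorph._utils import points_inside_mesh
        assert points_inside_mesh(sphere_mesh, cloud.points).all()
        nn = cloud.nn_spacing()
        assert (np.abs(nn - 1.75) <= 0.25 * 1.75).all()

    def test_open_mesh_rejected(self, sphere_mesh):
        open_mesh = sphere_mesh.copy()
        open_mesh.faces = open_mesh.faces[:-10]
        with pytest.raises(ValueError, match="watertight|closed"):
            canonical_cloud(open_mesh, spacing=2.0)


class TestCPD:
    def test_identity_rigid(self, rng):
        pts = rng.uniform(-5, 5, (200, 3))
        model, _ = cpd_register(pts, pts, mode="rigid", w=1e-9)
        assert np.abs(model.rotation_ - np.eye(3)).max() < 1e-6

    def test_planted_rotation_recovered(self, rng):
        pts = rng.uniform(-5, 5, (400, 3))
        R = rotation(15.0)
        tgt = pts @ R.T + np.array([0.3, -0.2, 0.1])
        model, _ = cpd_register(pts, tgt, mode="rigid", w=1e-9)
        Rd = model.rotation_ @ R.T
        angle = np.degrees(np.arccos(np.clip((np.trace(Rd) - 1) / 2, -1, 1)))
        assert angle <= 0.5

    def test_affine_recovered(self, rng):
        pts = rng.uniform(-5, 5, (300, 3))
        A = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        model, _ = cpd_register(pts, pts @ A.T + 1.0, mode="affine", w=1e-9)
        np.testing.assert_allclose(model.affine_, A, atol=1e-8)

    def test_deformable_recovers_smooth_warp(self):
        src = np.stack(
            np.meshgrid(*[np.arange(0, 10.0)] * 3, indexing="ij"), -1
        ).reshape(-1, 3)
        tgt = src + np.stack(
            [np.sin(src[:, 1] * 0.5), np.zeros(len(src)), np.cos(src[:, 0] * 0.5)], -1
        )
        model = CoherentPointDrift(mode="deformable", w=0.01, beta=2.0, lam=3.0).fit(src, tgt)
        rms = np.sqrt(((model.transformed_ - tgt) ** 2).sum(axis=1)).mean()
        assert rms < 0.25  # spacing units

    def test_objective_non_increasing(self, rng):
        pts = rng.uniform(-5, 5, (200, 3))
        tgt = pts @ rotation(10.0).T + 0.05 * rng.standard_normal((200, 3))
        for mode in ("rigid", "affine"):
            model, _ = cpd_register(pts, tgt, mode=mode, w=0.05)
            tr = model.nll_trace_
            assert all(tr[i + 1] <= tr[i] + 1e-6 * max(1, abs(tr[i])) for i in range(len(tr) - 1))

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            cpd_register(rng.standard_normal((5, 3)), rng.standard_normal((50, 3)))


class TestTransferScalars:
    def _cloud(self):
        from bonemorph.pointcloud import CanonicalCloud

        pts = np.stack(np.meshgrid(*[np.arange(1.0, 5.0)] * 3, indexing="ij"), -1).reshape(-1, 3)
        return CanonicalCloud(points=pts, spacing=1.0)

    def test_constant_field(self, rng):
        cloud = self._cloud()
        src = rng.uniform(0, 6, (100, 3))
        out, _ = transfer_scalars(src, np.full(100, 2.5), cloud)
        np.testing.assert_allclose(out, 2.5)

    def test_linear_field_exact_under_identity(self, rng):
        cloud = self._cloud()
        src = rng.uniform(-1, 7, (200, 3))
        vals = src @ np.array([1.0, -2.0, 0.5]) + 3.0
        out, flagged = transfer_scalars(src, vals, cloud)
        ref = cloud.points @ np.array([1.0, -2.0, 0.5]) + 3.0
        np.testing.assert_allclose(out[~flagged], ref[~flagged], atol=1e-9)

    def test_random_field_matches_barycentric_oracle(self, rng):
        from scipy.spatial import Delaunay

        cloud = self._cloud()
        src = rng.uniform(-1, 7, (80, 3))
        vals = rng.standard_normal(80)
        out, flagged = transfer_scalars(src, vals, cloud)
        tri = Delaunay(src)
        simp = tri.find_simplex(cloud.points)
        inside = simp >= 0
        T = tri.transform[simp[inside]]
        b = np.einsum("ijk,ik->ij", T[:, :3], cloud.points[inside] - T[:, 3])
        bary = np.column_stack([b, 1.0 - b.sum(axis=1)])
        oracle = (vals[tri.simplices[simp[inside]]] * bary).sum(axis=1)
        np.testing.assert_allclose(out[inside], oracle, atol=1e-10)

    def test_minimum_points(self):
        cloud = self._cloud()
        with pytest.raises(ValueError):
            transfer_scalars(np.zeros((3, 3)), np.zeros(3), cloud)
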