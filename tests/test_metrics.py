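"""Trabecular morphometry: grid, local BV/TV, MIL fabric, thickness maps."""

import numpy as np
import pytest

from bonemorph._utils import fibonacci_directions
from bonemorph.core import Volume
from bonemorph.metrics import (
    FabricSample,
    GridSpec,
    background_grid,
    da_from_eigs,
    fit_fabric_tensor,
    global_number,
    global_spacing,
    global_thickness,
    grid_samples,
    local_bvtv,
    local_thickness_map,
    mean_intercept_length,
    mil_tensor,
    samples_to_frame,
    summarize_specimen,
)

from conftest import face_count_mil


@pytest.fixture(scope="module")
def full_inner(plate_phantom):
    vol, _ = plate_phantom
    return Volume(np.ones(vol.shape, dtype=bool), vol.voxel_size)


class TestBackgroundGrid:
    def test_node_count_arithmetic(self):
        """10 mm cube at 2.5 mm spacing: 4 nodes per axis starting at half
        spacing (0.25 per unit cell convention)."""
        mask = Volume(np.ones((100, 100, 100), dtype=bool), 0.1)
        nodes = background_grid(mask, GridSpec(node_spacing=2.5, sphere_diameter=5.0))
        per_axis = np.unique(nodes[:, 0])
        assert len(per_axis) == 4
        assert len(nodes) == 4**3

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            background_grid(Volume(np.zeros((64, 64, 64), dtype=bool), 0.05))

    def test_node_clipping_matches_enumeration(self, plate_phantom, full_inner):
        """Kept nodes equal the brute-force rule: distance from node to the
        nearest inner voxel <= sphere radius."""
        from scipy import ndimage as ndi

        vol, _ = plate_phantom
        inner = np.zeros(vol.shape, dtype=bool)
        inner[20:50, 20:50, 20:50] = True
        iv = Volume(inner, vol.voxel_size)
        grid = GridSpec(node_spacing=0.5, sphere_diameter=1.0)
        nodes = background_grid(iv, grid)
        # oracle: enumerate the full lattice and test each node directly
        extent = iv.physical_extent()
        axes = [np.arange(0.25, e, 0.5) for e in extent]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        allnodes = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        d = ndi.distance_transform_edt(~inner) * vol.voxel_size
        idx = iv.indices(allnodes)
        keep = d[idx[:, 0], idx[:, 1], idx[:, 2]] <= 0.5
        assert len(nodes) == keep.sum()

    def test_small_mask_collapses_to_centroid(self):
        mask = np.zeros((64, 64, 64), dtype=bool)
        mask[30:34, 30:34, 30:34] = True
        with pytest.warns(UserWarning, match="centroid"):
            nodes = background_grid(Volume(mask, 0.05), GridSpec(node_spacing=2.5, sphere_diameter=5.0))
        assert nodes.shape == (1, 3)


class TestLocalBVTV:
    def test_all_bone_sphere(self):
        vol = Volume(np.ones((64, 64, 64), dtype=bool), 0.05)
        assert local_bvtv(vol, vol, np.array([1.6, 1.6, 1.6]), 1.0) == 1.0

    def test_bone_free_sphere(self, full_inner):
        empty = Volume(np.zeros((64, 64, 64), dtype=bool), 0.05)
        assert local_bvtv(empty, full_inner, np.array([1.6, 1.6, 1.6]), 1.0) == 0.0

    def test_plate_phantom_value(self, plate_phantom, full_inner):
        vol, truth = plate_phantom
        v = local_bvtv(vol, full_inner, np.array([1.6, 1.6, 1.6]), 2.0)
        assert v == pytest.approx(truth.true_bvtv, abs=0.02)

    def test_sphere_outside_mask_undefined(self, plate_phantom):
        vol, _ = plate_phantom
        inner = np.zeros(vol.shape, dtype=bool)
        inner[:10, :10, :10] = True
        v = local_bvtv(vol, Volume(inner, vol.voxel_size), np.array([3.0, 3.0, 3.0]), 0.5)
        assert np.isnan(v)

    def test_translation_invariance_by_period(self, plate_phantom, full_inner):
        """Periodic phantom: moving the sphere by whole periods along the
        plate normal leaves local BV/TV unchanged."""
        vol, _ = plate_phantom
        # centres on exact voxel centres so rounding is robust
        c0 = np.array([1.625, 1.625, 1.225])
        c1 = c0 + np.array([0.0, 0.0, 0.8])  # one period (16 voxels)
        v0 = local_bvtv(vol, full_inner, c0, 1.6)
        v1 = local_bvtv(vol, full_inner, c1, 1.6)
        assert v0 == pytest.approx(v1, abs=1e-12)


class TestDAFromEigs:
    @pytest.mark.parametrize(
        "eigs,expected",
        [((2.0, 2.0, 2.0), 0.0), ((2.0, 1.5, 1.0), 0.5), ((4.0, 3.0, 2.0), 0.5)],
    )
    def test_values(self, eigs, expected):
        assert da_from_eigs(*eigs) == pytest.approx(expected)

    def test_zero_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            da_from_eigs(1.0, 1.0, 0.0)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            da_from_eigs(1.0, 2.0, 0.5)


class TestMILFabric:
    def test_mil_agrees_with_face_count_oracle(self, iso_gaussian_phantom):
        vol, _ = iso_gaussian_phantom
        dirs = fibonacci_directions(128)
        mil = mean_intercept_length(vol.data, dirs, 1.0, line_spacing_vox=2.0)
        oracle = face_count_mil(vol.data, dirs)
        rel = np.abs(mil / oracle - 1.0)
        assert np.median(rel) < 0.02
        assert rel.max() < 0.05

    def test_axis_direction_exact(self, plate_phantom):
        """Along a coordinate axis the crossing count is exact, so MIL
        matches the per-column transition count oracle."""
        vol, _ = plate_phantom
        dirs = np.array([[0.0, 0.0, 1.0]])
        mil = mean_intercept_length(vol.data, dirs, vol.voxel_size, line_spacing_vox=1.0)
        crossings = (vol.data[:, :, 1:] != vol.data[:, :, :-1]).sum()
        oracle = vol.data.size * vol.voxel_size / crossings
        assert mil[0] == pytest.approx(oracle, rel=0.02)

    def test_plate_minor_axis_and_da(self, plate_phantom):
        vol, truth = plate_phantom
        fs = mil_tensor(vol, np.array([1.6, 1.6, 1.6]), GridSpec(node_spacing=1.6, sphere_diameter=2.5))
        assert fs.defined
        assert fs.da >= 0.5
        minor = fs.eigenvectors[:, 2]
        angle = np.degrees(np.arccos(abs(minor @ truth.true_fabric_axis)))
        assert angle <= 10.0

    def test_isotropic_da_small(self, iso_gaussian_phantom):
        vol, _ = iso_gaussian_phantom
        dirs = fibonacci_directions(128)
        mil = mean_intercept_length(vol.data, dirs, vol.voxel_size, line_spacing_vox=2.0)
        _, lam, _ = fit_fabric_tensor(dirs, mil)
        assert da_from_eigs(*lam) <= 0.05

    def test_rot90_spectrum_invariance(self):
        """90-degree rotation about x: normalized eigenvalue spectrum
        preserved within 0.02 and the dominant axis follows the rotation
        (checked on a stretched field, where all three eigenvalues are
        well determined)."""
        from bonemorph.phantoms import PhantomSpec, make_gaussian_phantom

        vol, _ = make_gaussian_phantom(
            0.3, (1, 1, 3),
            PhantomSpec(lattice_kind="gaussian_field", dims=(64, 64, 64), rng_seed=5),
        )
        dirs = fibonacci_directions(128)
        mil0 = mean_intercept_length(vol.data, dirs, 1.0, line_spacing_vox=2.0)
        _, lam0, _ = fit_fabric_tensor(dirs, mil0)
        rot = np.rot90(vol.data, k=1, axes=(1, 2)).copy()
        mil1 = mean_intercept_length(rot, dirs, 1.0, line_spacing_vox=2.0)
        _, lam1, vec1 = fit_fabric_tensor(dirs, mil1)
        np.testing.assert_allclose(lam0 / lam0.sum(), lam1 / lam1.sum(), atol=0.02)
        # elongation axis z maps to y under this rotation
        assert abs(vec1[1, 0]) > np.cos(np.radians(10))

    def test_sphere_without_both_phases_undefined(self):
        vol = Volume(np.ones((64, 64, 64), dtype=bool), 0.05)
        fs = mil_tensor(vol, np.array([1.6, 1.6, 1.6]), GridSpec(node_spacing=1.6, sphere_diameter=2.0))
        assert not fs.defined


class TestGlobalMetrics:
    def test_plate_thickness_spacing_number(self, plate_phantom, full_inner):
        vol, truth = plate_phantom
        # averaging region away from the half-open volume edges
        # averaging region spans fully enclosed plates and marrow slabs only
        roi = np.zeros(vol.shape, dtype=bool)
        roi[:, :, 4:52] = True
        th = global_thickness(vol, roi)
        sp = global_spacing(vol, full_inner, roi)
        assert th == pytest.approx(truth.true_thickness, abs=vol.voxel_size)
        assert sp == pytest.approx(truth.true_spacing, abs=vol.voxel_size)
        assert global_number(0.2, 0.6) == pytest.approx(1.25)

    def test_thickness_map_slab_oracle(self):
        """An isolated slab of width w has local thickness exactly w."""
        data = np.zeros((32, 32, 32), dtype=bool)
        data[:, :, 10:16] = True
        th = local_thickness_map(data, 1.0)
        assert th[:, :, 12].max() == pytest.approx(6.0)
        assert (th[~data] == 0).all()

    def test_empty_masks_rejected(self):
        empty = Volume(np.zeros((32, 32, 32), dtype=bool), 0.05)
        with pytest.raises(ValueError):
            global_thickness(empty)


class TestSummaries:
    def _sample(self, bvtv, da):
        lam = np.array([1.2, 1.0, 1.2 * (1 - da)])[np.argsort([0, 1, 2])]
        lam = np.sort(np.array([1.2, 1.0, 1.2 * (1.0 - da)]))[::-1]
        return FabricSample(
            position=np.zeros(3), bvtv=bvtv, defined=True,
            eigenvalues=lam, eigenvectors=np.eye(3), da=da,
        )

    def test_single_sample_zero_sd(self):
        s = summarize_specimen([self._sample(0.2, 0.1)], th=0.2, sp=0.6)
        assert s.bvtv_sd_pct == 0.0
        assert s.bvtv_mean_pct == pytest.approx(20.0)
        assert s.tb_n == pytest.approx(1.25)

    def test_two_sample_mean(self):
        s = summarize_specimen(
            [self._sample(0.1, 0.1), self._sample(0.3, 0.3)], th=0.2, sp=0.6
        )
        assert s.bvtv_mean_pct == pytest.approx(20.0)
        assert s.da_mean == pytest.approx(0.2)

    def test_summary_matches_brute_force(self, plate_phantom):
        vol, _ = plate_phantom
        inner = Volume(np.ones(vol.shape, dtype=bool), vol.voxel_size)
        grid = GridSpec(node_spacing=1.6, sphere_diameter=1.6, n_mil_directions=32)
        samples = grid_samples(vol, inner, grid)
        summary = summarize_specimen(samples, th=0.2, sp=0.6)
        defined = [s for s in samples if s.defined]
        bv = np.array([s.bvtv for s in defined])
        da = np.array([s.da for s in defined])
        assert summary.bvtv_mean_pct == 100.0 * bv.mean()
        assert summary.da_sd == da.std()
        assert summary.n_samples == len(defined)

    def test_all_undefined_rejected(self):
        s = FabricSample(position=np.zeros(3), bvtv=float("nan"), defined=False)
        with pytest.raises(ValueError):
            summarize_specimen([s], th=0.1, sp=0.2)

    def test_frame_round_trip(self, plate_phantom):
        vol, _ = plate_phantom
        inner = Volume(np.ones(vol.shape, dtype=bool), vol.voxel_size)
        samples = grid_samples(vol, inner, GridSpec(node_spacing=1.6, sphere_diameter=1.6, n_mil_directions=32))
        df = samples_to_frame(samples)
        assert {"x", "y", "z", "bvtv", "da", "lambda1"} <= set(df.columns)
        assert len(df) == sum(s.defined for s in samples)
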