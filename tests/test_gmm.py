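"""Geometric morphometrics: template, mirror, projection, GPA, sliding,
shape/form PCA and the conditional statistical battery."""

import numpy as np
import pytest
from scipy import stats as sps

from bonemorph.gmm import (
    CURVE_DESIGN,
    GeneralizedProcrustes,
    assign_age_class,
    dunn_test,
    form_pca,
    gpa,
    make_synthetic_template,
    mirror,
    pc_stats,
    project_template,
    shape_pca,
    slide_semilandmarks,
    _optimal_rotation,
)
from bonemorph.phantoms import LandmarkEnsemble, ShapeSeriesSpec, make_ontogenetic_series
from bonemorph.tps import TPSWarp, bending_energy


def random_rigid(rng, scale=True):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    s = rng.uniform(0.5, 3.0) if scale else 1.0
    t = rng.normal(0, 10, 3)
    return lambda x: s * x @ q.T + t


class TestTemplate:
    def test_composition(self, template):
        counts = template.counts()
        assert counts == {"fixed": 8, "curve": 45, "surface": 175}
        assert template.n_points == 228

    def test_curve_counts_follow_design(self, template):
        for (a, b, n), (ca, cb, idx) in zip(CURVE_DESIGN, template.curves):
            assert len(idx) == n
            assert (ca, cb) == (a - 1, b - 1)

    def test_per_curve_count_pattern(self, template):
        assert [len(idx) for _, _, idx in template.curves] == [9, 3, 9, 3, 6, 6, 5, 4]

    def test_points_on_surface(self, template):
        from bonemorph._utils import closest_on_surface

        _, d, _ = closest_on_surface(template.mesh, template.points)
        assert d.max() < 1e-6


class TestMirror:
    def test_double_mirror_identity(self, template):
        np.testing.assert_allclose(mirror(mirror(template.points)), template.points)

    def test_centroid_size_preserved(self, template, rng):
        from bonemorph.gmm import centroid_size

        cfg = template.points + rng.normal(0, 0.1, template.points.shape)
        assert centroid_size(mirror(cfg)) == pytest.approx(centroid_size(cfg))

    def test_chirality_flips(self, template):
        """Signed volume of any landmark tetrad changes sign."""
        tet = template.points[[0, 3, 5, 7]]
        mt = mirror(template.points)[[0, 3, 5, 7]]

        def signed_vol(p):
            return np.linalg.det(p[1:] - p[0])

        assert signed_vol(tet) == pytest.approx(-signed_vol(mt))

    def test_mesh_mirror_preserves_winding_volume(self, template):
        m = mirror(template.mesh)
        assert m.volume == pytest.approx(template.mesh.volume, rel=1e-6)


class TestProjectTemplate:
    def test_identity_projection(self, template):
        proj = project_template(template, template.mesh, template.points[:8])
        np.testing.assert_allclose(proj, template.points, atol=1e-9)

    def test_projected_points_on_target_surface(self, template):
        from bonemorph._utils import closest_on_surface

        target = template.mesh.copy()
        target.vertices = target.vertices * np.array([1.3, 1.1, 0.9])
        fixed = template.points[:8] * np.array([1.3, 1.1, 0.9])
        proj = project_template(template, target, fixed)
        _, d, _ = closest_on_surface(target, proj)
        assert d.max() < 1e-6

    def test_sphere_to_ellipsoid_matches_closest_point_oracle(self, template):
        """Affine target: TPS of 8 fixed pairs reproduces the affine map
        exactly, so projection reduces to closest-point of the affinely
        warped template."""
        from bonemorph._utils import closest_on_surface

        A = np.diag([1.4, 1.0, 0.8])
        target = template.mesh.copy()
        target.vertices = target.vertices @ A
        proj = project_template(template, target, template.points[:8] @ A)
        oracle = closest_on_surface(target, template.points @ A)[0]
        semi = template.slide_class != "fixed"
        np.testing.assert_allclose(proj[semi], oracle[semi], atol=1e-6)

    def test_degenerate_fixed_landmarks_rejected(self, template):
        bad = np.zeros((8, 3))
        bad[:, 0] = np.arange(8)
        with pytest.raises(ValueError):
            project_template(template, template.mesh, bad)


class TestGPA:
    def test_two_identical_shapes_distance_zero(self, rng):
        cfg = rng.standard_normal((20, 3))
        pe = gpa(np.stack([cfg, cfg.copy()]))
        assert pe.procrustes_distances().max() < 1e-12

    def test_similarity_invariance(self, rng):
        ens = make_ontogenetic_series(
            ShapeSeriesSpec(n_per_group=(4, 4, 4, 4), n_landmarks=30, noise_sd=0.02, rng_seed=5)
        )
        pe = gpa(ens)
        coords2 = np.stack([random_rigid(rng)(c) for c in ens.coords])
        pe2 = gpa(coords2)
        R = _optimal_rotation(pe2.consensus, pe.consensus)
        assert np.abs(pe2.aligned @ R - pe.aligned).max() < 1e-8

    def test_two_shape_closed_form(self, rng):
        """Two triangles: the GPA consensus solution matches the classical
        ordinary-Procrustes alignment of one onto the other."""
        a = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        b = np.array([[0.0, 0, 0], [1, 0.2, 0], [-0.1, 1.1, 0]])
        pe = gpa(np.stack([a, b]))
        # oracle: align unit-size b onto unit-size a by SVD directly
        ac = a - a.mean(0)
        bc = b - b.mean(0)
        ac /= np.linalg.norm(ac)
        bc /= np.linalg.norm(bc)
        R = _optimal_rotation(bc, ac)
        d_oracle = np.linalg.norm(bc @ R - ac)
        d_gpa = np.linalg.norm(pe.aligned[1] - pe.aligned[0])
        assert d_gpa == pytest.approx(d_oracle, abs=1e-8)

    def test_unit_centroid_size_and_centering(self, rng):
        ens = make_ontogenetic_series(
            ShapeSeriesSpec(n_per_group=(3, 3, 3, 3), n_landmarks=15, rng_seed=2)
        )
        pe = gpa(ens)
        for cfg in pe.aligned:
            assert np.abs(cfg.mean(axis=0)).max() < 1e-12
            assert np.linalg.norm(cfg) == pytest.approx(1.0)
        np.testing.assert_allclose(pe.consensus, pe.aligned.mean(axis=0), atol=1e-9)

    def test_collinear_rejected(self):
        line = np.zeros((5, 3))
        line[:, 0] = np.arange(5)
        with pytest.raises(ValueError, match="collinear"):
            gpa(np.stack([line, line + 1.0]))

    def test_transform_aligns_new_configuration(self, rng):
        ens = make_ontogenetic_series(
            ShapeSeriesSpec(n_per_group=(3, 3, 3, 3), n_landmarks=15, rng_seed=2)
        )
        model = GeneralizedProcrustes().fit(ens)
        moved = random_rigid(rng)(ens.coords[0])
        aligned = model.transform(moved)
        np.testing.assert_allclose(aligned, model.aligned_[0], atol=1e-8)


class TestSliding:
    def test_energy_non_increasing_and_fixed_immobile(self, template, rng):
        coords = np.stack(
            [
                template.points @ (np.eye(3) + 0.05 * rng.standard_normal((3, 3))).T
                + 0.01 * rng.standard_normal(template.points.shape)
                for _ in range(5)
            ]
        )
        ens = LandmarkEnsemble(coords=coords, groups=np.array(["a"] * 5))
        slid, trace = slide_semilandmarks(ens, template, n_sweeps=3)
        assert all(trace[i + 1] <= trace[i] + 1e-9 for i in range(len(trace) - 1))
        fixed = template.slide_class == "fixed"
        np.testing.assert_array_equal(slid.coords[:, fixed], ens.coords[:, fixed])

    def test_specimen_equal_to_reference_does_not_move(self, template):
        coords = np.stack([template.points.copy() for _ in range(3)])
        ens = LandmarkEnsemble(coords=coords, groups=np.array(["a"] * 3))
        slid, _ = slide_semilandmarks(ens, template, n_sweeps=1)
        # identical specimens: bending energy already zero, sliding is a no-op
        assert np.abs(slid.coords - coords).max() < 1e-6

    def test_sliding_reduces_procrustes_spread(self, template, rng):
        """Tangential jitter on two copies of one shape: sliding removes
        spurious (non-shape) variation, shrinking the Procrustes distance."""
        base = template.points
        coords = []
        for _ in range(2):
            jit = base.copy()
            semi = template.slide_class != "fixed"
            jit[semi] += 0.01 * rng.standard_normal(jit[semi].shape)
            coords.append(jit)
        ens = LandmarkEnsemble(coords=np.stack(coords), groups=np.array(["a", "b"]))
        pre = gpa(ens.coords)
        d_pre = np.linalg.norm(pre.aligned[0] - pre.aligned[1])
        slid, _ = slide_semilandmarks(ens, template, n_sweeps=3)
        post = gpa(slid.coords)
        d_post = np.linalg.norm(post.aligned[0] - post.aligned[1])
        assert d_post <= d_pre


class TestPCA:
    def test_variance_fractions_sum_to_one(self, rng):
        ens = make_ontogenetic_series(
            ShapeSeriesSpec(n_per_group=(3, 3, 3, 3), n_landmarks=15, noise_sd=0.02, rng_seed=3)
        )
        pe = gpa(ens)
        for res in (shape_pca(pe), form_pca(pe)):
            assert res.variance_fractions.sum() == pytest.approx(1.0)
            assert (res.variance_fractions >= 0).all()

    def test_scores_invariant_to_global_rotation(self, rng):
        ens = make_ontogenetic_series(
            ShapeSeriesSpec(n_per_group=(3, 3, 3, 3), n_landmarks=15, noise_sd=0.02, rng_seed=3)
        )
        pe = gpa(ens)
        res = shape_pca(pe)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        pe_rot = type(pe)(
            aligned=pe.aligned @ q.T,
            centroid_sizes=pe.centroid_sizes,
            consensus=pe.consensus @ q.T,
            groups=pe.groups,
        )
        res_rot = shape_pca(pe_rot)
        np.testing.assert_allclose(
            np.abs(res_rot.scores[:, :3]), np.abs(res.scores[:, :3]), atol=1e-8
        )

    def test_form_pc1_tracks_log_cs_exactly_at_zero_noise(self):
        ens = make_ontogenetic_series(
            ShapeSeriesSpec(n_per_group=(5, 5, 5, 5), n_landmarks=30, noise_sd=0.0, rng_seed=1)
        )
        pe = gpa(ens)
        res = form_pca(pe)
        r, _ = sps.pearsonr(res.scores[:, 0], np.log(pe.centroid_sizes))
        assert abs(r) >= 0.999

    def test_form_r_decreases_with_noise(self):
        rs = []
        for noise in (0.0, 0.03, 0.1):
            ens = make_ontogenetic_series(
                ShapeSeriesSpec(n_per_group=(5, 5, 5, 5), n_landmarks=30, noise_sd=noise, rng_seed=1)
            )
            pe = gpa(ens)
            res = form_pca(pe)
            r, _ = sps.pearsonr(res.scores[:, 0], np.log(pe.centroid_sizes))
            rs.append(abs(r))
        assert rs[0] > rs[1] > rs[2]

    def test_too_few_specimens_rejected(self, rng):
        with pytest.raises(ValueError):
            shape_pca(gpa(np.stack([rng.standard_normal((10, 3))] * 2)))


class TestPCStats:
    def test_identical_groups_all_pairs_nonsignificant(self, rng):
        scores = rng.standard_normal((40, 3))
        groups = np.repeat(["a", "b", "c", "d"], 10)
        rep = pc_stats(scores, groups, rng.standard_normal(40))
        for entry in rep["per_pc"]:
            for pair in entry["pairwise"]:
                assert pair["p_adj"] > 0.05

    def test_pearson_of_variable_with_itself(self, rng):
        scores = rng.standard_normal((24, 3))
        groups = np.repeat(["a", "b", "c", "d"], 6)
        rep = pc_stats(scores, groups, scores[:, 0])
        assert rep["per_pc"][0]["pearson_logcs"]["r"] == pytest.approx(1.0)

    def test_nonparametric_branch_on_skewed_scores(self, rng):
        scores = np.column_stack([rng.exponential(1.0, 40) ** 3, rng.standard_normal((40, 2))])
        groups = np.repeat(["a", "b", "c", "d"], 10)
        rep = pc_stats(scores, groups, rng.standard_normal(40))
        assert rep["per_pc"][0]["branch"] == "nonparametric"
        assert "kruskal" in rep["per_pc"][0]

    def test_constant_scores_flagged(self, rng):
        scores = np.column_stack([np.ones(20), rng.standard_normal((20, 2))])
        groups = np.repeat(["a", "b"], 10)
        rep = pc_stats(scores, groups, rng.standard_normal(20))
        assert "flag" in rep["per_pc"][0]

    def test_group_size_preconditions(self, rng):
        with pytest.raises(ValueError):
            pc_stats(rng.standard_normal((3, 3)), np.array(["a", "a", "b"]), np.arange(3.0))

    def test_dunn_matches_kruskal_direction(self, rng):
        """A strongly shifted group is flagged against both others."""
        x = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(6, 1, 10)])
        g = np.repeat(["a", "b", "c"], 10)
        out = dunn_test(x, g)
        sig = out[out["p_adj"] < 0.05]
        flagged = {frozenset((r.group_a, r.group_b)) for r in sig.itertuples()}
        assert frozenset(("a", "c")) in flagged and frozenset(("b", "c")) in flagged
        assert frozenset(("a", "b")) not in flagged


class TestAgeClasses:
    @pytest.mark.parametrize(
        "age,label",
        [
            (0.9, "Neonates and infants"),
            (1.0, "Neonates and infants"),
            (2.0, "Toddlers"),
            (3.05, "Early childhood"),
            (6.5, "Late childhood"),
            (10.0, "Late childhood"),
        ],
    )
    def test_assignment(self, age, label):
        assert assign_age_class(age) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            assign_age_class(10.5)
        with pytest.raises(ValueError):
            assign_age_class(-0.1)


class TestTPS:
    def test_affine_reproduced_exactly(self, rng):
        x = rng.standard_normal((15, 3))
        A = rng.standard_normal((3, 3))
        b = rng.standard_normal(3)
        warp = TPSWarp(x, x @ A.T + b)
        p = rng.standard_normal((40, 3))
        np.testing.assert_allclose(warp(p), p @ A.T + b, atol=1e-10)
        assert abs(bending_energy(x, x @ A.T + b)) < 1e-10

    def test_bending_energy_nonnegative(self, rng):
        x = rng.standard_normal((15, 3))
        for _ in range(5):
            y = x + 0.3 * rng.standard_normal((15, 3))
            assert bending_energy(x, y) >= -1e-10
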