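"""External-shape analysis: template, sliding semilandmarks, GPA, PCA, stats.

The external workflow mirrors standard 3D geometric morphometrics: a
template of fixed anatomical landmarks plus curve and surface semilandmarks
is projected onto each specimen, semilandmarks slide along their tangent
spaces to minimize thin-plate-spline bending energy against recursive
updates of the Procrustes consensus, configurations are superimposed by
generalized Procrustes analysis (translation + rotation, scaled to unit
centroid size), and shape variation is summarized by PCA in shape space
(Procrustes coordinates) or form space (coordinates augmented with ln
centroid size).  Group structure on the leading PCs is tested with the
usual conditional battery: Shapiro and Levene gate ANOVA/Tukey versus
Kruskal-Wallis/Dunn, and Pearson's r quantifies allometry against ln CS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from ._utils import closest_on_surface, farthest_point_indices
from .phantoms import LandmarkEnsemble
from .tps import TPSWarp, bending_energy_matrix

__all__ = [
    "Template",
    "make_synthetic_template",
    "mirror",
    "project_template",
    "GeneralizedProcrustes",
    "ProcrustesEnsemble",
    "gpa",
    "SemilandmarkSlider",
    "slide_semilandmarks",
    "PCAResult",
    "shape_pca",
    "form_pca",
    "pc_stats",
    "dunn_test",
    "assign_age_class",
    "AGE_CLASS_BINS",
]

# age-class partition of postnatal age in years: upper edges and labels
AGE_CLASS_BINS: list[tuple[float, str]] = [
    (1.0, "Neonates and infants"),
    (3.0, "Toddlers"),
    (6.0, "Early childhood"),
    (10.0, "Late childhood"),
]

#: semilandmark counts per curve, keyed by (start, end) fixed-landmark label
CURVE_DESIGN: list[tuple[int, int, int]] = [
    (1, 2, 9),
    (1, 3, 3),
    (3, 2, 9),
    (3, 4, 3),
    (4, 5, 6),
    (5, 6, 6),
    (6, 4, 5),
    (7, 8, 4),
]
N_FIXED = 8
N_CURVE = sum(c for _, _, c in CURVE_DESIGN)  # 45
N_SURFACE = 175
N_TOTAL = N_FIXED + N_CURVE + N_SURFACE  # 228


def assign_age_class(age: float) -> str:
    """Age-at-death (years) to locomotor age class."""
    if age < 0:
        raise ValueError("age must be >= 0")
    for upper, label in AGE_CLASS_BINS:
        if age <= upper:
            return label
    raise ValueError(f"age {age} outside the studied range (0-10 years)")


@dataclass
class Template:
    """Landmark template: fixed landmarks, curve and surface semilandmarks.

    ``slide_class`` holds 'fixed' | 'curve' | 'surface' per point;
    ``curve_id`` gives the curve index for curve points (-1 otherwise), and
    ``curves`` lists, per curve, the (start_fixed, end_fixed, point indices
    in order) so each curve runs between its two named fixed landmarks.
    ``mesh`` is the template surface (trimesh.Trimesh) when available.
    """

    points: np.ndarray
    slide_class: np.ndarray
    curve_id: np.ndarray
    curves: list[tuple[int, int, np.ndarray]]
    mesh: object | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        n = len(self.points)
        if len(self.slide_class) != n or len(self.curve_id) != n:
            raise ValueError("per-point annotations must match point count")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def counts(self) -> dict[str, int]:
        sc = np.asarray(self.slide_class)
        return {k: int((sc == k).sum()) for k in ("fixed", "curve", "surface")}


def _slerp_arc(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    """n interior points along the great-circle-ish arc between two points
    on a star-shaped surface (interpolate direction, then radius)."""
    ta = np.linspace(0.0, 1.0, n + 2)[1:-1]
    ra, rb = np.linalg.norm(a), np.linalg.norm(b)
    ua, ub = a / ra, b / rb
    dots = np.clip(ua @ ub, -1.0, 1.0)
    omega = np.arccos(dots)
    if omega < 1e-9:
        return np.outer(ta, b - a) + a
    sin_o = np.sin(omega)
    dirs = (
        np.sin((1 - ta))[:, None] * 0.0
        + (np.sin((1 - ta) * omega) / sin_o)[:, None] * ua
        + (np.sin(ta * omega) / sin_o)[:, None] * ub
    )
    radii = (1 - ta) * ra + ta * rb
    return dirs * radii[:, None]


def make_synthetic_template(
    seed: int = 0, ellipsoid_axes: tuple[float, float, float] = (1.0, 0.75, 0.55)
) -> Template:
    """Build the 228-point template on a synthetic ellipsoidal surface.

    Stand-in for interactive digitization on a real bone surface: 8 fixed
    landmarks spread over an ellipsoid, 8 curves with the standard per-curve
    semilandmark counts running between their named fixed landmarks, and 175
    surface semilandmarks by farthest-point sampling.
    """
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=4)
    mesh.apply_scale(1.0)
    mesh.vertices = mesh.vertices * np.asarray(ellipsoid_axes)
    verts = mesh.vertices.view(np.ndarray)

    fixed_idx = farthest_point_indices(verts, N_FIXED, start=0)
    fixed = verts[fixed_idx]

    points = [fixed]
    slide_class = ["fixed"] * N_FIXED
    curve_id = [-1] * N_FIXED
    curves = []
    nxt = N_FIXED
    for ci, (a, b, n) in enumerate(CURVE_DESIGN):
        arc = _slerp_arc(fixed[a - 1], fixed[b - 1], n)
        # snap interior points to the surface
        arc = closest_on_surface(mesh, arc)[0]
        points.append(arc)
        slide_class += ["curve"] * n
        curve_id += [ci] * n
        curves.append((a - 1, b - 1, np.arange(nxt, nxt + n)))
        nxt += n

    # surface semilandmarks: FPS over vertices, away from existing points
    existing = np.vstack(points)
    pool_idx = farthest_point_indices(verts, N_SURFACE + N_FIXED, start=1)
    chosen = []
    for i in pool_idx:
        if len(chosen) == N_SURFACE:
            break
        if np.linalg.norm(verts[i] - existing, axis=1).min() > 1e-6:
            chosen.append(i)
    surf = verts[np.asarray(chosen[:N_SURFACE])]
    points.append(surf)
    slide_class += ["surface"] * len(surf)
    curve_id += [-1] * len(surf)

    pts = np.vstack(points)
    assert len(pts) == N_TOTAL, f"template has {len(pts)} points"
    return Template(
        points=pts,
        slide_class=np.asarray(slide_class),
        curve_id=np.asarray(curve_id),
        curves=curves,
        mesh=mesh,
    )


def mirror(obj, plane_normal: int = 0):
    """Reflect a configuration (k, 3), an ensemble, or a mesh across the
    coordinate plane orthogonal to ``plane_normal``.  Involutive; preserves
    centroid size; flips chirality."""
    M = np.eye(3)
    M[plane_normal, plane_normal] = -1.0
    if isinstance(obj, LandmarkEnsemble):
        return LandmarkEnsemble(
            coords=obj.coords @ M,
            groups=obj.groups.copy(),
            ids=list(obj.ids),
            slide_class=obj.slide_class,
            true_log_cs=obj.true_log_cs,
        )
    if hasattr(obj, "vertices") and hasattr(obj, "faces"):
        out = obj.copy()
        out.vertices = out.vertices @ M
        out.faces = out.faces[:, ::-1]  # keep outward orientation
        return out
    return np.asarray(obj, dtype=float) @ M


def project_template(
    template: Template, target_mesh, target_fixed: np.ndarray
) -> np.ndarray:
    """Transfer the template onto a target surface.

    A TPS warp from the template's fixed landmarks to the target's fixed
    landmarks carries every semilandmark over; warped points are then
    projected to the nearest point on the target surface.  Returns the full
    (n_points, 3) configuration with fixed landmarks at their given target
    positions.
    """
    target_fixed = np.asarray(target_fixed, dtype=float)
    fixed_mask = template.slide_class == "fixed"
    src = template.points[fixed_mask]
    if target_fixed.shape != src.shape:
        raise ValueError("need one target position per fixed landmark")
    centred = target_fixed - target_fixed.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max())) < 3:
        raise ValueError("degenerate (coplanar) target fixed-landmark set")
    warp = TPSWarp(src, target_fixed)
    warped = warp(template.points)
    out = warped.copy()
    semi = ~fixed_mask
    out[semi] = closest_on_surface(target_mesh, warped[semi])[0]
    out[fixed_mask] = target_fixed
    return out


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------


@dataclass
class ProcrustesEnsemble:
    """GPA-aligned configurations: centred, unit centroid size, rotated to
    the consensus (the mean of the aligned shapes)."""

    aligned: np.ndarray  # (n, k, 3)
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray  # (k, 3)
    groups: np.ndarray | None = None
    ids: list[str] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    def procrustes_distances(self) -> np.ndarray:
        d = self.aligned - self.consensus[None]
        return np.sqrt((d**2).sum(axis=(1, 2)))


def centroid_size(config: np.ndarray) -> float:
    c = config - config.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R minimizing ||a @ R - b|| (proper, via SVD)."""
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, 1.0, d])
    return u @ s @ vt


class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Partial generalized Procrustes superimposition (sklearn-style).

    ``fit`` iterates rotation-to-consensus until the consensus stabilizes;
    ``transform`` aligns configurations to the fitted consensus.  Scaling is
    to unit centroid size only (no shape-space projection), matching the
    translate/rotate/CS=1 convention.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: np.ndarray | LandmarkEnsemble, y=None):
        ens = X if isinstance(X, LandmarkEnsemble) else None
        coords = ens.coords if ens is not None else np.asarray(X, dtype=float)
        if coords.ndim != 3 or coords.shape[0] < 2:
            raise ValueError("need >= 2 configurations of shape (k, 3)")
        n, k, _ = coords.shape
        if k < 3:
            raise ValueError("need >= 3 landmarks")
        cs = np.empty(n)
        unit = np.empty_like(coords)
        for i, cfg in enumerate(coords):
            c = cfg - cfg.mean(axis=0)
            s = np.sqrt((c**2).sum())
            if s <= 0:
                raise ValueError(f"specimen {i} has zero centroid size")
            if np.linalg.matrix_rank(c, tol=1e-12 * s) < 2:
                raise ValueError(f"specimen {i} is collinear")
            cs[i] = s
            unit[i] = c / s
        aligned = unit.copy()
        consensus = aligned[0].copy()
        for _ in range(self.max_iter):
            for i in range(n):
                aligned[i] = unit[i] @ _optimal_rotation(unit[i], consensus)
            new_consensus = aligned.mean(axis=0)
            new_consensus /= np.linalg.norm(new_consensus)
            if np.linalg.norm(new_consensus - consensus) < self.tol:
                consensus = new_consensus
                break
            consensus = new_consensus
        # final pass against the converged consensus; the stored consensus
        # is the plain mean of the aligned shapes (rotation alignment is
        # scale-invariant, so the unit-normalized iterate gives the same
        # rotations)
        for i in range(n):
            aligned[i] = unit[i] @ _optimal_rotation(unit[i], consensus)
        self.consensus_ = aligned.mean(axis=0)
        self.aligned_ = aligned
        self.centroid_sizes_ = cs
        self.groups_ = ens.groups if ens is not None else None
        self.ids_ = list(ens.ids) if ens is not None else []
        return self

    def transform(self, X: np.ndarray | LandmarkEnsemble) -> np.ndarray:
        coords = X.coords if isinstance(X, LandmarkEnsemble) else np.asarray(X)
        single = coords.ndim == 2
        coords = coords[None] if single else coords
        out = np.empty_like(coords, dtype=float)
        for i, cfg in enumerate(coords):
            c = cfg - cfg.mean(axis=0)
            c = c / np.sqrt((c**2).sum())
            out[i] = c @ _optimal_rotation(c, self.consensus_)
        return out[0] if single else out

    def to_ensemble(self) -> ProcrustesEnsemble:
        return ProcrustesEnsemble(
            aligned=self.aligned_,
            centroid_sizes=self.centroid_sizes_,
            consensus=self.consensus_,
            groups=self.groups_,
            ids=self.ids_,
        )


def gpa(ensemble: LandmarkEnsemble | np.ndarray) -> ProcrustesEnsemble:
    """Generalized Procrustes superimposition (functional wrapper)."""
    return GeneralizedProcrustes().fit(ensemble).to_ensemble()


# ---------------------------------------------------------------------------
# sliding semilandmarks
# ---------------------------------------------------------------------------


def _tangent_frames(
    config: np.ndarray, template: Template, meshes: object | None
) -> list[tuple[int, np.ndarray]]:
    """Per sliding point: (index, tangent basis (d, 3)) — one tangent vector
    for curve points (along the curve polyline), two for surface points
    (normal to the local outward direction)."""
    frames: list[tuple[int, np.ndarray]] = []
    sc = template.slide_class
    for ci, (a, b, idx) in enumerate(template.curves):
        chain = np.concatenate([[a], idx, [b]])
        for j, i in enumerate(idx):
            prev_p = config[chain[j]]
            next_p = config[chain[j + 2]]
            t = next_p - prev_p
            nrm = np.linalg.norm(t)
            t = t / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
            frames.append((int(i), t[None, :]))
    surf_idx = np.where(sc == "surface")[0]
    centre = config.mean(axis=0)
    if meshes is not None:
        # normals from the nearest surface point
        _, _, tri = closest_on_surface(meshes, config[surf_idx])
        normals = meshes.face_normals[tri]
    else:
        normals = config[surf_idx] - centre
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    for i, nrm in zip(surf_idx, normals):
        a = np.array([1.0, 0.0, 0.0]) if abs(nrm[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(nrm, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(nrm, e1)
        frames.append((int(i), np.stack([e1, e2])))
    return frames


class SemilandmarkSlider(BaseEstimator):
    """Slide semilandmarks to minimize TPS bending energy to the consensus.

    Each sweep: (1) compute the bending-energy matrix of the current
    reference (the template on the first sweep, the recursive Procrustes
    consensus thereafter); (2) per specimen, solve the least-squares slide
    of curve points along their tangent and surface points in their tangent
    plane; (3) reproject slid points onto the specimen surface (or the
    radial stand-in when no mesh is available); (4) damp the step if
    reprojection raised the energy, guaranteeing a non-increasing energy
    trace; (5) update the consensus by GPA.  Fixed landmarks never move.
    """

    def __init__(
        self,
        n_sweeps: int = 3,
        tol: float = 1e-8,
        damping_tries: int = 4,
        reference: str = "template-then-consensus",
    ):
        self.n_sweeps = n_sweeps
        self.tol = tol
        self.damping_tries = damping_tries
        self.reference = reference

    @staticmethod
    def _slide_once(
        config: np.ndarray,
        B: np.ndarray,
        frames: list[tuple[int, np.ndarray]],
    ) -> np.ndarray:
        """Unconstrained tangent-space minimizer of the bending energy of
        the map reference -> config."""
        idx = []
        vecs = []
        for i, basis in frames:
            for d in range(basis.shape[0]):
                idx.append(i)
                vecs.append(basis[d])
        idx = np.asarray(idx)
        V = np.asarray(vecs)  # (m, 3)
        m = len(idx)
        # energy E(t) = sum_d (y_d + S_d t)^T B (y_d + S_d t): the normal
        # system over slide parameters t factorizes into the bending matrix
        # restricted to sliding points times the tangent-vector Gram matrix
        By = B @ config  # (k, 3)
        rhs = -(V * By[idx]).sum(axis=1)
        G = B[np.ix_(idx, idx)] * (V @ V.T)
        t = np.linalg.lstsq(G + 1e-12 * np.eye(m), rhs, rcond=None)[0]
        out = config.copy()
        np.add.at(out, idx, t[:, None] * V)
        return out

    def fit(
        self,
        ensemble: LandmarkEnsemble,
        template: Template,
        meshes: list | None = None,
    ):
        coords = ensemble.coords.copy()
        n = len(coords)
        self.energy_trace_ = []
        fixed_mask = template.slide_class == "fixed"
        reference = template.points
        for sweep in range(self.n_sweeps):
            B = bending_energy_matrix(reference)
            energies = np.empty(n)
            for i in range(n):
                cfg = coords[i]
                mesh_i = meshes[i] if meshes is not None else None
                frames = _tangent_frames(cfg, template, mesh_i)
                e0 = float(np.einsum("id,ij,jd->", cfg, B, cfg))
                prop = self._slide_once(cfg, B, frames)
                prop = self._reproject(prop, template, mesh_i, cfg)
                e1 = float(np.einsum("id,ij,jd->", prop, B, prop))
                tries = 0
                while e1 > e0 and tries < self.damping_tries:
                    prop = 0.5 * (prop + cfg)
                    prop[fixed_mask] = cfg[fixed_mask]
                    e1 = float(np.einsum("id,ij,jd->", prop, B, prop))
                    tries += 1
                if e1 > e0:
                    prop, e1 = cfg, e0  # refuse a worsening step
                coords[i] = prop
                energies[i] = e1
            self.energy_trace_.append(float(energies.sum()))
            pe = gpa(coords)
            reference = pe.consensus * np.mean(
                [centroid_size(c) for c in coords]
            )  # consensus at data scale for the next TPS reference
            if (
                sweep > 0
                and abs(self.energy_trace_[-2] - self.energy_trace_[-1])
                <= self.tol * max(1.0, self.energy_trace_[-2])
            ):
                break
        if len(self.energy_trace_) == self.n_sweeps and (
            self.energy_trace_[0] - self.energy_trace_[-1]
        ) > self.tol * max(1.0, self.energy_trace_[0]) * 10:
            pass  # converged well enough; trace retained for inspection
        self.slid_ = LandmarkEnsemble(
            coords=coords,
            groups=ensemble.groups,
            ids=list(ensemble.ids),
            slide_class=template.slide_class,
            true_log_cs=ensemble.true_log_cs,
        )
        return self

    @staticmethod
    def _reproject(
        config: np.ndarray, template: Template, mesh, original: np.ndarray
    ) -> np.ndarray:
        out = config.copy()
        semi = template.slide_class != "fixed"
        if mesh is not None:
            out[semi] = closest_on_surface(mesh, config[semi])[0]
        else:
            # radial reprojection onto the star-shaped surface implied by the
            # original configuration (keeps each point at its original radius)
            centre = original.mean(axis=0)
            v = config[semi] - centre
            r_orig = np.linalg.norm(original[semi] - centre, axis=1)
            nv = np.linalg.norm(v, axis=1)
            nv[nv == 0] = 1.0
            out[semi] = centre + v / nv[:, None] * r_orig[:, None]
        out[~semi] = config[~semi]
        return out


def slide_semilandmarks(
    ensemble: LandmarkEnsemble,
    template: Template,
    meshes: list | None = None,
    n_sweeps: int = 3,
) -> tuple[LandmarkEnsemble, list[float]]:
    """Functional wrapper over :class:`SemilandmarkSlider`; returns the slid
    ensemble and the per-sweep total bending-energy trace."""
    sl = SemilandmarkSlider(n_sweeps=n_sweeps).fit(ensemble, template, meshes)
    return sl.slid_, sl.energy_trace_


# ---------------------------------------------------------------------------
# PCA in shape and form space
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # (n_features, n_pcs)
    variance_fractions: np.ndarray
    space: str
    mean: np.ndarray


def _pca(X: np.ndarray, space: str) -> PCAResult:
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| positive per PC
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    return PCAResult(
        scores=scores, loadings=vt.T, variance_fractions=frac, space=space, mean=mean
    )


def shape_pca(pe: ProcrustesEnsemble) -> PCAResult:
    """Covariance PCA of the flattened Procrustes coordinates."""
    X = pe.aligned.reshape(pe.n_specimens, -1)
    return _pca(X, "shape")


def form_pca(pe: ProcrustesEnsemble, log_cs: np.ndarray | None = None) -> PCAResult:
    """Form-space PCA: Procrustes coordinates augmented with ln CS."""
    lcs = np.log(pe.centroid_sizes) if log_cs is None else np.asarray(log_cs)
    X = np.column_stack([pe.aligned.reshape(pe.n_specimens, -1), lcs])
    return _pca(X, "form")


# ---------------------------------------------------------------------------
# statistics on PC scores
# ---------------------------------------------------------------------------


def dunn_test(values: np.ndarray, groups: np.ndarray, p_adjust: str = "holm"):
    """Dunn's post-hoc test of pairwise group differences on ranks.

    z_ij = (mean rank_i - mean rank_j) / sqrt(S (1/n_i + 1/n_j)) with the
    tie-corrected variance S = (N(N+1) - T/(N-1)) / 12; two-sided p values
    adjusted across all pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    N = len(values)
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (N - 1)
    S = (N * (N + 1) - tie_term) / 12.0
    rows = []
    pvals = []
    for a, b in combinations(labels, 2):
        ra = ranks[groups == a].mean()
        rb = ranks[groups == b].mean()
        na, nb = (groups == a).sum(), (groups == b).sum()
        z = (ra - rb) / np.sqrt(S * (1.0 / na + 1.0 / nb))
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
        pvals.append(p)
    adj = multipletests(pvals, method=p_adjust)[1]
    out = pd.DataFrame(rows)
    out["p_adj"] = adj
    return out


def pc_stats(
    scores: np.ndarray,
    groups: np.ndarray,
    log_cs: np.ndarray,
    n_pcs: int = 3,
    alpha: float = 0.05,
) -> dict:
    """The conditional test battery on the leading PC scores.

    Per PC: Shapiro normality and Levene homoscedasticity gate the branch —
    ANOVA with Tukey's HSD when both hold at ``alpha``, Kruskal-Wallis with
    Dunn's test otherwise — plus Pearson's r of the PC against ln CS.
    Returns a nested dict mirroring a pairwise-comparison report.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2 or min((groups == g).sum() for g in labels) < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    report: dict = {"alpha": alpha, "per_pc": []}
    for j in range(min(n_pcs, scores.shape[1])):
        x = scores[:, j]
        entry: dict = {"pc": j + 1}
        if np.ptp(x) <= 0:
            entry["flag"] = "constant scores; tests undefined"
            report["per_pc"].append(entry)
            continue
        by_group = [x[groups == g] for g in labels]
        sw_w, sw_p = sps.shapiro(x)
        lv_w, lv_p = sps.levene(*by_group)
        entry["shapiro"] = {"W": float(sw_w), "p": float(sw_p)}
        entry["levene"] = {"W": float(lv_w), "p": float(lv_p)}
        parametric = (sw_p > alpha) and (lv_p > alpha)
        entry["branch"] = "parametric" if parametric else "nonparametric"
        if parametric:
            f, p = sps.f_oneway(*by_group)
            entry["anova"] = {"F": float(f), "p": float(p)}
            tk = sps.tukey_hsd(*by_group)
            pairs = []
            for ia, ib in combinations(range(len(labels)), 2):
                pairs.append(
                    {
                        "group_a": labels[ia],
                        "group_b": labels[ib],
                        "diff": float(np.mean(by_group[ib]) - np.mean(by_group[ia])),
                        "p_adj": float(tk.pvalue[ia, ib]),
                    }
                )
            entry["pairwise"] = pairs
        else:
            h, p = sps.kruskal(*by_group)
            entry["kruskal"] = {"H": float(h), "p": float(p)}
            dn = dunn_test(x, groups)
            entry["pairwise"] = dn.to_dict("records")
        r, rp = sps.pearsonr(x, log_cs)
        entry["pearson_logcs"] = {"r": float(r), "p": float(rp)}
        report["per_pc"].append(entry)
    return report
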