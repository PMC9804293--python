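"""Ground-truthed phantoms for every stage of the pipeline.

Real whole-bone microCT series of growing bones are rarely shareable, so the
test substrate of this package is synthetic: periodic trabecular lattices and
thresholded Gaussian random fields with known bone volume fraction, strut
thickness/spacing and fabric axis; grayscale "scans" with a cortical shell,
partial-volume blur, noise and optional sediment; ontogenetic landmark series
with a planted allometric axis; and smooth scalar-field ensembles on a point
cloud with a planted group effect.

Every generator is a pure function of its spec and seed: rebuilding with the
same arguments reproduces the phantom and its stored ground truth bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from ._utils import farthest_point_indices, rng_from
from .core import CompartmentSet, Volume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "ImagingSpec",
    "ShapeSeriesSpec",
    "LandmarkEnsemble",
    "PointCloudEnsemble",
    "make_lattice_phantom",
    "make_gaussian_phantom",
    "add_cortex_and_grayscale",
    "make_ontogenetic_series",
    "make_scalar_ensemble",
    "AGE_CLASS_SIZES",
]

#: Study design of the emulated ontogenetic series: four locomotor age
#: classes (neonates/infants, toddlers, early childhood, late childhood)
#: with 12 + 25 + 21 + 12 = 70 specimens.
AGE_CLASS_SIZES: dict[str, int] = {
    "Neonates and infants": 12,
    "Toddlers": 25,
    "Early childhood": 21,
    "Late childhood": 12,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a voxel phantom.

    lattice_kind:
        ``plate``  — parallel plates normal to ``axis``;
        ``rod``    — square rods along ``axis``;
        ``rod3``   — union of three orthogonal rod families (isotropic);
        ``gaussian_field`` — thresholded smoothed Gaussian noise.
    thickness / spacing are in mm; anisotropy of the Gaussian field enters
    through per-axis smoothing stretch (see :func:`make_gaussian_phantom`).
    """

    lattice_kind: str = "plate"
    voxel_size: float = 0.05
    dims: tuple[int, int, int] = (128, 128, 128)
    thickness: float = 0.2
    spacing: float = 0.6
    axis: int = 2
    shell_thickness: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_kind not in ("plate", "rod", "rod3", "gaussian_field"):
            raise ValueError(f"unknown lattice_kind {self.lattice_kind!r}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be > 0")
        if min(self.dims) < 32:
            raise ValueError("dims must be >= 32 voxels per axis")
        if self.lattice_kind != "gaussian_field" and not self.thickness < self.spacing:
            raise ValueError("thickness must be < spacing on every axis")
        if self.shell_thickness < 0:
            raise ValueError("shell_thickness must be >= 0")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic (or measured, for Gaussian fields) truth of a phantom.

    ``fabric_axis_kind`` records how ``true_fabric_axis`` relates to the MIL
    fabric tensor: for plates the distinguished axis is the plate normal (the
    *minor* fabric eigenvector), for rods and stretched fields the elongation
    axis (the *major* eigenvector); ``undefined`` marks isotropic phantoms.
    ``true_da`` is None where no closed form exists.
    """

    true_bvtv: float
    true_thickness: float | None = None
    true_spacing: float | None = None
    true_fabric_axis: np.ndarray | None = None
    fabric_axis_kind: str = "undefined"
    true_da: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_bvtv <= 1.0:
            raise ValueError("true_bvtv must lie in [0, 1]")
        if self.true_fabric_axis is not None:
            a = np.asarray(self.true_fabric_axis, dtype=float)
            if not np.isclose(np.linalg.norm(a), 1.0):
                raise ValueError("fabric axis must have unit norm")
            object.__setattr__(self, "true_fabric_axis", a)


@dataclass(frozen=True)
class ImagingSpec:
    """Grayscale imaging model: phase means, PSF blur, additive noise.

    ``gray_means`` maps phase name (air, bone, sediment) to mean gray value;
    ``psf_sigma`` is the Gaussian point-spread sigma in mm; ``noise_sd`` the
    additive Gaussian noise SD in gray units; ``sediment_fraction`` the
    fraction of non-bone voxels occupied by sediment blobs.
    """

    gray_means: dict[str, float] = field(
        default_factory=lambda: {"air": 20.0, "bone": 200.0, "sediment": 110.0}
    )
    psf_sigma: float = 0.0
    noise_sd: float = 0.0
    sediment_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        vals = list(self.gray_means.values())
        if len(set(vals)) != len(vals):
            raise ValueError("phase gray means must be distinct")
        if self.psf_sigma < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma and noise_sd must be >= 0")
        if not 0.0 <= self.sediment_fraction < 1.0:
            raise ValueError("sediment_fraction must lie in [0, 1)")


def _axis_coord(spec: PhantomSpec, axis: int) -> np.ndarray:
    """Physical coordinate (mm) of voxel centres along one axis, broadcast
    to the full grid."""
    n = spec.dims[axis]
    c = (np.arange(n) + 0.5) * spec.voxel_size
    shape = [1, 1, 1]
    shape[axis] = n
    return c.reshape(shape)


def make_lattice_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Voxelize a periodic plate or rod lattice with analytic ground truth.

    Plates: bone where the coordinate along ``spec.axis`` falls in the first
    ``thickness`` of each ``thickness + spacing`` period; BV/TV = t/(t+s).
    Rods: square cross-section rods along ``spec.axis``; BV/TV = (t/(t+s))^2.
    ``rod3``: union of three orthogonal rod families; BV/TV by
    inclusion–exclusion, fabric axis undefined (cubic symmetry, DA ~ 0).
    """
    if spec.lattice_kind not in ("plate", "rod", "rod3"):
        raise ValueError("make_lattice_phantom requires a lattice kind")
    t, s = spec.thickness, spec.spacing
    period = t + s
    axes = [0, 1, 2]
    unit = np.zeros(3)
    unit[spec.axis] = 1.0

    def in_band(axis: int) -> np.ndarray:
        return (_axis_coord(spec, axis) % period) < t

    if spec.lattice_kind == "plate":
        bone = np.broadcast_to(in_band(spec.axis), spec.dims).copy()
        truth = GroundTruth(
            true_bvtv=t / period,
            true_thickness=t,
            true_spacing=s,
            true_fabric_axis=unit,
            fabric_axis_kind="minor",
            true_da=None,
        )
    elif spec.lattice_kind == "rod":
        trans = [a for a in axes if a != spec.axis]
        bone = np.broadcast_to(
            in_band(trans[0]) & in_band(trans[1]), spec.dims
        ).copy()
        truth = GroundTruth(
            true_bvtv=(t / period) ** 2,
            true_thickness=t,
            true_spacing=s,
            true_fabric_axis=unit,
            fabric_axis_kind="major",
            true_da=None,
        )
    else:  # rod3
        fams = []
        for ax in axes:
            trans = [a for a in axes if a != ax]
            fams.append(in_band(trans[0]) & in_band(trans[1]))
        bone = np.broadcast_to(fams[0] | fams[1] | fams[2], spec.dims).copy()
        # |A ∪ B ∪ C| on one period cell: 3 t^2 p − 3 t^3 + t^3
        bvtv = (3 * t**2 * period - 2 * t**3) / period**3
        truth = GroundTruth(
            true_bvtv=bvtv,
            true_thickness=t,
            true_spacing=s,
            true_fabric_axis=None,
            fabric_axis_kind="undefined",
            true_da=0.0,
        )
    return Volume(bone, spec.voxel_size), truth


def make_gaussian_phantom(
    target_bvtv: float,
    stretch: tuple[float, float, float] = (1.0, 1.0, 1.0),
    spec: PhantomSpec | None = None,
    base_sigma_vox: float = 3.0,
) -> tuple[Volume, GroundTruth]:
    """Thresholded Gaussian random field with a target bone fraction.

    White noise is smoothed with per-axis sigma ``base_sigma_vox * stretch``
    and thresholded at the quantile that realizes ``target_bvtv``.  Unequal
    stretch elongates structures along the most-smoothed axis, which becomes
    the dominant (major) MIL axis; its exact DA has no closed form, so truth
    carries the axis only.
    """
    if not 0.0 < target_bvtv < 1.0:
        raise ValueError("target_bvtv must lie in (0, 1)")
    if spec is None:
        spec = PhantomSpec(lattice_kind="gaussian_field")
    if spec.lattice_kind != "gaussian_field":
        spec = replace(spec, lattice_kind="gaussian_field")
    rng = rng_from(spec.rng_seed)
    field_ = rng.standard_normal(spec.dims)
    sigma = base_sigma_vox * np.asarray(stretch, dtype=float)
    field_ = ndi.gaussian_filter(field_, sigma=sigma, mode="wrap")
    thresh = np.quantile(field_, 1.0 - target_bvtv)
    bone = field_ > thresh
    realized = float(bone.mean())
    stretch_arr = np.asarray(stretch, dtype=float)
    if np.allclose(stretch_arr, stretch_arr[0]):
        axis, kind, da = None, "undefined", None
    else:
        unit = np.zeros(3)
        unit[int(np.argmax(stretch_arr))] = 1.0
        axis, kind, da = unit, "major", None
    truth = GroundTruth(
        true_bvtv=realized,
        true_fabric_axis=axis,
        fabric_axis_kind=kind,
        true_da=0.0 if kind == "undefined" else da,
    )
    return Volume(bone, spec.voxel_size), truth


def _envelope(spec: PhantomSpec, margin_vox: int = 2) -> np.ndarray:
    """Centered ellipsoidal bone envelope filling the grid minus a margin."""
    dims = np.asarray(spec.dims, dtype=float)
    semi = dims / 2.0 - margin_vox
    centre = (dims - 1) / 2.0
    grids = np.ogrid[: spec.dims[0], : spec.dims[1], : spec.dims[2]]
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return rho2 <= 1.0


def add_cortex_and_grayscale(
    trab: Volume, spec: PhantomSpec, img: ImagingSpec
) -> tuple[Volume, CompartmentSet]:
    """Wrap a trabecular mask in a cortical shell and image it.

    A solid shell of ``spec.shell_thickness`` mm is laid on the inside of an
    ellipsoidal envelope; trabecular bone is clipped to the endosteal
    interior.  Phases (air / bone / sediment) are mapped to their gray means,
    blurred by the PSF and degraded with Gaussian noise.  The returned
    :class:`~bonemorph.core.CompartmentSet` is the ground truth for the
    segmentation and compartment stages.
    """
    shell_vox = spec.shell_thickness / spec.voxel_size
    env = _envelope(spec)
    margin = 2
    if shell_vox > min(spec.dims) / 2.0 - margin:
        raise ValueError("shell thicker than the volume margin")
    if shell_vox > 0:
        dist_in = ndi.distance_transform_edt(env)
        interior = dist_in > shell_vox
        cortex = env & ~interior
    else:
        interior = env
        cortex = np.zeros(spec.dims, dtype=bool)
    trab_in = trab.data & interior
    bone = cortex | trab_in

    rng = rng_from(img.rng_seed)
    gray = np.full(spec.dims, img.gray_means["air"], dtype=np.float64)
    if img.sediment_fraction > 0:
        noise = ndi.gaussian_filter(rng.standard_normal(spec.dims), sigma=2.0)
        nonbone = ~bone
        cut = np.quantile(noise[nonbone], 1.0 - img.sediment_fraction)
        sed = nonbone & (noise > cut)
        gray[sed] = img.gray_means.get("sediment", img.gray_means["air"])
    gray[bone] = img.gray_means["bone"]
    if img.psf_sigma > 0:
        gray = ndi.gaussian_filter(gray, sigma=img.psf_sigma / spec.voxel_size)
    if img.noise_sd > 0:
        gray = gray + rng.normal(0.0, img.noise_sd, size=spec.dims)

    vs = spec.voxel_size
    truth = CompartmentSet(
        outer=Volume(env, vs),
        inner=Volume(interior, vs),
        cortical=Volume(cortex, vs),
        trabecular=Volume(trab_in, vs),
        meta={"bone": bone},
    )
    return Volume(gray, vs), truth


# ---------------------------------------------------------------------------
# landmark series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapeSeriesSpec:
    """Design of a synthetic ontogenetic landmark series.

    Configurations are built as ``CS * (mean + allometric_vector * ln CS +
    noise)`` with centroid size CS drawn per group on an increasing schedule,
    so shape changes linearly with log size along one planted axis — the
    simplest model of ontogenetic allometry.  Group labels follow the four
    locomotor age classes of the emulated study design.
    """

    n_per_group: tuple[int, ...] = (12, 25, 21, 12)
    n_landmarks: int = 228
    mean_config: np.ndarray | None = None
    allometric_vector: np.ndarray | None = None
    allometric_scale: float = 0.1
    cs_group_means: tuple[float, ...] = (20.0, 26.2, 34.3, 45.0)
    cs_log_sd: float = 0.12
    noise_sd: float = 0.0
    rigid_motion: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != len(AGE_CLASS_SIZES):
            raise ValueError("one group size per age class required")
        if len(self.cs_group_means) != len(self.n_per_group):
            raise ValueError("one CS mean per group required")
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("need >= 2 specimens per group")


@dataclass
class LandmarkEnsemble:
    """A set of landmark configurations with group labels.

    coords has shape (n_specimens, k, 3) in mm; ``true_log_cs`` stores the
    planted log centroid sizes where the ensemble is synthetic.
    """

    coords: np.ndarray
    groups: np.ndarray
    ids: list[str] = field(default_factory=list)
    slide_class: np.ndarray | None = None
    true_log_cs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n, k, 3)")
        if not self.ids:
            self.ids = [f"spec{i:03d}" for i in range(len(self.coords))]

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]


def _default_mean_config(k: int, rng: np.random.Generator) -> np.ndarray:
    """Well-spread unit-scale configuration: farthest-point subsample of a
    dense random ellipsoid surface cloud."""
    n_dense = max(8 * k, 2000)
    u = rng.standard_normal((n_dense, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = u * np.array([1.0, 0.75, 0.55])
    idx = farthest_point_indices(pts, k, start=0)
    cfg = pts[idx]
    cfg -= cfg.mean(axis=0)
    cfg /= np.linalg.norm(cfg)
    return cfg


def make_ontogenetic_series(spec: ShapeSeriesSpec) -> LandmarkEnsemble:
    """Generate an ontogenetic landmark series with a planted allometric axis.

    The allometric displacement field is a fixed (seed-reproducible) unit
    vector scaled by ``allometric_scale``; at ``noise_sd == 0`` the form-space
    PC1 of the series correlates perfectly with ln CS by construction.
    """
    rng = rng_from(spec.rng_seed)
    k = spec.n_landmarks
    mean = (
        np.asarray(spec.mean_config, dtype=float)
        if spec.mean_config is not None
        else _default_mean_config(k, rng)
    )
    if mean.shape != (k, 3):
        raise ValueError("mean_config must have shape (n_landmarks, 3)")
    centred = mean - mean.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) mean configuration")
    if spec.allometric_vector is not None:
        allo = np.asarray(spec.allometric_vector, dtype=float)
        if allo.shape != (k, 3):
            raise ValueError("allometric_vector must match the configuration")
    else:
        allo = rng.standard_normal((k, 3))
        allo -= allo.mean(axis=0)
        allo /= np.linalg.norm(allo)
        allo *= spec.allometric_scale

    labels = list(AGE_CLASS_SIZES)
    coords, groups, log_cs_all = [], [], []
    for g, n in enumerate(spec.n_per_group):
        log_cs = rng.normal(np.log(spec.cs_group_means[g]), spec.cs_log_sd, size=n)
        for lc in log_cs:
            shape = mean + allo * lc
            if spec.noise_sd > 0:
                shape = shape + rng.normal(0.0, spec.noise_sd, size=(k, 3))
            cfg = np.exp(lc) * shape
            if spec.rigid_motion:
                q = rng.standard_normal((3, 3))
                qr, _ = np.linalg.qr(q)
                if np.linalg.det(qr) < 0:
                    qr[:, 0] *= -1
                cfg = cfg @ qr.T + rng.normal(0.0, 5.0, size=3)
            coords.append(cfg)
            groups.append(labels[g])
            log_cs_all.append(lc)
    return LandmarkEnsemble(
        coords=np.stack(coords),
        groups=np.asarray(groups),
        true_log_cs=np.asarray(log_cs_all),
    )


# ---------------------------------------------------------------------------
# scalar-field ensembles on a point cloud
# ---------------------------------------------------------------------------


@dataclass
class PointCloudEnsemble:
    """Smooth scalar fields over a shared point cloud, two groups.

    ``values`` has shape (n_specimens, n_points); ``effect_mask`` marks the
    points where group B was shifted (the planted truth).
    """

    points: np.ndarray
    values: np.ndarray
    groups: np.ndarray
    spacing: float
    smoothness_fwhm: float
    effect_mask: np.ndarray | None = None

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _ball_lattice(radius: float, spacing: float) -> np.ndarray:
    ax = np.arange(-radius, radius + spacing / 2, spacing)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    return pts[np.linalg.norm(pts, axis=1) <= radius]


def make_scalar_ensemble(
    n_per_group: tuple[int, int] = (10, 10),
    effect_region: tuple[tuple[float, float, float], float] | None = None,
    effect_size: float = 0.0,
    smoothness_fwhm: float = 3.0,
    seed: int = 0,
    cloud_radius: float = 8.0,
    spacing: float = 1.0,
) -> PointCloudEnsemble:
    """Generate unit-variance smooth Gaussian fields on a ball lattice.

    Each specimen is white noise smoothed to the stated FWHM (in spacing
    units) on an enclosing grid, sampled at the lattice points and rescaled
    to unit variance.  Group B is then shifted by ``effect_size`` (in field
    SD units) strictly inside ``effect_region`` — a (centre, radius) ball —
    leaving a sharp boundary so "outside the region" is well defined.
    """
    if min(n_per_group) < 3:
        raise ValueError("need >= 3 specimens per group")
    rng = rng_from(seed)
    pts = _ball_lattice(cloud_radius, spacing)
    pad = int(np.ceil(2 * smoothness_fwhm)) + 2
    n_side = int(round(2 * cloud_radius / spacing)) + 1 + 2 * pad
    sigma = smoothness_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    # variance of white noise after Gaussian smoothing (theoretical):
    smooth_sd = (4.0 * np.pi * sigma**2) ** (-3.0 / 4.0)
    idx = np.round((pts + cloud_radius) / spacing).astype(int) + pad

    n_total = sum(n_per_group)
    values = np.empty((n_total, len(pts)))
    for i in range(n_total):
        f = ndi.gaussian_filter(
            rng.standard_normal((n_side, n_side, n_side)), sigma=sigma
        )
        values[i] = f[idx[:, 0], idx[:, 1], idx[:, 2]] / smooth_sd

    groups = np.asarray(["A"] * n_per_group[0] + ["B"] * n_per_group[1])
    if effect_region is not None and effect_size != 0.0:
        centre, radius = effect_region
        mask = np.linalg.norm(pts - np.asarray(centre), axis=1) <= radius
        values[groups == "B"] += effect_size * mask
    else:
        mask = np.zeros(len(pts), dtype=bool)
    return PointCloudEnsemble(
        points=pts,
        values=values,
        groups=groups,
        spacing=spacing,
        smoothness_fwhm=smoothness_fwhm,
        effect_mask=mask,
    )
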