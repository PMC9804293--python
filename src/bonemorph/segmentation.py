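"""Windowed two-stage clustering segmentation of gray-value volumes.

The volume is tiled into overlapping subvolumes; inside each tile, K-means
centroids (k-means++, seeded) initialize a fuzzy C-means run on the gray
values, and the per-voxel class memberships are blended across tile overlaps
with a separable triangular weight window.  Bone is taken as the class with
the highest mean gray value.  An optional white top-hat prefilter enhances
thin bright structures when bone/sediment contrast is poor.

Gray values are quantized to a fixed number of histogram bins before
clustering: with a single intensity feature this is lossless for practical
purposes and makes the tile loop cheap.  Clustering operates on relative
distances only, so the output is invariant to affine rescaling of the input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.morphology import ball, white_tophat as _sk_white_tophat
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .core import Volume

__all__ = ["ClusterConfig", "white_tophat", "mia_segment", "MIAClusterSegmenter"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterConfig:
    """Parameters of the windowed clustering segmentation."""

    n_classes: int = 3
    subvolume_edge: int = 64
    overlap_fraction: float = 0.25
    fuzzifier: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    n_bins: int = 1024
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.overlap_fraction < 0.5:
            raise ValueError("overlap_fraction must lie in [0, 0.5)")
        if not self.fuzzifier > 1.0:
            raise ValueError("fuzzifier m must be > 1")


def white_tophat(gray: Volume, radius: float) -> Volume:
    """White top-hat: input minus its opening by a ball of physical radius.

    Removes background structures wider than the ball while preserving
    bright features thinner than twice the radius; the output is nonnegative.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0 mm")
    r_vox = radius / gray.voxel_size
    if r_vox < 1.0:
        raise ValueError("top-hat radius is smaller than one voxel")
    out = _sk_white_tophat(gray.data.astype(np.float64), footprint=ball(int(round(r_vox))))
    return gray.like(np.maximum(out, 0.0))


def _fcm_1d(
    centers: np.ndarray,
    bin_values: np.ndarray,
    bin_weights: np.ndarray,
    m: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Weighted fuzzy C-means on scalar data; returns sorted centers."""
    c = np.sort(centers.astype(np.float64))
    expo = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        d = np.abs(bin_values[:, None] - c[None, :])
        d = np.maximum(d, 1e-12 * (np.ptp(bin_values) + 1e-300))
        inv = d ** (-expo)
        u = inv / inv.sum(axis=1, keepdims=True)
        um = (u**m) * bin_weights[:, None]
        new_c = (um * bin_values[:, None]).sum(axis=0) / um.sum(axis=0)
        new_c = np.sort(new_c)
        if np.max(np.abs(new_c - c)) <= tol * (np.ptp(bin_values) + 1e-300):
            c = new_c
            break
        c = new_c
    return c


def _memberships(values: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Fuzzy memberships of raw values to given centers, shape (..., k)."""
    d = np.abs(values[..., None] - centers)
    exact = d < 1e-12 * (np.abs(centers).max() + 1e-300)
    d = np.maximum(d, 1e-30)
    inv = d ** (-2.0 / (m - 1.0))
    u = inv / inv.sum(axis=-1, keepdims=True)
    hit = exact.any(axis=-1)
    if hit.any():
        u[hit] = exact[hit].astype(float)
        u[hit] /= u[hit].sum(axis=-1, keepdims=True)
    return u


def _tile_starts(dim: int, edge: int, step: int) -> list[int]:
    if dim <= edge:
        return [0]
    starts = list(range(0, dim - edge + 1, step))
    if starts[-1] != dim - edge:
        starts.append(dim - edge)
    return starts


def _tri_window(n: int) -> np.ndarray:
    # strictly positive triangular window so every voxel keeps support
    x = np.arange(n, dtype=np.float64)
    w = 1.0 - np.abs((x - (n - 1) / 2.0) / ((n + 1) / 2.0))
    return np.maximum(w, 1e-3)


class MIAClusterSegmenter(BaseEstimator):
    """Two-stage windowed clustering segmenter (K-means then fuzzy C-means).

    scikit-learn style estimator: :meth:`fit` learns per-tile class centers
    on a gray :class:`Volume`; :meth:`predict` returns the binary bone mask.
    Fitted attributes carry a trailing underscore.
    """

    def __init__(
        self,
        n_classes: int = 3,
        subvolume_edge: int = 64,
        overlap_fraction: float = 0.25,
        fuzzifier: float = 2.0,
        tol: float = 1e-5,
        max_iter: int = 100,
        n_bins: int = 1024,
        rng_seed: int = 0,
    ):
        self.n_classes = n_classes
        self.subvolume_edge = subvolume_edge
        self.overlap_fraction = overlap_fraction
        self.fuzzifier = fuzzifier
        self.tol = tol
        self.max_iter = max_iter
        self.n_bins = n_bins
        self.rng_seed = rng_seed

    def _config(self) -> ClusterConfig:
        return ClusterConfig(
            n_classes=self.n_classes,
            subvolume_edge=self.subvolume_edge,
            overlap_fraction=self.overlap_fraction,
            fuzzifier=self.fuzzifier,
            tol=self.tol,
            max_iter=self.max_iter,
            n_bins=self.n_bins,
            rng_seed=self.rng_seed,
        )

    def _cluster_values(self, vals: np.ndarray) -> np.ndarray | None:
        """K-means++ seeding then FCM on (possibly binned) scalar values.

        Returns sorted class centers, or None for a degenerate (constant)
        tile.
        """
        lo, hi = float(vals.min()), float(vals.max())
        if hi - lo <= 0:
            return None
        uniq = np.unique(vals)
        if len(uniq) < self.n_classes:
            raise ValueError(
                f"fewer distinct gray values ({len(uniq)}) than classes "
                f"({self.n_classes})"
            )
        if len(uniq) > self.n_bins:
            hist, edges = np.histogram(vals, bins=self.n_bins, range=(lo, hi))
            centers_bins = 0.5 * (edges[:-1] + edges[1:])
            keep = hist > 0
            bin_vals, bin_w = centers_bins[keep], hist[keep].astype(float)
        else:
            bin_vals, counts = np.unique(vals, return_counts=True)
            bin_w = counts.astype(float)
        # scale-invariant feature: normalize by range (k-means++ draws then
        # depend only on relative distances, keeping affine invariance)
        scale = hi - lo
        feat = ((bin_vals - lo) / scale).reshape(-1, 1)
        km = KMeans(
            n_clusters=self.n_classes,
            n_init=1,
            random_state=self.rng_seed,
            init="k-means++",
        ).fit(feat, sample_weight=bin_w)
        c0 = np.sort(km.cluster_centers_.ravel()) * scale + lo
        return _fcm_1d(c0, bin_vals, bin_w, self.fuzzifier, self.tol, self.max_iter)

    def fit(self, volume: Volume, y=None) -> "MIAClusterSegmenter":
        data = np.asarray(volume.data, dtype=np.float64)
        if np.ptp(data) <= 0:
            raise ValueError("cannot segment a constant volume")
        dims = data.shape
        edge = min(self.subvolume_edge, max(dims))
        step = max(1, int(round(edge * (1.0 - self.overlap_fraction))))
        tiles = []
        for sx in _tile_starts(dims[0], min(edge, dims[0]), step):
            for sy in _tile_starts(dims[1], min(edge, dims[1]), step):
                for sz in _tile_starts(dims[2], min(edge, dims[2]), step):
                    tiles.append((sx, sy, sz))
        self.tiles_ = tiles
        self.tile_edge_ = tuple(min(edge, d) for d in dims)
        self.tile_centers_ = []
        n_skipped = 0
        for sx, sy, sz in tiles:
            ex, ey, ez = self.tile_edge_
            sub = data[sx : sx + ex, sy : sy + ey, sz : sz + ez]
            if np.ptp(sub) <= 0:
                self.tile_centers_.append(None)
                n_skipped += 1
                continue
            self.tile_centers_.append(self._cluster_values(sub.ravel()))
        if n_skipped:
            warnings.warn(
                f"{n_skipped} constant subvolume(s); they inherit blended "
                "memberships from overlapping neighbours",
                stacklevel=2,
            )
        self.global_centers_ = self._cluster_values(data.ravel())
        self.shape_ = dims
        return self

    def predict(self, volume: Volume) -> Volume:
        mask, _ = self.predict_with_membership(volume)
        return mask

    def predict_with_membership(self, volume: Volume) -> tuple[Volume, Volume]:
        """Binary bone mask plus per-voxel bone membership in [0, 1]."""
        data = np.asarray(volume.data, dtype=np.float64)
        k = self.n_classes
        num = np.zeros(data.shape + (k,), dtype=np.float64)
        den = np.zeros(data.shape, dtype=np.float64)
        ex, ey, ez = self.tile_edge_
        wx, wy, wz = _tri_window(ex), _tri_window(ey), _tri_window(ez)
        w_tile = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
        for (sx, sy, sz), centers in zip(self.tiles_, self.tile_centers_):
            if centers is None:
                continue
            sl = np.s_[sx : sx + ex, sy : sy + ey, sz : sz + ez]
            u = _memberships(data[sl], centers, self.fuzzifier)
            num[sl] += u * w_tile[..., None]
            den[sl] += w_tile
        uncovered = den <= 0
        if uncovered.any():
            u = _memberships(data[uncovered], self.global_centers_, self.fuzzifier)
            num[uncovered] = u
            den[uncovered] = 1.0
        u_all = num / den[..., None]
        # classes are sorted by center gray value; bone = highest-mean class
        labels = np.argmax(u_all, axis=-1)
        bone = labels == (k - 1)
        return volume.like(bone), volume.like(u_all[..., k - 1])


def mia_segment(
    gray: Volume, cfg: ClusterConfig | None = None, return_membership: bool = False
):
    """Segment a gray volume into a binary bone mask.

    Thin functional wrapper over :class:`MIAClusterSegmenter`.
    """
    cfg = cfg or ClusterConfig()
    seg = MIAClusterSegmenter(
        n_classes=cfg.n_classes,
        subvolume_edge=cfg.subvolume_edge,
        overlap_fraction=cfg.overlap_fraction,
        fuzzifier=cfg.fuzzifier,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        n_bins=cfg.n_bins,
        rng_seed=cfg.rng_seed,
    ).fit(gray)
    mask, membership = seg.predict_with_membership(gray)
    if return_membership:
        return mask, membership
    return mask
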