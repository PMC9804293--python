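"""Core voxel containers shared by every stage of the pipeline.

A :class:`Volume` is a 3D voxel grid with an isotropic physical voxel size in
millimetres.  Grayscale volumes hold floats; binary masks hold booleans.  All
geometry in the package is expressed in millimetres, with voxel centres at
``(index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume", "CompartmentSet"]


@dataclass
class Volume:
    """A 3D voxel grid with physical scale.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values. Boolean for masks, float for gray volumes.
    voxel_size : float
        Isotropic edge length of one voxel in mm.
    """

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_mask(self) -> bool:
        return self.data.dtype == bool

    def physical_extent(self) -> np.ndarray:
        """Edge lengths of the volume in mm."""
        return np.asarray(self.shape, dtype=float) * self.voxel_size

    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(self.voxel_size**3)

    def count(self) -> int:
        """Number of foreground voxels (masks only)."""
        if not self.is_mask:
            raise TypeError("count() is defined for binary masks only")
        return int(self.data.sum())

    def like(self, data: np.ndarray) -> "Volume":
        """New volume on the same grid."""
        return Volume(data, self.voxel_size)

    def coords(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel indices (N, 3)."""
        return (np.asarray(indices, dtype=float) + 0.5) * self.voxel_size

    def indices(self, coords: np.ndarray) -> np.ndarray:
        """Nearest voxel indices of physical coordinates (N, 3)."""
        idx = np.floor(np.asarray(coords, dtype=float) / self.voxel_size).astype(int)
        return np.clip(idx, 0, np.asarray(self.shape) - 1)


@dataclass
class CompartmentSet:
    """Outer/inner/cortical/trabecular masks for one specimen.

    Invariants (checked on construction):

    * cortical and trabecular masks are disjoint,
    * cortical ⊆ outer, trabecular ⊆ inner, inner ⊆ outer.
    """

    outer: Volume
    inner: Volume
    cortical: Volume
    trabecular: Volume
    n_close_cycles: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vols = [self.outer, self.inner, self.cortical, self.trabecular]
        if len({v.shape for v in vols}) != 1:
            raise ValueError("compartment masks must share one grid")
        if any(not v.is_mask for v in vols):
            raise ValueError("compartment volumes must be binary masks")
        o, i = self.outer.data, self.inner.data
        c, t = self.cortical.data, self.trabecular.data
        if (c & t).any():
            raise ValueError("cortical and trabecular masks overlap")
        if (c & ~o).any():
            raise ValueError("cortical mask escapes the outer mask")
        if (t & ~i).any():
            raise ValueError("trabecular mask escapes the inner mask")
        if (i & ~o).any():
            raise ValueError("inner mask escapes the outer mask")
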