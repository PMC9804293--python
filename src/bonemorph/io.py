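"""Readers and writers for the pipeline's on-disk formats.

Volumes travel as multi-page TIFF stacks or NRRD (voxel size recorded in
the header, mm); binary masks as 8-bit {0, 255}; landmark ensembles and
grid-sample tables as CSV; tetrahedral meshes with cell data as legacy
ASCII VTK (readable by ParaView); ground truth and manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .core import Volume
from .meshing import TetMesh
from .phantoms import LandmarkEnsemble

__all__ = [
    "write_volume",
    "read_volume",
    "write_landmarks_csv",
    "read_landmarks_csv",
    "write_vtk_tetmesh",
    "write_json",
    "read_json",
]


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as .nrrd (with spacing) or multi-page .tif."""
    path = Path(path)
    data = vol.data
    if data.dtype == bool:
        data = (data * np.uint8(255)).astype(np.uint8)
    if path.suffix in (".nrrd", ".nhdr", ".mhd", ".mha"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(data))
        img.SetSpacing((vol.voxel_size,) * 3)
        sitk.WriteImage(img, str(path), useCompression=False)
    elif path.suffix in (".tif", ".tiff"):
        res = 10.0 / vol.voxel_size  # pixels per cm
        tifffile.imwrite(
            path,
            np.ascontiguousarray(data),
            resolution=(res, res),
            resolutionunit="CENTIMETER",
            metadata={"voxel_size_mm": vol.voxel_size, "spacing": vol.voxel_size},
        )
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")
    return path


def read_volume(path: str | Path, voxel_size: float | None = None) -> Volume:
    """Read a TIFF stack or NRRD/MHD volume; 8-bit masks with values in
    {0, 255} come back as boolean."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            if voxel_size is None:
                meta = tf.shaped_metadata or tf.imagej_metadata or {}
                if isinstance(meta, (list, tuple)):
                    meta = meta[0] if meta else {}
                voxel_size = float(meta.get("voxel_size_mm", 0) or 0) or None
        if voxel_size is None:
            raise ValueError("voxel_size not recoverable from TIFF; pass it explicitly")
    elif path.suffix in (".nrrd", ".nhdr", ".mhd", ".mha"):
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)
        voxel_size = voxel_size or float(img.GetSpacing()[0])
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")
    if data.dtype == np.uint8 and set(np.unique(data)) <= {0, 255}:
        data = data > 0
    return Volume(data, voxel_size)


def write_landmarks_csv(ens: LandmarkEnsemble, path: str | Path) -> Path:
    """Landmark CSV dialect: specimen_id, point_id, slide_class, x, y, z
    (mm), plus the group label."""
    path = Path(path)
    rows = []
    sc = ens.slide_class
    for i, sid in enumerate(ens.ids):
        for j in range(ens.n_landmarks):
            rows.append(
                {
                    "specimen_id": sid,
                    "point_id": j,
                    "slide_class": sc[j] if sc is not None else "fixed",
                    "x": ens.coords[i, j, 0],
                    "y": ens.coords[i, j, 1],
                    "z": ens.coords[i, j, 2],
                    "group": ens.groups[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_landmarks_csv(path: str | Path) -> LandmarkEnsemble:
    df = pd.read_csv(path)
    ids = list(pd.unique(df["specimen_id"]))
    k = df["point_id"].max() + 1
    coords = np.empty((len(ids), k, 3))
    groups = []
    for i, sid in enumerate(ids):
        sub = df[df["specimen_id"] == sid].sort_values("point_id")
        coords[i] = sub[["x", "y", "z"]].to_numpy()
        groups.append(sub["group"].iloc[0])
    first = df[df["specimen_id"] == ids[0]].sort_values("point_id")
    return LandmarkEnsemble(
        coords=coords,
        groups=np.asarray(groups),
        ids=[str(s) for s in ids],
        slide_class=first["slide_class"].to_numpy(),
    )


def write_vtk_tetmesh(mesh: TetMesh, path: str | Path) -> Path:
    """Legacy ASCII VTK unstructured grid with per-cell scalar arrays."""
    path = Path(path)
    v = mesh.vertices
    t = mesh.tetrahedra
    lines = [
        "# vtk DataFile Version 3.0",
        "tetrahedral mesh with cell data",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(v)} float",
    ]
    lines += [" ".join(f"{x:.8g}" for x in p) for p in v]
    lines.append(f"CELLS {len(t)} {len(t) * 5}")
    lines += ["4 " + " ".join(str(i) for i in tet) for tet in t]
    lines.append(f"CELL_TYPES {len(t)}")
    lines += ["10"] * len(t)
    if mesh.cell_data:
        lines.append(f"CELL_DATA {len(t)}")
        for name, arr in mesh.cell_data.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{x:.8g}" for x in np.asarray(arr, dtype=float)]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
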