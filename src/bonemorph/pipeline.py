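"""End-to-end orchestration of the phantom battery.

A single YAML/dict config drives every stage in order — phantom (or
ingest) → segmentation → compartments → trabecular metrics → mesh mapping
→ geometric morphometrics → pointcloud group comparison — writing each
artifact plus a manifest (config hash, seeds, package versions, output
checksums).  All randomness flows from explicit per-stage seeds derived
from one pipeline seed, so a rerun with the same config reproduces every
output bit-exactly.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compartments import CompartmentConfig, extract_masks
from .core import Volume
from .fieldstats import perm_maxT, rft_ttest
from .gmm import form_pca, gpa, make_synthetic_template, pc_stats, shape_pca, slide_semilandmarks
from .io import (
    write_json,
    write_landmarks_csv,
    write_vtk_tetmesh,
    write_volume,
)
from .meshing import interp_to_centroids, tet_mesh
from .metrics import (
    GridSpec,
    global_number,
    global_spacing,
    global_thickness,
    grid_samples,
    samples_to_frame,
    summarize_specimen,
)
from .phantoms import (
    ImagingSpec,
    PhantomSpec,
    ShapeSeriesSpec,
    add_cortex_and_grayscale,
    make_lattice_phantom,
    make_scalar_ensemble,
)
from .segmentation import ClusterConfig, mia_segment

log = logging.getLogger("bonemorph")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "run",
    "stages": ["phantom", "segment", "compartments", "metrics", "map", "gm", "compare"],
    "phantom": {
        "lattice_kind": "plate",
        "voxel_size": 0.05,
        "dims": [96, 96, 96],
        "thickness": 0.2,
        "spacing": 0.6,
        "shell_thickness": 0.5,
        "noise_sd": 18.0,
        "sediment_fraction": 0.1,
    },
    "segmentation": {"n_classes": 3, "subvolume_edge": 64, "overlap_fraction": 0.25,
                     "tophat_radius": None},
    "compartments": {"kernel": 3, "max_cycles": 10},
    "metrics": {"node_spacing": 1.0, "sphere_diameter": 2.0, "n_mil_directions": 64},
    "map": {"target_edge": None},
    "gm": {"n_per_group": [6, 6, 6, 6], "n_landmarks": 60, "noise_sd": 0.01,
           "n_sweeps": 2, "alpha": 0.05},
    "compare": {"n_per_group": [10, 10], "effect_size": 1.5, "effect_radius": 3.0,
                "smoothness_fwhm": 5.0, "cloud_radius": 6.0, "alpha": 0.05,
                "method": "both", "n_perm": 300},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> Path:
    """Execute the configured stages; returns the run directory.

    Every stage logs its wall time; a failure halts with a stage-tagged
    error while earlier outputs are preserved.  The manifest written at the
    end suffices to re-execute an identical run.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {},
        "stage_seconds": {},
    }
    stages = cfg["stages"]
    state: dict = {}

    def record(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    for stage in stages:
        t0 = time.time()
        log.info("stage %s: start", stage)
        try:
            if stage == "phantom":
                p = cfg["phantom"]
                spec = PhantomSpec(
                    lattice_kind=p["lattice_kind"],
                    voxel_size=p["voxel_size"],
                    dims=tuple(p["dims"]),
                    thickness=p["thickness"],
                    spacing=p["spacing"],
                    shell_thickness=p["shell_thickness"],
                    rng_seed=_stage_seed(seed, "phantom"),
                )
                trab, truth = make_lattice_phantom(spec)
                img = ImagingSpec(
                    noise_sd=p["noise_sd"],
                    sediment_fraction=p["sediment_fraction"],
                    rng_seed=_stage_seed(seed, "imaging"),
                )
                gray, ctruth = add_cortex_and_grayscale(trab, spec, img)
                state["gray"], state["ctruth"], state["spec"] = gray, ctruth, spec
                state["gtruth"] = truth
                record("gray", write_volume(gray, out / "gray.nrrd"))
                record("bone_truth", write_volume(
                    Volume(ctruth.meta["bone"], gray.voxel_size), out / "bone_truth.nrrd"))
                record("ground_truth", write_json(
                    {**{k: v for k, v in asdict(truth).items()}}, out / "ground_truth.json"))
            elif stage == "segment":
                s = cfg["segmentation"]
                gray = state["gray"]
                if s.get("tophat_radius"):
                    from .segmentation import white_tophat

                    gray = white_tophat(gray, float(s["tophat_radius"]))
                mask = mia_segment(
                    gray,
                    ClusterConfig(
                        n_classes=s["n_classes"],
                        subvolume_edge=s["subvolume_edge"],
                        overlap_fraction=s["overlap_fraction"],
                        rng_seed=_stage_seed(seed, "segment"),
                    ),
                )
                state["bone"] = mask
                record("bone", write_volume(mask, out / "bone.nrrd"))
            elif stage == "compartments":
                c = cfg["compartments"]
                cs = extract_masks(
                    state["bone"],
                    CompartmentConfig(kernel=c["kernel"], max_cycles=c["max_cycles"]),
                )
                state["compartments"] = cs
                record("trabecular", write_volume(cs.trabecular, out / "trabecular.nrrd"))
                record("cortical", write_volume(cs.cortical, out / "cortical.nrrd"))
            elif stage == "metrics":
                m = cfg["metrics"]
                cs = state["compartments"]
                grid = GridSpec(
                    node_spacing=m["node_spacing"],
                    sphere_diameter=m["sphere_diameter"],
                    n_mil_directions=m["n_mil_directions"],
                )
                samples = grid_samples(cs.trabecular, cs.inner, grid)
                th = global_thickness(cs.trabecular)
                sp = global_spacing(cs.trabecular, cs.inner)
                summary = summarize_specimen(samples, th, sp, global_number(th, sp))
                state["samples"], state["summary"], state["grid"] = samples, summary, grid
                df = samples_to_frame(samples)
                df.to_csv(out / "grid_samples.csv", index=False)
                record("grid_samples", out / "grid_samples.csv")
                summary.to_frame().to_csv(out / "specimen_summary.csv", index=False)
                record("specimen_summary", out / "specimen_summary.csv")
            elif stage == "map":
                cs = state["compartments"]
                mesh = tet_mesh(cs.inner, cfg["map"]["target_edge"])
                df = samples_to_frame(state["samples"])
                mesh = interp_to_centroids(
                    df[["x", "y", "z"]].to_numpy(),
                    {"BVTV": df["bvtv"].to_numpy(), "DA": df["da"].to_numpy()},
                    mesh,
                )
                record("tetmesh", write_vtk_tetmesh(mesh, out / "trabecular_map.vtk"))
            elif stage == "gm":
                g = cfg["gm"]
                series = ShapeSeriesSpec(
                    n_per_group=tuple(g["n_per_group"]),
                    n_landmarks=g["n_landmarks"],
                    noise_sd=g["noise_sd"],
                    rng_seed=_stage_seed(seed, "gm"),
                )
                from .phantoms import make_ontogenetic_series

                ens = make_ontogenetic_series(series)
                pe = gpa(ens)
                sp_res = shape_pca(pe)
                fp_res = form_pca(pe)
                report = {
                    "shape": pc_stats(sp_res.scores, pe.groups, np.log(pe.centroid_sizes),
                                      alpha=g["alpha"]),
                    "form": pc_stats(fp_res.scores, pe.groups, np.log(pe.centroid_sizes),
                                     alpha=g["alpha"]),
                    "shape_variance_fractions": sp_res.variance_fractions[:5],
                    "form_variance_fractions": fp_res.variance_fractions[:5],
                }
                record("landmarks", write_landmarks_csv(ens, out / "landmarks.csv"))
                record("gm_report", write_json(report, out / "gm_report.json"))
            elif stage == "compare":
                c = cfg["compare"]
                pce = make_scalar_ensemble(
                    n_per_group=tuple(c["n_per_group"]),
                    effect_region=((0.0, 0.0, 0.0), c["effect_radius"]),
                    effect_size=c["effect_size"],
                    smoothness_fwhm=c["smoothness_fwhm"],
                    seed=_stage_seed(seed, "compare"),
                    cloud_radius=c["cloud_radius"],
                )
                results = {}
                if c["method"] in ("rft", "both"):
                    sm = rft_ttest(pce.values, pce.groups, "A", "B", pce.points,
                                   pce.spacing, alpha=c["alpha"])
                    results["rft"] = {
                        "threshold": sm.threshold,
                        "fwhm": sm.fwhm,
                        "n_significant": int(sm.significant.sum()),
                    }
                if c["method"] in ("perm", "both"):
                    pm = perm_maxT(pce.values, pce.groups, "A", "B",
                                   n_perm=c["n_perm"],
                                   seed=_stage_seed(seed, "perm"), alpha=c["alpha"])
                    results["perm"] = {
                        "threshold": pm.threshold,
                        "n_significant": int(pm.significant.sum()),
                    }
                record("compare_report", write_json(results, out / "compare_report.json"))
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            write_json(manifest, out / "manifest.json")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stage_seconds"][stage] = round(time.time() - t0, 3)
        log.info("stage %s: done in %.1fs", stage, manifest["stage_seconds"][stage])
    write_json(manifest, out / "manifest.json")
    return out


def rerun_from_manifest(manifest_path: str | Path, output_dir: str | Path) -> Path:
    """Re-execute a run from its manifest alone."""
    import json

    manifest = json.loads(Path(manifest_path).read_text())
    return run_pipeline(manifest["config"], output_dir)
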