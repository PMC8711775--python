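"""Configuration, persistence and experiment orchestration.

A run configuration is a YAML/JSON mapping with ``geometry``, ``detector``,
``aperture``, ``grid``, ``acquisition`` and ``recon`` sections plus a
global ``seed`` and an optional ``scale`` section that coarsens the grid,
the detector pixelation and the MCE count for desk-scale runs.  Every
experiment writes a manifest carrying the configuration hash and seed so
reruns are reproducible bit for bit in counts mode.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from .apertures import assign_apertures
from .geometry import DetectorSpec, HelmetGeometry, build_helmet
from .system_matrix import (
    SRMOptions,
    SystemMatrix,
    VolumeGrid,
    aperture_snr,
    build_srm,
    point_sensitivity,
)

__all__ = [
    "load_config",
    "validate_config",
    "config_hash",
    "save_volume",
    "load_volume",
    "subsample_helmet",
    "build_system",
    "run_experiment",
    "DEFAULT_CONFIG",
    "STUDIES",
]

STUDIES = (
    "sensitivity", "aperture_snr", "fim", "point_projections",
    "defrise", "hotrod20", "hotrod5", "brain_noiseless", "brain_lesions",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "geometry": {
        "focal_distance_mm": 183.23,
        "mf_denominator": 12,
        "support_radius_mm": 196.0,
        "neck_arc_deg": 180.0,
    },
    "detector": {"n_pix": 80, "pitch_mm": 0.25, "n_doi_layers": 5,
                 "mu_czt": 0.354},
    "aperture": {"collimator": "ring_250", "mu_w": None, "step_mm": 0.025},
    "grid": {"n": 96, "voxel_size_mm": 2.0},
    "acquisition": {"time_min": 30.0, "photon_yield": 0.885},
    # n_iter None -> per-study default (500 for the noiseless brain study,
    # 50 otherwise, following the published iteration budgets)
    "recon": {"n_subsets": 8, "n_iter": None, "postfilter_fwhm_mm": 6.0},
    "scale": None,  # e.g. {"n_mce": 48, "det_n_pix": 16, "grid_n": 48,
    #                        "voxel_size_mm": 4.0}
}


def validate_config(cfg: dict) -> dict:
    """Fill defaults and fail with a named error for malformed sections."""
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in cfg.items():
        if key not in DEFAULT_CONFIG:
            raise ValueError(f"unknown configuration section {key!r}")
        if isinstance(DEFAULT_CONFIG[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"section {key!r} must be a mapping")
            unknown = set(val) - set(DEFAULT_CONFIG[key])
            if unknown:
                raise ValueError(f"unknown keys {sorted(unknown)} in section {key!r}")
            out[key].update(val)
        else:
            out[key] = val
    return out


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    return validate_config(cfg)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_volume(path, array: np.ndarray, voxel_size: float) -> None:
    """Write a grid volume as NIfTI with the origin at the volume centre."""
    import nibabel as nib

    shape = np.asarray(array.shape)
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -(shape / 2.0 - 0.5) * voxel_size
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, float]:
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), float(img.header.get_zooms()[0])


def subsample_helmet(geometry: HelmetGeometry, n_keep: int) -> HelmetGeometry:
    """Deterministically keep ``n_keep`` MCEs spread evenly over the helmet
    (azimuth-sorted within rings), for desk-scale studies."""
    if not (1 <= n_keep <= geometry.n_mce):
        raise ValueError(f"cannot keep {n_keep} of {geometry.n_mce} MCEs")
    order = sorted(
        range(geometry.n_mce),
        key=lambda i: (geometry.mces[i].ring_index, geometry.mces[i].azimuth_deg),
    )
    pick = sorted(order[int(round(p))] for p in
                  np.linspace(0, geometry.n_mce - 1, n_keep))
    mces = tuple(geometry.mces[i] for i in pick)
    return HelmetGeometry(
        support_radius=geometry.support_radius,
        focal_distance=geometry.focal_distance,
        image_distance=geometry.image_distance,
        mces=mces,
        ring_counts=geometry.ring_counts,
        neck_arc_deg=geometry.neck_arc_deg,
        n_hemisphere=geometry.n_hemisphere,
        n_neck=geometry.n_neck,
    )


def build_system(cfg: dict):
    """(geometry, detector, apertures, grid, options) from a configuration,
    honouring the ``scale`` section when present."""
    cfg = validate_config(cfg)
    g = cfg["geometry"]
    geometry = build_helmet(
        focal_distance=g["focal_distance_mm"],
        mf_denominator=g["mf_denominator"],
        support_radius=g["support_radius_mm"],
        neck_arc_deg=g["neck_arc_deg"],
    )
    d = cfg["detector"]
    n_pix, pitch = d["n_pix"], d["pitch_mm"]
    grid_n, vox = cfg["grid"]["n"], cfg["grid"]["voxel_size_mm"]
    scale = cfg.get("scale")
    if scale:
        if "n_mce" in scale:
            geometry = subsample_helmet(geometry, int(scale["n_mce"]))
        if "det_n_pix" in scale:
            n_pix = int(scale["det_n_pix"])
            pitch = 20.0 / n_pix
        grid_n = int(scale.get("grid_n", grid_n))
        vox = float(scale.get("voxel_size_mm", vox))
    det = DetectorSpec(
        n_pix_u=n_pix, n_pix_v=n_pix, pitch=pitch,
        n_doi_layers=d["n_doi_layers"], mu_czt=d["mu_czt"],
    )
    a = cfg["aperture"]
    apertures = assign_apertures(
        [m.ring_index for m in geometry.mces], a["collimator"],
        seed=int(cfg["seed"]), mu_w=a["mu_w"],
    )
    grid = VolumeGrid(shape=(grid_n,) * 3, voxel_size=vox)
    options = SRMOptions(step=a["step_mm"])
    return geometry, det, apertures, grid, options


def _cached_srm(cfg, geometry, det, apertures, grid, options, cache_dir) -> SystemMatrix:
    key = config_hash(
        {"cfg": {k: cfg[k] for k in ("geometry", "detector", "aperture", "grid", "scale")},
         "n_mce": geometry.n_mce, "grid": [grid.shape, grid.voxel_size],
         "det": [det.n_pix_u, det.pitch], "step": options.step}
    )
    path = Path(cache_dir) / f"srm_{key}.h5"
    if path.exists():
        return SystemMatrix.load(path)
    srm = build_srm(geometry, det, apertures, grid, options,
                    collimator=cfg["aperture"]["collimator"])
    path.parent.mkdir(parents=True, exist_ok=True)
    srm.save(path)
    return srm


def run_experiment(cfg: dict, study: str, out_dir, seed: "int | None" = None) -> dict:
    """Run one named study end to end and write results plus a manifest.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    from . import fim as fim_mod
    from . import metrics as met
    from .phantoms import (brain_phantom, defrise_phantom, hot_rod_phantom,
                           point_sources, uniform_fov)
    from .recon import gaussian_post_filter, osem, stopping_iteration
    from .simulate import add_poisson, forward_project, render_point_projection

    cfg = validate_config(cfg)
    if seed is not None:
        cfg["seed"] = int(seed)
    if study not in STUDIES:
        raise ValueError(f"unknown study {study!r}; valid: {STUDIES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry, det, apertures, grid, options = build_system(cfg)
    t0 = time.time()
    results: dict = {}

    if study == "sensitivity":
        center = point_sensitivity(geometry, det, apertures, [[0.0, 0.0, 0.0]], options)
        results["central_sensitivity_percent"] = float(center[0] * 100.0)
    elif study == "aperture_snr":
        r = aperture_snr(geometry, det, apertures[0], grid, stride=4, step=options.step)
        results["aperture_snr"] = r["snr"]
        results.update({k: r[k] for k in ("n_signal", "n_noise", "n_sources")})
    elif study == "point_projections":
        img = render_point_projection(
            geometry.mces[0], apertures[0], det, geometry.image_distance,
            [2.0, 0.0, 0.0],
        )
        np.savetxt(out / "point_projection.csv", img, delimiter=",")
        results["point_projection_nonzero"] = int((img > 0).sum())
    else:
        srm = _cached_srm(cfg, geometry, det, apertures, grid, options, out / "cache")
        if study == "fim":
            ybar = forward_project(
                srm, uniform_fov(grid), time_s=cfg["acquisition"]["time_min"] * 60.0
            ).values
            image = fim_mod.fim_column(srm, ybar, grid.center_index())
            results["fim_peak"] = image.peak
            for d in ("lateral", "craniocaudal"):
                results[f"fim_fwhm_{d}_mm"] = fim_mod.profile_fwhm(image, d)
        else:
            if study == "defrise":
                phantom = defrise_phantom(grid)
                phantom.total_photons = 2e8
                noise = False
            elif study in ("hotrod20", "hotrod5"):
                phantom = hot_rod_phantom(grid, 20.0 if study == "hotrod20" else 5.0)
                noise = True
            else:
                phantom = brain_phantom(grid, lesions=(study == "brain_lesions"))
                noise = study == "brain_lesions"
            from .simulate import emitted_photons

            truth = emitted_photons(phantom, time_s=cfg["acquisition"]["time_min"] * 60.0)
            mean = forward_project(srm, phantom,
                                   time_s=cfg["acquisition"]["time_min"] * 60.0)
            y = add_poisson(mean, seed=int(cfg["seed"])) if noise else mean
            rc = cfg["recon"]
            n_iter = rc["n_iter"]
            if n_iter is None:
                n_iter = 500 if study == "brain_noiseless" else 50
            res = osem(y, srm, geometry, n_subsets=rc["n_subsets"],
                       n_iter=n_iter, truth=truth)
            mode = "noisy_min" if noise else "noiseless_plateau"
            stop = stopping_iteration(res.nrmse_trace, mode=mode)
            results["stopping_iteration"] = stop
            results["nrmse_at_stop"] = float(res.nrmse_trace[stop - 1])
            img = res.image
            if noise and study.startswith("brain"):
                img = gaussian_post_filter(img, grid.voxel_size,
                                           rc["postfilter_fwhm_mm"])
            save_volume(out / f"{study}_recon.nii.gz", img, grid.voxel_size)
            np.savetxt(out / f"{study}_nrmse.csv", res.nrmse_trace, delimiter=",")
            if study.startswith("hotrod"):
                C = 20.0 if study == "hotrod20" else 5.0
                bck = phantom.rois["background_rod"]
                for name, roi in phantom.rois.items():
                    if roi.role == "rod":
                        results[f"crc_{name}"] = met.crc(img, roi, bck, C)
                        results[f"cnr_{name}"] = met.cnr(img, roi, bck)
                results["nc_percent"] = met.nc(img, bck)
            if study.startswith("brain"):
                ref = phantom.rois["reference"]
                for name, roi in phantom.rois.items():
                    if roi.role in ("voi_left", "voi_right"):
                        results[f"ur_{name}"] = met.uptake_ratio(img, roi, ref)

    manifest = {
        "study": study,
        "seed": int(cfg["seed"]),
        "config_hash": config_hash(cfg),
        "n_mce": geometry.n_mce,
        "grid": [list(grid.shape), grid.voxel_size],
        "elapsed_s": round(time.time() - t0, 2),
        "results": results,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
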