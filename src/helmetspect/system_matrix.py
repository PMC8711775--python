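"""Voxel-driven system response matrix (SRM), sensitivity and aperture SNR.

Every element ``a_mn`` of the SRM is the probability that a photon emitted
isotropically at voxel ``n`` is detected in bin ``m``, where a bin is one
(MCE, pixel i, pixel j, DOI layer k) combination.  A ray is traced from the
voxel centre to the pixel centre (at mid-crystal depth) and

    a_m = dOmega_pix / (4 pi) * T_aperture * P_layer * T_object

with ``dOmega_pix = A_pix cos(gamma) / dist^2`` the pixel solid angle at the
detector entrance face, ``T_aperture = exp(-mu_w x)`` the tungsten
transmission from ray marching, ``P_layer`` the Beer-Lambert absorption
probability in DOI layer k using oblique chord lengths in CZT, and
``T_object`` an optional uniform-water attenuation over the chord to the
edge of the 20-cm FOV sphere (off by default: the design-study sensitivity
accounts only for collimator passage and CZT efficiency).

Row ordering: ``m = mce * (n_pix_u*n_pix_v*n_doi) + (i*n_pix_v + j)*n_doi + k``.
Column ordering: C-order voxel index over the grid shape.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp

from . import _trace
from .apertures import ApertureSpec
from .geometry import DetectorSpec, HelmetGeometry, mce_frame, pixel_centers_local

__all__ = [
    "VolumeGrid",
    "SRMOptions",
    "SystemMatrix",
    "SensitivityMap",
    "voxel_response",
    "point_sensitivity",
    "build_srm",
    "sensitivity_map",
    "sensitivity_profiles",
    "aperture_snr",
    "MU_WATER_140KEV",
]

MU_WATER_140KEV = 0.0154  # mm^-1, water at 140 keV
FOV_RADIUS_MM = 100.0

AXES = {"lateral": 0, "ventrodorsal": 1, "craniocaudal": 2}


@dataclass(frozen=True)
class VolumeGrid:
    """Isotropic voxel grid centred on the FOV centre.

    Voxel centres sit at ``((i + 0.5) - N/2) * voxel_size`` per axis; the
    standard study grid is 96^3 voxels of 2 mm.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 2.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return ((np.arange(n) + 0.5) - n / 2.0) * self.voxel_size

    def voxel_centers(self) -> np.ndarray:
        cs = [self.axis_coords(a) for a in range(3)]
        g = np.meshgrid(*cs, indexing="ij")
        return np.stack([c.ravel() for c in g], axis=1)

    def center_index(self) -> tuple[int, int, int]:
        return tuple(n // 2 for n in self.shape)

    def fov_mask(self, radius: float = FOV_RADIUS_MM) -> np.ndarray:
        c = self.voxel_centers()
        return (np.einsum("ij,ij->i", c, c) <= radius**2).reshape(self.shape)

    def world_to_index(self, p) -> tuple[int, int, int]:
        p = np.asarray(p, dtype=float)
        idx = np.floor(p / self.voxel_size + np.array(self.shape) / 2.0).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.shape):
            raise ValueError(f"point {p} outside the grid")
        return tuple(int(i) for i in idx)


@dataclass(frozen=True)
class SRMOptions:
    """Numerical knobs for SRM construction and ray classification."""

    step: float = 0.025            # ray-march step in tungsten, mm
    coarse_step: float = 0.25      # coarse cell for the refined march, mm
    refine: bool = True            # transition-refined march (False: plain fine)
    trans_floor: float = 1e-6      # tungsten transmissions below this -> 0
    entry_floor: float = 1e-12     # SRM entries below this are dropped
    pixel_subsample: int = 1       # subdivide each pixel s x s for rays
    object_attenuation: str = "none"  # "none" | "water"
    mu_water: float = MU_WATER_140KEV
    ray_cap: float = 5e9           # refuse builds tracing more rays than this


def _mce_paths(
    frame, aperture: ApertureSpec, det: DetectorSpec, image_distance: float,
    voxels_world: np.ndarray, opt: SRMOptions,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tungsten path lengths and geometry factors for one MCE.

    Returns (paths, omega, sec_gamma): arrays of shape (n_voxel, n_subray)
    with the marched tungsten path (BLOCKED where opaque), the per-subray
    solid-angle fraction dOmega/(4 pi), and the secant of the incidence
    angle on the detector for the per-layer CZT chords.
    """
    s = opt.pixel_subsample
    sub = DetectorSpec(
        n_pix_u=det.n_pix_u * s, n_pix_v=det.n_pix_v * s, pitch=det.pitch / s,
        thickness=det.thickness, n_doi_layers=det.n_doi_layers,
        layer_thickness=det.layer_thickness, mu_czt=det.mu_czt,
    ) if s > 1 else det
    targets = pixel_centers_local(sub, image_distance)  # mid-crystal depth
    origins = (np.asarray(voxels_world, dtype=float) - frame.origin) @ frame.rot.T

    max_path = math.log(1.0 / opt.trans_floor) / aperture.mu_w
    prune = max_path * (1.0 + aperture.max_tan) / 2.0 * 1.3
    paths = np.empty((len(origins), len(targets)), dtype=np.float64)
    _trace.trace_paths(
        origins, targets, aperture.kind_code, aperture.params(),
        opt.step, max_path, prune, opt.coarse_step, paths, opt.refine,
    )

    entry = targets.copy()
    entry[:, 2] = image_distance  # entrance-face points for solid angle
    diff = entry[None, :, :] - origins[:, None, :]
    dist2 = np.einsum("vpk,vpk->vp", diff, diff)
    dist = np.sqrt(dist2)
    cosg = (image_distance - origins[:, None, 2]) / dist
    omega = (sub.pitch**2) * cosg / (4.0 * math.pi * dist2)

    dmid = targets[None, :, :] - origins[:, None, :]
    sec = np.linalg.norm(dmid, axis=2) / dmid[:, :, 2]
    return paths, omega, sec


def _water_factor(voxels_world, frame, det, image_distance, opt):
    """Uniform-water attenuation along the chord to the FOV-sphere edge,
    using the voxel-to-aperture-centre direction (narrow-cone approximation)."""
    o = np.asarray(voxels_world, dtype=float)
    d = frame.origin - o
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    od = np.einsum("ij,ij->i", o, d)
    oo = np.einsum("ij,ij->i", o, o)
    disc = np.maximum(od**2 - oo + FOV_RADIUS_MM**2, 0.0)
    s_exit = -od + np.sqrt(disc)
    return np.exp(-opt.mu_water * np.clip(s_exit, 0.0, None))


def _layer_probs(sec: np.ndarray, det: DetectorSpec) -> np.ndarray:
    """P_k for all DOI layers; shape (..., n_doi)."""
    mu_t = det.mu_czt * det.layer_thickness * np.abs(sec)
    k = np.arange(det.n_doi_layers)
    before = np.exp(-mu_t[..., None] * k)
    within = 1.0 - np.exp(-mu_t[..., None])
    return before * within


def _mce_response(
    frame, aperture, det, image_distance, voxels_world, opt: SRMOptions
) -> np.ndarray:
    """Dense response of one MCE: shape (n_voxel, n_pix, n_doi)."""
    paths, omega, sec = _mce_paths(
        frame, aperture, det, image_distance, voxels_world, opt
    )
    max_path = math.log(1.0 / opt.trans_floor) / aperture.mu_w
    t_ap = np.where(paths <= max_path, np.exp(-aperture.mu_w * paths), 0.0)
    t_ap[paths == 0.0] = 1.0
    resp = omega * t_ap
    s = opt.pixel_subsample
    if s > 1:  # fold subpixels back onto physical pixels
        nv = resp.shape[0]
        resp = resp.reshape(nv, det.n_pix_u, s, det.n_pix_v, s).sum(axis=(2, 4))
        sec = sec.reshape(nv, det.n_pix_u, s, det.n_pix_v, s).mean(axis=(2, 4))
        resp = resp.reshape(nv, -1)
        sec = sec.reshape(nv, -1)
    if opt.object_attenuation == "water":
        resp = resp * _water_factor(voxels_world, frame, det, image_distance, opt)[:, None]
    elif opt.object_attenuation != "none":
        raise ValueError(f"unknown object_attenuation {opt.object_attenuation!r}")
    return resp[:, :, None] * _layer_probs(sec, det)


def _apertures_list(apertures, n_mce: int) -> list[ApertureSpec]:
    if isinstance(apertures, ApertureSpec):
        return [apertures] * n_mce
    apertures = list(apertures)
    if len(apertures) != n_mce:
        raise ValueError(
            f"{len(apertures)} apertures supplied for {n_mce} MCEs"
        )
    return apertures


def voxel_response(
    geometry: HelmetGeometry,
    det: DetectorSpec,
    apertures,
    voxel_center,
    options: SRMOptions = SRMOptions(),
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse column of the SRM for a single source position.

    Returns ``(rows, values)`` with the row encoding documented in the
    module header; entries below ``options.entry_floor`` are dropped.
    """
    aps = _apertures_list(apertures, geometry.n_mce)
    v = np.asarray(voxel_center, dtype=float).reshape(1, 3)
    n_doi = det.n_doi_layers
    bins_per_mce = det.n_pixels * n_doi
    rows_out, vals_out = [], []
    for idx, pose in enumerate(geometry.mces):
        resp = _mce_response(
            mce_frame(pose), aps[idx], det, geometry.image_distance, v, options
        ).reshape(-1)
        keep = np.nonzero(resp > options.entry_floor)[0]
        if keep.size:
            rows_out.append(keep + idx * bins_per_mce)
            vals_out.append(resp[keep])
    if not rows_out:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return np.concatenate(rows_out), np.concatenate(vals_out)


def point_sensitivity(
    geometry: HelmetGeometry,
    det: DetectorSpec,
    apertures,
    points,
    options: SRMOptions = SRMOptions(),
) -> np.ndarray:
    """Detection probability (sum over all bins of the voxel response) for
    each source point, streamed over MCEs without storing a matrix."""
    aps = _apertures_list(apertures, geometry.n_mce)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    total = np.zeros(len(pts))
    for idx, pose in enumerate(geometry.mces):
        resp = _mce_response(
            mce_frame(pose), aps[idx], det, geometry.image_distance, pts, options
        )
        total += resp.sum(axis=(1, 2))
    return total


@dataclass
class SystemMatrix:
    """Sparse SRM with its defining geometry metadata."""

    matrix: sp.csr_matrix
    grid: VolumeGrid
    det: DetectorSpec
    n_mce: int
    options: SRMOptions = SRMOptions()
    collimator: str = ""

    @property
    def bins_per_mce(self) -> int:
        return self.det.n_pixels * self.det.n_doi_layers

    def rows_for_mce(self, idx: int) -> slice:
        b = self.bins_per_mce
        return slice(idx * b, (idx + 1) * b)

    def column(self, n: int) -> np.ndarray:
        return np.asarray(self.matrix[:, n].todense()).ravel()

    def save(self, path) -> None:
        a = self.matrix.tocsr()
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=a.data)
            f.create_dataset("indices", data=a.indices)
            f.create_dataset("indptr", data=a.indptr)
            f.attrs["shape"] = a.shape
            f.attrs["grid_shape"] = self.grid.shape
            f.attrs["voxel_size"] = self.grid.voxel_size
            f.attrs["n_mce"] = self.n_mce
            f.attrs["det"] = [
                self.det.n_pix_u, self.det.n_pix_v, self.det.n_doi_layers,
            ]
            f.attrs["det_pitch"] = self.det.pitch
            f.attrs["mu_czt"] = self.det.mu_czt
            f.attrs["collimator"] = self.collimator
            f.attrs["object_attenuation"] = self.options.object_attenuation
            f.attrs["row_order"] = "mce, pixel_i, pixel_j, doi_layer (C-order)"
            f.attrs["col_order"] = "voxel i, j, k (C-order)"

    @classmethod
    def load(cls, path) -> "SystemMatrix":
        with h5py.File(path, "r") as f:
            a = sp.csr_matrix(
                (f["data"][:], f["indices"][:], f["indptr"][:]),
                shape=tuple(f.attrs["shape"]),
            )
            npu, npv, ndoi = (int(x) for x in f.attrs["det"])
            det = DetectorSpec(
                n_pix_u=npu, n_pix_v=npv, pitch=float(f.attrs["det_pitch"]),
                thickness=ndoi * 1.0, n_doi_layers=ndoi,
                layer_thickness=1.0, mu_czt=float(f.attrs["mu_czt"]),
            )
            grid = VolumeGrid(
                shape=tuple(int(x) for x in f.attrs["grid_shape"]),
                voxel_size=float(f.attrs["voxel_size"]),
            )
            return cls(
                matrix=a, grid=grid, det=det, n_mce=int(f.attrs["n_mce"]),
                options=SRMOptions(
                    object_attenuation=str(f.attrs["object_attenuation"])
                ),
                collimator=str(f.attrs["collimator"]),
            )


def build_srm(
    geometry: HelmetGeometry,
    det: DetectorSpec,
    apertures,
    grid: VolumeGrid,
    options: SRMOptions = SRMOptions(),
    mask: "np.ndarray | None" = None,
    collimator: str = "",
    chunk: int = 2048,
) -> SystemMatrix:
    """Assemble the sparse SRM over all grid voxels (or a boolean mask).

    Refuses outright when the number of rays exceeds ``options.ray_cap``;
    coarsen the grid, subsample MCEs, or restrict the mask in that case.
    """
    aps = _apertures_list(apertures, geometry.n_mce)
    if mask is None:
        mask = grid.fov_mask()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    cols = np.nonzero(mask.ravel())[0]
    n_rays = len(cols) * geometry.n_mce * det.n_pixels * options.pixel_subsample**2
    if n_rays > options.ray_cap:
        raise ResourceWarning(
            f"SRM build would trace {n_rays:.2e} rays (cap {options.ray_cap:.0e}); "
            "coarsen the grid, restrict the mask or subsample MCEs"
        )
    centers = grid.voxel_centers()[cols]
    n_doi = det.n_doi_layers
    bins_per_mce = det.n_pixels * n_doi
    n_rows = geometry.n_mce * bins_per_mce

    r_idx, c_idx, vals = [], [], []
    for idx, pose in enumerate(geometry.mces):
        frame = mce_frame(pose)
        for lo in range(0, len(cols), chunk):
            sub = slice(lo, lo + chunk)
            resp = _mce_response(
                frame, aps[idx], det, geometry.image_distance, centers[sub], options
            ).reshape(len(centers[sub]), -1)
            vv, bb = np.nonzero(resp > options.entry_floor)
            r_idx.append((bb + idx * bins_per_mce).astype(np.int64))
            c_idx.append(cols[lo + vv])
            vals.append(resp[vv, bb])
    matrix = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(r_idx), np.concatenate(c_idx))),
        shape=(n_rows, grid.n_voxels),
    ).tocsr()
    return SystemMatrix(
        matrix=matrix, grid=grid, det=det, n_mce=geometry.n_mce,
        options=options, collimator=collimator,
    )


@dataclass(frozen=True)
class SensitivityMap:
    """Per-voxel detection probability s_i (column sums of the SRM)."""

    values: np.ndarray
    grid: VolumeGrid

    def percent(self) -> np.ndarray:
        return self.values * 100.0


def sensitivity_map(srm: SystemMatrix) -> SensitivityMap:
    s = np.asarray(srm.matrix.sum(axis=0)).ravel()
    return SensitivityMap(values=s.reshape(srm.grid.shape), grid=srm.grid)


def sensitivity_profiles(smap: SensitivityMap, axis: str) -> tuple[np.ndarray, np.ndarray]:
    """1-D profile through the FOV centre along a named anatomical axis.

    Returns (coordinates mm, values)."""
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}; valid: {sorted(AXES)}")
    a = AXES[axis]
    idx = list(smap.grid.center_index())
    sl = [idx[0], idx[1], idx[2]]
    sl[a] = slice(None)
    return smap.grid.axis_coords(a), smap.values[tuple(sl)]


def aperture_snr(
    geometry: HelmetGeometry,
    det: DetectorSpec,
    aperture: ApertureSpec,
    grid: VolumeGrid = VolumeGrid(),
    stride: int = 1,
    step: float = 0.025,
    trans_floor: float = 1e-12,
    weighted: bool = False,
    sources: "np.ndarray | None" = None,
) -> dict:
    """Aperture signal-to-noise ratio under a uniform 20-cm-FOV source.

    Rays are traced from every stride-subsampled voxel centre inside the
    FOV sphere to every pixel centre of a single MCE.  Unattenuated rays
    count as signal; partially transmitted rays contribute their
    transmission ``exp(-mu_w x)`` to the noise sum.  With ``weighted=True``
    both sums carry the per-ray solid-angle factor instead of unit weight.
    Returns a dict with ``snr``, ``n_signal``, ``n_noise`` and ``noise_sum``.
    """
    pose = geometry.mces[0]
    frame = mce_frame(pose)
    if sources is None:
        centers = grid.voxel_centers().reshape(*grid.shape, 3)
        centers = centers[::stride, ::stride, ::stride].reshape(-1, 3)
        inside = np.einsum("ij,ij->i", centers, centers) <= FOV_RADIUS_MM**2
        sources = centers[inside]
    else:
        sources = np.atleast_2d(np.asarray(sources, dtype=float))

    # exact fine march: signal rays are classified by an exactly-zero path
    opt = SRMOptions(step=step, trans_floor=trans_floor, refine=False)
    max_path = math.log(1.0 / trans_floor) / aperture.mu_w
    n_signal = 0
    n_noise = 0
    noise_sum = 0.0
    signal_sum = 0.0
    for lo in range(0, len(sources), 4096):
        paths, omega, _ = _mce_paths(
            frame, aperture, det, geometry.image_distance, sources[lo:lo + 4096], opt
        )
        sig = paths == 0.0
        noi = (paths > 0.0) & (paths <= max_path)
        w = omega if weighted else np.ones_like(paths)
        n_signal += int(sig.sum())
        n_noise += int(noi.sum())
        signal_sum += float(w[sig].sum())
        noise_sum += float((w[noi] * np.exp(-aperture.mu_w * paths[noi])).sum())
    if noise_sum == 0.0:
        warnings.warn("no noise rays found; aperture SNR is infinite")
        snr = math.inf
    else:
        snr = signal_sum / noise_sum
    return {
        "snr": snr, "n_signal": n_signal, "n_noise": n_noise,
        "signal_sum": signal_sum, "noise_sum": noise_sum,
        "n_sources": int(len(sources)),
    }
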