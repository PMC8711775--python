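"""Forward projection and Poisson noise (the linear model E[y] = A x).

Activity volumes are converted to expected emitted-photon counts per voxel
either from their total-photon normalization (brain studies: 2e9 emitted
photons) or from concentration x voxel volume x 37 kBq/uCi x imaging time x
photon yield (0.885 photons per decay for the 140.5-keV Tc-99m line).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import MCI_TO_BQ, UCI_PER_ML_TO_BQ_PER_MM3, ActivityVolume
from .system_matrix import SystemMatrix
from .geometry import DetectorSpec, mce_frame, pixel_centers_local
from .apertures import ApertureSpec
from . import _trace

__all__ = [
    "ProjectionSet",
    "emitted_photons",
    "forward_project",
    "add_poisson",
    "render_point_projection",
    "TC99M_PHOTON_YIELD",
]

TC99M_PHOTON_YIELD = 0.885


@dataclass
class ProjectionSet:
    """Flat vector of per-bin values plus the bin layout.

    ``values[m]`` follows the SRM row ordering (MCE, pixel i, pixel j, DOI
    layer, C-order).  ``counts`` marks integer Poisson realizations.
    """

    values: np.ndarray
    n_mce: int
    det: DetectorSpec
    counts: bool = False
    seed: "int | None" = None

    def __post_init__(self) -> None:
        expect = self.n_mce * self.det.n_pixels * self.det.n_doi_layers
        if self.values.shape != (expect,):
            raise ValueError(
                f"projection vector has {self.values.shape}, expected ({expect},)"
            )
        if np.any(self.values < 0):
            raise ValueError("projection values must be nonnegative")

    def mce_stack(self, idx: int) -> np.ndarray:
        """Projection of one MCE as an (n_pix_u, n_pix_v, n_doi) array."""
        b = self.det.n_pixels * self.det.n_doi_layers
        return self.values[idx * b : (idx + 1) * b].reshape(
            self.det.n_pix_u, self.det.n_pix_v, self.det.n_doi_layers
        )


def emitted_photons(x: ActivityVolume, time_s: "float | None" = None,
                    yield_per_decay: float = TC99M_PHOTON_YIELD) -> np.ndarray:
    """Expected emitted photons per voxel over the acquisition."""
    act = x.activity.astype(float)
    total = act.sum()
    if total == 0:
        return act.ravel()
    if x.total_photons is not None:
        return (act / total * x.total_photons).ravel()
    if time_s is None:
        time_s = x.imaging_time_s
    if time_s is None:
        raise ValueError("no total_photons normalization and no imaging time")
    if x.total_activity_mci is not None:
        # relative concentrations scaled so the volume totals the stated mCi
        bq = act / total * (x.total_activity_mci * MCI_TO_BQ)
    else:
        vox_mm3 = x.grid.voxel_size**3
        bq = act * UCI_PER_ML_TO_BQ_PER_MM3 * vox_mm3
    return (bq * time_s * yield_per_decay).ravel()


def forward_project(
    srm: SystemMatrix,
    x: ActivityVolume,
    time_s: "float | None" = None,
    yield_per_decay: float = TC99M_PHOTON_YIELD,
) -> ProjectionSet:
    """Noiseless mean projections ybar = A @ emitted(x)."""
    if x.grid.shape != srm.grid.shape or x.grid.voxel_size != srm.grid.voxel_size:
        raise ValueError("activity grid does not match the system matrix grid")
    ybar = srm.matrix @ emitted_photons(x, time_s, yield_per_decay)
    return ProjectionSet(values=ybar, n_mce=srm.n_mce, det=srm.det)


def add_poisson(mean: ProjectionSet, seed: int) -> ProjectionSet:
    """Independent Poisson draw per bin; reproducible for a given seed."""
    if not np.all(np.isfinite(mean.values)):
        raise ValueError("mean projections contain non-finite values")
    rng = np.random.default_rng(seed)
    y = rng.poisson(mean.values).astype(np.float64)
    return ProjectionSet(values=y, n_mce=mean.n_mce, det=mean.det,
                         counts=True, seed=seed)


def render_point_projection(
    pose,
    aperture: ApertureSpec,
    det: DetectorSpec,
    image_distance: float,
    source_position,
    subsample: int = 3,
    step: float = 0.025,
) -> np.ndarray:
    """Mean projection (summed over DOI) of an exact off-grid point source
    through one MCE, for aperture-footprint studies.

    Loftholes project a disc, micro-slits a line segment oriented with the
    slit rotation, micro-rings a narrow annulus.
    """
    frame = mce_frame(pose)
    sub = DetectorSpec(
        n_pix_u=det.n_pix_u * subsample, n_pix_v=det.n_pix_v * subsample,
        pitch=det.pitch / subsample, thickness=det.thickness,
        n_doi_layers=det.n_doi_layers, layer_thickness=det.layer_thickness,
        mu_czt=det.mu_czt,
    )
    targets = pixel_centers_local(sub, image_distance)
    origin = frame.to_local(np.asarray(source_position, dtype=float)).reshape(1, 3)
    max_path = np.log(1e9) / aperture.mu_w
    prune = max_path * (1.0 + aperture.max_tan) / 2.0 * 1.3
    paths = np.empty((1, len(targets)))
    _trace.trace_paths(
        origin, targets, aperture.kind_code, aperture.params(),
        step, max_path, prune, 0.25, paths,
    )
    t = np.where(paths[0] <= max_path, np.exp(-aperture.mu_w * paths[0]), 0.0)
    t[paths[0] == 0.0] = 1.0
    img = t.reshape(det.n_pix_u, subsample, det.n_pix_v, subsample).sum(axis=(1, 3))
    return img / subsample**2
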