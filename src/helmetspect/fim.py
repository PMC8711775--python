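"""Fisher-information-matrix (FIM) column images and profile analysis.

For the linear Poisson model the FIM is J = A^T diag(1/ybar) A with ybar
the mean projection of a uniform-FOV object.  A "FIM image" is one column
J_l rearranged on the object grid: its spread around the target voxel l
visualizes the system's intrinsic spatial resolution, and its peak the
information density, so competing aperture designs can be ranked without
running reconstructions.  Columns are computed on demand; the full M x N
product is never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system_matrix import SystemMatrix

__all__ = ["FIMImage", "fim_column", "profile_fwhm", "peak_ratio",
           "isotropy_report", "default_isotropy_positions"]

DIRECTIONS = {"lateral": 0, "ventrodorsal": 1, "craniocaudal": 2}


@dataclass(frozen=True)
class FIMImage:
    """One FIM column J_l on the object grid."""

    target_index: tuple[int, int, int]
    values: np.ndarray
    voxel_size: float

    @property
    def peak(self) -> float:
        return float(self.values[self.target_index])


def fim_column(srm: SystemMatrix, ybar: np.ndarray, target) -> FIMImage:
    """J_l[n] = sum_m a_ml a_mn / ybar_m for every voxel n.

    ``ybar`` is the mean uniform-object projection (bins with ybar = 0 are
    excluded); ``target`` is a voxel index triple or flat index.
    """
    vals = np.asarray(ybar, dtype=float).ravel()
    if vals.shape[0] != srm.matrix.shape[0]:
        raise ValueError("ybar length does not match SRM rows")
    if np.isscalar(target) or np.ndim(target) == 0:
        flat = int(target)
        idx = tuple(int(i) for i in np.unravel_index(flat, srm.grid.shape))
    else:
        idx = tuple(int(i) for i in target)
        flat = int(np.ravel_multi_index(idx, srm.grid.shape))
    col = srm.column(flat)
    if col.sum() == 0:
        raise ValueError("target voxel has zero system response (outside FOV?)")
    w = np.divide(col, vals, out=np.zeros_like(col), where=vals > 0)
    j = srm.matrix.T @ w
    return FIMImage(
        target_index=idx,
        values=np.asarray(j).reshape(srm.grid.shape),
        voxel_size=srm.grid.voxel_size,
    )


def _profile(image: FIMImage, direction: str) -> tuple[np.ndarray, np.ndarray]:
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}; valid: {sorted(DIRECTIONS)}")
    ax = DIRECTIONS[direction]
    sl = list(image.target_index)
    sl[ax] = slice(None)
    prof = image.values[tuple(sl)]
    n = prof.shape[0]
    coords = (np.arange(n) - image.target_index[ax]) * image.voxel_size
    return coords, prof


def profile_fwhm(image: FIMImage, direction: str) -> float:
    """Full width at half maximum of the 1-D profile through the target
    voxel, with the half-maximum crossings located by linear interpolation."""
    coords, prof = _profile(image, direction)
    i0 = int(image.target_index[DIRECTIONS[direction]])
    if prof[i0] <= 0 or prof[i0] < 0.8 * prof.max():
        raise ValueError("profile maximum is not at the target voxel")
    # walk from the profile maximum: discretization can put the top one
    # voxel off the target when the peak is locally flat
    i0 = int(np.argmax(prof))
    peak = prof[i0]
    half = peak / 2.0

    def crossing(side: int) -> float:
        i = i0
        while 0 <= i + side < len(prof):
            j = i + side
            if prof[j] < half:
                # linear interpolation between samples i and j
                frac = (prof[i] - half) / (prof[i] - prof[j])
                return coords[i] + frac * (coords[j] - coords[i])
            i = j
        raise ValueError(
            f"profile never falls below half maximum on the {'right' if side > 0 else 'left'}"
        )

    return float(crossing(+1) - crossing(-1))


def default_isotropy_positions() -> np.ndarray:
    """The 18 off-centre probe positions: +-2.5, 5 and 7.5 cm from the FOV
    centre along each anatomical axis."""
    out = []
    for ax in range(3):
        for d in (25.0, 50.0, 75.0):
            for sign in (+1.0, -1.0):
                p = [0.0, 0.0, 0.0]
                p[ax] = sign * d
                out.append(p)
    return np.array(out)


def isotropy_report(
    srm: SystemMatrix, ybar: np.ndarray, positions: "np.ndarray | None" = None
) -> list[dict]:
    """Per-position FIM FWHMs in the three directions, for judging how
    isotropic the resolution stays away from the FOV centre.

    Positions outside the grid or whose FIM image has no usable peak are
    reported with NaN widths rather than aborting the report.
    """
    if positions is None:
        positions = default_isotropy_positions()
    rows = []
    for p in np.atleast_2d(positions):
        row = {"position_mm": [float(v) for v in p]}
        try:
            idx = srm.grid.world_to_index(p)
            img = fim_column(srm, ybar, idx)
            for d in DIRECTIONS:
                try:
                    row[f"fwhm_{d}_mm"] = profile_fwhm(img, d)
                except ValueError:
                    row[f"fwhm_{d}_mm"] = float("nan")
        except ValueError:
            for d in DIRECTIONS:
                row[f"fwhm_{d}_mm"] = float("nan")
        rows.append(row)
    return rows


def peak_ratio(image_a: FIMImage, image_b: FIMImage) -> float:
    """peak(a) / peak(b) for two FIM images of the same target voxel."""
    if image_a.target_index != image_b.target_index:
        raise ValueError("FIM images target different voxels")
    if image_b.peak == 0:
        raise ValueError("second FIM image has zero peak")
    return image_a.peak / image_b.peak
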