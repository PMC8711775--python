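"""Image-quality and quantification metrics.

NRMSE, contrast recovery coefficient (CRC), contrast-to-noise ratio (CNR),
noise coefficient (NC), CRC-NC curves, uptake ratio (UR) against a
cerebellar reference, and the inter-hemispheric asymmetry index (AI).
ROI statistics use voxels whose centres fall inside the ROI mask, with no
partial-volume weighting.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "nrmse",
    "roi_mean",
    "roi_std",
    "crc",
    "cnr",
    "nc",
    "crc_nc_curve",
    "uptake_ratio",
    "asymmetry_index",
    "best_cnr_iteration",
]


def _as_mask(roi) -> np.ndarray:
    mask = roi.mask if hasattr(roi, "mask") else np.asarray(roi)
    return mask.astype(bool)


def roi_mean(image: np.ndarray, roi) -> float:
    return float(image[_as_mask(roi)].mean())


def roi_std(image: np.ndarray, roi) -> float:
    return float(image[_as_mask(roi)].std(ddof=0))


def nrmse(x: np.ndarray, x_true: np.ndarray) -> float:
    """sqrt(sum((x - x_T)^2)) / sqrt(sum(x_T^2))."""
    x = np.asarray(x, dtype=float).ravel()
    t = np.asarray(x_true, dtype=float).ravel()
    if x.shape != t.shape:
        raise ValueError("image and truth shapes differ")
    denom = np.sqrt(np.sum(t * t))
    if denom == 0:
        raise ValueError("truth image is identically zero")
    return float(np.sqrt(np.sum((x - t) ** 2)) / denom)


def crc(image: np.ndarray, rod_roi, bck_roi, C: float) -> float:
    """Contrast recovery coefficient in percent: 100% means the measured
    rod-to-background ratio equals the true ratio C."""
    if C <= 1:
        raise ValueError("true contrast C must exceed 1")
    mu_rod = roi_mean(image, rod_roi)
    mu_bck = roi_mean(image, bck_roi)
    if mu_bck == 0:
        raise ValueError("background mean is zero")
    return ((mu_rod - mu_bck) / mu_bck) / (C - 1.0) * 100.0


def cnr(image: np.ndarray, roi, bck_roi) -> float:
    """|mu_roi - mu_bck| / sigma_bck."""
    sigma = roi_std(image, bck_roi)
    if sigma == 0:
        raise ValueError("background standard deviation is zero")
    return abs(roi_mean(image, roi) - roi_mean(image, bck_roi)) / sigma


def nc(image: np.ndarray, bck_roi) -> float:
    """Noise coefficient in percent: sigma_bck / mu_bck * 100."""
    mu = roi_mean(image, bck_roi)
    if mu == 0:
        raise ValueError("background mean is zero")
    return roi_std(image, bck_roi) / mu * 100.0


def crc_nc_curve(images, rod_roi, bck_roi, C: float) -> np.ndarray:
    """(NC, CRC) point per iteration image; shape (n_iter, 2)."""
    return np.array([[nc(im, bck_roi), crc(im, rod_roi, bck_roi, C)] for im in images])


def uptake_ratio(image: np.ndarray, voi, reference_voi) -> float:
    """mu_voi / mu_reference."""
    mu_ref = roi_mean(image, reference_voi)
    if mu_ref == 0:
        raise ValueError("reference VOI mean is zero")
    return roi_mean(image, voi) / mu_ref


def asymmetry_index(image: np.ndarray, voi_left, voi_right) -> float:
    """(mu_L - mu_R) / mu_R, signed."""
    mu_r = roi_mean(image, voi_right)
    if mu_r == 0:
        raise ValueError("right-hemisphere VOI mean is zero")
    return (roi_mean(image, voi_left) - mu_r) / mu_r


def best_cnr_iteration(images, roi, bck_roi) -> int:
    """1-based iteration index with the maximum CNR (earliest on ties)."""
    values = [cnr(im, roi, bck_roi) for im in images]
    if not values:
        raise ValueError("empty image trace")
    return int(np.argmax(values)) + 1
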