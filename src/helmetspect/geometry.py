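"""Helmet geometry: micro-camera-element (MCE) poses on the spherical support.

The helmet is a synthetic compound-eye (SCE) arrangement of 502 MCEs, each a
20 mm x 20 mm pixelated CZT module behind a single minifying aperture.  All
aperture planes are tangent to a sphere of radius ``D_a`` centred on the
field-of-view (FOV) centre, with every camera axis pointing at that centre.
The hemispherical section holds 345 modules (11 full rings plus a top-cover
module on the pole); the neck section holds 157 modules on 7 partial rings
spanning 180 degrees of azimuth, leaving a frontal opening for the face.

World frame: right-handed, origin at the FOV centre, +z craniocaudal (toward
the vertex), +y ventro-dorsal (toward the back of the head), +x lateral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectorSpec",
    "MCEPose",
    "MCEFrame",
    "HelmetGeometry",
    "GeometryConfigError",
    "build_helmet",
    "default_ring_layout",
    "mce_frame",
    "pixel_center",
    "pixel_centers_local",
]

#: Aperture-plane-to-FOV-centre distance in mm.  With a 1:12 minification the
#: aperture-to-detector distance is D_A / 12.
DEFAULT_FOCAL_DISTANCE_MM = 183.23
DEFAULT_MF_DENOMINATOR = 12
DEFAULT_SUPPORT_RADIUS_MM = 196.0  # nominal mounting radius, informational
DEFAULT_N_MCE = 502
DEFAULT_NECK_ARC_DEG = 180.0


class GeometryConfigError(ValueError):
    """Raised for inconsistent helmet configuration parameters."""


@dataclass(frozen=True)
class DetectorSpec:
    """Pixelated CZT module: 80 x 80 pixels of 0.25 mm pitch, 5 mm thick,
    read out as five independent 1-mm depth-of-interaction (DOI) layers."""

    n_pix_u: int = 80
    n_pix_v: int = 80
    pitch: float = 0.25
    thickness: float = 5.0
    n_doi_layers: int = 5
    layer_thickness: float = 1.0
    mu_czt: float = 0.354  # linear attenuation of CZT at 140 keV, mm^-1

    def __post_init__(self) -> None:
        if abs(self.n_doi_layers * self.layer_thickness - self.thickness) > 1e-9:
            raise GeometryConfigError(
                "DOI layers do not tile the crystal: "
                f"{self.n_doi_layers} x {self.layer_thickness} != {self.thickness}"
            )

    @property
    def width_u(self) -> float:
        return self.n_pix_u * self.pitch

    @property
    def width_v(self) -> float:
        return self.n_pix_v * self.pitch

    @property
    def n_pixels(self) -> int:
        return self.n_pix_u * self.n_pix_v


@dataclass(frozen=True)
class MCEPose:
    """Pose of one micro-camera element.

    ``aperture_center`` lies on the sphere of radius D_a; ``axis`` is the unit
    vector from the aperture centre toward the FOV centre; ``basis_u`` and
    ``basis_v`` span the aperture plane so that (u, v, -axis) is right-handed.
    """

    ring_index: int
    azimuth_deg: float
    aperture_center: np.ndarray
    axis: np.ndarray
    basis_u: np.ndarray
    basis_v: np.ndarray
    aperture_id: int = 0


@dataclass(frozen=True)
class HelmetGeometry:
    support_radius: float
    focal_distance: float  # D_a, aperture plane to FOV centre
    image_distance: float  # f, aperture plane to detector entrance face
    mces: tuple[MCEPose, ...]
    ring_counts: tuple[int, ...]
    neck_arc_deg: float = DEFAULT_NECK_ARC_DEG
    n_hemisphere: int = 345
    n_neck: int = 157

    @property
    def mf(self) -> float:
        """Minification factor f / D_a (1:12 by default)."""
        return self.image_distance / self.focal_distance

    @property
    def n_mce(self) -> int:
        return len(self.mces)

    def centers(self) -> np.ndarray:
        return np.array([m.aperture_center for m in self.mces])

    def to_table(self) -> str:
        """Plain-text export, one MCE per row."""
        lines = ["# ring azimuth_deg cx cy cz ax ay az aperture_id"]
        for m in self.mces:
            c, a = m.aperture_center, m.axis
            lines.append(
                f"{m.ring_index} {m.azimuth_deg:.4f} "
                f"{c[0]:.6f} {c[1]:.6f} {c[2]:.6f} "
                f"{a[0]:.9f} {a[1]:.9f} {a[2]:.9f} {m.aperture_id}"
            )
        return "\n".join(lines) + "\n"


def default_ring_layout(
    n_total: int = DEFAULT_N_MCE,
    n_hemisphere: int = 345,
    n_neck: int = 157,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribute modules over rings proportionally to ring circumference.

    Returns (colatitudes_deg, counts) for the top cover (colatitude 0),
    11 full hemisphere rings, and 7 half-rings in the neck section.  The
    published per-ring counts are not in the open literature; any layout
    summing to the section totals can be supplied through ``ring_counts``.
    """
    if n_hemisphere + n_neck != n_total:
        raise GeometryConfigError(
            f"section counts {n_hemisphere}+{n_neck} != total {n_total}"
        )
    n_full_rings, n_neck_rings = 11, 7
    # top cover on the pole, rings evenly spaced in colatitude down the neck
    phi_first, phi_equator = 8.2, 90.0
    dphi = (phi_equator - phi_first) / (n_full_rings - 1)
    phi_full = phi_first + dphi * np.arange(n_full_rings)
    phi_neck = phi_equator + dphi * (1 + np.arange(n_neck_rings))
    counts_full = _proportional_counts(np.sin(np.radians(phi_full)), n_hemisphere - 1)
    # half-rings: weight is still sin(phi) (they share a common 180 deg arc)
    counts_neck = _proportional_counts(np.sin(np.radians(phi_neck)), n_neck)
    phis = np.concatenate(([0.0], phi_full, phi_neck))
    counts = np.concatenate(([1], counts_full, counts_neck))
    return phis, counts


def _proportional_counts(weights: np.ndarray, total: int) -> np.ndarray:
    raw = weights / weights.sum() * total
    counts = np.floor(raw).astype(int)
    # hand out the remainder to the largest fractional parts, deterministically
    frac = raw - counts
    for idx in np.argsort(-frac, kind="stable")[: total - counts.sum()]:
        counts[idx] += 1
    return counts


def _ring_pose(
    phi_deg: float, az_deg: float, ring_index: int, d_a: float
) -> MCEPose:
    phi, az = np.radians(phi_deg), np.radians(az_deg)
    n = np.array(
        [np.sin(phi) * np.cos(az), np.sin(phi) * np.sin(az), np.cos(phi)]
    )
    center = d_a * n
    axis = -n
    if abs(n[2]) > 1.0 - 1e-12:  # pole: azimuthal direction undefined
        u = np.array([1.0, 0.0, 0.0])
    else:
        u = np.cross([0.0, 0.0, 1.0], n)
        u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return MCEPose(
        ring_index=ring_index,
        azimuth_deg=az_deg % 360.0,
        aperture_center=center,
        axis=axis,
        basis_u=u,
        basis_v=v,
    )


def build_helmet(
    focal_distance: float = DEFAULT_FOCAL_DISTANCE_MM,
    mf_denominator: float = DEFAULT_MF_DENOMINATOR,
    support_radius: float = DEFAULT_SUPPORT_RADIUS_MM,
    ring_counts: "np.ndarray | None" = None,
    ring_colatitudes_deg: "np.ndarray | None" = None,
    n_total: int = DEFAULT_N_MCE,
    n_hemisphere: int = 345,
    n_neck: int = 157,
    neck_arc_deg: float = DEFAULT_NECK_ARC_DEG,
) -> HelmetGeometry:
    """Construct the helmet geometry.

    Adjacent full rings are azimuthally offset by half the ring's angular
    pitch so the trans-axial views interleave.  Neck half-rings span exactly
    ``neck_arc_deg`` of azimuth centred on the dorsal (+y) direction; the
    frontal half is left open.  Construction is fully deterministic.
    """
    if focal_distance <= 0:
        raise GeometryConfigError("focal distance must be positive")
    if ring_counts is None:
        phis, counts = default_ring_layout(n_total, n_hemisphere, n_neck)
    else:
        counts = np.asarray(ring_counts, dtype=int)
        if ring_colatitudes_deg is None:
            phis, _ = default_ring_layout(n_total, n_hemisphere, n_neck)
            if len(counts) != len(phis):
                raise GeometryConfigError(
                    f"ring_counts has {len(counts)} rings, layout has {len(phis)}"
                )
        else:
            phis = np.asarray(ring_colatitudes_deg, dtype=float)
        if counts.sum() != n_total:
            raise GeometryConfigError(
                f"ring_counts sum to {counts.sum()}, expected {n_total}"
            )

    n_full_rings = int(np.sum(phis < 90.0 + 1e-9)) - 1  # excludes top cover
    mces: list[MCEPose] = []
    for r, (phi, cnt) in enumerate(zip(phis, counts)):
        if r == 0:  # top cover
            mces.append(_ring_pose(0.0, 0.0, 0, focal_distance))
            continue
        if r <= n_full_rings:  # full ring, half-pitch stagger between rings
            pitch = 360.0 / cnt
            offset = 0.5 * pitch * (r % 2)
            azs = offset + pitch * np.arange(cnt)
        else:  # neck half-ring centred on +y (dorsal); frontal opening at -y
            pitch = neck_arc_deg / cnt
            azs = (90.0 - neck_arc_deg / 2.0) + (np.arange(cnt) + 0.5) * pitch
        for az in azs:
            mces.append(_ring_pose(phi, az, r, focal_distance))

    if len(mces) != n_total:
        raise GeometryConfigError(
            f"layout produced {len(mces)} MCEs, expected {n_total}"
        )
    return HelmetGeometry(
        support_radius=support_radius,
        focal_distance=focal_distance,
        image_distance=focal_distance / mf_denominator,
        mces=tuple(mces),
        ring_counts=tuple(int(c) for c in counts),
        neck_arc_deg=neck_arc_deg,
        n_hemisphere=n_hemisphere,
        n_neck=n_neck,
    )


@dataclass(frozen=True)
class MCEFrame:
    """Rigid transform between the world frame and an MCE-local frame.

    Local origin is the aperture centre; +w points along the camera axis
    toward the detector (away from the FOV centre); (u, v) span the aperture
    plane.  The FOV centre maps to local (0, 0, -D_a).
    """

    origin: np.ndarray
    rot: np.ndarray  # rows are (u, v, w) expressed in world coordinates

    def to_local(self, p: np.ndarray) -> np.ndarray:
        return (np.asarray(p, dtype=float) - self.origin) @ self.rot.T

    def to_world(self, p: np.ndarray) -> np.ndarray:
        return np.asarray(p, dtype=float) @ self.rot + self.origin


def mce_frame(pose: MCEPose) -> MCEFrame:
    w = -np.asarray(pose.axis, dtype=float)
    nrm = np.linalg.norm(w)
    if not np.isfinite(nrm) or nrm < 1e-12:
        raise GeometryConfigError("degenerate MCE axis")
    rot = np.vstack([pose.basis_u, pose.basis_v, w / nrm])
    return MCEFrame(origin=np.asarray(pose.aperture_center, dtype=float), rot=rot)


def pixel_centers_local(
    det: DetectorSpec, image_distance: float, depth: "float | None" = None
) -> np.ndarray:
    """Local (u, v, w) coordinates of all pixel centres, C-ordered over (i, j).

    ``depth`` is measured behind the detector entrance face (at w = f); it
    defaults to mid-crystal.
    """
    if depth is None:
        depth = det.thickness / 2.0
    u = (np.arange(det.n_pix_u) + 0.5 - det.n_pix_u / 2.0) * det.pitch
    v = (np.arange(det.n_pix_v) + 0.5 - det.n_pix_v / 2.0) * det.pitch
    uu, vv = np.meshgrid(u, v, indexing="ij")
    out = np.empty((det.n_pix_u * det.n_pix_v, 3))
    out[:, 0] = uu.ravel()
    out[:, 1] = vv.ravel()
    out[:, 2] = image_distance + depth
    return out


def pixel_center(
    pose: MCEPose,
    det: DetectorSpec,
    image_distance: float,
    i: int,
    j: int,
    k: int,
) -> np.ndarray:
    """World coordinate of the centre of pixel (i, j) in DOI layer k."""
    if not (0 <= i < det.n_pix_u and 0 <= j < det.n_pix_v):
        raise IndexError(f"pixel index ({i}, {j}) out of range")
    if not (0 <= k < det.n_doi_layers):
        raise IndexError(f"DOI layer {k} out of range")
    u = (i + 0.5 - det.n_pix_u / 2.0) * det.pitch
    v = (j + 0.5 - det.n_pix_v / 2.0) * det.pitch
    w = image_distance + (k + 0.5) * det.layer_thickness
    return mce_frame(pose).to_world(np.array([u, v, w]))
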