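"""Digital phantoms on the standard 96^3 x 2-mm grid.

All phantoms are deterministic functions of their configuration: a Defrise
disk phantom for axial-sampling assessment, quadrant hot-rod phantoms for
resolution and contrast, two-point sources for projection-footprint
studies, a uniform FOV sphere, and a parametric ictal-brain stand-in with
lateralized volumes of interest (VOIs), a hyperperfused left temporal pole,
and optional low-contrast focal lesions.

Activity fields are in activity-concentration units (uCi/mL) unless a
phantom is defined by relative concentrations and a total-activity
normalization; conversion to emitted photons happens at simulation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .system_matrix import FOV_RADIUS_MM, VolumeGrid

__all__ = [
    "ActivityVolume",
    "ROISpec",
    "defrise_phantom",
    "hot_rod_phantom",
    "brain_phantom",
    "point_sources",
    "uniform_fov",
    "MCI_TO_BQ",
    "UCI_PER_ML_TO_BQ_PER_MM3",
]

MCI_TO_BQ = 3.7e7
UCI_PER_ML_TO_BQ_PER_MM3 = 3.7e4 / 1000.0  # 1 uCi/mL = 37 Bq/mm^3


@dataclass(frozen=True)
class ROISpec:
    """A named region of interest as an explicit voxel mask."""

    name: str
    role: str  # rod | background_rod | lesion | reference | voi_left | voi_right | fov
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not np.any(self.mask):
            raise ValueError(f"ROI {self.name!r} rasterized to an empty voxel set")

    def mean(self, image: np.ndarray) -> float:
        return float(image[self.mask].mean())

    def std(self, image: np.ndarray) -> float:
        return float(image[self.mask].std(ddof=0))


@dataclass
class ActivityVolume:
    """Activity field with optional VOI labels and normalization metadata."""

    grid: VolumeGrid
    activity: np.ndarray
    labels: "np.ndarray | None" = None
    rois: dict = field(default_factory=dict)
    total_photons: "float | None" = None
    total_activity_mci: "float | None" = None
    imaging_time_s: "float | None" = None

    def __post_init__(self) -> None:
        if self.activity.shape != self.grid.shape:
            raise ValueError("activity shape does not match grid")
        if np.any(self.activity < 0):
            raise ValueError("activity must be nonnegative")
        if self.labels is not None:
            hot_unlabeled = (self.activity > 0) & (self.labels == 0)
            if np.any(hot_unlabeled):
                raise ValueError("labels do not cover all nonzero-activity voxels")

    def add_roi(self, roi: ROISpec) -> None:
        self.rois[roi.name] = roi


def _radii(grid: VolumeGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x = grid.axis_coords(0)[:, None, None]
    y = grid.axis_coords(1)[None, :, None]
    z = grid.axis_coords(2)[None, None, :]
    return x, y, z, np.sqrt(x * x + y * y + 0.0 * z)


def defrise_phantom(grid: VolumeGrid = VolumeGrid(), disk_mm: float = 6.0,
                    sphere_diameter: float = 160.0) -> ActivityVolume:
    """Defrise phantom: uniform disks of 6-mm thickness and spacing clipped
    to a 16-cm sphere, axis craniocaudal.  Slab boundaries sit at z = 0, so
    a disk occupies z mod 12 mm in [0, 6) and 14 disks are nonempty."""
    x, y, z, _ = _radii(grid)
    r2 = x * x + y * y + z * z
    in_sphere = r2 <= (sphere_diameter / 2.0) ** 2
    in_disk = np.mod(z, 2.0 * disk_mm) < disk_mm
    act = np.where(in_sphere & in_disk, 1.0, 0.0)
    vol = ActivityVolume(grid=grid, activity=act)
    vol.add_roi(ROISpec("sphere", "fov", np.broadcast_to(in_sphere, grid.shape).copy()))
    return vol


def _rod_centers(diameter: float, sector: int, cyl_radius: float) -> np.ndarray:
    """Triangular lattice of rod centres at 2x diameter pitch inside one
    90-degree sector, keeping one rod diameter clear of the cylinder wall
    and the sector boundaries."""
    pitch = 2.0 * diameter
    r_max = cyl_radius - 1.5 * diameter  # wall margin: one clear diameter
    pts = []
    n_rows = int(r_max / (pitch * math.sqrt(3) / 2)) + 2
    n_cols = int(r_max / pitch) + 2
    for row in range(n_rows + 1):
        yy = row * pitch * math.sqrt(3) / 2 + 1.5 * diameter
        x0 = (row % 2) * pitch / 2 + 1.5 * diameter
        for col in range(n_cols + 1):
            xx = x0 + col * pitch
            if math.hypot(xx, yy) <= r_max:
                pts.append((xx, yy))
    pts = np.array(pts) if pts else np.empty((0, 2))
    ang = math.radians(90.0 * sector)
    rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
    return pts @ rot.T


def hot_rod_phantom(
    grid: VolumeGrid = VolumeGrid(),
    s_b_ratio: float = 20.0,
    diameters: tuple = (4.0, 6.0, 8.0, 10.0),
    cyl_diameter: float = 160.0,
    cyl_length: float = 80.0,
    rod_total_mci: float = 1.0,
    bck_total_mci: "float | None" = None,
) -> ActivityVolume:
    """Quadrant hot-rod phantom in a 160-mm-D x 80-mm-L cylinder (axis
    craniocaudal).  Rod groups of 4/6/8/10-mm diameter at centre-to-centre
    spacing of twice the diameter; rod-to-background concentration ratio is
    authoritative (20:1 or 5:1) and the stated totals are applied by a
    single global scale afterwards.

    ROIs: the rod of each group closest to the central axis, and the
    central 8 x 8-voxel background column through the full length."""
    if bck_total_mci is None:
        bck_total_mci = {20.0: 0.5, 5.0: 2.0}.get(s_b_ratio, 1.0)
    x, y, z, rxy = _radii(grid)
    in_cyl = (rxy <= cyl_diameter / 2.0) & (np.abs(z) <= cyl_length / 2.0)
    in_cyl = np.broadcast_to(in_cyl, grid.shape)
    act = np.where(in_cyl, 1.0, 0.0)

    vol = ActivityVolume(grid=grid, activity=act)
    xx = grid.axis_coords(0)[:, None]
    yy = grid.axis_coords(1)[None, :]
    in_z = np.abs(grid.axis_coords(2)) <= cyl_length / 2.0
    rod_union = np.zeros(grid.shape[:2], dtype=bool)
    for sector, d in enumerate(diameters):
        centers = _rod_centers(d, sector, cyl_diameter / 2.0)
        if len(centers) == 0:
            raise ValueError(f"no {d}-mm rods fit the cylinder")
        nearest = centers[np.argmin(np.linalg.norm(centers, axis=1))]
        group = np.zeros(grid.shape[:2], dtype=bool)
        for cx, cy in centers:
            group |= (xx - cx) ** 2 + (yy - cy) ** 2 <= (d / 2.0) ** 2
        rod_union |= group
        m3 = ((xx - nearest[0]) ** 2 + (yy - nearest[1]) ** 2 <= (d / 2.0) ** 2)[
            :, :, None
        ] & in_z[None, None, :]
        vol.add_roi(ROISpec(f"rod_{d:g}mm", "rod", np.broadcast_to(m3, grid.shape).copy()))
    act[rod_union[:, :, None] & in_z[None, None, :] & in_cyl] = s_b_ratio

    # central 8x8-voxel background column
    n0, n1, _ = grid.shape
    bck = np.zeros(grid.shape, dtype=bool)
    bck[n0 // 2 - 4 : n0 // 2 + 4, n1 // 2 - 4 : n1 // 2 + 4, :] = True
    bck &= in_z[None, None, :]
    vol.add_roi(ROISpec("background_rod", "background_rod", bck))

    # concentration ratio is authoritative; the stated totals only set the
    # global scale (activity stays in relative units, background = 1)
    vol.activity = act
    vol.total_activity_mci = rod_total_mci + bck_total_mci
    vol.imaging_time_s = 30 * 60.0
    return vol


#: default 16 bilateral VOI pairs of the ictal-brain stand-in.
#: (name, centre_x>0 mm, cy, cz, radius mm, right conc uCi/mL, asymmetry AI)
#: The left (ictal) hemisphere concentration is right * (1 + AI); the
#: temporal-pole pair is pinned so the left TPo is 0.07 uCi/mL.
_BRAIN_VOIS = (
    ("TPo",        48, -38, -18,  7, 0.056, 0.250),
    ("TM",         34, -20, -22,  8, 0.058, 0.200),
    ("TL",         56, -12,  -12, 9, 0.060, 0.150),
    ("Frontal",    30,  46,  18, 13, 0.066, 0.060),
    ("Parietal",   32, -10,  44, 13, 0.066, 0.050),
    ("Occipital",  22, -62,   8, 11, 0.064, 0.040),
    ("Insula",     34,   6,   2,  7, 0.062, 0.090),
    ("CN",         12,  12,   8,  6, 0.064, 0.080),
    ("LN",         22,   2,   0,  6, 0.064, 0.070),
    ("Thalamus",   10, -12,   6,  6, 0.066, 0.050),
    ("Hippocampus",28, -26, -14,  6, 0.058, 0.180),
    ("Amygdala",   24, -10, -18,  5, 0.058, 0.160),
    ("Cingulate",   6,  10,  28,  7, 0.064, 0.060),
    ("Precuneus",   8, -52,  36,  9, 0.064, 0.040),
    ("SMA",        10,  18,  48,  8, 0.066, 0.030),
    ("Cerebellum", 28, -54, -34, 12, 0.068, 0.020),
)

#: lesion spheres of the low-contrast detectability variant:
#: (name, host VOI, diameter mm, lesion:background contrast)
_BRAIN_LESIONS = (
    ("lesion_1", "TPo", 5.0, 3.0),
    ("lesion_2", "TL", 6.0, 2.5),
    ("lesion_3", "TM", 7.0, 2.0),
    ("lesion_4", "TL", 8.0, 1.5),
)


def brain_phantom(
    grid: VolumeGrid = VolumeGrid(),
    white_matter: float = 0.056,
    left_tpo: float = 0.07,
    lesions: bool = False,
    total_photons: float = 2e9,
    voi_table=_BRAIN_VOIS,
) -> ActivityVolume:
    """Parametric ictal-brain perfusion stand-in.

    A two-hemisphere head ellipsoid filled with white-matter background
    (0.056 uCi/mL) hosts 16 bilateral VOI pairs (32 lateralized VOIs) with
    per-VOI concentrations and inter-hemispheric asymmetries; the left
    temporal pole (ictal side) is pinned at 0.07 uCi/mL.  The reference
    region is an 8-mm sphere inside the right cerebellum.  With
    ``lesions=True`` four spheres of 5/6/7/8-mm diameter are added in the
    left TPo/TL/TM/TL at contrasts 3/2.5/2/1.5 relative to white matter.

    This is a geometric stand-in, not an anatomical atlas: VOI shapes are
    spheres at plausible stereotactic positions so that uptake-ratio and
    asymmetry metrics are exercisable end to end.
    """
    x, y, z, _ = _radii(grid)
    head = (x / 70.0) ** 2 + (y / 85.0) ** 2 + ((z + 5.0) / 62.0) ** 2 <= 1.0
    head = np.broadcast_to(head, grid.shape).copy()
    act = np.where(head, white_matter, 0.0)
    labels = np.where(head, 1, 0).astype(np.int16)  # label 1 = white matter
    vol = ActivityVolume(grid=grid, activity=act, labels=None)

    label = 2
    voi_centers = {}
    for name, cx, cy, cz, rad, conc_r, ai in voi_table:
        for side, sgn in (("R", 1.0), ("L", -1.0)):
            cxs = sgn * cx
            m = (x - cxs) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= rad**2
            m = np.broadcast_to(m, grid.shape) & head
            conc = conc_r if side == "R" else conc_r * (1.0 + ai)
            if name == "TPo" and side == "L":
                conc = left_tpo  # pinned: hottest ictal region
            act[m] = conc
            labels[m] = label
            roi = ROISpec(f"{name}_{side}", "voi_left" if side == "L" else "voi_right", m.copy())
            vol.add_roi(roi)
            voi_centers[f"{name}_{side}"] = (cxs, cy, cz)
            label += 1

    # reference: 8-mm sphere centred in the right cerebellum
    ccx, ccy, ccz = voi_centers["Cerebellum_R"]
    ref = (x - ccx) ** 2 + (y - ccy) ** 2 + (z - ccz) ** 2 <= 4.0**2
    ref = np.broadcast_to(ref, grid.shape) & head
    vol.add_roi(ROISpec("reference", "reference", ref.copy()))

    if lesions:
        host_centers = {"TPo": voi_centers["TPo_L"], "TL": voi_centers["TL_L"],
                        "TM": voi_centers["TM_L"]}
        used = np.zeros(grid.shape, dtype=bool)
        offsets = {"lesion_1": (0, 0, 0), "lesion_2": (0, 6, 0),
                   "lesion_3": (0, 0, 0), "lesion_4": (0, -7, 0)}
        for name, host, diam, contrast in _BRAIN_LESIONS:
            cx, cy, cz = host_centers[host]
            ox, oy, oz = offsets[name]
            m = (x - cx - ox) ** 2 + (y - cy - oy) ** 2 + (z - cz - oz) ** 2 <= (
                diam / 2.0
            ) ** 2
            m = np.broadcast_to(m, grid.shape) & head
            if np.any(m & used):
                raise ValueError(f"{name} overlaps another lesion in {host}")
            used |= m
            act[m] = contrast * white_matter
            labels[m] = label
            vol.add_roi(ROISpec(name, "lesion", m.copy()))
            label += 1

    # white matter background ROI: head voxels not in any VOI or lesion
    wm = head & (labels == 1)
    vol.add_roi(ROISpec("white_matter", "background_rod", wm))
    vol.activity = act
    vol.labels = labels
    vol.total_photons = total_photons
    return vol


def point_sources(
    grid: VolumeGrid, positions, strengths=None
) -> ActivityVolume:
    """Delta-like sources at the voxels nearest the given world positions."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if strengths is None:
        strengths = np.ones(len(positions))
    strengths = np.asarray(strengths, dtype=float)
    act = np.zeros(grid.shape)
    for p, s in zip(positions, strengths):
        if np.dot(p, p) > FOV_RADIUS_MM**2:
            raise ValueError(f"point source {p} outside the FOV sphere")
        act[grid.world_to_index(p)] += s
    return ActivityVolume(grid=grid, activity=act)


def uniform_fov(grid: VolumeGrid = VolumeGrid(), value: float = 1.0) -> ActivityVolume:
    """Uniform activity inside the 20-cm FOV sphere, zero outside."""
    mask = grid.fov_mask()
    return ActivityVolume(grid=grid, activity=np.where(mask, value, 0.0))
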