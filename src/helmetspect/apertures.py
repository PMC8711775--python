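"""Parametric tungsten apertures: lofthole, micro-slit and micro-ring.

Each aperture is a 20-mm tungsten slab pierced by an open channel that
pinches to the nominal opening at the aperture plane and flares toward the
object with acceptance half-angle(s) alpha and toward the detector with
exit half-angle(s) beta:

* lofthole — circular opening of diameter ``d`` lofted into square channel
  cross-sections at the slab faces (square entry/exit profiles tile the
  projection efficiently onto the square detector);
* micro-slit — rectangular opening ``w x l`` with independent alpha/beta per
  direction; the opening and lower profile are rotated by ``theta`` about
  the camera axis while the upper profile stays squared to the module
  footprint;
* micro-ring — annular opening between a flared outer piece and a central
  plug that tapers away from the plane in both directions.

Transmission through the remaining tungsten follows Beer-Lambert,
``I/I0 = exp(-mu_w * x)`` with ``x`` the chord length in tungsten, estimated
by fixed-step ray marching (default 25 um).  Rays with exactly zero chord
are "signal", partially attenuated rays are "noise", and rays below a
transmission floor are "blocked".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _trace
from .geometry import MCEFrame

__all__ = [
    "ApertureSpec",
    "Ray",
    "tungsten_mu",
    "open_area",
    "opening_contains",
    "path_length_in_tungsten",
    "transmission",
    "classify_ray",
    "assign_slit_rotations",
    "aperture_defaults",
    "assign_apertures",
    "APERTURE_VARIANTS",
]

KIND_CODES = {"lofthole": 0, "micro_slit": 1, "micro_ring": 2}

#: NIST-derived mass attenuation of tungsten (keV -> cm^2/g), valid 80-300 keV
_W_MU_RHO = ((80.0, 7.810), (100.0, 4.438), (150.0, 1.581),
             (200.0, 0.7844), (300.0, 0.3238))
_W_DENSITY = 19.3  # g/cm^3


def tungsten_mu(energy_kev: float = 140.0) -> float:
    """Linear attenuation of tungsten in mm^-1, log-log interpolated."""
    e = np.array([p[0] for p in _W_MU_RHO])
    mr = np.array([p[1] for p in _W_MU_RHO])
    if not (e[0] <= energy_kev <= e[-1]):
        raise ValueError(f"energy {energy_kev} keV outside table range 80-300")
    lm = np.interp(np.log(energy_kev), np.log(e), np.log(mr))
    return float(np.exp(lm) * _W_DENSITY / 10.0)


@dataclass(frozen=True)
class Ray:
    """World-frame ray from a voxel centre to a detector-pixel centre."""

    origin: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        if np.allclose(self.origin, self.target):
            raise ValueError("ray origin and target coincide")


@dataclass(frozen=True)
class ApertureSpec:
    """One tungsten aperture.  Angles are half-angles in degrees; lengths mm.

    ``t_u`` and ``t_l`` are the tungsten thicknesses above (detector side)
    and below (object side) the aperture plane and must sum to 20 mm.
    """

    kind: str
    t_u: float
    t_l: float
    mu_w: float = tungsten_mu(140.0)
    # lofthole
    diameter: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    # micro-slit
    width: float = 0.0
    length: float = 0.0
    alpha_short: float = 0.0
    beta_short: float = 0.0
    alpha_long: float = 0.0
    beta_long: float = 0.0
    theta: float = 0.0
    half_module: float = 10.0
    # micro-ring
    r_outer: float = 0.0
    r_inner: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KIND_CODES:
            raise ValueError(f"unknown aperture kind {self.kind!r}")
        if abs(self.t_u + self.t_l - 20.0) > 1e-9:
            raise ValueError(
                f"t_u + t_l must equal 20 mm, got {self.t_u} + {self.t_l}"
            )
        if self.kind == "micro_slit" and self.width > 0:
            if self.length / self.width < 10.0:
                raise ValueError("micro-slit requires l/w >= 10")
        if self.kind == "micro_ring":
            if not (self.r_outer > self.r_inner > 0.0):
                raise ValueError("micro-ring requires r_o > r_i > 0")

    @property
    def kind_code(self) -> int:
        return KIND_CODES[self.kind]

    def params(self) -> np.ndarray:
        """Flat parameter vector for the numba kernels."""
        t = math.tan
        rad = math.radians
        if self.kind == "lofthole":
            p = [self.t_l, self.t_u, self.diameter / 2.0,
                 t(rad(self.alpha)), t(rad(self.beta))]
        elif self.kind == "micro_slit":
            th = rad(self.theta)
            p = [self.t_l, self.t_u, self.width / 2.0, self.length / 2.0,
                 t(rad(self.alpha_short)), t(rad(self.alpha_long)),
                 t(rad(self.beta_short)), t(rad(self.beta_long)),
                 math.cos(th), math.sin(th), self.half_module]
        else:
            p = [self.t_l, self.t_u, self.r_inner, self.r_outer,
                 t(rad(self.alpha)), t(rad(self.beta))]
        return np.asarray(p, dtype=np.float64)

    @property
    def max_tan(self) -> float:
        """Largest flare slope; bounds how fast the channel opens with |w|."""
        p = self.params()
        if self.kind == "lofthole":
            return float(max(p[3], p[4]))
        if self.kind == "micro_slit":
            return float(p[4:8].max())
        return float(max(p[4], p[5]))


def open_area(a: ApertureSpec) -> float:
    """Geometric open area of the aperture-plane opening in mm^2."""
    if a.kind == "lofthole":
        return math.pi * a.diameter**2 / 4.0
    if a.kind == "micro_slit":
        return a.width * a.length
    return math.pi * (a.r_outer**2 - a.r_inner**2)


def opening_contains(a: ApertureSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized membership of aperture-plane points in the nominal opening."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if a.kind == "lofthole":
        return x * x + y * y <= (a.diameter / 2.0) ** 2
    if a.kind == "micro_slit":
        th = math.radians(a.theta)
        xr = math.cos(th) * x + math.sin(th) * y
        yr = -math.sin(th) * x + math.cos(th) * y
        return (np.abs(xr) <= a.width / 2.0) & (np.abs(yr) <= a.length / 2.0)
    r2 = x * x + y * y
    return (r2 > a.r_inner**2) & (r2 < a.r_outer**2)


def _local_ray(r: Ray, frame: MCEFrame):
    o = frame.to_local(r.origin)
    t = frame.to_local(r.target)
    d = t - o
    slen = float(np.linalg.norm(d))
    return o, d / slen, slen


def path_length_in_tungsten(
    a: ApertureSpec, r: Ray, frame: MCEFrame, step: float = 0.025
) -> float:
    """Chord length of the ray inside tungsten, by fixed-step ray marching."""
    if step <= 0:
        raise ValueError("step must be positive")
    o, d, slen = _local_ray(r, frame)
    return float(
        _trace.march_path(
            o[0], o[1], o[2], d[0], d[1], d[2], slen,
            a.kind_code, a.params(), step, np.inf,
        )
    )


def transmission(
    a: ApertureSpec, r: Ray, frame: MCEFrame, step: float = 0.025
) -> float:
    """Beer-Lambert transmission exp(-mu_w * x); exactly 1 for signal rays."""
    x = path_length_in_tungsten(a, r, frame, step)
    return 1.0 if x == 0.0 else float(math.exp(-a.mu_w * x))


def classify_ray(
    a: ApertureSpec,
    r: Ray,
    frame: MCEFrame,
    step: float = 0.025,
    floor: "float | None" = None,
) -> str:
    """'signal' (no tungsten crossed), 'noise' (partially transmitted above
    the floor) or 'blocked'.  The default floor is the full-slab
    transmission exp(-mu_w * 20 mm), relaxed by one march step so a ray
    crossing the entire slab is never misclassified by discretization."""
    if floor is None:
        floor = math.exp(-a.mu_w * (20.0 - step))
    t = transmission(a, r, frame, step)
    if t == 1.0:
        return "signal"
    if t > floor:
        return "noise"
    return "blocked"


def assign_slit_rotations(n: int, seed: int = 0) -> np.ndarray:
    """Seeded random permutation of the n evenly spaced slit rotations
    {k * 360/n deg}; for n = 502 the increment is ~0.717 deg."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    angles = np.arange(n) * (360.0 / n)
    return np.random.default_rng(seed).permutation(angles)


#: published aperture parameter sets
APERTURE_VARIANTS = (
    "lofthole_0.5", "lofthole_1.0", "lofthole_1.5", "lofthole_3.0",
    "slit_250x5", "slit_150x6", "ring_250",
)


def aperture_defaults(variant: str, mu_w: "float | None" = None) -> ApertureSpec:
    """Default parameter set for a named aperture variant.

    Loftholes share alpha = 27.3 deg, beta = 29.4 deg with an 11/9 mm
    upper/lower split; slits use 9/11 mm and per-direction angles; the
    micro-ring (7.5 mm outer diameter, 250 um annulus) uses 7/13 mm.
    """
    mu = tungsten_mu(140.0) if mu_w is None else mu_w
    loft = dict(kind="lofthole", alpha=27.3, beta=29.4, t_u=11.0, t_l=9.0, mu_w=mu)
    table = {
        "lofthole_0.5": dict(diameter=0.5, **loft),
        "lofthole_1.0": dict(diameter=1.0, **loft),
        "lofthole_1.5": dict(diameter=1.5, **loft),
        "lofthole_3.0": dict(diameter=3.0, **loft),
        "slit_250x5": dict(
            kind="micro_slit", width=0.25, length=5.0,
            alpha_short=27.3, beta_short=29.4, alpha_long=35.3, beta_long=22.6,
            t_u=9.0, t_l=11.0, mu_w=mu,
        ),
        "slit_150x6": dict(
            kind="micro_slit", width=0.15, length=6.0,
            alpha_short=27.3, beta_short=29.4, alpha_long=35.3, beta_long=21.1,
            t_u=9.0, t_l=11.0, mu_w=mu,
        ),
        "ring_250": dict(
            kind="micro_ring", r_outer=3.75, r_inner=3.5,
            alpha=36.3, beta=32.7, t_u=7.0, t_l=13.0, mu_w=mu,
        ),
    }
    if variant not in table:
        raise ValueError(
            f"unknown aperture variant {variant!r}; valid: {sorted(table)}"
        )
    return ApertureSpec(**table[variant])


#: helmet-level collimator options (per-MCE aperture assignment schemes)
COLLIMATORS = APERTURE_VARIANTS + ("combined_lofthole",)


def assign_apertures(
    ring_indices, collimator: str, seed: int = 0, mu_w: "float | None" = None
) -> list[ApertureSpec]:
    """Per-MCE aperture list for a helmet-level collimator choice.

    ``ring_indices`` is the per-MCE ring index sequence (from the helmet
    geometry, in MCE order).  Slit collimators draw each MCE's rotation from
    the seeded permutation of evenly spaced angles; ``combined_lofthole``
    cycles 0.5 / 1.5 / 3.0 mm diameters along the ring-ordered MCE sequence
    so neighbours within a ring always differ and the global split is
    exactly 168 / 167 / 167 for 502 MCEs.
    """
    ring_indices = list(ring_indices)
    n = len(ring_indices)
    if collimator == "combined_lofthole":
        diam = ("lofthole_0.5", "lofthole_1.5", "lofthole_3.0")
        specs = {v: aperture_defaults(v, mu_w) for v in diam}
        return [specs[diam[p % 3]] for p in range(n)]
    base = aperture_defaults(collimator, mu_w)
    if base.kind == "micro_slit":
        thetas = assign_slit_rotations(n, seed)
        return [replace(base, theta=float(t)) for t in thetas]
    return [base] * n
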