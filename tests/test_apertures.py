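"""Aperture solids: open areas, defaults, ray transmission and its oracle."""

import math

import numpy as np
import pytest

from helmetspect.apertures import (
    ApertureSpec,
    Ray,
    aperture_defaults,
    assign_apertures,
    assign_slit_rotations,
    classify_ray,
    open_area,
    opening_contains,
    path_length_in_tungsten,
    transmission,
    tungsten_mu,
)
from helmetspect.geometry import mce_frame


@pytest.fixture(scope="module")
def frame(helmet):
    return mce_frame(helmet.mces[0])


def _ray_to(frame, local_target, local_origin=(0.0, 0.0, -183.23)):
    return Ray(
        origin=frame.to_world(np.asarray(local_origin, dtype=float)),
        target=frame.to_world(np.asarray(local_target, dtype=float)),
    )


@pytest.mark.parametrize(
    "variant, area",
    [
        ("lofthole_1.0", 0.785),
        ("slit_150x6", 0.9),
        ("lofthole_3.0", 7.07),
        ("slit_250x5", 1.25),
    ],
)
def test_open_areas_match_published(variant, area):
    assert open_area(aperture_defaults(variant)) == pytest.approx(area, rel=5e-3)


def test_micro_ring_open_area_formula():
    """pi (r_o^2 - r_i^2): the 3.75/3.5-mm annulus gives 5.69 mm^2."""
    ring = ApertureSpec(kind="micro_ring", r_outer=3.75, r_inner=3.5,
                        alpha=36.3, beta=32.7, t_u=7.0, t_l=13.0)
    assert open_area(ring) == pytest.approx(5.69, abs=0.005)


@pytest.mark.parametrize("variant", ["lofthole_1.0", "slit_150x6", "ring_250"])
def test_open_area_monte_carlo(variant, rng):
    """Open area agrees with 2-D Monte-Carlo membership integration."""
    a = aperture_defaults(variant)
    box = 10.0
    n = 10**6
    pts = rng.uniform(-box, box, size=(n, 2))
    frac = opening_contains(a, pts[:, 0], pts[:, 1]).mean()
    est = frac * (2 * box) ** 2
    se = (2 * box) ** 2 * math.sqrt(frac * (1 - frac) / n)
    assert abs(est - open_area(a)) < max(3.5 * se, 0.005 * open_area(a) + 3.5 * se)


def test_aperture_default_parameters():
    s = aperture_defaults("slit_150x6")
    assert s.beta_long == pytest.approx(21.1)
    assert s.alpha_long == pytest.approx(35.3)
    assert (s.t_u, s.t_l) == (9.0, 11.0)
    r = aperture_defaults("ring_250")
    assert (r.alpha, r.beta) == (36.3, 32.7)
    assert (r.t_u, r.t_l) == (7.0, 13.0)
    with pytest.raises(ValueError, match="valid"):
        aperture_defaults("pinhole_1.0")


def test_spec_validation():
    with pytest.raises(ValueError, match="20 mm"):
        ApertureSpec(kind="lofthole", diameter=1.0, alpha=27.3, beta=29.4,
                     t_u=5.0, t_l=5.0)
    with pytest.raises(ValueError, match="l/w"):
        ApertureSpec(kind="micro_slit", width=1.0, length=5.0, t_u=9, t_l=11,
                     alpha_short=27.3, beta_short=29.4, alpha_long=35.3,
                     beta_long=22.6)
    with pytest.raises(ValueError, match="r_o > r_i"):
        ApertureSpec(kind="micro_ring", r_outer=3.0, r_inner=3.5, t_u=7, t_l=13,
                     alpha=36.3, beta=32.7)


def test_tungsten_attenuation_at_working_energy():
    # NIST-derived: ~3.6 mm^-1 at 140 keV, decreasing with energy
    assert 3.3 < tungsten_mu(140.0) < 3.9
    assert tungsten_mu(200.0) < tungsten_mu(100.0)


def test_axial_ray_is_open(helmet, frame):
    a = aperture_defaults("lofthole_1.0")
    r = _ray_to(frame, (0.0, 0.0, 17.0))
    assert path_length_in_tungsten(a, r, frame) == 0.0
    assert transmission(a, r, frame) == 1.0
    assert classify_ray(a, r, frame) == "signal"


def test_far_ray_sees_full_slab(helmet, frame):
    a = aperture_defaults("lofthole_1.0")
    # parallel to the axis, 8 mm off: solid tungsten through 20 mm
    r = _ray_to(frame, (8.0, 0.0, 17.0), local_origin=(8.0, 0.0, -183.23))
    x = path_length_in_tungsten(a, r, frame)
    assert x == pytest.approx(20.0, abs=0.06)
    assert transmission(a, r, frame) < 1e-30
    assert classify_ray(a, r, frame) == "blocked"


def test_knife_edge_ray_is_noise(helmet, frame):
    a = aperture_defaults("lofthole_1.0")
    r = _ray_to(frame, (0.55, 0.0, 17.0), local_origin=(0.50, 0.0, -183.23))
    assert classify_ray(a, r, frame) == "noise"


@pytest.mark.parametrize("variant", ["lofthole_1.0", "slit_250x5", "ring_250"])
def test_path_length_against_fine_step_oracle(variant, helmet, frame, rng):
    """25-um marching agrees with a 5-um brute-force march within 2 steps
    on random oblique rays through the aperture region."""
    a = aperture_defaults(variant)
    for _ in range(40):
        o = rng.uniform((-30, -30, -190), (30, 30, -150))
        t = rng.uniform((-9, -9, 15), (9, 9, 21))
        r = _ray_to(frame, t, local_origin=o)
        coarse = path_length_in_tungsten(a, r, frame, step=0.025)
        fine = path_length_in_tungsten(a, r, frame, step=0.005)
        assert abs(coarse - fine) <= 2 * 0.025 + 1e-9
        assert transmission(a, r, frame) == pytest.approx(
            math.exp(-a.mu_w * fine), rel=0.25
        ) or coarse == fine == 0.0


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        ox=st.floats(-60, 60), oy=st.floats(-60, 60),
        tx=st.floats(-9, 9), ty=st.floats(-9, 9),
        variant=st.sampled_from(["lofthole_1.0", "slit_250x5", "ring_250"]),
    )
    def test_transmission_bounds_property(helmet_mod, ox, oy, tx, ty, variant):
        """Transmission is always in [0, 1], equals 1 exactly when the
        tungsten chord is zero, and never increases when mu_w grows."""
        frame = mce_frame(helmet_mod.mces[0])
        a_lo = aperture_defaults(variant, mu_w=2.0)
        a_hi = aperture_defaults(variant, mu_w=4.0)
        r = _ray_to(frame, (tx, ty, 17.0), local_origin=(ox, oy, -183.23))
        x = path_length_in_tungsten(a_lo, r, frame)
        t_lo = transmission(a_lo, r, frame)
        t_hi = transmission(a_hi, r, frame)
        assert 0.0 <= t_hi <= t_lo <= 1.0
        assert (t_lo == 1.0) == (x == 0.0)

    @pytest.fixture(scope="module")
    def helmet_mod():
        from helmetspect.geometry import build_helmet

        return build_helmet()

except ImportError:  # hypothesis is an optional test dependency
    pass


def test_transmission_monotone_in_path():
    mu = tungsten_mu(140.0)
    xs = np.linspace(0, 20, 50)
    t = np.exp(-mu * xs)
    assert np.all(np.diff(t) < 0) and t[0] == 1.0


def test_beta_cone_confines_projection(helmet, frame):
    """Rays from the FOV centre through the opening land within the 20-mm
    module at the detector entrance face, for every default aperture."""
    for variant in ("lofthole_1.0", "slit_250x5", "slit_150x6", "ring_250"):
        a = aperture_defaults(variant)
        f = helmet.image_distance
        # sample the opening boundary and continue to the entrance plane
        phis = np.linspace(0, 2 * math.pi, 64, endpoint=False)
        if a.kind == "lofthole":
            bx, by = a.diameter / 2 * np.cos(phis), a.diameter / 2 * np.sin(phis)
        elif a.kind == "micro_ring":
            bx, by = a.r_outer * np.cos(phis), a.r_outer * np.sin(phis)
        else:
            bx = np.concatenate([a.width / 2 * np.cos(phis), a.width / 2 * np.cos(phis)])
            by = np.concatenate([a.length / 2 * np.sin(phis), a.length / 2 * np.sin(phis)])
        scale = (183.23 + f) / 183.23
        assert np.all(np.abs(bx * scale) <= 10.0) and np.all(np.abs(by * scale) <= 10.0)


def test_signal_class_nonempty(helmet, frame):
    """The open channel passes a positive-measure bundle for every default."""
    for variant in ("lofthole_0.5", "slit_150x6", "ring_250"):
        a = aperture_defaults(variant)
        hits = 0
        if a.kind == "micro_ring":
            targets = [(3.9, 0.0, 17.0), (0.0, -3.9, 17.0)]
        else:
            targets = [(0.0, 0.0, 17.0), (0.02, 0.02, 17.0)]
        for t in targets:
            r = _ray_to(frame, t)
            if classify_ray(a, r, frame) == "signal":
                hits += 1
        assert hits > 0


def test_slit_rotation_assignment():
    angles = assign_slit_rotations(502, seed=7)
    diffs = np.diff(np.sort(angles))
    assert np.allclose(diffs, 360.0 / 502)
    assert 360.0 / 502 == pytest.approx(0.717, abs=5e-4)
    assert set(np.round(assign_slit_rotations(4, seed=1), 9)) == {0.0, 90.0, 180.0, 270.0}
    assert np.array_equal(assign_slit_rotations(50, seed=3),
                          assign_slit_rotations(50, seed=3))
    with pytest.raises(ValueError):
        assign_slit_rotations(0)


def test_combined_lofthole_assignment(helmet):
    aps = assign_apertures([m.ring_index for m in helmet.mces], "combined_lofthole")
    diams = [a.diameter for a in aps]
    from collections import Counter

    counts = Counter(diams)
    assert sorted(counts.values()) == [167, 167, 168]
    # neighbours within a ring differ
    rings = [m.ring_index for m in helmet.mces]
    for i in range(1, len(aps)):
        if rings[i] == rings[i - 1]:
            assert diams[i] != diams[i - 1]
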