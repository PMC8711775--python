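"""System response matrix: solid angles, DOI absorption, sensitivity,
storage round trip, and the Monte-Carlo photon-sampling oracle."""

import math

import numpy as np
import pytest

from helmetspect.apertures import ApertureSpec, aperture_defaults
from helmetspect.geometry import DetectorSpec, mce_frame, pixel_centers_local
from helmetspect.system_matrix import (
    SRMOptions,
    SystemMatrix,
    VolumeGrid,
    _layer_probs,
    _mce_response,
    aperture_snr,
    build_srm,
    point_sensitivity,
    sensitivity_map,
    sensitivity_profiles,
    voxel_response,
)

D_A = 183.23


def test_layer_absorption_normal_incidence():
    det = DetectorSpec()
    p = _layer_probs(np.array([1.0]), det)[0]
    assert p[0] == pytest.approx(1.0 - math.exp(-0.354), rel=1e-12)
    assert p[0] == pytest.approx(0.298, abs=0.005)
    assert p.sum() == pytest.approx(1.0 - math.exp(-0.354 * 5.0), rel=1e-12)
    assert p.sum() == pytest.approx(0.83, abs=0.005)


def test_onaxis_pinhole_solid_angle(helmet, det_full):
    """With penetration and CZT absorption disabled, the summed response of
    a single 1-mm lofthole equals the on-axis pinhole solid-angle fraction
    open_area / (4 pi D_a^2) = 1.861e-6."""
    ap = aperture_defaults("lofthole_1.0", mu_w=1e9)  # no penetration
    frame = mce_frame(helmet.mces[0])
    det = DetectorSpec(mu_czt=1e9)  # absorb in layer 0 with probability ~1
    resp = _mce_response(
        frame, ap, det, helmet.image_distance,
        np.zeros((1, 3)), SRMOptions(pixel_subsample=2),
    )
    total = resp.sum()
    expected = 0.785398 / (4 * math.pi * D_A**2)
    assert total == pytest.approx(expected, rel=0.02)


def test_voxel_response_empty_when_blocked(helmet, det_small):
    """A source far outside every acceptance cone yields an empty column."""
    import dataclasses

    ap = aperture_defaults("lofthole_0.5")
    single = dataclasses.replace(helmet, mces=helmet.mces[:1])  # top cover
    # 35 degrees off the top-cover axis, well beyond alpha = 27.3 deg
    rows, vals = voxel_response(single, det_small, ap, [130.0, 0.0, 0.0],
                                SRMOptions(trans_floor=1e-4))
    assert vals.size == 0


def test_srm_columns_match_voxel_response(tiny_system):
    srm = tiny_system["srm"]
    grid = tiny_system["grid"]
    centers = grid.voxel_centers()
    ci = np.ravel_multi_index(grid.center_index(), grid.shape)
    for flat in (ci, ci + 1):
        rows, vals = voxel_response(
            tiny_system["geometry"], tiny_system["det"], tiny_system["aperture"],
            centers[flat], tiny_system["options"],
        )
        col = srm.column(flat)
        dense = np.zeros(srm.matrix.shape[0])
        dense[rows] = vals
        assert np.allclose(dense, col, rtol=1e-12, atol=1e-15)


def test_sensitivity_equals_column_sums(tiny_system):
    srm = tiny_system["srm"]
    smap = sensitivity_map(srm)
    direct = np.asarray(srm.matrix.sum(axis=0)).ravel()
    assert np.array_equal(smap.values.ravel(), direct)


def test_point_sensitivity_matches_srm(tiny_system):
    grid = tiny_system["grid"]
    idx = grid.center_index()
    center = grid.voxel_centers()[np.ravel_multi_index(idx, grid.shape)]
    s = point_sensitivity(
        tiny_system["geometry"], tiny_system["det"], tiny_system["aperture"],
        [center], tiny_system["options"],
    )
    smap = sensitivity_map(tiny_system["srm"])
    assert s[0] == pytest.approx(smap.values[idx], rel=1e-9)


def test_subsample_convergence(helmet, det_full):
    """Doubling the pixel subsampling changes the centre-voxel total by <1%
    once past the coarsest sampling (the 1x -> 2x step moves it ~1.5%)."""
    ap = aperture_defaults("lofthole_1.0")
    frame = mce_frame(helmet.mces[0])
    totals = []
    for s in (1, 2, 4):
        resp = _mce_response(
            frame, ap, det_full, helmet.image_distance, np.zeros((1, 3)),
            SRMOptions(pixel_subsample=s),
        )
        totals.append(resp.sum())
    assert abs(totals[1] - totals[0]) / totals[0] < 0.02
    assert abs(totals[2] - totals[1]) / totals[1] < 0.01


def test_srm_round_trip(tmp_path, tiny_system):
    srm = tiny_system["srm"]
    path = tmp_path / "srm.h5"
    srm.save(path)
    back = SystemMatrix.load(path)
    assert back.matrix.shape == srm.matrix.shape
    assert np.array_equal(back.matrix.data, srm.matrix.data)
    assert np.array_equal(back.matrix.indices, srm.matrix.indices)
    assert back.grid == srm.grid
    assert back.n_mce == srm.n_mce


def test_build_refuses_oversized_jobs(helmet, det_full):
    grid = VolumeGrid()
    with pytest.raises(ResourceWarning, match="coarsen"):
        build_srm(helmet, det_full, aperture_defaults("ring_250"), grid,
                  SRMOptions(ray_cap=1e6))


def test_monte_carlo_photon_oracle(helmet, det_full, rng):
    """Photon-sampling simulation (isotropic directions within a cone
    covering the module, aperture transmission as survival probability,
    CZT absorption over the crystal chord) reproduces the deterministic
    centre-voxel response of one MCE within 3 standard errors plus the
    pixel-discretization allowance."""
    from helmetspect import _trace

    ap = aperture_defaults("ring_250")
    pose = helmet.mces[0]
    frame = mce_frame(pose)
    det = det_full
    f = helmet.image_distance

    resp = _mce_response(frame, ap, det, f, np.zeros((1, 3)), SRMOptions())
    deterministic = resp.sum()

    # cone that safely contains the module as seen from the FOV centre
    cos_max = (D_A + f) / math.hypot(D_A + f, 15.0)
    n = 120_000
    cos_t = rng.uniform(cos_max, 1.0, n)
    phi = rng.uniform(0, 2 * math.pi, n)
    sin_t = np.sqrt(1 - cos_t**2)
    # local directions toward the module (+w)
    dirs = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)
    origin_local = np.array([0.0, 0.0, -D_A])

    # intersect with the entrance face, keep photons hitting the module
    s_face = (f + D_A) / dirs[:, 2]
    hit = dirs * s_face[:, None] + origin_local[None, :]
    inside = (np.abs(hit[:, 0]) <= 10.0) & (np.abs(hit[:, 1]) <= 10.0)
    idx = np.nonzero(inside)[0]

    # batch-trace the surviving photons through the aperture
    targets = origin_local[None, :] + dirs[idx] * (s_face[idx, None] + 2.0)
    max_path = math.log(1e9) / ap.mu_w
    paths = np.empty((1, len(targets)))
    _trace.trace_paths(
        np.asarray(origin_local).reshape(1, 3), targets, ap.kind_code,
        ap.params(), 0.025, max_path,
        max_path * (1 + ap.max_tan) / 2 * 1.3, 0.25, paths, False,
    )
    t_ap = np.where(paths[0] <= max_path, np.exp(-ap.mu_w * paths[0]), 0.0)
    t_ap[paths[0] == 0.0] = 1.0
    absorb = 1.0 - np.exp(-det.mu_czt * det.thickness / dirs[idx, 2])
    weights = np.zeros(n)
    weights[idx] = t_ap * absorb

    cone_frac = (1.0 - cos_max) / 2.0
    est = weights.mean() * cone_frac
    se = weights.std(ddof=1) / math.sqrt(n) * cone_frac
    assert abs(est - deterministic) < 3 * se + 0.03 * deterministic


def test_sensitivity_monotone_in_mu_w(helmet, det_small):
    """Raising tungsten attenuation can only reduce detected photons."""
    values = []
    for mu in (2.0, 3.64, 6.0):
        ap = aperture_defaults("lofthole_1.0", mu_w=mu)
        values.append(
            point_sensitivity(helmet, det_small, ap, [[0.0, 0.0, 0.0]])[0]
        )
    assert values[0] > values[1] > values[2]


def test_sensitivity_profiles_and_errors(tiny_system):
    smap = sensitivity_map(tiny_system["srm"])
    coords, prof = sensitivity_profiles(smap, "lateral")
    assert prof.shape == (15,)
    assert coords[7] == pytest.approx(0.0)  # centre voxel on the axis
    with pytest.raises(ValueError, match="axis"):
        sensitivity_profiles(smap, "diagonal")


def test_aperture_snr_infinite_without_penetration(helmet, det_small):
    ap = aperture_defaults("lofthole_1.0", mu_w=1e9)
    with pytest.warns(UserWarning, match="infinite"):
        r = aperture_snr(helmet, det_small, ap, VolumeGrid((16, 16, 16), 12.0),
                         stride=4)
    assert math.isinf(r["snr"])


def test_aperture_snr_rotation_invariant(helmet, det_small):
    """Rigidly rotating the whole system (MCE pose and source cloud
    together) leaves the aperture SNR unchanged."""
    import dataclasses

    grid = VolumeGrid((16, 16, 16), 12.0)
    centers = grid.voxel_centers()
    sources = centers[np.einsum("ij,ij->i", centers, centers) <= 100.0**2]
    ap = aperture_defaults("lofthole_1.0")

    base = aperture_snr(helmet, det_small, ap, sources=sources)
    # rotate pose 0 and the sources by the rotation linking pose 0 to pose 250
    f0, f1 = mce_frame(helmet.mces[0]), mce_frame(helmet.mces[250])
    rot = f1.rot.T @ f0.rot
    geo2 = dataclasses.replace(helmet, mces=(helmet.mces[250],))
    rotated = aperture_snr(geo2, det_small, ap, sources=sources @ rot.T)
    assert rotated["snr"] == pytest.approx(base["snr"], rel=1e-9)
    assert rotated["n_signal"] == base["n_signal"]
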