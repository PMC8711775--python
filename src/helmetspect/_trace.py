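"""Numba kernels for ray marching through parametric tungsten apertures.

All kernels work in the MCE-local frame (aperture plane at w = 0, detector
side at w > 0).  An aperture is encoded as an integer kind code plus a flat
float parameter vector so the kernels stay monomorphic:

kind 0 (lofthole):   p = [t_l, t_u, r0, tan_a, tan_b]
kind 1 (micro-slit): p = [t_l, t_u, hw, hl, tan_as, tan_al, tan_bs, tan_bl,
                          cos_theta, sin_theta, half_module]
kind 2 (micro-ring): p = [t_l, t_u, r_i, r_o, tan_a, tan_b]

The tungsten solid is the slab w in [-t_l, t_u] minus the open channel; the
channel pinches to the nominal opening exactly at the aperture plane and
flares with half-angle alpha toward the object (w < 0) and beta toward the
detector (w > 0).  Path lengths are estimated by fixed-step midpoint
sampling along the ray, which is uniform across aperture kinds and whose
error is bounded by the step size (a few boundary crossings per ray).
"""

import numpy as np
from numba import njit

#: sentinel path length for rays pruned or found opaque
BLOCKED = 1.0e9


@njit(cache=True, inline="always")
def _in_channel(kind, p, x, y, w):
    """True if local point (x, y, w) lies in the open channel."""
    if kind == 0:  # lofthole: circular waist lofted to square faces
        if w < 0.0:
            aw = -w
            t = aw / p[0]
            h = p[2] + aw * p[3]
        else:
            t = w / p[1]
            h = p[2] + w * p[4]
        if t > 1.0:
            t = 1.0
        r2 = np.sqrt(x * x + y * y)
        ax = abs(x)
        ay = abs(y)
        rinf = ax if ax > ay else ay
        return (1.0 - t) * r2 + t * rinf <= h
    elif kind == 1:  # micro-slit: rotated rectangle, squared upper profile
        c = p[8]
        s = p[9]
        xr = c * x + s * y
        yr = -s * x + c * y
        if w < 0.0:
            aw = -w
            return abs(xr) <= p[2] + aw * p[4] and abs(yr) <= p[3] + aw * p[5]
        else:
            if abs(x) > p[10] or abs(y) > p[10]:
                return False
            return abs(xr) <= p[2] + w * p[6] and abs(yr) <= p[3] + w * p[7]
    else:  # micro-ring: annulus between flaring outer cone and tapering plug
        r = np.sqrt(x * x + y * y)
        if w < 0.0:
            aw = -w
            rin = p[2] - aw * p[4]
            rout = p[3] + aw * p[4]
        else:
            rin = p[2] - w * p[5]
            rout = p[3] + w * p[5]
        if rin < 0.0:
            rin = 0.0
        return rin < r < rout


@njit(cache=True, inline="always")
def _plane_distance(kind, p, x, y):
    """Distance from (x, y) at the aperture plane to the nominal opening
    (0 inside).  1-Lipschitz lower bound used for geometric pruning."""
    if kind == 0:
        d = np.sqrt(x * x + y * y) - p[2]
        return d if d > 0.0 else 0.0
    elif kind == 1:
        c = p[8]
        s = p[9]
        xr = abs(c * x + s * y) - p[2]
        yr = abs(-s * x + c * y) - p[3]
        if xr < 0.0:
            xr = 0.0
        if yr < 0.0:
            yr = 0.0
        return np.sqrt(xr * xr + yr * yr)
    else:
        r = np.sqrt(x * x + y * y)
        if r < p[2]:
            return p[2] - r
        if r > p[3]:
            return r - p[3]
        return 0.0


@njit(cache=True)
def march_path(ox, oy, oz, dx, dy, dz, slen, kind, p, step, max_path):
    """Tungsten chord length along the ray segment origin -> origin+slen*d.

    Midpoint sampling at the given step; accumulation stops once the path
    exceeds ``max_path`` (pass a huge value for an exact march).
    """
    t_l = p[0]
    t_u = p[1]
    if dz != 0.0:
        sa = (-t_l - oz) / dz
        sb = (t_u - oz) / dz
        s0 = sa if sa < sb else sb
        s1 = sb if sa < sb else sa
        if s0 < 0.0:
            s0 = 0.0
        if s1 > slen:
            s1 = slen
        if s1 <= s0:
            return 0.0
    else:
        if oz < -t_l or oz > t_u:
            return 0.0
        s0 = 0.0
        s1 = slen
    length = s1 - s0
    n_full = int(length / step)
    rem = length - n_full * step
    path = 0.0
    for i in range(n_full):
        s = s0 + (i + 0.5) * step
        x = ox + s * dx
        y = oy + s * dy
        w = oz + s * dz
        if not _in_channel(kind, p, x, y, w):
            path += step
            if path > max_path:
                return path
    if rem > 1e-12:
        s = s0 + n_full * step + 0.5 * rem
        if not _in_channel(kind, p, ox + s * dx, oy + s * dy, oz + s * dz):
            path += rem
    return path


@njit(cache=True, inline="always")
def _march_interval(ox, oy, oz, dx, dy, dz, a, b, kind, p, step):
    """Exact midpoint-sampled tungsten length on the sub-interval [a, b]."""
    length = b - a
    n_full = int(length / step)
    rem = length - n_full * step
    path = 0.0
    for i in range(n_full):
        s = a + (i + 0.5) * step
        if not _in_channel(kind, p, ox + s * dx, oy + s * dy, oz + s * dz):
            path += step
    if rem > 1e-12:
        s = a + n_full * step + 0.5 * rem
        if not _in_channel(kind, p, ox + s * dx, oy + s * dy, oz + s * dz):
            path += rem
    return path


@njit(cache=True)
def march_path_refined(ox, oy, oz, dx, dy, dz, slen, kind, p, step, coarse_step, max_path):
    """Tungsten path by coarse marching with fine refinement around material
    transitions.

    Coarse cells whose midpoint status matches both neighbours are counted
    wholesale; cells adjacent to a status change, cells near the aperture
    plane (within 1.25 mm of the waist, where the tungsten wedge is thinner
    than a coarse cell), and the first/last cells touching the slab faces
    are re-marched at the fine step.  A sliver thinner than the coarse step
    away from the waist can still be missed; the fine-step oracle bounds
    this in tests.
    """
    t_l = p[0]
    t_u = p[1]
    if dz != 0.0:
        sa = (-t_l - oz) / dz
        sb = (t_u - oz) / dz
        s0 = sa if sa < sb else sb
        s1 = sb if sa < sb else sa
        if s0 < 0.0:
            s0 = 0.0
        if s1 > slen:
            s1 = slen
        if s1 <= s0:
            return 0.0
    else:
        if oz < -t_l or oz > t_u:
            return 0.0
        s0 = 0.0
        s1 = slen
    n = int((s1 - s0) / coarse_step) + 1
    cell = (s1 - s0) / n
    path = 0.0
    prev_open = True
    prev_refined = False
    prev_contrib = 0.0
    for i in range(n):
        a = s0 + i * cell
        b = a + cell
        s = a + 0.5 * cell
        w_mid = oz + s * dz
        open_i = _in_channel(kind, p, ox + s * dx, oy + s * dy, w_mid)
        if i == 0 or i == n - 1 or abs(w_mid) < 1.25:
            contrib = _march_interval(ox, oy, oz, dx, dy, dz, a, b, kind, p, step)
            refined = True
        elif open_i != prev_open:
            if not prev_refined:
                path -= prev_contrib
                path += _march_interval(
                    ox, oy, oz, dx, dy, dz, a - cell, a, kind, p, step
                )
            contrib = _march_interval(ox, oy, oz, dx, dy, dz, a, b, kind, p, step)
            refined = True
        else:
            contrib = 0.0 if open_i else cell
            refined = False
        path += contrib
        prev_open = open_i
        prev_refined = refined
        prev_contrib = contrib
        if path > max_path + cell:
            return path
    return path


@njit(cache=True)
def trace_paths(origins, targets, kind, p, step, max_path, prune_dist, coarse_step, out,
                refine=True):
    """Tungsten path length for every (origin, target) ray pair.

    ``out[a, b]`` receives the marched path, or ``BLOCKED`` when the ray is
    provably opaque: either its aperture-plane crossing lies farther than
    ``prune_dist`` from the opening (geometric bound), or a coarse march at
    ``coarse_step`` already accumulates more than ``max_path`` plus the
    coarse discretization error.  Rays with path 0.0 passed entirely through
    the open channel.  With ``refine=True`` paths come from the
    transition-refined march; otherwise from the plain fine march.
    """
    ns = origins.shape[0]
    npx = targets.shape[0]
    coarse_err = 8.0 * coarse_step
    for a in range(ns):
        ox = origins[a, 0]
        oy = origins[a, 1]
        oz = origins[a, 2]
        for b in range(npx):
            dx = targets[b, 0] - ox
            dy = targets[b, 1] - oy
            dz = targets[b, 2] - oz
            slen = np.sqrt(dx * dx + dy * dy + dz * dz)
            dx /= slen
            dy /= slen
            dz /= slen
            if dz != 0.0:
                sp = -oz / dz
                if 0.0 <= sp <= slen:
                    xp = ox + sp * dx
                    yp = oy + sp * dy
                    if _plane_distance(kind, p, xp, yp) > prune_dist:
                        out[a, b] = BLOCKED
                        continue
            if refine:
                path = march_path_refined(
                    ox, oy, oz, dx, dy, dz, slen, kind, p, step, coarse_step,
                    max_path,
                )
            else:
                if coarse_step > step:
                    cp = march_path(
                        ox, oy, oz, dx, dy, dz, slen, kind, p, coarse_step,
                        max_path + coarse_err,
                    )
                    if cp > max_path + coarse_err:
                        out[a, b] = BLOCKED
                        continue
                path = march_path(
                    ox, oy, oz, dx, dy, dz, slen, kind, p, step, max_path
                )
            out[a, b] = path if path <= max_path else BLOCKED
    return out
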