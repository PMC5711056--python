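"""Numba-compiled core of the analog photon Monte Carlo engine.

Everything here operates on flat scalars/arrays so it can be jitted; the
public API lives in :mod:`brachydmf.transport`.  The random stream is an
explicit xoshiro256** state (seeded via splitmix64), so results are
bit-reproducible for a given seed on any platform.

Conventions: positions/lengths in cm, energies in MeV, materials indexed
0=water, 1=air, 2=steel; phantom kind 0=cuboid, 1=sphere.  Estimators:
0 = track-length kerma, 1 = collision-density kerma.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_SM_GAMMA = U64(0x9E3779B97F4A7C15)
_SM_M1 = U64(0xBF58476D1CE4E5B9)
_SM_M2 = U64(0x94D049BB133111EB)
_DOUBLE_NORM = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _rotl(x, k):
    return U64((x << U64(k)) | (x >> U64(64 - k)))


@njit(cache=True)
def splitmix64(state):
    state = U64(state + _SM_GAMMA)
    z = state
    z = U64((z ^ (z >> U64(30))) * _SM_M1)
    z = U64((z ^ (z >> U64(27))) * _SM_M2)
    return state, U64(z ^ (z >> U64(31)))


@njit(cache=True)
def seed_state(seed):
    s = np.empty(4, dtype=np.uint64)
    st = U64(seed)
    for i in range(4):
        st, v = splitmix64(st)
        s[i] = v
    return s


@njit(cache=True, inline="always")
def history_state(s, stream_seed, index):
    """(Re)seed the xoshiro state for one history.

    Each history draws from its own stream derived from (stream seed,
    history index).  This makes paired scene comparisons true
    common-random-number experiments: a history consumes an identical
    random sequence in both scenes unless its track actually reaches the
    altered geometry, so small perturbations (steel cable on/off, extra
    backscatter) difference out history by history.
    """
    st = U64(stream_seed) + U64(index) * _SM_GAMMA
    for i in range(4):
        st, v = splitmix64(st)
        s[i] = v


@njit(cache=True, inline="always")
def next_u64(s):
    result = U64(_rotl(U64(s[1] * U64(5)), 7) * U64(9))
    t = U64(s[1] << U64(17))
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = _rotl(s[3], 45)
    return result


@njit(cache=True, inline="always")
def next_double(s):
    return float(next_u64(s) >> U64(11)) * _DOUBLE_NORM


@njit(cache=True)
def fill_doubles(seed, n):
    """n uniform doubles from the stream seeded by ``seed`` (for helpers)."""
    s = seed_state(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = next_double(s)
    return out


# --------------------------------------------------------------------------
# physics lookups

ELECTRON_REST_MEV = 0.51099895


@njit(cache=True, inline="always")
def _lookup(log_e0, dlog, table, energy):
    """Linear interpolation of a 1-D lookup row at log(energy)."""
    x = (np.log(energy) - log_e0) / dlog
    if x < 0.0:
        x = 0.0
    n = table.shape[0]
    if x > n - 1.000001:
        x = n - 1.000001
    i = int(x)
    f = x - i
    return table[i] * (1.0 - f) + table[i + 1] * f


@njit(cache=True)
def sample_compton_scalar(energy, s):
    """Klein-Nishina energy fraction and scattering cosine (free electron)."""
    a = energy / ELECTRON_REST_MEV
    eps0 = 1.0 / (1.0 + 2.0 * a)
    w1 = -np.log(eps0)
    w2 = 0.5 * (1.0 - eps0 * eps0)
    p1 = w1 / (w1 + w2)
    while True:
        u1 = next_double(s)
        u2 = next_double(s)
        u3 = next_double(s)
        if u1 < p1:
            eps = eps0 * np.exp(u2 * w1)
        else:
            eps = np.sqrt(eps0 * eps0 + u2 * (1.0 - eps0 * eps0))
        t = (1.0 - eps) / (a * eps)
        sin2 = t * (2.0 - t)
        if u3 <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            cos_t = 1.0 - t
            return eps, cos_t


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cos_t, phi):
    """Rotate a unit vector by polar angle arccos(cos_t), azimuth phi."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) < 0.99999:
        denom = np.sqrt(1.0 - uz * uz)
        vx = sin_t * (ux * uz * cp - uy * sp) / denom + ux * cos_t
        vy = sin_t * (uy * uz * cp + ux * sp) / denom + uy * cos_t
        vz = -sin_t * cp * denom + uz * cos_t
    else:
        sign = 1.0 if uz > 0.0 else -1.0
        vx = sin_t * cp
        vy = sin_t * sp
        vz = sign * cos_t
    norm = 1.0 / np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx * norm, vy * norm, vz * norm


# --------------------------------------------------------------------------
# geometry primitives


@njit(cache=True, inline="always")
def _in_phantom(x, y, z, kind, bounds, radius2):
    if kind == 1:
        return x * x + y * y + z * z <= radius2
    return (
        bounds[0, 0] <= x <= bounds[0, 1]
        and bounds[1, 0] <= y <= bounds[1, 1]
        and bounds[2, 0] <= z <= bounds[2, 1]
    )


@njit(cache=True, inline="always")
def _in_wire(x, y, z, wp0, wax, whalf, wr2):
    for i in range(wp0.shape[0]):
        rx = x - wp0[i, 0]
        ry = y - wp0[i, 1]
        rz = z - wp0[i, 2]
        za = rx * wax[i, 0] + ry * wax[i, 1] + rz * wax[i, 2]
        if abs(za) > whalf[i]:
            continue
        px = rx - za * wax[i, 0]
        py = ry - za * wax[i, 1]
        pz = rz - za * wax[i, 2]
        if px * px + py * py + pz * pz <= wr2:
            return True
    return False


@njit(cache=True, inline="always")
def _material_at(
    x, y, z, kind, bounds, radius2, world_half, wp0, wax, whalf, wr2
):
    if abs(x) > world_half or abs(y) > world_half or abs(z) > world_half:
        return -1
    if wp0.shape[0] > 0 and _in_wire(x, y, z, wp0, wax, whalf, wr2):
        return 2
    if _in_phantom(x, y, z, kind, bounds, radius2):
        return 0
    return 1


@njit(cache=True, inline="always")
def _box_exit_ts(x, y, z, ux, uy, uz, lo0, hi0, lo1, hi1, lo2, hi2):
    """Nearest positive crossing with the 6 planes of an axis box (or inf)."""
    best = 1.0e30
    eps = 1e-9
    if abs(ux) > 1e-300:
        for b in (lo0, hi0):
            t = (b - x) / ux
            if eps < t < best:
                yy = y + t * uy
                zz = z + t * uz
                if lo1 - 1e-9 <= yy <= hi1 + 1e-9 and lo2 - 1e-9 <= zz <= hi2 + 1e-9:
                    best = t
    if abs(uy) > 1e-300:
        for b in (lo1, hi1):
            t = (b - y) / uy
            if eps < t < best:
                xx = x + t * ux
                zz = z + t * uz
                if lo0 - 1e-9 <= xx <= hi0 + 1e-9 and lo2 - 1e-9 <= zz <= hi2 + 1e-9:
                    best = t
    if abs(uz) > 1e-300:
        for b in (lo2, hi2):
            t = (b - z) / uz
            if eps < t < best:
                xx = x + t * ux
                yy = y + t * uy
                if lo0 - 1e-9 <= xx <= hi0 + 1e-9 and lo1 - 1e-9 <= yy <= hi1 + 1e-9:
                    best = t
    return best


@njit(cache=True, inline="always")
def _sphere_ts(x, y, z, ux, uy, uz, radius2):
    """Nearest positive crossing with a sphere centered at the origin."""
    b = x * ux + y * uy + z * uz
    c = x * x + y * y + z * z - radius2
    disc = b * b - c
    if disc <= 0.0:
        return 1.0e30
    s = np.sqrt(disc)
    t = -b - s
    if t > 1e-9:
        return t
    t = -b + s
    if t > 1e-9:
        return t
    return 1.0e30


@njit(cache=True)
def _next_boundary(
    x, y, z, ux, uy, uz, kind, bounds, radius2, world_half,
    wp0, wax, whalf, wradius, wire_bound2,
):
    best = _box_exit_ts(
        x, y, z, ux, uy, uz,
        -world_half, world_half, -world_half, world_half, -world_half, world_half,
    )
    if kind == 1:
        t = _sphere_ts(x, y, z, ux, uy, uz, radius2)
        if t < best:
            best = t
    else:
        t = _box_exit_ts(
            x, y, z, ux, uy, uz,
            bounds[0, 0], bounds[0, 1], bounds[1, 0], bounds[1, 1],
            bounds[2, 0], bounds[2, 1],
        )
        if t < best:
            best = t
    if wp0.shape[0] > 0:
        # bounding sphere rejection: the cable lives near the balloon
        b = x * ux + y * uy + z * uz
        c = x * x + y * y + z * z - wire_bound2
        if c <= 0.0 or b * b - c > 0.0 and -b - np.sqrt(b * b - c) < best:
            wr2 = wradius * wradius
            for i in range(wp0.shape[0]):
                rx = x - wp0[i, 0]
                ry = y - wp0[i, 1]
                rz = z - wp0[i, 2]
                za = rx * wax[i, 0] + ry * wax[i, 1] + rz * wax[i, 2]
                zd = ux * wax[i, 0] + uy * wax[i, 1] + uz * wax[i, 2]
                px = rx - za * wax[i, 0]
                py = ry - za * wax[i, 1]
                pz = rz - za * wax[i, 2]
                dx = ux - zd * wax[i, 0]
                dy = uy - zd * wax[i, 1]
                dz = uz - zd * wax[i, 2]
                a = dx * dx + dy * dy + dz * dz
                if a > 1e-20:
                    bb = px * dx + py * dy + pz * dz
                    cc = px * px + py * py + pz * pz - wr2
                    disc = bb * bb - a * cc
                    if disc > 0.0:
                        sq = np.sqrt(disc)
                        for tt in ((-bb - sq) / a, (-bb + sq) / a):
                            if 1e-9 < tt < best and abs(za + tt * zd) <= whalf[i]:
                                best = tt
                if abs(zd) > 1e-300:
                    for zcap in (-whalf[i], whalf[i]):
                        tt = (zcap - za) / zd
                        if 1e-9 < tt < best:
                            qx = px + tt * dx
                            qy = py + tt * dy
                            qz = pz + tt * dz
                            if qx * qx + qy * qy + qz * qz <= wr2:
                                best = tt
    return best


@njit(cache=True, inline="always")
def _segment_in_sphere(x, y, z, ux, uy, uz, s, cx, cy, cz, radius2):
    """Length of the segment [0, s] inside a sphere (0 when disjoint)."""
    rx = x - cx
    ry = y - cy
    rz = z - cz
    b = rx * ux + ry * uy + rz * uz
    c = rx * rx + ry * ry + rz * rz - radius2
    disc = b * b - c
    if disc <= 0.0:
        return 0.0
    sq = np.sqrt(disc)
    lo = -b - sq
    hi = -b + sq
    if lo < 0.0:
        lo = 0.0
    if hi > s:
        hi = s
    if hi <= lo:
        return 0.0
    return hi - lo


# --------------------------------------------------------------------------
# main drivers


@njit(cache=True)
def run_dwell(
    # dwell geometry
    dc, dax, d_half, d_radius,
    # scene
    kind, bounds, ph_radius, world_half,
    wp0, wax, whalf, wradius,
    det_center, det_radius,
    # physics tables
    log_e0, dlog, mu_lin, p_compton, p_coherent, muen_water, cutoff,
    # source spectrum
    sp_e, sp_cdf, mono_energy,
    # run control
    n_hist, n_batches, seed, estimator,
):
    """Transport ``n_hist`` photons from one dwell; return per-batch tally sums.

    The tally is kerma to water in the detector sphere per source photon,
    up to the constant detector volume (divided out by the caller):
    track-length estimator sum(w * L * E * muen_w(E)) or collision estimator
    sum(w * E * muen_w(E) / mu_local).
    """
    s = seed_state(seed)
    radius2 = ph_radius * ph_radius
    det_r2 = det_radius * det_radius
    # tight bounding sphere of the cable polyline (origin-centered): rays
    # that cannot reach it skip the per-cylinder intersection scan
    wire_bound = 0.0
    for i in range(wp0.shape[0]):
        ext = (
            np.sqrt(wp0[i, 0] ** 2 + wp0[i, 1] ** 2 + wp0[i, 2] ** 2)
            + whalf[i]
            + wradius
        )
        if ext > wire_bound:
            wire_bound = ext
    wire_bound2 = wire_bound * wire_bound
    batch = np.zeros(n_batches)
    per_batch = n_hist // n_batches
    # orthonormal frame of the dwell axis for emission sampling
    ax, ay, az = dax[0], dax[1], dax[2]
    if abs(az) < 0.9:
        e1x, e1y, e1z = ay * 1.0 - az * 0.0, az * 0.0 - ax * 1.0, ax * 0.0 - ay * 0.0
    else:
        e1x, e1y, e1z = ay * 0.0 - az * 1.0, az * 0.0 - ax * 0.0, ax * 1.0 - ay * 0.0
    n1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x, e1y, e1z = e1x / n1, e1y / n1, e1z / n1
    e2x = ay * e1z - az * e1y
    e2y = az * e1x - ax * e1z
    e2z = ax * e1y - ay * e1x
    n_lines = sp_e.shape[0]
    ihist = 0
    for ib in range(n_batches):
        acc = 0.0
        for _ in range(per_batch):
            history_state(s, seed, ihist)
            ihist += 1
            # --- emission point uniform in the dwell cylinder
            h = (2.0 * next_double(s) - 1.0) * d_half
            rr = d_radius * np.sqrt(next_double(s))
            phi = 6.283185307179586 * next_double(s)
            cp = np.cos(phi)
            sp = np.sin(phi)
            x = dc[0] + h * ax + rr * (cp * e1x + sp * e2x)
            y = dc[1] + h * ay + rr * (cp * e1y + sp * e2y)
            z = dc[2] + h * az + rr * (cp * e1z + sp * e2z)
            # --- isotropic direction
            uz = 2.0 * next_double(s) - 1.0
            phi = 6.283185307179586 * next_double(s)
            sr = np.sqrt(max(0.0, 1.0 - uz * uz))
            ux = sr * np.cos(phi)
            uy = sr * np.sin(phi)
            # --- emission energy
            if mono_energy > 0.0:
                energy = mono_energy
            else:
                u = next_double(s)
                j = 0
                while j < n_lines - 1 and u > sp_cdf[j]:
                    j += 1
                energy = sp_e[j]
            # --- transport; one optical depth drawn per flight and carried
            # across boundaries, so the number of random draws a history
            # consumes is independent of the boundary structure it crosses
            # (the basis of the common-random-number pairing).
            tau = -np.log(1.0 - next_double(s))
            while True:
                mat = _material_at(
                    x, y, z, kind, bounds, radius2, world_half,
                    wp0, wax, whalf, wradius * wradius,
                )
                if mat < 0:
                    break
                mu = _lookup(log_e0, dlog, mu_lin[mat], energy)
                s_bnd = _next_boundary(
                    x, y, z, ux, uy, uz, kind, bounds, radius2, world_half,
                    wp0, wax, whalf, wradius, wire_bound2,
                )
                if mu > 1e-30 and tau < mu * s_bnd:
                    step = tau / mu
                    collided = True
                else:
                    step = s_bnd
                    tau -= mu * s_bnd
                    collided = False
                if step > 1.0e29:
                    break
                if estimator == 0:
                    lseg = _segment_in_sphere(
                        x, y, z, ux, uy, uz, step,
                        det_center[0], det_center[1], det_center[2], det_r2,
                    )
                    if lseg > 0.0:
                        acc += lseg * energy * _lookup(
                            log_e0, dlog, muen_water, energy
                        )
                x += step * ux
                y += step * uy
                z += step * uz
                if not collided:
                    # nudge across the surface and continue
                    x += 1e-7 * ux
                    y += 1e-7 * uy
                    z += 1e-7 * uz
                    continue
                # --- collision
                if estimator == 1:
                    ddx = x - det_center[0]
                    ddy = y - det_center[1]
                    ddz = z - det_center[2]
                    if ddx * ddx + ddy * ddy + ddz * ddz <= det_r2:
                        acc += energy * _lookup(
                            log_e0, dlog, muen_water, energy
                        ) / mu
                u = next_double(s)
                pc = _lookup(log_e0, dlog, p_compton[mat], energy)
                if u < pc:
                    eps, cos_t = sample_compton_scalar(energy, s)
                    energy *= eps
                    if energy < cutoff:
                        break
                    phi = 6.283185307179586 * next_double(s)
                    ux, uy, uz = _rotate(ux, uy, uz, cos_t, phi)
                else:
                    pcoh = _lookup(log_e0, dlog, p_coherent[mat], energy)
                    if pcoh > 0.0 and u < pc + pcoh:
                        # coherent: Thomson-shaped angular kernel, no E loss
                        while True:
                            c = 2.0 * next_double(s) - 1.0
                            if next_double(s) <= 0.5 * (1.0 + c * c):
                                break
                        phi = 6.283185307179586 * next_double(s)
                        ux, uy, uz = _rotate(ux, uy, uz, c, phi)
                    else:
                        break  # absorbed
                tau = -np.log(1.0 - next_double(s))  # next flight
        batch[ib] = acc
    return batch


@njit(cache=True)
def run_kernel_tally(
    d_half, d_radius, ph_radius, world_half,
    log_e0, dlog, mu_lin, p_compton, p_coherent, muen_water, cutoff,
    sp_e, sp_cdf,
    r_edges, cos_edges, max_sub,
    n_hist, n_batches, seed,
):
    """Single unit-weight dwell at the origin (axis +z) in a full-scatter
    water sphere; track-length kerma tally on (radius, cos theta) ring bins.

    Returns per-batch sums with shape (n_batches, n_r, n_cos); the caller
    divides by bin volumes and history counts.
    """
    s = seed_state(seed)
    nr = r_edges.shape[0] - 1
    nc = cos_edges.shape[0] - 1
    out = np.zeros((n_batches, nr, nc))
    per_batch = n_hist // n_batches
    radius2 = ph_radius * ph_radius
    r_lo = r_edges[0]
    r_hi = r_edges[nr]
    tbuf = np.empty(2 * (nr + 1) + 2)
    n_lines = sp_e.shape[0]
    ihist = 0
    for ib in range(n_batches):
        for _ in range(per_batch):
            history_state(s, seed, ihist)
            ihist += 1
            h = (2.0 * next_double(s) - 1.0) * d_half
            rr = d_radius * np.sqrt(next_double(s))
            phi = 6.283185307179586 * next_double(s)
            x = rr * np.cos(phi)
            y = rr * np.sin(phi)
            z = h
            uz = 2.0 * next_double(s) - 1.0
            phi = 6.283185307179586 * next_double(s)
            sr = np.sqrt(max(0.0, 1.0 - uz * uz))
            ux = sr * np.cos(phi)
            uy = sr * np.sin(phi)
            u = next_double(s)
            j = 0
            while j < n_lines - 1 and u > sp_cdf[j]:
                j += 1
            energy = sp_e[j]
            while True:
                r2 = x * x + y * y + z * z
                inside = r2 <= radius2
                if (
                    abs(x) > world_half
                    or abs(y) > world_half
                    or abs(z) > world_half
                ):
                    break
                mat = 0 if inside else 1
                mu = _lookup(log_e0, dlog, mu_lin[mat], energy)
                s_int = -np.log(1.0 - next_double(s)) / mu
                if inside:
                    s_bnd = _sphere_ts(x, y, z, ux, uy, uz, radius2)
                else:
                    s_bnd = _sphere_ts(x, y, z, ux, uy, uz, radius2)
                    t = _box_exit_ts(
                        x, y, z, ux, uy, uz,
                        -world_half, world_half, -world_half, world_half,
                        -world_half, world_half,
                    )
                    if t < s_bnd:
                        s_bnd = t
                step = s_int if s_int < s_bnd else s_bnd
                # --- score the segment onto (r, cos) ring bins
                if inside:
                    escore = energy * _lookup(log_e0, dlog, muen_water, energy)
                    b = x * ux + y * uy + z * uz
                    c0 = r2
                    nts = 0
                    tbuf[nts] = 0.0
                    nts += 1
                    for ie in range(nr + 1):
                        re_ = r_edges[ie]
                        disc = b * b - (c0 - re_ * re_)
                        if disc > 0.0:
                            sq = np.sqrt(disc)
                            t1 = -b - sq
                            t2 = -b + sq
                            if 0.0 < t1 < step:
                                tbuf[nts] = t1
                                nts += 1
                            if 0.0 < t2 < step:
                                tbuf[nts] = t2
                                nts += 1
                    tbuf[nts] = step
                    nts += 1
                    # insertion sort of the crossing times
                    for a_ in range(1, nts):
                        key = tbuf[a_]
                        b_ = a_ - 1
                        while b_ >= 0 and tbuf[b_] > key:
                            tbuf[b_ + 1] = tbuf[b_]
                            b_ -= 1
                        tbuf[b_ + 1] = key
                    for k in range(nts - 1):
                        t0 = tbuf[k]
                        t1 = tbuf[k + 1]
                        seg = t1 - t0
                        if seg <= 1e-12:
                            continue
                        nsub = int(seg / max_sub) + 1
                        dsub = seg / nsub
                        for m in range(nsub):
                            tm = t0 + (m + 0.5) * dsub
                            xm = x + tm * ux
                            ym = y + tm * uy
                            zm = z + tm * uz
                            rm = np.sqrt(xm * xm + ym * ym + zm * zm)
                            if rm < r_lo or rm >= r_hi:
                                continue
                            # binary search radial bin
                            lo_i, hi_i = 0, nr
                            while hi_i - lo_i > 1:
                                mid = (lo_i + hi_i) // 2
                                if rm >= r_edges[mid]:
                                    lo_i = mid
                                else:
                                    hi_i = mid
                            cm = zm / rm
                            ic = int((cm - cos_edges[0]) / (cos_edges[1] - cos_edges[0]))
                            if ic < 0:
                                ic = 0
                            elif ic >= nc:
                                ic = nc - 1
                            out[ib, lo_i, ic] += dsub * escore
                x += step * ux
                y += step * uy
                z += step * uz
                if s_int >= s_bnd:
                    x += 1e-7 * ux
                    y += 1e-7 * uy
                    z += 1e-7 * uz
                    continue
                u = next_double(s)
                pc = _lookup(log_e0, dlog, p_compton[mat], energy)
                if u < pc:
                    eps, cos_t = sample_compton_scalar(energy, s)
                    energy *= eps
                    if energy < cutoff:
                        break
                    phi = 6.283185307179586 * next_double(s)
                    ux, uy, uz = _rotate(ux, uy, uz, cos_t, phi)
                else:
                    pcoh = _lookup(log_e0, dlog, p_coherent[mat], energy)
                    if pcoh > 0.0 and u < pc + pcoh:
                        while True:
                            c = 2.0 * next_double(s) - 1.0
                            if next_double(s) <= 0.5 * (1.0 + c * c):
                                break
                        phi = 6.283185307179586 * next_double(s)
                        ux, uy, uz = _rotate(ux, uy, uz, c, phi)
                    else:
                        break
        # end batch
    return out
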