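"""Numba kernels for positron and photon histories.

Scenes are packed into flat arrays (one row per volume) so the transport
loops compile to machine code.  Volume encoding:

* ``kind`` 0: finite cylinder; params = cx, cy, cz, ax, ay, az, r, half_len
* ``kind`` 1: axis-aligned box;  params = cx, cy, cz, hx, hy, hz, 0, 0

Materials are packed as a shared log10-energy grid with per-material log10
mass stopping powers, a linear-stopping conversion factor (keV/mm), 511 keV
linear attenuation (1/mm) and radiation length (mm).

The positron model is mixed condensed-history CSDA stepping with a
fractional energy loss per step: soft multiple scattering as Highland-style
Gaussian angular diffusion, plus explicit hard elastic events beyond a 30
degree cutoff sampled from the Wentzel (screened-Rutherford) cross-section
with Moliere screening — the tail the Gaussian model misses, which governs
backscatter and deep-penetration falloff.  A 10 keV tracking cutoff
deposits the residual locally; annihilation emits two collinear
back-to-back 511 keV photons.  Photons interact at most once (single
Compton in the fiber; any interaction elsewhere terminates the history).
"""

import numpy as np
from numba import njit

MEC2 = 510.99895
_EPS_CROSS = 1e-6  # mm overshoot when stepping across a boundary
_BIG = 1e30
_ALPHA = 1.0 / 137.035999084
_HARD_UC = 1.0 - np.cos(np.deg2rad(30.0))  # hard-event angular cutoff


@njit(cache=True)
def _ray_interval(kind, params, ox, oy, oz, dx, dy, dz):
    """Entry/exit distances of a ray with one solid; (t0, t1, hit)."""
    cx, cy, cz = params[0], params[1], params[2]
    px, py, pz = ox - cx, oy - cy, oz - cz
    if kind == 1:
        t0, t1 = -_BIG, _BIG
        for i in range(3):
            o = px if i == 0 else (py if i == 1 else pz)
            d = dx if i == 0 else (dy if i == 1 else dz)
            h = params[3 + i]
            if abs(d) < 1e-300:
                if abs(o) > h:
                    return 0.0, 0.0, False
                continue
            ta = (-h - o) / d
            tb = (h - o) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
        if t1 > t0:
            return t0, t1, True
        return 0.0, 0.0, False
    ax, ay, az = params[3], params[4], params[5]
    r = params[6]
    hl = params[7]
    za = px * ax + py * ay + pz * az
    da = dx * ax + dy * ay + dz * az
    opx, opy, opz = px - za * ax, py - za * ay, pz - za * az
    dpx, dpy, dpz = dx - da * ax, dy - da * ay, dz - da * az
    a = dpx * dpx + dpy * dpy + dpz * dpz
    b = 2.0 * (opx * dpx + opy * dpy + opz * dpz)
    c = opx * opx + opy * opy + opz * opz - r * r
    if a < 1e-300:
        if c > 0.0:
            return 0.0, 0.0, False
        t0, t1 = -_BIG, _BIG
    else:
        disc = b * b - 4.0 * a * c
        if disc <= 0.0:
            return 0.0, 0.0, False
        sq = np.sqrt(disc)
        t0 = (-b - sq) / (2.0 * a)
        t1 = (-b + sq) / (2.0 * a)
    if abs(da) < 1e-300:
        if abs(za) > hl:
            return 0.0, 0.0, False
    else:
        ta = (-hl - za) / da
        tb = (hl - za) / da
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    if t1 > t0:
        return t0, t1, True
    return 0.0, 0.0, False


@njit(cache=True)
def _contains(kind, params, x, y, z):
    px, py, pz = x - params[0], y - params[1], z - params[2]
    if kind == 1:
        return (abs(px) <= params[3] and abs(py) <= params[4]
                and abs(pz) <= params[5])
    ax, ay, az = params[3], params[4], params[5]
    za = px * ax + py * ay + pz * az
    if abs(za) > params[7]:
        return False
    r2 = px * px + py * py + pz * pz - za * za
    return r2 <= params[6] * params[6]


@njit(cache=True)
def _locate(vkind, vparams, vprio, x, y, z):
    """Index of the highest-priority volume containing the point; -1 if
    outside the enclosing world (volume 0)."""
    if not _contains(vkind[0], vparams[0], x, y, z):
        return -1
    best = 0
    bestp = vprio[0]
    for i in range(1, vkind.shape[0]):
        if vprio[i] > bestp and _contains(vkind[i], vparams[i], x, y, z):
            best = i
            bestp = vprio[i]
    return best


@njit(cache=True)
def _dist_to_boundary(vkind, vparams, ox, oy, oz, dx, dy, dz):
    """Distance to the nearest surface crossing ahead of the ray."""
    tmin = _BIG
    for i in range(vkind.shape[0]):
        t0, t1, hit = _ray_interval(vkind[i], vparams[i], ox, oy, oz, dx, dy, dz)
        if not hit:
            continue
        if t0 > 1e-9 and t0 < tmin:
            tmin = t0
        if t1 > 1e-9 and t1 < tmin:
            tmin = t1
    return tmin


@njit(cache=True)
def _stop_kev_mm(logE_grid, logS, s_scale, mat, E):
    """Linear collision stopping power, keV/mm (log-log interpolation)."""
    x = np.log10(E)
    if x < logE_grid[0]:
        x = logE_grid[0]
    elif x > logE_grid[-1]:
        x = logE_grid[-1]
    y = np.interp(x, logE_grid, logS[mat])
    return 10.0 ** y * s_scale[mat]


@njit(cache=True)
def _deflect(dx, dy, dz, theta, phi):
    """Rotate a unit vector by polar angle theta, azimuth phi about itself."""
    if abs(dx) < 0.9:
        tx, ty, tz = 1.0, 0.0, 0.0
    else:
        tx, ty, tz = 0.0, 1.0, 0.0
    ux = dy * tz - dz * ty
    uy = dz * tx - dx * tz
    uz = dx * ty - dy * tx
    un = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    wx = dy * uz - dz * uy
    wy = dz * ux - dx * uz
    wz = dx * uy - dy * ux
    st, ct = np.sin(theta), np.cos(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    nx = dx * ct + st * (ux * cp + wx * sp)
    ny = dy * ct + st * (uy * cp + wy * sp)
    nz = dz * ct + st * (uz * cp + wz * sp)
    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / nn, ny / nn, nz / nn


@njit(cache=True)
def _highland_theta0(E_keV, step_mm, x0_mm):
    """Highland multiple-scattering width (plane-projected, radians)."""
    if step_mm <= 0.0 or x0_mm <= 0.0:
        return 0.0
    pc2 = E_keV * (E_keV + 2.0 * MEC2)
    beta_pc = pc2 / (E_keV + MEC2)  # beta * p * c in keV
    x = step_mm / x0_mm
    lg = 1.0 + 0.038 * np.log(x)
    if lg < 0.25:
        lg = 0.25
    return 13600.0 / beta_pc * np.sqrt(x) * lg


@njit(cache=True)
def _hard_scatter_params(E, k_mm, z_eff):
    """Rate (1/mm) of elastic deflections beyond the angular cutoff, and
    the Moliere screening parameter eta, for kinetic energy E (keV)."""
    pc2 = E * (E + 2.0 * MEC2)
    pc = np.sqrt(pc2)
    beta = pc / (E + MEC2)
    beta_pc = pc * beta
    x = _ALPHA * z_eff ** (1.0 / 3.0) * MEC2 / (0.885 * pc)
    eta = 0.25 * x * x * (1.13 + 3.76 * (_ALPHA * z_eff / beta) ** 2)
    geom = 1.0 / (_HARD_UC + 2.0 * eta) - 1.0 / (2.0 + 2.0 * eta)
    rate = k_mm * (MEC2 / beta_pc) ** 2 * geom
    return rate, eta


@njit(cache=True)
def _sample_hard_u(eta):
    """Sample u = 1 - cos(theta) from the Wentzel tail above the cutoff."""
    A = 1.0 / (_HARD_UC + 2.0 * eta)
    B = 1.0 / (2.0 + 2.0 * eta)
    xi = np.random.random()
    return 1.0 / (A - xi * (A - B)) - 2.0 * eta


@njit(cache=True)
def _sample_kn_recoil(E):
    """Klein-Nishina electron recoil energy (keV) for photon energy E."""
    k = E / MEC2
    eps0 = 1.0 / (1.0 + 2.0 * k)
    a1 = np.log(1.0 / eps0)
    a2 = 0.5 * (1.0 - eps0 * eps0)
    while True:
        if np.random.random() < a1 / (a1 + a2):
            eps = eps0 * np.exp(a1 * np.random.random())
        else:
            eps = np.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * np.random.random())
        cost = 1.0 - (1.0 - eps) / (k * eps)
        sin2 = 1.0 - cost * cost
        g = 1.0 - eps * sin2 / (1.0 + eps * eps)
        if np.random.random() <= g:
            return E * (1.0 - eps)


@njit(cache=True)
def _transport_positron(
    vkind, vparams, vprio, vmat,
    logE_grid, logS, s_scale, x0_mm, k_hard, z_eff,
    x, y, z, dx, dy, dz, E,
    step_fraction, cutoff, scatter_scale, max_step, dep_row,
):
    """One condensed-history positron track.

    Deposits per volume are accumulated into ``dep_row``; returns
    (annihilated, x, y, z, escaped_energy).
    """
    while True:
        iv = _locate(vkind, vparams, vprio, x, y, z)
        if iv < 0:
            return False, x, y, z, E
        mat = vmat[iv]
        S = _stop_kev_mm(logE_grid, logS, s_scale, mat, E)
        ds = step_fraction * E / S
        if ds > max_step:
            ds = max_step
        tb = _dist_to_boundary(vkind, vparams, x, y, z, dx, dy, dz)
        cross = tb + _EPS_CROSS
        step = ds if ds < cross else cross
        l_stop = (E - cutoff) / S
        if l_stop <= step:
            # slows below the cutoff inside this step: residual deposited
            # locally, annihilate at rest
            x += l_stop * dx
            y += l_stop * dy
            z += l_stop * dz
            dep_row[iv] += E
            return True, x, y, z, 0.0
        dE = S * step
        dep_row[iv] += dE
        E -= dE
        x += step * dx
        y += step * dy
        z += step * dz
        if scatter_scale > 0.0:
            t0 = _highland_theta0(E + 0.5 * dE, step, x0_mm[mat]) * scatter_scale
            gx = np.random.normal() * t0
            gy = np.random.normal() * t0
            theta = np.sqrt(gx * gx + gy * gy)
            phi = 2.0 * np.pi * np.random.random()
            dx, dy, dz = _deflect(dx, dy, dz, theta, phi)
            rate, eta = _hard_scatter_params(E + 0.5 * dE, k_hard[mat], z_eff[mat])
            n_hard = np.random.poisson(rate * step)
            for _ in range(n_hard):
                u = _sample_hard_u(eta)
                th = np.arccos(1.0 - u)
                ph_h = 2.0 * np.pi * np.random.random()
                dx, dy, dz = _deflect(dx, dy, dz, th, ph_h)


@njit(cache=True)
def _trace_photon(
    vkind, vparams, vprio, vmat, visfiber, mu_mm,
    x, y, z, dx, dy, dz, energy,
):
    """Single-interaction photon trace; returns fiber deposit (keV)."""
    while True:
        iv = _locate(vkind, vparams, vprio, x, y, z)
        if iv < 0:
            return 0.0
        mat = vmat[iv]
        tb = _dist_to_boundary(vkind, vparams, x, y, z, dx, dy, dz)
        mu = mu_mm[mat]
        if mu > 0.0:
            s = -np.log(np.random.random()) / mu
        else:
            s = _BIG
        if s < tb:
            if visfiber[iv] == 1:
                return _sample_kn_recoil(energy)
            return 0.0  # scatter-as-absorption outside the fiber
        x += (tb + _EPS_CROSS) * dx
        y += (tb + _EPS_CROSS) * dy
        z += (tb + _EPS_CROSS) * dz


@njit(cache=True)
def positron_batch(
    vkind, vparams, vprio, vmat, visfiber,
    logE_grid, logS, s_scale, x0_mm, mu_mm, k_hard, z_eff,
    points, energies,
    step_fraction, cutoff, scatter_scale, max_step,
    seed, track_photons,
):
    """Batch of positron histories emitted at ``points`` with ``energies``.

    Returns (e_fiber_dep, g_fiber_dep, dep_matrix, escaped_energy,
    terminus, annih_points): terminus 0 = annihilated, 1 = escaped world.
    """
    np.random.seed(seed)
    n = points.shape[0]
    nv = vkind.shape[0]
    e_dep = np.zeros(n)
    g_dep = np.zeros(n)
    dep = np.zeros((n, nv))
    esc = np.zeros(n)
    term = np.zeros(n, dtype=np.int64)
    annih = np.zeros((n, 3))
    for i in range(n):
        ct = 2.0 * np.random.random() - 1.0
        st = np.sqrt(1.0 - ct * ct)
        ph = 2.0 * np.pi * np.random.random()
        dx, dy, dz = st * np.cos(ph), st * np.sin(ph), ct
        ok, ax_, ay_, az_, e_left = _transport_positron(
            vkind, vparams, vprio, vmat,
            logE_grid, logS, s_scale, x0_mm, k_hard, z_eff,
            points[i, 0], points[i, 1], points[i, 2],
            dx, dy, dz, energies[i],
            step_fraction, cutoff, scatter_scale, max_step, dep[i],
        )
        annih[i, 0], annih[i, 1], annih[i, 2] = ax_, ay_, az_
        for j in range(nv):
            if visfiber[j] == 1:
                e_dep[i] += dep[i, j]
        if ok:
            term[i] = 0
            if track_photons == 1:
                ct2 = 2.0 * np.random.random() - 1.0
                st2 = np.sqrt(1.0 - ct2 * ct2)
                ph2 = 2.0 * np.pi * np.random.random()
                gdx, gdy, gdz = st2 * np.cos(ph2), st2 * np.sin(ph2), ct2
                g_dep[i] += _trace_photon(
                    vkind, vparams, vprio, vmat, visfiber, mu_mm,
                    ax_, ay_, az_, gdx, gdy, gdz, 511.0)
                g_dep[i] += _trace_photon(
                    vkind, vparams, vprio, vmat, visfiber, mu_mm,
                    ax_, ay_, az_, -gdx, -gdy, -gdz, 511.0)
        else:
            term[i] = 1
            esc[i] = e_left
    return e_dep, g_dep, dep, esc, term, annih


@njit(cache=True)
def photon_batch(
    vkind, vparams, vprio, vmat, visfiber, mu_mm,
    points, directions, energy, seed,
):
    """Batch of single photons from given points/directions; fiber deposits."""
    np.random.seed(seed)
    n = points.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = _trace_photon(
            vkind, vparams, vprio, vmat, visfiber, mu_mm,
            points[i, 0], points[i, 1], points[i, 2],
            directions[i, 0], directions[i, 1], directions[i, 2], energy)
    return out


@njit(cache=True)
def range_batch(
    logE_grid, logS, s_scale, x0_mm, k_hard, z_eff, mat,
    energies, step_fraction, cutoff, scatter_scale, max_step, seed,
):
    """Emission-to-rest displacement (mm) in an infinite homogeneous medium."""
    np.random.seed(seed)
    n = energies.shape[0]
    out = np.empty(n)
    for i in range(n):
        ct = 2.0 * np.random.random() - 1.0
        st = np.sqrt(1.0 - ct * ct)
        ph = 2.0 * np.pi * np.random.random()
        dx, dy, dz = st * np.cos(ph), st * np.sin(ph), ct
        x = y = z = 0.0
        E = energies[i]
        while E > cutoff:
            S = _stop_kev_mm(logE_grid, logS, s_scale, mat, E)
            ds = step_fraction * E / S
            if ds > max_step:
                ds = max_step
            l_stop = (E - cutoff) / S
            if l_stop <= ds:
                x += l_stop * dx
                y += l_stop * dy
                z += l_stop * dz
                break
            dE = S * ds
            E -= dE
            x += ds * dx
            y += ds * dy
            z += ds * dz
            if scatter_scale > 0.0:
                t0 = _highland_theta0(E + 0.5 * dE, ds, x0_mm[mat]) * scatter_scale
                gx = np.random.normal() * t0
                gy = np.random.normal() * t0
                theta = np.sqrt(gx * gx + gy * gy)
                phi = 2.0 * np.pi * np.random.random()
                dx, dy, dz = _deflect(dx, dy, dz, theta, phi)
                rate, eta = _hard_scatter_params(E + 0.5 * dE, k_hard[mat], z_eff[mat])
                n_hard = np.random.poisson(rate * ds)
                for _ in range(n_hard):
                    u = _sample_hard_u(eta)
                    th = np.arccos(1.0 - u)
                    ph_h = 2.0 * np.pi * np.random.random()
                    dx, dy, dz = _deflect(dx, dy, dz, th, ph_h)
        out[i] = np.sqrt(x * x + y * y + z * z)
    return out
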