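"""Numba transport kernels.

The engine tracks photons with Woodcock (delta) tracking against a
cell-local majorant: free paths are sampled from the majorant attenuation of
the coarse cell the photon is in, capped at the cell boundary, and tentative
collisions are accepted with probability mu_local / mu_majorant.  Using a
cell-local majorant keeps the virtual-collision rate acceptable even though
the scene contains lead, whose attenuation exceeds air's by five orders of
magnitude.  The majorant mesh doubles as the air-kerma map grid, so every
movement substep lies inside a single air-map voxel and can be scored with
the track-length kerma estimator as it happens.

All positions are metres, energies keV, linear attenuations 1/m.  Energy
deposition is local (kerma approximation, electron transport suppressed).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MEC2_KEV = 510.99895


@njit(cache=True, inline="always")
def _rotate(u, v, w, cos_t, phi):
    """Rotate unit vector (u,v,w) by polar angle acos(cos_t), azimuth phi."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cphi = math.cos(phi)
    sphi = math.sin(phi)
    denom2 = 1.0 - w * w
    if denom2 > 1e-12:
        denom = math.sqrt(denom2)
        un = u * cos_t + sin_t * (u * w * cphi - v * sphi) / denom
        vn = v * cos_t + sin_t * (v * w * cphi + u * sphi) / denom
        wn = w * cos_t - sin_t * denom * cphi
    else:
        un = sin_t * cphi
        vn = sin_t * sphi
        wn = cos_t if w > 0 else -cos_t
    norm = math.sqrt(un * un + vn * vn + wn * wn)
    return un / norm, vn / norm, wn / norm


@njit(cache=True, inline="always")
def _kahn_compton(e_kev):
    """Sample a Klein-Nishina scattering cosine by Kahn's method.

    Returns (cos_theta, e_prime_kev) for a free electron at rest.
    """
    k = e_kev / MEC2_KEV
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 * (9.0 + 2.0 * k) <= (1.0 + 2.0 * k):
            x = 1.0 + 2.0 * k * r2          # x = E / E'
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                break
        else:
            x = (1.0 + 2.0 * k) / (1.0 + 2.0 * k * r2)
            cos_t = 1.0 - (x - 1.0) / k
            if r3 <= 0.5 * (cos_t * cos_t + 1.0 / x):
                break
    cos_t = 1.0 - (x - 1.0) / k
    return cos_t, e_kev / x


@njit(cache=True, inline="always")
def _thomson_cosine():
    """Sample cos(theta) from the Thomson law ~ (1 + cos^2)."""
    while True:
        mu = 2.0 * np.random.random() - 1.0
        if np.random.random() * 2.0 <= 1.0 + mu * mu:
            return mu


@njit(cache=True, inline="always")
def _mu_interp(table, e, e0, inv_de, n):
    """Linear interpolation of a (n,) fine-grid table at energy e."""
    t = (e - e0) * inv_de
    if t <= 0.0:
        return table[0]
    i = int(t)
    if i >= n - 1:
        return table[n - 1]
    f = t - i
    return table[i] * (1.0 - f) + table[i + 1] * f


@njit(cache=True)
def run_batch(seed, src_x, src_y, src_z, dirs, energies,
              mat, ox, oy, oz, sx, sy, sz,
              mu_fine, cum_photo, cum_pi, e0, de,
              maj, mox, moy, moz, msx, msy, msz, eb0, ebw,
              muen_air_fine, airmap, edep, muen_fine, kerma,
              cutoff, max_interactions, air_id):
    """Track one batch of photons from a common point source.

    ``mat`` is the (nx,ny,nz) uint8 material grid; ``mu_fine``/``cum_*`` are
    (n_ids, nE) fine-energy tables; ``maj`` is the (mx,my,mz,neb) cell-local
    majorant (1/m); ``airmap`` accumulates track-length kerma contributions
    (keV * cm^2/g * cm) in cells whose scene material is air; ``edep``
    accumulates analog energy deposits (keV) per scene voxel.

    ``kerma`` accumulates the collision-kerma estimate per scene voxel in
    the same units as ``airmap``: every tentative (real or virtual)
    collision scores E * (mu_en/rho)_material / mu_majorant, whose
    expectation per unit track length is E * mu_en/rho -- an unbiased,
    fluence-based kerma estimator with far lower variance than analog
    deposition in thin regions such as a phantom's skin shell.

    Returns (emitted, deposited, escaped, corrupted_energy,
    n_corrupted, n_virtual, n_real, n_escaped_uncollided); the last counter
    tags photons that left the scene without any real interaction, which is
    the narrow-beam (uncollided) transmission statistic.
    """
    np.random.seed(seed)
    nx, ny, nz = mat.shape
    mx, my, mz, neb = maj.shape
    n_e = mu_fine.shape[1]
    inv_de = 1.0 / de

    emitted = 0.0
    deposited = 0.0
    escaped = 0.0
    corrupted_e = 0.0
    n_corrupted = 0
    n_virtual = 0
    n_real = 0
    n_unc = 0

    for i in range(dirs.shape[0]):
        x = src_x
        y = src_y
        z = src_z
        u = dirs[i, 0]
        v = dirs[i, 1]
        w = dirs[i, 2]
        e = energies[i]
        emitted += e
        nint = 0
        nstep = 0
        alive = True
        while alive:
            nstep += 1
            if nstep > 10_000_000 or not (math.isfinite(x + y + z + e)):
                n_corrupted += 1
                corrupted_e += e
                break
            # majorant cell (floor, not int(): positions below the origin
            # must map to negative indices, i.e. escape)
            cx = int(math.floor((x - mox) / msx))
            cy = int(math.floor((y - moy) / msy))
            cz = int(math.floor((z - moz) / msz))
            if cx < 0 or cx >= mx or cy < 0 or cy >= my or cz < 0 or cz >= mz:
                escaped += e
                if nint == 0:
                    n_unc += 1
                break
            eb = int((e - eb0) / ebw)
            if eb < 0:
                eb = 0
            elif eb >= neb:
                eb = neb - 1
            mj = maj[cx, cy, cz, eb]

            # distance to the majorant-cell exit along the flight direction
            if u > 0.0:
                tx = ((cx + 1) * msx + mox - x) / u
            elif u < 0.0:
                tx = (cx * msx + mox - x) / u
            else:
                tx = 1e30
            if v > 0.0:
                ty = ((cy + 1) * msy + moy - y) / v
            elif v < 0.0:
                ty = (cy * msy + moy - y) / v
            else:
                ty = 1e30
            if w > 0.0:
                tz = ((cz + 1) * msz + moz - z) / w
            elif w < 0.0:
                tz = (cz * msz + moz - z) / w
            else:
                tz = 1e30
            d_exit = min(tx, min(ty, tz))
            if d_exit < 0.0:
                d_exit = 0.0

            s = -math.log(np.random.random()) / mj
            crossing = s >= d_exit
            step = d_exit + 1e-6 if crossing else s

            # track-length kerma scoring in air cells
            hx = x + 0.5 * step * u
            hy = y + 0.5 * step * v
            hz = z + 0.5 * step * w
            ix = int(math.floor((hx - ox) / sx))
            iy = int(math.floor((hy - oy) / sy))
            iz = int(math.floor((hz - oz) / sz))
            if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                if mat[ix, iy, iz] == air_id:
                    muen = _mu_interp(muen_air_fine, e, e0, inv_de, n_e)
                    airmap[cx, cy, cz] += e * muen * step * 100.0

            x += step * u
            y += step * v
            z += step * w
            if crossing:
                continue

            # tentative collision
            ix = int(math.floor((x - ox) / sx))
            iy = int(math.floor((y - oy) / sy))
            iz = int(math.floor((z - oz) / sz))
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                escaped += e
                if nint == 0:
                    n_unc += 1
                break
            m = mat[ix, iy, iz]
            kerma[ix, iy, iz] += e * _mu_interp(muen_fine[m], e, e0,
                                                inv_de, n_e) / mj * 100.0
            mu_loc = _mu_interp(mu_fine[m], e, e0, inv_de, n_e)
            if np.random.random() * mj > mu_loc:
                n_virtual += 1
                continue

            n_real += 1
            nint += 1
            if nint > max_interactions:
                n_corrupted += 1
                corrupted_e += e
                break
            r = np.random.random()
            cp = _mu_interp(cum_photo[m], e, e0, inv_de, n_e)
            if r < cp:
                edep[ix, iy, iz] += e
                deposited += e
                break
            cpi = _mu_interp(cum_pi[m], e, e0, inv_de, n_e)
            phi = 2.0 * math.pi * np.random.random()
            if r < cpi:
                cos_t, e_prime = _kahn_compton(e)
                if e_prime < cutoff:
                    edep[ix, iy, iz] += e
                    deposited += e
                    break
                edep[ix, iy, iz] += e - e_prime
                deposited += e - e_prime
                e = e_prime
                u, v, w = _rotate(u, v, w, cos_t, phi)
            else:
                cos_t = _thomson_cosine()
                u, v, w = _rotate(u, v, w, cos_t, phi)
    return (emitted, deposited, escaped, corrupted_e, n_corrupted,
            n_virtual, n_real, n_unc)


@njit(cache=True)
def trace_segment(p0, p1, origin, spacing, dims, idx_out, len_out):
    """Amanatides-Woo traversal of the segment p0 -> p1 over a voxel grid.

    Fills ``idx_out`` with flat voxel indices and ``len_out`` with chord
    lengths (m); returns the number of voxels visited.  Chords use half-open
    voxel intervals, so lengths sum to the in-grid portion of the segment.
    """
    dx = p1[0] - p0[0]
    dy = p1[1] - p0[1]
    dz = p1[2] - p0[2]
    seg = math.sqrt(dx * dx + dy * dy + dz * dz)
    if seg <= 0.0:
        return 0
    ux = dx / seg
    uy = dy / seg
    uz = dz / seg
    t = 0.0
    count = 0
    eps = 1e-12
    while t < seg - eps and count < idx_out.shape[0]:
        px = p0[0] + (t + eps) * ux
        py = p0[1] + (t + eps) * uy
        pz = p0[2] + (t + eps) * uz
        ix = int(math.floor((px - origin[0]) / spacing[0]))
        iy = int(math.floor((py - origin[1]) / spacing[1]))
        iz = int(math.floor((pz - origin[2]) / spacing[2]))
        if ix < 0 or ix >= dims[0] or iy < 0 or iy >= dims[1] \
                or iz < 0 or iz >= dims[2]:
            # advance to the grid boundary crossing and keep going
            t_next = seg
        else:
            t_next = seg
        # distance to next voxel boundary along each axis
        if ux > 0.0:
            bx = origin[0] + (ix + 1) * spacing[0]
            tb = (bx - p0[0]) / ux
        elif ux < 0.0:
            bx = origin[0] + ix * spacing[0]
            tb = (bx - p0[0]) / ux
        else:
            tb = 1e30
        if tb < t_next:
            t_next = tb
        if uy > 0.0:
            by = origin[1] + (iy + 1) * spacing[1]
            tb = (by - p0[1]) / uy
        elif uy < 0.0:
            by = origin[1] + iy * spacing[1]
            tb = (by - p0[1]) / uy
        else:
            tb = 1e30
        if tb < t_next:
            t_next = tb
        if uz > 0.0:
            bz = origin[2] + (iz + 1) * spacing[2]
            tb = (bz - p0[2]) / uz
        elif uz < 0.0:
            bz = origin[2] + iz * spacing[2]
            tb = (bz - p0[2]) / uz
        else:
            tb = 1e30
        if tb < t_next:
            t_next = tb
        if t_next <= t:
            t_next = t + eps * 10
        if t_next > seg:
            t_next = seg
        if 0 <= ix < dims[0] and 0 <= iy < dims[1] and 0 <= iz < dims[2]:
            idx_out[count] = (ix * dims[1] + iy) * dims[2] + iz
            len_out[count] = t_next - t
            count += 1
        t = t_next
    return count
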