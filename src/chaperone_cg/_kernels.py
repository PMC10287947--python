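"""Compiled Langevin-dynamics driver.

One monolithic numba kernel advances the system with the BAOAB splitting,
maintaining Verlet neighbour lists (separate lists for excluded-volume and
Debye–Hückel pairs, rebuilt on a fixed interval with a distance skin) and
accumulating per-term energies at the snapshot stride.  The energy terms
mirror :mod:`chaperone_cg.energy` exactly; agreement between the two paths
is asserted in the test suite.

Frozen beads (e.g. the translocase anchor ring) are encoded with inverse
mass 0, which removes them from the update without special-casing.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes
OK = 0
NONFINITE = 1

# energy-row layout in the output array
E_BONDED, E_CONTACT, E_EV, E_DH, E_RESTRAINT, E_KINETIC = range(6)
N_ENERGY_TERMS = 6


@njit(cache=True)
def _in_sorted(keys, value):
    lo = np.searchsorted(keys, value)
    return lo < keys.shape[0] and keys[lo] == value


@njit(cache=True)
def _build_pairs(pos, n, cutoff_sq, excl_keys, members, both_needed,
                 out_i, out_j, inv_mass):
    """Candidate pairs among ``members`` within sqrt(cutoff_sq), minus
    exclusions and fully frozen pairs."""
    count = 0
    m = members.shape[0]
    for a in range(m):
        i = members[a]
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        for b in range(a + 1, m):
            j = members[b]
            if inv_mass[i] == 0.0 and inv_mass[j] == 0.0:
                continue
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cutoff_sq:
                continue
            key = i * n + j if i < j else j * n + i
            if _in_sorted(excl_keys, key):
                continue
            out_i[count] = i if i < j else j
            out_j[count] = j if i < j else i
            count += 1
    _ = both_needed
    return count


@njit(cache=True)
def _compute_forces(pos, forces, charges, step_time,
                    bonds_idx, bonds_b0, bonds_k,
                    angles_idx, angles_t0, angles_k,
                    flex_idx, theta0_flex, k_flex,
                    dih_idx, dih_p0, dih_k,
                    con_idx, con_r0, con_eps,
                    ev_i, ev_j, n_ev, sigma_ev, eps_ev, ev_cut,
                    dh_i, dh_j, n_dh, dh_pref, lam, dh_cut,
                    anchor_idx, anchor_ref, anchor_k, anchor_vel,
                    torus_param, torus_on,
                    umb_a, umb_b, umb_d0, umb_k, umb_on,
                    sphere_center, sphere_R, sphere_k, sphere_on,
                    energies, umb_d_out):
    for i in range(pos.shape[0]):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    e_bonded = 0.0
    e_contact = 0.0
    e_ev = 0.0
    e_dh = 0.0
    e_restraint = 0.0

    # bonds
    for t in range(bonds_idx.shape[0]):
        i = bonds_idx[t, 0]
        j = bonds_idx[t, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        db = r - bonds_b0[t]
        kb = bonds_k[t]
        e_bonded += kb * db * db
        f = 2.0 * kb * db / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz

    # angles (native + flexible generic)
    for block in range(2):
        n_terms = angles_idx.shape[0] if block == 0 else flex_idx.shape[0]
        for t in range(n_terms):
            if block == 0:
                i = angles_idx[t, 0]
                j = angles_idx[t, 1]
                k = angles_idx[t, 2]
                t0 = angles_t0[t]
                ka = angles_k[t]
            else:
                i = flex_idx[t, 0]
                j = flex_idx[t, 1]
                k = flex_idx[t, 2]
                t0 = theta0_flex
                ka = k_flex
            ux = pos[i, 0] - pos[j, 0]
            uy = pos[i, 1] - pos[j, 1]
            uz = pos[i, 2] - pos[j, 2]
            vx = pos[k, 0] - pos[j, 0]
            vy = pos[k, 1] - pos[j, 1]
            vz = pos[k, 2] - pos[j, 2]
            nu = np.sqrt(ux * ux + uy * uy + uz * uz)
            nv = np.sqrt(vx * vx + vy * vy + vz * vz)
            c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            theta = np.arccos(c)
            s = np.sqrt(1.0 - c * c)
            if s < 1e-8:
                s = 1e-8
            dth = theta - t0
            e_bonded += ka * dth * dth
            dU = 2.0 * ka * dth
            gix = (c * ux / nu - vx / nv) / (nu * s)
            giy = (c * uy / nu - vy / nv) / (nu * s)
            giz = (c * uz / nu - vz / nv) / (nu * s)
            gkx = (c * vx / nv - ux / nu) / (nv * s)
            gky = (c * vy / nv - uy / nu) / (nv * s)
            gkz = (c * vz / nv - uz / nu) / (nv * s)
            forces[i, 0] -= dU * gix
            forces[i, 1] -= dU * giy
            forces[i, 2] -= dU * giz
            forces[k, 0] -= dU * gkx
            forces[k, 1] -= dU * gky
            forces[k, 2] -= dU * gkz
            forces[j, 0] += dU * (gix + gkx)
            forces[j, 1] += dU * (giy + gky)
            forces[j, 2] += dU * (giz + gkz)

    # dihedrals
    for t in range(dih_idx.shape[0]):
        i = dih_idx[t, 0]
        j = dih_idx[t, 1]
        k = dih_idx[t, 2]
        l = dih_idx[t, 3]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        b3x = pos[l, 0] - pos[k, 0]
        b3y = pos[l, 1] - pos[k, 1]
        b3z = pos[l, 2] - pos[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        # skip near-collinear configurations: the gradient diverges there
        b1sq = b1x * b1x + b1y * b1y + b1z * b1z
        b3sq = b3x * b3x + b3y * b3y + b3z * b3z
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if (n1sq < 0.01 * b1sq * nb2 * nb2
                or n2sq < 0.01 * b3sq * nb2 * nb2):
            continue
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        sinp = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        cosp = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sinp, cosp)
        dphi = phi - dih_p0[t]
        kd = dih_k[t]
        e_bonded += kd * (1.0 - np.cos(dphi))
        dU = kd * np.sin(dphi)
        dix = -nb2 / n1sq * n1x
        diy = -nb2 / n1sq * n1y
        diz = -nb2 / n1sq * n1z
        dlx = nb2 / n2sq * n2x
        dly = nb2 / n2sq * n2y
        dlz = nb2 / n2sq * n2z
        c12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        c32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        djx = -(1.0 + c12) * dix + c32 * dlx
        djy = -(1.0 + c12) * diy + c32 * dly
        djz = -(1.0 + c12) * diz + c32 * dlz
        dkx = c12 * dix - (1.0 + c32) * dlx
        dky = c12 * diy - (1.0 + c32) * dly
        dkz = c12 * diz - (1.0 + c32) * dlz
        forces[i, 0] -= dU * dix
        forces[i, 1] -= dU * diy
        forces[i, 2] -= dU * diz
        forces[j, 0] -= dU * djx
        forces[j, 1] -= dU * djy
        forces[j, 2] -= dU * djz
        forces[k, 0] -= dU * dkx
        forces[k, 1] -= dU * dky
        forces[k, 2] -= dU * dkz
        forces[l, 0] -= dU * dlx
        forces[l, 1] -= dU * dly
        forces[l, 2] -= dU * dlz

    # native contacts (10-12)
    for t in range(con_idx.shape[0]):
        i = con_idx[t, 0]
        j = con_idx[t, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        x = con_r0[t] / r
        x2 = x * x
        x10 = x2 * x2 * x2 * x2 * x2
        x12 = x10 * x2
        e_contact += con_eps[t] * (5.0 * x12 - 6.0 * x10)
        dU_dr = 60.0 * con_eps[t] * (x10 - x12) / r
        f = -dU_dr / r
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz

    # excluded volume (r^-12, shift-force truncation)
    ev_cut2 = ev_cut * ev_cut
    ev_shift = (sigma_ev / ev_cut) ** 12
    ev_fshift = 12.0 * ev_shift / ev_cut
    for t in range(n_ev):
        i = ev_i[t]
        j = ev_j[t]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= ev_cut2:
            continue
        r = np.sqrt(r2)
        x12 = (sigma_ev / r) ** 12
        e_ev += eps_ev * (x12 - ev_shift + ev_fshift * (r - ev_cut))
        dU_dr = eps_ev * (-12.0 * x12 / r + ev_fshift)
        f = -dU_dr / r
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz

    # Debye-Hueckel (shift-force truncation)
    dh_cut2 = dh_cut * dh_cut
    dh_shift = np.exp(-dh_cut / lam) / dh_cut
    dh_gprime = -np.exp(-dh_cut / lam) * (1.0 / (lam * dh_cut)
                                          + 1.0 / (dh_cut * dh_cut))
    for t in range(n_dh):
        i = dh_i[t]
        j = dh_j[t]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= dh_cut2:
            continue
        r = np.sqrt(r2)
        qq = dh_pref * charges[i] * charges[j]
        ex = np.exp(-r / lam)
        e_dh += qq * (ex / r - dh_shift - dh_gprime * (r - dh_cut))
        dU_dr = qq * (ex * (-1.0 / (lam * r) - 1.0 / r2) - dh_gprime)
        f = -dU_dr / r
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz

    # --- restraints ---------------------------------------------------
    # position anchors (optionally moving at anchor_vel Å/step)
    for t in range(anchor_idx.shape[0]):
        i = anchor_idx[t]
        rx = anchor_ref[t, 0] + anchor_vel[t, 0] * step_time
        ry = anchor_ref[t, 1] + anchor_vel[t, 1] * step_time
        rz = anchor_ref[t, 2] + anchor_vel[t, 2] * step_time
        dx = pos[i, 0] - rx
        dy = pos[i, 1] - ry
        dz = pos[i, 2] - rz
        e_restraint += anchor_k[t] * (dx * dx + dy * dy + dz * dz)
        forces[i, 0] -= 2.0 * anchor_k[t] * dx
        forces[i, 1] -= 2.0 * anchor_k[t] * dy
        forces[i, 2] -= 2.0 * anchor_k[t] * dz

    # torus translocase: repulsion from the tube centre circle
    if torus_on == 1:
        cx, cy, cz = torus_param[0], torus_param[1], torus_param[2]
        ax, ay, az = torus_param[3], torus_param[4], torus_param[5]
        R = torus_param[6]
        rt = torus_param[7]
        eps_t = torus_param[8]
        for i in range(pos.shape[0]):
            vx = pos[i, 0] - cx
            vy = pos[i, 1] - cy
            vz = pos[i, 2] - cz
            z = vx * ax + vy * ay + vz * az
            px = vx - z * ax
            py = vy - z * ay
            pz = vz - z * az
            rho = np.sqrt(px * px + py * py + pz * pz)
            d = np.sqrt((rho - R) * (rho - R) + z * z)
            if d >= rt or d < 1e-9:
                continue
            u = (rt - d) / rt
            e_restraint += eps_t * u * u
            dU_dd = -2.0 * eps_t * u / rt
            # dd/dp = ((rho-R) * p_hat + z * a) / d
            if rho > 1e-9:
                gx = ((rho - R) * px / rho + z * ax) / d
                gy = ((rho - R) * py / rho + z * ay) / d
                gz = ((rho - R) * pz / rho + z * az) / d
            else:
                gx = z * ax / d
                gy = z * ay / d
                gz = z * az / d
            forces[i, 0] -= dU_dd * gx
            forces[i, 1] -= dU_dd * gy
            forces[i, 2] -= dU_dd * gz

    # COM-distance umbrella
    umb_d = 0.0
    if umb_on == 1:
        ax_ = 0.0
        ay_ = 0.0
        az_ = 0.0
        for t in range(umb_a.shape[0]):
            i = umb_a[t]
            ax_ += pos[i, 0]
            ay_ += pos[i, 1]
            az_ += pos[i, 2]
        na = umb_a.shape[0]
        ax_ /= na
        ay_ /= na
        az_ /= na
        bx_ = 0.0
        by_ = 0.0
        bz_ = 0.0
        for t in range(umb_b.shape[0]):
            i = umb_b[t]
            bx_ += pos[i, 0]
            by_ += pos[i, 1]
            bz_ += pos[i, 2]
        nb = umb_b.shape[0]
        bx_ /= nb
        by_ /= nb
        bz_ /= nb
        dx = ax_ - bx_
        dy = ay_ - by_
        dz = az_ - bz_
        umb_d = np.sqrt(dx * dx + dy * dy + dz * dz)
        dev = umb_d - umb_d0
        e_restraint += umb_k * dev * dev
        if umb_d > 1e-9:
            fmag = 2.0 * umb_k * dev / umb_d
            fax = -fmag * dx / na
            fay = -fmag * dy / na
            faz = -fmag * dz / na
            for t in range(umb_a.shape[0]):
                i = umb_a[t]
                forces[i, 0] += fax
                forces[i, 1] += fay
                forces[i, 2] += faz
            fbx = fmag * dx / nb
            fby = fmag * dy / nb
            fbz = fmag * dz / nb
            for t in range(umb_b.shape[0]):
                i = umb_b[t]
                forces[i, 0] += fbx
                forces[i, 1] += fby
                forces[i, 2] += fbz

    # flat-bottom spherical confinement
    if sphere_on == 1:
        for i in range(pos.shape[0]):
            dx = pos[i, 0] - sphere_center[0]
            dy = pos[i, 1] - sphere_center[1]
            dz = pos[i, 2] - sphere_center[2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r <= sphere_R or r < 1e-9:
                continue
            dev = r - sphere_R
            e_restraint += sphere_k * dev * dev
            f = -2.0 * sphere_k * dev / r
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz

    # numerical-robustness cap: bound the per-bead force magnitude.  In
    # equilibrium sampling forces stay far below the cap; it only
    # disarms the singular cores of pair potentials after rare extreme
    # fluctuations, preventing unphysical bead launches.
    fcap2 = 500.0 * 500.0
    for i in range(pos.shape[0]):
        f2 = (forces[i, 0] * forces[i, 0] + forces[i, 1] * forces[i, 1]
              + forces[i, 2] * forces[i, 2])
        if f2 > fcap2:
            scale = np.sqrt(fcap2 / f2)
            forces[i, 0] *= scale
            forces[i, 1] *= scale
            forces[i, 2] *= scale

    energies[E_BONDED] = e_bonded
    energies[E_CONTACT] = e_contact
    energies[E_EV] = e_ev
    energies[E_DH] = e_dh
    energies[E_RESTRAINT] = e_restraint
    umb_d_out[0] = umb_d


@njit(cache=True)
def run_langevin(pos, vel, inv_mass, charges,
                 bonds_idx, bonds_b0, bonds_k,
                 angles_idx, angles_t0, angles_k,
                 flex_idx, theta0_flex, k_flex,
                 dih_idx, dih_p0, dih_k,
                 con_idx, con_r0, con_eps,
                 ev_excl_keys, dh_excl_keys,
                 sigma_ev, eps_ev, ev_cut,
                 dh_pref, lam, dh_cut,
                 anchor_idx, anchor_ref, anchor_k, anchor_vel,
                 torus_param, torus_on,
                 umb_a, umb_b, umb_d0, umb_k, umb_on,
                 sphere_center, sphere_R, sphere_k, sphere_on,
                 dt, gamma, kT, n_steps, stride, rebuild, skin, seed,
                 step_offset,
                 out_pos, out_energies, out_umb_d):
    """BAOAB Langevin propagation; returns (status, offending bead).

    ``out_pos``: (n_frames, N, 3); frame 0 is the initial configuration,
    then one frame per ``stride`` steps.  ``out_energies``: per-frame
    [bonded, contact, ev, dh, restraint, kinetic].  ``step_offset`` shifts
    the moving-anchor clock so chained runs continue smoothly.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energies = np.zeros(N_ENERGY_TERMS)
    umb_scratch = np.zeros(1)

    charged = np.flatnonzero(charges)
    everyone = np.arange(n)
    max_pairs = n * (n - 1) // 2
    ev_i = np.empty(max_pairs, np.int64)
    ev_j = np.empty(max_pairs, np.int64)
    nch = charged.shape[0]
    dh_i = np.empty(max(nch * (nch - 1) // 2, 1), np.int64)
    dh_j = np.empty(max(nch * (nch - 1) // 2, 1), np.int64)

    ev_build_cut = (ev_cut + skin) ** 2
    dh_build_cut = (dh_cut + skin) ** 2
    n_ev = _build_pairs(pos, n, ev_build_cut, ev_excl_keys, everyone, 0,
                        ev_i, ev_j, inv_mass)
    n_dh = _build_pairs(pos, n, dh_build_cut, dh_excl_keys, charged, 0,
                        dh_i, dh_j, inv_mass)

    c1 = np.exp(-gamma * dt)
    noise_scale = np.sqrt(kT * (1.0 - c1 * c1))

    _compute_forces(pos, forces, charges, step_offset,
                    bonds_idx, bonds_b0, bonds_k,
                    angles_idx, angles_t0, angles_k,
                    flex_idx, theta0_flex, k_flex,
                    dih_idx, dih_p0, dih_k,
                    con_idx, con_r0, con_eps,
                    ev_i, ev_j, n_ev, sigma_ev, eps_ev, ev_cut,
                    dh_i, dh_j, n_dh, dh_pref, lam, dh_cut,
                    anchor_idx, anchor_ref, anchor_k, anchor_vel,
                    torus_param, torus_on,
                    umb_a, umb_b, umb_d0, umb_k, umb_on,
                    sphere_center, sphere_R, sphere_k, sphere_on,
                    energies, umb_scratch)

    frame = 0
    ke = 0.0
    for i in range(n):
        if inv_mass[i] > 0.0:
            m = 1.0 / inv_mass[i]
            ke += 0.5 * m * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    for t in range(N_ENERGY_TERMS - 1):
        out_energies[frame, t] = energies[t]
    out_energies[frame, E_KINETIC] = ke
    out_umb_d[frame] = umb_scratch[0]
    for i in range(n):
        out_pos[frame, i, 0] = pos[i, 0]
        out_pos[frame, i, 1] = pos[i, 1]
        out_pos[frame, i, 2] = pos[i, 2]
    frame += 1

    for step in range(1, n_steps + 1):
        # B
        for i in range(n):
            im = inv_mass[i]
            vel[i, 0] += 0.5 * dt * forces[i, 0] * im
            vel[i, 1] += 0.5 * dt * forces[i, 1] * im
            vel[i, 2] += 0.5 * dt * forces[i, 2] * im
        # A
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        # O
        if gamma > 0.0:
            for i in range(n):
                im = inv_mass[i]
                if im > 0.0:
                    s = noise_scale * np.sqrt(im)
                    vel[i, 0] = c1 * vel[i, 0] + s * np.random.standard_normal()
                    vel[i, 1] = c1 * vel[i, 1] + s * np.random.standard_normal()
                    vel[i, 2] = c1 * vel[i, 2] + s * np.random.standard_normal()
        # A
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]

        if step % rebuild == 0:
            n_ev = _build_pairs(pos, n, ev_build_cut, ev_excl_keys, everyone,
                                0, ev_i, ev_j, inv_mass)
            n_dh = _build_pairs(pos, n, dh_build_cut, dh_excl_keys, charged,
                                0, dh_i, dh_j, inv_mass)

        _compute_forces(pos, forces, charges, step_offset + step,
                        bonds_idx, bonds_b0, bonds_k,
                        angles_idx, angles_t0, angles_k,
                        flex_idx, theta0_flex, k_flex,
                        dih_idx, dih_p0, dih_k,
                        con_idx, con_r0, con_eps,
                        ev_i, ev_j, n_ev, sigma_ev, eps_ev, ev_cut,
                        dh_i, dh_j, n_dh, dh_pref, lam, dh_cut,
                        anchor_idx, anchor_ref, anchor_k, anchor_vel,
                        torus_param, torus_on,
                        umb_a, umb_b, umb_d0, umb_k, umb_on,
                        sphere_center, sphere_R, sphere_k, sphere_on,
                        energies, umb_scratch)

        # B
        for i in range(n):
            im = inv_mass[i]
            vel[i, 0] += 0.5 * dt * forces[i, 0] * im
            vel[i, 1] += 0.5 * dt * forces[i, 1] * im
            vel[i, 2] += 0.5 * dt * forces[i, 2] * im

        if step % stride == 0:
            ke = 0.0
            bad = -1
            for i in range(n):
                if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])
                        and np.isfinite(pos[i, 2])):
                    bad = i
                    break
                if inv_mass[i] > 0.0:
                    m = 1.0 / inv_mass[i]
                    ke += 0.5 * m * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                     + vel[i, 2] ** 2)
            if bad >= 0:
                return NONFINITE, bad
            for t in range(N_ENERGY_TERMS - 1):
                out_energies[frame, t] = energies[t]
            out_energies[frame, E_KINETIC] = ke
            out_umb_d[frame] = umb_scratch[0]
            for i in range(n):
                out_pos[frame, i, 0] = pos[i, 0]
                out_pos[frame, i, 1] = pos[i, 1]
                out_pos[frame, i, 2] = pos[i, 2]
            frame += 1
    return OK, -1
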