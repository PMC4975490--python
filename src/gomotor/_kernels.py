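"""Numba kernels: energy/force evaluation and the BBK Langevin step.

All arrays are in reduced units (nm, eps_h, m = 1).  The kernels operate on
flat term arrays packed by :meth:`gomotor.hamiltonian.EnergyModel.pack`:

* bonds      — harmonic, E = k/2 (r - r0)^2
* angles     — harmonic, E = k/2 (theta - theta0)^2
* dihedrals  — E = sum_{n=1,3} k_n (1 - cos[n(phi - phi0)])
* contacts   — 10-12 form, E = eps (5 (r0/r)^12 - 6 (r0/r)^10)
* repulsion  — E = eps_l (sigma/r)^12

Degenerate internal coordinates (collinear angle/dihedral frames) are
guarded: the energy uses the limiting value and the force contribution is
dropped, which only matters at measure-zero configurations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TINY = 1e-12


@njit(cache=True)
def _ef_terms(coords,
              bond_idx, bond_r0, bond_k,
              ang_idx, ang_theta0, ang_k,
              dih_idx, dih_phi0, dih_k1, dih_k3,
              pair_idx, pair_r0, pair_eps,
              rep_idx, rep_eps, rep_sigma,
              forces):
    """Accumulate forces; return (e_bond, e_angle, e_dihedral, e_contact, e_rep)."""
    e_bond = 0.0
    for b in range(bond_idx.shape[0]):
        i = bond_idx[b, 0]
        j = bond_idx[b, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < _TINY:
            continue
        dr = r - bond_r0[b]
        e_bond += 0.5 * bond_k[b] * dr * dr
        f = -bond_k[b] * dr / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz

    e_ang = 0.0
    for a in range(ang_idx.shape[0]):
        ia = ang_idx[a, 0]
        ib = ang_idx[a, 1]
        ic = ang_idx[a, 2]
        ux = coords[ia, 0] - coords[ib, 0]
        uy = coords[ia, 1] - coords[ib, 1]
        uz = coords[ia, 2] - coords[ib, 2]
        wx = coords[ic, 0] - coords[ib, 0]
        wy = coords[ic, 1] - coords[ib, 1]
        wz = coords[ic, 2] - coords[ib, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nw = np.sqrt(wx * wx + wy * wy + wz * wz)
        if nu < _TINY or nw < _TINY:
            continue
        c = (ux * wx + uy * wy + uz * wz) / (nu * nw)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dtheta = theta - ang_theta0[a]
        e_ang += 0.5 * ang_k[a] * dtheta * dtheta
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            continue
        dEdt = ang_k[a] * dtheta
        # d(theta)/d(r_a) and d(theta)/d(r_c)
        fa_x = (c * ux / nu - wx / nw) / (nu * s)
        fa_y = (c * uy / nu - wy / nw) / (nu * s)
        fa_z = (c * uz / nu - wz / nw) / (nu * s)
        fc_x = (c * wx / nw - ux / nu) / (nw * s)
        fc_y = (c * wy / nw - uy / nu) / (nw * s)
        fc_z = (c * wz / nw - uz / nu) / (nw * s)
        forces[ia, 0] -= dEdt * fa_x
        forces[ia, 1] -= dEdt * fa_y
        forces[ia, 2] -= dEdt * fa_z
        forces[ic, 0] -= dEdt * fc_x
        forces[ic, 1] -= dEdt * fc_y
        forces[ic, 2] -= dEdt * fc_z
        forces[ib, 0] += dEdt * (fa_x + fc_x)
        forces[ib, 1] += dEdt * (fa_y + fc_y)
        forces[ib, 2] += dEdt * (fa_z + fc_z)

    e_dih = 0.0
    for d in range(dih_idx.shape[0]):
        i1 = dih_idx[d, 0]
        i2 = dih_idx[d, 1]
        i3 = dih_idx[d, 2]
        i4 = dih_idx[d, 3]
        b1x = coords[i2, 0] - coords[i1, 0]
        b1y = coords[i2, 1] - coords[i1, 1]
        b1z = coords[i2, 2] - coords[i1, 2]
        b2x = coords[i3, 0] - coords[i2, 0]
        b2y = coords[i3, 1] - coords[i2, 1]
        b2z = coords[i3, 2] - coords[i2, 2]
        b3x = coords[i4, 0] - coords[i3, 0]
        b3y = coords[i4, 1] - coords[i3, 1]
        b3z = coords[i4, 2] - coords[i3, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-16 or n2sq < 1e-16 or nb2 < _TINY:
            # collinear frame: phi undefined; use native value (zero energy)
            continue
        cx = n1y * n2z - n1z * n2y
        cy = n1z * n2x - n1x * n2z
        cz = n1x * n2y - n1y * n2x
        sin_term = (cx * b2x + cy * b2y + cz * b2z) / nb2
        cos_term = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sin_term, cos_term)
        dphi = phi - dih_phi0[d]
        e_dih += dih_k1[d] * (1.0 - np.cos(dphi)) \
            + dih_k3[d] * (1.0 - np.cos(3.0 * dphi))
        dEdphi = dih_k1[d] * np.sin(dphi) + 3.0 * dih_k3[d] * np.sin(3.0 * dphi)
        # standard dihedral gradient
        g1 = -nb2 / n1sq
        g4 = nb2 / n2sq
        s1x = g1 * n1x
        s1y = g1 * n1y
        s1z = g1 * n1z
        s4x = g4 * n2x
        s4y = g4 * n2y
        s4z = g4 * n2z
        p = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        q = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        s2x = -(1.0 + p) * s1x + q * s4x
        s2y = -(1.0 + p) * s1y + q * s4y
        s2z = -(1.0 + p) * s1z + q * s4z
        s3x = p * s1x - (1.0 + q) * s4x
        s3y = p * s1y - (1.0 + q) * s4y
        s3z = p * s1z - (1.0 + q) * s4z
        forces[i1, 0] -= dEdphi * s1x
        forces[i1, 1] -= dEdphi * s1y
        forces[i1, 2] -= dEdphi * s1z
        forces[i2, 0] -= dEdphi * s2x
        forces[i2, 1] -= dEdphi * s2y
        forces[i2, 2] -= dEdphi * s2z
        forces[i3, 0] -= dEdphi * s3x
        forces[i3, 1] -= dEdphi * s3y
        forces[i3, 2] -= dEdphi * s3z
        forces[i4, 0] -= dEdphi * s4x
        forces[i4, 1] -= dEdphi * s4y
        forces[i4, 2] -= dEdphi * s4z

    e_pair = 0.0
    for p_ in range(pair_idx.shape[0]):
        i = pair_idx[p_, 0]
        j = pair_idx[p_, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < _TINY:
            continue
        x2 = pair_r0[p_] * pair_r0[p_] / r2
        x10 = x2 * x2 * x2 * x2 * x2
        x12 = x10 * x2
        e_pair += pair_eps[p_] * (5.0 * x12 - 6.0 * x10)
        # dE/dr * (1/r) = -60 eps (x12 - x10) / r^2
        fpr = 60.0 * pair_eps[p_] * (x12 - x10) / r2
        forces[i, 0] += fpr * dx
        forces[i, 1] += fpr * dy
        forces[i, 2] += fpr * dz
        forces[j, 0] -= fpr * dx
        forces[j, 1] -= fpr * dy
        forces[j, 2] -= fpr * dz

    e_rep = 0.0
    s2 = rep_sigma * rep_sigma
    for p_ in range(rep_idx.shape[0]):
        i = rep_idx[p_, 0]
        j = rep_idx[p_, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < _TINY:
            continue
        x2 = s2 / r2
        x12 = x2 * x2 * x2 * x2 * x2 * x2
        e_rep += rep_eps * x12
        fpr = 12.0 * rep_eps * x12 / r2
        forces[i, 0] += fpr * dx
        forces[i, 1] += fpr * dy
        forces[i, 2] += fpr * dz
        forces[j, 0] -= fpr * dx
        forces[j, 1] -= fpr * dy
        forces[j, 2] -= fpr * dz

    return e_bond, e_ang, e_dih, e_pair, e_rep


@njit(cache=True)
def _compute_forces(coords, packed_ints, packed_floats, fext, free, forces):
    """Unpack tuple-of-arrays and evaluate total forces; returns potential energy."""
    (bond_idx, ang_idx, dih_idx, pair_idx, rep_idx) = packed_ints
    (bond_r0, bond_k, ang_theta0, ang_k, dih_phi0, dih_k1, dih_k3,
     pair_r0, pair_eps, rep_eps_arr, rep_sigma_arr) = packed_floats
    forces[:] = 0.0
    eb, ea, ed, ep, er = _ef_terms(
        coords, bond_idx, bond_r0, bond_k, ang_idx, ang_theta0, ang_k,
        dih_idx, dih_phi0, dih_k1, dih_k3, pair_idx, pair_r0, pair_eps,
        rep_idx, rep_eps_arr[0], rep_sigma_arr[0], forces)
    n = coords.shape[0]
    for i in range(n):
        if free[i] == 0.0:
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        else:
            forces[i, 0] += fext[i, 0]
            forces[i, 1] += fext[i, 1]
            forces[i, 2] += fext[i, 2]
    return eb + ea + ed + ep + er


@njit(cache=True)
def bbk_segment(coords, vels, forces, n_steps, h, zeta, mass,
                free, fext, noise, packed_ints, packed_floats):
    """Integrate ``n_steps`` BBK steps in place.

    ``noise`` is an (n_steps, N, 3) array of Gaussian random forces already
    scaled to std sqrt(2 zeta kB T / h); the same realisation enters both
    velocity half-kicks (the random force is constant over a step).  Frozen
    beads (free == 0) never move.  Returns the potential energy after the
    last step.
    """
    n = coords.shape[0]
    half = 0.5 * h / mass
    denom = 1.0 + 0.5 * zeta * h / mass
    epot = 0.0
    for step in range(n_steps):
        for i in range(n):
            if free[i] == 0.0:
                continue
            for k in range(3):
                g = noise[step, i, k]
                vh = vels[i, k] * (1.0 - 0.5 * zeta * h / mass) \
                    + half * (forces[i, k] + g)
                coords[i, k] += h * vh
                vels[i, k] = vh
        epot = _compute_forces(coords, packed_ints, packed_floats,
                               fext, free, forces)
        for i in range(n):
            if free[i] == 0.0:
                continue
            for k in range(3):
                g = noise[step, i, k]
                vels[i, k] = (vels[i, k] + half * (forces[i, k] + g)) / denom
    return epot
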