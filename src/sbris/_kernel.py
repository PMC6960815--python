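"""Numba Metropolis kernel for the coupled binding/conformational sampler.

The kernel operates on flat float64/int64 arrays and performs incremental
energy updates: a site flip touches only the one-body proton term and the
pair terms of that site; a rotational-isomeric pivot or an elastic
perturbation moves one chain arm rigidly, so intra-arm distances are
conserved and only cross-arm pair terms are recomputed.  The running total
energy is returned so callers can verify it against a from-scratch
recomputation of the final state.

All energies are in kBT, lengths in nm, angles in radians.
"""

import math

import numpy as np
from numba import njit

LN10 = math.log(10.0)

#: dihedral offset from trans per RIS state (t, g+, g-)
PHI = np.array([0.0, 2.0 * math.pi / 3.0, -2.0 * math.pi / 3.0])

# indices into the scalar accumulator vector
(S_NS, S_NP, S_NP2, S_G, S_RZ, S_R2,
 S_L, S_L2, S_A, S_A2, S_GP, S_E) = range(12)
N_SCALARS = 12

# per-block accumulator columns
(B_NS, B_NP, B_NP2, B_G, B_RZ, B_R2) = range(6)
N_BLOCK_COLS = 6


@njit(cache=True)
def _pair_lr(lb, kappa, d):
    return lb / d * math.exp(-kappa * d)


@njit(cache=True)
def full_energy(pos, q, rot_state, bond_len, bond_ang, site_nodes,
                fluct, pH, pK, lb, kappa, eps_rot, eps_int,
                l0, alpha0, kl, ka, beta_f):
    """All finite free-energy terms of the current state (kBT)."""
    n = pos.shape[0]
    nsite = q.size
    e = 0.0
    for k in range(rot_state.size):
        e += eps_rot[rot_state[k]]
    if fluct:
        ssum = 0.0
        for i in range(nsite):
            ssum += q[i]
        e += LN10 * (pH - pK) * ssum
    if lb > 0.0:
        for i in range(nsite - 2):
            if q[i] == 0.0:
                continue
            ni = site_nodes[i]
            for j in range(i + 2, nsite):
                if q[j] == 0.0:
                    continue
                nj = site_nodes[j]
                dx = pos[nj, 0] - pos[ni, 0]
                dy = pos[nj, 1] - pos[ni, 1]
                dz = pos[nj, 2] - pos[ni, 2]
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                e += _pair_lr(lb, kappa, d) * q[i] * q[j]
    for i in range(nsite - 1):
        e += LN10 * eps_int[rot_state[i]] * q[i] * q[i + 1]
    for j in range(bond_len.size):
        dl = bond_len[j] - l0
        e += 0.5 * kl * dl * dl
    for j in range(bond_ang.size):
        da = bond_ang[j] - alpha0
        e += 0.5 * ka * da * da
    e += -beta_f * (pos[n - 1, 2] - pos[0, 2])
    return e


@njit(cache=True)
def _rotate_range(pos, buf, lo, hi, px, py, pz, ux, uy, uz, ang):
    """Rodrigues rotation of pos[lo:hi] about unit axis u through (px,py,pz)."""
    c = math.cos(ang)
    s = math.sin(ang)
    one_c = 1.0 - c
    r00 = c + ux * ux * one_c
    r01 = ux * uy * one_c - uz * s
    r02 = ux * uz * one_c + uy * s
    r10 = uy * ux * one_c + uz * s
    r11 = c + uy * uy * one_c
    r12 = uy * uz * one_c - ux * s
    r20 = uz * ux * one_c - uy * s
    r21 = uz * uy * one_c + ux * s
    r22 = c + uz * uz * one_c
    for m in range(lo, hi):
        x = pos[m, 0] - px
        y = pos[m, 1] - py
        z = pos[m, 2] - pz
        buf[m, 0] = px + r00 * x + r01 * y + r02 * z
        buf[m, 1] = py + r10 * x + r11 * y + r12 * z
        buf[m, 2] = pz + r20 * x + r21 * y + r22 * z


@njit(cache=True)
def _cross_overlap(pos, buf, lo, hi, radii):
    """Hard-sphere clash between moved nodes buf[lo:hi] and the fixed rest.

    Only pairs at least 4 bonds apart along the chain are checked.
    """
    n = pos.shape[0]
    for m in range(lo, hi):
        rm = radii[m]
        for p in range(n):
            if lo <= p < hi:
                continue
            sep = m - p
            if sep < 0:
                sep = -sep
            if sep < 4:
                continue
            dx = buf[m, 0] - pos[p, 0]
            dy = buf[m, 1] - pos[p, 1]
            dz = buf[m, 2] - pos[p, 2]
            rs = rm + radii[p]
            if dx * dx + dy * dy + dz * dz <= rs * rs:
                return True
    return False


@njit(cache=True)
def _lr_cross_delta(pos, buf, q, site_nodes, lb, kappa,
                    i_max, j_min, moving_is_high):
    """Delta of the screened-Coulomb sum over cross pairs.

    Cross pairs are (i <= i_max, j >= j_min) with j - i >= 2; the moving
    side (positions taken from ``buf``) is the high-index side when
    ``moving_is_high``, else the low-index side.
    """
    de = 0.0
    nsite = q.size
    for i in range(i_max + 1):
        qi = q[i]
        if qi == 0.0:
            continue
        ni = site_nodes[i]
        jlo = j_min
        if jlo < i + 2:
            jlo = i + 2
        for j in range(jlo, nsite):
            qj = q[j]
            if qj == 0.0:
                continue
            nj = site_nodes[j]
            dx = pos[nj, 0] - pos[ni, 0]
            dy = pos[nj, 1] - pos[ni, 1]
            dz = pos[nj, 2] - pos[ni, 2]
            d_old = math.sqrt(dx * dx + dy * dy + dz * dz)
            if moving_is_high:
                dx = buf[nj, 0] - pos[ni, 0]
                dy = buf[nj, 1] - pos[ni, 1]
                dz = buf[nj, 2] - pos[ni, 2]
            else:
                dx = pos[nj, 0] - buf[ni, 0]
                dy = pos[nj, 1] - buf[ni, 1]
                dz = pos[nj, 2] - buf[ni, 2]
            d_new = math.sqrt(dx * dx + dy * dy + dz * dz)
            de += (_pair_lr(lb, kappa, d_new)
                   - _pair_lr(lb, kappa, d_old)) * qi * qj
    return de


@njit(cache=True)
def run_kernel(seed, n_steps, n_equil, stride, n_blocks,
               pos, q, rot_state, bond_len, bond_ang,
               site_nodes, rot_bonds,
               fluct, pH, pK, lb, kappa, eps_rot, eps_int,
               l0, alpha0, kl, ka, beta_f,
               sev, radii,
               p_flip, p_rot, p_grot, grot_step,
               sigma_l, sigma_a, pivot_shorter,
               out_scal, out_corr, out_blocks, out_counts):
    """Run one Markov chain of ``n_steps`` elementary move attempts.

    State arrays (pos, q, rot_state, bond_len, bond_ang) are updated in
    place; observable sums are accumulated every ``stride`` attempts after
    the first ``n_equil`` attempts into ``out_scal``/``out_corr``/
    ``out_blocks``; per-move-type attempt/acceptance counts go to
    ``out_counts``.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    nsite = q.size
    nrot = rot_bonds.size
    nbond = n - 1
    buf = np.empty((n, 3))
    n_prod = n_steps - n_equil

    e_total = full_energy(pos, q, rot_state, bond_len, bond_ang, site_nodes,
                          fluct, pH, pK, lb, kappa, eps_rot, eps_int,
                          l0, alpha0, kl, ka, beta_f)

    c0 = nbond // 2
    ncorr = out_corr.size

    for t in range(n_steps):
        u = np.random.random()
        if u < p_flip:
            # ---- protonation flip -----------------------------------
            out_counts[0] += 1
            i = int(np.random.random() * nsite)
            if i == nsite:
                i = nsite - 1
            qi = q[i]
            nqi = 1.0 - qi
            dq = nqi - qi
            de = LN10 * (pH - pK) * dq
            if i > 0:
                de += LN10 * eps_int[rot_state[i - 1]] * q[i - 1] * dq
            if i < nsite - 1:
                de += LN10 * eps_int[rot_state[i]] * q[i + 1] * dq
            if lb > 0.0:
                ni = site_nodes[i]
                for j in range(nsite):
                    if j >= i - 1 and j <= i + 1:
                        continue
                    qj = q[j]
                    if qj == 0.0:
                        continue
                    nj = site_nodes[j]
                    dx = pos[nj, 0] - pos[ni, 0]
                    dy = pos[nj, 1] - pos[ni, 1]
                    dz = pos[nj, 2] - pos[ni, 2]
                    d = math.sqrt(dx * dx + dy * dy + dz * dz)
                    de += _pair_lr(lb, kappa, d) * qj * dq
            if de <= 0.0 or np.random.random() < math.exp(-de):
                q[i] = nqi
                e_total += de
                out_counts[3] += 1
        elif u < p_flip + p_rot:
            # ---- rotational-isomeric pivot --------------------------
            out_counts[1] += 1
            k = int(np.random.random() * nrot)
            if k == nrot:
                k = nrot - 1
            b = rot_bonds[k]
            old = rot_state[k]
            if np.random.random() < 0.5:
                new = (old + 1) % 3
            else:
                new = (old + 2) % 3
            dphi = PHI[new] - PHI[old]
            down_cnt = n - (b + 2)
            up_cnt = b
            move_down = True
            if pivot_shorter and up_cnt < down_cnt:
                move_down = False
            ax = pos[b + 1, 0] - pos[b, 0]
            ay = pos[b + 1, 1] - pos[b, 1]
            az = pos[b + 1, 2] - pos[b, 2]
            anorm = math.sqrt(ax * ax + ay * ay + az * az)
            ax /= anorm
            ay /= anorm
            az /= anorm
            if move_down:
                lo, hi, ang = b + 2, n, dphi
            else:
                lo, hi, ang = 0, b, -dphi
            _rotate_range(pos, buf, lo, hi, pos[b, 0], pos[b, 1], pos[b, 2],
                          ax, ay, az, ang)
            if sev and _cross_overlap(pos, buf, lo, hi, radii):
                pass  # hard clash: reject
            else:
                de = eps_rot[new] - eps_rot[old]
                de += LN10 * (eps_int[new] - eps_int[old]) * q[k] * q[k + 1]
                if lb > 0.0:
                    de += _lr_cross_delta(pos, buf, q, site_nodes, lb, kappa,
                                          k, k + 1, move_down)
                if beta_f != 0.0:
                    if move_down:
                        drz = buf[n - 1, 2] - pos[n - 1, 2]
                    else:
                        drz = pos[0, 2] - buf[0, 2]
                    de += -beta_f * drz
                if de <= 0.0 or np.random.random() < math.exp(-de):
                    for m in range(lo, hi):
                        pos[m, 0] = buf[m, 0]
                        pos[m, 1] = buf[m, 1]
                        pos[m, 2] = buf[m, 2]
                    rot_state[k] = new
                    e_total += de
                    out_counts[4] += 1
        elif u < p_flip + p_rot + p_grot:
            # ---- global rotation ------------------------------------
            # rigid rotation of the whole chain about a random axis
            # through node 0; only the stretching work changes, so the
            # acceptance test needs just the end-to-end vector.
            out_counts[6] += 1
            zax = 2.0 * np.random.random() - 1.0
            phi_ax = 2.0 * math.pi * np.random.random()
            sth = math.sqrt(max(1.0 - zax * zax, 0.0))
            gx = sth * math.cos(phi_ax)
            gy = sth * math.sin(phi_ax)
            gz = zax
            gang = (2.0 * np.random.random() - 1.0) * grot_step
            c = math.cos(gang)
            s = math.sin(gang)
            one_c = 1.0 - c
            rx = pos[n - 1, 0] - pos[0, 0]
            ry = pos[n - 1, 1] - pos[0, 1]
            rz0 = pos[n - 1, 2] - pos[0, 2]
            # z component of the rotated end-to-end vector
            rz_new = ((gz * gx * one_c - gy * s) * rx
                      + (gz * gy * one_c + gx * s) * ry
                      + (c + gz * gz * one_c) * rz0)
            de = -beta_f * (rz_new - rz0)
            if de <= 0.0 or np.random.random() < math.exp(-de):
                _rotate_range(pos, buf, 0, n, pos[0, 0], pos[0, 1],
                              pos[0, 2], gx, gy, gz, gang)
                for m in range(n):
                    pos[m, 0] = buf[m, 0]
                    pos[m, 1] = buf[m, 1]
                    pos[m, 2] = buf[m, 2]
                e_total += de
                out_counts[7] += 1
        else:
            # ---- elastic perturbation -------------------------------
            out_counts[2] += 1
            accepted = False
            if np.random.random() < 0.5:
                # bond-length move: translate one arm along the bond
                jb = int(np.random.random() * nbond)
                if jb == nbond:
                    jb = nbond - 1
                delta = np.random.normal(0.0, sigma_l)
                old_l = bond_len[jb]
                new_l = old_l + delta
                if new_l > 1e-3:
                    ux = (pos[jb + 1, 0] - pos[jb, 0]) / old_l
                    uy = (pos[jb + 1, 1] - pos[jb, 1]) / old_l
                    uz = (pos[jb + 1, 2] - pos[jb, 2]) / old_l
                    down_cnt = n - jb - 1
                    up_cnt = jb + 1
                    move_down = True
                    if pivot_shorter and up_cnt < down_cnt:
                        move_down = False
                    if move_down:
                        lo, hi = jb + 1, n
                        tx, ty, tz = delta * ux, delta * uy, delta * uz
                    else:
                        lo, hi = 0, jb + 1
                        tx, ty, tz = -delta * ux, -delta * uy, -delta * uz
                    for m in range(lo, hi):
                        buf[m, 0] = pos[m, 0] + tx
                        buf[m, 1] = pos[m, 1] + ty
                        buf[m, 2] = pos[m, 2] + tz
                    if sev and _cross_overlap(pos, buf, lo, hi, radii):
                        pass
                    else:
                        dl_new = new_l - l0
                        dl_old = old_l - l0
                        de = 0.5 * kl * (dl_new * dl_new - dl_old * dl_old)
                        if lb > 0.0:
                            sA = jb // 3
                            de += _lr_cross_delta(pos, buf, q, site_nodes,
                                                  lb, kappa, sA, sA + 1,
                                                  move_down)
                        de += -beta_f * delta * uz
                        if de <= 0.0 or np.random.random() < math.exp(-de):
                            for m in range(lo, hi):
                                pos[m, 0] = buf[m, 0]
                                pos[m, 1] = buf[m, 1]
                                pos[m, 2] = buf[m, 2]
                            bond_len[jb] = new_l
                            e_total += de
                            accepted = True
            else:
                # bond-angle move: rotate one arm in the local bending plane
                v = 1 + int(np.random.random() * (n - 2))
                if v == n - 1:
                    v = n - 2
                ai = v - 1
                delta = np.random.normal(0.0, sigma_a)
                old_a = bond_ang[ai]
                new_a = old_a + delta
                if 1e-3 < new_a < math.pi - 1e-3:
                    e1x = pos[v, 0] - pos[v - 1, 0]
                    e1y = pos[v, 1] - pos[v - 1, 1]
                    e1z = pos[v, 2] - pos[v - 1, 2]
                    e2x = pos[v + 1, 0] - pos[v, 0]
                    e2y = pos[v + 1, 1] - pos[v, 1]
                    e2z = pos[v + 1, 2] - pos[v, 2]
                    nx = e1y * e2z - e1z * e2y
                    ny = e1z * e2x - e1x * e2z
                    nz = e1x * e2y - e1y * e2x
                    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
                    if nn > 1e-12:
                        nx /= nn
                        ny /= nn
                        nz /= nn
                        down_cnt = n - v - 1
                        up_cnt = v
                        move_down = True
                        if pivot_shorter and up_cnt < down_cnt:
                            move_down = False
                        # rotating the downstream arm by +chi about n-hat
                        # decreases the angle by chi; upstream increases it
                        if move_down:
                            lo, hi, ang = v + 1, n, -delta
                        else:
                            lo, hi, ang = 0, v, delta
                        _rotate_range(pos, buf, lo, hi,
                                      pos[v, 0], pos[v, 1], pos[v, 2],
                                      nx, ny, nz, ang)
                        if sev and _cross_overlap(pos, buf, lo, hi, radii):
                            pass
                        else:
                            da_new = new_a - alpha0
                            da_old = old_a - alpha0
                            de = 0.5 * ka * (da_new * da_new
                                             - da_old * da_old)
                            if lb > 0.0:
                                i_max = (v - 1) // 3
                                j_min = (v + 3) // 3
                                de += _lr_cross_delta(pos, buf, q,
                                                      site_nodes, lb, kappa,
                                                      i_max, j_min,
                                                      move_down)
                            if beta_f != 0.0:
                                if move_down:
                                    drz = buf[n - 1, 2] - pos[n - 1, 2]
                                else:
                                    drz = pos[0, 2] - buf[0, 2]
                                de += -beta_f * drz
                            if de <= 0.0 or np.random.random() < math.exp(-de):
                                for m in range(lo, hi):
                                    pos[m, 0] = buf[m, 0]
                                    pos[m, 1] = buf[m, 1]
                                    pos[m, 2] = buf[m, 2]
                                bond_ang[ai] = new_a
                                e_total += de
                                accepted = True
            if accepted:
                out_counts[5] += 1

        # ---- sampling ----------------------------------------------
        if t >= n_equil and (t - n_equil) % stride == 0:
            out_scal[S_NS] += 1.0
            npl = 0.0
            for i in range(nsite):
                npl += q[i]
            out_scal[S_NP] += npl
            out_scal[S_NP2] += npl * npl
            ng = 0.0
            ngp = 0.0
            for k in range(nrot):
                if rot_state[k] != 0:
                    ng += 1.0
                    if rot_state[k] == 1:
                        ngp += 1.0
            out_scal[S_G] += ng
            out_scal[S_GP] += ngp
            rx = pos[n - 1, 0] - pos[0, 0]
            ry = pos[n - 1, 1] - pos[0, 1]
            rz = pos[n - 1, 2] - pos[0, 2]
            r2 = rx * rx + ry * ry + rz * rz
            out_scal[S_RZ] += rz
            out_scal[S_R2] += r2
            for j in range(nbond):
                bl = bond_len[j]
                out_scal[S_L] += bl
                out_scal[S_L2] += bl * bl
            for j in range(nbond - 1):
                ba = bond_ang[j]
                out_scal[S_A] += ba
                out_scal[S_A2] += ba * ba
            if ncorr > 0:
                for rr in range(c0 - 1, c0 + 2):
                    drx = pos[rr + 1, 0] - pos[rr, 0]
                    dry = pos[rr + 1, 1] - pos[rr, 1]
                    drz2 = pos[rr + 1, 2] - pos[rr, 2]
                    dn = math.sqrt(drx * drx + dry * dry + drz2 * drz2)
                    drx /= dn
                    dry /= dn
                    drz2 /= dn
                    for kk in range(ncorr):
                        j = rr + kk
                        djx = pos[j + 1, 0] - pos[j, 0]
                        djy = pos[j + 1, 1] - pos[j, 1]
                        djz = pos[j + 1, 2] - pos[j, 2]
                        dnj = math.sqrt(djx * djx + djy * djy + djz * djz)
                        out_corr[kk] += (drx * djx + dry * djy
                                         + drz2 * djz) / dnj
            blk = (t - n_equil) * n_blocks // n_prod
            out_blocks[blk, B_NS] += 1.0
            out_blocks[blk, B_NP] += npl
            out_blocks[blk, B_NP2] += npl * npl
            out_blocks[blk, B_G] += ng
            out_blocks[blk, B_RZ] += rz
            out_blocks[blk, B_R2] += r2

    out_scal[S_E] = e_total
    return e_total
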