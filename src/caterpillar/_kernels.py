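"""Numba-compiled inner loops: backbone rebuild, energy evaluation, MC sweeps.

Everything here operates on plain float64 arrays so the hot paths stay
allocation-free.  The public modules wrap these in typed containers and are
the only intended entry points; tests compare every kernel against a pure
NumPy brute-force oracle.

Atom layout per residue: index 0 = N, 1 = CA, 2 = C', 3 = O, 4 = amide H.
Residue 0 has no amide H; its H slot holds NaN.

Internal-coordinate array layout (radian angles):
  [0] d(N-CA)  [1] d(CA-C)  [2] d(C-N)  [3] d(C=O)  [4] d(N-H)
  [5] ang(N-CA-C)  [6] ang(CA-C-N)  [7] ang(C-N-CA)  [8] omega
"""

import numpy as np
from numba import njit

N_, CA_, C_, O_, H_ = 0, 1, 2, 3, 4


@njit(cache=True, inline="always")
def _place_atom(a, b, c, bond, theta, chi, out):
    """Place atom D with bond |C-D|, angle B-C-D = theta, dihedral A-B-C-D = chi."""
    bcx = c[0] - b[0]
    bcy = c[1] - b[1]
    bcz = c[2] - b[2]
    ib = 1.0 / np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx *= ib
    bcy *= ib
    bcz *= ib
    abx = b[0] - a[0]
    aby = b[1] - a[1]
    abz = b[2] - a[2]
    # n = unit(ab x bc)
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inn = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    nx *= inn
    ny *= inn
    nz *= inn
    # m = n x bc  (completes right-handed frame [bc, m, n])
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    dx = -bond * np.cos(theta)
    dpar = bond * np.sin(theta) * np.cos(chi)
    # sign chosen so dihedral(A, B, C, D) = +chi under the IUPAC convention
    dperp = -bond * np.sin(theta) * np.sin(chi)
    out[0] = c[0] + dx * bcx + dpar * mx + dperp * nx
    out[1] = c[1] + dx * bcy + dpar * my + dperp * ny
    out[2] = c[2] + dx * bcz + dpar * mz + dperp * nz


@njit(cache=True, inline="always")
def _bisector_place(tip, u_atom, v_atom, bond, out):
    """Place atom along -(unit(u-tip)+unit(v-tip)) at distance bond from tip."""
    ux = u_atom[0] - tip[0]
    uy = u_atom[1] - tip[1]
    uz = u_atom[2] - tip[2]
    iu = 1.0 / np.sqrt(ux * ux + uy * uy + uz * uz)
    vx = v_atom[0] - tip[0]
    vy = v_atom[1] - tip[1]
    vz = v_atom[2] - tip[2]
    iv = 1.0 / np.sqrt(vx * vx + vy * vy + vz * vz)
    sx = ux * iu + vx * iv
    sy = uy * iu + vy * iv
    sz = uz * iu + vz * iv
    isn = 1.0 / np.sqrt(sx * sx + sy * sy + sz * sz)
    out[0] = tip[0] - bond * sx * isn
    out[1] = tip[1] - bond * sy * isn
    out[2] = tip[2] - bond * sz * isn


@njit(cache=True)
def rebuild_chain(phi, psi, ic, coords):
    """Sequential internal-to-Cartesian construction of the full backbone.

    phi[0] and psi[n-1] are never read (undefined at the termini); the
    terminal carbonyl O uses a virtual trans psi.  coords has shape (n, 5, 3)
    and is overwritten in place.
    """
    n = phi.shape[0]
    d_nca, d_cac, d_cn, d_co, d_nh = ic[0], ic[1], ic[2], ic[3], ic[4]
    a_ncac, a_cacn, a_cnca, omega = ic[5], ic[6], ic[7], ic[8]
    # canonical frame: N0 at origin, CA0 on +x, C0 in the xy-plane
    coords[0, N_, 0] = 0.0
    coords[0, N_, 1] = 0.0
    coords[0, N_, 2] = 0.0
    coords[0, CA_, 0] = d_nca
    coords[0, CA_, 1] = 0.0
    coords[0, CA_, 2] = 0.0
    coords[0, C_, 0] = d_nca - d_cac * np.cos(a_ncac)
    coords[0, C_, 1] = d_cac * np.sin(a_ncac)
    coords[0, C_, 2] = 0.0
    for i in range(n - 1):
        _place_atom(coords[i, N_], coords[i, CA_], coords[i, C_],
                    d_cn, a_cacn, psi[i], coords[i + 1, N_])
        _place_atom(coords[i, CA_], coords[i, C_], coords[i + 1, N_],
                    d_nca, a_cnca, omega, coords[i + 1, CA_])
        _place_atom(coords[i, C_], coords[i + 1, N_], coords[i + 1, CA_],
                    d_cac, a_ncac, phi[i + 1], coords[i + 1, C_])
        # carbonyl O of residue i: in-plane, anti to the CA/N(i+1) bisector
        _bisector_place(coords[i, C_], coords[i, CA_], coords[i + 1, N_],
                        d_co, coords[i, O_])
        # amide H of residue i+1: in-plane, anti to the C'(i)/CA(i+1) bisector
        _bisector_place(coords[i + 1, N_], coords[i, C_], coords[i + 1, CA_],
                        d_nh, coords[i + 1, H_])
    # terminal O via a virtual next N at trans psi
    vn = np.empty(3)
    _place_atom(coords[n - 1, N_], coords[n - 1, CA_], coords[n - 1, C_],
                d_cn, a_cacn, np.pi, vn)
    _bisector_place(coords[n - 1, C_], coords[n - 1, CA_], vn,
                    d_co, coords[n - 1, O_])
    coords[0, H_, 0] = np.nan
    coords[0, H_, 1] = np.nan
    coords[0, H_, 2] = np.nan


@njit(cache=True)
def chain_energy(coords, seq_idx, eps, hvec, pair_scale, r_cut, width,
                 hard_dist, hb_eps, hb_sig, hb_cut, hb_m, solv_scale,
                 n_thresh, use_solv):
    """Total caterpillar energy.  Returns (e_pair, e_hb, e_solv, overlap).

    overlap = 1.0 flags a hard-core violation (any non-consecutive CA pair
    closer than hard_dist); component values are meaningless in that case and
    callers must treat the conformation as infinitely penalized.
    """
    n = coords.shape[0]
    e_pair = 0.0
    e_hb = 0.0
    e_solv = 0.0
    ncont = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for j in range(i + 2, n):
            dx = coords[i, CA_, 0] - coords[j, CA_, 0]
            dy = coords[i, CA_, 1] - coords[j, CA_, 1]
            dz = coords[i, CA_, 2] - coords[j, CA_, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < hard_dist:
                return 0.0, 0.0, 0.0, 1.0
            s = 0.5 * (1.0 - np.tanh((d - r_cut) / width))
            e_pair += pair_scale * eps[seq_idx[i], seq_idx[j]] * s
            if d <= r_cut:
                ncont[i] += 1
                ncont[j] += 1
    for i in range(1, n):  # donor NH of residue i
        for j in range(n):  # acceptor C=O of residue j
            dij = i - j
            if dij < 0:
                dij = -dij
            if dij < 2:
                continue
            rx = coords[i, H_, 0] - coords[j, O_, 0]
            ry = coords[i, H_, 1] - coords[j, O_, 1]
            rz = coords[i, H_, 2] - coords[j, O_, 2]
            r = np.sqrt(rx * rx + ry * ry + rz * rz)
            if not (r <= hb_cut):  # also skips NaN (absent amide H)
                continue
            # alpha: C'-O...H angle at the acceptor oxygen
            cx = coords[j, C_, 0] - coords[j, O_, 0]
            cy = coords[j, C_, 1] - coords[j, O_, 1]
            cz = coords[j, C_, 2] - coords[j, O_, 2]
            cn = np.sqrt(cx * cx + cy * cy + cz * cz)
            cos_a = (cx * rx + cy * ry + cz * rz) / (cn * r)
            if cos_a >= 0.0:  # alpha <= 90 deg: angular gate closed
                continue
            # beta: O...H-N angle at the hydrogen
            nx = coords[i, N_, 0] - coords[i, H_, 0]
            ny = coords[i, N_, 1] - coords[i, H_, 1]
            nz = coords[i, N_, 2] - coords[i, H_, 2]
            nn = np.sqrt(nx * nx + ny * ny + nz * nz)
            cos_b = -(nx * rx + ny * ry + nz * rz) / (nn * r)
            if cos_b >= 0.0:
                continue
            x2 = (hb_sig / r) * (hb_sig / r)
            x10 = x2 * x2 * x2 * x2 * x2
            lj = hb_eps * (5.0 * x10 * x2 - 6.0 * x10)
            e_hb += lj * (-cos_a) ** hb_m * (-cos_b) ** hb_m
    if use_solv == 1:
        for i in range(n):
            h = hvec[seq_idx[i]]
            if h > 0.0 and ncont[i] < n_thresh:
                e_solv += solv_scale * h * (n_thresh - ncont[i]) / n_thresh
    return e_pair, e_hb, e_solv, 0.0


@njit(cache=True)
def contact_counts_kernel(ca, r_cut, out):
    n = ca.shape[0]
    for i in range(n):
        out[i] = 0
    for i in range(n):
        for j in range(i + 2, n):
            dx = ca[i, 0] - ca[j, 0]
            dy = ca[i, 1] - ca[j, 1]
            dz = ca[i, 2] - ca[j, 2]
            if dx * dx + dy * dy + dz * dz <= r_cut * r_cut:
                out[i] += 1
                out[j] += 1


@njit(cache=True)
def drmsd_kernel(ca_a, ca_b):
    n = ca_a.shape[0]
    acc = 0.0
    m = 0
    for i in range(n):
        for j in range(i + 2, n):
            dax = ca_a[i, 0] - ca_a[j, 0]
            day = ca_a[i, 1] - ca_a[j, 1]
            daz = ca_a[i, 2] - ca_a[j, 2]
            dbx = ca_b[i, 0] - ca_b[j, 0]
            dby = ca_b[i, 1] - ca_b[j, 1]
            dbz = ca_b[i, 2] - ca_b[j, 2]
            da = np.sqrt(dax * dax + day * day + daz * daz)
            db = np.sqrt(dbx * dbx + dby * dby + dbz * dbz)
            acc += (da - db) * (da - db)
            m += 1
    if m == 0:
        return 0.0
    return np.sqrt(acc / m)


@njit(cache=True)
def fold_sweep(phi, psi, coords, trial_coords, seq_idx, movable, rand,
               e_total, temperature, delta_local, pivot_prob,
               ic, eps, hvec, pair_scale, r_cut, width, hard_dist,
               hb_eps, hb_sig, hb_cut, hb_m, solv_scale, n_thresh, use_solv):
    """One Metropolis sweep over the movable torsions.

    rand: (n_moves, 4) uniforms = (torsion pick, move kind, displacement,
    acceptance).  Returns (new total energy, accepted count).  phi/psi/coords
    are updated in place on acceptance.
    """
    n_moves = rand.shape[0]
    n_mov = movable.shape[0]
    accepted = 0
    for m in range(n_moves):
        k = int(rand[m, 0] * n_mov)
        if k >= n_mov:
            k = n_mov - 1
        res = movable[k, 0]
        tor = movable[k, 1]
        if tor == 0:
            old = phi[res]
        else:
            old = psi[res]
        if rand[m, 1] < pivot_prob:
            new = -np.pi + 2.0 * np.pi * rand[m, 2]
        else:
            new = old + delta_local * (2.0 * rand[m, 2] - 1.0)
            if new > np.pi:
                new -= 2.0 * np.pi
            elif new < -np.pi:
                new += 2.0 * np.pi
        if tor == 0:
            phi[res] = new
        else:
            psi[res] = new
        rebuild_chain(phi, psi, ic, trial_coords)
        ep, eh, es, ov = chain_energy(trial_coords, seq_idx, eps, hvec,
                                      pair_scale, r_cut, width, hard_dist,
                                      hb_eps, hb_sig, hb_cut, hb_m,
                                      solv_scale, n_thresh, use_solv)
        if ov > 0.5:
            acc = False
        else:
            e_new = ep + eh + es
            de = e_new - e_total
            if de <= 0.0:
                acc = True
            else:
                acc = rand[m, 3] < np.exp(-de / temperature)
        if acc:
            e_total = ep + eh + es
            accepted += 1
            for i in range(coords.shape[0]):
                for a in range(5):
                    coords[i, a, 0] = trial_coords[i, a, 0]
                    coords[i, a, 1] = trial_coords[i, a, 1]
                    coords[i, a, 2] = trial_coords[i, a, 2]
        else:
            if tor == 0:
                phi[res] = old
            else:
                psi[res] = old
    return e_total, accepted
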