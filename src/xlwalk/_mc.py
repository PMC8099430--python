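"""Numba kernel for the Metropolis inner loop.

The sampler spends essentially all its time computing the local energy of a
proposed move; this module holds that loop in nopython-compiled form. All
bookkeeping (mover definitions, bond/link incidence, adjacency) is passed as
flat CSR-style arrays so the kernel allocates nothing per step. The energy
formulas mirror :mod:`xlwalk.restraints` exactly: flat-bottom harmonics on
crosslink ambiguity minima, excluded-volume overlap, connectivity stretch.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _local_energy(
    coords, radii, body, fixed,
    adj_ptr, adj_idx,
    bond_i, bond_j, bond_U,
    l1_ptr, l1_idx, l2_ptr, l2_idx, link_L,
    mv_idx,  # particle indices of the mover
    mb_ids,  # bond ids touching the mover
    ml_ids,  # link ids touching the mover
    k_ev, ev_slack, k_conn, k_xl, w_ev, w_conn, w_xl,
):
    n = coords.shape[0]
    e = 0.0
    # excluded volume: mover particles vs everything outside the mover
    for a in range(mv_idx.shape[0]):
        s = mv_idx[a]
        bs = body[s]
        for j in range(n):
            if j == s:
                continue
            if bs >= 0 and body[j] == bs:
                continue  # same rigid body (also covers other mover members)
            # skip other members of a multi-bead mover (single-bead movers
            # have no members to skip; rigid movers are covered by body id)
            if fixed[s] and fixed[j]:
                continue
            skip = False
            for q in range(adj_ptr[s], adj_ptr[s + 1]):
                if adj_idx[q] == j:
                    skip = True
                    break
            if skip:
                continue
            dx = coords[s, 0] - coords[j, 0]
            dy = coords[s, 1] - coords[j, 1]
            dz = coords[s, 2] - coords[j, 2]
            d = (dx * dx + dy * dy + dz * dz) ** 0.5
            ov = radii[s] + radii[j] - ev_slack - d
            if ov > 0.0:
                e += w_ev * k_ev * ov * ov
    # connectivity bonds touching the mover
    for q in range(mb_ids.shape[0]):
        k = mb_ids[q]
        i_, j_ = bond_i[k], bond_j[k]
        dx = coords[i_, 0] - coords[j_, 0]
        dy = coords[i_, 1] - coords[j_, 1]
        dz = coords[i_, 2] - coords[j_, 2]
        d = (dx * dx + dy * dy + dz * dz) ** 0.5
        st = d - bond_U[k]
        if st > 0.0:
            e += w_conn * k_conn * st * st
    # crosslinks whose candidate sets touch the mover: ambiguity minimum
    for q in range(ml_ids.shape[0]):
        li = ml_ids[q]
        dmin = 1.0e30
        for u in range(l1_ptr[li], l1_ptr[li + 1]):
            p1 = l1_idx[u]
            for v in range(l2_ptr[li], l2_ptr[li + 1]):
                p2 = l2_idx[v]
                if p1 == p2:
                    continue
                dx = coords[p1, 0] - coords[p2, 0]
                dy = coords[p1, 1] - coords[p2, 1]
                dz = coords[p1, 2] - coords[p2, 2]
                d = (dx * dx + dy * dy + dz * dz) ** 0.5
                if d < dmin:
                    dmin = d
        ex = dmin - link_L[li]
        if ex > 0.0:
            e += w_xl * k_xl * ex * ex
    return e


@njit(cache=True)
def mc_kernel(
    coords, radii, body, fixed,
    adj_ptr, adj_idx,
    bond_i, bond_j, bond_U,
    l1_ptr, l1_idx, l2_ptr, l2_idx, link_L,
    mover_ptr, mover_idx,
    mb_ptr, mb_idx, ml_ptr, ml_idx,
    temps, stage_steps,
    bead_sigma, trans_sigma, rot_sigma,
    k_ev, ev_slack, k_conn, k_xl, w_ev, w_conn, w_xl,
    record_every, snaps, seed,
):
    """Run annealed Metropolis MC; one step = one attempt per mover.

    ``snaps[0]`` must hold the initial coordinates; later slots are filled
    every ``record_every`` steps. Returns (n_accepted, n_attempts,
    nonfinite_step) where nonfinite_step is -1 unless a non-finite energy
    change aborted the run.
    """
    np.random.seed(seed)
    n_movers = mover_ptr.shape[0] - 1
    n_acc = 0
    n_att = 0
    step = 0
    snap_i = 1
    backup = np.empty_like(coords)
    for stage in range(temps.shape[0]):
        T = temps[stage]
        for _ in range(stage_steps[stage]):
            step += 1
            for _a in range(n_movers):
                n_att += 1
                m = np.random.randint(n_movers)
                lo, hi = mover_ptr[m], mover_ptr[m + 1]
                mv = mover_idx[lo:hi]
                mb = mb_idx[mb_ptr[m]:mb_ptr[m + 1]]
                ml = ml_idx[ml_ptr[m]:ml_ptr[m + 1]]
                e0 = _local_energy(
                    coords, radii, body, fixed, adj_ptr, adj_idx,
                    bond_i, bond_j, bond_U,
                    l1_ptr, l1_idx, l2_ptr, l2_idx, link_L,
                    mv, mb, ml,
                    k_ev, ev_slack, k_conn, k_xl, w_ev, w_conn, w_xl,
                )
                for a in range(mv.shape[0]):
                    backup[mv[a]] = coords[mv[a]]
                if hi - lo == 1:
                    s = mv[0]
                    coords[s, 0] += np.random.normal() * bead_sigma
                    coords[s, 1] += np.random.normal() * bead_sigma
                    coords[s, 2] += np.random.normal() * bead_sigma
                else:
                    # rigid move: rotation about the centroid plus translation
                    cx = cy = cz = 0.0
                    for a in range(mv.shape[0]):
                        cx += coords[mv[a], 0]
                        cy += coords[mv[a], 1]
                        cz += coords[mv[a], 2]
                    cx /= mv.shape[0]
                    cy /= mv.shape[0]
                    cz /= mv.shape[0]
                    ax = np.random.normal()
                    ay = np.random.normal()
                    az = np.random.normal()
                    norm = (ax * ax + ay * ay + az * az) ** 0.5
                    ax, ay, az = ax / norm, ay / norm, az / norm
                    ang = np.random.normal() * rot_sigma
                    ca, sa = np.cos(ang), np.sin(ang)
                    one_c = 1.0 - ca
                    r00 = ca + ax * ax * one_c
                    r01 = ax * ay * one_c - az * sa
                    r02 = ax * az * one_c + ay * sa
                    r10 = ay * ax * one_c + az * sa
                    r11 = ca + ay * ay * one_c
                    r12 = ay * az * one_c - ax * sa
                    r20 = az * ax * one_c - ay * sa
                    r21 = az * ay * one_c + ax * sa
                    r22 = ca + az * az * one_c
                    tx = np.random.normal() * trans_sigma
                    ty = np.random.normal() * trans_sigma
                    tz = np.random.normal() * trans_sigma
                    for a in range(mv.shape[0]):
                        s = mv[a]
                        x = coords[s, 0] - cx
                        y = coords[s, 1] - cy
                        z = coords[s, 2] - cz
                        coords[s, 0] = r00 * x + r01 * y + r02 * z + cx + tx
                        coords[s, 1] = r10 * x + r11 * y + r12 * z + cy + ty
                        coords[s, 2] = r20 * x + r21 * y + r22 * z + cz + tz
                e1 = _local_energy(
                    coords, radii, body, fixed, adj_ptr, adj_idx,
                    bond_i, bond_j, bond_U,
                    l1_ptr, l1_idx, l2_ptr, l2_idx, link_L,
                    mv, mb, ml,
                    k_ev, ev_slack, k_conn, k_xl, w_ev, w_conn, w_xl,
                )
                de = e1 - e0
                if not np.isfinite(de):
                    return n_acc, n_att, step
                accept = de <= 0.0
                if not accept:
                    if np.random.random() < np.exp(-de / T):
                        accept = True
                if accept:
                    n_acc += 1
                else:
                    for a in range(mv.shape[0]):
                        coords[mv[a]] = backup[mv[a]]
            if record_every > 0 and step % record_every == 0 and snap_i < snaps.shape[0]:
                snaps[snap_i] = coords
                snap_i += 1
    return n_acc, n_att, -1
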