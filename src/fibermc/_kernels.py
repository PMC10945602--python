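"""Numba kernels for the nonbonded energy terms.

Sites are the flattened interaction points of a fiber: core centers (excluded
volume only), core surface charges, linker/tail/LH beads. Pair exclusions are
group-based: sites of one rigid element share a group; bonded neighbours list
each other's groups in a fixed-width exclusion table.

The excluded-volume form is a purely repulsive shifted-truncated 12-6,
``eps * ((s/d)^12 - 2 (s/d)^6 + 1)`` for ``d < s = r_i + r_j`` and zero at and
beyond contact, continuous with continuous derivative at the cutoff.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "full_nonbond",
    "cross_nonbond_delta",
    "point_nonbond",
    "restraint_candidates",
    "chain_elastic",
    "tail_trial_weights",
]


@njit(cache=True, fastmath=True)
def _pair_ec_ev(d2, qi, qj, ri, rj, pref, lam, eps, ecs):
    # ecs = exp(-cutoff/lam)/cutoff: the screened-Coulomb kernel is shifted
    # to zero at the cutoff so pairs crossing it contribute continuously
    d = np.sqrt(d2)
    ec = 0.0
    if qi != 0.0 and qj != 0.0:
        ec = pref * qi * qj * (np.exp(-d / lam) / d - ecs)
    ev = 0.0
    sig = ri + rj
    if sig > 0.0 and d < sig:
        x = sig * sig / d2
        r6 = x * x * x
        ev = eps * (r6 * r6 - 2.0 * r6 + 1.0)
    return ec, ev


@njit(cache=True, fastmath=True)
def full_nonbond(pos, charge, radius, group, excl, pref, lam, eps, cutoff):
    """Total (EC, EV) over all non-excluded site pairs."""
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    ecs = np.exp(-cutoff / lam) / cutoff
    ec = 0.0
    ev = 0.0
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        qi = charge[i]
        ri = radius[i]
        gi = group[i]
        e0 = excl[i, 0]
        e1 = excl[i, 1]
        for j in range(i + 1, n):
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > cut2 or d2 == 0.0:
                continue
            gj = group[j]
            if gj == gi or gj == e0 or gj == e1 or excl[j, 0] == gi or excl[j, 1] == gi:
                continue
            dec, dev = _pair_ec_ev(d2, qi, charge[j], ri, radius[j], pref, lam, eps, ecs)
            ec += dec
            ev += dev
    return ec, ev


@njit(cache=True, fastmath=True)
def cross_nonbond_delta(
    pos_old, pos_new, charge, radius, group, excl, moved, static, pref, lam, eps, cutoff
):
    """(EC, EV) change for moved-vs-static site pairs.

    ``moved`` and ``static`` are (k, 2) arrays of half-open site-index ranges;
    static sites have identical coordinates in ``pos_old`` and ``pos_new``.
    """
    cut2 = cutoff * cutoff
    ecs = np.exp(-cutoff / lam) / cutoff
    dec = 0.0
    dev = 0.0
    for a in range(moved.shape[0]):
        for i in range(moved[a, 0], moved[a, 1]):
            qi = charge[i]
            ri = radius[i]
            gi = group[i]
            e0 = excl[i, 0]
            e1 = excl[i, 1]
            xo = pos_old[i, 0]
            yo = pos_old[i, 1]
            zo = pos_old[i, 2]
            xn = pos_new[i, 0]
            yn = pos_new[i, 1]
            zn = pos_new[i, 2]
            for b in range(static.shape[0]):
                for j in range(static[b, 0], static[b, 1]):
                    dx = pos_old[j, 0] - xo
                    dy = pos_old[j, 1] - yo
                    dz = pos_old[j, 2] - zo
                    d2o = dx * dx + dy * dy + dz * dz
                    dx = pos_old[j, 0] - xn
                    dy = pos_old[j, 1] - yn
                    dz = pos_old[j, 2] - zn
                    d2n = dx * dx + dy * dy + dz * dz
                    if d2o > cut2 and d2n > cut2:
                        continue
                    gj = group[j]
                    if (
                        gj == gi
                        or gj == e0
                        or gj == e1
                        or excl[j, 0] == gi
                        or excl[j, 1] == gi
                    ):
                        continue
                    qj = charge[j]
                    rj = radius[j]
                    if d2o <= cut2 and d2o > 0.0:
                        ec, ev = _pair_ec_ev(d2o, qi, qj, ri, rj, pref, lam, eps, ecs)
                        dec -= ec
                        dev -= ev
                    if d2n <= cut2 and d2n > 0.0:
                        ec, ev = _pair_ec_ev(d2n, qi, qj, ri, rj, pref, lam, eps, ecs)
                        dec += ec
                        dev += ev
    return dec, dev


@njit(cache=True, fastmath=True)
def point_nonbond(
    pos, charge, radius, group, excl, skip_lo, skip_hi,
    x, y, z, q, r, g, e0, e1, pref, lam, eps, cutoff,
):
    """(EC, EV) of one probe site against all sites outside [skip_lo, skip_hi)."""
    cut2 = cutoff * cutoff
    ecs = np.exp(-cutoff / lam) / cutoff
    ec = 0.0
    ev = 0.0
    for j in range(pos.shape[0]):
        if skip_lo <= j < skip_hi:
            continue
        dx = pos[j, 0] - x
        dy = pos[j, 1] - y
        dz = pos[j, 2] - z
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > cut2 or d2 == 0.0:
            continue
        gj = group[j]
        if gj == g or gj == e0 or gj == e1 or excl[j, 0] == g or excl[j, 1] == g:
            continue
        dec, dev = _pair_ec_ev(d2, q, charge[j], r, radius[j], pref, lam, eps, ecs)
        ec += dec
        ev += dev
    return ec, ev


@njit(cache=True)
def restraint_candidates(pos, bead_ids, capture, min_sep, out_i, out_j, out_d):
    """All bindable-bead pairs within ``capture`` nm and >= ``min_sep`` beads.

    ``pos`` holds bindable-bead coordinates, ``bead_ids`` their global linker
    indices. Fills ``out_*`` and returns the candidate count.
    """
    m = pos.shape[0]
    cap2 = capture * capture
    n = 0
    for a in range(m - 1):
        for b in range(a + 1, m):
            if abs(bead_ids[b] - bead_ids[a]) < min_sep:
                continue
            dx = pos[b, 0] - pos[a, 0]
            dy = pos[b, 1] - pos[a, 1]
            dz = pos[b, 2] - pos[a, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < cap2:
                out_i[n] = a
                out_j[n] = b
                out_d[n] = np.sqrt(d2)
                n += 1
    return n


@njit(cache=True, fastmath=True)
def chain_elastic(pts, t_start, t_end, use_t_end, ks, l0, kb):
    """(stretch, bend) of a bead chain.

    ``pts`` holds the anchor followed by the beads (and the far anchor for
    linker runs). ``t_start`` is the tangent direction preceding the first
    segment; ``t_end`` (used when ``use_t_end``) the tangent following the
    last one. Bends are harmonic in the angle from collinearity.
    """
    nseg = pts.shape[0] - 1
    es = 0.0
    eb = 0.0
    px = t_start[0]
    py = t_start[1]
    pz = t_start[2]
    pn = np.sqrt(px * px + py * py + pz * pz)
    for s in range(nseg):
        vx = pts[s + 1, 0] - pts[s, 0]
        vy = pts[s + 1, 1] - pts[s, 1]
        vz = pts[s + 1, 2] - pts[s, 2]
        vn = np.sqrt(vx * vx + vy * vy + vz * vz)
        es += ks * (vn - l0) * (vn - l0)
        c = (px * vx + py * vy + pz * vz) / (pn * vn)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        eb += kb * th * th
        px, py, pz, pn = vx, vy, vz, vn
    if use_t_end:
        vx = t_end[0]
        vy = t_end[1]
        vz = t_end[2]
        vn = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (px * vx + py * vy + pz * vz) / (pn * vn)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        eb += kb * th * th
    return es, eb


@njit(cache=True, fastmath=True)
def tail_trial_weights(
    pos, charge, radius, group, excl, skip_lo, skip_hi,
    trials, prev_pt, prev_dir, grown, n_grown,
    q, r, g, e0, e1, kb_eff, pref, lam, eps, cutoff, beta, out_w,
):
    """Boltzmann weights of Rosenbluth trial positions for one tail bead.

    Energy per trial: bend about the previous segment direction plus
    nonbonded interactions with all sites outside the chain's own block and
    with already-regrown chain beads (excluding the bonded predecessor).
    """
    cut2 = cutoff * cutoff
    ecs = np.exp(-cutoff / lam) / cutoff
    pdx = prev_dir[0]
    pdy = prev_dir[1]
    pdz = prev_dir[2]
    pdn = np.sqrt(pdx * pdx + pdy * pdy + pdz * pdz)
    for t in range(trials.shape[0]):
        x = trials[t, 0]
        y = trials[t, 1]
        z = trials[t, 2]
        sx = x - prev_pt[0]
        sy = y - prev_pt[1]
        sz = z - prev_pt[2]
        sn = np.sqrt(sx * sx + sy * sy + sz * sz)
        c = (pdx * sx + pdy * sy + pdz * sz) / (pdn * sn)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        e = kb_eff * th * th
        for j in range(pos.shape[0]):
            if skip_lo <= j < skip_hi:
                continue
            dx = pos[j, 0] - x
            dy = pos[j, 1] - y
            dz = pos[j, 2] - z
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > cut2 or d2 == 0.0:
                continue
            gj = group[j]
            if gj == g or gj == e0 or gj == e1 or excl[j, 0] == g or excl[j, 1] == g:
                continue
            ec, ev = _pair_ec_ev(d2, q, charge[j], r, radius[j], pref, lam, eps, ecs)
            e += ec + ev
        for m in range(n_grown - 1):  # skip the bonded predecessor
            dx = grown[m, 0] - x
            dy = grown[m, 1] - y
            dz = grown[m, 2] - z
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > cut2 or d2 == 0.0:
                continue
            ec, ev = _pair_ec_ev(d2, q, q, r, r, pref, lam, eps, ecs)
            e += ec + ev
        out_w[t] = np.exp(-beta * e)
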