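"""Numba kernels for the Monte Carlo engine and cluster labeling.

The hot loops (millions of trial moves, per-record cluster sweeps) are
compiled with numba; all randomness comes from numba's own Mersenne Twister
seeded once per run, so runs are bit-reproducible for a given seed.  Lattice
conventions (axial coordinates, direction indexing, class codes) follow
:mod:`hydrofilm.lattice` and :mod:`hydrofilm.spin_model`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# direction offsets, row-synchronised with lattice.DIRS
_DI = np.array([1, 0, -1, -1, 0, 1], dtype=np.int64)
_DJ = np.array([0, 1, 1, 0, -1, -1], dtype=np.int64)

INF = np.inf


@njit(cache=True)
def _rot_axial(i, j, k):
    """Rotate axial vector (i, j) by k*60 degrees CCW (k may be negative)."""
    kk = k % 6
    for _ in range(kk):
        i, j = -j, i + j
    return i, j


@njit(cache=True)
def insert_delta(spins, cls, J, jsurf, i, j, s):
    """Energy change of placing orientation s at vacant site (i, j).

    Returns +inf when any resulting contact is forbidden.
    """
    h, w = spins.shape
    e = -jsurf
    for d in range(6):
        ni = (i + _DI[d]) % w
        nj = (j + _DJ[d]) % h
        t = spins[nj, ni]
        if t >= 0:
            code = cls[d, s, t]
            if code == 0:
                return INF
            e -= J[code]
    return e


@njit(cache=True)
def full_energy(spins, cls, J, jsurf):
    """Total energy; +inf if a forbidden adjacent pair exists."""
    h, w = spins.shape
    e = 0.0
    for j in range(h):
        for i in range(w):
            s = spins[j, i]
            if s < 0:
                continue
            e -= jsurf
            for d in range(3):  # each unordered bond once
                ni = (i + _DI[d]) % w
                nj = (j + _DJ[d]) % h
                t = spins[nj, ni]
                if t >= 0:
                    code = cls[d, s, t]
                    if code == 0:
                        return INF
                    e -= J[code]
    return e


@njit(cache=True)
def bond_census_kernel(spins, cls):
    """(n_trimer, n_p6, n_p3, n_forbidden, n_occupied), unordered bonds."""
    h, w = spins.shape
    counts = np.zeros(4, dtype=np.int64)
    n_occ = 0
    for j in range(h):
        for i in range(w):
            s = spins[j, i]
            if s < 0:
                continue
            n_occ += 1
            for d in range(3):
                ni = (i + _DI[d]) % w
                nj = (j + _DJ[d]) % h
                t = spins[nj, ni]
                if t >= 0:
                    counts[cls[d, s, t]] += 1
    return counts[1], counts[2], counts[3], counts[0], n_occ


@njit(cache=True)
def label_clusters_kernel(spins, cls):
    """Connected components over attractive bonds, with winding detection.

    Returns ``(labels, sizes, wraps)``: per-site label (-1 for vacant or
    forbidden-isolated... vacant only), per-cluster sizes, and per-cluster
    flags set when a cycle closes with nonzero net periodic displacement
    (the cluster wraps the torus).  Bonds are adjacent occupied pairs whose
    class is attractive (non-forbidden).
    """
    h, w = spins.shape
    n = w * h
    labels = np.full(n, -1, dtype=np.int64)
    disp_i = np.zeros(n, dtype=np.int64)
    disp_j = np.zeros(n, dtype=np.int64)
    stack = np.empty(n, dtype=np.int64)
    sizes_buf = np.zeros(n, dtype=np.int64)
    wraps_buf = np.zeros(n, dtype=np.uint8)
    n_clusters = 0
    for j0 in range(h):
        for i0 in range(w):
            sid = j0 * w + i0
            if spins[j0, i0] < 0 or labels[sid] >= 0:
                continue
            lab = n_clusters
            n_clusters += 1
            labels[sid] = lab
            disp_i[sid] = 0
            disp_j[sid] = 0
            top = 0
            stack[top] = sid
            top += 1
            size = 0
            wrapped = False
            while top > 0:
                top -= 1
                cur = stack[top]
                ci = cur % w
                cj = cur // w
                size += 1
                s = spins[cj, ci]
                for d in range(6):
                    ni = (ci + _DI[d]) % w
                    nj = (cj + _DJ[d]) % h
                    t = spins[nj, ni]
                    if t < 0 or cls[d, s, t] == 0:
                        continue
                    nid = nj * w + ni
                    ndi = disp_i[cur] + _DI[d]
                    ndj = disp_j[cur] + _DJ[d]
                    if labels[nid] < 0:
                        labels[nid] = lab
                        disp_i[nid] = ndi
                        disp_j[nid] = ndj
                        stack[top] = nid
                        top += 1
                    else:
                        if disp_i[nid] != ndi or disp_j[nid] != ndj:
                            wrapped = True
            sizes_buf[lab] = size
            if wrapped:
                wraps_buf[lab] = 1
    return labels, sizes_buf[:n_clusters].copy(), wraps_buf[:n_clusters].copy()


@njit(cache=True)
def largest_cluster_kernel(spins, cls):
    """(largest cluster size, any cluster wraps) -- cheap per-record probe."""
    _, sizes, wraps = label_clusters_kernel(spins, cls)
    largest = 0
    perc = False
    for k in range(sizes.shape[0]):
        if sizes[k] > largest:
            largest = sizes[k]
        if wraps[k] == 1:
            perc = True
    return largest, perc


@njit(cache=True)
def _attempt(spins, cls, J, jsurf, beta, p_absent,
             w_ads, w_hop, occ_list, pos_of, state, quench,
             partner_d, partner_s):
    """One trial move.  ``state`` = [n_occ (float), energy, n_accepted]."""
    h, w = spins.shape
    nsites = w * h
    u = np.random.random()
    n_occ = int(state[0])

    if u < w_ads:
        # --- adsorb / desorb -------------------------------------------
        site = int(np.random.random() * nsites)
        if site >= nsites:
            site = nsites - 1
        i = site % w
        j = site // w
        if spins[j, i] < 0:
            if p_absent > 0.0 and np.random.random() < p_absent:
                return  # no protein available in the subphase
            s = int(np.random.random() * 6) % 6
            de = insert_delta(spins, cls, J, jsurf, i, j, s)
            if de == INF:
                return
            if quench:
                ok = de < 0.0
            else:
                # Hastings factor 6: insertion proposes 1 of 6 orientations
                ok = np.random.random() < min(1.0, 6.0 * np.exp(-beta * de))
            if ok:
                spins[j, i] = s
                pos_of[site] = n_occ
                occ_list[n_occ] = site
                state[0] += 1
                state[1] += de
                state[2] += 1
        else:
            s = spins[j, i]
            spins[j, i] = -1
            de = -insert_delta(spins, cls, J, jsurf, i, j, s)
            if quench:
                ok = de < 0.0
            else:
                ok = np.random.random() < min(1.0, np.exp(-beta * de) / 6.0)
            if ok:
                last = n_occ - 1
                moved = occ_list[last]
                pos = pos_of[site]
                occ_list[pos] = moved
                pos_of[moved] = pos
                pos_of[site] = -1
                state[0] -= 1
                state[1] += de
                state[2] += 1
            else:
                spins[j, i] = s
        return

    if u < w_ads + w_hop:
        # --- single-protein hop and/or rotate --------------------------
        if n_occ == 0:
            return
        idx = int(np.random.random() * n_occ)
        if idx >= n_occ:
            idx = n_occ - 1
        site = occ_list[idx]
        i = site % w
        j = site // w
        s = spins[j, i]
        q = 1 + int(np.random.random() * 20)  # 20 non-null proposals
        if q > 20:
            q = 20
        mv = q // 3
        rc = q % 3
        dr = 0
        if rc == 1:
            dr = 1
        elif rc == 2:
            dr = -1
        if mv == 0:
            ti, tj = i, j
        else:
            d = mv - 1
            ti = (i + _DI[d]) % w
            tj = (j + _DJ[d]) % h
            if spins[tj, ti] >= 0:
                return  # target must be vacant
        s_new = (s + dr) % 6
        spins[j, i] = -1
        ins_t = insert_delta(spins, cls, J, jsurf, ti, tj, s_new)
        if ins_t == INF:
            spins[j, i] = s
            return
        de = ins_t - insert_delta(spins, cls, J, jsurf, i, j, s)
        if quench:
            ok = de < 0.0
        else:
            ok = np.random.random() < min(1.0, np.exp(-beta * de))
        if ok:
            spins[tj, ti] = s_new
            tsite = tj * w + ti
            if tsite != site:
                occ_list[idx] = tsite
                pos_of[tsite] = idx
                pos_of[site] = -1
            state[1] += de
            state[2] += 1
        else:
            spins[j, i] = s
        return

    # --- rigid trimer move ---------------------------------------------
    if n_occ == 0:
        return
    idx = int(np.random.random() * n_occ)
    if idx >= n_occ:
        idx = n_occ - 1
    site = occ_list[idx]
    i0 = site % w
    j0 = site // w
    s0 = spins[j0, i0]
    si = np.empty(3, dtype=np.int64)
    sj = np.empty(3, dtype=np.int64)
    ss = np.empty(3, dtype=np.int64)
    si[0], sj[0], ss[0] = i0, j0, s0
    complete = True
    for k in range(2):
        d = partner_d[s0, k]
        ni = (i0 + _DI[d]) % w
        nj = (j0 + _DJ[d]) % h
        if spins[nj, ni] != partner_s[s0, k]:
            complete = False
            break
        si[k + 1], sj[k + 1], ss[k + 1] = ni, nj, spins[nj, ni]
    if not complete:
        return  # the picked protein is not in a complete trimer
    q = 1 + int(np.random.random() * 20)
    if q > 20:
        q = 20
    t = q // 3
    rc = q % 3
    dr = 0
    if rc == 1:
        dr = 1
    elif rc == 2:
        dr = -1
    piv = 0
    if dr != 0:
        piv = int(np.random.random() * 3) % 3
    tvi = 0
    tvj = 0
    if t > 0:
        tvi = _DI[t - 1]
        tvj = _DJ[t - 1]
    # target sites: rotate about the pivot vertex (unwrapped relative
    # offsets; members are nearest-neighbours so offsets are small)
    ni_ = np.empty(3, dtype=np.int64)
    nj_ = np.empty(3, dtype=np.int64)
    ns_ = np.empty(3, dtype=np.int64)
    for k in range(3):
        ri = si[k] - si[piv]
        rj = sj[k] - sj[piv]
        # unwrap across the periodic seam
        if ri > w // 2:
            ri -= w
        if ri < -(w // 2):
            ri += w
        if rj > h // 2:
            rj -= h
        if rj < -(h // 2):
            rj += h
        ri, rj = _rot_axial(ri, rj, dr)
        ni_[k] = (si[piv] + ri + tvi) % w
        nj_[k] = (sj[piv] + rj + tvj) % h
        ns_[k] = (ss[k] + dr) % 6
    # clear old sites, accumulating removal deltas
    de = 0.0
    for k in range(3):
        s = spins[sj[k], si[k]]
        spins[sj[k], si[k]] = -1
        de -= insert_delta(spins, cls, J, jsurf, si[k], sj[k], s)
    # place new sites
    placed = 0
    bad = False
    for k in range(3):
        if spins[nj_[k], ni_[k]] >= 0:
            bad = True
            break
        dd = insert_delta(spins, cls, J, jsurf, ni_[k], nj_[k], ns_[k])
        if dd == INF:
            bad = True
            break
        de += dd
        spins[nj_[k], ni_[k]] = ns_[k]
        placed += 1
    if bad:
        for k in range(placed - 1, -1, -1):
            spins[nj_[k], ni_[k]] = -1
        for k in range(3):
            spins[sj[k], si[k]] = ss[k]
        return
    if quench:
        ok = de < 0.0
    else:
        ok = np.random.random() < min(1.0, np.exp(-beta * de))
    if ok:
        # two-phase occupancy update: old and new site sets may overlap
        slots = np.empty(3, dtype=np.int64)
        for k in range(3):
            old = sj[k] * w + si[k]
            slots[k] = pos_of[old]
            pos_of[old] = -1
        for k in range(3):
            new = nj_[k] * w + ni_[k]
            occ_list[slots[k]] = new
            pos_of[new] = slots[k]
        state[1] += de
        state[2] += 1
    else:
        for k in range(2, -1, -1):
            spins[nj_[k], ni_[k]] = -1
        for k in range(3):
            spins[sj[k], si[k]] = ss[k]


@njit(cache=True)
def run_mc(spins, cls, J, jsurf, beta, p_absent, w_ads, w_hop,
           sweeps, seed, record_every, partner_d, partner_s):
    """Metropolis run; records observables every ``record_every`` sweeps.

    Returns record arrays (sweep, n_occupied, largest, energy, nT, nP6,
    nP3, percolated); ``spins`` is evolved in place.
    """
    np.random.seed(seed)
    h, w = spins.shape
    nsites = w * h
    occ_list = np.empty(nsites, dtype=np.int64)
    pos_of = np.full(nsites, -1, dtype=np.int64)
    n_occ = 0
    for j in range(h):
        for i in range(w):
            if spins[j, i] >= 0:
                occ_list[n_occ] = j * w + i
                pos_of[j * w + i] = n_occ
                n_occ += 1
    state = np.zeros(3, dtype=np.float64)
    state[0] = n_occ
    state[1] = full_energy(spins, cls, J, jsurf)

    n_rec = sweeps // record_every + 1
    rec_sweep = np.empty(n_rec, dtype=np.int64)
    rec_nocc = np.empty(n_rec, dtype=np.int64)
    rec_large = np.empty(n_rec, dtype=np.int64)
    rec_energy = np.empty(n_rec, dtype=np.float64)
    rec_nt = np.empty(n_rec, dtype=np.int64)
    rec_np6 = np.empty(n_rec, dtype=np.int64)
    rec_np3 = np.empty(n_rec, dtype=np.int64)
    rec_perc = np.empty(n_rec, dtype=np.uint8)

    # record initial state
    nt, np6, np3, _, nocc = bond_census_kernel(spins, cls)
    large, perc = largest_cluster_kernel(spins, cls)
    rec_sweep[0] = 0
    rec_nocc[0] = nocc
    rec_large[0] = large
    rec_energy[0] = state[1]
    rec_nt[0] = nt
    rec_np6[0] = np6
    rec_np3[0] = np3
    rec_perc[0] = 1 if perc else 0
    r = 1
    for sweep in range(1, sweeps + 1):
        for _ in range(nsites):
            _attempt(spins, cls, J, jsurf, beta, p_absent, w_ads, w_hop,
                     occ_list, pos_of, state, False, partner_d, partner_s)
        if sweep % record_every == 0:
            nt, np6, np3, _, nocc = bond_census_kernel(spins, cls)
            large, perc = largest_cluster_kernel(spins, cls)
            rec_sweep[r] = sweep
            rec_nocc[r] = nocc
            rec_large[r] = large
            rec_energy[r] = state[1]
            rec_nt[r] = nt
            rec_np6[r] = np6
            rec_np3[r] = np3
            rec_perc[r] = 1 if perc else 0
            r += 1
    return (rec_sweep[:r], rec_nocc[:r], rec_large[:r], rec_energy[:r],
            rec_nt[:r], rec_np6[:r], rec_np3[:r], rec_perc[:r])


@njit(cache=True)
def run_quench(spins, cls, J, jsurf, p_absent, w_ads, w_hop,
               seed, max_sweeps, partner_d, partner_s):
    """Zero-temperature relaxation: accept only strictly energy-lowering
    moves, stop after the first full sweep with no acceptance.  Returns the
    number of sweeps performed."""
    np.random.seed(seed)
    h, w = spins.shape
    nsites = w * h
    occ_list = np.empty(nsites, dtype=np.int64)
    pos_of = np.full(nsites, -1, dtype=np.int64)
    n_occ = 0
    for j in range(h):
        for i in range(w):
            if spins[j, i] >= 0:
                occ_list[n_occ] = j * w + i
                pos_of[j * w + i] = n_occ
                n_occ += 1
    state = np.zeros(3, dtype=np.float64)
    state[0] = n_occ
    state[1] = full_energy(spins, cls, J, jsurf)
    for sweep in range(1, max_sweeps + 1):
        before = state[2]
        for _ in range(nsites):
            _attempt(spins, cls, J, jsurf, 0.0, p_absent, w_ads, w_hop,
                     occ_list, pos_of, state, True, partner_d, partner_s)
        if state[2] == before:
            return sweep
    return max_sweeps
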