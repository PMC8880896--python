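"""Numba kernel for the adhesion-extended Act CPM.

All state lives in flat numpy arrays so that the Monte Carlo loop, the
asynchronous adhesion sweep and the Act decay run entirely inside jitted
code.  The same jitted helpers (``delta_cpm``, ``gm_act`` ...) are used by
the Python-level single-operation API in :mod:`adhact.engine`, so tests of
those operations exercise the exact code the full simulation runs.

Site indexing: ``site = y * width + x`` (row-major).  The eight Moore
directions are ordered so that the reverse of direction ``k`` is ``7 - k``.

Bookkeeping layout
------------------
``ibook`` (int64): [area, perimeter, adhesion_area, n_cell_sites, n_edges,
abort_flag].  ``fbook`` (float64): [sum_ux, sum_uy] — sums of *unwrapped*
site coordinates of the current cell, so the centroid tracks continuously
across the periodic boundary.

RNG: a single numba global stream per process, seeded with ``seed_rng``.
Draw order within one MCS: (1) sigma-sweep: geometric skip draw, edge index
draw, Metropolis uniform (only when needed); (2) adhesion sweep:
Fisher-Yates shuffle draws, then per visited site a formation uniform (only
if eligible) / an Eden neighbour index plus success uniform / an unbinding
uniform (only if it has non-adherent neighbours); (3) Act decay draws
nothing.
"""

import numpy as np
from numba import njit

# ibook indices
IB_AREA = 0
IB_PERIM = 1
IB_ADH = 2
IB_NCELL = 3
IB_NEDGE = 4
IB_ABORT = 5

# fbook indices
FB_SX = 0
FB_SY = 1

# parameter-vector indices
PV_T = 0
PV_AT = 1
PV_LA = 2
PV_PT = 3
PV_LP = 4
PV_JCM = 5
PV_LACT = 6
PV_MAXACT = 7
PV_THRESH = 8  # absolute Act threshold = act_threshold_fraction * max_act
PV_LADH = 9
PV_PS = 10
PV_PE = 11
PV_PD = 12
PV_FBE = 13
PV_FBB = 14
PV_FBS = 15
PV_LEN = 16

# Moore directions (dy, dx); rev(k) = 7 - k
DIRS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


def build_neighbor_table(width: int, height: int) -> np.ndarray:
    """Periodic Moore-neighbour lookup table, shape (width*height, 8)."""
    n = width * height
    ys, xs = np.divmod(np.arange(n), width)
    nbr = np.empty((n, 8), dtype=np.int32)
    for k, (dy, dx) in enumerate(DIRS):
        nbr[:, k] = ((ys + dy) % height) * width + (xs + dx) % width
    return nbr


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def gm_act(sigma, act, nbr, x):
    """Geometric mean of Act over the same-label Moore neighbourhood of x,
    including x itself.  0 for medium sites and whenever any member is 0."""
    if sigma[x] == 0:
        return 0.0
    prod = float(act[x])
    if prod == 0.0:
        return 0.0
    n = 1
    for k in range(8):
        u = nbr[x, k]
        if sigma[u] == sigma[x]:
            a = act[u]
            if a == 0:
                return 0.0
            prod *= a
            n += 1
    return prod ** (1.0 / n)


@njit(cache=True)
def delta_cpm(sigma, nbr, s, t, area, perim, pv):
    """(dH, dP) for copying sigma[s] into t: contact + area + perimeter terms.

    Contact energy is summed over unordered unlike Moore pairs; the
    perimeter is the count of directed (cell, non-cell) Moore pairs.
    """
    old = sigma[t]
    new = sigma[s]
    jcm = pv[PV_JCM]
    dcontact = 0.0
    cnt_cell = 0
    for k in range(8):
        su = sigma[nbr[t, k]]
        if su == 1:
            cnt_cell += 1
        if su != old:
            dcontact -= jcm
        if su != new:
            dcontact += jcm
    if new == 1:
        da = 1
        dp = (8 - cnt_cell) - cnt_cell
    else:
        da = -1
        dp = cnt_cell - (8 - cnt_cell)
    at = pv[PV_AT]
    pt = pv[PV_PT]
    dh = dcontact
    dh += pv[PV_LA] * ((area + da - at) ** 2 - (area - at) ** 2)
    dh += pv[PV_LP] * ((perim + dp - pt) ** 2 - (perim - pt) ** 2)
    return dh, dp


@njit(cache=True)
def delta_act(sigma, act, nbr, s, t, f, pv):
    """Act-model energy bias, to be SUBTRACTED from dH."""
    lact = pv[PV_LACT]
    mact = pv[PV_MAXACT]
    if lact == 0.0 or mact <= 0.0:
        return 0.0
    return f * (lact / mact) * (gm_act(sigma, act, nbr, s) - gm_act(sigma, act, nbr, t))


@njit(cache=True)
def delta_adhesion(sigma, adh, s, t, pv):
    """Rupture energy: lambda_adh per adhesion lost when the cell retracts."""
    if sigma[s] == 0 and sigma[t] == 1 and adh[t] == 1:
        return pv[PV_LADH]
    return 0.0


@njit(cache=True)
def feedback_factor(ibook, pv):
    if pv[PV_FBE] == 0.0:
        return 1.0
    a = ibook[IB_AREA]
    ratio = ibook[IB_ADH] / a
    s = pv[PV_FBS]
    if ratio > s:
        return 1.0
    b = pv[PV_FBB]
    return b + (1.0 - b) / s * ratio


@njit(cache=True, inline="always")
def _set_edge(edge_list, edge_pos, ibook, eid, unlike):
    pos = edge_pos[eid]
    if unlike:
        if pos < 0:
            n = ibook[IB_NEDGE]
            edge_list[n] = eid
            edge_pos[eid] = n
            ibook[IB_NEDGE] = n + 1
    else:
        if pos >= 0:
            n = ibook[IB_NEDGE] - 1
            last = edge_list[n]
            edge_list[pos] = last
            edge_pos[last] = pos
            ibook[IB_NEDGE] = n
            edge_pos[eid] = -1


@njit(cache=True)
def apply_flip(
    sigma, act, adh, nbr, ibook, fbook,
    cell_list, cell_pos, ux, uy, edge_list, edge_pos,
    t, new_label, dp, max_act, width,
):
    """Copy ``new_label`` into site t and update all incremental bookkeeping."""
    if new_label == 1:
        # extension: pick the periodic image of t closest to the current centroid
        a_prev = ibook[IB_AREA]
        cx = fbook[FB_SX] / a_prev
        cy = fbook[FB_SY] / a_prev
        x = float(t % width)
        y = float(t // width)
        height = sigma.shape[0] // width
        x += width * np.rint((cx - x) / width)
        y += height * np.rint((cy - y) / height)
        sigma[t] = 1
        act[t] = max_act
        ibook[IB_AREA] = a_prev + 1
        i = ibook[IB_NCELL]
        cell_list[i] = t
        cell_pos[t] = i
        ibook[IB_NCELL] = i + 1
        ux[t] = x
        uy[t] = y
        fbook[FB_SX] += x
        fbook[FB_SY] += y
    else:
        sigma[t] = 0
        act[t] = 0
        if adh[t] == 1:
            adh[t] = 0
            ibook[IB_ADH] -= 1
        ibook[IB_AREA] -= 1
        i = cell_pos[t]
        last = ibook[IB_NCELL] - 1
        m = cell_list[last]
        cell_list[i] = m
        cell_pos[m] = i
        ibook[IB_NCELL] = last
        cell_pos[t] = -1
        fbook[FB_SX] -= ux[t]
        fbook[FB_SY] -= uy[t]
    ibook[IB_PERIM] += dp
    for k in range(8):
        u = nbr[t, k]
        unlike = sigma[t] != sigma[u]
        _set_edge(edge_list, edge_pos, ibook, t * 8 + k, unlike)
        _set_edge(edge_list, edge_pos, ibook, u * 8 + (7 - k), unlike)


@njit(cache=True)
def attempt_copy_kernel(
    sigma, act, adh, nbr, ibook, fbook,
    cell_list, cell_pos, ux, uy, edge_list, edge_pos,
    pv, s, t, f, width,
):
    """One Metropolis copy attempt s -> t (labels must differ). Returns accept."""
    dh, dp = delta_cpm(sigma, nbr, s, t, ibook[IB_AREA], ibook[IB_PERIM], pv)
    dh -= delta_act(sigma, act, nbr, s, t, f, pv)
    dh += delta_adhesion(sigma, adh, s, t, pv)
    if dh >= 0.0:
        if np.random.random() >= np.exp(-dh / pv[PV_T]):
            return False
    apply_flip(
        sigma, act, adh, nbr, ibook, fbook,
        cell_list, cell_pos, ux, uy, edge_list, edge_pos,
        t, sigma[s], dp, int(pv[PV_MAXACT]), width,
    )
    return True


@njit(cache=True)
def sigma_sweep_rejection_free(
    sigma, act, adh, nbr, ibook, fbook,
    cell_list, cell_pos, ux, uy, edge_list, edge_pos,
    pv, f, width, n_sites,
):
    """One MCS worth of copy attempts, drawing only boundary (unlike) pairs.

    Statistically identical to ``n_sites`` naive attempts: the number of
    inactive (like-label) draws between boundary draws is sampled from the
    exact geometric distribution, with the boundary-pair count kept live.
    """
    budget = n_sites
    total = 8.0 * n_sites
    while budget > 0:
        n_edges = ibook[IB_NEDGE]
        if n_edges == 0:
            break
        p = n_edges / total
        r = np.random.random()
        if r <= 0.0:
            r = 1e-300
        k = 1 + int(np.log(r) / np.log1p(-p))
        if k > budget:
            break
        budget -= k
        eid = edge_list[int(np.random.random() * n_edges)]
        t = eid >> 3
        s = nbr[t, eid & 7]
        attempt_copy_kernel(
            sigma, act, adh, nbr, ibook, fbook,
            cell_list, cell_pos, ux, uy, edge_list, edge_pos,
            pv, s, t, f, width,
        )


@njit(cache=True)
def sigma_sweep_naive(
    sigma, act, adh, nbr, ibook, fbook,
    cell_list, cell_pos, ux, uy, edge_list, edge_pos,
    pv, f, width, n_sites,
):
    """Classic MCS: n_sites uniform (target, neighbour) draws; like-label
    draws are no-ops.  Reference sampler for equivalence checks."""
    for _ in range(n_sites):
        t = np.random.randint(n_sites)
        s = nbr[t, np.random.randint(8)]
        if sigma[s] == sigma[t]:
            continue
        attempt_copy_kernel(
            sigma, act, adh, nbr, ibook, fbook,
            cell_list, cell_pos, ux, uy, edge_list, edge_pos,
            pv, s, t, f, width,
        )


@njit(cache=True, inline="always")
def formation_eligible(sigma, act, nbr, x, thresh):
    """True when the same-label geometric mean of Act at x reaches thresh.

    Uses a sequentially multiplied power table so that exact integer
    boundary cases (e.g. every member equal to the threshold) compare equal.
    """
    if thresh <= 0.0:
        return True
    a0 = act[x]
    if a0 == 0:
        return False
    prod = float(a0)
    n = 1
    for k in range(8):
        u = nbr[x, k]
        if sigma[u] == sigma[x]:
            a = act[u]
            if a == 0:
                return False
            prod *= a
            n += 1
    lim = 1.0
    for _ in range(n):
        lim *= thresh
    return prod >= lim


@njit(cache=True)
def adhesion_sweep(sigma, act, adh, nbr, ibook, cell_list, order, pv):
    """Asynchronous per-MCS adhesion update.

    Visits every current cell site in a fresh random order; empty sites may
    gain a de novo adhesion (Act-gated), adhered sites first try an Eden
    expansion into one random Moore neighbour, then a spontaneous unbinding
    whose probability grows with the squared fraction of non-adherent
    neighbours.  All reads see the live, already-modified layer.
    """
    ps = pv[PV_PS]
    pe = pv[PV_PE]
    pd = pv[PV_PD]
    if ps == 0.0 and pe == 0.0 and pd == 0.0:
        return
    n = ibook[IB_NCELL]
    for i in range(n):
        order[i] = cell_list[i]
    for i in range(n - 1, 0, -1):
        j = int(np.random.random() * (i + 1))
        tmp = order[i]
        order[i] = order[j]
        order[j] = tmp
    thresh = pv[PV_THRESH]
    for i in range(n):
        x = order[i]
        if adh[x] == 0:
            if (
                ps > 0.0
                and (act[x] > 0 or thresh <= 0.0)
                and formation_eligible(sigma, act, nbr, x, thresh)
            ):
                if np.random.random() < ps:
                    adh[x] = 1
                    ibook[IB_ADH] += 1
        else:
            if pe > 0.0:
                u = nbr[x, int(np.random.random() * 8)]
                if sigma[u] == 1 and adh[u] == 0:
                    if np.random.random() < pe:
                        adh[u] = 1
                        ibook[IB_ADH] += 1
            if pd > 0.0:
                cnt = 0
                for k in range(8):
                    if adh[nbr[x, k]] == 0:
                        cnt += 1
                if cnt > 0:
                    frac = cnt / 8.0
                    if np.random.random() < pd * frac * frac:
                        adh[x] = 0
                        ibook[IB_ADH] -= 1


@njit(cache=True)
def act_decay(act, ibook, cell_list):
    for i in range(ibook[IB_NCELL]):
        x = cell_list[i]
        if act[x] > 0:
            act[x] -= 1


@njit(cache=True)
def run_mcs_kernel(
    sigma, act, adh, nbr, ibook, fbook,
    cell_list, cell_pos, ux, uy, edge_list, edge_pos, order,
    pv, width, naive,
):
    """One full MCS: sigma-sweep, adhesion sweep, Act decay."""
    n_sites = sigma.shape[0]
    f = feedback_factor(ibook, pv)
    if naive:
        sigma_sweep_naive(
            sigma, act, adh, nbr, ibook, fbook,
            cell_list, cell_pos, ux, uy, edge_list, edge_pos,
            pv, f, width, n_sites,
        )
    else:
        sigma_sweep_rejection_free(
            sigma, act, adh, nbr, ibook, fbook,
            cell_list, cell_pos, ux, uy, edge_list, edge_pos,
            pv, f, width, n_sites,
        )
    adhesion_sweep(sigma, act, adh, nbr, ibook, cell_list, order, pv)
    act_decay(act, ibook, cell_list)
    if ibook[IB_AREA] == 0:
        ibook[IB_ABORT] = 1
    return f


@njit(cache=True)
def run_kernel(
    sigma, act, adh, nbr, ibook, fbook,
    cell_list, cell_pos, ux, uy, edge_list, edge_pos, order,
    pv, width, naive, n_mcs, start_mcs,
    rec_interval, rec_mcs, rec_x, rec_y, rec_area, rec_adh,
    snap_interval, snap_start, snap_mcs, snap_count, snap_sites,
    counters,
):
    """Run ``n_mcs`` steps, recording the track and adhesion snapshots.

    counters: int64[2] = [n_recorded_rows, n_snapshots] (in/out).
    """
    cap = snap_sites.shape[1] if snap_sites.shape[0] > 0 else 0
    for step in range(1, n_mcs + 1):
        mcs = start_mcs + step
        run_mcs_kernel(
            sigma, act, adh, nbr, ibook, fbook,
            cell_list, cell_pos, ux, uy, edge_list, edge_pos, order,
            pv, width, naive,
        )
        if ibook[IB_ABORT] != 0:
            return mcs
        if rec_interval > 0 and mcs % rec_interval == 0:
            j = counters[0]
            a = ibook[IB_AREA]
            rec_mcs[j] = mcs
            rec_x[j] = fbook[FB_SX] / a
            rec_y[j] = fbook[FB_SY] / a
            rec_area[j] = a
            rec_adh[j] = ibook[IB_ADH]
            counters[0] = j + 1
        if snap_interval > 0 and mcs >= snap_start and mcs % snap_interval == 0:
            j = counters[1]
            if j < snap_mcs.shape[0]:
                cnt = 0
                for i in range(ibook[IB_NCELL]):
                    x = cell_list[i]
                    if adh[x] == 1 and cnt < cap:
                        snap_sites[j, cnt] = x
                        cnt += 1
                snap_mcs[j] = mcs
                snap_count[j] = cnt
                counters[1] = j + 1
    return start_mcs + n_mcs
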