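"""Numba kernels for the per-step hot path.

These fuse the myelin damage / repair / stress sweep into a single pass
over the parenchyma and provide the nearest-degradable-myelin query used
by chemotactic bias.  They are exact implementations of the reference
operations in :mod:`mslesion.myelin` and :mod:`mslesion.agents`; the test
suite checks the equivalence.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["field_step", "nearest_eligible"]

# ---------------------------------------------------------------------------
# nearest eligible myelin

@njit(cache=True)
def _collect_rows(mask):
    """CSR layout of the eligible sites: per-row sorted column lists."""
    h, w = mask.shape
    row_ptr = np.zeros(h + 1, np.int64)
    cols = np.empty(h * w, np.int64)
    n = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                cols[n] = c
                n += 1
        row_ptr[r + 1] = n
    return row_ptr, cols[:n]


@njit(cache=True)
def _nearest_kernel(pr, pc, row_ptr, cols, h):
    """Exact nearest site per query by expanding row bands.

    Rows are visited in order of |row - r0|; within a row the two columns
    bracketing c0 (binary search) are the only candidates.  The search
    stops once the row offset alone exceeds the best distance, which also
    guarantees the lowest-row / lowest-column tie-break is honoured.
    """
    n = pr.size
    out_r = np.empty(n, np.int64)
    out_c = np.empty(n, np.int64)
    out_d2 = np.empty(n, np.int64)
    for i in range(n):
        r0, c0 = pr[i], pc[i]
        best_d2 = np.int64(1) << 60
        br = np.int64(-1)
        bc = np.int64(-1)
        for drabs in range(h):
            dr2 = drabs * drabs
            if dr2 > best_d2:
                break
            for sgn in (-1, 1):
                if drabs == 0 and sgn == 1:
                    continue
                r = r0 + sgn * drabs
                if r < 0 or r >= h:
                    continue
                lo, hi = row_ptr[r], row_ptr[r + 1]
                if lo == hi:
                    continue
                a, b = lo, hi
                while a < b:
                    mid = (a + b) // 2
                    if cols[mid] < c0:
                        a = mid + 1
                    else:
                        b = mid
                for j in (a - 1, a):
                    if j < lo or j >= hi:
                        continue
                    dc = cols[j] - c0
                    d2 = dr2 + dc * dc
                    if d2 < best_d2 or (
                        d2 == best_d2 and (r < br or (r == br and cols[j] < bc))
                    ):
                        best_d2, br, bc = d2, r, cols[j]
        out_r[i], out_c[i], out_d2[i] = br, bc, best_d2
    return out_r, out_c, out_d2


def nearest_eligible(rows0, cols0, eligible_mask):
    """Nearest eligible site for each query position (0-based field frame).

    Euclidean metric, ties broken by lowest row then lowest column.
    Returns ``(target_row, target_col, dist2, found)``; ``found`` is all
    False when the mask is empty.  Column indices may be negative for
    agents left of the parenchyma.
    """
    rows0 = np.ascontiguousarray(rows0, dtype=np.int64)
    cols0 = np.ascontiguousarray(cols0, dtype=np.int64)
    mask = np.ascontiguousarray(eligible_mask)
    row_ptr, cols = _collect_rows(mask)
    n = rows0.size
    if cols.size == 0:
        z = np.zeros(n, np.int64)
        return z, z, z, np.zeros(n, bool)
    tr, tc, d2 = _nearest_kernel(rows0, cols0, row_ptr, cols,
                                 eligible_mask.shape[0])
    return tr, tc, d2, np.ones(n, bool)


# ---------------------------------------------------------------------------
# fused myelin field update

@njit(cache=True)
def field_step(state, counter, status, occ, fr, fc, block, delay, n_states,
               per_agent, omega, lam):
    """Damage, repair, stress and apoptosis in one parenchyma sweep.

    ``fr, fc`` are the field-frame coordinates (with duplicates) of every
    reactivated T cell standing on a parenchyma site this step; ``occ`` is
    a reusable scratch buffer which is cleared again before returning.

    Returns ``(damage_events, repair_events, intact, damaged, n_myel,
    n_nonmyel, n_apop, n_newly_apoptotic)`` where ``intact``/``damaged``
    count sites at state S / state 1 after the full update.

    Apoptotic blocks are assumed to hold only state-1 sites with cleared
    repair counters (guaranteed by the zeroing at their transition) so the
    sweep can skip them.
    """
    h, w = state.shape
    nbr, nbc = h // block, w // block
    area = block * block

    # damage at occupied sites with remaining health
    damage = 0
    for i in range(fr.size):
        r, c = fr[i], fc[i]
        if per_agent:
            if state[r, c] > 1:
                state[r, c] -= 1
                damage += 1
        elif not occ[r, c] and state[r, c] > 1:
            state[r, c] -= 1
            damage += 1
        occ[r, c] = True
        counter[r, c] = 0

    # per-block sweep: repair, stress tally and threshold crossings
    # (apoptotic blocks are frozen at full damage and are skipped)
    intact = 0
    damaged = 0
    n_my = 0
    n_nm = 0
    n_ap = 0
    newly_ap = 0
    repairs = 0
    for br in range(nbr):
        r0 = br * block
        for bc in range(nbc):
            st = status[br, bc]
            if st == 2:
                n_ap += 1
                damaged += area
                continue
            c0 = bc * block
            sg = 0
            bi = 0
            for r in range(r0, r0 + block):
                for c in range(c0, c0 + block):
                    s = state[r, c]
                    if not occ[r, c]:
                        if st == 0:
                            if s < n_states:
                                cnt = counter[r, c] + 1
                                if cnt >= delay:
                                    s += 1
                                    state[r, c] = s
                                    counter[r, c] = 0
                                    repairs += 1
                                else:
                                    counter[r, c] = cnt
                        else:
                            counter[r, c] = 0
                    if s == 1:
                        sg += 1
                    elif s == n_states:
                        bi += 1
            # one-way transitions; both may fire in the same step
            if st == 0 and sg >= omega:
                st = 1
            if st == 1 and sg >= lam:
                st = 2
                newly_ap += 1
                for r in range(r0, r0 + block):
                    for c in range(c0, c0 + block):
                        state[r, c] = 1
                        counter[r, c] = 0
                sg = area
                bi = 0
            status[br, bc] = st
            if st == 0:
                n_my += 1
            elif st == 1:
                n_nm += 1
            else:
                n_ap += 1
            intact += bi
            damaged += sg

    for i in range(fr.size):
        occ[fr[i], fc[i]] = False

    return damage, repairs, intact, damaged, n_my, n_nm, n_ap, newly_ap


# ---------------------------------------------------------------------------
# agent movement and conversion

@njit(cache=True)
def move_tcells(pos, dirs, u_cross, b_R, b_L, h, wmax, bbb_blood, bbb_pvs):
    """Resolve proposed T-cell moves in place; returns the kept count.

    Failed barrier crossings and left-edge reflections leave the cell where
    it is (the move is consumed); rows wrap periodically; crossing the
    right edge removes the cell.  ``u_cross`` holds one uniform draw per
    agent, consulted only for barrier attempts.  Kept rows are compacted to
    the front of ``pos``.
    """
    n = pos.shape[0]
    m = 0
    for i in range(n):
        col, row = pos[i, 0], pos[i, 1]
        d = dirs[i]
        if d == 0 or d == 1:  # vertical: always succeeds, wraps
            row = (row - 1 + (1 if d == 1 else -1)) % h + 1
        elif d == 2:  # east
            if col == bbb_blood:
                if u_cross[i] < b_R:
                    col += 1
            elif col == wmax:
                continue  # absorbed at the right boundary
            else:
                col += 1
        else:  # west
            if col == bbb_pvs:
                if u_cross[i] < b_L:
                    col -= 1
            elif col > 1:
                col -= 1
        pos[m, 0] = col
        pos[m, 1] = row
        m += 1
    return m


@njit(cache=True)
def move_pvms(pos, dirs, h, pvs_lo, pvs_hi):
    """Unbiased PVM moves confined to the PVS columns (reflecting sides)."""
    for i in range(pos.shape[0]):
        d = dirs[i]
        if d == 0 or d == 1:
            pos[i, 1] = (pos[i, 1] - 1 + (1 if d == 1 else -1)) % h + 1
        elif d == 2:
            if pos[i, 0] < pvs_hi:
                pos[i, 0] += 1
        else:
            if pos[i, 0] > pvs_lo:
                pos[i, 0] -= 1


@njit(cache=True)
def biased_directions(pos, tr, tc, d2, found, u_dir, beta, k, clamp, col_off):
    """Sample one direction (0=N, 1=S, 2=E, 3=W) per agent under bias.

    Implements the biased-walk probabilities: the two directions toward
    the target gain s_bias weighted by the component shares, the two
    opposite directions each lose s_bias / 2; an axis-aligned target
    leaves the zero-weight favoured direction (taken as north / west) at
    the baseline 0.25.  Agents with no target, or standing on one, walk
    unbiased.
    """
    n = pos.shape[0]
    out = np.empty(n, np.int64)
    p = np.empty(4, np.float64)
    for i in range(n):
        if not found[i] or d2[i] == 0:
            out[i] = int(u_dir[i] * 4.0) if u_dir[i] < 1.0 else 3
            continue
        dx = (tc[i] + col_off) - pos[i, 0]
        dy = (tr[i] + 1) - pos[i, 1]
        adx = -dx if dx < 0 else dx
        ady = -dy if dy < 0 else dy
        s = beta * np.exp(-k * np.sqrt(float(d2[i])))
        wx = s * adx / (adx + ady)
        wy = s * ady / (adx + ady)
        if dx > 0:
            p[2] = 0.25 + wx
            p[3] = 0.25 - s / 2
        else:
            p[3] = 0.25 + wx
            p[2] = 0.25 - s / 2
        if dy > 0:
            p[1] = 0.25 + wy
            p[0] = 0.25 - s / 2
        else:
            p[0] = 0.25 + wy
            p[1] = 0.25 - s / 2
        if clamp:
            tot = 0.0
            for j in range(4):
                if p[j] < 0.0:
                    p[j] = 0.0
                tot += p[j]
        else:
            tot = 1.0
        u = u_dir[i] * tot
        acc = 0.0
        d = 3
        for j in range(4):
            acc += p[j]
            if u < acc:
                d = j
                break
        out[i] = d
    return out


@njit(cache=True)
def convert_primed(primed, pvms, pvs_lo, pvs_hi, h):
    """Mark primed T cells co-located with a PVM (antigen presentation)."""
    width = pvs_hi - pvs_lo + 1
    occ = np.zeros(width * h, np.bool_)
    for i in range(pvms.shape[0]):
        occ[(pvms[i, 0] - pvs_lo) * h + (pvms[i, 1] - 1)] = True
    hit = np.zeros(primed.shape[0], np.bool_)
    for i in range(primed.shape[0]):
        col = primed[i, 0]
        if pvs_lo <= col <= pvs_hi:
            hit[i] = occ[(col - pvs_lo) * h + (primed[i, 1] - 1)]
    return hit
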