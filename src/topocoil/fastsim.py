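"""Numba-compiled SSA kernel for scenario-scale ensembles.

Implements exactly the reaction catalog of :mod:`topocoil.reactions`
(biased/random-walk supercoil drift, topoisomerase bind/unbind/catalysis,
supercoiling-sensitive initiation, twin-domain translocation with the
two-segment exclusion rule, counterrotation, termination, mRNA decay,
barrier loop/unloop, boundary relaxation, and instantaneous torque-based
stall/processive mode switching) on flat arrays, with a direct-method
sampler using block partial sums and localized propensity refreshes.

Supercoil drift dominates the event stream by orders of magnitude, so the
kernel distinguishes turn-only events (drift, counterrotation, catalysis,
boundary resets), which refresh a handful of channels around the touched
segments, from the rare occupancy-changing events (binding, initiation,
translocation, looping), which take a full local rebuild including the
per-RNAP flank caches.  Every propensity formula lives in exactly one
specialised function shared by both paths and by the periodic full
recomputation that cancels floating-point drift in the partial sums.

The kernel is cross-validated distributionally against the reference
engine in the test suite; :func:`run_fast` returns the same
:class:`~topocoil.state.Trajectory` structure as
:func:`topocoil.engine.run_ssa`.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from numba import njit

from .engine import RunControl
from .state import (
    BARRIER,
    RNAP,
    SimulationConfig,
    Trajectory,
    build_state,
)

__all__ = ["run_fast"]

# event kind codes (kernel <-> python)
KIND_NAMES = [
    "initiation",
    "termination",
    "window",
    "loop",
    "unloop",
    "promoter_block",
    "stall",
]

_BLK = 64  # block size for partial propensity sums


# ---------------------------------------------------------------- responses


@njit(cache=True, inline="always")
def _sigma(turn, lk0):
    return (turn - lk0) / lk0


@njit(cache=True, inline="always")
def _torque(sig, cs_eff, p_eff, tau0, ss, sp):
    a = abs(sig)
    if a <= ss:
        return cs_eff * sig
    if a >= sp:
        return p_eff * sig
    return tau0 if sig > 0 else -tau0


@njit(cache=True, inline="always")
def _init_rate(sig, kmin, kmax, sstar):
    if sig >= 0.0:
        return kmin
    if sig <= sstar:
        return kmax
    return kmin + (kmax - kmin) * sig / sstar


@njit(cache=True, inline="always")
def _kcat(sig, kcatmax, shalf, sign):
    if sig * sign <= 0.0:
        return 0.0
    a = abs(sig)
    if shalf <= 0.0:
        return kcatmax
    r = a / shalf
    if r > 1.0:
        r = 1.0
    return kcatmax * r


# -------------------------------------------------- per-channel propensities


@njit(cache=True, inline="always")
def _p_hop_right(k, turn, occ, k_drift, biased):
    if occ[k + 1] != 0:
        return 0.0
    if biased == 1:
        return k_drift if turn[k] > turn[k + 1] else 0.0
    return k_drift if turn[k] > 0 else 0.0


@njit(cache=True, inline="always")
def _p_hop_left(k, turn, occ, k_drift, biased):
    # pair (k+1 -> k)
    if occ[k] != 0:
        return 0.0
    if biased == 1:
        return k_drift if turn[k + 1] > turn[k] else 0.0
    return k_drift if turn[k + 1] > 0 else 0.0


@njit(cache=True, inline="always")
def _p_cat(k, ti, turn, occ, t_code, t_step, t_kcatmax, t_shalf, t_sign, lk0):
    if occ[k] != t_code[ti]:
        return 0.0
    step = t_step[ti]
    if step > 0 and turn[k] + step > lk0:
        return 0.0
    if step < 0 and turn[k] + step < lk0:
        return 0.0
    return _kcat(_sigma(turn[k], lk0), t_kcatmax[ti], t_shalf[ti], t_sign[ti])


@njit(cache=True, inline="always")
def _p_init(g, turn, occ, blocked, g_tss, g_dir, g_kmin, g_kmax, g_sstar, lk0):
    if blocked[g] == 1:
        return 0.0
    tss = g_tss[g]
    if occ[tss] != 0 or occ[tss + g_dir[g]] != 0:
        return 0.0
    return _init_rate(_sigma(turn[tss], lk0), g_kmin[g], g_kmax[g], g_sstar[g])


@njit(cache=True, inline="always")
def _p_transloc(slot, S, r_alive, r_gene, r_seg, r_mode, occ, g_dir, g_end, g_rate):
    if r_alive[slot] == 0 or r_mode[slot] != 0:
        return 0.0
    g = r_gene[slot]
    k = r_seg[slot]
    if k == g_end[g]:
        return g_rate[g]
    d = g_dir[g]
    k2 = k + 2 * d
    if k2 < 0 or k2 >= S:
        return 0.0
    if occ[k + d] != 0 or occ[k2] != 0:
        return 0.0
    return g_rate[g]


@njit(cache=True, inline="always")
def _p_rot(slot, S, r_alive, r_seg, turn, occ, k_rot):
    if r_alive[slot] == 0:
        return 0.0
    k = r_seg[slot]
    if k - 1 < 0 or k + 1 >= S:
        return 0.0
    a = turn[k - 1]
    b = turn[k + 1]
    if a == b:
        return 0.0
    lo = k - 1 if a < b else k + 1
    return k_rot if occ[lo] == 0 else 0.0


@njit(cache=True, inline="always")
def _setp(i, v, P, blk, A_):
    d = v - P[i]
    P[i] = v
    blk[i // _BLK] += d
    A_[0] += d


@njit(cache=True)
def _flank_seg(seg, side, occ, S):
    """Nearest unoccupied segment on one side of an RNAP (clamped fallback)."""
    k = seg + side
    while 0 <= k < S:
        if occ[k] == 0:
            return k
        k += side
    k = seg + side
    if k < 0:
        k = 0
    if k >= S:
        k = S - 1
    return k


@njit(cache=True)
def _kernel(
    # geometry / params
    S, lk0, seg_bp, turn0, occ0, k_drift, biased,
    b_left, b_right, b_rate, b_target,
    g_dir, g_tss, g_end, g_kmin, g_kmax, g_sstar, g_rate, g_decay, g_block, g_window,
    t_code, t_kbind, t_kunbind, t_step, t_kcatmax, t_shalf, t_sign,
    br_a, br_b, br_kloop, br_kunloop, br_perm, looped0,
    cs_eff, p_eff, tau0, sig_s, sig_p, tau_c, sig_stall, k_rot, two_sided,
    # run control
    t_end, record_dt, seed, M, record_turn, record_episodes,
    reg_ptr, reg_segs,
    ev_cap,
):
    np.random.seed(seed)
    G = g_dir.shape[0]
    B = br_a.shape[0]
    n_topo = t_code.shape[0]
    R = reg_ptr.shape[0] - 1

    # ---- channel layout
    off_topo = 2 * (S - 1)
    off_bnd = off_topo + n_topo * 3 * S
    off_init = off_bnd + 2
    off_decay = off_init + G
    off_loop = off_decay + G
    off_rnap = off_loop + 2 * B
    N = off_rnap + 2 * M

    # ---- state
    turn = turn0.copy()
    occ = occ0.copy()
    looped = looped0.copy()
    mrna = np.zeros(G, np.int64)
    blocked = np.zeros(G, np.int8)
    bp_total = np.zeros(G, np.int64)

    r_alive = np.zeros(M, np.int8)
    r_gene = np.zeros(M, np.int64)
    r_seg = np.zeros(M, np.int64)
    r_bp = np.zeros(M, np.int64)
    r_mode = np.zeros(M, np.int8)  # 0 processive, 1 stalled
    r_t0 = np.zeros(M, np.float64)
    r_id = np.zeros(M, np.int64)
    r_stall_enter = np.full(M, -1.0, np.float64)
    r_stall_tot = np.zeros(M, np.float64)
    r_fup = np.zeros(M, np.int64)  # cached flank segments (valid while occupancy static)
    r_fdn = np.zeros(M, np.int64)
    alive_list = np.zeros(M, np.int64)
    n_alive = 0

    next_id = 0

    # ---- counters
    c_init = np.zeros(G, np.int64)
    c_term = np.zeros(G, np.int64)
    c_cat = np.zeros(max(n_topo, 1), np.int64)
    c_stall_in = np.zeros(G, np.int64)
    c_stall_out = np.zeros(G, np.int64)
    lk_topo = 0
    lk_bnd = 0
    n_resets = 0

    # ---- events
    ev_t = np.zeros(ev_cap, np.float64)
    ev_kind = np.zeros(ev_cap, np.int8)
    ev_gene = np.full(ev_cap, -1, np.int64)
    ev_rid = np.full(ev_cap, -1, np.int64)
    ev_val = np.zeros(ev_cap, np.float64)
    ev_n = 0

    # ---- frames
    F = int(math.floor(t_end / record_dt + 1e-9)) + 1
    fr_mrna = np.zeros((F, G), np.int64)
    fr_loop = np.zeros((F, max(B, 1)), np.int8)
    fr_nr = np.zeros(F, np.int64)
    fr_rid = np.full((F, M), -1, np.int64)
    fr_gene = np.full((F, M), -1, np.int64)
    fr_seg = np.full((F, M), -1, np.int64)
    fr_mode = np.full((F, M), -1, np.int8)
    fr_tot = np.zeros(F, np.int64)
    fr_lk_topo = np.zeros(F, np.int64)
    fr_lk_bnd = np.zeros(F, np.int64)
    if record_turn == 1:
        fr_turn = np.zeros((F, S), np.int64)
    else:
        fr_turn = np.zeros((1, 1), np.int64)
    fr_regsig = np.zeros((F, max(R, 1)), np.float64)

    # ---- propensities
    P = np.zeros(N, np.float64)
    nblk = (N + _BLK - 1) // _BLK
    blk = np.zeros(nblk, np.float64)
    A_ = np.zeros(1, np.float64)

    err = 0
    need_refresh = True  # full build on entry

    t = 0.0
    next_f = 0
    steps = 0
    touched = np.zeros(8, np.int64)

    while True:
        steps += 1
        if need_refresh or steps % 65536 == 0:
            need_refresh = False
            # rebuild flank caches and modes are assumed current; recompute
            # every propensity and the partial sums from scratch
            for k in range(S - 1):
                P[k] = _p_hop_right(k, turn, occ, k_drift, biased)
                P[(S - 1) + k] = _p_hop_left(k, turn, occ, k_drift, biased)
            for ti in range(n_topo):
                base = off_topo + ti * 3 * S
                for k in range(S):
                    P[base + k] = t_kbind[ti] if occ[k] == 0 else 0.0
                    P[base + S + k] = t_kunbind[ti] if occ[k] == t_code[ti] else 0.0
                    P[base + 2 * S + k] = _p_cat(
                        k, ti, turn, occ, t_code, t_step, t_kcatmax, t_shalf, t_sign, lk0
                    )
            P[off_bnd] = b_rate if b_left == 1 else 0.0
            P[off_bnd + 1] = b_rate if b_right == 1 else 0.0
            for g in range(G):
                P[off_init + g] = _p_init(
                    g, turn, occ, blocked, g_tss, g_dir, g_kmin, g_kmax, g_sstar, lk0
                )
                P[off_decay + g] = g_decay[g] * mrna[g]
            for b in range(B):
                if br_perm[b] == 1:
                    P[off_loop + 2 * b] = 0.0
                    P[off_loop + 2 * b + 1] = 0.0
                else:
                    if looped[b] == 0 and occ[br_a[b]] == 0 and occ[br_b[b]] == 0:
                        P[off_loop + 2 * b] = br_kloop[b]
                    else:
                        P[off_loop + 2 * b] = 0.0
                    P[off_loop + 2 * b + 1] = br_kunloop[b] if looped[b] == 1 else 0.0
            for s_ in range(M):
                P[off_rnap + 2 * s_] = _p_transloc(
                    s_, S, r_alive, r_gene, r_seg, r_mode, occ, g_dir, g_end, g_rate
                )
                P[off_rnap + 2 * s_ + 1] = _p_rot(s_, S, r_alive, r_seg, turn, occ, k_rot)
            A_[0] = 0.0
            for b in range(nblk):
                s0 = 0.0
                for i in range(b * _BLK, min((b + 1) * _BLK, N)):
                    s0 += P[i]
                blk[b] = s0
                A_[0] += s0

        A = A_[0]
        if A > 1e-13:
            t_next = t - math.log(np.random.random()) / A
        else:
            t_next = t_end + 1.0

        horizon = t_next if t_next < t_end else t_end
        while next_f < F and next_f * record_dt <= horizon + 1e-12:
            f = next_f
            for g in range(G):
                fr_mrna[f, g] = mrna[g]
            for b in range(B):
                fr_loop[f, b] = looped[b]
            nr = 0
            for q in range(n_alive):
                s_ = alive_list[q]
                fr_rid[f, nr] = r_id[s_]
                fr_gene[f, nr] = r_gene[s_]
                fr_seg[f, nr] = r_seg[s_]
                fr_mode[f, nr] = r_mode[s_]
                nr += 1
            fr_nr[f] = nr
            tot = 0
            for k in range(S):
                tot += turn[k]
            fr_tot[f] = tot
            fr_lk_topo[f] = lk_topo
            fr_lk_bnd[f] = lk_bnd
            if record_turn == 1:
                for k in range(S):
                    fr_turn[f, k] = turn[k]
            for r_ in range(R):
                ssum = 0
                cnt = 0
                for q in range(reg_ptr[r_], reg_ptr[r_ + 1]):
                    k = reg_segs[q]
                    if occ[k] == 0:
                        ssum += turn[k]
                        cnt += 1
                if cnt == 0:
                    for q in range(reg_ptr[r_], reg_ptr[r_ + 1]):
                        ssum += turn[reg_segs[q]]
                        cnt += 1
                fr_regsig[f, r_] = (ssum - cnt * lk0) / (cnt * lk0)
            next_f += 1

        if t_next > t_end or err != 0:
            break

        # ---- select channel (block scan)
        r = np.random.random() * A
        ci = -1
        acc = 0.0
        for b in range(nblk):
            if acc + blk[b] >= r:
                hi = min((b + 1) * _BLK, N)
                for i in range(b * _BLK, hi):
                    acc += P[i]
                    if acc >= r:
                        ci = i
                        break
                if ci < 0:
                    for i in range(hi - 1, b * _BLK - 1, -1):
                        if P[i] > 0.0:
                            ci = i
                            break
                break
            acc += blk[b]
        if ci < 0:
            need_refresh = True
            continue

        # ---- apply + localized refresh
        occ_changed = False
        ntch = 0
        if ci < off_topo:
            # supercoil hop
            if ci < S - 1:
                k = ci
                turn[k] -= 1
                turn[k + 1] += 1
            else:
                k = ci - (S - 1)
                turn[k + 1] -= 1
                turn[k] += 1
            touched[0] = k
            touched[1] = k + 1
            ntch = 2
        elif ci < off_bnd:
            rem = ci - off_topo
            ti = rem // (3 * S)
            rem -= ti * 3 * S
            typ = rem // S
            k = rem % S
            if typ == 0:
                occ[k] = t_code[ti]
                occ_changed = True
            elif typ == 1:
                occ[k] = 0
                for g in range(G):
                    if blocked[g] == 1 and g_tss[g] == k:
                        occ[k] = BARRIER
                occ_changed = True
            else:
                turn[k] += t_step[ti]
                lk_topo += t_step[ti]
                c_cat[ti] += 1
            touched[0] = k
            ntch = 1
        elif ci < off_init:
            k = 0 if ci - off_bnd == 0 else S - 1
            lk_bnd += b_target - turn[k]
            turn[k] = b_target
            n_resets += 1
            touched[0] = k
            ntch = 1
        elif ci < off_decay:
            # initiation
            g = ci - off_init
            tss = g_tss[g]
            d = g_dir[g]
            slot = -1
            for s_ in range(M):
                if r_alive[s_] == 0:
                    slot = s_
                    break
            if slot < 0:
                err = 1
                break
            sig = _sigma(turn[tss], lk0)
            turn[tss + d] += turn[tss]
            turn[tss] = 0
            occ[tss] = RNAP
            r_alive[slot] = 1
            r_gene[slot] = g
            r_seg[slot] = tss
            r_bp[slot] = 0
            r_mode[slot] = 0
            r_t0[slot] = t_next
            r_id[slot] = next_id
            r_stall_enter[slot] = -1.0
            r_stall_tot[slot] = 0.0
            alive_list[n_alive] = slot
            n_alive += 1
            c_init[g] += 1
            if ev_n < ev_cap:
                ev_t[ev_n] = t_next
                ev_kind[ev_n] = 0
                ev_gene[ev_n] = g
                ev_rid[ev_n] = next_id
                ev_val[ev_n] = sig
                ev_n += 1
            else:
                err = 2
                break
            next_id += 1
            touched[0] = tss
            touched[1] = tss + d
            ntch = 2
            occ_changed = True
        elif ci < off_loop:
            g = ci - off_decay
            mrna[g] -= 1
            _setp(off_decay + g, g_decay[g] * mrna[g], P, blk, A_)
        elif ci < off_rnap:
            rem = ci - off_loop
            b = rem // 2
            typ = rem % 2
            if typ == 0:
                occ[br_a[b]] = BARRIER
                occ[br_b[b]] = BARRIER
                looped[b] = 1
                kind = 3
            else:
                occ[br_a[b]] = 0
                occ[br_b[b]] = 0
                for g in range(G):
                    if blocked[g] == 1:
                        if g_tss[g] == br_a[b]:
                            occ[br_a[b]] = BARRIER
                        if g_tss[g] == br_b[b]:
                            occ[br_b[b]] = BARRIER
                looped[b] = 0
                kind = 4
            if ev_n < ev_cap:
                ev_t[ev_n] = t_next
                ev_kind[ev_n] = kind
                ev_val[ev_n] = b
                ev_n += 1
            else:
                err = 2
                break
            touched[0] = br_a[b]
            touched[1] = br_b[b]
            ntch = 2
            occ_changed = True
        else:
            rem = ci - off_rnap
            slot = rem // 2
            typ = rem % 2
            g = r_gene[slot]
            k = r_seg[slot]
            d = g_dir[g]
            if typ == 0:
                if k == g_end[g]:
                    # termination
                    occ[k] = 0
                    for g2 in range(G):
                        if blocked[g2] == 1 and g_tss[g2] == k:
                            occ[k] = BARRIER
                    r_alive[slot] = 0
                    for q in range(n_alive):
                        if alive_list[q] == slot:
                            alive_list[q] = alive_list[n_alive - 1]
                            n_alive -= 1
                            break
                    mrna[g] += 1
                    _setp(off_decay + g, g_decay[g] * mrna[g], P, blk, A_)
                    c_term[g] += 1
                    if ev_n < ev_cap:
                        ev_t[ev_n] = t_next
                        ev_kind[ev_n] = 1
                        ev_gene[ev_n] = g
                        ev_rid[ev_n] = r_id[slot]
                        ev_val[ev_n] = t_next - r_t0[slot]
                        ev_n += 1
                    else:
                        err = 2
                        break
                    touched[0] = k
                    ntch = 1
                else:
                    k1 = k + d
                    k2 = k + 2 * d
                    turn[k2] += turn[k1]
                    turn[k1] = 0
                    occ[k] = 0
                    for g2 in range(G):
                        if blocked[g2] == 1 and g_tss[g2] == k:
                            occ[k] = BARRIER
                    occ[k1] = RNAP
                    r_seg[slot] = k1
                    r_bp[slot] += seg_bp
                    w = g_window[g]
                    if w >= 0 and r_bp[slot] - seg_bp < w <= r_bp[slot]:
                        if ev_n < ev_cap:
                            ev_t[ev_n] = t_next
                            ev_kind[ev_n] = 2
                            ev_gene[ev_n] = g
                            ev_rid[ev_n] = r_id[slot]
                            ev_val[ev_n] = t_next - r_t0[slot]
                            ev_n += 1
                        else:
                            err = 2
                            break
                    touched[0] = k
                    touched[1] = k1
                    touched[2] = k2
                    ntch = 3
                # cumulative transcription -> promoter shut-off
                bp_total[g] += seg_bp
                if g_block[g] >= 0 and blocked[g] == 0 and bp_total[g] >= g_block[g]:
                    blocked[g] = 1
                    if occ[g_tss[g]] == 0:
                        occ[g_tss[g]] = BARRIER
                    if ev_n < ev_cap:
                        ev_t[ev_n] = t_next
                        ev_kind[ev_n] = 5
                        ev_gene[ev_n] = g
                        ev_val[ev_n] = t_next
                        ev_n += 1
                    else:
                        err = 2
                        break
                    touched[ntch] = g_tss[g]
                    ntch += 1
                occ_changed = True
            else:
                a = k - 1
                b2 = k + 1
                if turn[a] > turn[b2]:
                    turn[a] -= 1
                    turn[b2] += 1
                else:
                    turn[b2] -= 1
                    turn[a] += 1
                touched[0] = a
                touched[1] = b2
                ntch = 2

        # ---- refresh channels around touched segments
        for q in range(ntch):
            k = touched[q]
            if k - 1 >= 0:
                _setp(k - 1, _p_hop_right(k - 1, turn, occ, k_drift, biased), P, blk, A_)
                _setp(
                    (S - 1) + (k - 1),
                    _p_hop_left(k - 1, turn, occ, k_drift, biased),
                    P,
                    blk,
                    A_,
                )
            if k + 1 < S:
                _setp(k, _p_hop_right(k, turn, occ, k_drift, biased), P, blk, A_)
                _setp((S - 1) + k, _p_hop_left(k, turn, occ, k_drift, biased), P, blk, A_)
            for ti in range(n_topo):
                base = off_topo + ti * 3 * S
                if occ_changed:
                    _setp(base + k, t_kbind[ti] if occ[k] == 0 else 0.0, P, blk, A_)
                    _setp(
                        base + S + k,
                        t_kunbind[ti] if occ[k] == t_code[ti] else 0.0,
                        P,
                        blk,
                        A_,
                    )
                _setp(
                    base + 2 * S + k,
                    _p_cat(k, ti, turn, occ, t_code, t_step, t_kcatmax, t_shalf, t_sign, lk0),
                    P,
                    blk,
                    A_,
                )
            for g in range(G):
                if g_tss[g] == k or g_tss[g] + g_dir[g] == k:
                    _setp(
                        off_init + g,
                        _p_init(g, turn, occ, blocked, g_tss, g_dir, g_kmin, g_kmax, g_sstar, lk0),
                        P,
                        blk,
                        A_,
                    )
            if occ_changed:
                for b in range(B):
                    if br_a[b] == k or br_b[b] == k:
                        if br_perm[b] == 0:
                            v = 0.0
                            if looped[b] == 0 and occ[br_a[b]] == 0 and occ[br_b[b]] == 0:
                                v = br_kloop[b]
                            _setp(off_loop + 2 * b, v, P, blk, A_)
                            _setp(
                                off_loop + 2 * b + 1,
                                br_kunloop[b] if looped[b] == 1 else 0.0,
                                P,
                                blk,
                                A_,
                            )
        if occ_changed:
            # loop/unloop propensities also flip on the looped flag itself
            for b in range(B):
                if br_perm[b] == 0:
                    v = 0.0
                    if looped[b] == 0 and occ[br_a[b]] == 0 and occ[br_b[b]] == 0:
                        v = br_kloop[b]
                    _setp(off_loop + 2 * b, v, P, blk, A_)
                    _setp(
                        off_loop + 2 * b + 1,
                        br_kunloop[b] if looped[b] == 1 else 0.0,
                        P,
                        blk,
                        A_,
                    )
            for g in range(G):
                _setp(
                    off_init + g,
                    _p_init(g, turn, occ, blocked, g_tss, g_dir, g_kmin, g_kmax, g_sstar, lk0),
                    P,
                    blk,
                    A_,
                )

        # ---- refresh RNAP modes and channels
        if occ_changed:
            # occupancy moved: flank caches are stale for every RNAP
            for q in range(n_alive):
                s_ = alive_list[q]
                d = g_dir[r_gene[s_]]
                r_fup[s_] = _flank_seg(r_seg[s_], -d, occ, S)
                r_fdn[s_] = _flank_seg(r_seg[s_], d, occ, S)
        for q in range(n_alive):
            s_ = alive_list[q]
            need_mode = occ_changed
            need_chan = occ_changed
            if not occ_changed:
                for q2 in range(ntch):
                    k = touched[q2]
                    if k == r_fup[s_] or k == r_fdn[s_]:
                        need_mode = True
                    if k == r_seg[s_] - 1 or k == r_seg[s_] + 1:
                        need_chan = True  # counterrotation gradient changed
            if need_mode:
                su = _sigma(turn[r_fup[s_]], lk0)
                sd = _sigma(turn[r_fdn[s_]], lk0)
                tau = _torque(sd, cs_eff, p_eff, tau0, sig_s, sig_p) - _torque(
                    su, cs_eff, p_eff, tau0, sig_s, sig_p
                )
                over = abs(tau) >= tau_c if two_sided == 1 else tau >= tau_c
                stalled = over or su <= -sig_stall or sd >= sig_stall
                g = r_gene[s_]
                if stalled and r_mode[s_] == 0:
                    r_mode[s_] = 1
                    r_stall_enter[s_] = t_next
                    c_stall_in[g] += 1
                    need_chan = True
                elif (not stalled) and r_mode[s_] == 1:
                    r_mode[s_] = 0
                    dur = t_next - r_stall_enter[s_]
                    r_stall_tot[s_] += dur
                    c_stall_out[g] += 1
                    if record_episodes == 1:
                        if ev_n < ev_cap:
                            ev_t[ev_n] = t_next
                            ev_kind[ev_n] = 6
                            ev_gene[ev_n] = g
                            ev_rid[ev_n] = r_id[s_]
                            ev_val[ev_n] = dur
                            ev_n += 1
                        else:
                            err = 2
                    r_stall_enter[s_] = -1.0
                    need_chan = True
            if need_chan:
                _setp(
                    off_rnap + 2 * s_,
                    _p_transloc(s_, S, r_alive, r_gene, r_seg, r_mode, occ, g_dir, g_end, g_rate),
                    P,
                    blk,
                    A_,
                )
                _setp(
                    off_rnap + 2 * s_ + 1,
                    _p_rot(s_, S, r_alive, r_seg, turn, occ, k_rot),
                    P,
                    blk,
                    A_,
                )
        if occ_changed:
            # dead slots may still carry stale propensities after termination
            for s_ in range(M):
                if r_alive[s_] == 0 and (P[off_rnap + 2 * s_] != 0.0 or P[off_rnap + 2 * s_ + 1] != 0.0):
                    _setp(off_rnap + 2 * s_, 0.0, P, blk, A_)
                    _setp(off_rnap + 2 * s_ + 1, 0.0, P, blk, A_)

        t = t_next

    # close censored stall episodes
    for q in range(n_alive):
        s_ = alive_list[q]
        if r_mode[s_] == 1 and r_stall_enter[s_] >= 0.0:
            r_stall_tot[s_] += t_end - r_stall_enter[s_]

    return (
        err, fr_mrna, fr_loop, fr_nr, fr_rid, fr_gene, fr_seg, fr_mode, fr_tot,
        fr_lk_topo, fr_lk_bnd, fr_turn, fr_regsig,
        ev_t[:ev_n], ev_kind[:ev_n], ev_gene[:ev_n], ev_rid[:ev_n], ev_val[:ev_n],
        c_init, c_term, c_cat, c_stall_in, c_stall_out, lk_topo, lk_bnd, n_resets,
        steps,
    )


def run_fast(config: SimulationConfig, run: RunControl, seed: Optional[int] = None) -> Trajectory:
    """Run one trajectory with the compiled kernel.

    Returns a :class:`Trajectory` with the same layout as the reference
    engine.  Requires ``torque_window_segments == 1`` (the kernel evaluates
    flank supercoiling at the nearest unoccupied segment on each side).
    """
    mech = config.mechanics
    if mech.torque_window_segments != 1:
        raise ValueError("fast kernel supports torque_window_segments == 1 only")
    lat = config.lattice
    state0 = build_state(config)  # validates + initial occupancy/loops
    S = lat.n_segments
    G = len(config.genes)
    B = len(config.barriers)
    use_seed = int(run.seed if seed is None else seed)

    g_dir = np.array([g.direction for g in config.genes], np.int64).reshape(G)
    g_tss = np.array([g.tss_segment for g in config.genes], np.int64).reshape(G)
    g_end = np.array([g.end_segment for g in config.genes], np.int64).reshape(G)
    g_kmin = np.array([g.k_min for g in config.genes], np.float64).reshape(G)
    g_kmax = np.array([g.k_max for g in config.genes], np.float64).reshape(G)
    g_sstar = np.array([g.sigma_star for g in config.genes], np.float64).reshape(G)
    g_rate = np.array([g.k_elong / lat.segment_bp for g in config.genes], np.float64).reshape(G)
    g_decay = np.array([g.mrna_decay_rate for g in config.genes], np.float64).reshape(G)
    g_block = np.array(
        [-1 if g.promoter_block_after_bp is None else g.promoter_block_after_bp for g in config.genes],
        np.int64,
    ).reshape(G)
    g_window = np.array(
        [-1 if g.report_window_bp is None else g.report_window_bp for g in config.genes],
        np.int64,
    ).reshape(G)

    T = len(config.topos)
    t_code = np.array([t.occupancy_code for t in config.topos], np.int8).reshape(T)
    t_kbind = np.array([t.k_bind for t in config.topos], np.float64).reshape(T)
    t_kunbind = np.array([t.k_unbind for t in config.topos], np.float64).reshape(T)
    t_step = np.array([t.catalytic_step_units for t in config.topos], np.int64).reshape(T)
    t_kcatmax = np.array([t.kcat_max for t in config.topos], np.float64).reshape(T)
    t_shalf = np.array([t.sigma_half for t in config.topos], np.float64).reshape(T)
    t_sign = np.array([t.active_sign for t in config.topos], np.int64).reshape(T)

    br_a = np.array([b.site_a for b in config.barriers], np.int64).reshape(B)
    br_b = np.array([b.site_b for b in config.barriers], np.int64).reshape(B)
    br_kloop = np.array([b.k_loop for b in config.barriers], np.float64).reshape(B)
    br_kunloop = np.array([b.k_unloop for b in config.barriers], np.float64).reshape(B)
    br_perm = np.array([1 if b.permanent else 0 for b in config.barriers], np.int8).reshape(B)
    looped0 = state0.looped.astype(np.int8).reshape(B)

    regions = run.regions or {}
    names = list(regions)
    reg_ptr = np.zeros(len(names) + 1, np.int64)
    segs_flat: list = []
    for i, nm in enumerate(names):
        segs_flat.extend(int(s) for s in regions[nm])
        reg_ptr[i + 1] = len(segs_flat)
    reg_segs = np.array(segs_flat, np.int64).reshape(len(segs_flat))

    M = int(min(run.max_rnap, sum(g.n_segments // 2 + 2 for g in config.genes) + 2 or 4))
    kmax_tot = float(sum(g.k_max for g in config.genes))
    loops_rate = float(sum(b.k_loop + b.k_unloop for b in config.barriers))
    ev_cap = int(1000 + run.t_end * (4.0 * kmax_tot + 2.0 * loops_rate) * 5)
    if run.record_stall_episodes:
        ev_cap += int(run.t_end * 500)

    out = _kernel(
        S, lat.lk0_units, lat.segment_bp,
        state0.turn.astype(np.int64), state0.occupancy.astype(np.int8),
        float(lat.k_drift), 1 if lat.diffusion_mode == "biased" else 0,
        1 if lat.boundary_left == "relaxing" else 0,
        1 if lat.boundary_right == "relaxing" else 0,
        float(lat.boundary_reset_rate), int(lat.boundary_target_units),
        g_dir, g_tss, g_end, g_kmin, g_kmax, g_sstar, g_rate, g_decay, g_block, g_window,
        t_code, t_kbind, t_kunbind, t_step, t_kcatmax, t_shalf, t_sign,
        br_a, br_b, br_kloop, br_kunloop, br_perm, looped0,
        mech.cs * mech.omega0, mech.p * mech.omega0, mech.coexistence_torque,
        mech.sigma_s, mech.sigma_p, mech.stall_torque, mech.sigma_stall,
        mech.k_rot, 1 if mech.stall_two_sided else 0,
        float(run.t_end), float(run.record_dt), use_seed % (2**31 - 1), M,
        1 if run.record_turn else 0, 1 if run.record_stall_episodes else 0,
        reg_ptr, reg_segs, ev_cap,
    )
    (
        err, fr_mrna, fr_loop, fr_nr, fr_rid, fr_gene, fr_seg, fr_mode, fr_tot,
        fr_lk_topo, fr_lk_bnd, fr_turn, fr_regsig,
        ev_t, ev_kind, ev_gene, ev_rid, ev_val,
        c_init, c_term, c_cat, c_stall_in, c_stall_out, lk_topo, lk_bnd, n_resets,
        n_events,
    ) = out
    if err == 1:
        raise RuntimeError("fast kernel: RNAP slot overflow (raise RunControl.max_rnap)")
    if err == 2:
        raise RuntimeError("fast kernel: event-log capacity exceeded")

    F = fr_mrna.shape[0]
    times = np.arange(F) * run.record_dt
    rnap_frames = []
    for f in range(F):
        n = int(fr_nr[f])
        arr = np.empty((n, 4), np.int64)
        arr[:, 0] = fr_rid[f, :n]
        arr[:, 1] = fr_gene[f, :n]
        arr[:, 2] = fr_seg[f, :n]
        arr[:, 3] = fr_mode[f, :n]
        # present RNAPs in genomic order for spacing statistics
        order = np.argsort(arr[:, 2], kind="stable")
        rnap_frames.append(arr[order])
    events = np.array(
        [
            (ev_t[i], KIND_NAMES[ev_kind[i]], ev_gene[i], ev_rid[i], ev_val[i])
            for i in range(len(ev_t))
        ],
        dtype=Trajectory.EVENT_DTYPE,
    )
    region_means = (
        {nm: fr_regsig[:, i].copy() for i, nm in enumerate(names)} if names else None
    )
    traj = Trajectory(
        times=times,
        mrna=fr_mrna.copy(),
        rnap_frames=rnap_frames,
        loop_state=fr_loop[:, :B].astype(bool).reshape(F, B),
        events=events,
        metadata={
            "seed": use_seed,
            "engine": "fast",
            "config": config,
            "record_dt": run.record_dt,
            "t_end": run.t_end,
            "n_events": int(n_events),
            "lk_audit": {
                "total": fr_tot.copy(),
                "topo_cum": fr_lk_topo.copy(),
                "boundary_cum": fr_lk_bnd.copy(),
            },
        },
        turn=fr_turn.copy() if run.record_turn else None,
        region_means=region_means,
        final_counters={
            "initiations": c_init.copy(),
            "terminations": c_term.copy(),
            "topo_catalyses": {t.enzyme: int(c_cat[i]) for i, t in enumerate(config.topos)},
            "lk_delta_topo": int(lk_topo),
            "lk_delta_boundary": int(lk_bnd),
            "boundary_resets": int(n_resets),
            "stall_entries": c_stall_in.copy(),
            "stall_exits": c_stall_out.copy(),
        },
    )
    return traj
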