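"""Numba inner loops of the frustrated conjugation dynamics.

All randomness is consumed from pre-generated arrays (`cell_draws`,
`u_partner`, `u_rep`, `perms`) so the kernels are pure functions of their
inputs; the python reference implementation in :mod:`cellfrust.engine`
consumes the same streams and must produce bit-identical event logs.

Conventions
-----------
* ``pref[j, i]`` is T cell ``j``'s rank of the symbol currently perceived on
  APC ``i`` (lower = preferred).
* ``a_partner[i]`` / ``t_partner[j]`` hold the partner index or -1.
* A new conjugation may terminate up to two existing ones (one per side);
  every termination increments ``c0`` for the APC involved and ``cact`` when
  the duration reached ``tau_act``.
* Event causes: 0 = displaced, 1 = anergy.
"""

import numpy as np
from numba import njit

INF_TAU = np.int64(2**62)


@njit(cache=True)
def run_window_kernel(
    pref, asub, tsub, conn, rev,
    cell_draws, u_partner, u_rep,
    t_partner, a_partner, a_start, cur_member, time0,
    anergy_tau, pref_rep, ring,
    c0, cact, tau_act,
    ev_time, ev_apc, ev_tc, ev_dur, ev_cause, record_events,
):
    n_t, n = pref.shape
    steps = cell_draws.shape[0]
    deg_t = conn.shape[1]
    deg_a = rev.shape[1]
    n_ev = 0
    for step in range(steps):
        t = time0 + step
        if anergy_tau > 0:
            slot = t % anergy_tau
            i = ring[slot]
            if i >= 0:
                j = a_partner[i]
                if j >= 0 and a_start[i] == t - anergy_tau:
                    c0[i] += 1
                    if anergy_tau >= tau_act:
                        cact[i] += 1
                    if record_events:
                        ev_time[n_ev] = t
                        ev_apc[n_ev] = i
                        ev_tc[n_ev] = j
                        ev_dur[n_ev] = anergy_tau
                        ev_cause[n_ev] = 1
                        n_ev += 1
                    a_partner[i] = -1
                    t_partner[j] = -1
                    r = int(u_rep[step] * pref_rep.shape[0])
                    cur_member[j] = r
                    for q in range(n):
                        pref[j, q] = pref_rep[r, j, q]
                ring[slot] = -1
        c = cell_draws[step]
        if c < n:
            i = c
            j = rev[i, int(u_partner[step] * deg_a)]
        else:
            j = c - n
            i = conn[j, int(u_partner[step] * deg_t)]
        cur_a = t_partner[j]
        if cur_a == i:
            continue
        cur_t = a_partner[i]
        # each side detaches when it strictly prefers the candidate,
        # whether or not the candidate reciprocates (synapse re-direction)
        t_pref = cur_a == -1 or pref[j, i] < pref[j, cur_a]
        a_pref = cur_t == -1 or (tsub[j] == asub[i] and tsub[cur_t] != asub[i])
        if t_pref and cur_a >= 0:
            dur = t - a_start[cur_a]
            c0[cur_a] += 1
            if dur >= tau_act:
                cact[cur_a] += 1
            if record_events:
                ev_time[n_ev] = t
                ev_apc[n_ev] = cur_a
                ev_tc[n_ev] = j
                ev_dur[n_ev] = dur
                ev_cause[n_ev] = 0
                n_ev += 1
            a_partner[cur_a] = -1
            t_partner[j] = -1
        if a_pref and cur_t >= 0:
            dur = t - a_start[i]
            c0[i] += 1
            if dur >= tau_act:
                cact[i] += 1
            if record_events:
                ev_time[n_ev] = t
                ev_apc[n_ev] = i
                ev_tc[n_ev] = cur_t
                ev_dur[n_ev] = dur
                ev_cause[n_ev] = 0
                n_ev += 1
            t_partner[cur_t] = -1
            a_partner[i] = -1
        if t_pref and a_pref:
            t_partner[j] = i
            a_partner[i] = j
            a_start[i] = t
            if anergy_tau > 0:
                ring[t % anergy_tau] = i
    return n_ev


@njit(cache=True)
def educate_kernel(
    ranks, pref, rare_s, asub, tsub, conn, rev,
    cell_draws, u_partner, perms,
    t_partner, a_partner, a_start,
    state, t_s, w_tau, stop_window, sweep, elim_tol,
    trace_iter, trace_tau, elim_counts, snap_ranks,
):
    """Negative-selection loop over one chunk of draws.

    All times (``t_s``, ``w_tau``, ``stop_window``, durations, ``tau_n``)
    are in elementary draws; the elimination scan and window bookkeeping run
    once per ``sweep`` draws (the protocol's iteration unit).  Every
    ``w_tau`` draws the threshold is lowered to the window's largest
    displacement-terminated duration, provided at most ``elim_tol``
    eliminations occurred in the window (a small tolerance keeps the
    ratchet moving despite the standing elimination/replacement mill).

    ``state``: int64 vector
        [0] t  [1] tau_n  [2] window start  [3] last tau_n change
        [4] window max displaced duration  [5] perms used  [6] trace length
        [7] stopped  [8] snapshot recorded  [9] eliminations in window
    Returns steps consumed (the caller refills draws/perms when the chunk is
    exhausted before the stop condition fires).
    """
    n_t, n = pref.shape
    n_samples = rare_s.shape[0]
    per_cell = rare_s.shape[1] > 1
    steps = cell_draws.shape[0]
    deg_t = conn.shape[1]
    deg_a = rev.shape[1]
    two_n = ranks.shape[1]

    for step in range(steps):
        t = state[0]
        # configuration switch
        if t % t_s == 0:
            s = (t // t_s) % n_samples
            for j in range(n_t):
                jj = j if per_cell else 0
                for i in range(n):
                    pref[j, i] = ranks[j, 2 * i + rare_s[s, jj, i]]
        s = (t // t_s) % n_samples
        # elimination scan against current ages, once per sweep
        scan = t % sweep == 0
        for i in range(n if scan else 0):
            j = a_partner[i]
            if j >= 0 and t - a_start[i] >= state[1]:
                if state[5] >= perms.shape[0]:
                    return step  # need a fresh permutation pool
                p = perms[state[5]]
                state[5] += 1
                for k in range(two_n):
                    ranks[j, p[k]] = k
                jj = j if per_cell else 0
                for q in range(n):
                    pref[j, q] = ranks[j, 2 * q + rare_s[s, jj, q]]
                elim_counts[j] += 1
                a_partner[i] = -1
                t_partner[j] = -1
                state[9] += 1
        # periodic threshold update over displacement-terminated durations
        # only; cells still holding a conjugate are handled by the
        # age-based elimination once tau_n drops below their age
        if scan and t - state[2] >= w_tau:
            new_tau = state[4]
            if state[9] <= elim_tol and new_tau < state[1]:
                state[1] = new_tau
                k = state[6]
                if k < trace_iter.shape[0]:
                    trace_iter[k] = t
                    trace_tau[k] = new_tau
                    state[6] = k + 1
                for j in range(n_t):
                    for q in range(two_n):
                        snap_ranks[j, q] = ranks[j, q]
                state[8] = 1
                state[3] = t
            state[2] = t
            state[4] = 0
            state[9] = 0
        if state[1] < INF_TAU and t - state[3] >= stop_window:
            state[7] = 1
            return step
        # one interaction
        c = cell_draws[step]
        if c < n:
            i = c
            j = rev[i, int(u_partner[step] * deg_a)]
        else:
            j = c - n
            i = conn[j, int(u_partner[step] * deg_t)]
        cur_a = t_partner[j]
        if cur_a != i:
            cur_t = a_partner[i]
            t_pref = cur_a == -1 or pref[j, i] < pref[j, cur_a]
            a_pref = cur_t == -1 or (tsub[j] == asub[i] and tsub[cur_t] != asub[i])
            if t_pref and cur_a >= 0:
                dur = t - a_start[cur_a]
                if dur > state[4]:
                    state[4] = dur
                a_partner[cur_a] = -1
                t_partner[j] = -1
            if a_pref and cur_t >= 0:
                dur = t - a_start[i]
                if dur > state[4]:
                    state[4] = dur
                t_partner[cur_t] = -1
                a_partner[i] = -1
            if t_pref and a_pref:
                t_partner[j] = i
                a_partner[i] = j
                a_start[i] = t
        state[0] = t + 1
    return steps


@njit(cache=True, inline="always")
def _xorshift(state):
    x = state
    x ^= x << 13
    x &= np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> 7
    x ^= x << 17
    x &= np.uint64(0xFFFFFFFFFFFFFFFF)
    return x


@njit(cache=True)
def run_batch_kernel(
    ranks_rep, rare_stack, asub, tsub,
    seed, window, anergy_tau, tau_act,
    t_partner, a_partner, a_start, cur_member, time0,
    c0_out, cact_out, tcact_out,
):
    """Consecutive anergy windows over a stack of samples (full connectivity).

    One window of ``window`` elementary draws per sample; partners, the
    anergy ring and the clock persist across windows, counts are per
    window.  Randomness comes from an inline xorshift64 generator seeded
    with ``seed`` (deterministic).  ``ranks_rep``: (R, n_t, 2n) repertoire
    rank matrices; ``rare_stack``: (S, R or 1, n_t or 1, n) rare flags per sample (and
    optionally per repertoire member).
    Returns the end time.
    """
    n_samples = rare_stack.shape[0]
    per_member = rare_stack.shape[1] > 1
    per_cell = rare_stack.shape[2] > 1
    n_rep = ranks_rep.shape[0]
    n_t = ranks_rep.shape[1]
    n = ranks_rep.shape[2] // 2
    two_nn = np.uint64(2 * n * n)
    pref = np.empty((n_t, n), dtype=np.int32)
    ring = np.full(max(anergy_tau, 1), -1, dtype=np.int64)
    rng_state = np.uint64(seed * 2654435761 + 0x9E3779B97F4A7C15)
    for _ in range(8):
        rng_state = _xorshift(rng_state)
    t = time0
    slot = time0 % anergy_tau if anergy_tau > 0 else 0
    for s in range(n_samples):
        for j in range(n_t):
            jj = j if per_cell else 0
            r0 = int(cur_member[j])
            rm = np.int64(r0) if per_member else np.int64(0)
            rr = ranks_rep[r0, j]
            for i in range(n):
                pref[j, i] = rr[2 * i + rare_stack[s, rm, jj, i]]
        for step in range(window):
            if anergy_tau > 0:
                i = ring[slot]
                if i >= 0:
                    j = a_partner[i]
                    if j >= 0 and a_start[i] == t - anergy_tau:
                        c0_out[s, i] += 1
                        if anergy_tau >= tau_act:
                            cact_out[s, i] += 1
                            tcact_out[s, j] += 1
                        a_partner[i] = -1
                        t_partner[j] = -1
                        rng_state = _xorshift(rng_state)
                        r = np.int64(rng_state % np.uint64(n_rep))
                        cur_member[j] = r
                        jj = j if per_cell else 0
                        rm = np.int64(r) if per_member else np.int64(0)
                        rr = ranks_rep[r, j]
                        for q in range(n):
                            pref[j, q] = rr[2 * q + rare_stack[s, rm, jj, q]]
                    ring[slot] = -1
            rng_state = _xorshift(rng_state)
            v = int(rng_state % two_nn)
            c = v // n
            p = v % n
            if c < n:
                i = c
                j = p
            else:
                j = c - n
                i = p
            cur_a = t_partner[j]
            if cur_a != i:
                cur_t = a_partner[i]
                t_pref = cur_a == -1 or pref[j, i] < pref[j, cur_a]
                a_pref = cur_t == -1 or (tsub[j] == asub[i] and tsub[cur_t] != asub[i])
                if t_pref and cur_a >= 0:
                    dur = t - a_start[cur_a]
                    c0_out[s, cur_a] += 1
                    if dur >= tau_act:
                        cact_out[s, cur_a] += 1
                        tcact_out[s, j] += 1
                    a_partner[cur_a] = -1
                    t_partner[j] = -1
                if a_pref and cur_t >= 0:
                    dur = t - a_start[i]
                    c0_out[s, i] += 1
                    if dur >= tau_act:
                        cact_out[s, i] += 1
                        tcact_out[s, cur_t] += 1
                    t_partner[cur_t] = -1
                    a_partner[i] = -1
                if t_pref and a_pref:
                    t_partner[j] = i
                    a_partner[i] = j
                    a_start[i] = t
                    if anergy_tau > 0:
                        ring[slot] = i
            t += 1
            if anergy_tau > 0:
                slot += 1
                if slot == anergy_tau:
                    slot = 0
    return t
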