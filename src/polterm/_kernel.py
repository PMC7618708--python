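"""Compiled inner loops of the transcription-unit lattice simulator.

Single source of truth for the per-step update: :func:`advance` performs one
``dt`` tick (initiation, biased translocation, premature termination,
run-off completion, occupancy accrual) on flat arrays; :func:`run_sim`
iterates it with numba's own RNG.  The object-level API in
:mod:`polterm.model_core` wraps these same kernels.

Counter array layout (int64, length 6):
``0`` initiations, ``1`` productive, ``2`` non_productive,
``3`` clamp warnings, ``4`` productive after burn-in,
``5`` non_productive after burn-in.
"""

import numpy as np
from numba import njit

NT_PER_TURN = 10.3  # one full DNA rotation per ~10.3 nt synthesized


@njit(cache=False)
def entrain(position, ler_length):
    """Torsional entrainment factor of a polymerase with nascent
    transcript of ~``position`` nt; linear ramp over the low-entrainment
    region, 1 beyond it (ler_length <= 0 disables the ramp)."""
    if ler_length <= 0:
        return 1.0
    v = position / ler_length
    return v if v < 1.0 else 1.0


@njit(cache=False)
def step_probs(blocked_f, blocked_b, s_sig, h_sig, torsion,
               v_bar, dt, p_move, dg_structure, dg_hybrid_ratio):
    """Forward/backward translocation probabilities for one tick.

    Brownian-ratchet rule: a baseline mobility ``p_move`` is split into
    forward/backward halves shifted by a net bias.  The bias is the
    calibrated drift ``v_bar*dt`` plus the nascent-structure and
    RNA:DNA-hybrid rectification terms (folded RNA behind the enzyme
    blocks backtracking) plus the torsion term.  Neutral template, no
    neighbours: p_f - p_b == v_bar*dt exactly.

    Returns (p_f, p_b, clamped_flag).
    """
    bias = v_bar * dt * (1.0 + dg_structure * s_sig
                         + dg_structure * dg_hybrid_ratio * h_sig) + torsion
    pf = 0.5 * (p_move + bias)
    pb = 0.5 * (p_move - bias)
    clamped = False
    if pf < 0.0:
        pf = 0.0
        clamped = True
    elif pf > 1.0:
        pf = 1.0
        clamped = True
    if pb < 0.0:
        pb = 0.0
        clamped = True
    elif pb > 1.0:
        pb = 1.0
        clamped = True
    if blocked_f:
        pf = 0.0
    if blocked_b:
        pb = 0.0
    tot = pf + pb
    if tot > 1.0:
        pf /= tot
        pb /= tot
        clamped = True
    return pf, pb, clamped


@njit(cache=False)
def _remove(positions, maxpos, birth, twist, n, i):
    """Drop polymerase i; the two flanking twist gaps merge and relax to 0
    (topoisomerase swivel abstraction)."""
    if i > 0:
        twist[i - 1] = 0.0
        start = i
    else:
        start = 0
    for j in range(start, n - 2):
        twist[j] = twist[j + 1]
    for j in range(i, n - 1):
        positions[j] = positions[j + 1]
        maxpos[j] = maxpos[j + 1]
        birth[j] = birth[j + 1]
    return n - 1


@njit(cache=False)
def advance(positions, maxpos, birth, twist, n, fold, occupancy,
            gene_length, footprint, dt, v_bar, p_move,
            dg_structure, dg_hybrid_ratio, structure_window,
            torsion_c, ler_length, hazard, pt_distance,
            const_vel, k_det, step_idx,
            attempt, init_prob, init_draw, move_draws, pt_draws,
            counters, after_burn):
    """One dt tick.  Polymerases are stored downstream->upstream
    (strictly decreasing position).  Update order: initiation, movement
    (downstream first), premature termination, completion, occupancy."""
    # --- initiation ---------------------------------------------------
    if attempt:
        free = (n == 0) or (positions[n - 1] > footprint)
        if free and init_draw < init_prob:
            positions[n] = 1
            maxpos[n] = 1
            birth[n] = step_idx
            if n > 0:
                twist[n - 1] = 0.0
            n += 1
            counters[0] += 1
    # --- movement -----------------------------------------------------
    turn = 1.0 / NT_PER_TURN
    for i in range(n):
        p = positions[i]
        blocked_f = (p >= gene_length) or \
            (i > 0 and positions[i - 1] - p <= footprint)
        blocked_b = (p <= 1) or \
            (i < n - 1 and p - positions[i + 1] <= footprint)
        move = 0
        if const_vel:
            if (not blocked_f) and ((step_idx - birth[i]) % k_det == 0):
                move = 1
        else:
            s_sig = 0.0
            lo = p - 1 - structure_window
            if lo < 0:
                lo = 0
            hi = p - 1
            if hi > lo:
                acc = 0.0
                for k in range(lo, hi):
                    acc += fold[k]
                s_sig = acc / (hi - lo)
            h_sig = fold[p - 1]
            e_i = entrain(p, ler_length)
            torsion = 0.0
            if i < n - 1:
                torsion += torsion_c * twist[i] * e_i * \
                    entrain(positions[i + 1], ler_length)
            if i > 0:
                torsion -= torsion_c * twist[i - 1] * e_i * \
                    entrain(positions[i - 1], ler_length)
            pf, pb, clamped = step_probs(
                blocked_f, blocked_b, s_sig, h_sig, torsion,
                v_bar, dt, p_move, dg_structure, dg_hybrid_ratio)
            if clamped:
                counters[3] += 1
            u = move_draws[i]
            if u < pf:
                move = 1
            elif u < pf + pb:
                move = -1
        if move == 1:
            positions[i] = p + 1
            if positions[i] > maxpos[i]:
                maxpos[i] = positions[i]
            if i < n - 1:
                twist[i] -= turn
            if i > 0:
                twist[i - 1] += turn
        elif move == -1:
            positions[i] = p - 1
            if i < n - 1:
                twist[i] += turn
            if i > 0:
                twist[i - 1] -= turn
    # --- premature termination ---------------------------------------
    p_term = hazard * dt
    if p_term > 0.0:
        i = n - 1
        while i >= 0:
            if positions[i] <= pt_distance and pt_draws[i] < p_term:
                counters[2] += 1
                if after_burn:
                    counters[5] += 1
                n = _remove(positions, maxpos, birth, twist, n, i)
            i -= 1
    # --- run-off completion -------------------------------------------
    i = n - 1
    while i >= 0:
        if positions[i] >= gene_length:
            counters[1] += 1
            if after_burn:
                counters[4] += 1
            n = _remove(positions, maxpos, birth, twist, n, i)
        i -= 1
    # --- occupancy -----------------------------------------------------
    for i in range(n):
        occupancy[positions[i] - 1] += dt
    return n


@njit(cache=False)
def run_sim(seed, n_steps, burn_steps, fold,
            gene_length, footprint, dt, v_bar, p_move,
            dg_structure, dg_hybrid_ratio, structure_window,
            torsion_c, ler_length, hazard, pt_distance,
            const_vel, k_det, init_every, init_prob, cap):
    """Full run of ``n_steps`` ticks from an empty unit under one seed.

    Returns (counters, occupancy, n_engaged_final, pol_steps_after_burn)
    where mean polymerase count after burn-in is
    pol_steps_after_burn / (n_steps - burn_steps).
    """
    np.random.seed(seed)
    positions = np.zeros(cap, np.int64)
    maxpos = np.zeros(cap, np.int64)
    birth = np.zeros(cap, np.int64)
    twist = np.zeros(cap, np.float64)
    occupancy = np.zeros(gene_length, np.float64)
    counters = np.zeros(6, np.int64)
    move_draws = np.empty(cap, np.float64)
    pt_draws = np.empty(cap, np.float64)
    n = 0
    pol_steps = 0
    for step in range(n_steps):
        attempt = (step % init_every) == 0
        init_draw = np.random.random() if attempt else 2.0
        m = n + 1
        if m > cap:
            m = cap
        for i in range(m):
            move_draws[i] = np.random.random()
        for i in range(m):
            pt_draws[i] = np.random.random()
        after = step >= burn_steps
        n = advance(positions, maxpos, birth, twist, n, fold, occupancy,
                    gene_length, footprint, dt, v_bar, p_move,
                    dg_structure, dg_hybrid_ratio, structure_window,
                    torsion_c, ler_length, hazard, pt_distance,
                    const_vel, k_det, step,
                    attempt, init_prob, init_draw, move_draws, pt_draws,
                    counters, after)
        if after:
            pol_steps += n
    return counters, occupancy, n, pol_steps
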