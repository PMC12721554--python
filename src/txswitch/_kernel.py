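"""Numba kernels for the Gillespie direct method.

Propensity kinds: 0 = mass action over at most two distinct unit-order
reactants; 1/2/3 = rate * n_i * f(n_RT) with f the free-activator,
free-repressor or complex branch of the titration QSSA evaluated at the
current repressor count (used by the feedback oscillator, whose promoter
propensities close over the protein equilibrium).
"""

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _qssa_branch(kind, at, oks, rt):
    d = at - rt - oks
    disc = np.sqrt(d * d + 4.0 * oks * at)
    if d >= 0.0:
        a = 0.5 * (d + disc)
    else:
        a = 2.0 * oks * at / (disc - d)
    if kind == 1:
        return a
    if kind == 2:
        r = a - at + rt
        return r if r > 0.0 else 0.0
    ra = at - a
    return ra if ra > 0.0 else 0.0


@njit(cache=True)
def _propensities(state, rates, reactants, kinds, qssa_at, qssa_oks,
                  qssa_rt_sp, a):
    total = 0.0
    for k in range(rates.shape[0]):
        p = rates[k]
        if kinds[k] == 0:
            i = reactants[k, 0]
            if i >= 0:
                p *= state[i]
            j = reactants[k, 1]
            if j >= 0:
                p *= state[j]
        else:
            i = reactants[k, 0]
            p *= state[i]
            if p > 0.0:
                p *= _qssa_branch(kinds[k], qssa_at, qssa_oks,
                                  float(state[qssa_rt_sp]))
        a[k] = p
        total += p
    return total


@njit(cache=True)
def ssa_grid(seed, state0, grid, rates, reactants, kinds, stoich,
             qssa_at, qssa_oks, qssa_rt_sp):
    """Simulate to grid[-1], recording the state at each grid time.

    Returns an (n_grid, n_species) int64 array; the state recorded at grid
    time g is the state just before the first event after g.
    """
    np.random.seed(seed)
    n_rxn = rates.shape[0]
    n_sp = state0.shape[0]
    n_grid = grid.shape[0]
    state = state0.copy()
    out = np.zeros((n_grid, n_sp), dtype=np.int64)
    a = np.zeros(n_rxn)
    t = 0.0
    ig = 0
    t_end = grid[n_grid - 1]
    while True:
        total = _propensities(state, rates, reactants, kinds, qssa_at,
                              qssa_oks, qssa_rt_sp, a)
        if total <= 0.0:
            t_next = t_end + 1.0
        else:
            t_next = t - np.log(np.random.random()) / total
        while ig < n_grid and grid[ig] < t_next:
            for s in range(n_sp):
                out[ig, s] = state[s]
            ig += 1
        if ig >= n_grid:
            return out
        t = t_next
        u = np.random.random() * total
        c = 0.0
        k = n_rxn - 1
        for kk in range(n_rxn):
            c += a[kk]
            if u < c:
                k = kk
                break
        for s in range(n_sp):
            state[s] += stoich[k, s]
            if state[s] < 0:
                state[s] = 0


@njit(cache=True)
def ssa_events(seed, state0, t_end, max_events, rates, reactants, kinds,
               stoich, qssa_at, qssa_oks, qssa_rt_sp):
    """Simulate recording every event; returns (times, states, n_events, final).

    ``times[0] = 0`` with the initial state; subsequent rows are post-event
    states.  Stops at t_end or when max_events is reached (the caller
    checks for truncation)."""
    np.random.seed(seed)
    n_rxn = rates.shape[0]
    n_sp = state0.shape[0]
    times = np.zeros(max_events + 1)
    states = np.zeros((max_events + 1, n_sp), dtype=np.int64)
    state = state0.copy()
    for s in range(n_sp):
        states[0, s] = state[s]
    a = np.zeros(n_rxn)
    t = 0.0
    n = 0
    while n < max_events:
        total = _propensities(state, rates, reactants, kinds, qssa_at,
                              qssa_oks, qssa_rt_sp, a)
        if total <= 0.0:
            break
        t = t - np.log(np.random.random()) / total
        if t > t_end:
            break
        u = np.random.random() * total
        c = 0.0
        k = n_rxn - 1
        for kk in range(n_rxn):
            c += a[kk]
            if u < c:
                k = kk
                break
        for s in range(n_sp):
            state[s] += stoich[k, s]
            if state[s] < 0:
                state[s] = 0
        n += 1
        times[n] = t
        for s in range(n_sp):
            states[n, s] = state[s]
    return times[:n + 1], states[:n + 1], n, state
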