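"""Numba kernels for the implicit cable integrator.

The spatial discretization is a chain of nodes (soma = node 0, axon nodes at
multiples of dx); each time step solves the backward-Euler tridiagonal system
with the Thomas algorithm, after advancing the gating variables one exact
exponential step using the pre-step voltage (staggered, semi-implicit scheme).
Sodium conductances enter the diagonal with the freshly updated m, so the
voltage solve is unconditionally stable even with τ_m = 0.1 ms.

Channel state is stored as a flat list of (set, node) entries: ``m[k]`` is the
gating variable of entry k, which contributes conductance ``ch_g[k]·m[k]`` at
node ``ch_node[k]``.  The static parts of the tridiagonal system (leak, axial
coupling, capacitive diagonal) are precomputed once per run; only the sodium
terms and the right-hand side change per step.
"""

import math

import numpy as np
from numba import njit

BLOWUP_LIMIT = 200.0  # mV; |V| beyond this aborts with a diagnostic flag


@njit(cache=True, fastmath=True)
def _gating_step(m, V, ch_node, ch_vh, ch_ka, ch_em):
    for k in range(m.size):
        v = V[ch_node[k]]
        mi = 1.0 / (1.0 + math.exp((ch_vh[k] - v) / ch_ka[k]))
        m[k] = mi + (m[k] - mi) * ch_em[k]


@njit(cache=True, fastmath=True)
def _solve_step(V, m, cdt, bstat, dstat, lower, upper, ch_node, ch_g, ch_ena,
                I_soma, clamp, Vcmd, b, d, cp, dp):
    """One backward-Euler step; V is updated in place.

    bstat = C/dt + gL + axial terms (static diagonal), dstat = gL·E_L,
    cdt = C/dt, lower/upper = −gax off-diagonals.
    """
    n = V.size
    for i in range(n):
        b[i] = bstat[i]
        d[i] = cdt[i] * V[i] + dstat[i]
    d[0] += I_soma
    for k in range(ch_g.size):
        i = ch_node[k]
        g = ch_g[k] * m[k]
        b[i] += g
        d[i] += g * ch_ena[k]
    if clamp:
        # Dirichlet row at the soma: V[0] = Vcmd exactly
        cp[0] = 0.0
        dp[0] = Vcmd
    else:
        cp[0] = upper[0] / b[0]
        dp[0] = d[0] / b[0]
    for i in range(1, n - 1):
        denom = b[i] - lower[i] * cp[i - 1]
        cp[i] = upper[i] / denom
        dp[i] = (d[i] - lower[i] * dp[i - 1]) / denom
    denom = b[n - 1] - lower[n - 1] * cp[n - 2]
    dp[n - 1] = (d[n - 1] - lower[n - 1] * dp[n - 2]) / denom
    V[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        V[i] = dp[i] - cp[i] * V[i + 1]


@njit(cache=True, fastmath=True)
def _clamp_current(V, m, gL, EL, gax, ch_node, ch_g, ch_ena):
    """Current (pA) the somatic voltage clamp must supply at this instant."""
    I = gL[0] * (V[0] - EL) + gax[0] * (V[0] - V[1])
    for k in range(ch_g.size):
        if ch_node[k] == 0:
            I -= ch_g[k] * m[k] * (ch_ena[k] - V[0])
    return I


@njit(cache=True)
def _statics(dt, C, gL, gax):
    n = C.size
    cdt = C / dt
    bstat = cdt + gL
    lower = np.zeros(n)
    upper = np.zeros(n)
    for i in range(n - 1):
        bstat[i] += gax[i]
        bstat[i + 1] += gax[i]
        lower[i + 1] = -gax[i]
        upper[i] = -gax[i]
    return cdt, bstat, lower, upper


@njit(cache=True)
def run_vclamp(V, m, dt, C, gL, EL, gax, ch_node, ch_vh, ch_ka, ch_em,
               ch_g, ch_ena, ch_set, n_sets, vcmd, record_every,
               V_rec, frac_rec, I_rec):
    """Integrate under a somatic voltage-clamp schedule, recording every
    ``record_every`` steps.  Returns 0, or 1 on numeric blow-up."""
    n = V.size
    cdt, bstat, lower, upper = _statics(dt, C, gL, gax)
    dstat = gL * EL
    b = np.empty(n); d = np.empty(n); cp = np.empty(n); dp = np.empty(n)
    g_per_set = np.zeros(n_sets)
    for k in range(ch_g.size):
        g_per_set[ch_set[k]] += ch_g[k]
    r = 0
    for t in range(vcmd.size):
        _gating_step(m, V, ch_node, ch_vh, ch_ka, ch_em)
        _solve_step(V, m, cdt, bstat, dstat, lower, upper, ch_node, ch_g,
                    ch_ena, 0.0, True, vcmd[t], b, d, cp, dp)
        if abs(V[n // 2]) > BLOWUP_LIMIT or abs(V[n - 1]) > BLOWUP_LIMIT:
            return 1
        if t % record_every == 0:
            for i in range(n):
                V_rec[r, i] = V[i]
            for s in range(n_sets):
                frac_rec[r, s] = 0.0
            for k in range(ch_g.size):
                frac_rec[r, ch_set[k]] += ch_g[k] * m[k]
            for s in range(n_sets):
                frac_rec[r, s] /= g_per_set[s]
            I_rec[r] = _clamp_current(V, m, gL, EL, gax, ch_node, ch_g, ch_ena)
            r += 1
    return 0


@njit(cache=True)
def run_to_steady(V, m, dt, C, gL, EL, gax, ch_node, ch_vh, ch_ka, ch_em,
                  ch_g, ch_ena, Vcmd, tol, sustain_steps, max_steps):
    """Hold the somatic clamp at ``Vcmd`` until max |dV/dt| over the free
    nodes stays below ``tol`` (mV/ms) for ``sustain_steps`` consecutive steps.

    Returns (steps_taken, converged, blown_up)."""
    n = V.size
    cdt, bstat, lower, upper = _statics(dt, C, gL, gax)
    dstat = gL * EL
    b = np.empty(n); d = np.empty(n); cp = np.empty(n); dp = np.empty(n)
    Vold = np.empty(n)
    quiet = 0
    for t in range(max_steps):
        for i in range(n):
            Vold[i] = V[i]
        _gating_step(m, V, ch_node, ch_vh, ch_ka, ch_em)
        _solve_step(V, m, cdt, bstat, dstat, lower, upper, ch_node, ch_g,
                    ch_ena, 0.0, True, Vcmd, b, d, cp, dp)
        maxdv = 0.0
        for i in range(1, n):
            dv = abs(V[i] - Vold[i]) / dt
            if dv > maxdv:
                maxdv = dv
        if abs(V[n - 1]) > BLOWUP_LIMIT or maxdv > 1e6:
            return t + 1, False, True
        if maxdv < tol:
            quiet += 1
            if quiet >= sustain_steps:
                return t + 1, True, False
        else:
            quiet = 0
    return max_steps, False, False


@njit(cache=True)
def run_iclamp(V, m, dt, C, gL, EL, gax, ch_node, ch_vh, ch_ka, ch_em,
               ch_g, ch_ena, ch_set, n_sets, I_inj, use_reset, threshold,
               hold_steps, record_every, rec_pos, V_rec, frac_rec,
               spike_steps, na_sum_out):
    """Integrate under somatic current clamp.

    With ``use_reset``, a spike is logged when the conductance-weighted open
    fraction first reaches ``threshold``; all compartments are then reset to
    the leak reversal and clamped there for ``hold_steps`` steps (gating keeps
    relaxing toward its resting value during the hold).

    ``na_sum_out[0]`` accumulates the total Na current (pA) summed over the
    steps outside hold windows; ``na_sum_out[1]`` counts those steps.
    Returns (n_spikes, status) with status 0 = ok, 1 = numeric blow-up.
    """
    n = V.size
    cdt, bstat, lower, upper = _statics(dt, C, gL, gax)
    dstat = gL * EL
    b = np.empty(n); d = np.empty(n); cp = np.empty(n); dp = np.empty(n)
    g_per_set = np.zeros(n_sets)
    g_all = 0.0
    for k in range(ch_g.size):
        g_per_set[ch_set[k]] += ch_g[k]
        g_all += ch_g[k]
    n_spikes = 0
    hold = 0
    r = 0
    for t in range(I_inj.size):
        if hold > 0:
            for i in range(n):
                V[i] = EL
            _gating_step(m, V, ch_node, ch_vh, ch_ka, ch_em)
            hold -= 1
        else:
            _gating_step(m, V, ch_node, ch_vh, ch_ka, ch_em)
            _solve_step(V, m, cdt, bstat, dstat, lower, upper, ch_node, ch_g,
                        ch_ena, I_inj[t], False, 0.0, b, d, cp, dp)
            if abs(V[0]) > BLOWUP_LIMIT or abs(V[n - 1]) > BLOWUP_LIMIT:
                return n_spikes, 1
            na = 0.0
            open_w = 0.0
            for k in range(ch_g.size):
                gm = ch_g[k] * m[k]
                na += gm * (ch_ena[k] - V[ch_node[k]])
                open_w += gm
            na_sum_out[0] += na
            na_sum_out[1] += 1.0
            if use_reset and g_all > 0.0 and open_w / g_all >= threshold:
                if n_spikes < spike_steps.size:
                    spike_steps[n_spikes] = t
                n_spikes += 1
                for i in range(n):
                    V[i] = EL
                hold = hold_steps
        if t % record_every == 0:
            for j in range(rec_pos.size):
                V_rec[r, j] = V[rec_pos[j]]
            for s in range(n_sets):
                frac_rec[r, s] = 0.0
            for k in range(ch_g.size):
                frac_rec[r, ch_set[k]] += ch_g[k] * m[k]
            for s in range(n_sets):
                if g_per_set[s] > 0.0:
                    frac_rec[r, s] /= g_per_set[s]
            r += 1
    return n_spikes, 0
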