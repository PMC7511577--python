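"""Numba-compiled inner loop of the cable integrator.

Semantically identical to the pure-numpy loop in :mod:`dendrocfc.simulator`
(which remains available as ``engine="numpy"`` and serves as its
cross-check); compiled here because the per-step work on ~22 compartments
is far below the size where vectorized numpy amortizes its call overhead.

tau_kind codes: 0 = constant, 1 = bell, 2 = hcn.
Returns (status, compartment, step): status 0 = ok, 1 = non-finite or
out-of-range voltage.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_kernel(
    L,  # (n, n) axial Laplacian, mS/cm^2
    v,  # (n,) initial voltage, modified in place
    x,  # (G, n) voltage-gate states
    chi,  # (n,) Ca pool
    q2,  # (n,) Ca-gated K2 gate
    vhalf, slope, gexp, tau_kind, tau_p,  # gate params; tau_p is (G, 5)
    gate_owner,  # (G,) channel index of each gate
    dens,  # (C, n) densities, mS/cm^2
    rev,  # (C,) reversals
    is_ca,  # (C,) bool: current feeds the Ca pool
    k2_chan, k2_apc, k2_amax, k2_beta, k2_exp,
    kc_chan, kc_half, ca_gain, ca_tau,
    g_leak, e_leak, cmem, dt,
    inj_idx,  # (S,) compartment index per source
    inj_cur,  # (S, n_steps + 1) current density per source
    record_every,
    v_out,  # (n_rec, n)
    h_out,  # (n_rec_h, n) or shape (0, 0)
    h_gate,  # gate row to record, or -1
    vmin, vmax,
):
    n = v.shape[0]
    G = vhalf.shape[0]
    C = dens.shape[0]
    S = inj_idx.shape[0]
    n_steps = inj_cur.shape[1] - 1
    chi_decay = -np.expm1(-dt / ca_tau)
    cmdt = cmem / dt
    A = np.empty((n, n))
    b = np.empty(n)
    g_open = np.empty((C, n))
    g_tot = np.empty(n)
    record_h = h_out.shape[0] > 0 and h_gate >= 0
    rec_i = 1
    for k in range(1, n_steps + 1):
        # gate update (exponential Euler at the pre-step voltage)
        for g in range(G):
            for i in range(n):
                xinf = 1.0 / (1.0 + np.exp((vhalf[g] - v[i]) / slope[g]))
                if tau_kind[g] == 0:
                    tau = tau_p[g, 0]
                elif tau_kind[g] == 1:
                    tau = tau_p[g, 0] + tau_p[g, 1] / (
                        np.exp((v[i] - tau_p[g, 2]) / tau_p[g, 3])
                        + np.exp(-(v[i] - tau_p[g, 2]) / tau_p[g, 4])
                    )
                else:
                    tau = tau_p[g, 0] / (
                        np.exp(-14.59 - 0.086 * v[i])
                        + np.exp(-1.87 + 0.0701 * v[i])
                    )
                x[g, i] += (xinf - x[g, i]) * (-np.expm1(-dt / tau))
        # open conductances (Ca-dependent factors lag one step)
        for c in range(C):
            for i in range(n):
                g_open[c, i] = dens[c, i]
        for g in range(G):
            c = gate_owner[g]
            e = gexp[g]
            for i in range(n):
                xx = x[g, i]
                if e == 2:
                    xx = xx * xx
                elif e == 3:
                    xx = xx * xx * xx
                elif e == 4:
                    xx = xx * xx * xx * xx
                g_open[c, i] *= xx
        if k2_chan >= 0:
            for i in range(n):
                q = q2[i]
                for _ in range(k2_exp - 1):
                    q *= q2[i]
                g_open[k2_chan, i] *= q
        if kc_chan >= 0:
            for i in range(n):
                f = chi[i] / kc_half
                if f > 1.0:
                    f = 1.0
                g_open[kc_chan, i] *= f
        # accumulate currents, update Ca pool, build the linear system
        for i in range(n):
            gt = g_leak
            ge = g_leak * e_leak
            ica = 0.0
            for c in range(C):
                gt += g_open[c, i]
                ge += g_open[c, i] * rev[c]
                if is_ca[c]:
                    ica += g_open[c, i] * (v[i] - rev[c])
            chi_inf = -ca_gain * ca_tau * ica
            if chi_inf < 0.0:
                chi_inf = 0.0
            chi[i] += (chi_inf - chi[i]) * chi_decay
            if k2_chan >= 0:
                a = k2_apc * chi[i]
                if a > k2_amax:
                    a = k2_amax
                q2[i] += (a / (a + k2_beta) - q2[i]) * (
                    -np.expm1(-dt * (a + k2_beta))
                )
            g_tot[i] = gt
            b[i] = cmdt * v[i] + ge
        for s in range(S):
            b[inj_idx[s]] += inj_cur[s, k]
        for i in range(n):
            for j in range(n):
                A[i, j] = L[i, j]
            A[i, i] += cmdt + g_tot[i]
        # Gaussian elimination without pivoting: A is strictly diagonally
        # dominant (cm/dt + g_tot on top of the Laplacian diagonal)
        for p in range(n - 1):
            for i in range(p + 1, n):
                if A[i, p] != 0.0:
                    f = A[i, p] / A[p, p]
                    for j in range(p + 1, n):
                        A[i, j] -= f * A[p, j]
                    b[i] -= f * b[p]
        for i in range(n - 1, -1, -1):
            acc = b[i]
            for j in range(i + 1, n):
                acc -= A[i, j] * v[j]
            v[i] = acc / A[i, i]
        for i in range(n):
            if not np.isfinite(v[i]) or v[i] < vmin or v[i] > vmax:
                return 1, i, k
        if k % record_every == 0:
            for i in range(n):
                v_out[rec_i, i] = v[i]
                if record_h:
                    h_out[rec_i, i] = x[h_gate, i]
            rec_i += 1
    return 0, -1, -1
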