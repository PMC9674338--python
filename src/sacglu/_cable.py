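"""Backward-Euler compartmental cable integrator (numba inner loop).

The membrane equation per compartment i,

    c_i dV_i/dt = g_leak_i (E_L − V_i) + Σ_j g_syn_j(t) (E_syn − V_i)
                  + g_ax_{i-1}(V_{i−1} − V_i) + g_ax_i (V_{i+1} − V_i) + I_inj_i,

is discretized implicitly in time (unconditionally stable for the stiff
0.54-ms synaptic conductance decay) and solved with the Thomas algorithm
on the tridiagonal system each step.  Synaptic conductances are double
exponentials maintained as two exponentially decaying state variables per
synapse that receive unit impulses at vesicle times.  A Boltzmann-
activated Ca conductance on one compartment feeds a first-order calcium
pool used as the dendritic activity readout (arbitrary units).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integrate"]


@njit(cache=True)
def _run(
    dt,
    n_steps,
    cm,          # (n,) F
    g_leak,      # (n,) S
    e_leak,      # V
    g_ax,        # (n-1,) S between i and i+1
    i_inj,       # (n,) A constant injection
    syn_comp,    # (m,) int compartment index per synapse
    syn_amp,     # (m,) S impulse amplitude (peak conductance / peak norm)
    f_decay,
    f_rise,
    e_syn,
    ev_step,     # (k,) int64 sorted event step indices
    ev_syn,      # (k,) int64 synapse index per event
    ca_comp,
    ca_gbar,
    ca_vhalf,
    ca_slope,
    ca_erev,
    ca_tau,
    ca_gain,
    record_every,
    v0,
):
    n = cm.size
    m = syn_comp.size
    v = np.full(n, v0)
    xd = np.zeros(m)
    xr = np.zeros(m)
    ca = 0.0

    n_rec = n_steps // record_every + 1
    rec_v = np.zeros((n_rec, n))
    rec_ca = np.zeros(n_rec)
    rec_v[0] = v

    sub = np.empty(n)
    diag = np.empty(n)
    sup = np.empty(n)
    rhs = np.empty(n)
    cp = np.empty(n)
    dp = np.empty(n)

    ev_ptr = 0
    k_events = ev_step.size
    ok = True

    for step in range(1, n_steps + 1):
        # synaptic gating states (exact exponential update + impulses)
        for j in range(m):
            xd[j] *= f_decay
            xr[j] *= f_rise
        while ev_ptr < k_events and ev_step[ev_ptr] <= step:
            j = ev_syn[ev_ptr]
            xd[j] += 1.0
            xr[j] += 1.0
            ev_ptr += 1

        for i in range(n):
            diag[i] = cm[i] / dt + g_leak[i]
            rhs[i] = cm[i] / dt * v[i] + g_leak[i] * e_leak + i_inj[i]
            sub[i] = 0.0
            sup[i] = 0.0
        for i in range(n - 1):
            diag[i] += g_ax[i]
            diag[i + 1] += g_ax[i]
            sup[i] = -g_ax[i]
            sub[i + 1] = -g_ax[i]
        for j in range(m):
            g = syn_amp[j] * (xd[j] - xr[j])
            diag[syn_comp[j]] += g
            rhs[syn_comp[j]] += g * e_syn

        # Thomas algorithm
        cp[0] = sup[0] / diag[0]
        dp[0] = rhs[0] / diag[0]
        for i in range(1, n):
            denom = diag[i] - sub[i] * cp[i - 1]
            cp[i] = sup[i] / denom
            dp[i] = (rhs[i] - sub[i] * dp[i - 1]) / denom
        v[n - 1] = dp[n - 1]
        for i in range(n - 2, -1, -1):
            v[i] = dp[i] - cp[i] * v[i + 1]

        if not np.isfinite(v[0]):
            ok = False
            break

        # Ca readout (voltage-gated, instantaneous activation; no feedback)
        vt = v[ca_comp]
        gca = ca_gbar / (1.0 + np.exp(-(vt - ca_vhalf) / ca_slope))
        influx = gca * (ca_erev - vt)  # ≥ 0 below reversal
        if influx < 0.0:
            influx = 0.0
        ca += dt * (ca_gain * influx - ca / ca_tau)

        if step % record_every == 0:
            r = step // record_every
            rec_v[r] = v
            rec_ca[r] = ca

    return rec_v, rec_ca, ok


def integrate(
    dt: float,
    n_steps: int,
    cm: np.ndarray,
    g_leak: np.ndarray,
    e_leak: float,
    g_ax: np.ndarray,
    i_inj: np.ndarray,
    syn_comp: np.ndarray,
    syn_amp: np.ndarray,
    tau_decay: float,
    tau_rise: float,
    e_syn: float,
    ev_step: np.ndarray,
    ev_syn: np.ndarray,
    ca_comp: int,
    ca_gbar: float,
    ca_vhalf: float,
    ca_slope: float,
    ca_erev: float,
    ca_tau: float,
    ca_gain: float,
    record_every: int,
    v0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the integrator; raises on numerical divergence."""
    rec_v, rec_ca, ok = _run(
        float(dt),
        int(n_steps),
        np.ascontiguousarray(cm, float),
        np.ascontiguousarray(g_leak, float),
        float(e_leak),
        np.ascontiguousarray(g_ax, float),
        np.ascontiguousarray(i_inj, float),
        np.ascontiguousarray(syn_comp, np.int64),
        np.ascontiguousarray(syn_amp, float),
        float(np.exp(-dt / tau_decay)),
        float(np.exp(-dt / tau_rise)),
        float(e_syn),
        np.ascontiguousarray(ev_step, np.int64),
        np.ascontiguousarray(ev_syn, np.int64),
        int(ca_comp),
        float(ca_gbar),
        float(ca_vhalf),
        float(ca_slope),
        float(ca_erev),
        float(ca_tau),
        float(ca_gain),
        int(record_every),
        float(v0),
    )
    if not ok:
        raise FloatingPointError(
            f"cable solver diverged (NaN/inf) at time step dt={dt:g} s; reduce the step"
        )
    return rec_v, rec_ca
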