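"""Conductance-based (cortical Hodgkin-Huxley) network simulation with Q10
temperature scaling.

The membrane equation per cell is

    Cm dV/dt = -I_ion(V) - I_syn(V)

with ionic currents leak + fast K (n^4) + slow M-type K (q) + Na (m^3 h), and
synaptic input through conductances gated by the presynaptic activations
``s`` of the same form as the LNP model.  Recurrent weights are the LNP
weight magnitudes rescaled by ``eta_scale`` and act as conductances toward
the excitatory (0 mV) or inhibitory (-80 mV) reversal.  A constant bias I0
depolarizes the cells (sign convention documented in the methods note: read
with the overall minus of the membrane equation, the bias enters I_syn
negatively so that a positive I0 drives the cells toward threshold).

Temperature enters through Q10 factors: conductance amplitudes (ionic g-bars
and synaptic weights) scale as Q10a^((T-T0)/10) and time constants (gate taus
and tau_syn) shrink as 1/Q10tau^((T-T0)/10), with T0 = 36 C.  Cooling can be
applied to the ionic group only, the synaptic group only, or both, to
dissociate their opposing effects on the population pattern period.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from . import chh_kinetics as kin
from .lnp_sim import PopulationActivity, SpikeRecord, Trajectory, pop_slices, PREFERRED_DIRECTION
from .net_core import POPULATIONS, NetworkConfig, WeightMatrix, envelope

__all__ = ["CHHParams", "ionic_current", "synaptic_current", "q10_scale", "run_chh",
           "rates_from_spikes"]


@dataclass(frozen=True)
class CHHParams:
    """Biophysical parameters of the regular-spiking cortical neuron.

    Units: Cm uF/cm^2, conductances mS/cm^2, voltages mV, I0 uA/cm^2.
    """

    Cm: float = 1.0
    gbar_L: float = 0.1
    gbar_K: float = 5.0
    gbar_M: float = 0.07
    gbar_Na: float = 50.0
    Vbar_L: float = -70.0
    Vbar_K: float = -90.0
    Vbar_Na: float = 50.0
    Vbar_E: float = 0.0
    Vbar_I: float = -80.0
    I0: float = 3.0
    T0: float = 36.0
    Q10a: float = 1.3
    Q10tau: float = 3.0
    eta_scale: float = 0.0015
    # scale factors applied by q10_scale (1.0 at T = T0)
    phi_g_ionic: float = 1.0
    phi_tau_ionic: float = 1.0
    phi_g_syn: float = 1.0
    phi_tau_syn: float = 1.0

    def __post_init__(self) -> None:
        if min(self.gbar_L, self.gbar_K, self.gbar_M, self.gbar_Na) < 0:
            raise ValueError("conductances must be non-negative")
        if self.Q10a <= 1 or self.Q10tau <= 1:
            raise ValueError("Q10 factors must exceed 1")


def ionic_current(V, n, m, h, q, params: CHHParams):
    """Sum of leak, fast-K, M-type-K and Na currents (uA/cm^2).

    Conductance amplitudes carry the ionic Q10 factor.
    """
    p = params
    g = p.phi_g_ionic
    V = np.asarray(V, dtype=float)
    return (
        g * p.gbar_L * (V - p.Vbar_L)
        + g * p.gbar_K * np.asarray(n) ** 4 * (V - p.Vbar_K)
        + g * p.gbar_M * np.asarray(q) * (V - p.Vbar_K)
        + g * p.gbar_Na * np.asarray(m) ** 3 * np.asarray(h) * (V - p.Vbar_Na)
    )


def synaptic_current(V, g_exc, g_inh, alpha_vel, A, params: CHHParams):
    """Synaptic current alpha_vel * [g_E (V - Vbar_E) + g_I (V - Vbar_I) - I0] * A.

    ``g_exc``/``g_inh`` are the summed recurrent conductances from excitatory
    and inhibitory sources (already weight-scaled); the constant bias I0
    enters with a negative sign so that, under the membrane equation's
    overall minus, it depolarizes.
    """
    p = params
    V = np.asarray(V, dtype=float)
    return np.asarray(alpha_vel) * (
        g_exc * (V - p.Vbar_E) + g_inh * (V - p.Vbar_I) - p.I0
    ) * np.asarray(A)


def q10_scale(params: CHHParams, T: float, mode: str = "all") -> CHHParams:
    """Return parameters rescaled to temperature T (C).

    Amplitudes pick up Q10a^((T-T0)/10); time constants are divided by
    Q10tau^((T-T0)/10).  ``mode`` selects the ionic group (g-bars and gate
    taus), the synaptic group (weights and tau_syn), or both.
    """
    if not 15.0 <= T <= 45.0:
        raise ValueError("temperature outside the supported physiological range")
    if mode not in ("all", "ionic_only", "synaptic_only"):
        raise ValueError(f"unknown q10 mode {mode!r}")
    phi_g = params.Q10a ** ((T - params.T0) / 10.0)
    phi_tau = params.Q10tau ** ((T - params.T0) / 10.0)
    ionic = mode in ("all", "ionic_only")
    syn = mode in ("all", "synaptic_only")
    return replace(
        params,
        phi_g_ionic=phi_g if ionic else 1.0,
        phi_tau_ionic=phi_tau if ionic else 1.0,
        phi_g_syn=phi_g if syn else 1.0,
        phi_tau_syn=phi_tau if syn else 1.0,
    )


@njit(cache=True)
def _chh_loop(W_E, W_I, A, popidx, alpha_pop, dt, n_steps,
              Cm, gL, gK, gM, gNa, VL, VK, VNa, VE, VI, I0,
              V_T, tau_max_q, phi_tau_ionic, tau_syn,
              v0, m0, h0, n0, q0, spike_cap):
    n = W_E.shape[0]
    V = np.full(n, v0)
    m = np.full(n, m0)
    h = np.full(n, h0)
    ng = np.full(n, n0)
    q = np.full(n, q0)
    sE = np.zeros(W_E.shape[1])
    sI = np.zeros(W_I.shape[1])
    n_exc = W_E.shape[1]
    spike_cells = np.empty(spike_cap, dtype=np.int32)
    spike_steps = np.empty(spike_cap, dtype=np.int64)
    n_spikes = 0
    ok = True
    gate_ok = True
    decay = 1.0 - dt / tau_syn
    for k in range(n_steps):
        gE = np.dot(W_E, sE)
        gI = np.dot(W_I, sI)
        sE *= decay
        sI *= decay
        for i in range(n):
            v = V[i]
            a = alpha_pop[k, popidx[i]]
            I_ion = (gL * (v - VL) + gK * ng[i] ** 4 * (v - VK)
                     + gM * q[i] * (v - VK) + gNa * m[i] ** 3 * h[i] * (v - VNa))
            I_syn = a * (gE[i] * (v - VE) + gI[i] * (v - VI) - I0) * A[i]
            v_new = v + dt * (-I_ion - I_syn) / Cm
            # Na/K alpha-beta rates (1/ms), scaled by the ionic tau factor
            u = v - V_T - 13.0
            am = 0.32 * (-u / (np.expm1(-u / 4.0))) if abs(u) > 1e-6 else 0.32 * 4.0
            u = v - V_T - 40.0
            bm = 0.28 * (u / np.expm1(u / 5.0)) if abs(u) > 1e-6 else 0.28 * 5.0
            ah = 0.128 * np.exp(-(v - V_T - 17.0) / 18.0)
            bh = 4.0 / (1.0 + np.exp(-(v - V_T - 40.0) / 5.0))
            u = v - V_T - 15.0
            an = 0.032 * (-u / np.expm1(-u / 5.0)) if abs(u) > 1e-6 else 0.032 * 5.0
            bn = 0.5 * np.exp(-(v - V_T - 10.0) / 40.0)
            qi = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
            tq = tau_max_q / (3.3 * np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0))
            f = phi_tau_ionic  # rates multiplied = taus divided
            m[i] += dt * f * (am * (1.0 - m[i]) - bm * m[i])
            h[i] += dt * f * (ah * (1.0 - h[i]) - bh * h[i])
            ng[i] += dt * f * (an * (1.0 - ng[i]) - bn * ng[i])
            q[i] += dt * f * (qi - q[i]) / tq
            if m[i] < 0.0 or m[i] > 1.0 or h[i] < 0.0 or h[i] > 1.0 or \
               ng[i] < 0.0 or ng[i] > 1.0 or q[i] < 0.0 or q[i] > 1.0:
                gate_ok = False
                m[i] = min(max(m[i], 0.0), 1.0)
                h[i] = min(max(h[i], 0.0), 1.0)
                ng[i] = min(max(ng[i], 0.0), 1.0)
                q[i] = min(max(q[i], 0.0), 1.0)
            if v < 0.0 <= v_new:  # upward 0 mV crossing = spike
                if i < n_exc:
                    sE[i] += 1.0
                else:
                    sI[i - n_exc] += 1.0
                if n_spikes < spike_cap:
                    spike_cells[n_spikes] = i
                    spike_steps[n_spikes] = k
                    n_spikes += 1
            V[i] = v_new
            if not np.isfinite(v_new) or abs(v_new) > 500.0:
                ok = False
        if not ok:
            break
    return spike_cells[:n_spikes], spike_steps[:n_spikes], V, ok, gate_ok


def rates_from_spikes(record: SpikeRecord, duration_ms: float, bin_ms: float = 10.0,
                      smooth_ms: float = 50.0) -> PopulationActivity:
    """Population rate frames from spikes: binned counts, boxcar-smoothed.

    Counts per (cell, bin) are converted to spikes/s and smoothed in time
    with a boxcar of width ``smooth_ms``.
    """
    from scipy.ndimage import uniform_filter1d

    n_bins = int(np.ceil(duration_ms / bin_ms))
    counts = np.zeros((n_bins, record.n_cells), dtype=np.float32)
    bins = np.minimum((record.times / bin_ms).astype(int), n_bins - 1)
    np.add.at(counts, (bins, record.cell_ids), 1.0)
    rates = counts * (1000.0 / bin_ms)
    width = max(1, int(round(smooth_ms / bin_ms)))
    rates = uniform_filter1d(rates, size=width, axis=0, mode="nearest")
    frame_times = (np.arange(n_bins) + 0.5) * bin_ms
    return PopulationActivity(rates, frame_times, record.pop_slices)


def run_chh(
    config: NetworkConfig,
    weights: WeightMatrix,
    trajectory: Trajectory,
    T: float = 36.0,
    mode: str = "all",
    params: CHHParams | None = None,
) -> tuple[SpikeRecord, PopulationActivity]:
    """Simulate the CHH network at temperature T along a trajectory.

    The base weights are copied and rescaled (eta_scale, synaptic Q10 factor,
    gamma_inh on inhibitory sources); the base WeightMatrix is never mutated.
    Spikes are detected at upward 0 mV crossings; population activity frames
    are formed from 10 ms spike-count bins smoothed with a 50 ms boxcar.
    """
    p = q10_scale(params or CHHParams(), T, mode)
    sl = pop_slices(config)
    n = sl["I"].stop
    n_exc = sl["ER"].stop
    # conductance blocks: unsigned magnitudes, eta-rescaled, thermal + inhibitory gain
    Wc = weights.combined(config, signed=False) * p.eta_scale * p.phi_g_syn
    Wc[:, sl["I"]] *= weights.gamma_inh
    W_E = np.ascontiguousarray(Wc[:, :n_exc])
    W_I = np.ascontiguousarray(Wc[:, n_exc:])
    A = np.ones(n)
    popidx = np.zeros(n, dtype=np.int8)
    for k, pop in enumerate(POPULATIONS):
        A[sl[pop]] = envelope(config, pop)
        popidx[sl[pop]] = k
    e_y = np.array([PREFERRED_DIRECTION[pop] for pop in POPULATIONS])
    alpha_pop = 1.0 + config.beta_vel * trajectory.v[:, None] * e_y[None, :]
    n_steps = len(trajectory.t)
    dt = trajectory.dt
    v0 = -70.0
    m0, h0, n0, q0 = kin.steady_state(v0)
    tau_syn = config.tau_syn / p.phi_tau_syn
    duration_ms = n_steps * dt
    spike_cap = max(1_000_000, int(n * duration_ms / 1000.0 * 200))
    sp_cells, sp_steps, V_final, ok, gate_ok = _chh_loop(
        W_E, W_I, A, popidx, alpha_pop, dt, n_steps,
        p.Cm, p.phi_g_ionic * p.gbar_L, p.phi_g_ionic * p.gbar_K,
        p.phi_g_ionic * p.gbar_M, p.phi_g_ionic * p.gbar_Na,
        p.Vbar_L, p.Vbar_K, p.Vbar_Na, p.Vbar_E, p.Vbar_I, p.I0,
        kin.V_T, kin.TAU_MAX_Q, p.phi_tau_ionic, tau_syn,
        v0, m0, h0, n0, q0, spike_cap,
    )
    if not ok:
        raise FloatingPointError("CHH simulation diverged (non-finite membrane voltage)")
    times = sp_steps * dt
    positions = trajectory.x[sp_steps] if len(sp_steps) else np.empty(0)
    record = SpikeRecord(sp_cells, times, positions, n, sl)
    record.gates_in_bounds = bool(gate_ok)
    activity = rates_from_spikes(record, duration_ms)
    return record, activity
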