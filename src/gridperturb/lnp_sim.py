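"""Linear-nonlinear-Poisson (sub-Poisson) spiking network simulation.

Each cell carries an instantaneous rate ``r = f(G)`` where ``f`` is
threshold-linear and ``G`` sums recurrent input, a constant bias and a
velocity-dependent gain.  Spikes are drawn from a gamma-renewal process of
order 4 via time rescaling, which yields an inter-spike-interval coefficient
of variation of 0.5 at constant rate.  Spikes drive exponentially decaying
synaptic activations ``s`` (time constant ``tau_syn``) that feed back through
the recurrent weights.  Integration is forward Euler with time step ``dt``
(0.5 ms default).

The velocity drive comes from a 1D trajectory: each excitatory population has
a preferred direction (ER rightward, EL leftward) and receives the gain
``1 + beta_vel * v`` along it; the inhibitory population is unmodulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .net_core import POPULATIONS, NetworkConfig, WeightMatrix, envelope

__all__ = [
    "Trajectory",
    "SpikeRecord",
    "PopulationActivity",
    "GammaRenewalSampler",
    "transfer",
    "velocity_modulation",
    "total_input",
    "synapse_step",
    "make_trajectory",
    "run_lnp",
]

TRACK_LENGTH_CM = 400.0
_RENEWAL_ORDER = 4  # gamma order k: ISI CV = 1/sqrt(k) = 0.5

# Preferred directions e_P = (0, e_y): I unmodulated, ER rightward, EL leftward.
PREFERRED_DIRECTION = {"EL": -1.0, "ER": +1.0, "I": 0.0}


@dataclass
class Trajectory:
    """Uniformly sampled 1D trajectory: time (ms), position (cm), velocity (m/s)."""

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    track_length: float = TRACK_LENGTH_CM

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.x) == len(self.v)):
            raise ValueError("t, x, v must have equal length")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def occupancy(self, bin_cm: float = 1.0) -> np.ndarray:
        """Time spent (s) in each spatial bin."""
        edges = np.arange(0.0, self.track_length + bin_cm, bin_cm)
        counts, _ = np.histogram(self.x, bins=edges)
        return counts * self.dt / 1000.0


class SpikeRecord:
    """Per-cell spike times (ms) and positions (cm) for one simulation run."""

    def __init__(self, cell_ids, times, positions, n_cells, pop_slices=None):
        order = np.lexsort((times, cell_ids))
        self.cell_ids = np.asarray(cell_ids)[order]
        self.times = np.asarray(times, dtype=float)[order]
        self.positions = np.asarray(positions, dtype=float)[order]
        self.n_cells = int(n_cells)
        self.pop_slices = pop_slices or {}

    def __len__(self) -> int:
        return len(self.times)

    def for_cell(self, cell: int) -> tuple[np.ndarray, np.ndarray]:
        m = self.cell_ids == cell
        return self.times[m], self.positions[m]

    def cells_of(self, pop: str) -> range:
        sl = self.pop_slices[pop]
        return range(sl.start, sl.stop)

    def to_text(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.cell_ids, self.times, self.positions]),
            fmt=["%d", "%.3f", "%.4f"],
            delimiter="\t",
            header="cell_id\tt_ms\tx_cm",
        )

    @classmethod
    def from_text(cls, path, n_cells=None):
        data = np.loadtxt(path, ndmin=2)
        ids = data[:, 0].astype(int)
        n = n_cells if n_cells is not None else (ids.max() + 1 if len(ids) else 0)
        return cls(ids, data[:, 1], data[:, 2], n)


@dataclass
class PopulationActivity:
    """Rate snapshots (frames x cells) with frame times (ms) and population slices."""

    frames: np.ndarray
    frame_times: np.ndarray
    pop_slices: dict

    def population_frames(self, pop: str) -> np.ndarray:
        return self.frames[:, self.pop_slices[pop]]

    def save_npz(self, path) -> None:
        np.savez(
            path,
            frames=self.frames,
            frame_times=self.frame_times,
            pops=np.array(
                [(p, s.start, s.stop) for p, s in self.pop_slices.items()], dtype=object
            ),
        )


def transfer(x):
    """Threshold-linear transfer f(x) = x for x > 0, else 0."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def velocity_modulation(v, e_y: float, beta_vel: float):
    """Velocity gain ``alpha = 1 + beta_vel * (v . e_P)`` for a 1D trajectory."""
    return 1.0 + beta_vel * np.asarray(v, dtype=float) * e_y


def pop_slices(config: NetworkConfig) -> dict:
    sizes = [config.n_pop[p] for p in POPULATIONS]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    return {p: slice(int(offs[k]), int(offs[k + 1])) for k, p in enumerate(POPULATIONS)}


def _cellwise(config: NetworkConfig):
    """Per-cell envelope, bias G0' and population index over [EL, ER, I]."""
    sl = pop_slices(config)
    n = sl["I"].stop
    A = np.ones(n)
    g0p = np.zeros(n)
    popidx = np.zeros(n, dtype=np.int8)
    for k, p in enumerate(POPULATIONS):
        A[sl[p]] = envelope(config, p)
        g0p[sl[p]] = config.G0p[p]
        popidx[sl[p]] = k
    return A, g0p, popidx


def total_input(s, weights: WeightMatrix, config: NetworkConfig, v: float,
                mode: str = "multiplicative"):
    """Summed input G per cell given synaptic activations ``s`` and velocity ``v``.

    multiplicative: ``[alpha_vel * (G_rec + G0) + G0'] * A``;
    additive:       ``[W_vel * alpha_vel + G_rec + G0 + G0'] * A``.
    """
    W = weights.combined(config, signed=True)
    if W.shape[1] != len(s):
        raise ValueError("state vector length does not match weight matrix")
    g_rec = W @ np.asarray(s, dtype=float)
    A, g0p, popidx = _cellwise(config)
    e_y = np.array([PREFERRED_DIRECTION[p] for p in POPULATIONS])
    alpha = velocity_modulation(v, e_y, config.beta_vel)[popidx]
    if mode == "multiplicative":
        return (alpha * (g_rec + config.G0) + g0p) * A
    if mode == "additive":
        return (config.W_vel * alpha + g_rec + config.G0 + g0p) * A
    raise ValueError(f"unknown velocity mode {mode!r}")


def synapse_step(s, spike_indicator, tau_syn: float, dt: float):
    """One Euler step of the synaptic activation: decay plus unit spike increments."""
    import warnings

    if dt >= tau_syn:
        warnings.warn("dt >= tau_syn: synaptic integration unstable", stacklevel=2)
    return np.asarray(s) * (1.0 - dt / tau_syn) + np.asarray(spike_indicator)


class GammaRenewalSampler:
    """Sub-Poisson spike generation by time-rescaling a gamma renewal process.

    The integrated rate (hazard) is accumulated per cell; a spike is emitted
    each time it crosses a threshold drawn from Gamma(order, 1/order), whose
    unit mean preserves the requested rate and whose shape sets
    CV = 1/sqrt(order).
    """

    def __init__(self, n_cells: int, rng: np.random.Generator, order: int = _RENEWAL_ORDER):
        self.order = order
        self.rng = rng
        self.hazard = np.zeros(n_cells)
        self.threshold = rng.gamma(order, 1.0 / order, size=n_cells)

    def step(self, rates, dt_s: float) -> np.ndarray:
        """Advance by dt (s) at the given rates (spikes/s); return spike indicator."""
        self.hazard += np.asarray(rates) * dt_s
        spiking = self.hazard >= self.threshold
        if np.any(spiking):
            self.hazard[spiking] -= self.threshold[spiking]
            self.threshold[spiking] = self.rng.gamma(
                self.order, 1.0 / self.order, size=int(spiking.sum())
            )
        return spiking


def spike_sample(rate, dt_s, sampler: GammaRenewalSampler):
    """Draw one step of renewal spiking (thin wrapper over the sampler)."""
    return sampler.step(rate, dt_s)


def make_trajectory(
    duration_s: float,
    kind: str = "quasi_random",
    v0: float = 0.25,
    seed: int = 0,
    dt_ms: float = 0.5,
    track_length: float = TRACK_LENGTH_CM,
) -> Trajectory:
    """Seeded 1D trajectory on a linear track.

    ``quasi_random`` runs full-track sweeps at per-sweep random base speeds
    (uniform 0.15-0.45 m/s) with Ornstein-Uhlenbeck jitter, speed clipped to
    [0.1, 0.5] m/s; alternating sweeps keep occupancy near-uniform.
    ``constant_velocity`` holds v = v0; position wraps periodically so the
    velocity input never changes sign.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * 1000.0 / dt_ms))
    t = np.arange(n) * dt_ms
    dt_s = dt_ms / 1000.0
    if kind == "constant_velocity":
        x = (v0 * 100.0 * t / 1000.0) % track_length
        return Trajectory(t, x, np.full(n, float(v0)), track_length)
    if kind != "quasi_random":
        raise ValueError(f"unknown trajectory kind {kind!r}")

    rng = np.random.default_rng(seed)
    x = np.empty(n)
    v = np.empty(n)
    pos = 0.0
    direction = 1.0
    base = rng.uniform(0.15, 0.45)
    jitter = 0.0
    tau_ou = 0.5  # s
    sigma_ou = 0.08
    for k in range(n):
        jitter += (-jitter / tau_ou) * dt_s + sigma_ou * np.sqrt(dt_s) * rng.standard_normal()
        speed = min(max(base + jitter, 0.1), 0.5)
        vk = direction * speed
        pos += vk * 100.0 * dt_s
        if pos >= track_length:
            pos = track_length - (pos - track_length)
            direction = -1.0
            base = rng.uniform(0.15, 0.45)
        elif pos <= 0.0:
            pos = -pos
            direction = 1.0
            base = rng.uniform(0.15, 0.45)
        x[k] = pos
        v[k] = vk
    return Trajectory(t, x, v, track_length)


@njit(cache=True)
def _lnp_loop(W, A, g0p, popidx, alpha_pop, G0, Wvel, additive, dt_ms, tau_syn,
              frame_every, max_frames, seed, spike_cap, s0, n_exc, split):
    np.random.seed(seed)
    n_steps = alpha_pop.shape[0]
    n = W.shape[0]
    dt_s = dt_ms / 1000.0
    s = s0.copy()
    hazard = np.zeros(n)
    thresh = np.empty(n)
    # E targets receive only I-source input unless E-E blocks are present
    W_exc_rows = np.ascontiguousarray(W[:n_exc, n_exc:])
    W_inh_rows = np.ascontiguousarray(W[n_exc:, :])
    for i in range(n):
        thresh[i] = np.random.gamma(4.0) * 0.25
    frames = np.zeros((max_frames, n), dtype=np.float32)
    frame_steps = np.full(max_frames, -1, dtype=np.int64)
    spike_cells = np.empty(spike_cap, dtype=np.int32)
    spike_steps = np.empty(spike_cap, dtype=np.int64)
    n_spikes = 0
    ok = True
    g_rec = np.empty(n)
    for k in range(n_steps):
        if split:
            g_rec[:n_exc] = np.dot(W_exc_rows, s[n_exc:])
            g_rec[n_exc:] = np.dot(W_inh_rows, s)
        else:
            g_rec = np.dot(W, s)
        G = np.empty(n)
        for i in range(n):
            a = alpha_pop[k, popidx[i]]
            if additive:
                G[i] = (Wvel * a + g_rec[i] + G0 + g0p[i]) * A[i]
            else:
                G[i] = (a * (g_rec[i] + G0) + g0p[i]) * A[i]
        decay = 1.0 - dt_ms / tau_syn
        for i in range(n):
            r = G[i] if G[i] > 0.0 else 0.0
            hazard[i] += r * dt_s
            s[i] *= decay
            if hazard[i] >= thresh[i]:
                hazard[i] -= thresh[i]
                thresh[i] = np.random.gamma(4.0) * 0.25
                s[i] += 1.0
                if n_spikes < spike_cap:
                    spike_cells[n_spikes] = i
                    spike_steps[n_spikes] = k
                    n_spikes += 1
        if k % frame_every == 0:
            fi = (k // frame_every) % max_frames
            fmax = 0.0
            for i in range(n):
                frames[fi, i] = G[i] if G[i] > 0.0 else 0.0
                if frames[fi, i] > fmax:
                    fmax = frames[fi, i]
            frame_steps[fi] = k
            if not np.isfinite(fmax) or fmax > 1e9:
                ok = False
                break
    return frames, frame_steps, spike_cells[:n_spikes], spike_steps[:n_spikes], ok, s


def run_lnp(
    config: NetworkConfig,
    weights: WeightMatrix,
    trajectory: Trajectory,
    seed: int = 0,
    mode: str = "multiplicative",
    frame_every: int = 1,
    max_frames: int = 10000,
    record_spikes: bool = True,
    s_init: np.ndarray | None = None,
) -> tuple[SpikeRecord, PopulationActivity]:
    """Simulate the LNP network along a trajectory.

    Rate frames are recorded every ``frame_every`` steps into a ring buffer
    holding the last ``max_frames`` frames (measurements average over the
    final 10000 snapshots).  ``s_init`` warm-starts the synaptic activations
    (e.g. from a previous run's final state, mimicking a perturbation applied
    to an ongoing network).  Fully reproducible for a given seed.  The final
    synaptic state is stored on the returned record (``final_state``).
    """
    if mode not in ("multiplicative", "additive"):
        raise ValueError(f"unknown velocity mode {mode!r}")
    W = weights.combined(config, signed=True)
    A, g0p, popidx = _cellwise(config)
    n = W.shape[0]
    e_y = np.array([PREFERRED_DIRECTION[p] for p in POPULATIONS])
    alpha_pop = 1.0 + config.beta_vel * trajectory.v[:, None] * e_y[None, :]
    n_steps = len(trajectory.t)
    # generous bound: 250 Hz sustained across all cells
    spike_cap = max(1_000_000, int(n * n_steps * config.dt / 1000.0 * 250))
    if not record_spikes:
        spike_cap = 1
    s0 = np.zeros(n) if s_init is None else np.asarray(s_init, dtype=float)
    if len(s0) != n:
        raise ValueError("s_init length does not match the network size")
    n_exc = config.N_EL + config.N_ER
    frames, frame_steps, sp_cells, sp_steps, ok, s_final = _lnp_loop(
        W, A, g0p, popidx, alpha_pop, config.G0, config.W_vel,
        mode == "additive", config.dt, config.tau_syn,
        frame_every, max_frames, int(seed) % (2**31 - 1), spike_cap,
        s0, n_exc, not config.ee_variant,
    )
    if not ok:
        raise FloatingPointError("LNP simulation diverged (non-finite or huge rates)")
    # unwrap the frame ring buffer into chronological order
    valid = frame_steps >= 0
    order = np.argsort(frame_steps[valid])
    frames = frames[valid][order]
    frame_times = frame_steps[valid][order] * config.dt
    sl = pop_slices(config)
    activity = PopulationActivity(frames, frame_times, sl)
    times = sp_steps * config.dt
    positions = trajectory.x[sp_steps] if len(sp_steps) else np.empty(0)
    record = SpikeRecord(sp_cells, times, positions, n, sl)
    record.final_state = s_final
    return record, activity
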