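"""Spatial-tuning and population-pattern measurements.

Spatial tuning curves are occupancy-normalized spike histograms (1 cm bins,
5-bin boxcar smoothing).  Tuning period is the wavelength of the dominant
nonzero-frequency peak of the curve's power spectrum; tuning amplitude is the
mean rate density over bins.  Population period and gridness come from the
power spectrum of normalized population-activity snapshots restricted to the
middle half of the population vector, with the spectrum rescaled by 2/L^2 so
a pure sinusoid scores 1.  The velocity response is the translation speed of
the population pattern under fixed velocity input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .lnp_sim import PopulationActivity, Trajectory, make_trajectory, run_lnp
from .net_core import NetworkConfig, WeightMatrix

__all__ = [
    "TuningCurve",
    "SpectrumStats",
    "tuning_curve",
    "tuning_period",
    "tuning_amplitude",
    "relative_change",
    "population_spectrum_stats",
    "velocity_response",
    "included_cells",
    "spectrum_peak",
]

BIN_CM = 1.0
BOXCAR_BINS = 5


@dataclass
class TuningCurve:
    """Occupancy-normalized, smoothed spatial firing-rate profile."""

    bin_edges: np.ndarray        # cm
    rate: np.ndarray             # spikes/s per bin (smoothed)
    visited: np.ndarray          # occupancy > 0 per bin
    smoothing: int = BOXCAR_BINS
    interpolated: bool = False   # True if unvisited bins were filled in

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_text(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.bin_centers, self.rate, self.visited]),
            delimiter="\t",
            header="x_cm\trate_hz\tvisited",
        )


@dataclass
class SpectrumStats:
    """Dominant wavelength and rescaled peak power of a 1D pattern."""

    period: float               # bins (or neurons)
    power: float                # rescaled peak power; 1 for a pure sinusoid
    spectrum: np.ndarray = field(default=None, repr=False)
    L: int = 0


def tuning_curve(
    spike_positions: np.ndarray,
    trajectory: Trajectory,
    bin_cm: float = BIN_CM,
    smooth_bins: int = BOXCAR_BINS,
) -> TuningCurve:
    """Occupancy-normalized spatial tuning curve of one cell.

    Unvisited bins are filled by linear interpolation before smoothing and
    flagged (``visited`` mask, ``interpolated``).
    """
    edges = np.arange(0.0, trajectory.track_length + bin_cm, bin_cm)
    occupancy = trajectory.occupancy(bin_cm)
    counts, _ = np.histogram(spike_positions, bins=edges)
    visited = occupancy > 0
    rate = np.zeros(len(counts))
    rate[visited] = counts[visited] / occupancy[visited]
    interpolated = False
    if not visited.all():
        interpolated = True
        if visited.any():
            idx = np.arange(len(rate))
            rate[~visited] = np.interp(idx[~visited], idx[visited], rate[visited])
    smoothed = uniform_filter1d(rate, size=smooth_bins, mode="nearest")
    return TuningCurve(edges, smoothed, visited, smooth_bins, interpolated)


def spectrum_peak(vec: np.ndarray, refine: bool = True) -> tuple[float, float, np.ndarray]:
    """Dominant nonzero frequency of a real vector.

    Returns (wavelength in samples, rescaled peak power, power spectrum).
    The power spectrum of the normalized (mean-subtracted, SD-divided) vector
    is rescaled by 2/L^2; the peak bin's power is reported unrefined, while
    the wavelength is refined by parabolic interpolation of log-power around
    the peak (frequencies remain those of the unpadded DFT grid).
    """
    v = np.asarray(vec, dtype=float)
    L = len(v)
    sd = v.std()
    if sd == 0 or not np.isfinite(sd):
        return np.nan, 0.0, np.zeros(L // 2 + 1)
    v = (v - v.mean()) / sd
    power = np.abs(np.fft.rfft(v)) ** 2 * (2.0 / L**2)
    if len(power) < 2:
        return np.nan, 0.0, power
    k = 1 + int(np.argmax(power[1:]))
    peak_power = float(power[k])
    freq = k / L
    if refine and 1 < k < len(power) - 1:
        lp = np.log(power[k - 1 : k + 2] + 1e-300)
        denom = lp[0] - 2 * lp[1] + lp[2]
        if denom < 0:
            shift = 0.5 * (lp[0] - lp[2]) / denom
            freq = (k + np.clip(shift, -0.5, 0.5)) / L
    return float(1.0 / freq), peak_power, power


def tuning_period(curve: TuningCurve) -> float:
    """Wavelength (cm) of the dominant spatial frequency; NaN for flat curves."""
    wavelength, _, _ = spectrum_peak(curve.rate)
    if np.isnan(wavelength):
        return np.nan
    bin_cm = curve.bin_edges[1] - curve.bin_edges[0]
    return wavelength * bin_cm


def tuning_amplitude(curve: TuningCurve) -> float:
    """Mean spike-rate density across bins of the smoothed curve."""
    return float(np.mean(curve.rate))


def relative_change(pre: float, post: float) -> float:
    """|post/pre - 1|: fractional change of a period or amplitude."""
    if pre == 0:
        raise ValueError("pre-perturbation value must be nonzero")
    return abs(post / pre - 1.0)


def middle_half(n: int) -> slice:
    """Indices [n/4, 3n/4) of a population vector."""
    return slice(n // 4, 3 * n // 4)


def included_cells(topology: str, n: int) -> slice:
    """Analysis inclusion rule: all cells for periodic topologies, the
    central 3/4 for aperiodic networks."""
    if topology == "aperiodic":
        return slice(n // 8, n - n // 8)
    return slice(0, n)


def population_spectrum_stats(
    activity: PopulationActivity,
    population: str = "I",
    window: int = 10000,
) -> SpectrumStats:
    """Population period and gridness averaged over the last ``window`` frames.

    Each frame is restricted to the middle half of the population vector,
    normalized, and Fourier-analyzed; zero-variance frames are skipped.
    """
    frames = activity.population_frames(population)
    if len(frames) < 1:
        raise ValueError("no frames available")
    frames = frames[-window:]
    sl = middle_half(frames.shape[1])
    seg = np.asarray(frames[:, sl], dtype=float)
    L = seg.shape[1]
    sd = seg.std(axis=1)
    good = sd > 0
    if not good.any():
        return SpectrumStats(np.nan, 0.0, np.zeros(L // 2 + 1), L)
    seg = seg[good]
    seg = (seg - seg.mean(axis=1, keepdims=True)) / seg.std(axis=1, keepdims=True)
    power = np.abs(np.fft.rfft(seg, axis=1)) ** 2 * (2.0 / L**2)
    k = 1 + np.argmax(power[:, 1:], axis=1)
    rows = np.arange(len(seg))
    peak_power = power[rows, k]
    freq = k.astype(float) / L
    # parabolic refinement of the per-frame peak frequency
    interior = (k > 1) & (k < power.shape[1] - 1)
    if interior.any():
        lp = np.log(power[rows[interior], :] + 1e-300)
        ki = k[interior]
        denom = lp[np.arange(len(ki)), ki - 1] - 2 * lp[np.arange(len(ki)), ki] + lp[np.arange(len(ki)), ki + 1]
        shift = np.where(denom < 0, 0.5 * (lp[np.arange(len(ki)), ki - 1] - lp[np.arange(len(ki)), ki + 1]) / np.where(denom < 0, denom, 1.0), 0.0)
        freq[interior] = (ki + np.clip(shift, -0.5, 0.5)) / L
    periods = 1.0 / freq
    return SpectrumStats(float(periods.mean()), float(peak_power.mean()),
                         power.mean(axis=0), L)


def population_bump_count(activity: PopulationActivity, population: str = "I",
                          window: int = 10000) -> int:
    """Modal number of bumps on the full population ring.

    The dominant integer frequency of the mean power spectrum over the full
    (unshortened) population vector; on a periodic network the pattern must
    accommodate an integer bump count, so this is exact.
    """
    frames = np.asarray(activity.population_frames(population)[-window:],
                        dtype=float)
    sd = frames.std(axis=1)
    frames = frames[sd > 0]
    if len(frames) == 0:
        raise ValueError("no patterned frames")
    frames = (frames - frames.mean(axis=1, keepdims=True)) / frames.std(
        axis=1, keepdims=True)
    power = (np.abs(np.fft.rfft(frames, axis=1)) ** 2).mean(axis=0)
    return int(1 + np.argmax(power[1:]))


def velocity_response(
    config: NetworkConfig,
    weights: WeightMatrix,
    v_fixed: float,
    seed: int = 0,
    settle_s: float = 3.0,
    measure_s: float = 10.0,
    frame_ms: float = 10.0,
    population: str = "I",
) -> float:
    """Pattern translation speed (neurons/s) under fixed velocity input.

    The network is settled, then the pattern is tracked for ``measure_s``
    via frame-to-frame circular cross-correlation (subpixel peak), the
    displacement trace smoothed with a 4 s moving average, and the mean speed
    over the middle half of the trace reported.
    """
    duration = settle_s + measure_s
    traj = make_trajectory(duration, "constant_velocity", v0=v_fixed, seed=seed,
                           dt_ms=config.dt)
    frame_every = max(1, int(round(frame_ms / config.dt)))
    n_frames_total = len(traj.t) // frame_every + 1
    _, activity = run_lnp(config, weights, traj, seed=seed,
                          frame_every=frame_every, max_frames=n_frames_total,
                          record_spikes=False)
    frames = activity.population_frames(population)
    t = activity.frame_times
    keep = t >= settle_s * 1000.0
    frames = frames[keep]
    # temporal smoothing before shift estimation (100 ms)
    frames = uniform_filter1d(frames.astype(float), size=max(1, int(100.0 / frame_ms)),
                              axis=0, mode="nearest")
    sl = middle_half(frames.shape[1]) if config.topology == "aperiodic" else slice(None)
    seg = frames[:, sl]
    sd = seg.std(axis=1)
    if (sd <= 1e-12).any() or np.nanmax(seg) <= 0:
        raise ValueError("population activity is unpatterned; cannot track the pattern")
    seg = (seg - seg.mean(axis=1, keepdims=True)) / sd[:, None]
    F = np.fft.rfft(seg, axis=1)
    cross = np.fft.irfft(F[1:] * np.conj(F[:-1]), n=seg.shape[1], axis=1)
    n_cells = seg.shape[1]
    shifts = np.empty(len(cross))
    for i, c in enumerate(cross):
        k = int(np.argmax(c))
        y0, y1, y2 = c[(k - 1) % n_cells], c[k], c[(k + 1) % n_cells]
        denom = y0 - 2 * y1 + y2
        frac = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
        sk = k + np.clip(frac, -0.5, 0.5)
        if sk > n_cells / 2:
            sk -= n_cells
        shifts[i] = sk
    displacement = np.concatenate([[0.0], np.cumsum(shifts)])
    win = max(1, int(round(4000.0 / frame_ms)))
    displacement = uniform_filter1d(displacement, size=win, mode="nearest")
    n = len(displacement)
    mid = displacement[n // 4 : 3 * n // 4]
    dt_s = frame_ms / 1000.0
    return float((mid[-1] - mid[0]) / ((len(mid) - 1) * dt_s))
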