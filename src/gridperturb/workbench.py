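"""End-to-end perturbation protocol: simulate, measure, compare, classify.

The protocol mirrors the proposed experimental workflow: characterize
spatial tuning (period, amplitude) and cell-cell relative phases at baseline,
re-characterize at each of several increasing perturbation strengths, build
the DRPS of each perturbed condition against baseline, and run the
decision-tree classifier on the resulting series.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .chh_sim import run_chh
from .lnp_sim import SpikeRecord, Trajectory, make_trajectory, run_lnp
from .net_core import NetworkConfig, WeightMatrix, apply_perturbation, build_weights
from .phase_drps import (classify_architecture, count_peaks,
                         drps_from_relative_phases, idealized_pattern,
                         relative_phase_1d)
from .tuning_measures import (included_cells, population_spectrum_stats,
                              tuning_amplitude, tuning_curve, tuning_period)

__all__ = ["ProtocolConfig", "ProtocolReport", "run_protocol", "generate_fixtures",
           "measure_run", "population_tuning_curves", "pairwise_relative_phases"]


@dataclass
class ProtocolConfig:
    """Configuration of one perturbation-and-analysis protocol."""

    architecture: str = "aperiodic"
    knob: str = "gamma_inh"            # gamma_inh | tau_syn | temperature
    strengths: tuple = (1.0, 1.165, 1.33, 1.66)  # baseline first
    settle_s: float = 5.0              # warm-up before the baseline condition
    duration_s: float = 60.0
    n_repeats: int = 3                 # trajectory seeds averaged per condition
    seed: int = 0
    n_sample_cells: int = 30
    population: str = "I"
    dynamics: str = "lnp"              # lnp | chh
    q10_mode: str = "all"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.knob not in ("gamma_inh", "tau_syn", "temperature"):
            raise ValueError(f"unknown perturbation knob {self.knob!r}")
        if len(self.strengths) < 4:
            raise ValueError("need a baseline plus at least 3 perturbation strengths")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ProtocolReport:
    config_hash: str
    measurements: list
    classification: object
    errors: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "config_hash": self.config_hash,
            "measurements": self.measurements,
            "classification": {
                "label": self.classification.label,
                "rationale": self.classification.rationale,
                "bump_estimate": self.classification.bump_estimate,
            } if self.classification is not None else None,
            "errors": self.errors,
        }
        text = json.dumps(payload, indent=2, default=_jsonable)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def population_tuning_curves(record: SpikeRecord, trajectory: Trajectory,
                             cells) -> list:
    """Tuning curves for the given cells from one run."""
    return [tuning_curve(record.for_cell(c)[1], trajectory) for c in cells]


def common_tuning_period(curves: list) -> float:
    """Shared tuning period (bins) of a cell sample from the summed power
    spectrum of the normalized curves (cells of one module share a period)."""
    from .tuning_measures import spectrum_peak

    total = None
    for c in curves:
        r = np.asarray(getattr(c, "rate", c), dtype=float)
        sd = r.std()
        if sd == 0:
            continue
        v = (r - r.mean()) / sd
        p = np.abs(np.fft.rfft(v)) ** 2
        total = p if total is None else total + p
    if total is None:
        return np.nan
    L = len(np.atleast_1d(getattr(curves[0], "rate", curves[0])))
    k = 1 + int(np.argmax(total[1:]))
    freq = k / L
    if 1 < k < len(total) - 1:
        lp = np.log(total[k - 1 : k + 2] + 1e-300)
        denom = lp[0] - 2 * lp[1] + lp[2]
        if denom < 0:
            freq = (k + np.clip(0.5 * (lp[0] - lp[2]) / denom, -0.5, 0.5)) / L
    return float(1.0 / freq)


def pairwise_relative_phases(curves: list, period: float | None = None,
                             period_tolerance: float = 0.10) -> np.ndarray:
    """Wrapped pairwise relative phases for all curve pairs (NaN on failure).

    If ``period`` is omitted, the sample's common tuning period (aggregate
    spectrum over the curves) is used as the shared period.
    """
    if period is None:
        period = common_tuning_period(curves)
    n = len(curves)
    out = []
    for a in range(n):
        for b in range(a + 1, n):
            try:
                delta, _ = relative_phase_1d(curves[a], curves[b], period=period,
                                             period_tolerance=period_tolerance)
            except ValueError:
                delta = np.nan
            out.append(delta)
    return np.array(out)


def sample_cells(config: NetworkConfig, population: str, n: int, seed: int) -> np.ndarray:
    """Deterministic sample of analyzable cells (absolute indices) in a population."""
    from .lnp_sim import pop_slices

    sl = pop_slices(config)[population]
    n_pop = sl.stop - sl.start
    incl = included_cells(config.topology, n_pop)
    pool = np.arange(incl.start, incl.stop) + sl.start
    rng = np.random.default_rng(seed)
    if n >= len(pool):
        return pool
    return np.sort(rng.choice(pool, size=n, replace=False))


def measure_run(record, activity, trajectory, config, population="I",
                cells=None) -> dict:
    """Standard measurement bundle for one simulation run."""
    stats = population_spectrum_stats(activity, population)
    if cells is None:
        cells = sample_cells(config, population, 30, config.seed)
    curves = population_tuning_curves(record, trajectory, cells)
    periods = np.array([tuning_period(c) for c in curves])
    amps = np.array([tuning_amplitude(c) for c in curves])
    return {
        "population_period": stats.period,
        "gridness": stats.power,
        "tuning_period": float(np.nanmean(periods)),
        "tuning_amplitude": float(np.nanmean(amps)),
        "n_cells_included": len(cells),
        "_curves": curves,
        "_cells": cells,
    }


def _average_measurements(reps: list) -> dict:
    """Pool repeated measurements of one condition: tuning curves averaged
    across trajectory seeds (as for a longer recording), scalars averaged."""
    from dataclasses import replace as dc_replace

    base = reps[0]
    if len(reps) == 1:
        return base
    curves = []
    for ci in range(len(base["_curves"])):
        mean_rate = np.mean([r["_curves"][ci].rate for r in reps], axis=0)
        curves.append(dc_replace(base["_curves"][ci], rate=mean_rate))
    periods = np.array([tuning_period(c) for c in curves])
    amps = np.array([tuning_amplitude(c) for c in curves])
    return {
        "population_period": float(np.mean([r["population_period"] for r in reps])),
        "gridness": float(np.mean([r["gridness"] for r in reps])),
        "tuning_period": float(np.nanmean(periods)),
        "tuning_amplitude": float(np.nanmean(amps)),
        "n_cells_included": base["n_cells_included"],
        "_curves": curves,
        "_cells": base["_cells"],
    }


def _simulate(cfg: NetworkConfig, weights: WeightMatrix, traj: Trajectory,
              protocol: ProtocolConfig, temperature: float = 36.0, s_init=None):
    if protocol.dynamics == "chh":
        return run_chh(cfg, weights, traj, T=temperature, mode=protocol.q10_mode)
    return run_lnp(cfg, weights, traj, seed=cfg.seed, s_init=s_init)


def run_protocol(protocol: ProtocolConfig) -> ProtocolReport:
    """Run the full perturb-measure-classify protocol.

    Stage failures beyond baseline produce a partial report with error
    provenance rather than an exception.
    """
    base_cfg = NetworkConfig.for_topology(protocol.architecture, seed=protocol.seed)
    if protocol.dynamics == "chh":
        base_cfg = NetworkConfig.for_topology(
            protocol.architecture, seed=protocol.seed, tau_syn=15.0, beta_vel=0.8,
            dt=0.025,
        )
    weights = build_weights(base_cfg)
    # Warm-start: settle the unperturbed network once and apply every condition
    # to that ongoing state, as a perturbation experiment would.  This pins the
    # (multistable) baseline bump configuration across conditions.
    s_init = None
    if protocol.dynamics == "lnp" and protocol.settle_s > 0:
        settle_traj = make_trajectory(protocol.settle_s, "constant_velocity",
                                      v0=0.0, dt_ms=base_cfg.dt)
        settle_rec, _ = run_lnp(base_cfg, weights, settle_traj,
                                seed=protocol.seed, record_spikes=False,
                                max_frames=100)
        s_init = settle_rec.final_state
    trajs = [make_trajectory(protocol.duration_s, "quasi_random",
                             seed=protocol.seed + 97 * r, dt_ms=base_cfg.dt)
             for r in range(protocol.n_repeats)]
    measurements = []
    errors = []
    baseline = None
    series = []
    cells = None
    for idx, strength in enumerate(protocol.strengths):
        cfg, w, temperature = base_cfg, weights, 36.0
        if protocol.knob == "gamma_inh":
            w, cfg = apply_perturbation(weights, base_cfg, gamma_inh=strength)
        elif protocol.knob == "tau_syn":
            w, cfg = apply_perturbation(weights, base_cfg, tau_scale=strength)
        else:
            temperature = strength
        try:
            reps = []
            for r, traj in enumerate(trajs):
                record, activity = _simulate(cfg, w, traj, protocol, temperature,
                                             s_init=s_init)
                reps.append(measure_run(record, activity, traj, cfg,
                                        protocol.population, cells=cells))
                cells = reps[-1]["_cells"]
            m = _average_measurements(reps)
        except (FloatingPointError, ValueError) as exc:
            errors.append({"strength": strength, "error": str(exc)})
            continue
        entry = {"strength": strength,
                 **{k: v for k, v in m.items() if not k.startswith("_")}}
        if idx == 0:
            baseline = m
            entry.update(amplitude_change=0.0, period_change=0.0,
                         drps_width=0.0, drps_peaks=0, drps_central_mass=1.0)
        else:
            deltas_pre = pairwise_relative_phases(baseline["_curves"])
            deltas_post = pairwise_relative_phases(m["_curves"])
            ok = np.isfinite(deltas_pre) & np.isfinite(deltas_post)
            d = drps_from_relative_phases(deltas_pre[ok], deltas_post[ok])
            central = (float(np.mean(np.abs(d.shifts) <= 0.025))
                       if d.n_pairs else np.nan)
            entry.update(
                amplitude_change=abs(m["tuning_amplitude"] / baseline["tuning_amplitude"] - 1),
                period_change=abs(m["tuning_period"] / baseline["tuning_period"] - 1),
                drps_width=d.sigma,
                drps_peaks=count_peaks(d) if d.n_pairs else 0,
                drps_central_mass=central,
            )
        measurements.append(entry)
        series.append((entry["strength"], entry["amplitude_change"],
                       entry["period_change"], entry["drps_width"],
                       entry["drps_peaks"], entry["drps_central_mass"]))
    classification = None
    if len(series) >= 3 and baseline is not None:
        classification = classify_architecture(series)
    report = ProtocolReport(protocol.content_hash(), measurements, classification,
                            errors)
    if protocol.out_dir:
        os.makedirs(protocol.out_dir, exist_ok=True)
        report.to_json(os.path.join(protocol.out_dir, "protocol_report.json"))
    return report


def generate_fixtures(kind: str, params: dict | None = None, seed: int = 0):
    """Seeded synthetic inputs for analysis-path tests and demos.

    ``idealized_pattern``: pre/post phase sets (1D or 2D).
    ``synthetic_spike_map``: spatially periodic Poisson spikes on a uniform
    quasi-random trajectory (returns positions, times, trajectory).
    ``sigma_series``: constructed width-vs-strength series (ramp/step/flat)
    for classifier checks.
    """
    params = dict(params or {})
    if kind == "idealized_pattern":
        return idealized_pattern(
            params.pop("N", 40), params.pop("lambda_pop", 40.0 / 3.0),
            params.pop("alpha", 0.1), params.pop("dims", 2), **params,
        )
    if kind == "synthetic_spike_map":
        rng = np.random.default_rng(seed)
        duration = params.get("duration_s", 120.0)
        lam = params.get("lambda_cm", 50.0)
        rate0 = params.get("rate_hz", 5.0)
        phase = params.get("phase", 0.0)
        traj = make_trajectory(duration, "quasi_random", seed=seed, dt_ms=5.0)
        rate = rate0 * (1.0 + np.sin(2 * np.pi * traj.x / lam + phase))
        p = rate * (traj.dt / 1000.0)
        spk = rng.random(len(p)) < p
        return traj.x[spk], traj.t[spk], traj
    if kind == "sigma_series":
        shape = params.get("shape", "ramp")
        strengths = np.asarray(params.get("strengths", [1.0, 1.22, 1.44, 1.66]))
        wmax = params.get("wmax", 0.15)
        excess = strengths - strengths[0]
        if shape == "ramp":
            widths = wmax * excess / excess[-1]
        elif shape == "step":
            widths = np.where(excess >= params.get("step_at", 0.3), wmax, 0.0)
        elif shape == "flat":
            widths = np.zeros_like(excess)
        else:
            raise ValueError(f"unknown sigma_series shape {shape!r}")
        amp = params.get("amplitude_change", 0.2)
        per = params.get("period_change", 0.1 if shape != "flat" else 0.0)
        series = [(float(s), 0.0 if k == 0 else amp,
                   0.0 if k == 0 else per, float(widths[k]),
                   int(params.get("peaks", 6)) if widths[k] > 0 else 0)
                  for k, s in enumerate(strengths)]
        return series
    raise ValueError(f"unknown fixture kind {kind!r}")
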