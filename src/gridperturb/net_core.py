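"""Network topologies and recurrent weight construction for 1D grid-cell models.

Three recurrent architectures are supported, distinguished by their boundary
conditions and connectivity range:

* ``aperiodic`` — local connectivity, hard boundaries, with a smooth activity/
  weight envelope that tapers toward the network edges;
* ``partially_periodic`` — the same local connectivity wrapped on a ring
  (periodicity scale ``rho = 1``);
* ``fully_periodic`` — ring connectivity dilated by ``rho = 11`` so that the
  coupling is effectively global and the pattern period is fixed by the wiring.

The network holds two excitatory populations (``EL``/``ER``, receiving
leftward/rightward velocity input) and one inhibitory population (``I``),
with N_I = (N_EL + N_ER) / 5 by default, as in cortex.

Weight blocks are Gaussian profiles in the offset coordinate
``x_ij = i - gamma * j`` (``gamma = N_P / N_P'``), with shifts ``Delta``,
widths ``sigma``, optional central cuts (half-width ``delta``) and one-sided
Heaviside windows for the I->E projections.  Magnitudes are stored
non-negative; inhibitory-source blocks enter the recurrent input sum with a
negative sign (see :meth:`WeightMatrix.combined`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "POPULATIONS",
    "NetworkConfig",
    "WeightBlockSpec",
    "WeightMatrix",
    "wrap_norm",
    "envelope_value",
    "envelope",
    "build_weight_block",
    "build_weights",
    "default_block_specs",
    "apply_perturbation",
]

POPULATIONS = ("EL", "ER", "I")

Topology = Literal["aperiodic", "partially_periodic", "fully_periodic"]


class ConfigurationError(ValueError):
    """Raised for invalid network or weight-block parameters."""


@dataclass
class NetworkConfig:
    """Topology, population sizes, dynamics and perturbation parameters.

    Defaults are the standard LNP simulation parameters: 400+400 excitatory
    cells, 160 inhibitory cells, dt = 0.5 ms, tau_syn = 30 ms, beta_vel = 1,
    gamma_inh = 1, biases G0 = 50, G0' = 0 (I) / 15 (E).
    """

    topology: Topology = "aperiodic"
    N_EL: int = 400
    N_ER: int = 400
    N_I: int = 160
    rho: float = 1.0
    dt: float = 0.5            # ms
    tau_syn: float = 30.0      # ms
    beta_vel: float = 1.0      # s/m (multiplies velocity in m/s)
    gamma_inh: float = 1.0
    CV: float = 0.5
    G0: float = 50.0
    G0p_I: float = 0.0
    G0p_EL: float = 15.0
    G0p_ER: float = 15.0
    W_vel: float = 200.0       # additive-velocity-mode weight
    kappa: float = 0.3
    a0: float = 30.0
    ee_variant: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tau_syn <= 0:
            raise ConfigurationError("dt and tau_syn must be positive")
        if self.gamma_inh <= 0:
            raise ConfigurationError("gamma_inh must be positive")
        if self.topology not in ("aperiodic", "partially_periodic", "fully_periodic"):
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        if min(self.N_EL, self.N_ER, self.N_I) <= 0:
            raise ConfigurationError("population sizes must be positive")

    @property
    def n_pop(self) -> dict:
        return {"EL": self.N_EL, "ER": self.N_ER, "I": self.N_I}

    @property
    def G0p(self) -> dict:
        return {"EL": self.G0p_EL, "ER": self.G0p_ER, "I": self.G0p_I}

    @classmethod
    def for_topology(cls, topology: Topology, **overrides) -> "NetworkConfig":
        """Default configuration for a named architecture.

        ``rho`` defaults to 1 for aperiodic / partially periodic networks and
        to 11 for the fully periodic network.
        """
        rho = overrides.pop("rho", 11.0 if topology == "fully_periodic" else 1.0)
        return cls(topology=topology, rho=rho, **overrides)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class WeightBlockSpec:
    """Parameters of one Gaussian coupling block between two populations.

    ``mu`` (direction sign of the one-sided window) applies only to I->E
    blocks; ``delta_cut`` (half-width of the central diagonal cut, in
    neurons) applies to I->E and I->I blocks.
    """

    kind: Literal["E_to_I", "I_to_E", "I_to_I", "E_to_E"]
    source_pop: str
    target_pop: str
    eta: float
    Delta: float
    sigma: float
    mu: int | None = None
    delta_cut: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("E_to_I", "I_to_E", "I_to_I", "E_to_E"):
            raise ConfigurationError(f"unknown block kind {self.kind!r}")
        if self.eta <= 0 or self.sigma <= 0:
            raise ConfigurationError("eta and sigma must be positive")
        if self.mu is not None and self.mu not in (-1, 1):
            raise ConfigurationError("mu must be +1 or -1")

    def mirrored(self) -> "WeightBlockSpec":
        """The L/R partner spec: Delta (and mu) negated, populations swapped L<->R."""
        swap = {"EL": "ER", "ER": "EL", "I": "I"}
        return replace(
            self,
            source_pop=swap[self.source_pop],
            target_pop=swap[self.target_pop],
            Delta=-self.Delta,
            mu=None if self.mu is None else -self.mu,
        )


# Default coupling tables.  The (eta, Delta, sigma, mu, delta) values for the
# standard network and for the E-E variant.
_DEFAULT_SPECS = [
    WeightBlockSpec("E_to_I", "EL", "I", eta=11.5, Delta=-2, sigma=4),
    WeightBlockSpec("E_to_I", "ER", "I", eta=11.5, Delta=+2, sigma=4),
    WeightBlockSpec("I_to_E", "I", "EL", eta=4, Delta=+8, sigma=10, mu=-1, delta_cut=3),
    WeightBlockSpec("I_to_E", "I", "ER", eta=4, Delta=-8, sigma=10, mu=+1, delta_cut=3),
    WeightBlockSpec("I_to_I", "I", "I", eta=12, Delta=4, sigma=6, delta_cut=3),
]

_EE_VARIANT_SPECS = [
    WeightBlockSpec("E_to_I", "EL", "I", eta=3, Delta=-2, sigma=8),
    WeightBlockSpec("E_to_I", "ER", "I", eta=3, Delta=+2, sigma=8),
    WeightBlockSpec("I_to_E", "I", "EL", eta=3.25, Delta=+8, sigma=8, mu=-1, delta_cut=3),
    WeightBlockSpec("I_to_E", "I", "ER", eta=3.25, Delta=-8, sigma=8, mu=+1, delta_cut=3),
    WeightBlockSpec("I_to_I", "I", "I", eta=4, Delta=4, sigma=6, delta_cut=3),
    WeightBlockSpec("E_to_E", "EL", "EL", eta=5.5, Delta=-4, sigma=4),
    WeightBlockSpec("E_to_E", "ER", "ER", eta=5.5, Delta=+4, sigma=4),
    WeightBlockSpec("E_to_E", "ER", "EL", eta=5.5, Delta=0, sigma=4),
    WeightBlockSpec("E_to_E", "EL", "ER", eta=5.5, Delta=0, sigma=4),
]


def default_block_specs(ee_variant: bool = False) -> list[WeightBlockSpec]:
    """The default coupling tables (optionally the E-E variant tables)."""
    return list(_EE_VARIANT_SPECS if ee_variant else _DEFAULT_SPECS)


def wrap_norm(x, N):
    """Circular distance ``||x||_N = min(N - |x|, |x|)`` on a ring of N cells.

    Accepts scalars or arrays; the result lies in [0, N/2].
    """
    if N <= 0:
        raise ConfigurationError("N must be positive")
    ax = np.abs(np.asarray(x, dtype=float)) % N
    return np.minimum(N - ax, ax)


def envelope_value(i, N, kappa=0.3, a0=30.0):
    """Activity/weight envelope A_i: 1 in the bulk, Gaussian taper near edges.

    A_i = 1 for r_i = |i - N/2| < kappa*N, else
    exp[-a0 * ((r_i - kappa*N) / ((1 - kappa)*N))^2].
    """
    if not 0 < kappa < 1:
        raise ConfigurationError("kappa must lie in (0, 1)")
    r = np.abs(np.asarray(i, dtype=float) - N / 2.0)
    out = np.ones_like(r)
    tapered = r >= kappa * N
    out[tapered] = np.exp(-a0 * ((r[tapered] - kappa * N) / ((1 - kappa) * N)) ** 2)
    return out if out.ndim else float(out)


def envelope(config: NetworkConfig, pop: str) -> np.ndarray:
    """Per-cell envelope vector for one population (all ones unless aperiodic)."""
    N = config.n_pop[pop]
    if config.topology != "aperiodic":
        return np.ones(N)
    return envelope_value(np.arange(N), N, config.kappa, config.a0)


def _heaviside(x):
    # Theta(0) = 1 by convention.
    return (np.asarray(x) >= 0).astype(float)


def build_weight_block(spec: WeightBlockSpec, config: NetworkConfig) -> np.ndarray:
    """Dense non-negative weight block W[i, j] from source j to target i.

    Periodic topologies use the ring norm with periodicity scale rho; the
    aperiodic topology uses the plain absolute offset and multiplies by the
    product of source and target envelopes.
    """
    n_tgt = config.n_pop[spec.target_pop]
    n_src = config.n_pop[spec.source_pop]
    rho = config.rho
    gamma = n_tgt / n_src
    i = np.arange(n_tgt, dtype=float)[:, None]
    j = np.arange(n_src, dtype=float)[None, :]
    x = i - gamma * j

    aperiodic = config.topology == "aperiodic"

    def dist(y):
        return np.abs(y) if aperiodic else wrap_norm(y, n_tgt)

    two_sig2 = 2.0 * (spec.sigma * rho) ** 2
    if spec.kind in ("E_to_I", "E_to_E"):
        W = (spec.eta / rho) * np.exp(-dist(x - rho * spec.Delta) ** 2 / two_sig2)
    elif spec.kind == "I_to_E":
        if spec.mu is None or spec.delta_cut is None:
            raise ConfigurationError("I_to_E blocks require mu and delta_cut")
        mu = spec.mu
        W = (spec.eta / rho) * np.exp(-dist(x - rho * spec.Delta) ** 2 / two_sig2)
        W *= _heaviside(dist(x) - rho * spec.delta_cut)
        W *= (
            _heaviside(-mu * x) * _heaviside(mu * x + n_tgt / 2)
            + _heaviside(mu * x - n_tgt / 2)
        )
    elif spec.kind == "I_to_I":
        if spec.delta_cut is None:
            raise ConfigurationError("I_to_I blocks require delta_cut")
        W = (spec.eta / rho) * (
            np.exp(-dist(x - rho * spec.Delta) ** 2 / two_sig2)
            + np.exp(-dist(x + rho * spec.Delta) ** 2 / two_sig2)
        )
        W *= _heaviside(dist(x) - rho * spec.delta_cut)
    else:
        raise ConfigurationError(f"unknown block kind {spec.kind!r}")

    if aperiodic:
        A_tgt = envelope(config, spec.target_pop)
        A_src = envelope(config, spec.source_pop)
        W = W * A_tgt[:, None] * A_src[None, :]
    return W


@dataclass
class WeightMatrix:
    """All recurrent coupling blocks, keyed by (target_pop, source_pop).

    Block magnitudes are non-negative.  For rate (LNP) dynamics the
    inhibitory-source blocks contribute negatively to the recurrent input
    (:meth:`combined` with ``signed=True``); for conductance (CHH) dynamics
    the magnitudes are used directly, with inhibition arising from the
    synaptic reversal potential.
    """

    blocks: dict = field(default_factory=dict)
    gamma_inh: float = 1.0

    def block(self, target: str, source: str) -> np.ndarray:
        return self.blocks[(target, source)]

    def effective_block(self, target: str, source: str, signed: bool = True) -> np.ndarray:
        """Block including the inhibitory gain and (optionally) the sign convention."""
        W = self.blocks[(target, source)]
        if source == "I":
            W = self.gamma_inh * W
            if signed:
                W = -W
        return W

    def combined(self, config: NetworkConfig, signed: bool = True) -> np.ndarray:
        """One dense matrix over the concatenated [EL, ER, I] state vector."""
        sizes = [config.n_pop[p] for p in POPULATIONS]
        offs = np.concatenate([[0], np.cumsum(sizes)])
        n = offs[-1]
        W = np.zeros((n, n))
        for (tgt, src), _ in self.blocks.items():
            it, is_ = POPULATIONS.index(tgt), POPULATIONS.index(src)
            W[offs[it]:offs[it + 1], offs[is_]:offs[is_ + 1]] = self.effective_block(
                tgt, src, signed=signed
            )
        return W

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(
            {k: v.copy() for k, v in self.blocks.items()}, gamma_inh=self.gamma_inh
        )

    def scaled(self, factor: float) -> "WeightMatrix":
        """All block magnitudes multiplied by ``factor`` (e.g. the CHH eta rescale)."""
        return WeightMatrix(
            {k: factor * v for k, v in self.blocks.items()}, gamma_inh=self.gamma_inh
        )

    def save_npz(self, path) -> None:
        arrays = {f"{t}__{s}": v for (t, s), v in self.blocks.items()}
        np.savez(path, gamma_inh=self.gamma_inh, **arrays)

    @classmethod
    def load_npz(cls, path) -> "WeightMatrix":
        with np.load(path) as data:
            blocks = {}
            gamma_inh = 1.0
            for key in data.files:
                if key == "gamma_inh":
                    gamma_inh = float(data[key])
                else:
                    t, s = key.split("__")
                    blocks[(t, s)] = data[key]
        return cls(blocks, gamma_inh=gamma_inh)

    def save_text(self, directory) -> None:
        """Write each block as delimited text for inspection."""
        import os

        os.makedirs(directory, exist_ok=True)
        for (t, s), v in self.blocks.items():
            np.savetxt(os.path.join(directory, f"W_{t}_from_{s}.tsv"), v, delimiter="\t")


def build_weights(config: NetworkConfig, specs=None) -> WeightMatrix:
    """Build all recurrent weight blocks for a configuration."""
    if specs is None:
        specs = default_block_specs(config.ee_variant)
    blocks = {
        (s.target_pop, s.source_pop): build_weight_block(s, config) for s in specs
    }
    return WeightMatrix(blocks, gamma_inh=config.gamma_inh)


def apply_perturbation(
    weights: WeightMatrix,
    config: NetworkConfig,
    gamma_inh: float = 1.0,
    tau_scale: float = 1.0,
) -> tuple[WeightMatrix, NetworkConfig]:
    """Global perturbation: scale inhibitory-source weights and/or tau_syn.

    Returns a new (WeightMatrix, NetworkConfig) pair; the inputs are not
    mutated.  ``gamma_inh`` composes multiplicatively with any gain already
    applied, so a perturbation followed by its reciprocal is the identity.
    """
    if gamma_inh <= 0 or tau_scale <= 0:
        raise ConfigurationError("perturbation factors must be positive")
    new_w = weights.copy()
    new_w.gamma_inh = weights.gamma_inh * gamma_inh
    new_cfg = replace(
        config, tau_syn=config.tau_syn * tau_scale, gamma_inh=new_w.gamma_inh
    )
    return new_w, new_cfg
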