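"""Grid-to-place Hebbian association and the familiar-vs-novel environment test.

Grid cells in module m fire as ``sin(2 pi x / lambda_m + phi_i + phitilde_mk)``
where ``phi_i = 2 pi i / N`` is the cell's fixed within-module phase and
``phitilde_mk`` is a random module-wide phase shift drawn independently per
module and environment (environment remapping).  Place-cell weights are
learned Hebbianly in familiar environments: each place cell i with preferred
location ``x_ik`` accumulates, over the L familiar environments, the grid
activity at that location.  Its subthreshold activation anywhere is then the
weight-sum over all grid cells.

The question probed here: do the learned associations fire spuriously in a
*novel* environment (fresh random module shifts, no learning)?  With several
incommensurate modules the familiar-field peaks stand well above the maximal
novel-environment activations, so learned place responses are not triggered
and cannot reset the perturbed grid phases in novel enclosures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridPlaceModel", "grid_rate", "learn_weights", "place_subthreshold",
           "familiar_novel_separation"]

DEFAULT_LAMBDAS = (30.0, 42.0, 59.0, 83.0)  # cm, ratio ~1.4, incommensurate


@dataclass
class GridPlaceModel:
    """Model configuration plus the random per-environment structure."""

    M_modules: int = 4
    N: int = 100                 # grid cells per module
    P: int = 200                 # place cells
    L_env: int = 2               # familiar environments
    env_length: float = 200.0    # cm
    lambda_m: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_LAMBDAS))
    seed: int = 0
    phi_tilde: np.ndarray = None   # (M, L) module-wide shifts, familiar envs
    x_pc: np.ndarray = None        # (P, L) place preferences, familiar envs

    def __post_init__(self) -> None:
        self.lambda_m = np.asarray(self.lambda_m, dtype=float)[: self.M_modules]
        if len(self.lambda_m) != self.M_modules:
            raise ValueError("need one spatial period per module")
        rng = np.random.default_rng(self.seed)
        if self.phi_tilde is None:
            self.phi_tilde = rng.uniform(0, 2 * np.pi, size=(self.M_modules, self.L_env))
        if self.x_pc is None:
            self.x_pc = rng.uniform(0, self.env_length, size=(self.P, self.L_env))

    @property
    def phi(self) -> np.ndarray:
        """Within-module phases 2 pi i / N, fixed across environments."""
        return 2 * np.pi * np.arange(self.N) / self.N

    def novel_shifts(self, rng) -> np.ndarray:
        """Fresh module-wide shifts for one novel environment."""
        return rng.uniform(0, 2 * np.pi, size=self.M_modules)


def grid_rate(x, j, m, model: GridPlaceModel, shifts=None, env: int = 0):
    """Tuning of grid cell j in module m: sin(2 pi x / lambda_m + phi_j + phitilde).

    ``shifts`` overrides the familiar-environment module shifts (used for
    novel environments); proportionality constant fixed at 1.
    """
    phit = model.phi_tilde[m, env] if shifts is None else shifts[m]
    x = np.asarray(x, dtype=float)
    return np.sin(2 * np.pi * x / model.lambda_m[m] + model.phi[j] + phit)


def _grid_activity_matrix(model: GridPlaceModel, x, shifts=None, env: int = 0):
    """Grid activities with shape (M, N, len(x))."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty((model.M_modules, model.N, len(x)))
    for m in range(model.M_modules):
        phit = model.phi_tilde[m, env] if shifts is None else shifts[m]
        arg = 2 * np.pi * x[None, :] / model.lambda_m[m] + model.phi[:, None] + phit
        out[m] = np.sin(arg)
    return out


def learn_weights(model: GridPlaceModel) -> np.ndarray:
    """Hebbian grid-to-place weights summed over familiar environments.

    W[i, m, j] = sum_k f_GC(j, m, k)(x_pc[i, k]); every place cell has a
    field in every familiar environment.
    """
    W = np.zeros((model.P, model.M_modules, model.N))
    for k in range(model.L_env):
        acts = _grid_activity_matrix(model, model.x_pc[:, k], env=k)  # (M, N, P)
        W += np.transpose(acts, (2, 0, 1))
    return W


def place_subthreshold(x, model: GridPlaceModel, W: np.ndarray,
                       shifts=None, env: int = 0) -> np.ndarray:
    """Subthreshold place-cell activations, shape (P, len(x)).

    Linear in W: the weighted sum of grid activities in the queried
    environment (familiar ``env`` or a novel one specified via ``shifts``).
    """
    acts = _grid_activity_matrix(model, x, shifts=shifts, env=env)  # (M, N, X)
    return np.einsum("pmn,mnx->px", W, acts)


@dataclass
class SeparationSummary:
    familiar_peaks: np.ndarray   # (P, L) activation at each cell's field
    novel_peaks: np.ndarray      # (P, n_novel) max over x per novel environment
    ratios: np.ndarray           # per place cell: min familiar / max novel
    novel_typical: float = np.nan  # median |activation| across cells, x, envs

    @property
    def median_ratio(self) -> float:
        return float(np.median(self.ratios))

    def quantile_gap(self, q: float = 0.05) -> tuple[float, float]:
        """(q-quantile of familiar peaks, (1-q)-quantile of novel peaks)."""
        return (
            float(np.quantile(self.familiar_peaks, q)),
            float(np.quantile(self.novel_peaks, 1 - q)),
        )


def familiar_novel_separation(
    model: GridPlaceModel,
    W: np.ndarray,
    n_novel: int = 100,
    rng=None,
    dx: float = 0.5,
) -> SeparationSummary:
    """Compare familiar-field activations against novel-environment maxima.

    For each place cell: its activation at its preferred location in each
    familiar environment, versus the maximum of its profile over position in
    each of ``n_novel`` novel environments (fresh module shifts, weights
    unchanged).
    """
    rng = np.random.default_rng(rng)
    xs = np.arange(0.0, model.env_length, dx)
    familiar = np.empty((model.P, model.L_env))
    for k in range(model.L_env):
        acts = _grid_activity_matrix(model, model.x_pc[:, k], env=k)
        familiar[:, k] = np.einsum("pmn,mnp->p", W, acts)
    novel = np.empty((model.P, n_novel))
    typical = np.empty(n_novel)
    for e in range(n_novel):
        prof = place_subthreshold(xs, model, W, shifts=model.novel_shifts(rng))
        novel[:, e] = prof.max(axis=1)
        typical[e] = np.median(np.abs(prof))
    ratios = familiar.min(axis=1) / novel.max(axis=1)
    return SeparationSummary(familiar, novel, ratios, float(np.median(typical)))
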