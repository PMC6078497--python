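"""Gate kinetics for the regular-spiking cortical Hodgkin-Huxley neuron.

This module is the single place where the voltage-dependent rate functions
live, so they can be swapped wholesale for a different cell model.  The
kinetics are the standard regular-spiking cortical parameterization
(Traub/Miles-style Na and K rates shifted by a spike threshold ``V_T``, plus
a slow non-inactivating M-type K current):

* ``m``, ``h`` — sodium activation/inactivation;
* ``n`` — delayed-rectifier potassium activation;
* ``q`` — M-current activation (first-order relaxation to ``q_inf`` with a
  voltage-dependent ``tau_q`` capped by ``TAU_MAX_Q``).

All rates are in 1/ms, voltages in mV.  ``tau_x = 1/(alpha_x + beta_x)`` for
the alpha/beta gates.
"""

from __future__ import annotations

import numpy as np

V_T = -56.2       # mV, spike-threshold shift of the Na/K rate curves
TAU_MAX_Q = 608.0  # ms, M-current maximal time constant


def _vtrap(x, y):
    """x / (exp(x/y) - 1), stable near x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x / y) < 1e-6, y * (1.0 - x / (2.0 * y)), x / np.expm1(x / y))
    return out


def alpha_m(V):
    return 0.32 * _vtrap(-(V - V_T - 13.0), 4.0)


def beta_m(V):
    return 0.28 * _vtrap(V - V_T - 40.0, 5.0)


def alpha_h(V):
    return 0.128 * np.exp(-(V - V_T - 17.0) / 18.0)


def beta_h(V):
    return 4.0 / (1.0 + np.exp(-(V - V_T - 40.0) / 5.0))


def alpha_n(V):
    return 0.032 * _vtrap(-(V - V_T - 15.0), 5.0)


def beta_n(V):
    return 0.5 * np.exp(-(V - V_T - 10.0) / 40.0)


def q_inf(V):
    return 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))


def tau_q(V):
    return TAU_MAX_Q / (3.3 * np.exp((V + 35.0) / 20.0) + np.exp(-(V + 35.0) / 20.0))


def steady_state(V):
    """Equilibrium gating values (m, h, n, q) at a fixed voltage."""
    m = alpha_m(V) / (alpha_m(V) + beta_m(V))
    h = alpha_h(V) / (alpha_h(V) + beta_h(V))
    n = alpha_n(V) / (alpha_n(V) + beta_n(V))
    return m, h, n, q_inf(V)
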