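"""Weight construction: norms, envelopes, blocks, symmetries, perturbation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gridperturb.net_core import (ConfigurationError, NetworkConfig,
                                  WeightBlockSpec, apply_perturbation,
                                  build_weight_block, build_weights,
                                  default_block_specs, envelope_value,
                                  wrap_norm)


@pytest.mark.parametrize("x,N,expected", [(3, 10, 3), (7, 10, 3), (-7, 10, 3),
                                          (5, 10, 5), (0, 10, 0), (13, 10, 3)])
def test_wrap_norm_values(x, N, expected):
    assert wrap_norm(x, N) == expected


@settings(deadline=None, max_examples=100, derandomize=True)
@given(x=st.floats(-1000, 1000), N=st.integers(1, 500))
def test_wrap_norm_range_and_symmetry(x, N):
    d = wrap_norm(x, N)
    assert 0 <= d <= N / 2
    assert wrap_norm(-x, N) == pytest.approx(d)


def test_wrap_norm_rejects_nonpositive_ring():
    with pytest.raises(ConfigurationError):
        wrap_norm(3, 0)


def test_envelope_value():
    assert envelope_value(50, 100, 0.3, 30) == 1.0
    # edge cell: r = 50, taper argument (50 - 30) / 70
    assert envelope_value(0, 100, 0.3, 30) == pytest.approx(
        np.exp(-30 * (20 / 70) ** 2)
    )
    # non-increasing in distance from the center beyond kappa*N
    vals = envelope_value(np.arange(50, 100), 100, 0.3, 30)
    assert np.all(np.diff(vals) <= 1e-15)
    with pytest.raises(ConfigurationError):
        envelope_value(0, 100, kappa=1.5)


class TestWeightBlocks:
    def test_e_to_i_peak_value(self):
        # at offset x = rho*Delta the Gaussian is at its peak, value eta/rho
        for topo, rho in [("partially_periodic", 1.0), ("fully_periodic", 11.0)]:
            cfg = NetworkConfig.for_topology(topo)
            spec = default_block_specs()[0]  # EL -> I, eta=11.5, Delta=-2
            W = build_weight_block(spec, cfg)
            gamma = cfg.N_I / cfg.N_EL
            # choose i, j with i - gamma*j = rho*Delta exactly
            j = 10
            x_target = rho * spec.Delta + gamma * j
            if x_target == int(x_target):
                i = int(x_target) % cfg.N_I
                assert W[i, j] == pytest.approx(spec.eta / rho)

    def test_default_tables(self):
        specs = {(s.target_pop, s.source_pop): s for s in default_block_specs()}
        el = specs[("I", "EL")]
        er = specs[("I", "ER")]
        assert (el.eta, el.Delta, el.sigma) == (11.5, -2, 4)
        assert (er.eta, er.Delta, er.sigma) == (11.5, +2, 4)
        assert specs[("EL", "I")].mirrored() == specs[("ER", "I")]

    def test_i_to_i_central_cut(self):
        cfg = NetworkConfig.for_topology("partially_periodic")
        spec = [s for s in default_block_specs() if s.kind == "I_to_I"][0]
        W = build_weight_block(spec, cfg)
        x = np.arange(cfg.N_I)[:, None] - np.arange(cfg.N_I)[None, :]
        dist = np.minimum(np.abs(x) % cfg.N_I, cfg.N_I - np.abs(x) % cfg.N_I)
        assert np.all(W[dist < cfg.rho * spec.delta_cut] == 0)

    def test_translation_invariance_periodic(self):
        for topo in ("partially_periodic", "fully_periodic"):
            cfg = NetworkConfig.for_topology(topo)
            W = build_weights(cfg)
            block = W.block("I", "I")
            k = 7
            rolled = np.roll(np.roll(block, k, axis=0), k, axis=1)
            np.testing.assert_allclose(rolled, block, atol=1e-12)

    def test_mirror_symmetry_exact(self):
        cfg = NetworkConfig.for_topology("partially_periodic")
        W = build_weights(cfg)
        # EL->I equals ER->I with the source axis reflected (Delta sign flip)
        a = W.block("I", "EL")
        b = W.block("I", "ER")
        n_i, n_e = a.shape
        i = np.arange(n_i)[:, None]
        j = np.arange(n_e)[None, :]
        gamma = n_i / n_e
        # reflection i -> -i, j -> -j maps x -> -x hence Delta -> -Delta
        refl = b[(-i) % n_i, (-j) % n_e]
        np.testing.assert_allclose(a, refl, atol=1e-12)

    def test_aperiodic_edge_taper(self):
        cfg = NetworkConfig.for_topology("aperiodic")
        W = build_weights(cfg)
        total_in = np.zeros(cfg.N_I)
        for src in ("EL", "ER", "I"):
            total_in += np.abs(W.block("I", src)).sum(axis=1)
        center = total_in[cfg.N_I // 2]
        assert total_in[0] < 0.15 * center
        assert total_in[-1] < 0.15 * center

    def test_unknown_kind_rejected(self):
        with pytest.raises(Exception):
            WeightBlockSpec("bogus", "EL", "I", eta=1, Delta=0, sigma=1)
        cfg = NetworkConfig.for_topology("aperiodic")
        bad = WeightBlockSpec("I_to_E", "I", "EL", eta=1, Delta=0, sigma=1)
        with pytest.raises(ConfigurationError):
            build_weight_block(bad, cfg)  # missing mu/delta_cut


class TestPerturbation:
    def test_identity(self, small_config, small_weights):
        w, cfg = apply_perturbation(small_weights, small_config, 1.0, 1.0)
        np.testing.assert_array_equal(
            w.combined(cfg), small_weights.combined(small_config)
        )
        assert cfg.tau_syn == small_config.tau_syn

    def test_scales_only_inhibitory_sources(self, small_config, small_weights):
        w, cfg = apply_perturbation(small_weights, small_config, gamma_inh=1.33)
        for (tgt, src) in w.blocks:
            eff0 = small_weights.effective_block(tgt, src)
            eff1 = w.effective_block(tgt, src)
            factor = 1.33 if src == "I" else 1.0
            np.testing.assert_allclose(eff1, factor * eff0)
        assert cfg.gamma_inh == pytest.approx(1.33)

    def test_inverse_recovers_weights(self, small_config, small_weights):
        w2, cfg2 = apply_perturbation(small_weights, small_config, gamma_inh=2.0)
        w3, _ = apply_perturbation(w2, cfg2, gamma_inh=0.5)
        np.testing.assert_allclose(
            w3.combined(small_config), small_weights.combined(small_config),
            rtol=1e-12,
        )

    def test_rejects_nonpositive_factors(self, small_config, small_weights):
        with pytest.raises(ConfigurationError):
            apply_perturbation(small_weights, small_config, gamma_inh=0)


def test_effective_inhibition_is_negative(small_config, small_weights):
    W = small_weights.combined(small_config, signed=True)
    n_exc = small_config.N_EL + small_config.N_ER
    assert np.all(W[:, n_exc:] <= 0)
    assert np.all(W[:, :n_exc] >= 0)


def test_config_roundtrip_yaml(tmp_path, small_config):
    path = tmp_path / "cfg.yaml"
    small_config.to_yaml(path)
    loaded = NetworkConfig.from_yaml(path)
    assert loaded == small_config


def test_weight_npz_roundtrip(tmp_path, small_weights):
    path = tmp_path / "w.npz"
    small_weights.save_npz(path)
    from gridperturb.net_core import WeightMatrix

    loaded = WeightMatrix.load_npz(path)
    for key in small_weights.blocks:
        np.testing.assert_array_equal(loaded.blocks[key], small_weights.blocks[key])


def test_default_sizes_and_rho():
    cfg = NetworkConfig()
    assert (cfg.N_EL, cfg.N_ER, cfg.N_I) == (400, 400, 160)
    assert cfg.N_I * 5 == cfg.N_EL + cfg.N_ER
    assert NetworkConfig.for_topology("fully_periodic").rho == 11
    assert NetworkConfig.for_topology("partially_periodic").rho == 1
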