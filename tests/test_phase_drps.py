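"""Phase analysis: DRPS construction, quanta, peak laws, alpha inference,
periodicity score, bootstrap, subsampling, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter1d

from gridperturb.lnp_sim import make_trajectory
from gridperturb.phase_drps import (DRPS, alt_shift_transform,
                                    bootstrap_phase_uncertainty,
                                    classify_architecture, count_peaks, drps,
                                    drps_from_relative_phases, idealized_pattern,
                                    infer_alpha, max_resolvable_stretch,
                                    peak_positions, periodicity_score,
                                    phase_magnitude, phase_wrap_2d,
                                    population_phase, quantum_of_shift,
                                    relative_phase_1d, relative_phase_2d,
                                    subsample_drps_distance, wrap_half)


class TestPhasePrimitives:
    def test_population_phase(self):
        assert population_phase(1, 20.0) == 0.0
        assert population_phase(21, 20.0) == pytest.approx(0.0)
        assert population_phase(11, 20.0) == pytest.approx(0.5)
        # non-integer period
        assert population_phase(41, 40 / 3) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("phi,expected", [(0.7, 0.3), (-0.4, 0.4),
                                              (0.5, 0.5), (0.0, 0.0),
                                              (1.3, 0.3)])
    def test_phase_magnitude(self, phi, expected):
        assert phase_magnitude(phi) == pytest.approx(expected)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(phi=st.floats(-5, 5))
    def test_magnitude_invariances(self, phi):
        m = phase_magnitude(phi)
        assert 0 <= m <= 0.5
        assert phase_magnitude(-phi) == pytest.approx(m)
        assert phase_magnitude(phi + 1.0) == pytest.approx(m)

    def test_quantum_and_resolvability(self):
        assert quantum_of_shift(0.1) == pytest.approx(0.1 / 1.1)
        assert max_resolvable_stretch(5) == 0.1
        assert round(max_resolvable_stretch(7), 2) <= 0.07

    def test_2d_wrap_branches(self):
        assert phase_wrap_2d(0.7, 0.2) == (pytest.approx(-0.3), pytest.approx(0.2))
        assert phase_wrap_2d(0.2, 0.2) == (pytest.approx(0.2), pytest.approx(0.2))
        assert phase_wrap_2d(0.7, 0.8) == (pytest.approx(-0.3), pytest.approx(-0.2))
        assert phase_wrap_2d(0.2, 0.8) == (pytest.approx(0.2), pytest.approx(-0.2))


class TestIdealizedPattern:
    def test_zero_alpha_identity(self):
        pre, post = idealized_pattern(100, 20.0, alpha=0.0)
        np.testing.assert_allclose(pre.phases, post.phases)

    def test_shift_grows_by_one_quantum_per_period(self):
        lam, alpha = 20.0, 0.1
        pre, post = idealized_pattern(200, lam, alpha)
        delta = quantum_of_shift(alpha)
        for K in (1, 2, 3):
            i = int(K * lam)  # cell K periods from the focus (1-based index i+1)
            shift = wrap_half(pre.phases[i] - post.phases[i])
            assert shift == pytest.approx(wrap_half(K * delta), abs=1e-9)

    def test_2d_defaults(self):
        pre, post = idealized_pattern(40, 40 / 3, 0.1, dims=2)
        assert pre.phases.shape == (1600, 2)
        assert pre.dims == 2

    def test_focus_independence_of_drps_width(self):
        a = drps(*idealized_pattern(100, 100 / 3, 0.05, focus=1))
        b = drps(*idealized_pattern(100, 100 / 3, 0.05, focus=40))
        assert a.sigma == pytest.approx(b.sigma, rel=0.1)


class TestDRPS:
    def test_unperturbed_is_degenerate(self):
        phases = np.linspace(0, 1, 50, endpoint=False)
        d = drps(phases, phases)
        assert d.sigma == 0.0
        assert np.all(d.shifts == 0)
        assert count_peaks(d) == 0

    def test_pair_count(self):
        pre, post = idealized_pattern(100, 100 / 3, 0.1)
        d = drps(pre, post)
        assert d.n_pairs == 100 * 99 // 2 == 4950

    def test_histogram_mass_equals_samples(self):
        pre, post = idealized_pattern(60, 20.0, 0.05)
        d = drps(pre, post)
        assert d.raw.sum() == d.n_pairs
        assert len(d.raw) == 200

    @pytest.mark.parametrize("alpha", [0.02, 0.05, 0.1])
    def test_quantum_peak_spacing(self, alpha):
        # median peak spacing equals Delta within one histogram bin; spacings
        # below the smoothing scale are resolved on the raw histogram
        pre, post = idealized_pattern(100, 100 / 3, alpha)
        d = drps(pre, post)
        use_smoothed = quantum_of_shift(alpha) > 4.0 / 200
        pos = np.sort(peak_positions(d, use_smoothed=use_smoothed))
        spacing = np.diff(pos)
        assert len(spacing) >= 3
        assert abs(np.median(spacing) - quantum_of_shift(alpha)) <= 1.0 / 200 + 1e-9

    @pytest.mark.parametrize("M", [3, 5])
    def test_peak_count_law(self, M):
        # 2M nonzero peaks when M * Delta < 1/2 (per-cell construction)
        pre, post = idealized_pattern(100, 100 / M, 0.05)
        d = drps(pre, post, mode="per_cell_population")
        assert M * quantum_of_shift(0.05) < 0.5
        assert count_peaks(d) == 2 * M

    def test_aliasing_undercount(self):
        # M * Delta > 1/2: peak count underestimates 2M
        M, alpha = 5, 0.2
        pre, post = idealized_pattern(100, 100 / M, alpha)
        d = drps(pre, post, mode="pairwise_relative")
        assert M * quantum_of_shift(alpha) > 0.5
        assert count_peaks(d) < 2 * M

    def test_2d_components_and_bump_count_rule(self):
        pre, post = idealized_pattern(40, 40 / 3, 0.05, dims=2)
        ds = drps(pre, post, mode="per_cell_population")
        assert len(ds) == 2
        p1, p2 = count_peaks(ds[0]), count_peaks(ds[1])
        assert p1 * p2 / 4 == pytest.approx((40 / (40 / 3)) ** 2)

    def test_mismatched_identities_rejected(self):
        with pytest.raises(ValueError):
            drps(np.zeros(5), np.zeros(6))


class TestEquivalenceOfConstructions:
    def test_tuning_curve_phases_match_population_phases(self):
        """Relative phases measured from synthetic spatial tuning curves agree
        with the direct population-phase differences (the core claim that
        spatial relative phase mirrors population phase)."""
        lam_pop, N, alpha = 20.0, 60, 0.1
        lam_space = 50.0  # cm per population period
        x = np.arange(0.0, 400.0, 1.0)
        pre_set, post_set = idealized_pattern(N, lam_pop, alpha)
        rng = np.random.default_rng(0)
        cells = rng.choice(N, 12, replace=False)
        for phases in (pre_set.phases,):
            curves = [1 + np.cos(2 * np.pi * (x / lam_space - phases[c]))
                      for c in cells]
            for a in range(0, len(cells), 3):
                for b in range(1, len(cells), 4):
                    if a == b:
                        continue
                    delta, lam = relative_phase_1d(curves[a], curves[b])
                    expected = wrap_half(phases[cells[b]] - phases[cells[a]])
                    # one histogram bin tolerance (1/200), sign convention:
                    # positive delta = curve b shifted rightward
                    assert delta == pytest.approx(expected, abs=2.0 / 200)

    def test_relative_phase_antisymmetry_and_shift(self):
        x = np.arange(0.0, 400.0, 1.0)
        lam = 50.0
        a = 1 + np.cos(2 * np.pi * x / lam)
        b = 1 + np.cos(2 * np.pi * (x - lam / 4) / lam)  # b shifted right by lam/4
        dab, _ = relative_phase_1d(a, b)
        dba, _ = relative_phase_1d(b, a)
        assert dab == pytest.approx(0.25, abs=0.01)
        assert dba == pytest.approx(-0.25, abs=0.01)

    def test_identical_curves_zero_phase(self):
        x = np.arange(400.0)
        a = 1 + np.sin(2 * np.pi * x / 40.0)
        assert relative_phase_1d(a, a)[0] == pytest.approx(0.0, abs=1e-6)

    def test_period_mismatch_rejected(self):
        x = np.arange(400.0)
        a = 1 + np.sin(2 * np.pi * x / 40.0)
        b = 1 + np.sin(2 * np.pi * x / 60.0)
        with pytest.raises(ValueError):
            relative_phase_1d(a, b)
        with pytest.raises(ValueError):
            relative_phase_1d(a, np.full(400, 2.0))


class TestRelativePhase2D:
    def make_map(self, ph1, ph2, lam=12.0, n=60):
        i = np.arange(n)
        X, Y = np.meshgrid(i, i, indexing="ij")
        return (np.cos(2 * np.pi * (X / lam - ph1))
                + np.cos(2 * np.pi * (Y / lam - ph2)) + 2)

    def test_recovers_imposed_shift(self):
        lattice = (12.0, [1, 0], 12.0, [0, 1])
        m1 = self.make_map(0.0, 0.0)
        m2 = self.make_map(0.25, -0.1)
        d1, d2 = relative_phase_2d(m1, m2, lattice)
        assert d1 == pytest.approx(0.25, abs=0.02)
        assert d2 == pytest.approx(-0.1, abs=0.02)

    def test_identical_maps(self):
        lattice = (12.0, [1, 0], 12.0, [0, 1])
        m = self.make_map(0.1, 0.2)
        d1, d2 = relative_phase_2d(m, m, lattice)
        assert (d1, d2) == (pytest.approx(0.0, abs=1e-6),
                            pytest.approx(0.0, abs=1e-6))

    def test_degenerate_lattice_rejected(self):
        with pytest.raises(ValueError):
            relative_phase_2d(np.ones((4, 4)), np.ones((4, 4)),
                              (10.0, [1, 0], 10.0, [1, 0]))


class TestAltTransformAndAlphaInference:
    def test_zero_alpha_unperturbed(self):
        phases = np.linspace(0, 1, 40, endpoint=False)
        out = alt_shift_transform(phases, phases, 0.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    @pytest.mark.parametrize("M", [3, 5])
    def test_exactly_m_clusters_spaced_alpha(self, M):
        alpha = 0.1
        pre, post = idealized_pattern(100, 100 / M, alpha)
        vals = alt_shift_transform(pre.phases, post.phases, alpha)
        clusters = np.unique(np.round(vals, 6))
        assert len(clusters) == M
        np.testing.assert_allclose(np.diff(np.sort(clusters)), alpha, atol=1e-6)

    @pytest.mark.parametrize("alpha_true", [0.05, 0.10])
    @pytest.mark.parametrize("M", [3, 5])
    def test_alpha_recovery(self, alpha_true, M):
        pre, post = idealized_pattern(100, 100 / M, alpha_true)
        alpha_hat, diag = infer_alpha(pre.phases, post.phases)
        assert abs(alpha_hat - alpha_true) <= 0.005
        assert not diag["inconclusive"]

    def test_alpha_recovery_under_subsampling(self, rng):
        pre, post = idealized_pattern(100, 100 / 5, 0.10)
        idx = rng.choice(100, 20, replace=False)
        alpha_hat, _ = infer_alpha(pre.phases[idx], post.phases[idx])
        assert abs(alpha_hat - 0.10) <= 0.005

    def test_unperturbed_flagged_inconclusive(self):
        phases = np.linspace(0, 1, 60, endpoint=False)
        _, diag = infer_alpha(phases, phases)
        assert diag["inconclusive"]


class TestPeriodicityScore:
    def test_pure_sinusoid_scores_one(self):
        h = np.sin(2 * np.pi * 5 * np.arange(200) / 200)
        assert periodicity_score(h) == pytest.approx(1.0, abs=1e-9)

    def test_flat_scores_zero(self):
        assert periodicity_score(np.full(200, 3.0)) == 0.0
        assert periodicity_score(np.zeros(200)) == 0.0

    def test_iid_uniform_average_below_threshold(self, rng):
        scores = [periodicity_score(rng.uniform(size=200)) for _ in range(300)]
        assert np.mean(scores) < 0.2

    def test_accepts_drps_object(self):
        pre, post = idealized_pattern(100, 100 / 3, 0.1)
        d = drps(pre, post)
        assert 0.0 <= periodicity_score(d) <= 1.0 + 1e-9


class TestSubsampling:
    def test_full_sample_distance_zero(self):
        pre, post = idealized_pattern(40, 40 / 3, 0.1, dims=1)
        assert subsample_drps_distance(pre.phases, post.phases, 40,
                                       n_draws=3, rng=0) == pytest.approx(
            0.0, abs=1e-3)

    def test_distance_decreases_with_n(self):
        pre, post = idealized_pattern(40, 40 / 3, 0.1, dims=2)
        p1, p2 = pre.phases[:, 0], post.phases[:, 0]
        dists = [subsample_drps_distance(p1, p2, n, n_draws=10, rng=1)
                 for n in (5, 20, 80, 400)]
        assert np.all(np.diff(dists) < 0)

    def test_ten_of_1600_preserves_peak_positions(self, rng):
        # the aggregate DRPS over repeated 10-cell samples retains the
        # multi-peak structure of the full-population DRPS
        pre, post = idealized_pattern(40, 40 / 3, 0.1, dims=2)
        p_pre, p_post = pre.phases[:, 0], post.phases[:, 0]
        d_full = drps(p_pre, p_post)
        full_peaks = peak_positions(d_full)
        agg = np.zeros(200)
        for _ in range(20):
            idx = rng.choice(1600, 10, replace=False)
            d_sub = drps(p_pre[idx], p_post[idx])
            agg += d_sub.smoothed
        sub = DRPS(agg, gaussian_filter1d(agg, 2.0, mode="wrap"),
                   d_full.bin_edges, 0.0, 20 * 45)
        sub_peaks = peak_positions(sub, prominence_frac=0.1)
        assert len(sub_peaks) >= 3
        for p in sub_peaks:
            assert np.min(np.abs(full_peaks - p)) <= 1.0 / 200 + 1e-9

    def test_too_few_cells_rejected(self):
        pre, post = idealized_pattern(40, 40 / 3, 0.1)
        with pytest.raises(ValueError):
            subsample_drps_distance(pre.phases, post.phases, 1)


class TestBootstrapUncertainty:
    @staticmethod
    def spike_pair(T_s, rate, lam, seed):
        rng = np.random.default_rng(seed)
        traj = make_trajectory(T_s, "quasi_random", seed=seed, dt_ms=5.0)
        out = []
        for ph in (0.0, 0.6):
            r = rate * (1 + np.sin(2 * np.pi * traj.x / lam + ph))
            spk = rng.random(len(r)) < r * traj.dt / 1000.0
            out.append(traj.x[spk])
        return out

    def test_concentrated_map_near_zero_uncertainty(self, rng):
        xi = np.full(300, 100.0) + rng.normal(0, 0.1, 300)
        xj = np.full(300, 130.0) + rng.normal(0, 0.1, 300)
        # delta-like maps: relative phase is pinned, bootstrap spread tiny
        u = bootstrap_phase_uncertainty(xi, xj, n_boot=30, rng=0)
        assert u.value < 0.01

    def test_unreliable_flag_below_50_spikes(self):
        xi, xj = self.spike_pair(30.0, 1.0, 50.0, seed=4)
        u = bootstrap_phase_uncertainty(xi[:40], xj[:40], n_boot=10, rng=0)
        assert not u.reliable

    def test_uncertainty_shrinks_with_record_length(self):
        u2 = bootstrap_phase_uncertainty(
            *self.spike_pair(120.0, 12.0, 50.0, seed=5), n_boot=50, rng=1)
        u16 = bootstrap_phase_uncertainty(
            *self.spike_pair(960.0, 12.0, 50.0, seed=5), n_boot=50, rng=1)
        assert u16.value < u2.value


class TestClassifier:
    def make_series(self, widths, amp=0.2, per=0.1, peaks=6):
        strengths = [1.0, 1.165, 1.33, 1.66]
        return [(s, 0.0 if k == 0 else amp, 0.0 if k == 0 else per,
                 w, peaks if w > 0.02 else 0)
                for k, (s, w) in enumerate(zip(strengths, widths))]

    def test_ramp_is_aperiodic(self):
        res = classify_architecture(self.make_series([0, 0.05, 0.1, 0.15]))
        assert res.label == "aperiodic recurrent"

    def test_step_is_partially_periodic(self):
        res = classify_architecture(self.make_series([0, 0.0, 0.2, 0.2]))
        assert res.label == "partially periodic recurrent"
        assert res.details.get("bump_estimate_is_lower_bound")

    def test_narrow_drps_with_period_change_is_fully_periodic(self):
        res = classify_architecture(self.make_series([0, 0.004, 0.005, 0.006]))
        assert res.label == "fully periodic recurrent"

    def test_flat_period_and_zero_width_is_feedforward(self):
        series = self.make_series([0, 0.0, 0.0, 0.0], per=0.0)
        res = classify_architecture(series)
        assert res.label == "feedforward"

    def test_no_amplitude_change_means_not_in_effect(self):
        series = self.make_series([0, 0.1, 0.2, 0.3], amp=0.0)
        assert classify_architecture(series).label == "perturbation not in effect"

    def test_bump_estimate_from_peaks(self):
        res = classify_architecture(self.make_series([0, 0.05, 0.1, 0.15],
                                                     peaks=10))
        assert res.bump_estimate == 5.0

    def test_too_few_strengths_rejected(self):
        with pytest.raises(ValueError):
            classify_architecture(self.make_series([0, 0.1, 0.2, 0.3])[:2])


def test_drps_from_relative_phases_matches_phase_route():
    pre, post = idealized_pattern(50, 50 / 3, 0.1)
    i, j = np.triu_indices(50, k=1)
    d_pre = wrap_half(pre.phases[i] - pre.phases[j])
    d_post = wrap_half(post.phases[i] - post.phases[j])
    a = drps_from_relative_phases(d_pre, d_post)
    b = drps(pre, post, mode="pairwise_relative")
    np.testing.assert_array_equal(a.raw, b.raw)
    assert a.sigma == pytest.approx(b.sigma)
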