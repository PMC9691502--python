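"""Spike-generator unit tests: deterministic rules, linearized and
exponential stochastic rules, EOD-grid behavior, and the noisy-time-constant
equivalence."""

import math

import numpy as np
import pytest

from dynthresh import (
    ARNoiseSpec,
    DomainError,
    EODGrid,
    ModelParams,
    ParameterError,
    SCCEstimatorConfig,
    estimate_sccs,
    generate_ar1,
    simulate_deterministic,
    simulate_exponential,
    simulate_isis,
    simulate_linearized,
    tau_sequence_from_threshold_noise,
)


class TestModelParams:
    def test_gamma_defaults_to_half_jump(self):
        p = ModelParams(v=1.845, A=0.15, tau=30.0)
        assert p.gamma == pytest.approx(0.075)

    def test_slope_and_deterministic_isis(self):
        p = ModelParams(v=1.845, A=0.15, tau=30.0, gamma=0.075)
        assert p.m == pytest.approx(1.92 / 30.0)
        assert p.isi_linearized == pytest.approx(4.5 / 1.92)  # = 2.34375 ms
        assert p.isi_exponential == pytest.approx(30.0 * math.log(1.92 / 1.77))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(v=-1.0, A=0.1, tau=30.0),
            dict(v=1.0, A=0.0, tau=30.0),
            dict(v=1.0, A=0.1, tau=-5.0),
            dict(v=1.0, A=0.1, tau=30.0, gamma=1.5),  # v - gamma <= 0
        ],
    )
    def test_invalid_params_name_the_invariant(self, kwargs):
        with pytest.raises(ParameterError):
            ModelParams(**kwargs)


class TestDeterministic:
    def test_constant_isi_hand_value(self):
        p = ModelParams(v=1.845, A=0.15, tau=30.0, gamma=0.075)
        train = simulate_deterministic(p, n_spikes=10)
        isis = train.isis().intervals
        assert train.times[0] == 0.0
        np.testing.assert_allclose(isis, 2.34375, rtol=1e-12)

    def test_small_jump_limit_shrinks_isi(self):
        isi = lambda A: ModelParams(v=1.0, A=A, tau=20.0, gamma=0.0).isi_linearized
        assert isi(1e-6) < isi(1e-3) < isi(0.1)
        assert isi(1e-9) == pytest.approx(0.0, abs=1e-7)

    def test_bias_at_threshold_gives_isi_tau(self):
        # v = gamma cancels: A*tau/A = tau
        p = ModelParams(v=1.0, A=0.2, tau=17.0, gamma=1.0 - 1e-12)
        assert p.isi_linearized == pytest.approx(17.0)

    def test_needs_two_spikes(self):
        p = ModelParams(v=1.0, A=0.1, tau=10.0)
        with pytest.raises(ParameterError):
            simulate_deterministic(p, n_spikes=1)


class TestLinearized:
    def test_zero_noise_reduces_to_deterministic(self, fig6_params):
        isis = simulate_linearized(fig6_params, np.zeros(11))
        np.testing.assert_allclose(isis.intervals, fig6_params.isi_linearized)

    def test_single_perturbation_balances(self, fig6_params):
        delta = 0.01
        isis = simulate_linearized(fig6_params, np.array([0.0, delta, 0.0]))
        m = fig6_params.m
        assert isis.intervals[0] == pytest.approx((delta + 0.15) / m)
        assert isis.intervals[1] == pytest.approx((-delta + 0.15) / m)
        base = fig6_params.isi_linearized
        devs = isis.intervals - base
        assert devs[0] == pytest.approx(-devs[1])

    def test_nonpositive_isi_reports_index(self, fig6_params):
        g = np.zeros(5)
        g[3] = -0.2  # drop larger than A between intervals 2 and 3
        with pytest.raises(DomainError) as exc:
            simulate_linearized(fig6_params, g)
        assert exc.value.index == 2

    def test_mean_isi_is_jump_over_slope(self, fig6_params):
        spec = ARNoiseSpec.from_snr(a=0.4, sign=+1, snr_db=45.0, v=1.845)
        noise = generate_ar1(spec, 100_001, seed=5)
        isis = simulate_linearized(fig6_params, noise)
        se = isis.intervals.std() / np.sqrt(len(isis))
        assert isis.mean == pytest.approx(fig6_params.isi_linearized, abs=4 * se)

    def test_ar1_noise_recovers_closed_form_rho1(self, fig6_params):
        # slow AR(1) noise with magnitude a gives rho_1 = -(1 - a)/2
        spec = ARNoiseSpec.from_snr(a=0.4, sign=+1, snr_db=45.0, v=1.845)
        noise = generate_ar1(spec, 300_001, seed=11)
        est = estimate_sccs(simulate_linearized(fig6_params, noise))
        assert est.rho[1] == pytest.approx(-0.3, abs=max(3 * est.se[1], 0.01))


class TestExponential:
    def test_zero_noise_log_crossing(self, fig6_params):
        train = simulate_exponential(fig6_params, np.zeros(11))
        expected = 30.0 * math.log(1.92 / 1.77)  # = 2.4403... ms
        np.testing.assert_allclose(train.isis().intervals, expected, rtol=1e-12)
        assert expected == pytest.approx(2.4403, abs=2e-4)

    def test_grid_ceils_to_next_cycle(self, fig6_params):
        # continuous crossing ~2.44 ms, grid far coarser -> exactly one period
        grid = EODGrid(period=5.0)
        train = simulate_exponential(fig6_params, np.zeros(11), grid=grid)
        np.testing.assert_allclose(train.isis().intervals, 5.0)
        isis_eod = train.isis(unit="eod")
        np.testing.assert_allclose(isis_eod.intervals, 1.0)

    def test_grid_invariants(self, fig6_params, type1_spec):
        grid = EODGrid(period=1.06)
        noise = generate_ar1(type1_spec, 2001, seed=2)
        train = simulate_exponential(fig6_params, noise, grid=grid)
        ratio = train.times / 1.06
        np.testing.assert_allclose(ratio, np.rint(ratio), atol=1e-9)
        assert np.all(np.diff(train.times) >= 1.06 - 1e-9)

    def test_no_crossing_raises(self):
        p = ModelParams(v=1.0, A=0.1, tau=10.0, gamma=0.9)
        g = np.array([0.0, 0.2, 0.0])  # realized threshold 1.1 > v
        with pytest.raises(DomainError):
            simulate_exponential(p, g)

    def test_agrees_with_linearized_to_first_order(self, fig6_params):
        # deterministic ISIs differ at O((T1/tau)^2) ~ 0.3%
        lin = fig6_params.isi_linearized
        expo = fig6_params.isi_exponential
        assert abs(expo - lin) / lin < (lin / fig6_params.tau)

    def test_scc_invariant_to_encoder_constants(self):
        # same noise ACF, different (v, A, tau, gamma), grid disabled:
        # the correlation structure depends on the noise alone
        spec = ARNoiseSpec.from_snr(a=0.4, sign=+1, snr_db=45.0, v=1.845)
        cfg = SCCEstimatorConfig()
        pa = ModelParams(v=1.845, A=0.15, tau=30.0)
        pb = ModelParams(v=1.845, A=0.30, tau=18.0, gamma=0.0)
        ra = estimate_sccs(simulate_isis(pa, spec, 150_000, seed=9), cfg)
        rb = estimate_sccs(simulate_isis(pb, spec, 150_000, seed=9), cfg)
        tol = 3 * np.hypot(ra.se[1:4], rb.se[1:4])
        np.testing.assert_allclose(ra.rho[1:4], rb.rho[1:4], atol=tol.max())


class TestTauEquivalence:
    def test_zero_noise_gives_constant_tau(self, fig6_params):
        seq = tau_sequence_from_threshold_noise(fig6_params, np.zeros(6))
        np.testing.assert_allclose(seq.tau_i, 30.0)
        np.testing.assert_allclose(seq.m_i, fig6_params.m)

    def test_half_jump_excursion_hand_values(self, fig6_params):
        g = np.array([0.0, 0.075, 0.0])  # A/2 excursion
        seq = tau_sequence_from_threshold_noise(fig6_params, g)
        np.testing.assert_allclose(seq.tau_i, [45.0, 15.0])  # 1.5 tau, 0.5 tau

    def test_full_jump_excursion_hits_boundary(self, fig6_params):
        g = np.array([0.0, 0.15, 0.0])  # excursion = A makes tau_2 = 0
        with pytest.raises(DomainError):
            tau_sequence_from_threshold_noise(fig6_params, g)

    def test_tau_sequence_mean_and_scc_match_isis(self, fig6_params):
        spec = ARNoiseSpec.from_snr(a=0.4, sign=+1, snr_db=45.0, v=1.845)
        noise = generate_ar1(spec, 100_001, seed=21)
        seq = tau_sequence_from_threshold_noise(fig6_params, noise)
        isis = simulate_linearized(fig6_params, noise)
        assert seq.tau_i.mean() == pytest.approx(30.0, rel=1e-3)
        # tau_i is proportional to ISI_i, so SCCs are identical
        from dynthresh.model import ISISequence

        r_tau = estimate_sccs(ISISequence(seq.tau_i, unit="ms"))
        r_isi = estimate_sccs(isis)
        np.testing.assert_allclose(r_tau.rho, r_isi.rho, atol=1e-12)

    def test_noisy_tau_train_reproduces_noisy_gamma_train(self, fig6_params):
        # linearized spike times from per-interval tau_i with fixed gamma
        # coincide with the gamma-noise spike times, point for point
        spec = ARNoiseSpec.from_snr(a=0.3, sign=-1, snr_db=45.0, v=1.845)
        noise = generate_ar1(spec, 1001, seed=3)
        isis_gamma = simulate_linearized(fig6_params, noise)
        seq = tau_sequence_from_threshold_noise(fig6_params, noise)
        isis_tau = fig6_params.A * seq.tau_i / (fig6_params.v - fig6_params.gamma + fig6_params.A)
        np.testing.assert_allclose(isis_tau, isis_gamma.intervals, rtol=1e-12)
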