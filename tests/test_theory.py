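"""Ring closed forms, order parameters, reduced dynamics, regime boundaries."""

import numpy as np
import pytest

from conjgrid import network1d as n1, theory


RING = theory.RingReduction()          # J0=-50, J1=20, beta=0.5, k=2, tau=10


def simulate_ring(psi, J0=-50.0, J1=20.0, n=96, T=800.0, I0=1.0, k=2,
                  tau=10.0, dt=0.5):
    """Direct ring simulation oracle; returns (drift rad/ms, final rates)."""
    th = np.arange(n) * 2 * np.pi / n
    W = (J0 + J1 * np.cos(k * (th[:, None] - th[None, :]) - psi)) / n
    m = np.maximum(np.cos(k * th), 0.0)
    ph = []
    for _ in range(int(T / dt)):
        def f(mm):
            return (-mm + np.maximum(I0 + W @ mm, 0.0)) / tau
        k1 = f(m); k2 = f(m + dt / 2 * k1); k3 = f(m + dt / 2 * k2); k4 = f(m + dt * k3)
        m = m + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        ph.append(np.angle(np.mean(m * np.exp(1j * k * th))))
    ph = np.unwrap(np.array(ph))
    half = len(ph) // 2
    drift = np.polyfit(np.arange(half) * dt, ph[half:], 1)[0] / k
    return drift, m


class TestRingSpeed:
    def test_zero_at_zero_label(self):
        assert theory.ring_speed(0.0, RING) == 0.0

    @pytest.mark.parametrize("vhat", [0.1, 0.4, 0.9])
    def test_odd_symmetry(self, vhat):
        assert theory.ring_speed(-vhat, RING) == -theory.ring_speed(vhat, RING)

    def test_monotone_near_zero(self):
        v = np.linspace(0.0, 0.5, 11)
        sp = [theory.ring_speed(x, RING) for x in v]
        assert np.all(np.diff(sp) > 0)

    @pytest.mark.parametrize("vhat", [0.2, 0.8, 1.6])
    def test_matches_simulated_ring_drift(self, vhat):
        # full ring simulation oracle, relative error < 5% (actually ~1e-4)
        drift, _ = simulate_ring(RING.beta * vhat)
        pred = theory.ring_speed(vhat, RING)
        assert drift == pytest.approx(pred, rel=5e-2)

    def test_outside_admissible_range_raises(self):
        lo, hi = theory.ring_admissible_vhat(RING)
        with pytest.raises(ValueError):
            theory.ring_speed(hi * 1.01, RING)


class TestRingAmplitude:
    def test_even_symmetry(self):
        assert theory.ring_amplitude(0.7, RING) == pytest.approx(
            theory.ring_amplitude(-0.7, RING), rel=1e-12)

    def test_vanishes_toward_range_limit(self):
        _, hi = theory.ring_admissible_vhat(RING)
        a_mid = theory.ring_amplitude(0.0, RING)
        a_edge = theory.ring_amplitude(0.98 * hi, RING)
        assert a_edge < 0.1 * a_mid

    @pytest.mark.parametrize("vhat", [0.0, 0.8, 1.6])
    def test_matches_simulated_ring_amplitude(self, vhat):
        _, m = simulate_ring(RING.beta * vhat)
        th = np.arange(len(m)) * 2 * np.pi / len(m)
        r1 = 2.0 * abs(np.mean(m * np.exp(-1j * RING.k * th)))
        assert r1 == pytest.approx(theory.ring_amplitude(vhat, RING), rel=0.05)


class TestAdmissibleRanges:
    def test_vhat_interval_symmetric(self):
        lo, hi = theory.ring_admissible_vhat(RING)
        assert lo == -hi
        assert hi == pytest.approx(np.arccos(2.0 / 20.0) / 0.5)

    def test_beta_interval_from_same_bound(self):
        lo, hi = theory.ring_admissible_beta(RING, v_max=0.5)
        assert lo == 0.0
        assert hi == pytest.approx(np.arccos(0.1) / 0.5)

    def test_binary_limit_contains_finite_gain_interval(self):
        hi_lin = theory.ring_admissible_vhat(RING)[1]
        ring_bin = theory.RingReduction(tf=n1.TransferFn("binary"))
        hi_bin = theory.ring_admissible_vhat(ring_bin)[1]
        assert hi_bin > hi_lin
        assert hi_bin == pytest.approx(0.5 * np.pi / RING.beta)

    def test_ring_sim_keeps_and_loses_bump_across_boundary(self):
        # existence boundary J1 cos(psi) = 2: bracket with simulations
        _, m_in = simulate_ring(0.3, J1=2.6)
        _, m_out = simulate_ring(0.3, J1=1.8)
        def harm(m):
            th = np.arange(len(m)) * 2 * np.pi / len(m)
            return abs(np.mean(m * np.exp(1j * 2 * th)))
        assert harm(m_in) > 1e-3
        assert harm(m_out) < 1e-6


class TestOrderParams:
    def test_uniform_state_amplitude_zero(self, test_manifold, default_wp):
        st = n1.RateState(0.0, np.full((20, 5), 0.2))
        op = theory.order_params_from_state(st, test_manifold, default_wp)
        assert op.amplitude == 0.0
        assert not op.defined

    def test_negative_rates_rejected(self, test_manifold, default_wp):
        st = n1.RateState(0.0, np.full((20, 5), -0.1))
        with pytest.raises(ValueError):
            theory.order_params_from_state(st, test_manifold, default_wp)

    @pytest.mark.parametrize("phase", [0.3, 2.0, 5.5])
    def test_recovers_spatial_phase_of_synthetic_bump(self, phase):
        man = n1.build_manifold_1d(128, 21, 0.5)
        wp = n1.WeightParams1D()
        expected = phase % (2 * np.pi / wp.k)
        # pure nonnegative harmonic: phase recovered to machine precision
        m = 1.0 + np.cos(wp.k * (man.theta_grid - phase))
        op = theory.order_params_from_state(n1.RateState(0.0, m), man, wp)
        assert op.psi_theta == pytest.approx(expected, abs=1e-8)
        # thresholded bump: recovery limited only by harmonic aliasing
        m2 = np.maximum(np.cos(wp.k * (man.theta_grid - phase)) - 0.2, 0.0)
        op2 = theory.order_params_from_state(n1.RateState(0.0, m2), man, wp)
        assert op2.psi_theta == pytest.approx(expected, abs=1e-3)


class TestReducedDynamics:
    def test_fixed_point_stays_fixed(self):
        man = n1.build_manifold_1d(48, 21, np.pi / 2)
        params = theory.ModelParams(man, n1.WeightParams1D(J0=-50, J1=24, beta=0.3))
        op = theory.static_fixed_point(params)
        ts, series = theory.integrate_order_dynamics(op, params, T=50.0)
        final = series[-1]
        assert final.amplitude == pytest.approx(op.amplitude, rel=1e-6)
        assert abs(final.M - op.M) < 1e-8

    def test_reduced_matches_full_network_steady_state(self):
        # same parameters: reduced ODE vs full network agree on (slant, x0)
        man = n1.build_manifold_1d(48, 21, np.pi / 2)
        wp = n1.WeightParams1D(J0=-50, J1=24, beta=0.3)
        params = theory.ModelParams(man, wp)
        st = n1.bump_seeded_state(man, wp, 0.0, sigma_v=10.0)  # spanning seed
        coupling = n1.LowRankCoupling1D(man, wp)
        tf, ip = n1.TransferFn(), n1.IntegratorParams()
        for _ in range(int(1500 / ip.dt)):
            st = n1.step_rk4(st, 1.0, coupling, tf, ip)
        op_full = theory.order_params_from_state(st, man, wp)
        op0 = theory.order_params_from_state(
            n1.bump_seeded_state(man, wp, 0.0, sigma_v=10.0), man, wp)
        _, series = theory.integrate_order_dynamics(op0, params, T=1500.0,
                                                    record_every=200)
        op_red = series[-1]
        assert op_red.slant == pytest.approx(op_full.slant, rel=0.01)
        assert op_red.threshold == pytest.approx(op_full.threshold, rel=0.01)

    def test_amplitude_divergence_reported(self):
        man = n1.build_manifold_1d(24, 11, np.pi / 2)
        # J0 > 0 with strong J1: runaway excitation
        wp = n1.WeightParams1D(J0=2.0, J1=30.0, beta=0.3)
        params = theory.ModelParams(man, wp)
        op0 = theory.OrderParams1D(slant=0, threshold=0, amplitude=0.1,
                                   psi_theta=0, psi_v=0, M=0.5,
                                   Za=0.05 + 0j, Zb=0.05 + 0j)
        with pytest.raises(theory.AmplitudeDivergence):
            theory.integrate_order_dynamics(op0, params, T=2000.0)


class TestStaticFixedPoint:
    def test_residual_below_tolerance(self):
        man = n1.build_manifold_1d(48, 21, np.pi / 2)
        params = theory.ModelParams(man, n1.WeightParams1D(J0=-50, J1=24, beta=0.3))
        op = theory.static_fixed_point(params)
        red = theory._Reduced(params)
        g = n1.transfer(red.u(op.M, op.Za, op.Zb), params.tf)
        M2, Za2, Zb2 = red.coupling.projections(g)
        assert abs(M2 - op.M) < 1e-8
        assert abs(Za2 - op.Za) < 1e-7
        assert abs(Zb2 - op.Zb) < 1e-7

    def test_slant_magnitude_decreases_with_beta(self):
        man = n1.build_manifold_1d(48, 21, np.pi / 2)
        slants = []
        for beta in [0.1, 0.25, 0.4]:
            params = theory.ModelParams(man, n1.WeightParams1D(J0=-50, J1=24,
                                                               beta=beta))
            slants.append(abs(theory.static_fixed_point(params).slant))
        assert slants[0] > slants[-1] or np.all(np.diff(slants) < 0.05)


class TestBoundaries:
    MAN = n1.build_manifold_1d(48, 21, np.pi / 2)

    def params(self, J0=-50.0, J1=20.0, beta=0.5):
        return theory.ModelParams(self.MAN, n1.WeightParams1D(J0=J0, J1=J1,
                                                              beta=beta))

    def test_zero_interaction_is_stable(self):
        # J1 below the boundary: homogeneous
        p = self.params(J1=0.5)
        assert theory.classify_regime(p).label == "homogeneous"

    def test_boundary_brackets_simulated_pattern_onset(self):
        from conjgrid import experiments
        p = self.params(J1=1.0, beta=0.3)
        J1c = theory.homogeneous_boundary(p)
        below = theory.ModelParams(self.MAN, n1.WeightParams1D(
            J0=-50.0, J1=0.95 * J1c, beta=0.3))
        above = theory.ModelParams(self.MAN, n1.WeightParams1D(
            J0=-50.0, J1=1.05 * J1c, beta=0.3))
        assert experiments.classify_by_simulation(below, seed=1) == "homogeneous"
        assert experiments.classify_by_simulation(above, seed=1) != "homogeneous"

    @staticmethod
    def _max_rate_sim(params, T_tau=100.0, cap=1e3):
        st = n1.jittered_initial_state(params.manifold, seed=2, level=0.1)
        coupling = n1.LowRankCoupling1D(params.manifold, params.wp)
        peak = 0.0
        try:
            for _ in range(int(T_tau * params.ip.tau / params.ip.dt)):
                st = n1.step_rk4(st, params.I0, coupling, params.tf, params.ip)
                peak = max(peak, st.m.max())
                if peak > cap:
                    return peak
        except n1.IntegrationFailure:
            return np.inf
        return peak

    def test_amplitude_bound_brackets_simulated_divergence(self):
        p = self.params(J1=24.0, beta=0.3)
        J0c = theory.amplitude_bound(p, J0_range=(-60.0, 5.0))
        ok = theory.ModelParams(self.MAN, n1.WeightParams1D(
            J0=J0c - 3.0, J1=24.0, beta=0.3))
        bad = theory.ModelParams(self.MAN, n1.WeightParams1D(
            J0=min(J0c + 3.0, -1e-6), J1=24.0, beta=0.3))
        assert self._max_rate_sim(ok) < 1e3
        assert self._max_rate_sim(bad) > 1e3

    def test_amplitude_bound_monotone_in_interaction_strength(self):
        # stronger structured coupling needs deeper uniform inhibition
        b1 = theory.amplitude_bound(self.params(J1=12.0, beta=0.3),
                                    J0_range=(-60.0, 5.0))
        b2 = theory.amplitude_bound(self.params(J1=30.0, beta=0.3),
                                    J0_range=(-60.0, 5.0))
        assert b2 < b1

    def test_traveling_onset_brackets(self):
        # the boundary along beta separates a traveling side from a static
        # side; theory and direct simulation agree on both sides
        from conjgrid import experiments
        p = self.params(J1=20.0)
        bc = theory.traveling_onset_beta(p, beta_range=(0.1, 1.2))
        sides = set()
        for beta in (0.8 * bc, 1.2 * bc):
            pp = theory.ModelParams(self.MAN, n1.WeightParams1D(
                J0=-50, J1=20, beta=beta))
            th = theory.classify_regime(pp).label
            sim = experiments.classify_by_simulation(pp, seed=2)
            assert th == sim
            sides.add(th)
        assert sides == {"static_bumps", "traveling_bumps"}

    def test_classify_examples(self):
        assert theory.classify_regime(self.params(J1=2.0)).label == "homogeneous"
        assert theory.classify_regime(self.params()).label == "traveling_bumps"
        assert theory.classify_regime(
            self.params(J1=12.0, beta=0.3)).label == "static_bumps"
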