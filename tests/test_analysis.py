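"""Decoding, rate maps, grid metrics, direction selectivity, field shifts."""

import numpy as np
import pytest

from conjgrid import analysis, network1d as n1


MAN = n1.build_manifold_1d(64, 21, 0.5)
K = 2


def synthetic_bump(phase, vhat, width=0.4):
    m = np.maximum(np.cos(K * (MAN.theta_grid - phase)) - 0.3, 0.0)
    m = m * np.exp(-((MAN.v_grid - vhat) ** 2) / (2 * 0.1 ** 2))
    return n1.RateState(0.0, m)


class TestBumpCenter:
    @pytest.mark.parametrize("phase,vhat", [(0.5, 0.0), (2.2, 0.25), (3.0, -0.3)])
    def test_recovers_known_center(self, phase, vhat):
        st = synthetic_bump(phase, vhat)
        pt, pv = analysis.bump_center(st, MAN, K)
        assert pt == pytest.approx(phase % (np.pi), abs=1e-3)
        assert pv == pytest.approx(vhat, abs=0.02)

    def test_uniform_state_raises(self):
        st = n1.RateState(0.0, np.full((64, 21), 0.5))
        with pytest.raises(analysis.UndefinedPhase):
            analysis.bump_center(st, MAN, K)

    def test_roll_equivariance(self):
        st = synthetic_bump(1.0, 0.0)
        pt0, _ = analysis.bump_center(st, MAN, K)
        st2 = n1.RateState(0.0, np.roll(st.m, 1, axis=0))
        pt1, _ = analysis.bump_center(st2, MAN, K)
        dbin = 2 * np.pi / 64
        assert (pt1 - pt0) % (np.pi) == pytest.approx(dbin, abs=1e-9)


class TestBumpVelocityAndDecode:
    def make_track(self, omega, T=1000.0, dt=1.0):
        t = np.arange(0, T, dt)
        psi = (omega * t) % (2 * np.pi / K)
        return analysis.make_track(t, psi, np.zeros_like(t), K)

    def test_static_bump_zero_velocity(self):
        tr = self.make_track(0.0)
        assert np.allclose(analysis.bump_velocity(tr), 0.0)

    @pytest.mark.parametrize("omega", [0.003, -0.008, 0.02])
    def test_imposed_drift_recovered(self, omega):
        tr = self.make_track(omega)
        v = analysis.bump_velocity(tr)
        assert np.allclose(v[1:], omega, atol=1e-12)

    def test_correct_across_wrap(self):
        # brute-force unwrap oracle on a drifting phase crossing 2pi/k
        omega, dt = 0.01, 1.0
        t = np.arange(0, 400.0, dt)
        true_phase = omega * t + 1.5
        tr = analysis.make_track(t, true_phase % (2 * np.pi / K),
                                 np.zeros_like(t), K)
        assert np.allclose(np.diff(tr.unwrapped_phase) / K / dt, omega)

    def test_decode_constant_drift_speed(self):
        S = 30.0
        omega = 0.005                      # rad/ms in psi_theta
        tr = self.make_track(omega)
        pos = analysis.decode_position(tr, S, K, anchor=12.0)
        v_cm_ms = np.gradient(pos, tr.t)
        expected = omega * K * S / (2 * np.pi)
        assert pos[0] == 12.0
        assert np.allclose(v_cm_ms[1:-1], expected, rtol=1e-9)

    def test_decode_zero_drift_constant(self):
        tr = self.make_track(0.0)
        pos = analysis.decode_position(tr, 30.0, K, anchor=5.0)
        assert np.allclose(pos, 5.0)

    def test_unwrap_failure_on_large_jumps(self):
        t = np.arange(0, 10.0, 1.0)
        psi = np.zeros_like(t)
        psi[5:] = 0.5 * np.pi
        with pytest.raises(analysis.UnwrapFailure):
            analysis.make_track(t, psi % (2 * np.pi / K), np.zeros_like(t), K)

    def test_roundtrip_decode_encode(self):
        omega = 0.004
        tr = self.make_track(omega)
        S = 30.0
        pos = analysis.decode_position(tr, S, K, anchor=0.0)
        phase_back = (pos * 2 * np.pi / S) / K + tr.psi_theta[0]
        assert np.allclose(phase_back % (2 * np.pi / K), tr.psi_theta,
                           atol=1e-9)


class TestTrackingError:
    def test_equal_series_zero(self):
        d = np.linspace(0, 10, 50)
        err, drift = analysis.tracking_error_and_drift(d, d)
        assert np.all(err == 0) and np.all(drift == 0)

    def test_constant_offset(self):
        d = np.linspace(0, 10, 50)
        err, drift = analysis.tracking_error_and_drift(d + 2.0, d)
        assert np.allclose(err, 2.0) and np.allclose(drift, 2.0)

    def test_mean_over_runs_matches_direct(self):
        rng = np.random.default_rng(0)
        runs = [rng.standard_normal(30) for _ in range(8)]
        _, drift = analysis.tracking_error_and_drift(runs[0], np.zeros(30),
                                                     runs=runs)
        direct = np.mean(np.abs(np.array(runs)), axis=0)
        assert np.allclose(drift, direct)


class TestRateMap:
    def test_constant_rate_flat_where_sampled(self):
        x = np.concatenate([np.linspace(0, 50, 500)])
        act = np.full_like(x, 1.7)
        rm = analysis.rate_map(act, [x], [np.arange(0, 101, 2.0)])
        sampled = np.isfinite(rm.rate)
        assert np.allclose(rm.rate[sampled], 1.7)
        # unvisited half of the track is marked missing
        assert np.all(~np.isfinite(rm.rate[30:]))

    def test_occupancy_sums_to_samples(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, 1000)
        rm = analysis.rate_map(np.ones_like(x), [x], [np.arange(0, 101, 2.0)])
        assert rm.occupancy.sum() == 1000

    def test_low_occupancy_masked(self):
        x = np.array([1.0, 1.2, 50.0])   # one sample in the 50-52 bin
        rm = analysis.rate_map(np.ones_like(x), [x], [np.arange(0, 101, 2.0)],
                               min_occ=2)
        assert np.isnan(rm.rate[25])
        assert np.isfinite(rm.rate[0])


def ideal_hex_map(spacing=30.0, stretch_y=1.0, n=150, bin_cm=2.0):
    x = np.arange(n) * bin_cm
    X, Y = np.meshgrid(x, x, indexing="ij")
    q = 4 * np.pi / (np.sqrt(3) * spacing)
    ang = [0.0, np.pi / 3, 2 * np.pi / 3]
    P = sum(np.cos(q * (np.cos(a) * X + np.sin(a) * Y / stretch_y))
            for a in ang)
    return np.maximum(P, 0.0)


class TestGridMetrics:
    def test_recovers_spacing_of_ideal_hexagonal_field(self):
        gm = analysis.grid_metrics(ideal_hex_map(spacing=24.0), bin_size=2.0)
        # the six nearest peaks sit one field spacing away
        assert gm.spacing_x == pytest.approx(24.0, abs=2.0)

    def test_isotropic_map_ellipse_ratio_one(self):
        gm = analysis.grid_metrics(ideal_hex_map(), bin_size=2.0)
        assert gm.ellipse_ratio == pytest.approx(1.0, abs=0.05)

    def test_stretched_map_ratio(self):
        gm = analysis.grid_metrics(ideal_hex_map(stretch_y=1.25), bin_size=2.0)
        assert gm.ellipse_ratio == pytest.approx(1.25, abs=0.08)

    def test_insufficient_structure_raises(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="insufficient"):
            analysis.grid_metrics(rng.random((10, 10)) * 0.01 + 5.0)

    def test_hex_angles_of_ideal_field(self):
        ac = analysis.autocorrelogram(ideal_hex_map())
        ang, dev = analysis.hex_peak_angles(ac)
        assert dev <= 5.0

    def test_lattice_ratio_isotropic_and_compressed(self):
        # offset-lattice template maps (the network's own pattern class)
        # domain commensurate with both lattices (120 = 4*30 = 5*24)
        x = np.arange(0, 120, 2.0)
        X, Y = np.meshgrid(x, x, indexing="ij")
        for Sy, expected in [(30.0, 1.0), (24.0, 1.25)]:
            q1x = 2 * np.pi / 30.0
            q2y = 2 * np.pi / Sy
            P = np.maximum(np.cos(q1x * X) + np.cos(-q1x / 2 * X + q2y * Y)
                           + np.cos(-q1x / 2 * X - q2y * Y), 0.0)
            Sx_m, Sy_m, ratio = analysis.lattice_spacing_ratio(P, bin_size=2.0)
            assert ratio == pytest.approx(expected, abs=0.08)


class TestDirectionSelectivity:
    def edges(self):
        return [np.linspace(-np.pi, np.pi, 25)]

    def test_tuned_unit_conjunctive(self):
        centers = 0.5 * (self.edges()[0][1:] + self.edges()[0][:-1])
        rng = np.random.default_rng(0)
        d = rng.uniform(-np.pi, np.pi, 4000)
        act = np.maximum(np.cos(d - 0.7), 0.0)
        rm = analysis.rate_map(act, [d], self.edges())
        assert analysis.direction_selectivity(rm) == "conjunctive"
        assert analysis.resultant_length(rm) > 0.2

    def test_untuned_unit_pure_grid(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(-np.pi, np.pi, 4000)
        rm = analysis.rate_map(np.ones_like(d), [d], self.edges())
        assert analysis.direction_selectivity(rm) == "pure_grid"


class TestFieldShift:
    def map_from(self, centers_cm, edges):
        x = 0.5 * (edges[1:] + edges[:-1])
        r = sum(np.exp(-((x - c) ** 2) / (2 * 3.0 ** 2)) for c in centers_cm)
        rm = analysis.RateMap(edges=(edges,), occupancy=np.full(len(x), 10),
                              rate=r)
        return rm

    def test_symmetric_maps_zero_shift(self):
        edges = np.arange(0, 201, 2.0)
        m = self.map_from([30, 60, 90, 120, 150], edges)
        assert analysis.field_shift({"left": m, "right": m}) == 0.0

    def test_shift_sign_matches_offset(self):
        edges = np.arange(0, 201, 2.0)
        a = self.map_from([30, 60, 90, 120, 150], edges)
        b = self.map_from([34, 64, 94, 124, 154], edges)
        shift = analysis.field_shift({"a_left": a, "b_right": b})
        assert shift == pytest.approx(4.0, abs=2.0)


class TestFieldPeaks1D:
    def test_spacing_of_synthetic_fields(self):
        edges = np.arange(0, 201, 2.0)
        x = 0.5 * (edges[1:] + edges[:-1])
        r = sum(np.exp(-((x - c) ** 2) / (2 * 3.0 ** 2))
                for c in [20, 50, 80, 110, 140, 170])
        rm = analysis.RateMap(edges=(edges,), occupancy=np.full(len(x), 5),
                              rate=r)
        peaks = analysis.find_field_peaks_1d(rm, min_separation=15.0)
        assert len(peaks) == 6
        assert np.allclose(np.diff(peaks), 30.0, atol=2.0)
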