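"""Scripted experiments: intrinsic-speed curve, linear-track path integration,
robustness sweeps, 2D arena exploration.

Each experiment takes an :class:`ExperimentConfig`, derives every random draw
from the listed seeds, and returns plain dictionaries of arrays so results
can be serialised alongside the config.  Desk-scale presets (coarser
manifolds, shorter durations) ship beside the full-scale ones; outputs echo
the preset used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from conjgrid import analysis, drive, network2d, trajectory
from conjgrid.network1d import (IntegratorParams, LowRankCoupling1D, Manifold1D,
                                RateState, TransferFn, WeightParams1D,
                                build_manifold_1d, build_weights_1d,
                                bump_seeded_state, dilute_weights,
                                jittered_initial_state, perturb_weights_gaussian,
                                step_rk4)
from conjgrid.network2d import (Structured2DCoupling, build_manifold_2d,
                                step_rk4_2d, triad_pattern)
from conjgrid.theory import ModelParams, RingReduction, ring_speed

__all__ = [
    "ExperimentConfig",
    "PRESETS",
    "run_intrinsic_speed",
    "run_track_1d",
    "run_robustness_1d",
    "run_robustness_2d",
    "run_arena_2d",
    "classify_by_simulation",
    "measure_speed_curve",
]


@dataclass
class ExperimentConfig:
    """All knobs of one experiment; every random draw traces to ``seeds``."""

    name: str = "experiment"
    preset: str = "desk"
    # 1D manifold / coupling
    n_theta: int = 128
    n_v: int = 31
    v_max: float = 0.5
    J0: float = -50.0
    J1: float = 20.0
    beta: float = 0.5
    k: int = 2
    transfer_kind: str = "threshold-linear"
    gain: float = 1.0
    tau: float = 10.0
    dt: float = 0.5
    I0: float = 1.0
    # velocity input
    alpha_v: float = 2.0
    sigma_v: float = 0.12
    S: float = 30.0           # grid spacing, cm
    S_y: Optional[float] = None  # 2D: y-axis spacing (defaults to S)
    mapping_mode: str = "calibrated"   # closed_form | lookup | calibrated
    lookup_bins: int = 201
    # trajectory
    duration: float = 120.0   # s
    track_length: float = 200.0
    arena_side: float = 100.0
    tau_v: float = 250.0
    # 2D manifold
    n_theta_2d: int = 16
    n_v_2d: int = 7
    v_max_2d: float = 0.6
    J0_2d: float = -150.0
    J1_2d: float = 140.0
    sigma_v_2d: float = 0.2
    # bookkeeping
    seeds: Tuple[int, ...] = (0,)
    record_ms: float = 5.0
    out_dir: Optional[str] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def wp(self) -> WeightParams1D:
        return WeightParams1D(J0=self.J0, J1=self.J1, beta=self.beta, k=self.k)

    def tf(self) -> TransferFn:
        return TransferFn(kind=self.transfer_kind, gain=self.gain)

    def ip(self) -> IntegratorParams:
        return IntegratorParams(tau=self.tau, dt=self.dt)

    def manifold(self) -> Manifold1D:
        return build_manifold_1d(self.n_theta, self.n_v, self.v_max)

    def ring(self) -> RingReduction:
        return RingReduction(J0=self.J0, J1=self.J1, k=self.k, beta=self.beta,
                             tf=self.tf(), I0=self.I0, tau=self.tau)

    def input_params(self) -> drive.InputParams:
        return drive.InputParams(I0=self.I0, alpha_v=self.alpha_v,
                                 sigma_v=self.sigma_v)


PRESETS: Dict[str, dict] = {
    # intrinsic-dynamics study: full velocity-label range
    "intrinsic-desk": dict(n_theta=48, n_v=41, v_max=np.pi / 2, duration=1.0,
                           sigma_v=0.2),
    "intrinsic-full": dict(n_theta=200, n_v=51, v_max=np.pi / 2, duration=1.0,
                           sigma_v=0.2),
    # linear-track path integration: reduced label range covering +-100 cm/s
    "track-desk": dict(n_theta=128, n_v=31, v_max=0.5, duration=120.0),
    "track-full": dict(n_theta=200, n_v=51, v_max=0.5, duration=1200.0),
    # nonlinear (threshold-sigmoid) network: connections scaled up 20x
    "nonlinear-desk": dict(n_theta=128, n_v=31, v_max=0.5, duration=240.0,
                           transfer_kind="threshold-sigmoid", gain=1.0,
                           J0=-1000.0, J1=400.0, alpha_v=2.0,
                           mapping_mode="calibrated"),
    "nonlinear-full": dict(n_theta=200, n_v=51, v_max=0.5, duration=1200.0,
                           transfer_kind="threshold-sigmoid", gain=1.0,
                           J0=-1000.0, J1=400.0),
    # 2D arena
    "arena-desk": dict(n_theta_2d=16, n_v_2d=7, v_max_2d=0.6, duration=150.0,
                       dt=1.0),
    "arena-full": dict(n_theta_2d=25, n_v_2d=9, v_max_2d=0.6, duration=1200.0),
}


def make_config(preset: str, **overrides) -> ExperimentConfig:
    base = dict(PRESETS[preset])
    base.update(overrides)
    return ExperimentConfig(name=preset, preset=preset, **base)


# --------------------------------------------------------------------------
# shared machinery
# --------------------------------------------------------------------------


def _v_profile(manifold: Manifold1D, vhat: float, ip: drive.InputParams) -> np.ndarray:
    return ip.I0 + ip.alpha_v * np.exp(
        -((manifold.v_coords - vhat) ** 2) / (2.0 * ip.sigma_v ** 2))


def _settle_pinned(coupling, manifold, tf, ip, inp: drive.InputParams,
                   vhat: float, wp: WeightParams1D, T: float,
                   state: Optional[RateState] = None,
                   pulse: float = 0.0) -> RateState:
    """Run with input pinned at vhat; optionally start from a seeded bump.

    ``pulse`` > 0 adds a decaying theta-modulated drive that breaks the
    translation symmetry (networks started uniform otherwise stay uniform).
    """
    if state is None:
        state = bump_seeded_state(manifold, wp, vhat)
    prof = _v_profile(manifold, vhat, inp)[None, :]
    th_mod = np.maximum(np.cos(wp.k * manifold.theta_grid), 0.0)
    n = int(round(T / ip.dt))
    for i in range(n):
        I = prof
        if pulse > 0.0:
            a = pulse * max(0.0, 1.0 - (i * ip.dt) / (0.5 * T))
            I = prof + a * th_mod * np.exp(
                -((manifold.v_grid - vhat) ** 2) / (2.0 * inp.sigma_v ** 2))
        state = step_rk4(state, I, coupling, tf, ip)
    return state


def measure_speed_curve(cfg: ExperimentConfig, vhat_grid: Sequence[float],
                        settle_ms: float = 400.0, measure_ms: float = 600.0):
    """Bump speed of the full network at input-pinned velocity-axis positions.

    Continuation along the grid (warm starts) with the velocity-tuned input
    holding psi_v; returns (vhat_grid, speeds in rad/ms along theta).
    """
    manifold, wp, tf, ip = cfg.manifold(), cfg.wp(), cfg.tf(), cfg.ip()
    inp = cfg.input_params()
    coupling = LowRankCoupling1D(manifold, wp)
    ex = np.exp(1j * wp.k * manifold.theta_grid)
    state = _settle_pinned(coupling, manifold, tf, ip, inp, float(vhat_grid[0]),
                           wp, settle_ms)
    speeds = []
    for vhat in vhat_grid:
        prof = _v_profile(manifold, float(vhat), inp)[None, :]
        for _ in range(int(round(settle_ms / ip.dt))):
            state = step_rk4(state, prof, coupling, tf, ip)
        ph = []
        n = int(round(measure_ms / ip.dt))
        for _ in range(n):
            state = step_rk4(state, prof, coupling, tf, ip)
            ph.append(np.angle((state.m * ex).sum()))
        ph = np.unwrap(np.array(ph))
        speeds.append(np.polyfit(np.arange(n) * ip.dt, ph, 1)[0] / wp.k)
    return np.asarray(vhat_grid, float), np.array(speeds)


def _make_mapping(cfg: ExperimentConfig, S: Optional[float] = None) -> drive.VelocityMapping:
    S = cfg.S if S is None else S
    ring = cfg.ring()
    if cfg.mapping_mode == "calibrated":
        # speed needed at 100 cm/s fixes the calibration range
        vh100 = drive.desired_vhat(100.0, ring, S)
        grid = np.linspace(0.0, min(1.15 * vh100, cfg.v_max * 0.95), 9)
        vh, sp = measure_speed_curve(cfg, grid)
        return drive.mapping_from_curve(vh, sp, S, ring, n_bins=cfg.lookup_bins)
    return drive.VelocityMapping(S=S, ring=ring, mode=cfg.mapping_mode,
                                 lookup_bins=cfg.lookup_bins)


# --------------------------------------------------------------------------
# intrinsic speed (release protocol)
# --------------------------------------------------------------------------


def run_intrinsic_speed(cfg: ExperimentConfig,
                        vhat_grid: Optional[Sequence[float]] = None,
                        release_ms: float = 1000.0) -> dict:
    """Seed bumps at positions on the velocity axis, release to uniform input,
    and measure one second of drift at 1 ms resolution.

    The network is first given stronger velocity-tuned input which is
    gradually decreased to uniform, then runs freely.  Returns measured mean
    speeds, instantaneous speed series and the ring-law prediction.
    """
    if vhat_grid is None:
        vhat_grid = np.linspace(-0.3, 0.3, 11)
    manifold, wp, tf, ip = cfg.manifold(), cfg.wp(), cfg.tf(), cfg.ip()
    inp = cfg.input_params()
    ring = cfg.ring()
    coupling = LowRankCoupling1D(manifold, wp)
    ex = np.exp(1j * wp.k * manifold.theta_grid)
    a_v = 0.5 * np.pi / manifold.v_max
    ev = np.exp(1j * a_v * manifold.v_grid)
    measured, inst_all, psi_v_mean = [], [], []
    for vhat in vhat_grid:
        state = bump_seeded_state(manifold, wp, float(vhat))
        # pinning input ramped down to uniform over 400 ms
        n_pin = int(round(400.0 / ip.dt))
        base = np.full((1, manifold.n_v), inp.I0)
        gauss = np.exp(-((manifold.v_coords - vhat) ** 2)
                       / (2.0 * inp.sigma_v ** 2))[None, :]
        for i in range(n_pin):
            a = inp.alpha_v * max(0.0, 1.0 - i / n_pin)
            state = step_rk4(state, base + a * gauss, coupling, tf, ip)
        ph, pvs = [], []
        n = int(round(release_ms / ip.dt))
        stride = max(1, int(round(1.0 / ip.dt)))  # 1 ms resolution
        for i in range(n):
            state = step_rk4(state, inp.I0, coupling, tf, ip)
            if i % stride == 0:
                ph.append(np.angle((state.m * ex).sum()))
                pvs.append(np.angle((state.m * ev).sum()) / a_v)
        ph = np.unwrap(np.array(ph))
        inst = np.diff(ph) / (stride * ip.dt) / wp.k
        measured.append(np.polyfit(np.arange(len(ph)) * stride * ip.dt, ph, 1)[0] / wp.k)
        inst_all.append(inst)
        psi_v_mean.append(float(np.mean(pvs)))
    # speeds are compared against the ring law at the *measured* bump centre
    # on the velocity axis (the released bump may settle a little away from
    # its nominal seeding position)
    predicted = np.array([ring_speed(v, ring) for v in psi_v_mean])
    return {
        "config": cfg.to_dict(),
        "vhat_grid": np.asarray(vhat_grid, float),
        "measured": np.array(measured),
        "instantaneous": inst_all,
        "predicted": predicted,
        "psi_v": np.array(psi_v_mean),
    }


# --------------------------------------------------------------------------
# linear-track closed loop
# --------------------------------------------------------------------------


def run_track_1d(cfg: ExperimentConfig, seed: Optional[int] = None,
                 coupling=None, record_units: Optional[List[Tuple[int, int]]] = None,
                 mapping: Optional[drive.VelocityMapping] = None) -> dict:
    """Full closed loop on the linear track.

    trajectory -> velocity-tuned input -> network dynamics -> phase decoding
    -> rate maps.  ``coupling`` may be a dense (possibly perturbed) weight
    matrix; by default the exact low-rank coupling is used.
    """
    seed = cfg.seeds[0] if seed is None else seed
    manifold, wp, tf, ip = cfg.manifold(), cfg.wp(), cfg.tf(), cfg.ip()
    inp = cfg.input_params()
    if coupling is None:
        coupling = LowRankCoupling1D(manifold, wp)
    if mapping is None:
        mapping = _make_mapping(cfg)
    traj = trajectory.simulate_track_1d(
        trajectory.TrajectoryParams(duration=cfg.duration, dt=ip.dt,
                                    track_length=cfg.track_length,
                                    tau_v=cfg.tau_v), seed)
    vhat_t = mapping(traj.velocity)           # velocity-axis target per step
    n_steps = len(traj.t) - 1
    if record_units is None:
        mid = manifold.n_v // 2
        hi = int(round(0.8 * (manifold.n_v - 1)))
        lo = manifold.n_v - 1 - hi
        record_units = [(0, mid), (0, hi), (0, lo),
                        (manifold.n_theta // 3, hi)]
    # warm start pinned at the initial velocity
    state = _settle_pinned(coupling, manifold, tf, ip, inp, float(vhat_t[0]),
                           wp, 300.0)
    ex = np.exp(1j * wp.k * manifold.theta_grid)
    a_v = 0.5 * np.pi / manifold.v_max
    ev = np.exp(1j * a_v * manifold.v_grid)
    stride = max(1, int(round(cfg.record_ms / ip.dt)))
    rec_t, rec_psi, rec_psiv, rec_rates = [], [], [], []
    rec_pos, rec_vel = [], []
    vcoords = manifold.v_coords
    for i in range(n_steps):
        prof = inp.I0 + inp.alpha_v * np.exp(
            -((vcoords - vhat_t[i]) ** 2) / (2.0 * inp.sigma_v ** 2))
        state = step_rk4(state, prof[None, :], coupling, tf, ip)
        if i % stride == 0:
            z = (state.m * ex).sum()
            zv = (state.m * ev).sum()
            rec_t.append(state.t)
            rec_psi.append((np.angle(z) / wp.k) % (2 * np.pi / wp.k))
            rec_psiv.append(np.angle(zv) / a_v)
            rec_rates.append([state.m[iu, ju] for iu, ju in record_units])
            rec_pos.append(traj.position[i + 1])
            rec_vel.append(traj.velocity[i + 1])
    track = analysis.make_track(np.array(rec_t), np.array(rec_psi),
                                np.array(rec_psiv), wp.k)
    pos = np.array(rec_pos)
    vel = np.array(rec_vel)
    decoded = analysis.decode_position(track, cfg.S, wp.k, anchor=pos[0])
    err, drift = analysis.tracking_error_and_drift(decoded, pos)
    rates = np.array(rec_rates)
    # per-unit maps: position x velocity, and direction-conditioned spatial maps
    pos_edges = np.arange(0.0, cfg.track_length + 1.0, 2.0)
    vel_edges = np.arange(-100.0, 101.0, 10.0)
    maps = []
    for u in range(rates.shape[1]):
        pv = analysis.rate_map(rates[:, u], [pos, vel], [pos_edges, vel_edges])
        right = vel > 5.0
        left = vel < -5.0
        m_r = analysis.rate_map(rates[right, u], [pos[right]], [pos_edges])
        m_l = analysis.rate_map(rates[left, u], [pos[left]], [pos_edges])
        maps.append({"pos_vel": pv, "right": m_r, "left": m_l})
    return {
        "config": cfg.to_dict(), "seed": seed,
        "trajectory": traj, "track": track,
        "position": pos, "velocity": vel,
        "decoded": decoded, "error": err, "drift": drift,
        "rates": rates, "record_units": record_units,
        "unit_vlabels": [manifold.v_coords[j] for _, j in record_units],
        "maps": maps, "mapping": mapping,
    }


# --------------------------------------------------------------------------
# robustness sweeps
# --------------------------------------------------------------------------


def run_robustness_1d(cfg: ExperimentConfig,
                      gauss_fracs: Sequence[float] = (0.0, 0.02, 0.10),
                      dilution_rhos: Sequence[float] = (0.0, 0.2, 0.4),
                      n_runs: int = 8) -> dict:
    """Path-integration drift under weight perturbations, averaged over seeds.

    Gaussian perturbation levels are relative to the weight range; dilution
    removes the stated fraction of entries (survivors rescaled).  Reports the
    per-condition mean drift time series and the time to half spacing.
    """
    manifold, wp = cfg.manifold(), cfg.wp()
    W0 = build_weights_1d(manifold, wp)
    conditions: Dict[str, tuple] = {}
    out: Dict[str, dict] = {}
    for frac in gauss_fracs:
        conditions[f"gauss_{frac:g}"] = ("gauss", frac)
    for rho in dilution_rhos:
        if rho > 0:
            conditions[f"dilute_{rho:g}"] = ("dilute", rho)
    t_ref = None
    for name, (kind, level) in conditions.items():
        drifts = []
        for r in range(n_runs):
            seed = cfg.seeds[0] * 1000 + r
            if kind == "gauss":
                W = perturb_weights_gaussian(W0, level, seed + 500_000)
            else:
                W = dilute_weights(W0, level, seed + 500_000)
            res = run_track_1d(cfg, seed=seed, coupling=W)
            drifts.append(np.abs(res["error"]))
            t_ref = res["track"].t
        mean_drift = np.mean(drifts, axis=0)
        half = np.nonzero(mean_drift > cfg.S / 2.0)[0]
        out[name] = {
            "mean_drift": mean_drift,
            "time_to_half_spacing": float(t_ref[half[0]]) if len(half) else np.inf,
        }
    return {"config": cfg.to_dict(), "t": t_ref, "conditions": out}


# --------------------------------------------------------------------------
# 2D arena
# --------------------------------------------------------------------------


def _arena_setup(cfg: ExperimentConfig):
    man = build_manifold_2d(cfg.n_theta_2d, cfg.n_v_2d, cfg.v_max_2d)
    wp = WeightParams1D(J0=cfg.J0_2d, J1=cfg.J1_2d, beta=cfg.beta, k=cfg.k)
    coupling = Structured2DCoupling(man, wp)
    return man, wp, coupling


def measure_speed_curve_2d(cfg: ExperimentConfig, vhat_grid: Sequence[float],
                           settle_ms: float = 400.0, measure_ms: float = 600.0):
    """Pattern speed along x at input-pinned (vhat, 0) on the velocity axes.

    Continuation with warm starts from a triad-seeded state; returns
    (vhat_grid, speeds) with speeds in rad/ms of pattern translation.
    """
    man, wp, coupling = _arena_setup(cfg)
    tf, ip = cfg.tf(), IntegratorParams(tau=cfg.tau, dt=cfg.dt)
    inp = drive.InputParams(I0=cfg.I0, alpha_v=cfg.alpha_v,
                            sigma_v=cfg.sigma_v_2d)
    v = man.v_coords
    kk = wp.k
    P = triad_pattern(man, kk)
    g0 = np.exp(-(v ** 2) / (2 * inp.sigma_v ** 2))
    m = 0.05 * (0.3 + P)[:, :, None, None] * (
        np.exp(-((v[:, None] - vhat_grid[0]) ** 2 + v[None, :] ** 2)
               / (2 * inp.sigma_v ** 2)))[None, None, :, :]
    rng = np.random.default_rng(12345)
    m *= (1.0 + 0.01 * rng.standard_normal(m.shape))
    state = RateState(t=0.0, m=m)
    speeds = []
    for vhat in vhat_grid:
        gx = np.exp(-((v - vhat) ** 2) / (2 * inp.sigma_v ** 2))
        prof = inp.I0 + inp.alpha_v * (gx[:, None] * g0[None, :])
        I = prof[None, None, :, :]
        for _ in range(int(round(settle_ms / ip.dt))):
            state = step_rk4_2d(state, I, coupling, tf, ip)
        ph = []
        n = int(round(measure_ms / ip.dt))
        for _ in range(n):
            state = step_rk4_2d(state, I, coupling, tf, ip)
            ph.append(np.angle(np.fft.fft2(state.m.sum(axis=(2, 3)))[kk % man.n_theta, 0]))
        ph = np.unwrap(np.array(ph))
        speeds.append(-np.polyfit(np.arange(n) * ip.dt, ph, 1)[0] / kk)
    return np.asarray(vhat_grid, float), np.array(speeds)


def run_arena_2d(cfg: ExperimentConfig, seed: Optional[int] = None,
                 coupling=None, n_record_units: int = 3) -> dict:
    """Closed-loop 2D exploration: triad-seeded lattice tracking a random walk.

    Per-axis velocity mappings support unequal grid scales Sx != Sy
    (elliptical-grid experiment).  Returns unit rate maps, the decoded
    positions and the population activity snapshot.
    """
    seed = cfg.seeds[0] if seed is None else seed
    man, wp, default_coupling = _arena_setup(cfg)
    if coupling is None:
        coupling = default_coupling
    tf, ip = cfg.tf(), IntegratorParams(tau=cfg.tau, dt=cfg.dt)
    ring = RingReduction(J0=cfg.J0, J1=cfg.J1, k=cfg.k, beta=cfg.beta,
                         tf=tf, I0=cfg.I0, tau=cfg.tau)
    Sx = cfg.S
    Sy = cfg.S_y if cfg.S_y is not None else cfg.S
    if cfg.mapping_mode == "calibrated":
        vh100 = drive.desired_vhat(100.0, ring, min(Sx, Sy))
        grid = np.linspace(0.0, min(1.15 * vh100, cfg.v_max_2d * 0.9), 7)
        vh, sp = measure_speed_curve_2d(cfg, grid)
        map_x = drive.mapping_from_curve(vh, sp, Sx, ring,
                                         n_bins=cfg.lookup_bins)
        map_y = drive.mapping_from_curve(vh, sp, Sy, ring,
                                         n_bins=cfg.lookup_bins)
    else:
        map_x = drive.VelocityMapping(S=Sx, ring=ring, mode="lookup",
                                      lookup_bins=cfg.lookup_bins)
        map_y = drive.VelocityMapping(S=Sy, ring=ring, mode="lookup",
                                      lookup_bins=cfg.lookup_bins)
    traj = trajectory.simulate_arena_2d(
        trajectory.TrajectoryParams(duration=cfg.duration, dt=cfg.dt,
                                    arena_side=cfg.arena_side,
                                    tau_v=cfg.tau_v), seed)
    vx_hat = map_x(traj.velocity[:, 0])
    vy_hat = map_y(traj.velocity[:, 1])
    inp = drive.InputParams(I0=cfg.I0, alpha_v=cfg.alpha_v,
                            sigma_v=cfg.sigma_v_2d)
    v = man.v_coords
    # triad-seeded start at the initial velocity target
    g0x = np.exp(-((v - vx_hat[0]) ** 2) / (2 * inp.sigma_v ** 2))
    g0y = np.exp(-((v - vy_hat[0]) ** 2) / (2 * inp.sigma_v ** 2))
    P = triad_pattern(man, wp.k)
    m0 = 0.05 * (0.3 + P)[:, :, None, None] * (g0x[:, None] * g0y[None, :])[None, None, :, :]
    rng = np.random.default_rng(seed)
    m0 = m0 * (1.0 + 0.01 * rng.standard_normal(m0.shape))
    state = RateState(t=0.0, m=m0)
    base = np.full((1, 1, man.n_v, man.n_v), 0.0)
    # settle 300 ms at the initial target
    prof0 = inp.I0 + inp.alpha_v * (g0x[:, None] * g0y[None, :])
    for _ in range(int(round(300.0 / ip.dt))):
        state = step_rk4_2d(state, prof0[None, None, :, :], coupling, tf, ip)
    # record units: distinct velocity labels (conjunctive and central)
    c = man.n_v // 2
    hi = min(man.n_v - 1, c + max(1, man.n_v // 3))
    record_units = [(0, 0, c, c), (0, 0, hi, c), (man.n_theta // 3, 0, c, hi)][:n_record_units]
    stride = max(1, int(round(cfg.record_ms / ip.dt)))
    rec = {"t": [], "rates": [], "pos": [], "vel": [], "ph1": [], "ph2": []}
    n_steps = len(traj.t) - 1
    kk = wp.k
    for i in range(n_steps):
        gx = np.exp(-((v - vx_hat[i]) ** 2) / (2 * inp.sigma_v ** 2))
        gy = np.exp(-((v - vy_hat[i]) ** 2) / (2 * inp.sigma_v ** 2))
        prof = inp.I0 + inp.alpha_v * (gx[:, None] * gy[None, :])
        state = step_rk4_2d(state, prof[None, None, :, :], coupling, tf, ip)
        if i % stride == 0:
            pop = state.m.sum(axis=(2, 3))
            F = np.fft.fft2(pop)
            # triad modes (k, 0) and (-k/2, k) carry the pattern phase
            rec["ph1"].append(np.angle(F[kk % man.n_theta, 0]))
            rec["ph2"].append(np.angle(F[(-kk // 2) % man.n_theta,
                                         kk % man.n_theta]))
            rec["t"].append(state.t)
            rec["rates"].append([state.m[u] for u in record_units])
            rec["pos"].append(traj.position[i + 1])
            rec["vel"].append(traj.velocity[i + 1])
    t = np.array(rec["t"])
    pos = np.array(rec["pos"])
    rates = np.array(rec["rates"])
    # pattern translation (ax, ay) in theta radians from the mode phases:
    # phi(q) = phi0 - q . a with q1 = (k, 0), q2 = (-k/2, k)
    d1 = np.diff(np.unwrap(np.array(rec["ph1"])))
    d2 = np.diff(np.unwrap(np.array(rec["ph2"])))
    dax = -d1 / kk
    day = (dax * (kk // 2) - d2) / kk
    ax = np.concatenate([[0.0], np.cumsum(dax)])
    ay = np.concatenate([[0.0], np.cumsum(day)])
    scale = kk / (2.0 * np.pi)
    dec_x = pos[0, 0] + ax * scale * Sx
    dec_y = pos[0, 1] + ay * scale * Sy
    drift = np.hypot(dec_x - pos[:, 0], dec_y - pos[:, 1])
    bin_cm = 5.0
    maps = [analysis.rate_map_2d(rates[:, u], pos[:, 0], pos[:, 1],
                                 cfg.arena_side, bin_cm=bin_cm)
            for u in range(rates.shape[1])]
    return {
        "config": cfg.to_dict(), "seed": seed, "trajectory": traj,
        "t": t, "position": pos, "rates": rates, "maps": maps,
        "bin_cm": bin_cm, "decoded": np.column_stack([dec_x, dec_y]),
        "drift": drift, "state": state, "manifold": man,
        "record_units": record_units,
    }


def run_robustness_2d(cfg: ExperimentConfig,
                      gauss_fracs: Sequence[float] = (0.0, 0.10),
                      dilution_rhos: Sequence[float] = (0.2,),
                      n_runs: int = 8) -> dict:
    """2D robustness: drift under perturbed/diluted weights (dense path)."""
    man, wp, _ = _arena_setup(cfg)
    W0 = network2d.build_weights_2d(man, wp)
    out = {}
    t_ref = None
    conditions = {f"gauss_{f:g}": ("gauss", f) for f in gauss_fracs}
    conditions.update({f"dilute_{r:g}": ("dilute", r) for r in dilution_rhos})
    for name, (kind, level) in conditions.items():
        drifts = []
        for r in range(n_runs):
            seed = cfg.seeds[0] * 1000 + r
            if kind == "gauss" and level > 0:
                W = perturb_weights_gaussian(W0, level, seed + 500_000)
            elif kind == "dilute" and level > 0:
                W = dilute_weights(W0, level, seed + 500_000)
            else:
                W = W0
            res = run_arena_2d(cfg, seed=seed, coupling=W)
            drifts.append(res["drift"])
            t_ref = res["t"]
        mean_drift = np.mean(drifts, axis=0)
        half = np.nonzero(mean_drift > cfg.S / 2.0)[0]
        out[name] = {"mean_drift": mean_drift,
                     "time_to_half_spacing": float(t_ref[half[0]]) if len(half) else np.inf}
    return {"config": cfg.to_dict(), "t": t_ref, "conditions": out}


# --------------------------------------------------------------------------
# simulation-based regime classification (test oracle)
# --------------------------------------------------------------------------


def classify_by_simulation(params: ModelParams, seed: int = 0,
                           T_factor: float = 200.0,
                           vhat_test: Optional[float] = None,
                           drift_tol: float = 1e-4,
                           amp_tol: float = 1e-6,
                           rate_cap: float = 1e6) -> str:
    """Operational regime label from direct simulation.

    homogeneous: spatial first-harmonic amplitude < amp_tol x mean rate after
    T = T_factor*tau from a jittered start.  traveling: |drift| of the bump
    phase exceeds drift_tol rad/tau after the bump is displaced along the
    velocity axis.  Divergence -> amplitude_instability; otherwise static.
    """
    man, wp, tf, ip = params.manifold, params.wp, params.tf, params.ip
    from conjgrid.network1d import IntegrationFailure  # local, avoids cycle
    state = jittered_initial_state(man, seed)
    ex = np.exp(1j * wp.k * man.theta_grid)
    try:
        n = int(round(T_factor * ip.tau / ip.dt))
        for _ in range(n):
            state = step_rk4(state, params.I0,
                             LowRankCoupling1D(man, wp), tf, ip)
            if state.m.max() > rate_cap:
                return "amplitude_instability"
    except IntegrationFailure:
        return "amplitude_instability"
    r1 = abs((state.m * ex).sum()) / man.n_units
    if r1 < amp_tol * max(state.m.mean(), 1e-30):
        return "homogeneous"
    # displacement test along v
    if vhat_test is None:
        vhat_test = 0.2 * man.v_max
    coupling = LowRankCoupling1D(man, wp)
    inp = drive.InputParams(I0=params.I0, alpha_v=3.0, sigma_v=0.2 * man.v_max)
    st = _settle_pinned(coupling, man, tf, ip, inp, vhat_test, wp, 300.0)
    ph = []
    n = int(round(50.0 * ip.tau / ip.dt))
    for _ in range(n):
        st = step_rk4(st, params.I0, coupling, tf, ip)
        ph.append(np.angle((st.m * ex).sum()))
    ph = np.unwrap(np.array(ph))
    half = n // 2
    drift_per_tau = abs(np.polyfit(np.arange(half) * ip.dt,
                                   ph[half:2 * half], 1)[0]) / wp.k * ip.tau
    pv = st.m.max(axis=0)
    edge = max(pv[0], pv[-1]) / max(pv.max(), 1e-30)
    return ("traveling_bumps" if drift_per_tau > drift_tol and edge < 0.5
            else "static_bumps")
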