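"""Synthetic animal trajectories: 1D back-and-forth track runs and 2D random walks.

The speed follows a first-order relaxation toward a piecewise-constant target
resampled uniformly in [0, v_peak] every ``resample_interval``; near a wall
the target is forced to zero, and once the speed drops below the
slow-reversal threshold during that deceleration the running direction flips
and a fresh target is drawn.  A 2D arena trajectory is two such independent
walkers, one per axis, confined to the square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["TrajectoryParams", "TrajectoryRecord", "simulate_track_1d",
           "simulate_arena_2d"]


@dataclass(frozen=True)
class TrajectoryParams:
    duration: float = 60.0            # s
    dt: float = 0.5                   # ms
    track_length: float = 200.0       # cm (1D)
    arena_side: float = 100.0         # cm (2D)
    v_peak: float = 100.0             # cm/s
    tau_v: float = 250.0              # ms, speed relaxation
    resample_interval: float = 1.0    # s
    slow_reversal_speed: float = 5.0  # cm/s
    boundary_zone: Optional[float] = None  # cm; default: deceleration distance

    def __post_init__(self):
        for name in ("duration", "dt", "track_length", "arena_side", "v_peak",
                     "tau_v", "resample_interval", "slow_reversal_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def zone(self) -> float:
        """Wall zone in which the target speed is forced to zero."""
        if self.boundary_zone is not None:
            return self.boundary_zone
        # distance needed to decelerate from v_peak with time constant tau_v
        return self.v_peak * self.tau_v / 1000.0


@dataclass
class TrajectoryRecord:
    """Time series of the virtual animal: t in ms, positions in cm, cm/s."""

    t: np.ndarray
    position: np.ndarray   # (n,) for 1D, (n, 2) for 2D
    velocity: np.ndarray   # signed, same shape as position
    heading: Optional[np.ndarray] = None  # radians, 2D only

    @property
    def speed(self) -> np.ndarray:
        if self.position.ndim == 1:
            return np.abs(self.velocity)
        return np.hypot(self.velocity[:, 0], self.velocity[:, 1])


def _walk_1d(params: TrajectoryParams, rng: np.random.Generator,
             length: float):
    """Single-axis walker; returns (t, x, v)."""
    dt = params.dt
    n = int(round(params.duration * 1000.0 / dt))
    resample_steps = max(1, int(round(params.resample_interval * 1000.0 / dt)))
    zone = params.zone
    t = np.arange(n + 1) * dt
    x = np.empty(n + 1)
    v = np.empty(n + 1)
    x[0] = length / 2.0
    speed = 0.0
    direction = 1.0
    target = rng.uniform(0.0, params.v_peak)
    decelerating = False
    v[0] = 0.0
    for i in range(n):
        if i % resample_steps == 0 and i > 0 and not decelerating:
            target = rng.uniform(0.0, params.v_peak)
        ahead = length - x[i] if direction > 0 else x[i]
        if ahead < zone:
            decelerating = True
        if decelerating:
            eff_target = 0.0
            if speed < params.slow_reversal_speed:
                direction = -direction
                target = rng.uniform(0.0, params.v_peak)
                decelerating = False
                eff_target = target
        else:
            eff_target = target
        speed += dt * (eff_target - speed) / params.tau_v
        speed = min(max(speed, 0.0), params.v_peak)
        x_new = x[i] + direction * speed * dt / 1000.0
        x[i + 1] = min(max(x_new, 0.0), length)
        v[i + 1] = direction * speed
    return t, x, v


def simulate_track_1d(params: TrajectoryParams, seed: int) -> TrajectoryRecord:
    """Back-and-forth run on a linear track; reverses only at the two ends."""
    rng = np.random.default_rng(seed)
    t, x, v = _walk_1d(params, rng, params.track_length)
    return TrajectoryRecord(t=t, position=x, velocity=v)


def simulate_arena_2d(params: TrajectoryParams, seed: int) -> TrajectoryRecord:
    """Smooth random walk in a square arena: two independent 1D walkers.

    Heading is atan2(vy, vx); at zero speed the last defined heading carries
    over.
    """
    rng = np.random.default_rng(seed)
    t, x, vx = _walk_1d(params, rng, params.arena_side)
    _, y, vy = _walk_1d(params, rng, params.arena_side)
    heading = np.empty_like(t)
    h = 0.0
    for i in range(len(t)):
        if abs(vx[i]) > 1e-12 or abs(vy[i]) > 1e-12:
            h = np.arctan2(vy[i], vx[i])
        heading[i] = h
    return TrajectoryRecord(t=t, position=np.column_stack([x, y]),
                            velocity=np.column_stack([vx, vy]), heading=heading)
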