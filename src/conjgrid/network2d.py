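"""Two-dimensional environment network: 4-D manifold (theta_x, theta_y, vx, vy).

The coupling extends the 1D form: a radially symmetric cosine of the wrapped
spatial displacement, displaced by (beta/k) times the presynaptic velocity
label vector, times a broad cosine of the velocity-label distance:

    W_ij = (1/N)[ J0 + J1 * cos(k * || d_ij - (beta/k) v_j ||)
                       * cos(|| v_i - v_j ||) ]

with d_ij the vector of per-axis signed circular differences.  On the
periodic sheet the radial cosine's spectrum peaks on the integer-wavevector
ring |q| ~ k sustaining the resonant triad (k,0), (-k/2 .. ) -- for k = 2 the
triad (2,0), (-1,2), (-1,-2) -- whose real-space pattern is 2 bumps per axis
arranged on a quasi-triangular (offset-row) lattice.

Dense construction is guarded above ``DENSE_GUARD`` units; the structured
evaluator performs per-velocity-slice FFT convolutions plus a slice-mixing
contraction, exactly equal to the dense product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

from conjgrid.network1d import (IntegratorParams, IntegrationFailure, RateState,
                                TransferFn, WeightParams1D, transfer)

__all__ = [
    "Manifold2D",
    "DENSE_GUARD",
    "circ_dist",
    "build_manifold_2d",
    "build_weights_2d",
    "Structured2DCoupling",
    "recurrent_field_lowrank_2d",
    "slice_activity",
    "triad_pattern",
    "step_rk4_2d",
]

DENSE_GUARD = 20_000


def circ_dist(a, b):
    """Signed circular difference a - b wrapped to (-pi, pi]."""
    return -((b - a + np.pi) % (2.0 * np.pi) - np.pi)


@dataclass(frozen=True)
class Manifold2D:
    """Discretised 4-D manifold; spatial axes periodic, velocity axes bounded."""

    n_theta: int
    n_v: int
    v_max: float
    theta_coords: np.ndarray = field(repr=False)
    v_coords: np.ndarray = field(repr=False)

    @property
    def n_units(self) -> int:
        return self.n_theta ** 2 * self.n_v ** 2


def build_manifold_2d(n_theta: int = 25, n_v: int = 9,
                      v_max: float = 0.6) -> Manifold2D:
    if n_theta < 4:
        raise ValueError("n_theta must be >= 4")
    if n_v < 1 or n_v % 2 == 0:
        raise ValueError("n_v must be odd")
    if v_max <= 0:
        raise ValueError("v_max must be positive")
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    v = np.linspace(-v_max, v_max, n_v) if n_v > 1 else np.zeros(1)
    return Manifold2D(n_theta=n_theta, n_v=n_v, v_max=v_max,
                      theta_coords=theta, v_coords=v)


def _unit_coords(man: Manifold2D):
    """Flat arrays (tx, ty, vx, vy) in C order over (tx, ty, vx, vy)."""
    TX, TY, VX, VY = np.meshgrid(man.theta_coords, man.theta_coords,
                                 man.v_coords, man.v_coords, indexing="ij")
    return TX.ravel(), TY.ravel(), VX.ravel(), VY.ravel()


def build_weights_2d(man: Manifold2D, wp: WeightParams1D,
                     guard: int = DENSE_GUARD) -> np.ndarray:
    """Dense (N x N) weight matrix; refuses above ``guard`` units."""
    if man.n_units > guard:
        raise MemoryError(
            f"dense 2D weights refused for {man.n_units} units (guard {guard}); "
            "use the structured coupling")
    tx, ty, vx, vy = _unit_coords(man)
    c = wp.beta / wp.k
    ddx = circ_dist(tx[:, None], tx[None, :] + c * vx[None, :])
    ddy = circ_dist(ty[:, None], ty[None, :] + c * vy[None, :])
    dist = np.hypot(ddx, ddy)
    dv = np.hypot(vx[:, None] - vx[None, :], vy[:, None] - vy[None, :])
    W = wp.J0 + wp.J1 * np.cos(wp.k * dist) * np.cos(dv)
    if wp.norm:
        W /= man.n_units
    return W


class Structured2DCoupling:
    """Exact O(N log N) recurrent field via per-slice FFT convolutions.

    For each presynaptic velocity slice s the spatial kernel is the shifted
    radial cosine; the field at postsynaptic slice i is
    J0 <m> + sum_s cos(||v_i - v_s||) (K_s * m_s) / N.
    """

    def __init__(self, man: Manifold2D, wp: WeightParams1D):
        self.man, self.wp = man, wp
        nt, nv = man.n_theta, man.n_v
        d = circ_dist(man.theta_coords, 0.0)
        DX, DY = np.meshgrid(d, d, indexing="ij")
        c = wp.beta / wp.k
        slices = [(a, b) for a in range(nv) for b in range(nv)]
        self.slices = slices
        Kf = np.empty((nv * nv, nt, nt // 2 + 1), complex)
        for s, (a, b) in enumerate(slices):
            sx, sy = c * man.v_coords[a], c * man.v_coords[b]
            dd = np.hypot(circ_dist(DX, sx), circ_dist(DY, sy))
            Kf[s] = np.fft.rfft2(wp.J1 * np.cos(wp.k * dd))
        self.Kf = Kf
        VX, VY = np.meshgrid(man.v_coords, man.v_coords, indexing="ij")
        vs = np.stack([VX.ravel(), VY.ravel()], 1)
        dv = np.hypot(vs[:, None, 0] - vs[None, :, 0],
                      vs[:, None, 1] - vs[None, :, 1])
        self.Wvel = np.cos(dv)
        self.scale = 1.0 / man.n_units if wp.norm else 1.0

    def __call__(self, m: np.ndarray) -> np.ndarray:
        """m has shape (nt, nt, nv, nv); returns the recurrent field."""
        nt, nv = self.man.n_theta, self.man.n_v
        ms = m.reshape(nt, nt, nv * nv).transpose(2, 0, 1)  # (S, nt, nt)
        conv_f = np.fft.rfft2(ms, axes=(1, 2)) * self.Kf
        mixed = np.tensordot(self.Wvel, conv_f, axes=(1, 0))
        h = np.fft.irfft2(mixed, s=(nt, nt), axes=(1, 2))
        out = h.transpose(1, 2, 0).reshape(nt, nt, nv, nv) * self.scale
        return self.wp.J0 * (m.sum() * self.scale) + out


def recurrent_field_lowrank_2d(state: RateState, man: Manifold2D,
                               wp: WeightParams1D) -> np.ndarray:
    """Structured evaluation of the 2D recurrent field (== dense product)."""
    return Structured2DCoupling(man, wp)(state.m)


def slice_activity(state: RateState, man: Manifold2D,
                   vx_index: int, vy_index: int) -> np.ndarray:
    """Spatial activity map (nt, nt) of the units with one fixed velocity label."""
    return state.m[:, :, vx_index, vy_index]


def triad_pattern(man: Manifold2D, k: int = 2) -> np.ndarray:
    """Rectified resonant-triad template: k bumps per axis on the offset lattice."""
    X, Y = np.meshgrid(man.theta_coords, man.theta_coords, indexing="ij")
    # triad (k, 0), (-k/2, k), (-k/2, -k); for k=2: (2,0), (-1,2), (-1,-2)
    p = (np.cos(k * X) + np.cos(-(k // 2) * X + k * Y)
         + np.cos(-(k // 2) * X - k * Y))
    return np.maximum(p, 0.0)


def step_rk4_2d(state: RateState, external_input,
                coupling: Union[np.ndarray, Structured2DCoupling, Callable],
                tf: TransferFn, ip: IntegratorParams) -> RateState:
    """One RK4 step of the 2D network (same dynamics as the 1D stepper)."""
    m = state.m
    if isinstance(coupling, np.ndarray):
        W = coupling

        def field_fn(mm):
            return (W @ mm.ravel()).reshape(m.shape)
    else:
        field_fn = coupling
    tau, dt = ip.tau, ip.dt
    I = external_input

    def f(mm):
        return (-mm + transfer(I + field_fn(mm), tf)) / tau

    k1 = f(m)
    k2 = f(m + 0.5 * dt * k1)
    k3 = f(m + 0.5 * dt * k2)
    k4 = f(m + dt * k3)
    m_new = m + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if not np.all(np.isfinite(m_new)):
        raise IntegrationFailure(
            f"non-finite 2D state after step at t={state.t + dt:.3f} ms")
    return RateState(t=state.t + dt, m=m_new)
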