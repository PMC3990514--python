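"""One-dimensional (linear-track) conjunctive position-by-velocity network.

Units live on a two-dimensional neural manifold: a periodic spatial coordinate
``theta`` in [0, 2*pi) and a bounded velocity-label coordinate ``v`` in
[-v_max, +v_max].  The recurrent coupling from unit j to unit i is

    W_ij = (1/N) * [ J0 + J1 * cos(k*(theta_i - theta_j) - beta*v_j)
                            * cos(v_i - v_j) ]

i.e. uniform inhibition J0 plus a k-periodic spatial cosine whose phase is
shifted by the *presynaptic* velocity label (strength beta), multiplied by a
broad cosine modulation along the velocity axis.  The asymmetric shift makes
activity bumps centred at velocity label v travel along theta at the intrinsic
speed tan(beta*v)/(tau*k); the velocity modulation makes only units with
similar labels co-active, which is what produces conjunctive (grid x
direction) tuning.

The coupling is exactly low-rank: the recurrent field depends on the state
only through its mean and two complex harmonic projections, which
:class:`LowRankCoupling1D` exploits for O(N) evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

__all__ = [
    "Manifold1D",
    "WeightParams1D",
    "TransferFn",
    "RateState",
    "IntegratorParams",
    "IntegrationFailure",
    "build_manifold_1d",
    "build_weights_1d",
    "LowRankCoupling1D",
    "recurrent_field_lowrank",
    "transfer",
    "step_rk4",
    "simulate",
    "perturb_weights_gaussian",
    "dilute_weights",
]


class IntegrationFailure(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass(frozen=True)
class Manifold1D:
    """Discretised neural manifold for the linear-track network."""

    n_theta: int
    n_v: int
    v_max: float
    theta_coords: np.ndarray = field(repr=False)
    v_coords: np.ndarray = field(repr=False)

    @property
    def n_units(self) -> int:
        return self.n_theta * self.n_v

    @property
    def theta_grid(self) -> np.ndarray:
        """(n_theta, n_v) array of theta per unit."""
        return np.broadcast_to(self.theta_coords[:, None], (self.n_theta, self.n_v))

    @property
    def v_grid(self) -> np.ndarray:
        """(n_theta, n_v) array of v per unit."""
        return np.broadcast_to(self.v_coords[None, :], (self.n_theta, self.n_v))


def build_manifold_1d(n_theta: int, n_v: int, v_max: float) -> Manifold1D:
    """Uniform discretisation of the (theta, v) manifold.

    ``theta`` is periodic over [0, 2*pi) with ``n_theta`` bins; ``v`` spans
    [-v_max, +v_max] inclusive with ``n_v`` bins.  ``n_v`` must be odd so a
    v = 0 row exists.
    """
    if n_theta < 4:
        raise ValueError(f"n_theta must be >= 4, got {n_theta}")
    if n_v < 1 or n_v % 2 == 0:
        raise ValueError(f"n_v must be odd and >= 1, got {n_v}")
    if v_max <= 0:
        raise ValueError(f"v_max must be positive, got {v_max}")
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    v = np.linspace(-v_max, v_max, n_v) if n_v > 1 else np.zeros(1)
    return Manifold1D(n_theta=n_theta, n_v=n_v, v_max=v_max,
                      theta_coords=theta, v_coords=v)


@dataclass(frozen=True)
class WeightParams1D:
    """Coupling parameters of the 1D network.

    J0 : uniform term (inhibitory, <= 0, in units of the mean-rate drive)
    J1 : strength of the structured (cosine) interaction
    beta : velocity-label shift strength in the spatial cosine; the
        asymmetry phase of a bump at label v is beta*v
    k : number of activity bumps along theta
    norm : divide the coupling by the unit count N (resolution-invariant)
    """

    J0: float = -50.0
    J1: float = 20.0
    beta: float = 0.5
    k: int = 2
    norm: bool = True

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        if self.J1 <= 0:
            raise ValueError(f"J1 must be > 0, got {self.J1}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class TransferFn:
    """Pointwise firing-rate transfer function.

    kind:
      * ``threshold-linear`` -- g(u) = G*u for u > 0, else 0
      * ``threshold-sigmoid`` -- g(u) = tanh(G*u) for u > 0, else 0
        (maximal rate normalised to 1)
      * ``binary`` -- Heaviside step, the G -> infinity sigmoid limit;
        g(u) = 0 at u exactly 0 (measure-zero tie-break)
    """

    kind: str = "threshold-linear"
    gain: float = 1.0

    def __post_init__(self):
        if self.kind not in ("threshold-linear", "threshold-sigmoid", "binary"):
            raise ValueError(f"unknown transfer kind {self.kind!r}")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")

    @property
    def bounded(self) -> bool:
        return self.kind in ("threshold-sigmoid", "binary")


def transfer(u: np.ndarray, tf: TransferFn) -> np.ndarray:
    """Apply the transfer function elementwise; output is always >= 0."""
    u = np.asarray(u)
    if tf.kind == "threshold-linear":
        return np.maximum(tf.gain * u, 0.0)
    if tf.kind == "threshold-sigmoid":
        return np.where(u > 0.0, np.tanh(tf.gain * np.maximum(u, 0.0)), 0.0)
    # binary: 0 at exactly threshold
    return np.where(u > 0.0, 1.0, 0.0)


@dataclass
class RateState:
    """Firing rates on the manifold at one time, shape (n_theta, n_v), in ms."""

    t: float
    m: np.ndarray

    def copy(self) -> "RateState":
        return RateState(t=self.t, m=self.m.copy())


@dataclass(frozen=True)
class IntegratorParams:
    """RK4 integration settings: membrane time constant and step, both in ms."""

    tau: float = 10.0
    dt: float = 0.5

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.dt > self.tau / 10.0:
            raise ValueError(
                f"dt={self.dt} too coarse; require dt <= tau/10 = {self.tau / 10.0}")


def build_weights_1d(manifold: Manifold1D, wp: WeightParams1D) -> np.ndarray:
    """Dense (N x N) weight matrix; row = postsynaptic, column = presynaptic.

    The outgoing profile of a unit with velocity label v peaks at its own
    theta shifted by beta*v/k to the right (for v > 0).
    """
    th = manifold.theta_grid.ravel()
    vv = manifold.v_grid.ravel()
    W = wp.J0 + wp.J1 * (
        np.cos(wp.k * (th[:, None] - th[None, :]) - wp.beta * vv[None, :])
        * np.cos(vv[:, None] - vv[None, :])
    )
    if wp.norm:
        W /= manifold.n_units
    return W


class LowRankCoupling1D:
    """O(N) evaluation of the recurrent field via the exact harmonic split.

    The structured part of the coupling separates into two channels,

        cos(k dth - beta v_j) cos(v_i - v_j)
          = 1/2 cos[(k th_i + v_i) - (k th_j + (beta+1) v_j)]
          + 1/2 cos[(k th_i - v_i) - (k th_j + (beta-1) v_j)]

    so the field is J0*<m> + (J1/2) Re[ e^{i(k th + v)} Za + e^{i(k th - v)} Zb ]
    with Za = <m e^{-i(k th + (beta+1) v)}> and Zb = <m e^{-i(k th + (beta-1) v)}>.
    """

    def __init__(self, manifold: Manifold1D, wp: WeightParams1D):
        self.manifold = manifold
        self.wp = wp
        th = manifold.theta_grid
        vv = manifold.v_grid
        k, beta = wp.k, wp.beta
        self._proj_a = np.exp(-1j * (k * th + (beta + 1.0) * vv))
        self._proj_b = np.exp(-1j * (k * th + (beta - 1.0) * vv))
        self._field_a = np.exp(1j * (k * th + vv))
        self._field_b = np.exp(1j * (k * th - vv))
        # with norm off, projections are sums rather than means
        self._scale = 1.0 / manifold.n_units if wp.norm else 1.0

    def projections(self, m: np.ndarray):
        """(mean, Za, Zb) of a state array of shape (n_theta, n_v)."""
        s = self._scale
        M = float(m.sum()) * s
        Za = complex((m * self._proj_a).sum()) * s
        Zb = complex((m * self._proj_b).sum()) * s
        return M, Za, Zb

    def field_from_projections(self, M: float, Za: complex, Zb: complex) -> np.ndarray:
        wp = self.wp
        return wp.J0 * M + (wp.J1 / 2.0) * np.real(
            self._field_a * Za + self._field_b * Zb)

    def __call__(self, m: np.ndarray) -> np.ndarray:
        return self.field_from_projections(*self.projections(m))


def recurrent_field_lowrank(state: RateState, manifold: Manifold1D,
                            wp: WeightParams1D) -> np.ndarray:
    """Recurrent drive of ``state`` under the analytic (unperturbed) weights.

    Equal to the dense matrix-vector product to within rounding.  Perturbed or
    diluted weight matrices are not separable; use the dense path for those.
    """
    if isinstance(wp, np.ndarray):
        raise TypeError(
            "recurrent_field_lowrank requires analytic WeightParams1D; "
            "perturbed/diluted weight matrices must use the dense product")
    return LowRankCoupling1D(manifold, wp)(state.m)


FieldFn = Callable[[np.ndarray], np.ndarray]


def _as_field_fn(weights_or_lowrank: Union[np.ndarray, LowRankCoupling1D, FieldFn],
                 shape) -> FieldFn:
    if isinstance(weights_or_lowrank, np.ndarray):
        W = weights_or_lowrank

        def dense_field(m: np.ndarray) -> np.ndarray:
            return (W @ m.ravel()).reshape(shape)

        return dense_field
    return weights_or_lowrank


def step_rk4(state: RateState,
             external_input: Union[float, np.ndarray],
             weights_or_lowrank: Union[np.ndarray, LowRankCoupling1D, FieldFn],
             tf: TransferFn,
             ip: IntegratorParams) -> RateState:
    """One RK4 step of tau dm/dt = -m + g(recurrent + external).

    Rates stay non-negative through the transfer function alone; no post-hoc
    clipping is applied.
    """
    m = state.m
    field_fn = _as_field_fn(weights_or_lowrank, m.shape)
    I = external_input
    tau, dt = ip.tau, ip.dt

    def f(mm: np.ndarray) -> np.ndarray:
        return (-mm + transfer(I + field_fn(mm), tf)) / tau

    k1 = f(m)
    k2 = f(m + 0.5 * dt * k1)
    k3 = f(m + 0.5 * dt * k2)
    k4 = f(m + dt * k3)
    m_new = m + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.isfinite(m_new)):
        u = I + field_fn(m)
        raise IntegrationFailure(
            f"non-finite state after step at t={state.t + dt:.3f} ms "
            f"(max |u| before step = {np.abs(u).max():.3g})")
    return RateState(t=state.t + dt, m=m_new)


def simulate(state: RateState,
             input_fn: Callable[[float], Union[float, np.ndarray]],
             weights_or_lowrank,
             tf: TransferFn,
             ip: IntegratorParams,
             duration: float,
             callback: Optional[Callable[[int, RateState], None]] = None,
             callback_every: int = 1) -> RateState:
    """Integrate for ``duration`` ms; ``input_fn(t)`` supplies the drive.

    ``callback(step_index, state)`` is invoked every ``callback_every`` steps
    after the state update (step_index counts completed steps from 1).
    """
    field_fn = _as_field_fn(weights_or_lowrank, state.m.shape)
    n_steps = int(round(duration / ip.dt))
    for i in range(1, n_steps + 1):
        state = step_rk4(state, input_fn(state.t), field_fn, tf, ip)
        if callback is not None and i % callback_every == 0:
            callback(i, state)
    return state


def jittered_initial_state(manifold: Manifold1D, seed: int,
                           level: float = 0.05, jitter: float = 0.01) -> RateState:
    """Small positive uniform rate with multiplicative jitter.

    The deterministic dynamics preserve theta-uniformity exactly, so the
    jitter is what allows spatial structure to grow from a featureless start.
    """
    rng = np.random.default_rng(seed)
    m = level * (1.0 + jitter * rng.standard_normal((manifold.n_theta, manifold.n_v)))
    return RateState(t=0.0, m=np.maximum(m, 0.0))


def bump_seeded_state(manifold: Manifold1D, wp: WeightParams1D, vhat: float,
                      sigma_v: float = 0.2, amplitude: float = 0.5,
                      phase: float = 0.0) -> RateState:
    """Bump-like initial state centred at spatial phase ``phase`` and label ``vhat``."""
    th = manifold.theta_grid
    vv = manifold.v_grid
    prof = np.maximum(np.cos(wp.k * (th - phase)), 0.0)
    env = np.exp(-((vv - vhat) ** 2) / (2.0 * sigma_v ** 2))
    return RateState(t=0.0, m=amplitude * prof * env)


def perturb_weights_gaussian(W: np.ndarray, frac: float, seed: int) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise, sd = frac * (max(W) - min(W)).

    Returns a new matrix; ``W`` is untouched.
    """
    if frac < 0:
        raise ValueError("frac must be >= 0")
    if frac == 0:
        return W.copy()
    rng = np.random.default_rng(seed)
    sd = frac * (W.max() - W.min())
    return W + sd * rng.standard_normal(W.shape)


def dilute_weights(W: np.ndarray, rho: float, seed: int) -> np.ndarray:
    """Zero each entry independently with probability ``rho``.

    Survivors are rescaled by 1/(1-rho) so the expected entry is preserved.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if rho == 0:
        return W.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(W.shape) >= rho
    return (W * mask) / (1.0 - rho)
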