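"""Velocity-tuned input: mapping from animal velocity to the velocity axis.

For path integration the bump pattern must advance one spatial period
(2*pi/k radians) in exactly the time the animal covers one grid spacing S, so
the bump speed must equal (2*pi/(k*S)) * V.  The mapping Lambda inverts the
intrinsic ring speed law to find the velocity-axis position that produces the
required speed; the external input is untuned in theta and Gaussian in v
around Lambda(V).

Besides the closed-form (ring-law) mapping, a lookup table over velocity bins
is provided, and the mapping can alternatively be calibrated directly from
simulated bump-speed measurements of the full network (the residual between
the ring approximation and the full network is then absorbed into the
mapping, as a developmentally learned mapping would be).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from conjgrid.network1d import Manifold1D
from conjgrid.theory import RingReduction, ring_admissible_vhat, ring_speed

logger = logging.getLogger(__name__)

__all__ = [
    "VelocityMapping",
    "InputParams",
    "desired_vhat",
    "build_lookup",
    "gaussian_input_1d",
    "gaussian_input_2d",
    "mapping_from_curve",
]

MS_PER_S = 1000.0


@dataclass(frozen=True)
class InputParams:
    """External drive: baseline I0, velocity-tuning strength and width."""

    I0: float = 1.0
    alpha_v: float = 2.0
    sigma_v: float = 0.12

    def __post_init__(self):
        if self.sigma_v <= 0:
            raise ValueError("sigma_v must be > 0")
        if self.alpha_v < 0:
            raise ValueError("alpha_v must be >= 0")


def required_speed(V: float, S: float, k: int) -> float:
    """Bump speed (rad/ms along theta) required for animal speed V (cm/s)."""
    return 2.0 * np.pi * V / (k * S * MS_PER_S)


def desired_vhat(V: float, ring: RingReduction, S: float,
                 tol: float = 1e-10) -> float:
    """Velocity-axis position whose intrinsic speed path-integrates V (cm/s).

    Solves ring_speed(vhat) = 2*pi*V / (k*S*1000) by monotone bisection on
    the ring law.  Odd in V; raises when |V| exceeds the reachable speed,
    naming the admissible maximum.
    """
    if V == 0:
        return 0.0
    lo, hi = ring_admissible_vhat(ring)
    target = required_speed(V, S, ring.k)
    vmax_adm = hi * (1.0 - 1e-9)
    reach = ring_speed(vmax_adm, ring)
    if abs(target) >= reach:
        Vmax = reach * ring.k * S * MS_PER_S / (2.0 * np.pi)
        raise ValueError(
            f"animal speed {V} cm/s unreachable; admissible max is "
            f"{Vmax:.2f} cm/s for S={S} cm")
    a, b = (0.0, vmax_adm) if V > 0 else (-vmax_adm, 0.0)
    while b - a > tol:
        mid = 0.5 * (a + b)
        if ring_speed(mid, ring) < target:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


@dataclass
class VelocityMapping:
    """Animal velocity (cm/s) -> velocity-axis position.

    mode is ``closed_form`` (bisection on the ring speed law), ``lookup``
    (binned table of the same), or ``calibrated`` (table built from measured
    full-network speeds).  Lambda(0) = 0 and Lambda is odd by construction.
    """

    S: float
    ring: RingReduction
    mode: str = "closed_form"
    lookup_bins: int = 201
    lookup_range: float = 100.0
    _centers: Optional[np.ndarray] = field(default=None, repr=False)
    _values: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        if self.mode not in ("closed_form", "lookup", "calibrated"):
            raise ValueError(f"unknown mapping mode {self.mode!r}")
        if self.mode == "lookup" and self._centers is None:
            self._centers, self._values = build_lookup(self, self.lookup_bins)

    @property
    def bin_width(self) -> float:
        return 2.0 * self.lookup_range / self.lookup_bins

    def __call__(self, V):
        if self.mode == "closed_form":
            if np.ndim(V) == 0:
                return desired_vhat(float(V), self.ring, self.S)
            return np.array([desired_vhat(float(x), self.ring, self.S) for x in V])
        return self._query_table(V)

    def _query_table(self, V):
        V_arr = np.atleast_1d(np.asarray(V, dtype=float))
        lo, hi = -self.lookup_range, self.lookup_range
        if np.any((V_arr < lo) | (V_arr > hi)):
            logger.warning("velocity query outside [%.1f, %.1f] cm/s clamped "
                           "to end bins", lo, hi)
            V_arr = np.clip(V_arr, lo, hi)
        idx = np.clip(((V_arr - lo) / self.bin_width).astype(int), 0,
                      self.lookup_bins - 1)
        out = self._values[idx]
        return float(out[0]) if np.ndim(V) == 0 else out


def build_lookup(mapping: VelocityMapping, n_bins: int):
    """Tabulate desired_vhat at bin centres over [-range, +range] cm/s.

    Queries return the stored value of the bin containing the velocity (the
    bin centre is the argument of the mapping).
    """
    r = mapping.lookup_range
    width = 2.0 * r / n_bins
    centers = -r + width * (np.arange(n_bins) + 0.5)
    values = np.array([desired_vhat(c, mapping.ring, mapping.S) if c != 0 else 0.0
                       for c in centers])
    return centers, values


def mapping_from_curve(vhat_grid: np.ndarray, speed_grid: np.ndarray,
                       S: float, ring: RingReduction,
                       n_bins: int = 201, lookup_range: float = 100.0) -> VelocityMapping:
    """Calibrated mapping from a measured speed(vhat) curve of the full network.

    The curve (odd-extended and monotone) is inverted by interpolation at each
    velocity bin's required bump speed.
    """
    vh = np.concatenate([-vhat_grid[::-1], vhat_grid[1:]]) if vhat_grid[0] == 0 \
        else np.concatenate([-vhat_grid[::-1], vhat_grid])
    sp = np.concatenate([-speed_grid[::-1], speed_grid[1:]]) if vhat_grid[0] == 0 \
        else np.concatenate([-speed_grid[::-1], speed_grid])
    order = np.argsort(sp)
    sp, vh = sp[order], vh[order]
    width = 2.0 * lookup_range / n_bins
    centers = -lookup_range + width * (np.arange(n_bins) + 0.5)
    targets = required_speed(centers, S, ring.k)
    if np.any(targets < sp[0]) or np.any(targets > sp[-1]):
        raise ValueError("calibration curve does not cover the required speed range")
    values = np.interp(targets, sp, vh)
    m = VelocityMapping(S=S, ring=ring, mode="calibrated", lookup_bins=n_bins,
                        lookup_range=lookup_range)
    m._centers, m._values = centers, values
    return m


def gaussian_input_1d(V: float, manifold: Manifold1D, ip: InputParams,
                      mapping: VelocityMapping) -> np.ndarray:
    """Velocity-tuned external input, shape (n_theta, n_v).

    Uniform in theta, Gaussian in v centred at Lambda(V) with width sigma_v
    and strength alpha_v on top of the baseline I0.
    """
    vhat = mapping(V)
    prof = ip.I0 + ip.alpha_v * np.exp(
        -((manifold.v_coords - vhat) ** 2) / (2.0 * ip.sigma_v ** 2))
    return np.broadcast_to(prof[None, :], (manifold.n_theta, manifold.n_v)).copy()


def gaussian_input_2d(Vx: float, Vy: float, manifold2d, ip: InputParams,
                      mapping_x: VelocityMapping,
                      mapping_y: Optional[VelocityMapping] = None) -> np.ndarray:
    """2D velocity-tuned input, shape (nt, nt, nv, nv): product of per-axis
    Gaussian tunings centred at (Lambda_x(Vx), Lambda_y(Vy)).

    Separate per-axis mappings support unequal grid scales (elliptical grids).
    """
    if mapping_y is None:
        mapping_y = mapping_x
    vx_hat, vy_hat = mapping_x(Vx), mapping_y(Vy)
    v = manifold2d.v_coords
    gx = np.exp(-((v - vx_hat) ** 2) / (2.0 * ip.sigma_v ** 2))
    gy = np.exp(-((v - vy_hat) ** 2) / (2.0 * ip.sigma_v ** 2))
    prof = ip.I0 + ip.alpha_v * gx[:, None] * gy[None, :]
    nt, nv = manifold2d.n_theta, manifold2d.n_v
    return np.broadcast_to(prof[None, None, :, :], (nt, nt, nv, nv)).copy()
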