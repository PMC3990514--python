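"""Decoding bump phase/velocity, position reconstruction, rate maps, grid metrics.

The bump pattern's spatial phase is read out with the population vector at
harmonic k; one pattern period (2*pi/k radians) corresponds to one grid
spacing S in physical space, so decoded position advances S cm per 2*pi of
unwrapped k*theta phase.  Rate maps are occupancy-normalised means over
behavioural bins with unsampled bins marked missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from conjgrid.network1d import Manifold1D, RateState
from conjgrid.network2d import circ_dist

__all__ = [
    "BumpTrack",
    "RateMap",
    "GridMetrics",
    "UndefinedPhase",
    "UnwrapFailure",
    "bump_center",
    "bump_velocity",
    "decode_position",
    "tracking_error_and_drift",
    "rate_map",
    "rate_map_2d",
    "grid_metrics",
    "autocorrelogram",
    "hex_peak_angles",
    "direction_selectivity",
    "field_shift",
    "find_field_peaks_1d",
]


class UndefinedPhase(ValueError):
    """Raised when the bump amplitude is too small to define a phase."""


class UnwrapFailure(RuntimeError):
    """Raised when a per-step phase jump exceeds the unwrap limit pi/k."""


@dataclass
class BumpTrack:
    """Time series of bump phase and the decoded position."""

    t: np.ndarray
    psi_theta: np.ndarray        # wrapped phase of the pattern, [0, 2*pi/k)
    psi_v: np.ndarray
    unwrapped_phase: np.ndarray  # continuous k*theta phase, radians
    period: float = 2.0 * np.pi  # wrapped-phase period, 2*pi/k
    decoded_position: Optional[np.ndarray] = None  # cm


@dataclass
class RateMap:
    """Occupancy-normalised firing map; rate is NaN where occupancy < min_occ."""

    edges: Tuple[np.ndarray, ...]
    occupancy: np.ndarray
    rate: np.ndarray

    @property
    def centers(self) -> Tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)


@dataclass
class GridMetrics:
    spacing_x: float
    spacing_y: float
    orientation: float      # degrees of the first peak direction
    ellipse_ratio: float    # major/minor, >= 1
    field_count: int


def bump_center(state: RateState, manifold: Manifold1D, k: int,
                amp_tol: float = 1e-6) -> Tuple[float, float]:
    """(psi_theta, psi_v) of the bump pattern via population vectors.

    psi_theta is the complex argument of the k-th spatial harmonic divided by
    k (position of one bump modulo the pattern period); psi_v maps the
    velocity axis onto a half-circle and takes the argument, which is robust
    to truncation at the axis ends.  Raises UndefinedPhase for states without
    harmonic structure (e.g. uniform).
    """
    m = state.m
    th = manifold.theta_grid
    z = (m * np.exp(1j * k * th)).sum()
    total = m.sum()
    if total <= 0 or abs(z) < amp_tol * max(total, 1e-30):
        raise UndefinedPhase("bump amplitude below threshold; phase undefined")
    psi_theta = (np.angle(z) / k) % (2.0 * np.pi / k)
    a = 0.5 * np.pi / manifold.v_max
    zv = (m * np.exp(1j * a * manifold.v_grid)).sum()
    psi_v = np.angle(zv) / a
    return psi_theta, psi_v


def bump_velocity(track: BumpTrack, window: int = 1) -> np.ndarray:
    """Instantaneous pattern speed (rad/ms along theta) by circular difference.

    Computed per recorded step from the wrapped phase with the circular
    difference at period 2*pi/k, optionally smoothed with a centered moving
    average of ``window`` samples.  Output has the same length as the track
    (first element repeated).
    """
    psi = track.psi_theta
    dt = np.diff(track.t)
    dphi = _circ_diff(psi[1:], psi[:-1], track.period)
    v = dphi / dt
    v = np.concatenate([[v[0]], v])
    if window > 1:
        kern = np.ones(window) / window
        v = np.convolve(v, kern, mode="same")
    return v


def _circ_diff(a, b, period):
    return (a - b + 0.5 * period) % period - 0.5 * period


def make_track(t: np.ndarray, psi_theta: np.ndarray, psi_v: np.ndarray,
               k: int) -> BumpTrack:
    """Assemble a BumpTrack, unwrapping the k*theta phase.

    Raises UnwrapFailure if any per-step jump reaches the half-period pi/k.
    """
    period = 2.0 * np.pi / k
    d = _circ_diff(psi_theta[1:], psi_theta[:-1], period)
    if np.any(np.abs(d) >= 0.5 * period * 0.999):
        raise UnwrapFailure("per-step phase jump >= pi/k; cannot unwrap")
    unwrapped = np.concatenate([[psi_theta[0]], psi_theta[0] + np.cumsum(d)]) * k
    return BumpTrack(t=t, psi_theta=psi_theta, psi_v=psi_v,
                     unwrapped_phase=unwrapped, period=period)


def decode_position(track: BumpTrack, S: float, k: int,
                    anchor: float = 0.0, sign: float = 1.0) -> np.ndarray:
    """Decode position from the phase history: S cm per 2*pi of k*theta phase.

    Anchored once at t = 0 (pure path integration, no re-anchoring).
    """
    phase = track.unwrapped_phase - track.unwrapped_phase[0]
    pos = anchor + sign * phase * S / (2.0 * np.pi)
    track.decoded_position = pos
    return pos


def tracking_error_and_drift(decoded: np.ndarray, actual: np.ndarray,
                             runs: Optional[Sequence[np.ndarray]] = None):
    """(error series, mean drift series).

    Error is decoded - actual; drift is |error| averaged across the given
    independent runs (each an error series) or, if none, the single run.
    """
    err = np.asarray(decoded) - np.asarray(actual)
    if runs is None:
        drift = np.abs(err)
    else:
        drift = np.mean([np.abs(np.asarray(r)) for r in runs], axis=0)
    return err, drift


def rate_map(activity: np.ndarray, covariates: Sequence[np.ndarray],
             bin_edges: Sequence[np.ndarray], min_occ: int = 2) -> RateMap:
    """Occupancy-weighted mean rate over behavioural bins (any dimensionality).

    ``activity``: (n_samples,) unit rate; ``covariates``: one array per map
    axis (position, velocity, head direction, ...); bins with fewer than
    ``min_occ`` samples are NaN.
    """
    edges = tuple(np.asarray(e) for e in bin_edges)
    shape = tuple(len(e) - 1 for e in edges)
    idx = []
    valid = np.ones(len(activity), dtype=bool)
    for cov, e in zip(covariates, edges):
        i = np.digitize(cov, e) - 1
        valid &= (i >= 0) & (i < len(e) - 1)
        idx.append(i)
    flat = np.ravel_multi_index([i[valid] for i in idx], shape)
    occ = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)
    tot = np.bincount(flat, weights=np.asarray(activity)[valid],
                      minlength=int(np.prod(shape))).reshape(shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ >= min_occ, tot / np.maximum(occ, 1), np.nan)
    return RateMap(edges=edges, occupancy=occ, rate=rate)


def rate_map_2d(activity, x, y, arena_side: float, bin_cm: float = 5.0,
                min_occ: int = 2) -> RateMap:
    e = np.arange(0.0, arena_side + bin_cm * 0.5, bin_cm)
    return rate_map(activity, [x, y], [e, e], min_occ=min_occ)


def autocorrelogram(map2d: np.ndarray) -> np.ndarray:
    """Spatial autocorrelation of a (possibly NaN-masked) 2D rate map.

    NaN bins are treated as missing: correlation is normalised by the overlap
    count at each lag (periodic FFT implementation, adequate for maps that
    tile the arena).
    """
    z = np.asarray(map2d, dtype=float)
    mask = np.isfinite(z)
    z0 = np.where(mask, z - np.nanmean(z), 0.0)
    F = np.fft.fft2(z0)
    num = np.real(np.fft.ifft2(F * np.conj(F)))
    Fm = np.fft.fft2(mask.astype(float))
    cnt = np.real(np.fft.ifft2(Fm * np.conj(Fm)))
    with np.errstate(invalid="ignore", divide="ignore"):
        ac = np.where(cnt > 0, num / np.maximum(cnt, 1), 0.0)
    ac = np.fft.fftshift(ac)
    c = ac[tuple(s // 2 for s in ac.shape)]
    return ac / c if c > 0 else ac


def _local_maxima(ac: np.ndarray, rel_thresh: float = 0.2):
    """(di, dj, value) of local maxima of the centered autocorrelogram."""
    n0, n1 = ac.shape
    c0, c1 = n0 // 2, n1 // 2
    mx = ndimage.maximum_filter(ac, size=3, mode="wrap")
    peaks = []
    thr = rel_thresh * ac[c0, c1]
    for i in range(n0):
        for j in range(n1):
            if (i, j) == (c0, c1):
                continue
            if ac[i, j] == mx[i, j] and ac[i, j] > thr:
                peaks.append((i - c0, j - c1, ac[i, j]))
    # the autocorrelogram is centro-symmetric; peaks at exactly half-period
    # lags represent both +p and -p, so symmetrise the direction set
    seen = {(p[0], p[1]) for p in peaks}
    for p in list(peaks):
        q = (-p[0], -p[1])
        qw = ((q[0] + c0) % n0 - c0, (q[1] + c1) % n1 - c1)
        if q not in seen and qw in seen and q != qw:
            peaks.append((q[0], q[1], p[2]))
            seen.add(q)
    return peaks


def _refine_peak(ac: np.ndarray, peak) -> tuple:
    """Sub-bin peak location by per-axis parabolic interpolation."""
    n0, n1 = ac.shape
    c0, c1 = n0 // 2, n1 // 2
    i, j = peak[0] + c0, peak[1] + c1

    def delta(fm, f0, fp):
        den = 2.0 * f0 - fm - fp
        if den <= 0:
            return 0.0
        return float(np.clip((fp - fm) / (2.0 * den), -0.5, 0.5))

    di = delta(ac[(i - 1) % n0, j % n1], ac[i % n0, j % n1],
               ac[(i + 1) % n0, j % n1])
    dj = delta(ac[i % n0, (j - 1) % n1], ac[i % n0, j % n1],
               ac[i % n0, (j + 1) % n1])
    return peak[0] + di, peak[1] + dj


def hex_peak_angles(ac: np.ndarray, n_peaks: int = 6):
    """Angles (deg) of the ``n_peaks`` nearest autocorrelogram peaks.

    Returns (angles sorted, max deviation from the best-rotated ideal
    60-degree template).  Raises ValueError with an insufficient-structure
    message when fewer than ``n_peaks`` peaks exist.
    """
    peaks = _local_maxima(ac)
    if len(peaks) < n_peaks:
        raise ValueError(
            f"insufficient structure: found {len(peaks)} autocorrelogram "
            f"peaks, need {n_peaks}")
    peaks.sort(key=lambda p: np.hypot(p[0], p[1]))
    # keep nearest ring: nearest six, dropping collinear duplicates at 2x radius
    near = peaks[:n_peaks]
    ang = np.sort([np.degrees(np.arctan2(p[1], p[0])) % 360.0 for p in near])
    ideal = np.arange(6) * 60.0
    best = np.inf
    for rot in np.arange(0.0, 60.0, 0.25):
        dev = np.abs((ang - (ideal + rot) + 180.0) % 360.0 - 180.0).max()
        best = min(best, dev)
    return ang, best


def grid_metrics(map2d: np.ndarray, bin_size: float = 1.0) -> GridMetrics:
    """Grid spacing per axis, orientation and ellipse ratio from the
    autocorrelogram's six nearest peaks.

    ``spacing_x`` is the mean |x-lag| of the peak pair closest to the x axis;
    ``spacing_y`` the mean |y-lag| of the remaining (off-axis) peaks, i.e.
    the row period of the lattice.  The ellipse ratio is major/minor of the
    best-fit ellipse through the six peaks.
    """
    ac = autocorrelogram(map2d)
    peaks = _local_maxima(ac)
    if len(peaks) < 6:
        raise ValueError(f"insufficient structure: {len(peaks)} peaks < 6")
    peaks.sort(key=lambda p: np.hypot(p[0], p[1]))
    six = np.array([_refine_peak(ac, p) for p in peaks[:6]], dtype=float)
    angs = np.degrees(np.arctan2(six[:, 1], six[:, 0]))
    # per-axis spacing from the lattice-template fit when it applies;
    # otherwise the mean nearest-peak distance on both axes
    try:
        spacing_x, spacing_y, _ = lattice_spacing_ratio(map2d, bin_size)
    except ValueError:
        spacing_x = spacing_y = float(
            np.mean(np.hypot(six[:, 0], six[:, 1]))) * bin_size
    orientation = float(np.min(np.abs(angs)))
    # algebraic ellipse through the six peaks: a x^2 + b xy + c y^2 = 1
    x, y = six[:, 0] * bin_size, six[:, 1] * bin_size
    Amat = np.column_stack([x * x, x * y, y * y])
    coef, *_ = np.linalg.lstsq(Amat, np.ones(6), rcond=None)
    a, b, c = coef
    M = np.array([[a, b / 2.0], [b / 2.0, c]])
    ev = np.linalg.eigvalsh(M)
    if np.any(ev <= 0):
        ratio = np.nan
    else:
        axes = 1.0 / np.sqrt(ev)        # semi-axes, descending -> major first
        ratio = float(axes.max() / axes.min())
    # field count on the original map (peaks above 20% of max)
    z = np.nan_to_num(np.asarray(map2d, float), nan=0.0)
    mx = ndimage.maximum_filter(z, size=3, mode="wrap")
    fields = int(np.sum((z == mx) & (z > 0.2 * z.max())))
    return GridMetrics(spacing_x=spacing_x, spacing_y=spacing_y,
                       orientation=orientation, ellipse_ratio=ratio,
                       field_count=fields)


def lattice_spacing_ratio(map2d: np.ndarray, bin_size: float = 1.0):
    """Per-axis grid scale (Sx, Sy) by fitting the offset-lattice template.

    The network's spatial pattern is an offset-row lattice with primitive
    vectors (S, 0) and (S/2, S) in the isotropic case; per-axis scaling maps
    these to (Sx mx, Sy my) with (mx, my) from the template in either of the
    two degenerate orientations.  The two shortest independent
    autocorrelogram peaks are least-squares fit against both orientations and
    the better fit wins.  Returns (Sx, Sy, Sx/Sy).
    """
    ac = autocorrelogram(map2d)
    peaks = _local_maxima(ac)
    if len(peaks) < 4:
        raise ValueError(f"insufficient structure: {len(peaks)} peaks < 4")
    peaks.sort(key=lambda p: np.hypot(p[0], p[1]))
    pts = [np.array(_refine_peak(ac, p)) * bin_size for p in peaks]
    a1 = pts[0]
    a2 = None
    for p in pts[1:]:
        cross = a1[0] * p[1] - a1[1] * p[0]
        if abs(cross) > 0.2 * (np.linalg.norm(a1) * np.linalg.norm(p)):
            a2 = p
            break
    if a2 is None:
        raise ValueError("insufficient structure: no independent lattice vector")
    templates = [np.array([[1.0, 0.0], [0.5, 1.0]]),
                 np.array([[1.0, 0.0], [-0.5, 1.0]]),
                 np.array([[0.0, 1.0], [1.0, 0.5]]),
                 np.array([[0.0, 1.0], [1.0, -0.5]])]
    best = None
    for T in templates:
        for order in ((a1, a2), (a2, a1)):
            for s1 in (1, -1):
                for s2 in (1, -1):
                    A = np.vstack([s1 * order[0], s2 * order[1]])
                    # solve per-axis: A[:,0] = Sx*T[:,0], A[:,1] = Sy*T[:,1]
                    denx = (T[:, 0] ** 2).sum()
                    deny = (T[:, 1] ** 2).sum()
                    Sx = float((T[:, 0] * A[:, 0]).sum() / denx)
                    Sy = float((T[:, 1] * A[:, 1]).sum() / deny)
                    if Sx <= 0 or Sy <= 0:
                        continue
                    resid = np.linalg.norm(A - np.column_stack(
                        [Sx * T[:, 0], Sy * T[:, 1]]))
                    if best is None or resid < best[0]:
                        best = (resid, Sx, Sy)
    if best is None:
        raise ValueError("lattice template fit failed")
    resid, Sx, Sy = best
    if resid > 0.15 * (np.linalg.norm(a1) + np.linalg.norm(a2)):
        raise ValueError(
            f"lattice template fit failed (residual {resid:.2f})")
    return Sx, Sy, Sx / Sy


def direction_selectivity(direction_tuning: RateMap,
                          threshold: float = 0.2) -> str:
    """Classify a unit as ``conjunctive`` or ``pure_grid``.

    A unit is conjunctive when the mean resultant length of its
    direction-binned rates exceeds ``threshold``.
    """
    centers = direction_tuning.centers[0]
    r = direction_tuning.rate
    ok = np.isfinite(r)
    if not np.any(ok) or np.nansum(r) <= 0:
        return "pure_grid"
    z = np.nansum(r[ok] * np.exp(1j * centers[ok])) / np.nansum(r[ok])
    return "conjunctive" if abs(z) > threshold else "pure_grid"


def resultant_length(direction_tuning: RateMap) -> float:
    centers = direction_tuning.centers[0]
    r = direction_tuning.rate
    ok = np.isfinite(r)
    if not np.any(ok) or np.nansum(r) <= 0:
        return 0.0
    return float(abs(np.nansum(r[ok] * np.exp(1j * centers[ok])) / np.nansum(r[ok])))


def find_field_peaks_1d(rm: RateMap, min_separation: float,
                        rel_thresh: float = 0.2) -> np.ndarray:
    """Positions (cm) of firing-field peaks in a 1D spatial rate map.

    Local maxima above ``rel_thresh`` of the map peak, greedily enforcing the
    minimum separation (strongest first).
    """
    x = rm.centers[0]
    r = np.nan_to_num(rm.rate, nan=0.0)
    cand = [i for i in range(len(r))
            if r[i] > rel_thresh * r.max()
            and r[i] >= r[max(0, i - 1)] and r[i] >= r[min(len(r) - 1, i + 1)]]
    cand.sort(key=lambda i: -r[i])
    kept = []
    for i in cand:
        if all(abs(x[i] - x[j]) >= min_separation for j in kept):
            kept.append(i)
    return np.sort(x[kept])


def field_shift(maps_by_direction: Dict[str, RateMap],
                period: Optional[float] = None) -> float:
    """Field-centre offset (cm) between running directions.

    Cross-correlates the two direction-conditioned 1D spatial maps and
    returns the lag of maximal correlation (positive: the map for the
    positive running direction is shifted toward larger positions).
    Symmetric maps give 0.
    """
    keys = sorted(maps_by_direction)
    if len(keys) != 2:
        raise ValueError("need exactly two direction-conditioned maps")
    a = np.nan_to_num(maps_by_direction[keys[0]].rate, nan=0.0)
    b = np.nan_to_num(maps_by_direction[keys[1]].rate, nan=0.0)
    a = a - a.mean()
    b = b - b.mean()
    n = len(a)
    corr = np.real(np.fft.ifft(np.fft.fft(b) * np.conj(np.fft.fft(a))))
    lags = np.arange(n)
    lags[lags > n // 2] -= n
    best = int(lags[np.argmax(corr)])
    dx = maps_by_direction[keys[0]].centers[0]
    binw = dx[1] - dx[0] if len(dx) > 1 else 1.0
    return best * binw
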