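"""FAP retention indexing and retention-time locking.

The FAP retention index generalises the linear temperature-programmed
(van den Dool-Kratz) index to a ladder of fatty acid pyrrolidides (FAPs)
that bracket the silylated-sterol elution range:

    RI_FAP = 100 * [ n + (t - t(n)) / (t(N) - t(n)) ]

with n and N the carbon numbers of the FAPs eluting immediately before and
after the analyte and t the corresponding retention times.  Each anchor sits
exactly at 100 x its carbon number, and because the index is invariant under
any affine transform of the time axis it absorbs uniform run-to-run drift.

Retention time locking (RTL) keeps the absolute time axis in place as well:
the 24:0 pyrrolidide is measured at the nominal inlet pressure and at
-20/-10/+10/+20 % deviations, the rt(p) relation is fitted, and the pressure
that puts 24:0-P back at its locked target (32.972 min) is solved for.  The
fit is quadratic in *inverse* pressure, since at constant temperature the
transit time of a compound scales essentially with 1/p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnchorGapError, CalibrationError, ExtrapolationError, OutOfLadderError

#: published lock settings for the FAP ladder
LOCK_CARBON = 24
LOCK_TARGET_MIN = 32.972

#: nominal relative calibration pressures
CALIBRATION_PRESSURES = (0.8, 0.9, 1.0, 1.1, 1.2)


def round_half_up(x: float) -> int:
    """RI values are reported as whole numbers (round half up)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class RIValue:
    """A FAP retention index with its bracketing anchor carbons."""

    value: float
    bracketing_carbons: tuple[int, int]

    def __post_init__(self):
        n, N = self.bracketing_carbons
        if not (100.0 * n - 1e-9 <= self.value <= 100.0 * N + 1e-9):
            raise ValueError(f"RI {self.value} outside bracket {n}-{N}")

    @property
    def rounded(self) -> int:
        return round_half_up(self.value)

    def __float__(self) -> float:
        return self.value


def _sorted_anchor_items(anchors) -> list[tuple[int, float]]:
    items = sorted(anchors.anchors.items())
    return items


def compute_ri_fap(t: float, anchors) -> RIValue:
    """FAP retention index of an analyte at time (or any monotone RT proxy) ``t``.

    ``anchors`` is a :class:`~fapindex.chrom.FAPAnchorSet` (or anything with an
    ``anchors`` mapping carbon -> time).  Raises
    :class:`~fapindex.errors.OutOfLadderError` outside the ladder (with a hint
    towards the 26:0 pyrrolidide for late eluters) and
    :class:`~fapindex.errors.AnchorGapError` when the bracketing carbons are
    not consecutive.
    """
    items = _sorted_anchor_items(anchors)
    carbons = [c for c, _ in items]
    times = [rt for _, rt in items]
    if t < times[0]:
        raise OutOfLadderError(
            f"t={t} elutes before the first anchor ({carbons[0]}:0-P at {times[0]})")
    if t > times[-1]:
        raise OutOfLadderError(
            f"t={t} elutes after the last anchor ({carbons[-1]}:0-P at {times[-1]})",
            hint="consider including the 26:0 pyrrolidide in the internal-standard mix")
    # anchor identity: exact hit on an anchor
    for c, rt in items:
        if t == rt:
            lo = c if c < carbons[-1] else c - 1
            return RIValue(100.0 * c, (lo, lo + 1))
    idx = int(np.searchsorted(times, t)) - 1
    n, t_n = items[idx]
    N, t_N = items[idx + 1]
    if N != n + 1:
        raise AnchorGapError(
            f"anchor ladder has a gap between {n}:0-P and {N}:0-P spanning t={t}")
    value = 100.0 * (n + (t - t_n) / (t_N - t_n))
    return RIValue(value, (n, N))


def invert_ri_fap(ri: float, anchors) -> float:
    """Retention time at which an analyte of index ``ri`` elutes on this ladder."""
    ri = float(ri)
    items = _sorted_anchor_items(anchors)
    carbons = [c for c, _ in items]
    lookup = dict(items)
    if not (100.0 * carbons[0] <= ri <= 100.0 * carbons[-1]):
        raise OutOfLadderError(
            f"RI {ri} outside the anchor ladder {100 * carbons[0]}-{100 * carbons[-1]}")
    n = int(ri // 100)
    if n == carbons[-1]:  # exactly the last anchor
        return lookup[n]
    if n not in lookup or n + 1 not in lookup:
        raise AnchorGapError(f"anchors {n} and {n + 1} required to invert RI {ri}")
    t_n, t_N = lookup[n], lookup[n + 1]
    return t_n + (ri / 100.0 - n) * (t_N - t_n)


def compute_rrt(t: float, t_reference: float) -> float:
    """Retention time relative to the internal standard (5a-cholestane)."""
    if t_reference <= 0:
        raise ValueError(f"reference retention time must be positive, got {t_reference}")
    return t / t_reference


# ---------------------------------------------------------------------------
# retention time locking


@dataclass(frozen=True)
class RTLCalibration:
    """Five-point pressure calibration of the lock compound's retention time.

    ``coefficients`` are for rt(p) = c0 + c1*(1/p) + c2*(1/p)^2 (highest order
    last); pressures are relative to the nominal method pressure.
    """

    points: tuple[tuple[float, float], ...]
    coefficients: tuple[float, float, float]
    lock_target: float
    residual_norm: float
    degenerate: bool = False
    non_monotone: bool = False

    def predict(self, pressure: float) -> float:
        q = 1.0 / pressure
        c0, c1, c2 = self.coefficients
        return c0 + c1 * q + c2 * q * q

    @property
    def rt_range(self) -> tuple[float, float]:
        rts = [rt for _, rt in self.points]
        return min(rts), max(rts)


def fit_rtl_calibration(points, lock_target: float = LOCK_TARGET_MIN,
                        pressure_tolerance: float = 0.02,
                        residual_tolerance: float = 0.05) -> RTLCalibration:
    """Least-squares fit of rt(1/p) to the five calibration measurements.

    ``points`` are (relative pressure, retention time) pairs measured at the
    nominal pressure and at -20/-10/+10/+20 % deviations.
    """
    pts = tuple((float(p), float(rt)) for p, rt in points)
    if len(pts) != 5:
        raise CalibrationError(f"exactly 5 calibration points required, got {len(pts)}")
    pressures = np.array([p for p, _ in pts])
    rts = np.array([rt for _, rt in pts])
    if len(np.unique(pressures)) != 5:
        raise CalibrationError("calibration pressures must be distinct")
    expected = np.sort(np.array(CALIBRATION_PRESSURES))
    if np.max(np.abs(np.sort(pressures) - expected)) > pressure_tolerance:
        raise CalibrationError(
            f"calibration pressures {sorted(pressures)} deviate from the nominal "
            f"grid {CALIBRATION_PRESSURES} by more than {pressure_tolerance}")
    q = 1.0 / pressures
    degenerate = bool(np.allclose(rts, rts[0]))
    coeffs = np.polyfit(q, rts, 2)  # highest order first
    c2, c1, c0 = coeffs
    resid = rts - (c0 + c1 * q + c2 * q * q)
    residual_norm = float(np.sqrt(np.mean(resid ** 2)))
    if not degenerate and residual_norm > residual_tolerance:
        raise CalibrationError(
            f"calibration fit residual {residual_norm:.4f} min exceeds {residual_tolerance}")
    order = np.argsort(pressures)
    non_monotone = not degenerate and not np.all(np.diff(rts[order]) < 0)
    return RTLCalibration(points=pts, coefficients=(float(c0), float(c1), float(c2)),
                          lock_target=float(lock_target), residual_norm=residual_norm,
                          degenerate=degenerate, non_monotone=non_monotone)


def solve_lock_pressure(cal: RTLCalibration) -> float:
    """Relative pressure that brings the lock compound back to its target time.

    Solves rt(p) = lock_target on the calibrated pressure interval; a target
    outside the calibrated retention-time range raises
    :class:`~fapindex.errors.ExtrapolationError` (strong column-length changes
    must be avoided rather than extrapolated over).
    """
    lo, hi = cal.rt_range
    if cal.degenerate:
        raise CalibrationError("degenerate calibration (constant retention times)")
    if not (lo - 1e-12 <= cal.lock_target <= hi + 1e-12):
        raise ExtrapolationError(
            f"lock target {cal.lock_target} min outside calibrated range "
            f"[{lo:.3f}, {hi:.3f}] min; relock after smaller column changes")
    c0, c1, c2 = cal.coefficients
    pressures = [p for p, _ in cal.points]
    q_lo, q_hi = 1.0 / max(pressures), 1.0 / min(pressures)
    roots = np.roots([c2, c1, c0 - cal.lock_target]) if abs(c2) > 1e-12 else \
        np.array([(cal.lock_target - c0) / c1])
    real = [float(r.real) for r in np.atleast_1d(roots)
            if abs(getattr(r, "imag", 0.0)) < 1e-9]
    inside = [q for q in real if q_lo - 1e-9 <= q <= q_hi + 1e-9]
    if not inside:
        raise ExtrapolationError(
            f"no locking pressure inside the calibrated interval for target {cal.lock_target}")
    q = min(inside, key=lambda v: abs(v - 1.0))
    return 1.0 / q
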