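"""Retention-index engine and retention time locking."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fapindex as fx
from fapindex.chrom import ANCHOR_RRT, FAPAnchorSet
from fapindex.errors import (AnchorGapError, CalibrationError,
                             ExtrapolationError, OutOfLadderError)
from fapindex.ri import (fit_rtl_calibration, round_half_up,
                         solve_lock_pressure)


@pytest.fixture
def two_anchors():
    return FAPAnchorSet({23: 30.000, 24: 32.972})


def test_ri_at_every_anchor_is_100_times_carbon(ref_anchors):
    for carbon, rt in ref_anchors.anchors.items():
        assert float(fx.compute_ri_fap(rt, ref_anchors)) == 100.0 * carbon


def test_hand_evaluated_midpoint(two_anchors):
    ri = fx.compute_ri_fap(31.486, two_anchors)
    assert float(ri) == pytest.approx(2350.0, abs=1e-9)
    assert ri.bracketing_carbons == (23, 24)
    assert ri.rounded == 2350


def test_invert_is_algebraic_inverse(two_anchors):
    assert fx.invert_ri_fap(2350.0, two_anchors) == pytest.approx(31.486, abs=1e-9)
    assert fx.invert_ri_fap(2300.0, two_anchors) == 30.000


def test_out_of_ladder_hints_at_26_carbon(ref_anchors):
    with pytest.raises(OutOfLadderError) as exc:
        fx.compute_ri_fap(40.0, ref_anchors)
    assert "26:0" in str(exc.value)
    with pytest.raises(OutOfLadderError):
        fx.compute_ri_fap(5.0, ref_anchors)
    with pytest.raises(OutOfLadderError):
        fx.invert_ri_fap(2700.0, ref_anchors)


def test_gap_in_ladder_raises():
    anchors = FAPAnchorSet({21: 26.4, 22: 29.0, 24: 33.0})
    with pytest.raises(AnchorGapError):
        fx.compute_ri_fap(31.0, anchors)
    with pytest.raises(AnchorGapError):
        fx.invert_ri_fap(2350.0, anchors)


def test_rrt_basics(ref_anchors):
    assert fx.compute_rrt(21.0, 21.0) == 1.0
    with pytest.raises(ValueError):
        fx.compute_rrt(21.0, 0.0)
    # RRT strictly increases with elution order
    times = sorted(ref_anchors.anchors.values())
    rrts = [fx.compute_rrt(t, 21.0) for t in times]
    assert all(b > a for a, b in zip(rrts, rrts[1:]))


def test_rrt_ladder_reproduces_stigmasterol_index():
    """Indexing works on any monotone RT proxy, here the printed RRT ladder."""
    anchors = FAPAnchorSet({22: 1.38, 23: 1.47})
    ri = fx.compute_ri_fap(1.42, anchors)
    assert abs(float(ri) - 2247) <= 6.0  # 2-decimal RRT rounding bound


@st.composite
def ladder_and_t(draw):
    start = draw(st.floats(min_value=5.0, max_value=30.0))
    gaps = [draw(st.floats(min_value=0.5, max_value=4.0)) for _ in range(4)]
    times = np.cumsum([start] + gaps)
    anchors = {21 + i: float(t) for i, t in enumerate(times)}
    frac = draw(st.floats(min_value=0.0, max_value=1.0))
    t = float(times[0] + frac * (times[-1] - times[0]))
    return FAPAnchorSet(anchors), t


@given(ladder_and_t())
def test_roundtrip_and_monotonicity(data):
    anchors, t = data
    ri = fx.compute_ri_fap(t, anchors)
    assert abs(fx.invert_ri_fap(float(ri), anchors) - t) < 1e-9
    ri2 = fx.compute_ri_fap(float(ri), FAPAnchorSet(
        {c: 100.0 * c for c in anchors.carbons}))  # identity ladder sanity
    assert float(ri2) == pytest.approx(float(ri), abs=1e-9)
    t2 = min(t + 0.01, max(anchors.anchors.values()))
    if t2 > t:
        assert float(fx.compute_ri_fap(t2, anchors)) > float(ri)


@given(ladder_and_t(),
       st.floats(min_value=0.5, max_value=2.0),
       st.floats(min_value=-5.0, max_value=20.0))
def test_affine_invariance_of_index(data, scale, offset):
    """RI is invariant under any affine transform of the time axis."""
    anchors, t = data
    if offset + scale * min(anchors.anchors.values()) <= 0:
        offset = 1.0 - scale * min(anchors.anchors.values()) + 1e-6
    warped = FAPAnchorSet({c: scale * rt + offset for c, rt in anchors.anchors.items()})
    ri_a = fx.compute_ri_fap(t, anchors)
    ri_b = fx.compute_ri_fap(scale * t + offset, warped)
    assert float(ri_a) == pytest.approx(float(ri_b), abs=1e-6)


def test_round_half_up():
    assert round_half_up(2246.5) == 2247
    assert round_half_up(2246.49) == 2246


class TestRTL:
    def points(self, a=5.0, rt_nominal=33.5):
        b = rt_nominal - a
        return [(p, a + b / p) for p in (0.8, 0.9, 1.0, 1.1, 1.2)]

    def test_fit_holdup_physics_exactly(self):
        cal = fit_rtl_calibration(self.points(), lock_target=32.972)
        assert cal.residual_norm < 0.01
        assert cal.lock_target == 32.972

    def test_solve_identity_at_nominal_pressure(self):
        pts = self.points()
        rt_at_nominal = dict(pts)[1.0]
        cal = fit_rtl_calibration(pts, lock_target=rt_at_nominal)
        assert solve_lock_pressure(cal) == pytest.approx(1.0, abs=1e-9)

    def test_solved_pressure_restores_drifted_lock_time(self):
        target = 32.972
        drifted = [(p, 5.0 + (target + 0.4 - 5.0) / p) for p in (0.8, 0.9, 1.0, 1.1, 1.2)]
        cal = fit_rtl_calibration(drifted, lock_target=target)
        p_star = solve_lock_pressure(cal)
        rt = 5.0 + (target + 0.4 - 5.0) / p_star
        assert abs(rt - target) <= 0.005

    def test_degenerate_fit_flagged(self):
        pts = [(p, 33.5) for p in (0.8, 0.9, 1.0, 1.1, 1.2)]
        cal = fit_rtl_calibration(pts, lock_target=33.5)
        assert cal.degenerate
        with pytest.raises(CalibrationError):
            solve_lock_pressure(cal)

    def test_target_outside_envelope_is_extrapolation_error(self):
        cal = fit_rtl_calibration(self.points(), lock_target=50.0)
        with pytest.raises(ExtrapolationError):
            solve_lock_pressure(cal)

    def test_wrong_point_count_and_duplicates(self):
        with pytest.raises(CalibrationError):
            fit_rtl_calibration(self.points()[:4])
        pts = self.points()
        pts[1] = pts[0]
        with pytest.raises(CalibrationError):
            fit_rtl_calibration(pts)

    def test_off_grid_pressures_rejected(self):
        pts = [(p, 5 + 28.5 / p) for p in (0.5, 0.9, 1.0, 1.1, 1.2)]
        with pytest.raises(CalibrationError):
            fit_rtl_calibration(pts)


def test_reference_ladder_locks_24_carbon():
    anchors = fx.reference_anchor_times()
    assert anchors[24] == pytest.approx(32.972)
    # ladder mirrors the published RRT ratios
    assert anchors[22] / anchors[24] == pytest.approx(ANCHOR_RRT[22] / ANCHOR_RRT[24])
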