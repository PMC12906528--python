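"""Binocular summation, curve shifting and depth-of-focus extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import monovis as mv
from monovis.monovision import NodeFlag, REPORT_FIELDS


def make_curve(grid, values):
    return mv.DefocusCurve(grid, values, "monocular")


GRID = np.round(np.arange(-2.5, 0.5001, 0.05), 10)


# -------------------------------------------------------- regression


def test_regression_intercept_and_worked_example():
    model = mv.BinocularEffectModel()
    assert mv.binocular_effect(0.0, 0.0, 0.0, model) == 1.17
    assert mv.binocular_effect(0.2, 0.1, 1.0, model) == pytest.approx(1.041)


def test_regression_decreases_with_interocular_difference():
    b = [mv.binocular_effect(d, 0.1, 0.5) for d in (0.0, 0.1, 0.2, 0.4)]
    assert np.all(np.diff(b) < 0)


def test_offset_magnitude_convention():
    mag = mv.BinocularEffectModel()
    signed = mv.BinocularEffectModel(offset_as_magnitude=False)
    assert mv.binocular_effect(0, 0, -1.0, mag) == pytest.approx(1.10)
    assert mv.binocular_effect(0, 0, -1.0, signed) == pytest.approx(1.24)


# ---------------------------------------------------------- shifting


def test_shift_identity_and_composition():
    curve = make_curve(GRID, 0.1 + 0.2 * np.abs(GRID))
    assert np.array_equal(mv.shift_defocus_curve(curve, 0.0).logmar, curve.logmar)
    once = mv.shift_defocus_curve(mv.shift_defocus_curve(curve, 0.5), 0.5)
    twice = mv.shift_defocus_curve(curve, 1.0)
    both = np.isfinite(once.logmar) & np.isfinite(twice.logmar)
    assert both.any()
    np.testing.assert_allclose(once.logmar[both], twice.logmar[both], atol=1e-12)


def test_shift_moves_peak_to_minus_offset():
    curve = make_curve(GRID, 0.1 + 0.3 * np.abs(GRID))  # peak (minimum) at 0
    shifted = mv.shift_defocus_curve(curve, 1.0)
    i = np.nanargmin(shifted.logmar)
    assert shifted.defocus_D[i] == pytest.approx(-1.0)
    # nodes whose support moved off-grid are missing, not extrapolated
    assert np.all(np.isnan(shifted.logmar[shifted.defocus_D > -0.5 + 0.01]))
    assert not np.any(np.isnan(shifted.logmar[shifted.defocus_D < -0.5 - 0.01]))


def test_shift_beyond_span_raises():
    curve = make_curve(GRID, np.full(len(GRID), 0.1))
    with pytest.raises(ValueError, match="span"):
        mv.shift_defocus_curve(curve, 5.0)


# ------------------------------------------------------- combination


def test_flat_identical_eyes_worked_example(flat_curve):
    bc = mv.combine_binocular(mv.make_scenario(flat_curve, 0.0))
    assert np.allclose(bc.be_factor, 1.17 - 0.11 * 0.1)
    expected = 0.1 - math.log10(1.17 - 0.11 * 0.1)
    assert np.allclose(bc.logmar, expected)
    assert expected == pytest.approx(0.036, abs=5e-4)


def test_swapping_eyes_leaves_output_unchanged():
    rng = np.random.default_rng(7)
    a = make_curve(GRID, rng.uniform(0.0, 0.5, len(GRID)))
    b = make_curve(GRID, rng.uniform(0.0, 0.5, len(GRID)))
    s1 = mv.MonovisionScenario(0.5, a, b)
    s2 = mv.MonovisionScenario(0.5, b, a)
    np.testing.assert_array_equal(
        mv.combine_binocular(s1).logmar, mv.combine_binocular(s2).logmar
    )


def test_single_eye_fallback_flagged():
    vals = np.full(len(GRID), 0.2)
    vals[3] = np.nan
    s = mv.MonovisionScenario(
        0.0, make_curve(GRID, vals), make_curve(GRID, np.full(len(GRID), 0.3))
    )
    bc = mv.combine_binocular(s)
    assert bc.flags[3] == NodeFlag.SINGLE_EYE
    assert bc.logmar[3] == 0.3 and bc.be_factor[3] == 1.0
    assert bc.flags[4] == NodeFlag.OK


def test_binocular_superiority_by_log_be():
    """Wherever BE > 1 the binocular curve beats the better eye by
    exactly log10(BE)."""
    rng = np.random.default_rng(11)
    a = make_curve(GRID, rng.uniform(0.0, 0.4, len(GRID)))
    bc = mv.combine_binocular(mv.make_scenario(a, 0.5))
    ok = bc.flags == NodeFlag.OK
    better = np.minimum(
        a.logmar[ok], mv.shift_defocus_curve(a, 0.5).logmar[ok]
    )
    gain = better - bc.logmar[ok]
    np.testing.assert_allclose(gain, np.log10(bc.be_factor[ok]), atol=1e-12)


@settings(max_examples=40, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    offset=st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
)
def test_vectorised_combination_matches_scalar_oracle(seed, offset):
    """Node-by-node scalar recomputation (pure Python floats) must agree
    exactly with the vectorised pipeline."""
    rng = np.random.default_rng(seed)
    left = rng.uniform(-0.1, 0.8, len(GRID))
    right = rng.uniform(-0.1, 0.8, len(GRID))
    left[rng.random(len(GRID)) < 0.1] = np.nan
    right[rng.random(len(GRID)) < 0.1] = np.nan
    s = mv.MonovisionScenario(
        offset, make_curve(GRID, left), make_curve(GRID, right)
    )
    bc = mv.combine_binocular(s)
    for i in range(len(GRID)):
        l, r = float(left[i]), float(right[i])
        if math.isnan(l) and math.isnan(r):
            assert math.isnan(bc.logmar[i]) and bc.flags[i] == NodeFlag.MISSING
        elif math.isnan(l) or math.isnan(r):
            assert bc.logmar[i] == (r if math.isnan(l) else l)
            assert bc.be_factor[i] == 1.0
        else:
            delta = abs(l - r)
            avg = (l + r) / 2.0
            be = 1.17 + -0.24 * delta + -0.11 * avg + -0.07 * abs(offset)
            assert bc.be_factor[i] == be
            assert bc.delta_va[i] == delta and bc.avg_va[i] == avg
            # scalar log10 via the same libm kernel as the array path
            assert bc.logmar[i] == min(l, r) - float(np.log10(be))


# --------------------------------------------------- depth of focus


def test_dof_flat_curve_covers_whole_grid(flat_curve):
    fr = mv.depth_of_focus(
        mv.DefocusCurve(GRID, np.full(len(GRID), 0.05), "monocular"), 0.1
    )
    assert fr.width_D == pytest.approx(3.0)


def test_dof_v_curve_width_by_interpolated_crossings():
    grid = np.round(np.arange(-2.5, 2.5001, 0.05), 10)
    curve = mv.DefocusCurve(grid, 0.3 * np.abs(grid), "monocular")
    fr = mv.depth_of_focus(curve, 0.2)
    assert fr.width_D == pytest.approx(4.0 / 3.0, abs=1e-9)
    a, b = fr.intervals[0]
    assert a == pytest.approx(-2.0 / 3.0) and b == pytest.approx(2.0 / 3.0)


def test_dof_nesting_of_cutoffs():
    rng = np.random.default_rng(3)
    curve = mv.DefocusCurve(
        GRID, np.abs(np.cumsum(rng.normal(0, 0.05, len(GRID)))), "monocular"
    )
    w1 = mv.depth_of_focus(curve, 0.1)
    w2 = mv.depth_of_focus(curve, 0.2)
    assert w2.width_D >= w1.width_D
    # every 0.1-interval is inside some 0.2-interval
    for a, b in w1.intervals:
        assert any(c <= a + 1e-12 and b - 1e-12 <= d for c, d in w2.intervals)


def test_dof_empty_when_curve_above_cutoff(flat_curve):
    fr = mv.depth_of_focus(flat_curve, 0.05)
    assert fr.width_D == 0.0 and fr.intervals == ()


# ---------------------------------------------------------- reports


def test_self_comparison_report_is_null(flat_curve):
    bc = mv.combine_binocular(mv.make_scenario(flat_curve, 0.0))
    rep = mv.scenario_report(bc, bc)
    assert tuple(rep) == REPORT_FIELDS
    assert rep["improvement_at_minus_2D"] == 0.0
    assert rep["far_distance_penalty"] == 0.0


def test_far_penalty_monotone_in_offset_on_presets(mono_curves_20d):
    for curve in mono_curves_20d.values():
        plano = mv.combine_binocular(mv.make_scenario(curve, 0.0))
        pens = [
            mv.scenario_report(
                plano, mv.combine_binocular(mv.make_scenario(curve, off))
            )["far_distance_penalty"]
            for off in (0.25, 0.5, 0.75, 1.0)
        ]
        assert np.all(np.diff(pens) >= -1e-12)
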