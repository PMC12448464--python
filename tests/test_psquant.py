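"""Rotation, cubic fitting, and the four separation measurements."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgsep.psquant import (
    PSMeasurements,
    SQRT2,
    ValidationBounds,
    fit_cubic,
    ps_measurements,
    quantify_curve,
    rotate_points,
    validate_network_ps,
)


class TestRotation:
    def test_equality_line_maps_to_axis(self):
        out = rotate_points([(1.0, 1.0)])
        assert out[0, 0] == pytest.approx(SQRT2)
        assert out[0, 1] == pytest.approx(0.0)

    def test_separation_point_below_zero(self):
        out = rotate_points([(1.0, 0.0)])
        assert out[0, 0] == pytest.approx(1 / SQRT2)
        assert out[0, 1] == pytest.approx(-1 / SQRT2)
        assert out[0, 1] < 0

    def test_completion_point_above_zero(self):
        out = rotate_points([(0.0, 1.0)])
        assert out[0, 1] == pytest.approx(+1 / SQRT2)

    def test_rotation_preserves_distances(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-1, 1, size=(10, 2))
        rot = rotate_points(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(rot[:, None] - rot[None], axis=-1)
        assert np.allclose(d0, d1)


class TestCubicFit:
    def test_exact_cubic_recovered(self):
        coeffs = np.array([0.5, -1.2, 0.3, 0.7])
        x = np.linspace(-1, 1, 11)
        got = fit_cubic(x, np.polyval(coeffs, x))
        assert np.allclose(got, coeffs, atol=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 2, 25)
        y = np.polyval([0.2, -0.5, 0.1, 0.4], x) + rng.normal(0, 0.05, 25)
        got = fit_cubic(x, y)
        V = np.vander(x, 4)
        oracle = np.linalg.lstsq(V, y, rcond=None)[0]
        assert np.allclose(got, oracle, atol=1e-8)

    def test_constant_data_gives_constant_fit(self):
        x = np.linspace(0, 1, 8)
        got = fit_cubic(x, np.full(8, 0.3))
        assert np.allclose(got[:3], 0.0, atol=1e-9)
        assert got[3] == pytest.approx(0.3)

    def test_degenerate_x_falls_back(self):
        x = np.array([0.0, 0.0, 1.0, 1.0, 2.0])
        y = np.array([0.0, 0.2, 1.0, 1.2, 2.1])
        got = fit_cubic(x, y)          # only 3 unique x -> quadratic
        assert got[0] == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_cubic(np.arange(3), np.arange(3))


class TestMeasurements:
    def test_linear_crossing_case(self):
        # p(x) = x - 0.5 on [0, 1]: negative then positive
        m = ps_measurements([0.0, 0.0, 1.0, -0.5], (0.0, 1.0))
        assert m.A_PS == pytest.approx(0.125)
        assert m.A_PC == pytest.approx(0.125)
        assert m.PS_max == pytest.approx(0.5)
        # the sign change is separation -> completion, so the transition
        # point is the start of the range (p < 0 there already)
        assert m.T_PCPS == pytest.approx(0.0)

    def test_constant_negative_case(self):
        c, L = 0.4, 2.0
        m = ps_measurements([0.0, 0.0, 0.0, -c], (0.0, L))
        assert m.A_PS == pytest.approx(c * L)
        assert m.A_PC == pytest.approx(0.0)
        assert m.PS_max == pytest.approx(c)
        assert m.T_PCPS == pytest.approx(0.0)

    def test_never_negative_transition_at_range_end(self):
        m = ps_measurements([0.0, 0.0, 0.0, 0.3], (0.0, 1.0))
        assert m.A_PS == 0.0
        assert m.T_PCPS == pytest.approx(1.0)

    def test_positive_to_negative_crossing_detected(self):
        # p(x) = 0.5 - x on [0, 1]: completion then separation at x = 0.5
        m = ps_measurements([0.0, 0.0, -1.0, 0.5], (0.0, 1.0))
        assert m.T_PCPS == pytest.approx(0.5)
        assert m.A_PS == pytest.approx(0.125)
        assert m.A_PC == pytest.approx(0.125)

    def test_random_cubics_match_quadrature_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            coeffs = rng.normal(0, 1, 4)
            lo, hi = sorted(rng.uniform(-2, 2, 2))
            if hi - lo < 0.1:
                continue
            m = ps_measurements(coeffs, (lo, hi))
            x = np.linspace(lo, hi, 200_001)
            p = np.polyval(coeffs, x)
            a_ps = np.trapezoid(np.maximum(-p, 0), x)
            a_pc = np.trapezoid(np.maximum(p, 0), x)
            assert m.A_PS == pytest.approx(a_ps, rel=1e-3, abs=1e-6)
            assert m.A_PC == pytest.approx(a_pc, rel=1e-3, abs=1e-6)
            assert m.PS_max == pytest.approx(max(np.max(-p), 0.0), rel=1e-4, abs=1e-9)

    def test_rectification_consistency(self):
        rng = np.random.default_rng(5)
        coeffs = rng.normal(0, 1, 4)
        m = ps_measurements(coeffs, (-1.0, 1.5))
        anti = np.polyint(coeffs)
        signed = np.polyval(anti, 1.5) - np.polyval(anti, -1.0)
        assert m.A_PC - m.A_PS == pytest.approx(signed, abs=1e-9)

    def test_identity_network_has_zero_measurements(self):
        s_in = np.linspace(0, 1, 11)
        m = quantify_curve(s_in, s_in)
        assert m.A_PS == pytest.approx(0.0, abs=1e-9)
        assert m.A_PC == pytest.approx(0.0, abs=1e-9)
        assert m.PS_max == pytest.approx(0.0, abs=1e-9)


_finite = st.floats(min_value=-5.0, max_value=5.0, allow_nan=False)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.tuples(_finite, _finite), min_size=2, max_size=8))
def test_rotation_is_an_isometry(points):
    pts = np.asarray(points)
    rot = rotate_points(pts)
    d0 = np.linalg.norm(pts[0] - pts[-1])
    d1 = np.linalg.norm(rot[0] - rot[-1])
    assert d1 == pytest.approx(d0, rel=1e-9, abs=1e-9)


@settings(derandomize=True, max_examples=50)
@given(st.tuples(_finite, _finite, _finite, _finite),
       st.tuples(st.floats(-2, 0.5), st.floats(0.6, 3)))
def test_measurements_respect_their_invariants(coeffs, x_range):
    m = ps_measurements(list(coeffs), x_range)
    assert m.A_PS >= 0 and m.A_PC >= 0 and m.PS_max >= 0
    assert x_range[0] <= m.T_PCPS <= x_range[1]
    # rectification consistency: A_PC - A_PS equals the signed integral
    anti = np.polyint(np.asarray(coeffs))
    signed = np.polyval(anti, x_range[1]) - np.polyval(anti, x_range[0])
    assert m.A_PC - m.A_PS == pytest.approx(signed, rel=1e-6, abs=1e-8)


class TestValidator:
    def _good(self, metric):
        return PSMeasurements(A_PS=0.3, A_PC=0.005, T_PCPS=0.1, PS_max=0.4,
                              metric_id=metric)

    def test_both_metrics_within_bounds_valid(self):
        valid, per = validate_network_ps(self._good("r"), self._good("R"))
        assert valid and len(per) == 8 and all(per.values())

    def test_completion_area_bound_enforced(self):
        bad = self._good("r")
        bad.A_PC = 0.03
        valid, per = validate_network_ps(bad, self._good("R"))
        assert not valid and not per["r:A_PC"]

    def test_undefined_metric_invalidates(self):
        valid, per = validate_network_ps(None, self._good("R"))
        assert not valid
        assert not any(per[f"r:{k}"] for k in ("A_PS", "A_PC", "T_PCPS", "PS_max"))

    def test_single_bound_toggling_conjunction(self):
        bounds = ValidationBounds()
        violations = {"A_PS": 0.1, "A_PC": 0.05, "T_PCPS": 0.3, "PS_max": 0.1}
        for field, bad_value in violations.items():
            m = self._good("r")
            setattr(m, field, bad_value)
            valid, per = validate_network_ps(m, self._good("R"), bounds)
            assert not valid
            assert sum(not v for v in per.values()) == 1
            assert not per[f"r:{field}"]
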