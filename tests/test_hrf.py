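"""Two-gamma HRF model: evaluation, derivatives, characterization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gamma as gamma_fn
from scipy.optimize import bisect

from hrfpipe import (HRFParams, HRFCurve, MOUSE, HUMAN, evaluate_hrf,
                     hrf_basis_derivatives, characterize_hrf,
                     normalize_to_max, default_grid)
from hrfpipe.hrf import DegenerateCurveError, ParameterDomainError


def hrf_oracle(t, A, b, p1, p2, V):
    """Term-by-term arithmetic evaluation of the two-gamma closed form."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    m = t > 0
    tm = t[m]
    out[m] = A * np.exp(-b * tm) * (
        b ** p1 / gamma_fn(p1) * tm ** (p1 - 1)
        - b ** p2 / (V * gamma_fn(p2)) * tm ** (p2 - 1))
    return out


def analytic_ddt(t, params):
    """d/dt of the closed form, per gamma term."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    m = t > 0
    tm = t[m]
    for p, scale in ((params.p1, 1.0), (params.p2, -1.0 / params.V)):
        c = params.A * scale * params.b ** p / gamma_fn(p)
        out[m] += c * np.exp(-params.b * tm) * tm ** (p - 2) * (
            (p - 1) - params.b * tm)
    return out


class TestEvaluate:
    def test_zero_at_origin(self):
        curve = evaluate_hrf(MOUSE, default_grid())
        assert curve.values[0] == 0.0

    @pytest.mark.parametrize("params", [MOUSE, HUMAN,
                                        HRFParams(A=2.5, b=0.5, p1=3.0,
                                                  p2=9.0, V=1.2)])
    def test_matches_arithmetic_oracle(self, params):
        t = default_grid(30.0, 0.05)
        got = evaluate_hrf(params, t).values
        want = hrf_oracle(t, params.A, params.b, params.p1, params.p2, params.V)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-300)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(b=st.floats(0.2, 3.0), p1=st.floats(1.5, 8.0),
           dp=st.floats(0.6, 12.0), V=st.floats(0.3, 10.0),
           A=st.floats(0.1, 5.0))
    def test_oracle_equivalence_random_params(self, b, p1, dp, V, A):
        params = HRFParams(A=A, b=b, p1=p1, p2=p1 + dp, V=V)
        t = default_grid(30.0, 0.25)
        got = evaluate_hrf(params, t).values
        want = hrf_oracle(t, A, b, p1, p1 + dp, V)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-300)

    def test_single_sign_change_located_by_bisection(self):
        """The curve crosses + -> - exactly once, at the root of the
        bracketed term (found independently by bisection)."""
        params = MOUSE
        t = default_grid(30.0, 0.01)
        y = evaluate_hrf(params, t).values
        signs = np.sign(y[1:])
        changes = np.flatnonzero(np.diff(signs) != 0)
        assert len(changes) == 1

        def bracket(tv):
            return (params.b ** params.p1 / gamma_fn(params.p1)
                    * tv ** (params.p1 - 1)
                    - params.b ** params.p2 / (params.V * gamma_fn(params.p2))
                    * tv ** (params.p2 - 1))

        root = bisect(bracket, 1.0, 29.0)
        t_change = t[1:][changes[0]]
        assert abs(t_change - root) <= 0.011

    def test_human_argmax_matches_dense_grid_oracle(self):
        t = np.arange(0, 32.0001, 0.001)
        y = hrf_oracle(t, 1.0, HUMAN.b, HUMAN.p1, HUMAN.p2, HUMAN.V)
        t_oracle = t[np.argmax(y)]
        curve = evaluate_hrf(HUMAN, t)
        assert abs(curve.time[np.argmax(curve.values)] - t_oracle) < 1e-9
        assert abs(t_oracle - 5.0) < 0.1

    @pytest.mark.parametrize("kwargs", [
        dict(b=-1.0), dict(p1=0.5), dict(p1=6.0, p2=5.0), dict(V=0.0),
        dict(A=0.0)])
    def test_invalid_params_rejected(self, kwargs):
        base = dict(A=1.0, b=1.0, p1=6.0, p2=16.0, V=6.0)
        base.update(kwargs)
        with pytest.raises(ParameterDomainError):
            HRFParams(**base)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            evaluate_hrf(MOUSE, np.array([]))


class TestDerivatives:
    def test_tail_decays_to_zero(self):
        grid = default_grid(60.0, 0.05)
        td, dd = hrf_basis_derivatives(MOUSE, grid)
        tail = grid > 50
        assert np.all(np.abs(td.values[tail]) < 1e-6)
        assert np.all(np.abs(dd.values[tail]) < 1e-6)

    def test_temporal_matches_analytic_derivative(self):
        grid = default_grid(30.0, 0.05)
        td, _ = hrf_basis_derivatives(MOUSE, grid, time_step=0.1)
        want = analytic_ddt(grid, MOUSE)
        interior = grid > 1.0   # finite difference is poor near the origin
        assert np.allclose(td.values[interior], want[interior], atol=5e-3)

    def test_finite_difference_converges_to_analytic(self):
        grid = default_grid(30.0, 0.05)
        want = analytic_ddt(grid, MOUSE)
        interior = grid > 1.0
        errs = []
        for step in (0.4, 0.2, 0.1, 0.05):
            td, _ = hrf_basis_derivatives(MOUSE, grid, time_step=step)
            errs.append(np.max(np.abs(td.values[interior] - want[interior])))
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))


class TestCharacterize:
    def test_human_fwhm_printed_value(self):
        """The standard human canonical HRF has FWHM 5.3 s (1 decimal)."""
        curve = evaluate_hrf(HUMAN, np.arange(0, 32.0001, 0.01))
        assert round(characterize_hrf(curve).fwhm, 1) == 5.3

    def test_amplitude_scale_invariance(self):
        curve = evaluate_hrf(HUMAN, default_grid(32.0, 0.01))
        s1 = characterize_hrf(curve)
        s2 = characterize_hrf(HRFCurve(curve.time, curve.values * 10))
        assert s1.time_to_peak == s2.time_to_peak
        assert np.isclose(s1.fwhm, s2.fwhm)
        assert s1.time_to_undershoot == s2.time_to_undershoot

    def test_fwhm_matches_brute_force_scan(self):
        """Near-single-gamma curve: FWHM equals a half-max grid scan."""
        params = HRFParams(A=1.0, b=1.0, p1=6.0, p2=16.0, V=1e6)
        t = np.arange(0, 32.0001, 0.001)
        y = hrf_oracle(t, 1.0, 1.0, 6.0, 16.0, 1e6)
        above = t[y >= y.max() / 2]
        scan_fwhm = above[-1] - above[0]
        got = characterize_hrf(evaluate_hrf(params, t)).fwhm
        assert abs(got - scan_fwhm) < 0.002

    def test_ordering_invariants(self):
        s = characterize_hrf(evaluate_hrf(MOUSE, default_grid(30.0, 0.01)))
        assert s.time_to_peak < s.time_to_undershoot
        assert s.fwhm > 0
        assert s.undershoot_value <= 0

    def test_no_positive_peak_rejected(self):
        curve = HRFCurve(np.arange(5.0), -np.ones(5))
        with pytest.raises(DegenerateCurveError):
            characterize_hrf(curve)


class TestNormalize:
    def test_scales_to_unit_max(self):
        curve = HRFCurve(np.arange(4.0), np.array([0.0, 0.5, 0.25, 0.1]))
        out = normalize_to_max(curve)
        assert out.values.max() == 1.0
        assert np.allclose(out.values, curve.values * 2)

    def test_idempotent_and_argmax_preserving(self):
        curve = evaluate_hrf(MOUSE, default_grid())
        once = normalize_to_max(curve)
        twice = normalize_to_max(once)
        assert np.allclose(once.values, twice.values)
        assert np.argmax(once.values) == np.argmax(curve.values)

    def test_nonpositive_max_rejected(self):
        with pytest.raises(DegenerateCurveError):
            normalize_to_max(HRFCurve(np.arange(3.0), np.array([-1.0, -2, -3])))


def test_params_round_trip(tmp_path):
    from hrfpipe import save_params, load_params
    path = tmp_path / "mouse.json"
    save_params(MOUSE, path, species="mouse")
    assert load_params(path) == MOUSE
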