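"""Closed-form response functions against analytics and the RK4 oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydromark import (
    LtiParams,
    RectShape,
    TrapezoidShape,
    ode_oracle,
    peak,
    rect_response,
    step_response,
    trapezoid_response,
)
from hydromark.lti import (
    _rk4_fast,
    _rk4_loop,
    input_breakpoints,
    rect_input,
    trapezoid_input,
)


def draw_params(rng, kind):
    p = LtiParams(
        gain=rng.uniform(10, 500),
        tau=rng.uniform(100, 1e4),
        delay=rng.uniform(0, 1200),
        baseline=rng.uniform(500, 1500),
    )
    if kind == "rect":
        return p, RectShape(rng.uniform(60, 3600))
    return p, TrapezoidShape(
        rng.uniform(60, 3600), rng.uniform(60, 3600), rng.uniform(60, 3600)
    )


class TestInvariantChecks:
    def test_positive_tau_required(self):
        with pytest.raises(ValueError):
            LtiParams(gain=100, tau=0.0, delay=0, baseline=700)
        with pytest.raises(ValueError):
            LtiParams(gain=100, tau=100, delay=-1, baseline=700)

    def test_shape_duration_checks(self):
        with pytest.raises(ValueError):
            RectShape(0.0)
        with pytest.raises(ValueError):
            TrapezoidShape(0.0, 10.0, 10.0)
        TrapezoidShape(10.0, 0.0, 10.0)  # zero flat top allowed


class TestStepResponse:
    def test_starts_at_baseline(self):
        p = LtiParams(gain=100, tau=500, delay=300, baseline=700)
        assert step_response(p.delay, p) == pytest.approx(700.0)
        assert np.all(step_response(np.array([-50.0, 0.0, 299.9]), p) == 700.0)

    def test_one_time_constant_point(self):
        p = LtiParams(gain=100, tau=500, delay=300, baseline=700)
        assert step_response(p.delay + p.tau, p) == pytest.approx(
            700 + 100 * (1 - np.exp(-1)), abs=1e-9
        )
        assert step_response(p.delay + p.tau, p) == pytest.approx(763.212, abs=1e-3)

    def test_steady_state_equals_plateau(self):
        p = LtiParams(gain=100, tau=500, delay=300, baseline=700)
        assert abs(step_response(p.delay + 20 * p.tau, p) - 800.0) < 1e-6 * p.gain


class TestRectResponse:
    def test_zero_gain_flat(self):
        p = LtiParams(gain=0.0, tau=500, delay=300, baseline=740)
        t = np.linspace(-600, 7200, 64)
        assert np.all(rect_response(t, p, RectShape(900)) == 740.0)

    def test_published_liver_operating_point(self, liver_params):
        # end-of-pulse value from direct evaluation of the two-exponential form
        p, shape = liver_params
        assert rect_response(2061.0, p, shape) == pytest.approx(798.0, abs=0.1)

    def test_causality(self, liver_params):
        p, shape = liver_params
        t = np.linspace(-600, p.delay - 1e-9, 50)
        assert np.all(rect_response(t, p, shape) == p.baseline)

    def test_monotone_rise_then_fall(self, liver_params):
        p, shape = liver_params
        rise = rect_response(np.linspace(p.delay + 1, p.delay + shape.delta, 200), p, shape)
        fall = rect_response(
            np.linspace(p.delay + shape.delta, p.delay + shape.delta + 8 * p.tau, 200),
            p, shape,
        )
        assert np.all(np.diff(rise) > 0)
        assert np.all(np.diff(fall) < 0)

    def test_long_pulse_tends_to_step(self, liver_params):
        p, _ = liver_params
        t = np.linspace(-300, p.delay + 5 * p.tau, 300)
        wide = rect_response(t, p, RectShape(1e7))
        assert np.max(np.abs(wide - step_response(t, p))) < 1e-6 * p.gain


class TestTrapezoidResponse:
    def test_causality(self, spleen_params):
        p, shape = spleen_params
        t = np.linspace(-600, p.delay - 1e-9, 50)
        assert np.all(trapezoid_response(t, p, shape) == p.baseline)

    def test_degenerates_to_rectangle(self, liver_params):
        p, rect = liver_params
        trap = TrapezoidShape(1e-6, rect.delta, 1e-6)
        t = np.linspace(-300, 12000, 2000)
        dev = trapezoid_response(t, p, trap) - rect_response(t, p, rect)
        assert np.max(np.abs(dev)) < 1e-6 * p.gain

    def test_matches_ode_oracle_at_spleen_point(self, spleen_params):
        p, shape = spleen_params
        t = np.linspace(0.0, 7200.0, 400)
        y_num = ode_oracle(
            lambda tt: trapezoid_input(tt, p, shape), p, t,
            breakpoints=input_breakpoints(p, shape),
        )
        assert np.max(np.abs(trapezoid_response(t, p, shape) - y_num)) < 1e-4


class TestOdeOracle:
    def test_zero_input_constant(self):
        p = LtiParams(gain=100, tau=500, delay=0, baseline=740)
        t = np.linspace(0, 3600, 50)
        assert np.allclose(ode_oracle(lambda tt: np.zeros_like(tt), p, t), 740.0)

    def test_step_input_matches_closed_form(self):
        p = LtiParams(gain=120, tau=800, delay=400, baseline=700)
        t = np.linspace(0, 8000, 300)
        u = lambda tt: p.gain * (np.asarray(tt) >= p.delay)
        y = ode_oracle(u, p, t, breakpoints=[p.delay])
        assert np.max(np.abs(y - step_response(t, p))) < 1e-6 * p.gain

    def test_rect_input_at_published_liver_point(self):
        p = LtiParams(gain=150.0, tau=3007.0, delay=821.0, baseline=740.0)
        shape = RectShape(1534.0)
        t = np.linspace(0, 9000, 300)
        y = ode_oracle(
            lambda tt: rect_input(tt, p, shape), p, t,
            breakpoints=input_breakpoints(p, shape),
        )
        assert np.max(np.abs(y - rect_response(t, p, shape))) < 1e-4

    def test_unsorted_grid_rejected(self):
        p = LtiParams(gain=1, tau=100, delay=0, baseline=700)
        with pytest.raises(ValueError):
            ode_oracle(lambda tt: np.zeros_like(tt), p, np.array([0.0, 10.0, 5.0]))

    def test_fast_path_is_rk4(self):
        # the lfilter recurrence must reproduce the naive per-step RK4 loop
        rng = np.random.default_rng(3)
        u = rng.uniform(0, 100, 2 * 500 + 1)
        g_loop = _rk4_loop(u, 0.1, 700.0)
        g_fast = _rk4_fast(u, 0.1, 700.0)
        assert np.max(np.abs(g_loop - g_fast)) < 1e-10


class TestPeak:
    def test_rect_peak_is_end_of_pulse(self, liver_params):
        p, shape = liver_params
        t_pk, y_pk, degen = peak(p, shape)
        assert not degen
        assert t_pk == pytest.approx(p.delay + shape.delta)
        # closed-form fraction of plateau reached: 1 - exp(-1303/2614)
        assert (y_pk - p.baseline) / p.gain == pytest.approx(0.392540503, abs=1e-6)

    def test_zero_gain_degenerate(self, liver_params):
        _, shape = liver_params
        p = LtiParams(gain=0.0, tau=2614, delay=758, baseline=740)
        t_pk, y_pk, degen = peak(p, shape)
        assert degen and t_pk == 758 and y_pk == 740

    def test_long_flat_top_reaches_plateau(self):
        p = LtiParams(gain=80.0, tau=300.0, delay=100.0, baseline=1300.0)
        shape = TrapezoidShape(200.0, 50 * p.tau, 200.0)
        _, y_pk, _ = peak(p, shape)
        assert y_pk == pytest.approx(p.baseline + p.gain, abs=1e-6 * p.gain)

    def test_peak_matches_dense_grid(self, spleen_params):
        p, shape = spleen_params
        t_pk, y_pk, _ = peak(p, shape)
        grid = np.linspace(p.delay, p.delay + shape.total_duration + 10 * p.tau, 200001)
        assert y_pk >= np.max(trapezoid_response(grid, p, shape)) - 1e-9


class TestProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.sampled_from(["rect", "trapezoid"]))
    def test_causal_bounded_and_returns_to_baseline(self, seed, kind):
        rng = np.random.default_rng(seed)
        p, shape = draw_params(rng, kind)
        f = rect_response if kind == "rect" else trapezoid_response
        t = np.linspace(-600, p.delay + shape.total_duration + 25 * p.tau, 800)
        y = f(t, p, shape)
        assert np.all(y[t < p.delay] == p.baseline)
        assert np.all(y >= p.baseline - 1e-9 * p.gain)
        assert np.all(y <= p.baseline + p.gain * (1 + 1e-9))
        t_end = p.delay + shape.total_duration + 20 * p.tau
        assert abs(float(f(t_end, p, shape)) - p.baseline) < 1e-6 * p.gain

    def test_oracle_equivalence_random_draws(self):
        # closed forms vs RK4 across 100 random parameter draws
        rng = np.random.default_rng(12345)
        worst = 0.0
        for i in range(100):
            kind = "rect" if i % 2 == 0 else "trapezoid"
            p, shape = draw_params(rng, kind)
            f = rect_response if kind == "rect" else trapezoid_response
            inp = rect_input if kind == "rect" else trapezoid_input
            t = np.linspace(0, p.delay + shape.total_duration + 2 * p.tau, 120)
            y_num = ode_oracle(
                lambda tt: inp(tt, p, shape), p, t, dt=0.05,
                breakpoints=input_breakpoints(p, shape),
            )
            worst = max(worst, float(np.max(np.abs(f(t, p, shape) - y_num))))
        assert worst < 1e-4


class TestSerialization:
    def test_params_json_round_trip(self):
        p = LtiParams(gain=147.8, tau=2614, delay=758, baseline=740)
        assert LtiParams.from_json(p.to_json()) == p
        s = TrapezoidShape(267, 992, 129)
        assert TrapezoidShape.from_json(s.to_json()) == s
        r = RectShape(1303)
        assert RectShape.from_json(r.to_json()) == r
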