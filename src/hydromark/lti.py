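"""Closed-form responses of a first-order LTI system to simple hydration inputs.

The organ T1 response to ingested fluid is modelled as a first-order linear
time-invariant system, ``tau * dy/dt + y = u``, driven by an idealised input:
a delayed step, a rectangle (liver: prolonged portal bolus) or a trapezoid
(spleen: gradual systemic arrival).  The state is the deviation of the marker
from its pre-ingestion baseline ``y0``; all responses are causal and return
``y0`` before the onset delay.

Times are in seconds from the start of drink ingestion (negative times are
pre-ingestion).  Gains and baselines carry the marker's unit, milliseconds
for T1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "LtiParams",
    "RectShape",
    "TrapezoidShape",
    "step_response",
    "rect_response",
    "trapezoid_response",
    "ode_oracle",
    "peak",
]


@dataclass(frozen=True)
class LtiParams:
    """Parameters of the first-order response.

    Attributes
    ----------
    gain : float
        Input plateau amplitude ``k`` (marker units, e.g. ms).  Governs the
        magnitude of the marker change.
    tau : float
        System time constant (s); the organ's water-uptake rate parameter.
    delay : float
        Onset lag after ingestion start (s).
    baseline : float
        Pre-ingestion marker value ``y0`` (marker units).
    """

    gain: float
    tau: float
    delay: float
    baseline: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"time constant must be positive, got {self.tau}")
        if self.delay < 0:
            raise ValueError(f"delay must be non-negative, got {self.delay}")
        if not self.baseline > 0:
            raise ValueError(f"baseline must be positive, got {self.baseline}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "gain_ms": self.gain,
                "tau_s": self.tau,
                "delay_s": self.delay,
                "baseline_ms": self.baseline,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "LtiParams":
        d = json.loads(s)
        return cls(
            gain=d["gain_ms"],
            tau=d["tau_s"],
            delay=d["delay_s"],
            baseline=d["baseline_ms"],
        )


@dataclass(frozen=True)
class RectShape:
    """Rectangular (top-hat) input: plateau of duration ``delta`` seconds."""

    delta: float

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"pulse duration must be positive, got {self.delta}")

    @property
    def total_duration(self) -> float:
        return self.delta

    def to_json(self) -> str:
        return json.dumps({"delta_s": self.delta})

    @classmethod
    def from_json(cls, s: str) -> "RectShape":
        return cls(delta=json.loads(s)["delta_s"])


@dataclass(frozen=True)
class TrapezoidShape:
    """Trapezoidal input: up-slope ``delta1``, flat top ``delta2``, down-slope
    ``delta3`` (seconds)."""

    delta1: float
    delta2: float
    delta3: float

    def __post_init__(self) -> None:
        if not self.delta1 > 0:
            raise ValueError(f"up-slope duration must be positive, got {self.delta1}")
        if self.delta2 < 0:
            raise ValueError(f"flat-top duration must be >= 0, got {self.delta2}")
        if not self.delta3 > 0:
            raise ValueError(f"down-slope duration must be positive, got {self.delta3}")

    @property
    def total_duration(self) -> float:
        return self.delta1 + self.delta2 + self.delta3

    def to_json(self) -> str:
        return json.dumps(
            {"delta1_s": self.delta1, "delta2_s": self.delta2, "delta3_s": self.delta3}
        )

    @classmethod
    def from_json(cls, s: str) -> "TrapezoidShape":
        d = json.loads(s)
        return cls(delta1=d["delta1_s"], delta2=d["delta2_s"], delta3=d["delta3_s"])


def _heaviside(x: np.ndarray) -> np.ndarray:
    # right-continuous convention u(0) = 1
    return np.where(x >= 0.0, 1.0, 0.0)


def step_response(t, p: LtiParams) -> np.ndarray:
    """Response to a delayed Heaviside step of amplitude ``gain``.

    ``y(t) = y0 + k (1 - exp(-(t - delay)/tau))`` for ``t >= delay``,
    ``y0`` otherwise.  Vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    x = t - p.delay
    return p.baseline + p.gain * (1.0 - np.exp(-np.maximum(x, 0.0) / p.tau)) * _heaviside(x)


def rect_response(t, p: LtiParams, shape: RectShape) -> np.ndarray:
    """Response to a delayed rectangular input (superposed on/off steps).

    ``y(t) = k(1-e^{-(t-D)/tau})u(t-D) - k(1-e^{-(t-D-d)/tau})u(t-D-d) + y0``
    with onset delay ``D`` and pulse duration ``d``.
    """
    t = np.asarray(t, dtype=float)
    x1 = t - p.delay
    x2 = t - p.delay - shape.delta
    on = (1.0 - np.exp(-np.maximum(x1, 0.0) / p.tau)) * _heaviside(x1)
    off = (1.0 - np.exp(-np.maximum(x2, 0.0) / p.tau)) * _heaviside(x2)
    return p.baseline + p.gain * (on - off)


def _ramp_kernel(x: np.ndarray, tau: float) -> np.ndarray:
    # response of the first-order system to a unit-slope ramp started at 0
    x = np.maximum(x, 0.0)
    return x - tau * (1.0 - np.exp(-x / tau))


def _ramp_pair(x: np.ndarray, d: float, tau: float) -> np.ndarray:
    """``[r(x) - r(x - d)] / d`` evaluated without cancellation.

    For ``x >= d`` the difference collapses to
    ``1 - (tau/d) expm1(d/tau) e^{-x/tau}``, which stays accurate even when
    ``d`` is orders of magnitude below ``x`` (the rectangle limit of a
    trapezoid slope).
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    rising = (x > 0) & (x < d)
    out[rising] = _ramp_kernel(x[rising], tau) / d
    done = x >= d
    out[done] = 1.0 - (tau / d) * np.expm1(d / tau) * np.exp(-x[done] / tau)
    return out


def trapezoid_response(t, p: LtiParams, shape: TrapezoidShape) -> np.ndarray:
    """Response to a delayed trapezoidal input, by superposing four ramps.

    With ramp kernel ``r(x) = x - tau (1 - e^{-x/tau})`` for ``x >= 0``:

    ``y(t) = y0 + (k/d1)[r(t-D) - r(t-D-d1)]
                - (k/d3)[r(t-D-d1-d2) - r(t-D-d1-d2-d3)]``

    which is the unique causal first-order response to a trapezoid with
    up-slope ``d1``, flat top ``d2`` and down-slope ``d3``.
    """
    t = np.asarray(t, dtype=float)
    d1, d2, d3 = shape.delta1, shape.delta2, shape.delta3
    up = _ramp_pair(t - p.delay, d1, p.tau)
    down = _ramp_pair(t - p.delay - d1 - d2, d3, p.tau)
    return p.baseline + p.gain * (up - down)


def rect_input(t, p: LtiParams, shape: RectShape) -> np.ndarray:
    """The rectangular input function itself (for the ODE oracle)."""
    t = np.asarray(t, dtype=float)
    return p.gain * (
        _heaviside(t - p.delay) - _heaviside(t - p.delay - shape.delta)
    )


def trapezoid_input(t, p: LtiParams, shape: TrapezoidShape) -> np.ndarray:
    """The trapezoidal input function itself (for the ODE oracle)."""
    t = np.asarray(t, dtype=float)
    d1, d2, d3 = shape.delta1, shape.delta2, shape.delta3
    x = t - p.delay
    up = np.clip(x / d1, 0.0, 1.0)
    down = np.clip((x - d1 - d2) / d3, 0.0, 1.0)
    return p.gain * (up - down)


def input_breakpoints(p: LtiParams, shape) -> list[float]:
    """Times where the input function jumps or kinks, for the ODE oracle."""
    if isinstance(shape, RectShape):
        return [p.delay, p.delay + shape.delta]
    if isinstance(shape, TrapezoidShape):
        e1 = p.delay + shape.delta1
        e2 = e1 + shape.delta2
        return [p.delay, e1, e2, e2 + shape.delta3]
    raise TypeError(f"unsupported input shape {type(shape).__name__}")


def _rk4_coeffs(dt: float, tau: float) -> float:
    # RK4 stability polynomial for y' = -y/tau: 4th-order Taylor of exp(-dt/tau)
    a = dt / tau
    return 1.0 - a + a * a / 2.0 - a**3 / 6.0 + a**4 / 24.0


def _rk4_loop(u: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Naive per-step RK4 of ``g' = (u - g)/tau``; reference for the fast path.

    ``u`` holds the input on the half-step grid (length ``2n + 1`` for ``n``
    steps).  Returns the state on the full-step grid (length ``n + 1``).
    """
    n = (len(u) - 1) // 2
    g = np.empty(n + 1)
    g[0] = 0.0
    for i in range(n):
        u1, um, u2 = u[2 * i], u[2 * i + 1], u[2 * i + 2]
        y = g[i]
        k1 = (u1 - y) / tau
        k2 = (um - (y + 0.5 * dt * k1)) / tau
        k3 = (um - (y + 0.5 * dt * k2)) / tau
        k4 = (u2 - (y + dt * k3)) / tau
        g[i + 1] = y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return g


def _rk4_fast(u: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Vectorized fixed-step RK4 of ``g' = (u - g)/tau``.

    Because the ODE is linear, the RK4 update is exactly the recurrence
    ``g[i+1] = A g[i] + B[i]`` with constant ``A`` and ``B[i]`` a fixed linear
    combination of the input at the step endpoints and midpoint; the
    recurrence is evaluated with an IIR filter.  Bit-for-bit this is the same
    scheme as :func:`_rk4_loop` (up to float reassociation).
    """
    a = dt / tau
    A = _rk4_coeffs(dt, tau)
    u1 = u[0:-2:2]
    um = u[1:-1:2]
    u2 = u[2::2]
    B = (a / 6.0) * (
        (1.0 - a + a * a / 2.0 - a**3 / 4.0) * u1
        + (4.0 - 2.0 * a + a * a / 2.0) * um
        + u2
    )
    g = np.empty(len(B) + 1)
    g[0] = 0.0
    g[1:] = lfilter([1.0], [1.0, -A], B)
    return g


def ode_oracle(
    input_fn, p: LtiParams, t_grid, dt: float = 0.02, breakpoints=None
) -> np.ndarray:
    """Numerically integrate ``tau dy/dt + y = u(t)`` as an independent check.

    The state is the deviation from baseline with ``g(t_grid[0]) = 0``;
    returned values add ``p.baseline``.  Fixed-step RK4 on an internal grid
    of step <= ``dt`` (``dt`` must be <= 0.1 s), linearly interpolated onto
    ``t_grid``.

    Parameters
    ----------
    input_fn : callable
        Maps an array of times (s) to input amplitudes (marker units).
    p : LtiParams
        Only ``tau`` and ``baseline`` are used here; the input function is
        expected to encode gain, delay and shape.
    t_grid : array-like
        Strictly increasing evaluation times (s).
    breakpoints : array-like, optional
        Times where the input jumps or kinks (e.g. pulse on/off).  The RK4
        grid restarts at each breakpoint so no step straddles a
        discontinuity; without this, a discontinuous input degrades the
        scheme to first order locally and the error floor is O(dt).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise ValueError("t_grid must be a 1-D array with at least one time")
    if len(t_grid) > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    if not 0 < dt <= 0.1:
        raise ValueError(f"RK4 step must be in (0, 0.1] s, got {dt}")
    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    if t1 == t0:
        return np.full_like(t_grid, p.baseline)
    edges = [t0]
    if breakpoints is not None:
        for b in sorted(float(b) for b in np.atleast_1d(breakpoints)):
            if t0 < b < t1 and b - edges[-1] > 1e-12:
                edges.append(b)
    edges.append(t1)

    times = [np.array([t0])]
    states = [np.array([0.0])]
    g0 = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        n = max(int(np.ceil((b - a) / dt)), 1)
        h = (b - a) / n
        half = a + np.arange(2 * n + 1) * (h / 2.0)
        # sample just inside the segment so jumps at the edges land on the
        # correct side regardless of the input's continuity convention
        eps = 1e-9 * max(h, 1.0)
        teval = half.copy()
        teval[0] += eps
        teval[-1] -= eps
        u = np.asarray(input_fn(teval), dtype=float)
        if not np.all(np.isfinite(u)):
            raise ValueError("input function returned non-finite values")
        # linearity: state = forced response from zero init + RK4-propagated
        # homogeneous decay of the incoming state
        g = _rk4_fast(u, h, p.tau) + g0 * _decay_profile(n, h, p.tau)
        times.append(a + np.arange(1, n + 1) * h)
        states.append(g[1:])
        g0 = float(g[-1])
    full_t = np.concatenate(times)
    full_g = np.concatenate(states)
    return p.baseline + np.interp(t_grid, full_t, full_g)


def _decay_profile(n: int, dt: float, tau: float) -> np.ndarray:
    # RK4 homogeneous propagation of a unit initial state over n steps
    A = _rk4_coeffs(dt, tau)
    return A ** np.arange(n + 1)


def peak(p: LtiParams, shape) -> tuple[float, float, bool]:
    """Time and value of the response maximum.

    Returns ``(t_peak, y_peak, degenerate)``.  For a rectangular input the
    peak is analytic: the response rises monotonically while the input is on,
    so ``t_peak = delay + delta`` and
    ``y_peak = y0 + k (1 - exp(-delta/tau))``.  For a trapezoid the closed
    form is maximised numerically (dense grid then golden-section refine)
    over ``[delay, delay + total + 10 tau]``.  ``gain == 0`` yields the flat
    degenerate result ``(delay, y0, True)``.
    """
    from scipy.optimize import minimize_scalar

    if p.gain == 0.0:
        return p.delay, p.baseline, True
    if isinstance(shape, RectShape):
        t_pk = p.delay + shape.delta
        y_pk = p.baseline + p.gain * (1.0 - np.exp(-shape.delta / p.tau))
        return t_pk, y_pk, False
    if not isinstance(shape, TrapezoidShape):
        raise TypeError(f"unsupported input shape {type(shape).__name__}")
    lo = p.delay
    hi = p.delay + shape.total_duration + 10.0 * p.tau
    grid = np.linspace(lo, hi, 4001)
    sign = 1.0 if p.gain > 0 else -1.0
    vals = sign * trapezoid_response(grid, p, shape)
    i = int(np.argmax(vals))
    blo, bhi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda t: -sign * float(trapezoid_response(t, p, shape)),
        bounds=(blo, bhi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    t_pk = float(res.x)
    y_pk = float(trapezoid_response(t_pk, p, shape))
    return t_pk, y_pk, False


def params_to_dict(p: LtiParams, shape) -> dict:
    """Flat JSON-ready dict of parameters and input-shape durations."""
    d = {
        "gain_ms": p.gain,
        "tau_s": p.tau,
        "delay_s": p.delay,
        "baseline_ms": p.baseline,
    }
    if isinstance(shape, RectShape):
        d["delta_s"] = shape.delta
    elif isinstance(shape, TrapezoidShape):
        d.update(
            delta1_s=shape.delta1, delta2_s=shape.delta2, delta3_s=shape.delta3
        )
    return d
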