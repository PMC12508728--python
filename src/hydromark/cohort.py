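"""Synthetic hydration-study cohort generator.

Emulates the study design the analysis pipeline expects: six healthy adult
participants, three sessions (0.5, 1.0 and 1.5 L isotonic drink) on separate
days, and eight marker time series per session.  Liver and spleen T1 follow
the first-order LTI forward models with per-volume dynamic parameters;
secondary markers (T2*, PDFF, ADC, stiffness, organ volumes) follow the liver
temporal shape scaled to their reported peak changes.  Gains are calibrated
so that the noiseless peak change matches the configured per-volume target;
between-participant variability enters as lognormal jitter on the dynamic
parameters and Gaussian jitter on the calibrated gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fitting import Marker, MarkerSeries
from .lti import (
    LtiParams,
    RectShape,
    TrapezoidShape,
    peak,
    rect_response,
    trapezoid_response,
)

__all__ = [
    "ParticipantProfile",
    "SessionSpec",
    "GeneratorConfig",
    "Cohort",
    "calibrate_gain",
    "generate_t1_series",
    "generate_secondary_marker",
    "generate_cohort",
    "default_schedules",
]

VOLUMES_L = (0.5, 1.0, 1.5)

# per-volume liver dynamics: tau (s), delay (s), pulse duration (s)
LIVER_DYNAMICS = {
    0.5: (2614.0, 758.0, 1303.0),
    1.0: (3007.0, 821.0, 1534.0),
    1.5: (6573.0, 632.0, 1521.0),
}
# per-volume spleen dynamics: tau, delay, up-slope, flat-top, down-slope (s)
SPLEEN_DYNAMICS = {
    0.5: (616.0, 609.0, 267.0, 992.0, 129.0),
    1.0: (1700.0, 745.0, 286.0, 894.0, 232.0),
    1.5: (2917.0, 568.0, 160.0, 1008.0, 141.0),
}

# per-volume target peak changes (signed; marker reporting units)
TARGET_MAX_CHANGE = {
    Marker.T1_LIVER: {0.5: 58.0, 1.0: 60.0, 1.5: 90.0},
    Marker.T1_SPLEEN: {0.5: 45.0, 1.0: 70.0, 1.5: 150.0},
    Marker.T2STAR: {0.5: 2.5, 1.0: 3.2, 1.5: 3.3},
    Marker.VOL_LIVER: {0.5: 90.0, 1.0: 120.0, 1.5: 140.0},
    Marker.ADC: {0.5: 90.0, 1.0: 140.0, 1.5: 200.0},
    Marker.PDFF: {0.5: 0.07, 1.0: 0.09, 1.5: 0.07},
    Marker.LSM: {0.5: -0.4, 1.0: -0.45, 1.5: -0.5},
    Marker.VOL_SPLEEN: {0.5: 16.0, 1.0: 21.0, 1.5: 30.0},
}

BASELINES = {
    Marker.T1_LIVER: 740.0,  # ms
    Marker.T1_SPLEEN: 1300.0,  # ms
    Marker.T2STAR: 27.0,  # ms
    Marker.ADC: 1000.0,  # 1e-6 mm^2/s
    Marker.PDFF: 2.0,  # %
    Marker.LSM: 2.6,  # kPa
    Marker.VOL_LIVER: 1600.0,  # mL
    Marker.VOL_SPLEEN: 200.0,  # mL
}

NOISE_SD = {
    Marker.T1_LIVER: 5.0,
    Marker.T1_SPLEEN: 7.0,
    Marker.T2STAR: 0.4,
    Marker.ADC: 15.0,
    Marker.PDFF: 0.15,
    Marker.LSM: 0.12,
    Marker.VOL_LIVER: 0.02 * 1600.0,
    Marker.VOL_SPLEEN: 0.02 * 200.0,
}

# acquisition cadence (s) per marker
CADENCE_S = {
    Marker.T1_LIVER: 300.0,
    Marker.T1_SPLEEN: 300.0,
    Marker.T2STAR: 900.0,
    Marker.PDFF: 900.0,
    Marker.ADC: 900.0,
    Marker.LSM: 1800.0,
    Marker.VOL_LIVER: 900.0,
    Marker.VOL_SPLEEN: 900.0,
}


@dataclass(frozen=True)
class ParticipantProfile:
    """Covariates of one participant, within the eligibility ranges."""

    id: str
    age: float  # years, 18-60
    bmi: float  # kg/m^2, 18.5-30
    baseline_liver_volume: float  # mL
    baseline_spleen_volume: float  # mL
    ivc_ao_ratio: float

    def __post_init__(self) -> None:
        if not 18.0 <= self.age <= 60.0:
            raise ValueError(f"age {self.age} outside eligibility range 18-60")
        if not 18.5 <= self.bmi <= 30.0:
            raise ValueError(f"BMI {self.bmi} outside eligibility range 18.5-30")


def default_schedules(
    post_duration: float = 4200.0, baseline_time: float = -300.0
) -> dict[Marker, np.ndarray]:
    """Per-marker sampling schedules: one pre-ingestion time plus the
    marker's cadence out to ``post_duration`` seconds."""
    out = {}
    for m, step in CADENCE_S.items():
        post = np.arange(step, post_duration + 0.5 * step, step)
        post = post[post <= post_duration]
        out[m] = np.concatenate(([baseline_time], post))
    return out


@dataclass(frozen=True)
class SessionSpec:
    """One study visit: drink volume and per-marker sampling schedules."""

    drink_volume: float  # L
    schedules: dict[Marker, np.ndarray] = field(default_factory=default_schedules)
    post_duration: float = 4200.0

    def __post_init__(self) -> None:
        if self.drink_volume not in VOLUMES_L:
            raise ValueError(f"drink volume must be one of {VOLUMES_L} L")
        for m, sched in self.schedules.items():
            sched = np.asarray(sched, dtype=float)
            if not np.any(sched < 0):
                raise ValueError(f"{m.value} schedule lacks a baseline time < 0")


@dataclass
class GeneratorConfig:
    """All dials of the synthetic cohort.

    Defaults reproduce the study conditions: per-volume dynamics, peak-change
    targets, baselines and cadences as above; lognormal jitter (sigma 0.15)
    on dynamic parameters and Gaussian jitter (CV 0.2) on gains create
    between-participant variability.  ``volume_effect_beta`` optionally scales
    the liver time constant by ``(volume / 1 L) ** beta`` to build in a drink
    volume effect for mixed-model power studies.
    """

    liver_dynamics: dict = field(default_factory=lambda: dict(LIVER_DYNAMICS))
    spleen_dynamics: dict = field(default_factory=lambda: dict(SPLEEN_DYNAMICS))
    target_max_change: dict = field(
        default_factory=lambda: {m: dict(v) for m, v in TARGET_MAX_CHANGE.items()}
    )
    baselines: dict = field(default_factory=lambda: dict(BASELINES))
    noise_sd: dict = field(default_factory=lambda: dict(NOISE_SD))
    param_jitter_sigma: float = 0.15  # lognormal sigma on tau/delay/durations
    gain_jitter_cv: float = 0.2  # Gaussian CV on calibrated gains
    volume_effect_beta: float = 0.0
    post_duration: float = 4200.0
    seed: int = 42

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        """Build from a JSON-style dict, coercing stringified volume and
        marker keys back to floats and Marker members."""
        d = dict(d)
        for key in ("liver_dynamics", "spleen_dynamics"):
            if key in d:
                d[key] = {float(v): tuple(row) for v, row in d[key].items()}
        if "target_max_change" in d:
            d["target_max_change"] = {
                Marker(m): {float(v): x for v, x in per.items()}
                for m, per in d["target_max_change"].items()
            }
        for key in ("baselines", "noise_sd"):
            if key in d:
                d[key] = {Marker(m): x for m, x in d[key].items()}
        return cls(**d)


@dataclass
class Cohort:
    """Participants x sessions x marker series, plus the generating config."""

    participants: list[ParticipantProfile]
    sessions: dict  # (participant_id, volume) -> {Marker: MarkerSeries}
    config: GeneratorConfig

    @property
    def volumes(self) -> list[float]:
        return sorted({v for (_, v) in self.sessions})

    def series(self, participant_id: str, volume: float, marker: Marker) -> MarkerSeries:
        return self.sessions[(participant_id, volume)][marker]


def calibrate_gain(p: LtiParams, shape, target_peak_change: float) -> float:
    """Gain for which the noiseless peak deviation equals the target.

    The peak deviation of a first-order response is proportional to the gain,
    so calibration is exact: for a rectangle,
    ``k = target / (1 - exp(-delta/tau))``; for a trapezoid the unit-gain
    peak is found numerically and divided out.  Negative targets (stiffness
    drops) yield negative gains.
    """
    if target_peak_change == 0:
        raise ValueError("target peak change must be non-zero")
    if isinstance(shape, RectShape):
        frac = 1.0 - np.exp(-shape.delta / p.tau)
    else:
        unit = replace(p, gain=1.0)
        _, y_pk, _ = peak(unit, shape)
        frac = y_pk - p.baseline
    return float(target_peak_change / frac)


def generate_t1_series(
    p: LtiParams,
    shape,
    schedule,
    noise_sd: float,
    rng: np.random.Generator,
    marker: Marker = Marker.T1_LIVER,
) -> MarkerSeries:
    """Evaluate the closed-form response on a schedule and add i.i.d.
    Gaussian measurement noise; pre-ingestion times sample baseline + noise."""
    schedule = np.asarray(schedule, dtype=float)
    if isinstance(shape, RectShape):
        clean = rect_response(schedule, p, shape)
    else:
        clean = trapezoid_response(schedule, p, shape)
    noisy = clean + noise_sd * rng.standard_normal(len(schedule))
    return MarkerSeries(times=schedule, values=noisy, marker=marker)


def generate_secondary_marker(
    marker: Marker,
    volume: float,
    schedule,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    liver_params: LtiParams | None = None,
    liver_shape: RectShape | None = None,
    amplitude: float | None = None,
) -> MarkerSeries:
    """Secondary-marker series: baseline + A * g(t) + noise.

    ``g`` is the session's liver response shape normalised to unit peak (the
    study reports only each marker's extremum, and every marker rose then
    returned to baseline, so the simplest consistent dynamic is shared).
    ``A`` is the target peak change for the marker and volume — negative for
    stiffness.  PDFF amplitudes are small relative to their noise, so its
    paired baseline-vs-peak test is expected non-significant.
    """
    if marker in (Marker.T1_LIVER, Marker.T1_SPLEEN):
        raise ValueError("T1 series are generated by generate_t1_series")
    if marker not in cfg.target_max_change:
        raise ValueError(f"unknown marker {marker!r}")
    schedule = np.asarray(schedule, dtype=float)
    if liver_params is None or liver_shape is None:
        tau, delay, delta = cfg.liver_dynamics[volume]
        liver_shape = RectShape(delta=delta)
        liver_params = LtiParams(gain=1.0, tau=tau, delay=delay, baseline=1.0)
    base = cfg.baselines[marker]
    A = cfg.target_max_change[marker][volume] if amplitude is None else amplitude
    unit = LtiParams(
        gain=1.0, tau=liver_params.tau, delay=liver_params.delay, baseline=1.0
    )
    _, y_pk, _ = peak(unit, liver_shape)
    g = (rect_response(schedule, unit, liver_shape) - 1.0) / (y_pk - 1.0)
    clean = base + A * g
    noisy = clean + cfg.noise_sd[marker] * rng.standard_normal(len(schedule))
    return MarkerSeries(times=schedule, values=noisy, marker=marker)


def _draw_participants(n: int, rng: np.random.Generator) -> list[ParticipantProfile]:
    out = []
    for i in range(n):
        out.append(
            ParticipantProfile(
                id=f"P{i + 1:02d}",
                age=float(rng.uniform(18.0, 60.0)),
                bmi=float(rng.uniform(18.5, 30.0)),
                baseline_liver_volume=float(rng.uniform(1200.0, 2000.0)),
                baseline_spleen_volume=float(rng.uniform(150.0, 300.0)),
                ivc_ao_ratio=float(rng.uniform(0.8, 1.4)),
            )
        )
    return out


def _jitter(value: float, sigma: float, rng: np.random.Generator) -> float:
    return float(value * np.exp(sigma * rng.standard_normal()))


def generate_cohort(
    n_participants: int = 6,
    volumes: tuple[float, ...] = VOLUMES_L,
    cfg: GeneratorConfig | None = None,
    seed: int | None = None,
) -> Cohort:
    """Generate the full synthetic cohort.

    For each participant x session, the per-volume dynamic parameters are
    jittered lognormally (``param_jitter_sigma``), the T1 gains are
    calibrated to the (Gaussian-jittered, ``gain_jitter_cv``) peak-change
    targets, and all eight marker series are emitted on their default
    schedules with marker-specific noise.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    cfg = cfg or GeneratorConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    participants = _draw_participants(n_participants, rng)
    schedules = default_schedules(cfg.post_duration)
    sj = cfg.param_jitter_sigma

    sessions: dict = {}
    for part in participants:
        for vol in volumes:
            series: dict[Marker, MarkerSeries] = {}
            # liver T1
            tau, delay, delta = cfg.liver_dynamics[vol]
            tau = _jitter(tau, sj, rng) * (vol / 1.0) ** cfg.volume_effect_beta
            delay = _jitter(delay, sj, rng)
            delta = _jitter(delta, sj, rng)
            l_shape = RectShape(delta=delta)
            l_p = LtiParams(
                gain=1.0, tau=tau, delay=delay, baseline=cfg.baselines[Marker.T1_LIVER]
            )
            target = cfg.target_max_change[Marker.T1_LIVER][vol]
            target = target * max(1.0 + cfg.gain_jitter_cv * rng.standard_normal(), 0.05)
            l_p = replace(l_p, gain=calibrate_gain(l_p, l_shape, target))
            series[Marker.T1_LIVER] = generate_t1_series(
                l_p, l_shape, schedules[Marker.T1_LIVER],
                cfg.noise_sd[Marker.T1_LIVER], rng, Marker.T1_LIVER,
            )
            # spleen T1
            s_tau, s_delay, d1, d2, d3 = cfg.spleen_dynamics[vol]
            s_tau = _jitter(s_tau, sj, rng)
            s_delay = _jitter(s_delay, sj, rng)
            s_shape = TrapezoidShape(
                delta1=_jitter(d1, sj, rng),
                delta2=_jitter(d2, sj, rng),
                delta3=_jitter(d3, sj, rng),
            )
            s_p = LtiParams(
                gain=1.0, tau=s_tau, delay=s_delay,
                baseline=cfg.baselines[Marker.T1_SPLEEN],
            )
            s_target = cfg.target_max_change[Marker.T1_SPLEEN][vol]
            s_target = s_target * max(1.0 + cfg.gain_jitter_cv * rng.standard_normal(), 0.05)
            s_p = replace(s_p, gain=calibrate_gain(s_p, s_shape, s_target))
            series[Marker.T1_SPLEEN] = generate_t1_series(
                s_p, s_shape, schedules[Marker.T1_SPLEEN],
                cfg.noise_sd[Marker.T1_SPLEEN], rng, Marker.T1_SPLEEN,
            )
            # secondary markers share the liver temporal shape
            for m in (
                Marker.T2STAR, Marker.PDFF, Marker.ADC, Marker.LSM,
                Marker.VOL_LIVER, Marker.VOL_SPLEEN,
            ):
                A = cfg.target_max_change[m][vol]
                A = A * max(1.0 + cfg.gain_jitter_cv * rng.standard_normal(), 0.05)
                series[m] = generate_secondary_marker(
                    m, vol, schedules[m], cfg, rng,
                    liver_params=l_p, liver_shape=l_shape, amplitude=A,
                )
            sessions[(part.id, vol)] = series
    return Cohort(participants=participants, sessions=sessions, config=cfg)
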