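"""Synthetic pressure/flow waveforms for manual-ventilation bench scenarios.

This module emulates an intubated, leak-free neonatal test lung (a
single-compartment RC model: one compliance, one resistance) ventilated by
hand through either a T-piece resuscitator or a self-inflating bag (SIB),
including the 10-second sustained-lung-inflation (SLI) maneuver.  It exists
so that every downstream analysis stage — breath segmentation, mechanics
extraction, the SLI efficacy screen and the cohort statistics — can be
exercised and validated without any recorded bench data.

Conventions
-----------
* pressure in cmH2O, flow in L/min (positive = into the lung), volume in mL,
  time in seconds.
* All randomness flows through :class:`numpy.random.Generator` objects or
  integer seeds; identical seeds give identical output arrays.
* The T-piece delivers a first-order (circuit time constant) rise toward the
  dialled PIP during inspiration and fall toward the dialled PEEP during
  expiration.  The SIB squeeze is modelled as a half-sine airway-pressure
  pulse with no PEEP between breaths and a pop-off valve capping the peak.
  The analyzers must not depend on the squeeze shape.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

logger = logging.getLogger(__name__)

#: conversion factor, flow in L/min -> mL/s
L_MIN_TO_ML_S = 1000.0 / 60.0

#: scale factor between the quartile z-score and the log-normal sigma:
#: for lognormal(mu, sigma), Q3/Q1 = exp(2 * 0.6745 * sigma)
_QUARTILE_Z = 0.6744897501960817


class SLINotPerformedError(RuntimeError):
    """Raised when a subject who does not know the SLI maneuver is asked for one."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LungParams:
    """Single-compartment test-lung, roughly a 2.5 kg term newborn equivalent.

    compliance : mL per cmH2O
    resistance : cmH2O per (mL/s), endotracheal tube + airway combined
    baseline_pressure : relaxed alveolar pressure, cmH2O

    Defaults are a bench calibration: with the default device settings the
    simulated cohort reproduces published bench-study tidal volumes for both
    devices (~21 mL T-piece, ~29 mL SIB).
    """

    compliance: float = 1.44
    resistance: float = 0.05
    baseline_pressure: float = 0.0

    def __post_init__(self) -> None:
        if not (self.compliance > 0):
            raise ValueError(f"compliance must be > 0, got {self.compliance}")
        if not (self.resistance > 0):
            raise ValueError(f"resistance must be > 0, got {self.resistance}")

    @property
    def tau(self) -> float:
        """Mechanical time constant R*C in seconds."""
        return self.compliance * self.resistance


@dataclass(frozen=True)
class DeviceParams:
    """Ventilation-device model parameters.

    device_kind : ``"tpiece"`` or ``"sib"``.
    circuit_tau : first-order rise/fall constant of delivered airway pressure
        during ordinary breaths (s).
    bias_flow : T-piece fresh-gas flow, L/min (recorded, not simulated).
    popoff_pressure : SIB pressure-relief valve, caps every delivered sample.
    bag_volume : SIB capacity, mL (recorded, not simulated).
    sli_rise_tau : T-piece only — first-order rise constant during the SLI
        hold (slower than a breath: the operator ramps onto the dial target).
    sli_rise_time : SIB only — duration of the quarter-sine rise to peak (s).
    sli_decay_tau : SIB only — exponential pressure-loss constant during an
        attempted hold (the bag cannot sustain the pressure).
    """

    device_kind: str
    set_pip: float | None = None
    set_peep: float | None = None
    bias_flow: float = 7.0
    popoff_pressure: float | None = None
    bag_volume: float | None = None
    circuit_tau: float = 0.08
    sli_rise_tau: float = 0.4
    sli_rise_time: float = 1.1
    sli_decay_tau: float = 1.9

    def __post_init__(self) -> None:
        if self.device_kind not in ("tpiece", "sib"):
            raise ValueError(f"unknown device_kind {self.device_kind!r}")
        for name in ("circuit_tau", "sli_rise_tau", "sli_rise_time", "sli_decay_tau"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.device_kind == "sib" and self.set_peep not in (None, 0, 0.0):
            raise ValueError("a self-inflating bag has no PEEP valve; set_peep must be 0")

    @classmethod
    def tpiece(cls, **kw) -> "DeviceParams":
        return cls(device_kind="tpiece", **kw)

    @classmethod
    def sib(cls, popoff_pressure: float = 40.0, bag_volume: float = 300.0, **kw) -> "DeviceParams":
        return cls(device_kind="sib", set_peep=0.0,
                   popoff_pressure=popoff_pressure, bag_volume=bag_volume, **kw)


@dataclass(frozen=True)
class OperatorParams:
    """One operator's hand-ventilation style for one device.

    ``pip_target``/``peep_target`` are the pressures the operator aims for,
    ``ti_mean``/``rr_mean`` the chosen inspiratory time and rate,
    ``breath_jitter_cv`` the per-breath multiplicative coefficient of
    variation applied to PIP and Ti, ``sli_target`` the pressure aimed at
    during the sustained inflation, and ``knows_sli`` whether the operator
    can perform the maneuver at all (if not, the subject is excluded from
    the SLI analysis).
    """

    pip_target: float
    peep_target: float = 0.0
    ti_mean: float = 1.0
    rr_mean: float = 40.0
    breath_jitter_cv: float = 0.10
    knows_sli: bool = True
    sli_target: float = 20.0

    def __post_init__(self) -> None:
        if not (self.rr_mean > 0):
            raise ValueError("rr_mean must be > 0")
        if not (0 < self.ti_mean < 60.0 / self.rr_mean):
            raise ValueError(
                f"ti_mean must lie in (0, breath period {60.0 / self.rr_mean:.3f} s)")
        if self.breath_jitter_cv < 0:
            raise ValueError("breath_jitter_cv must be >= 0")


@dataclass
class TimeSeries:
    """Uniformly sampled paired pressure/flow recording.

    pressure : cmH2O per sample; flow : L/min per sample (positive = into
    the lung), may be ``None`` for pressure-only traces; t0 : time of the
    first sample, seconds.
    """

    sample_rate: float
    pressure: np.ndarray
    flow: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.flow is not None:
            self.flow = np.asarray(self.flow, dtype=float)
            if self.flow.shape != self.pressure.shape:
                raise ValueError("pressure and flow must have equal length")
        if self.pressure.ndim != 1 or self.pressure.size < 2:
            raise ValueError("need a 1-D trace with at least 2 samples")
        if not (self.sample_rate > 0):
            raise ValueError("sample_rate must be > 0")

    def __len__(self) -> int:
        return self.pressure.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        return (len(self) - 1) * self.dt

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) * self.dt


# ---------------------------------------------------------------------------
# lung model
# ---------------------------------------------------------------------------

def simulate_single_compartment(airway: TimeSeries, lung: LungParams) -> TimeSeries:
    """Drive the RC lung with an airway-pressure trace and return pressure+flow.

    The alveolar pressure obeys ``C dP_alv/dt = (P_ao - P_alv)/R``.  It is
    advanced with the exact exponential update per sample for an airway
    pressure that is piecewise linear between samples, so for constant or
    linearly interpolated inputs the alveolar state is exact at sample
    times and the sampled flow carries no half-sample bias.  Returned flow
    is ``(P_ao - P_alv)/R`` converted to L/min; the volume above baseline
    is recoverable by integrating it.  The circuit is leak-free by
    construction.
    """
    if not isinstance(lung, LungParams):
        lung = LungParams(*lung)
    p_ao = airway.pressure
    dt = airway.dt
    tau = lung.tau
    a = np.exp(-dt / tau)
    # exact response to a linear input segment x[n-1] -> x[n]:
    #   y[n] = a*y[n-1] + b0*x[n] + b1*x[n-1]
    g = (tau / dt) * (1.0 - a)
    b0 = 1.0 - g
    b1 = g - a
    p_alv = np.empty_like(p_ao)
    p_alv[0] = lung.baseline_pressure
    zi = [lung.baseline_pressure - b0 * p_ao[0]]
    out, _ = lfilter([b0, b1], [1.0, -a], p_ao, zi=zi)
    p_alv[1:] = out[1:]
    flow_ml_s = (p_ao - p_alv) / lung.resistance
    return TimeSeries(sample_rate=airway.sample_rate,
                      pressure=p_ao.copy(),
                      flow=flow_ml_s / L_MIN_TO_ML_S,
                      t0=airway.t0)


def alveolar_volume(ts: TimeSeries, lung: LungParams) -> np.ndarray:
    """Cumulative volume above baseline (mL) by trapezoidal integration of flow."""
    if ts.flow is None:
        raise ValueError("trace has no flow channel")
    flow_ml_s = ts.flow * L_MIN_TO_ML_S
    v = np.concatenate([[0.0], np.cumsum((flow_ml_s[1:] + flow_ml_s[:-1]) * 0.5 * ts.dt)])
    return v


# ---------------------------------------------------------------------------
# operator sampling
# ---------------------------------------------------------------------------

def _lognormal_sigma(median: float, iqr: float) -> float:
    """Log-normal sigma whose interquartile range is exactly ``iqr``.

    Quartiles of lognormal(ln m, sigma) are m*exp(+/- z*sigma) with
    z = 0.6745, so Q3 - Q1 = 2 m sinh(z*sigma) and
    sigma = asinh(iqr / 2m) / z.
    """
    if iqr == 0:
        return 0.0
    return float(np.arcsinh(iqr / (2.0 * median)) / _QUARTILE_Z)


def lognormal_from_median_iqr(median: float, iqr: float,
                              rng: np.random.Generator,
                              size=None) -> np.ndarray | float:
    """Draw from a log-normal parameterized by its median and interquartile range.

    ``iqr == 0`` collapses to the constant ``median``; ``median == 0`` (only
    meaningful with ``iqr == 0``) collapses to zero.
    """
    if iqr < 0:
        raise ValueError("iqr (scale) must be >= 0")
    if median == 0.0:
        if iqr != 0.0:
            raise ValueError("median 0 requires iqr 0")
        return np.zeros(size) if size is not None else 0.0
    sigma = _lognormal_sigma(median, iqr)
    if sigma == 0.0:
        return np.full(size, float(median)) if size is not None else float(median)
    return median * np.exp(sigma * rng.standard_normal(size))


#: Table-style default operator behaviour per device: {field: (median, iqr)}.
#: T-piece pressures come from the dial; SIB has no PEEP and a wider PIP
#: spread.  ``ti`` for the SIB is the physical squeeze width (the measured
#: flow-based inspiratory time of a half-sine squeeze is ~0.58x the width).
TPIECE_OPERATOR_DEFAULTS: dict[str, tuple[float, float]] = {
    "pip": (19.9, 1.6),
    "peep": (5.1, 0.3),
    "ti": (1.0, 0.9),
    "rr": (40.0, 10.0),
    "sli_target": (20.3, 0.5),
}
SIB_OPERATOR_DEFAULTS: dict[str, tuple[float, float]] = {
    "pip": (21.1, 7.9),
    "peep": (0.0, 0.0),
    "ti": (0.85, 0.34),
    "rr": (40.0, 10.0),
    "sli_target": (23.6, 10.6),
}


def sample_operator(cohort_config: dict[str, tuple[float, float]],
                    seed: int | np.random.Generator,
                    breath_jitter_cv: float = 0.10,
                    knows_sli: bool = True,
                    max_duty: float = 0.6) -> OperatorParams:
    """Draw one operator from per-field (median, iqr) log-normal specs.

    Deterministic for a fixed seed.  A zero iqr degenerates to the configured
    median.  Operators who draw a long inspiratory time slow their rate so
    that Ti never exceeds ``max_duty`` of the breath period (hand ventilation
    needs expiratory time; without this cap a long-Ti draw would leave no
    room for exhalation at the drawn rate).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    draw = {}
    for name in ("pip", "peep", "ti", "rr", "sli_target"):
        median, iqr = cohort_config.get(name, (None, None))
        if median is None:
            raise ValueError(f"cohort_config missing field {name!r}")
        draw[name] = float(np.atleast_1d(lognormal_from_median_iqr(median, iqr, rng))[0])
    rr = min(draw["rr"], 60.0 * max_duty / draw["ti"])
    return OperatorParams(pip_target=draw["pip"], peep_target=draw["peep"],
                          ti_mean=draw["ti"], rr_mean=rr,
                          breath_jitter_cv=breath_jitter_cv,
                          knows_sli=knows_sli, sli_target=draw["sli_target"])


def _jitter_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Median-1 multiplicative log-normal per-breath jitter with the given cv."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(n))


# ---------------------------------------------------------------------------
# recording generators
# ---------------------------------------------------------------------------

def _first_order_piecewise(t: np.ndarray, phases: list[tuple[float, float, float]],
                           p0: float) -> np.ndarray:
    """Exact first-order relaxation through a list of (t_start, target, tau) phases.

    Each phase relaxes from the pressure reached at its start toward its
    target.  Evaluated analytically at the sample times ``t`` (continuous
    across phase boundaries, no integration error).
    """
    p = np.empty_like(t)
    cur = p0
    for i, (t_start, target, tau) in enumerate(phases):
        t_end = phases[i + 1][0] if i + 1 < len(phases) else np.inf
        m = (t >= t_start) & (t < t_end)
        p[m] = target + (cur - target) * np.exp(-(t[m] - t_start) / tau)
        if np.isfinite(t_end):
            cur = target + (cur - target) * np.exp(-(t_end - t_start) / tau)
    return p


def generate_tpiece_recording(op: OperatorParams, dev: DeviceParams, lung: LungParams,
                              duration: float, seed: int | np.random.Generator,
                              sample_rate: float = 200.0) -> TimeSeries:
    """Simulate a T-piece ventilation epoch.

    Delivered airway pressure rises first-order toward the per-breath PIP
    during Ti and falls first-order toward the set PEEP during expiration,
    with per-breath multiplicative jitter on PIP and Ti.  The flow channel
    comes from the RC lung model.
    """
    if dev.device_kind != "tpiece":
        raise ValueError("device is not a T-piece")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    period = 60.0 / op.rr_mean
    if duration <= period:
        raise ValueError("duration must exceed one breath period")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    n_breaths = int(np.ceil(duration / period))
    pip_f = _jitter_factors(rng, op.breath_jitter_cv, n_breaths)
    ti_f = _jitter_factors(rng, op.breath_jitter_cv, n_breaths)
    peep = op.peep_target if dev.set_peep is None else dev.set_peep

    phases: list[tuple[float, float, float]] = []
    for b in range(n_breaths):
        start = b * period
        pip_b = op.pip_target * pip_f[b]
        ti_b = op.ti_mean * ti_f[b]
        max_ti = period - 2.0 / sample_rate
        if ti_b >= period:
            logger.warning("breath %d: jittered Ti %.3f s >= period %.3f s, clamped",
                           b, ti_b, period)
            ti_b = max_ti
        phases.append((start, pip_b, dev.circuit_tau))
        phases.append((start + ti_b, peep, dev.circuit_tau))
    p_ao = _first_order_piecewise(t, phases, p0=peep)
    airway = TimeSeries(sample_rate=sample_rate, pressure=p_ao)
    lung_for_sim = replace(lung, baseline_pressure=peep) if lung.baseline_pressure != peep else lung
    return simulate_single_compartment(airway, lung_for_sim)


def generate_sib_recording(op: OperatorParams, dev: DeviceParams, lung: LungParams,
                           duration: float, seed: int | np.random.Generator,
                           sample_rate: float = 200.0) -> TimeSeries:
    """Simulate a self-inflating-bag ventilation epoch.

    Each squeeze is a half-sine airway-pressure pulse of width Ti with peak
    ``min(jittered pip_target, popoff_pressure)``; between breaths the
    airway sits at zero (no PEEP valve).
    """
    if dev.device_kind != "sib":
        raise ValueError("device is not a self-inflating bag")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    period = 60.0 / op.rr_mean
    if duration <= period:
        raise ValueError("duration must exceed one breath period")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    n_breaths = int(np.ceil(duration / period))
    pip_f = _jitter_factors(rng, op.breath_jitter_cv, n_breaths)
    ti_f = _jitter_factors(rng, op.breath_jitter_cv, n_breaths)
    popoff = dev.popoff_pressure if dev.popoff_pressure is not None else np.inf

    p_ao = np.zeros(n)
    for b in range(n_breaths):
        start = b * period
        ti_b = op.ti_mean * ti_f[b]
        if ti_b >= period:
            logger.warning("breath %d: jittered Ti %.3f s >= period %.3f s, clamped",
                           b, ti_b, period)
            ti_b = period - 2.0 / sample_rate
        peak = min(op.pip_target * pip_f[b], popoff)
        m = (t >= start) & (t < start + ti_b)
        p_ao[m] = peak * np.sin(np.pi * (t[m] - start) / ti_b)
    np.clip(p_ao, None, popoff, out=p_ao)
    airway = TimeSeries(sample_rate=sample_rate, pressure=p_ao)
    return simulate_single_compartment(airway, replace(lung, baseline_pressure=0.0))


def generate_sli_trace(op: OperatorParams, dev: DeviceParams, lung: LungParams,
                       seed: int | np.random.Generator = 0,
                       sample_rate: float = 200.0,
                       hold: float = 10.0,
                       pre: float = 2.0,
                       post: float = 2.0) -> TimeSeries:
    """Simulate one sustained-lung-inflation attempt (10-s hold at ~20 cmH2O).

    T-piece: first-order rise (``sli_rise_tau``) from the PEEP baseline to
    the operator's target, held through the window, fast release back to
    PEEP.  SIB: quarter-sine rise over ``sli_rise_time`` to
    ``min(target, popoff)``, then exponential pressure loss with
    ``sli_decay_tau`` toward zero — the bag cannot maintain the hold — and
    release to zero.  The trace includes ``pre`` seconds of baseline before
    maneuver onset and ``post`` seconds after release.
    """
    if not op.knows_sli:
        raise SLINotPerformedError(
            "operator does not know the SLI maneuver; subject excluded from SLI analysis")
    n = int(round((pre + hold + post) * sample_rate))
    t = np.arange(n) / sample_rate
    t_cmd = pre
    if dev.device_kind == "tpiece":
        peep = op.peep_target if dev.set_peep is None else dev.set_peep
        target = op.sli_target
        phases = [(0.0, peep, dev.circuit_tau),
                  (t_cmd, target, dev.sli_rise_tau),
                  (t_cmd + hold, peep, dev.circuit_tau)]
        p_ao = _first_order_piecewise(t, phases, p0=peep)
        lung = replace(lung, baseline_pressure=peep)
    else:
        popoff = dev.popoff_pressure if dev.popoff_pressure is not None else np.inf
        peak = min(op.sli_target, popoff)
        tr = dev.sli_rise_time
        p_ao = np.zeros(n)
        rise = (t >= t_cmd) & (t < t_cmd + tr)
        p_ao[rise] = peak * np.sin(np.pi * (t[rise] - t_cmd) / (2.0 * tr))
        decay = (t >= t_cmd + tr) & (t < t_cmd + hold)
        p_ao[decay] = peak * np.exp(-(t[decay] - t_cmd - tr) / dev.sli_decay_tau)
        rel = t >= t_cmd + hold
        p_rel = peak * np.exp(-(hold - tr) / dev.sli_decay_tau)
        p_ao[rel] = p_rel * np.exp(-(t[rel] - t_cmd - hold) / dev.circuit_tau)
        lung = replace(lung, baseline_pressure=0.0)
    airway = TimeSeries(sample_rate=sample_rate, pressure=p_ao)
    return simulate_single_compartment(airway, lung)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the bench study being emulated: 54 instructor and 60
    non-instructor operators, 3/1 acquisition failures, 13/13 operators per
    group unable to perform SLI, 3-minute ventilation epochs per device and
    a 10-s SLI attempt per device, sampled at 200 Hz.
    """

    lung: LungParams = field(default_factory=LungParams)
    tpiece_device: DeviceParams = field(default_factory=DeviceParams.tpiece)
    sib_device: DeviceParams = field(default_factory=DeviceParams.sib)
    tpiece_operator: dict = field(default_factory=lambda: dict(TPIECE_OPERATOR_DEFAULTS))
    sib_operator: dict = field(default_factory=lambda: dict(SIB_OPERATOR_DEFAULTS))
    breath_jitter_cv: float = 0.10
    n_acq_failures: tuple[int, int] = (3, 1)       # (instructor, non-instructor)
    n_sli_unknown: tuple[int, int] = (13, 13)
    epoch_duration: float = 180.0
    sli_hold: float = 10.0
    sample_rate: float = 200.0


GROUPS = ("instructor", "non_instructor")


def build_manifest(n_instructors: int, n_non_instructors: int,
                   config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Participant manifest with group labels, exclusion flags and device order."""
    if n_instructors < 0 or n_non_instructors < 0:
        raise ValueError("cohort sizes must be >= 0")
    rows = []
    counts = {"instructor": n_instructors, "non_instructor": n_non_instructors}
    k = 0
    for gi, group in enumerate(GROUPS):
        n = counts[group]
        n_fail = min(config.n_acq_failures[gi], n)
        n_unk = min(config.n_sli_unknown[gi], n - n_fail)
        idx = rng.permutation(n)
        fail = np.zeros(n, dtype=int)
        fail[idx[:n_fail]] = 1
        unk = np.zeros(n, dtype=int)
        unk[idx[n_fail:n_fail + n_unk]] = 1
        for i in range(n):
            k += 1
            order = "tpiece_first" if rng.random() < 0.5 else "sib_first"
            rows.append(dict(subject_id=f"S{k:03d}", group=group,
                             acq_failure=int(fail[i]),
                             knows_sli=int(1 - unk[i]),
                             device_order=order))
    cols = ["subject_id", "group", "acq_failure", "knows_sli", "device_order"]
    return pd.DataFrame(rows, columns=cols)


def iter_cohort_recordings(manifest: pd.DataFrame, config: CohortConfig,
                           seed: int):
    """Yield ``(manifest_row, recordings_dict)`` per retained subject.

    ``recordings_dict`` maps ``{device}_vent`` and (if the subject knows the
    maneuver) ``{device}_sli`` to :class:`TimeSeries`.  Subjects flagged as
    acquisition failures yield an empty dict.  Per-subject seeds are spawned
    from the run seed, so the stream is reproducible regardless of how many
    subjects the caller consumes.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(manifest))
    for (_, row), child in zip(manifest.iterrows(), children):
        if row.acq_failure:
            yield row, {}
            continue
        rng = np.random.default_rng(child)
        recs: dict[str, TimeSeries] = {}
        devices = (("tpiece", config.tpiece_device, config.tpiece_operator),
                   ("sib", config.sib_device, config.sib_operator))
        if row.device_order == "sib_first":
            devices = devices[::-1]
        for name, dev, op_cfg in devices:
            op = sample_operator(op_cfg, rng, breath_jitter_cv=config.breath_jitter_cv,
                                 knows_sli=bool(row.knows_sli))
            gen = generate_tpiece_recording if name == "tpiece" else generate_sib_recording
            recs[f"{name}_vent"] = gen(op, dev, config.lung, config.epoch_duration,
                                       rng, sample_rate=config.sample_rate)
            if op.knows_sli:
                recs[f"{name}_sli"] = generate_sli_trace(
                    op, dev, config.lung, rng, sample_rate=config.sample_rate,
                    hold=config.sli_hold)
        yield row, recs


def generate_cohort(n_instructors: int, n_non_instructors: int,
                    config: CohortConfig | None = None,
                    seed: int = 0) -> tuple[dict[str, dict[str, TimeSeries]], pd.DataFrame]:
    """Generate a full cohort: recordings per subject per device plus the manifest.

    Fully reproducible per seed.  For large cohorts prefer
    :func:`iter_cohort_recordings`, which does not retain all waveforms.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    manifest = build_manifest(n_instructors, n_non_instructors, config, rng)
    recordings = {row.subject_id: recs
                  for row, recs in iter_cohort_recordings(manifest, config, seed)
                  if recs}
    return recordings, manifest


def synthetic_subject_table(n: int, group_sizes: tuple[int, int],
                            device_stats: dict[str, dict[str, tuple[float, float]]],
                            ) -> pd.DataFrame:
    """Deterministic SYNTHETIC per-subject table built from group-level statistics.

    A stand-in for a per-subject summary table that is only available as
    printed group medians and interquartile ranges: each parameter column is
    filled with the inverse-CDF quantiles (plotting positions ``(i-0.5)/n``)
    of a log-normal with that median and IQR, independently shuffled per
    parameter by rank order so the columns are not comonotone.  The sample
    median and IQR of every column match the inputs to interpolation
    accuracy.  This is synthetic data, not a transcription.

    ``device_stats`` maps device -> {parameter: (median, iqr)}.
    """
    if sum(group_sizes) != n:
        raise ValueError("group sizes must sum to n")
    q = (np.arange(n) + 0.5) / n
    z = np.sqrt(2) * _erfinv(2 * q - 1)
    frames = []
    groups = np.repeat(GROUPS, group_sizes)
    for device, stats in device_stats.items():
        cols = {"subject_id": [f"S{i + 1:03d}" for i in range(n)],
                "group": groups, "device": device}
        for j, (param, (median, iqr)) in enumerate(stats.items()):
            if median == 0.0:
                vals = np.zeros(n)
            else:
                sigma = _lognormal_sigma(median, iqr)
                vals = median * np.exp(sigma * z)
            # deterministic de-alignment of parameter columns
            perm = np.argsort(np.sin(np.arange(n) * (j + 2) * 12.9898) * 43758.5453)
            cols[param] = vals[perm]
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def _erfinv(x):
    from scipy.special import erfinv
    return erfinv(x)
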