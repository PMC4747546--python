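"""Sustained-lung-inflation (SLI) efficacy metrics.

The screen quantifies how well a device/operator pair holds the target
airway pressure (nominally 20 cmH2O) over a 10-second inflation:

* ``p_max`` — maximum pressure reached within the window (cmH2O);
* ``t_max`` — time from maneuver onset to first attainment of that maximum,
  with attainment judged within a small tolerance so that an asymptotic
  plateau registers when it is reached, not at its last sample (s);
* ``auptc`` — area under the pressure-time curve over the window, absolute
  zero baseline (cmH2O*s); a perfect 20 cmH2O hold scores 200;
* ``pmn`` — mean airway pressure over the window, identically
  ``auptc / window`` (cmH2O);
* ``peep_post`` — pressure settled to shortly after release (cmH2O).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .synth import TimeSeries


@dataclass(frozen=True)
class SLIMetrics:
    p_max: float
    t_max: float
    auptc: float
    pmn: float
    peep_post: float | None
    onset_time: float
    window: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_max <= self.window):
            raise ValueError("t_max must lie within the window")


class OnsetInfo(NamedTuple):
    onset_time: float
    baseline: float


def detect_sli_onset(ts: TimeSeries, onset_threshold: float = 2.0) -> OnsetInfo:
    """Locate maneuver onset: first sample exceeding baseline + threshold.

    The pre-maneuver baseline is the median pressure over the first second
    of the trace.  Raises if no excursion crosses the threshold.
    """
    n_base = max(1, int(round(ts.sample_rate)))
    baseline = float(np.median(ts.pressure[:n_base]))
    above = ts.pressure > baseline + onset_threshold
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise ValueError("no maneuver detected: pressure never exceeds "
                         f"baseline {baseline:.2f} + threshold {onset_threshold:.2f}")
    return OnsetInfo(onset_time=ts.t0 + idx[0] * ts.dt, baseline=baseline)


def compute_sli_metrics(ts: TimeSeries, onset_time: float,
                        window: float = 10.0,
                        attainment_tol: float = 0.05) -> SLIMetrics:
    """Compute the five-number SLI screen over [onset, onset + window].

    The integral is trapezoidal on the samples with linear interpolation at
    the (possibly fractional) window end, zero-pressure baseline.  ``t_max``
    is the time to the first sample within ``attainment_tol`` of the window
    maximum (earliest-tie rule).  ``peep_post`` is the mean pressure over
    [onset + window + 0.25 s, onset + window + 0.75 s] when the trace covers
    it, else None.
    """
    fs = ts.sample_rate
    t = ts.time
    end_time = onset_time + window
    if end_time > t[-1] + 1e-9:
        raise ValueError("window extends past the end of the trace")
    i0 = int(np.searchsorted(t, onset_time - 1e-9))
    i1 = int(np.searchsorted(t, end_time + 1e-9)) - 1  # last sample <= end
    p = ts.pressure
    seg_t = t[i0:i1 + 1]
    seg_p = p[i0:i1 + 1]
    auptc = float(np.trapezoid(seg_p, seg_t))
    # fractional head/tail when the window edges fall between samples
    if seg_t[0] > onset_time + 1e-12:
        p_start = float(np.interp(onset_time, t, p))
        auptc += 0.5 * (p_start + seg_p[0]) * (seg_t[0] - onset_time)
    if seg_t[-1] < end_time - 1e-12:
        p_end = float(np.interp(end_time, t, p))
        auptc += 0.5 * (seg_p[-1] + p_end) * (end_time - seg_t[-1])
    p_max = float(seg_p.max())
    attained = np.flatnonzero(seg_p >= p_max - attainment_tol)
    t_max = float(seg_t[attained[0]] - onset_time)
    lo, hi = end_time + 0.25, end_time + 0.75
    if hi <= t[-1] + 1e-9:
        m = (t >= lo) & (t <= hi)
        peep_post = float(p[m].mean())
    else:
        peep_post = None
    return SLIMetrics(p_max=p_max, t_max=min(t_max, window), auptc=auptc,
                      pmn=auptc / window, peep_post=peep_post,
                      onset_time=onset_time, window=window)


def analyze_sli_trace(ts: TimeSeries, onset_threshold: float = 2.0,
                      window: float = 10.0) -> SLIMetrics:
    """Onset detection + metric computation in one step."""
    onset = detect_sli_onset(ts, onset_threshold)
    return compute_sli_metrics(ts, onset.onset_time, window=window)


def sli_metrics_to_frame(rows: list[tuple[str, str, SLIMetrics]]) -> pd.DataFrame:
    """(subject_id, device, metrics) triples -> one-row-per-subject frame."""
    recs = []
    for subject_id, device, m in rows:
        recs.append(dict(subject_id=subject_id, device=device, p_max=m.p_max,
                         t_max=m.t_max, auptc=m.auptc, pmn=m.pmn,
                         peep_post=m.peep_post, onset_time=m.onset_time))
    cols = ["subject_id", "device", "p_max", "t_max", "auptc", "pmn",
            "peep_post", "onset_time"]
    return pd.DataFrame(recs, columns=cols)


def plot_sli(ts: TimeSeries, metrics: SLIMetrics, ax=None):
    """Pressure-time plot with the AUPTC window shaded (screen-style figure)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t = ts.time
    ax.plot(t, ts.pressure, lw=1.0, color="tab:blue")
    w = (t >= metrics.onset_time) & (t <= metrics.onset_time + metrics.window)
    ax.fill_between(t[w], 0.0, ts.pressure[w], alpha=0.3, color="tab:blue",
                    label=f"AUPTC = {metrics.auptc:.1f} cmH$_2$O·s")
    ax.axhline(metrics.p_max, ls=":", color="tab:red",
               label=f"P Max = {metrics.p_max:.1f} cmH$_2$O")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("airway pressure (cmH$_2$O)")
    ax.legend(loc="upper right", fontsize=8)
    return ax
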