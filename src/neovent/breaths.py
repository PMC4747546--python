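"""Breath segmentation and per-breath respiratory-mechanics extraction.

Turns a ventilation epoch (paired pressure/flow trace) into per-breath
records of tidal volume, PIP, PEEP and inspiratory/expiratory times, and
reduces those to one summary per subject and device (adding respiratory
rate and minute volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import L_MIN_TO_ML_S, TimeSeries


@dataclass(frozen=True)
class BreathSegment:
    """Sample-index bounds of one breath: [onset, insp_end) inspiration,
    [insp_end, end) expiration.  0-based, half-open."""

    onset_index: int
    insp_end_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not (self.onset_index < self.insp_end_index <= self.end_index):
            raise ValueError("require onset < insp_end <= end")


@dataclass(frozen=True)
class BreathRecord:
    """Per-breath mechanics: vt (mL), pip/peep (cmH2O), ti/te (s)."""

    vt: float
    pip: float
    peep: float
    ti: float
    te: float

    def __post_init__(self) -> None:
        if self.vt < 0 or self.ti <= 0 or self.te < 0:
            raise ValueError("invalid breath record")
        if self.pip < self.peep:
            raise ValueError("pip must be >= peep")


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject, per-device epoch summary (central values over breaths)."""

    subject_id: str
    device: str
    vt: float
    pip: float
    peep: float
    ti: float
    te: float
    rr: float
    minute_volume: float
    n_breaths: int


def segment_breaths(ts: TimeSeries, flow_threshold: float = 0.2,
                    min_ti: float = 0.1) -> list[BreathSegment]:
    """Detect breaths from the flow channel.

    A breath onset is a rising crossing of ``+flow_threshold`` (L/min).  A
    new onset is accepted only after the previous breath's flow has either
    fallen through ``-flow_threshold`` or stayed below ``+flow_threshold``
    for at least ``min_ti`` seconds (hysteresis).  Inspiration ends at the
    first non-positive flow sample after onset; candidate inspirations
    shorter than ``min_ti`` are rejected as noise.  Each breath ends at the
    next accepted onset; the last ends at the trace end.  A flat or empty
    trace yields an empty list.
    """
    if ts.flow is None:
        raise ValueError("trace has no flow channel")
    if not (flow_threshold > 0):
        raise ValueError("flow_threshold must be > 0")
    flow = ts.flow
    n = len(flow)
    min_samples = max(1, int(round(min_ti * ts.sample_rate)))

    rising = np.flatnonzero((flow[:-1] < flow_threshold) & (flow[1:] >= flow_threshold)) + 1
    onsets: list[int] = []
    insp_ends: list[int] = []
    for c in rising:
        if onsets:
            prev = onsets[-1]
            between = flow[prev:c]
            fell = np.any(between <= -flow_threshold)
            if not fell:
                below = between < flow_threshold
                # longest run of sub-threshold flow since the previous onset
                runs = _max_run(below)
                if runs < min_samples:
                    continue
        rel = np.flatnonzero(flow[c + 1:] <= 0.0)
        insp_end = (c + 1 + rel[0]) if rel.size else n
        if insp_end - c < min_samples:
            continue  # too short to be an inspiration
        onsets.append(int(c))
        insp_ends.append(int(insp_end))

    segments = []
    for i, (onset, insp_end) in enumerate(zip(onsets, insp_ends)):
        end = onsets[i + 1] if i + 1 < len(onsets) else n
        segments.append(BreathSegment(onset, min(insp_end, end), end))
    return segments


def _max_run(mask: np.ndarray) -> int:
    """Length of the longest True run."""
    if mask.size == 0:
        return 0
    padded = np.concatenate([[0], mask.view(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max()) if starts.size else 0


def compute_breath_metrics(ts: TimeSeries, seg: BreathSegment,
                           peep_window: float = 0.05) -> BreathRecord:
    """Mechanics of one segmented breath.

    vt is the trapezoidal integral of positive flow (converted to mL/s) over
    the inspiration; pip the segment's maximum pressure; peep the mean
    pressure over the final ``peep_window`` seconds of the segment (just
    before the next onset); ti and te follow from the segment bounds.
    """
    if ts.flow is None:
        raise ValueError("trace has no flow channel")
    n = len(ts)
    if not (0 <= seg.onset_index < seg.insp_end_index <= seg.end_index <= n):
        raise ValueError("segment out of trace bounds")
    fs = ts.sample_rate
    insp = np.clip(ts.flow[seg.onset_index:seg.insp_end_index + 1
                           if seg.insp_end_index < n else n], 0.0, None)
    vt = float(np.trapezoid(insp * L_MIN_TO_ML_S, dx=1.0 / fs))
    pressure = ts.pressure[seg.onset_index:seg.end_index]
    pip = float(pressure.max())
    k = max(1, int(round(peep_window * fs)))
    peep = float(pressure[-k:].mean())
    ti = (seg.insp_end_index - seg.onset_index) / fs
    te = (seg.end_index - seg.insp_end_index) / fs
    return BreathRecord(vt=vt, pip=pip, peep=min(peep, pip), ti=ti, te=te)


def analyze_recording(ts: TimeSeries, flow_threshold: float = 0.2,
                      min_ti: float = 0.1) -> list[BreathRecord]:
    """Segment an epoch and compute mechanics for every breath."""
    return [compute_breath_metrics(ts, seg)
            for seg in segment_breaths(ts, flow_threshold, min_ti)]


def summarize_subject(breaths: list[BreathRecord], epoch_duration: float,
                      subject_id: str = "", device: str = "",
                      reducer: str = "mean") -> SubjectSummary:
    """Reduce an epoch's breaths to one per-subject summary.

    The central-value reducer is the arithmetic mean by default ("median"
    is available); rr = 60 * n_breaths / epoch_duration (breaths/min) and
    minute_volume = central vt * rr (mL/min).  Zero breaths is an
    acquisition failure and raises.
    """
    if not breaths:
        raise ValueError("no breaths: acquisition failure")
    if reducer not in ("mean", "median"):
        raise ValueError("reducer must be 'mean' or 'median'")
    red = np.mean if reducer == "mean" else np.median
    vt = float(red([b.vt for b in breaths]))
    rr = 60.0 * len(breaths) / epoch_duration
    return SubjectSummary(
        subject_id=subject_id, device=device,
        vt=vt,
        pip=float(red([b.pip for b in breaths])),
        peep=float(red([b.peep for b in breaths])),
        ti=float(red([b.ti for b in breaths])),
        te=float(red([b.te for b in breaths])),
        rr=rr,
        minute_volume=vt * rr,
        n_breaths=len(breaths),
    )


def breaths_to_frame(breaths: list[BreathRecord]) -> pd.DataFrame:
    """Per-breath records as a DataFrame (one row per breath)."""
    return pd.DataFrame([b.__dict__ for b in breaths],
                        columns=["vt", "pip", "peep", "ti", "te"])


def summaries_to_frame(summaries: list[SubjectSummary]) -> pd.DataFrame:
    cols = ["subject_id", "device", "vt", "pip", "peep", "ti", "te",
            "rr", "minute_volume", "n_breaths"]
    return pd.DataFrame([s.__dict__ for s in summaries], columns=cols)
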