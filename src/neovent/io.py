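"""File formats, run configuration and the end-to-end pipeline.

Recordings travel as plain CSV (columns ``time_s, pressure_cmH2O,
flow_L_min``, ``#``-prefixed comment header carrying the seed and config
hash); manifests, per-breath, per-subject, SLI and comparison tables are
CSV as well.  ``run_pipeline`` ties generation -> breath mechanics -> SLI
metrics -> cohort comparison into one reproducible, seed-stamped run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import breaths as bm
from . import cohort as cp
from . import sli as sm
from . import synth

logger = logging.getLogger(__name__)

TIMESERIES_COLUMNS = ["time_s", "pressure_cmH2O", "flow_L_min"]


# ---------------------------------------------------------------------------
# recording CSV
# ---------------------------------------------------------------------------

def write_timeseries(ts: synth.TimeSeries, path, header_meta: dict | None = None) -> None:
    """Write a recording as CSV with ``#`` comment header lines."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df = pd.DataFrame({
            "time_s": ts.time,
            "pressure_cmH2O": ts.pressure,
            "flow_L_min": ts.flow if ts.flow is not None else np.zeros(len(ts)),
        })
        df.to_csv(fh, index=False, float_format="%.17g")  # exact round-trip


def read_timeseries(path) -> synth.TimeSeries:
    """Read a recording CSV back into a :class:`TimeSeries`.

    Validates the column set, strict monotonic and uniform sampling (max
    jitter 1e-6 s) and complete cells (a missing value is reported with its
    row number).
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in TIMESERIES_COLUMNS:
        bad = df.index[df[col].isna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValueError(f"{path}: missing {col} value at row {bad[0] + 2}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise ValueError(f"{path}: non-monotonic time")
    if np.abs(dt - dt.mean()).max() > 1e-6:
        raise ValueError(f"{path}: non-uniform sampling (jitter > 1e-6 s)")
    return synth.TimeSeries(sample_rate=1.0 / dt.mean(),
                            pressure=df["pressure_cmH2O"].to_numpy(dtype=float),
                            flow=df["flow_L_min"].to_numpy(dtype=float),
                            t0=float(t[0]))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat, file-loadable configuration for one pipeline run."""

    seed: int = 0
    n_instructors: int = 54
    n_non_instructors: int = 60
    outdir: str = "neovent_out"
    write_waveforms: bool = False
    stratify: bool = False
    flow_threshold: float = 0.2
    min_ti: float = 0.1
    reducer: str = "mean"
    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` text file (``#`` comments allowed).

        Keys are namespaced: ``sim.seed``, ``sim.sample_rate``,
        ``cohort.n_instructors``, ``lung.compliance``,
        ``device.tpiece.circuit_tau``, ``device.sib.popoff_pressure``,
        ``operator.tpiece.pip = median,iqr`` and so on.
        """
        cfg = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            cfg._apply(key, val, where=f"{path}:{lineno}")
        return cfg

    def _apply(self, key: str, val: str, where: str = "") -> None:
        def num(v):
            return float(v) if ("." in v or "e" in v.lower()) else int(v)

        parts = key.split(".")
        try:
            if parts[0] == "sim":
                if parts[1] == "seed":
                    self.seed = int(val)
                elif parts[1] == "sample_rate":
                    self.cohort.sample_rate = float(val)
                elif parts[1] == "epoch_duration":
                    self.cohort.epoch_duration = float(val)
                else:
                    raise KeyError
            elif parts[0] == "cohort":
                if parts[1] in ("n_instructors", "n_non_instructors"):
                    setattr(self, parts[1], int(val))
                elif parts[1] in ("n_acq_failures", "n_sli_unknown"):
                    a, b = (int(x) for x in val.split(","))
                    setattr(self.cohort, parts[1], (a, b))
                else:
                    raise KeyError
            elif parts[0] == "run":
                if parts[1] in ("outdir", "reducer"):
                    setattr(self, parts[1], val)
                elif parts[1] in ("write_waveforms", "stratify"):
                    setattr(self, parts[1], val.lower() in ("1", "true", "yes"))
                elif parts[1] in ("flow_threshold", "min_ti"):
                    setattr(self, parts[1], float(val))
                else:
                    raise KeyError
            elif parts[0] == "lung":
                self.cohort.lung = dataclasses.replace(
                    self.cohort.lung, **{parts[1]: float(val)})
            elif parts[0] == "device":
                attr = f"{parts[1]}_device"
                dev = getattr(self.cohort, attr)
                setattr(self.cohort, attr,
                        dataclasses.replace(dev, **{parts[2]: float(val)}))
            elif parts[0] == "operator":
                if parts[1] == "jitter_cv":
                    self.cohort.breath_jitter_cv = float(val)
                else:
                    m, i = (float(x) for x in val.split(","))
                    getattr(self.cohort, f"{parts[1]}_operator")[parts[2]] = (m, i)
            else:
                raise KeyError
        except (KeyError, IndexError, TypeError) as exc:
            raise ValueError(f"{where}: unknown config key {key!r}") from exc
        except ValueError as exc:
            raise ValueError(f"{where}: bad value for {key!r}: {exc}") from exc

    def config_hash(self) -> str:
        payload = _as_jsonable(self)
        payload.pop("outdir", None)  # output location must not change the hash
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# supplementary-style fixture transcription
# ---------------------------------------------------------------------------

def transcribe_supplementary_fixture(path_table, n_mechanics: int | None = None,
                                     n_sli: int | None = None) -> pd.DataFrame:
    """Validate a hand-transcribed per-subject summary table.

    Accepts CSV (or whitespace-delimited) text with columns ``subject_id,
    group, device`` plus parameter columns, and checks per-device row
    counts against the declared accounting (mechanics parameters against
    ``n_mechanics``, SLI parameters against ``n_sli``).  Returns the
    validated frame in the per-subject summary schema.
    """
    text = Path(path_table).read_text()
    if not text.strip():
        raise ValueError(f"{path_table}: empty fixture")
    sep = "," if "," in text.splitlines()[0] else r"\s+"
    df = pd.read_csv(_io.StringIO(text), sep=sep, comment="#")
    required = {"subject_id", "group", "device"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path_table}: missing columns {sorted(missing)}")
    has_mech = any(c in df.columns for c in cp.MECHANICS_PARAMS)
    has_sli = any(c in df.columns for c in cp.SLI_PARAMS)
    for dev, sub in df.groupby("device"):
        expected = n_mechanics if has_mech else (n_sli if has_sli else None)
        if has_mech and n_mechanics is not None and len(sub) != n_mechanics:
            raise ValueError(
                f"{path_table}: device {dev!r} has {len(sub)} mechanics rows, "
                f"accounting declares {n_mechanics}")
        if has_sli and not has_mech and n_sli is not None and len(sub) != n_sli:
            raise ValueError(
                f"{path_table}: device {dev!r} has {len(sub)} SLI rows, "
                f"accounting declares {n_sli}")
    return df


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def analyze_cohort(manifest: pd.DataFrame, config: synth.CohortConfig, seed: int,
                   flow_threshold: float = 0.2, min_ti: float = 0.1,
                   reducer: str = "mean",
                   waveform_sink=None) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate and analyze every retained subject; waveforms are streamed.

    Returns (per-breath frame, per-subject mechanics frame, SLI metrics
    frame).  ``waveform_sink(subject_id, name, ts)`` is called per recording
    when given (e.g. to write waveform CSVs).
    """
    breath_rows, summaries, sli_rows = [], [], []
    for row, recs in synth.iter_cohort_recordings(manifest, config, seed):
        for name, ts in recs.items():
            if waveform_sink is not None:
                waveform_sink(row.subject_id, name, ts)
            device, kind = name.split("_")
            if kind == "vent":
                records = bm.analyze_recording(ts, flow_threshold, min_ti)
                frame = bm.breaths_to_frame(records)
                frame.insert(0, "device", device)
                frame.insert(0, "subject_id", row.subject_id)
                breath_rows.append(frame)
                summaries.append(bm.summarize_subject(
                    records, config.epoch_duration, subject_id=row.subject_id,
                    device=device, reducer=reducer))
            else:
                metrics = sm.analyze_sli_trace(ts, window=config.sli_hold)
                sli_rows.append((row.subject_id, device, metrics))
    breath_frame = (pd.concat(breath_rows, ignore_index=True)
                    if breath_rows else pd.DataFrame())
    return (breath_frame, bm.summaries_to_frame(summaries),
            sm.sli_metrics_to_frame(sli_rows))


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute synth -> breath mechanics -> SLI metrics -> comparison.

    Emits manifest, per-breath, per-subject, SLI-metrics and comparison CSVs
    plus a run log into ``config.outdir``; reruns with the same config are
    byte-identical.  Returns the artifact paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    manifest = synth.build_manifest(config.n_instructors, config.n_non_instructors,
                                    config.cohort, rng)
    accounting = cp.apply_participant_flow(manifest) if len(manifest) else None

    sink = None
    if config.write_waveforms:
        wavedir = outdir / "waveforms"
        wavedir.mkdir(exist_ok=True)

        def sink(sid, name, ts):
            write_timeseries(ts, wavedir / f"{sid}_{name}.csv", meta)

    try:
        breath_frame, subject_frame, sli_frame = analyze_cohort(
            manifest, config.cohort, config.seed,
            flow_threshold=config.flow_threshold, min_ti=config.min_ti,
            reducer=config.reducer, waveform_sink=sink)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"analysis stage failed: {exc}") from exc

    comparison = pd.DataFrame()
    if len(subject_frame):
        comparison = cp.build_comparison_table(
            subject_frame, sli_frame if len(sli_frame) else None,
            accounting=accounting, manifest=manifest, stratify=config.stratify)

    paths = {}
    tables = {
        "manifest": manifest,
        "breaths": breath_frame,
        "subject_summaries": subject_frame,
        "sli_metrics": sli_frame,
        "comparison": comparison,
    }
    for name, frame in tables.items():
        path = outdir / f"{name}.csv"
        with open(path, "w", newline="") as fh:
            for key, val in meta.items():
                fh.write(f"# {key}={val}\n")
            frame.to_csv(fh, index=False, float_format="%.6f")
        paths[name] = path

    log_lines = [f"seed={config.seed}", f"config_hash={meta['config_hash']}",
                 f"n_subjects={len(manifest)}"]
    if accounting is not None:
        log_lines += [
            f"mechanics_eligible={accounting.mechanics_total}",
            f"sli_eligible={accounting.sli_total}",
            cp.accounting_report(accounting),
        ]
    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    paths["run_log"] = log_path
    return paths
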