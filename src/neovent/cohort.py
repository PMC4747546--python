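"""Participant-flow accounting and the device-comparison table.

Applies the study's two-stage exclusion filter (acquisition failures, then
operators unable to perform the sustained inflation) and assembles the
grouped median(IQR) comparison of ventilation mechanics and SLI metrics
between devices, with the appropriate test statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import mann_whitney_u, summarize_group, wilcoxon_paired

MECHANICS_PARAMS = ("vt", "pip", "peep", "ti")
SLI_PARAMS = ("p_max", "auptc", "pmn", "t_max")
GROUPS = ("instructor", "non_instructor")


@dataclass(frozen=True)
class CohortAccounting:
    """Per-group participant counts at each filter stage."""

    enrolled: dict
    mechanics_eligible: dict
    sli_eligible: dict

    @property
    def enrolled_total(self) -> int:
        return sum(self.enrolled.values())

    @property
    def mechanics_total(self) -> int:
        return sum(self.mechanics_eligible.values())

    @property
    def sli_total(self) -> int:
        return sum(self.sli_eligible.values())


def apply_participant_flow(manifest: pd.DataFrame) -> CohortAccounting:
    """Two-stage exclusion: acquisition failures drop out of the mechanics
    analysis; of the remainder, subjects who cannot perform SLI drop out of
    the SLI analysis.  Duplicate subject ids are rejected."""
    required = {"subject_id", "group", "acq_failure", "knows_sli"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    if manifest.subject_id.duplicated().any():
        dupes = manifest.subject_id[manifest.subject_id.duplicated()].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    enrolled, mech, sli = {}, {}, {}
    for group, sub in manifest.groupby("group", sort=False):
        enrolled[group] = int(len(sub))
        ok = sub[sub.acq_failure == 0]
        mech[group] = int(len(ok))
        sli[group] = int(len(ok[ok.knows_sli == 1]))
    return CohortAccounting(enrolled=enrolled, mechanics_eligible=mech,
                            sli_eligible=sli)


def accounting_report(acc: CohortAccounting) -> str:
    lines = ["cohort accounting"]
    for stage, d in (("enrolled", acc.enrolled),
                     ("mechanics_eligible", acc.mechanics_eligible),
                     ("sli_eligible", acc.sli_eligible)):
        per = ", ".join(f"{g}={d.get(g, 0)}" for g in sorted(d))
        lines.append(f"  {stage}: {per} (total {sum(d.values())})")
    return "\n".join(lines)


def _compare_parameter(frame: pd.DataFrame, param: str, n_expected: int | None,
                       paired: bool) -> list[dict]:
    rows = []
    by_dev = {dev: sub for dev, sub in frame.groupby("device", sort=False)}
    if set(by_dev) != {"tpiece", "sib"}:
        raise ValueError("summaries must cover both devices")
    vals = {}
    for dev in ("tpiece", "sib"):
        v = by_dev[dev][param].to_numpy(dtype=float)
        if n_expected is not None and v.size != n_expected:
            raise ValueError(
                f"{param}/{dev}: {v.size} subjects but accounting expects {n_expected}")
        vals[dev] = v
    if paired:
        a = by_dev["tpiece"].sort_values("subject_id")[param].to_numpy(float)
        b = by_dev["sib"].sort_values("subject_id")[param].to_numpy(float)
        stat, p = wilcoxon_paired(a, b)
        test = "wilcoxon"
    else:
        stat, p = mann_whitney_u(vals["tpiece"], vals["sib"])
        test = "mann-whitney"
    for dev in ("tpiece", "sib"):
        med, iqr, n = summarize_group(vals[dev])
        rows.append(dict(parameter=param, device=dev, group="all", n=n,
                         median=med, iqr=iqr, test=test, statistic=stat, p=p))
    return rows


def build_comparison_table(mechanics: pd.DataFrame,
                           sli: pd.DataFrame | None,
                           accounting: CohortAccounting | None = None,
                           manifest: pd.DataFrame | None = None,
                           stratify: bool = False,
                           paired: bool = False) -> pd.DataFrame:
    """Grouped median(IQR) comparison table between devices.

    ``mechanics`` is a per-subject summary frame (columns subject_id,
    device, vt, pip, peep, ti, ...); ``sli`` an SLI-metrics frame (columns
    subject_id, device, p_max, auptc, pmn, t_max, ...).  Each parameter is
    compared between devices with the Mann-Whitney U on per-subject values
    (a paired Wilcoxon by flag).  When ``accounting`` is given, per-device
    subject counts must match the eligible totals.  ``stratify=True`` adds
    per-group (instructor / non-instructor) rows, which requires
    ``manifest`` for group membership unless the frames carry a ``group``
    column.
    """
    rows: list[dict] = []
    blocks = [(mechanics, MECHANICS_PARAMS,
               accounting.mechanics_total if accounting else None)]
    if sli is not None and len(sli):
        blocks.append((sli, SLI_PARAMS,
                       accounting.sli_total if accounting else None))
    for frame, params, n_expected in blocks:
        frame = _with_group(frame, manifest)
        for param in params:
            rows.extend(_compare_parameter(frame, param, n_expected, paired))
            if stratify:
                for group in GROUPS:
                    sub = frame[frame.group == group]
                    if len(sub):
                        strat = _compare_parameter(sub, param, None, paired)
                        for r in strat:
                            r["group"] = group
                        rows.extend(strat)
    cols = ["parameter", "device", "group", "n", "median", "iqr",
            "test", "statistic", "p"]
    return pd.DataFrame(rows, columns=cols)


def _with_group(frame: pd.DataFrame, manifest: pd.DataFrame | None) -> pd.DataFrame:
    if "group" in frame.columns:
        return frame
    if manifest is None:
        out = frame.copy()
        out["group"] = "unknown"
        return out
    return frame.merge(manifest[["subject_id", "group"]], on="subject_id",
                       how="left")
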