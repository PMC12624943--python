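"""Drinking-microstructure metrics from bout- and lick-level logs.

Everything a two-bottle-choice analysis needs from a
:class:`~sipcage.core.SessionLog`, emitted as tidy long-format
DataFrames (one row per subject x fluid x stratum x metric, with units
and a ``flag`` column that marks empty or undefined strata instead of
silently writing 0):

* :func:`filter_bouts` — apply the >= 20-lick bout criterion and
  annotate day index, Zeitgeber hour, light/dark phase and lick-count
  bin;
* :func:`daily_intake` — mL/day per fluid and ethanol dose in g/kg;
* :func:`preference` — ethanol volume as % of total fluid volume;
* :func:`hourly_zt_profile` — hourly intake by Zeitgeber time,
  averaged across days;
* :func:`phase_totals` — light- vs dark-phase intake per day;
* :func:`bout_stats` — mean/max bout size, volume per lick, bout
  frequency;
* :func:`bout_range_volumes` — volume binned by bout lick count, raw
  and normalised per fluid;
* :func:`lick_microstructure` — inter-lick interval, inter-bout
  interval, bout duration and within-bout lick rate from a lick-level
  log.

Conventions: days are 24 h windows from ``experiment_start``; hourly
and phase bins are half-open; "volume per lick" is total volume over
total licks (a pooled per-lick estimate), not the mean of per-bout
ratios. Undefined ratios (0/0 preference, single-lick rate) are
emitted as NaN with ``flag="undefined"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ExperimentConfig,
    SessionLog,
    SubjectRegistry,
    ethanol_dose_g_per_kg,
    is_dark,
    to_zeitgeber,
)

__all__ = [
    "BoutTable",
    "LickDataRequiredError",
    "filter_bouts",
    "daily_intake",
    "preference",
    "hourly_zt_profile",
    "phase_totals",
    "bout_stats",
    "bout_range_volumes",
    "lick_microstructure",
    "segment_lick_stream",
    "wide_summary",
]

METRIC_COLUMNS = ["subject_id", "fluid", "metric", "value", "units", "flag"]


class LickDataRequiredError(ValueError):
    """Raised when a lick-level metric is requested without a lick log."""


def _bin_labels(edges: Sequence[int]) -> list[str]:
    labels = [f"{a}-{b - 1}" for a, b in zip(edges, edges[1:])]
    labels.append(f"{edges[-1]}+")
    return labels


@dataclass
class BoutTable:
    """Filtered, annotated bout records plus the context needed by metrics.

    ``frame`` columns: start_time, device_id, fluid, rfid, subject_id,
    lick_count, volume_mL, duration_s, t_s, day, zt, zt_hour, phase,
    lick_bin.
    """

    frame: pd.DataFrame
    config: ExperimentConfig
    subjects: SubjectRegistry
    n_days: int
    n_removed_below_threshold: int
    n_removed_unknown_rfid: int

    @property
    def fluids(self) -> list[str]:
        return [f.label for f in self.config.fluids.values()]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def filter_bouts(
    session: SessionLog,
    n_days: Optional[int] = None,
    min_licks: Optional[int] = None,
) -> BoutTable:
    """Apply the bout criterion and annotate circadian context.

    Drinking events with fewer than ``min_licks`` licks (default: the
    config's ``min_licks_per_bout``, normally 20) are dropped, as are
    rows whose RFID is not in the registry (both counts are reported on
    the returned table). ``n_days`` defaults to the number of 24 h
    windows spanned by the data (at least 1); pass it explicitly when
    the planned session length exceeds the observed one.
    """
    cfg = session.config
    if min_licks is None:
        min_licks = cfg.min_licks_per_bout
    rows = []
    n_below = 0
    n_unknown = 0
    for b in session.bouts:
        if b.rfid not in session.subjects:
            n_unknown += 1
            continue
        if b.lick_count < min_licks:
            n_below += 1
            continue
        t_s = cfg.seconds_since_start(b.start_time)
        zt = to_zeitgeber(b.start_time, cfg.light_cycle)
        rows.append(
            {
                "start_time": b.start_time,
                "device_id": b.device_id,
                "fluid": b.fluid_label,
                "rfid": b.rfid,
                "subject_id": session.subjects[b.rfid].subject_id,
                "lick_count": b.lick_count,
                "volume_mL": b.volume_mL,
                "duration_s": b.duration_s,
                "t_s": t_s,
                "day": int(t_s // 86400.0),
                "zt": zt,
                "zt_hour": int(zt) % 24,
                "phase": "dark" if is_dark(b.start_time, cfg.light_cycle) else "light",
            }
        )
    cols = ["start_time", "device_id", "fluid", "rfid", "subject_id", "lick_count",
            "volume_mL", "duration_s", "t_s", "day", "zt", "zt_hour", "phase"]
    frame = pd.DataFrame(rows, columns=cols)
    edges = list(cfg.lick_bin_edges)
    labels = _bin_labels(edges)
    if len(frame):
        idx = np.digitize(frame["lick_count"].to_numpy(), edges) - 1
        frame["lick_bin"] = [labels[i] if i >= 0 else "<first-edge" for i in idx]
    else:
        frame["lick_bin"] = pd.Series(dtype=object)
    if n_days is None:
        n_days = max(1, int(math.ceil(frame["t_s"].max() / 86400.0))) if len(frame) else 1
    return BoutTable(
        frame=frame,
        config=cfg,
        subjects=session.subjects,
        n_days=n_days,
        n_removed_below_threshold=n_below,
        n_removed_unknown_rfid=n_unknown,
    )


def _fluid_specs(cfg: ExperimentConfig) -> dict[str, object]:
    return {f.label: f for f in cfg.fluids.values()}


def _ethanol_labels(cfg: ExperimentConfig) -> list[str]:
    return [f.label for f in cfg.fluids.values() if f.ethanol_fraction_vv > 0]


def _water_labels(cfg: ExperimentConfig) -> list[str]:
    return [f.label for f in cfg.fluids.values() if f.ethanol_fraction_vv == 0]


def daily_intake(bt: BoutTable) -> pd.DataFrame:
    """Per subject-day intake: mL per fluid, plus ethanol dose in g/kg.

    Every day in ``range(n_days)`` is enumerated for every subject and
    fluid; days without bouts get 0 (they are real observations of not
    drinking, not missing data). Raises ``KeyError`` naming the subject
    if a body mass is missing from the registry.
    """
    f = bt.frame
    sums = f.groupby(["subject_id", "fluid", "day"])["volume_mL"].sum() if len(f) else {}
    specs = _fluid_specs(bt.config)
    rows = []
    for subj in bt.subjects:
        for fluid_label, spec in specs.items():
            for day in range(bt.n_days):
                key = (subj.subject_id, fluid_label, day)
                vol = float(sums.get(key, 0.0)) if len(f) else 0.0
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "fluid": fluid_label,
                        "day": day,
                        "metric": "intake_mL",
                        "value": vol,
                        "units": "mL",
                        "flag": "",
                    }
                )
                if spec.ethanol_fraction_vv > 0:
                    rows.append(
                        {
                            "subject_id": subj.subject_id,
                            "fluid": fluid_label,
                            "day": day,
                            "metric": "ethanol_intake_g_per_kg",
                            "value": ethanol_dose_g_per_kg(vol, spec, subj),
                            "units": "g/kg",
                            "flag": "",
                        }
                    )
    return pd.DataFrame(rows, columns=["subject_id", "fluid", "day", "metric",
                                       "value", "units", "flag"])


def preference(bt: BoutTable, per: str = "day") -> pd.DataFrame:
    """Ethanol preference, 100 x ethanol mL / (ethanol + water mL).

    ``per="day"`` gives one row per subject-day; ``per="overall"`` one
    row per subject over the whole window. A zero denominator yields a
    NaN value flagged ``undefined`` (no drinking is not 0% preference).
    """
    if per not in ("day", "overall"):
        raise ValueError(f"per must be 'day' or 'overall', got {per!r}")
    eth = set(_ethanol_labels(bt.config))
    wat = set(_water_labels(bt.config))
    f = bt.frame
    rows = []
    strata = [(s.subject_id, d) for s in bt.subjects
              for d in (range(bt.n_days) if per == "day" else [None])]
    for subject_id, day in strata:
        sel = f[f["subject_id"] == subject_id] if len(f) else f
        if day is not None and len(sel):
            sel = sel[sel["day"] == day]
        e = float(sel[sel["fluid"].isin(eth)]["volume_mL"].sum()) if len(sel) else 0.0
        w = float(sel[sel["fluid"].isin(wat)]["volume_mL"].sum()) if len(sel) else 0.0
        total = e + w
        rows.append(
            {
                "subject_id": subject_id,
                "day": day if day is not None else pd.NA,
                "metric": "preference_pct",
                "value": 100.0 * e / total if total > 0 else float("nan"),
                "units": "%",
                "flag": "" if total > 0 else "undefined",
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "day", "metric", "value",
                                       "units", "flag"])


def hourly_zt_profile(bt: BoutTable) -> pd.DataFrame:
    """Mean hourly intake by Zeitgeber time (24 bins per subject-fluid).

    Each bout's volume is assigned to the ZT-hour bin of its start;
    per-day binned volumes are averaged across the ``n_days`` window,
    so bin values x n_days sum back to the total volume.
    """
    f = bt.frame
    sums = f.groupby(["subject_id", "fluid", "zt_hour"])["volume_mL"].sum() if len(f) else {}
    rows = []
    for subj_id in bt.subject_ids:
        for fluid in bt.fluids:
            for h in range(24):
                vol = float(sums.get((subj_id, fluid, h), 0.0)) if len(f) else 0.0
                rows.append(
                    {
                        "subject_id": subj_id,
                        "fluid": fluid,
                        "zt_hour": h,
                        "metric": "mean_hourly_intake_mL",
                        "value": vol / bt.n_days,
                        "units": "mL",
                        "flag": "",
                    }
                )
    return pd.DataFrame(rows, columns=["subject_id", "fluid", "zt_hour", "metric",
                                       "value", "units", "flag"])


def phase_totals(bt: BoutTable) -> pd.DataFrame:
    """Light- vs dark-phase intake per subject-fluid-day, plus the mean
    across days. Light + dark equals the daily total exactly (every
    bout is in exactly one phase)."""
    f = bt.frame
    sums = f.groupby(["subject_id", "fluid", "day", "phase"])["volume_mL"].sum() \
        if len(f) else {}
    rows = []
    for subj_id in bt.subject_ids:
        for fluid in bt.fluids:
            for phase in ("light", "dark"):
                per_day = []
                for day in range(bt.n_days):
                    vol = float(sums.get((subj_id, fluid, day, phase), 0.0)) if len(f) else 0.0
                    per_day.append(vol)
                    rows.append(
                        {
                            "subject_id": subj_id,
                            "fluid": fluid,
                            "day": day,
                            "phase": phase,
                            "metric": "intake_mL",
                            "value": vol,
                            "units": "mL",
                            "flag": "",
                        }
                    )
                rows.append(
                    {
                        "subject_id": subj_id,
                        "fluid": fluid,
                        "day": pd.NA,
                        "phase": phase,
                        "metric": "mean_daily_intake_mL",
                        "value": float(np.mean(per_day)),
                        "units": "mL",
                        "flag": "",
                    }
                )
    return pd.DataFrame(rows, columns=["subject_id", "fluid", "day", "phase",
                                       "metric", "value", "units", "flag"])


def bout_stats(bt: BoutTable) -> pd.DataFrame:
    """Bout-level summary per subject x fluid over the analysis window.

    Metrics: mean and max bout volume (mL), volume per lick (total mL /
    total licks), bout frequency (bouts per day, zero-bout days
    included in the denominator), plus labelled lick-count variants of
    bout size and the raw bout count. Empty strata are flagged.
    """
    f = bt.frame
    rows = []
    for subj_id in bt.subject_ids:
        for fluid in bt.fluids:
            sel = f[(f["subject_id"] == subj_id) & (f["fluid"] == fluid)] if len(f) else f

            def add(metric: str, value: float, units: str, flag: str = "") -> None:
                rows.append({"subject_id": subj_id, "fluid": fluid, "metric": metric,
                             "value": value, "units": units, "flag": flag})

            n = len(sel)
            add("n_bouts", float(n), "bouts")
            add("bout_frequency_per_day", n / bt.n_days, "bouts/day")
            if n == 0:
                for metric, units in [
                    ("mean_bout_volume_mL", "mL"), ("max_bout_volume_mL", "mL"),
                    ("volume_per_lick_mL", "mL/lick"),
                    ("mean_bout_licks", "licks"), ("max_bout_licks", "licks"),
                ]:
                    add(metric, float("nan"), units, flag="empty")
                continue
            total_mL = float(sel["volume_mL"].sum())
            total_licks = int(sel["lick_count"].sum())
            add("mean_bout_volume_mL", float(sel["volume_mL"].mean()), "mL")
            add("max_bout_volume_mL", float(sel["volume_mL"].max()), "mL")
            if total_licks > 0:
                add("volume_per_lick_mL", total_mL / total_licks, "mL/lick")
            else:
                add("volume_per_lick_mL", float("nan"), "mL/lick", flag="undefined")
            add("mean_bout_licks", float(sel["lick_count"].mean()), "licks")
            add("max_bout_licks", float(sel["lick_count"].max()), "licks")
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def bout_range_volumes(bt: BoutTable, edges: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """Volume by bout lick-count range, raw (mL) and normalised.

    Each bout falls in exactly one half-open lick-count bin (the last
    bin is open-ended). Fractions are normalised within subject x
    fluid and sum to 1 whenever that fluid's total is positive. The
    first edge must not exceed the bout threshold, otherwise filtered
    bouts could fall below the histogram's support.
    """
    cfg_edges = list(bt.config.lick_bin_edges)
    edges = list(edges) if edges is not None else cfg_edges
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"edges must be strictly ascending: {edges}")
    labels = _bin_labels(edges)
    f = bt.frame
    if len(f):
        below = int((f["lick_count"] < edges[0]).sum())
        if below:
            raise ValueError(
                f"{below} bout(s) below the first lick-bin edge {edges[0]}; "
                "lower the first edge or raise min_licks_per_bout"
            )
        idx = np.digitize(f["lick_count"].to_numpy(), edges) - 1
        work = f.assign(lick_bin=[labels[i] for i in idx])
        sums = work.groupby(["subject_id", "fluid", "lick_bin"])["volume_mL"].sum()
    else:
        sums = {}
    rows = []
    for subj_id in bt.subject_ids:
        for fluid in bt.fluids:
            bin_vols = [float(sums.get((subj_id, fluid, lab), 0.0)) if len(f) else 0.0
                        for lab in labels]
            total = sum(bin_vols)
            for lab, vol in zip(labels, bin_vols):
                rows.append(
                    {
                        "subject_id": subj_id,
                        "fluid": fluid,
                        "lick_bin": lab,
                        "metric": "volume_mL",
                        "value": vol,
                        "units": "mL",
                        "flag": "",
                    }
                )
                rows.append(
                    {
                        "subject_id": subj_id,
                        "fluid": fluid,
                        "lick_bin": lab,
                        "metric": "fraction_of_fluid_total",
                        "value": vol / total if total > 0 else float("nan"),
                        "units": "fraction",
                        "flag": "" if total > 0 else "undefined",
                    }
                )
    return pd.DataFrame(rows, columns=["subject_id", "fluid", "lick_bin", "metric",
                                       "value", "units", "flag"])


def segment_lick_stream(
    session: SessionLog,
    bout_gap_s: Optional[float] = None,
) -> list[dict]:
    """Split the lick-level stream into bouts.

    Licks are grouped per (rfid, device); a gap longer than
    ``bout_gap_s`` (default: config) starts a new bout. Returns one
    dict per bout with keys rfid, device_id, times (np.ndarray of
    seconds since experiment start), in chronological order.
    """
    if session.licks is None:
        raise LickDataRequiredError("lick-level data required")
    gap = bout_gap_s if bout_gap_s is not None else session.config.bout_gap_s
    cfg = session.config
    streams: dict[tuple[str, str], list[float]] = {}
    for e in sorted(session.licks, key=lambda e: e.time):
        streams.setdefault((e.rfid, e.device_id), []).append(
            cfg.seconds_since_start(e.time)
        )
    bouts = []
    for (rfid, device_id), times in streams.items():
        arr = np.asarray(times)
        if len(arr) == 0:
            continue
        breaks = np.flatnonzero(np.diff(arr) > gap)
        for chunk in np.split(arr, breaks + 1):
            bouts.append({"rfid": rfid, "device_id": device_id, "times": chunk})
    bouts.sort(key=lambda b: b["times"][0])
    return bouts


def lick_microstructure(
    session: SessionLog,
    min_licks: Optional[int] = None,
) -> pd.DataFrame:
    """Extended microstructure from the lick-level log.

    Per subject x fluid: mean and median inter-lick interval (ILI,
    within bouts only — pairs spanning a bout boundary are excluded),
    mean inter-bout interval (IBI: end of one bout to start of the
    next for the same animal at the same device), mean bout duration
    (first-to-last lick) and mean within-bout lick rate,
    (n_licks - 1) / duration. Bouts below ``min_licks`` (default: the
    config threshold) are excluded, mirroring the bout-level filter.
    Single-lick bouts have zero duration and an undefined rate.

    Raises :class:`LickDataRequiredError` when the session has no lick
    stream.
    """
    if session.licks is None:
        raise LickDataRequiredError("lick-level data required")
    cfg = session.config
    if min_licks is None:
        min_licks = cfg.min_licks_per_bout
    segments = [b for b in segment_lick_stream(session) if len(b["times"]) >= min_licks]

    per_key: dict[tuple[str, str], dict[str, list]] = {}
    last_end: dict[tuple[str, str], float] = {}
    for b in segments:
        rfid = b["rfid"]
        if rfid not in session.subjects:
            continue
        subj_id = session.subjects[rfid].subject_id
        fluid = cfg.fluid_for_device(b["device_id"]).label
        key = (subj_id, fluid)
        acc = per_key.setdefault(key, {"ili": [], "ibi": [], "dur": [], "rate": []})
        times = b["times"]
        if len(times) > 1:
            acc["ili"].extend(np.diff(times).tolist())
            dur = float(times[-1] - times[0])
            acc["dur"].append(dur)
            if dur > 0:
                acc["rate"].append((len(times) - 1) / dur)
        else:
            acc["dur"].append(0.0)
        dev_key = (rfid, b["device_id"])
        if dev_key in last_end:
            acc["ibi"].append(float(times[0]) - last_end[dev_key])
        last_end[dev_key] = float(times[-1])

    rows = []
    for (subj_id, fluid), acc in sorted(per_key.items()):
        def add(metric: str, values: list, units: str) -> None:
            if values:
                rows.append({"subject_id": subj_id, "fluid": fluid, "metric": metric,
                             "value": float(np.mean(values)), "units": units, "flag": ""})
            else:
                rows.append({"subject_id": subj_id, "fluid": fluid, "metric": metric,
                             "value": float("nan"), "units": units, "flag": "undefined"})

        rows.append({"subject_id": subj_id, "fluid": fluid, "metric": "n_bouts",
                     "value": float(len(acc["dur"])), "units": "bouts", "flag": ""})
        add("ili_mean_s", acc["ili"], "s")
        if acc["ili"]:
            rows.append({"subject_id": subj_id, "fluid": fluid, "metric": "ili_median_s",
                         "value": float(np.median(acc["ili"])), "units": "s", "flag": ""})
        else:
            rows.append({"subject_id": subj_id, "fluid": fluid, "metric": "ili_median_s",
                         "value": float("nan"), "units": "s", "flag": "undefined"})
        add("ibi_mean_s", acc["ibi"], "s")
        add("bout_duration_mean_s", acc["dur"], "s")
        add("lick_rate_mean_hz", acc["rate"], "Hz")
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def wide_summary(bt: BoutTable) -> pd.DataFrame:
    """Wide per-subject summary: one row per subject x fluid with the
    headline metrics as columns (for quick inspection / the CLI's
    summary CSV)."""
    stats = bout_stats(bt)
    wide = stats.pivot_table(index=["subject_id", "fluid"], columns="metric",
                             values="value", aggfunc="first").reset_index()
    di = daily_intake(bt)
    mean_mL = (
        di[di["metric"] == "intake_mL"]
        .groupby(["subject_id", "fluid"])["value"].mean()
        .rename("mean_daily_intake_mL")
        .reset_index()
    )
    wide = wide.merge(mean_mL, on=["subject_id", "fluid"], how="left")
    gkg = di[di["metric"] == "ethanol_intake_g_per_kg"]
    if len(gkg):
        mean_gkg = (
            gkg.groupby(["subject_id", "fluid"])["value"].mean()
            .rename("mean_daily_ethanol_g_per_kg")
            .reset_index()
        )
        wide = wide.merge(mean_gkg, on=["subject_id", "fluid"], how="left")
    wide.columns.name = None
    return wide
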