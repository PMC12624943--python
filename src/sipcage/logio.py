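"""Reading, writing and validating drinking-log CSV files.

Two dialects are defined, both RFC-4180 CSV with ISO-8601 timestamps:

* **bout-level** (what the device logs to its SD card), header
  ``datetime,device_id,fluid,rfid,licks,volume_mL,duration_s`` —
  one row per drinking bout; ``duration_s`` may be empty in legacy logs;
* **lick-level** (updated firmware), header
  ``datetime,device_id,rfid`` — one row per lick.

Volumes are written with 3 decimals (microlitre precision, matching the
step-quantised pump). Unknown extra columns are preserved on read but
ignored. ``read_log`` never raises on bad rows: it collects row-level
errors (with line numbers) and warnings into a :class:`ReadReport` and
returns whatever parsed cleanly, sorted by timestamp.

The registry file is CSV ``subject_id,rfid,body_mass_g[,notes]``; the
experiment config is a flat ``key = value`` text file (see
:func:`read_config` for the key set).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import datetime, time
from pathlib import Path
from typing import Optional, Union

from .core import (
    BoutRecord,
    ConfigError,
    ExperimentConfig,
    FluidSpec,
    LickEvent,
    LightCycle,
    SessionLog,
    Subject,
    SubjectRegistry,
)

__all__ = [
    "BOUT_HEADER",
    "LICK_HEADER",
    "LogFormatError",
    "ReadReport",
    "ValidationReport",
    "read_log",
    "write_log",
    "validate_session",
    "read_registry",
    "write_registry",
    "read_config",
    "write_config",
]

BOUT_HEADER = ["datetime", "device_id", "fluid", "rfid", "licks", "volume_mL", "duration_s"]
LICK_HEADER = ["datetime", "device_id", "rfid"]

#: Within-bout lick rates above this (Hz) are physiologically implausible
#: for rats (rhythmic licking is ~6-7 Hz) and flagged by validation.
MAX_PLAUSIBLE_LICK_HZ = 50.0


class LogFormatError(ValueError):
    """File-level format problem (e.g. missing or renamed header column)."""


@dataclass
class ReadReport:
    """Row-level problems collected while reading a log file."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_rows_read: int = 0
    n_rows_kept: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors and not self.warnings


def _check_header(found: list[str], expected: list[str], path: Path) -> None:
    missing = [c for c in expected if c not in found]
    if missing:
        raise LogFormatError(
            f"{path}: missing required column(s) {missing}; header was {found}"
        )


def read_log(
    path: Union[str, Path],
    dialect: str = "bout",
    registry: Optional[SubjectRegistry] = None,
    config: Optional[ExperimentConfig] = None,
) -> tuple[SessionLog, ReadReport]:
    """Parse a bout- or lick-level CSV into a :class:`SessionLog`.

    Rows that violate record invariants (negative lick counts, bad
    timestamps...) are excluded and reported with their line number;
    rows whose RFID is absent from ``registry`` are kept but flagged
    with a warning. Out-of-order rows are sorted (stably) with a
    warning.
    """
    if dialect not in ("bout", "lick"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    report = ReadReport()
    expected = BOUT_HEADER if dialect == "bout" else LICK_HEADER

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise LogFormatError(f"{path}: empty file, no header")
        _check_header(list(reader.fieldnames), expected, path)

        bouts: list[BoutRecord] = []
        licks: list[LickEvent] = []
        for row in reader:
            lineno = reader.line_num
            report.n_rows_read += 1
            try:
                ts = datetime.fromisoformat(row["datetime"])
            except (ValueError, TypeError):
                report.errors.append(
                    f"line {lineno}: unparseable timestamp {row.get('datetime')!r}"
                )
                continue
            rfid = (row.get("rfid") or "").strip()
            if registry is not None and rfid not in registry:
                report.warnings.append(f"line {lineno}: unknown RFID {rfid!r}")
            if dialect == "lick":
                licks.append(LickEvent(time=ts, device_id=row["device_id"], rfid=rfid))
                report.n_rows_kept += 1
                continue
            try:
                lick_count = int(row["licks"])
                volume_mL = float(row["volume_mL"])
                dur_raw = (row.get("duration_s") or "").strip()
                duration_s = float(dur_raw) if dur_raw else None
            except (ValueError, TypeError) as exc:
                report.errors.append(f"line {lineno}: unparseable number ({exc})")
                continue
            try:
                bouts.append(
                    BoutRecord(
                        start_time=ts,
                        device_id=row["device_id"],
                        fluid_label=row["fluid"],
                        rfid=rfid,
                        lick_count=lick_count,
                        volume_mL=volume_mL,
                        duration_s=duration_s,
                    )
                )
            except ValueError as exc:
                report.errors.append(f"line {lineno}: invalid record ({exc})")
                continue
            report.n_rows_kept += 1

    events = bouts if dialect == "bout" else licks
    keys = [b.start_time for b in bouts] if dialect == "bout" else [e.time for e in licks]
    if any(b > a for a, b in zip(keys[1:], keys)):
        report.warnings.append("rows were out of time order; sorted on read")
        if dialect == "bout":
            bouts = sorted(bouts, key=lambda b: b.start_time)
        else:
            licks = sorted(licks, key=lambda e: e.time)

    if config is None:
        config = _fallback_config(bouts, licks)
    if registry is None:
        registry = SubjectRegistry([])
    session = SessionLog(
        bouts=bouts,
        licks=licks if dialect == "lick" else None,
        config=config,
        subjects=registry,
    )
    return session, report


def _fallback_config(bouts: list[BoutRecord], licks: list[LickEvent]) -> ExperimentConfig:
    """Minimal config when none is supplied: fluids inferred from rows,
    experiment start at the first event, default 12:12 cycle."""
    fluids: dict[str, FluidSpec] = {}
    for b in bouts:
        fluids.setdefault(b.device_id, FluidSpec(label=b.fluid_label))
    for e in licks:
        fluids.setdefault(e.device_id, FluidSpec(label=e.device_id))
    if not fluids:
        fluids = {"dev0": FluidSpec(label="unknown")}
    times = [b.start_time for b in bouts] + [e.time for e in licks]
    start = min(times) if times else datetime(2000, 1, 1)
    return ExperimentConfig(
        light_cycle=LightCycle(lights_off=time(8, 0)),
        fluids=fluids,
        experiment_start=start,
    )


def _fmt_ts(t: datetime) -> str:
    return t.isoformat()


def write_log(session: SessionLog, path: Union[str, Path], dialect: str = "bout") -> None:
    """Write a session to CSV. ``write_log`` then :func:`read_log` is the
    identity on records (timestamps at stored resolution, volumes and
    durations rounded to 3 decimals)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if dialect == "bout":
            writer.writerow(BOUT_HEADER)
            for b in session.bouts:
                writer.writerow(
                    [
                        _fmt_ts(b.start_time),
                        b.device_id,
                        b.fluid_label,
                        b.rfid,
                        b.lick_count,
                        f"{b.volume_mL:.3f}",
                        "" if b.duration_s is None else f"{b.duration_s:.3f}",
                    ]
                )
        elif dialect == "lick":
            writer.writerow(LICK_HEADER)
            for e in session.licks or []:
                writer.writerow([_fmt_ts(e.time), e.device_id, e.rfid])
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


@dataclass
class ValidationReport:
    """Result of :func:`validate_session`.

    ``overlaps`` are hard violations of single-occupancy (two bouts on
    the same device overlapping in time); the remaining lists are
    warnings about data quality.
    """

    overlaps: list[str] = field(default_factory=list)
    unknown_rfids: list[str] = field(default_factory=list)
    bad_fields: list[str] = field(default_factory=list)
    nonmonotonic: list[str] = field(default_factory=list)
    implausible_durations: list[str] = field(default_factory=list)

    @property
    def violations(self) -> list[str]:
        return self.overlaps + self.bad_fields

    @property
    def n_overlaps(self) -> int:
        return len(self.overlaps)

    @property
    def ok(self) -> bool:
        return not (
            self.overlaps
            or self.unknown_rfids
            or self.bad_fields
            or self.nonmonotonic
            or self.implausible_durations
        )

    def as_dict(self) -> dict:
        return {
            "overlaps": self.overlaps,
            "unknown_rfids": self.unknown_rfids,
            "bad_fields": self.bad_fields,
            "nonmonotonic": self.nonmonotonic,
            "implausible_durations": self.implausible_durations,
            "ok": self.ok,
        }


def validate_session(session: SessionLog) -> ValidationReport:
    """Check a session against the device's physical guarantees.

    The spout housing admits one animal at a time, so bouts on one
    device must never overlap; overlap is tested on the half-open
    interval [start, start + duration). Also reports unknown RFIDs,
    NaN/negative fields, out-of-order timestamps, and bouts whose
    lick count implies an implausible within-bout lick rate.
    """
    rep = ValidationReport()
    for i, b in enumerate(session.bouts):
        if math.isnan(b.volume_mL) or (b.duration_s is not None and math.isnan(b.duration_s)):
            rep.bad_fields.append(f"bout {i}: NaN field")
        if b.rfid not in session.subjects and len(session.subjects) > 0:
            rep.unknown_rfids.append(f"bout {i}: unknown RFID {b.rfid!r}")
        if b.duration_s is not None and b.lick_count >= 2:
            if b.duration_s == 0:
                rep.implausible_durations.append(
                    f"bout {i}: {b.lick_count} licks in zero duration"
                )
            elif (b.lick_count - 1) / b.duration_s > MAX_PLAUSIBLE_LICK_HZ:
                rep.implausible_durations.append(
                    f"bout {i}: implied lick rate "
                    f"{(b.lick_count - 1) / b.duration_s:.0f} Hz"
                )
    for i in range(1, len(session.bouts)):
        if session.bouts[i].start_time < session.bouts[i - 1].start_time:
            rep.nonmonotonic.append(f"bout {i}: starts before bout {i - 1}")

    by_device: dict[str, list[tuple[int, BoutRecord]]] = {}
    for i, b in enumerate(session.bouts):
        by_device.setdefault(b.device_id, []).append((i, b))
    for device_id, items in by_device.items():
        items = sorted(items, key=lambda ib: ib[1].start_time)
        # sweep with a running max end so a bout spanning several later
        # ones is caught; one violation per offending bout
        max_end = None
        max_idx = -1
        for j, b in items:
            if max_end is not None and b.start_time < max_end:
                rep.overlaps.append(
                    f"device {device_id}: bout {j} (start {b.start_time.isoformat()}) "
                    f"overlaps bout {max_idx}"
                )
            if max_end is None or b.end_time > max_end:
                max_end = b.end_time
                max_idx = j
    return rep


# ---------------------------------------------------------------------------
# registry and config files

def read_registry(path: Union[str, Path]) -> SubjectRegistry:
    """Read ``subject_id,rfid,body_mass_g[,notes]`` CSV."""
    path = Path(path)
    subjects = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(list(reader.fieldnames or []), ["subject_id", "rfid", "body_mass_g"], path)
        for row in reader:
            subjects.append(
                Subject(
                    subject_id=row["subject_id"],
                    rfid=row["rfid"],
                    body_mass_g=float(row["body_mass_g"]),
                    notes=row.get("notes", "") or "",
                )
            )
    return SubjectRegistry(subjects)


def write_registry(registry: SubjectRegistry, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "rfid", "body_mass_g", "notes"])
        for s in registry:
            writer.writerow([s.subject_id, s.rfid, f"{s.body_mass_g:g}", s.notes])


def read_behaviors(path: Union[str, Path]):
    """Read a behaviours CSV (one row per rat) into RatBehavior objects.

    Header: ``subject_id,bout_rate_dark,bout_rate_light,ethanol_choice_p,
    lick_count_logmean,lick_count_logsd,interlick_mean_s,interlick_shape``;
    all columns after ``subject_id`` fall back to the RatBehavior default
    when empty.
    """
    from .simulator import RatBehavior

    path = Path(path)
    out = []
    numeric = [
        "bout_rate_dark", "bout_rate_light", "ethanol_choice_p",
        "lick_count_logmean", "lick_count_logsd",
        "interlick_mean_s", "interlick_shape",
    ]
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(list(reader.fieldnames or []), ["subject_id"], path)
        for row in reader:
            kwargs = {}
            for key in numeric:
                raw = (row.get(key) or "").strip()
                if raw:
                    try:
                        kwargs[key] = float(raw)
                    except ValueError as exc:
                        raise ConfigError(
                            f"{path}: subject {row['subject_id']!r}: bad {key} ({exc})"
                        ) from exc
            out.append(RatBehavior(subject_id=row["subject_id"], **kwargs))
    return out


def write_behaviors(behaviors, path: Union[str, Path]) -> None:
    cols = [
        "subject_id", "bout_rate_dark", "bout_rate_light", "ethanol_choice_p",
        "lick_count_logmean", "lick_count_logsd", "interlick_mean_s",
        "interlick_shape",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for b in behaviors:
            writer.writerow([getattr(b, c) for c in cols])


def write_config(config: ExperimentConfig, path: Union[str, Path]) -> None:
    """Write the flat ``key = value`` config file (see :func:`read_config`)."""
    lines = [
        f"experiment_start = {config.experiment_start.isoformat()}",
        f"lights_off = {config.light_cycle.lights_off.isoformat()}",
        f"dark_hours = {config.light_cycle.dark_hours:g}",
        f"min_licks_per_bout = {config.min_licks_per_bout}",
        f"bout_gap_s = {config.bout_gap_s:g}",
        f"pump_uL_per_step = {config.pump_uL_per_step:g}",
        "lick_bin_edges = " + ",".join(str(e) for e in config.lick_bin_edges),
    ]
    for device_id, fluid in config.fluids.items():
        lines.append(f"device.{device_id}.fluid = {fluid.label}")
        lines.append(f"device.{device_id}.ethanol_fraction_vv = {fluid.ethanol_fraction_vv:g}")
        lines.append(f"device.{device_id}.density_g_per_mL = {fluid.density_g_per_mL:g}")
        lines.append(f"device.{device_id}.is_water = {str(fluid.is_water).lower()}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: Union[str, Path]) -> ExperimentConfig:
    """Read the flat key-value experiment config.

    Recognised keys: ``experiment_start`` (ISO-8601), ``lights_off``
    (HH:MM[:SS]), ``dark_hours``, ``min_licks_per_bout``, ``bout_gap_s``,
    ``pump_uL_per_step``, ``lick_bin_edges`` (comma-separated ints), and
    per-device ``device.<id>.fluid``, ``device.<id>.ethanol_fraction_vv``,
    ``device.<id>.density_g_per_mL``, ``device.<id>.is_water``.
    Lines starting with ``#`` and blank lines are ignored.
    """
    path = Path(path)
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()

    def pop(key: str, default: Optional[str] = None) -> str:
        if key in kv:
            return kv.pop(key)
        if default is None:
            raise ConfigError(f"{path}: missing required config key {key!r}")
        return default

    try:
        experiment_start = datetime.fromisoformat(pop("experiment_start"))
        lights_off = time.fromisoformat(pop("lights_off"))
        dark_hours = float(pop("dark_hours", "12"))
        min_licks = int(pop("min_licks_per_bout", "20"))
        bout_gap_s = float(pop("bout_gap_s", "10"))
        pump_uL = float(pop("pump_uL_per_step", "0.5"))
        edges_raw = pop("lick_bin_edges", ",".join(str(e) for e in
                                                   ExperimentConfig.__dataclass_fields__["lick_bin_edges"].default))
        edges = tuple(int(x) for x in edges_raw.split(",") if x.strip())
    except ValueError as exc:
        raise ConfigError(f"{path}: bad config value ({exc})") from exc

    devices: dict[str, dict[str, str]] = {}
    for key in list(kv):
        if key.startswith("device."):
            parts = key.split(".", 2)
            if len(parts) != 3:
                raise ConfigError(f"{path}: malformed device key {key!r}")
            devices.setdefault(parts[1], {})[parts[2]] = kv.pop(key)
    if kv:
        raise ConfigError(f"{path}: unknown config key(s) {sorted(kv)}")
    if not devices:
        raise ConfigError(f"{path}: no device.<id>.* entries")

    fluids = {}
    for device_id, props in devices.items():
        try:
            fluids[device_id] = FluidSpec(
                label=props.get("fluid", device_id),
                ethanol_fraction_vv=float(props.get("ethanol_fraction_vv", "0")),
                density_g_per_mL=float(props.get("density_g_per_mL", "0.789")),
                is_water=props.get("is_water", "false").lower() in ("true", "1", "yes"),
            )
        except ValueError as exc:
            raise ConfigError(f"{path}: device {device_id!r}: {exc}") from exc

    return ExperimentConfig(
        light_cycle=LightCycle(lights_off=lights_off, dark_hours=dark_hours),
        fluids=fluids,
        experiment_start=experiment_start,
        min_licks_per_bout=min_licks,
        bout_gap_s=bout_gap_s,
        lick_bin_edges=edges,
        pump_uL_per_step=pump_uL,
    )
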