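"""Domain model for RFID-gated home-cage drinking experiments.

This module holds the pure data types and time/unit conventions shared by
the simulator, the log reader/writer and the analysis layer:

* subjects identified by implanted RFID tags, with body mass for dose
  normalisation;
* fluids (ethanol solutions vs. water) with the parameters needed to
  convert a consumed volume into an ethanol dose in g/kg;
* the light/dark cycle and the Zeitgeber-time (ZT) convention used for
  circadian binning — ZT0 is the lights-ON instant, so in a 12:12 cycle
  the dark phase spans ZT12–24;
* the event records themselves: one row per drinking bout (what the
  device logs to its SD card) and, optionally, one row per lick.

Everything here is plain data with validation; serialisation lives in
:mod:`sipcage.logio` and all stochastic behaviour in
:mod:`sipcage.simulator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "ETHANOL_DENSITY_G_PER_ML",
    "Subject",
    "SubjectRegistry",
    "FluidSpec",
    "LightCycle",
    "BoutRecord",
    "LickEvent",
    "ExperimentConfig",
    "SessionLog",
    "ConfigError",
    "to_zeitgeber",
    "is_dark",
    "is_light",
    "ethanol_dose_g_per_kg",
]

#: Density of pure ethanol at room temperature, g/mL.  Used to convert a
#: consumed volume of ethanol solution into grams of ethanol.
ETHANOL_DENSITY_G_PER_ML = 0.789


class ConfigError(ValueError):
    """Raised for invalid experiment or behaviour configuration."""


@dataclass(frozen=True)
class Subject:
    """One animal: a short id, its RFID tag code, and its body mass.

    Body mass is a single value per subject for the analysis window;
    per-day mass trajectories are out of scope (pass an updated registry
    to re-analyse with different masses).
    """

    subject_id: str
    rfid: str
    body_mass_g: float
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.rfid:
            raise ConfigError(f"subject {self.subject_id!r}: empty RFID")
        if not self.body_mass_g > 0:
            raise ConfigError(
                f"subject {self.subject_id!r}: body mass must be positive, "
                f"got {self.body_mass_g!r}"
            )


class SubjectRegistry:
    """RFID -> :class:`Subject` mapping; RFIDs must be unique."""

    def __init__(self, subjects: Iterable[Subject]):
        self._by_rfid: dict[str, Subject] = {}
        for s in subjects:
            if s.rfid in self._by_rfid:
                raise ConfigError(f"duplicate RFID {s.rfid!r} in registry")
            self._by_rfid[s.rfid] = s

    def __contains__(self, rfid: str) -> bool:
        return rfid in self._by_rfid

    def __getitem__(self, rfid: str) -> Subject:
        return self._by_rfid[rfid]

    def __iter__(self) -> Iterator[Subject]:
        return iter(self._by_rfid.values())

    def __len__(self) -> int:
        return len(self._by_rfid)

    @property
    def subjects(self) -> list[Subject]:
        return list(self._by_rfid.values())

    def by_id(self, subject_id: str) -> Subject:
        for s in self._by_rfid.values():
            if s.subject_id == subject_id:
                return s
        raise KeyError(f"no subject with id {subject_id!r}")


@dataclass(frozen=True)
class FluidSpec:
    """A fluid offered at a spout.

    ``ethanol_fraction_vv`` is the v/v ethanol fraction (0.10 for a 10%
    solution); ``density_g_per_mL`` is the density of pure ethanol used
    in the dose conversion, not of the solution.
    """

    label: str
    ethanol_fraction_vv: float = 0.0
    density_g_per_mL: float = ETHANOL_DENSITY_G_PER_ML
    is_water: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.ethanol_fraction_vv <= 1.0:
            raise ConfigError(
                f"fluid {self.label!r}: ethanol fraction must be in [0, 1], "
                f"got {self.ethanol_fraction_vv!r}"
            )
        if self.is_water and self.ethanol_fraction_vv != 0.0:
            raise ConfigError(
                f"fluid {self.label!r}: water cannot contain ethanol"
            )


@dataclass(frozen=True)
class LightCycle:
    """Light/dark schedule anchored to a clock time of lights-off.

    ZT0 is lights-on; the dark phase occupies the last ``dark_hours`` of
    the Zeitgeber day, i.e. ZT in ``[24 - dark_hours, 24)``.
    """

    lights_off: time
    dark_hours: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 < self.dark_hours < 24.0:
            raise ConfigError(
                f"dark_hours must be in (0, 24), got {self.dark_hours!r}"
            )

    @property
    def lights_on_hour(self) -> float:
        """Clock hour (0-24, fractional) at which lights turn on."""
        off = self.lights_off.hour + self.lights_off.minute / 60 + self.lights_off.second / 3600
        return (off + self.dark_hours) % 24.0


def _clock_hours(t: datetime) -> float:
    return t.hour + t.minute / 60 + t.second / 3600 + t.microsecond / 3.6e9


def to_zeitgeber(t: datetime, lc: LightCycle) -> float:
    """Zeitgeber time in hours, in ``[0, 24)``, for timestamp ``t``.

    ZT0 is the lights-on instant; the function is 24 h periodic with
    slope 1 hour per hour.
    """
    return (_clock_hours(t) - lc.lights_on_hour) % 24.0


def is_dark(t: datetime, lc: LightCycle) -> bool:
    """True iff ``t`` falls in the dark phase, ``ZT in [24 - dark_hours, 24)``.

    Intervals are half-open: the lights-off instant is dark, the
    lights-on instant is light.
    """
    return to_zeitgeber(t, lc) >= 24.0 - lc.dark_hours


def is_light(t: datetime, lc: LightCycle) -> bool:
    return not is_dark(t, lc)


def ethanol_dose_g_per_kg(volume_mL: float, fluid: FluidSpec, subject: Subject) -> float:
    """Grams of ethanol per kilogram body mass for a consumed volume.

    dose = volume_mL x ethanol_fraction_vv x density_g_per_mL / (mass_g / 1000)

    Water (ethanol fraction 0) yields 0 by construction.
    """
    if not subject.body_mass_g > 0:
        raise ConfigError(f"subject {subject.subject_id!r}: nonpositive body mass")
    grams = volume_mL * fluid.ethanol_fraction_vv * fluid.density_g_per_mL
    return grams / (subject.body_mass_g / 1000.0)


@dataclass(frozen=True)
class BoutRecord:
    """One logged drinking bout (one CSV row in the device's bout log).

    ``volume_mL`` may be 0 with ``lick_count > 0``: an extinction probe,
    logged when the animal licks a spout whose pump access is denied.
    ``duration_s`` is first-to-last-lick time and may be absent in
    legacy logs.
    """

    start_time: datetime
    device_id: str
    fluid_label: str
    rfid: str
    lick_count: int
    volume_mL: float
    duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lick_count < 0:
            raise ValueError(f"lick_count must be >= 0, got {self.lick_count}")
        if self.volume_mL < 0:
            raise ValueError(f"volume_mL must be >= 0, got {self.volume_mL}")
        if self.duration_s is not None and self.duration_s < 0:
            raise ValueError(f"duration_s must be >= 0, got {self.duration_s}")

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=self.duration_s or 0.0)


@dataclass(frozen=True)
class LickEvent:
    """One lick timestamp from the lick-level log."""

    time: datetime
    device_id: str
    rfid: str


#: Default lick-count bin edges for bout-range histograms (8 half-open
#: bins: [20,45), [45,70), ..., [195, inf)).
DEFAULT_LICK_BIN_EDGES: tuple[int, ...] = (20, 45, 70, 95, 120, 145, 170, 195)


@dataclass(frozen=True)
class ExperimentConfig:
    """Experiment-level settings shared by simulation and analysis.

    Parameters
    ----------
    light_cycle : LightCycle
        Clock anchor for ZT conversion and light/dark classification.
    fluids : dict[str, FluidSpec]
        Mapping device_id -> fluid offered at that device.
    experiment_start : datetime
        t=0 for day indexing; days are 24 h windows from this instant,
        not calendar midnights.
    min_licks_per_bout : int
        Analysis-level bout threshold; drinking events with fewer licks
        are logged by the device but dropped before metric computation.
    bout_gap_s : float
        Inter-lick gap that delimits drinking events (firmware model and
        lick-stream segmentation).
    lick_bin_edges : tuple[int, ...]
        Ascending lick-count edges for bout-range histograms; the last
        bin is open-ended.
    pump_uL_per_step : float
        Pump calibration constant, microlitres per motor step.
    """

    light_cycle: LightCycle
    fluids: dict[str, FluidSpec]
    experiment_start: datetime
    min_licks_per_bout: int = 20
    bout_gap_s: float = 10.0
    lick_bin_edges: tuple[int, ...] = DEFAULT_LICK_BIN_EDGES
    pump_uL_per_step: float = 0.5

    def __post_init__(self) -> None:
        if self.min_licks_per_bout < 1:
            raise ConfigError("min_licks_per_bout must be >= 1")
        edges = tuple(self.lick_bin_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigError(f"lick_bin_edges must be strictly ascending: {edges}")
        if not self.pump_uL_per_step > 0:
            raise ConfigError("pump_uL_per_step must be positive")
        if self.bout_gap_s < 0:
            raise ConfigError("bout_gap_s must be >= 0")
        if not self.fluids:
            raise ConfigError("at least one device/fluid must be configured")
        object.__setattr__(self, "lick_bin_edges", edges)

    def fluid_for_device(self, device_id: str) -> FluidSpec:
        try:
            return self.fluids[device_id]
        except KeyError:
            raise ConfigError(f"no fluid configured for device {device_id!r}") from None

    @property
    def ethanol_devices(self) -> list[str]:
        return [d for d, f in self.fluids.items() if f.ethanol_fraction_vv > 0]

    @property
    def water_devices(self) -> list[str]:
        return [d for d, f in self.fluids.items() if f.ethanol_fraction_vv == 0]

    def seconds_since_start(self, t: datetime) -> float:
        return (t - self.experiment_start).total_seconds()

    def day_index(self, t: datetime) -> int:
        """24 h day window index from ``experiment_start`` (0-based)."""
        return int(self.seconds_since_start(t) // 86400.0)


@dataclass
class SessionLog:
    """An experiment session: bout records, optional lick records, config.

    ``bouts`` should be time-ordered; :func:`sipcage.logio.validate_session`
    reports out-of-order records, unknown RFIDs and per-device occupancy
    overlaps rather than raising here, so that imperfect real logs can be
    loaded and inspected.
    """

    bouts: list[BoutRecord]
    config: ExperimentConfig
    subjects: SubjectRegistry
    licks: Optional[list[LickEvent]] = None

    def sorted(self) -> "SessionLog":
        """Copy with bouts (and licks) stably sorted by timestamp."""
        bouts = sorted(self.bouts, key=lambda b: b.start_time)
        licks = None
        if self.licks is not None:
            licks = sorted(self.licks, key=lambda e: e.time)
        return SessionLog(bouts=bouts, config=self.config,
                          subjects=self.subjects, licks=licks)

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)
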