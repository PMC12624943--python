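"""Digital twin of an RFID-gated, pump-metered group drinking cage.

The simulator produces :class:`~sipcage.core.SessionLog` objects from a
stochastic behavioural model passed through a firmware model, together
with the ground truth needed for parameter-recovery tests.

Behavioural model (per rat)
---------------------------
Bout initiations follow an inhomogeneous Poisson process with one rate
during the dark phase and another during the light phase (generated by
thinning at the larger rate). After each accepted bout the process is
suspended for the bout's duration plus the inter-lick gap that delimits
drinking events, so a rat's own bouts can never overlap and consecutive
logged rows are genuinely separate events. Each bout chooses the
ethanol device with probability ``ethanol_choice_p`` (when a water
device exists); its lick count is lognormal rounded to an integer >= 1,
and inter-lick intervals are gamma distributed (default mean 0.15 s,
shape 20: the ~6-7 Hz rhythmic licking of rats, fairly regular).

Firmware model
--------------
The spout housing admits a single head, so a device serves one rat at a
time: a rat arriving at a busy spout retries after an exponential delay
(mean 30 s) up to 3 times, then gives up; deferrals and drops are
recorded in the ground truth. While the tag is present and the rat is
licking, the pump advances a fixed number of motor steps per lick;
delivered volume is steps x uL_per_step, perturbed by per-step
mechanical noise with coefficient of variation ``noise_cv`` and logged
at microlitre (3-decimal mL) resolution. Every drinking event is
logged regardless of lick count; the >= 20-lick bout criterion is an
analysis-time filter.

All randomness flows from a single seeded generator in a documented
order: first each rat's intended schedule (in the order the behaviours
are given: candidate gap, thinning accept, device choice, lick count,
inter-lick intervals per bout), then the event-queue draws (retry
delays and per-bout pump noise) in chronological processing order.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    BoutRecord,
    ConfigError,
    ExperimentConfig,
    LickEvent,
    SessionLog,
    SubjectRegistry,
    is_dark,
)

__all__ = [
    "RatBehavior",
    "PumpModel",
    "AccessRule",
    "ScheduledBout",
    "GroundTruth",
    "DispenseTestResult",
    "simulate_session",
    "simulate_dispense_test",
    "apply_access_policy",
]

MAX_RETRIES = 3
RETRY_MEAN_S = 30.0


@dataclass(frozen=True)
class RatBehavior:
    """Stochastic drinking phenotype of one rat.

    Rates are bouts/hour; ``ethanol_choice_p`` is the per-bout
    probability of heading to the ethanol spout; lick counts per bout
    are lognormal (parameters on the log scale) rounded to an integer
    >= 1; inter-lick intervals are gamma with the given mean and shape.
    """

    subject_id: str
    bout_rate_dark: float = 2.0
    bout_rate_light: float = 0.2
    ethanol_choice_p: float = 0.75
    lick_count_logmean: float = 4.0
    lick_count_logsd: float = 0.5
    interlick_mean_s: float = 0.15
    interlick_shape: float = 20.0

    def __post_init__(self) -> None:
        if self.bout_rate_dark < 0 or self.bout_rate_light < 0:
            raise ConfigError(f"{self.subject_id}: bout rates must be >= 0")
        if not 0.0 <= self.ethanol_choice_p <= 1.0:
            raise ConfigError(f"{self.subject_id}: ethanol_choice_p must be in [0, 1]")
        if not self.interlick_mean_s > 0:
            raise ConfigError(f"{self.subject_id}: interlick_mean_s must be > 0")
        if not self.interlick_shape > 0:
            raise ConfigError(f"{self.subject_id}: interlick_shape must be > 0")
        if self.lick_count_logsd < 0:
            raise ConfigError(f"{self.subject_id}: lick_count_logsd must be >= 0")


@dataclass(frozen=True)
class PumpModel:
    """Peristaltic-pump model: step calibration and mechanical noise.

    ``uL_per_step`` is the calibration constant (microlitres delivered
    per motor step); ``steps_per_lick`` is the firmware's stepping
    policy while the animal licks; ``noise_cv`` is the coefficient of
    variation of the actually delivered per-step volume.
    """

    uL_per_step: float = 0.5
    steps_per_lick: int = 5
    noise_cv: float = 0.01

    def __post_init__(self) -> None:
        if not self.uL_per_step > 0:
            raise ConfigError("uL_per_step must be > 0")
        if self.steps_per_lick < 1:
            raise ConfigError("steps_per_lick must be >= 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")


@dataclass(frozen=True)
class AccessRule:
    """Deny pump access for an (rfid, device, time-window) combination.

    ``None`` fields match anything; ``start_s``/``end_s`` are seconds
    since experiment start (half-open window). Denied bouts are logged
    with volume 0 and lick count preserved — the extinction-probe
    semantics of a lickometer that stays active while delivery is off.
    """

    rfid: Optional[str] = None
    device_id: Optional[str] = None
    start_s: Optional[float] = None
    end_s: Optional[float] = None

    def __post_init__(self) -> None:
        if (
            self.start_s is not None
            and self.end_s is not None
            and not self.end_s > self.start_s
        ):
            raise ConfigError(
                f"access rule window must have end > start, got "
                f"[{self.start_s}, {self.end_s})"
            )

    def matches(self, rfid: str, device_id: str, t_s: float) -> bool:
        if self.rfid is not None and rfid != self.rfid:
            return False
        if self.device_id is not None and device_id != self.device_id:
            return False
        if self.start_s is not None and t_s < self.start_s:
            return False
        if self.end_s is not None and t_s >= self.end_s:
            return False
        return True


def _denied(policy: Sequence[AccessRule], rfid: str, device_id: str, t_s: float) -> bool:
    return any(rule.matches(rfid, device_id, t_s) for rule in policy)


@dataclass
class ScheduledBout:
    """One intended bout with its eventual fate."""

    subject_id: str
    rfid: str
    device_id: str
    fluid_label: str
    intended_start_s: float
    lick_count: int
    lick_offsets_s: np.ndarray  # lick times relative to bout start
    duration_s: float
    final_start_s: Optional[float] = None
    n_retries: int = 0
    status: str = "pending"  # logged | dropped
    access_denied: bool = False
    steps: int = 0
    delivered_uL: float = 0.0  # before logging rounding


@dataclass
class GroundTruth:
    """Simulator-internal truth exported for parameter-recovery tests."""

    intended: list[ScheduledBout] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)

    @property
    def logged(self) -> list[ScheduledBout]:
        return [b for b in self.intended if b.status == "logged"]

    @property
    def dropped(self) -> list[ScheduledBout]:
        return [b for b in self.intended if b.status == "dropped"]

    def delivered_uL_by_device(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for b in self.logged:
            out[b.device_id] = out.get(b.device_id, 0.0) + b.delivered_uL
        return out

    def steps_by_device(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.logged:
            out[b.device_id] = out.get(b.device_id, 0) + b.steps
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.intended:
            rows.append(
                {
                    "subject_id": b.subject_id,
                    "rfid": b.rfid,
                    "device_id": b.device_id,
                    "fluid": b.fluid_label,
                    "intended_start_s": b.intended_start_s,
                    "final_start_s": b.final_start_s,
                    "lick_count": b.lick_count,
                    "duration_s": b.duration_s,
                    "n_retries": b.n_retries,
                    "status": b.status,
                    "access_denied": b.access_denied,
                    "steps": b.steps,
                    "delivered_uL": b.delivered_uL,
                }
            )
        cols = [
            "subject_id", "rfid", "device_id", "fluid", "intended_start_s",
            "final_start_s", "lick_count", "duration_s", "n_retries",
            "status", "access_denied", "steps", "delivered_uL",
        ]
        return pd.DataFrame(rows, columns=cols)


def _rng(seed: Optional[int], rng: Optional[np.random.Generator]) -> np.random.Generator:
    if rng is not None:
        return rng
    if seed is None:
        raise ConfigError("a seed (or an explicit Generator) is required for reproducibility")
    return np.random.default_rng(seed)


def _choose_device(config: ExperimentConfig, behavior: RatBehavior,
                   rng: np.random.Generator) -> str:
    eth = config.ethanol_devices
    wat = config.water_devices
    if eth and wat:
        if rng.random() < behavior.ethanol_choice_p:
            return eth[0]
        return wat[0]
    # single-fluid setups: everything goes to the only class present
    pool = eth or wat
    return pool[0]


def _intended_schedule(
    behavior: RatBehavior,
    registry: SubjectRegistry,
    config: ExperimentConfig,
    duration_h: float,
    rng: np.random.Generator,
) -> list[ScheduledBout]:
    """Thinned piecewise-constant Poisson schedule for one rat."""
    subject = registry.by_id(behavior.subject_id)
    lam_max = max(behavior.bout_rate_dark, behavior.bout_rate_light) / 3600.0
    total_s = duration_h * 3600.0
    out: list[ScheduledBout] = []
    if lam_max == 0.0 or total_s <= 0:
        return out
    t = 0.0
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t >= total_s:
            break
        now = config.experiment_start + timedelta(seconds=t)
        rate = behavior.bout_rate_dark if is_dark(now, config.light_cycle) \
            else behavior.bout_rate_light
        if rng.random() >= rate / (lam_max * 3600.0):
            continue
        device_id = _choose_device(config, behavior, rng)
        n_licks = max(1, int(round(rng.lognormal(behavior.lick_count_logmean,
                                                 behavior.lick_count_logsd))))
        if n_licks > 1:
            ilis = rng.gamma(
                behavior.interlick_shape,
                behavior.interlick_mean_s / behavior.interlick_shape,
                size=n_licks - 1,
            )
            offsets = np.concatenate([[0.0], np.cumsum(ilis)])
        else:
            offsets = np.zeros(1)
        duration = float(offsets[-1])
        out.append(
            ScheduledBout(
                subject_id=behavior.subject_id,
                rfid=subject.rfid,
                device_id=device_id,
                fluid_label=config.fluid_for_device(device_id).label,
                intended_start_s=t,
                lick_count=n_licks,
                lick_offsets_s=offsets,
                duration_s=duration,
            )
        )
        # dead time: the bout itself plus the gap that delimits events
        t += duration + config.bout_gap_s
    return out


def simulate_session(
    behaviors: Sequence[RatBehavior],
    config: ExperimentConfig,
    registry: SubjectRegistry,
    pump: Optional[PumpModel] = None,
    duration_h: float = 216.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    policy: Sequence[AccessRule] = (),
    emit_licks: bool = True,
) -> tuple[SessionLog, GroundTruth]:
    """Simulate a multi-rat session and return (log, ground truth).

    Parameters
    ----------
    behaviors : sequence of RatBehavior
        One phenotype per rat; each ``subject_id`` must exist in
        ``registry``.
    duration_h : float
        Session length in hours from ``config.experiment_start``
        (default 216 h = 9 days of continuous two-bottle access).
    seed : int
        Required unless an explicit ``rng`` is given; identical
        (parameters, seed) yield identical logs.
    policy : sequence of AccessRule
        Deny rules applied at delivery time (extinction-probe rows).

    The returned log is sorted, microlitre-rounded, and passes
    :func:`sipcage.logio.validate_session` with zero occupancy
    violations.
    """
    if not duration_h >= 0:
        raise ConfigError(f"duration_h must be >= 0, got {duration_h}")
    pump = pump or PumpModel()
    gen = _rng(seed, rng)

    truth = GroundTruth()
    heap: list[tuple[float, int, ScheduledBout]] = []
    counter = 0
    for behavior in behaviors:
        for bout in _intended_schedule(behavior, registry, config, duration_h, gen):
            truth.intended.append(bout)
            heapq.heappush(heap, (bout.intended_start_s, counter, bout))
            counter += 1

    busy_until: dict[str, float] = {}
    accepted: list[ScheduledBout] = []
    while heap:
        start, _, bout = heapq.heappop(heap)
        free_at = busy_until.get(bout.device_id, -math.inf)
        if start >= free_at:
            bout.final_start_s = start
            bout.status = "logged"
            # occupancy uses the logged (ms-rounded) duration so the
            # written file can never show a sub-ms phantom overlap
            bout.duration_s = round(bout.duration_s, 3)
            busy_until[bout.device_id] = start + bout.duration_s
            denied = _denied(policy, bout.rfid, bout.device_id, start)
            bout.access_denied = denied
            if denied:
                bout.steps = 0
                bout.delivered_uL = 0.0
            else:
                steps = bout.lick_count * pump.steps_per_lick
                bout.steps = steps
                if pump.noise_cv > 0:
                    noise = pump.uL_per_step * pump.noise_cv * math.sqrt(steps) \
                        * gen.standard_normal()
                else:
                    noise = 0.0
                bout.delivered_uL = max(0.0, steps * pump.uL_per_step + noise)
            accepted.append(bout)
        elif bout.n_retries < MAX_RETRIES:
            delay = gen.exponential(RETRY_MEAN_S)
            bout.n_retries += 1
            truth.conflicts.append(
                f"{bout.subject_id}@{bout.device_id}: busy at t={start:.1f}s, "
                f"retry {bout.n_retries} after {delay:.1f}s"
            )
            counter += 1
            heapq.heappush(heap, (start + delay, counter, bout))
        else:
            bout.status = "dropped"
            truth.conflicts.append(
                f"{bout.subject_id}@{bout.device_id}: dropped after "
                f"{MAX_RETRIES} retries at t={start:.1f}s"
            )

    accepted.sort(key=lambda b: (b.final_start_s, b.device_id))
    bouts: list[BoutRecord] = []
    licks: list[LickEvent] = []
    for b in accepted:
        start_time = config.experiment_start + timedelta(seconds=b.final_start_s)
        bouts.append(
            BoutRecord(
                start_time=start_time,
                device_id=b.device_id,
                fluid_label=b.fluid_label,
                rfid=b.rfid,
                lick_count=b.lick_count,
                volume_mL=round(b.delivered_uL / 1000.0, 3),
                duration_s=round(b.duration_s, 3),
            )
        )
        if emit_licks:
            for off in b.lick_offsets_s:
                licks.append(
                    LickEvent(
                        time=start_time + timedelta(seconds=float(off)),
                        device_id=b.device_id,
                        rfid=b.rfid,
                    )
                )
    licks.sort(key=lambda e: e.time)
    session = SessionLog(
        bouts=bouts,
        config=config,
        subjects=registry,
        licks=licks if emit_licks else None,
    )
    return session, truth


def apply_access_policy(session: SessionLog, policy: Sequence[AccessRule]) -> SessionLog:
    """Re-gate an existing session: bouts matched by a deny rule keep
    their lick counts but have their volume zeroed (extinction probes).

    An empty policy is the identity.
    """
    if not policy:
        return session
    bouts = []
    for b in session.bouts:
        t_s = session.config.seconds_since_start(b.start_time)
        if _denied(policy, b.rfid, b.device_id, t_s):
            bouts.append(
                BoutRecord(
                    start_time=b.start_time,
                    device_id=b.device_id,
                    fluid_label=b.fluid_label,
                    rfid=b.rfid,
                    lick_count=b.lick_count,
                    volume_mL=0.0,
                    duration_s=b.duration_s,
                )
            )
        else:
            bouts.append(b)
    return SessionLog(bouts=bouts, config=session.config,
                      subjects=session.subjects, licks=session.licks)


@dataclass
class DispenseTestResult:
    """Per-trial volumes and errors from the bench dispense protocol."""

    trials: pd.DataFrame  # trial, steps, metered_mL, delivered_mL, error_mL, pct_error
    target_mL: float

    @property
    def mean_pct_error(self) -> float:
        return float(self.trials["pct_error"].mean())

    @property
    def mean_abs_pct_error(self) -> float:
        return float(self.trials["pct_error"].abs().mean())

    def ci95_pct_error(self) -> tuple[float, float]:
        """Two-sided 95% t-interval for the mean signed % error."""
        x = self.trials["pct_error"].to_numpy()
        n = len(x)
        if n < 2:
            return (float(x.mean()), float(x.mean()))
        sem = x.std(ddof=1) / math.sqrt(n)
        if sem == 0:
            return (float(x.mean()), float(x.mean()))
        lo, hi = stats.t.interval(0.95, n - 1, loc=x.mean(), scale=sem)
        return float(lo), float(hi)

    def summary(self) -> dict:
        lo, hi = self.ci95_pct_error()
        return {
            "n_trials": int(len(self.trials)),
            "target_mL": self.target_mL,
            "mean_pct_error": self.mean_pct_error,
            "mean_abs_pct_error": self.mean_abs_pct_error,
            "ci95_low_pct": lo,
            "ci95_high_pct": hi,
        }


def simulate_dispense_test(
    pump: PumpModel,
    n_repeats: int = 20,
    target_mL: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> DispenseTestResult:
    """Bench-style dispense accuracy protocol.

    Each trial advances the pump until the *metered* cumulative volume
    (steps x uL_per_step, what a display would show) first reaches the
    next multiple of ``target_mL``, without resetting between trials;
    the *delivered* volume additionally carries per-step mechanical
    noise. Returns per-trial signed and absolute % errors of delivered
    vs. target, as measured by weighing each dispensed aliquot.
    """
    if n_repeats < 1:
        raise ConfigError("n_repeats must be >= 1")
    if not target_mL > 0:
        raise ConfigError("target_mL must be > 0")
    gen = _rng(seed, rng)
    uL = pump.uL_per_step
    rows = []
    cum_steps = 0
    for trial in range(1, n_repeats + 1):
        needed = math.ceil(round(trial * target_mL * 1000.0 / uL, 9))
        steps = needed - cum_steps
        cum_steps = needed
        metered_mL = steps * uL / 1000.0
        if pump.noise_cv > 0:
            noise_uL = uL * pump.noise_cv * math.sqrt(steps) * gen.standard_normal()
        else:
            noise_uL = 0.0
        delivered_mL = steps * uL / 1000.0 + noise_uL / 1000.0
        error_mL = delivered_mL - target_mL
        rows.append(
            {
                "trial": trial,
                "steps": steps,
                "metered_mL": metered_mL,
                "delivered_mL": delivered_mL,
                "error_mL": error_mL,
                "pct_error": 100.0 * error_mL / target_mL,
            }
        )
    return DispenseTestResult(trials=pd.DataFrame(rows), target_mL=target_mL)
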