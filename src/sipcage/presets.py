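"""Reference study conditions: 4 group-housed female rats, two-bottle
choice (10% v/v ethanol vs. tap water), 24 h access for nine days, 12:12
light-dark cycle with lights off at 08:00.

These presets are the default scenario for the CLI, the acceptance
script and the examples; every number is configurable. Behavioural
parameters not fixed by the experimental design (bout rates, lick-count
distribution, licking rhythm, individual preferences) are set to values
typical of rat drinking behaviour: nearly all drinking in the dark
phase (dark:light bout-rate ratio 10), ~6-7 Hz rhythmic licking,
median ~55 licks per bout, and clear individual differences in ethanol
preference including one near-indifferent animal.
"""

from __future__ import annotations

from datetime import datetime, time

from .core import (
    ExperimentConfig,
    FluidSpec,
    LightCycle,
    Subject,
    SubjectRegistry,
)
from .simulator import PumpModel, RatBehavior

__all__ = [
    "default_config",
    "default_registry",
    "default_behaviors",
    "default_pump",
    "DEFAULT_DURATION_H",
]

#: Nine days of continuous access, in hours.
DEFAULT_DURATION_H = 9 * 24.0


def default_config(experiment_start: datetime | None = None) -> ExperimentConfig:
    """Two devices (10% v/v ethanol + water), 12:12 with lights off at
    08:00; the session starts at lights-on (ZT0) of day 0."""
    if experiment_start is None:
        experiment_start = datetime(2024, 1, 1, 20, 0, 0)
    return ExperimentConfig(
        light_cycle=LightCycle(lights_off=time(8, 0), dark_hours=12.0),
        fluids={
            "etoh": FluidSpec(label="ethanol10", ethanol_fraction_vv=0.10),
            "water": FluidSpec(label="water", is_water=True),
        },
        experiment_start=experiment_start,
    )


def default_registry() -> SubjectRegistry:
    """Four adult female rats, ~300 g."""
    return SubjectRegistry(
        [
            Subject("rat1", "RFID-0001", 290.0),
            Subject("rat2", "RFID-0002", 305.0),
            Subject("rat3", "RFID-0003", 312.0),
            Subject("rat4", "RFID-0004", 298.0),
        ]
    )


def default_behaviors() -> list[RatBehavior]:
    """Per-rat phenotypes with individual preference differences; one
    animal is nearly indifferent between ethanol and water."""
    common = dict(
        bout_rate_dark=2.0,
        bout_rate_light=0.2,
        lick_count_logmean=4.0,
        lick_count_logsd=0.5,
        interlick_mean_s=0.15,
        interlick_shape=20.0,
    )
    return [
        RatBehavior(subject_id="rat1", ethanol_choice_p=0.90, **common),
        RatBehavior(subject_id="rat2", ethanol_choice_p=0.80, **common),
        RatBehavior(subject_id="rat3", ethanol_choice_p=0.72, **common),
        RatBehavior(subject_id="rat4", ethanol_choice_p=0.52, **common),
    ]


def default_pump() -> PumpModel:
    """0.5 uL/step calibration, 5 steps per lick, 1% per-step CV."""
    return PumpModel(uL_per_step=0.5, steps_per_lick=5, noise_cv=0.01)
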