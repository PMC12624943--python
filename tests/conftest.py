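"""Shared fixtures: the reference two-bottle scenario and small
hand-built sessions."""

from datetime import datetime, time, timedelta

import numpy as np
import pytest

from sipcage.core import (
    BoutRecord,
    ExperimentConfig,
    FluidSpec,
    LightCycle,
    SessionLog,
    Subject,
    SubjectRegistry,
)
from sipcage import presets, simulator


@pytest.fixture
def config():
    return presets.default_config()


@pytest.fixture
def registry():
    return presets.default_registry()


@pytest.fixture
def behaviors():
    return presets.default_behaviors()


@pytest.fixture
def light_cycle(config):
    return config.light_cycle


@pytest.fixture
def one_day_session(config, registry, behaviors):
    """One simulated day, with lick-level stream."""
    session, truth = simulator.simulate_session(
        behaviors, config, registry, duration_h=24.0, seed=11)
    return session, truth


@pytest.fixture
def nine_day_session(config, registry, behaviors):
    """The full 9-day reference scenario (no lick stream: fast)."""
    session, truth = simulator.simulate_session(
        behaviors, config, registry, duration_h=216.0, seed=12,
        emit_licks=False)
    return session, truth


def make_bout(config, t_s, device="etoh", licks=30, volume=0.1, duration=5.0,
              rfid="RFID-0001"):
    """A bout at ``t_s`` seconds after experiment start."""
    fluid = config.fluid_for_device(device)
    return BoutRecord(
        start_time=config.experiment_start + timedelta(seconds=t_s),
        device_id=device,
        fluid_label=fluid.label,
        rfid=rfid,
        lick_count=licks,
        volume_mL=volume,
        duration_s=duration,
    )


@pytest.fixture
def hand_session(config, registry):
    """Three clean bouts, one per hour, single rat on the ethanol spout."""
    bouts = [make_bout(config, 3600.0 * i, licks=30 + i,
                       volume=round(0.1 + 0.01 * i, 3))
             for i in range(3)]
    return SessionLog(bouts=bouts, config=config, subjects=registry)


def random_session(seed, config, registry, duration_h=12.0, emit_licks=False):
    """A randomised simulated session with randomised phenotypes."""
    rng = np.random.default_rng(seed)
    behaviors = []
    for s in registry:
        behaviors.append(
            simulator.RatBehavior(
                subject_id=s.subject_id,
                bout_rate_dark=float(rng.uniform(0.5, 4.0)),
                bout_rate_light=float(rng.uniform(0.0, 1.0)),
                ethanol_choice_p=float(rng.uniform(0.0, 1.0)),
                lick_count_logmean=float(rng.uniform(3.0, 4.5)),
                lick_count_logsd=float(rng.uniform(0.1, 0.8)),
                interlick_mean_s=float(rng.uniform(0.12, 0.2)),
                interlick_shape=float(rng.uniform(5.0, 30.0)),
            )
        )
    pump = simulator.PumpModel(
        uL_per_step=float(rng.uniform(0.2, 1.0)),
        steps_per_lick=int(rng.integers(1, 8)),
        noise_cv=float(rng.uniform(0.0, 0.05)),
    )
    return simulator.simulate_session(
        behaviors, config, registry, pump=pump, duration_h=duration_h,
        seed=int(rng.integers(0, 2**31 - 1)), emit_licks=emit_licks)
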