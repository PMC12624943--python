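"""Metric tables: filtering, intake, preference, circadian profiles,
bout statistics and lick-level microstructure."""

import math
from datetime import timedelta

import numpy as np
import pandas as pd
import pytest

from sipcage import microstructure as ms
from sipcage import simulator
from sipcage.core import LickEvent, SessionLog
from sipcage.simulator import RatBehavior
from .conftest import make_bout, random_session


def session_of(config, registry, specs):
    """Build a session from (t_s, device, licks, volume) tuples."""
    bouts = [make_bout(config, t, device=d, licks=n, volume=v, duration=dur)
             for (t, d, n, v, dur) in specs]
    return SessionLog(bouts=sorted(bouts, key=lambda b: b.start_time),
                      config=config, subjects=registry)


def value_of(table, metric, **keys):
    sel = table[table["metric"] == metric]
    for col, val in keys.items():
        sel = sel[sel[col] == val]
    assert len(sel) == 1, f"{metric} {keys}: {len(sel)} rows"
    return sel.iloc[0]


class TestFilterBouts:
    def test_threshold_at_default_20(self, config, registry):
        session = session_of(config, registry, [
            (0.0, "etoh", 25, 0.1, 4.0), (100.0, "etoh", 19, 0.1, 3.0),
            (200.0, "etoh", 20, 0.1, 3.0), (300.0, "etoh", 3, 0.0, 0.5),
        ])
        bt = ms.filter_bouts(session)
        assert sorted(bt.frame["lick_count"]) == [20, 25]
        assert bt.n_removed_below_threshold == 2

    def test_min_licks_one_is_identity(self, config, registry):
        session = session_of(config, registry, [
            (0.0, "etoh", 1, 0.01, 0.0), (50.0, "water", 7, 0.02, 1.0)])
        bt = ms.filter_bouts(session, min_licks=1)
        assert len(bt.frame) == 2
        assert bt.n_removed_below_threshold == 0

    def test_kept_count_matches_linear_scan(self, config, registry):
        rng = np.random.default_rng(42)
        licks = rng.integers(0, 120, size=1000)
        specs = [(float(i * 20), "etoh", int(n), 0.01, 1.0)
                 for i, n in enumerate(licks)]
        session = session_of(config, registry, specs)
        bt = ms.filter_bouts(session)
        assert len(bt.frame) == sum(1 for n in licks if n >= 20)

    def test_annotations(self, config, registry):
        # 13 h after a lights-on start -> ZT13, dark, day 0
        session = session_of(config, registry, [(13 * 3600.0, "etoh", 30, 0.1, 4.0)])
        row = ms.filter_bouts(session).frame.iloc[0]
        assert row["zt_hour"] == 13
        assert row["phase"] == "dark"
        assert row["day"] == 0
        assert row["lick_bin"] == "20-44"


class TestDailyIntake:
    def test_single_bout_dose(self, config, registry):
        session = session_of(config, registry, [(0.0, "etoh", 30, 12.0, 5.0)])
        di = ms.daily_intake(ms.filter_bouts(session))
        # rat1 is 290 g: 12 x 0.10 x 0.789 / 0.290
        row = value_of(di, "ethanol_intake_g_per_kg", subject_id="rat1", day=0)
        assert row["value"] == pytest.approx(12.0 * 0.10 * 0.789 / 0.290)

    def test_days_without_bouts_enumerated_as_zero(self, config, registry):
        session = session_of(config, registry, [(0.0, "etoh", 30, 1.0, 5.0)])
        di = ms.daily_intake(ms.filter_bouts(session, n_days=3))
        zeros = di[(di["metric"] == "intake_mL") & (di["day"] > 0)]
        assert len(zeros) == 2 * 2 * len(registry)  # 2 days x 2 fluids x 4 rats
        assert (zeros["value"] == 0.0).all()

    def test_additive_over_bout_splitting(self, config, registry):
        one = session_of(config, registry, [(0.0, "etoh", 60, 3.0, 5.0)])
        split = session_of(config, registry, [
            (0.0, "etoh", 20, 1.0, 5.0), (100.0, "etoh", 20, 1.0, 5.0),
            (200.0, "etoh", 20, 1.0, 5.0)])
        v1 = value_of(ms.daily_intake(ms.filter_bouts(one)), "intake_mL",
                      subject_id="rat1", fluid="ethanol10", day=0)["value"]
        v2 = value_of(ms.daily_intake(ms.filter_bouts(split)), "intake_mL",
                      subject_id="rat1", fluid="ethanol10", day=0)["value"]
        assert v1 == pytest.approx(v2)

    def test_dose_rows_only_for_registered_subjects(self, config, registry):
        """Dose needs a body mass: subjects absent from the registry are
        dropped by the filter, never silently given a mass."""
        session = session_of(config, registry, [(0.0, "etoh", 30, 1.0, 5.0)])
        bt = ms.filter_bouts(session)
        from sipcage.core import SubjectRegistry
        bt.subjects = SubjectRegistry([])  # no masses known at all
        di = ms.daily_intake(bt)
        assert len(di) == 0


class TestPreference:
    def test_three_to_one(self, config, registry):
        session = session_of(config, registry, [
            (0.0, "etoh", 30, 3.0, 5.0), (100.0, "water", 30, 1.0, 5.0)])
        pref = ms.preference(ms.filter_bouts(session), per="overall")
        assert value_of(pref, "preference_pct",
                        subject_id="rat1")["value"] == pytest.approx(75.0)

    def test_equal_volumes_give_fifty(self, config, registry):
        session = session_of(config, registry, [
            (0.0, "etoh", 30, 2.0, 5.0), (100.0, "water", 30, 2.0, 5.0)])
        pref = ms.preference(ms.filter_bouts(session), per="overall")
        assert value_of(pref, "preference_pct",
                        subject_id="rat1")["value"] == pytest.approx(50.0)

    def test_zero_total_flagged_undefined(self, config, registry):
        session = session_of(config, registry, [(0.0, "etoh", 30, 1.0, 5.0)])
        pref = ms.preference(ms.filter_bouts(session), per="overall")
        row = value_of(pref, "preference_pct", subject_id="rat2")
        assert math.isnan(row["value"])
        assert row["flag"] == "undefined"


class TestCircadianTables:
    def test_single_clock_time_fills_single_bin(self, config, registry):
        session = session_of(config, registry, [
            (5 * 3600.0, "etoh", 30, 1.0, 5.0),
            (86400.0 + 5 * 3600.0, "etoh", 30, 2.0, 5.0)])
        prof = ms.hourly_zt_profile(ms.filter_bouts(session, n_days=2))
        mine = prof[(prof["subject_id"] == "rat1") & (prof["fluid"] == "ethanol10")]
        nonzero = mine[mine["value"] > 0]
        assert list(nonzero["zt_hour"]) == [5]
        assert nonzero.iloc[0]["value"] == pytest.approx(1.5)  # (1+2)/2 days

    def test_hourly_bins_conserve_total(self, nine_day_session):
        session, _ = nine_day_session
        bt = ms.filter_bouts(session, n_days=9)
        prof = ms.hourly_zt_profile(bt)
        totals = prof.groupby(["subject_id", "fluid"])["value"].sum() * bt.n_days
        direct = bt.frame.groupby(["subject_id", "fluid"])["volume_mL"].sum()
        for key, total in direct.items():
            assert totals[key] == pytest.approx(total, abs=1e-9)

    def test_phase_partition(self, nine_day_session):
        session, _ = nine_day_session
        bt = ms.filter_bouts(session, n_days=9)
        pt = ms.phase_totals(bt)
        per_day = pt[pt["metric"] == "intake_mL"]
        sums = per_day.groupby(["subject_id", "fluid", "day"])["value"].sum()
        di = ms.daily_intake(bt)
        daily = di[di["metric"] == "intake_mL"].set_index(
            ["subject_id", "fluid", "day"])["value"]
        for key, total in daily.items():
            assert sums[key] == pytest.approx(total, abs=1e-9)

    def test_light_silent_rats_put_everything_in_dark(self, config, registry):
        behaviors = [RatBehavior(subject_id=s.subject_id, bout_rate_dark=2.0,
                                 bout_rate_light=0.0) for s in registry]
        session, _ = simulator.simulate_session(
            behaviors, config, registry, duration_h=72.0, seed=31,
            emit_licks=False)
        pt = ms.phase_totals(ms.filter_bouts(session, n_days=3))
        light = pt[(pt["metric"] == "intake_mL") & (pt["phase"] == "light")]
        assert (light["value"] == 0.0).all()


class TestBoutStats:
    def test_hand_arithmetic(self, config, registry):
        session = session_of(config, registry, [
            (0.0, "etoh", 40, 0.2, 5.0), (100.0, "etoh", 60, 0.4, 8.0)])
        stats = ms.bout_stats(ms.filter_bouts(session, n_days=2))
        get = lambda m: value_of(stats, m, subject_id="rat1",
                                 fluid="ethanol10")["value"]
        assert get("mean_bout_volume_mL") == pytest.approx(0.3)
        assert get("max_bout_volume_mL") == pytest.approx(0.4)
        assert get("volume_per_lick_mL") == pytest.approx(0.006)
        assert get("bout_frequency_per_day") == pytest.approx(1.0)

    def test_single_bout_mean_equals_max(self, config, registry):
        session = session_of(config, registry, [(0.0, "etoh", 40, 0.25, 5.0)])
        stats = ms.bout_stats(ms.filter_bouts(session))
        mean = value_of(stats, "mean_bout_volume_mL", subject_id="rat1",
                        fluid="ethanol10")["value"]
        mx = value_of(stats, "max_bout_volume_mL", subject_id="rat1",
                      fluid="ethanol10")["value"]
        assert mean == mx

    def test_homogeneity_in_volume(self, config, registry):
        base = [(0.0, "etoh", 40, 0.2, 5.0), (100.0, "etoh", 60, 0.4, 8.0)]
        doubled = [(t, d, n, 2 * v, dur) for (t, d, n, v, dur) in base]
        s1 = ms.bout_stats(ms.filter_bouts(session_of(config, registry, base)))
        s2 = ms.bout_stats(ms.filter_bouts(session_of(config, registry, doubled)))
        for metric, factor in [("mean_bout_volume_mL", 2.0),
                               ("max_bout_volume_mL", 2.0),
                               ("volume_per_lick_mL", 2.0),
                               ("bout_frequency_per_day", 1.0)]:
            v1 = value_of(s1, metric, subject_id="rat1", fluid="ethanol10")["value"]
            v2 = value_of(s2, metric, subject_id="rat1", fluid="ethanol10")["value"]
            assert v2 == pytest.approx(factor * v1)

    def test_empty_stratum_flagged(self, config, registry):
        session = session_of(config, registry, [(0.0, "etoh", 40, 0.2, 5.0)])
        stats = ms.bout_stats(ms.filter_bouts(session))
        row = value_of(stats, "mean_bout_volume_mL", subject_id="rat2",
                       fluid="water")
        assert math.isnan(row["value"])
        assert row["flag"] == "empty"


class TestBoutRanges:
    def test_single_bout_fraction_is_one(self, config, registry):
        session = session_of(config, registry, [(0.0, "etoh", 50, 0.2, 5.0)])
        br = ms.bout_range_volumes(ms.filter_bouts(session))
        row = value_of(br, "fraction_of_fluid_total", subject_id="rat1",
                       fluid="ethanol10", lick_bin="45-69")
        assert row["value"] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, nine_day_session):
        session, _ = nine_day_session
        br = ms.bout_range_volumes(ms.filter_bouts(session, n_days=9))
        fr = br[(br["metric"] == "fraction_of_fluid_total") & (br["flag"] == "")]
        sums = fr.groupby(["subject_id", "fluid"])["value"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_binning_matches_linear_scan(self, config, registry):
        rng = np.random.default_rng(7)
        specs = [(float(i * 30), "etoh", int(rng.integers(20, 260)),
                  float(rng.uniform(0.01, 0.5)), 3.0) for i in range(300)]
        session = session_of(config, registry, specs)
        bt = ms.filter_bouts(session)
        br = ms.bout_range_volumes(bt)
        edges = list(config.lick_bin_edges) + [10**9]
        for k, (lo, hi) in enumerate(zip(edges, edges[1:])):
            expected = sum(v for (_, _, n, v, _) in specs if lo <= n < hi)
            label = f"{lo}-{hi - 1}" if hi != 10**9 else f"{lo}+"
            got = br[(br["metric"] == "volume_mL") & (br["lick_bin"] == label)
                     ]["value"].sum()
            assert got == pytest.approx(expected, abs=1e-9)

    def test_bout_below_first_edge_rejected(self, config, registry):
        session = session_of(config, registry, [(0.0, "etoh", 10, 0.1, 2.0)])
        bt = ms.filter_bouts(session, min_licks=1)
        with pytest.raises(ValueError, match="below the first"):
            ms.bout_range_volumes(bt)


def lick_session(config, registry, times_by_bout, device="etoh",
                 rfid="RFID-0001"):
    licks = []
    for times in times_by_bout:
        for t in times:
            licks.append(LickEvent(
                time=config.experiment_start + timedelta(seconds=t),
                device_id=device, rfid=rfid))
    return SessionLog(bouts=[], config=config, subjects=registry,
                      licks=sorted(licks, key=lambda e: e.time))


class TestLickMicrostructure:
    def test_three_lick_closed_form(self, config, registry):
        session = lick_session(config, registry, [[0.0, 0.15, 0.30]])
        table = ms.lick_microstructure(session, min_licks=1)
        get = lambda m: value_of(table, m, subject_id="rat1",
                                 fluid="ethanol10")["value"]
        assert get("ili_mean_s") == pytest.approx(0.15)
        assert get("bout_duration_mean_s") == pytest.approx(0.30)
        assert get("lick_rate_mean_hz") == pytest.approx(2 / 0.30)

    def test_one_lick_bout_degenerate(self, config, registry):
        session = lick_session(config, registry, [[5.0]])
        table = ms.lick_microstructure(session, min_licks=1)
        row = value_of(table, "bout_duration_mean_s", subject_id="rat1",
                       fluid="ethanol10")
        assert row["value"] == 0.0
        rate = value_of(table, "lick_rate_mean_hz", subject_id="rat1",
                        fluid="ethanol10")
        assert math.isnan(rate["value"]) and rate["flag"] == "undefined"

    def test_gap_splits_bouts_and_ibi(self, config, registry):
        # two bouts 100 s apart (gap > 10 s splits); ILI pairs spanning the
        # boundary are excluded
        session = lick_session(config, registry,
                               [[0.0, 0.2, 0.4], [100.4, 100.6]])
        table = ms.lick_microstructure(session, min_licks=1)
        get = lambda m: value_of(table, m, subject_id="rat1",
                                 fluid="ethanol10")["value"]
        assert get("n_bouts") == 2
        assert get("ili_mean_s") == pytest.approx(0.2)
        assert get("ibi_mean_s") == pytest.approx(100.0)

    def test_requires_lick_stream(self, hand_session):
        with pytest.raises(ms.LickDataRequiredError):
            ms.lick_microstructure(hand_session)

    def test_ili_recovery_from_simulator(self, one_day_session):
        """The gamma inter-lick model (mean 0.15 s) is recovered from the
        lick-level log within Monte-Carlo error."""
        session, _ = one_day_session
        table = ms.lick_microstructure(session)
        ilis = table[table["metric"] == "ili_mean_s"]["value"].dropna()
        assert abs(ilis.mean() - 0.15) < 0.005


class TestInvariants:
    @pytest.mark.parametrize("seed", range(3))
    def test_order_invariance(self, seed, config, registry):
        session, _ = random_session(seed, config, registry, duration_h=24.0)
        shuffled = list(session.bouts)
        np.random.default_rng(seed).shuffle(shuffled)
        s2 = SessionLog(bouts=sorted(shuffled, key=lambda b: b.start_time),
                        config=config, subjects=registry)
        bt1 = ms.filter_bouts(session, n_days=1)
        bt2 = ms.filter_bouts(s2, n_days=1)
        for fn in (ms.daily_intake, ms.hourly_zt_profile, ms.phase_totals,
                   ms.bout_stats, ms.bout_range_volumes):
            pd.testing.assert_frame_equal(fn(bt1), fn(bt2))

    def test_roundtrip_invariance(self, one_day_session, tmp_path):
        from sipcage import logio
        session, _ = one_day_session
        path = tmp_path / "log.csv"
        logio.write_log(session, path)
        session2, _ = logio.read_log(path, registry=session.subjects,
                                     config=session.config)
        bt1 = ms.filter_bouts(session, n_days=1)
        bt2 = ms.filter_bouts(session2, n_days=1)
        pd.testing.assert_frame_equal(ms.daily_intake(bt1), ms.daily_intake(bt2))
        pd.testing.assert_frame_equal(ms.bout_stats(bt1), ms.bout_stats(bt2))

    def test_filter_monotonicity(self, one_day_session):
        """Raising the bout threshold never increases any volume total."""
        session, _ = one_day_session
        prev = math.inf
        for threshold in (1, 20, 50, 100):
            bt = ms.filter_bouts(session, min_licks=threshold, n_days=1)
            total = float(bt.frame["volume_mL"].sum())
            assert total <= prev + 1e-12
            prev = total

    def test_wide_summary_shape(self, one_day_session):
        session, _ = one_day_session
        wide = ms.wide_summary(ms.filter_bouts(session, n_days=1))
        assert {"subject_id", "fluid", "mean_bout_volume_mL",
                "mean_daily_intake_mL"} <= set(wide.columns)
        assert len(wide) == 8  # 4 rats x 2 fluids
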