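"""Static resource models: schedulability, Poisson dive timing, activation
merging, energy and transmission budgets, composition rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floatcall.mission import (
    AcqModeSpec,
    DiveDurations,
    FunctionCall,
    FunctionProfile,
    MissionConfigError,
    MissionSpec,
    PeriodicSchedule,
    TaskProfile,
    analyze,
    ascent_lambda,
    compose_check,
    dive_duration,
    energy_budget,
    expected_tx_bytes,
    lifetime_years,
    ll_bound,
    mean_parking_d,
    merge_activation,
    poisson_p,
    processor_usage,
    satellite_energy_wh,
    task_period,
)

EXAMPLE_MISSION = MissionSpec(
    depth_m=1500.0,
    max_parking_d=10.0,
    descent_speed_m_s=0.1,
    ascent_speed_m_s=0.1,
    ascent_request_rate_per_d=2.0 / 7.0,
    battery_capacity_wh=4000.0,
    board_power_w=0.1,
    sensor_power_w={"hydro_lf": 0.05, "hydro_hf": 0.2},
    sat_power_w=2.0,
    tx_speed_bytes_s=100.0,
    descent_energy_wh=1.0,
    ascent_pump_coeff_wh_per_m2=5e-6,
    surface_fill_energy_wh=2.0,
)


class TestTaskPeriod:
    def test_continuous_period_is_array_over_rate(self):
        mode = AcqModeSpec("seis", "continuous", "hydro_lf",
                           sampling_hz=40, input_array_len=40)
        assert task_period(mode) == pytest.approx(1.0)

    def test_continuous_200hz_32(self):
        mode = AcqModeSpec("dcall", "continuous", "hydro_hf",
                           sampling_hz=200, input_array_len=32)
        assert task_period(mode) == pytest.approx(0.16)

    def test_short_period_is_coordinator_period(self):
        mode = AcqModeSpec("temp", "short", "thermo", coordinator_period_s=3600)
        assert task_period(mode) == 3600

    def test_short_mode_under_a_minute_rejected(self):
        with pytest.raises(MissionConfigError):
            AcqModeSpec("bad", "short", "thermo", coordinator_period_s=30)


class TestProcessorUsage:
    def test_full_utilization(self):
        assert processor_usage([TaskProfile("a", 2.0, 2.0)]) == 1.0

    def test_sum_of_ratios(self):
        tasks = [TaskProfile("a", 0.1, 1.0), TaskProfile("b", 0.2, 2.0)]
        assert processor_usage(tasks) == pytest.approx(0.2)

    def test_matches_per_task_oracle(self, rng):
        for _ in range(50):
            cs = rng.uniform(0, 1, 4)
            ts = rng.uniform(0.5, 10, 4)
            tasks = [TaskProfile(f"t{i}", c, t) for i, (c, t) in enumerate(zip(cs, ts))]
            assert processor_usage(tasks) == pytest.approx(sum(cs / ts))

    def test_invalid_period_rejected(self):
        with pytest.raises(MissionConfigError):
            TaskProfile("bad", 0.1, 0.0)


class TestLLBound:
    @pytest.mark.parametrize("n,pct", [(1, 100), (2, 83), (4, 76)])
    def test_printed_percentages(self, n, pct):
        assert round(ll_bound(n) * 100) == pct

    def test_limit_is_ln2(self):
        assert ll_bound(10**6) == pytest.approx(math.log(2), rel=1e-6)
        assert round(ll_bound(10**6) * 100) == 69

    def test_monotone_decreasing(self):
        vals = [ll_bound(n) for n in range(1, 20)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_n_rejected(self):
        with pytest.raises(MissionConfigError):
            ll_bound(0)


def rm_schedulable_by_simulation(tasks):
    """Exhaustive rate-monotonic simulation over one hyperperiod.

    Integer periods and execution times; unit time steps; deadline = period.
    Highest priority = shortest period. Returns True iff no job misses.
    """
    periods = [t.period_s for t in tasks]
    hyper = math.lcm(*(int(p) for p in periods))
    order = sorted(range(len(tasks)), key=lambda i: periods[i])
    remaining = [0] * len(tasks)
    deadline = [0] * len(tasks)
    for tick in range(hyper):
        for i, t in enumerate(tasks):
            if tick % int(t.period_s) == 0:
                if remaining[i] > 0:
                    return False  # previous job still unfinished
                remaining[i] = int(t.worst_case_exec_s)
                deadline[i] = tick + int(t.period_s)
        for i in order:
            if remaining[i] > 0:
                remaining[i] -= 1
                break
    return all(r == 0 for r in remaining)


class TestSchedulabilityOracle:
    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_ll_bound_is_sufficient(self, data):
        """LL-schedulable task sets always pass exhaustive RM simulation."""
        n = data.draw(st.integers(2, 4))
        periods = data.draw(
            st.lists(st.sampled_from([2, 3, 4, 5, 6, 8, 10, 12]),
                     min_size=n, max_size=n)
        )
        execs = [data.draw(st.integers(0, p)) for p in periods]
        tasks = [
            TaskProfile(f"t{i}", float(c), float(p))
            for i, (c, p) in enumerate(zip(execs, periods))
        ]
        u = processor_usage(tasks)
        if u <= ll_bound(n):
            assert rm_schedulable_by_simulation(tasks)


class TestPoissonModel:
    def test_worked_lambda(self):
        assert ascent_lambda(2.0 / 7.0, 10.0) == pytest.approx(2.857, abs=5e-3)

    def test_probability_of_at_least_one_request(self):
        lam = ascent_lambda(2.0 / 7.0, 10.0)
        assert 1 - poisson_p(0, lam) == pytest.approx(0.94, abs=5e-3)

    def test_zero_rate_degenerate(self):
        assert poisson_p(0, 0.0) == 1.0

    @pytest.mark.parametrize("lam", [0.1, 1.0, 2.86, 10.0])
    def test_pmf_normalizes(self, lam):
        assert sum(poisson_p(k, lam) for k in range(51)) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_worked_mean_parking(self):
        assert mean_parking_d(2.0 / 7.0, 10.0) == pytest.approx(3.3, abs=0.05)

    def test_zero_rate_gives_full_duration(self):
        assert mean_parking_d(0.0, 10.0) == 10.0

    def test_huge_rate_goes_to_zero(self):
        assert mean_parking_d(1e6, 10.0) == pytest.approx(0.0, abs=1e-5)

    @given(st.floats(min_value=1e-6, max_value=50.0))
    @settings(max_examples=100, deadline=None)
    def test_never_exceeds_default_duration(self, rate):
        assert 0 < mean_parking_d(rate, 10.0) <= 10.0

    def test_monotone_decreasing_in_rate(self):
        rates = np.linspace(0.01, 5, 100)
        vals = [mean_parking_d(r, 10.0) for r in rates]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_continuous_at_zero_rate(self):
        assert mean_parking_d(1e-9, 10.0) == pytest.approx(10.0, abs=1e-6)

    def test_ascent_path_probability_sums_trigger_branches(self):
        from floatcall.mission import ascent_path_probability

        mode = AcqModeSpec(
            "m", "short", "s", coordinator_period_s=3600,
            function_calls=(
                FunctionCall(FunctionProfile("a", triggers_ascent=True),
                             probability=0.3),
                FunctionCall(FunctionProfile("b"), probability=0.9),
                FunctionCall(FunctionProfile("c", triggers_ascent=True),
                             probability=0.2),
            ),
        )
        assert ascent_path_probability(mode) == pytest.approx(0.5)


class TestDiveDuration:
    def test_stage_arithmetic(self):
        dive = dive_duration(EXAMPLE_MISSION, parking_d=3.3)
        assert dive.descent_s == pytest.approx(15000)
        assert dive.ascent_s == pytest.approx(15000)
        assert dive.surface_s == 3600
        assert dive.total_d == pytest.approx(
            3.3 + 2 * 15000 / 86400 + 3600 / 86400
        )

    def test_surface_always_one_hour_by_default(self):
        deep = MissionSpec(depth_m=4000, max_parking_d=5,
                           descent_speed_m_s=0.2, ascent_speed_m_s=0.2)
        assert dive_duration(deep, 5.0).surface_s == 3600

    def test_zero_speed_rejected(self):
        bad = MissionSpec(depth_m=100, max_parking_d=5,
                          descent_speed_m_s=0.0, ascent_speed_m_s=0.1)
        with pytest.raises(MissionConfigError):
            dive_duration(bad, 5.0)


def minute_grid_oracle(schedules, hyper_min):
    """Boolean-OR simulation on a 1-minute grid (integer-minute schedules)."""
    active = np.zeros(hyper_min, dtype=bool)
    for s in schedules:
        on, period = int(s.on_s), int(s.period_s)
        for start in range(0, hyper_min, period):
            active[start : start + on] = True
    return active.mean()


class TestMergeActivation:
    def test_two_app_example(self):
        # 2 min on / 5 min period merged with 1 min on / 3 min period:
        # the union repeats every 15 min with 9 active minutes
        a = PeriodicSchedule(on_s=2, period_s=5)
        b = PeriodicSchedule(on_s=1, period_s=3)
        assert merge_activation([a, b]) == pytest.approx(0.6)

    def test_single_schedule(self):
        assert merge_activation([PeriodicSchedule(2, 5)]) == pytest.approx(0.4)

    def test_activation_time_for_ten_hour_stage(self):
        duty = merge_activation(
            [PeriodicSchedule(2, 5), PeriodicSchedule(1, 3)]
        )
        assert duty * 10.0 == pytest.approx(6.0)  # hours

    @given(st.data())
    @settings(max_examples=80, deadline=None)
    def test_matches_minute_grid_oracle(self, data):
        n = data.draw(st.integers(1, 3))
        schedules = []
        for _ in range(n):
            period = data.draw(st.integers(1, 12))
            on = data.draw(st.integers(1, period))
            schedules.append(PeriodicSchedule(float(on), float(period)))
        hyper = math.lcm(*(int(s.period_s) for s in schedules))
        assert merge_activation(schedules) == pytest.approx(
            minute_grid_oracle(schedules, hyper)
        )

    def test_always_on_is_unity(self):
        assert merge_activation([PeriodicSchedule(3, 3)]) == 1.0


class TestEnergyAndTransmission:
    DIVE = DiveDurations(descent_s=15000, parking_s=3.3 * 86400,
                         ascent_s=15000, surface_s=3600)

    def test_satellite_energy_example(self):
        # 1 MB at 100 B/s and 2 W: 10485.76 s of transmission
        e = satellite_energy_wh(2**20, 100.0, 2.0)
        assert e == pytest.approx(10485.76 * 2 / 3600, rel=1e-9)
        assert e == pytest.approx(5.83, abs=0.01)

    def test_zero_bytes_zero_energy(self):
        assert satellite_energy_wh(0, 100.0, 2.0) == 0.0

    def test_stage_energy_structure(self):
        duty = {"hydro_lf": {"parking": 0.6}}
        stages = energy_budget(EXAMPLE_MISSION, self.DIVE, duty, 2**20)
        assert stages["parking"].actuator_wh == 0.0
        assert stages["descent"].actuator_wh == 1.0
        assert stages["ascent"].actuator_wh == pytest.approx(
            5e-6 * 1500**2 + 2.0
        )
        # comms only at the surface
        assert stages["surface"].comms_wh > 0
        for st_ in ("descent", "parking", "ascent"):
            assert stages[st_].comms_wh == 0.0
        hours = 3.3 * 24
        assert stages["parking"].sensors_wh == pytest.approx(0.05 * 0.6 * hours)
        assert stages["parking"].board_wh == pytest.approx(0.1 * hours)

    def test_zero_depth_quadratic_term_vanishes(self):
        spec = MissionSpec(
            depth_m=1e-9, max_parking_d=1, descent_speed_m_s=0.1,
            ascent_speed_m_s=0.1, board_power_w=0.0, sat_power_w=0.0,
            tx_speed_bytes_s=1.0, descent_energy_wh=0.0,
            ascent_pump_coeff_wh_per_m2=1.0, surface_fill_energy_wh=7.0,
        )
        dive = DiveDurations(0, 86400, 0, 3600)
        stages = energy_budget(spec, dive, {}, 0.0)
        assert stages["ascent"].actuator_wh == pytest.approx(7.0)

    def test_missing_constant_named_in_error(self):
        spec = MissionSpec(depth_m=1500, max_parking_d=10,
                           descent_speed_m_s=0.1, ascent_speed_m_s=0.1)
        with pytest.raises(MissionConfigError, match="board_power_w"):
            energy_budget(spec, self.DIVE, {}, 0.0)

    def test_expected_bytes_probability_weighting(self):
        # one 1000 B recording call with probability 0.5, expected to run
        # 4 times per dive -> 2000 B/dive
        record = FunctionProfile("record", bytes_const=1000.0)
        dive = DiveDurations(0, 4 * 3600, 0, 0)
        mode = AcqModeSpec(
            "m", "short", "s", coordinator_period_s=3600,
            function_calls=(FunctionCall(record, probability=0.5),),
            stages=("parking",),
        )
        per_dive, per_month = expected_tx_bytes([mode], dive)
        assert per_dive == pytest.approx(2000.0)
        assert per_month == pytest.approx(2000.0 * 30 / dive.total_d)

    def test_certain_call_recovers_deterministic_count(self):
        record = FunctionProfile("record", bytes_const=100.0)
        dive = DiveDurations(0, 10 * 3600, 0, 0)
        mode = AcqModeSpec(
            "m", "short", "s", coordinator_period_s=3600,
            function_calls=(FunctionCall(record, probability=1.0),),
        )
        per_dive, _ = expected_tx_bytes([mode], dive)
        assert per_dive == pytest.approx(1000.0)

    def test_no_recording_calls_zero_bytes(self):
        mode = AcqModeSpec("m", "short", "s", coordinator_period_s=3600)
        assert expected_tx_bytes([mode], self.DIVE)[0] == 0.0

    def test_bad_probability_rejected(self):
        with pytest.raises(MissionConfigError):
            FunctionCall(FunctionProfile("f"), probability=1.5)


class TestLifetime:
    def test_worked_example(self):
        # 4 kWh battery, 20 Wh per 10-day dive: 200 dives = 2000 d
        assert lifetime_years(4000, 20, 10) == pytest.approx(5.48, abs=0.01)

    def test_one_year_identity(self):
        assert lifetime_years(100, 100, 365) == pytest.approx(1.0)

    def test_linear_in_battery(self):
        assert lifetime_years(8000, 20, 10) == pytest.approx(
            2 * lifetime_years(4000, 20, 10)
        )

    def test_monotone_in_power_draw(self, rng):
        base = EXAMPLE_MISSION
        modes = [
            AcqModeSpec("m", "continuous", "hydro_lf", sampling_hz=40,
                        input_array_len=40,
                        function_calls=(FunctionCall(
                            FunctionProfile("f", exec_s_const=1e-4)),))
        ]
        life_base = analyze(base, modes).lifetime_years
        import dataclasses

        hungrier = dataclasses.replace(base, board_power_w=0.5)
        assert analyze(hungrier, modes).lifetime_years < life_base

    def test_zero_energy_rejected(self):
        with pytest.raises(MissionConfigError):
            lifetime_years(4000, 0, 10)


def _app(depth=1500.0, parking=10.0, sensor="hydro_lf", fs=40.0,
         stages=("parking",)):
    spec = MissionSpec(depth_m=depth, max_parking_d=parking,
                       descent_speed_m_s=0.1, ascent_speed_m_s=0.1)
    mode = AcqModeSpec("m", "continuous", sensor, sampling_hz=fs,
                       input_array_len=40, stages=stages,
                       function_calls=(FunctionCall(
                           FunctionProfile("f", exec_s_const=1e-3)),))
    return spec, [mode]


class TestCompose:
    def test_depth_mismatch_is_conflict(self):
        conflicts = compose_check([_app(depth=1500), _app(depth=2000)])
        assert any("depth" in c for c in conflicts)

    def test_sensor_rate_mismatch_is_conflict(self):
        conflicts = compose_check([_app(fs=40), _app(fs=200)])
        assert any("sensor" in c for c in conflicts)

    def test_same_sensor_different_stages_is_fine(self):
        conflicts = compose_check(
            [_app(stages=("parking",)), _app(stages=("descent",))]
        )
        assert conflicts == []

    def test_different_sensors_below_bound_ok(self):
        conflicts = compose_check(
            [_app(sensor="hydro_lf"), _app(sensor="hydro_hf")]
        )
        assert conflicts == []

    def test_overload_is_schedulability_conflict(self):
        spec, modes = _app()
        heavy = AcqModeSpec(
            "heavy", "continuous", "hydro_hf", sampling_hz=200,
            input_array_len=40, stages=("parking",),
            function_calls=(FunctionCall(
                FunctionProfile("slow", exec_s_const=0.2)),),
        )
        conflicts = compose_check([(spec, modes), (spec, [heavy])])
        assert any("schedulability" in c for c in conflicts)


class TestAnalyze:
    def test_full_report_from_example_profile(self):
        modes = [
            AcqModeSpec(
                "seismic", "continuous", "hydro_lf", sampling_hz=40,
                input_array_len=40, stages=("parking",),
                function_calls=(
                    FunctionCall(FunctionProfile("stalta", exec_s_const=1e-4)),
                    FunctionCall(
                        FunctionProfile("record", exec_s_const=5e-4,
                                        bytes_const=5000, triggers_ascent=True),
                        probability=0.01,
                    ),
                ),
            )
        ]
        report = analyze(EXAMPLE_MISSION, modes)
        assert report.schedulable
        assert 0 < report.processor_utilization < 0.01
        assert report.mean_parking_d == pytest.approx(3.3, abs=0.05)
        assert report.dive_duration_d > report.mean_parking_d
        assert report.expected_tx_bytes_per_month > 0
        assert report.lifetime_years > 0
        assert set(report.stage_energy_wh) == {
            "descent", "parking", "ascent", "surface"
        }
        # report echoes the duty profile used
        assert report.sensor_duty == {"hydro_lf": {"parking": 1.0}}
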