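"""Static resource models for autonomous profiling floats.

Before an acquisition application is deployed on a float, four questions
must be answered from its description alone: will the processor keep up
(rate-monotonic schedulability under the Liu-Layland utilization bound),
how long does a dive last (a Poisson model of ascent requests shortens the
parking stage), how much energy does a dive cost (per-stage actuator /
sensor / board / satellite terms), and how many bytes go through the
satellite each month. Two applications can also be composed onto one float,
which requires equal dive geometry and consistent sensor configurations.

All hardware constants (powers, pump coefficient, transmission speed,
float speeds) are user-supplied: the models are exact given the constants,
and the constants depend on the instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

__all__ = [
    "MissionConfigError",
    "TaskProfile",
    "FunctionProfile",
    "FunctionCall",
    "AcqModeSpec",
    "MissionSpec",
    "PeriodicSchedule",
    "DiveDurations",
    "StageEnergy",
    "ResourceReport",
    "task_period",
    "processor_usage",
    "ll_bound",
    "ascent_lambda",
    "ascent_path_probability",
    "poisson_p",
    "mean_parking_d",
    "dive_duration",
    "merge_activation",
    "energy_budget",
    "expected_tx_bytes",
    "lifetime_years",
    "compose_check",
    "analyze",
]

STAGES = ("descent", "parking", "ascent", "surface")
DAY_S = 86400.0
MONTH_D = 30.0  # monthly-volume normalization


class MissionConfigError(ValueError):
    """A required mission or hardware constant is missing or invalid."""


@dataclass(frozen=True)
class TaskProfile:
    """A periodic task: worst-case execution time C and period T."""

    name: str
    worst_case_exec_s: float
    period_s: float

    def __post_init__(self) -> None:
        if self.worst_case_exec_s < 0:
            raise MissionConfigError(f"task {self.name}: C must be >= 0")
        if self.period_s <= 0:
            raise MissionConfigError(f"task {self.name}: T must be > 0")


@dataclass(frozen=True)
class FunctionProfile:
    """Library-function metadata: execution time and recorded bytes, each
    affine in the array length (constant + per-element term)."""

    name: str
    exec_s_const: float = 0.0
    exec_s_per_elem: float = 0.0
    bytes_const: float = 0.0
    bytes_per_elem: float = 0.0
    triggers_ascent: bool = False

    def exec_time_s(self, array_len: int = 0) -> float:
        t = self.exec_s_const + self.exec_s_per_elem * array_len
        if t < 0:
            raise MissionConfigError(f"function {self.name}: negative exec time")
        return t

    def recorded_bytes(self, array_len: int = 0) -> float:
        return self.bytes_const + self.bytes_per_elem * array_len


@dataclass(frozen=True)
class FunctionCall:
    """One call site: which function, on how large an array, with what
    branch probability."""

    fn: FunctionProfile
    probability: float = 1.0
    array_len: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise MissionConfigError(
                f"call of {self.fn.name}: probability must be in [0, 1]"
            )


@dataclass(frozen=True)
class PeriodicSchedule:
    """On for ``on_s`` out of every ``period_s``, phase-aligned at 0 and
    starting active."""

    on_s: float
    period_s: float
    phase_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.on_s <= self.period_s:
            raise MissionConfigError("need 0 < on_s <= period_s")


@dataclass(frozen=True)
class AcqModeSpec:
    """An acquisition mode: continuous (streamed packets, real-time) or
    short (periodic one-shot, coordinator-driven)."""

    name: str
    kind: str  # "continuous" | "short"
    sensor_id: str
    sampling_hz: float = 0.0
    input_array_len: int = 0
    coordinator_period_s: float = 0.0
    function_calls: tuple[FunctionCall, ...] = ()
    stages: tuple[str, ...] = ("parking",)
    activation: PeriodicSchedule | None = None  # sensor duty pattern

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "short"):
            raise MissionConfigError(f"unknown acquisition kind {self.kind!r}")
        if self.kind == "continuous" and self.input_array_len < 1:
            raise MissionConfigError(
                f"mode {self.name}: continuous acquisition needs input_array_len >= 1"
            )
        if self.kind == "short" and self.coordinator_period_s < 60:
            raise MissionConfigError(
                f"mode {self.name}: short-mode period must be at least one minute"
            )
        for st in self.stages:
            if st not in STAGES:
                raise MissionConfigError(f"unknown dive stage {st!r}")


_REQUIRED_HARDWARE = (
    "battery_capacity_wh",
    "board_power_w",
    "sat_power_w",
    "tx_speed_bytes_s",
    "descent_energy_wh",
    "ascent_pump_coeff_wh_per_m2",
    "surface_fill_energy_wh",
)


@dataclass(frozen=True)
class MissionSpec:
    """Dive geometry plus the hardware constants the models need.

    Hardware fields default to None; any model that needs one raises
    :class:`MissionConfigError` naming the missing constant.
    """

    depth_m: float
    max_parking_d: float
    descent_speed_m_s: float
    ascent_speed_m_s: float
    ascent_request_rate_per_d: float = 0.0
    surface_duration_h: float = 1.0
    battery_capacity_wh: float | None = None
    board_power_w: float | None = None
    sensor_power_w: Mapping[str, float] = field(default_factory=dict)
    sat_power_w: float | None = None
    tx_speed_bytes_s: float | None = None
    descent_energy_wh: float | None = None
    ascent_pump_coeff_wh_per_m2: float | None = None
    surface_fill_energy_wh: float | None = None

    def __post_init__(self) -> None:
        if self.depth_m <= 0:
            raise MissionConfigError("depth_m must be positive")
        if self.max_parking_d <= 0:
            raise MissionConfigError("max_parking_d must be positive")
        if self.ascent_request_rate_per_d < 0:
            raise MissionConfigError("ascent_request_rate_per_d must be >= 0")

    def require(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            raise MissionConfigError(f"missing hardware constant: {name}")
        if value < 0:
            raise MissionConfigError(f"hardware constant {name} must be >= 0")
        return value


# --------------------------------------------------------------------------
# processor schedulability


def task_period(mode: AcqModeSpec) -> float:
    """Execution period of an acquisition mode.

    Continuous modes run once per filled input array
    (input_array_len / sampling_hz); short modes run at the coordinator
    period.
    """
    if mode.kind == "continuous":
        if mode.sampling_hz <= 0:
            raise MissionConfigError(f"mode {mode.name}: sampling_hz must be > 0")
        return mode.input_array_len / mode.sampling_hz
    return mode.coordinator_period_s


def mode_exec_time_s(mode: AcqModeSpec) -> float:
    """Worst-case execution time of one mode activation: every call taken."""
    return sum(c.fn.exec_time_s(c.array_len) for c in mode.function_calls)


def processor_usage(tasks: Sequence[TaskProfile]) -> float:
    """Total utilization U = sum of C_i / T_i."""
    if not tasks:
        raise MissionConfigError("processor_usage needs at least one task")
    return sum(t.worst_case_exec_s / t.period_s for t in tasks)


def ll_bound(n: int) -> float:
    """Liu-Layland utilization bound n * (2**(1/n) - 1).

    A set of n rate-monotonic periodic tasks is schedulable if the total
    utilization does not exceed this bound (sufficient, not necessary):
    1.0 for one task, ~0.83 for two, approaching ln 2 ~ 0.69 as n grows.
    """
    if n < 1:
        raise MissionConfigError("ll_bound needs n >= 1")
    return n * (2.0 ** (1.0 / n) - 1.0)


# --------------------------------------------------------------------------
# dive-duration (Poisson) model


def ascent_lambda(rate_per_d: float, max_parking_d: float) -> float:
    """Mean number of ascent requests over the default parking duration."""
    if rate_per_d < 0:
        raise MissionConfigError("rate_per_d must be >= 0")
    if max_parking_d <= 0:
        raise MissionConfigError("max_parking_d must be positive")
    return rate_per_d * max_parking_d


def poisson_p(k: int, lam: float) -> float:
    """Poisson pmf p(k) = lam**k * exp(-lam) / k!."""
    if k < 0:
        raise MissionConfigError("k must be >= 0")
    if lam < 0:
        raise MissionConfigError("lambda must be >= 0")
    return math.exp(-lam) * lam**k / math.factorial(k)


def ascent_path_probability(mode: AcqModeSpec) -> float:
    """Per-activation probability that a mode requests the ascent.

    Aggregates the branch probabilities of every call that triggers the
    ascent (branches are independent alternatives, so probabilities add,
    capped at 1). This is a helper for deriving the ascent-request rate
    from an application's annotations; the rate in :class:`MissionSpec`
    remains the authoritative input, as annotated probabilities are meant
    to be conservative estimates.
    """
    p = sum(c.probability for c in mode.function_calls if c.fn.triggers_ascent)
    return min(1.0, p)


def mean_parking_d(rate_per_d: float, max_parking_d: float) -> float:
    """Expected parking-stage duration in days.

    The parking stage ends at the first ascent request or after
    ``max_parking_d``, whichever comes first. For exponential waiting times
    at rate r the expectation is the mean inter-request interval times the
    probability of at least one request within the window:
    (1/r) * (1 - exp(-r * D)), which is exactly E[min(T, D)]. The r -> 0
    limit is the full default duration.
    """
    if rate_per_d < 0:
        raise MissionConfigError("rate_per_d must be >= 0")
    if rate_per_d == 0:
        return max_parking_d
    return (1.0 / rate_per_d) * (1.0 - math.exp(-rate_per_d * max_parking_d))


@dataclass(frozen=True)
class DiveDurations:
    """Per-stage dive durations, in seconds, plus the total in days."""

    descent_s: float
    parking_s: float
    ascent_s: float
    surface_s: float

    @property
    def total_s(self) -> float:
        return self.descent_s + self.parking_s + self.ascent_s + self.surface_s

    @property
    def total_d(self) -> float:
        return self.total_s / DAY_S

    def stage_s(self, stage: str) -> float:
        return getattr(self, f"{stage}_s")


def dive_duration(spec: MissionSpec, parking_d: float) -> DiveDurations:
    """Stage durations: descent and ascent from depth over speed, parking
    from the Poisson model, surface fixed (one hour by default)."""
    if spec.descent_speed_m_s <= 0 or spec.ascent_speed_m_s <= 0:
        raise MissionConfigError("float speeds must be positive")
    return DiveDurations(
        descent_s=spec.depth_m / spec.descent_speed_m_s,
        parking_s=parking_d * DAY_S,
        ascent_s=spec.depth_m / spec.ascent_speed_m_s,
        surface_s=spec.surface_duration_h * 3600.0,
    )


# --------------------------------------------------------------------------
# sensor-activation merging


def _to_fraction(x: float) -> Fraction:
    return Fraction(x).limit_denominator(10**6)


def merge_activation(schedules: Sequence[PeriodicSchedule]) -> float:
    """Duty cycle of the union of periodic activation patterns.

    All schedules are phase-aligned at t=0 starting active; the active
    fraction is computed exactly over the hyperperiod (LCM of the periods,
    which must be commensurate).
    """
    if not schedules:
        raise MissionConfigError("merge_activation needs at least one schedule")
    periods = [_to_fraction(s.period_s) for s in schedules]
    hyper = _lcm_fractions(periods)
    intervals: list[tuple[Fraction, Fraction]] = []
    for s in schedules:
        period = _to_fraction(s.period_s)
        on = _to_fraction(s.on_s)
        phase = _to_fraction(s.phase_s)
        k = 0
        while k * period < hyper:
            start = k * period + phase
            intervals.append((start, min(start + on, hyper)))
            k += 1
    intervals.sort()
    active = Fraction(0)
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start <= cur_end:
            cur_end = max(cur_end, end)
        else:
            active += cur_end - cur_start
            cur_start, cur_end = start, end
    active += cur_end - cur_start
    return float(active / hyper)


def _lcm_fractions(fracs: Sequence[Fraction]) -> Fraction:
    num = fracs[0].numerator
    den = fracs[0].denominator
    for f in fracs[1:]:
        num = math.lcm(num, f.numerator)
        den = math.gcd(den, f.denominator)
    return Fraction(num, den)


# --------------------------------------------------------------------------
# energy and transmission


@dataclass(frozen=True)
class StageEnergy:
    actuator_wh: float
    sensors_wh: float
    board_wh: float
    comms_wh: float

    @property
    def total_wh(self) -> float:
        return self.actuator_wh + self.sensors_wh + self.board_wh + self.comms_wh


def satellite_energy_wh(tx_bytes: float, tx_speed_bytes_s: float,
                        sat_power_w: float) -> float:
    """Transmission energy: (bytes / speed) seconds at the modem power."""
    if tx_speed_bytes_s <= 0:
        raise MissionConfigError("tx_speed_bytes_s must be positive")
    return tx_bytes / tx_speed_bytes_s * sat_power_w / 3600.0


def energy_budget(
    spec: MissionSpec,
    dive: DiveDurations,
    sensor_duty: Mapping[str, Mapping[str, float]],
    tx_bytes_per_dive: float,
) -> dict[str, StageEnergy]:
    """Per-stage energy of one dive: Estage = Eact + Esens + Eboard + Ecom.

    Actuators: the descent costs a small configured constant (valve
    operation at the surface; the descent itself is driven by pressure),
    parking costs nothing, the ascent costs pump_coeff * depth**2 plus the
    constant surface bladder-fill energy. Sensors: power x duty x stage
    time, per sensor. Board: constant power x stage time. Satellite: only
    at the surface — underwater the modem is off.

    ``sensor_duty`` maps sensor id -> {stage: active fraction}.
    """
    board_w = spec.require("board_power_w")
    pump = spec.require("ascent_pump_coeff_wh_per_m2")
    fill = spec.require("surface_fill_energy_wh")
    descent_e = spec.require("descent_energy_wh")
    esat = satellite_energy_wh(
        tx_bytes_per_dive, spec.require("tx_speed_bytes_s"),
        spec.require("sat_power_w"),
    )
    act = {
        "descent": descent_e,
        "parking": 0.0,
        "ascent": pump * spec.depth_m**2 + fill,
        "surface": 0.0,
    }
    out: dict[str, StageEnergy] = {}
    for stage in STAGES:
        hours = dive.stage_s(stage) / 3600.0
        sens = 0.0
        for sensor, duties in sensor_duty.items():
            duty = duties.get(stage, 0.0)
            if duty:
                if sensor not in spec.sensor_power_w:
                    raise MissionConfigError(
                        f"missing hardware constant: sensor_power_w[{sensor}]"
                    )
                sens += spec.sensor_power_w[sensor] * duty * hours
        out[stage] = StageEnergy(
            actuator_wh=act[stage],
            sensors_wh=sens,
            board_wh=board_w * hours,
            comms_wh=esat if stage == "surface" else 0.0,
        )
    return out


def expected_tx_bytes(
    modes: Sequence[AcqModeSpec], dive: DiveDurations
) -> tuple[float, float]:
    """Expected satellite bytes per dive and per (30-day) month.

    Each recording call contributes bytes x branch probability x expected
    number of mode activations during the dive (active stage time over the
    mode period).
    """
    per_dive = 0.0
    for mode in modes:
        period = task_period(mode)
        active_s = sum(dive.stage_s(st) for st in mode.stages)
        n_activations = active_s / period
        per_call = sum(
            c.fn.recorded_bytes(c.array_len) * c.probability
            for c in mode.function_calls
        )
        per_dive += per_call * n_activations
    per_month = per_dive * (MONTH_D / dive.total_d)
    return per_dive, per_month


def lifetime_years(ebat_wh: float, edive_wh: float, tdive_d: float) -> float:
    """Float lifetime LT = (Ebat / Edive) * Tdive, in years."""
    if edive_wh <= 0:
        raise MissionConfigError("Edive must be positive")
    return ebat_wh / edive_wh * tdive_d / 365.0


# --------------------------------------------------------------------------
# composition and the full report


def compose_check(
    apps: Sequence[tuple[MissionSpec, Sequence[AcqModeSpec]]],
) -> list[str]:
    """Compatibility conflicts between applications sharing one float.

    Dive depth and maximum parking duration must agree; a sensor used by
    two applications during overlapping stages must be configured
    identically (same sampling rate); and the combined task set must stay
    under the Liu-Layland bound. Returns a list of conflict descriptions
    (empty means compatible).
    """
    if len(apps) < 2:
        raise MissionConfigError("compose_check needs at least two applications")
    conflicts: list[str] = []
    ref_spec = apps[0][0]
    for i, (spec, _) in enumerate(apps[1:], start=2):
        if spec.depth_m != ref_spec.depth_m:
            conflicts.append(
                f"depth conflict: app 1 dives to {ref_spec.depth_m} m, "
                f"app {i} to {spec.depth_m} m"
            )
        if spec.max_parking_d != ref_spec.max_parking_d:
            conflicts.append(
                f"duration conflict: app 1 parks up to {ref_spec.max_parking_d} d, "
                f"app {i} up to {spec.max_parking_d} d"
            )
    seen: dict[str, list[tuple[int, AcqModeSpec]]] = {}
    for i, (_, modes) in enumerate(apps, start=1):
        for mode in modes:
            seen.setdefault(mode.sensor_id, []).append((i, mode))
    for sensor, users in seen.items():
        for (ia, ma), (ib, mb) in (
            (users[x], users[y])
            for x in range(len(users))
            for y in range(x + 1, len(users))
        ):
            if ia == ib:
                continue
            if set(ma.stages) & set(mb.stages) and ma.sampling_hz != mb.sampling_hz:
                conflicts.append(
                    f"sensor conflict: {sensor} sampled at {ma.sampling_hz} Hz "
                    f"by app {ia} and {mb.sampling_hz} Hz by app {ib} in the "
                    f"same stage"
                )
    tasks = [
        TaskProfile(f"app{i}:{m.name}", mode_exec_time_s(m), task_period(m))
        for i, (_, modes) in enumerate(apps, start=1)
        for m in modes
    ]
    if tasks:
        u = processor_usage(tasks)
        bound = ll_bound(len(tasks))
        if u > bound:
            conflicts.append(
                f"schedulability conflict: combined utilization {u:.4f} exceeds "
                f"the Liu-Layland bound {bound:.4f} for {len(tasks)} tasks"
            )
    return conflicts


@dataclass(frozen=True)
class ResourceReport:
    """Everything the static analysis tells a developer about one
    application set on one float."""

    processor_utilization: float
    ll_bound: float
    schedulable: bool
    mean_parking_d: float
    dive_duration_d: float
    expected_tx_bytes_per_dive: float
    expected_tx_bytes_per_month: float
    energy_per_dive_wh: float
    lifetime_years: float
    stage_energy_wh: dict[str, float]
    sensor_duty: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "processor_utilization": self.processor_utilization,
            "ll_bound": self.ll_bound,
            "schedulable": self.schedulable,
            "mean_parking_d": self.mean_parking_d,
            "dive_duration_d": self.dive_duration_d,
            "expected_tx_bytes_per_dive": self.expected_tx_bytes_per_dive,
            "expected_tx_bytes_per_month": self.expected_tx_bytes_per_month,
            "energy_per_dive_wh": self.energy_per_dive_wh,
            "lifetime_years": self.lifetime_years,
            "stage_energy_wh": self.stage_energy_wh,
            "sensor_duty": self.sensor_duty,
        }


def sensor_duty_cycles(
    modes: Sequence[AcqModeSpec],
) -> dict[str, dict[str, float]]:
    """Merged per-sensor, per-stage duty cycles.

    A continuous mode keeps its sensor on for its whole stages (duty 1)
    unless it carries an explicit activation pattern; patterns of modes
    sharing a sensor in a stage are merged over their hyperperiod.
    """
    groups: dict[tuple[str, str], list[PeriodicSchedule | None]] = {}
    for mode in modes:
        for stage in mode.stages:
            groups.setdefault((mode.sensor_id, stage), []).append(mode.activation)
    duty: dict[str, dict[str, float]] = {}
    for (sensor, stage), activations in groups.items():
        if any(a is None for a in activations):
            frac = 1.0
        else:
            frac = merge_activation([a for a in activations if a is not None])
        duty.setdefault(sensor, {})[stage] = frac
    return duty


def analyze(
    spec: MissionSpec, modes: Sequence[AcqModeSpec]
) -> ResourceReport:
    """Run the full static analysis for one application set."""
    tasks = [
        TaskProfile(m.name, mode_exec_time_s(m), task_period(m)) for m in modes
    ]
    u = processor_usage(tasks) if tasks else 0.0
    bound = ll_bound(len(tasks)) if tasks else 1.0
    parking = mean_parking_d(spec.ascent_request_rate_per_d, spec.max_parking_d)
    dive = dive_duration(spec, parking)
    tx_dive, tx_month = expected_tx_bytes(modes, dive)
    duty = sensor_duty_cycles(modes)
    stages = energy_budget(spec, dive, duty, tx_dive)
    edive = sum(s.total_wh for s in stages.values())
    life = lifetime_years(spec.require("battery_capacity_wh"), edive,
                          dive.total_d)
    return ResourceReport(
        processor_utilization=u,
        ll_bound=bound,
        schedulable=u <= bound,
        mean_parking_d=parking,
        dive_duration_d=dive.total_d,
        expected_tx_bytes_per_dive=tx_dive,
        expected_tx_bytes_per_month=tx_month,
        energy_per_dive_wh=edive,
        lifetime_years=life,
        stage_energy_wh={st: e.total_wh for st, e in stages.items()},
        sensor_duty=duty,
    )
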