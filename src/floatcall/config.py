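"""Structured config files (YAML, with JSON accepted as a YAML subset).

Units are fixed across all config files: times in seconds (except where a
key name says otherwise, e.g. ``max_parking_d``), frequencies in Hz, depths
in m, energies in Wh, powers in W.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .dcall import CheckParams, DcallConfig
from .mission import (
    AcqModeSpec,
    FunctionCall,
    FunctionProfile,
    MissionConfigError,
    MissionSpec,
    PeriodicSchedule,
)
from .synth import SyntheticEvent

__all__ = [
    "load_yaml",
    "dcall_config_from_dict",
    "scene_recipe_from_dict",
    "mission_from_dict",
    "modes_from_dict",
]


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def dcall_config_from_dict(data: dict[str, Any]) -> DcallConfig:
    """Detector config; every validation-check threshold is overridable."""
    check_keys = {f.name for f in CheckParams.__dataclass_fields__.values()}
    checks = CheckParams(**{k: v for k, v in data.items() if k in check_keys})
    top_keys = {
        "sta_len", "lta_len", "trigger_threshold", "lowfreq_cutoff_hz",
        "window", "ratio_cap", "min_bin_separation", "pretrigger_frames",
    }
    unknown = set(data) - check_keys - top_keys
    if unknown:
        raise ValueError(f"unknown detector config keys: {sorted(unknown)}")
    return DcallConfig(
        **{k: v for k, v in data.items() if k in top_keys}, checks=checks
    )


def scene_recipe_from_dict(data: dict[str, Any]) -> dict[str, Any]:
    """A scene recipe: events + noise level + seed (+ rate, duration)."""
    events = [
        SyntheticEvent(
            kind=ev.get("kind", "dcall"),
            onset_s=float(ev["onset_s"]),
            duration_s=float(ev.get("duration_s", 4.0)),
            amplitude=float(ev.get("amplitude", 1.0)),
            f_start_hz=float(ev.get("f_start_hz", 80.0)),
            f_end_hz=float(ev.get("f_end_hz", 20.0)),
        )
        for ev in data.get("events", [])
    ]
    return {
        "events": events,
        "duration_s": float(data["duration_s"]),
        "sample_rate_hz": float(data.get("sample_rate_hz", 200.0)),
        "noise_rms": float(data.get("noise_rms", 0.05)),
        "seed": int(data.get("seed", 0)),
    }


def mission_from_dict(data: dict[str, Any]) -> MissionSpec:
    mission = data.get("mission", {})
    hardware = data.get("hardware", {})
    try:
        return MissionSpec(
            depth_m=float(mission["depth_m"]),
            max_parking_d=float(mission["max_parking_d"]),
            descent_speed_m_s=float(mission["descent_speed_m_s"]),
            ascent_speed_m_s=float(mission["ascent_speed_m_s"]),
            ascent_request_rate_per_d=float(
                mission.get("ascent_request_rate_per_d", 0.0)
            ),
            surface_duration_h=float(mission.get("surface_duration_h", 1.0)),
            battery_capacity_wh=hardware.get("battery_capacity_wh"),
            board_power_w=hardware.get("board_power_w"),
            sensor_power_w=dict(hardware.get("sensor_power_w", {})),
            sat_power_w=hardware.get("sat_power_w"),
            tx_speed_bytes_s=hardware.get("tx_speed_bytes_s"),
            descent_energy_wh=hardware.get("descent_energy_wh"),
            ascent_pump_coeff_wh_per_m2=hardware.get("ascent_pump_coeff_wh_per_m2"),
            surface_fill_energy_wh=hardware.get("surface_fill_energy_wh"),
        )
    except KeyError as exc:
        raise MissionConfigError(f"missing mission key: {exc.args[0]}") from exc


def modes_from_dict(data: dict[str, Any]) -> list[AcqModeSpec]:
    modes = []
    for m in data.get("modes", []):
        calls = tuple(
            FunctionCall(
                fn=FunctionProfile(
                    name=c["fn"],
                    exec_s_const=float(c.get("exec_s", 0.0)),
                    exec_s_per_elem=float(c.get("exec_s_per_elem", 0.0)),
                    bytes_const=float(c.get("bytes", 0.0)),
                    bytes_per_elem=float(c.get("bytes_per_elem", 0.0)),
                    triggers_ascent=bool(c.get("triggers_ascent", False)),
                ),
                probability=float(c.get("prob", 1.0)),
                array_len=int(c.get("array_len", 0)),
            )
            for c in m.get("calls", [])
        )
        activation = None
        if "activation" in m:
            a = m["activation"]
            activation = PeriodicSchedule(
                on_s=float(a["on_s"]), period_s=float(a["period_s"])
            )
        modes.append(
            AcqModeSpec(
                name=m["name"],
                kind=m["kind"],
                sensor_id=m["sensor"],
                sampling_hz=float(m.get("sampling_hz", 0.0)),
                input_array_len=int(m.get("array_len", 0)),
                coordinator_period_s=float(m.get("period_s", 0.0)),
                function_calls=calls,
                stages=tuple(m.get("stages", ["parking"])),
                activation=activation,
            )
        )
    return modes
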