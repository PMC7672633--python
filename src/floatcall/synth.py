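"""Synthetic hydrophone scenes: ocean-like noise, D-call chirps, transients.

Every detector in this package is exercised on scenes built here, so the
generators are deterministic under a seed and carry their own ground truth.
A D-call is modelled as a narrow-band downward frequency sweep (typically
80 -> 20 Hz) with a raised-cosine amplitude taper; a seismic-like transient
is a tapered broadband noise burst. Scenes are sums of event waveforms over
Gaussian background noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AudioSegment",
    "SyntheticEvent",
    "AnnotationList",
    "gen_noise",
    "gen_dcall",
    "gen_transient",
    "gen_scene",
    "gen_benchmark_scene",
]


@dataclass(frozen=True)
class AudioSegment:
    """A sampled pressure signal.

    Parameters
    ----------
    samples
        Dimensionless amplitude, nominal range [-1, 1].
    sample_rate_hz
        Sampling frequency, > 0.
    start_time_s
        Absolute time of the first sample.
    """

    samples: np.ndarray
    sample_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.start_time_s < 0:
            raise ValueError("start_time_s must be non-negative")
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64)
        )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class SyntheticEvent:
    """One event to be placed in a scene.

    ``kind`` is "dcall" (downward sweep, needs f_start_hz > f_end_hz) or
    "transient" (broadband burst; the frequency fields are ignored).
    """

    kind: str
    onset_s: float
    duration_s: float
    amplitude: float = 1.0
    f_start_hz: float = 80.0
    f_end_hz: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("dcall", "transient"):
            raise ValueError(f"unknown event kind: {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.kind == "dcall" and not self.f_start_hz > self.f_end_hz >= 0:
            raise ValueError("a D-call sweeps downward: f_start_hz > f_end_hz >= 0")


@dataclass
class AnnotationList:
    """Ground-truth onsets, as (onset_s, label) pairs sorted by onset."""

    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e[0])

    def onsets(self, label: str | None = None) -> list[float]:
        return [t for t, lab in self.events if label is None or lab == label]

    def __len__(self) -> int:
        return len(self.events)


def _check_duration(duration_s: float, sample_rate_hz: float) -> int:
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    return int(round(duration_s * sample_rate_hz))


def gen_noise(
    duration_s: float,
    sample_rate_hz: float = 200.0,
    rms_level: float = 0.05,
    seed: int = 0,
) -> AudioSegment:
    """Gaussian background noise with a requested RMS level.

    Identical seeds give bit-identical samples.
    """
    n = _check_duration(duration_s, sample_rate_hz)
    if rms_level < 0:
        raise ValueError("rms_level must be non-negative")
    rng = np.random.default_rng(seed)
    samples = rng.normal(0.0, 1.0, n) * rms_level
    return AudioSegment(samples, sample_rate_hz)


def _taper(n: int, fade_frac: float = 0.1) -> np.ndarray:
    """Raised-cosine fade-in/out over ``fade_frac`` of each end."""
    from scipy.signal.windows import tukey

    # tukey alpha is the *total* tapered fraction (both ends combined)
    return tukey(n, alpha=min(1.0, 2.0 * fade_frac))


def gen_dcall(
    onset_s: float,
    duration_s: float = 4.0,
    f_start_hz: float = 80.0,
    f_end_hz: float = 20.0,
    amplitude: float = 1.0,
    sample_rate_hz: float = 200.0,
    curvature: float = 1.0,
) -> AudioSegment:
    """A narrow-band downward frequency sweep emulating a blue-whale D-call.

    The instantaneous frequency decreases from ``f_start_hz`` to ``f_end_hz``
    following f(t) = f_start + (f_end - f_start) * (t/d)**curvature; the
    default ``curvature=1`` is a linear sweep. A raised-cosine taper (10% of
    each end) removes onset/offset clicks.
    """
    n = _check_duration(duration_s, sample_rate_hz)
    nyquist = sample_rate_hz / 2.0
    if not f_start_hz > f_end_hz >= 0:
        raise ValueError("downward sweep requires f_start_hz > f_end_hz >= 0")
    if f_start_hz >= nyquist:
        raise ValueError("f_start_hz must be below the Nyquist frequency")
    if curvature <= 0:
        raise ValueError("curvature must be positive")
    t = np.arange(n) / sample_rate_hz
    # phase(t) = 2*pi * integral of f; closed form for the power-law sweep
    frac = (t / duration_s) ** curvature
    phase = 2.0 * np.pi * (
        f_start_hz * t
        + (f_end_hz - f_start_hz) * t * frac / (curvature + 1.0)
    )
    samples = amplitude * np.sin(phase) * _taper(n)
    return AudioSegment(samples, sample_rate_hz, start_time_s=onset_s)


def gen_transient(
    onset_s: float,
    duration_s: float = 5.0,
    amplitude: float = 1.0,
    sample_rate_hz: float = 40.0,
    seed: int = 0,
) -> AudioSegment:
    """A seismic-like broadband burst: tapered white noise at a given RMS."""
    n = _check_duration(duration_s, sample_rate_hz)
    rng = np.random.default_rng(seed)
    samples = amplitude * rng.normal(0.0, 1.0, n) * _taper(n)
    return AudioSegment(samples, sample_rate_hz, start_time_s=onset_s)


def gen_scene(
    events: list[SyntheticEvent],
    duration_s: float,
    sample_rate_hz: float = 200.0,
    noise_rms: float = 0.05,
    seed: int = 0,
) -> tuple[AudioSegment, AnnotationList]:
    """A full scene: background noise plus every event waveform, summed.

    Events may overlap; an event extending past the scene end is an error.
    The returned annotation list holds each event's onset and kind.
    """
    n = _check_duration(duration_s, sample_rate_hz)
    for ev in events:
        if ev.onset_s < 0 or ev.onset_s + ev.duration_s > duration_s:
            raise ValueError(
                f"event at {ev.onset_s} s (+{ev.duration_s} s) exceeds the "
                f"{duration_s} s scene"
            )
    rng = np.random.default_rng(seed)
    samples = rng.normal(0.0, 1.0, n) * noise_rms
    annotations: list[tuple[float, str]] = []
    for i, ev in enumerate(events):
        if ev.kind == "dcall":
            wave = gen_dcall(
                ev.onset_s, ev.duration_s, ev.f_start_hz, ev.f_end_hz,
                ev.amplitude, sample_rate_hz,
            )
        else:
            # per-event sub-seed keeps scenes reproducible event by event
            wave = gen_transient(
                ev.onset_s, ev.duration_s, ev.amplitude, sample_rate_hz,
                seed=(seed * 1000003 + i) % (2**31),
            )
        start = int(round(ev.onset_s * sample_rate_hz))
        stop = start + len(wave)
        samples[start:stop] += wave.samples
        annotations.append((ev.onset_s, ev.kind))
    return AudioSegment(samples, sample_rate_hz), AnnotationList(annotations)


def gen_benchmark_scene(
    seed: int,
    n_calls: int = 20,
    duration_s: float = 1800.0,
    sample_rate_hz: float = 200.0,
    call_amplitude: float = 0.5,
    noise_rms: float = 0.05,
    call_duration_s: float = 4.0,
    min_separation_s: float = 20.0,
) -> tuple[AudioSegment, AnnotationList]:
    """The standard detector benchmark: high-SNR 80->20 Hz sweeps in noise.

    Defaults place 20 four-second D-calls at uniform-random, well-separated
    onsets in 30 minutes of Gaussian noise at 200 Hz, with a 20 dB
    amplitude ratio between call and noise.
    """
    rng = np.random.default_rng(seed)
    margin = call_duration_s + min_separation_s
    while True:
        onsets = np.sort(rng.uniform(min_separation_s, duration_s - margin,
                                     n_calls))
        if n_calls < 2 or np.all(np.diff(onsets) > min_separation_s):
            break
    events = [
        SyntheticEvent("dcall", float(t), call_duration_s,
                       amplitude=call_amplitude)
        for t in onsets
    ]
    return gen_scene(events, duration_s, sample_rate_hz, noise_rms, seed)
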