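"""Rule-based blue-whale D-call detector.

A D-call is a narrow-band downward sweep, typically 80 -> 20 Hz. The
detector mirrors what a low-power acquisition board can run in real time:

1. per frame (64-sample FFT, 50% overlap, low-frequency mask), compute the
   peak-ratio statistic (max1 + max2) / (max5 + max6) over bin magnitudes —
   large only when one narrow band dominates the spectrum — and the
   frequency of the maximum-amplitude bin;
2. smooth the ratio series with an STA/LTA (short-term over long-term
   average) and open a candidate window while the smoothed value sits at or
   above a trigger threshold;
3. truncate the window's peak-frequency trajectory to the span between its
   maximum and the first following minimum, count downward / upward / stable
   bin transitions, and apply seven empirical validation checks;
4. record the trigger time of every window that passes all checks.

Every threshold is configurable; the defaults are in :class:`DcallConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectral import HOP, Spectrogram, compute_spectrogram
from .synth import AudioSegment

__all__ = [
    "RatioPoint",
    "StaLtaConfig",
    "TriggerWindow",
    "DcallFeatures",
    "Detection",
    "CheckParams",
    "DcallConfig",
    "peak_ratio",
    "stalta",
    "run_trigger",
    "truncate_trajectory",
    "count_transitions",
    "validate_dcall",
    "detect_dcalls",
]


@dataclass(frozen=True)
class RatioPoint:
    """Per-frame statistic: the peak ratio and the peak-bin frequency."""

    frame_time_s: float
    ratio: float
    peak_freq_hz: float
    peak_bin: int


@dataclass(frozen=True)
class StaLtaConfig:
    """STA/LTA operator parameters, in windows (frames) of the input series.

    The defaults (5, 15, 10) mirror a typical embedded declaration; note the
    trigger threshold is bounded above by ``lta_len / sta_len`` when both
    averages end at the current sample (see :func:`stalta`), so detector
    front-ends use their own, reachable threshold.
    """

    sta_len: int = 5
    lta_len: int = 15
    threshold: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.sta_len < self.lta_len):
            raise ValueError("need 0 < sta_len < lta_len")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class TriggerWindow:
    """A maximal run of frames whose smoothed ratio sat above the trigger."""

    start: int
    end: int  # inclusive frame index
    ratios: np.ndarray
    peak_freqs_hz: np.ndarray
    peak_bins: np.ndarray

    def __post_init__(self) -> None:
        n = self.end - self.start + 1
        if n < 1 or len(self.ratios) != n or len(self.peak_freqs_hz) != n:
            raise ValueError("inconsistent trigger window")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DcallFeatures:
    """Quantities the validation checks test, from one trigger window."""

    n_windows: int
    mean_ratio: float
    n_down: int
    n_up: int
    n_stable: int
    max_freq_hz: float
    max_jump_hz_per_span: float


@dataclass(frozen=True)
class Detection:
    onset_s: float
    features: DcallFeatures
    accepted: bool
    checks: tuple[bool, bool, bool, bool, bool, bool, bool]


@dataclass(frozen=True)
class CheckParams:
    """Thresholds of the seven validation checks (all strict comparisons
    except the jump limit, which is an upper bound)."""

    min_n_windows: int = 4          # length must be above this
    min_mean_ratio: float = 2.5
    down_vs_up_factor: float = 3.0  # n_down must exceed factor * n_up
    min_n_down: int = 2
    down_vs_stable_factor: float = 0.25
    min_max_freq_hz: float = 40.0
    max_jump_hz: float = 20.0       # over any span of <= jump_span_s
    jump_span_s: float = 0.8


@dataclass(frozen=True)
class DcallConfig:
    """End-to-end detector configuration.

    The STA/LTA smoothing lengths follow the embedded declaration example
    (5 and 15 frames). With overlapping averaging windows the smoothed ratio
    cannot exceed lta_len/sta_len = 3, and it hovers near 1 on stationary
    noise; the trigger threshold defaults to 1.5, calibrated once by
    simulation on synthetic scenes (the coefficients of this detector are
    meant to be settled that way) to sit above noise fluctuations and below
    the response to a narrow-band sweep.
    """

    sta_len: int = 5
    lta_len: int = 15
    trigger_threshold: float = 1.5
    lowfreq_cutoff_hz: float = 20.0
    window: str = "rectangular"
    ratio_cap: float = 1000.0
    min_bin_separation: int = 0   # optional spacing between the six maxima
    pretrigger_frames: int = 0
    checks: CheckParams = field(default_factory=CheckParams)


def peak_ratio(
    spectrum: np.ndarray, cap: float = 1000.0, min_bin_separation: int = 0
) -> float:
    """(max1 + max2) / (max5 + max6) over the bin magnitudes.

    ``max1..max6`` are the six largest bin values regardless of adjacency
    unless ``min_bin_separation`` > 0, in which case maxima are picked
    greedily with at least that many bins between any two. An all-zero
    spectrum returns 1 (no signal, no contrast); a zero denominator with a
    nonzero numerator returns ``cap``.
    """
    s = np.asarray(spectrum, dtype=np.float64)
    if s.ndim != 1 or len(s) < 6:
        raise ValueError("spectrum must be 1-D with at least 6 bins")
    if min_bin_separation > 0:
        picked: list[float] = []
        available = s.copy()
        for _ in range(6):
            k = int(np.argmax(available))
            picked.append(available[k])
            lo = max(0, k - min_bin_separation)
            available[lo : k + min_bin_separation + 1] = -np.inf
        v = np.array(picked)
    else:
        v = np.sort(s)[::-1][:6]
    num = v[0] + v[1]
    den = v[4] + v[5]
    if den == 0.0:
        return 1.0 if num == 0.0 else cap
    return float(num / den)


def stalta(series: np.ndarray, sta_len: int, lta_len: int) -> np.ndarray:
    """Short-term over long-term average of a non-negative series.

    output[i] = mean(series[i-sta_len+1 : i+1]) / mean(series[i-lta_len+1 : i+1]);
    during warm-up (fewer than the window's worth of samples available) the
    available prefix is used for both averages. Indices where the long-term
    mean is zero yield 0 (signal absent). Both windows end at the current
    sample, so the output never exceeds lta_len / sta_len.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("series must be a non-empty 1-D array")
    if np.any(x < 0):
        raise ValueError("series values must be non-negative")
    if not (0 < sta_len < lta_len):
        raise ValueError("need 0 < sta_len < lta_len")
    n = len(x)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(n)
    sta_n = np.minimum(i + 1, sta_len)
    lta_n = np.minimum(i + 1, lta_len)
    sta = (csum[i + 1] - csum[i + 1 - sta_n]) / sta_n
    lta = (csum[i + 1] - csum[i + 1 - lta_n]) / lta_n
    out = np.zeros(n)
    np.divide(sta, lta, out=out, where=lta > 0)
    return out


def run_trigger(
    points: list[RatioPoint],
    sta_len: int,
    lta_len: int,
    threshold: float,
    pretrigger_frames: int = 0,
) -> list[TriggerWindow]:
    """Segment a ratio series into maximal supra-threshold runs.

    The smoothed (STA/LTA) ratio opens a window when it reaches
    ``threshold`` (>=) and closes it when it drops below; a window still
    open at end-of-signal closes there. Each window carries the *raw*
    ratios and peak frequencies of its frames. ``pretrigger_frames``
    prepends that many frames before the trigger (the trigger itself lags
    the call onset slightly), default 0.
    """
    if not points:
        return []
    ratios = np.array([p.ratio for p in points])
    freqs = np.array([p.peak_freq_hz for p in points])
    bins_ = np.array([p.peak_bin for p in points])
    smoothed = stalta(ratios, sta_len, lta_len)
    above = smoothed >= threshold
    windows: list[TriggerWindow] = []
    start: int | None = None
    for i, hi in enumerate(above):
        if hi and start is None:
            start = i
        elif not hi and start is not None:
            windows.append(_make_window(start, i - 1, ratios, freqs, bins_,
                                        pretrigger_frames))
            start = None
    if start is not None:
        windows.append(_make_window(start, len(above) - 1, ratios, freqs,
                                    bins_, pretrigger_frames))
    return windows


def _make_window(start, end, ratios, freqs, bins_, pre) -> TriggerWindow:
    s = max(0, start - pre)
    return TriggerWindow(s, end, ratios[s:end + 1], freqs[s:end + 1],
                         bins_[s:end + 1])


def truncate_trajectory(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Keep the span from the trajectory maximum to the first later minimum.

    Spurious values cling to the edges of a trigger window; the retained
    sub-list runs from the (earliest) index of the maximum to the first
    local minimum after it, inclusive. With no later local minimum the
    sub-list runs to the end. Returns (sub-list, start offset).
    """
    v = np.asarray(values, dtype=np.float64)
    if len(v) == 0:
        raise ValueError("empty trajectory")
    i_max = int(np.argmax(v))
    i_min = len(v) - 1
    for j in range(i_max + 1, len(v) - 1):
        if v[j] < v[j + 1]:  # turns upward: j is the first minimum
            i_min = j
            break
    return v[i_max : i_min + 1], i_max


def count_transitions(values: np.ndarray) -> tuple[int, int, int]:
    """Count downward / upward / stable steps between consecutive values.

    Operates on bin-quantized frequencies; the three counts sum to
    ``len(values) - 1``.
    """
    v = np.asarray(values)
    if len(v) == 0:
        raise ValueError("empty trajectory")
    d = np.diff(v)
    return int(np.sum(d < 0)), int(np.sum(d > 0)), int(np.sum(d == 0))


def _max_jump(freqs_hz: np.ndarray, hop_s: float, span_s: float) -> float:
    """Largest |freq change| over any pair of points within ``span_s``."""
    n = len(freqs_hz)
    if n < 2:
        return 0.0
    k = max(1, int(np.floor(span_s / hop_s + 1e-9)))
    best = 0.0
    for lag in range(1, min(k, n - 1) + 1):
        jump = np.max(np.abs(freqs_hz[lag:] - freqs_hz[:-lag]))
        best = max(best, float(jump))
    return best


def extract_features(
    window: TriggerWindow, hop_s: float, jump_span_s: float = 0.8
) -> DcallFeatures:
    """Features of one trigger window after trajectory truncation.

    ``n_windows`` is the full trigger-to-detrigger length; the remaining
    statistics are computed over the truncated part of the trajectory (the
    truncation exists to drop spurious edge values, so the mean ratio uses
    the truncated span too).
    """
    kept_bins, off = truncate_trajectory(window.peak_bins)
    kept_freqs = window.peak_freqs_hz[off : off + len(kept_bins)]
    kept_ratios = window.ratios[off : off + len(kept_bins)]
    n_down, n_up, n_stable = count_transitions(kept_bins)
    return DcallFeatures(
        n_windows=len(window),
        mean_ratio=float(np.mean(kept_ratios)),
        n_down=n_down,
        n_up=n_up,
        n_stable=n_stable,
        max_freq_hz=float(np.max(kept_freqs)),
        max_jump_hz_per_span=_max_jump(kept_freqs, hop_s, jump_span_s),
    )


def validate_dcall(
    features: DcallFeatures, params: CheckParams | None = None
) -> tuple[bool, tuple[bool, ...]]:
    """Apply the seven empirical D-call checks.

    1. the detection spans more than ``min_n_windows`` successive windows;
    2. the mean peak ratio exceeds ``min_mean_ratio``;
    3. downward steps outnumber ``down_vs_up_factor`` times the upward ones;
    4. more than ``min_n_down`` downward steps;
    5. downward steps exceed ``down_vs_stable_factor`` times the stable ones;
    6. the maximum frequency exceeds ``min_max_freq_hz``;
    7. the peak frequency never changes by more than ``max_jump_hz`` across
       any pair of retained points within ``jump_span_s``.

    Accepted iff all seven hold. Comparisons 1-6 are strict.
    """
    p = params or CheckParams()
    f = features
    checks = (
        f.n_windows > p.min_n_windows,
        f.mean_ratio > p.min_mean_ratio,
        f.n_down > p.down_vs_up_factor * f.n_up,
        f.n_down > p.min_n_down,
        f.n_down > p.down_vs_stable_factor * f.n_stable,
        f.max_freq_hz > p.min_max_freq_hz,
        f.max_jump_hz_per_span <= p.max_jump_hz,
    )
    return all(checks), checks


def ratio_series(
    spec: Spectrogram, cap: float = 1000.0, min_bin_separation: int = 0
) -> list[RatioPoint]:
    """Per-frame peak ratio and peak-bin frequency from a (masked) spectrogram."""
    points = []
    for i in range(spec.n_frames):
        frame = spec.frames[i]
        k = int(np.argmax(frame))
        points.append(
            RatioPoint(
                frame_time_s=float(spec.frame_times_s[i]),
                ratio=peak_ratio(frame, cap=cap,
                                 min_bin_separation=min_bin_separation),
                peak_freq_hz=float(spec.bin_freqs_hz[k]),
                peak_bin=k,
            )
        )
    return points


def detect_dcalls(
    audio: AudioSegment, config: DcallConfig | None = None
) -> list[Detection]:
    """Run the full D-call pipeline on a segment.

    Framing -> masking -> ratio / peak-frequency series -> STA/LTA trigger
    -> truncation -> features -> validation. The onset of a detection is the
    time of its trigger frame. Processing is causal: each trigger decision
    depends only on past frames. A segment shorter than one long-term
    averaging span yields no detections (with a warning).
    """
    cfg = config or DcallConfig()
    min_samples = cfg.lta_len * HOP
    if len(audio) < min_samples:
        warnings.warn(
            "audio shorter than one LTA span; no detections possible",
            stacklevel=2,
        )
        return []
    spec = compute_spectrogram(
        audio, window=cfg.window, lowfreq_cutoff_hz=cfg.lowfreq_cutoff_hz
    )
    points = ratio_series(spec, cap=cfg.ratio_cap,
                          min_bin_separation=cfg.min_bin_separation)
    windows = run_trigger(points, cfg.sta_len, cfg.lta_len,
                          cfg.trigger_threshold, cfg.pretrigger_frames)
    detections = []
    for w in windows:
        features = extract_features(w, spec.hop_s, cfg.checks.jump_span_s)
        accepted, checks = validate_dcall(features, cfg.checks)
        detections.append(
            Detection(
                onset_s=float(spec.frame_times_s[w.start]),
                features=features,
                accepted=accepted,
                checks=checks,
            )
        )
    return detections
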