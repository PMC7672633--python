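"""Simplified seismic P-wave trigger.

The front end of a float-borne earthquake detector: high-pass the
hydrophone signal to suppress micro-seismic noise below ~1 Hz, then watch
the short-term over long-term average (10 s over 100 s) of the absolute
amplitude and emit a trigger time whenever it crosses a threshold. The
discrimination stage that would follow (wavelet bands against reference
distributions) is outside this package's scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .dcall import stalta
from .synth import AudioSegment

__all__ = ["SeismicConfig", "highpass", "detect_seismic_triggers"]


@dataclass(frozen=True)
class SeismicConfig:
    """Trigger parameters. The threshold has no canonical value and must be
    supplied; with overlapping averaging windows it is bounded above by
    lta_s / sta_s."""

    threshold: float
    highpass_cutoff_hz: float = 1.0
    sta_s: float = 10.0
    lta_s: float = 100.0
    filter_order: int = 4
    stride: int = 1  # samples between STA/LTA evaluations (1 = per-sample)

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not 0 < self.sta_s < self.lta_s:
            raise ValueError("need 0 < sta_s < lta_s")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def highpass(
    audio: AudioSegment, cutoff_hz: float = 1.0, order: int = 4
) -> AudioSegment:
    """Causal Butterworth high-pass filter.

    4th order by default: >= 20 dB attenuation one octave below the cutoff
    and a passband flat within 1 dB above twice the cutoff.
    """
    nyquist = audio.sample_rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError("cutoff must lie strictly between 0 and Nyquist")
    sos = sps.butter(order, cutoff_hz, btype="highpass",
                     fs=audio.sample_rate_hz, output="sos")
    filtered = sps.sosfilt(sos, audio.samples)
    return AudioSegment(filtered, audio.sample_rate_hz, audio.start_time_s)


def detect_seismic_triggers(
    audio: AudioSegment, cfg: SeismicConfig
) -> list[float]:
    """Trigger times where the amplitude STA/LTA crosses the threshold.

    The STA/LTA runs sample-wise on |x| of the high-passed signal (set
    ``cfg.stride`` > 1 to evaluate on a coarser grid, e.g. packet-wise). A
    trigger time is the time of the first sample of each maximal
    supra-threshold run. A segment shorter than one long-term span yields
    no triggers (with a warning).
    """
    fs = audio.sample_rate_hz
    lta_len = int(round(cfg.lta_s * fs))
    sta_len = int(round(cfg.sta_s * fs))
    if len(audio) < lta_len:
        warnings.warn(
            "audio shorter than one LTA span; no triggers possible",
            stacklevel=2,
        )
        return []
    amplitude = np.abs(highpass(audio, cfg.highpass_cutoff_hz,
                                cfg.filter_order).samples)
    if cfg.stride > 1:
        n = (len(amplitude) // cfg.stride) * cfg.stride
        amplitude = amplitude[:n].reshape(-1, cfg.stride).mean(axis=1)
        sta_len = max(1, sta_len // cfg.stride)
        lta_len = max(sta_len + 1, lta_len // cfg.stride)
    ratio = stalta(amplitude, sta_len, lta_len)
    above = ratio >= cfg.threshold
    # first sample of each maximal supra-threshold run
    starts = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    dt = cfg.stride / fs
    return [float(audio.start_time_s + i * dt) for i in starts]
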