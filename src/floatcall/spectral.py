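"""Short-time spectra as consumed by the D-call detector.

The detector works on 64-sample transforms with 50% overlap (hop 32) and
keeps the 32 non-negative-frequency bins below Nyquist; the Nyquist bin is
discarded. "Spectrum" here means linear magnitude (the downstream peak-ratio
statistic is scale-invariant, but linear magnitude is fixed for
reproducibility). Low-frequency bins — dominated by flow and micro-seismic
noise — are zeroed by a mask before any statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import AudioSegment

__all__ = [
    "Spectrogram",
    "frame_signal",
    "magnitude_spectrum",
    "mask_low_freq",
    "compute_spectrogram",
]

FRAME_LEN = 64
HOP = 32
N_BINS = FRAME_LEN // 2  # bins 0..31; the Nyquist bin is dropped


@dataclass(frozen=True)
class Spectrogram:
    """A sequence of 32-bin magnitude spectra.

    ``frames`` has shape (n_frames, 32); ``bin_freqs_hz`` are the bin center
    frequencies k * sample_rate / 64 for k = 0..31; ``frame_times_s`` are
    frame-start times; ``hop_s`` the frame advance in seconds.
    """

    frames: np.ndarray
    bin_freqs_hz: np.ndarray
    frame_times_s: np.ndarray
    hop_s: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def frame_signal(
    x: np.ndarray | AudioSegment, frame_len: int = FRAME_LEN, hop: int = HOP
) -> np.ndarray:
    """Slice a signal into contiguous windows advancing by ``hop`` samples.

    The trailing partial window is discarded; a signal shorter than one frame
    yields an empty (0, frame_len) array.
    """
    samples = x.samples if isinstance(x, AudioSegment) else np.asarray(x)
    n = len(samples)
    if n < frame_len:
        return np.empty((0, frame_len), dtype=np.float64)
    n_frames = (n - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return samples[idx].astype(np.float64)


def magnitude_spectrum(
    frame: np.ndarray, window: str = "rectangular"
) -> np.ndarray:
    """|FFT| of one 64-sample frame, bins 0..31 (DC to just below Nyquist).

    The default window is rectangular; ``window="hann"`` applies a Hann
    window first.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 1 or len(frame) != FRAME_LEN:
        raise ValueError(f"frame must have exactly {FRAME_LEN} samples")
    if window == "hann":
        frame = frame * np.hanning(FRAME_LEN)
    elif window != "rectangular":
        raise ValueError(f"unknown window: {window!r}")
    return np.abs(np.fft.rfft(frame)[:N_BINS])


def mask_low_freq(
    spectrum: np.ndarray, bin_freqs_hz: np.ndarray, cutoff_hz: float = 20.0
) -> np.ndarray:
    """Zero every bin whose center frequency is below ``cutoff_hz``.

    Works on a single spectrum or a (n_frames, n_bins) stack; idempotent.
    """
    if cutoff_hz < 0:
        raise ValueError("cutoff_hz must be non-negative")
    out = np.array(spectrum, dtype=np.float64, copy=True)
    out[..., np.asarray(bin_freqs_hz) < cutoff_hz] = 0.0
    return out


def compute_spectrogram(
    audio: AudioSegment,
    window: str = "rectangular",
    lowfreq_cutoff_hz: float | None = 20.0,
) -> Spectrogram:
    """Frame, transform and (optionally) low-frequency-mask a signal."""
    frames = frame_signal(audio)
    fs = audio.sample_rate_hz
    bin_freqs = np.arange(N_BINS) * fs / FRAME_LEN
    if frames.shape[0]:
        if window == "hann":
            frames = frames * np.hanning(FRAME_LEN)[None, :]
        mags = np.abs(np.fft.rfft(frames, axis=1)[:, :N_BINS])
    else:
        mags = np.empty((0, N_BINS))
    if lowfreq_cutoff_hz is not None:
        mags = mask_low_freq(mags, bin_freqs, lowfreq_cutoff_hz)
    hop_s = HOP / fs
    times = audio.start_time_s + hop_s * np.arange(frames.shape[0])
    return Spectrogram(mags, bin_freqs, times, hop_s)


def spectrogram_to_csv(spec: Spectrogram, path) -> None:
    """Debug dump: one row per frame, first column the frame time."""
    import pandas as pd

    df = pd.DataFrame(spec.frames, columns=[f"{f:.3f}Hz" for f in spec.bin_freqs_hz])
    df.insert(0, "time_s", spec.frame_times_s)
    df.to_csv(path, index=False)
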