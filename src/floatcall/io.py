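"""WAV and annotation-list I/O.

WAV files are written as 16-bit PCM mono (the dialect hydrophone archives
commonly use at low sample rates); float samples are clipped to [-1, 1]
before quantization. Annotation lists round-trip through CSV with the header
``onset_s,label``.
"""

from __future__ import annotations

import wave
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import AnnotationList, AudioSegment

__all__ = ["read_wav", "write_wav", "read_annotations", "write_annotations"]

_PCM16_FULL_SCALE = 32767.0


def write_wav(path: str | Path, segment: AudioSegment) -> None:
    """Write a segment as RIFF PCM, 16-bit mono."""
    clipped = np.clip(segment.samples, -1.0, 1.0)
    pcm = np.round(clipped * _PCM16_FULL_SCALE).astype("<i2")
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(2)
        w.setframerate(int(round(segment.sample_rate_hz)))
        w.writeframes(pcm.tobytes())


def read_wav(path: str | Path, start_time_s: float = 0.0) -> AudioSegment:
    """Read a mono 16-bit PCM WAV file into an AudioSegment in [-1, 1]."""
    with wave.open(str(path), "rb") as w:
        if w.getnchannels() != 1:
            raise ValueError("only mono WAV files are supported")
        if w.getsampwidth() != 2:
            raise ValueError("only 16-bit PCM WAV files are supported")
        rate = w.getframerate()
        pcm = np.frombuffer(w.readframes(w.getnframes()), dtype="<i2")
    samples = pcm.astype(np.float64) / _PCM16_FULL_SCALE
    return AudioSegment(samples, float(rate), start_time_s=start_time_s)


def write_annotations(path: str | Path, annotations: AnnotationList) -> None:
    df = pd.DataFrame(annotations.events, columns=["onset_s", "label"])
    df.to_csv(path, index=False)


def read_annotations(path: str | Path) -> AnnotationList:
    df = pd.read_csv(path)
    if not {"onset_s", "label"}.issubset(df.columns):
        raise ValueError("annotation CSV needs columns onset_s,label")
    return AnnotationList(
        [(float(t), str(lab)) for t, lab in zip(df["onset_s"], df["label"])]
    )
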