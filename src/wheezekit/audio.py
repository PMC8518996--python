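"""Audio containers and WAV I/O for chest-wall lung-sound recordings.

A recording holds one mandatory *lung* channel (the chest-contact
microphone) and an optional *ambient* channel (a second, room-facing
microphone used to veto environmental sounds). Samples are float64 in
[-1, 1]; files are plain PCM WAV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile


@dataclass
class AudioRecording:
    """Sampled chest-wall pressure signal(s).

    Parameters
    ----------
    lung : ndarray
        Lung-channel samples, float in [-1, 1].
    rate_hz : float
        Sampling rate in samples/s.
    ambient : ndarray, optional
        Ambient-channel samples, same length and rate as ``lung``.
    bit_depth : int
        Quantization used when the recording is written to disk.
    """

    lung: np.ndarray
    rate_hz: float
    ambient: np.ndarray | None = None
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.lung = np.asarray(self.lung, dtype=np.float64)
        if self.lung.ndim != 1:
            raise ValueError("lung channel must be one-dimensional")
        if self.lung.size == 0:
            raise ValueError("empty recording")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.ambient is not None:
            self.ambient = np.asarray(self.ambient, dtype=np.float64)
            if self.ambient.shape != self.lung.shape:
                raise ValueError("ambient channel must match lung channel length")

    @property
    def n_samples(self) -> int:
        return int(self.lung.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def channels(self) -> dict[str, np.ndarray]:
        out = {"lung": self.lung}
        if self.ambient is not None:
            out["ambient"] = self.ambient
        return out


def write_wav(path: str | Path, rec: AudioRecording) -> None:
    """Write a recording as PCM WAV (16-bit; lung channel first)."""
    if rec.bit_depth != 16:
        raise ValueError("only 16-bit PCM output is supported")
    scale = 32767.0
    if rec.ambient is None:
        data = np.clip(np.round(rec.lung * scale), -32768, 32767).astype(np.int16)
    else:
        stacked = np.stack([rec.lung, rec.ambient], axis=1)
        data = np.clip(np.round(stacked * scale), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(round(rec.rate_hz)), data)


def read_wav(path: str | Path) -> AudioRecording:
    """Read a PCM WAV file; channel 0 is the lung channel, channel 1 (if
    present) the ambient channel. 8/16/24/32-bit integer and float PCM
    are normalized to [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        x = data / 32768.0
        depth = 16
    elif data.dtype == np.int32:
        x = data / 2147483648.0
        depth = 32
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
        depth = 8
    else:  # float WAV
        x = data.astype(np.float64)
        depth = 32
    if x.ndim == 1:
        return AudioRecording(lung=x, rate_hz=float(rate), bit_depth=depth)
    return AudioRecording(
        lung=x[:, 0], rate_hz=float(rate), ambient=x[:, 1], bit_depth=depth
    )
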