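"""Spectrogram computation for wheeze-band detection.

The analysis chain mirrors the recording protocol: lung sounds are
resampled to 44.1 kHz, high-pass filtered at 50 Hz to suppress DC drift
and heart-sound rumble, and transformed with a 4096-point short-time FFT
(Hann window, 75% overlap). Power is expressed in dB relative to the
file maximum — recording gain is uncalibrated, so only relative levels
are meaningful — and floored at -120 dB.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .audio import AudioRecording

DB_FLOOR = -120.0


@dataclass
class Spectrogram:
    """Time-frequency power matrix in dB.

    ``power_db`` has shape (frames, bins); ``frame_times_s`` are window
    centers; ``ref_power`` is the linear power of the 0 dB reference
    (the file maximum), kept so linear power can be reconstructed.
    """

    power_db: np.ndarray
    frame_times_s: np.ndarray
    bin_freqs_hz: np.ndarray
    window_len: int
    hop: int
    fft_len: int
    rate_hz: float
    ref_power: float

    @property
    def n_frames(self) -> int:
        return self.power_db.shape[0]

    @property
    def frame_dt_s(self) -> float:
        return self.hop / self.rate_hz

    @property
    def bin_spacing_hz(self) -> float:
        return self.rate_hz / self.fft_len

    def linear_power(self) -> np.ndarray:
        return self.ref_power * 10.0 ** (self.power_db / 10.0)


def preprocess(rec: AudioRecording, target_rate_hz: float = 44100.0) -> AudioRecording:
    """Resample to the analysis rate and high-pass the lung channel.

    Resampling is polyphase (anti-aliased, deterministic); the high-pass
    is a zero-phase 4th-order Butterworth at 50 Hz. The ambient channel
    is resampled to stay sample-aligned but is not filtered.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")

    def _resample(x: np.ndarray) -> np.ndarray:
        if rec.rate_hz == target_rate_hz:
            return x
        frac = Fraction(target_rate_hz / rec.rate_hz).limit_denominator(1000)
        return signal.resample_poly(x, frac.numerator, frac.denominator)

    lung = _resample(rec.lung)
    sos = signal.butter(4, 50.0, btype="highpass", fs=target_rate_hz, output="sos")
    lung = signal.sosfiltfilt(sos, lung)
    ambient = _resample(rec.ambient) if rec.ambient is not None else None
    return AudioRecording(
        lung=lung, rate_hz=target_rate_hz, ambient=ambient, bit_depth=rec.bit_depth
    )


def compute_spectrogram(
    rec: AudioRecording,
    window_len: int = 4096,
    hop: int = 1024,
    fft_len: int = 4096,
    channel: str = "lung",
    ref_power: float | None = None,
) -> Spectrogram:
    """Hann-windowed short-time power spectrogram in dB re file max.

    ``ref_power`` overrides the 0 dB reference; pass the lung channel's
    reference when computing an ambient spectrogram so the two are on a
    common dB scale.
    """
    if fft_len < window_len:
        raise ValueError("fft_len must be >= window_len")
    if hop > window_len:
        raise ValueError("hop must be <= window_len")
    x = rec.channels[channel]
    if x.size < window_len:
        raise ValueError("recording shorter than one analysis window")

    n_frames = 1 + (x.size - window_len) // hop
    idx = np.arange(window_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * signal.get_window("hann", window_len, fftbins=True)
    power = np.abs(np.fft.rfft(frames, n=fft_len, axis=1)) ** 2

    if ref_power is None:
        ref_power = float(power.max())
    if ref_power <= 0:
        ref_power = 1.0  # silent file: everything lands on the floor
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(power / ref_power)
    power_db = np.maximum(power_db, DB_FLOOR)

    times = (np.arange(n_frames) * hop + window_len / 2.0) / rec.rate_hz
    freqs = np.fft.rfftfreq(fft_len, 1.0 / rec.rate_hz)
    return Spectrogram(
        power_db=power_db,
        frame_times_s=times,
        bin_freqs_hz=freqs,
        window_len=window_len,
        hop=hop,
        fft_len=fft_len,
        rate_hz=rec.rate_hz,
        ref_power=ref_power,
    )
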