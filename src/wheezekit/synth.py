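"""Synthetic lung-sound and cohort generation.

Two generators live here:

* :func:`synthesize_recording` builds 30-s tidal-breathing audio with
  injected tonal wheezes whose onset, duration, frequency trajectory and
  signal-to-noise ratio are fully specified, so the downstream detector
  can be scored against exact ground truth.
* :func:`simulate_cohort` draws per-subject wheeze-index values from
  per-group truncated-normal models, emulating a two-group pediatric
  cohort (bronchodilator responders whose wheezing disappears after
  inhalation vs. non-responders).

:func:`reference_group_models` returns the published two-group models
(91 responders, 111 non-responders) with the reported mean +/- SD of
each wheeze index and of the clinical covariates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import norm as _norm, truncnorm

from .audio import AudioRecording

INDEX_COLUMNS = ("count_per_30s", "duration_ms", "lowest_hz", "highest_hz", "maxint_hz")

#: Clinical covariates carried by the reference cohort models.
COVARIATE_COLUMNS = (
    "age_months",
    "height_cm",
    "weight_kg",
    "sao2_pct",
    "heart_rate_bpm",
    "resp_rate_per_min",
)


@dataclass(frozen=True)
class WheezeSpec:
    """One injected wheeze: a harmonic tone stack with linear frequency
    glide from ``start_hz`` to ``end_hz``.

    ``snr_db`` is the power of the fundamental tone relative to the
    breath-noise power measured in a +/-50 Hz band around the mean
    fundamental frequency — a bandwidth-independent, reproducible
    definition.
    """

    onset_s: float
    duration_ms: float
    start_hz: float
    end_hz: float
    n_harmonics: int = 1
    snr_db: float = 25.0

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")
        for f in (self.start_hz, self.end_hz):
            if not 20.0 <= f <= 4000.0:
                raise ValueError("wheeze frequencies must lie in [20, 4000] Hz")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_ms / 1000.0

    @property
    def max_hz(self) -> float:
        return max(self.start_hz, self.end_hz) * self.n_harmonics


@dataclass(frozen=True)
class BreathModel:
    """Tidal-breathing noise floor.

    Pink-weighted noise band-passed to ``noise_band``, amplitude-modulated
    by a raised-cosine respiratory cycle. ``level_db`` is the RMS level in
    dB re full scale; ``-inf`` silences the breath channel entirely.
    """

    respiratory_rate_per_min: float = 30.0
    noise_band: tuple[float, float] = (100.0, 1000.0)
    envelope_depth: float = 0.7
    level_db: float = -30.0

    def __post_init__(self) -> None:
        if self.respiratory_rate_per_min <= 0:
            raise ValueError("respiratory rate must be positive")
        lo, hi = self.noise_band
        if not lo < hi:
            raise ValueError("noise_band must satisfy low < high")
        if not 0.0 <= self.envelope_depth <= 1.0:
            raise ValueError("envelope_depth must be in [0, 1]")


@dataclass
class GroupModel:
    """Per-group wheeze-index distribution: independent normals truncated
    at zero, parameterized by the printed (mean, SD) pairs.

    ``correlation`` is an optional 5x5 Gaussian-copula correlation matrix
    over the indexes (order as :data:`INDEX_COLUMNS`); identity (the
    default) yields independent draws.
    """

    label: str
    n: int
    indexes: dict[str, tuple[float, float]]
    covariates: dict[str, tuple[float, float]] = field(default_factory=dict)
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        for name, (_, sd) in {**self.indexes, **self.covariates}.items():
            if sd < 0:
                raise ValueError(f"negative sd for {name!r}")


def reference_group_models() -> list[GroupModel]:
    """The two published group models: non-disappear (n=111, wheezing
    persists after beta2-agonist inhalation) and disappear (n=91).

    Index values are the printed group mean +/- SD of each wheeze index;
    covariates carry the printed clinical characteristics.
    """
    return [
        GroupModel(
            label="non-disappear",
            n=111,
            indexes={
                "count_per_30s": (9.8, 7.3),
                "duration_ms": (398.3, 205.9),
                "lowest_hz": (235.2, 106.8),
                "highest_hz": (592.6, 223.4),
                "maxint_hz": (396.1, 136.7),
            },
            covariates={
                "age_months": (48.8, 34.0),
                "height_cm": (97.4, 18.9),
                "weight_kg": (16.4, 8.4),
                "sao2_pct": (97.7, 1.5),
                "heart_rate_bpm": (121.8, 17.8),
                "resp_rate_per_min": (30.6, 10.8),
            },
        ),
        GroupModel(
            label="disappear",
            n=91,
            indexes={
                "count_per_30s": (4.1, 5.3),
                "duration_ms": (338.9, 202.7),
                "lowest_hz": (210.3, 144.6),
                "highest_hz": (460.8, 220.1),
                "maxint_hz": (331.3, 175.7),
            },
            covariates={
                "age_months": (51.5, 41.2),
                "height_cm": (98.6, 21.8),
                "weight_kg": (16.4, 8.2),
                "sao2_pct": (98.0, 1.4),
                "heart_rate_bpm": (107.3, 26.1),
                "resp_rate_per_min": (31.0, 14.1),
            },
        ),
    ]


# ---------------------------------------------------------------------------
# Audio synthesis
# ---------------------------------------------------------------------------

_RAMP_S = 0.010  # raised-cosine on/off ramp applied to each wheeze tone
_SILENT_BAND_POWER = 1e-8  # SNR reference when the breath floor is silent


def _pink_band_noise(
    n: int, rate_hz: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Pink-weighted (1/sqrt(f) amplitude) Gaussian noise band-passed to
    ``band`` with a zero-phase 4th-order Butterworth."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    weight = np.ones_like(freqs)
    nz = freqs > 0
    weight[nz] = 1.0 / np.sqrt(freqs[nz])
    weight[0] = 0.0
    pink = np.fft.irfft(spec * weight, n)
    sos = signal.butter(4, band, btype="bandpass", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, pink)


def _respiratory_envelope(
    n: int, rate_hz: float, rate_per_min: float, depth: float
) -> np.ndarray:
    t = np.arange(n) / rate_hz
    cycle = 0.5 - 0.5 * np.cos(2.0 * np.pi * (rate_per_min / 60.0) * t)
    return (1.0 - depth) + depth * cycle


def _band_power(
    x: np.ndarray, rate_hz: float, center_hz: float, halfwidth_hz: float = 50.0
) -> float:
    lo = max(center_hz - halfwidth_hz, 1.0)
    hi = min(center_hz + halfwidth_hz, rate_hz / 2.0 - 1.0)
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=rate_hz, output="sos")
    return float(np.mean(signal.sosfiltfilt(sos, x) ** 2))


def _tone(
    spec: WheezeSpec, rate_hz: float, amplitude: float
) -> np.ndarray:
    """Harmonic stack with 10-ms raised-cosine ramps; harmonics roll off
    at -6 dB per harmonic and are dropped above Nyquist."""
    n = int(round(spec.duration_ms / 1000.0 * rate_hz))
    t = np.arange(n) / rate_hz
    dur = spec.duration_ms / 1000.0
    inst_freq = spec.start_hz + (spec.end_hz - spec.start_hz) * t / dur
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / rate_hz
    tone = np.zeros(n)
    for k in range(1, spec.n_harmonics + 1):
        if k * max(spec.start_hz, spec.end_hz) >= rate_hz / 2.0:
            break
        tone += amplitude * 10 ** (-6.0 * (k - 1) / 20.0) * np.sin(k * phase)
    ramp_n = min(int(round(_RAMP_S * rate_hz)), n // 2)
    if ramp_n > 0:
        ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(ramp_n) / ramp_n)
        tone[:ramp_n] *= ramp
        tone[-ramp_n:] *= ramp[::-1]
    return tone


def synthesize_recording(
    breath: BreathModel | None = None,
    wheezes: list[WheezeSpec] | None = None,
    duration_s: float = 30.0,
    rate_hz: float = 44100.0,
    seed: int = 0,
    with_ambient: bool = False,
) -> AudioRecording:
    """Synthesize a chest-wall recording: breath-noise floor plus the
    requested wheeze tones, deterministically from ``seed``.

    The lung channel is soft-normalized so its peak never exceeds full
    scale. With ``with_ambient`` a second channel of independent
    band-passed noise (no tones) is added, mimicking the room-facing
    microphone of a dual-microphone pickup.
    """
    breath = breath if breath is not None else BreathModel()
    wheezes = list(wheezes) if wheezes else []
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rate_hz < 8000:
        raise ValueError("rate_hz must be >= 8000")
    for w in wheezes:
        if w.end_s > duration_s + 1e-9:
            raise ValueError(
                f"wheeze at onset {w.onset_s:.3f}s with duration "
                f"{w.duration_ms:.0f}ms extends past the {duration_s:.1f}s "
                "end of the recording"
            )
        if rate_hz < 2.0 * w.max_hz:
            raise ValueError(
                f"sampling rate {rate_hz:.0f} Hz is below twice the highest "
                f"requested frequency ({w.max_hz:.0f} Hz)"
            )

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    if np.isneginf(breath.level_db):
        floor = np.zeros(n)
    else:
        noise = _pink_band_noise(n, rate_hz, breath.noise_band, rng)
        noise *= 10 ** (breath.level_db / 20.0) / np.sqrt(np.mean(noise**2))
        floor = noise * _respiratory_envelope(
            n, rate_hz, breath.respiratory_rate_per_min, breath.envelope_depth
        )

    lung = floor.copy()
    for w in wheezes:
        i0 = int(round(w.onset_s * rate_hz))
        center = 0.5 * (w.start_hz + w.end_hz)
        if np.isneginf(breath.level_db):
            ref_power = _SILENT_BAND_POWER
        else:
            seg = floor[i0 : i0 + int(round(w.duration_ms / 1000.0 * rate_hz))]
            ref_power = max(_band_power(floor, rate_hz, center), _SILENT_BAND_POWER)
            # scale the reference by the local respiratory envelope so SNR
            # holds over the wheeze interval, not the whole file
            env_scale = float(np.mean(seg**2)) / max(float(np.mean(floor**2)), 1e-300)
            ref_power *= max(env_scale, 1e-6)
        amp = np.sqrt(2.0 * ref_power * 10 ** (w.snr_db / 10.0))
        tone = _tone(w, rate_hz, amp)
        lung[i0 : i0 + tone.size] += tone

    ambient = None
    if with_ambient:
        ambient = _pink_band_noise(n, rate_hz, breath.noise_band, rng)
        if np.isneginf(breath.level_db):
            ambient *= 0.0
        else:
            ambient *= 10 ** (breath.level_db / 20.0) / np.sqrt(np.mean(ambient**2))

    peak = max(np.max(np.abs(lung)), 1e-12)
    if ambient is not None:
        peak = max(peak, np.max(np.abs(ambient)))
    if peak > 0.98:
        lung *= 0.98 / peak
        if ambient is not None:
            ambient *= 0.98 / peak
    return AudioRecording(lung=lung, rate_hz=rate_hz, ambient=ambient)


def wheeze_truth_frame(wheezes: list[WheezeSpec]) -> pd.DataFrame:
    """Ground-truth table for a set of injected wheezes."""
    return pd.DataFrame(
        [
            {
                "onset_s": w.onset_s,
                "duration_ms": w.duration_ms,
                "start_hz": w.start_hz,
                "end_hz": w.end_hz,
                "n_harmonics": w.n_harmonics,
                "snr_db": w.snr_db,
            }
            for w in wheezes
        ],
        columns=["onset_s", "duration_ms", "start_hz", "end_hz", "n_harmonics", "snr_db"],
    )


def place_random_wheezes(
    k: int,
    rng: np.random.Generator,
    duration_s: float = 30.0,
    freq_range: tuple[float, float] = (200.0, 800.0),
    dur_range_ms: tuple[float, float] = (150.0, 600.0),
    min_gap_s: float = 0.35,
    snr_db: float = 25.0,
    max_glide_hz: float = 60.0,
) -> list[WheezeSpec]:
    """Place ``k`` non-overlapping wheezes at random, separated by at
    least ``min_gap_s`` so the detector cannot merge neighbours.

    Raises ``ValueError`` if ``k`` events cannot fit.
    """
    if k == 0:
        return []
    durs = rng.uniform(*dur_range_ms, size=k) / 1000.0
    edge = 0.25
    needed = durs.sum() + (k - 1) * min_gap_s + 2 * edge
    if needed > duration_s:
        raise ValueError(f"cannot place {k} wheezes in {duration_s}s")
    slack = duration_s - needed
    # distribute the slack randomly over the k+1 gaps
    cuts = np.sort(rng.uniform(0.0, slack, size=k))
    gaps = np.diff(np.concatenate([[0.0], cuts]))
    specs = []
    t = edge
    for i in range(k):
        t += gaps[i]
        f0 = rng.uniform(*freq_range)
        glide = rng.uniform(-max_glide_hz, max_glide_hz)
        f1 = float(np.clip(f0 + glide, freq_range[0], freq_range[1]))
        specs.append(
            WheezeSpec(
                onset_s=float(t),
                duration_ms=float(durs[i] * 1000.0),
                start_hz=float(f0),
                end_hz=f1,
                snr_db=snr_db,
            )
        )
        t += durs[i] + min_gap_s
    return specs


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _draw_truncated(
    mean: float, sd: float, u: np.ndarray
) -> np.ndarray:
    """Inverse-CDF draw from N(mean, sd) truncated at 0 given uniforms."""
    if sd == 0:
        return np.full(u.shape, max(mean, 0.0))
    a = (0.0 - mean) / sd
    return truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def simulate_cohort(
    groups: list[GroupModel], seed: int = 0
) -> pd.DataFrame:
    """Draw a synthetic cohort of per-subject wheeze indexes.

    Each index is drawn from the group's normal truncated at 0 (via a
    Gaussian copula when the group carries a non-identity correlation
    matrix). Covariates are drawn the same way. Index values are kept
    continuous; band counts in particular are not rounded, consistent
    with a non-integer decision cutoff on the count scale.

    Returns a DataFrame with columns ``subject_id, group`` followed by
    the index and covariate columns present in the models.
    """
    rng = np.random.default_rng(seed)
    rows: list[pd.DataFrame] = []
    sid = 0
    for g in groups:
        cols = list(g.indexes.keys())
        k = len(cols)
        corr = np.eye(k) if g.correlation is None else np.asarray(g.correlation)
        if corr.shape != (k, k):
            raise ValueError("correlation matrix shape must match index count")
        if g.n == 0:
            continue
        z = rng.multivariate_normal(np.zeros(k), corr, size=g.n, method="cholesky")
        u = np.clip(_norm.cdf(z), 1e-12, 1 - 1e-12)
        data = {
            "subject_id": [f"S{sid + i:04d}" for i in range(g.n)],
            "group": [g.label] * g.n,
        }
        for j, name in enumerate(cols):
            mean, sd = g.indexes[name]
            data[name] = _draw_truncated(mean, sd, u[:, j])
        for name, (mean, sd) in g.covariates.items():
            uc = rng.uniform(1e-12, 1 - 1e-12, size=g.n)
            data[name] = _draw_truncated(mean, sd, uc)
        rows.append(pd.DataFrame(data))
        sid += g.n
    if not rows:
        all_cols = ["subject_id", "group"]
        for g in groups:
            all_cols += [c for c in g.indexes if c not in all_cols]
            all_cols += [c for c in g.covariates if c not in all_cols]
        return pd.DataFrame(columns=all_cols)
    out = pd.concat(rows, ignore_index=True)
    out.attrs["seed"] = seed
    return out


def write_cohort_csv(path: str | Path, cohort: pd.DataFrame, header_comment: str | None = None) -> None:
    """Write a cohort table as CSV, optionally with a ``#`` comment line
    recording provenance."""
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    cohort.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
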