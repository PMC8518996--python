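"""Wheeze power band detection.

A wheeze power band is a persistent sharp ridge of spectral power — the
time-frequency signature of a continuous musical (tonal) adventitious
sound. Detection proceeds in three stages:

1. :func:`frame_peaks` — per-frame spectral peaks that stand out from a
   running-median background by a prominence margin;
2. :func:`link_ridges` — greedy nearest-frequency linking of peaks into
   ridges, tolerating small frame gaps; simultaneous ridges at distinct
   frequencies stay distinct, which is what makes polyphonic wheezing
   countable (one band per tonal component);
3. :func:`filter_bands` — the acceptance rules for an adventitious
   musical sound: dominant frequency above 100 Hz and duration above
   100 ms, plus an optional ambient-channel veto.

:func:`detect` composes the full chain from raw audio.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter

from .audio import AudioRecording
from .spectro import Spectrogram, compute_spectrogram, preprocess


@dataclass
class WheezePowerBand:
    """One detected ridge. Time extent is half-open [start_s, end_s);
    the track holds one (time, frequency, power) triple per frame where
    the ridge had a peak (gap frames are absent)."""

    start_s: float
    end_s: float
    track_times_s: np.ndarray
    track_freqs_hz: np.ndarray
    track_power_db: np.ndarray

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0

    @property
    def lowest_hz(self) -> float:
        return float(np.min(self.track_freqs_hz))

    @property
    def highest_hz(self) -> float:
        return float(np.max(self.track_freqs_hz))

    @property
    def maxint_hz(self) -> float:
        """Frequency at the track's maximum intensity (dominant frequency)."""
        return float(self.track_freqs_hz[int(np.argmax(self.track_power_db))])

    @property
    def mean_power_db(self) -> float:
        return float(np.mean(self.track_power_db))


@dataclass(frozen=True)
class DetectorConfig:
    """Detector thresholds.

    ``min_duration_ms`` and ``min_dominant_hz`` default to the CORSA
    wheeze criteria (duration over 100 ms, dominant frequency over
    100 Hz). The remaining knobs control ridge extraction:

    * ``prominence_db`` — required peak height above the running-median
      spectral background within ``background_halfwidth_hz``; the default
      was calibrated so breath-noise-only audio yields essentially no
      peaks while tones a few dB above the local noise band still do.
    * ``max_jump_hz`` / ``max_gap_frames`` — frame-to-frame continuity:
      a ridge may move at most 50 Hz per hop and survive a single
      dropped frame, preserving "continuous" without splitting vibrato.
    * ``edge_trim_db`` — band extent is trimmed to frames within this
      margin of the track's peak power, undoing the temporal smearing of
      the analysis window at band onset/offset.
    * ``min_track_occupancy`` — fraction of the band's spanned frames
      that must actually carry a peak; sparse gap-bridged chains of
      isolated noise excursions fail this continuity requirement while
      genuine tonal ridges are near-fully occupied.
    * ``flatness_reject`` — frames whose spectral flatness over the
      search band exceeds this ceiling are treated as broadband artifact
      (e.g. microphone-skin friction) and contribute no peaks.
    * ``ambient_veto_db`` — if set and an ambient channel exists, bands
      whose ambient power is within this margin of lung power over the
      band footprint are rejected as environmental sound.
    """

    search_band_hz: tuple[float, float] = (100.0, 2500.0)
    prominence_db: float = 18.0
    background_halfwidth_hz: float = 250.0
    max_jump_hz: float = 50.0
    max_gap_frames: int = 1
    min_duration_ms: float = 100.0
    min_dominant_hz: float = 100.0
    edge_trim_db: float = 8.0
    min_track_occupancy: float = 0.7
    flatness_reject: float = 0.75
    ambient_veto_db: float | None = None
    target_rate_hz: float = 44100.0
    window_len: int = 4096
    hop: int = 1024
    fft_len: int = 4096

    def __post_init__(self) -> None:
        lo, hi = self.search_band_hz
        if not 0 < lo < hi:
            raise ValueError("search_band_hz must satisfy 0 < low < high")
        for name in ("prominence_db", "background_halfwidth_hz", "max_jump_hz",
                     "min_duration_ms", "min_dominant_hz", "edge_trim_db"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if not 0.0 < self.min_track_occupancy <= 1.0:
            raise ValueError("min_track_occupancy must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown detector config keys: {sorted(unknown)}")
        d = dict(d)
        if "search_band_hz" in d:
            d["search_band_hz"] = tuple(d["search_band_hz"])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            f.name: (list(v) if isinstance(v := getattr(self, f.name), tuple) else v)
            for f in fields(self)
        }


FramePeaks = list[list[tuple[float, float]]]


def frame_peaks(spec: Spectrogram, cfg: DetectorConfig) -> FramePeaks:
    """Per-frame spectral peaks within the search band.

    A bin is a peak if it is a local maximum and exceeds the running
    median of its +/-``background_halfwidth_hz`` neighbourhood by at
    least ``prominence_db``. Frames flatter than ``flatness_reject``
    (spectral flatness of linear power over the search band) yield no
    peaks.
    """
    lo, hi = cfg.search_band_hz
    band = (spec.bin_freqs_hz >= lo) & (spec.bin_freqs_hz <= hi)
    freqs = spec.bin_freqs_hz[band]
    pdb = spec.power_db[:, band]
    p = 10.0 ** (pdb / 10.0)  # relative linear power; ref cancels in ratios

    half_bins = max(int(round(cfg.background_halfwidth_hz / spec.bin_spacing_hz)), 1)
    bg = median_filter(p, size=(1, 2 * half_bins + 1), mode="nearest")
    with np.errstate(divide="ignore", invalid="ignore"):
        prom_db = 10.0 * np.log10(np.where(bg > 0, p / bg, np.inf))

    local_max = np.zeros_like(p, dtype=bool)
    local_max[:, 1:-1] = (p[:, 1:-1] > p[:, :-2]) & (p[:, 1:-1] >= p[:, 2:])
    is_peak = local_max & (prom_db >= cfg.prominence_db)

    flat = np.exp(np.mean(np.log(np.maximum(p, 1e-30)), axis=1)) / np.maximum(
        np.mean(p, axis=1), 1e-30
    )
    is_peak[flat > cfg.flatness_reject, :] = False

    out: FramePeaks = []
    for i in range(spec.n_frames):
        cols = np.flatnonzero(is_peak[i])
        out.append([(float(freqs[j]), float(pdb[i, j])) for j in cols])
    return out


def link_ridges(
    peaks: FramePeaks, cfg: DetectorConfig, spec: Spectrogram
) -> list[WheezePowerBand]:
    """Link per-frame peaks into ridges by greedy nearest-frequency
    matching (closest pairs first, each |Δf| <= ``max_jump_hz``).
    Ridges survive up to ``max_gap_frames`` missing frames; unmatched
    peaks open new ridges. Returns unfiltered bands."""
    open_ridges: list[dict] = []
    closed: list[dict] = []
    for i, frame in enumerate(peaks):
        still_open = []
        for r in open_ridges:
            if i - r["last_frame"] - 1 > cfg.max_gap_frames:
                closed.append(r)
            else:
                still_open.append(r)
        open_ridges = still_open

        # greedy matching, smallest frequency distance first
        pairs = []
        for pi, (f, _) in enumerate(frame):
            for ri, r in enumerate(open_ridges):
                d = abs(f - r["last_freq"])
                if d <= cfg.max_jump_hz:
                    pairs.append((d, pi, ri))
        pairs.sort()
        used_p: set[int] = set()
        used_r: set[int] = set()
        for d, pi, ri in pairs:
            if pi in used_p or ri in used_r:
                continue
            used_p.add(pi)
            used_r.add(ri)
            f, pw = frame[pi]
            r = open_ridges[ri]
            r["frames"].append(i)
            r["freqs"].append(f)
            r["powers"].append(pw)
            r["last_frame"] = i
            r["last_freq"] = f
        for pi, (f, pw) in enumerate(frame):
            if pi not in used_p:
                open_ridges.append(
                    {
                        "frames": [i],
                        "freqs": [f],
                        "powers": [pw],
                        "last_frame": i,
                        "last_freq": f,
                    }
                )
    closed.extend(open_ridges)

    dt = spec.frame_dt_s
    bands = []
    for r in closed:
        band = _ridge_to_band(r, spec, cfg.edge_trim_db, dt)
        if band is not None:
            bands.append(band)
    bands.sort(key=lambda b: (b.start_s, b.lowest_hz))
    return bands


_EDGE_CROSS_DB = 6.0  # half-amplitude point: window half-covers the tone edge


def _ridge_to_band(
    ridge: dict, spec: Spectrogram, edge_trim_db: float, dt: float
) -> WheezePowerBand | None:
    """Convert a raw ridge to a band.

    Track membership is trimmed to frames within ``edge_trim_db`` of the
    track peak (window smearing makes a tone bleed into neighbouring
    frames). The time extent is then refined to sub-frame resolution by
    linearly interpolating where the track power crosses 6 dB below its
    peak — the point at which the analysis window half-covers the sound's
    true onset/offset."""
    all_powers = np.asarray(ridge["powers"])
    all_times = spec.frame_times_s[np.asarray(ridge["frames"])]
    keep = all_powers >= all_powers.max() - edge_trim_db
    first, last = int(np.argmax(keep)), len(keep) - 1 - int(np.argmax(keep[::-1]))
    sl = slice(first, last + 1)
    freqs = np.asarray(ridge["freqs"])[sl]
    powers = all_powers[sl]
    times = all_times[sl]

    thr = all_powers.max() - _EDGE_CROSS_DB
    above = np.flatnonzero(all_powers >= thr)
    i0, i1 = int(above[0]), int(above[-1])

    def _cross(inner: int, outer: int) -> float:
        p_in, p_out = all_powers[inner], all_powers[outer]
        if p_in == p_out:
            return float(all_times[outer])
        frac = (p_in - thr) / (p_in - p_out)
        return float(all_times[inner] + frac * (all_times[outer] - all_times[inner]))

    start = _cross(i0, i0 - 1) if i0 > 0 else float(all_times[i0] - dt / 2.0)
    end = _cross(i1, i1 + 1) if i1 < all_powers.size - 1 else float(all_times[i1] + dt / 2.0)
    if end <= start:  # degenerate single-frame ridge
        start, end = float(times[0] - dt / 2.0), float(times[-1] + dt / 2.0)
    return WheezePowerBand(
        start_s=start,
        end_s=end,
        track_times_s=times,
        track_freqs_hz=freqs,
        track_power_db=powers,
    )


def filter_bands(
    bands: Sequence[WheezePowerBand],
    cfg: DetectorConfig,
    ambient_spec: Spectrogram | None = None,
    lung_spec: Spectrogram | None = None,
) -> list[WheezePowerBand]:
    """Apply the musical-sound acceptance rules: keep bands lasting more
    than ``min_duration_ms`` with dominant frequency above
    ``min_dominant_hz``; optionally veto bands that are as loud on the
    ambient channel as on the chest channel."""
    dt_s = cfg.hop / cfg.target_rate_hz
    kept = []
    for b in bands:
        if b.duration_ms <= cfg.min_duration_ms + 1e-6:  # strict "over", fp-safe
            continue
        if b.maxint_hz <= cfg.min_dominant_hz:
            continue
        spanned = max(int(round((b.end_s - b.start_s) / dt_s)), 1)
        if b.track_freqs_hz.size / spanned < cfg.min_track_occupancy:
            continue
        if (
            cfg.ambient_veto_db is not None
            and ambient_spec is not None
            and _ambient_margin_db(b, lung_spec, ambient_spec) < cfg.ambient_veto_db
        ):
            continue
        kept.append(b)
    return kept


def _ambient_margin_db(
    band: WheezePowerBand, lung: Spectrogram, ambient: Spectrogram
) -> float:
    """Mean lung-minus-ambient power margin (dB) over the band footprint.
    Both spectrograms must share axes and dB reference."""
    margins = []
    for t, f in zip(band.track_times_s, band.track_freqs_hz):
        i = int(np.argmin(np.abs(lung.frame_times_s - t)))
        j = int(np.argmin(np.abs(lung.bin_freqs_hz - f)))
        margins.append(lung.power_db[i, j] - ambient.power_db[i, j])
    return float(np.mean(margins))


def detect(
    rec: AudioRecording, cfg: DetectorConfig | None = None
) -> list[WheezePowerBand]:
    """Full detection chain: preprocess, spectrogram, peak picking,
    ridge linking, acceptance filtering. Bands are sorted by start time."""
    cfg = cfg if cfg is not None else DetectorConfig()
    rec = preprocess(rec, cfg.target_rate_hz)
    spec = compute_spectrogram(rec, cfg.window_len, cfg.hop, cfg.fft_len)
    peaks = frame_peaks(spec, cfg)
    bands = link_ridges(peaks, cfg, spec)
    ambient_spec = None
    if rec.ambient is not None and cfg.ambient_veto_db is not None:
        ambient_spec = compute_spectrogram(
            rec, cfg.window_len, cfg.hop, cfg.fft_len,
            channel="ambient", ref_power=spec.ref_power,
        )
    return filter_bands(bands, cfg, ambient_spec=ambient_spec, lung_spec=spec)
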