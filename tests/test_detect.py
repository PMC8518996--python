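"""Peak picking, ridge linking and the acceptance rules."""

import numpy as np
import pytest

from wheezekit import (
    AudioRecording,
    BreathModel,
    DetectorConfig,
    WheezeSpec,
    compute_spectrogram,
    detect,
    filter_bands,
    frame_peaks,
    link_ridges,
    synthesize_recording,
)
from wheezekit.detect import WheezePowerBand
from wheezekit.spectro import Spectrogram


def _toy_spectrogram(n_frames=40, rate=44100.0, fft_len=4096, hop=1024):
    freqs = np.fft.rfftfreq(fft_len, 1.0 / rate)
    times = (np.arange(n_frames) * hop + fft_len / 2.0) / rate
    return Spectrogram(
        power_db=np.full((n_frames, freqs.size), -120.0),
        frame_times_s=times,
        bin_freqs_hz=freqs,
        window_len=fft_len,
        hop=hop,
        fft_len=fft_len,
        rate_hz=rate,
        ref_power=1.0,
    )


def _band(duration_ms, maxint_hz, lowest=None, highest=None):
    lo = lowest if lowest is not None else maxint_hz
    hi = highest if highest is not None else maxint_hz
    dt = 1024.0 / 44100.0
    n = max(int(round(duration_ms / 1000.0 / dt)), 2)  # fully occupied track
    freqs = np.linspace(lo, hi, n)
    powers = np.full(n, -20.0)
    powers[int(np.argmin(np.abs(freqs - maxint_hz)))] = -10.0
    return WheezePowerBand(
        start_s=1.0,
        end_s=1.0 + duration_ms / 1000.0,
        track_times_s=1.0 + dt * np.arange(n),
        track_freqs_hz=freqs,
        track_power_db=powers,
    )


class TestFramePeaks:
    def test_silence_yields_no_peaks(self, default_cfg):
        rec = AudioRecording(np.zeros(44100), 44100.0)
        peaks = frame_peaks(compute_spectrogram(rec), default_cfg)
        assert all(len(p) == 0 for p in peaks)

    def test_single_tone_one_peak_per_frame(self, default_cfg):
        rec = synthesize_recording(
            BreathModel(),
            [WheezeSpec(0.5, 4000.0, 400.0, 400.0, snr_db=20)],
            5.0, 44100.0, seed=6,
        )
        spec = compute_spectrogram(rec)
        peaks = frame_peaks(spec, default_cfg)
        interior = (spec.frame_times_s > 0.7) & (spec.frame_times_s < 4.3)
        n_frames = n_single = 0
        for sel, plist in zip(interior, peaks):
            if not sel:
                continue
            n_frames += 1
            near_tone = [f for f, _ in plist if abs(f - 400.0) <= spec.bin_spacing_hz]
            assert len(near_tone) == 1  # the tone peak, exactly once
            n_single += len(plist) == 1
        # stray breath-noise peaks are rare
        assert n_single / n_frames > 0.9

    def test_white_noise_false_peak_audit(self, default_cfg, rng):
        """At the default prominence, fewer than 5% of white-noise frames
        carry any peak."""
        rec = AudioRecording(rng.standard_normal(30 * 44100) * 0.1, 44100.0)
        peaks = frame_peaks(compute_spectrogram(rec), default_cfg)
        frac = np.mean([len(p) > 0 for p in peaks])
        assert frac < 0.05

    def test_flat_frames_vetoed(self, default_cfg):
        spec = _toy_spectrogram(n_frames=5)
        # perfectly flat spectrum with one mild bump: flatness ~ 1
        spec.power_db[:] = -30.0
        spec.power_db[:, 100] = -29.0
        cfg = DetectorConfig(prominence_db=0.5, flatness_reject=0.9)
        assert all(len(p) == 0 for p in frame_peaks(spec, cfg))


class TestLinkRidges:
    def _peaks(self, spec, chains):
        """chains: list of {frame: freq} dicts."""
        out = [[] for _ in range(spec.n_frames)]
        for chain in chains:
            for fr, fq in chain.items():
                out[fr].append((fq, -10.0))
        return out

    def test_single_chain_one_ridge(self, default_cfg):
        spec = _toy_spectrogram()
        peaks = self._peaks(spec, [{i: 400.0 for i in range(5, 17)}])
        bands = link_ridges(peaks, default_cfg, spec)
        assert len(bands) == 1
        assert bands[0].track_freqs_hz.size == 12

    def test_simultaneous_chains_stay_distinct(self, default_cfg):
        spec = _toy_spectrogram()
        peaks = self._peaks(
            spec,
            [{i: 300.0 for i in range(5, 17)}, {i: 600.0 for i in range(5, 17)}],
        )
        bands = link_ridges(peaks, default_cfg, spec)
        assert len(bands) == 2
        assert {round(b.lowest_hz) for b in bands} == {300, 600}

    def test_gap_within_tolerance_bridged(self, default_cfg):
        spec = _toy_spectrogram()
        chain = {i: 400.0 for i in range(5, 17) if i != 10}
        bands = link_ridges(self._peaks(spec, [chain]), default_cfg, spec)
        assert len(bands) == 1
        assert bands[0].track_freqs_hz.size == 11

    def test_gap_beyond_tolerance_splits(self, default_cfg):
        spec = _toy_spectrogram()
        chain = {i: 400.0 for i in list(range(5, 11)) + list(range(14, 20))}
        bands = link_ridges(self._peaks(spec, [chain]), default_cfg, spec)
        assert len(bands) == 2

    def test_jump_beyond_max_opens_new_ridge(self, default_cfg):
        spec = _toy_spectrogram()
        chain = {i: (400.0 if i < 11 else 600.0) for i in range(5, 17)}
        bands = link_ridges(self._peaks(spec, [chain]), default_cfg, spec)
        assert len(bands) == 2


class TestFilterBands:
    def test_short_band_rejected(self, default_cfg):
        assert filter_bands([_band(80.0, 400.0)], default_cfg) == []

    def test_low_dominant_frequency_rejected(self, default_cfg):
        assert filter_bands([_band(500.0, 90.0)], default_cfg) == []

    def test_compliant_band_kept(self, default_cfg):
        assert len(filter_bands([_band(250.0, 400.0)], default_cfg)) == 1

    def test_boundary_values_excluded(self, default_cfg):
        # the criteria are strict inequalities: over 100 ms, over 100 Hz
        assert filter_bands([_band(100.0, 400.0)], default_cfg) == []
        assert filter_bands([_band(250.0, 100.0)], default_cfg) == []

    def test_sparse_track_fails_continuity(self, default_cfg):
        """A gap-bridged chain occupying under 70% of its spanned frames
        is not a continuous sound."""
        b = _band(250.0, 400.0)
        sparse = WheezePowerBand(
            start_s=b.start_s,
            end_s=b.end_s,
            track_times_s=b.track_times_s[::3],
            track_freqs_hz=b.track_freqs_hz[::3],
            track_power_db=b.track_power_db[::3],
        )
        assert filter_bands([sparse], default_cfg) == []


class TestDetect:
    def test_no_injection_no_bands(self, noise_recording, default_cfg):
        assert detect(noise_recording, default_cfg) == []

    def test_single_wheeze_recovered(self, tone_recording, default_cfg):
        rec, spec = tone_recording
        bands = detect(rec, default_cfg)
        assert len(bands) == 1
        b = bands[0]
        assert abs(b.start_s - spec.onset_s) < 0.05
        assert abs(b.duration_ms - spec.duration_ms) <= 1024 / 44100 * 1000
        assert abs(b.maxint_hz - spec.start_hz) <= 2 * 44100 / 4096

    def test_amplitude_scale_invariance(self, tone_recording, default_cfg):
        rec, _ = tone_recording
        scaled = AudioRecording(rec.lung * 0.25, rec.rate_hz)
        assert len(detect(scaled, default_cfg)) == len(detect(rec, default_cfg))

    def test_criterion_monotonicity(self, tone_recording):
        rec, _ = tone_recording
        base = len(detect(rec, DetectorConfig()))
        stricter_dur = len(detect(rec, DetectorConfig(min_duration_ms=300.0)))
        stricter_freq = len(detect(rec, DetectorConfig(min_dominant_hz=500.0)))
        assert stricter_dur <= base
        assert stricter_freq <= base

    def test_emitted_band_invariants(self, breath, default_cfg, rng):
        from wheezekit import place_random_wheezes

        specs = place_random_wheezes(6, rng)
        rec = synthesize_recording(breath, specs, 30.0, 44100.0, seed=77)
        for b in detect(rec, default_cfg):
            assert b.lowest_hz <= b.maxint_hz <= b.highest_hz
            assert b.duration_ms > default_cfg.min_duration_ms
            assert b.end_s > b.start_s

    def test_ambient_veto_rejects_environmental_tone(self):
        """A tone present identically on both channels is environmental
        sound, not a chest-wall wheeze."""
        rec = synthesize_recording(
            BreathModel(), [WheezeSpec(2.0, 400.0, 500.0, 500.0)],
            10.0, 44100.0, seed=8, with_ambient=True,
        )
        leaky = AudioRecording(rec.lung, rec.rate_hz, ambient=rec.lung.copy())
        cfg = DetectorConfig(ambient_veto_db=6.0)
        assert detect(leaky, cfg) == []
        # with an independent ambient channel the band survives
        assert len(detect(rec, cfg)) == 1


class TestDetectorConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown detector config"):
            DetectorConfig.from_dict({"prominence": 8})

    def test_roundtrip(self):
        cfg = DetectorConfig(prominence_db=12.0)
        assert DetectorConfig.from_dict(cfg.to_dict()) == cfg

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(min_duration_ms=0.0)
        with pytest.raises(ValueError):
            DetectorConfig(search_band_hz=(500.0, 100.0))
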