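"""End-to-end reproducible runs.

A :class:`RunConfig` fixes every stage parameter plus a single global
seed; :func:`run_pipeline` then executes

    simulate cohort -> synthesize per-subject audio -> detect bands ->
    compute indexes -> diagnostic evaluation -> group statistics

and writes all artifacts (cohort.csv, audio_indexes.csv, bands/,
summary.json, group_table.csv, correlations.csv, resolved config) into
the output directory. Identical config + seed reproduces every artifact
byte for byte: all randomness flows from ``numpy.random.SeedSequence``
children of the global seed, and no timestamps are written.

Audio subjects: each synthetic subject belongs to one of the two groups;
their *injected* wheeze count is drawn from the group's count model
(rounded, capped by what physically fits in the recording), which makes
the injected truth the ground-truth label source for the end-to-end
diagnostic evaluation of the detector.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audio import write_wav
from .cohort_stats import summarize_cohort
from .detect import DetectorConfig, detect
from .diagnostics import LabeledScores, evaluate
from .indexes import bands_frame, compute_indexes
from .synth import (
    BreathModel,
    GroupModel,
    place_random_wheezes,
    reference_group_models,
    simulate_cohort,
    synthesize_recording,
    wheeze_truth_frame,
    write_cohort_csv,
)

log = logging.getLogger("wheezekit")

_MAX_INJECTED = 25  # most 150-600 ms wheezes that fit a 30-s file with margins


@dataclass
class RunConfig:
    """Fully-resolved pipeline configuration."""

    seed: int = 0
    out_dir: str = "wheezekit_run"
    log_level: str = "INFO"
    # audio-subject simulation
    audio_subjects_per_group: dict[str, int] = field(
        default_factory=lambda: {"non-disappear": 10, "disappear": 10}
    )
    duration_s: float = 30.0
    rate_hz: float = 44100.0
    snr_db: float = 25.0
    write_audio: bool = False
    breath: dict = field(default_factory=dict)
    detector: dict = field(default_factory=dict)
    # cohort simulation (index-level, no audio)
    simulate_reference_cohort: bool = True
    # diagnostics
    score: str = "count_per_30s"
    positive_class: str = "non-disappear"
    criterion: str = "youden"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        # validate nested sections eagerly
        BreathModel(**cfg.breath)
        DetectorConfig.from_dict(cfg.detector)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved(self) -> dict:
        """Config with every default made explicit. The output location
        is excluded so identical analyses hash identically wherever
        their artifacts land."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d["breath"] = dataclasses.asdict(BreathModel(**self.breath))
        d["breath"]["noise_band"] = list(d["breath"]["noise_band"])
        d["detector"] = DetectorConfig.from_dict(self.detector).to_dict()
        d["version"] = __version__
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in ``stage``."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _group_lookup(label: str) -> GroupModel:
    for g in reference_group_models():
        if g.label == label:
            return g
    raise ValueError(f"unknown group label {label!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the artifact paths and summary dict."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"wheezekit v{__version__} config={config.config_hash()} seed={config.seed}"
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("cohort", "audio"), ss.spawn(2)
    )}
    artifacts: dict = {"out_dir": str(out)}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as e:  # noqa: BLE001 - named-stage abort
                raise StageError(name, e) from e
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return deco

    # ---- reference cohort simulation -------------------------------------
    cohort_summary = {}
    if config.simulate_reference_cohort:
        @stage("cohort")
        def _():
            cohort = simulate_cohort(
                reference_group_models(),
                seed=int(seeds["cohort"].generate_state(1)[0] % (2**31)),
            )
            if cohort.empty:
                raise ValueError("simulated cohort is empty")
            write_cohort_csv(out / "cohort.csv", cohort, header)
            data = LabeledScores(
                scores=cohort[config.score].to_numpy(),
                labels=cohort["group"].to_numpy(),
                positive_class=config.positive_class,
            )
            cohort_summary["diagnostics"] = evaluate(data, config.criterion).as_dict()
            gt, ct = summarize_cohort(cohort)
            gt.to_csv(out / "group_table.csv", index=False)
            ct.to_csv(out / "correlations.csv", index=False)
            artifacts["cohort_csv"] = str(out / "cohort.csv")

    # ---- audio subjects ---------------------------------------------------
    audio_summary = {}
    n_total = sum(config.audio_subjects_per_group.values())
    if n_total == 0 and not config.simulate_reference_cohort:
        raise StageError("cohort", ValueError("cohort has no subjects"))
    if n_total > 0:
        @stage("audio")
        def _():
            if any(n < 0 for n in config.audio_subjects_per_group.values()):
                raise ValueError("negative subject count")
            if n_total == 0:
                raise ValueError("no audio subjects configured")
            breath = BreathModel(**config.breath)
            det_cfg = DetectorConfig.from_dict(config.detector)
            rows = []
            truth_rows = []
            child_seeds = seeds["audio"].spawn(n_total)
            i = 0
            bands_dir = out / "bands"
            bands_dir.mkdir(exist_ok=True)
            for label, n_subj in sorted(config.audio_subjects_per_group.items()):
                gm = _group_lookup(label)
                mean, sd = gm.indexes["count_per_30s"]
                for _k in range(n_subj):
                    rng = np.random.default_rng(child_seeds[i])
                    k_inj = int(np.clip(round(rng.normal(mean, sd)), 0, _MAX_INJECTED))
                    specs = place_random_wheezes(
                        k_inj, rng, duration_s=config.duration_s, snr_db=config.snr_db
                    )
                    rec = synthesize_recording(
                        breath, specs, config.duration_s, config.rate_hz,
                        seed=int(rng.integers(2**31)),
                    )
                    if config.write_audio:
                        write_wav(out / f"subject_{i:03d}.wav", rec)
                    bands = detect(rec, det_cfg)
                    idx = compute_indexes(bands, config.duration_s)
                    bands_frame(bands).to_csv(
                        bands_dir / f"subject_{i:03d}_bands.csv", index=False
                    )
                    row = {"subject_id": f"A{i:03d}", "group": label,
                           "injected_count": k_inj}
                    row.update(idx.as_dict())
                    rows.append(row)
                    tf = wheeze_truth_frame(specs)
                    tf.insert(0, "subject_id", f"A{i:03d}")
                    truth_rows.append(tf)
                    i += 1
            table = pd.DataFrame(rows)
            write_cohort_csv(out / "audio_indexes.csv", table, header)
            non_empty = [t for t in truth_rows if not t.empty]
            if non_empty:
                truth = pd.concat(non_empty, ignore_index=True)
            else:
                truth = wheeze_truth_frame([])
                truth.insert(0, "subject_id", pd.Series(dtype=str))
            truth.to_csv(out / "audio_truth.csv", index=False)
            data = LabeledScores(
                scores=table[config.score].to_numpy(),
                labels=table["group"].to_numpy(),
                positive_class=config.positive_class,
            )
            if data.n_pos and data.n_neg:
                audio_summary["diagnostics"] = evaluate(data, config.criterion).as_dict()
            audio_summary["recovery_exact"] = float(
                np.mean(table["injected_count"] == table["n_bands_raw"])
            )
            artifacts["audio_indexes_csv"] = str(out / "audio_indexes.csv")

    # ---- summary ----------------------------------------------------------
    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "cohort": cohort_summary,
        "audio": audio_summary,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "config_resolved.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=True)
    )
    artifacts["summary_json"] = str(out / "summary.json")
    artifacts["summary"] = summary
    return artifacts
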