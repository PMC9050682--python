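"""End-to-end orchestration: design -> synth -> preprocess -> decode -> bayes.

A run is fully determined by its :class:`RunConfig`: every stochastic stage
derives its seed from the master seed and the stage name, so reruns are
bit-identical and independent of the parallelism level.  Numeric tables
(tidy decoding CSV, per-contrast summary CSVs, onsets JSON) are the
canonical outputs; a provenance record stores the config, derived seeds and
package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import __version__
from .bayes import (
    DEFAULT_EXCLUDED_HALF_WIDTH,
    DEFAULT_PRIOR_SCALE,
    ONSET_BF_THRESHOLD,
    bf_timecourse,
    contrast_summary,
    onset_time,
)
from .decode import DEFAULT_LAMBDA, run_all_conditions
from .design import write_events_tsv
from .preprocess import preprocess_participant
from .synth import (
    DEFAULT_AMPLITUDE,
    DEFAULT_BETWEEN_SUBJECT_SD,
    ParticipantSimulation,
    simulate_participants,
)

logger = logging.getLogger(__name__)

#: Contrasts reported by a standard run.
RUN_CONTRASTS = (
    "cued_vs_chance",
    "uncued_vs_chance",
    "constant_vs_chance",
    "varied_vs_chance",
    "attention_effect",
    "attention_effect_constant",
    "attention_effect_varied",
    "expectation_effect",
    "interaction",
)

FIXTURE_SIZES = {
    # (n_participants, n_sequences, n_channels)
    "tiny": (2, 4, 16),
    "small": (10, 16, 32),
}


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    seed: int = 1
    n_participants: int = 20
    n_sequences: int = 64
    n_channels: int = 64
    amplitude_mean: float = DEFAULT_AMPLITUDE
    between_subject_sd: float = DEFAULT_BETWEEN_SUBJECT_SD
    fm_overrides: dict = field(default_factory=dict)
    l_freq: float = 0.1
    h_freq: float = 100.0
    target_hz: int = 250
    lam: float = DEFAULT_LAMBDA
    prior_scale: float = DEFAULT_PRIOR_SCALE
    prior_interval: float = DEFAULT_EXCLUDED_HALF_WIDTH
    n_boot: int = 10_000
    bf_threshold: float = ONSET_BF_THRESHOLD
    n_jobs: int = 1
    out_dir: str | None = None
    contrasts: tuple = RUN_CONTRASTS

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["contrasts"] = list(raw["contrasts"])
        Path(path).write_text(yaml.safe_dump(raw))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "contrasts" in raw:
            raw["contrasts"] = tuple(raw["contrasts"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str, participant: int | None = None) -> int:
    """Deterministic per-stage (optionally per-participant) seed below 2^31."""
    key = f"{master_seed}:{stage}" + ("" if participant is None else f":{participant}")
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _participant_curves(sim: ParticipantSimulation, cfg: RunConfig) -> pd.DataFrame:
    epochs = preprocess_participant(
        sim, l_freq=cfg.l_freq, h_freq=cfg.h_freq, target_hz=cfg.target_hz
    )
    return run_all_conditions(epochs, sim.session.participant_id, lam=cfg.lam)


def decode_group(cfg: RunConfig) -> pd.DataFrame:
    """Simulate, preprocess and decode every participant; tidy curves table.

    Results are identical for any ``n_jobs``: each participant's work is a
    pure function of the config.
    """
    sims = simulate_participants(
        cfg.n_participants,
        base_seed=stage_seed(cfg.seed, "synth"),
        n_sequences=cfg.n_sequences,
        n_channels=cfg.n_channels,
        fm_overrides=cfg.fm_overrides,
        amplitude_mean=cfg.amplitude_mean,
        between_subject_sd=cfg.between_subject_sd,
    )
    frames = Parallel(n_jobs=cfg.n_jobs)(
        delayed(_participant_curves)(sim, cfg) for sim in sims
    )
    return pd.concat(frames, ignore_index=True)


def group_inference(curves: pd.DataFrame, cfg: RunConfig) -> tuple[dict, dict]:
    """Per-contrast summaries and detected onsets from the curves table."""
    summaries: dict[str, pd.DataFrame] = {}
    onsets: dict[str, float | None] = {}
    for contrast in cfg.contrasts:
        rng = np.random.default_rng(stage_seed(cfg.seed, f"bootstrap:{contrast}"))
        summaries[contrast] = contrast_summary(
            curves,
            contrast,
            prior_scale=cfg.prior_scale,
            excluded_half_width=cfg.prior_interval,
            n_boot=cfg.n_boot,
            rng=rng,
        )
        bf = bf_timecourse(
            curves, contrast, cfg.prior_scale, cfg.prior_interval
        )
        onsets[contrast] = onset_time(bf, threshold=cfg.bf_threshold)
    return summaries, onsets


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full pipeline; write canonical outputs if an out_dir is set.

    Returns a dict with the curves table, per-contrast summary tables, the
    detected onsets and the output directory (or None).
    """
    logger.info("pipeline run: seed=%d, n=%d participants", cfg.seed, cfg.n_participants)
    try:
        curves = decode_group(cfg)
    except Exception:
        logger.exception("stage failed: simulate/decode")
        raise
    try:
        summaries, onsets = group_inference(curves, cfg)
    except Exception:
        logger.exception("stage failed: group inference")
        raise

    out_dir = None
    if cfg.out_dir is not None:
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out_dir / "config.yaml")
        curves.to_csv(out_dir / "decoding.csv", index=False)
        for contrast, summary in summaries.items():
            summary.to_csv(out_dir / f"summary_{contrast}.csv", index=False)
        (out_dir / "onsets.json").write_text(json.dumps(onsets, indent=2))
        provenance = {
            "package_version": __version__,
            "config_hash": cfg.config_hash(),
            "config": dataclasses.asdict(cfg),
            "stage_seeds": {
                "synth": stage_seed(cfg.seed, "synth"),
                "bootstrap": {
                    c: stage_seed(cfg.seed, f"bootstrap:{c}")
                    for c in cfg.contrasts
                },
            },
        }
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return {
        "curves": curves,
        "summaries": summaries,
        "onsets": onsets,
        "out_dir": out_dir,
    }


def make_fixtures(size: str, out_dir, seed: int = 7) -> Path:
    """Write a small self-contained fixture set (events TSVs + config).

    ``tiny`` (2 participants x 4 sequences x 16 channels) supports unit
    tests; ``small`` (10 x 16 x 32) supports integration tests.  Epoched
    data are regenerated from the config at load time rather than stored.
    """
    if size not in FIXTURE_SIZES:
        raise ValueError(f"unknown fixture size: {size!r}")
    n_part, n_seq, n_ch = FIXTURE_SIZES[size]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(
        seed=seed,
        n_participants=n_part,
        n_sequences=n_seq,
        n_channels=n_ch,
        n_boot=1000,
    )
    cfg.to_yaml(out / "config.yaml")
    sims = simulate_participants(
        n_part,
        base_seed=stage_seed(seed, "synth"),
        n_sequences=n_seq,
        n_channels=n_ch,
    )
    for sim in sims:
        write_events_tsv(
            sim.session, out / f"{sim.session.participant_id}_events.tsv"
        )
    manifest = {
        "size": size,
        "n_participants": n_part,
        "n_sequences": n_seq,
        "n_channels": n_ch,
        "seed": seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
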