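"""End-to-end orchestration: simulate -> assemble -> evaluate -> interpret.

A :class:`RunConfig` fully determines a run. The global seed fans out to
per-stage seeds through a counter scheme (``SeedSequence(seed).spawn``),
so each stage is independently reproducible; every derived seed is
recorded in the run manifest together with SHA-256 checksums of every
output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import assembly, evaluation, interpretation, simulate
from .model import ModelConfig, build_model, save_checkpoint, train

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "assemble", "evaluate", "interpret")


@dataclass
class RunConfig:
    n_control: int = 20
    n_concussed: int = 20
    seed: int = 0
    k_folds: int = 10
    #: fraction of concussed subjects returning for a follow-up session
    returning_fraction: float = 0.75
    #: fraction of returning subjects whose effect is removed at follow-up
    recovered_fraction: float = 0.4
    attenuation: dict = field(
        default_factory=lambda: {"N2b": 0.6, "P300": 0.6}
    )
    latency_delay_ms: dict = field(
        default_factory=lambda: {"N2b": 20.0, "P300": 20.0}
    )
    noise: dict = field(default_factory=dict)  # NoiseParams overrides
    model: dict = field(default_factory=dict)  # ModelConfig overrides
    rejection_fraction: float = 0.0
    verbosity: str = "INFO"

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.n_control < 1 or self.n_concussed < 1:
            raise ValueError("both groups need at least one subject")
        if not 0.0 <= self.returning_fraction <= 1.0:
            raise ValueError("returning_fraction must lie in [0, 1]")
        if not 0.0 <= self.recovered_fraction <= 1.0:
            raise ValueError("recovered_fraction must lie in [0, 1]")

    def effect(self) -> simulate.EffectSpec:
        return simulate.EffectSpec(
            attenuation=dict(self.attenuation),
            latency_delay_ms=dict(self.latency_delay_ms),
        )

    def noise_params(self) -> simulate.NoiseParams:
        return simulate.NoiseParams(**self.noise)

    def model_config(self) -> ModelConfig:
        return ModelConfig(**self.model)

    def stage_seeds(self) -> dict:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {
            stage: int(child.generate_state(1)[0] % 2**31)
            for stage, child in zip(_STAGES, children)
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Outputs under ``out_dir``: the resolved config, first/second-session
    tensors, per-subject predictions CSV, confusion JSON, mixed-ANOVA CSV
    (when both recovery groups are populated), the all-data model
    checkpoint, and the attribution summary (npz + CSV).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.verbosity)
    seeds = config.stage_seeds()
    manifest: dict = {"seeds": seeds, "outputs": {}, "stages_completed": []}

    def record(name: str, path: Path):
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    config.save(out / "config.yaml")
    record("config", out / "config.yaml")

    stage = "simulate"
    try:
        rng = np.random.default_rng(seeds[stage])
        cohort = simulate.generate_cohort(
            config.n_control,
            config.n_concussed,
            effect=config.effect(),
            noise=config.noise_params(),
            seed=int(rng.integers(2**31)),
            rejection_fraction=config.rejection_fraction,
        )
        concussed_ids = [s.subject_id for s in cohort.subjects if s.group == "concussed"]
        n_return = int(round(config.returning_fraction * len(concussed_ids)))
        returning = list(rng.choice(concussed_ids, size=n_return, replace=False))
        n_rec = int(round(config.recovered_fraction * n_return))
        recovered = list(rng.choice(returning, size=n_rec, replace=False))
        followup = (
            simulate.simulate_followup(
                cohort, returning, recovered,
                noise=config.noise_params(),
                seed=int(rng.integers(2**31)),
            )
            if returning
            else None
        )
        manifest["stages_completed"].append(stage)

        stage = "assemble"
        rng = np.random.default_rng(seeds[stage])
        tensor = assembly.assemble_cohort(cohort, seed=int(rng.integers(2**31)))
        tensor.save(out / "tensor_first")
        record("tensor_first", out / "tensor_first.npz")
        second = None
        if followup is not None:
            second = assembly.assemble_cohort(
                followup, seed=int(rng.integers(2**31)), session="second"
            )
            second.save(out / "tensor_second")
            record("tensor_second", out / "tensor_second.npz")
        manifest["stages_completed"].append(stage)

        stage = "evaluate"
        result = evaluation.run_cv(
            tensor,
            config=config.model_config(),
            seed=seeds[stage],
            k=config.k_folds,
            second_tensor=second,
            keep_models=second is not None,
        )
        result.per_subject_frame().to_csv(out / "subject_predictions.csv", index=False)
        record("subject_predictions", out / "subject_predictions.csv")
        conf = result.confusion.as_dict()
        conf["trial_accuracy"] = result.trial_accuracy
        with open(out / "confusion.json", "w") as fh:
            json.dump(conf, fh, indent=1)
        record("confusion", out / "confusion.json")
        if second is not None:
            recovery = {
                sid: ("SR" if sid in set(recovered) else "NSR") for sid in returning
            }
            table = evaluation.evaluate_longitudinal(result, second, recovery)
            table.to_csv(out / "longitudinal.csv", index=False)
            record("longitudinal", out / "longitudinal.csv")
            by_group = table["recovery"].value_counts()
            if len(by_group) == 2 and by_group.min() >= 2:
                anova = evaluation.mixed_anova(table)
                anova.to_csv(out / "anova.csv", index=False)
                record("anova", out / "anova.csv")
        manifest["stages_completed"].append(stage)

        stage = "interpret"
        rng = np.random.default_rng(seeds[stage])
        std = assembly.fit_standardizer(tensor)
        standardized = std.transform(tensor)
        model = build_model(config.model_config(), seed=int(rng.integers(2**31)))
        train(model, standardized.X, standardized.labels, seed=int(rng.integers(2**31)))
        save_checkpoint(model, out / "model_all_data")
        record("model_all_data", out / "model_all_data.npz")
        summary, _, _ = interpretation.explain_cohort(model, standardized)
        summary.save(out / "attributions")
        record("attributions", out / "attributions.npz")
        record("attributions_csv", out / "attributions.csv")
        manifest["stages_completed"].append(stage)
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = repr(err)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
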