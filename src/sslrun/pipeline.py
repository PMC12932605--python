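"""End-to-end orchestration: config validation, stage chaining, artifacts.

A single YAML-serializable RunConfig drives the chain
synthesize -> detect events -> build steps -> features -> train -> evaluate;
every intermediate table is written as delimited text and a manifest records
the seeds and stage row counts.  All randomness flows from config seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, features as features_mod, loads, models, synth
from .synth import STRUCTURES

log = logging.getLogger("sslrun")

VALID_MODELS = set(models.MODEL_TYPES)
VALID_SENSORS = {"dual", "pelvis", "foot"}


@dataclass
class RunConfig:
    """Validated configuration for one end-to-end run."""

    out_dir: str = "run_out"
    generator: synth.GeneratorConfig = field(default_factory=synth.GeneratorConfig)
    steps_per_trial: int | None = None
    sensors: str = "dual"
    model_types: tuple[str, ...] = ("mean", "f_nn")
    structures: tuple[str, ...] = STRUCTURES
    k_folds: int = 5
    fold_seed: int = 0
    learning_rate: float = 1e-4
    max_epochs: int = 500
    patience: int = 30

    def validate(self) -> "RunConfig":
        if self.sensors not in VALID_SENSORS:
            raise ValueError(f"sensors must be one of {sorted(VALID_SENSORS)}")
        unknown = set(self.model_types) - VALID_MODELS
        if unknown:
            raise ValueError(f"unknown model type(s): {sorted(unknown)}")
        unknown_s = set(self.structures) - set(STRUCTURES)
        if unknown_s:
            raise ValueError(f"unknown structure(s): {sorted(unknown_s)}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = synth.GeneratorConfig(**raw.pop("generator", {}))
        for key in ("model_types", "structures"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=gen, **raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["generator"] = asdict(self.generator)
        Path(path).write_text(yaml.safe_dump(d))


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute all stages, writing intermediate tables under config.out_dir.

    Returns the cross-validation report (one row per fold x model x
    structure plus macro-average rows).  Any stage failure aborts with the
    failing stage named; partial outputs stay on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.generator.seed, "fold_seed": config.fold_seed, "stages": {}}

    stage = "synth"
    try:
        subjects, trials = synth.generate_cohort(
            config.generator, n_steps_per_trial=config.steps_per_trial
        )
        synth.write_dataset(trials, subjects, out / "cohort")
        manifest["stages"][stage] = {"subjects": len(subjects), "trials": len(trials)}
        log.info("synth: %d subjects, %d trials", len(subjects), len(trials))

        stage = "steps"
        profiles = {s.subject_id: s for s in subjects}
        all_steps = []
        for trial in trials:
            all_steps.extend(loads.build_step_samples(trial, profiles[trial.subject_id]))
        table = loads.steps_table(all_steps)
        table.to_csv(out / "steps.csv", index=False)
        steps = [s for s in all_steps if s.accepted]
        manifest["stages"][stage] = {
            "candidate_steps": len(all_steps),
            "accepted_steps": len(steps),
        }
        log.info("steps: %d accepted of %d", len(steps), len(all_steps))

        stage = "features"
        fmat, names = features_mod.feature_matrix(steps, profiles, config.sensors)
        pd.DataFrame(fmat, columns=names).to_csv(out / "features.csv", index=False)
        manifest["stages"][stage] = {"rows": int(fmat.shape[0]), "columns": int(fmat.shape[1])}

        stage = "evaluate"
        specs = [
            models.ModelSpec(
                model_type=mt,
                sensors=config.sensors,
                structure=structure,
                learning_rate=config.learning_rate,
                max_epochs=config.max_epochs,
                patience=config.patience,
                seed=config.generator.seed,
            )
            for structure in config.structures
            for mt in config.model_types
        ]
        report = evaluate.cross_validate(
            subjects, steps, specs, k=config.k_folds, seed=config.fold_seed
        )
        report.to_csv(out / "report.csv", index=False)
        manifest["stages"][stage] = {"rows": int(len(report))}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report


def export_events(cohort_dir: str | Path, out_csv: str | Path) -> pd.DataFrame:
    """Detect gait events for every trial of a stored cohort and export them."""
    from . import imu as imu_mod

    trials, _subjects = synth.read_dataset(cohort_dir)
    rows = []
    for trial in trials:
        filt = imu_mod.filter_acceleration(trial.foot_acc, trial.imu_rate)
        ev = imu_mod.detect_gait_events(filt[2] / synth.G, trial.imu_rate)
        for ic, to in zip(ev.ic_indices, ev.to_indices):
            rows.append(
                {
                    "subject_id": trial.subject_id,
                    "trial_id": f"{trial.subject_id}_{trial.speed:.2f}",
                    "ic_index": int(ic),
                    "to_index": int(to),
                    "ic_time_s": ic / trial.imu_rate,
                    "to_time_s": to / trial.imu_rate,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out_csv, index=False)
    return df
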