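"""Subject-level cross-validation, metrics and uncertainty quantification.

Folds are partitions of *subjects*, never of steps, so no individual
contributes to both training and testing; within each fold the training
subjects are further split five-sixths / one-sixth into train and validation.
Scalers are fitted on training data only.  Curve metrics (MSE in BW^2, MAPE
in %, R^2) are pooled over steps x 100 timestamps within a fold and
macro-averaged (unweighted mean) across folds.  Characteristics (peak,
impulse, average loading rate) are derived from predicted curves with the
same operations used for the ground truth.  Predictive uncertainty comes
from Monte Carlo dropout: repeated stochastic forward passes with dropout
active at inference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from . import features as features_mod
from . import loads, models, synth
from .synth import STRUCTURES

MAPE_FLOOR_BW = 0.1  # curve MAPE only uses timestamps with truth >= this

#: imu_matrix row blocks per sensor set (pelvis acc, pelvis gyro, foot acc, foot gyro)
SENSOR_TS_ROWS = {
    "dual": list(range(12)),
    "pelvis": [0, 1, 2, 3, 4, 5],
    "foot": [6, 7, 8, 9, 10, 11],
}


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """Subject-level k-fold assignment with a nested validation split."""

    k: int
    seed: int
    test_subjects: list  # fold -> list of subject ids
    val_subjects: list  # fold -> list of subject ids (from the training pool)
    train_subjects: list  # fold -> list of subject ids

    def fold_of(self, subject_id: str) -> int:
        for f, subs in enumerate(self.test_subjects):
            if subject_id in subs:
                return f
        raise KeyError(subject_id)


def make_folds(subject_ids: list, k: int = 5, seed: int = 0) -> FoldPlan:
    """Balanced random subject partition; deterministic in ``seed``.

    Each fold's remaining subjects are split five-sixths train / one-sixth
    validation (at least one validation subject).
    """
    ids = list(subject_ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test = [list(chunk) for chunk in np.array_split(np.array(order, dtype=object), k)]
    val, train = [], []
    for f in range(k):
        pool = [s for s in order if s not in test[f]]
        n_val = max(1, int(round(len(pool) / 6.0)))
        val.append(pool[:n_val])
        train.append(pool[n_val:])
    plan = FoldPlan(k=k, seed=seed, test_subjects=test, val_subjects=val, train_subjects=train)
    _assert_no_leakage(plan)
    return plan


def _assert_no_leakage(plan: FoldPlan) -> None:
    for f in range(plan.k):
        a, b, c = map(set, (plan.train_subjects[f], plan.val_subjects[f], plan.test_subjects[f]))
        if a & b or a & c or b & c:
            raise AssertionError(f"fold {f}: train/val/test subject sets overlap")


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


@dataclass
class Scalers:
    ts_mean: np.ndarray | None = None  # (C,)
    ts_std: np.ndarray | None = None
    tab_mean: np.ndarray | None = None  # (F,)
    tab_std: np.ndarray | None = None

    def transform(self, data: models.ModelData) -> models.ModelData:
        x_ts = data.x_ts
        x_tab = data.x_tab
        if x_ts is not None and self.ts_mean is not None:
            x_ts = (x_ts - self.ts_mean) / self.ts_std
        if x_tab is not None and self.tab_mean is not None:
            x_tab = (x_tab - self.tab_mean) / self.tab_std
        return models.ModelData(x_ts=x_ts, x_tab=x_tab, y=data.y)


def standardize(
    train: models.ModelData, *others: models.ModelData
) -> tuple[list[models.ModelData], Scalers]:
    """Z-score per time-series channel (statistics pooled over training
    timestamps) and per tabular feature; the identical transform is applied
    to every other split.  Zero-variance features are centred, not divided.
    """
    if train.n == 0:
        raise ValueError("empty training set")
    sc = Scalers()
    if train.x_ts is not None:
        sc.ts_mean = train.x_ts.mean(axis=(0, 1))
        std = train.x_ts.std(axis=(0, 1))
        sc.ts_std = np.where(std > 0, std, 1.0)
    if train.x_tab is not None:
        sc.tab_mean = train.x_tab.mean(axis=0)
        std = train.x_tab.std(axis=0)
        sc.tab_std = np.where(std > 0, std, 1.0)
    out = [sc.transform(d) for d in (train, *others)]
    return out, sc


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def curve_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Pooled MSE (BW^2), MAPE (%) over timestamps with truth >= 0.1 BW, and
    pooled R^2 = 1 - SSres/SStot about the pooled mean."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    err = pred - truth
    mse = float(np.mean(err**2))
    mask = truth >= MAPE_FLOOR_BW
    mape = float(np.mean(np.abs(err[mask]) / truth[mask]) * 100.0) if mask.any() else np.nan
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return {"mse": mse, "mape": mape, "r2": r2}


def characteristic_metrics(
    pred_curves: np.ndarray,
    truth_curves: np.ndarray,
    stance_durations: np.ndarray,
    structure: str,
    cfg: loads.CharacteristicConfig | None = None,
) -> dict:
    """Per-characteristic MSE and MAPE over steps.

    Characteristics of the predicted curves use the predicted curve's own
    peak frame for the ``ic_to_peak`` loading-rate interval.  Steps whose
    loading-rate interval degenerates (peak in frame 0) are excluded from the
    loading-rate metric and counted.
    """
    cfg = cfg or loads.DEFAULT_CHARACTERISTIC_CONFIGS[structure]
    rows = {"peak": [], "impulse": [], "loading_rate": []}
    n_degenerate = 0
    for p, t, sd in zip(pred_curves, truth_curves, stance_durations):
        cp = loads.characteristics(p, sd, structure, cfg)
        ct = loads.characteristics(t, sd, structure, cfg)
        rows["peak"].append((cp.peak, ct.peak))
        rows["impulse"].append((cp.impulse, ct.impulse))
        if cp.loading_rate is None or ct.loading_rate is None:
            n_degenerate += 1
        else:
            rows["loading_rate"].append((cp.loading_rate, ct.loading_rate))
    out = {"loading_rate_excluded": n_degenerate}
    for name, pairs in rows.items():
        if not pairs:
            out[name] = {"mse": np.nan, "mape": np.nan}
            continue
        arr = np.array(pairs, dtype=float)
        err = arr[:, 0] - arr[:, 1]
        denom = np.maximum(np.abs(arr[:, 1]), 1e-9)
        out[name] = {
            "mse": float(np.mean(err**2)),
            "mape": float(np.mean(np.abs(err) / denom) * 100.0),
        }
    return out


def macro_average(per_fold: list[dict]) -> dict:
    """Unweighted mean of a metric dict across folds (NaN-aware)."""
    keys = per_fold[0].keys()
    return {k: float(np.nanmean([f[k] for f in per_fold])) for k in keys}


# ---------------------------------------------------------------------------
# Monte Carlo dropout
# ---------------------------------------------------------------------------


@dataclass
class UncertaintyEstimate:
    """Per-step predictive SDs from repeated stochastic forward passes."""

    curve_sd: np.ndarray  # (n_steps, 100) BW
    mean_curve: np.ndarray  # (n_steps, 100) BW
    peak_sd: np.ndarray  # (n_steps,)
    impulse_sd: np.ndarray
    loading_rate_sd: np.ndarray  # NaN where every pass degenerated
    n_passes: int


def mc_dropout(
    model,
    data: models.ModelData,
    stance_durations: np.ndarray,
    structure: str,
    n_passes: int = 100,
    seed: int = 0,
) -> UncertaintyEstimate:
    """Monte Carlo dropout: ``n_passes`` stochastic forward passes per step;
    SDs across passes per timestamp and per derived characteristic."""
    if not getattr(model, "has_dropout", False):
        raise ValueError("model has no dropout layers; MC dropout is undefined")
    rng = np.random.default_rng(seed)
    curves = np.stack([model.mc_forward(data, rng) for _ in range(n_passes)])  # (P, n, 100)
    cfg = loads.DEFAULT_CHARACTERISTIC_CONFIGS[structure]
    n = data.n
    peaks = np.empty((n_passes, n))
    imps = np.empty((n_passes, n))
    lrs = np.full((n_passes, n), np.nan)
    for p in range(n_passes):
        for i in range(n):
            ch = loads.characteristics(curves[p, i], float(stance_durations[i]), structure, cfg)
            peaks[p, i] = ch.peak
            imps[p, i] = ch.impulse
            if ch.loading_rate is not None:
                lrs[p, i] = ch.loading_rate
    # SDs are computed on pass-minus-first-pass residuals: mathematically
    # identical, but exactly zero (not rounding noise) when dropout is off
    return UncertaintyEstimate(
        curve_sd=(curves - curves[0]).std(axis=0),
        mean_curve=curves.mean(axis=0),
        peak_sd=(peaks - peaks[0]).std(axis=0),
        impulse_sd=(imps - imps[0]).std(axis=0),
        loading_rate_sd=np.nanstd(lrs - lrs[0], axis=0),
        n_passes=n_passes,
    )


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def steps_to_modeldata(
    steps: list[loads.StepSample],
    profiles: dict,
    structure: str,
    sensors: str = "dual",
    feature_names: list | None = None,
) -> tuple[models.ModelData, np.ndarray]:
    """Accepted steps -> (unstandardized ModelData, stance durations).

    Time series: (n, 100, C) with the sensor set's imu_matrix rows as
    channels.  Tabular: the full feature battery for the sensor set.
    """
    rows = SENSOR_TS_ROWS[sensors]
    x_ts = np.stack([st.imu_matrix[rows].T for st in steps])  # (n, 100, C)
    x_tab, _names = features_mod.feature_matrix(steps, profiles, sensors)
    k = STRUCTURES.index(structure)
    y = np.stack([st.ssl_curves[k] for st in steps])
    sd = np.array([st.stance_duration for st in steps])
    return models.ModelData(x_ts=x_ts, x_tab=x_tab, y=y), sd


def cohort_steps(
    subjects: list[synth.SubjectProfile],
    trials: list[synth.TrialRecording],
    accepted_only: bool = True,
) -> list[loads.StepSample]:
    """Run every trial through the stance pipeline and pool the steps."""
    profiles = {s.subject_id: s for s in subjects}
    out = []
    for trial in trials:
        out.extend(loads.build_step_samples(trial, profiles[trial.subject_id]))
    if accepted_only:
        out = [s for s in out if s.accepted]
    return out


def _subset(steps, subjects_wanted):
    wanted = set(subjects_wanted)
    return [s for s in steps if s.subject_id in wanted]


# ---------------------------------------------------------------------------
# cross-validation / ablation orchestrators
# ---------------------------------------------------------------------------


def evaluate_fold(
    model_spec: models.ModelSpec,
    train_steps,
    val_steps,
    test_steps,
    profiles: dict,
) -> dict:
    """Train one model on one fold and measure curves + characteristics."""
    structure, sensors = model_spec.structure, model_spec.sensors
    tr, sd_tr = steps_to_modeldata(train_steps, profiles, structure, sensors)
    va, _ = steps_to_modeldata(val_steps, profiles, structure, sensors)
    te, sd_te = steps_to_modeldata(test_steps, profiles, structure, sensors)
    (tr_s, va_s, te_s), scalers = standardize(tr, va, te)

    if model_spec.model_type == "mean":
        model = models.MeanRegressor(model_spec).fit(tr_s)
    elif model_spec.model_type == "linear_l1":
        model, _, _ = models.fit_linear_l1(tr_s, va_s, spec=model_spec)
    else:
        model = models.build(
            model_spec, ts_channels=tr_s.x_ts.shape[2], n_tab=tr_s.x_tab.shape[1]
        ).fit(tr_s, va_s)
    model.scalers = scalers
    pred = model.predict(te_s)
    out = curve_metrics(pred, te_s.y)
    out["characteristics"] = characteristic_metrics(pred, te_s.y, sd_te, structure)
    out["model"] = model
    out["test_data"] = te_s
    out["test_stance_durations"] = sd_te
    return out


def cross_validate(
    subjects,
    steps,
    model_specs: list[models.ModelSpec],
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Full subject-level k-fold CV for a list of model specs.

    Returns one row per fold x spec plus a per-spec macro-average row
    (fold = -1).
    """
    profiles = {s.subject_id: s for s in subjects}
    plan = make_folds([s.subject_id for s in subjects], k=k, seed=seed)
    rows = []
    for spec in model_specs:
        fold_metrics = []
        for f in range(k):
            res = evaluate_fold(
                spec,
                _subset(steps, plan.train_subjects[f]),
                _subset(steps, plan.val_subjects[f]),
                _subset(steps, plan.test_subjects[f]),
                profiles,
            )
            flat = {
                "fold": f,
                "model": spec.model_type,
                "sensors": spec.sensors,
                "structure": spec.structure,
                "mse": res["mse"],
                "mape": res["mape"],
                "r2": res["r2"],
            }
            for ch in ("peak", "impulse", "loading_rate"):
                flat[f"{ch}_mse"] = res["characteristics"][ch]["mse"]
                flat[f"{ch}_mape"] = res["characteristics"][ch]["mape"]
            fold_metrics.append(flat)
            rows.append(flat)
        macro = macro_average(
            [{k_: v for k_, v in fm.items() if isinstance(v, (int, float))} for fm in fold_metrics]
        )
        macro.update(fold=-1, model=spec.model_type, sensors=spec.sensors, structure=spec.structure)
        rows.append(macro)
    return pd.DataFrame(rows)


def ablate_channel(
    spec: models.ModelSpec,
    channel_index: int,
    train: models.ModelData,
    val: models.ModelData,
    test: models.ModelData,
) -> dict:
    """Retrain a single-sensor time-series model with one channel removed."""
    if spec.model_type != "ts_lstm":
        raise ValueError("channel ablation is defined for ts_lstm specs")
    n_ch = train.x_ts.shape[2]
    if not 0 <= channel_index < n_ch:
        raise ValueError(f"channel_index {channel_index} out of range (0..{n_ch - 1})")
    keep = [c for c in range(n_ch) if c != channel_index]

    def cut(d: models.ModelData) -> models.ModelData:
        return models.ModelData(x_ts=d.x_ts[:, :, keep], x_tab=d.x_tab, y=d.y)

    model = models.build(dc_replace(spec), ts_channels=n_ch - 1, n_tab=None).fit(
        cut(train), cut(val)
    )
    return curve_metrics(model.predict(cut(test)), test.y)


# ---------------------------------------------------------------------------
# the scaled end-to-end recovery experiment
# ---------------------------------------------------------------------------


@dataclass
class RecoveryResult:
    """Outputs of the scaled synthetic-cohort experiment."""

    metrics: dict  # (model_type, structure) -> curve metric dict
    characteristics: dict  # (model_type, structure) -> characteristic dict
    models: dict  # (model_type, structure) -> trained model
    test_data: dict  # structure -> standardized test ModelData
    test_stance: dict  # structure -> stance durations (s)
    n_steps: dict  # split -> step count
    plan: dict  # split -> subject ids


def run_recovery_experiment(
    seed: int = 0,
    n_subjects: int = 10,
    speeds: tuple[float, ...] = (2.22, 2.78, 3.33),
    steps_per_trial: int = 30,
    noise_scale: float = 0.3,
    structures: tuple[str, ...] = STRUCTURES,
    model_types: tuple[str, ...] = ("ts_lstm", "hybrid_lstm", "mean"),
    sensors: str = "dual",
    learning_rate: float = 1e-3,
    max_epochs: int = 120,
    patience: int = 30,
) -> RecoveryResult:
    """Generate a low-noise cohort, run the full stance pipeline, train the
    requested models on a subject-disjoint split and measure held-out
    performance.

    Desk-scale conditions: 10 subjects x 3 speeds x 30 steps with a single
    2-subject test split and 1 validation subject; the learning rate is
    raised to 1e-3 because the optimizer-step budget is roughly forty times
    smaller than in a full-size study (Adam's parameter displacement is
    bounded by lr x steps, so the study-scale 1e-4 cannot traverse the
    BW-scale targets here).
    """
    cfg = synth.GeneratorConfig(
        n_subjects=n_subjects, speeds=speeds, noise_scale=noise_scale, seed=seed
    )
    subjects, trials = synth.generate_cohort(cfg, n_steps_per_trial=steps_per_trial)
    steps = cohort_steps(subjects, trials)
    profiles = {s.subject_id: s for s in subjects}

    ids = [s.subject_id for s in subjects]
    rng = np.random.default_rng(seed + 1)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test_ids, val_ids, train_ids = order[:2], order[2:3], order[3:]
    split_steps = {
        "train": _subset(steps, train_ids),
        "val": _subset(steps, val_ids),
        "test": _subset(steps, test_ids),
    }

    metrics, chars, trained, test_data, test_stance = {}, {}, {}, {}, {}
    for structure in structures:
        tr, _ = steps_to_modeldata(split_steps["train"], profiles, structure, sensors)
        va, _ = steps_to_modeldata(split_steps["val"], profiles, structure, sensors)
        te, sd_te = steps_to_modeldata(split_steps["test"], profiles, structure, sensors)
        (tr_s, va_s, te_s), _sc = standardize(tr, va, te)
        test_data[structure] = te_s
        test_stance[structure] = sd_te
        for mt in model_types:
            spec = models.ModelSpec(
                model_type=mt,
                sensors=sensors,
                structure=structure,
                learning_rate=learning_rate,
                max_epochs=max_epochs,
                patience=patience,
                seed=seed + 100 + STRUCTURES.index(structure),
            )
            if mt == "mean":
                model = models.MeanRegressor(spec).fit(tr_s)
            elif mt == "linear_l1":
                model, _, _ = models.fit_linear_l1(tr_s, va_s, spec=spec)
            else:
                model = models.build(
                    spec, ts_channels=tr_s.x_ts.shape[2], n_tab=tr_s.x_tab.shape[1]
                ).fit(tr_s, va_s)
            pred = model.predict(te_s)
            metrics[(mt, structure)] = curve_metrics(pred, te_s.y)
            chars[(mt, structure)] = characteristic_metrics(pred, te_s.y, sd_te, structure)
            trained[(mt, structure)] = model
    return RecoveryResult(
        metrics=metrics,
        characteristics=chars,
        models=trained,
        test_data=test_data,
        test_stance=test_stance,
        n_steps={k_: len(v) for k_, v in split_steps.items()},
        plan={"train": train_ids, "val": val_ids, "test": test_ids},
    )
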