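"""End-to-end orchestration: simulate/load -> preprocess -> detect ->
characterize -> featurize -> train -> evaluate.

`run_all` produces, for each of the four vGRF characteristics, test and
LOSO-validation metrics for the Lasso model with and without speed, the
per-target literature comparison method (Alcantara-style for active peak /
impulse / contact time, Veras-style for the impact peak), and the
mean-regressor baseline, plus per-speed test metrics for the no-speed
model.  A manifest records the config hash, the seed, and the row counts
surviving each filtering stage, so every number in the report is
reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparison as cmp
from .characteristics import extract_characteristics
from .config import TARGETS, RunConfig, config_hash
from .events import (
    MatchedStep,
    detect_steps_accel,
    detect_steps_grf,
    filter_steps,
    match_steps,
)
from .features import KEY_COLUMNS, step_feature_row
from .modeling import (
    MeanRegressor,
    evaluate,
    evaluate_by_speed,
    fit_final,
    loso_cv,
    split_subjects,
)
from .signals import SampledSignal, TrialRecord, butterworth_lowpass, normalize_to_bw
from .simulate import SimulatedTrial, simulate_cohort

logger = logging.getLogger(__name__)

#: columns that never enter the Lasso design matrix
_NON_FEATURE = set(KEY_COLUMNS) | set(TARGETS) | {
    "est_active_peak",
    "est_contact_time",
    "est_impulse",
    "est_step_frequency",
    "est_impact_peak",
    "veras_found",
}


@dataclass
class TrialSteps:
    """Per-trial outcome of detection + characterization + featurization."""

    stance_rows: list[dict]
    step_rows: list[dict]
    counts: dict[str, int]


def preprocess_trial(record: TrialRecord, config: RunConfig) -> dict[str, SampledSignal]:
    """Filter all channels and normalize the force to body weight.

    Returns a dict with keys grf_n (filtered N), grf_bw, v, ap, ml and,
    when present, neck_v / l5_v.  If the cohort convention is raw
    (gravity-inclusive) g units, vertical channels are shifted to the
    gravity-subtracted convention first.
    """
    f = config.filter
    grf_f = butterworth_lowpass(record.grf, f.order, f.grf_cutoff_hz)

    def prep_accel(sig: SampledSignal) -> SampledSignal:
        out = butterworth_lowpass(sig, f.order, f.accel_cutoff_hz)
        if not config.cohort.gravity_subtracted and sig.label.endswith("v"):
            out = dataclasses.replace(out, values=out.values - 1.0)
        return out

    out = {
        "grf_n": grf_f,
        "grf_bw": normalize_to_bw(grf_f, record.subject.mass),
        "v": prep_accel(record.accel_v),
        "ap": prep_accel(record.accel_ap),
        "ml": prep_accel(record.accel_ml),
    }
    if record.accel_neck_v is not None and record.accel_l5_v is not None:
        out["neck_v"] = prep_accel(record.accel_neck_v)
        out["l5_v"] = prep_accel(record.accel_l5_v)
    return out


def process_trial(record: TrialRecord, trial_id: str, config: RunConfig) -> TrialSteps:
    """Detect, match, filter, characterize and featurize one trial."""
    sigs = preprocess_trial(record, config)
    ev = config.events
    grf_stances = detect_steps_grf(sigs["grf_n"], ev.grf_threshold_n)
    accel_stances = detect_steps_accel(sigs["v"], ev)
    matched = match_steps(accel_stances, grf_stances, ev.match_tolerance_s)
    kept = filter_steps(matched, sigs["grf_bw"], ev)

    veras_est = veras_found = None
    if "neck_v" in sigs:
        a_com = cmp.trunk_com_acceleration(sigs["neck_v"], sigs["l5_v"])
        veras_est, veras_found = cmp.veras_impact_peak(
            a_com, [s.accel_stance for s in kept], config=config.characteristics
        )

    est_vgrf = cmp.estimated_vgrf_bw(sigs["v"])

    def alcantara_row(step: MatchedStep) -> dict[str, float]:
        a = step.accel_stance
        window = est_vgrf.values[a.ic_index : a.to_index + 1]
        return {
            "est_active_peak": float(np.max(window)),
            "est_contact_time": a.duration,
            "est_impulse": float(np.trapezoid(window, dx=1.0 / est_vgrf.rate)),
            "est_step_frequency": 1.0 / step.step_period,
        }

    accel_channels = {k: sigs[k] for k in ("v", "ap", "ml")}
    stance_rows, step_rows = [], []
    n_impact = 0
    for i, step in enumerate(kept):
        chars = extract_characteristics(
            sigs["grf_bw"], step.grf_stance, config.characteristics
        )
        if chars.impact_peak is not None:
            n_impact += 1
        keys = {
            "subject_id": record.subject.subject_id,
            "trial": trial_id,
            "step_index": i,
            "speed": record.speed,
        }
        targets = {
            "active_peak": chars.active_peak,
            "impact_peak": np.nan if chars.impact_peak is None else chars.impact_peak,
            "impulse": chars.impulse,
            "contact_time": chars.contact_time,
        }
        extras = alcantara_row(step)
        if veras_est is not None:
            extras["est_impact_peak"] = veras_est[i]
            extras["veras_found"] = float(veras_found[i])
        for kind, rows in (("stance", stance_rows), ("entire_step", step_rows)):
            feats = step_feature_row(
                record.subject, record.speed, accel_channels, step, kind,
                config.features,
            )
            rows.append({**keys, **feats, **targets, **extras})

    counts = {
        "steps_detected_grf": len(grf_stances),
        "steps_detected_accel": len(accel_stances),
        "steps_matched": len(matched),
        "steps_filtered": len(kept),
        "steps_with_impact_peak": n_impact,
    }
    return TrialSteps(stance_rows, step_rows, counts)


def build_step_tables(
    trials: list[SimulatedTrial] | list[TrialRecord], config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Run detection/featurization over a cohort.

    Returns (stance_table, entire_step_table, counts); the two tables share
    keys, targets and baseline estimates and differ only in the windows the
    general features are computed on.
    """
    totals: dict[str, int] = {}
    stance_rows: list[dict] = []
    step_rows: list[dict] = []
    for trial in trials:
        record = trial.record if isinstance(trial, SimulatedTrial) else trial
        trial_id = f"{record.subject.subject_id}@{record.speed:g}"
        ts = process_trial(record, trial_id, config)
        stance_rows.extend(ts.stance_rows)
        step_rows.extend(ts.step_rows)
        for k, v in ts.counts.items():
            totals[k] = totals.get(k, 0) + v
    return pd.DataFrame(stance_rows), pd.DataFrame(step_rows), totals


def _model_columns(df: pd.DataFrame, use_speed: bool) -> list[str]:
    cols = [c for c in df.columns if c not in _NON_FEATURE]
    if use_speed:
        cols.append("speed_ms") if "speed_ms" not in cols else None
    else:
        cols = [c for c in cols if c != "speed_ms"]
    return cols


def _loso_ols(
    df: pd.DataFrame, x_cols: list[str], y_col: str
) -> dict[str, float]:
    """LOSO validation of an OLS baseline (no hyperparameters)."""
    metrics = []
    for held in sorted(df["subject_id"].unique()):
        tr = df[df["subject_id"] != held]
        va = df[df["subject_id"] == held]
        model = cmp.OlsModel.fit(tr[x_cols], tr[y_col].to_numpy())
        metrics.append(evaluate(model.predict(va[x_cols]), va[y_col].to_numpy()))
    return _mean_metrics(metrics, int(len(df)))


def _loso_mean(df: pd.DataFrame, y_col: str) -> dict[str, float]:
    metrics = []
    for held in sorted(df["subject_id"].unique()):
        tr = df[df["subject_id"] != held]
        va = df[df["subject_id"] == held]
        model = MeanRegressor.fit(tr[y_col].to_numpy())
        metrics.append(evaluate(model.predict(va), va[y_col].to_numpy()))
    return _mean_metrics(metrics, int(len(df)))


def _mean_metrics(metrics: list[dict[str, float]], n: int) -> dict[str, float]:
    return {
        "rmse": float(np.mean([m["rmse"] for m in metrics])),
        "mape_percent": float(np.mean([m["mape_percent"] for m in metrics])),
        "r2": float(np.mean([m["r2"] for m in metrics])),
        "n_steps": n,
    }


@dataclass
class PipelineResult:
    report: pd.DataFrame
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(out_dir / "report.csv", index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _report_row(target: str, model: str, split: str, metrics: dict, **extra):
    return {
        "characteristic": target,
        "model": model,
        "split": split,
        "rmse": metrics["rmse"],
        "mape": metrics["mape_percent"],
        "r2": metrics["r2"],
        "n_steps": metrics["n_steps"],
        **extra,
    }


def run_all(config: RunConfig, trials: list | None = None) -> PipelineResult:
    """Execute the full pipeline on a simulated (default) or supplied cohort."""
    root = np.random.SeedSequence(config.seed)
    sim_seed = int(root.spawn(2)[0].generate_state(1)[0] % (2**31))
    split_seed = int(root.spawn(2)[1].generate_state(1)[0] % (2**31))

    if trials is None:
        cohort_cfg = dataclasses.replace(config.cohort, seed=sim_seed)
        trials, _truth = simulate_cohort(cohort_cfg)
    stance_df, step_df, counts = build_step_tables(trials, config)
    if stance_df.empty:
        raise RuntimeError("pipeline aborted at detection: no steps survived")

    subjects = stance_df["subject_id"].tolist()
    train_subj, test_subj = split_subjects(subjects, config.test_fraction, split_seed)

    rows = []
    window_by_target = config.features.window_by_target
    for target in TARGETS:
        df = stance_df if window_by_target.get(target, "stance") == "stance" else step_df
        df = df[df[target].notna()]
        drop_targets = [t for t in TARGETS if t != target]
        df = df.drop(columns=drop_targets)
        train = df[df["subject_id"].isin(train_subj)]
        test = df[df["subject_id"].isin(test_subj)]
        if len(train) == 0 or len(test) == 0:
            raise RuntimeError(f"pipeline aborted at split for target {target}")

        # --- our method, with and without speed -------------------------
        for use_speed in (False, True):
            label = "ours_with_speed" if use_speed else "ours_no_speed"
            x_cols = _model_columns(df, use_speed)
            cols = ["subject_id"] + x_cols + [target]
            loso = loso_cv(train[cols], target, config.lambda_grid)
            rows.append(_report_row(target, label, "validation", loso.validation,
                                    selected_lambda=loso.selected_lambda))
            fit, _, test_pred = fit_final(
                train[cols], test[cols], target, loso.selected_lambda
            )
            truth = test[target].to_numpy(dtype=float)
            rows.append(_report_row(target, label, "test", evaluate(test_pred, truth),
                                    selected_lambda=loso.selected_lambda))
            if not use_speed:
                by_speed = evaluate_by_speed(
                    test_pred, truth, test["speed"].to_numpy(),
                    list(config.speed_groups) if config.speed_groups else None,
                )
                for speed, m in by_speed.items():
                    rows.append(_report_row(target, label, "test_speed", m, speed=speed))

        # --- comparison method ------------------------------------------
        if target == "impact_peak":
            if "veras_found" in df.columns:
                dv = df[df["veras_found"] > 0]
                trv = dv[dv["subject_id"].isin(train_subj)]
                tev = dv[dv["subject_id"].isin(test_subj)]
                rows.append(_report_row(
                    target, "comparison", "validation",
                    _loso_ols(trv, ["est_impact_peak"], target),
                ))
                model = cmp.OlsModel.fit(
                    trv[["est_impact_peak"]], trv[target].to_numpy()
                )
                rows.append(_report_row(
                    target, "comparison", "test",
                    evaluate(model.predict(tev[["est_impact_peak"]]),
                             tev[target].to_numpy()),
                ))
        else:
            est_col = cmp.ALCANTARA_MATCH[target]
            x_cols = [est_col, "mass_kg", "speed_ms"]
            rows.append(_report_row(
                target, "comparison", "validation", _loso_ols(train, x_cols, target),
            ))
            model = cmp.OlsModel.fit(train[x_cols], train[target].to_numpy())
            rows.append(_report_row(
                target, "comparison", "test",
                evaluate(model.predict(test[x_cols]), test[target].to_numpy()),
            ))

        # --- mean regressor ---------------------------------------------
        rows.append(_report_row(target, "mean", "validation", _loso_mean(train, target)))
        mr = MeanRegressor.fit(train[target].to_numpy())
        rows.append(_report_row(
            target, "mean", "test",
            evaluate(mr.predict(test), test[target].to_numpy()),
        ))

    report = pd.DataFrame(rows)
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "train_subjects": train_subj,
        "test_subjects": test_subj,
        "counts": counts,
        "n_rows_stance": int(len(stance_df)),
        "n_rows_step": int(len(step_df)),
    }
    return PipelineResult(report, manifest)
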