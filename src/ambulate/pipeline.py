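"""End-to-end pipelines: simulate -> featurize -> label -> split -> train ->
threshold -> evaluate.

These functions are the programmatic equivalents of chaining the CLI
commands, and they are what the validation experiments run. Raw 30 Hz
streams are featurized one participant-day at a time, so cohorts of
hundreds of participant-days never hold more than one day of raw signal
in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import labels as lb
from .features import FEATURE_NAMES, featurize_stream
from .model import AmbulatoryStatusClassifier, CvThresholdTrace
from .simulate import (DAY_MS, CohortConfig, SyntheticCohort, TagNoiseConfig,
                       derive_seed, simulate_cohort, simulate_participant_day)
from .split import (SplitAssignment, assert_no_leakage, mean_daily_steps,
                    split_random, split_stratified_by_steps)


def featurize_cohort(cohort: SyntheticCohort) -> pd.DataFrame:
    """Feature rows for every complete epoch of every participant-day."""
    parts = []
    for pid, d in cohort.iter_days():
        day = simulate_participant_day(cohort.profile(pid), d, cohort.seed)
        if len(day.stream) == 0:
            continue
        parts.append(featurize_stream(day.stream, day_origin_ms=d * DAY_MS))
    if not parts:
        return pd.DataFrame(columns=["participant_id", "epoch_start_ms",
                                     *FEATURE_NAMES])
    return pd.concat(parts, ignore_index=True)


def labeled_features(features: pd.DataFrame,
                     labels: pd.DataFrame) -> pd.DataFrame:
    """Inner-join features with labels; adds binary ``y`` (1 = ambulatory)."""
    merged = features.merge(labels, on=["participant_id", "epoch_start_ms"],
                            how="inner")
    merged["y"] = (merged["label"] == lb.AMBULATORY).astype(int)
    return merged


def reference_daily_minutes(labels: pd.DataFrame,
                            evaluable: set | None = None) -> dict:
    """(participant_id, day) -> reference ambulatory minutes from labels."""
    agg = ev.daily_ambulatory_minutes(
        (labels["label"] == lb.AMBULATORY).to_numpy(),
        labels["participant_id"].to_numpy(),
        labels["epoch_start_ms"].to_numpy(np.int64))
    out = {(str(r.participant_id), int(r.day)): float(r.minutes)
           for r in agg.itertuples(index=False)}
    if evaluable is not None:
        out = {k: v for k, v in out.items() if k in evaluable}
    return out


@dataclass
class PilotValidationResult:
    """Everything the end-to-end pilot-style validation produces."""

    cohort_seed: int
    split: SplitAssignment
    model: AmbulatoryStatusClassifier
    threshold_trace: CvThresholdTrace
    report: ev.MetricsReport
    bland_altman: pd.DataFrame
    step_curve: pd.DataFrame

    def summary(self) -> dict:
        d = self.report.to_dict()
        d["threshold"] = self.threshold_trace.chosen_threshold
        d["split_balance_steps"] = self.split.balance_stat
        return d


def run_pilot_validation(n_participants: int = 70, n_days: int = 7,
                         seed: int = 0, bootstrap_iterations: int = 1000,
                         config: CohortConfig | None = None
                         ) -> PilotValidationResult:
    """The full pilot-style analytical validation on a synthetic cohort.

    Simulates a pilot-like cohort with device step references, splits it
    50-50 stratified by daily step count, trains the classifier on the
    training half, tunes the decision threshold by participant-level
    5-fold cross-validated daily MAPE, and evaluates epoch-level and
    daily-aggregate performance on the held-out half (evaluable days
    only), with participant-level bootstrap CIs for the headline metrics.
    """
    config = config or CohortConfig(style="pilot_like",
                                    n_participants=n_participants,
                                    n_days=n_days)
    cohort = simulate_cohort(config, seed)
    features = featurize_cohort(cohort)
    labels = lb.device_labels(cohort.steps)
    data = labeled_features(features, labels)

    split = split_stratified_by_steps(mean_daily_steps(cohort.steps),
                                      seed=derive_seed(seed, "split"))
    train_ids, test_ids = split.train_ids(), split.test_ids()
    assert_no_leakage(train_ids, test_ids)

    train = data[data["participant_id"].isin(train_ids)]
    test = data[data["participant_id"].isin(test_ids)]
    Xcols = list(FEATURE_NAMES)

    model = AmbulatoryStatusClassifier(random_state=derive_seed(seed, "fit"))
    model.fit(train[Xcols].to_numpy(), train["y"].to_numpy())

    evaluable = lb.evaluable_days(cohort.wear, require_both_devices=True)
    ref_min_train = reference_daily_minutes(
        labels[labels["participant_id"].isin(train_ids)], evaluable)
    trace = model.optimize_threshold(
        train[Xcols].to_numpy(), train["y"].to_numpy(),
        train["participant_id"].to_numpy(),
        (train["epoch_start_ms"] // DAY_MS).to_numpy(),
        ref_min_train)

    # --- held-out evaluation ---------------------------------------------
    scores = model.predict_scores(test[Xcols].to_numpy())
    preds = (scores >= model.threshold_).astype(int)
    y = test["y"].to_numpy()
    report = ev.epoch_metrics(preds, y, scores=scores)
    report.n_participants = len(test_ids)

    test_keys = list(zip(test["participant_id"].astype(str),
                         test["epoch_start_ms"] // DAY_MS))
    eval_mask = np.array([k in evaluable for k in test_keys])
    pred_daily = ev.daily_ambulatory_minutes(
        preds[eval_mask], test["participant_id"].to_numpy()[eval_mask],
        test["epoch_start_ms"].to_numpy(np.int64)[eval_mask])
    ref_daily = ev.daily_ambulatory_minutes(
        y[eval_mask], test["participant_id"].to_numpy()[eval_mask],
        test["epoch_start_ms"].to_numpy(np.int64)[eval_mask])
    agg = pred_daily.merge(ref_daily, on=["participant_id", "day"],
                           suffixes=("_pred", "_ref"))
    agg = agg.rename(columns={"minutes_pred": "predicted_minutes",
                              "minutes_ref": "reference_minutes"})
    daily_report, bland_altman = ev.daily_agreement(agg)
    report.mape_daily = daily_report.mape_daily
    report.median_ape_daily = daily_report.median_ape_daily
    report.mae_daily = daily_report.mae_daily
    report.median_ae_daily = daily_report.median_ae_daily
    report.r_squared_daily = daily_report.r_squared_daily
    report.n_days = daily_report.n_days
    report.notes.update(daily_report.notes)

    if bootstrap_iterations > 0:
        ci = ev.bootstrap_auc_ci(scores, y, test["participant_id"],
                                 iterations=bootstrap_iterations,
                                 seed=derive_seed(seed, "boot-auc"))
        if ci is not None:
            report.ci["auc_roc"] = ci
        groups = {pid: g for pid, g in agg.groupby("participant_id")}

        def mape_stat(sampled):
            df = pd.concat(sampled)
            nz = df["reference_minutes"] > 0
            if not nz.any():
                return None
            return float((np.abs(df["predicted_minutes"] - df["reference_minutes"])
                          [nz] / df["reference_minutes"][nz]).mean() * 100)

        def mae_stat(sampled):
            df = pd.concat(sampled)
            return float(np.abs(df["predicted_minutes"]
                                - df["reference_minutes"]).mean())

        if len(groups) >= 2:
            report.ci["mape_daily"] = ev.bootstrap_ci(
                mape_stat, groups, iterations=bootstrap_iterations,
                seed=derive_seed(seed, "boot-mape"))
            report.ci["mae_daily"] = ev.bootstrap_ci(
                mae_stat, groups, iterations=bootstrap_iterations,
                seed=derive_seed(seed, "boot-mae"))

    steps_joined = test.merge(
        cohort.steps, left_on=["participant_id", "epoch_start_ms"],
        right_on=["participant_id", "window_start_ms"], how="inner")
    step_scores = model.predict_scores(steps_joined[Xcols].to_numpy())
    step_preds = (step_scores >= model.threshold_).astype(int)
    step_curve = ev.stepcount_sensitivity(step_preds,
                                          steps_joined["steps"].to_numpy())

    return PilotValidationResult(cohort_seed=seed, split=split, model=model,
                                 threshold_trace=trace, report=report,
                                 bland_altman=bland_altman,
                                 step_curve=step_curve)


# ---------------------------------------------------------------------------
# data-quality (crossed train x test) experiment
# ---------------------------------------------------------------------------

CANONICAL_MIXTURES = ("qc_high", "qc_minimal", "qc_high+pilot",
                      "qc_minimal+pilot", "pilot")


@dataclass
class QualityExperimentResult:
    auc_matrix: pd.DataFrame  # mixtures x test sets
    per_model_range: dict[str, float]
    per_test_set_range: dict[str, float]

    @property
    def test_set_spread_dominates(self) -> bool:
        """True when AUC varies more across test sets than across models."""
        return (max(self.per_model_range.values())
                > max(self.per_test_set_range.values()))


def _pbhs_label_sets(cohort: SyntheticCohort, features: pd.DataFrame):
    """Labeled epoch tables for the two QC strata of a pbhs-like cohort."""
    grid = features[["participant_id", "epoch_start_ms"]]
    out = {}
    for stratum in ("qc_minimal", "qc_high"):
        qc_tags, _ = lb.apply_qc(cohort.tags, stratum, cohort.wear)
        out[stratum] = lb.self_report_labels(qc_tags, grid, qc_stratum=stratum)
    return out


def run_quality_experiment(seed: int, n_pilot: int = 16, n_pbhs: int = 16,
                           n_days: int = 2,
                           tag_noise: TagNoiseConfig | None = None
                           ) -> QualityExperimentResult:
    """Train the five canonical mixtures; evaluate on clean vs noisy tests.

    Mirrors the crossed train x test design: models trained on pbhs-style
    QC strata (noisy self-report labels), on pilot-style device labels, or
    on pooled combinations, are each evaluated on the held-out pilot test
    set (clean labels) and on the held-out pbhs-style QC strata (noisy labels).
    Labels in the noisy test sets inherit tag-corruption errors, so test
    AUC differences reflect test-label quality as much as model quality.
    """
    tag_noise = tag_noise or TagNoiseConfig(
        start_latency_sd=45.0, end_latency_sd=90.0, missing_tag_prob=0.10,
        overlong_tag_prob=0.03, mislabel_prob=0.12)

    pilot = simulate_cohort(
        CohortConfig(style="pilot_like", n_participants=n_pilot,
                     n_days=n_days), derive_seed(seed, "pilot"))
    pbhs = simulate_cohort(
        CohortConfig(style="pbhs_like", n_participants=n_pbhs,
                     n_days=n_days, tag_noise=tag_noise),
        derive_seed(seed, "pbhs"))

    pilot_feats = featurize_cohort(pilot)
    pbhs_feats = featurize_cohort(pbhs)
    pilot_data = labeled_features(pilot_feats, lb.device_labels(pilot.steps))
    pbhs_labels = _pbhs_label_sets(pbhs, pbhs_feats)

    pilot_split = split_stratified_by_steps(
        mean_daily_steps(pilot.steps), seed=derive_seed(seed, "ps"))
    pbhs_split = split_random(pbhs.participant_ids, 0.5,
                              seed=derive_seed(seed, "rs"))

    Xcols = list(FEATURE_NAMES)

    def side(df, ids):
        return df[df["participant_id"].isin(ids)]

    pilot_train = side(pilot_data, pilot_split.train_ids())
    pilot_test = side(pilot_data, pilot_split.test_ids())
    train_sets = {"pilot": pilot_train}
    test_sets = {"pilot": (pilot_test[Xcols].to_numpy(),
                           pilot_test["y"].to_numpy())}
    for stratum in ("qc_minimal", "qc_high"):
        data = labeled_features(pbhs_feats, pbhs_labels[stratum])
        tr = side(data, pbhs_split.train_ids())
        te = side(data, pbhs_split.test_ids())
        train_sets[stratum] = tr
        test_sets[stratum] = (te[Xcols].to_numpy(), te["y"].to_numpy())

    mixtures = {
        "qc_high": train_sets["qc_high"],
        "qc_minimal": train_sets["qc_minimal"],
        "qc_high+pilot": pd.concat([train_sets["qc_high"], pilot_train]),
        "qc_minimal+pilot": pd.concat([train_sets["qc_minimal"], pilot_train]),
        "pilot": pilot_train,
    }
    models = {}
    for name, df in mixtures.items():
        m = AmbulatoryStatusClassifier(random_state=derive_seed(seed, name))
        m.fit(df[Xcols].to_numpy(), df["y"].to_numpy())
        models[name] = m

    matrix, summary = ev.crossed_evaluation(models, test_sets)
    return QualityExperimentResult(
        auc_matrix=matrix,
        per_model_range=summary["per_model_range"],
        per_test_set_range=summary["per_test_set_range"])
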