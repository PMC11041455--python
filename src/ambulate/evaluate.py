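"""Validation statistics: epoch metrics, daily agreement, bootstrap CIs,
per-step-count sensitivity, demographic subgroups and crossed evaluation.

Conventions used throughout:

* *ambulatory* is the positive class;
* AUC-ROC is the Mann-Whitney statistic (ties count half), AUC-PRC the
  trapezoidal area under the precision-recall curve;
* daily ambulatory time is ``10 s x (ambulatory epochs in the calendar
  day) / 60`` minutes; agreement statistics (MAPE, MAE, R^2,
  Bland-Altman) compare predicted and reference daily minutes over
  evaluable days only;
* days with zero reference minutes are excluded from percentage errors
  (undefined) but retained in absolute errors;
* confidence intervals are percentile bootstrap (2.5th / 97.5th) with
  resampling at the participant level, so all of a participant's epochs
  and days enter or leave a resample together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .simulate import DAY_MS

DEFAULT_AGE_BANDS = ((18, 30), (31, 65), (66, 200))
MAX_STEP_BIN = 11


# ---------------------------------------------------------------------------
# epoch-level metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Epoch-level and daily-aggregate performance with optional CIs."""

    auc_roc: float | None = None
    auc_prc: float | None = None
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    f1: float | None = None
    mape_daily: float | None = None  # percent
    median_ape_daily: float | None = None  # percent
    mae_daily: float | None = None  # minutes
    median_ae_daily: float | None = None  # minutes
    r_squared_daily: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_epochs: int = 0
    n_days: int = 0
    n_participants: int = 0
    notes: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "ci"}
        out["ci"] = {k: list(v) for k, v in self.ci.items()}
        return out


def epoch_metrics(predictions, labels, scores=None) -> MetricsReport:
    """Confusion-matrix rates and AUCs with ambulatory as positive class.

    ``predictions`` and ``labels`` are binary (1 = ambulatory). AUCs need
    ``scores``; with a single label class they are undefined and reported
    absent with a reason.
    """
    y = np.asarray(labels).astype(int)
    report = MetricsReport(n_epochs=len(y))

    if predictions is not None:
        p = np.asarray(predictions).astype(int)
        if len(p) != len(y):
            raise ValueError("predictions and labels differ in length")
        tp = int(np.sum((p == 1) & (y == 1)))
        tn = int(np.sum((p == 0) & (y == 0)))
        fp = int(np.sum((p == 1) & (y == 0)))
        fn = int(np.sum((p == 0) & (y == 1)))
        report.accuracy = (tp + tn) / len(y) if len(y) else None
        report.sensitivity = tp / (tp + fn) if tp + fn else None
        report.specificity = tn / (tn + fp) if tn + fp else None
        report.ppv = tp / (tp + fp) if tp + fp else None
        if report.sensitivity is not None and report.ppv is not None and \
                (report.sensitivity + report.ppv) > 0:
            report.f1 = (2 * report.ppv * report.sensitivity
                         / (report.ppv + report.sensitivity))

    if scores is not None:
        s = np.asarray(scores, dtype=float)
        if len(np.unique(y)) < 2:
            report.notes["auc"] = "undefined: single label class"
        else:
            report.auc_roc = float(skm.roc_auc_score(y, s))
            prec, rec, _ = skm.precision_recall_curve(y, s)
            report.auc_prc = float(skm.auc(rec, prec))
    return report


def mann_whitney_auc(labels, scores) -> float:
    """Brute-force pairwise AUC (ties half) — the oracle form of AUC-ROC."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined with a single label class")
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# daily aggregates and agreement
# ---------------------------------------------------------------------------


def daily_ambulatory_minutes(flags, participant_ids, epoch_start_ms) -> pd.DataFrame:
    """Sum ambulatory epochs into minutes per participant per calendar day.

    Returns columns ``participant_id``, ``day``, ``minutes`` where
    ``minutes = 10 s x count(flags) / 60``. Days with zero ambulatory
    epochs but present epochs appear with 0 minutes.
    """
    df = pd.DataFrame({
        "participant_id": np.asarray(participant_ids),
        "day": np.asarray(epoch_start_ms, dtype=np.int64) // DAY_MS,
        "flag": np.asarray(flags).astype(int),
    })
    agg = (df.groupby(["participant_id", "day"], sort=True)["flag"].sum()
             .rename("n_ambulatory").reset_index())
    agg["minutes"] = agg["n_ambulatory"] * 10.0 / 60.0
    return agg[["participant_id", "day", "minutes"]]


def daily_agreement(aggregates: pd.DataFrame) -> tuple[MetricsReport, pd.DataFrame]:
    """Agreement between predicted and reference daily ambulatory minutes.

    ``aggregates`` needs columns ``participant_id``, ``day``,
    ``predicted_minutes``, ``reference_minutes`` (evaluable days only).
    Returns the report (MAPE/MAE, medians, R^2) and the modified
    Bland-Altman pairs ``(reference_minutes, error = pred - ref)``.
    """
    df = aggregates
    if df.empty:
        raise ValueError("no evaluable days")
    pred = df["predicted_minutes"].to_numpy(float)
    ref = df["reference_minutes"].to_numpy(float)
    err = pred - ref
    report = MetricsReport(n_days=len(df),
                           n_participants=df["participant_id"].nunique())

    nonzero = ref > 0
    if nonzero.any():
        ape = np.abs(err[nonzero]) / ref[nonzero] * 100.0
        report.mape_daily = float(ape.mean())
        report.median_ape_daily = float(np.median(ape))
        if (~nonzero).any():
            report.notes["mape"] = (
                f"{int((~nonzero).sum())} zero-reference day(s) excluded")
    else:
        report.notes["mape"] = "undefined: all reference days are zero"
    report.mae_daily = float(np.abs(err).mean())
    report.median_ae_daily = float(np.median(np.abs(err)))
    if len(df) >= 2 and np.std(pred) > 0 and np.std(ref) > 0:
        r, _ = stats.pearsonr(pred, ref)
        report.r_squared_daily = float(r**2)

    bland_altman = pd.DataFrame({
        "participant_id": df["participant_id"].to_numpy(),
        "day": df["day"].to_numpy(),
        "reference_minutes": ref,
        "error_minutes": err,
    })
    return report, bland_altman


# ---------------------------------------------------------------------------
# participant-level bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(statistic, groups: dict, iterations: int = 1000,
                 seed: int = 0, max_attempt_factor: int = 10
                 ) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI resampling participants with replacement.

    ``groups`` maps participant_id -> that participant's data (any object
    the statistic understands); ``statistic`` receives the list of sampled
    group objects (with multiplicity) and returns a float or ``None``/NaN
    when undefined on that resample. Undefined resamples are redrawn up to
    ``max_attempt_factor x iterations`` total draws; if more than half of
    all draws are undefined an error is raised.
    """
    if len(groups) < 2:
        raise ValueError("bootstrap requires >= 2 participants")
    rng = np.random.default_rng(seed)
    ids = sorted(groups)
    values: list[float] = []
    attempts = 0
    max_attempts = max_attempt_factor * iterations
    while len(values) < iterations:
        if attempts >= max_attempts:
            raise ValueError(
                f"statistic undefined on too many resamples "
                f"({attempts - len(values)}/{attempts})")
        attempts += 1
        sample = rng.choice(ids, size=len(ids), replace=True)
        v = statistic([groups[p] for p in sample])
        if v is None or not np.isfinite(v):
            continue
        values.append(float(v))
    if (attempts - len(values)) > attempts / 2:
        raise ValueError("statistic undefined on more than half of resamples")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def bootstrap_auc_ci(scores, labels, participant_ids, iterations: int = 1000,
                     seed: int = 0) -> tuple[float, float] | None:
    """Participant-level bootstrap CI for AUC-ROC (None if degenerate).

    Uses the pairwise decomposition of the Mann-Whitney statistic: with
    per-participant positive/negative score multisets fixed, the pooled
    AUC of any participant resample is a quadratic form in the resampling
    multiplicities over precomputed between-participant win/tie counts.
    Each bootstrap iteration is then O(participants^2) regardless of epoch
    count, and numerically identical to recomputing AUC on the pooled
    resampled epochs. Resamples with a single label class are redrawn (up
    to 10x the iteration count).
    """
    df = pd.DataFrame({"pid": np.asarray(participant_ids).astype(str),
                       "y": np.asarray(labels).astype(int),
                       "s": np.asarray(scores, dtype=float)})
    if len(df) == 0 or df["pid"].nunique() < 2:
        return None
    pos_by, neg_by = [], []
    for _, g in df.groupby("pid", sort=True):
        pos_by.append(np.sort(g.loc[g["y"] == 1, "s"].to_numpy()))
        neg_by.append(np.sort(g.loc[g["y"] == 0, "s"].to_numpy()))
    k = len(pos_by)
    W = np.zeros((k, k))
    T = np.zeros((k, k))
    for i, pos in enumerate(pos_by):
        if len(pos) == 0:
            continue
        for j, neg in enumerate(neg_by):
            if len(neg) == 0:
                continue
            lo = np.searchsorted(neg, pos, side="left")
            hi = np.searchsorted(neg, pos, side="right")
            W[i, j] = lo.sum()
            T[i, j] = (hi - lo).sum()
    n_pos = np.array([len(p) for p in pos_by], dtype=float)
    n_neg = np.array([len(n) for n in neg_by], dtype=float)

    rng = np.random.default_rng(seed)
    values = []
    attempts, max_attempts = 0, 10 * iterations
    while len(values) < iterations and attempts < max_attempts:
        attempts += 1
        counts = np.bincount(rng.integers(0, k, size=k), minlength=k).astype(float)
        P, N = counts @ n_pos, counts @ n_neg
        if P == 0 or N == 0:
            continue
        wins = counts @ W @ counts
        ties = counts @ T @ counts
        values.append((wins + 0.5 * ties) / (P * N))
    if len(values) < iterations:
        return None
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# subgroup analysis
# ---------------------------------------------------------------------------


@dataclass
class SubgroupResult:
    axis: str
    level: str
    auc: float | None
    ci: tuple[float, float] | None
    n_participants: int
    n_epochs: int
    reason_absent: str | None = None


def _age_band_label(age: float, bands) -> str:
    for lo, hi in bands:
        if lo <= age <= hi:
            return f"{lo}-{hi}" if hi < 150 else f">{lo - 1}"
    return "unknown"


def subgroup_auc(scores, labels, participant_ids, demographics: pd.DataFrame,
                 axes=("gender", "age_band", "race"),
                 age_bands=DEFAULT_AGE_BANDS, iterations: int = 1000,
                 seed: int = 0) -> tuple[list[SubgroupResult], dict[str, bool]]:
    """AUC with participant-level bootstrap CI per demographic subgroup.

    ``demographics`` needs ``participant_id`` plus the raw axes present
    (``gender``, ``age_years``, ``race``); ``age_band`` is derived from
    ``age_years`` using ``age_bands``. Missing demographic values collect
    into an ``unknown`` level. Returns per-level results plus, per axis, a
    flag saying whether all pairwise 95% CIs overlap (the qualitative
    no-subgroup-difference criterion).
    """
    demo = demographics.copy()
    demo["participant_id"] = demo["participant_id"].astype(str)
    if "age_band" in axes:
        if "age_years" not in demo.columns:
            raise ValueError("axis 'age_band' requires an age_years column")
        demo["age_band"] = [
            _age_band_label(a, age_bands) if np.isfinite(a) else "unknown"
            for a in pd.to_numeric(demo["age_years"], errors="coerce")]
    for ax in axes:
        if ax not in demo.columns:
            raise ValueError(f"axis {ax!r} absent from demographics")
        demo[ax] = demo[ax].fillna("unknown").replace("", "unknown")

    df = pd.DataFrame({"pid": [str(p) for p in participant_ids],
                       "y": np.asarray(labels).astype(int),
                       "s": np.asarray(scores, dtype=float)})
    df = df.merge(demo, left_on="pid", right_on="participant_id", how="left")
    for ax in axes:
        df[ax] = df[ax].fillna("unknown")

    results: list[SubgroupResult] = []
    overlap_flags: dict[str, bool] = {}
    for ax in axes:
        level_cis = []
        for level, grp in df.groupby(ax, sort=True):
            n_p = grp["pid"].nunique()
            res = SubgroupResult(axis=ax, level=str(level), auc=None, ci=None,
                                 n_participants=n_p, n_epochs=len(grp))
            if grp["y"].nunique() < 2:
                res.reason_absent = "one class"
            else:
                res.auc = float(skm.roc_auc_score(grp["y"], grp["s"]))
                res.ci = bootstrap_auc_ci(
                    grp["s"], grp["y"], grp["pid"], iterations=iterations,
                    seed=seed)
                if res.ci is not None:
                    level_cis.append(res.ci)
            results.append(res)
        overlap = True
        for i in range(len(level_cis)):
            for j in range(i + 1, len(level_cis)):
                lo_i, hi_i = level_cis[i]
                lo_j, hi_j = level_cis[j]
                if hi_i < lo_j or hi_j < lo_i:
                    overlap = False
        overlap_flags[ax] = overlap
    return results, overlap_flags


# ---------------------------------------------------------------------------
# per-step-count sensitivity (device-labeled cohorts)
# ---------------------------------------------------------------------------


def stepcount_sensitivity(predictions, steps, max_steps: int = MAX_STEP_BIN
                          ) -> pd.DataFrame:
    """Proportion of epochs predicted ambulatory per single-leg step count.

    ``predictions`` are binary flags aligned with ``steps`` (the window
    step counts). Counts above ``max_steps`` are excluded (rare). Returns
    columns ``steps``, ``proportion_ambulatory``, ``n_epochs`` for counts
    0..max_steps.
    """
    p = np.asarray(predictions).astype(int)
    s = np.asarray(steps).astype(int)
    if len(p) != len(s):
        raise ValueError("predictions and steps differ in length")
    rows = []
    for k in range(max_steps + 1):
        mask = s == k
        n = int(mask.sum())
        rows.append({"steps": k,
                     "proportion_ambulatory": float(p[mask].mean()) if n else np.nan,
                     "n_epochs": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# crossed train x test evaluation
# ---------------------------------------------------------------------------


def crossed_evaluation(models: dict, test_sets: dict,
                       with_ci: bool = False, iterations: int = 1000,
                       seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """AUC for every (model, test set) pair, plus spread summaries.

    ``models`` maps name -> fitted classifier; ``test_sets`` maps name ->
    ``(X, y)`` or ``(X, y, participant_ids)`` (ids required for CIs). A
    one-class test set yields a NaN cell. The summary reports, for each
    model, the AUC range across test sets, and for each test set, the
    range across models — the comparison that shows whether test-data
    quality or training-data quality dominates performance variability.
    """
    matrix = pd.DataFrame(index=list(models), columns=list(test_sets),
                          dtype=float)
    cis: dict[tuple[str, str], tuple[float, float]] = {}
    for tname, tset in test_sets.items():
        X, y = tset[0], np.asarray(tset[1]).astype(int)
        pids = tset[2] if len(tset) > 2 else None
        for mname, model in models.items():
            if len(np.unique(y)) < 2:
                matrix.loc[mname, tname] = np.nan
                continue
            s = model.predict_scores(X)
            matrix.loc[mname, tname] = skm.roc_auc_score(y, s)
            if with_ci and pids is not None:
                ci = bootstrap_auc_ci(s, y, pids, iterations=iterations,
                                      seed=seed)
                if ci is not None:
                    cis[(mname, tname)] = ci

    summary = {
        "per_model_range": {
            m: float(matrix.loc[m].max() - matrix.loc[m].min())
            for m in matrix.index},
        "per_test_set_range": {
            t: float(matrix[t].max() - matrix[t].min())
            for t in matrix.columns},
        "ci": cis,
    }
    return matrix, summary
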