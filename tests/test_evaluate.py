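"""Validation statistics: AUC oracles, daily agreement, bootstrap, subgroups."""

import numpy as np
import pandas as pd
import pytest

import ambulate.evaluate as ev
from ambulate.evaluate import (bootstrap_auc_ci, bootstrap_ci,
                               crossed_evaluation, daily_agreement,
                               daily_ambulatory_minutes, epoch_metrics,
                               mann_whitney_auc, stepcount_sensitivity,
                               subgroup_auc)


class TestEpochMetrics:
    def test_worked_six_epoch_auc(self):
        """Hand-worked 6-epoch set: 8 wins over the 9 pos-neg pairs.

        Positives {0.9, 0.8, 0.4} vs negatives {0.7, 0.2, 0.1}: 0.9 and 0.8
        each beat all three negatives, 0.4 beats two -> AUC = 8/9.
        """
        labels = [1, 1, 1, 0, 0, 0]
        scores = [0.9, 0.8, 0.4, 0.7, 0.2, 0.1]
        rep = epoch_metrics(None, labels, scores=scores)
        assert rep.auc_roc == pytest.approx(8 / 9)
        assert rep.auc_roc == pytest.approx(mann_whitney_auc(labels, scores))

    def test_perfect_separation(self):
        labels = [0] * 10 + [1] * 10
        scores = np.concatenate([np.linspace(0, 0.4, 10),
                                 np.linspace(0.6, 1.0, 10)])
        preds = (scores >= 0.5).astype(int)
        rep = epoch_metrics(preds, labels, scores=scores)
        assert rep.auc_roc == 1.0
        assert rep.accuracy == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_constant_scores_give_half_auc(self):
        rep = epoch_metrics(None, [0, 1, 0, 1], scores=[0.3] * 4)
        assert rep.auc_roc == pytest.approx(0.5)

    def test_single_class_auc_absent_with_reason(self):
        rep = epoch_metrics(None, [1, 1, 1], scores=[0.2, 0.5, 0.9])
        assert rep.auc_roc is None
        assert "single label class" in rep.notes["auc"]

    def test_confusion_matrix_conservation(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 500)
        p = rng.integers(0, 2, 500)
        rep = epoch_metrics(p, y)
        tp = rep.sensitivity * (y == 1).sum()
        tn = rep.specificity * (y == 0).sum()
        assert rep.accuracy * 500 == pytest.approx(tp + tn)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_auc_equals_mann_whitney_oracle(self, seed):
        """Library AUC == brute-force pairwise statistic on every instance."""
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 2000)
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[:2] = [0, 1]
        s = np.round(rng.random(n), 2)  # coarse scores force ties
        rep = epoch_metrics(None, y, scores=s)
        assert rep.auc_roc == pytest.approx(mann_whitney_auc(y, s), abs=1e-12)


class TestDailyAggregates:
    def _minutes(self, flags):
        return daily_ambulatory_minutes(
            flags, ["P0"] * len(flags),
            np.arange(len(flags), dtype=np.int64) * 10_000)

    @pytest.mark.parametrize("n_amb,expected", [(0, 0.0), (6, 1.0), (360, 60.0)])
    def test_minutes_from_epoch_counts(self, n_amb, expected):
        flags = [1] * n_amb + [0] * 10
        assert self._minutes(flags)["minutes"].iloc[0] == expected

    def test_linearity_over_disjoint_days(self):
        rng = np.random.default_rng(1)
        flags = rng.integers(0, 2, 2000)
        t = np.arange(2000, dtype=np.int64) * 10_000
        t[1000:] += 86_400_000  # second calendar day
        out = daily_ambulatory_minutes(flags, ["P0"] * 2000, t)
        assert len(out) == 2
        total = daily_ambulatory_minutes(flags, ["P0"] * 2000,
                                         np.zeros(2000, np.int64))
        assert out["minutes"].sum() == pytest.approx(total["minutes"].sum())

    def test_agreement_identity(self):
        agg = pd.DataFrame({"participant_id": ["P0"] * 3, "day": [0, 1, 2],
                            "predicted_minutes": [30.0, 45.0, 60.0],
                            "reference_minutes": [30.0, 45.0, 60.0]})
        rep, ba = daily_agreement(agg)
        assert rep.mape_daily == 0.0
        assert rep.mae_daily == 0.0
        assert rep.r_squared_daily == pytest.approx(1.0)
        assert (ba["error_minutes"] == 0).all()

    def test_agreement_single_day(self):
        agg = pd.DataFrame({"participant_id": ["P0"], "day": [0],
                            "predicted_minutes": [50.0],
                            "reference_minutes": [40.0]})
        rep, _ = daily_agreement(agg)
        assert rep.mape_daily == pytest.approx(25.0)
        assert rep.mae_daily == pytest.approx(10.0)

    def test_agreement_two_day_hand_computation(self):
        agg = pd.DataFrame({"participant_id": ["P0", "P0"], "day": [0, 1],
                            "predicted_minutes": [30.0, 60.0],
                            "reference_minutes": [40.0, 50.0]})
        rep, ba = daily_agreement(agg)
        assert rep.mape_daily == pytest.approx(22.5)  # (25% + 20%) / 2
        assert rep.mae_daily == pytest.approx(10.0)
        assert list(ba["error_minutes"]) == [-10.0, 10.0]

    def test_zero_reference_days_excluded_from_mape_kept_in_mae(self):
        agg = pd.DataFrame({"participant_id": ["P0"] * 2, "day": [0, 1],
                            "predicted_minutes": [10.0, 44.0],
                            "reference_minutes": [0.0, 40.0]})
        rep, _ = daily_agreement(agg)
        assert rep.mape_daily == pytest.approx(10.0)
        assert "excluded" in rep.notes["mape"]
        assert rep.mae_daily == pytest.approx((10.0 + 4.0) / 2)

    def test_all_zero_reference_mape_absent(self):
        agg = pd.DataFrame({"participant_id": ["P0"], "day": [0],
                            "predicted_minutes": [5.0],
                            "reference_minutes": [0.0]})
        rep, _ = daily_agreement(agg)
        assert rep.mape_daily is None
        assert rep.mae_daily == pytest.approx(5.0)


class TestBootstrap:
    def test_degenerate_distribution_collapses_ci(self):
        groups = {f"P{i}": 7.0 for i in range(10)}
        lo, hi = bootstrap_ci(lambda vals: float(np.mean(vals)), groups,
                              iterations=200, seed=0)
        assert lo == hi == 7.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        groups = {f"P{i}": float(v) for i, v in enumerate(rng.normal(size=20))}
        stat = lambda vals: float(np.mean(vals))
        assert bootstrap_ci(stat, groups, seed=5) == \
            bootstrap_ci(stat, groups, seed=5)

    def test_mostly_undefined_statistic_rejected(self):
        groups = {f"P{i}": float(i) for i in range(5)}
        with pytest.raises(ValueError, match="undefined"):
            bootstrap_ci(lambda vals: None, groups, iterations=50)

    def test_ci_width_shrinks_with_participants(self):
        rng = np.random.default_rng(3)
        stat = lambda vals: float(np.mean(vals))

        def width(n, seed):
            groups = {f"P{i}": float(v)
                      for i, v in enumerate(rng.normal(size=n))}
            lo, hi = bootstrap_ci(stat, groups, iterations=300, seed=seed)
            return hi - lo

        w20 = np.median([width(20, s) for s in range(5)])
        w100 = np.median([width(100, s) for s in range(5)])
        assert w100 < w20

    def test_fast_auc_bootstrap_matches_generic_resampling(self):
        """The pairwise-decomposition AUC bootstrap equals naive pooled
        recomputation under the same participant resamples."""
        rng = np.random.default_rng(4)
        pids = np.repeat([f"P{i}" for i in range(6)], 30)
        y = rng.integers(0, 2, len(pids))
        s = np.clip(y * 0.4 + rng.normal(0.3, 0.25, len(pids)), 0, 1)
        fast = bootstrap_auc_ci(s, y, pids, iterations=400, seed=9)

        from sklearn.metrics import roc_auc_score
        ids = sorted(set(pids))
        rng2 = np.random.default_rng(9)
        vals = []
        while len(vals) < 400:
            counts = np.bincount(rng2.integers(0, len(ids), size=len(ids)),
                                 minlength=len(ids))
            take = np.concatenate([
                np.flatnonzero(pids == ids[i]).repeat(c)
                for i, c in enumerate(counts) if c]) if counts.any() else []
            yy, ss = y[take], s[take]
            if len(np.unique(yy)) < 2:
                continue
            vals.append(roc_auc_score(yy, ss))
        lo, hi = np.percentile(vals, [2.5, 97.5])
        assert fast == pytest.approx((lo, hi), abs=1e-12)


class TestStepcountSensitivity:
    def test_all_nonambulatory_gives_zero_proportions(self):
        out = stepcount_sensitivity(np.zeros(100, int),
                                    np.random.default_rng(0).integers(0, 12, 100))
        assert (out["proportion_ambulatory"].fillna(0) == 0).all()

    def test_oracle_predictor_reproduces_step_rule(self):
        steps = np.tile(np.arange(12), 10)
        preds = (steps >= 3).astype(int)
        out = stepcount_sensitivity(preds, steps)
        expected = [0.0] * 3 + [1.0] * 9
        assert list(out["proportion_ambulatory"]) == expected

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(5)
        steps = rng.integers(0, 15, 10_000)
        preds = rng.integers(0, 2, 10_000)
        out = stepcount_sensitivity(preds, steps)
        for k in range(12):
            mask = steps == k
            assert out.loc[k, "n_epochs"] == mask.sum()
            assert out.loc[k, "proportion_ambulatory"] == pytest.approx(
                preds[mask].mean())
        assert out["n_epochs"].sum() == (steps <= 11).sum()


class TestSubgroups:
    def _data(self, n_pid=8, seed=0, neutral=True):
        rng = np.random.default_rng(seed)
        pids = np.repeat([f"P{i}" for i in range(n_pid)], 50)
        y = rng.integers(0, 2, len(pids))
        s = np.clip(y * 0.5 + rng.normal(0.25, 0.2, len(pids)), 0, 1)
        demo = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n_pid)],
            "gender": ["female" if i % 2 else "male" for i in range(n_pid)],
            "age_years": rng.integers(20, 80, n_pid),
            "race": rng.choice(["white", "black", "asian"], n_pid),
        })
        return s, y, pids, demo

    def test_single_subgroup_equals_overall_auc(self):
        s, y, pids, demo = self._data()
        demo["gender"] = "female"
        results, _ = subgroup_auc(s, y, pids, demo, axes=("gender",),
                                  iterations=50)
        overall = epoch_metrics(None, y, scores=s).auc_roc
        assert len(results) == 1
        assert results[0].auc == pytest.approx(overall, abs=1e-12)

    def test_subgroup_auc_matches_filtered_epoch_metrics(self):
        s, y, pids, demo = self._data()
        results, _ = subgroup_auc(s, y, pids, demo, axes=("gender",),
                                  iterations=50)
        for res in results:
            members = set(demo.loc[demo["gender"] == res.level,
                                   "participant_id"])
            mask = np.isin(pids, list(members))
            direct = epoch_metrics(None, y[mask], scores=s[mask]).auc_roc
            assert res.auc == pytest.approx(direct, abs=1e-12)

    def test_one_class_subgroup_absent_with_reason(self):
        s, y, pids, demo = self._data()
        y = y.copy()
        members = demo.loc[demo["gender"] == "male", "participant_id"]
        y[np.isin(pids, list(members))] = 0
        results, _ = subgroup_auc(s, y, pids, demo, axes=("gender",),
                                  iterations=50)
        male = next(r for r in results if r.level == "male")
        assert male.auc is None and male.reason_absent == "one class"

    def test_missing_axis_rejected(self):
        s, y, pids, demo = self._data()
        with pytest.raises(ValueError, match="axis"):
            subgroup_auc(s, y, pids, demo.drop(columns=["race"]),
                         axes=("race",))

    def test_missing_race_collects_into_unknown(self):
        s, y, pids, demo = self._data()
        demo.loc[0, "race"] = ""
        results, _ = subgroup_auc(s, y, pids, demo, axes=("race",),
                                  iterations=50)
        assert any(r.level == "unknown" for r in results)


class TestCrossedEvaluation:
    class _FixedScores:
        def __init__(self, seed):
            self.seed = seed

        def predict_scores(self, X):
            rng = np.random.default_rng(self.seed)
            return rng.random(len(X))

    def test_identical_model_gives_identical_cells(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 14))
        y = rng.integers(0, 2, 100)
        m = self._FixedScores(1)
        matrix, _ = crossed_evaluation({"a": m, "b": m}, {"t": (X, y)})
        assert matrix.loc["a", "t"] == matrix.loc["b", "t"]

    def test_single_cell_reduces_to_epoch_metrics(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 14))
        y = rng.integers(0, 2, 200)
        m = self._FixedScores(2)
        matrix, summary = crossed_evaluation({"m": m}, {"t": (X, y)})
        expected = epoch_metrics(None, y, scores=m.predict_scores(X)).auc_roc
        assert matrix.loc["m", "t"] == pytest.approx(expected, abs=1e-12)
        assert summary["per_model_range"]["m"] == 0.0

    def test_one_class_test_set_yields_nan_cell(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 14))
        matrix, _ = crossed_evaluation({"m": self._FixedScores(3)},
                                       {"t": (X, np.ones(50, int))})
        assert np.isnan(matrix.loc["m", "t"])
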