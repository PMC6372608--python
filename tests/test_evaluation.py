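"""Hourly-AUC protocol: oracle equivalence, carry-forward, bootstrap, CV."""

import numpy as np
import pandas as pd
import pytest

from deepsofa.evaluation import (
    EvalConfig,
    auc,
    compare_models,
    hourly_curve,
    render_reports,
    run_external_validation,
    run_internal_cv,
    stratified_mean_probability,
)


def pair_counting_auc(scores, labels) -> float:
    """O(n^2) oracle: (concordant + 0.5 * tied) / (pos * neg pairs)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def preds_from_matrix(trajs: dict) -> pd.DataFrame:
    rows = []
    for eid, p in trajs.items():
        rows.append(pd.DataFrame({
            "encounter_id": eid, "hour": np.arange(1, len(p) + 1), "probability": p
        }))
    return pd.concat(rows, ignore_index=True)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(30):
            n = int(rng.integers(10, 200))
            # coarse scores force plenty of ties
            scores = rng.integers(0, 8, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )


class TestHourlyCurve:
    def test_carry_forward_uses_final_prediction(self):
        trajs = {"A": np.linspace(0.1, 0.9, 5),      # T=5, ends at 0.9
                 "B": np.full(12, 0.2), "C": np.full(12, 0.3),
                 "D": np.full(12, 0.8)}
        labels = pd.Series({"A": True, "B": False, "C": False, "D": True})
        curve = hourly_curve(preds_from_matrix(trajs), labels,
                             config=EvalConfig(max_hours=10, n_bootstrap=20))
        # at hour 10, A contributes its hour-5 value 0.9 -> perfect separation
        assert curve.loc[curve["hour"] == 10, "auc"].iloc[0] == 1.0

    def test_encounter_count_constant(self):
        rng = np.random.default_rng(1)
        trajs = {f"E{i}": rng.uniform(size=rng.integers(3, 40))
                 for i in range(30)}
        labels = pd.Series({f"E{i}": i < 6 for i in range(30)})
        curve = hourly_curve(preds_from_matrix(trajs), labels,
                             config=EvalConfig(max_hours=50, n_bootstrap=10))
        assert curve["n_encounters"].nunique() == 1
        assert len(curve) == 50

    def test_seeded_bootstrap_reproducible(self):
        rng = np.random.default_rng(2)
        trajs = {f"E{i}": rng.uniform(size=5) for i in range(40)}
        labels = pd.Series({f"E{i}": i % 4 == 0 for i in range(40)})
        cfg = EvalConfig(max_hours=5, n_bootstrap=30, seed=9)
        a = hourly_curve(preds_from_matrix(trajs), labels, config=cfg)
        b = hourly_curve(preds_from_matrix(trajs), labels, config=cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_before_end_alignment_indexes_backwards(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        trajs = {"A": p, "B": 1 - p}
        labels = pd.Series({"A": True, "B": False})
        from deepsofa.evaluation import _score_matrix

        mat, y, ids = _score_matrix(preds_from_matrix(trajs), labels,
                                    "before_end", 6)
        a = mat[list(ids).index("A")]
        np.testing.assert_allclose(a, [0.4, 0.3, 0.2, 0.1, 0.1, 0.1])

    def test_no_deaths_raises(self):
        trajs = {"A": np.full(3, 0.2), "B": np.full(3, 0.4)}
        labels = pd.Series({"A": False, "B": False})
        with pytest.raises(ValueError, match="no deaths"):
            hourly_curve(preds_from_matrix(trajs), labels)

    def test_null_ci_coverage(self):
        """~95% of bootstrap CIs on random scores should contain AUC 0.5."""
        from scipy.stats import binom

        rng = np.random.default_rng(5)
        n_datasets, n = 50, 100
        contained = 0
        for i in range(n_datasets):
            scores = rng.uniform(size=n)
            labels = np.zeros(n, dtype=bool)
            labels[:20] = True
            trajs = {f"E{j}": np.array([scores[j]]) for j in range(n)}
            lab = pd.Series({f"E{j}": bool(labels[j]) for j in range(n)})
            curve = hourly_curve(preds_from_matrix(trajs), lab,
                                 config=EvalConfig(max_hours=1, n_bootstrap=100,
                                                   seed=1000 + i))
            if curve["ci_lo"].iloc[0] <= 0.5 <= curve["ci_hi"].iloc[0]:
                contained += 1
        lo = binom.ppf(0.005, n_datasets, 0.95)
        assert lo <= contained <= n_datasets


class TestCompareModels:
    def test_identical_models_null(self):
        rng = np.random.default_rng(3)
        trajs = {f"E{i}": rng.uniform(size=4) for i in range(60)}
        labels = pd.Series({f"E{i}": i % 5 == 0 for i in range(60)})
        preds = preds_from_matrix(trajs)
        out = compare_models(preds, preds.copy(), labels, hour=4)
        assert out["auc_difference"] == 0.0
        assert out["p_value"] > 0.5

    def test_perfect_vs_constant(self):
        labels = pd.Series({f"E{i}": i < 40 for i in range(200)})
        perfect = {f"E{i}": np.array([1.0 if i < 40 else 0.0]) for i in range(200)}
        constant = {f"E{i}": np.array([0.5]) for i in range(200)}
        out = compare_models(preds_from_matrix(perfect),
                             preds_from_matrix(constant), labels, hour=1)
        assert out["auc_difference"] == pytest.approx(0.5)
        assert out["p_value"] < 0.05

    def test_mismatched_encounters_raise(self):
        labels = pd.Series({"A": True, "B": False})
        a = preds_from_matrix({"A": np.array([0.1]), "B": np.array([0.2])})
        b = preds_from_matrix({"A": np.array([0.1]), "C": np.array([0.2])})
        with pytest.raises(ValueError, match="different encounter"):
            compare_models(a, b, labels, hour=1)

    def test_paired_resampling_reduces_variance(self):
        """Shared resamples: paired difference spread < sum of marginal spreads."""
        rng = np.random.default_rng(4)
        n = 150
        y = rng.integers(0, 2, size=n)
        base = rng.normal(size=n) + y
        a = {f"E{i}": np.array([base[i] + rng.normal(0, 0.1)]) for i in range(n)}
        b = {f"E{i}": np.array([base[i] + rng.normal(0, 0.1)]) for i in range(n)}
        labels = pd.Series({f"E{i}": bool(y[i]) for i in range(n)})
        out = compare_models(preds_from_matrix(a), preds_from_matrix(b),
                             labels, hour=1, config=EvalConfig(n_bootstrap=100))
        paired_width = out["ci_hi"] - out["ci_lo"]
        # unpaired: bootstrap each model independently
        from deepsofa.evaluation import bootstrap_se

        sa = np.array([a[f"E{i}"][0] for i in range(n)])
        sb = np.array([b[f"E{i}"][0] for i in range(n)])
        unpaired = 3.92 * np.hypot(bootstrap_se(sa, y, seed=1),
                                   bootstrap_se(sb, y, seed=2))
        assert paired_width < unpaired


class SeverityMeanModel:
    """Cheap stand-in estimator for orchestration tests: mean channel z-score."""

    def __init__(self, seed=0):
        self.seed = seed

    def fit(self, grids, y):
        pooled = np.concatenate([np.asarray(g.values if hasattr(g, "values") else g)
                                 for g in grids])
        self.mean_ = pooled.mean(axis=0)
        self.std_ = pooled.std(axis=0) + 1e-9
        self.fitted_ = True
        return self

    def predict_cohort(self, grids):
        rows = []
        for eid, g in grids.items():
            x = np.asarray(g.values if hasattr(g, "values") else g)
            z = np.abs((x - self.mean_) / self.std_).mean(axis=1)
            score = np.maximum.accumulate(z)
            rows.append(pd.DataFrame({
                "encounter_id": eid, "hour": np.arange(1, len(x) + 1),
                "probability": 1 / (1 + np.exp(-score)),
            }))
        return pd.concat(rows, ignore_index=True)


class TestOrchestration:
    def test_internal_cv_partition(self, small_grids, small_labels):
        preds = run_internal_cv(small_grids, small_labels,
                                lambda seed: SeverityMeanModel(seed),
                                EvalConfig(n_cv_folds=5, seed=3))
        per_enc = preds.groupby("encounter_id")["fold"].nunique()
        assert (per_enc == 1).all()                      # predicted exactly once
        assert set(per_enc.index) == set(small_grids)    # union = cohort
        fold_sizes = preds.groupby("fold")["encounter_id"].nunique()
        assert fold_sizes.max() - fold_sizes.min() <= 1

    def test_external_validation_contract(self, small_grids, small_labels):
        ids = list(small_grids.keys())
        a = {i: small_grids[i] for i in ids[: len(ids) // 2]}
        b = {i: small_grids[i] for i in ids[len(ids) // 2 :]}
        la = small_labels.loc[list(a)]
        lb = small_labels.loc[list(b)]
        out = run_external_validation(a, la, b, lb,
                                      lambda seed: SeverityMeanModel(seed))
        assert set(out["preds"]["encounter_id"]) == set(b)

    def test_external_validation_stats_from_training_only(self, small_grids,
                                                          small_labels):
        ids = list(small_grids.keys())
        a = {i: small_grids[i] for i in ids[:30]}
        b = {i: small_grids[i] for i in ids[30:60]}
        out = run_external_validation(a, small_labels.loc[list(a)],
                                      b, small_labels.loc[list(b)],
                                      lambda seed: SeverityMeanModel(seed))
        model = out["model"]
        # rescaling the *test* cohort must not change the stored statistics
        mean_before = model.mean_.copy()
        scaled_b = {k: 100.0 * np.asarray(g.values) for k, g in b.items()}
        model.predict_cohort(scaled_b)
        np.testing.assert_array_equal(model.mean_, mean_before)

    def test_overlapping_cohorts_raise(self, small_grids, small_labels):
        ids = list(small_grids.keys())[:10]
        a = {i: small_grids[i] for i in ids}
        with pytest.raises(ValueError, match="overlap"):
            run_external_validation(a, small_labels.loc[ids], a,
                                    small_labels.loc[ids],
                                    lambda seed: SeverityMeanModel(seed))


class TestStratifiedCurves:
    def test_constant_predictor_flat(self):
        trajs = {f"E{i}": np.full(6, 0.3) for i in range(30)}
        labels = pd.Series({f"E{i}": i < 5 for i in range(30)})
        out = stratified_mean_probability(preds_from_matrix(trajs), labels,
                                          config=EvalConfig(max_hours=6,
                                                            n_bootstrap=20))
        assert (out["mean_survivor"] == pytest.approx(0.3)) is not False
        np.testing.assert_allclose(out["mean_survivor"], 0.3)
        np.testing.assert_allclose(out["mean_nonsurvivor"], 0.3)

    def test_active_count_non_increasing(self):
        rng = np.random.default_rng(6)
        trajs = {f"E{i}": rng.uniform(size=rng.integers(2, 30))
                 for i in range(40)}
        labels = pd.Series({f"E{i}": i % 6 == 0 for i in range(40)})
        out = stratified_mean_probability(preds_from_matrix(trajs), labels,
                                          config=EvalConfig(max_hours=30,
                                                            n_bootstrap=10))
        assert (np.diff(out["n_active"]) <= 0).all()


class TestRenderReports:
    def test_writes_figures(self, tmp_path):
        curve = pd.DataFrame({
            "alignment": "since_admission", "hour": [1, 2, 3],
            "auc": [0.6, 0.7, 0.8], "ci_lo": [0.5, 0.6, 0.7],
            "ci_hi": [0.7, 0.8, 0.9], "n_encounters": 10, "n_deaths": 3,
        })
        A = np.triu(np.full((4, 4), 0.25))
        A /= A.sum(axis=0, keepdims=True)
        written = render_reports(curve, tmp_path, attention={"E1": A})
        assert all(p.exists() for p in written)
        assert len(written) == 2
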