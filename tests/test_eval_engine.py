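import re

import numpy as np
import pytest

from amyvox.eval_engine import (
    METRICS,
    MetricDistribution,
    PredictionSet,
    bootstrap_loocv,
    compute_metrics,
    format_metric,
    loocv,
    run_study,
)
from amyvox.io_config import RunConfig
from amyvox.model_zoo import ModelSpec
from conftest import separable_data


def _pred_from_confusion(tp, fn, fp, tn, rng):
    y = np.concatenate([np.ones(tp + fn), np.zeros(fp + tn)]).astype(int)
    yhat = np.concatenate(
        [np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)]
    ).astype(int)
    scores = np.clip(yhat * 0.8 + rng.random(len(y)) * 0.1, 0, 1)
    return PredictionSet(y, yhat, scores)


class TestComputeMetrics:
    def test_confusion_arithmetic(self, rng):
        m = compute_metrics(_pred_from_confusion(25, 5, 8, 14, rng))
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(25 / 30, abs=1e-4)
        assert m["precision"] == pytest.approx(25 / 33)
        p, r = m["precision"], m["recall"]
        assert m["f1"] == pytest.approx(2 * p * r / (p + r))

    def test_perfectly_ordered_scores_auc_one(self):
        y = np.array([0, 0, 1, 1])
        pred = PredictionSet(y, y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert compute_metrics(pred)["auc"] == 1.0

    def test_tied_scores_auc_half(self):
        y = np.array([0, 1, 0, 1])
        pred = PredictionSet(y, y, np.full(4, 0.5))
        assert compute_metrics(pred)["auc"] == 0.5

    def test_auc_equals_all_pairs_count(self, rng):
        # Brute-force oracle: fraction of (pos, neg) pairs correctly ordered,
        # ties counting one half.
        for _ in range(20):
            n = int(rng.integers(6, 20))
            y = np.array([0, 1] * (n // 2) + [1] * (n % 2))
            scores = rng.choice(np.linspace(0, 1, 5), size=len(y))  # force ties
            pred = PredictionSet(y, (scores >= 0.5).astype(int), scores)
            pairs = []
            for i in np.flatnonzero(y == 1):
                for j in np.flatnonzero(y == 0):
                    pairs.append(
                        1.0 if scores[i] > scores[j]
                        else 0.5 if scores[i] == scores[j] else 0.0
                    )
            assert compute_metrics(pred)["auc"] == pytest.approx(np.mean(pairs))

    def test_single_class_rejected(self):
        y = np.ones(5, dtype=int)
        with pytest.raises(ValueError):
            compute_metrics(PredictionSet(y, y, np.full(5, 0.7)))

    def test_no_predicted_positives_warns(self):
        y = np.array([0, 1, 0, 1])
        yhat = np.zeros(4, dtype=int)
        with pytest.warns(UserWarning, match="precision"):
            m = compute_metrics(PredictionSet(y, yhat, np.full(4, 0.1)))
        assert m["precision"] == 0.0
        assert m["f1"] == 0.0


class TestLoocv:
    def test_twin_construction_perfect(self, rng):
        base = rng.standard_normal((6, 3))
        X = np.vstack([base, base])  # every subject has an identical twin
        y = np.concatenate([np.arange(6) % 2, np.arange(6) % 2]).astype(int)
        pred = loocv(ModelSpec(family="knn", hyperparameters={"k": 1}), X, y)
        assert compute_metrics(pred)["accuracy"] == 1.0

    def test_deterministic(self, rng):
        X, y = separable_data(rng, n=20, p=4, delta=1.0)
        spec = ModelSpec(family="knn")
        p1 = loocv(spec, X, y, seed=3)
        p2 = loocv(spec, X, y, seed=3)
        np.testing.assert_array_equal(p1.scores, p2.scores)
        np.testing.assert_array_equal(p1.y_pred, p2.y_pred)

    def test_null_permutation_auc(self, rng):
        # Mean held-out AUC over label permutations must center on 0.5.
        # 1-NN is used because larger vote counts carry a small pessimistic
        # leave-one-out bias (the held-out subject's class loses one vote).
        X = rng.standard_normal((40, 4))
        spec = ModelSpec(family="knn", hyperparameters={"k": 1})
        aucs = []
        for _ in range(200):
            y = rng.permutation(np.array([0, 1] * 20))
            aucs.append(compute_metrics(loocv(spec, X, y))["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            loocv(ModelSpec(family="knn"), rng.standard_normal((2, 2)), np.array([0, 1]))


class TestBootstrapLoocv:
    def test_b1_distribution_length_one(self, rng):
        X, y = separable_data(rng, n=16, p=3, delta=2.0)
        dists = bootstrap_loocv(ModelSpec(family="knn"), X, y, B=1, seed=0)
        for m in METRICS:
            assert len(dists[m].values) == 1
            assert dists[m].mean == dists[m].values[0]

    def test_identity_hook_reproduces_loocv(self, rng):
        X, y = separable_data(rng, n=18, p=4, delta=1.0)
        spec = ModelSpec(family="knn")
        pred = loocv(spec, X, y, seed=5)
        expected = compute_metrics(pred)
        dists = bootstrap_loocv(spec, X, y, B=2, seed=5, identity_resample=True)
        for m in METRICS:
            assert dists[m].values[0] == expected[m]
            assert dists[m].values[1] == expected[m]

    def test_separable_high_auc(self, rng):
        X, y = separable_data(rng, n=20, p=3, n_informative=2, delta=4.0)
        dists = bootstrap_loocv(ModelSpec(family="knn"), X, y, B=200, seed=1)
        assert dists["auc"].mean > 0.95

    def test_percentile_bracket_invariant(self, rng):
        X, y = separable_data(rng, n=16, p=3, delta=1.0)
        dists = bootstrap_loocv(ModelSpec(family="knn"), X, y, B=50, seed=2)
        for d in dists.values():
            assert d.values.min() <= d.lo <= d.mean <= d.hi <= d.values.max()

    def test_null_interval_covers_half(self, rng):
        # Reduced-scale coverage check on label-independent data.
        covered = 0
        n_rep = 12
        for rep in range(n_rep):
            X = rng.standard_normal((16, 3))
            y = np.array([0, 1] * 8)
            d = bootstrap_loocv(ModelSpec(family="knn"), X, y, B=60, seed=rep)["auc"]
            covered += d.lo <= 0.5 <= d.hi
        assert covered >= 0.9 * n_rep - 1e-9 or covered >= n_rep - 1

    def test_deterministic(self, rng):
        X, y = separable_data(rng, n=14, p=3, delta=1.0)
        d1 = bootstrap_loocv(ModelSpec(family="knn"), X, y, B=10, seed=7)
        d2 = bootstrap_loocv(ModelSpec(family="knn"), X, y, B=10, seed=7)
        for m in METRICS:
            np.testing.assert_array_equal(d1[m].values, d2[m].values)


class TestRunStudy:
    ROW_RE = re.compile(r"^\d\.\d{2} \[\d\.\d{2}–\d\.\d{2}\]$")

    def test_row_format(self, default_cohort):
        features, cohort = default_cohort
        config = RunConfig(feature_set="acoustic", model="knn",
                           evaluation="bootstrap_loocv", n_bootstrap=5, seed=0)
        report = run_study(config, features, cohort)
        assert set(report["row"]) == set(METRICS)
        for cell in report["row"].values():
            assert self.ROW_RE.match(cell), cell

    def test_identical_config_identical_report(self, default_cohort):
        features, cohort = default_cohort
        config = RunConfig(feature_set="acoustic", model="knn",
                           evaluation="loocv", seed=1)
        r1 = run_study(config, features, cohort)
        r2 = run_study(config, features, cohort)
        assert r1 == r2

    def test_vlpso_run_emits_selection(self, default_cohort):
        features, cohort = default_cohort
        config = RunConfig(
            feature_set="acoustic", model="vlpso_knn", evaluation="loocv", seed=0,
            swarm={"max_iterations": 15, "population_size": 10, "n_divisions": 4},
        )
        report = run_study(config, features, cohort)
        assert len(report["selection"]["selected_names"]) >= 1
        assert 0 <= report["metrics"]["auc"]["mean"] <= 1

    def test_format_metric(self):
        d = MetricDistribution.from_values("auc", np.array([0.7, 0.8, 0.9]))
        assert format_metric(d) == f"{d.mean:.2f} [{d.lo:.2f}–{d.hi:.2f}]"
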