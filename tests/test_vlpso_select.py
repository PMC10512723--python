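import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from amyvox.vlpso_select import (
    SwarmConfig,
    decode,
    rank_relevance,
    subset_fitness,
    symmetric_uncertainty,
    vlpso_run,
)
from conftest import separable_data


class TestSymmetricUncertainty:
    def test_feature_identical_to_label(self):
        y = np.array([0, 1] * 20)
        assert symmetric_uncertainty(y.astype(float), y) == pytest.approx(1.0)
        X = np.column_stack([np.random.default_rng(0).standard_normal(40), y])
        assert rank_relevance(X, y)[0] == 1

    def test_independent_feature_near_zero(self, rng):
        n = 10_000
        x = rng.standard_normal(n)
        y = (rng.random(n) < 0.5).astype(int)
        assert symmetric_uncertainty(x, y) < 0.01

    def test_tie_broken_by_column_index(self, rng):
        x = rng.standard_normal(30)
        y = (rng.random(30) < 0.5).astype(int)
        X = np.column_stack([x, x])  # identical -> equal SU
        order = rank_relevance(X, y)
        assert order[0] == 0

    def test_constant_feature_ranked_last(self, rng):
        y = np.array([0, 1] * 15)
        X = np.column_stack([np.ones(30), y.astype(float)])
        order = rank_relevance(X, y)
        assert list(order) == [1, 0]
        assert symmetric_uncertainty(np.ones(30), y) == 0.0


class TestDecode:
    def test_all_selected(self):
        assert list(decode(np.ones(5), 0.6)) == [0, 1, 2, 3, 4]

    def test_none_selected(self):
        assert len(decode(np.zeros(5), 0.6)) == 0

    def test_strict_inequality_at_threshold(self):
        sel = decode(np.array([0.7, 0.6, 0.61]), 0.6)
        assert list(sel) == [0, 2]


class TestSubsetFitness:
    def test_empty_subset_is_one(self, rng):
        X = rng.standard_normal((20, 4))
        y = np.array([0, 1] * 10)
        assert subset_fitness(X, y, np.array([], dtype=int)) == 1.0

    def test_separable_subset_near_zero(self, rng):
        X, y = separable_data(rng, n=80, p=6, n_informative=2, delta=6.0)
        assert subset_fitness(X, y, np.array([0, 1]), folds=10, seed=0) < 0.05

    def test_matches_hand_rolled_cv(self, rng):
        # Brute-force oracle: replicate the stratified splits, the z-scoring
        # and the KNN vote with explicit loops, independent of the library path.
        X = rng.standard_normal((6, 3))
        y = np.array([0, 1, 0, 1, 0, 1])
        subset = np.array([0, 2])
        k, folds, seed = 3, 2, 5

        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        pred = np.empty(6, dtype=int)
        Xs = X[:, subset]
        for train, test in skf.split(Xs, y):
            mu, sd = Xs[train].mean(axis=0), Xs[train].std(axis=0)
            sd[sd == 0] = 1.0
            Ztr, Zte = (Xs[train] - mu) / sd, (Xs[test] - mu) / sd
            for row, i in enumerate(test):
                d = cdist(Zte[row : row + 1], Ztr)[0]
                nearest = np.argsort(d, kind="stable")[:k]
                votes = y[train][nearest].sum()
                pred[i] = 1 if votes / k >= 0.5 else 0
        sens = (pred[y == 1] == 1).mean()
        spec = (pred[y == 0] == 0).mean()
        expected = 1.0 - 0.5 * (sens + spec)

        got = subset_fitness(X, y, subset, knn_k=k, folds=folds, seed=seed)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_folds_reduced_to_minority(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        with pytest.warns(UserWarning, match="reducing"):
            f = subset_fitness(X, y, np.array([0]), folds=10, seed=0)
        assert 0.0 <= f <= 1.0

    def test_minority_too_small_rejected(self, rng):
        X = rng.standard_normal((5, 2))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            subset_fitness(X, y, np.array([0]))


class TestSwarmConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"threshold": 0.0},
            {"threshold": 1.0},
            {"n_divisions": 40, "population_size": 30},
            {"max_iterations": 0},
            {"max_velocity": 0.0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SwarmConfig(**kwargs)


class TestVlpsoRun:
    def test_trace_non_increasing(self, rng):
        X, y = separable_data(rng, n=40, p=10)
        for seed in (0, 1, 2):
            res = vlpso_run(X, y, SwarmConfig(seed=seed, max_iterations=15,
                                              population_size=12, n_divisions=4))
            trace = np.array(res.fitness_trace)
            assert np.all(np.diff(trace) <= 1e-12)
            assert res.best_fitness == trace[-1]

    def test_reproducible(self, rng):
        X, y = separable_data(rng, n=40, p=10)
        cfg = SwarmConfig(seed=9, max_iterations=10, population_size=10, n_divisions=5)
        r1 = vlpso_run(X, y, cfg)
        r2 = vlpso_run(X, y, cfg)
        assert r1 == r2

    def test_selected_nonempty_and_valid(self, rng):
        X, y = separable_data(rng, n=40, p=10)
        res = vlpso_run(X, y, SwarmConfig(seed=0, max_iterations=10, population_size=10))
        assert len(res.selected_indices) >= 1
        assert all(0 <= j < 10 for j in res.selected_indices)

    def test_evaluation_budget(self, rng):
        X, y = separable_data(rng, n=40, p=10)
        cfg = SwarmConfig(seed=4, max_iterations=20, population_size=10, n_divisions=5)
        res = vlpso_run(X, y, cfg)
        # init + per-iteration evaluations + at most one truncation
        # re-evaluation per particle per possible renewal event
        renewals = math.ceil(cfg.max_iterations / cfg.renewal_gap)
        bound = cfg.population_size * (cfg.max_iterations + 1 + renewals)
        assert res.n_evaluations <= bound

    def test_matches_exhaustive_oracle_on_toy(self, rng):
        # Small version of the acceptance check: 5 seeds, 8 features.
        from itertools import combinations

        X, y = separable_data(rng, n=60, p=8, n_informative=2, delta=6.0)
        fitness_seed = 0
        best = min(
            subset_fitness(X, y, np.array(s), seed=fitness_seed)
            for r in range(1, 9)
            for s in combinations(range(8), r)
        )
        # Single-seed equivalence (the 40-seed sweep lives in the acceptance suite).
        res = vlpso_run(X, y, SwarmConfig(seed=fitness_seed, max_iterations=40,
                                          population_size=20, n_divisions=4))
        assert res.best_fitness == pytest.approx(best, abs=1e-12)

    def test_planted_feature_recovery_quick(self, rng):
        X, y = separable_data(rng, n=150, p=12, n_informative=3, delta=1.5)
        found = 0
        for seed in range(5):
            res = vlpso_run(X, y, SwarmConfig(seed=seed, max_iterations=30,
                                              population_size=20, n_divisions=4))
            if {0, 1, 2} <= set(res.selected_indices):
                found += 1
        assert found >= 4

    def test_median_selected_size_on_default_cohort(self, default_cohort):
        # Qualitative regime check: 7 planted of 88 -> median size in [5, 15].
        from amyvox.io_config import assemble_design

        features, cohort = default_cohort
        X, y, names = assemble_design(features, cohort, "acoustic")
        sizes = []
        for seed in range(20):
            res = vlpso_run(X, y, SwarmConfig(seed=seed), feature_names=names)
            sizes.append(len(res.selected_indices))
        assert 5 <= np.median(sizes) <= 15
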