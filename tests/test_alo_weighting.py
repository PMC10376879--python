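"""Feature weighting, k-NN fitness, and the ant lion optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from oagrade.alo_weighting import (ALOConfig, KnnCvFitness, alo_minimize,
                                   alo_optimize, apply_weights, decode_k,
                                   knn_cv_loss, random_walk, roulette_select,
                                   trace_to_csv, weight_report)
from oagrade.synthetic_data import SyntheticSpec, generate_features

from conftest import make_table


class TestApplyWeights:
    def test_identity_annihilation_and_scaling(self, small_table):
        p = small_table.n_features
        assert apply_weights(small_table, np.ones(p)).equals(small_table)
        assert np.all(apply_weights(small_table, np.zeros(p)).values == 0)
        # the published weighting is a plain per-feature multiplication
        table = make_table(np.array([[2.0]]))
        weighted = apply_weights(table, [0.522642])
        assert weighted.values[0, 0] == pytest.approx(1.045284)

    def test_length_and_range_checked(self, small_table):
        with pytest.raises(ValueError):
            apply_weights(small_table, np.ones(small_table.n_features - 1))
        with pytest.raises(ValueError):
            apply_weights(small_table, np.full(small_table.n_features, 1.5))


class TestKnnCvLoss:
    def test_perfect_separation_gives_zero_loss(self):
        table = generate_features(SyntheticSpec(
            n_per_class=10, n_informative=4, n_noise=6, separation=10.0, seed=0))
        assert knn_cv_loss(table, np.ones(10), k=1) == 0.0

    def test_uniform_scaling_invariance(self, small_table):
        p = small_table.n_features
        for c in (0.2, 0.5, 1.0):
            assert knn_cv_loss(small_table, np.full(p, c), k=3) == \
                   knn_cv_loss(small_table, np.full(p, 1.0), k=3)

    def test_permuted_labels_are_chance_level(self):
        """4 balanced classes with shuffled labels lose 3 in 4."""
        losses = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            table = generate_features(SyntheticSpec(
                n_per_class=30, n_informative=4, n_noise=6, separation=4.0,
                seed=seed))
            table.labels = rng.permutation(table.labels)
            losses.append(knn_cv_loss(table, np.ones(10), k=5, seed=seed))
        losses = np.array(losses)
        se = losses.std(ddof=1) / np.sqrt(len(losses))
        assert abs(losses.mean() - 0.75) < 3 * se

    def test_k_bounds_enforced(self, small_table):
        with pytest.raises(ValueError, match="k="):
            knn_cv_loss(small_table, np.ones(10), k=100)

    def test_matches_sklearn_knn(self):
        """Cached-distance CV agrees with sklearn on identical folds."""
        table = generate_features(SyntheticSpec(
            n_per_class=15, n_informative=4, n_noise=6, separation=3.0, seed=3))
        weights = np.linspace(0.1, 1.0, 10)
        for k in (1, 5):
            mine = knn_cv_loss(table, weights, k=k, folds=5, seed=9)
            x = table.values * weights
            splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=9)
            correct = total = 0
            for tr, te in splitter.split(x, table.labels):
                clf = KNeighborsClassifier(n_neighbors=k).fit(x[tr], table.labels[tr])
                correct += (clf.predict(x[te]) == table.labels[te]).sum()
                total += len(te)
            assert mine == pytest.approx(1 - correct / total, abs=1e-12)


class TestWalkAndRoulette:
    @given(st.integers(min_value=1, max_value=200))
    @settings(max_examples=50, derandomize=True)
    def test_walk_shape_and_steps(self, n_steps):
        walk = random_walk(n_steps, np.random.default_rng(0))
        assert walk.shape == (n_steps + 1,)
        assert walk[0] == 0.0
        assert set(np.unique(np.diff(walk))) <= {-1.0, 1.0}

    def test_walk_is_unbiased(self):
        rng = np.random.default_rng(1)
        finals = np.array([random_walk(100, rng)[-1] for _ in range(10000)])
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean()) < 4 * se

    def test_minmax_normalization_stays_in_bounds(self):
        rng = np.random.default_rng(2)
        walk = random_walk(100, rng)
        c, d = -0.3, 0.8
        scaled = (walk - walk.min()) * (d - c) / (walk.max() - walk.min()) + c
        assert scaled.min() >= c - 1e-12 and scaled.max() <= d + 1e-12

    def test_single_candidate_always_chosen(self):
        rng = np.random.default_rng(3)
        assert all(roulette_select([0.4], rng) == 0 for _ in range(20))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            roulette_select([], np.random.default_rng(0))

    @pytest.mark.parametrize("losses,p0", [((0.1, 0.1), 0.5),
                                           ((0.01, 0.99), 0.99)])
    def test_selection_frequencies(self, losses, p0):
        rng = np.random.default_rng(4)
        draws = np.array([roulette_select(losses, rng) for _ in range(10000)])
        freq0 = (draws == 0).mean()
        se = np.sqrt(p0 * (1 - p0) / len(draws))
        assert abs(freq0 - p0) < 3 * se


class TestOptimizer:
    def test_elitism_and_reproducibility(self, small_table):
        config = ALOConfig(n_ants=8, n_antlions=8, max_iterations=15, seed=5)
        sol1, trace1 = alo_optimize(small_table, config)
        sol2, trace2 = alo_optimize(small_table, config)
        assert np.all(np.diff(trace1.elite_loss_per_iteration) <= 0)
        assert np.array_equal(sol1.weights, sol2.weights)
        assert sol1.k == sol2.k and sol1.final_loss == sol2.final_loss
        assert np.array_equal(trace1.elite_loss_per_iteration,
                              trace2.elite_loss_per_iteration)

    def test_solution_respects_bounds(self, small_table):
        config = ALOConfig(n_ants=6, n_antlions=6, max_iterations=10,
                           k_max=9, seed=6)
        sol, _ = alo_optimize(small_table, config)
        assert (sol.weights >= 0).all() and (sol.weights <= 1).all()
        assert sol.k % 2 == 1 and 1 <= sol.k <= 9

    def test_final_loss_is_minimum_seen(self, small_table):
        """The elite is the best candidate ever evaluated."""
        losses = []
        fitness = KnnCvFitness(small_table, folds=5, seed=7)

        def spying_loss(vec):
            loss = fitness(vec[:10], decode_k(vec[10], 9))
            losses.append(loss)
            return loss

        config = ALOConfig(n_ants=6, n_antlions=6, max_iterations=10, seed=7)
        lower = np.concatenate([np.zeros(10), [1.0]])
        upper = np.concatenate([np.ones(10), [9.0]])
        _, elite_loss, _ = alo_minimize(spying_loss, lower, upper, config)
        assert elite_loss == min(losses)

    def test_sphere_benchmark_converges(self):
        """Elite loss on sum(w^2) drops below 1e-2 with 20 antlions."""
        hits = 0
        for seed in range(5):
            config = ALOConfig(n_ants=20, n_antlions=20, max_iterations=100,
                               seed=seed)
            _, loss, _ = alo_minimize(lambda v: float(np.sum(v ** 2)),
                                      np.zeros(10), np.ones(10), config)
            hits += loss < 1e-2
        assert hits >= 4

    def test_weight_recovery_tendency(self):
        """Informative features receive larger mean weights than noise."""
        wins = 0
        for seed in range(5):
            spec = SyntheticSpec(n_per_class=40, n_informative=4, n_noise=6,
                                 separation=4.0, seed=seed)
            table = generate_features(spec)
            info = spec.informative_indices
            noise = np.setdiff1d(np.arange(10), info)
            sol, _ = alo_optimize(table, ALOConfig(max_iterations=50, seed=seed))
            wins += sol.weights[info].mean() > sol.weights[noise].mean()
        assert wins >= 4

    def test_reports(self, small_table):
        config = ALOConfig(n_ants=4, n_antlions=4, max_iterations=5, seed=8)
        sol, trace = alo_optimize(small_table, config)
        text = weight_report(sol, small_table.feature_names)
        assert "y =" in text and str(sol.k) in text
        csv = trace_to_csv(trace)
        assert csv.startswith("iteration,elite_loss")
        assert len(csv.strip().splitlines()) == 6
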