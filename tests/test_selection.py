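"""Subset searches against brute-force oracles on small feature universes."""

import itertools

import numpy as np
import pytest

from hostsieve.models import Hyperparameters
from hostsieve.selection import (
    SubsetEvaluator,
    bottom_up_search,
    embedded_select,
    ga_search,
    subset_to_bitmask,
    write_selection_log,
)
from hostsieve.synthetic import planted_dataset

HP = Hyperparameters("knn", k=3)


@pytest.fixture(scope="module")
def planted():
    X, y, informative = planted_dataset(
        n_samples=60, n_informative=2, n_noise=3, effect_size=2.0, seed=5
    )
    return X, y, informative


@pytest.fixture(scope="module")
def oracle_best(planted):
    """Exhaustive brute-force evaluation of all 31 subsets of 5 features."""
    X, y, _ = planted
    ev = SubsetEvaluator(X, y, HP, seed=0)
    log = {
        s: ev.fitness(s)
        for r in range(1, 6)
        for s in itertools.combinations(range(5), r)
    }
    best = max(log, key=log.get)
    return best, log[best], log


class TestSubsetEvaluator:
    def test_memoization_returns_identical_fitness(self, planted):
        X, y, _ = planted
        ev = SubsetEvaluator(X, y, HP, seed=0)
        f1 = ev.fitness((0, 1))
        n_after_first = ev.n_evaluations
        f2 = ev.fitness((1, 0))  # same canonical subset
        assert f1 == f2
        assert ev.n_evaluations == n_after_first

    def test_empty_subset_rejected(self, planted):
        X, y, _ = planted
        with pytest.raises(ValueError, match="empty"):
            SubsetEvaluator(X, y, HP).fitness(())

    def test_informative_subset_beats_noise_subset(self, planted):
        X, y, informative = planted
        ev = SubsetEvaluator(X, y, HP, seed=0)
        assert ev.fitness(tuple(informative)) > ev.fitness((3, 4))


class TestBottomUp:
    def test_finds_brute_force_optimum_and_covers_informative(
        self, planted, oracle_best
    ):
        X, y, informative = planted
        best_subset, best_fitness, _ = oracle_best
        res = bottom_up_search(X, y, HP, top_k=10, patience=5, seed=0)
        assert res.best_fitness == pytest.approx(best_fitness)
        assert set(informative) <= set(res.best_subset)

    def test_evaluation_count_bounded_by_all_subsets(self, planted):
        X, y, _ = planted
        res = bottom_up_search(X, y, HP, top_k=10, patience=5, seed=0)
        assert len(res.log) <= 2**5 - 1

    def test_patience_zero_stops_after_initial_enumeration(self, planted):
        X, y, _ = planted
        res = bottom_up_search(X, y, HP, patience=0, init_max_len=2, seed=0)
        n = X.shape[1]
        assert len(res.log) == n + n * (n - 1) // 2  # sizes 1 and 2 only
        assert len(res.best_subset) <= 2

    def test_best_fitness_equals_max_over_log(self, planted):
        X, y, _ = planted
        res = bottom_up_search(X, y, HP, top_k=5, patience=3, seed=1)
        assert res.best_fitness == pytest.approx(max(res.log.values()))

    def test_invalid_settings_rejected(self, planted):
        X, y, _ = planted
        with pytest.raises(ValueError):
            bottom_up_search(X, y, HP, top_k=0)
        with pytest.raises(ValueError):
            bottom_up_search(X, y, HP, patience=-1)

    def test_logged_fitness_matches_reevaluation(self, planted):
        X, y, _ = planted
        res = bottom_up_search(X, y, HP, top_k=10, patience=2, seed=0)
        ev = SubsetEvaluator(X, y, HP, seed=0)
        assert ev.fitness(res.best_subset) == res.log[res.best_subset]


class TestGeneticAlgorithm:
    def test_reaches_near_oracle_on_six_features(self):
        X, y, _ = planted_dataset(
            n_samples=60, n_informative=2, n_noise=4, effect_size=2.0, seed=6
        )
        ev = SubsetEvaluator(X, y, HP, seed=0)
        oracle = max(
            ev.fitness(s)
            for r in range(1, 7)
            for s in itertools.combinations(range(6), r)
        )
        res = ga_search(
            X, y, HP, pop_size=20, generations=30, repeats=3, seed=0
        )
        assert res.best_fitness >= 0.95 * oracle

    def test_uniform_population_without_mutation_terminates_immediately(
        self, planted
    ):
        X, y, _ = planted
        res = ga_search(
            X, y, HP, pop_size=4, generations=50, crossover_p=0.0,
            mutation_p=0.0, repeats=1, seed=0,
        )
        # selection-only evolution reaches uniformity long before the cap
        assert res.settings["generations_run"][0] < 50

    def test_generation_cap_respected(self, planted):
        X, y, _ = planted
        res = ga_search(X, y, HP, pop_size=6, generations=3, repeats=2, seed=0)
        assert all(g <= 3 for g in res.settings["generations_run"])

    def test_pop_size_validated(self, planted):
        X, y, _ = planted
        with pytest.raises(ValueError):
            ga_search(X, y, HP, pop_size=1)


class TestEmbeddedSelectors:
    def test_kbest_with_k_equal_n_selects_everything(self, planted):
        X, y, _ = planted
        res = embedded_select(X, y, "kbest", k_grid=[X.shape[1]], seed=0)
        assert res.best_subset == tuple(range(X.shape[1]))

    def test_rfe_down_to_single_feature(self, planted):
        X, y, _ = planted
        res = embedded_select(X, y, "rfe", k_grid=[1], seed=0)
        assert len(res.best_subset) == 1

    def test_anova_ranks_informative_above_noise(self, planted):
        from sklearn.feature_selection import f_classif

        X, y, informative = planted
        F, _ = f_classif(X, y)
        assert min(F[informative]) > max(np.delete(F, informative))

    def test_lasso_selects_signal_features(self, planted):
        X, y, informative = planted
        res = embedded_select(X, y, "lasso", seed=0)
        assert set(informative) <= set(res.best_subset)

    def test_constant_feature_column_not_fatal_for_kbest(self, planted):
        X, y, _ = planted
        Xc = np.column_stack([X, np.ones(len(y))])
        res = embedded_select(X=Xc, y=y, method="kbest", k_grid=[2], seed=0)
        assert len(res.best_subset) == 2

    def test_external_package_selectors_rejected(self, planted):
        X, y, _ = planted
        for name in ("scad", "quipt"):
            with pytest.raises(NotImplementedError, match="external"):
                embedded_select(X, y, name)


class TestAgreementBetweenMethods:
    def test_two_methods_share_the_planted_features(self, planted):
        X, y, informative = planted
        a = bottom_up_search(X, y, HP, top_k=10, patience=5, seed=0)
        b = ga_search(X, y, HP, pop_size=20, generations=30, repeats=3, seed=0)
        common = set(a.best_subset) & set(b.best_subset)
        assert set(informative) <= common


def test_bitmask_encoding_and_log_writer(tmp_path, planted):
    assert subset_to_bitmask((0, 3), 5) == "10010"
    X, y, _ = planted
    res = bottom_up_search(X, y, HP, top_k=5, patience=1, seed=0)
    out = tmp_path / "log.tsv"
    write_selection_log(out, res, X.shape[1])
    lines = out.read_text().strip().split("\n")
    assert lines[0] == "subset_bitmask\tn_features\tfitness"
    assert len(lines) == len(res.log) + 1
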