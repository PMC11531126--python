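import numpy as np
import pytest

from survsel.data import SimulationConfig, SurvivalDataset, simulate_dataset
from survsel.forest import (
    RSFConfig,
    _candidate_cutpoints,
    ensemble_chf,
    grow_forest,
    logrank_split_scores,
    minimal_depth,
    oob_error,
    rsf_select,
)

from conftest import random_survival_instance


def brute_force_logrank(times, events, group1) -> float:
    """Two-sample log-rank statistic by direct summation over event times."""
    num = var = 0.0
    for t in np.unique(times[events == 1]):
        Y = float((times >= t).sum())
        Y1 = float(((times >= t) & group1).sum())
        d = float(((times == t) & (events == 1)).sum())
        d1 = float(((times == t) & (events == 1) & group1).sum())
        num += d1 - Y1 * d / Y
        if Y > 1:
            var += (Y1 / Y) * (1 - Y1 / Y) * ((Y - d) / (Y - 1)) * d
    if var <= 1e-12:
        return -np.inf
    return num**2 / var


class TestLogRankScores:
    def test_hand_six_row_dataset(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([0.1, 0.2, 0.3, 1.1, 1.2, 1.3])
        cuts = _candidate_cutpoints(x, 32)
        scores = logrank_split_scores(times, events, x, cuts)
        for c, s in zip(cuts, scores):
            expected = brute_force_logrank(times, events, x <= c)
            g1, g2 = x <= c, x > c
            if events[g1].sum() < 1 or events[g2].sum() < 1:
                assert s == -np.inf
            else:
                assert s == pytest.approx(expected, abs=1e-10)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            data = random_survival_instance(rng, n_max=10, p_max=1, allow_ties=True)
            x = data.covariates[:, 0]
            cuts = _candidate_cutpoints(x, 32)
            if len(cuts) == 0:
                continue
            scores = logrank_split_scores(data.times, data.events, x, cuts)
            for c, s in zip(cuts, scores):
                g1 = x <= c
                if (
                    data.events[g1].sum() < 1
                    or data.events[~g1].sum() < 1
                    or brute_force_logrank(data.times, data.events, g1) == -np.inf
                ):
                    assert s == -np.inf
                else:
                    assert s == pytest.approx(
                        brute_force_logrank(data.times, data.events, g1), abs=1e-10
                    )


@pytest.fixture(scope="module")
def informative_forest():
    data, beta = simulate_dataset(
        SimulationConfig(n=150, p=5, n_informative=1, beta_magnitude=2.0,
                         censor_rate=0.2, correlation=0.0, seed=8)
    )
    forest = grow_forest(data, B=60, seed=8, nodesize=10)
    return data, beta, forest


class TestGrowth:
    def test_mtry_bounds(self, small_informative):
        data, _ = small_informative
        with pytest.raises(ValueError):
            grow_forest(data, B=2, mtry=data.p + 1)

    def test_deterministic_under_seed(self):
        data, _ = simulate_dataset(SimulationConfig(n=60, p=4, n_informative=2, seed=3))
        f1 = grow_forest(data, B=5, seed=7)
        f2 = grow_forest(data, B=5, seed=7)
        for a, b in zip(f1.bootstrap_indices, f2.bootstrap_indices):
            np.testing.assert_array_equal(a, b)
        grid = np.linspace(0, data.times.max(), 10)
        np.testing.assert_array_equal(
            ensemble_chf(f1, data.covariates[:5], grid)[0],
            ensemble_chf(f2, data.covariates[:5], grid)[0],
        )

    def test_dominant_covariate_splits_every_root(self):
        rng = np.random.default_rng(5)
        n = 60
        x = np.concatenate([rng.uniform(0, 1, n // 2), rng.uniform(5, 6, n // 2)])
        times = np.concatenate(
            [rng.uniform(0.1, 1.0, n // 2), rng.uniform(8.0, 10.0, n // 2)]
        )
        data = SurvivalDataset(times, np.ones(n, int), x[:, None], ["x1"])
        forest = grow_forest(data, B=10, seed=1, nodesize=10)
        assert all(t.split_feature == 0 for t in forest.trees)

    def test_oob_fraction_near_one_over_e(self):
        data, _ = simulate_dataset(SimulationConfig(n=150, p=3, n_informative=1, seed=4))
        forest = grow_forest(data, B=60, seed=2)
        frac = np.mean([len(forest.oob_indices(b)) / data.n for b in range(60)])
        assert abs(frac - np.exp(-1)) < 0.03

    def test_monotone_transform_leaves_structure(self):
        data, _ = simulate_dataset(
            SimulationConfig(n=80, p=2, n_informative=1, beta_magnitude=1.5,
                             censor_rate=0.2, seed=9)
        )
        transformed = SurvivalDataset(
            data.times, data.events, data.covariates**3, data.feature_names
        )
        f1 = grow_forest(data, B=8, seed=3)
        f2 = grow_forest(transformed, B=8, seed=3)
        grid = np.linspace(0, data.times.max(), 12)
        np.testing.assert_allclose(
            ensemble_chf(f1, data.covariates, grid)[0],
            ensemble_chf(f2, data.covariates**3, grid)[0],
            atol=1e-12,
        )


class TestEnsemble:
    def test_single_tree_equals_its_leaf(self, informative_forest):
        data, _, _ = informative_forest
        forest = grow_forest(data, B=1, seed=0)
        grid = np.linspace(0, data.times.max(), 8)
        chf, surv = ensemble_chf(forest, data.covariates[:3], grid)
        from survsel.forest import _chf_at, _leaf_of

        for i in range(3):
            leaf = _leaf_of(forest.trees[0], data.covariates[i])
            np.testing.assert_allclose(chf[i], _chf_at(leaf, grid))

    def test_time_zero_is_certain_survival(self, informative_forest):
        data, _, forest = informative_forest
        chf, surv = ensemble_chf(forest, data.covariates[:4], np.array([0.0, 1.0]))
        np.testing.assert_allclose(chf[:, 0], 0.0)
        np.testing.assert_allclose(surv.surv[:, 0], 1.0)

    def test_chf_nondecreasing_per_subject(self, informative_forest):
        data, _, forest = informative_forest
        grid = np.linspace(0, data.times.max(), 25)
        chf, _ = ensemble_chf(forest, data.covariates[:10], grid)
        assert np.all(np.diff(chf, axis=1) >= -1e-12)


class TestOOB:
    def test_informative_forest_beats_chance(self, informative_forest):
        data, _, forest = informative_forest
        assert oob_error(forest, data) < 0.3

    def test_pure_noise_near_half(self):
        errs = []
        for s in range(3):
            data, _ = simulate_dataset(
                SimulationConfig(n=120, p=5, n_informative=0, beta_magnitude=0.0,
                                 censor_rate=0.3, seed=300 + s)
            )
            errs.append(oob_error(grow_forest(data, B=40, seed=s), data))
        assert abs(np.mean(errs) - 0.5) < 0.1


class TestMinimalDepth:
    def test_dominant_feature_shallowest(self, informative_forest):
        data, beta, forest = informative_forest
        md = minimal_depth(forest)
        assert int(np.argmin(md)) == 0  # the single informative feature

    def test_unused_feature_deeper_than_any_used(self):
        data, _ = simulate_dataset(
            SimulationConfig(n=60, p=2, n_informative=1, beta_magnitude=2.5,
                             censor_rate=0.1, correlation=0.0, seed=12)
        )
        forest = grow_forest(data, B=10, mtry=2, seed=0, nodesize=20)
        used = set()
        for t in forest.trees:
            stack = [t]
            while stack:
                nd = stack.pop()
                if not nd.is_leaf:
                    used.add(nd.split_feature)
                    stack += [nd.left, nd.right]
        md = minimal_depth(forest)
        for j in range(data.p):
            if j not in used:
                assert md[j] > max(md[k] for k in used)


class TestSelect:
    def test_minimal_depth_branch_for_low_ratio(self, informative_forest):
        data, _, _ = informative_forest
        fs = rsf_select(data, RSFConfig(B=30, seed=1))
        assert fs.tuning["mode"] == "minimal_depth"
        assert data.feature_names[0] in fs.features

    def test_variable_hunting_branch_for_high_ratio(self):
        data, _ = simulate_dataset(
            SimulationConfig(n=25, p=260, n_informative=2, beta_magnitude=2.0,
                             censor_rate=0.2, correlation=0.0, seed=13)
        )
        fs = rsf_select(data, RSFConfig(B=10, vh_B=8, vh_repetitions=4, seed=13))
        assert fs.tuning["mode"] == "variable_hunting"
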