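import numpy as np
import pytest

from survsel.coxph import SurvCurveSet
from survsel.data import SimulationConfig, SurvivalDataset, simulate_dataset
from survsel.metrics import (
    brier_score,
    c_index,
    comparable_pairs,
    iae_ise,
    integrated_brier,
    km_survival,
    reverse_km,
)

from conftest import random_survival_instance


def constant_curves(test, value, grid=None):
    grid = np.unique(test.times) if grid is None else grid
    return SurvCurveSet(grid, np.full((test.n, len(grid)), value))


class TestReverseKM:
    def test_no_censoring_gives_unit_G(self):
        data = SurvivalDataset([1, 2, 3], [1, 1, 1], np.zeros((3, 1)), ["x"])
        G = reverse_km(data)
        np.testing.assert_allclose(G.at(np.array([0.5, 1.5, 2.5])), 1.0)

    def test_hand_product_limit(self):
        data = SurvivalDataset([1, 2, 3], [1, 0, 1], np.zeros((3, 1)), ["x"])
        G = reverse_km(data)
        np.testing.assert_allclose(G.at(np.array([1.5, 2.0, 2.9])), [1.0, 0.5, 0.5])


class TestBrierScore:
    def test_perfect_prediction_zero(self):
        test = SurvivalDataset([3, 4, 5], [1, 1, 1], np.zeros((3, 1)), ["x"])
        surv = constant_curves(test, 1.0)
        assert brier_score(surv, test, 2.0, reverse_km(test)) == 0.0

    def test_constant_half_gives_quarter(self):
        test = SurvivalDataset([1, 2, 3, 4], [1, 1, 1, 1], np.zeros((4, 1)), ["x"])
        surv = constant_curves(test, 0.5)
        assert brier_score(surv, test, 2.5, reverse_km(test)) == pytest.approx(0.25)

    def test_hand_mixed_case(self):
        test = SurvivalDataset([1, 3], [1, 1], np.zeros((2, 1)), ["x"])
        grid = np.array([2.0])
        surv = SurvCurveSet(grid, np.array([[0.2], [0.9]]))
        bs = brier_score(surv, test, 2.0, reverse_km(test))
        assert bs == pytest.approx(((0 - 0.2) ** 2 + (1 - 0.9) ** 2) / 2)

    def test_censored_before_t_contributes_nothing(self):
        test = SurvivalDataset([1, 5], [0, 1], np.zeros((2, 1)), ["x"])
        surv = constant_curves(test, 0.7, np.array([2.0]))
        # subject 1 censored before t=2: only subject 2's (1-0.7)^2 / G(2) counts
        G = reverse_km(test)
        bs = brier_score(surv, test, 2.0, G)
        assert bs == pytest.approx((1 - 0.7) ** 2 / G.at(np.array([2.0]))[0] / 2)

    def test_ipcw_recovers_uncensored_score(self):
        # same event times scored with and without independent censoring
        cfg = SimulationConfig(n=2000, p=2, n_informative=1, beta_magnitude=1.0,
                               censor_rate=0.0, seed=17)
        full, beta = simulate_dataset(cfg)
        rng = np.random.default_rng(17)
        C = rng.exponential(scale=np.quantile(full.times, 0.85), size=full.n)
        cens = SurvivalDataset(
            np.minimum(full.times, C), (full.times <= C).astype(int),
            full.covariates, full.feature_names,
        )
        t0 = float(np.quantile(full.times, 0.4))
        grid = np.array([t0])
        risk = full.covariates @ beta
        s_pred = np.exp(-0.3 * np.exp(risk - risk.mean()))[:, None]
        surv_full = SurvCurveSet(grid, s_pred)
        bs_full = brier_score(surv_full, full, t0, reverse_km(full))
        bs_cens = brier_score(SurvCurveSet(grid, s_pred), cens, t0, reverse_km(cens))
        assert bs_cens == pytest.approx(bs_full, abs=0.02)


class TestIntegratedBrier:
    def test_constant_bs_normalizes_to_itself(self):
        test = SurvivalDataset([1, 2, 3, 4], [1, 1, 1, 1], np.zeros((4, 1)), ["x"])
        surv = constant_curves(test, 0.5)
        assert integrated_brier(surv, test) == pytest.approx(0.25)

    def test_perfect_prediction_zero(self):
        test = SurvivalDataset([1, 2, 3], [1, 1, 1], np.zeros((3, 1)), ["x"])
        grid = np.array([1.0, 2.0, 3.0])
        surv = SurvCurveSet(grid, np.tile([1.0, 1.0, 0.0], (3, 1)))
        # subject-wise: the model is wrong for early deaths; use indicator-true curves
        truth = np.array([
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0],
        ])
        surv = SurvCurveSet(grid, truth)
        assert integrated_brier(surv, test) == pytest.approx(0.0)

    def test_two_point_trapezoid_hand_case(self):
        test = SurvivalDataset([2.0, 4.0], [1, 1], np.zeros((2, 1)), ["x"])
        grid = np.array([2.0, 4.0])
        surv = SurvCurveSet(grid, np.array([[0.5, 0.25], [0.5, 0.25]]))
        G = reverse_km(test)
        bs2 = brier_score(surv, test, 2.0, G)
        bs4 = brier_score(surv, test, 4.0, G)
        # step-constant extension to (0, 4]: bs2 on [0,2] then trapezoid to 4
        expected = (bs2 * 2.0 + (bs2 + bs4) / 2 * 2.0) / 4.0
        assert integrated_brier(surv, test, G) == pytest.approx(expected, abs=1e-12)


class TestComparablePairs:
    def test_all_uncensored_gives_ten(self):
        test = SurvivalDataset([1, 2, 3, 4, 5], [1] * 5, np.zeros((5, 1)), ["x"])
        assert len(comparable_pairs(test)) == 10

    def test_censoring_second_and_fourth_gives_six(self):
        test = SurvivalDataset([1, 2, 3, 4, 5], [1, 0, 1, 0, 1], np.zeros((5, 1)), ["x"])
        assert len(comparable_pairs(test)) == 6

    def test_all_censored_is_rejected_upstream(self):
        with pytest.raises(ValueError):
            SurvivalDataset([1, 2, 3], [0, 0, 0], np.zeros((3, 1)), ["x"])

    def test_matches_rule_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            data = random_survival_instance(rng, n_max=8, allow_ties=True)
            pairs = set(comparable_pairs(data))
            expected = set()
            for i in range(data.n):
                for j in range(data.n):
                    if i == j:
                        continue
                    if data.times[i] < data.times[j] and data.events[i] == 1:
                        expected.add((i, j))
                    elif (
                        data.times[i] == data.times[j]
                        and data.events[i] == 1
                        and data.events[j] == 0
                    ):
                        expected.add((i, j))
            assert pairs == expected


class TestCIndex:
    def test_perfect_separation(self):
        test = SurvivalDataset([1, 2, 3], [1, 1, 1], np.zeros((3, 1)), ["x"])
        assert c_index(np.array([3.0, 2.0, 1.0]), test) == 1.0
        assert c_index(np.array([1.0, 2.0, 3.0]), test) == 0.0

    def test_constant_scores_are_random_guessing(self):
        test = SurvivalDataset([1, 2, 3, 4], [1, 1, 0, 1], np.zeros((4, 1)), ["x"])
        assert c_index(np.ones(4), test) == 0.5

    def test_complement_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            data = random_survival_instance(rng, n_max=10)
            if not comparable_pairs(data):
                continue
            risk = rng.normal(size=data.n)
            assert c_index(risk, data) + c_index(-risk, data) == pytest.approx(1.0)

    def test_matches_double_loop_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            data = random_survival_instance(rng, n_max=8, allow_ties=True)
            risk = rng.normal(size=data.n)
            pairs = comparable_pairs(data)
            if not pairs:
                continue
            conc = sum(
                1.0 if risk[i] > risk[j] else 0.5 if risk[i] == risk[j] else 0.0
                for i, j in pairs
            )
            assert c_index(risk, data) == pytest.approx(conc / len(pairs), abs=1e-12)

    def test_survival_mode_orders_by_curve_height(self):
        test = SurvivalDataset([1, 2, 3], [1, 1, 1], np.zeros((3, 1)), ["x"])
        grid = np.array([1.0, 2.0, 3.0])
        surv = SurvCurveSet(
            grid, np.array([[0.2, 0.1, 0.0], [0.6, 0.5, 0.4], [0.9, 0.8, 0.7]])
        )
        assert c_index(surv, test, mode="survival") == 1.0


class TestIaeIse:
    def test_zero_when_model_equals_km(self):
        data, _ = simulate_dataset(SimulationConfig(n=50, p=2, n_informative=1, censor_rate=0.3, seed=6))
        km_t, km_s = km_survival(data)
        grid = np.unique(data.times[data.events == 1])
        idx = np.searchsorted(km_t, grid, side="right") - 1
        vals = np.where(idx >= 0, km_s[np.clip(idx, 0, None)], 1.0)
        surv = SurvCurveSet(grid, np.tile(vals, (data.n, 1)))
        iae, ise = iae_ise(surv, data)
        assert iae == pytest.approx(0.0, abs=1e-12)
        assert ise == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_hand_integral(self):
        # KM over times 1..4 (all events): 0.75, 0.5, 0.25, 0; model = KM + 0.1
        data = SurvivalDataset([1, 2, 3, 4], [1, 1, 1, 1], np.zeros((4, 1)), ["x"])
        grid = np.array([1.0, 2.0, 3.0, 4.0])
        model = np.array([0.85, 0.6, 0.35, 0.1])
        surv = SurvCurveSet(grid, np.tile(model, (4, 1)))
        iae, ise = iae_ise(surv, data)
        # |diff| = 0.1 at each grid point, 0 at t=0: trapezoid 0.05 + 0.3
        assert iae == pytest.approx(0.05 + 0.3, abs=1e-12)
        assert ise == pytest.approx(0.005 + 0.03, abs=1e-12)
        assert ise <= iae * 0.1 + 1e-12  # bounded by IAE * max deviation
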