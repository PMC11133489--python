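"""Cellular automaton: suitability learning, kernel rules, allocation,
validation metrics."""

import numpy as np
import pytest

from landes import landuse_ca as ca
from landes.grids import CLASS_NAMES, Grid, class_census
from landes.landuse_ca import (AllocationError, CAState, allocate,
                               figure_of_merit, fit_suitability, kappa,
                               neighborhood_effect, sample_training, simulate,
                               total_probability, update_inertia)
from conftest import make_lu


class TestSampleTraining:
    def test_exhaustive_uniform_sample(self, bundle60):
        lu = bundle60.landuse_t0
        drivers = [bundle60.dem, bundle60.precip_annual]
        X, y = sample_training(lu, drivers, n=lu.n_valid, seed=0)
        assert len(y) == lu.n_valid
        assert np.array_equal(np.bincount(y, minlength=6),
                              np.bincount(lu.values[~lu.nodata_mask],
                                          minlength=6))

    def test_stratified_covers_every_class(self, bundle60):
        lu = bundle60.landuse_t0
        X, y = sample_training(lu, [bundle60.dem], n=600, seed=1,
                               strategy="stratified")
        assert set(np.unique(y)) == set(range(6))

    def test_uniform_frequencies_match_census(self, bundle60):
        lu = bundle60.landuse_t0
        n = 3000
        X, y = sample_training(lu, [bundle60.dem], n=n, seed=2)
        census = class_census(lu)
        total = lu.n_valid
        for code, name in enumerate(CLASS_NAMES):
            p = census[name] / total
            se = np.sqrt(p * (1 - p) / n)
            assert abs(np.mean(y == code) - p) <= 3 * se + 1e-9

    def test_absent_class_stratum_warned(self):
        lu = make_lu(np.zeros((10, 10)))
        lu.values[:5] = 1
        with pytest.warns(UserWarning, match="absent"):
            sample_training(lu, [Grid(np.random.default_rng(0)
                                      .normal(size=(10, 10)))],
                            n=20, seed=0, strategy="stratified")


class TestFitSuitability:
    def _separable(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        X0 = rng.normal([-3, -3], 0.5, (n, 2))
        X1 = rng.normal([3, 3], 0.5, (n, 2))
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        return X, y

    def test_separable_classes_learned(self):
        X, y = self._separable()
        model = fit_suitability(X, y, seed=0)
        acc = np.mean(model.pipeline.predict(X) == y)
        assert acc >= 0.95

    def test_probabilities_sum_to_one(self):
        X, y = self._separable()
        model = fit_suitability(X, y, seed=0)
        probe = np.random.default_rng(1).normal(size=(1000, 2))
        proba = model.predict_proba(probe)
        assert proba.shape == (1000, 6)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_deterministic_per_seed(self):
        X, y = self._separable()
        p1 = fit_suitability(X, y, seed=7).predict_proba(X)
        p2 = fit_suitability(X, y, seed=7).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_suitability(np.zeros((10, 2)), np.zeros(10, int))


class TestNeighborhoodEffect:
    def test_interior_of_uniform_map_is_full(self):
        lu = make_lu(np.full((5, 5), 2))
        omega = neighborhood_effect(lu, k=2, N=3, w_k=1.0)
        assert omega.values[2, 2] == pytest.approx(1.0)  # 8/8

    def test_no_neighbors_is_zero(self):
        lu = make_lu(np.zeros((5, 5)))
        lu.values[2, 2] = 4  # lone urban cell
        omega = neighborhood_effect(lu, k=4, N=3)
        assert omega.values[2, 2] == 0.0  # centre excluded

    def test_single_neighbor_weighted(self):
        lu = make_lu(np.zeros((5, 5)))
        lu.values[2, 3] = 4
        omega = neighborhood_effect(lu, k=4, N=3, w_k=0.5)
        assert omega.values[2, 2] == pytest.approx(0.0625)  # 1/8 * 0.5

    def test_edge_truncation_keeps_divisor(self):
        lu = make_lu(np.full((5, 5), 1))
        omega = neighborhood_effect(lu, k=1, N=3)
        assert omega.values[0, 0] == pytest.approx(3 / 8)

    def test_bounds(self, bundle60):
        omega = neighborhood_effect(bundle60.landuse_t0, k=0, N=5, w_k=0.7)
        assert omega.values.min() >= 0.0
        assert omega.values.max() <= 0.7 + 1e-12


class TestInertia:
    @pytest.mark.parametrize("inertia,d1,d2,expected", [
        (1.0, -3.0, -5.0, 1.0),    # |D1| <= |D2|: unchanged
        (1.0, -10.0, -5.0, 0.5),   # deepening deficit: * D2/D1
        (1.0, 8.0, 4.0, 2.0),      # growing surplus: * D1/D2
        (1.3, 10.0, -4.0, 1.3),    # sign crossing: unchanged (fallback)
        (0.7, 0.0, 0.0, 0.7),      # zero gaps: unchanged
    ])
    def test_three_branch_rule(self, inertia, d1, d2, expected):
        assert update_inertia(inertia, d1, d2) == pytest.approx(expected)

    def test_result_stays_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            out = update_inertia(rng.uniform(0.01, 5),
                                 rng.normal(0, 10), rng.normal(0, 10))
            assert out > 0


class TestTotalProbability:
    def test_forbidden_transition_zero(self):
        assert total_probability(0.9, 0.9, 5.0, 1.0) == 0.0

    def test_arithmetic(self):
        assert total_probability(0.5, 0.4, 1.25, 0.2) == pytest.approx(0.2)

    def test_identity(self):
        assert total_probability(1.0, 1.0, 1.0, 0.0) == 1.0


def _uniform_state(n_valid, seed=0):
    rng = np.random.default_rng(seed)
    suit = rng.dirichlet(np.ones(6), size=n_valid)
    return CAState(suitability=suit)


class TestAllocate:
    def test_zero_gap_returns_map_unchanged(self, bundle60, suitability60):
        lu = bundle60.landuse_t0
        state = CAState(suitability=suitability60)
        out = allocate(state, lu, class_census(lu), seed=0)
        assert np.array_equal(out.values, lu.values)

    def test_demand_met_and_cells_conserved(self, bundle60, suitability60):
        lu = bundle60.landuse_t0
        demands = dict(class_census(lu))
        demands["urban"] += 10
        demands["barren"] -= 10
        state = CAState(suitability=suitability60)
        out = allocate(state, lu, demands, seed=1, tolerance=0)
        assert out.n_valid == lu.n_valid
        assert class_census(out) == demands

    def test_forbidden_demand_raises(self, bundle60, suitability60):
        lu = bundle60.landuse_t0
        census = class_census(lu)
        demands = dict(census)
        demands["barren"] += census["water"]
        demands["water"] = 0
        costs = np.zeros((6, 6))
        costs[CLASS_NAMES.index("water"), :] = 1.0
        np.fill_diagonal(costs, 0.0)
        state = CAState(suitability=suitability60, costs=costs)
        with pytest.raises(AllocationError):
            allocate(state, lu, demands, seed=0, max_iters=10)

    def test_monotone_pressure(self, bundle60, suitability60):
        lu = bundle60.landuse_t0
        census = class_census(lu)
        finals = []
        for extra in (10, 40):
            demands = dict(census)
            demands["urban"] += extra
            demands["grassland"] -= extra
            state = CAState(suitability=suitability60.copy())
            out = allocate(state, lu, demands, seed=5, tolerance=0)
            finals.append(class_census(out)["urban"])
        assert finals[1] >= finals[0]

    def test_deterministic_per_seed(self, bundle60, suitability60):
        lu = bundle60.landuse_t0
        demands = dict(class_census(lu))
        demands["urban"] += 20
        demands["barren"] -= 20
        outs = []
        for _ in range(2):
            state = CAState(suitability=suitability60.copy())
            outs.append(allocate(state, lu, demands, seed=9))
        assert np.array_equal(outs[0].values, outs[1].values)


@pytest.fixture(scope="module")
def suitability60(bundle60):
    drivers = [getattr(bundle60, n) for n in bundle60.driver_names()]
    X, y = sample_training(bundle60.landuse_t0, drivers, n=1500, seed=0,
                           strategy="stratified")
    model = fit_suitability(X, y, seed=0)
    return ca.suitability_surfaces(model, bundle60.landuse_t0, drivers)


class TestSimulate:
    def test_zero_change_schedule_returns_t0(self, bundle60, suitability60):
        lu = bundle60.landuse_t0
        state = CAState(suitability=suitability60.copy())
        maps = simulate(lu, [bundle60.dem], {"p1": class_census(lu)},
                        state=state, seed=0)
        assert np.array_equal(maps["p1"].values, lu.values)

    def test_true_demand_schedule_census(self, bundle60, suitability60):
        lu = bundle60.landuse_t0
        state = CAState(suitability=suitability60.copy())
        maps = simulate(lu, [bundle60.dem], {"t1": bundle60.true_demands},
                        state=state, seed=4)
        census = class_census(maps["t1"])
        for name in CLASS_NAMES:
            want = bundle60.true_demands[name]
            assert abs(census[name] - want) <= max(5, 0.005 * want)

    def test_seeds_differ_but_census_agrees(self, bundle60, suitability60):
        lu = bundle60.landuse_t0
        demands = bundle60.true_demands
        censuses = []
        for seed in (21, 22):
            state = CAState(suitability=suitability60.copy())
            maps = simulate(lu, [bundle60.dem], {"t1": demands},
                            state=state, seed=seed)
            censuses.append(class_census(maps["t1"]))
        for name in CLASS_NAMES:
            assert abs(censuses[0][name] - censuses[1][name]) <= \
                2 * max(5, 0.005 * demands[name])


class TestKappa:
    def test_identical_maps(self, bundle60):
        assert kappa(bundle60.landuse_t0, bundle60.landuse_t0) == 1.0

    def test_constructed_confusion(self):
        # 2-class map engineered so p0 = 0.9, pc = 0.5 -> kappa = 0.8
        n = 100
        obs = np.zeros(n, dtype=int)
        obs[50:] = 1
        sim = obs.copy()
        sim[:5] = 1   # 5 of class 0 wrong
        sim[50:55] = 0  # 5 of class 1 wrong
        observed = make_lu(obs.reshape(10, 10))
        simulated = make_lu(sim.reshape(10, 10))
        assert kappa(observed, simulated) == pytest.approx(0.8)

    def test_shuffled_map_near_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 6, 10000)
        obs = make_lu(vals.reshape(100, 100))
        sim = make_lu(rng.permutation(vals).reshape(100, 100))
        assert abs(kappa(obs, sim)) < 0.05

    def test_constant_equal_maps_convention(self):
        lu = make_lu(np.full((5, 5), 3))
        with pytest.warns(UserWarning):
            assert kappa(lu, lu) == 1.0


class TestFigureOfMerit:
    def test_perfect_overlap(self):
        ini = make_lu(np.zeros((3, 3)))
        obs = make_lu(np.zeros((3, 3)))
        obs.values[0, :] = 1
        assert figure_of_merit(ini, obs, obs) == 1.0

    def test_constructed_tallies(self):
        # A=2 misses, B=6 hits, C=1 wrong class, D=1 false alarm -> 0.6
        ini = make_lu(np.zeros((10, 1)))
        obs = make_lu(np.zeros((10, 1)))
        sim = make_lu(np.zeros((10, 1)))
        obs.values[0:9, 0] = 1          # 9 observed changes
        sim.values[0:6, 0] = 1          # 6 correct (B)
        sim.values[6, 0] = 2            # 1 wrong new class (C)
        # cells 7,8 observed change, simulated persistence (A=2)
        sim.values[9, 0] = 1            # observed persistence simulated change (D)
        assert figure_of_merit(ini, obs, sim) == pytest.approx(0.6)

    def test_all_misses(self):
        ini = make_lu(np.zeros((4, 4)))
        obs = make_lu(np.ones((4, 4)))
        assert figure_of_merit(ini, obs, ini) == 0.0

    def test_no_change_convention(self):
        lu = make_lu(np.zeros((3, 3)))
        with pytest.warns(UserWarning):
            assert figure_of_merit(lu, lu, lu) == 0.0
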