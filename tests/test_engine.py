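import numpy as np
import pytest

from fcatools import (
    RandomScenarioConfig,
    Scenario,
    WeightMatrix,
    binary,
    evaluate,
    random_scenario,
    run_method,
    selection_weights,
    step1_demand,
    step1_los,
    step2_accessibility,
)
from fcatools.scenario import CostMatrix, EntityTable

POP = np.array([250, 250, 500, 500, 1000, 500, 1000, 250, 250], dtype=float)
SUPPLY = np.array([1, 3, 2], dtype=float)


def equal_split_oracle(P, S, reach):
    """Brute-force balanced-binary allocator.

    Each center splits its population equally among its reachable
    facilities; each facility splits its level of service equally among the
    centers that reach it. Independent of the engine's linear algebra.
    """
    n, j = reach.shape
    D = np.zeros(j)
    for i in range(n):
        k = reach[i].sum()
        if k:
            D[reach[i]] += P[i] / k
    L = np.where(D > 0, S / np.where(D > 0, D, 1.0), np.nan)
    A = np.zeros(n)
    for jj in range(j):
        users = reach[:, jj]
        k = users.sum()
        if k and D[jj] > 0:
            A[users] += L[jj] / k
    return D, np.nan_to_num(L, nan=0.0), A


class TestSimulatedExampleUnadjusted:
    """Facility demand, LOS and accessibility of the nine-center system."""

    def test_binary_demand_and_los(self, simulated):
        scenario, specs = simulated
        r = run_method(scenario, specs["binary"], "2sfca")
        np.testing.assert_allclose(r.demand.facility_demand, [1500, 4250, 4000])
        np.testing.assert_allclose(
            np.round(r.los.per_scale, 3), [0.667, 0.706, 0.5])

    def test_stepwise_demand_and_los(self, simulated):
        scenario, specs = simulated
        r = run_method(scenario, specs["stepwise"], "e2sfca")
        np.testing.assert_allclose(r.demand.facility_demand, [631.5, 1834, 1850])
        np.testing.assert_allclose(
            np.round(r.los.per_scale, 3), [1.584, 1.636, 1.081])

    def test_binary_accessibility_row(self, simulated):
        scenario, specs = simulated
        r = run_method(scenario, specs["binary"], "2sfca")
        np.testing.assert_allclose(
            np.round(r.access.per_scale, 2),
            [0.67, 1.37, 1.87, 1.87, 1.21, 1.21, 1.21, 1.21, 1.21])

    def test_stepwise_accessibility_row(self, simulated):
        scenario, specs = simulated
        r = run_method(scenario, specs["stepwise"], "e2sfca")
        np.testing.assert_allclose(
            np.round(r.access.per_scale, 2),
            [0.38, 1.35, 1.63, 2.19, 2.0, 1.04, 0.66, 1.24, 0.66])

    def test_3sfca_demand_and_los(self, simulated):
        scenario, specs = simulated
        r = run_method(scenario, specs["stepwise"], "3sfca")
        np.testing.assert_allclose(
            np.round(r.demand.facility_demand, 3), [319.228, 834.191, 1007.744])
        np.testing.assert_allclose(
            np.round(r.los.per_scale, 3), [3.133, 3.596, 1.985])

    def test_3sfca_pair_demand_cells(self, simulated):
        # selection-weighted disaggregated demand, e.g. 250 x 0.71259 x 0.600
        scenario, specs = simulated
        r = run_method(scenario, specs["stepwise"], "3sfca")
        assert r.demand.pair_demand[1, 0] == pytest.approx(106.89, abs=5e-3)
        assert r.demand.pair_demand[1, 1] == pytest.approx(17.388, abs=5e-4)

    def test_m2sfca_demand_matches_e2sfca_but_access_is_lower(self, simulated):
        scenario, specs = simulated
        m2 = run_method(scenario, specs["stepwise"], "m2sfca")
        e2 = run_method(scenario, specs["stepwise"], "e2sfca")
        np.testing.assert_allclose(
            m2.demand.facility_demand, e2.demand.facility_demand)
        assert round(m2.access.per_scale[0], 4) == 0.0927
        assert round(m2.access.per_scale[4], 2) == 1.55


class TestSimulatedExampleBalanced:
    def test_binary_adjusted_demand_los_access(self, simulated):
        scenario, specs = simulated
        r = run_method(scenario, specs["binary"], "balanced")
        np.testing.assert_allclose(
            np.round(r.demand.facility_demand, 3), [708.333, 1958.333, 1833.333])
        np.testing.assert_allclose(
            np.round(r.los.per_scale, 3), [1.412, 1.532, 1.091])
        np.testing.assert_allclose(
            np.round(r.access.per_scale, 3),
            [0.353, 0.544, 0.7, 0.7, 0.347, 0.347, 0.347, 0.347, 0.347])

    def test_stepwise_adjusted_demand_los_access(self, simulated):
        scenario, specs = simulated
        r = run_method(scenario, specs["stepwise"], "balanced")
        np.testing.assert_allclose(
            np.round(r.demand.facility_demand, 3), [747.815, 1891.852, 1860.333])
        np.testing.assert_allclose(
            np.round(r.los.per_scale, 3), [1.337, 1.586, 1.075])
        np.testing.assert_allclose(
            np.round(r.access.per_scale, 3),
            [0.192, 0.59, 0.569, 0.853, 0.651, 0.348, 0.208, 0.377, 0.208])

    def test_binary_pair_demand_table(self, simulated):
        scenario, specs = simulated
        r = run_method(scenario, specs["binary"], "balanced")
        assert r.demand.pair_demand[0, 0] == 250          # only clinic in reach
        assert r.demand.pair_demand[1, 0] == 125
        assert r.demand.pair_demand[2, 2] == pytest.approx(166.67, abs=5e-3)


class TestToyExample:
    def test_unadjusted_binary_los(self, toy):
        scenario, specs = toy
        r = run_method(scenario, specs["binary"], "2sfca")
        np.testing.assert_allclose(r.los.los, [10 / 300, 10 / 300])

    def test_balanced_demand_is_150_under_both_impedances(self, toy):
        scenario, specs = toy
        for key in ("binary", "stepwise"):
            r = run_method(scenario, specs[key], "balanced")
            np.testing.assert_allclose(r.demand.facility_demand, [150, 150])
            np.testing.assert_allclose(r.los.los, [10 / 150, 10 / 150])

    def test_balanced_accessibility(self, toy):
        scenario, specs = toy
        b = run_method(scenario, specs["binary"], "balanced")
        np.testing.assert_allclose(np.round(b.access.accessibility, 3),
                                   [0.044, 0.044, 0.044])
        s = run_method(scenario, specs["stepwise"], "balanced")
        np.testing.assert_allclose(np.round(s.access.accessibility, 3),
                                   [0.053, 0.040, 0.040])


class TestSelectionWeights:
    def test_row_normalization(self):
        W = WeightMatrix(np.array([[0.600, 0.242, 0.0]]), ["c"], ["a", "b", "d"])
        g = selection_weights(W).values[0]
        np.testing.assert_allclose(np.round(g, 5), [0.71259, 0.28741, 0.0])

    def test_single_positive_entry_gets_share_one(self):
        W = WeightMatrix(np.array([[0.0, 0.3, 0.0]]), ["c"], ["a", "b", "d"])
        np.testing.assert_array_equal(selection_weights(W).values[0], [0, 1, 0])

    def test_covered_rows_sum_to_one_zero_rows_stay_zero(self):
        W = WeightMatrix(np.array([[0.2, 0.8], [0.0, 0.0]]), ["c1", "c2"], ["a", "b"])
        g = selection_weights(W).values
        assert g[0].sum() == pytest.approx(1.0)
        assert np.all(g[1] == 0)


class TestSteps:
    def test_all_zero_weights_give_zero_demand_and_undefined_los(self):
        W = WeightMatrix(np.zeros((2, 2)), ["c1", "c2"], ["f1", "f2"])
        d = step1_demand(np.array([10.0, 20.0]), W)
        np.testing.assert_array_equal(d.facility_demand, [0, 0])
        los = step1_los(np.array([1.0, 1.0]), d)
        assert np.isnan(los.los).all()
        assert los.undefined == ["f1", "f2"]
        a = step2_accessibility(los, W)
        np.testing.assert_array_equal(a.accessibility, [0, 0])

    def test_dimension_mismatch_raises(self):
        W = WeightMatrix(np.ones((2, 2)), ["c1", "c2"], ["f1", "f2"])
        with pytest.raises(ValueError, match="does not match"):
            step1_demand(np.ones(3), W)

    def test_unknown_method_rejected(self, toy):
        scenario, specs = toy
        with pytest.raises(ValueError, match="unknown method"):
            run_method(scenario, specs["binary"], "4sfca")


def _scenarios(n_seeds):
    for seed in range(n_seeds):
        cfg = RandomScenarioConfig(
            n_centers=6 + seed % 5, n_facilities=2 + seed % 4, seed=seed)
        yield random_scenario(cfg)


class TestEngineInvariants:
    def test_unadjusted_mass_identity(self):
        # sum_i P_i A_i == sum_j S_j when every facility has demand
        for sc in _scenarios(100):
            r = run_method(sc, binary(45), "2sfca")
            if r.los.undefined:
                continue
            lhs = float(sc.centers.size @ r.access.accessibility)
            assert lhs == pytest.approx(sc.facilities.size.sum(), rel=1e-10)

    def test_balanced_conservation_on_random_scenarios(self):
        # demand: sum_j D*_j == population of covered centers;
        # service: sum_i A*_i == total LOS of patronized facilities
        for sc in _scenarios(100):
            r = run_method(sc, binary(12), "balanced")
            W = r.weights.values
            covered_pop = sc.centers.size[W.sum(axis=1) > 0].sum()
            assert r.demand.facility_demand.sum() == pytest.approx(
                covered_pop, rel=1e-10, abs=1e-10)
            assert r.access.accessibility.sum() == pytest.approx(
                r.los.total, rel=1e-10, abs=1e-12)

    def test_balanced_full_coverage_conserves_total_population(self):
        for sc in _scenarios(30):
            r = run_method(sc, binary(100), "balanced")  # threshold > diameter
            assert not r.los.undefined
            assert r.demand.facility_demand.sum() == pytest.approx(
                sc.centers.size.sum(), rel=1e-12)

    def test_balanced_binary_matches_equal_split_oracle(self):
        for seed in range(50):
            sc = random_scenario(RandomScenarioConfig(
                n_centers=6, n_facilities=4, seed=1000 + seed))
            spec = binary(14)
            reach = evaluate(sc.costs, spec).values > 0
            D, L, A = equal_split_oracle(sc.centers.size, sc.facilities.size, reach)
            r = run_method(sc, spec, "balanced")
            np.testing.assert_allclose(r.demand.facility_demand, D, rtol=1e-12)
            np.testing.assert_allclose(np.nan_to_num(r.los.los), L, rtol=1e-12)
            np.testing.assert_allclose(r.access.accessibility, A, rtol=1e-12)

    def test_m2sfca_never_exceeds_unadjusted(self):
        for sc in _scenarios(30):
            m2 = run_method(sc, binary(20), "m2sfca")
            un = run_method(sc, binary(20), "2sfca")
            assert np.all(m2.access.accessibility
                          <= un.access.accessibility + 1e-12)

    @pytest.mark.parametrize("method", ["2sfca", "3sfca", "m2sfca", "balanced"])
    def test_permutation_equivariance(self, method, rng):
        sc = random_scenario(RandomScenarioConfig(n_centers=7, n_facilities=4, seed=7))
        pi = rng.permutation(sc.n_centers)
        pj = rng.permutation(sc.n_facilities)
        permuted = Scenario(
            EntityTable([sc.centers.ids[i] for i in pi], sc.centers.size[pi],
                        x=sc.centers.x[pi], y=sc.centers.y[pi]),
            EntityTable([sc.facilities.ids[j] for j in pj], sc.facilities.size[pj],
                        x=sc.facilities.x[pj], y=sc.facilities.y[pj]),
            CostMatrix([sc.centers.ids[i] for i in pi],
                       [sc.facilities.ids[j] for j in pj],
                       sc.costs.cost[np.ix_(pi, pj)]),
        )
        base = run_method(sc, binary(15), method)
        perm = run_method(permuted, binary(15), method)
        np.testing.assert_allclose(
            perm.access.accessibility, base.access.accessibility[pi], rtol=1e-12)
        np.testing.assert_allclose(
            perm.demand.facility_demand, base.demand.facility_demand[pj],
            rtol=1e-12)
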