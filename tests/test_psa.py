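"""Probabilistic analysis: sampling, coherence, dominance, CEAC."""

import numpy as np
import pytest

from tmscea.bundle import deterministic_run, point_estimate
from tmscea.psa import (
    PSAResult,
    WillingnessToPay,
    ceac,
    incremental_analysis,
    prob_cost_effective_vs,
    run_psa,
    running_mean,
    sample_parameters,
    societal_totals,
)

from _oracles import nmb_frontier


@pytest.fixture(scope="module")
def small_psa(base_bundle):
    return run_psa(base_bundle.spec, n_sims=400, seed=3)


class TestSampling:
    def test_point_mass_draw_equals_base_case(self, base_bundle):
        spec = base_bundle.spec.all_point_mass()
        ps = sample_parameters(spec, 1)
        base = point_estimate(spec)
        assert np.allclose(ps.tau_p6, base.tau_p6)
        assert np.allclose(ps.utility, base.utility)
        assert ps.maintenance == base.maintenance

    def test_identical_seed_identical_draw(self, base_bundle):
        a = sample_parameters(base_bundle.spec, 42)
        b = sample_parameters(base_bundle.spec, 42)
        assert np.allclose(a.p_rtms, b.p_rtms)
        assert np.allclose(a.cost_per_cycle, b.cost_per_cycle)
        assert a.maintenance == b.maintenance

    def test_dirichlet_rows_sum_to_one(self, base_bundle):
        ps = sample_parameters(base_bundle.spec, 0)
        for m in (ps.tau_p6, ps.p_rtms, ps.p_itbs):
            assert np.allclose(m.sum(axis=1), 1.0)
            assert np.all(m >= 0)

    def test_gamma_means_converge(self, base_bundle):
        rng = np.random.default_rng(0)
        draws = np.array([
            sample_parameters(base_bundle.spec, rng).cost_per_cycle
            for _ in range(4000)
        ])
        assert np.allclose(draws.mean(axis=0), base_bundle.spec.cost.mean,
                           atol=0.5)

    def test_maintenance_draws_are_coherent_curves(self, base_bundle):
        rng = np.random.default_rng(1)
        for _ in range(200):
            m = sample_parameters(base_bundle.spec, rng).maintenance
            w52, w78 = m.weight(52.0), m.weight(78.0)
            assert 0.0 <= w78 <= w52 <= 1.0


class TestRunPSA:
    def test_point_mass_spec_reproduces_deterministic(self, base_bundle):
        spec = base_bundle.spec.all_point_mass()
        res = run_psa(spec, n_sims=5, seed=9)
        det = deterministic_run(point_estimate(spec), spec.settings)
        for arm in res.arms:
            assert np.allclose(res.cost[arm], det[arm].cost)
            assert np.allclose(res.qalys[arm], det[arm].qalys)

    def test_running_mean_stabilises(self, small_psa):
        dq = small_psa.qalys["rtms"] - small_psa.qalys["tau"]
        rm = running_mean(dq)
        se = dq.std(ddof=1) / np.sqrt(len(dq))
        assert abs(rm[len(dq) // 2] - rm[-1]) < 2 * se * np.sqrt(2)

    def test_seed_changes_draws_not_means(self, base_bundle, small_psa):
        other = run_psa(base_bundle.spec, n_sims=400, seed=4)
        dq1 = small_psa.qalys["itbs"] - small_psa.qalys["tau"]
        dq2 = other.qalys["itbs"] - other.qalys["tau"]
        assert not np.allclose(dq1, dq2)
        se = np.sqrt(dq1.var() / 400 + dq2.var() / 400)
        assert abs(dq1.mean() - dq2.mean()) < 3 * se

    def test_no_excluded_draws_in_base_case(self, small_psa):
        assert small_psa.n_excluded == 0

    def test_common_random_numbers_reduce_incremental_variance(self, base_bundle):
        """Shared draws across arms beat independent draws on ΔQ variance."""
        res = run_psa(base_bundle.spec, n_sims=400, seed=3)
        paired = (res.qalys["rtms"] - res.qalys["tau"]).var()
        indep = run_psa(base_bundle.spec, n_sims=400, seed=5)
        unpaired = (res.qalys["rtms"] - indep.qalys["tau"]).var()
        assert paired < unpaired


class TestIncremental:
    # Published base-case means (health-service perspective)
    TABLE = {"tau": (5940.0, 0.9253), "rtms": (6521.0, 0.9734),
             "itbs": (6709.0, 0.9847)}

    def test_pairwise_increments_from_published_means(self):
        out = incremental_analysis(self.TABLE)
        pw = out[out["block"] == "pairwise"].set_index("arm")
        assert pw.loc["rtms", "d_cost"] == pytest.approx(581.0)
        assert pw.loc["itbs", "d_qalys"] == pytest.approx(0.0594)
        assert pw.loc["rtms", "icer"] == pytest.approx(12093.0, rel=0.01)
        assert pw.loc["itbs", "icer"] == pytest.approx(12959.0, rel=0.01)

    def test_fully_incremental_from_published_means(self):
        out = incremental_analysis(self.TABLE)
        inc = out[out["block"] == "incremental"].set_index("arm")
        assert (inc["status"] == "on_frontier").all()
        assert inc.loc["itbs", "comparator"] == "rtms"
        assert inc.loc["itbs", "d_qalys"] == pytest.approx(0.0113)
        assert inc.loc["itbs", "icer"] == pytest.approx(16621.0, rel=0.01)

    def test_dominant_arm_flagged_without_icer(self):
        means = {"tau": (6000.0, 0.90), "rtms": (5800.0, 0.95)}
        out = incremental_analysis(means)
        row = out[(out["block"] == "pairwise") & (out["arm"] == "rtms")].iloc[0]
        assert row["status"] == "dominant"
        assert np.isnan(row["icer"])

    def test_extended_dominance_matches_nmb_brute_force(self):
        means = {"tau": (1000.0, 0.50), "mid": (2000.0, 0.52),
                 "top": (2200.0, 0.60)}
        out = incremental_analysis(means)
        inc = out[out["block"] == "incremental"].set_index("arm")
        assert inc.loc["mid", "status"] == "extendedly_dominated"
        winners = nmb_frontier(means, np.linspace(0, 200_000, 4001))
        frontier = set(inc[inc["status"] == "on_frontier"].index)
        assert winners <= frontier

    def test_frontier_equals_nmb_argmax_on_psa_means(self, small_psa):
        m = small_psa.means()
        means = {a: (m.loc[a, "cost"], m.loc[a, "qalys"]) for a in small_psa.arms}
        out = incremental_analysis(means)
        inc = out[out["block"] == "incremental"].set_index("arm")
        winners = nmb_frontier(means, np.linspace(0, 200_000, 4001))
        frontier = set(inc[inc["status"] == "on_frontier"].index)
        assert winners <= frontier


class TestCEAC:
    def test_curves_partition_probability(self, small_psa):
        curves = ceac(small_psa)
        total = curves[list(small_psa.arms)].sum(axis=1)
        assert np.allclose(total, 1.0)
        assert len(curves) == 101  # £0-100k in £1000 steps

    def test_lambda_zero_is_cheapest_frequency(self, small_psa):
        curves = ceac(small_psa)
        costs = np.column_stack([small_psa.cost[a] for a in small_psa.arms])
        cheapest = costs.argmin(axis=1)
        for j, arm in enumerate(small_psa.arms):
            assert curves.iloc[0][arm] == pytest.approx(
                (cheapest == j).mean(), abs=1e-9
            )

    def test_limit_is_probability_of_max_qalys(self, small_psa):
        wtp = WillingnessToPay(grid=np.array([0.0, 1e9]))
        curves = ceac(small_psa, wtp)
        q = np.column_stack([small_psa.qalys[a] for a in small_psa.arms])
        best = q.argmax(axis=1)
        for j, arm in enumerate(small_psa.arms):
            assert curves.iloc[-1][arm] == pytest.approx(
                (best == j).mean(), abs=1e-9
            )

    def test_two_arm_deterministic_step_at_icer(self):
        res = PSAResult(
            cost={"tau": np.full(10, 1000.0), "new": np.full(10, 2000.0)},
            qalys={"tau": np.full(10, 1.0), "new": np.full(10, 1.1)},
            informal_hours={"tau": np.zeros(10), "new": np.zeros(10)},
            productivity_cost={"tau": np.zeros(10), "new": np.zeros(10)},
            seed=0, n_sims=10,
        )
        curves = ceac(res, WillingnessToPay(np.array([0.0, 9000.0, 11000.0])))
        assert curves["new"].tolist() == [0.0, 0.0, 1.0]  # ICER = 10 000


class TestSocietal:
    def test_additivity_per_draw(self, small_psa):
        soc = societal_totals(small_psa)
        for arm in small_psa.arms:
            assert np.allclose(
                soc.cost[arm],
                small_psa.cost[arm] + small_psa.productivity_cost[arm],
            )

    def test_zero_productivity_equals_health_perspective(self, small_psa):
        import dataclasses

        zeroed = dataclasses.replace(
            small_psa,
            productivity_cost={a: np.zeros(small_psa.n_sims)
                               for a in small_psa.arms},
        )
        soc = societal_totals(zeroed)
        for arm in small_psa.arms:
            assert np.allclose(soc.cost[arm], small_psa.cost[arm])

    def test_pairwise_probability_definition(self, small_psa):
        p = prob_cost_effective_vs(small_psa, "rtms", "tau", 20_000.0)
        nmb_r = 20_000.0 * small_psa.qalys["rtms"] - small_psa.cost["rtms"]
        nmb_t = 20_000.0 * small_psa.qalys["tau"] - small_psa.cost["tau"]
        assert p == pytest.approx((nmb_r > nmb_t).mean())
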