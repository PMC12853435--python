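"""Intervention costing and state-reward estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from tmscea.bundle import default_intervention_costs, per_cycle_econ
from tmscea.econ import (
    InterventionCostInputs,
    annuitise,
    course_cost,
    fit_state_costs,
    fit_state_utilities,
    state_informal_care,
    state_productivity,
)
from tmscea.simulate import (
    DESIGN_ITBS,
    DESIGN_RTMS,
    default_ground_truth,
    simulate_trial,
)


class TestAnnuity:
    def test_zero_rate_is_straight_line(self):
        assert annuitise(1000.0, 10.0, 0.0) == pytest.approx(100.0)

    def test_single_year_identity(self):
        assert annuitise(1000.0, 1.0, 0.035) == pytest.approx(1035.0)

    def test_ten_year_closed_form(self):
        assert annuitise(1000.0, 10.0, 0.035) == pytest.approx(
            120.2413678673915, rel=1e-12
        )

    def test_continuous_at_zero_rate(self):
        assert annuitise(1000.0, 10.0, 1e-9) == pytest.approx(
            annuitise(1000.0, 10.0, 0.0), rel=1e-6
        )

    def test_invalid_lifetime(self):
        with pytest.raises(ValueError):
            annuitise(1000.0, 0.0, 0.035)


class TestCourseCost:
    def test_staff_component_arithmetic(self):
        inputs = InterventionCostInputs(
            equipment_capital=1e-9, staff_cost_per_hour=40.0,
            sessions_per_course=27.0, minutes_per_session=30.0,
        )
        assert course_cost(inputs) == pytest.approx(540.0, abs=1e-3)

    def test_doubling_throughput_halves_equipment_component_only(self):
        base = default_intervention_costs()["rtms"]
        fast = base.replace(throughput_per_year=2 * base.throughput_per_year)
        equip = annuitise(base.equipment_capital, base.equipment_lifetime_years,
                          base.discount_rate) / base.throughput_per_year
        assert course_cost(base) - course_cost(fast) == pytest.approx(equip / 2)

    def test_base_case_matches_published_course_costs(self):
        costs = default_intervention_costs()
        assert course_cost(costs["rtms"]) == pytest.approx(1184.0, abs=1.0)
        assert course_cost(costs["itbs"]) == pytest.approx(1440.0, abs=1.0)
        # the difference is the MRI-guidance imaging component
        assert costs["itbs"].imaging_cost == pytest.approx(
            course_cost(costs["itbs"]) - course_cost(costs["rtms"])
        )

    @given(mult=st.floats(1.1, 4.0))
    @hyp_settings(max_examples=20, deadline=None)
    def test_monotone_in_throughput_linear_in_sessions(self, mult):
        base = default_intervention_costs()["rtms"]
        assert course_cost(
            base.replace(throughput_per_year=base.throughput_per_year * mult)
        ) < course_cost(base)
        c1 = course_cost(base)
        c2 = course_cost(base.replace(sessions_per_course=base.sessions_per_course * 2))
        c3 = course_cost(base.replace(sessions_per_course=base.sessions_per_course * 3))
        assert c3 - c2 == pytest.approx(c2 - c1, rel=1e-9)

    def test_zero_throughput_rejected(self):
        with pytest.raises(ValueError):
            InterventionCostInputs(equipment_capital=1e5, throughput_per_year=0)


def _balanced_panel(costs_by_state, utils_by_state=None, n_subjects=40,
                    n_periods=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for p in range(1, n_periods + 1):
            s = (i + p) % 4
            rows.append({
                "subject_id": i, "period": p, "period_start_week": 26.0 * (p - 1),
                "period_weeks": 26.0, "state": s,
                "cost": costs_by_state[s] + noise * rng.normal(),
                "utility": (utils_by_state[s] if utils_by_state is not None
                            else 0.7),
                "workdays_lost": s * 2.0, "care_hours": s * 4.0,
                "age": 40 + (i % 20), "sex": "female" if i % 2 else "male",
                "site": 1 + i % 3, "baseline_utility": 0.5,
            })
    return pd.DataFrame(rows)


class TestStateCosts:
    def test_noiseless_state_costs_recovered_exactly(self):
        truth = [50.0, 110.0, 180.0, 280.0]
        est = fit_state_costs(_balanced_panel(truth))
        assert np.allclose(est.mean, truth, atol=1e-6)

    def test_identity_correlation_equals_ols(self):
        truth = [50.0, 110.0, 180.0, 280.0]
        df = _balanced_panel(truth, noise=20.0, seed=3)
        import statsmodels.formula.api as smf

        gee = fit_state_costs(df, cov_struct="independence")
        ols = fit_state_costs(df, cov_struct="exchangeable")  # balanced: close
        # independence-GEE coefficients equal pooled least squares
        df2 = df.copy()
        names = ["remission", "mild", "moderate", "severe"]
        df2["state_name"] = pd.Categorical(
            [names[int(s)] for s in df2["state"]], categories=names
        )
        fit = smf.ols(
            "cost ~ C(state_name) + age + C(sex) + C(period) + C(site)", df2
        ).fit()
        gee_fit = smf.gee(
            "cost ~ C(state_name) + age + C(sex) + C(period) + C(site)",
            groups="subject_id", data=df2,
        ).fit()
        assert np.allclose(gee_fit.params.values, fit.params.values, atol=1e-8)
        assert np.allclose(gee.mean, ols.mean, atol=5.0)

    def test_recovery_on_simulated_trial_data(self):
        """State cost recovery within 5% of the effect size at trial n."""
        truth = default_ground_truth()
        _, econ_r = simulate_trial(truth, DESIGN_RTMS, seed=4)
        _, econ_i = simulate_trial(truth, DESIGN_ITBS, seed=4)
        econ = per_cycle_econ(pd.concat(
            [econ_r, econ_i.assign(subject_id=econ_i["subject_id"] + 10_000)],
            ignore_index=True,
        ))
        est = fit_state_costs(econ)
        effect = truth.cost_per_cycle[3] - truth.cost_per_cycle[0]
        assert np.max(np.abs(est.mean - truth.cost_per_cycle)) < 0.05 * effect


class TestStateUtilities:
    def test_noiseless_recovery(self):
        utils = [0.85, 0.70, 0.55, 0.40]
        est = fit_state_utilities(_balanced_panel([0] * 4, utils))
        assert np.allclose(est.mean, utils, atol=1e-8)

    def test_recovery_on_simulated_trial_data(self):
        truth = default_ground_truth()
        _, econ_r = simulate_trial(truth, DESIGN_RTMS, seed=4)
        _, econ_i = simulate_trial(truth, DESIGN_ITBS, seed=4)
        econ = per_cycle_econ(pd.concat(
            [econ_r, econ_i.assign(subject_id=econ_i["subject_id"] + 10_000)],
            ignore_index=True,
        ))
        est = fit_state_utilities(econ)
        assert np.max(np.abs(est.mean - truth.utility)) < 0.02

    def test_subject_order_invariance(self):
        truth = default_ground_truth()
        _, econ = simulate_trial(truth, DESIGN_RTMS, seed=4)
        econ = per_cycle_econ(econ)
        shuffled = econ.sample(frac=1.0, random_state=1)
        a = fit_state_utilities(econ)
        b = fit_state_utilities(shuffled)
        assert np.allclose(a.mean, b.mean, atol=1e-10)

    def test_utilities_above_one_rejected(self):
        df = _balanced_panel([0] * 4, [0.8, 0.7, 0.6, 1.2])
        with pytest.raises(ValueError):
            fit_state_utilities(df)


class TestProductivityAndCare:
    def test_zero_days_zero_cost(self):
        df = _balanced_panel([0] * 4).assign(workdays_lost=0.0)
        est = state_productivity(df, 120.0, window=None)
        assert np.allclose(est.mean, 0.0)

    def test_simple_arithmetic(self):
        df = _balanced_panel([0] * 4)
        df["workdays_lost"] = np.where(df["state"] == 3, 2.0, 0.0)
        est = state_productivity(df, 120.0, window=None)
        assert est.mean[3] == pytest.approx(240.0)

    def test_window_stratified_means_match_brute_force(self):
        truth = default_ground_truth()
        _, econ = simulate_trial(truth, DESIGN_RTMS, seed=4)
        econ = per_cycle_econ(econ)
        est = state_productivity(econ, 120.0, window=(0.0, 16.0),
                                 employed_fraction=0.5)
        sub = econ[econ["period_start_week"] < 16.0]
        for s in range(4):
            manual = sub.loc[sub["state"] == s, "workdays_lost"].mean() * 60.0
            assert est.mean[s] == pytest.approx(manual)

    def test_informal_care_uniform_hours(self):
        df = _balanced_panel([0] * 4).assign(care_hours=4.0)
        est = state_informal_care(df, window=None)
        assert np.allclose(est.mean, 4.0)

    def test_negative_workdays_rejected(self):
        df = _balanced_panel([0] * 4).assign(workdays_lost=-1.0)
        with pytest.raises(ValueError):
            state_productivity(df, 120.0, window=None)
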