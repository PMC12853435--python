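"""Transition estimation: HDRS banding, CTMC fit, matrix roots, maintenance."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm, logm

from tmscea.engine import ModelSettings
from tmscea.simulate import DESIGN_RTMS, default_ground_truth, simulate_trial
from tmscea.states import HealthState, classify_hdrs
from tmscea.transitions import (
    MaintenanceModel,
    blend_to_tau,
    count_interval_transitions,
    ctmc_to_cycle_matrix,
    fit_ctmc,
    fit_weibull_maintenance,
    interval_matrix_to_cycle,
    panel_with_states,
)

from conftest import panel_from_states, random_alive_matrix


class TestHdrsBands:
    @pytest.mark.parametrize(
        "score, state",
        [
            (0, HealthState.REMISSION),
            (7, HealthState.REMISSION),
            (8, HealthState.MILD),
            (13, HealthState.MILD),
            (14, HealthState.MODERATE),
            (22, HealthState.MODERATE),
            (23, HealthState.SEVERE),
            (52, HealthState.SEVERE),
        ],
    )
    def test_band_edges(self, score, state):
        assert classify_hdrs(score) is state

    @pytest.mark.parametrize("score", [-1, 53])
    def test_out_of_range(self, score):
        with pytest.raises(ValueError):
            classify_hdrs(score)

    def test_panel_accepts_scores_and_orders_visits(self):
        panel = pd.DataFrame({
            "subject_id": [1, 1, 2, 2],
            "visit_week": [8, 0, 0, 8],
            "hdrs_score": [5, 25, 15, 9],
        })
        out = panel_with_states(panel)
        assert out["state"].tolist() == [3, 0, 2, 1]  # sorted by week


class TestFitCTMC:
    def test_two_state_matches_matrix_log_of_empirical_frequencies(self):
        """With one observation gap, the interval MLE has a closed form.

        For a two-state chain observed at a constant gap, the likelihood
        factorises over rows of the empirical transition-frequency matrix,
        so the fitted generator must equal logm(P_hat)/gap.
        """
        rng = np.random.default_rng(3)
        Q = np.array([[-0.10, 0.10], [0.04, -0.04]])
        dt = 4.0
        P = expm(Q * dt)
        n, k = 400, 7
        states = np.empty((n, k), dtype=int)
        states[:, 0] = rng.integers(0, 2, n)
        for j in range(1, k):
            u = rng.random(n)
            states[:, j] = np.where(u < P[states[:, j - 1], 1], 1, 0)
        panel = panel_from_states(states, np.arange(k) * dt)
        # closed-form MLE from empirical frequencies
        counts = np.zeros((2, 2))
        for i in range(n):
            for j in range(k - 1):
                counts[states[i, j], states[i, j + 1]] += 1
        P_hat = counts / counts.sum(axis=1, keepdims=True)
        Q_closed = logm(P_hat).real / dt
        fit = fit_ctmc(panel, n_states=2, n_starts=2)
        assert np.allclose(fit.Q, Q_closed, atol=1e-4)

    def test_recovers_generating_matrix(self, settings):
        """Fit on simulated TMS-trial-design data recovers the 2-week matrix."""
        from tmscea.simulate import BRIGHTMIND_VISITS, TrialDesign

        truth = default_ground_truth()
        design = TrialDesign(500, BRIGHTMIND_VISITS, "ctmc", seed_offset=1)
        panel, _ = simulate_trial(truth, design, seed=5)
        fit = fit_ctmc(panel, seed=0)
        P_true = expm(truth.Q_rtms * 2.0)
        assert np.max(np.abs(fit.cycle_matrix(settings) - P_true)) < 0.02

    def test_likelihood_at_fit_beats_truth(self, settings):
        truth = default_ground_truth()
        panel, _ = simulate_trial(truth, DESIGN_RTMS, seed=6)
        fit = fit_ctmc(panel, seed=0)

        def loglik(Q):
            df = panel_with_states(panel)
            total = 0.0
            for _, g in df.groupby("subject_id"):
                s = g["state"].to_numpy()
                t = g["visit_week"].to_numpy(dtype=float)
                for i in range(len(s) - 1):
                    P = expm(Q * (t[i + 1] - t[i]))
                    total += np.log(max(P[s[i], s[i + 1]], 1e-300))
            return total

        assert fit.log_likelihood >= loglik(truth.Q_rtms) - 1e-6
        assert fit.log_likelihood == pytest.approx(loglik(fit.Q), rel=1e-8)

    def test_static_subjects_shrink_off_diagonals(self):
        states = np.tile([[0], [1], [2], [3]], (10, 5))
        panel = panel_from_states(states, [0.0, 8.0, 16.0, 26.0, 40.0])
        fit = fit_ctmc(panel, n_starts=1)
        off = fit.Q[~np.eye(4, dtype=bool)]
        assert np.all(off < 1e-4)

    def test_tridiagonal_structure_blocks_jumps(self):
        truth = default_ground_truth()
        panel, _ = simulate_trial(truth, DESIGN_RTMS, seed=7)
        fit = fit_ctmc(panel, structure="tridiagonal", n_starts=1)
        assert fit.Q[0, 2] == 0.0 and fit.Q[0, 3] == 0.0 and fit.Q[3, 0] == 0.0


class TestCycleMatrix:
    def test_zero_generator_gives_identity(self, settings):
        assert np.allclose(ctmc_to_cycle_matrix(np.zeros((4, 4)), settings),
                           np.eye(4))

    def test_semigroup_property(self, settings):
        truth = default_ground_truth()
        P2 = ctmc_to_cycle_matrix(truth.Q_rtms, settings)
        P4 = expm(truth.Q_rtms * 4.0)
        assert np.allclose(P2 @ P2, P4, atol=1e-10)
        assert np.allclose(P2.sum(axis=1), 1.0, atol=1e-10)

    def test_invalid_generator_rejected(self, settings):
        with pytest.raises(ValueError):
            ctmc_to_cycle_matrix(np.ones((4, 4)), settings)


class TestIntervalRoot:
    def test_identity_root_is_identity(self):
        P, err = interval_matrix_to_cycle(np.eye(4), 13)
        assert np.allclose(P, np.eye(4))
        assert err < 1e-12

    def test_round_trip_with_constructed_generator(self):
        truth = default_ground_truth()
        Q = truth.Q_rtms  # a valid generator: embeddable by construction
        P_interval = expm(Q * 13 * 2.0)
        P_cycle, err = interval_matrix_to_cycle(P_interval, 13)
        assert np.allclose(P_cycle, expm(Q * 2.0), atol=1e-8)
        assert err < 1e-8

    def test_regularisation_error_small_for_diagonally_dominant(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            P_interval = random_alive_matrix(rng, diag_dominant=True)
            P_cycle, err = interval_matrix_to_cycle(P_interval, 13)
            assert np.all(P_cycle >= 0)
            assert np.allclose(P_cycle.sum(axis=1), 1.0, atol=1e-10)
            assert err < 0.01

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            interval_matrix_to_cycle(np.ones((4, 4)), 13)


class TestIntervalCounts:
    def test_stayers_give_identity(self):
        states = np.tile([[0], [1], [2], [3]], (1, 4))
        states = np.vstack([states] * 10)  # 40 subjects staying put
        panel = panel_from_states(states, [0.0, 26.0, 52.0, 78.0])
        counts, matrix = count_interval_transitions(panel, 26.0)
        assert np.allclose(matrix, np.eye(4))
        assert np.allclose(counts.sum(axis=1), 30.0)  # 10 subjects x 3 pairs

    def test_uniform_split_from_moderate(self):
        states = np.array([[2, 0], [2, 1], [2, 2], [2, 3]])
        panel = panel_from_states(states, [0.0, 26.0])
        _, matrix = count_interval_transitions(panel, 26.0)
        assert np.allclose(matrix[2], 0.25)

    def test_estimates_tighten_with_sample_size(self):
        truth = default_ground_truth()
        rng = np.random.default_rng(8)

        def sim(n):
            states = np.empty((n, 4), dtype=int)
            states[:, 0] = rng.choice(4, n, p=truth.baseline_alive)
            for j in range(1, 4):
                for i in range(n):
                    states[i, j] = rng.choice(4, p=truth.tau_p6[states[i, j - 1]])
            _, m = count_interval_transitions(
                panel_from_states(states, [0.0, 26.0, 52.0, 78.0]), 26.0
            )
            return np.max(np.abs(m - truth.tau_p6))

        assert sim(900) < sim(90)


class TestMaintenance:
    def test_all_ones_degenerate(self):
        m = fit_weibull_maintenance([(52.0, 1.0), (78.0, 1.0)])
        assert m.degenerate
        assert m.weight(999.0) == 1.0

    def test_exponential_special_case_closed_form(self):
        m = fit_weibull_maintenance([(78.0, 0.5)], shape=1.0)
        assert m.scale_weeks == pytest.approx(75.0201421262261, rel=1e-12)

    def test_parameter_recovery_with_noise(self):
        rng = np.random.default_rng(9)
        true = MaintenanceModel(shape=1.3, scale_weeks=30.0)
        t = np.array([39.0, 52.0, 65.0, 78.0])
        f = np.clip(np.asarray(true.weight(t)) + rng.normal(0, 0.01, 4), 0.01, 0.99)
        fit = fit_weibull_maintenance(list(zip(t, f)))
        assert fit.shape == pytest.approx(true.shape, rel=0.10)
        assert fit.scale_weeks == pytest.approx(true.scale_weeks, rel=0.10)

    def test_weight_anchored_and_monotone(self):
        m = MaintenanceModel(shape=1.3, scale_weeks=30.0)
        t = np.linspace(26.0, 100.0, 50)
        w = np.asarray(m.weight(t))
        assert w[0] == pytest.approx(1.0)
        assert np.all(np.diff(w) <= 0)
        assert np.all((w >= 0) & (w <= 1))

    def test_points_before_anchor_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull_maintenance([(20.0, 0.9), (52.0, 0.5)])


class TestBlend:
    tms = np.array([0.5, 0.3, 0.15, 0.05])
    tau = np.array([0.2, 0.3, 0.3, 0.2])

    def test_full_weight_keeps_tms(self):
        m = MaintenanceModel.constant_one()
        out = blend_to_tau(self.tms, self.tau, m, cycle=20)
        assert np.allclose(out, self.tms)

    def test_zero_weight_gives_tau(self):
        m = MaintenanceModel(shape=1.0, scale_weeks=1e-9)
        out = blend_to_tau(self.tms, self.tau, m, cycle=20)
        assert np.allclose(out, self.tau)

    def test_half_weight_convex_combination(self):
        # shape/scale chosen so w = 0.5 exactly at 40 weeks (cycle 20)
        m = MaintenanceModel(shape=1.0, scale_weeks=14.0 / np.log(2.0))
        out = blend_to_tau(np.array([1.0, 0, 0, 0]), np.array([0.0, 0, 0, 1.0]),
                           m, cycle=20)
        assert np.allclose(out, [0.5, 0, 0, 0.5])

    def test_before_26_weeks_rejected(self):
        m = MaintenanceModel.constant_one()
        with pytest.raises(ValueError):
            blend_to_tau(self.tms, self.tau, m, cycle=12)

    def test_blend_bounded_by_endpoints_when_tms_dominates(self):
        """Blended severity lies between the TMS and TAU compositions."""
        m = MaintenanceModel(shape=1.3, scale_weeks=30.0)
        cum = np.cumsum  # stochastic ordering via cumulative occupancy
        for cycle in (14, 20, 30, 39):
            out = blend_to_tau(self.tms, self.tau, m, cycle=cycle)
            assert np.all(cum(out) <= cum(self.tms) + 1e-12)
            assert np.all(cum(out) >= cum(self.tau) - 1e-12)
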