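"""Multistate model: generator, transition probabilities, likelihood, MLE."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

import sarcolife as sl
from sarcolife._linalg import expm_batch

from _oracles import ode_panel_loglik, ode_transition_matrix
from conftest import death_only_model, two_state_structure


class TestGenerator:
    def test_row_sums_zero_and_dead_row_absorbing(self):
        model = sl.default_true_model()
        rng = np.random.default_rng(1)
        for age in rng.uniform(60, 110, size=20):
            q = sl.build_q(model, age)
            assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
            assert np.all(q[3] == 0.0)
            off = q.copy()
            np.fill_diagonal(off, 0.0)
            assert np.all(off >= 0.0)

    def test_disallowed_entries_zero(self):
        q = sl.build_q(sl.default_true_model(), 70.0)
        assert q[0, 2] == 0.0 and q[2, 0] == 0.0  # no direct 1<->3

    def test_direct_1_3_config(self):
        structure = sl.adjacent_structure(direct_1_3=True)
        model = sl.IntensityModel(structure, alpha=np.full(9, -2.0))
        q = sl.build_q(model, 70.0)
        assert q[0, 2] > 0 and q[2, 0] > 0

    def test_zero_rate_limit(self):
        model = sl.IntensityModel(sl.DEFAULT_STRUCTURE, alpha=np.full(7, -600.0))
        assert np.allclose(sl.build_q(model, 70.0), 0.0)

    def test_positive_age_slope_gives_increasing_rates(self):
        model = sl.default_true_model()
        r60 = model.rates(60.0)[0]
        r80 = model.rates(80.0)[0]
        rising = model.beta > 0
        assert np.all(r80[rising] > r60[rising])

    def test_covariate_effect_matches_manual(self):
        structure = two_state_structure()
        model = sl.IntensityModel(
            structure,
            alpha=np.log([0.05]),
            beta=np.array([0.1]),
            gamma=np.array([[0.7]]),
            covariate_names=("smoker",),
        )
        q = sl.build_q(model, 65.0, covariates=[1.0])
        assert q[0, 1] == pytest.approx(0.05 * np.exp(0.1 * 5 + 0.7), rel=1e-12)


class TestExpmBatch:
    def test_against_scipy(self):
        rng = np.random.default_rng(7)
        mats = rng.normal(scale=2.0, size=(40, 4, 4))
        ours = expm_batch(mats)
        for i in range(40):
            assert np.allclose(ours[i], scipy.linalg.expm(mats[i]), atol=1e-11)

    def test_large_norm(self):
        q = sl.default_true_model().intensity_matrix(115.0)
        assert np.allclose(
            expm_batch(q[None] * 2.0)[0], scipy.linalg.expm(q * 2.0), atol=1e-10
        )


class TestTransitionProbability:
    def test_zero_dt_identity(self):
        p = sl.transition_probability(sl.default_true_model(), 70.0, 0.0)
        assert np.array_equal(p, np.eye(4))

    def test_rows_stochastic(self):
        model = sl.default_true_model()
        for dt in (0.5, 2.0, 10.0):
            p = sl.transition_probability(model, 65.0, dt)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
            assert np.all((p >= 0) & (p <= 1))

    def test_two_state_closed_form(self):
        p = sl.transition_probability(death_only_model(0.05), 60.0, 10.0)
        assert p[0, 1] == pytest.approx(1 - np.exp(-0.5), abs=1e-10)

    def test_matches_kolmogorov_forward_oracle(self):
        model = sl.default_true_model()
        for age0, dt in [(62.0, 2.3), (75.0, 4.0), (88.0, 1.1)]:
            ours = sl.transition_probability(model, age0, dt, approx_step=1.0)
            oracle = ode_transition_matrix(model, age0, dt, approx_step=1.0)
            assert np.allclose(ours, oracle, atol=1e-6)

    def test_chapman_kolmogorov_on_aligned_grid(self):
        model = sl.default_true_model()
        step = 1.0
        p_full = sl.transition_probability(model, 70.0, 3.0, approx_step=step)
        p_a = sl.transition_probability(model, 70.0, 1.0, approx_step=step)
        p_b = sl.transition_probability(model, 71.0, 2.0, approx_step=step)
        assert np.allclose(p_full, p_a @ p_b, atol=1e-12)

    def test_negative_dt_raises(self):
        with pytest.raises(ValueError):
            sl.transition_probability(sl.default_true_model(), 70.0, -1.0)


class TestPanelLoglik:
    def test_zero_rates_same_state_gives_zero(self):
        df = pd.DataFrame(
            {"subject_id": [1, 1], "age": [70.0, 72.0], "state": [1, 1]}
        )
        model = sl.IntensityModel(sl.DEFAULT_STRUCTURE, alpha=np.full(7, -600.0))
        assert sl.panel_loglik(model, sl.PanelDataset(df)) == pytest.approx(0.0)

    def test_exact_death_density_closed_form(self):
        df = pd.DataFrame(
            {"subject_id": [1, 1], "age": [60.0, 62.0], "state": [1, 2]}
        )
        data = sl.PanelDataset(df, n_states=2, dead_state=2)
        ll = sl.panel_loglik(death_only_model(0.1), data)
        assert ll == pytest.approx(np.log(0.1) - 0.2, abs=1e-10)

    def test_matches_ode_oracle_on_toy_panel(self, toy_panel):
        model = sl.default_true_model()
        ours = sl.panel_loglik(model, toy_panel, approx_step=1.0)
        oracle = ode_panel_loglik(model, toy_panel, approx_step=1.0)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_invariant_to_subject_order_and_batching(self, toy_panel):
        model = sl.default_true_model()
        full = sl.panel_loglik(model, toy_panel)
        df = toy_panel.data
        shuffled = sl.PanelDataset(
            df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        )
        assert sl.panel_loglik(model, shuffled) == pytest.approx(full, abs=1e-12)
        ids = sorted(df["subject_id"].unique())
        half = len(ids) // 2
        parts = [
            sl.PanelDataset(df[df.subject_id.isin(ids[:half])].copy()),
            sl.PanelDataset(df[df.subject_id.isin(ids[half:])].copy()),
        ]
        assert sum(sl.panel_loglik(model, p) for p in parts) == pytest.approx(
            full, abs=1e-12
        )

    def test_step_refinement_converges(self, toy_panel):
        model = sl.default_true_model()
        lls = [
            sl.panel_loglik(model, toy_panel, approx_step=s)
            for s in (2.0, 1.0, 0.5, 0.25)
        ]
        gaps = np.abs(np.diff(lls))
        assert np.all(np.diff(gaps) <= 1e-12)  # halving shrinks the change

    def test_impossible_transition_reported(self):
        # structure without recovery: an observed 2->1 move has probability 0
        structure = sl.TransitionStructure(((1, 2), (1, 3), (2, 3)), n_states=3,
                                           dead_state=3)
        model = sl.IntensityModel(structure, alpha=np.log([0.1, 0.05, 0.05]))
        df = pd.DataFrame(
            {"subject_id": [1, 1], "age": [60.0, 62.0], "state": [2, 1]}
        )
        data = sl.PanelDataset(df, n_states=3, dead_state=3)
        assert sl.panel_loglik(model, data) == -np.inf
        bad = sl.loglik_breakdown(model, data)
        assert (bad["likelihood"] <= 0).sum() == 1


class TestFit:
    def test_two_state_exact_mle(self):
        rng = np.random.default_rng(11)
        mu_true = 0.08
        rows = []
        person_time = 0.0
        deaths = 0
        for i in range(400):
            t = rng.exponential(1.0 / mu_true)
            horizon = rng.uniform(2.0, 8.0)
            if t < horizon:
                rows += [(i, 60.0, 1), (i, 60.0 + t, 2)]
                person_time += t
                deaths += 1
            else:
                rows += [(i, 60.0, 1), (i, 60.0 + horizon, 1)]
                person_time += horizon
        df = pd.DataFrame(rows, columns=["subject_id", "age", "state"])
        data = sl.PanelDataset(df, n_states=2, dead_state=2)
        fit = sl.fit_msm(
            data, structure=two_state_structure(), age_effect=False,
            compute_covariance=False,
        )
        analytic = deaths / person_time
        assert np.exp(fit.params[0]) == pytest.approx(analytic, abs=1e-4)

    def test_refit_from_mle_is_fixed_point(self, recovery_fit, recovery_cohort):
        refit = sl.fit_msm(
            recovery_cohort.panel, init=recovery_fit.params,
            compute_covariance=False,
        )
        assert refit.loglik == pytest.approx(recovery_fit.loglik, abs=1e-6)

    def test_parameter_recovery_within_three_se(self, recovery_fit, recovery_cohort):
        truth = np.concatenate(
            [recovery_cohort.truth["alpha"], recovery_cohort.truth["beta"]]
        )
        z = np.abs(recovery_fit.params - truth) / recovery_fit.se()
        assert np.all(z < 3.0), dict(zip(recovery_fit.param_names, z))

    def test_covariance_symmetric_psd(self, recovery_fit):
        cov = recovery_fit.cov
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > -1e-8

    def test_unobserved_transition_warns(self):
        df = pd.DataFrame(
            {"subject_id": [1, 1, 2, 2], "age": [60, 62, 61, 63.2],
             "state": [1, 1, 1, 2]}
        )
        with pytest.warns(UserWarning, match="2->3"):
            sl.crude_init(sl.PanelDataset(df), sl.DEFAULT_STRUCTURE)

    def test_fitted_model_json_roundtrip(self, recovery_fit, tmp_path):
        path = tmp_path / "fit.json"
        recovery_fit.to_json(path)
        back = sl.FittedModel.from_json(path)
        assert np.allclose(back.params, recovery_fit.params)
        assert np.allclose(back.cov, recovery_fit.cov)
        assert back.loglik == pytest.approx(recovery_fit.loglik)
        assert back.param_names == recovery_fit.param_names
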