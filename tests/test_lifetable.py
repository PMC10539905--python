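"""Life-table: occupancy, quadratures, prevalence weighting, bootstrap."""

import numpy as np
import pytest

import sarcolife as sl

from conftest import death_only_model

CLOSED_FORM_TLE = (1 / 0.05) * (1 - np.exp(-3.0))  # 19.004 y


class TestOccupancy:
    def test_identity_at_start(self):
        ages, occ = sl.state_occupancy(
            sl.default_true_model(), 60.0, sl.LEConfig(h=0.5)
        )
        assert ages[0] == 60.0 and ages[-1] == 120.0
        assert np.array_equal(occ[0], np.eye(4))

    def test_rows_stochastic_and_death_monotone(self):
        _, occ = sl.state_occupancy(sl.default_true_model(), 65.0, sl.LEConfig(x=65))
        assert np.allclose(occ.sum(axis=2), 1.0, atol=1e-10)
        dead_col = occ[:, :, 3]
        assert np.all(np.diff(dead_col, axis=0) >= -1e-12)

    def test_death_only_closed_form(self):
        mu = 0.05
        _, occ = sl.state_occupancy(
            death_only_model(mu), 60.0, sl.LEConfig(h=0.5)
        )
        t = 0.5 * np.arange(occ.shape[0])
        assert np.allclose(occ[:, 0, 0], np.exp(-mu * t), atol=1e-6)

    def test_bad_start_age(self):
        with pytest.raises(ValueError):
            sl.state_occupancy(
                sl.default_true_model(), 130.0, sl.LEConfig(x=60.0)
            )


class TestQuadratures:
    @pytest.mark.parametrize("method", ["step", "middle_riemann", "simpson"])
    def test_death_only_closed_form_tle(self, method):
        cfg = sl.LEConfig(x=60, omega_max=120, h=0.02, method=method)
        tab = sl.life_expectancies(death_only_model(0.05), prev=None, cfg=cfg)
        assert tab.tle == pytest.approx(CLOSED_FORM_TLE, abs=0.02)

    def test_midpoint_and_simpson_are_sharper(self):
        vals = {}
        for method in ("step", "middle_riemann", "simpson"):
            cfg = sl.LEConfig(h=0.1, method=method)
            vals[method] = sl.life_expectancies(
                death_only_model(0.05), prev=None, cfg=cfg
            ).tle
        err = {k: abs(v - CLOSED_FORM_TLE) for k, v in vals.items()}
        assert err["simpson"] < 1e-6
        assert err["middle_riemann"] < 1e-3
        assert err["middle_riemann"] < err["step"]

    def test_step_converges_to_simpson_as_h_shrinks(self):
        gaps = []
        for h in (0.5, 0.1, 0.02):
            tles = {
                m: sl.life_expectancies(
                    death_only_model(0.05), prev=None,
                    cfg=sl.LEConfig(h=h, method=m),
                ).tle
                for m in ("step", "simpson")
            }
            gaps.append(abs(tles["step"] - tles["simpson"]))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.01


@pytest.fixture(scope="module")
def table(recovery_fit, recovery_prevalence):
    return sl.life_expectancies(
        recovery_fit, recovery_prevalence, sl.LEConfig(h=0.5)
    )


class TestLifeExpectancyTable:
    def test_tle_decomposition_exact(self, table):
        assert table.tle == pytest.approx(
            table.nsle + table.psle + table.sle, abs=1e-12
        )
        assert np.allclose(table.tle_cond, table.e_cond.sum(axis=1), atol=1e-12)

    def test_all_entries_bounded(self, table):
        assert np.all(table.e_cond >= 0)
        assert np.all(table.tle_cond <= 120.0 - 60.0)
        assert min(table.tle_cond) <= table.tle <= max(table.tle_cond)

    def test_tle_decreasing_in_age(self, recovery_fit, recovery_prevalence):
        tles = [
            sl.life_expectancies(
                recovery_fit, recovery_prevalence, sl.LEConfig(x=x)
            ).tle
            for x in (60.0, 70.0, 80.0)
        ]
        assert tles[0] > tles[1] > tles[2]

    def test_scaling_death_rates_up_decreases_tle(self, recovery_prevalence):
        model = sl.default_true_model()
        boosted = sl.IntensityModel(
            model.structure,
            model.alpha + np.log([1, 1, 1, 1, 2, 2, 2]),
            model.beta,
        )
        cfg = sl.LEConfig()
        base = sl.life_expectancies(model, recovery_prevalence, cfg).tle
        worse = sl.life_expectancies(boosted, recovery_prevalence, cfg).tle
        assert worse < base

    def test_empirical_vs_model_weighting(self, recovery_fit, recovery_cohort,
                                          recovery_prevalence):
        emp = sl.life_expectancies(
            recovery_fit, recovery_prevalence,
            sl.LEConfig(weight_mode="empirical"),
        )
        assert np.allclose(emp.weights, recovery_prevalence.empirical)
        assert emp.weights.sum() == pytest.approx(1.0)

    def test_tidy_output(self, table):
        df = sl.le_table_to_tidy(table)
        assert list(df.columns) == ["stratum", "quantity", "estimate", "lo95", "hi95"]
        assert list(df["quantity"]) == ["NSLE", "PSLE", "SLE", "TLE"]


class TestPrevalence:
    def test_equal_ages_give_observed_proportions(self):
        states = [1] * 30 + [2] * 50 + [3] * 20
        ages = [70.0] * 100
        prev = sl.fit_prevalence(states, ages)
        assert np.allclose(prev.predict(70.0), [0.3, 0.5, 0.2], atol=1e-6)

    def test_recovery_from_known_logit(self):
        rng = np.random.default_rng(21)
        n = 5000
        true = sl.default_baseline_prevalence()
        ages = rng.uniform(60, 90, size=n)
        probs = np.atleast_2d(true.predict(ages))
        states = np.array(
            [rng.choice((1, 2, 3), p=p) for p in probs]
        )
        fitted = sl.fit_prevalence(states, ages)
        z = np.abs(fitted.coef - true.coef) / fitted.bse
        assert np.all(z < 3.0)

    def test_probabilities_sum_to_one(self, recovery_prevalence):
        probs = recovery_prevalence.predict(np.arange(60.0, 101.0))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(probs > 0)

    def test_absent_state_is_named(self):
        with pytest.raises(ValueError, match="state 3"):
            sl.fit_prevalence([1, 2, 1, 2], [61, 62, 63, 64])


class TestBootstrap:
    def test_zero_covariance_gives_zero_width(self, recovery_fit,
                                              recovery_prevalence):
        frozen = sl.FittedModel(
            model=recovery_fit.model,
            layout=recovery_fit.layout,
            params=recovery_fit.params,
            cov=np.zeros_like(recovery_fit.cov),
            loglik=recovery_fit.loglik,
            converged=True,
            n_iter=0,
            n_evals=0,
            approx_step=1.0,
        )
        boot = sl.bootstrap_le(frozen, recovery_prevalence,
                               sl.LEConfig(n_boot=5, seed=0))
        lo, hi = boot.ci_percentile["TLE"]
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_bit_identical(self, recovery_fit, recovery_prevalence):
        cfg = sl.LEConfig(n_boot=10, seed=123)
        a = sl.bootstrap_le(recovery_fit, recovery_prevalence, cfg)
        b = sl.bootstrap_le(recovery_fit, recovery_prevalence, cfg)
        assert np.array_equal(a.tle_draws, b.tle_draws)
        assert a.ci_percentile == b.ci_percentile

    def test_default_draw_count_is_thirty(self):
        assert sl.LEConfig().n_boot == 30

    def test_draws_respect_invariants(self, recovery_fit, recovery_prevalence):
        boot = sl.bootstrap_le(recovery_fit, recovery_prevalence,
                               sl.LEConfig(n_boot=8, seed=5))
        assert np.all(boot.e_cond_draws >= 0)
        assert np.allclose(
            boot.marginal_draws.sum(axis=1), boot.tle_draws, atol=1e-10
        )
        assert np.all(boot.tle_draws <= 60.0)
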