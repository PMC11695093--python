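"""Poisson hazard model: closed forms, optimizer oracle, sandwich algebra."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

import twinppd as tp
from twinppd.model import poisson_irls, cluster_robust_vcov

KNOTS = tp.KnotSet(time=(30.0, 105.0, 195.0, 330.0))


def toy_table(rows):
    """rows: (risk_days, events, twin, t, parent_id)"""
    df = pd.DataFrame(
        rows, columns=["risk_days", "events", "twin", "band_midpoint_day", "parent_id"]
    )
    df["plurality"] = np.where(df.pop("twin") == 1, "twin", "singleton")
    return df


def neg_loglik(beta, X, y, offset):
    mu = np.exp(X @ beta + offset)
    return -(np.sum(special.xlogy(y, mu) - mu))


class TestClosedForms:
    def test_single_rate_is_events_over_person_time(self):
        X = np.ones((4, 1))
        y = np.array([2.0, 1.0, 1.0, 1.0])  # 5 events
        offset = np.log(np.array([10.0, 30.0, 40.0, 20.0]))  # 100 person-days
        beta, *_ = poisson_irls(X, y, offset)
        assert np.exp(beta[0]) == pytest.approx(0.05, abs=1e-12)

    def test_two_group_log_rate_ratio(self):
        # group 0: 3 events / 50 d; group 1: 12 events / 100 d -> ratio 2
        X = np.column_stack([np.ones(2), [0.0, 1.0]])
        y = np.array([3.0, 12.0])
        offset = np.log(np.array([50.0, 100.0]))
        beta, *_ = poisson_irls(X, y, offset)
        assert beta[1] == pytest.approx(np.log(2.0), abs=1e-10)
        assert np.exp(beta[0]) == pytest.approx(0.06, abs=1e-12)


class TestOptimizerOracle:
    def test_irls_matches_generic_optimizer_on_small_table(self):
        """IRLS and a derivative-free optimizer agree to 4 decimals per
        coefficient on a <=20-row person-period table."""
        rng = np.random.default_rng(9)
        rows = []
        for i in range(10):
            t = float(rng.uniform(5, 360))
            rows.append(
                (float(rng.uniform(5, 30)), int(rng.random() < 0.5), i % 2, t, f"P{i}")
            )
        rows.append((20.0, 1, 0, 100.0, "P99"))  # ensure events in both arms
        rows.append((20.0, 1, 1, 200.0, "P98"))
        table = toy_table(rows)
        spec = tp.ModelSpec(role="mother", time_interaction=False)
        fit = tp.fit_piecewise_poisson(table, spec, KNOTS)

        X, names = tp.build_design(table, spec, KNOTS)
        y = table["events"].to_numpy(float)
        offset = np.log(table["risk_days"].to_numpy(float))
        res = optimize.minimize(
            neg_loglik,
            np.zeros(X.shape[1]),
            args=(X, y, offset),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 100_000, "maxfev": 100_000},
        )
        assert res.success
        assert np.max(np.abs(fit.params.to_numpy() - res.x)) < 1e-4

    def test_score_equation_balances_events(self, scaled_fit):
        _, _, pp, fit = scaled_fit
        X, _ = tp.build_design(pp, fit.spec, fit.knots)
        mu = pp["risk_days"].to_numpy() * np.exp(X @ fit.params.to_numpy())
        assert abs(mu.sum() - pp["events"].sum()) < 1e-6

    def test_interaction_never_increases_deviance(self, scaled_fit):
        _, _, pp, fit_full = scaled_fit
        fit_prop = tp.fit_piecewise_poisson(
            pp, tp.ModelSpec(role="mother", time_interaction=False), fit_full.knots
        )
        assert fit_full.deviance <= fit_prop.deviance + 1e-8

    def test_fitted_rates_invariant_to_affine_basis_change(self, scaled_fit):
        """Any tail-linear basis spanning the same space must give the same
        fitted hazard; rescaling/shifting the nonlinear columns is such a
        change."""
        _, _, pp, fit = scaled_fit
        X, names = tp.build_design(pp, fit.spec, fit.knots)
        A = np.eye(X.shape[1])
        # mix the two nonlinear time columns and rescale (invertible)
        i1, i2 = names.index("time_rcs2"), names.index("time_rcs3")
        A[i1, i1], A[i1, i2], A[i2, i2] = 2.0, 0.7, -1.5
        Xt = X @ A
        y = pp["events"].to_numpy(float)
        offset = np.log(pp["risk_days"].to_numpy(float))
        beta_t, *_ = poisson_irls(Xt, y, offset)
        eta_orig = X @ fit.params.to_numpy()
        assert np.allclose(Xt @ beta_t, eta_orig, atol=1e-6)


class TestStatsmodelsCrossCheck:
    def test_coefficients_and_cluster_se_match_glm(self, scaled_fit):
        import statsmodels.api as sm

        _, _, pp, fit = scaled_fit
        X, names = tp.build_design(pp, fit.spec, fit.knots)
        glm = sm.GLM(
            pp["events"].to_numpy(float),
            X,
            family=sm.families.Poisson(),
            offset=np.log(pp["risk_days"].to_numpy(float)),
        )
        res = glm.fit(
            cov_type="cluster",
            cov_kwds={
                "groups": pd.factorize(pp["parent_id"])[0],
                "df_correction": False,
            },
        )
        assert np.allclose(res.params, fit.params.to_numpy(), atol=1e-6)
        assert np.allclose(
            res.cov_params(), fit.cov_cluster.to_numpy(), rtol=1e-4, atol=1e-10
        )


class TestSandwich:
    def small_fit(self):
        rng = np.random.default_rng(2)
        rows = [
            (float(rng.uniform(10, 30)), int(rng.random() < 0.4), i % 2,
             float(rng.uniform(10, 350)), f"C{i % 6}")
            for i in range(24)
        ]
        table = toy_table(rows)
        spec = tp.ModelSpec(time_interaction=False)
        return table, tp.fit_piecewise_poisson(table, spec, KNOTS)

    def test_singleton_clusters_reduce_to_hc0(self):
        table, fit = self.small_fit()
        X, _ = tp.build_design(table, fit.spec, fit.knots)
        y = table["events"].to_numpy(float)
        mu = table["risk_days"].to_numpy() * np.exp(X @ fit.params.to_numpy())
        V, g = cluster_robust_vcov(X, y, mu, np.arange(len(table)))
        A_inv = np.linalg.inv((X * mu[:, None]).T @ X)
        hc0 = A_inv @ (X * ((y - mu) ** 2)[:, None]).T @ X @ A_inv
        assert g == len(table)
        assert np.allclose(V, hc0, atol=1e-12)

    def test_duplicating_clusters_halves_robust_variance(self):
        table, fit = self.small_fit()
        dup = pd.concat(
            [table, table.assign(parent_id=table["parent_id"] + "_copy")],
            ignore_index=True,
        )
        fit2 = tp.fit_piecewise_poisson(dup, fit.spec, fit.knots)
        assert np.allclose(fit2.params, fit.params, atol=1e-8)
        assert np.allclose(
            fit2.cov_cluster.to_numpy(), fit.cov_cluster.to_numpy() / 2, rtol=1e-6
        )

    def test_robust_close_to_model_se_under_independence(self):
        """Correctly specified model, independent parents: sandwich and
        model-based standard errors agree within 15%."""
        sc = tp.paper_shaped_scenario(
            n_births=50_000, seed=77, risk_scale=5.0, repeat_birth_rate=0.0
        )
        cohort = tp.build_cohort(tp.simulate_scenario(sc), role="mother")
        pp = tp.split_follow_up(cohort)
        spec = tp.ModelSpec(role="mother", time_interaction=False)
        fit = tp.fit_piecewise_poisson(pp, spec, tp.default_knots(cohort, spec))
        se_m = np.sqrt(np.diag(fit.cov_model))
        se_r = np.sqrt(np.diag(fit.cov_cluster))
        assert np.all(np.abs(se_r / se_m - 1) < 0.15)

    def test_single_cluster_rejected(self):
        table, fit = self.small_fit()
        X, _ = tp.build_design(table, fit.spec, fit.knots)
        y = table["events"].to_numpy(float)
        mu = np.ones(len(table))
        with pytest.raises(ValueError, match="cluster"):
            cluster_robust_vcov(X, y, mu, np.zeros(len(table)))


class TestErrorHandling:
    def test_rank_deficiency_names_columns(self):
        rows = [(10.0, 1, 0, 50.0, f"P{i}") for i in range(10)]
        table = toy_table(rows)  # all singleton: twin column is all zero
        with pytest.raises(np.linalg.LinAlgError, match="twin"):
            tp.fit_piecewise_poisson(table, tp.ModelSpec(time_interaction=False), KNOTS)

    def test_zero_events_rejected(self):
        rows = [(10.0, 0, i % 2, 50.0 + i, f"P{i}") for i in range(10)]
        with pytest.raises(ValueError, match="no events"):
            tp.fit_piecewise_poisson(toy_table(rows), tp.ModelSpec(), KNOTS)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tp.fit_piecewise_poisson(toy_table([]), tp.ModelSpec(), KNOTS)


def test_adjusted_mother_spec_fits_and_nests_father_terms(scaled_fit):
    sc, cohort, _, _ = scaled_fit
    pp = tp.split_follow_up(cohort)
    spec_m = tp.ModelSpec(role="mother", adjusted=True)
    knots = tp.default_knots(cohort, spec_m)
    fit = tp.fit_piecewise_poisson(pp, spec_m, knots)
    assert fit.converged
    assert "primiparous" in fit.names
    father_terms = set(fit.names) - {"primiparous"}
    assert {"art", "cohabiting", "age_rcs1", "year_rcs1"} <= father_terms


def test_fit_json_roundtrip(scaled_fit, tmp_path):
    _, _, _, fit = scaled_fit
    path = tmp_path / "fit.json"
    fit.to_json(path)
    back = tp.SplineHazardFit.from_json(path)
    assert np.allclose(back.params.to_numpy(), fit.params.to_numpy())
    assert back.knots.time == fit.knots.time
    assert back.spec == fit.spec
    assert np.allclose(back.cov_cluster.to_numpy(), fit.cov_cluster.to_numpy())


def test_wald_test_on_null_interaction_terms(scaled_fit):
    _, _, _, fit = scaled_fit
    terms = [nm for nm in fit.names if nm.startswith("twin:")]
    stat, df, p = tp.wald_test(fit, terms)
    assert df == 3 and stat >= 0 and 0 <= p <= 1
    with pytest.raises(ValueError, match="not in the model"):
        tp.wald_test(fit, ["nonexistent"])
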