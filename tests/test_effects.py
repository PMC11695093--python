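"""Standardized curves, HR(t), landmark RRs: arithmetic and invariants."""

import numpy as np
import pandas as pd
import pytest

import twinppd as tp
from twinppd.effects import _risk_paths

KNOTS = tp.KnotSet(time=(30.0, 105.0, 195.0, 330.0))


def toy_fit(coef: dict, time_interaction=True, role="mother", adjusted=False):
    """Hand-built fit with the given coefficients (others zero) and a tiny
    diagonal covariance."""
    spec = tp.ModelSpec(role=role, adjusted=adjusted, time_interaction=time_interaction)
    names = ["const", "time_rcs1", "time_rcs2", "time_rcs3", "twin"]
    if time_interaction:
        names += ["twin:time_rcs1", "twin:time_rcs2", "twin:time_rcs3"]
    params = pd.Series(0.0, index=names)
    for k, v in coef.items():
        params[k] = v
    cov = pd.DataFrame(np.eye(len(names)) * 1e-8, index=names, columns=names)
    return tp.SplineHazardFit(
        spec=spec, knots=KNOTS, params=params, cov_model=cov, cov_cluster=cov,
        loglik=0.0, deviance=0.0, n_iter=1, converged=True,
        n_rows=1, n_events=1, n_clusters=2,
    )


class TestStandardizedRate:
    def test_unadjusted_rate_is_exp_linear_predictor(self):
        fit = toy_fit({"const": -6.0, "time_rcs1": 0.01})
        t = 20.0  # below first knot: nonlinear terms vanish
        expected = np.exp(-6.0 + 0.01 * t)
        assert tp.standardized_rate(fit, None, "singleton", t)[0] == pytest.approx(
            expected, rel=1e-12
        )

    def test_hand_computed_linear_predictor_with_twin(self):
        fit = toy_fit({"const": -5.0, "twin": 0.3, "time_rcs2": 1.5})
        t = 150.0
        basis = tp.rcs_basis(t, KNOTS.time)[0]
        expected = np.exp(-5.0 + 0.3 + 1.5 * basis[1])
        assert tp.standardized_rate(fit, None, "twin", t)[0] == pytest.approx(
            expected, rel=1e-12
        )

    def test_adjusted_fit_requires_profile(self, scaled_fit):
        _, cohort, pp, _ = scaled_fit
        spec = tp.ModelSpec(role="mother", adjusted=True)
        knots = tp.default_knots(cohort, spec)
        fit = tp.fit_piecewise_poisson(pp, spec, knots)
        with pytest.raises(ValueError, match="profile"):
            tp.standardized_rate(fit, None, "twin", 60.0)
        with pytest.raises(ValueError, match="role"):
            tp.standardized_rate(fit, tp.father_reference(), "twin", 60.0)
        rate = tp.standardized_rate(fit, tp.mother_reference(), "twin", 60.0)
        assert rate[0] > 0


class TestCumulativeIncidence:
    def test_constant_hazard_closed_form(self):
        lam = 1e-4
        fit = toy_fit({"const": np.log(lam)})
        grid = np.array([0.0, 100.0, 365.0])
        curve = tp.cumulative_incidence_curve(fit, None, "singleton", grid, n_draws=100)
        expected = 1000 * -np.expm1(-lam * grid)
        assert np.allclose(curve["cuminc_per_1000"], expected, rtol=1e-9, atol=1e-9)

    def test_risk_zero_at_time_zero(self, scaled_fit):
        _, _, _, fit = scaled_fit
        curve = tp.cumulative_incidence_curve(
            fit, None, "twin", np.array([0.0, 10.0]), n_draws=100
        )
        assert curve["cuminc_per_1000"].iloc[0] == 0.0

    def test_exponential_hazard_closed_form(self):
        """log-linear hazard rate exp(a + b t) integrates to
        (exp(a)/b)(exp(bt) - 1); the trapezoid curve matches to ~1e-8."""
        a, b = np.log(5e-5), 0.004
        fit = toy_fit({"const": a, "time_rcs1": b})
        # keep t below the first knot so the predictor stays exactly linear
        grid = np.array([10.0, 20.0, 30.0])
        point, _ = _risk_paths(fit, None, "singleton", grid, None)
        lam = np.exp(a) / b * (np.exp(b * grid) - 1)
        assert np.allclose(point, 1000 * -np.expm1(-lam), rtol=1e-8)

    def test_monotone_and_ci_contains_point(self, scaled_fit):
        _, _, _, fit = scaled_fit
        grid = np.arange(1.0, 366.0, 7.0)
        for pl in ("twin", "singleton"):
            c = tp.cumulative_incidence_curve(fit, None, pl, grid, n_draws=500, seed=5)
            assert np.all(np.diff(c["cuminc_per_1000"]) >= -1e-12)
            assert ((c["lo"] <= c["cuminc_per_1000"]) & (c["cuminc_per_1000"] <= c["hi"])).all()
            assert c["cuminc_per_1000"].between(0, 1000).all()

    def test_rate_is_derivative_of_cumulative_hazard(self, scaled_fit):
        _, _, _, fit = scaled_fit
        t = np.array([60.0, 200.0])
        h = 0.01
        for pl in ("twin", "singleton"):
            lo, _ = _risk_paths(fit, None, pl, t - h, None)
            hi, _ = _risk_paths(fit, None, pl, t + h, None)
            lam_lo = -np.log1p(-lo / 1000)
            lam_hi = -np.log1p(-hi / 1000)
            dlam = (lam_hi - lam_lo) / (2 * h)
            rate = tp.standardized_rate(fit, None, pl, t)
            assert np.allclose(dlam, rate, rtol=1e-4)


class TestHazardRatioCurve:
    def test_zero_interactions_give_constant_hr(self):
        fit = toy_fit({"twin": np.log(1.4)})
        hr = tp.hr_curve(fit, np.linspace(1, 365, 50))
        assert np.allclose(hr["hr"], 1.4, rtol=1e-12)

    def test_hand_set_coefficients(self):
        fit = toy_fit({"twin": 0.2, "twin:time_rcs1": 0.001, "twin:time_rcs2": -0.5})
        t = 150.0
        basis = tp.rcs_basis(t, KNOTS.time)[0]
        expected = np.exp(0.2 + 0.001 * basis[0] - 0.5 * basis[1])
        assert tp.hr_curve(fit, [t])["hr"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_ci_positive_and_contains_point(self, scaled_fit):
        _, _, _, fit = scaled_fit
        hr = tp.hr_curve(fit, np.linspace(1, 365, 30))
        assert (hr["lo"] > 0).all()
        assert ((hr["lo"] <= hr["hr"]) & (hr["hr"] <= hr["hi"])).all()


class TestCumulativeRR:
    def test_null_effect_gives_unit_rr(self, scaled_fit):
        _, _, pp, _ = scaled_fit
        fit = toy_fit({"const": -6.0, "time_rcs1": 0.002})
        rr = tp.cumulative_rr(fit, None, n_draws=500, seed=1)
        assert np.allclose(rr["rr"], 1.0, rtol=1e-12)
        assert ((rr["lo"] <= 1.0) & (1.0 <= rr["hi"])).all()

    def test_small_risk_rr_approaches_hazard_ratio(self):
        c = 1.5
        fit = toy_fit({"const": np.log(1e-5), "twin": np.log(c)}, time_interaction=False)
        rr = tp.cumulative_rr(fit, None, n_draws=50, seed=0)
        assert np.allclose(rr["rr"], c, rtol=2e-3)

    def test_seed_determinism(self, scaled_fit):
        _, _, _, fit = scaled_fit
        a = tp.cumulative_rr(fit, None, n_draws=400, seed=11)
        b = tp.cumulative_rr(fit, None, n_draws=400, seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = tp.cumulative_rr(fit, None, n_draws=400, seed=12)
        assert not np.allclose(a["lo"], c["lo"])

    def test_invalid_landmarks_rejected(self, scaled_fit):
        _, _, _, fit = scaled_fit
        with pytest.raises(ValueError, match="landmarks"):
            tp.cumulative_rr(fit, None, landmarks=(0.0, 90.0), n_draws=10)


class TestCrudeRR:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((505, 25_611, 21_960, 1_257_947), 1.13),
            ((258, 25_611, 10_131, 1_257_947), 1.25),
            ((100, 1_000, 100, 1_000), 1.00),
        ],
    )
    def test_worked_examples(self, args, expected):
        assert tp.crude_cumulative_rr(*args, dp=2) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            tp.crude_cumulative_rr(0, 10, 5, 100)
        with pytest.raises(ValueError):
            tp.crude_cumulative_rr(11, 10, 5, 100)


def test_estimate_curves_bundle_and_io(scaled_fit, tmp_path):
    _, _, _, fit = scaled_fit
    cs = tp.estimate_curves(fit, None, grid=np.arange(5.0, 366.0, 10.0), n_draws=300, seed=3)
    assert set(cs.curves["plurality"]) == {"twin", "singleton"}
    assert list(cs.rr_landmarks["day"]) == [90.0, 180.0, 270.0, 365.0]
    assert cs.metadata["seed"] == 3
    cs.write(tmp_path)
    assert (tmp_path / "curves.csv").exists()
    assert (tmp_path / "hr_curve.csv").exists()
    assert (tmp_path / "rr_landmarks.csv").exists()


def test_small_risk_landmark_rr_matches_average_hr(scaled_fit):
    """Proportional-hazards fit at small risk: cumulative RR equals the
    (person-time-weighted) HR within 2%."""
    fit = toy_fit({"const": np.log(2e-5), "twin": np.log(1.3)}, time_interaction=False)
    rr = tp.cumulative_rr(fit, None, n_draws=50, seed=0)
    assert np.allclose(rr["rr"], 1.3, rtol=0.02)
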