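import numpy as np
import pandas as pd
import pytest

from gradmeta.gradients import fit_study_slope
from gradmeta.regression import (BackwardStepwiseOLS, backward_stepwise,
                                 fit_family, gaussian_aic, r2_grid,
                                 select_best_model)


def sites_frame(rng, n=100, eco_effect=0.0, mat_effect=0.0, noise=1.0):
    mat = rng.uniform(-5, 25, n)
    map_ = rng.uniform(100, 1500, n)
    aridity = rng.uniform(0, 1.2, n)
    eco = rng.choice(["forest", "grassland", "tundra"], n)
    soil = rng.choice(["Cambisol", "Luvisol"], n)
    eco_means = {"forest": 0.0, "grassland": 2.0, "tundra": -1.0}
    y = (mat_effect * mat
         + eco_effect * np.array([eco_means[e] for e in eco])
         + rng.normal(0, noise, n))
    return pd.DataFrame({"value": y, "mat": mat, "map": map_,
                         "aridity": aridity, "ecosystem": eco, "soil": soil})


class TestFitFamily:
    def test_exact_linear(self):
        x = np.linspace(0, 10, 12)
        fit = fit_family(x, 2.0 * x, "linear")
        assert fit.params == pytest.approx((0.0, 2.0), abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_exact_power_law(self):
        x = np.linspace(1, 10, 12)
        fit = fit_family(x, 3.0 * x ** 2, "power")
        assert fit.params == pytest.approx((3.0, 2.0), abs=1e-8)

    def test_exact_logarithmic_and_exponential(self):
        x = np.linspace(1, 5, 12)
        flog = fit_family(x, 1.0 + 2.0 * np.log(x), "logarithmic")
        assert flog.params == pytest.approx((1.0, 2.0), abs=1e-9)
        fexp = fit_family(x, 0.5 * np.exp(0.3 * x), "exponential")
        assert fexp.params == pytest.approx((0.5, 0.3), abs=1e-8)

    def test_quadratic_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 10, 12)
        y = 1.0 + 0.5 * x - 0.2 * x ** 2 + rng.normal(0, 0.3, 12)
        fit = fit_family(x, y, "quadratic")
        X = np.column_stack([np.ones(12), x, x ** 2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.params == pytest.approx(tuple(beta), abs=1e-9)

    @pytest.mark.parametrize("family,x,y", [
        ("power", [-1.0, 1, 2, 3, 4, 5], [1.0, 1, 2, 3, 4, 5]),
        ("logarithmic", [0.0, 1, 2, 3, 4, 5], [1.0, 1, 2, 3, 4, 5]),
        ("exponential", [1.0, 2, 3, 4, 5, 6], [-1.0, 1, 2, 3, 4, 5]),
    ])
    def test_domain_violations_mark_inapplicable(self, family, x, y):
        fit = fit_family(np.array(x), np.array(y), family)
        assert not fit.applicable
        assert "requires" in fit.message

    def test_linear_family_agrees_with_study_slope(self, rng):
        x = rng.uniform(100, 900, 10)
        y = 1.0 + 4e-4 * x + rng.normal(0, 0.1, 10)
        fit = fit_family(x, y, "linear")
        sites = pd.DataFrame({"study_id": "G1", "region": "R1",
                              "site_id": [f"p{i}" for i in range(10)],
                              "variable": "N", "value": y, "mat": 0.0,
                              "map": x, "mae": 1000.0, "ecosystem": "f",
                              "soil": "c"})
        rec = fit_study_slope(sites, "map", "N")
        assert fit.params[1] == pytest.approx(rec["slope"], abs=1e-10)
        assert fit.r2 == pytest.approx(rec["r2"], abs=1e-10)


class TestSelection:
    def test_exact_quadratic_selected(self):
        x = np.linspace(-3, 3, 20)
        best = select_best_model(x, 1.0 + 2.0 * x - 0.5 * x ** 2)
        assert best.family == "quadratic"
        assert best.r2 == pytest.approx(1.0)

    def test_pure_noise_mostly_unselected(self):
        """Sanity bound; the calibrated familywise rate is checked in the
        acceptance suite."""
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(100):
            x = rng.uniform(100.0, 2000.0, 20)
            y = rng.normal(0.0, 0.2, 20)
            if select_best_model(x, y) is None:
                hits += 1
        assert hits >= 80

    def test_power_never_selected_on_negative_domain(self, rng):
        x = np.linspace(-5, 5, 30)
        y = 1.0 + 0.8 * x + rng.normal(0, 0.3, 30)
        best = select_best_model(x, y)
        assert best is not None
        assert best.family in ("linear", "quadratic")


class TestR2Grid:
    def test_grid_has_31_rows(self, rng):
        grid = r2_grid(sites_frame(rng), predictors="TPASE")
        assert len(grid) == 31
        assert set(len(s) for s in grid["predictor_set"]) == {1, 2, 3, 4, 5}

    def test_nested_monotonicity(self, rng):
        grid = r2_grid(sites_frame(rng, mat_effect=0.1), predictors="TPASE")
        r2 = dict(zip(grid["predictor_set"], grid["r2"]))
        for s, val in r2.items():
            for t, val2 in r2.items():
                if set(t) < set(s):
                    assert val >= val2 - 1e-10

    def test_ecosystem_only_signal(self, rng):
        sites = sites_frame(rng, eco_effect=1.0, noise=1e-3)
        grid = r2_grid(sites, predictors="TE")
        r2 = dict(zip(grid["predictor_set"], grid["r2"]))
        assert r2["E"] > 0.99
        assert r2["T"] < 0.05

    def test_aic_differences_invariant_under_rescaling(self, rng):
        n = 50
        ss1, ss2 = 4.0, 2.5
        d1 = gaussian_aic(ss1, n, 3) - gaussian_aic(ss2, n, 2)
        c = 7.3  # rescaling y by c multiplies both SSR by c^2
        d2 = gaussian_aic(ss1 * c ** 2, n, 3) - gaussian_aic(ss2 * c ** 2, n, 2)
        assert d1 == pytest.approx(d2, abs=1e-10)


class TestBackwardStepwise:
    def test_strong_signal_retained(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sites = sites_frame(rng, mat_effect=0.5, noise=1.0, n=200)
            fit = backward_stepwise(sites, "value", "TPASE")
            hits += "T" in fit.family
        assert hits >= 95

    def test_pure_noise_mostly_intercept_only(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            sites = sites_frame(rng, noise=1.0, n=150)
            fit = backward_stepwise(sites, "value", "TPASE")
            hits += fit.family == "ols:intercept"
        assert hits >= 30

    def test_final_aic_within_two_of_full_model(self, rng):
        sites = sites_frame(rng, mat_effect=0.2, eco_effect=0.5, n=120)
        est = BackwardStepwiseOLS(full_set="TPASE").fit(sites, "value")
        full_aic = est.steps_[0]["aic"]
        assert est.aic_ <= full_aic + 2.0 + 1e-9
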