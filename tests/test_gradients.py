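import numpy as np
import pandas as pd
import pytest

from gradmeta.gradients import (RegionMixedModel, bootstrap_grand_slope,
                                fit_study_slope, grand_slopes_table)


def make_study(x, y, study="G1", region="R1", variable="N"):
    return pd.DataFrame({"study_id": study, "region": region,
                         "site_id": [f"p{i}" for i in range(len(x))],
                         "variable": variable, "value": y, "mat": 5.0,
                         "map": x, "mae": 1000.0, "ecosystem": "forest",
                         "soil": "Cambisol"})


class TestStudySlope:
    def test_exact_line(self):
        rec = fit_study_slope(make_study([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]),
                              "map", "N")
        assert rec["slope"] == pytest.approx(1.0)
        assert rec["r2"] == pytest.approx(1.0)

    def test_constant_response_zero_slope(self):
        rec = fit_study_slope(make_study([0.0, 1.0, 2.0], [3.0, 3.0, 3.0]),
                              "map", "N")
        assert rec["slope"] == 0.0

    def test_closed_form_oracle(self, rng):
        x = rng.uniform(100, 900, 10)
        y = 1.0 + 4e-4 * x + rng.normal(0, 0.1, 10)
        rec = fit_study_slope(make_study(x, y), "map", "N")
        slope = np.sum((x - x.mean()) * (y - y.mean())) \
            / np.sum((x - x.mean()) ** 2)
        assert rec["slope"] == pytest.approx(slope, abs=1e-12)

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_study_slope(make_study([5.0, 5.0, 5.0], [1.0, 2.0, 3.0]),
                            "map", "N")

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_study_slope(make_study([1.0, 2.0], [1.0, 2.0]), "map", "N")

    def test_order_and_shift_invariance(self, rng):
        x = rng.uniform(0, 10, 8)
        y = 2.0 + 0.5 * x + rng.normal(0, 0.2, 8)
        base = fit_study_slope(make_study(x, y), "map", "N")
        perm = rng.permutation(8)
        shuffled = fit_study_slope(make_study(x[perm], y[perm]), "map", "N")
        shifted = fit_study_slope(make_study(x, y + 100.0), "map", "N")
        assert shuffled["slope"] == pytest.approx(base["slope"], abs=1e-12)
        assert shifted["slope"] == pytest.approx(base["slope"], abs=1e-9)


def reml_grid_oracle(y, regions):
    """Independent REML maximizer: brute-force over both variance
    components using the matrix form of the restricted likelihood."""
    y = np.asarray(y, float)
    labels, codes = np.unique(regions, return_inverse=True)
    Z = np.eye(labels.size)[codes]
    one = np.ones_like(y)

    def nll(s2r, s2e):
        V = s2r * Z @ Z.T + s2e * np.eye(y.size)
        Vi = np.linalg.inv(V)
        mu = (one @ Vi @ y) / (one @ Vi @ one)
        r = y - mu
        sign, logdet = np.linalg.slogdet(V)
        return logdet + np.log(one @ Vi @ one) + r @ Vi @ r

    s2r_lo, s2r_hi = 0.0, 4.0 * np.var(y)
    s2e_lo, s2e_hi = 1e-8, 4.0 * np.var(y)
    best = None
    for _ in range(5):
        g_r = np.linspace(s2r_lo, s2r_hi, 41)
        g_e = np.linspace(s2e_lo, s2e_hi, 41)
        vals = [(nll(a, b), a, b) for a in g_r for b in g_e]
        best = min(vals)
        dr, de = g_r[1] - g_r[0], g_e[1] - g_e[0]
        s2r_lo, s2r_hi = max(0.0, best[1] - dr), best[1] + dr
        s2e_lo, s2e_hi = max(1e-8, best[2] - de), best[2] + de
    return best[1], best[2]


class TestRegionMixedModel:
    def test_constant_slopes_degenerate(self):
        m = RegionMixedModel().fit([0.4] * 6, ["R1", "R1", "R2", "R2",
                                               "R3", "R3"])
        assert m.mean_ == pytest.approx(0.4)
        assert m.sigma2_region_ == 0.0
        assert m.sigma2_res_ == 0.0

    def test_balanced_two_regions_average(self):
        y = [1.0, 1.2, 0.8, 3.0, 3.2, 2.8]
        m = RegionMixedModel().fit(y, ["R1"] * 3 + ["R2"] * 3)
        assert m.mean_ == pytest.approx(2.0, abs=1e-6)

    def test_single_region_fixed_zero_region_variance(self, rng):
        y = rng.normal(0.5, 0.1, 10)
        m = RegionMixedModel().fit(y, ["R1"] * 10)
        assert m.single_region_
        assert m.sigma2_region_ == 0.0
        assert m.mean_ == pytest.approx(y.mean())

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_restricted_likelihood_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        regions = np.repeat([f"R{i}" for i in range(5)], 6)
        u = rng.normal(0, 0.3, 5)
        y = 0.5 + u[np.repeat(np.arange(5), 6)] + rng.normal(0, 0.4, 30)
        m = RegionMixedModel().fit(y, regions)
        s2r, s2e = reml_grid_oracle(y, regions)
        assert m.sigma2_region_ == pytest.approx(s2r, abs=1e-5)
        assert m.sigma2_res_ == pytest.approx(s2e, abs=1e-5)

    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.formula.api as smf
        regions = np.repeat([f"R{i}" for i in range(6)], 5)
        u = rng.normal(0, 0.2, 6)
        y = -0.3 + u[np.repeat(np.arange(6), 5)] + rng.normal(0, 0.3, 30)
        m = RegionMixedModel().fit(y, regions)
        df = pd.DataFrame({"y": y, "region": regions})
        sm_fit = smf.mixedlm("y ~ 1", df, groups="region").fit(reml=True)
        assert m.mean_ == pytest.approx(sm_fit.params["Intercept"], abs=1e-4)
        assert m.sigma2_region_ == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), abs=1e-4)
        assert m.sigma2_res_ == pytest.approx(sm_fit.scale, abs=1e-4)


class TestBootstrap:
    def test_degenerate_variances_zero_width(self):
        m = RegionMixedModel().fit([0.4] * 6, ["R1"] * 3 + ["R2"] * 3)
        gs = bootstrap_grand_slope(m, 1000, seed=1)
        assert gs.ci_low == gs.ci_high == pytest.approx(0.4)

    def test_same_seed_reproducible(self, rng):
        y = rng.normal(-0.004, 0.002, 20)
        m = RegionMixedModel().fit(y, np.repeat(np.arange(4), 5))
        a = bootstrap_grand_slope(m, 500, seed=9)
        b = bootstrap_grand_slope(m, 500, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_seed_required(self, rng):
        m = RegionMixedModel().fit(rng.normal(0, 1, 10), ["R1"] * 10)
        with pytest.raises(ValueError, match="seed"):
            bootstrap_grand_slope(m, 1000)

    def test_single_region_matches_normal_theory(self, rng):
        """With one region and i.i.d. slopes the bootstrap CI approaches
        the classical normal-theory CI of a mean."""
        y = rng.normal(0.5, 0.2, 40)
        m = RegionMixedModel().fit(y, ["R1"] * 40)
        gs = bootstrap_grand_slope(m, 4000, seed=3)
        half = 1.96 * y.std(ddof=1) / np.sqrt(40)
        assert gs.ci_low == pytest.approx(y.mean() - half, abs=0.3 * half)
        assert gs.ci_high == pytest.approx(y.mean() + half, abs=0.3 * half)

    def test_table_by_covariate_and_variable(self, rng):
        rows = []
        for cov in ("map", "mat"):
            for i in range(6):
                rows.append({"study_id": f"G{i}", "region": f"R{i % 2}",
                             "covariate": cov, "variable": "N",
                             "slope": rng.normal(0.001, 0.0005),
                             "se": 0.0002, "n_sites": 8, "r2": 0.5})
        table = grand_slopes_table(pd.DataFrame(rows), n_boot=200, seed=5)
        assert set(table["covariate"]) == {"map", "mat"}
        assert (table["n_studies"] == 6).all()
        again = grand_slopes_table(pd.DataFrame(rows), n_boot=200, seed=5)
        pd.testing.assert_frame_equal(table, again)


class TestParameterRecovery:
    def test_pooled_mean_unbiased(self, rng):
        """|bias| of the pooled grand slope < 0.1 sd over 500 replicates."""
        mu, s2r, s2e = -0.004, 0.001 ** 2, 0.002 ** 2
        est = np.empty(500)
        for r in range(500):
            u = rng.normal(0, np.sqrt(s2r), 4)
            codes = rng.integers(0, 4, 16)
            y = mu + u[codes] + rng.normal(0, np.sqrt(s2e), 16)
            est[r] = RegionMixedModel().fit(y, codes).mean_
        assert abs(est.mean() - mu) < 0.1 * est.std()
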