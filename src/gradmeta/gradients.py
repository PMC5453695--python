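"""Observational track: per-study slopes and their mixed-model synthesis.

Each gradient study contributes the ordinary-least-squares slope of a soil
variable against a climate covariate (MAP, MAT or aridity) over its sites.
The study slopes are then pooled with an intercept-only mixed model

    slope_i = mu + u_region(i) + eps_i,
    u ~ Normal(0, sigma2_region),  eps ~ Normal(0, sigma2_res),

fitted by REML, with region as a random effect to absorb geographic
clustering. The uncertainty of the grand mean slope mu is summarized by an
unconditional parametric bootstrap: each replicate simulates fresh region
effects and residuals from the fitted variances, refits the model, and the
95% CI is the 2.5/97.5 percentile range of the replicate means. Slopes are
pooled unweighted; per-study slope SEs are carried in the outputs only.

The REML fit profiles the residual variance out of the one-way
random-intercept likelihood, leaving a one-dimensional search over the
variance ratio; this keeps thousands of bootstrap refits cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .meta import classify_direction

SLOPE_COLUMNS = ["study_id", "region", "covariate", "variable",
                 "slope", "se", "n_sites", "r2"]
GRAND_SLOPE_COLUMNS = ["covariate", "variable", "mean", "ci_low", "ci_high",
                       "n_studies", "n_regions", "n_boot", "seed", "direction"]


def fit_study_slope(sites: pd.DataFrame, covariate: str, variable: str) -> dict:
    """OLS slope of one study's soil values against a climate covariate.

    Requires at least 3 sites with non-degenerate covariate values. Returns
    a dict with the slope, its SE, R^2 and bookkeeping fields.
    """
    sub = sites[sites["variable"] == variable]
    x = sub[covariate].to_numpy(dtype=float)
    y = sub["value"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError(
            f"study {sites['study_id'].iloc[0] if len(sites) else '?'}: "
            f"need >= 3 sites to fit a slope, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate covariate: zero variance across sites")
    if np.ptp(y) == 0:  # constant response: exact zero slope, define r2 = 0
        res = None
        slope, se, r2 = 0.0, 0.0, 0.0
    else:
        res = stats.linregress(x, y)
        slope, se, r2 = float(res.slope), float(res.stderr), float(res.rvalue ** 2)
    return {
        "study_id": sub["study_id"].iloc[0],
        "region": sub["region"].iloc[0],
        "covariate": covariate,
        "variable": variable,
        "slope": slope,
        "se": se,
        "n_sites": int(x.size),
        "r2": r2,
    }


def fit_all_slopes(sites: pd.DataFrame, covariates=("map", "mat", "aridity"),
                   log: list | None = None) -> pd.DataFrame:
    """Per-study slopes for every covariate x variable with enough sites."""
    rows = []
    for (study, variable), sub in sites.groupby(["study_id", "variable"],
                                                sort=True, observed=True):
        for cov in covariates:
            if cov not in sub.columns:
                continue
            try:
                rows.append(fit_study_slope(sub, cov, variable))
            except ValueError as err:
                if log is not None:
                    log.append({"event": "skipped_slope", "study_id": study,
                                "variable": variable, "covariate": cov,
                                "reason": str(err)})
    return pd.DataFrame(rows, columns=SLOPE_COLUMNS)


def _profile_reml_nll(rho: float, n: np.ndarray, ybar: np.ndarray,
                      ssw: float, ntot: int):
    """Restricted -2 log-likelihood profiled over the residual variance.

    ``rho`` = sigma2_region / sigma2_res. Returns (nll, mu, sigma2_res).
    """
    wt = n / (1.0 + n * rho)          # sigma2_res * GLS weights
    sw = wt.sum()
    mu = np.sum(wt * ybar) / sw
    q = ssw + np.sum(wt * (ybar - mu) ** 2)
    sigma2_res = q / (ntot - 1)
    nll = ((ntot - 1) * np.log(sigma2_res) + np.sum(np.log1p(n * rho))
           + np.log(sw) + (ntot - 1))
    return nll, mu, sigma2_res


class RegionMixedModel(BaseEstimator):
    """Intercept-only linear mixed model with a region random intercept.

    Fits ``y_ij = mu + u_j + e_ij`` by REML, profiling the residual
    variance and searching the variance ratio on a bounded interval.

    Attributes (after ``fit``)
    --------------------------
    mean_ : grand mean mu
    sigma2_region_, sigma2_res_ : variance components
    n_obs_, n_regions_ : sizes
    group_sizes_, group_labels_ : per-region layout (reused by the bootstrap)
    single_region_ : True when only one region was present (sigma2_region
        fixed at zero)
    """

    def __init__(self, max_ratio: float = 1e4):
        self.max_ratio = max_ratio

    def fit(self, y, regions):
        y = np.asarray(y, dtype=float).ravel()
        regions = np.asarray(regions)
        if y.size < 2:
            raise ValueError("need >= 2 observations to fit the mixed model")
        labels, codes = np.unique(regions, return_inverse=True)
        n = np.bincount(codes).astype(float)
        ybar = np.bincount(codes, weights=y) / n
        ssw = float(np.sum((y - ybar[codes]) ** 2))
        ntot = y.size

        self.group_labels_ = labels
        self.group_sizes_ = n.astype(int)
        self.n_obs_ = int(ntot)
        self.n_regions_ = int(labels.size)
        self.single_region_ = labels.size == 1

        if self.single_region_ or np.ptp(y) == 0:
            self.mean_ = float(np.mean(y))
            self.sigma2_region_ = 0.0
            self.sigma2_res_ = 0.0 if np.ptp(y) == 0 else \
                float(np.sum((y - self.mean_) ** 2) / max(ntot - 1, 1))
            return self

        def obj(rho):
            return _profile_reml_nll(rho, n, ybar, ssw, ntot)[0]

        res = minimize_scalar(obj, bounds=(0.0, self.max_ratio),
                              method="bounded", options={"xatol": 1e-10})
        rho = float(res.x)
        if obj(0.0) <= res.fun:  # boundary solution: no region variance
            rho = 0.0
        _, mu, s2res = _profile_reml_nll(rho, n, ybar, ssw, ntot)
        self.mean_ = float(mu)
        self.sigma2_res_ = float(s2res)
        self.sigma2_region_ = float(rho * s2res)
        return self


def _batched_nll_mu(rho, n, ybar, ssw, ntot):
    """Vectorized profiled REML -2 log-likelihood over replicates.

    ``rho`` (B,) variance ratio per replicate; ``ybar`` (B, J) region means;
    ``ssw`` (B,) within-region sums of squares. Returns (nll, mu), each (B,).
    """
    wt = n[None, :] / (1.0 + np.outer(rho, n))
    sw = wt.sum(axis=1)
    mu = np.sum(wt * ybar, axis=1) / sw
    q = ssw + np.sum(wt * (ybar - mu[:, None]) ** 2, axis=1)
    s2 = np.maximum(q / (ntot - 1), 1e-300)
    nll = ((ntot - 1) * np.log(s2) + np.sum(np.log1p(np.outer(rho, n)), axis=1)
           + np.log(sw))
    return nll, mu


def _batched_profile_reml(n, ybar, ssw, ntot, max_ratio):
    """Golden-section REML over the variance ratio, all replicates at once."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    B = ybar.shape[0]
    a = np.zeros(B)
    b = np.full(B, float(max_ratio))
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, _ = _batched_nll_mu(c, n, ybar, ssw, ntot)
    fd, _ = _batched_nll_mu(d, n, ybar, ssw, ntot)
    for _ in range(80):
        left = fc < fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c_new = b - invphi * (b - a)
        d_new = a + invphi * (b - a)
        fc_new = np.where(left, np.nan, fd)
        fd_new = np.where(left, fc, np.nan)
        need_c = left
        need_d = ~left
        if need_c.any():
            fc_eval, _ = _batched_nll_mu(c_new[need_c], n, ybar[need_c],
                                         ssw[need_c], ntot)
            fc_new[need_c] = fc_eval
        if need_d.any():
            fd_eval, _ = _batched_nll_mu(d_new[need_d], n, ybar[need_d],
                                         ssw[need_d], ntot)
            fd_new[need_d] = fd_eval
        c, d, fc, fd = c_new, d_new, fc_new, fd_new
    rho = 0.5 * (a + b)
    nll, mu = _batched_nll_mu(rho, n, ybar, ssw, ntot)
    nll0, mu0 = _batched_nll_mu(np.zeros(B), n, ybar, ssw, ntot)
    return np.where(nll0 <= nll, mu0, mu)


@dataclass
class GrandSlope:
    """Bootstrap-summarized mean slope of one variable vs one covariate."""
    covariate: str
    variable: str
    mean: float
    ci_low: float
    ci_high: float
    n_studies: int
    n_regions: int
    n_boot: int
    seed: int
    direction: str
    n_discarded: int = 0


def pool_slopes_mixed(slopes, regions=None) -> RegionMixedModel:
    """Fit the region mixed model to a vector (or table) of study slopes."""
    if isinstance(slopes, pd.DataFrame):
        regions = slopes["region"].to_numpy()
        slopes = slopes["slope"].to_numpy()
    return RegionMixedModel().fit(slopes, regions)


def bootstrap_grand_slope(model: RegionMixedModel, n_boot: int = 1000,
                          seed: int | None = None, covariate: str = "",
                          variable: str = "",
                          log: list | None = None) -> GrandSlope:
    """Unconditional parametric bootstrap CI for the grand mean slope.

    Each replicate draws new region effects from Normal(0, sigma2_region)
    and residuals from Normal(0, sigma2_res) around the fitted mean, refits
    the mixed model, and collects the refit mean. The CI is the 2.5/97.5
    percentile range; with both variance components zero every replicate
    reproduces the fitted mean and the CI has zero width. Replicates whose
    refit does not produce a finite mean are discarded and counted.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if seed is None:
        raise ValueError("a seed is required for the parametric bootstrap")
    rng = np.random.default_rng(seed)
    n = model.group_sizes_.astype(float)
    codes = np.repeat(np.arange(model.n_regions_), model.group_sizes_)
    ntot = model.n_obs_
    sd_u = np.sqrt(model.sigma2_region_)
    sd_e = np.sqrt(model.sigma2_res_)

    if sd_u == 0.0 and sd_e == 0.0:
        means = np.full(n_boot, model.mean_)
    else:
        u = rng.normal(0.0, sd_u, size=(n_boot, model.n_regions_))
        e = rng.normal(0.0, sd_e, size=(n_boot, ntot))
        ystar = model.mean_ + u[:, codes] + e
        # per-region means and pooled within-region sum of squares, batched
        ybar = np.stack([np.bincount(codes, weights=row) for row in ystar]) / n
        ssw = np.sum((ystar - ybar[:, codes]) ** 2, axis=1)
        means = _batched_profile_reml(n, ybar, ssw, ntot, model.max_ratio)

    ok = np.isfinite(means)
    n_disc = int(n_boot - ok.sum())
    if n_disc > 0.05 * n_boot and log is not None:
        log.append({"event": "bootstrap_warning",
                    "discarded": n_disc, "n_boot": n_boot})
    lo, hi = np.percentile(means[ok], [2.5, 97.5])
    return GrandSlope(covariate=covariate, variable=variable,
                      mean=float(model.mean_), ci_low=float(lo),
                      ci_high=float(hi), n_studies=model.n_obs_,
                      n_regions=model.n_regions_, n_boot=n_boot,
                      seed=int(seed),
                      direction=classify_direction(model.mean_, lo, hi),
                      n_discarded=n_disc)


def grand_slopes_table(slopes: pd.DataFrame, n_boot: int = 1000,
                       seed: int | None = None,
                       log: list | None = None) -> pd.DataFrame:
    """Grand slope per covariate x variable from a per-study slope table."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for (cov, var), sub in slopes.groupby(["covariate", "variable"],
                                          sort=True, observed=True):
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        if len(sub) < 2:
            if log is not None:
                log.append({"event": "skipped_grand_slope", "covariate": cov,
                            "variable": var, "n_studies": int(len(sub))})
            continue
        model = pool_slopes_mixed(sub)
        gs = bootstrap_grand_slope(model, n_boot=n_boot, seed=sub_seed,
                                   covariate=cov, variable=var, log=log)
        rows.append({"covariate": cov, "variable": var, "mean": gs.mean,
                     "ci_low": gs.ci_low, "ci_high": gs.ci_high,
                     "n_studies": int(len(sub)),
                     "n_regions": gs.n_regions, "n_boot": gs.n_boot,
                     "seed": gs.seed, "direction": gs.direction})
    return pd.DataFrame(rows, columns=GRAND_SLOPE_COLUMNS)
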