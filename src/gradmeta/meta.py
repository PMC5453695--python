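"""Random-effects pooling of log response ratios.

Model: observed effects y_i ~ Normal(theta_i, v_i) with known sampling
variances v_i, and true study effects theta_i ~ Normal(mu, tau2). The
pooled mean is the inverse-variance weighted average with weights
w_i* = 1/(v_i + tau2); its standard error is sqrt(1 / sum w_i*), and the
95% CI uses the normal quantile 1.96. A group effect is called significant
when the CI excludes zero.

tau2 is estimated by REML (Fisher scoring, the default) or by the
DerSimonian-Laird method-of-moments closed form, both truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .effects import percent_change

Z95 = 1.959963984540054  # standard normal 97.5% quantile

POOLED_COLUMNS = [
    "treatment", "variable", "grouping", "group", "k",
    "mean", "se", "ci_low", "ci_high", "tau2", "method", "percent", "direction",
]


def estimate_tau2_dl(effects, variances) -> float:
    """DerSimonian-Laird between-study variance, truncated at zero.

    tau2 = max(0, (Q - (k-1)) / C) with Q the fixed-effect weighted sum of
    squares, C = sum(w) - sum(w^2)/sum(w) and w = 1/v. Requires k >= 2.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.size < 2:
        raise ValueError("DerSimonian-Laird estimation requires k >= 2 effects")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu_fe) ** 2)
    c = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    return max(0.0, (q - (y.size - 1)) / c)


def _restricted_nll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Negative restricted log-likelihood of tau2 (constants dropped)."""
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                  + np.sum(w * (y - mu) ** 2))


def estimate_tau2_reml(effects, variances, tol: float = 1e-8,
                       maxiter: int = 100) -> float:
    """REML between-study variance via Fisher scoring, truncated at zero.

    Scoring uses the restricted score and expected information of tau2;
    if the iteration fails to converge the restricted likelihood is
    maximized directly by bounded scalar search.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.size < 2:
        raise ValueError("REML estimation requires k >= 2 effects")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")

    tau2 = max(estimate_tau2_dl(y, v), 1e-6)
    converged = False
    for _ in range(maxiter):
        w = 1.0 / (v + tau2)
        sw, sw2, sw3 = np.sum(w), np.sum(w ** 2), np.sum(w ** 3)
        mu = np.sum(w * y) / sw
        r2 = (y - mu) ** 2
        score = -0.5 * sw + 0.5 * sw2 / sw + 0.5 * np.sum(w ** 2 * r2)
        info = 0.5 * sw2 - sw3 / sw + 0.5 * (sw2 / sw) ** 2
        if info <= 0:
            break
        new = tau2 + score / info
        if new < 0.0:
            new = tau2 / 2.0 if score < 0 else 0.0
        if abs(new - tau2) < tol * (1.0 + tau2):
            tau2 = new
            converged = True
            break
        tau2 = new
    if not converged:
        hi = max(10.0 * float(np.var(y)), 10.0 * float(np.max(v)), 1.0)
        res = minimize_scalar(_restricted_nll, bounds=(0.0, hi), args=(y, v),
                              method="bounded",
                              options={"xatol": 1e-12})
        tau2 = float(res.x)
    # accept the boundary when it beats the interior stationary point
    if _restricted_nll(0.0, y, v) <= _restricted_nll(tau2, y, v):
        tau2 = 0.0
    return max(0.0, float(tau2))


def classify_direction(mean: float, ci_low: float, ci_high: float) -> str:
    """Direction/significance label from the CI-excludes-zero rule.

    ``positive_sig`` / ``negative_sig`` when the 95% CI excludes zero,
    otherwise ``positive_ns`` / ``negative_ns`` by the sign of the mean
    (an exactly-zero mean counts as positive_ns by tie-break).
    """
    if ci_low > 0:
        return "positive_sig"
    if ci_high < 0:
        return "negative_sig"
    return "positive_ns" if mean >= 0 else "negative_ns"


@dataclass
class PooledEffect:
    """Random-effects summary for one driver x variable x group cell."""
    k: int
    mean: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    method: str
    percent: float
    direction: str


class RandomEffectsMeta(BaseEstimator):
    """Random-effects meta-analysis of effect sizes with known variances.

    Parameters
    ----------
    method : {"REML", "DL"}, default "REML"
        Between-study variance estimator. REML uses Fisher scoring
        (tolerance 1e-8, at most 100 iterations, truncated at zero); DL is
        the DerSimonian-Laird closed form.

    Attributes (after ``fit``)
    --------------------------
    mean_, se_, ci_low_, ci_high_, tau2_, k_, direction_, percent_
    """

    def __init__(self, method: str = "REML"):
        self.method = method

    def fit(self, y, v):
        y = np.asarray(y, dtype=float).ravel()
        v = np.asarray(v, dtype=float).ravel()
        if y.size == 0:
            raise ValueError("cannot pool an empty set of effects")
        if y.size != v.size:
            raise ValueError("effects and variances differ in length")
        if self.method not in ("REML", "DL"):
            raise ValueError(f"unknown pooling method {self.method!r}")
        if y.size == 1:
            tau2 = 0.0
            self.mean_ = float(y[0])
            self.se_ = float(np.sqrt(v[0]))
        else:
            if self.method == "DL":
                tau2 = estimate_tau2_dl(y, v)
            else:
                tau2 = estimate_tau2_reml(y, v)
            w = 1.0 / (v + tau2)
            self.mean_ = float(np.sum(w * y) / np.sum(w))
            self.se_ = float(np.sqrt(1.0 / np.sum(w)))
        self.tau2_ = float(tau2)
        self.k_ = int(y.size)
        self.ci_low_ = self.mean_ - Z95 * self.se_
        self.ci_high_ = self.mean_ + Z95 * self.se_
        self.direction_ = classify_direction(self.mean_, self.ci_low_,
                                             self.ci_high_)
        self.percent_ = percent_change(self.mean_)
        return self

    def summary(self) -> PooledEffect:
        return PooledEffect(k=self.k_, mean=self.mean_, se=self.se_,
                            ci_low=self.ci_low_, ci_high=self.ci_high_,
                            tau2=self.tau2_, method=self.method,
                            percent=self.percent_, direction=self.direction_)


def pool_random_effects(effects, variances, method: str = "REML") -> PooledEffect:
    """Pool a vector of effects; thin wrapper over :class:`RandomEffectsMeta`."""
    return RandomEffectsMeta(method=method).fit(effects, variances).summary()


def pool_by_group(effects: pd.DataFrame, grouping: str = "overall",
                  method: str = "REML", min_k: int = 3,
                  log: list | None = None) -> pd.DataFrame:
    """Pool effects per (treatment, variable) cell, optionally split by group.

    ``grouping`` is ``"overall"`` or one of the label columns ``"ecosystem"``
    / ``"soil"``. Cells with fewer than ``min_k`` effects are skipped and
    recorded in ``log`` (a list the caller may pass in). The overall pooling
    has no floor so single-study cells still appear.
    """
    if grouping not in ("overall", "ecosystem", "soil"):
        raise ValueError(f"unknown grouping {grouping!r}")
    keys = ["treatment", "variable"]
    if grouping != "overall":
        keys = keys + [grouping]
    rows = []
    for key, sub in effects.groupby(keys, sort=True, observed=True):
        treatment, variable = key[0], key[1]
        group = key[2] if grouping != "overall" else "all"
        if grouping != "overall" and len(sub) < min_k:
            if log is not None:
                log.append({"event": "skipped_group", "grouping": grouping,
                            "treatment": treatment, "variable": variable,
                            "group": group, "k": int(len(sub)),
                            "min_k": min_k})
            continue
        pe = pool_random_effects(sub["lnrr"].to_numpy(),
                                 sub["var"].to_numpy(), method=method)
        rows.append({"treatment": treatment, "variable": variable,
                     "grouping": grouping, "group": group, "k": pe.k,
                     "mean": pe.mean, "se": pe.se, "ci_low": pe.ci_low,
                     "ci_high": pe.ci_high, "tau2": pe.tau2,
                     "method": pe.method, "percent": pe.percent,
                     "direction": pe.direction})
    return pd.DataFrame(rows, columns=POOLED_COLUMNS)
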