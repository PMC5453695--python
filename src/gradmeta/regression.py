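"""Cross-study regression suite.

Three pieces:

* five-family curve fitting (linear, quadratic, logarithmic ``a + b ln x``,
  power ``a x^b``, exponential ``a e^(bx)``) with best-model selection
  among significant fits by maximum R^2;
* an all-subsets multiple-regression R^2 grid over the explanatory terms
  T (MAT), P (MAP), A (aridity), S (soil class, dummy-coded) and
  E (ecosystem, dummy-coded) — up to all 31 non-empty letter combinations;
* backward stepwise elimination on the full model using AIC, where two
  candidate models are declared distinct only when they differ by more
  than 2 AIC units, otherwise the smaller model is preferred.

R^2 is always computed on the original response scale as 1 - SSres/SStot.
AIC uses the Gaussian-likelihood form n*ln(SSres/n) + 2k, with k counting
the regression coefficients plus the error variance, so models fit to the
same response are directly comparable. p-values come from the overall
F-test against the intercept-only model (for power and exponential, the
F-test of the log-linearized form) and are not multiplicity-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

FAMILIES = ("linear", "quadratic", "logarithmic", "power", "exponential")

#: letter code -> column, with S/E categorical
TERM_COLUMNS = {"T": "mat", "P": "map", "A": "aridity",
                "S": "soil", "E": "ecosystem"}
CATEGORICAL_TERMS = ("S", "E")


@dataclass
class ModelFit:
    """One fitted curve family (or OLS model) and its fit statistics."""
    family: str
    params: tuple = ()
    r2: float = np.nan
    p: float = np.nan
    aic: float = np.nan
    n: int = 0
    applicable: bool = True
    message: str = ""


def gaussian_aic(ss_res: float, n: int, n_coef: int) -> float:
    """AIC = n ln(SSres/n) + 2k with k = n_coef + 1 (error variance)."""
    ss_res = max(float(ss_res), 1e-300)
    return n * np.log(ss_res / n) + 2 * (n_coef + 1)


def _f_test(ss_res: float, ss_tot: float, n: int, n_coef: int) -> float:
    """Overall model F-test p-value against the intercept-only model."""
    df_model = n_coef - 1
    df_res = n - n_coef
    if df_model <= 0 or df_res <= 0:
        return np.nan
    if ss_tot <= 0:
        return np.nan
    num = max(ss_tot - ss_res, 0.0) / df_model
    den = ss_res / df_res
    if den == 0.0:
        return 0.0
    return float(stats.f.sf(num / den, df_model, df_res))


def _ols(X: np.ndarray, y: np.ndarray):
    """Least-squares fit with intercept column prepended; returns
    (coefs, ss_res, rank)."""
    n = y.size
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    coefs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coefs
    return coefs, float(resid @ resid), rank, design.shape[1]


class CurveModel(BaseEstimator):
    """A single curve family ``y = f(x; params)`` fitted by least squares.

    Nonlinear families (power, exponential) use Levenberg-Marquardt with
    initial values from the log-linearized fit; the logarithmic family is
    linear in ``ln x``. Domain violations (x <= 0 for logarithmic/power,
    y <= 0 for power/exponential) mark the fit inapplicable rather than
    raising, so selection can proceed over the applicable set.
    """

    def __init__(self, family: str = "linear", maxfev: int = 500,
                 ftol: float = 1e-10):
        self.family = family
        self.maxfev = maxfev
        self.ftol = ftol

    def fit(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        fam = self.family
        if fam not in FAMILIES:
            raise ValueError(f"unknown family {fam!r}")
        n = x.size
        n_coef = 3 if fam == "quadratic" else 2
        self.fit_ = ModelFit(family=fam, n=n)
        if n < n_coef + 2:
            return self._inapplicable(f"need n >= {n_coef + 2}")
        if fam in ("logarithmic", "power") and np.any(x <= 0):
            return self._inapplicable("requires all x > 0")
        if fam in ("power", "exponential") and np.any(y <= 0):
            return self._inapplicable("requires all y > 0")
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        try:
            params, ss_res, p = self._fit_family(x, y, fam)
        except (RuntimeError, np.linalg.LinAlgError) as err:
            return self._inapplicable(f"no convergence: {err}")
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        self.fit_ = ModelFit(family=fam, params=tuple(float(v) for v in params),
                             r2=float(np.clip(r2, 0.0, 1.0)), p=p,
                             aic=gaussian_aic(ss_res, n, n_coef), n=n)
        return self

    def _inapplicable(self, why: str):
        self.fit_.applicable = False
        self.fit_.message = why
        return self

    def _fit_family(self, x, y, fam):
        n = x.size
        if fam == "linear":
            coefs, ss_res, _, ncol = _ols(x[:, None], y)
            return coefs, ss_res, _f_test(ss_res, np.sum((y - y.mean()) ** 2),
                                          n, ncol)
        if fam == "quadratic":
            coefs, ss_res, _, ncol = _ols(np.column_stack([x, x ** 2]), y)
            return coefs, ss_res, _f_test(ss_res, np.sum((y - y.mean()) ** 2),
                                          n, ncol)
        if fam == "logarithmic":
            coefs, ss_res, _, ncol = _ols(np.log(x)[:, None], y)
            return coefs, ss_res, _f_test(ss_res, np.sum((y - y.mean()) ** 2),
                                          n, ncol)
        if fam == "power":
            b0, _, _, _ = _ols(np.log(x)[:, None], np.log(y))
            p0 = (np.exp(b0[0]), b0[1])
            params, _ = curve_fit(lambda t, a, b: a * np.power(t, b), x, y,
                                  p0=p0, maxfev=self.maxfev, ftol=self.ftol,
                                  method="lm")
            resid = y - params[0] * np.power(x, params[1])
            # p-value from the log-linearized form
            ly = np.log(y)
            _, ssr_log, _, ncol = _ols(np.log(x)[:, None], ly)
            p = _f_test(ssr_log, np.sum((ly - ly.mean()) ** 2), n, ncol)
            return params, float(resid @ resid), p
        # exponential
        b0, _, _, _ = _ols(x[:, None], np.log(y))
        p0 = (np.exp(b0[0]), b0[1])
        params, _ = curve_fit(lambda t, a, b: a * np.exp(b * t), x, y,
                              p0=p0, maxfev=self.maxfev, ftol=self.ftol,
                              method="lm")
        resid = y - params[0] * np.exp(params[1] * x)
        ly = np.log(y)
        _, ssr_log, _, ncol = _ols(x[:, None], ly)
        p = _f_test(ssr_log, np.sum((ly - ly.mean()) ** 2), n, ncol)
        return params, float(resid @ resid), p

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        a, b, *rest = self.fit_.params + (0.0,) * 3
        return {"linear": a + b * x,
                "quadratic": a + b * x + rest[0] * x ** 2,
                "logarithmic": a + b * np.log(x),
                "power": a * np.power(x, b),
                "exponential": a * np.exp(b * x)}[self.family]


def fit_family(x, y, family: str) -> ModelFit:
    """Fit one family; returns a :class:`ModelFit` (possibly inapplicable)."""
    return CurveModel(family=family).fit(x, y).fit_


class BestCurveSelector(BaseEstimator):
    """Fit all five families and keep the best significant one.

    Among applicable families with p < ``alpha`` the maximum-R^2 fit wins;
    exact R^2 ties are broken by fewer parameters, then by canonical family
    order. ``best_`` is None when no family is significant.
    """

    def __init__(self, alpha: float = 0.05, tie_tol: float = 1e-10):
        self.alpha = alpha
        self.tie_tol = tie_tol

    def fit(self, x, y):
        self.fits_ = {fam: fit_family(x, y, fam) for fam in FAMILIES}
        candidates = [f for f in self.fits_.values()
                      if f.applicable and np.isfinite(f.p) and f.p < self.alpha]
        self.best_ = None
        self.tie_note_ = ""
        if candidates:
            best_r2 = max(f.r2 for f in candidates)
            tied = [f for f in candidates if best_r2 - f.r2 <= self.tie_tol]
            if len(tied) > 1:
                tied.sort(key=lambda f: (len(f.params), FAMILIES.index(f.family)))
                self.tie_note_ = ("tie broken by parameter count / family "
                                  f"order among {[f.family for f in tied]}")
            self.best_ = tied[0]
        return self


def select_best_model(x, y, alpha: float = 0.05) -> ModelFit | None:
    """Best significant curve family by max R^2, or None."""
    return BestCurveSelector(alpha=alpha).fit(x, y).best_


def _design_for_terms(sites: pd.DataFrame, terms: str) -> np.ndarray:
    """Numeric design matrix (no intercept) for a letter combination."""
    blocks = []
    for letter in terms:
        col = TERM_COLUMNS[letter]
        if letter in CATEGORICAL_TERMS:
            dummies = pd.get_dummies(sites[col].astype(str), drop_first=True)
            blocks.append(dummies.to_numpy(dtype=float))
        else:
            blocks.append(sites[col].to_numpy(dtype=float)[:, None])
    return np.hstack(blocks) if blocks else np.empty((len(sites), 0))


def r2_grid(sites: pd.DataFrame, response: str = "value",
            predictors: str = "TPASE") -> pd.DataFrame:
    """OLS R^2 and overall F-test p for every non-empty predictor subset.

    ``predictors`` is a string of letters from TPASE; all non-empty subsets
    (31 for the full set) are fitted, each encoded in the output in the
    canonical letter order. Collinear (rank-deficient) designs use the
    minimum-norm least-squares fit with rank-based degrees of freedom and
    are marked ``ok = False``; a design whose rank exhausts the sample is
    given NaN statistics.
    """
    letters = [c for c in "TPASE" if c in predictors.upper()]
    if not letters:
        raise ValueError("need at least one predictor letter from TPASE")
    y = sites[response].to_numpy(dtype=float)
    n = y.size
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rows = []
    for size in range(1, len(letters) + 1):
        for combo in combinations(letters, size):
            terms = "".join(combo)
            X = _design_for_terms(sites, terms)
            coefs, ss_res, rank, ncol = _ols(X, y)
            fittable = n > rank and ss_tot > 0
            r2 = 1.0 - ss_res / ss_tot if fittable else np.nan
            rows.append({"response": response, "predictor_set": terms,
                         "r2": r2,
                         "p": _f_test(ss_res, ss_tot, n, rank) if fittable
                         else np.nan,
                         "n": n, "ok": bool(rank == ncol and fittable)})
    return pd.DataFrame(rows)


class BackwardStepwiseOLS(BaseEstimator):
    """Backward stepwise term elimination by AIC with a 2-unit rule.

    Starting from the full term set, each step removes the term whose
    removal yields the lowest AIC, when that either strictly improves the
    AIC or stays within 2 AIC units of the best model seen so far (models
    closer than 2 units are not considered distinct, so the smaller one is
    preferred; such drops are recorded in ``steps_``). The returned model's
    AIC therefore never exceeds the full model's AIC by more than 2.
    """

    def __init__(self, full_set: str = "TPASE", aic_rule: float = 2.0):
        self.full_set = full_set
        self.aic_rule = aic_rule

    def fit(self, sites: pd.DataFrame, response: str = "value"):
        y = sites[response].to_numpy(dtype=float)
        n = y.size

        def model_aic(terms: tuple) -> float:
            X = _design_for_terms(sites, "".join(terms))
            _, ss_res, rank, ncol = _ols(X, y)
            if rank < ncol:
                return np.inf
            return gaussian_aic(ss_res, n, ncol)

        current = tuple(c for c in "TPASE" if c in self.full_set.upper())
        current_aic = model_aic(current)
        best_seen = current_aic
        self.steps_ = [{"terms": "".join(current), "aic": current_aic,
                        "action": "full"}]
        while current:
            drops = [(model_aic(tuple(t for t in current if t != term)), term)
                     for term in current]
            cand_aic, cand_term = min(drops)
            if cand_aic < current_aic:
                action = "drop_improves"
            elif cand_aic <= best_seen + self.aic_rule:
                action = "drop_parsimony"
            else:
                break
            current = tuple(t for t in current if t != cand_term)
            current_aic = cand_aic
            best_seen = min(best_seen, cand_aic)
            self.steps_.append({"terms": "".join(current), "aic": cand_aic,
                                "action": action, "dropped": cand_term})
        self.terms_ = "".join(current)
        self.aic_ = float(current_aic)
        X = _design_for_terms(sites, self.terms_)
        coefs, ss_res, _, ncol = _ols(X, y)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.model_ = ModelFit(
            family="ols:" + (self.terms_ or "intercept"),
            params=tuple(float(c) for c in coefs),
            r2=float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0,
            p=_f_test(ss_res, ss_tot, n, ncol), aic=self.aic_, n=n)
        return self


def backward_stepwise(sites: pd.DataFrame, response: str = "value",
                      full_set: str = "TPASE") -> ModelFit:
    """Backward stepwise elimination; returns the final model's fit."""
    return BackwardStepwiseOLS(full_set=full_set).fit(sites, response).model_
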