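"""Experimental-vs-observational direction contrast and sensitivity checks.

The headline comparison pairs each experimental driver with the matching
observational covariate — water addition with MAP, drought with aridity,
warming with MAT — and compares only the *directions* of the two tracks'
effects (magnitudes across designs are not statistically comparable).
A pair is *contrasting* when both effects are significant with opposite
signs, *consistent* when both are significant with the same sign, and
*indeterminate* otherwise. Because aridity increases with dryness, and the
drought lnRR treats drier as the treatment, signs are compared directly on
every pair, with no flip.

Non-independence of multiple records per study is probed by re-running the
pooling on a *reduced database* with one randomly selected record per
study; the full and reduced summaries are compared through overlap of the
bias-corrected 95% bootstrap CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DRIVER_PAIRS

CONTRAST_COLUMNS = ["treatment", "covariate", "variable",
                    "exp_direction", "obs_direction", "classification"]
SENSITIVITY_COLUMNS = ["treatment", "variable", "full_mean", "full_lo",
                       "full_hi", "reduced_mean", "reduced_lo", "reduced_hi",
                       "overlap", "n_full", "n_reduced"]

_SIGN = {"positive_sig": +1, "negative_sig": -1,
         "positive_ns": 0, "negative_ns": 0}


@dataclass
class ContrastResult:
    treatment: str
    covariate: str
    variable: str
    exp_direction: str
    obs_direction: str
    classification: str


def classify_pair(exp_direction: str, obs_direction: str) -> str:
    """Three-way classification from two direction labels."""
    se, so = _SIGN[exp_direction], _SIGN[obs_direction]
    if se != 0 and so != 0:
        return "consistent" if se == so else "contrasting"
    return "indeterminate"


def compare_directions(exp, obs) -> ContrastResult:
    """Contrast one pooled experimental effect with one grand slope.

    ``exp`` needs attributes/keys treatment, variable, direction; ``obs``
    needs covariate, variable, direction. The (treatment, covariate) pair
    must be one of the three driver pairings and the variables must match.
    """
    def get(o, k):
        return o[k] if isinstance(o, (dict, pd.Series)) else getattr(o, k)

    treatment, covariate = get(exp, "treatment"), get(obs, "covariate")
    if DRIVER_PAIRS.get(treatment) != covariate:
        raise ValueError(
            f"invalid driver pair: {treatment!r} vs {covariate!r}")
    if get(exp, "variable") != get(obs, "variable"):
        raise ValueError(
            f"variable mismatch: {get(exp, 'variable')!r} vs "
            f"{get(obs, 'variable')!r}")
    e_dir, o_dir = get(exp, "direction"), get(obs, "direction")
    return ContrastResult(treatment=treatment, covariate=covariate,
                          variable=get(exp, "variable"),
                          exp_direction=e_dir, obs_direction=o_dir,
                          classification=classify_pair(e_dir, o_dir))


def contrast_table(pooled: pd.DataFrame, grand: pd.DataFrame) -> pd.DataFrame:
    """All driver-pair contrasts available in the two summary tables."""
    rows = []
    overall = pooled[pooled["grouping"] == "overall"] \
        if "grouping" in pooled.columns else pooled
    for _, exp in overall.iterrows():
        cov = DRIVER_PAIRS.get(exp["treatment"])
        match = grand[(grand["covariate"] == cov)
                      & (grand["variable"] == exp["variable"])]
        if cov is None or match.empty:
            continue
        res = compare_directions(exp, match.iloc[0])
        rows.append(vars(res))
    return pd.DataFrame(rows, columns=CONTRAST_COLUMNS)


def reduce_database(effects: pd.DataFrame, seed: int) -> pd.DataFrame:
    """One uniformly random record per study (seeded, deterministic).

    Output has exactly one row per distinct ``study_id``; applying the
    reduction to an already-reduced table returns it unchanged (up to row
    order, which follows sorted study ids).
    """
    if len(effects) == 0:
        raise ValueError("cannot reduce an empty effects table")
    rng = np.random.default_rng(seed)
    picks = []
    for _, sub in effects.groupby("study_id", sort=True, observed=True):
        picks.append(sub.index[rng.integers(len(sub))])
    return effects.loc[picks]


def bias_corrected_bootstrap_ci(values, n_boot: int = 1999,
                                seed: int | None = None,
                                level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected (BC, not BCa) percentile bootstrap CI for the mean.

    z0 is the normal quantile of the fraction of bootstrap means below the
    observed mean; the interval takes the bootstrap percentiles
    Phi(2 z0 +/- z_alpha). Constant input yields a zero-width interval.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 5:
        raise ValueError("need >= 5 values for a bootstrap CI")
    if n_boot < 999:
        raise ValueError("n_boot must be >= 999")
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    if np.ptp(x) == 0:
        return float(x[0]), float(x[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot = x[idx].mean(axis=1)
    obs = x.mean()
    frac = np.mean(boot < obs)
    frac = min(max(frac, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = stats.norm.ppf(frac)
    za = stats.norm.ppf(0.5 + level / 2)
    lo_q = stats.norm.cdf(2 * z0 - za)
    hi_q = stats.norm.cdf(2 * z0 + za)
    lo, hi = np.quantile(boot, [lo_q, hi_q])
    return float(lo), float(hi)


@dataclass
class SensitivityReport:
    """Full-vs-reduced database comparison for one pooled cell."""
    full_mean: float
    full_lo: float
    full_hi: float
    reduced_mean: float
    reduced_lo: float
    reduced_hi: float
    overlap: bool
    n_full: int
    n_reduced: int


def sensitivity_check(full, reduced_values, n_boot: int = 1999,
                      seed: int | None = None) -> SensitivityReport:
    """Compare a full-database pooled effect with the reduced database.

    ``full`` is a PooledEffect-like object (mean, ci_low, ci_high, k);
    ``reduced_values`` the reduced database's effect sizes, summarized by
    their mean and BC bootstrap CI. ``overlap`` is True when the two
    intervals intersect.
    """
    def get(o, k):
        return o[k] if isinstance(o, (dict, pd.Series)) else getattr(o, k)

    vals = np.asarray(reduced_values, dtype=float).ravel()
    lo, hi = bias_corrected_bootstrap_ci(vals, n_boot=n_boot, seed=seed)
    f_lo, f_hi = float(get(full, "ci_low")), float(get(full, "ci_high"))
    overlap = (lo <= f_hi) and (f_lo <= hi)
    return SensitivityReport(full_mean=float(get(full, "mean")),
                             full_lo=f_lo, full_hi=f_hi,
                             reduced_mean=float(vals.mean()),
                             reduced_lo=lo, reduced_hi=hi,
                             overlap=bool(overlap),
                             n_full=int(get(full, "k")),
                             n_reduced=int(vals.size))
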