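"""Log response ratio effect sizes for manipulative experiments.

The effect size is the natural-log response ratio

    lnRR = ln(x_e / x_c) = ln x_e - ln x_c

with sampling variance

    v = (1/n_e) (s_e/x_e)^2 + (1/n_c) (s_c/x_c)^2

where (x, s, n) are the group mean, SD and sample size of the treatment (e)
and control (c) groups. Both quantities are dimensionless and invariant to
a common rescaling of the measurement units. Pooled log-ratios are reported
to readers as percent change via the exact back-transform
(exp(lnRR) - 1) * 100.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EFFECT_COLUMNS = [
    "study_id", "record_id", "treatment", "variable",
    "lnrr", "var", "mat", "map", "ecosystem", "soil",
]


def log_response_ratio(x_e, x_c):
    """ln(x_e / x_c); antisymmetric under swapping treatment and control."""
    x_e = np.asarray(x_e, dtype=float)
    x_c = np.asarray(x_c, dtype=float)
    if np.any(x_e <= 0) or np.any(x_c <= 0):
        raise ValueError("log response ratio requires positive group means")
    out = np.log(x_e) - np.log(x_c)
    return float(out) if out.ndim == 0 else out


def lnrr_sampling_variance(s_e, x_e, n_e, s_c, x_c, n_c):
    """Sampling variance of lnRR: (1/n_e)(s_e/x_e)^2 + (1/n_c)(s_c/x_c)^2.

    Strictly decreasing in both sample sizes; zero iff both SDs are zero.
    """
    s_e, x_e, s_c, x_c = (np.asarray(a, dtype=float) for a in (s_e, x_e, s_c, x_c))
    n_e = np.asarray(n_e, dtype=float)
    n_c = np.asarray(n_c, dtype=float)
    if np.any(x_e <= 0) or np.any(x_c <= 0):
        raise ValueError("group means must be positive")
    if np.any(s_e < 0) or np.any(s_c < 0):
        raise ValueError("group SDs must be non-negative")
    if np.any(n_e < 2) or np.any(n_c < 2):
        raise ValueError("group sizes must be >= 2")
    out = (s_e / x_e) ** 2 / n_e + (s_c / x_c) ** 2 / n_c
    return float(out) if out.ndim == 0 else out


def percent_change(lnrr):
    """Exact back-transform of a log response ratio: (exp(lnrr) - 1) * 100."""
    out = (np.exp(np.asarray(lnrr, dtype=float)) - 1.0) * 100.0
    return float(out) if out.ndim == 0 else out


def effects_from_records(records: pd.DataFrame) -> pd.DataFrame:
    """One effect size per experimental record, site metadata carried through.

    Input must be a validated experimental table; the result has columns
    ``EFFECT_COLUMNS`` and the same row order.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=EFFECT_COLUMNS)
    out = records[["study_id", "record_id", "treatment", "variable"]].copy()
    try:
        out["lnrr"] = log_response_ratio(records["x_e"].to_numpy(),
                                         records["x_c"].to_numpy())
        out["var"] = lnrr_sampling_variance(
            records["s_e"].to_numpy(), records["x_e"].to_numpy(),
            records["n_e"].to_numpy(), records["s_c"].to_numpy(),
            records["x_c"].to_numpy(), records["n_c"].to_numpy(),
        )
    except ValueError as err:
        # recompute row-wise to name the offender
        for _, row in records.iterrows():
            try:
                log_response_ratio(row["x_e"], row["x_c"])
                lnrr_sampling_variance(row["s_e"], row["x_e"], row["n_e"],
                                       row["s_c"], row["x_c"], row["n_c"])
            except ValueError as row_err:
                raise ValueError(
                    f"record ({row['study_id']}, {row['record_id']}): {row_err}"
                ) from err
        raise
    for col in ("mat", "map", "ecosystem", "soil"):
        out[col] = records[col].to_numpy()
    return out[EFFECT_COLUMNS]
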