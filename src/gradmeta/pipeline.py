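"""End-to-end orchestration: simulate or load, compute, compare, report.

``run_pipeline`` executes the full two-track synthesis in order — I/O and
climate derivation, effect sizes, random-effects pooling, gradient slope
synthesis, the regression suite, and the direction contrast plus reduced-
database sensitivity check — and returns (and optionally writes) the six
result tables together with a structured run log. All stochastic steps
draw from substreams of the single configured seed, so a rerun with the
same config is bit-identical.
"""

from __future__ import annotations

import difflib
import json
import platform
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (read_experimental, read_observational, derive_aridity,
                 write_experimental, write_observational)
from .effects import effects_from_records
from .meta import pool_by_group
from .gradients import fit_all_slopes, grand_slopes_table
from .regression import select_best_model, r2_grid, backward_stepwise
from .contrast import (contrast_table, reduce_database, sensitivity_check,
                       SENSITIVITY_COLUMNS)
from .simulate import (ExperimentalSimConfig, ObservationalSimConfig,
                       generate_experimental, generate_observational,
                       _jsonable)


class PipelineConfigError(ValueError):
    """The run configuration is invalid."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""
    mode: str = "analyze"
    experimental_csv: str | None = None
    observational_csv: str | None = None
    sim_experimental: dict = field(default_factory=dict)
    sim_observational: dict = field(default_factory=dict)
    method: str = "REML"
    n_boot: int = 1000
    min_k: int = 3
    seed: int | None = None
    out_dir: str | None = None


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected.

    Defaults (method REML, n_boot 1000, min_k 3) are applied; a seed is
    mandatory whenever any stochastic step is enabled (simulation or a
    positive bootstrap count).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise PipelineConfigError("run config must be a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f" — did you mean {hint[0]!r}?" if hint else ""
            raise PipelineConfigError(f"unknown config key {key!r}{suffix}")
    cfg = RunConfig(**raw)
    if cfg.mode not in ("simulate", "analyze"):
        raise PipelineConfigError(f"unknown mode {cfg.mode!r}")
    if cfg.method not in ("REML", "DL"):
        raise PipelineConfigError(f"unknown pooling method {cfg.method!r}")
    stochastic = cfg.mode == "simulate" or cfg.n_boot > 0
    if stochastic and cfg.seed is None:
        raise PipelineConfigError(
            "a seed is required: the run includes stochastic steps "
            "(simulation or bootstrap)")
    if cfg.mode == "analyze" and not cfg.sim_experimental \
            and cfg.experimental_csv is None:
        raise PipelineConfigError(
            "analyze mode needs experimental_csv (and observational_csv) "
            "or sim_* sections")
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


@dataclass
class ResultBundle:
    """All pipeline outputs of one run."""
    effects: pd.DataFrame
    pooled: pd.DataFrame
    slopes: pd.DataFrame
    grand_slopes: pd.DataFrame
    r2: pd.DataFrame
    model_fits: pd.DataFrame
    contrasts: pd.DataFrame
    sensitivity: pd.DataFrame
    log: list

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.effects.to_csv(out / "effects.csv", index=False)
        self.pooled.to_csv(out / "pooled_effects.csv", index=False)
        self.slopes.to_csv(out / "slopes.csv", index=False)
        self.grand_slopes.to_csv(out / "grand_slopes.csv", index=False)
        self.r2.to_csv(out / "r2_grid.csv", index=False)
        self.model_fits.to_csv(out / "model_fits.csv", index=False)
        self.contrasts.to_csv(out / "contrasts.csv", index=False)
        self.sensitivity.to_csv(out / "sensitivity.csv", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(_jsonable(self.log), fh, indent=1)


def _curve_fit_rows(x, y, response, covariate, n_min=8):
    fit = select_best_model(np.asarray(x), np.asarray(y)) \
        if len(x) >= n_min else None
    if fit is None:
        return [{"response": response, "covariate": covariate,
                 "family": "none", "params": "", "r2": np.nan, "p": np.nan,
                 "aic": np.nan, "n": len(x)}]
    return [{"response": response, "covariate": covariate,
             "family": fit.family,
             "params": ";".join(f"{v:.6g}" for v in fit.params),
             "r2": fit.r2, "p": fit.p, "aic": fit.aic, "n": fit.n}]


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the full two-track synthesis under one validated config."""
    log: list = [{"event": "start", "gradmeta": __version__,
                  "python": platform.python_version(),
                  "numpy": np.__version__, "pandas": pd.__version__,
                  "seed": config.seed, "method": config.method,
                  "n_boot": config.n_boot, "min_k": config.min_k}]
    ss = np.random.SeedSequence(config.seed if config.seed is not None else 0)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]

    stage = "data_model_io"
    try:
        if config.mode == "simulate" or config.sim_experimental:
            exp_cfg = ExperimentalSimConfig(
                **{**config.sim_experimental, "seed": sub[0]})
            obs_cfg = ObservationalSimConfig(
                **{**config.sim_observational, "seed": sub[1]})
            records, exp_truth = generate_experimental(exp_cfg)
            sites, obs_truth = generate_observational(obs_cfg)
            log.append({"event": "simulated",
                        "n_records": len(records), "n_sites": len(sites)})
        else:
            records = read_experimental(config.experimental_csv)
            sites = read_observational(config.observational_csv)
            exp_truth = obs_truth = None
        sites = derive_aridity(sites)
        log.append({"event": "climate_derived",
                    "ai_max": sites.attrs.get("ai_max")})

        stage = "effect_sizes"
        effects = effects_from_records(records)
        log.append({"event": "effects", "n": len(effects)})

        stage = "meta_pooling"
        pooled = pd.concat(
            [pool_by_group(effects, g, method=config.method,
                           min_k=config.min_k, log=log)
             for g in ("overall", "ecosystem", "soil")],
            ignore_index=True)
        log.append({"event": "pooled", "n": len(pooled)})

        stage = "gradient_synthesis"
        slopes = fit_all_slopes(sites, log=log)
        grand = grand_slopes_table(slopes, n_boot=config.n_boot,
                                   seed=sub[2], log=log)
        log.append({"event": "grand_slopes", "n": len(grand)})

        stage = "regression_models"
        fit_rows, r2_rows = [], []
        for (t, v), sub_eff in effects.groupby(["treatment", "variable"],
                                               observed=True):
            for cov in ("map", "mat"):
                fit_rows += _curve_fit_rows(sub_eff[cov], sub_eff["lnrr"],
                                            f"lnrr:{t}:{v}", cov)
        for v, sub_sites in sites.groupby("variable", observed=True):
            for cov in ("map", "mat", "aridity"):
                fit_rows += _curve_fit_rows(sub_sites[cov],
                                            sub_sites["value"], v, cov)
            grid = r2_grid(sub_sites, response="value", predictors="TPASE")
            grid.insert(0, "variable", v)
            r2_rows.append(grid)
            step = backward_stepwise(sub_sites, response="value",
                                     full_set="TPASE")
            fit_rows.append({"response": v, "covariate": "TPASE",
                             "family": step.family,
                             "params": ";".join(f"{c:.6g}"
                                                for c in step.params),
                             "r2": step.r2, "p": step.p, "aic": step.aic,
                             "n": step.n})
        model_fits = pd.DataFrame(fit_rows)
        r2 = pd.concat(r2_rows, ignore_index=True) if r2_rows \
            else pd.DataFrame()

        stage = "contrast_sensitivity"
        contrasts = contrast_table(pooled, grand)
        sens_rows = []
        sens_ss = np.random.SeedSequence(sub[3])
        overall = pooled[pooled["grouping"] == "overall"]
        for _, row in overall.iterrows():
            sub_eff = effects[(effects["treatment"] == row["treatment"])
                              & (effects["variable"] == row["variable"])]
            n_studies = sub_eff["study_id"].nunique()
            if n_studies < 5:
                log.append({"event": "skipped_sensitivity",
                            "treatment": row["treatment"],
                            "variable": row["variable"],
                            "n_studies": int(n_studies)})
                continue
            s1, s2 = (int(s.generate_state(1)[0] % (2 ** 31))
                      for s in sens_ss.spawn(2))
            reduced = reduce_database(sub_eff, seed=s1)
            rep = sensitivity_check(row, reduced["lnrr"].to_numpy(),
                                    n_boot=max(1999, config.n_boot),
                                    seed=s2)
            sens_rows.append({"treatment": row["treatment"],
                              "variable": row["variable"],
                              "full_mean": rep.full_mean,
                              "full_lo": rep.full_lo,
                              "full_hi": rep.full_hi,
                              "reduced_mean": rep.reduced_mean,
                              "reduced_lo": rep.reduced_lo,
                              "reduced_hi": rep.reduced_hi,
                              "overlap": rep.overlap,
                              "n_full": rep.n_full,
                              "n_reduced": rep.n_reduced})
        sensitivity = pd.DataFrame(sens_rows, columns=SENSITIVITY_COLUMNS)
    except (ValueError, RuntimeError) as err:
        raise PipelineStageError(f"stage {stage!r} failed: {err}") from err

    for name, table in (("pooled_effects", pooled),
                        ("grand_slopes", grand),
                        ("contrasts", contrasts)):
        if len(table) == 0:
            log.append({"event": "empty_table", "table": name,
                        "note": "no qualifying groups"})

    bundle = ResultBundle(effects=effects, pooled=pooled, slopes=slopes,
                          grand_slopes=grand, r2=r2, model_fits=model_fits,
                          contrasts=contrasts, sensitivity=sensitivity,
                          log=log)
    if config.out_dir:
        bundle.write(config.out_dir)
        if config.mode == "simulate" or config.sim_experimental:
            out = Path(config.out_dir)
            write_experimental(records, out / "experimental.csv")
            write_observational(sites, out / "observational.csv")
            with open(out / "truth.json", "w") as fh:
                json.dump(_jsonable({"experimental": exp_truth,
                                     "observational": obs_truth}), fh,
                          indent=1)
    return bundle
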