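"""Reproducible pipeline: simulate → preprocess → measure → fit → loocv →
regress → report.

A run is fully determined by a :class:`RunConfig` (serializable, schema
checked) and its seed.  Every output file embeds the SHA-256 hash of the
canonical config (CSV files as a leading ``# config_hash=...`` comment
line, JSON files as a top-level key), so re-running with a changed config
changes every hash.  Stages communicate through files in the output
directory and are independently runnable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fit as hfit
from . import measures, regress
from .generate import GeneratorParams, simulate_cohort
from .models import MODEL_SPECS

__all__ = ["RunConfig", "validate_config", "run_pipeline",
           "simulate_stage", "measure_stage", "fit_stage", "loocv_stage",
           "regress_stage", "report_stage"]

_PLAN_KEYS = {"forced_fraction", "error_rate", "duration_s", "mid_split"}
_GEN_KEYS = {"model", "group_mean", "group_sd", "pep_deterioration_gain",
             "pep_gain_subject_sd", "hr_value_gain", "resp_leak_pep",
             "resp_leak_hr", "phys_noise_sd", "phys_ar1", "error_rate",
             "rho_init", "branch_on"}
_EM_KEYS = {"tol", "max_iter", "starts"}
_LOO_KEYS = {"inner_max_iter", "refit_per_fold"}


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 20
    plan: dict = field(default_factory=dict)
    generator: dict = field(default_factory=dict)
    models: list = field(default_factory=lambda: ["symmetric", "asymmetric"])
    em: dict = field(default_factory=lambda: {"tol": 1e-3, "max_iter": 200,
                                              "starts": 5})
    loocv: dict = field(default_factory=lambda: {"inner_max_iter": 6,
                                                 "refit_per_fold": True})
    outdir: str = "runs/default"

    def hash(self) -> str:
        """Hash of everything that determines the results (outdir excluded,
        so re-running the same analysis elsewhere reproduces byte-identical
        outputs)."""
        d = asdict(self)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def generator_params(self) -> GeneratorParams:
        kwargs = dict(self.generator)
        model = kwargs.pop("model", "asymmetric")
        return GeneratorParams(model=MODEL_SPECS[model], **kwargs)


def validate_config(raw) -> RunConfig:
    """Schema-check a raw config (dict or YAML text); fill defaults.

    Unknown keys, type mismatches and out-of-range values are rejected with
    the offending field named.
    """
    if isinstance(raw, str):
        import yaml

        raw = yaml.safe_load(raw) or {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    defaults = RunConfig()
    known = set(asdict(defaults))
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**{**asdict(defaults), **raw})
    if not isinstance(cfg.seed, int) or cfg.seed < 0 or cfg.seed >= 2 ** 31:
        raise ValueError("seed: must be an integer in [0, 2^31)")
    if not isinstance(cfg.n_subjects, int) or cfg.n_subjects < 1:
        raise ValueError("n_subjects: must be a positive integer")
    for key, allowed in (("plan", _PLAN_KEYS), ("generator", _GEN_KEYS),
                         ("em", _EM_KEYS), ("loocv", _LOO_KEYS)):
        block = getattr(cfg, key)
        if not isinstance(block, dict):
            raise ValueError(f"{key}: must be a mapping")
        bad = set(block) - allowed
        if bad:
            raise ValueError(f"{key}: unknown key(s) {sorted(bad)}")
    ff = cfg.plan.get("forced_fraction")
    if ff is not None and not 0.0 <= ff < 1.0:
        raise ValueError("plan.forced_fraction: must lie in [0, 1)")
    er = cfg.plan.get("error_rate")
    if er is not None and not 0.0 <= er < 1.0:
        raise ValueError("plan.error_rate: must lie in [0, 1)")
    if len(set(cfg.models)) != len(cfg.models):
        raise ValueError("models: duplicate model name")
    for m in cfg.models:
        if m not in MODEL_SPECS:
            raise ValueError(f"models: unknown model {m!r}")
    gm = cfg.generator.get("model")
    if gm is not None and gm not in MODEL_SPECS:
        raise ValueError(f"generator.model: unknown model {gm!r}")
    return cfg


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str):
    with open(path, "w") as f:
        f.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(f, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _write_json(obj: dict, path: Path, cfg_hash: str):
    obj = {"config_hash": cfg_hash, **obj}
    with open(path, "w") as f:
        json.dump(obj, f, indent=1, sort_keys=True, default=_jsonable)
    path.write_text(path.read_text() + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def simulate_stage(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    gen = cfg.generator_params()
    cohort, truth = simulate_cohort(cfg.n_subjects, gen, cfg.seed,
                                    plan_overrides=cfg.plan or None)
    _write_csv(cohort, outdir / "cohort.csv", cfg.hash())
    truth["pep_drive_signed"] = True
    _write_json(truth, outdir / "truth.json", cfg.hash())
    return cohort


def measure_stage(cfg: RunConfig, outdir: Path,
                  cohort: pd.DataFrame | None = None) -> pd.DataFrame:
    if cohort is None:
        cohort = _read_csv(outdir / "cohort.csv")
        truth = json.loads((outdir / "truth.json").read_text())
        cohort.attrs["pep_drive_signed"] = truth.get("pep_drive_signed", False)
    df = measures.preprocess_physiology(cohort)
    df = measures.add_objective_rates(df)
    _write_csv(df, outdir / "measures.csv", cfg.hash())
    split = cfg.plan.get("duration_s", 720.0) / 2.0
    _write_csv(measures.db_table(df, split_s=split),
               outdir / "db_metrics.csv", cfg.hash())
    return df


def fit_stage(cfg: RunConfig, outdir: Path,
              df: pd.DataFrame | None = None) -> dict:
    if df is None:
        df = _read_csv(outdir / "measures.csv")
    prepared = hfit.prepare_sessions(df)
    fits = {}
    for k, name in enumerate(cfg.models):
        spec = MODEL_SPECS[name]
        fr = hfit.em_fit(prepared, spec, seed=(cfg.seed * 1000 + k) % 2 ** 31,
                         **cfg.em)
        fits[name] = fr
        _write_json({
            "model": name, "iterations": fr.iterations,
            "converged": fr.converged, "rho0": fr.rho0,
            "summed_evidence": fr.summed_evidence,
            "group_mean": fr.prior.mean, "group_variance": fr.prior.variance,
            "param_names": list(spec.param_names),
            "evidence_trajectory": fr.evidence_trajectory,
            "seed": (cfg.seed * 1000 + k) % 2 ** 31,
        }, outdir / f"fit_{name}.json", cfg.hash())
        _write_csv(fr.params_table(), outdir / f"params_{name}.csv",
                   cfg.hash())
    return fits


def loocv_stage(cfg: RunConfig, outdir: Path, df: pd.DataFrame | None = None,
                fits: dict | None = None) -> dict:
    import warnings as _w

    if df is None:
        df = _read_csv(outdir / "measures.csv")
    prepared = hfit.prepare_sessions(df)
    if fits is None:
        fits = fit_stage(cfg, outdir, df)
    scores = {}
    rows = []
    for k, name in enumerate(cfg.models):
        sc = hfit.loocv(prepared, MODEL_SPECS[name],
                        seed=(cfg.seed * 1000 + 500 + k) % 2 ** 31,
                        full_fit=fits[name], **cfg.loocv)
        scores[name] = sc
        for sid, s in zip(sc.subject_ids, sc.scores):
            rows.append({"model": name, "subject_id": sid, "loocv": s})
    _write_csv(pd.DataFrame(rows), outdir / "loocv.csv", cfg.hash())
    comparisons = {}
    if len(cfg.models) < 2:
        _w.warn("fewer than two models: no comparison table", stacklevel=2)
    else:
        ref = cfg.models[0]
        for name in cfg.models[1:]:
            t, dfree, p = hfit.compare_models(scores[ref], scores[name])
            comparisons[f"{ref}_vs_{name}"] = {
                "t": t, "df": dfree, "p": p,
                "summed_" + ref: scores[ref].summed,
                "summed_" + name: scores[name].summed,
            }
        _write_json(comparisons, outdir / "model_comparison.json", cfg.hash())
    return scores


def regress_stage(cfg: RunConfig, outdir: Path,
                  df: pd.DataFrame | None = None) -> dict:
    if df is None:
        df = _read_csv(outdir / "measures.csv")
    out = {}
    out["choice_history"] = regress.jackknife_coefficients(
        regress.choice_history_model, df)
    out["phys_value"] = regress.jackknife_coefficients(
        lambda d: regress.phys_value_model(d, "combined_value"), df)
    for subset in ("all", "deterioration", "improvement"):
        out[f"mu_derivative_{subset}"] = regress.mu_derivative_model(df, subset)
    dbt = measures.db_table(df, split_s=cfg.plan.get("duration_s", 720.0) / 2.0)
    for window in ("early", "late"):
        out[f"db_optimality_{window}"] = regress.db_optimality_model(dbt, window)
    for name, res in out.items():
        tab = res.table[~res.table["term"].str.startswith("subj:")].copy()
        if res.jackknife is not None:
            tab = tab.merge(res.jackknife, on="term", how="left")
        tab["n_obs"] = res.n_obs
        _write_csv(tab, outdir / f"regression_{name}.csv", cfg.hash())
    return out


def report_stage(cfg: RunConfig, outdir: Path) -> dict:
    """Collect headline numbers from the stage outputs into summary.json."""
    summary: dict = {"n_subjects": cfg.n_subjects, "models": cfg.models}
    loo = outdir / "loocv.csv"
    if loo.exists():
        tab = _read_csv(loo)
        summary["loocv_summed"] = {
            m: float(s) for m, s in tab.groupby("model")["loocv"].sum().items()}
    comp = outdir / "model_comparison.json"
    if comp.exists():
        summary["model_comparison"] = json.loads(comp.read_text())
    dbm = outdir / "db_metrics.csv"
    if dbm.exists():
        tab = _read_csv(dbm)
        summary["db_mid_by_order"] = {
            o: float(v) for o, v in tab.groupby("order")["db_mid"].mean().items()}
    _write_json(summary, outdir / "summary.json", cfg.hash())
    return summary


def run_pipeline(config: RunConfig | dict | str) -> dict:
    """Run every stage; returns the summary dict.

    Writes cohort/measures/fit/LOOcv/regression/D−B tables plus
    ``summary.json`` and a ``run.log`` with per-stage wall times (the log is
    the only output that is not byte-reproducible across runs).
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    import numpy as _np
    import scipy as _sp

    from . import __version__

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash={cfg.hash()}", f"seed={cfg.seed}",
                 f"versions: foragerl={__version__} numpy={_np.__version__} "
                 f"scipy={_sp.__version__} pandas={pd.__version__}"]

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        res = fn(cfg, outdir, *args)
        log_lines.append(f"{name}: {time.perf_counter() - t0:.2f}s")
        return res

    cohort = timed("simulate", simulate_stage)
    df = timed("measure", measure_stage, cohort)
    fits = timed("fit", fit_stage, df)
    timed("loocv", loocv_stage, df, fits)
    timed("regress", regress_stage, df)
    summary = timed("report", report_stage)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
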