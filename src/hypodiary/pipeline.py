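"""End-to-end orchestration: simulate or load, classify, model, report.

A run is driven by a :class:`RunConfig` (usually parsed from YAML): either
existing input files (glucose traces, check-ins, covariates) or a
simulation block. Artifacts written per run: the interval table with
validity reason codes, classified intervals, the category frequency table,
completion summary, SDH episode table, the tidy model-results table, and a
JSON manifest recording seed, config hash, version and row counts at every
filter stage so attrition stays auditable. Given deterministic estimation
settings, identical config + seed reproduce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cgm import detect_sdh_episodes, episodes_frame, read_traces, regularize
from .classify import classification_frame, classify_interval
from .ema import (
    EVENING_DOMAINS,
    EVENING_SOURCED_MORNING_DOMAINS,
    MORNING_CHECKIN_DOMAINS,
    apply_coverage_filter,
    build_intervals,
    intervals_frame,
    read_checkins,
)
from .errors import ConfigurationError
from .models import results_frame, run_model_family
from .simulate import SimulationConfig, generate_study

logger = logging.getLogger("hypodiary")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    simulate: SimulationConfig | None = None
    inputs: dict | None = None  # {"traces": path, "checkins": path, "covariates": path}
    trace_dialect: dict | None = None
    checkin_dialect: dict | None = None
    covariates: tuple | None = None  # None -> default list restricted to present columns
    exposures: tuple = ("category", "prh", "sdh")
    alpha_family: float = 0.05
    n_model_iterations: int = 7
    seed: int | None = None  # overrides simulate.seed when given
    robust: bool = True
    ar1: bool = True
    max_missing_pct: float = 30.0
    n_days: int | None = None  # completion denominator for loaded (non-simulated) data
    out: str = "hypodiary_run"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ConfigurationError("config must set either 'simulate' or 'inputs'")
        if self.simulate is not None and self.inputs is not None:
            raise ConfigurationError("'simulate' and 'inputs' are mutually exclusive")
        if self.inputs is not None:
            for key in ("traces", "checkins", "covariates"):
                if key not in self.inputs:
                    raise ConfigurationError(f"inputs must name a {key!r} file")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "exposures"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        # output location and verbosity do not affect the analysis
        payload = dataclasses.asdict(self)
        payload.pop("out", None)
        payload.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclass
class RunResult:
    outdir: Path
    manifest: dict
    frames: dict = field(default_factory=dict)
    results: list = field(default_factory=list)
    plan: object = None


def checkin_capacity(n_participants: int, n_days: int) -> int:
    """Potential maximum number of morning (or evening) check-ins."""
    if n_participants < 0 or n_days < 0:
        raise ValueError("counts must be non-negative")
    return int(n_participants) * int(n_days)


def completion_summary(checkins, covariates: pd.DataFrame, n_days: int) -> pd.DataFrame:
    """Per-cohort completion: capacity plus mean +- SD of the per-participant
    percentage of submitted morning and evening check-ins."""
    counts: dict[tuple, int] = {}
    for ci in checkins:
        counts[(ci.participant_id, ci.kind)] = counts.get((ci.participant_id, ci.kind), 0) + 1
    rows = []
    for cohort, sub in covariates.groupby("diabetes_type", sort=True):
        pids = sub["participant_id"].astype(str)
        rates = {
            kind: np.array(
                [100.0 * counts.get((pid, kind), 0) / n_days for pid in pids]
            )
            for kind in ("morning", "evening")
        }
        rows.append(
            {
                "cohort": cohort,
                "n_participants": len(pids),
                "n_days": n_days,
                "max_checkins_per_kind": checkin_capacity(len(pids), n_days),
                "completion_morning_mean": rates["morning"].mean(),
                "completion_morning_sd": rates["morning"].std(ddof=1) if len(pids) > 1 else 0.0,
                "completion_evening_mean": rates["evening"].mean(),
                "completion_evening_sd": rates["evening"].std(ddof=1) if len(pids) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def add_completion_rate(covariates: pd.DataFrame, checkins, n_days: int) -> pd.DataFrame:
    """Attach the app-engagement covariate: mean % of morning+evening
    check-ins each participant submitted."""
    counts: dict[str, int] = {}
    for ci in checkins:
        if ci.kind in ("morning", "evening"):
            counts[ci.participant_id] = counts.get(ci.participant_id, 0) + 1
    out = covariates.copy()
    out["completion_rate"] = [
        100.0 * counts.get(str(pid), 0) / (2 * n_days)
        for pid in out["participant_id"]
    ]
    return out


def frequency_table(classified: pd.DataFrame) -> pd.DataFrame:
    """Category shares (count and %) per cohort x phase over valid intervals."""
    if classified.empty:
        import warnings

        warnings.warn("no valid intervals: frequency table is empty", stacklevel=2)
        return pd.DataFrame(columns=["cohort", "phase", "category", "n", "pct"])
    freq = (
        classified.groupby(["cohort", "phase", "category"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    freq["pct"] = 100.0 * freq["n"] / freq.groupby(
        [freq["cohort"], freq["phase"]]
    )["n"].transform("sum")
    return freq


def assemble_model_table(pairs, checkins, covariates: pd.DataFrame) -> pd.DataFrame:
    """Join classified intervals to their outcome scores and covariates.

    One output row per (interval, domain). Day exposure pairs with the same
    evening's nine domains; night exposure with the next morning's seven
    domains plus that evening's memory / productivity / social scores.
    ``order`` (the within-participant day index) drives the AR(1) ordering.
    """
    lookup = {(ci.participant_id, ci.date, ci.kind): ci for ci in checkins}
    rows = []
    for iv, cls in pairs:
        base = {
            "participant_id": iv.participant_id,
            "phase": iv.phase,
            "date": iv.date,
            "order": iv.date.toordinal(),
            "category": cls.category,
            "prh_combined": cls.prh_combined,
            "sdh_subtype": cls.sdh_subtype,
            "prh_present": int(cls.prh_present),
            "sdh_present": int(cls.sdh_present),
        }
        if iv.phase == "day":
            src = [(lookup.get((iv.participant_id, iv.date, "evening")), EVENING_DOMAINS)]
        else:
            nxt = iv.date + pd.Timedelta(days=1)
            src = [
                (lookup.get((iv.participant_id, nxt, "morning")), MORNING_CHECKIN_DOMAINS),
                (
                    lookup.get((iv.participant_id, nxt, "evening")),
                    EVENING_SOURCED_MORNING_DOMAINS,
                ),
            ]
        for checkin, domains in src:
            if checkin is None:
                continue
            for domain in domains:
                if domain in checkin.scores:
                    rows.append({**base, "domain": domain, "score": checkin.scores[domain]})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    cov = covariates.rename(columns={"diabetes_type": "cohort"})
    cov["participant_id"] = cov["participant_id"].astype(str)
    return table.merge(cov, on="participant_id", how="left")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run(config: RunConfig, model_stage: bool = True) -> RunResult:
    """Execute the pipeline and write all artifacts to ``config.out``."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    attrition: dict = {}

    # --- inputs -------------------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        if config.seed is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
        logger.info("simulating cohort: %d+%d participants x %d days",
                    sim.n_type1, sim.n_type2, sim.n_days)
        study = generate_study(sim)
        paths = study.write(outdir / "inputs")
        n_days = sim.n_days
        start_date = pd.Timestamp(sim.start_date)
        end_date = start_date + pd.Timedelta(days=sim.n_days - 1)
        seed = sim.seed
    else:
        paths = {k: str(v) for k, v in config.inputs.items()}
        n_days = config.n_days
        start_date = end_date = None
        seed = config.seed

    traces, trace_report = read_traces(paths["traces"], config.trace_dialect)
    checkins, checkin_report = read_checkins(paths["checkins"], config.checkin_dialect)
    covariates = pd.read_csv(paths["covariates"])
    if "participant_id" not in covariates.columns or "diabetes_type" not in covariates.columns:
        raise ConfigurationError(
            f"covariate file {paths['covariates']} needs participant_id and diabetes_type"
        )
    attrition["trace_load"] = trace_report.to_dict()
    attrition["checkin_load"] = checkin_report.to_dict()

    if n_days is None:
        dates = [ci.date for ci in checkins]
        n_days = int((max(dates) - min(dates)).days) + 1 if dates else 0

    # --- regularise, detect, divide, filter ----------------------------------
    rtraces = {pid: regularize(t) for pid, t in traces.items()}
    episodes = {pid: detect_sdh_episodes(rt) for pid, rt in rtraces.items()}
    intervals = build_intervals(checkins, start_date=start_date, end_date=end_date)
    attrition["intervals_built"] = len(intervals)
    apply_coverage_filter(intervals, rtraces, config.max_missing_pct)
    reasons = pd.Series([iv.reason for iv in intervals]).value_counts().to_dict()
    attrition["interval_reasons"] = {str(k): int(v) for k, v in reasons.items()}

    valid = [iv for iv in intervals if iv.valid]
    attrition["intervals_valid"] = len(valid)
    pairs = [(iv, classify_interval(iv, episodes.get(iv.participant_id, []))) for iv in valid]

    # --- tables ---------------------------------------------------------------
    classified = classification_frame(pairs)
    cohort_map = dict(
        zip(covariates["participant_id"].astype(str), covariates["diabetes_type"])
    )
    if not classified.empty:
        classified.insert(1, "cohort", classified["participant_id"].map(cohort_map))
    covariates = add_completion_rate(covariates, checkins, n_days) if n_days else covariates
    freq = frequency_table(classified)
    completion = completion_summary(checkins, covariates, n_days) if n_days else pd.DataFrame()

    model_table = assemble_model_table(pairs, checkins, covariates)
    if model_table.empty:
        raise ConfigurationError("interval-outcome join produced zero rows")
    attrition["model_rows"] = len(model_table)

    frames = {
        "intervals": intervals_frame(intervals),
        "classified_intervals": classified,
        "episodes": episodes_frame(episodes),
        "category_frequencies": freq,
        "completion_summary": completion,
        "model_table": model_table,
    }

    results, plan = [], None
    if model_stage:
        results, plan = run_model_family(
            model_table,
            covariates=config.covariates,
            exposures=config.exposures,
            alpha_family=config.alpha_family,
            n_model_iterations=config.n_model_iterations,
            robust=config.robust,
            ar1=config.ar1,
        )
        frames["model_results"] = results_frame(results)
        attrition["models_fitted"] = len(results)
        attrition["models_nonconverged"] = int(sum(not r.converged for r in results))

    for name, df in frames.items():
        _write_csv(df, outdir / f"{name}.csv")

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config.config_hash(),
        # keep the manifest byte-identical across output locations
        "inputs": {
            k: str(Path(p).relative_to(outdir)) if str(p).startswith(str(outdir)) else str(p)
            for k, p in paths.items()
        },
        "n_days": n_days,
        "attrition": attrition,
        "multiplicity": (
            {
                "alpha_family": plan.alpha_family,
                "n_tests": plan.n_tests,
                "alpha_per_test": plan.alpha_per_test,
            }
            if plan is not None
            else None
        ),
        "artifacts": sorted(f"{name}.csv" for name in frames),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete: %d valid intervals, %d models", len(valid), len(results))
    return RunResult(outdir=outdir, manifest=manifest, frames=frames, results=results, plan=plan)
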