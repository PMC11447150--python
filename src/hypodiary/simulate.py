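"""Seedable synthetic study generator with known ground truth.

Emulates the three data streams of a diary + blinded-CGM study: 5-min
interstitial glucose traces with inserted hypoglycaemic excursions, thrice
daily app check-ins (0-10 functioning scores, PRH reports, realistic
missingness) and a baseline covariate table -- plus the ground truth
(per-interval true category, participant intercepts, injected effects)
needed for recovery testing.

Design of the glucose stream: a discretised mean-reverting (OU) process
around a participant-specific baseline of 7-9 mmol/l, floored well above
the 3.9 mmol/l threshold so that sub-threshold excursions occur *only* by
explicit insertion; each excursion is a smooth dip of configured nadir and
below-threshold duration placed wholly inside one exposure interval. This
keeps the generator's category labels exact rather than approximate.

Scores follow the same model the analysis fits: domain mean + participant
random intercept + category effect + AR(1) residual, clipped to the 0-10
instrument range. Check-ins are dropped independently at the study's
observed completion rates (86% morning, 90% evening); the morning check-in
carries the preceding night's PRH report, the evening check-in the day's.

Default hypoglycaemia rates are calibrated so the expected night-time
category split matches 72% / 17% / 3.2% / 7.8% (A / SDH-only / PRH-only /
both); the detection and false-report probabilities are shared between
phases, so the daytime split is matched only qualitatively.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .classify import classify_category
from .cgm import subtype_from_nadir
from .ema import (
    EVENING_CHECKIN_DOMAINS,
    MORNING_CHECKIN_DOMAINS,
    MORNING_DOMAINS,
    SCHEDULED_TIMES,
)
from .errors import ConfigurationError

#: Expected night-time category probabilities (A, B, C, D) under the default
#: rates; also the default for the interval-level score simulator.
DEFAULT_NIGHT_CATEGORY_PROBS = (0.72, 0.17, 0.032, 0.078)

_DEPTH_STRATA = ((3.05, 3.85), (2.25, 2.95), (1.85, 2.2))

_D_EFFECTS = {
    "sleep_quality": -0.8,
    "energy_level": -0.55,
    "mood": -0.45,
    "negative_affect": -0.5,
    "cognitive_function": -0.4,
    "memory": -0.25,
    "productivity": -0.3,
    "social_function": -0.2,
    "fear_hypoglycaemia": -0.6,
    "fear_hyperglycaemia": -0.2,
}


def default_effects() -> dict:
    """Category -> domain -> score-point shift. SDH-only nights/days carry no
    effect; reported hypoglycaemia does, strongest when sensor-confirmed."""
    return {
        "A": {d: 0.0 for d in MORNING_DOMAINS},
        "B": {d: 0.0 for d in MORNING_DOMAINS},
        "C": {d: round(0.6 * v, 3) for d, v in _D_EFFECTS.items()},
        "D": dict(_D_EFFECTS),
    }


def default_domain_means() -> dict:
    return {
        "sleep_quality": 7.2,
        "energy_level": 6.8,
        "mood": 7.4,
        "negative_affect": 7.8,
        "cognitive_function": 7.5,
        "memory": 7.6,
        "productivity": 7.0,
        "social_function": 7.3,
        "fear_hypoglycaemia": 8.0,
        "fear_hyperglycaemia": 8.2,
    }


@dataclass
class SimulationConfig:
    """Full study-generator configuration; defaults are the study conditions."""

    n_type1: int = 274
    n_type2: int = 320
    n_days: int = 70
    step_minutes: int = 5
    start_date: str = "2023-01-02"
    # glucose process
    baseline_range: tuple = (7.0, 9.0)
    reversion_hours: float = 2.0  # OU mean-reversion timescale
    stationary_sd: float = 0.8
    base_floor: float = 4.5  # keeps the base process clear of the threshold
    # hypoglycaemic excursions
    excursion_rate_night: float = 0.248
    excursion_rate_day: float = 0.27
    depth_probs: tuple = (0.65, 0.28, 0.07)  # strata 3.0-3.9 / 2.2-3.0 / <=2.2
    below_duration_min: tuple = (20.0, 50.0)  # minutes below threshold
    ramp_minutes: float = 10.0
    margin_minutes: float = 15.0  # excursion clearance from interval boundaries
    # reporting behaviour
    p_detect: float = 0.315
    p_false_report: float = 0.043
    symptomatic_fraction: float = 0.6
    management_probs: tuple = (0.55, 0.3, 0.15)  # treated / prevented / other
    severe_rate: float = 0.0
    # functioning scores
    domain_means: dict = field(default_factory=default_domain_means)
    intercept_sd: float = 1.0
    residual_sd: float = 1.2
    ar_rho: float = 0.2
    effects: dict = field(default_factory=default_effects)
    # check-in behaviour
    p_morning: float = 0.86
    p_evening: float = 0.90
    p_afternoon: float = 0.80
    submit_delay_mean_min: float = 25.0  # truncated-exponential delay, 6-h cap
    # sensor missingness
    sensor_dropout: float = 0.05  # expected fraction of missing slots
    dropout_gap_mean_slots: float = 6.0
    timestamp_jitter_s: float = 30.0  # uniform jitter, well under half a slot
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.p_detect,
            self.p_false_report,
            self.symptomatic_fraction,
            self.severe_rate,
            self.p_morning,
            self.p_evening,
            self.p_afternoon,
            self.sensor_dropout,
            self.excursion_rate_night,
            self.excursion_rate_day,
            *self.depth_probs,
            *self.management_probs,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if not math.isclose(sum(self.depth_probs), 1.0, abs_tol=1e-9):
            raise ConfigurationError("depth_probs must sum to 1")
        if not math.isclose(sum(self.management_probs), 1.0, abs_tol=1e-9):
            raise ConfigurationError("management_probs must sum to 1")
        if self.intercept_sd < 0 or self.residual_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if not abs(self.ar_rho) < 1:
            raise ConfigurationError("|ar_rho| must be below 1")
        if any(not 0.0 <= m <= 10.0 for m in self.domain_means.values()):
            raise ConfigurationError("domain means must lie in [0, 10]")
        if min(self.n_type1 + self.n_type2, self.n_days) < 1:
            raise ConfigurationError("need at least one participant and one day")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})
        cfg.validate()
        return cfg


@dataclass
class SimulationTruth:
    """Ground truth of one generated study."""

    seed: int
    effects: dict
    intercepts: dict  # participant -> random intercept
    intervals: pd.DataFrame  # one row per participant-interval with true category
    scores: pd.DataFrame  # emitted scores with their true exposure category

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "effects": self.effects,
            "intercepts": self.intercepts,
            "intervals": self.intervals.assign(
                date=self.intervals["date"].dt.strftime("%Y-%m-%d")
            ).to_dict(orient="list"),
        }
        return json.dumps(payload, sort_keys=True)


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    traces: pd.DataFrame
    checkins: pd.DataFrame
    covariates: pd.DataFrame
    truth: SimulationTruth

    def write(self, outdir) -> dict:
        """Write the CSV inputs + truth JSON; returns the path map.

        Output formatting is fully deterministic, so identical (config,
        seed) pairs produce byte-identical files.
        """
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "traces": outdir / "traces.csv",
            "checkins": outdir / "checkins.csv",
            "covariates": outdir / "covariates.csv",
            "truth": outdir / "truth.json",
        }
        self.traces.to_csv(paths["traces"], index=False, float_format="%.2f")
        self.checkins.to_csv(paths["checkins"], index=False, float_format="%.2f")
        self.covariates.to_csv(paths["covariates"], index=False, float_format="%.3f")
        paths["truth"].write_text(self.truth.to_json())
        return {k: str(v) for k, v in paths.items()}


def _ou_path(rng, n, mu, reversion_hours, stationary_sd, step_minutes):
    a = 1.0 - step_minutes / (reversion_hours * 60.0)
    step_sd = stationary_sd * math.sqrt(1.0 - a * a)
    x = (1.0 - a) * mu + rng.normal(0.0, step_sd, n)
    g, _ = lfilter([1.0], [1.0, -a], x, zi=[a * mu])
    return g


def _apply_excursion(g, t0_min, below_min, nadir, ramp_min, step_min):
    """Overwrite grid samples with a smooth dip below 3.9 mmol/l."""
    lo = 3.8  # value at the edges of the below-threshold window

    def ticks(a, b):  # tick indices with time in [a, b)
        return range(math.ceil(a / step_min), math.ceil(b / step_min))

    for i in ticks(t0_min - ramp_min, t0_min):
        u = (i * step_min - (t0_min - ramp_min)) / ramp_min
        g[i] = g[i] * (1.0 - u) + 3.95 * u
    for i in ticks(t0_min, t0_min + below_min):
        u = (i * step_min - t0_min) / below_min
        g[i] = lo - (lo - nadir) * math.sin(math.pi * u)
    for i in ticks(t0_min + below_min, t0_min + below_min + ramp_min):
        u = (i * step_min - (t0_min + below_min)) / ramp_min
        g[i] = 3.95 * (1.0 - u) + g[i] * u


def _covariate_row(rng, cohort):
    t1 = cohort == "type1"
    age = float(np.clip(rng.normal(44.9, 16.0) if t1 else rng.normal(61.9, 10.2), 18, 90))
    gender = rng.choice(
        ["male", "female", "other"],
        p=(0.46, 0.533, 0.007) if t1 else (0.63, 0.37, 0.0),
    )
    duration = float(np.clip(rng.normal(23.8, 15.6) if t1 else rng.normal(20.4, 8.9), 1, 60))
    impaired = int(rng.random() < (0.21 if t1 else 0.27))
    modality = rng.choice(
        ["fingerprick", "cgm_no_alerts", "cgm_alerts"],
        p=(0.244, 0.679, 0.077) if t1 else (0.588, 0.397, 0.015),
    )
    hfs = float(np.clip(rng.normal(32.4, 20.9) if t1 else rng.normal(29.0, 21.9), 0, 132))
    depress = rng.choice(
        ["none", "mild", "moderate_severe"],
        p=(0.59, 0.27, 0.14) if t1 else (0.52, 0.25, 0.23),
    )
    return {
        "age": age,
        "gender": gender,
        "diabetes_duration": duration,
        "impaired_awareness": impaired,
        "monitoring_modality": modality,
        "hfs_total": hfs,
        "depressive_symptoms": depress,
    }


def generate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study (traces, check-ins, covariates, truth)."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    step_min = cfg.step_minutes
    per_day = 24 * 60 // step_min
    start0 = pd.Timestamp(cfg.start_date)
    window_min = 6 * 60.0
    mgmt_levels = ("treated", "prevented", "other")

    trace_rows = []
    checkin_rows = []
    cov_rows = []
    truth_intervals = []
    score_rows = []
    intercepts = {}

    participants = [("type1", f"T1-{i + 1:04d}") for i in range(cfg.n_type1)] + [
        ("type2", f"T2-{i + 1:04d}") for i in range(cfg.n_type2)
    ]

    for cohort, pid in participants:
        cov_rows.append(
            {"participant_id": pid, "diabetes_type": cohort, **_covariate_row(rng, cohort)}
        )
        b = float(rng.normal(0.0, cfg.intercept_sd))
        intercepts[pid] = b

        # --- check-in presence and submission delays -----------------------
        present = {
            "morning": rng.random(cfg.n_days) < cfg.p_morning,
            "afternoon": rng.random(cfg.n_days) < cfg.p_afternoon,
            "evening": rng.random(cfg.n_days) < cfg.p_evening,
        }
        delays = {
            k: np.minimum(
                rng.exponential(cfg.submit_delay_mean_min, cfg.n_days), window_min - 1.0
            )
            for k in present
        }

        def sub_min(kind, d):  # submission time in minutes from start0 midnight
            sched = SCHEDULED_TIMES[kind].total_seconds() / 60.0
            return d * 24 * 60 + sched + delays[kind][d]

        # --- interval boundaries (minutes from day-0 midnight) -------------
        day_bounds, night_bounds = [], []
        for d in range(cfg.n_days):
            ds = sub_min("morning", d) if present["morning"][d] else d * 1440 + 7 * 60
            de = sub_min("evening", d) if present["evening"][d] else d * 1440 + 21 * 60
            day_bounds.append((ds, de))
            ne = (
                sub_min("morning", d + 1)
                if d + 1 < cfg.n_days and present["morning"][d + 1]
                else (d + 1) * 1440 + 7 * 60
            )
            night_bounds.append((de, ne))

        # --- glucose base process + excursions ------------------------------
        n_samp = cfg.n_days * per_day
        mu = float(rng.uniform(*cfg.baseline_range))
        g = _ou_path(rng, n_samp, mu, cfg.reversion_hours, cfg.stationary_sd, step_min)
        np.clip(g, cfg.base_floor, None, out=g)

        interval_meta = {}
        for phase, bounds, rate in (
            ("day", day_bounds, cfg.excursion_rate_day),
            ("night", night_bounds, cfg.excursion_rate_night),
        ):
            for d, (lo, hi) in enumerate(bounds):
                last_night = phase == "night" and d == cfg.n_days - 1
                sdh, nadir = False, np.nan
                if not last_night and rng.random() < rate:
                    stratum = rng.choice(3, p=cfg.depth_probs)
                    nadir = float(rng.uniform(*_DEPTH_STRATA[stratum]))
                    below = float(rng.uniform(*cfg.below_duration_min))
                    pad = cfg.margin_minutes + cfg.ramp_minutes
                    avail = (hi - lo) - 2.0 * pad - below
                    if avail > 0:
                        t0 = lo + pad + float(rng.uniform(0.0, avail))
                        _apply_excursion(g, t0, below, nadir, cfg.ramp_minutes, step_min)
                        sdh = True
                    else:
                        nadir = np.nan
                interval_meta[(phase, d)] = {"sdh": sdh, "nadir": nadir}

        # --- PRH reports and true categories --------------------------------
        for phase, d in interval_meta:
            meta = interval_meta[(phase, d)]
            reporting_present = (
                bool(present["evening"][d])
                if phase == "day"
                else (d + 1 < cfg.n_days and bool(present["morning"][d + 1]))
            )
            reported, severe, det, man = False, False, "", ""
            if reporting_present:
                p = cfg.p_detect if meta["sdh"] else cfg.p_false_report
                reported = bool(rng.random() < p)
                if reported:
                    det = (
                        "symptomatic"
                        if rng.random() < cfg.symptomatic_fraction
                        else "asymptomatic"
                    )
                    man = str(rng.choice(mgmt_levels, p=cfg.management_probs))
                    severe = bool(rng.random() < cfg.severe_rate)
            prh_effective = reported and not severe
            meta.update(
                reporting_present=reporting_present,
                reported=reported,
                severe=severe,
                detection=det,
                management=man,
                category=(
                    classify_category(prh_effective, meta["sdh"])
                    if reporting_present
                    else ""
                ),
            )
            truth_intervals.append(
                {
                    "participant_id": pid,
                    "cohort": cohort,
                    "date": start0 + pd.Timedelta(days=d),
                    "phase": phase,
                    "reporting_present": reporting_present,
                    "true_category": meta["category"],
                    "sdh_true": meta["sdh"],
                    "prh_true": prh_effective,
                    "sdh_subtype_true": (
                        subtype_from_nadir(meta["nadir"]) if meta["sdh"] else "none"
                    ),
                    "nadir_true": meta["nadir"],
                }
            )

        # --- sensor dropout and jitter --------------------------------------
        missing = np.zeros(n_samp, dtype=bool)
        if cfg.sensor_dropout > 0:
            p_start = cfg.sensor_dropout / cfg.dropout_gap_mean_slots
            starts = np.flatnonzero(rng.random(n_samp) < p_start)
            lengths = rng.geometric(1.0 / cfg.dropout_gap_mean_slots, len(starts))
            for s, ln in zip(starts, lengths):
                missing[s : s + ln] = True
        keep = np.flatnonzero(~missing)
        jitter = rng.uniform(-cfg.timestamp_jitter_s, cfg.timestamp_jitter_s, len(keep))
        times = (
            start0
            + pd.to_timedelta(keep * step_min, unit="m")
            + pd.to_timedelta(np.round(jitter), unit="s")
        )
        trace_rows.append(
            pd.DataFrame(
                {"participant_id": pid, "timestamp": times, "glucose": g[keep]}
            )
        )

        # --- functioning scores ---------------------------------------------
        def exposure_category(kind, d):
            if kind == "evening":
                return interval_meta[("day", d)]["category"] or "A"
            if d == 0:
                return "A"  # no preceding study night
            return interval_meta[("night", d - 1)]["category"] or "A"

        scores_by_slot: dict[tuple, dict] = {}
        c = math.sqrt(1.0 - cfg.ar_rho**2)
        for domain, mean in cfg.domain_means.items():
            slots = [
                (d, kind)
                for d in range(cfg.n_days)
                for kind in ("morning", "evening")
                if (kind == "morning" and domain in MORNING_CHECKIN_DOMAINS)
                or (kind == "evening" and domain in EVENING_CHECKIN_DOMAINS)
            ]
            e = 0.0
            for j, (d, kind) in enumerate(slots):
                draw = rng.normal(0.0, cfg.residual_sd)
                e = draw if j == 0 else cfg.ar_rho * e + c * draw
                cat = exposure_category(kind, d)
                raw = mean + b + cfg.effects[cat].get(domain, 0.0) + e
                val = float(np.clip(raw, 0.0, 10.0))
                scores_by_slot.setdefault((d, kind), {})[domain] = round(val, 2)
                if present[kind][d]:
                    score_rows.append(
                        {
                            "participant_id": pid,
                            "cohort": cohort,
                            "domain": domain,
                            "category": cat,
                            "checkin_kind": kind,
                            "score": round(val, 2),
                        }
                    )

        # --- check-in rows ----------------------------------------------------
        for d in range(cfg.n_days):
            date = start0 + pd.Timedelta(days=d)
            for kind in ("morning", "afternoon", "evening"):
                if not present[kind][d]:
                    continue
                row = {
                    "participant_id": pid,
                    "kind": kind,
                    "date": date.strftime("%Y-%m-%d"),
                    "submitted_time": (
                        start0 + pd.Timedelta(minutes=sub_min(kind, d))
                    ).strftime("%Y-%m-%dT%H:%M:%S"),
                    "prh_reported": "",
                    "prh_detection": "",
                    "prh_management": "",
                    "prh_severe": "",
                }
                meta = None
                if kind == "evening":
                    meta = interval_meta[("day", d)]
                elif kind == "morning" and d > 0:
                    meta = interval_meta[("night", d - 1)]
                if meta is not None and meta.get("reporting_present"):
                    row["prh_reported"] = int(meta["reported"])
                    if meta["reported"]:
                        row["prh_detection"] = meta["detection"]
                        row["prh_management"] = meta["management"]
                        row["prh_severe"] = int(meta["severe"])
                elif kind != "afternoon":
                    row["prh_reported"] = 0
                for domain, val in scores_by_slot.get((d, kind), {}).items():
                    row[f"score_{domain}"] = val
                checkin_rows.append(row)

    traces = pd.concat(trace_rows, ignore_index=True)
    traces["timestamp"] = traces["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    score_cols = [f"score_{d}" for d in MORNING_DOMAINS]
    checkins = pd.DataFrame(checkin_rows).reindex(
        columns=[
            "participant_id",
            "kind",
            "date",
            "submitted_time",
            "prh_reported",
            "prh_detection",
            "prh_management",
            "prh_severe",
            *score_cols,
        ]
    )
    covariates = pd.DataFrame(cov_rows)
    truth = SimulationTruth(
        seed=cfg.seed,
        effects=cfg.effects,
        intercepts=intercepts,
        intervals=pd.DataFrame(truth_intervals),
        scores=pd.DataFrame(score_rows),
    )
    return SyntheticStudy(
        config=cfg, traces=traces, checkins=checkins, covariates=covariates, truth=truth
    )


def truth_report(truth: SimulationTruth) -> dict:
    """Realised category frequencies and per-domain mean score shifts.

    Returns ``{"category_frequencies": ..., "realised_shifts": ...}``;
    frequencies are over intervals whose reporting check-in exists, shifts
    are mean(score | category) - mean(score | A) per cohort and domain.
    """
    iv = truth.intervals[truth.intervals["reporting_present"]]
    freq = (
        iv.groupby(["cohort", "phase", "true_category"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    freq["pct"] = 100.0 * freq["n"] / freq.groupby(
        [freq["cohort"], freq["phase"]]
    )["n"].transform("sum")

    sc = truth.scores
    means = (
        sc.groupby(["cohort", "domain", "category"], observed=True)["score"]
        .mean()
        .rename("mean_score")
        .reset_index()
    )
    ref = means[means["category"] == "A"][["cohort", "domain", "mean_score"]].rename(
        columns={"mean_score": "mean_a"}
    )
    shifts = means.merge(ref, on=["cohort", "domain"])
    shifts["realised_shift"] = shifts["mean_score"] - shifts["mean_a"]
    return {"category_frequencies": freq, "realised_shifts": shifts}


def simulate_interval_scores(
    n_participants: int = 200,
    n_intervals: int = 60,
    *,
    effects: dict | None = None,
    category_probs=DEFAULT_NIGHT_CATEGORY_PROBS,
    mean: float = 7.0,
    intercept_sd: float = 1.0,
    residual_sd: float = 1.2,
    rho: float = 0.2,
    clip: tuple | None = (0.0, 10.0),
    seed: int | None = None,
    rng=None,
) -> pd.DataFrame:
    """Fast interval-level score simulator for Monte Carlo studies.

    Generates one domain's scores for ``n_participants`` x ``n_intervals``
    consecutive exposure intervals: category drawn iid from
    ``category_probs`` (A, B, C, D), score = mean + participant intercept +
    effect(category) + AR(1) residual, optionally clipped to the 0-10 scale.
    Returns a tidy frame with participant_id, order, category, score.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    eff = {"A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0, **(effects or {})}
    p = np.asarray(category_probs, dtype=float)
    p = p / p.sum()
    cats = rng.choice(4, size=(n_participants, n_intervals), p=p)
    b = rng.normal(0.0, intercept_sd, n_participants)
    e = np.empty((n_participants, n_intervals))
    e[:, 0] = rng.normal(0.0, residual_sd, n_participants)
    c = math.sqrt(1.0 - rho**2)
    for t in range(1, n_intervals):
        e[:, t] = rho * e[:, t - 1] + c * rng.normal(0.0, residual_sd, n_participants)
    shift = np.array([eff["A"], eff["B"], eff["C"], eff["D"]])
    scores = mean + b[:, None] + shift[cats] + e
    if clip is not None:
        np.clip(scores, clip[0], clip[1], out=scores)
    labels = np.array(["A", "B", "C", "D"])
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n_participants), n_intervals),
            "order": np.tile(np.arange(n_intervals), n_participants),
            "category": labels[cats.ravel()],
            "score": scores.ravel(),
        }
    )


def study_hashes(study: SyntheticStudy, outdir) -> dict:
    """SHA-256 of every written artifact (reproducibility check)."""
    paths = study.write(outdir)
    return {
        name: hashlib.sha256(open(p, "rb").read()).hexdigest()
        for name, p in paths.items()
    }
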