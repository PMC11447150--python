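"""Diary check-ins and day/night exposure intervals.

Participants answer brief app check-ins scheduled at 07:00 (morning),
15:00 (afternoon) and 21:00 (evening), each with a 6-h response window.
Morning and evening submission times divide every 24-h period into a
night-time interval (evening submission -> next morning submission) and a
daytime interval (morning submission -> evening submission). The morning
check-in carries the person-reported hypoglycaemia (PRH) report for the
preceding night; the evening check-in carries the report for that day.

When a *boundary* check-in is missing its scheduled clock time stands in;
when the *reporting* check-in is missing the interval is invalid. An
interval is also excluded when strictly more than 30% of its expected
5-min sensor slots are missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cgm import STEP, LoadReport, RegularTrace
from .errors import ConfigurationError, UndefinedStatisticError

#: Analysis domains attached to morning functioning (10). Memory, productivity
#: and social functioning are asked only at the evening check-in but are
#: analysed against the preceding night as well.
MORNING_DOMAINS = (
    "sleep_quality",
    "energy_level",
    "mood",
    "negative_affect",
    "cognitive_function",
    "memory",
    "productivity",
    "social_function",
    "fear_hypoglycaemia",
    "fear_hyperglycaemia",
)

#: Analysis domains attached to evening functioning (9): all but sleep quality.
EVENING_DOMAINS = tuple(d for d in MORNING_DOMAINS if d != "sleep_quality")

#: Domains actually asked at each check-in.
MORNING_CHECKIN_DOMAINS = (
    "sleep_quality",
    "energy_level",
    "mood",
    "negative_affect",
    "cognitive_function",
    "fear_hypoglycaemia",
    "fear_hyperglycaemia",
)
EVENING_CHECKIN_DOMAINS = EVENING_DOMAINS

#: Evening-only domains that are nonetheless analysed as morning functioning.
EVENING_SOURCED_MORNING_DOMAINS = ("memory", "productivity", "social_function")

SCHEDULED_TIMES = {
    "morning": pd.Timedelta(hours=7),
    "afternoon": pd.Timedelta(hours=15),
    "evening": pd.Timedelta(hours=21),
}

RESPONSE_WINDOW = pd.Timedelta(hours=6)

#: Intervals with strictly more missing sensor data than this are excluded.
MAX_MISSING_PCT = 30.0

CHECKIN_KINDS = ("morning", "afternoon", "evening")
PHASES = ("night", "day")


@dataclass(frozen=True)
class DomainCatalogue:
    """Functioning domains per phase; higher scores mean better functioning."""

    morning: tuple = MORNING_DOMAINS
    evening: tuple = EVENING_DOMAINS

    def __post_init__(self):
        if not set(self.evening) <= set(self.morning):
            raise ValueError("evening domains must be a subset of morning domains")

    def for_phase(self, phase: str) -> tuple:
        # night exposure -> morning functioning, day exposure -> evening functioning
        return self.morning if phase == "night" else self.evening


DEFAULT_CATALOGUE = DomainCatalogue()


@dataclass(frozen=True)
class PRHReport:
    """One person-reported hypoglycaemia follow-up answer."""

    detection: str  # raw detection answer (how the episode was noticed)
    management: str  # raw management answer (what was done about it)
    severe: bool = False  # adjudicated severe episodes are excluded downstream


@dataclass(frozen=True)
class CheckIn:
    """One submitted app check-in."""

    participant_id: str
    kind: str  # morning / afternoon / evening
    date: pd.Timestamp  # scheduled calendar date (midnight-normalised)
    submitted: pd.Timestamp | None
    scores: dict = field(default_factory=dict)  # domain -> 0..10
    prh: PRHReport | None = None  # None means "no PRH reported"

    @property
    def scheduled(self) -> pd.Timestamp:
        return self.date + SCHEDULED_TIMES[self.kind]


@dataclass
class Interval:
    """One participant-night or participant-day exposure window."""

    participant_id: str
    date: pd.Timestamp  # night intervals are indexed by their starting date
    phase: str  # "night" or "day"
    start: pd.Timestamp
    end: pd.Timestamp
    reporting: CheckIn | None = None
    pct_sensor_missing: float | None = None
    valid: bool = False
    reason: str = "pending"

    @property
    def duration(self) -> pd.Timedelta:
        return self.end - self.start


DEFAULT_CHECKIN_DIALECT = {
    "participant": "participant_id",
    "kind": "kind",
    "date": "date",
    "submitted": "submitted_time",
    "prh_reported": "prh_reported",
    "prh_detection": "prh_detection",
    "prh_management": "prh_management",
    "prh_severe": "prh_severe",
    "score_prefix": "score_",
    "sep": ",",
}


def read_checkins(
    path,
    dialect: dict | None = None,
    response_window: pd.Timedelta = RESPONSE_WINDOW,
    enforce_window: bool = True,
) -> tuple[list[CheckIn], LoadReport]:
    """Load submitted check-ins from a delimited text file.

    Rejected (and counted) rows: unknown kind, unparseable timestamps,
    any score outside [0, 10], submissions outside the response window
    (unless ``enforce_window`` is off). Duplicate (participant, date, kind)
    entries keep the earliest submission.
    """
    d = {**DEFAULT_CHECKIN_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep=d["sep"])
    report = LoadReport(n_rows=len(df))
    for key in ("participant", "kind", "date", "submitted"):
        if d[key] not in df.columns:
            raise ConfigurationError(
                f"column {d[key]!r} (mapped from {key!r}) not found in {path}"
            )
    score_cols = {
        c[len(d["score_prefix"]) :]: c
        for c in df.columns
        if c.startswith(d["score_prefix"])
    }

    checkins: list[CheckIn] = []
    for _, row in df.iterrows():
        kind = str(row[d["kind"]]).strip().lower()
        if kind not in CHECKIN_KINDS:
            report.count("unknown_kind")
            continue
        date = pd.to_datetime(row[d["date"]], errors="coerce")
        submitted = pd.to_datetime(row[d["submitted"]], errors="coerce")
        if pd.isna(date) or pd.isna(submitted):
            report.count("unparseable_timestamp")
            continue
        date = date.normalize()
        scheduled = date + SCHEDULED_TIMES[kind]
        if enforce_window and not (
            scheduled <= submitted <= scheduled + response_window
        ):
            report.count("outside_response_window")
            continue

        scores: dict[str, float] = {}
        bad_score = False
        for domain, col in score_cols.items():
            v = row[col]
            if pd.isna(v):
                continue
            v = float(v)
            if not 0.0 <= v <= 10.0:
                bad_score = True
                break
            scores[domain] = v
        if bad_score:
            report.count("score_out_of_range")
            continue

        prh = None
        prh_flag = row.get(d["prh_reported"])
        if pd.notna(prh_flag) and int(prh_flag) == 1:
            prh = PRHReport(
                detection=str(row.get(d["prh_detection"], "")).strip(),
                management=str(row.get(d["prh_management"], "")).strip(),
                severe=bool(
                    pd.notna(row.get(d["prh_severe"]))
                    and int(row.get(d["prh_severe"], 0)) == 1
                ),
            )
        checkins.append(
            CheckIn(
                participant_id=str(row[d["participant"]]),
                kind=kind,
                date=date,
                submitted=submitted,
                scores=scores,
                prh=prh,
            )
        )

    # duplicate policy: earliest submission wins, deterministically
    best: dict[tuple, CheckIn] = {}
    for ci in checkins:
        key = (ci.participant_id, ci.date, ci.kind)
        prev = best.get(key)
        if prev is None:
            best[key] = ci
        else:
            report.count("duplicate_checkin")
            if ci.submitted < prev.submitted:
                best[key] = ci
    out = sorted(best.values(), key=lambda c: (c.participant_id, c.submitted))
    report.n_loaded = len(out)
    return out, report


def build_intervals(
    checkins,
    start_date: pd.Timestamp | None = None,
    end_date: pd.Timestamp | None = None,
) -> list[Interval]:
    """Derive night/day intervals from submission times for every participant.

    For calendar date ``d``: day = [morning(d), evening(d)) reported by the
    evening check-in; night = [evening(d), morning(d+1)) reported by the next
    morning check-in. A missing boundary check-in falls back to its scheduled
    clock time; a missing reporting check-in makes the interval invalid.
    Afternoon check-ins play no role here.
    """
    by_participant: dict[str, dict] = {}
    for ci in checkins:
        by_participant.setdefault(ci.participant_id, {})[(ci.date, ci.kind)] = ci

    intervals: list[Interval] = []
    for pid in sorted(by_participant):
        lookup = by_participant[pid]
        dates = [k[0] for k in lookup]
        lo = (start_date or min(dates)).normalize()
        hi = (end_date or max(dates)).normalize()
        for date in pd.date_range(lo, hi, freq="D"):
            morning = lookup.get((date, "morning"))
            evening = lookup.get((date, "evening"))
            next_morning = lookup.get((date + pd.Timedelta(days=1), "morning"))

            day_start = morning.submitted if morning else date + SCHEDULED_TIMES["morning"]
            day_end = evening.submitted if evening else date + SCHEDULED_TIMES["evening"]
            day = Interval(pid, date, "day", day_start, day_end, reporting=evening)
            if evening is None:
                day.valid, day.reason = False, "no_reporting_checkin"
            elif day_start >= day_end:
                day.valid, day.reason = False, "degenerate_boundaries"
            else:
                day.valid, day.reason = True, "ok"
            intervals.append(day)

            night_start = evening.submitted if evening else date + SCHEDULED_TIMES["evening"]
            night_end = (
                next_morning.submitted
                if next_morning
                else date + pd.Timedelta(days=1) + SCHEDULED_TIMES["morning"]
            )
            night = Interval(pid, date, "night", night_start, night_end, reporting=next_morning)
            if next_morning is None:
                night.valid, night.reason = False, "no_reporting_checkin"
            elif night_start >= night_end:
                night.valid, night.reason = False, "degenerate_boundaries"
            else:
                night.valid, night.reason = True, "ok"
            intervals.append(night)
    return intervals


def sensor_coverage(interval: Interval, trace: RegularTrace) -> float:
    """Percentage of expected 5-min slots missing within [start, end).

    Expected slots = floor(duration / step); grid slots outside the trace's
    recorded span count as missing.
    """
    step = trace.step
    expected = int(interval.duration / step)
    if expected <= 0:
        raise UndefinedStatisticError(
            f"coverage undefined for zero-length interval {interval.participant_id} "
            f"{interval.date.date()} {interval.phase}"
        )
    grid = trace.grid
    i0, i1 = grid.searchsorted(interval.start, "left"), grid.searchsorted(interval.end, "left")
    observed = int((~np.isnan(trace.glucose[i0:i1])).sum())
    missing = expected - min(observed, expected)
    return 100.0 * missing / expected


def apply_coverage_filter(
    intervals,
    traces: dict,
    max_missing_pct: float = MAX_MISSING_PCT,
) -> list[Interval]:
    """Annotate intervals with sensor coverage and apply the exclusion rule.

    Exclusion requires *strictly more* than ``max_missing_pct`` missing;
    exactly 30% missing is retained. Intervals already invalid keep their
    reason. Participants without any trace are fully missing.
    """
    for iv in intervals:
        if not iv.valid:
            continue
        trace = traces.get(iv.participant_id)
        if trace is None:
            iv.pct_sensor_missing = 100.0
        else:
            try:
                iv.pct_sensor_missing = sensor_coverage(iv, trace)
            except UndefinedStatisticError:
                iv.valid, iv.reason = False, "degenerate_boundaries"
                continue
        if iv.pct_sensor_missing > max_missing_pct:
            iv.valid, iv.reason = False, "excess_sensor_missing"
    return intervals


def intervals_frame(intervals) -> pd.DataFrame:
    """Tidy interval table with validity reason codes."""
    rows = [
        {
            "participant_id": iv.participant_id,
            "date": iv.date,
            "phase": iv.phase,
            "start": iv.start,
            "end": iv.end,
            "pct_sensor_missing": iv.pct_sensor_missing,
            "valid": iv.valid,
            "reason": iv.reason,
        }
        for iv in intervals
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "date",
            "phase",
            "start",
            "end",
            "pct_sensor_missing",
            "valid",
            "reason",
        ],
    )
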