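"""Hypoglycaemia category and subtype assignment per exposure interval.

Every valid interval is classified by the 2x2 cross of person-reported
hypoglycaemia (PRH) and sensor-detected hypoglycaemia (SDH):

    A: PRH(-) SDH(-)   no hypoglycaemia (reference)
    B: PRH(-) SDH(+)   sensor only
    C: PRH(+) SDH(-)   person-reported only
    D: PRH(+) SDH(+)   both

PRH reports carry a detection answer (symptomatic vs asymptomatic, i.e.
noticed via symptoms vs via the person's own glucose monitoring) and a
management answer (treated / prevented / other). Multiple reports within
one interval are merged by an ordered ranking -- symptomatic outranks
asymptomatic; treated > prevented > other -- reflecting the impact
gradient observed across subtypes; both rankings are overridable.
Prevented episodes count as PRH present; severe episodes are dropped
before classification.

SDH subtype of an interval is the severity stratum of the lowest nadir
among episodes that retain >=15 min of covered readings after clipping to
the interval (so night and day exposures stay disjoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cgm import SDH_MIN_DURATION, STEP, SDHEpisode, subtype_from_nadir
from .ema import Interval, PRHReport
from .errors import CodingError

CATEGORIES = ("A", "B", "C", "D")
DETECTION_LEVELS = ("none", "symptomatic", "asymptomatic")
MANAGEMENT_LEVELS = ("none", "prevented", "treated", "other")
SDH_SUBTYPE_LEVELS = ("none", "SDH_3.9", "SDH_3.0", "SDH_2.2")

#: Severity order used to pick the dominant subtype within an interval.
SDH_SEVERITY = {"none": 0, "SDH_3.9": 1, "SDH_3.0": 2, "SDH_2.2": 3}

#: Higher rank wins when merging multiple reports in one interval.
DETECTION_RANK = {"symptomatic": 2, "asymptomatic": 1}
MANAGEMENT_RANK = {"treated": 3, "prevented": 2, "other": 1}

#: Raw app answers -> canonical levels. Extend via the *_map arguments.
DETECTION_MAP = {
    "symptomatic": "symptomatic",
    "symptoms": "symptomatic",
    "asymptomatic": "asymptomatic",
    "own_monitoring": "asymptomatic",
    "glucose_reading": "asymptomatic",
}
MANAGEMENT_MAP = {
    "treated": "treated",
    "prevented": "prevented",
    "other": "other",
}


@dataclass(frozen=True)
class IntervalClassification:
    """Category plus PRH/SDH subtypes for one interval."""

    category: str
    prh_detection: str
    prh_management: str
    prh_combined: str  # "detection-management" or "none"
    sdh_subtype: str

    def __post_init__(self):
        prh = self.prh_detection != "none"
        sdh = self.sdh_subtype != "none"
        if self.category != classify_category(prh, sdh):
            raise ValueError("category inconsistent with PRH/SDH presence")
        if (self.prh_management == "none") != (self.prh_detection == "none"):
            raise ValueError("detection and management must be jointly none or set")

    @property
    def prh_present(self) -> bool:
        return self.prh_detection != "none"

    @property
    def sdh_present(self) -> bool:
        return self.sdh_subtype != "none"


def classify_category(prh_present: bool, sdh_present: bool) -> str:
    """2x2 truth table: (-,-)->A, (-,+)->B, (+,-)->C, (+,+)->D."""
    if prh_present:
        return "D" if sdh_present else "C"
    return "B" if sdh_present else "A"


def code_prh_subtypes(
    reports,
    detection_map: dict | None = None,
    management_map: dict | None = None,
    detection_rank: dict | None = None,
    management_rank: dict | None = None,
) -> tuple[str, str, str]:
    """Merge an interval's PRH reports into (detection, management, combined).

    Empty input yields ("none", "none", "none"). Each report's raw answers
    are mapped to canonical levels; across reports the highest-ranked value
    on each axis wins. Unmappable answers raise :class:`CodingError` naming
    the raw value.
    """
    det_map = {**DETECTION_MAP, **(detection_map or {})}
    man_map = {**MANAGEMENT_MAP, **(management_map or {})}
    det_rank = detection_rank or DETECTION_RANK
    man_rank = management_rank or MANAGEMENT_RANK

    best_det, best_man = None, None
    for rep in reports:
        raw_det = rep.detection.strip().lower()
        raw_man = rep.management.strip().lower()
        if raw_det not in det_map:
            raise CodingError(f"unmappable PRH detection answer: {rep.detection!r}")
        if raw_man not in man_map:
            raise CodingError(f"unmappable PRH management answer: {rep.management!r}")
        det, man = det_map[raw_det], man_map[raw_man]
        if best_det is None or det_rank[det] > det_rank[best_det]:
            best_det = det
        if best_man is None or man_rank[man] > man_rank[best_man]:
            best_man = man
    if best_det is None:
        return "none", "none", "none"
    return best_det, best_man, f"{best_det}-{best_man}"


def assign_sdh_subtype(
    interval: Interval,
    episodes,
    min_duration: pd.Timedelta = SDH_MIN_DURATION,
    step: pd.Timedelta = STEP,
) -> str:
    """Dominant SDH severity stratum within an interval.

    Each episode is clipped to [start, end); its covered duration within
    the interval (clipped readings x step) must reach ``min_duration`` to
    count. Among qualifying episodes the lowest clipped nadir determines
    the subtype; "none" if no episode qualifies.
    """
    best = "none"
    for ep in episodes:
        mask = (ep.times >= interval.start) & (ep.times < interval.end)
        n = int(mask.sum())
        if n * step < min_duration:
            continue
        sub = subtype_from_nadir(float(ep.values[np.asarray(mask)].min()))
        if SDH_SEVERITY[sub] > SDH_SEVERITY[best]:
            best = sub
    return best


def classify_interval(
    interval: Interval,
    episodes,
    drop_severe: bool = True,
    **coding_kwargs,
) -> IntervalClassification:
    """Classify one valid interval from its PRH report(s) and SDH episodes."""
    reports = []
    if interval.reporting is not None and interval.reporting.prh is not None:
        reports = [interval.reporting.prh]
    if drop_severe:
        reports = [r for r in reports if not r.severe]
    det, man, combined = code_prh_subtypes(reports, **coding_kwargs)
    sdh = assign_sdh_subtype(interval, episodes)
    return IntervalClassification(
        category=classify_category(det != "none", sdh != "none"),
        prh_detection=det,
        prh_management=man,
        prh_combined=combined,
        sdh_subtype=sdh,
    )


def classification_frame(rows) -> pd.DataFrame:
    """Tidy classified-interval table from (Interval, IntervalClassification) pairs."""
    records = [
        {
            "participant_id": iv.participant_id,
            "date": iv.date,
            "phase": iv.phase,
            "start": iv.start,
            "end": iv.end,
            "pct_sensor_missing": iv.pct_sensor_missing,
            "category": cls.category,
            "prh_detection": cls.prh_detection,
            "prh_management": cls.prh_management,
            "prh_combined": cls.prh_combined,
            "sdh_subtype": cls.sdh_subtype,
        }
        for iv, cls in rows
    ]
    return pd.DataFrame(
        records,
        columns=[
            "participant_id",
            "date",
            "phase",
            "start",
            "end",
            "pct_sensor_missing",
            "category",
            "prh_detection",
            "prh_management",
            "prh_combined",
            "sdh_subtype",
        ],
    )
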