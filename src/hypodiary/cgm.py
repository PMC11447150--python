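"""Continuous glucose monitor (CGM) trace handling.

A blinded sensor records interstitial glucose (mmol/l) at a nominal 5-min
cadence. This module loads per-participant traces from delimited text,
snaps samples onto the 5-min grid without interpolating, detects
sensor-detected hypoglycaemia (SDH) episodes -- maximal runs of readings
below 3.9 mmol/l sustained for at least 15 min -- and computes the standard
time-in-range / above / below summary.

Duration convention: each 5-min reading stands for 5 min of coverage, so
the >=15 min rule is >=3 consecutive sub-threshold readings. A run is
broken by a reading at or above the threshold or by a gap longer than
10 min (shorter gaps are bridged but contribute no covered duration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractViolation, UndefinedStatisticError

#: Nominal sampling step of the blinded sensor.
STEP = pd.Timedelta(minutes=5)

#: Hypoglycaemia threshold (mmol/l): readings strictly below count as "below range".
SDH_THRESHOLD = 3.9

#: Upper bound of the target range (mmol/l), inclusive.
TAR_THRESHOLD = 10.0

#: Minimum sustained duration for an SDH episode.
SDH_MIN_DURATION = pd.Timedelta(minutes=15)

#: Gaps longer than this break an episode run; shorter gaps are bridged.
GAP_BRIDGE = pd.Timedelta(minutes=10)

#: Severity subtype labels, mildest to most severe.
SDH_SUBTYPES = ("SDH_3.9", "SDH_3.0", "SDH_2.2")

_EPOCH = pd.Timestamp("1970-01-01")


def subtype_from_nadir(nadir: float) -> str:
    """Severity stratum of an episode from its lowest glucose reading.

    <3.9 but >=3.0 -> SDH_3.9; <3.0 but >2.2 -> SDH_3.0; <=2.2 -> SDH_2.2.
    """
    if nadir <= 2.2:
        return "SDH_2.2"
    if nadir < 3.0:
        return "SDH_3.0"
    if nadir < SDH_THRESHOLD:
        return "SDH_3.9"
    raise ValueError(f"nadir {nadir} is not below the {SDH_THRESHOLD} mmol/l threshold")


@dataclass(frozen=True)
class GlucoseTrace:
    """One participant's raw timestamped glucose series (mmol/l)."""

    participant_id: str
    times: pd.DatetimeIndex
    glucose: np.ndarray
    nominal_step: pd.Timedelta = STEP

    def __post_init__(self):
        times = pd.DatetimeIndex(self.times)
        glucose = np.asarray(self.glucose, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "glucose", glucose)
        if len(times) != len(glucose):
            raise ValueError("times and glucose must have equal length")
        if len(times) > 1 and not (times[1:] > times[:-1]).all():
            raise ValueError("timestamps must be strictly increasing")
        if len(glucose) and (~np.isfinite(glucose) | (glucose <= 0)).any():
            raise ValueError("glucose values must be finite and positive")
        if self.nominal_step <= pd.Timedelta(0):
            raise ValueError("nominal_step must be positive")

    def __len__(self) -> int:
        return len(self.glucose)


@dataclass(frozen=True)
class RegularTrace:
    """A trace snapped onto the nominal 5-min grid; NaN marks missing slots."""

    participant_id: str
    start: pd.Timestamp  # grid-aligned timestamp of the first slot
    glucose: np.ndarray  # NaN where no sample fell within +-2.5 min of the slot
    step: pd.Timedelta = STEP
    n_conflicts: int = 0  # samples discarded because two mapped to one slot

    @property
    def grid(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.glucose), freq=self.step)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.glucose)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def __len__(self) -> int:
        return len(self.glucose)


@dataclass(frozen=True)
class SDHEpisode:
    """A maximal sustained run of sub-threshold readings.

    ``times``/``values`` hold the individual grid readings of the run so a
    downstream consumer can clip the episode to an exposure interval and
    recompute covered duration and nadir within it.
    """

    start: pd.Timestamp
    end: pd.Timestamp
    nadir: float
    subtype: str
    times: pd.DatetimeIndex
    values: np.ndarray

    @property
    def duration(self) -> pd.Timedelta:
        return self.end - self.start

    @property
    def n_readings(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GlycaemicSummary:
    """Percentages of non-missing readings in / above / below 3.9-10 mmol/l."""

    pct_in_range: float
    pct_above: float
    pct_below: float


@dataclass
class LoadReport:
    """Row-level accounting for a delimited-file load."""

    n_rows: int = 0
    n_loaded: int = 0
    reasons: dict = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return int(sum(self.reasons.values()))

    def count(self, reason: str, n: int = 1) -> None:
        if n:
            self.reasons[reason] = self.reasons.get(reason, 0) + int(n)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_loaded": self.n_loaded,
            "n_rejected": self.n_rejected,
            "reasons": dict(self.reasons),
        }


DEFAULT_TRACE_DIALECT = {
    "participant": "participant_id",
    "timestamp": "timestamp",
    "glucose": "glucose",
    "sep": ",",
}


def read_traces(path, dialect: dict | None = None) -> tuple[dict, LoadReport]:
    """Load per-participant glucose traces from a delimited text file.

    Returns a ``{participant_id: GlucoseTrace}`` mapping plus a
    :class:`LoadReport`. Rows with unparseable timestamps or non-positive
    glucose are dropped and counted; duplicate timestamps within a
    participant keep the first occurrence.
    """
    d = {**DEFAULT_TRACE_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep=d["sep"])
    report = LoadReport(n_rows=len(df))
    for key in ("participant", "timestamp", "glucose"):
        if d[key] not in df.columns:
            raise ConfigurationError(
                f"column {d[key]!r} (mapped from {key!r}) not found in {path}"
            )
    if df.empty:
        import warnings

        warnings.warn(f"glucose file {path} contains no rows", stacklevel=2)
        return {}, report

    ts = pd.to_datetime(df[d["timestamp"]], errors="coerce", format="ISO8601")
    glu = pd.to_numeric(df[d["glucose"]], errors="coerce")
    bad_ts = ts.isna()
    bad_glu = ~bad_ts & (glu.isna() | (glu <= 0) | ~np.isfinite(glu.fillna(np.nan)))
    report.count("unparseable_timestamp", int(bad_ts.sum()))
    report.count("nonpositive_or_missing_glucose", int(bad_glu.sum()))
    keep = ~(bad_ts | bad_glu)

    clean = pd.DataFrame(
        {"pid": df[d["participant"]].astype(str), "ts": ts, "glu": glu}
    )[keep]
    traces: dict[str, GlucoseTrace] = {}
    for pid, sub in clean.groupby("pid", sort=True):
        sub = sub.sort_values("ts", kind="stable")
        dup = sub["ts"].duplicated(keep="first")
        report.count("duplicate_timestamp", int(dup.sum()))
        sub = sub[~dup]
        traces[pid] = GlucoseTrace(
            participant_id=pid,
            times=pd.DatetimeIndex(sub["ts"]),
            glucose=sub["glu"].to_numpy(),
        )
    report.n_loaded = int(sum(len(t) for t in traces.values()))
    return traces, report


def regularize(trace: GlucoseTrace, step: pd.Timedelta = STEP) -> RegularTrace:
    """Snap samples to the wall-clock 5-min grid (nearest slot, ties earlier).

    Slots with no sample within half a step are missing (NaN). Glucose is
    never interpolated. If two samples map to one slot the temporally
    closest wins and the conflict is counted.
    """
    step_s = int(step.total_seconds())
    sec = ((trace.times - _EPOCH) // pd.Timedelta(seconds=1)).to_numpy()
    q, r = np.divmod(sec, step_s)
    slot = q + (r > step_s // 2)  # a sample exactly halfway rounds down
    offset = np.abs(sec - slot * step_s)

    # resolve slot conflicts: smallest offset wins, earlier sample on ties
    order = np.lexsort((np.arange(len(slot)), offset, slot))
    slot_sorted = slot[order]
    first = np.ones(len(slot_sorted), dtype=bool)
    first[1:] = slot_sorted[1:] != slot_sorted[:-1]
    kept = order[first]
    n_conflicts = len(slot) - len(kept)

    lo, hi = int(slot.min()), int(slot.max())
    values = np.full(hi - lo + 1, np.nan)
    values[slot[kept] - lo] = trace.glucose[kept]
    return RegularTrace(
        participant_id=trace.participant_id,
        start=_EPOCH + pd.Timedelta(seconds=lo * step_s),
        glucose=values,
        step=step,
        n_conflicts=n_conflicts,
    )


def detect_sdh_episodes(
    trace: RegularTrace,
    threshold: float = SDH_THRESHOLD,
    min_duration: pd.Timedelta = SDH_MIN_DURATION,
    gap_bridge: pd.Timedelta = GAP_BRIDGE,
) -> list[SDHEpisode]:
    """Detect SDH episodes on a regularised trace.

    An episode is a maximal run of non-missing readings strictly below
    ``threshold`` whose covered duration (readings x step) reaches
    ``min_duration``. The run ends at a reading >= threshold or at a gap
    longer than ``gap_bridge``; shorter gaps are bridged.
    """
    if not isinstance(trace, RegularTrace):
        raise ContractViolation("detect_sdh_episodes requires a regularised trace")
    step = trace.step
    max_bridge = int(gap_bridge / step)  # missing slots that may be bridged
    min_readings = math.ceil(min_duration / step)
    g = trace.glucose
    grid = trace.grid

    episodes: list[SDHEpisode] = []
    run: list[int] = []
    gap = 0

    def close() -> None:
        if len(run) >= min_readings:
            idx = np.asarray(run)
            vals = g[idx]
            nadir = float(vals.min())
            episodes.append(
                SDHEpisode(
                    start=grid[idx[0]],
                    end=grid[idx[-1]] + step,
                    nadir=nadir,
                    subtype=subtype_from_nadir(nadir),
                    times=grid[idx],
                    values=vals,
                )
            )

    for i, v in enumerate(g):
        if np.isnan(v):
            gap += 1
            if gap > max_bridge and run:
                close()
                run = []
        elif v < threshold:
            run.append(i)
            gap = 0
        else:
            close()
            run = []
            gap = 0
    close()
    return episodes


def glycaemic_summary(trace) -> GlycaemicSummary:
    """Time-in-range summary over non-missing readings.

    Accepts a :class:`GlucoseTrace`, :class:`RegularTrace` or a plain array.
    Boundary values 3.9 and 10.0 count as in range (inclusive).
    """
    if isinstance(trace, (GlucoseTrace, RegularTrace)):
        values = trace.glucose
    else:
        values = np.asarray(trace, dtype=float)
    values = values[~np.isnan(values)]
    n = len(values)
    if n == 0:
        raise UndefinedStatisticError("glycaemic summary undefined: no readings")
    below = int((values < SDH_THRESHOLD).sum())
    above = int((values > TAR_THRESHOLD).sum())
    in_range = n - below - above
    return GlycaemicSummary(
        pct_in_range=100.0 * in_range / n,
        pct_above=100.0 * above / n,
        pct_below=100.0 * below / n,
    )


def episodes_frame(episodes_by_participant: dict) -> pd.DataFrame:
    """Tidy episode table (participant, start, end, nadir, subtype)."""
    rows = [
        {
            "participant_id": pid,
            "start": ep.start,
            "end": ep.end,
            "nadir": ep.nadir,
            "subtype": ep.subtype,
        }
        for pid, eps in episodes_by_participant.items()
        for ep in eps
    ]
    return pd.DataFrame(
        rows, columns=["participant_id", "start", "end", "nadir", "subtype"]
    )
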