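"""Divide a participant's days into night/day exposure intervals.

Simulates a one-participant week of check-ins, shows how morning/evening
submission times delimit daytime and night-time intervals, and how the
30%-missing sensor-coverage rule marks validity.
"""

import pandas as pd

from hypodiary import (
    SimulationConfig,
    apply_coverage_filter,
    build_intervals,
    generate_study,
    read_checkins,
    read_traces,
    regularize,
)
import tempfile

cfg = SimulationConfig(n_type1=1, n_type2=0, n_days=7, seed=11)
with tempfile.TemporaryDirectory() as td:
    paths = generate_study(cfg).write(td)
    checkins, report = read_checkins(paths["checkins"])
    traces, _ = read_traces(paths["traces"])

print(f"loaded {len(checkins)} check-ins ({report.n_rejected} rejected)")
start = pd.Timestamp(cfg.start_date)
intervals = build_intervals(
    checkins, start_date=start, end_date=start + pd.Timedelta(days=cfg.n_days - 1)
)
regular = {pid: regularize(t) for pid, t in traces.items()}
apply_coverage_filter(intervals, regular)

for iv in intervals:
    print(
        f"{iv.date.date()} {iv.phase:5s}  {iv.start:%d %H:%M} -> {iv.end:%d %H:%M}  "
        f"missing {iv.pct_sensor_missing if iv.pct_sensor_missing is not None else float('nan'):5.1f}%  "
        f"{'valid' if iv.valid else 'INVALID (' + iv.reason + ')'}"
    )
print(
    "\nA night runs from the evening submission to the next morning submission"
    " (scheduled 21:00/07:00 stand in when a boundary check-in is missing);"
    " an interval without its reporting check-in, or with >30% of sensor"
    " slots missing, is excluded."
)
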