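"""Detect sensor-detected hypoglycaemia (SDH) episodes on a small CGM trace.

Builds a two-hour 5-min glucose series containing one sustained dip below
3.9 mmol/l, snaps it onto the nominal grid, runs the episode detector and
prints the episodes plus the time-in-range summary.
"""

import numpy as np
import pandas as pd

from hypodiary import GlucoseTrace, detect_sdh_episodes, glycaemic_summary, regularize

times = pd.date_range("2023-03-06 00:00", periods=24, freq="5min")
glucose = np.full(24, 5.5)
glucose[8:13] = [3.7, 3.3, 2.8, 3.2, 3.6]  # 25 min below threshold, nadir 2.8

trace = GlucoseTrace("P001", times, glucose)
regular = regularize(trace)
episodes = detect_sdh_episodes(regular)

print(f"{len(episodes)} episode(s) detected")
for ep in episodes:
    print(
        f"  {ep.start:%H:%M}-{ep.end:%H:%M}  nadir {ep.nadir:.1f} mmol/l  "
        f"subtype {ep.subtype}  ({ep.n_readings} readings)"
    )
s = glycaemic_summary(regular)
print(
    f"time in range {s.pct_in_range:.1f}% | above {s.pct_above:.1f}% | "
    f"below {s.pct_below:.1f}%"
)
print(
    "An episode needs >=15 min (three 5-min readings) strictly below 3.9 mmol/l;"
    " the subtype reflects the lowest reading reached."
)
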