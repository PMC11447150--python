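"""Classify intervals into hypoglycaemia categories A-D and tabulate shares.

Runs the generator + processing chain on a small cohort and prints the
category frequency table per cohort and phase, next to the generator's
ground-truth shares.
"""

import pandas as pd

from hypodiary import (
    SimulationConfig,
    apply_coverage_filter,
    build_intervals,
    classify_interval,
    detect_sdh_episodes,
    frequency_table,
    generate_study,
    read_checkins,
    read_traces,
    regularize,
    truth_report,
)
from hypodiary.classify import classification_frame
import tempfile

cfg = SimulationConfig(n_type1=15, n_type2=15, n_days=14, seed=4)
study = generate_study(cfg)
with tempfile.TemporaryDirectory() as td:
    paths = study.write(td)
    checkins, _ = read_checkins(paths["checkins"])
    traces, _ = read_traces(paths["traces"])

regular = {pid: regularize(t) for pid, t in traces.items()}
episodes = {pid: detect_sdh_episodes(rt) for pid, rt in regular.items()}
start = pd.Timestamp(cfg.start_date)
intervals = build_intervals(
    checkins, start_date=start, end_date=start + pd.Timedelta(days=cfg.n_days - 1)
)
apply_coverage_filter(intervals, regular)

pairs = [
    (iv, classify_interval(iv, episodes.get(iv.participant_id, [])))
    for iv in intervals
    if iv.valid
]
classified = classification_frame(pairs)
cohort = {pid: ("type1" if pid.startswith("T1") else "type2") for pid in regular}
classified.insert(1, "cohort", classified["participant_id"].map(cohort))

freq = frequency_table(classified)
print(freq.pivot_table(index=["cohort", "phase"], columns="category",
                       values="pct", fill_value=0.0).round(1))
print("\ngenerator truth (night, pooled):")
tr = truth_report(study.truth)["category_frequencies"]
night = tr[tr["phase"] == "night"].groupby("true_category")["n"].sum()
print((100 * night / night.sum()).round(1).to_string())
print(
    "\nA = no hypoglycaemia, B = sensor-only, C = person-reported-only,"
    " D = both. Shares are over valid intervals and sum to 100 per cell."
)
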