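"""Independent reference implementations used only to cross-check the package.

Two deliberately different formulations of sustained-hypoglycaemia episode
detection:

* :func:`brute_force_episodes` enumerates every (start, end) reading pair,
  tests qualification directly, and keeps maximal windows -- O(n^2) and
  usable only on short traces;
* :func:`segment_scan_episodes` splits the trace at "breakers"
  (at-or-above-threshold readings and gaps too long to bridge) and trims
  each remaining segment to its first/last reading.

Both return ``(first_reading_index, last_reading_index, nadir)`` tuples.
"""

import math

import numpy as np

THRESHOLD = 3.9
MIN_READINGS = 3  # >=15 min at 5 min per reading
MAX_BRIDGE = 2  # missing slots bridgeable (10 min)


def brute_force_episodes(
    values, threshold=THRESHOLD, min_readings=MIN_READINGS, max_bridge=MAX_BRIDGE
):
    values = [float(v) for v in values]
    n = len(values)

    def is_reading(i):
        return not math.isnan(values[i])

    def below(i):
        return is_reading(i) and values[i] < threshold

    def qualifies(i, j):
        if not (below(i) and below(j)):
            return False
        gap = 0
        for k in range(i, j + 1):
            if not is_reading(k):
                gap += 1
                if gap > max_bridge:
                    return False
            else:
                if values[k] >= threshold:
                    return False
                gap = 0
        return True

    windows = [(i, j) for i in range(n) for j in range(i, n) if qualifies(i, j)]
    maximal = [
        (i, j)
        for i, j in windows
        if not any((a <= i and j <= b and (a, b) != (i, j)) for a, b in windows)
    ]
    episodes = []
    for i, j in sorted(maximal):
        readings = [values[k] for k in range(i, j + 1) if below(k)]
        if len(readings) >= min_readings:
            episodes.append((i, j, min(readings)))
    return episodes


def segment_scan_episodes(
    values, threshold=THRESHOLD, min_readings=MIN_READINGS, max_bridge=MAX_BRIDGE
):
    values = np.asarray(values, dtype=float)
    n = len(values)
    is_reading = ~np.isnan(values)
    breaker = np.zeros(n, dtype=bool)
    breaker[is_reading & (values >= threshold)] = True
    missing_idx = np.flatnonzero(~is_reading)
    if len(missing_idx):
        for run in np.split(missing_idx, np.flatnonzero(np.diff(missing_idx) > 1) + 1):
            if len(run) > max_bridge:
                breaker[run] = True

    episodes = []
    for seg in np.split(np.arange(n), np.flatnonzero(breaker) + 1):
        seg = seg[~breaker[seg]]
        readings = seg[is_reading[seg]]
        if len(readings) >= min_readings:
            episodes.append(
                (int(readings[0]), int(readings[-1]), float(values[readings].min()))
            )
    return episodes


def episode_index_tuples(trace, episodes):
    """Map detector output onto (first_idx, last_idx, nadir) tuples."""
    out = []
    for ep in episodes:
        first = int((ep.times[0] - trace.start) / trace.step)
        last = int((ep.times[-1] - trace.start) / trace.step)
        out.append((first, last, float(ep.nadir)))
    return out
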