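"""Brute-force reference implementation of run/pause segmentation and the
five transport metrics, written as plain loops over speed sequences.

Used as an independent oracle: trajectories are built from per-interval
speed sequences (1-D monotone tracks, so Euclidean speeds equal the
sequence), and the reference results are compared with the package's
vectorized implementation over exhaustive enumerations.
"""

from __future__ import annotations

import numpy as np


def trajectory_from_speeds(speeds, dt=2.0):
    """1-D monotone track whose interval speeds equal ``speeds`` exactly."""
    from mtkit.transport import Trajectory

    x = [0.0]
    for s in speeds:
        x.append(x[-1] + s * dt)
    pos = np.column_stack([x, np.zeros(len(x))])
    return Trajectory("ref", np.arange(len(x)) * dt, pos, axis=(1.0, 0.0))


def ref_window(speeds, v_pause):
    idx = [i for i, s in enumerate(speeds) if s >= v_pause]
    if not idx:
        return None
    return idx[0], idx[-1]


def ref_segment(speeds, v_pause, lo, hi, min_pause_frames=1):
    labels = [speeds[i] >= v_pause for i in range(lo, hi + 1)]
    events = []
    i = 0
    while i < len(labels):
        if not labels[i]:
            j = i
            while j + 1 < len(labels) and not labels[j + 1]:
                j += 1
            if j - i + 1 >= min_pause_frames:
                events.append((lo + i, lo + j))
            i = j + 1
        else:
            i += 1
    return labels, events


def ref_metrics(speeds, dt=2.0, v_pause=0.2, min_pause_frames=1):
    """All five metrics by direct summation; None if never motile."""
    win = ref_window(speeds, v_pause)
    if win is None:
        return None
    lo, hi = win
    labels, events = ref_segment(speeds, v_pause, lo, hi, min_pause_frames)
    run_time = len(labels) * dt
    transp = [speeds[lo + k] for k, lab in enumerate(labels) if lab]
    run_length = sum(s * dt for s in transp)
    pausing_time = (len(labels) - len(transp)) * dt
    return {
        "window": win,
        "labels": labels,
        "n_pauses": len(events),
        "run_length": run_length,
        "run_time": run_time,
        "total_run_velocity": run_length / run_time,
        "transport_velocity": sum(transp) / len(transp),
        "pausing_time_total": pausing_time,
        "pausing_time_ratio": pausing_time / run_time,
        "pausing_frequency": len(events) / run_length if run_length > 0 else float("nan"),
    }
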