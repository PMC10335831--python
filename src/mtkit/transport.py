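"""Run/pause segmentation and transport statistics for tracked particles.

Implements the standard quantification of organelle transport used for
axonal mitochondria: per-interval instant speeds, a speed-threshold
segmentation into *transport* and *pause* states, a run window that strips
the stationary tails before movement starts and after it ends, and the
five per-particle metrics (run length, total run velocity, transport
velocity, pausing time ratio, pausing frequency), with anterograde /
retrograde assignment and group comparison.

Conventions
-----------
* An *interval* is the stretch between two consecutive frames; a track of
  ``n`` points has ``n - 1`` intervals.
* An interval is a *pause* iff its instant speed is strictly below
  ``v_pause`` (default 0.2 um/s); a speed exactly equal to the threshold
  counts as transported.
* A *pause event* is a maximal stretch of consecutive pause intervals of
  at least ``min_pause_frames`` intervals.
* The *run window* spans from the first to the last interval at or above
  ``v_pause``; leading/trailing stationary tails are excluded from run
  time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sstats

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    NeverMotileError,
    TrajectoryError,
)

__all__ = [
    "Trajectory",
    "SegmentationParams",
    "RunMetrics",
    "PauseEvent",
    "instant_velocity",
    "detect_run_window",
    "segment_run",
    "is_motile",
    "compute_metrics",
    "assign_direction",
    "trajectory_kymograph",
    "compare_groups",
    "sem",
]

_UNIFORM_DT_TOL = 1e-6


@dataclass(frozen=True)
class Trajectory:
    """One particle's time-ordered positions.

    Parameters
    ----------
    track_id
        Identifier carried through to output tables.
    times
        Acquisition times in seconds, strictly increasing, uniformly spaced
        (within 1e-6 s).
    positions
        ``(n, 2)`` array of positions in micrometers.
    axis
        Optional unit 2-vector pointing in the anterograde direction.
    """

    track_id: str
    times: np.ndarray
    positions: np.ndarray
    axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if positions.ndim != 2 or positions.shape[1] != 2:
            raise TrajectoryError(
                f"track {self.track_id!r}: positions must be (n, 2), got {positions.shape}"
            )
        if times.shape[0] != positions.shape[0]:
            raise TrajectoryError(
                f"track {self.track_id!r}: {times.shape[0]} times vs "
                f"{positions.shape[0]} positions"
            )
        if times.shape[0] < 2:
            raise TrajectoryError(f"track {self.track_id!r}: needs >= 2 points")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(positions)):
            raise TrajectoryError(f"track {self.track_id!r}: non-finite coordinates")
        dts = np.diff(times)
        if np.any(dts <= 0):
            k = int(np.argmax(dts <= 0))
            raise TrajectoryError(
                f"track {self.track_id!r}: times not strictly increasing at frame {k + 1}"
            )
        if np.any(np.abs(dts - dts[0]) > _UNIFORM_DT_TOL):
            k = int(np.argmax(np.abs(dts - dts[0]) > _UNIFORM_DT_TOL))
            raise TrajectoryError(
                f"track {self.track_id!r}: non-uniform frame interval at frame {k + 1} "
                f"(dt={dts[k]:.6g} s vs {dts[0]:.6g} s)"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        if self.axis is not None:
            ax = np.asarray(self.axis, dtype=float).ravel()
            if ax.shape != (2,) or not np.all(np.isfinite(ax)):
                raise ConfigurationError("axis must be a finite 2-vector")
            n = float(np.hypot(ax[0], ax[1]))
            if n == 0.0:
                raise ConfigurationError("axis must have nonzero length")
            object.__setattr__(self, "axis", ax / n)

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def n_intervals(self) -> int:
        return self.positions.shape[0] - 1


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds of the run/pause segmentation.

    ``v_pause``: instant speed below which an interval is a pause (um/s).
    ``d_min_motile``: a particle is motile iff its run length strictly
    exceeds this distance (um).  ``min_pause_frames``: minimum number of
    consecutive sub-threshold intervals forming a pause event.
    """

    v_pause: float = 0.2
    d_min_motile: float = 2.0
    min_pause_frames: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.v_pause) or self.v_pause <= 0:
            raise ConfigurationError(f"v_pause must be > 0, got {self.v_pause}")
        if not np.isfinite(self.d_min_motile) or self.d_min_motile < 0:
            raise ConfigurationError(f"d_min_motile must be >= 0, got {self.d_min_motile}")
        if self.min_pause_frames < 1:
            raise ConfigurationError(
                f"min_pause_frames must be >= 1, got {self.min_pause_frames}"
            )


@dataclass(frozen=True)
class PauseEvent:
    """A maximal stretch of pause intervals, indices inclusive (interval units)."""

    start: int
    stop: int

    @property
    def n_intervals(self) -> int:
        return self.stop - self.start + 1


@dataclass(frozen=True)
class RunMetrics:
    """Per-particle transport statistics over the run window."""

    track_id: str
    run_length: float  # um, sum of transport-interval displacements
    run_time: float  # s, transporting + pausing time
    total_run_velocity: float  # um/s, run_length / run_time
    transport_velocity: float  # um/s, mean instant speed over transport intervals
    transporting_time: float  # s
    pausing_time_total: float  # s
    pausing_time_ratio: float  # in [0, 1]
    n_pauses: int
    pausing_frequency: float  # pauses per um of run length
    direction: Literal["anterograde", "retrograde", "ambiguous", "unknown"] = "unknown"


def instant_velocity(traj: Trajectory) -> np.ndarray:
    """Per-interval instant speed: Euclidean inter-frame displacement / dt (um/s)."""
    disp = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    return disp / traj.dt


def detect_run_window(
    traj: Trajectory, params: SegmentationParams = SegmentationParams()
) -> tuple[int, int]:
    """Locate the run window: (first, last) interval with speed >= ``v_pause``.

    The window excludes the stationary tails before movement starts and
    after it terminates.  Indices are inclusive interval indices.

    Raises
    ------
    NeverMotileError
        If no interval ever reaches ``v_pause``.
    """
    speeds = instant_velocity(traj)
    supra = np.flatnonzero(speeds >= params.v_pause)
    if supra.size == 0:
        raise NeverMotileError(
            f"track {traj.track_id!r}: no interval reaches {params.v_pause} um/s"
        )
    return int(supra[0]), int(supra[-1])


def segment_run(
    traj: Trajectory,
    params: SegmentationParams = SegmentationParams(),
    window: tuple[int, int] | None = None,
) -> tuple[np.ndarray, list[PauseEvent]]:
    """Label each interval inside the run window as transport or pause.

    Returns
    -------
    labels
        Boolean array over the window's intervals; True = transport
        (speed >= ``v_pause``), False = pause.
    events
        Maximal pause stretches of at least ``min_pause_frames`` intervals,
        as inclusive interval-index ranges in trajectory coordinates.
    """
    speeds = instant_velocity(traj)
    if window is None:
        window = (0, speeds.size - 1)
    lo, hi = window
    if not (0 <= lo <= hi < speeds.size):
        raise TrajectoryError(f"window {window} out of range for {speeds.size} intervals")
    labels = speeds[lo : hi + 1] >= params.v_pause
    events: list[PauseEvent] = []
    i = 0
    n = labels.size
    while i < n:
        if not labels[i]:
            j = i
            while j + 1 < n and not labels[j + 1]:
                j += 1
            if j - i + 1 >= params.min_pause_frames:
                events.append(PauseEvent(start=lo + i, stop=lo + j))
            i = j + 1
        else:
            i += 1
    return labels, events


def is_motile(traj: Trajectory, params: SegmentationParams = SegmentationParams()) -> bool:
    """True iff the summed transport-interval displacement strictly exceeds
    ``d_min_motile`` (the 'more than 2 um' motility filter)."""
    try:
        window = detect_run_window(traj, params)
    except NeverMotileError:
        return False
    labels, _ = segment_run(traj, params, window)
    speeds = instant_velocity(traj)[window[0] : window[1] + 1]
    run_length = float(np.sum(speeds[labels]) * traj.dt)
    return run_length > params.d_min_motile


def compute_metrics(
    traj: Trajectory,
    params: SegmentationParams = SegmentationParams(),
    direction: str = "unknown",
) -> RunMetrics:
    """Compute the five transport statistics over the detected run window.

    run_length = sum of distances traveled in the transporting state;
    total_run_velocity = run_length / run_time where run_time is pausing
    plus transporting time; transport_velocity = mean instant speed of the
    transported intervals; pausing_time_ratio = total pausing time /
    run_time; pausing_frequency = number of pause events / run_length.
    """
    window = detect_run_window(traj, params)
    labels, events = segment_run(traj, params, window)
    dt = traj.dt
    speeds = instant_velocity(traj)[window[0] : window[1] + 1]
    run_time = labels.size * dt
    transporting_time = int(np.sum(labels)) * dt
    pausing_time = run_time - transporting_time
    run_length = float(np.sum(speeds[labels]) * dt)
    transport_velocity = float(np.mean(speeds[labels]))  # window has >= 1 transport interval
    n_pauses = len(events)
    if run_length > 0:
        pausing_frequency = n_pauses / run_length
    else:
        warnings.warn(
            f"track {traj.track_id!r}: zero run length; pausing_frequency undefined",
            stacklevel=2,
        )
        pausing_frequency = float("nan")
    return RunMetrics(
        track_id=traj.track_id,
        run_length=run_length,
        run_time=run_time,
        total_run_velocity=run_length / run_time,
        transport_velocity=transport_velocity,
        transporting_time=transporting_time,
        pausing_time_total=pausing_time,
        pausing_time_ratio=pausing_time / run_time,
        n_pauses=n_pauses,
        pausing_frequency=pausing_frequency,
        direction=direction,  # type: ignore[arg-type]
    )


def assign_direction(
    traj: Trajectory,
    axis: np.ndarray | None = None,
    ambiguous_min_um: float = 0.5,
) -> str:
    """Classify a track as anterograde or retrograde by the sign of its net
    displacement projected on the anterograde axis.

    Net projected displacement smaller than ``ambiguous_min_um`` in
    magnitude yields ``"ambiguous"``.
    """
    if axis is None:
        axis = traj.axis
    if axis is None:
        raise ConfigurationError("no anterograde axis provided")
    ax = np.asarray(axis, dtype=float).ravel()
    norm = float(np.hypot(ax[0], ax[1]))
    if norm == 0.0 or not np.all(np.isfinite(ax)):
        raise ConfigurationError("axis must be a finite nonzero 2-vector")
    ax = ax / norm
    net = float(np.dot(traj.positions[-1] - traj.positions[0], ax))
    if abs(net) < ambiguous_min_um:
        return "ambiguous"
    return "anterograde" if net > 0 else "retrograde"


@dataclass(frozen=True)
class TrajectoryKymographLine:
    """Distance-vs-time polyline for a single track, with pause annotations."""

    times: np.ndarray  # s, one entry per frame
    distance: np.ndarray  # um, cumulative signed path coordinate
    pause_spans: list[tuple[float, float]]  # (t_start, t_end) of each pause event


def trajectory_kymograph(
    traj: Trajectory,
    params: SegmentationParams = SegmentationParams(),
) -> TrajectoryKymographLine:
    """Cumulative signed path coordinate vs time for kymograph-style plots.

    Displacements are signed by their projection onto the track axis when
    one is present (so reversals show as sign changes), otherwise unsigned
    path length is accumulated.  Pause events from :func:`segment_run` over
    the full track are annotated as time spans (the arrowhead positions).
    """
    steps = np.diff(traj.positions, axis=0)
    if traj.axis is not None:
        proj = steps @ traj.axis
        signed = np.where(proj >= 0, 1.0, -1.0) * np.linalg.norm(steps, axis=1)
    else:
        signed = np.linalg.norm(steps, axis=1)
    distance = np.concatenate([[0.0], np.cumsum(signed)])
    _, events = segment_run(traj, params)
    spans = [
        (float(traj.times[ev.start]), float(traj.times[ev.stop + 1])) for ev in events
    ]
    return TrajectoryKymographLine(times=traj.times.copy(), distance=distance, pause_spans=spans)


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean, sd (ddof=1) / sqrt(n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("SEM needs n >= 2")
    return float(np.std(arr, ddof=1) / np.sqrt(arr.size))


# Exact Mann-Whitney below this group size (exact null enumeration).
_EXACT_MW_MAX_N = 8


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    test: Literal["t", "mannwhitney"] = "t",
) -> dict:
    """Two-group comparison: means, SEMs and a two-sided p-value.

    ``test='t'`` runs Student's unpaired two-tailed t-test;
    ``test='mannwhitney'`` the Mann-Whitney U test, computed exactly when
    the smaller group has at most 8 observations (and no ties), otherwise
    with the normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if test == "t":
        tres = _sstats.ttest_ind(a, b)
        p = float(tres.pvalue)
        stat = float(tres.statistic)
        if np.isnan(p) and np.array_equal(np.sort(a), np.sort(b)):
            # zero-variance identical groups: no evidence of difference
            p, stat = 1.0, 0.0
    elif test == "mannwhitney":
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (min(a.size, b.size) <= _EXACT_MW_MAX_N and not has_ties) else "asymptotic"
        mres = _sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        p = float(mres.pvalue)
        stat = float(mres.statistic)
    else:
        raise ConfigurationError(f"unknown test {test!r}")
    return {
        "mean_a": float(np.mean(a)),
        "mean_b": float(np.mean(b)),
        "sem_a": sem(a),
        "sem_b": sem(b),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "statistic": stat,
        "p_value": min(p, 1.0),
        "test": test,
    }


def metrics_table(metrics: Sequence[RunMetrics]):
    """Collect RunMetrics into a pandas DataFrame (one row per track)."""
    import pandas as pd

    return pd.DataFrame([m.__dict__ for m in metrics])


def compare_metric_groups(
    metrics_a: Sequence[RunMetrics],
    metrics_b: Sequence[RunMetrics],
    test: Literal["t", "mannwhitney"] = "t",
    fields: Sequence[str] = (
        "run_length",
        "total_run_velocity",
        "transport_velocity",
        "pausing_time_ratio",
        "pausing_frequency",
    ),
) -> dict:
    """Per-metric group comparison over the five transport statistics."""
    out = {}
    for f in fields:
        va = [getattr(m, f) for m in metrics_a]
        vb = [getattr(m, f) for m in metrics_b]
        out[f] = compare_groups(va, vb, test=test)
    return out
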