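"""Two-state (transport/pause) trajectory simulator.

Particles alternate between a *transport* state, in which they advance
along a 1-D track coordinate with a Gaussian speed, and a *pause* state,
in which the underlying position does not move.  State switching is a
two-state Markov chain with per-frame entry/exit probabilities, so the
stationary pause probability is ``p_pause / (p_pause + p_resume)``.
Positions are embedded in 2-D along a unit axis and blurred with isotropic
Gaussian localization noise, which is the only source of apparent motion
while paused.  Defaults mirror spinning-disk imaging of axonal mitochondria:
0.5 frames/s for 3 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ..errors import ConfigurationError
from ..transport import Trajectory

__all__ = ["TrajectorySimConfig", "SimulatedTrack", "simulate_trajectories"]


def _check_prob(name: str, p: float) -> None:
    if not np.isfinite(p) or not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Parameters of the two-state transport simulator.

    Speeds in um/s, times in s, localization noise in um (per axis).
    ``p_pause_per_frame`` / ``p_resume_per_frame`` are the per-interval
    probabilities of entering / leaving the pause state;
    ``reversal_prob_per_frame`` flips the direction of travel.
    """

    n_tracks: int = 50
    duration_s: float = 180.0
    frame_interval_s: float = 2.0  # 0.5 frames/s
    transport_speed_mean: float = 0.5
    transport_speed_sd: float = 0.1
    p_pause_per_frame: float = 0.1
    p_resume_per_frame: float = 0.5
    localization_sd: float = 0.05
    direction: Literal["anterograde", "retrograde"] = "anterograde"
    reversal_prob_per_frame: float = 0.0
    seed: int = 0
    axis: tuple[float, float] = (1.0, 0.0)
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise ConfigurationError(f"n_tracks must be >= 1, got {self.n_tracks}")
        for name in ("duration_s", "frame_interval_s", "transport_speed_mean"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigurationError(f"{name} must be finite and > 0, got {v}")
        for name in ("transport_speed_sd", "localization_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v}")
        for name in ("p_pause_per_frame", "p_resume_per_frame", "reversal_prob_per_frame"):
            _check_prob(name, getattr(self, name))
        if self.direction not in ("anterograde", "retrograde"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        ax = np.asarray(self.axis, dtype=float)
        if ax.shape != (2,) or not np.all(np.isfinite(ax)) or np.hypot(*ax) == 0:
            raise ConfigurationError("axis must be a finite nonzero 2-vector")

    @property
    def n_frames(self) -> int:
        """Number of positions per track (duration / interval + 1)."""
        return int(round(self.duration_s / self.frame_interval_s)) + 1

    @property
    def stationary_pause_prob(self) -> float:
        """Stationary probability of the pause state of the two-state chain."""
        s = self.p_pause_per_frame + self.p_resume_per_frame
        if s == 0.0:
            return 0.0
        return self.p_pause_per_frame / s


@dataclass(frozen=True)
class SimulatedTrack:
    """A simulated trajectory plus its ground truth.

    ``transport_truth[i]`` is True when interval ``i`` was generated in the
    transport state; ``direction_truth`` is the configured direction.
    """

    trajectory: Trajectory
    transport_truth: np.ndarray
    direction_truth: str


def simulate_trajectories(cfg: TrajectorySimConfig) -> list[SimulatedTrack]:
    """Draw ``cfg.n_tracks`` trajectories with per-interval ground-truth labels.

    The initial state of each track is drawn from the chain's stationary
    distribution, so the expected fraction of pause-labeled intervals equals
    ``cfg.stationary_pause_prob`` at every frame.
    """
    rng = np.random.default_rng(cfg.seed)
    ax = np.asarray(cfg.axis, dtype=float)
    ax = ax / np.hypot(*ax)
    normal = np.array([-ax[1], ax[0]])
    dt = cfg.frame_interval_s
    n_iv = cfg.n_frames - 1
    sign0 = 1.0 if cfg.direction == "anterograde" else -1.0

    tracks: list[SimulatedTrack] = []
    for k in range(cfg.n_tracks):
        transporting = rng.random() >= cfg.stationary_pause_prob
        sign = sign0
        u = np.empty(cfg.n_frames)
        u[0] = 0.0
        truth = np.empty(n_iv, dtype=bool)
        for i in range(n_iv):
            truth[i] = transporting
            if transporting:
                speed = max(rng.normal(cfg.transport_speed_mean, cfg.transport_speed_sd), 0.0)
                u[i + 1] = u[i] + sign * speed * dt
            else:
                u[i + 1] = u[i]
            # state/direction updates apply from the next interval on
            if transporting:
                if rng.random() < cfg.p_pause_per_frame:
                    transporting = False
            else:
                if rng.random() < cfg.p_resume_per_frame:
                    transporting = True
            if cfg.reversal_prob_per_frame > 0 and rng.random() < cfg.reversal_prob_per_frame:
                sign = -sign
        noise = (
            rng.normal(0.0, cfg.localization_sd, size=(cfg.n_frames, 2))
            if cfg.localization_sd > 0
            else np.zeros((cfg.n_frames, 2))
        )
        positions = (
            np.asarray(cfg.origin, dtype=float)
            + u[:, None] * ax[None, :]
            + noise
        )
        times = np.arange(cfg.n_frames) * dt
        traj = Trajectory(
            track_id=f"sim-{cfg.seed}-{k:04d}",
            times=times,
            positions=positions,
            axis=ax,
        )
        tracks.append(
            SimulatedTrack(trajectory=traj, transport_truth=truth, direction_truth=cfg.direction)
        )
    return tracks
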