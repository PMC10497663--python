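"""Marker kinematics: Savitzky-Golay velocity, speed, quantity of motion.

Positions are in mm, time in seconds, velocities in mm/s.  The analysis
signal fed to the wavelet stage is the scalar speed (Euclidean norm of the
3-D velocity) of each performer's front-head marker; speed is used because,
unlike position, it does not depend on the performer's orientation in the
capture volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "MARKER_INVENTORY",
    "FRONT_HEAD",
    "MarkerTrajectory",
    "SpeedSeries",
    "QoMSeries",
    "sg_velocity",
    "speed",
    "quantity_of_motion",
]

#: The 14 head/upper-body markers tracked per performer: 3 on the head,
#: 2 on the back, 1 per shoulder/arm/wrist/hand, 1 on the chest.
MARKER_INVENTORY: tuple[str, ...] = (
    "front_head",
    "left_head",
    "right_head",
    "back_upper",
    "back_lower",
    "left_shoulder",
    "right_shoulder",
    "left_arm",
    "right_arm",
    "left_wrist",
    "right_wrist",
    "left_hand",
    "right_hand",
    "chest",
)

FRONT_HEAD = "front_head"

PERFORMERS = ("pianist", "singer")


def _is_hip_marker(name: str) -> bool:
    return "hip" in name.lower()


@dataclass(frozen=True)
class MarkerTrajectory:
    """One marker's uniformly sampled 3-D position series (mm)."""

    performer: str
    marker: str
    fs: float
    positions: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        if self.performer not in PERFORMERS:
            raise ValueError(f"performer must be one of {PERFORMERS}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions contain non-finite samples (gaps rejected)")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs


@dataclass(frozen=True)
class SpeedSeries:
    """Non-negative scalar speed (mm/s) of one marker."""

    performer: str
    marker: str
    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("speed values must be 1-D")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("speed must be finite and non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs


@dataclass(frozen=True)
class QoMSeries:
    """Quantity of motion: path length (mm) per whole second of recording,
    summed over markers (and performers when pooled upstream)."""

    duo_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("QoM must be non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def sg_velocity(
    traj: MarkerTrajectory, window: int = 25, polyorder: int = 3
) -> np.ndarray:
    """Smoothed per-axis first derivative via a Savitzky-Golay filter.

    Returns an (n, 3) velocity array in mm/s.  Boundary samples are
    evaluated from the same-order polynomial fitted over the edge window
    (no output truncation), so the velocity series stays aligned with the
    position timestamps.  Exact for polynomial positions of degree
    <= polyorder.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if len(traj) < window:
        raise ValueError(
            f"series of length {len(traj)} shorter than SG window {window}"
        )
    return savgol_filter(
        traj.positions,
        window_length=window,
        polyorder=polyorder,
        deriv=1,
        delta=1.0 / traj.fs,
        axis=0,
        mode="interp",
    )


def speed(vel3d: np.ndarray, *, performer: str, marker: str, fs: float) -> SpeedSeries:
    """Pointwise Euclidean norm of a 3-D velocity series."""
    vel3d = np.asarray(vel3d, dtype=float)
    if vel3d.ndim != 2 or vel3d.shape[1] != 3:
        raise ValueError("velocity must have shape (n, 3)")
    return SpeedSeries(
        performer=performer,
        marker=marker,
        fs=fs,
        values=np.linalg.norm(vel3d, axis=1),
    )


def traj_speed(traj: MarkerTrajectory, window: int = 25, polyorder: int = 3) -> SpeedSeries:
    """Convenience: SG velocity then Euclidean norm for one trajectory."""
    vel = sg_velocity(traj, window=window, polyorder=polyorder)
    return speed(vel, performer=traj.performer, marker=traj.marker, fs=traj.fs)


def quantity_of_motion(
    speeds: list[SpeedSeries], duo_id: str = "", mode: str = "path_length"
) -> QoMSeries:
    """Path length travelled per whole second, summed over markers.

    QoM(w) = sum over markers of sum over samples in second w of speed/fs,
    i.e. mm travelled during that second.  Pass the speed series of both
    performers' head/upper-body markers to obtain the duo-level series.
    Hip markers must be excluded upstream and are rejected here.

    ``mode="mean_speed"`` divides each window by its actual duration in
    samples instead (mean speed, mm/s); for integer sampling rates the two
    modes coincide numerically.
    """
    if mode not in ("path_length", "mean_speed"):
        raise ValueError("mode must be 'path_length' or 'mean_speed'")
    if not speeds:
        raise ValueError("need at least one speed series")
    hips = [s.marker for s in speeds if _is_hip_marker(s.marker)]
    if hips:
        raise ValueError(f"hip markers are excluded from QoM: {sorted(set(hips))}")
    fs = speeds[0].fs
    n = len(speeds[0])
    for s in speeds:
        if s.fs != fs or len(s) != n:
            raise ValueError("all speed series must share sampling rate and length")
    n_seconds = int(np.floor(n / fs))
    if n_seconds < 1:
        raise ValueError("recording shorter than one second")
    total = np.sum([s.values for s in speeds], axis=0)
    edges = (np.arange(n_seconds + 1) * fs).astype(int)
    sums = np.add.reduceat(total, edges[:-1])[:n_seconds]
    # reduceat includes samples up to the next edge; trim any overshoot in
    # the last window when fs is not integer
    if edges[-1] < n:
        sums[-1] = total[edges[-2]:edges[-1]].sum()
    if mode == "mean_speed":
        qom = sums / np.diff(edges)
    else:
        qom = sums / fs
    return QoMSeries(duo_id=duo_id, values=qom)
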