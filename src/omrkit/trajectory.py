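"""Tracker output -> continuous angular kinematics about the arena centre.

A video tracker reduces each frame to one (x, y) position of the fish.  For a
circular arena the natural coordinate is the planar angle about the arena
centre: unwrapping it yields a continuous angular position theta(t) whose
time derivative (signed angular velocity omega, deg/s) carries all the
information the optomotor parameters need.

Tracking dropouts are flagged, never silently dropped: short gaps (<=
``max_gap_s``) are bridged by linear interpolation of the unwrapped angle;
longer gaps split the track into independent analysis segments so that no
motion is fabricated across them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .arena import SessionConfig
from .errors import ConfigurationError, InsufficientDataError, TrackFormatError

__all__ = ["Trajectory", "AngularTrack", "read_track", "to_angular", "angular_velocity", "write_track"]

_FRAME_ALIASES = ("frame", "frame_idx", "frames", "f")
_TIME_ALIASES = ("t", "time", "time_s", "timestamp", "time_ms")
_X_ALIASES = ("x", "x_cm", "x_px", "pos_x", "xpos")
_Y_ALIASES = ("y", "y_cm", "y_px", "pos_y", "ypos")


@dataclass
class Trajectory:
    """Time-stamped x-y positions of one fish, with a per-sample validity mask.

    Coordinates are centimetres in the arena frame; timestamps are strictly
    increasing seconds from recording start.
    """

    fish_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.x) & np.isfinite(self.y)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("t, x, y, valid must have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise TrackFormatError("timestamps are not strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class AngularTrack:
    """Unwrapped angular representation of a trajectory.

    ``theta_deg`` is the cumulative (unwrapped) angular position in degrees;
    NaN runs mark gaps too long to interpolate.  ``omega_deg_s`` is filled by
    :func:`angular_velocity`.  ``segments`` are the contiguous non-NaN index
    slices that downstream operations may treat as independent.
    """

    t: np.ndarray
    theta_deg: np.ndarray
    r_cm: np.ndarray
    center: tuple[float, float]
    omega_deg_s: np.ndarray | None = None
    segments: list[slice] = field(default_factory=list)
    fps: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "theta_unwrapped_deg": self.theta_deg,
                "omega_deg_s": self.omega_deg_s if self.omega_deg_s is not None else np.nan,
                "r_cm": self.r_cm,
            }
        )


def _resolve_column(columns: list[str], aliases: tuple[str, ...]) -> str | None:
    lower = {c.lower().strip(): c for c in columns}
    for a in aliases:
        if a in lower:
            return lower[a]
    return None


def read_track(path: str | Path, config: SessionConfig) -> Trajectory:
    """Read a tracker CSV/TSV into a :class:`Trajectory`.

    Accepts a header with either a frame column (``frame``, ``f``, ...) or an
    explicit time column (``t``, ``time``, ``time_ms``, ...) plus ``x`` and
    ``y``.  Timestamps come from frame index / ``config.fps`` when only a
    frame column is present; an explicit time column is interpreted in
    ``config.time_unit`` (a ``time_ms`` column forces milliseconds).  Pixel
    coordinates are converted with ``config.px_per_cm`` when set.  Rows with
    missing coordinates are flagged invalid but kept, so sample count and
    timing are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise TrackFormatError("track file does not exist", path=path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise TrackFormatError("empty track file", path=path) from None
    if df.empty:
        raise TrackFormatError("track file has no data rows", path=path)

    cols = list(df.columns)
    xcol = _resolve_column(cols, _X_ALIASES)
    ycol = _resolve_column(cols, _Y_ALIASES)
    tcol = _resolve_column(cols, _TIME_ALIASES)
    fcol = _resolve_column(cols, _FRAME_ALIASES)
    if xcol is None or ycol is None:
        raise TrackFormatError(f"could not resolve x/y columns among {cols}", path=path)
    if tcol is None and fcol is None:
        raise TrackFormatError(f"no frame or time column among {cols}", path=path)

    x = pd.to_numeric(df[xcol], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df[ycol], errors="coerce").to_numpy(dtype=float)
    if tcol is not None:
        t = pd.to_numeric(df[tcol], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(t)):
            row = int(np.flatnonzero(~np.isfinite(t))[0])
            raise TrackFormatError("non-numeric timestamp", path=path, row=row)
        if tcol.lower().strip() == "time_ms" or config.time_unit == "ms":
            t = t / 1000.0
    else:
        frames = pd.to_numeric(df[fcol], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(frames)):
            row = int(np.flatnonzero(~np.isfinite(frames))[0])
            raise TrackFormatError("non-numeric frame index", path=path, row=row)
        t = frames / config.fps
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise TrackFormatError("non-monotone time", path=path, row=row)

    if config.px_per_cm is not None:
        x = x / config.px_per_cm
        y = y / config.px_per_cm

    return Trajectory(fish_id=config.fish_id or path.stem, t=t, x=x, y=y, fps=config.fps)


def write_track(traj: Trajectory, path: str | Path) -> None:
    """Write the canonical track form: ``frame,t,x,y`` CSV."""
    df = pd.DataFrame(
        {
            "frame": np.arange(len(traj)),
            "t": traj.t,
            "x": np.where(traj.valid, traj.x, np.nan),
            "y": np.where(traj.valid, traj.y, np.nan),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def to_angular(
    traj: Trajectory,
    center: tuple[float, float] | None = None,
    max_gap_s: float = 1.0,
) -> AngularTrack:
    """Convert a trajectory to an unwrapped angular track about ``center``.

    The centre defaults to the mean of all valid positions (the fish orbits
    the arena centre, so the track centroid is an adequate estimate when the
    tracker frame is uncalibrated).  Consecutive valid samples are assumed to
    differ by less than 180 deg of arc, the standard shortest-arc unwrapping
    assumption.  Gaps no longer than ``max_gap_s`` are linearly interpolated
    in unwrapped angle (and radius); longer gaps are left NaN and split the
    track into independent ``segments``.
    """
    valid = traj.valid
    if valid.sum() < 2:
        raise InsufficientDataError("need at least 2 valid samples to unwrap an angle")
    if center is None:
        center = (float(np.mean(traj.x[valid])), float(np.mean(traj.y[valid])))
    cx, cy = center

    n = len(traj)
    theta = np.full(n, np.nan)
    r = np.full(n, np.nan)
    iv = np.flatnonzero(valid)
    ang = np.arctan2(traj.y[iv] - cy, traj.x[iv] - cx)
    theta[iv] = np.degrees(np.unwrap(ang))
    r[iv] = np.hypot(traj.x[iv] - cx, traj.y[iv] - cy)

    # bridge short dropouts; long ones stay NaN and become segment breaks
    for a, b in zip(iv[:-1], iv[1:]):
        if b - a > 1:
            gap = traj.t[b] - traj.t[a]
            if gap <= max_gap_s:
                theta[a : b + 1] = np.interp(traj.t[a : b + 1], [traj.t[a], traj.t[b]], [theta[a], theta[b]])
                r[a : b + 1] = np.interp(traj.t[a : b + 1], [traj.t[a], traj.t[b]], [r[a], r[b]])

    segments = _nan_segments(theta)
    return AngularTrack(t=traj.t, theta_deg=theta, r_cm=r, center=center, segments=segments, fps=traj.fps)


def _nan_segments(a: np.ndarray) -> list[slice]:
    """Contiguous finite runs of ``a`` as slices."""
    finite = np.isfinite(a)
    segs: list[slice] = []
    i = 0
    n = len(a)
    while i < n:
        if finite[i]:
            j = i
            while j < n and finite[j]:
                j += 1
            segs.append(slice(i, j))
            i = j
        else:
            i += 1
    return segs


def _moving_average(a: np.ndarray, win: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if win <= 1 or len(a) < 2:
        return a.copy()
    half = win // 2
    c = np.concatenate(([0.0], np.cumsum(a)))
    n = len(a)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (c[hi + 1] - c[lo]) / (hi + 1 - lo)


def angular_velocity(
    track: AngularTrack,
    smooth_window_s: float | None = 0.5,
    breaks: Sequence[float] | None = None,
) -> AngularTrack:
    """Fill the signed angular-velocity series (deg/s) of an angular track.

    omega is the central finite difference of the unwrapped angle over time
    (one-sided at run endpoints), optionally smoothed by a centred moving
    average of ``smooth_window_s``; pass ``None`` to skip smoothing.

    ``breaks`` — typically the drum-reversal times — additionally split the
    differentiation runs so that samples on either side of a known stimulus
    discontinuity are never mixed into one estimate.
    """
    if smooth_window_s is not None and not smooth_window_s > 0:
        raise ConfigurationError("smooth_window_s must be > 0 (or None for no smoothing)")
    omega = np.full(len(track.t), np.nan)
    t = track.t
    dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
    win = 1
    if smooth_window_s is not None:
        win = max(1, int(round(smooth_window_s / dt)))

    for seg in track.segments:
        bounds = [seg.start, seg.stop]
        if breaks is not None:
            for b in breaks:
                k = int(np.searchsorted(t[seg], b) + seg.start)
                if seg.start < k < seg.stop:
                    bounds.append(k)
        bounds = sorted(set(bounds))
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < 2:
                continue  # isolated sample: no rate estimate, stays NaN
            w = np.gradient(track.theta_deg[a:b], t[a:b])
            if win > 1:
                w = _moving_average(w, win)
            omega[a:b] = w
    return replace(track, omega_deg_s=omega)
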