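"""The four optomotor-response parameters for one fish in one session.

Given an angular track and the drum schedule, a fish is "following" the
stripes at a sample when the drum is rotating, the fish's angular velocity
has the drum's sign, and its magnitude is at least a configurable fraction
of the drum speed; runs of following samples shorter than a minimum bout
length are discarded as incidental drift.  From the following series and the
raw angular increments the session is summarized by:

* **Delay** (s) — mean elapsed time after each drum reversal until the first
  following bout begins in that epoch; epochs with no bout contribute the
  epoch length as a cap, which keeps Delay finite for non-responding fish.
* **Duration** — time spent following divided by total rotation time.
* **Angular velocity** (deg/s) — mean |omega| over the whole rotation phase
  (not only following samples, so a moving but non-following fish still
  shows its locomotor speed).
* **Distance** (rounds) — net angle travelled in the drum direction / 360,
  with motion against the drum subtracted; computed from raw unwrapped-angle
  increments so it is exact regardless of smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .arena import Epoch, SessionConfig, build_schedule, drum_directions
from .errors import AlignmentError, ConfigurationError
from .trajectory import AngularTrack, Trajectory, angular_velocity, to_angular

__all__ = [
    "FollowingCriterion",
    "Bout",
    "OMRResult",
    "detect_following",
    "delay",
    "duration",
    "mean_angular_speed",
    "distance",
    "quantify_session",
    "results_to_frame",
]


@dataclass(frozen=True)
class FollowingCriterion:
    """Operational definition of "the fish follows the stripes".

    ``min_speed_fraction`` of the drum speed must be reached with the drum's
    sign for at least ``min_bout_s`` contiguous seconds.
    """

    min_speed_fraction: float = 0.25
    min_bout_s: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.min_speed_fraction < 1):
            raise ConfigurationError("min_speed_fraction must be in (0, 1)")
        if not self.min_bout_s > 0:
            raise ConfigurationError("min_bout_s must be > 0")


@dataclass(frozen=True)
class Bout:
    """One retained following bout: sample span [i0, i1] inclusive."""

    start_s: float
    end_s: float
    i0: int
    i1: int

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class OMRResult:
    """The four OMR parameters for one fish at one wavelength, plus QC."""

    fish_id: str
    wavelength_nm: float | None
    delay_s: float
    duration_ratio: float
    angular_velocity_deg_s: float
    distance_rounds: float
    per_epoch_delays: list[float] = field(default_factory=list)
    species: str | None = None
    qc_valid_fraction: float = 1.0
    qc_n_segments: int = 1
    qc_fail: bool = False

    def to_dict(self) -> dict:
        return {
            "fish_id": self.fish_id,
            "species": self.species,
            "wavelength_nm": self.wavelength_nm,
            "delay_s": self.delay_s,
            "duration_ratio": self.duration_ratio,
            "angular_velocity_deg_s": self.angular_velocity_deg_s,
            "distance_rounds": self.distance_rounds,
            "qc_valid_fraction": self.qc_valid_fraction,
            "qc_n_segments": self.qc_n_segments,
            "qc_fail": self.qc_fail,
        }


def results_to_frame(results: Sequence[OMRResult]) -> pd.DataFrame:
    """Tidy frame: one row per fish x wavelength."""
    return pd.DataFrame([r.to_dict() for r in results])


def _check_alignment(track: AngularTrack, epochs: Sequence[Epoch]) -> None:
    if len(track.t) == 0:
        raise AlignmentError("empty track")
    tol = 2.0 / (track.fps or 30.0)
    if track.t[0] > epochs[0].start_s + tol or track.t[-1] < epochs[-1].end_s - tol:
        raise AlignmentError(
            f"track [{track.t[0]:.3f}, {track.t[-1]:.3f}] s does not cover the "
            f"session [{epochs[0].start_s:.3f}, {epochs[-1].end_s:.3f}] s"
        )


def _sample_dt(t: np.ndarray) -> np.ndarray:
    """Time owned by each sample: [t_i, t_{i+1}); the last sample owns nothing."""
    dt = np.zeros_like(t)
    dt[:-1] = np.diff(t)
    return dt


def _rotation_mask(t: np.ndarray, epochs: Sequence[Epoch]) -> np.ndarray:
    rot = [ep for ep in epochs if ep.direction != 0]
    m = np.zeros(len(t), dtype=bool)
    for ep in rot:
        m |= (t >= ep.start_s) & (t < ep.end_s)
    return m


def detect_following(
    track: AngularTrack,
    epochs: Sequence[Epoch],
    crit: FollowingCriterion | None = None,
    drum_speed_deg_s: float | None = None,
) -> tuple[np.ndarray, list[Bout]]:
    """Per-sample following series and the retained bouts.

    ``drum_speed_deg_s`` defaults to the maximum |direction|-weighted drum
    speed implied by the epochs' schedule and must be given explicitly when
    epochs were built by hand.
    """
    crit = crit or FollowingCriterion()
    if track.omega_deg_s is None:
        raise ConfigurationError("angular velocity not computed; call angular_velocity first")
    if drum_speed_deg_s is None:
        raise ConfigurationError("drum_speed_deg_s is required")
    _check_alignment(track, epochs)

    t = track.t
    omega = track.omega_deg_s
    d = drum_directions(epochs, t)
    # the sample at the session end owns no time; exclude it from epochs
    d = np.where(t >= epochs[-1].end_s, 0, d)
    threshold = crit.min_speed_fraction * drum_speed_deg_s
    following = (
        (d != 0)
        & np.isfinite(omega)
        & (np.sign(omega) == d)
        & (np.abs(omega) >= threshold)
    )

    dt = _sample_dt(t)
    bouts: list[Bout] = []
    # contiguous following runs; runs cannot span a direction change because d flips
    i = 0
    n = len(t)
    while i < n:
        if following[i]:
            j = i
            while j + 1 < n and following[j + 1] and d[j + 1] == d[i]:
                j += 1
            length = float(dt[i : j + 1].sum())
            if length >= crit.min_bout_s:
                bouts.append(Bout(start_s=float(t[i]), end_s=float(t[i] + length), i0=i, i1=j))
            else:
                following[i : j + 1] = False
            i = j + 1
        else:
            i += 1
    return following, bouts


def delay(
    bouts: Sequence[Bout],
    epochs: Sequence[Epoch],
    include_onset_epoch: bool = False,
    aggregate: str = "mean",
) -> tuple[float, list[float]]:
    """Per-reversal reaction times and their aggregate.

    For every post-switch epoch (optionally also the rotation-onset epoch),
    the delay is the start of the first bout beginning within that epoch
    minus the epoch start; epochs without such a bout contribute the epoch
    length as a cap.  ``aggregate`` is ``"mean"`` (default) or ``"first"``.
    """
    sel = [ep for ep in epochs if ep.is_post_switch or (include_onset_epoch and ep.direction != 0)]
    if not sel:
        raise ConfigurationError("schedule has no post-switch epochs; Delay is undefined")
    per_epoch: list[float] = []
    for ep in sel:
        starts = [b.start_s for b in bouts if ep.start_s <= b.start_s < ep.end_s]
        per_epoch.append(min(starts) - ep.start_s if starts else ep.length_s)
    if aggregate == "mean":
        agg = float(np.mean(per_epoch))
    elif aggregate == "first":
        agg = per_epoch[0]
    else:
        raise ConfigurationError(f"unknown delay aggregate {aggregate!r}")
    return agg, per_epoch


def duration(
    following: np.ndarray,
    track: AngularTrack,
    epochs: Sequence[Epoch],
) -> float:
    """Fraction of rotation time spent following (acclimatization excluded)."""
    rotation_time = sum(ep.length_s for ep in epochs if ep.direction != 0)
    if not rotation_time > 0:
        raise ConfigurationError("schedule has zero rotation time")
    dt = _sample_dt(track.t)
    rot = _rotation_mask(track.t, epochs)
    return float(dt[rot & following].sum() / rotation_time)


def mean_angular_speed(track: AngularTrack, epochs: Sequence[Epoch]) -> float:
    """Mean |omega| (deg/s) over all rotation-phase samples."""
    rot = _rotation_mask(track.t, epochs)
    w = track.omega_deg_s[rot]
    w = w[np.isfinite(w)]
    return float(np.mean(np.abs(w))) if w.size else 0.0


def distance(track: AngularTrack, epochs: Sequence[Epoch]) -> float:
    """Net rounds in the drum direction (signed; motion against subtracted).

    Summed from raw unwrapped-angle increments, each weighted by the drum
    direction of the epoch owning the interval's left endpoint; intervals
    inside unbridged gaps contribute nothing.
    """
    t = track.t
    th = track.theta_deg
    if len(t) < 2:
        return 0.0
    d = drum_directions(epochs, t[:-1])
    dth = th[1:] - th[:-1]
    ok = np.isfinite(dth) & (d != 0)
    return float(np.sum(d[ok] * dth[ok]) / 360.0)


def quantify_session(
    traj: Trajectory,
    config: SessionConfig,
    criterion: FollowingCriterion | None = None,
    *,
    max_gap_s: float = 1.0,
    smooth_window_s: float | None = 0.5,
    include_onset_epoch: bool = False,
    delay_aggregate: str = "mean",
) -> OMRResult:
    """Run the full per-fish chain and return the four OMR parameters.

    Chain: angular conversion -> angular velocity (runs split at drum
    reversals) -> following detection -> Delay / Duration / Angular velocity
    / Distance.  A session whose rotation phase has < 50% valid samples is
    flagged ``qc_fail`` but its parameters are still reported.
    """
    epochs = build_schedule(config.schedule)
    track = to_angular(traj, center=config.center_xy_cm, max_gap_s=max_gap_s)
    # differentiate within epochs only: the drum state is discontinuous at
    # every epoch boundary, so velocity estimates never straddle one
    boundaries = [ep.start_s for ep in epochs[1:]]
    track = angular_velocity(track, smooth_window_s=smooth_window_s, breaks=boundaries)

    crit = criterion or FollowingCriterion()
    speed = config.schedule.drum_speed_deg_s
    following, bouts = detect_following(track, epochs, crit, drum_speed_deg_s=speed)
    delay_s, per_epoch = delay(bouts, epochs, include_onset_epoch=include_onset_epoch, aggregate=delay_aggregate)
    dur = duration(following, track, epochs)
    speed_mean = mean_angular_speed(track, epochs)
    dist = distance(track, epochs)

    rot = _rotation_mask(traj.t, epochs)
    valid_fraction = float(traj.valid[rot].mean()) if rot.any() else 0.0
    return OMRResult(
        fish_id=traj.fish_id,
        species=config.species,
        wavelength_nm=config.wavelength_nm,
        delay_s=delay_s,
        duration_ratio=dur,
        angular_velocity_deg_s=speed_mean,
        distance_rounds=dist,
        per_epoch_delays=per_epoch,
        qc_valid_fraction=valid_fraction,
        qc_n_segments=len(track.segments),
        qc_fail=valid_fraction < 0.5,
    )
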