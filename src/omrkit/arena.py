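"""Apparatus model: circular arena geometry and the timed drum-rotation schedule.

The assay puts a single fish in a cylindrical tank surrounded by a striped
drum.  After an acclimatization phase with the drum at rest, the drum rotates
at constant angular speed and reverses direction a fixed number of times at
regular intervals.  This module models that physical/temporal definition and
discretizes a recording into constant-direction :class:`Epoch` segments from
which all downstream quantities are computed.

Conventions
-----------
* Times are seconds from recording start; intervals are half-open
  ``[start, end)`` so every instant belongs to exactly one epoch.
* Positive direction is counter-clockwise seen from above (camera view).
  Direction ``0`` denotes the acclimatization phase (drum at rest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigurationError

__all__ = [
    "ArenaGeometry",
    "DrumSchedule",
    "Epoch",
    "SessionConfig",
    "build_schedule",
    "drum_direction_at",
    "radial_gap",
    "light_conditions",
    "load_session_config",
    "PAPER_GEOMETRY",
    "PAPER_SCHEDULE",
]


@dataclass(frozen=True)
class ArenaGeometry:
    """Physical dimensions of the OMR apparatus, in centimetres.

    The tank sits inside the drum, so ``tank_diameter_cm`` must be strictly
    smaller than ``drum_diameter_cm``.  ``stripe_width_cm`` is the width of
    one stripe on the drum circumference; an optional central obstacle
    (e.g. a water-filled tube preventing the fish from cutting across the
    centre) can be recorded for provenance.
    """

    tank_diameter_cm: float
    drum_diameter_cm: float
    stripe_width_cm: float = 2.0
    center_obstacle_diameter_cm: float | None = None

    def __post_init__(self) -> None:
        for name in ("tank_diameter_cm", "drum_diameter_cm", "stripe_width_cm"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.center_obstacle_diameter_cm is not None and not self.center_obstacle_diameter_cm > 0:
            raise ConfigurationError("center_obstacle_diameter_cm must be > 0 when given")
        if not self.tank_diameter_cm < self.drum_diameter_cm:
            raise ConfigurationError("tank_diameter_cm must be smaller than drum_diameter_cm")

    @property
    def tank_radius_cm(self) -> float:
        return self.tank_diameter_cm / 2.0


@dataclass(frozen=True)
class DrumSchedule:
    """Timed rotation protocol of the striped drum.

    One acclimatization phase of ``acclimatization_s`` with the drum at rest
    is followed by ``n_reversals + 1`` rotation epochs of ``epoch_length_s``
    each, alternating direction starting from ``initial_direction``.
    """

    acclimatization_s: float = 30.0
    epoch_length_s: float = 30.0
    n_reversals: int = 3
    initial_direction: int = +1
    drum_speed_deg_s: float = 60.0

    def __post_init__(self) -> None:
        if self.acclimatization_s < 0:
            raise ConfigurationError("acclimatization_s must be >= 0")
        if not self.epoch_length_s > 0:
            raise ConfigurationError("epoch_length_s must be > 0")
        if self.n_reversals < 0:
            raise ConfigurationError("n_reversals must be >= 0")
        if self.initial_direction not in (-1, 1):
            raise ConfigurationError("initial_direction must be +1 or -1")
        if not self.drum_speed_deg_s > 0:
            raise ConfigurationError("drum_speed_deg_s must be > 0")

    @property
    def rotation_time_s(self) -> float:
        """Total time with the drum rotating."""
        return (self.n_reversals + 1) * self.epoch_length_s

    @property
    def session_length_s(self) -> float:
        return self.acclimatization_s + self.rotation_time_s


@dataclass(frozen=True)
class Epoch:
    """A constant-drum-direction segment of the session (half-open in time)."""

    index: int
    start_s: float
    end_s: float
    direction: int  # +1 / -1, or 0 during acclimatization
    is_post_switch: bool = False

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


# The apparatus used to anchor all worked examples: 18.5 cm tank inside a
# 24 cm drum with 2 cm stripes, rotating at 10 rpm (60 deg/s), 30 s
# acclimatization then four 30 s epochs (three reversals).
PAPER_GEOMETRY = ArenaGeometry(tank_diameter_cm=18.5, drum_diameter_cm=24.0, stripe_width_cm=2.0)
PAPER_SCHEDULE = DrumSchedule()


def build_schedule(config: DrumSchedule) -> list[Epoch]:
    """Discretize a :class:`DrumSchedule` into an ordered list of epochs.

    Returns one acclimatization epoch (direction 0; omitted when the
    acclimatization time is zero) followed by ``n_reversals + 1`` rotation
    epochs alternating direction.  Every rotation epoch preceded by a
    reversal carries ``is_post_switch=True``.
    """
    epochs: list[Epoch] = []
    t = 0.0
    idx = 0
    if config.acclimatization_s > 0:
        epochs.append(Epoch(idx, 0.0, config.acclimatization_s, 0, False))
        t = config.acclimatization_s
        idx += 1
    direction = config.initial_direction
    for i in range(config.n_reversals + 1):
        epochs.append(
            Epoch(idx, t, t + config.epoch_length_s, direction, is_post_switch=(i > 0))
        )
        t += config.epoch_length_s
        idx += 1
        direction = -direction
    return epochs


def drum_direction_at(epochs: Sequence[Epoch], t: float) -> int:
    """Drum direction at time ``t`` (scalar); boundaries belong to the later epoch."""
    if not epochs:
        raise ConfigurationError("empty epoch list")
    end = epochs[-1].end_s
    if not (epochs[0].start_s <= t <= end):
        raise ValueError(f"t={t} outside session [{epochs[0].start_s}, {end}]")
    for ep in epochs:
        if ep.start_s <= t < ep.end_s:
            return ep.direction
    return epochs[-1].direction  # t == session end


def drum_directions(epochs: Sequence[Epoch], t: np.ndarray) -> np.ndarray:
    """Vectorized drum direction lookup; times past the last epoch end get its direction."""
    t = np.asarray(t, dtype=float)
    starts = np.array([ep.start_s for ep in epochs])
    dirs = np.array([ep.direction for ep in epochs])
    idx = np.searchsorted(starts, t, side="right") - 1
    idx = np.clip(idx, 0, len(epochs) - 1)
    return dirs[idx]


def radial_gap(geom: ArenaGeometry) -> float:
    """Annular gap (cm) between the tank wall and the drum: (drum - tank)/2."""
    return (geom.drum_diameter_cm - geom.tank_diameter_cm) / 2.0


def light_conditions() -> dict[int, float]:
    """Packaged wavelength (nm) -> photon flux density (umol m^-2 s^-1) table.

    These are the measured monochromatic light intensities at the testing
    apparatus for each peak wavelength used in the assays.
    """
    with resources.files("omrkit.data").joinpath("light_conditions.json").open() as fh:
        raw = json.load(fh)
    return {int(k): float(v) for k, v in raw["photon_flux_umol_m2_s"].items()}


@dataclass
class SessionConfig:
    """Everything needed to analyse one recording of one fish.

    ``fps`` is a required recording property (trackers emit frame indices);
    ``px_per_cm`` must be given when track coordinates are in pixels.
    """

    geometry: ArenaGeometry = field(default_factory=lambda: PAPER_GEOMETRY)
    schedule: DrumSchedule = field(default_factory=lambda: PAPER_SCHEDULE)
    fps: float = 30.0
    wavelength_nm: float | None = None
    photon_flux_umol_m2_s: float | None = None
    species: str | None = None
    fish_id: str | None = None
    px_per_cm: float | None = None
    time_unit: str = "s"  # unit of an explicit time column: "s" or "ms"
    center_xy_cm: tuple[float, float] | None = None  # arena centre override

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ConfigurationError("fps must be > 0")
        if self.time_unit not in ("s", "ms"):
            raise ConfigurationError("time_unit must be 's' or 'ms'")
        if self.px_per_cm is not None and not self.px_per_cm > 0:
            raise ConfigurationError("px_per_cm must be > 0 when given")

    def to_dict(self) -> dict:
        d = {
            "geometry": asdict(self.geometry),
            "schedule": asdict(self.schedule),
            "recording": {
                "fps": self.fps,
                "px_per_cm": self.px_per_cm,
                "time_unit": self.time_unit,
                "center_xy_cm": list(self.center_xy_cm) if self.center_xy_cm else None,
            },
            "condition": {
                "wavelength_nm": self.wavelength_nm,
                "photon_flux_umol_m2_s": self.photon_flux_umol_m2_s,
                "species": self.species,
                "fish_id": self.fish_id,
            },
        }
        return d

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=2)


def session_config_from_dict(d: dict) -> SessionConfig:
    geom = d.get("geometry", {})
    sched = d.get("schedule", {})
    rec = d.get("recording", {})
    cond = d.get("condition", {})
    try:
        geometry = ArenaGeometry(
            tank_diameter_cm=float(geom.get("tank_diameter_cm", PAPER_GEOMETRY.tank_diameter_cm)),
            drum_diameter_cm=float(geom.get("drum_diameter_cm", PAPER_GEOMETRY.drum_diameter_cm)),
            stripe_width_cm=float(geom.get("stripe_width_cm", PAPER_GEOMETRY.stripe_width_cm)),
            center_obstacle_diameter_cm=geom.get("center_obstacle_diameter_cm"),
        )
        schedule = DrumSchedule(
            acclimatization_s=float(sched.get("acclimatization_s", PAPER_SCHEDULE.acclimatization_s)),
            epoch_length_s=float(sched.get("epoch_length_s", PAPER_SCHEDULE.epoch_length_s)),
            n_reversals=int(sched.get("n_reversals", PAPER_SCHEDULE.n_reversals)),
            initial_direction=int(sched.get("initial_direction", PAPER_SCHEDULE.initial_direction)),
            drum_speed_deg_s=float(sched.get("drum_speed_deg_s", PAPER_SCHEDULE.drum_speed_deg_s)),
        )
        center = rec.get("center_xy_cm")
        return SessionConfig(
            geometry=geometry,
            schedule=schedule,
            fps=float(rec.get("fps", 30.0)),
            px_per_cm=rec.get("px_per_cm"),
            time_unit=rec.get("time_unit", "s"),
            center_xy_cm=tuple(center) if center else None,
            wavelength_nm=cond.get("wavelength_nm"),
            photon_flux_umol_m2_s=cond.get("photon_flux_umol_m2_s"),
            species=cond.get("species"),
            fish_id=cond.get("fish_id"),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise ConfigurationError(f"malformed session config: {exc}") from exc


def load_session_config(path: str | Path) -> SessionConfig:
    """Load a session configuration from a YAML or JSON file."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            d = yaml.safe_load(fh)
        else:
            d = json.load(fh)
    if not isinstance(d, dict):
        raise ConfigurationError(f"session config {path} is not a mapping")
    return session_config_from_dict(d)
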