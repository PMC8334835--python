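"""Seeded synthetic fish trajectories emulating the assay's behavioural phenotypes.

Four phenotypes cover what the drum assay elicits in practice:

``follower``
    A two-state (idle/engaged) continuous-time Markov chain.  Engagement is
    only possible once an exponential reaction latency has elapsed after
    each drum reversal; the engagement rate is scaled by a logistic
    psychometric function p(lambda) = 1 / (1 + exp((lambda - lambda50) /
    slope)), so followers go blind smoothly with wavelength.  While engaged
    the fish matches the drum (direction x speed x gain) plus noise; while
    idle it drifts with autocorrelated (AR(1)) angular-velocity noise.
``random_walker``
    Idle dynamics throughout — an active but stimulus-blind swimmer (the
    eyeless-cavefish negative control).
``turner``
    Swims at drum-like speed but reverses heading at Poisson times,
    regardless of the stimulus (the frequent-turner phenotype that makes
    some species untestable).
``still``
    Near-zero angular velocity with small noise (the seldom-swimming
    phenotype).

The radial coordinate is a reflected random walk inside an annular band;
positions are emitted as x-y about the arena centre.  Everything is
reproducible from integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .arena import Epoch, SessionConfig, build_schedule
from .errors import ConfigurationError
from .trajectory import Trajectory

__all__ = [
    "SimFishConfig",
    "phenotype_template",
    "psychometric_probability",
    "simulate_fish",
    "CohortRecord",
    "generate_cohort",
]

PHENOTYPES = ("follower", "random_walker", "turner", "still")


@dataclass(frozen=True)
class SimFishConfig:
    """Parameters of one simulated fish (units: s, Hz, deg/s, cm, nm)."""

    phenotype: str = "follower"
    lambda50_nm: float | None = 830.0
    slope_nm: float = 3.0
    follow_gain: float = 1.0
    latency_mean_s: float = 1.0
    engage_rate_hz: float = 0.2
    disengage_rate_hz: float = 0.3
    omega_noise_sd_deg_s: float = 10.0
    noise_tau_s: float = 1.0
    turn_rate_hz: float = 1.5
    r_band_cm: tuple[float, float] = (3.0, 8.0)
    radial_step_cm_sqrt_s: float = 0.8
    jitter_sd: float = 0.2  # log-normal sd of per-fish gain & latency variation

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ConfigurationError(f"unknown phenotype {self.phenotype!r}")
        for name in ("engage_rate_hz", "disengage_rate_hz", "turn_rate_hz",
                     "omega_noise_sd_deg_s", "latency_mean_s", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not self.slope_nm > 0:
            raise ConfigurationError("slope_nm must be > 0")
        r0, r1 = self.r_band_cm
        if not (0 < r0 < r1):
            raise ConfigurationError("radial band must satisfy 0 < r_min < r_max")


_TEMPLATE_OVERRIDES = {
    "follower": {},
    "random_walker": {"omega_noise_sd_deg_s": 20.0, "lambda50_nm": None},
    "turner": {"omega_noise_sd_deg_s": 10.0, "lambda50_nm": None},
    "still": {"omega_noise_sd_deg_s": 2.0, "radial_step_cm_sqrt_s": 0.1, "lambda50_nm": None},
}


def phenotype_template(name: str, **overrides) -> SimFishConfig:
    """Study-condition defaults for one phenotype, with optional overrides."""
    if name not in PHENOTYPES:
        raise ConfigurationError(f"unknown phenotype {name!r}")
    kwargs = {"phenotype": name, **_TEMPLATE_OVERRIDES[name], **overrides}
    return SimFishConfig(**kwargs)


def psychometric_probability(wavelength_nm: float, lambda50_nm: float, slope_nm: float) -> float:
    """Logistic detection probability, decreasing in wavelength."""
    return 1.0 / (1.0 + math.exp((wavelength_nm - lambda50_nm) / slope_nm))


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, tau_s: float, dt: float) -> np.ndarray:
    """Stationary AR(1) series with marginal sd ``sd`` and correlation time ``tau_s``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    a = math.exp(-dt / tau_s)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - a * a), size=n)
    x0 = rng.normal(0.0, sd)
    out, _ = lfilter([1.0], [1.0, -a], innov, zi=np.array([a * x0]))
    return out


def _engaged_spans(
    rng: np.random.Generator,
    epochs: Sequence[Epoch],
    p_detect: float,
    latency_mean_s: float,
    engage_rate_hz: float,
    disengage_rate_hz: float,
) -> list[tuple[float, float]]:
    """Engaged time intervals of the follower's idle/engaged chain.

    The chain resets to idle at every drum reversal (and at rotation onset);
    a fresh exponential latency then gates re-engagement.
    """
    spans: list[tuple[float, float]] = []
    rate_on = engage_rate_hz * p_detect
    for ep in epochs:
        if ep.direction == 0:
            continue
        cursor = ep.start_s
        if latency_mean_s > 0:
            cursor += rng.exponential(latency_mean_s)
        while cursor < ep.end_s:
            if rate_on <= 0:
                break
            wait = 0.0 if math.isinf(rate_on) else rng.exponential(1.0 / rate_on)
            start = cursor + wait
            if start >= ep.end_s:
                break
            dur = math.inf if disengage_rate_hz <= 0 else rng.exponential(1.0 / disengage_rate_hz)
            end = min(start + dur, ep.end_s)
            spans.append((start, end))
            cursor = end if math.isfinite(dur) else ep.end_s
    return spans


def _spans_to_mask(spans: Sequence[tuple[float, float]], t_left: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(t_left), dtype=bool)
    for a, b in spans:
        mask |= (t_left >= a) & (t_left < b)
    return mask


def _reflected_walk(rng: np.random.Generator, n: int, lo: float, hi: float, step_sd: float, dt: float) -> np.ndarray:
    """Random walk reflected into [lo, hi] via triangle-wave folding."""
    width = hi - lo
    start = rng.uniform(lo, hi)
    raw = start + np.concatenate(([0.0], np.cumsum(rng.normal(0.0, step_sd * math.sqrt(dt), size=n))))
    phase = np.mod(raw - lo, 2.0 * width)
    return lo + np.where(phase <= width, phase, 2.0 * width - phase)


def simulate_fish(
    config: SimFishConfig,
    session: SessionConfig,
    wavelength_nm: float | None = None,
    seed: int | Sequence[int] | np.random.Generator = 0,
) -> Trajectory:
    """Simulate one fish for one session; fully reproducible from ``seed``.

    The trajectory is sampled at ``session.fps`` from t = 0 to the session
    end inclusive; the angular velocity on each inter-sample interval is set
    by the phenotype state at the interval's left endpoint.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if wavelength_nm is None:
        wavelength_nm = session.wavelength_nm
    if config.phenotype == "follower":
        if wavelength_nm is None:
            raise ConfigurationError("follower simulation requires a wavelength")
        if config.lambda50_nm is None:
            raise ConfigurationError("follower simulation requires lambda50_nm")

    epochs = build_schedule(session.schedule)
    total = epochs[-1].end_s
    dt = 1.0 / session.fps
    n_int = int(round(total * session.fps))
    t = np.arange(n_int + 1) / session.fps
    t_left = t[:-1]
    speed = session.schedule.drum_speed_deg_s

    from .arena import drum_directions  # local import to avoid cycle at module load

    d = drum_directions(epochs, t_left)
    d = np.where(t_left >= total, 0, d)

    noise = _ar1_noise(rng, n_int, config.omega_noise_sd_deg_s, config.noise_tau_s, dt)
    if config.phenotype == "follower":
        p = psychometric_probability(wavelength_nm, config.lambda50_nm, config.slope_nm)
        spans = _engaged_spans(rng, epochs, p, config.latency_mean_s,
                               config.engage_rate_hz, config.disengage_rate_hz)
        engaged = _spans_to_mask(spans, t_left) & (d != 0)
        omega = np.where(engaged, d * speed * config.follow_gain, 0.0) + np.where(engaged, 0.3, 1.0) * noise
    elif config.phenotype == "random_walker":
        omega = noise
    elif config.phenotype == "turner":
        # Poisson sign flips of a drum-speed-scale heading
        sign = 1.0 if rng.random() < 0.5 else -1.0
        flips = []
        cursor = 0.0
        while cursor < total:
            cursor += rng.exponential(1.0 / config.turn_rate_hz) if config.turn_rate_hz > 0 else math.inf
            if cursor < total:
                flips.append(cursor)
        signs = sign * (-1.0) ** np.searchsorted(np.asarray(flips), t_left, side="right")
        omega = signs * speed * config.follow_gain + noise
    else:  # still
        omega = noise

    theta0 = rng.uniform(0.0, 360.0)
    theta = theta0 + np.concatenate(([0.0], np.cumsum(omega * dt)))
    r = _reflected_walk(rng, n_int, config.r_band_cm[0], config.r_band_cm[1],
                        config.radial_step_cm_sqrt_s, dt)
    rad = np.radians(theta)
    x = r * np.cos(rad)
    y = r * np.sin(rad)
    return Trajectory(fish_id=session.fish_id or "sim", t=t, x=x, y=y, fps=session.fps)


@dataclass
class CohortRecord:
    trajectory: Trajectory
    session: SessionConfig
    fish_index: int
    seed: tuple[int, ...]
    fish_config: SimFishConfig


def generate_cohort(
    template: SimFishConfig,
    n_fish: int,
    wavelength_grid: Sequence[float],
    base_seed: int,
    session: SessionConfig | None = None,
    species: str | None = None,
    photon_flux: dict[int, float] | None = None,
) -> list[CohortRecord]:
    """Simulate ``n_fish`` fish at every wavelength of a grid.

    Each fish gets multiplicative log-normal jitter (sd ``template.jitter_sd``)
    on its follow gain and reaction latency, drawn once per fish so the same
    animal is consistent across wavelengths (a repeated-measures design).
    Each (fish, wavelength) trajectory is deterministic in
    ``(base_seed, fish index, wavelength)``.
    """
    if n_fish < 1:
        raise ConfigurationError("n_fish must be >= 1")
    grid = [float(w) for w in wavelength_grid]
    if not grid:
        raise ConfigurationError("wavelength grid must be nonempty")
    base = session or SessionConfig()
    records: list[CohortRecord] = []
    label = species or template.phenotype
    for i in range(n_fish):
        fish_rng = np.random.default_rng((base_seed, i))
        if template.jitter_sd > 0:
            gain = template.follow_gain * fish_rng.lognormal(0.0, template.jitter_sd)
            latency = template.latency_mean_s * fish_rng.lognormal(0.0, template.jitter_sd)
        else:
            gain, latency = template.follow_gain, template.latency_mean_s
        fish_cfg = replace(template, follow_gain=gain, latency_mean_s=latency)
        for w in grid:
            seed = (base_seed, i, int(round(w)))
            cfg = replace(
                base,
                wavelength_nm=w,
                photon_flux_umol_m2_s=(photon_flux or {}).get(int(round(w))),
                species=label,
                fish_id=f"{label}_{i:02d}",
                # synthetic coordinates are emitted about the true arena centre
                center_xy_cm=base.center_xy_cm or (0.0, 0.0),
            )
            traj = simulate_fish(fish_cfg, cfg, wavelength_nm=w, seed=seed)
            records.append(CohortRecord(traj, cfg, i, seed, fish_cfg))
    return records
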