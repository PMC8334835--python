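import math

import numpy as np
import pytest

from omrkit.arena import SessionConfig, build_schedule
from omrkit.synthetic import phenotype_template, simulate_fish
from omrkit.trajectory import Trajectory


@pytest.fixture
def session():
    """Standard-apparatus session: 30 s acclimatization, 4 x 30 s epochs at 60 deg/s."""
    return SessionConfig(wavelength_nm=700.0, fish_id="fish", center_xy_cm=(0.0, 0.0))


@pytest.fixture
def epochs(session):
    return build_schedule(session.schedule)


@pytest.fixture
def lockstep_template():
    """Deterministic perfect follower: engaged from every epoch start, no noise."""
    return phenotype_template(
        "follower",
        latency_mean_s=0.0,
        engage_rate_hz=math.inf,
        disengage_rate_hz=0.0,
        omega_noise_sd_deg_s=0.0,
        jitter_sd=0.0,
        radial_step_cm_sqrt_s=1e-6,
    )


@pytest.fixture
def lockstep_trajectory(lockstep_template, session):
    return simulate_fish(lockstep_template, session, seed=1)


def traj_from_omega(omega_left: np.ndarray, session: SessionConfig, r_cm: float = 5.0,
                    theta0_deg: float = 0.0, fish_id: str = "constructed") -> Trajectory:
    """Build a circular-orbit trajectory from a per-interval angular velocity profile.

    ``omega_left[i]`` (deg/s) applies on the interval [t_i, t_{i+1}); the
    fish circles at constant radius ``r_cm``.
    """
    dt = 1.0 / session.fps
    theta = theta0_deg + np.concatenate(([0.0], np.cumsum(omega_left * dt)))
    rad = np.radians(theta)
    return Trajectory(fish_id=fish_id, t=np.arange(len(theta)) * dt,
                      x=r_cm * np.cos(rad), y=r_cm * np.sin(rad), fps=session.fps)


def session_interval_times(session: SessionConfig) -> np.ndarray:
    """Left endpoints of the sampling intervals covering the whole session."""
    n = int(round(session.schedule.session_length_s * session.fps))
    return np.arange(n) / session.fps
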