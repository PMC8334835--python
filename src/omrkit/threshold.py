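"""Cohort-level OMR positivity and the visible-invisible boundary.

A cohort at one wavelength is judged OMR positive from the Distance
parameter — the one that converges to zero when the animals can no longer
see the stripes — by a deliberately explicit dual rule: the cohort mean
Distance must exceed a zero band (default 1.0 round, the scale of what a
non-following random swimmer accumulates over a standard session) AND an
exact one-sided sign-flip permutation test of Distance > 0 must reject at
alpha.  Both constants are exposed.

The boundary is the interval between the largest wavelength with all
smaller tested wavelengths positive and the next tested wavelength; a
continuous alternative fits a decreasing logistic psychometric function to
cohort mean Distance and reports its midpoint lambda50.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "WavelengthClassification",
    "ThresholdEstimate",
    "PsychometricFit",
    "sign_flip_pvalue",
    "classify_wavelength",
    "boundary_from_grid",
    "two_round_plan",
    "psychometric_fit",
]


@dataclass
class WavelengthClassification:
    wavelength_nm: float
    n: int
    mean_distance: float
    sign_flip_p: float
    positive: bool


@dataclass
class ThresholdEstimate:
    """Visible-invisible boundary interval for one cohort.

    ``last_positive_nm`` is the largest tested wavelength such that it and
    every smaller tested wavelength are positive; ``first_negative_nm`` is
    the next tested wavelength.  Either endpoint is None when the boundary
    falls outside the grid.
    """

    species: str | None
    last_positive_nm: float | None
    first_negative_nm: float | None
    method: str = "rule"
    lambda50_nm: float | None = None
    fit_slope: float | None = None
    flags: list[str] = field(default_factory=list)

    def contains(self, wavelength: float) -> bool:
        lo = self.last_positive_nm if self.last_positive_nm is not None else -np.inf
        hi = self.first_negative_nm if self.first_negative_nm is not None else np.inf
        return lo <= wavelength <= hi


@dataclass
class PsychometricFit:
    status: str  # "ok" | "refused"
    lambda50_nm: float | None = None
    slope_nm: float | None = None
    amplitude: float | None = None
    reason: str | None = None


def sign_flip_pvalue(values: np.ndarray, alternative: str = "greater") -> float:
    """Exact one-sided sign-flip permutation p for mean(values) vs 0.

    Enumerates all 2^n sign assignments for n <= 16 (a cohort is six fish),
    otherwise falls back to the normal approximation of the flip
    distribution.  The identity flip is included, so p >= 1/2^n.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    obs = v.mean()
    if alternative == "less":
        v, obs = -v, -obs
    if n <= 16:
        signs = np.array(np.meshgrid(*([[1.0, -1.0]] * n), indexing="ij")).reshape(n, -1)
        flipped = (v @ signs) / n
        return float(np.mean(flipped >= obs - 1e-12))
    # large-n normal approximation: mean 0, var sum(v^2)/n^2
    sd = np.sqrt(np.sum(v**2)) / n
    if sd == 0:
        return 1.0
    from scipy.stats import norm

    return float(norm.sf(obs / sd))


def classify_wavelength(
    distances: Sequence[float],
    zero_band: float = 1.0,
    alpha: float = 0.05,
    wavelength_nm: float = np.nan,
) -> WavelengthClassification:
    """Judge one cohort OMR positive/negative from per-fish Distance values."""
    d = np.asarray(list(distances), dtype=float)
    if len(d) < 2:
        raise InsufficientDataError("need at least 2 fish to classify a wavelength")
    p = sign_flip_pvalue(d, "greater")
    positive = (d.mean() > zero_band) and (p < alpha)
    return WavelengthClassification(
        wavelength_nm=float(wavelength_nm),
        n=len(d),
        mean_distance=float(d.mean()),
        sign_flip_p=p,
        positive=bool(positive),
    )


def boundary_from_grid(
    classifications: Mapping[float, bool] | Sequence[WavelengthClassification],
    species: str | None = None,
) -> ThresholdEstimate:
    """Boundary interval from per-wavelength positive/negative calls.

    Non-monotone patterns (a positive above a negative) are flagged and
    resolved conservatively: the boundary is placed after the largest
    wavelength below which everything tested is positive.
    """
    if not isinstance(classifications, Mapping):
        classifications = {c.wavelength_nm: c.positive for c in classifications}
    if not classifications:
        raise InsufficientDataError("no classifications given")
    grid = np.array(sorted(classifications))
    calls = np.array([bool(classifications[w]) for w in grid])

    flags: list[str] = []
    if np.any(~calls[:-1] & calls[1:]):
        flags.append("non-monotone")

    if calls.all():
        return ThresholdEstimate(species, float(grid[-1]), None, flags=flags + ["boundary above grid"])
    first_neg = int(np.argmin(calls))  # first False in grid order
    if first_neg == 0:
        return ThresholdEstimate(species, None, float(grid[0]), flags=flags + ["boundary below grid"])
    return ThresholdEstimate(species, float(grid[first_neg - 1]), float(grid[first_neg]), flags=flags)


def two_round_plan(
    round1: ThresholdEstimate,
    round1_grid: Sequence[float],
    round2_step: float,
) -> np.ndarray:
    """Plan the finer second-round wavelength grid around a first-round boundary.

    The plan covers one ``round2_step`` beyond each boundary endpoint,
    snapped outward to multiples of the step and clipped to the round-1
    tested range; e.g. a coarse boundary of (800, 850) refined at 20 nm
    yields 780, 800, ..., 880.
    """
    if not round2_step > 0:
        raise ConfigurationError("round2_step must be > 0")
    grid1 = np.array(sorted(round1_grid), dtype=float)
    if round1.last_positive_nm is None or round1.first_negative_nm is None:
        raise ConfigurationError(
            "round-1 boundary is open-ended; extend the round-1 grid "
            f"({'below' if round1.last_positive_nm is None else 'above'} its current range) before refining"
        )
    step1 = float(np.min(np.diff(grid1))) if len(grid1) > 1 else round2_step
    if round2_step >= step1:
        import warnings

        warnings.warn("round-2 step does not refine the round-1 grid", stacklevel=2)
    lo = np.floor((round1.last_positive_nm - round2_step) / round2_step) * round2_step
    hi = np.ceil((round1.first_negative_nm + round2_step) / round2_step) * round2_step
    lo = max(lo, grid1[0])
    hi = min(hi, grid1[-1])
    out = np.arange(lo, hi + 0.5 * round2_step, round2_step)
    return out


def _logistic(lam, amplitude, lambda50, inv_slope):
    return amplitude / (1.0 + np.exp(inv_slope * (lam - lambda50)))


def psychometric_fit(
    wavelengths: Sequence[float],
    values: Sequence[float],
    normalize: bool = True,
) -> PsychometricFit:
    """Least-squares decreasing-logistic fit of cohort response vs wavelength.

    ``values`` are cohort mean Distances (any monotone response works); when
    ``normalize`` they are scaled by the response at the shortest tested
    wavelength.  The fit is refused — a status, not a number — when fewer
    than four wavelengths are given, when the fitted slope's 95% CI spans
    zero (no detectable decrease), or when the optimizer cannot converge.
    """
    lam = np.asarray(list(wavelengths), dtype=float)
    y = np.asarray(list(values), dtype=float)
    if len(lam) < 4:
        return PsychometricFit(status="refused", reason="need >= 4 wavelengths")
    order = np.argsort(lam)
    lam, y = lam[order], y[order]
    if normalize:
        ref = y[0]
        if ref <= 0:
            return PsychometricFit(status="refused", reason="non-positive reference response")
        y = y / ref
    span = lam[-1] - lam[0]
    if span <= 0 or np.allclose(y, y[0]):
        return PsychometricFit(status="refused", reason="flat response")

    a0 = max(y.max(), 1e-6)
    mid_guess = float(np.interp(a0 / 2.0, y[::-1], lam[::-1]))
    p0 = [a0, mid_guess, 4.0 / max(span / len(lam), 1.0)]
    try:
        popt, pcov = curve_fit(
            _logistic, lam, y, p0=p0, maxfev=20000,
            bounds=([0.0, lam[0] - span, -5.0], [10.0 * a0, lam[-1] + span, 5.0]),
        )
    except (RuntimeError, ValueError):
        return PsychometricFit(status="refused", reason="fit did not converge")
    amplitude, lambda50, inv_slope = popt
    # decrease detectability: Wald CI on the slope when the fit is
    # well-conditioned; for step-like transitions the slope is unidentified
    # (huge variance) even though the decrease is obvious, so fall back to a
    # one-sided Kendall trend test on the raw points
    se = np.sqrt(max(pcov[2, 2], 0.0)) if np.all(np.isfinite(pcov)) else np.inf
    wald_ok = np.isfinite(se) and se < abs(inv_slope) and inv_slope - 1.96 * se > 0.0
    if not wald_ok:
        # step-like transitions leave the slope unidentified (huge Wald
        # variance); judge the decrease by the fitted drop across the grid
        # against the residual noise instead
        resid = y - _logistic(lam, *popt)
        rms = float(np.sqrt(np.mean(resid**2)))
        drop = float(_logistic(lam[0], *popt) - _logistic(lam[-1], *popt))
        if not (inv_slope > 0 and drop > 2.0 * max(rms, 1e-12)):
            return PsychometricFit(status="refused", reason="no detectable decrease")
    if inv_slope <= 0:
        return PsychometricFit(status="refused", reason="fitted response is non-decreasing")
    if not (lam[0] <= lambda50 <= lam[-1]):
        return PsychometricFit(status="refused", reason="transition not bracketed by the tested grid")
    return PsychometricFit(
        status="ok",
        lambda50_nm=float(lambda50),
        slope_nm=float(1.0 / inv_slope),
        amplitude=float(amplitude),
    )
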