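"""Reference-distribution tails for rank-based multiple comparisons.

Both tails here are one-dimensional integrals over a latent standard-normal
variable, evaluated on a fixed fine grid with Simpson's rule; absolute error
is well below 1e-6, which is ample for p-values.

* :func:`studentized_range_sf` — the range of k iid standard normals
  (the infinite-degrees-of-freedom studentized range), the reference used by
  all-pairs rank comparisons.
* :func:`max_abs_equicorrelated_sf` / :func:`max_equicorrelated_sf` — the
  maximum (absolute) component of an m-variate equicorrelated standard
  normal (correlation rho, 0.5 for balanced many-to-one designs), the
  reference used by treatments-versus-control rank comparisons.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy.stats import norm

__all__ = ["studentized_range_sf", "max_abs_equicorrelated_sf", "max_equicorrelated_sf"]

_GRID = np.linspace(-8.5, 8.5, 4001)
_PHI = norm.pdf(_GRID)
_PHI_CDF = norm.cdf(_GRID)


def _as_batch(q) -> tuple[np.ndarray, bool]:
    arr = np.atleast_1d(np.asarray(q, dtype=float))
    return arr, np.isscalar(q) or (hasattr(q, "ndim") and getattr(q, "ndim") == 0)


def studentized_range_sf(q, k: int):
    """P(range of k iid standard normals >= q); vectorized in ``q``."""
    if k < 2:
        raise ValueError("k must be >= 2")
    qa, scalar = _as_batch(q)
    out = np.ones_like(qa)
    pos = qa > 0
    if np.any(pos):
        qp = qa[pos][:, None]
        inner = np.clip(_PHI_CDF[None, :] - norm.cdf(_GRID[None, :] - qp), 0.0, 1.0)
        cdf = k * integrate.simpson(_PHI[None, :] * inner ** (k - 1), x=_GRID, axis=1)
        out[pos] = np.clip(1.0 - cdf, 0.0, 1.0)
    return float(out[0]) if scalar else out


def _equicorrelated_sf(t, m: int, rho: float, two_sided: bool):
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    ta, scalar = _as_batch(t)
    s, w = np.sqrt(rho), np.sqrt(1.0 - rho)
    c = ta[:, None]
    u = _GRID[None, :]
    if two_sided:
        inner = norm.cdf((c - s * u) / w) - norm.cdf((-c - s * u) / w)
        inner = np.clip(inner, 0.0, 1.0)
    else:
        inner = norm.cdf((c - s * u) / w)
    cdf = integrate.simpson(_PHI[None, :] * inner ** m, x=_GRID, axis=1)
    out = np.clip(1.0 - cdf, 0.0, 1.0)
    if two_sided:
        out[ta <= 0] = 1.0
    return float(out[0]) if scalar else out


def max_abs_equicorrelated_sf(t, m: int, rho: float = 0.5):
    """P(max_j |Z_j| >= t) for m equicorrelated standard normals (two-sided)."""
    return _equicorrelated_sf(t, m, rho, two_sided=True)


def max_equicorrelated_sf(t, m: int, rho: float = 0.5):
    """P(max_j Z_j >= t) for m equicorrelated standard normals (one-sided)."""
    return _equicorrelated_sf(t, m, rho, two_sided=False)
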