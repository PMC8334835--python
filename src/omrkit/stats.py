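"""Statistics cascade for a parameter measured across a wavelength grid.

The unit of analysis is a complete repeated-measures matrix: n fish x k
wavelengths of one OMR parameter.  The cascade mirrors common practice in
behavioural work:

1. Bartlett's test gates on homogeneity of variances across wavelengths.
2. Homogeneous data take the parametric branch: a likelihood-ratio
   (Mauchly-type) sphericity test on the orthonormal-contrast covariance;
   one-way repeated-measures ANOVA, with both degrees of freedom deflated by
   the Greenhouse-Geisser epsilon when sphericity is rejected; and all-pairs
   paired t-tests adjusted by Shaffer's modified sequentially rejective
   Bonferroni procedure (step multipliers from exhaustive enumeration of the
   logically achievable numbers of true pairwise hypotheses).
3. Otherwise the non-parametric branch applies the Steel-Dwass all-pairs
   rank procedure (studentized-range reference) and, when a control level is
   configured, the Steel many-to-one rank procedure (equicorrelated
   max-normal reference, rho = 1/2).

Steel-Dwass and Steel are implemented in their standard independent-samples
form; applying them to repeated measures (same fish across wavelengths) is
flagged in the outcome notes rather than silently accepted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

from .distributions import (
    max_abs_equicorrelated_sf,
    max_equicorrelated_sf,
    studentized_range_sf,
)
from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "WavelengthSeries",
    "StatOutcome",
    "PairwiseOutcome",
    "CascadeResult",
    "bartlett_test",
    "gg_epsilon",
    "mendoza_sphericity",
    "rm_anova",
    "shaffer_multipliers",
    "achievable_true_counts",
    "shaffer_pairwise",
    "steel_dwass",
    "steel_control",
    "run_cascade",
]

PARAMETERS = ("delay", "duration", "angular_velocity", "distance")


@dataclass
class WavelengthSeries:
    """n fish x k wavelengths of one OMR parameter (complete design)."""

    parameter: str
    wavelengths: np.ndarray
    values: np.ndarray  # shape (n, k), row = fish

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InsufficientDataError("values must be an n x k matrix")
        n, k = self.values.shape
        if k != len(self.wavelengths):
            raise InsufficientDataError("values column count must match wavelength grid")
        if k < 2 or n < 2:
            raise InsufficientDataError("need at least 2 fish and 2 wavelengths")
        if not np.all(np.isfinite(self.values)):
            raise InsufficientDataError("repeated-measures design must be complete (no missing cells)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, parameter: str, value_column: str | None = None) -> "WavelengthSeries":
        """Pivot a tidy per-fish frame (fish_id, wavelength_nm, <parameter>)."""
        col = value_column or {
            "delay": "delay_s",
            "duration": "duration_ratio",
            "angular_velocity": "angular_velocity_deg_s",
            "distance": "distance_rounds",
        }.get(parameter, parameter)
        wide = df.pivot_table(index="fish_id", columns="wavelength_nm", values=col)
        if wide.isna().any().any():
            raise InsufficientDataError(f"incomplete design for parameter {parameter!r}")
        return cls(parameter=parameter, wavelengths=wide.columns.to_numpy(float), values=wide.to_numpy(float))


@dataclass
class PairwiseOutcome:
    level_a: float
    level_b: float
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool | None = None


@dataclass
class StatOutcome:
    test: str
    statistic: float
    df: tuple[float, ...] | None
    p: float
    branch: str | None = None
    epsilon: float | None = None
    pairwise: list[PairwiseOutcome] | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class CascadeResult:
    """Outcome of the full gate -> omnibus -> pairwise cascade."""

    parameter: str
    branch: str  # "parametric" | "nonparametric"
    bartlett: StatOutcome
    sphericity: StatOutcome | None = None
    epsilon: float | None = None
    omnibus: StatOutcome | None = None
    pairwise: list[PairwiseOutcome] | None = None
    control_pairwise: list[PairwiseOutcome] | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def pw(lst):
            if lst is None:
                return None
            return [
                {
                    "level_a": o.level_a,
                    "level_b": o.level_b,
                    "statistic": o.statistic,
                    "p_raw": o.p_raw,
                    "p_adjusted": o.p_adjusted,
                    "significant": o.significant,
                }
                for o in lst
            ]

        return {
            "parameter": self.parameter,
            "branch": self.branch,
            "bartlett_p": self.bartlett.p,
            "sphericity_p": self.sphericity.p if self.sphericity else None,
            "epsilon": self.epsilon,
            "omnibus": None
            if self.omnibus is None
            else {"test": self.omnibus.test, "statistic": self.omnibus.statistic, "df": self.omnibus.df, "p": self.omnibus.p},
            "pairwise": pw(self.pairwise),
            "control_pairwise": pw(self.control_pairwise),
            "notes": self.notes,
        }


# --------------------------------------------------------------------------
# gates


def bartlett_test(series: WavelengthSeries) -> StatOutcome:
    """Bartlett's chi-square test of equal variances across wavelengths."""
    cols = [series.values[:, j] for j in range(series.k)]
    variances = [np.var(c, ddof=1) for c in cols]
    if any(v == 0 for v in variances):
        return StatOutcome(
            test="bartlett", statistic=np.nan, df=(series.k - 1,), p=np.nan,
            notes=["zero-variance column: statistic undefined"],
        )
    stat, p = sps.bartlett(*cols)
    return StatOutcome(test="bartlett", statistic=float(stat), df=(series.k - 1,), p=float(p))


def _contrast_cov(values: np.ndarray) -> np.ndarray:
    """Sample covariance of the data projected on orthonormal contrasts."""
    k = values.shape[1]
    c = helmert(k, full=False)  # (k-1) x k, rows orthonormal, orthogonal to 1
    proj = values @ c.T
    return np.cov(proj, rowvar=False, ddof=1).reshape(k - 1, k - 1)


def gg_epsilon(series: WavelengthSeries) -> float:
    """Greenhouse-Geisser sphericity correction factor.

    epsilon = tr(S_c)^2 / ((k-1) tr(S_c^2)) on the orthonormal-contrast
    covariance S_c, clamped to [1/(k-1), 1]; 1 means sphericity holds.
    """
    k = series.k
    if k == 2:
        return 1.0
    sc = _contrast_cov(series.values)
    tr = np.trace(sc)
    tr2 = np.trace(sc @ sc)
    if tr2 <= 0 or not np.isfinite(tr2):
        return 1.0 / (k - 1)
    eps = tr**2 / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mendoza_sphericity(series: WavelengthSeries) -> StatOutcome:
    """Likelihood-ratio sphericity test on the contrast covariance.

    For the single-group repeated-measures designs analysed here this is the
    Mauchly-type criterion W = det(S_c) / (tr(S_c)/(k-1))^(k-1) with the
    standard chi-square approximation.  Degenerate cases (k = 2, or n too
    small for an estimable covariance) return p = 1 with a note, so the
    caller falls back to an unconditional epsilon adjustment.
    """
    n, k = series.n, series.k
    p_dim = k - 1
    if p_dim == 1:
        return StatOutcome(test="mendoza_sphericity", statistic=0.0, df=(0,), p=1.0,
                           notes=["k=2: single contrast, sphericity trivially holds"])
    if n <= p_dim:
        return StatOutcome(test="mendoza_sphericity", statistic=np.nan, df=None, p=np.nan,
                           notes=["n <= k-1: contrast covariance singular, sphericity inestimable"])
    sc = _contrast_cov(series.values)
    det = np.linalg.det(sc)
    tr = np.trace(sc)
    if det <= 0 or tr <= 0:
        return StatOutcome(test="mendoza_sphericity", statistic=np.nan, df=None, p=np.nan,
                           notes=["degenerate contrast covariance"])
    w = det / (tr / p_dim) ** p_dim
    f = (n - 1) - (2 * p_dim**2 + p_dim + 2) / (6.0 * p_dim)
    stat = -f * np.log(w)
    df = p_dim * (p_dim + 1) // 2 - 1
    p = float(sps.chi2.sf(stat, df))
    return StatOutcome(test="mendoza_sphericity", statistic=float(stat), df=(df,), p=p)


# --------------------------------------------------------------------------
# parametric branch


def rm_anova(series: WavelengthSeries, epsilon: float | None = None) -> StatOutcome:
    """One-way repeated-measures ANOVA (condition = wavelength, subject = fish).

    F = MS_condition / MS_(condition x subject) on (k-1, (k-1)(n-1)) degrees
    of freedom; when ``epsilon`` is supplied both df are multiplied by it
    before the p lookup (Greenhouse-Geisser adjustment).
    """
    x = series.values
    n, k = x.shape
    grand = x.mean()
    col_means = x.mean(axis=0)
    row_means = x.mean(axis=1)
    ss_cond = n * np.sum((col_means - grand) ** 2)
    ss_subj = k * np.sum((row_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        if ms_cond <= 0:
            return StatOutcome(test="rm_anova", statistic=0.0, df=(df1, df2), p=1.0,
                               notes=["no variance anywhere"])
        return StatOutcome(test="rm_anova", statistic=np.inf, df=(df1, df2), p=np.nan,
                           notes=["zero error mean square: p undefined"], epsilon=epsilon)
    fstat = ms_cond / ms_err
    e = 1.0 if epsilon is None else float(epsilon)
    p = float(sps.f.sf(fstat, df1 * e, df2 * e))
    return StatOutcome(test="rm_anova", statistic=float(fstat), df=(df1 * e, df2 * e), p=p, epsilon=epsilon)


def _partitions(n: int, max_part: int | None = None):
    """Integer partitions of n, as non-increasing tuples."""
    if max_part is None:
        max_part = n
    if n == 0:
        yield ()
        return
    for first in range(min(n, max_part), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


def achievable_true_counts(k: int) -> list[int]:
    """Numbers of pairwise equalities achievable by partitioning k levels.

    Each partition of the k levels into equality classes makes exactly
    sum over classes of C(size, 2) pairwise null hypotheses true.
    """
    counts = {sum(s * (s - 1) // 2 for s in part) for part in _partitions(k)}
    return sorted(counts)


def shaffer_multipliers(k: int) -> list[int]:
    """Shaffer (S1) step multipliers for the all-pairs family of k levels.

    At step i (p-values sorted ascending) the multiplier is the largest
    achievable number of true pairwise hypotheses given that i-1 have been
    rejected, i.e. max{a in A : a <= m - (i-1)} with m = C(k,2).
    """
    m = k * (k - 1) // 2
    a = achievable_true_counts(k)
    mult = []
    for i in range(1, m + 1):
        remaining = m - (i - 1)
        mult.append(max(x for x in a if x <= remaining))
    return mult


def shaffer_pairwise(series: WavelengthSeries, alpha: float = 0.05) -> list[PairwiseOutcome]:
    """All-pairs paired t-tests with Shaffer's sequentially rejective adjustment.

    The pairwise tests are paired t on within-fish differences (robust to
    sphericity violation); adjusted p is the running maximum of
    p_(i) x multiplier_i, capped at 1, and significance follows the
    sequential rule at level ``alpha``.
    """
    k = series.k
    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        diff = series.values[:, i] - series.values[:, j]
        if np.allclose(diff, diff[0]):
            # constant difference: t undefined if zero spread
            sd = diff.std(ddof=1)
            if sd == 0:
                stat, p = (0.0, 1.0) if diff[0] == 0 else (np.inf, 0.0)
            else:  # pragma: no cover
                stat, p = sps.ttest_rel(series.values[:, i], series.values[:, j])
        else:
            stat, p = sps.ttest_rel(series.values[:, i], series.values[:, j])
        raw.append((float(stat), float(p)))

    mult = shaffer_multipliers(k)
    order = np.argsort([p for _, p in raw], kind="stable")
    adjusted = np.empty(len(pairs))
    significant = np.empty(len(pairs), dtype=bool)
    running = 0.0
    still_rejecting = True
    for step, idx in enumerate(order):
        p_adj = min(1.0, raw[idx][1] * mult[step])
        running = max(running, p_adj)
        adjusted[idx] = running
        if still_rejecting and raw[idx][1] <= alpha / mult[step]:
            significant[idx] = True
        else:
            significant[idx] = False
            still_rejecting = False
    return [
        PairwiseOutcome(
            level_a=float(series.wavelengths[i]),
            level_b=float(series.wavelengths[j]),
            statistic=raw[idx][0],
            p_raw=raw[idx][1],
            p_adjusted=float(adjusted[idx]),
            significant=bool(significant[idx]),
        )
        for idx, (i, j) in enumerate(pairs)
    ]


# --------------------------------------------------------------------------
# non-parametric branch


def rank_sum_standardized(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized rank-sum statistic of sample ``a`` in the pooled pair.

    Midranks handle ties; the permutation variance uses the exact
    tie-corrected form Var = n_a n_b / (N (N-1)) * (sum r_i^2 - N (N+1)^2/4).
    Returns 0 when every pooled value is tied.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a, n_b = len(a), len(b)
    n_tot = n_a + n_b
    w = ranks[:n_a].sum()
    e_w = n_a * (n_tot + 1) / 2.0
    var_w = n_a * n_b / (n_tot * (n_tot - 1.0)) * (np.sum(ranks**2) - n_tot * (n_tot + 1) ** 2 / 4.0)
    if var_w <= 0:
        return 0.0
    return float((w - e_w) / np.sqrt(var_w))


def steel_dwass(series: WavelengthSeries) -> list[PairwiseOutcome]:
    """Steel-Dwass all-pairs rank comparisons.

    Each pair is ranked on its own pooled sample; the standardized statistic
    t is referred to the infinite-df studentized range with k groups via
    q = |t| * sqrt(2).  For k = 2 this reduces exactly to the two-sided
    normal-approximation rank-sum test.
    """
    k = series.k
    out = []
    for i, j in itertools.combinations(range(k), 2):
        t = rank_sum_standardized(series.values[:, i], series.values[:, j])
        p = studentized_range_sf(abs(t) * np.sqrt(2.0), k) if t != 0 else 1.0
        out.append(
            PairwiseOutcome(
                level_a=float(series.wavelengths[i]),
                level_b=float(series.wavelengths[j]),
                statistic=t,
                p_raw=float(p),
                p_adjusted=float(p),  # the reference distribution is already familywise
            )
        )
    return out


def steel_control(
    series: WavelengthSeries,
    control_level: float,
    alternative: str = "two-sided",
) -> list[PairwiseOutcome]:
    """Steel many-to-one rank comparisons against a control wavelength.

    Every non-control level is compared to the control by the standardized
    rank-sum statistic; multiplicity across the m = k-1 comparisons is
    handled by the equicorrelated (rho = 1/2) multivariate-normal
    max-statistic reference appropriate for balanced many-to-one designs.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ConfigurationError("alternative must be 'two-sided', 'less' or 'greater'")
    match = np.flatnonzero(np.isclose(series.wavelengths, control_level))
    if match.size == 0:
        raise ConfigurationError(f"control level {control_level} not in the wavelength grid")
    c = int(match[0])
    control = series.values[:, c]
    m = series.k - 1
    out = []
    for j in range(series.k):
        if j == c:
            continue
        t = rank_sum_standardized(series.values[:, j], control)
        if alternative == "two-sided":
            p = max_abs_equicorrelated_sf(abs(t), m) if t != 0 else 1.0
        elif alternative == "greater":
            p = max_equicorrelated_sf(t, m)
        else:
            p = max_equicorrelated_sf(-t, m)
        out.append(
            PairwiseOutcome(
                level_a=float(series.wavelengths[j]),
                level_b=float(control_level),
                statistic=t,
                p_raw=float(p),
                p_adjusted=float(p),
            )
        )
    return out


# --------------------------------------------------------------------------
# the cascade


def run_cascade(
    series: WavelengthSeries,
    alpha: float = 0.05,
    control_level: float | None = None,
    steel_alternative: str = "two-sided",
) -> CascadeResult:
    """Bartlett gate -> parametric or non-parametric analysis of one series."""
    bart = bartlett_test(series)
    notes: list[str] = []
    parametric = np.isfinite(bart.p) and bart.p >= alpha
    if not parametric and not np.isfinite(bart.p):
        notes.append("Bartlett statistic undefined (zero-variance column); non-parametric branch")

    if parametric:
        sph = mendoza_sphericity(series)
        eps: float | None = None
        if not np.isfinite(sph.p):
            eps = gg_epsilon(series)
            notes.append("sphericity inestimable; epsilon adjustment applied unconditionally")
        elif sph.p < alpha:
            eps = gg_epsilon(series)
        omnibus = rm_anova(series, epsilon=eps)
        pairwise = shaffer_pairwise(series, alpha=alpha)
        return CascadeResult(
            parameter=series.parameter,
            branch="parametric",
            bartlett=bart,
            sphericity=sph,
            epsilon=eps,
            omnibus=omnibus,
            pairwise=pairwise,
            notes=notes,
        )

    notes.append("independent-samples rank procedures applied to repeated measures")
    pairwise = steel_dwass(series)
    control_pw = None
    if control_level is not None:
        control_pw = steel_control(series, control_level, alternative=steel_alternative)
    return CascadeResult(
        parameter=series.parameter,
        branch="nonparametric",
        bartlett=bart,
        pairwise=pairwise,
        control_pairwise=control_pw,
        notes=notes,
    )
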