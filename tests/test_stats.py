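import itertools

import numpy as np
import pytest
from scipy import stats as sps

from omrkit.distributions import (
    max_abs_equicorrelated_sf,
    max_equicorrelated_sf,
    studentized_range_sf,
)
from omrkit.errors import InsufficientDataError
from omrkit.stats import (
    WavelengthSeries,
    achievable_true_counts,
    bartlett_test,
    gg_epsilon,
    mendoza_sphericity,
    rank_sum_standardized,
    rm_anova,
    run_cascade,
    shaffer_multipliers,
    shaffer_pairwise,
    steel_control,
    steel_dwass,
)


def series(values, wavelengths=None, parameter="distance"):
    values = np.asarray(values, dtype=float)
    if wavelengths is None:
        wavelengths = 700 + 50 * np.arange(values.shape[1])
    return WavelengthSeries(parameter, wavelengths, values)


# --------------------------------------------------------------------------
# reference distributions


class TestDistributions:
    @pytest.mark.parametrize("k,q05", [(2, 2.772), (3, 3.314), (4, 3.633), (5, 3.858)])
    def test_studentized_range_tabulated_critical_values(self, k, q05):
        assert studentized_range_sf(q05, k) == pytest.approx(0.05, abs=2e-4)

    def test_studentized_range_matches_scipy_large_df(self):
        for k, q in [(3, 2.0), (4, 3.5), (6, 4.2)]:
            ref = sps.studentized_range.sf(q, k, 1e7)
            assert studentized_range_sf(q, k) == pytest.approx(ref, abs=1e-6)

    def test_max_abs_m1_is_two_sided_normal(self):
        for t in (0.5, 1.96, 3.0):
            assert max_abs_equicorrelated_sf(t, 1) == pytest.approx(2 * sps.norm.sf(t), abs=1e-8)

    def test_max_abs_m2_matches_bivariate_normal(self):
        rho = 0.5
        cov = np.array([[1, rho], [rho, 1]])
        mvn = sps.multivariate_normal(mean=[0, 0], cov=cov)
        for c in (1.0, 2.0, 2.5):
            inside = (
                mvn.cdf([c, c]) - mvn.cdf([c, -c]) - mvn.cdf([-c, c]) + mvn.cdf([-c, -c])
            )
            assert max_abs_equicorrelated_sf(c, 2) == pytest.approx(1 - inside, abs=1e-6)

    def test_one_sided_bounds_two_sided(self):
        assert max_equicorrelated_sf(2.0, 4) < max_abs_equicorrelated_sf(2.0, 4)


# --------------------------------------------------------------------------
# gates


class TestBartlett:
    def test_identical_variances_give_zero_statistic(self):
        col = np.arange(10.0)
        out = bartlett_test(series(np.column_stack([col, col + 5, col - 3])))
        assert out.statistic == pytest.approx(0.0, abs=1e-12)
        assert out.p == pytest.approx(1.0)

    def test_two_group_hand_formula(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(10)
        b = 2 * rng.standard_normal(10)
        out = bartlett_test(series(np.column_stack([a, b])))
        # direct evaluation of Bartlett's statistic
        n, k = 10, 2
        sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        num = (2 * n - k) * np.log(sp2) - (n - 1) * (np.log(np.var(a, ddof=1)) + np.log(np.var(b, ddof=1)))
        den = 1 + (2 / (n - 1) - 1 / (2 * n - k)) / (3 * (k - 1))
        assert out.statistic == pytest.approx(num / den, rel=1e-10)

    def test_zero_variance_column_flagged(self):
        out = bartlett_test(series(np.column_stack([np.ones(5), np.arange(5.0)])))
        assert np.isnan(out.p)
        assert out.notes

    def test_single_column_rejected(self):
        with pytest.raises(InsufficientDataError):
            series(np.ones((5, 1)))


class TestEpsilonAndSphericity:
    def test_two_levels_epsilon_is_one(self):
        rng = np.random.default_rng(1)
        assert gg_epsilon(series(rng.standard_normal((6, 2)))) == 1.0

    def test_exact_compound_symmetry_epsilon_is_one(self):
        """Data whose sample covariance is exactly compound-symmetric."""
        rng = np.random.default_rng(2)
        k = 4
        z = rng.standard_normal((20, k))
        z -= z.mean(axis=0)
        # whiten the sample covariance, then colour with a CS matrix
        s = np.cov(z, rowvar=False)
        white = z @ np.linalg.inv(np.linalg.cholesky(s)).T
        cs = 0.4 * np.ones((k, k)) + 0.6 * np.eye(k)
        x = white @ np.linalg.cholesky(cs).T
        assert gg_epsilon(series(x)) == pytest.approx(1.0, abs=1e-10)

    def test_epsilon_matches_eigenvalue_oracle(self):
        """epsilon equals (sum li)^2 / ((k-1) sum li^2) over contrast-cov eigenvalues."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((8, 4)) @ np.diag([1.0, 2.0, 0.5, 3.0])
        from scipy.linalg import helmert

        c = helmert(4, full=False)
        lam = np.linalg.eigvalsh(c @ np.cov(x, rowvar=False) @ c.T)
        oracle = lam.sum() ** 2 / (3 * (lam**2).sum())
        assert gg_epsilon(series(x)) == pytest.approx(oracle, rel=1e-10)

    def test_two_levels_sphericity_degenerate(self):
        rng = np.random.default_rng(4)
        out = mendoza_sphericity(series(rng.standard_normal((6, 2))))
        assert out.p == 1.0

    def test_statistic_matches_pingouin_mauchly(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        x = rng.standard_normal((10, 4)) @ np.diag([1, 1.5, 0.7, 2.0])
        df = pd.DataFrame(
            {"y": x.ravel(), "s": np.repeat(range(10), 4), "c": list(range(4)) * 10}
        )
        ref = pg.sphericity(df, dv="y", subject="s", within="c")
        out = mendoza_sphericity(series(x))
        assert out.statistic == pytest.approx(float(ref.chi2), rel=1e-9)

    def test_null_calibration_and_power(self):
        """Near-nominal size on spherical data; high power on AR structure."""
        rng = np.random.default_rng(6)
        n, k, reps = 60, 4, 300
        rej_null = 0
        for _ in range(reps):
            out = mendoza_sphericity(series(rng.standard_normal((n, k))))
            rej_null += out.p < 0.05
        assert 0.015 <= rej_null / reps <= 0.10  # 0.05 +- ~4 MC s.e.

        ar = np.array([[0.8 ** abs(i - j) for j in range(k)] for i in range(k)])
        chol = np.linalg.cholesky(ar)
        rej_alt = 0
        for _ in range(100):
            x = rng.standard_normal((n, k)) @ chol.T
            rej_alt += mendoza_sphericity(series(x)).p < 0.05
        assert rej_alt / 100 > 0.9


# --------------------------------------------------------------------------
# parametric branch


class TestRmAnova:
    def test_no_condition_effect_f_zero(self):
        subj = np.arange(6.0)[:, None]
        x = np.tile(subj, (1, 4))  # identical condition means, arbitrary subject offsets
        out = rm_anova(series(x))
        assert out.statistic == pytest.approx(0.0, abs=1e-12)
        assert out.p == pytest.approx(1.0)

    def test_two_levels_equals_squared_paired_t(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((9, 2))
        x[:, 1] += 0.8
        out = rm_anova(series(x))
        t, _ = sps.ttest_rel(x[:, 0], x[:, 1])
        assert out.statistic == pytest.approx(t**2, rel=1e-10)

    def test_brute_force_sums_of_squares(self):
        """F from an independent cell-by-cell SS decomposition."""
        rng = np.random.default_rng(8)
        x = rng.standard_normal((6, 5)) + np.linspace(0, 2, 5)
        n, k = x.shape
        grand = x.mean()
        ss_cond = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
        ss_subj = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
        ss_err = sum(
            (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
            for i in range(n)
            for j in range(k)
        )
        f_oracle = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        out = rm_anova(series(x))
        assert out.statistic == pytest.approx(f_oracle, rel=1e-10)
        assert out.p == pytest.approx(float(sps.f.sf(f_oracle, k - 1, (k - 1) * (n - 1))), rel=1e-10)

    def test_subject_shift_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((6, 4))
        shifted = x + rng.standard_normal((6, 1)) * 100
        assert rm_anova(series(x)).statistic == pytest.approx(
            rm_anova(series(shifted)).statistic, rel=1e-8
        )

    def test_epsilon_deflates_df(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((6, 4)) + np.linspace(0, 1, 4)
        full = rm_anova(series(x))
        adj = rm_anova(series(x), epsilon=0.5)
        assert adj.df == (full.df[0] * 0.5, full.df[1] * 0.5)
        assert adj.p > full.p  # same F, fewer df

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(11)
        x = rng.standard_normal((8, 4)) + np.linspace(0, 1.5, 4)
        df = pd.DataFrame({"y": x.ravel(), "s": np.repeat(range(8), 4), "c": list(range(4)) * 8})
        aov = pg.rm_anova(dv="y", within="c", subject="s", data=df, correction=True, detailed=True)
        out = rm_anova(series(x))
        assert out.statistic == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert out.p == pytest.approx(float(aov["p_unc"].iloc[0]), rel=1e-6)
        gg = rm_anova(series(x), epsilon=gg_epsilon(series(x)))
        assert gg.p == pytest.approx(float(aov["p_GG_corr"].iloc[0]), rel=1e-6)


def partition_truth_counts_oracle(k):
    """Independent enumeration: all set partitions of k levels via restricted growth."""
    counts = set()

    def grow(assignment, next_label):
        if len(assignment) == k:
            sizes = np.bincount(assignment)
            counts.add(int(sum(s * (s - 1) // 2 for s in sizes)))
            return
        for lab in range(next_label + 1):
            grow(assignment + [lab], max(next_label, lab + 1))

    grow([0], 1)
    return sorted(counts)


class TestShaffer:
    @pytest.mark.parametrize("k,expected", [(3, [3, 1, 1]), (4, [6, 3, 3, 3, 2, 1])])
    def test_multipliers_match_enumeration(self, k, expected):
        assert shaffer_multipliers(k) == expected

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_achievable_counts_against_set_partition_oracle(self, k):
        assert achievable_true_counts(k) == partition_truth_counts_oracle(k)

    def test_single_pair_adjusted_equals_raw(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((8, 2))
        out = shaffer_pairwise(series(x))
        assert out[0].p_adjusted == pytest.approx(out[0].p_raw)

    def test_adjusted_between_raw_and_bonferroni(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((8, 5)) + np.linspace(0, 1, 5)
        out = shaffer_pairwise(series(x))
        m = len(out)
        for o in out:
            assert o.p_adjusted >= o.p_raw - 1e-12
            assert o.p_adjusted <= min(1.0, o.p_raw * m) + 1e-12

    def test_adjusted_monotone_in_step_order(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((6, 4)) + np.linspace(0, 2, 4)
        out = shaffer_pairwise(series(x))
        ordered = sorted(out, key=lambda o: o.p_raw)
        adj = [o.p_adjusted for o in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(adj[:-1], adj[1:]))


# --------------------------------------------------------------------------
# non-parametric branch


def enumerate_rank_splits(pooled, n_a):
    """All C(N, n_a) assignments of the pooled sample to group a."""
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    sums = np.array([ranks[list(c)].sum() for c in itertools.combinations(range(n_tot), n_a)])
    return sums


class TestSteelDwass:
    def test_two_groups_reduce_to_normal_rank_sum(self):
        rng = np.random.default_rng(15)
        x = np.column_stack([rng.standard_normal(10), rng.standard_normal(10) + 1])
        out = steel_dwass(series(x))[0]
        assert out.p_raw == pytest.approx(2 * sps.norm.sf(abs(out.statistic)), rel=1e-9)

    def test_identical_samples_statistic_zero_p_one(self):
        x = np.column_stack([np.arange(6.0), np.arange(6.0), np.arange(6.0)])
        for o in steel_dwass(series(x)):
            assert o.statistic == 0.0
            assert o.p_raw == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal((8, 3)) + [0, 1, 2]
        p1 = [o.p_raw for o in steel_dwass(series(x))]
        p2 = [o.p_raw for o in steel_dwass(series(np.exp(x)))]
        assert np.allclose(p1, p2)

    def test_moments_match_exhaustive_enumeration(self):
        """Tie-corrected E[W], Var[W] equal brute-force permutation moments."""
        a = np.array([1.0, 2.0, 2.0, 4.0])
        b = np.array([2.0, 3.0, 5.0, 5.0])
        sums = enumerate_rank_splits(np.concatenate([a, b]), 4)
        t_impl = rank_sum_standardized(a, b)
        ranks = sps.rankdata(np.concatenate([a, b]))
        w_obs = ranks[:4].sum()
        t_oracle = (w_obs - sums.mean()) / sums.std(ddof=0)
        assert t_impl == pytest.approx(t_oracle, abs=1e-12)

    def test_asymptotic_close_to_exact_max_statistic_enumeration(self):
        """Approximation check: studentized-range p within a few percent of the
        exact permutation distribution of the max pairwise statistic."""
        groups = [np.array([1.0, 2.0, 3.0, 4.0]),
                  np.array([2.0, 4.0, 5.0, 6.0]),
                  np.array([5.0, 6.0, 7.0, 9.0])]
        ws = series(np.column_stack(groups), [700, 750, 800])
        asym = steel_dwass(ws)
        pooled = np.concatenate(groups)
        maxts = []
        for g1 in itertools.combinations(range(12), 4):
            rest = [i for i in range(12) if i not in g1]
            for g2 in itertools.combinations(rest, 4):
                g3 = [i for i in rest if i not in g2]
                a, b, c = pooled[list(g1)], pooled[list(g2)], pooled[g3]
                maxts.append(
                    max(
                        abs(rank_sum_standardized(a, b)),
                        abs(rank_sum_standardized(a, c)),
                        abs(rank_sum_standardized(b, c)),
                    )
                )
        maxts = np.array(maxts)
        for o in asym:
            p_exact = float(np.mean(maxts >= abs(o.statistic) - 1e-9))
            assert o.p_raw == pytest.approx(p_exact, abs=0.05)


class TestSteelControl:
    def test_control_identical_to_treatments(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 4))
        for o in steel_control(series(x), control_level=850.0):
            assert o.p_raw == 1.0

    def test_single_treatment_reduces_to_rank_sum(self):
        rng = np.random.default_rng(17)
        x = np.column_stack([rng.standard_normal(8), rng.standard_normal(8) + 1])
        out = steel_control(series(x), control_level=700.0)
        assert len(out) == 1
        assert out[0].p_raw == pytest.approx(2 * sps.norm.sf(abs(out[0].statistic)), rel=1e-6)

    def test_missing_control_level_rejected(self):
        rng = np.random.default_rng(18)
        from omrkit.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            steel_control(series(rng.standard_normal((6, 3))), control_level=999.0)


# --------------------------------------------------------------------------
# the cascade


class TestRunCascade:
    def test_homoscedastic_gaussian_goes_parametric(self):
        rng = np.random.default_rng(19)
        x = rng.standard_normal((6, 5)) + np.linspace(0, 1, 5)
        out = run_cascade(series(x))
        assert out.branch == "parametric"
        assert out.omnibus is not None
        assert out.pairwise is not None

    def test_heteroscedastic_heavy_tails_go_nonparametric(self):
        rng = np.random.default_rng(20)
        chosen = 0
        reps = 100
        for _ in range(reps):
            x = np.column_stack(
                [rng.standard_normal(8)]
                + [scale * rng.standard_t(2, size=8) for scale in (1, 3, 10, 30)]
            )
            if run_cascade(series(x)).branch == "nonparametric":
                chosen += 1
        assert chosen / reps > 0.9

    def test_control_comparison_included_on_request(self):
        x = np.column_stack([np.ones(6), np.arange(6.0), 10 * np.arange(6.0)])
        out = run_cascade(series(x, [780, 860, 950]), control_level=950.0)
        assert out.branch == "nonparametric"  # zero-variance column fails the gate
        assert out.control_pairwise is not None
        assert len(out.control_pairwise) == 2

    def test_epsilon_engaged_when_sphericity_rejected(self):
        rng = np.random.default_rng(21)
        # strongly non-spherical covariance
        k = 5
        ar = np.array([[0.95 ** abs(i - j) for j in range(k)] for i in range(k)])
        x = rng.standard_normal((40, k)) @ np.linalg.cholesky(ar).T * [1, 2, 4, 8, 16]
        out = run_cascade(series(x))
        if out.branch == "parametric" and out.sphericity.p < 0.05:
            assert out.epsilon is not None
            assert out.epsilon < 1.0
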