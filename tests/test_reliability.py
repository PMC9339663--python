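"""ICC forms, permutation paired t-test, GG-corrected rmANOVA, Spearman."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dfckit as dk


def _icc_oracle(x, form):
    """Two-pass sums-of-squares oracle, written independently with loops."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    row_means = [x[i].sum() / k for i in range(n)]
    col_means = [x[:, j].sum() / n for j in range(k)]
    ss_b = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_w = sum((x[i, j] - row_means[i]) ** 2 for i in range(n) for j in range(k))
    ss_j = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_e = ss_w - ss_j
    bms = ss_b / (n - 1)
    wms = ss_w / (n * (k - 1))
    ems = ss_e / ((n - 1) * (k - 1))
    if form == "1,1":
        return (bms - wms) / (bms + (k - 1) * wms)
    return (bms - ems) / (bms + (k - 1) * ems)


class TestIcc:
    def test_perfect_agreement_gives_unity(self):
        col = np.array([1.0, 2.0, 5.0, 9.0, 3.0, 7.0])
        x = np.tile(col[:, None], (1, 4))
        assert dk.icc(x, "1,1").value == pytest.approx(1.0)
        assert dk.icc(x, "3,1").value == pytest.approx(1.0)

    @pytest.mark.parametrize("form", ["1,1", "3,1"])
    def test_random_table_matches_mean_squares_oracle(self, form):
        rng = np.random.default_rng(70)
        x = rng.normal(size=(6, 4))
        assert dk.icc(x, form).value == pytest.approx(_icc_oracle(x, form), abs=1e-12)

    @pytest.mark.parametrize("form", ["1,1", "3,1"])
    def test_agrees_with_pingouin(self, form):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(71)
        x = rng.normal(size=(8, 4)) + 2 * rng.normal(size=(8, 1))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 4),
            "rater": np.tile(np.arange(4), 8),
            "y": x.ravel(),
        })
        res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="y")
        row = 0 if form == "1,1" else 2  # ICC1 / ICC3 (consistency, single)
        assert dk.icc(x, form).value == pytest.approx(res["ICC"].iloc[row], abs=1e-10)

    def test_pure_noise_mean_near_zero(self):
        rng = np.random.default_rng(72)
        vals = [dk.icc(rng.normal(size=(10, 4)), "1,1").value for _ in range(200)]
        assert abs(np.mean(vals)) < 0.05

    def test_zero_variance_flagged_undefined(self):
        with pytest.warns(UserWarning, match="zero total variance"):
            res = dk.icc(np.full((5, 3), 2.0), "1,1")
        assert np.isnan(res.value)

    def test_affine_invariance(self):
        rng = np.random.default_rng(73)
        x = rng.normal(size=(7, 4))
        for form in ("1,1", "3,1"):
            a = dk.icc(x, form).value
            b = dk.icc(3.7 * x - 11.2, form).value
            assert a == pytest.approx(b, abs=1e-10)


class TestPermPairedTtest:
    def test_identical_samples_give_p_one(self):
        a = np.arange(8.0)
        res = dk.perm_paired_ttest(a, a, n_perm=100, seed=0)
        assert res.p_value == 1.0 and res.t_observed == 0.0

    def test_within_monte_carlo_error_of_exhaustive_enumeration(self):
        rng = np.random.default_rng(74)
        a = rng.normal(size=8)
        b = a + 0.8 + rng.normal(size=8)
        d = a - b
        # exhaustive 2^8 sign-flip oracle
        n = 8
        t_obs = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        count = 0
        for signs in itertools.product((-1, 1), repeat=n):
            dd = d * np.array(signs)
            t = dd.mean() / (dd.std(ddof=1) / np.sqrt(n))
            if abs(t) >= abs(t_obs):
                count += 1
        p_exact = count / 2 ** n
        res = dk.perm_paired_ttest(a, b, n_perm=4000, seed=1)
        se = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(res.p_value - p_exact) < 4 * se + 1 / 4000

    def test_detects_large_shift(self):
        rng = np.random.default_rng(75)
        a = rng.normal(size=20)
        res = dk.perm_paired_ttest(a, a + 2.0, n_perm=999, seed=2)
        assert res.p_value < 0.01

    def test_p_values_valid_under_null(self):
        # P(p <= alpha) <= alpha + Monte-Carlo slack for alpha .01 and .05
        rng = np.random.default_rng(76)
        pvals = []
        for i in range(400):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            pvals.append(dk.perm_paired_ttest(a, b, n_perm=199, seed=1000 + i).p_value)
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05):
            assert np.mean(pvals <= alpha) <= alpha + 0.03


def _rm_anova_oracle(x):
    n, k = x.shape
    grand = x.mean()
    ss_subj = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cond = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_subj - ss_cond
    f = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    s = np.cov(x, rowvar=False, ddof=1)
    sc = s - s.mean(axis=0)[None, :] - s.mean(axis=1)[:, None] + s.mean()
    eps = np.trace(sc) ** 2 / ((k - 1) * (sc ** 2).sum())
    return f, eps


class TestRmAnovaGG:
    def test_two_conditions_have_epsilon_one(self):
        rng = np.random.default_rng(77)
        res = dk.rm_anova_gg(rng.normal(size=(8, 2)))
        assert res.epsilon == pytest.approx(1.0, abs=1e-12)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(78)
        x = rng.normal(size=(6, 4))
        res = dk.rm_anova_gg(x)
        f, eps = _rm_anova_oracle(x)
        assert res.f_value == pytest.approx(f, abs=1e-10)
        assert res.epsilon == pytest.approx(eps, abs=1e-10)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(79)
        x = rng.normal(size=(9, 4))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(9), 4),
            "cond": np.tile(np.arange(4), 9),
            "y": x.ravel(),
        })
        aov = pg.rm_anova(data=df, dv="y", within="cond", subject="subject",
                          correction=True)
        res = dk.rm_anova_gg(x)
        assert res.f_value == pytest.approx(aov["F"].iloc[0], abs=1e-8)
        assert res.epsilon == pytest.approx(aov["eps"].iloc[0], abs=1e-8)
        assert res.p_value == pytest.approx(aov["p_GG_corr"].iloc[0], abs=1e-8)

    def test_null_effect_small_f(self):
        rng = np.random.default_rng(80)
        offsets = rng.normal(size=(10, 1)) * 3
        x = np.tile(offsets, (1, 4)) + 1e-6 * rng.normal(size=(10, 4))
        res = dk.rm_anova_gg(x)
        assert res.p_value > 0.1

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(81)
        for _ in range(20):
            k = rng.integers(2, 6)
            x = rng.normal(size=(8, k))
            eps = dk.rm_anova_gg(x).epsilon
            assert 1 / (k - 1) - 1e-12 <= eps <= 1 + 1e-12


class TestSpearman:
    def _frame(self, cols):
        return pd.DataFrame(cols)

    def test_monotone_pair_perfect_correlation(self):
        x = np.array([1.0, 3.0, 4.0, 8.0, 10.0])
        df = self._frame({"a": x, "b": np.exp(x)})
        rho, _, _ = dk.spearman_matrix(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_reversed_monotone_pair(self):
        x = np.array([1.0, 3.0, 4.0, 8.0, 10.0])
        df = self._frame({"a": x, "b": -(x ** 3)})
        rho, _, _ = dk.spearman_matrix(df)
        assert rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_ties_match_midrank_pearson_oracle(self):
        rng = np.random.default_rng(82)
        a = rng.integers(0, 4, size=30).astype(float)
        b = a + rng.integers(0, 3, size=30)
        rho, _, _ = dk.spearman_matrix(self._frame({"a": a, "b": b}))
        ra = stats.rankdata(a)  # mid-ranks
        rb = stats.rankdata(b)
        expect = stats.pearsonr(ra, rb).statistic
        assert rho.loc["a", "b"] == pytest.approx(expect, abs=1e-12)

    def test_constant_column_flagged(self):
        df = self._frame({"a": np.arange(6.0), "b": np.ones(6)})
        with pytest.warns(UserWarning, match="constant"):
            rho, _, sig = dk.spearman_matrix(df)
        assert np.isnan(rho.loc["a", "b"])
        assert not sig.loc["a", "b"]


class TestMetricTableHelpers:
    def _table(self):
        rng = np.random.default_rng(83)
        rows = []
        for s in range(6):
            for r in range(1, 5):
                rows.append({"subject": f"s{s}", "run": r, "metric": "META",
                             "mode": "global", "value": rng.normal()})
        return pd.DataFrame(rows)

    def test_wide_pivot_shape(self):
        wide = dk.metric_table_to_wide(self._table(), "META")
        assert wide.shape == (6, 4)

    def test_standardize_zero_mean_unit_sd(self):
        z = dk.standardize_metric_table(self._table())
        assert z["value"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z["value"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
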