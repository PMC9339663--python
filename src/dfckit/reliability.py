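"""Test-retest and relational statistics over the per-subject metric table.

Implements the Shrout & Fleiss intraclass correlations ICC(1,1) (one-way
random, agreement) and ICC(3,1) (two-way mixed, consistency) from ANOVA
mean squares, a sign-flip permutation paired t-test, one-factor
repeated-measures ANOVA with Greenhouse-Geisser sphericity correction,
and Spearman correlation matrices across metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IccResult",
    "PermTestResult",
    "RmAnovaResult",
    "icc",
    "perm_paired_ttest",
    "rm_anova_gg",
    "spearman_matrix",
    "standardize_metric_table",
    "metric_table_to_wide",
]


@dataclass
class IccResult:
    value: float
    form: str
    bms: float
    wms: float
    jms: float
    ems: float
    n_subjects: int
    n_raters: int


def icc(table: np.ndarray, form: str = "3,1") -> IccResult:
    """Intraclass correlation from a complete subjects x raters matrix.

    ICC(1,1) = (BMS - WMS) / (BMS + (k-1) WMS)   one-way random, agreement
    ICC(3,1) = (BMS - EMS) / (BMS + (k-1) EMS)   two-way mixed, consistency

    with BMS/WMS/JMS/EMS the between-subject, within-subject, between-rater
    and residual ANOVA mean squares and k the rater count. A table with zero
    total variance has no defined ICC (homogeneous-sample caveat) and
    returns NaN with a warning.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be 2-D subjects x raters")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 subjects and >= 2 raters, got {n} x {k}")
    if not np.isfinite(x).all():
        raise ValueError("table must be complete (no missing values)")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = np.sum((x - grand) ** 2)
    ss_subj = k * np.sum((row_means - grand) ** 2)
    ss_rater = n * np.sum((col_means - grand) ** 2)
    ss_within = np.sum((x - row_means[:, None]) ** 2)
    ss_err = ss_within - ss_rater
    bms = ss_subj / (n - 1)
    wms = ss_within / (n * (k - 1))
    jms = ss_rater / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if ss_total <= 1e-300:
        warnings.warn("zero total variance: ICC undefined")
        value = float("nan")
    elif form == "1,1":
        value = (bms - wms) / (bms + (k - 1) * wms)
    elif form == "3,1":
        value = (bms - ems) / (bms + (k - 1) * ems)
    else:
        raise ValueError(f"unsupported ICC form {form!r}; use '1,1' or '3,1'")
    return IccResult(float(value), form, bms, wms, jms, ems, n, k)


@dataclass
class PermTestResult:
    p_value: float
    t_observed: float
    n_permutations: int


def perm_paired_ttest(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermTestResult:
    """Permutation paired t-test via random sign-flips of the differences.

    The null exchanges condition labels within each pair, i.e. flips the
    sign of each difference. The reported p uses the add-one estimator
    p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1), which is valid at any
    permutation count. All-zero differences give p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D samples")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.all(d == 0):
        return PermTestResult(1.0, 0.0, n_perm)

    def tstat(diffs: np.ndarray) -> np.ndarray:
        m = diffs.mean(axis=-1)
        s = diffs.std(axis=-1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(s > 0, m / (s / np.sqrt(n)), np.sign(m) * np.inf)

    t_obs = float(tstat(d))
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    t_perm = tstat(signs * d)
    exceed = int(np.sum(np.abs(t_perm) >= abs(t_obs)))
    p = (1 + exceed) / (n_perm + 1)
    return PermTestResult(float(p), t_obs, n_perm)


@dataclass
class RmAnovaResult:
    f_value: float
    df1: float
    df2: float
    epsilon: float
    p_value: float
    p_uncorrected: float


def rm_anova_gg(table: np.ndarray) -> RmAnovaResult:
    """One-factor within-subject ANOVA with Greenhouse-Geisser correction.

    ``table`` is complete subjects x conditions. F = MS_condition /
    MS_(subject x condition); epsilon = (tr S~)^2 / ((k-1) sum S~_ij^2) on
    the double-centered condition covariance, and both degrees of freedom
    are multiplied by epsilon before the F-distribution p-value.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be 2-D subjects x conditions")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 subjects and >= 2 conditions, got {n} x {k}")
    if not np.isfinite(x).all():
        raise ValueError("table must be complete")
    grand = x.mean()
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_cond
    if ss_total <= 1e-300 or ss_err <= 1e-300:
        warnings.warn("degenerate table: F undefined")
        return RmAnovaResult(float("nan"), k - 1, (n - 1) * (k - 1), 1.0,
                             float("nan"), float("nan"))
    ms_cond = ss_cond / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    f = ms_cond / ms_err
    cov = np.cov(x, rowvar=False, ddof=1)
    centered = cov - cov.mean(axis=0) - cov.mean(axis=1)[:, None] + cov.mean()
    eps = np.trace(centered) ** 2 / ((k - 1) * np.sum(centered ** 2))
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))
    df1, df2 = eps * (k - 1), eps * (n - 1) * (k - 1)
    p = float(stats.f.sf(f, df1, df2))
    p_unc = float(stats.f.sf(f, k - 1, (n - 1) * (k - 1)))
    return RmAnovaResult(float(f), df1, df2, eps, p, p_unc)


def spearman_matrix(
    metrics: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations across metric columns.

    ``metrics`` is subjects x metrics (aligned within one run). Mid-rank
    ties; two-sided p via the t approximation. Constant columns yield NaN
    correlations, flagged non-significant. Returns (rho, p, significant).
    """
    if metrics.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    cols = list(metrics.columns)
    m = len(cols)
    rho = np.eye(m)
    pmat = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            xi = metrics.iloc[:, i].to_numpy(dtype=float)
            xj = metrics.iloc[:, j].to_numpy(dtype=float)
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                warnings.warn(
                    f"constant metric column in pair ({cols[i]}, {cols[j]}): "
                    "correlation undefined"
                )
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(xi, xj)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(pmat, index=cols, columns=cols)
    sig = (p_df < alpha) & np.isfinite(rho_df)
    np.fill_diagonal(sig.values, False)
    return rho_df, p_df, sig


def standardize_metric_table(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score the long-format metric table within each (metric, mode) cell.

    This is the standardized tidy table an external mixed-effects fit
    consumes; columns: subject, run, metric, mode, value.
    """
    out = table.copy()

    def _z(g: pd.Series) -> pd.Series:
        sd = g.std(ddof=1)
        return (g - g.mean()) / sd if sd > 0 else g * 0.0

    out["value"] = out.groupby(["metric", "mode"])["value"].transform(_z)
    return out


def metric_table_to_wide(
    table: pd.DataFrame, metric: str, mode: str = "global"
) -> pd.DataFrame:
    """Pivot one metric of the long table to a subjects x runs matrix."""
    sel = table[(table["metric"] == metric) & (table["mode"] == mode)]
    wide = sel.pivot(index="subject", columns="run", values="value")
    if wide.isna().any().any():
        n_drop = int(wide.isna().any(axis=1).sum())
        warnings.warn(f"dropping {n_drop} subjects with missing cells ({metric})")
        wide = wide.dropna()
    return wide
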