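"""Mode-resolved temporal metrics and fractal scaling of the dFC stream.

Fractional occurrence and mean dwell duration come straight from the
mode-label sequence; reconfiguration speed is 1 minus the Pearson
correlation between consecutive phase-locking matrices; detrended
fluctuation analysis (DFA) quantifies long-range temporal correlation in
any derived series, with a BIC-based polynomial model comparison guarding
against non-power-law (curved) log-log scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeedSeries",
    "DfaResult",
    "fractional_occurrence",
    "mean_duration",
    "run_lengths",
    "reconfiguration_speed",
    "dfa_alpha",
    "dfa_linearity",
    "default_dfa_scales",
]


def _check_mode(labels: np.ndarray, k: int, n_modes: int | None) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    kmax = int(n_modes) if n_modes is not None else int(labels.max())
    if not 1 <= k <= kmax:
        raise ValueError(f"mode {k} outside 1..{kmax}")
    return labels


def fractional_occurrence(labels: np.ndarray, k: int, n_modes: int | None = None) -> float:
    """Proportion of timepoints assigned to mode ``k`` (bounded in [0, 1])."""
    labels = _check_mode(labels, k, n_modes)
    return float(np.mean(labels == k))


def run_lengths(labels: np.ndarray, k: int) -> np.ndarray:
    """Lengths (in timepoints) of consecutive visits to mode ``k``."""
    labels = np.asarray(labels)
    is_k = np.concatenate(([0], (labels == k).astype(int), [0]))
    d = np.diff(is_k)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def mean_duration(
    labels: np.ndarray, k: int, tr: float, n_modes: int | None = None
) -> float:
    """Mean dwell time of mode ``k`` in seconds.

    Runs touching the series boundaries count. Returns NaN when the mode
    never occurs (never zero, which would bias cohort means).
    """
    labels = _check_mode(labels, k, n_modes)
    runs = run_lengths(labels, k)
    if runs.size == 0:
        return float("nan")
    return float(runs.mean() * tr)


@dataclass
class SpeedSeries:
    """Per-step dFC reconfiguration speed, 1 - corr(iPL(t), iPL(t+1)) in [0, 2].

    ``labels_at_t`` carries the mode label of the step's earlier timepoint
    (a step belongs to the state it departs from), or None.
    """

    values: np.ndarray
    labels_at_t: np.ndarray | None = None

    @property
    def typical(self) -> float:
        """Median speed — robust to the heavy-tailed 'knots and leaps' profile."""
        return float(np.nanmedian(self.values))

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    def per_mode(self, n_modes: int) -> dict[int, float]:
        if self.labels_at_t is None:
            raise ValueError("no mode labels attached to this speed series")
        out = {}
        for k in range(1, n_modes + 1):
            vals = self.values[self.labels_at_t == k]
            out[k] = float(np.nanmedian(vals)) if vals.size else float("nan")
        return out


def reconfiguration_speed(
    slices: np.ndarray, labels: np.ndarray | None = None
) -> SpeedSeries:
    """Speed of the dFC stream from consecutive phase-locking matrices.

    ``slices`` is the (T_eff, N, N) phase-locking tensor. For each step the
    strict upper triangles at t and t+1 are correlated (Pearson); speed is
    1 - r. Identical consecutive slices give speed 0; a constant (zero
    variance) triangle against a differing one yields NaN (flagged missing).
    """
    slices = np.asarray(slices, dtype=float)
    if slices.ndim != 3 or slices.shape[0] < 2:
        raise ValueError("need a (T, N, N) tensor with T >= 2")
    n = slices.shape[1]
    iu = np.triu_indices(n, k=1)
    v = slices[:, iu[0], iu[1]]  # (T, E)
    vc = v - v.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(vc, axis=1)
    num = np.sum(vc[:-1] * vc[1:], axis=1)
    den = norms[:-1] * norms[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    speed = 1.0 - r
    degenerate = den == 0
    if degenerate.any():
        same = np.all(np.isclose(v[:-1], v[1:]), axis=1)
        speed[degenerate & same] = 0.0
        speed[degenerate & ~same] = np.nan
    speed = np.clip(speed, 0.0, 2.0, out=speed, where=~np.isnan(speed))
    labels_at_t = None if labels is None else np.asarray(labels)[:-1]
    return SpeedSeries(values=speed, labels_at_t=labels_at_t)


@dataclass
class DfaResult:
    """DFA output: scaling exponent with its fluctuation function and linearity gate.

    ``alpha`` is the least-squares slope of log F(n) on log n; ``genuine``
    is True when a straight line beats higher-order polynomials under BIC,
    i.e. the scaling is an extended power law rather than a curved trend.
    """

    alpha: float
    intercept: float
    scales: np.ndarray
    fluct: np.ndarray
    best_order: int
    genuine: bool
    bic: dict[int, float] = field(default_factory=dict)


def default_dfa_scales(length: int, n_scales: int = 20, smallest: int = 10) -> np.ndarray:
    """~20 log-spaced integer window sizes from ``smallest`` to length/4."""
    largest = length // 4
    if largest < smallest:
        raise ValueError(f"series of length {length} too short for DFA")
    scales = np.unique(
        np.round(np.logspace(np.log10(smallest), np.log10(largest), n_scales)).astype(int)
    )
    return scales


def dfa_alpha(
    series: np.ndarray,
    scales: np.ndarray | None = None,
    *,
    max_order: int = 3,
) -> DfaResult:
    """Detrended fluctuation analysis with order-1 detrending.

    The series is demeaned and integrated; within non-overlapping windows of
    each size a linear trend is removed and F(n) is the RMS residual. Alpha
    0.5 marks a memoryless process, (0.5, 1] persistent long-range
    correlation, ~1.5 integrated noise.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    t = x.size
    if scales is None:
        scales = default_dfa_scales(t)
    scales = np.asarray(scales, dtype=int)
    if scales.size < 8:
        raise ValueError(f"need at least 8 scales, got {scales.size}")
    if np.any(np.diff(scales) <= 0):
        raise ValueError("scales must be strictly increasing")
    if t < 4 * scales[-1]:
        raise ValueError(
            f"series length {t} below 4 x largest scale ({4 * scales[-1]})"
        )
    profile = np.cumsum(x - x.mean())
    fluct = np.empty(scales.size)
    for i, n in enumerate(scales):
        m = t // n
        seg = profile[: m * n].reshape(m, n)
        tt = np.arange(n, dtype=float)
        # per-window linear least squares, vectorized over windows
        coeffs = np.polynomial.polynomial.polyfit(tt, seg.T, 1)  # (2, m)
        trend = coeffs[0][:, None] + coeffs[1][:, None] * tt[None, :]
        fluct[i] = np.sqrt(np.mean((seg - trend) ** 2))
    if np.any(fluct <= 0):
        raise ValueError("zero fluctuation at some scale (constant series?)")
    logn, logf = np.log(scales.astype(float)), np.log(fluct)
    slope, intercept = np.polyfit(logn, logf, 1)
    best_order, bic = dfa_linearity(logn, logf, max_order=max_order)
    return DfaResult(
        alpha=float(slope),
        intercept=float(intercept),
        scales=scales,
        fluct=fluct,
        best_order=best_order,
        genuine=(best_order == 1),
        bic=bic,
    )


def dfa_linearity(
    logn_or_result, logf: np.ndarray | None = None, *, max_order: int = 3
) -> tuple[int, dict[int, float]]:
    """Model comparison for power-law linearity of the log-log fluctuation plot.

    Fits polynomials of order 1..max_order by least squares and scores each
    with BIC = m*ln(RSS/m) + p*ln(m) (m scales, p = order + 1 parameters).
    Returns (best order, BIC per order); scaling is genuine iff the best
    order is 1.
    """
    if logf is None:
        res: DfaResult = logn_or_result
        logn = np.log(res.scales.astype(float))
        logf = np.log(res.fluct)
    else:
        logn = np.asarray(logn_or_result, dtype=float)
        logf = np.asarray(logf, dtype=float)
    m = logn.size
    if m < max_order + 3:
        raise ValueError(f"need at least max_order + 3 = {max_order + 3} scales")
    bic: dict[int, float] = {}
    for order in range(1, max_order + 1):
        coef = np.polyfit(logn, logf, order)
        rss = float(np.sum((logf - np.polyval(coef, logn)) ** 2))
        rss = max(rss, 1e-300)
        bic[order] = m * np.log(rss / m) + (order + 1) * np.log(m)
    best = min(bic, key=bic.get)
    return best, bic
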