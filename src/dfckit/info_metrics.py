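"""Information-theoretic metrics on binarized coalition dynamics.

Community synchrony series are thresholded into binary coalition states
("which communities are internally synchronized now"). Coalition entropy
H_C is the Shannon entropy of the visited-state distribution in bits.
Integrated information Phi-R is whole-minus-sum integrated information
with the minimum-mutual-information (MMI) double-redundancy correction,
computed on the discrete state sequence at a lag tau and swept over an
integration-timescale range, retaining the maximum.

All distributions are discrete plug-in estimates; a Miller-Madow entropy
bias correction is available for diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .sync_metrics import CommunitySyncSeries, DEFAULT_LAMBDA

__all__ = [
    "CoalitionSeries",
    "LaggedJointDistribution",
    "PhiBipartition",
    "PhiResult",
    "binarize_coalitions",
    "coalition_entropy",
    "lagged_joint_distribution",
    "phi_r_from_joint",
    "phi_r",
]

_EPS = 1e-12


@dataclass
class CoalitionSeries:
    """Binary coalition matrix, shape (T_eff, K); entry 1 = community synchronized."""

    bits: np.ndarray
    lambda_threshold: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2:
            raise ValueError("bits must be (T_eff, K)")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        self.bits = self.bits.astype(np.uint8)

    @property
    def n_timepoints(self) -> int:
        return self.bits.shape[0]

    @property
    def n_channels(self) -> int:
        return self.bits.shape[1]

    def codes(self) -> np.ndarray:
        """Encode each row as an integer state in [0, 2^K)."""
        weights = 1 << np.arange(self.n_channels)
        return (self.bits.astype(np.int64) * weights).sum(axis=1)


def binarize_coalitions(
    css: CommunitySyncSeries, lambda_threshold: float | None = None
) -> CoalitionSeries:
    """bit(t, psi) = 1 iff |Z_psi(t)| > lambda (strict)."""
    lam = css.lambda_threshold if lambda_threshold is None else lambda_threshold
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    return CoalitionSeries((css.magnitude > lam).T.astype(np.uint8), lam)


def _entropy_from_probs(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def coalition_entropy(cs: CoalitionSeries, *, miller_madow: bool = False) -> float:
    """Shannon entropy, in bits, of the coalition-state distribution.

    Plug-in estimate from state counts; bounded in [0, K]. The optional
    Miller-Madow term adds (#observed states - 1) / (2 T ln 2).
    """
    codes = cs.codes()
    counts = np.bincount(codes, minlength=2 ** cs.n_channels)
    p = counts / counts.sum()
    h = _entropy_from_probs(p)
    if miller_madow:
        h += (np.count_nonzero(counts) - 1) / (2 * cs.n_timepoints * np.log(2))
    return h


@dataclass
class LaggedJointDistribution:
    """Joint distribution of (X_t, X_{t+tau}) over 2^K x 2^K coalition states.

    Supports exact analytic tables (``n_pairs`` None) as well as plug-in
    empirical estimates; provides marginalization to any channel subsets
    and the entropy/mutual-information terms Phi-R needs.
    """

    joint: np.ndarray
    n_channels: int
    tau: int
    n_pairs: int | None = None

    def __post_init__(self) -> None:
        self.joint = np.asarray(self.joint, dtype=float)
        s = 2 ** self.n_channels
        if self.joint.shape != (s, s):
            raise ValueError(f"joint must be {s} x {s}")
        if np.any(self.joint < -_EPS):
            raise ValueError("negative joint probabilities")
        total = self.joint.sum()
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"joint sums to {total}, not 1")

    def _submap(self, channels: tuple[int, ...]) -> np.ndarray:
        """Map full-state code -> sub-state code over the given channels."""
        s = 2 ** self.n_channels
        codes = np.arange(s)
        sub = np.zeros(s, dtype=np.int64)
        for bit, ch in enumerate(channels):
            sub |= ((codes >> ch) & 1) << bit
        return sub

    def sub_joint(
        self, channels_t: tuple[int, ...], channels_tau: tuple[int, ...]
    ) -> np.ndarray:
        """Marginal joint table over (subset at t, subset at t+tau)."""
        ma = self._submap(tuple(channels_t))
        mb = self._submap(tuple(channels_tau))
        out = np.zeros((2 ** len(channels_t), 2 ** len(channels_tau)))
        np.add.at(out, (ma[:, None], mb[None, :]), self.joint)
        return out

    def marginal_t(self, channels: tuple[int, ...] | None = None) -> np.ndarray:
        channels = tuple(range(self.n_channels)) if channels is None else tuple(channels)
        return np.bincount(self._submap(channels), weights=self.joint.sum(axis=1),
                           minlength=2 ** len(channels))

    def marginal_tau(self, channels: tuple[int, ...] | None = None) -> np.ndarray:
        channels = tuple(range(self.n_channels)) if channels is None else tuple(channels)
        return np.bincount(self._submap(channels), weights=self.joint.sum(axis=0),
                           minlength=2 ** len(channels))

    def entropy_t(self, channels: tuple[int, ...] | None = None,
                  *, miller_madow: bool = False) -> float:
        p = self.marginal_t(channels)
        h = _entropy_from_probs(p)
        if miller_madow and self.n_pairs:
            h += (np.count_nonzero(p > 0) - 1) / (2 * self.n_pairs * np.log(2))
        return h

    def mutual_information(
        self,
        channels_t: tuple[int, ...] | None = None,
        channels_tau: tuple[int, ...] | None = None,
        *,
        miller_madow: bool = False,
    ) -> float:
        """I(subset at t ; subset at t+tau) in bits, via H(X)+H(Y)-H(X,Y)."""
        channels_t = tuple(range(self.n_channels)) if channels_t is None else tuple(channels_t)
        channels_tau = tuple(range(self.n_channels)) if channels_tau is None else tuple(channels_tau)
        pj = self.sub_joint(channels_t, channels_tau)
        px = pj.sum(axis=1)
        py = pj.sum(axis=0)
        hx, hy, hxy = (_entropy_from_probs(p) for p in (px, py, pj.ravel()))
        if miller_madow and self.n_pairs:
            corr = lambda p: (np.count_nonzero(np.asarray(p) > 0) - 1) / (
                2 * self.n_pairs * np.log(2)
            )
            hx, hy, hxy = hx + corr(px), hy + corr(py), hxy + corr(pj.ravel())
        return hx + hy - hxy


def lagged_joint_distribution(cs: CoalitionSeries, tau: int) -> LaggedJointDistribution:
    """Plug-in joint over (X_t, X_{t+tau}) from the T_eff - tau overlapping pairs."""
    t_eff = cs.n_timepoints
    if not 1 <= tau < t_eff - 1:
        raise ValueError(f"tau={tau} infeasible for series of length {t_eff}")
    codes = cs.codes()
    s = 2 ** cs.n_channels
    pairs = codes[:-tau] * s + codes[tau:]
    counts = np.bincount(pairs, minlength=s * s).reshape(s, s).astype(float)
    n = t_eff - tau
    return LaggedJointDistribution(counts / n, cs.n_channels, tau, n_pairs=n)


@dataclass
class PhiBipartition:
    """Phi-R evaluated at one bipartition {part, complement}."""

    part: tuple[int, ...]
    complement: tuple[int, ...]
    wms: float
    redundancy: float
    phi_r: float
    normalization: float


@dataclass
class PhiResult:
    """Phi-R across an integration-timescale sweep."""

    per_tau: list[tuple[int, float, tuple[int, ...]]]
    max_phi: float
    argmax_tau: int
    details: dict[int, PhiBipartition] = field(default_factory=dict)


def _bipartitions(k: int):
    """All 2^(K-1) - 1 unordered bipartitions; channel 0 stays in part 1."""
    rest = list(range(1, k))
    for r in range(0, k - 1 + 1):
        for combo in combinations(rest, r):
            part = (0, *combo)
            if len(part) == k:
                continue
            comp = tuple(c for c in range(k) if c not in part)
            yield part, comp


def phi_r_from_joint(
    joint: LaggedJointDistribution,
    *,
    normalized_mib: bool = True,
    miller_madow: bool = False,
) -> PhiBipartition:
    """Phi-R of a lagged joint distribution at its minimum-information bipartition.

    For a bipartition B = {M1, M2}:
        PhiWMS(B) = I(X_t; X_{t+tau}) - I(M1_t; M1_{t+tau}) - I(M2_t; M2_{t+tau})
        red(B)    = min over (j, k) of I(Mj_t; Mk_{t+tau})   (MMI double redundancy)
        PhiR(B)   = PhiWMS(B) + red(B)
    The MIB minimizes PhiWMS normalized by min(H(M1_t), H(M2_t)); bipartitions
    with a zero-entropy part are skipped, falling back to unnormalized
    selection when every denominator vanishes.
    """
    k = joint.n_channels
    if k < 2:
        raise ValueError("Phi-R needs at least 2 channels")
    if k > 8:
        raise ValueError("exhaustive bipartition scan limited to K <= 8")
    mm = miller_madow
    i_whole = joint.mutual_information(miller_madow=mm)
    candidates: list[PhiBipartition] = []
    for part, comp in _bipartitions(k):
        i_11 = joint.mutual_information(part, part, miller_madow=mm)
        i_22 = joint.mutual_information(comp, comp, miller_madow=mm)
        i_12 = joint.mutual_information(part, comp, miller_madow=mm)
        i_21 = joint.mutual_information(comp, part, miller_madow=mm)
        wms = i_whole - i_11 - i_22
        red = min(i_11, i_12, i_21, i_22)
        denom = min(joint.entropy_t(part, miller_madow=mm),
                    joint.entropy_t(comp, miller_madow=mm))
        candidates.append(
            PhiBipartition(part, comp, wms, red, wms + red, denom)
        )
    usable = [c for c in candidates if c.normalization > _EPS]
    if usable and normalized_mib:
        mib = min(usable, key=lambda c: c.wms / c.normalization)
    else:
        mib = min(candidates, key=lambda c: c.wms)
    return mib


def phi_r(
    cs: CoalitionSeries,
    tau_range=range(1, 501),
    *,
    normalized_mib: bool = True,
    miller_madow: bool = False,
    min_pairs: int = 2,
) -> PhiResult:
    """Integrated information Phi-R over an integration-timescale sweep.

    For each lag tau in ``tau_range`` (truncated automatically to the series
    length), the plug-in lagged joint is formed and Phi-R evaluated at the
    minimum-information bipartition; the maximum over tau and its argmax are
    retained, in bits. A constant series has no dynamics: Phi-R is defined
    as 0 with a warning.
    """
    t_eff = cs.n_timepoints
    if np.all(cs.bits == cs.bits[0]):
        warnings.warn("all coalition channels constant; Phi-R defined as 0")
        return PhiResult(per_tau=[], max_phi=0.0, argmax_tau=0)
    per_tau: list[tuple[int, float, tuple[int, ...]]] = []
    details: dict[int, PhiBipartition] = {}
    for tau in tau_range:
        if tau >= t_eff - 1 or (t_eff - tau) < min_pairs:
            continue
        joint = lagged_joint_distribution(cs, tau)
        bp = phi_r_from_joint(
            joint, normalized_mib=normalized_mib, miller_madow=miller_madow
        )
        per_tau.append((tau, bp.phi_r, bp.part))
        details[tau] = bp
    if not per_tau:
        raise ValueError("no feasible tau in the requested range")
    best = max(per_tau, key=lambda t: t[1])
    return PhiResult(
        per_tau=per_tau, max_phi=best[1], argmax_tau=best[0], details=details
    )
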