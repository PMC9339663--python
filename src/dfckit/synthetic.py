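"""Synthetic generators with known ground truth for every pipeline stage.

Four families of fixtures:

* modular Kuramoto oscillator networks (tunable intra/inter-community
  coupling: full-sync, incoherent, and metastable/chimera regimes),
* planted recurring phase-locking modes driven by a Markov dwell process,
* exact fractional Gaussian noise with a chosen Hurst exponent
  (circulant embedding), and
* binary Markov coalition sources whose stationary lagged joint — hence
  coalition entropy and integrated information — is available in closed
  form.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_prep import ParcelTimeSeries, bandpass_dft
from .info_metrics import CoalitionSeries, LaggedJointDistribution
from .leida import leading_eigenvector, _sign_normalize

__all__ = [
    "KuramotoConfig",
    "KuramotoResult",
    "simulate_modular_kuramoto",
    "PlantedModesResult",
    "generate_planted_modes",
    "generate_fgn",
    "MarkovCoalitionSource",
    "generate_binary_markov",
]


@dataclass
class KuramotoConfig:
    """Modular Kuramoto network configuration.

    Natural frequencies are Gaussian in the resting-state BOLD band
    (mean 0.04 Hz, SD 0.005 Hz by default, converted to rad/s). Pairwise
    coupling is ``k_intra`` within a community and ``k_inter`` between,
    scaled by 1/N (mean-field normalization). ``noise_sd`` is the phase
    diffusion intensity in rad/sqrt(s). Output matches the fMRI sampling
    geometry: TR 0.72 s and 1200 samples by default, after a burn-in
    discarded to let the dynamics settle.
    """

    n_oscillators: int = 90
    n_communities: int = 5
    communities: list[np.ndarray] | None = None
    omega: np.ndarray | None = None
    omega_mean_hz: float = 0.04
    omega_sd_hz: float = 0.02
    k_intra: float = 1.2
    k_inter: float = 0.02
    noise_sd: float = 0.15
    dt: float = 0.036
    tr: float = 0.72
    duration: float = 864.0
    burn_in: float = 72.0
    obs_noise_sd: float = 0.0
    band_limit: bool = True
    band: tuple[float, float] = (0.01, 0.08)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt > self.tr / 10 + 1e-12:
            raise ValueError("dt must be <= tr/10")
        if self.duration / self.tr < 256:
            raise ValueError("duration must cover at least 256 output samples")
        if self.communities is None:
            blocks = np.array_split(np.arange(self.n_oscillators), self.n_communities)
            self.communities = [np.asarray(b) for b in blocks]
        else:
            self.communities = [np.asarray(c, dtype=int) for c in self.communities]
            self.n_communities = len(self.communities)


@dataclass
class KuramotoResult:
    ts: ParcelTimeSeries
    phases: np.ndarray
    communities: list[np.ndarray]
    omega: np.ndarray


def _coupling_matrix(cfg: KuramotoConfig) -> np.ndarray:
    n = cfg.n_oscillators
    k = np.full((n, n), cfg.k_inter, dtype=float)
    for comm in cfg.communities:
        k[np.ix_(comm, comm)] = cfg.k_intra
    np.fill_diagonal(k, 0.0)
    return k


def simulate_modular_kuramoto(cfg: KuramotoConfig) -> KuramotoResult:
    """Euler-Maruyama integration of a modular Kuramoto network.

        dtheta_i = omega_i dt + (1/N) sum_j K_ij sin(theta_j - theta_i) dt
                   + noise_sd dW_i

    The BOLD-like observable is cos(theta) (plus optional observation
    noise), downsampled to the TR grid; ground-truth phases at the sampled
    instants are returned for oracle tests.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_oscillators
    omega = cfg.omega
    if omega is None:
        omega = 2 * np.pi * rng.normal(cfg.omega_mean_hz, cfg.omega_sd_hz, size=n)
    kmat = _coupling_matrix(cfg)
    stride = int(round(cfg.tr / cfg.dt))
    n_samples = int(round(cfg.duration / cfg.tr))
    burn_steps = int(round(cfg.burn_in / cfg.dt))
    total_steps = burn_steps + n_samples * stride
    theta = rng.uniform(-np.pi, np.pi, size=n)
    sqrt_dt = np.sqrt(cfg.dt)
    phases = np.empty((n, n_samples))
    sample_idx = 0
    for step in range(total_steps + 1):
        if step >= burn_steps and (step - burn_steps) % stride == 0:
            if sample_idx < n_samples:
                phases[:, sample_idx] = theta
                sample_idx += 1
        if step == total_steps:
            break
        p = np.exp(1j * theta)
        coupling = (np.conj(p) * (kmat @ p)).imag / n
        dtheta = (omega + coupling) * cfg.dt + cfg.noise_sd * sqrt_dt * rng.standard_normal(n)
        if np.max(np.abs(dtheta)) > np.pi:
            raise ValueError(
                f"unstable integration step at t={step * cfg.dt:.3f}s: "
                "|dtheta| > pi; reduce dt or coupling"
            )
        theta = theta + dtheta
    wrapped = np.angle(np.exp(1j * phases))
    wrapped[wrapped == -np.pi] = np.pi
    x = np.cos(phases)
    if cfg.obs_noise_sd > 0:
        x = x + cfg.obs_noise_sd * rng.standard_normal(x.shape)
    ts = ParcelTimeSeries(x, cfg.tr, [f"osc_{i}" for i in range(n)])
    if cfg.band_limit:
        ts = bandpass_dft(ts, *cfg.band)
    return KuramotoResult(ts=ts, phases=wrapped, communities=cfg.communities, omega=omega)


@dataclass
class PlantedModesResult:
    ts: ParcelTimeSeries
    labels: np.ndarray
    phases: np.ndarray
    centroids: np.ndarray
    patterns: np.ndarray
    tr: float


def generate_planted_modes(
    patterns: np.ndarray,
    occupancies: np.ndarray,
    dwell: float,
    noise_sd: float = 0.1,
    *,
    n_timepoints: int = 1200,
    tr: float = 0.72,
    carrier_hz: float = 0.04,
    heterogeneity: float = 0.35,
    layout_seed: int = 0,
    seed: int | None = None,
) -> PlantedModesResult:
    """Plant recurring phase-locking modes with a Markov dwell process.

    ``patterns`` (N x K) are unit-norm, sign-normalized two-community sign
    patterns: the positive minority is phase-shifted by pi against the
    rest. Each pattern additionally carries a fixed per-region phase-offset
    profile (scale ``heterogeneity`` rad, seeded by ``layout_seed`` so it is
    shared across runs); the induced leading eigenvectors — returned as
    ``centroids`` — are the effective ground truth the pipeline should
    recover. At each timepoint the active pattern's phase profile gets a
    common in-band carrier rotation plus von-Mises jitter of scale
    ``noise_sd`` rad.

    The label process stays in place and re-draws from ``occupancies`` at
    rate 1/dwell, so targeted occupancies are the stationary distribution.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2:
        raise ValueError("patterns must be N x K")
    n, k = patterns.shape
    occupancies = np.asarray(occupancies, dtype=float)
    if occupancies.shape != (k,) or abs(occupancies.sum() - 1) > 1e-8:
        raise ValueError("occupancies must be length K and sum to 1")
    norms = np.linalg.norm(patterns, axis=0)
    if np.any(np.abs(norms - 1) > 1e-6):
        raise ValueError("infeasible pattern: columns must be unit vectors")
    for j in range(k):
        if np.sum(patterns[:, j] > 0) > np.sum(patterns[:, j] < 0):
            raise ValueError(f"pattern {j} not sign-normalized (majority positive)")
    if dwell < 1:
        raise ValueError("dwell must be >= 1 timepoint")
    # fixed per-pattern phase profiles, independent of the run seed
    layout_rng = np.random.default_rng(layout_seed)
    base = np.where(patterns > 0, np.pi, 0.0)
    offsets = heterogeneity * layout_rng.uniform(-1.0, 1.0, size=(n, k))
    profiles = base + offsets  # (N, K)
    centroids = np.empty((n, k))
    for j in range(k):
        ipl = np.cos(profiles[:, j][:, None] - profiles[:, j][None, :])
        centroids[:, j], _ = leading_eigenvector(ipl)
    rng = np.random.default_rng(seed)
    labels = np.empty(n_timepoints, dtype=int)
    state = int(rng.choice(k, p=occupancies))
    for t in range(n_timepoints):
        if t > 0 and rng.random() < 1.0 / dwell:
            state = int(rng.choice(k, p=occupancies))
        labels[t] = state
    kappa = 1.0 / max(noise_sd, 1e-6) ** 2
    jitter = rng.vonmises(0.0, kappa, size=(n, n_timepoints)) if noise_sd > 0 else 0.0
    carrier = 2 * np.pi * carrier_hz * tr * np.arange(n_timepoints)
    theta = profiles[:, labels] + carrier[None, :] + jitter
    theta = np.angle(np.exp(1j * theta))
    theta[theta == -np.pi] = np.pi
    ts = ParcelTimeSeries(np.cos(theta), tr, [f"region_{i}" for i in range(n)])
    return PlantedModesResult(
        ts=ts,
        labels=labels + 1,
        phases=theta,
        centroids=centroids,
        patterns=patterns,
        tr=tr,
    )


def generate_fgn(hurst: float, length: int, seed: int | None = None) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding.

    Uses the fGn autocovariance gamma(m) = 0.5 (|m+1|^{2H} - 2|m|^{2H} +
    |m-1|^{2H}) embedded in a circulant matrix whose eigenvalues come from
    one FFT (Davies-Harte / Dietrich-Newsam). ``length`` must be a power of
    two. A numerically non-PSD embedding falls back to eigenvalue clipping
    with a warning.
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must lie in (0, 1)")
    if length < 2 or length & (length - 1):
        raise ValueError("length must be a power of 2")
    n = length
    m = 2 * n
    lag = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (
        np.abs(lag + 1) ** (2 * hurst)
        - 2 * np.abs(lag) ** (2 * hurst)
        + np.abs(lag - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-9:
        warnings.warn(
            f"circulant embedding not PSD (min eigenvalue {lam.min():.3g}); "
            "clipping negative eigenvalues"
        )
    lam = np.clip(lam, 0.0, None)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(np.sqrt(lam / m) * eps)
    return w.real[:n]


@dataclass
class MarkovCoalitionSource:
    """Sampled binary Markov coalition series plus its analytic distributions."""

    series: CoalitionSeries
    transition: np.ndarray
    stationary: np.ndarray
    n_channels: int

    def lagged_joint(self, tau: int) -> LaggedJointDistribution:
        """Exact stationary joint of (X_t, X_{t+tau}): diag(pi) P^tau."""
        if tau < 1:
            raise ValueError("tau must be >= 1")
        ptau = np.linalg.matrix_power(self.transition, tau)
        joint = self.stationary[:, None] * ptau
        return LaggedJointDistribution(joint, self.n_channels, tau, n_pairs=None)

    def exact_entropy(self) -> float:
        """Stationary coalition entropy in bits."""
        p = self.stationary[self.stationary > 0]
        return float(-np.sum(p * np.log2(p)))


def generate_binary_markov(
    transition: np.ndarray, length: int, seed: int | None = None
) -> MarkovCoalitionSource:
    """Sample a binary coalition series from a joint-state Markov chain.

    ``transition`` is row-stochastic over the 2^K joint states (state i is
    the K-bit pattern of channel values). The chain must be irreducible; its
    stationary distribution and lag-tau joints are computed analytically so
    entropy and Phi-R estimators can be checked against exact values.
    """
    p = np.asarray(transition, dtype=float)
    s = p.shape[0]
    if p.ndim != 2 or p.shape[1] != s:
        raise ValueError("transition must be square")
    k = int(round(np.log2(s)))
    if 2 ** k != s:
        raise ValueError("transition size must be a power of 2")
    if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1) > 1e-8):
        raise ValueError("rows must be non-negative and sum to 1")
    n_comp, _ = connected_components(csr_matrix(p > 0), connection="strong")
    if n_comp != 1:
        raise ValueError("chain is reducible; no unique stationary distribution")
    vals, vecs = np.linalg.eig(p.T)
    i = int(np.argmin(np.abs(vals - 1)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(p, axis=1)
    codes = np.empty(length, dtype=np.int64)
    state = int(rng.choice(s, p=pi))
    u = rng.random(length)
    for t in range(length):
        codes[t] = state
        state = int(np.searchsorted(cdf[state], u[t], side="right"))
        state = min(state, s - 1)
    bits = ((codes[:, None] >> np.arange(k)[None, :]) & 1).astype(np.uint8)
    return MarkovCoalitionSource(
        series=CoalitionSeries(bits),
        transition=p,
        stationary=pi,
        n_channels=k,
    )
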