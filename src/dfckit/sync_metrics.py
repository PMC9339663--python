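"""Community-level Kuramoto statistics.

Each LEiDA mode defines a community of oscillating regions (communities may
overlap — the global mode spans all regions). The complex order parameter
Z_psi(t) = <e^{i theta(r,t)}>, r in psi, yields per-community synchrony
(time mean of |Z|), metastability (SD over time of |Z|), the chimera index
(variance of |Z| across communities at each instant), and phase-coherence
events between internally synchronized communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_prep import PhaseStream

__all__ = [
    "CommunitySyncSeries",
    "SyncMetastability",
    "community_order_parameter",
    "sync_and_metastability",
    "chimera_index",
    "phase_coherence_events",
]

DEFAULT_LAMBDA = 0.8


@dataclass
class CommunitySyncSeries:
    """Complex Kuramoto order parameter per community, shape (K, T_eff)."""

    z: np.ndarray
    tr_seconds: float = 1.0
    lambda_threshold: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=complex)
        if self.z.ndim != 2:
            raise ValueError("z must be (K, T_eff)")
        if np.any(np.abs(self.z) > 1 + 1e-9):
            raise ValueError("|Z| must not exceed 1")

    @property
    def magnitude(self) -> np.ndarray:
        """|Z_psi(t)|: 1 fully synchronized, 0 fully desynchronized."""
        return np.minimum(np.abs(self.z), 1.0)

    @property
    def mean_phase(self) -> np.ndarray:
        return np.angle(self.z)

    @property
    def n_communities(self) -> int:
        return self.z.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.z.shape[1]


def community_order_parameter(
    ps: PhaseStream | np.ndarray,
    communities: list[np.ndarray],
    *,
    lambda_threshold: float = DEFAULT_LAMBDA,
) -> CommunitySyncSeries:
    """Z_psi(t) = mean of e^{i theta(r,t)} over each community's regions."""
    theta = ps.theta if isinstance(ps, PhaseStream) else np.asarray(ps, float)
    tr = ps.tr_seconds if isinstance(ps, PhaseStream) else 1.0
    n = theta.shape[0]
    phasors = np.exp(1j * theta)
    rows = []
    for idx, comm in enumerate(communities):
        comm = np.asarray(comm, dtype=int)
        if comm.size == 0:
            raise ValueError(f"community {idx} is empty")
        if comm.min() < 0 or comm.max() >= n:
            raise ValueError(f"community {idx} has region indices outside 0..{n - 1}")
        rows.append(phasors[comm].mean(axis=0))
    return CommunitySyncSeries(
        np.vstack(rows), tr_seconds=tr, lambda_threshold=lambda_threshold
    )


@dataclass
class SyncMetastability:
    """Per-community and global synchrony/metastability summary."""

    sync: np.ndarray
    meta: np.ndarray
    global_sync: float
    global_meta: float


def sync_and_metastability(css: CommunitySyncSeries) -> SyncMetastability:
    """SYNC = time mean of |Z|; META = sample SD (ddof=1) of |Z| over time.

    Global values are arithmetic means across the K communities.
    """
    mag = css.magnitude
    if mag.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    sync = mag.mean(axis=1)
    meta = mag.std(axis=1, ddof=1)
    return SyncMetastability(
        sync=sync,
        meta=meta,
        global_sync=float(sync.mean()),
        global_meta=float(meta.mean()),
    )


def chimera_index(css: CommunitySyncSeries) -> tuple[np.ndarray, float]:
    """Instantaneous chimerality and its time average CHI.

    Chimerality at t is the population variance across the K communities of
    |Z_psi(t)| — nonzero when some communities are synchronized while others
    are not. Bounded in [0, 0.25].
    """
    if css.n_communities < 2:
        raise ValueError("chimera index needs at least 2 communities")
    inst = css.magnitude.var(axis=0, ddof=0)
    return inst, float(inst.mean())


def phase_coherence_events(
    css: CommunitySyncSeries, lambda_threshold: float | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Cross-community phase-coherence events and the PCC.

    At each t, communities with |Z| > lambda are internally synchronized; if
    at least two are, their mean phases are combined into a cross-community
    order parameter R_cross(t) = |mean of e^{i arg Z_psi(t)}|. Coherence
    occurs when R_cross(t) > lambda (one threshold for both roles). PCC is
    the fraction of timepoints with coherence.

    Returns ``(occurred, r_cross, pcc)``; ``r_cross`` is NaN where fewer
    than two communities are supra-threshold.
    """
    lam = css.lambda_threshold if lambda_threshold is None else lambda_threshold
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    mag = css.magnitude
    phase = css.mean_phase
    supra = mag > lam
    t_eff = css.n_timepoints
    r_cross = np.full(t_eff, np.nan)
    occurred = np.zeros(t_eff, dtype=bool)
    counts = supra.sum(axis=0)
    for t in np.flatnonzero(counts >= 2):
        ph = phase[supra[:, t], t]
        r = np.abs(np.mean(np.exp(1j * ph)))
        r_cross[t] = r
        occurred[t] = r > lam
    pcc = float(occurred.mean())
    return occurred, r_cross, pcc
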