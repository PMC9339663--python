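"""Leading-eigenvector dynamics analysis (LEiDA).

From an instantaneous phase stream, build the per-timepoint phase-locking
matrices cos(theta_n - theta_p), reduce each to its leading eigenvector,
cluster the eigenvector stream into K recurring modes with cosine-distance
K-means, select K by silhouette, assign timepoints, match modes across
runs, and read off each mode's phase-shifted community.

Mode labels are 1-based (psi_1 .. psi_K), following the field's naming;
region and column indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_prep import PhaseStream

__all__ = [
    "EigenStream",
    "ModeSet",
    "phase_locking_tensor",
    "leading_eigenvector",
    "eigen_stream",
    "cluster_modes",
    "select_k_silhouette",
    "assign_modes",
    "match_modes_across_runs",
    "reorder_modes",
    "extract_community",
    "mode_agreement_icc",
]


def phase_locking_tensor(ps: PhaseStream | np.ndarray) -> np.ndarray:
    """Instantaneous phase-locking tensor, shape (T_eff, N, N).

    Entry (t, n, p) is cos(theta_n(t) - theta_p(t)): +1 in-phase, -1
    anti-phase. Each slice is symmetric with an exactly unit diagonal.
    """
    theta = ps.theta if isinstance(ps, PhaseStream) else np.asarray(ps, float)
    c, s = np.cos(theta), np.sin(theta)  # (N, T)
    ipl = np.einsum("nt,pt->tnp", c, c) + np.einsum("nt,pt->tnp", s, s)
    n = theta.shape[0]
    ipl[:, np.arange(n), np.arange(n)] = 1.0
    # enforce exact symmetry against floating-point asymmetry in einsum
    ipl = 0.5 * (ipl + np.swapaxes(ipl, 1, 2))
    return np.clip(ipl, -1.0, 1.0)


def _sign_normalize(v: np.ndarray) -> np.ndarray:
    """Flip so strictly more than half the elements are negative.

    Exact positive/negative ties are broken by forcing the largest-magnitude
    element negative.
    """
    v = np.asarray(v, dtype=float)
    n_pos = int(np.sum(v > 0))
    n_neg = int(np.sum(v < 0))
    if n_pos > n_neg:
        return -v
    if n_pos == n_neg and v[np.argmax(np.abs(v))] > 0:
        return -v
    return v


def leading_eigenvector(slice_: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit eigenvector of the largest-magnitude eigenvalue of a symmetric slice.

    The sign convention makes the majority of elements negative, so the
    phase-shifted minority community carries positive sign.
    """
    m = np.asarray(slice_, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("slice must be square")
    vals, vecs = np.linalg.eigh(m)
    i = int(np.argmax(np.abs(vals)))
    v = vecs[:, i]
    v = v / np.linalg.norm(v)
    return _sign_normalize(v), float(vals[i])


@dataclass
class EigenStream:
    """Leading-eigenvector time series: ``vectors`` is N x T_eff (unit columns)."""

    vectors: np.ndarray
    eigenvalues: np.ndarray
    tr_seconds: float = 1.0
    region_labels: list[str] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.vectors.shape[1]


def eigen_stream(ps: PhaseStream, *, tensor: np.ndarray | None = None) -> EigenStream:
    """Leading eigenvector V1(t) for every phase-locking slice."""
    ipl = phase_locking_tensor(ps) if tensor is None else tensor
    t_eff, n, _ = ipl.shape
    vectors = np.empty((n, t_eff))
    eigenvalues = np.empty(t_eff)
    for t in range(t_eff):
        try:
            vectors[:, t], eigenvalues[t] = leading_eigenvector(ipl[t])
        except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy fallback
            raise np.linalg.LinAlgError(
                f"eigendecomposition failed at timepoint {t}: {exc}"
            ) from exc
    return EigenStream(
        vectors,
        eigenvalues,
        tr_seconds=ps.tr_seconds,
        region_labels=list(ps.region_labels),
    )


@dataclass
class ModeSet:
    """K recurring phase-locking modes from clustering an eigenvector stream.

    ``centroids`` is N x K (unit-norm, sign-normalized columns), ``labels``
    the 1-based assignment of every pooled timepoint, sorted so mode 1 has
    the highest fractional occurrence. ``communities[k]`` holds the 0-based
    region indices of mode k+1's phase-shifted community.
    """

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    silhouette: float | None = None
    communities: list[np.ndarray] = field(default_factory=list)
    inertia: float = np.nan
    seed: int | None = None

    @property
    def occupancies(self) -> np.ndarray:
        return np.array(
            [np.mean(self.labels == k) for k in range(1, self.k + 1)]
        )


def _cosine_kmeans_once(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float] | None:
    """One restart of K-means under cosine distance on unit columns.

    Returns (centroids, labels0, inertia) or None if a cluster emptied.
    """
    d, n = x.shape
    centroids = x[:, rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        sim = centroids.T @ x  # (k, n)
        new_labels = np.argmax(sim, axis=0)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = x[:, labels == j]
            if members.shape[1] == 0:
                return None
            c = members.mean(axis=1)
            norm = np.linalg.norm(c)
            if norm == 0:
                return None
            centroids[:, j] = c / norm
    inertia = float(np.sum(1.0 - np.max(centroids.T @ x, axis=0)))
    return centroids, labels, inertia


def cluster_modes(
    streams: EigenStream | list[EigenStream],
    k_range=range(2, 11),
    *,
    replicates: int = 300,
    max_iter: int = 400,
    seed: int | None = None,
    compute_silhouette: bool = True,
) -> dict[int, ModeSet]:
    """Cluster pooled leading eigenvectors into recurring modes, per K.

    Cosine-distance K-means, best of ``replicates`` random restarts by
    within-cluster distance sum; a restart whose cluster empties is re-seeded
    deterministically from the master seed. Centroids are renormalized to
    unit norm, sign-normalized, and modes sorted by descending occupancy.
    """
    if isinstance(streams, EigenStream):
        streams = [streams]
    x = np.concatenate([s.vectors for s in streams], axis=1)
    norms = np.linalg.norm(x, axis=0)
    x = x / norms
    n = x.shape[1]
    root = np.random.SeedSequence(seed)
    out: dict[int, ModeSet] = {}
    for k in k_range:
        if not 1 <= k <= n:
            raise ValueError(f"K={k} infeasible for {n} pooled vectors")
        best = None
        children = root.spawn(replicates)
        for rep_seq in children:
            rng = np.random.Generator(np.random.PCG64(rep_seq))
            result = None
            for _retry in range(100):
                result = _cosine_kmeans_once(x, k, rng, max_iter)
                if result is not None:
                    break
            if result is None:
                continue
            if best is None or result[2] < best[2]:
                best = result
        if best is None:
            raise RuntimeError(f"all {replicates} K-means replicates degenerate at K={k}")
        centroids, labels, inertia = best
        centroids = np.column_stack(
            [_sign_normalize(centroids[:, j]) for j in range(k)]
        )
        # re-assign after sign normalization so labels stay consistent
        labels = np.argmax(centroids.T @ x, axis=0)
        order = np.argsort(-np.array([np.mean(labels == j) for j in range(k)]), kind="stable")
        centroids = centroids[:, order]
        remap = np.empty(k, dtype=int)
        remap[order] = np.arange(k)
        labels1 = remap[labels] + 1
        sil = None
        if compute_silhouette and k >= 2:
            if len(np.unique(labels1)) >= 2:
                from sklearn.metrics import silhouette_score

                sil = float(silhouette_score(x.T, labels1, metric="cosine"))
            else:  # clustering collapsed: worst possible separation score
                sil = -1.0
        out[k] = ModeSet(
            k=k,
            centroids=centroids,
            labels=labels1,
            silhouette=sil,
            communities=[extract_community(centroids[:, j]) for j in range(k)],
            inertia=inertia,
            seed=seed,
        )
    return out


def select_k_silhouette(modesets: dict[int, ModeSet]):
    """Pick K maximizing mean silhouette (ties -> smaller K); returns (K, table)."""
    import pandas as pd

    if len(modesets) < 2:
        raise ValueError("need at least 2 candidate K")
    rows = []
    for k in sorted(modesets):
        ms = modesets[k]
        if ms.silhouette is None:
            raise ValueError(f"silhouette missing for K={k}; re-run clustering")
        rows.append({"k": k, "silhouette": ms.silhouette})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["silhouette"].idxmax(), "k"])  # idxmax -> first max
    return best, table


def assign_modes(es: EigenStream | np.ndarray, modes: ModeSet) -> np.ndarray:
    """Assign each eigenvector to its cosine-nearest centroid (1-based labels).

    Ties break deterministically to the lowest mode index.
    """
    x = es.vectors if isinstance(es, EigenStream) else np.asarray(es, float)
    if x.shape[0] != modes.centroids.shape[0]:
        raise ValueError("region dimension mismatch between stream and centroids")
    xn = x / np.linalg.norm(x, axis=0)
    sim = modes.centroids.T @ xn
    return np.argmax(sim, axis=0) + 1


def match_modes_across_runs(
    reference: ModeSet, other: ModeSet
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal mode correspondence between two runs.

    Returns ``(perm, sims)`` where ``other`` mode ``perm[i]`` (0-based column)
    pairs with reference mode ``i`` and ``sims[i]`` is their cosine
    similarity; the assignment maximizes total similarity over all K!
    pairings. A matched similarity below 0.5 triggers a warning.
    """
    if reference.k != other.k:
        raise ValueError("mode counts differ")
    if reference.centroids.shape[0] != other.centroids.shape[0]:
        raise ValueError("region dimensions differ")
    sim = reference.centroids.T @ other.centroids
    rows, cols = linear_sum_assignment(-sim)
    perm = cols[np.argsort(rows)]
    sims = sim[np.arange(reference.k), perm]
    if np.any(sims < 0.5):
        warnings.warn(
            "matched mode similarity below 0.5; runs may not share modes "
            f"(sims={np.round(sims, 3)})"
        )
    return perm, sims


def reorder_modes(modes: ModeSet, perm: np.ndarray) -> ModeSet:
    """Reorder a ModeSet so its modes follow ``perm`` (e.g. to match run 1)."""
    perm = np.asarray(perm, dtype=int)
    remap = np.empty(modes.k, dtype=int)
    remap[perm] = np.arange(modes.k)
    return ModeSet(
        k=modes.k,
        centroids=modes.centroids[:, perm],
        labels=remap[modes.labels - 1] + 1,
        silhouette=modes.silhouette,
        communities=(
            [modes.communities[j] for j in perm]
            if len(modes.communities) == modes.k
            else list(modes.communities)
        ),
        inertia=modes.inertia,
        seed=modes.seed,
    )


def extract_community(centroid: np.ndarray) -> np.ndarray:
    """Region indices of the phase-shifted community of a sign-normalized mode.

    The community is the strictly-positive minority; a mode with no positive
    element is the global in-phase mode, whose community is all regions.
    """
    centroid = np.asarray(centroid, dtype=float)
    pos = np.flatnonzero(centroid > 0)
    if pos.size == 0:
        return np.arange(centroid.size)
    return pos


def mode_agreement_icc(
    centroid_sets: list[np.ndarray], form: str = "1,1"
) -> np.ndarray:
    """Per-mode ICC across runs, treating regions as targets and runs as raters.

    ``centroid_sets`` holds one N x K centroid matrix per run, already
    matched (same mode order). Returns one ICC per mode.
    """
    from .reliability import icc

    mats = [np.asarray(c, float) for c in centroid_sets]
    if len(mats) < 2:
        raise ValueError("need centroids from at least 2 runs")
    k = mats[0].shape[1]
    out = np.empty(k)
    for j in range(k):
        table = np.column_stack([m[:, j] for m in mats])
        out[j] = icc(table, form=form).value
    return out
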