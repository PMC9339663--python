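"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import dfckit as dk


def make_sign_patterns(n_regions: int, community_sizes, rng) -> np.ndarray:
    """Unit-norm, sign-normalized two-community sign patterns (N x K).

    ``community_sizes[k]`` regions are phase-shifted (positive); size 0
    produces the global all-negative mode.
    """
    cols = []
    for sz in community_sizes:
        s = -np.ones(n_regions)
        if sz:
            s[rng.choice(n_regions, size=sz, replace=False)] = 1.0
        cols.append(s / np.sqrt(n_regions))
    return np.column_stack(cols)


PLANTED_OCC = np.array([0.4, 0.2, 0.2, 0.1, 0.1])


@pytest.fixture(scope="session")
def planted_patterns():
    rng = np.random.default_rng(7)
    return make_sign_patterns(30, [0, 5, 8, 10, 12], rng)


@pytest.fixture(scope="session")
def planted_runs(planted_patterns):
    """Five planted-mode 'runs' (seeds 1..5) with their LEiDA recovery.

    Each entry: (generator result, recovered ModeSet with columns matched
    to the generator's effective centroids, matched cosine similarities).
    """
    runs = []
    for seed in range(1, 6):
        res = dk.generate_planted_modes(
            planted_patterns, PLANTED_OCC, dwell=3, noise_sd=0.1,
            n_timepoints=1200, seed=seed,
        )
        ps = dk.PhaseStream(
            theta=res.phases, amplitude=np.ones_like(res.phases),
            tr_seconds=res.tr,
        )
        ms = dk.cluster_modes(
            dk.eigen_stream(ps), k_range=[5], replicates=20, seed=0,
            compute_silhouette=False,
        )[5]
        sim = res.centroids.T @ ms.centroids
        rows, cols = linear_sum_assignment(-sim)
        perm = cols[np.argsort(rows)]
        runs.append((res, dk.reorder_modes(ms, perm), sim[np.arange(5), perm]))
    return runs


@pytest.fixture(scope="session")
def kuramoto_fullsync():
    cfg = dk.KuramotoConfig(
        k_intra=5.0, k_inter=5.0, noise_sd=0.0, omega_sd_hz=0.005, seed=1
    )
    return dk.simulate_modular_kuramoto(cfg)


@pytest.fixture(scope="session")
def kuramoto_modular():
    return dk.simulate_modular_kuramoto(dk.KuramotoConfig(seed=2))


def community_metrics(result):
    """SYNC/META/CHI of a Kuramoto result via the measurement pipeline."""
    ps = dk.analytic_phase(result.ts)
    css = dk.community_order_parameter(ps, result.communities)
    sm = dk.sync_and_metastability(css)
    _, chi = dk.chimera_index(css)
    return sm, chi


def coupled_markov_transition(p_a: float = 0.9, p_b: float = 0.8) -> np.ndarray:
    """2-channel chain: a' copies b (prob p_a), b' copies a (prob p_b)."""
    t = np.zeros((4, 4))
    for s in range(4):
        a, b = s & 1, (s >> 1) & 1
        for s2 in range(4):
            a2, b2 = s2 & 1, (s2 >> 1) & 1
            pa = p_a if a2 == b else 1 - p_a
            pb = p_b if b2 == a else 1 - p_b
            t[s, s2] = pa * pb
    return t
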