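"""LEiDA mode recovery from planted phase-locking patterns.

Plants 5 recurring two-community phase-locking modes with occupancies
(0.4, 0.2, 0.2, 0.1, 0.1), generates 4 independent "runs", recovers the
modes by cosine K-means on the leading-eigenvector stream, matches them
across runs, and reports centroid similarity, occupancies and the
region-as-target ICC(1,1) of mode agreement.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

import dfckit as dk

rng = np.random.default_rng(7)
n_regions = 30
patterns = []
for size in [0, 5, 8, 10, 12]:  # 0 = global all-in-phase mode
    s = -np.ones(n_regions)
    if size:
        s[rng.choice(n_regions, size, replace=False)] = 1.0
    patterns.append(s / np.sqrt(n_regions))
patterns = np.column_stack(patterns)
occupancies = np.array([0.4, 0.2, 0.2, 0.1, 0.1])

matched = []
for run_seed in range(1, 5):
    res = dk.generate_planted_modes(
        patterns, occupancies, dwell=3, noise_sd=0.1, n_timepoints=1200,
        seed=run_seed,
    )
    ps = dk.PhaseStream(theta=res.phases, amplitude=np.ones_like(res.phases),
                        tr_seconds=res.tr)
    ms = dk.cluster_modes(dk.eigen_stream(ps), k_range=[5], replicates=20,
                          seed=0, compute_silhouette=False)[5]
    sim = res.centroids.T @ ms.centroids
    rows, cols = linear_sum_assignment(-sim)
    perm = cols[np.argsort(rows)]
    ms = dk.reorder_modes(ms, perm)
    matched.append(ms)
    print(f"run {run_seed}: centroid cosine similarity "
          f"{np.round(sim[np.arange(5), perm], 4)}")
    print(f"        recovered occupancies {np.round(ms.occupancies, 3)}")

iccs = dk.mode_agreement_icc([m.centroids for m in matched], form="1,1")
print(f"\nplanted occupancies          {occupancies}")
print(f"cross-run mode ICC(1,1):     {np.round(iccs, 4)}")
print("\nSimilarities near 1 and ICC near 1 mean each run independently")
print("recovers the same spatial modes, mirroring test-retest mode stability.")
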