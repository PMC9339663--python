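"""Test-retest statistics over a simulated 4-run metric table.

Simulates a cohort of 40 subjects whose metastability has a stable
subject-specific component plus run noise, then runs the reliability
battery: ICC(3,1), the permutation paired t-test between runs, the
Greenhouse-Geisser-corrected repeated-measures ANOVA, and the Spearman
matrix across metrics.
"""

import numpy as np
import pandas as pd

import dfckit as dk

rng = np.random.default_rng(0)
n_subjects, n_runs = 40, 4
trait = rng.normal(0.10, 0.02, size=(n_subjects, 1))  # subject-level META
meta = trait + rng.normal(0, 0.005, size=(n_subjects, n_runs))

icc = dk.icc(meta, form="3,1")
print(f"ICC(3,1) for META across runs: {icc.value:.3f}")

perm = dk.perm_paired_ttest(meta[:, 0], meta[:, 1], n_perm=1000, seed=1)
print(f"run 1 vs run 2 permutation paired t-test: t = {perm.t_observed:.2f}, "
      f"p = {perm.p_value:.3f}")

aov = dk.rm_anova_gg(meta)
print(f"rmANOVA (GG): F = {aov.f_value:.2f}, eps = {aov.epsilon:.2f}, "
      f"p = {aov.p_value:.3f}")

# cross-metric relationships in one run: SYNC correlates with META here,
# SPEED is constructed independent
metrics = pd.DataFrame({
    "META": meta[:, 0],
    "SYNC": 0.5 + 2.0 * meta[:, 0] + rng.normal(0, 0.01, n_subjects),
    "SPEED": rng.normal(0.4, 0.05, n_subjects),
})
rho, p, sig = dk.spearman_matrix(metrics)
print("\nSpearman correlations (X = significant at alpha 0.05):")
for a in metrics.columns:
    line = "  ".join(
        f"{rho.loc[a, b]:+.2f}{'X' if sig.loc[a, b] else ' '}"
        for b in metrics.columns
    )
    print(f"{a:>6}: {line}")
print("\nHigh ICC with a non-significant run effect is the signature of a")
print("metric that is stable within subjects yet varies between them.")
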