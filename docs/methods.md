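# Methods

This note records the models, estimators, defaults and numerical choices
behind `dfckit`, and what the synthetic fixtures do and do not establish
about real fMRI data.

## Signal preparation

Parcellated BOLD tables (regions × timepoints, TR in seconds) are the
canonical input; `parcellate_volume` produces them from a 4-D NIFTI and an
integer-label atlas by arithmetic voxel means per label, ordered by
ascending label. Bandpass filtering is a brick-wall DFT filter: demean,
FFT, zero every bin whose center frequency falls outside the closed
interval [f_lo, f_hi], inverse FFT. Closed-interval bin retention makes
non-aligned band edges deterministic; demeaning precedes filtering even
when f_lo > 0 so the mean cannot leak. The filter is exactly idempotent.

Instantaneous phase and amplitude come from the Hilbert analytic signal.
One timepoint per end is trimmed by default (`edge_trim=1`) to drop the
transform's edge transients; the choice is configurable and all regions
are trimmed identically so streams stay aligned.

The Carson-rule diagnostic estimates, per region, a carrier (amplitude-
weighted mean instantaneous frequency) and a bandwidth
B = 2 (Δf_peak + W_env), where Δf_peak is the 95th percentile of
|f_inst − carrier| over samples with above-median amplitude (robust to
phase slips at amplitude nulls) and W_env is the frequency containing 95 %
of the demeaned envelope's power. An envelope with relative ripple
(SD/mean) below 5 % counts as unmodulated (W_env = 0): the spectral
quantile of a near-flat envelope measures numerical residue, not
modulation. A region passes when carrier ± B/2 lies inside the filter
band, which is the practical Bedrosian condition that the envelope
spectrum sits below the phase spectrum. The check is diagnostic only and
never blocks the pipeline.

## LEiDA

Each phase-locking slice cos(θ_n − θ_p) is symmetric with unit diagonal by
construction. Its leading eigenvector (largest-|λ|) is sign-normalized so
that strictly more than half of the elements are negative; an exact
positive/negative tie is broken by forcing the largest-magnitude element
negative. The convention is total: no vector leaves normalization with an
ambiguous sign state.

Clustering uses K-means under cosine distance for both fitting and
assignment — the assignment metric is cosine, and using the same metric in
training keeps the two consistent. Defaults mirror standard practice: 300
random restarts, up to 400 iterations, K swept over 2–10, best restart by
within-cluster cosine-distance sum. A restart whose cluster empties is
re-seeded from the master seed's spawn sequence, so the whole procedure is
bit-deterministic given one seed. Centroids are renormalized to unit norm,
sign-normalized, re-assigned, and sorted by descending occupancy. K is
selected by mean silhouette under cosine distance; exact ties go to the
smaller K (parsimony). Runs are clustered separately by default and
matched afterwards by maximizing total centroid cosine similarity over
all pairings (Hungarian assignment); a matched similarity below 0.5 warns
of possible non-correspondence.

A mode's community is the set of strictly-positive (phase-shifted)
elements; an all-negative centroid is the global in-phase mode whose
community is all regions. Communities therefore overlap by design and no
exclusivity is enforced anywhere downstream.

## Mode and stream metrics

Occupancy and dwell duration are counting statistics on the label stream;
runs touching the series boundaries count, and a mode that never occurs
reports NaN (never 0, which would bias cohort means). Reconfiguration
speed correlates the strict upper triangles of consecutive phase-locking
matrices; the typical speed is the median (the stream's "knots and leaps"
make the mean heavy-tail sensitive; the mean is also available). A speed
step is attributed to the mode of its earlier timepoint — a step belongs
to the state it departs from.

DFA: demean, integrate, split into non-overlapping windows, remove a
linear trend per window, F(n) = RMS residual; α is the least-squares slope
of log F on log n over ~20 log-spaced integer scales from 10 to T/4.
These scale choices are the package's defaults and are configurable. The
linearity gate fits polynomials of order 1–3 to the log-log plot and
scores them with BIC = m ln(RSS/m) + p ln m; scaling is "genuine" iff
order 1 wins, and only genuine series should enter cohort summaries of α.
By default DFA is applied to the reconfiguration-speed series of each
run. Calibration on known processes (white noise α ≈ 0.5, fGn α ≈ H,
integrated noise α ≈ 1.5) is part of the test suite.

## Community synchrony and information metrics

Metastability uses the sample SD (ddof 1) over time; the chimera index
uses the population variance across the fixed, small set of K communities.
Both conventions are pinned and tested. The phase-coherence coefficient
requires an explicit occurrence criterion, which the package defines as:
at least two communities internally synchronized (|Z| > λ) whose mean
phases themselves yield a cross-community order parameter above the same
λ. One threshold plays both roles (λ = 0.8 default, λ = 0.7 supported for
sensitivity analysis; PCC is monotone non-increasing in λ).

Coalition states are the K-bit patterns of supra-threshold communities
(strict inequality, so |Z| ≡ λ binarizes to 0). Entropy and all ΦR terms
use discrete plug-in distributions; a Miller–Madow correction is available
as a diagnostic switch but is off by default. ΦR at a bipartition
{M1, M2} is whole-minus-sum mutual information at lag τ plus the
minimum-mutual-information double redundancy
min_{j,k} I(Mj_t ; Mk_{t+τ}), which restores non-negativity. The
minimum-information bipartition minimizes ΦWMS normalized by
min(H(M1), H(M2)); zero-entropy parts are skipped, with unnormalized
selection as fallback (and as a config option, since conventions differ
across the practical Φ literature). The τ sweep defaults to 1..500 TR,
truncated automatically to the series length; the argmax τ is reported but
is a maximum statistic and should not be given inferential weight. A
constant coalition series has no dynamics; ΦR is defined as 0 with a
warning.

## Reliability statistics

ICC(1,1) (one-way random, agreement) and ICC(3,1) (two-way mixed,
consistency) are computed from ANOVA mean squares, with the mean squares
returned for audit; a zero-variance table is undefined (homogeneous-sample
caveat) and returns NaN. Mode-extraction reliability treats regions as
targets and runs as raters, per mode, after matching. The permutation
paired t-test flips the signs of paired differences and uses the add-one
estimator p = (1 + #{|t*| ≥ |t|}) / (n_perm + 1), which is valid at any
permutation count; its type-I error calibration is regression-tested. The
repeated-measures ANOVA computes Greenhouse–Geisser ε from the
double-centered condition covariance and scales both degrees of freedom;
ε ∈ [1/(k−1), 1] always, and ε = 1 exactly for two conditions. Spearman
matrices use mid-rank ties with the t-approximation p-value. A
mixed-effects fit relating ΦR to the other metrics is out of scope here;
`standardize_metric_table` exports the z-scored tidy table such a fit
consumes.

## Synthetic fixtures: what they emulate

**Modular Kuramoto.** Euler–Maruyama integration of
dθ_i = ω_i dt + (1/N) Σ_j K_ij sin(θ_j − θ_i) dt + σ dW, with block
coupling (k_intra within, k_inter between communities) and Gaussian
natural frequencies inside the resting-state band (0.04 ± 0.02 Hz). The
1/N factor is the standard mean-field normalization; coupling constants
are interpreted accordingly. The observable is cos θ plus optional noise,
bandpassed with the default filter so the measurement path matches real
data, sampled at TR 0.72 s for 1200 frames after a 72 s burn-in. The
default regime (k_intra = 1.2, k_inter = 0.02, σ = 0.15) places
within-community coupling near the locking threshold for the frequency
spread, which is what produces slow, in-band |Z| fluctuations — SYNC ≈
0.6, META ≈ 0.1, CHI ≈ 0.03 — rather than the near-total synchrony that
stronger coupling yields. Setting k_intra = k_inter large with σ = 0
gives the full-synchronization limit; zero coupling gives incoherence at
the finite-size 1/√N floor.

**Planted modes.** Recurring modes are two-community sign patterns; the
active pattern sets a π phase opposition between its communities, plus an
in-band carrier rotation and von-Mises phase jitter. Each pattern also
carries a fixed per-region phase-offset profile (±0.35 rad, seeded
independently of the run seed so all "runs" share it). The offsets give
the induced leading eigenvectors region-level heterogeneity — without
them every centroid element would be ±1/√N and a region-as-target ICC
would be degenerate — and the generator returns those induced
eigenvectors as the effective ground truth. The label stream re-draws
from the target occupancy distribution at rate 1/dwell, making the
targets the stationary occupancies.

**fGn.** Exact fractional Gaussian noise by circulant embedding of the
fGn autocovariance (one FFT; power-of-two lengths), with eigenvalue
clipping plus a warning in the numerically non-PSD case.

**Binary Markov coalitions.** A row-stochastic transition over the 2^K
joint states, with the stationary distribution and every lag-τ joint
available in closed form (diag(π) P^τ), so entropy and ΦR estimators are
checked against exact values and brute-force summation oracles.

What passing these fixtures does **not** show: the generators contain no
hemodynamic forward model (cos θ stands in for BOLD deliberately, since
the pipeline consumes phases and a hemodynamic model would add
unvalidated confounds), no measurement artifacts (motion, physiological
noise, scanner drift), and no spatial autocorrelation structure of real
parcellations. Results on real data additionally depend on upstream
preprocessing quality, which is out of scope here.

## Problem sizes and determinism

Test and example runs use reduced sizes chosen to exercise every code
path at full fidelity: 20–90 regions, 400–1200 timepoints, 10–30
clustering restarts, τ sweeps to ~100, and 8–20 Monte-Carlo replicates
per calibration — sizes at which the Monte-Carlo tolerances quoted in the
tests hold comfortably. Every stochastic component takes an explicit seed
and is bit-deterministic given it; K-means replicates and Kuramoto/Markov
sampling all derive their streams from a single `SeedSequence` root.

## Known limitations

- The BIC-over-polynomial-orders linearity gate is a deliberately compact
  stand-in for fuller Bayesian model comparison of scaling laws; it ranks
  the same candidate models by the same residuals but does not integrate
  over parameter uncertainty.
- Plug-in ΦR is biased upward at short series length (order
  (2^K − 1)² / (2 N ln 2) bits for the whole-system MI term); the
  Miller–Madow switch mitigates but does not remove this. K > 8 channels
  are refused because bipartition scanning is exhaustive.
- The voxel-space mode rendering, t-SNE stream embedding and
  mixed-effects modeling that often accompany these analyses are
  visualization/inference layers outside this package's scope.
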