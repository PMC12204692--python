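# Methods

`statefda` analyses time series whose observations are curves on a
shared grid — the motivating case is one EEG power spectral density
(PSD) per second of resting-state recording — by (1) reducing each raw
spectrum to its oscillatory peak content, (2) fitting a functional
hidden Markov model (FHMM) across individuals, (3) summarising each
individual's decoded latent-state dynamics, and (4) decomposing the
within-state variation by functional PCA. This note records the model,
the numerical choices, and what the synthetic tests do and do not show.

## Functional hidden Markov model

Each individual `p` contributes a sequence `x_{p1}, …, x_{pK}` of
curves. A single model is shared across individuals: a Markov chain on
states `1..N` with initial distribution `ν` and transition matrix
`A = {a_ij}`, where state `i` carries a centroid curve `μ_i`. Emissions
are *distance-based pseudo-likelihoods*, not probability densities:

    b_i(x) = 1 / (d(x, μ_i)^2 + ε),

with `d` the L2 distance between curves, computed by trapezoidal
quadrature on the grid. The similarity transform `1/y²` is undefined at
`y = 0`, so a regulariser `ε` (default `1e-12 ×` grid range,
configurable) caps the emission when a curve coincides with a centroid.
Because emissions are unnormalised, every "likelihood" in this package
is a pseudo-likelihood; the scaled forward–backward recursions,
Baum–Welch EM and Viterbi decoding are otherwise the standard HMM
constructions, with per-step normalisation and the log pseudo-likelihood
equal to the sum of log scaling factors.

**Multiple sequences.** The E-step runs per individual (sequences of
equal length are batched internally); the M-step pools: `ν` is the
average of first-step posteriors `γ_1` across individuals, each row of
`A` is the pooled `Σξ / Σγ`, and centroids are responsibility-weighted
pointwise means of all observed curves.

**Centroid update.** The exact maximiser of the EM surrogate for this
emission model minimises `Σ γ log(d² + ε)`, which has no closed form.
The default update is one majorise-minimise step for that objective — a
pointwise mean weighted by `γ / (d² + ε)`, i.e. responsibilities
sharpened by closeness to the current centroid. This guarantees the EM
objective never decreases, which the plain `γ`-weighted mean (the
k-means-style minimiser of `Σ γ d²`, available as
`centroid_update="mean"`) does not: with near-zero distances the log
term is steep and a plain mean step can lower the objective. Both
updates leave noiseless fixed points untouched and agree closely in
well-separated regimes.

**Convergence and degeneracy.** EM stops when the relative objective
change falls below `tol` (default `1e-6`) or after `max_iter` (default
200) iterations; the full objective history is recorded. A state whose
total responsibility falls below `1e-8` is flagged degenerate and its
centroid frozen, with a warning.

**Decoding.** Viterbi runs in log space; ties break toward the lowest
state index so output is deterministic. Zero entries of `ν` or `A` are
honoured as `-inf` log weights.

**Segments.** By default each individual's sequence is one chain, even
if the recording has gaps (eyes-open blocks between eyes-closed
segments). With `break_at_segments` the chain instead restarts with `ν`
at every segment boundary, and occupancy statistics exclude
boundary-straddling pairs from transition counts. The single-chain
default was chosen because latent brain states plausibly persist across
a 20 s gap; the option exists because neither convention is clearly
right.

## Initialisation by subsampling consensus

Functional k-means with random restarts tends to collapse several
cluster centroids onto one mode in high dimension, which seeds the FHMM
with redundant states. The consensus strategy therefore fits 10 models,
each on a random 80% subsample of individuals (without replacement
within a draw), each with a deliberately generous 8 states, initialised
by functional k-means on the subsample's curves. The 80 pooled
centroids are grouped — by average-linkage agglomerative clustering on
pairwise L2 distances, cut at `N` groups or at a distance threshold, or
manually from inspection of the pooled-centroid plot — and each group's
pointwise mean becomes one initial centroid of the final `N`-state fit.
Initial `ν` is uniform and `A` is sticky (0.9 on the diagonal).
k-means itself is Lloyd's algorithm under the quadrature-weighted L2
distance (implemented by scaling grid columns by the root quadrature
weight and delegating to scikit-learn's seeded KMeans), best of 10
restarts by within-cluster sum of squared distances.

After fitting, states are relabelled by decreasing allocation count
over the decoded paths (ties toward the lower original index), and
`ν`, `A`, centroids and paths are permuted consistently.

## Occupancy statistics

From each decoded path: number of distinct states visited, number of
transitions (adjacent unequal pairs), fraction of time per state, and
the dominant state (ties toward the lowest label, flagged). Individuals
with dominant-state share at or above the threshold (default 0.8,
inclusive) form that state's group; the rest are "mixed". Counts of
visited-state combinations partition the cohort and are reported for
every nonempty subset when `N ≤ 4`.

## Functional PCA

Within each state's curve subset, curves are represented by penalised
B-spline smooths (cubic basis, breakpoints at every other grid point by
default, exact second-derivative penalty matrix, default penalty
`1e-4`); the coefficient mean gives the mean function and the
covariance of the smoothed curves the eigenproblem.

All L2 inner products in the eigenproblem and scores use one fixed
quadrature rule on the observation grid: weight = grid spacing on
uniform grids (trapezoid weights otherwise). This turns the functional
eigenproblem into a weighted matrix PCA with two useful consequences:
eigenfunctions are exactly orthonormal under the package's own inner
product, and in the degenerate configuration (zero penalty, saturated
basis, uniform grid) scores coincide exactly with classical PCA scores
of the discretised curves times `sqrt(Δ)` — the oracle the test suite
checks at `1e-6`.

Scores are projections of the *raw* centered curves onto the
eigenfunctions; smoothing enters only through the mean and covariance
estimates. Stored training scores are therefore bit-identical to
re-projection, and a probe curve `mean + 2·φ₁` scores exactly `(2, 0,
…)` regardless of the penalty. Eigenvalues are clipped at zero and
sorted; each eigenfunction is flipped so its largest-magnitude value is
positive, making output deterministic. Component retention keeps the
smallest `C` whose cumulative variance share strictly exceeds 70%
(default), with scree data emitted for inspection. Per-individual
scores are arithmetic means of that individual's observation-level
scores within the state; means were chosen over medians as the
conventional aggregate for approximately symmetric score
distributions.

## Spectral parameterisation

The parameteriser decomposes a log10-power spectrum over a fit range
(default 1.5–30 Hz) into `offset − exponent·log10 f` plus Gaussian
peaks, with the conventional settings: peak full-width limits 1–12 Hz
(interpreted as bounds on `2·sd`, so `sd ∈ [0.5, 6]` Hz), no cap on
peak count, minimum peak height 0.05, relative threshold 2 residual
standard deviations, fixed aperiodic mode (no knee).

The aperiodic fit is made robust by dropping the upper 2.5% residual
tail and refitting, since peaks only bias the background upward. Peaks
are extracted iteratively from the flattened spectrum (tallest point,
sd guessed from the half-height span, subtract, repeat until below
`max(0.05, 2·sd_resid)`), then jointly refined by bounded least
squares, then the aperiodic component is refit on the peak-subtracted
spectrum. This extract–refine–refit cycle runs twice (configurable):
the first background fit cannot see the peaks and leaves a bias of the
order of the minimum peak height, and the second pass against the
corrected background removes it — making extraction idempotent
(refitting the peak-subtracted spectrum finds nothing). Goodness of fit
is `r² = 1 − SSE/SST` in log10-power space. If the nonlinear refinement
fails, the unrefined guesses are kept with a warning. Peaks that end
below the height floor after refinement are dropped, so every reported
peak satisfies the declared constraints by construction.

This is a self-contained implementation of the "peaks over 1/f" idea,
not a clone of any particular tool; its acceptance surface is parameter
recovery on simulated spectra, not cross-tool numerical equality. The
peak curves it feeds to the FHMM stay in log10-power units (a rescaling
hook exists on the fit object via its peak list).

## Synthetic data

The generator emulates the study design the pipeline targets:
multi-individual sequences of peak-parameterised PSD curves emitted
from a small set of latent-state centroids under Markov switching. The
default grid is 1.5–30 Hz at 0.5 Hz (58 points). The default 4-state
centroid preset mimics the qualitative state profiles of resting-state
EEG: delta-dominant with elevated beta-2; theta with a 9 Hz alpha peak;
11 Hz alpha with beta-1; strong 10 Hz alpha.

Emission noise is a *random function*, not pointwise jitter: i.i.d.
Gaussian coefficients on ~10 evenly spaced cubic B-spline basis
functions, interpolated to the grid and rescaled so the pointwise
marginal sd equals `noise_sd` exactly. No generative noise model is
implied by the emission pseudo-likelihood itself (it is a similarity,
not a density), so this choice is a stand-in: it produces smooth,
spectrally plausible perturbations, but real PSD-to-PSD variation also
includes peak-frequency drift and amplitude scaling that it does not
model. Passing recovery tests therefore demonstrates correctness of
the algorithms under smooth additive noise, not robustness to every
real-data failure mode. Raw-spectrum simulation is the closed form
aperiodic-plus-Gaussians model with i.i.d. Gaussian noise.

One seed sequence per call is split per individual, so any individual's
data is reproducible regardless of cohort size or ordering; all
stochastic steps (simulation, k-means, subsampling) take explicit
integer seeds recorded in the pipeline manifest.

## Problem sizes and determinism

The test suite and the acceptance script use simulation sizes chosen to
make Monte-Carlo bands tight while keeping runs interactive: transition
frequency checks at 200 individuals × 100 steps (±0.02), full
subsample-initialised recovery at 50 individuals × 100 steps over 10
seeds (well-separated regime: minimum inter-centroid L2 ≥ 10× the
pointwise noise sd), FPCA variance-share recovery at 500 curves
(±0.03), and spectral batches of 30–50 spectra at noise sd 0.02. The
whole pipeline is a pure function of (inputs, config, seed); reruns
reproduce identical artifact hashes.

## Known limitations

- Emissions are pseudo-likelihoods, so objective values are comparable
  only within a run — information criteria across different `N` are not
  meaningful, which is also why initialisation relies on the
  subsampling consensus rather than model selection.
- No hidden semi-Markov or autoregressive dynamics; dwell times are
  implicitly geometric.
- The spectral parameteriser has no aperiodic "knee" mode and does not
  fit outside the declared range.
- FPCA assumes a shared grid; curves observed on irregular per-subject
  grids would need resampling first.
- The grouping step of the consensus initialisation is a heuristic; the
  agglomerative cut reproduces clear-cut pools, but ambiguous pools
  still warrant the manual mode with visual inspection.
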