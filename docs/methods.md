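# Methods

## Data model and preprocessing

A recording unit (trial) is a `T × M × 3` array of marker positions at a
fixed frame rate; the default marker set has 21 upper-body markers with the
pelvis as the declared origin. Trials are validated at load time: missing
marker labels and NaN frames are hard errors (no gap-filling is performed —
interpolation would silently manufacture kinematics), and CSV input without
a frame rate is rejected unless a side-car file or explicit rate supplies
one.

Coordinates are expressed per frame relative to the origin marker, which
removes whole-body translation exactly and is idempotent. The analysis
window is a half-open frame interval `[start, start + round(duration·fps))`
taken from the start of each trial (default 5 s, i.e. 1250 frames at
250 fps). Flattened frames are stacked into a posture matrix with exact
per-trial segment bookkeeping.

**Column count.** With 21 markers the posture vector has 63 coordinates,
but after pelvis referencing the origin marker's three columns are
identically zero, and any marker rigid with the pelvis is constant within a
signer. The pipeline therefore removes columns that are constant within
*every* signer's block (config flag `drop_static_columns`, default on),
retaining the per-signer constants for display reconstruction. On the
default synthetic cohort this leaves 57 informative columns (19 moving
markers × 3). Published descriptions of comparable corpora state 21
markers alongside 57-column matrices without identifying which columns
were removed; this package makes the removal rule explicit rather than
guessing a specific marker list, and keeps the full 63-column layout when
the flag is off.

Units are millimetres at load. The choice is irrelevant to the
decomposition (normalization divides it out) but fixes the scale of
resynthesized movements.

## Normalization

Per signer, over the signer's full concatenated block (not per trial):
centering by the mean posture, then division by the mean per-frame
Euclidean norm `d̄` of the centered vectors. `d̄` is the mean of row norms
— not an RMS, not the norm of the mean. Consequences used as invariants:
each block has zero column means and unit mean row norm; the mapping is
exactly invertible per signer; a uniformly scaled, rigidly shifted copy of
a signer normalizes to the identical block, which is the point — the
pooled variance is not dominated by body size or habitual pose. Constant
(degenerate) blocks are rejected rather than passed through with `d̄ = 0`.

## Decomposition

PCA is computed by SVD of the pooled normalized matrix **without
re-centering**: blocks are centered per signer, and subtracting a second,
cross-signer mean would change what the decomposition measures. An input
check requires column means below 1e-8 (relative to the mean row norm).
Eigenvalues use the `1/T` convention, so the variance (ddof = 0) of each
weight column equals its eigenvalue exactly and the eigenvalue sum equals
the mean squared row norm. SVD signs are arbitrary; each component is
flipped so its largest-magnitude loading is positive, making outputs
reproducible across runs and platforms. Component retention defaults to
the smallest K whose cumulative explained variance reaches 0.946
(`ev_target`), overridable by a fixed `n_pms`; the leave-one-out analysis
is available for users who prefer a robustness criterion.

Weight signals are filtered with a zero-phase (forward-backward) 4th-order
Butterworth low-pass at 6 Hz. Only the filter family, order and cut-off
are scientifically prescribed; zero-phase application is the biomechanics
norm for kinematic signals because it cancels phase delay. The effective
amplitude response is `|H(f)|²`; in closed form for the discrete
(bilinear, prewarped) filter,
`|H(f)|² = 1 / (1 + (tan(πf/fs)/tan(πfc/fs))^(2n))`,
which is what the tests check empirical tone gains against (the analog
formula `1/(1+(f/fc)^(2n))` deviates by ~14% at 20 Hz for fs = 250 Hz, so
the discrete form is the correct oracle for a digital filter). Weights are
filtered before any similarity or extreme-frame analysis.

Welch periodograms use 4 s Hann segments with 50% overlap by default
(configurable; no canonical values are prescribed), density normalization,
so the PSD integrates to the signal variance up to window bias (~5%).

Resynthesis maps component `i` back to original coordinates for one signer
using that signer's `p̄` and `d̄`. Flipping a component and its weights
together leaves the resynthesized movement unchanged. Extreme-weighting
frames (for stick-figure/point-light key postures) are the global argmin
and argmax of the filtered weight signal, earliest index on ties.

## Comparison procedures

*Leave-one-out*: because normalization is per signer, removing a signer's
rows leaves the other blocks unchanged, so the reduced fit simply drops
those rows. Angles are computed same-rank (`PC_i` vs `PC_i`), on unsigned
axes (`arccos |v·v′|`), threshold 15°. Sign handling matters: PC signs are
arbitrary, so the absolute-value convention is the default for both angles
and cosines, with signed values available for auditing.

*Cosine similarity*: PM matrices are built from normalized data only
(`outer(w_i, PC_i)`, no `p̄`, no `d̄`), flattened, and compared by Eq-style
normalized inner product. For two PMs sharing one weight signal this
factorizes exactly to `PC_i · PC_j`, which the tests exploit as an oracle.
In the individual-versus-common report, both weight sets come from
projecting the *same* signer's normalized block on each basis, then
filtering with the same 6 Hz filter. Rows with no single similarity above
0.7 but at least two above 0.4 are flagged as combinations of common PMs.

*Cross-projection*: `V` is the sum over the first N components of the
variance of the projection coefficients of a signer's normalized rows —
the only reading under which `V2 ≤ V1` for every N (PCA optimality of the
own basis), so each directed ratio is ≤ 1 and the symmetric value is their
mean. Whether `V` is further divided by total variance is immaterial: the
ratio cancels it.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
sign content: per signer, `n_trials` fixed-duration trials at a common
frame rate; a shared orthonormal `K × 57` synergy basis (QR of a seeded
Gaussian matrix, sign-fixed for uniqueness); band-limited Gaussian weight
signals (white noise low-passed at 3 Hz, independent per trial) whose
*empirical* covariance is made exactly `diag(planted variances)` by
Cholesky decorrelation — planted variances are true sample moments, so
noise-free eigenvalue recovery is exact rather than asymptotic; geometric
variance decay (ratio 0.65) over K = 8 synergies; per-signer mean-posture
offsets (SD 20 mm) on a fixed anatomical template, uniform body scale
(0.85–1.15), and optional within-subspace rotation / component permutation
/ per-synergy activation profiles to model signers using shared synergies
differently; white Gaussian coordinate noise at a configured SNR (default
20 dB, defined as total planted signal variance over total noise variance
across the informative coordinates); and a slow (< 0.5 Hz) whole-body
drift added to every marker, which pelvis referencing must remove exactly.

Defaults reproduce the study geometry: 6 signers × 24 trials × 5 s at
250 fps → 30,000 rows/signer, 180,000 pooled rows, 57 informative columns.
The base variance (1600 mm²) puts per-coordinate movement SD near 9 mm —
plausible for upper-body signing — though its absolute value cancels in
the normalized analysis.

Noise is white in *coordinates*, not in weights, so the 6 Hz filter
genuinely denoises the weight signals. Because weights are band-limited at
3 Hz with filter roll-off, residual power remains between 3 and 6 Hz, and
the coordinate noise contributes broadband weight power above that.

What the generator does **not** model: articulated-skeleton constraints
(frames are unconstrained marker clouds; bone lengths are not preserved
under synergy motion), marker occlusion and gap structure, soft-tissue
artifact, or linguistically meaningful movement. Passing recovery tests
therefore show the estimator chain is correct under the stated statistical
assumptions, not that real signing is 8-dimensional.

## Validation-scenario design

The leave-one-out rotation scenario deserves explanation because its
outcome is constrained by covariance algebra. If a signer contributes a
fraction λ of the pooled variance in the rotated plane, the pooled
components rotate by `φ` with `tan 2φ = λ sin 2θ / (1 − λ + λ cos 2θ)`;
for an equal two-signer split (λ = ½) a planted θ = 25° moves the pooled
components only 12.5° — below the 15° threshold. A detectable scenario
therefore requires the rotated signer to dominate that plane. The bundled
scenario (`rotated_pair_scenario`) uses two signers, 5,000 frames each at
50 fps (100 s of 3 Hz-band weights, enough effective samples for stable
eigenvectors), a variance profile that isolates components 5–6 from their
neighbours, and a 4× activation of those synergies by the rotated signer
(λ = 0.8, expected φ ≈ 20°). Signers activating shared synergies with
different strengths is itself part of the phenomenon being modelled.

Similarly, the planted-permutation demonstration uses four signers with
one permuted: with only two signers, the pooled variance attached to the
swapped pair is equal by symmetry and the pooled pair is degenerate.

## Numerical conventions and edge cases

- Tolerances: orthonormality and inverse-mapping checks at 1e-10;
  reconstruction at 1e-8 relative Frobenius; eigenvalue/weight-variance
  identity at 1e-8 relative.
- Ties in extreme-frame selection break to the earliest frame.
- `fit_pca` requires at least as many rows as columns and refuses
  uncentered input rather than silently centering.
- Cosine similarity of an all-zero PM, degenerate signer blocks, empty
  blocks, cut-offs at or above Nyquist, and Welch segments longer than the
  signal are all errors, not warnings.
- HDF5 datasets are written with `track_times=False` so that rerunning the
  pipeline with the same config and seed produces byte-identical files;
  the manifest records SHA-256 checksums.

## Problem sizes

The test suite exercises the full study geometry (180,000 × 57) in the
acceptance tests and scaled cohorts (thousands of frames) elsewhere;
statistical checks state their own sampling tolerances (Marchenko–Pastur
edges for isotropic eigenvalue spread, window bias for Welch flatness).
The acceptance script runs the default geometry end to end.

## Known limitations

- C3D files are not read; convert to TRC or CSV.
- The leave-one-out refit is a full SVD per signer; for much larger
  cohorts an incremental downdate would be preferable.
- The variance-based retention rule and the robustness criterion can
  disagree; both are reported, neither is privileged.
- Real-corpus headline percentages depend on the actual recordings and are
  not reproducible from synthetic data; the package validates the
  machinery, the geometry, and the planted-structure recovery instead.
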