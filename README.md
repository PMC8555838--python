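# signsynergy

Principal-movement analysis of continuous upper-body motion capture, built
for the study of movement synergies in sign language but applicable to any
multi-marker posture time series.

## The problem and the model

Continuous signing engages dozens of kinematic degrees of freedom at once.
A long-standing idea in motor control is that such movement is organized
through a small number of *synergies*: coordinated patterns of many joints
controlled as single units. This package operationalizes that idea with
principal component analysis of posture vectors.

Each frame of a recording is flattened into a posture vector
`p(t) = [x1, y1, z1, …, xM, yM, zM]` of the 3-D coordinates of M markers,
expressed relative to the pelvis. Before pooling signers, each signer's
block is normalized in two steps:

1. centering: `p_cent(t) = p(t) − p̄`, where `p̄` is that signer's mean
   posture over all their trials;
2. scaling: `p_norm(t) = p_cent(t) / d̄`, where `d̄ = mean_t ‖p_cent(t)‖₂`,
   so every signer contributes comparably to the pooled variance
   regardless of body size.

PCA (by SVD, without re-centering the pooled matrix) yields orthonormal
principal components `PC_i` — *eigenpostures* — with eigenvalues `λ_i` and
weight time series `w_i(t) = p_norm(t) · PC_i`. The weights are low-pass
filtered (zero-phase 4th-order Butterworth, 6 Hz cut-off) because
volitional movement power concentrates in the low frequencies; Welch
periodograms of the weights document this. A *principal movement* is one
component resynthesized as a trajectory in original millimetre coordinates:

```
PM_i(t) = p̄_signer + d̄_signer · w_i(t) · PC_i
```

Three comparison procedures assess how shared the synergies are:

- **Leave-one-out robustness** — refit the PCA with one signer removed and
  measure the angle each `PC_i` rotates; ≤ 15° counts as robust.
- **Cosine similarity of PMs** — `sim(PM_i, PM_j) = Σ_k PM_i,k PM_j,k /
  (√Σ PM_i,k² √Σ PM_j,k²)` on the flattened weight-times-component
  matrices built from normalized data; thresholds 0.7 (high) and 0.5
  (moderate).
- **Cross-projection similarity** — the variance of one signer's movements
  captured by another signer's leading N components, relative to their own
  (`V2/V1`), averaged over both directions; 1 means interchangeable
  subspaces.

Because the analysis needs ground truth to be validated, the package ships
a first-class synthetic cohort generator: multi-signer mocap with a planted
orthonormal synergy basis, band-limited weight dynamics, per-signer
anthropometry (mean posture, uniform scale), per-signer synergy use
(rotations, permutations, activation profiles), and white measurement
noise at a configurable SNR.

## Worked example

`examples/01_decompose_cohort.py` simulates three signers sharing eight
synergies (SNR 20 dB), normalizes, and fits the pooled PCA:

```
normalized posture matrix: 22500 x 57
 pm  ev_pct  cumulative_ev_pct
  1   35.82              35.82
  2   23.29              59.10
  3   15.13              74.23
  4    9.84              84.08
  5    6.41              90.49
  6    4.17              94.66
  7    2.72              97.38
  8    1.77              99.15
  9    0.02              99.17
 10    0.02              99.19

6 components reach 94.6% cumulative variance
max principal angle to the planted 8-synergy basis: 0.28 deg
```

The eight planted synergies absorb 99.15% of the variance (the remainder is
the planted measurement noise), and the recovered leading subspace is
within a fraction of a degree of the construction. The other examples walk
through signer comparison (`02`), leave-one-out robustness including a
planted 25° rotation (`03`), weight spectra and filtering (`04`), and
point-light export of a resynthesized PM (`05`).

The same analysis runs from the shell:

```
signsynergy run --simulate --seed 1 -o results/
signsynergy ingest --format trc -o cohort.h5 trials/*.trc   # real recordings
```

`run` writes an HDF5 bundle (posture matrices, normalization parameters,
decompositions, spectra), CSV reports (explained variance, similarity
matrices, leave-one-out angles, cross-projection curve), point-light JSON
animations, and a checksum manifest; reruns with the same seed are
byte-identical.

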