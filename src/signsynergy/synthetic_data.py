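"""Synthetic multi-signer mocap cohorts with planted synergy structure.

The generator emulates the geometry and statistics of a continuous
sign-language mocap corpus: per signer, a fixed number of fixed-duration
recording units sampled at a common frame rate; per-signer mean posture and
uniform body scale; a shared low-dimensional set of orthonormal movement
synergies whose weight dynamics are band-limited (default below 3 Hz, with
roll-off up to ~6 Hz); and white measurement noise on the moving marker
coordinates at a configurable signal-to-noise ratio.

Frames are generated in the pelvis reference frame.  The pelvis sits at the
origin and the stomach marker rides rigidly with it, so after static-column
removal the informative posture dimensionality is 3 x (M - 2) (57 for the
default 21-marker set).  A common low-frequency drift can be added to every
marker to emulate whole-body translation; pelvis referencing removes it
exactly.

Ground truth (basis, weight signals, per-signer transforms, noise level) is
returned alongside the trials so every downstream stage can be scored
against construction.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from scipy import linalg, signal

from .mocap_io import MarkerSet, Trial


class SyntheticDataError(ValueError):
    """Invalid generator configuration."""


#: Rough upper-body template posture (mm, pelvis frame): x mediolateral,
#: y vertical, z anteroposterior.  Order matches DEFAULT_UPPER_BODY_MARKERS.
TEMPLATE_POSTURE_MM = np.array(
    [
        [0.0, 0.0, 0.0],  # pelvis
        [0.0, 180.0, 60.0],  # stomach
        [0.0, 220.0, -80.0],  # T10
        [0.0, 380.0, 70.0],  # sternum
        [0.0, 450.0, -60.0],  # C7
        [-70.0, 620.0, -70.0],  # head_LB
        [-70.0, 650.0, 60.0],  # head_LF
        [70.0, 620.0, -70.0],  # head_RB
        [70.0, 650.0, 60.0],  # head_RF
        [-180.0, 480.0, 0.0],  # shoulder_L
        [-250.0, 260.0, 80.0],  # elbow_L
        [-200.0, 150.0, 250.0],  # wrist_LB
        [-190.0, 140.0, 300.0],  # wrist_LF
        [-180.0, 120.0, 330.0],  # hand_LB
        [-170.0, 110.0, 370.0],  # hand_LF
        [180.0, 480.0, 0.0],  # shoulder_R
        [250.0, 260.0, 80.0],  # elbow_R
        [200.0, 150.0, 250.0],  # wrist_RB
        [190.0, 140.0, 300.0],  # wrist_RF
        [180.0, 120.0, 330.0],  # hand_RB
        [170.0, 110.0, 370.0],  # hand_RF
    ]
)

#: Markers that move rigidly with the origin in the synthetic model (their
#: coordinates are constant in the pelvis frame and carry no movement).
RIGID_WITH_ORIGIN = ("pelvis", "stomach")

ShareMode = Literal["identical", "rotated", "permuted", "mixed"]


@dataclasses.dataclass
class CohortConfig:
    """Study-geometry defaults: 6 signers x 24 trials x 5 s at 250 fps."""

    n_signers: int = 6
    n_trials: int = 24
    trial_s: float = 5.0
    fps: float = 250.0
    n_markers: int = 21
    n_synergies: int = 8
    variance_decay: float = 0.65
    base_variance_mm2: float = 1600.0
    weight_band_hz: float = 3.0
    snr_db: float | None = 20.0
    share_mode: ShareMode = "identical"
    mean_offset_sd_mm: float = 20.0
    scale_range: tuple[float, float] = (0.85, 1.15)
    drift_sd_mm: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_signers", "n_trials", "n_markers", "n_synergies"):
            if getattr(self, name) <= 0:
                raise SyntheticDataError(f"{name} must be positive")
        if not self.weight_band_hz < self.fps / 2:
            raise SyntheticDataError("weight band must be below Nyquist")
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            self.snr_db = None

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_s * self.fps))

    @property
    def frames_per_signer(self) -> int:
        return self.frames_per_trial * self.n_trials

    @property
    def n_moving_markers(self) -> int:
        return self.n_markers - len(RIGID_WITH_ORIGIN)

    @property
    def n_informative_dims(self) -> int:
        return 3 * self.n_moving_markers

    def planted_variances(self) -> np.ndarray:
        k = np.arange(self.n_synergies)
        return self.base_variance_mm2 * self.variance_decay**k

    def markerset(self) -> MarkerSet:
        ms = MarkerSet.default_upper_body()
        if self.n_markers != ms.count:
            raise SyntheticDataError(
                "non-default marker counts need an explicit marker set"
            )
        return ms


@dataclasses.dataclass
class SignerTransform:
    """Per-signer anthropometric and synergy-use differences."""

    mean_offset: np.ndarray  # M x 3, zero for origin-rigid markers
    scale: float
    rotation: np.ndarray | None = None  # K x K orthogonal, within-subspace
    permutation: np.ndarray | None = None
    weight_variance_scale: np.ndarray | None = None  # per-synergy multipliers

    def effective_basis(self, basis: np.ndarray) -> np.ndarray:
        b = basis
        if self.permutation is not None:
            b = b[self.permutation]
        if self.rotation is not None:
            b = self.rotation @ b
        return b


@dataclasses.dataclass
class SynergyGroundTruth:
    """Everything the generator planted, for recovery scoring."""

    basis: np.ndarray  # K x D over the informative dimensions
    planted_variances: np.ndarray
    weight_signals: dict[str, np.ndarray]
    signer_transforms: dict[str, SignerTransform]
    noise_sd: dict[str, float]
    seed: int


def make_basis(n_dims: int, n_synergies: int, seed: int | np.random.Generator) -> np.ndarray:
    """Random orthonormal K x D basis (QR of a Gaussian matrix), seed-deterministic."""
    if n_synergies > n_dims:
        raise SyntheticDataError(f"cannot fit {n_synergies} synergies in {n_dims} dims")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = rng.standard_normal((n_dims, n_synergies))
    q, r = np.linalg.qr(g)
    q *= np.sign(np.diag(r))  # make the factorization (and hence output) unique
    return q.T


def make_weight_signals(
    n_frames: int,
    n_synergies: int,
    fps: float,
    variance_decay: float = 0.65,
    band_hz: float = 3.0,
    seed: int | np.random.Generator = 0,
    n_trials: int = 1,
    variances: np.ndarray | None = None,
) -> np.ndarray:
    """Band-limited Gaussian weight signals with geometric variance decay.

    White noise is low-passed (4th-order Butterworth at ``band_hz``) per
    trial segment, so segments are statistically independent; columns are
    then decorrelated and rescaled so the empirical covariance over the
    whole signal equals ``diag(variances)`` exactly — the planted variances
    are the true second moments of the sample, not just expectations.
    """
    if not band_hz < fps / 2:
        raise SyntheticDataError("band edge must be below Nyquist")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if variances is None:
        variances = variance_decay ** np.arange(n_synergies)
    variances = np.asarray(variances, dtype=float)
    per_trial = n_frames // n_trials
    if per_trial * n_trials != n_frames:
        raise SyntheticDataError("n_frames must be divisible by n_trials")
    sos = signal.butter(4, band_hz, btype="low", fs=fps, output="sos")
    chunks = []
    for _ in range(n_trials):
        white = rng.standard_normal((per_trial, n_synergies))
        chunks.append(signal.sosfiltfilt(sos, white, axis=0))
    w = np.concatenate(chunks, axis=0)
    w -= w.mean(axis=0)
    cov = w.T @ w / w.shape[0]
    # exact decorrelation: whiten by the Cholesky factor, then scale columns
    chol = np.linalg.cholesky(cov)
    w = linalg.solve_triangular(chol, w.T, lower=True).T
    return w * np.sqrt(variances)


def pair_rotation(n_synergies: int, i: int, j: int, angle_deg: float) -> np.ndarray:
    """K x K rotation acting in the plane of synergies ``i`` and ``j`` (0-based)."""
    r = np.eye(n_synergies)
    a = np.radians(angle_deg)
    r[i, i] = r[j, j] = np.cos(a)
    r[i, j] = -np.sin(a)
    r[j, i] = np.sin(a)
    return r


def _moving_coordinate_indices(markerset: MarkerSet) -> np.ndarray:
    idx = []
    for m, name in enumerate(markerset.names):
        if name not in RIGID_WITH_ORIGIN:
            idx.extend(range(3 * m, 3 * m + 3))
    return np.array(idx)


def noise_sd_for_snr(
    scale: float, total_signal_variance: float, n_dims: int, snr_db: float | None
) -> float:
    """Per-coordinate white-noise SD realizing the requested SNR.

    SNR is the ratio of total planted signal variance (summed over the
    informative coordinates, after body scaling) to total noise variance.
    """
    if snr_db is None:
        return 0.0
    total_noise = scale**2 * total_signal_variance / 10.0 ** (snr_db / 10.0)
    return float(np.sqrt(total_noise / n_dims))


def synthesize_signer(
    config: CohortConfig,
    basis: np.ndarray,
    weights: np.ndarray,
    transform: SignerTransform,
    signer_id: str,
    rng: np.random.Generator,
    drift: np.ndarray | None = None,
) -> tuple[list[Trial], float]:
    """Assemble one signer's trials from planted pieces.

    frames = scale * (template + offset) + scale * (w @ basis') + noise,
    expanded to the full marker layout; a shared ``drift`` trajectory (one
    3-vector per frame) is added to *every* marker, to be removed by pelvis
    referencing downstream.  Returns the trials and the noise SD used.
    """
    markerset = config.markerset()
    move_idx = _moving_coordinate_indices(markerset)
    T = weights.shape[0]
    b_eff = transform.effective_basis(basis)
    motion = weights @ b_eff  # T x D_informative, unit = mm before scaling
    mean_marker = transform.scale * (TEMPLATE_POSTURE_MM + transform.mean_offset)
    frames_flat = np.tile(mean_marker.reshape(1, -1), (T, 1))
    frames_flat[:, move_idx] += transform.scale * motion
    sd = noise_sd_for_snr(
        transform.scale,
        float((weights.var(axis=0, ddof=0)).sum()),
        move_idx.size,
        config.snr_db,
    )
    if sd > 0:
        frames_flat[:, move_idx] += rng.normal(0.0, sd, size=(T, move_idx.size))
    frames = frames_flat.reshape(T, markerset.count, 3)
    if drift is not None:
        frames = frames + drift[:, None, :]
    per_trial = config.frames_per_trial
    trials = [
        Trial(
            signer_id,
            f"{signer_id}__trial{k:02d}",
            frames[k * per_trial : (k + 1) * per_trial],
            config.fps,
        )
        for k in range(config.n_trials)
    ]
    return trials, sd


def _signer_transform(
    config: CohortConfig, rng: np.random.Generator, markerset: MarkerSet
) -> SignerTransform:
    offset = rng.normal(0.0, config.mean_offset_sd_mm, size=(markerset.count, 3))
    for m, name in enumerate(markerset.names):
        if name in RIGID_WITH_ORIGIN and name == markerset.origin_marker:
            offset[m] = 0.0
    scale = float(rng.uniform(*config.scale_range))
    rotation = permutation = None
    mode = config.share_mode
    if mode == "mixed":
        mode = "rotated" if rng.random() < 0.5 else "permuted"
    if mode == "rotated":
        rotation = linalg.qr(rng.standard_normal((config.n_synergies,) * 2))[0]
        if np.linalg.det(rotation) < 0:
            rotation[0] *= -1
    elif mode == "permuted":
        permutation = rng.permutation(config.n_synergies)
    return SignerTransform(offset, scale, rotation, permutation)


def _drift(config: CohortConfig, rng: np.random.Generator, T: int) -> np.ndarray:
    """Slow whole-body translation: band-limited (0.5 Hz) random walk-like path."""
    if config.drift_sd_mm <= 0:
        return np.zeros((T, 3))
    sos = signal.butter(2, 0.5, btype="low", fs=config.fps, output="sos")
    d = signal.sosfiltfilt(sos, rng.standard_normal((T, 3)), axis=0)
    sd = d.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return d * (config.drift_sd_mm / sd)


def generate_cohort(
    config: CohortConfig,
    transforms: dict[str, SignerTransform] | None = None,
) -> tuple[dict[str, list[Trial]], SynergyGroundTruth]:
    """Generate the full multi-signer cohort plus its ground truth.

    Reproducible bitwise for a given config and seed.  ``transforms`` may
    override the drawn per-signer transforms (keyed by signer id) to plant
    specific rotations, permutations or synergy-use profiles.
    """
    rng = np.random.default_rng(config.seed)
    markerset = config.markerset()
    basis = make_basis(config.n_informative_dims, config.n_synergies, rng)
    variances = config.planted_variances()
    trials: dict[str, list[Trial]] = {}
    gt_weights: dict[str, np.ndarray] = {}
    gt_transforms: dict[str, SignerTransform] = {}
    noise_sds: dict[str, float] = {}
    for s in range(config.n_signers):
        signer_id = f"signer{s + 1}"
        tr = _signer_transform(config, rng, markerset)
        if transforms and signer_id in transforms:
            tr = transforms[signer_id]
        v = variances
        if tr.weight_variance_scale is not None:
            v = variances * np.asarray(tr.weight_variance_scale, dtype=float)
        w = make_weight_signals(
            config.frames_per_signer,
            config.n_synergies,
            config.fps,
            band_hz=config.weight_band_hz,
            seed=rng,
            n_trials=config.n_trials,
            variances=v,
        )
        drift = _drift(config, rng, config.frames_per_signer)
        signer_trials, sd = synthesize_signer(
            config, basis, w, tr, signer_id, rng, drift
        )
        trials[signer_id] = signer_trials
        gt_weights[signer_id] = w
        gt_transforms[signer_id] = tr
        noise_sds[signer_id] = sd
    truth = SynergyGroundTruth(
        basis=basis,
        planted_variances=variances,
        weight_signals=gt_weights,
        signer_transforms=gt_transforms,
        noise_sd=noise_sds,
        seed=config.seed,
    )
    return trials, truth


def rotated_pair_scenario(
    seed: int = 0,
    angle_deg: float = 25.0,
    pair: tuple[int, int] = (4, 5),
) -> tuple[dict[str, list[Trial]], CohortConfig, str]:
    """Two-signer cohort in which one signer's synergy pair is rotated.

    A validation scenario for leave-one-out robustness: both signers share
    the planted basis, but ``signer2``'s components ``pair`` (0-based) are
    rotated by ``angle_deg`` within their span, and that signer activates
    those two synergies more strongly (signers may weight shared synergies
    differently).  5,000 frames per signer at 50 fps keep the scenario
    cheap while leaving enough effective samples of the band-limited
    weights for eigenvector estimates to be stable; the variance profile
    isolates the pair spectrally from its neighbours so the planted
    rotation, not sampling noise, dominates the pooled-versus-reduced
    component angles.
    """
    config = CohortConfig(
        n_signers=2, n_trials=4, trial_s=25.0, fps=50.0, seed=seed
    )
    profile = np.array([1.0, 0.5, 0.25, 0.125, 0.028, 0.011, 0.0025, 0.001])
    profile *= config.base_variance_mm2 / config.planted_variances()
    boost = np.ones(config.n_synergies)
    boost[list(pair)] = 4.0
    _, base_truth = generate_cohort(config)
    transforms = {}
    for sid, base in base_truth.signer_transforms.items():
        scale = profile * (boost if sid == "signer2" else 1.0)
        rot = (
            pair_rotation(config.n_synergies, pair[0], pair[1], angle_deg)
            if sid == "signer2"
            else None
        )
        transforms[sid] = dataclasses.replace(
            base, rotation=rot, permutation=None, weight_variance_scale=scale
        )
    trials, _ = generate_cohort(config, transforms=transforms)
    return trials, config, "signer2"


def principal_angles_deg(basis_a: np.ndarray, basis_b: np.ndarray) -> np.ndarray:
    """Principal angles (degrees, descending) between two row-spanned subspaces."""
    return np.degrees(linalg.subspace_angles(np.asarray(basis_a).T, np.asarray(basis_b).T))


def measured_snr_db(centered_block: np.ndarray, basis: np.ndarray) -> float:
    """Empirical SNR: in-subspace power over out-of-subspace residual power."""
    X = np.asarray(centered_block, dtype=float)
    proj = (X @ basis.T) @ basis
    sig = float((proj**2).sum())
    resid = float(((X - proj) ** 2).sum())
    if resid == 0.0:
        return float("inf")
    return 10.0 * np.log10(sig / resid)
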