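"""Principal-movement extraction.

PCA by singular value decomposition of the normalized posture matrix yields
orthonormal principal components (eigenpostures) and their eigenvalues; the
weight time series ``w_i(t)`` is the projection of each normalized posture
onto component ``i`` and describes how strongly that movement pattern is
expressed over time.  Weights are low-pass filtered (zero-phase Butterworth,
default 6 Hz cut-off, order 4) before downstream comparisons, since
volitional movement power concentrates in the low frequencies; Welch
periodograms of the weights document that frequency content.  A principal
movement is resynthesized into original coordinates as

    PM_i(t) = p_mean + d_mean * w_i(t) * PC_i

using one signer's normalization parameters.

No re-centering is performed before the SVD: the cohort blocks are already
centered signer-by-signer, and subtracting a second, pooled mean would alter
what the decomposition measures.  An input check enforces near-zero column
means.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np
from scipy import signal

from .normalization import NormalizationParams, NormalizedCohort


class DecompositionError(ValueError):
    """Invalid input to PCA or resynthesis."""


@dataclasses.dataclass
class PMDecomposition:
    """Principal components, eigenvalues and weight time series.

    ``pcs`` is ``K x D`` with orthonormal rows; ``eigenvalues[i]`` equals the
    variance of ``weights[:, i]`` over the fitted rows; ``ev_fraction`` is
    each eigenvalue over the total variance of the fitted matrix.
    """

    pcs: np.ndarray
    eigenvalues: np.ndarray
    ev_fraction: np.ndarray
    weights: np.ndarray
    frame_rate: float
    fitted_on: str = ""

    @property
    def n_components(self) -> int:
        return self.pcs.shape[0]

    def cumulative_ev(self) -> np.ndarray:
        return np.cumsum(self.ev_fraction)


@dataclasses.dataclass
class PrincipalMovement:
    """One PM resynthesized as a 3-D trajectory in original units."""

    index: int
    trajectory: np.ndarray
    signer_id: str
    weighting: np.ndarray


@dataclasses.dataclass
class WeightSpectrum:
    """Welch power spectral densities of the weight signals (one per PM)."""

    frequencies: np.ndarray
    psd: np.ndarray  # n_frequencies x K
    segment_s: float
    overlap: float
    window: str


def _apply_sign_convention(pcs: np.ndarray) -> np.ndarray:
    """Fix each component's arbitrary SVD sign: largest-|loading| positive."""
    flip = np.sign(pcs[np.arange(pcs.shape[0]), np.abs(pcs).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return pcs * flip[:, None]


def fit_pca(
    cohort: NormalizedCohort | np.ndarray,
    n_components: int | None = None,
    fitted_on: str = "",
    frame_rate: float | None = None,
) -> PMDecomposition:
    """Extract principal movements from a normalized posture matrix.

    Accepts a :class:`NormalizedCohort` or a bare (already centered) matrix.
    Eigenvalues use the 1/T convention so that the variance of each weight
    column equals its eigenvalue exactly.
    """
    if isinstance(cohort, NormalizedCohort):
        X = cohort.matrix.rows
        frame_rate = cohort.matrix.frame_rate
        fitted_on = fitted_on or "+".join(cohort.matrix.signer_ids())
    else:
        X = np.asarray(cohort, dtype=float)
        if frame_rate is None:
            frame_rate = float("nan")
    T, D = X.shape
    if T < D:
        raise DecompositionError(
            f"{T} rows for {D} columns: PCA needs at least as many frames as "
            "coordinates; record more frames"
        )
    scale = max(1.0, float(np.sqrt((X**2).sum(axis=1).mean())))
    col_means = X.mean(axis=0)
    if np.abs(col_means).max() > 1e-8 * scale:
        raise DecompositionError(
            "matrix is not centered (column means are not ~0); normalize per "
            "signer before fitting"
        )
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    pcs = _apply_sign_convention(Vt)
    eig = s**2 / T
    total = eig.sum()
    if n_components is not None:
        pcs = pcs[:n_components]
        eig_kept = eig[:n_components]
    else:
        eig_kept = eig
    weights = X @ pcs.T
    return PMDecomposition(
        pcs=pcs,
        eigenvalues=eig_kept,
        ev_fraction=eig_kept / total,
        weights=weights,
        frame_rate=float(frame_rate),
        fitted_on=fitted_on,
    )


def project_weights(
    cohort: NormalizedCohort | np.ndarray, decomposition: PMDecomposition
) -> np.ndarray:
    """Project normalized postures onto the components: ``w_i(t) = p_norm(t) . PC_i``."""
    X = cohort.matrix.rows if isinstance(cohort, NormalizedCohort) else np.asarray(cohort)
    if X.shape[1] != decomposition.pcs.shape[1]:
        raise DecompositionError(
            f"dimension mismatch: data has {X.shape[1]} columns, "
            f"components have {decomposition.pcs.shape[1]}"
        )
    return X @ decomposition.pcs.T


def filter_weights(
    weights: np.ndarray,
    frame_rate: float,
    cutoff_hz: float = 6.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter, applied per weight column.

    Forward-backward application (filtfilt) doubles the attenuation in dB
    and cancels phase delay, the norm for kinematic signals.
    """
    if not cutoff_hz < frame_rate / 2:
        raise DecompositionError(
            f"cut-off {cutoff_hz} Hz must be below Nyquist {frame_rate / 2} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=frame_rate, output="sos")
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    squeeze = weights.ndim == 1
    if squeeze:
        w = w.T if w.shape[0] == 1 else w
    out = signal.sosfiltfilt(sos, w, axis=0)
    return out[:, 0] if squeeze and out.ndim == 2 else out


def welch_psd(
    weights: np.ndarray,
    frame_rate: float,
    segment_s: float = 4.0,
    overlap_fraction: float = 0.5,
    window: str = "hann",
) -> WeightSpectrum:
    """Welch PSD per weight column, density convention (integral ~ variance)."""
    w = np.asarray(weights, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    nperseg = int(round(segment_s * frame_rate))
    if nperseg > w.shape[0]:
        raise DecompositionError(
            f"segment of {nperseg} samples exceeds signal length {w.shape[0]}"
        )
    noverlap = int(round(overlap_fraction * nperseg))
    freqs, psd = signal.welch(
        w, fs=frame_rate, window=window, nperseg=nperseg, noverlap=noverlap, axis=0
    )
    return WeightSpectrum(freqs, psd, segment_s, overlap_fraction, window)


def n_components_for_variance(
    decomposition: PMDecomposition, target: float = 0.946
) -> int:
    """Smallest K whose cumulative explained-variance fraction reaches ``target``."""
    return int(np.searchsorted(decomposition.cumulative_ev(), target) + 1)


def resynthesize_pm(
    decomposition: PMDecomposition,
    params: NormalizationParams,
    index: int,
    weights: np.ndarray | None = None,
    rows: slice | np.ndarray | None = None,
) -> PrincipalMovement:
    """Project one component back to original coordinates for one signer.

    ``index`` is zero-based.  By default the decomposition's own weight rows
    are used (optionally restricted with ``rows``); pass filtered weights
    explicitly to resynthesize the denoised movement.
    """
    if not 0 <= index < decomposition.n_components:
        raise DecompositionError(f"component index {index} out of range")
    if params.mean_posture.shape[0] != decomposition.pcs.shape[1]:
        raise DecompositionError(
            "normalization params dimensionality does not match components"
        )
    if weights is None:
        weights = decomposition.weights
    w = np.asarray(weights, dtype=float)
    w_i = w[:, index] if w.ndim == 2 else w
    if rows is not None:
        w_i = w_i[rows]
    traj = (
        params.mean_posture[None, :]
        + params.mean_norm * w_i[:, None] * decomposition.pcs[index][None, :]
    )
    return PrincipalMovement(index, traj, params.signer_id, w_i)


def extreme_posture_frames(weights: np.ndarray, index: int = 0) -> tuple[int, int]:
    """Row indices of the global minimum and maximum weighting (first on ties)."""
    w = np.asarray(weights, dtype=float)
    w_i = w[:, index] if w.ndim == 2 else w
    return int(np.argmin(w_i)), int(np.argmax(w_i))


def save_decomposition(group: h5py.Group, d: PMDecomposition) -> None:
    for name in ("pcs", "eigenvalues", "ev_fraction", "weights"):
        group.create_dataset(name, data=getattr(d, name), track_times=False)
    group.attrs["frame_rate"] = d.frame_rate
    group.attrs["fitted_on"] = d.fitted_on


def load_decomposition(group: h5py.Group) -> PMDecomposition:
    return PMDecomposition(
        pcs=group["pcs"][...],
        eigenvalues=group["eigenvalues"][...],
        ev_fraction=group["ev_fraction"][...],
        weights=group["weights"][...],
        frame_rate=float(group.attrs["frame_rate"]),
        fitted_on=str(group.attrs["fitted_on"]),
    )
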