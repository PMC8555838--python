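"""Per-signer anthropometric normalization.

Two steps, applied to each signer's full block of concatenated trials:

1. subtract the signer's mean posture, so the analysis captures deviations
   from the habitual pose rather than differences in mean posture;
2. divide by the mean per-frame Euclidean norm of the centered postures, so
   every signer contributes comparably to the pooled variance regardless of
   body size.

Both steps are exactly invertible per signer; the parameters are retained so
principal movements can be resynthesized in original coordinates.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import h5py
import numpy as np

from .mocap_io import MocapIOError, PostureMatrix


class NormalizationError(ValueError):
    """Degenerate or mismatched input to the normalization step."""


@dataclasses.dataclass
class NormalizationParams:
    """Per-signer mean posture and mean Euclidean norm (the inverse mapping)."""

    signer_id: str
    mean_posture: np.ndarray
    mean_norm: float

    def __post_init__(self) -> None:
        self.mean_posture = np.asarray(self.mean_posture, dtype=float)
        if not self.mean_norm > 0:
            raise NormalizationError("mean_norm must be positive")


@dataclasses.dataclass
class NormalizedCohort:
    """Normalized posture matrix plus the per-signer parameters used."""

    matrix: PostureMatrix
    params: dict[str, NormalizationParams]

    def __post_init__(self) -> None:
        for signer in self.matrix.signer_ids():
            if signer not in self.params:
                raise NormalizationError(f"missing params for signer {signer!r}")

    def signer_block(self, signer_id: str) -> np.ndarray:
        return self.matrix.signer_block(signer_id)


def mean_posture(block: np.ndarray) -> np.ndarray:
    """Column-wise mean posture of one signer's rows."""
    block = np.asarray(block, dtype=float)
    if block.size == 0:
        raise NormalizationError("empty signer block")
    return block.mean(axis=0)


def center(block: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Subtract a mean posture from every row."""
    block = np.asarray(block, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if block.shape[1] != mean.shape[0]:
        raise NormalizationError(
            f"dimension mismatch: block has {block.shape[1]} columns, "
            f"mean has {mean.shape[0]}"
        )
    return block - mean


def mean_euclidean_norm(centered: np.ndarray) -> float:
    """Mean over frames of the per-frame Euclidean norm of the posture vector."""
    norms = np.linalg.norm(np.asarray(centered, dtype=float), axis=1)
    d = float(norms.mean())
    if d == 0.0:
        raise NormalizationError("degenerate (constant) signer block: zero mean norm")
    return d


def normalize_signer(
    block: np.ndarray, signer_id: str
) -> tuple[np.ndarray, NormalizationParams]:
    """Center one signer's block and scale it to unit mean row norm."""
    pbar = mean_posture(block)
    cent = center(block, pbar)
    dbar = mean_euclidean_norm(cent)
    return cent / dbar, NormalizationParams(signer_id, pbar, dbar)


def denormalize(block: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Exact inverse of :func:`normalize_signer`."""
    return np.asarray(block, dtype=float) * params.mean_norm + params.mean_posture


def normalize_cohort(pm: PostureMatrix) -> NormalizedCohort:
    """Normalize every signer's block in place of the cohort posture matrix."""
    rows = pm.rows.copy()
    params: dict[str, NormalizationParams] = {}
    for signer in pm.signer_ids():
        idx = pm.signer_row_indices(signer)
        rows[idx], params[signer] = normalize_signer(pm.rows[idx], signer)
    out = PostureMatrix(rows, pm.frame_rate, list(pm.segments), pm.column_labels)
    return NormalizedCohort(out, params)


def assemble_cohort(signer_matrices: Sequence[PostureMatrix]) -> NormalizedCohort:
    """Concatenate per-signer posture matrices and normalize each block.

    Each signer then has zero column means and unit mean row norm, ensuring
    equal contribution to the pooled variance.
    """
    if not signer_matrices:
        raise NormalizationError("no signer matrices given")
    first = signer_matrices[0]
    blocks = []
    segments = []
    pos = 0
    for pm in signer_matrices:
        if pm.column_labels != first.column_labels:
            raise MocapIOError("inconsistent column layouts across signers")
        if pm.frame_rate != first.frame_rate:
            raise MocapIOError("inconsistent frame rates across signers")
        blocks.append(pm.rows)
        for s in pm.segments:
            segments.append(
                dataclasses.replace(s, start=s.start + pos, stop=s.stop + pos)
            )
        pos += pm.n_rows
    combined = PostureMatrix(
        np.concatenate(blocks, axis=0), first.frame_rate, segments, first.column_labels
    )
    return normalize_cohort(combined)


def normalized_cohort_from_trials(
    trials: "dict[str, list]",
    markerset=None,
    drop_static: bool = True,
) -> NormalizedCohort:
    """Convenience path: trials -> pelvis frame -> posture matrix -> normalize.

    Static columns (origin marker, markers rigid with it) are removed by
    default so the analysis runs on the informative coordinates only.
    """
    from . import mocap_io as mio

    markerset = markerset or mio.MarkerSet.default_upper_body()
    flat = [
        mio.reference_to_pelvis(t, markerset)
        for signer in trials
        for t in trials[signer]
    ]
    pm = mio.build_posture_matrix(flat, markerset)
    if drop_static:
        pm, _ = mio.drop_static_columns(pm)
    return normalize_cohort(pm)


def save_params(group: h5py.Group, params: dict[str, NormalizationParams]) -> None:
    for signer, p in params.items():
        sub = group.create_group(signer)
        sub.create_dataset("mean_posture", data=p.mean_posture, track_times=False)
        sub.attrs["mean_norm"] = p.mean_norm


def load_params(group: h5py.Group) -> dict[str, NormalizationParams]:
    return {
        signer: NormalizationParams(
            signer, group[signer]["mean_posture"][...], float(group[signer].attrs["mean_norm"])
        )
        for signer in group
    }
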