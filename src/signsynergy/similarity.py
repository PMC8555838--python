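"""Comparing principal movements within and across signers.

Three procedures:

* **Leave-one-out robustness** — refit the PCA with each signer removed and
  measure, per component, the angle between the full-cohort and reduced
  component vectors.  Components whose orientation moves by at most a
  threshold (default 15 degrees) are robust to signer changes.
* **Cosine similarity of PMs** — the normalized inner product of two PMs'
  flattened weight-times-component matrices (built from normalized data, so
  anthropometric differences cancel).  For PMs sharing a weight signal this
  factorizes exactly into (w_a . w_b)(PC_a . PC_b)/(|w_a||w_b|).
* **Cross-projection subspace similarity** — variance of one signer's
  movements captured by another signer's leading N components, relative to
  the variance captured by their own leading N; symmetrized by averaging
  both directions.  Values near 1 mean near-identical subspaces.

Component signs are arbitrary in PCA, so the default for angles and cosines
is absolute-value ("abs") mode; signed values are available for auditing.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .normalization import NormalizedCohort
from .pm_extraction import PMDecomposition, filter_weights, fit_pca


class SimilarityError(ValueError):
    """Invalid input to a comparison procedure."""


@dataclasses.dataclass
class RobustnessResult:
    """Angles between full-cohort and leave-one-out component vectors."""

    left_out: str
    angles_deg: np.ndarray
    robust_flags: np.ndarray
    threshold_deg: float


@dataclasses.dataclass
class SimilarityResult:
    """Cosine-similarity matrix between one signer's PMs and reference PMs."""

    sim_matrix: np.ndarray  # K_individual x K_reference
    high_mask: np.ndarray
    moderate_mask: np.ndarray
    best_match: np.ndarray  # per individual PM, index of best reference PM
    combination_flags: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]


@dataclasses.dataclass
class CrossProjectionResult:
    """Directed and symmetrized cross-projection subspace similarity."""

    n_components: int
    v1: float
    v2: float
    ratio: float
    reverse_ratio: float
    symmetric: float


def pm_cosine_similarity(
    pm_a: np.ndarray, pm_b: np.ndarray, mode: str = "abs"
) -> float:
    """Cosine similarity of two PM matrices, flattened to vectors.

    Both inputs must share shape; typically each is ``T x D`` built as
    ``outer(w_i, PC_i)`` from normalized weights and components.
    """
    a = np.asarray(pm_a, dtype=float).ravel()
    b = np.asarray(pm_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise SimilarityError("PM matrices must share shape")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise SimilarityError("cosine similarity undefined for an all-zero PM")
    c = float(a @ b / (na * nb))
    return abs(c) if mode == "abs" else c


def weighted_pm_matrix(weights_i: np.ndarray, pc_i: np.ndarray) -> np.ndarray:
    """Normalized PM matrix of one component: rank-1 ``outer(w_i, PC_i)``."""
    return np.outer(np.asarray(weights_i, dtype=float), np.asarray(pc_i, dtype=float))


def component_angles_deg(
    pcs_a: np.ndarray, pcs_b: np.ndarray, mode: str = "abs"
) -> np.ndarray:
    """Same-rank angles (degrees) between two component sets."""
    a = np.asarray(pcs_a, dtype=float)
    b = np.asarray(pcs_b, dtype=float)
    n = min(a.shape[0], b.shape[0])
    dots = np.einsum("ij,ij->i", a[:n], b[:n])
    if mode == "abs":
        dots = np.abs(dots)
    return np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))


def loo_robustness(
    cohort: NormalizedCohort,
    n_pms: int,
    threshold_deg: float = 15.0,
    mode: str = "abs",
) -> list[RobustnessResult]:
    """Leave-one-out orientation robustness of the first ``n_pms`` components.

    The reduced fit simply drops the left-out signer's rows: blocks are
    normalized per signer, so the remaining blocks are unchanged.
    """
    signers = cohort.matrix.signer_ids()
    if len(signers) < 2:
        raise SimilarityError("leave-one-out needs at least two signers")
    full = fit_pca(cohort)
    if n_pms > full.n_components:
        raise SimilarityError(
            f"n_pms={n_pms} exceeds available components {full.n_components}"
        )
    results = []
    for signer in signers:
        keep = np.ones(cohort.matrix.n_rows, dtype=bool)
        keep[cohort.matrix.signer_row_indices(signer)] = False
        reduced = fit_pca(cohort.matrix.rows[keep], frame_rate=cohort.matrix.frame_rate)
        angles = component_angles_deg(full.pcs[:n_pms], reduced.pcs[:n_pms], mode=mode)
        results.append(
            RobustnessResult(signer, angles, angles <= threshold_deg, threshold_deg)
        )
    return results


def individual_vs_common(
    signer_block: np.ndarray,
    common: PMDecomposition,
    n_pms: int,
    frame_rate: float,
    individual: PMDecomposition | None = None,
    cutoff_hz: float = 6.0,
    order: int = 4,
    mode: str = "abs",
    high_threshold: float = 0.7,
    moderate_threshold: float = 0.5,
    combination_threshold: float = 0.4,
) -> SimilarityResult:
    """Cosine similarities between one signer's own PMs and the common PMs.

    Both sets of weights come from projecting the *same* normalized data
    (the signer's own block) on each basis, then low-pass filtering; each PM
    matrix is the rank-1 product of its weight signal and component vector.
    Rows with no single high match but at least two matches above the
    combination threshold are flagged as combinations of common PMs.
    """
    X = np.asarray(signer_block, dtype=float)
    if individual is None:
        individual = fit_pca(X, frame_rate=frame_rate)
    if X.shape[1] != common.pcs.shape[1] or X.shape[1] != individual.pcs.shape[1]:
        raise SimilarityError("dimension mismatch between data and components")
    if n_pms > min(individual.n_components, common.n_components):
        raise SimilarityError("n_pms exceeds available components")
    w_ind = filter_weights(X @ individual.pcs[:n_pms].T, frame_rate, cutoff_hz, order)
    w_com = filter_weights(X @ common.pcs[:n_pms].T, frame_rate, cutoff_hz, order)
    sim = np.empty((n_pms, n_pms))
    for i in range(n_pms):
        pm_i = weighted_pm_matrix(w_ind[:, i], individual.pcs[i])
        for j in range(n_pms):
            pm_j = weighted_pm_matrix(w_com[:, j], common.pcs[j])
            sim[i, j] = pm_cosine_similarity(pm_i, pm_j, mode=mode)
    comparable = np.abs(sim) if mode != "abs" else sim
    high = comparable > high_threshold
    combo = (~high.any(axis=1)) & (
        (comparable > combination_threshold).sum(axis=1) >= 2
    )
    return SimilarityResult(
        sim_matrix=sim,
        high_mask=high,
        moderate_mask=comparable > moderate_threshold,
        best_match=comparable.argmax(axis=1),
        combination_flags=combo,
        row_labels=tuple(f"individual_PM{i + 1}" for i in range(n_pms)),
        col_labels=tuple(f"common_PM{j + 1}" for j in range(n_pms)),
    )


def _captured_variance(block: np.ndarray, pcs: np.ndarray, n: int) -> float:
    """Cumulative variance of projections on the first ``n`` components."""
    proj = block @ pcs[:n].T
    return float(proj.var(axis=0, ddof=0).sum())


def cross_projection(
    block_a: np.ndarray,
    decomp_a: PMDecomposition,
    block_b: np.ndarray,
    decomp_b: PMDecomposition,
    n_components: int,
) -> CrossProjectionResult:
    """Symmetric cross-projection similarity between two signers' subspaces.

    ``v1`` is the variance of signer a's movements on their own first N
    components, ``v2`` the same movements on signer b's first N; the
    directed ratio is v2/v1 and the symmetric value averages both
    directions.
    """
    if n_components > min(decomp_a.n_components, decomp_b.n_components):
        raise SimilarityError("n_components exceeds rank of a decomposition")
    A = np.asarray(block_a, dtype=float)
    B = np.asarray(block_b, dtype=float)
    v1 = _captured_variance(A, decomp_a.pcs, n_components)
    if v1 == 0.0:
        raise SimilarityError("zero variance on signer a's own components")
    v2 = _captured_variance(A, decomp_b.pcs, n_components)
    v1_rev = _captured_variance(B, decomp_b.pcs, n_components)
    if v1_rev == 0.0:
        raise SimilarityError("zero variance on signer b's own components")
    v2_rev = _captured_variance(B, decomp_a.pcs, n_components)
    ratio = v2 / v1
    reverse = v2_rev / v1_rev
    return CrossProjectionResult(
        n_components=n_components,
        v1=v1,
        v2=v2,
        ratio=ratio,
        reverse_ratio=reverse,
        symmetric=0.5 * (ratio + reverse),
    )
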