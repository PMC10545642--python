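"""Cross-run representational similarity.

Each condition's voxel pattern is estimated once per run; similarity between
two conditions is the Pearson correlation of their voxel patterns, computed
for every admissible run pair, Fisher-z transformed, and averaged. Averaging
is done in z (variance-stabilised) space. Within-condition (diagonal) cells
use distinct-run pairs only -- the correlation of a pattern with itself in the
same run is 1 by construction and carries no information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .poi_models import N_CONDITIONS

__all__ = [
    "SimilarityMatrix",
    "SimilarityCells",
    "fisher_z",
    "cross_run_similarity",
    "vectorize_cells",
    "N_CELLS",
]

#: 12*13/2 unique cells of a symmetric 12x12 matrix (diagonal included).
N_CELLS = N_CONDITIONS * (N_CONDITIONS + 1) // 2

R_CLIP = 1.0 - 1e-6


@dataclass
class SimilarityMatrix:
    """A subject's 12x12 Fisher-z similarity matrix for one ROI.

    ``n_pairs[i, j]`` counts the run pairs averaged into cell (i, j).
    """

    subject: object
    roi: object
    matrix: np.ndarray
    n_pairs: np.ndarray


@dataclass
class SimilarityCells:
    """The 78 unique cells of a SimilarityMatrix.

    Order: upper triangle including the diagonal, row-major in canonical
    condition order, i.e. (0,0), (0,1), ..., (0,11), (1,1), (1,2), ...
    """

    subject: object
    roi: object
    values: np.ndarray


def fisher_z(r) -> np.ndarray:
    """Variance-stabilising Fisher transform z = atanh(r).

    |r| is clipped to 1 - 1e-6 so that degenerate (noise-free) correlations
    of exactly +/-1 stay finite.
    """
    r = np.asarray(r, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("fisher_z requires finite correlations")
    if (np.abs(r) > 1 + 1e-12).any():
        raise ValueError("correlations must lie in [-1, 1]")
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def cross_run_similarity(
    dataset,
    subject,
    roi,
    cross_run_only: bool = False,
) -> SimilarityMatrix:
    """Fisher-z similarity matrix for one subject and ROI.

    For a condition pair (i, j), i != j, all run pairs are used (including
    same-run pairs unless ``cross_run_only``); for i == j only distinct-run
    pairs. Each run-pair Pearson correlation over voxels is Fisher
    transformed before averaging.
    """
    betas = np.asarray(dataset.patterns(subject, roi), dtype=float)
    n_runs, n_cond, n_vox = betas.shape
    if n_cond != N_CONDITIONS:
        raise ValueError(f"expected {N_CONDITIONS} conditions, got {n_cond}")
    if n_runs < 2 or n_vox < 2:
        raise ValueError("need at least 2 runs and 2 voxels")

    flat = betas.reshape(n_runs * n_cond, n_vox)
    sd = flat.std(axis=1)
    if (sd == 0).any():
        k = int(np.flatnonzero(sd == 0)[0])
        run, cond = divmod(k, n_cond)
        label = dataset.scheme.conditions[cond].label
        raise ValueError(
            f"zero-variance pattern: subject={subject!r} run={run + 1} condition={label!r}"
        )
    z = fisher_z(np.corrcoef(flat))  # (runs*cond) x (runs*cond)
    z4 = z.reshape(n_runs, n_cond, n_runs, n_cond)

    mat = np.zeros((N_CONDITIONS, N_CONDITIONS))
    n_pairs = np.zeros((N_CONDITIONS, N_CONDITIONS), dtype=int)
    run_eq = np.eye(n_runs, dtype=bool)
    off_mask = ~run_eq if cross_run_only else np.ones((n_runs, n_runs), dtype=bool)
    diag_mask = np.triu(~run_eq)  # unordered distinct-run pairs
    for i in range(N_CONDITIONS):
        for j in range(i, N_CONDITIONS):
            block = z4[:, i, :, j]
            mask = diag_mask if i == j else off_mask
            mat[i, j] = mat[j, i] = block[mask].mean()
            n_pairs[i, j] = n_pairs[j, i] = int(mask.sum())
    return SimilarityMatrix(subject=subject, roi=roi, matrix=mat, n_pairs=n_pairs)


def vectorize_cells(sim: SimilarityMatrix) -> SimilarityCells:
    """Vectorize to the 78 unique cells (upper triangle incl. diagonal,
    row-major). The same ordering applied to a POI matrix yields aligned
    predictors."""
    iu = np.triu_indices(N_CONDITIONS)
    return SimilarityCells(subject=sim.subject, roi=sim.roi, values=sim.matrix[iu])


def dataset_cells(dataset, roi, cross_run_only: bool = False) -> list[SimilarityCells]:
    """Similarity cells for every subject of a dataset (one ROI)."""
    return [
        vectorize_cells(cross_run_similarity(dataset, s, roi, cross_run_only))
        for s in dataset.subjects
    ]
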