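"""MLC leaf sequencing and aperture-weight (direct aperture) optimisation.

An optimised fluence map is quantised to integer levels and decomposed
into deliverable MLC apertures by a unidirectional sweep (level
decomposition): level ``t`` opens every bixel whose quantised value is
at least ``t``.  When a level's open set is non-contiguous within a
row, the level is split into one aperture per run rank so each aperture
exposes a single [left, right) interval per leaf pair.  With no cap on
the segment count the weighted sum of aperture masks reconstructs the
quantised map integer-exactly.

Aperture weights are then re-optimised against the plan objective by
the same projected L-BFGS machinery used for fluence: each aperture
contributes one dose column (the sum of its open bixels' d_ij columns),
turning direct aperture optimisation into a small nonnegative fluence
problem.  Aperture shapes are fixed; only weights move.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse

from .dose import DoseInfluenceMatrix, MAX_ROWS
from .fluence import OptimizerConfig, optimize_fluence
from .objective import MatrixProblem, PlanObjective


@dataclass(frozen=True)
class Aperture:
    """One MLC shape for one beam with a scalar delivery weight.

    ``rows`` holds, per fluence-grid row, a half-open bixel-column
    interval (left, right) or None for a closed leaf pair.  One grid
    row drives two adjacent physical leaf pairs moving together (the
    bixel height is two leaf widths).
    """

    beam_index: int
    rows: tuple[tuple[int, int] | None, ...]
    weight: float

    def __post_init__(self) -> None:
        if len(self.rows) > MAX_ROWS:
            raise ValueError("aperture exceeds the MLC leaf-pair capacity")
        for lr in self.rows:
            if lr is not None and lr[0] >= lr[1]:
                raise ValueError("open leaf pair needs left < right")

    def mask(self, n_cols: int) -> np.ndarray:
        m = np.zeros((len(self.rows), n_cols), dtype=bool)
        for r, lr in enumerate(self.rows):
            if lr is not None:
                m[r, lr[0]:lr[1]] = True
        return m

    def open_bixels(self, n_cols: int) -> np.ndarray:
        """Flat bixel indices (row-major) opened by this aperture."""
        return np.flatnonzero(self.mask(n_cols).ravel())

    @property
    def open_area(self) -> int:
        return sum(r - l for pair in self.rows if pair
                   for l, r in [pair])


def quantize_fluence(fmap: np.ndarray, levels: int) -> np.ndarray:
    """Bin a nonnegative fluence map to integers 0..levels.

    Values are rounded to ``v * levels / max(v)``; an all-zero map stays
    zero.  One quantisation level corresponds to ``max(v) / levels``
    fluence weight.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    fmap = np.asarray(fmap, dtype=float)
    if np.any(fmap < 0):
        raise ValueError("fluence map must be nonnegative")
    vmax = fmap.max()
    if vmax <= 0:
        return np.zeros(fmap.shape, dtype=int)
    return np.rint(fmap * levels / vmax).astype(int)


def _row_runs(mask_row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (left, right) intervals."""
    padded = np.concatenate([[False], mask_row, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(edges[k]), int(edges[k + 1]))
            for k in range(0, len(edges), 2)]


@dataclass(frozen=True)
class SequencingResult:
    apertures: tuple[Aperture, ...]
    exact: bool  # False when capping dropped segments


def sweep_sequence(intmap: np.ndarray,
                   max_apertures: int | None = None,
                   beam_index: int = 0) -> SequencingResult:
    """Decompose an integer fluence map into unit-weight MLC apertures.

    Levels are swept from 1 to max(intmap); identical consecutive
    shapes merge with summed weight.  If a cap is given and exceeded,
    the ``max_apertures`` segments of largest weight x open area are
    kept and the result is marked approximate.
    """
    intmap = np.asarray(intmap)
    if np.any(intmap < 0):
        raise ValueError("integer fluence map must be nonnegative")
    n_rows, n_cols = intmap.shape
    top = int(intmap.max(initial=0))
    shapes: list[tuple[tuple[int, int] | None, ...]] = []
    for t in range(1, top + 1):
        mask = intmap >= t
        runs = [_row_runs(mask[r]) for r in range(n_rows)]
        for q in range(max(len(rr) for rr in runs)):
            shapes.append(tuple(rr[q] if q < len(rr) else None
                                for rr in runs))
    apertures: list[Aperture] = []
    for shape in shapes:
        if apertures and apertures[-1].rows == shape:
            apertures[-1] = replace(apertures[-1],
                                    weight=apertures[-1].weight + 1.0)
        else:
            apertures.append(Aperture(beam_index, shape, 1.0))

    exact = True
    if max_apertures is not None and len(apertures) > max_apertures:
        ranked = sorted(range(len(apertures)),
                        key=lambda k: (-apertures[k].weight
                                       * apertures[k].open_area, k))
        keep = sorted(ranked[:max_apertures])
        apertures = [apertures[k] for k in keep]
        exact = False
    return SequencingResult(tuple(apertures), exact)


def aperture_dose_matrix(apertures, dij: DoseInfluenceMatrix,
                         voxel_indices: np.ndarray) -> sparse.csr_matrix:
    """One dose column per aperture over the given voxels.

    Column a = sum over the aperture's open bixels of the beam's d_ij
    columns — the linear map that turns weight optimisation back into
    a fluence problem.
    """
    cols = []
    for ap in apertures:
        block = dij.blocks[ap.beam_index].tocsr()[voxel_indices]
        open_j = ap.open_bixels(dij.grids[ap.beam_index].n_cols)
        sel = np.zeros(block.shape[1])
        sel[open_j] = 1.0
        cols.append(block @ sel)
    if not cols:
        return sparse.csr_matrix((voxel_indices.size, 0))
    return sparse.csr_matrix(np.stack(cols, axis=1))


def optimize_aperture_weights(apertures, dij: DoseInfluenceMatrix,
                              obj: PlanObjective,
                              cfg: OptimizerConfig | None = None,
                              init_weights: np.ndarray | None = None
                              ) -> tuple[np.ndarray, list[float]]:
    """Re-optimise aperture weights; never increases the objective.

    Starts from ``init_weights`` (default: the weights carried by the
    apertures) and runs projected L-BFGS over the nonnegative weight
    vector.
    """
    if not apertures:
        raise ValueError("no apertures to optimise")
    matrix = aperture_dose_matrix(apertures, dij, obj.voxel_indices)
    problem = MatrixProblem(matrix, obj)
    if init_weights is None:
        init_weights = np.array([ap.weight for ap in apertures], dtype=float)
    return optimize_fluence(problem, init_weights, cfg or OptimizerConfig())
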