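"""Quadratic dose-penalty objective and its gradient.

The plan objective is a sum of one-sided quadratic penalties over every
voxel of every structure that carries an objective:

    F(w) = sum_i a_i ( [d_i^min - d_i]_+^2 + [d_i - d_i^max]_+^2 ),
    d_i  = sum_j d_ij w_j,

where ``a_i`` is the structure's importance factor, ``[x]_+`` the
positive part, and the bounds are per-structure minimum (targets only)
and maximum doses in Gy.  F is convex in the fluence ``w`` (a squared
hinge composed with a linear map) and identically zero when every
objective voxel lies within its bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

from .dose import DoseInfluenceMatrix
from .geometry import VoxelPhantom


@dataclass(frozen=True)
class PlanObjective:
    """Per-objective-voxel importance and dose bounds.

    ``voxel_indices`` selects, in the flat phantom voxel space, the
    voxels belonging to structures with objectives; absent bounds are
    stored as -inf (minimum) / +inf (maximum) so their hinge vanishes.
    """

    voxel_indices: np.ndarray
    importance: np.ndarray
    d_min: np.ndarray
    d_max: np.ndarray
    structure_of: np.ndarray  # structure id per objective voxel

    def __post_init__(self) -> None:
        if np.any(self.importance < 0):
            raise ValueError("importance factors must be >= 0")

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.size)

    @classmethod
    def from_phantom(cls, phantom: VoxelPhantom,
                     overrides: dict[str, "float | None"] | None = None
                     ) -> "PlanObjective":
        """Collect objectives from the phantom's structure specs.

        ``overrides`` may remap importance factors by structure name
        (e.g. to re-weight a run without rebuilding the phantom).
        """
        idx_parts, a_parts, lo_parts, hi_parts, sid_parts = [], [], [], [], []
        for k, s in enumerate(phantom.structures):
            if s.objective is None:
                continue
            vox = np.flatnonzero(phantom.labels == k)
            if vox.size == 0:
                continue
            a = s.objective.importance
            if overrides and s.name in overrides:
                a = float(overrides[s.name])
            idx_parts.append(vox)
            a_parts.append(np.full(vox.size, a))
            lo = s.objective.d_min if s.objective.d_min is not None else -np.inf
            hi = s.objective.d_max if s.objective.d_max is not None else np.inf
            lo_parts.append(np.full(vox.size, lo))
            hi_parts.append(np.full(vox.size, hi))
            sid_parts.append(np.full(vox.size, k, dtype=np.int32))
        if not idx_parts:
            raise ValueError("phantom has no structures with objectives")
        return cls(np.concatenate(idx_parts), np.concatenate(a_parts),
                   np.concatenate(lo_parts), np.concatenate(hi_parts),
                   np.concatenate(sid_parts))


def compute_dose(dij: DoseInfluenceMatrix, w: np.ndarray,
                 active_beams: Sequence[int]) -> np.ndarray:
    """Total dose d = sum_j d_ij w_j over the active beams (all voxels)."""
    offsets = np.concatenate(
        [[0], np.cumsum([dij.grids[b].n_bixels for b in active_beams])])
    if w.shape[0] != offsets[-1]:
        raise ValueError("fluence vector length does not match the active "
                         "beams' bixel count")
    d = np.zeros(dij.n_voxels)
    for k, b in enumerate(active_beams):
        d += dij.blocks[b] @ w[offsets[k]:offsets[k + 1]]
    return d


def objective_value(d_obj: np.ndarray, obj: PlanObjective) -> float:
    """F for a dose vector given over the objective voxels."""
    under = np.maximum(obj.d_min - d_obj, 0.0)
    over = np.maximum(d_obj - obj.d_max, 0.0)
    return float(np.sum(obj.importance * (under ** 2 + over ** 2)))


def dose_residual(d_obj: np.ndarray, obj: PlanObjective) -> np.ndarray:
    """dF/dd per objective voxel: 2 a (-[dmin-d]_+ + [d-dmax]_+)."""
    under = np.maximum(obj.d_min - d_obj, 0.0)
    over = np.maximum(d_obj - obj.d_max, 0.0)
    return 2.0 * obj.importance * (over - under)


class FluenceProblem:
    """F and grad F as functions of a stacked fluence vector.

    Restricts the d_ij blocks of the active beams to the objective
    voxels once, then evaluates F(w) and its gradient with two sparse
    products per call.
    """

    def __init__(self, dij: DoseInfluenceMatrix, obj: PlanObjective,
                 active_beams: Sequence[int]):
        self.obj = obj
        self.active_beams = tuple(active_beams)
        cols = [dij.blocks[b].tocsr()[obj.voxel_indices]
                for b in self.active_beams]
        if cols:
            self.matrix = sparse.hstack(cols, format="csr")
            self.n_weights = self.matrix.shape[1]
        else:
            self.matrix = sparse.csr_matrix((obj.n_voxels, 0))
            self.n_weights = 0
        self.offsets = np.concatenate(
            [[0], np.cumsum([c.shape[1] for c in cols])]
        ) if cols else np.array([0])

    def dose(self, w: np.ndarray) -> np.ndarray:
        return self.matrix @ w

    def value(self, w: np.ndarray) -> float:
        return objective_value(self.dose(w), self.obj)

    def value_and_grad(self, w: np.ndarray) -> tuple[float, np.ndarray]:
        d = self.dose(w)
        under = np.maximum(self.obj.d_min - d, 0.0)
        over = np.maximum(d - self.obj.d_max, 0.0)
        f = float(np.sum(self.obj.importance * (under ** 2 + over ** 2)))
        resid = 2.0 * self.obj.importance * (over - under)
        return f, self.matrix.T @ resid


class MatrixProblem(FluenceProblem):
    """FluenceProblem over an explicit (possibly dense) dose matrix.

    Used for aperture-weight optimisation, where each column is the
    dose of one whole aperture, and in small synthetic tests.
    """

    def __init__(self, matrix, obj: PlanObjective):
        self.obj = obj
        self.active_beams = ()
        self.matrix = sparse.csr_matrix(matrix)
        self.n_weights = self.matrix.shape[1]
        self.offsets = np.array([0, self.n_weights])
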