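"""Projected L-BFGS minimisation of the fluence objective.

The update is ``w^{x+1} = [w^x - alpha p^x]_+`` where the clamp at zero
enforces nonnegative fluence and the direction ``p^x`` comes from the
limited-memory BFGS two-loop recursion, so no inverse Hessian is ever
formed.  The relaxation ``alpha`` is found by backtracking Armijo line
search on the projected point, which makes every accepted step a strict
descent step; with empty memory the first iteration is projected
steepest descent.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .dose import DoseInfluenceMatrix
from .geometry import VoxelPhantom


@dataclass(frozen=True)
class OptimizerConfig:
    """Projected L-BFGS settings.

    ``iterations`` follows the planning workflow: 40 for standalone
    reference plans, 20 inside beam-orientation selection.
    """

    iterations: int = 40
    memory: int = 10
    armijo_c: float = 1e-4
    max_backtracks: int = 40
    curvature_eps: float = 1e-12
    rel_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.memory < 1:
            raise ValueError("iterations and memory must be >= 1")


def _two_loop(g: np.ndarray, mem: deque,
              free: np.ndarray | None = None) -> np.ndarray:
    """L-BFGS two-loop recursion: approximate (inverse Hessian) @ g.

    With a ``free`` mask the recursion acts on the free variables only
    while bound-active coordinates fall back to the raw gradient
    (two-metric projection) — plain projection of a quasi-Newton
    direction can stall on the active set.
    """
    q = g.copy()
    if free is not None:
        q[~free] = 0.0
    alphas = []
    for s, y, rho in reversed(mem):
        a = rho * np.dot(s, q)
        alphas.append(a)
        q -= a * y
    if mem:
        s, y, _ = mem[-1]
        q *= np.dot(s, y) / np.dot(y, y)
    for (s, y, rho), a in zip(mem, reversed(alphas)):
        b = rho * np.dot(y, q)
        q += (a - b) * s
    if free is not None:
        q[~free] = g[~free]
    return q


def optimize_fluence(problem, w0: np.ndarray,
                     cfg: OptimizerConfig | None = None
                     ) -> tuple[np.ndarray, list[float]]:
    """Minimise problem.value_and_grad over w >= 0 from w0.

    Returns the final iterate and the objective trace (one entry per
    accepted iterate, starting at F(w0)); the trace is non-increasing.
    Stops early when the relative objective change falls below
    ``cfg.rel_tol`` or no descent step can be found.
    """
    cfg = cfg or OptimizerConfig()
    w = np.maximum(np.asarray(w0, dtype=float), 0.0)
    f, g = problem.value_and_grad(w)
    if not np.isfinite(f) or not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite objective or gradient at w0")
    trace = [f]
    mem: deque = deque(maxlen=cfg.memory)
    n_small = 0

    for _ in range(cfg.iterations):
        if f == 0.0:
            break
        free = (w > 1e-12) | (g < 0)
        accepted = False
        for direction in ("lbfgs", "steepest"):
            p = _two_loop(g, mem, free) if direction == "lbfgs" and mem \
                else g
            alpha = 1.0
            for _bt in range(cfg.max_backtracks):
                w_new = np.maximum(w - alpha * p, 0.0)
                decrease = np.dot(g, w - w_new)
                if decrease > 0.0:
                    f_new = problem.value(w_new)
                    if not np.isfinite(f_new):
                        raise FloatingPointError("non-finite objective")
                    if f_new <= f - cfg.armijo_c * decrease:
                        accepted = True
                        break
                alpha *= 0.5
            if accepted:
                break
        if not accepted:
            break

        _, g_new = problem.value_and_grad(w_new)
        s = w_new - w
        y = g_new - g
        sy = float(np.dot(s, y))
        if sy > cfg.curvature_eps:   # keep only positive-curvature pairs
            mem.append((s, y, 1.0 / sy))
        rel_change = (f - f_new) / max(f, 1e-300)
        w, f, g = w_new, f_new, g_new
        trace.append(f)
        # stop only after sustained stagnation: a single slow iteration
        # near an active-set change is not convergence
        n_small = n_small + 1 if rel_change < cfg.rel_tol else 0
        if n_small >= 3:
            break
    return w, trace


def initial_fluence(dij: DoseInfluenceMatrix, phantom: VoxelPhantom,
                    active_beams, prescription_gy: float,
                    mode: str = "uniform") -> np.ndarray:
    """Starting fluence for the active beams.

    ``uniform`` gives every bixel the same weight, scaled so the mean
    PTV dose equals the prescription; ``zeros`` gives an all-zero
    vector.  An empty beam set yields an empty vector.
    """
    active_beams = list(active_beams)
    n = int(sum(dij.grids[b].n_bixels for b in active_beams))
    if mode == "zeros" or n == 0:
        return np.zeros(n)
    if mode != "uniform":
        raise ValueError(f"unknown initial-fluence mode {mode!r}")
    w = np.ones(n)
    ptv = phantom.structure_voxels("ptv")
    d_ptv = np.zeros(ptv.size)
    off = 0
    for b in active_beams:
        nb = dij.grids[b].n_bixels
        d_ptv += dij.blocks[b].tocsr()[ptv] @ w[off:off + nb]
        off += nb
    mean = float(d_ptv.mean())
    if mean <= 0:
        return w
    return w * (prescription_gy / mean)
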