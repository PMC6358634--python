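"""The inner planning pipeline: fluence optimisation, sequencing, DAO.

This is the evaluation every candidate beam set receives — both the
reference plans on fixed node sets (40 fluence + 40 aperture
iterations) and each individual inside beam-orientation selection
(20 + 20 by default, fewer at reduced scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dose import DoseInfluenceMatrix, BIXEL_DU_MM, BIXEL_DV_MM
from .fluence import OptimizerConfig, initial_fluence, optimize_fluence
from .geometry import VoxelPhantom
from .objective import FluenceProblem, PlanObjective, objective_value
from .sequencing import (Aperture, aperture_dose_matrix,
                         optimize_aperture_weights, quantize_fluence,
                         sweep_sequence)


@dataclass(frozen=True)
class PlanConfig:
    """Knobs of the inner pipeline.

    ``max_apertures_per_beam`` follows clinical intricacy (5 by default
    for selected-orientation plans); ``levels`` defaults to
    max_apertures + 2, giving the sweep room before capping.
    """

    fluence_iterations: int = 40
    dao_iterations: int = 40
    max_apertures_per_beam: int = 5
    levels: int | None = None
    prescription_gy: float = 20.0
    prune_rel_weight: float = 1e-6
    initial_mode: str = "uniform"

    @property
    def n_levels(self) -> int:
        return self.levels if self.levels is not None \
            else self.max_apertures_per_beam + 2


@dataclass
class Plan:
    """A fully evaluated treatment plan for one beam subset."""

    beam_indices: tuple[int, ...]
    apertures: tuple[Aperture, ...]       # weights in fluence units
    dose: np.ndarray                      # Gy per phantom voxel
    objective_value: float
    fluence_trace: list[float] = field(default_factory=list)
    dao_trace: list[float] = field(default_factory=list)
    sequencing_exact: bool = True
    metrics: dict = field(default_factory=dict)

    @property
    def n_apertures(self) -> int:
        return len(self.apertures)

    @property
    def nodes_used(self) -> tuple[int, ...]:
        return tuple(sorted({ap.beam_index for ap in self.apertures}))

    def total_weight(self) -> float:
        return float(sum(ap.weight for ap in self.apertures))


def optimize_plan(dij: DoseInfluenceMatrix, obj: PlanObjective,
                  phantom: VoxelPhantom, beam_indices,
                  cfg: PlanConfig | None = None) -> Plan:
    """Run fluence optimisation, sweep sequencing and DAO for a beam set.

    Duplicate beam indices collapse to the unique set.  Returns the
    deliverable plan with its full-phantom dose and final objective.
    """
    cfg = cfg or PlanConfig()
    beams = sorted(set(int(b) for b in beam_indices))
    if not beams:
        d = np.zeros(dij.n_voxels)
        f = objective_value(d[obj.voxel_indices], obj)
        return Plan((), (), d, f)

    w0 = initial_fluence(dij, phantom, beams, cfg.prescription_gy,
                         mode=cfg.initial_mode)
    problem = FluenceProblem(dij, obj, beams)
    opt_cfg = OptimizerConfig(iterations=cfg.fluence_iterations)
    w_star, ftrace = optimize_fluence(problem, w0, opt_cfg)

    apertures: list[Aperture] = []
    init_weights: list[float] = []
    exact = True
    for k, b in enumerate(beams):
        g = dij.grids[b]
        fmap = w_star[problem.offsets[k]:problem.offsets[k + 1]].reshape(
            g.n_rows, g.n_cols)
        vmax = float(fmap.max())
        if vmax <= 0:
            continue
        intmap = quantize_fluence(fmap, cfg.n_levels)
        seq = sweep_sequence(intmap, cfg.max_apertures_per_beam,
                             beam_index=b)
        exact = exact and seq.exact
        unit = vmax / cfg.n_levels  # fluence weight of one level
        for ap in seq.apertures:
            apertures.append(ap)
            init_weights.append(ap.weight * unit)

    if not apertures:
        d = np.zeros(dij.n_voxels)
        f = objective_value(d[obj.voxel_indices], obj)
        return Plan(tuple(beams), (), d, f, ftrace, [], exact)

    dao_cfg = OptimizerConfig(iterations=cfg.dao_iterations)
    weights, dtrace = optimize_aperture_weights(
        apertures, dij, obj, dao_cfg, np.asarray(init_weights))

    # prune numerically irrelevant apertures
    wmax = float(weights.max())
    final = tuple(Aperture(ap.beam_index, ap.rows, float(wt))
                  for ap, wt in zip(apertures, weights)
                  if wmax > 0 and wt >= cfg.prune_rel_weight * wmax)

    d = np.zeros(dij.n_voxels)
    for ap in final:
        g = dij.grids[ap.beam_index]
        sel = np.zeros(g.n_bixels)
        sel[ap.open_bixels(g.n_cols)] = ap.weight
        d += dij.blocks[ap.beam_index] @ sel
    f = objective_value(d[obj.voxel_indices], obj)
    return Plan(tuple(beams), final, d, f, ftrace, dtrace, exact)


def plan_to_dict(plan: Plan, dij: DoseInfluenceMatrix,
                 mu_per_weight: float = 1.0) -> dict:
    """JSON-serialisable plan export: nodes, apertures, weights, MU."""
    aps = []
    for ap in plan.apertures:
        g = dij.grids[ap.beam_index]
        u0, v0 = g.origin_uv
        rows = []
        for r, lr in enumerate(ap.rows):
            if lr is None:
                rows.append(None)
                continue
            left_mm = u0 + (lr[0] - 0.5) * BIXEL_DU_MM
            right_mm = u0 + (lr[1] - 0.5) * BIXEL_DU_MM
            rows.append({"row": r, "v_mm": v0 + r * BIXEL_DV_MM,
                         "left_bixel": lr[0], "right_bixel": lr[1],
                         "left_mm": left_mm, "right_mm": right_mm})
        aps.append({"beam": ap.beam_index, "weight": ap.weight,
                    "mu": ap.weight * mu_per_weight, "rows": rows})
    return {
        "beam_indices": list(plan.beam_indices),
        "nodes_used": list(plan.nodes_used),
        "objective_value": plan.objective_value,
        "sequencing_exact": plan.sequencing_exact,
        "total_mu": plan.total_weight() * mu_per_weight,
        "apertures": aps,
        "metrics": plan.metrics,
    }


def save_plan(path, plan: Plan, dij: DoseInfluenceMatrix,
              mu_per_weight: float = 1.0) -> None:
    with open(path, "w") as fh:
        json.dump(plan_to_dict(plan, dij, mu_per_weight), fh, indent=1)
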