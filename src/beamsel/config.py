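"""Run configuration: one YAML file describes a whole planning run.

Validation is strict — unknown keys are rejected with the offending key
named — so a manifest written by a run reproduces it exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .dose import KernelParams
from .geometry import (NodeGeometry, Objective, StructureSpec, VoxelGrid,
                       build_phantom, default_phantom)
from .metrics import TimeModelParams
from .planning import PlanConfig
from .selection import EAConfig


@dataclass(frozen=True)
class NodesConfig:
    n: int = 110
    file: str | None = None
    geometry: NodeGeometry = field(default_factory=NodeGeometry)
    subset: int | None = None


@dataclass(frozen=True)
class PhantomConfig:
    spacing_mm: float = 5.0
    structures: tuple[StructureSpec, ...] | None = None  # None = default
    grid: VoxelGrid | None = None


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    nodes: NodesConfig = field(default_factory=NodesConfig)
    kernel: KernelParams = field(default_factory=KernelParams)
    plan: PlanConfig = field(default_factory=PlanConfig)
    ea: EAConfig = field(default_factory=EAConfig)
    time_model: TimeModelParams = field(default_factory=TimeModelParams)
    prescription_gy: float = 20.0
    importance_overrides: dict = field(default_factory=dict)
    seed: int = 0
    source_hash: str | None = None

    def build_phantom(self):
        if self.phantom.structures is None:
            return default_phantom(self.phantom.spacing_mm)
        return build_phantom(self.phantom.grid, list(self.phantom.structures))


def _from_mapping(cls, data: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {context}")
    return cls(**data)


def _parse_structures(items: list, context: str):
    structs = []
    for it in items:
        it = dict(it)
        obj = it.pop("objective", None)
        if obj is not None:
            obj = dict(obj)
            if "a_i" in obj:
                obj["importance"] = obj.pop("a_i")
            if obj.get("importance", 0) < 0:
                raise ValueError(
                    f"negative importance factor a_i in {context} "
                    f"structure {it.get('name')!r}")
            obj = _from_mapping(Objective, obj, f"{context}.objective")
        structs.append(_from_mapping(
            StructureSpec, {**it, "objective": obj},
            f"{context}.{it.get('name')}"))
    return tuple(structs)


_TOP_KEYS = {"phantom", "nodes", "kernel", "plan", "ea", "time_model",
             "prescription_gy", "importance_overrides", "seed"}


def config_from_dict(data: dict) -> RunConfig:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level key(s) {sorted(unknown)}")
    kw: dict = {}
    if "phantom" in data:
        ph = dict(data["phantom"])
        if "structures" in ph:
            grid = ph.pop("grid", None)
            if grid is None:
                raise ValueError("phantom.structures requires phantom.grid")
            ph["grid"] = _from_mapping(
                VoxelGrid,
                {k: tuple(v) for k, v in grid.items()}, "phantom.grid")
            ph["structures"] = _parse_structures(ph["structures"],
                                                 "phantom.structures")
        kw["phantom"] = _from_mapping(PhantomConfig, ph, "phantom")
    if "nodes" in data:
        nd = dict(data["nodes"])
        if "geometry" in nd:
            geo = dict(nd["geometry"])
            for key in ("cap_axis", "exclusion_axis"):
                if key in geo:
                    geo[key] = tuple(geo[key])
            nd["geometry"] = _from_mapping(NodeGeometry, geo,
                                           "nodes.geometry")
        kw["nodes"] = _from_mapping(NodesConfig, nd, "nodes")
    for key, cls in (("kernel", KernelParams), ("plan", PlanConfig),
                     ("ea", EAConfig), ("time_model", TimeModelParams)):
        if key in data:
            kw[key] = _from_mapping(cls, dict(data[key]), key)
    for key in ("prescription_gy", "seed"):
        if key in data:
            kw[key] = data[key]
    if "importance_overrides" in data:
        ov = dict(data["importance_overrides"])
        for name, a in ov.items():
            if a is not None and a < 0:
                raise ValueError(f"negative importance factor a_i for "
                                 f"{name!r} in importance_overrides")
        kw["importance_overrides"] = ov
    return RunConfig(**kw)


def config_to_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d.pop("source_hash", None)
    ph = d["phantom"]
    if ph["structures"] is None:
        ph.pop("structures")
        ph.pop("grid")
    else:
        for s in ph["structures"]:
            if s["objective"] is not None:
                s["objective"] = {k: v for k, v in s["objective"].items()
                                  if v is not None}
            else:
                del s["objective"]
    return d


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Records a content hash of the file so any output manifest can name
    the exact configuration it came from.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    cfg = config_from_dict(data)
    digest = hashlib.sha256(text.encode()).hexdigest()[:16]
    object.__setattr__(cfg, "source_hash", digest)
    return cfg


def save_config(path, cfg: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg),
                                         sort_keys=False))
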