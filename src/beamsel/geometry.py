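"""Synthetic voxel phantoms and candidate beam-node sets.

Coordinate convention (used everywhere in this package): right-handed
patient-centred frame in millimetres — +x patient left, +y anterior,
+z superior.  Voxel indices are 0-based and a voxel's position is the
position of its centre.

A phantom is a voxel grid in which every voxel carries exactly one
structure label.  Overlap between analytic solids is resolved by
priority: the lowest priority number wins, so a voxel inside both the
planning target volume (PTV) and an organ at risk is labelled PTV.
Voxels outside the body are labelled air and excluded from every
objective.

Candidate source positions ("nodes") sit on a sphere of radius SAD
(source–axis distance, 800 mm for the robotic delivery system modelled
here) around the aim point, placed by a deterministic Fibonacci spiral
over a polar cap, with a posterior exclusion cone standing in for the
treatment couch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

AIR_LABEL = -1
DEFAULT_SAD_MM = 800.0
_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice: shape (nx, ny, nz), spacing and origin in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacings must be positive")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape entries must be >= 1")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centres(self) -> np.ndarray:
        """(N, 3) array of voxel-centre positions in mm, C-order flat index."""
        ax = [self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
              for k in range(3)]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


@dataclass(frozen=True)
class Objective:
    """Per-structure planning objective: importance and dose bounds in Gy."""

    importance: float
    d_min: float | None = None
    d_max: float | None = None

    def __post_init__(self) -> None:
        if self.importance < 0:
            raise ValueError("importance factor a_i must be >= 0")
        if self.d_min is None and self.d_max is None:
            raise ValueError("objective needs at least one dose bound")


@dataclass(frozen=True)
class StructureSpec:
    """Analytic solid with a priority; lower priority number wins overlap.

    ``shape`` is one of ``sphere``, ``cylinder``, ``box``, ``annulus``.
    Geometry parameters (mm):

    - sphere:   center, radius
    - cylinder: center, radius, height (axis along +z)
    - box:      center, size (full edge lengths)
    - annulus:  ref (name of an existing structure), width, offset
                (shell of voxels whose distance from the reference solid
                lies in (offset, offset + width])
    """

    name: str
    priority: int
    shape: str
    params: dict
    objective: Objective | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "cylinder", "box", "annulus"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "annulus" and self.params.get("width", 0.0) <= 0:
            raise ValueError("annulus width must be > 0")


def _solid_mask(spec: StructureSpec, centres: np.ndarray) -> np.ndarray:
    p = spec.params
    c = np.asarray(p["center"], dtype=float)
    if spec.shape == "sphere":
        return np.sum((centres - c) ** 2, axis=1) <= float(p["radius"]) ** 2
    if spec.shape == "cylinder":
        r2 = np.sum((centres[:, :2] - c[:2]) ** 2, axis=1)
        half_h = float(p["height"]) / 2.0
        return (r2 <= float(p["radius"]) ** 2) & (
            np.abs(centres[:, 2] - c[2]) <= half_h)
    if spec.shape == "box":
        half = np.asarray(p["size"], dtype=float) / 2.0
        return np.all(np.abs(centres - c) <= half, axis=1)
    raise ValueError(spec.shape)


@dataclass(frozen=True)
class VoxelPhantom:
    """Priority-resolved labelled voxel geometry plus the aim point."""

    grid: VoxelGrid
    labels: np.ndarray  # flat int array, index into structures; AIR_LABEL = air
    structures: tuple[StructureSpec, ...]
    target_point: tuple[float, float, float]

    def structure_index(self, name: str) -> int:
        for k, s in enumerate(self.structures):
            if s.name == name:
                return k
        raise KeyError(f"no structure named {name!r}")

    def structure_voxels(self, name: str) -> np.ndarray:
        """Flat voxel indices labelled with the named structure."""
        return np.flatnonzero(self.labels == self.structure_index(name))

    @property
    def in_body(self) -> np.ndarray:
        """Boolean flat mask of voxels inside the body (any non-air label)."""
        return self.labels != AIR_LABEL

    @property
    def ptv_name(self) -> str:
        return "ptv"


def build_phantom(grid: VoxelGrid,
                  structures: list[StructureSpec]) -> VoxelPhantom:
    """Voxelise analytic structures and resolve overlap by priority.

    Requires a structure named ``body`` (outermost, lowest clinical
    priority by convention) and one named ``ptv``.  Annuli are clipped to
    the body; voxels outside the body are labelled air.  A voxel belongs
    to a solid iff its centre is inside (centre-inclusion voxelisation).
    """
    names = [s.name for s in structures]
    if "body" not in names or "ptv" not in names:
        raise ValueError("phantom needs structures named 'body' and 'ptv'")
    priorities = [s.priority for s in structures]
    if len(set(priorities)) != len(priorities):
        raise ValueError("structure priorities must be unique")

    centres = grid.voxel_centres()
    masks: dict[str, np.ndarray] = {}
    # Non-annuli first: annuli measure distance from an already-built solid.
    for s in structures:
        if s.shape != "annulus":
            masks[s.name] = _solid_mask(s, centres)
    spacing = np.asarray(grid.spacing)
    for s in structures:
        if s.shape != "annulus":
            continue
        ref = s.params["ref"]
        if ref not in masks:
            raise ValueError(f"annulus {s.name!r} references unknown or "
                             f"annular structure {ref!r}")
        ref_grid = masks[ref].reshape(grid.shape)
        if not ref_grid.any():
            raise ValueError(f"annulus reference {ref!r} is empty")
        # Euclidean distance (mm) from the reference solid, on the lattice.
        dist = ndimage.distance_transform_edt(~ref_grid, sampling=spacing)
        offset = float(s.params.get("offset", 0.0))
        width = float(s.params["width"])
        masks[s.name] = ((dist.ravel() > offset)
                         & (dist.ravel() <= offset + width))

    body = masks["body"]
    if not masks["ptv"].any():
        raise ValueError("PTV contains no voxels at this grid resolution")
    if not np.all(body[masks["ptv"]]):
        raise ValueError("PTV extends outside the body")

    labels = np.full(grid.n_voxels, AIR_LABEL, dtype=np.int32)
    order = sorted(range(len(structures)),
                   key=lambda k: structures[k].priority, reverse=True)
    for k in order:  # paint lowest priority first; higher overwrites
        m = masks[structures[k].name] & body
        labels[m] = k

    ptv_centres = centres[masks["ptv"] & body]
    target = tuple(float(v) for v in ptv_centres.mean(axis=0))
    return VoxelPhantom(grid=grid, labels=labels,
                        structures=tuple(structures), target_point=target)


def default_phantom(spacing_mm: float = 5.0) -> VoxelPhantom:
    """The package's reference phantom.

    Cylindrical body (radius 120 mm, height 200 mm), spherical PTV of
    radius 25 mm offset from the axis, a cylindrical organ at risk
    abutting the PTV, and three concentric 10 mm annular shells A1–A3
    around the PTV that grade the dose fall-off.  Objectives are chosen
    so the target bounds are attainable with a modest number of beams.
    """
    half = 125.0
    n_xy = int(round(2 * half / spacing_mm)) + 1
    n_z = int(round(2 * 100.0 / spacing_mm)) + 1
    grid = VoxelGrid(shape=(n_xy, n_xy, n_z),
                     spacing=(spacing_mm,) * 3,
                     origin=(-half, -half, -100.0))
    rx = 20.0  # prescription, Gy
    structures = [
        StructureSpec("body", 10, "cylinder",
                      {"center": (0, 0, 0), "radius": 120.0, "height": 200.0},
                      Objective(1.0, d_max=0.40 * rx)),
        StructureSpec("ptv", 1, "sphere",
                      {"center": (50.0, 0.0, 0.0), "radius": 25.0},
                      Objective(100.0, d_min=rx, d_max=1.10 * rx)),
        StructureSpec("oar", 2, "cylinder",
                      {"center": (90.0, 0.0, 0.0), "radius": 15.0,
                       "height": 80.0},
                      Objective(5.0, d_max=0.60 * rx)),
        StructureSpec("a1", 3, "annulus",
                      {"ref": "ptv", "width": 10.0, "offset": 0.0},
                      Objective(1.0, d_max=1.00 * rx)),
        StructureSpec("a2", 4, "annulus",
                      {"ref": "ptv", "width": 10.0, "offset": 10.0},
                      Objective(1.0, d_max=0.75 * rx)),
        StructureSpec("a3", 5, "annulus",
                      {"ref": "ptv", "width": 10.0, "offset": 20.0},
                      Objective(1.0, d_max=0.50 * rx)),
    ]
    return build_phantom(grid, structures)


DEFAULT_PRESCRIPTION_GY = 20.0


# ---------------------------------------------------------------------------
# Beam nodes


@dataclass(frozen=True)
class BeamNode:
    index: int
    source: tuple[float, float, float]
    direction: tuple[float, float, float]  # unit, source -> target


@dataclass(frozen=True)
class NodeSet:
    nodes: tuple[BeamNode, ...]
    name: str = "nodes"

    def __len__(self) -> int:
        return len(self.nodes)

    def sources(self) -> np.ndarray:
        return np.array([n.source for n in self.nodes])

    def directions(self) -> np.ndarray:
        return np.array([n.direction for n in self.nodes])


@dataclass(frozen=True)
class NodeGeometry:
    """Placement rule for candidate nodes.

    Nodes are spread over a polar cap (apex along ``cap_axis``, anterior
    by default) of half-angle ``cap_angle_deg`` on the SAD sphere; any
    direction within ``exclusion_half_angle_deg`` of ``exclusion_axis``
    (posterior — the couch) is removed.
    """

    sad_mm: float = DEFAULT_SAD_MM
    cap_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    cap_angle_deg: float = 110.0
    exclusion_axis: tuple[float, float, float] = (0.0, -1.0, 0.0)
    exclusion_half_angle_deg: float = 30.0
    min_separation_deg: float = 5.0


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to the given unit axis (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    axis = axis / np.linalg.norm(axis)
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _spiral_directions(m: int, cos_cap: float, phi0: float) -> np.ndarray:
    if m == 1:  # degenerate spiral: the cap apex
        return np.array([[0.0, 0.0, 1.0]])
    i = np.arange(m)
    u = (i + 0.5) / m
    cos_t = 1.0 - u * (1.0 - cos_cap)
    sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, None))
    phi = phi0 + i * _GOLDEN_ANGLE
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)


def generate_nodeset(n: int,
                     target_point: tuple[float, float, float],
                     geometry: NodeGeometry | None = None,
                     seed: int = 0,
                     name: str = "generated") -> NodeSet:
    """Place ``n`` nodes on the SAD sphere by a Fibonacci cap spiral.

    Deterministic for a given (n, geometry, seed); the seed only rotates
    the spiral's starting azimuth.  Raises if the cap cannot hold ``n``
    nodes at the configured minimum separation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    geo = geometry or NodeGeometry()
    rng = np.random.default_rng(seed)
    phi0 = float(rng.uniform(0.0, 2.0 * math.pi))
    cos_cap = math.cos(math.radians(geo.cap_angle_deg))
    rot = _rotation_to(np.asarray(geo.cap_axis, dtype=float))
    excl = np.asarray(geo.exclusion_axis, dtype=float)
    excl = excl / np.linalg.norm(excl)
    cos_excl = math.cos(math.radians(geo.exclusion_half_angle_deg))

    dirs = None
    for m in (n, int(1.5 * n) + 1, 2 * n, 4 * n):
        cand = _spiral_directions(m, cos_cap, phi0) @ rot.T
        keep = cand @ excl < cos_excl  # outside the couch cone
        if int(keep.sum()) >= n:
            dirs = cand[keep][:n]
            break
    if dirs is None:
        raise ValueError("exclusion cone leaves too few directions "
                         f"for n={n}")

    dots = np.clip(dirs @ dirs.T, -1.0, 1.0)
    np.fill_diagonal(dots, -1.0)
    min_sep = math.degrees(math.acos(float(dots.max())))
    if min_sep < geo.min_separation_deg - 1e-9:
        raise ValueError(
            f"n={n} violates the minimum node separation "
            f"({min_sep:.2f} deg < {geo.min_separation_deg} deg)")

    t = np.asarray(target_point, dtype=float)
    nodes = []
    for k, d in enumerate(dirs):
        src = t + geo.sad_mm * d
        beam_dir = -d
        nodes.append(BeamNode(k, tuple(src), tuple(beam_dir)))
    return NodeSet(tuple(nodes), name=name)


def subset_nodeset(full: NodeSet, n: int, name: str | None = None) -> NodeSet:
    """Evenly-spread subset by greedy farthest-point sampling.

    Seeded with the globally maximal-separation pair, then repeatedly
    adds the node farthest (in angle) from the current selection.
    Deterministic; ties broken toward the lower index.
    """
    if n > len(full):
        raise ValueError("cannot subset to more nodes than available")
    if n == len(full):
        return replace(full, name=name or f"{full.name}-subset{n}")
    dirs = full.directions()
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    ang = np.arccos(np.clip(dirs @ dirs.T, -1.0, 1.0))
    if n == 1:
        chosen = [0]
    else:
        i, j = np.unravel_index(int(np.argmax(ang)), ang.shape)
        chosen = sorted((int(i), int(j)))
        while len(chosen) < n:
            d_min = ang[:, chosen].min(axis=1)
            d_min[chosen] = -1.0
            chosen.append(int(np.argmax(d_min)))
    chosen = sorted(chosen)
    nodes = [replace(full.nodes[c], index=k) for k, c in enumerate(chosen)]
    return NodeSet(tuple(nodes), name=name or f"{full.name}-subset{n}")


def write_nodeset(path, nodeset: NodeSet) -> None:
    """Tab-separated node table: index, x, y, z (mm)."""
    with open(path, "w") as fh:
        fh.write(f"# nodeset {nodeset.name}: index\tx_mm\ty_mm\tz_mm\n")
        for nd in nodeset.nodes:
            x, y, z = nd.source
            fh.write(f"{nd.index}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_nodeset(path, target_point: tuple[float, float, float],
                 name: str = "loaded") -> NodeSet:
    """Read a tab-separated node table; directions aim at target_point."""
    t = np.asarray(target_point, dtype=float)
    nodes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx, x, y, z = line.split("\t")
            src = np.array([float(x), float(y), float(z)])
            d = t - src
            d = d / np.linalg.norm(d)
            nodes.append(BeamNode(int(idx), tuple(src), tuple(d)))
    nodes.sort(key=lambda nd: nd.index)
    if [nd.index for nd in nodes] != list(range(len(nodes))):
        raise ValueError("node indices must be unique and contiguous from 0")
    return NodeSet(tuple(nodes), name=name)
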