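"""Per-beam fluence grids and the sparse dose-influence matrix.

The dose model is linear: ``d_i = sum_j d_ij w_j`` where ``w_j`` is the
weight of fluence element (bixel) ``j`` and ``d_ij`` is the dose to
voxel ``i`` per unit weight of that bixel.  ``d_ij`` is computed with a
simple analytic pencil-beam kernel — inverse square, exponential depth
attenuation and a Gaussian lateral penumbra widening with depth:

    d(r, depth, l) = C * (SAD/r)^2 * exp(-mu*(depth - z_ref))
                       * exp(-l^2 / (2*sigma(depth)^2)),
    sigma(depth) = sigma0 + k*depth

with ``r`` the distance from the source, ``depth`` the path length
inside the body along the bixel ray, and ``l`` the perpendicular
distance from the ray.  The defaults are qualitatively water-like for a
6 MV beam; they are a documented stand-in, not a clinical dose engine.

Entries below 0.015% of each bixel column's maximum are dropped, so
every stored column keeps essentially all of its scattered dose while
the matrix stays sparse.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import sparse

from .geometry import BeamNode, NodeSet, VoxelPhantom

#: MLC of the modelled delivery system: 26 leaf pairs of 3.85 mm width,
#: maximum field 115 mm x 100 mm at the 800 mm source-axis distance.
N_LEAF_PAIRS = 26
LEAF_WIDTH_MM = 3.85
MAX_FIELD_U_MM = 115.0   # leaf-travel direction
MAX_FIELD_V_MM = 100.0   # leaf-stacking direction

#: Fluence bixel: 2 leaf widths across the leaves by 5 mm along them.
BIXEL_DV_MM = 2 * LEAF_WIDTH_MM
BIXEL_DU_MM = 5.0
MAX_ROWS = N_LEAF_PAIRS // 2            # one grid row drives 2 leaf pairs
MAX_COLS = int(MAX_FIELD_U_MM // BIXEL_DU_MM)

DIJ_THRESHOLD = 1.5e-4  # 0.015% of each column's maximum


@dataclass(frozen=True)
class KernelParams:
    """Pencil-kernel parameters (all configurable; defaults water-like)."""

    mu_per_mm: float = 0.005          # effective linear attenuation
    sigma0_mm: float = 2.0            # penumbra sigma at the surface
    sigma_growth: float = 0.02        # d sigma / d depth (dimensionless)
    calibration_gy: float = 0.01      # Gy per weight unit at reference
    reference_depth_mm: float = 15.0  # depth of the calibration point

    def __post_init__(self) -> None:
        if self.mu_per_mm <= 0 or self.sigma0_mm <= 0 or self.sigma_growth < 0:
            raise ValueError("kernel requires mu > 0, sigma0 > 0, k >= 0")

    def sigma(self, depth_mm: np.ndarray) -> np.ndarray:
        return self.sigma0_mm + self.sigma_growth * np.asarray(depth_mm)


@dataclass(frozen=True)
class FluenceGrid:
    """Bixel lattice in the beam's eye view (BEV), at isocentre distance.

    ``origin_uv`` is the (u, v) of the centre of bixel (row 0, col 0);
    columns advance along ``e_u`` (leaf travel), rows along ``e_v``
    (leaf stacking).  All BEV coordinates are mm in the plane through
    the target point perpendicular to the beam axis.
    """

    beam_index: int
    n_rows: int
    n_cols: int
    origin_uv: tuple[float, float]
    source: tuple[float, float, float]
    axis: tuple[float, float, float]       # unit, source -> target
    e_u: tuple[float, float, float]
    e_v: tuple[float, float, float]
    sad_mm: float

    @property
    def n_bixels(self) -> int:
        return self.n_rows * self.n_cols

    def bixel_centres_uv(self) -> np.ndarray:
        """(n_bixels, 2) of (u, v) centres; bixel j = row*n_cols + col."""
        u0, v0 = self.origin_uv
        cols = u0 + BIXEL_DU_MM * np.arange(self.n_cols)
        rows = v0 + BIXEL_DV_MM * np.arange(self.n_rows)
        vv, uu = np.meshgrid(rows, cols, indexing="ij")
        return np.stack([uu.ravel(), vv.ravel()], axis=1)


def _bev_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal BEV frame; leaf stacking (e_v) as superior as possible."""
    z = np.array([0.0, 0.0, 1.0])
    ev = z - np.dot(z, axis) * axis
    if np.linalg.norm(ev) < 1e-9:          # beam along z: stack along +y
        ev = np.array([0.0, 1.0, 0.0]) - np.dot([0, 1, 0], axis) * axis
    ev = ev / np.linalg.norm(ev)
    eu = np.cross(ev, axis)
    return eu, ev


def fluence_grid_for_beam(beam: BeamNode, phantom: VoxelPhantom,
                          margin_mm: float = 5.0,
                          sad_mm: float | None = None) -> FluenceGrid:
    """Bixel grid covering the PTV's beam's-eye-view plus a margin.

    The grid bounds are the axis-aligned BEV bounding box of the
    projected PTV voxel centres, expanded by ``margin_mm`` and snapped
    outward to whole bixels, clipped to the MLC's maximum field.
    """
    src = np.asarray(beam.source)
    axis = np.asarray(beam.direction)
    if sad_mm is None:
        sad_mm = float(np.linalg.norm(
            np.asarray(phantom.target_point) - src))
    eu, ev = _bev_basis(axis)

    ptv_idx = phantom.structure_voxels("ptv")
    if ptv_idx.size == 0:
        raise ValueError("phantom PTV is empty")
    pts = phantom.grid.voxel_centres()[ptv_idx] - src
    t = pts @ axis
    u = (pts @ eu) * sad_mm / t
    v = (pts @ ev) * sad_mm / t

    spans = []
    for lo, hi, pitch in ((u.min() - margin_mm, u.max() + margin_mm,
                           BIXEL_DU_MM),
                          (v.min() - margin_mm, v.max() + margin_mm,
                           BIXEL_DV_MM)):
        n = max(1, int(np.ceil((hi - lo) / pitch - 1e-9)))
        centre = 0.5 * (lo + hi)
        spans.append((n, centre))
    (n_cols, cu), (n_rows, cv) = spans
    if u.max() - u.min() < 1e-9 and v.max() - v.min() < 1e-9:
        warnings.warn("PTV projects to a point in this BEV; "
                      "using a single-bixel grid", stacklevel=2)
    if n_cols > MAX_COLS or n_rows > MAX_ROWS:
        warnings.warn("PTV projection exceeds the MLC maximum field; "
                      "grid clipped", stacklevel=2)
        n_cols = min(n_cols, MAX_COLS)
        n_rows = min(n_rows, MAX_ROWS)
    u0 = cu - (n_cols - 1) * BIXEL_DU_MM / 2.0
    v0 = cv - (n_rows - 1) * BIXEL_DV_MM / 2.0
    return FluenceGrid(beam.index, n_rows, n_cols, (float(u0), float(v0)),
                       tuple(src), tuple(axis),
                       tuple(eu), tuple(ev), float(sad_mm))


def _body_depth_profile(src: np.ndarray, ray: np.ndarray,
                        in_body_grid: np.ndarray,
                        phantom: VoxelPhantom,
                        t_lo: float, t_hi: float,
                        step: float) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative in-body path length along a ray, by uniform marching."""
    ts = np.arange(t_lo, t_hi + step, step)
    pts = src[None, :] + ts[:, None] * ray[None, :]
    origin = np.asarray(phantom.grid.origin)
    spacing = np.asarray(phantom.grid.spacing)
    idx = np.rint((pts - origin) / spacing).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(phantom.grid.shape)), axis=1)
    inside = np.zeros(ts.shape, dtype=bool)
    if ok.any():
        ii = idx[ok]
        inside[ok] = in_body_grid[ii[:, 0], ii[:, 1], ii[:, 2]]
    cum = np.cumsum(inside) * step
    return ts, cum


def compute_dij(grid: FluenceGrid, phantom: VoxelPhantom,
                kernel: KernelParams | None = None) -> sparse.csc_matrix:
    """Sparse dose-influence block for one beam: (n_voxels, n_bixels).

    For each bixel, a ray is cast from the source through the bixel
    centre; every in-body voxel receives kernel dose as a function of
    its source distance, in-body depth along the ray, and perpendicular
    distance from the ray.  Entries below 0.015% of the column maximum
    are dropped; air voxels are always zero.
    """
    kernel = kernel or KernelParams()
    src = np.asarray(grid.source)
    axis = np.asarray(grid.axis)
    eu = np.asarray(grid.e_u)
    ev = np.asarray(grid.e_v)
    sad = grid.sad_mm

    body_flat = np.flatnonzero(phantom.in_body)
    centres = phantom.grid.voxel_centres()[body_flat]
    rel = centres - src
    t_axis = rel @ axis
    r_i = np.linalg.norm(rel, axis=1)
    # divergent BEV coordinates of every body voxel (isocentre plane, mm)
    u_i = (rel @ eu) * sad / t_axis
    v_i = (rel @ ev) * sad / t_axis
    scale = t_axis / sad    # isocentre-plane mm -> mm at the voxel

    in_body_grid = phantom.in_body.reshape(phantom.grid.shape)
    step = 0.5 * min(phantom.grid.spacing)
    diag = float(np.linalg.norm(
        np.asarray(phantom.grid.spacing) * np.asarray(phantom.grid.shape)))
    sigma_max = float(kernel.sigma(diag))
    l_cut = 4.5 * sigma_max

    t_lo = max(step, float(t_axis.min()) - diag)
    t_hi = float(t_axis.max()) + 2 * step

    data: list[np.ndarray] = []
    rows: list[np.ndarray] = []
    indptr = [0]
    nnz = 0
    uv = grid.bixel_centres_uv()
    target = src + sad * axis
    for (u_j, v_j) in uv:
        # generous preselection in scaled BEV coordinates
        du = (u_i - u_j) * scale
        dv = (v_i - v_j) * scale
        cand = np.flatnonzero((np.abs(du) < 1.6 * l_cut)
                              & (np.abs(dv) < 1.6 * l_cut)
                              & (t_axis > 0))
        if cand.size == 0:
            warnings.warn("bixel ray misses the body entirely", stacklevel=2)
            indptr.append(nnz)
            continue
        ray = (target + u_j * eu + v_j * ev) - src
        ray = ray / np.linalg.norm(ray)
        t_ray = rel[cand] @ ray
        perp = rel[cand] - t_ray[:, None] * ray[None, :]
        l_exact = np.linalg.norm(perp, axis=1)
        near = l_exact < l_cut
        cand = cand[near]
        if cand.size == 0:
            indptr.append(nnz)
            continue
        t_ray = t_ray[near]
        l_exact = l_exact[near]

        ts, cum = _body_depth_profile(src, ray, in_body_grid, phantom,
                                      t_lo, t_hi, step)
        depth = np.interp(t_ray, ts, cum)
        sig = kernel.sigma(depth)
        dose = (kernel.calibration_gy
                * (sad / r_i[cand]) ** 2
                * np.exp(-kernel.mu_per_mm
                         * (depth - kernel.reference_depth_mm))
                * np.exp(-0.5 * (l_exact / sig) ** 2))
        if dose.size:
            keep = dose >= DIJ_THRESHOLD * dose.max()
            cand, dose = cand[keep], dose[keep]
        order = np.argsort(cand)
        rows.append(body_flat[cand[order]])
        data.append(dose[order])
        nnz += cand.size
        indptr.append(nnz)

    n_vox = phantom.grid.n_voxels
    if nnz == 0:
        return sparse.csc_matrix((n_vox, grid.n_bixels))
    return sparse.csc_matrix(
        (np.concatenate(data), np.concatenate(rows), np.array(indptr)),
        shape=(n_vox, grid.n_bixels))


@dataclass(frozen=True)
class DoseInfluenceMatrix:
    """Per-beam sparse d_ij blocks over the whole phantom voxel space."""

    blocks: tuple[sparse.csc_matrix, ...]
    grids: tuple[FluenceGrid, ...]
    n_voxels: int

    @property
    def n_beams(self) -> int:
        return len(self.blocks)

    def bixel_counts(self) -> np.ndarray:
        return np.array([g.n_bixels for g in self.grids])


def _content_hash(nodes: NodeSet, phantom: VoxelPhantom,
                  kernel: KernelParams, margin_mm: float) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(phantom.labels).tobytes())
    h.update(json.dumps([phantom.grid.shape, phantom.grid.spacing,
                         phantom.grid.origin]).encode())
    h.update(nodes.sources().tobytes())
    h.update(json.dumps(asdict(kernel), sort_keys=True).encode())
    h.update(f"{margin_mm}".encode())
    return h.hexdigest()[:16]


def assemble_dij(nodes: NodeSet, phantom: VoxelPhantom,
                 kernel: KernelParams | None = None,
                 margin_mm: float = 5.0,
                 cache_dir: str | Path | None = None,
                 progress: bool = False) -> DoseInfluenceMatrix:
    """d_ij blocks for every node, optionally cached on disk.

    The cache key is a content hash of (phantom, node sources, kernel,
    margin); a corrupt cache entry is recomputed with a warning.
    """
    kernel = kernel or KernelParams()
    grids = tuple(fluence_grid_for_beam(nd, phantom, margin_mm)
                  for nd in nodes.nodes)

    cache_path = None
    if cache_dir is not None:
        key = _content_hash(nodes, phantom, kernel, margin_mm)
        cache_path = Path(cache_dir) / f"dij-{key}"
        loaded = _load_cache(cache_path, grids, phantom.grid.n_voxels)
        if loaded is not None:
            return loaded

    blocks = []
    for k, g in enumerate(grids):
        if progress:
            print(f"  d_ij beam {k + 1}/{len(grids)}", flush=True)
        blocks.append(compute_dij(g, phantom, kernel))
    dij = DoseInfluenceMatrix(tuple(blocks), grids, phantom.grid.n_voxels)
    if cache_path is not None:
        _write_cache(cache_path, dij)
    return dij


def _write_cache(path: Path, dij: DoseInfluenceMatrix) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for k, block in enumerate(dij.blocks):
        sparse.save_npz(path / f"beam{k:04d}.npz", block)
    sidecar = {
        "n_beams": dij.n_beams,
        "n_voxels": dij.n_voxels,
        "bixels": [int(b) for b in dij.bixel_counts()],
    }
    (path / "sidecar.json").write_text(json.dumps(sidecar, indent=1))


def _load_cache(path: Path, grids, n_voxels: int):
    side = path / "sidecar.json"
    if not side.exists():
        return None
    try:
        meta = json.loads(side.read_text())
        if (meta["n_beams"] != len(grids) or meta["n_voxels"] != n_voxels
                or meta["bixels"] != [g.n_bixels for g in grids]):
            raise ValueError("cache metadata mismatch")
        blocks = tuple(sparse.load_npz(path / f"beam{k:04d}.npz").tocsc()
                       for k in range(len(grids)))
    except Exception:  # corrupt cache: recompute
        warnings.warn(f"d_ij cache at {path} unreadable; recomputing",
                      stacklevel=2)
        return None
    return DoseInfluenceMatrix(blocks, tuple(grids), n_voxels)
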