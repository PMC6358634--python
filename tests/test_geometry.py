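"""Phantom voxelisation, priority resolution and node placement."""

import numpy as np
import pytest

import beamsel as bs
from beamsel.geometry import AIR_LABEL, NodeGeometry


def small_grid(spacing=5.0, half=60.0):
    n = int(round(2 * half / spacing)) + 1
    return bs.VoxelGrid((n, n, n), (spacing,) * 3, (-half, -half, -half))


def overlap_phantom():
    """PTV sphere overlapping an OAR box inside a spherical body."""
    structures = [
        bs.StructureSpec("body", 9, "sphere",
                         {"center": (0, 0, 0), "radius": 55.0},
                         bs.Objective(1.0, d_max=10.0)),
        bs.StructureSpec("ptv", 1, "sphere",
                         {"center": (10, 0, 0), "radius": 15.0},
                         bs.Objective(10.0, d_min=20.0, d_max=22.0)),
        bs.StructureSpec("rectum", 2, "box",
                         {"center": (25, 0, 0), "size": (30, 20, 20)},
                         bs.Objective(5.0, d_max=12.0)),
    ]
    return bs.build_phantom(small_grid(), structures)


class TestBuildPhantom:
    def test_overlap_resolved_toward_ptv(self):
        """A voxel inside both PTV and rectum is labelled PTV (highest
        priority), and rectum-only voxels keep their own label."""
        ph = overlap_phantom()
        centres = ph.grid.voxel_centres()
        in_ptv = np.sum((centres - [10, 0, 0]) ** 2, axis=1) <= 15.0 ** 2
        in_box = np.all(np.abs(centres - [25, 0, 0])
                        <= [15, 10, 10], axis=1)
        both = in_ptv & in_box
        assert both.any()
        assert np.all(ph.labels[both] == ph.structure_index("ptv"))
        only_box = in_box & ~in_ptv
        assert np.all(ph.labels[only_box] == ph.structure_index("rectum"))

    def test_body_is_fallback_label(self):
        ph = overlap_phantom()
        centres = ph.grid.voxel_centres()
        r2 = np.sum(centres ** 2, axis=1)
        body_only = (r2 <= 55.0 ** 2) & (np.sum(
            (centres - [10, 0, 0]) ** 2, axis=1) > 15.0 ** 2) & ~np.all(
            np.abs(centres - [25, 0, 0]) <= [15, 10, 10], axis=1)
        assert np.all(ph.labels[body_only] == ph.structure_index("body"))
        outside = r2 > 55.0 ** 2
        assert np.all(ph.labels[outside] == AIR_LABEL)

    def test_no_overlap_equals_naive_membership(self):
        structures = [
            bs.StructureSpec("body", 9, "sphere",
                             {"center": (0, 0, 0), "radius": 55.0}),
            bs.StructureSpec("ptv", 1, "sphere",
                             {"center": (-20, 0, 0), "radius": 10.0},
                             bs.Objective(1.0, d_min=1.0, d_max=2.0)),
            bs.StructureSpec("lump", 2, "sphere",
                             {"center": (25, 0, 0), "radius": 10.0}),
        ]
        ph = bs.build_phantom(small_grid(), structures)
        centres = ph.grid.voxel_centres()
        naive = np.sum((centres - [25, 0, 0]) ** 2, axis=1) <= 100.0
        assert np.array_equal(ph.labels == ph.structure_index("lump"), naive)

    def test_label_partition(self, phantom_coarse):
        """Every voxel carries exactly one label; structure counts sum to
        the in-body count."""
        ph = phantom_coarse
        counts = [np.count_nonzero(ph.labels == k)
                  for k in range(len(ph.structures))]
        assert sum(counts) == int(ph.in_body.sum())
        assert int(ph.in_body.sum()) + np.count_nonzero(
            ph.labels == AIR_LABEL) == ph.grid.n_voxels

    def test_priority_dominance(self, phantom_coarse):
        """No voxel is labelled with a lower-priority structure than any
        structure that contains it (annuli checked against PTV)."""
        ph = phantom_coarse
        ptv_k = ph.structure_index("ptv")
        centres = ph.grid.voxel_centres()
        ptv_spec = ph.structures[ptv_k]
        inside_ptv = np.sum(
            (centres - np.asarray(ptv_spec.params["center"])) ** 2,
            axis=1) <= ptv_spec.params["radius"] ** 2
        labelled = ph.labels[inside_ptv]
        prio = {k: s.priority for k, s in enumerate(ph.structures)}
        assert all(prio[int(l)] <= ptv_spec.priority for l in labelled)

    def test_annuli_are_concentric_shells(self, phantom_coarse):
        ph = phantom_coarse
        centres = ph.grid.voxel_centres()
        c = np.asarray(ph.structures[ph.structure_index("ptv")]
                       .params["center"])
        r = np.sqrt(np.sum((centres - c) ** 2, axis=1)) - 25.0
        for name, lo, hi in (("a1", 0, 10), ("a2", 10, 20), ("a3", 20, 30)):
            vox = ph.structure_voxels(name)
            # shell distance measured voxel-to-voxel: allow one voxel slack
            assert r[vox].min() > lo - ph.grid.spacing[0]
            assert r[vox].max() < hi + ph.grid.spacing[0]

    def test_duplicate_priorities_rejected(self):
        structures = [
            bs.StructureSpec("body", 1, "sphere",
                             {"center": (0, 0, 0), "radius": 55.0}),
            bs.StructureSpec("ptv", 1, "sphere",
                             {"center": (0, 0, 0), "radius": 10.0}),
        ]
        with pytest.raises(ValueError, match="unique"):
            bs.build_phantom(small_grid(), structures)

    def test_ptv_outside_body_rejected(self):
        structures = [
            bs.StructureSpec("body", 9, "sphere",
                             {"center": (0, 0, 0), "radius": 30.0}),
            bs.StructureSpec("ptv", 1, "sphere",
                             {"center": (50, 0, 0), "radius": 8.0}),
        ]
        with pytest.raises(ValueError, match="outside the body"):
            bs.build_phantom(small_grid(), structures)


class TestNodeSet:
    def test_all_nodes_at_sad(self, phantom_coarse):
        ns = bs.generate_nodeset(110, phantom_coarse.target_point, seed=0)
        d = np.linalg.norm(ns.sources()
                           - np.asarray(phantom_coarse.target_point), axis=1)
        assert np.allclose(d, 800.0)
        assert len(ns) == 110
        dirs = ns.directions()
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0)

    def test_single_node_at_cap_apex(self):
        geo = NodeGeometry()
        ns = bs.generate_nodeset(1, (0.0, 0.0, 0.0), geo, seed=3)
        # one sample sits near the apex of the polar cap (anterior)
        u = np.asarray(ns.nodes[0].source) / geo.sad_mm
        assert np.dot(u, geo.cap_axis) > np.cos(
            np.radians(geo.cap_angle_deg) / 2)

    def test_min_separation_holds(self):
        """All 630 pairwise separations of a 36-node set respect the
        configured minimum (brute force)."""
        ns = bs.generate_nodeset(36, (0.0, 0.0, 0.0), seed=5)
        dirs = ns.directions()
        ang = np.degrees(np.arccos(np.clip(dirs @ dirs.T, -1, 1)))
        iu = np.triu_indices(36, k=1)
        assert iu[0].size == 630
        assert ang[iu].min() >= NodeGeometry().min_separation_deg

    def test_determinism(self):
        a = bs.generate_nodeset(40, (1.0, 2.0, 3.0), seed=9)
        b = bs.generate_nodeset(40, (1.0, 2.0, 3.0), seed=9)
        assert np.array_equal(a.sources(), b.sources())
        c = bs.generate_nodeset(40, (1.0, 2.0, 3.0), seed=10)
        assert not np.array_equal(a.sources(), c.sources())

    def test_overpacked_cap_rejected(self):
        geo = NodeGeometry(min_separation_deg=30.0)
        with pytest.raises(ValueError, match="separation"):
            bs.generate_nodeset(100, (0.0, 0.0, 0.0), geo, seed=0)


class TestSubsetNodeset:
    def test_identity_when_full(self):
        full = bs.generate_nodeset(20, (0, 0, 0), seed=1)
        sub = bs.subset_nodeset(full, 20)
        assert np.array_equal(sub.sources(), full.sources())

    def test_pair_is_maximal_separation(self):
        """n=2 selects the globally farthest pair (brute force check)."""
        full = bs.generate_nodeset(30, (0, 0, 0), seed=2)
        sub = bs.subset_nodeset(full, 2)
        dirs = full.directions()
        ang = np.arccos(np.clip(dirs @ dirs.T, -1, 1))
        best = np.max(ang)
        d = sub.directions()
        got = np.arccos(np.clip(np.dot(d[0], d[1]), -1, 1))
        assert got == pytest.approx(best, abs=1e-12)

    def test_subsampling_not_tighter_than_full(self):
        full = bs.generate_nodeset(110, (0, 0, 0), seed=0)
        sub = bs.subset_nodeset(full, 36)
        def min_sep(ns):
            dirs = ns.directions()
            ang = np.arccos(np.clip(dirs @ dirs.T, -1, 1))
            np.fill_diagonal(ang, np.inf)
            return ang.min()
        assert min_sep(sub) >= min_sep(full) - 1e-12

    def test_too_large_rejected(self):
        full = bs.generate_nodeset(5, (0, 0, 0), seed=1)
        with pytest.raises(ValueError):
            bs.subset_nodeset(full, 6)


def test_nodeset_tsv_roundtrip(tmp_path):
    ns = bs.generate_nodeset(15, (5.0, -3.0, 2.0), seed=4)
    path = tmp_path / "nodes.tsv"
    bs.write_nodeset(path, ns)
    assert path.read_text().startswith("#")
    back = bs.read_nodeset(path, (5.0, -3.0, 2.0))
    assert np.allclose(back.sources(), ns.sources(), atol=1e-5)
    assert np.allclose(back.directions(), ns.directions(), atol=1e-7)
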