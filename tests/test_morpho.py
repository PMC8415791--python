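"""Skeleton graph extraction, stem/branch counting, lengths, MIP."""

import numpy as np
import pytest

from lsavol.errors import GeometryError, RootingError
from lsavol.image_io import ScalarVolume
from lsavol.morpho import (
    count_stems_branches,
    longest_vessel_length,
    morphometry_report,
    project_mip,
    skeletonize_to_graph,
)
from lsavol.synth import Segment, VesselTreeSpec, generate_vessel_tree, render_angiogram

SPACING = (0.5, 0.5, 0.5)


def _render_mask(segments, shape=(64, 64, 64), spacing=SPACING):
    _, truth = render_angiogram(segments, shape, spacing, vessel_intensity=100.0,
                                background_intensity=0.0)
    return truth.vessel_mask


def _root_mask_at(point_mm, shape, spacing=SPACING, radius_vox=2):
    m = np.zeros(shape, dtype=bool)
    c = np.round(np.asarray(point_mm) / np.asarray(spacing)).astype(int)
    lo = np.maximum(c - radius_vox, 0)
    hi = np.minimum(c + radius_vox + 1, shape)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


class TestSkeletonGraph:
    def test_straight_tube_two_nodes_one_edge(self):
        p0, p1 = np.array([16.3, 16.2, 4.1]), np.array([16.3, 16.2, 24.1])
        mask = _render_mask([Segment(0, None, np.array([p0, p1]), 1.0, 0)])
        skel = skeletonize_to_graph(mask, SPACING, parent_mask=_root_mask_at(p0, mask.shape))
        G = skel.graph
        assert G.number_of_nodes() == 2
        assert G.number_of_edges() == 1
        (_, _, d), = G.edges(data=True)
        assert d["length_mm"] == pytest.approx(20.0, rel=0.10)

    def test_y_shape_four_nodes_three_edges(self):
        stem_top = np.array([16.3, 16.2, 16.1])
        base = np.array([16.3, 16.2, 4.1])
        tip1 = stem_top + np.array([8.0, 0.0, 8.0])
        tip2 = stem_top + np.array([-8.0, 0.0, 8.0])
        segs = [
            Segment(0, None, np.array([base, stem_top]), 1.0, 0),
            Segment(1, 0, np.array([stem_top, tip1]), 0.8, 1),
            Segment(2, 0, np.array([stem_top, tip2]), 0.8, 1),
        ]
        mask = _render_mask(segs)
        skel = skeletonize_to_graph(mask, SPACING, parent_mask=_root_mask_at(base, mask.shape))
        G = skel.graph
        degs = sorted(dict(G.degree()).values())
        assert G.number_of_edges() == 3
        assert degs == [1, 1, 1, 3]

    def test_phantom_tree_endpoint_count_matches_truth(self):
        spec = VesselTreeSpec(
            root_position_mm=(16.0, 16.0, 4.0),
            root_radius_mm=0.8,
            n_generations=2,
            segment_length_mm=(7.0, 9.0),
            branching_angle_deg=(35.0, 55.0),
            seed=5,
        )
        tree = generate_vessel_tree(spec, bounds_mm=[[1, 1, 1], [31, 31, 31]])
        leaves = [s for s in tree if not any(c.parent_id == s.segment_id for c in tree)]
        mask = _render_mask(tree, shape=(64, 64, 64))
        skel = skeletonize_to_graph(
            mask, SPACING, parent_mask=_root_mask_at(spec.root_position_mm, mask.shape)
        )
        assert len(skel.endpoints) == len(leaves)

    def test_skeleton_is_subset_and_preserves_components(self):
        from scipy import ndimage
        from skimage.morphology import skeletonize

        segs = [
            Segment(0, None, np.array([[6.2, 6.1, 4.3], [6.2, 6.1, 26.0]]), 1.0, 0),
            Segment(1, None, np.array([[24.3, 24.2, 4.3], [24.3, 24.2, 26.0]]), 1.0, 0),
        ]
        mask = _render_mask(segs)
        skel = skeletonize(mask)
        assert not skel[~mask].any()
        s26 = np.ones((3, 3, 3))
        assert ndimage.label(skel, s26)[1] == ndimage.label(mask, s26)[1] == 2

    def test_unrooted_raises(self):
        mask = _render_mask([Segment(0, None, np.array([[16.3, 16.2, 4.1], [16.3, 16.2, 24.1]]), 1.0, 0)])
        with pytest.raises(RootingError):
            skeletonize_to_graph(mask, SPACING)
        far = np.zeros(mask.shape, dtype=bool)
        far[0, 0, 0] = True
        with pytest.raises(RootingError):
            skeletonize_to_graph(mask, SPACING, parent_mask=far)


class TestStemsBranches:
    def _skel(self, segs, root_mm, shape=(64, 64, 64)):
        mask = _render_mask(segs, shape=shape)
        return skeletonize_to_graph(mask, SPACING, parent_mask=_root_mask_at(root_mm, shape))

    def test_unbranched_trunk_counts_one_one(self):
        base = np.array([16.3, 16.2, 4.1])
        skel = self._skel([Segment(0, None, np.array([base, base + [0, 0, 20]]), 1.0, 0)], base)
        assert count_stems_branches(skel) == (1, 1)

    def test_single_bifurcation_counts_one_two(self):
        base = np.array([16.3, 16.2, 4.1])
        top = base + np.array([0.0, 0.0, 12.0])
        segs = [
            Segment(0, None, np.array([base, top]), 1.0, 0),
            Segment(1, 0, np.array([top, top + [8, 0, 8]]), 0.8, 1),
            Segment(2, 0, np.array([top, top + [-8, 0, 8]]), 0.8, 1),
        ]
        assert count_stems_branches(self._skel(segs, base)) == (1, 2)

    def test_three_trunks_each_splitting_counts_three_six(self):
        shape = (96, 96, 64)
        segs = []
        bases = []
        sid = 0
        for x in (10.0, 24.0, 38.0):
            base = np.array([x + 0.3, 24.2, 4.1])
            top = base + np.array([0.0, 0.0, 10.0])
            bases.append(base)
            segs.append(Segment(sid, None, np.array([base, top]), 1.0, 0))
            trunk = sid
            sid += 1
            for dx in (5.0, -5.0):
                segs.append(
                    Segment(sid, trunk, np.array([top, top + [dx, 0, 9]]), 0.8, 1)
                )
                sid += 1
        mask = _render_mask(segs, shape=shape)
        parent = np.zeros(shape, dtype=bool)
        for b in bases:
            parent |= _root_mask_at(b, shape)
        skel = skeletonize_to_graph(mask, SPACING, parent_mask=parent)
        # oracle: brute-force traversal of the generating topology
        trunks = [s for s in segs if s.parent_id is None]
        leaves = [s for s in segs if not any(c.parent_id == s.segment_id for c in segs)]
        assert (len(trunks), len(leaves)) == (3, 6)
        assert count_stems_branches(skel) == (3, 6)

    def test_invariant_under_node_relabelling(self):
        base = np.array([16.3, 16.2, 4.1])
        top = base + np.array([0.0, 0.0, 12.0])
        segs = [
            Segment(0, None, np.array([base, top]), 1.0, 0),
            Segment(1, 0, np.array([top, top + [8, 0, 8]]), 0.8, 1),
            Segment(2, 0, np.array([top, top + [-8, 0, 8]]), 0.8, 1),
        ]
        skel = self._skel(segs, base)
        import networkx as nx

        mapping = {n: 1000 + i for i, n in enumerate(sorted(skel.graph.nodes))}
        relabeled = skel.__class__(
            graph=nx.relabel_nodes(skel.graph, mapping),
            roots=[mapping[r] for r in skel.roots],
            spacing=skel.spacing,
        )
        assert count_stems_branches(relabeled) == count_stems_branches(skel)
        assert longest_vessel_length(relabeled) == pytest.approx(
            longest_vessel_length(skel)
        )


class TestLongestLength:
    def test_straight_trunk_30mm_is_3cm(self):
        base = np.array([16.3, 16.2, 1.2])
        shape = (64, 64, 72)
        mask = _render_mask(
            [Segment(0, None, np.array([base, base + [0, 0, 30.0]]), 1.0, 0)], shape=shape
        )
        skel = skeletonize_to_graph(mask, SPACING, parent_mask=_root_mask_at(base, shape))
        assert longest_vessel_length(skel) == pytest.approx(3.0, rel=0.10)

    def test_curved_trunk_arc_length(self):
        # quarter-ish sine arc with known parametric length
        t = np.linspace(0, 1, 200)
        amp, height = 6.0, 32.0
        pts = np.column_stack(
            [16.3 + amp * np.sin(2 * np.pi * t), np.full_like(t, 16.2), 2.2 + height * t]
        )
        deriv = np.diff(pts, axis=0)
        arc = np.linalg.norm(deriv, axis=1).sum()
        shape = (64, 64, 80)
        mask = _render_mask([Segment(0, None, pts, 1.0, 0)], shape=shape)
        skel = skeletonize_to_graph(mask, SPACING, parent_mask=_root_mask_at(pts[0], shape))
        assert longest_vessel_length(skel) == pytest.approx(arc / 10.0, rel=0.10)

    def test_max_over_endpoints(self):
        base = np.array([16.3, 16.2, 4.1])
        top = base + np.array([0.0, 0.0, 10.0])
        segs = [
            Segment(0, None, np.array([base, top]), 1.0, 0),
            Segment(1, 0, np.array([top, top + [0, 8, 6]]), 0.8, 1),
            Segment(2, 0, np.array([top, top + [0, -12, 9]]), 0.8, 1),
        ]
        mask = _render_mask(segs)
        skel = skeletonize_to_graph(mask, SPACING, parent_mask=_root_mask_at(base, mask.shape))
        lengths = [10.0 + 10.0, 10.0 + 15.0]  # root->tip geodesics
        assert longest_vessel_length(skel) == pytest.approx(max(lengths) / 10.0, rel=0.12)

    def test_report_bundles_counts_and_length(self):
        base = np.array([16.3, 16.2, 4.1])
        mask = _render_mask([Segment(0, None, np.array([base, base + [0, 0, 20]]), 1.0, 0)])
        skel = skeletonize_to_graph(mask, SPACING, parent_mask=_root_mask_at(base, mask.shape))
        rep = morphometry_report(skel)
        assert (rep.n_stems, rep.n_branches) == (1, 1)
        assert rep.longest_length_cm > 0


class TestMIP:
    def _vol(self, rng):
        return ScalarVolume(rng.normal(size=(20, 24, 28)), spacing=(0.5, 1.0, 0.5))

    def test_single_slice_slab_returns_that_slice(self, rng):
        vol = self._vol(rng)
        # coronal axis = y, spacing 1.0: slab of 1 mm centred on slice 7
        out = project_mip(vol, "coronal", slab_thickness_mm=1.0, slab_center_mm=7.5)
        np.testing.assert_array_equal(out, vol.data[:, 7, :])

    def test_full_axis_slab_is_global_max(self, rng):
        vol = self._vol(rng)
        out = project_mip(vol, "coronal", slab_thickness_mm=1e4)
        np.testing.assert_array_equal(out, vol.data.max(axis=1))

    def test_oblique_tube_line_max_oracle(self):
        segs = [Segment(0, None, np.array([[3.2, 3.1, 2.3], [12.0, 20.0, 12.0]]), 1.0, 0)]
        vol, _ = render_angiogram(segs, (32, 24, 32), (0.5, 1.0, 0.5),
                                  vessel_intensity=100.0, background_intensity=10.0)
        out = project_mip(vol, "coronal", slab_thickness_mm=1e4)
        # brute-force per-line maximum
        np.testing.assert_array_equal(out, np.max(vol.data, axis=1))

    def test_slab_outside_volume_raises(self, rng):
        vol = self._vol(rng)
        with pytest.raises(GeometryError):
            project_mip(vol, "axial", slab_thickness_mm=2.0, slab_center_mm=500.0)

    def test_default_view_is_coronal_28mm(self, rng):
        vol = ScalarVolume(rng.normal(size=(20, 80, 28)), spacing=(0.5, 0.5, 0.5))
        out = project_mip(vol)
        # 28 mm slab at 0.5 mm spacing = 56 central coronal slices
        lo = int((40 * 0.5 - 14) / 0.5)
        expected = vol.data[:, lo:lo + 56, :].max(axis=1)
        np.testing.assert_array_equal(out, expected)
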