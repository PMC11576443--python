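"""Masking, decile thresholding, clustering, depth constraint, selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conntarget import (
    ConnectivityMap,
    SurfaceMesh,
    Volume3D,
    apply_mask,
    label_clusters,
    make_scalp_mesh,
    percentile_threshold,
    rank_and_select,
    scalp_depth,
    select_target,
)
from conntarget.target_selection import Cluster, ClusterSet


def _fc(data, affine=None):
    data = np.asarray(data, dtype=float)
    return ConnectivityMap(Volume3D(np.clip(data, -1, 1), np.eye(4)
                                    if affine is None else affine), "FC")


def _ones_mask(shape, affine=None):
    return Volume3D(np.ones(shape), np.eye(4) if affine is None else affine)


class TestApplyMask:
    def test_full_mask_identity(self, rng):
        cmap = _fc(rng.uniform(-1, 1, (4, 4, 4)))
        out = apply_mask(cmap, _ones_mask((4, 4, 4)))
        np.testing.assert_array_equal(out.map.data, cmap.map.data)

    def test_idempotent(self, rng):
        cmap = _fc(rng.uniform(-1, 1, (4, 4, 4)))
        mask = Volume3D((rng.uniform(size=(4, 4, 4)) > 0.5).astype(int), np.eye(4))
        mask.data[0, 0, 0] = 1
        once = apply_mask(cmap, mask)
        twice = apply_mask(once, mask)
        np.testing.assert_array_equal(once.map.data, twice.map.data)

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            apply_mask(_fc(rng.uniform(size=(4, 4, 4))), _ones_mask((5, 5, 5)))

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            apply_mask(_fc(rng.uniform(size=(4, 4, 4))),
                       Volume3D(np.zeros((4, 4, 4)), np.eye(4)))

    def test_no_positive_overlap_fails_downstream(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = 0.9  # positive value outside the mask
        mask = np.zeros((4, 4, 4))
        mask[3, 3, 3] = 1
        masked = apply_mask(_fc(data), Volume3D(mask, np.eye(4)))
        with pytest.raises(ValueError, match="no positive"):
            percentile_threshold(masked, Volume3D(mask, np.eye(4)))


class TestPercentileThreshold:
    def test_top_decile_of_ten_distinct_values(self):
        data = np.zeros((10, 1, 1))
        data[:, 0, 0] = np.arange(1, 11) / 11.0
        binary = percentile_threshold(_fc(data), _ones_mask((10, 1, 1)), 0.10)
        assert binary.data.sum() == 1
        assert binary.data[9, 0, 0] == 1

    def test_total_tie_retains_all(self):
        data = np.full((5, 2, 1), 0.5)
        binary = percentile_threshold(_fc(data), _ones_mask((5, 2, 1)), 0.10)
        assert binary.data.sum() == 10

    def test_top_two_of_twenty(self):
        data = np.zeros((20, 1, 1))
        data[:, 0, 0] = np.arange(1, 21) / 21.0
        binary = percentile_threshold(_fc(data), _ones_mask((20, 1, 1)), 0.10)
        assert set(np.flatnonzero(binary.data[:, 0, 0])) == {18, 19}

    def test_no_positive_values_rejected(self):
        with pytest.raises(ValueError, match="no positive"):
            percentile_threshold(_fc(-np.ones((3, 3, 3)) * 0.5),
                                 _ones_mask((3, 3, 3)))

    def test_negative_values_never_retained(self, rng):
        data = rng.uniform(-1, 1, (6, 6, 6))
        binary = percentile_threshold(_fc(data), _ones_mask((6, 6, 6)), 0.10)
        assert np.all(data[binary.data > 0] > 0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_retention_count_law(self, seed):
        # retained in [ceil(0.1 P), ceil(0.1 P) + ties at the cut]
        rng = np.random.default_rng(seed)
        data = np.round(rng.uniform(-1, 1, (8, 8, 8)), 2)  # induces ties
        pos = data > 0
        if pos.sum() == 0:
            return
        binary = percentile_threshold(_fc(data), _ones_mask((8, 8, 8)), 0.10)
        k = int(np.ceil(0.10 * pos.sum()))
        vals = np.sort(data[pos])[::-1]
        ties = int((data[pos] == vals[k - 1]).sum())
        assert k <= binary.data.sum() <= k + ties


class TestLabelClusters:
    def test_corner_touch_connectivity(self):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = 0.5
        data[2, 2, 2] = 0.7  # touches only at a corner
        cmap = _fc(data)
        binary = Volume3D((data > 0).astype(int), np.eye(4))
        assert len(label_clusters(binary, cmap, connectivity=26).clusters) == 1
        assert len(label_clusters(binary, cmap, connectivity=6).clusters) == 2

    def test_single_voxel_mass_and_cog(self):
        affine = np.eye(4)
        affine[:3, 3] = [10.0, -60.0, 40.0]
        data = np.zeros((3, 3, 3))
        data[0, 0, 0] = 0.7
        cmap = ConnectivityMap(Volume3D(data, affine), "FC")
        cs = label_clusters(Volume3D((data > 0).astype(int), affine), cmap)
        assert len(cs.clusters) == 1
        assert cs.clusters[0].mass == pytest.approx(0.7)
        np.testing.assert_allclose(cs.clusters[0].cog_world, [10.0, -60.0, 40.0])

    def test_weighted_cog_two_voxels(self):
        # 2 mm spacing, voxels at x-index 0 (value 1) and 1 (value 3):
        # world x = 0 and 2, COG x = (0*1 + 2*3)/4 = 1.5
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        data = np.zeros((2, 1, 1))
        data[0, 0, 0] = 1.0
        data[1, 0, 0] = 3.0
        cmap = ConnectivityMap(Volume3D(data / 4.0, affine), "FC")
        cs = label_clusters(Volume3D(np.ones((2, 1, 1)), affine), cmap)
        assert len(cs.clusters) == 1
        assert cs.clusters[0].cog_world[0] == pytest.approx(1.5)

    def test_empty_binary_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            label_clusters(Volume3D(np.zeros((3, 3, 3)), np.eye(4)),
                           _fc(np.zeros((3, 3, 3))))

    def test_cog_inside_cluster_bounding_box(self, rng):
        data = np.clip(rng.uniform(0, 1, (10, 10, 10)), 0, 1)
        cmap = _fc(data)
        binary = percentile_threshold(cmap, _ones_mask((10, 10, 10)), 0.10)
        for c in label_clusters(binary, cmap).clusters:
            world = cmap.map.voxel_to_world(c.voxel_indices)
            assert np.all(c.cog_world >= world.min(axis=0) - 1e-9)
            assert np.all(c.cog_world <= world.max(axis=0) + 1e-9)


class TestScalpDepth:
    def test_sphere_geometry(self):
        mesh = make_scalp_mesh((85, 85, 85), subdivisions=3)
        assert scalp_depth(np.array([70.0, 0, 0]), mesh) == pytest.approx(15.0, abs=1.5)
        assert scalp_depth(np.zeros(3), mesh) == pytest.approx(85.0, abs=0.01)

    def test_point_on_vertex_zero(self):
        mesh = make_scalp_mesh((85, 85, 85), subdivisions=2)
        assert scalp_depth(mesh.vertices[17], mesh) == 0.0

    def test_surface_method_at_most_vertex_method(self):
        mesh = make_scalp_mesh((85, 85, 85), subdivisions=2)
        p = np.array([40.0, 30.0, 20.0])
        assert scalp_depth(p, mesh, "surface") <= scalp_depth(p, mesh, "vertex") + 1e-9

    def test_empty_mesh_rejected(self):
        mesh = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError, match="vertices"):
            scalp_depth(np.zeros(3), mesh)


def _cluster(cid, cog, mass, peak=None):
    return Cluster(cid, np.zeros((1, 3), dtype=int), mass, np.asarray(cog, float),
                   peak if peak is not None else mass)


def _cluster_set(clusters):
    return ClusterSet(Volume3D(np.zeros((2, 2, 2), dtype=int), np.eye(4)), clusters)


class TestRankAndSelect:
    def setup_method(self):
        self.mesh = make_scalp_mesh((85, 85, 85), subdivisions=3)

    def test_single_reachable_cluster(self):
        cs = _cluster_set([_cluster(1, [70.0, 0, 0], 5.0)])  # depth ~15
        t = rank_and_select(cs, self.mesh)
        assert t.reachable and t.cluster_rank == 1
        assert t.depth_mm == pytest.approx(15.0, abs=1.5)

    def test_unreachable_rank1_falls_through_to_rank2(self):
        cs = _cluster_set([
            _cluster(1, [43.0, 0, 0], 9.0),  # depth ~42
            _cluster(2, [67.0, 0, 0], 4.0),  # depth ~18
        ])
        t = rank_and_select(cs, self.mesh, max_depth=30.0)
        assert t.reachable and t.cluster_rank == 2
        assert t.depth_mm == pytest.approx(18.0, abs=1.5)

    def test_all_deep_returns_min_depth_unreachable(self):
        cs = _cluster_set([
            _cluster(1, [20.0, 0, 0], 9.0),  # depth ~65
            _cluster(2, [50.0, 0, 0], 4.0),  # depth ~35
        ])
        t = rank_and_select(cs, self.mesh, max_depth=30.0)
        assert not t.reachable
        assert t.depth_mm == pytest.approx(35.0, abs=1.5)

    def test_mass_tie_broken_by_peak_then_id(self):
        cs = _cluster_set([
            _cluster(1, [70.0, 0, 0], 5.0, peak=0.3),
            _cluster(2, [0.0, 70.0, 0], 5.0, peak=0.9),
        ])
        t = rank_and_select(cs, self.mesh)
        np.testing.assert_allclose(t.world, [0.0, 70.0, 0])

    def test_peak_ranking_config(self):
        cs = _cluster_set([
            _cluster(1, [70.0, 0, 0], 9.0, peak=0.2),
            _cluster(2, [0.0, 70.0, 0], 1.0, peak=0.8),
        ])
        t = rank_and_select(cs, self.mesh, rank_by="peak")
        np.testing.assert_allclose(t.world, [0.0, 70.0, 0])

    def test_empty_cluster_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rank_and_select(_cluster_set([]), self.mesh)


class TestSelectTarget:
    def _fixture(self, shift=np.zeros(3)):
        rng = np.random.default_rng(5)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = np.array([-15.0, -15.0, -15.0]) + shift
        data = rng.uniform(0, 0.2, (16, 16, 16))
        data[10:13, 10:13, 10:13] = 0.9  # dominant blob near the surface
        cmap = ConnectivityMap(Volume3D(np.clip(data, 0, 1), affine), "SC")
        mask = Volume3D(np.ones((16, 16, 16)), affine)
        mesh = make_scalp_mesh((40, 40, 40), center=shift, subdivisions=3)
        return cmap, mask, mesh

    def test_translation_equivariance(self):
        t = np.array([7.0, -13.0, 29.0])
        base = select_target(*self._fixture())
        moved = select_target(*self._fixture(shift=t))
        np.testing.assert_allclose(moved.world - base.world, t, atol=1e-9)
        assert moved.depth_mm == pytest.approx(base.depth_mm, abs=1e-9)
        assert moved.cluster_rank == base.cluster_rank

    def test_target_inside_mask_support(self):
        cmap, mask, mesh = self._fixture()
        t = select_target(cmap, mask, mesh)
        world = mask.voxel_to_world(np.argwhere(mask.data > 0))
        assert np.all(t.world >= world.min(axis=0) - 1e-9)
        assert np.all(t.world <= world.max(axis=0) + 1e-9)

    def test_metadata_records_choices(self):
        t = select_target(*self._fixture(), rank_by="mass", top_fraction=0.10)
        assert t.meta["rank_by"] == "mass"
        assert t.meta["top_fraction"] == 0.10
        assert t.meta["coordinate"] == "value-weighted cluster COG"
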