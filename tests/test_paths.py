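import numpy as np
import pytest

from atriarecon.grid import GridSpec, OccupancyVolume
from atriarecon.paths import (
    AUGMENTATION_LABEL,
    SEGMENTS,
    AugmentationConfig,
    NoPathError,
    PathPointCloud,
    augment_path,
    build_traversal_graph,
    compose_path,
    locate_ostia_entries,
    path_to_volume,
    shortest_path,
)


def full_volume(n=3, spacing=2.0):
    g = GridSpec(dims=(n, n, n), spacing=spacing)
    return OccupancyVolume(g, np.ones(g.dims, np.uint8))


def bellman_ford(n_nodes, edges, src):
    """Brute-force relaxation oracle: edges = [(u, v, w)] undirected."""
    dist = np.full(n_nodes, np.inf)
    dist[src] = 0.0
    for _ in range(n_nodes):
        changed = False
        for u, v, w in edges:
            if dist[u] + w < dist[v] - 1e-15:
                dist[v] = dist[u] + w
                changed = True
            if dist[v] + w < dist[u] - 1e-15:
                dist[u] = dist[v] + w
                changed = True
        if not changed:
            break
    return dist


class TestGraph:
    def test_zero_weight_gives_pure_geometric_costs(self):
        vol = full_volume(3, spacing=2.0)
        g = build_traversal_graph(vol, navigability_weight=0.0)
        a = g.node_of((1, 1, 1))
        b = g.node_of((1, 1, 2))
        assert g.adjacency[a, b] == pytest.approx(2.0)
        c = g.node_of((0, 0, 0))
        assert g.adjacency[a, c] == pytest.approx(2.0 * np.sqrt(3))

    def test_center_edges_cheaper_than_wall_edges(self):
        vol = full_volume(5, spacing=2.0)
        g = build_traversal_graph(vol, navigability_weight=2.0)
        center = g.adjacency[g.node_of((2, 2, 1)), g.node_of((2, 2, 2))]
        wall = g.adjacency[g.node_of((0, 0, 0)), g.node_of((0, 0, 1))]
        assert center < wall

    def test_center_voxel_has_26_neighbors(self):
        g = build_traversal_graph(full_volume(3))
        c = g.node_of((1, 1, 1))
        assert g.adjacency[c].getnnz() == 26

    def test_disconnected_interior_reports_component_sizes(self):
        grid = GridSpec(dims=(5, 5, 5))
        vals = np.zeros(grid.dims, np.uint8)
        vals[0, 0, 0] = 1
        vals[4, 4, 4] = 1
        with pytest.raises(ValueError, match="components"):
            build_traversal_graph(OccupancyVolume(grid, vals))


class TestShortestPath:
    def test_src_equals_dst(self):
        g = build_traversal_graph(full_volume(3))
        path, cost = shortest_path(g, (1, 1, 1), (1, 1, 1))
        assert cost == 0.0 and len(path) == 1

    def test_wall_with_gap_routes_through_gap(self):
        grid = GridSpec(dims=(4, 4, 1), spacing=1.0)
        vals = np.ones(grid.dims, np.uint8)
        vals[2, :, 0] = 0  # wall across the slab ...
        vals[2, 3, 0] = 1  # ... with one gap
        vol = OccupancyVolume(grid, vals)
        g = build_traversal_graph(vol, navigability_weight=0.0)
        path, cost = shortest_path(g, (0, 0, 0), (3, 0, 0))
        assert [2, 3, 0] in path.tolist()  # passes through the gap
        # oracle: relax all edges until convergence
        m = len(g.node_voxels)
        coo = g.adjacency.tocoo()
        edges = [(i, j, w) for i, j, w in zip(coo.row, coo.col, coo.data) if i < j]
        dist = bellman_ford(m, edges, g.node_of((0, 0, 0)))
        assert cost == pytest.approx(dist[g.node_of((3, 0, 0))])

    @pytest.mark.parametrize("weight", [0.0, 2.0])
    def test_matches_bruteforce_oracle_on_random_interiors(self, weight):
        rng = np.random.default_rng(int(weight * 10) + 1)
        n_checked = 0
        while n_checked < 30:
            grid = GridSpec(dims=(5, 5, 5), spacing=2.0)
            vals = (rng.random(grid.dims) < 0.6).astype(np.uint8)
            vol = OccupancyVolume(grid, vals)
            try:
                g = build_traversal_graph(vol, navigability_weight=weight)
            except ValueError:
                continue
            if len(g.node_voxels) < 2:
                continue
            coo = g.adjacency.tocoo()
            edges = [(i, j, w) for i, j, w in zip(coo.row, coo.col, coo.data) if i < j]
            src, dst = rng.choice(len(g.node_voxels), 2, replace=False)
            dist = bellman_ford(len(g.node_voxels), edges, src)
            try:
                _, cost = shortest_path(g, g.node_voxels[src], g.node_voxels[dst])
                assert cost == pytest.approx(dist[dst], rel=1e-9)
            except NoPathError:
                assert not np.isfinite(dist[dst])
            n_checked += 1

    def test_unreachable_destination_raises(self):
        grid = GridSpec(dims=(3, 3, 3))
        vals = np.ones(grid.dims, np.uint8)
        vol = OccupancyVolume(grid, vals)
        g = build_traversal_graph(vol)
        with pytest.raises(KeyError):
            g.node_of((10, 0, 0))


class TestComposePath:
    def test_entries_are_interior_voxels(self, small_dataset):
        for shape, vol in small_dataset:
            entries = locate_ostia_entries(shape, vol)
            for name, p in entries.points.items():
                idx = tuple(np.rint(vol.grid.world_to_index(p)).astype(int))
                assert vol.values[idx] == 1

    def test_path_spans_septum_to_pvrs_in_leg_order(self, one_shape):
        shape, vol = one_shape
        entries = locate_ostia_entries(shape, vol)
        path = compose_path(shape, vol)
        np.testing.assert_allclose(path.points[0], entries["septum"])
        np.testing.assert_allclose(path.points[-1], entries["ostium_PVRS"])
        seen = [path.labels[0]]
        for lab in path.labels:
            if lab != seen[-1]:
                seen.append(lab)
        assert tuple(seen) == SEGMENTS  # each leg nonempty, clinical order

    def test_path_stays_interior(self, small_dataset):
        for shape, vol in small_dataset:
            path = compose_path(shape, vol)
            idx = np.rint(vol.grid.world_to_index(path.points)).astype(int)
            assert vol.values[tuple(idx.T)].all()

    def test_consecutive_points_within_two_spacings(self, one_shape):
        shape, vol = one_shape
        path = compose_path(shape, vol)
        steps = np.linalg.norm(np.diff(path.points, axis=0), axis=1)
        assert steps.max() <= 2 * vol.grid.spacing

    def test_higher_navigability_weight_moves_paths_off_the_wall(self, small_dataset):
        from scipy import ndimage

        deltas = []
        for shape, vol in small_dataset:
            dwall = ndimage.distance_transform_edt(vol.values) * vol.grid.spacing
            means = []
            for w in (0.0, 4.0):
                path = compose_path(shape, vol, navigability_weight=w)
                idx = np.rint(vol.grid.world_to_index(path.points)).astype(int)
                means.append(dwall[tuple(idx.T)].mean())
            deltas.append(means[1] - means[0])
        assert np.mean(deltas) >= 0.0


class TestAugmentation:
    def test_n_zero_is_identity(self, one_shape):
        shape, vol = one_shape
        path = compose_path(shape, vol)
        out = augment_path(path, shape, AugmentationConfig(n=0, seed=1))
        np.testing.assert_array_equal(out.points, path.points)

    def test_zero_keep_probability_adds_nothing(self, one_shape):
        shape, vol = one_shape
        path = compose_path(shape, vol)
        out = augment_path(path, shape, AugmentationConfig(s_f=0.0, seed=1))
        assert len(out) == len(path)

    def test_count_and_interiority_without_jitter(self, one_shape):
        shape, vol = one_shape
        path = compose_path(shape, vol)
        cfg = AugmentationConfig(n=10, sigma=2.0, s_f=0.5, mu_s=0.0, seed=7)
        out = augment_path(path, shape, cfg)
        aug = out.points[out.labels == AUGMENTATION_LABEL]
        expected = len(path) * cfg.n * cfg.s_f
        tol = 4 * np.sqrt(len(path) * cfg.n * cfg.s_f * (1 - cfg.s_f))
        # interior filtering only removes points, so bound from above;
        # nearly all samples at sigma=2 stay inside the chamber
        assert len(aug) <= expected + tol
        assert len(aug) > 0.5 * expected
        assert shape.contains(aug).all()

    def test_deterministic_per_seed(self, one_shape):
        shape, vol = one_shape
        path = compose_path(shape, vol)
        a = augment_path(path, shape, AugmentationConfig(seed=3))
        b = augment_path(path, shape, AugmentationConfig(seed=3))
        np.testing.assert_array_equal(a.points, b.points)


class TestPathToVolume:
    def test_single_point_occupies_one_voxel(self):
        g = GridSpec(dims=(5, 5, 5), spacing=2.0)
        p = PathPointCloud(np.array([g.index_to_world([2, 2, 2])] * 2),
                           np.array(["a", "a"], dtype=object))
        assert path_to_volume(p, g).count() == 1

    def test_straight_voxel_path_occupies_its_length(self):
        g = GridSpec(dims=(10, 10, 10), spacing=2.0)
        idx = np.array([[i, i, i] for i in range(10)])  # 26-connected diagonal
        pts = g.index_to_world(idx)
        p = PathPointCloud(pts, np.array(["a"] * 10, dtype=object))
        assert path_to_volume(p, g).count() == 10

    def test_all_points_outside_raises(self):
        g = GridSpec(dims=(5, 5, 5), spacing=2.0)
        p = PathPointCloud(np.full((3, 3), 1e3), np.array(["a"] * 3, dtype=object))
        with pytest.raises(ValueError, match="outside"):
            path_to_volume(p, g)

    def test_outliers_clipped_with_log(self, caplog):
        import logging

        g = GridSpec(dims=(5, 5, 5), spacing=2.0)
        pts = np.vstack([g.index_to_world([[2, 2, 2]]), [[500.0, 0, 0]]])
        p = PathPointCloud(pts, np.array(["a", "a"], dtype=object))
        with caplog.at_level(logging.WARNING):
            vol = path_to_volume(p, g)
        assert vol.count() == 1
        assert "clipped 1" in caplog.text
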