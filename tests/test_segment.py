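"""Shortest-path boundary extraction and the sequential segmentation."""

import numpy as np
import pytest
from scipy.sparse.csgraph import bellman_ford

from octlayers import (
    BOUNDARY_LABELS,
    Boundary,
    BoundaryOrderError,
    BScanImage,
    GradientMap,
    PhantomSpec,
    RegionEmptyError,
    add_endpoint_columns,
    build_adjacency,
    disambiguate_by_mean_row,
    fuzzify_weights,
    generate_bscan,
    limit_region,
    segment_all,
    shortest_path_boundary,
    simulate_bscan,
    vertical_gradient,
)
from octlayers.segment import SearchRegion, check_ordering


def random_graph(rng, h, w, fuzzify=True):
    grad = GradientMap(rng.random((h, w)), "dark_to_bright")
    g = build_adjacency(grad, w_min=1e-5)
    if fuzzify:
        g = fuzzify_weights(g, 2.0)
    return add_endpoint_columns(g)


def exhaustive_min_cost(mat, source, sink):
    """Depth-first enumeration of all simple source->sink paths."""
    n = mat.shape[0]
    best = [np.inf]
    adj = [list(zip(mat.indices[mat.indptr[i]:mat.indptr[i + 1]],
                    mat.data[mat.indptr[i]:mat.indptr[i + 1]])) for i in range(n)]
    visited = np.zeros(n, dtype=bool)

    def dfs(node, cost):
        if cost >= best[0]:
            return
        if node == sink:
            best[0] = cost
            return
        visited[node] = True
        for nxt, wgt in adj[node]:
            if not visited[nxt]:
                dfs(nxt, cost + wgt)
        visited[node] = False

    dfs(source, 0.0)
    return best[0]


class TestShortestPathBoundary:
    def test_near_zero_row_is_found(self):
        # one row of maximal gradient -> unique minimum path on that row
        values = np.full((5, 5), 0.1)
        values[2] = 1.0
        graph = add_endpoint_columns(
            build_adjacency(GradientMap(values, "dark_to_bright"))
        )
        boundary, _ = shortest_path_boundary(graph)
        np.testing.assert_array_equal(boundary.rows, np.full(5, 2))

    def test_cost_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            graph = random_graph(rng, 3, 3)
            mat, source, sink = graph.to_sparse()
            _, cost = shortest_path_boundary(graph)
            assert cost == pytest.approx(exhaustive_min_cost(mat, source, sink))

    def test_cost_matches_bellman_ford(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            h, w = rng.integers(2, 7, size=2)
            graph = random_graph(rng, int(h), int(w))
            mat, source, sink = graph.to_sparse()
            _, cost = shortest_path_boundary(graph)
            oracle = bellman_ford(mat, directed=True, indices=source)[sink]
            assert cost == pytest.approx(oracle, rel=1e-10)

    def test_region_mask_forces_second_best_row(self):
        values = np.full((6, 5), 0.1)
        values[1] = 1.0  # global optimum
        values[4] = 0.8  # best admissible alternative
        graph = add_endpoint_columns(
            build_adjacency(GradientMap(values, "dark_to_bright"))
        )
        region = SearchRegion(
            lo=np.full(5, 3), hi=np.full(5, 5), height=6
        )
        boundary, _ = shortest_path_boundary(graph, region)
        np.testing.assert_array_equal(boundary.rows, np.full(5, 4))

    def test_masked_cost_matches_bellman_ford(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            graph = random_graph(rng, 6, 6)
            region = SearchRegion(lo=np.full(6, 2), hi=np.full(6, 5), height=6)
            mat, source, sink = graph.to_sparse(region.mask())
            _, cost = shortest_path_boundary(graph, region)
            oracle = bellman_ford(mat, directed=True, indices=source)[sink]
            assert cost == pytest.approx(oracle, rel=1e-10)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        graph = random_graph(rng, 6, 6)
        b1, c1 = shortest_path_boundary(graph)
        b2, c2 = shortest_path_boundary(graph)
        np.testing.assert_array_equal(b1.rows, b2.rows)
        assert c1 == c2


class TestLimitRegion:
    def test_unbounded_covers_whole_image(self):
        region = limit_region(None, None, 0, (10, 4))
        assert np.all(region.lo == 0)
        assert np.all(region.hi == 9)
        assert region.mask().all()

    def test_margin_arithmetic(self):
        ilm = Boundary("ILM", np.full(4, 10))
        isos = Boundary("IS-OS", np.full(4, 100))
        region = limit_region(ilm, isos, 2, (200, 4))
        assert np.all(region.lo == 13)
        assert np.all(region.hi == 97)

    def test_too_tight_region_is_empty(self):
        upper = Boundary("ILM", np.full(4, 10))
        lower = Boundary("X", np.full(4, 12))
        with pytest.raises(RegionEmptyError):
            limit_region(upper, lower, 2, (200, 4))

    def test_crossing_references_rejected(self):
        upper = Boundary("A", np.array([10, 10, 50, 10]))
        lower = Boundary("B", np.array([40, 40, 40, 40]))
        with pytest.raises(BoundaryOrderError):
            limit_region(upper, lower, 1, (100, 4))


class TestDisambiguation:
    def test_smaller_mean_is_upper_and_order_invariant(self):
        shallow = Boundary("a", np.full(5, 20))
        deep = Boundary("b", np.full(5, 200))
        assert disambiguate_by_mean_row(shallow, deep) == (shallow, deep)
        assert disambiguate_by_mean_row(deep, shallow) == (shallow, deep)

    def test_tie_keeps_input_order(self, caplog):
        a = Boundary("a", np.array([10, 30]))
        b = Boundary("b", np.array([30, 10]))
        with caplog.at_level("WARNING"):
            up, low = disambiguate_by_mean_row(a, b)
        assert (up, low) == (a, b)
        assert any("tie" in r.message for r in caplog.records)

    def test_labels_match_phantom_truth(self, flat_phantom_spec):
        _, truth = generate_bscan(flat_phantom_spec)
        up, low = disambiguate_by_mean_row(truth["IS-OS"], truth["ILM"])
        assert up.label == "ILM"
        assert low.label == "IS-OS"


class TestSegmentAll:
    def test_noise_free_recovery_is_exact(self, flat_phantom_spec):
        from octlayers import FhhConfig, enhance

        image, truth = generate_bscan(flat_phantom_spec)
        enhanced, _ = enhance(image, FhhConfig())
        result = segment_all(enhanced)
        for lb in BOUNDARY_LABELS:
            np.testing.assert_array_equal(
                result.boundaries[lb].rows, truth[lb].rows, err_msg=lb
            )
        assert result.ordering_ok
        assert result.order_of_extraction == [
            "ILM", "IS-OS", "RPE-Choroid", "NFL-GCL",
            "OS-RPE", "INL-OPL", "IPL-INL", "OPL-ONL",
        ]

    def test_speckled_recovery_close_and_ordered(self):
        from octlayers import FhhConfig, enhance, mad

        spec = PhantomSpec(height=128, width=256, seed=5)
        image, truth = simulate_bscan(spec)
        enhanced, _ = enhance(image, FhhConfig())
        result = segment_all(enhanced)
        assert result.ordering_ok
        for lb in BOUNDARY_LABELS:
            assert mad(result.boundaries[lb], truth[lb]) <= 1.5, lb

    def test_layer_masks_partition_the_retina(self, flat_phantom_spec):
        from octlayers import FhhConfig, enhance

        image, _ = generate_bscan(flat_phantom_spec)
        enhanced, _ = enhance(image, FhhConfig())
        result = segment_all(enhanced)
        masks = result.layer_masks()
        total = sum(m.astype(int) for m in masks.values())
        assert total.max() == 1  # no overlap
        rows = result.rows_matrix()
        band = rows[-1] - rows[0]  # ILM..RPE-Choroid, half-open
        assert total.sum() == band.sum()

    def test_ordering_checker_flags_inversions(self):
        rows = np.tile(np.arange(8)[:, None] * 10, (1, 4))
        assert check_ordering(rows)
        rows[3, 2] = 100  # push one boundary below its successor
        assert not check_ordering(rows)


class TestEndToEndCoordinates:
    def test_cropped_rows_are_reported_in_original_frame(self, flat_phantom_spec):
        from octlayers import PipelineConfig, run_pipeline

        image, truth = generate_bscan(flat_phantom_spec)
        result, info = run_pipeline(image, PipelineConfig(crop_fraction=0.15))
        assert info["crop_rows"] == 38  # floor(0.15 * 256)
        assert result.row_offset == 0
        for lb in BOUNDARY_LABELS:
            np.testing.assert_array_equal(
                result.boundaries[lb].rows, truth[lb].rows, err_msg=lb
            )
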