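"""OCT segmentation: gradient graph, shortest-path boundaries, thickness."""

import itertools

import numpy as np
import pytest

import capillux as cx
from capillux.oct import build_boundary_graph, review_segmentation, segment_boundary


def brute_force_min_cost(gradient: np.ndarray, w_min: float) -> float:
    """Exhaustive minimum source->sink path cost over simple 8-connected paths.

    Independent oracle: depth-first enumeration with cost pruning; terminals
    attach to every row of the first/last column at cost ``w_min``.
    """
    n_rows, n_cols = gradient.shape
    best = [np.inf]

    def weight(a, b):
        return 2.0 - (gradient[a] + gradient[b]) + w_min

    def neighbors(node):
        r, c = node
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols:
                yield rr, cc

    def dfs(node, cost, visited):
        if cost >= best[0]:
            return
        if node[1] == n_cols - 1:
            best[0] = min(best[0], cost + w_min)
            return
        for nxt in neighbors(node):
            if nxt not in visited:
                visited.add(nxt)
                dfs(nxt, cost + weight(node, nxt), visited)
                visited.remove(nxt)

    for r in range(n_rows):
        start = (r, 0)
        dfs(start, w_min, {start})
    return best[0]


class TestBoundaryGraph:
    def test_bright_bottom_interface_has_maximal_gradient(self):
        # dark top half, bright bottom half: the dark-to-bright ridge sits on
        # the interface rows, so the cheapest edges run along it
        img = np.vstack([np.zeros((2, 5)), np.ones((2, 5))])
        graph = build_boundary_graph(img, "dark_to_bright")
        ridge_rows = np.argmax(graph.gradient, axis=0)
        assert np.all((ridge_rows == 1) | (ridge_rows == 2))
        boundary = segment_boundary(graph)
        assert np.all((boundary >= 1) & (boundary <= 2))

    def test_constant_image_all_paths_equal_cost(self):
        graph = build_boundary_graph(np.full((4, 4), 2.0))
        assert np.all(graph.gradient == 0.0)
        rows, cost = segment_boundary(graph, return_cost=True)
        # any monotone 4-column path: w_min + 3 edges of (2 + w_min) + w_min
        assert cost == pytest.approx(2 * graph.w_min + 3 * (2 + graph.w_min))

    def test_noiseless_bscan_argmax_matches_truth(self, flat_bscan_fixture):
        bscan, ilm, _, _ = flat_bscan_fixture
        graph = build_boundary_graph(bscan, "dark_to_bright")
        assert np.all(np.argmax(graph.gradient, axis=0) == ilm.astype(int))

    def test_rejects_nonpositive_w_min(self):
        with pytest.raises(ValueError):
            build_boundary_graph(np.zeros((3, 3)), w_min=0.0)


class TestShortestPathOracle:
    @pytest.mark.parametrize("shape,seed", [((4, 4), 0), ((5, 5), 1), ((6, 6), 2), ((6, 5), 3)])
    def test_dijkstra_cost_equals_exhaustive_enumeration(self, shape, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, size=shape)
        graph = build_boundary_graph(img, "dark_to_bright")
        _, cost = segment_boundary(graph, return_cost=True)
        assert cost == pytest.approx(
            brute_force_min_cost(graph.gradient, graph.w_min), rel=1e-9
        )

    def test_cost_not_above_any_monotone_path(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 1, size=(6, 6))
        graph = build_boundary_graph(img, "dark_to_bright")
        _, cost = segment_boundary(graph, return_cost=True)
        g = graph.gradient
        for _ in range(200):  # random monotone paths as upper bounds
            r = rng.integers(0, 6)
            path = [(r, 0)]
            for c in range(1, 6):
                r = int(np.clip(r + rng.integers(-1, 2), 0, 5))
                path.append((r, c))
            path_cost = 2 * graph.w_min + sum(
                2 - (g[a] + g[b]) + graph.w_min for a, b in zip(path, path[1:])
            )
            assert cost <= path_cost + 1e-12


class TestSegmentBscan:
    def test_flat_noiseless_exact(self, flat_bscan_fixture):
        bscan, ilm, rpe, params = flat_bscan_fixture
        seg = cx.segment_bscan(bscan)
        assert np.array_equal(seg.ilm_row, ilm)
        assert np.array_equal(seg.rpe_row, rpe)
        thickness = cx.total_retinal_thickness(seg, params.axial_pitch_um)
        assert np.allclose(thickness, 220.0)

    def test_sinusoidal_ilm_recovered(self):
        cols = np.arange(80)
        ilm = 50 + 8 * np.sin(2 * np.pi * cols / 40)
        p = cx.OctSimParams(
            n_cols=80, n_rows=200, ilm_profile=ilm, rpe_profile=ilm + 100,
            speckle_sd=0.05, seed=3,
        )
        bscan, _, _ = cx.simulate_bscan(p)
        seg = cx.segment_bscan(bscan)
        assert np.corrcoef(seg.ilm_row, ilm)[0, 1] > 0.99

    def test_speckle_boundary_error_small(self):
        errs = []
        for seed in range(5):
            p = cx.OctSimParams(n_cols=100, n_rows=220, speckle_sd=0.2, seed=seed)
            bscan, ilm, rpe = cx.simulate_bscan(p)
            seg = cx.segment_bscan(bscan)
            errs.append(np.abs(seg.ilm_row - ilm).mean())
            errs.append(np.abs(seg.rpe_row - rpe).mean())
        assert np.mean(errs) <= 1.0

    def test_affine_intensity_invariance(self):
        p = cx.OctSimParams(n_cols=60, n_rows=200, speckle_sd=0.1, seed=5)
        bscan, _, _ = cx.simulate_bscan(p)
        seg1 = cx.segment_bscan(bscan)
        rescaled = cx.BScan(3.5 * bscan.image + 11.0, bscan.axial_pitch_um)
        seg2 = cx.segment_bscan(rescaled)
        assert np.array_equal(seg1.ilm_row, seg2.ilm_row)
        assert np.array_equal(seg1.rpe_row, seg2.rpe_row)

    def test_constant_image_fails_loudly(self):
        with pytest.raises(cx.SegmentationError):
            cx.segment_bscan(cx.BScan(np.full((50, 40), 0.3)))

    def test_band_excluding_column_rejected(self):
        graph = build_boundary_graph(np.random.default_rng(0).uniform(size=(10, 8)))
        with pytest.raises(ValueError):
            segment_boundary(graph, row_band=(np.full(8, 10), np.full(8, 10)))


class TestThickness:
    def test_arithmetic(self):
        seg = cx.LayerSegmentation(np.full(5, 40.0), np.full(5, 150.0))
        assert np.allclose(cx.total_retinal_thickness(seg, 2.0), 220.0)

    def test_session_mean_of_cubes(self):
        assert cx.session_thickness([210.0, 214.0]) == 212.0

    def test_thickness_map_stacks_bscans(self):
        segs = [
            cx.LayerSegmentation(np.full(4, 40.0), np.full(4, 150.0)),
            cx.LayerSegmentation(np.full(4, 42.0), np.full(4, 150.0)),
        ]
        enface = cx.thickness_map(segs, 2.0)
        assert enface.shape == (2, 4)
        assert enface[0, 0] == 220.0 and enface[1, 0] == 216.0

    def test_cube_segmentation_close_to_analytic_truth(self):
        p = cx.OctSimParams(n_cols=80, n_rows=220, speckle_sd=0.1, seed=8)
        cube, ilm, rpe = cx.simulate_oct_cube(p, n_bscans=3)
        segs = [cx.segment_bscan(b) for b in cube]
        enface = cx.thickness_map(segs, p.axial_pitch_um)
        truth = (rpe - ilm) * p.axial_pitch_um
        assert np.max(np.abs(enface - truth[None, :])) <= 2 * p.axial_pitch_um


class TestReview:
    def test_empty_corrections_identity(self):
        seg = cx.LayerSegmentation(np.full(5, 40.0), np.full(5, 150.0))
        out = review_segmentation(seg, {})
        assert np.array_equal(out.ilm_row, seg.ilm_row)
        assert not out.flags.any()

    def test_single_column_override_flagged(self):
        seg = cx.LayerSegmentation(np.full(5, 40.0), np.full(5, 150.0))
        out = review_segmentation(seg, {2: {"ilm": 45.0}})
        assert out.ilm_row[2] == 45.0
        assert list(out.flags) == [False, False, True, False, False]
        assert np.array_equal(np.delete(out.ilm_row, 2), np.full(4, 40.0))

    def test_override_inverting_layers_rejected(self):
        seg = cx.LayerSegmentation(np.full(5, 40.0), np.full(5, 150.0))
        with pytest.raises(ValueError):
            review_segmentation(seg, {1: {"rpe": 30.0}})
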