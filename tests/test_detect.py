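"""Color-coding greedy search, permutation null, harvest, combining."""

import itertools

import numpy as np
import pytest

from empath import (
    DetectionConfig,
    combine_paths,
    draw_coloring,
    greedy_colorful_path,
    harvest,
    null_score_distribution,
    path_pvalue,
    run_detection,
)
from empath.detect import Path, write_paths_jsonl, read_paths_jsonl
from tests.conftest import make_weighted_line, random_weighted_graph


def exhaustive_best_score(wnet, k):
    """Brute-force maximum over all simple k-paths (small graphs only)."""
    g = wnet.network.graph
    w = wnet.w_tot
    best = -np.inf
    found = False

    def extend(path, score):
        nonlocal best, found
        if len(path) == k:
            found = True
            best = max(best, score)
            return
        for nbr in g.neighbors(path[-1]):
            if nbr not in path:
                extend(path + [nbr], score + float(w[nbr]))

    for start in g.nodes:
        extend([start], float(w[start]))
    return best if found else None


class TestGreedy:
    def test_forced_walk_on_weighted_line(self):
        wnet = make_weighted_line({"v1": 5, "v2": 4, "v3": 3, "v4": 2})
        coloring = {"v1": 1, "v2": 2, "v3": 3, "v4": 1}
        path = greedy_colorful_path(wnet, 3, coloring, rng=0)
        assert path.nodes == ("v1", "v2", "v3")
        assert path.score == pytest.approx(12.0)

    def test_color_clash_blocks_extension(self):
        wnet = make_weighted_line({"v1": 5, "v2": 4, "v3": 3, "v4": 2})
        coloring = {"v1": 1, "v2": 1, "v3": 2, "v4": 3}
        assert greedy_colorful_path(wnet, 3, coloring, rng=0) is None

    @pytest.mark.parametrize("seed", range(30))
    def test_paths_valid_and_bounded_by_exhaustive_optimum(self, seed):
        wnet = random_weighted_graph(seed, n_max=25)
        rng = np.random.default_rng(seed)
        coloring = draw_coloring(wnet, 4, rng)
        path = greedy_colorful_path(wnet, 4, coloring, rng=rng)
        if path is None:
            return
        assert len(set(path.nodes)) == 4
        for u, v in zip(path.nodes, path.nodes[1:]):
            assert wnet.network.graph.has_edge(u, v)
        assert len({coloring[n] for n in path.nodes}) == 4
        assert path.score == pytest.approx(sum(float(wnet.w_tot[n]) for n in path.nodes))
        assert path.score <= exhaustive_best_score(wnet, 4) + 1e-9


class TestColorCoding:
    def test_colorful_probability_matches_theory(self):
        # a fixed simple 4-path is colorful with prob 4!/4^4 = 0.09375
        rng = np.random.default_rng(123)
        n_trials = 10_000
        hits = (
            np.array([
                len(set(rng.integers(1, 5, size=4))) == 4 for _ in range(n_trials)
            ]).sum()
        )
        p = 24 / 256
        se = np.sqrt(p * (1 - p) / n_trials)
        assert abs(hits / n_trials - p) < 3 * se


class TestPvalue:
    def test_add_one_convention(self):
        nulls = np.arange(1000, dtype=float)
        assert path_pvalue(2000.0, nulls) == pytest.approx(1 / 1001)
        assert path_pvalue(0.0, nulls) == pytest.approx(1.0)

    def test_counting_oracle_at_the_tail(self):
        nulls = np.arange(1000, dtype=float)
        assert path_pvalue(975.0, nulls) == pytest.approx(26 / 1001)


class TestNull:
    def test_equal_weights_give_constant_null(self):
        wnet = make_weighted_line({f"v{i}": 2.0 for i in range(6)})
        scores = null_score_distribution(wnet, 3, 50, rng=0)
        assert np.allclose(scores, 6.0)

    def test_seeded_determinism(self):
        wnet = random_weighted_graph(5, n_max=15)
        a = null_score_distribution(wnet, 4, 100, rng=42)
        b = null_score_distribution(wnet, 4, 100, rng=42)
        assert np.array_equal(a, b)

    def test_observed_weights_untouched(self):
        wnet = random_weighted_graph(6, n_max=15)
        before = wnet.w_tot.copy()
        null_score_distribution(wnet, 4, 100, rng=0)
        assert (wnet.w_tot == before).all()


class TestHarvest:
    def test_recovers_dominant_planted_path(self):
        # one clearly dominant path on a line; short patience suffices at
        # k=3 where 6/27 of colorings make the planted walk colorful
        weights = {"v0": 5.0, "v1": 4.0, "v2": 3.0}
        weights.update({f"v{i}": 0.1 for i in range(3, 30)})
        wnet = make_weighted_line(weights)
        paths = harvest(wnet, DetectionConfig(k=3, i=10, n_shuffles=200, seed=0))
        assert paths
        assert set(paths[0].nodes) == {"v0", "v1", "v2"}
        assert paths[0].p_value <= 0.025

    def test_zero_weights_yield_no_significant_paths(self):
        wnet = make_weighted_line({f"v{i}": 0.0 for i in range(12)})
        paths = harvest(wnet, DetectionConfig(k=4, i=3, n_shuffles=100, seed=0))
        assert paths == []

    def test_seeded_run_is_reproducible(self, small_bundle):
        cfg = DetectionConfig(seed=5, n_shuffles=100, i=5)
        a = run_detection(small_bundle.network, small_bundle.expression,
                          small_bundle.flux, "case", "control", 0.0, "up", cfg)
        b = run_detection(small_bundle.network, small_bundle.expression,
                          small_bundle.flux, "case", "control", 0.0, "up", cfg)
        assert [p.nodes for p in a.paths] == [p.nodes for p in b.paths]
        assert [p.p_value for p in a.paths] == [p.p_value for p in b.paths]

    def test_network_smaller_than_k_rejected(self):
        wnet = make_weighted_line({"v1": 1.0, "v2": 2.0})
        with pytest.raises(ValueError, match="fewer"):
            harvest(wnet, DetectionConfig(k=8, seed=0))

    def test_results_sorted_by_score_descending(self, small_bundle):
        res = run_detection(small_bundle.network, small_bundle.expression,
                            small_bundle.flux, "case", "control", 0.0, "up",
                            DetectionConfig(seed=9, n_shuffles=100))
        scores = [p.score for p in res.paths]
        assert scores == sorted(scores, reverse=True)


class TestRunDetection:
    def test_down_direction_equals_up_on_swapped_conditions(self, small_bundle):
        cfg = DetectionConfig(seed=21, n_shuffles=100)
        down = run_detection(small_bundle.network, small_bundle.expression,
                             small_bundle.flux, "case", "control", 0.0, "down", cfg)
        swapped = run_detection(small_bundle.network, small_bundle.expression,
                                small_bundle.flux, "control", "case", 0.0, "up", cfg)
        assert [p.nodes for p in down.paths] == [p.nodes for p in swapped.paths]

    def test_full_grid_runs(self, small_bundle):
        results = {}
        for a, direction in itertools.product((0.0, 0.5, 1.0), ("up", "down")):
            res = run_detection(small_bundle.network, small_bundle.expression,
                                small_bundle.flux, "case", "control", a, direction,
                                DetectionConfig(seed=3, n_shuffles=50, i=3))
            results[(a, direction)] = res
            assert res.metadata["a"] == a
        assert len(results) == 6


class TestCombine:
    def _path(self, nodes, kinds=None):
        kinds = kinds or ("metabolic",) * (len(nodes) - 1)
        return Path(nodes=tuple(nodes), score=1.0, p_value=0.01, edge_kinds=tuple(kinds))

    def test_union_arithmetic_for_two_overlapping_paths(self):
        k = 4
        wnet = make_weighted_line({f"v{i}": float(i) for i in range(6)})
        p1 = self._path([f"v{i}" for i in range(4)])
        p2 = self._path([f"v{i}" for i in range(2, 6)])
        combined = combine_paths([p1, p2], wnet)
        assert combined.counts["n_nodes"] == 2 * k - 2
        assert combined.counts["n_metabolic_edges"] == 2 * (k - 1) - 1
        assert combined.counts["n_paths"] == 2

    def test_percentage_rounding(self):
        wnet = make_weighted_line({f"v{i}": 1.0 for i in range(8)})
        kinds = ("ppi",) * 3 + ("metabolic",) * 4
        combined = combine_paths([self._path([f"v{i}" for i in range(8)], kinds)], wnet)
        assert combined.percentages == {"pct_ppi_edges": 43, "pct_metabolic_edges": 57}

    def test_counts_invariant_to_path_order(self):
        wnet = make_weighted_line({f"v{i}": 1.0 for i in range(6)})
        p1 = self._path(["v0", "v1", "v2"])
        p2 = self._path(["v3", "v4", "v5"])
        assert combine_paths([p1, p2], wnet).counts == combine_paths([p2, p1], wnet).counts

    def test_empty_path_list_gives_zero_counts(self):
        wnet = make_weighted_line({"v0": 1.0, "v1": 2.0})
        combined = combine_paths([], wnet)
        assert combined.counts == {"n_ppi_edges": 0, "n_metabolic_edges": 0,
                                   "n_nodes": 0, "n_paths": 0}


class TestExports:
    def test_paths_jsonl_roundtrip(self, tmp_path):
        paths = [Path(("a", "b", "c"), 3.5, 0.01, ("metabolic", "ppi"))]
        f = tmp_path / "paths.jsonl"
        write_paths_jsonl(paths, f)
        assert read_paths_jsonl(f) == paths

    def test_combined_exports_are_deterministic(self, tmp_path, small_bundle):
        from empath import write_combined_graphml, write_combined_sif

        res = run_detection(small_bundle.network, small_bundle.expression,
                            small_bundle.flux, "case", "control", 0.5, "up",
                            DetectionConfig(seed=13, n_shuffles=100, i=5))
        combined = combine_paths(res.paths, res.weighted)
        out = {}
        for tag in ("one", "two"):
            write_combined_graphml(combined, tmp_path / f"{tag}.graphml")
            write_combined_sif(combined, tmp_path / f"{tag}.sif")
            out[tag] = ((tmp_path / f"{tag}.graphml").read_bytes(),
                        (tmp_path / f"{tag}.sif").read_bytes())
        assert out["one"] == out["two"]
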