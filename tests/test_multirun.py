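import itertools

import networkx as nx
import numpy as np
import pytest

from xicalign.model import AlignmentError, Feature, ValidationError, Xic, XicGroup
from xicalign.multirun import (
    DistanceMatrix,
    GuideTree,
    PairwiseCache,
    anchors_between,
    build_distance_matrix,
    build_hierarchy,
    build_mst,
    features_by_cell,
    merge_xics,
    mst_align,
    progressive_align,
    star_align,
)
from xicalign.pairwise import AlignConfig, align_pair, identity_fit
from xicalign.simulate import SimConfig, simulate_experiment


def brute_force_mst_weight(d):
    """Oracle: minimum spanning-tree weight by Cayley/Prüfer enumeration."""
    n = d.shape[0]
    best = np.inf
    for prufer in itertools.product(range(n), repeat=n - 2):
        g = nx.from_prufer_sequence(list(prufer))
        w = sum(d[a, b] for a, b in g.edges)
        best = min(best, w)
    return best


def _feature(prec, run, apex, q=0.001, p=None, d=3.0, width=12.5):
    return Feature(prec, run, apex, apex - width, apex + width, 1000.0,
                   d_score=d, p_value=p if p is not None else q / 2, q_value=q)


class TestDistanceMatrix:
    def test_identical_runs_have_zero_distance(self):
        feats = []
        for run in ("r1", "r2"):
            for k in range(20):
                feats.append(_feature(f"P{k}/2", run, 100.0 + 30 * k))
        dist = build_distance_matrix(["r1", "r2"], feats)
        assert dist.d[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_noisier_run_is_farther(self):
        rng = np.random.default_rng(0)
        feats = []
        apexes = rng.uniform(100, 2000, 60)
        for k, mu in enumerate(apexes):
            feats.append(_feature(f"P{k}/2", "r1", mu + rng.normal(0, 1)))
            feats.append(_feature(f"P{k}/2", "r2", mu + rng.normal(0, 1)))
            feats.append(_feature(f"P{k}/2", "r3", mu + rng.normal(0, 6)))
        dist = build_distance_matrix(["r1", "r2", "r3"], feats)
        assert dist.d[0, 1] < dist.d[0, 2]
        assert dist.d[0, 1] < dist.d[1, 2]
        assert np.allclose(dist.d, dist.d.T)

    def test_isolated_run_is_named(self):
        feats = [_feature("P1/2", "r1", 100.0), _feature("P1/2", "r2", 101.0),
                 _feature("P9/2", "r3", 500.0)]
        with pytest.raises(AlignmentError, match="r3"):
            build_distance_matrix(["r1", "r2", "r3"], feats)

    def test_validation(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestMST:
    def test_unique_mst(self):
        d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        tree = build_mst(DistanceMatrix(["A", "B", "C"], d))
        assert tree.edges == [("A", "B"), ("B", "C")]

    def test_equal_distances_tie_break_is_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        runs = ["r3", "r1", "r4", "r2"]
        tree = build_mst(DistanceMatrix(runs, d))
        assert tree.edges == [("r1", "r2"), ("r1", "r3"), ("r1", "r4")]

    @pytest.mark.parametrize("case", range(25))
    def test_weight_matches_exhaustive_enumeration(self, case):
        rng = np.random.default_rng(300 + case)
        n = 6
        d = rng.uniform(1, 10, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        runs = [f"r{k}" for k in range(n)]
        tree = build_mst(DistanceMatrix(runs, d))
        idx = {r: i for i, r in enumerate(runs)}
        weight = sum(d[idx[a], idx[b]] for a, b in tree.edges)
        assert weight == pytest.approx(brute_force_mst_weight(d))


class TestHierarchy:
    def test_two_runs_single_root(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        tree = build_hierarchy(DistanceMatrix(["a", "b"], d))
        assert sorted([tree.root.left, tree.root.right]) == ["a", "b"]

    def test_tight_pairs_merge_first(self):
        # two tight pairs far apart; independent UPGMA ordering check
        d = np.array(
            [
                [0.0, 1.0, 9.0, 9.0],
                [1.0, 0.0, 9.0, 9.0],
                [9.0, 9.0, 0.0, 1.5],
                [9.0, 9.0, 1.5, 0.0],
            ]
        )
        tree = build_hierarchy(DistanceMatrix(["a", "b", "c", "d"], d))
        kids = [tree.root.left, tree.root.right]
        leaf_sets = [sorted(k.leaves) if not isinstance(k, str) else [k] for k in kids]
        assert sorted(map(tuple, leaf_sets)) == [("a", "b"), ("c", "d")]

    @pytest.mark.parametrize("n", range(2, 9))
    def test_internal_node_count(self, n):
        rng = np.random.default_rng(n)
        d = rng.uniform(1, 5, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = build_hierarchy(DistanceMatrix([f"r{k}" for k in range(n)], d))
        assert len(tree.root.internal_nodes()) == n - 1

    def test_site_aware_clustering_merges_within_site_first(self):
        d = np.full((4, 4), 5.0) - 5.0 * np.eye(4)
        labels = {"r0": "s1", "r1": "s2", "r2": "s1", "r3": "s2"}
        tree = build_hierarchy(
            DistanceMatrix(["r0", "r1", "r2", "r3"], d), site_labels=labels
        )
        kids = [tree.root.left, tree.root.right]
        leaf_sets = sorted(tuple(sorted(k.leaves)) for k in kids)
        assert leaf_sets == [("r0", "r2"), ("r1", "r3")]


class TestStarAndMst:
    def _cache(self, feats, xics=None):
        return PairwiseCache(features_by_cell(feats), xics or {}, AlignConfig())

    def test_single_run_maps_to_itself(self):
        feats = [_feature("P/2", "r1", 100.0)]
        out = star_align("P/2", ["r1"], self._cache(feats))
        assert out["r1"].apex == 100.0

    def test_seed_is_lowest_q_feature(self):
        feats = [_feature("P/2", "r1", 100.0, q=0.01),
                 _feature("P/2", "r2", 200.0, q=0.001)]
        # shared anchors so the pairwise fit exists
        for k in range(10):
            feats.append(_feature(f"A{k}/2", "r1", 50.0 + 40 * k))
            feats.append(_feature(f"A{k}/2", "r2", 150.0 + 40 * k))
        out = star_align("P/2", ["r1", "r2"], self._cache(feats))
        assert out["r2"].apex == 200.0 and out["r2"].source == "r2"
        assert out["r1"].apex == pytest.approx(100.0, abs=2.0)

    def test_global_shift_recovered_in_simulation(self):
        feats = []
        rng = np.random.default_rng(4)
        for k in range(30):
            mu = rng.uniform(100, 2000)
            feats.append(_feature(f"P{k}/2", "r1", mu))
            feats.append(_feature(f"P{k}/2", "r2", mu + 5.0, q=0.002))
        feats.append(_feature("T/2", "r1", 100.0, q=0.0001))
        out = star_align("T/2", ["r1", "r2"], self._cache(feats))
        assert out["r2"].apex == pytest.approx(105.0, abs=3.4)

    def test_no_feature_anywhere_skips_precursor(self):
        feats = [_feature("A/2", "r1", 100.0)]
        assert star_align("MISSING/2", ["r1"], self._cache(feats)) == {}

    def test_mst_composes_shifts_along_path_tree(self):
        feats = []
        for k in range(30):
            mu = 100.0 + 60 * k
            feats.append(_feature(f"P{k}/2", "A", mu))
            feats.append(_feature(f"P{k}/2", "B", mu + 3.0))
            feats.append(_feature(f"P{k}/2", "C", mu + 7.0))
        feats.append(_feature("T/2", "A", 400.0, q=0.0001))
        tree = GuideTree(kind="mst", run_ids=["A", "B", "C"],
                         edges=[("A", "B"), ("B", "C")])
        out = mst_align("T/2", tree, self._cache(feats))
        assert out["C"].apex == pytest.approx(407.0, abs=3.4)
        assert set(out) == {"A", "B", "C"}  # every run visited exactly once

    def test_single_edge_tree_equals_star_on_two_runs(self):
        feats = []
        for k in range(20):
            mu = 100.0 + 60 * k
            feats.append(_feature(f"P{k}/2", "A", mu))
            feats.append(_feature(f"P{k}/2", "B", mu + 4.0))
        feats.append(_feature("T/2", "A", 500.0, q=0.0001))
        tree = GuideTree(kind="mst", run_ids=["A", "B"], edges=[("A", "B")])
        star = star_align("T/2", ["A", "B"], self._cache(feats))
        mst = mst_align("T/2", tree, self._cache(feats))
        assert star["B"].apex == pytest.approx(mst["B"].apex)
        assert star["A"].apex == mst["A"].apex


class TestMerge:
    def test_merge_with_itself_is_identity(self, gaussian_group):
        g = gaussian_group(noise_sd=30.0, seed=8)
        path = align_pair(g, g, "hybrid", fit=identity_fit())
        merged = merge_xics(g, g, path, (1.0, 1.0))
        assert np.allclose(merged.times, g.times)
        assert np.allclose(merged.intensity_matrix, g.intensity_matrix)

    def test_weighted_mean_of_matched_intensities(self):
        t = [0.0, 1.0, 2.0]
        a = XicGroup("P/2", "r1", ["y1"], [Xic(t, [8.0, 8.0, 8.0])])
        b = XicGroup("P/2", "r2", ["y1"], [Xic(t, [4.0, 4.0, 4.0])])
        path = align_pair(a, b, "hybrid", fit=identity_fit())
        merged = merge_xics(a, b, path, (3.0, 1.0))
        assert np.allclose(merged.intensity_matrix, 7.0)

    def test_merging_reduces_noise_variance(self, gaussian_group):
        clean = gaussian_group(baseline=300.0)
        copies = [gaussian_group(noise_sd=80.0, seed=100 + k, baseline=300.0,
                                 run_id=f"c{k}")
                  for k in range(6)]

        def rms(g):
            diff = g.intensity_matrix - np.vstack(
                [np.interp(g.times, clean.times, tr.intensities)
                 for tr in clean.traces]
            )
            return float(np.sqrt(np.mean(diff**2)))

        level = [(g, 1.0) for g in copies]
        while len(level) > 1:
            nxt = []
            for k in range(0, len(level) - 1, 2):
                (ga, wa), (gb, wb) = level[k], level[k + 1]
                path = align_pair(ga, gb, "hybrid", fit=identity_fit())
                nxt.append((merge_xics(ga, gb, path, (wa, wb)), wa + wb))
            if len(level) % 2:
                nxt.append(level[-1])
            level = nxt
        master = level[0][0]
        singles = [rms(g) for g in copies]
        assert rms(master) < min(singles)

    def test_area_between_children_for_equal_weights(self, gaussian_group):
        a = gaussian_group(amps=(1000.0,), noise_sd=0.0)
        b = gaussian_group(amps=(500.0,), noise_sd=0.0)
        path = align_pair(a, b, "hybrid", fit=identity_fit())
        merged = merge_xics(a, b, path, (1.0, 1.0))
        area = lambda g: float(np.trapezoid(g.summed, g.times))
        assert min(area(a), area(b)) <= area(merged) <= max(area(a), area(b))

    def test_different_fragment_sets_rejected(self, gaussian_group):
        a = gaussian_group()
        b = XicGroup("P/2", "r2", ["zz"], [Xic(a.times, a.traces[0].intensities)])
        path = align_pair(a, a, "hybrid", fit=identity_fit())
        with pytest.raises(ValidationError):
            merge_xics(a, b, path, (1.0, 1.0))


class TestProgressive:
    def test_two_identical_runs_give_identity_mappings(self):
        sim = simulate_experiment(SimConfig(
            n_precursors=10, n_runs=2, seed=2, warp_slope_sd=0.0,
            warp_intercept_sd=0.0, spline_amplitude=0.0, local_shift_prob=0.0,
            signal_dropout=0.0, feature_dropout=0.0))
        fmap = features_by_cell(sim.features)
        dist = build_distance_matrix(sim.run_ids, sim.features)
        tree = build_hierarchy(dist)
        mapped, masters, _ = progressive_align(
            sim.precursors, tree, fmap, sim.xics)
        assert len(masters) == 1
        for prec in sim.precursors:
            refs = mapped[prec]
            assert abs(refs["run00"].apex - refs["run01"].apex) <= 3.4

    def test_warped_runs_recovered_at_leaves(self):
        sim = simulate_experiment(SimConfig(
            n_precursors=100, n_runs=4, seed=3, local_shift_prob=0.0))
        fmap = features_by_cell(sim.features)
        tree = build_hierarchy(build_distance_matrix(sim.run_ids, sim.features))
        mapped, masters, _ = progressive_align(
            sim.precursors, tree, fmap, sim.xics)
        ok = total = 0
        for prec in sim.precursors:
            errs = [abs(ref.apex - sim.truth.apex[(prec, run)])
                    for run, ref in mapped.get(prec, {}).items()
                    if sim.truth.present[(prec, run)]]
            if not errs:
                continue
            total += 1
            ok += max(errs) <= sim.config.grid_step
        assert total >= 80
        assert ok / total >= 0.9

    def test_root_master_apex_within_children_span(self):
        sim = simulate_experiment(SimConfig(n_precursors=8, n_runs=6, seed=9,
                                            snr=20.0, local_shift_prob=0.0,
                                            decoys_per_precursor=0,
                                            confusable_prob=0.0))
        fmap = features_by_cell(sim.features)
        tree = build_hierarchy(build_distance_matrix(sim.run_ids, sim.features))
        _, masters, _ = progressive_align(sim.precursors, tree, fmap, sim.xics)
        root = max(masters.values(), key=lambda m: m.weight)
        assert root.weight == 6
        for prec, group in root.xics.items():
            apex = group.times[np.argmax(group.summed)]
            leaf_apexes = [sim.truth.apex[(prec, r)] for r in sim.run_ids
                           if sim.truth.present[(prec, r)]]
            if not leaf_apexes:
                continue
            lo, hi = min(leaf_apexes) - 2 * 3.4, max(leaf_apexes) + 2 * 3.4
            assert lo <= apex <= hi
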