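"""Multirun alignment strategies: Star, MST and Progressive.

All three strategies turn per-run picked features and XICs into, for each
precursor, a mapped reference peak (apex and boundaries) in every run:

* **Star** — the run holding the precursor's most confident feature is the
  seed; every other run is aligned pairwise to it. The seed differs from
  precursor to precursor, so no single run biases the experiment.
* **MST** — the reference is propagated edge-by-edge along a minimum
  spanning tree over runs, so every pairwise fit involves chromatographic
  neighbours and keeps a low residual standard error.
* **Progressive** — runs are merged two at a time up a rooted guide tree
  into weighted-average "master" chromatograms; a reference peak is picked
  on the root master and mapped back down to every leaf.

Run-to-run distance is the RSE of the pairwise global (lowess) fit on
shared high-confidence anchor features.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple, Union

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .model import (
    AlignmentError,
    Feature,
    ValidationError,
    Xic,
    XicGroup,
)
from .pairwise import (
    AlignConfig,
    AlignmentPath,
    GlobalFit,
    _PiecewiseLinear,
    align_pair,
    compute_similarity,
    constrain,
    align_dp,
    fit_global,
    identity_fit,
    mapping_from_path,
)

logger = logging.getLogger(__name__)

# sentinel distance for run pairs with too few shared anchors
INSUFFICIENT_ANCHOR_DISTANCE = 1.0e6

FeatureMap = Dict[Tuple[str, str], List[Feature]]  # (precursor, run) -> features
XicMap = Dict[Tuple[str, str], XicGroup]

__all__ = [
    "DistanceMatrix",
    "GuideTree",
    "TreeNode",
    "MasterRun",
    "MappedReference",
    "features_by_cell",
    "anchors_between",
    "fit_between_runs",
    "build_distance_matrix",
    "build_mst",
    "build_hierarchy",
    "PairwiseCache",
    "star_align",
    "mst_align",
    "merge_xics",
    "progressive_align",
]


@dataclass
class DistanceMatrix:
    """Symmetric run-to-run chromatographic dissimilarity in seconds."""

    run_ids: List[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.run_ids)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match runs")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("distance matrix entries must be finite")


@dataclass
class TreeNode:
    """Internal node of the progressive guide tree."""

    node_id: str
    left: Union["TreeNode", str]
    right: Union["TreeNode", str]

    @property
    def leaves(self) -> List[str]:
        out: List[str] = []
        for child in (self.left, self.right):
            out.extend([child] if isinstance(child, str) else child.leaves)
        return out

    def internal_nodes(self) -> List["TreeNode"]:
        out = []
        for child in (self.left, self.right):
            if isinstance(child, TreeNode):
                out.extend(child.internal_nodes())
        out.append(self)
        return out


@dataclass
class GuideTree:
    kind: str  # "mst" | "hierarchy"
    run_ids: List[str]
    edges: List[Tuple[str, str]] = field(default_factory=list)
    root: Optional[TreeNode] = None

    def __post_init__(self) -> None:
        if self.kind == "mst":
            g = nx.Graph(self.edges)
            if set(g.nodes) != set(self.run_ids) or len(self.edges) != len(
                self.run_ids
            ) - 1 or not nx.is_connected(g):
                raise ValidationError("MST edges must span all runs without cycles")
        elif self.kind == "hierarchy":
            if self.root is None and len(self.run_ids) > 1:
                raise ValidationError("hierarchy tree needs a root")
            if self.root is not None:
                if sorted(self.root.leaves) != sorted(self.run_ids):
                    raise ValidationError("hierarchy leaves must equal the runs")
                n_internal = len(self.root.internal_nodes())
                if n_internal != len(self.run_ids) - 1:
                    raise ValidationError(
                        f"hierarchy must have n-1 internal nodes, got {n_internal}"
                    )
        else:
            raise ValidationError(f"unknown guide-tree kind {self.kind!r}")


@dataclass
class MappedReference:
    """Reference peak coordinates mapped into one run."""

    apex: float
    left: float
    right: float
    rse: float  # accumulated fit uncertainty along the mapping, seconds
    source: str  # seed run / rule that produced the reference


# ---------------------------------------------------------------------------
# Anchors, fits and distances


def features_by_cell(features: Sequence[Feature]) -> FeatureMap:
    out: FeatureMap = {}
    for f in features:
        out.setdefault((f.precursor_id, f.run_id), []).append(f)
    return out


def _best_scored(feats: Sequence[Feature], q_max: float) -> Optional[Feature]:
    scored = [f for f in feats if f.q_value is not None and f.q_value <= q_max]
    if not scored:
        return None
    return min(scored, key=lambda f: (f.q_value, f.rt_apex))


def anchors_between(
    fmap: FeatureMap, run_a: str, run_b: str, q_max: float = 0.01
) -> List[Tuple[float, float]]:
    """High-confidence anchor pairs: one (best-q) feature per precursor
    passing the anchor q-value cut-off in both runs."""
    precursors = {p for (p, r) in fmap if r in (run_a, run_b)}
    anchors = []
    for prec in sorted(precursors):
        fa = _best_scored(fmap.get((prec, run_a), ()), q_max)
        fb = _best_scored(fmap.get((prec, run_b), ()), q_max)
        if fa is not None and fb is not None:
            anchors.append((fa.rt_apex, fb.rt_apex))
    return anchors


def fit_between_runs(
    fmap: FeatureMap, run_a: str, run_b: str, config: Optional[AlignConfig] = None
) -> GlobalFit:
    """Global fit run_a -> run_b with graceful degradation.

    Tries the configured kind (lowess by default), falls back to linear
    with few anchors, and to the identity with fewer than two.
    """
    config = config or AlignConfig()
    anchors = anchors_between(fmap, run_a, run_b, config.anchor_q_value)
    if config.fit_kind == "lowess":
        try:
            return fit_global(anchors, "lowess", lowess_span=config.lowess_span)
        except Exception:
            pass
    try:
        return fit_global(anchors, "linear")
    except Exception:
        logger.debug("identity fallback for fit %s -> %s", run_a, run_b)
        fit = identity_fit()
        fit.rse = INSUFFICIENT_ANCHOR_DISTANCE
        return fit


def build_distance_matrix(
    runs: Sequence[str],
    features: Sequence[Feature],
    config: Optional[AlignConfig] = None,
    min_anchors: int = 2,
) -> DistanceMatrix:
    """Run-pair distance = RSE of the pairwise global fit on shared anchors."""
    config = config or AlignConfig()
    fmap = features_by_cell(features)
    runs = list(runs)
    n = len(runs)
    d = np.zeros((n, n))
    connected = np.zeros(n, dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        anchors = anchors_between(fmap, runs[i], runs[j], config.anchor_q_value)
        if len(anchors) < min_anchors:
            rse = INSUFFICIENT_ANCHOR_DISTANCE
        else:
            rse = fit_between_runs(fmap, runs[i], runs[j], config).rse
            connected[i] = connected[j] = True
        d[i, j] = d[j, i] = rse
    if n > 1 and not connected.all():
        isolated = [runs[k] for k in np.flatnonzero(~connected)]
        raise AlignmentError(
            f"runs sharing no anchors with any other run: {isolated}"
        )
    return DistanceMatrix(run_ids=runs, d=d)


def build_mst(dist: DistanceMatrix) -> GuideTree:
    """Minimum spanning tree over runs, lexicographic tie-break."""
    idx = {r: i for i, r in enumerate(dist.run_ids)}
    candidates = sorted(
        itertools.combinations(sorted(dist.run_ids), 2),
        key=lambda e: (dist.d[idx[e[0]], idx[e[1]]], e),
    )
    # Kruskal with union-find; equal-weight edges resolve lexicographically
    parent = {r: r for r in dist.run_ids}

    def find(r: str) -> str:
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    edges: List[Tuple[str, str]] = []
    for a, b in candidates:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append((a, b))
        if len(edges) == len(dist.run_ids) - 1:
            break
    return GuideTree(kind="mst", run_ids=list(dist.run_ids), edges=sorted(edges))


def _linkage_tree(
    run_ids: List[str], d: np.ndarray, counter: itertools.count
) -> Union[TreeNode, str]:
    if len(run_ids) == 1:
        return run_ids[0]
    z = linkage(squareform(d, checks=False), method="average")
    nodes: List[Union[TreeNode, str]] = list(run_ids)
    for row in z:
        left, right = nodes[int(row[0])], nodes[int(row[1])]
        nodes.append(
            TreeNode(node_id=f"node{next(counter)}", left=left, right=right)
        )
    return nodes[-1]


def build_hierarchy(
    dist: DistanceMatrix, site_labels: Optional[Dict[str, str]] = None
) -> GuideTree:
    """Rooted binary guide tree by UPGMA (average linkage).

    With ``site_labels``, runs of one acquisition site are merged before
    sites are joined: each site's subtree is built first, then site roots
    are clustered on the mean cross-site leaf distances.
    """
    counter = itertools.count(1)
    runs = list(dist.run_ids)
    if len(runs) == 1:
        return GuideTree(kind="hierarchy", run_ids=runs, root=None)
    idx = {r: i for i, r in enumerate(runs)}
    if site_labels and len(set(site_labels.get(r) for r in runs)) > 1:
        sites = sorted({site_labels[r] for r in runs})
        site_roots: List[Union[TreeNode, str]] = []
        site_members: List[List[str]] = []
        for site in sites:
            members = [r for r in runs if site_labels[r] == site]
            sub = dist.d[np.ix_([idx[r] for r in members], [idx[r] for r in members])]
            site_roots.append(_linkage_tree(members, sub, counter))
            site_members.append(members)
        m = len(sites)
        sd = np.zeros((m, m))
        for i, j in itertools.combinations(range(m), 2):
            block = dist.d[
                np.ix_(
                    [idx[r] for r in site_members[i]],
                    [idx[r] for r in site_members[j]],
                )
            ]
            sd[i, j] = sd[j, i] = float(block.mean())
        z = linkage(squareform(sd, checks=False), method="average")
        nodes: List[Union[TreeNode, str]] = list(site_roots)
        for row in z:
            nodes.append(
                TreeNode(
                    node_id=f"node{next(counter)}",
                    left=nodes[int(row[0])],
                    right=nodes[int(row[1])],
                )
            )
        root = nodes[-1]
    else:
        root = _linkage_tree(runs, dist.d, counter)
    return GuideTree(kind="hierarchy", run_ids=runs, root=root)


# ---------------------------------------------------------------------------
# Pairwise mapping cache


class PairwiseCache:
    """Caches global fits and per-precursor pairwise mappings between runs."""

    def __init__(
        self,
        fmap: FeatureMap,
        xics: XicMap,
        config: Optional[AlignConfig] = None,
        method: str = "hybrid",
    ) -> None:
        self.fmap = fmap
        self.xics = xics
        self.config = config or AlignConfig()
        self.method = method
        self._fits: Dict[Tuple[str, str], GlobalFit] = {}

    def fit(self, run_a: str, run_b: str) -> GlobalFit:
        key = (run_a, run_b)
        if key not in self._fits:
            self._fits[key] = fit_between_runs(self.fmap, run_a, run_b, self.config)
        return self._fits[key]

    def mapping(
        self, precursor: str, run_a: str, run_b: str
    ) -> Tuple[Callable[[np.ndarray], np.ndarray], float]:
        """Time mapping run_a -> run_b for one precursor, with its RSE.

        Uses the configured pairwise method on the precursor's XICs; falls
        back to the global fit where a chromatogram is missing.
        """
        fit = self.fit(run_a, run_b)
        ga = self.xics.get((precursor, run_a))
        gb = self.xics.get((precursor, run_b))
        if self.method != "global" and ga is not None and gb is not None:
            try:
                path = align_pair(ga, gb, self.method, fit=fit, config=self.config)
                return mapping_from_path(path, ga.times, gb.times), fit.rse
            except AlignmentError:
                logger.debug(
                    "DP fallback to global fit for %s %s->%s", precursor, run_a, run_b
                )
        return fit.mapping, fit.rse


# ---------------------------------------------------------------------------
# Star and MST strategies


def _seed_feature(
    precursor: str, runs: Sequence[str], fmap: FeatureMap, q_max: float
) -> Optional[Feature]:
    """Most confident picked feature of the precursor over all runs."""
    best: Optional[Feature] = None
    for run in sorted(runs):
        cand = _best_scored(fmap.get((precursor, run), ()), q_max)
        if cand is not None and (
            best is None or (cand.q_value, cand.run_id) < (best.q_value, best.run_id)
        ):
            best = cand
    return best


def _map_reference(
    mapping: Callable, seed: Feature, rse: float, source: str
) -> MappedReference:
    apex, left, right = (
        float(mapping(seed.rt_apex)),
        float(mapping(seed.left_boundary)),
        float(mapping(seed.right_boundary)),
    )
    if not left < apex < right:  # degenerate mapping (flat segment)
        half = max((seed.right_boundary - seed.left_boundary) / 2.0, 1.0)
        left, right = apex - half, apex + half
    return MappedReference(apex=apex, left=left, right=right, rse=rse, source=source)


def star_align(
    precursor: str,
    runs: Sequence[str],
    cache: PairwiseCache,
    seed_q_max: float = 0.05,
) -> Dict[str, MappedReference]:
    """Map the best-scoring run's peak to all runs by direct pairwise alignment."""
    seed = _seed_feature(precursor, runs, cache.fmap, seed_q_max)
    if seed is None:
        logger.debug("precursor %s has no scored feature anywhere; skipped", precursor)
        return {}
    out = {
        seed.run_id: MappedReference(
            seed.rt_apex, seed.left_boundary, seed.right_boundary, 0.0, seed.run_id
        )
    }
    for run in runs:
        if run == seed.run_id:
            continue
        mapping, rse = cache.mapping(precursor, seed.run_id, run)
        out[run] = _map_reference(mapping, seed, rse, seed.run_id)
    return out


def star_fit_rses(
    precursors: Sequence[str],
    runs: Sequence[str],
    cache: PairwiseCache,
    seed_q_max: float = 0.05,
) -> List[float]:
    """RSEs of every seed-to-run global fit the Star strategy would use."""
    rses = []
    for prec in precursors:
        seed = _seed_feature(prec, runs, cache.fmap, seed_q_max)
        if seed is None:
            continue
        for run in runs:
            if run != seed.run_id:
                rses.append(cache.fit(seed.run_id, run).rse)
    return rses


def mst_align(
    precursor: str,
    tree: GuideTree,
    cache: PairwiseCache,
    seed_q_max: float = 0.05,
) -> Dict[str, MappedReference]:
    """Propagate the seed reference along the MST edges (breadth-first)."""
    if tree.kind != "mst":
        raise ValidationError("mst_align needs an MST guide tree")
    seed = _seed_feature(precursor, tree.run_ids, cache.fmap, seed_q_max)
    if seed is None:
        return {}
    adjacency: Dict[str, List[str]] = {r: [] for r in tree.run_ids}
    for a, b in tree.edges:
        adjacency[a].append(b)
        adjacency[b].append(a)
    out = {
        seed.run_id: MappedReference(
            seed.rt_apex, seed.left_boundary, seed.right_boundary, 0.0, seed.run_id
        )
    }
    queue = [seed.run_id]
    while queue:
        u = queue.pop(0)
        here = out[u]
        for v in sorted(adjacency[u]):
            if v in out:
                continue
            mapping, rse = cache.mapping(precursor, u, v)
            apex = float(mapping(here.apex))
            left = float(mapping(here.left))
            right = float(mapping(here.right))
            if not left < apex < right:
                half = max((here.right - here.left) / 2.0, 1.0)
                left, right = apex - half, apex + half
            out[v] = MappedReference(
                apex=apex,
                left=left,
                right=right,
                rse=math.hypot(here.rse, rse),
                source=seed.run_id,
            )
            queue.append(v)
    return out


# ---------------------------------------------------------------------------
# Progressive strategy


def _merge_with_mappings(
    group_a: XicGroup,
    group_b: XicGroup,
    path: AlignmentPath,
    weights: Tuple[float, float],
    node_id: str,
) -> Tuple[XicGroup, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted-average merge of two aligned XIC groups.

    Returns the merged group plus the (child-time, merged-time) anchor
    arrays of both children used for up/down time mapping.
    """
    from .pairwise import _matched_intensity_matrices

    a = group_a.intensity_matrix
    b = _matched_intensity_matrices(group_a, group_b)[1]
    wa, wb = float(weights[0]), float(weights[1])
    if wa <= 0 or wb <= 0:
        raise ValidationError("merge weights must be positive")
    times_a, times_b = group_a.times, group_b.times
    t_merged: List[float] = []
    inten: List[np.ndarray] = []
    # time mappings child -> merged are anchored on matched pairs only: a
    # gap step's raw child time is off the merged timeline by the whole
    # inter-run shift and would poison the projection
    anchors_a: List[Tuple[float, float]] = []
    anchors_b: List[Tuple[float, float]] = []
    for i, j in path.pairs:
        if i is not None and j is not None:
            t = (wa * times_a[i] + wb * times_b[j]) / (wa + wb)
            v = (wa * a[:, i] + wb * b[:, j]) / (wa + wb)
            anchors_a.append((times_a[i], t))
            anchors_b.append((times_b[j], t))
        elif i is not None:  # gap in B: carry A's point with its own weight
            t = float(times_a[i])
            v = a[:, i]
        else:
            t = float(times_b[j])
            v = b[:, j]
        t_merged.append(t)
        inten.append(v)
    if not anchors_a:
        anchors_a = [(times_a[0], times_a[0]), (times_a[-1], times_a[-1])]
    if not anchors_b:
        anchors_b = [(times_b[0], times_b[0]), (times_b[-1], times_b[-1])]
    t_arr = np.asarray(t_merged)
    v_arr = np.asarray(inten).T  # fragments x points
    order = np.argsort(t_arr, kind="stable")
    t_arr, v_arr = t_arr[order], v_arr[:, order]
    # collapse non-increasing time points so the merged grid is strictly rising
    keep_t: List[float] = []
    keep_v: List[np.ndarray] = []
    for k in range(len(t_arr)):
        if keep_t and t_arr[k] <= keep_t[-1] + 1e-9:
            keep_v[-1] = (keep_v[-1] + v_arr[:, k]) / 2.0
        else:
            keep_t.append(float(t_arr[k]))
            keep_v.append(v_arr[:, k].copy())
    grid = np.asarray(keep_t)
    vals = np.asarray(keep_v).T
    merged = XicGroup(
        precursor_id=group_a.precursor_id,
        run_id=node_id,
        fragment_ids=list(group_a.fragment_ids),
        traces=[Xic(grid, vals[k]) for k in range(vals.shape[0])],
    )
    aa = np.asarray(anchors_a).reshape(-1, 2)
    bb = np.asarray(anchors_b).reshape(-1, 2)
    return merged, aa[:, 0], aa[:, 1], bb[:, 0], bb[:, 1]


def merge_xics(
    group_a: XicGroup,
    group_b: XicGroup,
    path: AlignmentPath,
    weights: Tuple[float, float] = (1.0, 1.0),
    node_id: str = "master",
) -> XicGroup:
    """Weighted-average merged chromatogram of two aligned XIC groups.

    Matched time points average with the children's leaf-count weights;
    gap points carry the present child's time and intensity unchanged.
    """
    return _merge_with_mappings(group_a, group_b, path, weights, node_id)[0]


@dataclass
class MasterRun:
    """Merged chromatogram node produced during progressive alignment."""

    node_id: str
    children: Tuple[str, str]
    weight: int
    xics: Dict[str, XicGroup]
    fit_to_children: Dict[str, GlobalFit]
    # per child, per precursor: (child-time, node-time) anchor arrays
    child_anchors: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]]
    projected_features: Dict[str, List[Feature]] = field(default_factory=dict)


@dataclass
class _NodeState:
    node_id: str
    weight: int
    xics: Dict[str, XicGroup]
    feats: Dict[str, List[Feature]]
    rse_to_leaves: float  # accumulated fit rse from this node down


def _project_feature(f: Feature, mapping: Callable, node_id: str) -> Feature:
    apex = float(mapping(f.rt_apex))
    left = float(mapping(f.left_boundary))
    right = float(mapping(f.right_boundary))
    if not left < apex < right:
        half = max((f.right_boundary - f.left_boundary) / 2.0, 1.0)
        left, right = apex - half, apex + half
    return Feature(
        precursor_id=f.precursor_id,
        run_id=node_id,
        rt_apex=apex,
        left_boundary=left,
        right_boundary=right,
        intensity=f.intensity,
        d_score=f.d_score,
        p_value=f.p_value,
        q_value=f.q_value,
        provenance=f.provenance,
    )


def _node_fit(
    left: _NodeState, right: _NodeState, config: AlignConfig
) -> GlobalFit:
    anchors = []
    for prec, lf in left.feats.items():
        rf = right.feats.get(prec)
        if not rf:
            continue
        la = _best_scored(lf, config.anchor_q_value)
        ra = _best_scored(rf, config.anchor_q_value)
        if la is not None and ra is not None:
            anchors.append((la.rt_apex, ra.rt_apex))
    if config.fit_kind == "lowess":
        try:
            return fit_global(anchors, "lowess", lowess_span=config.lowess_span)
        except Exception:
            pass
    try:
        return fit_global(anchors, "linear")
    except Exception:
        fit = identity_fit()
        fit.rse = INSUFFICIENT_ANCHOR_DISTANCE
        return fit


def progressive_align(
    precursors: Sequence[str],
    tree: GuideTree,
    fmap: FeatureMap,
    xics: XicMap,
    config: Optional[AlignConfig] = None,
    max_fdr_query: float = 0.05,
) -> Tuple[Dict[str, Dict[str, MappedReference]], Dict[str, MasterRun], List[float]]:
    """Progressive multirun alignment with merged master chromatograms.

    Upward pass: at every internal node the two children's chromatograms
    are hybrid-aligned and merged into a weighted-average master; features
    are projected onto the master's time grid. Downward pass: for each
    precursor the reference peak picked at the root (best projected
    feature, falling back to the summed-trace maximum) is mapped back to
    every leaf run.

    Returns per-precursor per-run mapped references, all master-run
    objects, and the RSEs of the node-level global fits used.
    """
    config = config or AlignConfig()
    if tree.kind != "hierarchy":
        raise ValidationError("progressive_align needs a hierarchy guide tree")
    precursors = list(precursors)
    masters: Dict[str, MasterRun] = {}
    node_rses: List[float] = []

    def leaf_state(run_id: str) -> _NodeState:
        return _NodeState(
            node_id=run_id,
            weight=1,
            xics={
                p: xics[(p, run_id)] for p in precursors if (p, run_id) in xics
            },
            feats={
                p: list(fmap.get((p, run_id), ()))
                for p in precursors
                if fmap.get((p, run_id))
            },
            rse_to_leaves=0.0,
        )

    def combine(node: Union[TreeNode, str]) -> _NodeState:
        if isinstance(node, str):
            return leaf_state(node)
        ls = combine(node.left)
        rs = combine(node.right)
        fit = _node_fit(ls, rs, config)
        if fit.rse < INSUFFICIENT_ANCHOR_DISTANCE:
            node_rses.append(fit.rse)
        merged_xics: Dict[str, XicGroup] = {}
        anchors_l: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        anchors_r: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        feats: Dict[str, List[Feature]] = {}
        for prec in precursors:
            gl, gr = ls.xics.get(prec), rs.xics.get(prec)
            map_l = map_r = None
            if gl is not None and gr is not None:
                try:
                    path = align_pair(gl, gr, "hybrid", fit=fit, config=config)
                    merged, xa, ya, xb, yb = _merge_with_mappings(
                        gl, gr, path, (ls.weight, rs.weight), node.node_id
                    )
                    merged_xics[prec] = merged
                    anchors_l[prec] = (xa, ya)
                    anchors_r[prec] = (xb, yb)
                    map_l = _PiecewiseLinear(xa, ya)
                    map_r = _PiecewiseLinear(xb, yb)
                except AlignmentError:
                    gl_only = gl  # alignment failed: keep the heavier child
                    merged_xics[prec] = gl_only
                    t = gl_only.times
                    anchors_l[prec] = (t, t)
                    map_l = lambda x: x
            elif gl is not None:
                merged_xics[prec] = gl
                anchors_l[prec] = (gl.times, gl.times)
                map_l = lambda x: x
            elif gr is not None:
                merged_xics[prec] = gr
                anchors_r[prec] = (gr.times, gr.times)
                map_r = lambda x: x
            # project child features upward through the merge mappings;
            # without a chromatogram-level mapping use the node fit.
            projected: List[Feature] = []
            for f in ls.feats.get(prec, ()):
                m = map_l if map_l is not None else fit.mapping
                projected.append(_project_feature(f, m, node.node_id))
            for f in rs.feats.get(prec, ()):
                m = map_r if map_r is not None else (lambda x: x)
                projected.append(_project_feature(f, m, node.node_id))
            if projected:
                feats[prec] = projected
        masters[node.node_id] = MasterRun(
            node_id=node.node_id,
            children=(
                node.left if isinstance(node.left, str) else node.left.node_id,
                node.right if isinstance(node.right, str) else node.right.node_id,
            ),
            weight=ls.weight + rs.weight,
            xics=merged_xics,
            fit_to_children={ls.node_id: fit, rs.node_id: fit},
            child_anchors={ls.node_id: anchors_l, rs.node_id: anchors_r},
        )
        masters[node.node_id].projected_features = feats
        return _NodeState(
            node_id=node.node_id,
            weight=ls.weight + rs.weight,
            xics=merged_xics,
            feats=feats,
            rse_to_leaves=math.hypot(
                max(ls.rse_to_leaves, rs.rse_to_leaves),
                fit.rse if fit.rse < INSUFFICIENT_ANCHOR_DISTANCE else 0.0,
            ),
        )

    mapped: Dict[str, Dict[str, MappedReference]] = {p: {} for p in precursors}

    if tree.root is None:  # single run: references are the picked features
        run = tree.run_ids[0]
        for prec in precursors:
            best = _best_scored(fmap.get((prec, run), ()), max_fdr_query)
            if best is not None:
                mapped[prec][run] = MappedReference(
                    best.rt_apex, best.left_boundary, best.right_boundary, 0.0, run
                )
        return mapped, masters, node_rses

    root_state = combine(tree.root)

    def descend(
        node: Union[TreeNode, str],
        prec: str,
        apex: float,
        left: float,
        right: float,
        rse: float,
        rule: str,
    ) -> None:
        if isinstance(node, str):
            mapped[prec][node] = MappedReference(apex, left, right, rse, rule)
            return
        master = masters[node.node_id]
        for child in (node.left, node.right):
            child_id = child if isinstance(child, str) else child.node_id
            anchors = master.child_anchors[child_id].get(prec)
            fit = master.fit_to_children[child_id]
            if anchors is None or len(anchors[0]) < 2:
                continue  # precursor absent from this subtree: contributes gaps
            inv = _PiecewiseLinear(anchors[1], anchors[0])  # node -> child
            a, l, r = float(inv(apex)), float(inv(left)), float(inv(right))
            if not l < a < r:
                half = max((right - left) / 2.0, 1.0)
                l, r = a - half, a + half
            child_rse = math.hypot(
                rse, fit.rse if fit.rse < INSUFFICIENT_ANCHOR_DISTANCE else 0.0
            )
            descend(child, prec, a, l, r, child_rse, rule)

    for prec in precursors:
        best = _best_scored(root_state.feats.get(prec, ()), max_fdr_query)
        if best is not None:
            apex, left, right = best.rt_apex, best.left_boundary, best.right_boundary
            rule = "projected-feature"
        else:
            group = root_state.xics.get(prec)
            if group is None:
                continue
            apex, left, right = _trace_argmax_peak(group)
            rule = "trace-argmax"
        descend(tree.root, prec, apex, left, right, 0.0, rule)

    return mapped, masters, node_rses


def _trace_argmax_peak(group: XicGroup) -> Tuple[float, float, float]:
    """Fallback reference: maximum of the summed trace, half-max boundaries."""
    summed = group.summed
    times = group.times
    k = int(np.argmax(summed))
    half = summed[k] / 2.0
    li = k
    while li > 0 and summed[li - 1] > half:
        li -= 1
    ri = k
    while ri < len(summed) - 1 and summed[ri + 1] > half:
        ri += 1
    dt = group.sampling_interval
    left = times[li] - dt / 2.0
    right = times[ri] + dt / 2.0
    apex = float(times[k])
    if not left < apex:
        left = apex - dt
    if not apex < right:
        right = apex + dt
    return apex, float(left), float(right)
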