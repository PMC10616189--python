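"""Pairwise retention-time alignment between two runs.

Three methods are provided:

* **global** — a monotone RT mapping (linear or lowess) fitted on
  high-confidence features shared by the two runs; fast but blind to
  analyte-specific local shifts.
* **local** — dynamic programming over a similarity matrix of the two
  fragment-ion chromatogram sets; follows local shifts but can be misled
  by similar-looking decoy signals far from the true elution.
* **hybrid** — dynamic programming constrained to a band around the global
  fit, combining the robustness of the fit with the locality of the DP.

The residual standard error (RSE, seconds) of a global fit doubles as the
package's measure of chromatographic distance between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import savgol_filter
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .model import AlignmentError, FitError, ValidationError, XicGroup

__all__ = [
    "AlignConfig",
    "GlobalFit",
    "SimilarityMatrix",
    "AlignmentPath",
    "fit_global",
    "identity_fit",
    "compute_similarity",
    "constrain",
    "align_dp",
    "map_time",
    "mapping_from_path",
    "align_pair",
]


@dataclass
class AlignConfig:
    """Tunable parameters of pairwise alignment.

    rse_factor scales the global-fit RSE into the half-width of the
    hybrid constraint band; the band is floored at ``min_band_intervals``
    sampling intervals so that a near-perfect fit still admits matches.
    The gap penalty of the DP is an adaptive quantile of the off-diagonal
    similarity distribution of the matrix at hand.
    """

    measure: str = "dot_scaled"
    mask_factor: float = 2.0  # noise floor = mask_factor * median column norm
    fit_kind: str = "lowess"
    lowess_span: float = 0.1
    rse_factor: float = 3.5
    min_band_intervals: float = 3.0
    min_band_seconds: Optional[float] = None
    gap_quantile: float = 0.5
    hard_constrain: bool = True
    soft_penalty: float = -1.0
    anchor_q_value: float = 0.01
    smooth: bool = False  # optional Savitzky-Golay smoothing before similarity
    smooth_window: int = 7


class _PiecewiseLinear:
    """Monotone piecewise-linear map with straight-line extrapolation."""

    def __init__(self, xs: np.ndarray, ys: np.ndarray) -> None:
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        # collapse duplicate abscissae (averaging ordinates), keep monotone
        ux, inverse = np.unique(xs, return_inverse=True)
        if len(ux) != len(xs):
            uy = np.zeros(len(ux))
            counts = np.zeros(len(ux))
            np.add.at(uy, inverse, ys)
            np.add.at(counts, inverse, 1.0)
            xs, ys = ux, uy / counts
        ys = np.maximum.accumulate(ys)
        if len(xs) < 2:
            raise FitError("a piecewise-linear map needs >= 2 nodes")
        self.xs, self.ys = xs, ys
        self._lo_slope = self._edge_slope(0, 1)
        self._hi_slope = self._edge_slope(-2, -1)

    def _edge_slope(self, a: int, b: int) -> float:
        dx = self.xs[b] - self.xs[a]
        dy = self.ys[b] - self.ys[a]
        if dx <= 0:
            return 1.0
        # fall back to the overall slope where the edge segment is flat
        span = self.xs[-1] - self.xs[0]
        overall = (self.ys[-1] - self.ys[0]) / span if span > 0 else 1.0
        return dy / dx if dy > 0 else max(overall, 0.0)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.xs, self.ys)
        lo, hi = self.xs[0], self.xs[-1]
        out = np.where(t < lo, self.ys[0] + (t - lo) * self._lo_slope, out)
        out = np.where(t > hi, self.ys[-1] + (t - hi) * self._hi_slope, out)
        return float(out) if out.ndim == 0 else out


@dataclass
class GlobalFit:
    """Monotone RT mapping run A -> run B with its residual standard error."""

    kind: str
    mapping: Callable[[np.ndarray], np.ndarray]
    rse: float
    n_anchors: int

    def __call__(self, t):
        return self.mapping(t)


def identity_fit() -> GlobalFit:
    return GlobalFit(kind="identity", mapping=lambda t: t, rse=0.0, n_anchors=0)


def fit_global(
    anchors: Sequence[Tuple[float, float]],
    kind: str = "linear",
    *,
    lowess_span: float = 0.1,
    min_lowess_anchors: int = 10,
) -> GlobalFit:
    """Fit a monotone RT mapping on anchor (rt_A, rt_B) pairs.

    ``kind`` is ``"linear"`` or ``"lowess"``; the lowess curve is projected
    onto the monotone cone (isotonic regression) so the mapping honours the
    monotonicity contract. RSE is ``sqrt(sum(res^2) / (n - 2))``.
    """
    anchors = np.asarray(list(anchors), dtype=float)
    if anchors.ndim != 2 or anchors.shape[1] != 2:
        raise FitError("anchors must be (rt_A, rt_B) pairs")
    n = len(anchors)
    if kind == "linear":
        if n < 2:
            raise FitError(f"linear fit needs >= 2 anchors, got {n}")
        x, y = anchors[:, 0], anchors[:, 1]
        if np.ptp(x) == 0:
            raise FitError("anchors are degenerate: zero RT span in run A")
        slope, intercept = np.polyfit(x, y, 1)
        if slope <= 0:
            raise FitError(f"linear fit is non-monotone (slope {slope:.3g})")
        mapping = _PiecewiseLinear(
            np.array([x.min(), x.max()]),
            np.array([slope * x.min() + intercept, slope * x.max() + intercept]),
        )
        residuals = y - mapping(x)
        rse = float(np.sqrt((residuals**2).sum() / max(n - 2, 1)))
        return GlobalFit("linear", mapping, rse, n)
    if kind == "lowess":
        if n < min_lowess_anchors:
            raise FitError(
                f"lowess fit needs >= {min_lowess_anchors} anchors, got {n}; "
                "fall back to linear or identity"
            )
        x, y = anchors[:, 0], anchors[:, 1]
        # a span that always covers a handful of anchors
        frac = min(1.0, max(lowess_span, 10.0 / n))
        smoothed = sm_lowess(y, x, frac=frac, it=3, return_sorted=True)
        xs, ys = smoothed[:, 0], smoothed[:, 1]
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        ys_mono = iso.fit_transform(xs, ys)
        mapping = _PiecewiseLinear(xs, ys_mono)
        residuals = y - mapping(x)
        rse = float(np.sqrt((residuals**2).sum() / max(n - 2, 1)))
        return GlobalFit("lowess", mapping, rse, n)
    raise FitError(f"unknown fit kind {kind!r}")


# ---------------------------------------------------------------------------
# Similarity matrix


@dataclass
class SimilarityMatrix:
    values: np.ndarray  # len(grid_a) x len(grid_b)
    mask: np.ndarray  # boolean, True = admissible
    grid_a: np.ndarray
    grid_b: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.grid_a), len(self.grid_b)):
            raise ValidationError("similarity matrix shape does not match grids")
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask shape does not match values")


def _matched_intensity_matrices(
    group_a: XicGroup, group_b: XicGroup
) -> Tuple[np.ndarray, np.ndarray]:
    set_a, set_b = set(group_a.fragment_ids), set(group_b.fragment_ids)
    if set_a != set_b:
        unmatched = sorted(set_a.symmetric_difference(set_b))
        raise ValidationError(
            f"fragment sets differ between runs {group_a.run_id!r} and "
            f"{group_b.run_id!r}: unmatched {unmatched}"
        )
    order = {f: i for i, f in enumerate(group_b.fragment_ids)}
    a = group_a.intensity_matrix
    b = group_b.intensity_matrix[[order[f] for f in group_a.fragment_ids], :]
    return a, b


def compute_similarity(
    group_a: XicGroup,
    group_b: XicGroup,
    measure: str = "dot_scaled",
    smooth: bool = False,
    smooth_window: int = 7,
    mask_factor: float = 2.0,
) -> SimilarityMatrix:
    """Similarity between the per-time multi-fragment intensity vectors.

    ``masked_cosine`` (default) is cosine similarity with time points whose
    fragment-vector norm falls below a noise floor (``mask_factor`` times
    the run's median column norm) zeroed out: baseline noise then
    contributes no similarity, so the adaptive gap penalty stays small and
    the dynamic program is free to track analyte-specific shifts. Plain
    ``cosine`` compares pattern direction everywhere; ``dot`` is the raw
    dot product.
    """
    a, b = _matched_intensity_matrices(group_a, group_b)
    if smooth:
        w = min(smooth_window, a.shape[1] - (1 - a.shape[1] % 2))
        if w >= 5:
            a = np.clip(savgol_filter(a, w, 2, axis=1), 0.0, None)
        w = min(smooth_window, b.shape[1] - (1 - b.shape[1] % 2))
        if w >= 5:
            b = np.clip(savgol_filter(b, w, 2, axis=1), 0.0, None)
    if measure in ("cosine", "masked_cosine"):
        na = np.linalg.norm(a, axis=0)
        nb = np.linalg.norm(b, axis=0)
        an = np.divide(a, na, out=np.zeros_like(a), where=na > 0)
        bn = np.divide(b, nb, out=np.zeros_like(b), where=nb > 0)
        if measure == "masked_cosine":
            an[:, na < mask_factor * np.median(na)] = 0.0
            bn[:, nb < mask_factor * np.median(nb)] = 0.0
        values = an.T @ bn
    elif measure == "dot_scaled":
        # dot product scaled by the peak column norms: intensity-aware, in
        # [0, ~1], with baseline noise contributing next to nothing
        na = np.linalg.norm(a, axis=0)
        nb = np.linalg.norm(b, axis=0)
        denom = (na.max() * nb.max()) or 1.0
        values = (a.T @ b) / denom
    elif measure == "dot":
        values = a.T @ b
    else:
        raise ValidationError(f"unknown similarity measure {measure!r}")
    return SimilarityMatrix(
        values=values,
        mask=np.ones_like(values, dtype=bool),
        grid_a=group_a.times,
        grid_b=group_b.times,
    )


def constrain(
    sim: SimilarityMatrix,
    fit: GlobalFit,
    rse_factor: float = 3.5,
    min_band_seconds: Optional[float] = None,
    hard: bool = True,
    penalty: float = -1.0,
    min_band_intervals: float = 3.0,
) -> SimilarityMatrix:
    """Restrict the similarity matrix to a band around the global fit.

    A cell (i, j) is admissible iff ``|grid_B[j] - fit(grid_A[i])|`` is
    within ``rse_factor * rse`` seconds, floored at ``min_band_intervals``
    sampling intervals (or at an explicit ``min_band_seconds``). With
    ``hard=True`` masked cells are inadmissible for matching; otherwise
    they keep a penalty similarity and stay admissible.
    """
    dt = float(
        np.median(np.concatenate([np.diff(sim.grid_a), np.diff(sim.grid_b)]))
    )
    floor = dt * min_band_intervals if min_band_seconds is None else min_band_seconds
    scaled = rse_factor * fit.rse
    if np.isnan(scaled):  # inf * 0: an unbounded factor means no constraint
        scaled = np.inf if np.isinf(rse_factor) else 0.0
    band = max(scaled, floor)
    predicted = np.asarray(fit(sim.grid_a), dtype=float)
    inside = np.abs(sim.grid_b[None, :] - predicted[:, None]) <= band
    if not inside.any():
        raise AlignmentError(
            f"constraint band of {band:.3g} s excludes the entire matrix; "
            "widen rse_factor or the band floor"
        )
    if hard:
        return SimilarityMatrix(sim.values.copy(), inside, sim.grid_a, sim.grid_b)
    values = np.where(inside, sim.values, penalty)
    return SimilarityMatrix(values, np.ones_like(inside), sim.grid_a, sim.grid_b)


# ---------------------------------------------------------------------------
# Dynamic programming


@dataclass
class AlignmentPath:
    """Monotone correspondence between two time grids.

    ``pairs`` lists (i, j) index pairs in path order; a gap is encoded with
    ``None`` on the unmatched side. ``score`` is the DP objective: summed
    similarity over matched cells minus the gap penalty per gap step.
    """

    pairs: List[Tuple[Optional[int], Optional[int]]]
    score: float
    gap_penalty: float

    @property
    def matched(self) -> np.ndarray:
        m = [(i, j) for i, j in self.pairs if i is not None and j is not None]
        return np.asarray(m, dtype=int).reshape(-1, 2)


def resolve_gap_penalty(sim: SimilarityMatrix, quantile: float = 0.5) -> float:
    """Adaptive gap penalty: a quantile of the off-diagonal similarities."""
    n_a, n_b = sim.values.shape
    ii, jj = np.meshgrid(np.arange(n_a), np.arange(n_b), indexing="ij")
    # off-diagonal relative to the rescaled main diagonal
    diag_j = np.round(ii * (n_b - 1) / max(n_a - 1, 1)).astype(int)
    # the penalty characterizes the similarity distribution itself, not the
    # constraint: local and hybrid then share one penalty on the same data
    off = sim.values[jj != diag_j]
    pool = off if off.size else sim.values.ravel()
    if pool.size == 0:
        raise AlignmentError("cannot resolve gap penalty on an empty matrix")
    return float(np.quantile(pool, quantile))


def align_dp(
    sim: SimilarityMatrix,
    gap_penalty: Optional[float] = None,
    gap_quantile: float = 0.5,
) -> AlignmentPath:
    """Optimal monotone path through the similarity matrix.

    Needleman-Wunsch-style recursion with steps (+1,+1) match, (+1,0) and
    (0,+1) gaps; matching is only allowed in admissible (unmasked) cells,
    gaps may traverse anywhere. Ties in traceback prefer diagonal, then
    vertical (advance in A), then horizontal.
    """
    if not sim.mask.any():
        raise AlignmentError("similarity matrix is entirely masked")
    if gap_penalty is None:
        gap_penalty = resolve_gap_penalty(sim, gap_quantile)
    n_a, n_b = sim.values.shape
    neg_inf = float("-inf")
    scores = np.where(sim.mask, sim.values, neg_inf)
    # DP over the (n_a+1) x (n_b+1) edit graph
    prev = [0.0 - gap_penalty * j for j in range(n_b + 1)]
    ptr = np.zeros((n_a + 1, n_b + 1), dtype=np.int8)  # 1=diag, 2=up, 3=left
    ptr[0, 1:] = 3
    for i in range(1, n_a + 1):
        cur = [0.0] * (n_b + 1)
        cur[0] = -gap_penalty * i
        ptr[i, 0] = 2
        row_scores = scores[i - 1]
        ptr_row = ptr[i]
        for j in range(1, n_b + 1):
            diag = prev[j - 1] + row_scores[j - 1]
            up = prev[j] - gap_penalty
            left = cur[j - 1] - gap_penalty
            if diag >= up and diag >= left:
                cur[j] = diag
                ptr_row[j] = 1
            elif up >= left:
                cur[j] = up
                ptr_row[j] = 2
            else:
                cur[j] = left
                ptr_row[j] = 3
        prev = cur
    pairs: List[Tuple[Optional[int], Optional[int]]] = []
    i, j = n_a, n_b
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 1:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif move == 2:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()
    return AlignmentPath(pairs=pairs, score=float(prev[n_b]), gap_penalty=gap_penalty)


def mapping_from_path(
    path: AlignmentPath, grid_a: np.ndarray, grid_b: np.ndarray
) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-linear time mapping A -> B through the matched path pairs."""
    matched = path.matched
    if len(matched) == 0:
        raise AlignmentError("path has no matched pairs; no RT mapping exists")
    xs = np.asarray(grid_a, dtype=float)[matched[:, 0]]
    ys = np.asarray(grid_b, dtype=float)[matched[:, 1]]
    if len(matched) == 1:
        offset = float(ys[0] - xs[0])
        return lambda t: np.asarray(t, dtype=float) + offset
    return _PiecewiseLinear(xs, ys)


def map_time(
    path: AlignmentPath, grid_a: np.ndarray, grid_b: np.ndarray, t: float
) -> float:
    """Map a run-A time to run-B time along an alignment path.

    Raises :class:`AlignmentError` when ``t`` falls more than one sampling
    interval outside run A's grid span.
    """
    grid_a = np.asarray(grid_a, dtype=float)
    dt = float(np.median(np.diff(grid_a)))
    if t < grid_a[0] - dt or t > grid_a[-1] + dt:
        raise AlignmentError(
            f"time {t:.3f} s is far outside grid A span "
            f"[{grid_a[0]:.3f}, {grid_a[-1]:.3f}]"
        )
    return float(mapping_from_path(path, grid_a, grid_b)(t))


# ---------------------------------------------------------------------------
# Method dispatch


def _path_from_fit(
    fit: GlobalFit, grid_a: np.ndarray, grid_b: np.ndarray
) -> AlignmentPath:
    """Discretize a global fit onto the grids as a monotone path (no DP)."""
    targets = np.searchsorted(grid_b, np.asarray(fit(grid_a), dtype=float))
    targets = np.clip(targets, 0, len(grid_b) - 1)
    # snap to nearest of the two flanking grid points
    left = np.clip(targets - 1, 0, len(grid_b) - 1)
    pick_left = np.abs(grid_b[left] - fit(grid_a)) < np.abs(
        grid_b[targets] - fit(grid_a)
    )
    targets = np.where(pick_left, left, targets)
    targets = np.maximum.accumulate(targets)
    pairs: List[Tuple[Optional[int], Optional[int]]] = []
    j_done = -1
    for i, jt in enumerate(targets):
        jt = int(jt)
        for j in range(j_done + 1, jt):
            pairs.append((None, j))
        if jt > j_done:
            pairs.append((i, jt))
            j_done = jt
        else:
            pairs.append((i, None))
    for j in range(j_done + 1, len(grid_b)):
        pairs.append((None, j))
    return AlignmentPath(pairs=pairs, score=float("nan"), gap_penalty=0.0)


def align_pair(
    group_a: XicGroup,
    group_b: XicGroup,
    method: str = "hybrid",
    fit: Optional[GlobalFit] = None,
    config: Optional[AlignConfig] = None,
) -> AlignmentPath:
    """Align two XIC groups with the chosen pairwise method."""
    config = config or AlignConfig()
    if method in ("global", "hybrid") and fit is None:
        raise AlignmentError(f"method {method!r} requires a GlobalFit")
    if method == "global":
        return _path_from_fit(fit, group_a.times, group_b.times)
    sim = compute_similarity(
        group_a,
        group_b,
        measure=config.measure,
        smooth=config.smooth,
        smooth_window=config.smooth_window,
        mask_factor=config.mask_factor,
    )
    if method == "hybrid":
        sim = constrain(
            sim,
            fit,
            rse_factor=config.rse_factor,
            min_band_seconds=config.min_band_seconds,
            hard=config.hard_constrain,
            penalty=config.soft_penalty,
            min_band_intervals=config.min_band_intervals,
        )
    elif method != "local":
        raise AlignmentError(f"unknown pairwise method {method!r}")
    return align_dp(sim, gap_quantile=config.gap_quantile)
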