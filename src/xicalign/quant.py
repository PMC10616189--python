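"""Alignment-guided peak selection, signal integration and quantitation.

Peak selection is two-tier: a candidate whose apex falls inside a window
around the aligned reference time is accepted up to the alignment-assisted
q-value ceiling (``aligned_fdr2``); a candidate outside the window is only
accepted up to the stricter direct-acceptance ceiling (``aligned_fdr1``)
when nothing inside the window qualifies, and is flagged. When no scored
candidate survives, the fragment signal inside the aligned boundaries is
integrated into a new score-less feature, so the matrix gains a
quantification without inventing a confidence estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    AnnotationTable,
    Feature,
    IntensityMatrix,
    PROVENANCE_INTEGRATED,
    PROVENANCE_PICKED,
    PROVENANCE_REASSIGNED,
    ValidationError,
    XicGroup,
    split_precursor_id,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionParams",
    "QuantResult",
    "pick_aligned_peak",
    "integrate_signal",
    "transpose_across_charges",
    "assemble_matrix",
    "quantitation_error_rate",
    "cv_metrics",
    "summarize_proteins",
]


@dataclass
class SelectionParams:
    """FDR thresholds and window settings for aligned peak selection.

    Defaults follow common practice for this workflow family: candidate
    query ceiling and both alignment FDR tiers at 0.05, final matrix
    filters (peak-group mscore and peptide q value) at 0.025, and signal
    integration within run enabled.
    """

    max_fdr_query: float = 0.05
    aligned_fdr1: float = 0.05  # direct acceptance (outside the window)
    aligned_fdr2: float = 0.05  # alignment-assisted acceptance (inside)
    window_seconds: Optional[float] = None  # None: adaptive, 3.5*rse floor 3 dt
    window_rse_factor: float = 3.5
    window_min_intervals: float = 3.0
    final_mscore: float = 0.025
    final_qvalue: float = 0.025
    enable_integration_within_run: bool = True
    enable_integration_across_runs: bool = True
    baseline_subtraction: bool = False

    def __post_init__(self) -> None:
        if not (self.aligned_fdr1 <= self.aligned_fdr2 <= self.max_fdr_query):
            raise ValidationError(
                "require aligned_fdr1 <= aligned_fdr2 <= max_fdr_query"
            )
        if self.window_seconds is not None and self.window_seconds <= 0:
            raise ValidationError("window_seconds must be > 0")

    def window_for(self, rse: float, sampling_interval: float) -> float:
        if self.window_seconds is not None:
            return self.window_seconds
        return max(
            self.window_rse_factor * rse,
            self.window_min_intervals * sampling_interval,
        )


def pick_aligned_peak(
    candidates: Sequence[Feature],
    t_ref: float,
    params: SelectionParams,
    window_seconds: float,
) -> Optional[Feature]:
    """Select the peak for one run given the aligned reference time.

    Candidates must be pre-filtered to ``q_value <= max_fdr_query``. The
    lowest-p candidate inside the window wins if its q value passes the
    alignment-assisted ceiling; an out-of-window candidate is returned
    (flagged) only under the direct ceiling when nothing inside qualifies.
    """
    if not math.isfinite(t_ref):
        raise ValidationError("aligned reference time must be finite")
    scored = [
        c
        for c in candidates
        if c.q_value is not None and c.q_value <= params.max_fdr_query
    ]
    inside = [c for c in scored if abs(c.rt_apex - t_ref) <= window_seconds]
    inside_ok = [c for c in inside if c.q_value <= params.aligned_fdr2]
    if inside_ok:
        return min(inside_ok, key=lambda c: (_p_or_q(c), c.rt_apex))
    outside_ok = [
        c
        for c in scored
        if abs(c.rt_apex - t_ref) > window_seconds
        and c.q_value <= params.aligned_fdr1
    ]
    if outside_ok:
        best = min(outside_ok, key=lambda c: (_p_or_q(c), c.rt_apex))
        best = best.reassigned() if best.provenance == PROVENANCE_PICKED else best
        best.flag = "outside-window"
        return best
    return None


def _p_or_q(f: Feature) -> float:
    return f.p_value if f.p_value is not None else f.q_value


def integrate_signal(
    group: XicGroup,
    left: float,
    right: float,
    baseline_subtraction: bool = False,
) -> Feature:
    """Integrate fragment traces over [left, right] into a score-less feature.

    Intensity is the trapezoidal area of each fragment trace over the
    window, summed across fragments, optionally after subtracting the
    straight line through the window's end points (linear baseline). The
    apex is the in-window maximum of the summed trace.
    """
    times = group.times
    dt = group.sampling_interval
    if right - left < 2 * dt:
        raise ValidationError(
            f"integration window [{left:.2f}, {right:.2f}] narrower than "
            f"two sampling intervals ({dt:.2f} s each)"
        )
    if right <= times[0] or left >= times[-1]:
        raise ValidationError(
            f"integration window [{left:.2f}, {right:.2f}] outside the grid "
            f"span [{times[0]:.2f}, {times[-1]:.2f}]"
        )
    lo = max(left, times[0])
    hi = min(right, times[-1])
    # refine the window grid with interpolated end points
    inner = times[(times > lo) & (times < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    total = 0.0
    for trace in group.traces:
        vals = np.interp(grid, times, trace.intensities)
        if baseline_subtraction:
            base = np.interp(grid, [lo, hi], [vals[0], vals[-1]])
            vals = np.clip(vals - base, 0.0, None)
        total += float(np.trapezoid(vals, grid))
    summed = group.summed
    in_win = (times >= lo) & (times <= hi)
    if in_win.any():
        apex = float(times[in_win][np.argmax(summed[in_win])])
    else:
        apex = (lo + hi) / 2.0
    apex = min(max(apex, left + 1e-9), right - 1e-9)
    feature = Feature(
        precursor_id=group.precursor_id,
        run_id=group.run_id,
        rt_apex=apex,
        left_boundary=left,
        right_boundary=right,
        intensity=total,
        provenance=PROVENANCE_INTEGRATED,
    )
    if total == 0.0:
        feature.flag = "low-signal"
    return feature


def transpose_across_charges(
    features_by_cell: Mapping[Tuple[str, str], Sequence[Feature]],
    xics: Mapping[Tuple[str, str], XicGroup],
    params: SelectionParams,
) -> List[Feature]:
    """Within-run signal integration across charge states of one peptide.

    The boundaries of the best-scoring charge state are copied, without
    any time mapping, to sibling charge states of the same sequence in the
    same run that lack a qualifying feature; the signal there is
    integrated. A transposed window over an empty trace still yields a
    (zero-intensity, flagged) feature so the event is recorded.
    """
    by_seq_run: Dict[Tuple[str, str], List[str]] = {}
    for (prec, run) in set(features_by_cell) | set(xics):
        seq, _ = split_precursor_id(prec)
        group = by_seq_run.setdefault((seq, run), [])
        if prec not in group:
            group.append(prec)
    out: List[Feature] = []
    for (seq, run), precs in sorted(by_seq_run.items()):
        if len(precs) < 2:
            continue
        qualifying: Dict[str, Optional[Feature]] = {}
        for prec in precs:
            cands = [
                f
                for f in features_by_cell.get((prec, run), ())
                if f.q_value is not None and f.q_value <= params.max_fdr_query
            ]
            qualifying[prec] = (
                min(cands, key=lambda f: (f.q_value, f.rt_apex)) if cands else None
            )
        donors = [f for f in qualifying.values() if f is not None]
        if not donors:
            continue
        donor = min(donors, key=lambda f: (f.q_value, f.rt_apex))
        for prec in sorted(precs):
            if qualifying[prec] is not None:
                continue
            group = xics.get((prec, run))
            if group is None:
                continue
            try:
                out.append(
                    integrate_signal(
                        group,
                        donor.left_boundary,
                        donor.right_boundary,
                        params.baseline_subtraction,
                    )
                )
            except ValidationError:
                logger.debug(
                    "charge transposition window invalid for %s in %s", prec, run
                )
    return out


@dataclass
class QuantResult:
    """The quantitative matrix with per-cell provenance and change report."""

    matrix: IntensityMatrix
    report: Dict[str, int] = field(default_factory=dict)

    def boundaries(self, precursor: str, run: str) -> Optional[Tuple[float, float]]:
        f = self.matrix.cell(precursor, run)
        if f is None:
            return None
        return (f.left_boundary, f.right_boundary)


def assemble_matrix(
    precursors: Sequence[str],
    runs: Sequence[str],
    selections: Mapping[Tuple[str, str], Optional[Feature]],
    original_picks: Mapping[Tuple[str, str], Optional[Feature]],
    params: SelectionParams,
) -> QuantResult:
    """Fill the intensity matrix from per-cell selections.

    Scored cells must pass both final filters (mscore and q value);
    integrated features are exempt from the score filters but obey the
    enable flags. The report counts quantitation-event changes relative to
    the score-only picks: unchanged / reassigned / removed / integrated.
    """
    matrix = IntensityMatrix(precursors, runs)
    final_ceiling = min(params.final_mscore, params.final_qvalue)
    report = {"unchanged": 0, "reassigned": 0, "removed": 0, "integrated": 0}
    for prec in precursors:
        for run in runs:
            selected = selections.get((prec, run))
            original = original_picks.get((prec, run))
            if selected is not None and selected.provenance == PROVENANCE_INTEGRATED:
                if (
                    params.enable_integration_across_runs
                    or params.enable_integration_within_run
                ):
                    matrix.set_cell(selected)
                    report["integrated"] += 1
                continue
            if selected is not None and selected.q_value is not None:
                if selected.q_value <= final_ceiling:
                    matrix.set_cell(selected)
                    if original is not None and _same_peak(selected, original):
                        report["unchanged"] += 1
                    else:
                        report["reassigned"] += 1
                    continue
            if original is not None and (
                original.q_value is not None
                and original.q_value <= final_ceiling
            ):
                report["removed"] += 1
    return QuantResult(matrix=matrix, report=report)


def _same_peak(a: Feature, b: Feature) -> bool:
    return abs(a.rt_apex - b.rt_apex) <= 1e-6


def _overlaps(a: Tuple[float, float], b: Tuple[float, float]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def quantitation_error_rate(
    result: QuantResult,
    annotations: AnnotationTable,
    thresholds: Sequence[float] = (0.01, 0.05),
) -> pd.DataFrame:
    """Compare selected peaks against manual annotations per q-value cutoff.

    Over annotated, scored (non-integrated) cells whose q value passes the
    cutoff: a peak is correct when its boundaries overlap the annotated
    ones; it is incorrect when the annotation says absent or there is no
    overlap. Both the correct and the incorrect fraction are reported;
    integrated, score-less cells are excluded entirely.
    """
    if len(annotations) == 0:
        raise ValidationError("annotation table is empty")
    cells = []
    for (prec, run), feature in result.matrix.features.items():
        verdict = annotations.get(prec, run)
        if verdict == "unknown":
            continue
        if feature.provenance == PROVENANCE_INTEGRATED or feature.q_value is None:
            continue
        correct = verdict is not None and _overlaps(
            (feature.left_boundary, feature.right_boundary), verdict
        )
        cells.append((feature.q_value, correct))
    if not cells:
        raise ValidationError(
            "no overlap between annotations and scored matrix cells"
        )
    rows = []
    for thr in thresholds:
        passing = [c for q, c in cells if q <= thr]
        total = len(passing)
        n_correct = sum(passing)
        rows.append(
            {
                "threshold": thr,
                "total_peaks": total,
                "correct_fraction": (n_correct / total) if total else float("nan"),
                "incorrect_fraction": (
                    (total - n_correct) / total if total else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def cv_metrics(
    matrix: IntensityMatrix, site_labels: Optional[Mapping[str, str]] = None
) -> Dict[str, object]:
    """Coefficient of variation (sd / mean, linear scale) per analyte.

    Returns per-analyte cross-site CVs, the cross-site summary (CV over
    all runs, averaged over analytes) and, when site labels are given, the
    site-specific summary (mean over within-site CVs). Analytes with zero
    mean or fewer than two values in a grouping are excluded and flagged.
    """
    values = matrix.values
    flagged: List[str] = []

    def cv_of(row: pd.Series) -> float:
        x = row.dropna().to_numpy(dtype=float)
        if len(x) < 2:
            return float("nan")
        m = x.mean()
        if m == 0:
            return float("nan")
        return float(x.std(ddof=1) / m)

    cross = values.apply(cv_of, axis=1)
    flagged.extend(list(cross.index[cross.isna()]))
    out: Dict[str, object] = {
        "per_analyte_cross_site": cross,
        "cross_site_mean_cv": float(cross.dropna().mean()),
        "flagged_analytes": sorted(set(flagged)),
    }
    if site_labels:
        sites = sorted(set(site_labels.values()))
        per_site = {}
        for site in sites:
            cols = [r for r in values.columns if site_labels.get(r) == site]
            if len(cols) >= 2:
                per_site[site] = values[cols].apply(cv_of, axis=1)
        if per_site:
            site_df = pd.DataFrame(per_site)
            per_analyte_site = site_df.mean(axis=1, skipna=True)
            out["per_analyte_site_specific"] = per_analyte_site
            out["site_specific_mean_cv"] = float(per_analyte_site.dropna().mean())
    return out


def summarize_proteins(
    matrix: IntensityMatrix,
    protein_of: Mapping[str, str],
    top_peptides: int = 3,
) -> pd.DataFrame:
    """Top-k protein rollup: sum the top peptides per protein per run.

    A plain convenience summarizer (no inference model): peptides are
    ranked per protein by mean intensity across runs.
    """
    values = matrix.values
    groups: Dict[str, List[str]] = {}
    for prec in values.index:
        prot = protein_of.get(prec)
        if prot is not None:
            groups.setdefault(prot, []).append(prec)
    rows = {}
    for prot, precs in sorted(groups.items()):
        sub = values.loc[precs]
        ranked = sub.mean(axis=1, skipna=True).sort_values(ascending=False)
        rows[prot] = sub.loc[ranked.index[:top_peptides]].sum(axis=0, min_count=1)
    return pd.DataFrame(rows).T
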