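"""End-to-end orchestration: strategy -> mapped references -> matrix.

`align_experiment` is the library entry point the CLI wraps: it builds the
guide structure required by the chosen multirun strategy, maps a reference
peak into every run for every precursor, runs two-tier aligned peak
selection (with signal integration for cells left empty), and assembles
the quantitative matrix together with a change report against score-only
selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import Feature, IntensityMatrix, ValidationError, XicGroup
from .multirun import (
    GuideTree,
    MappedReference,
    MasterRun,
    PairwiseCache,
    build_distance_matrix,
    build_hierarchy,
    build_mst,
    features_by_cell,
    mst_align,
    progressive_align,
    star_align,
)
from .pairwise import AlignConfig
from .quant import (
    QuantResult,
    SelectionParams,
    assemble_matrix,
    integrate_signal,
    pick_aligned_peak,
    transpose_across_charges,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentOutcome",
    "score_only_picks",
    "baseline_matrix",
    "align_experiment",
    "completeness_at",
    "error_completeness_curves",
]


@dataclass
class AlignmentOutcome:
    """Everything a workflow invocation produced."""

    result: QuantResult
    references: Dict[str, Dict[str, MappedReference]]
    tree: Optional[GuideTree] = None
    masters: Dict[str, MasterRun] = field(default_factory=dict)
    fit_rses: List[float] = field(default_factory=list)


def score_only_picks(
    fmap: Mapping[Tuple[str, str], Sequence[Feature]],
    precursors: Sequence[str],
    runs: Sequence[str],
) -> Dict[Tuple[str, str], Optional[Feature]]:
    """The classifier's unaligned choice: highest d-score per cell."""
    picks: Dict[Tuple[str, str], Optional[Feature]] = {}
    for prec in precursors:
        for run in runs:
            cands = [
                f
                for f in fmap.get((prec, run), ())
                if f.d_score is not None and f.q_value is not None
            ]
            picks[(prec, run)] = (
                max(cands, key=lambda f: (f.d_score, -f.rt_apex)) if cands else None
            )
    return picks


def baseline_matrix(
    precursors: Sequence[str],
    runs: Sequence[str],
    fmap: Mapping[Tuple[str, str], Sequence[Feature]],
    params: SelectionParams,
) -> QuantResult:
    """Score-only matrix: classifier picks filtered at the final ceilings."""
    picks = score_only_picks(fmap, precursors, runs)
    return assemble_matrix(precursors, runs, picks, picks, params)


def align_experiment(
    precursors: Sequence[str],
    runs: Sequence[str],
    features: Sequence[Feature],
    xics: Mapping[Tuple[str, str], XicGroup],
    strategy: str = "mst",
    method: str = "hybrid",
    config: Optional[AlignConfig] = None,
    params: Optional[SelectionParams] = None,
    site_labels: Optional[Mapping[str, str]] = None,
) -> AlignmentOutcome:
    """Run one multirun strategy end-to-end and assemble the matrix."""
    config = config or AlignConfig()
    params = params or SelectionParams()
    precursors = sorted(set(precursors))
    runs = sorted(set(runs))
    fmap = features_by_cell(features)
    cache = PairwiseCache(fmap, dict(xics), config, method=method)

    tree: Optional[GuideTree] = None
    masters: Dict[str, MasterRun] = {}
    fit_rses: List[float] = []
    references: Dict[str, Dict[str, MappedReference]] = {}

    if strategy == "star":
        for prec in precursors:
            references[prec] = star_align(prec, runs, cache, params.max_fdr_query)
        fit_rses = [f.rse for f in cache._fits.values()]
    elif strategy == "mst":
        dist = build_distance_matrix(runs, features, config)
        tree = build_mst(dist)
        for prec in precursors:
            references[prec] = mst_align(prec, tree, cache, params.max_fdr_query)
        idx = {r: i for i, r in enumerate(dist.run_ids)}
        fit_rses = [dist.d[idx[a], idx[b]] for a, b in tree.edges]
    elif strategy == "progressive":
        dist = build_distance_matrix(runs, features, config)
        tree = build_hierarchy(dist, dict(site_labels) if site_labels else None)
        references, masters, fit_rses = progressive_align(
            precursors, tree, fmap, dict(xics), config, params.max_fdr_query
        )
    else:
        raise ValidationError(f"unknown multirun strategy {strategy!r}")

    originals = score_only_picks(fmap, precursors, runs)
    selections: Dict[Tuple[str, str], Optional[Feature]] = {}
    for prec in precursors:
        refs = references.get(prec, {})
        for run in runs:
            cell = (prec, run)
            candidates = [
                f
                for f in fmap.get(cell, ())
                if f.q_value is not None and f.q_value <= params.max_fdr_query
            ]
            ref = refs.get(run)
            selected: Optional[Feature] = None
            if ref is not None:
                group = xics.get(cell)
                dt = group.sampling_interval if group is not None else 3.4
                # the aligned peak boundaries realize "a window about the
                # aligned time"; floor at a few sampling intervals
                if params.window_seconds is not None:
                    window = params.window_seconds
                else:
                    window = max(
                        (ref.right - ref.left) / 2.0,
                        params.window_min_intervals * dt,
                    )
                selected = pick_aligned_peak(candidates, ref.apex, params, window)
                if (
                    selected is None
                    and params.enable_integration_across_runs
                    and group is not None
                ):
                    try:
                        selected = integrate_signal(
                            group, ref.left, ref.right, params.baseline_subtraction
                        )
                    except ValidationError:
                        selected = None
            else:
                # no alignment support for this cell: direct acceptance tier
                direct = [
                    c for c in candidates if c.q_value <= params.aligned_fdr1
                ]
                if direct:
                    selected = min(
                        direct,
                        key=lambda c: (
                            c.p_value if c.p_value is not None else c.q_value,
                            c.rt_apex,
                        ),
                    )
            original = originals.get(cell)
            if (
                selected is not None
                and selected.q_value is not None
                and original is not None
                and abs(selected.rt_apex - original.rt_apex) > 1e-9
                and selected.provenance == "picked"
            ):
                selected = selected.reassigned()
            selections[cell] = selected

    if params.enable_integration_within_run:
        for feat in transpose_across_charges(fmap, xics, params):
            cell = (feat.precursor_id, feat.run_id)
            if cell in selections and selections[cell] is None:
                selections[cell] = feat

    result = assemble_matrix(precursors, runs, selections, originals, params)
    return AlignmentOutcome(
        result=result,
        references=references,
        tree=tree,
        masters=masters,
        fit_rses=fit_rses,
    )


def completeness_at(result: QuantResult, threshold: float) -> float:
    """Fraction of matrix cells quantified at a q-value cutoff.

    Integrated (score-less) cells count as quantified at any cutoff.
    """
    matrix = result.matrix
    total = len(matrix.precursors) * len(matrix.runs)
    n = 0
    for feature in matrix.features.values():
        if feature.q_value is None or feature.q_value <= threshold:
            n += 1
    return n / total if total else float("nan")


def error_completeness_curves(
    aligned: QuantResult,
    unaligned: QuantResult,
    annotations,
    thresholds: Sequence[float] = (0.005, 0.01, 0.025, 0.05),
) -> pd.DataFrame:
    """Error-rate and completeness versus q-value cutoff, aligned vs not."""
    from .quant import quantitation_error_rate

    err_a = quantitation_error_rate(aligned, annotations, thresholds)
    err_u = quantitation_error_rate(unaligned, annotations, thresholds)
    rows = []
    for k, thr in enumerate(thresholds):
        rows.append(
            {
                "threshold": thr,
                "error_rate_aligned": err_a.loc[k, "incorrect_fraction"],
                "error_rate_unaligned": err_u.loc[k, "incorrect_fraction"],
                "completeness_aligned": completeness_at(aligned, thr),
                "completeness_unaligned": completeness_at(unaligned, thr),
            }
        )
    return pd.DataFrame(rows)
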