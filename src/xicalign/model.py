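"""Core domain types for multirun DIA chromatogram alignment.

The unit of alignment is the :class:`XicGroup` — the set of fragment-ion
extracted-ion chromatograms (XICs) of one precursor in one LC-MS/MS run,
all sampled on a single time grid. Scored candidate peaks produced by an
upstream peak picker / classifier are represented as :class:`Feature`
objects; the workflow's end product is an :class:`IntensityMatrix` of
precursors x runs with per-cell provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "XicAlignError",
    "FormatError",
    "ValidationError",
    "FitError",
    "AlignmentError",
    "Run",
    "Xic",
    "XicGroup",
    "Feature",
    "AnnotationTable",
    "IntensityMatrix",
    "split_precursor_id",
]


class XicAlignError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(XicAlignError):
    """A file could not be parsed in the named format."""


class ValidationError(XicAlignError):
    """An object violates a domain invariant."""


class FitError(XicAlignError):
    """A retention-time fit could not be computed (e.g. too few anchors)."""


class AlignmentError(XicAlignError):
    """A pairwise or multirun alignment could not be produced."""


def split_precursor_id(precursor_id: str) -> Tuple[str, int]:
    """Split ``"SEQUENCE/charge"`` into ``(sequence, charge)``.

    Raises :class:`ValidationError` if no charge suffix is present.
    """
    seq, sep, z = precursor_id.rpartition("/")
    if not sep or not z.isdigit():
        raise ValidationError(
            f"precursor id {precursor_id!r} is not of the form 'SEQUENCE/charge'"
        )
    return seq, int(z)


@dataclass(frozen=True)
class Run:
    """One LC-MS/MS injection, optionally tagged with an acquisition site."""

    run_id: str
    site_id: Optional[str] = None


@dataclass
class Xic:
    """A single extracted-ion chromatogram: intensity versus retention time.

    times are seconds and strictly increasing; intensities are finite,
    non-negative ion counts on the same grid.
    """

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError("XIC times/intensities must be 1-D")
        if len(self.times) != len(self.intensities):
            raise ValidationError(
                f"XIC length mismatch: {len(self.times)} times vs "
                f"{len(self.intensities)} intensities"
            )
        if len(self.times) < 2:
            raise ValidationError("an XIC needs at least 2 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("XIC time grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValidationError("XIC intensities must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class XicGroup:
    """All fragment-ion XICs of one precursor in one run, on a shared grid."""

    precursor_id: str
    run_id: str
    fragment_ids: List[str]
    traces: List[Xic]

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValidationError("XicGroup needs at least one trace")
        if len(self.fragment_ids) != len(self.traces):
            raise ValidationError("one fragment_id per trace required")
        t0 = self.traces[0].times
        for frag, tr in zip(self.fragment_ids, self.traces):
            if len(tr.times) != len(t0) or not np.array_equal(tr.times, t0):
                raise ValidationError(
                    f"trace {frag!r} of {self.precursor_id!r} in run "
                    f"{self.run_id!r} does not share the group time grid"
                )

    @property
    def times(self) -> np.ndarray:
        return self.traces[0].times

    @property
    def intensity_matrix(self) -> np.ndarray:
        """Fragment x time intensity matrix."""
        return np.vstack([tr.intensities for tr in self.traces])

    @property
    def summed(self) -> np.ndarray:
        """Total ion intensity across fragments at each time point."""
        return self.intensity_matrix.sum(axis=0)

    @property
    def sampling_interval(self) -> float:
        return float(np.median(np.diff(self.times)))

    def __len__(self) -> int:
        return len(self.times)


# Provenance values a quantified cell can carry.
PROVENANCE_PICKED = "picked"
PROVENANCE_REASSIGNED = "aligned-reassigned"
PROVENANCE_INTEGRATED = "integrated"
_PROVENANCES = {PROVENANCE_PICKED, PROVENANCE_REASSIGNED, PROVENANCE_INTEGRATED}


@dataclass
class Feature:
    """One candidate peak of a precursor in a run.

    ``d_score`` is the discriminant score of the upstream classifier;
    ``p_value`` and ``q_value`` are its error estimates (the q value is the
    peak-group "mscore"). Features created by signal integration carry no
    scores at all.
    """

    precursor_id: str
    run_id: str
    rt_apex: float
    left_boundary: float
    right_boundary: float
    intensity: float
    d_score: Optional[float] = None
    p_value: Optional[float] = None
    q_value: Optional[float] = None
    provenance: str = PROVENANCE_PICKED
    flag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.provenance not in _PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if not (self.left_boundary < self.rt_apex < self.right_boundary):
            raise ValidationError(
                f"feature for {self.precursor_id!r} in {self.run_id!r}: "
                f"boundaries must satisfy left < apex < right, got "
                f"({self.left_boundary}, {self.rt_apex}, {self.right_boundary})"
            )
        if self.provenance == PROVENANCE_INTEGRATED:
            if self.p_value is not None or self.q_value is not None:
                raise ValidationError("integrated features carry no p/q value")
        else:
            for name in ("p_value", "q_value"):
                v = getattr(self, name)
                if v is not None and not (0.0 < v <= 1.0):
                    raise ValidationError(f"{name} must lie in (0, 1], got {v}")

    def reassigned(self) -> "Feature":
        return replace(self, provenance=PROVENANCE_REASSIGNED)


class AnnotationTable:
    """Manually validated peak boundaries per precursor x run.

    A cell maps to an ``(left, right)`` interval, or to ``None`` for an
    explicit "analyte absent in this run" verdict. Cells not covered by the
    table are unknown and excluded from error-rate computations.
    """

    def __init__(
        self,
        entries: Optional[
            Dict[Tuple[str, str], Optional[Tuple[float, float]]]
        ] = None,
    ) -> None:
        self._entries: Dict[Tuple[str, str], Optional[Tuple[float, float]]] = {}
        for key, val in (entries or {}).items():
            self.set(key[0], key[1], val)

    def set(
        self, precursor_id: str, run_id: str, interval: Optional[Tuple[float, float]]
    ) -> None:
        if interval is not None:
            left, right = interval
            if not left < right:
                raise ValidationError(
                    f"annotation for ({precursor_id}, {run_id}): "
                    f"boundaries out of order ({left}, {right})"
                )
            interval = (float(left), float(right))
        self._entries[(precursor_id, run_id)] = interval

    def get(self, precursor_id: str, run_id: str):
        return self._entries.get((precursor_id, run_id), "unknown")

    def __contains__(self, key: Tuple[str, str]) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()


class IntensityMatrix:
    """Precursor x run intensity table with per-cell provenance.

    Backed by two aligned pandas DataFrames (values, provenance); missing
    cells are NaN / empty-string. Every non-missing cell traces to exactly
    one Feature, kept in ``features``.
    """

    def __init__(self, precursors: Sequence[str], runs: Sequence[str]) -> None:
        if len(set(runs)) != len(runs):
            raise ValidationError("run ids must be unique")
        self.values = pd.DataFrame(
            np.nan, index=list(precursors), columns=list(runs), dtype=float
        )
        self.provenance = pd.DataFrame(
            "", index=list(precursors), columns=list(runs), dtype=object
        )
        self.features: Dict[Tuple[str, str], Feature] = {}

    @property
    def precursors(self) -> List[str]:
        return list(self.values.index)

    @property
    def runs(self) -> List[str]:
        return list(self.values.columns)

    def set_cell(self, feature: Feature) -> None:
        key = (feature.precursor_id, feature.run_id)
        if key in self.features:
            raise ValidationError(
                f"duplicate feature for cell {key}: one feature per cell"
            )
        self.values.loc[key] = feature.intensity
        self.provenance.loc[key] = feature.provenance
        self.features[key] = feature

    def completeness(self) -> float:
        """Fraction of non-missing cells."""
        return float(self.values.notna().values.mean())

    def cell(self, precursor_id: str, run_id: str) -> Optional[Feature]:
        return self.features.get((precursor_id, run_id))
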