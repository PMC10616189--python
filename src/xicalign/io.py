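"""Readers and writers for chromatograms, feature tables and matrices.

Two chromatogram formats are supported:

* a plain TSV dialect with columns ``precursor_id, fragment_id, time_sec,
  intensity`` — the round-trippable desk-scale format;
* mzML restricted to ``<chromatogram>`` entries (the shape of targeted
  extraction output). Chromatogram ids follow ``"<precursor_id>|<fragment_id>"``;
  time arrays tagged in minutes are converted to seconds on read.

All readers validate domain invariants and refuse to repair broken input.
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from lxml import etree

from .model import (
    AnnotationTable,
    Feature,
    FormatError,
    IntensityMatrix,
    ValidationError,
    Xic,
    XicGroup,
)

logger = logging.getLogger(__name__)

XIC_TSV_COLUMNS = ["precursor_id", "fragment_id", "time_sec", "intensity"]
FEATURE_COLUMNS = [
    "precursor_id",
    "run_id",
    "rt_apex",
    "left_boundary",
    "right_boundary",
    "intensity",
    "d_score",
    "p_value",
    "q_value",
]

_MZML_NS = "http://psi.hupo.org/ms/mzml"
# PSI-MS controlled-vocabulary accessions used in chromatogram binary arrays
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_NO_COMPRESSION = "MS:1000576"
_CV_TIME_ARRAY = "MS:1000595"
_CV_INTENSITY_ARRAY = "MS:1000515"
_UNIT_MINUTE = "UO:0000031"


# ---------------------------------------------------------------------------
# TSV chromatogram dialect


def read_xics(path, format: str = "tsv", run_id: str = "") -> List[XicGroup]:
    """Read chromatograms grouped per precursor.

    ``format`` is ``"tsv"`` or ``"mzml"``. ``run_id`` is attached to every
    group (chromatogram files carry no run identity of their own).
    """
    if format == "tsv":
        return _read_xics_tsv(path, run_id)
    if format == "mzml":
        return _read_xics_mzml(path, run_id)
    raise FormatError(f"unknown chromatogram format {format!r}")


def _read_xics_tsv(path, run_id: str) -> List[XicGroup]:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc
    missing = [c for c in XIC_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    groups: List[XicGroup] = []
    for prec, sub in df.groupby("precursor_id", sort=True):
        fragment_ids: List[str] = []
        traces: List[Xic] = []
        for frag, fsub in sub.groupby("fragment_id", sort=True):
            fsub = fsub.sort_values("time_sec")
            times = fsub["time_sec"].to_numpy(dtype=float)
            if not np.all(np.diff(times) > 0):
                raise ValidationError(
                    f"{path}: non-monotone time grid for precursor {prec!r} "
                    f"fragment {frag!r}"
                )
            fragment_ids.append(str(frag))
            traces.append(Xic(times, fsub["intensity"].to_numpy(dtype=float)))
        groups.append(
            XicGroup(
                precursor_id=str(prec),
                run_id=run_id,
                fragment_ids=fragment_ids,
                traces=traces,
            )
        )
    return groups


def write_xics(groups: Iterable[XicGroup], path, format: str = "tsv") -> None:
    if format == "tsv":
        return _write_xics_tsv(groups, path)
    if format == "mzml":
        return _write_xics_mzml(groups, path)
    raise FormatError(f"unknown chromatogram format {format!r}")


def _write_xics_tsv(groups: Iterable[XicGroup], path) -> None:
    records = []
    for g in groups:
        for frag, tr in zip(g.fragment_ids, g.traces):
            for t, i in zip(tr.times, tr.intensities):
                records.append((g.precursor_id, frag, t, i))
    df = pd.DataFrame(records, columns=XIC_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# mzML (chromatogram entries only)


def _decode_binary(elem) -> np.ndarray:
    accessions = {
        cv.get("accession")
        for cv in elem.iterfind(f"{{{_MZML_NS}}}cvParam")
    }
    raw_el = elem.find(f"{{{_MZML_NS}}}binary")
    raw = base64.b64decode(raw_el.text or "")
    if _CV_ZLIB in accessions:
        raw = zlib.decompress(raw)
    if _CV_FLOAT32 in accessions:
        fmt = "f"
    elif _CV_FLOAT64 in accessions:
        fmt = "d"
    else:
        raise FormatError("binary array without a float precision cvParam")
    n = len(raw) // struct.calcsize(fmt)
    return np.asarray(struct.unpack("<%d%s" % (n, fmt), raw), dtype=float)


def _read_xics_mzml(path, run_id: str) -> List[XicGroup]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"cannot parse {path} as mzML: {exc}") from exc
    by_precursor: Dict[str, Tuple[List[str], List[Xic]]] = {}
    for chrom in tree.iter(f"{{{_MZML_NS}}}chromatogram"):
        cid = chrom.get("id") or ""
        if "|" not in cid:
            # TICs and other non-fragment chromatograms are skipped
            logger.debug("skipping chromatogram %r without '|' id", cid)
            continue
        precursor_id, _, fragment_id = cid.rpartition("|")
        times = intens = None
        for arr in chrom.iter(f"{{{_MZML_NS}}}binaryDataArray"):
            accs = {
                cv.get("accession"): cv
                for cv in arr.iterfind(f"{{{_MZML_NS}}}cvParam")
            }
            values = _decode_binary(arr)
            if _CV_TIME_ARRAY in accs:
                if accs[_CV_TIME_ARRAY].get("unitAccession") == _UNIT_MINUTE:
                    values = values * 60.0
                times = values
            elif _CV_INTENSITY_ARRAY in accs:
                intens = values
        if times is None or intens is None:
            raise FormatError(f"chromatogram {cid!r} lacks time/intensity arrays")
        if not np.all(np.diff(times) > 0):
            raise ValidationError(f"chromatogram {cid!r}: non-monotone time grid")
        fragment_ids, traces = by_precursor.setdefault(precursor_id, ([], []))
        fragment_ids.append(fragment_id)
        traces.append(Xic(times, intens))
    return [
        XicGroup(precursor_id=prec, run_id=run_id, fragment_ids=frags, traces=traces)
        for prec, (frags, traces) in sorted(by_precursor.items())
    ]


def _encode_binary(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack("<%dd" % len(values), *np.asarray(values, dtype=float))
    ).decode("ascii")


def _write_xics_mzml(groups: Iterable[XicGroup], path) -> None:
    groups = list(groups)
    nsmap = {None: _MZML_NS}
    root = etree.Element(f"{{{_MZML_NS}}}mzML", nsmap=nsmap, version="1.1.0")
    run = etree.SubElement(root, f"{{{_MZML_NS}}}run", id="xicalign_export")
    n = sum(len(g.traces) for g in groups)
    clist = etree.SubElement(
        run, f"{{{_MZML_NS}}}chromatogramList", count=str(n)
    )
    idx = 0
    for g in groups:
        for frag, tr in zip(g.fragment_ids, g.traces):
            chrom = etree.SubElement(
                clist,
                f"{{{_MZML_NS}}}chromatogram",
                id=f"{g.precursor_id}|{frag}",
                index=str(idx),
                defaultArrayLength=str(len(tr)),
            )
            idx += 1
            balist = etree.SubElement(
                chrom, f"{{{_MZML_NS}}}binaryDataArrayList", count="2"
            )
            for kind, values in (("time", tr.times), ("intensity", tr.intensities)):
                enc = _encode_binary(values)
                arr = etree.SubElement(
                    balist,
                    f"{{{_MZML_NS}}}binaryDataArray",
                    encodedLength=str(len(enc)),
                )

                def cv(acc, name, **extra):
                    etree.SubElement(
                        arr,
                        f"{{{_MZML_NS}}}cvParam",
                        cvRef="MS",
                        accession=acc,
                        name=name,
                        **extra,
                    )

                cv(_CV_FLOAT64, "64-bit float")
                cv(_CV_NO_COMPRESSION, "no compression")
                if kind == "time":
                    cv(
                        _CV_TIME_ARRAY,
                        "time array",
                        unitCvRef="UO",
                        unitAccession="UO:0000010",
                        unitName="second",
                    )
                else:
                    cv(_CV_INTENSITY_ARRAY, "intensity array")
                etree.SubElement(arr, f"{{{_MZML_NS}}}binary").text = enc
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# Feature tables


def read_features(path) -> List[Feature]:
    """Read a scored-feature TSV export (the OpenSWATH+PyProphet shape)."""
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        logger.warning("feature table %s is empty", path)
        return []
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing feature columns {missing}")
    if df.empty:
        logger.warning("feature table %s has no rows", path)
        return []
    features: List[Feature] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            features.append(
                Feature(
                    precursor_id=str(row.precursor_id),
                    run_id=str(row.run_id),
                    rt_apex=float(row.rt_apex),
                    left_boundary=float(row.left_boundary),
                    right_boundary=float(row.right_boundary),
                    intensity=float(row.intensity),
                    d_score=_opt_float(row.d_score),
                    p_value=_opt_float(row.p_value),
                    q_value=_opt_float(row.q_value),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {row_no}: {exc}") from exc
    return features


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def write_features(features: Iterable[Feature], path) -> None:
    rows = [
        {
            "precursor_id": f.precursor_id,
            "run_id": f.run_id,
            "rt_apex": f.rt_apex,
            "left_boundary": f.left_boundary,
            "right_boundary": f.right_boundary,
            "intensity": f.intensity,
            "d_score": f.d_score,
            "p_value": f.p_value,
            "q_value": f.q_value,
            "provenance": f.provenance,
        }
        for f in features
    ]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["provenance"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(path) -> AnnotationTable:
    """Read a manual-annotation TSV.

    Columns: precursor_id, run_id, left_boundary, right_boundary, absent.
    ``absent`` is 0/1; for absent cells the boundary fields are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["precursor_id", "run_id", "absent"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    table = AnnotationTable()
    for row in df.itertuples(index=False):
        if int(row.absent):
            table.set(str(row.precursor_id), str(row.run_id), None)
        else:
            table.set(
                str(row.precursor_id),
                str(row.run_id),
                (float(row.left_boundary), float(row.right_boundary)),
            )
    return table


def write_annotations(table: AnnotationTable, path) -> None:
    rows = []
    for (prec, run), interval in sorted(table.items()):
        absent = interval is None
        rows.append(
            {
                "precursor_id": prec,
                "run_id": run,
                "left_boundary": "" if absent else interval[0],
                "right_boundary": "" if absent else interval[1],
                "absent": int(absent),
            }
        )
    pd.DataFrame(
        rows,
        columns=["precursor_id", "run_id", "left_boundary", "right_boundary", "absent"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Intensity matrix


def write_matrix(matrix: IntensityMatrix, path) -> None:
    """Write the intensity matrix as TSV plus a ``.provenance.tsv`` sidecar.

    Missing cells are empty fields; the sidecar holds the per-cell
    provenance tags on the same layout.
    """
    df = matrix.values.copy()
    df.index.name = "precursor_id"
    df.to_csv(path, sep="\t", float_format="%.17g", na_rep="")
    prov = matrix.provenance.copy()
    prov.index.name = "precursor_id"
    prov.to_csv(_sidecar_path(path), sep="\t")


def _sidecar_path(path) -> str:
    return str(path) + ".provenance.tsv"


def read_matrix(path) -> IntensityMatrix:
    df = pd.read_csv(
        path, sep="\t", index_col="precursor_id", float_precision="round_trip"
    )
    matrix = IntensityMatrix(list(df.index), list(df.columns))
    matrix.values.loc[:, :] = df.values.astype(float)
    try:
        prov = pd.read_csv(
            _sidecar_path(path), sep="\t", index_col="precursor_id"
        ).fillna("")
        matrix.provenance.loc[:, :] = prov.values
    except FileNotFoundError:
        pass
    return matrix
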