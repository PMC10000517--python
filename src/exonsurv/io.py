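"""Readers and writers for the pipeline's tabular formats.

Column mapping is configured, never sniffed: each reader takes a mapping from
logical field names to the column headers actually present, with defaults
mirroring exon-level expression summary files (tab separated).  Readers log —
rather than silently apply — every dropped row, collapsed duplicate, and
unparseable cell in the returned object's ``provenance`` dict.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CLINICAL_COLUMNS,
    ENDPOINTS,
    EXON_QUANT_COLUMNS,
    KNOWN_MARKERS,
    ClinicalTable,
    ExonQuantTable,
    ExonRef,
    FormatError,
    ProbeMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Default header names for exon quantification TSVs.  ``location`` is the
#: combined "chrom:start-end" form; separate chrom/start/end columns are used
#: instead when present in the mapping.
EXON_QUANT_DEFAULT_COLUMNS: dict[str, str] = {
    "sample": "sample",
    "location": "location",
    "chrom": "chrom",
    "start": "start",
    "end": "end",
    "raw_count": "raw_count",
    "length_bp": "length_bp",
    "rpkm": "rpkm",
    "total_reads": "total_reads",
}

_LOCATION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def _parse_locations(series: pd.Series) -> pd.DataFrame:
    parts = series.astype(str).str.extract(_LOCATION_RE)
    if parts["chrom"].isna().any():
        bad = series[parts["chrom"].isna()].head(3).tolist()
        raise FormatError(f"unparseable exon locations, e.g. {bad}")
    return pd.DataFrame(
        {
            "chrom": parts["chrom"],
            "start": parts["start"].astype(int),
            "end": parts["end"].astype(int),
        }
    )


def read_exon_quant(
    path,
    panel: Sequence[ExonRef],
    columns: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> ExonQuantTable:
    """Read an exon-level quantification table restricted to ``panel``.

    Rows whose coordinates match no panel exon are dropped (count logged in
    provenance).  Duplicate (sample, exon) rows are retained and flagged;
    :func:`exonsurv.index.collapse_duplicates` averages them.
    """
    colmap = {**EXON_QUANT_DEFAULT_COLUMNS, **(columns or {})}
    raw = pd.read_csv(path, sep=sep)

    required = [colmap["sample"], colmap["raw_count"], colmap["length_bp"]]
    has_separate_coords = all(
        k in colmap and colmap[k] in raw.columns for k in ("chrom", "start", "end")
    )
    if not has_separate_coords:
        required.append(colmap["location"])
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    if has_separate_coords:
        coords = raw[[colmap["chrom"], colmap["start"], colmap["end"]]].copy()
        coords.columns = ["chrom", "start", "end"]
        coords["start"] = coords["start"].astype(int)
        coords["end"] = coords["end"].astype(int)
    else:
        coords = _parse_locations(raw[colmap["location"]])

    df = pd.DataFrame(
        {
            "sample": raw[colmap["sample"]].astype(str),
            "chrom": coords["chrom"],
            "start": coords["start"],
            "end": coords["end"],
            "raw_count": raw[colmap["raw_count"]].astype(int),
            "length_bp": raw[colmap["length_bp"]].astype(int),
        }
    )
    for opt in ("rpkm", "total_reads"):
        col = colmap.get(opt)
        df[opt] = raw[col].astype(float) if col in raw.columns else np.nan

    by_coord = {(e.chrom, e.start, e.end): e.exon_label for e in panel}
    keys = list(zip(df["chrom"], df["start"], df["end"]))
    df["exon_label"] = [by_coord.get(k) for k in keys]
    dropped = int(df["exon_label"].isna().sum())
    if dropped:
        log.warning("%s: dropped %d rows outside the %d-exon panel", path, dropped, len(panel))
    df = df.dropna(subset=["exon_label"]).reset_index(drop=True)

    n_dup = int(df.duplicated(["sample", "exon_label"]).sum())
    if n_dup:
        log.warning("%s: %d duplicate (sample, exon) rows flagged", path, n_dup)

    table = ExonQuantTable(
        df=df[list(EXON_QUANT_COLUMNS)],
        panel=tuple(panel),
        provenance={"rows_dropped_outside_panel": dropped, "duplicate_rows": n_dup},
    )
    return table


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

CLINICAL_DEFAULT_COLUMNS: dict[str, str] = {c: c for c in CLINICAL_COLUMNS}

_SEX_MAP = {"male": "male", "m": "male", "female": "female", "f": "female"}
_CNS_VALUES = {"CNS1", "CNS2", "CNS3"}
_NCI_MAP = {"standard": "standard", "high": "high", "sr": "standard", "hr": "high"}


def _coerce_float(series: pd.Series, prov: dict, field_name: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    n_bad = int(out.isna().sum() - series.isna().sum())
    if n_bad > 0:
        prov[f"unparseable_{field_name}"] = n_bad
        log.warning("%d unparseable %s cells set to missing", n_bad, field_name)
    return out.astype(float)


def _coerce_event(series: pd.Series) -> pd.Series:
    mapped = series.map(
        {1: 1.0, 0: 0.0, "1": 1.0, "0": 0.0, True: 1.0, False: 0.0,
         "yes": 1.0, "no": 0.0, 1.0: 1.0, 0.0: 0.0}
    )
    return mapped.astype(float)


def _parse_markers(val) -> object:
    if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
        return np.nan
    if isinstance(val, frozenset):
        return val
    items = {m.strip() for m in str(val).split(";") if m.strip()}
    unknown = items - KNOWN_MARKERS
    if unknown:
        raise ValidationError(f"unknown molecular markers: {sorted(unknown)}")
    return frozenset(items)


def read_clinical(
    path, columns: Mapping[str, str] | None = None, sep: str = "\t"
) -> ClinicalTable:
    """Read a clinical annotation table into a typed :class:`ClinicalTable`.

    Unparseable numeric cells become missing (count logged); event flags are
    coerced to 0/1.  A table from which no time/event column pair can be
    resolved is a format error.
    """
    colmap = {**CLINICAL_DEFAULT_COLUMNS, **(columns or {})}
    raw = pd.read_csv(path, sep=sep)
    if colmap["patient"] not in raw.columns:
        raise FormatError(f"{path}: no patient ID column {colmap['patient']!r}")
    resolvable = [
        ep
        for ep in ENDPOINTS
        if colmap[f"{ep}_time"] in raw.columns and colmap[f"{ep}_event"] in raw.columns
    ]
    if not resolvable:
        raise FormatError(f"{path}: no time/event column pair resolvable")

    prov: dict = {}
    out = pd.DataFrame({"patient": raw[colmap["patient"]].astype(str)})
    for fieldn in ("age_years", "wbc", "mrd_day29"):
        col = colmap[fieldn]
        out[fieldn] = (
            _coerce_float(raw[col], prov, fieldn) if col in raw.columns else np.nan
        )
    out["sex"] = (
        raw[colmap["sex"]].astype(str).str.lower().map(_SEX_MAP)
        if colmap["sex"] in raw.columns
        else np.nan
    )
    if colmap["cns_status"] in raw.columns:
        cns = raw[colmap["cns_status"]].astype(str).str.upper().str.replace(" ", "")
        out["cns_status"] = cns.where(cns.isin(_CNS_VALUES))
    else:
        out["cns_status"] = np.nan
    out["nci_risk"] = (
        raw[colmap["nci_risk"]].astype(str).str.lower().map(_NCI_MAP)
        if colmap["nci_risk"] in raw.columns
        else np.nan
    )
    out["markers"] = (
        raw[colmap["markers"]].map(_parse_markers)
        if colmap["markers"] in raw.columns
        else np.nan
    )
    out["karyotype_class"] = (
        raw[colmap["karyotype_class"]]
        if colmap["karyotype_class"] in raw.columns
        else np.nan
    )
    for ep in ENDPOINTS:
        tcol, ecol = colmap[f"{ep}_time"], colmap[f"{ep}_event"]
        if ep in resolvable:
            out[f"{ep}_time"] = _coerce_float(raw[tcol], prov, f"{ep}_time")
            out[f"{ep}_event"] = _coerce_event(raw[ecol])
        else:
            out[f"{ep}_time"] = np.nan
            out[f"{ep}_event"] = np.nan

    return ClinicalTable(df=out[list(CLINICAL_COLUMNS)], provenance=prov)


# ---------------------------------------------------------------------------
# Probe matrix
# ---------------------------------------------------------------------------

def read_probe_matrix(
    path,
    probe_map: Mapping[str, str],
    control_ids: Sequence[str] = (),
    log2_scale: bool = False,
    sep: str = "\t",
) -> ProbeMatrix:
    """Read a probes x samples intensity TSV (first column = probe ID).

    Probes absent from ``probe_map`` are dropped with a logged count.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0)
    keep = [p for p in raw.index if p in probe_map]
    n_dropped = len(raw.index) - len(keep)
    if n_dropped:
        log.warning("%s: dropped %d unmapped probe rows", path, n_dropped)
    mat = raw.loc[keep].astype(float)
    return ProbeMatrix(
        intensity=mat,
        probe_map={p: probe_map[p] for p in keep},
        control_ids=frozenset(control_ids),
        log2_scale=log2_scale,
        provenance={"probes_dropped_unmapped": n_dropped},
    )
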