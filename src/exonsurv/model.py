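"""Typed containers for the exon-quantification / clinical / probe-level data
the pipeline touches.

The central objects are thin dataclass wrappers around pandas DataFrames with
validation at construction and a provenance log recording every row the
readers dropped, collapsed, or failed to parse, so that no value is ever
silently altered on the way in.

Genomic coordinates are 1-based inclusive (the GRCh37 annotation convention
used by exon-level expression summaries), so an exon's length in base pairs
is ``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class FormatError(ValueError):
    """A file does not match the expected tabular dialect."""


# ---------------------------------------------------------------------------
# Exon references and built-in panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonRef:
    """A single exon of a gene on a genome build.

    ``start``/``end`` are 1-based inclusive genomic coordinates in bp.
    Strand is carried for bookkeeping but never enters length or index math
    (lengths are strand independent).
    """

    gene: str
    chrom: str
    start: int
    end: int
    exon_label: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"{self.exon_label}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


#: CD22 exons 11-14 on GRCh37 (all on the positive strand).  Exon 12 encodes
#: the cytoplasmic signalling elements lost in the exon-skipping defect; exons
#: 11, 13 and 14 flank it and serve as the within-gene reference panel.
CD22_E11_E14_PANEL: tuple[ExonRef, ...] = (
    ExonRef("CD22", "chr19", 35835954, 35836029, "E11"),
    ExonRef("CD22", "chr19", 35836505, 35836623, "E12"),
    ExonRef("CD22", "chr19", 35837054, 35837138, "E13"),
    ExonRef("CD22", "chr19", 35837469, 35838258, "E14"),
)

#: Default normalized-RPKM cutoff below which a patient is called low for the
#: target exon of the E11-E14 panel.
CD22_E12_LOW_THRESHOLD: float = 0.8

#: Cutoff for the exon-2 skipping panel (exons 1-4); configuration, not a
#: derived quantity.
CD22_E2_LOW_THRESHOLD: float = 0.397


# ---------------------------------------------------------------------------
# Exon quantification table
# ---------------------------------------------------------------------------

EXON_QUANT_COLUMNS = (
    "sample",
    "exon_label",
    "chrom",
    "start",
    "end",
    "length_bp",
    "raw_count",
    "total_reads",
    "rpkm",
)


@dataclass
class ExonQuantTable:
    """Per-sample, per-exon raw counts / lengths / RPKM for an exon panel.

    ``df`` is a long-format frame with the columns in :data:`EXON_QUANT_COLUMNS`
    (``total_reads`` and ``rpkm`` may be NaN where unknown).  ``provenance``
    records counts of dropped / duplicate / unparseable rows.
    """

    df: pd.DataFrame
    panel: tuple[ExonRef, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in EXON_QUANT_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"exon table missing columns: {missing}")
        df = self.df
        counts = df["raw_count"].to_numpy()
        if np.any(counts < 0):
            raise ValidationError("negative raw_count")
        if np.any(df["length_bp"].to_numpy() <= 0):
            raise ValidationError("non-positive exon length")
        total = df["total_reads"].to_numpy(dtype=float)
        bad = (counts > 0) & np.isfinite(total) & (total <= 0)
        if np.any(bad):
            raise ValidationError("total_reads <= 0 for rows with positive counts")
        rpkm = df["rpkm"].to_numpy(dtype=float)
        if np.any(rpkm[np.isfinite(rpkm)] < 0):
            raise ValidationError("negative RPKM")

    # -- convenience views -------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.df["sample"]))

    @property
    def exon_labels(self) -> list[str]:
        return [e.exon_label for e in self.panel]

    def duplicated_pairs(self) -> pd.DataFrame:
        """Rows belonging to a (sample, exon) pair that occurs more than once."""
        dup = self.df.duplicated(["sample", "exon_label"], keep=False)
        return self.df.loc[dup]

    @property
    def has_duplicates(self) -> bool:
        return bool(self.df.duplicated(["sample", "exon_label"]).any())

    def rpkm_matrix(self) -> pd.DataFrame:
        """samples x exon-labels RPKM matrix (requires unique pairs)."""
        if self.has_duplicates:
            raise ValidationError(
                "duplicate (sample, exon) rows present; collapse_duplicates first"
            )
        mat = self.df.pivot(index="sample", columns="exon_label", values="rpkm")
        return mat.reindex(columns=self.exon_labels)

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Clinical annotation table
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = (
    "patient",
    "age_years",
    "sex",
    "wbc",
    "mrd_day29",
    "cns_status",
    "nci_risk",
    "markers",
    "karyotype_class",
    "relapse_time",
    "relapse_event",
    "lfs_time",
    "lfs_event",
    "os_time",
    "os_event",
)

#: Molecular markers recognised in the ``markers`` set-valued column.
KNOWN_MARKERS = frozenset(
    {"BCR-ABL1", "MLL-R", "TCF3-PBX1", "ETV6-RUNX1", "trisomy4_10"}
)

#: Markers conferring poor-risk molecular classification.
POOR_RISK_MARKERS = frozenset({"BCR-ABL1", "MLL-R", "TCF3-PBX1"})

ENDPOINTS = ("relapse", "lfs", "os")


@dataclass
class ClinicalTable:
    """Per-patient covariates plus (time, event) pairs for each endpoint.

    ``markers`` holds frozensets of marker names (NaN when unevaluated);
    missing covariates stay missing — downstream models do complete-case
    deletion per model.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        df = self.df
        if df["patient"].duplicated().any():
            raise ValidationError("duplicate patient IDs in clinical table")
        for ep in ENDPOINTS:
            t = df[f"{ep}_time"].to_numpy(dtype=float)
            e = df[f"{ep}_event"].to_numpy(dtype=float)
            ok = np.isfinite(t)
            if np.any(t[ok] <= 0):
                raise ValidationError(f"{ep}_time must be > 0")
            ev = e[np.isfinite(e)]
            if not np.all(np.isin(ev, (0.0, 1.0))):
                raise ValidationError(f"{ep}_event flags must be 0/1")
        lfs = df["lfs_time"].to_numpy(dtype=float)
        os_ = df["os_time"].to_numpy(dtype=float)
        both = np.isfinite(lfs) & np.isfinite(os_)
        if np.any(lfs[both] > os_[both] + 1e-9):
            raise ValidationError("lfs_time exceeds os_time for some patient")

    @property
    def patients(self) -> list[str]:
        return list(self.df["patient"])

    def write_tsv(self, path) -> None:
        out = self.df.copy()
        out["markers"] = out["markers"].map(
            lambda m: ";".join(sorted(m)) if isinstance(m, frozenset) else np.nan
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Probe-level microarray matrix
# ---------------------------------------------------------------------------

@dataclass
class ProbeMatrix:
    """Probe x sample intensity matrix for a multi-probe exon panel.

    ``intensity``: probes (rows) x samples (columns); either linear-scale
    positive values or log2 values, disambiguated by ``log2_scale``.
    ``probe_map`` assigns each retained probe to exactly one exon label;
    ``control_ids`` flags non-leukemic control samples used for per-probe
    control centering.
    """

    intensity: pd.DataFrame
    probe_map: Mapping[str, str]
    control_ids: frozenset[str] = frozenset()
    log2_scale: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unmapped = [p for p in self.intensity.index if p not in self.probe_map]
        if unmapped:
            raise ValidationError(f"probes without an exon assignment: {unmapped}")
        if not self.log2_scale:
            vals = self.intensity.to_numpy(dtype=float)
            if np.any(vals <= 0):
                raise ValidationError("linear-scale intensities must be positive")
        self.control_ids = frozenset(self.control_ids)
        unknown = self.control_ids - set(self.intensity.columns)
        if unknown:
            raise ValidationError(f"control IDs absent from matrix: {sorted(unknown)}")

    def probes_for(self, exon_label: str) -> list[str]:
        return [p for p in self.intensity.index if self.probe_map[p] == exon_label]

    @property
    def leukemia_ids(self) -> list[str]:
        return [s for s in self.intensity.columns if s not in self.control_ids]


# ---------------------------------------------------------------------------
# Derived matrices and labels
# ---------------------------------------------------------------------------

@dataclass
class NormalizedExonMatrix:
    """Samples x panel-exons matrix of panel-normalized RPKM values.

    Each row is the sample's exon RPKMs divided by its panel mean, so values
    are dimensionless ratios with per-row mean exactly 1; a uniformly included
    exon sits near 1 and a skipped exon well below it.
    """

    values: pd.DataFrame
    panel: tuple[ExonRef, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.size and np.any(arr < 0):
            raise ValidationError("normalized RPKM must be non-negative")
        if arr.size:
            rowmeans = arr.mean(axis=1)
            if np.any(np.abs(rowmeans - 1.0) > 1e-9):
                raise ValidationError("per-sample panel mean must equal 1 (1e-9)")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class CohortLabels:
    """Low/other classification of a cohort by a target-exon threshold."""

    labels: pd.Series           # index: sample -> {"low", "other"}
    threshold: float
    target_exon: str

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"low", "other"}
        if bad:
            raise ValidationError(f"unexpected labels: {bad}")

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())

    @property
    def n_other(self) -> int:
        return int((self.labels == "other").sum())

    @property
    def low_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "low"])

    def write_tsv(self, path) -> None:
        self.labels.rename("label").rename_axis("sample").to_csv(path, sep="\t")
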