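"""Exon-level expression indices.

Three measurement platforms, one question — how much of the target exon's
mRNA is present relative to its neighbours:

* RNA-seq: RPKM per exon, then each exon divided by the per-patient mean over
  the panel ("normalized RPKM", a ratio centred at 1; a skipped exon falls
  well below 1 while the flanking exons rise slightly above it).
* microarray: a log2-scale index = mean(target-exon probes) - mean(flanking
  probes), after within-sample median centering and optional per-probe
  centering to non-leukemic control samples.
* qRT-PCR: delta-Ct against a housekeeping gene.

The panel normalization is a division, not a subtraction: the resulting
values are positive ratios whose per-patient panel mean is exactly 1, which
is the only reading consistent with low-subset means near 0.7 under a
cutoff of 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    ExonQuantTable,
    ExonRef,
    NormalizedExonMatrix,
    ProbeMatrix,
    ValidationError,
)


def compute_rpkm(raw_count, total_reads, length_bp):
    """Reads per kilobase of exon per million mapped reads.

    ``rpkm = (raw_count / (total_reads / 1e6)) / (length_bp / 1e3)``.
    Vectorized; scalars in, scalar out.
    """
    raw_count = np.asarray(raw_count, dtype=float)
    total_reads = np.asarray(total_reads, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(length_bp <= 0):
        raise ValidationError("length_bp must be > 0")
    if np.any((total_reads <= 0) & (raw_count > 0)):
        raise ValidationError("total_reads must be > 0 where counts are positive")
    if np.any(raw_count < 0):
        raise ValidationError("raw_count must be >= 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        rpm = np.where(raw_count == 0, 0.0, raw_count / (total_reads / 1e6))
    out = rpm / (length_bp / 1e3)
    return float(out) if out.ndim == 0 else out


def fill_rpkm(table: ExonQuantTable) -> ExonQuantTable:
    """Return a copy of ``table`` with the RPKM column computed from counts."""
    df = table.df.copy()
    df["rpkm"] = compute_rpkm(
        df["raw_count"].to_numpy(),
        df["total_reads"].to_numpy(dtype=float),
        df["length_bp"].to_numpy(),
    )
    return ExonQuantTable(df=df, panel=table.panel, provenance=dict(table.provenance))


def collapse_duplicates(table: ExonQuantTable) -> ExonQuantTable:
    """Collapse duplicate (sample, exon) rows to one row each.

    RPKM values are averaged arithmetically; raw counts are summed and the
    affected rows flagged as aggregated in provenance.  A table without
    duplicates is returned unchanged (same object).
    """
    if not table.has_duplicates:
        return table
    df = table.df
    n_before = len(df)
    agg = (
        df.groupby(["sample", "exon_label"], sort=False)
        .agg(
            chrom=("chrom", "first"),
            start=("start", "first"),
            end=("end", "first"),
            length_bp=("length_bp", "first"),
            raw_count=("raw_count", "sum"),
            total_reads=("total_reads", "first"),
            rpkm=("rpkm", "mean"),
        )
        .reset_index()
    )
    prov = dict(table.provenance)
    prov["duplicate_rows_collapsed"] = n_before - len(agg)
    prov["raw_counts_aggregated"] = True
    cols = list(table.df.columns)
    return ExonQuantTable(df=agg[cols], panel=table.panel, provenance=prov)


def normalize_exon_panel(
    table: ExonQuantTable, panel: Sequence[ExonRef] | None = None
) -> NormalizedExonMatrix:
    """Mean-centre each patient's exon RPKMs to the panel average.

    Each sample's RPKM vector over the panel is divided by its mean, so the
    output is scale free (any uniform rescaling of a sample's RPKMs — or of
    counts and library size together — leaves it unchanged) and idempotent.
    Samples missing any panel exon, or with a non-positive panel mean, are
    excluded with a logged count.
    """
    panel = tuple(panel) if panel is not None else table.panel
    labels = [e.exon_label for e in panel]
    table = collapse_duplicates(table)
    mat = table.rpkm_matrix().reindex(columns=labels)

    complete = mat.notna().all(axis=1)
    means = mat.mean(axis=1)
    usable = complete & (means > 0)
    n_excluded = int((~usable).sum())
    norm = mat.loc[usable].div(means[usable], axis=0)

    prov = dict(table.provenance)
    prov["samples_excluded_incomplete_or_zero"] = n_excluded
    prov["n_samples"] = int(usable.sum())
    return NormalizedExonMatrix(values=norm, panel=panel, provenance=prov)


# ---------------------------------------------------------------------------
# Microarray index
# ---------------------------------------------------------------------------

@dataclass
class MicroarrayIndex:
    """Per-sample log2 exon index with its two components.

    ``index = mean(target-exon probes) - mean(flanking probes)`` computed on
    the processed log2 matrix.
    """

    index: pd.Series
    target_component: pd.Series
    flanking_component: pd.Series
    target_exon: str

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "index": self.index,
                "target_mean": self.target_component,
                "flanking_mean": self.flanking_component,
            }
        ).rename_axis("sample").to_csv(path, sep="\t", float_format="%.17g")


def microarray_index(
    matrix: ProbeMatrix,
    target_exon: str = "E12",
    control_center: bool = True,
) -> MicroarrayIndex:
    """Probe-based exon index in log2 units.

    Processing order per sample: log2 (if the matrix is linear scale) →
    median-centre across probes within the sample → optionally mean-centre
    each probe to the control samples → index = mean(target probes) −
    mean(flanking probes).  Median centering makes the index invariant to
    per-sample multiplicative scaling of linear intensities.
    """
    target_probes = matrix.probes_for(target_exon)
    flank_probes = [p for p in matrix.intensity.index if p not in target_probes]
    if not target_probes:
        raise ValidationError(f"no probes mapped to target exon {target_exon!r}")
    if not flank_probes:
        raise ValidationError("no flanking probes in matrix")
    if control_center and not matrix.control_ids:
        raise ValidationError("control centering requested but no control samples")

    vals = matrix.intensity.astype(float)
    if not matrix.log2_scale:
        vals = np.log2(vals)
    vals = vals.sub(vals.median(axis=0), axis=1)
    if control_center:
        con_mean = vals[list(matrix.control_ids)].mean(axis=1)
        vals = vals.sub(con_mean, axis=0)

    tgt = vals.loc[target_probes].mean(axis=0)
    flk = vals.loc[flank_probes].mean(axis=0)
    return MicroarrayIndex(
        index=tgt - flk,
        target_component=tgt,
        flanking_component=flk,
        target_exon=target_exon,
    )


# ---------------------------------------------------------------------------
# qRT-PCR
# ---------------------------------------------------------------------------

@dataclass
class DeltaCt:
    ct_target: float
    ct_reference: float

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def delta_ct(ct_target: float, ct_reference: float) -> DeltaCt:
    """Ct of the target transcript minus the housekeeping-gene Ct (cycles)."""
    for name, v in (("ct_target", ct_target), ("ct_reference", ct_reference)):
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(f"{name} must be finite and > 0, got {v}")
    return DeltaCt(float(ct_target), float(ct_reference))
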