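import numpy as np
import pandas as pd
import pytest

from exonsurv.model import (
    CD22_E11_E14_PANEL,
    CohortLabels,
    NormalizedExonMatrix,
)
from exonsurv.simulate import SyntheticSpec, planted_truth, simulate_cohort


EXON_LABELS = ["E11", "E12", "E13", "E14"]


@pytest.fixture
def panel():
    return CD22_E11_E14_PANEL


@pytest.fixture
def exon_tsv(tmp_path):
    """Factory writing a minimal exon quantification TSV; returns the path."""

    def _write(rows, name="exon.tsv"):
        path = tmp_path / name
        frame = pd.DataFrame(
            rows,
            columns=["sample", "chrom", "start", "end", "raw_count",
                     "length_bp", "total_reads", "rpkm"],
        )
        frame.to_csv(path, sep="\t", index=False)
        return path

    return _write


def panel_rows(sample="S1", counts=(100, 100, 100, 100), total=1e7):
    """One row per panel exon for a single sample."""
    rows = []
    for exon, count in zip(CD22_E11_E14_PANEL, counts):
        rpkm = (count / (total / 1e6)) / (exon.length_bp / 1e3)
        rows.append(
            [sample, exon.chrom, exon.start, exon.end, count,
             exon.length_bp, total, rpkm]
        )
    return rows


@pytest.fixture
def clinical_tsv(tmp_path):
    def _write(frame, name="clinical.tsv"):
        path = tmp_path / name
        frame.to_csv(path, sep="\t", index=False)
        return path

    return _write


def norm_matrix(values, samples=None):
    """NormalizedExonMatrix from per-sample ratio rows (rows must average 1)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if samples is None:
        samples = [f"S{i + 1}" for i in range(len(values))]
    frame = pd.DataFrame(values, index=samples, columns=EXON_LABELS)
    return NormalizedExonMatrix(values=frame, panel=CD22_E11_E14_PANEL)


def labels_from(mapping):
    ser = pd.Series(mapping, name="label")
    return CohortLabels(labels=ser, threshold=0.8, target_exon="E12")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    return simulate_cohort(SyntheticSpec(), seed=20240901)


@pytest.fixture(scope="session")
def truth_labels(default_cohort):
    return CohortLabels(
        labels=default_cohort.truth.rename("label"),
        threshold=0.8,
        target_exon="E12",
    )
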