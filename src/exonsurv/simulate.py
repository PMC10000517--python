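"""Fully synthetic cohorts for exercising every pipeline stage.

The generator emulates a 141-patient exon-level RNA-seq cohort in which a
planted subset of 21 patients shows selective skipping of the target exon:

* exon counts — per patient a latent normalized target-exon index is drawn
  from the group's distribution (low vs other), an expected RPKM profile over
  the four-exon panel is constructed to realise that index exactly in
  expectation, and negative-binomial counts are drawn at a log-normal library
  size;
* clinical covariates — frequencies follow the published cohort makeup and
  are independent of the planted status by default (dependence is opt-in via
  association knobs);
* survival — exponential event times per endpoint with configurable hazard
  ratios for the planted-low group, coupled through a single shared uniform
  per patient so that each endpoint is exactly marginally exponential with
  its hazard ratio while LFS <= relapse-time and LFS <= OS hold by
  construction; censoring is uniform over the follow-up window.

The latent index distributions are normals truncated to the observed group
ranges (which sit on either side of the 0.8 classification cutoff), with the
location solved so the truncated mean equals the group target mean; see the
methods note for why truncation is part of the emulated conditions.

Everything is deterministic under (spec, seed): regenerating with the same
seed reproduces the cohort bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .index import compute_rpkm
from .model import (
    CD22_E11_E14_PANEL,
    CLINICAL_COLUMNS,
    ClinicalTable,
    ExonQuantTable,
    ExonRef,
    ValidationError,
)

EXON_QUANT_COLS = (
    "sample", "exon_label", "chrom", "start", "end",
    "length_bp", "raw_count", "total_reads", "rpkm",
)


@dataclass
class GroupIndexModel:
    """Latent normalized-index distribution for one patient group."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValidationError("index SD must be > 0")
        if not (self.lower < self.mean < self.upper):
            raise ValidationError("index mean must lie inside the support")


@dataclass
class SurvivalModel:
    """Exponential endpoint model: baseline medians (days) for the reference
    group and hazard ratios for the planted-low group."""

    median_other: dict = field(
        default_factory=lambda: {"relapse": 1012.0, "lfs": 958.0, "os": 2029.0}
    )
    hazard_ratio_low: dict = field(
        default_factory=lambda: {"relapse": 1.8, "lfs": 1.8, "os": 2.3}
    )
    censor_low: float = 77.0
    censor_high: float = 4175.0
    #: optional log-hazard effects of covariate columns, e.g. {"poor_marker": 1.2}
    covariate_effects: dict = field(default_factory=dict)


@dataclass
class SyntheticSpec:
    """All knobs of the synthetic cohort, with study-scale defaults."""

    n_patients: int = 141
    n_low: int = 21
    panel: tuple[ExonRef, ...] = CD22_E11_E14_PANEL
    target_exon: str = "E12"

    low_index: GroupIndexModel = field(
        default_factory=lambda: GroupIndexModel(0.714, 0.064, 0.572, 0.785)
    )
    other_index: GroupIndexModel = field(
        default_factory=lambda: GroupIndexModel(0.934, 0.066, 0.805, 1.133)
    )
    #: mean relative levels of the flanking exons (normalized scale) and their
    #: patient-to-patient spread
    flank_shape_mean: tuple[float, ...] = (1.101, 1.073, 1.112)
    flank_shape_sd: tuple[float, ...] = (0.082, 0.050, 0.069)

    #: panel-average RPKM for an abundantly expressed transcript, and the
    #: log-normal spread of overall gene expression across patients
    base_rpkm: float = 600.0
    gene_level_sd_log: float = 0.5
    #: negative-binomial size (residual technical dispersion; biological
    #: variation is carried by the latent index draws).  None => Poisson.
    nb_size: float | None = 2000.0
    library_median: float = 2e7
    library_sd_log: float = 0.35

    survival: SurvivalModel = field(default_factory=SurvivalModel)

    # clinical covariate frequencies
    p_male: float = 0.55
    p_nci_high_low: float = 11 / 21       # NCI high-risk rate in planted-low
    p_nci_high_other: float = 79 / 120
    p_age_poor: float = 64 / 141          # age < 2 or >= 10
    p_age_under2_given_poor: float = 0.15
    wbc_median: float = 33.0
    wbc_sd_log: float = 1.3
    p_mrd_positive: float = 0.53
    mrd_median: float = 0.05
    mrd_sd_log: float = 2.0
    p_cns23: float = 28 / 141
    marker_probs: dict = field(
        default_factory=lambda: {
            "BCR-ABL1": 5 / 132,
            "MLL-R": 4 / 132,
            "TCF3-PBX1": 14 / 132,
            "ETV6-RUNX1": 11 / 132,
            "trisomy4_10": 10 / 132,
        }
    )
    p_marker_missing: float = 9 / 141
    p_karyotype_missing: float = 35 / 141
    #: opt-in log-odds shift of each trait in the planted-low group
    association_knobs: dict = field(default_factory=dict)

    id_prefix: str = "P"

    def __post_init__(self):
        if not (0 <= self.n_low <= self.n_patients):
            raise ValidationError("need 0 <= n_low <= n_patients")
        for name in ("p_male", "p_nci_high_low", "p_nci_high_other",
                     "p_age_poor", "p_mrd_positive", "p_cns23",
                     "p_marker_missing", "p_karyotype_missing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        for hr in self.survival.hazard_ratio_low.values():
            if hr <= 0:
                raise ValidationError("hazard ratios must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["panel"] = [asdict(e) for e in self.panel]
        return d


@dataclass
class SyntheticCohort:
    exon_table: ExonQuantTable
    clinical: ClinicalTable
    truth: pd.Series          # sample -> {"low", "other"} planted status
    spec: SyntheticSpec
    seed: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _truncnorm_mean_matched(model: GroupIndexModel):
    """Truncated normal over [lower, upper] whose *truncated* mean equals the
    target mean, with the target sd as the underlying scale.

    The location is solved by root finding; this keeps the realised group
    mean on target instead of letting the truncation drag it off.
    """
    lo, hi, sd = model.lower, model.upper, model.sd

    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    loc = optimize.brentq(
        lambda m: trunc_mean(m) - model.mean, lo - 5 * sd, hi + 5 * sd, xtol=1e-12
    )
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, size: float | None):
    if size is None or not np.isfinite(size):
        return rng.poisson(mu)
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _patient_ids(spec: SyntheticSpec) -> list[str]:
    width = len(str(spec.n_patients))
    return [f"{spec.id_prefix}{i + 1:0{width}d}" for i in range(spec.n_patients)]


def planted_truth(spec: SyntheticSpec, seed: int) -> pd.Series:
    """Random assignment of the planted low subset (deterministic per seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    ids = _patient_ids(spec)
    low_idx = rng.choice(spec.n_patients, size=spec.n_low, replace=False)
    labels = np.array(["other"] * spec.n_patients, dtype=object)
    labels[low_idx] = "low"
    return pd.Series(labels, index=ids, name="truth")


# ---------------------------------------------------------------------------
# exon counts
# ---------------------------------------------------------------------------

def simulate_exon_counts(
    spec: SyntheticSpec, seed: int, truth: pd.Series | None = None
) -> tuple[ExonQuantTable, pd.Series]:
    """Exon-level count table with a planted low-inclusion subset.

    Per patient: latent index -> expected RPKM profile whose normalized
    target-exon value equals the latent index exactly -> expected counts
    (count = RPKM x length_kb x library/1e6) -> negative-binomial draws.
    Returns the table (with RPKM recomputed from the drawn counts) and the
    planted truth labels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    if truth is None:
        truth = planted_truth(spec, seed)
    ids = list(truth.index)
    is_low = (truth == "low").to_numpy()
    n = len(ids)

    labels = [e.exon_label for e in spec.panel]
    tgt_pos = labels.index(spec.target_exon)
    flank_pos = [i for i in range(len(labels)) if i != tgt_pos]
    lengths_kb = np.array([e.length_bp for e in spec.panel]) / 1e3
    k = len(labels)

    low_dist = _truncnorm_mean_matched(spec.low_index)
    other_dist = _truncnorm_mean_matched(spec.other_index)
    t_latent = np.where(
        is_low,
        low_dist.ppf(rng.uniform(size=n)),
        other_dist.ppf(rng.uniform(size=n)),
    )

    # flanking shape, strictly positive
    shape = rng.normal(
        loc=np.array(spec.flank_shape_mean),
        scale=np.array(spec.flank_shape_sd),
        size=(n, k - 1),
    )
    shape = np.clip(shape, 0.05, None)

    # profile p with p_target / mean(p) = latent index exactly
    w_sum = shape.sum(axis=1)
    x_t = t_latent * w_sum / (k - t_latent)
    profile = np.empty((n, k))
    profile[:, tgt_pos] = x_t
    profile[:, flank_pos] = shape
    profile /= profile.mean(axis=1, keepdims=True)   # panel mean -> 1

    gene_level = np.exp(rng.normal(0.0, spec.gene_level_sd_log, size=n))
    expected_rpkm = spec.base_rpkm * gene_level[:, None] * profile

    library = np.exp(
        rng.normal(np.log(spec.library_median), spec.library_sd_log, size=n)
    )
    library = np.round(library).astype(np.int64)

    mu = expected_rpkm * lengths_kb[None, :] * (library[:, None] / 1e6)
    counts = _draw_counts(rng, mu, spec.nb_size)

    rows = {
        "sample": np.repeat(ids, k),
        "exon_label": np.tile(labels, n),
        "chrom": np.tile([e.chrom for e in spec.panel], n),
        "start": np.tile([e.start for e in spec.panel], n),
        "end": np.tile([e.end for e in spec.panel], n),
        "length_bp": np.tile([e.length_bp for e in spec.panel], n),
        "raw_count": counts.ravel(),
        "total_reads": np.repeat(library, k).astype(float),
    }
    df = pd.DataFrame(rows)
    df["rpkm"] = compute_rpkm(
        df["raw_count"].to_numpy(),
        df["total_reads"].to_numpy(),
        df["length_bp"].to_numpy(),
    )
    table = ExonQuantTable(
        df=df[list(EXON_QUANT_COLS)], panel=spec.panel,
        provenance={"synthetic": True, "seed": int(seed)},
    )
    return table, truth


# ---------------------------------------------------------------------------
# clinical covariates
# ---------------------------------------------------------------------------

def simulate_clinical(
    spec: SyntheticSpec, truth: pd.Series, seed: int
) -> pd.DataFrame:
    """Covariate columns only (endpoints appended by simulate_survival).

    Covariates are independent of the planted status by default; NCI risk
    keeps its published per-group frequencies, and any trait can be tilted
    in the low group via ``association_knobs`` (log-odds shifts).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    ids = list(truth.index)
    n = len(ids)
    is_low = (truth == "low").to_numpy()

    def bern(p_base: float, knob_name: str) -> np.ndarray:
        shift = spec.association_knobs.get(knob_name, 0.0)
        if shift:
            logit = np.log(p_base / (1 - p_base)) + shift * is_low
            p = 1 / (1 + np.exp(-logit))
        else:
            p = np.full(n, p_base)
        return rng.uniform(size=n) < p

    age_poor = bern(spec.p_age_poor, "age_poor")
    under2 = rng.uniform(size=n) < spec.p_age_under2_given_poor
    age = np.where(
        age_poor,
        np.where(under2, rng.uniform(1.0, 2.0, n), rng.uniform(10.0, 18.0, n)),
        rng.uniform(2.0, 10.0, n),
    )
    sex = np.where(bern(spec.p_male, "male"), "male", "female")
    wbc = np.exp(rng.normal(np.log(spec.wbc_median), spec.wbc_sd_log, n))
    mrd_pos = bern(spec.p_mrd_positive, "mrd_positive")
    mrd_val = np.exp(rng.normal(np.log(spec.mrd_median), spec.mrd_sd_log, n))
    mrd = np.where(mrd_pos, np.maximum(mrd_val, 0.001), 0.0)
    cns23 = bern(spec.p_cns23, "cns23")
    cns2 = rng.uniform(size=n) < 2 / 3
    cns = np.where(cns23, np.where(cns2, "CNS2", "CNS3"), "CNS1")

    p_high = np.where(is_low, spec.p_nci_high_low, spec.p_nci_high_other)
    nci = np.where(rng.uniform(size=n) < p_high, "high", "standard")

    # mutually exclusive molecular markers
    names = list(spec.marker_probs)
    probs = np.array([spec.marker_probs[m] for m in names])
    if probs.sum() > 1:
        raise ValidationError("marker probabilities sum to more than 1")
    cut = np.concatenate([[0.0], np.cumsum(probs)])
    u = rng.uniform(size=n)
    marker_idx = np.searchsorted(cut, u, side="right") - 1
    markers = [
        frozenset({names[i]}) if i < len(names) else frozenset()
        for i in marker_idx
    ]
    marker_missing = rng.uniform(size=n) < spec.p_marker_missing
    markers = [np.nan if miss else m for m, miss in zip(markers, marker_missing)]

    karyo_classes = np.array(["normal", "pseudodiploid", "hyperdiploid_SCA"])
    karyo = karyo_classes[rng.choice(3, size=n, p=[0.3, 0.4, 0.3])].astype(object)
    karyo_missing = rng.uniform(size=n) < spec.p_karyotype_missing
    karyo[karyo_missing] = np.nan

    return pd.DataFrame(
        {
            "patient": ids,
            "age_years": age,
            "sex": sex,
            "wbc": wbc,
            "mrd_day29": mrd,
            "cns_status": cns,
            "nci_risk": nci,
            "markers": markers,
            "karyotype_class": karyo,
        }
    )


# ---------------------------------------------------------------------------
# survival endpoints
# ---------------------------------------------------------------------------

def simulate_survival(
    spec: SyntheticSpec,
    truth: pd.Series,
    covariates: pd.DataFrame,
    seed: int,
) -> ClinicalTable:
    """Append exponential (time, event) pairs per endpoint to the covariates.

    Endpoint e has hazard lambda_e = ln2 / median_other[e] x HR_e^low x
    exp(sum beta_j z_j).  One shared uniform per patient couples the
    endpoints comonotonically, so each is exactly marginally exponential with
    its configured hazard ratio and the LFS <= relapse / LFS <= OS orderings
    hold patient by patient.  A single uniform censoring time per patient is
    applied to all endpoints.
    """
    sv = spec.survival
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 37]))
    ids = list(truth.index)
    n = len(ids)
    is_low = (truth == "low").to_numpy().astype(float)

    extra_loghaz = np.zeros(n)
    for cov, beta in sv.covariate_effects.items():
        if cov not in covariates.columns:
            raise ValidationError(f"covariate effect for unknown column {cov!r}")
        extra_loghaz += beta * covariates[cov].to_numpy(dtype=float)

    u = rng.uniform(size=n)
    u = np.clip(u, 1e-300, 1 - 1e-16)
    censor = rng.uniform(sv.censor_low, sv.censor_high, size=n)

    df = covariates.copy()
    for ep in ("relapse", "lfs", "os"):
        lam = (
            np.log(2.0) / sv.median_other[ep]
            * sv.hazard_ratio_low[ep] ** is_low
            * np.exp(extra_loghaz)
        )
        event_time = -np.log(u) / lam
        observed = np.minimum(event_time, censor)
        df[f"{ep}_time"] = observed
        df[f"{ep}_event"] = (event_time <= censor).astype(float)
    return ClinicalTable(
        df=df[list(CLINICAL_COLUMNS)],
        provenance={"synthetic": True, "seed": int(seed),
                    "censoring": "uniform(77, 4175) shared across endpoints"},
    )


# ---------------------------------------------------------------------------
# probe matrix
# ---------------------------------------------------------------------------

#: probe layout of the multi-probe exon panel: 3 target-exon probes and 6
#: probes over the flanking exons
DEFAULT_PROBE_MAP = {
    "probe_E11_a": "E11", "probe_E11_b": "E11",
    "probe_E12_a": "E12", "probe_E12_b": "E12", "probe_E12_c": "E12",
    "probe_E13_a": "E13", "probe_E13_b": "E13",
    "probe_E14_a": "E14", "probe_E14_b": "E14",
}


def simulate_probe_matrix(
    spec: SyntheticSpec,
    truth: pd.Series,
    seed: int,
    n_controls: int = 74,
    delta_log2: float = 1.0,
    probe_sd: float = 1.0,
    sample_sd: float = 0.5,
    noise_sd: float = 0.15,
):
    """Log2 probe x sample matrix: planted-low patients have their
    target-exon probes shifted down by ``delta_log2``; controls are unshifted.
    """
    from .model import ProbeMatrix   # local import avoids cycle at module load

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    probes = list(DEFAULT_PROBE_MAP)
    samples = list(truth.index) + [f"CON{i + 1:02d}" for i in range(n_controls)]
    is_low = np.concatenate(
        [(truth == "low").to_numpy(), np.zeros(n_controls, dtype=bool)]
    )
    is_e12 = np.array([DEFAULT_PROBE_MAP[p] == spec.target_exon for p in probes])

    affinity = rng.normal(8.0, probe_sd, size=len(probes))
    sample_eff = rng.normal(0.0, sample_sd, size=len(samples))
    noise = rng.normal(0.0, noise_sd, size=(len(probes), len(samples)))
    vals = affinity[:, None] + sample_eff[None, :] + noise
    vals -= delta_log2 * np.outer(is_e12, is_low)

    mat = pd.DataFrame(vals, index=probes, columns=samples)
    return ProbeMatrix(
        intensity=mat,
        probe_map=dict(DEFAULT_PROBE_MAP),
        control_ids=frozenset(s for s in samples if s.startswith("CON")),
        log2_scale=True,
        provenance={"synthetic": True, "seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def simulate_cohort(spec: SyntheticSpec | None = None, seed: int = 0) -> SyntheticCohort:
    """Exon table + clinical table + truth labels in one call."""
    spec = spec or SyntheticSpec()
    truth = planted_truth(spec, seed)
    table, _ = simulate_exon_counts(spec, seed, truth)
    covs = simulate_clinical(spec, truth, seed)
    clinical = simulate_survival(spec, truth, covs, seed)
    return SyntheticCohort(
        exon_table=table, clinical=clinical, truth=truth, spec=spec, seed=int(seed)
    )
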