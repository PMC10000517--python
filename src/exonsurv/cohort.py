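"""Cohort-characteristics statistics.

The three tests behind a typical baseline-characteristics table: the
two-sided Fisher exact test on 2x2 contingency tables (categorical traits),
the Mann–Whitney U test (continuous traits), and the Welch two-sample t test
(summary comparisons with unequal variances).  Each is computed from its
definition — the hypergeometric point-probability criterion for Fisher,
midrank U with exact small-sample enumeration for Mann–Whitney — with scipy
supplying only distribution functions.

Evaluable denominators: each trait row uses only patients in whom the trait was
observed, so denominators vary across rows exactly as they do in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (
    ClinicalTable,
    CohortLabels,
    ValidationError,
)


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    effect_name: str
    effect: float
    degenerate: bool = False
    extra: dict | None = None


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

#: Relative tolerance when comparing hypergeometric point probabilities, so
#: that tables tied with the observed one up to floating-point error are
#: included in the two-sided sum.
_FISHER_RELTOL = 1e-7


def _conditional_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Conditional MLE of the odds ratio given all margins.

    Maximises the Fisher noncentral hypergeometric likelihood in the observed
    cell; boundary tables give 0 or inf.
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    if a == lo:
        return 0.0
    if a == hi:
        return np.inf

    def neg_logpmf(log_or: float) -> float:
        dist = stats.nchypergeom_fisher(n, c1, r1, np.exp(log_or))
        return -dist.logpmf(a)

    res = optimize.minimize_scalar(neg_logpmf, bounds=(-35, 35), method="bounded")
    return float(np.exp(res.x))


def fisher_2x2(
    a: int, b: int, c: int, d: int, odds_ratio: bool = True
) -> TestResult:
    """Two-sided Fisher exact test for the table [[a, b], [c, d]].

    The two-sided p-value sums the probabilities of all tables with the same
    margins whose hypergeometric point probability does not exceed that of
    the observed table (within relative tolerance 1e-7).  A zero margin makes
    the table degenerate: p = 1 with a flag.  ``odds_ratio=False`` skips the
    conditional-MLE odds ratio (an iterative optimisation) when only the
    p-value is needed.
    """
    cells = np.array([a, b, c, d])
    if np.any(cells < 0):
        raise ValidationError("contingency cells must be non-negative")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return TestResult("fisher_exact", np.nan, 1.0, "odds_ratio", np.nan, True)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + _FISHER_RELTOL)].sum())
    p = min(p, 1.0)
    or_hat = _conditional_odds_ratio(a, b, c, d) if odds_ratio else np.nan
    return TestResult("fisher_exact", p_obs, p, "odds_ratio", or_hat)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U for sample sizes (n1, n2) without ties.

    Classic two-sample recursion on the number of rank arrangements,
    f(m, n; u) = f(m-1, n; u-n) + f(m, n-1; u), whose total is C(m+n, m)
    (the counts are Gaussian-binomial coefficients).
    """
    umax = n1 * n2
    # table[m] = count array over u for sample sizes (m, current n)
    table = [np.zeros(umax + 1) for _ in range(n1 + 1)]
    for m in range(n1 + 1):
        table[m][0] = 1.0          # n = 0 base case: only u = 0
    for n in range(1, n2 + 1):
        new = [np.zeros(umax + 1) for _ in range(n1 + 1)]
        new[0][0] = 1.0
        for m in range(1, n1 + 1):
            shifted = np.zeros(umax + 1)
            shifted[n:] = new[m - 1][: umax + 1 - n]
            new[m] = shifted + table[m]
        table = new
    counts = table[n1]
    return counts / counts.sum()


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U test with midrank ties.

    Exact p by enumerating the null U distribution when both samples have at
    most 8 observations and no ties are present; otherwise the normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if n1 <= 8 and n2 <= 8 and not has_ties:
        pmf = _exact_u_pmf(n1, n2)
        u_small = min(u1, u2)
        # symmetric null: double the lower tail, capped at 1
        p = min(1.0, 2.0 * float(pmf[: int(u_small) + 1].sum()))
        method = "mann_whitney_exact"
    else:
        n = n1 + n2
        mean_u = n1 * n2 / 2.0
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_u == 0:
            return TestResult(
                "mann_whitney_normal", u1, 1.0, "location_shift", 0.0, True
            )
        cc = 0.5 if abs(u1 - mean_u) > 0 else 0.0
        z = (u1 - mean_u - np.sign(u1 - mean_u) * cc) / np.sqrt(var_u)
        p = float(2 * stats.norm.sf(abs(z)))
        p = min(p, 1.0)
        method = "mann_whitney_normal"

    shift = float(np.median(x) - np.median(y))
    return TestResult(method, float(u1), p, "location_shift", shift)


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch two-sample t test (unequal variances), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("Welch t needs n >= 2 per sample")
    return welch_t_from_summary(
        x.mean(), x.std(ddof=1) / np.sqrt(x.size), x.size,
        y.mean(), y.std(ddof=1) / np.sqrt(y.size), y.size,
    )


def welch_t_from_summary(
    mean_x: float, sem_x: float, n_x: int,
    mean_y: float, sem_y: float, n_y: int,
) -> TestResult:
    """Welch t from group means and standard errors (sem = s / sqrt(n)).

    Useful when only summary statistics are available, e.g. printed tables.
    """
    vx, vy = sem_x**2, sem_y**2   # variances of the means
    diff = mean_x - mean_y
    denom = vx + vy
    if denom == 0:
        if diff == 0:
            return TestResult("welch_t", 0.0, 1.0, "mean_difference", 0.0)
        return TestResult("welch_t", np.inf, 0.0, "mean_difference", diff, True)
    t = diff / np.sqrt(denom)
    df = denom**2 / (vx**2 / (n_x - 1) + vy**2 / (n_y - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return TestResult("welch_t", float(t), p, "mean_difference", float(diff),
                      extra={"df": float(df)})


# ---------------------------------------------------------------------------
# Characteristics table
# ---------------------------------------------------------------------------

def _cont_summary(v: pd.Series) -> dict:
    vv = v.dropna()
    if vv.empty:
        return {"n": 0, "mean": np.nan, "sem": np.nan, "median": np.nan,
                "min": np.nan, "max": np.nan}
    return {
        "n": int(vv.size),
        "mean": float(vv.mean()),
        "sem": float(vv.std(ddof=1) / np.sqrt(vv.size)) if vv.size > 1 else np.nan,
        "median": float(vv.median()),
        "min": float(vv.min()),
        "max": float(vv.max()),
    }


def characteristics_table(
    clinical: ClinicalTable, labels: CohortLabels
) -> pd.DataFrame:
    """Baseline-characteristics comparison of the low vs other groups.

    Continuous traits (age, WBC, day-29 MRD) are compared by Mann–Whitney;
    binary traits by two-sided Fisher exact on the evaluable 2x2.  Each row
    reports group summaries and a p-value; rows where a group has no
    evaluable patients carry a missing p and a flag.
    """
    df = clinical.df.set_index("patient")
    lab = labels.labels.reindex(df.index)
    low = lab == "low"
    other = lab == "other"

    rows = []

    def add_continuous(name: str, values: pd.Series) -> None:
        sx, sy = values[low], values[other]
        s_low, s_oth = _cont_summary(sx), _cont_summary(sy)
        if s_low["n"] == 0 or s_oth["n"] == 0:
            rows.append({"trait": name, "kind": "continuous", "p": np.nan,
                         "flag": "no evaluable patients in a group",
                         **_prefix(s_low, "low_"), **_prefix(s_oth, "other_")})
            return
        res = mann_whitney(sx.dropna(), sy.dropna())
        rows.append({"trait": name, "kind": "continuous", "p": res.p_value,
                     "statistic": res.statistic, "flag": "",
                     **_prefix(s_low, "low_"), **_prefix(s_oth, "other_")})

    def add_binary(name: str, flagged: pd.Series) -> None:
        """``flagged``: boolean with NaN for unevaluable patients."""
        ev = flagged.notna()
        a = int((flagged[low & ev]).sum())
        na = int((low & ev).sum())
        c = int((flagged[other & ev]).sum())
        nc = int((other & ev).sum())
        if na == 0 or nc == 0:
            rows.append({"trait": name, "kind": "binary", "p": np.nan,
                         "flag": "no evaluable patients in a group",
                         "low_n_yes": a, "low_n": na,
                         "other_n_yes": c, "other_n": nc})
            return
        res = fisher_2x2(a, na - a, c, nc - c)
        rows.append({"trait": name, "kind": "binary", "p": res.p_value,
                     "odds_ratio": res.effect,
                     "flag": "degenerate margin" if res.degenerate else "",
                     "low_n_yes": a, "low_n": na,
                     "other_n_yes": c, "other_n": nc})

    add_continuous("age_years", df["age_years"])
    add_continuous("wbc", df["wbc"])
    add_continuous("mrd_day29", df["mrd_day29"])

    age = df["age_years"]
    add_binary("age_risk_lt2_or_ge10", ((age < 2) | (age >= 10)).where(age.notna()))
    add_binary("adult_ge18", (age >= 18).where(age.notna()))
    add_binary("male", (df["sex"] == "male").where(df["sex"].notna()))
    add_binary("nci_high_risk",
               (df["nci_risk"] == "high").where(df["nci_risk"].notna()))
    add_binary("wbc_ge20", (df["wbc"] >= 20).where(df["wbc"].notna()))
    add_binary(
        "cns2_or_cns3",
        df["cns_status"].isin(["CNS2", "CNS3"]).where(df["cns_status"].notna()),
    )
    add_binary(
        "mrd_day29_positive",
        (df["mrd_day29"] >= 0.001).where(df["mrd_day29"].notna()),
    )
    markers = df["markers"]
    evaluable = markers.map(lambda m: isinstance(m, frozenset))
    for marker in ("BCR-ABL1", "MLL-R", "TCF3-PBX1", "ETV6-RUNX1", "trisomy4_10"):
        has = markers.map(
            lambda m, marker=marker: marker in m if isinstance(m, frozenset) else np.nan
        )
        add_binary(f"marker_{marker}", has.where(evaluable))

    return pd.DataFrame(rows)


def _prefix(d: dict, prefix: str) -> dict:
    return {prefix + k: v for k, v in d.items()}
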