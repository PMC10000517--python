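"""Right-censored survival analysis: Kaplan–Meier, log-rank, Cox PH.

All three estimators are implemented directly from their defining formulas
rather than delegated to a survival library, so that every numerical choice
(Greenwood variance, log-scale confidence bands, hypergeometric log-rank
variance, Efron tie correction, Newton–Raphson with step halving) is explicit
and testable against independent oracles.

Conventions
-----------
* Event flags are 1 = event, 0 = right-censored; times are positive.
* KM confidence bands default to the log transform with Greenwood variance
  (the common survival-package default); "log-log" and "plain" are available.
* Cox ties default to the Efron correction; "breslow" is provided and makes
  the score test at beta = 0 for a binary covariate identical to the
  two-group log-rank chi-square.
* Wald inference is reported: HR = exp(coef), CI = exp(coef +/- 1.96 se).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    POOR_RISK_MARKERS,
    ClinicalTable,
    CohortLabels,
    ValidationError,
)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _check_times_events(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValidationError("times must be finite and > 0")
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise ValidationError("event flags must be 0/1")
    return t, e.astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate over the distinct event times.

    Arrays are aligned on ``times`` (ascending distinct event times).
    ``survival[j]`` is S(t) just after times[j]; S is 1 before the first
    event time.  ``variance`` is the Greenwood variance of S.
    """

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n: int
    ci_method: str = "log"

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S at time ``t``."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def km_fit(times, events, ci: str = "log", alpha: float = 0.05) -> KMCurve:
    """Kaplan–Meier estimator with Greenwood variance and confidence bands.

    ``ci``: "log" (band on log S, clipped to [0, 1]), "log-log", or "plain".
    """
    t, e = _check_times_events(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size

    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        # all censored: S(t) = 1 everywhere
        empty = np.array([])
        return KMCurve(empty, empty, empty, empty, empty, empty, empty, n, ci)

    # at risk just before each event time; events at each
    n_at_risk = n - np.searchsorted(t, event_times, side="left")
    d = np.array([np.sum((t == et) & (e == 1)) for et in event_times])

    frac = 1.0 - d / n_at_risk
    S = np.cumprod(frac)

    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(
            n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf
        )
    cum = np.cumsum(gw_terms)
    with np.errstate(invalid="ignore"):
        var = np.where(S > 0, S**2 * cum, 0.0)

    z = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        if ci == "log":
            se_log = np.sqrt(cum)
            lower = S * np.exp(-z * se_log)
            upper = S * np.exp(z * se_log)
        elif ci == "log-log":
            logS = np.log(S)
            se_ll = np.sqrt(cum) / np.abs(logS)
            lower = S ** np.exp(z * se_ll)
            upper = S ** np.exp(-z * se_ll)
        elif ci == "plain":
            half = z * np.sqrt(var)
            lower, upper = S - half, S + half
        else:
            raise ValidationError(f"unknown CI method {ci!r}")
    lower = np.clip(np.where(S == 0, 0.0, np.nan_to_num(lower, nan=0.0)), 0, 1)
    upper = np.clip(np.where(S == 0, 0.0, np.nan_to_num(upper, nan=1.0)), 0, 1)

    return KMCurve(event_times, S, var, lower, upper, n_at_risk, d, n, ci)


@dataclass
class MedianSurvival:
    """Median survival time with CI-band bounds; None means undefined/open."""

    median: float | None
    ci_lower: float | None
    ci_upper: float | None


def median_survival(curve: KMCurve) -> MedianSurvival:
    """Median = smallest event time with S(t) <= 0.5; CI bounds are the first
    times the confidence band's limits cross 0.5.  A band limit that never
    reaches 0.5 yields an open (None) bound."""
    def first_time(values: np.ndarray) -> float | None:
        hit = np.nonzero(values <= 0.5 + 1e-12)[0]
        return float(curve.times[hit[0]]) if hit.size else None

    if curve.times.size == 0:
        return MedianSurvival(None, None, None)
    return MedianSurvival(
        median=first_time(curve.survival),
        ci_lower=first_time(curve.ci_lower),
        ci_upper=first_time(curve.ci_upper),
    )


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed: np.ndarray   # events per group
    expected: np.ndarray   # hypergeometric expectation per group
    groups: tuple


def logrank_test(times, events, group) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time the group-1 events are compared with their
    hypergeometric expectation given the margins; the statistic is
    (sum(O - E))^2 / sum(V) with V the hypergeometric variance, referred to a
    1-df chi-square.
    """
    t, e = _check_times_events(times, events)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValidationError(f"need exactly two non-empty groups, got {levels}")
    in1 = g == levels[0]

    event_times = np.unique(t[e == 1])
    n1 = np.array([np.sum(in1 & (t >= et)) for et in event_times], dtype=float)
    ntot = np.array([np.sum(t >= et) for et in event_times], dtype=float)
    d1 = np.array([np.sum(in1 & (t == et) & (e == 1)) for et in event_times], dtype=float)
    d = np.array([np.sum((t == et) & (e == 1)) for et in event_times], dtype=float)

    expected1 = d * n1 / ntot
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(
            ntot > 1,
            d * (n1 / ntot) * (1 - n1 / ntot) * (ntot - d) / (ntot - 1),
            0.0,
        )
    num = np.sum(d1 - expected1)
    denom = np.sum(v)
    chi2 = 0.0 if denom == 0 else num**2 / denom
    p = float(stats.chi2.sf(chi2, df=1)) if denom > 0 else 1.0

    obs = np.array([np.sum(d1), np.sum(d) - np.sum(d1)])
    exp = np.array([np.sum(expected1), np.sum(d) - np.sum(expected1)])
    return LogRankResult(float(chi2), p, obs, exp, tuple(levels))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Fitted Cox model with Wald inference.

    ``summary`` columns: coef, se, hr, hr_lower, hr_upper, z, p.  Covariates
    with zero variance are flagged non-identifiable (coef 0, SE inf) and do
    not enter the optimisation.
    """

    summary: pd.DataFrame
    log_likelihood: float
    iterations: int
    ties: str
    n: int
    n_events: int
    converged: bool
    flags: list = field(default_factory=list)

    @property
    def coef(self) -> np.ndarray:
        return self.summary["coef"].to_numpy()

    @property
    def hazard_ratios(self) -> np.ndarray:
        return self.summary["hr"].to_numpy()


def _cox_loglik_derivs(beta, X, t, e, ties):
    """Log partial likelihood, gradient, and negative Hessian (information).

    Rows must be sorted by ascending time.  Tied event times are handled by
    the Efron or Breslow correction.
    """
    n, p = X.shape
    eta = X @ beta
    # numerical guard: shift eta by max (cancels in ratios)
    w = np.exp(eta - eta.max())
    logshift = eta.max()

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))

    # cumulative risk-set sums from the largest time downwards
    order = np.arange(n - 1, -1, -1)
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = n - 1
    # iterate over distinct times descending; risk set = all with time >= current
    times_desc = np.unique(t)[::-1]
    idx_by_time = {}
    for ti in times_desc:
        idx_by_time[ti] = np.nonzero(t == ti)[0]
    for ti in times_desc:
        idx = idx_by_time[ti]
        wi = w[idx]
        Xi = X[idx]
        S0 += wi.sum()
        S1 += wi @ Xi
        S2 += (Xi * wi[:, None]).T @ Xi

        ev = idx[e[idx] == 1]
        dcount = ev.size
        if dcount == 0:
            continue
        Xd = X[ev]
        wd = w[ev]
        s0d = wd.sum()
        s1d = wd @ Xd
        s2d = (Xd * wd[:, None]).T @ Xd

        ll += float(eta[ev].sum())
        if ties == "efron":
            fracs = np.arange(dcount) / dcount
        elif ties == "breslow":
            fracs = np.zeros(dcount)
        else:
            raise ValidationError(f"unknown tie method {ties!r}")
        for f in fracs:
            phi0 = S0 - f * s0d
            phi1 = S1 - f * s1d
            phi2 = S2 - f * s2d
            ll -= np.log(phi0) + logshift
            grad -= phi1 / phi0
            info += phi2 / phi0 - np.outer(phi1, phi1) / phi0**2
        grad += Xd.sum(axis=0)
    return ll, grad, info


def cox_fit(
    design,
    times,
    events,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
    names: Sequence[str] | None = None,
) -> CoxResult:
    """Maximise the Cox partial likelihood by Newton–Raphson.

    ``design`` is the n x p covariate matrix (no missing cells; complete-case
    deletion happens upstream).  Convergence: max-norm of the coefficient
    update < ``tol`` or ``max_iter`` iterations.  Monotone-likelihood
    (separation-like) behaviour is flagged, not silently reported; a singular
    information matrix among identifiable covariates is a validation error.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and np.asarray(times).size > 1:
        X = X.T
    t, e = _check_times_events(times, events)
    if X.shape[0] != t.size:
        raise ValidationError("design rows must match number of subjects")
    if np.any(~np.isfinite(X)):
        raise ValidationError("design contains missing/non-finite cells")
    if e.sum() < 1:
        raise ValidationError("need at least one event")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)

    order = np.argsort(t, kind="stable")
    Xs, ts, es = X[order], t[order], e[order]

    flags: list[str] = []
    variances = Xs.var(axis=0)
    identifiable = variances > 0
    if not identifiable.all():
        flags.append(
            "non-identifiable: constant covariates "
            + ", ".join(np.array(names)[~identifiable])
        )
    Xa = Xs[:, identifiable]
    pa = Xa.shape[1]
    center = Xa.mean(axis=0) if pa else np.zeros(0)
    Xa = Xa - center  # centering improves conditioning; coefs unchanged

    beta = np.zeros(pa)
    ll = -np.inf
    converged = False
    iterations = 0
    info = np.eye(max(pa, 1))
    if pa:
        for iterations in range(1, max_iter + 1):
            ll_new, grad, info = _cox_loglik_derivs(beta, Xa, ts, es, ties)
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as err:
                raise ValidationError(f"singular information matrix: {err}") from err
            # step-halving if the likelihood would decrease
            scale = 1.0
            while True:
                cand = beta + scale * step
                ll_cand = _cox_loglik_derivs(cand, Xa, ts, es, ties)[0]
                if ll_cand >= ll_new - 1e-12 or scale < 1e-4:
                    break
                scale /= 2.0
            delta = scale * step
            beta = beta + delta
            if np.max(np.abs(delta)) < tol:
                converged = True
                ll = _cox_loglik_derivs(beta, Xa, ts, es, ties)[0]
                break
            ll = ll_cand
        else:
            iterations = max_iter
        _, _, info = _cox_loglik_derivs(beta, Xa, ts, es, ties)
        if not converged:
            flags.append("non-convergence (possible monotone likelihood)")
        if np.max(np.abs(beta)) > 30:
            flags.append("separation suspected: |coef| > 30")
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError as err:
            raise ValidationError(f"singular information matrix: {err}") from err
        se_a = np.sqrt(np.clip(np.diag(cov), 0, None))
        ll_final = _cox_loglik_derivs(beta, Xa, ts, es, ties)[0]
    else:
        se_a = np.zeros(0)
        ll_final = _cox_loglik_derivs(np.zeros(0), Xs[:, :0], ts, es, ties)[0]
        converged = True

    coef = np.zeros(p)
    se = np.full(p, np.inf)
    coef[identifiable] = beta
    se[identifiable] = se_a

    with np.errstate(over="ignore"):
        z = np.where(np.isfinite(se) & (se > 0), coef / se, 0.0)
        pvals = 2 * stats.norm.sf(np.abs(z))
        pvals = np.where(np.isfinite(se), pvals, np.nan)
        hr = np.exp(coef)
        lower = np.exp(coef - Z95 * se)
        upper = np.exp(coef + Z95 * se)
    summary = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "hr": hr,
            "hr_lower": lower,
            "hr_upper": upper,
            "z": z,
            "p": pvals,
        },
        index=names,
    )
    return CoxResult(
        summary=summary,
        log_likelihood=float(ll_final),
        iterations=iterations,
        ties=ties,
        n=n,
        n_events=int(es.sum()),
        converged=converged,
        flags=flags,
    )


def cox_score_test(design, times, events, ties: str = "breslow") -> float:
    """Score (Rao) chi-square at beta = 0.

    For a single binary covariate with Breslow ties this equals the two-group
    log-rank chi-square.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] == 1 and np.asarray(times).size > 1:
        X = X.T
    t, e = _check_times_events(times, events)
    order = np.argsort(t, kind="stable")
    Xs, ts, es = X[order], t[order], e[order]
    Xs = Xs - Xs.mean(axis=0)
    _, grad, info = _cox_loglik_derivs(np.zeros(Xs.shape[1]), Xs, ts, es, ties)
    return float(grad @ np.linalg.solve(info, grad))


# ---------------------------------------------------------------------------
# Outcome analysis orchestration
# ---------------------------------------------------------------------------

#: Default covariate set for the multivariate model: exon-low status, the
#: poor-risk age band (< 2 or >= 10 years), male sex, a poor-risk molecular
#: marker, WBC as a linear covariate, and detectable end-of-induction MRD.
DEFAULT_COVARIATES = ("low", "age_risk", "male", "poor_marker", "wbc", "mrd_positive")


def build_covariates(
    clinical: ClinicalTable,
    labels: CohortLabels,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    wbc_categorical: bool = False,
) -> pd.DataFrame:
    """Numeric covariate frame (one row per patient; NaN where unevaluable).

    ``wbc_categorical`` switches WBC from linear 10^9/L to the >= 20 x 10^9/L
    indicator.
    """
    df = clinical.df.set_index("patient")
    out = pd.DataFrame(index=df.index)
    for cov in covariates:
        if cov == "low":
            lab = labels.labels.reindex(df.index)
            out["low"] = (lab == "low").astype(float).where(lab.notna())
        elif cov == "age_risk":
            age = df["age_years"]
            out["age_risk"] = (((age < 2) | (age >= 10)).astype(float)).where(age.notna())
        elif cov == "male":
            out["male"] = (df["sex"] == "male").astype(float).where(df["sex"].notna())
        elif cov == "poor_marker":
            out["poor_marker"] = df["markers"].map(
                lambda m: float(bool(m & POOR_RISK_MARKERS))
                if isinstance(m, frozenset)
                else np.nan
            )
        elif cov == "wbc":
            if wbc_categorical:
                out["wbc"] = (df["wbc"] >= 20).astype(float).where(df["wbc"].notna())
            else:
                out["wbc"] = df["wbc"]
        elif cov == "mrd_positive":
            # detectable MRD means >= 0.001%; stored zeros are below detection
            mrd = df["mrd_day29"]
            out["mrd_positive"] = (mrd >= 0.001).astype(float).where(mrd.notna())
        else:
            raise ValidationError(f"unknown covariate {cov!r}")
    return out


@dataclass
class EndpointReport:
    endpoint: str
    km: dict                      # group label -> KMCurve
    medians: dict                 # group label -> MedianSurvival
    logrank: LogRankResult
    univariate: pd.DataFrame      # one Wald row per covariate
    multivariate: CoxResult
    n: int
    n_events: int


def run_outcome_analysis(
    clinical: ClinicalTable,
    labels: CohortLabels,
    endpoints: Sequence[str] = ("relapse", "lfs", "os"),
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    subset: str | None = None,
    ties: str = "efron",
    wbc_categorical: bool = False,
) -> dict[str, EndpointReport]:
    """Kaplan–Meier + log-rank + univariate/multivariate Cox per endpoint.

    ``subset="high-risk"`` restricts every analysis to NCI high-risk
    patients.  Complete-case deletion is applied per model: KM/log-rank use
    all patients with the endpoint observed; each Cox model uses patients
    with all of its covariates observed.
    """
    df = clinical.df.set_index("patient")
    if subset == "high-risk":
        df = df[df["nci_risk"] == "high"]
    elif subset is not None:
        raise ValidationError(f"unknown subset filter {subset!r}")

    covs = build_covariates(clinical, labels, covariates, wbc_categorical).reindex(
        df.index
    )
    reports: dict[str, EndpointReport] = {}
    for ep in endpoints:
        tcol, ecol = f"{ep}_time", f"{ep}_event"
        if tcol not in df.columns:
            raise ValidationError(f"endpoint column {tcol!r} missing")
        observed = df[tcol].notna() & df[ecol].notna()
        if not observed.any():
            raise ValidationError(f"no observed data for endpoint {ep}")
        sub = df.loc[observed]
        lab = labels.labels.reindex(sub.index)

        km = {}
        medians = {}
        for gname in ("low", "other"):
            in_g = lab == gname
            if in_g.any():
                curve = km_fit(sub.loc[in_g, tcol], sub.loc[in_g, ecol])
                km[gname] = curve
                medians[gname] = median_survival(curve)
        lr = logrank_test(sub[tcol], sub[ecol], lab.to_numpy())

        uni_rows = []
        for cov in covs.columns:
            mask = observed & covs[cov].notna()
            fit = cox_fit(
                covs.loc[mask, [cov]].to_numpy(),
                df.loc[mask, tcol],
                df.loc[mask, ecol],
                ties=ties,
                names=[cov],
            )
            uni_rows.append(fit.summary.loc[cov])
        univariate = pd.DataFrame(uni_rows)

        mask = observed & covs.notna().all(axis=1)
        multi = cox_fit(
            covs.loc[mask].to_numpy(),
            df.loc[mask, tcol],
            df.loc[mask, ecol],
            ties=ties,
            names=list(covs.columns),
        )
        reports[ep] = EndpointReport(
            endpoint=ep,
            km=km,
            medians=medians,
            logrank=lr,
            univariate=univariate,
            multivariate=multi,
            n=int(observed.sum()),
            n_events=int(sub[ecol].sum()),
        )
    return reports


def report_to_frames(reports: Mapping[str, EndpointReport]) -> dict[str, pd.DataFrame]:
    """Flatten endpoint reports to TSV-ready frames."""
    out: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for ep, rep in reports.items():
        for gname, curve in rep.km.items():
            out[f"km_{ep}_{gname}"] = curve.to_frame()
        out[f"cox_{ep}_univariate"] = rep.univariate.rename_axis("covariate").reset_index()
        out[f"cox_{ep}_multivariate"] = (
            rep.multivariate.summary.rename_axis("covariate").reset_index()
        )
        med = {
            f"median_{g}": (m.median if m.median is not None else np.nan)
            for g, m in rep.medians.items()
        }
        summary_rows.append(
            {
                "endpoint": ep,
                "n": rep.n,
                "n_events": rep.n_events,
                "logrank_chi_square": rep.logrank.chi_square,
                "logrank_p": rep.logrank.p_value,
                **med,
            }
        )
    out["outcome_summary"] = pd.DataFrame(summary_rows)
    return out
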