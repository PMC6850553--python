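"""The three estimands of generic competition, with cluster-robust variance.

Drugs of the same therapeutic class behave alike, so every model treats the
class as the clustering unit:

* ``fit_any_generic`` — population-averaged logistic model (GEE, logit link)
  for the presence of at least one generic manufacturer; reports an OR.
* ``fit_count`` — population-averaged log-link count model (GEE, Poisson
  mean–variance, robust to overdispersion through the sandwich variance)
  for the number of generic manufacturers; reports an IRR.
* ``fit_gap_time`` — Cox proportional-hazards model for the gap time
  between consecutive generic approvals (Efron ties, cluster-robust
  variance); reports an HR.

The adjusted specification controls for the availability of a drug
substance monograph, log10 market size in the year before first generic
entry (or loss of exclusivity), drug age, vintage (approval order within
class), and route of administration.  Confidence intervals are two-sided
95% Wald intervals on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

from .errors import FitError
from .markets import ROUTE_GROUPS, STUDY_END

Z975 = stats.norm.ppf(0.975)

ESTIMANDS = ("any_generic_OR", "gap23_HR", "count_IRR", "gap12_HR")


@dataclass
class ModelFit:
    """A fitted estimand on the ratio scale with its cluster-robust CI."""

    estimand: str
    estimate_ratio: float
    ci_low: float
    ci_high: float
    robust_se_log: float
    n_drugs: int
    n_clusters: int
    covariate_estimates: dict = field(default_factory=dict)
    adjusted: bool = True
    n_events: int | None = None
    n_dropped_missing: int = 0
    dropped_constant: list = field(default_factory=list)

    @property
    def log_estimate(self) -> float:
        return float(np.log(self.estimate_ratio))

    def covers(self, ratio: float) -> bool:
        """Does the 95% CI contain the given ratio-scale value?"""
        return self.ci_low <= ratio <= self.ci_high


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def build_design(
    markets: pd.DataFrame, exposure_col: str, adjusted: bool
) -> tuple[pd.DataFrame, pd.DataFrame, list, int]:
    """Assemble the design matrix for a GEE/Cox fit.

    Returns ``(frame, X, dropped_constant, n_dropped_missing)``.  Adjusted
    fits drop markets with missing market size (counted, never silent) and
    zero-variance covariate columns (collinear with the intercept; this is
    also how route dummies vanish inside a single-route stratum).
    """
    df = markets
    n_dropped = 0
    if adjusted:
        if "market_size_missing" in df.columns:
            keep = ~df["market_size_missing"].astype(bool)
        else:
            keep = df["market_size_usd"].notna()
        n_dropped = int((~keep).sum())
        df = df.loc[keep]
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["exposure"] = df[exposure_col].astype(float)
    if adjusted:
        X["substance_monograph"] = df["has_substance_monograph"].astype(float)
        X["log10_market_size"] = np.log10(df["market_size_usd"].astype(float) + 1.0)
        X["age_years"] = df["age_years"].astype(float)
        X["vintage"] = df["vintage"].astype(float)
        for g in ROUTE_GROUPS:
            if g == "oral":  # reference category (largest group)
                continue
            X[f"route_{g}"] = (df["route_group"] == g).astype(float)
    dropped = [
        c for c in X.columns if c not in ("const", "exposure") and X[c].nunique() <= 1
    ]
    X = X.drop(columns=dropped)
    if X["exposure"].nunique() <= 1:
        raise FitError(
            "exposure has no variation in this subset",
            {"n": len(df), "exposure_col": exposure_col},
        )
    return df, X, dropped, n_dropped


# ---------------------------------------------------------------------------
# GEE fits
# ---------------------------------------------------------------------------

_COV_STRUCTS = {
    "exchangeable": sm.cov_struct.Exchangeable,
    "independence": sm.cov_struct.Independence,
}


def _fit_gee(
    markets: pd.DataFrame,
    outcome_col: str,
    exposure_col: str,
    family,
    estimand: str,
    adjusted: bool,
    cov_struct: str,
) -> ModelFit:
    df, X, dropped, n_missing = build_design(markets, exposure_col, adjusted)
    y = df[outcome_col].astype(float)
    groups = df["therapeutic_class"].astype(str)
    if groups.nunique() < 2:
        raise FitError("need at least 2 therapeutic classes", {"n_clusters": groups.nunique()})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(
                y,
                X,
                groups=groups,
                family=family,
                cov_struct=_COV_STRUCTS[cov_struct](),
            )
            res = model.fit(maxiter=100)
    except Exception as exc:  # statsmodels raises several linalg/convergence types
        raise FitError(f"GEE fit failed: {exc}", {"estimand": estimand}) from exc
    beta = res.params["exposure"]
    se = res.bse["exposure"]
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 30:
        raise FitError(
            "non-finite or diverging exposure estimate (possible separation)",
            {"beta": float(beta), "se": float(se)},
        )
    return ModelFit(
        estimand=estimand,
        estimate_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        robust_se_log=float(se),
        n_drugs=len(df),
        n_clusters=int(groups.nunique()),
        covariate_estimates={k: float(v) for k, v in res.params.items()},
        adjusted=adjusted,
        n_dropped_missing=n_missing,
        dropped_constant=dropped,
    )


def fit_any_generic(
    markets: pd.DataFrame,
    adjusted: bool = True,
    cov_struct: str = "exchangeable",
    exposure_timing: str = "before_first",
) -> ModelFit:
    """Odds ratio for having at least one generic manufacturer (GEE logit)."""
    return _fit_gee(
        markets,
        outcome_col="any_generic",
        exposure_col=f"exp_{exposure_timing}",
        family=sm.families.Binomial(),
        estimand="any_generic_OR",
        adjusted=adjusted,
        cov_struct=cov_struct,
    )


def fit_count(
    markets: pd.DataFrame,
    exposure_timing: str = "before_first",
    adjusted: bool = True,
    cov_struct: str = "exchangeable",
) -> ModelFit:
    """Incidence rate ratio for the number of generic manufacturers (GEE log link)."""
    return _fit_gee(
        markets,
        outcome_col="n_generics",
        exposure_col=f"exp_{exposure_timing}",
        family=sm.families.Poisson(),
        estimand="count_IRR",
        adjusted=adjusted,
        cov_struct=cov_struct,
    )


# ---------------------------------------------------------------------------
# Gap-time Cox model
# ---------------------------------------------------------------------------

_FROM_K_TIMING = {1: "before_first", 2: "before_second", 3: "before_third"}


def fit_gap_time(
    markets: pd.DataFrame,
    from_k: int = 2,
    to_k: int = 3,
    adjusted: bool = True,
    study_end: date = STUDY_END,
) -> ModelFit:
    """Hazard ratio for the gap time between the ``from_k``-th and
    ``to_k``-th generic approvals.

    Restricted to markets with at least ``from_k`` generics; markets whose
    ``to_k``-th entrant is unobserved are censored at the end of study.
    Exposure is a product monograph official before the ``from_k``-th
    entrant.  Efron tie handling; variance is cluster-robust by
    therapeutic class.
    """
    if to_k != from_k + 1:
        raise ValueError("gap model is defined for consecutive entrants")
    sub = markets.loc[markets["n_generics"] >= from_k].copy()
    if not len(sub):
        raise FitError(f"no markets with >= {from_k} generics", {"from_k": from_k})
    durations, events = [], []
    for dates in sub["generic_approval_dates"]:
        start = dates[from_k - 1]
        if len(dates) >= to_k:
            durations.append(max((dates[to_k - 1] - start).days, 0.5))
            events.append(1)
        else:
            durations.append(max((study_end - start).days, 0.5))
            events.append(0)
    sub["gap_duration"] = durations
    sub["gap_event"] = events
    if sum(events) == 0:
        raise FitError("no events in gap-time model", {"n": len(sub)})
    exposure_col = f"exp_{_FROM_K_TIMING[from_k]}"
    df, X, dropped, n_missing = build_design(sub, exposure_col, adjusted)
    fit_df = X.drop(columns=["const"]).copy()
    fit_df["gap_duration"] = sub.loc[df.index, "gap_duration"]
    fit_df["gap_event"] = sub.loc[df.index, "gap_event"]
    fit_df["_cluster"] = df["therapeutic_class"].astype(str).values
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                fit_df,
                duration_col="gap_duration",
                event_col="gap_event",
                cluster_col="_cluster",
                robust=True,
                show_progress=False,
            )
    except Exception as exc:
        raise FitError(f"Cox fit failed: {exc}", {"n": len(fit_df)}) from exc
    beta = float(cph.params_["exposure"])
    se = float(cph.standard_errors_["exposure"])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 30:
        raise FitError("diverging Cox estimate", {"beta": beta, "se": se})
    estimand = "gap12_HR" if from_k == 1 else "gap23_HR"
    return ModelFit(
        estimand=estimand,
        estimate_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        robust_se_log=se,
        n_drugs=len(fit_df),
        n_clusters=int(fit_df["_cluster"].nunique()),
        covariate_estimates={k: float(v) for k, v in cph.params_.items()},
        adjusted=adjusted,
        n_events=int(fit_df["gap_event"].sum()),
        n_dropped_missing=n_missing,
        dropped_constant=dropped,
    )


# ---------------------------------------------------------------------------
# Kaplan–Meier summary
# ---------------------------------------------------------------------------


@dataclass
class KMSummary:
    median: float  # inf when not reached
    ci_low: float
    ci_high: float
    curve: pd.DataFrame  # columns: time, survival

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


def km_summary(times, event_flags) -> KMSummary:
    """Product-limit estimate with median and log-log CI of the median.

    The median is the first time at which estimated survival drops to 0.5
    or below; when survival never reaches 0.5 the median is reported as
    not reached (``inf``).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=int)
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    ci_low = float(ci.iloc[0, 0])
    ci_high = float(ci.iloc[0, 1])
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    return KMSummary(median=median, ci_low=ci_low, ci_high=ci_high, curve=curve)


# ---------------------------------------------------------------------------
# Sandwich covariance primitive
# ---------------------------------------------------------------------------


def sandwich_covariance(cluster_scores, bread) -> np.ndarray:
    """Cluster-robust sandwich covariance B^-1 (sum_c s_c s_c^T) B^-T.

    ``cluster_scores`` is an (n_clusters, p) array whose c-th row is the
    summed estimating-function contribution of cluster c; ``bread`` is the
    p x p derivative (bread) matrix.  The result is symmetrized to guard
    against floating-point asymmetry.
    """
    S = np.atleast_2d(np.asarray(cluster_scores, dtype=float))
    B = np.asarray(bread, dtype=float)
    meat = S.T @ S
    Binv = np.linalg.inv(B)
    cov = Binv @ meat @ Binv.T
    return (cov + cov.T) / 2.0


# ---------------------------------------------------------------------------
# Table-2-style report
# ---------------------------------------------------------------------------


def make_table2(markets: pd.DataFrame, cov_struct: str = "exchangeable") -> pd.DataFrame:
    """Crude and adjusted rows for the three main estimands."""
    rows = []
    specs = [
        ("availability of generics", "OR", lambda adj: fit_any_generic(markets, adjusted=adj, cov_struct=cov_struct)),
        ("time between second and third generic", "HR", lambda adj: fit_gap_time(markets, 2, 3, adjusted=adj)),
        ("number of generic manufacturers", "IRR", lambda adj: fit_count(markets, adjusted=adj, cov_struct=cov_struct)),
    ]
    for label, scale, fitter in specs:
        for adj in (False, True):
            try:
                f = fitter(adj)
                rows.append(
                    {
                        "association": label,
                        "model": ("Adj. " if adj else "Crude ") + scale,
                        "estimate": f.estimate_ratio,
                        "ci_low": f.ci_low,
                        "ci_high": f.ci_high,
                        "n_drugs": f.n_drugs,
                        "n_clusters": f.n_clusters,
                        "error": "",
                    }
                )
            except FitError as exc:
                rows.append(
                    {
                        "association": label,
                        "model": ("Adj. " if adj else "Crude ") + scale,
                        "estimate": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "n_drugs": 0,
                        "n_clusters": 0,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)
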