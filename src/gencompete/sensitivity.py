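"""Sensitivity and secondary analyses.

Every function here re-runs the *same* fitting code as the main analysis
(:func:`gencompete.models.fit_count` / :func:`gencompete.models.fit_gap_time`),
differing only in the input subset or the exposure-timing flag, so a
sensitivity estimate can never drift from the main estimand's
implementation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FitError
from .markets import ROUTE_GROUPS
from .models import ModelFit, fit_count, fit_gap_time


def run_timing_variants(
    markets: pd.DataFrame, adjusted: bool = True, cov_struct: str = "exchangeable"
) -> dict[str, ModelFit]:
    """Main count model with the exposure timed before the 2nd / 3rd entrant."""
    out = {}
    for timing in ("before_second", "before_third"):
        out[timing] = fit_count(
            markets, exposure_timing=timing, adjusted=adjusted, cov_struct=cov_struct
        )
    return out


def run_interval_restrictions(
    markets: pd.DataFrame,
    thresholds_years=(3, 5, 8),
    adjusted: bool = True,
    cov_struct: str = "exchangeable",
) -> dict[int, ModelFit | FitError]:
    """Refit the main model excluding drugs whose first generic arrived
    within ``threshold`` years of the NDA.

    Markets with no generic are never excluded (they have no interval).
    An empty or degenerate subset is reported as the :class:`FitError`
    itself rather than raised, so one unestimable restriction does not
    abort the rest.
    """
    out: dict[int, ModelFit | FitError] = {}
    nda = pd.to_datetime(markets["nda_approval_date"])
    g1 = pd.to_datetime(markets["first_generic_date"])
    interval_years = (g1 - nda).dt.days / 365.25
    for thr in thresholds_years:
        keep = interval_years.isna() | (interval_years > thr)
        try:
            out[thr] = fit_count(
                markets.loc[keep], adjusted=adjusted, cov_struct=cov_struct
            )
        except FitError as exc:
            out[thr] = exc
    return out


def run_class_size_restrictions(
    markets: pd.DataFrame,
    max_class_sizes=(10, 21, 54),
    adjusted: bool = True,
    cov_struct: str = "exchangeable",
) -> dict[int, ModelFit | FitError]:
    """Refit the main model keeping only classes with fewer than N drugs
    (strict inequality)."""
    out: dict[int, ModelFit | FitError] = {}
    sizes = markets.groupby("therapeutic_class")["ingredient"].transform("size")
    for cap in max_class_sizes:
        keep = sizes < cap
        try:
            out[cap] = fit_count(
                markets.loc[keep], adjusted=adjusted, cov_struct=cov_struct
            )
        except FitError as exc:
            out[cap] = exc
    return out


def run_route_strata(
    markets: pd.DataFrame, adjusted: bool = True, cov_struct: str = "exchangeable"
) -> dict[str, ModelFit | FitError]:
    """Refit the main model within each route-of-administration stratum.

    Route dummies are constant within a stratum and drop out of the design
    automatically; class clustering is retained within strata.
    """
    out: dict[str, ModelFit | FitError] = {}
    for group in ROUTE_GROUPS:
        sub = markets.loc[markets["route_group"] == group]
        if not len(sub):
            out[group] = FitError(f"empty stratum: {group}", {"n": 0})
            continue
        try:
            out[group] = fit_count(sub, adjusted=adjusted, cov_struct=cov_struct)
        except FitError as exc:
            out[group] = exc
    return out


def run_gap12(markets: pd.DataFrame, adjusted: bool = True) -> ModelFit:
    """Cox model for the time between the first and second generic approvals."""
    return fit_gap_time(markets, from_k=1, to_k=2, adjusted=adjusted)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


def _row(label: str, fit) -> dict:
    if isinstance(fit, ModelFit):
        return {
            "analysis": label,
            "estimate": fit.estimate_ratio,
            "ci_low": fit.ci_low,
            "ci_high": fit.ci_high,
            "n_drugs": fit.n_drugs,
            "error": "",
        }
    return {
        "analysis": label, "estimate": np.nan, "ci_low": np.nan,
        "ci_high": np.nan, "n_drugs": 0, "error": str(fit),
    }


def make_table3(
    markets: pd.DataFrame, adjusted: bool = True, cov_struct: str = "exchangeable"
) -> pd.DataFrame:
    """Sensitivity-analysis report: timing variants, interval and class-size
    restrictions, route strata (all IRRs)."""
    rows = []
    timing_labels = {
        "before_second": "monograph before 2nd generic entry",
        "before_third": "monograph before 3rd generic entry",
    }
    for timing, fit in run_timing_variants(markets, adjusted, cov_struct).items():
        rows.append(_row(timing_labels[timing], fit))
    for thr, fit in run_interval_restrictions(
        markets, adjusted=adjusted, cov_struct=cov_struct
    ).items():
        rows.append(_row(f"first generic > {thr} years after NDA", fit))
    for cap, fit in run_class_size_restrictions(
        markets, adjusted=adjusted, cov_struct=cov_struct
    ).items():
        rows.append(_row(f"therapeutic classes with < {cap} drugs", fit))
    for group, fit in run_route_strata(markets, adjusted, cov_struct).items():
        rows.append(_row(f"route stratum: {group}", fit))
    return pd.DataFrame(rows)


def make_table4(markets: pd.DataFrame) -> pd.DataFrame:
    """Secondary analysis report: first-to-second generic gap time (HR)."""
    rows = []
    for adjusted in (False, True):
        try:
            fit = run_gap12(markets, adjusted=adjusted)
        except FitError as exc:
            fit = exc
        rows.append(_row(("Adj." if adjusted else "Crude") + " gap 1st-to-2nd HR", fit))
    return pd.DataFrame(rows)
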