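"""Model fits against independent closed-form oracles."""

import math
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from gencompete.errors import FitError
from gencompete.models import (
    fit_any_generic,
    fit_count,
    fit_gap_time,
    km_summary,
    sandwich_covariance,
)


def _toy_markets(exposures, counts, classes=None, entrant_gap_days=None):
    """Markets frame with just enough structure for crude fits."""
    n = len(exposures)
    classes = classes or [f"K{i}" for i in range(n)]
    rows = []
    for i in range(n):
        k = counts[i]
        base = date(2000, 1, 1)
        if entrant_gap_days is not None:
            gaps = entrant_gap_days[i]
            dates, t = [], base
            for g in gaps:
                t = t + timedelta(days=g)
                dates.append(t)
        else:
            dates = [base + timedelta(days=365 * (j + 1)) for j in range(k)]
        rows.append(
            {
                "ingredient": f"D{i}",
                "route": "ORAL",
                "therapeutic_class": classes[i],
                "route_group": "oral",
                "n_generics": len(dates),
                "generic_approval_dates": dates,
                "any_generic": int(len(dates) >= 1),
                "exp_before_first": exposures[i],
                "exp_before_second": exposures[i],
                "exp_before_third": exposures[i],
                "exp_ever": exposures[i],
                "has_substance_monograph": 0,
                "market_size_usd": 1.0e7,
                "market_size_missing": False,
                "age_years": 10.0,
                "vintage": 1,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GEE count model
# ---------------------------------------------------------------------------


def test_covariate_free_irr_is_ratio_of_group_means():
    # score identity for log link with intercept + binary exposure
    exposures = [1] * 6 + [0] * 6
    counts = [5, 3, 4, 6, 2, 4] + [1, 2, 1, 0, 3, 1]
    m = _toy_markets(exposures, counts, classes=["A", "B"] * 6)
    fit = fit_count(m, adjusted=False, cov_struct="independence")
    expected = np.mean(counts[:6]) / np.mean(counts[6:])
    assert fit.estimate_ratio == pytest.approx(expected, rel=1e-6)


def test_crude_equals_adjusted_when_covariates_constant():
    exposures = [1, 1, 0, 0, 1, 0]
    counts = [4, 5, 2, 1, 3, 2]
    m = _toy_markets(exposures, counts, classes=["A", "A", "A", "B", "B", "B"])
    crude = fit_count(m, adjusted=False, cov_struct="independence")
    adjusted = fit_count(m, adjusted=True, cov_struct="independence")
    assert adjusted.estimate_ratio == pytest.approx(crude.estimate_ratio, rel=1e-8)
    # every adjustment covariate was constant, hence dropped
    assert set(adjusted.covariate_estimates) == {"const", "exposure"}


def test_single_class_raises_fit_error():
    m = _toy_markets([1, 0, 1, 0], [3, 1, 2, 1], classes=["A"] * 4)
    with pytest.raises(FitError):
        fit_count(m, adjusted=False)


def test_constant_exposure_raises_fit_error():
    m = _toy_markets([1, 1, 1, 1], [3, 1, 2, 1])
    with pytest.raises(FitError):
        fit_count(m, adjusted=False)


def test_logistic_fit_runs_and_is_symmetric_under_flip():
    exposures = [1] * 8 + [0] * 8
    counts = [1, 1, 1, 0, 1, 1, 0, 1] + [1, 0, 0, 1, 0, 0, 1, 0]
    m = _toy_markets(exposures, counts, classes=list("ABCDEFGH") * 2)
    fit = fit_any_generic(m, adjusted=False, cov_struct="independence")
    # crude OR equals the 2x2 cross-product ratio
    a, b = 6, 2  # exposed with/without generic
    c, d = 3, 5  # unexposed with/without
    assert fit.estimate_ratio == pytest.approx((a * d) / (b * c), rel=1e-5)


# ---------------------------------------------------------------------------
# Cox gap-time model
# ---------------------------------------------------------------------------


def test_gap_time_matches_hand_solved_partial_likelihood():
    """Three markets, all with 3 entrants; 2nd->3rd gaps of 1, 2, 3 days for
    (exposed, unexposed, exposed).  The partial likelihood
    L = [e^b/(2e^b+1)] * [1/(e^b+1)] is maximized at e^b = 1/sqrt(2)."""
    m = _toy_markets(
        [1, 0, 1],
        [3, 3, 3],
        entrant_gap_days=[[100, 100, 1], [100, 100, 2], [100, 100, 3]],
    )
    fit = fit_gap_time(m, from_k=2, to_k=3, adjusted=False)
    assert fit.estimate_ratio == pytest.approx(2 ** -0.5, rel=1e-3)
    assert fit.n_events == 3


def test_gap_time_invariant_to_time_unit():
    gaps = [[100, 100, 7], [100, 100, 21], [100, 100, 35], [100, 100, 14]]
    gaps_wk = [[g[0], g[1], g[2] // 7] for g in gaps]
    m_days = _toy_markets([1, 0, 1, 0], [3, 3, 3, 3], entrant_gap_days=gaps)
    m_weeks = _toy_markets([1, 0, 1, 0], [3, 3, 3, 3], entrant_gap_days=gaps_wk)
    f1 = fit_gap_time(m_days, adjusted=False)
    f2 = fit_gap_time(m_weeks, adjusted=False)
    assert f1.estimate_ratio == pytest.approx(f2.estimate_ratio, rel=1e-6)


def test_gap_time_censors_markets_without_third_entrant(small_markets):
    fit = fit_gap_time(small_markets, from_k=2, to_k=3, adjusted=True)
    at_risk = (small_markets["n_generics"] >= 2).sum()
    events = (small_markets["n_generics"] >= 3).sum()
    assert fit.n_drugs == at_risk - fit.n_dropped_missing
    assert fit.n_events <= events
    assert fit.ci_low < fit.estimate_ratio < fit.ci_high


def test_gap_time_no_events_raises():
    m = _toy_markets([1, 0], [2, 2])
    with pytest.raises(FitError):
        fit_gap_time(m, from_k=2, to_k=3, adjusted=False)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def test_km_median_uncensored_1_to_100():
    km = km_summary(list(range(1, 101)), [1] * 100)
    assert km.median == 50  # first time survival drops to <= 0.5
    assert km.curve["survival"].iloc[-1] == 0.0


def test_km_all_censored_median_not_reached():
    km = km_summary([10, 20, 30], [0, 0, 0])
    assert not km.median_reached


def test_km_single_event():
    km = km_summary([5.0], [1])
    assert km.median == 5.0


def test_km_negative_times_rejected():
    with pytest.raises(ValueError):
        km_summary([-1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# sandwich covariance
# ---------------------------------------------------------------------------


def test_sandwich_equals_textbook_hc0_linear_model():
    rng = np.random.default_rng(42)
    n, p = 20, 3
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta = np.array([1.0, 2.0, -0.5])
    y = X @ beta + rng.normal(scale=0.5 + 0.5 * np.abs(X[:, 1]), size=n)
    bhat = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ bhat
    # each observation is its own cluster
    scores = X * resid[:, None]
    cov = sandwich_covariance(scores, X.T @ X)
    hc0 = np.linalg.inv(X.T @ X) @ (X.T @ np.diag(resid**2) @ X) @ np.linalg.inv(X.T @ X)
    np.testing.assert_allclose(cov, hc0, rtol=1e-12)


def test_sandwich_duplicating_clusters_halves_covariance():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=(6, 2))
    bread = np.array([[4.0, 1.0], [1.0, 3.0]])
    cov1 = sandwich_covariance(scores, bread)
    cov2 = sandwich_covariance(np.vstack([scores, scores]), 2 * bread)
    np.testing.assert_allclose(cov2, cov1 / 2.0, rtol=1e-12)


def test_sandwich_zero_scores_zero_covariance():
    cov = sandwich_covariance(np.zeros((5, 2)), np.eye(2))
    np.testing.assert_array_equal(cov, np.zeros((2, 2)))


def test_sandwich_output_symmetric_psd():
    rng = np.random.default_rng(3)
    cov = sandwich_covariance(rng.normal(size=(8, 4)), rng.normal(size=(4, 4)) + 4 * np.eye(4))
    np.testing.assert_allclose(cov, cov.T)
    assert np.linalg.eigvalsh(cov).min() >= -1e-10
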