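"""Counterfactual cost-savings engine.

The counterfactual asks what drug spending would have been had no drug
product monographs existed.  For each exposed market (product monograph
official before the first generic entrant) and each calendar year:

1.  N_P = N_A / IRR — the predicted manufacturer count with the monograph
    effect removed (the IRR is the fitted multiplicative effect of the
    monograph on the number of generic manufacturers);
2.  P_P = (D(N_P) / D(N_A)) * P_A — the predicted price, where D(n) is a
    competition–price curve giving relative price as a function of the
    number of generic competitors;
3.  predicted sales = P_P * V_A (volume is held fixed: no demand response
    to price is modelled);
4.  savings = predicted sales - actual sales, summed within year.

Unexposed markets contribute nothing.  Predicted counts are kept
continuous; the curve is interpolated linearly between integer knots and
extrapolated as constant beyond the last knot; only the aggregate
"additional manufacturers" total is rounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class PriceCompetitionCurve:
    """Relative price as a function of the number of generic manufacturers.

    ``points`` maps strictly increasing integer competitor counts (starting
    at 0) to relative prices in (0, 1]; a market with no generic
    competition is the price reference, so D(0) = 1 and D is nonincreasing.
    """

    points: tuple  # ordered tuple of (n_generics, relative_price)

    def __post_init__(self):
        pts = tuple((int(n), float(p)) for n, p in self.points)
        object.__setattr__(self, "points", pts)
        ns = [n for n, _ in pts]
        ps = [p for _, p in pts]
        if not pts or ns[0] != 0:
            raise ValidationError("curve must start at n = 0")
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValidationError("competitor counts must be strictly increasing")
        if abs(ps[0] - 1.0) > 1e-12:
            raise ValidationError("relative price at n = 0 must be 1")
        if any(p <= 0 or p > 1 for p in ps):
            raise ValidationError("relative prices must lie in (0, 1]")
        if any(b > a + 1e-12 for a, b in zip(ps, ps[1:])):
            raise ValidationError("relative price must be nonincreasing in n")

    def __call__(self, n) -> float:
        return relative_price(self, n)

    @classmethod
    def from_csv(cls, path) -> "PriceCompetitionCurve":
        df = pd.read_csv(path)
        for col in ("n_generics", "relative_price"):
            if col not in df.columns:
                raise ValidationError(f"curve file {path} lacks column {col!r}")
        return cls(tuple(zip(df["n_generics"], df["relative_price"])))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.points, columns=["n_generics", "relative_price"]).to_csv(
            path, index=False
        )


#: Illustrative curve for tests and simulation only.  The magnitude of the
#: price decline with competitor count is loosely in line with published
#: generic-competition analyses, but these knots are NOT estimates from any
#: real dataset; supply your own curve for substantive use.
ILLUSTRATIVE_CURVE = PriceCompetitionCurve(
    ((0, 1.00), (1, 0.85), (2, 0.55), (3, 0.45), (4, 0.40),
     (5, 0.36), (6, 0.33), (8, 0.28), (10, 0.25))
)


def relative_price(curve: PriceCompetitionCurve, n) -> float:
    """Evaluate the curve at a (possibly non-integer) competitor count.

    Exact at knots, linear between knots, constant beyond the last knot.
    """
    n = float(n)
    if n < 0:
        raise ValidationError("competitor count must be nonnegative")
    ns = np.array([k for k, _ in curve.points], dtype=float)
    ps = np.array([p for _, p in curve.points], dtype=float)
    return float(np.interp(n, ns, ps))


def predict_manufacturers(n_actual: float, irr: float) -> float:
    """Counterfactual manufacturer count with the monograph effect removed.

    Dividing the actual count by the IRR undoes the multiplicative effect
    of the monograph on entry; the result is continuous, not rounded.
    """
    if irr <= 0:
        raise ValidationError(f"IRR must be positive, got {irr}")
    if n_actual < 0:
        raise ValidationError("n_actual must be nonnegative")
    return n_actual / irr


def predicted_price(
    price_actual: float, curve: PriceCompetitionCurve, n_actual: float, n_predicted: float
) -> float:
    """P_P = (D(N_P) / D(N_A)) * P_A."""
    if price_actual <= 0:
        raise ValidationError("price_actual must be positive")
    return relative_price(curve, n_predicted) / relative_price(curve, n_actual) * price_actual


def _entrants_by_end_of_year(dates, year: int) -> int:
    return sum(1 for d in dates if d.year <= year)


def compute_savings(
    markets: pd.DataFrame,
    sales: pd.DataFrame,
    irr: float,
    curve: PriceCompetitionCurve,
    years,
    exposure_col: str = "exp_before_first",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per market-year counterfactual quantities and yearly totals.

    ``markets`` must carry the exposure indicator named by ``exposure_col``
    and the entrant timelines; ``sales`` is the drug-year panel.  The
    actual manufacturer count for a market-year is the number of generic
    entrants approved by the end of that year.  Rows with zero volume but
    nonzero dollars are flagged and skipped.  Returns ``(rows, totals)``;
    totals report the yearly savings sum and the rounded aggregate
    difference between actual and predicted manufacturer counts.
    """
    if irr <= 0:
        raise ValidationError(f"IRR must be positive, got {irr}")
    panel = {
        (i, r, int(y)): (float(d), float(v))
        for i, r, y, d, v in zip(
            sales["ingredient"], sales["route"], sales["year"],
            sales["dollars"], sales["volume"],
        )
    }
    rows = []
    exposed = markets.loc[markets[exposure_col].astype(bool)]
    for _, m in exposed.iterrows():
        for year in years:
            key = (m["ingredient"], m["route"], int(year))
            if key not in panel:
                continue
            dollars, volume = panel[key]
            if volume <= 0:
                if dollars > 0:
                    rows.append(
                        {
                            "ingredient": m["ingredient"], "route": m["route"],
                            "year": int(year), "flag": "zero_volume", "savings": np.nan,
                        }
                    )
                continue
            n_actual = _entrants_by_end_of_year(m["generic_approval_dates"], int(year))
            n_pred = predict_manufacturers(n_actual, irr)
            price_actual = dollars / volume
            price_pred = predicted_price(price_actual, curve, n_actual, n_pred)
            sales_pred = price_pred * volume
            rows.append(
                {
                    "ingredient": m["ingredient"],
                    "route": m["route"],
                    "year": int(year),
                    "n_actual": n_actual,
                    "n_predicted": n_pred,
                    "price_actual": price_actual,
                    "price_predicted": price_pred,
                    "volume_actual": volume,
                    "sales_actual": dollars,
                    "sales_predicted": sales_pred,
                    "savings": sales_pred - dollars,
                    "flag": "",
                }
            )
    rows_df = pd.DataFrame(
        rows,
        columns=[
            "ingredient", "route", "year", "n_actual", "n_predicted",
            "price_actual", "price_predicted", "volume_actual",
            "sales_actual", "sales_predicted", "savings", "flag",
        ],
    )
    ok = rows_df.loc[rows_df["flag"] == ""] if len(rows_df) else rows_df
    totals = []
    for year in years:
        sub = ok.loc[ok["year"] == int(year)] if len(ok) else ok
        extra = float((sub["n_actual"] - sub["n_predicted"]).sum()) if len(sub) else 0.0
        totals.append(
            {
                "year": int(year),
                "total_savings": float(sub["savings"].sum()) if len(sub) else 0.0,
                "additional_manufacturers": int(round(extra)),
                "n_markets": int(len(sub)),
            }
        )
    return rows_df, pd.DataFrame(totals)
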