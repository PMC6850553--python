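"""Collapse product records into one market per ingredient–route.

A *market* is an ingredient–route combination: the originator's NDA defines
its approval date, and each distinct ANDA applicant contributes at most one
generic entrant timed at that applicant's first approval (the outcome of
interest is the number of generic *manufacturers*, not the number of
applications).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import MarketKey, normalize_key
from .errors import ValidationError
from .io import ProductRecord

logger = logging.getLogger(__name__)

#: Administrative end of follow-up: approvals after this date are unobserved.
STUDY_END = date(2018, 4, 3)

ROUTE_GROUPS = ("inhalation", "intravenous", "oral", "topical", "other")

_ROUTE_KEYWORDS = {
    "inhalation": ("INHALATION", "RESPIRATORY", "NASAL"),
    "intravenous": ("INTRAVENOUS", "INJECTION", "INJECTABLE", "IV ", "INTRAMUSCULAR",
                    "SUBCUTANEOUS", "PARENTERAL"),
    "oral": ("ORAL", "SUBLINGUAL", "BUCCAL"),
    "topical": ("TOPICAL", "TRANSDERMAL", "DERMAL", "OPHTHALMIC", "OTIC"),
}

TIMINGS = ("before_first", "before_second", "before_third", "ever")
_TIMING_K = {"before_first": 1, "before_second": 2, "before_third": 3}


def route_group(route: str) -> str:
    """Map a free-text route of administration to one of five groups."""
    r = (route or "").upper()
    for group, words in _ROUTE_KEYWORDS.items():
        if any(w in r for w in words):
            return group
    return "other"


@dataclass
class DrugMarket:
    """One ingredient–route market with its entrant timeline and covariates."""

    key: MarketKey
    nda_approval_date: date | None
    generic_approval_dates: list[date]
    therapeutic_class: str | None
    route_group: str
    product_monograph_date: date | None = None
    substance_monograph_date: date | None = None
    age_years: float = float("nan")
    vintage: int = 0
    market_size_usd: float = float("nan")
    loss_of_exclusivity_date: date | None = None

    @property
    def n_generics(self) -> int:
        return len(self.generic_approval_dates)


# ---------------------------------------------------------------------------
# build_markets
# ---------------------------------------------------------------------------


def build_markets(
    products: Sequence[ProductRecord],
    sales: pd.DataFrame | None = None,
    study_end: date = STUDY_END,
) -> pd.DataFrame:
    """Collapse product records into one row per ingredient–route market.

    The earliest NDA defines the market's approval date; generic entrants
    are distinct ANDA applicants timed at their first approval and sorted
    ascending.  Markets with no NDA record are excluded with a warning
    (their age since brand approval is undefined).  ``sales`` (a frame with
    ``ingredient``/``route`` columns, already canonical) sets the
    ``sales_match`` flag.
    """
    sales_keys: set[tuple] = set()
    if sales is not None and len(sales):
        sales_keys = {
            (normalize_key(i, r).ingredient_norm, normalize_key(i, r).route_norm)
            for i, r in zip(sales["ingredient"], sales["route"])
        }

    groups: dict[tuple, list[ProductRecord]] = {}
    for rec in products:
        key = normalize_key(rec.ingredient, rec.route)
        groups.setdefault(tuple(key), []).append(rec)

    rows = []
    for key in sorted(groups):
        recs = groups[key]
        ndas = [r for r in recs if r.application_type == "NDA"]
        andas = [r for r in recs if r.application_type == "ANDA"]
        if not ndas:
            logger.warning("market %s has no NDA record; excluded", key)
            continue
        pre82 = any(r.approved_pre_1982 for r in ndas)
        dated = [r.approval_date for r in ndas if r.approval_date is not None]
        nda_date = min(dated) if dated else None
        # one entrant per distinct ANDA applicant, at its first approval
        by_applicant: dict[str, date] = {}
        for r in andas:
            if r.approval_date is None:
                continue
            a = r.applicant.strip().upper()
            if a not in by_applicant or r.approval_date < by_applicant[a]:
                by_applicant[a] = r.approval_date
        entrant_dates = sorted(d for d in by_applicant.values() if d <= study_end)
        classes = [r.therapeutic_class for r in recs if r.therapeutic_class]
        loes = [r.loe_date for r in recs if r.loe_date is not None]
        rows.append(
            {
                "ingredient": key[0],
                "route": key[1],
                "is_combination": ";" in key[0],
                "nda_approval_date": nda_date,
                "nda_pre_1982": pre82,
                "generic_approval_dates": entrant_dates,
                "n_generics": len(entrant_dates),
                "first_generic_date": entrant_dates[0] if entrant_dates else None,
                "therapeutic_class": classes[0] if classes else None,
                "route_group": route_group(key[1]),
                "otc": any(r.otc_flag for r in ndas),
                "discontinued": any(r.discontinued_flag for r in ndas),
                "under_patent": any(r.under_patent_flag for r in recs),
                "loe_date": min(loes) if loes else None,
                "sales_match": key in sales_keys,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------


def compute_vintage(markets: pd.DataFrame) -> pd.Series:
    """Approval order within therapeutic class (competition ranking).

    The earliest NDA in a class gets vintage 1; ties share the lower rank
    and the next rank is skipped (1, 2, 2, 4, ...).
    """
    approved = pd.to_datetime(markets["nda_approval_date"])
    return (
        approved.groupby(markets["therapeutic_class"])
        .rank(method="min")
        .astype(int)
    )


def _sales_lookup(sales: pd.DataFrame) -> dict[tuple, float]:
    return {
        (i, r, int(y)): float(d)
        for i, r, y, d in zip(
            sales["ingredient"], sales["route"], sales["year"], sales["dollars"]
        )
    }


def compute_market_size(market_row, sales) -> tuple[float, bool]:
    """Dollar sales in the year before first generic entry (or LOE).

    ``sales`` may be the panel frame or a prebuilt lookup dict.  Returns
    ``(dollars, flagged)``; ``flagged`` is True when the reference year is
    missing from the panel (the market's size is unknown and the market is
    dropped from adjusted fits).
    """
    lookup = sales if isinstance(sales, dict) else _sales_lookup(sales)
    event = market_row["first_generic_date"]
    if event is None or (isinstance(event, float) and math.isnan(event)):
        event = market_row["loe_date"]
    if event is None or (isinstance(event, float) and math.isnan(event)):
        return float("nan"), True
    ref_year = pd.Timestamp(event).year - 1
    key = (market_row["ingredient"], market_row["route"], ref_year)
    if key not in lookup:
        return float("nan"), True
    return lookup[key], False


def compute_exposure(
    product_monograph_date: date | None,
    generic_approval_dates: Sequence[date],
    timing: str,
    study_end: date = STUDY_END,
) -> bool:
    """Was the product monograph official before the k-th generic entrant?

    True iff a product monograph exists and its official date strictly
    precedes the relevant entrant's approval date; for a market with fewer
    entrants than the timing requires, the date must precede the end of
    study.  ``timing`` is one of ``before_first`` / ``before_second`` /
    ``before_third`` / ``ever``.
    """
    if timing not in TIMINGS:
        raise ValidationError(f"unknown exposure timing: {timing!r}")
    if product_monograph_date is None:
        return False
    if timing == "ever":
        return product_monograph_date < study_end
    k = _TIMING_K[timing]
    if len(generic_approval_dates) >= k:
        return product_monograph_date < generic_approval_dates[k - 1]
    return product_monograph_date < study_end


def add_covariates(
    markets: pd.DataFrame,
    sales: pd.DataFrame | None = None,
    study_end: date = STUDY_END,
) -> pd.DataFrame:
    """Add model covariates to a cohort markets frame.

    Adds ``age_years`` (NDA approval to end of study, fractional years),
    ``vintage``, ``market_size_usd`` (+ ``market_size_missing`` flag),
    ``any_generic``, ``has_substance_monograph``, and the four exposure
    timing indicators ``exp_before_first`` ... ``exp_ever``.
    """
    m = markets.copy()
    approved = pd.to_datetime(m["nda_approval_date"])
    m["age_years"] = (pd.Timestamp(study_end) - approved).dt.days / 365.25
    m["vintage"] = compute_vintage(m)
    if sales is not None:
        lookup = _sales_lookup(sales)
        vals, flags = [], []
        for ing, rt, g1, loe in zip(
            m["ingredient"], m["route"], m["first_generic_date"], m["loe_date"]
        ):
            event = g1 if pd.notna(g1) else (loe if pd.notna(loe) else None)
            if event is None:
                vals.append(float("nan"))
                flags.append(True)
                continue
            key = (ing, rt, pd.Timestamp(event).year - 1)
            vals.append(lookup.get(key, float("nan")))
            flags.append(key not in lookup)
        m["market_size_usd"] = vals
        m["market_size_missing"] = flags
    elif "market_size_usd" not in m.columns:
        m["market_size_usd"] = np.nan
        m["market_size_missing"] = True
    m["any_generic"] = (m["n_generics"] >= 1).astype(int)
    m["has_substance_monograph"] = m["substance_monograph_date"].notna().astype(int)
    for timing in TIMINGS:
        m[f"exp_{timing}"] = [
            compute_exposure(pm if pd.notna(pm) else None, dates, timing, study_end)
            for pm, dates in zip(m["product_monograph_date"], m["generic_approval_dates"])
        ]
        m[f"exp_{timing}"] = m[f"exp_{timing}"].astype(int)
    return m


# ---------------------------------------------------------------------------
# Flat-file round trip for the markets table
# ---------------------------------------------------------------------------

_DATE_COLS = (
    "nda_approval_date",
    "first_generic_date",
    "product_monograph_date",
    "substance_monograph_date",
    "loe_date",
)


def markets_to_csv(markets: pd.DataFrame, path) -> None:
    out = markets.copy()
    out["generic_approval_dates"] = [
        ";".join(d.isoformat() for d in dates) for dates in out["generic_approval_dates"]
    ]
    for col in _DATE_COLS:
        if col in out.columns:
            out[col] = [
                pd.Timestamp(v).date().isoformat() if pd.notna(v) else ""
                for v in out[col]
            ]
    out.to_csv(path, index=False)


def markets_from_csv(path) -> pd.DataFrame:
    m = pd.read_csv(path, keep_default_na=False, na_values=[""])
    m["generic_approval_dates"] = [
        [date.fromisoformat(p) for p in str(s).split(";") if p]
        if pd.notna(s) and str(s) != ""
        else []
        for s in m["generic_approval_dates"]
    ]
    for col in _DATE_COLS:
        if col in m.columns:
            m[col] = [
                date.fromisoformat(str(v)) if pd.notna(v) and str(v) else None
                for v in m[col]
            ]
    if "therapeutic_class" in m.columns:
        m["therapeutic_class"] = m["therapeutic_class"].astype(str)
    return m
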