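"""Ingredient–route linkage and the eligibility cascade.

Monograph linkage is performed at the ingredient–route level (e.g.
furosemide–intravenous): drug *product* monographs, which standardize a
finished dosage form, match on ingredient and route; drug *substance*
monographs describe the active ingredient itself and match on ingredient
alone.

Eligibility is a sequential flow-diagram cascade: each market is attributed
to the FIRST filter it fails, and an attrition ledger records every step so
the final cohort size is auditable (ledger counts telescope exactly).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from typing import Callable, NamedTuple

import pandas as pd

from .errors import ConfigError, ValidationError

_WS = re.compile(r"\s+")


class MarketKey(NamedTuple):
    """Canonical (ingredient, route) key: upper-cased, whitespace-collapsed."""

    ingredient_norm: str
    route_norm: str


def normalize_key(ingredient: str, route: str) -> MarketKey:
    """Canonicalize an ingredient–route pair.

    Upper-cases, trims, and collapses internal whitespace.  Idempotent:
    normalizing an already-normal key is the identity.
    """
    ing = _WS.sub(" ", (ingredient or "").strip()).upper()
    rt = _WS.sub(" ", (route or "").strip()).upper()
    if not ing or not rt:
        raise ValidationError("ingredient and route must be non-empty")
    return MarketKey(ing, rt)


def normalize_text(text: str) -> str:
    """Canonical form of a single text field (used for ingredient-only joins)."""
    return _WS.sub(" ", (text or "").strip()).upper()


# ---------------------------------------------------------------------------
# Monograph attachment
# ---------------------------------------------------------------------------


def attach_monographs(markets: pd.DataFrame, monographs) -> pd.DataFrame:
    """Attach product/substance monograph official dates to markets.

    Parameters
    ----------
    markets : DataFrame
        One row per market with ``ingredient`` and ``route`` columns already
        in canonical form (see :func:`normalize_key`).
    monographs : list of MonographRecord
        Monograph directory rows; keys are normalized here.

    Product monographs match on (ingredient, route); substance monographs on
    ingredient alone.  When several monographs match a market the earliest
    official date wins.  Monographs matching no market are reported in the
    returned frame's ``attrs["unmatched_monographs"]``, never fatal.
    """
    markets = markets.copy()
    prod_dates: dict[tuple, date] = {}
    subst_dates: dict[str, date] = {}
    for m in monographs:
        ing = normalize_text(m.ingredient)
        if m.monograph_type == "product":
            key = (ing, normalize_text(m.route or ""))
            if key not in prod_dates or m.official_date < prod_dates[key]:
                prod_dates[key] = m.official_date
        else:
            if ing not in subst_dates or m.official_date < subst_dates[ing]:
                subst_dates[ing] = m.official_date

    market_keys = set(zip(markets["ingredient"], markets["route"]))
    market_ings = set(markets["ingredient"])
    unmatched = [k for k in prod_dates if k not in market_keys]
    unmatched += [(i, None) for i in subst_dates if i not in market_ings]

    markets["product_monograph_date"] = [
        prod_dates.get((ing, rt)) for ing, rt in zip(markets["ingredient"], markets["route"])
    ]
    markets["substance_monograph_date"] = [
        subst_dates.get(ing) for ing in markets["ingredient"]
    ]
    markets.attrs["unmatched_monographs"] = unmatched
    return markets


# ---------------------------------------------------------------------------
# Attrition ledger
# ---------------------------------------------------------------------------


@dataclass
class AttritionLedger:
    """Ordered record of an eligibility cascade: one step per filter."""

    n_start: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)  # (name, removed, left)

    def add(self, filter_name: str, n_removed: int) -> None:
        n_prev = self.steps[-1][2] if self.steps else self.n_start
        self.steps.append((filter_name, n_removed, n_prev - n_removed))

    @property
    def n_final(self) -> int:
        return self.steps[-1][2] if self.steps else self.n_start

    def validate(self) -> None:
        n = self.n_start
        for name, removed, remaining in self.steps:
            if removed < 0 or remaining != n - removed:
                raise ValidationError(f"ledger does not telescope at step {name!r}")
            n = remaining

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter_name", "n_removed", "n_remaining"])


# ---------------------------------------------------------------------------
# Eligibility cascade
# ---------------------------------------------------------------------------

# Each filter maps (markets_frame, params) -> boolean Series, True = exclude.
# Order and cut years below follow the published sample-derivation flow:
# pre-1982 approvals (no exact dates), generics or loss of exclusivity before
# the sales panel begins, product monograph official before the NDA,
# still under patent, unmatched to the sales panel, unclassifiable, and
# OTC/discontinued products.


def _f_pre_1982(m: pd.DataFrame, p: dict) -> pd.Series:
    cutoff = date(int(p.get("cutoff_year", 1982)), 1, 1)
    approved = pd.to_datetime(m["nda_approval_date"], errors="coerce")
    return m["nda_pre_1982"].fillna(False).astype(bool) | (
        approved < pd.Timestamp(cutoff)
    )


def _f_generic_or_loe_before_cutoff(m: pd.DataFrame, p: dict) -> pd.Series:
    cutoff = pd.Timestamp(date(int(p.get("cutoff_year", 1998)), 1, 1))
    g1 = pd.to_datetime(m["first_generic_date"], errors="coerce")
    loe = pd.to_datetime(m["loe_date"], errors="coerce")
    return (g1 < cutoff) | (loe < cutoff)


def _f_monograph_before_nda(m: pd.DataFrame, p: dict) -> pd.Series:
    pm = pd.to_datetime(m["product_monograph_date"], errors="coerce")
    nda = pd.to_datetime(m["nda_approval_date"], errors="coerce")
    return pm < nda


def _f_under_patent(m: pd.DataFrame, p: dict) -> pd.Series:
    return m["under_patent"].fillna(False).astype(bool)


def _f_no_sales_match(m: pd.DataFrame, p: dict) -> pd.Series:
    return ~m["sales_match"].fillna(False).astype(bool)


def _f_no_therapeutic_class(m: pd.DataFrame, p: dict) -> pd.Series:
    cls = m["therapeutic_class"]
    return cls.isna() | (cls.astype(str).str.strip() == "")


def _f_otc_or_discontinued(m: pd.DataFrame, p: dict) -> pd.Series:
    return m["otc"].fillna(False).astype(bool) | m["discontinued"].fillna(False).astype(bool)


FILTERS: dict[str, Callable[[pd.DataFrame, dict], pd.Series]] = {
    "pre_1982": _f_pre_1982,
    "generic_or_loe_before_cutoff": _f_generic_or_loe_before_cutoff,
    "monograph_before_nda": _f_monograph_before_nda,
    "under_patent": _f_under_patent,
    "no_sales_match": _f_no_sales_match,
    "no_therapeutic_class": _f_no_therapeutic_class,
    "otc_or_discontinued": _f_otc_or_discontinued,
}

DEFAULT_CASCADE: list[dict] = [
    {"name": "pre_1982", "cutoff_year": 1982},
    {"name": "generic_or_loe_before_cutoff", "cutoff_year": 1998},
    {"name": "monograph_before_nda"},
    {"name": "under_patent"},
    {"name": "no_sales_match"},
    {"name": "no_therapeutic_class"},
    {"name": "otc_or_discontinued"},
]


def apply_eligibility_cascade(
    markets: pd.DataFrame, cascade_config: list[dict] | None = None
) -> tuple[pd.DataFrame, AttritionLedger]:
    """Apply the sequential eligibility cascade.

    A market is removed at the FIRST filter it fails (flow-diagram
    semantics), so per-filter counts are sequential and the ledger
    telescopes from the input market count to the cohort size.
    """
    cascade = cascade_config if cascade_config is not None else DEFAULT_CASCADE
    markets = markets.sort_values(["ingredient", "route"], kind="mergesort").reset_index(
        drop=True
    )
    ledger = AttritionLedger(n_start=len(markets))
    remaining = markets
    for step in cascade:
        step = dict(step)
        name = step.pop("name", None)
        if name not in FILTERS:
            raise ConfigError(f"cascade references unknown filter: {name!r}")
        if len(remaining):
            fails = FILTERS[name](remaining, step).fillna(False).astype(bool)
        else:
            fails = pd.Series([], dtype=bool)
        ledger.add(name, int(fails.sum()))
        remaining = remaining.loc[~fails]
    ledger.validate()
    return remaining.reset_index(drop=True), ledger
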