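"""Reading and writing the three input tables.

The pipeline consumes (1) drug-product approval records in the FDA Orange
Book "products" dialect (tilde-delimited text) or an equivalent CSV, (2) a
monograph directory table, and (3) a drug-year sales panel.  Reading is
strict-schema: rows whose mandatory fields do not parse are collected into a
rejects report rather than silently dropped, so that downstream cohort
attrition counts remain auditable.

All text fields are trimmed; files are UTF-8.  Dates in the Orange Book
dialect use the "Mon DD, YYYY" form; the literal value
``"Approved Prior to Jan 1, 1982"`` maps to a sentinel pre-1982 flag rather
than a date (exact approval dates are unavailable before 1982 and such
products are excluded at the cohort stage).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import pandas as pd

from .errors import InputError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

PRE_1982_LITERAL = "Approved Prior to Jan 1, 1982"

APPLICATION_TYPES = ("NDA", "ANDA")
MONOGRAPH_TYPES = ("product", "substance")


# ---------------------------------------------------------------------------
# Row-level domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProductRecord:
    """One approved drug product (one row of the products table)."""

    ingredient: str
    route: str
    dosage_form: str
    trade_name: str
    applicant: str
    application_type: str  # "NDA" | "ANDA"
    application_number: str
    approval_date: date | None  # None iff approved_pre_1982
    otc_flag: bool
    discontinued_flag: bool
    therapeutic_class: str | None = None
    approved_pre_1982: bool = False
    under_patent_flag: bool = False
    loe_date: date | None = None

    def __post_init__(self):
        if self.application_type not in APPLICATION_TYPES:
            raise ValidationError(
                f"application_type must be one of {APPLICATION_TYPES}, "
                f"got {self.application_type!r}"
            )
        if not self.ingredient.strip() or not self.route.strip():
            raise ValidationError("ingredient and route must be non-empty")
        if self.approval_date is None and not self.approved_pre_1982:
            raise ValidationError("approval_date missing without pre-1982 sentinel")


@dataclass(frozen=True)
class MonographRecord:
    """One pharmacopeial monograph (product or substance) with official date."""

    ingredient: str
    route: str | None  # substance monographs are route-agnostic
    monograph_type: str  # "product" | "substance"
    official_date: date

    def __post_init__(self):
        if self.monograph_type not in MONOGRAPH_TYPES:
            raise ValidationError(
                f"monograph_type must be one of {MONOGRAPH_TYPES}, "
                f"got {self.monograph_type!r}"
            )


@dataclass(frozen=True)
class SalesObservation:
    """Dollar sales and prescription volume for one market-year."""

    ingredient: str
    route: str
    year: int
    dollars: float
    volume: float

    def __post_init__(self):
        if self.dollars < 0:
            raise ValidationError(f"dollars must be >= 0, got {self.dollars}")
        if self.volume < 0:
            raise ValidationError(f"volume must be >= 0, got {self.volume}")


@dataclass(frozen=True)
class RejectedRow:
    line_number: int
    reason: str
    raw: str


@dataclass
class ReadResult:
    """Accepted records plus the rejects sidecar for one input file."""

    records: list = field(default_factory=list)
    rejects: list[RejectedRow] = field(default_factory=list)

    @property
    def n_input_rows(self) -> int:
        return len(self.records) + len(self.rejects)

    def rejects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.line_number, r.reason, r.raw) for r in self.rejects],
            columns=["line_number", "reason", "raw"],
        )


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------


def _parse_ob_date(text: str) -> tuple[date | None, bool]:
    """Parse an Orange Book approval date; returns (date, pre_1982_flag)."""
    text = text.strip()
    if text == PRE_1982_LITERAL:
        return None, True
    return datetime.strptime(text, "%b %d, %Y").date(), False


def _parse_iso_date(text: str) -> date | None:
    text = (text or "").strip()
    if not text:
        return None
    return date.fromisoformat(text)


def _parse_bool(text: str) -> bool:
    return (text or "").strip().upper() in ("1", "TRUE", "Y", "YES")


def _require_columns(header: list[str], required: list[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def _open_rows(path, delimiter: str):
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    with open(path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if not rows:
        raise SchemaError(f"{path}: empty file (no header row)")
    header = [c.strip() for c in rows[0]]
    return header, rows[1:]


# ---------------------------------------------------------------------------
# Products
# ---------------------------------------------------------------------------

# Orange Book "products" dialect columns. "DF;Route" packs dosage form and
# route separated by ';' as in the distributed products file. "Type" holds
# RX / OTC / DISCN.
_OB_REQUIRED = [
    "Ingredient",
    "DF;Route",
    "Trade_Name",
    "Applicant",
    "Appl_Type",
    "Appl_No",
    "Approval_Date",
    "Type",
]
_OB_OPTIONAL = ["Therapeutic_Class", "Patent_Flag", "LOE_Date"]

_CSV_REQUIRED = [
    "ingredient",
    "route",
    "dosage_form",
    "trade_name",
    "applicant",
    "application_type",
    "application_number",
    "approval_date",
    "otc_flag",
    "discontinued_flag",
]
_CSV_OPTIONAL = ["therapeutic_class", "under_patent_flag", "loe_date"]


def read_products(path, dialect: str = "orange_book") -> ReadResult:
    """Read the products table.

    Parameters
    ----------
    path : path-like
        Input file.
    dialect : {"orange_book", "csv"}
        ``"orange_book"`` expects tilde-delimited text with a header row and
        "Mon DD, YYYY" dates; ``"csv"`` expects comma-separated ISO dates.

    Returns
    -------
    ReadResult
        ``.records`` is a list of :class:`ProductRecord`; rows with
        unparseable mandatory fields land in ``.rejects``.
    """
    if dialect == "orange_book":
        return _read_products_ob(path)
    if dialect == "csv":
        return _read_products_csv(path)
    raise ValueError(f"unknown products dialect: {dialect!r}")


def _read_products_ob(path) -> ReadResult:
    header, rows = _open_rows(path, "~")
    _require_columns(header, _OB_REQUIRED, path)
    idx = {c: header.index(c) for c in header}
    result = ReadResult()
    for lineno, row in enumerate(rows, start=2):
        raw = "~".join(row)
        if not any(cell.strip() for cell in row):
            continue
        try:
            get = lambda c: row[idx[c]].strip() if c in idx and idx[c] < len(row) else ""
            df_route = get("DF;Route")
            if ";" in df_route:
                dosage_form, route = (p.strip() for p in df_route.split(";", 1))
            else:
                dosage_form, route = "", df_route
            approval, pre82 = _parse_ob_date(get("Approval_Date"))
            appl_type_raw = get("Appl_Type").upper()
            appl_type = {"N": "NDA", "A": "ANDA", "NDA": "NDA", "ANDA": "ANDA"}[appl_type_raw]
            prod_type = get("Type").upper()
            rec = ProductRecord(
                ingredient=get("Ingredient"),
                route=route,
                dosage_form=dosage_form,
                trade_name=get("Trade_Name"),
                applicant=get("Applicant"),
                application_type=appl_type,
                application_number=get("Appl_No"),
                approval_date=approval,
                otc_flag=prod_type == "OTC",
                discontinued_flag=prod_type == "DISCN",
                therapeutic_class=get("Therapeutic_Class") or None,
                approved_pre_1982=pre82,
                under_patent_flag=_parse_bool(get("Patent_Flag")),
                loe_date=_parse_iso_date(get("LOE_Date")),
            )
            result.records.append(rec)
        except (ValueError, KeyError, ValidationError) as exc:
            result.rejects.append(RejectedRow(lineno, str(exc) or repr(exc), raw))
    return result


def _read_products_csv(path) -> ReadResult:
    header, rows = _open_rows(path, ",")
    _require_columns(header, _CSV_REQUIRED, path)
    idx = {c: header.index(c) for c in header}
    result = ReadResult()
    for lineno, row in enumerate(rows, start=2):
        raw = ",".join(row)
        if not any(cell.strip() for cell in row):
            continue
        try:
            get = lambda c: row[idx[c]].strip() if c in idx and idx[c] < len(row) else ""
            approval_raw = get("approval_date")
            pre82 = approval_raw == "PRE_1982"
            rec = ProductRecord(
                ingredient=get("ingredient"),
                route=get("route"),
                dosage_form=get("dosage_form"),
                trade_name=get("trade_name"),
                applicant=get("applicant"),
                application_type=get("application_type").upper(),
                application_number=get("application_number"),
                approval_date=None if pre82 else _parse_iso_date(approval_raw),
                otc_flag=_parse_bool(get("otc_flag")),
                discontinued_flag=_parse_bool(get("discontinued_flag")),
                therapeutic_class=get("therapeutic_class") or None,
                approved_pre_1982=pre82,
                under_patent_flag=_parse_bool(get("under_patent_flag")),
                loe_date=_parse_iso_date(get("loe_date")),
            )
            result.records.append(rec)
        except (ValueError, KeyError, ValidationError) as exc:
            result.rejects.append(RejectedRow(lineno, str(exc) or repr(exc), raw))
    return result


def write_products_csv(records: list[ProductRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_REQUIRED + _CSV_OPTIONAL)
        for r in records:
            w.writerow(
                [
                    r.ingredient,
                    r.route,
                    r.dosage_form,
                    r.trade_name,
                    r.applicant,
                    r.application_type,
                    r.application_number,
                    "PRE_1982" if r.approved_pre_1982 else r.approval_date.isoformat(),
                    str(r.otc_flag),
                    str(r.discontinued_flag),
                    r.therapeutic_class or "",
                    str(r.under_patent_flag),
                    r.loe_date.isoformat() if r.loe_date else "",
                ]
            )


def write_products_orange_book(records: list[ProductRecord], path) -> None:
    """Write records in the tilde-delimited Orange Book "products" dialect."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("~".join(_OB_REQUIRED + _OB_OPTIONAL) + "\n")
        for r in records:
            if r.approved_pre_1982:
                date_text = PRE_1982_LITERAL
            else:
                date_text = r.approval_date.strftime("%b %d, %Y").replace(" 0", " ")
                # strftime pads the day; Orange Book prints e.g. "Jan 2, 1999"
            prod_type = "OTC" if r.otc_flag else ("DISCN" if r.discontinued_flag else "RX")
            fh.write(
                "~".join(
                    [
                        r.ingredient,
                        f"{r.dosage_form};{r.route}",
                        r.trade_name,
                        r.applicant,
                        r.application_type,
                        r.application_number,
                        date_text,
                        prod_type,
                        r.therapeutic_class or "",
                        "Y" if r.under_patent_flag else "N",
                        r.loe_date.isoformat() if r.loe_date else "",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Monographs
# ---------------------------------------------------------------------------

_MONO_REQUIRED = ["ingredient", "route", "monograph_type", "official_date"]


def read_monographs(path) -> ReadResult:
    """Read the monograph directory CSV.

    Duplicated (ingredient, route, monograph_type) rows are deduplicated
    keeping the earliest official date, with a logged warning.  An unknown
    ``monograph_type`` anywhere in the file is a schema error (the column's
    vocabulary is broken, not a single bad row).
    """
    header, rows = _open_rows(path, ",")
    _require_columns(header, _MONO_REQUIRED, path)
    idx = {c: header.index(c) for c in header}
    result = ReadResult()
    seen: dict[tuple, int] = {}  # key -> index into result.records
    for lineno, row in enumerate(rows, start=2):
        raw = ",".join(row)
        if not any(cell.strip() for cell in row):
            continue
        mtype = row[idx["monograph_type"]].strip().lower()
        if mtype not in MONOGRAPH_TYPES:
            raise SchemaError(
                f"{path}:{lineno}: unknown monograph_type {mtype!r} "
                f"(expected one of {MONOGRAPH_TYPES})"
            )
        try:
            route_raw = row[idx["route"]].strip()
            rec = MonographRecord(
                ingredient=row[idx["ingredient"]].strip(),
                route=route_raw or None,
                monograph_type=mtype,
                official_date=date.fromisoformat(row[idx["official_date"]].strip()),
            )
        except (ValueError, ValidationError) as exc:
            result.rejects.append(RejectedRow(lineno, str(exc), raw))
            continue
        key = (rec.ingredient, rec.route, rec.monograph_type)
        if key in seen:
            kept = result.records[seen[key]]
            if rec.official_date < kept.official_date:
                result.records[seen[key]] = rec
            logger.warning(
                "duplicate monograph row for %s at line %d; keeping earliest "
                "official date",
                key,
                lineno,
            )
        else:
            seen[key] = len(result.records)
            result.records.append(rec)
    return result


def write_monographs_csv(records: list[MonographRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_MONO_REQUIRED)
        for r in records:
            w.writerow(
                [r.ingredient, r.route or "", r.monograph_type, r.official_date.isoformat()]
            )


# ---------------------------------------------------------------------------
# Sales panel
# ---------------------------------------------------------------------------

_SALES_REQUIRED = ["ingredient", "route", "year", "dollars", "volume"]


def read_sales(path) -> ReadResult:
    """Read the drug-year sales panel CSV.

    Negative dollars/volume and duplicate (ingredient, route, year) keys are
    validation errors — a broken panel must not silently feed the models.
    """
    header, rows = _open_rows(path, ",")
    _require_columns(header, _SALES_REQUIRED, path)
    idx = {c: header.index(c) for c in header}
    result = ReadResult()
    keys: set[tuple] = set()
    dupes: list[tuple] = []
    for lineno, row in enumerate(rows, start=2):
        if not any(cell.strip() for cell in row):
            continue
        rec = SalesObservation(
            ingredient=row[idx["ingredient"]].strip(),
            route=row[idx["route"]].strip(),
            year=int(row[idx["year"]].strip()),
            dollars=float(row[idx["dollars"]].strip()),
            volume=float(row[idx["volume"]].strip()),
        )
        key = (rec.ingredient, rec.route, rec.year)
        if key in keys:
            dupes.append(key)
        keys.add(key)
        result.records.append(rec)
    if dupes:
        raise ValidationError(
            f"{path}: duplicate (ingredient, route, year) keys: {sorted(set(dupes))}"
        )
    return result


def write_sales_csv(records: list[SalesObservation], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SALES_REQUIRED)
        for r in records:
            w.writerow([r.ingredient, r.route, r.year, repr(r.dollars), repr(r.volume)])


def sales_to_frame(records: list[SalesObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.ingredient, r.route, r.year, r.dollars, r.volume) for r in records],
        columns=_SALES_REQUIRED,
    )
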