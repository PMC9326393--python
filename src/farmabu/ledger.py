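"""Invoice and statement-of-account ingestion and reconciliation.

Purchases serve as the proxy for usage, attributed to the purchase date; the
monthly statement of account (the supplier's list of issued invoice numbers)
is the completeness reference.  An issued number with no captured invoice
line is a *missing invoice*: its purchases are unknowable and simply absent
from every downstream total, so the reconciliation report carries the
missing rate as the data-completeness caveat for the whole analysis.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .catalog import Catalog
from .errors import ConfigurationError, RecordValidationError
from .units import round_half_up

INVOICE_COLUMNS = [
    "invoice_number",
    "date",
    "supplier",
    "product_id",
    "package",
    "quantity",
    "unit_price_zar",
]
STATEMENT_COLUMNS = ["month", "supplier", "invoice_number"]


@dataclass(frozen=True)
class InvoiceLine:
    """One line of a purchase invoice (an invoice usually has several)."""

    invoice_number: str
    date: dt.date
    supplier: str
    product_id: str
    package: str
    quantity: int
    unit_price_zar: float  # ex-VAT, as captured

    @property
    def year(self) -> int:
        return self.date.year

    @property
    def month(self) -> str:
        return f"{self.date.year:04d}-{self.date.month:02d}"

    @property
    def line_cost_zar(self) -> float:
        return self.quantity * self.unit_price_zar


@dataclass(frozen=True)
class Statement:
    """A supplier's monthly list of issued invoice numbers."""

    month: str  # "YYYY-MM"
    supplier: str
    invoice_numbers: tuple[str, ...]


@dataclass
class ReconciliationReport:
    """Cross-check of statements against captured invoices."""

    n_issued: int
    n_missing: int
    missing_numbers: list[str]
    months_without_statement: list[str]

    @property
    def missing_rate_percent(self) -> float:
        if self.n_issued == 0:
            return 0.0
        return round_half_up(100.0 * self.n_missing / self.n_issued, 2)

    def to_dict(self) -> dict:
        return {
            "n_issued": self.n_issued,
            "n_missing": self.n_missing,
            "missing_rate_percent": self.missing_rate_percent,
            "missing_numbers": sorted(self.missing_numbers),
            "months_without_statement": sorted(self.months_without_statement),
        }


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_invoices(path, catalog: Optional[Catalog] = None) -> list[InvoiceLine]:
    """Read ``invoices.csv`` and validate rows.

    Columns: invoice_number,date,supplier,product_id,package,quantity,
    unit_price_zar (dates ISO-8601).  With a catalog, every (product,
    package) reference must resolve; offending rows are reported with their
    1-based data row numbers.  An empty file returns an empty list with a
    warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in INVOICE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise RecordValidationError(f"invoices file lacks columns {missing_cols}")
    if df.empty:
        warnings.warn(f"invoice file {path} contains no rows", stacklevel=2)
        return []

    lines: list[InvoiceLine] = []
    bad: list[tuple[int, str]] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        problems = []
        try:
            date = dt.date.fromisoformat(row.date)
        except ValueError:
            problems.append(f"bad date {row.date!r}")
            date = None
        try:
            qty = int(row.quantity)
            if qty < 1:
                problems.append(f"quantity must be >= 1, got {qty}")
        except ValueError:
            problems.append(f"bad quantity {row.quantity!r}")
            qty = 0
        try:
            price = float(row.unit_price_zar)
            if price < 0:
                problems.append(f"negative price {price}")
        except ValueError:
            problems.append(f"bad price {row.unit_price_zar!r}")
            price = 0.0
        if catalog is not None:
            try:
                catalog.product(row.product_id).package(row.package)
            except Exception as exc:  # CatalogLookupError
                problems.append(str(exc))
        if problems:
            bad.append((idx, "; ".join(problems)))
            continue
        lines.append(
            InvoiceLine(
                invoice_number=str(row.invoice_number),
                date=date,
                supplier=str(row.supplier),
                product_id=str(row.product_id),
                package=str(row.package),
                quantity=qty,
                unit_price_zar=price,
            )
        )
    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad)
        raise RecordValidationError(f"invalid invoice rows: {detail}", rows=[i for i, _ in bad])
    return lines


def read_statements(path) -> list[Statement]:
    """Read ``statements.csv`` (one row per issued invoice number)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in STATEMENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise RecordValidationError(f"statements file lacks columns {missing_cols}")
    if df.empty:
        warnings.warn(f"statement file {path} contains no rows", stacklevel=2)
        return []
    out: list[Statement] = []
    for (month, supplier), grp in df.groupby(["month", "supplier"], sort=True):
        numbers = list(grp["invoice_number"])
        if len(set(numbers)) != len(numbers):
            dupes = sorted({n for n in numbers if numbers.count(n) > 1})
            raise RecordValidationError(
                f"statement {month}/{supplier} lists duplicate invoice numbers {dupes}"
            )
        out.append(Statement(month=month, supplier=supplier, invoice_numbers=tuple(numbers)))
    return out


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------


def reconcile(statements: Iterable[Statement], invoices: Iterable[InvoiceLine]) -> ReconciliationReport:
    """Detect issued invoice numbers with no captured invoice lines.

    A number is missing iff it appears in a statement but in no invoice line.
    Months that have invoices but no statement cannot be checked and are
    listed separately — they are *not* counted as missing (the statement,
    not the invoice file, is the completeness reference).
    """
    issued: set[str] = set()
    statement_months: set[str] = set()
    for st in statements:
        issued.update(st.invoice_numbers)
        statement_months.add(st.month)
    captured = {line.invoice_number for line in invoices}
    invoice_months = {line.month for line in invoices}
    missing = sorted(issued - captured)
    return ReconciliationReport(
        n_issued=len(issued),
        n_missing=len(missing),
        missing_numbers=missing,
        months_without_statement=sorted(invoice_months - statement_months),
    )


# ---------------------------------------------------------------------------
# Grouped purchase counts
# ---------------------------------------------------------------------------

_SIMPLE_KEYS = {"year", "month", "product"}
_CATALOG_KEYS = {"ingredient", "route", "stage"}


def purchases_by(
    invoices: Iterable[InvoiceLine], key: str, catalog: Optional[Catalog] = None
) -> pd.Series:
    """Sum purchased package quantities by a grouping key.

    ``key`` is one of year, month, product, ingredient, route, stage; the
    last three require a catalog.  Month grouping uses the invoice date's
    calendar month (purchase-date seasonality).  For ``ingredient``, a line
    of a multi-ingredient product counts its quantity toward every
    ingredient.
    """
    if key not in _SIMPLE_KEYS | _CATALOG_KEYS:
        raise ConfigurationError(f"unknown grouping key {key!r}")
    if key in _CATALOG_KEYS and catalog is None:
        raise ConfigurationError(f"grouping by {key!r} requires a catalog")
    rows: list[tuple] = []
    for line in invoices:
        if key == "year":
            rows.append((line.year, line.quantity))
        elif key == "month":
            rows.append((line.month, line.quantity))
        elif key == "product":
            rows.append((line.product_id, line.quantity))
        else:
            product = catalog.product(line.product_id)
            if key == "route":
                rows.append((product.route, line.quantity))
            elif key == "stage":
                rows.append((product.stage_label, line.quantity))
            else:  # ingredient
                for entry in product.ingredients:
                    rows.append((entry.ingredient, line.quantity))
    if not rows:
        return pd.Series(dtype="int64", name="quantity")
    df = pd.DataFrame(rows, columns=[key, "quantity"])
    return df.groupby(key)["quantity"].sum().sort_index()
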