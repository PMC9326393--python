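"""Procurement costing in ZAR ex-VAT and USD.

Prices are captured excluding VAT (farming inputs are zero-rated in the
study setting, so the VAT engine is an identity pass-through there, kept for
portability to non-zero-rated ledgers).  A product with two active
ingredients carries a single price: its cost is attributed once, to the
product, and ingredient- or class-level cost tables show co-formulated
costs under an explicit combined label rather than splitting or double
counting them.  Currency conversion uses one average exchange rate per
year; converted figures are rounded to the nearest dollar only at reporting.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .catalog import Catalog
from .errors import ConfigurationError
from .ledger import InvoiceLine

#: Study-period average ZAR per USD rates.
DEFAULT_EXCHANGE_RATES = {2016: 14.7049, 2017: 13.3055, 2018: 11.5445}


class VatRule(BaseModel):
    """A VAT rate applying from ``start`` (inclusive) to ``end`` (exclusive, open if None)."""

    start: dt.date
    end: Optional[dt.date] = None
    rate: float = Field(ge=0.0)


class CostingConfig(BaseModel):
    """VAT rules, zero-rating flag and per-year exchange rates."""

    vat_rules: list[VatRule] = Field(
        default_factory=lambda: [
            VatRule(start=dt.date(2016, 1, 1), end=dt.date(2018, 4, 1), rate=0.14),
            VatRule(start=dt.date(2018, 4, 1), end=None, rate=0.15),
        ]
    )
    zero_rated: bool = True
    exchange_rates_zar_per_usd: dict[int, float] = Field(
        default_factory=lambda: dict(DEFAULT_EXCHANGE_RATES)
    )

    @model_validator(mode="after")
    def _check(self) -> "CostingConfig":
        for rate in self.exchange_rates_zar_per_usd.values():
            if rate <= 0:
                raise ValueError("exchange rates must be positive")
        rules = sorted(self.vat_rules, key=lambda r: r.start)
        for a, b in zip(rules, rules[1:]):
            if a.end is None or a.end > b.start:
                raise ValueError("VAT date ranges overlap")
        return self

    def vat_rate(self, date: dt.date) -> float:
        """Applicable VAT rate; 0 under zero-rating."""
        if self.zero_rated:
            return 0.0
        for rule in self.vat_rules:
            if date >= rule.start and (rule.end is None or date < rule.end):
                return rule.rate
        raise ConfigurationError(f"no VAT rule covers {date.isoformat()}")


def zar_to_usd(amount_zar: float, year: int, config: Optional[CostingConfig] = None) -> float:
    """Convert ZAR to USD with the year's average rate (unrounded).

    Reports round to the nearest dollar; keep this unrounded for
    aggregation (conversion is linear before rounding).
    """
    config = config or CostingConfig()
    try:
        rate = config.exchange_rates_zar_per_usd[year]
    except KeyError:
        raise ConfigurationError(f"no exchange rate configured for year {year}") from None
    return amount_zar / rate


COST_KEYS = ("product", "ingredient", "class", "kind", "total")


def annual_cost(
    invoices: Iterable[InvoiceLine],
    catalog: Catalog,
    key: str = "product",
    config: Optional[CostingConfig] = None,
) -> pd.DataFrame:
    """Ex-VAT procurement cost per (year, stratum) in ZAR and USD.

    ``key``: product | ingredient | class | kind | total.  Cost is summed as
    quantity x unit price at product level first; ingredient- and
    class-level views label a multi-ingredient product by its combined
    ingredients (primary first) and attribute the cost once, so every view
    preserves the grand total.
    """
    if key not in COST_KEYS:
        raise ConfigurationError(f"unknown cost key {key!r}; expected one of {COST_KEYS}")
    config = config or CostingConfig()
    rows = []
    for line in invoices:
        product = catalog.product(line.product_id)
        if key == "product":
            stratum = line.product_id
        elif key == "kind":
            stratum = product.kind
        elif key == "total":
            stratum = "total"
        elif product.kind == "vaccine":
            stratum = product.disease if key == "ingredient" else "vaccines"
        elif key == "ingredient":
            stratum = cost_label(product)
        else:  # class: attributed to the primary (first-listed) ingredient's class
            primary = catalog.ingredient(product.ingredients[0].ingredient)
            stratum = primary.antibiotic_class
        rows.append({"year": line.year, "stratum": stratum, "cost_zar": line.line_cost_zar})
    if not rows:
        return pd.DataFrame(columns=["year", "stratum", "cost_zar", "cost_usd"])
    df = pd.DataFrame(rows).groupby(["year", "stratum"], as_index=False)["cost_zar"].sum()
    df["cost_usd"] = [
        zar_to_usd(z, int(y), config) for y, z in zip(df["year"], df["cost_zar"])
    ]
    return df.sort_values(["year", "stratum"], ignore_index=True)


def cost_label(product) -> str:
    """Ingredient-level cost label: primary ingredient, co-formulations combined."""
    names = [e.ingredient for e in product.ingredients]
    if len(names) == 1:
        return names[0]
    return f"{names[0]} (incl. {', '.join(names[1:])})"


def cost_per_dosage(unit_prices_zar: Sequence[float], dosages_per_vial: int) -> float:
    """Average vial price over the year divided by doses per vial.

    Computed per (vaccine, vial size, year); the averaging absorbs in-year
    price increases.
    """
    if dosages_per_vial < 1:
        raise ConfigurationError("dosages_per_vial must be >= 1")
    prices = list(unit_prices_zar)
    if not prices:
        raise ConfigurationError("need at least one unit price observation")
    return (sum(prices) / len(prices)) / dosages_per_vial


def vaccine_cost_per_dosage(
    invoices: Iterable[InvoiceLine],
    catalog: Catalog,
    year: int,
    config: Optional[CostingConfig] = None,
) -> pd.DataFrame:
    """Average cost per dosage per (disease, product, vial size) for a year."""
    config = config or CostingConfig()
    prices: dict[tuple[str, str, str, int], list[float]] = {}
    for line in invoices:
        product = catalog.product(line.product_id)
        if product.kind != "vaccine" or line.year != year:
            continue
        doses = product.dosages_per_vial(line.package)
        keyt = (product.disease, line.product_id, line.package, doses)
        prices.setdefault(keyt, []).extend([line.unit_price_zar] * line.quantity)
    rows = []
    for (disease, pid, pkg, doses), obs in sorted(prices.items()):
        per_dose = cost_per_dosage(obs, doses)
        rows.append(
            {
                "year": year,
                "disease": disease,
                "product_id": pid,
                "package": pkg,
                "dosages_per_vial": doses,
                "cost_per_dosage_zar": per_dose,
                "cost_per_dosage_usd": zar_to_usd(per_dose, year, config),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "year", "disease", "product_id", "package", "dosages_per_vial",
            "cost_per_dosage_zar", "cost_per_dosage_usd",
        ],
    )
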