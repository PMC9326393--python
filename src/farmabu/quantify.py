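"""Usage quantification: numerators, weight adjustment, stratified tables.

The numerator for an active ingredient is the sum over invoice lines of
standardized grams per package times packages purchased; a two-ingredient
product contributes to both ingredients independently.  Weight-adjusted
usage divides the numerator (converted to mg) by the animal-biomass
denominator:

    mg/kg = grams x 1000 / biomass_kg

All aggregation runs on unrounded grams; rounding is a formatting concern.
Vaccine usage is counted in purchased dosages (doses per vial x vials) per
targeted disease, and coverage is expressed as the administration ratio,
dosages over the average eligible population (close to 1 meaning every
eligible animal could have received its scheduled shots).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .catalog import Catalog
from .errors import CatalogLookupError, ConfigurationError
from .ledger import InvoiceLine

#: Stratification keys supported by :func:`stratify`.
STRATA = ("total", "class", "ingredient", "route", "stage", "month", "who", "ema", "woah", "pvs")


def usage_lines(invoices: Iterable[InvoiceLine], catalog: Catalog) -> pd.DataFrame:
    """Expand invoice lines to one row per (line, active ingredient).

    The returned frame carries the stratum attributes needed downstream:
    year, month, product_id, package, quantity, ingredient, antibiotic class,
    route, production-stage label, the four importance categories, the
    growth-promoter flag and unrounded grams (per-package grams x quantity).
    Vaccine lines are excluded (see :func:`vaccine_dosages`).  Unresolvable
    product references raise rather than dropping silently.
    """
    rows = []
    for line in invoices:
        product = catalog.product(line.product_id)
        if product.kind != "antibiotic":
            continue
        per_pkg = catalog.grams_per_package(line.product_id, line.package)
        for entry in product.ingredients:
            ing = catalog.ingredient(entry.ingredient)
            rows.append(
                {
                    "year": line.year,
                    "month": line.month,
                    "product_id": line.product_id,
                    "package": line.package,
                    "quantity": line.quantity,
                    "ingredient": entry.ingredient,
                    "class": ing.antibiotic_class,
                    "route": product.route,
                    "stage": product.stage_label,
                    "who": ing.who_class,
                    "ema": ing.ema_class,
                    "woah": ing.woah_class,
                    "pvs": ing.pvs_class,
                    "growth_promoter": ing.growth_promoter,
                    "grams": per_pkg[entry.ingredient] * line.quantity,
                }
            )
    columns = [
        "year", "month", "product_id", "package", "quantity", "ingredient", "class",
        "route", "stage", "who", "ema", "woah", "pvs", "growth_promoter", "grams",
    ]
    return pd.DataFrame(rows, columns=columns)


def annual_numerator(
    invoices: Iterable[InvoiceLine], catalog: Catalog, year: int
) -> dict[str, float]:
    """Unrounded grams of each active ingredient purchased in a year."""
    usage = usage_lines(invoices, catalog)
    usage = usage[usage["year"] == year]
    if usage.empty:
        return {}
    return usage.groupby("ingredient")["grams"].sum().to_dict()


def abu_mg_per_kg(numerator_g: float, biomass_kg: float) -> float:
    """Weight-adjusted usage: numerator grams x 1000 over biomass kg."""
    if biomass_kg <= 0:
        raise ConfigurationError(f"biomass must be positive, got {biomass_kg}")
    return numerator_g * 1000.0 / biomass_kg


def stratify(usage: pd.DataFrame, by: str = "total") -> pd.DataFrame:
    """Group a usage-lines frame into a (year, stratum) table.

    Returns grams and volume_kg (= grams/1000) per row.  Combined
    production-stage labels are preserved as single strata, never split or
    apportioned; dual-route ingredients are attributed per product line's
    route.
    """
    if by not in STRATA:
        raise ConfigurationError(f"unknown stratum {by!r}; expected one of {STRATA}")
    if usage.empty:
        return pd.DataFrame(columns=["year", "stratum", "grams", "volume_kg"])
    work = usage.copy()
    work["stratum"] = "total" if by == "total" else work[by]
    out = work.groupby(["year", "stratum"], as_index=False)["grams"].sum()
    out["volume_kg"] = out["grams"] / 1000.0
    return out.sort_values(["year", "stratum"], ignore_index=True)


def with_biomass(table: pd.DataFrame, biomass_by_year: Mapping[int, float]) -> pd.DataFrame:
    """Join mg/kg onto a stratified table given per-year biomass (kg)."""
    out = table.copy()
    mg = []
    for _, row in out.iterrows():
        year = int(row["year"])
        if year not in biomass_by_year:
            raise ConfigurationError(f"no biomass configured for year {year}")
        mg.append(abu_mg_per_kg(row["grams"], biomass_by_year[year]))
    out["mg_per_kg"] = mg
    return out


def growth_promoter_scenario(usage: pd.DataFrame, exclude: bool = True) -> pd.DataFrame:
    """Usage-lines frame with growth-promoter ingredients removed (or identity).

    Lets the with/without-growth-promoter scenarios be reported side by side.
    """
    if not exclude or usage.empty:
        return usage.copy()
    return usage[~usage["growth_promoter"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Vaccines
# ---------------------------------------------------------------------------


def vaccine_dosages(
    invoices: Iterable[InvoiceLine], catalog: Catalog, year: int | None = None
) -> dict[str, float]:
    """Purchased vaccine dosages per targeted disease.

    dosages = doses per vial x vials purchased, summed per disease label;
    competitor products targeting the same disease pool into that label.
    Passing an antibiotic product's line raises a type error.
    """
    out: dict[str, float] = {}
    for line in invoices:
        product = catalog.product(line.product_id)
        if product.kind != "vaccine":
            raise TypeError(
                f"{line.product_id!r} is not a vaccine; filter antibiotic lines first"
            )
        if year is not None and line.year != year:
            continue
        doses = product.dosages_per_vial(line.package)
        out[product.disease] = out.get(product.disease, 0.0) + doses * line.quantity
    return out


def vaccine_lines(invoices: Iterable[InvoiceLine], catalog: Catalog) -> list[InvoiceLine]:
    """The vaccine subset of a mixed ledger."""
    return [l for l in invoices if catalog.product(l.product_id).kind == "vaccine"]


def antibiotic_lines(invoices: Iterable[InvoiceLine], catalog: Catalog) -> list[InvoiceLine]:
    """The antibiotic subset of a mixed ledger."""
    return [l for l in invoices if catalog.product(l.product_id).kind == "antibiotic"]


def administration_ratio(dosages: float, eligible_denominator: float) -> float:
    """Dosages purchased over the average eligible population.

    A ratio near 1 indicates procurement sufficient for full coverage of the
    eligible population under the schedule; below 1, not every eligible
    animal could have been vaccinated.
    """
    if eligible_denominator <= 0:
        raise ConfigurationError(
            f"eligible denominator must be positive, got {eligible_denominator}"
        )
    return dosages / eligible_denominator


# ---------------------------------------------------------------------------
# Multi-year summaries
# ---------------------------------------------------------------------------


def mean_sd_over_years(table: pd.DataFrame, value: str = "volume_kg") -> pd.DataFrame:
    """Mean and sample standard deviation (ddof=1) of a value across years.

    Strata absent in a year count as zero for that year, so a compound
    purchased in one year out of three averages over all three.  SD is NaN
    for single-year windows (formatted as "n/c" at the reporting layer).
    """
    if table.empty:
        return pd.DataFrame(columns=["stratum", "mean", "sd"])
    years = sorted(table["year"].unique())
    wide = (
        table.pivot_table(index="stratum", columns="year", values=value, aggfunc="sum")
        .reindex(columns=years)
        .astype(float)
        .fillna(0.0)
    )
    out = pd.DataFrame(
        {"stratum": wide.index, "mean": wide.mean(axis=1).values}
    )
    out["sd"] = wide.std(axis=1, ddof=1).values if len(years) > 1 else float("nan")
    return out.reset_index(drop=True)
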