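"""Synthetic farm-record generator with exact, recorded ground truth.

Emulates the ledger of a farrow-to-finish pig farm over a multi-year window:
a seasonal stream of antibiotic and vaccine purchases (roughly a hundred
invoices a year, December-peaked), monthly statements of account, monthly
livestock counts and slaughter live weights, with a configurable fraction of
invoices deliberately "lost" (their numbers stay on the statements, their
lines vanish — exactly the situation the reconciler must detect).

The generator is target-driven, not epidemiological: annual gram targets per
ingredient and dosage targets per disease are converted to integer package
counts, so the *realized* totals (what the integerized, post-drop ledger
actually contains) are recorded as ground truth.  Pipeline recovery tests
can therefore assert exact equality, not approximate agreement.  All
randomness flows through a single seeded generator; the same seed yields
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from statistics import mean
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .catalog import Catalog, reference_catalog
from .errors import ConfigurationError
from .herd import HerdRecord, VaccinationProgramme, default_programmes
from .ledger import InvoiceLine, Statement

# Annual grams of the driver ingredient purchased, sized to the magnitudes
# of the pilot farm's ledger (in-feed tetracyclines and quinoxalines
# dominate; injectables are small).
DEFAULT_TARGET_GRAMS = {
    "chlortetracycline": 453_000.0,
    "olaquindox": 258_000.0,
    "amoxicillin": 103_300.0,
    "virginiamycin": 48_900.0,
    "tiamulin": 34_000.0,
    "dihydrostreptomycin": 12_400.0,
    "penicillin-g": 5_400.0,
    "benzylpenicillin": 3_300.0,
    "sulphadiazine": 920.0,
    "neomycin": 840.0,
    "danofloxacin": 440.0,
    "oxytetracycline": 320.0,
    "lincomycin": 250.0,
    "tulathromycin": 180.0,
    "florfenicol": 180.0,
    "gentamycin": 90.0,
    "cefquinome": 70.0,
}

# Which product/package realizes each ingredient target (co-formulated
# partners — spectinomycin, trimethoprim, the pen G share of combination
# injectables — ride along and appear in the realized truth).
DEFAULT_DRIVER_PRODUCTS = {
    "chlortetracycline": ("chlortetracycline-feed", "25kg"),
    "olaquindox": ("olaquindox-feed", "25kg"),
    "amoxicillin": ("amoxicillin-feed", "1kg"),
    "virginiamycin": ("virginiamycin-feed", "10x40g"),
    "tiamulin": ("tiamulin-feed-10", "10kg"),
    "dihydrostreptomycin": ("penicillin-streptomycin-inj", "100ml"),
    "penicillin-g": ("procaine-penicillin-inj", "100ml"),
    "benzylpenicillin": ("duplex-penicillin-inj", "100ml"),
    "sulphadiazine": ("sulphadiazine-trimethoprim-water", "5l"),
    "neomycin": ("neomycin-water", "1kg"),
    "danofloxacin": ("danofloxacin-inj", "100ml"),
    "oxytetracycline": ("oxytetracycline-inj", "100ml"),
    "lincomycin": ("lincomycin-spectinomycin-feed", "1kg"),
    "tulathromycin": ("tulathromycin-inj", "100ml"),
    "florfenicol": ("florfenicol-inj", "100ml"),
    "gentamycin": ("gentamycin-inj", "50ml"),
    "cefquinome": ("cefquinome-inj", "100ml"),
}

# Annual vaccine dosage targets per disease, sized so administration ratios
# land in the observed pattern (around or above one, well below one for the
# neonatal-diarrhoea programme).
DEFAULT_VACCINE_TARGETS = {
    "enzootic pneumonia": 24_500.0,
    "ileitis": 30_600.0,
    "erysipelas, PPV & leptospirosis": 4_200.0,
    "neonatal pig diarrhoea": 1_350.0,
    "porcine circovirus disease": 31_000.0,
}
DEFAULT_VACCINE_PRODUCTS = {
    "enzootic pneumonia": ("mhyo-vax", "100ml"),
    "ileitis": ("ileitis-vax", "100ml"),
    "erysipelas, PPV & leptospirosis": ("ery-ppv-lepto-vax", "100ml"),
    "neonatal pig diarrhoea": ("neonatal-diarrhoea-vax", "100ml"),
    "porcine circovirus disease": ("pcv2-vax", "100ml"),
}

# Mean monthly head counts; piglet and gilt magnitudes follow the farm's
# recorded eligible-population denominators rather than standing stock.
DEFAULT_HERD_MEANS = {
    "dry_sows": 160,
    "lactating_sows": 240,
    "pregnant_sows": 700,
    "boars": 25,
    "piglets": 23_000,
    "weaner_gilts": 1_500,
    "slaughter_weaners": 9_000,
}

DEFAULT_BASE_PRICES = {
    "chlortetracycline-feed/25kg": 1815.0,
    "olaquindox-feed/25kg": 1780.0,
    "amoxicillin-feed/1kg": 750.0,
    "virginiamycin-feed/10x40g": 390.0,
    "tiamulin-feed-10/10kg": 2830.0,
    "penicillin-streptomycin-inj/100ml": 187.0,
    "procaine-penicillin-inj/100ml": 155.0,
    "duplex-penicillin-inj/100ml": 101.0,
    "sulphadiazine-trimethoprim-water/5l": 601.0,
    "neomycin-water/1kg": 910.0,
    "danofloxacin-inj/100ml": 532.0,
    "oxytetracycline-inj/100ml": 176.0,
    "lincomycin-spectinomycin-feed/1kg": 410.0,
    "tulathromycin-inj/100ml": 1993.0,
    "florfenicol-inj/100ml": 96.0,
    "gentamycin-inj/50ml": 99.0,
    "cefquinome-inj/100ml": 131.0,
    "mhyo-vax/100ml": 280.0,
    "ileitis-vax/100ml": 690.0,
    "ery-ppv-lepto-vax/100ml": 1430.0,
    "neonatal-diarrhoea-vax/100ml": 560.0,
    "pcv2-vax/100ml": 1600.0,
}

#: January..December purchase weights (December peak, January trough).
DEFAULT_SEASONALITY = (0.5, 0.8, 0.9, 0.95, 1.0, 1.0, 1.05, 1.05, 1.1, 1.15, 1.25, 1.6)


class SynthConfig(BaseModel):
    """Everything the generator needs; defaults are the study-like conditions."""

    seed: int = 0
    years: list[int] = Field(default_factory=lambda: [2016, 2017, 2018])
    supplier: str = "vet-practice-1"
    target_annual_grams: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_TARGET_GRAMS)
    )
    driver_products: dict[str, tuple[str, str]] = Field(
        default_factory=lambda: dict(DEFAULT_DRIVER_PRODUCTS)
    )
    vaccine_targets: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_VACCINE_TARGETS)
    )
    vaccine_products: dict[str, tuple[str, str]] = Field(
        default_factory=lambda: dict(DEFAULT_VACCINE_PRODUCTS)
    )
    monthly_seasonality_weights: tuple[float, ...] = DEFAULT_SEASONALITY
    missing_invoice_rate: float = Field(default=0.03, ge=0.0, lt=1.0)
    herd_means: dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_HERD_MEANS))
    herd_jitter: float = Field(default=0.03, ge=0.0)
    slaughter_mean_kg: float = Field(default=260_000.0, gt=0.0)
    slaughter_jitter: float = Field(default=0.08, ge=0.0)
    base_prices_zar: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_BASE_PRICES)
    )
    price_annual_drift: float = 0.05
    lines_per_invoice: int = Field(default=2, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "SynthConfig":
        if len(self.monthly_seasonality_weights) != 12:
            raise ValueError("need 12 monthly seasonality weights")
        if sum(self.monthly_seasonality_weights) <= 0:
            raise ValueError("seasonality weights must sum > 0")
        if any(w < 0 for w in self.monthly_seasonality_weights):
            raise ValueError("seasonality weights must be non-negative")
        for t in list(self.target_annual_grams.values()) + list(self.vaccine_targets.values()):
            if t < 0:
                raise ValueError("targets must be >= 0")
        return self


@dataclass
class SyntheticFarm:
    """A generated record set plus its realized ground truth."""

    config: SynthConfig
    catalog: Catalog
    invoices: list[InvoiceLine]
    statements: list[Statement]
    herd_records: list[HerdRecord]
    truth: dict

    def write(self, out_dir) -> None:
        """Emit invoices.csv, statements.csv, herd.csv, slaughter.csv, truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "invoices.csv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("invoice_number,date,supplier,product_id,package,quantity,unit_price_zar\n")
            for l in self.invoices:
                fh.write(
                    f"{l.invoice_number},{l.date.isoformat()},{l.supplier},"
                    f"{l.product_id},{l.package},{l.quantity},{l.unit_price_zar:.2f}\n"
                )
        with open(out / "statements.csv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("month,supplier,invoice_number\n")
            for st in self.statements:
                for num in st.invoice_numbers:
                    fh.write(f"{st.month},{st.supplier},{num}\n")
        with open(out / "herd.csv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("month,population,count\n")
            for rec in self.herd_records:
                for pop in sorted(rec.counts):
                    fh.write(f"{rec.month},{pop},{int(rec.counts[pop])}\n")
        with open(out / "slaughter.csv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("month,live_weight_kg\n")
            for rec in self.herd_records:
                fh.write(f"{rec.month},{rec.slaughter_live_weight_kg:.1f}\n")
        with open(out / "truth.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def generate_farm(
    config: Optional[SynthConfig] = None, catalog: Optional[Catalog] = None
) -> SyntheticFarm:
    """Generate a complete synthetic record set with recorded ground truth.

    Package counts are ``round(target / grams_per_package)`` so realized
    totals match targets exactly when package sizes divide them, else within
    one package; the realized (post-integerization, post-drop) totals are
    what ``truth`` records.  Deliberately dropped invoices keep their
    numbers on the statements.
    """
    config = config or SynthConfig()
    catalog = catalog or reference_catalog()
    rng = np.random.default_rng(config.seed)
    weights = np.asarray(config.monthly_seasonality_weights, dtype=float)
    weights = weights / weights.sum()

    # -- purchase plan: (year, month, product, package) -> package count ----
    plan: dict[tuple[int, int, str, str], int] = {}

    def add_plan(year: int, product_id: str, package: str, n_packages: int) -> None:
        if n_packages <= 0:
            return
        monthly = rng.multinomial(n_packages, weights)
        for m, qty in enumerate(monthly, start=1):
            if qty > 0:
                key = (year, m, product_id, package)
                plan[key] = plan.get(key, 0) + int(qty)

    for year in config.years:
        for ingredient, target in sorted(config.target_annual_grams.items()):
            if ingredient not in config.driver_products:
                raise ConfigurationError(f"no driver product configured for {ingredient!r}")
            pid, pkg = config.driver_products[ingredient]
            per_pkg = catalog.grams_per_package(pid, pkg).get(ingredient)
            if per_pkg is None or per_pkg <= 0:
                raise ConfigurationError(
                    f"ingredient {ingredient!r} not delivered by {pid}/{pkg}"
                )
            add_plan(year, pid, pkg, round(target / per_pkg))
        for disease, target in sorted(config.vaccine_targets.items()):
            if disease not in config.vaccine_products:
                raise ConfigurationError(f"no vaccine product configured for {disease!r}")
            pid, pkg = config.vaccine_products[disease]
            doses = catalog.product(pid).dosages_per_vial(pkg)
            add_plan(year, pid, pkg, round(target / doses))

    # -- price per (product/package, year): base x drift ---------------------
    year0 = min(config.years)

    def price(pid: str, pkg: str, year: int) -> float:
        base = config.base_prices_zar.get(f"{pid}/{pkg}", 250.0)
        return round(base * (1.0 + config.price_annual_drift) ** (year - year0), 2)

    # -- group monthly lines into invoices, then drop a fraction -------------
    all_lines: list[InvoiceLine] = []
    statements: list[Statement] = []
    dropped: list[str] = []
    counters = {year: 0 for year in config.years}
    import datetime as dt

    for year in config.years:
        for month in range(1, 13):
            month_lines = [
                (pid, pkg, qty)
                for (y, m, pid, pkg), qty in sorted(plan.items())
                if y == year and m == month
            ]
            if not month_lines:
                continue
            order = rng.permutation(len(month_lines))
            month_numbers: list[str] = []
            invoice_lines: dict[str, list[tuple[str, str, int]]] = {}
            chunk: list[tuple[str, str, int]] = []
            for pos in order:
                chunk.append(month_lines[pos])
                if len(chunk) >= config.lines_per_invoice:
                    counters[year] += 1
                    num = f"INV{year}-{counters[year]:04d}"
                    invoice_lines[num] = chunk
                    month_numbers.append(num)
                    chunk = []
            if chunk:
                counters[year] += 1
                num = f"INV{year}-{counters[year]:04d}"
                invoice_lines[num] = chunk
                month_numbers.append(num)
            # one purchase day per invoice, within the month
            for num in month_numbers:
                day = int(rng.integers(1, 29))
                keep = rng.random() >= config.missing_invoice_rate
                if not keep:
                    dropped.append(num)
                for pid, pkg, qty in sorted(invoice_lines[num]):
                    if keep:
                        all_lines.append(
                            InvoiceLine(
                                invoice_number=num,
                                date=dt.date(year, month, day),
                                supplier=config.supplier,
                                product_id=pid,
                                package=pkg,
                                quantity=qty,
                                unit_price_zar=price(pid, pkg, year),
                            )
                        )
            statements.append(
                Statement(
                    month=f"{year:04d}-{month:02d}",
                    supplier=config.supplier,
                    invoice_numbers=tuple(sorted(month_numbers)),
                )
            )
    all_lines.sort(key=lambda l: (l.date, l.invoice_number, l.product_id, l.package))

    # -- herd and slaughter series ------------------------------------------
    herd_records: list[HerdRecord] = []
    for year in config.years:
        for month in range(1, 13):
            counts = {}
            for pop in sorted(config.herd_means):
                m = config.herd_means[pop]
                counts[pop] = max(
                    0, int(round(m * (1.0 + config.herd_jitter * rng.standard_normal())))
                )
            weight = max(
                0.0,
                round(
                    config.slaughter_mean_kg
                    * (1.0 + config.slaughter_jitter * rng.standard_normal()),
                    1,
                ),
            )
            herd_records.append(
                HerdRecord(
                    month=f"{year:04d}-{month:02d}",
                    counts=counts,
                    slaughter_live_weight_kg=weight,
                )
            )

    truth = _realized_truth(config, catalog, all_lines, herd_records, dropped)
    return SyntheticFarm(
        config=config,
        catalog=catalog,
        invoices=all_lines,
        statements=statements,
        herd_records=herd_records,
        truth=truth,
    )


def _realized_truth(
    config: SynthConfig,
    catalog: Catalog,
    lines: list[InvoiceLine],
    herd_records: list[HerdRecord],
    dropped: list[str],
) -> dict:
    """Ground truth computed from the retained lines by direct accumulation.

    Deliberately plain arithmetic (no calls into the quantification
    pipeline) so recovery tests compare two independent code paths.
    """
    per_year: dict[str, dict] = {}
    programmes = {p.disease: p for p in default_programmes()}
    for year in config.years:
        ylines = [l for l in lines if l.year == year]
        grams: dict[str, float] = {}
        dosages: dict[str, float] = {}
        cost = {"antibiotic": 0.0, "vaccine": 0.0}
        for l in ylines:
            product = catalog.product(l.product_id)
            cost[product.kind] += l.quantity * l.unit_price_zar
            if product.kind == "antibiotic":
                for ing, g in catalog.grams_per_package(l.product_id, l.package).items():
                    grams[ing] = grams.get(ing, 0.0) + g * l.quantity
            else:
                doses = product.dosages_per_vial(l.package)
                dosages[product.disease] = dosages.get(product.disease, 0.0) + doses * l.quantity
        yrecs = [r for r in herd_records if r.year == year]
        sows = mean(
            r.count("dry_sows") + r.count("lactating_sows") + r.count("pregnant_sows")
            for r in yrecs
        )
        biomass = sum(r.slaughter_live_weight_kg for r in yrecs) + sows * 220.0
        ratios = {}
        for disease, dose_count in dosages.items():
            prog = programmes.get(disease)
            if prog is None:
                continue
            denom = sum(
                mean(r.count(e.population) for r in yrecs) * e.multiplier
                for e in prog.eligible
            )
            ratios[disease] = dose_count / denom
        # grams to 0.1 mg and ratios to 1e-6: far below any package's
        # resolution, so recovery comparisons are bit-exact at the recorded
        # precision without depending on float summation order
        per_year[str(year)] = {
            "ingredient_grams": {k: round(grams[k], 4) for k in sorted(grams)},
            "vaccine_dosages": {k: dosages[k] for k in sorted(dosages)},
            "administration_ratio": {k: round(ratios[k], 6) for k in sorted(ratios)},
            "biomass_kg": round(biomass, 4),
            "cost_zar": {
                "antibiotics": round(cost["antibiotic"], 2),
                "vaccines": round(cost["vaccine"], 2),
                "total": round(cost["antibiotic"] + cost["vaccine"], 2),
            },
        }
    return {
        "seed": config.seed,
        "years": list(config.years),
        "dropped_invoice_numbers": sorted(dropped),
        "per_year": per_year,
    }
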