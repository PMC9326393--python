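"""Run-level orchestration: load inputs, compute every table, write a bundle.

The report layer never recomputes science — it calls the catalog, ledger,
herd, quantify and costing modules and only *formats* their unrounded
outputs (kg, mg/kg and ratios to 2 decimals, ZAR to cents, USD to the
nearest dollar).  Reports are built fully in memory and written last, so a
failing stage never leaves a partial bundle on disk; re-running on
identical inputs yields identical bytes (stable row ordering, fixed float
formatting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import costing as costing_mod
from . import herd as herd_mod
from . import ledger as ledger_mod
from . import quantify
from .catalog import Catalog, load_catalog, reference_catalog
from .costing import CostingConfig
from .errors import ConfigurationError
from .herd import HerdConfig, VaccinationProgramme, default_programmes
from .units import round_half_up


class RunConfig(BaseModel):
    """Paths plus the study-window, herd, costing and programme settings."""

    invoices: str
    statements: Optional[str] = None
    herd: Optional[str] = None
    slaughter: Optional[str] = None
    catalog: Optional[str] = None  # None -> packaged reference catalog
    years: Optional[list[int]] = None  # None -> inferred from invoices
    herd_config: HerdConfig = Field(default_factory=HerdConfig)
    costing: CostingConfig = Field(default_factory=CostingConfig)
    programmes: list[VaccinationProgramme] = Field(default_factory=default_programmes)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


class ReportSummary(BaseModel):
    """Machine-readable run summary; its JSON schema is published via
    ``ReportSummary.model_json_schema()``."""

    years: list[int]
    n_invoice_lines: int
    reconciliation: dict
    biomass_kg: dict[str, float]
    total_volume_kg: dict[str, float]
    total_mg_per_kg: dict[str, float]
    total_volume_kg_excl_growth_promoters: dict[str, float]
    total_mg_per_kg_excl_growth_promoters: dict[str, float]
    total_cost_zar: dict[str, float]
    total_cost_usd: dict[str, float]
    vaccine_dosages: dict[str, float]
    vaccine_cost_zar: dict[str, float]


@dataclass
class ReportBundle:
    summary: ReportSummary
    tables: dict[str, pd.DataFrame]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = json.dumps(self.summary.model_dump(), indent=2, sort_keys=True)
        (out / "report.json").write_text(payload + "\n", encoding="utf-8")
        for name, df in sorted(self.tables.items()):
            df.to_csv(out / f"{name}.csv", index=False, lineterminator="\n")


def _fmt(df: pd.DataFrame, decimals: dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, nd in decimals.items():
        if col in out.columns:
            out[col] = [
                "n/c" if pd.isna(v) else f"{round_half_up(float(v), nd):.{nd}f}"
                for v in out[col]
            ]
    return out


def run_report(config: RunConfig) -> ReportBundle:
    """Assemble the full usage/vaccine/cost report bundle for a run."""
    catalog = load_catalog(config.catalog) if config.catalog else reference_catalog()
    invoices = ledger_mod.read_invoices(config.invoices, catalog=catalog)
    statements = ledger_mod.read_statements(config.statements) if config.statements else []
    recon = ledger_mod.reconcile(statements, invoices)
    herd_records = (
        herd_mod.read_herd(config.herd, config.slaughter) if config.herd else []
    )

    years = config.years or sorted({l.year for l in invoices})
    if not years:
        raise ConfigurationError("no study years: empty invoice file and no years configured")

    biomass = {}
    if herd_records:
        for year in years:
            biomass[year] = herd_mod.annual_biomass(herd_records, config.herd_config, year)

    ab_lines = quantify.antibiotic_lines(invoices, catalog)
    vx_lines = quantify.vaccine_lines(invoices, catalog)
    usage = quantify.usage_lines(ab_lines, catalog)
    usage = usage[usage["year"].isin(years)] if not usage.empty else usage
    usage_no_agp = quantify.growth_promoter_scenario(usage, exclude=True)

    tables: dict[str, pd.DataFrame] = {}

    def stratified(frame: pd.DataFrame, by: str) -> pd.DataFrame:
        tab = quantify.stratify(frame, by)
        if by == "class":
            # explicit zero rows for catalog classes absent from the ledger
            classes = sorted({i.antibiotic_class for i in catalog.ingredients})
            full = pd.MultiIndex.from_product([years, classes], names=["year", "stratum"])
            tab = (
                tab.set_index(["year", "stratum"]).reindex(full, fill_value=0.0).reset_index()
            )
            tab["volume_kg"] = tab["grams"] / 1000.0
        if biomass:
            tab = quantify.with_biomass(tab, biomass)
        return tab

    per_stratum = {}
    for by in ("total", "class", "ingredient", "route", "stage", "month"):
        tab = stratified(usage, by)
        per_stratum[by] = tab
        decimals = {"grams": 2, "volume_kg": 2, "mg_per_kg": 2}
        if by == "ingredient" and not tab.empty:
            schemes = (
                usage[["ingredient", "who", "ema", "woah", "pvs"]]
                .drop_duplicates()
                .rename(columns={"ingredient": "stratum"})
            )
            tab = tab.merge(schemes, on="stratum", how="left")
        tables[f"usage_by_{by}"] = _fmt(tab, decimals)

    for by in ("total", "class"):
        tab = stratified(usage_no_agp, by)
        tables[f"usage_excl_growth_promoters_by_{by}"] = _fmt(
            tab, {"grams": 2, "volume_kg": 2, "mg_per_kg": 2}
        )

    summary_cls = quantify.mean_sd_over_years(per_stratum["class"], "volume_kg")
    if biomass and "mg_per_kg" in per_stratum["class"].columns:
        mg = quantify.mean_sd_over_years(per_stratum["class"], "mg_per_kg")
        summary_cls = summary_cls.merge(
            mg, on="stratum", suffixes=("_volume_kg", "_mg_per_kg")
        )
    tables["usage_class_mean_sd"] = _fmt(
        summary_cls,
        {c: 2 for c in summary_cls.columns if c != "stratum"},
    )

    # ---- vaccines ----------------------------------------------------------
    vx_rows = []
    programmes = {p.disease: p for p in config.programmes}
    dosage_totals: dict[str, float] = {}
    for year in years:
        dosages = quantify.vaccine_dosages(vx_lines, catalog, year)
        for disease in sorted(dosages):
            dosage_totals[str(year)] = dosage_totals.get(str(year), 0.0) + dosages[disease]
            row = {"year": year, "disease": disease, "dosages": dosages[disease]}
            prog = programmes.get(disease)
            if prog is not None and herd_records:
                denom = herd_mod.eligible_population(prog, herd_records, year)
                row["eligible_population"] = denom
                row["administration_ratio"] = quantify.administration_ratio(
                    dosages[disease], denom
                )
            vx_rows.append(row)
    vaccines = pd.DataFrame(
        vx_rows,
        columns=["year", "disease", "dosages", "eligible_population", "administration_ratio"],
    )
    tables["vaccines"] = _fmt(
        vaccines, {"dosages": 0, "eligible_population": 2, "administration_ratio": 2}
    )
    cpd = pd.concat(
        [
            costing_mod.vaccine_cost_per_dosage(vx_lines, catalog, year, config.costing)
            for year in years
        ],
        ignore_index=True,
    ) if vx_lines else pd.DataFrame()
    tables["vaccine_cost_per_dosage"] = _fmt(
        cpd, {"cost_per_dosage_zar": 2, "cost_per_dosage_usd": 0}
    )

    # ---- costs -------------------------------------------------------------
    for key in ("product", "class", "kind", "total"):
        ct = costing_mod.annual_cost(invoices, catalog, key, config.costing)
        tables[f"costs_by_{key}"] = _fmt(ct, {"cost_zar": 2, "cost_usd": 0})

    # ---- machine-readable summary -----------------------------------------
    def per_year_total(frame: pd.DataFrame, col: str) -> dict[str, float]:
        out = {}
        for year in years:
            if frame.empty or col not in frame.columns:
                out[str(year)] = 0.0
            else:
                sel = frame[frame["year"] == year]
                out[str(year)] = round_half_up(float(sel[col].sum()), 2)
        return out

    cost_total = costing_mod.annual_cost(invoices, catalog, "total", config.costing)
    vx_cost = costing_mod.annual_cost(vx_lines, catalog, "total", config.costing)
    summary = ReportSummary(
        years=list(years),
        n_invoice_lines=len(invoices),
        reconciliation=recon.to_dict(),
        biomass_kg={str(y): round_half_up(v, 2) for y, v in biomass.items()},
        total_volume_kg=per_year_total(per_stratum["total"], "volume_kg"),
        total_mg_per_kg=per_year_total(per_stratum["total"], "mg_per_kg"),
        total_volume_kg_excl_growth_promoters=per_year_total(
            stratified(usage_no_agp, "total"), "volume_kg"
        ),
        total_mg_per_kg_excl_growth_promoters=per_year_total(
            stratified(usage_no_agp, "total"), "mg_per_kg"
        ),
        total_cost_zar=per_year_total(cost_total, "cost_zar"),
        total_cost_usd={
            str(y): float(round(per_year_total(cost_total, "cost_usd")[str(y)]))
            for y in years
        },
        vaccine_dosages={k: dosage_totals.get(k, 0.0) for k in map(str, years)},
        vaccine_cost_zar=per_year_total(vx_cost, "cost_zar"),
    )
    return ReportBundle(summary=summary, tables=tables)
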