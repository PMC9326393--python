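"""Vaccine dosage totals, administration ratios and cost per dosage.

Dosages are vials purchased x doses per vial, pooled per targeted disease.
The administration ratio divides dosages by the average eligible population
(doubled where a booster is scheduled); near 1 means procurement covered
the eligible herd.
"""

import tempfile
from pathlib import Path

from farmabu import (
    SynthConfig,
    administration_ratio,
    default_programmes,
    eligible_population,
    generate_farm,
    read_herd,
    read_invoices,
    vaccine_dosages,
)
from farmabu.costing import vaccine_cost_per_dosage
from farmabu.quantify import vaccine_lines

farm = generate_farm(SynthConfig(seed=42))
with tempfile.TemporaryDirectory() as d:
    farm.write(d)
    invoices = read_invoices(Path(d) / "invoices.csv", catalog=farm.catalog)
    herd = read_herd(Path(d) / "herd.csv", Path(d) / "slaughter.csv")

year = farm.config.years[0]
vx = vaccine_lines(invoices, farm.catalog)
dosages = vaccine_dosages(vx, farm.catalog, year)
programmes = {p.disease: p for p in default_programmes()}

print(f"vaccine programme, {year}:")
for disease in sorted(dosages):
    denom = eligible_population(programmes[disease], herd, year)
    ratio = administration_ratio(dosages[disease], denom)
    print(f"  {disease:<34} {dosages[disease]:>8.0f} doses  eligible {denom:>9.0f}  ratio {ratio:4.2f}")

print("\ncost per dosage (ZAR / USD):")
for _, row in vaccine_cost_per_dosage(vx, farm.catalog, year).iterrows():
    print(
        f"  {row['disease']:<34} {row['cost_per_dosage_zar']:6.2f} ZAR"
        f"  {row['cost_per_dosage_usd']:5.2f} $"
    )
# Ratios sit near or above one except the neonatal-diarrhoea programme,
# whose procurement covers well under half the eligible breeding animals.
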