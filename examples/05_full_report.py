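"""End-to-end: generate a synthetic 3-year farm and build the full report.

The report bundle holds the machine-readable JSON summary plus every CSV
table (usage by class/route/stage/month with mean±SD, vaccines, costs),
all formatted deterministically.
"""

import tempfile
from pathlib import Path

from farmabu import RunConfig, SynthConfig, generate_farm, run_report

with tempfile.TemporaryDirectory() as d:
    generate_farm(SynthConfig(seed=42)).write(d)
    bundle = run_report(
        RunConfig(
            invoices=str(Path(d) / "invoices.csv"),
            statements=str(Path(d) / "statements.csv"),
            herd=str(Path(d) / "herd.csv"),
            slaughter=str(Path(d) / "slaughter.csv"),
        )
    )
    out = Path(d) / "report"
    bundle.write(out)
    print("tables written:", ", ".join(sorted(t for t in bundle.tables)))

s = bundle.summary
print(f"\nmissing-invoice rate: {s.reconciliation['missing_rate_percent']}%")
for year in s.years:
    y = str(year)
    print(
        f"{year}: {s.total_volume_kg[y]:8.2f} kg  {s.total_mg_per_kg[y]:7.2f} mg/kg  "
        f"ZAR {s.total_cost_zar[y]:12,.2f}  ${s.total_cost_usd[y]:10,.0f}"
    )
print("\nmean±SD usage per class:")
print(bundle.tables["usage_class_mean_sd"].to_string(index=False))
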