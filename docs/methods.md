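# Methods

## Scope and model

`farmabu` implements purchase-based antimicrobial-usage quantification: the
quantity of antibiotic active ingredient *purchased* is taken as the proxy
for the quantity used, attributed to the purchase date, with no lag or
consumption model. This is the appropriate design when prescriptions are
unavailable and the farm buys only what it intends to use; it cannot
distinguish stockpiling from administration, and it deliberately computes no
dose-based metrics (DDDvet/DCDvet) — those require knowing how many animals
were treated, which a ledger does not record.

## Strength standardization

A product label declares the strength of a *chemical compound* (often a salt
or ester) in one of several dialects. The parser accepts:

| dialect | resolution |
|---|---|
| `x mg/mℓ`, `x g/kg`, `x g/ℓ` | identity |
| `x g/100 mℓ` | ×10 → g/ℓ |
| `p% = x g/kg` | the explicit `x` governs |
| `p%` alone | p×10 g/kg |
| `n IU = x mg/mℓ` | consistency check `n × iu_to_mg ≈ x` (0.5% tolerance) |
| `n IU/mℓ` | `n × iu_to_mg` mg/mℓ |

Grams of active base per package are strength × conversion factor ×
effective package content (container size × pack multiplicity). Two
numerically delicate rules:

* **IU factors are consumed once.** The 0.0006 mg/IU penicillin factor is
  used to resolve the IU declaration to mg/mℓ; the subsequent
  standardization multiplies by 1.0, not by 0.0006 again. Conversion
  factors are carried per product-ingredient entry (with an
  ingredient-level default) because the same base compound appears as
  different salts in different products — injectable amoxicillin needs no
  conversion while the in-feed trihydrate needs ×0.8712.
* **Rounding is half-up to 2 decimals, at reporting only.** All aggregation
  uses unrounded values; e.g. two 1 kg packs of the in-feed aminopenicillin
  are 2×980×0.8712 = 1707.552 → 1707.55 g, not 2×853.78. Python's banker's
  rounding is never used for reported figures.

One packaged catalog entry (the quinoxaline premix) carries a printed label
whose percentage is inconsistent with its printed per-package grams; the
catalog stores the strength consistent with the per-package figure, keeps
the printed label verbatim, and flags the discrepancy rather than guessing
intent.

## Census conventions

Class and classification-scheme shares use distinct active ingredients as
denominator. Route shares use distinct (ingredient, route) pairs:
dual-route ingredients count once per route, and the trimethoprim of the
potentiated sulphonamide is folded into the sulphonamide entry (standard
reporting practice for fixed-ratio combinations) rather than counted as an
own pair. Other co-formulated ingredients (dihydrostreptomycin,
spectinomycin, the penicillin G share of combination injectables) *are*
counted, because they are reported as own entries.

## Denominator

Biomass = annual slaughter live weight + average sow population × standard
sow weight. The standard sow weight defaults to 220 kg (South African herds
run heavier than the 192 kg continental default) and the sow population is
the sum of dry, lactating and pregnant sows; both are configuration, not
constants. No sow-proportion factor (0.09) is applied because the sow
inventory is observed monthly, not anticipated. Yearly averages are
arithmetic means over the months on file; a year with fewer than 12 records
averages what exists and emits a completeness warning instead of failing —
real ledgers have gaps, and refusing to compute would discard the year.

## Vaccines

Dosages per disease are doses/vial × vials purchased; dose counts live on
the package (the same vaccine ships as 20 mℓ/10-dose and 100 mℓ/50-dose
vials), and competitor products targeting the same disease pool into one
label. The administration ratio divides dosages by the average eligible
population, doubling populations whose schedule includes a primary plus a
booster within the year (gilts in two of the default programmes). Lactating
sows stand in for sows vaccinated two weeks pre-farrow. Ratios near 1
indicate procurement sufficient for full coverage; the metric says nothing
about actual injection events.

## Costing

Prices are captured ex-VAT; the VAT engine (14% to March 2018, 15% after)
exists for portability but is an identity pass-through under zero-rating.
Currency conversion uses one average ZAR/USD rate per year (14.7049,
13.3055, 11.5445 for 2016–2018), unrounded internally, rounded to the
nearest dollar in reports. A multi-ingredient product's cost is attributed
once — to the product, or at ingredient level to a combined label headed by
the first-listed (primary) ingredient — so every stratification preserves
the grand total. Multi-year USD summaries average the per-year conversions
rather than converting a multi-year ZAR mean at any single rate.
Mean ± SD summaries use the sample standard deviation (ddof = 1), with
strata absent in a year counted as zero for that year.

## Synthetic generator

The generator emulates the *structure and magnitudes* of a 3-year
farrow-to-finish ledger: roughly a hundred invoices a year from one
supplier, December-peaked seasonality (multinomial allocation of annual
package counts over configurable monthly weights), ~3% of invoices dropped
while their numbers remain on statements, monthly herd counts and slaughter
weights with small lognormal-ish jitter, and per-product prices with a 5%
annual drift. Default annual targets are sized to the reference farm's
reported magnitudes (≈920 kg of active ingredient, ≈270 mg/kg, in-feed
growth promoters dominant; vaccine ratios near 1 except a deliberately
under-procured neonatal-diarrhoea programme at ≈0.4). Herd count magnitudes
follow the farm's *recorded eligible-population denominators* (piglet
counts of ~23 000), not a demographic standing-stock model — the ratios
only make sense against counts of that magnitude.

Targets are integerized to whole packages (`round(target / grams-per-
package)`), and the **realized** totals — after integerization and after
the invoice drop — are recorded as ground truth, computed by plain per-line
accumulation independent of the pipeline's pandas path. Truth grams are
recorded at 0.1 mg resolution and ratios at 1e-6 (far below any package's
resolution) so recovery tests compare bit-exactly at the recorded precision
without depending on float summation order. What passing recovery tests
show is that ingestion, standardization, aggregation, reconciliation and
costing are mutually consistent and lossless; they do not validate the
generator's realism against any real farm, nor the purchase-as-use proxy
itself.

## Numerical and degenerate-input choices

Zero or negative biomass, zero eligible denominators, zero-size packages,
conversion factors outside (0, 1], unknown populations, unparseable labels
and unresolved product/package references all raise typed errors — nothing
is silently dropped or imputed. Strata are sorted lexicographically and
floats formatted at fixed precision in reports, so identical inputs yield
byte-identical output files. Reports are assembled fully in memory and
written last; a failing stage never leaves a partial bundle.

## Limitations

Single-supplier, single-farm design assumptions; purchase timing as a
seasonality proxy; combined production-stage labels are reported unsplit
(no apportionment rule exists when one product serves several stages);
vaccine costing excludes needles, syringes and labor; no inflation
adjustment.
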