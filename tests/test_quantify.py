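"""Numerators, weight adjustment, stratification and vaccine metrics."""

import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from farmabu import (
    InvoiceLine,
    abu_mg_per_kg,
    administration_ratio,
    annual_numerator,
    growth_promoter_scenario,
    stratify,
    usage_lines,
    vaccine_dosages,
    with_biomass,
)
from farmabu.errors import CatalogLookupError, ConfigurationError


def _line(product, package, qty, date="2016-03-05", num="I1", price=100.0):
    return InvoiceLine(
        invoice_number=num, date=dt.date.fromisoformat(date), supplier="vet",
        product_id=product, package=package, quantity=qty, unit_price_zar=price,
    )


# ---------------------------------------------------------------------------
# Numerator
# ---------------------------------------------------------------------------


def test_numerator_uses_unrounded_package_grams(catalog):
    """Two 1 kg in-feed aminopenicillin packs: 2 x 980 x 0.8712 = 1707.552 g.

    Aggregation runs on unrounded per-package grams (not on the 2-decimal
    reported figure), so the annual numerator is 1707.55 g after final
    rounding, not 2 x 853.78."""
    lines = [_line("amoxicillin-feed", "1kg", 2)]
    grams = annual_numerator(lines, catalog, 2016)["amoxicillin"]
    assert grams == pytest.approx(1707.552)
    assert round(grams, 2) == 1707.55


def test_numerator_empty_ledger(catalog):
    assert annual_numerator([], catalog, 2016) == {}


def test_numerator_multi_ingredient_contributes_to_each(catalog):
    lines = [_line("penicillin-streptomycin-inj", "100ml", 3)]
    grams = annual_numerator(lines, catalog, 2016)
    assert grams["dihydrostreptomycin"] == pytest.approx(150.0)
    assert grams["penicillin-g"] == pytest.approx(27.0)


def test_numerator_unresolved_product_raises(catalog):
    with pytest.raises(CatalogLookupError):
        annual_numerator([_line("mystery", "1kg", 1)], catalog, 2016)


@given(
    plan=st.lists(
        st.tuples(
            st.sampled_from(
                ["amoxicillin-feed", "chlortetracycline-feed", "penicillin-streptomycin-inj"]
            ),
            st.integers(1, 12),
        ),
        max_size=20,
    )
)
def test_numerator_matches_per_line_accumulation(catalog, plan):
    packages = {"amoxicillin-feed": "1kg", "chlortetracycline-feed": "25kg",
                "penicillin-streptomycin-inj": "100ml"}
    lines = [_line(p, packages[p], q, num=f"I{i}") for i, (p, q) in enumerate(plan)]
    expected: dict[str, float] = {}
    for p, q in plan:
        for ing, g in catalog.grams_per_package(p, packages[p]).items():
            expected[ing] = expected.get(ing, 0.0) + g * q
    result = annual_numerator(lines, catalog, 2016)
    assert set(result) == set(expected)
    for ing in expected:
        assert result[ing] == pytest.approx(expected[ing])


# ---------------------------------------------------------------------------
# Weight adjustment
# ---------------------------------------------------------------------------


def test_mg_per_kg_identity():
    assert abu_mg_per_kg(500_000.0, 2_000_000.0) == 250.0
    assert abu_mg_per_kg(0.0, 123.0) == 0.0


def test_mg_per_kg_rejects_nonpositive_biomass():
    with pytest.raises(ConfigurationError):
        abu_mg_per_kg(1.0, 0.0)


@given(g=st.floats(0, 1e7), kg=st.floats(1e3, 1e7))
def test_mg_per_kg_matches_independent_computation(g, kg):
    assert abu_mg_per_kg(g, kg) == pytest.approx((g * 1000.0) / kg)


def test_unit_consistency_volume_vs_mg_per_kg(catalog):
    """volume_kg x 1e6 / biomass == mg_per_kg, exactly, row by row."""
    lines = [_line("chlortetracycline-feed", "25kg", 4), _line("amoxicillin-feed", "1kg", 7)]
    table = with_biomass(stratify(usage_lines(lines, catalog), "class"), {2016: 3.2e6})
    for _, row in table.iterrows():
        assert row["volume_kg"] * 1e6 / 3.2e6 == pytest.approx(row["mg_per_kg"], rel=1e-12)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------


def test_single_class_ledger_class_table_equals_total(catalog):
    lines = [_line("chlortetracycline-feed", "25kg", 2)]
    usage = usage_lines(lines, catalog)
    cls = stratify(usage, "class")
    total = stratify(usage, "total")
    assert cls["grams"].sum() == pytest.approx(total["grams"].sum())
    assert list(cls["stratum"]) == ["tetracyclines"]


def test_month_split_attributes_by_invoice_year(catalog):
    lines = [
        _line("amoxicillin-feed", "1kg", 1, date="2016-12-31"),
        _line("amoxicillin-feed", "1kg", 1, date="2017-01-01"),
    ]
    tab = stratify(usage_lines(lines, catalog), "month")
    assert set(zip(tab["year"], tab["stratum"])) == {(2016, "2016-12"), (2017, "2017-01")}


@pytest.mark.parametrize("by", ["class", "ingredient", "route", "stage", "month",
                                "who", "ema", "woah", "pvs"])
def test_stratified_sums_conserve_total(catalog, farm, by):
    from farmabu.quantify import antibiotic_lines

    usage = usage_lines(antibiotic_lines(farm.invoices, catalog), catalog)
    total = stratify(usage, "total")["grams"].sum()
    assert stratify(usage, by)["grams"].sum() == pytest.approx(total, rel=1e-9)


def test_combined_stage_labels_not_split(catalog):
    lines = [_line("amoxicillin-inj", "100ml", 1)]
    tab = stratify(usage_lines(lines, catalog), "stage")
    assert list(tab["stratum"]) == ["farrowing & weaning"]


# ---------------------------------------------------------------------------
# Growth-promoter scenario
# ---------------------------------------------------------------------------


def test_growth_promoter_only_ledger_excludes_to_zero(catalog):
    lines = [_line("chlortetracycline-feed", "25kg", 2), _line("olaquindox-feed", "25kg", 1)]
    usage = usage_lines(lines, catalog)
    assert growth_promoter_scenario(usage, exclude=True).empty


def test_growth_promoter_exclude_false_is_identity(catalog):
    lines = [_line("chlortetracycline-feed", "25kg", 2)]
    usage = usage_lines(lines, catalog)
    assert growth_promoter_scenario(usage, exclude=False).equals(usage)


def test_growth_promoter_exclusion_never_increases_any_stratum(catalog, farm):
    from farmabu.quantify import antibiotic_lines

    usage = usage_lines(antibiotic_lines(farm.invoices, catalog), catalog)
    reduced = growth_promoter_scenario(usage, exclude=True)
    for by in ("total", "class", "route", "month"):
        full = stratify(usage, by).set_index(["year", "stratum"])["grams"]
        excl = stratify(reduced, by).set_index(["year", "stratum"])["grams"]
        joined = excl.reindex(full.index, fill_value=0.0)
        assert (joined <= full + 1e-9).all()


# ---------------------------------------------------------------------------
# Vaccines
# ---------------------------------------------------------------------------


def test_vaccine_dosages_vials_times_doses(catalog):
    lines = [_line("mhyo-vax", "100ml", 10)]
    assert vaccine_dosages(lines, catalog, 2016) == {"enzootic pneumonia": 500}


def test_vaccine_dosages_mixed_vial_sizes_sum(catalog):
    lines = [_line("ileitis-vax", "20ml", 5), _line("ileitis-vax", "100ml", 2)]
    assert vaccine_dosages(lines, catalog, 2016) == {"ileitis": 5 * 10 + 2 * 50}


def test_vaccine_competitor_products_pool_by_disease(catalog):
    lines = [
        _line("neonatal-diarrhoea-vax", "100ml", 2),
        _line("neonatal-diarrhoea-alt-vax", "100ml", 1),
    ]
    assert vaccine_dosages(lines, catalog, 2016) == {"neonatal pig diarrhoea": 150}


def test_vaccine_dosages_rejects_antibiotic_lines(catalog):
    with pytest.raises(TypeError):
        vaccine_dosages([_line("amoxicillin-feed", "1kg", 1)], catalog, 2016)


def test_administration_ratio_examples():
    assert administration_ratio(24_000, 24_000) == 1.0
    assert administration_ratio(4_100, 10_000) == 0.41
    with pytest.raises(ConfigurationError):
        administration_ratio(10, 0)


@given(d=st.integers(0, 10**6), n=st.integers(1, 10**6))
def test_administration_ratio_matches_oracle_division(d, n):
    assert administration_ratio(d, n) == pytest.approx(d / n)
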