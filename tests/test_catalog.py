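"""Catalog model, strength-dialect parsing and standardization calculus."""

import pytest
from hypothesis import given
from hypothesis import strategies as st
from pydantic import ValidationError

from farmabu import (
    ActiveIngredient,
    PackageSpec,
    catalog_summary,
    parse_strength,
    reported_grams,
    standardized_grams,
)
from farmabu.catalog import catalog_json_schema
from farmabu.errors import (
    CatalogLookupError,
    ConfigurationError,
    StrengthFormatError,
    UnitCompatibilityError,
)
from farmabu.units import round_half_up

PEN = ActiveIngredient(name="pen", antibiotic_class="beta-lactams", iu_to_mg=0.0006)


# ---------------------------------------------------------------------------
# Strength parsing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "label,value,unit",
    [
        ("100 mg/mℓ", 100.0, "mg/mL"),
        ("150 mg/mℓ", 150.0, "mg/mL"),
        ("500 mg/mℓ", 500.0, "mg/mL"),
        ("22 g/kg", 22.0, "g/kg"),
        ("22g /kg", 22.0, "g/kg"),
        ("20% = 200g/kg", 200.0, "g/kg"),
        ("98% = 980 g/kg", 980.0, "g/kg"),
        ("70% = 70g/kg", 70.0, "g/kg"),  # explicit figure governs, not 700
        ("20%", 200.0, "g/kg"),  # bare percent: p x 10 g/kg
        ("20 g/100 mℓ", 200.0, "g/L"),
        ("4 g/100 mℓ", 40.0, "g/L"),
        ("300 000 IU = 180 mg/mℓ", 180.0, "mg/mL"),
        ("168 000 IU = 100.8 mg/mℓ", 100.8, "mg/mL"),
        ("300 000 IU/mℓ", 180.0, "mg/mL"),
    ],
)
def test_parse_strength_dialects(label, value, unit):
    decl = parse_strength(label, PEN)
    assert decl.resolved_value == pytest.approx(value)
    assert decl.resolved_unit == unit


def test_iu_label_must_agree_with_iu_factor():
    # 300 000 IU x 0.0006 = 180, label claiming 200 mg/mL is off by >0.5%
    with pytest.raises(StrengthFormatError):
        parse_strength("300 000 IU = 200 mg/mℓ", PEN)


def test_iu_label_without_factor_is_a_configuration_error():
    bare = ActiveIngredient(name="x", antibiotic_class="beta-lactams")
    with pytest.raises(ConfigurationError):
        parse_strength("300 000 IU = 180 mg/mℓ", bare)


def test_unparseable_label_names_the_label():
    with pytest.raises(StrengthFormatError, match="three spoonfuls"):
        parse_strength("three spoonfuls per bucket")


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def _pkg(size, unit, mult=1):
    return PackageSpec(id="p", size=size, unit=unit, multiplicity=mult)


@pytest.mark.parametrize(
    "label,factor,size,unit,mult,expected",
    [
        ("98% = 980 g/kg", 0.8712, 1, "kg", 1, 853.78),
        ("200 mg/mℓ", 0.9274, 100, "ml", 1, 18.55),
        ("200 mg/mℓ", 0.9274, 250, "ml", 1, 46.37),
        ("500 g/kg", 1.0, 40, "g", 10, 200.0),
        ("99.9% = 999 g/kg", 0.8097, 25, "kg", 1, 20222.26),
        ("20 g/100 mℓ", 0.9193, 5, "l", 1, 919.3),
        ("300 000 IU = 180 mg/mℓ", 1.0, 100, "ml", 1, 18.0),
        ("168 000 IU = 100.8 mg/mℓ", 1.0, 100, "ml", 1, 10.08),
    ],
)
def test_standardized_grams_reproduces_printed_values(label, factor, size, unit, mult, expected):
    decl = parse_strength(label, PEN)
    assert reported_grams(decl, factor, _pkg(size, unit, mult)) == expected


def test_basis_unit_mismatch_raises():
    decl = parse_strength("22 g/kg")
    with pytest.raises(UnitCompatibilityError):
        standardized_grams(decl, 1.0, _pkg(100, "ml"))
    decl = parse_strength("100 mg/mℓ")
    with pytest.raises(UnitCompatibilityError):
        standardized_grams(decl, 1.0, _pkg(1, "kg"))


def test_zero_size_package_rejected():
    with pytest.raises(ValidationError):
        _pkg(0, "kg")


@given(
    strength=st.floats(1.0, 1000.0),
    factor=st.floats(0.1, 1.0),
    size=st.floats(0.1, 100.0),
    mult=st.integers(1, 20),
)
def test_standardization_linear_in_package(strength, factor, size, mult):
    """grams(k-fold package) == k x grams(unit package), before rounding."""
    decl = parse_strength(f"{strength} g/kg")
    unit = standardized_grams(decl, factor, _pkg(size, "kg", 1))
    kfold = standardized_grams(decl, factor, _pkg(size, "kg", mult))
    assert kfold == pytest.approx(mult * unit, abs=1e-9, rel=1e-12)


@given(
    strength=st.floats(1.0, 1000.0),
    factor=st.floats(0.1, 0.9),
    size=st.floats(0.1, 100.0),
)
def test_standardization_strictly_increasing(strength, factor, size):
    decl = parse_strength(f"{strength} g/kg")
    base = standardized_grams(decl, factor, _pkg(size, "kg"))
    assert standardized_grams(decl, factor, _pkg(size * 1.5, "kg")) > base
    assert standardized_grams(decl, factor * 1.1, _pkg(size, "kg")) > base
    assert standardized_grams(decl, factor, _pkg(size, "kg", 2)) > base


# ---------------------------------------------------------------------------
# Full catalog round-trip against the printed per-package grams
# ---------------------------------------------------------------------------

# (product, package, ingredient) -> grams of active base per package as
# printed on the compiled SPC sheet; 2-decimal half-up rounding.
PRINTED_PACKAGE_GRAMS = [
    ("penicillin-streptomycin-inj", "100ml", "dihydrostreptomycin", 50.0),
    ("penicillin-streptomycin-inj", "100ml", "penicillin-g", 9.0),
    ("gentamycin-inj", "50ml", "gentamycin", 2.5),
    ("neomycin-water", "1kg", "neomycin", 70.0),
    ("lincomycin-spectinomycin-feed", "1kg", "lincomycin", 22.0),
    ("lincomycin-spectinomycin-feed", "1kg", "spectinomycin", 22.0),
    ("amoxicillin-inj", "100ml", "amoxicillin", 15.0),
    ("amoxicillin-feed", "1kg", "amoxicillin", 853.78),
    ("duplex-penicillin-inj", "100ml", "benzylpenicillin", 9.0),
    ("duplex-penicillin-inj", "100ml", "penicillin-g", 9.0),
    ("benzathine-penicillin-inj", "100ml", "benzylpenicillin", 10.08),
    ("cefquinome-inj", "100ml", "cefquinome", 2.5),
    ("procaine-penicillin-inj", "100ml", "penicillin-g", 18.0),
    ("danofloxacin-inj", "100ml", "danofloxacin", 2.5),
    ("lincomycin-inj", "100ml", "lincomycin", 10.0),
    ("tulathromycin-inj", "50ml", "tulathromycin", 5.0),
    ("tulathromycin-inj", "100ml", "tulathromycin", 10.0),
    ("tulathromycin-inj", "250ml", "tulathromycin", 25.0),
    ("florfenicol-inj", "100ml", "florfenicol", 30.0),
    ("tiamulin-feed-10", "10kg", "tiamulin", 809.7),
    ("tiamulin-feed-999", "25kg", "tiamulin", 20222.26),
    ("olaquindox-feed", "25kg", "olaquindox", 2500.0),
    ("virginiamycin-feed", "10x40g", "virginiamycin", 200.0),
    ("sulphadiazine-trimethoprim-water", "5l", "sulphadiazine", 919.3),
    ("sulphadiazine-trimethoprim-water", "5l", "trimethoprim", 200.0),
    ("chlortetracycline-feed", "25kg", "chlortetracycline", 5000.0),
    ("oxytetracycline-inj", "100ml", "oxytetracycline", 18.55),
    ("oxytetracycline-inj", "250ml", "oxytetracycline", 46.37),
]


@pytest.mark.parametrize("product,package,ingredient,expected", PRINTED_PACKAGE_GRAMS)
def test_reference_catalog_reproduces_printed_grams(catalog, product, package, ingredient, expected):
    grams = catalog.grams_per_package(product, package)[ingredient]
    assert round_half_up(grams, 2) == expected


def test_discrepant_label_is_flagged_not_guessed(catalog):
    """The quinoxaline premix label disagrees with its per-package grams; the
    effective strength consistent with the package figure is stored, the
    printed label preserved and flagged."""
    entry = catalog.product("olaquindox-feed").ingredients[0]
    assert entry.label_discrepant
    assert entry.declared_label is not None
    assert entry.strength != entry.declared_label


# ---------------------------------------------------------------------------
# Classification and census
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ingredient,scheme,expected",
    [
        ("cefquinome", "who", "CIA-highest"),
        ("virginiamycin", "ema", "A"),
        ("olaquindox", "ema", "NC"),
        ("tiamulin", "woah", "VHIA"),
        ("chlortetracycline", "pvs", "HV & CI"),
    ],
)
def test_classify_lookup(catalog, ingredient, scheme, expected):
    assert catalog.classify(ingredient, scheme) == expected


def test_classify_is_total_over_catalog(catalog):
    for ing in catalog.ingredients:
        for scheme in ("who", "ema", "woah", "pvs"):
            assert catalog.classify(ing.name, scheme)  # never empty/None


def test_missing_scheme_value_returns_unclassified_sentinel():
    ing = ActiveIngredient(name="x", antibiotic_class="phenicols")
    assert ing.who_class == "unclassified"


def test_census_counts(catalog):
    assert len(catalog.ingredients) == 19
    assert len({i.antibiotic_class for i in catalog.ingredients}) == 11
    cls = catalog_summary(catalog, "class")
    assert cls.loc["aminoglycosides", "count"] == 4
    assert cls.loc["aminoglycosides", "percent"] == 21.05
    route = catalog_summary(catalog, "route")
    assert int(route["count"].sum()) == 20
    assert route.loc["injectable", "count"] == 11
    assert route.loc["injectable", "percent"] == 55.00
    woah = catalog_summary(catalog, "woah")
    assert woah.loc["VCIA", "count"] == 15
    assert woah.loc["VCIA", "percent"] == 78.95


@pytest.mark.parametrize("by", ["class", "route", "who", "ema", "woah", "pvs"])
def test_census_percentages_sum_to_100(catalog, by):
    total = catalog_summary(catalog, by)["percent"].sum()
    assert abs(total - 100.0) <= 0.02


def test_single_ingredient_catalog_normalizes_to_100():
    from farmabu import Catalog

    cat = Catalog(
        ingredients=[ActiveIngredient(name="only", antibiotic_class="phenicols")],
        products=[],
    )
    assert catalog_summary(cat, "class").loc["phenicols", "percent"] == 100.0


def test_catalog_schema_and_yaml_round_trip(catalog, tmp_path):
    from farmabu.catalog import dump_catalog, load_catalog

    schema = catalog_json_schema()
    assert schema["title"] == "Catalog"
    path = tmp_path / "cat.yaml"
    dump_catalog(catalog, path)
    again = load_catalog(path)
    assert again == catalog


def test_unknown_package_lookup_raises(catalog):
    with pytest.raises(CatalogLookupError):
        catalog.product("amoxicillin-feed").package("9000kg")
    with pytest.raises(CatalogLookupError):
        catalog.product("not-a-product")
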