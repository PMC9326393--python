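"""Summary-of-product-characteristics (SPC) catalog and strength standardization.

A veterinary medicinal product (VMP) declares the strength of each chemical
compound on its label in one of several dialects (mg/mL, g/kg, percentages,
g per 100 mL, international units).  Usage quantification needs a single
common numerator unit: grams of *active base compound* per package.  This
module provides

* the data model for active ingredients, strength declarations, packages and
  products (pydantic, with a publishable JSON schema),
* :func:`parse_strength` — the label-dialect parser,
* :func:`standardized_grams` — strength x salt-conversion factor x package
  content, the core standardization calculus,
* importance classification lookups (WHO CIA, EMA AMEG categories, WOAH and
  the South African Pig Veterinary Society scheme), and
* :func:`catalog_summary` — ingredient / scheme / route census tables.

Salt declarations (e.g. amoxicillin trihydrate, oxytetracycline dihydrate)
are rescaled to the active base via a conversion factor in (0, 1].  IU
declarations are resolved to mg via a compound-specific factor (0.0006 mg/IU
for the penicillins) *before* standardization; the IU factor is never applied
twice.
"""

from __future__ import annotations

import re
from typing import Iterable, Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import (
    CatalogLookupError,
    ConfigurationError,
    StrengthFormatError,
    UnitCompatibilityError,
)
from .units import normalise_label, round_half_up

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

ANTIBIOTIC_CLASSES = frozenset(
    {
        "aminoglycosides",
        "beta-lactams",
        "fluoroquinolones",
        "lincosamides",
        "macrolides",
        "phenicols",
        "pleuromutilins",
        "quinoxalines",
        "streptogramins",
        "sulphonamides",
        "tetracyclines",
    }
)

UNCLASSIFIED = "unclassified"

#: WHO critically-important-antimicrobials tiers.
WHO_CATEGORIES = frozenset({"CIA-highest", "CIA-high", "HI", "I", "NU"})
#: EMA antimicrobial advice ad-hoc expert group prescribing categories.
EMA_CATEGORIES = frozenset({"A", "B", "C", "D", "NC"})
#: WOAH veterinary importance tiers.
WOAH_CATEGORIES = frozenset({"VCIA", "VHIA", "VIA"})
#: Pig Veterinary Society (South Africa) combinations.
PVS_CATEGORIES = frozenset({"HV & CI", "CI", "HV & HI", "HI", "NC"})

SCHEMES = {
    "who": WHO_CATEGORIES,
    "ema": EMA_CATEGORIES,
    "woah": WOAH_CATEGORIES,
    "pvs": PVS_CATEGORIES,
}

PRODUCTION_STAGES = frozenset({"breeding", "farrowing", "weaning", "growing", "all"})

Route = Literal["injectable", "in-feed", "in-water", "oral-drench"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class ActiveIngredient(BaseModel):
    """An antibiotic base compound and its classification metadata.

    ``salt_conversion_factor`` is the ingredient-level default fraction of
    active base per unit of declared salt/ester; individual product entries
    may override it (the same base can be marketed as different salts).
    ``iu_to_mg`` converts an IU potency declaration to mg and is
    compound-specific.
    """

    name: str
    antibiotic_class: str
    salt_conversion_factor: float = Field(default=1.0, gt=0.0, le=1.0)
    iu_to_mg: Optional[float] = Field(default=None, gt=0.0)
    growth_promoter: bool = False
    who_class: str = UNCLASSIFIED
    ema_class: str = UNCLASSIFIED
    woah_class: str = UNCLASSIFIED
    pvs_class: str = UNCLASSIFIED

    @field_validator("antibiotic_class")
    @classmethod
    def _class_in_vocab(cls, v: str) -> str:
        if v not in ANTIBIOTIC_CLASSES:
            raise ValueError(f"unknown antibiotic class {v!r}")
        return v

    @field_validator("who_class")
    @classmethod
    def _who(cls, v: str) -> str:
        return _check_scheme(v, WHO_CATEGORIES, "WHO")

    @field_validator("ema_class")
    @classmethod
    def _ema(cls, v: str) -> str:
        return _check_scheme(v, EMA_CATEGORIES, "EMA")

    @field_validator("woah_class")
    @classmethod
    def _woah(cls, v: str) -> str:
        return _check_scheme(v, WOAH_CATEGORIES, "WOAH")

    @field_validator("pvs_class")
    @classmethod
    def _pvs(cls, v: str) -> str:
        return _check_scheme(v, PVS_CATEGORIES, "PVS")


def _check_scheme(v: str, vocab: frozenset, label: str) -> str:
    if v != UNCLASSIFIED and v not in vocab:
        raise ValueError(f"{v!r} is not a {label} category")
    return v


class StrengthDeclaration(BaseModel):
    """A resolved label strength.

    ``resolved_value``/``resolved_unit`` give the strength in one of mg/mL,
    g/L (both mass-per-volume) or g/kg (mass-per-mass).  ``from_iu`` marks
    declarations resolved from an IU potency; for those the IU→mg conversion
    is already folded into the value.
    """

    raw_label: str
    resolved_value: float = Field(gt=0.0)
    resolved_unit: Literal["mg/mL", "g/L", "g/kg"]
    basis: Literal["mass-per-volume", "mass-per-mass"]
    from_iu: bool = False

    @property
    def grams_per_ml(self) -> float:
        if self.basis != "mass-per-volume":
            raise UnitCompatibilityError(
                f"{self.raw_label!r} is a mass-per-mass strength, has no g/mL value"
            )
        if self.resolved_unit == "mg/mL":
            return self.resolved_value / 1000.0
        return self.resolved_value / 1000.0  # g/L == mg/mL numerically

    @property
    def grams_per_kg(self) -> float:
        if self.basis != "mass-per-mass":
            raise UnitCompatibilityError(
                f"{self.raw_label!r} is a mass-per-volume strength, has no g/kg value"
            )
        return self.resolved_value


class PackageSpec(BaseModel):
    """A purchasable package: container size, unit and pack multiplicity.

    ``multiplicity`` covers multi-unit packs such as "10 x 40 g" sachet boxes;
    the effective content is ``size * multiplicity``.  ``doses`` is the number
    of vaccine dosages per vial and is only set on vaccine packages.
    """

    id: str
    size: float = Field(gt=0.0)
    unit: Literal["ml", "l", "g", "kg"]
    multiplicity: int = Field(default=1, ge=1)
    doses: Optional[int] = Field(default=None, ge=1)

    @field_validator("unit", mode="before")
    @classmethod
    def _normalise_unit(cls, v: str) -> str:
        return str(v).replace("ℓ", "l").replace("mL", "ml").lower()

    @property
    def content_ml(self) -> float:
        if self.unit == "ml":
            return self.size * self.multiplicity
        if self.unit == "l":
            return self.size * 1000.0 * self.multiplicity
        raise UnitCompatibilityError(f"package {self.id!r} is not a volume package")

    @property
    def content_kg(self) -> float:
        if self.unit == "kg":
            return self.size * self.multiplicity
        if self.unit == "g":
            return self.size / 1000.0 * self.multiplicity
        raise UnitCompatibilityError(f"package {self.id!r} is not a mass package")

    @property
    def is_volume(self) -> bool:
        return self.unit in ("ml", "l")


class ProductIngredient(BaseModel):
    """One ingredient entry of a product.

    ``strength`` is the effective label parsed for standardization;
    ``declared_label`` preserves the printed label when it differs (a label
    whose percentage and per-package figures disagree is stored with the
    figure consistent with the per-package grams and ``label_discrepant``
    set).  ``census_exclude`` marks a co-formulated secondary ingredient that
    reporting folds into its partner's entry (e.g. trimethoprim in a
    potentiated sulphonamide), so it is not counted as an own
    ingredient-route pair.
    """

    ingredient: str
    strength: str
    declared_label: Optional[str] = None
    conversion_factor: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    census_exclude: bool = False
    label_discrepant: bool = False


class ProductSpec(BaseModel):
    """A veterinary medicinal product (antibiotic or vaccine)."""

    product_id: str
    name: Optional[str] = None
    kind: Literal["antibiotic", "vaccine"]
    route: Route
    production_stages: list[str] = Field(default_factory=list)
    statute: str = "unknown"
    ingredients: list[ProductIngredient] = Field(default_factory=list)
    packages: list[PackageSpec]
    # vaccine-only fields
    disease: Optional[str] = None
    diseases_covered: list[str] = Field(default_factory=list)
    pathogens: list[str] = Field(default_factory=list)
    vaccine_type: Optional[str] = None
    schedule: Optional[str] = None

    @field_validator("production_stages")
    @classmethod
    def _stages(cls, v: list[str]) -> list[str]:
        bad = [s for s in v if s not in PRODUCTION_STAGES]
        if bad:
            raise ValueError(f"unknown production stage(s): {bad}")
        return v

    @model_validator(mode="after")
    def _kind_constraints(self) -> "ProductSpec":
        if self.kind == "antibiotic" and not self.ingredients:
            raise ValueError(f"antibiotic product {self.product_id!r} needs >=1 ingredient")
        if self.kind == "vaccine":
            if self.disease is None:
                raise ValueError(f"vaccine product {self.product_id!r} needs a disease")
            for p in self.packages:
                if p.doses is None:
                    raise ValueError(
                        f"vaccine package {self.product_id}/{p.id} needs dosages per vial"
                    )
        if not self.packages:
            raise ValueError(f"product {self.product_id!r} has no packages")
        ids = [p.id for p in self.packages]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate package ids in {self.product_id!r}")
        return self

    @property
    def stage_label(self) -> str:
        """Combined production-stage label, preserved unsplit (e.g. 'farrowing & weaning')."""
        return " & ".join(self.production_stages) if self.production_stages else "unspecified"

    def package(self, ref: str) -> PackageSpec:
        for p in self.packages:
            if p.id == ref:
                return p
        raise CatalogLookupError(f"package {ref!r} not found on product {self.product_id!r}")

    def dosages_per_vial(self, package_ref: str) -> int:
        pkg = self.package(package_ref)
        if pkg.doses is None:
            raise CatalogLookupError(
                f"{self.product_id}/{package_ref} carries no dosage count (not a vaccine vial?)"
            )
        return pkg.doses


# ---------------------------------------------------------------------------
# Strength parsing
# ---------------------------------------------------------------------------

_NUM = r"(\d+(?:\.\d+)?)"

_RE_IU_EQ = re.compile(rf"^{_NUM}\s*iu\s*=\s*{_NUM}\s*mg/ml$")
_RE_IU_PER_ML = re.compile(rf"^{_NUM}\s*iu/ml$")
_RE_PCT_EQ_GKG = re.compile(rf"^{_NUM}\s*%\s*=\s*{_NUM}\s*g/kg$")
_RE_G_PER_100ML = re.compile(rf"^{_NUM}\s*g/100\s*ml$")
_RE_MG_PER_ML = re.compile(rf"^{_NUM}\s*mg/ml$")
_RE_G_PER_KG = re.compile(rf"^{_NUM}\s*g/kg$")
_RE_G_PER_L = re.compile(rf"^{_NUM}\s*g/l$")
_RE_PCT = re.compile(rf"^{_NUM}\s*%$")

IU_TOLERANCE = 0.005  # relative: IU count x iu_to_mg must match stated mg/mL within 0.5%


def parse_strength(
    raw_label: str, ingredient: Optional[ActiveIngredient] = None
) -> StrengthDeclaration:
    """Parse a declared label strength into a resolved value and unit.

    Supported dialects (script-ell, spaced thousands and spacing variants are
    normalised first):

    * ``"150 mg/mℓ"`` — mass per volume, identity.
    * ``"22 g/kg"`` — mass per mass, identity.
    * ``"98% = 980 g/kg"`` — the explicit g/kg figure governs.
    * ``"p%"`` alone — p x 10 g/kg.
    * ``"20 g/100 mℓ"`` — resolved to g/L.
    * ``"40 g/ℓ"`` — g/L identity.
    * ``"300 000 IU = 180 mg/mℓ"`` — the stated mg/mL must agree with
      ``IU x ingredient.iu_to_mg`` within 0.5% or an error is raised.
    * ``"300 000 IU/mℓ"`` — resolved via ``ingredient.iu_to_mg``.

    Raises :class:`StrengthFormatError` for unknown dialects and
    :class:`ConfigurationError` when an IU label is given but the ingredient
    has no ``iu_to_mg`` on file.
    """
    label = normalise_label(raw_label)

    m = _RE_IU_EQ.match(label)
    if m:
        iu, mg_ml = float(m.group(1)), float(m.group(2))
        expected = _resolve_iu(iu, ingredient, raw_label)
        if abs(expected - mg_ml) > IU_TOLERANCE * mg_ml:
            raise StrengthFormatError(
                f"{raw_label!r}: {iu:.0f} IU x {ingredient.iu_to_mg} mg/IU = "
                f"{expected:g} mg/mL, label states {mg_ml:g} mg/mL"
            )
        return StrengthDeclaration(
            raw_label=raw_label, resolved_value=mg_ml, resolved_unit="mg/mL",
            basis="mass-per-volume", from_iu=True,
        )
    m = _RE_IU_PER_ML.match(label)
    if m:
        mg_ml = _resolve_iu(float(m.group(1)), ingredient, raw_label)
        return StrengthDeclaration(
            raw_label=raw_label, resolved_value=mg_ml, resolved_unit="mg/mL",
            basis="mass-per-volume", from_iu=True,
        )
    m = _RE_PCT_EQ_GKG.match(label)
    if m:  # explicit g/kg wins over the percentage
        return _mass_decl(raw_label, float(m.group(2)))
    m = _RE_G_PER_100ML.match(label)
    if m:
        return StrengthDeclaration(
            raw_label=raw_label, resolved_value=float(m.group(1)) * 10.0,
            resolved_unit="g/L", basis="mass-per-volume",
        )
    m = _RE_MG_PER_ML.match(label)
    if m:
        return StrengthDeclaration(
            raw_label=raw_label, resolved_value=float(m.group(1)),
            resolved_unit="mg/mL", basis="mass-per-volume",
        )
    m = _RE_G_PER_KG.match(label)
    if m:
        return _mass_decl(raw_label, float(m.group(1)))
    m = _RE_G_PER_L.match(label)
    if m:
        return StrengthDeclaration(
            raw_label=raw_label, resolved_value=float(m.group(1)),
            resolved_unit="g/L", basis="mass-per-volume",
        )
    m = _RE_PCT.match(label)
    if m:  # p% == p*10 g/kg when no explicit figure is printed
        return _mass_decl(raw_label, float(m.group(1)) * 10.0)
    raise StrengthFormatError(f"unparseable strength label: {raw_label!r}")


def _resolve_iu(iu: float, ingredient: Optional[ActiveIngredient], raw: str) -> float:
    if ingredient is None or ingredient.iu_to_mg is None:
        raise ConfigurationError(
            f"label {raw!r} declares IU but no iu_to_mg factor is on file"
        )
    return iu * ingredient.iu_to_mg


def _mass_decl(raw: str, g_per_kg: float) -> StrengthDeclaration:
    return StrengthDeclaration(
        raw_label=raw, resolved_value=g_per_kg, resolved_unit="g/kg", basis="mass-per-mass"
    )


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def standardized_grams(
    strength: StrengthDeclaration, conversion_factor: float, package: PackageSpec
) -> float:
    """Grams of active base compound per package, unrounded.

    grams = strength (g per container unit) x conversion_factor x effective
    package content.  Mass-per-volume strengths pair with mL/L packages and
    mass-per-mass with g/kg packages; a mismatch raises
    :class:`UnitCompatibilityError`.  Use :func:`reported_grams` for the
    2-decimal half-up figure printed in reports.
    """
    if conversion_factor <= 0:
        raise ConfigurationError(f"conversion factor must be positive, got {conversion_factor}")
    if strength.basis == "mass-per-volume":
        return strength.grams_per_ml * conversion_factor * package.content_ml
    return strength.grams_per_kg * conversion_factor * package.content_kg


def reported_grams(
    strength: StrengthDeclaration, conversion_factor: float, package: PackageSpec
) -> float:
    """Reporting form of :func:`standardized_grams` (half-up, 2 decimals)."""
    return round_half_up(standardized_grams(strength, conversion_factor, package), 2)


# ---------------------------------------------------------------------------
# Catalog container
# ---------------------------------------------------------------------------


class Catalog(BaseModel):
    """The full SPC catalog: active ingredients plus products."""

    ingredients: list[ActiveIngredient] = Field(default_factory=list)
    products: list[ProductSpec] = Field(default_factory=list)

    @model_validator(mode="after")
    def _referential_integrity(self) -> "Catalog":
        names = {i.name for i in self.ingredients}
        if len(names) != len(self.ingredients):
            raise ValueError("duplicate ingredient names in catalog")
        pids = [p.product_id for p in self.products]
        if len(set(pids)) != len(pids):
            raise ValueError("duplicate product ids in catalog")
        for p in self.products:
            for entry in p.ingredients:
                if entry.ingredient not in names:
                    raise ValueError(
                        f"product {p.product_id!r} references unknown ingredient "
                        f"{entry.ingredient!r}"
                    )
        return self

    # -- lookups ----------------------------------------------------------

    def ingredient(self, name: str) -> ActiveIngredient:
        for i in self.ingredients:
            if i.name == name:
                return i
        raise CatalogLookupError(f"ingredient {name!r} not in catalog")

    def product(self, product_id: str) -> ProductSpec:
        for p in self.products:
            if p.product_id == product_id:
                return p
        raise CatalogLookupError(f"product {product_id!r} not in catalog")

    def has_product(self, product_id: str) -> bool:
        return any(p.product_id == product_id for p in self.products)

    def antibiotic_products(self) -> list[ProductSpec]:
        return [p for p in self.products if p.kind == "antibiotic"]

    def vaccine_products(self) -> list[ProductSpec]:
        return [p for p in self.products if p.kind == "vaccine"]

    # -- standardization over the catalog ---------------------------------

    def grams_per_package(self, product_id: str, package_ref: str) -> dict[str, float]:
        """Unrounded grams of each active ingredient in one package of a product."""
        product = self.product(product_id)
        pkg = product.package(package_ref)
        out: dict[str, float] = {}
        for entry in product.ingredients:
            ing = self.ingredient(entry.ingredient)
            strength = parse_strength(entry.strength, ing)
            factor = (
                entry.conversion_factor
                if entry.conversion_factor is not None
                else (1.0 if strength.from_iu else ing.salt_conversion_factor)
            )
            out[entry.ingredient] = standardized_grams(strength, factor, pkg)
        return out

    def classify(self, ingredient_name: str, scheme: str) -> str:
        """Importance category of an ingredient under one of the four schemes.

        Total over the catalog: a missing value returns the explicit
        ``"unclassified"`` sentinel, never a silent omission.
        """
        scheme = scheme.lower()
        if scheme not in SCHEMES:
            raise ConfigurationError(f"unknown classification scheme {scheme!r}")
        ing = self.ingredient(ingredient_name)
        return getattr(ing, f"{scheme}_class")

    # -- (ingredient, route) pairs for the census and stratification ------

    def ingredient_route_pairs(self) -> list[tuple[str, str]]:
        """Distinct (ingredient, route) pairs over antibiotic products.

        Co-formulated secondary entries flagged ``census_exclude`` are folded
        into their partner's entry and not counted separately.
        """
        pairs: set[tuple[str, str]] = set()
        for p in self.antibiotic_products():
            for entry in p.ingredients:
                if not entry.census_exclude:
                    pairs.add((entry.ingredient, p.route))
        return sorted(pairs)


# ---------------------------------------------------------------------------
# Census / summary tables
# ---------------------------------------------------------------------------


def catalog_summary(catalog: Catalog, by: str = "class") -> pd.DataFrame:
    """Counts and percentage shares over the catalog.

    ``by`` is one of ``class``, ``who``, ``ema``, ``woah``, ``pvs`` (denominator:
    distinct active ingredients) or ``route`` (denominator: distinct
    ingredient-route pairs).  Percentages are count/total x 100, half-up to 2
    decimals.
    """
    if not catalog.ingredients and by != "route":
        raise CatalogLookupError("empty catalog")
    if by == "class":
        keys = [i.antibiotic_class for i in catalog.ingredients]
    elif by in SCHEMES:
        keys = [getattr(i, f"{by}_class") for i in catalog.ingredients]
    elif by == "route":
        pairs = catalog.ingredient_route_pairs()
        if not pairs:
            raise CatalogLookupError("catalog has no antibiotic products")
        keys = [route for _, route in pairs]
    else:
        raise ConfigurationError(f"unknown summary key {by!r}")
    counts = pd.Series(keys, dtype="object").value_counts().sort_index()
    total = int(counts.sum())
    df = pd.DataFrame({"count": counts})
    df["percent"] = [round_half_up(100.0 * c / total, 2) for c in counts]
    df.index.name = by
    return df


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------


def load_catalog(path) -> Catalog:
    """Load and validate a YAML catalog file."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if payload is None:
        payload = {}
    return Catalog.model_validate(payload)


def dump_catalog(catalog: Catalog, path) -> None:
    """Write a catalog back to YAML (stable key order)."""
    payload = catalog.model_dump(exclude_none=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


def catalog_json_schema() -> dict:
    """The published JSON schema catalog files validate against."""
    return Catalog.model_json_schema()


def reference_catalog() -> Catalog:
    """The packaged SPC catalog of the pilot pig farm.

    19 antibiotic active ingredients in 11 classes with their declared
    strengths, conversion factors, packages and the four importance
    classifications, plus the seven-disease vaccination programme's
    products.
    """
    from importlib import resources

    ref = resources.files("farmabu.data").joinpath("pig_farm_spc.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return Catalog.model_validate(yaml.safe_load(fh))
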