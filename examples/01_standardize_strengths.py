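"""Standardize declared label strengths to grams of active base per package.

Products declare strengths as salts (amoxicillin trihydrate), percentages,
g per 100 mL, or international units; a usage numerator needs one common
unit.  This walks a few catalog entries through the standardization calculus.
"""

from farmabu import parse_strength, reference_catalog, reported_grams

catalog = reference_catalog()

examples = [
    ("amoxicillin-feed", "1kg", "amoxicillin"),
    ("oxytetracycline-inj", "100ml", "oxytetracycline"),
    ("procaine-penicillin-inj", "100ml", "penicillin-g"),
    ("virginiamycin-feed", "10x40g", "virginiamycin"),
]

print("product                    package   ingredient        label                      g/package")
for pid, pkg, ing_name in examples:
    product = catalog.product(pid)
    entry = next(e for e in product.ingredients if e.ingredient == ing_name)
    ingredient = catalog.ingredient(ing_name)
    decl = parse_strength(entry.strength, ingredient)
    factor = entry.conversion_factor or (1.0 if decl.from_iu else ingredient.salt_conversion_factor)
    grams = reported_grams(decl, factor, product.package(pkg))
    print(f"{pid:<26} {pkg:<9} {ing_name:<17} {entry.strength:<26} {grams:>9}")

# The amoxicillin row shows the salt conversion at work: the 1 kg pack holds
# 980 g of trihydrate but only 980 x 0.8712 = 853.78 g of amoxicillin base.
# The penicillin row resolves 300 000 IU/mL to 180 mg/mL via 0.0006 mg/IU
# before scaling over the 100 mL vial (18 g of penicillin G).
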