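"""Small numeric and unit helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

#: Unicode script-ell variants seen on product labels.
_ELL_VARIANTS = {"ℓ": "l", "℔": "l"}


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round ``value`` half-up (commercial rounding) to ``ndigits`` decimals.

    Python's builtin ``round`` uses banker's rounding; reported figures here
    follow the half-up convention (e.g. 1707.552 -> 1707.55, 18.548 -> 18.55,
    20222.2575 -> 20222.26).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def normalise_label(text: str) -> str:
    """Lower-case a label, map script-ell to 'l', collapse spacing.

    Thousands separators written as spaces ("300 000 IU") and stray spaces
    around '/' ("22g /kg", "mg/ mℓ") are tolerated.
    """
    out = text.strip().lower()
    for ell, repl in _ELL_VARIANTS.items():
        out = out.replace(ell, repl)
    out = out.replace(" ", " ").replace(" ", " ")
    # join digit groups: "300 000" -> "300000"
    while True:
        joined = _join_digit_groups(out)
        if joined == out:
            break
        out = joined
    out = out.replace(" /", "/").replace("/ ", "/")
    return " ".join(out.split())


def _join_digit_groups(s: str) -> str:
    import re

    return re.sub(r"(\d) (\d)", r"\1\2", s)
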