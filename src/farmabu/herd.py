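"""Herd records, the animal-biomass denominator, and vaccine-eligible populations.

The weight-adjusted usage denominator follows the WOAH-style formula with
two deliberate modifications for a farm where the sow inventory is known:

    biomass(year, kg) = sum of monthly slaughter live weights
                        + average sow population x standard sow weight

No sow-proportion factor (0.09) is applied — the monthly sow counts are
actual, not anticipated — and the standard sow weight defaults to 220 kg
(heavier South African sows) rather than the 192 kg continental default.
Both the weight and which populations count as "sows" are configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .errors import ConfigurationError, RecordValidationError

POPULATIONS = (
    "dry_sows",
    "lactating_sows",
    "pregnant_sows",
    "boars",
    "piglets",
    "weaner_gilts",
    "slaughter_weaners",
)

DEFAULT_SOW_POPULATIONS = ("dry_sows", "lactating_sows", "pregnant_sows")


@dataclass(frozen=True)
class HerdRecord:
    """One month of livestock counts plus the slaughter live weight."""

    month: str  # "YYYY-MM"
    counts: dict  # population -> head count
    slaughter_live_weight_kg: float = 0.0

    @property
    def year(self) -> int:
        return int(self.month.split("-")[0])

    def count(self, population: str) -> float:
        if population not in POPULATIONS:
            raise ConfigurationError(f"unknown population {population!r}")
        return float(self.counts.get(population, 0.0))


class HerdConfig(BaseModel):
    """Denominator configuration (study defaults shown)."""

    sow_standard_weight_kg: float = Field(default=220.0, gt=0.0)
    sow_populations: tuple[str, ...] = DEFAULT_SOW_POPULATIONS


class EligiblePopulation(BaseModel):
    """One eligible population of a vaccination programme.

    ``multiplier`` is 2 when the schedule includes both a primary and a
    booster shot within the year, else 1.
    """

    population: str
    multiplier: int = Field(default=1, ge=1)

    @field_validator("population")
    @classmethod
    def _known_population(cls, v: str) -> str:
        if v not in POPULATIONS:
            raise ValueError(f"unknown population {v!r}; expected one of {POPULATIONS}")
        return v


class VaccinationProgramme(BaseModel):
    """Table-style encoding of one disease's programme."""

    disease: str
    eligible: list[EligiblePopulation]
    schedule: str = ""


def default_programmes() -> list[VaccinationProgramme]:
    """The pilot farm's vaccination programmes.

    Eligible populations mirror the farm schedule: piglet vaccines count the
    average piglet population; sow-administered vaccines use lactating sows
    (assumed vaccinated two weeks pre-farrow); gilts with a primary plus
    booster schedule are counted twice.
    """
    ep = EligiblePopulation
    return [
        VaccinationProgramme(
            disease="enzootic pneumonia",
            eligible=[ep(population="piglets")],
            schedule="7 days before weaning",
        ),
        VaccinationProgramme(
            disease="ileitis",
            eligible=[ep(population="piglets")],
            schedule="7 days before weaning",
        ),
        VaccinationProgramme(
            disease="erysipelas, PPV & leptospirosis",
            eligible=[
                ep(population="lactating_sows"),
                ep(population="weaner_gilts", multiplier=2),
                ep(population="boars"),
            ],
            schedule="gilts 23 & 26 weeks; sows 2 weeks pre-farrow; boars six-monthly",
        ),
        VaccinationProgramme(
            disease="neonatal pig diarrhoea",
            eligible=[
                ep(population="lactating_sows"),
                ep(population="weaner_gilts", multiplier=2),
            ],
            schedule="gilts 6 & 4 weeks pre-farrow; sows 2 weeks pre-farrow booster",
        ),
        VaccinationProgramme(
            disease="porcine circovirus disease",
            eligible=[ep(population="piglets"), ep(population="weaner_gilts")],
            schedule="piglets 7 days before weaning; gilts 2 weeks pre-farrow",
        ),
    ]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_herd(herd_path, slaughter_path=None) -> list[HerdRecord]:
    """Read herd.csv (month,population,count) and slaughter.csv (month,live_weight_kg)."""
    hdf = pd.read_csv(herd_path, dtype={"month": str, "population": str})
    for col in ("month", "population", "count"):
        if col not in hdf.columns:
            raise RecordValidationError(f"herd file lacks column {col!r}")
    bad = [p for p in hdf["population"].unique() if p not in POPULATIONS]
    if bad:
        raise RecordValidationError(f"unknown population(s) in herd file: {sorted(bad)}")
    if (hdf["count"].astype(float) < 0).any():
        raise RecordValidationError("negative head counts in herd file")
    slaughter: dict[str, float] = {}
    if slaughter_path is not None:
        sdf = pd.read_csv(slaughter_path, dtype={"month": str})
        for col in ("month", "live_weight_kg"):
            if col not in sdf.columns:
                raise RecordValidationError(f"slaughter file lacks column {col!r}")
        if (sdf["live_weight_kg"].astype(float) < 0).any():
            raise RecordValidationError("negative slaughter weights")
        slaughter = dict(zip(sdf["month"], sdf["live_weight_kg"].astype(float)))
    records = []
    for month, grp in hdf.groupby("month", sort=True):
        counts = dict(zip(grp["population"], grp["count"].astype(float)))
        records.append(
            HerdRecord(
                month=str(month),
                counts=counts,
                slaughter_live_weight_kg=slaughter.get(str(month), 0.0),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _year_records(records: Iterable[HerdRecord], year: int) -> list[HerdRecord]:
    recs = sorted((r for r in records if r.year == year), key=lambda r: r.month)
    if not recs:
        raise ConfigurationError(f"no herd records for year {year}")
    if len(recs) < 12:
        warnings.warn(
            f"year {year} has {len(recs)} monthly herd records; averaging over "
            "available months",
            stacklevel=3,
        )
    return recs


def average_population(
    records: Iterable[HerdRecord], populations: Sequence[str] | str, year: int
) -> float:
    """Yearly average head count of one or more populations (summed per month).

    Arithmetic mean over the months available in the year; years with fewer
    than 12 records average what exists and emit a completeness warning.
    """
    if isinstance(populations, str):
        populations = (populations,)
    recs = _year_records(records, year)
    monthly = [sum(r.count(p) for p in populations) for r in recs]
    return sum(monthly) / len(monthly)


def annual_biomass(
    records: Iterable[HerdRecord], config: Optional[HerdConfig] = None, year: int | None = None
) -> float:
    """Animal biomass denominator (kg) for a year.

    Total live weight slaughtered over the year plus the average sow
    population times the standard sow weight.
    """
    if year is None:
        raise ConfigurationError("annual_biomass requires a year")
    config = config or HerdConfig()
    recs = _year_records(records, year)
    slaughter = sum(r.slaughter_live_weight_kg for r in recs)
    if slaughter < 0:
        raise RecordValidationError("negative slaughter total")
    sows = average_population(recs, config.sow_populations, year)
    return slaughter + sows * config.sow_standard_weight_kg


def eligible_population(
    programme: VaccinationProgramme, records: Iterable[HerdRecord], year: int
) -> float:
    """Average head count eligible for a programme's vaccine in a year.

    Sum over the programme's eligible populations of the yearly average
    count times the booster multiplier.
    """
    total = 0.0
    for item in programme.eligible:
        if item.population not in POPULATIONS:
            raise ConfigurationError(
                f"programme {programme.disease!r} references unknown population "
                f"{item.population!r}"
            )
        total += average_population(records, item.population, year) * item.multiplier
    return total
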