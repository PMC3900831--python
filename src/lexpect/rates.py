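"""Age-specific mortality rates, the open-interval correction, and direct
age standardization.

Rates are deaths per person-year within 5-year bands.  The open 85+ rate
observed in a cohort with finite follow-up under-represents the oldest
ages, so it is replaced by the observed 85-89 rate scaled by the national
85+/85-89 rate ratio.  Age-adjusted rates are direct-standardized over the
band grid with the sex-specific whole-cohort person-years as the standard
population, which makes the cohort's own standardized rate equal its crude
rate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .bands import OPEN, AgeBandGrid, DEFAULT_GRID
from .io import ReferenceLifeTable
from .persontime import PersonTimeTable
from .sentinels import UNDEFINED, is_undefined

#: Rate provenance flags.
OBSERVED = "observed"
CORRECTED = "corrected"
UNDEFINED_FLAG = "undefined"


@dataclass(frozen=True)
class RateCell:
    m: float | None  # deaths per person-year; None when undefined
    deaths: int
    person_years: float
    flag: str = OBSERVED

    @property
    def defined(self) -> bool:
        return self.flag != UNDEFINED_FLAG


@dataclass
class RateTable:
    """Per-band mortality rates for one (sex, stratum), with the observed
    deaths and person-years retained for variance computation."""

    sex: str
    stratum: str
    cells: dict = field(default_factory=dict)  # band -> RateCell
    grid: AgeBandGrid = field(default_factory=lambda: DEFAULT_GRID)

    def cell(self, band) -> RateCell:
        return self.cells[band]

    def rate(self, band):
        c = self.cells[band]
        return UNDEFINED if not c.defined else c.m

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for band in self.grid.table_bands:
            c = self.cells[band]
            lo, _hi = self.grid.band_interval(band)
            rows.append({
                "sex": self.sex, "stratum": self.stratum,
                "band_start": "85+" if band == OPEN else f"{lo:g}",
                "m": c.m, "deaths": c.deaths,
                "person_years": c.person_years, "flag": c.flag,
            })
        return pd.DataFrame(rows)


def compute_rates(ptt: PersonTimeTable, sex: str, stratum: str) -> RateTable:
    """Band-specific rates m = deaths / person-years for one stratum.

    Bands with zero person-years are flagged undefined (zero deaths with
    positive person-time give a defined rate of 0).
    """
    rt = RateTable(sex=sex, stratum=stratum, grid=ptt.grid)
    for band in ptt.grid.table_bands:
        c = ptt.cell(sex, stratum, band)
        if c.person_years > 0:
            rt.cells[band] = RateCell(c.deaths / c.person_years, c.deaths,
                                      c.person_years, OBSERVED)
        else:
            rt.cells[band] = RateCell(None, c.deaths, c.person_years,
                                      UNDEFINED_FLAG)
    return rt


def correct_open_interval(rt: RateTable, ref: ReferenceLifeTable) -> RateTable:
    """Replace the open 85+ rate by MR(85-89) times the national
    85+/85-89 rate ratio.

    If the cohort's 85-89 rate is undefined or based on zero deaths the
    corrected rate -- and with it the stratum's life expectancy -- is
    undefined: this is the non-calculable sparse-stratum case.  The
    observed open-band deaths and person-years are retained for the
    life-expectancy variance.
    """
    tracking = rt.cells[rt.grid.tracking_start]
    open_cell = rt.cells[OPEN]
    out = RateTable(sex=rt.sex, stratum=rt.stratum, grid=rt.grid,
                    cells=dict(rt.cells))
    if not tracking.defined or tracking.deaths == 0:
        out.cells[OPEN] = replace(open_cell, m=None, flag=UNDEFINED_FLAG)
    else:
        corrected = tracking.m * ref.open_rate_ratio
        out.cells[OPEN] = replace(open_cell, m=corrected, flag=CORRECTED)
    return out


@dataclass(frozen=True)
class StandardPopulation:
    """Age weights (person-years of the standard) on the standardization
    grid: closed bands plus the open aggregate."""

    weights: dict  # band -> weight >= 0
    grid: AgeBandGrid = DEFAULT_GRID

    def __post_init__(self):
        total = sum(self.weights.get(b, 0.0)
                    for b in self.grid.standardization_bands)
        if total <= 0:
            raise ValueError("standard population needs a positive weight")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("negative standard weight")

    def normalized(self) -> dict:
        bands = self.grid.standardization_bands
        total = sum(self.weights.get(b, 0.0) for b in bands)
        return {b: self.weights.get(b, 0.0) / total for b in bands}


def cohort_standard(ptt: PersonTimeTable, sex: str) -> StandardPopulation:
    """Whole-cohort person-years by band for one sex (the standard used
    for the age-adjusted rates)."""
    weights: dict = {}
    for band in ptt.grid.standardization_bands:
        weights[band] = sum(
            ptt.cell(s, g, band).person_years
            for (s, g) in ptt.groups() if s == sex)
    return StandardPopulation(weights=weights, grid=ptt.grid)


def direct_standardize(rt: RateTable, std: StandardPopulation):
    """Directly age-standardized mortality rate per 1000 person-years.

    Any undefined band carrying positive standard weight makes the result
    undefined rather than silently reweighted.
    """
    w = std.normalized()
    total = 0.0
    for band, weight in w.items():
        if weight == 0.0:
            continue
        cell = rt.cells[band]
        if not cell.defined:
            return UNDEFINED
        total += weight * cell.m
    return 1000.0 * total


def crude_rate_per_1000(deaths: float, person_years: float) -> float:
    """Crude all-ages mortality rate per 1000 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    return 1000.0 * deaths / person_years
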