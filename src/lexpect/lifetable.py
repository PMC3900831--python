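"""Chiang abridged life tables and life-expectancy confidence intervals.

From band mortality rates m_i the conditional death probability in a
closed band of width n_i with fraction-of-last-interval a_i is

    q_i = n_i m_i / (1 + (1 - a_i) n_i m_i)

Survivors l_i start from the radix at the pivot age; d_i = l_i q_i die in
the band and live a_i n_i of it on average, so person-years lived are
L_i = n_i (l_i - d_i) + a_i n_i d_i.  The open terminal interval has
q = 1 and L = l / m.  Life expectancy at any band start is
e_i = T_i / l_i with T_i the person-years lived at and above the band.

Sampling variance follows Chiang's formulation: each q_i is estimated
from D_i deaths, Var(q_i) = q_i^2 (1 - q_i) / D_i, and

    Var(e_pivot) = [ sum_i l_i^2 ((1-a_i) n_i + e_{i+1})^2 Var(q_i)
                     + l_open^2 e_open^2 / D_open ] / l_pivot^2

where the terminal term treats open-interval deaths as Poisson.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .bands import OPEN
from .io import ReferenceLifeTable
from .rates import RateTable
from .sentinels import UNDEFINED, is_undefined


@dataclass(frozen=True)
class AnalysisConfig:
    """Life-table settings: pivot ages, radix and CI level."""

    pivot_ages: tuple[float, ...] = (40.0, 60.0)
    radix: float = 100_000.0
    confidence_level: float = 0.95
    z: float = 1.959964  # normal quantile matching confidence_level

    def __post_init__(self):
        if self.z <= 0:
            raise ValueError("z must be positive")


@dataclass
class LifeTableRow:
    band: object  # band-start float, or "85+" for the open interval
    m: float
    a: float
    n: float  # band width; inf for the open interval
    q: float
    l: float
    d: float
    L: float
    T: float = 0.0
    e: float = 0.0
    var_q: float = 0.0


@dataclass
class LifeTable:
    """Abridged life table from a pivot age, or an undefined sentinel
    when the stratum's rates cannot support one."""

    sex: str
    stratum: str
    pivot: float
    rows: list[LifeTableRow] = field(default_factory=list)
    e: object = UNDEFINED  # life expectancy at the pivot
    var_e: object = UNDEFINED
    ci: object = UNDEFINED  # (lower, upper)
    undefined: bool = False
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return not self.undefined

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rows:
            rows.append({
                "band_start": "85+" if r.band == OPEN else f"{r.band:g}",
                "m": r.m, "a": r.a, "q": r.q, "l": r.l, "d": r.d,
                "L": r.L, "T": r.T, "e": r.e, "var_q": r.var_q,
            })
        return pd.DataFrame(rows)


def _undefined_table(sex, stratum, pivot, reason) -> LifeTable:
    return LifeTable(sex=sex, stratum=stratum, pivot=pivot,
                     undefined=True, reason=reason)


def build_life_table(rt: RateTable, ref: ReferenceLifeTable,
                     cfg: AnalysisConfig, pivot: float) -> LifeTable:
    """Build the abridged life table for one stratum from a corrected
    rate table, starting at *pivot* with the configured radix.

    The open-interval rate must be defined (corrected) and positive;
    otherwise the whole table is the undefined sentinel, mirroring the
    non-calculable sparse-stratum case.
    """
    grid = rt.grid
    bands = grid.lifetable_bands(pivot)

    open_cell = rt.cells[OPEN]
    if not open_cell.defined:
        return _undefined_table(rt.sex, rt.stratum, pivot,
                                "open-interval rate undefined "
                                "(no deaths at ages 85-89)")
    if open_cell.m <= 0:
        return _undefined_table(rt.sex, rt.stratum, pivot,
                                "open-interval rate is zero")
    for band in bands[:-1]:
        if not rt.cells[band].defined:
            return _undefined_table(
                rt.sex, rt.stratum, pivot,
                f"rate undefined in band starting {band:g} "
                "(no person-years)")

    lt = LifeTable(sex=rt.sex, stratum=rt.stratum, pivot=pivot)
    l = cfg.radix
    for band in bands[:-1]:
        m = rt.cells[band].m
        a = ref.a(band)
        n = grid.width
        q = min(n * m / (1.0 + (1.0 - a) * n * m), 1.0)
        d = l * q
        L = n * (l - d) + a * n * d
        lt.rows.append(LifeTableRow(band=band, m=m, a=a, n=n, q=q,
                                    l=l, d=d, L=L))
        l -= d
    m_open = open_cell.m
    lt.rows.append(LifeTableRow(band=OPEN, m=m_open, a=1.0,
                                n=math.inf, q=1.0, l=l, d=l,
                                L=l / m_open))
    T = 0.0
    for r in reversed(lt.rows):
        T += r.L
        r.T = T
        r.e = T / r.l if r.l > 0 else 0.0
    lt.e = lt.rows[0].e
    return lt


def chiang_variance(lt: LifeTable, rt: RateTable,
                    cfg: AnalysisConfig) -> tuple:
    """Sampling variance of the pivot life expectancy and its CI.

    Closed bands with zero observed deaths contribute zero variance (their
    q is 0 or estimated without sampling error at this approximation),
    which keeps CIs computable for sparse-but-nonempty strata.  Zero
    observed deaths in the open interval leave the variance undefined.
    The result is also stored on *lt*.
    """
    if lt.undefined:
        return UNDEFINED, UNDEFINED
    open_cell = rt.cells[OPEN]
    if open_cell.deaths == 0:
        lt.var_e, lt.ci = UNDEFINED, UNDEFINED
        return UNDEFINED, UNDEFINED

    total = 0.0
    for i, r in enumerate(lt.rows[:-1]):
        D = rt.cells[r.band].deaths
        var_q = (r.q ** 2) * (1.0 - r.q) / D if D > 0 else 0.0
        r.var_q = var_q
        e_next = lt.rows[i + 1].e
        total += (r.l ** 2) * ((1.0 - r.a) * r.n + e_next) ** 2 * var_q
    open_row = lt.rows[-1]
    total += (open_row.l ** 2) * (open_row.e ** 2) / open_cell.deaths
    var_e = total / (lt.rows[0].l ** 2)
    half = cfg.z * math.sqrt(var_e)
    lt.var_e = var_e
    lt.ci = (lt.e - half, lt.e + half)
    return var_e, lt.ci


def life_expectancy_difference(lt_a: LifeTable, lt_b: LifeTable):
    """Difference e(a) - e(b) at the tables' pivot age; undefined when
    either side is."""
    if lt_a.undefined or lt_b.undefined:
        return UNDEFINED
    if lt_a.pivot != lt_b.pivot:
        raise ValueError("life tables have different pivot ages")
    return lt_a.e - lt_b.e


def expectancy_gap(e_a, e_b, decimals: int = 1):
    """Difference of two (possibly reported, pre-rounded) life
    expectancies, rounded for display; undefined when either side is."""
    if is_undefined(e_a) or is_undefined(e_b):
        return UNDEFINED
    return round(float(e_a) - float(e_b), decimals)
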