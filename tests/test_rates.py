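"""Rates, the 85+ open-interval correction, and direct standardization."""

import numpy as np
import pytest

from lexpect.bands import OPEN, DEFAULT_GRID
from lexpect.io import ReferenceLifeTable
from lexpect.persontime import PersonTimeTable, tabulate_arrays
from lexpect.rates import (CORRECTED, OBSERVED, UNDEFINED_FLAG, RateCell,
                           StandardPopulation, cohort_standard,
                           compute_rates, correct_open_interval,
                           crude_rate_per_1000, direct_standardize)
from lexpect.sentinels import is_undefined


def make_ptt(cells):
    """cells: {(sex, stratum, band): (py, deaths)}"""
    ptt = PersonTimeTable()
    for key, (py, d) in cells.items():
        c = ptt._mutable_cell(*key)
        c.person_years, c.deaths = py, d
    return ptt


def full_ptt(py=1000.0, deaths=10, sex="male", stratum="all"):
    return make_ptt({(sex, stratum, b): (py, deaths)
                     for b in DEFAULT_GRID.table_bands})


def test_compute_rates_basic():
    rt = compute_rates(full_ptt(py=1000.0, deaths=10), "male", "all")
    assert rt.cells[40.0].m == pytest.approx(0.010)
    assert rt.cells[40.0].flag == OBSERVED


def test_zero_deaths_is_defined_zero_rate():
    rt = compute_rates(full_ptt(py=500.0, deaths=0), "male", "all")
    assert rt.cells[60.0].m == 0.0
    assert rt.cells[60.0].defined


def test_zero_person_years_is_undefined():
    ptt = full_ptt()
    ptt._mutable_cell("male", "all", 70.0).person_years = 0.0
    rt = compute_rates(ptt, "male", "all")
    assert rt.cells[70.0].flag == UNDEFINED_FLAG
    assert is_undefined(rt.rate(70.0))


def reference(jmr_85_89, jmr_open):
    bands = DEFAULT_GRID.closed_starts + (85.0,)
    return ReferenceLifeTable(
        a_fraction={b: 0.5 for b in bands},
        national_rate={**{b: 0.01 for b in bands},
                       85.0: jmr_85_89, OPEN: jmr_open})


def test_open_interval_correction_arithmetic():
    ptt = full_ptt()
    ptt._mutable_cell("male", "all", 85.0).person_years = 100.0
    ptt._mutable_cell("male", "all", 85.0).deaths = 10  # MR = 0.10
    rt = compute_rates(ptt, "male", "all")
    out = correct_open_interval(rt, reference(0.140, 0.182))
    assert out.cells[OPEN].m == pytest.approx(0.13)
    assert out.cells[OPEN].flag == CORRECTED
    # other bands untouched
    assert out.cells[40.0] == rt.cells[40.0]


def test_identity_ratio_leaves_rate_equal_to_85_89():
    rt = compute_rates(full_ptt(), "male", "all")
    out = correct_open_interval(rt, reference(0.05, 0.05))
    assert out.cells[OPEN].m == pytest.approx(rt.cells[85.0].m)


def test_zero_deaths_at_85_89_makes_open_undefined():
    ptt = full_ptt()
    ptt._mutable_cell("male", "all", 85.0).deaths = 0
    rt = compute_rates(ptt, "male", "all")
    out = correct_open_interval(rt, reference(0.140, 0.182))
    assert out.cells[OPEN].flag == UNDEFINED_FLAG
    # observed exposure retained for variance bookkeeping
    assert out.cells[OPEN].person_years == rt.cells[OPEN].person_years


def test_self_standard_identity():
    """Standardizing a stratum's rates by its own person-years returns
    its crude rate exactly."""
    rng = np.random.default_rng(5)
    n = 2000
    entry = rng.uniform(40, 79, n)
    exit_ = entry + rng.uniform(0.2, 14.5, n)
    died = rng.random(n) < 0.25
    ptt = tabulate_arrays(entry, exit_, died,
                          np.full(n, "male", dtype=object),
                          np.full(n, "all", dtype=object))
    rt = compute_rates(ptt, "male", "all")
    std = cohort_standard(ptt, "male")
    adj = direct_standardize(rt, std)
    crude = crude_rate_per_1000(ptt.total_deaths("male", "all"),
                                ptt.total_person_years("male", "all"))
    assert adj == pytest.approx(crude, rel=1e-12)


def test_identical_rates_give_identical_standardized_rates(rng):
    """Strata sharing age-specific rates standardize identically under
    any weights (brute force over random weight vectors)."""
    bands = DEFAULT_GRID.standardization_bands
    rt_cells = {b: RateCell(m=0.001 * (i + 1), deaths=5, person_years=100.0)
                for i, b in enumerate(bands)}
    rt_cells[85.0] = RateCell(m=0.05, deaths=5, person_years=100.0)
    from lexpect.rates import RateTable
    rt_a = RateTable("male", "a", dict(rt_cells))
    rt_b = RateTable("male", "b", dict(rt_cells))
    for _ in range(20):
        w = {b: float(x) for b, x in zip(bands, rng.uniform(0.1, 5, 10))}
        std = StandardPopulation(weights=w)
        assert direct_standardize(rt_a, std) == pytest.approx(
            direct_standardize(rt_b, std))


def test_monotonicity_and_scale():
    bands = DEFAULT_GRID.standardization_bands
    from lexpect.rates import RateTable
    cells = {b: RateCell(m=0.01, deaths=10, person_years=1000.0)
             for b in DEFAULT_GRID.table_bands}
    rt = RateTable("male", "x", cells)
    std = StandardPopulation(weights={b: 1.0 for b in bands})
    base = direct_standardize(rt, std)
    bumped_cells = dict(cells)
    bumped_cells[60.0] = RateCell(m=0.02, deaths=20, person_years=1000.0)
    bumped = direct_standardize(RateTable("male", "x", bumped_cells), std)
    assert bumped > base
    doubled_cells = {b: RateCell(m=c.m * 2, deaths=c.deaths * 2,
                                 person_years=c.person_years)
                     for b, c in cells.items()}
    doubled = direct_standardize(RateTable("male", "x", doubled_cells), std)
    assert doubled == pytest.approx(2 * base)


def test_undefined_band_with_positive_weight_propagates():
    from lexpect.rates import RateTable
    cells = {b: RateCell(m=0.01, deaths=10, person_years=1000.0)
             for b in DEFAULT_GRID.table_bands}
    cells[50.0] = RateCell(m=None, deaths=0, person_years=0.0,
                           flag=UNDEFINED_FLAG)
    rt = RateTable("male", "x", cells)
    std = StandardPopulation(
        weights={b: 1.0 for b in DEFAULT_GRID.standardization_bands})
    assert is_undefined(direct_standardize(rt, std))
    # ...but not when the undefined band carries zero weight
    w = {b: 1.0 for b in DEFAULT_GRID.standardization_bands}
    w[50.0] = 0.0
    assert not is_undefined(direct_standardize(
        rt, StandardPopulation(weights=w)))


def test_all_zero_weights_rejected():
    with pytest.raises(ValueError):
        StandardPopulation(weights={})
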