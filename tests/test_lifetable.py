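"""Chiang life-table construction, closed forms and variance formulas."""

import math

import numpy as np
import pytest

from lexpect.bands import OPEN, DEFAULT_GRID
from lexpect.io import ReferenceLifeTable
from lexpect.lifetable import (AnalysisConfig, build_life_table,
                               chiang_variance, expectancy_gap,
                               life_expectancy_difference)
from lexpect.rates import CORRECTED, OBSERVED, RateCell, RateTable
from lexpect.sentinels import UNDEFINED, is_undefined

from conftest import make_rate_table


def test_zero_mortality_closed_bands(grid, lt_cfg, flat_reference):
    """Nine empty 5-year bands then 1/m in the open interval: e40 = 55."""
    rt = make_rate_table(grid, m_closed=0.0, m_open=0.1)
    lt = build_life_table(rt, flat_reference, lt_cfg, 40.0)
    assert lt.e == pytest.approx(45.0 + 10.0, abs=1e-12)


@pytest.mark.parametrize("m", [0.005, 0.01, 0.02, 0.05])
def test_constant_hazard_closed_form(grid, lt_cfg, flat_reference, m):
    """With constant m in every band (open included) and a = 0.5, the
    abridged table telescopes to e = 1/m exactly."""
    rt = make_rate_table(grid, m_closed=m, m_open=m)
    lt = build_life_table(rt, flat_reference, lt_cfg, 40.0)
    assert abs(lt.e - 1.0 / m) < 1e-9


def _fine_grained_e(rate_fn, pivot=40.0, top=110.0):
    """Independent oracle: 1-year-band life table with a = 0.5 from a
    continuous hazard, terminal open interval at *top*."""
    l, T = 1.0, 0.0
    Ls = []
    ages = np.arange(pivot, top, 1.0)
    for x in ages:
        t = np.linspace(x, x + 1.0, 101)
        m = np.trapezoid(rate_fn(t), t)
        q = m / (1.0 + 0.5 * m)
        d = l * q
        Ls.append(l - d + 0.5 * d)
        l -= d
    m_open = rate_fn(top + 5.0)
    Ls.append(l / m_open)
    return sum(Ls)


def test_agreement_with_fine_grained_gompertz_table(grid, lt_cfg):
    """Abridged 5-year table within 0.2 years of a 1-year table built
    from the same Gompertz hazard."""
    b, theta = 2e-5, 0.095

    def rate(t):
        return b * np.exp(theta * np.asarray(t))

    closed = {}
    for x in grid.closed_starts + (grid.tracking_start,):
        t = np.linspace(x, x + 5.0, 501)
        closed[x] = float(np.trapezoid(rate(t), t) / 5.0)
    # open interval: stationary-population rate over [85, inf)
    t = np.linspace(85.0, 130.0, 4501)
    surv = np.exp(-np.concatenate(
        [[0.0], np.cumsum(np.diff(t) * rate(t[:-1]))]))
    m_open = float(np.trapezoid(surv * rate(t), t) / np.trapezoid(surv, t))
    rt = make_rate_table(grid, m_closed=closed, m_open=m_open)
    ref = ReferenceLifeTable(
        a_fraction={x: 0.5 for x in closed},
        national_rate={**closed, OPEN: m_open})
    for pivot in (40.0, 60.0):
        lt = build_life_table(rt, ref, AnalysisConfig(), pivot)
        fine = _fine_grained_e(rate, pivot=pivot, top=110.0)
        assert lt.e == pytest.approx(fine, abs=0.2)


def test_structural_monotonicity(grid, lt_cfg, flat_reference):
    """With rising positive rates, survivors decrease strictly and e
    decreases across pivot ages."""
    ms = {b: 0.002 * 1.6 ** i
          for i, b in enumerate(grid.closed_starts + (grid.tracking_start,))}
    rt = make_rate_table(grid, m_closed=ms, m_open=0.2)
    es = []
    for pivot in (40.0, 60.0):
        lt = build_life_table(rt, flat_reference, lt_cfg, pivot)
        ls = [r.l for r in lt.rows]
        assert all(a > b for a, b in zip(ls, ls[1:]))
        es.append(lt.e)
    assert es[0] > es[1]


def test_dominance(grid, lt_cfg, flat_reference):
    """Lower rates everywhere (strictly somewhere) give longer life."""
    ms = {b: 0.002 * 1.5 ** i
          for i, b in enumerate(grid.closed_starts + (grid.tracking_start,))}
    rt_b = make_rate_table(grid, m_closed=ms, m_open=0.2)
    ms_a = dict(ms)
    ms_a[60.0] *= 0.5
    rt_a = make_rate_table(grid, m_closed=ms_a, m_open=0.2)
    e_a = build_life_table(rt_a, flat_reference, lt_cfg, 40.0).e
    e_b = build_life_table(rt_b, flat_reference, lt_cfg, 40.0).e
    assert e_a > e_b


def test_hand_computed_variance_fixture(grid, flat_reference):
    """Single closed band [80,85) + open interval, all quantities checked
    against a retained hand calculation.

    m=0.1, a=0.5, D=50 in the closed band; m=0.2, D=100 in the open:
    q = 0.5/1.25 = 0.4; l=1e5, d=4e4, L=4e5; L_open=3e5; T=7e5, e=7.0;
    e_open=5.0; Var(q)=0.16*0.6/50=0.00192;
    closed term = 1e10*(2.5+5)^2*0.00192 = 1.08e9;
    open term = 3.6e9*25/100 = 9e8; Var(e) = 1.98e9/1e10 = 0.198.
    """
    rt = make_rate_table(grid, m_closed=0.1, m_open=0.2, deaths=50,
                         open_deaths=100)
    cfg = AnalysisConfig()
    lt = build_life_table(rt, flat_reference, cfg, 80.0)
    assert lt.e == pytest.approx(7.0, abs=1e-12)
    assert lt.rows[0].q == pytest.approx(0.4, abs=1e-12)
    assert lt.rows[-1].e == pytest.approx(5.0, abs=1e-12)
    var, ci = chiang_variance(lt, rt, cfg)
    assert var == pytest.approx(0.198, abs=1e-12)
    half = cfg.z * math.sqrt(0.198)
    assert ci == pytest.approx((7.0 - half, 7.0 + half), abs=1e-9)


def test_zero_deaths_closed_bands_give_zero_variance(grid, lt_cfg,
                                                     flat_reference):
    rt = make_rate_table(grid, m_closed=0.01, m_open=0.1, deaths=0,
                         open_deaths=1000)
    lt = build_life_table(rt, flat_reference, lt_cfg, 40.0)
    var, ci = chiang_variance(lt, rt, lt_cfg)
    # only the open interval contributes
    open_row = lt.rows[-1]
    expected = (open_row.l ** 2) * (open_row.e ** 2) / 1000 / (1e5 ** 2)
    assert var == pytest.approx(expected, rel=1e-12)
    assert all(r.var_q == 0.0 for r in lt.rows[:-1])


def test_ci_width_scales_inverse_sqrt_k(grid, lt_cfg, flat_reference):
    def width(k):
        rt = make_rate_table(grid, m_closed=0.01, m_open=0.1,
                             deaths=int(100 * k), py=10_000.0 * k,
                             open_deaths=int(200 * k), open_py=2000.0 * k)
        lt = build_life_table(rt, flat_reference, lt_cfg, 40.0)
        _, ci = chiang_variance(lt, rt, lt_cfg)
        return ci[1] - ci[0]

    assert width(1) / width(4) == pytest.approx(2.0, rel=1e-9)


def test_zero_open_deaths_leaves_ci_undefined(grid, lt_cfg, flat_reference):
    rt = make_rate_table(grid, m_closed=0.01, m_open=0.1, open_deaths=0)
    lt = build_life_table(rt, flat_reference, lt_cfg, 40.0)
    var, ci = chiang_variance(lt, rt, lt_cfg)
    assert is_undefined(var) and is_undefined(ci)
    assert not is_undefined(lt.e)


def test_undefined_open_rate_gives_undefined_table(grid, lt_cfg,
                                                   flat_reference):
    from lexpect.rates import UNDEFINED_FLAG
    rt = make_rate_table(grid, m_closed=0.01, m_open=0.1)
    rt.cells[OPEN] = RateCell(m=None, deaths=0, person_years=100.0,
                              flag=UNDEFINED_FLAG)
    lt = build_life_table(rt, flat_reference, lt_cfg, 40.0)
    assert lt.undefined
    assert is_undefined(lt.e)
    rt.cells[OPEN] = RateCell(m=0.0, deaths=0, person_years=100.0,
                              flag=CORRECTED)
    lt = build_life_table(rt, flat_reference, lt_cfg, 40.0)
    assert lt.undefined


def test_life_expectancy_difference(grid, lt_cfg, flat_reference):
    rt_a = make_rate_table(grid, m_closed=0.01, m_open=0.1)
    rt_b = make_rate_table(grid, m_closed=0.02, m_open=0.15)
    lt_a = build_life_table(rt_a, flat_reference, lt_cfg, 40.0)
    lt_b = build_life_table(rt_b, flat_reference, lt_cfg, 40.0)
    assert life_expectancy_difference(lt_a, lt_a) == 0.0
    assert life_expectancy_difference(lt_a, lt_b) == pytest.approx(
        lt_a.e - lt_b.e)
    undef = build_life_table(
        make_rate_table(grid, m_closed=0.01, m_open=0.0),
        flat_reference, lt_cfg, 40.0)
    assert is_undefined(life_expectancy_difference(lt_a, undef))


def test_expectancy_gap_on_reported_values():
    assert expectancy_gap(50.2, 39.9) == 10.3
    assert is_undefined(expectancy_gap(50.2, UNDEFINED))
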