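import numpy as np
import pytest

from lexpect.bands import DEFAULT_GRID, OPEN
from lexpect.io import ReferenceLifeTable
from lexpect.lifetable import AnalysisConfig
from lexpect.rates import OBSERVED, CORRECTED, RateCell, RateTable


@pytest.fixture
def grid():
    return DEFAULT_GRID


@pytest.fixture
def lt_cfg():
    return AnalysisConfig()


@pytest.fixture
def flat_reference(grid):
    """Reference table with a = 0.5 everywhere and identical national
    rates at 85-89 and 85+ (open-interval correction is the identity)."""
    bands = grid.closed_starts + (grid.tracking_start,)
    return ReferenceLifeTable(
        a_fraction={b: 0.5 for b in bands},
        national_rate={**{b: 0.05 for b in bands}, OPEN: 0.05},
        grid=grid,
    )


def make_rate_table(grid, m_closed, m_open, deaths=100, py=1000.0,
                    open_deaths=100, open_py=1000.0, sex="male",
                    stratum="all"):
    """RateTable with constant closed-band rate(s) and a corrected open
    rate -- ready for build_life_table."""
    cells = {}
    closed = grid.closed_starts + (grid.tracking_start,)
    ms = (m_closed if isinstance(m_closed, dict)
          else {b: m_closed for b in closed})
    for b in closed:
        cells[b] = RateCell(m=ms[b], deaths=deaths, person_years=py,
                            flag=OBSERVED)
    cells[OPEN] = RateCell(m=m_open, deaths=open_deaths,
                           person_years=open_py, flag=CORRECTED)
    return RateTable(sex=sex, stratum=stratum, cells=cells, grid=grid)


@pytest.fixture
def rate_table_factory(grid):
    def factory(**kw):
        return make_rate_table(grid, **kw)
    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
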