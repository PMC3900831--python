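"""Five-year age-band grid used throughout the analysis.

Mortality tabulation starts at age 40 and runs in half-open 5-year bands
[40,45), [45,50), ..., [80,85).  The terminal category is the open interval
[85, inf).  Because the open-interval rate is corrected against a national
reference via the 85-89 rate ratio, the grid also tracks the [85,90)
sub-band alongside the open aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Label of the open-ended terminal band [85, inf).
OPEN = "85+"


@dataclass(frozen=True)
class AgeBandGrid:
    """Half-open 5-year bands covering [start, inf).

    Parameters
    ----------
    start : float
        First band start (age at which mortality calculation begins).
    open_start : float
        Start of the open terminal interval.  The sub-band
        [open_start, open_start + width) is tracked separately so the
        open-interval correction can use its observed rate.
    width : float
        Width of each closed band, in years.
    """

    start: float = 40.0
    open_start: float = 85.0
    width: float = 5.0

    def __post_init__(self):
        n = (self.open_start - self.start) / self.width
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("open_start must sit on the band grid above start")

    @property
    def closed_starts(self) -> tuple[float, ...]:
        """Starts of the closed bands [x, x+width) below the open interval."""
        n = int(round((self.open_start - self.start) / self.width))
        return tuple(self.start + i * self.width for i in range(n))

    @property
    def tracking_start(self) -> float:
        """Start of the tracked sub-band [open_start, open_start+width)."""
        return self.open_start

    @property
    def table_bands(self) -> tuple:
        """All band labels in order: closed, tracking sub-band, open aggregate."""
        return self.closed_starts + (self.tracking_start, OPEN)

    @property
    def standardization_bands(self) -> tuple:
        """Bands over which rates are standardized: closed bands plus the
        open aggregate (the tracking sub-band is excluded; its person-time
        is already inside the aggregate)."""
        return self.closed_starts + (OPEN,)

    def lifetable_bands(self, pivot: float) -> tuple:
        """Band labels for a life table starting at *pivot*."""
        if pivot not in self.closed_starts:
            raise ValueError(f"pivot {pivot} is not a closed band start")
        return tuple(b for b in self.closed_starts if b >= pivot) + (OPEN,)

    def band_of_death(self, age: float):
        """Band label a death at exact age *age* is attributed to.

        Bands are half-open, so a death exactly at a boundary belongs to the
        band starting there.  Deaths at or above open_start+width fall only
        in the open aggregate; deaths in the tracking sub-band are reported
        under its label (they count toward the aggregate as well when
        tabulated).
        """
        if age < self.start:
            raise ValueError("death before grid start")
        if age >= self.open_start + self.width:
            return OPEN
        if age >= self.open_start:
            return self.tracking_start
        idx = int((age - self.start) // self.width)
        return self.closed_starts[idx]

    def band_interval(self, band) -> tuple[float, float]:
        """(start, end) of a band; end is ``inf`` for the open aggregate."""
        if band == OPEN:
            return (self.open_start, float("inf"))
        return (float(band), float(band) + self.width)


#: Default grid of the analysis (40 to 85+, 5-year bands).
DEFAULT_GRID = AgeBandGrid()
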