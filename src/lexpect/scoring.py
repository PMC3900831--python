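"""Dichotomization of six lifestyle factors and the healthy-behavior score.

The six factors and their "healthy" definitions are:

* smoking    -- current nonsmoker (never or former smoker)
* alcohol    -- current nondrinker (never or former), or drinking no more
                than 23 g of ethanol (one *gou* of sake) per occasion
* walking    -- walking at least 1 hour per day
* sleep      -- sleeping 6.5 to 7.4 hours per day
* greens     -- eating green leafy vegetables almost daily
* bmi        -- body-mass index between 18.5 and 24.9 kg/m2

The healthy-behavior score is the count of criteria met (0-6).  Analyses
stratified by smoking status use the score over the five non-smoking
factors (0-5).  Sleep and BMI bounds are treated as closed intervals
compared at one-decimal precision, matching how the thresholds are stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

ALCOHOL_MAX_G = 23.0  # one gou of sake, in grams of ethanol
WALKING_MIN_H = 1.0
SLEEP_RANGE_H = (6.5, 7.4)
BMI_RANGE = (18.5, 24.9)

_EPS = 1e-9

Sex = Literal["male", "female"]
Status = Literal["current", "former", "never"]

#: Canonical order of the six behaviors.
BEHAVIORS = ("smoking", "alcohol", "walking", "sleep", "greens", "bmi")

#: Stratum labels for the full six-behavior score.
FULL_GROUPS = ("0-2", "3", "4", "5", "6")
#: Stratum labels for the five-behavior score (smoking excluded).
OTHER_GROUPS = ("0-1", "2", "3", "4", "5")


@dataclass(frozen=True)
class LifestyleAssessment:
    """Raw baseline lifestyle measurements for one subject.

    ``alcohol_g_per_occasion`` is meaningful when ``drinker_status`` is
    ``current``; for never/former drinkers it may be 0.
    """

    smoking_status: Status
    drinker_status: Status
    alcohol_g_per_occasion: float
    walking_h_per_day: float
    sleep_h_per_day: float
    greens_daily: bool
    bmi: float

    def __post_init__(self):
        if self.smoking_status not in ("current", "former", "never"):
            raise ValueError(f"bad smoking_status {self.smoking_status!r}")
        if self.drinker_status not in ("current", "former", "never"):
            raise ValueError(f"bad drinker_status {self.drinker_status!r}")
        for name in ("alcohol_g_per_occasion", "walking_h_per_day",
                     "sleep_h_per_day", "bmi"):
            v = getattr(self, name)
            if v is None or not (v == v):  # None or NaN
                raise ValueError(f"missing lifestyle field {name}")


@dataclass(frozen=True)
class BehaviorProfile:
    """Six healthy/unhealthy flags for one subject."""

    healthy_smoking: bool
    healthy_alcohol: bool
    healthy_walking: bool
    healthy_sleep: bool
    healthy_greens: bool
    healthy_bmi: bool

    @property
    def flags(self) -> tuple[bool, ...]:
        return (self.healthy_smoking, self.healthy_alcohol,
                self.healthy_walking, self.healthy_sleep,
                self.healthy_greens, self.healthy_bmi)

    @property
    def score(self) -> int:
        """Number of healthy behaviors (0-6)."""
        return sum(self.flags)

    @property
    def score_other_than_smoking(self) -> int:
        """Number of healthy behaviors among the five non-smoking factors."""
        return sum(self.flags[1:])


def _round1(x: float) -> float:
    return round(float(x), 1)


def dichotomize(a: LifestyleAssessment) -> BehaviorProfile:
    """Map a raw assessment to the six healthy/unhealthy flags.

    Former smokers and former drinkers count as healthy.  Interval bounds
    for sleep and BMI are closed and compared at one-decimal precision.
    """
    healthy_smoking = a.smoking_status in ("former", "never")
    healthy_alcohol = (
        a.drinker_status in ("former", "never")
        or (a.drinker_status == "current"
            and a.alcohol_g_per_occasion <= ALCOHOL_MAX_G + _EPS)
    )
    healthy_walking = a.walking_h_per_day >= WALKING_MIN_H - _EPS
    sleep = _round1(a.sleep_h_per_day)
    healthy_sleep = (SLEEP_RANGE_H[0] - _EPS <= sleep <= SLEEP_RANGE_H[1] + _EPS)
    bmi = _round1(a.bmi)
    healthy_bmi = (BMI_RANGE[0] - _EPS <= bmi <= BMI_RANGE[1] + _EPS)
    return BehaviorProfile(
        healthy_smoking=healthy_smoking,
        healthy_alcohol=healthy_alcohol,
        healthy_walking=healthy_walking,
        healthy_sleep=healthy_sleep,
        healthy_greens=bool(a.greens_daily),
        healthy_bmi=healthy_bmi,
    )


def assign_group(score: int, scheme: str = "full") -> str:
    """Map a behavior score to its analysis stratum label.

    ``full`` groups the 0-6 score as {0,1,2} -> "0-2", then "3".."6".
    ``other_than_smoking`` groups the 0-5 score over the five non-smoking
    factors as {0,1} -> "0-1", then "2".."5".
    """
    if scheme == "full":
        if not 0 <= score <= 6:
            raise ValueError(f"score {score} out of range for full scheme")
        return "0-2" if score <= 2 else str(score)
    if scheme == "other_than_smoking":
        if not 0 <= score <= 5:
            raise ValueError(
                f"score {score} out of range for other_than_smoking scheme")
        return "0-1" if score <= 1 else str(score)
    raise ValueError(f"unknown scheme {scheme!r}")


def group_labels(scheme: str) -> tuple[str, ...]:
    """Ordered stratum labels for a scheme."""
    if scheme == "full":
        return FULL_GROUPS
    if scheme == "other_than_smoking":
        return OTHER_GROUPS
    raise ValueError(f"unknown scheme {scheme!r}")
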