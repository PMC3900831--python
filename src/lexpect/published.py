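"""Published summary tables from the source cohort study.

The package reimplements the life-expectancy analysis of a nationwide
Japanese cohort (enrolled 1988-1990, ages 40-79, followed to 2006) whose
individual-level records are not publicly deposited.  Its published
summary tables -- person-years, deaths and age-adjusted mortality per
behavior stratum, and life expectancies at ages 40 and 60 with 95% CIs --
are reproduced here as plain data.  They serve as inputs for arithmetic
identities (crude rates, life-expectancy gaps) and as the layout template
for report generation.

Keys: sex -> scheme ("full", "smoker", "nonsmoker") -> stratum label.
The non-calculable cells of the sparsest stratum (smoking women with 5
other healthy behaviors) are ``None``.
"""

from __future__ import annotations

#: Stratum rows of the age-adjusted mortality table:
#: (number of subjects, person-years, deaths, age-adjusted rate per 1000).
MORTALITY_TABLE = {
    "male": {
        "full": {
            "0-2": (5092, 141_967, 2478, 20.7),
            "3": (9147, 125_658, 2133, 16.9),
            "4": (8969, 85_414, 1464, 14.9),
            "5": (3694, 31_931, 494, 12.6),
            "6": (680, 5587, 64, 8.9),
            "overall": (27_582, 390_504, 6633, 17.0),
        },
        "smoker": {
            "0-1": (2908, 40_953, 706, 22.9),
            "2": (4980, 70_007, 1309, 22.2),
            "3": (4711, 67_370, 1179, 18.6),
            "4": (1763, 25_546, 443, 18.1),
            "5": (301, 4315, 80, 18.7),
            "overall": (14_663, 208_184, 3717, 20.4),
        },
        "nonsmoker": {
            "0-1": (2184, 31_012, 463, 15.4),
            "2": (4167, 58_289, 954, 15.0),
            "3": (4258, 59_873, 1021, 13.9),
            "4": (1931, 27_617, 414, 11.6),
            "5": (379, 5587, 64, 8.9),
            "overall": (12_919, 182_358, 2916, 13.9),
        },
    },
    "female": {
        "full": {
            "0-2": (2277, 39_055, 500, 11.6),
            "3": (9014, 131_480, 1292, 9.4),
            "4": (13_147, 189_491, 1466, 7.9),
            "5": (8287, 120_141, 795, 7.0),
            "6": (1799, 26_550, 157, 6.2),
            "overall": (34_524, 506_720, 4210, 8.3),
        },
        "smoker": {
            "0-1": (202, 2668, 44, 19.1),
            "2": (527, 7171, 103, 14.5),
            "3": (600, 8708, 91, 11.7),
            "4": (322, 4669, 39, 9.1),
            "5": (49, None, 9, None),
            "overall": (1700, 23_940, 286, 13.0),
        },
        "nonsmoker": {
            "0-1": (2075, 29_213, 353, 10.5),
            "2": (8487, 122_771, 1201, 9.3),
            "3": (12_547, 184_822, 1427, 7.8),
            "4": (7965, 119_413, 786, 7.0),
            "5": (1750, 26_550, 157, 6.2),
            "overall": (32_824, 482_760, 3924, 8.1),
        },
    },
}

#: Life expectancies at ages 40 and 60 with 95% CIs:
#: stratum -> {pivot: (e, ci_low, ci_high)}; None where not calculable.
LIFE_EXPECTANCY_TABLE = {
    "male": {
        "full": {
            "0-2": {40: (39.9, 39.5, 40.3), 60: (21.9, 21.6, 22.2)},
            "3": {40: (42.3, 41.9, 42.8), 60: (23.9, 23.6, 24.2)},
            "4": {40: (43.4, 42.8, 44.1), 60: (25.1, 24.7, 25.5)},
            "5": {40: (44.7, 43.8, 45.7), 60: (25.9, 25.4, 26.5)},
            "6": {40: (50.2, 48.1, 52.3), 60: (31.5, 29.8, 33.2)},
            "overall": {40: (42.1, 41.8, 42.3), 60: (23.8, 23.6, 24.0)},
        },
        "smoker": {
            "0-1": {40: (39.0, 38.3, 39.7), 60: (21.0, 20.4, 21.5)},
            "2": {40: (39.0, 38.5, 39.6), 60: (21.3, 20.9, 21.7)},
            "3": {40: (41.2, 40.6, 41.9), 60: (23.0, 22.6, 23.4)},
            "4": {40: (42.0, 41.0, 42.9), 60: (23.2, 22.5, 23.9)},
            "5": {40: (41.4, 39.3, 43.4), 60: (23.2, 21.4, 24.9)},
            "overall": {40: (40.1, 39.8, 40.5), 60: (22.1, 21.8, 22.3)},
        },
        "nonsmoker": {
            "0-1": {40: (43.4, 42.7, 44.2), 60: (24.5, 23.9, 25.1)},
            "2": {40: (43.6, 43.0, 44.2), 60: (24.9, 24.5, 25.3)},
            "3": {40: (43.9, 43.1, 44.7), 60: (25.8, 25.3, 26.2)},
            "4": {40: (45.3, 44.2, 46.4), 60: (26.4, 25.8, 27.0)},
            "5": {40: (50.2, 48.1, 52.3), 60: (31.5, 29.8, 33.2)},
            "overall": {40: (44.2, 43.8, 44.5), 60: (25.6, 25.3, 25.8)},
        },
    },
    "female": {
        "full": {
            "0-2": {40: (46.5, 45.5, 47.4), 60: (28.1, 27.5, 28.7)},
            "3": {40: (48.0, 47.6, 48.4), 60: (29.1, 28.8, 29.4)},
            "4": {40: (50.1, 49.8, 50.4), 60: (30.9, 30.6, 31.2)},
            "5": {40: (50.9, 50.5, 51.2), 60: (31.5, 31.2, 31.8)},
            "6": {40: (54.8, 53.3, 56.2), 60: (36.3, 35.4, 37.1)},
            "overall": {40: (49.5, 49.2, 49.7), 60: (30.4, 30.2, 30.6)},
        },
        "smoker": {
            "0-1": {40: (39.7, 36.8, 42.7), 60: (22.9, 20.8, 25.0)},
            "2": {40: (44.0, 42.0, 45.9), 60: (25.4, 24.1, 26.7)},
            "3": {40: (46.6, 45.0, 48.1), 60: (27.7, 26.3, 29.1)},
            "4": {40: (48.1, 45.9, 50.3), 60: (29.3, 27.5, 31.0)},
            "5": {40: None, 60: None},
            "overall": {40: (44.9, 43.9, 45.9), 60: (26.4, 25.7, 27.2)},
        },
        "nonsmoker": {
            "0-1": {40: (47.9, 46.8, 49.0), 60: (29.3, 28.6, 30.0)},
            "2": {40: (48.1, 47.6, 48.5), 60: (29.2, 28.9, 29.5)},
            "3": {40: (50.1, 49.8, 50.5), 60: (30.9, 30.7, 31.2)},
            "4": {40: (50.9, 50.5, 51.2), 60: (31.5, 31.2, 31.8)},
            "5": {40: (54.8, 53.3, 56.2), 60: (36.3, 35.4, 37.1)},
            "overall": {40: (49.7, 49.5, 49.9), 60: (30.6, 30.4, 30.8)},
        },
    },
}

#: National complete-life-table life expectancies (Japan, 2000).
JAPAN_2000_LIFE_EXPECTANCY = {
    "male": {40: 39.1, 60: 21.4},
    "female": {40: 45.5, 60: 26.9},
}


def overall_counts(sex: str) -> tuple[int, int, int]:
    """(subjects, person-years, deaths) of the whole cohort for a sex."""
    n, py, d, _rate = MORTALITY_TABLE[sex]["full"]["overall"]
    return n, py, d


def life_expectancy(sex: str, scheme: str, stratum: str, pivot: int):
    """Published point estimate, or None where not calculable."""
    cell = LIFE_EXPECTANCY_TABLE[sex][scheme][stratum][pivot]
    return None if cell is None else cell[0]
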