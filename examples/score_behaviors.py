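"""Score a subject's six lifestyle behaviors.

Each behavior is dichotomized into healthy/unhealthy (nonsmoking, at most
23 g of alcohol per occasion, walking >= 1 h/day, sleeping 6.5-7.4 h,
green leafy vegetables almost daily, BMI 18.5-24.9) and the healthy flags
are summed into the 0-6 behavior score that defines the analysis strata.
"""

from lexpect import LifestyleAssessment, assign_group, dichotomize

subjects = {
    "ideal": LifestyleAssessment("never", "current", 15.0, 2.0, 7.0,
                                 True, 22.0),
    "smoker, otherwise healthy": LifestyleAssessment(
        "current", "former", 0.0, 1.5, 7.2, True, 23.5),
    "heavy drinker, short sleeper": LifestyleAssessment(
        "never", "current", 60.0, 0.5, 5.5, False, 26.0),
}

for name, a in subjects.items():
    p = dichotomize(a)
    flags = ", ".join(n for n, ok in zip(
        ("smoking", "alcohol", "walking", "sleep", "greens", "bmi"),
        p.flags) if ok)
    print(f"{name}:")
    print(f"  healthy: {flags or '(none)'}")
    print(f"  score {p.score}/6 -> stratum {assign_group(p.score, 'full')!r}"
          f"; non-smoking score {p.score_other_than_smoking}/5 -> "
          f"{assign_group(p.score_other_than_smoking, 'other_than_smoking')!r}")

# The stratum labels ("0-2" ... "6", or "0-1" ... "5" within smoking
# strata) are the rows of the mortality and life-expectancy reports.
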