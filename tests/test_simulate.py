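"""Synthetic-cohort generator and its analytic ground truth."""

import dataclasses

import numpy as np
import pytest

from lexpect.bands import OPEN
from lexpect.io import ReferenceLifeTable, SubjectRecord
from lexpect.scoring import dichotomize
from lexpect.simulate import (BehaviorModel, GompertzHazard,
                              SimulationConfig, profile_probabilities,
                              reference_from_config, simulate,
                              true_band_rates, true_life_expectancy,
                              _base_band_rates, _expected_exposure,
                              _risk_multiplier, _PROFILES)


def small_cfg(**kw):
    defaults = dict(n={"male": 3000, "female": 3000}, seed=11)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def null_cfg(**kw):
    """All hazard ratios 1: behaviors have no effect."""
    cfg = small_cfg(**kw)
    behaviors = tuple(dataclasses.replace(b, hazard_ratio=1.0)
                      for b in cfg.behaviors)
    return dataclasses.replace(cfg, behaviors=behaviors)


def test_same_seed_reproduces_cohort():
    a, b = simulate(small_cfg()), simulate(small_cfg())
    assert np.array_equal(a.age_exit, b.age_exit)
    assert np.array_equal(a.healthy, b.healthy)
    assert np.array_equal(a.raw["bmi"], b.raw["bmi"])


def test_different_seeds_differ():
    a = simulate(small_cfg())
    b = simulate(small_cfg(seed=12))
    assert not np.array_equal(a.age_exit, b.age_exit)


def test_empty_cohort():
    co = simulate(SimulationConfig(n={"male": 0, "female": 0}))
    assert co.n == 0
    assert co.to_records() == []


def test_records_are_valid_and_match_flags():
    co = simulate(small_cfg())
    records = co.to_records()
    assert all(isinstance(r, SubjectRecord) for r in records)
    # raw lifestyle values dichotomize back to the generating flags
    for r, flags in zip(records[:500], co.healthy[:500]):
        assert dichotomize(r.lifestyle).flags == tuple(flags)


def test_administrative_censoring_at_horizon():
    cfg = small_cfg(moveout_fraction=0.0)
    co = simulate(cfg)
    censored = ~co.died
    follow = co.age_exit[censored] - co.age_entry[censored]
    assert np.allclose(follow, cfg.horizon)
    assert (co.age_exit > co.age_entry).all()


def test_flag_prevalence_matches_config():
    cfg = small_cfg(n={"male": 20000, "female": 0})
    co = simulate(cfg, include_raw=False)
    for j, b in enumerate(cfg.behaviors):
        p = b.prevalence["male"]
        se = np.sqrt(p * (1 - p) / co.n)
        assert abs(co.healthy[:, j].mean() - p) < 5 * se


def test_profile_probabilities_sum_to_one_and_match_empirical():
    cfg = small_cfg(rho=0.3, n={"male": 50000, "female": 0}, seed=3)
    probs = profile_probabilities(cfg, "male")
    assert probs.sum() == pytest.approx(1.0)
    co = simulate(cfg, include_raw=False)
    # empirical frequency of the all-healthy profile
    idx = int(np.flatnonzero((_PROFILES == True).all(axis=1))[0])
    emp = (co.healthy.all(axis=1)).mean()
    se = np.sqrt(probs[idx] * (1 - probs[idx]) / co.n)
    assert abs(emp - probs[idx]) < 5 * se


def test_correlated_flags_raise_all_healthy_share():
    cfg0 = small_cfg(rho=0.0)
    cfg5 = small_cfg(rho=0.5)
    p0 = profile_probabilities(cfg0, "male")
    p5 = profile_probabilities(cfg5, "male")
    all_healthy = (_PROFILES == True).all(axis=1)
    assert p5[all_healthy][0] > p0[all_healthy][0]


def test_band_death_counts_match_poisson_expectation():
    """Empirical deaths per band sit within 4 sigma of the analytic
    expectation from the hazard and design."""
    cfg = small_cfg(n={"male": 20000, "female": 0}, seed=21)
    co = simulate(cfg, include_raw=False)
    base = _base_band_rates(cfg, "male")
    probs = profile_probabilities(cfg, "male")
    expected = np.zeros(len(base))
    for g in range(len(_PROFILES)):
        lam = base * _risk_multiplier(cfg, _PROFILES[g])
        _, d = _expected_exposure(cfg, lam)
        expected += probs[g] * d
    expected *= co.n
    edges = np.arange(40.0, 110.0 + 1e-9, 5.0)
    deaths = np.histogram(co.age_exit[co.died], bins=edges)[0]
    for j in range(len(base)):
        if expected[j] < 5:
            continue
        assert abs(deaths[j] - expected[j]) < 4 * np.sqrt(expected[j])


def test_constant_hazard_truth_is_one_over_b(grid):
    b = 0.02
    cfg = null_cfg(gompertz={
        "male": GompertzHazard(b=b, theta=0.0),
        "female": GompertzHazard(b=b, theta=0.0)})
    bands = grid.closed_starts + (grid.tracking_start,)
    ref = ReferenceLifeTable(a_fraction={x: 0.5 for x in bands},
                             national_rate={**{x: b for x in bands},
                                            OPEN: b})
    e = true_life_expectancy(cfg, "male", 40.0, None, None, ref=ref)
    assert e == pytest.approx(1.0 / b, abs=1e-9)


def test_null_effect_truth_identical_across_strata():
    cfg = null_cfg()
    ref = reference_from_config(cfg, "male")
    es = [true_life_expectancy(cfg, "male", 40.0, "full", s, ref=ref)
          for s in ("0-2", "3", "6")]
    assert max(es) - min(es) < 1e-9


def test_stronger_hazard_ratios_widen_the_truth_gap():
    cfg = small_cfg()
    strong = dataclasses.replace(cfg, behaviors=tuple(
        dataclasses.replace(b, hazard_ratio=b.hazard_ratio ** 2)
        for b in cfg.behaviors))
    ref_w = reference_from_config(cfg, "male")
    ref_s = reference_from_config(strong, "male")
    gap_weak = (true_life_expectancy(cfg, "male", 40.0, "full", "6",
                                     ref=ref_w)
                - true_life_expectancy(cfg, "male", 40.0, "full", "0-2",
                                       ref=ref_w))
    gap_strong = (true_life_expectancy(strong, "male", 40.0, "full", "6",
                                       ref=ref_s)
                  - true_life_expectancy(strong, "male", 40.0, "full",
                                         "0-2", ref=ref_s))
    assert gap_strong > gap_weak > 0


def test_true_band_rates_monotone_in_age():
    cfg = small_cfg()
    rates = true_band_rates(cfg, "male", None, None)
    closed = [rates[b] for b in cfg.grid.closed_starts]
    assert all(a < b for a, b in zip(closed, closed[1:]))
    assert rates[OPEN] > rates[85.0] * 0.9  # truncated open aggregate


def test_reference_from_config_is_valid():
    ref = reference_from_config(small_cfg(), "female")
    assert 0.0 < ref.a(40.0) < 1.0
    assert ref.open_rate_ratio > 1.0  # full 85+ tail dies faster than 85-89
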