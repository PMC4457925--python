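"""Deterministic cell-cycle model: closed forms vs independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowcycle import model
from flowcycle.model import CellCycleParams, UnsupportedRegimeError

LN2 = math.log(2.0)

# parameter sets covering 1-4 overlapping generations
PARAM_GRID = [
    CellCycleParams(tau=240, C=80, D=13),
    CellCycleParams(tau=70, C=60, D=40),
    CellCycleParams(tau=30, C=60, D=15),
    CellCycleParams(tau=30, C=60, D=29),
    CellCycleParams(tau=25, C=55, D=22),
    CellCycleParams(tau=40, C=40, D=0),
    CellCycleParams(tau=60, C=45, D=15),  # C + D == tau exactly
    CellCycleParams(tau=30, C=75, D=45),  # C + D == 4 tau exactly
]

params_strategy = st.builds(
    CellCycleParams,
    tau=st.floats(20.0, 300.0),
    C=st.floats(10.0, 250.0),
    D=st.floats(0.0, 120.0),
)


# --- hand-derived worked examples ------------------------------------------

def test_slow_growth_worked_example():
    # tau=240, C=80, D=13: B = 147, initiation at age 147, termination at 227
    p = CellCycleParams(tau=240, C=80, D=13)
    assert model.initiation_age(p) == pytest.approx(147.0)
    assert model.origins_at_initiation(p) == 1
    # halfway through replication (age 187): one fork pair 50% done
    s = model.chromosome_state_at_age(p, 187.0)
    assert s.dna == pytest.approx(1.5)
    assert s.n_origins == 2
    assert s.n_units == 1
    # before initiation: a single resting chromosome
    s0 = model.chromosome_state_at_age(p, 10.0)
    assert (s0.dna, s0.n_origins, s0.fork_fractions) == (1.0, 1, ())


def test_multifork_worked_example():
    # tau=30, C=60, D=15: C+D = 75 in (2 tau, 3 tau], initiation age 15,
    # newborn carries rounds started 15 and 45 min before birth
    p = CellCycleParams(tau=30, C=60, D=15)
    assert model.initiation_age(p) == pytest.approx(15.0)
    assert model.origins_at_initiation(p) == 4
    s = model.chromosome_state_at_age(p, 0.0)
    # one unit, rounds at fractions 45/60 and 15/60: dna = 1 + 0.75 + 2*0.25
    assert s.dna == pytest.approx(2.25)
    assert s.n_origins == 4
    assert s.n_units == 1
    assert s.fork_fractions == pytest.approx((0.75, 0.25))


def test_average_dna_closed_form_worked_example():
    p = CellCycleParams(tau=240, C=80, D=13)
    expected = (240 / (80 * LN2)) * (2 ** (93 / 240) - 2 ** (13 / 240))
    assert model.average_dna_per_cell(p) == pytest.approx(expected)
    assert model.average_dna_per_cell(p) == pytest.approx(1.1677, abs=1e-3)
    assert model.average_origins_per_cell(p) == pytest.approx(2 ** (93 / 240))


def test_period_fractions_slow_growth():
    p = CellCycleParams(tau=240, C=80, D=13)
    fr = model.period_fractions(p)
    assert fr.frac_B + fr.frac_C + fr.frac_D == pytest.approx(1.0)
    assert fr.frac_C == pytest.approx(0.2699, abs=5e-4)
    assert fr.frac_D == pytest.approx(2 ** (13 / 240) - 1.0)


def test_period_fractions_undefined_for_overlapping_cycles():
    with pytest.raises(UnsupportedRegimeError):
        model.period_fractions(CellCycleParams(tau=30, C=60, D=15))


# --- two independent evaluation paths agree --------------------------------

@pytest.mark.parametrize("p", PARAM_GRID, ids=lambda p: f"t{p.tau}C{p.C}D{p.D}")
def test_lineage_replay_matches_closed_form(p):
    # generic (irrational-ish) ages avoid event-time ties, which the two
    # paths may bookkeep differently without affecting DNA
    for frac in (0.137, 0.349, 0.552, 0.718, 0.941):
        age = frac * p.tau
        a = model.chromosome_state_at_age(p, age)
        b = model.lineage_chromosome_state(p, age)
        assert a.n_origins == b.n_origins
        assert a.n_units == b.n_units
        assert a.dna == pytest.approx(b.dna, rel=1e-12)
        assert np.allclose(a.fork_fractions, b.fork_fractions)


@pytest.mark.parametrize("p", PARAM_GRID, ids=lambda p: f"t{p.tau}C{p.C}D{p.D}")
def test_vectorised_dna_matches_scalar(p):
    ages = np.linspace(0.0, p.tau, 57, endpoint=False)
    vec = model.dna_at_ages(p, ages)
    scalar = [model.chromosome_state_at_age(p, a).dna for a in ages]
    assert np.allclose(vec, scalar, rtol=1e-12)
    ovec = model.origins_at_ages(p, ages)
    oscalar = [model.origin_count_at_age(p, a) for a in ages]
    assert np.array_equal(ovec, oscalar)


# --- structural properties -------------------------------------------------

@given(p=params_strategy)
def test_initiation_age_within_one_generation(p):
    a_i = model.initiation_age(p)
    assert 0.0 <= a_i < p.tau + 1e-9
    assert math.log2(model.origins_at_initiation(p)).is_integer()


@given(p=params_strategy)
def test_dna_doubles_over_one_generation(p):
    birth = model.dna_at_ages(p, np.array([0.0]))[0]
    end = model.dna_at_ages(p, np.array([np.nextafter(p.tau, 0.0)]))[0]
    assert end == pytest.approx(2.0 * birth, rel=1e-6)
    assert birth >= 1.0


@given(p=params_strategy)
@settings(max_examples=30)
def test_dna_nondecreasing_in_age(p):
    ages = np.linspace(0.0, p.tau, 101, endpoint=False)
    dna = model.dna_at_ages(p, ages)
    assert np.all(np.diff(dna) >= -1e-12)


@pytest.mark.parametrize("p", PARAM_GRID, ids=lambda p: f"t{p.tau}C{p.C}D{p.D}")
def test_origin_count_is_origins_per_unit_times_units(p):
    for frac in (0.1, 0.45, 0.8):
        s = model.chromosome_state_at_age(p, frac * p.tau)
        assert s.n_origins == s.n_units * 2 ** len(s.fork_fractions)
        assert s.n_origins in {1, 2, 4, 8, 16, 32}


# --- the age distribution --------------------------------------------------

def test_age_distribution_density_integrates_to_cdf():
    tau = 70.0
    ages = np.linspace(0.0, tau, 20001)
    dens = model.age_density(tau, ages)
    cdf = model.age_cdf(tau, ages)
    trapz = np.concatenate([[0.0], np.cumsum(
        0.5 * (dens[1:] + dens[:-1]) * np.diff(ages))])
    assert np.allclose(trapz, cdf, atol=1e-6)
    assert cdf[0] == 0.0
    assert cdf[-1] == pytest.approx(1.0)
    # twice as many newborns as dividing cells
    assert dens[0] == pytest.approx(2.0 * dens[-1])


def test_sampled_ages_follow_the_age_distribution():
    tau = 70.0
    rng = np.random.default_rng(123)
    ages = model.sample_ages(tau, 50000, rng)
    assert ages.min() >= 0.0 and ages.max() <= tau
    grid = np.linspace(0.0, tau, 201)
    emp = np.searchsorted(np.sort(ages), grid) / ages.size
    ks = np.abs(emp - model.age_cdf(tau, grid)).max()
    assert ks < 0.01


def test_average_mass_is_two_ln_two():
    tau = 70.0
    ages = np.linspace(0.0, tau, 200001)
    dens = model.age_density(tau, ages)
    mass = 2.0 ** (ages / tau)
    avg = np.trapezoid(dens * mass, ages)
    assert avg == pytest.approx(model.average_mass_per_cell(), rel=1e-8)
    assert model.average_mass_per_cell() == pytest.approx(2 * LN2)


# --- validation ------------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    {"tau": 0, "C": 40, "D": 20},
    {"tau": -5, "C": 40, "D": 20},
    {"tau": 60, "C": 0, "D": 20},
    {"tau": 60, "C": 40, "D": -1},
    {"tau": float("nan"), "C": 40, "D": 20},
    {"tau": float("inf"), "C": 40, "D": 20},
])
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(ValueError):
        CellCycleParams(**kwargs)


def test_age_outside_generation_rejected():
    p = CellCycleParams(tau=60, C=40, D=10)
    with pytest.raises(ValueError):
        model.chromosome_state_at_age(p, 60.0)
    with pytest.raises(ValueError):
        model.chromosome_state_at_age(p, -0.1)
    with pytest.raises(ValueError):
        model.dna_at_ages(p, np.array([10.0, 61.0]))
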