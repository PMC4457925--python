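"""Deterministic multifork cell-cycle model for exponentially growing bacteria.

The model is the classic age-structured description of the bacterial cell
cycle: a chromosome takes C minutes to replicate (origin to terminus), the
cell divides D minutes after termination, and every cell in the steady-state
culture doubles in τ minutes.  When C + D exceeds τ, replication rounds
overlap and cells carry 2, 4, ... origins that all fire synchronously
("multifork" replication).  All quantities here are per cell in a
steady-state exponential culture with the canonical age distribution
n(a) = (2 ln2 / τ) · 2^(−a/τ).

Two evaluation paths are provided for the per-cell chromosome configuration:

* :func:`chromosome_state_at_age` enumerates the replication rounds active
  at a given age in closed form (fast, vectorisable);
* :func:`lineage_chromosome_state` replays the cell's ancestry event by
  event (initiations, terminations, divisions) from a single non-replicating
  chromosome far in the past.  It is the authoritative definition for edge
  cases (termination coinciding with initiation or division) and serves as
  an independent cross-check of the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellCycleParams",
    "PeriodFractions",
    "ChromosomeState",
    "initiation_age",
    "origins_at_initiation",
    "origin_count_at_age",
    "chromosome_state_at_age",
    "lineage_chromosome_state",
    "dna_at_ages",
    "origins_at_ages",
    "age_density",
    "age_cdf",
    "sample_ages",
    "period_fractions",
    "average_dna_per_cell",
    "average_origins_per_cell",
    "average_mass_per_cell",
]

LN2 = math.log(2.0)


class UnsupportedRegimeError(ValueError):
    """Raised when an operation is only defined for non-overlapping cycles."""


@dataclass(frozen=True)
class CellCycleParams:
    """Cell-cycle parameter vector.

    Parameters
    ----------
    tau : float
        Doubling (generation) time of the culture, minutes.
    C : float
        Replication period — time to replicate the chromosome, minutes.
    D : float
        Interval from termination of replication to division, minutes.
        May exceed tau (termination in an ancestor generation).
    """

    tau: float
    C: float
    D: float

    def __post_init__(self) -> None:
        for name in ("tau", "C", "D"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.C <= 0:
            raise ValueError(f"C must be > 0, got {self.C}")
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")

    @property
    def generations_spanned(self) -> int:
        """Number of generations spanned by C + D (= ⌈(C+D)/τ⌉, ≥ 1)."""
        return max(1, math.ceil((self.C + self.D) / self.tau - 1e-12))


@dataclass(frozen=True)
class PeriodFractions:
    """Fractions of the population in the B, C and D periods (sum to 1)."""

    frac_B: float
    frac_C: float
    frac_D: float


@dataclass(frozen=True)
class ChromosomeState:
    """Chromosome configuration of a single cell.

    Attributes
    ----------
    n_origins : int
        Number of replication origins (a power of two).
    n_units : int
        Number of physically separate chromosomes.
    fork_fractions : tuple of float
        Replication fraction of each active round within one unit,
        oldest round first, each in [0, 1).
    dna : float
        DNA content in genome (chromosome) equivalents.
    """

    n_origins: int
    n_units: int
    fork_fractions: tuple
    dna: float


def _check_age(p: CellCycleParams, age: float) -> None:
    if not (0 <= age < p.tau):
        raise ValueError(f"age must lie in [0, tau={p.tau}), got {age}")


def initiation_age(p: CellCycleParams) -> float:
    """Age a_i at which a cell fires a new round of initiation.

    a_i = ⌈(C+D)/τ⌉·τ − (C+D).  When C + D is an exact multiple of τ the
    initiation coincides with birth (a_i = 0); when C + D < τ it equals the
    B period τ − (C + D).
    """
    return p.generations_spanned * p.tau - (p.C + p.D)


def origins_at_initiation(p: CellCycleParams) -> int:
    """Number of origins that fire together at the initiation event.

    2^(⌈(C+D)/τ⌉ − 1): one origin for slow growth (C+D < τ), two with one
    overlapping generation, four with two, and so on.
    """
    return 2 ** (p.generations_spanned - 1)


def origin_count_at_age(p: CellCycleParams, age: float) -> int:
    """Origins present in a cell of the given age (doubles at a_i)."""
    _check_age(p, age)
    n0 = origins_at_initiation(p)
    return 2 * n0 if age >= initiation_age(p) else n0


def _active_rounds(p: CellCycleParams, age: float) -> list:
    """Replication fractions of rounds active at `age`, oldest first.

    Round m (m = 0 in this cell, m ≥ 1 in ancestors) initiates at lineage
    time a_i − m·τ and is active while 0 ≤ age − t_m < C.
    """
    a_i = initiation_age(p)
    fracs = []
    # oldest possible active round: a - t_m < C  =>  m < (C + a - a_i)/tau
    m_max = math.ceil((p.C + age - a_i) / p.tau) + 1
    for m in range(m_max, -1, -1):
        t_m = a_i - m * p.tau
        elapsed = age - t_m
        if 0 <= elapsed < p.C:
            fracs.append(elapsed / p.C)
    return fracs  # descending fractions = oldest first


def chromosome_state_at_age(p: CellCycleParams, age: float) -> ChromosomeState:
    """Chromosome configuration of a cell at the given age.

    Enumerates the replication rounds active at this age.  Each physically
    separate chromosome ("unit") carries the same ladder of rounds; a unit
    with R active rounds holds 2^R origins and
    DNA = 1 + Σ_r 2^r · f_r genome equivalents, with r = 0 the oldest round.
    """
    _check_age(p, age)
    fracs = _active_rounds(p, age)
    n_origins = origin_count_at_age(p, age)
    n_units = n_origins // (2 ** len(fracs))
    per_unit = 1.0 + sum((2.0**r) * f for r, f in enumerate(fracs))
    return ChromosomeState(
        n_origins=n_origins,
        n_units=n_units,
        fork_fractions=tuple(fracs),
        dna=n_units * per_unit,
    )


def lineage_chromosome_state(p: CellCycleParams, age: float) -> ChromosomeState:
    """Event-driven replay of the cell's ancestry; cross-check oracle.

    Starts more than C + D + 2τ before birth, at an ancestral birth, from
    non-replicating chromosomes; fires all origins at every time
    j·τ − (C+D), advances fork pairs at 1/C genome per minute, splits a unit
    in two when its oldest round completes, and halves the cell content at
    every division j·τ.  Events at equal times are ordered
    termination → division → initiation, so a round whose C + D is an exact
    multiple of τ initiates at birth.

    Replication rounds already in flight at the starting time are not
    replayed; their missing terminations are compensated exactly by seeding
    the start with 2^(N−1) chromosomes, N = ⌈(C+D)/τ⌉ (one chromosome in
    the non-overlapping regime).
    """
    _check_age(p, age)
    tau, C, D = p.tau, p.C, p.D
    a_i = initiation_age(p)
    t_start = -(math.ceil((C + D + 2 * tau) / tau) + 1) * tau  # an ancestral birth

    events = []  # (time, priority, kind); priority orders ties
    j = math.floor((t_start - a_i) / tau)
    while True:
        t_init = a_i + j * tau
        if t_init > age:
            break
        # >=: a round firing exactly at the starting birth (a_i = 0) is replayed,
        # keeping the 2^(N-1) seeding exact
        if t_init >= t_start:
            events.append((t_init, 2, "init"))
            t_term = t_init + C
            if t_term <= age:
                events.append((t_term, 0, "term"))
        j += 1
    j = math.ceil(t_start / tau)
    while j * tau <= age:
        if j * tau > t_start:
            events.append((j * tau, 1, "div"))
        j += 1
    events.sort()

    n_units = 2 ** (p.generations_spanned - 1)
    fracs: list = []  # initiation times of active rounds, oldest first
    for t, _, kind in events:
        if kind == "term":
            fracs.pop(0)
            n_units *= 2
        elif kind == "div":
            if n_units % 2:
                raise AssertionError("odd unit count at division (internal error)")
            n_units //= 2
        else:  # init: every origin fires, adding one round per unit
            fracs.append(t)

    fork = tuple((age - t0) / C for t0 in fracs)
    per_unit = 1.0 + sum((2.0**r) * f for r, f in enumerate(fork))
    return ChromosomeState(
        n_origins=n_units * 2 ** len(fork),
        n_units=n_units,
        fork_fractions=fork,
        dna=n_units * per_unit,
    )


def dna_at_ages(p: CellCycleParams, ages: np.ndarray) -> np.ndarray:
    """Vectorised DNA content (genome equivalents) at the given ages."""
    ages = np.asarray(ages, dtype=float)
    if ages.size and (ages.min() < 0 or ages.max() >= p.tau):
        raise ValueError("ages must lie in [0, tau)")
    a_i = initiation_age(p)
    m_max = math.ceil((p.C + p.tau - a_i) / p.tau) + 1

    elapsed = ages[:, None] - (a_i - np.arange(m_max + 1) * p.tau)[None, :]
    active = (elapsed >= 0) & (elapsed < p.C)
    frac = np.where(active, elapsed / p.C, 0.0)
    m_idx = np.arange(m_max + 1)[None, :]
    m_hi = np.max(np.where(active, m_idx, -1), axis=1)  # oldest active round
    n_rounds = active.sum(axis=1)
    weights = np.where(active, 2.0 ** (m_hi[:, None] - m_idx), 0.0)
    per_unit = 1.0 + (weights * frac).sum(axis=1)

    n0 = origins_at_initiation(p)
    n_origins = np.where(ages >= a_i, 2 * n0, n0)
    n_units = n_origins / 2.0**n_rounds
    return n_units * per_unit


def origins_at_ages(p: CellCycleParams, ages: np.ndarray) -> np.ndarray:
    """Vectorised origin count at the given ages."""
    ages = np.asarray(ages, dtype=float)
    n0 = origins_at_initiation(p)
    return np.where(ages >= initiation_age(p), 2 * n0, n0).astype(np.int64)


def age_density(tau: float, age) -> np.ndarray:
    """Steady-state age density n(a) = (2 ln2 / τ)·2^(−a/τ) on [0, τ]."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    a = np.asarray(age, dtype=float)
    if a.size and (a.min() < 0 or a.max() > tau):
        raise ValueError("age must lie in [0, tau]")
    return (2.0 * LN2 / tau) * 2.0 ** (-a / tau)


def age_cdf(tau: float, age) -> np.ndarray:
    """CDF of the steady-state age distribution, F(a) = 2(1 − 2^(−a/τ))."""
    a = np.asarray(age, dtype=float)
    return 2.0 * (1.0 - 2.0 ** (-a / tau))


def sample_ages(tau: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. ages by inverse transform: a = −τ·log2(1 − u/2)."""
    u = rng.random(n)
    return -tau * np.log2(1.0 - u / 2.0)


def period_fractions(p: CellCycleParams) -> PeriodFractions:
    """Population fractions in the B, C and D periods (C + D < τ only).

    With B = τ − C − D and the exponential age distribution:
    frac_B = 2 − 2^(1−B/τ), frac_C = 2^(1−B/τ) − 2^(1−(B+C)/τ),
    frac_D = 2^(1−(B+C)/τ) − 1.
    """
    if p.C + p.D >= p.tau:
        raise UnsupportedRegimeError(
            "period fractions are defined only for non-overlapping cycles (C + D < tau)"
        )
    B = p.tau - p.C - p.D
    e1 = 2.0 ** (1.0 - B / p.tau)
    e2 = 2.0 ** (1.0 - (B + p.C) / p.tau)
    return PeriodFractions(frac_B=2.0 - e1, frac_C=e1 - e2, frac_D=e2 - 1.0)


def average_dna_per_cell(p: CellCycleParams) -> float:
    """Population-average DNA, (τ/(C ln2))·(2^((C+D)/τ) − 2^(D/τ))."""
    return (p.tau / (p.C * LN2)) * (
        2.0 ** ((p.C + p.D) / p.tau) - 2.0 ** (p.D / p.tau)
    )


def average_origins_per_cell(p: CellCycleParams) -> float:
    """Population-average origin count, 2^((C+D)/τ)."""
    return 2.0 ** ((p.C + p.D) / p.tau)


def average_mass_per_cell() -> float:
    """Population-average mass in newborn-mass units: ∫n(a)·2^(a/τ) da = 2 ln2."""
    return 2.0 * LN2
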