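"""Synthetic steady-state populations and measured DNA histograms.

Bridges the deterministic cell-cycle model and flow-cytometry-like data:
draws per-cell (age, DNA, origins, mass) records from the steady-state age
distribution, applies multiplicative instrument noise, bins signals into
channels, and applies the replication run-out transform (rifampicin +
cephalexin: ongoing rounds finish, no new initiations, no division — each
cell ends with one complete chromosome per origin present at drug addition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model
from .model import CellCycleParams

__all__ = [
    "PopulationSample",
    "DNAHistogram",
    "NoiseModel",
    "sample_population",
    "measure_histogram",
    "runout_transform",
    "dna_per_mass",
]

MAX_CV = 0.3


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative normal measurement noise with coefficient of variation `cv`."""

    cv: float
    kind: str = "multiplicative-normal"

    def __post_init__(self) -> None:
        if not (0 <= self.cv < MAX_CV):
            raise ValueError(f"cv must lie in [0, {MAX_CV}), got {self.cv}")


@dataclass(frozen=True)
class PopulationSample:
    """Per-cell records of a steady-state (or run-out) population.

    ages are minutes since birth; dna is in genome equivalents; origins are
    counts; mass is in units of newborn mass (exponential growth 2^(a/τ)).
    """

    ages: np.ndarray
    dna: np.ndarray
    origins: np.ndarray
    mass: np.ndarray
    params: CellCycleParams
    seed: int

    @property
    def n_cells(self) -> int:
        return self.ages.size


@dataclass(frozen=True)
class DNAHistogram:
    """Binned DNA-content distribution in instrument channels.

    `edges` has one more entry than `counts`; `calibration` is channels per
    genome equivalent (None when unknown / to be fitted).
    """

    edges: np.ndarray
    counts: np.ndarray
    calibration: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        counts = np.asarray(self.counts)
        if edges.ndim != 1 or counts.ndim != 1 or edges.size != counts.size + 1:
            raise ValueError("edges must be 1-D with len(counts) + 1 entries")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("channel edges must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("channel counts must be non-negative")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if self.calibration is not None and self.calibration <= 0:
            raise ValueError("calibration must be > 0")

    @property
    def n_cells(self) -> int:
        return int(self.counts.sum())

    @property
    def n_channels(self) -> int:
        return self.counts.size

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def mean_signal(self) -> float:
        """Count-weighted mean channel position (instrument units)."""
        if self.n_cells == 0:
            raise ValueError("empty histogram")
        return float(np.average(self.midpoints, weights=self.counts))


def sample_population(p: CellCycleParams, n: int, seed: int) -> PopulationSample:
    """Draw `n` cells from the steady-state model.

    Ages are sampled by inverse transform from the exponential-culture age
    distribution; DNA and origin counts are the deterministic model
    functions of age; mass grows exponentially from 1 at birth to 2 at
    division.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    ages = model.sample_ages(p.tau, n, rng)
    # guard against the measure-zero age == tau from float rounding
    ages = np.minimum(ages, np.nextafter(p.tau, 0.0))
    return PopulationSample(
        ages=ages,
        dna=model.dna_at_ages(p, ages),
        origins=model.origins_at_ages(p, ages),
        mass=2.0 ** (ages / p.tau),
        params=p,
        seed=seed,
    )


def measure_histogram(
    sample: PopulationSample,
    noise: NoiseModel,
    calibration: float = 100.0,
    n_channels: int = 1024,
    seed: int = 0,
) -> DNAHistogram:
    """Measure a population into a binned DNA histogram.

    Each cell's signal is dna × calibration × (1 + ε) with ε ~ N(0, cv²);
    signals fall into `n_channels` unit-width channels covering
    [0, n_channels); out-of-range signals are clipped into the end channels
    so that counts are conserved.
    """
    if calibration <= 0:
        raise ValueError("calibration must be > 0")
    if n_channels < 64:
        raise ValueError("n_channels must be >= 64")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise.cv, size=sample.n_cells) if noise.cv > 0 else 0.0
    signal = sample.dna * calibration * (1.0 + eps)
    idx = np.clip(np.floor(signal).astype(np.int64), 0, n_channels - 1)
    counts = np.bincount(idx, minlength=n_channels)
    edges = np.arange(n_channels + 1, dtype=float)
    return DNAHistogram(
        edges=edges,
        counts=counts,
        calibration=calibration,
        meta={
            "n_cells": sample.n_cells,
            "cv": noise.cv,
            "seed": seed,
            "params": {"tau": sample.params.tau, "C": sample.params.C, "D": sample.params.D},
        },
    )


def runout_transform(
    sample: PopulationSample, reinit_prob: float = 0.0, seed: int = 0
) -> PopulationSample:
    """Replication run-out: DNA becomes the integer origin count at drug addition.

    Ongoing rounds finish while new initiations and division are blocked, so
    each origin present ends up heading one complete chromosome.  With
    `reinit_prob` > 0 each origin independently fires once more during the
    drug treatment (rifampicin-resistant initiation), adding one extra
    complete chromosome per firing origin.
    """
    if not (0.0 <= reinit_prob <= 1.0):
        raise ValueError(f"reinit_prob must lie in [0, 1], got {reinit_prob}")
    chroms = sample.origins.astype(np.int64)
    if reinit_prob > 0:
        rng = np.random.default_rng(seed)
        chroms = chroms + rng.binomial(chroms, reinit_prob)
    return PopulationSample(
        ages=sample.ages,
        dna=chroms.astype(float),
        origins=chroms,
        mass=sample.mass,
        params=sample.params,
        seed=sample.seed,
    )


def dna_per_mass(sample: PopulationSample) -> float:
    """Population DNA/mass ratio, mean(dna)/mean(mass).

    Comparisons between conditions are reported as ratios of this quantity.
    """
    if sample.n_cells == 0:
        raise ValueError("empty sample")
    return float(sample.dna.mean() / sample.mass.mean())
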