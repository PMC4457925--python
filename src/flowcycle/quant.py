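"""Quantification arithmetic: blot ratios, ATP-DnaA accounting, expression
fold changes, and the oriC/ter marker-ratio ↔ C-period conversion.

These are the small, exactly-reproducible computations that accompany the
histogram analysis: relative protein concentrations from paired replicate
blot intensities, the number and relative concentration of ATP-bound DnaA
molecules, expression fold changes between conditions, and the
marker-frequency relation oriC/ter = 2^(C/τ) linking the replication period
to locus copy-number ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import CellCycleParams

__all__ = [
    "BlotSeries",
    "AtpAccounting",
    "ExpressionPair",
    "relative_concentration",
    "atp_molecules",
    "relative_atp_concentration",
    "fold_change",
    "c_from_marker_ratio",
    "marker_ratio_from_c",
    "expected_marker_ratio",
    "format_mean_sd",
]


@dataclass(frozen=True)
class BlotSeries:
    """Replicate blot intensities (ng protein per μg cell extract)."""

    intensities: tuple
    strain: str = ""
    medium: str = ""

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.intensities)
        if len(vals) < 1:
            raise ValueError("at least one replicate required")
        if any(v <= 0 for v in vals):
            raise ValueError("intensities must be > 0")
        object.__setattr__(self, "intensities", vals)


@dataclass(frozen=True)
class AtpAccounting:
    """Per-cell DnaA molecule counts and the ATP-bound share."""

    total_molecules: int
    percent_atp: float
    strain: str = ""
    molecules_atp: int = field(init=False)

    def __post_init__(self) -> None:
        if self.total_molecules < 0:
            raise ValueError("total_molecules must be >= 0")
        if not (0 <= self.percent_atp <= 100):
            raise ValueError("percent_atp must lie in [0, 100]")
        object.__setattr__(
            self, "molecules_atp", atp_molecules(self.total_molecules, self.percent_atp)
        )


@dataclass(frozen=True)
class ExpressionPair:
    """Upper-quartile-normalised expression of one gene in two conditions.

    The q value is carried as an annotation from the upstream differential
    expression tool; it is not recomputed here.
    """

    gene: str
    expression_a: float
    expression_b: float
    q_value: float | None = None

    def __post_init__(self) -> None:
        if self.expression_a <= 0 or self.expression_b <= 0:
            raise ValueError("expressions must be > 0")


def relative_concentration(test: BlotSeries, reference: BlotSeries):
    """Mean ± SD of per-replicate ratios test/reference (paired per gel)."""
    if len(test.intensities) != len(reference.intensities):
        raise ValueError("test and reference series must have equal replicate counts")
    ratios = np.array(test.intensities) / np.array(reference.intensities)
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return float(ratios.mean()), sd


def format_mean_sd(mean: float, sd: float) -> str:
    """Render a relative concentration as e.g. '1.72 ± 0.25'."""
    return f"{mean:.2f} ± {sd:.2f}"


def atp_molecules(total: int, percent_atp: float) -> int:
    """Molecules in ATP-form: total × percent/100, rounded to nearest integer."""
    if total < 0:
        raise ValueError("total must be >= 0")
    if not (0 <= percent_atp <= 100):
        raise ValueError(f"percent_atp must lie in [0, 100], got {percent_atp}")
    return round(total * percent_atp / 100.0)


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def relative_atp_concentration(strain: AtpAccounting, reference: AtpAccounting) -> float:
    """ATP-DnaA molecules relative to a reference strain, to 2 significant figures."""
    if reference.molecules_atp <= 0:
        raise ZeroDivisionError("reference has no ATP-form molecules")
    return _round_sig(strain.molecules_atp / reference.molecules_atp, 2)


def fold_change(pair: ExpressionPair) -> float:
    """Expression ratio B/A, rounded to two decimals."""
    return round(pair.expression_b / pair.expression_a, 2)


def c_from_marker_ratio(ratio: float, tau: float) -> float:
    """Replication period from the oriC/ter copy-number ratio: C = τ·log2(ratio).

    The ratio must first be normalised so that a non-replicating sample
    gives oriC/ter = 1.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if ratio < 1:
        raise ValueError(f"oriC/ter ratio must be >= 1 after normalisation, got {ratio}")
    return tau * math.log2(ratio)


def marker_ratio_from_c(C: float, tau: float) -> float:
    """Inverse relation: oriC/ter = 2^(C/τ)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if C < 0:
        raise ValueError("C must be >= 0")
    return 2.0 ** (C / tau)


def expected_marker_ratio(p: CellCycleParams) -> float:
    """Model-expected oriC/ter ratio, 2^(C/τ).

    Equals the ratio of the population-average origin count 2^((C+D)/τ) to
    the population-average terminus count 2^(D/τ).
    """
    return 2.0 ** (p.C / p.tau)
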