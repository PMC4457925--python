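"""Fit cell-cycle parameters to an observed DNA histogram.

Given the culture's doubling time τ (measured independently, e.g. from OD
growth curves) the expected DNA histogram of a steady-state population is a
deterministic function of (C, D, noise CV, channel calibration).  The fitter
minimises the squared deviation between observed and expected channel counts
with a coarse grid search over (C, D, cv) — calibration pinned at each grid
point by matching the histogram mean — followed by Nelder–Mead refinement of
all four parameters.  The objective has ridges along C↔D trade-offs, which
is why the global grid stage precedes the local simplex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import ndtr

from . import model
from .model import CellCycleParams, PeriodFractions
from .population import DNAHistogram

__all__ = [
    "FitConfig",
    "FitResult",
    "theoretical_histogram",
    "fit_objective",
    "fit_cell_cycle",
    "fraction_replicating",
]


@dataclass(frozen=True)
class FitConfig:
    """Search space and optimizer settings for :func:`fit_cell_cycle`.

    Bounds are in minutes (C, D), dimensionless (cv) and channels per
    genome equivalent (calibration; None bounds derive them from the data).
    """

    c_bounds: tuple | None = None  # default (0.1 tau, 2.6 tau)
    d_bounds: tuple | None = None  # default (0, tau): D and D + tau fit
    # identically with a halved calibration, so D is searched within one
    # generation and reported as the parsimonious representative
    cv_bounds: tuple = (0.01, 0.12)
    cal_bounds: tuple | None = None
    n_grid_c: int = 24
    n_grid_d: int = 12
    cv_grid: tuple = (0.03, 0.06, 0.10)
    n_ages: int = 200
    xatol: float = 0.02
    fatol: float = 1e-4
    max_evals: int = 1500
    # poor fit when observed-vs-model TV exceeds this multiple of the TV
    # expected from multinomial sampling noise alone under the fitted model
    poor_fit_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for b in (self.c_bounds, self.d_bounds, self.cv_bounds, self.cal_bounds):
            if b is not None and not (len(b) == 2 and b[0] < b[1] and math.isfinite(b[1])):
                raise ValueError(f"bounds must be finite and ordered, got {b}")
        if self.n_grid_c < 2 or self.n_grid_d < 2:
            raise ValueError("grid resolution must be >= 2")

    def resolve(self, tau: float, hist: DNAHistogram) -> "FitConfig":
        """Fill data-dependent defaults for a given τ and histogram."""
        c_b = self.c_bounds or (0.1 * tau, 2.6 * tau)
        d_b = self.d_bounds or (0.0, tau)
        if self.cal_bounds is not None:
            cal_b = self.cal_bounds
        elif hist.calibration is not None:
            # anchor to the histogram's declared channels-per-equivalent
            # (established from run-out integer peaks) within a gain-drift
            # margin: with a fully free calibration the DNA histogram is
            # nearly invariant under C -> C/2 at a rescaled axis, making C
            # unidentifiable
            cal_b = (0.85 * hist.calibration, 1.15 * hist.calibration)
        else:
            # mean signal corresponds to avg DNA somewhere in [1, 8] equivalents
            m = hist.mean_signal()
            cal_b = (max(2.0, m / 10.0), max(4.0, 1.2 * m))
        return FitConfig(
            c_bounds=c_b, d_bounds=d_b, cv_bounds=self.cv_bounds, cal_bounds=cal_b,
            n_grid_c=self.n_grid_c, n_grid_d=self.n_grid_d, cv_grid=self.cv_grid,
            n_ages=self.n_ages, xatol=self.xatol, fatol=self.fatol,
            max_evals=self.max_evals, poor_fit_ratio=self.poor_fit_ratio,
            seed=self.seed,
        )


@dataclass(frozen=True)
class FitResult:
    """Best-fit cell-cycle parameters and derived summaries."""

    params: CellCycleParams
    cv: float
    calibration: float
    objective: float
    initiation_age: float
    period_fractions: PeriodFractions | None
    fraction_replicating: float | None
    tv_distance: float
    converged: bool
    poor_fit: bool
    average_mass: float | None = None
    dna_per_mass: float | None = None
    config: FitConfig | None = None

    def to_dict(self) -> dict:
        d = {
            "tau": self.params.tau,
            "C": self.params.C,
            "D": self.params.D,
            "cv": self.cv,
            "calibration": self.calibration,
            "objective": self.objective,
            "initiation_age": self.initiation_age,
            "fraction_replicating": self.fraction_replicating,
            "tv_distance": self.tv_distance,
            "converged": self.converged,
            "poor_fit": self.poor_fit,
            "average_mass": self.average_mass,
            "dna_per_mass": self.dna_per_mass,
        }
        if self.period_fractions is not None:
            d["period_fractions"] = {
                "B": self.period_fractions.frac_B,
                "C": self.period_fractions.frac_C,
                "D": self.period_fractions.frac_D,
            }
        return d


def theoretical_histogram(
    p: CellCycleParams,
    cv: float,
    calibration: float,
    n_channels: int = 1024,
    n_ages: int = 400,
    edges: np.ndarray | None = None,
) -> np.ndarray:
    """Expected channel probabilities of the measured DNA histogram.

    For each channel, probability = ∫ n(a)·Φ(channel | dna(a)·cal,
    cv·dna(a)·cal) da, evaluated by a fixed-order midpoint rule over age;
    out-of-range mass is absorbed into the end channels so the result sums
    to one.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if calibration <= 0:
        raise ValueError("calibration must be > 0")
    if edges is None:
        edges = np.arange(n_channels + 1, dtype=float)
    ages = (np.arange(n_ages) + 0.5) * (p.tau / n_ages)
    w = model.age_density(p.tau, ages)
    w = w / w.sum()
    mu = model.dna_at_ages(p, ages) * calibration

    if cv == 0:
        idx = np.clip(np.searchsorted(edges, mu, side="right") - 1, 0, len(edges) - 2)
        probs = np.zeros(len(edges) - 1)
        np.add.at(probs, idx, w)
        return probs

    sigma = cv * mu
    z = (edges[None, :] - mu[:, None]) / sigma[:, None]
    cdf = ndtr(z)
    cdf[:, 0] = 0.0  # clip: everything below the axis goes to channel 0
    cdf[:, -1] = 1.0  # and everything above into the last channel
    probs = w @ np.diff(cdf, axis=1)
    return probs


def fit_objective(observed: DNAHistogram, expected_probs: np.ndarray) -> float:
    """Sum of squared deviations between observed and expected channel counts."""
    expected_probs = np.asarray(expected_probs, dtype=float)
    if expected_probs.shape != observed.counts.shape:
        raise ValueError(
            f"channel count mismatch: {observed.counts.shape} vs {expected_probs.shape}"
        )
    resid = observed.counts - observed.n_cells * expected_probs
    return float(resid @ resid)


def _tv_distance(observed: DNAHistogram, expected_probs: np.ndarray) -> float:
    obs_freq = observed.counts / observed.n_cells
    return 0.5 * float(np.abs(obs_freq - expected_probs).sum())


def _expected_sampling_tv(probs: np.ndarray, n: int) -> float:
    """TV expected from multinomial noise alone: E|X_i − np_i| ≈ √(2np_i(1−p_i)/π)."""
    return float(np.sum(np.sqrt(2.0 * probs * (1.0 - probs) * n / np.pi)) / (2 * n))


def fit_cell_cycle(
    observed: DNAHistogram,
    tau: float,
    config: FitConfig | None = None,
    mass_mean: float | None = None,
) -> FitResult:
    """Recover (C, D, cv, calibration) from a DNA histogram given τ.

    Coarse grid over (C, D, cv) with the calibration pinned by matching the
    histogram mean to the model's average DNA, then Nelder–Mead refinement
    of all four parameters from the best grid point.  Ties on the grid break
    toward smaller C (parsimony).  Non-convergence and poor fits are
    flagged on the result, not raised.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if np.count_nonzero(observed.counts) < 2:
        raise ValueError("degenerate histogram: needs at least 2 non-empty channels")
    cfg = (config or FitConfig()).resolve(tau, observed)
    edges = observed.edges
    n_ch = observed.n_channels
    mean_sig = observed.mean_signal()

    def expected(theta):
        C, D, cv, cal = theta
        p = CellCycleParams(tau=tau, C=C, D=D)
        return theoretical_histogram(p, cv, cal, n_channels=n_ch,
                                     n_ages=cfg.n_ages, edges=edges)

    lo = (cfg.c_bounds[0], cfg.d_bounds[0], cfg.cv_bounds[0], cfg.cal_bounds[0])
    hi = (cfg.c_bounds[1], cfg.d_bounds[1], cfg.cv_bounds[1], cfg.cal_bounds[1])

    def objective(theta):
        if any(t < l or t > h for t, l, h in zip(theta, lo, hi)):
            return 1e18
        return fit_objective(observed, expected(theta))

    # --- grid stage: C ascending so strict improvement keeps the smallest C on ties
    c_grid = np.linspace(*cfg.c_bounds, cfg.n_grid_c)
    d_grid = np.linspace(*cfg.d_bounds, cfg.n_grid_d)
    evals = []
    for C in c_grid:
        for D in d_grid:
            avg_dna = model.average_dna_per_cell(CellCycleParams(tau=tau, C=C, D=D))
            cal = float(np.clip(mean_sig / avg_dna, *cfg.cal_bounds))
            point_best = None
            for cv in cfg.cv_grid:
                cv = float(np.clip(cv, *cfg.cv_bounds))
                val = objective((C, D, cv, cal))
                if point_best is None or val < point_best[0]:
                    point_best = (val, (C, D, cv, cal))
            evals.append(point_best)

    # The objective has ridges along C+D = const (initiation age) and local
    # valleys in neighbouring multifork regimes (different ⌈(C+D)/τ⌉), so
    # refine from the best grid point of each regime and keep the overall best.
    by_regime: dict = {}
    for val, theta in evals:
        n_gen = math.ceil((theta[0] + theta[1]) / tau - 1e-12)
        cur = by_regime.get(n_gen)
        if cur is None or val < cur[0]:
            by_regime[n_gen] = (val, theta)
    starts = sorted(by_regime.values(), key=lambda e: (e[0], e[1][0]))[:4]

    c_step = c_grid[1] - c_grid[0]
    d_step = d_grid[1] - d_grid[0]
    best = None
    for val0, theta0 in starts:
        # fine scan around the regime's best grid point before the simplex:
        # the ridge is curved in (C, D, calibration) and a raw coarse start
        # often strands the simplex on the wrong side of it
        C0, D0, cv0, _ = theta0
        refined = (val0, np.array(theta0))
        for C in np.clip(C0 + np.linspace(-c_step, c_step, 7), *cfg.c_bounds):
            for D in np.clip(D0 + np.linspace(-d_step, d_step, 7), *cfg.d_bounds):
                avg_dna = model.average_dna_per_cell(CellCycleParams(tau=tau, C=C, D=D))
                cal = float(np.clip(mean_sig / avg_dna, *cfg.cal_bounds))
                val = objective((C, D, cv0, cal))
                if val < refined[0]:
                    refined = (val, np.array((C, D, cv0, cal)))
        # nudge the start off any bound: a vertex pinned to a bound collapses
        # the clipped simplex in that dimension
        margin = 0.01 * (np.array(hi) - np.array(lo))
        x0 = np.clip(refined[1], np.array(lo) + margin, np.array(hi) - margin)
        res = optimize.minimize(
            objective,
            x0=x0,
            method="Nelder-Mead",
            bounds=optimize.Bounds(np.array(lo), np.array(hi)),
            options={
                "xatol": cfg.xatol,
                "fatol": cfg.fatol,
                "maxfev": cfg.max_evals,
                "adaptive": True,
            },
        )
        cand = (float(res.fun), res.x, bool(res.success)) if res.fun <= refined[0] \
            else (float(refined[0]), refined[1], False)
        if best is None or cand[0] < best[0]:
            best = cand

    obj, theta, converged = best
    C, D, cv, cal = (float(v) for v in theta)
    p = CellCycleParams(tau=tau, C=C, D=D)

    probs = expected(theta)
    tv = _tv_distance(observed, probs)
    fracs = model.period_fractions(p) if C + D < tau else None
    # the reflection estimator is sensitive to where the 1- and 2-equivalent
    # boundaries fall, so prefer the histogram's declared calibration over
    # the fitted one when available
    frac_rep = (
        fraction_replicating(observed, calibration=observed.calibration or cal)
        if C + D < tau else None
    )
    return FitResult(
        params=p,
        cv=cv,
        calibration=cal,
        objective=obj,
        initiation_age=model.initiation_age(p),
        period_fractions=fracs,
        fraction_replicating=frac_rep,
        tv_distance=tv,
        converged=converged,
        poor_fit=tv > cfg.poor_fit_ratio
        * _expected_sampling_tv(probs, observed.n_cells),
        average_mass=mass_mean,
        dna_per_mass=(None if mass_mean is None
                      else model.average_dna_per_cell(p) / mass_mean),
        config=cfg,
    )


def fraction_replicating(
    observed: DNAHistogram, calibration: float | None = None
) -> float:
    """Fraction of cells with DNA strictly between 1 and 2 genome equivalents.

    Instrument noise smears the 1- and 2-chromosome peaks symmetrically
    across the exact 1 and 2 positions, so raw channel counting misassigns
    roughly half of each peak.  This estimator uses the reflection rule:
    the mass of the 1-chromosome peak is twice the counts measured below
    1 genome equivalent plus the boundary channel itself (and symmetrically,
    above 2 for the 2-chromosome peak); replicating cells are the remainder.
    Valid for slow-growth histograms whose peaks sit at 1 and 2 equivalents.
    """
    cal = calibration if calibration is not None else observed.calibration
    if cal is None:
        raise ValueError("calibration required to locate the 1- and 2-equivalent peaks")
    total = observed.n_cells
    if total == 0:
        raise ValueError("empty histogram")
    edges = observed.edges
    c1 = int(np.clip(np.searchsorted(edges, 1.0 * cal, side="right") - 1,
                     0, observed.n_channels - 1))
    c2 = int(np.clip(np.searchsorted(edges, 2.0 * cal, side="right") - 1,
                     0, observed.n_channels - 1))
    counts = observed.counts
    # doubled outer counts estimate the symmetric halves of each peak; the
    # differential term catches a noiseless spike sitting on the boundary
    # channel without double counting the smeared case (where the boundary
    # channel mirrors its lower/upper neighbour)
    left1 = counts[c1 - 1] if c1 >= 1 else 0
    right2 = counts[c2 + 1] if c2 + 1 < counts.size else 0
    peak1 = 2 * counts[:c1].sum() + max(0, counts[c1] - left1)
    peak2 = 2 * counts[c2 + 1:].sum() + max(0, counts[c2] - right2)
    frac = 1.0 - (peak1 + peak2) / total
    return float(np.clip(frac, 0.0, 1.0))
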