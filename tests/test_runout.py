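"""Integer-peak decomposition of replication run-out histograms."""

import numpy as np
import pytest

from flowcycle.population import DNAHistogram, NoiseModel, measure_histogram, \
    runout_transform, sample_population
from flowcycle.model import CellCycleParams
from flowcycle.runout import (
    RunoutDecomposition,
    asynchrony_index,
    average_chromosome_number,
    decompose_runout,
)

FAST = CellCycleParams(tau=30, C=60, D=15)


def synthetic_runout(weights: dict, cal: float, cv: float, n: int, seed: int,
                     n_channels: int = 1024, with_cal: bool = True) -> DNAHistogram:
    """Histogram drawn directly from known integer-peak weights (oracle)."""
    rng = np.random.default_rng(seed)
    ks = np.array(sorted(weights))
    probs = np.array([weights[k] for k in ks], dtype=float)
    chroms = rng.choice(ks, size=n, p=probs / probs.sum())
    signal = chroms * cal * (1.0 + rng.normal(0.0, cv, size=n))
    counts = np.bincount(
        np.clip(np.floor(signal).astype(int), 0, n_channels - 1),
        minlength=n_channels)
    return DNAHistogram(edges=np.arange(n_channels + 1, dtype=float),
                        counts=counts, calibration=cal if with_cal else None)


def test_known_mixture_weights_are_recovered():
    truth = {1: 0.35, 2: 0.40, 4: 0.20, 3: 0.05}
    h = synthetic_runout(truth, cal=120.0, cv=0.03, n=30000, seed=31)
    d = decompose_runout(h)
    for k in range(1, d.max_chrom + 1):
        assert d.weight(k) == pytest.approx(truth.get(k, 0.0), abs=0.02)
    assert d.calibration == pytest.approx(120.0, rel=0.02)
    assert not d.flagged
    assert asynchrony_index(d) == pytest.approx(0.05, abs=0.02)


def test_decomposition_from_simulated_runout():
    s = sample_population(FAST, 20000, seed=32)
    r = runout_transform(s, reinit_prob=0.0, seed=33)
    h = measure_histogram(r, NoiseModel(cv=0.03), calibration=50.0,
                          n_channels=1024, seed=34)
    d = decompose_runout(h)
    # the 4-origin regime runs out to {4, 8} with the observed split
    observed_frac8 = float(np.mean(r.dna == 8.0))
    assert d.weight(4) == pytest.approx(1.0 - observed_frac8, abs=0.02)
    assert d.weight(8) == pytest.approx(observed_frac8, abs=0.02)
    assert sum(d.weight(k) for k in (1, 2, 4, 8, 16)) >= 0.98
    assert average_chromosome_number(d) == pytest.approx(r.dna.mean(), rel=0.02)


def test_reinitiation_produces_asynchronous_peaks():
    s = sample_population(FAST, 20000, seed=35)
    r = runout_transform(s, reinit_prob=0.3, seed=36)
    h = measure_histogram(r, NoiseModel(cv=0.03), calibration=50.0,
                          n_channels=1024, seed=37)
    d = decompose_runout(h)
    true_async = float(np.mean(~np.isin(r.dna, (1.0, 2.0, 4.0, 8.0, 16.0))))
    assert asynchrony_index(d) == pytest.approx(true_async, abs=0.03)
    assert average_chromosome_number(d) == pytest.approx(r.dna.mean(), rel=0.02)


def test_weights_invariant_under_axis_rescaling():
    # same cells, different instrument gain, calibration refit from scratch
    truth = {4: 0.6, 8: 0.4}
    a = synthetic_runout(truth, cal=50.0, cv=0.03, n=20000, seed=38,
                         with_cal=False)
    b = synthetic_runout(truth, cal=85.0, cv=0.03, n=20000, seed=38,
                         with_cal=False, n_channels=2048)
    da, db = decompose_runout(a), decompose_runout(b)
    assert np.allclose(da.weights, db.weights, atol=0.02)
    assert db.calibration / da.calibration == pytest.approx(85.0 / 50.0, rel=0.03)


def test_supplied_calibration_pins_the_peak_assignment():
    # {4, 8} at cal 50 is indistinguishable from {1, 2} at cal 200 without
    # an anchor; the histogram's own calibration resolves it
    truth = {4: 0.6, 8: 0.4}
    h = synthetic_runout(truth, cal=50.0, cv=0.03, n=20000, seed=39)
    d = decompose_runout(h)
    assert d.weight(4) == pytest.approx(0.6, abs=0.02)
    assert d.weight(8) == pytest.approx(0.4, abs=0.02)
    assert d.calibration == pytest.approx(50.0, rel=0.05)


def test_structureless_histogram_is_flagged():
    rng = np.random.default_rng(40)
    counts = rng.integers(50, 60, size=512)
    h = DNAHistogram(edges=np.arange(513, dtype=float), counts=counts)
    d = decompose_runout(h)
    assert d.flagged


def test_decomposition_summaries():
    w = np.zeros(16)
    w[[0, 1, 2, 3]] = (0.4, 0.3, 0.1, 0.2)  # chromosomes 1, 2, 3, 4
    d = RunoutDecomposition(weights=w, cv=0.03, calibration=100.0, residual=0.0)
    assert asynchrony_index(d) == pytest.approx(0.1)
    assert average_chromosome_number(d) == pytest.approx(
        1 * 0.4 + 2 * 0.3 + 3 * 0.1 + 4 * 0.2)
    assert d.weight(3) == pytest.approx(0.1)
    assert d.weight(99) == 0.0
    js = d.to_dict()
    assert js["weights"]["3"] == pytest.approx(0.1)


def test_decomposition_validation():
    with pytest.raises(ValueError):
        RunoutDecomposition(weights=np.array([-0.1, 1.1]), cv=0.03,
                            calibration=10.0, residual=0.0)
    with pytest.raises(ValueError):
        RunoutDecomposition(weights=np.array([0.2, 0.2]), cv=0.03,
                            calibration=10.0, residual=0.0)
    h = DNAHistogram(edges=np.arange(513, dtype=float),
                     counts=np.zeros(512, dtype=int))
    with pytest.raises(ValueError):
        decompose_runout(h)
    with pytest.raises(ValueError):
        decompose_runout(
            DNAHistogram(edges=np.arange(513, dtype=float),
                         counts=np.ones(512, dtype=int)), max_chrom=1)
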