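# Methods

## The age-structured cell-cycle model

A steady-state exponential culture with doubling time τ has age density
n(a) = (2 ln2/τ)·2^(−a/τ) on [0, τ): newborn cells are twice as frequent as
dividing cells. Replication takes C minutes per chromosome; division follows
termination after D minutes. Working backwards from division, a round of
replication that terminates D minutes before a division must have initiated
C + D minutes before it, i.e. at cell age

a_i = ⌈(C+D)/τ⌉·τ − (C+D),

counted in the generation where the initiation falls. All origins fire
together at a_i; their number is 2^(⌈(C+D)/τ⌉−1), doubling to twice that for
cells older than a_i. When C + D < τ the cycle has a B period (birth to
initiation) of τ − C − D and the population splits into fractions

frac_B = 2 − 2^(1−B/τ), frac_C = 2^(1−B/τ) − 2^(1−(B+C)/τ),
frac_D = 2^(1−(B+C)/τ) − 1.

A cell of age a carries a ladder of active replication rounds: round m
(m = 0 in this cell, m ≥ 1 initiated in ancestors) started at lineage time
a_i − mτ and is active while 0 ≤ a − t_m < C. A physically separate
chromosome with R active rounds contributes 1 + Σ_r 2^r·f_r genome
equivalents (r = 0 the oldest round, f_r the completed fraction).
Integrating over the age density gives the closed forms

average DNA = (τ/(C ln2))·(2^((C+D)/τ) − 2^(D/τ)),
average origins = 2^((C+D)/τ), average mass = 2 ln2

(mass grows exponentially from 1 at birth to 2 at division).

Two independent implementations of the per-cell configuration are kept: the
closed-form round enumeration, and an event-driven replay of the cell's
ancestry (initiations, terminations, divisions, with ties ordered
termination → division → initiation). The replay starts at an ancestral
birth more than C + D + 2τ in the past; replication rounds already in flight
at that time are not replayed, and their missing terminations are
compensated exactly by seeding the start with 2^(⌈(C+D)/τ⌉−1) chromosomes.
The two paths are required to agree in the test suite and serve as each
other's oracle.

## Synthetic populations and measurement

Ages are drawn by inverse transform, a = −τ·log2(1 − u/2). DNA and origin
counts are deterministic functions of age. Measurement multiplies DNA by a
channel calibration (channels per genome equivalent) and by (1 + ε) with
ε ~ N(0, cv²), then bins into unit-width channels, clipping out-of-range
signals into the end channels so counts are conserved. Replication run-out
(rifampicin + cephalexin) replaces each cell's DNA by its integer origin
count; with a per-origin re-initiation probability p each origin
independently adds one further chromosome (binomial), modelling
drug-resistant initiation.

Generator realism limits: noise is purely multiplicative and Gaussian (no
autofluorescence floor, debris, doublets or dead-time losses); ages are
exactly steady-state (no mother-daughter correlations or division-size
noise); all origins fire perfectly synchronously unless the run-out
re-initiation channel is used; mass is a deterministic exponential of age.

## Histogram fitting

The expected histogram under (C, D, cv, calibration) is computed by a
fixed-order midpoint quadrature over age: each age contributes a normal
channel-mass profile centred at dna(a)·calibration with standard deviation
cv·dna(a)·calibration, and out-of-range mass is absorbed into the end
channels. The objective is the sum of squared deviations between observed
and expected channel counts.

The objective surface has ridges along C + D ≈ const (fixed initiation age)
and separate valleys in neighbouring multifork regimes (different
⌈(C+D)/τ⌉). The search therefore proceeds in stages: a coarse (C, D, cv)
grid with the calibration pinned at each point by matching the histogram
mean to the model's average DNA; the best grid point of each regime is
refined by a local fine scan and then by bounded Nelder–Mead over all four
parameters, starting slightly off any bound (a simplex vertex pinned to a
bound collapses the clipped simplex). Ties break toward smaller C.

Two identifiability choices are deliberate:

- D is searched within [0, τ): (C, D + τ) with a halved calibration produces
  an identical histogram, so D is reported as the parsimonious
  representative of its equivalence class.
- When the histogram carries a calibration (established experimentally from
  run-out integer peaks), the fitted calibration is bounded to ±15% of it.
  With a fully free calibration the histogram is nearly invariant under
  C → C/2 at a rescaled axis, making C unidentifiable.

A fit is flagged `poor_fit` when the total-variation distance between the
observed and fitted histograms exceeds twice the TV expected from
multinomial sampling noise alone under the fitted model
(E|X − np| ≈ √(2np(1−p)/π)); a fixed TV threshold would misfire because the
sampling TV itself varies severalfold with channel count and histogram
shape.

The fraction of replicating cells in slow-growth histograms uses a
reflection estimator: instrument noise smears the 1- and 2-chromosome peaks
symmetrically about their centres, so the 1-chromosome peak mass is
estimated as twice the counts below 1 genome equivalent (plus a boundary
correction that handles a noiseless spike without double counting), and
symmetrically above 2 for the 2-chromosome peak; replicating cells are the
remainder. The estimator degrades with noise — early-S cells just above 1
equivalent leak below the boundary as cv grows — and is validated in the
suite to ±0.02 at cv 0.02, ±0.03 at 0.04, ±0.05 at 0.06.

## Run-out decomposition

Run-out histograms are mixtures of peaks at integer multiples of the
calibration. Component means are anchored at k × calibration (k = 1…16)
with one shared CV, leaving non-negative weights (solved by NNLS) plus the
(calibration, cv) pair (refined by Nelder–Mead on the NNLS residual).
Weights below 0.5% are truncated and the rest renormalised. The asynchrony
index is the total weight on non-power-of-two chromosome numbers.

The integer grid is self-similar — peaks at {k} with calibration c fit
exactly as well as {m·k} with c/m — so the assignment is pinned by the
histogram's own calibration (±15%) when present; without one, candidate
calibrations are tried from largest to smallest and an incumbent is only
replaced on a >0.1% residual improvement, resolving ties to the smallest
chromosome numbers and making the weights invariant under uniform rescaling
of the channel axis. A decomposition is flagged when the observed-vs-model
TV exceeds twice the expected sampling TV, or when the fitted component CV
exceeds 12% — at that width adjacent integer peaks are no longer resolvable
and the integer-peak reading of the histogram has broken down.

## Quantification arithmetic

Relative protein concentrations are means ± sample SD of per-replicate
ratios (paired per gel). ATP-DnaA accounting rounds total × percent/100 to
the nearest molecule; relative ATP concentrations are reported to two
significant figures and expression fold changes to two decimals, matching
the precision conventions of the tables they reproduce. The
marker-frequency relation is oriC/ter = 2^(C/τ) (the ratio of average origin
to average terminus copy number, 2^((C+D)/τ)/2^(D/τ)); its inverse is
C = τ·log2(ratio), defined for ratios ≥ 1 after normalising a
non-replicating control to 1.

## Numerical choices

- Histogram quadrature: 200 age points during fitting, 400 for reference
  evaluations; channel masses via the normal CDF (`scipy.special.ndtr`).
- Fitter budget: 24 × 12 (C, D) grid, cv grid {0.03, 0.06, 0.10}, up to 4
  regime starts, 7 × 7 fine scan, Nelder–Mead with xatol 0.02 min.
- Closed-form vs quadrature comparisons use 20,001-point trapezoid/midpoint
  sums; agreement is required to 0.5%.
- All stochastic steps take explicit integer seeds; scenario datasets derive
  sub-seeds (+10, +20, +30) for noise, run-out and run-out noise so each
  stage is independently reproducible.

## Limitations

- The model assumes perfectly synchronous initiation at all origins and a
  single (C, D) for the whole population; heterogeneous cultures are flagged
  rather than fitted, by design.
- C and D enter the likelihood only through the DNA-vs-age profile;
  for C + D ≥ τ the B/C/D period fractions are undefined and not reported.
- The reflection estimator of the replicating fraction requires peaks at 1
  and 2 genome equivalents (slow growth) and a known calibration.
- Fitted parameters inherit the generator's idealisations; on real
  instruments the unmodelled noise floor and debris will bias cv and the
  low-channel fit, and the ±15% calibration anchor presumes a run-out-based
  calibration of the same instrument session.
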