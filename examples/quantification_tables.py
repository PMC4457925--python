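"""Quantification arithmetic: DnaA accounting, fold changes, marker ratios."""

from flowcycle import quant
from flowcycle.model import CellCycleParams
from flowcycle.quant import AtpAccounting, BlotSeries, ExpressionPair

# ATP-bound DnaA molecules per cell: overproducer vs wild type
wild = AtpAccounting(total_molecules=1000, percent_atp=41.0, strain="wild type")
over = AtpAccounting(total_molecules=2000, percent_atp=37.0, strain="overproducer")
print(f"{wild.strain}: {wild.molecules_atp} ATP-DnaA molecules")
print(f"{over.strain}: {over.molecules_atp} ATP-DnaA molecules "
      f"({quant.relative_atp_concentration(over, wild):g}x relative)")

# relative protein concentration from paired replicate blots
mean, sd = quant.relative_concentration(
    BlotSeries((3.1, 3.6, 3.3), strain="overproducer"),
    BlotSeries((1.9, 2.0, 1.8), strain="wild type"))
print(f"relative DnaA concentration: {quant.format_mean_sd(mean, sd)}")

# expression fold changes between two growth conditions
for gene, a, b in [("dnaA", 61, 165), ("ybhB", 117, 1087),
                   ("bioA", 32, 194), ("pka", 103, 171)]:
    fc = quant.fold_change(ExpressionPair(gene, a, b))
    print(f"{gene}: {fc:.2f}-fold")

# replication period from the oriC/ter copy-number ratio
p = CellCycleParams(tau=240, C=80, D=13)
ratio = quant.expected_marker_ratio(p)
print(f"expected oriC/ter at C={p.C}, tau={p.tau}: {ratio:.3f}")
print(f"back-computed C: {quant.c_from_marker_ratio(ratio, p.tau):.1f} min")
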