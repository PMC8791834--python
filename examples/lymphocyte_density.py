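"""Estimate lymphocyte density from a classified cell table.

For each lymphocyte the local density is Sigma_N = N / (pi * d_N^2) where
d_N is the distance to the Nth nearest lymphocyte (N = 50); the slide-level
feature is the median per-cell density.  A stability sweep over N = 40..60
confirms the choice of N barely matters.
"""

import numpy as np

from neoresponse import pathfeat
from neoresponse.synth import simulate_cells

rng = np.random.default_rng(11)
true_intensity = 0.004  # lymphocytes per px^2
cells = simulate_cells(
    {"cancer": 0.006, "stromal": 0.004, "lymphocyte": true_intensity},
    window=(1000.0, 1000.0), rng=rng,
)

fractions = pathfeat.cell_fractions(cells)
print("cell fractions:", fractions.round(3).to_dict())

per_cell, summary = pathfeat.knn_density(cells, "lymphocyte", n_neighbours=50)
print(f"median density: {summary.median:.5f} px^-2 "
      f"(true intensity {true_intensity})")
print(f"relative error: {abs(summary.median - true_intensity) / true_intensity:.1%}")

table, deviation = pathfeat.density_stability(cells, "lymphocyte")
print("\nstability over N = 40..60:")
print(table.round(5).to_string(index=False))
print(f"max relative deviation vs N=50: {deviation:.1%}")
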