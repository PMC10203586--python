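#!/usr/bin/env python
"""Simulate the study dataset.

Generates the desk-scale multi-environment trial used throughout the
analysis: 10 elite crosses (8 biparental, 2 three-way) x 32 F2:4 lines,
bulk-genotyped at 300 markers, grown in four site-year environments with
between-environment genetic correlation 0.3, a modified alpha-lattice
layout with the full trial's unbalanced replication pattern, and a ~110
trait phenomic panel in ~40 redundancy groups. Writes the dataset bundle
and the realized genetic-correlation matrix under results/dataset/.
"""

import numpy as np
import pandas as pd

from phenosel import io
from phenosel.simdata import simulate_study
from phenosel.studies import core_conditions
from _common import RESULTS, SEED

out = RESULTS / "dataset"
out.mkdir(parents=True, exist_ok=True)

sim = simulate_study(core_conditions(), SEED)
io.write_genotypes_csv(sim.genotypes, out / "genotypes.csv")
io.write_genotypes_vcf(sim.genotypes, out / "genotypes.vcf")
io.write_table(sim.design, out / "design.csv")
io.write_table(sim.plots, out / "plots.csv")
io.write_table(sim.panel, out / "panel.csv")
io.write_table(sim.truth.genetic_values, out / "truth_genetic_values.csv", index=True)

realized = pd.DataFrame(
    np.corrcoef(sim.truth.genetic_values.to_numpy().T),
    index=sim.env_ids, columns=sim.env_ids,
)
io.write_table(realized, out / "realized_genetic_correlations.csv", index=True)

print(f"{len(sim.line_ids)} lines x {sim.genotypes.shape[1]} markers, "
      f"{len(sim.plots)} plots over {len(sim.env_ids)} environments, "
      f"{len(sim.trait_ids)} traits in {sim.panel['group'].nunique()} groups")
print("realized between-environment genetic correlations:")
print(realized.round(3).to_string())
print(f"wrote dataset bundle to {out}")
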