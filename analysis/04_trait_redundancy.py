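#!/usr/bin/env python
"""Trait redundancy and dimensionality reduction.

Counts unique (non-redundant) traits across a sweep of correlation
thresholds, computes the cumulative PCA variance curve of the panel, and
extracts the first three principal components and yield-supervised PLS
components of the line-level trait BLUEs, with their correlation to yield
and dominant trait categories. Writes results/traits/.
"""

import numpy as np
import pandas as pd

from phenosel import io, trait_reduction
from _common import RESULTS

out = RESULTS / "traits"
out.mkdir(parents=True, exist_ok=True)

plots = io.read_table(RESULTS / "dataset" / "plots.csv")
panel = io.read_table(RESULTS / "dataset" / "panel.csv")
blues = io.read_table(RESULTS / "blues" / "blues.csv")
traits = list(panel["trait_id"])

sweep = [0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99]
counts = [trait_reduction.unique_trait_count(plots[traits], t) for t in sweep]
io.write_table(pd.DataFrame({"threshold": sweep, "unique_traits": counts}),
               out / "unique_trait_counts.csv")
print(f"{len(traits)} traits collapse to "
      f"{dict(zip(sweep, counts))[0.9]} distinct traits at |r| < 0.9")

cum = trait_reduction.pca_cumvar(plots[traits])
io.write_table(pd.DataFrame({"component": np.arange(1, len(cum) + 1),
                             "cumulative_variance": cum}),
               out / "pca_cumulative_variance.csv")
print(f"first 3 PCs explain {cum[2]:.1%} of the panel variance")

wide = blues.groupby("line")[traits].mean()
y = blues.groupby("line")["yield_t_ha"].mean().reindex(wide.index)
pco = trait_reduction.select_pco(wide, y.to_numpy(), k=3, panel=panel)
pls = trait_reduction.pls_components(wide, y.to_numpy(), k=3, panel=panel)

summary = pd.concat([
    pd.DataFrame({"component": pco.yield_corr.index,
                  "yield_corr": pco.yield_corr.to_numpy()}),
    pd.DataFrame({"component": pls.yield_corr.index,
                  "yield_corr": pls.yield_corr.to_numpy()}),
])
dom = pls.dominant_categories.astype(int)
dom.insert(0, "component", dom.index)
io.write_table(summary, out / "component_yield_correlations.csv")
io.write_table(dom, out / "pls_dominant_categories.csv")
io.write_table(pd.concat([pco.scores, pls.scores], axis=1),
               out / "component_scores.csv", index=True)

print("component correlations with yield (PCO unsupervised, PLS supervised):")
print(summary.round(3).to_string(index=False))
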