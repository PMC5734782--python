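"""Generate a synthetic endophyte-like dataset and inspect its structure.

Builds a two-group community count table from the "strong" preset (a
pronounced geographic-style contrast, 24 + 14 samples at 20,000 reads each),
and prints its shape, depth, and richness.
"""

import numpy as np

from betaci import preset, simulate_grouped_dataset

table, groups, hierarchy = simulate_grouped_dataset(preset("strong", seed=1))

richness = (table.counts > 0).sum(axis=0)
print(f"taxa × samples: {table.n_taxa} × {table.n_samples}")
print(f"groups: {groups.labels()} with sizes "
      f"{[len(groups.samples(g)) for g in groups.labels()]}")
print(f"reads per sample: {table.sample_totals()[0]}")
print(f"observed richness per sample: min {richness.min()}, "
      f"median {int(np.median(richness))}, max {richness.max()}")
print(f"hierarchy levels (finest → coarsest): {hierarchy.levels}")

# Each sample is one multinomial draw from its group's lognormal taxon
# weights; the median sample detects only a fraction of the 500 taxa, which
# is what makes sequencing depth matter downstream.
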