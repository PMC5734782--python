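"""Neutral drift is only detectable with deep sequencing.

Drifts two communities for 20 generations from one census population of 954
taxa and five million individuals (Wright-Fisher resampling), then asks at
each sequencing depth whether ANOSIM on raw counts can tell them apart with
20 samples per community.
"""

from betaci import DriftConfig, community_stats, drift_experiment, lognormal_community

community = lognormal_community(954, population_size=5_000_000, seed=1)
stats = community_stats(community)
print(f"seed community: richness {stats.richness}, "
      f"heterozygosity {stats.heterozygosity:.3f}")

config = DriftConfig(
    generations=20,
    n_replicates_per_community=(20,),
    depth_grid=(100, 1000, 5000, 10000, 50000, 100000),
    n_permutations=1000,
    seed=1,
)
frame = drift_experiment(community, config, metric="bray-curtis")
print("\n  depth   ANOSIM R       p")
for row in frame.itertuples():
    mark = "  <- detected" if row.p < 0.05 else ""
    print(f"{row.depth:>7d}   {row.R:+.3f}   {row.p:.3f}{mark}")

# Drift moves rare taxa proportionally far more than abundant ones.  At 100
# reads/sample the two communities look identical; detection emerges once
# the depth samples the rare tail (here around 1% of the census population,
# 50,000 reads).
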