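"""Sequencing depth, rare taxa, and the two dissimilarity metrics.

On rare-turnover data (groups differ only in which rare taxa they carry),
sweeps rarefaction depth at fixed effort and contrasts the PERMANOVA R²
confidence intervals under Bray-Curtis vs binary Jaccard.
"""

from betaci import SweepConfig, ci_width_decrease, preset, run_sweep, simulate_grouped_dataset

table, groups, _ = simulate_grouped_dataset(preset("rare-turnover", seed=1))

for metric in ("bray-curtis", "jaccard"):
    config = SweepConfig(
        effort_grid=(20,),
        depth_grid=(100, 1000, 5000, 20000),
        metric=metric,
        test="PERMANOVA",
        n_boot=200,
        normalization="none",
        seed=1,
    )
    records = run_sweep(table, groups, None, config)
    print(f"\n{metric}: depth  mean R²  95% CI           width")
    for r in records:
        print(f"  {r.depth:>12d}   {r.mean:.3f}  "
              f"[{r.lower:.3f}, {r.upper:.3f}]   {r.width:.3f}")
    decrease = ci_width_decrease(records, 100, 20000)
    print(f"  CI width decrease from depth 100 to 20,000: {decrease:+.1f}%")

# The abundance-weighted metric settles as depth grows; the presence/absence
# metric keeps responding to the rare tail, so its interval can stay wide
# (or widen) even at high depth — rare taxa carry its signal and its noise.
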