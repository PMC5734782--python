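"""How sampling effort drives the precision of effect-size estimates.

Bootstrap-resamples the strong preset at increasing per-group sample sizes
(with replacement, CSS normalization) and prints the 95% percentile CI of
ANOSIM R at each effort: the interval narrows as effort grows.
"""

from betaci import SweepConfig, preset, run_sweep, simulate_grouped_dataset

table, groups, _ = simulate_grouped_dataset(preset("strong", seed=1))
config = SweepConfig(
    effort_grid=(5, 10, 20, 40, 60),
    metric="bray-curtis",
    test="ANOSIM",
    n_boot=200,
    normalization="css",
    seed=1,
)

print("effort   mean R   95% CI           width")
for record in run_sweep(table, groups, None, config):
    print(f"{record.effort:6d}   {record.mean:.3f}   "
          f"[{record.lower:.3f}, {record.upper:.3f}]   {record.width:.3f}")

# With 5 samples per group the CI spans half the R scale — a single study
# at that effort could report anything in that range.  By 40-60 samples the
# interval is a few hundredths wide.
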