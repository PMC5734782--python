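"""ANOSIM and PERMANOVA effect sizes with permutation p-values.

Compares the "strong" and "weak" presets: Bray-Curtis dissimilarity on
CSS-normalized counts, then both tests with 999 permutations.
"""

from betaci import (
    bray_curtis,
    css_normalize,
    permutation_test,
    preset,
    simulate_grouped_dataset,
)

for name in ("strong", "weak"):
    table, groups, _ = simulate_grouped_dataset(preset(name, seed=1))
    dm = bray_curtis(css_normalize(table))
    for test in ("ANOSIM", "PERMANOVA"):
        result = permutation_test(dm, groups, test=test, n_permutations=999, seed=1)
        extra = "" if result.pseudo_F is None else f", pseudo-F = {result.pseudo_F:.2f}"
        print(f"{name:6s} {test:9s}: statistic = {result.statistic:.3f}"
              f"{extra}, p = {result.p_value:.3f}  (n = {result.n_samples})")

# ANOSIM R near 1 means between-group dissimilarities outrank within-group
# ones almost completely; PERMANOVA R² is the fraction of the total sum of
# squared dissimilarities explained by the grouping.  Both presets are
# significant at p < 0.05 — the point of the CI analysis is that equal
# significance can hide very different effect sizes.
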