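"""Localise a 5'-restricted effect with sliding windows and regional tests.

The effect (beta = 4) is planted only within the first 60 nucleotides —
the translation-initiation region — so early windows should show larger
odds ratios than downstream ones, and only the (1, 60) regional test should
reach significance.
"""

import numpy as np

from foldcons import (
    FoldParams,
    SimConfig,
    annotate_dataset,
    generate_dataset,
    regional_correlation_test,
    sliding_windows,
    windowed_analysis,
)

config = SimConfig(n_genes=30, n_species=8, gene_length=100,
                   effect_beta=4.0, effect_region=(1, 60), seed=11)
dataset = generate_dataset(config, FoldParams(flank=40))
sites = annotate_dataset(dataset)

print("window      OR_MH   p        sensitive%")
for w in windowed_analysis(sites, sliding_windows(36, 12, 109)):
    or_str = f"{w['or_mh']:.3f}" if np.isfinite(w["or_mh"]) else "  -  "
    print(f"[{w['window_start']:3d},{w['window_end']:3d}]  {or_str:>7s} "
          f"{w['p_two_sided']:.3f}    {100 * w['sensitive_fraction']:.1f}")

for region in [(1, 60), (91, 150)]:
    res = regional_correlation_test(sites, region, n_perm=500, seed=11)
    print(f"region {region}: mean r = {res.mean_r:.3f}, "
          f"left-tail p = {res.p_left:.4f}")

print()
print("Windows overlapping the first 60 nt inherit the planted effect")
print("(OR above 1) while downstream windows hover around 1, and the")
print("initiation-region test's left-tail p is far smaller than the")
print("elongation region's; at this demo size (30 genes) it does not")
print("always cross 0.05 — the full-scale study in the test suite does.")
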