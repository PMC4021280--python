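"""Simulate orthologs with a planted structure-conservation coupling and
recover it with the Mantel-Haenszel and permutation tests.

Sensitive 4-fold sites evolve at rate r/(1+beta); with beta = 4 they diverge
five times more slowly than the rest, which should surface as OR_MH > 1 and
a negative mean correlation between sensitivity and E_w.
"""

from foldcons import (
    FoldParams,
    SimConfig,
    annotate_dataset,
    constrained_permutation_test,
    generate_dataset,
    run_species_analysis,
)

config = SimConfig(n_genes=25, n_species=8, gene_length=100,
                   effect_beta=4.0, seed=7)
dataset = generate_dataset(config, FoldParams(flank=40))
sites = annotate_dataset(dataset)

mh, tables, sens_frac = run_species_analysis(sites)
print(f"genes: {len(tables)}, 4-fold sites: {sum(t.s for t in tables.values())}")
print(f"OR_MH = {mh.or_mh:.3f} (95% CI {mh.ci95[0]:.3f}-{mh.ci95[1]:.3f}), "
      f"chi2 = {mh.chi2:.2f}, p = {mh.p_two_sided:.2e}")

perm = constrained_permutation_test(sites, n_perm=500, seed=7)
print(f"mean per-gene r(sensitivity, E_w) = {perm.mean_r:.3f}, "
      f"left-tail p = {perm.p_left:.4f}")

print()
print("OR_MH > 1 with a small p means structurally sensitive sites are")
print("over-represented among conserved sites; the negative mean correlation")
print("shows the same association without dichotomising either variable.")
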