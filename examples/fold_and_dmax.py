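"""Fold a designed hairpin and score how much a point mutation disrupts it.

Builds a 12-nt stem-loop, computes exact base-pair probabilities, then
compares a stem mutation against a loop mutation with the local structural
distance d_max.
"""

from foldcons import FoldParams, d_max, partition_bpp

params = FoldParams(flank=40, temperature=250.0)
wild_type = "GGGGAAAACCCC"  # 4-bp stem enclosing a 4-nt loop

bp = partition_bpp(wild_type, params)
print("wild-type stem pair probabilities (1-12, 2-11, 3-10, 4-9):")
print("  ", [round(float(bp.P[i, 11 - i]), 3) for i in range(4)])

stem_mutant = "GAGGAAAACCCC"  # G2A breaks a stem pair
loop_mutant = "GGGGACAACCCC"  # A6C sits in the loop

for name, mutant in [("stem G2A", stem_mutant), ("loop A6C", loop_mutant)]:
    score = d_max(bp, partition_bpp(mutant, params), d_min_span=10)
    print(f"d_max for {name}: {score:.4f}")

print()
print("The stem mutation dissolves the helix (large d_max); the loop")
print("mutation barely moves the ensemble. d_max is the maximum over local")
print("subintervals of the length-normalised distance between the two")
print("base-pair probability matrices.")
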