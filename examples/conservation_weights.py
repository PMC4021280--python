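"""Phylogenetic leaf weights and weighted column entropy E_w.

Shows how equal-split weights down-weight a pair of nearly identical species
so that a shared derived nucleotide is not counted twice, and how E_w
summarises an alignment column.
"""

from foldcons import leaf_weights, weighted_entropy

# A and B are very close relatives; C is an outgroup at distance 1
wt = leaf_weights("((A:0.01,B:0.01):1,C:1);")
print("equal-split weights:", {k: round(v, 3) for k, v in wt.weights.items()})

for label, column in [
    ("invariant column", {"A": "G", "B": "G", "C": "G"}),
    ("outgroup differs", {"A": "G", "B": "G", "C": "T"}),
    ("close pair differs", {"A": "G", "B": "T", "C": "G"}),
]:
    res = weighted_entropy(column, wt)
    conserved = "conserved" if res.E_w < 0.5 else "not conserved"
    print(f"{label:20s} E_w = {res.E_w:.3f} bits ({conserved})")

print()
print("E_w = 0 means no variation; 2 bits is the maximum. Because A and B")
print("share most of their history, a difference in the A/B pair moves E_w")
print("less than the same difference in the independent outgroup lineage.")
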