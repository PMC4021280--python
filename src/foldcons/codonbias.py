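"""Codon usage bias via ENC' (composition-corrected effective number of codons).

ENC' extends Wright's effective number of codons by measuring each
synonymous family's deviation from the frequencies *expected under the
gene's background nucleotide composition* rather than from uniformity, so
that compositional bias (e.g. GC-rich genomes) is not mistaken for
translational selection.  ENC' = 20 means one codon per amino acid (maximal
bias); 61 means no bias at all.

For each synonymous family with k codons and n counted codons:

    X^2 = n * sum_i (p_i - e_i)^2 / e_i
    F'  = (X^2 + n - k) / (k * (n - 1))          (n > 1)

where e_i are the background-expected within-family frequencies.  Class
averages F'_k are weighted by family counts and combined as

    ENC' = 2 + 9/F'_2 + 1/F'_3 + 5/F'_4 + 3/F'_6

with Wright's interpolation F'_3 ~ (F'_2 + F'_4)/2 when the 3-fold class is
missing, clipped to [20, 61].
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "CodonCounts",
    "SYNONYMOUS_FAMILIES",
    "codon_counts_from_cds",
    "encprime",
    "median_split",
]


def _build_families() -> list:
    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: dict = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    return [tuple(sorted(codons)) for codons in by_aa.values()]


#: synonymous codon families of the standard genetic code (stops excluded)
SYNONYMOUS_FAMILIES = _build_families()

_CLASS_MULTIPLICITY = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}


@dataclass
class CodonCounts:
    """Per-codon counts for one gene plus its background composition."""

    gene_id: str
    counts: dict  # codon -> count (stop codons excluded)
    background: dict = field(default_factory=dict)  # nt -> frequency

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative codon count")
        if not self.background:
            nt = Counter()
            for codon, c in self.counts.items():
                for ch in codon:
                    nt[ch] += c
            total = sum(nt.values())
            if total == 0:
                raise ValueError(f"{self.gene_id}: no counted codons")
            self.background = {b: nt.get(b, 0) / total for b in "ACGT"}

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())


def codon_counts_from_cds(gene_id: str, cds: str) -> CodonCounts:
    """Count codons of an in-frame CDS, dropping stop codons."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"{gene_id}: CDS length {len(cds)} not a multiple of 3")
    stops = {"TAA", "TAG", "TGA"}
    counts: Counter = Counter()
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in stops or "N" in codon:
            continue
        counts[codon] += 1
    return CodonCounts(gene_id=gene_id, counts=dict(counts))


def _expected_family_frequencies(family, background) -> np.ndarray:
    """Background-expected within-family codon frequencies.

    Product of background frequencies over the positions at which the family's
    codons actually vary, renormalized within the family.
    """
    varying = [p for p in range(3) if len({c[p] for c in family}) > 1]
    if not varying:
        return np.ones(len(family)) / len(family)
    raw = np.array(
        [np.prod([background[c[p]] for p in varying]) for c in family], dtype=float
    )
    if raw.sum() <= 0:
        return np.ones(len(family)) / len(family)
    return raw / raw.sum()


def encprime(codon_counts: CodonCounts, min_codons: int = 10) -> float:
    """Background-corrected effective number of codons, in [20, 61].

    Genes with fewer than ``min_codons`` counted codons return nan with a
    warning and are excluded from stratification by the caller.
    """
    if codon_counts.n_codons < min_codons:
        warnings.warn(
            f"{codon_counts.gene_id}: only {codon_counts.n_codons} codons; "
            "ENC' undefined"
        )
        return float("nan")
    class_num: dict = {}
    class_den: dict = {}
    for family in SYNONYMOUS_FAMILIES:
        k = len(family)
        if k == 1:
            continue  # Met, Trp contribute the constant 2
        counts = np.array([codon_counts.counts.get(c, 0) for c in family], dtype=float)
        n = counts.sum()
        if n < 2:
            continue
        p = counts / n
        e = _expected_family_frequencies(family, codon_counts.background)
        chi2 = n * float(((p - e) ** 2 / e).sum())
        f_prime = (chi2 + n - k) / (k * (n - 1))
        class_num[k] = class_num.get(k, 0.0) + n * f_prime
        class_den[k] = class_den.get(k, 0.0) + n
    class_f = {k: class_num[k] / class_den[k] for k in class_num}
    if 3 not in class_f and 2 in class_f and 4 in class_f:
        class_f[3] = (class_f[2] + class_f[4]) / 2.0
    enc = 2.0
    for k, mult in _CLASS_MULTIPLICITY.items():
        f = class_f.get(k, 1.0 / k)  # neutral fallback for an absent class
        enc += mult / max(f, 1e-12)
    return float(min(61.0, max(20.0, enc)))


def median_split(values_by_gene: dict) -> tuple:
    """Split genes into (top_half_ids, bottom_half_ids) by value.

    Genes are sorted by (value, gene_id); exact ties at the median fall into
    the bottom half via the stable gene-id order, and with an odd count the
    bottom half gets the extra gene.  Genes with nan values are excluded.
    """
    items = [
        (gid, v)
        for gid, v in values_by_gene.items()
        if v is not None and not np.isnan(v)
    ]
    if len(items) < 2:
        raise ValueError("median split needs >= 2 genes with defined values")
    items.sort(key=lambda kv: (kv[1], kv[0]))
    n_bottom = (len(items) + 1) // 2
    bottom = [gid for gid, _ in items[:n_bottom]]
    top = [gid for gid, _ in items[n_bottom:]]
    return top, bottom
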