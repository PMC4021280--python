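"""Phylogenetically weighted per-column conservation.

A column's conservation is measured by weighted Shannon entropy

    E_w = -sum_i p_i log2 p_i

where p_i is the weighted fraction of sequences carrying nucleotide i and
the per-sequence weights come from the tree (equal-split measure), so that
clusters of closely related species do not dominate the column composition.
E_w = 0 means no variation; 2 bits is the maximum (four equiprobable
nucleotides).  Sites with E_w below a cutoff (default 0.5) are classified
as conserved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy

__all__ = [
    "WeightedTree",
    "EntropyResult",
    "leaf_weights",
    "weighted_entropy",
    "batch_weighted_entropy",
    "classify_conserved",
]

_GAPLIKE = {"-", "N", "?", "."}
_NUCLEOTIDES = {"A", "C", "G", "T"}


@dataclass
class WeightedTree:
    """A phylogeny together with per-leaf weights summing to one."""

    tree: dendropy.Tree
    weights: dict  # taxon label -> weight

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"leaf weights sum to {total}, expected 1")

    def weight_vector(self, species_order) -> list:
        try:
            return [self.weights[s] for s in species_order]
        except KeyError as exc:
            raise KeyError(f"species {exc} not present in the tree") from exc


@dataclass
class EntropyResult:
    E_w: float  # bits; nan when the column is entirely gaps
    n_effective: float  # sum of weights of non-gap rows
    nucleotide_fractions: dict  # nucleotide -> weighted fraction p_i

    @property
    def defined(self) -> bool:
        return not math.isnan(self.E_w)


def leaf_weights(tree: dendropy.Tree | str) -> WeightedTree:
    """Equal-split leaf weights from topology and branch lengths.

    Each branch's length is divided equally among the leaves descending from
    it; a leaf's raw weight is the sum of its shares over all ancestral
    branches, normalized to sum 1.  Trees with zero total branch length fall
    back to uniform weights with a warning.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    leaves = tree.leaf_nodes()
    if not leaves:
        raise ValueError("tree has no leaves")
    raw = {lf.taxon.label: 0.0 for lf in leaves}
    for node in tree.preorder_node_iter():
        length = node.edge.length
        if length is None or node.parent_node is None:
            continue
        below = [lf.taxon.label for lf in node.leaf_iter()]
        share = length / len(below)
        for label in below:
            raw[label] += share
    total = sum(raw.values())
    if total <= 0.0:
        warnings.warn("all branch lengths are zero; using uniform leaf weights")
        w = 1.0 / len(raw)
        return WeightedTree(tree=tree, weights={k: w for k in raw})
    return WeightedTree(tree=tree, weights={k: v / total for k, v in raw.items()})


def weighted_entropy(column_chars, weights) -> EntropyResult:
    """Weighted entropy of one alignment column.

    ``weights`` is either a sequence aligned with ``column_chars`` or a
    :class:`WeightedTree` (then ``column_chars`` must be a mapping
    species -> char).  Gap and N rows are excluded and the remaining weights
    renormalized; an all-gap column yields E_w = nan (dropped downstream).
    """
    if isinstance(weights, WeightedTree):
        if not hasattr(column_chars, "items"):
            raise TypeError("with a WeightedTree, pass a mapping species -> char")
        species = list(column_chars.keys())
        chars = [column_chars[s] for s in species]
        wvec = weights.weight_vector(species)
    else:
        chars = list(column_chars)
        wvec = list(weights)
        if len(chars) != len(wvec):
            raise ValueError("one weight per character required")
    masses: dict = {}
    kept = 0.0
    for ch, w in zip(chars, wvec):
        ch = ch.upper().replace("U", "T")
        if ch in _GAPLIKE:
            continue
        if ch not in _NUCLEOTIDES:
            raise ValueError(f"invalid alignment character {ch!r}")
        masses[ch] = masses.get(ch, 0.0) + w
        kept += w
    if kept <= 0.0:
        return EntropyResult(E_w=float("nan"), n_effective=0.0, nucleotide_fractions={})
    fractions = {nt: m / kept for nt, m in masses.items()}
    e_w = -sum(p * math.log2(p) for p in fractions.values() if p > 0.0) + 0.0
    return EntropyResult(E_w=e_w, n_effective=kept, nucleotide_fractions=fractions)


def batch_weighted_entropy(rows, weights, columns):
    """Vectorized E_w for many columns of one alignment.

    ``rows`` are the aligned sequences (one per leaf, same order as
    ``weights``); ``columns`` are 0-based column indices.  Returns a float
    array of E_w values (nan where a column is entirely gaps).  Semantics
    match :func:`weighted_entropy` with gap renormalization.
    """
    import numpy as np

    mat = np.array([list(r) for r in rows])
    cols = mat[:, np.asarray(columns, dtype=int)]
    w = np.asarray(list(weights), dtype=float)[:, None]
    masses = np.stack([(np.isin(cols, [nt])) * w for nt in "ACGT"]).sum(axis=1)
    kept = masses.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = masses / kept
        terms = np.where(p > 0, p * np.log2(p), 0.0)
        e = -terms.sum(axis=0)
    e[kept <= 0] = np.nan
    return e


def classify_conserved(e_w: float, cutoff: float = 0.5) -> bool:
    """A site is conserved iff E_w is strictly below the cutoff."""
    if math.isnan(e_w):
        raise ValueError("E_w undefined (all-gap column); drop the site instead")
    return e_w < cutoff
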