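"""Synthetic ortholog datasets with a plantable structure-conservation coupling.

The generator produces the ingredients the analysis assumes: a rooted binary
phylogeny with branch lengths, per-gene codon alignments evolved along it
with the protein frozen (only 4-fold degenerate third positions change, so
every species carries the identical amino acid sequence), log-normal
expression values, and per-site ground truth.  An effect size ``beta``
plants the coupling the association statistics are designed to detect:
structurally sensitive 4-fold sites evolve at rate

    r_sensitive = syn_rate_mean / (1 + beta)

while all other 4-fold sites evolve at ``syn_rate_mean``.  ``beta = 0``
makes all 4-fold rates equal, so site conservation is exchangeable and the
permutation null holds exactly.

Substitution along each branch is a single change/no-change draw
(probability 1 - exp(-rate * t), then uniform over the 3 alternative
nucleotides) rather than a full CTMC; at the branch scales used here
(<= ~0.3 expected substitutions/site) multiple hits on one branch are rare
and the simple model keeps a closed-form oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import FOURFOLD_PREFIXES, FourfoldSiteRecord, OrthologAlignment
from .structure import FoldParams, site_sensitivity

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "generate_tree",
    "generate_root_cds",
    "plant_effect",
    "evolve_alignment",
    "generate_expression",
    "prepare_genes",
    "evolve_dataset",
    "replant",
    "generate_dataset",
    "write_dataset",
]

_STOPS = {"TAA", "TAG", "TGA"}
_NT = np.array(list("ACGT"))


class InvalidConfigError(ValueError):
    """A simulation parameter is outside its valid range."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a mid-sized study: 200 genes of 150 codons across 8
    species, a Yule-shaped tree with mean branch length 0.2 substitutions/
    site, and a synonymous rate of 0.3/site (about 0.8 expected
    substitutions per 4-fold site over the whole tree, yielding a balanced
    mix of conserved and variable columns).  ``effect_beta = 0`` is the
    null; ``effect_region`` optionally confines the planted effect to a
    1-based CDS interval (e.g. ``(1, 60)`` for a 5'-only effect).
    """

    n_genes: int = 200
    n_species: int = 8
    gene_length: int = 150  # codons
    tree_shape: str = "yule"  # or "balanced"
    branch_scale: float = 0.2  # expected substitutions/site per branch
    syn_rate_mean: float = 0.3
    effect_beta: float = 0.0
    effect_region: tuple | None = None
    gc_bias: float = 0.5
    expr_logmean: float = 0.0
    expr_logsd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise InvalidConfigError("n_species must be >= 4")
        if self.gene_length < 20:
            raise InvalidConfigError("gene_length must be >= 20 codons")
        if self.effect_beta < 0:
            raise InvalidConfigError("effect_beta must be >= 0")
        if self.branch_scale <= 0:
            raise InvalidConfigError("branch_scale must be > 0")
        if self.syn_rate_mean < 0:
            raise InvalidConfigError("syn_rate_mean must be >= 0")
        if self.expr_logsd < 0:
            raise InvalidConfigError("expr_logsd must be >= 0")
        if not 0.0 < self.gc_bias < 1.0:
            raise InvalidConfigError("gc_bias must be in (0, 1)")
        if self.tree_shape not in ("balanced", "yule"):
            raise InvalidConfigError(f"unknown tree_shape {self.tree_shape!r}")


@dataclass
class PreparedGene:
    """Root CDS plus folded sensitivities and planted rates (evolution-free)."""

    gene_id: str
    root_cds: str
    sites: list  # FourfoldSiteRecord with sensitivity/sensitive filled
    site_rates: np.ndarray  # per-codon synonymous rate


@dataclass
class SyntheticDataset:
    tree_newick: str
    alignments: list  # OrthologAlignment, reference species sp1 first
    expression: pd.Series
    truth: pd.DataFrame  # gene_id, cds_pos, ref_nt, sensitivity, sensitive, rate
    config: SimConfig


def _newick_balanced(labels) -> str:
    if len(labels) == 1:
        return labels[0]
    half = (len(labels) + 1) // 2
    return f"({_newick_balanced(labels[:half])},{_newick_balanced(labels[half:])})"


def _newick_yule(labels, rng) -> str:
    # pure-birth topology: repeatedly split a uniformly chosen extant tip
    children: dict = {0: (1, 2)}
    leaves = [1, 2]
    next_id = 3
    for _ in range(len(labels) - 2):
        i = int(rng.integers(len(leaves)))
        node = leaves[i]
        children[node] = (next_id, next_id + 1)
        leaves[i] = next_id
        leaves.append(next_id + 1)
        next_id += 2
    label_of = dict(zip(leaves, labels))

    def render(node):
        if node in children:
            left, right = children[node]
            return f"({render(left)},{render(right)})"
        return label_of[node]

    return render(0)


def generate_tree(n_species: int, tree_shape: str = "yule",
                  branch_scale: float = 0.2, seed: int = 0) -> str:
    """Rooted binary tree in Newick; every branch length ~ Exp(branch_scale).

    Leaves are named sp1..spN.  ``balanced`` forces the most balanced
    topology; ``yule`` grows the topology by splitting random tips.
    Deterministic given the seed.
    """
    if n_species < 4:
        raise InvalidConfigError("n_species must be >= 4")
    if branch_scale <= 0:
        raise InvalidConfigError("branch_scale must be > 0")
    rng = np.random.default_rng(seed)
    labels = [f"sp{i + 1}" for i in range(n_species)]
    if tree_shape == "balanced":
        topo = _newick_balanced(labels)
    elif tree_shape == "yule":
        topo = _newick_yule(labels, rng)
    else:
        raise InvalidConfigError(f"unknown tree_shape {tree_shape!r}")
    # attach an Exp(branch_scale) length to every node except the root
    out = []
    depth = 0
    i = 0
    n = len(topo)
    while i < n:
        ch = topo[i]
        out.append(ch)
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth > 0:  # internal, non-root edge
                out.append(f":{rng.exponential(branch_scale):.8f}")
        elif ch not in ",()" and (i + 1 == n or topo[i + 1] in ",()"):
            out.append(f":{rng.exponential(branch_scale):.8f}")
        i += 1
    return "".join(out) + ";"


def _fourfold_codon_indices(cds: str) -> np.ndarray:
    return np.array(
        [k for k in range(len(cds) // 3) if cds[3 * k : 3 * k + 2] in FOURFOLD_PREFIXES],
        dtype=int,
    )


def generate_root_cds(gene_length: int, gc_bias: float = 0.5, seed: int = 0) -> str:
    """Random in-frame, stop-free CDS starting with ATG.

    Nucleotides are drawn with P(G) = P(C) = gc_bias/2; stop codons are
    rejection-sampled away, and the sequence is redrawn in the (practically
    impossible) event that fewer than 10% of third positions are 4-fold
    degenerate.
    """
    if gene_length < 20:
        raise InvalidConfigError("gene_length must be >= 20 codons")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    for _ in range(1000):
        codons = ["ATG"]
        while len(codons) < gene_length:
            codon = "".join(rng.choice(_NT, size=3, p=p))
            if codon not in _STOPS:
                codons.append(codon)
        cds = "".join(codons)
        if len(_fourfold_codon_indices(cds)) >= 0.1 * gene_length:
            return cds
    raise RuntimeError("could not generate a CDS with enough 4-fold sites")


def plant_effect(root_cds: str, sensitive_by_pos: dict, effect_beta: float,
                 syn_rate_mean: float, effect_region: tuple | None = None) -> np.ndarray:
    """Per-codon synonymous rates with the planted coupling.

    ``sensitive_by_pos`` maps 1-based 4-fold cds positions to booleans.  A
    sensitive site's rate is divided by (1 + beta); with ``effect_region``
    the reduction applies only to sensitive sites inside that interval.
    Non-4-fold codons get rate 0.
    """
    if effect_beta < 0:
        raise InvalidConfigError("effect_beta must be >= 0")
    n_codons = len(root_cds) // 3
    rates = np.zeros(n_codons)
    for k in _fourfold_codon_indices(root_cds):
        pos = 3 * k + 3
        rate = syn_rate_mean
        sensitive = sensitive_by_pos.get(pos, False)
        in_region = (
            effect_region is None
            or effect_region[0] <= pos <= effect_region[1]
        )
        if sensitive and in_region:
            rate = syn_rate_mean / (1.0 + effect_beta)
        rates[k] = rate
    return rates


def _parse_tree_edges(newick: str):
    import dendropy

    return dendropy.Tree.get(data=newick, schema="newick")


def evolve_alignment(root_cds: str, tree_newick: str, site_rates: np.ndarray,
                     seed: int = 0, gene_id: str = "gene") -> OrthologAlignment:
    """Evolve the root CDS along the tree at its 4-fold third positions.

    Per branch and site, the nucleotide changes with probability
    1 - exp(-rate * t) and then moves uniformly to one of the 3 alternatives;
    everything else is frozen, so the alignment is gap-free and the protein
    identical across species.  Rates at non-4-fold codons must be 0.
    """
    site_rates = np.asarray(site_rates, dtype=float)
    if (site_rates < 0).any():
        raise InvalidConfigError("negative substitution rate")
    four = _fourfold_codon_indices(root_cds)
    n_codons = len(root_cds) // 3
    if len(site_rates) != n_codons:
        raise ValueError("site_rates must have one entry per codon")
    mask = np.zeros(n_codons, dtype=bool)
    mask[four] = True
    if (site_rates[~mask] > 0).any():
        raise InvalidConfigError("nonzero rate at a non-4-fold codon")
    rng = np.random.default_rng(seed)
    tree = _parse_tree_edges(tree_newick)
    nt_index = {c: i for i, c in enumerate("ACGT")}
    root_state = np.array([nt_index[root_cds[3 * k + 2]] for k in four], dtype=np.int8)
    rates = site_rates[four]
    states = {}  # node -> state vector at 4-fold third positions
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = root_state
            continue
        parent = states[node.parent_node]
        t = node.edge.length or 0.0
        p_change = 1.0 - np.exp(-rates * t)
        change = rng.random(len(parent)) < p_change
        state = parent.copy()
        if change.any():
            # uniform over the 3 alternatives: shift by 1..3 mod 4
            shift = rng.integers(1, 4, size=int(change.sum()))
            state[change] = (state[change] + shift) % 4
        states[node] = state
    species, rows = [], []
    base = list(root_cds)
    for leaf in tree.leaf_node_iter():
        seq = base.copy()
        for k, s in zip(four, states[leaf]):
            seq[3 * k + 2] = "ACGT"[s]
        species.append(leaf.taxon.label)
        rows.append("".join(seq))
    # reference species sp1 first
    order = sorted(range(len(species)), key=lambda i: (species[i] != "sp1", species[i]))
    return OrthologAlignment(
        gene_id=gene_id,
        species_order=[species[i] for i in order],
        rows=[rows[i] for i in order],
        reference_index=0,
    )


def generate_expression(n_genes: int, expr_logmean: float = 0.0,
                        expr_logsd: float = 1.0, seed: int = 0,
                        gene_ids=None) -> pd.Series:
    """Log-normal expression values keyed by gene id (deterministic per seed)."""
    if expr_logsd < 0:
        raise InvalidConfigError("expr_logsd must be >= 0")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"gene{i + 1:04d}" for i in range(n_genes)]
    values = np.exp(rng.normal(expr_logmean, expr_logsd, size=n_genes))
    return pd.Series(values, index=pd.Index(gene_ids, name="gene_id"),
                     name="expression")


def _gene_seeds(master_seed: int, n: int, stream: int):
    """Counter-based per-gene seed streams, independent of n ordering."""
    return [
        np.random.SeedSequence(entropy=master_seed, spawn_key=(stream, g))
        for g in range(n)
    ]


def prepare_genes(config: SimConfig, fold_params: FoldParams | None = None) -> list:
    """Generate root CDSs, fold them, and fix per-site rates (no evolution).

    This is the expensive, folding-dominated half of dataset generation; the
    result can be re-used across many evolution replicates (the sensitivity
    labels depend only on the root sequences).
    """
    fold_params = fold_params or FoldParams(flank=40)
    prepared = []
    for g, ss in enumerate(_gene_seeds(config.seed, config.n_genes, stream=1)):
        gene_id = f"gene{g + 1:04d}"
        rng_seed = int(ss.generate_state(1)[0] % (2**31))
        root = generate_root_cds(config.gene_length, config.gc_bias, rng_seed)
        sites = []
        sensitive_by_pos = {}
        for k in _fourfold_codon_indices(root):
            pos = 3 * k + 3
            res = site_sensitivity(root, pos, fold_params)
            sensitive_by_pos[pos] = res.sensitive
            sites.append(
                FourfoldSiteRecord(
                    gene_id=gene_id,
                    cds_pos=pos,
                    aln_col=pos - 1,
                    ref_nt=root[pos - 1],
                    sensitivity=res.sensitivity,
                    sensitive=res.sensitive,
                )
            )
        rates = plant_effect(
            root, sensitive_by_pos, config.effect_beta, config.syn_rate_mean,
            config.effect_region,
        )
        prepared.append(
            PreparedGene(gene_id=gene_id, root_cds=root, sites=sites,
                         site_rates=rates)
        )
    return prepared


def replant(prepared: list, config: SimConfig) -> list:
    """New PreparedGene list with rates re-planted under ``config``.

    Folded sensitivities are reused, so sweeping ``effect_beta`` or
    ``effect_region`` across study conditions costs no additional folding.
    """
    out = []
    for gene in prepared:
        sensitive_by_pos = {s.cds_pos: bool(s.sensitive) for s in gene.sites}
        rates = plant_effect(
            gene.root_cds, sensitive_by_pos, config.effect_beta,
            config.syn_rate_mean, config.effect_region,
        )
        out.append(
            PreparedGene(gene_id=gene.gene_id, root_cds=gene.root_cds,
                         sites=gene.sites, site_rates=rates)
        )
    return out


def evolve_dataset(prepared: list, config: SimConfig,
                   seed: int | None = None) -> SyntheticDataset:
    """Evolve alignments for prepared genes and assemble the dataset."""
    seed = config.seed if seed is None else seed
    tree_newick = generate_tree(
        config.n_species, config.tree_shape, config.branch_scale, config.seed
    )
    alignments = []
    truth_rows = []
    for g, (gene, ss) in enumerate(
        zip(prepared, _gene_seeds(seed, len(prepared), stream=2))
    ):
        aln_seed = int(ss.generate_state(1)[0] % (2**31))
        aln = evolve_alignment(
            gene.root_cds, tree_newick, gene.site_rates, seed=aln_seed,
            gene_id=gene.gene_id,
        )
        alignments.append(aln)
        for s in gene.sites:
            truth_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "cds_pos": s.cds_pos,
                    "ref_nt": s.ref_nt,
                    "sensitivity": s.sensitivity,
                    "sensitive": s.sensitive,
                    "rate": gene.site_rates[(s.cds_pos - 3) // 3],
                }
            )
    expression = generate_expression(
        len(prepared), config.expr_logmean, config.expr_logsd,
        seed=int(np.random.SeedSequence(entropy=config.seed, spawn_key=(3,))
                 .generate_state(1)[0] % (2**31)),
        gene_ids=[g.gene_id for g in prepared],
    )
    return SyntheticDataset(
        tree_newick=tree_newick,
        alignments=alignments,
        expression=expression,
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def generate_dataset(config: SimConfig,
                     fold_params: FoldParams | None = None) -> SyntheticDataset:
    """Full dataset generation: prepare (fold) then evolve with config.seed."""
    return evolve_dataset(prepare_genes(config, fold_params), config)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write per-gene FASTA alignments, the tree, expression and truth TSVs."""
    outdir = Path(outdir)
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(parents=True, exist_ok=True)
    for aln in dataset.alignments:
        with open(aln_dir / f"{aln.gene_id}.fasta", "w") as fh:
            for sp, row in zip(aln.species_order, aln.rows):
                fh.write(f">{sp}\n{row}\n")
    (outdir / "tree.nwk").write_text(dataset.tree_newick + "\n")
    dataset.expression.reset_index().to_csv(
        outdir / "expression.tsv", sep="\t", index=False
    )
    dataset.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
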