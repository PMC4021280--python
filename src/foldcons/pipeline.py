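"""End-to-end orchestration: filters -> sites -> E_w -> sensitivity -> stats.

Stages communicate through plain TSV files so each one can be rerun or
inspected independently; a JSON manifest records the configuration, seed and
per-stage gene counts of every run.  The in-memory entry points
(:func:`analyze_alignments`, :func:`annotate_dataset`) drive the same code
without touching disk and are what the simulation studies use.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from .codonbias import codon_counts_from_cds, encprime
from .conservation import batch_weighted_entropy, leaf_weights
from .seqio import fourfold_sites, read_alignment, read_expression, write_site_table
from .structure import FoldParams, site_sensitivity

__all__ = ["RunConfig", "annotate_dataset", "analyze_alignments", "run_simulation",
           "run_analysis"]


@dataclass
class RunConfig:
    """Declarative configuration of a full run (YAML-loadable).

    CLI flags override individual keys.  Thresholds: ``e_cut`` (weighted
    entropy, bits), ``s_cut`` (structural sensitivity), ``min_frac``
    (pairwise alignability); ``flank``/``d_min_span`` parameterize folding
    locality; ``n_perm`` the permutation replicates.
    """

    alignments_dir: str = "alignments"
    tree_file: str = "tree.nwk"
    expression_file: str | None = "expression.tsv"
    output_dir: str = "results"
    reference_species: str = "sp1"
    e_cut: float = 0.5
    s_cut: float = 0.1
    min_frac: float = 0.80
    flank: int = 40
    d_min_span: int = 10
    window_win: int = 36
    window_step: int = 12
    window_last_start: int = 109
    regions: tuple = ((1, 60), (91, 150))
    n_perm: int = 1000
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides for `simulate`

    def __post_init__(self) -> None:
        if not 0 < self.min_frac <= 1:
            raise ValueError("min_frac must be in (0, 1]")
        if not 0 <= self.e_cut <= 2:
            raise ValueError("e_cut must be in [0, 2] bits")
        if self.s_cut < 0:
            raise ValueError("s_cut must be >= 0")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "regions" in data:
            data["regions"] = tuple(tuple(r) for r in data["regions"])
        return cls(**data)

    def fold_params(self) -> FoldParams:
        return FoldParams(flank=self.flank, d_min_span=self.d_min_span,
                          sensitivity_cutoff=self.s_cut)


def _annotate_gene(alignment, weighted_tree, sites, e_cut):
    """Fill E_w/conserved on copies of the site records for one alignment."""
    wvec = weighted_tree.weight_vector(alignment.species_order)
    cols = [s.aln_col for s in sites]
    if not cols:
        return []
    e_w = batch_weighted_entropy(alignment.rows, wvec, cols)
    out = []
    for s, e in zip(sites, e_w):
        conserved = None if math.isnan(e) else bool(e < e_cut)
        out.append(replace(s, E_w=float(e), conserved=conserved))
    return out


def annotate_dataset(dataset, prepared=None, e_cut: float = 0.5,
                     fold_params: FoldParams | None = None) -> dict:
    """Per-gene annotated site records for a synthetic dataset.

    When ``prepared`` (the output of :func:`foldcons.simulate.prepare_genes`)
    is given, its folded sensitivities are reused; otherwise each reference
    CDS is folded here.  Returns ``{gene_id: [FourfoldSiteRecord, ...]}``
    with E_w, sensitivity and both classifications filled.
    """
    wt = leaf_weights(dataset.tree_newick)
    fold_params = fold_params or FoldParams(flank=40)
    by_gene = {}
    prepared_sites = (
        {p.gene_id: p.sites for p in prepared} if prepared is not None else None
    )
    for aln in dataset.alignments:
        if prepared_sites is not None:
            sites = prepared_sites[aln.gene_id]
        else:
            sites = fourfold_sites(aln)
            cds = aln.reference_cds()
            filled = []
            for s in sites:
                res = site_sensitivity(cds, s.cds_pos, fold_params)
                filled.append(replace(s, sensitivity=res.sensitivity,
                                      sensitive=res.sensitive))
            sites = filled
        by_gene[aln.gene_id] = _annotate_gene(aln, wt, sites, e_cut)
    return by_gene


def analyze_alignments(alignments, tree_newick: str, config: RunConfig):
    """Filters + sites + E_w + sensitivity for a list of alignments.

    Returns ``(sites_by_gene, enc_by_gene, exclusions)`` where exclusions
    maps gene_id -> reason for every gene dropped by a filter.
    """
    from .seqio import alignability_filter

    wt = leaf_weights(tree_newick)
    fold_params = config.fold_params()
    sites_by_gene = {}
    enc_by_gene = {}
    exclusions = {}
    for aln in alignments:
        keep, _fracs = alignability_filter(aln, config.min_frac)
        if not keep:
            exclusions[aln.gene_id] = "alignability < min_frac"
            continue
        leaf_labels = set(wt.weights)
        if set(aln.species_order) != leaf_labels:
            exclusions[aln.gene_id] = "species set differs from tree leaves"
            continue
        sites = fourfold_sites(aln)
        if not sites:
            exclusions[aln.gene_id] = "no 4-fold degenerate sites"
            continue
        cds = aln.reference_cds()
        filled = []
        for s in sites:
            res = site_sensitivity(cds, s.cds_pos, fold_params)
            filled.append(replace(s, sensitivity=res.sensitivity,
                                  sensitive=res.sensitive))
        sites_by_gene[aln.gene_id] = _annotate_gene(aln, wt, filled, config.e_cut)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            enc_by_gene[aln.gene_id] = encprime(
                codon_counts_from_cds(aln.gene_id, cds)
            )
    return sites_by_gene, enc_by_gene, exclusions


def _mh_row(label, r) -> dict:
    return {
        "stratum": label,
        "or_mh": r.or_mh,
        "chi2": r.chi2,
        "p_two_sided": r.p_two_sided,
        "ci_low": r.ci95[0],
        "ci_high": r.ci95[1],
        "n_strata": r.n_strata_used,
    }


def run_simulation(config: RunConfig, outdir=None) -> Path:
    """`simulate` stage: write a synthetic dataset + manifest under outdir."""
    from .simulate import SimConfig, generate_dataset, write_dataset

    outdir = Path(outdir or config.output_dir)
    sim_kwargs = dict(config.sim)
    sim_kwargs.setdefault("seed", config.seed)
    sim_cfg = SimConfig(**sim_kwargs)
    dataset = generate_dataset(sim_cfg, FoldParams(flank=config.flank,
                                                   d_min_span=config.d_min_span,
                                                   sensitivity_cutoff=config.s_cut))
    write_dataset(dataset, outdir)
    manifest = {
        "stage": "simulate",
        "seed": sim_cfg.seed,
        "sim_config": dataclasses.asdict(sim_cfg),
        "n_genes": len(dataset.alignments),
        "n_species": sim_cfg.n_species,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def run_analysis(config: RunConfig) -> dict:
    """`run` stage: full analysis chain over alignments on disk.

    Writes per-stage TSVs and a manifest into ``config.output_dir`` and
    returns the in-memory results.  If a previously written site table with
    sensitivities exists (``sites.tsv``) the folding stage is skipped and
    the cached values reused.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln_dir = Path(config.alignments_dir)
    tree_newick = Path(config.tree_file).read_text()
    fasta_files = sorted(aln_dir.glob("*.fasta")) + sorted(aln_dir.glob("*.fa"))
    alignments = [read_alignment(f, config.reference_species) for f in fasta_files]

    cache = outdir / "sites.tsv"
    if cache.exists():
        cached = pd.read_csv(cache, sep="\t")
        sites_by_gene = {}
        from .seqio import FourfoldSiteRecord

        for gid, grp in cached.groupby("gene_id"):
            sites_by_gene[gid] = [
                FourfoldSiteRecord(
                    gene_id=gid, cds_pos=int(r.cds_pos), aln_col=int(r.aln_col),
                    ref_nt=r.ref_nt, E_w=float(r.E_w),
                    sensitivity=float(r.sensitivity),
                    conserved=bool(r.conserved), sensitive=bool(r.sensitive),
                )
                for r in grp.itertuples()
            ]
        enc_by_gene = {}
        exclusions = {}
        for aln in alignments:
            if aln.gene_id in sites_by_gene:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    enc_by_gene[aln.gene_id] = encprime(
                        codon_counts_from_cds(aln.gene_id, aln.reference_cds())
                    )
    else:
        sites_by_gene, enc_by_gene, exclusions = analyze_alignments(
            alignments, tree_newick, config
        )
        write_site_table(
            [s for sites in sites_by_gene.values() for s in sites], cache
        )

    results: dict = {"exclusions": exclusions if not cache.exists() or exclusions
                     else {}}
    overall, tables, sens_frac = assoc.run_species_analysis(
        sites_by_gene, e_cut=config.e_cut, s_cut=config.s_cut
    )
    results["overall"] = overall
    mh_rows = [_mh_row("overall", overall)]

    expression = None
    if config.expression_file and Path(config.expression_file).exists():
        expression = read_expression(config.expression_file)
        strat = assoc.stratified_analysis(
            sites_by_gene, expression.to_dict(), higher_is_top=True,
            e_cut=config.e_cut, s_cut=config.s_cut,
        )
        results["expression_strata"] = strat
        mh_rows.append(_mh_row("expression_top50", strat["top"]))
        mh_rows.append(_mh_row("expression_bottom50", strat["bottom"]))
    strat_enc = assoc.stratified_analysis(
        sites_by_gene, enc_by_gene, higher_is_top=False,
        e_cut=config.e_cut, s_cut=config.s_cut,
    )
    results["enc_strata"] = strat_enc
    # for ENC' "top" = strongest bias = lowest values
    mh_rows.append(_mh_row("encprime_strongest_bias50", strat_enc["top"]))
    mh_rows.append(_mh_row("encprime_weakest_bias50", strat_enc["bottom"]))
    pd.DataFrame(mh_rows).to_csv(outdir / "mantel_haenszel.tsv", sep="\t",
                                 index=False)

    windows = assoc.sliding_windows(config.window_win, config.window_step,
                                    config.window_last_start)
    win_results = assoc.windowed_analysis(sites_by_gene, windows,
                                          e_cut=config.e_cut, s_cut=config.s_cut)
    results["windows"] = win_results
    pd.DataFrame(win_results).to_csv(outdir / "windows.tsv", sep="\t", index=False)

    perm = assoc.constrained_permutation_test(sites_by_gene, n_perm=config.n_perm,
                                              seed=config.seed)
    results["permutation"] = perm
    perm_rows = [{"region": "whole", "mean_r": perm.mean_r, "p_left": perm.p_left,
                  "n_genes": perm.n_genes_used, "excluded": perm.n_genes_excluded}]
    for region in config.regions:
        try:
            rt = assoc.regional_correlation_test(sites_by_gene, tuple(region),
                                                 n_perm=config.n_perm,
                                                 seed=config.seed)
            perm_rows.append({"region": f"{region[0]}-{region[1]}",
                              "mean_r": rt.mean_r, "p_left": rt.p_left,
                              "n_genes": rt.n_genes_used,
                              "excluded": rt.n_genes_excluded})
            results[f"region_{region[0]}_{region[1]}"] = rt
        except ValueError as exc:
            perm_rows.append({"region": f"{region[0]}-{region[1]}",
                              "mean_r": math.nan, "p_left": math.nan,
                              "n_genes": 0, "excluded": len(sites_by_gene),
                              "note": str(exc)})
    pd.DataFrame(perm_rows).to_csv(outdir / "permutation.tsv", sep="\t",
                                   index=False)
    pd.DataFrame(
        [{"gene_id": g, "encprime": enc_by_gene.get(g),
          "expression": (expression.get(g) if expression is not None else None),
          "sensitive_fraction": sens_frac.get(g)}
         for g in sorted(sites_by_gene)]
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)

    manifest = {
        "stage": "run",
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_alignments": len(alignments),
        "n_genes_analyzed": len(sites_by_gene),
        "n_sites": int(sum(len(v) for v in sites_by_gene.values())),
        "exclusions": results["exclusions"],
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return results
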