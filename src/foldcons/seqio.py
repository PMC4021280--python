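"""Reading alignments/trees/expression tables and extracting 4-fold sites.

Coordinate conventions: CDS positions are 1-based (position 1 is the A of
ATG) so a third codon position is always ``cds_pos % 3 == 0``; alignment
columns are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "OrthologAlignment",
    "FourfoldSiteRecord",
    "AlignmentFormatError",
    "read_alignment",
    "alignability_filter",
    "fourfold_sites",
    "read_expression",
    "write_site_table",
    "FOURFOLD_PREFIXES",
]

#: dinucleotide prefixes of the 8 fully 4-fold codon families
#: (Ala GCN, Arg4 CGN, Gly GGN, Leu4 CTN, Pro CCN, Ser4 TCN, Thr ACN, Val GTN)
FOURFOLD_PREFIXES = frozenset({"GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT"})

_ALLOWED = set("ACGT-N")


class AlignmentFormatError(ValueError):
    """Raised for ragged alignments, bad characters or untranslatable CDSs."""


@dataclass
class OrthologAlignment:
    """One gene's codon-aware ortholog alignment, reference species focal."""

    gene_id: str
    species_order: list
    rows: list  # equal-length nucleotide strings, gaps allowed
    reference_index: int = 0

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"{self.gene_id}: rows have unequal lengths {sorted(lengths)}"
            )
        for sp, row in zip(self.species_order, self.rows):
            bad = set(row) - _ALLOWED
            if bad:
                raise AlignmentFormatError(
                    f"{self.gene_id}/{sp}: invalid characters {sorted(bad)}"
                )

    @property
    def reference_species(self) -> str:
        return self.species_order[self.reference_index]

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_index]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def reference_cds(self) -> str:
        return self.reference_row.replace("-", "")

    def column(self, col: int) -> dict:
        return {sp: row[col] for sp, row in zip(self.species_order, self.rows)}


@dataclass
class FourfoldSiteRecord:
    """One 4-fold degenerate site of the reference CDS, with analysis values."""

    gene_id: str
    cds_pos: int  # 1-based third codon position in the reference CDS
    aln_col: int  # 0-based alignment column
    ref_nt: str
    E_w: float | None = None  # bits
    sensitivity: float | None = None  # mean d_max over the 3 mutations
    conserved: bool | None = None
    sensitive: bool | None = None
    flags: dict = field(default_factory=dict)


def read_alignment(fasta_path, reference_species: str,
                   gene_id: str | None = None) -> OrthologAlignment:
    """Read a multi-FASTA alignment; rows uppercased, U mapped to T.

    The record whose id equals ``reference_species`` becomes the focal row.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) < 2:
        raise AlignmentFormatError(f"{fasta_path}: need >= 2 aligned records")
    species = [r.id for r in records]
    rows = [str(r.seq).upper().replace("U", "T") for r in records]
    if reference_species not in species:
        raise KeyError(f"reference species {reference_species!r} not in {fasta_path}")
    return OrthologAlignment(
        gene_id=gene_id or fasta_path.stem,
        species_order=species,
        rows=rows,
        reference_index=species.index(reference_species),
    )


def alignability_filter(alignment: OrthologAlignment,
                        min_frac: float = 0.80) -> tuple[bool, dict]:
    """Pairwise alignability between the reference and every ortholog.

    For each pair the aligned fraction is (columns where both are non-gap) /
    (ungapped length of each sequence), in both directions.  The gene is
    kept only if every fraction is >= ``min_frac`` (the boundary is
    inclusive: genes with exactly 80% alignable are retained).
    """
    ref = alignment.reference_row
    ref_len = len(ref) - ref.count("-")
    fractions = {}
    keep = True
    for sp, row in zip(alignment.species_order, alignment.rows):
        if sp == alignment.reference_species:
            continue
        both = sum(1 for x, y in zip(ref, row) if x != "-" and y != "-")
        other_len = len(row) - row.count("-")
        f_ref = both / ref_len if ref_len else 0.0
        f_other = both / other_len if other_len else 0.0
        fractions[sp] = (f_ref, f_other)
        if f_ref < min_frac or f_other < min_frac:
            keep = False
    return keep, fractions


def fourfold_sites(alignment: OrthologAlignment) -> list:
    """4-fold degenerate third codon positions of the reference CDS.

    A position qualifies iff the reference codon's first two nucleotides form
    one of the 8 fully 4-fold families; 6-fold amino acids contribute only
    their 4-fold subfamily (CTN, CGN, TCN).  Pure function of the reference
    row; orthologs may differ at the column.
    """
    ref_row = alignment.reference_row
    cds = ref_row.replace("-", "")
    if len(cds) % 3 != 0:
        raise AlignmentFormatError(
            f"{alignment.gene_id}: ungapped reference length {len(cds)} not a "
            "multiple of 3"
        )
    protein = str(Seq(cds).translate())
    if "*" in protein[:-1]:
        raise AlignmentFormatError(
            f"{alignment.gene_id}: internal stop codon in reference CDS"
        )
    # map ungapped reference position (0-based) -> alignment column
    col_of = [i for i, ch in enumerate(ref_row) if ch != "-"]
    sites = []
    for codon_idx in range(len(cds) // 3):
        codon = cds[3 * codon_idx : 3 * codon_idx + 3]
        if "N" in codon:
            continue
        if codon[:2] in FOURFOLD_PREFIXES:
            pos0 = 3 * codon_idx + 2
            sites.append(
                FourfoldSiteRecord(
                    gene_id=alignment.gene_id,
                    cds_pos=pos0 + 1,
                    aln_col=col_of[pos0],
                    ref_nt=cds[pos0],
                )
            )
    return sites


def read_expression(tsv_path) -> pd.Series:
    """Expression table (gene_id, expression) as a Series indexed by gene."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={0: str})
    df.columns = [c.lower() for c in df.columns]
    return df.set_index("gene_id")["expression"].astype(float)


def write_site_table(sites, path) -> None:
    """Write one FourfoldSiteRecord per row as TSV."""
    rows = [
        {
            "gene_id": s.gene_id,
            "cds_pos": s.cds_pos,
            "aln_col": s.aln_col,
            "ref_nt": s.ref_nt,
            "E_w": s.E_w,
            "sensitivity": s.sensitivity,
            "conserved": s.conserved,
            "sensitive": s.sensitive,
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
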