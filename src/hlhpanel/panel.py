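"""The default 12-gene HLH diagnostic panel.

Gene set, inheritance models, associated diseases and per-gene amplicon
counts of the reference AmpliSeq design.  Three genes (SH2D1A, XIAP,
MAGT1) are X-linked; the remainder are autosomal recessive.  The exact
amplicon coordinates of the commercial design are not public, so
:func:`default_panel` lays out a synthetic but size-faithful geometry
(amplicon lengths within the assay's 125-175 bp range, per-gene counts
as designed) for simulation and testing.
"""

from __future__ import annotations

from .model import Amplicon, Inheritance, PanelGene

__all__ = ["DEFAULT_GENES", "AMPLICON_COUNTS", "default_genes", "default_panel"]

# name, transcript, chromosome, inheritance, disease, n_amplicons
_GENE_TABLE = [
    ("PRF1", "ENST00000373209", "chr10", "AR", "FHL2", 11),
    ("UNC13D", "ENST00000207549", "chr17", "AR", "FHL3", 51),
    ("STX11", "ENST00000367568", "chr6", "AR", "FHL4", 28),
    ("STXBP2", "ENST00000441779", "chr19", "AR", "FHL5", 25),
    ("SH2D1A", "ENST00000371139", "chrX", "XL", "XLP1", 5),
    ("XIAP", "ENST00000371199", "chrX", "XL", "XLP2", 13),
    ("RAB27A", "ENST00000396307", "chr15", "AR", "GS2", 10),
    ("LYST", "ENST00000389794", "chr1", "AR", "CHS", 120),
    ("AP3B1", "ENST00000255194", "chr5", "AR", "HPS2", 50),
    ("BLOC1S6", "ENST00000220531", "chr15", "AR", "HPS9", 8),
    ("MAGT1", "ENST00000358075", "chrX", "XL", "XMEN", 18),
    ("ITK", "ENST00000422843", "chr5", "AR", "ITK deficiency", 22),
]

AMPLICON_COUNTS: dict[str, int] = {row[0]: row[5] for row in _GENE_TABLE}

DEFAULT_GENES: list[PanelGene] = [
    PanelGene(
        name=name,
        chromosome=chrom,
        inheritance=Inheritance(inh),
        associated_disease=disease,
        transcript_id=tx,
    )
    for name, tx, chrom, inh, disease, _ in _GENE_TABLE
]


def default_genes() -> list[PanelGene]:
    """A fresh copy of the 12 default panel genes."""
    return list(DEFAULT_GENES)


def default_panel(
    amplicon_length: int = 150,
    spacing: int = 30,
) -> tuple[list[PanelGene], list[Amplicon]]:
    """Build the default panel with a synthetic tiling geometry.

    Each gene receives its designed number of amplicons, tiled as
    non-overlapping ``amplicon_length``-bp intervals separated by
    ``spacing`` bp, starting at an arbitrary per-gene offset.  Geometry
    is deterministic; only counts and the 125-175 bp size range mirror
    the real design.
    """
    if not 125 <= amplicon_length <= 175:
        raise ValueError("amplicon_length must lie in the assay range 125-175 bp")
    genes = default_genes()
    amplicons: list[Amplicon] = []
    for gi, gene in enumerate(genes):
        n = AMPLICON_COUNTS[gene.name]
        offset = 1_000_000 * (gi + 1)
        for i in range(n):
            start = offset + i * (amplicon_length + spacing)
            amplicons.append(
                Amplicon(
                    id=f"{gene.name}_amp{i + 1:03d}",
                    gene=gene.name,
                    chromosome=gene.chromosome,
                    start=start,
                    end=start + amplicon_length,
                )
            )
    return genes, amplicons
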