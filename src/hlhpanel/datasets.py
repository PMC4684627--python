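"""Reference study inputs encoded as pipeline data.

Two bundles are provided:

* :func:`validation_sets` — the assay-validation experiment: 74
  expected variants (18 disease-causing mutations across 13 control
  samples plus 56 exonic polymorphisms), of which the variant caller
  recovered 72; the two misses are a homopolymer-stretch indel
  (RAB27A c.148_149delinsC) and one polymorphism.
* :func:`prospective_cohort` — the 58-patient prospective cohort:
  per-patient disease-causing genotypes for the 22 molecularly
  diagnosable patients (including two large exonic deletions, planted
  into a simulated coverage matrix so the CNV caller has to find them,
  and one externally typed intronic inversion completing a compound-
  het pair), monoallelic VUS carriers among the undiagnosed, age bins
  and secondary-trigger metadata.

These are *inputs* (genotypes and metadata); diagnoses and statistics
are always recomputed by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    Amplicon,
    AnnotatedVariant,
    Consequence,
    CoverageMatrix,
    ExternalAllele,
    GenotypeCall,
    PanelGene,
    PatientRecord,
    Zygosity,
)
from .panel import default_panel
from .synthetic_data import (
    CoverageTruth,
    DeletionSpec,
    SimulationConfig,
    simulate_coverage,
)

__all__ = ["validation_sets", "prospective_cohort", "CohortBundle"]

_GENE_CHROM = {
    "PRF1": "chr10",
    "UNC13D": "chr17",
    "STX11": "chr6",
    "STXBP2": "chr19",
    "SH2D1A": "chrX",
    "XIAP": "chrX",
    "RAB27A": "chr15",
    "LYST": "chr1",
    "AP3B1": "chr5",
    "BLOC1S6": "chr15",
    "MAGT1": "chrX",
    "ITK": "chr5",
}

_POS_COUNTER: dict[str, int] = {}


def _pos(gene: str) -> int:
    """Deterministic distinct placeholder position per gene (the real
    hg19 coordinates are immaterial to the logic)."""
    _POS_COUNTER[gene] = _POS_COUNTER.get(gene, 0) + 1
    base = 10_000_000 + list(_GENE_CHROM).index(gene) * 1_000_000
    return base + _POS_COUNTER[gene] * 50


# gene, hgvs_c, hgvs_p, zygosity, consequence, sample
_VALIDATION_MUTATIONS = [
    ("PRF1", "c.272C>T", "p.Ala91Val", "het", Consequence.MISSENSE, "V01"),
    ("PRF1", "c.797T>C", "p.Ile266Thr", "het", Consequence.MISSENSE, "V01"),
    ("UNC13D", "c.2135_2137del", "p.Ile712_Gly713delinsSer", "het", Consequence.INFRAME_INDEL, "V02"),
    ("UNC13D", "c.2346_2349del", "p.Arg782Serfs*12", "het", Consequence.FRAMESHIFT, "V02"),
    ("UNC13D", "c.1388A>C", "p.Gln463Pro", "het", Consequence.MISSENSE, "V03"),
    ("UNC13D", "c.118-307G>A", "", "het", Consequence.REGULATORY, "V03"),
    ("UNC13D", "c.2719_2722dup", "p.Ser908TyrfsX3", "het", Consequence.FRAMESHIFT, "V04"),
    ("UNC13D", "c.1992+1G>C", "", "het", Consequence.SPLICE_DONOR, "V04"),
    ("STXBP2", "c.56T>C", "p.Ile19Thr", "het", Consequence.MISSENSE, "V06"),
    ("STXBP2", "c.704G>C", "p.Arg235Pro", "het", Consequence.MISSENSE, "V06"),
    ("XIAP", "c.877G>A", "p.Gly293Ser", "hemi", Consequence.MISSENSE, "V07"),
    ("XIAP", "c.1141C>T", "p.Arg381*", "hemi", Consequence.STOP_GAINED, "V08"),
    ("RAB27A", "c.148_149delinsC", "p.Arg50Glnfs*35", "hom", Consequence.FRAMESHIFT, "V09"),
    ("RAB27A", "c.514_518del", "p.Gln172Asnfs*2", "hom", Consequence.FRAMESHIFT, "V10"),
    ("LYST", "c.2311C>T", "p.Gln771*", "hom", Consequence.STOP_GAINED, "V11"),
    ("LYST", "c.1902dup", "p.Ala635Serfs*4", "hom", Consequence.FRAMESHIFT, "V11"),
    ("AP3B1", "c.1254dup", "p.Gln419Thrfs*22", "het", Consequence.FRAMESHIFT, "V12"),
    ("AP3B1", "c.2626C>T", "p.Arg876*", "het", Consequence.STOP_GAINED, "V12"),
]

#: identities the caller missed: the homopolymer indel and one polymorphism
_MISSED_MUTATION = "c.148_149delinsC"
_MISSED_POLYMORPHISM_INDEX = 17


def validation_sets() -> tuple[set[tuple], set[tuple]]:
    """(truth, called) identity sets for the sensitivity analysis.

    Identities are (chrom, pos, ref, alt, sample); 74 expected, 72
    recovered.  The 298-bp homozygous exonic deletion used to probe
    CNV detection is not part of the small-variant truth set.
    """
    _POS_COUNTER.clear()
    truth: set[tuple] = set()
    called: set[tuple] = set()
    for gene, hgvs_c, _p, _zyg, _cq, sample in _VALIDATION_MUTATIONS:
        ident = (_GENE_CHROM[gene], _pos(gene), "G", "A", sample)
        truth.add(ident)
        if hgvs_c != _MISSED_MUTATION:
            called.add(ident)
    genes = list(_GENE_CHROM)
    for i in range(56):  # exonic polymorphisms across the 13 control samples
        gene = genes[i % len(genes)]
        sample = f"V{i % 13 + 1:02d}"
        ident = (_GENE_CHROM[gene], _pos(gene), "C", "T", sample)
        truth.add(ident)
        if i != _MISSED_POLYMORPHISM_INDEX:
            called.add(ident)
    return truth, called


# ---------------------------------------------------------------------------
# prospective cohort

# patient, gene, [(hgvs_c, hgvs_p, zygosity, consequence, maf)]
_DIAGNOSED_GENOTYPES: list[tuple[str, str, list[tuple]]] = [
    ("P48", "PRF1", [("c.272C>T", "p.Ala91Val", "het", Consequence.MISSENSE, 0.03),
                     ("c.1288G>T", "p.Asp430Tyr", "het", Consequence.MISSENSE, 0.0005)]),
    ("P20", "PRF1", [("c.659G>A", "p.Gly220Asp", "hom", Consequence.MISSENSE, 0.0)]),
    ("P35", "PRF1", [("c.673C>T", "p.Arg225Trp", "hom", Consequence.MISSENSE, 0.0002)]),
    ("P16", "PRF1", [("c.1122G>A", "p.Trp374*", "hom", Consequence.STOP_GAINED, 0.0002)]),
    ("P40", "PRF1", [("c.1122G>A", "p.Trp374*", "hom", Consequence.STOP_GAINED, 0.0002)]),
    ("P17", "PRF1", [("c.1349C>T", "p.Thr450Met", "hom", Consequence.MISSENSE, 0.001)]),
    ("P19", "PRF1", [("c.1179C>A", "p.Cys393*", "het", Consequence.STOP_GAINED, 0.0),
                     ("c.1434G>T", "p.Leu478Arg", "het", Consequence.MISSENSE, 0.0)]),
    ("P11", "UNC13D", [("c.569+5G>A", "", "het", Consequence.SPLICE_REGION, 0.0)]),
    ("P1", "UNC13D", [("c.570-1G>A", "", "hom", Consequence.SPLICE_ACCEPTOR, 0.0)]),
    ("P37", "UNC13D", [("c.753+1G>T", "", "hom", Consequence.SPLICE_DONOR, 0.0)]),
    ("P10", "UNC13D", [("c.2236C>T", "p.Gln746*", "het", Consequence.STOP_GAINED, 0.0),
                       ("c.2346_2349del", "p.Arg748Serfs*12", "het", Consequence.FRAMESHIFT, 0.0)]),
    ("P50", "UNC13D", [("c.2709+2T>A", "", "hom", Consequence.SPLICE_DONOR, 0.0)]),
    ("P58", "UNC13D", [("c.2544delT", "p.Ile848Metfs*67", "hom", Consequence.FRAMESHIFT, 0.0)]),
    ("P9", "STX11", [("c.369_376delinsTGG", "p.Val124Glyfs*60", "hom", Consequence.FRAMESHIFT, 0.0)]),
    ("P38", "STX11", [("c.369_376delinsTGG", "p.Val124Glyfs*60", "hom", Consequence.FRAMESHIFT, 0.0)]),
    ("P39", "STX11", [("c.369_376delinsTGG", "p.Val124Glyfs*60", "hom", Consequence.FRAMESHIFT, 0.0)]),
    ("P2", "LYST", [("c.9107-20_9109del", "", "hom", Consequence.SPLICE_REGION, 0.0)]),
    ("P22", "LYST", [("c.2749_2750del", "p.Arg917Glyfs*5", "hom", Consequence.FRAMESHIFT, 0.0)]),
    ("P53", "RAB27A", [("c.148_149delinsC", "p.Arg50Glnfs*35", "hom", Consequence.FRAMESHIFT, 0.0)]),
    ("P41", "RAB27A", [("c.514_518del", "p.Gln172Asnfs*2", "hom", Consequence.FRAMESHIFT, 0.0)]),
]
# P56 (STX11) and P26 (XIAP) are diagnosed via large exonic deletions
# found by coverage analysis; P11's second allele is the externally
# typed intronic inversion.

# patient -> [(gene, hgvs_c, hgvs_p)] of monoallelic damaging VUS
_VUS_GENOTYPES: dict[str, list[tuple[str, str, str]]] = {
    "P3": [("PRF1", "c.272C>T", "p.Ala91Val")],
    "P4": [("PRF1", "c.272C>T", "p.Ala91Val"),
           ("STXBP2", "c.1034C>T", "p.Thr345Met")],
    "P5": [("PRF1", "c.272C>T", "p.Ala91Val")],
    "P6": [("UNC13D", "c.1579C>T", "p.Arg527Trp")],
    "P7": [("STXBP2", "c.1247G>A", "p.Arg416His")],
    "P8": [("LYST", "c.4189T>G", "p.Phe1397Val")],
    "P12": [("RAB27A", "c.239G>C", "p.Arg80Thr")],
    "P13": [("AP3B1", "c.502C>T", "p.Arg168Cys")],
    "P14": [("ITK", "c.1741C>T", "p.Arg581Trp")],
}


@dataclass
class CohortBundle:
    """The encoded prospective cohort, ready for the pipeline."""

    genes: list[PanelGene]
    amplicons: list[Amplicon]
    patients: list[PatientRecord]
    variants: list[AnnotatedVariant]
    genotypes: list[GenotypeCall]
    external_alleles: list[ExternalAllele]
    coverage: CoverageMatrix
    coverage_truth: CoverageTruth
    sexes: dict[str, str]


def prospective_cohort(seed: int = 0) -> CohortBundle:
    """Build the 58-patient prospective cohort.

    Small-variant genotypes, metadata and the inversion allele are the
    reported per-patient values; the coverage matrix (with the two
    exonic deletions of P56/STX11 and P26/XIAP planted, plus two failed
    amplicons) is simulated, so deletion diagnoses must be produced by
    the CNV caller at run time.
    """
    _POS_COUNTER.clear()
    genes, amplicons = default_panel()

    diagnosed_ids = [p for p, _, _ in _DIAGNOSED_GENOTYPES] + ["P56", "P26"]
    vus_ids = list(_VUS_GENOTYPES)
    all_ids = [f"P{i}" for i in range(1, 59)]
    undiagnosed_ids = [i for i in all_ids if i not in diagnosed_ids]

    # ages: diagnosed 13 / 4 / 4 / 1 / 0 per bin; undiagnosed
    # 7 / 8 / 5 / 7 / 8 plus one unknown age (age denominators are 57)
    ages: dict[str, float | None] = {}
    d_order = [p for p in all_ids if p in diagnosed_ids]
    d_order.remove("P48")
    for pid, age in zip(d_order, [0.5] * 13 + [3.0] * 4 + [8.0] * 4):
        ages[pid] = age
    ages["P48"] = 16.0  # the oldest patient with primary HLH, bin 12-18
    u_order = [p for p in all_ids if p in undiagnosed_ids]
    u_ages: list[float | None] = [0.5] * 7 + [3.0] * 8 + [8.0] * 5 + [15.0] * 7 + [30.0] * 8 + [None]
    for pid, age in zip(u_order, u_ages):
        ages[pid] = age

    # triggers: 4 of 22 diagnosed (infectious), 22 of 36 undiagnosed
    triggers: dict[str, str] = {}
    for i, pid in enumerate([p for p in all_ids if p in diagnosed_ids]):
        triggers[pid] = "EBV" if i < 4 else "none"
    u_triggers = ["EBV"] * 10 + ["other_infection"] * 4 + ["malignancy"] * 3 + ["autoimmune"] * 5 + ["none"] * 14
    for pid, trig in zip(u_order, u_triggers):
        triggers[pid] = trig

    sexes = {pid: ("M" if i % 2 == 0 else "F") for i, pid in enumerate(all_ids)}
    sexes["P26"] = "M"  # hemizygous XIAP deletion requires a male

    patients = [
        PatientRecord(
            id=pid,
            age_at_diagnosis=ages[pid],
            sex=sexes[pid],
            trigger=triggers[pid],
        )
        for pid in all_ids
    ]

    variants: dict[tuple, AnnotatedVariant] = {}
    genotypes: list[GenotypeCall] = []

    def add(gene: str, hgvs_c: str, hgvs_p: str, zyg: str, conseq: Consequence,
            maf: float, sample: str) -> None:
        existing = next(
            (v for v in variants.values() if v.gene == gene and v.hgvs_c == hgvs_c),
            None,
        )
        if existing is None:
            damaging = conseq is Consequence.MISSENSE
            existing = AnnotatedVariant(
                chromosome=_GENE_CHROM[gene],
                position=_pos(gene),
                ref="G",
                alt="A",
                gene=gene,
                consequence=conseq,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                maf=maf,
                sift_pred="deleterious" if damaging else None,
                polyphen_pred="probably_damaging" if damaging else None,
            )
            variants[existing.key] = existing
        genotypes.append(GenotypeCall(sample, existing.key, Zygosity(zyg)))

    for pid, gene, alleles in _DIAGNOSED_GENOTYPES:
        for hgvs_c, hgvs_p, zyg, conseq, maf in alleles:
            add(gene, hgvs_c, hgvs_p, zyg, conseq, maf, pid)
    for pid, vus_list in _VUS_GENOTYPES.items():
        for gene, hgvs_c, hgvs_p in vus_list:
            add(gene, hgvs_c, hgvs_p, "het", Consequence.MISSENSE, 0.02, pid)

    external = [
        ExternalAllele(
            sample_id="P11",
            gene="UNC13D",
            description="intronic inversion (multiplex PCR typed)",
            zygosity=Zygosity.HET,
        )
    ]

    # coverage with the two exonic deletions planted
    stx11_n = sum(1 for a in amplicons if a.gene == "STX11")
    xiap_n = sum(1 for a in amplicons if a.gene == "XIAP")
    config = SimulationConfig(
        seed=seed,
        n_samples=58,
        deletion_specs=(
            DeletionSpec(all_ids.index("P56"), "STX11", 2, min(6, stx11_n - 2), "hom"),
            DeletionSpec(all_ids.index("P26"), "XIAP", 0, xiap_n, "hemi"),
        ),
    )
    coverage, cov_truth = simulate_coverage(genes, amplicons, config)
    coverage.depth.index = all_ids  # samples are the cohort patients
    for rec in cov_truth.deletions:
        rec["sample"] = all_ids[int(rec["sample"][1:]) - 1]

    return CohortBundle(
        genes=genes,
        amplicons=amplicons,
        patients=patients,
        variants=list(variants.values()),
        genotypes=genotypes,
        external_alleles=external,
        coverage=coverage,
        coverage_truth=cov_truth,
        sexes=sexes,
    )
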