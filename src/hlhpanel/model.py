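"""Domain types shared by every stage of the HLH panel pipeline.

The pipeline operates on a 12-gene targeted amplicon panel for
hemophagocytic lymphohistiocytosis (HLH) and related lymphoproliferative
syndromes.  Genes are either autosomal recessive (AR; two pathogenic
alleles required) or X-linked (XL; one hemizygous allele in a male
suffices).  Coordinates are 0-based half-open internally (BED
convention); VCF positions are converted on ingest.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Inheritance",
    "Zygosity",
    "Consequence",
    "IMPACT_CONSEQUENCES",
    "LOF_CONSEQUENCES",
    "CONSEQUENCE_DIALECT",
    "normalize_consequence",
    "PanelGene",
    "Amplicon",
    "CoverageMatrix",
    "AnnotatedVariant",
    "GenotypeCall",
    "ExternalAllele",
    "PatientRecord",
    "DiagnosisResult",
    "DeletionCall",
    "FilterStep",
    "FilterTrace",
    "AGE_BINS",
    "age_bin_of",
]


class Inheritance(str, enum.Enum):
    """Inheritance model of a panel gene."""

    AR = "AR"
    XL = "XL"


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


class Consequence(str, enum.Enum):
    """Internal controlled vocabulary for variant consequences."""

    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_REGION = "splice_region"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    UTR = "UTR"
    REGULATORY = "regulatory"
    OTHER = "other"


#: Consequences retained by the protein-impact filter.
IMPACT_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.STOP_GAINED,
        Consequence.STOP_LOST,
        Consequence.START_LOST,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
        Consequence.SPLICE_DONOR,
        Consequence.SPLICE_ACCEPTOR,
        Consequence.SPLICE_REGION,
    }
)

#: Loss-of-function classes that bypass the in-silico damaging filter
#: (SIFT/PolyPhen-2 score missense only).
LOF_CONSEQUENCES = frozenset(
    {
        Consequence.STOP_GAINED,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_DONOR,
        Consequence.SPLICE_ACCEPTOR,
    }
)

#: Mapping from common annotation dialects (VEP / SnpEff style terms) to
#: the internal vocabulary.
CONSEQUENCE_DIALECT: Mapping[str, Consequence] = {
    "missense_variant": Consequence.MISSENSE,
    "missense": Consequence.MISSENSE,
    "stop_gained": Consequence.STOP_GAINED,
    "nonsense": Consequence.STOP_GAINED,
    "stop_lost": Consequence.STOP_LOST,
    "start_lost": Consequence.START_LOST,
    "initiator_codon_variant": Consequence.START_LOST,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "frameshift": Consequence.FRAMESHIFT,
    "inframe_insertion": Consequence.INFRAME_INDEL,
    "inframe_deletion": Consequence.INFRAME_INDEL,
    "inframe_indel": Consequence.INFRAME_INDEL,
    "splice_donor_variant": Consequence.SPLICE_DONOR,
    "splice_donor": Consequence.SPLICE_DONOR,
    "splice_acceptor_variant": Consequence.SPLICE_ACCEPTOR,
    "splice_acceptor": Consequence.SPLICE_ACCEPTOR,
    "splice_region_variant": Consequence.SPLICE_REGION,
    "splice_region": Consequence.SPLICE_REGION,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "synonymous": Consequence.SYNONYMOUS,
    "stop_retained_variant": Consequence.SYNONYMOUS,
    "intron_variant": Consequence.INTRONIC,
    "intronic": Consequence.INTRONIC,
    "5_prime_UTR_variant": Consequence.UTR,
    "3_prime_UTR_variant": Consequence.UTR,
    "UTR": Consequence.UTR,
    "regulatory_region_variant": Consequence.REGULATORY,
    "regulatory": Consequence.REGULATORY,
    "upstream_gene_variant": Consequence.REGULATORY,
    "downstream_gene_variant": Consequence.REGULATORY,
}


def normalize_consequence(term: str) -> Consequence:
    """Map an annotation-dialect consequence term to the internal enum.

    Unknown terms map to :attr:`Consequence.OTHER`; downstream filters
    treat ``OTHER`` conservatively (retained and flagged).
    """
    return CONSEQUENCE_DIALECT.get(term.strip(), Consequence.OTHER)


@dataclass(frozen=True)
class PanelGene:
    """One gene of the diagnostic panel."""

    name: str
    chromosome: str
    inheritance: Inheritance
    associated_disease: str
    transcript_id: str = ""

    def __post_init__(self) -> None:
        is_x = self.chromosome.removeprefix("chr") == "X"
        if (self.inheritance is Inheritance.XL) != is_x:
            raise ValueError(
                f"gene {self.name}: inheritance {self.inheritance.value} "
                f"inconsistent with chromosome {self.chromosome} "
                "(XL if and only if chrX)"
            )


@dataclass(frozen=True)
class Amplicon:
    """One PCR-targeted interval; coordinates 0-based half-open."""

    id: str
    gene: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"amplicon {self.id}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chromosome: str, pos0: int) -> bool:
        """True if the 0-based point ``pos0`` lies inside this amplicon."""
        return self.chromosome == chromosome and self.start <= pos0 < self.end


@dataclass
class CoverageMatrix:
    """Samples x amplicons mean read depth.

    ``depth`` is a DataFrame with sample ids as index and amplicon ids
    as columns; all entries are non-negative.
    """

    depth: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.depth.to_numpy() < 0).any():
            raise ValueError("coverage depths must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.depth.index)

    @property
    def amplicons(self) -> list[str]:
        return list(self.depth.columns)


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated site.  ``position`` is 1-based (VCF convention)."""

    chromosome: str
    position: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    hgvs_c: str = ""
    hgvs_p: str = ""
    maf: float | None = None
    sift_pred: str | None = None  # deleterious / tolerated / None
    polyphen_pred: str | None = None  # probably_damaging / possibly_damaging / benign / None
    cadd: float | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.key}: ref equals alt")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"{self.key}: MAF {self.maf} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)

    @property
    def is_lof(self) -> bool:
        return self.consequence in LOF_CONSEQUENCES

    @property
    def is_damaging_predicted(self) -> bool:
        """At least one in-silico damaging prediction by SIFT or PolyPhen-2."""
        return self.sift_pred == "deleterious" or self.polyphen_pred in (
            "probably_damaging",
            "possibly_damaging",
        )


@dataclass(frozen=True)
class GenotypeCall:
    """Zygosity of one sample at one variant."""

    sample_id: str
    variant_key: tuple[str, int, str, str]
    zygosity: Zygosity
    flagged: bool = False  # e.g. X het/hom call with unknown sex


@dataclass(frozen=True)
class ExternalAllele:
    """An externally typed allele (e.g. an intronic inversion detected by
    a dedicated multiplex PCR assay) that can complete a compound-het
    diagnosis alongside a panel-detected small variant."""

    sample_id: str
    gene: str
    description: str
    zygosity: Zygosity


AGE_BINS: Sequence[tuple[str, float, float]] = (
    ("0-1", 0.0, 1.0),
    ("1-5", 1.0, 5.0),
    ("5-12", 5.0, 12.0),
    ("12-18", 12.0, 18.0),
    ("18+", 18.0, float("inf")),
)


def age_bin_of(age_years: float | None) -> str | None:
    """Assign the clinical age bin; bins are left-closed, right-open."""
    if age_years is None:
        return None
    if age_years < 0:
        raise ValueError(f"negative age: {age_years}")
    for label, lo, hi in AGE_BINS:
        if lo <= age_years < hi:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class PatientRecord:
    """Clinical metadata for one cohort patient."""

    id: str
    age_at_diagnosis: float | None
    sex: str  # "M" / "F"
    consanguinity: str = "unknown"  # yes / no / unknown
    albinism: str = "unknown"
    family_history: str = "unknown"
    trigger: str = "none"  # none / EBV / other_infection / malignancy / autoimmune / unknown

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"patient {self.id}: sex must be M or F, got {self.sex!r}")

    @property
    def age_bin(self) -> str | None:
        return age_bin_of(self.age_at_diagnosis)


@dataclass(frozen=True)
class DeletionCall:
    """A multi-amplicon homozygous/hemizygous exonic deletion call."""

    sample_id: str
    gene: str
    first_amplicon: str
    last_amplicon: str
    n_amplicons: int
    zygosity_label: str  # "homozygous" | "hemizygous"
    mean_ratio: float
    amplicon_ratios: tuple[float, ...] = ()

    @property
    def zygosity(self) -> Zygosity:
        return Zygosity.HEMI if self.zygosity_label == "hemizygous" else Zygosity.HOM


@dataclass(frozen=True)
class DiagnosisResult:
    """Molecular classification of one patient."""

    patient_id: str
    status: str  # diagnosed / vus_only / undiagnosed
    causal_gene: str | None = None
    causal_variants: tuple[str, ...] = ()
    disease_label: str | None = None
    notes: str = ""


@dataclass(frozen=True)
class FilterStep:
    name: str
    input_count: int
    output_count: int
    by_consequence: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.output_count > self.input_count:
            raise ValueError(
                f"filter step {self.name}: output {self.output_count} exceeds "
                f"input {self.input_count}"
            )


@dataclass
class FilterTrace:
    """Per-step survivor counts of the filter cascade."""

    steps: list[FilterStep] = field(default_factory=list)

    def add(
        self,
        name: str,
        input_count: int,
        output_count: int,
        by_consequence: Mapping[str, int] | None = None,
    ) -> None:
        if self.steps and input_count != self.steps[-1].output_count:
            raise ValueError(
                f"filter step {name}: input count {input_count} does not match "
                f"previous output {self.steps[-1].output_count}"
            )
        breakdown = tuple(sorted((by_consequence or {}).items()))
        self.steps.append(FilterStep(name, input_count, output_count, breakdown))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.name,
                    "input": s.input_count,
                    "output": s.output_count,
                    "breakdown": ";".join(f"{k}={v}" for k, v in s.by_consequence),
                }
                for s in self.steps
            ]
        )


def amplicons_by_gene(amplicons: Iterable[Amplicon]) -> dict[str, list[Amplicon]]:
    """Group amplicons by gene, each group sorted by genomic position."""
    groups: dict[str, list[Amplicon]] = {}
    for amp in amplicons:
        groups.setdefault(amp.gene, []).append(amp)
    for amps in groups.values():
        amps.sort(key=lambda a: (a.chromosome, a.start, a.end))
    return groups
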