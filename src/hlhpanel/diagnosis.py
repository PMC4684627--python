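"""Zygosity-aware molecular diagnosis and cohort yield statistics.

A patient is molecularly diagnosed when one autosomal-recessive panel
gene carries a homozygous qualifying variant, two distinct heterozygous
qualifying variants (presumed compound heterozygous in trans unless
parental genotypes veto), or a homozygous exonic-deletion call — or
when an X-linked gene in a male carries a hemizygous qualifying variant
or hemizygous deletion call.  Externally typed alleles (e.g. an
intronic inversion detected by a dedicated PCR assay) can complete a
compound-heterozygous pair.  A female heterozygous for an X-linked
variant is a carrier, never diagnosed.  Patients left without a
diagnosis but carrying at least one damaging-predicted monoallelic
variant are classified ``vus_only``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AnnotatedVariant,
    DeletionCall,
    DiagnosisResult,
    ExternalAllele,
    GenotypeCall,
    Inheritance,
    PanelGene,
    PatientRecord,
    Zygosity,
    AGE_BINS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InheritanceModel",
    "classify_patient",
    "classify_cohort",
    "CohortYield",
    "cohort_yield",
    "trigger_table",
]


@dataclass(frozen=True)
class InheritanceModel:
    """Gene -> inheritance and gene -> disease-label maps."""

    inheritance: Mapping[str, Inheritance]
    disease_label: Mapping[str, str]

    @classmethod
    def from_genes(cls, genes: Sequence[PanelGene]) -> "InheritanceModel":
        return cls(
            inheritance={g.name: g.inheritance for g in genes},
            disease_label={g.name: g.associated_disease for g in genes},
        )


def _variant_label(v: AnnotatedVariant, zyg: Zygosity) -> str:
    name = v.hgvs_c or f"{v.chromosome}:{v.position}{v.ref}>{v.alt}"
    return f"{v.gene}:{name}({zyg.value})"


def classify_patient(
    patient: PatientRecord,
    variants: Sequence[AnnotatedVariant],
    genotypes: Sequence[GenotypeCall],
    model: InheritanceModel,
    deletion_calls: Sequence[DeletionCall] = (),
    external_alleles: Sequence[ExternalAllele] = (),
) -> DiagnosisResult:
    """Classify one patient from qualifying variants and structural calls.

    ``variants``/``genotypes`` must already have passed the patient-mode
    cascade (plus any manual-curation allow/deny list); only this
    patient's genotypes are considered.
    """
    by_key = {v.key: v for v in variants}
    notes: list[str] = []

    # gene -> list of (label, zygosity, position-or-None)
    alleles: dict[str, list[tuple[str, Zygosity, int | None]]] = {}
    for gt in genotypes:
        if gt.sample_id != patient.id or gt.variant_key not in by_key:
            continue
        v = by_key[gt.variant_key]
        alleles.setdefault(v.gene, []).append(
            (_variant_label(v, gt.zygosity), gt.zygosity, v.position)
        )
    for call in deletion_calls:
        if call.sample_id != patient.id:
            continue
        label = f"{call.gene}:exonic_deletion({call.zygosity_label})"
        alleles.setdefault(call.gene, []).append((label, call.zygosity, None))
    for ext in external_alleles:
        if ext.sample_id != patient.id:
            continue
        alleles.setdefault(ext.gene, []).append(
            (f"{ext.gene}:{ext.description}({ext.zygosity.value})", ext.zygosity, None)
        )

    for gene in sorted(alleles):
        inh = model.inheritance.get(gene)
        if inh is None:
            logger.warning("patient %s: gene %s not in panel model", patient.id, gene)
            continue
        entries = alleles[gene]
        if inh is Inheritance.XL:
            if patient.sex == "M":
                hemi = [e for e in entries if e[1] is Zygosity.HEMI]
                if hemi:
                    return DiagnosisResult(
                        patient_id=patient.id,
                        status="diagnosed",
                        causal_gene=gene,
                        causal_variants=(hemi[0][0],),
                        disease_label=model.disease_label.get(gene),
                    )
            continue  # female XL het = carrier, never diagnosed here
        # autosomal recessive
        homs = [e for e in entries if e[1] is Zygosity.HOM]
        if homs:
            return DiagnosisResult(
                patient_id=patient.id,
                status="diagnosed",
                causal_gene=gene,
                causal_variants=(homs[0][0],),
                disease_label=model.disease_label.get(gene),
            )
        hets = [e for e in entries if e[1] is Zygosity.HET]
        if len(hets) >= 2:
            positions = [p for _, _, p in hets]
            distinct = {p for p in positions if p is not None}
            # same-position het pair = candidate same allele, not compound het
            if len(distinct) + sum(1 for p in positions if p is None) >= 2:
                pair = tuple(label for label, _, _ in hets[:2])
                return DiagnosisResult(
                    patient_id=patient.id,
                    status="diagnosed",
                    causal_gene=gene,
                    causal_variants=pair,
                    disease_label=model.disease_label.get(gene),
                    notes="presumed compound heterozygous (phase unconfirmed)",
                )
            notes.append(
                f"{gene}: two het calls at one position — same-allele candidate, "
                "flagged for review"
            )

    # no diagnosis: VUS tier if any damaging-predicted monoallelic variant
    has_vus = False
    vus_labels = []
    for gt in genotypes:
        if gt.sample_id != patient.id or gt.variant_key not in by_key:
            continue
        v = by_key[gt.variant_key]
        if gt.zygosity is Zygosity.HET and (v.is_damaging_predicted or v.is_lof):
            has_vus = True
            vus_labels.append(_variant_label(v, gt.zygosity))
    if has_vus:
        return DiagnosisResult(
            patient_id=patient.id,
            status="vus_only",
            causal_variants=tuple(vus_labels),
            notes="; ".join(notes),
        )
    return DiagnosisResult(patient_id=patient.id, status="undiagnosed", notes="; ".join(notes))


def classify_cohort(
    patients: Sequence[PatientRecord],
    variants: Sequence[AnnotatedVariant],
    genotypes: Sequence[GenotypeCall],
    model: InheritanceModel,
    deletion_calls: Sequence[DeletionCall] = (),
    external_alleles: Sequence[ExternalAllele] = (),
) -> list[DiagnosisResult]:
    return [
        classify_patient(p, variants, genotypes, model, deletion_calls, external_alleles)
        for p in patients
    ]


@dataclass
class CohortYield:
    """Diagnostic-yield fractions with exact numerators/denominators."""

    overall: tuple[int, int]
    per_bin: dict[str, tuple[int, int]]
    older: tuple[int, int]  # known age >= 1 year
    pediatric: tuple[int, int]  # not in the 18+ bin (unknown age counted pediatric)
    vus_among_undiagnosed: tuple[int, int]

    @staticmethod
    def pct(frac: tuple[int, int]) -> float:
        num, den = frac
        return 100.0 * num / den if den else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [("overall", *self.overall)]
        rows += [(f"age {b}", *self.per_bin[b]) for b, _, _ in AGE_BINS]
        rows += [
            ("older (>=1y)", *self.older),
            ("pediatric (<18y)", *self.pediatric),
            ("VUS among undiagnosed", *self.vus_among_undiagnosed),
        ]
        df = pd.DataFrame(rows, columns=["group", "n", "denominator"])
        df["percent"] = [
            round(self.pct((n, d)), 1) if d else float("nan")
            for n, d in zip(df["n"], df["denominator"])
        ]
        return df


def cohort_yield(
    results: Sequence[DiagnosisResult],
    patients: Sequence[PatientRecord],
) -> CohortYield:
    """Diagnostic yields overall, per age bin, for older (>= 1 year)
    and pediatric (< 18 years) subsets, and the fraction of undiagnosed
    patients carrying a monoallelic VUS.

    Patients with unknown age are excluded from age-binned and older
    yields but included overall and in the pediatric subset (logged).
    """
    if not patients:
        return CohortYield((0, 0), {b: (0, 0) for b, _, _ in AGE_BINS}, (0, 0), (0, 0), (0, 0))
    status = {r.patient_id: r.status for r in results}
    missing = [p.id for p in patients if p.id not in status]
    if missing:
        raise ValueError(f"patients without a diagnosis result: {missing}")
    diagnosed = {p.id for p in patients if status[p.id] == "diagnosed"}
    overall = (len(diagnosed), len(patients))
    per_bin: dict[str, tuple[int, int]] = {}
    for label, _, _ in AGE_BINS:
        members = [p for p in patients if p.age_bin == label]
        per_bin[label] = (sum(1 for p in members if p.id in diagnosed), len(members))
    unknown_age = [p for p in patients if p.age_bin is None]
    if unknown_age:
        logger.info(
            "%d patients with unknown age excluded from binned yields", len(unknown_age)
        )
    older = [p for p in patients if p.age_bin not in (None, "0-1")]
    older_frac = (sum(1 for p in older if p.id in diagnosed), len(older))
    pediatric = [p for p in patients if p.age_bin != "18+"]
    ped_frac = (sum(1 for p in pediatric if p.id in diagnosed), len(pediatric))
    undiag = [p for p in patients if status[p.id] != "diagnosed"]
    vus = sum(1 for p in undiag if status[p.id] == "vus_only")
    return CohortYield(overall, per_bin, older_frac, ped_frac, (vus, len(undiag)))


def trigger_table(
    results: Sequence[DiagnosisResult],
    patients: Sequence[PatientRecord],
    exclude_unknown: bool = True,
) -> np.ndarray:
    """2x2 counts for trigger enrichment.

    Rows: [undiagnosed (incl. vus_only), diagnosed]; columns:
    [trigger present, trigger absent].  ``unknown`` triggers are
    excluded by default; ``none`` counts as absent.
    """
    status = {r.patient_id: r.status for r in results}
    table = np.zeros((2, 2), dtype=int)
    for p in patients:
        if p.trigger == "unknown" and exclude_unknown:
            continue
        row = 1 if status.get(p.id) == "diagnosed" else 0
        col = 1 if p.trigger in ("none", "unknown") else 0
        table[row, col] += 1
    return table
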