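"""Readers and writers for the plain-text formats the pipeline touches.

Formats: BED (panel geometry), YAML (gene configuration, thresholds),
TSV (coverage matrix, variant tables, patient metadata, reports) and
VCF 4.x (variant calls with annotations in INFO).  Internal coordinates
are 0-based half-open; VCF positions are 1-based and converted on
ingest for interval arithmetic only (the ``position`` field of
:class:`AnnotatedVariant` stays 1-based, VCF convention).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .model import (
    Amplicon,
    AnnotatedVariant,
    CoverageMatrix,
    GenotypeCall,
    Inheritance,
    PanelGene,
    PatientRecord,
    Zygosity,
    normalize_consequence,
)

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "hgvs_c",
    "hgvs_p",
    "maf",
    "sift",
    "polyphen",
    "cadd",
    "sample",
    "zygosity",
]


# ---------------------------------------------------------------------------
# panel


def load_panel(
    bed_path: str | Path, gene_config_path: str | Path
) -> tuple[list[PanelGene], list[Amplicon]]:
    """Load panel geometry (BED, 4+ columns) and gene configuration (YAML).

    Every amplicon must map, via the 4th BED column ``<GENE>_<suffix>``
    or an exact gene-name match, to a gene declared in the config.
    """
    genes = load_gene_config(gene_config_path)
    known = {g.name for g in genes}
    amplicons: list[Amplicon] = []
    seen_ids: set[str] = set()
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{bed_path}:{lineno}: BED needs >= 4 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, amp_id = fields[:4]
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise ValueError(
                    f"{bed_path}:{lineno}: malformed interval ({start}, {end}) "
                    f"for amplicon {amp_id!r}"
                )
            gene = amp_id.split("_")[0] if "_" in amp_id else amp_id
            if gene not in known:
                raise ValueError(
                    f"{bed_path}:{lineno}: amplicon {amp_id!r} references unknown "
                    f"gene {gene!r} (line: {line!r})"
                )
            if amp_id in seen_ids:
                raise ValueError(f"{bed_path}:{lineno}: duplicate amplicon id {amp_id!r}")
            seen_ids.add(amp_id)
            amplicons.append(Amplicon(amp_id, gene, chrom, start, end))
    return genes, amplicons


def load_gene_config(path: str | Path) -> list[PanelGene]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    genes = []
    for entry in cfg["genes"]:
        genes.append(
            PanelGene(
                name=entry["name"],
                chromosome=entry["chromosome"],
                inheritance=Inheritance(entry["inheritance"]),
                associated_disease=entry.get("associated_disease", ""),
                transcript_id=entry.get("transcript_id", ""),
            )
        )
    return genes


def write_gene_config(genes: Sequence[PanelGene], path: str | Path) -> None:
    payload = {
        "genes": [
            {
                "name": g.name,
                "chromosome": g.chromosome,
                "inheritance": g.inheritance.value,
                "associated_disease": g.associated_disease,
                "transcript_id": g.transcript_id,
            }
            for g in genes
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def write_panel_bed(amplicons: Sequence[Amplicon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in amplicons:
            fh.write(f"{a.chromosome}\t{a.start}\t{a.end}\t{a.id}\n")


# ---------------------------------------------------------------------------
# coverage matrix


def load_coverage(path: str | Path) -> CoverageMatrix:
    """TSV: first column sample id, one column per amplicon id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CoverageMatrix(depth=df.astype(float))


def write_coverage(matrix: CoverageMatrix, path: str | Path) -> None:
    df = matrix.depth.copy()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# variants


def _zygosity_from_alt_count(
    n_alt: int,
    ploidy: int,
    chromosome: str,
    sample_sex: str | None,
) -> tuple[Zygosity | None, bool]:
    """Map an alt-allele dosage to zygosity.

    Returns (zygosity, flagged).  On chrX, hom calls in known males are
    promoted to hemi; X calls with unknown sex are kept het/hom but
    flagged, never auto-promoted.
    """
    on_x = chromosome.removeprefix("chr") == "X"
    if n_alt == 0:
        return None, False
    if ploidy == 1:
        if on_x and sample_sex == "M":
            return Zygosity.HEMI, False
        return Zygosity.HET, True  # haploid call off-X or with unknown sex
    if n_alt >= ploidy:  # all called alleles are alt
        if on_x and sample_sex == "M":
            return Zygosity.HEMI, False
        return Zygosity.HOM, on_x and sample_sex is None
    return Zygosity.HET, on_x and sample_sex is None


def load_variants(
    path: str | Path,
    sex: Mapping[str, str] | None = None,
) -> tuple[list[AnnotatedVariant], list[GenotypeCall]]:
    """Load annotated variants plus per-sample genotypes (VCF or TSV).

    Dispatches on extension: ``.vcf`` uses cyvcf2, anything else is read
    as the flat TSV dialect (:data:`VARIANT_COLUMNS`).  Records lacking
    a consequence annotation are skipped with a logged count.
    Multi-allelic VCF records are split into one variant per alt.
    """
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _load_variants_vcf(path, sex or {})
    return _load_variants_tsv(path, sex or {})


def _load_variants_tsv(
    path: Path, sex: Mapping[str, str]
) -> tuple[list[AnnotatedVariant], list[GenotypeCall]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    variants: dict[tuple, AnnotatedVariant] = {}
    genotypes: list[GenotypeCall] = []
    n_skipped = 0
    for _, row in df.iterrows():
        if not row.get("consequence", ""):
            n_skipped += 1
            continue
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        if key not in variants:
            variants[key] = AnnotatedVariant(
                chromosome=key[0],
                position=key[1],
                ref=key[2],
                alt=key[3],
                gene=row.get("gene", ""),
                consequence=normalize_consequence(row["consequence"]),
                hgvs_c=row.get("hgvs_c", ""),
                hgvs_p=row.get("hgvs_p", ""),
                maf=float(row["maf"]) if row.get("maf", "") != "" else None,
                sift_pred=row.get("sift") or None,
                polyphen_pred=row.get("polyphen") or None,
                cadd=float(row["cadd"]) if row.get("cadd", "") != "" else None,
            )
        sample = row.get("sample", "")
        if sample:
            zyg = Zygosity(row["zygosity"])
            on_x = key[0].removeprefix("chr") == "X"
            flagged = on_x and sex.get(sample) is None and zyg is not Zygosity.HEMI
            if zyg is Zygosity.HEMI and not (on_x and sex.get(sample, "M") == "M"):
                raise ValueError(
                    f"{path}: hemizygous call for {sample} at {key} is only valid "
                    "on chrX in a male sample"
                )
            genotypes.append(GenotypeCall(sample, key, zyg, flagged=flagged))
    if n_skipped:
        logger.warning("%s: skipped %d records lacking a consequence", path, n_skipped)
    return list(variants.values()), genotypes


def _load_variants_vcf(
    path: Path, sex: Mapping[str, str]
) -> tuple[list[AnnotatedVariant], list[GenotypeCall]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: dict[tuple, AnnotatedVariant] = {}
    genotypes: list[GenotypeCall] = []
    n_skipped = 0
    for rec in vcf:
        conseq_raw = rec.INFO.get("CSQ") or rec.INFO.get("CONSEQUENCE")
        if conseq_raw is None:
            n_skipped += 1
            continue
        conseq_list = str(conseq_raw).split(",")
        maf_raw = rec.INFO.get("MAF")
        maf_list = str(maf_raw).split(",") if maf_raw is not None else []
        for ai, alt in enumerate(rec.ALT):
            conseq = conseq_list[ai] if ai < len(conseq_list) else conseq_list[0]
            maf = None
            if maf_list:
                m = maf_list[ai] if ai < len(maf_list) else maf_list[0]
                maf = float(m) if m not in ("", ".") else None
            key = (rec.CHROM, rec.POS, rec.REF, alt)
            if key not in variants:
                variants[key] = AnnotatedVariant(
                    chromosome=rec.CHROM,
                    position=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=str(rec.INFO.get("GENE") or ""),
                    consequence=normalize_consequence(conseq),
                    hgvs_c=str(rec.INFO.get("HGVSC") or ""),
                    hgvs_p=str(rec.INFO.get("HGVSP") or ""),
                    maf=maf,
                    sift_pred=rec.INFO.get("SIFT") or None,
                    polyphen_pred=rec.INFO.get("PP2") or None,
                    cadd=float(rec.INFO["CADD"]) if rec.INFO.get("CADD") else None,
                )
            alt_index = ai + 1
            for si, gt in enumerate(rec.genotypes):
                alleles = [a for a in gt[:-1] if a >= 0]
                if not alleles:
                    continue
                n_alt = sum(1 for a in alleles if a == alt_index)
                zyg, flagged = _zygosity_from_alt_count(
                    n_alt, len(alleles), rec.CHROM, sex.get(samples[si])
                )
                if zyg is not None:
                    genotypes.append(GenotypeCall(samples[si], key, zyg, flagged))
    if n_skipped:
        logger.warning("%s: skipped %d records lacking a consequence", path, n_skipped)
    return list(variants.values()), genotypes


def write_variants_tsv(
    variants: Iterable[AnnotatedVariant],
    genotypes: Iterable[GenotypeCall],
    path: str | Path,
) -> None:
    """Write the flat variant TSV (one row per genotype; carrier-less
    variants get one row with an empty sample column)."""
    by_key: dict[tuple, list[GenotypeCall]] = {}
    for gt in genotypes:
        by_key.setdefault(gt.variant_key, []).append(gt)
    rows = []
    for v in sorted(variants, key=lambda v: v.key):
        gts = sorted(by_key.get(v.key, []), key=lambda g: g.sample_id)
        base = {
            "chrom": v.chromosome,
            "pos": v.position,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "consequence": v.consequence.value,
            "hgvs_c": v.hgvs_c,
            "hgvs_p": v.hgvs_p,
            "maf": "" if v.maf is None else v.maf,
            "sift": v.sift_pred or "",
            "polyphen": v.polyphen_pred or "",
            "cadd": "" if v.cadd is None else v.cadd,
        }
        if not gts:
            rows.append({**base, "sample": "", "zygosity": ""})
        for gt in gts:
            rows.append({**base, "sample": gt.sample_id, "zygosity": gt.zygosity.value})
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_variants_vcf(
    variants: Iterable[AnnotatedVariant],
    genotypes: Iterable[GenotypeCall],
    samples: Sequence[str],
    path: str | Path,
) -> None:
    """Write a minimal annotated VCF 4.2 with one alt per record."""
    by_key: dict[tuple, dict[str, GenotypeCall]] = {}
    for gt in genotypes:
        by_key.setdefault(gt.variant_key, {})[gt.sample_id] = gt
    gt_string = {Zygosity.HET: "0/1", Zygosity.HOM: "1/1", Zygosity.HEMI: "1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for k, desc in [
            ("GENE", "Gene symbol"),
            ("CSQ", "Consequence (per alt)"),
            ("MAF", "Reference-population minor allele frequency"),
            ("SIFT", "SIFT prediction"),
            ("PP2", "PolyPhen-2 prediction"),
            ("CADD", "CADD phred score"),
            ("HGVSC", "HGVS cDNA"),
            ("HGVSP", "HGVS protein"),
        ]:
            num = "A" if k in ("CSQ", "MAF") else "1"
            typ = "Float" if k in ("MAF", "CADD") else "String"
            fh.write(f'##INFO=<ID={k},Number={num},Type={typ},Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in sorted(variants, key=lambda v: v.key):
            info = [f"GENE={v.gene}", f"CSQ={v.consequence.value}"]
            if v.maf is not None:
                info.append(f"MAF={v.maf:g}")
            if v.sift_pred:
                info.append(f"SIFT={v.sift_pred}")
            if v.polyphen_pred:
                info.append(f"PP2={v.polyphen_pred}")
            if v.cadd is not None:
                info.append(f"CADD={v.cadd:g}")
            if v.hgvs_c:
                info.append(f"HGVSC={v.hgvs_c}")
            gts = by_key.get(v.key, {})
            cols = [
                gt_string[gts[s].zygosity] if s in gts else "0/0" for s in samples
            ]
            fh.write(
                f"{v.chromosome}\t{v.position}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                + ";".join(info)
                + "\tGT\t"
                + "\t".join(cols)
                + "\n"
            )


# ---------------------------------------------------------------------------
# patients, sites, reports


def load_patients(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    patients = []
    for _, row in df.iterrows():
        age = row.get("age_at_diagnosis", "")
        patients.append(
            PatientRecord(
                id=row["id"],
                age_at_diagnosis=float(age) if age not in ("", "NA") else None,
                sex=row["sex"],
                consanguinity=row.get("consanguinity", "unknown") or "unknown",
                albinism=row.get("albinism", "unknown") or "unknown",
                family_history=row.get("family_history", "unknown") or "unknown",
                trigger=row.get("trigger", "unknown") or "unknown",
            )
        )
    return patients


def write_patients(patients: Sequence[PatientRecord], path: str | Path) -> None:
    rows = [
        {
            "id": p.id,
            "age_at_diagnosis": "" if p.age_at_diagnosis is None else p.age_at_diagnosis,
            "sex": p.sex,
            "consanguinity": p.consanguinity,
            "albinism": p.albinism,
            "family_history": p.family_history,
            "trigger": p.trigger,
        }
        for p in patients
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_sites(path: str | Path) -> list[tuple[str, int]]:
    """Known-mutation sites: TSV with columns chrom, pos (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int})
    return list(zip(df["chrom"], df["pos"]))


def write_report(df: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Deterministic report writer; identical inputs give identical bytes."""
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    elif format == "md":
        with open(path, "w") as fh:
            fh.write("| " + " | ".join(map(str, df.columns)) + " |\n")
            fh.write("|" + "---|" * len(df.columns) + "\n")
            for _, row in df.iterrows():
                fh.write("| " + " | ".join(str(x) for x in row) + " |\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
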