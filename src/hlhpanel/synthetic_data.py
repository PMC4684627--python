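"""Synthetic data with known ground truth for every pipeline stage.

Raw diagnostic-panel data are access-restricted, so simulation stands
in for them.  Three generators share one seed but use independent RNG
streams:

* ``simulate_coverage`` — per-(sample, amplicon) mean depths drawn from
  a negative binomial (overdispersed counts; Poisson in the large-
  dispersion limit) whose mean is the product of a global depth, a
  log-normal amplicon-efficiency factor and a log-normal library-size
  factor.  A configurable number of amplicons fail outright (mean
  forced to a few reads) and specified multi-amplicon deletions reduce
  the local mean to a residual background (default 1 read, so a caller
  threshold is meaningfully exercised).
* ``simulate_cohort`` — a patient cohort with planted biallelic,
  hemizygous, monoallelic-VUS and benign-only genotypes plus common
  background polymorphisms, and clinical metadata sampled from
  categorical distributions mirroring the reference cohort's make-up.
* ``simulate_population`` — per-site genotype counts (and an
  individual-level 0/1/2 matrix) multinomial around Hardy-Weinberg
  proportions, optionally distorted by a per-site inbreeding-like
  parameter f: P(AA), P(Aa), P(aa) = p^2+fpq, 2pq(1-f), q^2+fpq.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    Amplicon,
    AnnotatedVariant,
    Consequence,
    CoverageMatrix,
    GenotypeCall,
    Inheritance,
    PanelGene,
    PatientRecord,
    Zygosity,
    amplicons_by_gene,
)

__all__ = [
    "DeletionSpec",
    "PopulationSite",
    "SimulationConfig",
    "CoverageTruth",
    "CohortTruth",
    "simulate_coverage",
    "simulate_cohort",
    "simulate_population",
]


@dataclass(frozen=True)
class DeletionSpec:
    """A deletion to plant: ``n_amplicons`` consecutive amplicons of
    ``gene`` starting at 0-based in-gene index ``start_index``."""

    sample_index: int
    gene: str
    start_index: int
    n_amplicons: int
    zygosity: str = "hom"  # hom | hemi


@dataclass(frozen=True)
class PopulationSite:
    """One biallelic site for the population generator."""

    gene: str
    allele_freq: float
    distortion: float = 0.0  # inbreeding-like f; 0 = exact HWE proportions
    consequence: Consequence = Consequence.MISSENSE
    damaging: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.allele_freq < 1:
            raise ValueError("allele frequency must lie strictly in (0, 1)")


@dataclass
class SimulationConfig:
    """All knobs of the generators; identical seed => identical output.

    Defaults emulate the reference study conditions: a 58-patient
    prospective cohort with 22 molecularly diagnosable patients (21
    biallelic + 1 hemizygous), 9 monoallelic-VUS carriers among the
    remainder, two systematically failed amplicons, and a 2504-person
    reference population.
    """

    seed: int = 0
    # coverage
    n_samples: int = 58
    depth_mean: float = 200.0
    depth_dispersion: float = 5.0  # NB size parameter k; var = m + m^2/k
    amplicon_efficiency_sd: float = 0.4  # log-scale SD
    sample_factor_sd: float = 0.25  # log-scale SD
    n_failed_amplicons: int = 2
    failed_mean: float = 3.0
    deletion_residual_mean: float = 1.0
    deletion_specs: tuple[DeletionSpec, ...] = ()
    # cohort
    frac_biallelic: float = 21 / 58
    frac_hemizygous: float = 1 / 58
    frac_monoallelic_vus: float = 9 / 58
    female_fraction: float = 30 / 58
    background_poly_mean: float = 3.0  # common polymorphisms per patient
    # population
    pop_n: int = 2504
    pop_sites: tuple[PopulationSite, ...] = ()

    def __post_init__(self) -> None:
        fr = self.frac_biallelic + self.frac_hemizygous + self.frac_monoallelic_vus
        if fr > 1 + 1e-9:
            raise ValueError("cohort fractions must sum to <= 1")
        for sd in (self.amplicon_efficiency_sd, self.sample_factor_sd):
            if sd < 0:
                raise ValueError("factor SDs must be >= 0")
        if self.frac_hemizygous > 0 and self.female_fraction >= 1:
            raise ValueError(
                "hemizygous genotypes require male patients; female_fraction = 1"
            )


@dataclass
class CoverageTruth:
    failed: list[str]
    deletions: list[dict]


@dataclass
class CohortTruth:
    """Intended classification per patient: status and (optionally) gene."""

    labels: dict[str, dict]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, k: float
) -> np.ndarray:
    """Negative binomial with mean ``mean`` and size ``k``; Poisson when
    k is infinite."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    if not np.isfinite(k):
        return rng.poisson(mean).astype(float)
    p = k / (k + mean)
    return rng.negative_binomial(k, p).astype(float)


def simulate_coverage(
    genes: Sequence[PanelGene],
    amplicons: Sequence[Amplicon],
    config: SimulationConfig,
) -> tuple[CoverageMatrix, CoverageTruth]:
    """Simulate the samples x amplicons depth matrix with truth."""
    rng = _rng(config, 1)
    by_gene = amplicons_by_gene(amplicons)
    amp_ids = [a.id for a in amplicons]
    n_s, n_a = config.n_samples, len(amplicons)

    # choose failed amplicons away from planted deletions
    deleted_ids: set[str] = set()
    deletions: list[dict] = []
    for spec in config.deletion_specs:
        if spec.gene not in by_gene:
            raise ValueError(f"deletion spec references unknown gene {spec.gene}")
        gene_amps = by_gene[spec.gene]
        if spec.start_index + spec.n_amplicons > len(gene_amps):
            raise ValueError(
                f"deletion run exceeds {spec.gene} amplicon count "
                f"({len(gene_amps)})"
            )
        if not 0 <= spec.sample_index < n_s:
            raise ValueError("deletion sample index out of range")
        run = gene_amps[spec.start_index : spec.start_index + spec.n_amplicons]
        deleted_ids.update(a.id for a in run)
        deletions.append(
            {
                "sample": f"S{spec.sample_index + 1:03d}",
                "gene": spec.gene,
                "amplicons": [a.id for a in run],
                "zygosity": spec.zygosity,
            }
        )
    candidates = [a for a in amp_ids if a not in deleted_ids]
    if config.n_failed_amplicons > len(candidates):
        raise ValueError("more failed amplicons requested than available")
    failed = sorted(
        str(a) for a in rng.choice(candidates, size=config.n_failed_amplicons, replace=False)
    )
    # a deletion overlapping a failed amplicon would confound the truth
    if deleted_ids & set(failed):
        raise ValueError("deletion overlaps a designated failed amplicon")

    amp_factor = np.exp(
        rng.normal(0.0, config.amplicon_efficiency_sd, size=n_a)
        - config.amplicon_efficiency_sd**2 / 2
    )
    sample_factor = np.exp(
        rng.normal(0.0, config.sample_factor_sd, size=n_s)
        - config.sample_factor_sd**2 / 2
    )
    mean = config.depth_mean * np.outer(sample_factor, amp_factor)
    amp_index = {aid: i for i, aid in enumerate(amp_ids)}
    for aid in failed:
        mean[:, amp_index[aid]] = min(config.failed_mean, 10.0)
    for rec in deletions:
        si = int(rec["sample"][1:]) - 1
        for aid in rec["amplicons"]:
            mean[si, amp_index[aid]] = config.deletion_residual_mean
    depth = _nb_draw(rng, mean, config.depth_dispersion)
    samples = [f"S{i + 1:03d}" for i in range(n_s)]
    matrix = CoverageMatrix(
        depth=pd.DataFrame(depth, index=samples, columns=amp_ids)
    )
    return matrix, CoverageTruth(failed=list(failed), deletions=deletions)


_PATHOGENIC_TEMPLATES = (
    (Consequence.MISSENSE, "deleterious", "probably_damaging"),
    (Consequence.STOP_GAINED, None, None),
    (Consequence.FRAMESHIFT, None, None),
    (Consequence.SPLICE_DONOR, None, None),
    (Consequence.MISSENSE, "deleterious", "benign"),
)


def _plant_variant(
    rng: np.random.Generator,
    gene: PanelGene,
    gene_amps: Sequence[Amplicon],
    used_positions: set[int],
    template_i: int,
    maf: float = 0.0005,
) -> AnnotatedVariant:
    conseq, sift, pp2 = _PATHOGENIC_TEMPLATES[template_i % len(_PATHOGENIC_TEMPLATES)]
    amp = gene_amps[int(rng.integers(len(gene_amps)))]
    pos = int(rng.integers(amp.start + 1, amp.end + 1))  # 1-based inside amplicon
    while pos in used_positions:
        pos += 1
    used_positions.add(pos)
    bases = ["A", "C", "G", "T"]
    ref, alt = rng.choice(bases, size=2, replace=False)
    return AnnotatedVariant(
        chromosome=gene.chromosome,
        position=pos,
        ref=str(ref),
        alt=str(alt),
        gene=gene.name,
        consequence=conseq,
        hgvs_c=f"c.{pos % 3000 + 1}{ref}>{alt}",
        maf=maf,
        sift_pred=sift,
        polyphen_pred=pp2,
        cadd=float(rng.uniform(20, 35)) if (sift or conseq is not Consequence.MISSENSE) else None,
    )


def simulate_cohort(
    genes: Sequence[PanelGene],
    amplicons: Sequence[Amplicon],
    config: SimulationConfig,
) -> tuple[
    list[AnnotatedVariant],
    list[GenotypeCall],
    list[PatientRecord],
    CohortTruth,
]:
    """Simulate a patient cohort with planted diagnostic genotypes.

    Biallelic patients receive one homozygous or two distinct
    heterozygous qualifying variants in one AR gene (alternating);
    hemizygous patients are male with one XL variant; monoallelic-VUS
    patients carry exactly one damaging-predicted heterozygous variant;
    everyone additionally receives common benign background
    polymorphisms and occasional rare synonymous variants.
    """
    rng = _rng(config, 2)
    by_gene = amplicons_by_gene(amplicons)
    ar_genes = [g for g in genes if g.inheritance is Inheritance.AR and g.name in by_gene]
    xl_genes = [g for g in genes if g.inheritance is Inheritance.XL and g.name in by_gene]
    n = config.n_samples
    n_bi = round(config.frac_biallelic * n)
    n_hemi = round(config.frac_hemizygous * n)
    n_vus = round(config.frac_monoallelic_vus * n)
    if n_bi + n_hemi + n_vus > n:
        raise ValueError("cohort fractions exceed the cohort size")
    if n_hemi > 0 and not xl_genes:
        raise ValueError("hemizygous genotypes requested but panel has no XL gene")

    # patient metadata; age-bin and trigger defaults mirror the cohort's
    # reference cohort's proportions
    age_bins = ["0-1", "1-5", "5-12", "12-18", "18+"]
    age_probs = np.array([20, 12, 9, 8, 8], dtype=float) / 57
    bin_ranges = {"0-1": (0.05, 1.0), "1-5": (1.0, 5.0), "5-12": (5.0, 12.0),
                  "12-18": (12.0, 18.0), "18+": (18.0, 70.0)}
    triggers = ["none", "EBV", "other_infection", "malignancy", "autoimmune", "unknown"]
    trig_probs = [0.50, 0.17, 0.10, 0.06, 0.03, 0.14]

    sexes = np.where(rng.random(n) < config.female_fraction, "F", "M")
    # roles in a fixed order; hemizygous slots must be male
    roles = (
        ["biallelic"] * n_bi
        + ["hemizygous"] * n_hemi
        + ["monoallelic_vus"] * n_vus
        + ["benign_only"] * (n - n_bi - n_hemi - n_vus)
    )
    rng.shuffle(roles)
    for i, role in enumerate(roles):
        if role == "hemizygous":
            sexes[i] = "M"

    patients: list[PatientRecord] = []
    for i in range(n):
        b = str(rng.choice(age_bins, p=age_probs))
        lo, hi = bin_ranges[b]
        patients.append(
            PatientRecord(
                id=f"S{i + 1:03d}",
                age_at_diagnosis=float(rng.uniform(lo, hi)),
                sex=str(sexes[i]),
                trigger=str(rng.choice(triggers, p=trig_probs)),
            )
        )

    variants: dict[tuple, AnnotatedVariant] = {}
    genotypes: list[GenotypeCall] = []
    used_positions: set[int] = set()
    labels: dict[str, dict] = {}

    def register(v: AnnotatedVariant) -> AnnotatedVariant:
        return variants.setdefault(v.key, v)

    for i, (patient, role) in enumerate(zip(patients, roles)):
        if role == "biallelic":
            gene = ar_genes[i % len(ar_genes)]
            gene_amps = by_gene[gene.name]
            if i % 2 == 0:  # homozygous
                v = register(
                    _plant_variant(rng, gene, gene_amps, used_positions, i)
                )
                genotypes.append(GenotypeCall(patient.id, v.key, Zygosity.HOM))
                planted = [v.key]
            else:  # compound het: two distinct positions, same gene
                v1 = register(
                    _plant_variant(rng, gene, gene_amps, used_positions, i)
                )
                v2 = register(
                    _plant_variant(rng, gene, gene_amps, used_positions, i + 1)
                )
                genotypes.append(GenotypeCall(patient.id, v1.key, Zygosity.HET))
                genotypes.append(GenotypeCall(patient.id, v2.key, Zygosity.HET))
                planted = [v1.key, v2.key]
            labels[patient.id] = {
                "status": "diagnosed",
                "gene": gene.name,
                "variants": planted,
            }
        elif role == "hemizygous":
            gene = xl_genes[i % len(xl_genes)]
            v = register(
                _plant_variant(rng, gene, by_gene[gene.name], used_positions, i)
            )
            genotypes.append(GenotypeCall(patient.id, v.key, Zygosity.HEMI))
            labels[patient.id] = {
                "status": "diagnosed",
                "gene": gene.name,
                "variants": [v.key],
            }
        elif role == "monoallelic_vus":
            gene = ar_genes[i % len(ar_genes)]
            # always a damaging-predicted missense (template 0)
            v = register(
                _plant_variant(rng, gene, by_gene[gene.name], used_positions, 0)
            )
            genotypes.append(GenotypeCall(patient.id, v.key, Zygosity.HET))
            labels[patient.id] = {
                "status": "vus_only",
                "gene": gene.name,
                "variants": [v.key],
            }
        else:
            labels[patient.id] = {"status": "undiagnosed", "gene": None, "variants": []}

    # background: common benign polymorphisms and rare synonymous calls
    pool: list[AnnotatedVariant] = []
    for j in range(30):
        gene = genes[j % len(genes)]
        if gene.name not in by_gene:
            continue
        conseq = [Consequence.MISSENSE, Consequence.SYNONYMOUS, Consequence.INTRONIC][j % 3]
        amp = by_gene[gene.name][int(rng.integers(len(by_gene[gene.name])))]
        pos = int(rng.integers(amp.start + 1, amp.end + 1))
        while pos in used_positions:
            pos += 1
        used_positions.add(pos)
        ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
        # synonymous entries are made rare so the consequence filter (not
        # the MAF filter) is what removes them
        maf = (
            float(rng.uniform(0.0, 0.04))
            if conseq is Consequence.SYNONYMOUS
            else float(rng.uniform(0.05, 0.5))
        )
        pool.append(
            AnnotatedVariant(
                chromosome=gene.chromosome,
                position=pos,
                ref=str(ref),
                alt=str(alt),
                gene=gene.name,
                consequence=conseq,
                maf=maf,
                sift_pred="tolerated" if conseq is Consequence.MISSENSE else None,
                polyphen_pred="benign" if conseq is Consequence.MISSENSE else None,
            )
        )
    for patient in patients:
        k = rng.poisson(config.background_poly_mean)
        for idx in rng.choice(len(pool), size=min(k, len(pool)), replace=False):
            v = register(pool[idx])
            on_x = v.chromosome.removeprefix("chr") == "X"
            if on_x and patient.sex == "M":
                zyg = Zygosity.HEMI
            else:
                zyg = Zygosity.HET if rng.random() < 0.8 else Zygosity.HOM
            genotypes.append(GenotypeCall(patient.id, v.key, zyg))

    return list(variants.values()), genotypes, patients, CohortTruth(labels=labels)


def simulate_population(
    genes: Sequence[PanelGene],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[AnnotatedVariant]]:
    """Simulate per-site genotype counts in a reference population.

    Returns (counts, genotype matrix, site annotations): ``counts`` has
    one row per site with columns n_AA/n_Aa/n_aa; the matrix holds 0/1/2
    alt-allele dosages per individual (rows) and site (columns).
    """
    rng = _rng(config, 3)
    gene_map = {g.name: g for g in genes}
    n = config.pop_n
    rows = []
    columns = {}
    site_variants: list[AnnotatedVariant] = []
    for si, site in enumerate(config.pop_sites):
        gene = gene_map.get(site.gene)
        if gene is None:
            raise ValueError(f"population site references unknown gene {site.gene}")
        q, f = site.allele_freq, site.distortion
        p = 1 - q
        probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
        probs = np.clip(probs, 0, None)
        probs /= probs.sum()
        if n > 0:
            dosage = rng.choice([0, 1, 2], size=n, p=probs)
        else:
            dosage = np.zeros(0, dtype=int)
        key = f"{gene.name}_site{si + 1}"
        counts = (
            int(np.sum(dosage == 0)),
            int(np.sum(dosage == 1)),
            int(np.sum(dosage == 2)),
        )
        rows.append(
            {"site": key, "gene": gene.name, "n_AA": counts[0], "n_Aa": counts[1], "n_aa": counts[2]}
        )
        columns[key] = dosage
        pos = 500_000 + si * 100 + 1
        site_variants.append(
            AnnotatedVariant(
                chromosome=gene.chromosome,
                position=pos,
                ref="G",
                alt="A",
                gene=gene.name,
                consequence=site.consequence,
                maf=site.allele_freq,
                sift_pred="deleterious" if site.damaging else "tolerated",
                polyphen_pred=None if site.damaging else "benign",
                hgvs_c=key,
            )
        )
    counts_df = pd.DataFrame(rows, columns=["site", "gene", "n_AA", "n_Aa", "n_aa"])
    geno_df = pd.DataFrame(
        columns, index=[f"I{i + 1:05d}" for i in range(n)] if n else []
    )
    return counts_df, geno_df, site_variants
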