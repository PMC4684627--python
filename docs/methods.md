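# Methods

## Scope and model

`hlhpanel` covers the analysis that turns an amplicon-panel sequencing run
into molecular diagnoses for HLH: coverage quality control, coverage-based
detection of large homozygous/hemizygous exonic deletions, a rare-variant
prioritization cascade, zygosity-aware diagnosis under a per-gene
inheritance model (autosomal recessive, or X-linked where one hemizygous
allele in a male suffices), and the surrounding statistics. Upstream steps
(read mapping, primary variant calling, annotation with consequence, MAF,
SIFT/PolyPhen-2/CADD) are consumed as inputs, never computed; wet-lab
validation and immunological assays are out of scope.

Coordinates are 0-based half-open internally (BED convention); variant
positions stay 1-based (VCF convention) and are converted only for interval
arithmetic. An amplicon's half-open interval means a site exactly at the
`end` coordinate is *not* covered — tested explicitly.

## Coverage QC

Depths are binned for display into <10×, 10–50× and >50× ([0,10),
[10,50], (50,∞)). Whether 50 belongs to the middle category is an
arbitrary, documented choice (inclusive here). The *failure* rule is
distinct and inclusive: an amplicon fails when its mean depth across all
samples is ≤ the cut-off (default 10×). A depth of exactly 10 therefore
displays as "10–50×" yet can belong to a failed amplicon through the mean
rule; both conventions are kept deliberately.

Effective coverage is bp-weighted: `100 × (designed_bp − failed_bp) /
total_target_bp`, with the designed shortfall (regions where no primers
could be placed) entering through `total_target_bp`. Per-gene coverage is
the bp fraction of that gene's targeted regions lying in non-failed
amplicons; genes with zero targeted bp report missing, not 0. Known-site
coverage counts point sites inside at least one non-failed amplicon.

## Deletion calling

Normalization is median-of-ratios: each sample is scaled by its median
depth over amplicons (library size), then each amplicon by the
across-sample median of those scaled values (amplicon efficiency). Medians
rather than means make the reference robust to the failed-amplicon tail
and to the deleted samples themselves. Samples with median depth 0 are
uncallable and flagged; normalization requires ≥ 3 samples for a stable
reference; failed amplicons are excluded before calling.

A call is a maximal run of ≥ `min_run` (default 2) consecutive same-gene
amplicons with ratio < `threshold` (default 0.1). A homozygous or
hemizygous deletion removes the PCR template entirely, so its ratio is
~0 up to mispriming background; 0.1 tolerates that background while
excluding heterozygous losses (~0.5), which this assay does not claim to
detect — heterozygous-carrier CNV detection is explicitly out of scope.
Single-amplicon dips are reported in a separate "possible deletion
(unconfirmed)" tier and never as calls, because one amplicon cannot be
distinguished from a local PCR failure or a primer-site SNP. Zygosity is
labelled hemizygous only for an X-linked gene in a known male.

## Variant filtering

Patient mode applies, in order: consequence → MAF. The retained
consequence set (missense, stop gained/lost, start lost, frameshift,
in-frame indel, splice donor/acceptor/region) is the package's reading of
"possible impact at the protein level"; synonymous, non-splice intronic,
UTR and regulatory-only annotations are dropped. Unknown consequence
terms are retained and flagged (conservative). Known deep-intronic
regulatory disease alleles survive only via a user-supplied allow-list of
sites, since any consequence rule would drop them. The MAF filter is
strict (`maf < 0.05`); a missing MAF means the variant is absent from the
reference population and is retained.

Population mode (carrier-burden analysis) adds, after MAF: an exact
Hardy–Weinberg filter (p < 0.05, removing likely genotyping artifacts
before further analysis) and then the damaging filter — SIFT deleterious
OR PolyPhen-2 possibly/probably damaging. Loss-of-function classes
(stop gained, frameshift, canonical splice) bypass the damaging filter
because the predictors only score missense; without the bypass every
nonsense and frameshift allele would be discarded. Variants with both
predictions missing are dropped in population mode but retained-with-flag
in patient mode, where a human reviews the shortlist. Every step appends
(input, output, per-consequence breakdown) to a `FilterTrace` whose counts
are checked to be weakly decreasing and chained.

The HWE test is the exact conditional test (not chi-square), enumerating
all heterozygote counts compatible with the observed allele counts in log
space; it is valid at the rare-allele counts that dominate these genes,
and monomorphic sites return p = 1 by convention. It matches an
exact-rational enumeration oracle for every genotype table of ≤ 20
individuals.

## Diagnosis

Within one gene: AR diagnosis requires a homozygous qualifying variant,
two heterozygous qualifying variants at distinct positions, or a
homozygous deletion call; XL diagnosis requires a hemizygous variant or
deletion call in a male. Two heterozygous calls at the same position are
a same-allele candidate, flagged for review and never counted as compound
het. Compound heterozygosity is presumed trans without phase information;
externally typed alleles (e.g. an intronic inversion detected by a
dedicated multiplex PCR) enter as allele records and can complete a pair.
Females heterozygous for an X-linked variant are carriers, never
diagnosed. Patients left undiagnosed but carrying ≥ 1 damaging-predicted
monoallelic variant are `vus_only`. The automatic tier is deliberately
called "qualifying", not "pathogenic": manual curation enters as an
allow/deny list input, not an algorithm.

Age bins are [0,1), [1,5), [5,12), [12,18), [18,∞) years. Yields report
exact numerators and denominators: overall (all patients), per bin and
the "older" subset (known age ≥ 1) over known-age patients only, and the
pediatric subset as everyone outside the 18+ bin, with unknown-age
patients counted pediatric and logged. The trigger table counts
diagnosed vs non-diagnosed patients against secondary-HLH trigger
present/absent (`none` is absent; `unknown` excluded by default).

## Statistics

The Wilson interval is used without continuity correction; its lower
bound for 72/74 at 95 % is 0.9067 (90.7 %) and its upper bound 0.9926
(99.3 % when rounded) — full precision is always reported. Fisher's
two-sided p sums hypergeometric probabilities ≤ that of the observed
table (the convention differs between tools, hence documented; the
implementation delegates to scipy and is verified against an
exact-rational enumeration oracle). The rank-sum test uses midranks for
ties, full enumeration of rank assignments when min(n) ≤ 10 and combined
n ≤ 20 (two-sided by symmetric deviation from the null mean), and
otherwise a normal approximation with tie and continuity corrections that
agrees with the exact branch to < 0.01 at n = 10 per group. Burden
comparisons report raw Fisher p-values with a Bonferroni column alongside
as an artifact addition.

## Synthetic data

Depth of sample s at amplicon a is negative binomial with mean
`depth_mean × amplicon_factor(a) × sample_factor(s)` and dispersion k
(variance m + m²/k; Poisson as k → ∞). Factors are log-normal with
log-scale SDs `amplicon_efficiency_sd` and `sample_factor_sd`, mean-
corrected to 1. Defaults — depth_mean 200, k = 5, SDs 0.4 and 0.25, two
systematically failed amplicons (mean forced to 3 reads), residual depth
of mean 1 read inside deletions so the caller's threshold is genuinely
exercised — are fixed once as a realistic bench-top amplicon run; no
depth distribution is prescribed by the assay itself. The default panel
geometry tiles each gene with its designed number of amplicons (361 in
total) at 150 bp, inside the assay's 125–175 bp range; real coordinates
are immaterial to the logic.

The cohort generator plants, per the default 58-sample configuration,
21/58 biallelic and 1/58 hemizygous diagnosable patients and 9/58
monoallelic-VUS carriers, mirroring the reference cohort's make-up; age-bin
and trigger distributions default to that cohort's proportions. All
patients also receive common benign polymorphisms and rare synonymous
variants, so the cascade's MAF and consequence steps are each exercised
independently. The population generator draws per-site genotypes from
HWE proportions distorted by an inbreeding-like parameter f (P(Aa) =
2pq(1−f)); f = 0 is exact HWE, f = 1 all homozygotes.

What the simulations do *not* emulate: read-level error profiles,
homopolymer artifacts, haplotype LD structure, annotation disagreement
between tools, and pedigree structure. Passing planted-truth tests
therefore shows the pipeline's logic is correct under its stated model,
not that real-world sensitivity equals the simulated one. Likewise the
study-scale cohort-filter counts and the 1000 Genomes carrier tallies
depend on restricted data and annotation versions and are deliberately
not reproduction targets; those stages are instead held to exhaustive
small-case oracles and planted-truth recovery.

## Problem sizes and determinism

All generators draw from `numpy` Generator streams keyed `[seed, stage]`,
so stages are independently reproducible and a fixed seed reproduces
byte-identical pipeline outputs (checksummed in the run manifest). The
test suite uses cohorts of 20–58 samples, populations of up to 10 000,
20-seed CNV experiments and 2000-replicate null calibrations — sizes
chosen so the whole suite runs in about a minute on one CPU while keeping
Monte-Carlo assertions at ≥ 3-SE separation.

## Known limitations

Phase is presumed, not proven, for compound heterozygotes (parental
genotypes can veto when supplied). The deletion caller has no breakpoint
resolution and reports amplicon runs only. The diagnosis tier is not an
ACMG classifier. The consequence vocabulary normalizes common VEP/SnpEff
terms; exotic dialects fall into a flagged `other` class that is retained
conservatively.
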