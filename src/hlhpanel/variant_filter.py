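"""The variant prioritization cascade.

Patient mode mirrors the diagnostic flow: keep variants with a possible
impact at the protein level (missense, nonsense, frameshift, in-frame
indel, splice-site/region), then keep rare ones (reference-population
MAF < 0.05, strict; absent-from-reference treated as MAF 0 and kept).
Population mode (carrier-burden analysis) additionally removes sites
deviating from Hardy-Weinberg equilibrium (exact conditional test,
p < alpha) and then requires at least one in-silico damaging prediction
by SIFT or PolyPhen-2 — with a loss-of-function bypass, since those
tools score missense variants only.

Deep-intronic regulatory variants with known disease relevance survive
only through a user-supplied allow-list of sites; a consequence-based
rule would drop them.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import (
    AnnotatedVariant,
    Consequence,
    FilterTrace,
    IMPACT_CONSEQUENCES,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "consequence_filter",
    "maf_filter",
    "damaging_filter",
    "hwe_exact_p",
    "hwe_filter",
    "run_cascade",
]


@dataclass
class FilterConfig:
    """Thresholds and options for the cascade."""

    maf_threshold: float = 0.05
    impact_consequences: frozenset[Consequence] = IMPACT_CONSEQUENCES
    hwe_alpha: float = 0.05
    apply_hwe: bool = False  # population mode only
    #: (chrom, pos, ref, alt) keys of known regulatory/deep-intronic
    #: disease sites that bypass the consequence filter.
    allowlist: frozenset[tuple[str, int, str, str]] = frozenset()

    def __post_init__(self) -> None:
        if not 0 < self.maf_threshold < 1:
            raise ValueError("maf_threshold must be in (0, 1)")
        if not self.impact_consequences:
            raise ValueError("impact_consequences must be non-empty")


def _breakdown(variants: Iterable[AnnotatedVariant]) -> dict[str, int]:
    return dict(Counter(v.consequence.value for v in variants))


def consequence_filter(
    variants: Sequence[AnnotatedVariant],
    config: FilterConfig,
    trace: FilterTrace | None = None,
) -> list[AnnotatedVariant]:
    """Retain protein-impact consequences (plus allow-listed sites).

    Unknown consequence terms (``OTHER``) are retained conservatively
    with a logged warning.
    """
    out = []
    for v in variants:
        if v.key in config.allowlist:
            out.append(v)
        elif v.consequence in config.impact_consequences:
            out.append(v)
        elif v.consequence is Consequence.OTHER:
            logger.warning("unknown consequence term retained (flagged): %s", v.key)
            out.append(v)
    if trace is not None:
        trace.add("consequence", len(variants), len(out), _breakdown(out))
    return out


def maf_filter(
    variants: Sequence[AnnotatedVariant],
    config: FilterConfig,
    trace: FilterTrace | None = None,
) -> list[AnnotatedVariant]:
    """Retain rare variants: MAF strictly below the threshold; a missing
    MAF means absent from the reference population and is retained."""
    out = [v for v in variants if (v.maf or 0.0) < config.maf_threshold]
    if trace is not None:
        trace.add("maf", len(variants), len(out), _breakdown(out))
    return out


def damaging_filter(
    variants: Sequence[AnnotatedVariant],
    config: FilterConfig,
    mode: str = "population",
    trace: FilterTrace | None = None,
) -> list[AnnotatedVariant]:
    """Require an in-silico damaging prediction (SIFT deleterious OR
    PolyPhen-2 possibly/probably damaging).

    Loss-of-function consequences bypass the filter (predictors score
    missense only).  Variants with both predictions missing are dropped
    in population mode and retained (flagged) in patient mode.
    """
    out = []
    for v in variants:
        if v.is_lof or v.is_damaging_predicted:
            out.append(v)
        elif v.sift_pred is None and v.polyphen_pred is None:
            if mode == "patient":
                logger.info("retaining unscored variant in patient mode: %s", v.key)
                out.append(v)
    if trace is not None:
        trace.add("damaging", len(variants), len(out), _breakdown(out))
    return out


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test for Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and enumerates every
    compatible heterozygote count; the p-value is the total probability
    of configurations no more probable than the observed one.
    Monomorphic sites return 1.0 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")
    n_a = n_Aa + 2 * n_aa  # copies of the a allele
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    # enumerate heterozygote counts with the parity of n_a
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    n_aa_all = (n_a - hets) // 2
    n_AA_all = n - hets - n_aa_all
    logp = (
        gammaln(n + 1)
        - gammaln(n_AA_all + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa_all + 1)
        + hets * np.log(2.0)
    )
    logp -= logsumexp(logp)
    p_obs = logp[np.searchsorted(hets, n_Aa)]
    return float(np.exp(logsumexp(logp[logp <= p_obs + 1e-9])))


def hwe_filter(
    variants: Sequence[AnnotatedVariant],
    genotype_counts: Mapping[tuple[str, int, str, str], tuple[int, int, int]],
    config: FilterConfig,
    trace: FilterTrace | None = None,
) -> list[AnnotatedVariant]:
    """Remove variants deviating from HWE (exact test, p < alpha).

    Variants absent from the genotype-count table are retained (no
    population evidence against them)."""
    out = []
    for v in variants:
        counts = genotype_counts.get(v.key)
        if counts is None or hwe_exact_p(*counts) >= config.hwe_alpha:
            out.append(v)
    if trace is not None:
        trace.add("hwe", len(variants), len(out), _breakdown(out))
    return out


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    config: FilterConfig,
    mode: str = "patient",
    genotype_counts: Mapping[tuple[str, int, str, str], tuple[int, int, int]]
    | None = None,
) -> tuple[list[AnnotatedVariant], FilterTrace]:
    """Apply the full cascade in fixed order.

    Patient mode: consequence -> MAF.  Population mode: consequence ->
    MAF -> HWE -> damaging.  Every step is recorded in the trace.
    """
    if mode not in ("patient", "population"):
        raise ValueError(f"unknown cascade mode {mode!r}")
    trace = FilterTrace()
    trace.add("input", len(variants), len(variants), _breakdown(variants))
    out = consequence_filter(variants, config, trace)
    out = maf_filter(out, config, trace)
    if mode == "population":
        if config.apply_hwe or genotype_counts is not None:
            out = hwe_filter(out, genotype_counts or {}, config, trace)
        out = damaging_filter(out, config, mode="population", trace=trace)
    return out, trace
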