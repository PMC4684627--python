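"""Coverage-based calling of large homozygous/hemizygous exonic deletions.

A biallelic (or male X hemizygous) exonic deletion removes the PCR
template entirely, so affected amplicons drop to near-zero depth while
the rest of the sample behaves normally.  Depths are normalized by a
median-of-ratios scheme (robust to library size and to the failed-
amplicon tail), and maximal runs of >= ``min_run`` consecutive
same-gene amplicons with normalized ratio below ``threshold`` are
emitted as deletion calls.  Heterozygous-carrier CNV detection
(ratio ~ 0.5) is deliberately out of scope: the assay only claims
near-total losses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    Amplicon,
    CoverageMatrix,
    DeletionCall,
    Inheritance,
    PanelGene,
    amplicons_by_gene,
)

logger = logging.getLogger(__name__)

__all__ = ["NormalizedCoverage", "normalize", "call_deletions"]


@dataclass
class NormalizedCoverage:
    """Per-(sample, amplicon) depth ratios; ~1 for diploid coverage."""

    ratio: pd.DataFrame
    uncallable_samples: list[str]


def normalize(
    matrix: CoverageMatrix,
    failed: Sequence[str] = (),
) -> NormalizedCoverage:
    """Median-of-ratios normalization.

    Each sample is first scaled by its median depth over amplicons
    (library-size correction), then each amplicon by the across-sample
    median of those scaled values (amplicon-efficiency correction).
    Samples with median depth 0 are excluded from calling and flagged
    uncallable.  Failed amplicons must be excluded beforehand.
    """
    depth = matrix.depth.drop(columns=list(failed), errors="ignore")
    if depth.shape[0] < 3:
        raise ValueError("normalization needs >= 3 samples for a stable reference")
    sample_median = depth.median(axis=1)
    uncallable = list(sample_median.index[sample_median == 0])
    if uncallable:
        logger.warning("uncallable samples (median depth 0): %s", uncallable)
    ok = depth.drop(index=uncallable)
    scaled = ok.div(ok.median(axis=1), axis=0)
    ref = scaled.median(axis=0)
    ref = ref.replace(0, np.nan)  # amplicon dead in >half the cohort
    ratio = scaled.div(ref, axis=1)
    return NormalizedCoverage(ratio=ratio, uncallable_samples=uncallable)


def call_deletions(
    normalized: NormalizedCoverage,
    genes: Sequence[PanelGene],
    amplicons: Sequence[Amplicon],
    sexes: Mapping[str, str],
    threshold: float = 0.1,
    min_run: int = 2,
) -> tuple[list[DeletionCall], list[DeletionCall]]:
    """Emit deletion calls from a normalized ratio matrix.

    Returns ``(calls, unconfirmed)``: maximal runs of >= ``min_run``
    consecutive same-gene low-ratio amplicons become calls; single-
    amplicon dips are reported separately as possible deletions
    (unconfirmed) and never as calls.  The zygosity label is
    *hemizygous* for an X-linked gene in a male, else *homozygous*.
    """
    if threshold >= 1:
        raise ValueError("deletion ratio threshold must be < 1")
    inheritance = {g.name: g.inheritance for g in genes}
    by_gene = amplicons_by_gene(
        a for a in amplicons if a.id in set(normalized.ratio.columns)
    )
    calls: list[DeletionCall] = []
    unconfirmed: list[DeletionCall] = []
    for sample in normalized.ratio.index:
        row = normalized.ratio.loc[sample]
        for gene, amps in by_gene.items():
            low = [bool(row[a.id] < threshold) for a in amps]
            i = 0
            while i < len(amps):
                if not low[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < len(amps) and low[j + 1]:
                    j += 1
                run = amps[i : j + 1]
                ratios = tuple(float(row[a.id]) for a in run)
                hemi = (
                    inheritance.get(gene) is Inheritance.XL
                    and sexes.get(sample) == "M"
                )
                call = DeletionCall(
                    sample_id=sample,
                    gene=gene,
                    first_amplicon=run[0].id,
                    last_amplicon=run[-1].id,
                    n_amplicons=len(run),
                    zygosity_label="hemizygous" if hemi else "homozygous",
                    mean_ratio=float(np.mean(ratios)),
                    amplicon_ratios=ratios,
                )
                (calls if len(run) >= min_run else unconfirmed).append(call)
                i = j + 1
    return calls, unconfirmed


def calls_to_frame(calls: Sequence[DeletionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "gene": c.gene,
                "first_amplicon": c.first_amplicon,
                "last_amplicon": c.last_amplicon,
                "n_amplicons": c.n_amplicons,
                "zygosity": c.zygosity_label,
                "mean_ratio": round(c.mean_ratio, 4),
            }
            for c in calls
        ],
        columns=[
            "sample",
            "gene",
            "first_amplicon",
            "last_amplicon",
            "n_amplicons",
            "zygosity",
            "mean_ratio",
        ],
    )
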