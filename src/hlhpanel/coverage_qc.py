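"""Coverage quality control for the amplicon panel.

Per-amplicon depths are binned into three display categories (<10x,
10-50x, >50x).  An amplicon is *failed* when its mean depth across all
samples is <= the cut-off (default 10x, inclusive — note the display
category boundary at 10 is exclusive while the failure cut-off is
inclusive; both conventions are kept as used in practice).  Effective
coverage and per-gene/known-site coverage are bp-weighted fractions of
target covered by non-failed amplicons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import Amplicon, CoverageMatrix, PanelGene

logger = logging.getLogger(__name__)

CATEGORIES = ("<10x", "10-50x", ">50x")

__all__ = [
    "CATEGORIES",
    "CoverageSummary",
    "categorize_depth",
    "category_counts",
    "failed_amplicons",
    "effective_coverage",
    "gene_coverage",
    "site_coverage",
    "summarize_coverage",
    "coverage_heatmap",
]


def categorize_depth(depth: float) -> str:
    """Display category of a single depth value.

    Boundaries: [0, 10) -> "<10x", [10, 50] -> "10-50x", (50, inf) -> ">50x".
    """
    if depth < 0:
        raise ValueError(f"negative depth: {depth}")
    if depth < 10:
        return CATEGORIES[0]
    if depth <= 50:
        return CATEGORIES[1]
    return CATEGORIES[2]


def category_counts(matrix: CoverageMatrix) -> pd.DataFrame:
    """Per-amplicon sample counts in each display category.

    Rows are amplicon ids, columns the three categories; each row sums
    to the number of samples.
    """
    depth = matrix.depth
    low = (depth < 10).sum(axis=0)
    mid = ((depth >= 10) & (depth <= 50)).sum(axis=0)
    high = (depth > 50).sum(axis=0)
    return pd.DataFrame(
        {CATEGORIES[0]: low, CATEGORIES[1]: mid, CATEGORIES[2]: high}
    )


def failed_amplicons(
    matrix: CoverageMatrix,
    cutoff: float = 10.0,
    amplicons: Sequence[Amplicon] | None = None,
) -> list[str]:
    """Amplicons whose mean depth across samples is <= ``cutoff``.

    Sorted by genomic position when ``amplicons`` is given, otherwise
    in matrix column order.
    """
    if matrix.depth.empty:
        raise ValueError("coverage matrix is empty")
    means = matrix.depth.mean(axis=0)
    failed = [a for a in matrix.amplicons if means[a] <= cutoff]
    if amplicons is not None:
        pos = {a.id: (a.chromosome, a.start) for a in amplicons}
        failed.sort(key=lambda aid: pos.get(aid, ("~", 0)))
    return failed


def effective_coverage(
    total_target_bp: int, designed_bp: int, failed_bp: int
) -> float:
    """Percent of the initial target that is both designed and non-failed."""
    if total_target_bp <= 0:
        raise ValueError("total_target_bp must be positive")
    if designed_bp > total_target_bp:
        raise ValueError("designed_bp exceeds total_target_bp")
    if failed_bp > designed_bp:
        raise ValueError("failed_bp exceeds designed_bp")
    return 100.0 * (designed_bp - failed_bp) / total_target_bp


def gene_coverage(
    genes: Sequence[PanelGene],
    amplicons: Sequence[Amplicon],
    failed: Iterable[str],
) -> tuple[dict[str, float | None], float]:
    """Per-gene percent of targeted bp in non-failed amplicons, plus the
    unweighted mean across genes with any targeted bp.

    Genes with zero targeted bp report ``None`` (missing, not 0).
    """
    failed_set = set(failed)
    per_gene: dict[str, float | None] = {}
    values = []
    for gene in genes:
        amps = [a for a in amplicons if a.gene == gene.name]
        total = sum(a.length for a in amps)
        if total == 0:
            per_gene[gene.name] = None
            continue
        ok = sum(a.length for a in amps if a.id not in failed_set)
        pct = 100.0 * ok / total
        per_gene[gene.name] = pct
        values.append(pct)
    mean = float(np.mean(values)) if values else float("nan")
    return per_gene, mean


def site_coverage(
    known_sites: Sequence[tuple[str, int]],
    amplicons: Sequence[Amplicon],
    failed: Iterable[str],
) -> float:
    """Percent of known mutation sites (chrom, 1-based pos) inside at
    least one non-failed amplicon (half-open interval check)."""
    if not known_sites:
        raise ValueError("no known sites supplied")
    failed_set = set(failed)
    passing = [a for a in amplicons if a.id not in failed_set]
    contigs = {a.chromosome for a in passing}
    n_cov = 0
    for chrom, pos in known_sites:
        pos0 = pos - 1
        if chrom not in contigs:
            logger.warning("site %s:%d on contig absent from panel", chrom, pos)
            continue
        if any(a.contains(chrom, pos0) for a in passing):
            n_cov += 1
    return 100.0 * n_cov / len(known_sites)


@dataclass
class CoverageSummary:
    """Aggregate output of the QC stage."""

    amplicon_means: pd.Series
    category_counts: pd.DataFrame
    failed: list[str]
    per_gene_pct: dict[str, float | None]
    mean_gene_pct: float
    effective_pct: float | None = None
    known_site_pct: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.category_counts.copy()
        df.insert(0, "amplicon", df.index)
        df["mean_depth"] = self.amplicon_means.round(3)
        df["failed"] = df["amplicon"].isin(set(self.failed))
        return df.reset_index(drop=True)


def summarize_coverage(
    matrix: CoverageMatrix,
    genes: Sequence[PanelGene],
    amplicons: Sequence[Amplicon],
    known_sites: Sequence[tuple[str, int]] | None = None,
    cutoff: float = 10.0,
    total_target_bp: int | None = None,
) -> CoverageSummary:
    """Run the full QC stage on one coverage matrix."""
    failed = failed_amplicons(matrix, cutoff=cutoff, amplicons=amplicons)
    per_gene, mean_gene = gene_coverage(genes, amplicons, failed)
    designed_bp = sum(a.length for a in amplicons)
    failed_bp = sum(a.length for a in amplicons if a.id in set(failed))
    eff = None
    if total_target_bp is not None:
        eff = effective_coverage(total_target_bp, designed_bp, failed_bp)
    site_pct = None
    if known_sites:
        site_pct = site_coverage(known_sites, amplicons, failed)
    return CoverageSummary(
        amplicon_means=matrix.depth.mean(axis=0),
        category_counts=category_counts(matrix),
        failed=failed,
        per_gene_pct=per_gene,
        mean_gene_pct=mean_gene,
        effective_pct=eff,
        known_site_pct=site_pct,
    )


def coverage_heatmap(
    matrix: CoverageMatrix,
    amplicons: Sequence[Amplicon],
    path: str,
) -> None:
    """Categorical coverage heatmap: rows = amplicons sorted by position,
    columns = samples sorted by their mean coverage."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    order = [a.id for a in sorted(amplicons, key=lambda a: (a.chromosome, a.start))]
    order = [a for a in order if a in matrix.depth.columns]
    sample_order = matrix.depth.mean(axis=1).sort_values().index
    depth = matrix.depth.loc[sample_order, order].T
    coded = np.digitize(depth.to_numpy(), [10, 50.000001])  # 0,1,2 categories
    fig, ax = plt.subplots(figsize=(8, 10))
    cmap = ListedColormap(["#b2182b", "#fddbc7", "#2166ac"])
    ax.imshow(coded, aspect="auto", cmap=cmap, norm=BoundaryNorm([0, 1, 2, 3], 3))
    ax.set_xlabel("samples (by mean coverage)")
    ax.set_ylabel("amplicons (by position)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
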