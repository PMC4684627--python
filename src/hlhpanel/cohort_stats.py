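"""Statistical layer: validation sensitivity with a Wilson score CI,
Fisher's exact and Wilcoxon rank-sum tests, and population
carrier-burden accounting.

The Wilson interval is the score-test inversion for a binomial
proportion, used without continuity correction.  Fisher's exact test is
two-sided by the "probability mass <= observed" convention (as in
scipy).  The rank-sum test enumerates the exact null for small groups
and falls back to a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "wilson_ci",
    "SensitivityReport",
    "sensitivity_eval",
    "fisher_2x2",
    "wilcoxon_rank_sum",
    "BurdenReport",
    "carrier_burden",
    "compare_burden",
]


def wilson_ci(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval, no continuity correction."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    p = successes / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (center - half, center + half)


@dataclass(frozen=True)
class SensitivityReport:
    n_expected: int
    n_called: int
    sensitivity: float
    ci_low: float
    ci_high: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_expected": self.n_expected,
                    "n_called": self.n_called,
                    "sensitivity": round(self.sensitivity, 4),
                    "ci_low": round(self.ci_low, 4),
                    "ci_high": round(self.ci_high, 4),
                }
            ]
        )


def sensitivity_eval(
    truth: Iterable[tuple],
    called: Iterable[tuple],
    confidence: float = 0.95,
) -> SensitivityReport:
    """Detection sensitivity of the assay against a truth set.

    Variant identity is (chrom, pos, ref, alt, sample).  Extra calls
    (false positives) do not enter this metric.
    """
    truth_set = set(truth)
    if not truth_set:
        raise ValueError("empty truth set")
    called_set = set(called)
    hit = len(truth_set & called_set)
    lo, hi = wilson_ci(hit, len(truth_set), confidence)
    return SensitivityReport(
        n_expected=len(truth_set),
        n_called=hit,
        sensitivity=hit / len(truth_set),
        ci_low=lo,
        ci_high=hi,
    )


def fisher_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums the hypergeometric probability of every table with the
    observed margins whose probability is <= that of the observed
    table.  All-zero tables return 1.0 by convention.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if arr.sum() == 0:
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def _rank_sum_stat(pooled_ranks: np.ndarray, idx: Sequence[int]) -> float:
    return float(pooled_ranks[list(idx)].sum())


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_each: int = 10,
    exact_max_total: int = 20,
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Midranks resolve ties.  The exact null is enumerated over all rank
    assignments when min(n) <= ``exact_max_each`` and the combined size
    is <= ``exact_max_total``; larger samples use the tie-corrected
    normal approximation.  Two identical multisets give p = 1.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(pooled)  # midranks
    w_obs = ranks[:n1].sum()
    mu = ranks.sum() * n1 / n  # = n1 (n+1)/2 absent ties
    if min(n1, n2) <= exact_max_each and n <= exact_max_total:
        dev_obs = abs(w_obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(n), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev_obs - 1e-9:
                count += 1
        return count / total
    # normal approximation with tie and continuity corrections
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    dev = max(abs(w_obs - mu) - 0.5, 0.0)
    return float(2 * stats.norm.sf(dev / np.sqrt(sigma2)))


@dataclass
class BurdenReport:
    """Carrier burden of qualifying variants in a population sample."""

    n_individuals: int
    n_carriers: int
    carrier_fraction: float
    per_gene_variants: dict[str, int]
    n_homozygous_carriers: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "n_individuals": self.n_individuals,
                "n_carriers": self.n_carriers,
                "carrier_fraction": round(self.carrier_fraction, 4),
                "n_homozygous_carriers": self.n_homozygous_carriers,
                "per_gene": ";".join(
                    f"{g}={c}" for g, c in sorted(self.per_gene_variants.items())
                ),
            }
        ]
        return pd.DataFrame(rows)


def carrier_burden(
    genotypes: pd.DataFrame,
    qualifying: Mapping[tuple, str],
    gene_subset: Iterable[str] | None = None,
) -> BurdenReport:
    """Count carriers of qualifying variants.

    ``genotypes``: individuals x variant-key columns, entries 0/1/2 alt
    allele copies.  ``qualifying``: variant key -> gene symbol for
    variants surviving the population-mode cascade.  ``gene_subset``
    optionally restricts the tally (e.g. to the four FHL genes).
    """
    keep = {
        k: g
        for k, g in qualifying.items()
        if gene_subset is None or g in set(gene_subset)
    }
    cols = [c for c in genotypes.columns if c in keep]
    missing = set(keep) - set(genotypes.columns)
    if not cols:
        return BurdenReport(len(genotypes), 0, 0.0, {}, 0)
    sub = genotypes[cols]
    if sub.isna().any().any():
        raise ValueError("genotype table contains missing entries")
    carrier_mask = (sub > 0).any(axis=1)
    hom_mask = (sub >= 2).any(axis=1)
    per_gene: dict[str, int] = {}
    for key in cols:
        per_gene[keep[key]] = per_gene.get(keep[key], 0) + 1
    n = len(genotypes)
    n_carriers = int(carrier_mask.sum())
    return BurdenReport(
        n_individuals=n,
        n_carriers=n_carriers,
        carrier_fraction=n_carriers / n if n else 0.0,
        per_gene_variants=per_gene,
        n_homozygous_carriers=int(hom_mask.sum()),
    )


def compare_burden(
    cohort: Mapping[str, tuple[int, int]],
    population: Mapping[str, tuple[int, int]],
) -> pd.DataFrame:
    """Per-group Fisher comparison of carrier fractions.

    Both inputs map a comparison label (variant or gene) to
    (carriers, total).  Returns raw two-sided p-values with a
    Bonferroni-adjusted column.
    """
    labels = sorted(set(cohort) & set(population))
    rows = []
    for label in labels:
        k1, n1 = cohort[label]
        k2, n2 = population[label]
        p = fisher_2x2([[k1, n1 - k1], [k2, n2 - k2]])
        rows.append(
            {
                "label": label,
                "cohort_carriers": k1,
                "cohort_n": n1,
                "population_carriers": k2,
                "population_n": n2,
                "p": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "label",
            "cohort_carriers",
            "cohort_n",
            "population_carriers",
            "population_n",
            "p",
        ],
    )
    if len(df):
        df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    else:
        df["p_bonferroni"] = pd.Series(dtype=float)
    return df
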