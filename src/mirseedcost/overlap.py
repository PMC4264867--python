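"""Target-set overlap statistics, mismatch-class aggregation, and 2x2 comparison.

Overlap between two miRNAs' target gene sets is measured by cosine
similarity: |A ∩ B| / sqrt(|A| * |B|). Dividing by the square root of the
product of the set sizes damps the influence of miRNAs with unusually many
targets and normalizes the score to [0, 1]. Cosine always dominates the
Jaccard index of the same pair.

Pairwise overlap is aggregated by seed mismatch class (Hamming distance
0-7) and summarized as box-and-whisker statistics; the class median is the
headline number. Two pairs' overlap/cost proportions are compared with a
Pearson chi-square test of association on a 2x2 table, where "cost"
(non-overlap) for a pair is |A ∪ B| - |A ∩ B| — the symmetric count of
genes targeted by exactly one of the two miRNAs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .seed import MismatchClassTable
from .targets import TargetSet

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "DistributionSummary",
    "cosine_similarity",
    "jaccard_similarity",
    "pair_overlap",
    "overlap_by_mismatch_class",
    "summarize_distribution",
    "chi_square_overlap",
    "write_overlap_table",
    "write_summary_table",
    "plot_overlap_boxes",
]


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of one miRNA pair, annotated with its seed mismatch class."""

    id_a: str
    id_b: str
    mismatch_class: int
    n_a: int
    n_b: int
    n_shared: int
    cosine: float

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_a, self.n_b):
            raise ValueError("shared count exceeds a set size")

    @property
    def n_cost(self) -> int:
        """Non-overlap count: genes targeted by exactly one of the pair (|A∪B| - |A∩B|)."""
        return self.n_a + self.n_b - 2 * self.n_shared

    @property
    def jaccard(self) -> float:
        union = self.n_a + self.n_b - self.n_shared
        return self.n_shared / union if union else 0.0


@dataclass(frozen=True)
class DistributionSummary:
    """Five-number box-plot summary of one mismatch class's overlap values."""

    mismatch_class: int
    n_pairs: int
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float


def cosine_similarity(set_a: set, set_b: set) -> float:
    """|A ∩ B| / sqrt(|A| * |B|), in [0, 1]; undefined (error) for empty sets."""
    if not set_a or not set_b:
        raise ValueError("cosine similarity is undefined for empty sets")
    return len(set_a & set_b) / math.sqrt(len(set_a) * len(set_b))


def jaccard_similarity(set_a: set, set_b: set) -> float:
    """|A ∩ B| / |A ∪ B|; always <= cosine for non-empty sets."""
    union = set_a | set_b
    if not union:
        raise ValueError("Jaccard similarity is undefined for two empty sets")
    return len(set_a & set_b) / len(union)


def pair_overlap(ts_a: TargetSet, ts_b: TargetSet, mismatch_class: int) -> OverlapResult:
    shared = ts_a.genes & ts_b.genes
    return OverlapResult(
        id_a=ts_a.mirna_id,
        id_b=ts_b.mirna_id,
        mismatch_class=mismatch_class,
        n_a=len(ts_a.genes),
        n_b=len(ts_b.genes),
        n_shared=len(shared),
        cosine=cosine_similarity(ts_a.genes, ts_b.genes),
    )


def overlap_by_mismatch_class(
    target_sets: Mapping[str, TargetSet],
    mismatch_table: MismatchClassTable,
) -> list[OverlapResult]:
    """One OverlapResult per evaluable pair in the mismatch table.

    Pairs where either miRNA lacks a target set or has an empty one are
    skipped with a logged warning (cosine is undefined there); the skip
    count is reported once at the end.
    """
    results: list[OverlapResult] = []
    skipped = 0
    for a, b, dist in mismatch_table.pairs:
        ts_a, ts_b = target_sets.get(a), target_sets.get(b)
        if ts_a is None or ts_b is None or not ts_a.genes or not ts_b.genes:
            skipped += 1
            logger.warning("skipping pair (%s, %s): empty or missing target set", a, b)
            continue
        results.append(pair_overlap(ts_a, ts_b, mismatch_class=dist))
    if skipped:
        logger.warning("%d pair(s) skipped for empty/missing target sets", skipped)
    return results


def summarize_distribution(
    values_by_class: Mapping[int, Sequence[float]],
) -> list[DistributionSummary]:
    """Box-plot summaries per mismatch class.

    Quartiles use linear interpolation; whiskers follow the Tukey
    convention — the most extreme observed values within 1.5 x IQR of the
    box (so with zero IQR the whiskers collapse onto the median). Classes
    with no values are omitted.
    """
    summaries: list[DistributionSummary] = []
    for cls in sorted(values_by_class):
        vals = np.asarray(values_by_class[cls], dtype=float)
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        in_fence = vals[(vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)]
        summaries.append(
            DistributionSummary(
                mismatch_class=cls,
                n_pairs=int(vals.size),
                q1=float(q1),
                median=float(med),
                q3=float(q3),
                whisker_low=float(in_fence.min()),
                whisker_high=float(in_fence.max()),
            )
        )
    return summaries


def chi_square_overlap(
    pair1: tuple[int, int], pair2: tuple[int, int]
) -> tuple[float, int, float]:
    """Pearson chi-square of association on [[shared1, cost1], [shared2, cost2]].

    Compares the overlap/cost proportions of two miRNA pairs. No continuity
    correction (the motivating comparisons involve thousands of genes per
    cell). Returns (statistic, df, p_value) with df = 1.
    """
    table = np.array([pair1, pair2], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    row_totals = table.sum(axis=1)
    col_totals = table.sum(axis=0)
    if (row_totals <= 0).any():
        raise ValueError("both pairs must have a positive total count")
    if (col_totals <= 0).any():
        raise ValueError("degenerate table: a column total is zero")
    expected = np.outer(row_totals, col_totals) / table.sum()
    statistic = float(((table - expected) ** 2 / expected).sum())
    return statistic, 1, float(stats.chi2.sf(statistic, df=1))


def write_overlap_table(results: Iterable[OverlapResult], path: str | Path) -> None:
    """Per-pair TSV: ids, class, set sizes, shared/cost counts, cosine, Jaccard."""
    with open(path, "w") as out:
        out.write(
            "mirna_a\tmirna_b\tmismatch_class\tn_a\tn_b\tn_shared\tn_cost\tcosine\tjaccard\n"
        )
        for r in results:
            out.write(
                f"{r.id_a}\t{r.id_b}\t{r.mismatch_class}\t{r.n_a}\t{r.n_b}\t"
                f"{r.n_shared}\t{r.n_cost}\t{r.cosine:.6f}\t{r.jaccard:.6f}\n"
            )


def write_summary_table(summaries: Iterable[DistributionSummary], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("mismatch_class\tn_pairs\tq1\tmedian\tq3\twhisker_low\twhisker_high\n")
        for s in summaries:
            out.write(
                f"{s.mismatch_class}\t{s.n_pairs}\t{s.q1:.6f}\t{s.median:.6f}\t"
                f"{s.q3:.6f}\t{s.whisker_low:.6f}\t{s.whisker_high:.6f}\n"
            )


def plot_overlap_boxes(
    values_by_class: Mapping[int, Sequence[float]], path: str | Path
) -> None:
    """Box-and-whisker plot of overlap (as %) per mismatch class (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = sorted(values_by_class)
    data = [np.asarray(values_by_class[c], dtype=float) * 100.0 for c in classes]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot(data, tick_labels=[str(c) for c in classes], whis=1.5)
    ax.set_xlabel("seed mismatches")
    ax.set_ylabel("target overlap (%)")
    ax.set_ylim(-2, 102)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
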