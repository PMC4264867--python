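"""Differential-expression pipeline: filtering, probe collapse, and a SAM-style test.

The pipeline consumes an already-normalized (log2-scale) expression matrix
with two sample groups (treated vs control) and mirrors the classic
two-class microarray workflow:

1. presence filter — drop features with fewer than 50% present calls across
   all samples, both groups pooled (strictly fewer: exactly 50% is kept);
2. annotation filter — drop features without a gene-symbol annotation;
3. SNR collapse — per gene, keep the single probe set maximizing
   signal-to-noise ratio (mean / standard deviation across all samples);
4. a SAM-style permutation test: the moderated statistic
   d_i = (mean_treated_i - mean_control_i) / (s_i + s0), with s_i the
   pooled standard error and s0 a small "fudge factor" that stabilizes d
   for low-variance genes; the null distribution comes from group-label
   permutations, and genes are called at the smallest threshold delta whose
   estimated FDR (median null exceedance count / observed count) meets the
   target, default 2%.

Significant genes split into up- (d > 0) and down-regulated (d < 0) lists,
and DE-set overlap between contrasts reuses the cosine statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .overlap import cosine_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SAMResult",
    "DEGeneSets",
    "read_expression_tsv",
    "quantile_normalize",
    "presence_filter",
    "drop_unannotated",
    "snr_collapse",
    "sam_statistic",
    "permutation_fdr",
    "de_gene_sets",
    "de_overlap",
]


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of log2 expression signals plus group labels.

    ``groups`` maps each sample id to "treated" or "control"; at least two
    samples per group are required for the SAM statistic.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups).reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.values.columns[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.unique()) - {"treated", "control"}
        if bad:
            raise ValueError(f"group labels must be treated/control, got {sorted(bad)}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    def group_columns(self, label: str) -> list[str]:
        return list(self.groups.index[self.groups == label])


@dataclass
class SAMResult:
    """Per-gene SAM statistics plus the threshold and FDR estimate used for calling."""

    d: pd.Series
    s0: float
    n_permutations: int
    delta: float
    estimated_fdr: float
    significant: pd.Series  # boolean, aligned with d
    fdr_target: float

    @property
    def directions(self) -> pd.Series:
        """+1 / -1 per significant gene (sign of d)."""
        sig = self.d[self.significant]
        return np.sign(sig).astype(int)


@dataclass
class DEGeneSets:
    """Up- and down-regulated gene lists for one contrast at a stated FDR target."""

    contrast: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)
    fdr_target: float = 0.02

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")

    @property
    def all_genes(self) -> set[str]:
        return self.up | self.down


def read_expression_tsv(
    matrix_path: str | Path, groups: Mapping[str, str] | str | Path
) -> ExpressionMatrix:
    """Read a features x samples TSV (header row of sample ids, first column ids).

    ``groups`` is either a sample->label mapping or the path of a two-column
    TSV (sample_id, group) with header.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if not isinstance(groups, Mapping):
        gdf = pd.read_csv(groups, sep="\t")
        groups = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
    return ExpressionMatrix(values=values, groups=pd.Series(groups))


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across samples (optional utility; the pipeline
    otherwise assumes its input matrix is already normalized)."""
    ranks = values.rank(method="first").astype(int) - 1
    mean_by_rank = np.sort(values.values, axis=0).mean(axis=1)
    out = values.copy()
    for col in values.columns:
        out[col] = mean_by_rank[ranks[col].values]
    return out


def presence_filter(
    matrix: ExpressionMatrix,
    calls: pd.DataFrame,
    min_fraction: float = 0.5,
) -> ExpressionMatrix:
    """Remove features with less than ``min_fraction`` present calls.

    The fraction is computed across ALL samples, both groups pooled.
    Removal is strict ("less than"), so a feature present in exactly half
    the samples is kept. ``calls`` may be boolean or hold the detection
    letters P/M/A; marginal (M) is treated as absent.
    """
    if calls.shape != matrix.values.shape:
        raise ValueError(
            f"calls shape {calls.shape} does not match matrix shape {matrix.values.shape}"
        )
    calls = calls.reindex(index=matrix.values.index, columns=matrix.values.columns)
    if calls.isna().any().any():
        raise ValueError("presence calls do not cover the matrix's features/samples")
    if calls.dtypes.eq(object).any():
        present = calls.apply(lambda col: col.astype(str).str.upper().eq("P"))
    else:
        present = calls.astype(bool)
    frac = present.mean(axis=1)
    return ExpressionMatrix(values=matrix.values.loc[frac >= min_fraction], groups=matrix.groups)


def drop_unannotated(
    matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Remove features lacking a gene-symbol annotation (absent from the map)."""
    keep = [f for f in matrix.values.index if f in probe_to_gene]
    if not keep:
        logger.warning("annotation filter removed every feature")
    return ExpressionMatrix(values=matrix.values.loc[keep], groups=matrix.groups)


def snr_collapse(
    matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe sets to genes, keeping the probe with the highest SNR.

    SNR = mean / standard deviation, computed across all samples pooled
    (ddof=1). A zero-variance probe gets SNR = +inf — a perfectly stable
    signal wins — and is logged. Ties break to the lexicographically
    smallest probe id so the collapse is deterministic. Rows are re-labeled
    by gene symbol, sorted.
    """
    unannotated = [f for f in matrix.values.index if f not in probe_to_gene]
    if unannotated:
        raise ValueError(
            f"{len(unannotated)} feature(s) lack annotation; run drop_unannotated first"
        )
    means = matrix.values.mean(axis=1)
    sds = matrix.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore"):
        snr = means / sds
    zero_sd = sds == 0
    if zero_sd.any():
        snr[zero_sd] = np.inf
        logger.warning("%d probe(s) with zero variance: SNR treated as +inf", int(zero_sd.sum()))

    best: dict[str, str] = {}
    for probe in sorted(matrix.values.index):  # sorted => lexicographic tie-break
        gene = probe_to_gene[probe]
        if gene not in best or snr[probe] > snr[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    collapsed = matrix.values.loc[[best[g] for g in genes]].copy()
    collapsed.index = pd.Index(genes, name="gene")
    return ExpressionMatrix(values=collapsed, groups=matrix.groups)


def _pooled_se(values: np.ndarray, idx_t: np.ndarray, idx_c: np.ndarray) -> np.ndarray:
    """Per-gene pooled standard error of the difference in group means."""
    n1, n2 = len(idx_t), len(idx_c)
    t, c = values[:, idx_t], values[:, idx_c]
    ss = ((t - t.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (c - c.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))


def _d_statistic(
    values: np.ndarray, idx_t: np.ndarray, idx_c: np.ndarray, s0: float
) -> np.ndarray:
    diff = values[:, idx_t].mean(axis=1) - values[:, idx_c].mean(axis=1)
    return diff / (_pooled_se(values, idx_t, idx_c) + s0)


def _resolve_s0(se: np.ndarray, s0: float | str) -> float:
    if s0 == "auto":
        return float(np.median(se))
    s0 = float(s0)
    if s0 == 0 and (se == 0).any():
        raise ValueError(
            "zero-variance gene(s) present with s0 = 0; use s0 > 0 (e.g. 'auto')"
        )
    return s0


def _group_indices(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    cols = list(matrix.values.columns)
    idx_t = np.array([cols.index(c) for c in matrix.group_columns("treated")])
    idx_c = np.array([cols.index(c) for c in matrix.group_columns("control")])
    if len(idx_t) < 2 or len(idx_c) < 2:
        raise ValueError("need at least 2 samples per group")
    return idx_t, idx_c


def sam_statistic(matrix: ExpressionMatrix, s0: float | str = "auto") -> pd.Series:
    """The SAM moderated statistic d_i = (mean_t - mean_c) / (s_i + s0) per gene.

    s0 = "auto" uses the median of the per-gene pooled standard errors.
    """
    idx_t, idx_c = _group_indices(matrix)
    values = matrix.values.to_numpy(dtype=float)
    se = _pooled_se(values, idx_t, idx_c)
    s0_val = _resolve_s0(se, s0)
    d = _d_statistic(values, idx_t, idx_c, s0_val)
    return pd.Series(d, index=matrix.values.index, name="d")


def _label_permutations(
    n_samples: int, n_treated: int, n_permutations: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Distinct treated-index assignments for the null distribution.

    If the number of distinct assignments is at most ``n_permutations`` they
    are all enumerated exactly (a 3 vs 3 contrast has only 20); otherwise
    ``n_permutations`` are sampled uniformly without replacement guarantees.
    """
    total = math.comb(n_samples, n_treated)
    if total < 2:
        raise ValueError("fewer than 2 distinct group-label permutations possible")
    if total <= n_permutations:
        return [np.array(c) for c in combinations(range(n_samples), n_treated)]
    perms = []
    for _ in range(n_permutations):
        perms.append(rng.choice(n_samples, size=n_treated, replace=False))
    return perms


def permutation_fdr(
    matrix: ExpressionMatrix,
    s0: float | str = "auto",
    n_permutations: int = 200,
    fdr_target: float | None = 0.02,
    delta: float | None = None,
    rng_seed: int = 0,
) -> SAMResult:
    """SAM-style significance calling with a permutation-estimated FDR.

    Null d-distributions come from re-assigning group labels (all distinct
    assignments when there are at most ``n_permutations``, else a uniform
    sample). For a candidate threshold delta, a gene is called when
    |d_i| >= delta, and the FDR estimate is the median over permutations of
    the null exceedance count divided by the observed call count. With
    ``fdr_target`` set (the default, 2%), the smallest delta meeting the
    target — i.e. the largest call set — is chosen; passing ``delta``
    directly skips the search. Deterministic given ``rng_seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if (fdr_target is None) == (delta is None):
        raise ValueError("specify exactly one of fdr_target and delta")
    idx_t, idx_c = _group_indices(matrix)
    values = matrix.values.to_numpy(dtype=float)
    se = _pooled_se(values, idx_t, idx_c)
    s0_val = _resolve_s0(se, s0)
    d_obs = _d_statistic(values, idx_t, idx_c, s0_val)

    rng = np.random.default_rng(rng_seed)
    n_samples = values.shape[1]
    all_cols = np.arange(n_samples)
    perms = _label_permutations(n_samples, len(idx_t), n_permutations, rng)
    null_sorted = []
    for treated_idx in perms:
        control_idx = np.setdiff1d(all_cols, treated_idx)
        null_sorted.append(
            np.sort(np.abs(_d_statistic(values, treated_idx, control_idx, s0_val)))
        )

    abs_obs = np.abs(d_obs)
    obs_sorted = np.sort(abs_obs)

    def fdr_at(thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Observed call counts and FDR estimates at each candidate delta."""
        n_called = len(obs_sorted) - np.searchsorted(obs_sorted, thresholds, side="left")
        null_counts = np.stack(
            [len(ns) - np.searchsorted(ns, thresholds, side="left") for ns in null_sorted]
        )
        med_null = np.median(null_counts, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            est = np.where(n_called > 0, np.minimum(1.0, med_null / n_called), 0.0)
        return n_called, est

    if delta is None:
        # candidate thresholds: each observed |d|; smallest qualifying delta
        # (= largest call set meeting the target) wins
        thresholds = np.unique(abs_obs)
        n_called, est = fdr_at(thresholds)
        ok = (n_called > 0) & (est <= fdr_target)
        if ok.any():
            first = int(np.argmax(ok))
            chosen_delta, chosen_fdr = float(thresholds[first]), float(est[first])
        else:
            chosen_delta, chosen_fdr = float(np.inf), 0.0
    else:
        chosen_delta = float(delta)
        _, est = fdr_at(np.array([chosen_delta]))
        chosen_fdr = float(est[0])

    significant = abs_obs >= chosen_delta
    return SAMResult(
        d=pd.Series(d_obs, index=matrix.values.index, name="d"),
        s0=s0_val,
        n_permutations=len(perms),
        delta=chosen_delta,
        estimated_fdr=chosen_fdr,
        significant=pd.Series(significant, index=matrix.values.index, name="significant"),
        fdr_target=fdr_target if fdr_target is not None else float("nan"),
    )


def de_gene_sets(sam: SAMResult, contrast: str = "contrast") -> DEGeneSets:
    """Split significant genes into up- (d > 0) and down-regulated (d < 0) lists."""
    sig = sam.d[sam.significant]
    return DEGeneSets(
        contrast=contrast,
        up=set(sig.index[sig > 0]),
        down=set(sig.index[sig < 0]),
        fdr_target=sam.fdr_target,
    )


def de_overlap(sets_a: DEGeneSets, sets_b: DEGeneSets, mode: str = "all") -> float:
    """Cosine overlap of two contrasts' DE gene sets.

    mode "all" pools up and down lists; mode "directional" tags each gene
    with its direction first, so a gene up in one contrast and down in the
    other does not count as shared.
    """
    if mode == "all":
        a, b = sets_a.all_genes, sets_b.all_genes
    elif mode == "directional":
        a = {f"{g}|up" for g in sets_a.up} | {f"{g}|down" for g in sets_a.down}
        b = {f"{g}|up" for g in sets_b.up} | {f"{g}|down" for g in sets_b.down}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not a or not b:
        raise ValueError("DE overlap is undefined for empty DE sets")
    return cosine_similarity(a, b)


def write_sam_result(sam: SAMResult, path: str | Path) -> None:
    """Per-gene TSV of d, significance flag and direction."""
    with open(path, "w") as out:
        out.write(f"# s0={sam.s0:.6g}\tn_permutations={sam.n_permutations}\t")
        out.write(f"delta={sam.delta:.6g}\testimated_fdr={sam.estimated_fdr:.6g}\n")
        out.write("gene\td\tsignificant\tdirection\n")
        for gene in sam.d.index:
            d = sam.d[gene]
            sig = bool(sam.significant[gene])
            direction = "up" if (sig and d > 0) else "down" if (sig and d < 0) else ""
            out.write(f"{gene}\t{d:.6f}\t{int(sig)}\t{direction}\n")


def write_de_sets(sets: DEGeneSets, path: str | Path) -> None:
    """Two-column TSV (gene, direction) for one contrast, sorted."""
    with open(path, "w") as out:
        out.write(f"# contrast={sets.contrast}\tfdr_target={sets.fdr_target}\n")
        out.write("gene\tdirection\n")
        for gene in sorted(sets.up):
            out.write(f"{gene}\tup\n")
        for gene in sorted(sets.down):
            out.write(f"{gene}\tdown\n")
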