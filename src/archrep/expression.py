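"""Expression-matrix filtering, differential analysis, and overlap tests.

Matrices are pandas DataFrames with genes as rows (index = gene_id) and
samples as columns, in FPKM/RPKM-like non-negative units.  Differential
abundance uses a two-sided permutation test on group-mean differences with
a variance-stabilizing offset s0 (the median of per-gene pooled standard
deviations), followed by Benjamini-Hochberg FDR.  Rank-based analysis
first converts each sample to within-sample ranks (1 = highest-expressed
gene, ties averaged) so datasets from different platforms become
comparable, then applies the same permutation machinery at a stricter FDR.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

__all__ = [
    "read_expression",
    "read_labels",
    "filter_bottom_mean",
    "keep_top_expressed",
    "mean_threshold_filter",
    "fold_change_de",
    "permutation_de",
    "rank_normalize",
    "differential_rank",
    "hypergeometric_overlap",
    "DETable",
]


def read_expression(source) -> pd.DataFrame:
    """Expression TSV: first column gene_id, remaining columns samples."""
    df = pd.read_csv(source, sep="\t")
    df = df.set_index(df.columns[0])
    if (df.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    return df


def read_labels(source) -> pd.Series:
    """Label TSV (sample, group) as a Series indexed by sample."""
    df = pd.read_csv(source, sep="\t")
    return df.set_index(df.columns[0]).iloc[:, 0]


def _rank_by_mean(matrix: pd.DataFrame) -> pd.DataFrame:
    # deterministic: sort by (mean, gene_id) so cutoff ties break by id order
    means = matrix.mean(axis=1)
    order = pd.DataFrame({"mean": means, "gene_id": matrix.index}).sort_values(
        ["mean", "gene_id"]
    )
    return matrix.loc[order["gene_id"]]


def filter_bottom_mean(matrix: pd.DataFrame, fraction: float = 0.25) -> pd.DataFrame:
    """Drop the ``floor(fraction * n)`` genes of lowest mean expression."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_drop = math.floor(fraction * len(matrix))
    ordered = _rank_by_mean(matrix)
    kept = ordered.index[n_drop:]
    return matrix.loc[matrix.index.intersection(kept, sort=False)]


def keep_top_expressed(matrix: pd.DataFrame, fraction: float = 0.5) -> pd.DataFrame:
    """Keep the ``floor(fraction * n)`` genes of highest mean expression."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_keep = math.floor(fraction * len(matrix))
    ordered = _rank_by_mean(matrix)
    kept = ordered.index[len(matrix) - n_keep :]
    return matrix.loc[matrix.index.intersection(kept, sort=False)]


def mean_threshold_filter(matrix: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Keep genes with mean expression strictly greater than ``threshold``."""
    return matrix.loc[matrix.mean(axis=1) > threshold]


def fold_change_de(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    fold: float = 2.0,
    pseudocount: float = 0.1,
) -> tuple[set[str], set[str]]:
    """Fold-change calls: up = mean(B)/mean(A) >= fold, down = the converse.

    Zero means are stabilized with a small pseudo-count so ratios stay
    finite.  Returns (up_in_b, down_in_b).
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    mean_a = matrix[group_a].mean(axis=1) + pseudocount
    mean_b = matrix[group_b].mean(axis=1) + pseudocount
    up = set(matrix.index[(mean_b / mean_a) >= fold])
    down = set(matrix.index[(mean_a / mean_b) >= fold])
    return up, down


@dataclass
class DETable:
    """Per-gene permutation differential-abundance results."""

    table: pd.DataFrame  # gene_id index; columns effect, p, fdr
    up: set[str]
    down: set[str]
    n_permutations: int
    s0: float
    seed: int


def _group_mean_diffs(values: np.ndarray, idx_a: np.ndarray) -> np.ndarray:
    """Mean(B) - mean(A) for each row, where columns in idx_a form group A."""
    n = values.shape[1]
    mask = np.zeros(n, dtype=bool)
    mask[idx_a] = True
    return values[:, ~mask].mean(axis=1) - values[:, mask].mean(axis=1)


def permutation_de(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    n_perm: int = 5000,
    fdr: float = 0.05,
    seed: int = 0,
) -> DETable:
    """Two-sided permutation test on stabilized group-mean differences.

    The statistic is d = (mean_B - mean_A) / (s + s0) with s the per-gene
    pooled standard deviation and s0 the median of all s — a
    variance-stabilized moderated difference.  Labels are permuted jointly
    across genes and the permuted statistics of *all* genes form one pooled
    null (the stabilized statistics are exchangeable across genes), so
    p-value resolution is 1/(permutations x genes) rather than
    1/permutations — small designs can still clear a stringent FDR.  When
    ``n_perm`` meets or exceeds the number of distinct label assignments,
    all assignments are enumerated instead.  Deterministic given ``seed``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    cols = list(group_a) + list(group_b)
    values = matrix[cols].to_numpy(dtype=float)
    n_a = len(group_a)
    n_total = len(cols)

    sd_a = values[:, :n_a].std(axis=1, ddof=1)
    sd_b = values[:, n_a:].std(axis=1, ddof=1)
    pooled = np.sqrt(
        ((n_a - 1) * sd_a**2 + (n_total - n_a - 1) * sd_b**2) / (n_total - 2)
    )
    s0 = float(np.median(pooled))
    denom = pooled + s0
    degenerate = denom == 0  # every value of the gene identical in both groups

    observed_diff = _group_mean_diffs(values, np.arange(n_a))
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.where(degenerate, 0.0, observed_diff / np.where(denom == 0, 1, denom))

    n_exhaustive = math.comb(n_total, n_a)
    rng = np.random.default_rng(seed)
    if n_perm >= n_exhaustive:
        assignments = [np.array(c) for c in itertools.combinations(range(n_total), n_a)]
    else:
        assignments = [rng.choice(n_total, size=n_a, replace=False) for _ in range(n_perm)]

    exceed = np.zeros(values.shape[0], dtype=np.int64)
    abs_obs = np.abs(observed)
    obs_order = np.argsort(abs_obs)
    sorted_obs = abs_obs[obs_order]
    for idx_a in assignments:
        diff = _group_mean_diffs(values, idx_a)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(degenerate, 0.0, diff / np.where(denom == 0, 1, denom))
        # pooled null: every gene's permuted statistic counts against every
        # observed statistic
        perm_sorted = np.sort(np.abs(stat))
        exceed[obs_order] += perm_sorted.size - np.searchsorted(
            perm_sorted, sorted_obs - 1e-12, side="left"
        )
    total = len(assignments) * values.shape[0]
    if n_perm >= n_exhaustive:
        # identity assignment is among the enumerated ones, so p > 0
        p = exceed / total
    else:
        p = (1 + exceed) / (1 + total)
    p = np.clip(p, 0.0, 1.0)
    q = bh_fdr(p)

    table = pd.DataFrame(
        {"effect": observed_diff, "statistic": observed, "p": p, "fdr": q},
        index=matrix.index,
    )
    sig = table["fdr"] <= fdr
    up = set(table.index[sig & (table["effect"] > 0)])
    down = set(table.index[sig & (table["effect"] < 0)])
    return DETable(
        table=table,
        up=up,
        down=down,
        n_permutations=len(assignments),
        s0=s0,
        seed=seed,
    )


def rank_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Within-sample ranks: 1 = highest-expressed gene, ties averaged."""
    return matrix.rank(axis=0, ascending=False, method="average")


def differential_rank(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    n_perm: int = 5000,
    fdr: float = 0.01,
    seed: int = 0,
) -> DETable:
    """Permutation DE on rank-normalized matrices (cross-platform).

    ``up`` holds genes whose rank *number* decreases in B, i.e. genes that
    move towards the top of the expression ordering.
    """
    common = matrix_a.index.intersection(matrix_b.index)
    if len(common) != len(matrix_a) or len(common) != len(matrix_b):
        raise ValueError("matrices must share the same gene universe")
    ranks_a = rank_normalize(matrix_a.loc[common])
    ranks_b = rank_normalize(matrix_b.loc[common])
    joined = pd.concat([ranks_a, ranks_b], axis=1)
    res = permutation_de(
        joined,
        group_a=list(ranks_a.columns),
        group_b=list(ranks_b.columns),
        n_perm=n_perm,
        fdr=fdr,
        seed=seed,
    )
    # a *decrease* in rank number means higher relative expression
    return DETable(
        table=res.table,
        up=res.down,
        down=res.up,
        n_permutations=res.n_permutations,
        s0=res.s0,
        seed=res.seed,
    )


def hypergeometric_overlap(set_a, set_b, universe) -> float:
    """Upper-tail hypergeometric p of observing >= |A ∩ B| shared genes."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    a = set(set_a) & universe
    b = set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))
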