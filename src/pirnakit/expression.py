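"""Expression matrices, profile clustering and differential expression.

Abundance is expressed in tags per million (TPM): a tag's read count scaled
by 1e6 over the library's total genome-mapped piRNA-like reads, so TPM over
all mapped tags sums to 1e6 per library.  Two-library differential calls
use the exact conditional-binomial formulation of the Poisson tag-count
test (Audic-Claverie equivalent): conditional on x + y observed reads, x is
Binomial(x + y, Na / (Na + Nb)) under the null of equal relative abundance;
the two-sided p doubles the smaller tail, capped at 1.  Benjamini-Hochberg
adjusted p-values are emitted alongside raw ones, and a call requires
adjusted p <= alpha together with |log2 ratio| >= the fold threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("pirnakit")


def tpm_matrix(
    counts: pd.DataFrame, library_totals: Mapping[str, int], log2: bool = False
) -> pd.DataFrame:
    """TPM = count x 1e6 / library total; optionally log2(TPM + 1).

    ``counts`` has one row per tag or cluster, one column per library.
    Libraries with a zero total are excluded with a warning.
    """
    cols = []
    for lib in counts.columns:
        total = library_totals.get(lib, 0)
        if total <= 0:
            logger.warning("tpm_matrix: library %s has zero total, excluded", lib)
            continue
        cols.append(counts[lib] * 1e6 / total)
    mat = pd.concat(cols, axis=1) if cols else pd.DataFrame(index=counts.index)
    if log2:
        mat = np.log2(mat + 1.0)
    return mat


def top_n_union(matrix: pd.DataFrame, n: int = 100) -> pd.DataFrame:
    """Union of each library's top-n rows by TPM.

    Ties at the cut break by row total (descending) then row label; the
    union is returned in that deterministic order.
    """
    totals = matrix.sum(axis=1)
    chosen: set = set()
    for lib in matrix.columns:
        order = sorted(
            matrix.index, key=lambda r: (-matrix.at[r, lib], -totals[r], str(r))
        )
        chosen.update(order[: min(n, len(order))])
    keep = sorted(chosen, key=lambda r: (-totals[r], str(r)))
    return matrix.loc[keep]


@dataclass
class HierarchicalResult:
    linkage: np.ndarray
    labels: list
    groups: pd.Series  # flat group id per row

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return str(self.labels[node.id])
            return f"({render(node.left)},{render(node.right)}):{node.dist:.6g}"

        return render(tree) + ";"


def _correlation_distance(log_mat: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distances with a Euclidean fallback.

    Pairs involving a constant (zero-variance) row have no defined
    correlation; those pairs fall back to Euclidean distance rescaled into
    [0, 2] so they remain comparable to correlation distances.
    """
    n = log_mat.shape[0]
    sd = log_mat.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info("%d constant rows use the Euclidean fallback distance", constant.sum())
    centered = log_mat - log_mat.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1)
    span = max(np.ptp(log_mat), 1.0)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if constant[i] or constant[j]:
                d = np.linalg.norm(log_mat[i] - log_mat[j]) / (span * math.sqrt(log_mat.shape[1]))
                out[k] = min(2.0, d)
            else:
                r = float(centered[i] @ centered[j] / (norm[i] * norm[j]))
                out[k] = 1.0 - max(-1.0, min(1.0, r))
            k += 1
    return out


def hierarchical_cluster(
    matrix: pd.DataFrame,
    n_groups: Optional[int] = None,
    cut_height: Optional[float] = None,
) -> HierarchicalResult:
    """Average-linkage clustering of log2(TPM + 1) expression profiles.

    Distance is 1 - Pearson correlation between row profiles (constant rows
    fall back to Euclidean, logged).  Flat groups come from cutting the
    tree at ``n_groups`` leaves or at ``cut_height``.
    """
    if len(matrix) < 2:
        raise ValueError("hierarchical clustering needs >= 2 rows")
    log_mat = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    dist = _correlation_distance(log_mat)
    Z = hierarchy.average(dist)
    if n_groups is not None:
        flat = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    elif cut_height is not None:
        flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    else:
        flat = hierarchy.fcluster(Z, t=0.5 * Z[:, 2].max(), criterion="distance")
    groups = pd.Series(flat, index=matrix.index, name="group")
    return HierarchicalResult(linkage=Z, labels=list(matrix.index), groups=groups)


def poisson_de(
    count_a: int, total_a: float, count_b: int, total_b: float
) -> tuple[float, float]:
    """Exact conditional tag-count test and normalised log2 ratio.

    Returns (two-sided p, log2 ratio).  The ratio compares counts scaled by
    their library totals; when either count is zero, a pseudocount of 1 is
    added to both raw counts before normalising so the ratio stays finite.
    Both counts zero gives p = 1, ratio 0.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    n = count_a + count_b
    if n == 0:
        return 1.0, 0.0
    p_null = total_a / (total_a + total_b)
    lower = float(binom.cdf(count_a, n, p_null))
    upper = float(binom.sf(count_a - 1, n, p_null))
    p_value = min(1.0, 2.0 * min(lower, upper))
    if count_a == 0 or count_b == 0:
        ca, cb = count_a + 1, count_b + 1
    else:
        ca, cb = count_a, count_b
    log2_ratio = math.log2((ca / total_a) / (cb / total_b))
    return p_value, log2_ratio


def de_table(
    counts: pd.DataFrame,
    lib_a: str,
    lib_b: str,
    total_a: Optional[int] = None,
    total_b: Optional[int] = None,
    alpha: float = 0.05,
    min_log2_ratio: float = 1.0,
) -> pd.DataFrame:
    """Two-library differential table with BH adjustment and direction calls.

    Library totals default to the column sums of ``counts``.  ``direction``
    is a_up/b_up when adjusted p <= alpha and |log2 ratio| >= the
    threshold, else ns; ``specific_flag`` marks significant tags whose
    lower count is exactly 0 (library-specific piRNAs).
    """
    total_a = int(counts[lib_a].sum()) if total_a is None else total_a
    total_b = int(counts[lib_b].sum()) if total_b is None else total_b
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    x = counts[lib_a].to_numpy(dtype=int)
    y = counts[lib_b].to_numpy(dtype=int)
    n = x + y
    p_null = total_a / (total_a + total_b)
    # vectorised form of poisson_de over the whole table
    lower = binom.cdf(x, n, p_null)
    upper = binom.sf(x - 1, n, p_null)
    p_values = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p_values[n == 0] = 1.0
    zero = (x == 0) | (y == 0)
    ca = np.where(zero, x + 1, np.maximum(x, 1))
    cb = np.where(zero, y + 1, np.maximum(y, 1))
    log2_ratio = np.log2((ca / total_a) / (cb / total_b))
    log2_ratio[n == 0] = 0.0
    df = pd.DataFrame(
        {
            "count_a": x,
            "count_b": y,
            "log2_ratio": log2_ratio,
            "p_value": p_values,
        },
        index=pd.Index(counts.index, name="tag_id"),
    )
    df["total_a"] = total_a
    df["total_b"] = total_b
    if len(df):
        df["adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["adjusted_p"] = []
    significant = (df["adjusted_p"] <= alpha) & (df["log2_ratio"].abs() >= min_log2_ratio)
    df["direction"] = np.where(
        significant & (df["log2_ratio"] > 0),
        "a_up",
        np.where(significant & (df["log2_ratio"] < 0), "b_up", "ns"),
    )
    df["specific_flag"] = significant & (
        (df[["count_a", "count_b"]].min(axis=1) == 0)
    )
    return df
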