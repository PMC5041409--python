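"""Capture-recapture estimation of the piRNA sequence-pool size.

Each library is a "capture" of distinct piRNA sequences from a common
pool; the pool size is estimated pairwise from the two libraries' distinct
tag counts and their overlap.  The bias-corrected Chapman estimator

    N_hat = (n_i + 1)(n_j + 1) / (m_ij + 1) - 1

is the default (finite even at zero overlap, less biased than plain
Lincoln-Petersen n_i n_j / m_ij at small overlap, which is available as an
alternative).  The point estimate over many libraries is the median of all
pairwise estimates, with the pairwise extremes reported as the minimum and
maximum estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .preprocess import UniqueTag


def pairwise_overlap(
    tags: Iterable[UniqueTag], lib_i: str, lib_j: str
) -> tuple[int, int, int]:
    """Distinct-sequence counts of two libraries and their shared count."""
    n_i = n_j = m = 0
    for tag in tags:
        in_i = tag.counts.get(lib_i, 0) > 0
        in_j = tag.counts.get(lib_j, 0) > 0
        n_i += in_i
        n_j += in_j
        m += in_i and in_j
    return n_i, n_j, m


def chapman_estimate(n_i: int, n_j: int, m_ij: int) -> float:
    if n_i < 1 or n_j < 1:
        raise ValueError("both samples must be non-empty")
    if m_ij > min(n_i, n_j):
        raise ValueError("overlap cannot exceed either sample size")
    return (n_i + 1) * (n_j + 1) / (m_ij + 1) - 1


def lincoln_petersen_estimate(n_i: int, n_j: int, m_ij: int) -> float:
    if m_ij <= 0:
        return float("inf")
    return n_i * n_j / m_ij


@dataclass
class PoolEstimate:
    pairwise: pd.DataFrame  # lib_i, lib_j, n_i, n_j, m_ij, estimate
    point: float  # median over pairs
    minimum: float
    maximum: float
    min_pair: tuple[str, str]
    max_pair: tuple[str, str]


def pool_summary(
    tags: Sequence[UniqueTag],
    libraries: Sequence[str],
    estimator: str = "chapman",
) -> PoolEstimate:
    """Evaluate every library pair and summarise (median, min, max)."""
    if len(libraries) < 2:
        raise ValueError("pool estimation needs >= 2 libraries")
    est_fn = {"chapman": chapman_estimate, "lincoln-petersen": lincoln_petersen_estimate}[
        estimator
    ]
    rows = []
    for a in range(len(libraries)):
        for b in range(a + 1, len(libraries)):
            li, lj = libraries[a], libraries[b]
            n_i, n_j, m = pairwise_overlap(tags, li, lj)
            rows.append((li, lj, n_i, n_j, m, est_fn(n_i, n_j, m)))
    table = pd.DataFrame(
        rows, columns=["lib_i", "lib_j", "n_i", "n_j", "m_ij", "estimate"]
    )
    idx_min = table["estimate"].idxmin()
    idx_max = table["estimate"].idxmax()
    return PoolEstimate(
        pairwise=table,
        point=float(median(table["estimate"])),
        minimum=float(table.loc[idx_min, "estimate"]),
        maximum=float(table.loc[idx_max, "estimate"]),
        min_pair=(table.loc[idx_min, "lib_i"], table.loc[idx_min, "lib_j"]),
        max_pair=(table.loc[idx_max, "lib_i"], table.loc[idx_max, "lib_j"]),
    )
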