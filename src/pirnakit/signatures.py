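"""piRNA biogenesis statistics.

Three families of statistics diagnose piRNA biogenesis:

* positional base composition of the tag population (sequence-logo matrix),
  from which the 1U fraction (uridine at the 5' end, primary pathway) and
  the 10A fraction (adenosine at position ten, ping-pong products) are read;
* the ping-pong profile: a histogram over the 5'-5' overlap distance d
  between opposite-strand tags, where the secondary amplification loop
  produces a spike at exactly d = 10;
* sense/antisense strand bias per category, TE class, gene subfeature or
  library.

Overlap convention: for a plus-strand 5' end at p and a minus-strand 5' end
at q on the same contig, d = q - p + 1, counting both boundary bases, so a
"precise 10-nt 5' overlap" is d = 10.  Ping-pong statistics use uniquely
mapped tags only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import MappedTag
from .annotate import FeatureAssignment

logger = logging.getLogger("pirnakit")

BASES = ("A", "C", "G", "T")
MAX_OVERLAP = 30


@dataclass
class NucleotideProfile:
    """Position x base frequency matrix with the 1U/10A summary fractions."""

    matrix: pd.DataFrame  # rows 1..L, columns A,C,G,T
    n_sequences: int
    weighting: str  # per-tag | per-read

    @property
    def frac_1U(self) -> float:
        """T frequency at position 1 (DNA alphabet; U in the RNA)."""
        if self.n_sequences == 0:
            return float("nan")
        return float(self.matrix.loc[1, "T"])

    @property
    def frac_10A(self) -> float:
        if self.n_sequences == 0 or 10 not in self.matrix.index:
            return float("nan")
        return float(self.matrix.loc[10, "A"])


def base_composition(
    tags: Iterable[tuple[str, float]], L: int = 30, weighting: str = "per-read"
) -> NucleotideProfile:
    """Weighted positional base frequencies over the first ``L`` positions.

    ``tags`` yields (sequence, weight); per-tag weighting passes weight 1.
    Positions beyond a sequence's length contribute nothing, and each row is
    normalised by the weight present at that position, so every populated
    row sums to 1.
    """
    counts = np.zeros((L, 4))
    base_idx = {b: i for i, b in enumerate(BASES)}
    n = 0
    for seq, weight in tags:
        n += 1
        for pos, base in enumerate(seq[:L]):
            j = base_idx.get(base)
            if j is not None:
                counts[pos, j] += weight
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, np.nan)
    matrix = pd.DataFrame(freqs, index=range(1, L + 1), columns=list(BASES))
    return NucleotideProfile(matrix=matrix, n_sequences=n, weighting=weighting)


@dataclass
class PingPongProfile:
    """5'-overlap histogram, per-distance 5'-base usage and the d=10 summary."""

    histogram: pd.Series  # index d = 1..MAX_OVERLAP
    base_by_distance: pd.DataFrame  # rows d, columns A,C,G,T (participants' 5' base)
    n_pairs_weight: float

    @property
    def ping_pong_fraction(self) -> float:
        total = float(self.histogram.sum())
        if total == 0:
            return float("nan")
        return float(self.histogram.loc[10]) / total

    @property
    def z10(self) -> float:
        """z-score of the d=10 weight against the other distances."""
        others = self.histogram.drop(10).to_numpy(dtype=float)
        if len(others) < 2 or float(self.histogram.sum()) == 0:
            return float("nan")
        sd = others.std(ddof=1)
        if sd == 0:
            return float("nan")
        return (float(self.histogram.loc[10]) - others.mean()) / sd


def ping_pong_profile(
    mapped: Iterable[MappedTag],
    weighting: str = "read-count-product",
    library: str | None = None,
    max_overlap: int = MAX_OVERLAP,
) -> PingPongProfile:
    """Opposite-strand 5'-overlap profile of uniquely mapped tags.

    For every (+ tag 5' at p, - tag 5' at q) pair on one contig with
    1 <= q - p + 1 <= max_overlap the histogram accumulates the product of
    the two read counts (or 1 under ``distinct-pair`` weighting), and both
    participants' 5' bases accrue the same weight at that distance.
    Restricting ``library`` scores only that library's counts.
    """
    if weighting not in ("read-count-product", "distinct-pair"):
        raise ValueError(f"unknown weighting {weighting!r}")
    plus: dict[str, dict[int, list]] = {}
    minus: dict[str, dict[int, list]] = {}
    for mt in mapped:
        if mt.mapping_class != "unique":
            continue
        count = (
            mt.tag.counts.get(library, 0) if library is not None else mt.tag.total_count
        )
        if count == 0:
            continue
        (contig, pos, strand) = mt.five_prime_positions[0]
        side = plus if strand == "+" else minus
        side.setdefault(contig, {}).setdefault(pos, []).append(
            (count, mt.tag.sequence[0])
        )
    hist = np.zeros(max_overlap + 1)
    base_w = np.zeros((max_overlap + 1, 4))
    base_idx = {b: i for i, b in enumerate(BASES)}
    for contig, by_pos in plus.items():
        minus_pos = minus.get(contig)
        if not minus_pos:
            continue
        for p, plus_reads in by_pos.items():
            for d in range(1, max_overlap + 1):
                q = p + d - 1
                minus_reads = minus_pos.get(q)
                if not minus_reads:
                    continue
                for cp, bp in plus_reads:
                    for cm, bm in minus_reads:
                        w = cp * cm if weighting == "read-count-product" else 1.0
                        hist[d] += w
                        if bp in base_idx:
                            base_w[d, base_idx[bp]] += w
                        if bm in base_idx:
                            base_w[d, base_idx[bm]] += w
    if hist.sum() == 0:
        logger.info("ping_pong_profile: no opposite-strand pairs found")
    totals = base_w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        base_freq = np.where(totals > 0, base_w / totals, np.nan)
    index = range(1, max_overlap + 1)
    return PingPongProfile(
        histogram=pd.Series(hist[1:], index=index, name="weight"),
        base_by_distance=pd.DataFrame(base_freq[1:], index=index, columns=list(BASES)),
        n_pairs_weight=float(hist.sum()),
    )


def strand_bias(
    frame: pd.DataFrame, group_by: str = "category"
) -> pd.DataFrame:
    """Sense/antisense read counts and ratio per group.

    ``frame`` is the long assignment table (one row per tag x library).
    ``group_by`` is one of category, repeat_class, gene_subfeature or
    library.  Groups with zero antisense reads carry ratio inf; empty
    groups are omitted (logged).
    """
    if group_by not in ("category", "repeat_class", "gene_subfeature", "library"):
        raise ValueError(f"cannot group strand bias by {group_by!r}")
    sub = frame[frame.orientation.isin(["sense", "antisense"])]
    if sub.empty:
        logger.info("strand_bias: no oriented tags for group_by=%s", group_by)
        return pd.DataFrame(columns=["sense", "antisense", "ratio"])
    piv = sub.pivot_table(
        index=group_by, columns="orientation", values="count", aggfunc="sum", fill_value=0
    )
    for col in ("sense", "antisense"):
        if col not in piv:
            piv[col] = 0
    piv = piv[["sense", "antisense"]].astype(float)
    piv["ratio"] = [
        s / a if a > 0 else (float("inf") if s > 0 else float("nan"))
        for s, a in zip(piv["sense"], piv["antisense"])
    ]
    return piv


def signature_summary(
    mapped_unique: Sequence[MappedTag], libraries: Sequence[str]
) -> pd.DataFrame:
    """Per-library and pooled 1U/10A fractions and ping-pong summaries."""
    rows = []
    for lib in list(libraries) + ["pooled"]:
        sel = None if lib == "pooled" else lib
        seqs = [
            (mt.tag.sequence, mt.tag.total_count if sel is None else mt.tag.counts.get(sel, 0))
            for mt in mapped_unique
        ]
        seqs = [(s, w) for s, w in seqs if w > 0]
        prof = base_composition(seqs)
        pp = ping_pong_profile(mapped_unique, library=sel)
        rows.append(
            {
                "library": lib,
                "n_tags": prof.n_sequences,
                "frac_1U": prof.frac_1U,
                "frac_10A": prof.frac_10A,
                "ping_pong_fraction": pp.ping_pong_fraction,
                "z10": pp.z10,
            }
        )
    return pd.DataFrame(rows).set_index("library")
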