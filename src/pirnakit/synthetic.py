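"""Synthetic genome, annotation and six-stage small-RNA libraries.

Everything downstream is exercised against data with planted, fully known
structure: a toy genome carrying repeats of all six classes, protein-coding
genes with exon/intron/UTR architecture and structural ncRNAs; a pool of
piRNA-producing loci split between planted clusters, repeats, gene
subfeatures and plain intergenic space; and six stage-labelled libraries
(embryo, larva, pupa, adult male, sugar-fed female, blood-fed female) whose
reads carry planted length mixtures, 5'-uridine and position-10 adenosine
biases, ping-pong pairs, strand biases, stage-specific expression and
contaminants (miRNA-sized reads, ncRNA fragments, homopolymer artifacts,
a ligated 3' adapter).

Planting notes
--------------
* Read lengths come from a two-component truncated discrete Gaussian
  mixture: a miRNA-like component (mean 21.5, sd 1, on 18-23 nt) and a
  piRNA-like component (mean 27, sd 1, on 24-30 nt); the mixture weight is
  per-library, so the embryo and sugar-fed female libraries peak at
  26-28 nt while the other stages peak at 20-23 nt.
* 1U/10A biases are planted by rejection-sampling locus positions until the
  genomic base under the 5' end (and under position 10) matches an
  independently drawn Bernoulli target — reads stay exact genome
  substrings.
* A ping-pong partner is an opposite-strand read whose 5' end overlaps the
  primary's 5' end by exactly 10 nt.  Because partner reads are also exact
  substrings, the partner's position-10 base is complementary to the
  primary's first base; planted 1U/10A marginals therefore refer to
  primary loci, and partnered emissions inherit the coupled geometry.
  Paired loci emit an opposite-strand partner with every read: overlap
  exactly 10 with probability ``ping_pong_rate``, else uniform on 1-30 nt
  (the flat background the profile is judged against).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import DEFAULT_LIBRARIES
from .io import (
    AnnotationRecord,
    GenomeSequence,
    NCRNA_KINDS,
    synthesize_introns,
    write_bed,
    write_fastq,
    write_genome,
    write_gff3,
)
from .preprocess import UniqueTag, has_homopolymer

logger = logging.getLogger("pirnakit")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

FAMILY_NAMES = {
    "LINE": ("R1", "Jockey", "CR1"),
    "LTR": ("Gypsy", "Pao", "Copia"),
    "SINE": ("Feilai",),
    "DNA": ("Tc1", "hAT", "Mariner"),
    "Helitron": ("Helibat",),
    "Satellite": ("AlbSat",),
}
#: this family is pasted as identical copies, so its reads multi-map
DUPLICATED_FAMILY = ("LTR", "Gypsy")

DEFAULT_REPEATS_PER_CLASS = {
    "LINE": 6, "LTR": 6, "SINE": 3, "DNA": 5, "Helitron": 3, "Satellite": 3,
}

#: sense-orientation probability of repeat-derived loci per class (plants
#: the observed antisense dominance of LINE/LTR/DNA and sense bias of SINE)
REPEAT_SENSE_PROB = {
    "LINE": 0.22, "LTR": 0.21, "SINE": 0.92, "DNA": 0.07,
    "Helitron": 0.30, "Satellite": 0.60,
}
GENE_SUBFEATURE_WEIGHTS = {
    "intron": 0.50, "CDS": 0.34, "five_prime_UTR": 0.08, "three_prime_UTR": 0.08,
}
GENE_SENSE_PROB = {
    "intron": 0.60, "CDS": 0.70, "five_prime_UTR": 0.35, "three_prime_UTR": 0.35,
}

#: per-library weight of the piRNA-like length component; the two
#: piRNA-dominant libraries reproduce the major/minor peak inversion
DEFAULT_PIRNA_WEIGHT = {
    "embryo": 0.65,
    "larva": 0.35,
    "pupa": 0.30,
    "adult_male": 0.35,
    "sugarfed_female": 0.60,
    "bloodfed_female": 0.40,
}

#: stage-expression multipliers of the planted clusters (cluster i -> lib -> x)
DEFAULT_CLUSTER_PROFILES = (
    {"embryo": 5.0},
    {"larva": 4.0},
    {"pupa": 4.0},
    {"adult_male": 3.0, "sugarfed_female": 3.0, "bloodfed_female": 3.0},
    {"sugarfed_female": 4.0, "bloodfed_female": 4.0},
    {"bloodfed_female": 5.0},
)

#: planted differential-expression groups: name -> (n_loci, lib -> multiplier)
DEFAULT_DE_GROUPS = {
    "male_biased": (60, {"adult_male": 4.0}),
    "female_biased": (60, {"sugarfed_female": 4.0, "bloodfed_female": 4.0}),
    "blood_induced": (40, {"bloodfed_female": 4.0}),
    "blood_specific": (10, {"sugarfed_female": 0.0, "bloodfed_female": 4.0}),
    "embryo_high": (80, {"embryo": 6.0}),
}


@dataclass
class SimulationParams:
    """Planted statistical structure of the simulated libraries."""

    p_1U: float = 0.76
    p_10A: float = 0.41
    ping_pong_rate: float = 0.30
    pairing_fraction: float = 0.25
    category_fractions: dict = field(
        default_factory=lambda: {"intergenic": 0.5, "repeat": 0.3, "gene": 0.2}
    )
    cluster_share: float = 0.9  # of intergenic reads that come from clusters
    cluster_loci_per_cluster: int = 20
    n_loci: int = 2400
    n_multi_loci: int = 30
    n_ncrna_loci: int = 40
    n_clusters: int = 6
    cluster_length: tuple = (5000, 7000)
    de_lam_boost: float = 6.0  # planted DE piRNAs are drawn abundant
    pirna_weight: dict = field(default_factory=lambda: dict(DEFAULT_PIRNA_WEIGHT))
    artifact_fraction: float = 0.01
    ncrna_fraction: float = 0.04
    mirna_length: tuple = (21.5, 1.0, 18, 23)  # mean, sd, lo, hi
    pirna_length: tuple = (27.0, 1.0, 24, 30)
    lognormal_sigma: float = 0.6
    cluster_lognormal_sigma: float = 0.25
    adapter: str = "TCGTATGCCGTCTTCTGCTTGT"
    read_length: int = 36
    max_overlap: int = 30

    def __post_init__(self) -> None:
        for name in ("p_1U", "p_10A", "ping_pong_rate", "pairing_fraction",
                     "cluster_share", "artifact_fraction", "ncrna_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.category_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")


@dataclass
class PlantedCluster:
    cluster_id: str
    contig: str
    start: int
    end: int
    strandness: str  # plus_only | minus_only | divergent_non_overlapping
    profile: dict  # library -> multiplier
    expected_tpm_share: dict = field(default_factory=dict)


@dataclass
class Locus:
    locus_id: str
    contig: str
    five_prime: int
    strand: str
    length: int
    sequence: str
    category: str  # intergenic | repeat | gene | ncRNA
    repeat_class: Optional[str] = None
    repeat_family: Optional[str] = None
    gene_subfeature: Optional[str] = None
    orientation: str = "n/a"
    cluster_id: Optional[str] = None
    paired: bool = False
    de_group: Optional[str] = None
    expected_mapping: str = "unique"
    lam: float = 1.0

    @property
    def start(self) -> int:
        return self.five_prime if self.strand == "+" else self.five_prime - self.length + 1

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SyntheticTruth:
    params: SimulationParams
    planted_clusters: list
    loci: list
    reads: pd.DataFrame  # one row per emitted read
    library_names: tuple


def _trunc_gauss_int(rng, mean, sd, lo, hi, size=None):
    xs = np.arange(lo, hi + 1)
    w = np.exp(-0.5 * ((xs - mean) / sd) ** 2)
    w /= w.sum()
    return rng.choice(xs, size=size, p=w)


def _random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class _SizingError(ValueError):
    pass


def build_genome(
    n_contigs: int = 6,
    contig_length: int = 80000,
    n_repeats_per_class: Optional[Mapping[str, int]] = None,
    n_genes: int = 8,
    n_ncrna: int = 10,
    seed: int = 0,
) -> tuple[list[GenomeSequence], list[AnnotationRecord]]:
    """Random genome with planted repeats, genes and ncRNAs.

    Genes never overlap other features; one repeat family (LTR/Gypsy) is
    pasted as identical copies so that reads from it multi-map, all other
    features sit on unique random sequence.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    if n_repeats_per_class is None:
        n_repeats_per_class = DEFAULT_REPEATS_PER_CLASS
    contigs = [f"contig_{i + 1}" for i in range(n_contigs)]
    seq_arrays = {
        cid: np.array(list(_random_dna(rng, contig_length))) for cid in contigs
    }

    requests = []
    for _ in range(n_genes):
        requests.append(("gene", None, int(rng.integers(2600, 4200))))
    dup_consensus = _random_dna(rng, 800)
    for cls in sorted(n_repeats_per_class):
        n = n_repeats_per_class[cls]
        families = FAMILY_NAMES.get(cls, (cls,))
        for i in range(n):
            family = families[i % len(families)]
            if (cls, family) == DUPLICATED_FAMILY:
                requests.append(("repeat", (cls, family, dup_consensus), len(dup_consensus)))
            else:
                requests.append(("repeat", (cls, family, None), int(rng.integers(400, 1400))))
    for i in range(n_ncrna):
        requests.append(("ncrna", NCRNA_KINDS[i % len(NCRNA_KINDS)], int(rng.integers(90, 200))))
    rng.shuffle(requests)

    cursors = {cid: int(rng.integers(500, 2000)) for cid in contigs}
    records: list[AnnotationRecord] = []
    gene_i = repeat_i = ncrna_i = 0
    for kind, payload, length in requests:
        placed = False
        order = sorted(contigs, key=lambda c: cursors[c])
        for cid in order:
            start = cursors[cid]
            if start + length + 500 > contig_length:
                continue
            cursors[cid] = start + length + int(rng.integers(400, 1600))
            placed = True
            break
        if not placed:
            raise _SizingError("requested features exceed contig capacity")
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "gene":
            gene_i += 1
            records.extend(_gene_records(cid, start, end, strand, f"gene_{gene_i}", rng))
        elif kind == "repeat":
            repeat_i += 1
            cls, family, consensus = payload
            if consensus is not None:
                seq_arrays[cid][start:end] = list(consensus)
            records.append(
                AnnotationRecord(
                    contig_id=cid, start=start, end=end, strand=strand,
                    feature_kind="repeat", repeat_class=cls, repeat_family=family,
                    record_id=f"repeat_{repeat_i}",
                )
            )
        else:
            ncrna_i += 1
            records.append(
                AnnotationRecord(
                    contig_id=cid, start=start, end=end, strand=strand,
                    feature_kind=payload, record_id=f"{payload}_{ncrna_i}",
                )
            )
    genome = [GenomeSequence(cid, "".join(seq_arrays[cid])) for cid in contigs]
    return genome, synthesize_introns(records)


def _gene_records(cid, start, end, strand, gene_id, rng):
    """Three-exon gene with strand-aware UTRs flanking the CDS."""
    span = end - start
    e1, e2, e3 = (int(rng.integers(350, 650)) for _ in range(3))
    gap_total = span - e1 - e2 - e3
    i1 = int(rng.integers(int(gap_total * 0.3), int(gap_total * 0.7)))
    i2 = gap_total - i1
    b = [start, start + e1, start + e1 + i1, start + e1 + i1 + e2,
         start + e1 + i1 + e2 + i2, end]
    exons = [(b[0], b[1]), (b[2], b[3]), (b[4], b[5])]
    utr = 120
    recs = [AnnotationRecord(cid, start, end, strand, "gene", record_id=gene_id)]
    for i, (es, ee) in enumerate(exons):
        recs.append(AnnotationRecord(cid, es, ee, strand, "exon",
                                     parent_id=gene_id, record_id=f"{gene_id}.e{i + 1}"))
    (fs, fe), (ls, le) = exons[0], exons[-1]
    if strand == "+":
        recs.append(AnnotationRecord(cid, fs, fs + utr, strand, "five_prime_UTR", parent_id=gene_id))
        recs.append(AnnotationRecord(cid, fs + utr, fe, strand, "CDS", parent_id=gene_id))
        recs.append(AnnotationRecord(cid, ls, le - utr, strand, "CDS", parent_id=gene_id))
        recs.append(AnnotationRecord(cid, le - utr, le, strand, "three_prime_UTR", parent_id=gene_id))
    else:
        recs.append(AnnotationRecord(cid, le - utr, le, strand, "five_prime_UTR", parent_id=gene_id))
        recs.append(AnnotationRecord(cid, ls, le - utr, strand, "CDS", parent_id=gene_id))
        recs.append(AnnotationRecord(cid, fs + utr, fe, strand, "CDS", parent_id=gene_id))
        recs.append(AnnotationRecord(cid, fs, fs + utr, strand, "three_prime_UTR", parent_id=gene_id))
    mid_s, mid_e = exons[1]
    recs.append(AnnotationRecord(cid, mid_s, mid_e, strand, "CDS", parent_id=gene_id))
    return recs


def _free_intervals(
    genome: Sequence[GenomeSequence],
    annotations: Sequence[AnnotationRecord],
    margin: int = 200,
) -> dict[str, list[tuple[int, int]]]:
    """Per-contig intervals not covered by any annotated feature (+margin)."""
    occupied: dict[str, list[tuple[int, int]]] = {g.contig_id: [] for g in genome}
    for rec in annotations:
        if rec.feature_kind in ("gene", "repeat") or rec.feature_kind in NCRNA_KINDS:
            occupied[rec.contig_id].append((rec.start - margin, rec.end + margin))
    free = {}
    for g in genome:
        ivs = sorted(occupied[g.contig_id])
        merged = []
        for a, b in ivs:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        out, cursor = [], margin
        for a, b in merged:
            if a > cursor:
                out.append((cursor, a))
            cursor = max(cursor, b)
        if g.length - margin > cursor:
            out.append((cursor, g.length - margin))
        free[g.contig_id] = out
    return free


def _carve(free: dict, length: int, rng) -> Optional[tuple[str, int, int]]:
    """Take a random interval of ``length`` out of the free space."""
    candidates = [
        (cid, i) for cid, ivs in sorted(free.items())
        for i, (a, b) in enumerate(ivs) if b - a >= length
    ]
    if not candidates:
        return None
    cid, i = candidates[rng.integers(0, len(candidates))]
    a, b = free[cid][i]
    start = int(rng.integers(a, b - length + 1))
    pieces = []
    if start - a > 0:
        pieces.append((a, start))
    if b - (start + length) > 0:
        pieces.append((start + length, b))
    free[cid][i:i + 1] = pieces
    return cid, start, start + length


class _BaseSampler:
    """Rejection sampler for 5'-end positions with planted base targets."""

    def __init__(self, genome: Sequence[GenomeSequence]):
        self.seqs = {g.contig_id: g.sequence for g in genome}

    def insert(self, contig: str, five_prime: int, strand: str, length: int) -> Optional[str]:
        seq = self.seqs[contig]
        if strand == "+":
            start, end = five_prime, five_prime + length
        else:
            start, end = five_prime - length + 1, five_prime + 1
        if start < 0 or end > len(seq):
            return None
        sub = seq[start:end]
        return sub if strand == "+" else sub.translate(_COMPLEMENT)[::-1]

    def matches(self, insert: str, want_1U: bool, want_10A: bool) -> bool:
        return ((insert[0] == "T") == want_1U) and ((insert[9] == "A") == want_10A)

    def sample(
        self, rng, contig: str, lo: int, hi: int, strand: str, length: int,
        want_1U: bool, want_10A: bool, min_run: int = 8, max_tries: int = 300,
    ) -> Optional[tuple[int, str]]:
        """5' position in [lo, hi) whose insert satisfies the base targets."""
        fallback = None
        for _ in range(max_tries):
            p = int(rng.integers(lo, hi))
            ins = self.insert(contig, p, strand, length)
            if ins is None or "N" in ins or has_homopolymer(ins, min_run):
                continue
            if fallback is None:
                fallback = (p, ins)
            if self.matches(ins, want_1U, want_10A):
                return p, ins
        return fallback


def plant_loci(
    genome: Sequence[GenomeSequence],
    annotations: Sequence[AnnotationRecord],
    params: SimulationParams,
    rng,
    libraries: Sequence[str] = DEFAULT_LIBRARIES,
) -> tuple[list[PlantedCluster], list[Locus]]:
    """Plant clusters and the piRNA locus pool on a built genome."""
    sampler = _BaseSampler(genome)
    free = _free_intervals(genome, annotations)
    lm, ls, llo, lhi = params.pirna_length

    clusters: list[PlantedCluster] = []
    # planted clusters keep > merge-gap separation so each is recoverable
    # as its own locus rather than merging with a neighbour
    min_separation = 22000
    for i in range(params.n_clusters):
        length = int(rng.integers(*params.cluster_length))
        spot = None
        for _ in range(200):
            cand = _carve(free, length + 400, rng)
            if cand is None:
                break
            cid, start, end = cand
            if all(
                cl.contig != cid
                or start >= cl.end + min_separation
                or end <= cl.start - min_separation
                for cl in clusters
            ):
                spot = cand
                break
            free[cid].append((start, end))  # give the rejected spot back
        if spot is None:
            raise _SizingError("no intergenic room left for planted clusters")
        cid, start, end = spot
        start, end = start + 200, end - 200
        profile = dict(DEFAULT_CLUSTER_PROFILES[i % len(DEFAULT_CLUSTER_PROFILES)])
        divergent = i == params.n_clusters - 1 and params.n_clusters > 1
        strandness = (
            "divergent_non_overlapping" if divergent
            else ("plus_only" if rng.random() < 0.5 else "minus_only")
        )
        clusters.append(PlantedCluster(f"planted_{i + 1}", cid, start, end, strandness, profile))

    loci: list[Locus] = []
    serial = 0

    def new_locus(**kw) -> Locus:
        nonlocal serial
        serial += 1
        return Locus(locus_id=f"locus_{serial}", **kw)

    def sample_in(contig, lo, hi, strand, category, sigma, margin=2, **kw) -> Optional[Locus]:
        length = int(_trunc_gauss_int(rng, lm, ls, llo, lhi))
        # 5'-position bounds keeping the insert inside [lo, hi)
        if strand == "+":
            lo5, hi5 = lo + margin, hi - length - margin
        else:
            lo5, hi5 = lo + length - 1 + margin, hi - margin
        if hi5 <= lo5:
            return None
        got = sampler.sample(
            rng, contig, lo5, hi5, strand, length,
            want_1U=rng.random() < params.p_1U, want_10A=rng.random() < params.p_10A,
        )
        if got is None:
            return None
        p, ins = got
        return new_locus(
            contig=contig, five_prime=p, strand=strand, length=length,
            sequence=ins, category=category,
            lam=float(rng.lognormal(0.0, sigma)), **kw,
        )

    frac = params.category_fractions
    n_cluster_loci = params.cluster_loci_per_cluster * max(len(clusters), 1)
    n_plain = int(round(params.n_loci * frac["intergenic"] * (1 - params.cluster_share)))
    n_repeat = int(round(params.n_loci * frac["repeat"]))
    n_gene = int(round(params.n_loci * frac["gene"]))

    # --- cluster loci (strand fixed by the cluster; never paired) ---------
    per_cluster_n = n_cluster_loci // max(len(clusters), 1)
    for cl in clusters:
        for k in range(per_cluster_n):
            if cl.strandness == "divergent_non_overlapping":
                mid = (cl.start + cl.end) // 2
                if k % 2 == 0:
                    lo, hi, strand = cl.start, mid - 200, "-"
                else:
                    lo, hi, strand = mid + 200, cl.end, "+"
            else:
                lo, hi = cl.start, cl.end
                strand = "+" if cl.strandness == "plus_only" else "-"
            loc = sample_in(cl.contig, lo, hi, strand, "intergenic",
                            params.cluster_lognormal_sigma, margin=40,
                            cluster_id=cl.cluster_id)
            if loc is not None:
                loci.append(loc)

    # --- repeat loci (unique families only; strand from class bias) ------
    repeats = [r for r in annotations if r.feature_kind == "repeat"
               and (r.repeat_class, r.repeat_family) != DUPLICATED_FAMILY
               and r.length >= lhi + 90]
    for _ in range(n_repeat):
        rec = repeats[rng.integers(0, len(repeats))]
        sense = rng.random() < REPEAT_SENSE_PROB[rec.repeat_class]
        strand = rec.strand if sense else ("-" if rec.strand == "+" else "+")
        loc = sample_in(rec.contig_id, rec.start, rec.end, strand, "repeat",
                        params.lognormal_sigma,
                        repeat_class=rec.repeat_class, repeat_family=rec.repeat_family,
                        orientation="sense" if sense else "antisense")
        if loc is not None:
            loci.append(loc)

    # --- gene loci (subfeature-weighted; strand from subfeature bias) ----
    parts: dict[str, list[AnnotationRecord]] = {}
    for rec in annotations:
        if rec.feature_kind in GENE_SUBFEATURE_WEIGHTS and rec.length >= lhi + 90:
            parts.setdefault(rec.feature_kind, []).append(rec)
    part_kinds = [k for k in GENE_SUBFEATURE_WEIGHTS if parts.get(k)]
    part_w = np.array([GENE_SUBFEATURE_WEIGHTS[k] for k in part_kinds])
    part_w = part_w / part_w.sum() if len(part_w) else part_w
    for _ in range(n_gene):
        if not part_kinds:
            break
        kind = part_kinds[rng.choice(len(part_kinds), p=part_w)]
        rec = parts[kind][rng.integers(0, len(parts[kind]))]
        sense = rng.random() < GENE_SENSE_PROB[kind]
        strand = rec.strand if sense else ("-" if rec.strand == "+" else "+")
        loc = sample_in(rec.contig_id, rec.start, rec.end, strand, "gene",
                        params.lognormal_sigma, gene_subfeature=kind,
                        orientation="sense" if sense else "antisense")
        if loc is not None:
            loci.append(loc)

    # --- plain intergenic loci -------------------------------------------
    for _ in range(n_plain):
        spot = _carve(free, lhi + 120, rng)
        if spot is None:
            break
        cid, a, b = spot
        loc = sample_in(cid, a, b, "+" if rng.random() < 0.5 else "-",
                        "intergenic", params.lognormal_sigma)
        if loc is not None:
            loci.append(loc)

    # --- multi-mapping loci in the duplicated repeat family --------------
    dup = [r for r in annotations if (r.repeat_class, r.repeat_family) == DUPLICATED_FAMILY]
    for _ in range(params.n_multi_loci if dup else 0):
        rec = dup[rng.integers(0, len(dup))]
        loc = sample_in(rec.contig_id, rec.start, rec.end,
                        rec.strand if rng.random() < REPEAT_SENSE_PROB["LTR"]
                        else ("-" if rec.strand == "+" else "+"),
                        "repeat", params.lognormal_sigma,
                        repeat_class=rec.repeat_class, repeat_family=rec.repeat_family)
        if loc is not None:
            loc.expected_mapping = "multi"
            loci.append(loc)

    # --- ncRNA contamination loci ----------------------------------------
    ncrnas = [r for r in annotations if r.feature_kind in NCRNA_KINDS and r.length >= lhi + 4]
    for _ in range(params.n_ncrna_loci if ncrnas else 0):
        rec = ncrnas[rng.integers(0, len(ncrnas))]
        length = int(_trunc_gauss_int(rng, lm, ls, llo, min(lhi, rec.length - 2)))
        p_lo, p_hi = rec.start, rec.end - length
        strand = "+" if rng.random() < 0.5 else "-"
        p = int(rng.integers(p_lo, p_hi))
        five = p if strand == "+" else p + length - 1
        ins = sampler.insert(rec.contig_id, five, strand, length)
        if ins is None or has_homopolymer(ins, 8):
            continue
        loci.append(new_locus(
            contig=rec.contig_id, five_prime=five, strand=strand, length=length,
            sequence=ins, category="ncRNA", lam=float(rng.lognormal(0.0, 0.6)),
        ))

    # --- pairing flags and differential-expression groups ----------------
    pairable = [l for l in loci if l.cluster_id is None and l.category != "ncRNA"
                and l.expected_mapping == "unique"]
    for loc in pairable:
        loc.paired = bool(rng.random() < params.pairing_fraction)
    assignable = [l for l in pairable]
    rng.shuffle(assignable)
    cursor = 0
    for group, (n, _mult) in DEFAULT_DE_GROUPS.items():
        for loc in assignable[cursor:cursor + n]:
            loc.de_group = group
            loc.lam *= params.de_lam_boost
        cursor += n

    # rescale cluster loci so the planted cluster read share holds exactly
    # in expectation, whatever the other masses came out to be; the few
    # member tags then carry cluster-grade read support individually
    share = frac["intergenic"] * params.cluster_share
    mass_cluster = sum(l.lam for l in loci if l.cluster_id is not None)
    mass_other = sum(l.lam for l in loci
                     if l.cluster_id is None and l.category != "ncRNA")
    if mass_cluster > 0 and share < 1.0:
        scale = (mass_other * share / (1.0 - share)) / mass_cluster
        for l in loci:
            if l.cluster_id is not None:
                l.lam *= scale

    # expected per-library TPM share of each cluster
    weights = {lib: 0.0 for lib in libraries}
    per_cluster = {cl.cluster_id: {lib: 0.0 for lib in libraries} for cl in clusters}
    for loc in loci:
        if loc.category == "ncRNA":
            continue
        for lib in libraries:
            w = loc.lam * _lib_multiplier(loc, lib, clusters)
            weights[lib] += w
            if loc.cluster_id is not None:
                per_cluster[loc.cluster_id][lib] += w
    for cl in clusters:
        cl.expected_tpm_share = {
            lib: (per_cluster[cl.cluster_id][lib] / weights[lib]) if weights[lib] else 0.0
            for lib in libraries
        }
    return clusters, loci


def _lib_multiplier(loc: Locus, lib: str, clusters: Sequence[PlantedCluster]) -> float:
    mult = 1.0
    if loc.cluster_id is not None:
        cl = next(c for c in clusters if c.cluster_id == loc.cluster_id)
        mult *= cl.profile.get(lib, 1.0)
    if loc.de_group is not None:
        mult *= DEFAULT_DE_GROUPS[loc.de_group][1].get(lib, 1.0)
    return mult


def simulate_libraries(
    genome: Sequence[GenomeSequence],
    annotations: Sequence[AnnotationRecord],
    params: Optional[SimulationParams] = None,
    per_library_depth: Optional[Mapping[str, int]] = None,
    seed: int = 0,
    libraries: Sequence[str] = DEFAULT_LIBRARIES,
    out_dir: Optional[str] = None,
) -> tuple[dict[str, list[tuple[str, str]]], SyntheticTruth]:
    """Emit the stage libraries as raw (adapter-carrying) reads plus truth.

    ``per_library_depth`` counts primary emission events per library
    (default 50,000); ping-pong partners are additional reads.  Reads are
    exact genome substrings with the 3' adapter appended and the whole
    read truncated to the machine read length.  With ``out_dir`` set, one
    FASTQ per library and the truth tables are written there.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    if per_library_depth is None:
        per_library_depth = {lib: 50000 for lib in libraries}
    clusters, loci = plant_loci(genome, annotations, params, rng, libraries)
    sampler = _BaseSampler(genome)
    contig_lens = {g.contig_id: g.length for g in genome}
    emit_loci = [l for l in loci if l.category != "ncRNA"]
    nc_loci = [l for l in loci if l.category == "ncRNA"]
    mm, ms, mlo, mhi = params.mirna_length
    pm, ps, plo, phi = params.pirna_length

    reads_per_library: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for lib in libraries:
        depth = int(per_library_depth.get(lib, 0))
        out: list[tuple[str, str]] = []
        reads_per_library[lib] = out
        if depth == 0:
            logger.warning("library %s simulated at depth 0", lib)
            continue
        n_art = rng.binomial(depth, params.artifact_fraction)
        n_nc = rng.binomial(depth - n_art, params.ncrna_fraction) if nc_loci else 0
        w_pi = params.pirna_weight.get(lib, 0.5)
        n_pi = rng.binomial(depth - n_art - n_nc, w_pi)
        n_mi = depth - n_art - n_nc - n_pi
        serial = 0

        def emit(insert: str, **truth):
            nonlocal serial
            serial += 1
            rid = f"rd_{lib}_{serial}"
            raw = (insert + params.adapter)[: params.read_length]
            out.append((rid, raw))
            truth_rows.append({"read_id": rid, "library": lib, **truth})

        # piRNA-like reads from the locus pool
        lam = np.array([l.lam * _lib_multiplier(l, lib, clusters) for l in emit_loci])
        if lam.sum() > 0 and n_pi > 0:
            draws = rng.multinomial(n_pi, lam / lam.sum())
            for loc, n in zip(emit_loci, draws):
                for _ in range(int(n)):
                    emit(loc.sequence, category=loc.category,
                         origin_class=loc.repeat_class or loc.gene_subfeature,
                         repeat_family=loc.repeat_family, orientation=loc.orientation,
                         locus_id=loc.locus_id, cluster_id=loc.cluster_id,
                         is_ping_pong_partner=False, de_group=loc.de_group,
                         expected_mapping=loc.expected_mapping)
                    if not loc.paired:
                        continue
                    is_pp = bool(rng.random() < params.ping_pong_rate)
                    d = 10 if is_pp else int(rng.integers(1, params.max_overlap + 1))
                    p_len = int(_trunc_gauss_int(rng, pm, ps, plo, phi))
                    if loc.strand == "+":
                        q, p_strand = loc.five_prime + d - 1, "-"
                    else:
                        q, p_strand = loc.five_prime - d + 1, "+"
                    ins = sampler.insert(loc.contig, q, p_strand, p_len)
                    if ins is None or has_homopolymer(ins, 8):
                        continue
                    emit(ins, category=loc.category,
                         origin_class=loc.repeat_class or loc.gene_subfeature,
                         repeat_family=loc.repeat_family, orientation="n/a",
                         locus_id=loc.locus_id, cluster_id=loc.cluster_id,
                         is_ping_pong_partner=is_pp, de_group=loc.de_group,
                         expected_mapping=loc.expected_mapping)

        # ncRNA fragments (mapped, then excluded by annotation overlap)
        if nc_loci and n_nc:
            lam_nc = np.array([l.lam for l in nc_loci])
            for loc, n in zip(nc_loci, rng.multinomial(n_nc, lam_nc / lam_nc.sum())):
                for _ in range(int(n)):
                    emit(loc.sequence, category="ncRNA", origin_class=None,
                         repeat_family=None, orientation="n/a", locus_id=loc.locus_id,
                         cluster_id=None, is_ping_pong_partner=False, de_group=None,
                         expected_mapping="unique")

        # miRNA-sized contaminants at random genomic spots
        contigs = sorted(contig_lens)
        for _ in range(int(n_mi)):
            length = int(_trunc_gauss_int(rng, mm, ms, mlo, mhi))
            cid = contigs[rng.integers(0, len(contigs))]
            strand = "+" if rng.random() < 0.5 else "-"
            p = int(rng.integers(length + 1, contig_lens[cid] - length - 1))
            ins = sampler.insert(cid, p, strand, length)
            if ins is None:
                continue
            emit(ins, category="mirna_like", origin_class=None, repeat_family=None,
                 orientation="n/a", locus_id=None, cluster_id=None,
                 is_ping_pong_partner=False, de_group=None, expected_mapping="n/a")

        # homopolymer artifacts (genome-free)
        for _ in range(int(n_art)):
            length = int(_trunc_gauss_int(rng, pm, ps, plo, phi))
            ins = list(_random_dna(rng, length))
            base = "ACGT"[rng.integers(0, 4)]
            pos = int(rng.integers(0, length - 8 + 1))
            ins[pos:pos + 8] = base * 8
            emit("".join(ins), category="artifact", origin_class=None,
                 repeat_family=None, orientation="n/a", locus_id=None,
                 cluster_id=None, is_ping_pong_partner=False, de_group=None,
                 expected_mapping="n/a")

    truth = SyntheticTruth(
        params=params,
        planted_clusters=clusters,
        loci=loci,
        reads=pd.DataFrame(truth_rows),
        library_names=tuple(libraries),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for lib, reads in reads_per_library.items():
            write_fastq(reads, out_dir / f"{lib}.fastq")
        emit_truth(truth, out_dir)
    return reads_per_library, truth


def emit_truth(truth: SyntheticTruth, out_dir) -> None:
    """Write the planted-structure tables: clusters BED, loci and reads TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "truth_clusters.bed", "w") as fh:
        for cl in truth.planted_clusters:
            strand = {"plus_only": "+", "minus_only": "-"}.get(cl.strandness, ".")
            fh.write(f"{cl.contig}\t{cl.start}\t{cl.end}\t{cl.cluster_id}\t0\t{strand}\n")
    loci_rows = []
    for l in truth.loci:
        loci_rows.append({
            "locus_id": l.locus_id, "contig": l.contig, "start": l.start, "end": l.end,
            "strand": l.strand, "length": l.length, "sequence": l.sequence,
            "category": l.category, "repeat_class": l.repeat_class,
            "repeat_family": l.repeat_family, "gene_subfeature": l.gene_subfeature,
            "orientation": l.orientation, "cluster_id": l.cluster_id,
            "paired": l.paired, "de_group": l.de_group,
            "expected_mapping": l.expected_mapping, "lam": l.lam,
        })
    pd.DataFrame(loci_rows).to_csv(out_dir / "truth_loci.tsv", sep="\t", index=False)
    truth.reads.to_csv(out_dir / "truth_reads.tsv", sep="\t", index=False)
    shares = pd.DataFrame(
        [{"cluster_id": cl.cluster_id, **cl.expected_tpm_share}
         for cl in truth.planted_clusters]
    )
    shares.to_csv(out_dir / "truth_cluster_shares.tsv", sep="\t", index=False)


def load_truth_clusters(path) -> list[tuple[str, int, int, str]]:
    """Read a truth BED back into (contig, start, end, cluster_id) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3]))
    return out


# ---------------------------------------------------------------------------
# focused simulations for single statistics
# ---------------------------------------------------------------------------

def sample_pool_libraries(
    pool_size: int,
    per_library_distinct: int,
    libraries: Sequence[str],
    seed: int = 0,
    length: int = 26,
    sequences: Optional[list[str]] = None,
) -> list[UniqueTag]:
    """Capture-recapture fixture: libraries sample a pool of distinct tags.

    Builds ``pool_size`` distinct synthetic sequences (or reuses a
    pre-built ``sequences`` pool across replicates) and gives each library
    a uniform without-replacement sample of ``per_library_distinct`` of
    them (count 1 each).
    """
    if per_library_distinct > pool_size:
        raise ValueError("sample cannot exceed the pool")
    rng = np.random.default_rng(seed)
    if sequences is None:
        letters = np.array(list("ACGT"))
        seen: set[str] = set()
        sequences = []
        while len(sequences) < pool_size:
            block = letters[rng.integers(0, 4, (pool_size - len(sequences), length))]
            for row in block:
                s = "".join(row)
                if s not in seen:
                    seen.add(s)
                    sequences.append(s)
    tags = [UniqueTag(s) for s in sequences[:pool_size]]
    for lib in libraries:
        for i in rng.choice(pool_size, size=per_library_distinct, replace=False):
            tags[int(i)].counts[lib] += 1
    return [t for t in tags if t.total_count > 0]


def simulate_de_counts(
    n_tags: int,
    mean_count: float = 25.0,
    fold: float = 1.0,
    frac_up: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-library Poisson tag counts with an optional planted fold change.

    A ``frac_up`` fraction of tags has its library-A mean multiplied by
    ``fold``; everything else is null.  Returns the counts table (columns
    A, B) and the boolean truth vector of planted tags.
    """
    rng = np.random.default_rng(seed)
    is_up = np.zeros(n_tags, dtype=bool)
    n_up = int(round(n_tags * frac_up))
    is_up[:n_up] = True
    mu_a = np.where(is_up, mean_count * fold, mean_count)
    counts = pd.DataFrame(
        {
            "A": rng.poisson(mu_a),
            "B": rng.poisson(np.full(n_tags, mean_count)),
        },
        index=[f"tag_{i}" for i in range(n_tags)],
    )
    return counts, is_up


def simulate_profile_groups(
    n_per_group: int,
    libraries: Sequence[str] = DEFAULT_LIBRARIES,
    patterns: Optional[Sequence[Mapping[str, float]]] = None,
    base_tpm: float = 50.0,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Expression profiles with planted groups for clustering tests.

    Each group follows a library-multiplier pattern; rows get multiplicative
    lognormal noise.  Returns (TPM matrix, group labels).
    """
    if patterns is None:
        patterns = (
            {"embryo": 8.0},
            {"larva": 8.0, "pupa": 8.0},
            {"adult_male": 8.0, "sugarfed_female": 8.0, "bloodfed_female": 8.0},
        )
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for g, pattern in enumerate(patterns):
        for i in range(n_per_group):
            mult = np.array([pattern.get(lib, 1.0) for lib in libraries])
            noise = rng.lognormal(0.0, noise_sd, size=len(libraries))
            rows.append(base_tpm * mult * noise)
            labels.append(g)
    matrix = pd.DataFrame(
        rows, columns=list(libraries),
        index=[f"profile_{i}" for i in range(len(rows))],
    )
    return matrix, np.array(labels)


def simulate_base_bias_reads(
    genome: Sequence[GenomeSequence],
    n_reads: int,
    p_1U: float = 0.76,
    p_10A: float = 0.41,
    seed: int = 0,
    adapter: str = SimulationParams.adapter,
    read_length: int = 36,
) -> list[str]:
    """i.i.d. per-read planting of the 1U/10A base biases.

    Every read independently draws its own Bernoulli(p_1U) and
    Bernoulli(p_10A) targets and a fresh genomic position satisfying them,
    so the observed fractions are genuinely binomial in the read count.
    Reads are piRNA-sized, adapter-carrying, and unpaired (no opposite-
    strand partners), the condition under which the marginal biases are
    identifiable.
    """
    rng = np.random.default_rng(seed)
    sampler = _BaseSampler(genome)
    contigs = sorted(sampler.seqs)
    lens = {c: len(sampler.seqs[c]) for c in contigs}
    out = []
    while len(out) < n_reads:
        length = int(_trunc_gauss_int(rng, 27.0, 1.0, 24, 30))
        cid = contigs[rng.integers(0, len(contigs))]
        strand = "+" if rng.random() < 0.5 else "-"
        lo, hi = length + 1, lens[cid] - length - 1
        got = sampler.sample(
            rng, cid, lo, hi, strand, length,
            want_1U=rng.random() < p_1U, want_10A=rng.random() < p_10A,
        )
        if got is None:
            continue
        out.append((got[1] + adapter)[:read_length])
    return out


def _free_blocks(
    genome: Sequence[GenomeSequence],
    annotations: Sequence[AnnotationRecord],
    block: int,
    rng,
) -> list[tuple[str, int, int]]:
    """Chop the intergenic free space into shuffled fixed-size blocks."""
    free = _free_intervals(genome, annotations)
    blocks = []
    for cid in sorted(free):
        for a, b in free[cid]:
            for s in range(a, b - block + 1, block):
                blocks.append((cid, s, s + block))
    rng.shuffle(blocks)
    return blocks


def simulate_ping_pong_reads(
    genome: Sequence[GenomeSequence],
    annotations: Sequence[AnnotationRecord],
    n_events: int,
    ping_pong_rate: float,
    p_1U: float = 0.76,
    p_10A: float = 0.41,
    seed: int = 0,
    adapter: str = SimulationParams.adapter,
    read_length: int = 36,
    max_overlap: int = 30,
    block: int = 160,
) -> list[str]:
    """Planted opposite-strand pair events with controlled 5'-overlaps.

    Each event occupies its own intergenic block (blocks are wider than
    twice the maximum overlap, so events can never overlap each other and
    the profile carries only the planted signal) and emits a primary read
    plus an opposite-strand partner whose 5'-5' overlap is exactly 10 nt
    with probability ``ping_pong_rate`` and uniform on 1..max_overlap
    otherwise.  At rate 0 the overlap histogram is flat by construction.
    """
    rng = np.random.default_rng(seed)
    sampler = _BaseSampler(genome)
    blocks = _free_blocks(genome, annotations, block, rng)
    if n_events > len(blocks):
        raise _SizingError(
            f"{n_events} events need more intergenic blocks than the genome holds"
        )
    out = []
    for cid, lo, hi in blocks[:n_events]:
        length = int(_trunc_gauss_int(rng, 27.0, 1.0, 24, 30))
        strand = "+" if rng.random() < 0.5 else "-"
        margin = max_overlap + 31
        if strand == "+":
            lo5, hi5 = lo + margin, hi - margin
        else:
            lo5, hi5 = lo + margin, hi - margin
        got = sampler.sample(
            rng, cid, lo5, hi5, strand, length,
            want_1U=rng.random() < p_1U, want_10A=rng.random() < p_10A,
        )
        if got is None:
            continue
        p, ins = got
        d = 10 if rng.random() < ping_pong_rate else int(rng.integers(1, max_overlap + 1))
        p_len = int(_trunc_gauss_int(rng, 27.0, 1.0, 24, 30))
        if strand == "+":
            q, p_strand = p + d - 1, "-"
        else:
            q, p_strand = p - d + 1, "+"
        partner = sampler.insert(cid, q, p_strand, p_len)
        if partner is None or has_homopolymer(partner, 8):
            continue
        out.append((ins + adapter)[:read_length])
        out.append((partner + adapter)[:read_length])
    return out


def simulate_cluster_placements(
    genome: Sequence[GenomeSequence],
    n_clusters: int = 5,
    tags_per_cluster: int = 20,
    reads_per_tag: int = 250,
    cluster_span: int = 6000,
    n_background: int = 50,
    background_reads: int = 150,
    seed: int = 0,
    libraries: Sequence[str] = DEFAULT_LIBRARIES,
) -> tuple[list, dict, dict, list]:
    """Placement-level cluster fixture for the window caller.

    Plants ``n_clusters`` loci of evenly spread distinct tags (each with
    ``reads_per_tag`` supporting reads split over the libraries) separated
    by more than the merge gap, plus a sparse uniform background whose
    default read support sits below the per-tag prefilter (isolated
    piRNAs rarely reach cluster-grade support).  Returns
    (placement stream, counts_by_sequence, library_totals, truth spans),
    where each truth span is the (contig, start, end) extent of one
    planted cluster's placements.
    """
    rng = np.random.default_rng(seed)
    contigs = [(g.contig_id, g.length) for g in genome]
    stream, counts, truth = [], {}, []
    serial = 0

    def add(contig, start, length, strand, reads):
        nonlocal serial
        serial += 1
        seq_id = f"ctag_{serial}"
        stream.append((contig, start, start + length, strand, seq_id))
        per_lib = rng.multinomial(reads, np.full(len(libraries), 1 / len(libraries)))
        counts[seq_id] = {lib: int(n) for lib, n in zip(libraries, per_lib)}
        return start, start + length

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in contigs}
    for _ in range(n_clusters):
        for _try in range(500):
            cid, clen = contigs[rng.integers(0, len(contigs))]
            start = int(rng.integers(1000, clen - cluster_span - 1000))
            if all(start >= e + 25000 or start + cluster_span <= s - 25000
                   for s, e in placed[cid]):
                break
        else:
            raise _SizingError("cannot separate planted clusters by the merge gap")
        placed[cid].append((start, start + cluster_span))
        strand = "+" if rng.random() < 0.5 else "-"
        spots = np.sort(rng.choice(cluster_span - 30, size=tags_per_cluster, replace=False))
        ext = []
        for s in spots:
            ext.append(add(cid, start + int(s), int(rng.integers(24, 31)), strand,
                           reads_per_tag))
        truth.append((cid, min(a for a, _ in ext), max(b for _, b in ext)))
    for _ in range(n_background):
        cid, clen = contigs[rng.integers(0, len(contigs))]
        add(cid, int(rng.integers(0, clen - 30)), int(rng.integers(24, 31)),
            "+" if rng.random() < 0.5 else "-", background_reads)
    stream.sort(key=lambda e: (e[0], e[1], e[2], e[3]))
    totals = {lib: sum(c.get(lib, 0) for c in counts.values()) for lib in libraries}
    return stream, counts, totals, truth
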