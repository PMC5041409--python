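"""Run configuration.

Every analysis threshold is a named parameter with the study's value as the
default, so a whole run is declared by one config file and any threshold can
be perturbed for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: canonical stage labels of the six developmental libraries
DEFAULT_LIBRARIES = (
    "embryo",
    "larva",
    "pupa",
    "adult_male",
    "sugarfed_female",
    "bloodfed_female",
)


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline.

    Defaults are the analysis constants of the study design: piRNA-sized
    tags are 24-30 nt, reads shorter than 18 nt are dropped outright,
    tags containing a homopolymer run of >= 8 nt are artifacts, clusters
    are called in 5-kb windows holding >= 10 distinct piRNA sequences,
    qualifying windows < 20 kb apart merge into one locus, cluster calling
    uses tags with >= 200 supporting reads across libraries, and
    differential expression calls require p <= 0.05 and |log2 ratio| >= 1.
    """

    library_names: tuple[str, ...] = DEFAULT_LIBRARIES
    piRNA_length_min: int = 24
    piRNA_length_max: int = 30
    read_length_keep_min: int = 18
    homopolymer_min_run: int = 8
    adapter: str = "TCGTATGCCGTCTTCTGCTTGT"
    adapter_min_overlap: int = 6
    cluster_window: int = 5000
    cluster_min_sequences: int = 10
    cluster_merge_gap: int = 20000
    cluster_min_support_reads: int = 200
    de_alpha: float = 0.05
    de_min_log2_ratio: float = 1.0
    top_n_per_stage: int = 100
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if self.piRNA_length_min > self.piRNA_length_max:
            raise ValueError("piRNA_length_min must be <= piRNA_length_max")
        for name in (
            "piRNA_length_min",
            "piRNA_length_max",
            "read_length_keep_min",
            "homopolymer_min_run",
            "adapter_min_overlap",
            "cluster_window",
            "cluster_min_sequences",
            "cluster_merge_gap",
            "cluster_min_support_reads",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.de_alpha < 1:
            raise ValueError("de_alpha must lie in (0, 1)")
        if self.de_min_log2_ratio < 0:
            raise ValueError("de_min_log2_ratio must be non-negative")
        self.library_names = tuple(self.library_names)
        if len(set(self.library_names)) != len(self.library_names):
            raise ValueError("library names must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["library_names"] = list(self.library_names)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
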