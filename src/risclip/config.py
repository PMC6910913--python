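"""Pipeline configuration: every fixed constant of the processing pipeline in one place."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

#: 3' sequencing adapter and its one-base-shorter variant, both trimmed.
DEFAULT_ADAPTER = "GTGTCAGTCACTTCCAG"
DEFAULT_ADAPTER_ALT = "TGTCAGTCACTTCCAG"


@dataclass
class PipelineConfig:
    """Parameters of the HITS-CLIP processing pipeline.

    Attributes
    ----------
    adapter, adapter_alt:
        3' adapter sequences removed from reads. Full internal occurrences
        take precedence; otherwise a read suffix matching an adapter prefix
        of at least ``min_partial_overlap`` nt is removed.
    min_length:
        Minimum post-trim read length kept (nt).
    bin_size:
        Width of the footprint bins that cluster alignment 5'-starts (nt).
    bin_anchor:
        ``"downstream"`` opens the bin at the heaviest start position,
        [p, p+bin_size); ``"centered"`` places it around it,
        [p-4, p+6) for the default 10-nt bin.
    mature_len_range:
        Inclusive length range (nt) a dangling end must have to count as a
        candidate mature miRNA.
    min_partial_overlap:
        Minimum read-suffix/adapter-prefix overlap for partial trimming (nt).
    max_mismatches:
        Maximum Hamming mismatches tolerated in any alignment (0-2).
    multimap_policy:
        ``"count_all"`` gives each reported alignment weight 1;
        ``"fractional"`` gives each alignment weight 1/n_hits.
    overlap_min:
        Minimum overlap (nt) between a hairpin alignment and an annotated
        mature site for the read to be attributed to that mature miRNA.
    seed:
        Seed for any randomized step.
    """

    adapter: str = DEFAULT_ADAPTER
    adapter_alt: str = DEFAULT_ADAPTER_ALT
    min_length: int = 16
    bin_size: int = 10
    bin_anchor: str = "downstream"
    mature_len_range: Tuple[int, int] = (18, 25)
    min_partial_overlap: int = 6
    max_mismatches: int = 0
    multimap_policy: str = "count_all"
    overlap_min: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.mature_len_range[0] > self.mature_len_range[1]:
            raise ValueError("mature_len_range must be (lo, hi) with lo <= hi")
        if self.multimap_policy not in ("count_all", "fractional"):
            raise ValueError(f"unknown multimap_policy {self.multimap_policy!r}")
        if self.bin_anchor not in ("downstream", "centered"):
            raise ValueError(f"unknown bin_anchor {self.bin_anchor!r}")
        if not 0 <= self.max_mismatches <= 2:
            raise ValueError("max_mismatches must be in 0..2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "mature_len_range" in d:
            d["mature_len_range"] = tuple(d["mature_len_range"])
        return cls(**d)
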