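"""RISC footprint calling by greedy clustering of weighted alignment 5'-starts.

Each transcript position is weighted by the number of alignments starting
there (optionally 1/n_hits for multi-mapped reads). Positions are then
clustered from heavy to light: the heaviest remaining position opens a
fixed-width bin (10 nt by default) that absorbs every remaining start
inside it; the procedure repeats until no starts remain. The emitted bins
are the 5'-ends of the RISC footprints.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, NamedTuple, Optional, Tuple

from .config import PipelineConfig
from .formats import Alignment


@dataclass
class StartProfile:
    """Per-transcript map from 0-based position to alignment 5'-start weight."""

    transcript_id: str
    counts: Dict[int, float]


@dataclass(frozen=True)
class Footprint:
    """A called RISC occupancy bin on a transcript.

    ``weight`` sums the start-position weights absorbed into the bin;
    ``seed_position`` is the heaviest position that anchored it.
    """

    footprint_id: str
    transcript_id: str
    bin: Tuple[int, int]
    weight: float
    seed_position: int


def build_start_profile(
    alignments: Iterable[Alignment], cfg: PipelineConfig
) -> List[StartProfile]:
    """Tally alignment 5'-start positions per transcript.

    Under ``count_all`` each alignment contributes weight 1; under
    ``fractional`` it contributes 1/n_hits, so each read contributes total
    weight 1 across all its placements. Profiles are returned sorted by
    transcript id; only transcripts with at least one alignment appear.
    """
    fractional = cfg.multimap_policy == "fractional"
    profiles: Dict[str, Dict[int, float]] = {}
    for aln in alignments:
        weight = 1.0 / aln.n_hits if fractional else 1.0
        counts = profiles.setdefault(aln.reference_id, {})
        counts[aln.start] = counts.get(aln.start, 0.0) + weight
    return [
        StartProfile(transcript_id=tx, counts=profiles[tx]) for tx in sorted(profiles)
    ]


def _bin_interval(seed: int, cfg: PipelineConfig, ref_length: Optional[int]) -> Tuple[int, int]:
    if cfg.bin_anchor == "downstream":
        lo, hi = seed, seed + cfg.bin_size
    else:  # centered: e.g. [p-4, p+6) for bin_size 10
        half = (cfg.bin_size - 1) // 2
        lo, hi = seed - half, seed - half + cfg.bin_size
    lo = max(lo, 0)
    if ref_length is not None:
        hi = min(hi, ref_length)
    return lo, hi


def call_footprints(
    profile: StartProfile, cfg: PipelineConfig, ref_length: Optional[int] = None
) -> List[Footprint]:
    """Greedily cluster a start profile into disjoint footprint bins.

    Repeat until no positions remain: pick the heaviest remaining position
    (ties broken toward the smallest coordinate), open its bin, absorb and
    remove every remaining position inside the bin, and emit a footprint
    whose weight is the absorbed sum. Every input position is absorbed by
    exactly one footprint; footprints are returned sorted by bin start
    with ids ``fp_1, fp_2, ...`` in that order. The result is independent
    of the ``counts`` dict iteration order.
    """
    positions = sorted(profile.counts)
    # heavy-to-light, ties to the left; explicit sort makes the order total
    order = sorted(positions, key=lambda p: (-profile.counts[p], p))
    remaining = set(positions)
    called: List[Tuple[Tuple[int, int], float, int]] = []
    for seed in order:
        if seed not in remaining:
            continue
        lo, hi = _bin_interval(seed, cfg, ref_length)
        weight = 0.0
        for idx in range(bisect_left(positions, lo), bisect_right(positions, hi - 1)):
            pos = positions[idx]
            if pos in remaining:
                weight += profile.counts[pos]
                remaining.discard(pos)
        called.append(((lo, hi), weight, seed))
    called.sort(key=lambda item: item[0][0])
    return [
        Footprint(
            footprint_id=f"fp_{i + 1}",
            transcript_id=profile.transcript_id,
            bin=interval,
            weight=weight,
            seed_position=seed,
        )
        for i, (interval, weight, seed) in enumerate(called)
    ]


class FootprintSummary(NamedTuple):
    n_footprints: int
    n_transcripts: int
    weight_histogram: Counter


def summarize_footprints(footprints: Iterable[Footprint]) -> FootprintSummary:
    """Count footprints, transcripts carrying them, and the footprint weight histogram."""
    footprints = list(footprints)
    histogram = Counter(fp.weight for fp in footprints)
    return FootprintSummary(
        n_footprints=len(footprints),
        n_transcripts=len({fp.transcript_id for fp in footprints}),
        weight_histogram=histogram,
    )
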