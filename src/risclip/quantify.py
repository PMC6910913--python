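"""miRNA occupancy counting, small-RNA count lists, chimera resolution, target ranking.

Occupancy in the RISC is measured by counting hairpin-aligned reads that
overlap an annotated mature-miRNA interval by at least ``overlap_min`` nt.
Chimeric (dangling-end) reads are resolved into miRNA-target pairs by
matching the dangling sequence, when its length is consistent with a
mature miRNA, against the hairpins and attributing it by the same overlap
rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .align import DanglingAlignment, ReferenceIndex
from .config import PipelineConfig
from .formats import Alignment, HairpinAnnotation, Read, TranscriptAnnotation
from .footprints import Footprint

logger = logging.getLogger(__name__)

UNASSIGNED = "_unassigned"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNACount:
    mature_id: str
    count: float
    rank: int


@dataclass(frozen=True)
class ChimeraCall:
    """A resolved miRNA-target interaction from one dangling-end read."""

    read_id: str
    mature_id: str
    transcript_id: str
    target_start: int


def _attribute_to_mature(
    interval: Tuple[int, int], annotation: HairpinAnnotation, overlap_min: int
) -> Optional[str]:
    """Mature id whose annotated site overlaps the interval best (>= overlap_min nt).

    Ties between two mature sites of one hairpin go to the 5'-most site.
    """
    lo, hi = interval
    best: Optional[str] = None
    best_key: Tuple[int, int] = (0, 0)
    for mature_id, (s, e) in annotation.mature_sites:
        overlap = min(hi, e) - max(lo, s)
        if overlap >= overlap_min:
            key = (overlap, -s)  # larger overlap wins; tie -> 5' site
            if best is None or key > best_key:
                best, best_key = mature_id, key
    return best


def count_mirna_occupancy(
    hairpin_alignments: Iterable[Alignment],
    hairpins: Sequence[HairpinAnnotation],
    cfg: PipelineConfig,
) -> List[MiRNACount]:
    """Count hairpin-aligned reads per annotated mature miRNA, ranked by abundance.

    A read is attributed to the mature site it overlaps by at least
    ``cfg.overlap_min`` nt (largest overlap wins within a hairpin, tie to
    the 5' site); reads overlapping no site (e.g. loop reads) are not
    counted. Counts follow the multimap policy (1 per alignment, or
    1/n_hits). Ranks are 1..K by descending count, ties ordered by
    mature id.
    """
    by_id = {ann.hairpin_id: ann for ann in hairpins}
    fractional = cfg.multimap_policy == "fractional"
    counts: Dict[str, float] = {}
    for aln in hairpin_alignments:
        if aln.reference_id not in by_id:
            raise ValueError(f"alignment to unknown hairpin {aln.reference_id!r}")
        mature = _attribute_to_mature(aln.interval, by_id[aln.reference_id], cfg.overlap_min)
        if mature is None:
            continue
        counts[mature] = counts.get(mature, 0.0) + (1.0 / aln.n_hits if fractional else 1.0)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        MiRNACount(mature_id=mature_id, count=count, rank=rank)
        for rank, (mature_id, count) in enumerate(ordered, start=1)
    ]


def build_smallrna_count_list(
    reads: Iterable[Read], mature_fasta: Dict[str, str], cfg: PipelineConfig
) -> pd.DataFrame:
    """Count trimmed, filtered small-RNA reads against mature miRNA sequences.

    A read is counted for a mature miRNA when its full sequence matches
    within that sequence (at most ``max_mismatches`` mismatches).
    Reads matching several matures follow the multimap policy. Returns a
    DataFrame with columns ``mature_id``, ``count``, sorted by count
    descending (ties by id); reads matching nothing are pooled under the
    ``_unassigned`` id.
    """
    index = ReferenceIndex(mature_fasta, k=min(12, cfg.min_length))
    fractional = cfg.multimap_policy == "fractional"
    counts: Dict[str, float] = {mature_id: 0.0 for mature_id in mature_fasta}
    unassigned = 0.0
    for read in reads:
        hits = index.find_full(read.sequence, cfg.max_mismatches)
        matched = sorted({ref_id for ref_id, _pos, _mm in hits})
        if not matched:
            unassigned += 1.0
            continue
        weight = 1.0 / len(matched) if fractional else 1.0
        for mature_id in matched:
            counts[mature_id] += weight
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rows.append((UNASSIGNED, unassigned))
    return pd.DataFrame(rows, columns=["mature_id", "count"])


def resolve_chimeras(
    dangling: Iterable[DanglingAlignment],
    hairpin_fasta: Dict[str, str],
    hairpins: Sequence[HairpinAnnotation],
    cfg: PipelineConfig,
) -> List[ChimeraCall]:
    """Resolve dangling-end alignments into miRNA-target interaction calls.

    A dangling end is a candidate mature miRNA when its length falls in
    ``cfg.mature_len_range``; it is then matched in full against the
    hairpin sequences and attributed to a mature site by the occupancy
    overlap rule. Records whose dangling end matches no mature site, or
    matches more than one mature id without a unique best, are dropped
    (counts logged). The mRNA side keeps the transcript placement of the
    aligned segment.
    """
    by_id = {ann.hairpin_id: ann for ann in hairpins}
    index = ReferenceIndex(hairpin_fasta, k=min(12, cfg.mature_len_range[0]))
    lo, hi = cfg.mature_len_range
    calls: List[ChimeraCall] = []
    n_bad_length = n_unmatched = n_ambiguous = 0
    for d in dangling:
        if not (lo <= len(d.dangling_seq) <= hi):
            n_bad_length += 1
            continue
        matures = set()
        for ref_id, pos, _mm in index.find_full(d.dangling_seq, cfg.max_mismatches):
            ann = by_id.get(ref_id)
            if ann is None:
                continue
            mature = _attribute_to_mature(
                (pos, pos + len(d.dangling_seq)), ann, cfg.overlap_min
            )
            if mature is not None:
                matures.add(mature)
        if not matures:
            n_unmatched += 1
            continue
        if len(matures) > 1:
            n_ambiguous += 1
            continue
        calls.append(
            ChimeraCall(
                read_id=d.read_id,
                mature_id=matures.pop(),
                transcript_id=d.reference_id,
                target_start=d.start,
            )
        )
    if n_bad_length or n_unmatched or n_ambiguous:
        logger.info(
            "resolve_chimeras: dropped %d (length), %d (unmatched), %d (ambiguous)",
            n_bad_length,
            n_unmatched,
            n_ambiguous,
        )
    return calls


def top_targets(
    footprints: Iterable[Footprint],
    annotations: Sequence[TranscriptAnnotation],
    n: int,
) -> pd.DataFrame:
    """Rank transcripts by total footprint weight; return the top ``n``.

    Ties are broken by footprint count (more first), then transcript id.
    Columns: ``transcript_id``, ``total_weight``, ``n_footprints``, ``rank``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    totals: Dict[str, Tuple[float, int]] = {}
    for fp in footprints:
        weight, count = totals.get(fp.transcript_id, (0.0, 0))
        totals[fp.transcript_id] = (weight + fp.weight, count + 1)
    rows = sorted(totals.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))[:n]
    return pd.DataFrame(
        [
            {"transcript_id": tx, "total_weight": w, "n_footprints": c, "rank": i + 1}
            for i, (tx, (w, c)) in enumerate(rows)
        ],
        columns=["transcript_id", "total_weight", "n_footprints", "rank"],
    )


def seed_match_scan(
    footprint: Footprint,
    transcript_seq: str,
    mature_seq: str,
    flank: int = 0,
) -> List[Tuple[int, str]]:
    """Scan a footprint (plus flank) for canonical miRNA seed-match sites.

    Sites are matches on the transcript to the reverse complement of the
    miRNA seed (mature positions 2-7/2-8): 6mer (positions 2-7), 7mer-m8
    (2-8), 7mer-A1 (2-7 followed by an A opposite position 1) and 8mer
    (2-8 plus the A). Returns (site start on transcript, site type),
    strongest type per core match, sorted by position.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if len(mature_seq) < 8:
        raise ValueError("mature sequence shorter than 8 nt has no full seed")
    core = reverse_complement(mature_seq[1:7])  # 6 nt, opposite positions 2-7
    m8_base = reverse_complement(mature_seq[7])  # opposite position 8, 5' of the core
    lo = max(0, footprint.bin[0] - flank)
    hi = min(len(transcript_seq), footprint.bin[1] + flank)
    hits: List[Tuple[int, str]] = []
    search = transcript_seq
    pos = search.find(core, lo)
    while pos != -1 and pos + len(core) <= hi:
        has_m8 = pos > 0 and search[pos - 1] == m8_base
        has_a1 = pos + len(core) < len(search) and search[pos + len(core)] == "A"
        if has_m8 and has_a1:
            hits.append((pos - 1, "8mer"))
        elif has_m8:
            hits.append((pos - 1, "7mer-m8"))
        elif has_a1:
            hits.append((pos, "7mer-A1"))
        else:
            hits.append((pos, "6mer"))
        pos = search.find(core, pos + 1)
    return hits
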