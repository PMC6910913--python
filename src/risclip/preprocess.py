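"""Adapter trimming, length filtering and contaminant removal.

The 3' adapter (or its one-base-shorter variant) is removed wherever it
occurs in full; failing that, the longest read suffix equal to an adapter
prefix of at least ``min_partial_overlap`` nt is removed. Reads shorter
than ``min_length`` after trimming are discarded. Contaminant filtering
removes reads that align in full to any sequence of a contaminant set
(rRNA/tRNA/snRNA/snoRNA-style references).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

from .config import PipelineConfig
from .formats import Read


@dataclass(frozen=True)
class TrimmedRead:
    """A read after 3' adapter removal.

    ``adapter_found`` is ``"full"`` when a complete adapter occurred in the
    read, ``"partial"`` when only a suffix/prefix overlap was removed, and
    ``"none"`` when the read is unchanged.
    """

    read: Read
    adapter_found: str
    trimmed_bases: int


@dataclass
class FilterReport:
    n_input: int = 0
    n_trimmed_kept: int = 0
    n_too_short: int = 0
    n_contaminant: int = 0


def _best_cut(sequence: str, adapter: str, min_partial_overlap: int) -> Tuple[int, str]:
    """Return (post-trim length, kind) for one adapter; kind in {full, partial, none}."""
    idx = sequence.find(adapter)
    if idx != -1:
        return idx, "full"
    # longest suffix of the read equal to a proper prefix of the adapter
    max_overlap = min(len(sequence), len(adapter) - 1)
    for overlap in range(max_overlap, min_partial_overlap - 1, -1):
        if sequence.endswith(adapter[:overlap]):
            return len(sequence) - overlap, "partial"
    return len(sequence), "none"


def trim_adapter(read: Read, cfg: PipelineConfig) -> TrimmedRead:
    """Remove the 3' adapter from a read.

    A full occurrence of either adapter variant truncates the read at its
    leftmost occurrence and takes precedence over any partial match. When
    both variants match, the one removing more bases wins; on an exact tie
    the first-listed adapter is used. Trimming to length 0 is legal; the
    length filter discards such reads.
    """
    adapters = (cfg.adapter, cfg.adapter_alt)
    candidates = [
        _best_cut(read.sequence, adapter, cfg.min_partial_overlap) for adapter in adapters
    ]
    # full occurrences beat partial ones regardless of bases removed
    fulls = [(cut, kind) for cut, kind in candidates if kind == "full"]
    pool = fulls if fulls else candidates
    cut, kind = min(pool, key=lambda ck: ck[0])  # most bases removed; tie -> first adapter
    if kind == "none":
        return TrimmedRead(read=read, adapter_found="none", trimmed_bases=0)
    trimmed = Read(
        id=read.id,
        sequence=read.sequence[:cut],
        quality=read.quality[:cut] if read.quality is not None else None,
    )
    return TrimmedRead(read=trimmed, adapter_found=kind, trimmed_bases=len(read.sequence) - cut)


def length_filter(
    trimmed: Iterable[TrimmedRead], cfg: PipelineConfig
) -> Tuple[List[TrimmedRead], FilterReport]:
    """Keep trimmed reads of length >= ``min_length``; count the rest.

    The report conserves the input: n_input = n_trimmed_kept + n_too_short.
    """
    kept: List[TrimmedRead] = []
    report = FilterReport()
    for record in trimmed:
        report.n_input += 1
        if len(record.read.sequence) >= cfg.min_length:
            kept.append(record)
            report.n_trimmed_kept += 1
        else:
            report.n_too_short += 1
    return kept, report


def filter_contaminants(
    reads: Iterable[Read], contaminants: Dict[str, str], cfg: PipelineConfig
) -> Tuple[List[Read], List[Read]]:
    """Partition reads into (clean, removed) against a contaminant sequence set.

    A read is removed iff its full sequence aligns to any contaminant with
    at most ``max_mismatches`` mismatches (same contract as the aligner).
    """
    from .align import ReferenceIndex

    if not contaminants:
        raise ValueError("contaminant set is empty")
    index = ReferenceIndex(contaminants)
    clean: List[Read] = []
    removed: List[Read] = []
    for read in reads:
        if index.find_full(read.sequence, cfg.max_mismatches):
            removed.append(read)
        else:
            clean.append(read)
    return clean, removed
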