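"""Desk-scale alignment: full-read multi-hit and dangling-end (anchored) matching.

The internal aligner is an exact contract, not a heuristic: for a read it
reports *all* ungapped + strand placements on the reference set with at
most ``max_mismatches`` Hamming mismatches, via a k-mer index with
pigeonhole seeding. For the chimeric pipeline, :func:`align_dangling`
finds the longest read-terminal segment (anchored at either read end)
that aligns, leaving the opposite-end remainder as the dangling sequence.
SAM ingestion lets an external aligner's output replace the internal one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .config import PipelineConfig
from .formats import Alignment, Read

logger = logging.getLogger(__name__)

_Hit = Tuple[str, int, int]  # (reference_id, start, mismatches)


@dataclass(frozen=True)
class DanglingAlignment:
    """A read whose terminal segment aligns to a transcript, with an unaligned remainder.

    ``dangling_side`` names the read end carrying the unaligned sequence:
    ``"five_prime"`` means the read suffix is aligned and the 5' remainder
    dangles (the geometry of a miRNA-first chimera).
    """

    read_id: str
    reference_id: str
    start: int
    aligned_length: int
    dangling_side: str
    dangling_seq: str

    @property
    def end(self) -> int:
        return self.start + self.aligned_length


class ReferenceIndex:
    """Substring index over a reference set supporting Hamming-tolerant lookup.

    Exact k-mer seeds are combined with pigeonhole splitting: a query with
    at most m mismatches contains at least one of m+1 equal chunks exactly,
    so seeding each chunk and verifying every candidate offset finds all
    placements. Queries shorter than the seed length fall back to a brute
    scan of every offset.
    """

    def __init__(self, references: Dict[str, str], k: int = 12):
        if not references:
            raise ValueError("reference set is empty")
        self.references = dict(references)
        self.k = k
        self._kmers: Dict[str, List[Tuple[str, int]]] = {}
        for ref_id, seq in self.references.items():
            for pos in range(len(seq) - k + 1):
                self._kmers.setdefault(seq[pos : pos + k], []).append((ref_id, pos))

    def _verify(self, query: str, ref_id: str, start: int, max_mm: int) -> Optional[int]:
        seq = self.references[ref_id]
        if start < 0 or start + len(query) > len(seq):
            return None
        mism = 0
        for a, b in zip(query, seq[start : start + len(query)]):
            if a != b:
                mism += 1
                if mism > max_mm:
                    return None
        return mism

    def _brute_hits(self, query: str, max_mm: int) -> List[_Hit]:
        hits: List[_Hit] = []
        for ref_id, seq in self.references.items():
            for start in range(len(seq) - len(query) + 1):
                mism = self._verify(query, ref_id, start, max_mm)
                if mism is not None:
                    hits.append((ref_id, start, mism))
        return sorted(hits)

    def find_full(self, query: str, max_mm: int = 0) -> List[_Hit]:
        """All (reference_id, start, mismatches) placements of the whole query."""
        n = len(query)
        if n == 0:
            return []
        n_chunks = max_mm + 1
        if n < self.k * n_chunks:
            return self._brute_hits(query, max_mm)
        candidates = set()
        for i in range(n_chunks):
            offset = i * n // n_chunks
            seed = query[offset : offset + self.k]
            for ref_id, pos in self._kmers.get(seed, ()):
                candidates.add((ref_id, pos - offset))
        hits: List[_Hit] = []
        for ref_id, start in candidates:
            mism = self._verify(query, ref_id, start, max_mm)
            if mism is not None:
                hits.append((ref_id, start, mism))
        return sorted(hits)

    def has_match(self, query: str, max_mm: int = 0) -> bool:
        return bool(self.find_full(query, max_mm))


def align_full(
    reads: Iterable[Read], reference: Dict[str, str], cfg: PipelineConfig
) -> List[Alignment]:
    """Align each full read to every matching position of the reference set.

    Each placement becomes one :class:`Alignment`; ``n_hits`` on every
    record of a read is the total number of placements of that read.
    Reads with no placement are absent from the output. The result is
    independent of read input order (records follow input order, and each
    read's hits are sorted by reference then position).
    """
    index = ReferenceIndex(reference)
    alignments: List[Alignment] = []
    for read in reads:
        hits = index.find_full(read.sequence, cfg.max_mismatches)
        for ref_id, start, mism in hits:
            alignments.append(
                Alignment(
                    read_id=read.id,
                    reference_id=ref_id,
                    start=start,
                    length=len(read.sequence),
                    mismatches=mism,
                    n_hits=len(hits),
                )
            )
    return alignments


def _longest_anchored(
    index: ReferenceIndex, sequence: str, anchor: str, min_length: int, max_mm: int
) -> int:
    """Length of the longest prefix (anchor='five_prime') or suffix of the read
    that matches somewhere in the reference; 0 if none of length >= min_length.

    Matchable lengths are downward closed (a sub-segment of a matching
    segment matches at the same placement), so binary search applies.
    """
    def matches(L: int) -> bool:
        seg = sequence[:L] if anchor == "five_prime" else sequence[-L:]
        return index.has_match(seg, max_mm)

    lo, hi = min_length, len(sequence)
    if lo > hi or not matches(lo):
        return 0
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if matches(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def align_dangling(
    reads: Iterable[Read], transcriptome: Dict[str, str], cfg: PipelineConfig
) -> List[DanglingAlignment]:
    """Report, per read, its longest aligning terminal segment plus dangling end.

    Both read ends are tried; the longer anchored match wins, and a length
    tie prefers the 3'-anchored (read suffix on mRNA) placement, the
    geometry of a 5'-miRNA chimera. Reads whose best anchored match is
    shorter than ``min_length`` are absent. The placement reported for a
    multi-mapping segment is the lexicographically first (reference id,
    position).
    """
    index = ReferenceIndex(transcriptome)
    results: List[DanglingAlignment] = []
    for read in reads:
        seq = read.sequence
        suffix_len = _longest_anchored(index, seq, "three_prime", cfg.min_length, cfg.max_mismatches)
        prefix_len = _longest_anchored(index, seq, "five_prime", cfg.min_length, cfg.max_mismatches)
        if suffix_len == 0 and prefix_len == 0:
            continue
        if suffix_len >= prefix_len:  # tie prefers the 3'-anchored mRNA match
            aligned, dangling_side = seq[-suffix_len:], "five_prime"
            dangling_seq = seq[: len(seq) - suffix_len]
        else:
            aligned, dangling_side = seq[:prefix_len], "three_prime"
            dangling_seq = seq[prefix_len:]
        ref_id, start, _mism = index.find_full(aligned, cfg.max_mismatches)[0]
        results.append(
            DanglingAlignment(
                read_id=read.id,
                reference_id=ref_id,
                start=start,
                aligned_length=len(aligned),
                dangling_side=dangling_side,
                dangling_seq=dangling_seq,
            )
        )
    return results


def ingest_sam(
    path,
    known_references: Optional[Sequence[str]] = None,
    with_dangling: bool = False,
):
    """Convert mapped, + strand, ungapped SAM records to pipeline alignments.

    Returns ``list[Alignment]``, or ``(list[Alignment], list[DanglingAlignment])``
    when ``with_dangling`` is true, in which case a record with one
    soft-clipped tail becomes a dangling-end alignment (the clipped
    sequence dangles). Reverse-strand and unmapped records are skipped
    (counted in the log); a reference name absent from
    ``known_references`` raises ``ValueError``. ``n_hits`` is taken from
    the NH tag when present, else from the record multiplicity per read id.
    """
    import pysam

    known = set(known_references) if known_references is not None else None
    alignments: List[Alignment] = []
    danglings: List[DanglingAlignment] = []
    n_skipped_reverse = 0
    n_skipped_other = 0
    raw: List[Tuple] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                n_skipped_other += 1
                continue
            if rec.is_reverse:
                n_skipped_reverse += 1
                continue
            ref_name = rec.reference_name
            if known is not None and ref_name not in known:
                raise ValueError(f"SAM reference {ref_name!r} absent from annotations")
            cigar = rec.cigartuples or []
            ops = [op for op, _ in cigar]
            if any(op not in (0, 4) for op in ops):  # M and S only: ungapped contract
                n_skipped_other += 1
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            raw.append((rec.query_name, ref_name, rec.reference_start, cigar, rec.query_sequence, nh))
    multiplicity: Dict[str, int] = {}
    for name, *_ in raw:
        multiplicity[name] = multiplicity.get(name, 0) + 1
    for name, ref_name, start, cigar, query, nh in raw:
        n_hits = int(nh) if nh is not None else multiplicity[name]
        clip5 = cigar[0][1] if cigar and cigar[0][0] == 4 else 0
        clip3 = cigar[-1][1] if cigar and cigar[-1][0] == 4 else 0
        matched = sum(length for op, length in cigar if op == 0)
        if with_dangling and (clip5 or clip3):
            if clip5 and clip3:
                n_skipped_other += 1
                continue
            side = "five_prime" if clip5 else "three_prime"
            dangling_seq = ""
            if query:
                dangling_seq = query[:clip5] if clip5 else query[len(query) - clip3 :]
            danglings.append(
                DanglingAlignment(
                    read_id=name,
                    reference_id=ref_name,
                    start=start,
                    aligned_length=matched,
                    dangling_side=side,
                    dangling_seq=dangling_seq,
                )
            )
        elif not (clip5 or clip3):
            alignments.append(
                Alignment(
                    read_id=name,
                    reference_id=ref_name,
                    start=start,
                    length=matched,
                    n_hits=n_hits,
                )
            )
        else:
            n_skipped_other += 1
    if n_skipped_reverse:
        logger.info("ingest_sam: skipped %d reverse-strand records", n_skipped_reverse)
    if n_skipped_other:
        logger.info("ingest_sam: skipped %d unmapped/gapped/clipped records", n_skipped_other)
    if with_dangling:
        return alignments, danglings
    return alignments
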