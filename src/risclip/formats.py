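"""Standard-format I/O and the canonical in-memory records of the pipeline.

All coordinates are 0-based half-open, internally and in BED output.
Only the + strand is modeled: alignment is against transcript and hairpin
sequences, not a genome. FASTQ/FASTA readers and writers are transparently
gzip-aware (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqIO.FastaIO import SimpleFastaParser

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Read:
    """A sequencing read; ``quality`` is optional but must match the sequence length.

    Input reads are non-empty (enforced at FASTQ ingestion); a zero-length
    sequence is permitted so that trimming an adapter-only read is legal.
    """

    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Region boundaries of one transcript.

    The 5'UTR [0, cds_start), CDS [cds_start, cds_end) and 3'UTR
    [cds_end, length) partition the transcript; any region may be empty.
    """

    transcript_id: str
    length: int
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start <= self.cds_end <= self.length):
            raise ValueError(
                f"transcript {self.transcript_id!r}: regions "
                f"(0, {self.cds_start}, {self.cds_end}, {self.length}) do not "
                f"partition [0, length)"
            )

    @property
    def utr5(self) -> Tuple[int, int]:
        return (0, self.cds_start)

    @property
    def cds(self) -> Tuple[int, int]:
        return (self.cds_start, self.cds_end)

    @property
    def utr3(self) -> Tuple[int, int]:
        return (self.cds_end, self.length)

    @property
    def regions(self) -> Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]:
        return (self.utr5, self.cds, self.utr3)


@dataclass(frozen=True)
class HairpinAnnotation:
    """A miRNA hairpin with the intervals of its annotated mature miRNAs."""

    hairpin_id: str
    length: int
    mature_sites: Tuple[Tuple[str, Tuple[int, int]], ...]

    def __post_init__(self) -> None:
        seen = set()
        for mature_id, (s, e) in self.mature_sites:
            if not (0 <= s < e <= self.length):
                raise ValueError(
                    f"hairpin {self.hairpin_id!r}: mature site {mature_id!r} "
                    f"[{s}, {e}) outside [0, {self.length})"
                )
            if mature_id in seen:
                raise ValueError(
                    f"hairpin {self.hairpin_id!r}: duplicate mature id {mature_id!r}"
                )
            seen.add(mature_id)


@dataclass(frozen=True)
class Alignment:
    """Ungapped placement of a full read on a transcript or hairpin (+ strand)."""

    read_id: str
    reference_id: str
    start: int
    length: int
    mismatches: int = 0
    n_hits: int = 1
    strand: str = "+"

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path: PathLike) -> Iterator[Read]:
    """Yield reads from a (possibly gzipped) FASTQ file in file order.

    Raises ``ValueError`` naming the 1-based record index on a malformed
    record (sequence/quality length mismatch, truncated record).
    """
    with _open_text(path) as handle:
        index = 0
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {index + 1}: {exc}") from exc
            index += 1
            if not seq:
                raise ValueError(f"malformed FASTQ record {index}: empty sequence")
            try:
                yield Read(id=title.split()[0], sequence=seq, quality=qual)
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {index}: {exc}") from exc


def write_fastq(reads: Iterable[Read], path: PathLike) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = read.quality if read.quality is not None else "I" * len(read.sequence)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a (possibly gzipped) FASTA file into an ordered id -> sequence dict."""
    sequences: Dict[str, str] = {}
    with _open_text(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            sequences[title.split()[0]] = seq.upper()
    return sequences


def write_fasta(sequences: Dict[str, str], path: PathLike, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation tables (TSV)
# ---------------------------------------------------------------------------

def read_annotations(path: PathLike) -> List[TranscriptAnnotation]:
    """Read a transcript annotation table.

    Tab-separated columns: transcript_id, length, cds_start, cds_end
    (0-based half-open). A header line starting with ``transcript_id`` or
    ``#`` is skipped.
    """
    annotations: List[TranscriptAnnotation] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("transcript_id"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"annotation line has {len(fields)} fields, expected 4: {line!r}")
            tx_id = fields[0]
            try:
                annotations.append(
                    TranscriptAnnotation(tx_id, int(fields[1]), int(fields[2]), int(fields[3]))
                )
            except ValueError as exc:
                raise ValueError(f"invalid annotation for transcript {tx_id!r}: {exc}") from exc
    return annotations


def write_annotations(annotations: Iterable[TranscriptAnnotation], path: PathLike) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("transcript_id\tlength\tcds_start\tcds_end\n")
        for ann in annotations:
            handle.write(f"{ann.transcript_id}\t{ann.length}\t{ann.cds_start}\t{ann.cds_end}\n")


def read_hairpin_annotations(path: PathLike) -> List[HairpinAnnotation]:
    """Read a hairpin annotation table.

    Tab-separated columns: hairpin_id, length, mature_id, start, end;
    one row per mature site, rows of one hairpin grouped by id.
    """
    sites: Dict[str, Tuple[int, List[Tuple[str, Tuple[int, int]]]]] = {}
    order: List[str] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("hairpin_id"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"hairpin annotation line has {len(fields)} fields, expected 5: {line!r}")
            hp_id, length, mature_id, s, e = fields[0], int(fields[1]), fields[2], int(fields[3]), int(fields[4])
            if hp_id not in sites:
                sites[hp_id] = (length, [])
                order.append(hp_id)
            sites[hp_id][1].append((mature_id, (s, e)))
    return [
        HairpinAnnotation(hp_id, sites[hp_id][0], tuple(sites[hp_id][1])) for hp_id in order
    ]


def write_hairpin_annotations(annotations: Iterable[HairpinAnnotation], path: PathLike) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("hairpin_id\tlength\tmature_id\tstart\tend\n")
        for ann in annotations:
            for mature_id, (s, e) in ann.mature_sites:
                handle.write(f"{ann.hairpin_id}\t{ann.length}\t{mature_id}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Footprint BED
# ---------------------------------------------------------------------------

def write_footprints_bed(footprints, path: PathLike) -> None:
    """Write footprints as BED6 (transcript-space, 0-based half-open, + strand).

    Columns: transcript_id, bin_start, bin_end, footprint_id, weight, strand.
    Lines are sorted by (transcript_id, bin_start).
    """
    rows = sorted(footprints, key=lambda fp: (fp.transcript_id, fp.bin[0]))
    with _open_text(path, "wt") as handle:
        for fp in rows:
            weight = int(fp.weight) if float(fp.weight).is_integer() else fp.weight
            handle.write(
                f"{fp.transcript_id}\t{fp.bin[0]}\t{fp.bin[1]}\t{fp.footprint_id}\t{weight}\t+\n"
            )


def read_footprints_bed(path: PathLike):
    """Read footprints written by :func:`write_footprints_bed`."""
    from .footprints import Footprint  # local import to avoid a cycle

    footprints = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            tx, start, end, fp_id, weight, _strand = line.split("\t")
            footprints.append(
                Footprint(
                    footprint_id=fp_id,
                    transcript_id=tx,
                    bin=(int(start), int(end)),
                    weight=float(weight),
                    seed_position=int(start),
                )
            )
    return footprints
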