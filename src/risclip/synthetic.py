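"""Synthetic CLIP libraries with complete planted ground truth.

Emulates the structure of an Argonaute CLIP experiment at desk scale:
random transcripts with 5'UTR/CDS/3'UTR annotations, miRNA hairpins with
1-2 annotated mature sites, and a contaminant set. Library reads are mRNA
fragments starting at planted footprint sites (with optional Gaussian
start jitter), exact mature-miRNA copies, chimeric miRNA+mRNA
concatenations, and contaminant fragments, each with the 3' adapter
appended in full, partially, or not at all. Every read's origin is
recorded in a truth table so each pipeline stage can be scored against
what was planted.

Chimeric junctions are planted so that the maximal anchored match equals
the planted mRNA fragment (the transcript base 5' of the fragment is
required to differ from the last miRNA base); without this the ground
truth junction would be ill-defined under local-extension alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .formats import (
    Alignment,
    HairpinAnnotation,
    Read,
    TranscriptAnnotation,
    write_annotations,
    write_fasta,
    write_fastq,
    write_hairpin_annotations,
)

BASES = np.array(list("ACGT"))


@dataclass
class SimulationParams:
    """Knobs of the synthetic library; the defaults are the study conditions.

    Fragment lengths default to 30-60 nt, a desk-scale stand-in for the
    80-180 bp mRNA gel cut minus adapters. ``reads_per_site_mean`` is the
    mean of the geometric read count per planted footprint site. Category
    fractions are fractions of the final library; explicit ``n_*`` counts
    override the corresponding fraction when given.
    """

    n_transcripts: int = 50
    transcript_length_range: Tuple[int, int] = (500, 1500)
    n_hairpins: int = 20
    hairpin_length_range: Tuple[int, int] = (70, 110)
    n_contaminants: int = 10
    contaminant_length_range: Tuple[int, int] = (100, 300)
    n_footprint_sites: int = 200
    reads_per_site_mean: float = 20.0
    start_jitter_sd: float = 0.0
    fragment_length_range: Tuple[int, int] = (30, 60)
    min_site_separation: int = 10
    mirna_read_fraction: float = 0.0
    chimera_fraction: float = 0.0
    contaminant_fraction: float = 0.0
    adapter_full_fraction: float = 1.0
    adapter_partial_fraction: float = 0.0
    region_enrichment: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    error_rate: float = 0.0
    adapter: str = "GTGTCAGTCACTTCCAG"
    min_partial_overlap: int = 6
    n_mirna_reads: Optional[int] = None
    mirna_abundances: Optional[Dict[str, int]] = None
    n_chimeras: Optional[int] = None
    n_contaminant_reads: Optional[int] = None
    dirichlet_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mirna_read_fraction", "chimera_fraction", "contaminant_fraction",
                     "adapter_full_fraction", "adapter_partial_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.mirna_read_fraction + self.chimera_fraction + self.contaminant_fraction >= 1.0:
            raise ValueError("category fractions must sum to < 1")
        if self.adapter_full_fraction + self.adapter_partial_fraction > 1.0:
            raise ValueError("adapter fractions must sum to <= 1")
        for name in ("transcript_length_range", "hairpin_length_range",
                     "contaminant_length_range", "fragment_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} must be (lo, hi) with 1 <= lo <= hi")


@dataclass
class Reference:
    transcripts: Dict[str, str]
    annotations: List[TranscriptAnnotation]
    hairpins: Dict[str, str]
    hairpin_annotations: List[HairpinAnnotation]
    contaminants: Dict[str, str]


@dataclass
class SimulationTruth:
    """Complete provenance of a simulated library."""

    planted_footprints: List[Tuple[str, int, int]]  # (transcript_id, position, n_reads)
    mirna_abundances: Dict[str, int]
    chimeras: List[dict]  # read_id, mature_id, transcript_id, target_start, junction
    contaminant_read_ids: set
    per_read_provenance: Dict[str, dict]

    @property
    def library_size(self) -> int:
        return len(self.per_read_provenance)

    def to_json(self, path) -> None:
        payload = {
            "planted_footprints": [list(t) for t in self.planted_footprints],
            "mirna_abundances": self.mirna_abundances,
            "chimeras": self.chimeras,
            "contaminant_read_ids": sorted(self.contaminant_read_ids),
            "per_read_provenance": self.per_read_provenance,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(
            planted_footprints=[tuple(t) for t in payload["planted_footprints"]],
            mirna_abundances=payload["mirna_abundances"],
            chimeras=payload["chimeras"],
            contaminant_read_ids=set(payload["contaminant_read_ids"]),
            per_read_provenance=payload["per_read_provenance"],
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def simulate_reference(params: SimulationParams) -> Reference:
    """Generate transcripts, hairpins and contaminants, deterministically from the seed.

    Transcript region boundaries leave every region at least 50 nt when
    the transcript is long enough; hairpins carry one mature site per arm
    (20-23 nt), dropping the 3' arm when the hairpin is too short for two
    disjoint sites.
    """
    rng = np.random.default_rng([params.seed, 0])
    transcripts: Dict[str, str] = {}
    annotations: List[TranscriptAnnotation] = []
    lo, hi = params.transcript_length_range
    for i in range(params.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        tx_id = f"tx{i + 1:04d}"
        transcripts[tx_id] = _random_seq(rng, length)
        if length >= 150:
            # mRNA-like proportions: short 5'UTR, long CDS, moderate 3'UTR
            a = int(rng.integers(50, min(300, length - 100) + 1))
            utr3_len = int(rng.integers(50, min(600, length - a - 50) + 1))
            b = length - utr3_len
        else:
            a, b = 0, length
        annotations.append(TranscriptAnnotation(tx_id, length, a, b))

    hairpins: Dict[str, str] = {}
    hairpin_annotations: List[HairpinAnnotation] = []
    hlo, hhi = params.hairpin_length_range
    for i in range(params.n_hairpins):
        length = int(rng.integers(hlo, hhi + 1))
        hp_id = f"hp{i + 1:03d}"
        hairpins[hp_id] = _random_seq(rng, length)
        sites = []
        len5 = int(rng.integers(20, 24))
        s5 = int(rng.integers(1, 6))
        if s5 + len5 <= length:
            sites.append((f"{hp_id}-5p", (s5, s5 + len5)))
        len3 = int(rng.integers(20, 24))
        e3 = length - int(rng.integers(1, 6))
        s3 = e3 - len3
        if sites and s3 >= sites[0][1][1] + 2:
            sites.append((f"{hp_id}-3p", (s3, e3)))
        hairpin_annotations.append(HairpinAnnotation(hp_id, length, tuple(sites)))

    contaminants: Dict[str, str] = {}
    clo, chi = params.contaminant_length_range
    for i in range(params.n_contaminants):
        contaminants[f"rfam{i + 1:03d}"] = _random_seq(rng, int(rng.integers(clo, chi + 1)))
    return Reference(transcripts, annotations, hairpins, hairpin_annotations, contaminants)


def _mature_catalog(reference: Reference) -> Dict[str, str]:
    catalog: Dict[str, str] = {}
    for ann in reference.hairpin_annotations:
        seq = reference.hairpins[ann.hairpin_id]
        for mature_id, (s, e) in ann.mature_sites:
            catalog[mature_id] = seq[s:e]
    return catalog


def _pick_site_positions(
    reference: Reference, params: SimulationParams, rng: np.random.Generator
) -> List[Tuple[str, int]]:
    """Plant footprint sites, respecting region enrichment and minimum separation."""
    ann_by_id = {a.transcript_id: a for a in reference.annotations}
    tx_ids = sorted(reference.transcripts)
    frag_min = params.fragment_length_range[0]
    sites: List[Tuple[str, int]] = []
    taken: Dict[str, List[int]] = {t: [] for t in tx_ids}
    attempts = 0
    while len(sites) < params.n_footprint_sites and attempts < params.n_footprint_sites * 200:
        attempts += 1
        tx = tx_ids[int(rng.integers(0, len(tx_ids)))]
        ann = ann_by_id[tx]
        usable = len(reference.transcripts[tx]) - frag_min
        if usable < 1:
            continue
        region_lens = np.array([max(0, min(hi, usable) - lo) for lo, hi in ann.regions], dtype=float)
        weights = region_lens * np.asarray(params.region_enrichment, dtype=float)
        if weights.sum() <= 0:
            continue
        region = int(rng.choice(3, p=weights / weights.sum()))
        lo, hi = ann.regions[region]
        hi = min(hi, usable)
        if hi <= lo:
            continue
        pos = int(rng.integers(lo, hi))
        if any(abs(pos - p) < params.min_site_separation for p in taken[tx]):
            continue
        taken[tx].append(pos)
        sites.append((tx, pos))
    if len(sites) < params.n_footprint_sites:
        raise RuntimeError("could not place all footprint sites; relax separation or add transcripts")
    return sites


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def simulate_library(
    reference: Reference, params: SimulationParams
) -> Tuple[List[Read], SimulationTruth]:
    """Draw a CLIP-like read library from a reference, with full provenance.

    Footprint reads start at a planted site plus rounded Gaussian jitter
    (clipped so the fragment fits); miRNA reads copy mature sequences with
    multinomial counts over Dirichlet proportions (or explicit
    abundances); chimeric reads concatenate a mature sequence with an
    mRNA fragment; contaminant reads are substrings of the contaminant
    set. The adapter is appended in full / partially / not at all per the
    configured fractions, and the read list is shuffled. Deterministic
    given the seed.
    """
    rng = np.random.default_rng([params.seed, 1])
    frag_lo, frag_hi = params.fragment_length_range
    catalog = _mature_catalog(reference)

    records: List[Tuple[str, str, dict]] = []  # (category, fragment, provenance)

    # --- footprint-site reads -------------------------------------------
    planted: List[Tuple[str, int, int]] = []
    if params.n_footprint_sites > 0:
        sites = _pick_site_positions(reference, params, rng)
        p_geom = 1.0 / params.reads_per_site_mean
        for tx, pos in sites:
            seq = reference.transcripts[tx]
            n_reads = int(rng.geometric(p_geom))
            planted.append((tx, pos, n_reads))
            for _ in range(n_reads):
                start = pos
                if params.start_jitter_sd > 0:
                    start = pos + int(round(rng.normal(0.0, params.start_jitter_sd)))
                frag_len = int(rng.integers(frag_lo, frag_hi + 1))
                start = min(max(start, 0), len(seq) - frag_lo)
                fragment = seq[start : start + frag_len]
                records.append(
                    ("footprint", fragment, {"transcript_id": tx, "site": pos, "start": start})
                )
    n_fp = len(records)

    denom = 1.0 - params.mirna_read_fraction - params.chimera_fraction - params.contaminant_fraction
    total_target = n_fp / denom if n_fp else 0.0

    # --- miRNA reads -----------------------------------------------------
    abundances: Dict[str, int] = {}
    if params.mirna_abundances is not None:
        abundances = dict(params.mirna_abundances)
    else:
        n_mi = params.n_mirna_reads
        if n_mi is None:
            n_mi = int(round(total_target * params.mirna_read_fraction))
        if n_mi > 0:
            mature_ids = sorted(catalog)
            props = rng.dirichlet(np.full(len(mature_ids), params.dirichlet_alpha))
            counts = rng.multinomial(n_mi, props)
            abundances = {m: int(c) for m, c in zip(mature_ids, counts)}
    for mature_id, count in sorted(abundances.items()):
        for _ in range(count):
            records.append(("mirna", catalog[mature_id], {"mature_id": mature_id}))

    # --- chimeric reads --------------------------------------------------
    n_ch = params.n_chimeras
    if n_ch is None:
        n_ch = int(round(total_target * params.chimera_fraction))
    chimera_plan: List[dict] = []
    tx_ids = sorted(reference.transcripts)
    mature_ids = sorted(catalog)
    for _ in range(n_ch):
        mature_id = mature_ids[int(rng.integers(0, len(mature_ids)))]
        mature_seq = catalog[mature_id]
        while True:
            tx = tx_ids[int(rng.integers(0, len(tx_ids)))]
            seq = reference.transcripts[tx]
            frag_len = int(rng.integers(frag_lo, frag_hi + 1))
            if len(seq) <= frag_len:
                continue
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            # the planted junction must be the maximal anchored match
            if start > 0 and seq[start - 1] == mature_seq[-1]:
                continue
            break
        fragment = mature_seq + seq[start : start + frag_len]
        chimera_plan.append(
            {"mature_id": mature_id, "transcript_id": tx, "target_start": start,
             "junction": len(mature_seq)}
        )
        records.append(("chimera", fragment, dict(chimera_plan[-1])))

    # --- contaminant reads ----------------------------------------------
    n_co = params.n_contaminant_reads
    if n_co is None:
        n_co = int(round(total_target * params.contaminant_fraction))
    cont_ids = sorted(reference.contaminants)
    for _ in range(n_co):
        cid = cont_ids[int(rng.integers(0, len(cont_ids)))]
        seq = reference.contaminants[cid]
        frag_len = min(int(rng.integers(frag_lo, frag_hi + 1)), len(seq))
        start = int(rng.integers(0, len(seq) - frag_len + 1))
        records.append(("contaminant", seq[start : start + frag_len], {"contaminant_id": cid}))

    # --- adapters, errors, shuffle --------------------------------------
    order = rng.permutation(len(records))
    reads: List[Read] = []
    provenance: Dict[str, dict] = {}
    chimeras: List[dict] = []
    contaminant_read_ids: set = set()
    adapter = params.adapter
    for out_idx, rec_idx in enumerate(order):
        category, fragment, info = records[rec_idx]
        fragment = _apply_errors(fragment, params.error_rate, rng)
        u = rng.random()
        if u < params.adapter_full_fraction:
            sequence, adapter_state = fragment + adapter, "full"
        elif u < params.adapter_full_fraction + params.adapter_partial_fraction:
            cut = int(rng.integers(params.min_partial_overlap, len(adapter)))
            sequence, adapter_state = fragment + adapter[:cut], "partial"
        else:
            sequence, adapter_state = fragment, "none"
        read_id = f"r{out_idx + 1:06d}"
        reads.append(Read(id=read_id, sequence=sequence, quality="I" * len(sequence)))
        info = dict(info, category=category, adapter=adapter_state)
        provenance[read_id] = info
        if category == "chimera":
            chimeras.append(
                {"read_id": read_id, "mature_id": info["mature_id"],
                 "transcript_id": info["transcript_id"],
                 "target_start": info["target_start"], "junction": info["junction"]}
            )
        elif category == "contaminant":
            contaminant_read_ids.add(read_id)

    truth = SimulationTruth(
        planted_footprints=planted,
        mirna_abundances=abundances,
        chimeras=chimeras,
        contaminant_read_ids=contaminant_read_ids,
        per_read_provenance=provenance,
    )
    return reads, truth


def simulate_fragments(
    reference: Reference,
    n_fragments: int,
    params: Optional[SimulationParams] = None,
    seed: Optional[int] = None,
) -> List[Alignment]:
    """Place mRNA fragments directly as alignments, for region-density studies.

    Transcripts are drawn uniformly (each contributes equally, matching
    the standardized-mRNA averaging); within a transcript the fragment
    midpoint is uniform within a region chosen with probability
    proportional to region length times its enrichment multiplier, and
    the fragment is clipped at transcript ends. Midpoint placement keeps
    uniform sampling unbiased with respect to region assignment at the
    transcript edges.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng([params.seed if seed is None else seed, 2])
    ann_by_id = {a.transcript_id: a for a in reference.annotations}
    tx_ids = sorted(reference.transcripts)
    frag_lo, frag_hi = params.fragment_length_range
    enrichment = np.asarray(params.region_enrichment, dtype=float)
    alignments: List[Alignment] = []
    for i in range(n_fragments):
        tx = tx_ids[int(rng.integers(0, len(tx_ids)))]
        ann = ann_by_id[tx]
        region_lens = np.array([hi - lo for lo, hi in ann.regions], dtype=float)
        weights = region_lens * enrichment
        region = int(rng.choice(3, p=weights / weights.sum()))
        lo, hi = ann.regions[region]
        mid = int(rng.integers(lo, hi))
        frag_len = int(rng.integers(frag_lo, frag_hi + 1))
        start = max(0, mid - frag_len // 2)
        end = min(ann.length, start + frag_len)
        start = max(0, end - frag_len)
        alignments.append(
            Alignment(read_id=f"frag{i + 1:06d}", reference_id=tx, start=start,
                      length=end - start)
        )
    return alignments


def write_reference(reference: Reference, outdir) -> None:
    """Write the reference as FASTA + annotation TSVs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(reference.transcripts, outdir / "transcripts.fa")
    write_annotations(reference.annotations, outdir / "transcripts.tsv")
    write_fasta(reference.hairpins, outdir / "hairpins.fa")
    write_hairpin_annotations(reference.hairpin_annotations, outdir / "hairpins.tsv")
    write_fasta(reference.contaminants, outdir / "contaminants.fa")


def write_library(reads: Sequence[Read], truth: SimulationTruth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fastq(reads, outdir / "reads.fastq")
    truth.to_json(outdir / "truth.json")
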