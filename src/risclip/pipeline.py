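"""End-to-end pipeline runs: trim -> filter -> align -> footprints / quantify / metagene.

Two entry points mirror the two processing routes of a HITS-CLIP
experiment. The nonchimeric route aligns whole trimmed reads to the
transcriptome and hairpins, calls footprints from the transcript
alignments and ranks miRNA occupancy from the hairpin alignments. The
chimeric route aligns with dangling ends and resolves the dangling
sequences into miRNA-target interaction calls. Both emit a run report
whose counts are internally consistent, and all outputs are
deterministic functions of the inputs and configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
import yaml

from . import metagene as _metagene
from .align import align_dangling, align_full
from .config import PipelineConfig
from .footprints import build_start_profile, call_footprints, summarize_footprints
from .formats import (
    HairpinAnnotation,
    Read,
    TranscriptAnnotation,
    read_annotations,
    read_fasta,
    read_fastq,
    read_hairpin_annotations,
    write_fastq,
    write_footprints_bed,
)
from .preprocess import filter_contaminants, length_filter, trim_adapter
from .quantify import count_mirna_occupancy, resolve_chimeras


def _rate(numerator: float, denominator: float) -> float:
    return round(numerator / denominator, 4) if denominator else 0.0


def _preprocess(reads: Iterable[Read], cfg: PipelineConfig):
    trimmed = [trim_adapter(read, cfg) for read in reads]
    kept, report = length_filter(trimmed, cfg)
    n_full = sum(1 for t in trimmed if t.adapter_found == "full")
    n_partial = sum(1 for t in trimmed if t.adapter_found == "partial")
    return [t.read for t in kept], report, n_full, n_partial


def run_nonchimeric(config: dict) -> dict:
    """Run the nonchimeric pipeline; return the run report.

    ``config`` keys: ``fastq``, ``transcripts_fasta``, ``annotations``,
    ``hairpins_fasta``, ``hairpin_annotations``, optional
    ``contaminants_fasta`` (enables contaminant filtering), optional
    ``out_dir`` (stage outputs written there), optional ``params``
    (:class:`PipelineConfig` fields).
    """
    cfg = PipelineConfig.from_dict(config.get("params", {}))
    reads = list(read_fastq(config["fastq"]))
    transcripts = read_fasta(config["transcripts_fasta"])
    annotations = read_annotations(config["annotations"])
    hairpins = read_fasta(config["hairpins_fasta"])
    hairpin_annotations = read_hairpin_annotations(config["hairpin_annotations"])

    kept, filt, n_full, n_partial = _preprocess(reads, cfg)
    if config.get("contaminants_fasta"):
        contaminants = read_fasta(config["contaminants_fasta"])
        kept, removed = filter_contaminants(kept, contaminants, cfg)
        filt.n_contaminant = len(removed)

    tx_alignments = align_full(kept, transcripts, cfg) if kept else []
    hp_alignments = align_full(kept, hairpins, cfg) if kept else []
    n_tx_reads = len({a.read_id for a in tx_alignments})
    n_hp_reads = len({a.read_id for a in hp_alignments})

    tx_lengths = {t: len(seq) for t, seq in transcripts.items()}
    footprints = []
    for profile in build_start_profile(tx_alignments, cfg):
        footprints.extend(
            call_footprints(profile, cfg, ref_length=tx_lengths.get(profile.transcript_id))
        )
    summary = summarize_footprints(footprints)
    mirna_counts = count_mirna_occupancy(hp_alignments, hairpin_annotations, cfg)

    profile = _metagene.compute_metagene(tx_alignments, annotations)
    proportions = _metagene.compute_region_proportions(tx_alignments, annotations)

    n_kept_post = filt.n_trimmed_kept - filt.n_contaminant
    report = {
        "n_raw": filt.n_input,
        "n_trimmed_kept": filt.n_trimmed_kept,
        "n_too_short": filt.n_too_short,
        "n_contaminant": filt.n_contaminant,
        "n_adapter_full": n_full,
        "n_adapter_partial": n_partial,
        "n_transcript_aligned": n_tx_reads,
        "transcript_alignment_rate": _rate(n_tx_reads, n_kept_post),
        "n_hairpin_aligned": n_hp_reads,
        "hairpin_alignment_rate": _rate(n_hp_reads, n_kept_post),
        "n_footprints": summary.n_footprints,
        "n_transcripts_with_footprints": summary.n_transcripts,
        "region_density_ratio": [round(x, 4) for x in proportions.density_ratio.tolist()],
    }

    out_dir = config.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fastq(kept, out / "kept.fastq")
        write_footprints_bed(footprints, out / "footprints.bed")
        pd.DataFrame(
            [(m.mature_id, m.count, m.rank) for m in mirna_counts],
            columns=["mature_id", "count", "rank"],
        ).to_csv(out / "mirna_counts.tsv", sep="\t", index=False)
        rows = []
        for i, region in enumerate(_metagene.REGIONS):
            for b, value in enumerate(profile.region_slice(region)):
                rows.append((region, b, round(float(value), 6)))
        pd.DataFrame(rows, columns=["region", "bin", "mean_coverage"]).to_csv(
            out / "metagene.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {
                "region": _metagene.REGIONS,
                "size_fraction": proportions.size_fraction.round(6),
                "fragment_fraction": proportions.fragment_fraction.round(6),
                "density_ratio": proportions.density_ratio.round(6),
            }
        ).to_csv(out / "proportions.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as handle:
            json.dump(report, handle, indent=1, sort_keys=True)
        with open(out / "config.yaml", "w") as handle:
            yaml.safe_dump({"params": cfg.to_dict()}, handle, sort_keys=True)
    return report


def run_chimeric(config: dict) -> dict:
    """Run the chimeric (dangling-end) pipeline; return report with chimera calls.

    ``config`` keys as :func:`run_nonchimeric`; chimera calls are written
    to ``chimeras.tsv`` under ``out_dir`` when given and returned under
    the ``"chimeras"`` key of the report.
    """
    cfg = PipelineConfig.from_dict(config.get("params", {}))
    reads = list(read_fastq(config["fastq"]))
    transcripts = read_fasta(config["transcripts_fasta"])
    hairpins = read_fasta(config["hairpins_fasta"])
    hairpin_annotations = read_hairpin_annotations(config["hairpin_annotations"])

    kept, filt, _n_full, _n_partial = _preprocess(reads, cfg)
    dangling = align_dangling(kept, transcripts, cfg) if kept else []
    with_dangle = [d for d in dangling if d.dangling_seq]
    calls = resolve_chimeras(with_dangle, hairpins, hairpin_annotations, cfg)

    report = {
        "n_raw": filt.n_input,
        "n_trimmed_kept": filt.n_trimmed_kept,
        "n_dangling_aligned": len(dangling),
        "n_with_dangling_end": len(with_dangle),
        "n_chimera_calls": len(calls),
        "chimeras": [
            {
                "read_id": c.read_id,
                "mature_id": c.mature_id,
                "transcript_id": c.transcript_id,
                "target_start": c.target_start,
            }
            for c in calls
        ],
    }
    out_dir = config.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            report["chimeras"],
            columns=["read_id", "mature_id", "transcript_id", "target_start"],
        ).to_csv(out / "chimeras.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as handle:
            json.dump({k: v for k, v in report.items() if k != "chimeras"}, handle,
                      indent=1, sort_keys=True)
    return report
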