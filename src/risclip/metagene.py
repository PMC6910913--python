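"""Standardized-mRNA (metagene) coverage profile and region-density analysis.

Each transcript's 5'UTR, CDS and 3'UTR are rescaled to a common number of
bins before averaging coverage across transcripts, producing an average
profile "over a standardized mRNA". Region proportions compare the share
of aligned fragments falling in each region against the average share of
transcript length the region occupies; their ratio is the region's
fragment density relative to uniform placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .formats import Alignment, TranscriptAnnotation

REGIONS = ("utr5", "cds", "utr3")


@dataclass
class MetageneProfile:
    """Mean coverage over a standardized mRNA: three regions x ``bins_per_region`` bins."""

    bins_per_region: int
    profile: np.ndarray  # length 3 * bins_per_region: 5'UTR, CDS, 3'UTR concatenated
    region_means: Tuple[float, float, float]

    def region_slice(self, region: str) -> np.ndarray:
        i = REGIONS.index(region)
        b = self.bins_per_region
        return self.profile[i * b : (i + 1) * b]


@dataclass
class RegionProportions:
    """Fragment and length shares of the three mRNA regions, and their ratio.

    ``density_ratio`` > 1 for a region means fragments fall there more
    often than its share of transcript length predicts.
    """

    size_fraction: np.ndarray
    fragment_fraction: np.ndarray
    density_ratio: np.ndarray
    n_fragments: int


def _coverage_by_transcript(
    alignments: Iterable[Alignment], annotations: Dict[str, TranscriptAnnotation]
) -> Dict[str, np.ndarray]:
    coverage: Dict[str, np.ndarray] = {}
    for aln in alignments:
        ann = annotations.get(aln.reference_id)
        if ann is None:
            raise ValueError(f"alignment on unannotated transcript {aln.reference_id!r}")
        cov = coverage.get(aln.reference_id)
        if cov is None:
            cov = np.zeros(ann.length)
            coverage[aln.reference_id] = cov
        cov[aln.start : aln.end] += 1.0
    return coverage


def _rescale(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean of ``values`` over ``n_bins`` equal-width windows.

    When the region is shorter than ``n_bins`` a window may span less than
    one base; it then takes the value of the base it falls on.
    """
    length = len(values)
    edges = np.floor(np.arange(n_bins + 1) * length / n_bins).astype(int)
    out = np.empty(n_bins)
    for j in range(n_bins):
        lo, hi = edges[j], edges[j + 1]
        if hi <= lo:
            hi = min(lo + 1, length)
            lo = hi - 1
        out[j] = values[lo:hi].mean()
    return out


def compute_metagene(
    alignments: Sequence[Alignment],
    annotations: Sequence[TranscriptAnnotation],
    bins_per_region: int = 100,
) -> MetageneProfile:
    """Average per-base coverage over a standardized mRNA.

    Per transcript, coverage from full alignment intervals is rescaled
    region-by-region to ``bins_per_region`` bins; the profile is the
    unweighted mean across transcripts carrying at least one alignment.
    Transcripts with an empty region are excluded from that region's
    averaging. With no alignments the profile is all zero.
    """
    ann_by_id = {ann.transcript_id: ann for ann in annotations}
    coverage = _coverage_by_transcript(alignments, ann_by_id)
    sums = np.zeros((3, bins_per_region))
    counts = np.zeros(3)
    for tx_id, cov in coverage.items():
        ann = ann_by_id[tx_id]
        for i, (lo, hi) in enumerate(ann.regions):
            if hi <= lo:
                continue
            sums[i] += _rescale(cov[lo:hi], bins_per_region)
            counts[i] += 1
    means = np.zeros((3, bins_per_region))
    for i in range(3):
        if counts[i] > 0:
            means[i] = sums[i] / counts[i]
    profile = means.reshape(-1)
    region_means = tuple(float(means[i].mean()) for i in range(3))
    return MetageneProfile(
        bins_per_region=bins_per_region, profile=profile, region_means=region_means
    )


def _assign_region(aln: Alignment, ann: TranscriptAnnotation) -> int:
    """Region index holding the majority of the fragment's bases; tie -> 5'-end region."""
    overlaps = [
        max(0, min(aln.end, hi) - max(aln.start, lo)) for lo, hi in ann.regions
    ]
    best = max(overlaps)
    tied = [i for i, ov in enumerate(overlaps) if ov == best]
    if len(tied) == 1:
        return tied[0]
    for i, (lo, hi) in enumerate(ann.regions):
        if lo <= aln.start < hi:
            return i if i in tied else tied[0]
    return tied[0]


def compute_region_proportions(
    alignments: Sequence[Alignment],
    annotations: Sequence[TranscriptAnnotation],
) -> RegionProportions:
    """Fragment share vs length share of 5'UTR / CDS / 3'UTR.

    Each fragment is assigned to the region containing the majority of its
    aligned bases (tie broken toward the region holding its 5' end).
    ``size_fraction`` is the mean, over all annotated transcripts, of
    region length / transcript length. Both fraction triples sum to 1.
    """
    ann_by_id = {ann.transcript_id: ann for ann in annotations}
    frag_counts = np.zeros(3)
    for aln in alignments:
        ann = ann_by_id.get(aln.reference_id)
        if ann is None:
            raise ValueError(f"alignment on unannotated transcript {aln.reference_id!r}")
        frag_counts[_assign_region(aln, ann)] += 1
    n_fragments = int(frag_counts.sum())
    fragment_fraction = (
        frag_counts / n_fragments if n_fragments else np.zeros(3)
    )
    shares = np.array(
        [
            [(hi - lo) / ann.length for lo, hi in ann.regions]
            for ann in annotations
            if ann.length > 0
        ]
    )
    size_fraction = shares.mean(axis=0) if len(shares) else np.zeros(3)
    with np.errstate(divide="ignore", invalid="ignore"):
        density_ratio = np.where(
            size_fraction > 0, fragment_fraction / size_fraction, 0.0
        )
    return RegionProportions(
        size_fraction=size_fraction,
        fragment_fraction=fragment_fraction,
        density_ratio=density_ratio,
        n_fragments=n_fragments,
    )
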