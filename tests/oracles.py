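"""Independent brute-force oracles the implementation is checked against.

Every function here re-derives an expected result by explicit enumeration,
without touching the production code paths.
"""

from typing import Dict, List, Tuple


def trim_oracle(seq: str, adapters: Tuple[str, str], min_overlap: int) -> Tuple[int, str]:
    """Expected (post-trim length, kind) by enumerating every cut candidate."""
    fulls = []
    for adapter in adapters:
        for i in range(len(seq) - len(adapter) + 1):
            if seq[i : i + len(adapter)] == adapter:
                fulls.append(i)
                break  # leftmost occurrence for this adapter
    if fulls:
        return min(fulls), "full"
    partials = []
    for adapter in adapters:
        for overlap in range(min_overlap, min(len(seq), len(adapter) - 1) + 1):
            if seq[len(seq) - overlap :] == adapter[:overlap]:
                partials.append(len(seq) - overlap)
    if partials:
        return min(partials), "partial"
    return len(seq), "none"


def scan_alignments(query: str, references: Dict[str, str], max_mm: int) -> List[Tuple[str, int, int]]:
    """All (ref_id, start, mismatches) placements by scanning every offset."""
    hits = []
    for ref_id, seq in references.items():
        for start in range(len(seq) - len(query) + 1):
            mism = sum(1 for a, b in zip(query, seq[start : start + len(query)]) if a != b)
            if mism <= max_mm:
                hits.append((ref_id, start, mism))
    return sorted(hits)


def dangling_oracle(seq: str, references: Dict[str, str], min_length: int, max_mm: int):
    """Expected (anchored length, side) by trying every terminal segment length.

    Returns None when no terminal segment of at least min_length matches.
    Side is the dangling side: 'five_prime' when the read suffix aligns.
    """
    best_suffix = best_prefix = 0
    for L in range(min_length, len(seq) + 1):
        if scan_alignments(seq[-L:], references, max_mm):
            best_suffix = L
        if scan_alignments(seq[:L], references, max_mm):
            best_prefix = L
    if best_suffix == 0 and best_prefix == 0:
        return None
    if best_suffix >= best_prefix:
        return best_suffix, "five_prime"
    return best_prefix, "three_prime"


def greedy_oracle(counts: Dict[int, float], bin_size: int) -> List[Tuple[int, int, float, int]]:
    """Expected footprints [(lo, hi, weight, seed)] by explicit max-scan each round."""
    remaining = dict(counts)
    emitted = []
    while remaining:
        best = None
        for pos in remaining:
            if (
                best is None
                or remaining[pos] > remaining[best]
                or (remaining[pos] == remaining[best] and pos < best)
            ):
                best = pos
        lo, hi = best, best + bin_size
        absorbed = [p for p in remaining if lo <= p < hi]
        weight = sum(remaining[p] for p in absorbed)
        for p in absorbed:
            del remaining[p]
        emitted.append((lo, hi, weight, best))
    return sorted(emitted)


def seed_sites_oracle(transcript: str, lo: int, hi: int, mature: str) -> List[Tuple[int, str]]:
    """Expected seed-match sites by checking every core start position in [lo, hi)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = lambda s: "".join(comp[b] for b in reversed(s))
    core = rc(mature[1:7])
    m8 = rc(mature[7])
    hits = []
    for i in range(max(lo, 0), hi - len(core) + 1):
        if transcript[i : i + len(core)] != core:
            continue
        has_m8 = i > 0 and transcript[i - 1] == m8
        has_a1 = i + len(core) < len(transcript) and transcript[i + len(core)] == "A"
        if has_m8 and has_a1:
            hits.append((i - 1, "8mer"))
        elif has_m8:
            hits.append((i - 1, "7mer-m8"))
        elif has_a1:
            hits.append((i, "7mer-A1"))
        else:
            hits.append((i, "6mer"))
    return hits
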