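# Methods

This note documents the models, conventions and design choices behind
each stage of the pipeline, and what the synthetic-data experiments do
and do not demonstrate.

## Coordinates and records

All intervals are 0-based half-open, internally and in BED output. Only
the + strand is modeled: alignment is against transcript and hairpin
sequences, not a genome, so reverse-strand placements are rejected (and
counted when ingesting SAM). Transcript annotations are a partition of
[0, length) into 5′UTR [0, a), CDS [a, b) and 3′UTR [b, length); any
region may be empty.

## Adapter trimming

Two 3′ adapter variants are searched (`GTGTCAGTCACTTCCAG` and its
one-base-shorter form `TGTCAGTCACTTCCAG`). A full occurrence of either
truncates the read at the leftmost occurrence and takes precedence over
any partial match. Failing that, the longest read suffix equal to an
adapter prefix is removed, provided the overlap is at least
`min_partial_overlap` (default 6 nt — at desk scale a random 3′
hexamer matches an adapter prefix with probability 4⁻⁶ ≈ 2×10⁻⁴, so
false trims are rare while genuine read-through into the adapter is
still caught). When both variants match, the one removing more bases
wins; exact ties go to the first-listed adapter. Matching is exact
(mismatches configurable but 0 by default), trimming is applied once
(no iterated double-adapter removal), and trimming to length 0 is
legal — the ≥ 16 nt length filter then discards the read. Trimming is
idempotent and monotone in the overlap threshold; both properties are
tested.

## Alignment contract

The internal aligner is an exact specification rather than a heuristic:
for each read it reports *every* ungapped placement on the reference
set with at most `max_mismatches` (0–2) mismatches, found via a 12-mer
index with pigeonhole seeding (a query with ≤ m mismatches contains at
least one of m+1 equal chunks exactly) and verified by Hamming count;
queries too short for seeding fall back to a brute scan of every
offset. Property tests assert equivalence with an exhaustive
offset-scan oracle. `n_hits` on every record of a read is its total
placement count; multi-mapped reads contribute weight 1 per placement
(`count_all`, default) or 1/n_hits (`fractional`).

Dangling-end alignment, the desk-scale stand-in for local alignment of
chimeric reads, reports the longest read-terminal segment (anchored at
either end) of length ≥ `min_length` that matches anywhere; matchable
anchored lengths are downward closed, so the maximum is found by binary
search over segment length. A length tie between the two anchorings
prefers the 3′-anchored (read suffix on mRNA) placement — the geometry
of a miRNA-first chimera; which end actually carries the miRNA is
recorded per read, not assumed. For a multi-mapping segment the
lexicographically first (reference, position) placement is reported.
External aligner output can replace the internal aligner via SAM
ingestion (mapped, + strand, M/S-only CIGARs; soft-clipped tails become
dangling ends on request).

## Footprint calling

Each transcript position is weighted by the number of alignments whose
5′ end starts there. Positions are clustered greedily from heavy to
light: the heaviest remaining position (ties to the smallest
coordinate, making the procedure deterministic and independent of map
iteration order) opens a `bin_size` = 10 nt bin that absorbs every
remaining start inside it; this repeats until no starts remain. Bins
extend downstream of their seed, [p, p+10), reflecting footprints
extending 3′ of the fragment start; a centered mode ([p−4, p+6)) is
available. Two consequences of downstream anchoring are deliberate and
documented: starts within 10 nt *upstream* of a heavier seed are not
absorbed and later seed their own bins, and such bins may overlap the
earlier bin as intervals — the greedy partition is of start positions
(each absorbed exactly once, total weight conserved), not of transcript
bases. An independent max-scan-per-round implementation serves as the
oracle in the tests.

## miRNA occupancy and chimera resolution

A hairpin-aligned read is attributed to a mature miRNA when its
alignment interval overlaps the annotated mature interval by at least
`overlap_min` = 10 nt (bare "overlap" would let a 1-nt graze count; 10
nt demands roughly half a mature sequence). Within one hairpin the
larger overlap wins, ties to the 5′ site; loop-only reads are not
counted. Counts are ranked descending with lexicographic tie order.
Both raw counts and fractions of assigned reads are emitted.

A dangling end is a chimeric miRNA candidate when its length is within
`mature_len_range` = [18, 25] nt. It is matched in full against the
hairpin sequences and attributed by the same overlap rule; candidates
matching no mature site, or more than one mature id, are dropped with
logged counts — chimeras serve as qualitative interaction evidence, so
ambiguous fractional assignment is not attempted.

## Standardized-mRNA profile and region densities

Per-base coverage from full alignment intervals is computed per
transcript; each nonempty region is rescaled to `bins_per_region` = 100
equal-width bins (a window shorter than one base takes the value of the
base it falls on) and the profile is the unweighted mean over
transcripts carrying at least one alignment — each transcript counts
equally, which is what "standardized mRNA" averaging means here; a
coverage-weighted reading would let a few deep transcripts dominate.
For region proportions, a fragment is assigned to the region containing
the majority of its aligned bases (ties to the region holding its 5′
end); `size_fraction` is the unweighted mean over annotated transcripts
of region length / transcript length, and `density_ratio` =
fragment share / size share, 1 meaning no preference. Fragments (reads)
are counted rather than aligned bases; a base-counting mode could be
added but reads are the unit the rest of the pipeline counts.

## Synthetic libraries and what they show

The generator emulates the *structure* of a CLIP library, not its
biochemistry. Defaults: 50 random uniform-composition transcripts of
500–1500 nt with mRNA-like region proportions (5′UTR 50–300 nt, 3′UTR
50–600 nt, every region ≥ 50 nt), 20 hairpins of 70–110 nt carrying one
20–23-nt mature site per arm, 10 contaminant sequences of 100–300 nt,
200 footprint sites with geometric read counts (mean 20) and fragments
of 30–60 nt — a desk-scale stand-in for the 80–180 bp mRNA gel cut
minus adapters. Start jitter is Gaussian (rounded, clipped), a simple
stress model for the bin clustering rather than a crosslinking model.
Planted sites keep ≥ 10 nt (one bin) separation so that noiseless
recovery has a well-defined truth. Chimeric junctions are planted such
that the transcript base 5′ of the mRNA fragment differs from the last
miRNA base; otherwise maximal anchored matching would legitimately
extend the mRNA segment past the planted junction (a 1-in-4 chance per
boundary base) and the planted truth would be ill-defined — an inherent
ambiguity of chimera calling, resolved here at generation time.
Footprint sites and metagene fragments draw transcripts uniformly (not
length-weighted) so that uniform placement is calibrated against the
unweighted size-fraction definition, and metagene fragments are placed
by midpoint to avoid transcript-edge bias in region assignment.

Passing these experiments shows the pipeline implements its stated
contracts exactly and recovers planted signal under the modeled noise.
It does not show robustness to properties of real CLIP data the
generator omits: non-uniform base composition and repeats (hence heavy
multi-mapping), ligation and RT biases, sequencing errors beyond
optional uniform substitution, crosslink-induced truncations/mutations,
and double-ligated adapters.

## Validation experiment sizes

The validation suite and `scripts/acceptance.py` use: 1,000 random
profiles (≤ 50 positions, weights 1–20) for clustering-oracle
equivalence; 1,000 random reads for trimming-oracle agreement; 50
transcripts × 200 sites × mean 50 reads (~10⁴ reads) for noiseless and
jittered (sd 2 nt) footprint recovery; 20 mature miRNAs × 5,000 reads
at Dirichlet proportions for quantification; 200 planted chimeras
(alone, and with ~10% background reads) for deconvolution; 10⁴ uniform
and 5×10³ enriched fragments for region densities. At these sizes the
whole validation runs in seconds on one CPU. Under jitter sd 2, site
recovery is expected near 98–99%: a site is missed only when every one
of its reads jitters strictly downstream of the planted position, so
no bin reaches back over it — a rare event at mean 50 reads/site but
the dominant failure mode for low-coverage sites under downstream
anchoring.

## Numerical and degenerate-input choices

Weights are floats; conservation is exact for integer (`count_all`)
weights and asserted to 1e−9 under `fractional`. Empty inputs are legal
everywhere (empty FASTQ → zero report; empty profile list → no
footprints; no alignments → zero metagene profile); an empty reference
or contaminant set is an error. Determinism: every stage is a pure
function of its inputs and configuration, the generator derives
independent named streams from one seed, and repeated runs produce
byte-identical output files. The pipeline is single-threaded; a
`--threads` option is accepted for interface stability and results are
trivially thread-count invariant.
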