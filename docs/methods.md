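# Methods

## Vector and ITR model

An AAV vector genome is modelled as `left ITR + cargo + revcomp(left
ITR)`: the two 145-nt inverted terminal repeats are sequence-identical
inverted copies of the canonical AAV2 ITR. Sub-regions follow the
a–b–c–a'–d palindrome layout: `a' = [0,20)`, two 41-nt internal
palindrome blocks at `[20,61)` and `[61,102)` (the b/b' and c/c' hairpin
loops, their order set by the flip/flop conformation), `a = [102,125)`,
`d = [125,145)`. Exact region boundaries are conventions, not
measurements — they determine region *labels* only, never breakpoint
coordinates — and are overridable. Because the two ITR copies are
identical, a breakpoint inside ITR sequence cannot be attributed to a
side; all ITR-local reporting therefore uses a shared 145-nt frame onto
which both copies are superimposed (the right copy through its reverse
complement). Calls whose vector evidence extends into the cargo are
additionally placed in whole-vector coordinates.

The packaged miniature vector (`aav_lambda_465`) is 465 bp: a 175-nt
synthetic stuffer — random sequence orthogonal to the toy host genome,
standing in for a phage-derived stuffer whose exact sequence is not
restated here — flanked by the two ITRs. A standard-size preset
(4062 bp) carries a labelled promoter-like feature used by the curation
filters.

Cut sites are blunt, 3 bp upstream of the PAM, stored as 0-based
insertion coordinates (the first base 3' of the cut on the plus strand).
SpCas9, SaCas9 and PAM-variant nucleases share this offset.

## Alignment

All pairwise alignment uses affine-gap scoring (match +2, mismatch −3,
gap open −5, gap extend −2; a length-L gap costs 5 + 2L) via
Bio.Align.PairwiseAligner — local mode for segment finding, overlap-style
global (free end gaps) for read-vs-amplicon decomposition. Scanning a
short read remainder against megabase-scale host sequence uses edlib's
bit-parallel infix search, with all tied best placements retained so
ambiguous hits can be discarded. Vector evidence requires ≥15 nt at
≥90% identity (config-exposed); shorter matches to the GC-rich ITR arise
by chance. A deterministic optimal alignment is returned; co-optimal
alignments are not enumerated.

## Junction calling and canonicalization

A fusion read is detected by aligning the read to the amplicon, taking
any unexplained segment (terminal clip or internal insertion ≥15 nt),
and aligning that segment to the vector on both strands. The host
breakpoint is the amplicon insertion coordinate flanking the vector
segment; the vector breakpoint is the junction-proximal aligned vector
base.

When the junction carries microhomology — host and vector sharing bases
across it — its position is inherently ambiguous: several gap placements
score identically. Placement is canonicalized to the **host-proximal
edge**: starting from the 5' host flank, the host claim is extended
base-by-base across the junction as long as exact matches continue, and
the vector breakpoint shifts in step. The synthetic-data generator
computes its truth coordinates with the same rule, so planted and
detected junctions agree exactly at zero sequencing error. The shared
bases themselves are not assigned an owner; the overlap is recorded, not
resolved.

The same ambiguity affects small indels at the classification-window
edge: an indel whose content matches its flank can slide between
equivalent placements. Window membership is therefore computed over the
indel's full equivalent-placement range (its homology slack in both
directions), which is invariant to whichever placement the aligner
reports.

## Editing-outcome classification

Reads are classified `unmodified`, `substitution_only`, `small_indel`,
`vector_fusion`, or `unaligned` (fewer than 60% of read bases matching
the amplicon — below this, classification is meaningless and the read
must not enter denominators). Substitutions never make a read an edit.
Only indels overlapping the ±5-nt cut-site window count (the `-w 5`
convention of standard amplicon-editing tools); net indel size sums
insertions (+) and deletions (−), one count per read. Fusion takes
precedence over the indel call, so a vector insertion with flanking
deletions is a single capture event — consistent with a capture-ratio
denominator that includes the integration events themselves.

## Genome-wide site calling and curation

Reads must start with the ITR primer (≤2 mismatches). After aligning
the read to the vector, a ≥15-nt remainder is scanned against every host
chromosome; only a unique best hit becomes a site (ties → ambiguous,
dropped; no remainder → episomal, dropped). Curation automates what
would otherwise be manual exclusion, as reproducibility demands a rule:

* **shared homology** — a site fails if any ungapped 20-nt window of its
  ±40-nt host flank matches vector sequence at ≥90% on either strand.
  The scan is deliberately ungapped: gapped chaining of short
  coincidental matches is not homology.
* **ITR evidence** — a site fails unless its vector segment covers ≥10 nt
  of ITR outside the primer binding site (primer-only amplification
  artifacts carry no unique ITR).

Filters are monotone and order-independent. Sites are annotated by
precedence exonic > promoter > downstream > intronic > intergenic
(promoter/downstream = 1 kb, config-exposed), normalized to reads per
million, clustered into unique sites by single-linkage within 50 nt
(breakpoint wobble from microhomology and trimming is well under that),
and flagged recurrent when a clustered site appears in ≥3 conditions.
The minimum supporting depth per site is 1 by default, with a
config-exposed floor.

## Architecture classification

Clones are anchored by their host flanks (≥20 nt each side; clones
without both flanks are unclassifiable). The insert between the flank
anchors is tiled greedily with non-overlapping vector alignments by
descending score, and each aligned block is split at ITR/cargo
boundaries. Decision rules (thresholds config-exposed): full cargo =
coverage ≥0.90; ITR-only = coverage <0.05 and <10 nt absolute; ITR
"present" = ≥20 nt at ≥90% identity; copies counted by cargo blocks that
restart rather than continue colinearly, with ≥2 copies a concatemer.
Cargo present without any ITR is reported `unclassifiable` rather than
given a type — ITR-free integration is not an expected architecture and
is surfaced, never silently typed. Junction microhomology is the
longest exact overlap shared by the host terminus and the vector
terminus; host-flank indels are measured against the reference flanks
(deletions negative).

## Synthetic data: what it emulates, and what not

The generator's defaults encode the study conditions the analyses
assume: 150-nt MiSeq-style reads; NHEJ indels with geometric sizes
(p = 0.6, so single-nucleotide events dominate) and a deletion bias of
0.6; junction offsets 98% within 1 bp of the cut; ITR breakpoint weights
elevated 6-fold in the b/c loop block; 83.5% of fusion junctions
involving the ITR; a single-copy architecture mix of
0.10/0.20/0.25/0.45 (types 1–4), concatemers off by default; independent
per-base substitution errors at 0.001 with constant base quality.
Sequencing *indel* errors default to off so that pipeline indel calls are
not confounded with error-model indels (an optional rate exists).
Class counts are multinomial by default; an exact-count planting mode
supports integer worked examples (e.g. the 2/4/5/9 composition of 20
clones).

Two identifiability controls exist for junction-position tests:
`fusion_flank_deletion_prob` defaults to 0 (so junction offsets equal
the jitter model; end-resection at fusion junctions remains available as
a parameter), and `avoid_junction_microhomology` redraws breakpoints
whose insert start matches the host base at the junction, making the
planted junction position well-defined. Without the latter, ~25% of
junctions are ambiguous by one or more bases — a property of the biology,
not of any detector.

Not modelled: PCR amplification bias and duplicates (recovery properties
should not be over-read as validation against real duplication
structure), sonication fragment lengths, quality-score realism, PCR
chimeras, and real genomes — the toy host is 5 × 100 kb of seeded random
sequence with ~20 toy genes. Recovery tests on these data show the
pipeline's correctness under its stated assumptions, not performance on
real libraries.

ITR hotspot recovery is assessed at region-group granularity (a/b/c/d,
primes stripped): the ITR's internal palindromes make mirrored positions
(a↔a', and positions within each loop palindrome) indistinguishable to
any aligner, and that mirror maps every position into its own letter
group, so group totals are identifiable even where single positions are
not.

## Problem sizes and numerics

Default validation runs use 2000–4000 reads per amplicon condition, 200
clones per architecture type, and libraries of a few hundred genome-wide
reads against the 500-kb toy host — sizes chosen so the full validation
suite completes in minutes on one CPU while keeping multinomial standard
errors small enough for 3-SE recovery checks. All internal coordinates
are 0-based half-open; emitted tables are 1-based inclusive except BED
(0-based half-open per the BED standard). Ratios with zero denominators
are NaN, never 0. A single top-level seed expands into per-stage seeds;
identical configurations reproduce byte-identical outputs.

## Known limitations

* The fusion caller reports one junction per read (the host-proximal
  one); reads spanning both junctions of a short insert contribute their
  left junction only.
* Genome-wide minus-strand breakpoints can shift by ~1 nt when a
  junction base coincidentally extends the vector alignment; well within
  the 50-nt clustering window.
* Concatemer detection presumes cargo-bearing repeats; ITR-only
  concatemer junctions are counted as junction ITRs, not copies.
* The genome-wide caller does not assay concatemeric integrants.
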