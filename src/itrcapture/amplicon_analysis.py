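"""Per-locus editing-outcome quantification at a CRISPR cut site.

Each merged read is classified into one of five mutually exclusive
outcomes: ``unmodified``, ``substitution_only``, ``small_indel``,
``vector_fusion`` or ``unaligned``.  Substitutions never make a read an
edit; only insertions/deletions overlapping a +/- ``window_halfwidth``
window around the blunt cut count, matching the standard amplicon-editing
convention of scoring indels in a narrow cut-site window while ignoring
point errors.  A read carrying both a vector insertion and flanking indels
counts once, as a fusion.

The headline statistic is the *AAV capture ratio*: the fraction of all
edited reads (small indels plus vector fusions) that carry vector
sequence, i.e. ``n_fusion / (n_fusion + n_small_indel)``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .fusion_detection import (
    AlignParams,
    FusionCall,
    _unexplained_intervals,
    detect_fusion,
    global_align,
    junction_distance,
)
from .vector_model import TargetLocus, VectorGenome

__all__ = [
    "EditOutcome",
    "AmpliconSummary",
    "TwoCutSummary",
    "quantify_indels",
    "capture_ratio",
    "indel_size_spectrum",
    "itr_junction_fraction",
    "summarize_amplicon",
    "classify_two_cut",
]

#: Size (nt) separating "small" NHEJ indels from long, vector-scale insertions.
SMALL_INDEL_CUTOFF = 25


@dataclass
class EditOutcome:
    read_id: str
    outcome: str  # unmodified | substitution_only | small_indel | vector_fusion | unaligned
    net_indel_size: int = 0
    fusion: FusionCall | None = None

    def __post_init__(self):
        if self.outcome == "vector_fusion" and self.fusion is None:
            raise ValueError("vector_fusion outcome requires an attached FusionCall")


def _indel_slide(amp: str, left_edge: int, right_edge: int, segment: str, cap: int = 30):
    """Equivalent-placement slide range of an indel.

    An indel's position is ambiguous wherever its content matches the
    flanking reference (homology slack): a deletion of [s, s+l) can move
    left while ``amp[s-1] == amp[s+l-1]`` and right while
    ``amp[s] == amp[s+l]``; an insertion rotates against its own content
    the same way.  Returns ``(left_slack, right_slack)``.  Window
    membership computed over the full slide range is invariant to which
    equivalent placement an aligner happens to report.
    """
    L = len(segment)
    if L == 0:
        return 0, 0
    kl = 0
    while (
        kl < cap
        and left_edge - 1 - kl >= 0
        and amp[left_edge - 1 - kl] == segment[(L - 1 - kl) % L]
    ):
        kl += 1
    kr = 0
    while (
        kr < cap
        and right_edge + kr < len(amp)
        and amp[right_edge + kr] == segment[kr % L]
    ):
        kr += 1
    return kl, kr


def quantify_indels(
    reads,
    locus: TargetLocus,
    vector: VectorGenome | None = None,
    window_halfwidth: int = 5,
    params: AlignParams | None = None,
    min_align_identity: float = 0.60,
) -> list[EditOutcome]:
    """Classify merged/single-end reads against the amplicon.

    ``reads`` yields ``(read_id, sequence)`` pairs or plain sequences.
    Fusion detection (when a vector is given) takes precedence over the
    indel call, so a vector insertion with flanking deletions is counted
    once as a capture event.
    """
    params = params or AlignParams()
    cut = locus.cut_point
    lo, hi = cut - window_halfwidth, cut + window_halfwidth  # inclusive window
    outcomes: list[EditOutcome] = []
    for i, item in enumerate(reads):
        read_id, seq = item if isinstance(item, tuple) else (f"read{i}", item)
        seq = seq.upper()
        if not seq:
            outcomes.append(EditOutcome(read_id, "unaligned"))
            continue
        ga = global_align(seq, locus.amplicon, params, ref_id=locus.name)
        aligned = sum(t[1] - t[0] for t, _ in ga.aligned_blocks)
        matches = aligned - ga.substitutions
        # identity over the shorter of read/amplicon, so partial molecules
        # still qualify but off-amplicon reads do not
        if matches / min(len(seq), len(locus.amplicon)) < min_align_identity:
            outcomes.append(EditOutcome(read_id, "unaligned"))
            continue

        if vector is not None:
            unexplained = _unexplained_intervals(
                len(seq), ga.aligned_blocks, params.min_clip_len
            )
            big_insert = any(l >= params.min_clip_len for _, l, _ in ga.insertions)
            if unexplained or big_insert:
                call = detect_fusion(seq, locus, vector, params, read_id=read_id)
                if call is not None:
                    size = call.vector_segment.read_span
                    outcomes.append(
                        EditOutcome(read_id, "vector_fusion", size, call)
                    )
                    continue

        net = 0
        hit = False
        amp = locus.amplicon
        for pos, length, qstart in ga.insertions:
            ins = seq[qstart : qstart + length]
            kl, kr = _indel_slide(amp, pos, pos, ins)
            if lo <= pos + kr and pos - kl <= hi:
                net += length
                hit = True
        for start, length in ga.deletions:
            deleted = amp[start : start + length]
            kl, kr = _indel_slide(amp, start, start + length, deleted)
            if (start - kl) <= hi and (start + length + kr) > lo:
                net -= length
                hit = True
        if hit:
            outcomes.append(EditOutcome(read_id, "small_indel", net))
        elif ga.substitutions > 0:
            outcomes.append(EditOutcome(read_id, "substitution_only"))
        else:
            outcomes.append(EditOutcome(read_id, "unmodified"))
    return outcomes


def capture_ratio(outcomes) -> float:
    """n_fusion / (n_fusion + n_small_indel); NaN when no edited reads."""
    n_fus = sum(1 for o in outcomes if o.outcome == "vector_fusion")
    n_ind = sum(1 for o in outcomes if o.outcome == "small_indel")
    if n_fus + n_ind == 0:
        return math.nan
    return n_fus / (n_fus + n_ind)


def indel_size_spectrum(outcomes):
    """Histogram of net indel sizes over edited reads.

    Small-indel reads contribute their net size (insertions positive,
    deletions negative); fusion reads contribute the inserted vector
    length.  Returns ``(histogram, frac_indels_small, frac_insertions_long)``
    with the small/long split at +/-25 nt.
    """
    hist: Counter[int] = Counter()
    for o in outcomes:
        if o.outcome in ("small_indel", "vector_fusion"):
            hist[o.net_indel_size] += 1
    n = sum(hist.values())
    if n == 0:
        return dict(hist), math.nan, math.nan
    small = sum(c for s, c in hist.items() if abs(s) <= SMALL_INDEL_CUTOFF)
    long_ins = sum(c for s, c in hist.items() if s > SMALL_INDEL_CUTOFF)
    return dict(hist), small / n, long_ins / n


def itr_junction_fraction(outcomes) -> float:
    """Fraction of fusion calls whose vector segment touches an ITR."""
    fusions = [o for o in outcomes if o.outcome == "vector_fusion"]
    if not fusions:
        return math.nan
    return sum(1 for o in fusions if o.fusion.itr_overlap) / len(fusions)


@dataclass
class AmpliconSummary:
    n_total: int
    n_unmodified: int
    n_substitution_only: int
    n_small_indel: int
    n_fusion: int
    n_unaligned: int
    capture_ratio: float
    indel_size_histogram: dict[int, int]
    frac_indels_small: float
    frac_insertions_long: float
    itr_at_junction_fraction: float
    junction_distance_histogram: dict[int, int] = field(default_factory=dict)

    def to_dict(self):
        d = dict(self.__dict__)
        d["indel_size_histogram"] = {str(k): v for k, v in self.indel_size_histogram.items()}
        d["junction_distance_histogram"] = {
            str(k): v for k, v in self.junction_distance_histogram.items()
        }
        return d


def summarize_amplicon(outcomes, locus: TargetLocus) -> AmpliconSummary:
    counts = Counter(o.outcome for o in outcomes)
    hist, frac_small, frac_long = indel_size_spectrum(outcomes)
    jd = Counter(
        junction_distance(o.fusion, locus)
        for o in outcomes
        if o.outcome == "vector_fusion"
    )
    return AmpliconSummary(
        n_total=len(outcomes),
        n_unmodified=counts.get("unmodified", 0),
        n_substitution_only=counts.get("substitution_only", 0),
        n_small_indel=counts.get("small_indel", 0),
        n_fusion=counts.get("vector_fusion", 0),
        n_unaligned=counts.get("unaligned", 0),
        capture_ratio=capture_ratio(outcomes),
        indel_size_histogram=hist,
        frac_indels_small=frac_small,
        frac_insertions_long=frac_long,
        itr_at_junction_fraction=itr_junction_fraction(outcomes),
        junction_distance_histogram=dict(jd),
    )


# -- two-cut (exon excision) analysis ---------------------------------------


@dataclass
class TwoCutSummary:
    n_intact: int
    n_deletion_junction: int
    n_deletion_with_vector: int
    n_other: int
    inter_cut_capture_ratio: float

    @property
    def n_total(self):
        return (
            self.n_intact
            + self.n_deletion_junction
            + self.n_deletion_with_vector
            + self.n_other
        )


def _junction_locus(reference: str, cut_a: int, name: str) -> TargetLocus:
    # synthetic locus whose cut point equals the excision junction; only the
    # amplicon and cut coordinate are consumed downstream
    return TargetLocus(
        name, reference, (cut_a - 17, cut_a + 3), (cut_a + 3, cut_a + 6), "+"
    )


def _spans_contiguously(
    seq: str, ref: str, pos: int, params: AlignParams, tol: int
) -> bool:
    """True when the read aligns near-fully to ``ref`` and crosses ``pos``
    contiguously (allowing only an indel shorter than ``tol`` at it)."""
    ga = global_align(seq, ref, params)
    blocks = ga.aligned_blocks
    if not blocks:
        return False
    aligned = sum(q[1] - q[0] for _, q in blocks)
    if (aligned - ga.substitutions) / aligned < 0.9 or aligned / len(seq) < 0.85:
        return False
    for t, _ in blocks:
        if t[0] <= pos - tol and t[1] >= pos + tol:
            return True
    for i in range(1, len(blocks)):
        (t0, q0), (t1, q1) = blocks[i - 1], blocks[i]
        if (
            abs(t0[1] - pos) <= tol
            and t1[0] - t0[1] <= tol
            and q1[0] - q0[1] <= tol
        ):
            return True
    return False


def classify_two_cut(
    reads,
    locus_a: TargetLocus,
    locus_b: TargetLocus,
    vector: VectorGenome,
    params: AlignParams | None = None,
    junction_tolerance: int = 15,
) -> TwoCutSummary:
    """Classify reads from a PCR spanning two cut sites after excision.

    Both loci must sit on one shared reference with ``locus_a`` upstream.
    Outcomes: ``deletion_junction`` (the two outer flanks fused, small
    indels allowed), ``deletion_with_vector`` (vector sequence between the
    flanks), ``intact`` (read crosses cut A with no excision junction) and
    ``other``.  The inter-cut capture ratio is
    ``n_with_vector / (n_junction + n_with_vector)``.
    """
    params = params or AlignParams()
    if locus_a.amplicon != locus_b.amplicon:
        raise ValueError("two-cut loci must lie on one shared reference")
    ref = locus_a.amplicon
    cut_a, cut_b = locus_a.cut_point, locus_b.cut_point
    if cut_a >= cut_b:
        raise ValueError("locus_a must be upstream of locus_b")
    del_ref = ref[:cut_a] + ref[cut_b:]
    del_locus = _junction_locus(del_ref, cut_a, "excision_junction")

    n_intact = n_junc = n_vec = n_other = 0
    for item in reads:
        _, seq = item if isinstance(item, tuple) else ("r", item)
        seq = seq.upper()
        call = detect_fusion(seq, del_locus, vector, params)
        if call is not None and abs(call.host_breakpoint - cut_a) <= junction_tolerance:
            n_vec += 1
            continue
        if _spans_contiguously(seq, del_ref, cut_a, params, junction_tolerance):
            n_junc += 1
            continue
        if _spans_contiguously(seq, ref, cut_a, params, junction_tolerance):
            n_intact += 1
            continue
        n_other += 1

    denom = n_junc + n_vec
    ratio = n_vec / denom if denom else math.nan
    return TwoCutSummary(n_intact, n_junc, n_vec, n_other, ratio)
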