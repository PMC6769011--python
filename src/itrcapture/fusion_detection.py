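"""Split-read detection of vector-host fusion reads.

A fusion read carries both host (amplicon/genomic) and AAV vector sequence
and evidences an integration junction.  Detection is alignment-based: the
read is aligned locally to the host amplicon; any unexplained read segment
(terminal soft clip or internal insertion) at least ``min_clip_len`` long
is then aligned to the vector genome on both strands.  A junction call
records the host-side insertion coordinate, the junction-proximal vector
base, and whether the vector evidence lies in the ITR.

Because the two ITRs of a vector are sequence-identical inverted copies, a
vector segment contained entirely within ITR sequence cannot be attributed
to a side; such calls are flagged ``ambiguous_itr`` and reported in the
shared 145-nt ITR-local frame where both copies superimpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align

from .vector_model import TargetLocus, VectorGenome, revcomp, to_itr_local

__all__ = [
    "AlignParams",
    "AlignmentSegment",
    "FusionCall",
    "BreakpointProfile",
    "FastqRead",
    "local_align",
    "global_align",
    "scan_hits",
    "merge_pairs",
    "detect_fusion",
    "junction_distance",
    "vector_breakpoint_profile",
]


@dataclass(frozen=True)
class AlignParams:
    """Scoring and evidence thresholds shared by all alignment steps."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_clip_len: int = 15
    min_identity: float = 0.90

    def __post_init__(self):
        if self.min_clip_len < 1:
            raise ValueError("min_clip_len must be >= 1")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class AlignmentSegment:
    ref_id: str
    ref_interval: tuple[int, int]
    read_interval: tuple[int, int]
    strand: str
    identity: float
    score: float

    @property
    def ref_span(self) -> int:
        return self.ref_interval[1] - self.ref_interval[0]

    @property
    def read_span(self) -> int:
        return self.read_interval[1] - self.read_interval[0]


def _aligner(params: AlignParams, mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open + params.gap_extend
    a.extend_gap_score = params.gap_extend
    if mode == "global":
        # free end gaps: partial molecules and vector-terminated reads still
        # align end-anchored (overlap-style global alignment)
        a.end_gap_score = 0
    return a


def _segment(alignment, ref_id: str, strand: str, qlen: int) -> AlignmentSegment:
    tblocks, qblocks = alignment.aligned
    rs, re = int(tblocks[0][0]), int(tblocks[-1][1])
    qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    if strand == "-":
        qs, qe = qlen - qe, qlen - qs
    return AlignmentSegment(
        ref_id=ref_id,
        ref_interval=(rs, re),
        read_interval=(qs, qe),
        strand=strand,
        identity=identity,
        score=float(alignment.score),
    )


def local_align(
    query: str, ref: str, params: AlignParams | None = None, ref_id: str = "ref"
) -> AlignmentSegment | None:
    """Best local (Smith-Waterman, affine gaps) alignment of query vs ref.

    Both strands of the query are scored; the better one is returned with
    its strand recorded and the read interval mapped back onto the input
    orientation.  Returns None when no positive-scoring alignment exists.
    """
    params = params or AlignParams()
    if not query or not ref:
        raise ValueError("local_align requires non-empty sequences")
    aligner = _aligner(params, "local")
    best = None
    for strand, q in (("+", query), ("-", revcomp(query))):
        alns = aligner.align(ref, q)
        if len(q) == 0:
            continue
        try:
            aln = alns[0]
        except (IndexError, ValueError):
            continue
        if aln.score <= 0 or len(aln.aligned[0]) == 0:
            continue
        if best is None or aln.score > best[0].score:
            best = (aln, strand)
    if best is None:
        return None
    aln, strand = best
    return _segment(aln, ref_id, strand, len(query))


@dataclass(frozen=True)
class GlobalAlignment:
    """A read-vs-amplicon global alignment decomposed into edit events."""

    segment: AlignmentSegment
    insertions: list[tuple[int, int, int]]  # (amplicon pos, length, read start)
    deletions: list[tuple[int, int]]        # (amplicon start, deleted length)
    substitutions: int
    aligned_blocks: list[tuple[tuple[int, int], tuple[int, int]]]


def global_align(
    query: str, ref: str, params: AlignParams | None = None, ref_id: str = "ref"
) -> GlobalAlignment:
    """Global alignment of a read to an amplicon with free end gaps on the
    read, decomposed into insertion/deletion/substitution events."""
    params = params or AlignParams()
    if not query or not ref:
        raise ValueError("global_align requires non-empty sequences")
    aligner = _aligner(params, "global")
    aln = aligner.align(ref, query)[0]
    tblocks, qblocks = aln.aligned
    insertions, deletions = [], []
    subs = 0
    blocks = []
    for (trs, tre), (qrs, qre) in zip(tblocks, qblocks):
        blocks.append(((int(trs), int(tre)), (int(qrs), int(qre))))
        for i in range(tre - trs):
            if ref[trs + i] != query[qrs + i]:
                subs += 1
    for i in range(1, len(blocks)):
        (p_tre, p_qre) = blocks[i - 1][0][1], blocks[i - 1][1][1]
        (n_trs, n_qrs) = blocks[i][0][0], blocks[i][1][0]
        dref = n_trs - p_tre
        dread = n_qrs - p_qre
        if dread > 0:
            insertions.append((p_tre, dread, p_qre))
        if dref > 0:
            deletions.append((p_tre, dref))
    seg = _segment(aln, ref_id, "+", len(query))
    return GlobalAlignment(seg, insertions, deletions, subs, blocks)


def scan_hits(query: str, ref: str, max_mismatch_frac: float = 0.1):
    """Locate all best-scoring placements of a query in a long reference.

    Infix (glocal) scan on both strands via bit-parallel edit distance;
    returns ``(edit_distance, [(start, end, strand), ...])`` for the best
    distance, or ``(None, [])`` when nothing within the tolerance.
    Overlapping equal-score placements are merged to one representative.
    """
    k = max(1, int(len(query) * max_mismatch_frac))
    best_ed, hits = None, []
    for strand, q in (("+", query), ("-", revcomp(query))):
        r = edlib.align(q, ref, mode="HW", task="locations", k=k)
        if r["editDistance"] < 0:
            continue
        ed = r["editDistance"]
        if best_ed is None or ed < best_ed:
            best_ed, hits = ed, []
        if ed == best_ed:
            for s, e in r["locations"]:
                hits.append((s, e + 1, strand))
    if best_ed is None:
        return None, []
    merged = []
    for s, e, strand in sorted(hits):
        if merged and merged[-1][2] == strand and s <= merged[-1][1]:
            continue
        merged.append((s, e, strand))
    return best_ed, merged


# -- paired-read merging -----------------------------------------------------


@dataclass
class FastqRead:
    name: str
    sequence: str
    quality: str = ""

    def __post_init__(self):
        if not self.quality:
            self.quality = "I" * len(self.sequence)
        if len(self.quality) != len(self.sequence):
            raise ValueError(f"quality/sequence length mismatch for {self.name}")

    def __len__(self):
        return len(self.sequence)


def merge_pairs(
    read1: FastqRead,
    read2: FastqRead,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> FastqRead | None:
    """Overlap-merge a read pair into one fragment-spanning record.

    Read 2 is reverse-complemented from sequencing orientation, the 3' end
    of read 1 is slid over the 5' end of read 2, and the overlap with the
    lowest mismatch fraction (ties to the longest overlap) is accepted if
    it spans >= ``min_overlap`` nt at <= ``max_mismatch_frac`` mismatches.
    Disagreeing overlap bases are resolved by the higher base quality.
    Returns None when the pair cannot be merged.
    """
    if len(read1) == 0 or len(read2) == 0:
        raise ValueError("cannot merge length-0 reads")
    s1 = np.frombuffer(read1.sequence.encode(), dtype=np.uint8)
    r2 = revcomp(read2.sequence)
    q2 = read2.quality[::-1]
    s2 = np.frombuffer(r2.encode(), dtype=np.uint8)
    l1, l2 = len(s1), len(s2)
    best = None  # (mismatch_frac, -overlap, overlap)
    for ov in range(min(l1, l2), min_overlap - 1, -1):
        mm = int((s1[l1 - ov:] != s2[:ov]).sum())
        frac = mm / ov
        if frac <= max_mismatch_frac:
            key = (frac, -ov)
            if best is None or key < best[0]:
                best = (key, ov)
    if best is None:
        return None
    ov = best[1]
    left = read1.sequence[: l1 - ov]
    lq = read1.quality[: l1 - ov]
    right = r2[ov:]
    rq = q2[ov:]
    mid, midq = [], []
    for i in range(ov):
        b1, b2 = read1.sequence[l1 - ov + i], r2[i]
        c1, c2 = read1.quality[l1 - ov + i], q2[i]
        if b1 == b2 or c1 >= c2:
            mid.append(b1)
            midq.append(max(c1, c2) if b1 == b2 else c1)
        else:
            mid.append(b2)
            midq.append(c2)
    return FastqRead(read1.name, left + "".join(mid) + right, lq + "".join(midq) + rq)


# -- fusion calling ----------------------------------------------------------


@dataclass
class FusionCall:
    read_id: str
    host_segment: AlignmentSegment
    vector_segment: AlignmentSegment
    host_breakpoint: int
    vector_breakpoint: int
    itr_overlap: bool
    itr_local: tuple
    ambiguous_itr: bool
    junction_gap: int = 0  # unexplained nt between host and vector read segments


def _unexplained_intervals(read_len: int, ga_blocks, min_len: int):
    """Read intervals not explained by the host alignment blocks."""
    out = []
    if not ga_blocks:
        return [(0, read_len)] if read_len >= min_len else []
    first_q = ga_blocks[0][1][0]
    last_q = ga_blocks[-1][1][1]
    if first_q >= min_len:
        out.append((0, first_q))
    for i in range(1, len(ga_blocks)):
        gap = (ga_blocks[i - 1][1][1], ga_blocks[i][1][0])
        if gap[1] - gap[0] >= min_len:
            out.append(gap)
    if read_len - last_q >= min_len:
        out.append((last_q, read_len))
    return out


def detect_fusion(
    read: str,
    locus: TargetLocus,
    vector: VectorGenome,
    params: AlignParams | None = None,
    read_id: str = "read",
) -> FusionCall | None:
    """Detect a vector-host junction in a single (merged) read.

    The read is aligned locally to the amplicon; unexplained segments of at
    least ``min_clip_len`` nt are aligned to the vector on both strands.  A
    call is emitted when the vector evidence reaches ``min_identity`` over
    ``min_clip_len`` nt.  The host breakpoint is the amplicon insertion
    coordinate flanking the unexplained segment (host-proximal edge); the
    vector breakpoint is the junction-proximal aligned vector base.
    """
    params = params or AlignParams()
    read = read.upper()
    hseg = local_align(read, locus.amplicon, params, ref_id=locus.name)
    if hseg is None:
        return None
    if hseg.strand == "-":
        read = revcomp(read)
        hseg = local_align(read, locus.amplicon, params, ref_id=locus.name)
        if hseg is None or hseg.strand == "-":
            return None

    # block decomposition of the plus-strand host alignment, so internal
    # insertions show up as read gaps between consecutive blocks
    aligner = _aligner(params, "local")
    aln = aligner.align(locus.amplicon, read)[0]
    tb, qb = aln.aligned
    blocks = [((int(t[0]), int(t[1])), (int(q[0]), int(q[1]))) for t, q in zip(tb, qb)]

    candidates = _unexplained_intervals(len(read), blocks, params.min_clip_len)
    best = None  # (vseg in local coords, interval)
    for a, b in candidates:
        vseg = local_align(read[a:b], vector.sequence, params, ref_id=vector.name)
        if vseg is None:
            continue
        if vseg.read_span < params.min_clip_len or vseg.identity < params.min_identity:
            continue
        if best is None or vseg.score > best[0].score:
            best = (vseg, (a, b))
    if best is None:
        return None
    vseg_local, (a, b) = best
    vseg = AlignmentSegment(
        ref_id=vseg_local.ref_id,
        ref_interval=vseg_local.ref_interval,
        read_interval=(a + vseg_local.read_interval[0], a + vseg_local.read_interval[1]),
        strand=vseg_local.strand,
        identity=vseg_local.identity,
        score=vseg_local.score,
    )

    v_rs, v_re = vseg.read_interval
    # host blocks flanking the vector segment; a clipped 5' host arm that was
    # not part of the primary alignment is recovered by realignment
    left_end = None  # (host ref end, read end) of host block 5' of vector
    right_start = None
    for t, q in blocks:
        if q[1] <= v_rs + 5 and (left_end is None or q[1] > left_end[1]):
            left_end = (t[1], q[1])
        if q[0] >= v_re - 5 and (right_start is None or q[0] < right_start[1]):
            right_start = (t[0], q[0])
    if left_end is None and v_rs >= 10:
        arm = local_align(read[:v_rs], locus.amplicon, params, ref_id=locus.name)
        if (
            arm is not None
            and arm.strand == "+"
            and arm.read_span >= 10
            and arm.read_interval[1] >= v_rs - 5
        ):
            left_end = (arm.ref_interval[1], arm.read_interval[1])
    if left_end is None and right_start is None:
        return None

    # The junction adjacent to the 5' host flank is primary.  Microhomology
    # makes the exact junction placement ambiguous, so it is canonicalized
    # to the host-proximal edge: the host claim is extended base-by-base
    # across the junction as far as exact matches go, and the vector
    # breakpoint (junction-proximal aligned vector base) shifts in step.
    amp = locus.amplicon
    if left_end is not None:
        t1, q1 = left_end
        while q1 < len(read) and t1 < len(amp) and read[q1] == amp[t1]:
            q1 += 1
            t1 += 1
        host_breakpoint = t1
        junction_gap = max(0, v_rs - q1)
        claimed = max(0, q1 - v_rs)
        claimed = min(claimed, vseg.read_span - 1)
        if vseg.strand == "+":
            vector_breakpoint = vseg.ref_interval[0] + claimed
        else:
            vector_breakpoint = vseg.ref_interval[1] - 1 - claimed
    else:
        t0, q0 = right_start
        while q0 > 0 and t0 > 0 and read[q0 - 1] == amp[t0 - 1]:
            q0 -= 1
            t0 -= 1
        host_breakpoint = t0
        junction_gap = max(0, q0 - v_re)
        claimed = max(0, v_re - q0)
        claimed = min(claimed, vseg.read_span - 1)
        if vseg.strand == "+":
            vector_breakpoint = vseg.ref_interval[1] - 1 - claimed
        else:
            vector_breakpoint = vseg.ref_interval[0] + claimed

    itr_overlap = any(
        vseg.ref_interval[0] < hi and vseg.ref_interval[1] > lo
        for lo, hi in vector.itr_intervals()
    )
    ambiguous = any(
        lo <= vseg.ref_interval[0] and vseg.ref_interval[1] <= hi
        for lo, hi in vector.itr_intervals()
    )
    return FusionCall(
        read_id=read_id,
        host_segment=hseg,
        vector_segment=vseg,
        host_breakpoint=host_breakpoint,
        vector_breakpoint=vector_breakpoint,
        itr_overlap=itr_overlap,
        itr_local=to_itr_local(vector_breakpoint, vector),
        ambiguous_itr=ambiguous,
        junction_gap=junction_gap,
    )


def junction_distance(call: FusionCall, locus: TargetLocus) -> int:
    """Signed distance (bp) from the host breakpoint to the blunt cut."""
    return call.host_breakpoint - locus.cut_point


@dataclass
class BreakpointProfile:
    """Per-nucleotide junction counts over the shared ITR frame and cargo.

    Every call contributes exactly one count: ITR breakpoints land in the
    145-nt shared frame (both ITR copies superimposed, so side-ambiguous
    calls are counted once without attribution); cargo breakpoints land in
    the cargo frame.  ``vector_full`` additionally places side-unambiguous
    calls in whole-vector coordinates for coverage-style plots.
    """

    itr: np.ndarray
    cargo: np.ndarray
    vector_full: np.ndarray
    n_calls: int = 0

    @property
    def total(self) -> int:
        return int(self.itr.sum() + self.cargo.sum())

    def normalized(self) -> tuple[np.ndarray, np.ndarray]:
        if self.n_calls == 0:
            return self.itr.astype(float), self.cargo.astype(float)
        return self.itr / self.n_calls, self.cargo / self.n_calls


def vector_breakpoint_profile(calls, vector: VectorGenome) -> BreakpointProfile:
    clo, chi = vector.cargo_interval
    prof = BreakpointProfile(
        itr=np.zeros(145, dtype=int),
        cargo=np.zeros(chi - clo, dtype=int),
        vector_full=np.zeros(len(vector), dtype=int),
    )
    for call in calls:
        side, local, _ = call.itr_local
        if side != "none":
            prof.itr[local] += 1
            if not call.ambiguous_itr:
                prof.vector_full[call.vector_breakpoint] += 1
        else:
            prof.cargo[call.vector_breakpoint - clo] += 1
            prof.vector_full[call.vector_breakpoint] += 1
        prof.n_calls += 1
    return prof
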