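"""Classification of full-length integrant clones into integration types.

Sanger-sequenced clones spanning an integration event reveal the complete
architecture of the integrated vector.  Four major single-copy forms are
distinguished, plus concatemers:

* **Type 1** — both ITRs present, full cargo;
* **Type 2** — full cargo with a single ITR;
* **Type 3** — ITR-only integrant, essentially no cargo;
* **Type 4** — one ITR with a partial cargo fragment;
* **concatemer** — two or more tandem vector copies;
* integrants with cargo but no detectable ITR are flagged
  ``unclassifiable`` rather than typed, since ITR-free integration is not
  an expected architecture; clones without vector sequence are
  ``no_vector``.

Vector-aligned blocks are tiled greedily on the clone by descending
alignment score, then decomposed at ITR/cargo boundaries.  Junction
microhomology (longest exact overlap shared by the host and vector
termini) and host-flank indels are measured per junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fusion_detection import AlignmentSegment, AlignParams, local_align
from .vector_model import VectorGenome

__all__ = [
    "ArchitectureCall",
    "ArchitectureThresholds",
    "CoverageProfile",
    "classify_clone",
    "microhomology",
    "detect_concatemer",
    "tile_vector_blocks",
    "vector_coverage_profile",
]

TYPES = (
    "type1_full_both_itrs",
    "type2_full_one_itr",
    "type3_itr_only",
    "type4_partial_one_itr",
    "concatemer",
    "no_vector",
    "unclassifiable",
)


@dataclass(frozen=True)
class ArchitectureThresholds:
    full_cargo_coverage: float = 0.90
    itr_only_coverage: float = 0.05
    itr_only_max_nt: int = 10
    min_itr_block: int = 20      # nt of ITR alignment for an ITR to count
    min_itr_identity: float = 0.90
    min_block_score: float = 24  # tiling stops below this local score
    min_flank_nt: int = 20


@dataclass
class VectorBlock:
    """One vector-aligned block on the clone, split at ITR/cargo bounds."""

    clone_interval: tuple[int, int]
    vector_interval: tuple[int, int]
    strand: str
    kind: str  # "itr" | "cargo"
    identity: float


@dataclass
class ArchitectureCall:
    clone_id: str
    type: str
    itr_count: int
    cargo_coverage: float
    vector_copies: int
    microhomology_left: int
    microhomology_right: int
    host_indel: int
    blocks: list[VectorBlock] = field(default_factory=list)


def microhomology(host_terminus: str, vector_terminus: str) -> int:
    """Longest exact overlap across a junction.

    Both termini are oriented toward the junction: the host terminus ends
    at it, the vector terminus begins at it.  Returns the largest ``k``
    with ``host_terminus[-k:] == vector_terminus[:k]`` (0 when none).
    """
    if not host_terminus or not vector_terminus:
        raise ValueError("termini must be non-empty")
    host_terminus = host_terminus.upper()
    vector_terminus = vector_terminus.upper()
    for k in range(min(len(host_terminus), len(vector_terminus)), 0, -1):
        if host_terminus[-k:] == vector_terminus[:k]:
            return k
    return 0


def tile_vector_blocks(
    clone: str,
    vector: VectorGenome,
    params: AlignParams | None = None,
    thresholds: ArchitectureThresholds | None = None,
) -> list[VectorBlock]:
    """Greedy non-overlapping tiling of vector alignments on a clone.

    The best local alignment is taken, its clone span masked, and the
    search repeated until no block reaches ``min_block_score``.  Each
    block is then decomposed at the vector's ITR/cargo boundaries so a
    full-length match yields ITR + cargo + ITR sub-blocks.  Blocks are
    returned in clone order.
    """
    params = params or AlignParams()
    th = thresholds or ArchitectureThresholds()
    masked = list(clone.upper())
    raw = []
    while True:
        seg = local_align("".join(masked), vector.sequence, params, ref_id=vector.name)
        if seg is None or seg.score < th.min_block_score:
            break
        if seg.identity < 0.75:
            break
        raw.append(seg)
        a, b = seg.read_interval
        masked[a:b] = "N" * (b - a)
    blocks = []
    for seg in raw:
        blocks.extend(_decompose(seg, vector))
    blocks.sort(key=lambda b: b.clone_interval)
    return blocks


def _decompose(seg: AlignmentSegment, vector: VectorGenome) -> list[VectorBlock]:
    """Split an aligned segment at ITR/cargo boundaries (vector coords).

    Clone coordinates of the splits are interpolated linearly within the
    segment, which is exact for gap-free blocks and off by at most the
    indel count otherwise.
    """
    vlo, vhi = seg.ref_interval
    clo, chi = seg.read_interval
    bounds = sorted(
        {vlo, vhi}
        | {b for iv in vector.itr_intervals() for b in iv if vlo < b < vhi}
    )
    out = []
    span_v = vhi - vlo or 1
    span_c = chi - clo
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = (lo + hi) / 2
        kind = "itr" if vector.in_itr(int(mid)) else "cargo"
        if seg.strand == "+":
            c0 = clo + round((lo - vlo) / span_v * span_c)
            c1 = clo + round((hi - vlo) / span_v * span_c)
        else:
            c0 = clo + round((vhi - hi) / span_v * span_c)
            c1 = clo + round((vhi - lo) / span_v * span_c)
        out.append(
            VectorBlock((c0, c1), (lo, hi), seg.strand, kind, seg.identity)
        )
    return out


def detect_concatemer(blocks: list[VectorBlock], vector: VectorGenome) -> int:
    """Number of vector copies implied by cargo blocks along the clone.

    Cargo blocks that continue colinearly (vector coordinates advancing in
    clone order) belong to one copy; a cargo block that restarts or
    overlaps the previous copy's vector span opens a new copy.  ITR-only
    repeats count as junction ITRs, not extra copies.  Returns 0 for
    ITR-only integrants.
    """
    cargo = [b for b in blocks if b.kind == "cargo"]
    if not cargo:
        return 0
    copies = 1
    prev = cargo[0]
    for b in cargo[1:]:
        colinear = (
            b.strand == prev.strand
            and (
                (b.strand == "+" and b.vector_interval[0] >= prev.vector_interval[1] - 5)
                or (b.strand == "-" and b.vector_interval[1] <= prev.vector_interval[0] + 5)
            )
        )
        if not colinear:
            copies += 1
        prev = b
    return copies


def _flank_anchor(clone: str, flank: str, side: str, params: AlignParams, min_nt: int = 20):
    """Locate a host flank at a clone end; returns (clone_edge, flank_edge)
    as the junction-side coordinates, or None when absent."""
    seg = local_align(clone, flank, params, ref_id=f"flank_{side}")
    if seg is None or seg.strand != "+" or seg.read_span < min_nt:
        return None
    if side == "left":
        # flank must sit at the clone start; junction at its right edge
        if seg.read_interval[0] > 10:
            return None
        return seg.read_interval[1], seg.ref_interval[1]
    if seg.read_interval[1] < len(clone) - 10:
        return None
    return seg.read_interval[0], seg.ref_interval[0]


def classify_clone(
    clone: str,
    vector: VectorGenome,
    locus_flanks: tuple[str, str],
    clone_id: str = "clone",
    params: AlignParams | None = None,
    thresholds: ArchitectureThresholds | None = None,
) -> ArchitectureCall:
    """Classify one full-length integrant clone.

    ``locus_flanks`` are the reference host sequences immediately left and
    right of the cut.  The clone must begin and end in host flank
    (>= ``min_flank_nt`` each); otherwise it is unclassifiable.
    """
    params = params or AlignParams()
    th = thresholds or ArchitectureThresholds()
    clone = clone.upper()
    left_flank, right_flank = locus_flanks[0].upper(), locus_flanks[1].upper()

    left = _flank_anchor(clone, left_flank, "left", params, th.min_flank_nt)
    right = _flank_anchor(clone, right_flank, "right", params, th.min_flank_nt)
    if left is None or right is None:
        return ArchitectureCall(clone_id, "unclassifiable", 0, 0.0, 0, 0, 0, 0)
    left_end, left_flank_end = left
    right_start, right_flank_start = right
    host_indel = (left_flank_end - len(left_flank)) + (-right_flank_start)

    insert = clone[left_end:right_start]
    if len(insert) == 0:
        return ArchitectureCall(
            clone_id, "no_vector", 0, 0.0, 0, 0, 0, host_indel
        )
    blocks = [
        VectorBlock(
            (b.clone_interval[0] + left_end, b.clone_interval[1] + left_end),
            b.vector_interval,
            b.strand,
            b.kind,
            b.identity,
        )
        for b in tile_vector_blocks(insert, vector, params, th)
    ]

    itr_blocks = [
        b
        for b in blocks
        if b.kind == "itr"
        and b.vector_interval[1] - b.vector_interval[0] >= th.min_itr_block
        and b.identity >= th.min_itr_identity
    ]
    cargo_cov = np.zeros(vector.cargo_interval[1] - vector.cargo_interval[0], bool)
    clo = vector.cargo_interval[0]
    for b in blocks:
        if b.kind == "cargo":
            cargo_cov[b.vector_interval[0] - clo : b.vector_interval[1] - clo] = True
    coverage = float(cargo_cov.mean()) if cargo_cov.size else 0.0
    itr_count = _count_itrs(itr_blocks)
    copies = detect_concatemer(blocks, vector)

    mh_left = mh_right = 0
    if blocks:
        first, last = blocks[0], blocks[-1]
        w = 20
        # termini are taken at the vector block edges: the host terminus ends
        # where vector sequence begins, and vice versa on the right
        host_l = clone[max(0, first.clone_interval[0] - w) : first.clone_interval[0]]
        vec_l = clone[first.clone_interval[0] : first.clone_interval[0] + w]
        if host_l and vec_l:
            mh_left = microhomology(host_l, vec_l)
        vec_r = clone[max(0, last.clone_interval[1] - w) : last.clone_interval[1]]
        host_r = clone[last.clone_interval[1] : last.clone_interval[1] + w]
        if vec_r and host_r:
            mh_right = microhomology(vec_r, host_r)

    if not blocks:
        type_ = "no_vector"
    elif not itr_blocks:
        type_ = "unclassifiable"
    elif copies >= 2:
        type_ = "concatemer"
    elif coverage >= th.full_cargo_coverage:
        type_ = "type1_full_both_itrs" if itr_count >= 2 else "type2_full_one_itr"
    elif coverage < th.itr_only_coverage and int(cargo_cov.sum()) < th.itr_only_max_nt:
        type_ = "type3_itr_only"
    else:
        type_ = "type4_partial_one_itr"

    return ArchitectureCall(
        clone_id=clone_id,
        type=type_,
        itr_count=itr_count,
        cargo_coverage=coverage,
        vector_copies=copies,
        microhomology_left=mh_left,
        microhomology_right=mh_right,
        host_indel=host_indel,
        blocks=blocks,
    )


def _count_itrs(itr_blocks: list[VectorBlock]) -> int:
    """Distinct ITR copies along the clone.

    Decomposition merges the contiguous parts of one aligned segment, so
    each surviving ITR block is a separate ITR occurrence on the clone.
    """
    return len(itr_blocks)


@dataclass
class CoverageProfile:
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def vector_coverage_profile(calls, vector: VectorGenome) -> CoverageProfile:
    """Per-vector-nucleotide presence counts across clones or fusion calls.

    Each ArchitectureCall contributes 1 at every vector position covered by
    its blocks (concatemer copies stack); FusionCall-like objects with a
    ``vector_segment`` contribute their aligned vector interval.  The
    profile is computed only over observed blocks, so short-read inputs
    yield the junction-biased profile such data can support.
    """
    counts = np.zeros(len(vector), dtype=int)
    for call in calls:
        if hasattr(call, "blocks"):
            for b in call.blocks:
                counts[b.vector_interval[0] : b.vector_interval[1]] += 1
        elif hasattr(call, "vector_segment"):
            lo, hi = call.vector_segment.ref_interval
            counts[lo:hi] += 1
    return CoverageProfile(counts)
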