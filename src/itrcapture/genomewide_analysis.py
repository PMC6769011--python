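"""Genome-wide AAV integration-site calling from ITR-primer-anchored reads.

Reads from a GUIDE-seq-style library begin with an ITR primer, continue
through unique ITR sequence, and cross into the host genome at the
integration breakpoint.  Site calling aligns each read to the vector,
maps the non-vector remainder to the host, and applies two curation
filters that automate the study design's manual exclusions:

* **shared-homology filter** — a putative site is rejected when its host
  flank matches vector sequence (vector-borne promoters and similar
  elements recruit reads to homologous host loci, producing false sites);
* **ITR-evidence filter** — a site is rejected unless its vector segment
  extends beyond the primer binding site into unique ITR sequence, which
  removes primer-only amplification artifacts.

Purely episomal reads (vector only, no host) never become sites, and
reads whose host remainder maps equally well to multiple loci are dropped
as ambiguous.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

from .fusion_detection import AlignmentSegment, AlignParams, local_align, scan_hits
from .vector_model import TargetLocus, VectorGenome, revcomp

__all__ = [
    "GeneModel",
    "HostGenome",
    "RawSite",
    "CuratedSite",
    "ConditionSummary",
    "RecurrenceTable",
    "call_sites",
    "filter_shared_homology",
    "filter_itr_evidence",
    "annotate_sites",
    "cluster_unique_sites",
    "summarize_condition",
    "recurrence",
]

CATEGORY_PRECEDENCE = ["exonic", "promoter", "downstream", "intronic", "intergenic"]


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    start: int  # 0-based half-open, plus strand
    end: int
    exons: tuple[tuple[int, int], ...]


@dataclass
class HostGenome:
    """Host chromosome sequences plus gene models for annotation."""

    sequences: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)
    promoter_extent: int = 1000
    downstream_extent: int = 1000
    _trees: dict[str, dict[str, IntervalTree]] = field(default_factory=dict, repr=False)

    def _tree(self, chrom: str) -> dict[str, IntervalTree]:
        if chrom not in self._trees:
            trees = {c: IntervalTree() for c in ("exonic", "promoter", "downstream", "intronic")}
            n = len(self.sequences[chrom])
            for g in self.genes:
                if g.chrom != chrom:
                    continue
                for lo, hi in g.exons:
                    trees["exonic"][lo:hi] = g.name
                if g.start < g.end:
                    trees["intronic"][g.start:g.end] = g.name
                plo, phi = max(0, g.start - self.promoter_extent), g.start
                if plo < phi:
                    trees["promoter"][plo:phi] = g.name
                dlo, dhi = g.end, min(n, g.end + self.downstream_extent)
                if dlo < dhi:
                    trees["downstream"][dlo:dhi] = g.name
            self._trees[chrom] = trees
        return self._trees[chrom]

    def category_of(self, chrom: str, pos: int) -> str:
        if chrom not in self.sequences:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < len(self.sequences[chrom]):
            raise ValueError(f"position {pos} outside {chrom} bounds")
        trees = self._tree(chrom)
        for cat in ("exonic", "promoter", "downstream", "intronic"):
            if trees[cat][pos]:
                return cat
        return "intergenic"


@dataclass
class RawSite:
    chrom: str
    breakpoint: int
    strand: str
    supporting_read_ids: list[str]
    vector_segment: AlignmentSegment
    host_flank: str

    @property
    def read_count(self) -> int:
        return len(self.supporting_read_ids)


@dataclass
class CuratedSite:
    chrom: str
    breakpoint: int
    strand: str
    supporting_read_ids: list[str]
    vector_segment: AlignmentSegment
    host_flank: str
    category: str = ""
    read_count: int = 0
    normalized_count: float = 0.0
    filter_status: str = "pass"
    condition_id: str = ""

    @classmethod
    def from_raw(cls, raw: RawSite, **kw) -> "CuratedSite":
        return cls(
            chrom=raw.chrom,
            breakpoint=raw.breakpoint,
            strand=raw.strand,
            supporting_read_ids=list(raw.supporting_read_ids),
            vector_segment=raw.vector_segment,
            host_flank=raw.host_flank,
            read_count=raw.read_count,
            **kw,
        )


@dataclass
class ReadAccounting:
    n_input: int = 0
    n_no_primer: int = 0
    n_episomal: int = 0
    n_ambiguous_host: int = 0
    n_unmapped_remainder: int = 0
    n_site_reads: int = 0

    def check(self):
        assert self.n_input == (
            self.n_no_primer
            + self.n_episomal
            + self.n_ambiguous_host
            + self.n_unmapped_remainder
            + self.n_site_reads
        )


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def call_sites(
    reads,
    vector: VectorGenome,
    host: HostGenome,
    primer: str,
    params: AlignParams | None = None,
    max_primer_mismatches: int = 2,
    flank_halfwidth: int = 40,
    accounting: ReadAccounting | None = None,
) -> list[RawSite]:
    """Call raw integration sites from ITR-primer-anchored reads.

    ``reads`` yields ``(read_id, sequence)``.  Reads lacking the primer at
    the 5' end (<= ``max_primer_mismatches``) are dropped; the read is
    aligned to the vector, and the remaining 3' tail (>= ``min_clip_len``)
    is scanned against every host chromosome.  A unique best host hit
    defines the breakpoint (host coordinate of the first host base at the
    junction); score-tied hits are discarded as ambiguous and vector-only
    reads as episomal.  Reads are grouped into one RawSite per exact
    (chrom, breakpoint, strand).
    """
    params = params or AlignParams()
    acct = accounting if accounting is not None else ReadAccounting()
    plen = len(primer)
    grouped: dict[tuple, list] = defaultdict(list)
    for item in reads:
        read_id, seq = item
        seq = seq.upper()
        acct.n_input += 1
        if len(seq) < plen or _mismatches(seq[:plen], primer.upper()) > max_primer_mismatches:
            acct.n_no_primer += 1
            continue
        vseg = local_align(seq, vector.sequence, params, ref_id=vector.name)
        if vseg is None or vseg.read_interval[0] > 5:
            # primer matched but no anchored vector alignment: treat the
            # whole post-primer tail as the host remainder
            v_end = plen
            vseg = None
        else:
            v_end = vseg.read_interval[1]
        remainder = seq[v_end:]
        if len(remainder) < params.min_clip_len:
            acct.n_episomal += 1
            continue
        best_ed, hits = None, []
        hit_chrom = None
        for chrom, cseq in host.sequences.items():
            ed, locs = scan_hits(remainder, cseq)
            if ed is None:
                continue
            if best_ed is None or ed < best_ed:
                best_ed, hits, hit_chrom = ed, [(chrom, *l) for l in locs], chrom
            elif ed == best_ed:
                hits.extend((chrom, *l) for l in locs)
        if best_ed is None:
            acct.n_unmapped_remainder += 1
            continue
        if len(hits) != 1:
            acct.n_ambiguous_host += 1
            continue
        chrom, hstart, hend, strand = hits[0]
        # junction-proximal host base: the first remainder base in host coords
        breakpoint = hstart if strand == "+" else hend - 1
        acct.n_site_reads += 1
        if vseg is None:
            vseg = AlignmentSegment(
                ref_id=vector.name,
                ref_interval=(0, 0),
                read_interval=(0, plen),
                strand="+",
                identity=1.0,
                score=0.0,
            )
        grouped[(chrom, breakpoint, strand)].append((read_id, vseg))
    acct.check()

    sites = []
    for (chrom, breakpoint, strand), members in sorted(grouped.items()):
        cseq = host.sequences[chrom]
        lo = max(0, breakpoint - flank_halfwidth)
        hi = min(len(cseq), breakpoint + flank_halfwidth + 1)
        # keep the longest vector segment as the site's representative
        best_vseg = max((v for _, v in members), key=lambda v: v.read_span)
        sites.append(
            RawSite(
                chrom=chrom,
                breakpoint=breakpoint,
                strand=strand,
                supporting_read_ids=[r for r, _ in members],
                vector_segment=best_vseg,
                host_flank=cseq[lo:hi],
            )
        )
    return sites


# -- curation filters --------------------------------------------------------


def filter_shared_homology(
    sites,
    vector: VectorGenome,
    params: AlignParams | None = None,
    min_len: int = 20,
    min_identity: float = 0.90,
):
    """Fail sites whose host flank shares >= ``min_len`` nt at
    >= ``min_identity`` with any vector subsequence (either strand).

    The scan is ungapped: every ``min_len``-nt window of every
    flank-vs-vector diagonal (both strands) is tested for a match fraction
    >= ``min_identity``.  Gapped chaining of short coincidental matches is
    deliberately not counted as homology.
    """
    out = []
    for site in sites:
        cur = _as_curated(site)
        if cur.filter_status != "pass":
            out.append(cur)
            continue
        fail = _has_ungapped_match(
            cur.host_flank, vector.sequence, min_len, min_identity
        )
        cur.filter_status = "fail_shared_homology" if fail else "pass"
        out.append(cur)
    return out


def _has_ungapped_match(query: str, ref: str, min_len: int, min_identity: float) -> bool:
    import numpy as np

    need = int(np.ceil(min_len * min_identity))
    q0 = np.frombuffer(query.encode(), dtype=np.uint8)
    for r in (ref, revcomp(ref)):
        r0 = np.frombuffer(r.encode(), dtype=np.uint8)
        eq = q0[:, None] == r0[None, :]
        n, m = eq.shape
        if min(n, m) < min_len:
            continue
        for d in range(-(n - min_len), m - min_len + 1):
            diag = np.diagonal(eq, offset=d)
            if diag.size < min_len:
                continue
            c = np.convolve(diag.astype(np.int32), np.ones(min_len, dtype=np.int32), "valid")
            if (c >= need).max():
                return True
    return False


def filter_itr_evidence(
    sites,
    vector: VectorGenome,
    primer_sites=None,
    min_extra: int = 10,
):
    """Fail sites whose vector evidence does not extend >= ``min_extra`` nt
    beyond the primer binding site into unique ITR sequence."""
    primer_sites = primer_sites if primer_sites is not None else vector.primer_sites
    primer_intervals = [iv for _, iv, _ in primer_sites]
    out = []
    for site in sites:
        cur = _as_curated(site)
        if cur.filter_status != "pass":
            out.append(cur)
            continue
        vlo, vhi = cur.vector_segment.ref_interval
        extra = 0
        for pos in range(vlo, vhi):
            if not vector.in_itr(pos):
                continue
            if any(lo <= pos < hi for lo, hi in primer_intervals):
                continue
            extra += 1
        cur.filter_status = "pass" if extra >= min_extra else "fail_no_unique_itr"
        out.append(cur)
    return out


def _as_curated(site) -> CuratedSite:
    if isinstance(site, CuratedSite):
        return replace(site, supporting_read_ids=list(site.supporting_read_ids))
    return CuratedSite.from_raw(site)


def annotate_sites(sites, host: HostGenome):
    """Assign a genomic category to each site by precedence
    exonic > promoter > downstream > intronic > intergenic."""
    out = []
    for site in sites:
        cur = _as_curated(site)
        cur.category = host.category_of(cur.chrom, cur.breakpoint)
        out.append(cur)
    return out


# -- clustering, normalization, recurrence -----------------------------------


@dataclass
class ClusteredSite:
    chrom: str
    position: int  # read-count-weighted mode of member breakpoints
    read_count: int
    members: list
    category: str = ""


def cluster_unique_sites(sites, window: int = 50) -> list[ClusteredSite]:
    """Single-linkage clustering of breakpoints within ``window`` nt on the
    same chromosome; cluster position is the read-count-weighted mode."""
    by_chrom: dict[str, list] = defaultdict(list)
    for s in sites:
        by_chrom[s.chrom].append(s)
    clusters = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda s: s.breakpoint)
        block = [members[0]]
        for s in members[1:]:
            if s.breakpoint - block[-1].breakpoint <= window:
                block.append(s)
            else:
                clusters.append(_make_cluster(chrom, block))
                block = [s]
        clusters.append(_make_cluster(chrom, block))
    return clusters


def _make_cluster(chrom, members) -> ClusteredSite:
    support = Counter()
    for s in members:
        support[s.breakpoint] += s.read_count
    # weighted mode; ties to the smallest coordinate
    pos = min(sorted(support), key=lambda p: (-support[p], p))
    cats = Counter(getattr(s, "category", "") for s in members)
    return ClusteredSite(
        chrom=chrom,
        position=pos,
        read_count=sum(support.values()),
        members=list(members),
        category=cats.most_common(1)[0][0],
    )


def normalized_count(read_count: int, total_reads: int) -> float:
    """Reads per million total sequenced reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return read_count / total_reads * 1e6


@dataclass
class ConditionSummary:
    condition_id: str
    n_unique_sites: int
    n_integrant_reads: int
    total_reads: int
    normalized_integrant_reads: float
    category_proportions: dict[str, float]
    on_target_fraction: float | None
    clusters: list[ClusteredSite] = field(default_factory=list)

    def to_dict(self):
        d = dict(self.__dict__)
        d["clusters"] = [
            {"chrom": c.chrom, "position": c.position, "read_count": c.read_count,
             "category": c.category}
            for c in self.clusters
        ]
        return d


def summarize_condition(
    sites,
    total_reads: int,
    locus: TargetLocus | None = None,
    on_target_chrom: str | None = None,
    on_target_pos: int | None = None,
    on_target_halfwidth: int = 1000,
    window: int = 50,
    condition_id: str = "condition",
    min_reads: int = 1,
) -> ConditionSummary:
    """Per-condition summary over curated (passing) sites.

    The on-target fraction is the share of integrant reads whose cluster
    lies within ``on_target_halfwidth`` of the cut-site coordinate, over
    all integrant reads.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    passing = [s for s in sites if s.filter_status == "pass" and s.read_count >= min_reads]
    for s in passing:
        s.normalized_count = normalized_count(s.read_count, total_reads)
        s.condition_id = condition_id
    clusters = cluster_unique_sites(passing, window=window) if passing else []
    n_reads = sum(c.read_count for c in clusters)
    cats = Counter(c.category for c in clusters)
    n_clusters = len(clusters)
    cat_props = {
        cat: (cats.get(cat, 0) / n_clusters if n_clusters else 0.0)
        for cat in CATEGORY_PRECEDENCE
    }
    on_target = None
    if on_target_chrom is not None and on_target_pos is not None:
        on_reads = sum(
            c.read_count
            for c in clusters
            if c.chrom == on_target_chrom
            and abs(c.position - on_target_pos) <= on_target_halfwidth
        )
        on_target = on_reads / n_reads if n_reads else math.nan
    return ConditionSummary(
        condition_id=condition_id,
        n_unique_sites=n_clusters,
        n_integrant_reads=n_reads,
        total_reads=total_reads,
        normalized_integrant_reads=normalized_count(n_reads, total_reads),
        category_proportions=cat_props,
        on_target_fraction=on_target,
        clusters=clusters,
    )


@dataclass
class RecurrenceTable:
    entries: dict[tuple[str, int], set[str]]
    k: int = 3

    def recurrent_sites(self):
        return sorted(
            key for key, conds in self.entries.items() if len(conds) >= self.k
        )

    def is_recurrent(self, chrom: str, position: int, window: int = 50) -> bool:
        return any(
            c == chrom and abs(p - position) <= window
            for c, p in self.recurrent_sites()
        )


def recurrence(per_condition_clusters: dict[str, list], k: int = 3, window: int = 50) -> RecurrenceTable:
    """Cross-condition recurrence of clustered sites.

    ``per_condition_clusters`` maps condition id -> list of ClusteredSite.
    Clusters from all conditions are re-clustered with the same window;
    a joint site is recurrent when supported by >= ``k`` conditions.
    """
    tagged = []
    for cond, clusters in per_condition_clusters.items():
        for c in clusters:
            tagged.append((cond, c))
    entries: dict[tuple[str, int], set[str]] = {}
    by_chrom: dict[str, list] = defaultdict(list)
    for cond, c in tagged:
        by_chrom[c.chrom].append((cond, c))
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda t: t[1].position)
        block = [members[0]]
        for t in members[1:]:
            if t[1].position - block[-1][1].position <= window:
                block.append(t)
            else:
                _add_entry(entries, chrom, block)
                block = [t]
        _add_entry(entries, chrom, block)
    return RecurrenceTable(entries=entries, k=k)


def _add_entry(entries, chrom, block):
    support = Counter()
    for _, c in block:
        support[c.position] += c.read_count
    pos = min(sorted(support), key=lambda p: (-support[p], p))
    entries[(chrom, pos)] = {cond for cond, _ in block}
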