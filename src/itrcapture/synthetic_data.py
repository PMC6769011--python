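"""Synthetic read and clone generators with per-record ground truth.

Every generator is fully determined by its seed and emits a truth table
sufficient to score the downstream analyses.  The statistical structure
emulates MiSeq-style amplicon and junction libraries from a CRISPR/AAV
co-delivery experiment:

* amplicon reads carry NHEJ indels dominated by single-nucleotide events,
  and vector-fusion reads whose junctions sit at the cut site (98% within
  1 bp by default) with vector termini drawn from an ITR breakpoint
  distribution elevated in the b/c hairpin loops;
* genome-wide libraries are ITR-primer-anchored and include, besides true
  junction reads, the artifact classes the curation filters exist for:
  purely episomal vector reads, primer-only amplification products, reads
  from host loci sharing planted vector homology (decoys), and reads
  mapping ambiguously to repeated loci;
* full-length clones follow the four integration-type schematics plus
  concatemers, with configurable junction microhomology and host-flank
  indels.

The error model is independent per-base substitution at a constant rate
(no indel errors by default), with constant base quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fusion_detection import FastqRead
from .genomewide_analysis import GeneModel, HostGenome
from .vector_model import (
    AAV2_ITR,
    ITR_LENGTH,
    TargetLocus,
    VectorGenome,
    aav_lambda_465,
    revcomp,
    to_itr_local,
)

__all__ = [
    "SimConfig",
    "PlantedSite",
    "DecoyLocus",
    "simulate_amplicon_reads",
    "simulate_aavseq_reads",
    "simulate_clones",
    "make_toy_host",
    "make_toy_locus",
    "attach_itr_primer",
    "ITR_PRIMER_LOCAL",
    "plant_decoy_homology",
    "plant_repeat",
]

BASES = np.array(list("ACGT"))

#: ITR-local primer binding site in the 'a' stem; the 5' read anchor of the
#: genome-wide junction library.
ITR_PRIMER_LOCAL = (102, 122)

ARCHITECTURES = ("type1", "type2", "type3", "type4", "concatemer")


def _default_jitter() -> dict[int, float]:
    # 98% of junctions within 1 bp of the cut; rare offsets up to 5 bp
    return {0: 0.90, -1: 0.04, 1: 0.04, -3: 0.005, 3: 0.005, -5: 0.005, 5: 0.005}


def _default_mix() -> dict[str, float]:
    # 2:4:5:9 single-copy composition, no concatemers by default
    return {"type1": 0.10, "type2": 0.20, "type3": 0.25, "type4": 0.45, "concatemer": 0.0}


def default_itr_breakpoint_weights(hotspot_factor: float = 6.0) -> np.ndarray:
    """Per-nucleotide breakpoint weights over the shared ITR frame, with
    the internal-palindrome (b/c loop) block [20, 102) elevated."""
    w = np.ones(ITR_LENGTH)
    w[20:102] = hotspot_factor
    return w / w.sum()


@dataclass
class SimConfig:
    seed: int = 1
    n_reads: int = 2000
    read_length: int = 150
    paired: bool = False
    substitution_error_rate: float = 0.001
    indel_error_rate: float = 0.0
    edited_fraction: float = 0.5
    capture_fraction: float = 0.25
    indel_geometric_p: float = 0.6
    deletion_bias: float = 0.6  # probability an NHEJ indel is a deletion
    fusion_flank_deletion_prob: float = 0.0
    itr_at_junction_fraction: float = 0.835
    architecture_mix: dict[str, float] = field(default_factory=_default_mix)
    junction_jitter: dict[int, float] = field(default_factory=_default_jitter)
    itr_breakpoint_weights: np.ndarray = field(
        default_factory=default_itr_breakpoint_weights
    )
    microhomology_rate: float = 0.3
    host_indel_rate: float = 0.5
    #: redraw fusion breakpoints whose insert start matches the host base at
    #: the junction, making the planted junction position identifiable (the
    #: canonical host-proximal placement then equals the planted one)
    avoid_junction_microhomology: bool = False
    non_vector_fraction: float = 0.0
    exact_counts: bool = False

    def __post_init__(self):
        for name, probs in (
            ("architecture_mix", self.architecture_mix.values()),
            ("junction_jitter", self.junction_jitter.values()),
        ):
            total = sum(probs)
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        w = np.asarray(self.itr_breakpoint_weights, dtype=float)
        if w.shape != (ITR_LENGTH,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("itr_breakpoint_weights must be 145 non-negative weights")
        self.itr_breakpoint_weights = w / w.sum()
        for name, p in (
            ("substitution_error_rate", self.substitution_error_rate),
            ("edited_fraction", self.edited_fraction),
            ("capture_fraction", self.capture_fraction),
            ("itr_at_junction_fraction", self.itr_at_junction_fraction),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def _random_dna(rng, n: int) -> str:
    return "".join(rng.choice(BASES, n))


def _add_substitutions(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _draw_counts(rng, n: int, probs: np.ndarray, exact: bool) -> np.ndarray:
    if exact:
        counts = np.floor(probs * n).astype(int)
        # distribute the remainder to the largest fractional parts
        rem = n - counts.sum()
        order = np.argsort(-(probs * n - counts))
        counts[order[:rem]] += 1
        return counts
    return rng.multinomial(n, probs)


def make_toy_locus(seed: int = 7, amplicon_length: int = 200, name: str = "toy_locus") -> TargetLocus:
    """Deterministic toy amplicon with the protospacer placed so the cut
    (3 bp upstream of the PAM) falls at position 80 of 200."""
    rng = np.random.default_rng(seed)
    amp = _random_dna(rng, amplicon_length)
    s = 63  # protospacer [63, 83), PAM [83, 86) -> cut at 80
    return TargetLocus(name, amp, (s, s + 20), (s + 20, s + 23), "+")


def attach_itr_primer(
    vector: VectorGenome, local_interval: tuple[int, int] = ITR_PRIMER_LOCAL
) -> VectorGenome:
    """Annotate the ITR primer binding site on both ITR copies."""
    lo, hi = local_interval
    seq = AAV2_ITR[lo:hi]
    n = len(vector)
    sites = [
        (seq, (lo, hi), "+"),
        (seq, (n - hi, n - lo), "-"),
    ]
    return replace(vector, primer_sites=sites)


# -- amplicon reads ----------------------------------------------------------


def simulate_amplicon_reads(
    config: SimConfig, locus: TargetLocus, vector: VectorGenome
):
    """Simulate merged-orientation amplicon reads (or pairs) with truth.

    Returns ``(reads, truth)``.  In unpaired mode each record is one
    molecule-spanning read (the merged-pair equivalent); in paired mode
    ``reads`` is a list of (R1, R2) tuples read from the molecule ends.
    Truth columns: read_id, planted_class, indel_size, junction_offset,
    vector_breakpoint (vector coordinate), itr_local, insert_length.
    """
    rng = np.random.default_rng(config.seed)
    cut = locus.cut_point
    amp = locus.amplicon
    n = config.n_reads
    n_edited = (
        round(config.edited_fraction * n)
        if config.exact_counts
        else rng.binomial(n, config.edited_fraction)
    )
    n_fusion = (
        round(config.capture_fraction * n_edited)
        if config.exact_counts
        else rng.binomial(n_edited, config.capture_fraction)
    )
    classes = (
        ["vector_fusion"] * n_fusion
        + ["small_indel"] * (n_edited - n_fusion)
        + ["unmodified"] * (n - n_edited)
    )
    rng.shuffle(classes)

    jit_offsets = np.array(list(config.junction_jitter.keys()))
    jit_probs = np.array(list(config.junction_jitter.values()))
    bp_weights = config.itr_breakpoint_weights
    vlen = len(vector)

    reads, rows = [], []
    for i, cls in enumerate(classes):
        read_id = f"amp_{i:06d}"
        offset = indel_size = insert_len = 0
        vb = itr_local = -1
        if cls == "unmodified":
            mol = amp
        elif cls == "small_indel":
            offset = int(rng.choice(jit_offsets, p=jit_probs))
            size = 1 + int(rng.geometric(config.indel_geometric_p) - 1)
            size = min(size, 20)
            pos = cut + offset
            if rng.random() < config.deletion_bias:
                indel_size = -size
                mol = amp[:pos] + amp[pos + size :]
            else:
                indel_size = size
                mol = amp[:pos] + _random_dna(rng, size) + amp[pos:]
        else:  # vector_fusion
            offset = int(rng.choice(jit_offsets, p=jit_probs))
            pos = cut + offset
            insert_len = int(rng.integers(40, 81))
            itr_junction = rng.random() < config.itr_at_junction_fraction
            if itr_junction:
                itr_local = int(rng.choice(ITR_LENGTH, p=bp_weights))
                # the junction-proximal terminus is the insert start; on the
                # right ITR copy the insert runs toward the vector end, so
                # positions too close to it map to the left copy instead
                side = (
                    "right"
                    if itr_local >= insert_len - 1 and rng.random() < 0.5
                    else "left"
                )
                vb = itr_local if side == "left" else vlen - 1 - itr_local
            else:
                clo, chi = vector.cargo_interval
                vb = int(rng.integers(clo, chi - insert_len))
            if config.avoid_junction_microhomology:
                for _ in range(50):
                    if vector.sequence[vb] != amp[pos]:
                        break
                    vb = (vb + 1) % (vlen - insert_len)
                itr_local = (
                    to_itr_local(vb, vector)[1]
                    if to_itr_local(vb, vector)[0] != "none"
                    else -1
                )
            insert = vector.sequence[vb : vb + insert_len]
            left_arm = amp[:pos]
            if rng.random() < config.fusion_flank_deletion_prob:
                k = min(int(rng.geometric(0.5)), 5, len(left_arm))
                left_arm = left_arm[: len(left_arm) - k]
                pos -= k
            mol = left_arm + insert + amp[cut + offset :]
            indel_size = insert_len
            # junction placement under microhomology is canonicalized to the
            # host-proximal edge: chance matches between the insert start and
            # the host bases after the junction shift the observable junction
            m = 0
            right_arm = amp[pos:]
            while (
                m < insert_len - 1
                and m < len(right_arm)
                and insert[m] == right_arm[m]
            ):
                m += 1
            offset = (pos - cut) + m
            vb += m
        mol = _add_substitutions(rng, mol, config.substitution_error_rate)
        if config.paired:
            r1 = FastqRead(read_id, mol[: config.read_length])
            r2 = FastqRead(read_id, revcomp(mol)[: config.read_length])
            reads.append((r1, r2))
        else:
            reads.append(FastqRead(read_id, mol))
        rows.append(
            {
                "read_id": read_id,
                "planted_class": cls,
                "indel_size": indel_size,
                "junction_offset": offset,
                "vector_breakpoint": vb,
                "itr_local": itr_local,
                "itr_junction": cls == "vector_fusion" and itr_local >= 0,
                "insert_length": insert_len,
            }
        )
    return reads, pd.DataFrame(rows)


# -- genome-wide (AAV-Seq style) reads --------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    position: int
    strand: str = "+"
    n_reads: int = 5


@dataclass(frozen=True)
class DecoyLocus:
    chrom: str
    position: int
    homology_length: int = 30
    n_reads: int = 5


def plant_decoy_homology(
    host: HostGenome, vector: VectorGenome, decoy: DecoyLocus
) -> None:
    """Overwrite host sequence at the decoy breakpoint with a vector-derived
    stretch so reads from this locus carry shared vector homology."""
    clo, chi = vector.cargo_interval
    # mid-cargo source so the homologous stretch is not contiguous with the
    # ITR tail carried by the reads themselves
    off = min(50, max(0, (chi - clo) - decoy.homology_length))
    src = vector.sequence[clo + off : clo + off + decoy.homology_length]
    seq = host.sequences[decoy.chrom]
    p = decoy.position
    host.sequences[decoy.chrom] = seq[:p] + src + seq[p + len(src) :]
    host._trees.clear()


def plant_repeat(host: HostGenome, chrom_a: str, pos_a: int, chrom_b: str, pos_b: int, length: int = 60) -> None:
    """Copy a host stretch to a second locus, creating a mapping ambiguity."""
    src = host.sequences[chrom_a][pos_a : pos_a + length]
    seq = host.sequences[chrom_b]
    host.sequences[chrom_b] = seq[:pos_b] + src + seq[pos_b + length :]
    host._trees.clear()


def simulate_aavseq_reads(
    config: SimConfig,
    host: HostGenome,
    vector: VectorGenome,
    planted_sites: list[PlantedSite],
    decoys: list[DecoyLocus] = (),
    n_episomal: int = 20,
    n_primer_only: int = 10,
    ambiguous_loci: list[tuple[str, int, int]] = (),
    host_read_nt: int = 100,
):
    """Simulate an ITR-primer-anchored genome-wide junction library.

    True junction reads are primer + unique ITR + host sequence starting at
    the planted breakpoint.  Decoy loci must already carry planted vector
    homology (see :func:`plant_decoy_homology`); their reads have the same
    structure.  Episomal reads continue from the primer into vector
    sequence only; primer-only artifacts jump straight from the primer
    into the host.  ``ambiguous_loci`` emit reads from repeated sequence
    planted with :func:`plant_repeat`.

    Returns ``(reads, truth)`` with truth columns read_id, kind, chrom,
    position.
    """
    rng = np.random.default_rng(config.seed + 1)
    for d in decoys:
        for s in planted_sites:
            if d.chrom == s.chrom and abs(d.position - s.position) < 200:
                raise ValueError("decoy locus overlaps a planted true site")
    lo, hi = ITR_PRIMER_LOCAL
    primer = AAV2_ITR[lo:hi]
    itr_tail = AAV2_ITR[hi:ITR_LENGTH]
    reads, rows = [], []
    counter = 0

    def emit(kind, seq, chrom="", pos=-1):
        nonlocal counter
        read_id = f"gw_{counter:06d}"
        counter += 1
        seq = _add_substitutions(rng, seq, config.substitution_error_rate)
        reads.append(FastqRead(read_id, seq))
        rows.append({"read_id": read_id, "kind": kind, "chrom": chrom, "position": pos})

    for site in planted_sites:
        cseq = host.sequences[site.chrom]
        for _ in range(site.n_reads):
            if site.strand == "+":
                hpart = cseq[site.position : site.position + host_read_nt]
            else:
                hpart = revcomp(cseq[site.position - host_read_nt + 1 : site.position + 1])
            emit("true_site", primer + itr_tail + hpart, site.chrom, site.position)
    for decoy in decoys:
        cseq = host.sequences[decoy.chrom]
        for _ in range(decoy.n_reads):
            hpart = cseq[decoy.position : decoy.position + host_read_nt]
            emit("decoy", primer + itr_tail + hpart, decoy.chrom, decoy.position)
    for _ in range(n_primer_only):
        chrom = sorted(host.sequences)[int(rng.integers(len(host.sequences)))]
        pos = int(rng.integers(1000, len(host.sequences[chrom]) - 1000))
        emit("primer_only", primer + host.sequences[chrom][pos : pos + host_read_nt], chrom, pos)
    for _ in range(n_episomal):
        start = lo
        emit("episomal", vector.sequence[start : start + config.read_length])
    for chrom, pos, n_r in ambiguous_loci:
        for _ in range(n_r):
            hpart = host.sequences[chrom][pos : pos + 50]
            emit("ambiguous", primer + itr_tail + hpart, chrom, pos)
    return reads, pd.DataFrame(rows)


# -- full-length clones ------------------------------------------------------


def _clone_insert(rng, vector: VectorGenome, arch: str) -> str:
    seq = vector.sequence
    n = len(seq)
    clo, chi = vector.cargo_interval
    cargo_len = chi - clo
    if arch == "type1":
        return seq
    if arch == "type2":
        return seq[: chi] if rng.random() < 0.5 else seq[clo:]
    if arch == "type3":
        length = int(rng.integers(40, 121))
        start = int(rng.integers(0, ITR_LENGTH - length + 1))
        return seq[start : start + length]
    if arch == "type4":
        frac = rng.uniform(0.15, 0.75)
        return seq[: ITR_LENGTH + int(frac * cargo_len)]
    if arch == "concatemer":
        return seq + seq
    raise ValueError(f"unknown architecture {arch!r}")


def simulate_clones(
    config: SimConfig, vector: VectorGenome, locus_flanks: tuple[str, str]
):
    """Simulate full-length integrant clones per the type schematics.

    Returns ``(clones, truth)``; clones are (clone_id, sequence) pairs.
    Truth columns: clone_id, planted_type, microhomology_left (planted
    minimum), host_deletion_left/right.
    """
    rng = np.random.default_rng(config.seed + 2)
    left0, right0 = locus_flanks[0].upper(), locus_flanks[1].upper()
    mix_names = list(config.architecture_mix.keys())
    probs = np.array([config.architecture_mix[k] for k in mix_names], dtype=float)
    n_vec = config.n_reads
    n_plain = (
        round(config.non_vector_fraction * n_vec)
        if config.exact_counts
        else rng.binomial(n_vec, config.non_vector_fraction)
    )
    n_arch = n_vec - n_plain
    counts = _draw_counts(rng, n_arch, probs, config.exact_counts)
    archs = [name for name, c in zip(mix_names, counts) for _ in range(c)]
    archs += ["no_vector"] * n_plain
    rng.shuffle(archs)

    clones, rows = [], []
    for i, arch in enumerate(archs):
        clone_id = f"clone_{i:04d}"
        left, right = left0, right0
        del_l = del_r = 0
        if rng.random() < config.host_indel_rate:
            del_l = min(int(rng.geometric(0.4)), 8)
            left = left[: len(left) - del_l]
        if rng.random() < config.host_indel_rate:
            del_r = min(int(rng.geometric(0.4)), 8)
            right = right[del_r:]
        mh = 0
        if arch == "no_vector":
            seq = left + right
        else:
            insert = _clone_insert(rng, vector, arch)
            if rng.random() < config.microhomology_rate:
                mh = int(rng.integers(2, 7))
                left = left[:-mh] + insert[:mh]
            seq = left + insert + right
        seq = _add_substitutions(rng, seq, config.substitution_error_rate)
        clones.append((clone_id, seq))
        rows.append(
            {
                "clone_id": clone_id,
                "planted_type": arch,
                "microhomology_left": mh,
                "host_deletion_left": -del_l,
                "host_deletion_right": -del_r,
            }
        )
    return clones, pd.DataFrame(rows)


# -- toy host genome ---------------------------------------------------------


def make_toy_host(
    seed: int = 42,
    n_chroms: int = 5,
    chrom_length: int = 100_000,
    genes_per_chrom: int = 4,
) -> HostGenome:
    """Desk-scale synthetic host: seeded random chromosomes with toy gene
    models (exons, 1-kb promoters and downstream regions) spaced so an
    intergenic fraction remains."""
    rng = np.random.default_rng(seed)
    sequences = {}
    genes = []
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        sequences[chrom] = _random_dna(rng, chrom_length)
        spacing = chrom_length // (genes_per_chrom + 1)
        for g in range(genes_per_chrom):
            start = spacing * (g + 1) + int(rng.integers(0, 2000))
            length = int(rng.integers(3000, 8000))
            end = min(start + length, chrom_length - 2000)
            n_ex = int(rng.integers(2, 5))
            bounds = np.sort(rng.choice(np.arange(start, end, 50), 2 * n_ex, replace=False))
            exons = tuple(
                (int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_ex)
            )
            exons = tuple((a, b) for a, b in exons if b > a)
            genes.append(GeneModel(f"{chrom}_gene{g + 1}", chrom, start, end, exons))
    return HostGenome(sequences=sequences, genes=genes)
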