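"""Models of AAV vector genomes, ITR structure and CRISPR target loci.

An AAV vector genome is a cargo cassette flanked by two 145-nt inverted
terminal repeats (ITRs).  Each ITR folds into a T-shaped hairpin built from
palindromic sub-regions: the long ``a``/``a'`` stem, the two small internal
palindromes ``b``/``b'`` and ``c``/``c'`` (the hairpin "loops"), and the
non-palindromic ``d`` region that connects the ITR to the cargo.  The two
internal palindromes occur in either of two sequence orders, called *flip*
and *flop*, which arise interchangeably during replication.

CRISPR target loci are modelled as an amplicon with protospacer and PAM
coordinates; the Cas9 blunt cut falls 3 bp upstream of the PAM and is
stored as a 0-based insertion coordinate (the first base 3' of the cut on
the amplicon plus strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AAV2_ITR",
    "ITR_LENGTH",
    "ItrModel",
    "VectorGenome",
    "TargetLocus",
    "revcomp",
    "assemble_vector",
    "locate_cut_site",
    "to_itr_local",
    "region_of",
    "aav_lambda_465",
    "full_length_vector",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


#: Canonical AAV2 inverted terminal repeat, 145 nt, flip conformation.
AAV2_ITR = (
    "TTGGCCACTCCCTCTCTGCGCGCTCGCTCGCTCACTGAGGCCGGGCGACCAAAGGTCGCC"
    "CGACGCCCGGGCTTTGCCCGGGCGGCCTCAGTGAGCGAGCGAGCGCGCAGAGAGGGAGTG"
    "GCCAACTCCATCACTAGGGGTTCCT"
)

ITR_LENGTH = 145

# ITR-local sub-region boundaries (0-based half-open).  The a/a' stem flanks
# the two 41-nt internal palindrome blocks whose order distinguishes flip
# from flop; d is the unique (non-palindromic) segment next to the cargo.
_DEFAULT_BLOCKS = {
    "a_prime": (0, 20),
    "block1": (20, 61),
    "block2": (61, 102),
    "a": (102, 125),
    "d": (125, 145),
}


def _region_map(orientation: str, blocks=None) -> dict[str, tuple[int, int]]:
    blocks = blocks or _DEFAULT_BLOCKS
    b1 = blocks["block1"]
    b2 = blocks["block2"]
    mid1 = (b1[0] + b1[1] + 1) // 2
    mid2 = (b2[0] + b2[1] + 1) // 2
    if orientation == "flip":
        loops = {
            "b'": (b1[0], mid1), "b": (mid1, b1[1]),
            "c": (b2[0], mid2), "c'": (mid2, b2[1]),
        }
    elif orientation == "flop":
        loops = {
            "c'": (b1[0], mid1), "c": (mid1, b1[1]),
            "b": (b2[0], mid2), "b'": (mid2, b2[1]),
        }
    else:
        raise ValueError(f"orientation must be 'flip' or 'flop', got {orientation!r}")
    regions = {"a'": blocks["a_prime"], "a": blocks["a"], "d": blocks["d"]}
    regions.update(loops)
    return regions


@dataclass(frozen=True)
class ItrModel:
    """A 145-nt AAV ITR with named sub-regions in ITR-local coordinates."""

    sequence: str = AAV2_ITR
    orientation: str = "flip"
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.sequence) != ITR_LENGTH:
            raise ValueError(
                f"ITR sequence must be {ITR_LENGTH} nt, got {len(self.sequence)}"
            )
        if not self.regions:
            object.__setattr__(self, "regions", _region_map(self.orientation))


def region_of(local_pos: int, itr: ItrModel) -> str:
    """Name of the ITR sub-region containing an ITR-local position."""
    if not 0 <= local_pos < ITR_LENGTH:
        raise ValueError(f"ITR-local position out of range: {local_pos}")
    for name, (lo, hi) in itr.regions.items():
        if lo <= local_pos < hi:
            return name
    raise ValueError(f"position {local_pos} not covered by region map")


@dataclass(frozen=True)
class VectorGenome:
    """An ITR-flanked AAV vector genome.

    The plus-strand sequence is ``left ITR + cargo + revcomp(left ITR)``;
    the right ITR is the inverted copy of the left.  ``features`` carries
    labelled cargo intervals (promoters etc.) used by the shared-homology
    curation filter; ``primer_sites`` are (sequence, interval, strand)
    triples in vector coordinates.
    """

    name: str
    sequence: str
    left_itr: ItrModel
    right_itr: ItrModel
    left_itr_interval: tuple[int, int]
    right_itr_interval: tuple[int, int]
    cargo_interval: tuple[int, int]
    features: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    primer_sites: list[tuple[str, tuple[int, int], str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cargo(self) -> str:
        lo, hi = self.cargo_interval
        return self.sequence[lo:hi]

    def itr_intervals(self) -> list[tuple[int, int]]:
        return [self.left_itr_interval, self.right_itr_interval]

    def in_itr(self, pos: int) -> bool:
        return any(lo <= pos < hi for lo, hi in self.itr_intervals())


def assemble_vector(
    cargo: str,
    left_orientation: str = "flip",
    right_orientation: str = "flop",
    name: str = "vector",
    features: list[tuple[str, tuple[int, int]]] | None = None,
) -> VectorGenome:
    """Assemble an ITR-flanked vector genome around a cargo sequence.

    Total length is always ``2*145 + len(cargo)``.  Feature intervals are
    given in cargo-local coordinates and shifted into vector coordinates.
    """
    cargo = cargo.upper()
    if set(cargo) - set("ACGT"):
        bad = sorted(set(cargo) - set("ACGT"))
        raise ValueError(f"cargo contains non-ACGT characters: {bad}")
    left = ItrModel(orientation=left_orientation)
    right = ItrModel(orientation=right_orientation)
    seq = AAV2_ITR + cargo + revcomp(AAV2_ITR)
    n = len(seq)
    feats = [
        (label, (lo + ITR_LENGTH, hi + ITR_LENGTH)) for label, (lo, hi) in (features or [])
    ]
    return VectorGenome(
        name=name,
        sequence=seq,
        left_itr=left,
        right_itr=right,
        left_itr_interval=(0, ITR_LENGTH),
        right_itr_interval=(n - ITR_LENGTH, n),
        cargo_interval=(ITR_LENGTH, n - ITR_LENGTH),
        features=feats,
    )


def to_itr_local(vector_coord: int, vector: VectorGenome):
    """Map a vector coordinate into the shared 145-nt ITR frame.

    The two ITRs are sequence-identical inverted copies, so a single local
    frame (that of the left ITR) represents both: right-ITR coordinates are
    mapped through the reverse complement so the copies superimpose.
    Returns ``(side, local_pos, orientation)`` with ``side='none'`` and
    ``local_pos=None`` for cargo coordinates.
    """
    if not 0 <= vector_coord < len(vector):
        raise ValueError(f"vector coordinate out of range: {vector_coord}")
    llo, lhi = vector.left_itr_interval
    rlo, rhi = vector.right_itr_interval
    if llo <= vector_coord < lhi:
        return ("left", vector_coord - llo, vector.left_itr.orientation)
    if rlo <= vector_coord < rhi:
        return ("right", rhi - 1 - vector_coord, vector.right_itr.orientation)
    return ("none", None, None)


@dataclass
class TargetLocus:
    """A CRISPR target site on a sequenced amplicon."""

    name: str
    amplicon: str
    protospacer_interval: tuple[int, int]
    pam_interval: tuple[int, int]
    strand: str = "+"
    nuclease: str = "SpCas9"
    cut_point: int = field(init=False)

    def __post_init__(self):
        self.amplicon = self.amplicon.upper()
        self.cut_point = locate_cut_site(self)


def locate_cut_site(locus: TargetLocus) -> int:
    """Blunt-cut insertion coordinate, 3 bp upstream of the PAM.

    For a plus-strand protospacer [s, e) with PAM at [e, e+3) the cut falls
    between positions e-4 and e-3, i.e. insertion coordinate e-3.  The
    minus-strand case is the mirror: PAM at [p, p+3), protospacer at
    [p+3, ...), insertion coordinate p+6.
    """
    ps, pe = locus.protospacer_interval
    ms, me = locus.pam_interval
    if locus.strand == "+":
        if ms != pe:
            raise ValueError("PAM must abut the protospacer 3' end on the plus strand")
        return pe - 3
    if locus.strand == "-":
        if me != ps:
            raise ValueError("PAM must abut the protospacer 5' end on the minus strand")
        return me + 3
    raise ValueError(f"strand must be '+' or '-', got {locus.strand!r}")


# -- built-in vector presets -------------------------------------------------

_LAMBDA_STUFFER_RNG_NOTE = """\
The miniature-vector preset uses a synthetic 175-nt stuffer orthogonal to
the toy host genome; the published construct used a lambda-phage fragment
whose exact coordinates are not restated here."""


def _synthetic_stuffer(n: int, seed: int = 46572913) -> str:
    import numpy as np

    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def aav_lambda_465() -> VectorGenome:
    """Miniature 465-bp vector: 175-nt synthetic stuffer flanked by ITRs."""
    return assemble_vector(
        _synthetic_stuffer(175), name="AAV-465", features=[("stuffer", (0, 175))]
    )


def full_length_vector(cargo_length: int = 3772, name: str = "AAV-full") -> VectorGenome:
    """Standard-size vector preset (default 4062 bp total) with a synthetic
    cargo carrying a labelled promoter-like feature used by curation tests."""
    cargo = _synthetic_stuffer(cargo_length, seed=77)
    return assemble_vector(
        cargo,
        name=name,
        features=[("promoter", (0, min(300, cargo_length))),
                  ("transgene", (min(300, cargo_length), cargo_length))],
    )
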