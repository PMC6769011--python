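"""File input/output: FASTQ/FASTA, GFF3 gene models, tables.

All emitted coordinate tables are 1-based inclusive (BED output is 0-based
half-open per the BED convention); everything in memory is 0-based
half-open.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fusion_detection import FastqRead
from .genomewide_analysis import GeneModel, HostGenome
from .vector_model import ITR_LENGTH, VectorGenome, assemble_vector

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_host_genome",
    "read_host_genome",
    "write_vector",
    "read_vector",
    "write_table",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> list[FastqRead]:
    with _open_text(path) as fh:
        return [
            FastqRead(
                rec.id,
                str(rec.seq),
                "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads, path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences, path) -> None:
    """``sequences``: mapping name -> sequence or iterable of (name, seq)."""
    items = sequences.items() if hasattr(sequences, "items") else sequences
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in items]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# -- host genome (FASTA + GFF3) ---------------------------------------------


def write_host_genome(host: HostGenome, fasta_path, gff_path) -> None:
    write_fasta(host.sequences, fasta_path)
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in host.sequences.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for g in host.genes:
            attrs = f"ID={g.name};Name={g.name}"
            fh.write(
                f"{g.chrom}\ttoy\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t{attrs}\n"
            )
            for i, (lo, hi) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\ttoy\texon\t{lo + 1}\t{hi}\t.\t+\t.\t"
                    f"ID={g.name}.exon{i};Parent={g.name}\n"
                )


def read_host_genome(fasta_path, gff_path) -> HostGenome:
    """Load chromosomes plus gene/exon models from FASTA and GFF3."""
    import gffutils

    sequences = read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            sorted(
                (e.start - 1, e.end)
                for e in db.children(g, featuretype="exon")
            )
        )
        genes.append(GeneModel(g.id, g.seqid, g.start - 1, g.end, exons))
    return HostGenome(sequences=sequences, genes=genes)


# -- vector definitions ------------------------------------------------------


def write_vector(vector: VectorGenome, fasta_path, annotation_path) -> None:
    """FASTA plus a 1-based inclusive sidecar annotation table."""
    write_fasta({vector.name: vector.sequence}, fasta_path)
    rows = [
        ("left_itr", *vector.left_itr_interval, vector.left_itr.orientation),
        ("right_itr", *vector.right_itr_interval, vector.right_itr.orientation),
        ("cargo", *vector.cargo_interval, "."),
    ]
    rows += [(label, lo, hi, ".") for label, (lo, hi) in vector.features]
    rows += [
        (f"primer:{seq}", lo, hi, strand)
        for seq, (lo, hi), strand in vector.primer_sites
    ]
    with open(annotation_path, "w") as fh:
        fh.write("feature\tstart\tend\tinfo\n")
        for label, lo, hi, info in rows:
            fh.write(f"{label}\t{lo + 1}\t{hi}\t{info}\n")


def read_vector(fasta_path, name: str | None = None) -> VectorGenome:
    """Reconstruct a vector from plain FASTA, assuming canonical 145-nt
    ITRs at both ends (the cargo is everything in between)."""
    seqs = read_fasta(fasta_path)
    if name is None:
        name, seq = next(iter(seqs.items()))
    else:
        seq = seqs[name]
    if len(seq) < 2 * ITR_LENGTH:
        raise ValueError(f"vector {name!r} shorter than two ITRs ({len(seq)} nt)")
    from .vector_model import ItrModel, revcomp

    n = len(seq)
    return VectorGenome(
        name=name,
        sequence=seq,
        left_itr=ItrModel(sequence=seq[:ITR_LENGTH]),
        right_itr=ItrModel(sequence=revcomp(seq[n - ITR_LENGTH :]), orientation="flop"),
        left_itr_interval=(0, ITR_LENGTH),
        right_itr_interval=(n - ITR_LENGTH, n),
        cargo_interval=(ITR_LENGTH, n - ITR_LENGTH),
    )


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
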