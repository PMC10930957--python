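"""FASTA and GTF readers/writers.

GTF is 1-based inclusive and forbids ``end < start``, so a wrap-around
gene is serialized as two exon lines of a single transcript (one exon
ending at ``L``, one starting at 1); the reader reassembles such pairs
into a single wrapping :class:`~orispan.circular.GeneModel`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .circular import CircularInterval, CircularSequence, GeneModel


class GtfFormatError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[CircularSequence]:
    return [
        CircularSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path: str | Path, seqs: Iterable[CircularSequence]) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.seq_id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path, genome_length: int) -> list[GeneModel]:
    """Read gene models, reassembling wrap-around genes from split exons.

    Two exons of one transcript, one ending at ``genome_length`` and one
    starting at 1, are merged into a single wrapping interval.
    """
    exons: dict[str, list[tuple[int, int, str, dict[str, str]]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfFormatError(f"line {lineno}: expected 9 fields")
            _, _, feature, start, end, _, strand, _, attr_text = fields
            if feature != "exon":
                continue
            attrs = _parse_attributes(attr_text)
            tid = attrs.get("transcript_id") or attrs.get("gene_id")
            if tid is None:
                raise GtfFormatError(f"line {lineno}: missing transcript_id/gene_id")
            if tid not in exons:
                order.append(tid)
            exons.setdefault(tid, []).append((int(start), int(end), strand, attrs))

    genes: list[GeneModel] = []
    for tid in order:
        parts = sorted(exons[tid])
        strand = parts[0][2]
        attrs = parts[0][3]
        gene_id = attrs.get("gene_id", tid)
        biotype = attrs.get("gene_biotype", attrs.get("biotype", "lncRNA"))
        if len(parts) == 1:
            start, end = parts[0][0], parts[0][1]
        elif (
            len(parts) == 2
            and parts[0][0] == 1
            and parts[1][1] == genome_length
        ):
            # wrap-around: exon at L-end continues into the exon starting at 1
            start, end = parts[1][0], parts[0][1]
        else:
            raise GtfFormatError(
                f"transcript {tid}: only single-exon or wrap-around "
                f"two-exon models are supported"
            )
        genes.append(
            GeneModel(gene_id, CircularInterval(start, end, strand), biotype)
        )
    return genes


def write_gtf(
    path: str | Path,
    genes: Sequence[GeneModel],
    genome_length: int,
    seq_id: str = "chrM",
    source: str = "orispan",
) -> None:
    def line(feature: str, start: int, end: int, strand: str, attrs: str) -> str:
        return "\t".join(
            [seq_id, source, feature, str(start), str(end), ".", strand, ".", attrs]
        )

    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                f'gene_biotype "{g.biotype}";'
            )
            if not iv.wraps:
                fh.write(line("exon", iv.start, iv.end, iv.strand, attrs) + "\n")
            else:
                fh.write(line("exon", iv.start, genome_length, iv.strand, attrs) + "\n")
                fh.write(line("exon", 1, iv.end, iv.strand, attrs) + "\n")
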