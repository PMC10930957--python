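"""Strand-aware short-read simulation from circular transcript models.

Reads are drawn uniformly along each transcript (circular-aware, so reads
from origin-spanning genes straddle the linearization junction), with
optional per-base substitution errors.  The truth of every read — source
gene, canonical heavy-strand start, sequenced strand — goes into a sidecar
truth table, never into the FASTQ itself.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .circular import (
    HEAVY,
    LIGHT,
    CircularSequence,
    GeneModel,
    circular_length,
    reverse_complement,
)

_BASES = "ACGT"
# errors substitute to one of the other three bases
_ALTERNATIVES = {b: _BASES.replace(b, "") for b in _BASES}
_ALTERNATIVES["N"] = _BASES

STRANDEDNESS_MODES = ("unstranded", "forward", "reverse")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    read_length: int = 100
    n_reads: int = 1000
    abundances: Mapping[str, float] | None = None  # relative weights per gene
    error_rate: float = 0.0
    strandedness: str = "reverse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 20:
            raise SimulationError("read_length must be >= 20")
        if not 0.0 <= self.error_rate <= 0.1:
            raise SimulationError("error_rate must be in [0, 0.1]")
        if self.strandedness not in STRANDEDNESS_MODES:
            raise SimulationError(f"strandedness must be one of {STRANDEDNESS_MODES}")


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: str
    truth_gene: str
    truth_start: int  # canonical 1-based heavy-strand start of the footprint
    truth_strand: str  # strand the (error-free) read sequence matches

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise SimulationError(
                f"read {self.read_id}: sequence/quality length mismatch"
            )


def junction_fraction(gene: GeneModel, L: int, read_length: int) -> float:
    """Exact fraction of transcript placements whose footprint crosses L|1."""
    glen = circular_length(gene.interval, L)
    n_positions = glen - read_length + 1
    if n_positions < 1:
        raise SimulationError("gene shorter than read length")
    n_junction = 0
    for offset in range(n_positions):
        start = (gene.interval.start - 1 + offset) % L + 1
        if start + read_length - 1 > L:
            n_junction += 1
    return n_junction / n_positions


def simulate_reads(
    genome: CircularSequence,
    genes: Sequence[GeneModel],
    cfg: SimulationConfig,
) -> list[ReadRecord]:
    """Simulate ``cfg.n_reads`` single-end reads across ``genes``.

    Gene of origin is drawn i.i.d. proportional to ``cfg.abundances``
    (uniform across genes if unset); the start offset is uniform over the
    transcript.  Deterministic under ``cfg.seed``.
    """
    L = genome.length
    r = cfg.read_length
    for g in genes:
        if circular_length(g.interval, L) < r:
            raise SimulationError(
                f"gene {g.gene_id} shorter than read length {r}"
            )
    rng = np.random.default_rng(cfg.seed)

    if cfg.abundances is None:
        weights = np.ones(len(genes))
    else:
        weights = np.array([float(cfg.abundances[g.gene_id]) for g in genes])
    probs = weights / weights.sum()
    gene_idx = rng.choice(len(genes), size=cfg.n_reads, p=probs)

    glens = [circular_length(g.interval, L) for g in genes]
    reads: list[ReadRecord] = []
    qual = "I" * r
    for i, gi in enumerate(gene_idx):
        gene = genes[gi]
        offset = int(rng.integers(0, glens[gi] - r + 1))
        if gene.strand == HEAVY:
            heavy_start = (gene.interval.start - 1 + offset) % L + 1
        else:
            # transcript runs along the light strand, from interval.end backwards
            heavy_start = (gene.interval.end - offset - r) % L + 1
        heavy_end = (heavy_start - 1 + r - 1) % L + 1
        fragment = genome.slice(heavy_start, heavy_end)
        transcript_frag = (
            fragment if gene.strand == HEAVY else reverse_complement(fragment)
        )

        if cfg.strandedness == "forward":
            sequenced_strand = gene.strand
        elif cfg.strandedness == "reverse":
            sequenced_strand = LIGHT if gene.strand == HEAVY else HEAVY
        else:
            sequenced_strand = HEAVY if rng.integers(0, 2) == 0 else LIGHT
        seq = (
            transcript_frag
            if sequenced_strand == gene.strand
            else reverse_complement(transcript_frag)
        )

        if cfg.error_rate > 0:
            seq = _apply_errors(seq, cfg.error_rate, rng)

        reads.append(
            ReadRecord(
                read_id=f"read{i:06d}",
                sequence=seq,
                qualities=qual,
                truth_gene=gene.gene_id,
                truth_start=heavy_start,
                truth_strand=sequenced_strand,
            )
        )
    return reads


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    out = list(seq)
    for pos in np.flatnonzero(mask):
        alts = _ALTERNATIVES[out[pos]]
        out[pos] = alts[int(rng.integers(0, len(alts)))]
    return "".join(out)


class FastqFormatError(ValueError):
    pass


def write_fastq(path: str | Path, reads: Sequence[ReadRecord]) -> None:
    with open(path, "w") as fh:
        for rec in reads:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.qualities}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a 4-line FASTQ; truth fields of the returned records are blank."""
    reads: list[ReadRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise FastqFormatError(
            f"truncated FASTQ: {len(lines)} lines is not a multiple of 4"
        )
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@"):
            raise FastqFormatError(f"line {i + 1}: header must start with '@'")
        if not plus.startswith("+"):
            raise FastqFormatError(f"line {i + 3}: separator must start with '+'")
        if len(seq) != len(qual):
            raise FastqFormatError(f"line {i + 2}: sequence/quality length mismatch")
        reads.append(ReadRecord(header[1:].split()[0], seq, qual, "", 0, HEAVY))
    return reads


def write_truth_table(
    path: str | Path, reads: Sequence[ReadRecord], seed: int
) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# seed={seed}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["read_id", "gene", "start", "strand"])
        for rec in reads:
            writer.writerow(
                [rec.read_id, rec.truth_gene, rec.truth_start, rec.truth_strand]
            )


def read_truth_table(path: str | Path) -> dict[str, tuple[str, int, str]]:
    truth: dict[str, tuple[str, int, str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("read_id"):
                continue
            read_id, gene, start, strand = line.rstrip("\n").split("\t")
            truth[read_id] = (gene, int(start), strand)
    return truth
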