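"""Circular coordinate algebra for small circular genomes.

Everything here is 1-based inclusive (GTF convention).  An interval on a
circular sequence of length ``L`` may wrap the linearization origin, which
is encoded as ``start > end``.  A rotation (re-origining) of the reference
is represented explicitly by :class:`RotationMap`, a bijection on
``[1, L]`` that can be inverted and composed, so annotations can be lifted
onto a rotated reference and back without loss.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

HEAVY = "+"
LIGHT = "-"

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class CoordinateError(ValueError):
    """A position or interval falls outside ``[1, L]``."""


class AlphabetError(ValueError):
    """A residue outside the ACGTN alphabet was encountered."""


class ConfigurationError(ValueError):
    """An operation was configured with inconsistent parameters."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN, case preserved)."""
    bad = set(seq.upper()) - _ALPHABET
    if bad:
        raise AlphabetError(f"non-ACGTN residues: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularSequence:
    """A circular nucleotide sequence with an explicit length.

    Parameters
    ----------
    seq_id:
        Identifier used in FASTA/SAM output.
    residues:
        The linearized residues starting from the current origin;
        ``len(residues)`` defines the circle length ``L``.
    """

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("circular sequence must contain at least 1 residue")
        bad = set(self.residues.upper()) - _ALPHABET
        if bad:
            raise AlphabetError(f"non-ACGTN residues: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Heavy-strand residues of the (possibly wrapping) region ``start..end``."""
        L = self.length
        _check_pos(start, L)
        _check_pos(end, L)
        if start <= end:
            return self.residues[start - 1 : end]
        return self.residues[start - 1 :] + self.residues[:end]

    def base_at(self, pos: int) -> str:
        _check_pos(pos, self.length)
        return self.residues[pos - 1]


def _check_pos(pos: int, L: int) -> None:
    if not 1 <= pos <= L:
        raise CoordinateError(f"position {pos} outside [1, {L}]")


@dataclass(frozen=True)
class CircularInterval:
    """1-based inclusive stranded interval; ``start > end`` means it wraps."""

    start: int
    end: int
    strand: str = HEAVY

    def __post_init__(self) -> None:
        if self.strand not in (HEAVY, LIGHT):
            raise ValueError(f"strand must be {HEAVY!r} or {LIGHT!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError("interval positions must be >= 1")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, L: int) -> int:
        return circular_length(self, L)

    def positions(self, L: int) -> Iterator[int]:
        """Heavy-strand positions covered, in heavy-strand order."""
        _check_pos(self.start, L)
        _check_pos(self.end, L)
        if not self.wraps:
            yield from range(self.start, self.end + 1)
        else:
            yield from range(self.start, L + 1)
            yield from range(1, self.end + 1)

    def contains(self, pos: int, L: int) -> bool:
        _check_pos(pos, L)
        if not self.wraps:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end


def circular_length(interval: CircularInterval, L: int) -> int:
    """Span of ``interval`` on a circle of length ``L``, in [1, L]."""
    _check_pos(interval.start, L)
    _check_pos(interval.end, L)
    if not interval.wraps:
        return interval.end - interval.start + 1
    return (L - interval.start + 1) + interval.end


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: CircularInterval
    biotype: str = "lncRNA"

    def length(self, L: int) -> int:
        return circular_length(self.interval, L)

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class RotationMap:
    """Bijection between original and rotated coordinates.

    ``new_origin`` is the original position that becomes position 1 after
    rotation.  ``new_origin == 1`` is the identity.
    """

    length: int
    new_origin: int

    def __post_init__(self) -> None:
        _check_pos(self.new_origin, self.length)

    def lift(self, pos: int) -> int:
        _check_pos(pos, self.length)
        return (pos - self.new_origin) % self.length + 1

    def inverse(self) -> "RotationMap":
        return RotationMap(self.length, (1 - self.new_origin) % self.length + 1)

    def unlift(self, pos: int) -> int:
        return self.inverse().lift(pos)

    def compose(self, other: "RotationMap") -> "RotationMap":
        """Map equivalent to applying ``self`` first, then ``other``."""
        if self.length != other.length:
            raise ConfigurationError("cannot compose maps of different lengths")
        # other.new_origin is in self's rotated coordinates; pull it back.
        return RotationMap(self.length, self.unlift(other.new_origin))


def lift_position(pos: int, rmap: RotationMap) -> int:
    return rmap.lift(pos)


def rotate_reference(
    seq: CircularSequence, new_origin: int
) -> tuple[CircularSequence, RotationMap]:
    """Re-origin ``seq`` so that original position ``new_origin`` becomes 1.

    Returns the rotated sequence and the map lifting original coordinates
    onto it.
    """
    L = seq.length
    _check_pos(new_origin, L)
    rotated = seq.residues[new_origin - 1 :] + seq.residues[: new_origin - 1]
    return CircularSequence(seq.seq_id, rotated), RotationMap(L, new_origin)


def lift_gene(gene: GeneModel, rmap: RotationMap) -> GeneModel:
    """Lift a gene model through a rotation; span and strand are preserved."""
    iv = gene.interval
    new_iv = CircularInterval(
        start=rmap.lift(iv.start), end=rmap.lift(iv.end), strand=iv.strand
    )
    return replace(gene, interval=new_iv)


def lift_annotation(genes: Sequence[GeneModel], rmap: RotationMap) -> list[GeneModel]:
    return [lift_gene(g, rmap) for g in genes]


@dataclass(frozen=True)
class ExtendedReference:
    """Linearization of a circle with the first ``pad`` residues re-appended.

    With ``pad = read_length - 1`` every circular placement of a read is
    visible as a contiguous substring.  Alignments starting at ``s > L``
    are canonicalized to ``s - L``.
    """

    base: CircularSequence
    pad: int

    def __post_init__(self) -> None:
        if self.pad < 0 or self.pad > self.base.length:
            raise ConfigurationError(
                f"pad must be in [0, {self.base.length}], got {self.pad}"
            )

    @property
    def circle_length(self) -> int:
        return self.base.length

    @property
    def linear_residues(self) -> str:
        return self.base.residues + self.base.residues[: self.pad]

    def canonicalize(self, start: int) -> int:
        """Report an alignment start in the padded copy at its circle position."""
        L = self.base.length
        if not 1 <= start <= L + self.pad:
            raise CoordinateError(f"start {start} outside extended reference")
        return start - L if start > L else start


def build_extended_reference(seq: CircularSequence, pad: int) -> ExtendedReference:
    return ExtendedReference(seq, pad)


def extract_transcript(seq: CircularSequence, interval: CircularInterval) -> str:
    """Transcript sequence of a gene interval, reverse-complemented for light strand."""
    region = seq.slice(interval.start, interval.end)
    if interval.strand == LIGHT:
        return reverse_complement(region)
    return region


def reverse_complement_region(seq: CircularSequence, interval: CircularInterval) -> str:
    """Reverse complement of the (possibly wrapping) heavy-strand region."""
    return reverse_complement(seq.slice(interval.start, interval.end))
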