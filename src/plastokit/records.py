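"""Core domain types for circular plastid genomes.

A plastome is modelled as a :class:`CircularSequence` plus an ordered list of
:class:`GeneFeature` annotations.  All coordinates are 0-based half-open on the
genome.  On a circular molecule a feature may span the origin; such features
are stored as a single interval with ``end <= start`` and are interpreted as
wrapping (``[start, n) + [0, end)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "other")


class PlastokitError(Exception):
    """Base class for all package errors."""


class ParseError(PlastokitError):
    """A file could not be parsed in the named dialect."""


class CoordinateError(PlastokitError):
    """A feature interval does not fit on its sequence."""


class ParameterError(PlastokitError):
    """An argument is outside its documented domain."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularSequence:
    """A nucleotide sequence, by default a closed circle.

    ``residues`` is restricted to the alphabet ``ACGTN`` (uppercased on
    construction); indexing helpers wrap modulo the length when the sequence
    is circular.
    """

    residues: str
    name: str = ""
    is_circular: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) == 0:
            raise ParameterError("sequence must be non-empty")
        bad = set(self.residues) - VALID_BASES
        if bad:
            raise ParameterError(f"invalid residues {sorted(bad)!r} in sequence {self.name!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of ``[start, end)``; ``end <= start`` wraps the origin."""
        n = len(self.residues)
        if not (0 <= start < n) or not (0 <= end <= n):
            raise CoordinateError(f"interval [{start}, {end}) outside sequence of length {n}")
        if end > start:
            return self.residues[start:end]
        if not self.is_circular:
            raise CoordinateError(
                f"wrapped interval [{start}, {end}) on non-circular sequence {self.name!r}"
            )
        return self.residues[start:] + self.residues[:end]

    def reverse_complement(self) -> "CircularSequence":
        return replace(self, residues=reverse_complement(self.residues))

    def rotate(self, offset: int) -> "CircularSequence":
        """Rotate so that current position ``offset`` becomes position 0."""
        if not self.is_circular:
            raise ParameterError("cannot rotate a non-circular sequence")
        n = len(self.residues)
        offset %= n
        return replace(self, residues=self.residues[offset:] + self.residues[:offset])


@dataclass(frozen=True)
class GeneFeature:
    """A typed, stranded gene annotation.

    ``parts`` optionally records a multi-segment (spliced) location as
    0-based half-open segments in genome order; a single wrapped interval is
    *not* multi-segment — it models one contiguous gene crossing the origin.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str
    parts: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ParameterError(f"feature kind {self.kind!r} not one of {FEATURE_KINDS}")
        if self.strand not in ("+", "-"):
            raise ParameterError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end < 0:
            raise CoordinateError(f"negative coordinate in feature {self.name!r}")

    @property
    def wraps(self) -> bool:
        return self.end <= self.start

    def length(self, genome_len: int) -> int:
        if self.parts is not None:
            return sum(_span_len(s, e, genome_len) for s, e in self.parts)
        return _span_len(self.start, self.end, genome_len)

    @property
    def has_intron(self) -> bool:
        return self.parts is not None and len(self.parts) > 1


def _span_len(start: int, end: int, genome_len: int) -> int:
    return end - start if end > start else genome_len - start + end


@dataclass
class PlastomeRecord:
    """A circular genome plus its ordered feature annotations."""

    sequence: CircularSequence
    features: list[GeneFeature] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            if f.start >= n or f.end > n:
                raise CoordinateError(
                    f"feature {f.name!r} [{f.start}, {f.end}) beyond sequence length {n}"
                )
            if f.wraps and not self.sequence.is_circular:
                raise CoordinateError(
                    f"feature {f.name!r} wraps the origin of non-circular {self.sequence.name!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def feature_sequence(self, feature: GeneFeature) -> str:
        """Spliced, strand-oriented nucleotide sequence of a feature."""
        if feature.parts is not None:
            raw = "".join(self.sequence.fetch(s, e) for s, e in feature.parts)
        else:
            raw = self.sequence.fetch(feature.start, feature.end)
        return reverse_complement(raw) if feature.strand == "-" else raw


def extract_cds(record: PlastomeRecord, feature: GeneFeature) -> str:
    """Strand-oriented coding sequence of a CDS feature (wrap-aware)."""
    if feature.kind != "CDS":
        raise ParameterError(f"extract_cds requires a CDS feature, got {feature.kind!r}")
    return record.feature_sequence(feature)


START_CODONS = ("ATG", "GTG", "ATT")
STOP_CODONS = ("TAA", "TAG", "TGA")


def translate(cds: str, table: int = 11, is_start: bool = False) -> str:
    """Translate a coding sequence under the bacterial/plastid code.

    When ``is_start`` is true the first codon is rendered as methionine if it
    is one of the alternative initiators (ATG/GTG/ATT).  Translation stops at
    the first in-frame stop; a stop before the final codon is logged as a
    warning and the protein is truncated there.  Trailing incomplete codons
    are ignored; codons containing N translate to X.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ParameterError("coding sequence shorter than one codon")
    usable = len(cds) - len(cds) % 3
    aa = str(Seq(cds[:usable]).translate(table=table))
    if is_start and cds[:3] in START_CODONS:
        aa = "M" + aa[1:]
    stop_at = aa.find("*")
    if stop_at == -1:
        return aa
    if stop_at < len(aa) - 1:
        logger.warning(
            "internal stop codon at codon %d of %d; translation truncated", stop_at + 1, len(aa)
        )
    return aa[:stop_at]


def rotate_record(record: PlastomeRecord, offset: int) -> PlastomeRecord:
    """Rotate the circle so position ``offset`` becomes the new origin."""
    n = len(record.sequence)
    offset %= n

    def shift(pos: int, is_end: bool) -> int:
        p = (pos - offset) % n
        if is_end and p == 0:
            return n
        return p

    feats = [
        replace(
            f,
            start=shift(f.start, False),
            end=shift(f.end, True),
            parts=tuple((shift(s, False), shift(e, True)) for s, e in f.parts)
            if f.parts is not None
            else None,
        )
        for f in record.features
    ]
    feats.sort(key=lambda f: f.start)
    return PlastomeRecord(
        sequence=record.sequence.rotate(offset),
        features=feats,
        provenance=record.provenance + f" (rotated {offset})",
    )


def reverse_complement_record(record: PlastomeRecord) -> PlastomeRecord:
    """Mirror the whole record onto the opposite strand."""
    n = len(record.sequence)

    def flip_interval(s: int, e: int) -> tuple[int, int]:
        return (n - e) % n, n - s  # s == 0 maps to half-open end n

    feats = []
    for f in record.features:
        ns, ne = flip_interval(f.start, f.end)
        parts = None
        if f.parts is not None:
            parts = tuple(flip_interval(s, e) for s, e in reversed(f.parts))
        feats.append(
            replace(f, start=ns, end=ne, strand="-" if f.strand == "+" else "+", parts=parts)
        )
    feats.sort(key=lambda f: f.start)
    return PlastomeRecord(
        sequence=record.sequence.reverse_complement(),
        features=feats,
        provenance=record.provenance + " (reverse complemented)",
    )
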