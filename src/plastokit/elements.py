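"""Intergenic stem-loops and tandem-repeat length polymorphisms.

The stem-loop search treats a hairpin as a maximal perfect even-length
palindrome (a sequence equal to its own reverse complement, zero loop).
Tandem arrays are maximal perfect repeats of a 1-6 nt unit, reported in a
canonical phase (leftmost start, lexicographically smallest unit rotation).
Ortholog comparison aligns two coding sequences globally and interprets each
gap that sits in or next to a tandem array as a copy-number polymorphism;
a 3-nt unit changes gene length without shifting the reading frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from .records import (
    ParameterError,
    PlastokitError,
    PlastomeRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)

_COMP_NO_N = str.maketrans("ACGTN", "TGCA?")


class IncomparableOrthologsError(PlastokitError):
    """Two sequences are too diverged to be compared as orthologs."""


@dataclass(frozen=True)
class Palindrome:
    interval: tuple[int, int]  # 0-based half-open, may wrap
    span: int
    flank_upstream: str
    flank_downstream: str


@dataclass(frozen=True)
class TandemArray:
    unit: str  # lexicographically smallest rotation
    start: int
    copies: int

    @property
    def span(self) -> int:
        return len(self.unit) * self.copies


@dataclass(frozen=True)
class RepeatPolymorphism:
    gene: str
    unit: str
    copies_a: int
    copies_b: int
    delta_nt: int  # signed: len(A locus) - len(B locus)
    frame_preserved: bool
    context: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.delta_nt != len(self.unit) * (self.copies_a - self.copies_b):
            raise PlastokitError("delta_nt inconsistent with unit and copy numbers")
        if self.frame_preserved != (self.delta_nt % 3 == 0):
            raise PlastokitError("frame flag inconsistent with delta_nt")


# ---------------------------------------------------------------- palindromes

def find_palindromes(
    record: PlastomeRecord, min_span: int = 30, intergenic_only: bool = False
) -> list[Palindrome]:
    """Maximal perfect even palindromes >= min_span, with flanking gene names."""
    if min_span < 10 or min_span % 2 != 0:
        raise ParameterError("min_span must be an even number >= 10")
    seq = record.sequence.residues
    n = len(seq)
    comp = seq.translate(_COMP_NO_N)
    circular = record.sequence.is_circular
    hits: list[tuple[int, int]] = []  # (start, span)
    centers = range(n) if circular else range(1, n)
    for c in centers:
        e = 0
        while e < n // 2:
            left = (c - 1 - e) % n
            right = (c + e) % n
            if not circular and (c - 1 - e < 0 or c + e >= n):
                break
            if seq[left] != comp[right]:
                break
            e += 1
        span = 2 * e
        if span >= min_span:
            hits.append(((c - e) % n, span))
    out = []
    for start, span in hits:
        end = (start + span) % n
        up, down = _flanking_features(record, start, end)
        if intergenic_only and _touches_feature(record, start, span):
            continue
        out.append(Palindrome(interval=(start, end), span=span,
                              flank_upstream=up, flank_downstream=down))
    out.sort(key=lambda p: (-p.span, p.interval[0]))
    for p in out:  # invariant: reported interval equals its reverse complement
        sub = record.sequence.fetch(p.interval[0], p.interval[1]) if p.interval[0] != p.interval[1] \
            else record.sequence.residues
        assert sub == reverse_complement(sub)
    return out


def _positions(start: int, span: int, n: int):
    return ((start + t) % n for t in range(span))


def _touches_feature(record: PlastomeRecord, start: int, span: int) -> bool:
    n = len(record.sequence)
    covered = [False] * n
    for f in record.features:
        length = f.length(n)
        for t in range(length):
            covered[(f.start + t) % n] = True
    return any(covered[p] for p in _positions(start, span, n))


def _flanking_features(record: PlastomeRecord, start: int, end: int) -> tuple[str, str]:
    """Nearest feature names upstream of ``start`` and downstream of ``end``."""
    n = len(record.sequence)
    if not record.features:
        return "", ""
    up = min(record.features, key=lambda f: (start - f.end) % n)
    down = min(record.features, key=lambda f: (f.start - end) % n)
    return up.name, down.name


# ---------------------------------------------------------------- tandem repeats

def canonical_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    u = len(unit)
    for d in range(1, u):
        if u % d == 0 and unit == unit[:d] * (u // d):
            return False
    return True


def find_tandem_repeats(
    seq: str, unit_sizes: range = range(1, 7), min_copies: int = 2
) -> list[TandemArray]:
    """Maximal perfect tandem arrays of 1-6 nt units in a linear string."""
    if min_copies < 2:
        raise ParameterError("min_copies must be >= 2")
    if min(unit_sizes) < 1 or max(unit_sizes) > 6:
        raise ParameterError("unit sizes must lie within 1..6")
    seq = seq.upper()
    n = len(seq)
    out: list[TandemArray] = []
    for u in unit_sizes:
        x = 0
        while x < n - u:
            if seq[x] != seq[x + u]:
                x += 1
                continue
            a = x
            while x < n - u and seq[x] == seq[x + u]:
                x += 1
            run_len = x - a  # positions a..x-1 satisfy seq[t] == seq[t+u]
            copies = (run_len + u) // u
            unit = seq[a : a + u]
            if copies >= min_copies and _is_primitive(unit):
                out.append(TandemArray(unit=canonical_rotation(unit), start=a, copies=copies))
    out.sort(key=lambda t: (t.start, len(t.unit)))
    return out


# ---------------------------------------------------------------- ortholog comparison

def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def _shift_gaps_right(row_x: list[str], row_y: list[str]) -> None:
    """Canonicalize gap placement to the 3'-most score-equivalent position."""

    def sub(a: str, b: str) -> int:
        return 1 if a == b else -1

    moved = True
    while moved:
        moved = False
        c = 0
        m = len(row_x)
        while c < m:
            if row_x[c] == "-":
                c0 = c
                while c < m and row_x[c] == "-":
                    c += 1
                # gap block [c0, c); try shifting right one column at a time
                while c < m and row_x[c] != "-" and row_y[c0] != "-" and row_y[c] != "-" \
                        and sub(row_x[c], row_y[c0]) == sub(row_x[c], row_y[c]):
                    row_x[c0] = row_x[c]
                    row_x[c] = "-"
                    c0 += 1
                    c += 1
                    moved = True
            else:
                c += 1


def _copies_at(seq: str, pos: int, unit: str) -> int:
    """Copies of ``unit`` in the tandem array at/around position ``pos``."""
    u = len(unit)
    copies = 0
    q = pos
    while q + u <= len(seq) and seq[q : q + u] == unit:
        copies += 1
        q += u
    q = pos - u
    while q >= 0 and seq[q : q + u] == unit:
        copies += 1
        q -= u
    return copies


def global_alignment(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Deterministic global alignment with 3'-canonicalized gaps."""
    aln = _aligner().align(seq_a, seq_b)[0]
    row_a, row_b = list(str(aln[0])), list(str(aln[1]))
    _shift_gaps_right(row_a, row_b)
    _shift_gaps_right(row_b, row_a)
    return "".join(row_a), "".join(row_b)


def compare_ortholog_repeats(
    cds_a: str, cds_b: str, gene: str = "", context_window: int = 15
) -> list[RepeatPolymorphism]:
    """Tandem-repeat copy-number differences between two orthologous CDS.

    Each alignment gap whose inserted/deleted segment is an integer number of
    copies of a 1-6 nt unit, lying inside or adjacent to a tandem array, is
    reported with signed length difference (A minus B) and frame status.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if cds_a == cds_b:
        return []
    row_a, row_b = global_alignment(cds_a, cds_b)
    matches = sum(a == b for a, b in zip(row_a, row_b) if a != "-" and b != "-")
    if matches / len(row_a) < 0.5:
        raise IncomparableOrthologsError(
            f"alignment identity {matches / len(row_a):.2f} below 0.5 for gene {gene!r}"
        )
    out: list[RepeatPolymorphism] = []
    c = 0
    pos_a = pos_b = 0
    m = len(row_a)
    while c < m:
        gap_in_a = row_a[c] == "-"
        gap_in_b = row_b[c] == "-"
        if not (gap_in_a or gap_in_b):
            pos_a += 1
            pos_b += 1
            c += 1
            continue
        c0 = c
        row, longer, p_long, p_short = (
            (row_a, cds_b, pos_b, pos_a) if gap_in_a else (row_b, cds_a, pos_a, pos_b)
        )
        while c < m and row[c] == "-":
            c += 1
        g = c - c0
        segment = longer[p_long : p_long + g]
        poly = _classify_gap(gene, segment, gap_in_a, cds_a, cds_b, pos_a, pos_b,
                             longer, p_long, context_window)
        if poly is not None:
            out.append(poly)
        if gap_in_a:
            pos_b += g
        else:
            pos_a += g
    return out


def _classify_gap(
    gene: str, segment: str, gap_in_a: bool, cds_a: str, cds_b: str,
    pos_a: int, pos_b: int, longer: str, p_long: int, context_window: int,
) -> RepeatPolymorphism | None:
    g = len(segment)
    for u in range(1, 7):
        if g % u != 0:
            continue
        unit = segment[:u]
        if segment != unit * (g // u) or not _is_primitive(unit):
            continue
        copies_a = _copies_at(cds_a, pos_a, unit)
        copies_b = _copies_at(cds_b, pos_b, unit)
        if max(copies_a, copies_b) < 2:
            return None  # an isolated indel, not a tandem-array polymorphism
        lo = max(0, p_long - context_window)
        hi = min(len(longer), p_long + g + context_window)
        context = tuple(
            (t.unit, t.copies)
            for t in find_tandem_repeats(longer[lo:hi])
            if canonical_rotation(t.unit) != canonical_rotation(unit)
        )
        delta = len(unit) * (copies_a - copies_b)
        return RepeatPolymorphism(
            gene=gene, unit=unit, copies_a=copies_a, copies_b=copies_b,
            delta_nt=delta, frame_preserved=delta % 3 == 0, context=context,
        )
    logger.info("gene %s: %d-nt gap is not a tandem-unit multiple; ignored", gene, g)
    return None
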