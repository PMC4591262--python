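"""Quadripartite architecture of a circular plastome.

Plastid genomes of brown algae carry a pair of kilobase-scale exact inverted
repeats (IRa/IRb) that split the circle into a large and a small single-copy
region (LSC/SSC).  This module finds exact inverted-repeat pairs by
seed-and-extend on k-mer matches between the sequence and its reverse
complement, and partitions the circle accordingly.

A pair ``(A, B, L)`` satisfies ``sequence(A) == reverse_complement(sequence(B))``
with ``|A| == |B| == L``, the two intervals disjoint on the circle, and no
extension in either direction that keeps both the match and disjointness.
Internally a pair lives on one "anti-diagonal" ``s = (x + y) mod n`` of the
complementarity relation ``seq[x] == complement(seq[y])``: a maximal circular
run of matching positions on an anti-diagonal either mirrors a second run
(giving a two-copy repeat) or mirrors itself (a palindrome, whose two halves
form the maximal disjoint pair).
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import CircularSequence, ParameterError, PlastokitError, reverse_complement

# N must never match anything, including itself
_COMP_NO_N = str.maketrans("ACGTN", "TGCA?")


class CompositionError(PlastokitError):
    """Base composition undefined (no unambiguous residues)."""


@dataclass(frozen=True)
class InvertedRepeatPair:
    interval_a: tuple[int, int]  # 0-based half-open, may wrap
    interval_b: tuple[int, int]
    length: int


@dataclass(frozen=True)
class QuadripartiteArchitecture:
    lsc: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    irb: tuple[int, int]
    lengths: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        ln = self.lengths
        if ln["lsc"] + ln["ssc"] + 2 * ln["ir"] != self.total:
            raise PlastokitError("quadripartite regions do not cover the circle")
        if ln["lsc"] < ln["ssc"]:
            raise PlastokitError("LSC shorter than SSC")


def _match_run(seq: str, comp: str, s: int, x: int, n: int) -> tuple[int, int]:
    """Maximal circular run of matching positions through ``x`` on anti-diagonal ``s``.

    Returns (start, run_length); assumes position ``x`` matches.
    """
    a = x
    length = 1
    while length < n and seq[(a - 1) % n] == comp[(s - (a - 1)) % n]:
        a = (a - 1) % n
        length += 1
    b = (a + length - 1) % n
    while length < n and seq[(b + 1) % n] == comp[(s - (b + 1)) % n]:
        b = (b + 1) % n
        length += 1
    return a, length


def run_to_pair(a: int, run_len: int, s: int, n: int) -> tuple[int, int, int] | None:
    """Convert a maximal anti-diagonal match run into the (i, j, L) repeat pair.

    A run mirrors onto the run of its partner positions; if the mirror is the
    run itself the run is palindromic and the disjoint pair is its two halves.
    Returns None for degenerate runs that yield no positive-length pair.
    """
    b = (a + run_len - 1) % n
    mirror_start = (s - b) % n
    if mirror_start == a and (s - a) % n == b:
        # self-mirror: palindrome; pair = the two halves (odd centres cannot match)
        half = run_len // 2
        if half == 0:
            return None
        i = a
        j = (a + run_len - half) % n
        return i, j, half
    return a, mirror_start, run_len


def find_inverted_repeats(
    seq: CircularSequence, min_len: int, k: int | None = None
) -> list[InvertedRepeatPair]:
    """All maximal exact inverted-repeat pairs of length >= min_len, longest first.

    Deterministic order: length descending, then smaller start coordinate.
    """
    if min_len < 10:
        raise ParameterError("min_len must be >= 10")
    s_str = seq.residues
    n = len(s_str)
    comp = s_str.translate(_COMP_NO_N)
    k = min(k if k is not None else 12, min_len, n)

    # seed table: k-mer -> positions (with wrap when circular)
    limit = n if seq.is_circular else n - k + 1
    doubled = s_str + s_str[: k - 1]
    index: dict[str, list[int]] = {}
    for y in range(limit):
        index.setdefault(doubled[y : y + k], []).append(y)

    runs_by_s: dict[int, list[tuple[int, int]]] = {}
    pairs: set[tuple[int, int, int]] = set()
    for x in range(limit):
        word = doubled[x : x + k]
        if "N" in word:
            continue
        for y in index.get(reverse_complement(word), ()):  # match(x+t, y+k-1-t)
            s = (x + y + k - 1) % n
            runs = runs_by_s.setdefault(s, [])
            if any((x - a) % n < run_len for a, run_len in runs):
                continue  # seed lies inside a run already extended
            a, run_len = _match_run(s_str, comp, s, x, n)
            runs.append((a, run_len))
            converted = run_to_pair(a, run_len, s, n)
            if converted is None:
                continue
            i, j, length = converted
            if length < min_len:
                continue
            if i > j:
                i, j = j, i
            pairs.add((i, j, length))

    out = [
        InvertedRepeatPair((i, (i + length) % n), (j, (j + length) % n), length)
        for i, j, length in pairs
    ]
    out.sort(key=lambda p: (-p.length, p.interval_a[0], p.interval_b[0]))
    for p in out:  # safety: every reported pair is an exact reverse complement
        assert seq.fetch(*p.interval_a) == reverse_complement(seq.fetch(*p.interval_b))
    return out


def detect_quadripartite(
    seq: CircularSequence, min_ir: int = 1000
) -> QuadripartiteArchitecture | None:
    """Partition the circle into LSC/SSC/IRa/IRb from the longest IR pair.

    The two arcs between the repeat copies become the single-copy regions
    (longer = LSC); IRa is the copy whose clockwise neighbour is the SSC.
    Returns None when no exact inverted-repeat pair reaches ``min_ir``.
    """
    if not seq.is_circular:
        raise ParameterError("quadripartite detection requires a circular sequence")
    pairs = find_inverted_repeats(seq, min_len=min_ir, k=21 if min_ir >= 21 else None)
    if not pairs:
        return None
    top = pairs[0]
    n = len(seq)
    a0, _ = top.interval_a
    b0, _ = top.interval_b
    L = top.length
    arc1 = ((a0 + L) % n, b0)  # clockwise from copy A to copy B
    arc2 = ((b0 + L) % n, a0)  # clockwise from copy B back to copy A
    len1 = (arc1[1] - arc1[0]) % n
    len2 = (arc2[1] - arc2[0]) % n
    if len1 == 0 or len2 == 0:
        return None  # copies abut: no quadripartite structure
    if len1 > len2 or (len1 == len2 and arc1[0] <= arc2[0]):
        lsc, ssc, lsc_len, ssc_len = arc1, arc2, len1, len2
    else:
        lsc, ssc, lsc_len, ssc_len = arc2, arc1, len2, len1
    # IRa: copy whose clockwise downstream arc is the SSC
    ira = top.interval_a if ssc == arc1 else top.interval_b
    irb = top.interval_b if ira == top.interval_a else top.interval_a
    return QuadripartiteArchitecture(
        lsc=lsc,
        ssc=ssc,
        ira=ira,
        irb=irb,
        lengths={"lsc": lsc_len, "ssc": ssc_len, "ir": L},
        total=n,
    )


def base_composition(seq: CircularSequence) -> dict[str, float]:
    """Proportions of A/C/G/T (N excluded from the denominator) plus A+T."""
    counts = {b: seq.residues.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise CompositionError("sequence contains no unambiguous residues")
    props = {b: c / denom for b, c in counts.items()}
    props["AT"] = props["A"] + props["T"]
    return props
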