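"""Reference-guided read recruitment and contig ordering via canonical k-mers.

Reads are classified by k-mer containment against an index of reference
plastomes: a read is recruited when the fraction of its k-mers found in the
index reaches a threshold.  Contigs are placed on a reference by majority vote
of unique anchors (k-mers occurring exactly once in the reference), which
yields an offset and an orientation per contig.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass

from .records import CircularSequence, ParameterError, PlastomeRecord, reverse_complement
from .simulate import ReadSet

logger = logging.getLogger(__name__)


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _kmers(seq: str, k: int, circular: bool) -> Iterable[tuple[int, str]]:
    n = len(seq)
    if circular:
        doubled = seq + seq[: k - 1]
        return ((i, doubled[i : i + k]) for i in range(n))
    return ((i, seq[i : i + k]) for i in range(n - k + 1))


@dataclass(frozen=True)
class KmerIndex:
    k: int
    words: frozenset[str]  # canonical k-mers

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.words


def build_index(references: Iterable[CircularSequence], k: int = 21) -> KmerIndex:
    """Canonical k-mer set of the references (origin-wrapping words included)."""
    refs = list(references)
    if not refs:
        raise ParameterError("no reference sequences given")
    if k < 11:
        raise ParameterError("k must be >= 11")
    if k > min(len(r) for r in refs):
        raise ParameterError("k longer than the shortest reference")
    words: set[str] = set()
    for ref in refs:
        for _, word in _kmers(ref.residues, k, ref.is_circular):
            if "N" not in word:
                words.add(canonical(word))
    return KmerIndex(k=k, words=frozenset(words))


def containment(read: str, index: KmerIndex) -> float:
    """Fraction of the read's k-mers present in the index (N k-mers never match)."""
    k = index.k
    if len(read) < k:
        raise ParameterError(f"read shorter than k={k}")
    total = len(read) - k + 1
    hits = sum(1 for i in range(total) if "N" not in read[i : i + k]
               and read[i : i + k] in index)
    return hits / total


def classify_reads(reads: ReadSet, index: KmerIndex, min_containment: float = 0.5) -> ReadSet:
    """Subset of reads whose k-mer containment reaches the threshold."""
    if not reads.reads:
        logger.warning("classify_reads called on an empty read set")
        return ReadSet(reads=(), read_len=reads.read_len)
    kept = tuple(r for r in reads.reads if containment(r[1], index) >= min_containment)
    return ReadSet(reads=kept, read_len=reads.read_len)


@dataclass(frozen=True)
class ContigPlacement:
    name: str
    offset: int
    strand: str
    votes: int


def _unique_anchors(reference: PlastomeRecord, k: int) -> dict[str, tuple[int, bool]]:
    """Canonical k-mers occurring exactly once in the reference -> (pos, was_forward)."""
    seen: dict[str, tuple[int, bool] | None] = {}
    seq = reference.sequence
    for pos, word in _kmers(seq.residues, k, seq.is_circular):
        if "N" in word:
            continue
        canon = canonical(word)
        seen[canon] = None if canon in seen else (pos, word == canon)
    return {w: v for w, v in seen.items() if v is not None}


def order_contigs(
    contigs: dict[str, str] | list[tuple[str, str]],
    reference: PlastomeRecord,
    anchor_k: int = 21,
) -> tuple[list[ContigPlacement], list[str]]:
    """Order and orient contigs along a reference by unique-anchor voting.

    Returns (placements sorted by offset, unplaceable contig names).  A contig
    with no unique anchor hits is unplaceable, not an error.  Ties are broken
    toward the forward orientation and the smallest offset.
    """
    items = sorted(dict(contigs).items())
    if not items:
        raise ParameterError("no contigs given")
    anchors = _unique_anchors(reference, anchor_k)
    n_ref = len(reference.sequence)
    placed: list[ContigPlacement] = []
    unplaceable: list[str] = []
    for name, contig in items:
        votes: Counter[tuple[str, int]] = Counter()
        if len(contig) >= anchor_k:
            for pos, word in _kmers(contig, anchor_k, circular=False):
                if "N" in word:
                    continue
                canon = canonical(word)
                hit = anchors.get(canon)
                if hit is None:
                    continue
                ref_pos, ref_forward = hit
                same = (word == canon) == ref_forward
                if same:
                    votes[("+", (ref_pos - pos) % n_ref)] += 1
                else:
                    rc_pos = len(contig) - anchor_k - pos
                    votes[("-", (ref_pos - rc_pos) % n_ref)] += 1
        if not votes:
            unplaceable.append(name)
            continue
        (strand, offset), n_votes = min(
            votes.items(), key=lambda kv: (-kv[1], kv[0][0] != "+", kv[0][1])
        )
        placed.append(ContigPlacement(name=name, offset=offset, strand=strand, votes=n_votes))
    placed.sort(key=lambda p: (p.offset, p.name))
    return placed, unplaceable
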