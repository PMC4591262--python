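"""Gene-order collinearity between two annotated plastomes.

Two genomes are reduced to a signed permutation: genome B's shared genes are
expressed as signed indices in genome A's circular order (sign = strand
agreement), linearized at a deterministic anchor (the shared gene with the
lexicographically smallest name).  Maximal strips of the permutation are the
collinear blocks; an inverted segment appears as a run of negated indices.
tRNAs are excluded by default, matching how gene-order comparisons of plastid
genomes are usually drawn for protein-coding genes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import PlastokitError, PlastomeRecord

# tiny alias table for cross-annotation symbol drift
_ALIASES = {"rbcl": "rbcL", "psba": "psbA", "orf76": "ORF76"}


class EmptyPermutationError(PlastokitError):
    """The two genomes share no genes."""


def _normalize(name: str) -> str:
    return _ALIASES.get(name.lower(), name.lower())


@dataclass(frozen=True)
class SignedPermutation:
    order: tuple[int, ...]  # genome B in the frame of A; |values| = 1..n
    gene_names: tuple[str, ...]  # index i (1-based) -> name
    excluded_a: tuple[str, ...]  # private to A
    excluded_b: tuple[str, ...]  # private to B

    def __post_init__(self) -> None:
        if sorted(abs(v) for v in self.order) != list(range(1, len(self.order) + 1)):
            raise PlastokitError("signed values are not a permutation of 1..n")


@dataclass(frozen=True)
class CollinearBlock:
    genes: tuple[str, ...]
    orientation: str  # "same" | "inverted"
    length: int


def _gene_sequence(record: PlastomeRecord, include_trna: bool) -> list[tuple[str, str]]:
    """(name, strand) of features in circular order, duplicates disambiguated."""
    kinds = {"CDS", "rRNA"} | ({"tRNA"} if include_trna else set())
    feats = [f for f in sorted(record.features, key=lambda f: f.start) if f.kind in kinds]
    seen: dict[str, int] = {}
    out = []
    for f in feats:
        base = _normalize(f.name)
        idx = seen.get(base, 0)
        seen[base] = idx + 1
        out.append((f"{base}#{idx}" if idx else base, f.strand))
    return out


def shared_gene_permutation(
    record_a: PlastomeRecord, record_b: PlastomeRecord, include_trna: bool = False
) -> SignedPermutation:
    """Genome B's shared-gene order as signed indices in genome A's frame."""
    genes_a = _gene_sequence(record_a, include_trna)
    genes_b = _gene_sequence(record_b, include_trna)
    names_a = {g for g, _ in genes_a}
    names_b = {g for g, _ in genes_b}
    shared = names_a & names_b
    if not shared:
        raise EmptyPermutationError("no shared gene names between the two genomes")
    anchor = min(shared)

    def linearize(genes: list[tuple[str, str]], flip: bool) -> list[tuple[str, str]]:
        kept = [(g, s) for g, s in genes if g in shared]
        if flip:  # traverse the other way round the circle, strands flip
            kept = [(g, "-" if s == "+" else "+") for g, s in reversed(kept)]
        k = next(i for i, (g, _) in enumerate(kept) if g == anchor)
        return kept[k:] + kept[:k]

    lin_a = linearize(genes_a, flip=False)
    strand_a = dict(lin_a)
    # orient B so the anchor gene agrees in strand with A (circular alignment
    # start and reading direction are both arbitrary)
    strand_b_raw = dict((g, s) for g, s in genes_b if g in shared)
    lin_b = linearize(genes_b, flip=strand_b_raw[anchor] != strand_a[anchor])

    index_a = {g: i + 1 for i, (g, _) in enumerate(lin_a)}
    order = tuple(
        index_a[g] if s == strand_a[g] else -index_a[g] for g, s in lin_b
    )
    return SignedPermutation(
        order=order,
        gene_names=tuple(g for g, _ in lin_a),
        excluded_a=tuple(sorted(names_a - shared)),
        excluded_b=tuple(sorted(names_b - shared)),
    )


def collinear_blocks(perm: SignedPermutation) -> list[CollinearBlock]:
    """Partition the permutation into maximal strips.

    Consecutive entries extend a strip when the signed value increases by one
    with an unchanged sign: (1,2,3) is a same-orientation strip and
    (-6,-5,-4) an inverted one.
    """
    if not perm.order:
        raise PlastokitError("empty permutation")
    blocks: list[CollinearBlock] = []
    run = [perm.order[0]]
    for v in perm.order[1:]:
        if v == run[-1] + 1 and (v > 0) == (run[-1] > 0):
            run.append(v)
        else:
            blocks.append(_block(run, perm.gene_names))
            run = [v]
    blocks.append(_block(run, perm.gene_names))
    return blocks


def _block(run: list[int], names: tuple[str, ...]) -> CollinearBlock:
    return CollinearBlock(
        genes=tuple(names[abs(v) - 1] for v in run),
        orientation="same" if run[0] > 0 else "inverted",
        length=len(run),
    )


def synteny_summary(blocks: list[CollinearBlock]) -> dict[str, float]:
    """Block count, largest block, and fraction of genes inside blocks >= 2 genes."""
    total = sum(b.length for b in blocks)
    in_blocks = sum(b.length for b in blocks if b.length >= 2)
    return {
        "n_blocks": len(blocks),
        "largest_block": max((b.length for b in blocks), default=0),
        "fraction_in_blocks": in_blocks / total if total else 0.0,
    }
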