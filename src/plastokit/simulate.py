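"""Synthetic plastome generator.

Builds circular genomes with the structural properties the downstream analyses
measure: a quadripartite LSC/IRa/SSC/IRb layout with an exact inverted-repeat
pair, a configurable gene inventory without introns, planted gene overlaps,
a perfect-palindrome intergenic hairpin, trinucleotide tandem repeats inside
designated coding genes, and exact start/stop codon assignments.  Defaults
reproduce the architecture of the *Undaria pinnatifida* plastome (130,383 nt;
LSC 76,598 / SSC 42,977 / IR 5,404; 69.38% A+T; 139 CDS + 28 tRNA + 6 rRNA).

Gene sequences are random codons drawn to match the target A+T fraction; no
attempt is made at realistic protein content, since only structural statistics
are analysed downstream.  Each gene's base sequence is seeded from
``(gene_seed, crc32(name))`` so the same gene is identical across simulated
species, which makes ortholog comparisons meaningful; species-level layout
uses an independent stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .records import (
    CircularSequence,
    GeneFeature,
    ParameterError,
    PlastokitError,
    PlastomeRecord,
    STOP_CODONS,
    reverse_complement,
)

BASES = np.array(list("ACGT"))


class CapacityError(PlastokitError):
    """The requested gene inventory does not fit in the requested lengths."""


# ---------------------------------------------------------------- config

# canonical ordering used for the base species; adjacent constrained pairs
# (overlaps, hairpin flanks) are kept adjacent here
_NAMED_ORDER = (
    "psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbL", "psbN",
    "psaA", "psaB", "psaC", "psaL", "rbcR", "rbcL",
    "atpA", "atpB", "atpH", "petB", "petG",
    "rpl2", "rpl20", "rpl23", "rpl4", "rpl3", "rpl33",
    "rps8", "rps11", "rps12", "rps14", "rps19", "rps20",
    "rpoA", "rpoB", "ftrB", "ycf12", "ycf16", "ycf24", "ycf35", "ilvB",
)

_TRNA_NAMES = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnQ", "trnE", "trnG", "trnH",
    "trnI", "trnL", "trnK", "trnM", "trnF", "trnP", "trnS", "trnT", "trnW",
    "trnY", "trnV", "trnfM", "trnL2", "trnS2", "trnR2", "trnG2", "trnI2",
    "trnM2", "trnT2", "trnV2", "trnW2",
)

_RRNA = (("rrn16", 1491), ("rrn23", 2894), ("rrn5", 111))


def default_cds_names(n_cds: int = 139, include_petL: bool = False,
                      include_orf76: bool = False) -> tuple[str, ...]:
    names = list(_NAMED_ORDER)
    if include_petL:
        names.insert(names.index("petG") + 1, "petL")
    if include_orf76:
        names.append("ORF76")
    fillers_needed = n_cds - len(names)
    if fillers_needed < 0:
        raise ParameterError(f"n_cds={n_cds} smaller than the named gene set")
    names.extend(f"orf{100 + i}" for i in range(fillers_needed))
    return tuple(names)


@dataclass(frozen=True)
class RepeatPlan:
    gene: str
    unit: str  # 1-6 nt
    copies: int
    context_before: tuple[str, int] | None = None
    context_after: tuple[str, int] | None = None


@dataclass(frozen=True)
class SimConfig:
    """Planted parameters of one synthetic plastome.

    Defaults are the *U. pinnatifida* study conditions.  ``gene_seed`` feeds
    the species-independent per-gene streams; leave it equal across configs
    that should represent orthologous genomes.
    """

    seed: int = 0
    name: str = "synthetic_plastome"
    lsc_len: int = 76598
    ssc_len: int = 42977
    ir_len: int = 5404
    at_fraction: float = 0.6938
    n_trna: int = 28
    n_rrna: int = 6  # 6 = one rRNA operon per IR copy; 3 = single copy in SSC; 0 = none
    cds_names: tuple[str, ...] = field(default_factory=default_cds_names)
    # an overlap that is a multiple of 3 would put geneA's stop in geneB's
    # frame on the same strand, so the 6-nt pair is convergent (3'-3')
    overlap_spec: tuple[tuple[str, str, int, bool], ...] = (
        ("rpl23", "rpl4", 8, True),
        ("ftrB", "ycf12", 6, False),
        ("ycf16", "ycf24", 4, True),
        ("psbC", "psbD", 53, True),
    )
    hairpin_spec: tuple[str, str, int] | None = ("psaL", "rbcR", 84)
    repeat_spec: tuple[RepeatPlan, ...] = (
        RepeatPlan("ycf35", "ATT", 3, context_before=("AAT", 4)),
        RepeatPlan("ilvB", "AAA", 4, context_after=("GAA", 3)),
    )
    start_codon_spec: dict[str, str] = field(
        default_factory=lambda: {"atpA": "ATT", "rps8": "GTG", "psbF": "GTG"}
    )
    stop_codon_spec: dict[str, str] = field(default_factory=lambda: {"ycf16": "TGA"})
    stop_counts: dict[str, int] = field(default_factory=lambda: {"TAG": 21, "TGA": 2})
    length_deltas: dict[str, int] = field(default_factory=lambda: {"rpl33": 15})
    inverted_segments: tuple[tuple[int, int], ...] = ()
    gene_seed: int | None = None

    def __post_init__(self) -> None:
        if self.lsc_len < self.ssc_len:
            raise ParameterError("lsc_len must be >= ssc_len")
        if self.ir_len < 0:
            raise ParameterError("ir_len must be >= 0")
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ParameterError("at_fraction must lie in [0, 1]")
        if self.hairpin_spec is not None and self.hairpin_spec[2] % 2 != 0:
            raise ParameterError("palindrome span must be even (zero-loop hairpin)")
        if self.n_rrna not in (0, 3, 6):
            raise ParameterError("n_rrna must be 0, 3 or 6")
        if self.n_rrna == 6 and 0 < self.ir_len < 5000:
            raise CapacityError("ir_len too small for an rRNA operon in each repeat")
        order = {g: i for i, g in enumerate(self.cds_names)}
        for a, b, ov, _ in self.overlap_spec:
            if order.get(b, -99) != order.get(a, 99) + 1:
                raise ParameterError(f"overlap pair {a}/{b} must be adjacent in cds_names")
            if ov < 4:
                raise ParameterError("overlaps shorter than 4 nt are not supported")

    @property
    def gene_inventory(self) -> dict[str, int]:
        rrna = self.n_rrna
        if rrna == 6 and self.ir_len == 0:
            rrna = 3  # no repeat to duplicate the operon into
        return {"CDS": len(self.cds_names), "tRNA": self.n_trna, "rRNA": rrna}

    @property
    def total_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


def paper_config(species: str, seed: int = 0) -> SimConfig:
    """Preset configs emulating the four compared brown-algal plastomes.

    All four share ``gene_seed`` so orthologous genes have identical base
    sequences apart from the planted differences; they are synthetic
    stand-ins, not the GenBank records.
    """
    base = SimConfig(seed=seed, gene_seed=seed, name=f"{species}_synthetic")
    if species == "U_pinnatifida":
        return base
    if species == "S_japonica":
        return replace(
            base,
            seed=seed + 1,
            name=f"{species}_synthetic",
            ir_len=5404 + 92,
            n_trna=29,
            start_codon_spec={"rps8": "GTG", "psbF": "GTG"},
            stop_counts={"TAG": 24, "TGA": 1},
            stop_codon_spec={"ycf16": "TGA"},
            repeat_spec=(
                RepeatPlan("ycf35", "ATT", 4, context_before=("AAT", 4)),
                RepeatPlan("ilvB", "AAA", 3, context_after=("GAA", 3)),
            ),
            length_deltas={"rps20": 30, "rpoB": 15, "rpoA": 12},
            hairpin_spec=None,
        )
    if species == "E_siliculosus":
        names = default_cds_names(148, include_petL=True)
        return replace(
            base,
            seed=seed + 2,
            name=f"{species}_synthetic",
            cds_names=names,
            start_codon_spec={"rpl3": "GTG", "rps8": "GTG", "rbcR": "GTG"},
            stop_counts={"TAG": 14, "TGA": 5},
            stop_codon_spec={"ycf16": "TGA"},
            repeat_spec=(
                RepeatPlan("ycf35", "ATT", 3, context_before=("AAT", 4)),
                RepeatPlan("ilvB", "AAA", 4, context_after=("GAA", 3)),
            ),
            length_deltas={},
            hairpin_spec=None,
            inverted_segments=((60, 90),),
        )
    if species == "F_vesiculosus":
        names = default_cds_names(139, include_petL=True, include_orf76=True)
        return replace(
            base,
            seed=seed + 3,
            name=f"{species}_synthetic",
            cds_names=names,
            start_codon_spec={"rpl3": "GTG", "psbF": "GTG", "ORF76": "ATT"},
            stop_counts={"TAG": 17, "TGA": 9},
            stop_codon_spec={"ycf16": "TGA"},
            repeat_spec=(),
            length_deltas={},
            hairpin_spec=None,
            inverted_segments=((50, 70), (100, 120)),
        )
    raise ParameterError(f"unknown species preset {species!r}")


# ---------------------------------------------------------------- randomness helpers

def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng([int(k) & 0x7FFFFFFF for k in keys])


def _gene_key(name: str) -> int:
    return zlib.crc32(name.encode())


def _base_probs(at: float) -> np.ndarray:
    return np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])


def _random_bases(rng: np.random.Generator, n: int, at: float) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(BASES, size=n, p=_base_probs(at)))


def _random_codons(rng: np.random.Generator, n_codons: int, at: float) -> list[str]:
    """Random codons at the target base composition, stop codons excluded."""
    out: list[str] = []
    while len(out) < n_codons:
        chunk = rng.choice(BASES, size=(n_codons - len(out), 3), p=_base_probs(at))
        for row in chunk:
            codon = "".join(row)
            if codon not in STOP_CODONS:
                out.append(codon)
    return out


# ---------------------------------------------------------------- gene construction

def _plant_repeat(plan: RepeatPlan) -> str:
    parts = ["GGC"]
    if plan.context_before:
        unit, copies = plan.context_before
        parts.append(unit * copies)
    parts.append(plan.unit * plan.copies)
    if plan.context_after:
        unit, copies = plan.context_after
        parts.append(unit * copies)
    parts.append("GGC")
    planted = "".join(parts)
    if len(planted) % 3 != 0:
        raise ParameterError("planted repeat cassette must be codon-aligned")
    return planted


def _build_cds(config: SimConfig, gene: str, start: str, stop: str) -> str:
    gseed = config.gene_seed if config.gene_seed is not None else config.seed
    rng = _rng(gseed, _gene_key(gene))
    n_codons = 100 + int(rng.integers(0, 234))  # 300-999 nt
    body = _random_codons(rng, n_codons - 2, config.at_fraction)
    for plan in config.repeat_spec:
        if plan.gene == gene:
            # pure insertion at the midpoint, so orthologs built with different
            # copy numbers differ by exactly the extra units
            cassette = _plant_repeat(plan)
            mid = len(body) // 2
            body = body[:mid] + [cassette[i : i + 3] for i in range(0, len(cassette), 3)] \
                + body[mid:]
    delta = config.length_deltas.get(gene, 0)
    if delta:
        if delta % 3 != 0:
            raise ParameterError(f"length delta for {gene} must be a codon multiple")
        extra_rng = _rng(gseed, _gene_key(gene), 901)
        if delta > 0:
            body = body + _random_codons(extra_rng, delta // 3, config.at_fraction)
        else:
            body = body[: delta // 3]
    return start + "".join(body) + stop


def _gene_strand(config: SimConfig, gene: str) -> str:
    gseed = config.gene_seed if config.gene_seed is not None else config.seed
    rng = _rng(gseed, _gene_key(gene), 77)
    return "+" if rng.random() < 0.5 else "-"


def _assign_codons(config: SimConfig) -> tuple[dict[str, str], dict[str, str]]:
    starts = {g: config.start_codon_spec.get(g, "ATG") for g in config.cds_names}
    stops = dict(config.stop_codon_spec)
    rng = _rng(config.seed, 1311)
    remaining = [g for g in sorted(config.cds_names) if g not in stops]
    for codon in ("TAG", "TGA"):
        want = config.stop_counts.get(codon, 0) - sum(1 for s in stops.values() if s == codon)
        if want < 0:
            raise ParameterError(f"explicit stop assignments exceed requested {codon} count")
        picked = list(rng.choice(np.array(remaining), size=want, replace=False)) if want else []
        for g in picked:
            stops[str(g)] = codon
        remaining = [g for g in remaining if g not in stops]
    for g in remaining:
        stops[g] = "TAA"
    return starts, stops


# ---------------------------------------------------------------- overlap realization

def _frame_clean(seq: str, skip_final: bool = True) -> bool:
    end = len(seq) - 3 if skip_final else len(seq)
    return all(seq[i : i + 3] not in STOP_CODONS for i in range(0, end, 3))


def _realize_same_strand_overlap(
    seq_a: str, len_b: int, ov: int, start_b: str, stop_a: str, stop_b: str,
    rng: np.random.Generator, at: float,
) -> tuple[str, str]:
    """Rewrite geneA's tail so geneB starts ``ov`` nt before geneA's end."""
    la = len(seq_a)
    if ov >= min(la, len_b):
        raise ParameterError("overlap must be shorter than both genes")
    # rewrite a window that includes two geneA body codons upstream of the
    # overlap: for short overlaps the tail itself has no free bases, and the
    # upstream codon must be steerable away from stops in the new context
    win = ov + 6
    region = list(seq_a[la - win :])
    sb_off = win - ov  # geneB's start codon sits at the overlap start
    region[sb_off : sb_off + 3] = list(start_b)
    for offset, idx in enumerate(range(win - 3, win)):  # geneA's stop
        if sb_off <= idx < sb_off + 3:
            if region[idx] != stop_a[offset]:
                raise ParameterError(
                    f"a {ov} nt same-strand overlap with start {start_b!r} forces "
                    f"geneA stop {''.join(region[win - 3:])!r}, not {stop_a!r}"
                )
        else:
            region[idx] = stop_a[offset]
    fixed = set(range(sb_off, sb_off + 3)) | set(range(win - 3, win))
    free = [i for i in range(win) if i not in fixed]
    for _ in range(10000):
        for i in free:
            region[i] = str(rng.choice(BASES, p=_base_probs(at)))
        cand_a = seq_a[: la - win] + "".join(region)
        a_ok = _frame_clean(cand_a[la - win - (la - win) % 3 :], skip_final=True) \
            and cand_a[-3:] == stop_a
        tail = region[sb_off:]
        b_inner = all(
            "".join(tail[j : j + 3]) not in STOP_CODONS for j in range(3, ov - 2, 3)
        )
        if a_ok and b_inner:
            break
    else:
        raise CapacityError("could not satisfy overlap frame constraints")
    # geneB: fixed prefix, random stop-free continuation, its own stop at the end
    b = list("".join(tail) + _random_bases(rng, len_b - ov, at))
    b[len_b - 3 :] = list(stop_b)
    for j in range(3, len_b - 3, 3):
        guard = 0
        while "".join(b[j : j + 3]) in STOP_CODONS:
            frees = [p for p in range(j, j + 3) if p >= ov and p < len_b - 3]
            if not frees:
                raise CapacityError("fixed overlap bases force a stop codon in geneB")
            for p in frees:
                b[p] = str(rng.choice(BASES, p=_base_probs(at)))
            guard += 1
            if guard > 10000:
                raise CapacityError("could not de-stop geneB continuation")
    return cand_a, "".join(b)


def _realize_opposite_strand_overlap(
    seq_a: str, len_b: int, ov: int, start_b: str, stop_a: str, stop_b: str,
    rng: np.random.Generator, at: float,
) -> tuple[str, str]:
    """GeneB on the minus strand, its 3' end overlapping geneA's tail."""
    if ov < 6:
        raise ParameterError("opposite-strand overlaps need ov >= 6")
    la = len(seq_a)
    tail = list(seq_a[la - ov :])
    tail[0:3] = list(reverse_complement(stop_b))  # B's stop read off the minus strand
    tail[ov - 3 :] = list(stop_a)
    free = [i for i in range(3, ov - 3)]
    for _ in range(10000):
        for i in free:
            tail[i] = str(rng.choice(BASES, p=_base_probs(at)))
        cand_a = seq_a[: la - ov] + "".join(tail)
        b_fixed = reverse_complement("".join(tail))  # = seq_b[len_b-ov:]
        phase = (len_b - ov) % 3
        b_inner = all(
            b_fixed[j : j + 3] not in STOP_CODONS
            for j in range((3 - phase) % 3, ov - 5, 3)
        )
        if _frame_clean(cand_a[la - ov - (la - ov) % 3 :]) and cand_a[-3:] == stop_a and b_inner:
            break
    else:
        raise CapacityError("could not satisfy opposite-strand overlap constraints")
    for _ in range(10000):
        prefix = [start_b] + _random_codons(rng, (len_b - ov) // 3 + 2, at)
        b = "".join(prefix)[: len_b - ov] + reverse_complement("".join(tail))
        if _frame_clean(b) and b[-3:] == stop_b:
            return cand_a, b
    raise CapacityError("could not build a stop-free minus-strand partner")


# ---------------------------------------------------------------- assembly

@dataclass
class _Group:
    """A block of one or more genes placed as a unit (with internal geometry)."""

    genes: list[tuple[str, str, int, int, str]]  # (name, kind, rel_start, rel_end, strand)
    seq: str

    @property
    def span(self) -> int:
        return len(self.seq)


def _flip_group(group: _Group) -> _Group:
    n = len(group.seq)
    flipped = [
        (name, kind, n - e, n - s, "-" if strand == "+" else "+")
        for name, kind, s, e, strand in group.genes
    ]
    flipped.sort(key=lambda g: g[2])
    return _Group(genes=flipped, seq=reverse_complement(group.seq))


def _single_gene_group(name: str, kind: str, seq: str, strand: str) -> _Group:
    g = _Group(genes=[(name, kind, 0, len(seq), "+")], seq=seq)
    return _flip_group(g) if strand == "-" else g


def _build_groups(config: SimConfig, rng: np.random.Generator) -> list[_Group]:
    starts, stops = _assign_codons(config)
    cds_seqs = {g: _build_cds(config, g, starts[g], stops[g]) for g in config.cds_names}

    order = list(config.cds_names)
    forced_minus: set[str] = set()
    for lo, hi in config.inverted_segments:
        hi = min(hi, len(order))
        order[lo:hi] = order[lo:hi][::-1]
        forced_minus.update(order[lo:hi])

    def strand_of(gene: str) -> str:
        s = _gene_strand(config, gene)
        if gene in forced_minus:
            s = "-" if s == "+" else "+"
        return s

    overlap_by_first = {a: (b, ov, same) for a, b, ov, same in config.overlap_spec}
    hairpin = config.hairpin_spec
    gseed = config.gene_seed if config.gene_seed is not None else config.seed

    groups: list[_Group] = []
    used: set[str] = set()
    for gene in order:
        if gene in used:
            continue
        if gene in overlap_by_first:
            partner, ov, same = overlap_by_first[gene]
            if partner in used:
                raise ParameterError(f"overlap partner {partner} placed twice")
            seq_a = cds_seqs[gene]
            len_b = len(cds_seqs[partner])
            if same:
                seq_a, seq_b = _realize_same_strand_overlap(
                    seq_a, len_b, ov, starts[partner], stops[gene], stops[partner],
                    rng, config.at_fraction,
                )
                seg = seq_a + seq_b[ov:]
                grp = _Group(
                    genes=[(gene, "CDS", 0, len(seq_a), "+"),
                           (partner, "CDS", len(seq_a) - ov, len(seq_a) - ov + len_b, "+")],
                    seq=seg,
                )
            else:
                seq_a, seq_b = _realize_opposite_strand_overlap(
                    seq_a, len_b, ov, starts[partner], stops[gene], stops[partner],
                    rng, config.at_fraction,
                )
                seg = seq_a + reverse_complement(seq_b)[ov:]
                grp = _Group(
                    genes=[(gene, "CDS", 0, len(seq_a), "+"),
                           (partner, "CDS", len(seq_a) - ov, len(seq_a) - ov + len_b, "-")],
                    seq=seg,
                )
            if strand_of(gene) == "-":
                grp = _flip_group(grp)
            groups.append(grp)
            used.update((gene, partner))
        elif hairpin is not None and gene == hairpin[0]:
            # hairpin spacer between the two flanking genes, planted verbatim
            flank_a, flank_b, span = hairpin
            pal_rng = _rng(config.seed, 4242)
            half = _random_bases(pal_rng, span // 2, config.at_fraction)
            pal = half + reverse_complement(half)
            sa = cds_seqs[flank_a] if strand_of(flank_a) == "+" \
                else reverse_complement(cds_seqs[flank_a])
            sb = cds_seqs[flank_b] if strand_of(flank_b) == "+" \
                else reverse_complement(cds_seqs[flank_b])
            seg = sa + "GCA" + pal + "AGC" + sb  # A/A borders: palindrome stays maximal
            grp = _Group(
                genes=[(flank_a, "CDS", 0, len(sa), strand_of(flank_a)),
                       (flank_b, "CDS", len(sa) + 6 + span, len(seg), strand_of(flank_b))],
                seq=seg,
            )
            groups.append(grp)
            used.update((flank_a, flank_b))
        else:
            seq = cds_seqs[gene]
            groups.append(_single_gene_group(gene, "CDS", seq, strand_of(gene)))
            used.add(gene)

    # interleave tRNAs roughly evenly among the CDS groups
    trna_names = _TRNA_NAMES[: config.n_trna]
    if config.n_trna > len(_TRNA_NAMES):
        raise ParameterError("too many tRNAs requested")
    step = max(1, len(groups) // max(1, config.n_trna))
    for i, tname in enumerate(trna_names):
        trng = _rng(gseed, _gene_key(tname))
        tlen = 72 + int(trng.integers(0, 19))
        tseq = _random_bases(trng, tlen, config.at_fraction)
        pos = min(len(groups), (i + 1) * step + i)
        groups.insert(pos, _single_gene_group(tname, "tRNA", tseq, _gene_strand(config, tname)))
    return groups


def _rrna_group(config: SimConfig) -> list[tuple[str, int, str]]:
    gseed = config.gene_seed if config.gene_seed is not None else config.seed
    out = []
    for name, length in _RRNA:
        rng = _rng(gseed, _gene_key(name))
        out.append((name, length, _random_bases(rng, length, config.at_fraction)))
    return out


def _layout_region(
    groups: list[_Group], region_len: int, spacer_at: float, rng: np.random.Generator
) -> tuple[str, list[tuple[str, str, int, int, str]]]:
    """Concatenate groups with spacers filling the region to its exact length."""
    genic = sum(g.span for g in groups)
    n_gaps = len(groups) + 1
    rem = region_len - genic
    if rem < 2 * n_gaps:
        raise CapacityError(
            f"inventory needs {genic} nt plus {2 * n_gaps} nt of spacers; "
            f"region is only {region_len} nt"
        )
    base, extra = divmod(rem, n_gaps)
    pieces: list[str] = []
    feats: list[tuple[str, str, int, int, str]] = []
    cursor = 0
    for i, grp in enumerate(groups):
        gap = base + (1 if i < extra else 0)
        pieces.append(_random_bases(rng, gap, spacer_at))
        cursor += gap
        pieces.append(grp.seq)
        for name, kind, s, e, strand in grp.genes:
            feats.append((name, kind, cursor + s, cursor + e, strand))
        cursor += grp.span
    pieces.append(_random_bases(rng, base + (1 if len(groups) < extra else 0), spacer_at))
    region = "".join(pieces)
    assert len(region) == region_len
    return region, feats


def _spacer_at_fraction(config: SimConfig, genic_at: int, genic_len: int) -> float:
    nongenic = config.total_len - genic_len
    if nongenic <= 0:
        return config.at_fraction
    needed = (config.at_fraction * config.total_len - genic_at) / nongenic
    return min(0.98, max(0.02, needed))


def simulate_plastome(config: SimConfig) -> PlastomeRecord:
    """Build the synthetic circular plastome described by ``config``.

    Deterministic: the same config yields a byte-identical genome.
    """
    rng = _rng(config.seed, 9001)
    groups = _build_groups(config, rng)

    rrnas = _rrna_group(config) if config.n_rrna else []
    ir_core = sum(length for _, length, _ in rrnas) if config.n_rrna == 6 else 0
    if config.n_rrna == 6 and config.ir_len > 0:
        ir_rrnas, ssc_extra = rrnas, []
    else:
        ir_rrnas, ssc_extra = [], rrnas

    # split CDS/tRNA groups between LSC and SSC proportionally to capacity
    genic_total = sum(g.span for g in groups)
    ssc_rrna_len = sum(length for _, length, _ in ssc_extra)
    lsc_share = (config.lsc_len - 0) / (config.lsc_len + config.ssc_len - ssc_rrna_len)
    lsc_groups: list[_Group] = []
    ssc_groups: list[_Group] = []
    acc = 0
    for grp in groups:
        if acc + grp.span / 2 <= lsc_share * genic_total:
            lsc_groups.append(grp)
        else:
            ssc_groups.append(grp)
        acc += grp.span
    for name, length, seq in ssc_extra:
        ssc_groups.append(_single_gene_group(name, "rRNA", seq, "+"))

    # A+T compensation: spacers absorb the difference between the genic
    # composition and the genome-wide target
    genic_at = sum(g.seq.count("A") + g.seq.count("T") for g in lsc_groups + ssc_groups)
    genic_len = sum(g.span for g in lsc_groups + ssc_groups)
    if ir_rrnas:
        rr_at = sum(s.count("A") + s.count("T") for _, _, s in ir_rrnas)
        genic_at += 2 * rr_at
        genic_len += 2 * ir_core
    spacer_at = _spacer_at_fraction(config, genic_at, genic_len)

    lsc_seq, lsc_feats = _layout_region(lsc_groups, config.lsc_len, spacer_at, rng)
    ssc_seq, ssc_feats = _layout_region(ssc_groups, config.ssc_len, spacer_at, rng)

    ira_feats: list[tuple[str, str, int, int, str]] = []
    if config.ir_len > 0:
        if ir_rrnas:
            gaps = config.ir_len - ir_core
            n_gaps = len(ir_rrnas) + 1
            if gaps < 2 * n_gaps:
                raise CapacityError("ir_len too small for the rRNA operon")
            base, extra = divmod(gaps, n_gaps)
            pieces, cursor = [], 0
            for i, (name, length, seq) in enumerate(ir_rrnas):
                gap = base + (1 if i < extra else 0)
                pieces.append(_random_bases(rng, gap, spacer_at))
                cursor += gap
                pieces.append(seq)
                ira_feats.append((name, "rRNA", cursor, cursor + length, "+"))
                cursor += length
            pieces.append(_random_bases(rng, base + (1 if len(ir_rrnas) < extra else 0),
                                        spacer_at))
            ira_seq = "".join(pieces)
        else:
            ira_seq = _random_bases(rng, config.ir_len, spacer_at)
        irb_seq = reverse_complement(ira_seq)
    else:
        ira_seq = irb_seq = ""

    genome = list(lsc_seq + ira_seq + ssc_seq + irb_seq)
    total = config.total_len
    assert len(genome) == total

    if config.ir_len > 0:
        # keep the planted pair maximal: break complementarity at the junctions
        ls, ir, ss = config.lsc_len, config.ir_len, config.ssc_len
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        if genome[ls - 1] == comp[genome[0]]:
            genome[ls - 1] = "A" if comp[genome[0]] != "A" else "C"
        if genome[ls + ir] == comp[genome[ls + ir + ss - 1]]:
            genome[ls + ir + ss - 1] = "A" if comp[genome[ls + ir]] != "A" else "C"

    features: list[GeneFeature] = []
    offsets = [0, config.lsc_len + config.ir_len]
    for feats, off in ((lsc_feats, 0), (ssc_feats, config.lsc_len + config.ir_len)):
        for name, kind, s, e, strand in feats:
            features.append(GeneFeature(name=name, kind=kind, start=off + s, end=off + e,
                                        strand=strand))
    ira_off = config.lsc_len
    irb_off = config.lsc_len + config.ir_len + config.ssc_len
    for name, kind, s, e, strand in ira_feats:
        features.append(GeneFeature(name=name, kind=kind, start=ira_off + s, end=ira_off + e,
                                    strand=strand))
        # mirrored copy in IRb (reverse complemented)
        features.append(GeneFeature(
            name=name, kind=kind,
            start=irb_off + (config.ir_len - e), end=irb_off + (config.ir_len - s),
            strand="-" if strand == "+" else "+",
        ))
    features.sort(key=lambda f: f.start)

    seq = CircularSequence("".join(genome), name=config.name, is_circular=True)
    return PlastomeRecord(sequence=seq, features=features,
                          provenance=f"simulated seed={config.seed}")


def truth_table(config: SimConfig) -> dict[str, object]:
    """The planted parameters, as a flat mapping (the truth sidecar)."""
    starts, stops = _assign_codons(config)
    start_tally: dict[str, int] = {}
    stop_tally: dict[str, int] = {}
    for g in config.cds_names:
        start_tally[starts[g]] = start_tally.get(starts[g], 0) + 1
        stop_tally[stops[g]] = stop_tally.get(stops[g], 0) + 1
    truth: dict[str, object] = {
        "name": config.name,
        "total_len": config.total_len,
        "lsc_len": config.lsc_len,
        "ssc_len": config.ssc_len,
        "ir_len": config.ir_len,
        "at_fraction": config.at_fraction,
        "n_cds": len(config.cds_names),
        "n_trna": config.n_trna,
        "n_rrna": config.gene_inventory["rRNA"],
    }
    for codon, count in sorted(start_tally.items()):
        truth[f"start_{codon}"] = count
    for codon, count in sorted(stop_tally.items()):
        truth[f"stop_{codon}"] = count
    for a, b, ov, same in config.overlap_spec:
        truth[f"overlap_{a}_{b}"] = ov
    if config.hairpin_spec:
        fa, fb, span = config.hairpin_spec
        truth["palindrome_span"] = span
        truth["palindrome_flanks"] = f"{fa},{fb}"
    for plan in config.repeat_spec:
        truth[f"repeat_{plan.gene}"] = f"{plan.unit}x{plan.copies}"
    truth["gene_starts"] = ";".join(f"{g}={starts[g]}" for g in config.cds_names)
    truth["gene_stops"] = ";".join(f"{g}={stops[g]}" for g in config.cds_names)
    return truth


def write_truth_table(truth: dict[str, object], path) -> None:
    with open(path, "w") as fh:
        for key, value in truth.items():
            fh.write(f"{key}\t{value}\n")


# ---------------------------------------------------------------- reads

@dataclass(frozen=True)
class ReadSet:
    """Simulated reads with origin labels (for truth-set evaluation only)."""

    reads: tuple[tuple[str, str, str], ...]  # (id, sequence, label in {plastid, decoy})
    read_len: int


def simulate_reads(
    record: PlastomeRecord, decoy: CircularSequence, n_reads: int, read_len: int,
    plastid_fraction: float, seed: int,
) -> ReadSet:
    """Uniform (wrap-aware) reads from the plastome/decoy mix, labels retained."""
    if not 0.0 <= plastid_fraction <= 1.0:
        raise ParameterError("plastid_fraction must lie in [0, 1]")
    if read_len > min(len(record.sequence), len(decoy)):
        raise ParameterError("read_len exceeds a source sequence length")
    rng = _rng(seed, 5150)
    reads = []
    for i in range(n_reads):
        from_plastid = rng.random() < plastid_fraction
        src = record.sequence if from_plastid else decoy
        n = len(src)
        if src.is_circular:
            start = int(rng.integers(0, n))
            seq = src.fetch(start, (start + read_len) % n) if (start + read_len) % n != start \
                else src.residues
        else:
            start = int(rng.integers(0, n - read_len + 1))
            seq = src.residues[start : start + read_len]
        reads.append((f"read{i}", seq, "plastid" if from_plastid else "decoy"))
    return ReadSet(reads=tuple(reads), read_len=read_len)


def random_decoy(length: int, seed: int, at: float = 0.5) -> CircularSequence:
    """An i.i.d. background genome (default 50% A+T) for recruitment tests."""
    return CircularSequence(_random_bases(_rng(seed, 31337), length, at),
                            name="decoy", is_circular=True)


# ---------------------------------------------------------------- ortholog mutation

def mutate_ortholog(
    cds: str, unit: str, insert_copies: int, at_repeat_locus: bool = True
) -> str:
    """Insert (positive) or delete (negative) tandem-unit copies in a CDS.

    With ``at_repeat_locus`` the mutation lands on an existing array of >= 2
    copies of ``unit``; otherwise it is applied at the sequence midpoint.
    """
    if insert_copies == 0:
        raise ParameterError("insert_copies must be non-zero")
    if not 1 <= len(unit) <= 6:
        raise ParameterError("unit must be 1-6 nt")
    cds = cds.upper()
    u = len(unit)
    pos = None
    copies_here = 0
    if at_repeat_locus:
        for i in range(len(cds) - 2 * u + 1):
            c = 0
            while cds[i + c * u : i + (c + 1) * u] == unit:
                c += 1
            if c >= 2 and (i < u or cds[i - u : i] != unit):
                pos, copies_here = i, c
                break
        if pos is None:
            raise ParameterError(f"no tandem locus of {unit!r} (>=2 copies) in the CDS")
    else:
        pos = len(cds) // 2
    if insert_copies < 0 and -insert_copies > copies_here:
        raise ParameterError("deletion exceeds available copies at the locus")
    if insert_copies > 0:
        return cds[:pos] + unit * insert_copies + cds[pos:]
    return cds[:pos] + cds[pos + (-insert_copies) * u :]


# ---------------------------------------------------------------- protein families

_AA20 = np.array(list("ARNDCQEGHILKMFPSTWYV"))


def evolve_proteins(
    topology, n_sites: int = 200, subst_prob: float = 0.05, indel_prob: float = 0.0,
    seed: int = 0,
) -> dict[str, list[tuple[int, str]]]:
    """Evolve a protein family down a tree given as nested name tuples.

    Each site carries a persistent identity so tests can score how much true
    (planted) homology an aligner recovers.  Per branch, each site substitutes
    with ``subst_prob``; with ``indel_prob`` a site seeds a short (1-3 residue)
    deletion or insertion (inserted sites get fresh identities).

    Returns taxon -> list of (site_id, residue).
    """
    rng = _rng(seed, 2718)
    counter = [n_sites]
    root = [(i, str(rng.choice(_AA20))) for i in range(n_sites)]

    def mutate(seq: list[tuple[int, str]]) -> list[tuple[int, str]]:
        out: list[tuple[int, str]] = []
        i = 0
        while i < len(seq):
            sid, aa = seq[i]
            if indel_prob > 0 and rng.random() < indel_prob:
                if rng.random() < 0.5:  # deletion
                    i += 1 + int(rng.integers(0, 3))
                    continue
                for _ in range(1 + int(rng.integers(0, 3))):  # insertion
                    out.append((counter[0], str(rng.choice(_AA20))))
                    counter[0] += 1
            if rng.random() < subst_prob:
                aa = str(rng.choice(_AA20))
            out.append((sid, aa))
            i += 1
        return out

    leaves: dict[str, list[tuple[int, str]]] = {}

    def walk(node, seq) -> None:
        if isinstance(node, str):
            leaves[node] = seq
            return
        for child in node:
            walk(child, mutate(list(seq)))

    walk(topology, root)
    return leaves


def protein_strings(family: dict[str, list[tuple[int, str]]]) -> dict[str, str]:
    return {taxon: "".join(aa for _, aa in seq) for taxon, seq in family.items()}
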