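"""Marker-gene phylogeny: alignment, concatenation, distances, NJ, consensus.

The marker set is the 23 plastid protein-coding genes shared across published
plastid genomes.  Families are aligned progressively (pairwise affine-gap
alignments under BLOSUM62 -> UPGMA guide tree -> profile-profile merges) and
concatenated gene by gene; gap-containing sites are kept.  Distances are
Poisson-corrected p-distances over shared non-gap columns (pairwise deletion),
trees are built by neighbor joining with deterministic tie-breaking, and
support comes from bootstrap column resampling summarized as a majority-rule
consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .records import ParameterError, PlastokitError, PlastomeRecord, extract_cds, translate

logger = logging.getLogger(__name__)

DEFAULT_MARKERS = (
    "atpA", "atpB", "atpH", "rbcL", "petB", "petG", "psaA", "psaB", "psaC",
    "psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbL", "psbN",
    "rpl2", "rpl20", "rps11", "rps12", "rps14", "rps19",
)

_AA = "ARNDCQEGHILKMFPSTWYV"
_BLOSUM = substitution_matrices.load("BLOSUM62")
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_B62 = np.array([[float(_BLOSUM[a, b]) for b in _AA] for a in _AA])

GAP_OPEN = -10.0
GAP_EXTEND = -1.0
PROFILE_GAP = -8.0


class DistanceError(PlastokitError):
    """A pairwise distance is undefined (saturated or no shared sites)."""


# ---------------------------------------------------------------- trees

@dataclass
class TreeNode:
    """A rooted view of an (usually unrooted) tree; the root is a trifurcation
    for unrooted topologies.  ``length`` is the edge above the node."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name or ""]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support: bool = True) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.3g}"
        return f"({inner}){label}:{self.length:.6g}"

    def bipartitions(self, min_length: float | None = None) -> set[frozenset[str]]:
        """Leaf sets of internal edges (anchored: the side away from the root
        for each non-root internal node); trivial splits excluded."""
        all_leaves = set(self.leaves())
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode, is_root: bool) -> None:
            for child in node.children:
                if child.children:
                    side = frozenset(child.leaves())
                    if 2 <= len(side) <= len(all_leaves) - 2 and (
                        min_length is None or child.length >= min_length
                    ):
                        out.add(side)
                    walk(child, False)

        walk(self, True)
        return out


def tree_distance_matrix(tree: TreeNode) -> pd.DataFrame:
    """Leaf-to-leaf path lengths (for additivity checks)."""
    names = sorted(tree.leaves())
    dist = pd.DataFrame(0.0, index=names, columns=names)

    def walk(node: TreeNode) -> dict[str, float]:
        if not node.children:
            return {node.name: 0.0}
        sides = [walk(c) for c in node.children]
        for i in range(len(sides)):
            for j in range(i + 1, len(sides)):
                for la, da in sides[i].items():
                    for lb, db in sides[j].items():
                        d = da + node.children[i].length + db + node.children[j].length
                        dist.loc[la, lb] = dist.loc[lb, la] = d
        merged: dict[str, float] = {}
        for c, side in zip(node.children, sides):
            for leaf, d in side.items():
                merged[leaf] = d + c.length
        return merged

    walk(tree)
    return dist


def random_tree(names: list[str], rng: np.random.Generator,
                min_branch: float = 0.05, max_branch: float = 0.5) -> TreeNode:
    """A random unrooted binary topology with positive branch lengths."""
    if len(names) < 3:
        raise ParameterError("need >= 3 taxa")

    def bl() -> float:
        return float(rng.uniform(min_branch, max_branch))

    nodes = [TreeNode(name=n, length=bl()) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]], length=bl())
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return TreeNode(children=nodes)


# ---------------------------------------------------------------- markers

@dataclass
class MarkerSet:
    genes: dict[str, dict[str, str]]  # gene -> taxon -> protein
    taxa: tuple[str, ...]
    missing: tuple[tuple[str, str], ...]  # (taxon, gene)


def extract_markers(
    records: list[PlastomeRecord], markers: tuple[str, ...] = DEFAULT_MARKERS
) -> MarkerSet:
    """Translated marker proteins per taxon; duplicates resolved by first occurrence."""
    if len(records) < 3:
        raise ParameterError("marker extraction needs >= 3 genomes")
    taxa = tuple(r.sequence.name for r in records)
    genes: dict[str, dict[str, str]] = {}
    missing: list[tuple[str, str]] = []
    for gene in markers:
        per_taxon: dict[str, str] = {}
        for rec in records:
            feat = next((f for f in rec.features if f.kind == "CDS" and f.name == gene), None)
            if feat is None:
                missing.append((rec.sequence.name, gene))
                continue
            per_taxon[rec.sequence.name] = translate(extract_cds(rec, feat), is_start=True)
        if per_taxon:
            genes[gene] = per_taxon
        else:
            logger.warning("marker %s absent in all genomes; dropped", gene)
    return MarkerSet(genes=genes, taxa=taxa, missing=tuple(missing))


# ---------------------------------------------------------------- alignment

def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def align_pair(seq_a: str, seq_b: str) -> tuple[str, str, float]:
    """Global affine-gap alignment of two proteins (BLOSUM62, -10/-1)."""
    aln = _protein_aligner().align(seq_a, seq_b)
    best = aln[0]
    return str(best[0]), str(best[1]), float(best.score)


def _p_distance(row_a: str, row_b: str) -> float:
    shared = [(a, b) for a, b in zip(row_a, row_b) if a != "-" and b != "-"]
    if not shared:
        return 1.0
    return sum(a != b for a, b in shared) / len(shared)


def _profile_counts(rows: list[str]) -> np.ndarray:
    """20 x L residue-count matrix (gaps and unknown residues contribute zero)."""
    length = len(rows[0])
    counts = np.zeros((20, length))
    for row in rows:
        for pos, ch in enumerate(row):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx, pos] += 1
    return counts


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Profile-profile global DP with column scores = mean pairwise BLOSUM62."""
    la, lb = len(rows_a[0]), len(rows_b[0])
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    denom = len(rows_a) * len(rows_b)
    S = (ca.T @ _B62 @ cb) / denom  # (la, lb)
    g = -PROFILE_GAP  # positive cost
    H = np.full((la + 1, lb + 1), -np.inf)
    H[0, :] = -g * np.arange(lb + 1)
    H[:, 0] = -g * np.arange(la + 1)
    # wavefront over anti-diagonals: each depends only on the previous two
    for d in range(2, la + lb + 1):
        i_lo, i_hi = max(1, d - lb), min(la, d - 1)
        if i_lo > i_hi:
            continue
        ii = np.arange(i_lo, i_hi + 1)
        jj = d - ii
        diag = H[ii - 1, jj - 1] + S[ii - 1, jj - 1]
        up = H[ii - 1, jj] - g
        left = H[ii, jj - 1] - g
        H[ii, jj] = np.maximum(diag, np.maximum(up, left))
    # traceback, preferring diagonal, then up, then left (deterministic)
    i, j = la, lb
    ops: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
            ops.append("D")
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] - g:
            ops.append("U")
            i -= 1
        else:
            ops.append("L")
            j -= 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    for op in ops:
        if op in ("D", "U"):
            for r, row in enumerate(rows_a):
                out_a[r] += row[i]
            i += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
        if op in ("D", "L"):
            for r, row in enumerate(rows_b):
                out_b[r] += row[j]
            j += 1
        else:
            for r in range(len(rows_b)):
                out_b[r] += "-"
    return out_a, out_b


def align_protein_family(seqs: dict[str, str]) -> dict[str, str]:
    """Progressive multiple alignment of one protein family.

    Deterministic: pairwise distances feed a UPGMA guide tree (ties broken by
    taxon order) and profiles are merged along it.  Empty sequences are
    excluded with a warning.
    """
    items = [(t, s) for t, s in seqs.items() if s]
    for t, s in seqs.items():
        if not s:
            logger.warning("taxon %s has an empty sequence; excluded from family", t)
    if len(items) < 2:
        return {t: s for t, s in items}
    names = [t for t, _ in items]
    m = len(items)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ra, rb, _ = align_pair(items[i][1], items[j][1])
            dist[i, j] = dist[j, i] = _p_distance(ra, rb)
    # UPGMA agglomeration as guide
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([names[i]], [items[i][1]]) for i in range(m)
    }
    sizes = {i: 1 for i in range(m)}
    d = {(i, j): dist[i, j] for i in range(m) for j in range(i + 1, m)}
    next_id = m
    while len(clusters) > 1:
        (i, j), _ = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        names_i, rows_i = clusters.pop(i)
        names_j, rows_j = clusters.pop(j)
        rows_i, rows_j = _align_profiles(rows_i, rows_j)
        merged = (names_i + names_j, rows_i + rows_j)
        for k in list(clusters):
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(next_id, k), max(next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        d.pop((i, j), None)
        sizes[next_id] = sizes[i] + sizes[j]
        clusters[next_id] = merged
        next_id += 1
    final_names, final_rows = next(iter(clusters.values()))
    return dict(zip(final_names, final_rows))


# ---------------------------------------------------------------- concatenation

@dataclass
class ConcatenatedAlignment:
    taxa: tuple[str, ...]
    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]]  # gene -> half-open column range

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def concatenate(
    families: dict[str, dict[str, str]], taxa: tuple[str, ...],
    order: tuple[str, ...] | None = None,
) -> ConcatenatedAlignment:
    """Join aligned families in marker order; missing taxa get all-gap blocks.

    Gap-containing columns are retained as-is.
    """
    order = order or tuple(families)
    rows = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    cursor = 0
    for gene in order:
        fam = families.get(gene)
        if not fam:
            continue
        width = len(next(iter(fam.values())))
        if any(len(r) != width for r in fam.values()):
            raise ParameterError(f"family {gene} rows have unequal lengths")
        for t in taxa:
            rows[t].append(fam.get(t, "-" * width))
        partitions[gene] = (cursor, cursor + width)
        cursor += width
    return ConcatenatedAlignment(
        taxa=taxa, rows={t: "".join(parts) for t, parts in rows.items()},
        partitions=partitions,
    )


# ---------------------------------------------------------------- distances & NJ

def distance_matrix(aln: ConcatenatedAlignment) -> pd.DataFrame:
    """Poisson-corrected pairwise distances over shared non-gap columns."""
    if len(aln.taxa) < 3:
        raise ParameterError("need >= 3 taxa")
    names = list(aln.taxa)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    arr = {t: np.frombuffer(aln.rows[t].encode(), dtype="S1") for t in names}
    gap = np.bytes_(b"-")
    for i, ti in enumerate(names):
        for tj in names[i + 1 :]:
            shared = (arr[ti] != gap) & (arr[tj] != gap)
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise DistanceError(f"no shared sites between {ti} and {tj}")
            p = float((arr[ti][shared] != arr[tj][shared]).sum()) / n_shared
            if p >= 1.0:
                raise DistanceError(f"saturated distance between {ti} and {tj} (p={p})")
            mat.loc[ti, tj] = mat.loc[tj, ti] = -np.log(1.0 - p)
    return mat


def nj_tree(dist: pd.DataFrame) -> TreeNode:
    """Neighbor joining with deterministic tie-breaking (smallest index pair).

    Negative branch lengths are clamped to zero with a warning.
    """
    names = list(dist.index)
    if len(names) < 3:
        raise ParameterError("neighbor joining needs >= 3 taxa")
    d = dist.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ParameterError("distance matrix must be symmetric with zero diagonal")

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    nodes: list[TreeNode] = [TreeNode(name=n) for n in names]
    active = list(range(len(names)))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                key = (q[i, j], i, j)
                if best is None or key < best:
                    best = key
        _, bi, bj = best
        i_glob, j_glob = active[bi], active[bj]
        dij = sub[bi, bj]
        li = clamp(0.5 * dij + (r[bi] - r[bj]) / (2 * (m - 2)))
        lj = clamp(dij - (0.5 * dij + (r[bi] - r[bj]) / (2 * (m - 2))))
        nodes[i_glob].length = li
        nodes[j_glob].length = lj
        new = TreeNode(children=[nodes[i_glob], nodes[j_glob]])
        new_dist = 0.5 * (d[i_glob, :] + d[j_glob, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_dist
        d[:-1, -1] = new_dist
        d[-1, -1] = 0.0
        nodes.append(new)
        active = [a for a in active if a not in (i_glob, j_glob)] + [len(nodes) - 1]
    # join the last three at the root trifurcation
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    nodes[a].length = clamp(0.5 * (dab + dac - dbc))
    nodes[b].length = clamp(0.5 * (dab + dbc - dac))
    nodes[c].length = clamp(0.5 * (dac + dbc - dab))
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


# ---------------------------------------------------------------- bootstrap consensus

_ZERO_EDGE = 1e-9  # edges shorter than this carry no signal and are collapsed


def bootstrap_consensus(
    aln: ConcatenatedAlignment, replicates: int, threshold: float = 0.5, seed: int = 0
) -> TreeNode:
    """Majority-rule consensus of NJ trees over bootstrap column resamples.

    Bipartitions present in more than ``threshold`` of the replicates are
    assembled into a (possibly multifurcating) consensus; supports are the
    bipartition frequencies.  Zero-length internal edges are collapsed in each
    replicate before counting so that signal-free alignments yield a star.
    """
    if replicates < 10:
        raise ParameterError("use at least 10 bootstrap replicates")
    if not 0.0 < threshold < 1.0:
        raise ParameterError("threshold must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    width = aln.width
    taxa = aln.taxa
    counts: dict[frozenset[str], int] = {}
    n_ok = 0
    for _ in range(replicates):
        cols = rng.integers(0, width, size=width)
        rows = {t: "".join(aln.rows[t][c] for c in cols) for t in taxa}
        boot = ConcatenatedAlignment(taxa=taxa, rows=rows, partitions={})
        try:
            tree = nj_tree(distance_matrix(boot))
        except DistanceError:
            logger.warning("bootstrap replicate skipped (saturated distances)")
            continue
        n_ok += 1
        anchor = sorted(taxa)[0]
        for bp in tree.bipartitions(min_length=_ZERO_EDGE):
            canon = bp if anchor not in bp else frozenset(taxa) - bp
            counts[canon] = counts.get(canon, 0) + 1
    if n_ok == 0:
        raise DistanceError("all bootstrap replicates failed")
    majority = {bp: c / n_ok for bp, c in counts.items() if c / n_ok > threshold}

    # assemble: star tree refined by the majority clusters, largest first
    root = TreeNode(children=[TreeNode(name=t) for t in sorted(taxa)])
    for bp in sorted(majority, key=lambda b: (-len(b), sorted(b))):
        side = bp if sorted(taxa)[0] not in bp else frozenset(taxa) - bp
        _insert_cluster(root, side, majority[bp])
    return root


def _insert_cluster(root: TreeNode, cluster: frozenset[str], support: float) -> None:
    node = root
    while True:
        child_match = None
        for child in node.children:
            leaves = set(child.leaves())
            if cluster <= leaves and cluster != leaves:
                child_match = child
                break
        if child_match is None or not child_match.children:
            break
        node = child_match
    inside = [c for c in node.children if set(c.leaves()) <= cluster]
    if len(inside) < 2 or sum(len(c.leaves()) for c in inside) != len(cluster):
        logger.warning("cluster %s incompatible with consensus so far; skipped", sorted(cluster))
        return
    for c in inside:
        node.children.remove(c)
    node.children.append(TreeNode(children=inside, support=support, length=1.0))
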