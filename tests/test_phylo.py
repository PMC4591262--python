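"""Marker extraction, alignment, distances, NJ, and bootstrap consensus."""

import numpy as np
import pytest

from plastokit.phylo import (
    DEFAULT_MARKERS,
    ConcatenatedAlignment,
    DistanceError,
    align_pair,
    align_protein_family,
    bootstrap_consensus,
    concatenate,
    distance_matrix,
    extract_markers,
    nj_tree,
    random_tree,
    tree_distance_matrix,
)
from plastokit.simulate import evolve_proteins, protein_strings

BLOSUM_PAIRS = {("M", "M"): 5, ("K", "K"): 5, ("V", "V"): 4, ("K", "V"): -2}


def _aln_from_rows(**rows: str) -> ConcatenatedAlignment:
    return ConcatenatedAlignment(taxa=tuple(rows), rows=rows, partitions={})


class TestExtractMarkers:
    def test_full_marker_matrix(self, four_records):
        ms = extract_markers(list(four_records.values()))
        assert len(ms.genes) == 23
        assert all(len(per_taxon) == 4 for per_taxon in ms.genes.values())
        assert ms.missing == ()

    def test_deliberate_deletion_is_flagged_missing(self, four_records):
        from plastokit.records import PlastomeRecord

        recs = list(four_records.values())
        target = recs[0]
        pruned = PlastomeRecord(
            sequence=target.sequence,
            features=[f for f in target.features if f.name != "petG"],
        )
        ms = extract_markers([pruned] + recs[1:])
        assert (target.sequence.name, "petG") in ms.missing
        assert len(ms.genes["petG"]) == 3  # the other genomes are intact

    def test_default_marker_list_has_23_names(self):
        assert len(DEFAULT_MARKERS) == 23
        assert len(set(DEFAULT_MARKERS)) == 23

    def test_too_few_genomes_rejected(self, four_records):
        with pytest.raises(Exception):
            extract_markers(list(four_records.values())[:2])


class TestAlignment:
    def test_identical_sequences_align_without_gaps(self):
        rows = align_protein_family({"a": "MKVLW", "b": "MKVLW"})
        assert rows == {"a": "MKVLW", "b": "MKVLW"}

    def test_small_pair_matches_hand_dp(self):
        # brute force over the three possible single-gap placements of MV on MKV
        from Bio.Align import substitution_matrices

        B = substitution_matrices.load("BLOSUM62")
        candidates = {
            "M-V": B["M", "M"] - 10 + B["V", "V"],
            "MV-": B["M", "M"] + B["K", "V"] - 10,
            "-MV": -10 + B["K", "M"] + B["V", "V"],
        }
        row_a, row_b, score = align_pair("MKV", "MV")
        assert score == max(candidates.values())
        assert (row_a, row_b) == ("MKV", max(candidates, key=candidates.get))

    def test_planted_homologous_columns_recovered(self):
        fams = evolve_proteins(
            (("A", "B"), ("C", "D")), n_sites=150, subst_prob=0.08,
            indel_prob=0.02, seed=9,
        )
        aligned = align_protein_family(protein_strings(fams))
        # map aligned columns back to planted site identities
        ids = {}
        for taxon, row in aligned.items():
            sids = iter(sid for sid, _ in fams[taxon])
            ids[taxon] = [next(sids) if ch != "-" else None for ch in row]
        taxa = list(aligned)
        total = correct = 0
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                common = set(s for s, _ in fams[taxa[i]]) & set(
                    s for s, _ in fams[taxa[j]]
                )
                total += len(common)
                correct += sum(
                    1 for a, b in zip(ids[taxa[i]], ids[taxa[j]])
                    if a is not None and a == b
                )
        assert correct / total >= 0.90

    def test_empty_sequence_excluded(self, caplog):
        rows = align_protein_family({"a": "MKV", "b": "", "c": "MKV"})
        assert set(rows) == {"a", "c"}


class TestConcatenate:
    def test_single_family_equals_itself(self):
        fam = {"g": {"a": "MK-", "b": "MKV"}}
        aln = concatenate(fam, ("a", "b"))
        assert aln.rows == fam["g"]
        assert aln.partitions == {"g": (0, 3)}

    def test_width_bookkeeping(self, four_records):
        ms = extract_markers(list(four_records.values()))
        fams = {g: align_protein_family(s) for g, s in ms.genes.items()}
        aln = concatenate(fams, ms.taxa, order=DEFAULT_MARKERS)
        widths = [len(next(iter(f.values()))) for f in fams.values()]
        assert aln.width == sum(widths)
        assert all(len(r) == aln.width for r in aln.rows.values())
        spans = sorted(aln.partitions.values())
        assert spans[0][0] == 0 and spans[-1][1] == aln.width
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))

    def test_missing_taxon_gets_gap_block(self):
        fam = {"g1": {"a": "MK", "b": "MK"}, "g2": {"a": "VW"}}
        aln = concatenate(fam, ("a", "b"))
        assert aln.rows["b"] == "MK--"


class TestDistanceMatrix:
    def test_identical_rows_have_zero_distance(self):
        aln = _aln_from_rows(a="MKVW" * 20, b="MKVW" * 20, c="MKVW" * 20)
        assert (distance_matrix(aln).to_numpy() == 0).all()

    def test_closed_form_poisson_correction(self):
        base = "A" * 1000
        changed = "C" * 100 + "A" * 900
        aln = _aln_from_rows(a=base, b=changed, c=base)
        d = distance_matrix(aln)
        assert d.loc["a", "b"] == pytest.approx(-np.log(0.9))

    def test_pairwise_deletion_recount_oracle(self):
        rng = np.random.default_rng(40)
        alphabet = list("MKVW-")
        rows = {
            t: "".join(rng.choice(alphabet, size=300, p=[0.3, 0.3, 0.2, 0.1, 0.1]))
            for t in "abcd"
        }
        aln = _aln_from_rows(**rows)
        d = distance_matrix(aln)
        for t1 in "abcd":
            for t2 in "abcd":
                if t1 >= t2:
                    continue
                shared = [
                    (x, y) for x, y in zip(rows[t1], rows[t2]) if x != "-" and y != "-"
                ]
                p = sum(x != y for x, y in shared) / len(shared)
                assert d.loc[t1, t2] == pytest.approx(-np.log(1 - p))

    def test_saturated_pair_is_an_error(self):
        aln = _aln_from_rows(a="MMMM", b="KKKK", c="MMMM")
        with pytest.raises(DistanceError):
            distance_matrix(aln)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        import pandas as pd

        d = pd.DataFrame(
            [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        tree = nj_tree(d)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_four_taxon_additive_matrix_recovers_topology(self):
        # ((a,b),(c,d)) with internal edge 0.2: check against the 3 topologies
        import pandas as pd

        names = list("abcd")
        d = pd.DataFrame(0.0, index=names, columns=names)
        leaf = {"a": 0.1, "b": 0.15, "c": 0.12, "d": 0.2}
        for x in names:
            for y in names:
                if x == y:
                    continue
                inner = 0.0 if {x, y} in ({"a", "b"}, {"c", "d"}) else 0.2
                d.loc[x, y] = leaf[x] + leaf[y] + inner
        tree = nj_tree(d)
        assert frozenset({"a", "b"}) in tree.bipartitions() or \
            frozenset({"c", "d"}) in tree.bipartitions()
        # additivity: path lengths reproduce the input exactly
        td = tree_distance_matrix(tree)
        assert np.allclose(td.loc[names, names].to_numpy(), d.to_numpy())

    def test_sister_pair_recovered_on_simulated_families(self):
        hits = 0
        for rep in range(100):
            fams = evolve_proteins(
                ((("A", "B"), "E"), ("C", "D")), n_sites=120,
                subst_prob=0.06, indel_prob=0.0, seed=1000 + rep,
            )
            aln = _aln_from_rows(**protein_strings(fams))
            tree = nj_tree(distance_matrix(aln))
            bps = tree.bipartitions()
            if frozenset({"A", "B"}) in bps or frozenset({"C", "D", "E"}) in bps:
                hits += 1
        assert hits >= 95

    def test_matches_scikit_bio_on_random_matrices(self):
        # independent implementation cross-check
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        import pandas as pd

        rng = np.random.default_rng(41)
        for trial in range(10):
            names = [f"t{i}" for i in range(6)]
            tree = random_tree(names, rng)
            d = tree_distance_matrix(tree)
            ours = nj_tree(d)
            theirs = skbio_nj(SkbioDM(d.loc[names, names].to_numpy(), ids=names))
            our_bps = ours.bipartitions()
            their_bps = set()
            for node in theirs.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= len(names) - 2:
                    anchor = sorted(names)[0]
                    side = side if anchor not in side else frozenset(names) - side
                    their_bps.add(side)
            anchor = sorted(names)[0]
            ours_canon = {
                bp if anchor not in bp else frozenset(names) - bp for bp in our_bps
            }
            assert ours_canon == their_bps, f"trial {trial}"


class TestBootstrapConsensus:
    def test_identical_sequences_give_star_tree(self):
        aln = _aln_from_rows(a="MKVW" * 30, b="MKVW" * 30, c="MKVW" * 30, d="MKVW" * 30)
        cons = bootstrap_consensus(aln, replicates=20, seed=1)
        assert cons.bipartitions() == set()

    def test_structured_alignment_recovers_bipartition(self):
        fams = evolve_proteins(
            (("A", "B"), ("C", "D"), "E"), n_sites=300, subst_prob=0.08, seed=7,
        )
        aln = _aln_from_rows(**protein_strings(fams))
        cons = bootstrap_consensus(aln, replicates=100, seed=7)
        supports = {}

        def walk(node):
            for ch in node.children:
                if ch.children:
                    supports[frozenset(ch.leaves())] = ch.support
                    walk(ch)

        walk(cons)
        taxa = frozenset("ABCDE")
        ab = frozenset({"A", "B"})  # equivalently the {C,D,E} side when rooted at A
        support = supports.get(ab, supports.get(taxa - ab))
        assert support is not None and support >= 0.95

    def test_support_sets_shrink_as_threshold_rises(self):
        fams = evolve_proteins(
            (("A", "B"), ("C", "D"), "E"), n_sites=120, subst_prob=0.15, seed=8,
        )
        aln = _aln_from_rows(**protein_strings(fams))
        n_bipartitions = []
        for thr in (0.5, 0.7, 0.9):
            cons = bootstrap_consensus(aln, replicates=50, threshold=thr, seed=8)
            n_bipartitions.append(len(cons.bipartitions()))
        assert n_bipartitions == sorted(n_bipartitions, reverse=True)

    def test_too_few_replicates_rejected(self):
        aln = _aln_from_rows(a="MKVW", b="MKVW", c="MKVW")
        with pytest.raises(Exception):
            bootstrap_consensus(aln, replicates=5)
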