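"""Palindromes, tandem repeats, and ortholog repeat polymorphisms."""

import numpy as np
import pytest

from plastokit.elements import (
    IncomparableOrthologsError,
    canonical_rotation,
    compare_ortholog_repeats,
    find_palindromes,
    find_tandem_repeats,
)
from plastokit.records import (
    CircularSequence,
    PlastomeRecord,
    extract_cds,
    reverse_complement,
)
from plastokit.simulate import mutate_ortholog

from .conftest import random_circle


def brute_force_palindromes(seq: str, min_span: int) -> set[tuple[int, int]]:
    """Independent oracle: test every even-length circular substring directly."""
    n = len(seq)
    doubled = seq + seq
    out = set()
    for start in range(n):
        for span in range(min_span, n + 1, 2):
            sub = doubled[start : start + span]
            if sub != reverse_complement(sub):
                continue
            before = doubled[(start - 1) % n]
            after = doubled[start + span]
            if span < n and before == reverse_complement(after):
                continue  # extendable, not maximal
            out.add((start % n, span))
    return out


def brute_force_tandems(seq: str, min_copies: int = 2) -> set[tuple[str, int, int]]:
    """Independent quadratic oracle for maximal tandem arrays of 1-6 nt units."""
    out = set()
    n = len(seq)
    for u in range(1, 7):
        for i in range(n - 2 * u + 1):
            unit = seq[i : i + u]
            if any(u % d == 0 and unit == unit[:d] * (u // d) for d in range(1, u)):
                continue  # non-primitive unit
            if i >= 1 and seq[i - 1] == seq[i - 1 + u]:
                continue  # not the leftmost phase of this run
            copies = 0
            while seq[i + copies * u : i + (copies + 1) * u] == unit:
                copies += 1
            if copies >= min_copies:
                out.add((canonical_rotation(unit), i, copies))
    return out


class TestFindPalindromes:
    def test_planted_hairpin_with_flanks(self, up_record):
        pals = find_palindromes(up_record, min_span=40, intergenic_only=True)
        assert len(pals) == 1
        assert pals[0].span == 84
        assert {pals[0].flank_upstream, pals[0].flank_downstream} == {"psaL", "rbcR"}

    def test_poly_a_has_no_palindromes(self):
        rec = PlastomeRecord(sequence=CircularSequence("A" * 200))
        assert find_palindromes(rec, min_span=10) == []

    def test_matches_enumeration_oracle_on_fuzzed_strings(self):
        rng = np.random.default_rng(30)
        lengths = [60, 80, 120, 200, 1000]
        for trial in range(12):
            n = lengths[trial % len(lengths)]
            seq = random_circle(rng, n)
            if trial % 2 == 0:  # plant one palindrome to exercise long spans
                half = "".join(rng.choice(list("ACGT"), size=9))
                planted = "A" + half + reverse_complement(half) + "A"
                residues = seq.residues[: n - len(planted)] + planted
                seq = CircularSequence(residues, is_circular=True)
            rec = PlastomeRecord(sequence=seq)
            got = {(p.interval[0], p.span) for p in find_palindromes(rec, min_span=10)}
            assert got == brute_force_palindromes(seq.residues, 10), f"trial {trial}"

    def test_intergenic_filter(self, up_record):
        everywhere = find_palindromes(up_record, min_span=40, intergenic_only=False)
        intergenic = find_palindromes(up_record, min_span=40, intergenic_only=True)
        assert {p.interval for p in intergenic} <= {p.interval for p in everywhere}


class TestFindTandemRepeats:
    def test_gaa_example_canonicalized(self):
        hits = find_tandem_repeats("GAAGAAGAA")
        assert any(t.unit == "AAG" and t.copies == 3 and t.start == 0 for t in hits)

    def test_no_array_below_min_copies(self):
        assert find_tandem_repeats("ACGT") == []

    def test_matches_quadratic_oracle_on_fuzzed_strings(self):
        rng = np.random.default_rng(31)
        for trial in range(30):
            n = 1000 if trial < 3 else int(rng.integers(30, 200))
            # low-entropy alphabet makes arrays common
            seq = "".join(rng.choice(list("ACG"), size=n))
            got = {(t.unit, t.start, t.copies) for t in find_tandem_repeats(seq)}
            assert got == brute_force_tandems(seq), f"trial {trial}"


class TestCompareOrthologRepeats:
    def test_identical_sequences_give_empty_list(self):
        cds = "ATGGCA" + "ATT" * 3 + "TAA"
        assert compare_ortholog_repeats(cds, cds) == []

    def test_planted_ycf35_style_pair(self, four_records):
        up, sj = four_records["U_pinnatifida"], four_records["S_japonica"]
        fa = next(f for f in up.features if f.name == "ycf35")
        fb = next(f for f in sj.features if f.name == "ycf35")
        polys = compare_ortholog_repeats(
            extract_cds(up, fa), extract_cds(sj, fb), gene="ycf35"
        )
        assert len(polys) == 1
        poly = polys[0]
        assert poly.unit == "ATT" and poly.delta_nt == -3 and poly.frame_preserved
        assert (poly.copies_a, poly.copies_b) == (3, 4)
        assert any(canonical_rotation(u) == "AAT" for u, _ in poly.context)

    def test_mirror_symmetry_negates_delta(self, four_records):
        up, sj = four_records["U_pinnatifida"], four_records["S_japonica"]
        for gene in ("ycf35", "ilvB"):
            a = extract_cds(up, next(f for f in up.features if f.name == gene))
            b = extract_cds(sj, next(f for f in sj.features if f.name == gene))
            fwd = compare_ortholog_repeats(a, b, gene=gene)
            rev = compare_ortholog_repeats(b, a, gene=gene)
            assert [(p.unit, p.delta_nt) for p in fwd] == [
                (p.unit, -p.delta_nt) for p in rev
            ]

    def test_frame_flag_consistent_with_delta(self, four_records):
        up, sj = four_records["U_pinnatifida"], four_records["S_japonica"]
        for gene in ("ycf35", "ilvB"):
            a = extract_cds(up, next(f for f in up.features if f.name == gene))
            b = extract_cds(sj, next(f for f in sj.features if f.name == gene))
            for p in compare_ortholog_repeats(a, b, gene=gene):
                assert p.frame_preserved == (p.delta_nt % 3 == 0)

    def test_recovers_simulated_mutations(self):
        rng = np.random.default_rng(32)
        units = ["ATT", "AAG", "TGC", "GA"]
        recovered = 0
        for trial in range(100):
            unit = units[trial % len(units)]
            copies = int(rng.integers(2, 5))
            body = "".join(rng.choice(["GGC", "CAG", "TCC", "GAC", "TAC"], size=40))
            cds = "ATG" + body[:60] + unit * copies + body[60:] + "TAA"
            k = int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
            if k < 0 and -k >= copies:
                k = -1
            mutated = mutate_ortholog(cds, unit, k)
            polys = compare_ortholog_repeats(cds, mutated, gene="sim")
            assert len(polys) == 1, f"trial {trial}"
            p = polys[0]
            assert p.delta_nt == -k * len(unit), f"trial {trial}"
            assert canonical_rotation(p.unit) == canonical_rotation(unit)
            assert p.copies_a - p.copies_b == -k
            recovered += 1
        assert recovered == 100

    def test_diverged_sequences_rejected(self):
        rng = np.random.default_rng(33)
        a = "".join(rng.choice(list("ACGT"), size=120))
        b = "".join(rng.choice(list("ACGT"), size=120))
        with pytest.raises(IncomparableOrthologsError):
            compare_ortholog_repeats(a, b)
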