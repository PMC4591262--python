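"""Inverted-repeat detection, quadripartite partition, base composition."""

import numpy as np
import pytest

from plastokit.architecture import (
    CompositionError,
    base_composition,
    detect_quadripartite,
    find_inverted_repeats,
)
from plastokit.records import CircularSequence, ParameterError, reverse_complement
from plastokit.simulate import SimConfig, simulate_plastome

from .conftest import plant_inverted_repeat, random_circle

_COMP = str.maketrans("ACGTN", "TGCA?")


def brute_force_ir_pairs(seq: str, min_len: int) -> set[tuple[int, int, int]]:
    """Independent O(n^2) enumeration of maximal inverted-repeat pairs.

    For every anti-diagonal s of the complementarity relation
    ``seq[x] == complement(seq[(s - x) % n])`` the maximal circular runs of
    matching x are found by direct scanning; a run either mirrors a second
    run (two-copy repeat) or itself (palindrome -> its two disjoint halves).
    """
    n = len(seq)
    seq_arr = np.frombuffer(seq.encode(), dtype="S1")
    comp_arr = np.frombuffer(seq.translate(_COMP).encode(), dtype="S1")
    idx = np.arange(n)
    pairs: set[tuple[int, int, int]] = set()
    for s in range(n):
        match = seq_arr == comp_arr[(s - idx) % n]
        if match.all():
            runs = [(0, n)]
        else:
            # circular runs: rotate so position 0 is a mismatch, then diff
            start = int(np.flatnonzero(~match)[0])
            rolled = np.roll(match, -start)
            edges = np.flatnonzero(np.diff(np.concatenate(([0], rolled.view(np.int8), [0]))))
            runs = [
                ((start + int(lo)) % n, int(hi - lo))
                for lo, hi in zip(edges[::2], edges[1::2])
            ]
        for a, run_len in runs:
            b = (a + run_len - 1) % n
            mirror_start = (s - b) % n
            if mirror_start == a and (s - a) % n == b:  # palindromic run
                half = run_len // 2
                if half >= min_len:
                    i, j = a, (a + run_len - half) % n
                    pairs.add((min(i, j), max(i, j), half))
            elif run_len >= min_len:
                i, j = a, mirror_start
                pairs.add((min(i, j), max(i, j), run_len))
    return pairs


class TestFindInvertedRepeats:
    def test_matches_brute_force_on_fuzzed_circles(self):
        rng = np.random.default_rng(10)
        for trial in range(60):
            length = int(rng.integers(60, 320))
            if trial % 3 == 0:
                seq = plant_inverted_repeat(rng, length, ir_len=int(rng.integers(12, 25)),
                                            gap=int(rng.integers(5, 20)))
            else:
                seq = random_circle(rng, length)
            got = {
                (min(p.interval_a[0], p.interval_b[0]),
                 max(p.interval_a[0], p.interval_b[0]), p.length)
                for p in find_inverted_repeats(seq, min_len=10)
            }
            expected = brute_force_ir_pairs(seq.residues, 10)
            assert got == expected, f"trial {trial}, n={length}"

    def test_matches_brute_force_on_kilobase_circles(self):
        rng = np.random.default_rng(11)
        for length in (1500, 3000):
            seq = plant_inverted_repeat(rng, length, ir_len=40, gap=300)
            got = {
                (min(p.interval_a[0], p.interval_b[0]),
                 max(p.interval_a[0], p.interval_b[0]), p.length)
                for p in find_inverted_repeats(seq, min_len=12)
            }
            assert got == brute_force_ir_pairs(seq.residues, 12)

    def test_no_repeat_gives_empty_list(self):
        seq = CircularSequence("ACG" * 20)
        assert find_inverted_repeats(seq, min_len=15) == []

    def test_reported_pairs_are_reverse_complements(self):
        rng = np.random.default_rng(12)
        seq = plant_inverted_repeat(rng, 400, ir_len=30, gap=100)
        for p in find_inverted_repeats(seq, min_len=10):
            assert seq.fetch(*p.interval_a) == reverse_complement(seq.fetch(*p.interval_b))

    def test_min_len_floor_enforced(self):
        with pytest.raises(ParameterError):
            find_inverted_repeats(CircularSequence("ACGT" * 10), min_len=5)

    def test_planted_paper_ir_is_top_pair(self, up_record):
        pairs = find_inverted_repeats(up_record.sequence, min_len=1000, k=21)
        assert pairs[0].length == 5404


class TestDetectQuadripartite:
    def test_paper_region_lengths_exact(self, up_quadripartite):
        quad = up_quadripartite
        assert quad.lengths == {"lsc": 76598, "ssc": 42977, "ir": 5404}
        assert quad.total == 130383

    def test_partition_covers_circle(self, up_quadripartite):
        ln = up_quadripartite.lengths
        assert ln["lsc"] + ln["ssc"] + 2 * ln["ir"] == up_quadripartite.total

    def test_ira_is_upstream_of_ssc(self, up_quadripartite):
        quad = up_quadripartite
        # clockwise neighbour of IRa must be the SSC start
        assert quad.ira[1] == quad.ssc[0]

    def test_rotation_invariance(self, up_record):
        for offset in (1, 999, 76598, 100000):
            rotated = up_record.sequence.rotate(offset)
            quad = detect_quadripartite(rotated, min_ir=1000)
            assert quad.lengths == {"lsc": 76598, "ssc": 42977, "ir": 5404}

    def test_strand_symmetry(self, up_record, up_quadripartite):
        quad_rc = detect_quadripartite(up_record.sequence.reverse_complement(), min_ir=1000)
        assert quad_rc.lengths == up_quadripartite.lengths

    def test_no_ir_genome_returns_none(self):
        cfg = SimConfig(seed=2, lsc_len=22000, ssc_len=15000, ir_len=0, n_rrna=3,
                        cds_names=tuple(f"g{i}" for i in range(30)), n_trna=4,
                        overlap_spec=(), hairpin_spec=None, repeat_spec=(),
                        start_codon_spec={}, stop_codon_spec={}, stop_counts={},
                        length_deltas={})
        rec = simulate_plastome(cfg)
        assert detect_quadripartite(rec.sequence, min_ir=1000) is None


class TestBaseComposition:
    def test_pure_at(self):
        assert base_composition(CircularSequence("ATAT"))["AT"] == 1.0

    def test_matches_tally_oracle(self):
        rng = np.random.default_rng(13)
        seq = random_circle(rng, 500, at=0.7)
        props = base_composition(seq)
        for b in "ACGT":
            assert props[b] == seq.residues.count(b) / 500
        assert abs(sum(props[b] for b in "ACGT") - 1.0) < 1e-12

    def test_n_excluded_from_denominator(self):
        props = base_composition(CircularSequence("ATNN"))
        assert props["AT"] == 1.0

    def test_all_n_is_an_error(self):
        with pytest.raises(CompositionError):
            base_composition(CircularSequence("NNNN"))

    def test_paper_at_content_on_synthetic_genome(self, up_record):
        at = base_composition(up_record.sequence)["AT"]
        assert abs(100 * at - 69.38) < 0.5
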