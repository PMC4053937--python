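from functools import lru_cache

import numpy as np
import pytest

from paremir import hairpin as hp
from paremir.synthetic_data import Defect, build_precursor

PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def oracle_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Independent max-base-pair recurrence anchored on the right end."""

    @lru_cache(maxsize=None)
    def n(i, j):
        if j - i <= min_loop:
            return 0
        best = n(i, j - 1)
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in PAIRS:
                best = max(best, n(i, k - 1) if k > i else 0, )
                cand = (n(i, k - 1) if k > i else 0) + 1 + n(k + 1, j - 1)
                best = max(best, cand)
        return best

    return n(0, len(seq) - 1)


class TestFoldHairpin:
    def test_inverted_repeat_forms_full_stem(self):
        s = hp.fold_hairpin("GGGGAAAACCCC")
        assert s.dotbracket == "((((....))))" and s.n_pairs == 4

    def test_homopolymer_has_no_pairs(self):
        assert hp.fold_hairpin("A" * 20).n_pairs == 0

    def test_n_positions_forced_unpaired(self):
        s = hp.fold_hairpin("GGNGAAAACNCC")
        for i, c in enumerate(s.sequence):
            if c == "N":
                assert s.pair_map[i] == -1

    def test_pair_count_matches_independent_recurrence(self, rng):
        for _ in range(15):
            seq = "".join(rng.choice(list("ACGT"), 60))
            assert hp.fold_hairpin(seq).n_pairs == oracle_max_pairs(seq)

    def test_structure_is_maximal_no_pair_addable(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 30))
            s = hp.fold_hairpin(seq)
            unpaired = [i for i in range(30) if s.pair_map[i] < 0]
            existing = [(i, j) for i, j in enumerate(s.pair_map) if 0 <= i < j]
            for a in unpaired:
                for b in unpaired:
                    if b - a <= 3 or (seq[a], seq[b]) not in PAIRS:
                        continue
                    crossing = any(
                        (i < a < j < b) or (a < i < b < j) for i, j in existing
                    )
                    assert crossing, f"pair ({a},{b}) could be added"

    def test_deterministic(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 80))
        assert hp.fold_hairpin(seq).dotbracket == hp.fold_hairpin(seq).dotbracket

    def test_dotbracket_round_trip(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 50))
        s = hp.fold_hairpin(seq)
        assert hp.pairmap_from_dotbracket(s.dotbracket) == s.pair_map


class TestLocateStar:
    def test_canonical_two_nt_overhang_geometry(self, rng):
        p = build_precursor("".join(rng.choice(list("ACGT"), 21)),
                            defects=[Defect("mismatch", 12)], rng=rng)
        st = hp.fold_hairpin(p.sequence)
        star_start, star_len = hp.locate_star(st, p.mir_start, p.mir_len)
        assert (star_start, star_len) == (p.star_start, p.star_len)
        assert star_len == p.mir_len
        # the star's 3' end extends 2 nt past the partner of the miRNA 5' base
        assert star_start + star_len - 3 == st.pair_map[p.mir_start]

    def test_star_length_changes_with_bulged_arm(self, rng):
        bulged_star = build_precursor(
            "".join(rng.choice(list("ACGT"), 21)),
            defects=[Defect("bulge", 9, 1, "star")], rng=rng)
        assert bulged_star.star_len == 22
        bulged_mir = build_precursor(
            "".join(rng.choice(list("ACGT"), 21)),
            defects=[Defect("bulge", 9, 1, "mir")], rng=rng)
        assert bulged_mir.star_len == 20

    def test_mir_spanning_loop_is_an_error(self):
        st = hp.fold_hairpin("GGGGGGGGGGGAAAACCCCCCCCCCC")
        with pytest.raises(hp.NoStarError):
            hp.locate_star(st, 5, 16, min_paired=5)

    def test_unpaired_mir_is_an_error(self):
        st = hp.fold_hairpin("A" * 60)
        with pytest.raises(hp.NoStarError):
            hp.locate_star(st, 10, 21)


def _duplex_case(top_db: str, bottom_db: str):
    """Build a hairpin from explicit pairing masks for the two arms.

    The k-th '(' on the top arm pairs the k-th-from-last ')' on the bottom
    arm (antiparallel).  2-nt unpaired 3' tails are appended to both arms so
    the intervals follow the overhang convention; arm sequences are dummies
    (G against C) since the pairing is set explicitly.
    """
    loop = "AAAA"
    top_full = "G" * len(top_db) + "AA"
    bottom_full = "C" * len(bottom_db) + "AA"
    seq = top_full + loop + bottom_full
    pair_map = [-1] * len(seq)
    top_idx = [i for i, c in enumerate(top_db) if c == "("]
    bot_idx = [i for i, c in enumerate(bottom_db) if c == ")"]
    assert len(top_idx) == len(bot_idx)
    off = len(top_full) + len(loop)
    for a, b in zip(top_idx, reversed(bot_idx)):
        pair_map[a], pair_map[off + b] = off + b, a
    db = hp.dotbracket_from_pairmap(pair_map)
    structure = hp.HairpinStructure(seq, db, pair_map)
    return structure, (0, len(top_full)), (off, off + len(bottom_full))


# hand-enumerated defect cases: (top mask, bottom mask, (mm, bulges, max_len))
DUPLEX_CASES = [
    ("((((((((((", "))))))))))", (0, 0, 0)),   # perfect 10-bp duplex
    ("(((((.((((", ")))).)))))", (1, 0, 0)),   # symmetric 1-nt internal loop
    ("((((..((((", "))))..))))", (2, 0, 0)),   # symmetric 2-nt loop = 2 mm
    ("(((.((.(((", "))).)).)))", (2, 0, 0)),   # two symmetric 1-nt loops
    ("(((((.((((", ")))))))))", (0, 1, 1)),    # 1-nt bulge on the top arm
    ("(((((((((", ")))).)))))", (0, 1, 1)),    # 1-nt bulge on the bottom arm
    ("((((..((((", ")))).))))", (1, 1, 1)),    # asymmetric 2 vs 1 loop
    ("(((.((((.(((", "))))))))))", (0, 2, 1)), # two 1-nt bulges, top arm
    ("(((((((((", ")))...))))))", (0, 1, 3)),  # 3-nt bulge on the bottom arm
    ("((((.(((((", ")))))...))))", (1, 1, 2)), # 1-nt loop opposed by 3-nt run
]


class TestDuplexStats:
    @pytest.mark.parametrize("top,bottom,expect", DUPLEX_CASES)
    def test_enumerated_defect_table(self, top, bottom, expect):
        structure, mir, star = _duplex_case(top, bottom)
        stats = hp.duplex_stats(structure, mir, star)
        assert (stats.mismatches, stats.bulges, stats.max_bulge_len) == expect
        assert stats.total_defects == expect[0] + expect[1]

    @pytest.mark.parametrize("top,bottom,expect", DUPLEX_CASES)
    def test_symmetric_in_arguments(self, top, bottom, expect):
        structure, mir, star = _duplex_case(top, bottom)
        assert hp.duplex_stats(structure, mir, star) == hp.duplex_stats(
            structure, star, mir
        )

    def test_restoring_a_planted_bulge_removes_it(self, rng):
        """A 1-nt bulge near the miRNA 3' end disappears when the inserted
        base is removed (the miR162-vs-miR162-20A comparison geometry)."""
        mature = "".join(rng.choice(list("ACGT"), 21))
        bulged = build_precursor(mature, defects=[Defect("bulge", 18, 1, "star")],
                                 rng=np.random.default_rng(5))
        clean = build_precursor(mature, rng=np.random.default_rng(5))
        stats_b = hp.duplex_stats(
            hp.fold_hairpin(bulged.sequence),
            (bulged.mir_start, bulged.mir_start + bulged.mir_len),
            (bulged.star_start, bulged.star_start + bulged.star_len),
        )
        stats_c = hp.duplex_stats(
            hp.fold_hairpin(clean.sequence),
            (clean.mir_start, clean.mir_start + clean.mir_len),
            (clean.star_start, clean.star_start + clean.star_len),
        )
        assert stats_b.bulges == 1 and stats_b.max_bulge_len == 1
        assert stats_c.bulges == 0 and stats_c.total_defects == 0


class TestBias:
    def tags(self, spec):
        return [hp.LocusTag(f"T{i}", i, s, a) for i, (s, a) in enumerate(spec)]

    def test_all_sense_is_one(self):
        assert hp.strand_bias(self.tags([("+", 10), ("+", 5)])) == 1.0

    def test_ninety_ten_split(self):
        assert hp.strand_bias(self.tags([("+", 90), ("-", 10)])) == pytest.approx(0.9)

    def test_scaling_invariance(self, rng):
        spec = [("+" if rng.random() < 0.7 else "-", float(a))
                for a in rng.uniform(1, 100, 20)]
        base = hp.strand_bias(self.tags(spec))
        scaled = hp.strand_bias(self.tags([(s, a * 13.7) for s, a in spec]))
        assert base == pytest.approx(scaled)
        ab = hp.abundance_bias(self.tags(spec))
        ab_scaled = hp.abundance_bias(self.tags([(s, a * 13.7) for s, a in spec]))
        assert ab == pytest.approx(ab_scaled)

    def test_zero_total_undefined(self):
        with pytest.raises(ValueError):
            hp.strand_bias(self.tags([("+", 0)]))

    def test_abundance_bias_top_two_share(self):
        assert hp.abundance_bias(
            self.tags([("+", 50), ("+", 20), ("+", 10), ("+", 10), ("+", 10)])
        ) == pytest.approx(0.7)

    def test_single_tag_bias_is_one(self):
        assert hp.abundance_bias(self.tags([("+", 42)])) == 1.0

    def test_matches_sort_oracle(self, rng):
        for _ in range(10):
            ab = rng.uniform(0.1, 50, size=12)
            tags = self.tags([("+", float(a)) for a in ab])
            expect = sum(sorted(ab, reverse=True)[:2]) / ab.sum()
            assert hp.abundance_bias(tags) == pytest.approx(expect)
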