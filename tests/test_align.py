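import itertools

import numpy as np
import pytest

from prodomainkit.align import (
    ALPHABET,
    AlignParams,
    count_informative,
    pairwise_global_align,
    progressive_align,
)
from prodomainkit.seqio import Alignment, ProteinRecord

BLOSUM = AlignParams().score_matrix
IDX = {ch: i for i, ch in enumerate(ALPHABET)}


def oracle_best_score(a: str, b: str, go: float = -10.0, ge: float = -1.0) -> float:
    """Exhaustive affine-gap global alignment score by enumerating every
    alignment (all interleavings of match/insert/delete moves)."""

    best = [-np.inf]

    def rec(i, j, last, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + BLOSUM[IDX[a[i]], IDX[b[j]]])
        if j < len(b):  # gap in a
            rec(i, j + 1, "X", score + (ge if last == "X" else go))
        if i < len(a):  # gap in b
            rec(i + 1, j, "Y", score + (ge if last == "Y" else go))

    rec(0, 0, None, 0.0)
    return best[0]


class TestPairwiseAligner:
    def test_identical_sequences_align_without_gaps(self):
        ra, rb, score = pairwise_global_align("ACD", "ACD")
        assert (ra, rb) == ("ACD", "ACD")
        assert score == sum(BLOSUM[IDX[c], IDX[c]] for c in "ACD")

    def test_single_gap_placed_opposite_missing_residue(self):
        ra, rb, _ = pairwise_global_align("ACD", "AD")
        assert ra == "ACD"
        assert rb in ("A-D",)

    def test_score_symmetry(self):
        _, _, s1 = pairwise_global_align("ACDW", "AW")
        _, _, s2 = pairwise_global_align("AW", "ACDW")
        assert s1 == s2

    def test_matches_exhaustive_oracle_all_short_pairs(self):
        """DP score equals brute-force enumeration for every pair of sequences
        of length <= 4 over a 4-letter alphabet."""
        letters = "ACDW"
        seqs = [
            "".join(t)
            for n in (1, 2, 3, 4)
            for t in itertools.product(letters, repeat=n)
        ]
        rng = np.random.default_rng(0)
        pairs = [(seqs[i], seqs[j]) for i, j in
                 rng.integers(0, len(seqs), size=(300, 2))]
        # ensure systematic coverage of the shortest cases too
        pairs += list(itertools.product(
            ["".join(t) for n in (1, 2) for t in itertools.product(letters, repeat=n)],
            repeat=2,
        ))
        for a, b in pairs:
            _, _, got = pairwise_global_align(a, b)
            assert got == oracle_best_score(a, b), (a, b)

    def test_alignment_rows_ungap_to_inputs(self):
        ra, rb, _ = pairwise_global_align("MKWVLAA", "MKVL")
        assert ra.replace("-", "") == "MKWVLAA"
        assert rb.replace("-", "") == "MKVL"


class TestProgressiveAlign:
    def test_identical_sequences_give_gapfree_alignment(self):
        recs = [ProteinRecord(f"r{i}", "MKWVLA") for i in range(5)]
        aln = progressive_align(recs)
        assert aln.n_cols == 6
        assert all(row == "MKWVLA" for row in aln.matrix)

    def test_two_records_reduce_to_pairwise(self):
        recs = [ProteinRecord("a", "MKWVLAA"), ProteinRecord("b", "MKVL")]
        aln = progressive_align(recs)
        ra, rb, _ = pairwise_global_align("MKWVLAA", "MKVL")
        assert aln.matrix == [ra, rb]

    def test_single_record_is_error(self):
        with pytest.raises(ValueError):
            progressive_align([ProteinRecord("a", "MK")])

    def test_rows_ungap_to_inputs_and_order_preserved(self, small_family):
        reg, _ = small_family
        aln = progressive_align(reg.records)
        assert aln.row_ids == reg.ids()
        for rec in reg:
            assert aln.ungapped(rec.id) == rec.sequence

    def test_invariant_motif_occupies_shared_column_block(self, small_family):
        """The planted cleavage tetrapeptide ends in one shared column for
        every member of a subfamily."""
        reg, truth = small_family
        members = [r for r in reg if r.subfamily_label == "Activin"]
        aln = progressive_align(members)
        end_cols = set()
        for rec in members:
            row = aln.row(rec.id)
            res = 0
            for col, ch in enumerate(row, start=1):
                if ch != "-":
                    res += 1
                    if res == truth.cleavage_end[rec.id]:
                        end_cols.add(col)
                        break
        assert len(end_cols) == 1


def _aln(rows):
    return Alignment([f"r{i}" for i in range(len(rows))], rows)


class TestCountInformative:
    def test_constant_alignment_has_zero(self):
        rep = count_informative(_aln(["AC", "AC", "AC", "AC"]))
        assert rep.n_informative == 0
        assert rep.n_cols_with_gaps == 2

    @pytest.mark.parametrize(
        "column,expected",
        [
            ("AABBC", True),   # two residues twice each
            ("AAAAB", False),  # one singleton
            ("AABBB", True),
            ("ABCDE", False),
        ],
    )
    def test_two_by_two_rule(self, column, expected):
        rep = count_informative(_aln(list(column)))
        assert (rep.n_informative == 1) is expected

    def test_gap_or_x_column_excluded(self):
        # col 2 (gap / X) is excluded even though its residues would qualify;
        # col 3 stays informative
        rep = count_informative(_aln(["A-A", "AAA", "ABB", "AAB", "ABA"]))
        assert rep.informative_column_indices == [3]
        rep = count_informative(_aln(["AXA", "AAA", "ABB", "AAB", "ABA"]))
        assert rep.informative_column_indices == [3]

    def test_fewer_than_four_rows_is_error(self):
        with pytest.raises(ValueError):
            count_informative(_aln(["A", "A", "A"]))

    def test_invariant_under_row_and_column_permutation(self):
        rows = ["ACDW", "ACDA", "WCDA", "WCAA", "ACAW"]
        base = count_informative(_aln(rows)).n_informative
        assert count_informative(_aln(rows[::-1])).n_informative == base
        flipped = ["".join(r[c] for c in (3, 1, 0, 2)) for r in rows]
        assert count_informative(_aln(flipped)).n_informative == base

    def test_duplicate_row_never_decreases_count(self):
        rows = ["ACDW", "ACDA", "WCDA", "WCAA"]
        base = count_informative(_aln(rows)).n_informative
        assert count_informative(_aln(rows + [rows[0]])).n_informative >= base
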