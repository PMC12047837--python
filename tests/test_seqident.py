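"""Global alignment, identity matrices and consensus profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calproscreen.fasta import SequenceRecord
from calproscreen.seqident import (
    AlignmentError,
    consensus_profile,
    global_align,
    identity_matrix,
    load_substitution_matrix,
)
from calproscreen.simulate import FamilySimParams, simulate_sequence_family

# toy matrix over a 4-letter alphabet; chosen so that a mismatch always beats
# an adjacent pair of opposite gaps (s_min = -4 > -2*gap_open = -6)
TOY_ALPHABET = "ACGT"
TOY_MATRIX = {
    (a, b): (5.0 if a == b else -4.0) for a in TOY_ALPHABET for b in TOY_ALPHABET
}
TOY_OPEN, TOY_EXT = 3.0, 1.0


def brute_force_best_score(a: str, b: str) -> float:
    """Exhaustive maximum over all global alignments with affine gap costs.

    A gap run of length k costs TOY_OPEN + (k-1)*TOY_EXT; recursion carries
    the previous column type so extensions are priced correctly.
    """

    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, TOY_MATRIX[a[i], b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = TOY_EXT if last == "X" else TOY_OPEN
            best = max(best, -cost + rec(i + 1, j, "X"))
        if j < len(b):
            cost = TOY_EXT if last == "Y" else TOY_OPEN
            best = max(best, -cost + rec(i, j + 1, "Y"))
        return best

    return rec(0, 0, "")


def rec_(s: str) -> SequenceRecord:
    return SequenceRecord(id=f"s{abs(hash(s)) % 10**6}_{len(s)}", residues=s)


class TestGlobalAlign:
    def test_identical_sequences(self):
        m = load_substitution_matrix()
        res = global_align(rec_("ACDE"), rec_("ACDE"))
        assert res.percent_identity == 100.0
        assert res.n_differences == 0
        assert res.score == sum(float(m[c, c]) for c in "ACDE")

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list(TOY_ALPHABET), size=rng.integers(3, 8)))
        b = "".join(rng.choice(list(TOY_ALPHABET), size=rng.integers(3, 8)))
        res = global_align(
            SequenceRecord(id="a", residues=a),
            SequenceRecord(id="b", residues=b),
            matrix=TOY_MATRIX, gap_open=TOY_OPEN, gap_extend=TOY_EXT,
        )
        assert res.score == pytest.approx(brute_force_best_score(a, b), abs=1e-9)

    def test_score_matches_biopython_aligner(self):
        # independent implementation cross-check on protein sequences
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = load_substitution_matrix()
        # Biopython prices a length-k gap as open + (k-1)*extend via
        # open_gap_score/extend_gap_score
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(5):
            a = "".join(rng.choice(aas, size=30))
            b = "".join(rng.choice(aas, size=25))
            ours = global_align(
                SequenceRecord(id="a", residues=a),
                SequenceRecord(id="b", residues=b),
            )
            assert ours.score == pytest.approx(
                aligner.score(a, b), abs=1e-6
            )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
    )
    def test_swap_invariance(self, a, b):
        ra = SequenceRecord(id="a", residues=a)
        rb = SequenceRecord(id="b", residues=b)
        fwd = global_align(ra, rb)
        rev = global_align(rb, ra)
        assert fwd.score == pytest.approx(rev.score)
        assert fwd.percent_identity == pytest.approx(rev.percent_identity)

    def test_ungapping_recovers_inputs(self):
        a, b = "MKVLAW", "MKAW"
        res = global_align(
            SequenceRecord(id="a", residues=a), SequenceRecord(id="b", residues=b)
        )
        assert res.aligned_a.replace("-", "") == a
        assert res.aligned_b.replace("-", "") == b
        assert len(res.aligned_a) == len(res.aligned_b)
        assert res.n_identical <= res.n_both_aligned

    def test_pure_substitutions_counted_exactly(self):
        # sequences differing by k substitutions, no indels
        a = "ACDEFGHIKLMNPQRSTVWY" * 3
        b = list(a)
        for pos in (3, 17, 41):
            b[pos] = "W" if b[pos] != "W" else "Y"
        res = global_align(
            SequenceRecord(id="a", residues=a),
            SequenceRecord(id="b", residues="".join(b)),
        )
        assert "-" not in res.aligned_a + res.aligned_b
        assert res.n_differences == 3
        assert res.percent_identity == pytest.approx(100 * (60 - 3) / 60)

    def test_residue_missing_from_matrix_is_named(self):
        with pytest.raises(AlignmentError, match="'X'.*position 2"):
            global_align(
                SequenceRecord(id="a", residues="AXC"),
                SequenceRecord(id="b", residues="AAC"),
                matrix=TOY_MATRIX.copy(),
            )


class TestIdentityMatrix:
    def test_copies_are_all_100(self):
        seqs = [
            SequenceRecord(id=f"s{i}", residues="MKVLAWGRE") for i in range(3)
        ]
        mat = identity_matrix(seqs)
        assert np.allclose(mat.values, 100.0)

    def test_symmetric_with_exact_diagonal(self):
        seqs, _ = simulate_sequence_family(FamilySimParams(seed=5))
        mat = identity_matrix(seqs)
        assert np.array_equal(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 100.0)

    def test_planted_substitution_counts_recovered(self):
        params = FamilySimParams(length=120, substitutions=(4, 9, 15), seed=11)
        seqs, truth = simulate_sequence_family(params)
        mat = identity_matrix(seqs)
        for pair, k in truth["pairwise_differences"].items():
            i, j = pair.split("|")
            expected = 100.0 * (params.length - k) / params.length
            assert mat[i, j] == pytest.approx(expected, abs=1e-9)

    def test_duplicate_ids_rejected(self):
        s = SequenceRecord(id="dup", residues="MKVLAW")
        with pytest.raises(AlignmentError, match="duplicate"):
            identity_matrix([s, s])


class TestConsensusProfile:
    def test_identical_rows(self):
        prof = consensus_profile(["MKVLA"] * 5)
        assert prof.consensus == "MKVLA"
        assert np.allclose(
            prof.frequencies.max(axis=1).to_numpy(), 1.0
        )

    def test_majority_rule_at_threshold(self):
        prof = consensus_profile(["A", "A", "A", "G", "G"])
        assert prof.consensus == "A"  # 0.6 >= 0.5
        below = consensus_profile(["A", "A", "G", "G", "C"])
        assert below.consensus == "."  # 0.4 < 0.5

    def test_gaps_count_in_denominator(self):
        # residue must reach the threshold over all rows, gaps included
        prof = consensus_profile(["A", "A", "-", "-", "-"])
        assert prof.consensus == "."

    def test_random_msa_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        letters = list("ACDEFG-")
        msa = [
            "".join(rng.choice(letters, size=30)) for _ in range(10)
        ]
        prof = consensus_profile(msa)
        for col in range(30):
            column = [row[col] for row in msa]
            counts = {}
            for ch in column:
                counts[ch] = counts.get(ch, 0) + 1
            residue_counts = {c: n for c, n in counts.items() if c != "-"}
            if residue_counts:
                top = max(residue_counts.values())
                best = sorted(
                    c for c, n in residue_counts.items() if n == top
                )[0]
                expect = best if top / 10 >= 0.5 else "."
            else:
                expect = "."
            assert prof.consensus[col] == expect
            for ch, n in counts.items():
                assert prof.frequencies.iloc[col][ch] == pytest.approx(n / 10)

    def test_ragged_rows_rejected(self):
        with pytest.raises(AlignmentError, match="ragged"):
            consensus_profile(["AC", "A"])
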