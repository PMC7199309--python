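"""Similarity-matrix construction: alignment scores, |PCC|, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsimbench import (
    AlignmentParams,
    ComputationError,
    ExpressionMatrix,
    InputError,
    SequenceSet,
    SimilarityMatrix,
    align_matrices,
    align_score,
    diagonal_normalize,
    expression_similarity,
    preprocess_expression,
    sequence_similarity,
)
from conftest import make_similarity, make_associations
from oracles import brute_force_align


def check_similarity_contract(sim: SimilarityMatrix) -> None:
    v = sim.values
    assert np.allclose(v, v.T, atol=1e-12)
    assert np.allclose(np.diag(v), 1.0)
    assert v.min() >= 0 and v.max() <= 1


class TestAlignScore:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 20.0),  # 4 matches
            ("ACGT", "ACGA", 11.0),  # 3 matches, 1 mismatch beats gapping
            ("ACGU", "ACGT", 20.0),  # U/T interchangeable
            ("ACGT", "ACG", 5.0),    # terminal gap costs the open penalty
            ("A", "T", -4.0),
            ("AAAA", "A", -6.0),     # 5 - (10 + 2*0.5)
        ],
    )
    def test_worked_scores(self, a, b, expected):
        assert align_score(a, b) == pytest.approx(expected)

    def test_symmetric_in_arguments(self):
        assert align_score("ACGGU", "AGU") == align_score("AGU", "ACGGU")

    def test_rejects_non_nucleotide_characters(self):
        with pytest.raises(InputError, match="X"):
            align_score("ACXG", "ACGG")

    def test_matches_exhaustive_enumeration_on_random_short_pairs(self):
        """Affine-gap optimum equals brute-force enumeration, 100+ pairs."""
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(110):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(bases, la))
            b = "".join(rng.choice(bases, lb))
            assert align_score(a, b) == pytest.approx(
                brute_force_align(a, b)
            ), (a, b)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_property_oracle_equivalence(self, data):
        seq = st.text(alphabet="ACGU", min_size=1, max_size=6)
        a, b = data.draw(seq), data.draw(seq)
        assert align_score(a, b) == pytest.approx(brute_force_align(a, b))


class TestSequenceSimilarity:
    def test_identical_sequences_have_similarity_one(self):
        seqs = SequenceSet(ids=("a", "b"), sequences=("ACGUACGU", "ACGUACGU"))
        sim = sequence_similarity(seqs)
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_negative_raw_scores_clip_to_zero(self):
        # maximally dissimilar short sequences align with negative score
        seqs = SequenceSet(ids=("a", "b"), sequences=("AAAA", "UUUU"))
        sim = sequence_similarity(seqs)
        assert sim.values[0, 1] == 0.0

    def test_matches_pairwise_oracle_on_toy_set(self):
        seqs = SequenceSet(
            ids=tuple("abcde"),
            sequences=("ACGUAC", "ACGUAA", "UGCAUG", "ACGGAC", "CCCGGG"),
        )
        sim = sequence_similarity(seqs)
        check_similarity_contract(sim)
        raw = np.array(
            [[align_score(x, y) for y in seqs.sequences] for x in seqs.sequences]
        )
        expected = np.maximum(raw, 0) / np.sqrt(np.outer(np.diag(raw), np.diag(raw)))
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(sim.values, expected, atol=1e-12)

    def test_permutation_equivariance(self):
        seqs = SequenceSet(
            ids=tuple("abcd"), sequences=("ACGUAC", "ACGUAA", "UGCAUG", "ACGGAC")
        )
        sim = sequence_similarity(seqs)
        perm = [2, 0, 3, 1]
        permuted = SequenceSet(
            ids=tuple(seqs.ids[i] for i in perm),
            sequences=tuple(seqs.sequences[i] for i in perm),
        )
        sim_p = sequence_similarity(permuted)
        np.testing.assert_allclose(
            sim_p.values, sim.values[np.ix_(perm, perm)], atol=1e-12
        )

    def test_requires_two_sequences(self):
        with pytest.raises(InputError):
            sequence_similarity(SequenceSet(ids=("a",), sequences=("ACGU",)))


class TestPreprocessExpression:
    def test_duplicate_rows_merged_by_mean(self):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["m1", "m1"],
                          columns=["c1", "c2"])
        out = preprocess_expression(ExpressionMatrix.from_frame(df))
        assert out.ids == ("m1",)
        np.testing.assert_allclose(out.values, [[2.0, 3.0]])

    def test_all_zero_rows_deleted(self):
        df = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["m1", "m2"],
                          columns=["c1", "c2"])
        out = preprocess_expression(ExpressionMatrix.from_frame(df))
        assert out.ids == ("m1",)

    def test_clean_input_passes_through(self):
        df = pd.DataFrame(
            np.arange(6.0).reshape(3, 2) + 1, index=["a", "b", "c"],
            columns=["c1", "c2"],
        )
        out = preprocess_expression(ExpressionMatrix.from_frame(df))
        assert out.ids == ("a", "b", "c")
        np.testing.assert_array_equal(out.values, df.to_numpy())

    def test_everything_removed_is_an_error(self):
        df = pd.DataFrame([[0.0, 0.0]], index=["m1"], columns=["c1", "c2"])
        with pytest.raises(InputError):
            preprocess_expression(ExpressionMatrix.from_frame(df))


class TestExpressionSimilarity:
    def _matrix(self, rows, ids=None):
        rows = np.asarray(rows, dtype=float)
        ids = ids or tuple(f"m{i}" for i in range(rows.shape[0]))
        labels = tuple(f"c{j}" for j in range(rows.shape[1]))
        return ExpressionMatrix(ids=tuple(ids), condition_labels=labels,
                                values=rows)

    def test_linear_dependence_gives_one(self):
        base = np.array([1.0, 4.0, 2.0, 7.0])
        sim = expression_similarity(self._matrix([base, 2 * base + 1]))
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_anticorrelation_gives_one_via_absolute_value(self):
        base = np.array([1.0, 4.0, 2.0, 7.0])
        sim = expression_similarity(self._matrix([base, -base]))
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_pearson_half(self):
        sim = expression_similarity(self._matrix([[1, 2, 3], [1, 3, 2]]))
        assert sim.values[0, 1] == pytest.approx(0.5)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        rows = rng.random((4, 6))
        sim = expression_similarity(self._matrix(rows))
        rescaled = rows * np.array([[2.0], [0.5], [-3.0], [7.0]]) + 1.0
        sim2 = expression_similarity(self._matrix(rescaled))
        np.testing.assert_allclose(sim.values, sim2.values, atol=1e-10)

    def test_zero_variance_row_gets_zero_similarity(self):
        sim = expression_similarity(self._matrix([[1, 2, 3], [5, 5, 5]]))
        check_similarity_contract(sim)
        assert sim.values[0, 1] == 0.0

    def test_too_few_conditions_rejected(self):
        with pytest.raises(InputError):
            expression_similarity(self._matrix([[1, 2], [3, 4]]))


class TestDiagonalNormalize:
    def test_hand_worked_two_by_two(self):
        sim = diagonal_normalize(["a", "b"], np.array([[2.0, 1.0], [1.0, 4.0]]))
        np.testing.assert_allclose(
            sim.values, [[1.0, 0.375], [0.375, 1.0]], atol=1e-12
        )

    def test_unit_diagonal_symmetric_input_is_fixed_point(self):
        raw = np.array([[1.0, 0.3, 0.6], [0.3, 1.0, 0.1], [0.6, 0.1, 1.0]])
        sim = diagonal_normalize(list("abc"), raw)
        np.testing.assert_allclose(sim.values, raw, atol=1e-12)

    def test_output_contract_on_random_input(self):
        rng = np.random.default_rng(0)
        raw = rng.random((6, 6)) + np.diag(np.full(6, 2.0))
        sim = diagonal_normalize([f"m{i}" for i in range(6)], raw)
        check_similarity_contract(sim)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(InputError):
            diagonal_normalize(["a", "b"], np.array([[0.0, 1.0], [1.0, 2.0]]))

    def test_non_square_rejected(self):
        with pytest.raises(InputError):
            diagonal_normalize(["a", "b"], np.ones((2, 3)))


class TestSimilarityMatrixContract:
    def test_asymmetry_rejected(self):
        v = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ComputationError):
            SimilarityMatrix(ids=("a", "b"), values=v)

    def test_bad_diagonal_rejected(self):
        v = np.array([[0.9, 0.2], [0.2, 1.0]])
        with pytest.raises(ComputationError):
            SimilarityMatrix(ids=("a", "b"), values=v)

    def test_out_of_range_rejected(self):
        v = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ComputationError):
            SimilarityMatrix(ids=("a", "b"), values=v)

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        raw = rng.random((4, 4))
        v = np.round((raw + raw.T) / 4, 6)
        np.fill_diagonal(v, 1.0)
        sim = make_similarity(v)
        path = tmp_path / "sim.tsv"
        sim.write_tsv(path)
        back = SimilarityMatrix.read_tsv(path)
        assert back.ids == sim.ids
        np.testing.assert_allclose(back.values, sim.values, atol=1e-6)


class TestAlignMatrices:
    def test_identical_id_sets_pass_through(self):
        v = np.array([[1.0, 0.5], [0.5, 1.0]])
        a = make_similarity(v, ids=("x", "y"))
        b = make_similarity(v, ids=("y", "x"))
        (ra, rb), _ = align_matrices([a, b])
        assert ra.ids == rb.ids == ("x", "y")
        assert rb.values[0, 1] == pytest.approx(0.5)

    def test_intersection_is_exact(self):
        v3 = np.eye(3)
        v3[v3 == 0] = 0.2
        a = make_similarity(v3, ids=("a", "b", "c"))
        b = make_similarity(v3, ids=("b", "c", "d"))
        (ra, rb), _ = align_matrices([a, b])
        assert set(ra.ids) == {"b", "c"}
        assert ra.ids == rb.ids

    def test_planted_overlap_of_twelve(self):
        rng = np.random.default_rng(11)
        shared = [f"s{i}" for i in range(12)]
        mats, tables = [], []
        for k in range(5):
            ids = shared + [f"x{k}_{i}" for i in range(4)]
            order = rng.permutation(len(ids))
            ids = [ids[i] for i in order]
            raw = rng.random((16, 16))
            v = (raw + raw.T) / 4
            np.fill_diagonal(v, 1.0)
            mats.append(make_similarity(v, ids=ids))
        incidence = (rng.random((12, 5)) < 0.5).astype(int)
        tables.append(make_associations(incidence, mirna_ids=shared))
        out_mats, out_tables = align_matrices(mats, tables)
        for m in out_mats:
            assert m.n == 12
            assert m.ids == out_mats[0].ids
        assert out_tables[0].mirna_ids == out_mats[0].ids

    def test_empty_intersection_is_error(self):
        v = np.array([[1.0, 0.1], [0.1, 1.0]])
        a = make_similarity(v, ids=("a", "b"))
        b = make_similarity(v, ids=("c", "d"))
        with pytest.raises(InputError):
            align_matrices([a, b])
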