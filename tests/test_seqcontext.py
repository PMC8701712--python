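import numpy as np
import pytest

from rdnanet.seqcontext import (
    ALPHABET,
    ContextMatrix,
    difference_logo,
    extract_context_matrix,
    select_top_positions,
)

from conftest import make_profile


class TestSelectTopPositions:
    def test_top_quantile_of_distinct_values(self, rng):
        values = rng.permutation(np.arange(1000, dtype=float) + 1)
        prof = make_profile(values)
        top = select_top_positions(prof, q=0.025, region=(1, 1000))
        assert top.size == 25
        expected = np.sort(np.argsort(values)[-25:] + 1)
        np.testing.assert_array_equal(top, expected)

    def test_q_one_returns_every_position(self, rng):
        prof = make_profile(rng.random(100))
        assert select_top_positions(prof, q=1.0, region=(1, 100)).size == 100

    def test_all_tied_takes_lowest_coordinates(self):
        prof = make_profile(np.full(200, 3.0))
        top = select_top_positions(prof, q=0.1, region=(1, 200))
        np.testing.assert_array_equal(top, np.arange(1, 21))

    def test_threshold_ties_break_by_ascending_position(self):
        values = np.array([5.0, 1, 1, 1, 1, 1, 1, 1, 1, 1])
        top = select_top_positions(make_profile(values), q=0.3, region=(1, 10))
        np.testing.assert_array_equal(top, [1, 2, 3])

    def test_monotone_transform_invariance(self, rng):
        values = rng.random(400)
        prof = make_profile(values)
        transformed = make_profile(np.exp(5 * values))
        np.testing.assert_array_equal(
            select_top_positions(prof, region=(1, 400), q=0.05),
            select_top_positions(transformed, region=(1, 400), q=0.05),
        )

    def test_invalid_q_rejected(self, rng):
        prof = make_profile(rng.random(10))
        for q in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                select_top_positions(prof, q=q, region=(1, 10))


class TestExtractContextMatrix:
    def test_single_position_one_hot(self):
        template = "CCGATCC"
        cm = extract_context_matrix([4], template, window=(-1, 1))
        assert cm.n_sequences == 1
        assert cm.sequences == ["GAT"]
        expected = np.zeros((4, 3), dtype=int)
        expected[ALPHABET.index("G"), 0] = 1
        expected[ALPHABET.index("A"), 1] = 1
        expected[ALPHABET.index("T"), 2] = 1
        np.testing.assert_array_equal(cm.counts, expected)

    def test_column_sums_equal_kept_contexts(self, rng):
        template = "".join(rng.choice(list(ALPHABET), 500))
        positions = rng.integers(10, 490, size=30)
        cm = extract_context_matrix(positions, template, window=(-8, 4))
        np.testing.assert_array_equal(cm.counts.sum(axis=0), cm.n_sequences)

    def test_out_of_bounds_position_skipped(self):
        cm = extract_context_matrix([1], "ACGTACGT", window=(-5, 0))
        assert cm.n_sequences == 0
        assert cm.n_skipped_bounds == 1

    def test_ambiguous_symbols_skipped_with_count(self):
        cm = extract_context_matrix([3], "ANGTT", window=(-1, 1))
        assert cm.n_sequences == 0
        assert cm.n_skipped_symbols == 1


def _cm_from_sequences(seqs, window=(-1, 1)):
    lo, hi = window
    width = hi - lo + 1
    counts = np.zeros((4, width), dtype=int)
    for s in seqs:
        for w, c in enumerate(s):
            counts[ALPHABET.index(c), w] += 1
    return ContextMatrix(
        counts=counts,
        offsets=np.arange(lo, hi + 1),
        n_sequences=len(seqs),
        sequences=list(seqs),
    )


class TestDifferenceLogo:
    def test_identical_matrices_flat_and_insignificant(self):
        cm = _cm_from_sequences(["ACG", "TGA", "ACG", "CCT"])
        res = difference_logo(cm, cm, n_permutations=200, seed=0)
        np.testing.assert_allclose(res.heights, 0.0, atol=1e-12)
        assert (res.p_values > 0.9).all()

    def test_disjoint_point_masses_give_one_bit(self):
        """All-A vs all-C columns diverge by exactly 1 bit (no pseudocount)."""
        cm_a = _cm_from_sequences(["AAA"] * 10)
        cm_b = _cm_from_sequences(["CCC"] * 10)
        res = difference_logo(cm_a, cm_b, n_permutations=10, seed=0, pseudocount=0.0)
        np.testing.assert_allclose(res.heights, 1.0)

    def test_divergence_bounded_by_one_bit(self, rng):
        seqs_a = ["".join(rng.choice(list(ALPHABET), 3)) for _ in range(30)]
        seqs_b = ["".join(rng.choice(list(ALPHABET), 3)) for _ in range(30)]
        res = difference_logo(
            _cm_from_sequences(seqs_a), _cm_from_sequences(seqs_b),
            n_permutations=10, seed=0,
        )
        assert (res.heights >= 0).all() and (res.heights <= 1.0).all()

    def test_swap_symmetry(self, rng):
        seqs_a = ["".join(rng.choice(list(ALPHABET), 3)) for _ in range(20)]
        seqs_b = ["".join(rng.choice(list("AC"), 3)) for _ in range(20)]
        cm_a, cm_b = _cm_from_sequences(seqs_a), _cm_from_sequences(seqs_b)
        r1 = difference_logo(cm_a, cm_b, n_permutations=300, seed=5)
        r2 = difference_logo(cm_b, cm_a, n_permutations=300, seed=5)
        np.testing.assert_allclose(r1.heights, r2.heights)
        np.testing.assert_allclose(r1.contributions, -r2.contributions)
        np.testing.assert_allclose(r1.p_values, r2.p_values)

    def test_absolute_contributions_sum_to_height(self, rng):
        seqs_a = ["".join(rng.choice(list(ALPHABET), 4)) for _ in range(25)]
        seqs_b = ["".join(rng.choice(list("AG"), 4)) for _ in range(25)]
        res = difference_logo(
            _cm_from_sequences(seqs_a, (-2, 1)),
            _cm_from_sequences(seqs_b, (-2, 1)),
            n_permutations=10,
            seed=0,
        )
        np.testing.assert_allclose(
            np.abs(res.contributions).sum(axis=0), res.heights, atol=1e-12
        )

    def test_seed_reproducibility(self, rng):
        seqs_a = ["".join(rng.choice(list(ALPHABET), 3)) for _ in range(15)]
        seqs_b = ["".join(rng.choice(list(ALPHABET), 3)) for _ in range(15)]
        cm_a, cm_b = _cm_from_sequences(seqs_a), _cm_from_sequences(seqs_b)
        r1 = difference_logo(cm_a, cm_b, n_permutations=100, seed=7)
        r2 = difference_logo(cm_a, cm_b, n_permutations=100, seed=7)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)

    def test_window_mismatch_rejected(self):
        cm_a = _cm_from_sequences(["ACG"], window=(-1, 1))
        cm_b = _cm_from_sequences(["ACGT"], window=(-1, 2))
        with pytest.raises(ValueError, match="window"):
            difference_logo(cm_a, cm_b)
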