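"""Maximum-gap discretization: worked examples, oracle equivalence, invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgbiclust import (
    ExpressionMatrix,
    discretize_foldchange,
    discretize_matrix,
    discretize_profile,
    discretize_zscore,
    gap_select,
    l2_normalize,
)


def brute_force_gap_profile(raw):
    """Independent reference: explicit stable sort, enumerate every gap,
    select strictly above the largest (ties toward the largest index)."""
    raw = np.asarray(raw, dtype=float)
    row = raw / np.linalg.norm(raw)
    a = np.abs(row)
    order = sorted(range(len(a)), key=lambda i: (a[i], i))
    v = [a[i] for i in order]
    gaps = [v[i + 1] - v[i] for i in range(len(v) - 1)]
    maxgap = max(gaps)
    if maxgap == 0:
        return [0] * len(a)
    istar = max(i for i, g in enumerate(gaps) if g == maxgap)
    chosen = set(order[istar + 1:])
    return [int(np.sign(raw[i])) if i in chosen else 0 for i in range(len(a))]


class TestNormalize:
    def test_three_four_five(self):
        m = ExpressionMatrix([[3.0, 4.0]], ["g1"], ["c1", "c2"])
        out, skipped = l2_normalize(m)
        assert np.allclose(out.values, [[0.6, 0.8]])
        assert skipped == []

    def test_single_spike(self):
        m = ExpressionMatrix([[0.0, 0.0, 5.0, 0.0]], ["g1"], list("abcd"))
        out, _ = l2_normalize(m)
        assert np.allclose(out.values, [[0, 0, 1, 0]])

    def test_zero_row_skipped_with_reason(self):
        m = ExpressionMatrix([[0.0, 0.0], [1.0, 2.0]], ["gz", "g2"], ["c1", "c2"])
        out, skipped = l2_normalize(m)
        assert skipped == [("gz", "zero norm")]
        assert np.isclose(np.linalg.norm(out.values[1]), 1.0)

    def test_nonzero_rows_unit_norm(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(rng.normal(size=(20, 7)), [f"g{i}" for i in range(20)],
                             [f"c{j}" for j in range(7)])
        out, _ = l2_normalize(m)
        assert np.allclose(np.linalg.norm(out.values, axis=1), 1.0, atol=1e-12)


class TestGapProfile:
    def test_single_spike_selected(self):
        p = discretize_profile([0.0, 0.0, 1.0, 0.0])
        assert p.states == (0, 0, 1, 0)
        assert p.selected == {2}

    def test_two_large_values_with_signs(self):
        raw = np.array([3.0, -3.0, 0.1, 0.05])
        row = raw / np.linalg.norm(raw)
        p = discretize_profile(row, raw)
        assert p.states == (1, -1, 0, 0)

    def test_all_equal_selects_nothing(self):
        p = discretize_profile([0.5, 0.5, 0.5, 0.5])
        assert p.selected == frozenset()

    def test_rejects_unnormalized_input(self):
        with pytest.raises(ValueError, match="normalized"):
            discretize_profile([3.0, 4.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            c = int(rng.integers(3, 21))
            raw = rng.normal(size=c)
            row = raw / np.linalg.norm(raw)
            p = discretize_profile(row, raw)
            assert list(p.states) == brute_force_gap_profile(raw)

    @settings(derandomize=True, max_examples=200)
    @given(
        raw=st.lists(
            st.floats(-100, 100, allow_nan=False).filter(lambda x: abs(x) > 1e-6),
            min_size=2, max_size=12,
        ),
        k=st.floats(0.01, 50).filter(lambda x: x > 0),
        flip=st.booleans(),
    )
    def test_scale_invariance(self, raw, k, flip):
        raw = np.asarray(raw)
        scale = -k if flip else k
        base = brute_force_gap_profile(raw)
        scaled = brute_force_gap_profile(raw * scale)
        row = raw / np.linalg.norm(raw)
        p = discretize_profile(row, raw)
        assert list(p.states) == base
        expected = [-s for s in base] if flip else base
        assert scaled == expected

    def test_selected_count_between_1_and_c_minus_1(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            c = int(rng.integers(3, 15))
            row = rng.normal(size=c)
            row /= np.linalg.norm(row)
            n_sel = len(discretize_profile(row).selected)
            assert 1 <= n_sel <= c - 1


class TestGapSelectKernel:
    def test_matrix_agrees_with_rowwise(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(50, 8))
        sel = gap_select(vals)
        for i in range(50):
            assert np.array_equal(sel[i], gap_select(vals[i]))

    def test_requires_two_columns(self):
        with pytest.raises(ValueError):
            gap_select(np.ones((3, 1)))


class TestDiscretizeMatrix:
    def test_block_genes_select_their_block(self):
        from cgbiclust import generate_block_dataset

        ds = generate_block_dataset(noise_sd=0.0)
        disc = discretize_matrix(ds.matrix)
        assert disc.kept.size == 100
        for b in range(10):
            for i in range(b * 10, b * 10 + 10):
                sel = np.flatnonzero(disc.states[i])
                assert np.array_equal(sel, np.arange(b * 10, b * 10 + 10))
                assert np.all(disc.states[i][sel] == 1)

    def test_constant_gene_skipped_spiked_kept(self):
        m = ExpressionMatrix(
            [[2.0, 2.0, 2.0], [0.0, 9.0, 0.0]], ["flat", "spike"], list("abc")
        )
        disc = discretize_matrix(m)
        assert [g for g, _ in disc.skipped] == ["flat"]
        assert np.array_equal(disc.states[1], [0, 1, 0])
        assert list(disc.kept) == [1]

    def test_zero_row_in_skip_report(self):
        m = ExpressionMatrix([[0.0, 0.0], [1.0, 3.0]], ["gz", "g2"], ["c1", "c2"])
        disc = discretize_matrix(m)
        assert ("gz", "zero norm") in disc.skipped


class TestFixedCutoffs:
    def test_foldchange_thresholds(self):
        m = ExpressionMatrix([[1.5, -0.2, -2.0]], ["g1"], list("abc"))
        disc = discretize_foldchange(m)
        assert np.array_equal(disc.states[0], [1, 0, -1])

    def test_foldchange_boundary_inclusive_and_empty(self):
        m = ExpressionMatrix([[1.0, -0.99, 0.5], [0.9, -0.9, 0.0]],
                             ["g1", "g2"], list("abc"))
        disc = discretize_foldchange(m)
        assert np.array_equal(disc.states[0], [1, 0, 0])
        assert np.array_equal(disc.states[1], [0, 0, 0])
        assert [g for g, _ in disc.skipped] == ["g2"]

    def test_zscore_spike_row(self):
        # [0,0,0,10]: mean 2.5, sample sd 5 -> z = (1.5, selected), others 0.5
        m = ExpressionMatrix([[0.0, 0.0, 0.0, 10.0]], ["g1"], list("abcd"))
        disc = discretize_zscore(m, z=1.5)
        assert np.array_equal(disc.states[0], [0, 0, 0, 1])

    def test_zscore_symmetric_pair_empty_with_sample_sd(self):
        # [-5, 5]: sample sd = sqrt(50) so each |z| ~ 0.707 < 1.5
        m = ExpressionMatrix([[-5.0, 5.0]], ["g1"], ["c1", "c2"])
        disc = discretize_zscore(m, z=1.5)
        assert np.array_equal(disc.states[0], [0, 0])

    def test_zscore_constant_row_empty(self):
        m = ExpressionMatrix([[3.0, 3.0, 3.0]], ["g1"], list("abc"))
        disc = discretize_zscore(m)
        assert np.array_equal(disc.states[0], [0, 0, 0])

    def test_zscore_sign_from_deviation(self):
        # all-positive row: the low outlier is "down" relative to the mean
        m = ExpressionMatrix([[10.0, 10.0, 10.0, 10.0, 0.1]], ["g1"], list("abcde"))
        disc = discretize_zscore(m, z=1.5)
        assert disc.states[0][4] == -1


class TestGapVersusFixedCutoff:
    def test_gap_method_recovers_heterogeneous_blocks(self):
        """Blocks rescaled to magnitude 0.1*b: the gap method still finds all
        blocks, a fixed 2-fold cutoff misses the low-magnitude ones."""
        from cgbiclust import generate_block_dataset, recovery_relevance, run_cg

        ds = generate_block_dataset(noise_sd=0.0)
        vals = ds.matrix.values.copy()
        for b in range(10):
            vals[b * 10 : b * 10 + 10] *= 0.1 * (b + 1)
        m = ExpressionMatrix(vals, ds.matrix.gene_ids, ds.matrix.condition_ids)
        found = run_cg(m, overlap_param=0)
        rep = recovery_relevance(ds.truth, found)
        assert rep.recovery == 1.0

        fc = discretize_foldchange(m)  # 2-fold cutoff on the same data
        # blocks with value below 1.0 select nothing under the fixed cutoff
        low_block_rows = range(0, 90)  # blocks 1..9 have magnitude <= 0.9
        assert all(not fc.states[i].any() for i in low_block_rows)
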