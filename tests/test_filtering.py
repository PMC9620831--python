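"""Two-step coefficient filtering: loading t-test, permutation test, BH-FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ccpls.filtering import (
    bh_adjust,
    coefficient_significance_test,
    filter_coefficients,
    loading_significance_test,
)
from ccpls.pls import fit_pls


def _planted_problem(rng, n=100, strong=True):
    X = rng.normal(size=(n, 3))
    X = (X - X.mean(0)) / X.std(0)
    B = np.zeros((3, 6))
    if strong:
        B[0, :3] = 1.0
    noise = 0.2 if strong else 1.0
    Y = X @ B + noise * rng.normal(size=(n, 6))
    Y = (Y - Y.mean(0)) / Y.std(0)
    return X, Y


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.123]))[0] == pytest.approx(0.123)

    def test_known_step_up_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_independent_step_up_oracle(self, rng):
        p = rng.uniform(size=37)
        q = bh_adjust(p)
        # oracle: sort, scale by m/rank, enforce monotonicity from the top
        order = np.argsort(p)
        scaled = p[order] * len(p) / np.arange(1, len(p) + 1)
        expected = np.minimum.accumulate(scaled[::-1])[::-1].clip(max=1.0)
        assert np.allclose(q[order], expected)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjustment_bounds(self, ps):
        p = np.array(ps)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)


class TestLoadingTest:
    def test_gene_equal_to_score_retained(self, rng):
        X, Y = _planted_problem(rng)
        fit = fit_pls(X, Y, 2, check_centered=False)
        Y2 = np.column_stack([Y, fit.T[:, 0]])  # copy of t_1 as a "gene"
        q, mask = loading_significance_test(fit, Y2)
        assert q[-1, 0] < 1e-10
        assert mask[-1, 0]

    def test_pvalue_matches_correlation_test_oracle(self, rng):
        """Loading p-values equal scipy's independent Pearson test."""
        X, Y = _planted_problem(rng, n=40)
        fit = fit_pls(X, Y, 2, check_centered=False)
        q, _ = loading_significance_test(fit, Y)
        # reconstruct raw p for one (gene, component) pair via pearsonr
        p_raw = np.empty((Y.shape[1], 2))
        for h in range(Y.shape[1]):
            for c in range(2):
                p_raw[h, c] = stats.pearsonr(Y[:, h], fit.T[:, c]).pvalue
        assert np.allclose(q, bh_adjust(p_raw), atol=1e-10)

    def test_independent_noise_gene_filtered(self, rng):
        X = rng.normal(size=(100, 3))
        X -= X.mean(0)
        B = np.zeros((3, 5))
        B[0] = 2.0
        Y = X @ B + 0.1 * rng.normal(size=(100, 5))
        Y = np.column_stack([Y, rng.normal(size=100)])  # pure noise gene
        Y -= Y.mean(0)
        fit = fit_pls(X, Y, 1, check_centered=False)
        _, mask = loading_significance_test(fit, Y)
        assert mask[:5, 0].all()
        assert not mask[5, 0]


class TestPermutationTest:
    def test_planted_effect_reaches_resolution_floor(self, rng):
        X, Y = _planted_problem(rng, strong=True)
        fit = fit_pls(X, Y, 1, check_centered=False)
        q, mask, null = coefficient_significance_test(
            fit.W_sum, X, Y, 1, n_perm=199, seed=1, return_null=True
        )
        # strongest observed coefficient: no permutation exceeds it, p = 1/200
        f, h = np.unravel_index(np.argmax(np.abs(fit.W_sum)), fit.W_sum.shape)
        p_manual = (1 + (np.abs(null[:, f, h]) >= abs(fit.W_sum[f, h])).sum()) / 200
        assert p_manual == pytest.approx(1 / 200)
        assert mask[f, h]

    def test_q_matches_count_over_recorded_permutations(self, rng):
        """The reported q-values equal BH over p recomputed by explicit
        counting against the recorded null coefficients."""
        X, Y = _planted_problem(rng, n=30, strong=False)
        fit = fit_pls(X, Y, 1, check_centered=False)
        q, _, null = coefficient_significance_test(
            fit.W_sum, X, Y, 1, n_perm=120, seed=3, return_null=True
        )
        counts = (np.abs(null) >= np.abs(fit.W_sum)[None]).sum(axis=0)
        p_manual = (1.0 + counts) / 121.0
        assert np.allclose(q, bh_adjust(p_manual))

    def test_small_n_perm_warns(self, rng):
        X, Y = _planted_problem(rng, n=20)
        fit = fit_pls(X, Y, 1, check_centered=False)
        with pytest.warns(UserWarning, match="resolution"):
            coefficient_significance_test(fit.W_sum, X, Y, 1, n_perm=9, seed=0)


class TestFullFilter:
    def test_nonzero_entries_imply_both_masks(self, rng):
        X, Y = _planted_problem(rng)
        fit = fit_pls(X, Y, 2, check_centered=False)
        out = filter_coefficients(fit, X, Y, n_perm=99, seed=2)
        nz = out.W_filtered != 0
        assert np.all(out.step2_mask[nz])
        gene_pass_step1 = out.step1_mask.any(axis=1)
        assert np.all(gene_pass_step1[np.where(nz.any(axis=0))[0]])
        # filtering is a projection: re-masking changes nothing
        again = np.where(out.step2_mask, out.W_filtered, 0.0)
        assert np.array_equal(again, out.W_filtered)

    def test_planted_signal_survives_noise_does_not(self, rng):
        X, Y = _planted_problem(rng, strong=True)
        fit = fit_pls(X, Y, 1, check_centered=False)
        out = filter_coefficients(fit, X, Y, n_perm=199, seed=4)
        assert np.all(out.W_filtered[0, :3] != 0)  # planted (f=0, genes 0-2)
        assert np.all(out.W_filtered[1:, 3:] == 0)

    def test_component_scope_masks_summed_increments(self, rng):
        """With step1_scope='component', candidate coefficients are the
        sums of only the retained per-component increments."""
        X, Y = _planted_problem(rng)
        fit = fit_pls(X, Y, 2, check_centered=False)
        out = filter_coefficients(
            fit, X, Y, n_perm=99, seed=5, step1_scope="component"
        )
        expected = np.einsum(
            "lhc,hc->lh", fit.W_comp, out.step1_mask.astype(float)
        )
        recovered = np.where(out.step2_mask, expected, 0.0)
        assert np.array_equal(out.W_filtered, recovered)
        with pytest.raises(ValueError, match="step1_scope"):
            filter_coefficients(fit, X, Y, n_perm=99, step1_scope="rows")

    def test_global_null_false_positive_rate_controlled(self):
        """Under X independent of Y, nonzero entries are rare (FDR level)."""
        frac = []
        for rep in range(60):
            rng = np.random.default_rng(1000 + rep)
            X = rng.normal(size=(50, 3))
            X -= X.mean(0)
            Y = rng.normal(size=(50, 20))
            Y -= Y.mean(0)
            fit = fit_pls(X, Y, 1, check_centered=False)
            out = filter_coefficients(fit, X, Y, n_perm=99, seed=rep)
            frac.append((out.W_filtered != 0).mean())
        assert np.mean(frac) <= 0.05 * 1.5
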