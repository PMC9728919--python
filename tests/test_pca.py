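"""PCA engine: centering, spectra, loadings, factor scores, contributions.

The independent oracle throughout is the explicit covariance-matrix
eigendecomposition (scipy.linalg.eigh on ``Xc.T @ Xc``), which the SVD path
must reproduce.
"""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st

from bpfs import (
    DegenerateMatrixError,
    PCAResult,
    center_columns,
    contribution_scores,
    loading_scores,
    pca,
    proportion_of_variance,
)
from conftest import make_matrix


def random_matrix(rng, m, p, scale=1.0):
    return rng.normal(0, scale, (m, p))


# ---------------------------------------------------------------- centering


class TestCenterColumns:
    def test_worked_example(self):
        centered, means = center_columns(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(centered, [[-1, -1], [1, 1]])
        np.testing.assert_allclose(means, [2, 3])

    def test_already_centered_is_identity(self):
        X = np.array([[1.0, -2.0], [-1.0, 2.0]])
        centered, means = center_columns(X)
        np.testing.assert_allclose(centered, X)
        np.testing.assert_allclose(means, [0, 0])

    def test_column_sums_vanish(self, rng):
        X = random_matrix(rng, 5, 3, scale=10)
        centered, _ = center_columns(X)
        np.testing.assert_allclose(
            centered.sum(axis=0), 0, atol=1e-12 * np.abs(X).max()
        )

    def test_single_row_rejected(self):
        with pytest.raises(DegenerateMatrixError):
            center_columns(np.array([[1.0, 2.0]]))


# ---------------------------------------------------- proportion of variance


class TestProportionOfVariance:
    @pytest.mark.parametrize(
        "lam, ppv, cppv",
        [
            ([3, 1], [0.75, 0.25], [0.75, 1.0]),
            ([5, 0, 0], [1, 0, 0], [1, 1, 1]),
            ([2, 1, 1], [0.5, 0.25, 0.25], [0.5, 0.75, 1.0]),
        ],
    )
    def test_worked_examples(self, lam, ppv, cppv):
        got_ppv, got_cppv = proportion_of_variance(np.array(lam, dtype=float))
        np.testing.assert_allclose(got_ppv, ppv)
        np.testing.assert_allclose(got_cppv, cppv)

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            proportion_of_variance(np.array([1.0, -0.5]))

    def test_tiny_negative_clipped(self):
        ppv, _ = proportion_of_variance(np.array([1.0, -1e-12]))
        np.testing.assert_allclose(ppv, [1.0, 0.0])


# ----------------------------------------------------------------- pca core


class TestPCA:
    def test_axis_aligned_example(self):
        # spread 2x larger along the first axis: eigen-directions are the axes
        M = make_matrix([[2, 0], [0, 1], [-2, 0], [0, -1]])
        res = pca(M)
        # squared-singular-value convention: lambda = sum of squared centered values
        np.testing.assert_allclose(res.eigenvalues, [8.0, 2.0], atol=1e-12)
        assert abs(abs(res.components[0, 0]) - 1) < 1e-12
        assert abs(res.components[0, 1]) < 1e-12

    def test_column_permutation_symmetry(self, rng):
        X = random_matrix(rng, 8, 5)
        perm = rng.permutation(5)
        res, res_p = pca(X), pca(X[:, perm])
        np.testing.assert_allclose(res_p.eigenvalues, res.eigenvalues, rtol=1e-10)
        np.testing.assert_allclose(
            np.abs(res_p.components[:, np.argsort(perm)]),
            np.abs(res.components),
            atol=1e-8,
        )

    def test_rank_one_matrix_explains_everything(self, rng):
        X = np.outer(rng.normal(size=6), rng.normal(size=4))
        res = pca(X)
        assert res.r == 1
        np.testing.assert_allclose(res.cppv[0], 1.0, atol=1e-9)

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateMatrixError, match="zero total variance"):
            pca(np.full((4, 3), 7.0))

    def test_excess_components_truncated_with_warning(self, rng):
        X = np.outer(rng.normal(size=5), rng.normal(size=3))
        with pytest.warns(UserWarning, match="rank"):
            res = pca(X, n_components=3)
        assert res.r == 1

    def test_oracle_equivalence_random(self, rng):
        """SVD eigenvalues/components match the explicit covariance route."""
        for _ in range(30):
            m, p = rng.integers(3, 15), rng.integers(2, 12)
            X = random_matrix(rng, int(m), int(p), scale=rng.uniform(0.1, 5))
            Xc = X - X.mean(axis=0)
            lam_oracle, vecs = scipy.linalg.eigh(Xc.T @ Xc)
            lam_oracle = lam_oracle[::-1]
            vecs = vecs[:, ::-1]
            res = pca(X)
            np.testing.assert_allclose(
                res.eigenvalues, lam_oracle[: res.r], rtol=1e-8, atol=1e-8 * lam_oracle[0]
            )
            for i in range(res.r):
                assert abs(abs(res.components[i] @ vecs[:, i]) - 1) < 1e-8

    def test_scale_equivariance(self, rng):
        X = random_matrix(rng, 7, 4)
        res, res_c = pca(X), pca(3.5 * X)
        np.testing.assert_allclose(res_c.eigenvalues, 3.5**2 * res.eigenvalues, rtol=1e-10)
        np.testing.assert_allclose(np.abs(res_c.components), np.abs(res.components), atol=1e-9)

    def test_result_invariants(self, rng):
        X = random_matrix(rng, 10, 6)
        res = pca(X)
        # orthonormal components
        np.testing.assert_allclose(
            res.components @ res.components.T, np.eye(res.r), atol=1e-8
        )
        # lambda = s^2; sum of squared factor scores = lambda
        np.testing.assert_allclose(
            res.eigenvalues, res.singular_values**2, rtol=1e-10
        )
        np.testing.assert_allclose(
            (res.factor_scores**2).sum(axis=0), res.eigenvalues,
            atol=1e-8 * res.eigenvalues[0],
        )
        # ppv sums to 1 at full rank, cppv non-decreasing
        np.testing.assert_allclose(res.ppv.sum(), 1.0, atol=1e-9)
        assert np.all(np.diff(res.cppv) >= -1e-12)
        np.testing.assert_allclose(res.cppv[-1], 1.0, atol=1e-9)


# --------------------------------------------------- loadings & contributions


class TestScores:
    def test_loading_formula(self):
        res = _manual_result(components=[[0.6, 0.8]], eigenvalues=[2.0])
        np.testing.assert_allclose(loading_scores(res, 0), [1.2, 1.6])

    def test_loading_rank_matches_component_rank(self, rng):
        X = random_matrix(rng, 9, 7)
        res = pca(X)
        for i in range(res.r):
            gamma = np.abs(loading_scores(res, i))
            v = np.abs(res.components[i])
            np.testing.assert_array_equal(np.argsort(-gamma), np.argsort(-v))

    def test_loading_component_out_of_range(self, rng):
        res = pca(random_matrix(rng, 5, 3))
        with pytest.raises(IndexError):
            loading_scores(res, res.r)

    def test_contribution_worked_example(self):
        f = np.array([[1.0], [1.0], [np.sqrt(2.0)]])
        lam = float((f**2).sum())
        res = _manual_result(
            components=[[1.0, 0.0, 0.0]], eigenvalues=[lam], scores=f
        )
        np.testing.assert_allclose(contribution_scores(res, 0), [0.25, 0.25, 0.5])

    def test_contributions_match_independent_svd(self, rng):
        X = random_matrix(rng, 6, 4)
        res = pca(X)
        Xc = X - X.mean(axis=0)
        _, s, _ = scipy.linalg.svd(Xc, full_matrices=False)
        U, _, _ = scipy.linalg.svd(Xc, full_matrices=False)
        F = U[:, : res.r] * s[: res.r]
        np.testing.assert_allclose(
            res.contributions, F**2 / s[: res.r] ** 2, atol=1e-10
        )
        np.testing.assert_allclose(res.contributions.sum(axis=0), 1.0, atol=1e-8)
        assert np.all(res.contributions >= 0) and np.all(res.contributions <= 1)

    def test_sign_flip_leaves_contributions_unchanged(self, rng):
        X = random_matrix(rng, 8, 5)
        res = pca(X)
        flipped = PCAResult(
            eigenvalues=res.eigenvalues,
            singular_values=res.singular_values,
            components=-res.components,
            scores=-res.scores,
            ppv=res.ppv,
            cppv=res.cppv,
            loadings=-res.loadings,
            contributions=(-res.scores) ** 2 / res.eigenvalues,
            column_means=res.column_means,
            r=res.r,
        )
        np.testing.assert_allclose(flipped.contributions, res.contributions)
        np.testing.assert_allclose(np.abs(flipped.loadings), np.abs(res.loadings))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_normalisation_properties(seed):
    """Sum of PPV == 1 and per-component contribution sums == 1."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, rng.uniform(0.5, 3), (int(rng.integers(3, 12)), int(rng.integers(2, 10))))
    res = pca(X)
    np.testing.assert_allclose(res.ppv.sum(), 1.0, atol=1e-8)
    np.testing.assert_allclose(res.contributions.sum(axis=0), 1.0, atol=1e-8)


def _manual_result(components, eigenvalues, scores=None):
    components = np.asarray(components, dtype=float)
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    r, p = components.shape
    scores = (
        np.asarray(scores, dtype=float)
        if scores is not None
        else np.zeros((2, r))
    )
    ppv, cppv = proportion_of_variance(eigenvalues)
    return PCAResult(
        eigenvalues=eigenvalues,
        singular_values=np.sqrt(eigenvalues),
        components=components,
        scores=scores,
        ppv=ppv,
        cppv=cppv,
        loadings=components * eigenvalues[:, None],
        contributions=scores**2 / eigenvalues,
        column_means=np.zeros(p),
        r=r,
    )
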