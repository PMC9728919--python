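"""SVD-backed principal component analysis.

This module exposes every PCA-derived quantity the two-phase gene selection
consumes: eigenvalues, orthonormal components, proportion of variance,
loading scores, factor scores and per-entity contribution scores.

Conventions
-----------
The decomposition is computed from the thin SVD of the column-centered data
matrix ``Xc = U S V^T`` — never by materialising the p x p covariance — so
memory stays proportional to ``rows x cols``.  Eigenvalues are stored as the
squared singular values of the centered matrix, ``lambda_i = s_i**2``.  This
is the un-normalised convention (no ``1/(m-1)`` factor), chosen so that the
factor scores ``F = U S`` satisfy ``sum_g f_{g,i}^2 == lambda_i`` exactly and
contribution scores normalise to one per component.  Every quantity used for
feature ranking (proportion of variance, |loading| order, contributions) is a
ratio, so the choice of normalisation never changes a selection.

Loading scores follow the eigenvalue-weighted form ``gamma_i = v_i * lambda_i``
rather than the textbook ``v_i * sqrt(lambda_i)``; since the weight is one
scalar per component the absolute-value ranking of genes within a component
is identical either way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

from .matrix import ExpressionMatrix

#: relative tolerance below which a singular value is treated as zero rank
RANK_RTOL = 1e-12
#: relative tolerance for clipping small negative eigenvalues to zero
NEG_EIG_RTOL = 1e-10


class DegenerateMatrixError(ValueError):
    """Raised when a matrix cannot support PCA (too few rows, zero variance)."""


MatrixLike = Union[ExpressionMatrix, np.ndarray]


def _as_array(M: MatrixLike) -> np.ndarray:
    if isinstance(M, ExpressionMatrix):
        return M.values
    return np.asarray(M, dtype=float)


@dataclass(frozen=True)
class PCAResult:
    """Everything PCA produces, truncated to ``r`` retained components.

    Attributes
    ----------
    eigenvalues:
        ``lambda_i = s_i**2`` of the centered matrix, non-increasing, length r.
    singular_values:
        ``s_i`` of the centered matrix, length r.
    components:
        ``(r, n_cols)`` orthonormal direction vectors over the column variables.
    scores:
        ``(n_rows, r)`` projections of the centered rows; equals ``U S``.
        These are the factor scores, so :attr:`factor_scores` is an alias.
    ppv, cppv:
        Per-component and cumulative proportion of variance, length r, with
        the denominator taken over the full rank (so ``cppv[-1] == 1`` only
        when r equals the rank).
    loadings:
        ``(r, n_cols)`` eigenvalue-weighted loadings ``gamma_i = v_i * lambda_i``.
    contributions:
        ``(n_rows, r)`` per-row contribution scores ``f**2 / lambda``; each
        column sums to one.
    column_means:
        The subtracted per-column means, length n_cols.
    r:
        Number of retained components.
    """

    eigenvalues: np.ndarray
    singular_values: np.ndarray
    components: np.ndarray
    scores: np.ndarray
    ppv: np.ndarray
    cppv: np.ndarray
    loadings: np.ndarray
    contributions: np.ndarray
    column_means: np.ndarray
    r: int

    @property
    def factor_scores(self) -> np.ndarray:
        """Alias for :attr:`scores`: the factor score matrix ``F = U S``."""
        return self.scores


def center_columns(M: MatrixLike) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the per-column mean from every column.

    Returns the centered array and the vector of column means.  Requires at
    least two rows, below which the notion of column variance is undefined.
    """
    X = _as_array(M)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {X.shape}")
    if X.shape[0] < 2:
        raise DegenerateMatrixError(
            f"need at least 2 rows to center; got {X.shape[0]}"
        )
    means = X.mean(axis=0)
    return X - means, means


def proportion_of_variance(eigenvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-component and cumulative proportion of variance.

    ``ppv_i = lambda_i / sum_j lambda_j`` and ``cppv_i = sum_{j<=i} ppv_j``.
    Small negative eigenvalues (numerical noise above ``-1e-10 * lambda_1``)
    are clipped to zero; anything more negative is rejected.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("no eigenvalues given")
    lam_max = float(lam.max(initial=0.0))
    if np.any(lam < -NEG_EIG_RTOL * max(lam_max, 1.0)):
        raise ValueError(f"negative eigenvalue in {lam!r}")
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero; proportion undefined")
    ppv = lam / total
    return ppv, np.cumsum(ppv)


def pca(M: MatrixLike, n_components: int | str = "all") -> PCAResult:
    """Principal component analysis via thin SVD of the centered matrix.

    Parameters
    ----------
    M:
        Matrix with observations on rows and variables on columns; columns
        are centered (no unit-variance scaling).
    n_components:
        Number of leading components to retain, or ``"all"`` for the full
        numerical rank.  Requests beyond the rank are truncated with a
        warning.

    Raises
    ------
    DegenerateMatrixError
        For fewer than two rows or an all-constant (zero total variance)
        matrix.
    """
    X = _as_array(M)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError(f"expected a 2-D matrix with >=1 column, got {X.shape}")
    Xc, means = center_columns(X)

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s.size == 0 or s[0] <= 0 or not np.isfinite(s[0]):
        raise DegenerateMatrixError("matrix has zero total variance after centering")

    rank = int(np.sum(s > RANK_RTOL * s[0]))
    if n_components == "all":
        r = rank
    else:
        k = int(n_components)
        if k < 1:
            raise ValueError(f"n_components must be >= 1, got {k}")
        if k > rank:
            warnings.warn(
                f"requested {k} components but numerical rank is {rank}; "
                f"retaining {rank}",
                stacklevel=2,
            )
        r = min(k, rank)

    # deterministic sign: largest-|entry| coordinate of each component positive
    eig_full = s**2
    for i in range(r):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0

    ppv_full, cppv_full = proportion_of_variance(eig_full[:rank])

    eigenvalues = eig_full[:r]
    components = Vt[:r].copy()
    scores = U[:, :r] * s[:r]
    loadings = components * eigenvalues[:, None]
    contributions = scores**2 / eigenvalues

    return PCAResult(
        eigenvalues=eigenvalues,
        singular_values=s[:r].copy(),
        components=components,
        scores=scores,
        ppv=ppv_full[:r],
        cppv=cppv_full[:r],
        loadings=loadings,
        contributions=contributions,
        column_means=means,
        r=r,
    )


def loading_scores(result: PCAResult, component: int) -> np.ndarray:
    """Loading scores ``gamma_i = v_i * lambda_i`` for one component.

    The absolute-value ranking of variables is invariant to the per-component
    scalar, so selections built on ``|gamma|`` equal selections on ``|v|``.
    """
    if not 0 <= component < result.r:
        raise IndexError(
            f"component {component} out of range for {result.r} retained components"
        )
    return result.loadings[component]


def contribution_scores(result: PCAResult, component: int) -> np.ndarray:
    """Contribution of each row entity to one component.

    ``ctrib_{g,i} = f_{g,i}**2 / sum_g f_{g,i}**2``; entries lie in [0, 1]
    and sum to one.  The denominator equals ``lambda_i`` under the squared
    singular value convention.
    """
    if not 0 <= component < result.r:
        raise IndexError(
            f"component {component} out of range for {result.r} retained components"
        )
    s = result.singular_values[component]
    if s <= RANK_RTOL * result.singular_values[0]:
        raise ZeroDivisionError(
            f"component {component} has a numerically zero singular value"
        )
    return result.contributions[:, component]
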