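"""Two-phase principal feature selection.

The algorithm reduces a samples x genes expression matrix ``A`` to a small
set of informative genes in two PCA passes:

* **Phase 1 (sample domain).** PCA on ``A`` (genes are the variables).  For
  each of the top ``alpha`` components, genes are ranked by absolute loading
  score and the top ``beta`` fraction kept; the per-component gene sets are
  unioned.  Because ``A`` has few rows in the n << p regime, this pass is
  cheap and never touches a genes x genes covariance.
* **Phase 2 (gene domain).** The filtered matrix is transposed to genes x
  samples (``B``) and PCA is run again, now with genes as observations.  For
  each of the top ``alpha`` components, genes are ranked by contribution
  score (squared factor score over component eigenvalue) and the top ``tau``
  fraction kept, again unioned across components.

The whole procedure is unsupervised and fully deterministic: ties in any
score are broken by ascending original gene index.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matrix import ExpressionMatrix, Orientation
from .pca import PCAResult, pca

logger = logging.getLogger("bpfs")


@dataclass(frozen=True)
class BPFSConfig:
    """Selection parameters.

    Parameters
    ----------
    alpha:
        Number of top principal components used in each phase (default 1).
        With ``cpv_mode=True`` it is instead a cumulative-proportion-of-
        variance threshold in (0, 1] and the retained components are the
        smallest leading set whose cPPV reaches it.
    beta:
        Phase-1 per-component fraction of genes kept by |loading score|
        (default 0.08).
    tau:
        Phase-2 per-component fraction of genes kept by contribution score
        (default 0.01).
    """

    alpha: float = 1
    beta: float = 0.08
    tau: float = 0.01
    cpv_mode: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if not 0 < self.tau <= 1:
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")
        if self.cpv_mode:
            if not 0 < self.alpha <= 1:
                raise ValueError(
                    f"with cpv_mode, alpha is a cPPV threshold in (0, 1]; got {self.alpha}"
                )
        else:
            if self.alpha < 1 or self.alpha != int(self.alpha):
                raise ValueError(
                    f"alpha must be a positive integer count of PCs, got {self.alpha}"
                )
            object.__setattr__(self, "alpha", int(self.alpha))


@dataclass(frozen=True)
class SelectionResult:
    """Provenance of a selection run.

    ``final_genes`` is a subset of ``phase1_genes``, which is a subset of the
    input gene set; both lists follow the original input column order.
    ``per_pc_rankings`` maps ``"phase1"``/``"phase2"`` to one ranked gene-ID
    list per retained component (best first).
    """

    phase1_genes: tuple[str, ...]
    final_genes: tuple[str, ...]
    per_pc_rankings: Mapping[str, tuple[tuple[str, ...], ...]]
    config_used: BPFSConfig
    n_input_genes: int

    @property
    def n_phase1_genes(self) -> int:
        return len(self.phase1_genes)

    @property
    def n_final_genes(self) -> int:
        return len(self.final_genes)


def count_per_pc(fraction: float, n_items: int) -> int:
    """How many items a 'top fraction' keeps: ``max(1, floor(fraction * n))``.

    The floor rule reproduces the published gene counts: from 56,309 genes,
    beta=0.08 keeps 4,504 and tau=0.01 then keeps 45.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    return max(1, math.floor(fraction * n_items))


def _n_components_for(config: BPFSConfig, result_rank_hint: int | None = None) -> int | str:
    # cpv_mode needs the full spectrum to evaluate the cumulative threshold
    return "all" if config.cpv_mode else int(config.alpha)


def _select_pcs(result: PCAResult, config: BPFSConfig) -> list[int]:
    """Indices of the retained components under either alpha semantics."""
    if config.cpv_mode:
        k = int(np.searchsorted(result.cppv, config.alpha - 1e-12) + 1)
        k = min(k, result.r)
        return list(range(k))
    k = int(config.alpha)
    if k > result.r:
        warnings.warn(
            f"alpha={k} exceeds the {result.r} available components; using {result.r}",
            stacklevel=3,
        )
        k = result.r
    return list(range(k))


def _rank_items(scores: np.ndarray) -> np.ndarray:
    """Indices sorted by score descending, ties by ascending original index."""
    return np.lexsort((np.arange(scores.size), -scores))


def _union_top(
    per_pc_scores: Sequence[np.ndarray], count: int, ids: Sequence[str]
) -> tuple[list[str], tuple[tuple[str, ...], ...]]:
    keep = np.zeros(len(ids), dtype=bool)
    rankings = []
    for scores in per_pc_scores:
        order = _rank_items(scores)
        rankings.append(tuple(ids[j] for j in order))
        keep[order[:count]] = True
    kept = [ids[j] for j in range(len(ids)) if keep[j]]  # original order
    return kept, tuple(rankings)


def phase1_select(
    A: ExpressionMatrix, config: BPFSConfig
) -> tuple[list[str], tuple[tuple[str, ...], ...]]:
    """Sample-domain pass: keep genes with top |loading scores|.

    PCA runs on ``A`` (samples on rows); for each retained component the top
    ``count_per_pc(beta, n_genes)`` genes by absolute loading are kept and
    the per-component sets unioned.  Returns the kept gene IDs in original
    column order plus the full per-component rankings.
    """
    if A.orientation is not Orientation.SAMPLES_BY_GENES:
        raise ValueError("phase 1 expects a samples_by_genes matrix")
    if A.n_rows < 3 or A.n_cols < 2:
        raise ValueError(
            f"phase 1 needs >=3 samples and >=2 genes; got {A.shape}"
        )
    result = pca(A, _n_components_for(config))
    pcs = _select_pcs(result, config)
    count = count_per_pc(config.beta, A.n_cols)
    scores = [np.abs(result.loadings[i]) for i in pcs]
    kept, rankings = _union_top(scores, count, A.col_ids)
    logger.info("phase 1 kept %d of %d genes (%d PCs)", len(kept), A.n_cols, len(pcs))
    return kept, rankings


def filter_and_transpose(
    M: ExpressionMatrix, genes: Sequence[str]
) -> ExpressionMatrix:
    """Keep the named gene columns and flip to genes x samples."""
    if not genes:
        raise ValueError("gene set must be nonempty")
    if M.orientation is not Orientation.SAMPLES_BY_GENES:
        raise ValueError("expected a samples_by_genes matrix")
    return M.subset_columns(genes).transpose()


def phase2_select(
    B: ExpressionMatrix, config: BPFSConfig, n_keep: int | None = None
) -> tuple[list[str], tuple[tuple[str, ...], ...]]:
    """Gene-domain pass: keep genes with top contribution scores.

    PCA runs on ``B`` (genes on rows, samples the centered variables); for
    each retained component the top ``count_per_pc(tau, n_genes)`` genes by
    contribution score are kept, unioned across components.
    """
    if B.orientation is not Orientation.GENES_BY_SAMPLES:
        raise ValueError("phase 2 expects a genes_by_samples matrix")
    if B.n_rows < 2 or B.n_cols < 3:
        raise ValueError(
            f"phase 2 needs >=2 genes and >=3 samples; got {B.shape}"
        )
    result = pca(B, _n_components_for(config))
    pcs = _select_pcs(result, config)
    count = n_keep if n_keep is not None else count_per_pc(config.tau, B.n_rows)
    scores = [result.contributions[:, i] for i in pcs]
    kept, rankings = _union_top(scores, count, B.row_ids)
    logger.info("phase 2 kept %d of %d genes (%d PCs)", len(kept), B.n_rows, len(pcs))
    return kept, rankings


def run_bpfs(
    A: ExpressionMatrix,
    config: BPFSConfig | None = None,
    phase1_only: bool = False,
) -> tuple[ExpressionMatrix, SelectionResult]:
    """Run the full two-phase selection on a samples x genes matrix.

    Returns the reduced samples x genes matrix ``C`` (values copied from
    ``A``, columns restricted to the final gene set) and a
    :class:`SelectionResult` with full provenance.  ``phase1_only=True``
    skips the gene-domain pass (the ablation variant), in which case the
    final set equals the phase-1 set.

    The run is deterministic: no randomness enters either phase.
    """
    config = config or BPFSConfig()
    phase1, rank1 = phase1_select(A, config)

    rank2: tuple[tuple[str, ...], ...] = ()
    if phase1_only:
        final = list(phase1)
    elif len(phase1) < 2:
        logger.warning(
            "phase 1 kept a single gene; gene-domain PCA is undefined, "
            "returning the phase-1 set"
        )
        final = list(phase1)
    else:
        B = filter_and_transpose(A, phase1)
        final, rank2 = phase2_select(B, config)

    C = A.subset_columns(final)
    result = SelectionResult(
        phase1_genes=tuple(phase1),
        final_genes=tuple(final),
        per_pc_rankings={"phase1": rank1, "phase2": rank2},
        config_used=config,
        n_input_genes=A.n_cols,
    )
    return C, result
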