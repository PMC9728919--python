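"""Synthetic expression data with planted class signal.

The generator emulates the statistical regime of bulk cancer-vs-normal TPM
matrices: far fewer samples than genes, a strong class imbalance (about 1:9
normal to cancer by default), a minority of class-informative genes, blocks
of redundant genes correlated with an informative anchor, and a majority of
class-independent noise genes.

Model, on the log2 scale: every gene has a baseline level drawn from
``Normal(baseline_mean, baseline_sd)``; a sample's log2 expression is the
baseline plus ``Normal(0, sample_sd)`` measurement spread.  Informative
genes gain ``effect_size`` log2 units in the cancer class.  Each redundant
block gene copies its anchor's per-sample values plus ``Normal(0, noise_sd)``
jitter, inducing strong within-block correlation.  Values are exponentiated
(``2**x``) to a non-negative TPM-like scale, reproducing the right-skew and
the wide dynamic range that the selection algorithm sees on real data.

What it deliberately does not model: RNA-seq count overdispersion, batch
effects and library-size artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .evaluate import LabelVector
from .matrix import ExpressionMatrix, Orientation
from .select import SelectionResult


@dataclass(frozen=True)
class SyntheticDataset:
    """A planted-signal dataset plus its ground truth.

    ``informative_genes`` are the anchors that separate the classes;
    ``redundant_blocks`` holds, per anchor, the IDs of its correlated
    copies.  All remaining genes are class-independent noise.
    """

    matrix: ExpressionMatrix
    labels: LabelVector
    informative_genes: tuple[str, ...]
    redundant_blocks: tuple[tuple[str, ...], ...]
    seed: int

    @property
    def planted_genes(self) -> frozenset[str]:
        """Informative anchors plus all redundant-block members."""
        planted = set(self.informative_genes)
        for block in self.redundant_blocks:
            planted.update(block)
        return frozenset(planted)

    @property
    def noise_genes(self) -> frozenset[str]:
        return frozenset(self.matrix.gene_ids) - self.planted_genes

    def gene_groups(self) -> tuple[frozenset[str], ...]:
        """Anchor-plus-block groups (the units of redundancy)."""
        return tuple(
            frozenset({anchor, *block})
            for anchor, block in zip(self.informative_genes, self.redundant_blocks)
        )


def generate(
    n_samples_per_class: tuple[int, int] = (50, 450),
    n_genes: int = 2000,
    n_informative: int = 20,
    block_size: int = 4,
    effect_size: float = 3.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    baseline_mean: float = 4.0,
    baseline_sd: float = 1.0,
    sample_sd: float = 1.0,
) -> SyntheticDataset:
    """Generate a planted-signal expression dataset.

    Parameters
    ----------
    n_samples_per_class:
        ``(n_normal, n_cancer)``; the default 50/450 mirrors the ~1:9
        imbalance of public cancer cohorts.
    n_genes, n_informative, block_size:
        Total genes, number of informative anchors, and redundant copies per
        anchor.  Requires ``n_informative * (1 + block_size) <= n_genes``.
    effect_size:
        Log2-unit mean shift of informative genes in the cancer class
        (3 = an eight-fold change, a strong but realistic cancer signal).
    noise_sd:
        Log2 sd of the jitter separating a block gene from its anchor.
    baseline_mean, baseline_sd:
        Per-gene baseline log2-TPM distribution.
    sample_sd:
        Log2 sd of per-sample biological/technical spread within a gene.

    The same seed regenerates the matrix bit-identically.
    """
    n_normal, n_cancer = n_samples_per_class
    if min(n_normal, n_cancer, n_genes, n_informative, block_size) < 1:
        raise ValueError("all counts must be positive")
    if n_informative * (1 + block_size) > n_genes:
        raise ValueError(
            f"{n_informative} informative genes with blocks of {block_size} "
            f"need {n_informative * (1 + block_size)} genes; only {n_genes} available"
        )

    rng = np.random.default_rng(seed)
    n_samples = n_normal + n_cancer
    labels = np.concatenate([np.zeros(n_normal, int), np.ones(n_cancer, int)])

    # scatter the planted genes across the column order
    perm = rng.permutation(n_genes)
    anchors = perm[:n_informative]
    block_cols = perm[n_informative : n_informative * (1 + block_size)].reshape(
        n_informative, block_size
    )

    baseline = rng.normal(baseline_mean, baseline_sd, n_genes)
    log2x = baseline[None, :] + rng.normal(0.0, sample_sd, (n_samples, n_genes))
    log2x[np.ix_(labels == 1, anchors)] += effect_size
    for a, block in zip(anchors, block_cols):
        log2x[:, block] = log2x[:, [a]] + rng.normal(
            0.0, noise_sd, (n_samples, block_size)
        )

    gene_ids = tuple(f"G{j:05d}" for j in range(n_genes))
    sample_ids = tuple(
        f"N{i:04d}" if labels[i] == 0 else f"T{i:04d}" for i in range(n_samples)
    )
    matrix = ExpressionMatrix(
        values=np.exp2(log2x),
        row_ids=sample_ids,
        col_ids=gene_ids,
        orientation=Orientation.SAMPLES_BY_GENES,
    )
    return SyntheticDataset(
        matrix=matrix,
        labels=LabelVector(sample_ids=sample_ids, labels=labels),
        informative_genes=tuple(gene_ids[a] for a in anchors),
        redundant_blocks=tuple(
            tuple(gene_ids[j] for j in block) for block in block_cols
        ),
        seed=seed,
    )


def recovery_score(
    selection: SelectionResult | Sequence[str], truth: SyntheticDataset
) -> float:
    """Fraction of the selected genes that are planted (anchor or block member)."""
    genes = (
        selection.final_genes
        if isinstance(selection, SelectionResult)
        else tuple(selection)
    )
    unknown = set(genes) - set(truth.matrix.gene_ids)
    if unknown:
        raise KeyError(f"selected genes absent from the dataset: {sorted(unknown)[:10]}")
    if not genes:
        raise ValueError("empty selection")
    planted = truth.planted_genes
    return sum(g in planted for g in genes) / len(genes)


def enrichment_pvalue(
    selection: SelectionResult | Sequence[str], truth: SyntheticDataset
) -> float:
    """Hypergeometric tail probability of the observed planted-gene overlap.

    Probability that a uniform random draw of the same size from the gene
    domain contains at least as many planted genes as the selection did.
    """
    genes = (
        selection.final_genes
        if isinstance(selection, SelectionResult)
        else tuple(selection)
    )
    n_total = len(truth.matrix.gene_ids)
    n_planted = len(truth.planted_genes)
    k = round(recovery_score(genes, truth) * len(genes))
    return float(hypergeom.sf(k - 1, n_total, n_planted, len(genes)))


def same_block_duplicates(
    genes: Sequence[str], truth: SyntheticDataset
) -> int:
    """Number of redundant picks: selected genes beyond one per anchor group."""
    gene_set = set(genes)
    return sum(
        max(0, len(group & gene_set) - 1) for group in truth.gene_groups()
    )
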