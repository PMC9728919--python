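"""Labelled expression matrices.

A gene expression matrix carries non-negative, TPM-normalised expression
values together with sample and gene identifiers.  The two-phase selection
algorithm works with both orientations of the same data — samples on rows
for the sample-domain pass and genes on rows for the gene-domain pass — so
the orientation is tracked explicitly and flipped by :meth:`ExpressionMatrix.transpose`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np


class Orientation(str, enum.Enum):
    """Which entity sits on the rows of the matrix."""

    SAMPLES_BY_GENES = "samples_by_genes"
    GENES_BY_SAMPLES = "genes_by_samples"

    def flipped(self) -> "Orientation":
        if self is Orientation.SAMPLES_BY_GENES:
            return Orientation.GENES_BY_SAMPLES
        return Orientation.SAMPLES_BY_GENES


def _check_ids(ids: Sequence[str], n: int, axis: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(ids) != n:
        raise ValueError(f"{axis} has {n} entries but {len(ids)} IDs were given")
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {axis} IDs: {dupes[:10]}")
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """A 2-D labelled numeric matrix with declared orientation.

    Parameters
    ----------
    values:
        2-D float array; must be free of NaN/inf.
    row_ids, col_ids:
        Unique identifiers for rows and columns, in matrix order.
    orientation:
        Whether rows are samples (``samples_by_genes``) or genes
        (``genes_by_samples``).
    """

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    orientation: Orientation = Orientation.SAMPLES_BY_GENES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"matrix contains a non-finite entry at row {bad[0]}, column {bad[1]}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "row_ids", _check_ids(self.row_ids, values.shape[0], "row")
        )
        object.__setattr__(
            self, "col_ids", _check_ids(self.col_ids, values.shape[1], "column")
        )
        object.__setattr__(self, "orientation", Orientation(self.orientation))

    # -- basic geometry ----------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def transpose(self) -> "ExpressionMatrix":
        """Swap rows and columns, IDs and orientation together."""
        return ExpressionMatrix(
            values=self.values.T.copy(),
            row_ids=self.col_ids,
            col_ids=self.row_ids,
            orientation=self.orientation.flipped(),
        )

    # -- ID-aware accessors ------------------------------------------------

    @property
    def sample_ids(self) -> tuple[str, ...]:
        if self.orientation is Orientation.SAMPLES_BY_GENES:
            return self.row_ids
        return self.col_ids

    @property
    def gene_ids(self) -> tuple[str, ...]:
        if self.orientation is Orientation.SAMPLES_BY_GENES:
            return self.col_ids
        return self.row_ids

    def subset_columns(self, ids: Iterable[str]) -> "ExpressionMatrix":
        """Keep the named columns, preserving original column order."""
        wanted = set(ids)
        unknown = wanted - set(self.col_ids)
        if unknown:
            raise KeyError(f"unknown column IDs: {sorted(unknown)[:10]}")
        idx = [j for j, c in enumerate(self.col_ids) if c in wanted]
        return ExpressionMatrix(
            values=self.values[:, idx].copy(),
            row_ids=self.row_ids,
            col_ids=tuple(self.col_ids[j] for j in idx),
            orientation=self.orientation,
        )

    def subset_rows(self, ids: Iterable[str]) -> "ExpressionMatrix":
        """Keep the named rows, preserving original row order."""
        wanted = set(ids)
        unknown = wanted - set(self.row_ids)
        if unknown:
            raise KeyError(f"unknown row IDs: {sorted(unknown)[:10]}")
        idx = [i for i, r in enumerate(self.row_ids) if r in wanted]
        return ExpressionMatrix(
            values=self.values[idx, :].copy(),
            row_ids=tuple(self.row_ids[i] for i in idx),
            col_ids=self.col_ids,
            orientation=self.orientation,
        )
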