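"""Reading and writing expression matrices, labels, gene lists and reports.

Expression matrices are delimited text (TSV or CSV, inferred from the file
extension) with row IDs in the first column and column IDs in the header.
Labels are a two-column table of sample ID and class, where the class may be
``0``/``1`` or ``normal``/``cancer``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .evaluate import ConfusionCounts, LabelVector, MetricsReport
from .matrix import ExpressionMatrix, Orientation
from .select import SelectionResult

LABEL_CODES = {"0": 0, "1": 1, "normal": 0, "cancer": 1}


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    orientation: Orientation | str = Orientation.SAMPLES_BY_GENES,
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression matrix with IDs on the first row/column.

    Duplicate IDs, missing values and non-numeric cells are rejected with
    the offending location named.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    # pandas silently renames duplicate header fields, so inspect them raw
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)[1:]
    if len(set(header)) != len(header):
        seen: set[str] = set()
        dupes = sorted({c for c in header if c in seen or seen.add(c)})
        raise ValueError(f"{path}: duplicate column IDs {dupes[:10]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row IDs {dupes[:10]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column IDs {dupes[:10]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: missing or non-numeric value at row '{df.index[i]}', "
            f"column '{df.columns[j]}'"
        )
    return ExpressionMatrix(
        values=numeric.to_numpy(dtype=float),
        row_ids=tuple(map(str, df.index)),
        col_ids=tuple(map(str, df.columns)),
        orientation=Orientation(orientation),
    )


def write_expression(
    M: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.DataFrame(M.values, index=list(M.row_ids), columns=list(M.col_ids))
    df.to_csv(path, sep=sep)


def read_labels(path: str | Path, delimiter: str | None = None) -> LabelVector:
    """Read a two-column sample-ID/label table; a header row is optional."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
    # tolerate a header row such as "sample_id<tab>label"
    if len(df) > 1 and str(df.iloc[0, 1]).strip().lower() not in LABEL_CODES:
        df = df.iloc[1:]
    ids, codes = [], []
    for _, (sid, raw) in df.iterrows():
        key = str(raw).strip().lower()
        if key not in LABEL_CODES:
            raise ValueError(
                f"{path}: unrecognised label '{raw}' for sample '{sid}' "
                f"(expected 0/1 or normal/cancer)"
            )
        ids.append(str(sid).strip())
        codes.append(LABEL_CODES[key])
    return LabelVector(sample_ids=tuple(ids), labels=np.array(codes, dtype=int))


def write_labels(y: LabelVector, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path, "w") as fh:
        for sid, lab in zip(y.sample_ids, y.labels):
            fh.write(f"{sid}{sep}{int(lab)}\n")


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path: str | Path) -> tuple[str, ...]:
    with open(path) as fh:
        return tuple(line.strip() for line in fh if line.strip())


def metrics_to_json(
    report: MetricsReport,
    confusion: ConfusionCounts | None = None,
    ndigits: int = 4,
) -> dict:
    """Flatten a metrics report (and optional confusion counts) to JSON-able form."""
    doc: dict = report.as_dict(ndigits=ndigits)
    if report.warnings:
        doc["zero_denominator_metrics"] = list(report.warnings)
    if confusion is not None:
        doc.update(
            tp=confusion.tp, fp=confusion.fp, tn=confusion.tn, fn=confusion.fn
        )
    return doc


def write_outputs(
    result: SelectionResult,
    C: ExpressionMatrix,
    report: MetricsReport | None = None,
    confusion: ConfusionCounts | None = None,
    out_genes: str | Path | None = None,
    out_matrix: str | Path | None = None,
    out_metrics: str | Path | None = None,
    out_manifest: str | Path | None = None,
    seed: int | None = None,
) -> None:
    """Write the selection artifacts: gene list, reduced matrix, metrics, manifest."""
    if out_genes is not None:
        write_gene_list(result.final_genes, out_genes)
    if out_matrix is not None:
        write_expression(C, out_matrix)
    if out_metrics is not None and report is not None:
        with open(out_metrics, "w") as fh:
            json.dump(metrics_to_json(report, confusion), fh, indent=2)
            fh.write("\n")
    if out_manifest is not None:
        manifest = {
            "config": dataclasses.asdict(result.config_used),
            "seed": seed,
            "n_input_genes": result.n_input_genes,
            "n_phase1_genes": result.n_phase1_genes,
            "n_final_genes": result.n_final_genes,
            "final_genes": list(result.final_genes),
        }
        with open(out_manifest, "w") as fh:
            json.dump(manifest, fh, indent=2)
            fh.write("\n")
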