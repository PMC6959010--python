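"""Expression-matrix input/output, probeset collapsing and qPCR quantification.

Matrices are feature x sample tables on a log2 (microarray/RMA-style) or FPKM
scale. TSV is the primary on-disk dialect: header row of sample ids, first
column feature ids. FPKM inputs can be brought onto a log2 scale with
``log2(FPKM + 1)`` so that correlation-based scoring sees comparable values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ExpressionParseError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "collapse_to_genes",
    "delta_delta_ct",
]


@dataclass
class ExpressionMatrix:
    """A feature x sample expression table.

    Parameters
    ----------
    values
        DataFrame indexed by feature id (probeset or gene symbol) with one
        column per sample. Values are log2-scale intensities or FPKM.
    scale
        ``"log2"`` or ``"fpkm"``.
    gene_symbols
        Optional feature_id -> gene symbol mapping for probeset-level data.
    """

    values: pd.DataFrame
    scale: str = "log2"
    gene_symbols: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "fpkm"):
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ExpressionParseError(f"duplicate feature ids: {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ExpressionParseError(f"duplicate sample ids: {dupes}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2-scale matrix; FPKM values become log2(FPKM + 1)."""
        if self.scale == "log2":
            return self
        vals = np.log2(self.values + 1.0)
        return ExpressionMatrix(vals, scale="log2", gene_symbols=self.gene_symbols)


def read_expression(
    path,
    sep: str = "\t",
    scale: str = "log2",
    log_transform_fpkm: bool = False,
) -> ExpressionMatrix:
    """Read an expression table (first column feature ids, header sample ids).

    Raises :class:`ExpressionParseError` naming the offending row/column for
    ragged rows, duplicate ids or non-numeric cells.
    """
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    dupes = []
    for sample_id in header:
        if sample_id in seen:
            dupes.append(sample_id)
        seen.add(sample_id)
    if dupes:
        raise ExpressionParseError(f"{path}: duplicate sample ids in header: {dupes}")
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                          on_bad_lines="error", skip_blank_lines=True)
    except pd.errors.ParserError as exc:  # ragged rows
        raise ExpressionParseError(f"{path}: {exc}") from exc
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ExpressionParseError(f"{path}: duplicate feature ids: {dupes}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ExpressionParseError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at feature "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ExpressionParseError(
            f"{path}: missing value at feature {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    mat = ExpressionMatrix(numeric.astype(float), scale=scale)
    if scale == "fpkm" and log_transform_fpkm:
        mat = mat.to_log2()
    return mat


def write_expression(matrix: ExpressionMatrix, path, sep: str = "\t") -> None:
    """Write the matrix in the same dialect :func:`read_expression` consumes."""
    matrix.values.to_csv(path, sep=sep, index_label="feature_id")


def collapse_to_genes(
    matrix: ExpressionMatrix,
    mapping: Mapping[str, str],
    rule: str = "max_variance",
) -> ExpressionMatrix:
    """Collapse probeset rows to one row per gene symbol.

    ``rule="max_variance"`` (the default convention) keeps, for each gene, the
    probeset with maximal variance across samples; ``rule="mean"`` averages
    probesets.
    """
    present = [f for f in matrix.feature_ids if f in mapping]
    if not present:
        raise ValidationError("mapping shares no features with the matrix")
    sub = matrix.values.loc[present]
    symbols = pd.Series([mapping[f] for f in present], index=sub.index)
    if rule == "max_variance":
        variances = sub.var(axis=1, ddof=1).fillna(0.0)
        keep = variances.groupby(symbols).idxmax()
        out = sub.loc[keep.to_numpy()]
        out.index = keep.index
        out = out.sort_index()
    elif rule == "mean":
        out = sub.groupby(symbols).mean().sort_index()
    else:
        raise ValidationError(f"unknown collapse rule {rule!r}")
    return ExpressionMatrix(out, scale=matrix.scale)


def delta_delta_ct(
    ct_target,
    ct_reference,
    calibrator_ct_target,
    calibrator_ct_reference,
):
    """Relative expression fold by the delta-delta-Ct method.

    Returns ``2**(-ddCt)`` with
    ``ddCt = (ct_target - ct_reference) - (calibrator_ct_target - calibrator_ct_reference)``.
    The reference is the endogenous control gene (e.g. GAPDH); the calibrator
    is the baseline condition.
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    cal_t = np.asarray(calibrator_ct_target, dtype=float)
    cal_r = np.asarray(calibrator_ct_reference, dtype=float)
    for name, arr in (("ct_target", ct_target), ("ct_reference", ct_reference),
                      ("calibrator_ct_target", cal_t), ("calibrator_ct_reference", cal_r)):
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"{name} contains non-finite Ct values")
    ddct = (ct_target - ct_reference) - (cal_t - cal_r)
    out = np.power(2.0, -ddct)
    return float(out) if out.ndim == 0 else out
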