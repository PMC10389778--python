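"""Unit conversions between counts, FPKM, TPM and CPM.

All conversions are per-sample (column-wise) closed forms:

* ``CPM_i  = counts_i / sum(counts) * 1e6``
* ``FPKM_i = counts_i * 1e9 / (sum(counts) * length_i)``
* ``TPM_i  = FPKM_i / sum(FPKM) * 1e6``

TPM columns therefore always sum to one million.  A pseudocounted
log2 group-mean helper feeds the fold-change computation downstream:
fold changes are taken on group means, not on per-replicate logs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import PER_MILLION, ExpressionMatrix


def _column(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if (arr < 0).any():
        raise ValueError(f"{name} contains negative values")
    return arr


def fpkm_to_tpm(fpkm_column) -> np.ndarray:
    """Rescale one sample's FPKM values so they sum to 1e6."""
    fpkm = _column(fpkm_column, "fpkm_column")
    total = fpkm.sum()
    if total <= 0:
        raise ValueError("all-zero FPKM column: TPM transform is undefined")
    return fpkm / total * PER_MILLION


def counts_to_cpm(count_column) -> np.ndarray:
    """Counts per million for one sample."""
    counts = _column(count_column, "count_column")
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero library size: CPM is undefined")
    return counts / total * PER_MILLION


def counts_to_fpkm(count_column, gene_lengths_bp) -> np.ndarray:
    """Fragments per kilobase per million mapped reads for one sample."""
    counts = _column(count_column, "count_column")
    lengths = np.asarray(gene_lengths_bp, dtype=float)
    if lengths.shape != counts.shape:
        raise ValueError("gene_lengths_bp must match count_column in length")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero library size: FPKM is undefined")
    return counts * 1.0e9 / (total * lengths)


_CONVERSIONS = {
    ("counts", "cpm"),
    ("counts", "fpkm"),
    ("counts", "tpm"),
    ("fpkm", "tpm"),
}


def to_unit(matrix: ExpressionMatrix, unit: str) -> ExpressionMatrix:
    """Convert a whole matrix to another unit, column by column.

    Supported directions: counts -> {cpm, fpkm, tpm} and fpkm -> tpm.
    Converting to the matrix's own unit returns a copy.
    """
    if unit == matrix.unit:
        return ExpressionMatrix(
            matrix.values.copy(),
            unit=unit,
            gene_lengths_bp=matrix.gene_lengths_bp,
            design=matrix.design,
        )
    if (matrix.unit, unit) not in _CONVERSIONS:
        raise ValueError(f"cannot convert {matrix.unit!r} to {unit!r}")
    if unit in ("fpkm", "tpm") and matrix.unit == "counts" and matrix.gene_lengths_bp is None:
        raise ValueError("gene lengths are required for counts -> FPKM/TPM")

    arr = matrix.values.to_numpy(dtype=float)
    out = np.empty_like(arr)
    lengths = None
    if matrix.gene_lengths_bp is not None:
        lengths = matrix.gene_lengths_bp.to_numpy(dtype=float)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if matrix.unit == "counts":
            if unit == "cpm":
                out[:, j] = counts_to_cpm(col)
            else:
                fpkm = counts_to_fpkm(col, lengths)
                out[:, j] = fpkm if unit == "fpkm" else fpkm_to_tpm(fpkm)
        else:  # fpkm -> tpm
            out[:, j] = fpkm_to_tpm(col)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, unit=unit, gene_lengths_bp=matrix.gene_lengths_bp, design=matrix.design)


def log2_mean_expression(
    matrix: ExpressionMatrix,
    group: tuple[str, str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """``log2(mean over the group's replicates + pseudocount)`` per gene."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    background, condition = group
    values = matrix.group_values(background, condition)
    return np.log2(values.mean(axis=1) + pseudocount)
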