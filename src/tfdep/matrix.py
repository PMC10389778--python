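"""Expression matrices, sample designs, and plain-text round-tripping.

The containers here are deliberately thin wrappers around pandas objects:
an :class:`ExpressionMatrix` is a genes x samples table tagged with its
unit (counts, FPKM, TPM or CPM), optional per-gene lengths, and a
:class:`SampleDesign` mapping each sample to a (background, condition,
replicate) cell of the two-genotype, two-condition experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNITS = ("counts", "fpkm", "tpm", "cpm")

#: column total that defines the TPM (and CPM) scale
PER_MILLION = 1.0e6

#: relative tolerance used when validating that TPM columns sum to 1e6
TPM_RTOL = 1.0e-6

DESIGN_COLUMNS = ("sample_id", "background", "condition", "replicate")


def _unique_in_order(values) -> list:
    seen = set()
    out = []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


@dataclass
class SampleDesign:
    """Assignment of samples to experimental groups.

    The underlying table has one row per sample with columns
    ``sample_id``, ``background`` (genetic context, e.g. WT vs KO),
    ``condition`` (e.g. unstimulated vs stimulated) and ``replicate``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(DESIGN_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"sample design is missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids in design: {sorted(set(dupes))}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def backgrounds(self) -> list[str]:
        return _unique_in_order(self.table["background"])

    @property
    def conditions(self) -> list[str]:
        return _unique_in_order(self.table["condition"])

    def samples(self, background: str | None = None, condition: str | None = None) -> list[str]:
        """Sample ids of one (background, condition) group, in design order."""
        t = self.table
        if background is not None:
            t = t[t["background"] == background]
        if condition is not None:
            t = t[t["condition"] == condition]
        return list(t["sample_id"])

    def write_tsv(self, path: str | Path) -> None:
        self.table.loc[:, list(DESIGN_COLUMNS)].to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with a unit tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample.  All values
        must be finite and non-negative.
    unit
        One of ``counts``, ``fpkm``, ``tpm`` or ``cpm``.
    gene_lengths_bp
        Optional per-gene lengths (bp), required for FPKM/TPM conversion
        from counts.
    design
        Optional sample design; if given, its samples must be exactly the
        matrix columns.
    """

    values: pd.DataFrame
    unit: str = "counts"
    gene_lengths_bp: pd.Series | None = None
    design: SampleDesign | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values")
        if (arr < 0).any():
            raise ValueError("expression matrix contains negative values")
        if self.unit == "tpm" and arr.size:
            sums = arr.sum(axis=0)
            if not np.allclose(sums, PER_MILLION, rtol=TPM_RTOL):
                raise ValueError("TPM columns must each sum to 1e6")
        if self.gene_lengths_bp is not None:
            lengths = self.gene_lengths_bp.reindex(self.values.index)
            if lengths.isna().any():
                missing = list(self.values.index[lengths.isna()])[:5]
                raise ValueError(f"gene lengths missing for genes such as {missing}")
            if (lengths <= 0).any():
                raise ValueError("gene lengths must be positive")
            self.gene_lengths_bp = lengths
        if self.design is not None:
            design_samples = set(self.design.sample_ids)
            matrix_samples = set(self.values.columns)
            if design_samples != matrix_samples:
                raise ValueError(
                    "design samples and matrix columns differ: "
                    f"{sorted(design_samples ^ matrix_samples)}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def group_values(self, background: str, condition: str) -> pd.DataFrame:
        """Sub-matrix of the replicates of one (background, condition) group."""
        if self.design is None:
            raise ValueError("matrix has no sample design attached")
        samples = self.design.samples(background, condition)
        if not samples:
            raise ValueError(f"no samples for group ({background!r}, {condition!r})")
        return self.values.loc[:, samples]


def _meta_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path, *, sidecar: bool = True) -> None:
    """Write a matrix as TSV (first column ``gene_id``) plus a unit sidecar.

    Values are written with ``repr`` precision so that write-then-read
    round-trips bit-exactly.
    """
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    if sidecar:
        _meta_path(path).write_text(json.dumps({"unit": matrix.unit}) + "\n")


def read_expression_tsv(
    path: str | Path,
    *,
    unit: str | None = None,
    design: SampleDesign | None = None,
    gene_lengths_bp: pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression table.

    The unit is taken from the explicit argument, falling back to the
    ``<path>.meta.json`` sidecar, falling back to ``counts``.
    """
    if unit is None:
        meta = _meta_path(path)
        unit = json.loads(meta.read_text())["unit"] if meta.exists() else "counts"
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    values.index = values.index.astype(str)
    return ExpressionMatrix(values, unit=unit, gene_lengths_bp=gene_lengths_bp, design=design)


def write_gene_lengths_tsv(lengths: pd.Series, path: str | Path) -> None:
    frame = lengths.rename("length_bp").rename_axis("gene_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_gene_lengths_tsv(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return frame.set_index("gene_id")["length_bp"]
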