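"""Per-background induction statistics and threshold classification.

For each background the stimulated group is compared with the
unstimulated group gene by gene:

* the induction log2 fold change is taken on pseudocounted group means,
  ``log2((mean_stim + c) / (mean_unstim + c))``;
* a two-sided Welch t-test on ``log2(normalized value + c)`` per
  replicate gives the p-value (this is the package's own, transparent
  differential-expression statistic -- it is *not* a reimplementation of
  limma or DESeq moderated tests and will not reproduce their numbers);
* Benjamini-Hochberg adjustment across the tested genes;
* classification against linear fold-change thresholds: ``up`` when the
  fold change is at least ``up_fc`` and adj-p < alpha, ``down`` when at
  most ``down_fc`` and adj-p < alpha, ``ns`` otherwise.

Degenerate replicate structure (fewer than two replicates, or zero
variance in both groups, as happens in the simulator's noise-free mode)
is resolved by convention rather than error: p = 1 when the group means
are equal, p = 0 when zero-variance groups have different means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NS = "ns"

DE_COLUMNS = ("gene_id", "log2fc", "p_value", "adj_p", "status")


@dataclass(frozen=True)
class ThresholdConfig:
    """Linear-scale fold-change thresholds and the significance level.

    The defaults (2, 0.5, 0.05) select two-fold induced/repressed genes;
    :meth:`dysregulation` gives the laxer (1.5, 0.66) preset used when
    scoring knockout-dysregulated genes.
    """

    up_fc: float = 2.0
    down_fc: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.up_fc > 1.0:
            raise ValueError("up_fc must be > 1")
        if not 0.0 < self.down_fc < 1.0:
            raise ValueError("down_fc must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def dysregulation(cls) -> "ThresholdConfig":
        return cls(up_fc=1.5, down_fc=0.66, alpha=0.05)

    @property
    def log2_up(self) -> float:
        return float(np.log2(self.up_fc))

    @property
    def log2_down(self) -> float:
        return float(np.log2(self.down_fc))


def log2_fold_change(mean_stim, mean_unstim, pseudocount: float = 1.0):
    """Pseudocounted log2 ratio of group means; scalar or vectorized."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    stim = np.asarray(mean_stim, dtype=float)
    unstim = np.asarray(mean_unstim, dtype=float)
    out = np.log2((stim + pseudocount) / (unstim + pseudocount))
    return float(out) if out.ndim == 0 else out


def _welch_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    """Row-wise two-sided Welch p-values with explicit degenerate handling.

    Returns the p-values and the number of rows that could not be tested
    (fewer than two replicates in a group), for which p is set to 1.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n_rows = a.shape[0]
    p = np.ones(n_rows)
    if a.shape[1] < 2 or b.shape[1] < 2:
        return p, n_rows

    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    means_equal = np.isclose(a.mean(axis=1), b.mean(axis=1), rtol=0.0, atol=0.0)
    degenerate = (va == 0) & (vb == 0)
    regular = ~degenerate
    if regular.any():
        with warnings.catch_warnings():
            # near-identical replicate rows trigger scipy precision-loss chatter
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(a[regular], b[regular], axis=1, equal_var=False)
        p[regular] = res.pvalue
    p[degenerate & means_equal] = 1.0
    p[degenerate & ~means_equal] = 0.0
    return p, 0


def two_group_test(values_stim, values_unstim) -> float:
    """Two-sided Welch t-test p-value for one gene (symmetric in group order)."""
    a = np.asarray(values_stim, dtype=float)[None, :]
    b = np.asarray(values_unstim, dtype=float)[None, :]
    p, n_warn = _welch_rows(a, b)
    if n_warn:
        log.warning("fewer than two replicates in a group; p-value set to 1")
    return float(p[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_induction(records: pd.DataFrame, thresholds: ThresholdConfig | None = None) -> pd.DataFrame:
    """Assign up/down/ns status from ``log2fc`` and ``adj_p`` columns."""
    thresholds = thresholds or ThresholdConfig()
    records = records.copy()
    significant = records["adj_p"] < thresholds.alpha
    status = np.full(len(records), NS, dtype=object)
    status[significant & (records["log2fc"] >= thresholds.log2_up)] = UP
    status[significant & (records["log2fc"] <= thresholds.log2_down)] = DOWN
    records["status"] = status
    return records


def test_induction(
    matrix: ExpressionMatrix,
    background: str,
    *,
    thresholds: ThresholdConfig | None = None,
    pseudocount: float = 1.0,
    min_expression: float | None = 1.0,
    stimulated: str = "stimulated",
    unstimulated: str = "unstimulated",
) -> pd.DataFrame:
    """Full induction table for one background.

    ``min_expression`` drops genes whose mean normalized value is below
    the cutoff in both groups before testing (pass ``None`` to keep
    everything).  Returns a DataFrame with columns ``gene_id, log2fc,
    p_value, adj_p, status``; the number of filtered genes and untestable
    genes are recorded in ``DataFrame.attrs``.
    """
    thresholds = thresholds or ThresholdConfig()
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")

    stim = matrix.group_values(background, stimulated)
    unstim = matrix.group_values(background, unstimulated)

    mean_stim = stim.mean(axis=1)
    mean_unstim = unstim.mean(axis=1)

    if min_expression is not None:
        keep = (mean_stim >= min_expression) | (mean_unstim >= min_expression)
    else:
        keep = pd.Series(True, index=stim.index)
    n_filtered = int((~keep).sum())

    stim = stim.loc[keep]
    unstim = unstim.loc[keep]
    fc = log2_fold_change(mean_stim[keep].to_numpy(), mean_unstim[keep].to_numpy(), pseudocount)

    log_stim = np.log2(stim.to_numpy(dtype=float) + pseudocount)
    log_unstim = np.log2(unstim.to_numpy(dtype=float) + pseudocount)
    p, n_untestable = _welch_rows(log_stim, log_unstim)
    if n_untestable:
        log.warning(
            "background %s: %d genes had <2 replicates per group; p set to 1",
            background,
            n_untestable,
        )

    records = pd.DataFrame(
        {
            "gene_id": stim.index.astype(str),
            "log2fc": fc,
            "p_value": p,
            "adj_p": bh_adjust(p),
        }
    )
    records = classify_induction(records, thresholds)
    records.attrs["background"] = background
    records.attrs["n_filtered"] = n_filtered
    records.attrs["n_untestable"] = n_untestable
    return records


def write_induction_tsv(records: pd.DataFrame, path: str | Path) -> None:
    records.loc[:, list(DE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_induction_tsv(path: str | Path) -> pd.DataFrame:
    records = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(DE_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"induction table is missing columns: {sorted(missing)}")
    return records
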