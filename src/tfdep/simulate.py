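"""Synthetic two-background, two-condition RNA-seq count generator.

The generator emulates the experimental design the downstream analysis
expects: two genetic backgrounds (e.g. wild type and knockout) measured
unstimulated and stimulated, with replicates.  Each gene g has a
baseline relative abundance q_g (log-normal), and an induced gene
carries a true log2 induction effect beta_g in background 1.  In
background 2 the effect is multiplied by a dependence factor delta:
delta < 1 models impaired induction, delta > 1 enhanced induction,
delta = 1 no dependence.  Counts for sample s are drawn negative
binomial around

    mu[g, s] = L_s * q_g * 2 ** (beta_g * I[stimulated] * delta_g)

with variance ``mu + phi * mu**2`` (the usual RNA-seq dispersion
convention).  ``phi = 0`` selects a fully deterministic noise-free mode:
counts are the rounded means and every sample gets the same library
size, so replicate columns within a group are bit-identical.  This mode
exists to make exact analytic checks of the downstream regression
possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import DESIGN_COLUMNS, ExpressionMatrix, SampleDesign

INDEPENDENT = "independent"
IMPAIRED = "impaired"
ENHANCED = "enhanced"

TRUTH_COLUMNS = ("gene_id", "induced", "dependence_class", "true_log2fc_bg1", "true_log2fc_bg2")


@dataclass(frozen=True)
class SimulationParams:
    """Settings of one simulated experiment.

    Defaults describe a mid-sized experiment: 2000 genes, a quarter of
    them stimulation-induced with log2 effects drawn from N(2.0, 0.5)
    truncated to [1.2, 4] (so every induced gene clears the conventional
    two-fold threshold), 80% of induced genes fully dependent on the
    second background (``dependence_factor = 0`` abolishes their
    induction there), moderate biological dispersion ``phi = 0.05`` and
    triplicate libraries of ~1e7 reads.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    frac_induced: float = 0.25
    frac_dependent_impaired: float = 0.8
    frac_dependent_enhanced: float = 0.0
    base_expression_log_mean: float = 4.0
    base_expression_log_sd: float = 1.2
    induction_log2fc_mean: float = 2.0
    induction_log2fc_sd: float = 0.5
    induction_log2fc_min: float = 1.2
    induction_log2fc_max: float = 4.0
    #: delta applied to beta_g in background 2 for impaired genes
    dependence_factor: float = 0.0
    #: delta applied to beta_g in background 2 for enhanced genes
    enhanced_factor: float = 2.0
    #: NB dispersion phi (variance mu + phi mu^2); 0 = deterministic mode
    dispersion: float = 0.05
    library_size_log_sd: float = 0.1
    mean_library_size: float = 1.0e7
    gene_length_range: tuple[int, int] = (200, 10_000)
    background_labels: tuple[str, str] = ("WT", "KO")
    condition_labels: tuple[str, str] = ("unstimulated", "stimulated")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive integer")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        for name in ("frac_induced", "frac_dependent_impaired", "frac_dependent_enhanced"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.frac_dependent_impaired + self.frac_dependent_enhanced > 1.0 + 1e-12:
            raise ValueError("frac_dependent_impaired + frac_dependent_enhanced must be <= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.dependence_factor < 0:
            raise ValueError("dependence_factor must be >= 0")
        if self.enhanced_factor < 0:
            raise ValueError("enhanced_factor must be >= 0")
        if self.library_size_log_sd < 0:
            raise ValueError("library_size_log_sd must be >= 0")
        if self.mean_library_size <= 0:
            raise ValueError("mean_library_size must be positive")
        if self.base_expression_log_sd < 0:
            raise ValueError("base_expression_log_sd must be >= 0")
        if self.induction_log2fc_sd < 0:
            raise ValueError("induction_log2fc_sd must be >= 0")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("gene_length_range must satisfy 0 < min <= max")
        if self.induction_log2fc_min > self.induction_log2fc_max:
            raise ValueError("induction_log2fc_min must be <= induction_log2fc_max")

    def replace(self, **changes) -> "SimulationParams":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(changes)
        return SimulationParams(**current)


@dataclass(frozen=True)
class TruthRecord:
    """Per-gene ground truth the analysis is meant to recover."""

    gene_id: str
    induced: bool
    dependence_class: str
    true_log2fc_bg1: float
    true_log2fc_bg2: float

    def __post_init__(self) -> None:
        if self.dependence_class not in (INDEPENDENT, IMPAIRED, ENHANCED):
            raise ValueError(f"unknown dependence_class {self.dependence_class!r}")
        if self.dependence_class != INDEPENDENT and not self.induced:
            raise ValueError("only induced genes may be dependent")


def simulate_experiment(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, SampleDesign, list[TruthRecord]]:
    """Draw one count matrix with its design and per-gene ground truth.

    The matrix has ``n_genes`` rows and ``4 * n_replicates`` columns
    (two backgrounds x two conditions).  Identical params (including the
    seed) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    width = max(4, len(str(n)))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(1, n + 1)])

    lo, hi = params.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)

    baseline = rng.lognormal(params.base_expression_log_mean, params.base_expression_log_sd, size=n)
    rel_abundance = baseline / baseline.sum()

    # induced genes: the first ceil(frac * n) ids of a seeded shuffle;
    # impaired genes lead the induced block, enhanced genes follow.
    perm = rng.permutation(n)
    n_induced = math.ceil(params.frac_induced * n)
    n_impaired = math.ceil(params.frac_dependent_impaired * n_induced)
    n_enhanced = min(math.ceil(params.frac_dependent_enhanced * n_induced), n_induced - n_impaired)
    induced_idx = perm[:n_induced]

    beta = np.zeros(n)
    beta[induced_idx] = np.clip(
        rng.normal(params.induction_log2fc_mean, params.induction_log2fc_sd, size=n_induced),
        params.induction_log2fc_min,
        params.induction_log2fc_max,
    )

    delta = np.ones(n)
    delta[induced_idx[:n_impaired]] = params.dependence_factor
    delta[induced_idx[n_impaired : n_impaired + n_enhanced]] = params.enhanced_factor

    dep_class = np.full(n, INDEPENDENT, dtype=object)
    dep_class[induced_idx[:n_impaired]] = IMPAIRED
    dep_class[induced_idx[n_impaired : n_impaired + n_enhanced]] = ENHANCED

    bg1, bg2 = params.background_labels
    unstim, stim = params.condition_labels
    rows = []
    for background in (bg1, bg2):
        for condition in (unstim, stim):
            for rep in range(1, params.n_replicates + 1):
                rows.append((f"{background}_{condition}_{rep}", background, condition, rep))
    design = SampleDesign(pd.DataFrame(rows, columns=list(DESIGN_COLUMNS)))

    n_samples = len(rows)
    noise_free = params.dispersion == 0
    if noise_free:
        # noise-free mode removes every stochastic element, library sizes included
        lib_sizes = np.full(n_samples, params.mean_library_size)
    else:
        lib_sizes = rng.lognormal(np.log(params.mean_library_size), params.library_size_log_sd, size=n_samples)

    stim_flag = np.array([row[2] == stim for row in rows], dtype=float)
    bg2_flag = np.array([row[1] == bg2 for row in rows], dtype=bool)
    per_sample_delta = np.where(bg2_flag[None, :], delta[:, None], 1.0)
    mu = lib_sizes[None, :] * rel_abundance[:, None] * 2.0 ** (beta[:, None] * stim_flag[None, :] * per_sample_delta)

    if noise_free:
        counts = np.rint(mu).astype(np.int64)
    else:
        size = 1.0 / params.dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p).astype(np.int64)

    values = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=[r[0] for r in rows])
    matrix = ExpressionMatrix(
        values,
        unit="counts",
        gene_lengths_bp=pd.Series(lengths, index=values.index, name="length_bp"),
        design=design,
    )

    induced_mask = np.zeros(n, dtype=bool)
    induced_mask[induced_idx] = True
    truth = [
        TruthRecord(
            gene_id=gene_ids[i],
            induced=bool(induced_mask[i]),
            dependence_class=str(dep_class[i]) if induced_mask[i] else INDEPENDENT,
            true_log2fc_bg1=float(beta[i]),
            true_log2fc_bg2=float(beta[i] * delta[i]) if induced_mask[i] else 0.0,
        )
        for i in range(n)
    ]
    return matrix, design, truth


def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.gene_id, t.induced, t.dependence_class, t.true_log2fc_bg1, t.true_log2fc_bg2) for t in truth],
        columns=list(TRUTH_COLUMNS),
    )


def write_truth_tsv(truth: list[TruthRecord], path: str | Path) -> None:
    truth_to_frame(truth).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return [
        TruthRecord(
            gene_id=row.gene_id,
            induced=bool(row.induced),
            dependence_class=row.dependence_class,
            true_log2fc_bg1=float(row.true_log2fc_bg1),
            true_log2fc_bg2=float(row.true_log2fc_bg2),
        )
        for row in frame.itertuples()
    ]
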