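"""Fold-change dependence regression with iterative distance filtering.

This is the core method of the package.  For every gene induced in
background 1 a point is placed at

    x = log2 induction fold change in background 1
    y = (log2FC in background 1) - (log2FC in background 2)

Genes whose induction requires the factor disrupted in background 2
fall systematically above y = 0 (impaired induction) or below it
(enhanced induction), and x and y are then linearly related: in the
limit of perfect dependence (no induction at all in background 2)
y = x, so an ordinary least-squares line through the above-side points
has slope 1 and r-squared 1.  If the two backgrounds differ only by
technical noise, y is independent of x and the fitted slope tends to 0.

Each side of y = 0 is fitted separately, tested for systematic bias,
and cleaned with an iterative loop that re-fits the line and keeps
exactly the points whose perpendicular (Euclidean point-to-line)
distance is within ``k`` robust standard deviations (1.4826 x median
absolute distance) of the current line.  Genes in the converged
inclusion set of a significantly biased side are called dependent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ABOVE = "above"
BELOW = "below"
ON_LINE = "on_line"

DEPENDENT_IMPAIRED = "dependent_impaired"
DEPENDENT_ENHANCED = "dependent_enhanced"
INDEPENDENT_CALL = "independent"

#: bias test names: slope t-test (default) or the extra-sum-of-squares
#: F-test of the fitted line against the fixed line y = 0
SLOPE_T = "slope_t"
F_VS_ZERO = "f_vs_zero"


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the iterative inclusion/exclusion loop."""

    distance_multiplier: float = 2.5
    max_iterations: int = 50
    min_points_per_side: int = 3
    alpha_bias: float = 0.05
    bias_test: str = SLOPE_T

    def __post_init__(self) -> None:
        if self.distance_multiplier <= 0:
            raise ValueError("distance_multiplier must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.min_points_per_side < 3:
            raise ValueError("min_points_per_side must be >= 3 (bias test needs 3 points)")
        if not 0.0 < self.alpha_bias < 1.0:
            raise ValueError("alpha_bias must lie in (0, 1)")
        if self.bias_test not in (SLOPE_T, F_VS_ZERO):
            raise ValueError(f"bias_test must be {SLOPE_T!r} or {F_VS_ZERO!r}")


class LineFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    spearman_rho: float


@dataclass
class RegressionFit:
    """Report of one side's filtered regression."""

    side: str
    slope: float
    intercept: float
    r_squared: float
    spearman_rho: float
    bias_p: float
    n_points: int
    included_gene_ids: list[str]
    n_iterations: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "spearman_rho": self.spearman_rho,
            "bias_p": self.bias_p,
            "n_points": self.n_points,
            "included_gene_ids": list(self.included_gene_ids),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }


class InsufficientPointsError(ValueError):
    pass


def build_dependence_points(
    records_bg1: pd.DataFrame,
    records_bg2: pd.DataFrame,
    gene_subset: Iterable[str],
) -> pd.DataFrame:
    """One (x, y) point per subset gene present in both backgrounds.

    Genes missing from either background's records are dropped; the drop
    count is stored in ``DataFrame.attrs["n_dropped"]``.
    """
    genes = list(dict.fromkeys(gene_subset))
    if not genes:
        raise ValueError("gene subset is empty")
    fc1 = records_bg1.set_index("gene_id")["log2fc"]
    fc2 = records_bg2.set_index("gene_id")["log2fc"]
    present = [g for g in genes if g in fc1.index and g in fc2.index]
    n_dropped = len(genes) - len(present)
    if n_dropped:
        log.warning("%d subset genes missing from one background; dropped", n_dropped)
    x = fc1.loc[present].to_numpy(dtype=float)
    y = x - fc2.loc[present].to_numpy(dtype=float)
    points = pd.DataFrame({"gene_id": present, "x": x, "y": y})
    if not np.all(np.isfinite(points[["x", "y"]].to_numpy())):
        raise ValueError("non-finite fold changes in dependence points")
    points.attrs["n_dropped"] = n_dropped
    return points


def split_sides(points: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition points into (y > 0, y < 0, y == 0)."""
    above = points[points["y"] > 0].reset_index(drop=True)
    below = points[points["y"] < 0].reset_index(drop=True)
    on_line = points[points["y"] == 0].reset_index(drop=True)
    return above, below, on_line


def fit_line(x, y) -> LineFit:
    """Closed-form OLS with intercept, plus Spearman rank correlation.

    r-squared is ``1 - SS_res / SS_tot``; a constant-y input gives slope
    0 and r-squared 0 by convention, while fewer than two points or a
    constant x raise :class:`InsufficientPointsError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and the same length")
    n = x.size
    if n < 2 or np.all(x == x[0]):
        raise InsufficientPointsError("insufficient points for fit")
    xm = x.mean()
    ym = y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    slope = sxy / sxx
    intercept = ym - slope * xm
    if syy == 0.0:
        return LineFit(0.0, float(ym), 0.0, 0.0)
    ss_res = float(np.sum((y - intercept - slope * x) ** 2))
    r_squared = 1.0 - ss_res / syy
    rho = stats.spearmanr(x, y).statistic
    if not np.isfinite(rho):
        rho = 0.0
    return LineFit(float(slope), float(intercept), float(r_squared), float(rho))


def test_bias(x, y, method: str = SLOPE_T) -> float:
    """p-value for systematic deviation of the points from the line y = 0.

    ``slope_t`` (default) is the two-sided t-test of the OLS slope
    against zero -- the literal reading of "the regression should
    generate a significantly nonzero slope", and the only variant whose
    false-positive rate on one-sided noise (points selected by y > 0)
    is controlled at alpha.  ``f_vs_zero`` is the extra-sum-of-squares
    F-test of the two-parameter line against the fixed line y = 0; it
    also reacts to a pure intercept offset.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise InsufficientPointsError("bias test needs at least 3 points")
    fit = fit_line(x, y)
    residuals = y - fit.intercept - fit.slope * x
    ss1 = float(np.sum(residuals**2))
    if method == F_VS_ZERO:
        ss0 = float(np.sum(y**2))
        if ss0 == 0.0:
            return 1.0
        if ss1 == 0.0:
            return 0.0
        f = ((ss0 - ss1) / 2.0) / (ss1 / (n - 2))
        return float(stats.f.sf(f, 2, n - 2))
    if method == SLOPE_T:
        if ss1 == 0.0:
            return 0.0 if fit.slope != 0.0 else 1.0
        xm = x.mean()
        sxx = float(np.sum((x - xm) ** 2))
        se = np.sqrt(ss1 / (n - 2) / sxx)
        t = fit.slope / se
        return float(2.0 * stats.t.sf(abs(t), n - 2))
    raise ValueError(f"unknown bias test {method!r}")


def _perpendicular_distances(x: np.ndarray, y: np.ndarray, fit: LineFit) -> np.ndarray:
    return np.abs(y - fit.intercept - fit.slope * x) / np.sqrt(1.0 + fit.slope**2)


def _failed_fit(side: str, n_iterations: int) -> RegressionFit:
    return RegressionFit(
        side=side,
        slope=float("nan"),
        intercept=float("nan"),
        r_squared=float("nan"),
        spearman_rho=float("nan"),
        bias_p=1.0,
        n_points=0,
        included_gene_ids=[],
        n_iterations=max(n_iterations, 1),
        converged=False,
    )


def iterative_filter(
    points_on_side: pd.DataFrame,
    config: FilterConfig | None = None,
    *,
    side: str = ABOVE,
) -> RegressionFit:
    """Fit one side with iterative inclusion by perpendicular distance.

    Each iteration fits the currently included points, measures every
    side point's perpendicular distance to that line, and includes
    exactly the points within ``distance_multiplier`` robust sigmas
    (1.4826 x the median distance of the included points).  The loop
    stops when an inclusion set repeats (fixed point or cycle -- on a
    cycle the lexicographically smallest set is reported) or after
    ``max_iterations``.  The procedure is deterministic.
    """
    config = config or FilterConfig()
    gene_ids = points_on_side["gene_id"].to_numpy()
    x = points_on_side["x"].to_numpy(dtype=float)
    y = points_on_side["y"].to_numpy(dtype=float)
    n = x.size
    if n < config.min_points_per_side:
        return _failed_fit(side, 1)

    def _key(idx_set: frozenset) -> tuple:
        return tuple(sorted(gene_ids[i] for i in idx_set))

    included = frozenset(range(n))
    seen: dict[frozenset, int] = {included: 0}
    order: list[frozenset] = [included]
    converged = False
    n_iterations = 0
    for _ in range(config.max_iterations):
        n_iterations += 1
        idx = np.fromiter(sorted(included), dtype=int)
        try:
            fit = fit_line(x[idx], y[idx])
        except InsufficientPointsError:
            return _failed_fit(side, n_iterations)
        distances = _perpendicular_distances(x, y, fit)
        sigma = 1.4826 * float(np.median(distances[idx]))
        new = frozenset(np.flatnonzero(distances <= config.distance_multiplier * sigma).tolist())
        if len(new) < config.min_points_per_side:
            return _failed_fit(side, n_iterations)
        if new in seen:
            cycle = order[seen[new] :]
            included = min(cycle, key=_key)
            converged = True
            break
        seen[new] = len(order)
        order.append(new)
        included = new

    idx = np.fromiter(sorted(included), dtype=int)
    try:
        fit = fit_line(x[idx], y[idx])
        bias_p = test_bias(x[idx], y[idx], config.bias_test)
    except InsufficientPointsError:
        return _failed_fit(side, n_iterations)
    return RegressionFit(
        side=side,
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        spearman_rho=fit.spearman_rho,
        bias_p=bias_p,
        n_points=len(idx),
        included_gene_ids=[str(g) for g in gene_ids[idx]],
        n_iterations=n_iterations,
        converged=converged,
    )


def call_dependence(
    points: pd.DataFrame,
    fit_above: RegressionFit,
    fit_below: RegressionFit,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Classify every point as dependent (impaired/enhanced) or independent.

    A gene is ``dependent_impaired`` iff it survives the above-side
    filter of a side whose bias p-value is below ``alpha_bias``;
    ``dependent_enhanced`` symmetrically for the below side.  Genes on
    y = 0, excluded genes, and genes on non-significant sides are
    ``independent``.
    """
    config = config or FilterConfig()
    calls = pd.Series(INDEPENDENT_CALL, index=points["gene_id"], dtype=object)
    if fit_above.converged and fit_above.bias_p < config.alpha_bias:
        calls.loc[fit_above.included_gene_ids] = DEPENDENT_IMPAIRED
    if fit_below.converged and fit_below.bias_p < config.alpha_bias:
        calls.loc[fit_below.included_gene_ids] = DEPENDENT_ENHANCED
    return pd.DataFrame({"gene_id": points["gene_id"], "call": calls.to_numpy()})


@dataclass
class DependenceResult:
    """Full dependence analysis: annotated points and per-side fits."""

    points: pd.DataFrame  # gene_id, x, y, side, included, call
    fit_above: RegressionFit
    fit_below: RegressionFit

    def calls(self, call: str) -> list[str]:
        return list(self.points.loc[self.points["call"] == call, "gene_id"])

    def fits_dict(self) -> dict:
        return {ABOVE: self.fit_above.to_dict(), BELOW: self.fit_below.to_dict()}


def analyze_dependence(
    records_bg1: pd.DataFrame,
    records_bg2: pd.DataFrame,
    *,
    subset: str | Iterable[str] = "up",
    config: FilterConfig | None = None,
) -> DependenceResult:
    """End-to-end dependence analysis of two backgrounds' induction tables.

    ``subset`` selects the genes entering the plot: ``"up"`` (default,
    the background-1 induced genes), ``"down"`` for the repression-side
    analysis, or an explicit iterable of gene ids.
    """
    config = config or FilterConfig()
    if isinstance(subset, str):
        genes = list(records_bg1.loc[records_bg1["status"] == subset, "gene_id"])
        if not genes:
            raise ValueError(f"no background-1 genes with status {subset!r}")
    else:
        genes = list(subset)
    points = build_dependence_points(records_bg1, records_bg2, genes)
    above, below, on_line = split_sides(points)
    fit_above = iterative_filter(above, config, side=ABOVE)
    fit_below = iterative_filter(below, config, side=BELOW)
    calls = call_dependence(points, fit_above, fit_below, config).set_index("gene_id")["call"]

    annotated = points.copy()
    side = np.full(len(points), ON_LINE, dtype=object)
    side[points["y"] > 0] = ABOVE
    side[points["y"] < 0] = BELOW
    annotated["side"] = side
    included = set(fit_above.included_gene_ids) | set(fit_below.included_gene_ids)
    annotated["included"] = annotated["gene_id"].isin(included)
    annotated["call"] = calls.loc[annotated["gene_id"]].to_numpy()
    annotated.attrs.update(points.attrs)
    return DependenceResult(points=annotated, fit_above=fit_above, fit_below=fit_below)
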