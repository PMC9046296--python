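"""Single-cell QC filters and pseudotime expression-pattern classification.

QC mirrors the standard trajectory preprocessing: cells expressing
fewer than 500 genes are dropped, genes expressed in fewer than 10
cells are dropped, and cells whose total count falls outside the mean
+/- 2 sd window are dropped (in that fixed order: cells -> genes ->
totals; changing the order can change the result).

Dynamic genes are ranked by a likelihood-ratio test of a cubic-spline
mean model against a constant mean on log1p values, BH-adjusted; genes
with q below threshold are kept (at most ``top_n``, 1000 by default).

Each dynamic gene is then assigned one of five temporal archetypes —
immediate downregulation, gradual downregulation, delayed upregulation,
gradual upregulation, tide wave — or the FLAT rejection class, from a
small set of shape features of its binned pseudotime trajectory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from statsmodels.stats.multitest import multipletests

from .datatypes import PatternClass, TrajectoryMatrix

__all__ = [
    "QcConfig",
    "filter_cells_min_genes",
    "filter_genes_min_cells",
    "qualify_cells_total_counts",
    "rank_dynamic_genes",
    "classify_pattern",
    "classify_all",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for QC, dynamic-gene ranking, and pattern assignment.

    ``flat_range_eps`` (epsilon) is the minimum relative dynamic range a
    gene needs to escape the FLAT class; ``net_change_theta`` (theta)
    the minimum |net change| of the scaled trajectory for a direction to
    count; ``tau_early``/``tau_late`` the midpoint-crossing fractions
    separating immediate from gradual downregulation and delayed from
    gradual upregulation.  ``extremum_tol`` is the minimum scaled step
    for an internal extremum to be counted (tide-wave detection).
    """

    min_genes_per_cell: int = 500
    min_cells_per_gene: int = 10
    total_count_sd: float = 2.0
    q_threshold: float = 0.01
    top_n: int = 1000
    n_bins: int = 10
    flat_range_eps: float = 0.1
    net_change_theta: float = 0.2
    tau_early: float = 0.3
    tau_late: float = 0.7
    extremum_tol: float = 0.05
    log1p: bool = True
    spline_df: int = 6

    def __post_init__(self) -> None:
        if min(
            self.min_genes_per_cell, self.min_cells_per_gene
        ) < 0 or self.total_count_sd <= 0:
            raise ValueError("QC thresholds must be positive")
        if not (0 < self.tau_early < self.tau_late < 1):
            raise ValueError("need 0 < tau_early < tau_late < 1")
        if not (0 < self.flat_range_eps < self.net_change_theta):
            raise ValueError("need 0 < flat_range_eps < net_change_theta")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


# ---------------------------------------------------------------------------
# QC filters


def filter_cells_min_genes(
    matrix: TrajectoryMatrix, config: QcConfig | None = None
) -> TrajectoryMatrix:
    """Drop cells expressing fewer than ``min_genes_per_cell`` genes.

    A gene counts as expressed in a cell when its value is nonzero; the
    boundary is inclusive (a cell at exactly the threshold is kept).
    """
    config = config or QcConfig()
    genes_per_cell = (matrix.expression > 0).sum(axis=0)
    keep = genes_per_cell >= config.min_genes_per_cell
    if not keep.any():
        raise ValueError(
            f"all {matrix.n_cells} cells express < "
            f"{config.min_genes_per_cell} genes"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_cells_min_genes: dropped %d cell(s)", dropped)
    return matrix.subset(cells=matrix.expression.columns[keep])


def filter_genes_min_cells(
    matrix: TrajectoryMatrix, config: QcConfig | None = None
) -> TrajectoryMatrix:
    """Drop genes expressed (nonzero) in fewer than ``min_cells_per_gene`` cells."""
    config = config or QcConfig()
    cells_per_gene = (matrix.expression > 0).sum(axis=1)
    keep = cells_per_gene >= config.min_cells_per_gene
    if not keep.any():
        raise ValueError(
            f"all {matrix.n_genes} genes are expressed in < "
            f"{config.min_cells_per_gene} cells"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_genes_min_cells: dropped %d gene(s)", dropped)
    return matrix.subset(genes=matrix.expression.index[keep])


def qualify_cells_total_counts(
    matrix: TrajectoryMatrix, config: QcConfig | None = None
) -> TrajectoryMatrix:
    """Keep cells whose total count lies within mean +/- k sd (closed interval).

    The sample standard deviation (n-1 denominator) is used; with a
    single cell the matrix is returned unchanged with a warning.
    """
    config = config or QcConfig()
    totals = matrix.expression.sum(axis=0)
    if matrix.n_cells < 2:
        warnings.warn("single cell: total-count window undefined, keeping all",
                      stacklevel=2)
        return matrix
    mean = float(totals.mean())
    sd = float(totals.std(ddof=1))
    lo, hi = mean - config.total_count_sd * sd, mean + config.total_count_sd * sd
    keep = (totals >= lo) & (totals <= hi)
    if not keep.any():
        raise ValueError("all cells fall outside the total-count window")
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "qualify_cells_total_counts: dropped %d cell(s) outside "
            "[%.2f, %.2f]", dropped, lo, hi,
        )
    return matrix.subset(cells=matrix.expression.columns[keep])


def apply_qc(matrix: TrajectoryMatrix, config: QcConfig | None = None) -> TrajectoryMatrix:
    """Fixed-order QC: cells -> genes -> total-count window."""
    config = config or QcConfig()
    return qualify_cells_total_counts(
        filter_genes_min_cells(filter_cells_min_genes(matrix, config), config),
        config,
    )


# ---------------------------------------------------------------------------
# dynamic-gene ranking


def _spline_design(t: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline basis with interior knots at pseudotime quantiles.

    ``df`` columns spanning constants; the LRT therefore has df-1
    degrees of freedom against the constant-mean null.
    """
    degree = 3
    n_interior = max(df - degree - 1, 0)
    lo, hi = float(t.min()), float(t.max())
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(t, qs)
    else:
        interior = np.array([])
    knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    return BSpline.design_matrix(t, knots, degree).toarray()


def rank_dynamic_genes(
    matrix: TrajectoryMatrix, config: QcConfig | None = None
) -> pd.DataFrame:
    """Rank pseudotime-associated genes by a spline likelihood-ratio test.

    For each gene, log1p values are regressed on a cubic-spline basis of
    pseudotime and on a constant; the Gaussian LRT statistic
    n*log(RSS0/RSS1) is referred to chi-square with (spline_df - 1)
    degrees of freedom.  P-values are BH-adjusted; genes with q below
    ``q_threshold`` are ranked by q then by fitted effect size
    (descending), and at most ``top_n`` are returned.

    Returns a DataFrame indexed by gene with columns
    (statistic, p_value, q_value, effect_size).
    """
    config = config or QcConfig()
    t = matrix.pseudotime.to_numpy(dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct pseudotime values")
    y = matrix.expression.to_numpy(dtype=float)
    if config.log1p:
        y = np.log1p(y)
    n = y.shape[1]

    X = _spline_design(t, config.spline_df)
    # least-squares fit of all genes at once
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    fitted = X @ beta  # cells x genes
    resid = y.T - fitted
    rss1 = np.maximum(np.sum(resid**2, axis=0), 1e-300)
    rss0 = np.maximum(np.sum((y - y.mean(axis=1, keepdims=True)) ** 2, axis=1),
                      1e-300)
    lrt = n * np.log(rss0 / rss1)
    lrt = np.clip(lrt, 0.0, None)
    df_test = X.shape[1] - 1
    pvals = stats.chi2.sf(lrt, df_test)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    effect = fitted.max(axis=0) - fitted.min(axis=0)

    table = pd.DataFrame(
        {
            "statistic": lrt,
            "p_value": pvals,
            "q_value": qvals,
            "effect_size": effect,
        },
        index=matrix.expression.index,
    )
    selected = table[table["q_value"] < config.q_threshold].copy()
    selected = selected.sort_values(
        ["q_value", "effect_size"], ascending=[True, False]
    )
    return selected.head(config.top_n)


# ---------------------------------------------------------------------------
# pattern classification


def _bin_means(
    values: np.ndarray, t: np.ndarray, n_bins: int
) -> np.ndarray:
    """Means of ``values`` over equal-width pseudotime bins.

    Empty bins are filled by linear interpolation between neighbouring
    occupied bins (extrapolation holds the edge value).
    """
    lo, hi = float(t.min()), float(t.max())
    if hi == lo:
        raise ValueError("pseudotime is constant; cannot bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.full(n_bins, np.nan)
    occupied = counts > 0
    means[occupied] = sums[occupied] / counts[occupied]
    if not occupied.all():
        centers = np.arange(n_bins)
        means = np.interp(centers, centers[occupied], means[occupied])
    return means


def _smooth(s: np.ndarray) -> np.ndarray:
    """3-point moving average with reflection padding."""
    padded = np.r_[s[0], s, s[-1]]
    return np.convolve(padded, np.ones(3) / 3.0, mode="valid")


def _count_internal_extrema(scaled: np.ndarray, tol: float) -> int:
    """Sign alternations of smoothed bin-to-bin steps larger than ``tol``."""
    diffs = np.diff(_smooth(scaled))
    signs = np.sign(diffs[np.abs(diffs) > tol])
    if len(signs) < 2:
        return 0
    return int(np.sum(signs[1:] != signs[:-1]))


def trajectory_features(
    values: np.ndarray,
    pseudotime: np.ndarray,
    config: QcConfig | None = None,
) -> dict[str, float]:
    """Shape features of one gene's binned pseudotime trajectory.

    Returns relative range R, net change delta (last - first scaled bin),
    internal extrema count E, and midpoint crossing time t_half (bin-
    center fraction where the scaled trajectory first crosses 0.5 in the
    direction of its net change).
    """
    config = config or QcConfig()
    values = np.asarray(values, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    if len(values) < config.n_bins:
        raise ValueError(
            f"need at least n_bins={config.n_bins} cells, have {len(values)}"
        )
    if config.log1p:
        values = np.log1p(np.clip(values, 0.0, None))
    b = _bin_means(values, t, config.n_bins)

    bmax, bmin = float(b.max()), float(b.min())
    scale = max(abs(bmax), abs(bmin), 1e-12)
    r_rel = (bmax - bmin) / scale
    if bmax == bmin:
        scaled = np.zeros_like(b)
    else:
        scaled = (b - bmin) / (bmax - bmin)
    delta = float(scaled[-1] - scaled[0])
    n_extrema = _count_internal_extrema(scaled, config.extremum_tol)

    centers = (np.arange(config.n_bins) + 0.5) / config.n_bins
    if delta < 0:
        crossing = np.flatnonzero(scaled <= 0.5)
    else:
        crossing = np.flatnonzero(scaled >= 0.5)
    t_half = float(centers[crossing[0]]) if len(crossing) else 1.0
    return {
        "range_rel": float(r_rel),
        "net_change": delta,
        "n_extrema": float(n_extrema),
        "t_half": t_half,
    }


def classify_pattern(
    values: np.ndarray,
    pseudotime: np.ndarray,
    config: QcConfig | None = None,
) -> PatternClass:
    """Assign one gene trajectory to a temporal archetype.

    Decision rule on the binned, min-max-scaled trajectory: FLAT if the
    relative range R < epsilon; TIDE_WAVE if there are >= 2 internal
    extrema, or >= 1 internal extremum with |net change| < theta (non-
    monotone without direction); otherwise the sign of the net change
    picks down vs up, and the midpoint crossing time t_half separates
    immediate (t_half <= tau_early) from gradual downregulation and
    delayed (t_half >= tau_late) from gradual upregulation.
    """
    config = config or QcConfig()
    f = trajectory_features(values, pseudotime, config)
    if f["range_rel"] < config.flat_range_eps:
        return PatternClass.FLAT
    if f["n_extrema"] >= 2:
        return PatternClass.TIDE_WAVE
    if f["n_extrema"] >= 1 and abs(f["net_change"]) < config.net_change_theta:
        return PatternClass.TIDE_WAVE
    if f["net_change"] < 0:
        if f["t_half"] <= config.tau_early:
            return PatternClass.IMMEDIATE_DOWN
        return PatternClass.GRADUAL_DOWN
    if f["t_half"] >= config.tau_late:
        return PatternClass.DELAYED_UP
    return PatternClass.GRADUAL_UP


def classify_all(
    matrix: TrajectoryMatrix, config: QcConfig | None = None
) -> pd.DataFrame:
    """Classify every gene; returns a table of class and shape features.

    The result carries per-class counts in ``.attrs["class_counts"]``.
    """
    config = config or QcConfig()
    t = matrix.pseudotime.to_numpy(dtype=float)
    rows = []
    for gene, values in matrix.expression.iterrows():
        f = trajectory_features(values.to_numpy(), t, config)
        cls = classify_pattern(values.to_numpy(), t, config)
        rows.append({"gene": gene, "pattern": cls.value, **f})
    table = pd.DataFrame(rows).set_index("gene")
    table.attrs["class_counts"] = table["pattern"].value_counts().to_dict()
    return table
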