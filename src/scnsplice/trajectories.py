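"""Developmental trajectories of mutually exclusive exon usage.

The central quantity is the per-sample A:N expression ratio
r_s = CPM_A / CPM_N for a registered mutually exclusive exon pair, which
tracks exon utilization independently of whole-gene expression changes.
Trajectories are summarized three ways, all on log2 scales:

* an ordinary least-squares trend of log2(ratio) on log2(age in
  post-conceptual days, pcd);
* a Loess smooth (tri-cube weighted local polynomials) with pointwise
  95% confidence bands;
* a fetal-vs-mature contrast of log2(ratio) by two-tailed Wilcoxon
  rank-sum test after binning samples into fetal / transitional / mature
  stages.

An all-pairs exon-ratio screen generalizes the same regression to every
pair of bins of a gene, flagging bins whose expression trajectory departs
from the rest of the gene (high median R^2 against the other bins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import MxePair
from .counting import ExonMatrix

FETAL = "fetal"
TRANSITIONAL = "transitional"
MATURE = "mature"

#: Default stage boundaries in post-conceptual days: fetal ends at
#: 37 post-conceptual weeks (birth at term, 259 pcd); mature begins at
#: 2 years post-conception (730 pcd).
DEFAULT_STAGE_BOUNDARIES = (259.0, 730.0)


def assign_stage(
    age_pcd: float, boundaries: tuple[float, float] = DEFAULT_STAGE_BOUNDARIES
) -> str:
    """Bin an age into fetal / transitional / mature (left-closed rule)."""
    fetal_end, mature_start = boundaries
    if not fetal_end < mature_start:
        raise ValueError("fetal_end must be below mature_start")
    if age_pcd < fetal_end:
        return FETAL
    if age_pcd >= mature_start:
        return MATURE
    return TRANSITIONAL


def add_stage_column(
    meta: pd.DataFrame, boundaries: tuple[float, float] = DEFAULT_STAGE_BOUNDARIES
) -> pd.DataFrame:
    out = meta.copy()
    out["stage"] = [assign_stage(a, boundaries) for a in out["age_pcd"]]
    return out


@dataclass
class RatioSeries:
    pair: MxePair
    ratios: pd.Series  # defined ratios only, indexed by sample_id
    n_undefined: int
    zero_policy: str

    @property
    def n_defined(self) -> int:
        return len(self.ratios)


def compute_ratio_series(
    matrix: ExonMatrix,
    pair: MxePair,
    zero_policy: str = "exclude",
    pseudocount: float = 0.01,
) -> RatioSeries:
    """Per-sample CPM_A / CPM_N for a mutually exclusive pair.

    Under ``zero_policy='exclude'`` samples with zero CPM in either exon
    are undefined (counted in ``n_undefined``); under ``'pseudocount'``
    both CPM values get ``pseudocount`` added before dividing.
    """
    if matrix.cpm is None:
        raise ValueError("matrix has no CPM values; run cpm_normalize first")
    key_a = f"{pair.gene_id}:{pair.bin_a}"
    key_n = f"{pair.gene_id}:{pair.bin_n}"
    for key in (key_a, key_n):
        if key not in matrix.cpm.index:
            raise KeyError(f"pair bin {key} absent from matrix")
    cpm_a = matrix.cpm.loc[key_a]
    cpm_n = matrix.cpm.loc[key_n]
    if zero_policy == "exclude":
        defined = (cpm_a > 0) & (cpm_n > 0)
        ratios = (cpm_a[defined] / cpm_n[defined]).astype(float)
        n_undef = int((~defined).sum())
    elif zero_policy == "pseudocount":
        ratios = ((cpm_a + pseudocount) / (cpm_n + pseudocount)).astype(float)
        n_undef = 0
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    return RatioSeries(pair=pair, ratios=ratios, n_undefined=n_undef, zero_policy=zero_policy)


@dataclass
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fit_loglog_trend(ages_pcd, ratios) -> TrendFit:
    """OLS of log2(ratio) on log2(age_pcd).

    A constant response (zero total sum of squares) is reported as
    slope 0, R^2 0, p 1 by convention.
    """
    x = np.log2(np.asarray(ages_pcd, dtype=float))
    y = np.log2(np.asarray(ratios, dtype=float))
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ages and ratios must be equal-length 1-d sequences")
    if len(x) < 3:
        raise ValueError("trend fit requires at least 3 defined points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("ages and ratios must be positive and finite")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return TrendFit(slope=0.0, intercept=float(y.mean()), r_squared=0.0, p_value=1.0, n=len(x))
    res = stats.linregress(x, y)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


@dataclass
class LoessFit:
    grid: np.ndarray
    fitted: np.ndarray
    ci_half_width: np.ndarray
    span: float
    degree: int


def _loess_point(x0, x, y, k, degree):
    """Local weighted polynomial fit at x0; returns the operator row l."""
    d = np.abs(x - x0)
    idx = np.argpartition(d, k - 1)[:k]
    d_max = d[idx].max()
    if d_max == 0:
        w = np.ones(k)
    else:
        w = (1.0 - (d[idx] / d_max) ** 3) ** 3
        w = np.clip(w, 0.0, None)
    X = np.vander(x[idx] - x0, N=degree + 1, increasing=True)
    XtW = X.T * w
    # value at x0 is the intercept coefficient of the local polynomial
    A = XtW @ X
    l_local = np.linalg.solve(A, XtW)[0]
    l_row = np.zeros(len(x))
    l_row[idx] = l_local
    return l_row


def loess_smooth(
    x, y, span: float = 0.75, degree: int = 1, grid=None, z: float = 1.96
) -> LoessFit:
    """Loess: tri-cube weighted local polynomial smooth with 95% CI.

    At each grid point the nearest ceil(span*n) points are weighted by
    w = (1 - (d/d_max)^3)^3 and a degree-1 or degree-2 polynomial is fit
    by weighted least squares.  The pointwise standard error comes from
    the local linear operator and a residual-based variance estimate, so
    an exactly reproduced signal has zero-width bands.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = len(x)
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    k = max(int(math.ceil(span * n)), degree + 2)
    k = min(k, n)
    if grid is None:
        grid = np.unique(x)
    grid = np.asarray(grid, dtype=float)

    # residual variance from the fit evaluated at the data points
    L_data = np.array([_loess_point(xi, x, y, k, degree) for xi in x])
    resid = y - L_data @ y
    dof = max(n - (degree + 1), 1)
    sigma2 = float(resid @ resid) / dof

    fitted = np.empty(len(grid))
    half = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        l_row = _loess_point(x0, x, y, k, degree)
        fitted[i] = l_row @ y
        half[i] = z * math.sqrt(sigma2 * float(l_row @ l_row))
    return LoessFit(grid=grid, fitted=fitted, ci_half_width=half, span=span, degree=degree)


@dataclass
class StageContrast:
    median_a: float
    median_b: float
    iqr_a: tuple[float, float]
    iqr_b: tuple[float, float]
    statistic: float
    p_value: float
    method: str


def wilcoxon_ranksum(group_a, group_b, max_exact_n: int = 12) -> StageContrast:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) contrast.

    Exact p by enumeration when the pooled size is <= ``max_exact_n`` and
    there are no ties; otherwise normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= max_exact_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return StageContrast(
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        iqr_a=(float(np.percentile(a, 25)), float(np.percentile(a, 75))),
        iqr_b=(float(np.percentile(b, 25)), float(np.percentile(b, 75))),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
    )


@dataclass
class PairwiseScreen:
    r_squared: pd.DataFrame  # symmetric, zero diagonal
    row_median: pd.Series
    flagged: list[str] = field(default_factory=list)
    threshold: float = 0.3


def pairwise_ratio_screen(
    matrix: ExonMatrix,
    bin_keys,
    ages_pcd: pd.Series,
    min_cpm: float = 1.0,
    pseudocount: float = 0.01,
    distinct_threshold: float = 0.3,
) -> PairwiseScreen:
    """All-pairs exon-ratio screen for one gene.

    For each unordered bin pair (i, j) the ratio (CPM_i + c) / (CPM_j + c)
    is regressed on log2(age); samples where both bins fall below
    ``min_cpm`` are dropped.  Bins whose median off-diagonal R^2 exceeds
    ``distinct_threshold`` are flagged as having a distinct developmental
    trajectory.
    """
    if matrix.cpm is None:
        raise ValueError("matrix has no CPM values; run cpm_normalize first")
    bin_keys = list(bin_keys)
    if len(bin_keys) < 2:
        raise ValueError("screen needs at least 2 bins")
    ages = ages_pcd.reindex(matrix.cpm.columns).astype(float)
    cpm = matrix.cpm.loc[bin_keys]
    B = len(bin_keys)
    r2 = np.zeros((B, B))
    for i in range(B):
        for j in range(i + 1, B):
            ci = cpm.iloc[i].to_numpy()
            cj = cpm.iloc[j].to_numpy()
            keep = ~((ci < min_cpm) & (cj < min_cpm))
            if keep.sum() < 3:
                continue
            ratio = (ci[keep] + pseudocount) / (cj[keep] + pseudocount)
            fit = fit_loglog_trend(ages.to_numpy()[keep], ratio)
            r2[i, j] = r2[j, i] = fit.r_squared
    df = pd.DataFrame(r2, index=bin_keys, columns=bin_keys)
    off_diag = df.where(~np.eye(B, dtype=bool))
    row_median = off_diag.median(axis=1)
    flagged = list(row_median[row_median > distinct_threshold].index)
    return PairwiseScreen(
        r_squared=df, row_median=row_median, flagged=flagged, threshold=distinct_threshold
    )


def stage_geometric_mean_ratios(
    ratios: pd.Series, stages: pd.Series
) -> dict[str, float]:
    """Geometric mean of ratios per developmental stage."""
    out = {}
    aligned = stages.reindex(ratios.index)
    for stage in (FETAL, TRANSITIONAL, MATURE):
        vals = ratios[aligned == stage]
        if len(vals):
            out[stage] = float(2 ** np.log2(vals).mean())
    return out
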