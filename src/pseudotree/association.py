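"""Association between pseudotime and outcomes.

Binary logistic regression for case/control status, proportional-odds
ordinal regression for neuropathology-like ordinal scores (and allele
dosage), a Spearman correlation-shift test for gene sets against the
background of analyzed genes, and smoothed cell-type marker trajectories
along pseudotime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import CubicSpline
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "AssociationResult",
    "TrajectorySummary",
    "SeparationError",
    "logistic_assoc",
    "ordinal_assoc",
    "geneset_correlation_shift",
    "celltype_trajectory",
    "smoothing_spline",
]


class SeparationError(ValueError):
    """Raised when a logistic-type likelihood has no finite maximizer
    (complete or quasi-complete separation)."""


@dataclass
class AssociationResult:
    model: str  # "logistic" | "ordinal" | "linear"
    coef: float  # pseudotime coefficient
    se: float
    statistic: float
    p: float
    n: int
    converged: bool
    covariates: list[str] = field(default_factory=list)


@dataclass
class TrajectorySummary:
    cell_type: str
    genes_used: list[str]
    grid: np.ndarray  # strictly increasing pseudotime grid
    mean_curve: np.ndarray  # smoothed, [0, 1]-normalized, gene-averaged
    slope: float
    slope_p: float


_SEPARATION_COEF = 30.0  # |beta| beyond this on a [0,1] regressor means divergence


def _design(pseudotime, covariates):
    x = np.asarray(pseudotime, dtype=float)
    cols = {"pseudotime": x}
    names = []
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            cols[str(c)] = cov[c].to_numpy(dtype=float)
            names.append(str(c))
    X = sm.add_constant(pd.DataFrame(cols), prepend=True)
    return X, names


def logistic_assoc(
    pseudotime: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> AssociationResult:
    """Logistic regression of a binary outcome on pseudotime (Newton MLE,
    Wald z-test for the pseudotime coefficient).

    Complete or quasi-complete separation raises SeparationError.
    """
    y = np.asarray(outcome)
    if y.dtype.kind not in "biuf":
        y = (y == np.unique(y)[-1]).astype(float)
    y = y.astype(float)
    if np.unique(y).size != 2:
        raise ValueError("outcome must have exactly two classes")
    X, names = _design(pseudotime, covariates)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError("separation in logistic regression") from exc
    beta = np.asarray(res.params)
    if not np.all(np.isfinite(beta)) or np.abs(beta).max() > _SEPARATION_COEF:
        raise SeparationError("separation in logistic regression (diverging coefficient)")
    i = list(X.columns).index("pseudotime")
    return AssociationResult(
        model="logistic",
        coef=float(res.params.iloc[i]),
        se=float(res.bse.iloc[i]),
        statistic=float(res.tvalues.iloc[i]),
        p=float(res.pvalues.iloc[i]),
        n=int(y.size),
        converged=bool(res.mle_retvals.get("converged", True)),
        covariates=names,
    )


def ordinal_assoc(
    pseudotime: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    test: str = "lr",
) -> AssociationResult:
    """Proportional-odds ordinal regression, P(Y <= j) = expit(theta_j -
    beta * x), with a likelihood-ratio (default) or Wald test of beta = 0.

    Unobserved intermediate levels are collapsed with a warning.
    """
    y = np.asarray(outcome)
    levels = np.unique(y)
    if levels.size < 2:
        raise ValueError("outcome must have at least 2 observed levels")
    full_range = np.arange(levels.min(), levels.max() + 1)
    if y.dtype.kind in "iu" and levels.size < full_range.size:
        warnings.warn("unobserved intermediate level(s) collapsed")
    rank = {v: i for i, v in enumerate(levels)}
    y_ord = pd.Series(pd.Categorical([rank[v] for v in y], ordered=True))
    X, names = _design(pseudotime, covariates)
    X = X.drop(columns="const")  # OrderedModel has its own cutpoints
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = OrderedModel(y_ord, X, distr="logit").fit(
            method="bfgs", maxiter=200, disp=False
        )
    i = list(X.columns).index("pseudotime")
    beta = float(res.params.iloc[i])
    if abs(beta) > _SEPARATION_COEF:
        raise SeparationError("separation in ordinal regression (diverging coefficient)")
    if test == "lr":
        if names:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                null = OrderedModel(
                    y_ord, X.drop(columns="pseudotime"), distr="logit"
                ).fit(method="bfgs", maxiter=200, disp=False)
            ll0 = null.llf
        else:
            counts = np.bincount(y_ord.cat.codes)
            counts = counts[counts > 0]
            ll0 = float(np.sum(counts * np.log(counts / counts.sum())))
        lr = 2.0 * (res.llf - ll0)
        statistic = float(max(lr, 0.0))
        p = float(stats.chi2.sf(statistic, df=1))
    elif test == "wald":
        statistic = float(res.tvalues.iloc[i])
        p = float(res.pvalues.iloc[i])
    else:
        raise ValueError("test must be 'lr' or 'wald'")
    return AssociationResult(
        model="ordinal",
        coef=beta,
        se=float(res.bse.iloc[i]),
        statistic=statistic,
        p=p,
        n=int(y.size),
        converged=bool(res.mle_retvals.get("converged", True)),
        covariates=names,
    )


def _spearman_vs(x: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row of *values* with *x*, average
    ranks for ties (vectorized across rows)."""
    rx = stats.rankdata(x)
    rv = stats.rankdata(values, axis=1)
    rx = rx - rx.mean()
    rv = rv - rv.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum() * (rv**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rv @ rx) / denom
    return rho


def geneset_correlation_shift(
    expr,
    pseudotime: np.ndarray,
    gene_set: list[str],
    background: list[str] | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Test whether a gene set's expression-pseudotime Spearman
    correlations are shifted relative to the background of all other
    analyzed genes (two-group linear model on the correlations).

    Returns (per-gene table, mean shift, two-sided p).
    """
    genes = list(expr.gene_ids)
    in_set = set(gene_set) & set(genes)
    if not in_set:
        raise ValueError("gene_set is empty after intersecting with the expression matrix")
    if background is not None:
        universe = [g for g in genes if g in set(background) | in_set]
    else:
        universe = genes
    idx = [genes.index(g) for g in universe]
    rho = _spearman_vs(np.asarray(pseudotime, dtype=float), expr.values[idx])
    member = np.array([g in in_set for g in universe])
    table = pd.DataFrame({"gene": universe, "rho": rho, "in_set": member})
    ok = ~np.isnan(rho)
    a = rho[member & ok]
    b = rho[~member & ok]
    if b.size < 2:
        raise ValueError("background too small for the shift test")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return table, float(a.mean() - b.mean()), float(p)


def _natural_spline_penalty(x: np.ndarray) -> np.ndarray:
    """Green-Silverman roughness penalty K = Q R^{-1} Q^T for a natural
    cubic spline with knots at the (sorted, unique) x."""
    n = x.size
    h = np.diff(x)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        c = j - 1
        Q[j - 1, c] = 1.0 / h[j - 1]
        Q[j, c] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, c] = 1.0 / h[j]
        R[c, c] = (h[j - 1] + h[j]) / 3.0
        if c + 1 < n - 2:
            R[c, c + 1] = R[c + 1, c] = h[j] / 6.0
    return Q @ np.linalg.solve(R, Q.T)


def smoothing_spline(
    x: np.ndarray, Y: np.ndarray, df: float = 3.0, df_tol: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic smoothing spline with the penalty tuned (bisection on
    log lambda) so the effective degrees of freedom — the trace of the
    smoother matrix — equals *df*.

    Ties in x are handled by weighting unique knots with their
    multiplicity.  Y may hold several response rows (genes x samples).
    Returns (unique_x, fitted values at unique_x per row).
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    ux, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    n = ux.size
    ybar = np.zeros((Y.shape[0], n))
    np.add.at(ybar.T, inv, Y.T)
    ybar /= counts
    if n <= 3 or n <= df:
        return ux, ybar  # too few distinct knots to smooth below df
    Wd = np.diag(counts.astype(float))
    K = _natural_spline_penalty(ux)

    def df_of(log_lam: float) -> float:
        A = np.linalg.solve(Wd + 10.0**log_lam * K, Wd)
        return float(np.trace(A))

    lo, hi = -12.0, 12.0
    while df_of(hi) > df and hi < 40:
        hi += 4
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = df_of(mid)
        if abs(val - df) < df_tol:
            break
        if val > df:
            lo = mid
        else:
            hi = mid
    lam = 10.0**mid
    fitted = np.linalg.solve(Wd + lam * K, (ybar * counts).T).T
    return ux, fitted


def celltype_trajectory(
    expr,
    pseudotime: np.ndarray,
    marker_sets: dict[str, list[str]],
    spline_df: float = 3.0,
    grid_size: int = 100,
    normalize: str = "before_average",
) -> dict[str, TrajectorySummary]:
    """Smoothed cell-type marker trajectories along pseudotime.

    Per marker gene: a cubic smoothing spline with effective df =
    *spline_df*, min-max normalized to [0, 1] (constant fits map to 0.5).
    Per cell type: the gene-averaged curve on a pseudotime grid, plus the
    OLS slope (with p-value) of the per-sample averaged normalized
    expression against pseudotime.  ``normalize="after_average"``
    normalizes the averaged curve instead of each gene.
    """
    if normalize not in ("before_average", "after_average"):
        raise ValueError("normalize must be 'before_average' or 'after_average'")
    t = np.asarray(pseudotime, dtype=float)
    genes = {g: i for i, g in enumerate(expr.gene_ids)}
    out: dict[str, TrajectorySummary] = {}
    grid = np.linspace(t.min(), t.max(), grid_size)
    for cell_type, members in marker_sets.items():
        present = [g for g in members if g in genes]
        if not present:
            missing = [g for g in members if g not in genes]
            raise ValueError(
                f"marker set {cell_type!r} has no genes in the matrix; missing: {missing}"
            )
        rows = expr.values[[genes[g] for g in present]]
        ux, fitted = smoothing_spline(t, rows, df=spline_df)
        splines = [CubicSpline(ux, f, bc_type="natural") for f in fitted]
        raw_curves = np.vstack([s(grid) for s in splines])
        raw_at_samples = np.vstack([s(t) for s in splines])

        def _minmax(c, ref):
            lo, hi = ref.min(), ref.max()
            if hi - lo <= 1e-8 * (1.0 + abs(hi)):  # constant fit (to precision)
                return np.full_like(c, 0.5)
            return np.clip((c - lo) / (hi - lo), 0.0, 1.0)

        if normalize == "before_average":
            mean_curve = np.vstack(
                [_minmax(c, c) for c in raw_curves]
            ).mean(axis=0)
            mean_at_samples = np.vstack(
                [_minmax(a, c) for a, c in zip(raw_at_samples, raw_curves)]
            ).mean(axis=0)
        else:
            ref = raw_curves.mean(axis=0)
            mean_curve = _minmax(ref, ref)
            mean_at_samples = _minmax(raw_at_samples.mean(axis=0), ref)
        lr = stats.linregress(t, mean_at_samples)
        out[cell_type] = TrajectorySummary(
            cell_type=cell_type,
            genes_used=present,
            grid=grid,
            mean_curve=mean_curve,
            slope=float(lr.slope),
            slope_p=float(lr.pvalue),
        )
    return out
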