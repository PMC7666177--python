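"""Gene filtering, normalization and covariate adjustment.

These steps produce the matrix handed to the manifold learner: counts are
filtered on counts-per-million (CPM) abundance, log-transformed, reduced to
a disease-informative gene subset (differential-expression or high-variance
selection), and optionally adjusted for technical covariates by ordinary
least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust

__all__ = [
    "ExpressionMatrix",
    "GeneSelection",
    "cpm_filter",
    "log_normalize",
    "de_gene_selection",
    "variance_gene_selection",
    "covariate_adjust",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with identifiers.

    ``scale`` tags the values as raw ``counts``, ``log_cpm``
    (log2(CPM + 1)) or covariate-``adjusted`` log-scale values.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    scale: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.isnan(self.values).any():
            raise ValueError("missing values in expression matrix")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale: str = "counts") -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns), scale)

    def subset_genes(self, keep: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in keep]
        return replace(self, values=self.values[rows], gene_ids=list(keep))


@dataclass
class GeneSelection:
    """Outcome of a gene-filtering step, with the per-gene statistics."""

    method: str  # "de" | "variance"
    kept_gene_ids: list[str]
    table: pd.DataFrame = field(repr=False)  # gene, statistic, p, adjusted_p, kept
    fdr_threshold: float | None = None


def _cpm(counts: np.ndarray, sample_ids: list[str]) -> np.ndarray:
    libsize = counts.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValueError(f"zero library size for sample(s): {[sample_ids[i] for i in zero]}")
    return counts / libsize * 1e6


def cpm_filter(
    counts: ExpressionMatrix,
    cpm_threshold: float = 1.0,
    sample_fraction: float = 0.5,
    groups: np.ndarray | list | None = None,
) -> ExpressionMatrix:
    """Keep genes with CPM above *cpm_threshold* in at least
    *sample_fraction* of the samples of every group.

    With no *groups*, all samples form a single group.  The default
    (CPM > 1 in at least half the samples) is the conventional abundance
    filter for bulk RNA-seq counts.
    """
    if counts.scale != "counts":
        raise ValueError("cpm_filter expects a counts-scale matrix")
    if np.any(counts.values < 0):
        raise ValueError("negative counts")
    cpm = _cpm(counts.values, counts.sample_ids)
    above = cpm > cpm_threshold
    if groups is None:
        groups = np.zeros(counts.n_samples, dtype=int)
    groups = np.asarray(groups)
    keep = np.ones(counts.n_genes, dtype=bool)
    for g in np.unique(groups):
        cols = groups == g
        frac = above[:, cols].mean(axis=1)
        keep &= frac >= sample_fraction
    kept = [gid for gid, k in zip(counts.gene_ids, keep) if k]
    return counts.subset_genes(kept)


def log_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1) transform; deterministic, scale tag becomes log_cpm."""
    if np.any(counts.values < 0):
        raise ValueError("negative counts")
    cpm = _cpm(counts.values, counts.sample_ids)
    return replace(counts, values=np.log2(cpm + 1.0), scale="log_cpm")


def de_gene_selection(
    expr: ExpressionMatrix,
    labels: np.ndarray | list,
    fdr_threshold: float = 0.10,
) -> GeneSelection:
    """Per-gene two-group t-test on log-scale values, BH-adjusted; genes
    with adjusted p below *fdr_threshold* are retained.

    This is the case/control differential-expression filter used before
    manifold learning; zero-variance genes have no defined statistic and
    are dropped with a warning.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"labels must be binary, got {classes.size} classes")
    a = expr.values[:, y == classes[0]]
    b = expr.values[:, y == classes[1]]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 samples per class")
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene(s) dropped from DE selection"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, np.nan, p)
    adj = bh_adjust(p)
    kept_mask = (adj < fdr_threshold) & ~np.isnan(adj)
    table = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "statistic": t,
            "p": p,
            "adjusted_p": adj,
            "kept": kept_mask,
        }
    )
    kept = [g for g, k in zip(expr.gene_ids, kept_mask) if k]
    return GeneSelection("de", kept, table, fdr_threshold)


def variance_gene_selection(expr: ExpressionMatrix, top_n: int) -> GeneSelection:
    """Keep the *top_n* genes by across-sample variance (ties broken by
    gene id, lexicographic) — the high-variance sensitivity alternative
    to the case/control DE filter."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if top_n > expr.n_genes:
        raise ValueError("top_n exceeds gene count")
    var = expr.values.var(axis=1, ddof=1)
    order = sorted(range(expr.n_genes), key=lambda i: (-var[i], expr.gene_ids[i]))
    kept_idx = sorted(order[:top_n])
    kept_mask = np.zeros(expr.n_genes, dtype=bool)
    kept_mask[kept_idx] = True
    table = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "statistic": var,
            "p": np.nan,
            "adjusted_p": np.nan,
            "kept": kept_mask,
        }
    )
    return GeneSelection("variance", [expr.gene_ids[i] for i in kept_idx], table, None)


def covariate_adjust(expr: ExpressionMatrix, covariates: pd.DataFrame) -> ExpressionMatrix:
    """Replace each gene by its OLS residual (plus the gene mean) after
    regressing on the covariates with an intercept.

    Residuals are exactly orthogonal to every covariate column; used to
    remove plate/PMI/RIN-style technical effects before manifold learning.
    """
    if list(covariates.index) != list(expr.sample_ids):
        if len(covariates) != expr.n_samples:
            raise ValueError("covariates not aligned to samples")
        covariates = covariates.copy()
        covariates.index = expr.sample_ids
    C = covariates.to_numpy(dtype=float)
    X = np.column_stack([np.ones(expr.n_samples), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for j, name in enumerate(covariates.columns):
            Xr = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                bad.append(str(name))
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    Y = expr.values.T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    adjusted = resid.T + expr.values.mean(axis=1, keepdims=True)
    return replace(expr, values=adjusted, scale="adjusted")
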