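"""Module-environment and module-module statistics.

Eigengenes summarize module activity per sample; this module relates them to
soil/plant factors (pairwise correlations, multiple linear regression after
min-max standardization and collinearity pruning), to each other (eigengene
correlations, gene-eigengene cross-correlation distributions), and provides
the PCA "biplot of correlations" that places modules and factors in a common
plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from foragenet.errors import (
    ConstantFactorError,
    InvalidConfigError,
    RankDeficientDesignError,
)
from foragenet.expression import ExpressionMatrix

__all__ = [
    "CorrelationTable",
    "RegressionResult",
    "BiplotResult",
    "module_factor_correlations",
    "drop_collinear_factors",
    "standardize_minmax",
    "fit_module_regression",
    "correlation_pca_biplot",
    "gene_eigengene_crosscorrelation",
    "eigengene_correlation",
]


def _pearson_p(r: float, n: int) -> float:
    if n < 3 or not np.isfinite(r):
        return np.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass
class CorrelationTable:
    """Pairwise r / p / n between row entities and column variables."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def module_factor_correlations(
    eigengenes: pd.DataFrame, factors: pd.DataFrame
) -> CorrelationTable:
    """Pairwise-complete Pearson correlation of eigengenes vs factors.

    ``eigengenes`` is modules x samples, ``factors`` samples x factors.
    Cells with a constant variable over the shared complete observations are
    NaN with a warning; n per cell records the observations actually used.
    """
    shared = [s for s in eigengenes.columns if s in factors.index]
    if len(shared) < 4:
        raise InvalidConfigError("need at least 4 shared samples")
    modules = list(eigengenes.index)
    names = list(factors.columns)
    r = pd.DataFrame(np.nan, index=modules, columns=names)
    p = pd.DataFrame(np.nan, index=modules, columns=names)
    n = pd.DataFrame(0, index=modules, columns=names, dtype=int)
    for m in modules:
        e = eigengenes.loc[m, shared].to_numpy(dtype=float)
        for f in names:
            v = factors.loc[shared, f].to_numpy(dtype=float)
            ok = np.isfinite(e) & np.isfinite(v)
            n.loc[m, f] = int(ok.sum())
            if ok.sum() < 4:
                warnings.warn(f"fewer than 4 complete pairs for {m} x {f}")
                continue
            if np.ptp(e[ok]) == 0 or np.ptp(v[ok]) == 0:
                warnings.warn(f"constant variable in cell {m} x {f}; r undefined")
                continue
            rr = float(np.corrcoef(e[ok], v[ok])[0, 1])
            r.loc[m, f] = rr
            p.loc[m, f] = _pearson_p(rr, int(ok.sum()))
    return CorrelationTable(r=r, p=p, n=n)


def drop_collinear_factors(
    factors: pd.DataFrame, r_cut: float = 0.9
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Prune highly correlated factor pairs, keeping the earlier-listed one.

    Factors are scanned in column order; whenever a retained pair has
    ``|r| >= r_cut`` (pairwise-complete Pearson), the later-listed factor is
    dropped.  Returns (retained names, log of (kept, dropped, r) pairs).
    The boundary is inclusive: ``|r|`` exactly at the cut drops the pair's
    later member.
    """
    if factors.shape[1] < 2:
        raise InvalidConfigError("need at least 2 factors")
    names = list(factors.columns)
    corr = factors.corr(method="pearson")  # pairwise-complete
    retained: list[str] = []
    dropped_log: list[tuple[str, str, float]] = []
    dropped: set[str] = set()
    for j, f in enumerate(names):
        if f in dropped:
            continue
        retained.append(f)
        for g in names[j + 1 :]:
            if g in dropped:
                continue
            r = corr.loc[f, g]
            if np.isfinite(r) and abs(r) >= r_cut:
                dropped.add(g)
                dropped_log.append((f, g, float(r)))
    return retained, dropped_log


def standardize_minmax(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Linear rescale of a vector to [-50, +50] (min -> -50, max -> +50).

    Missing values are ignored for the range and preserved in the output.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise InvalidConfigError("no finite values to standardize")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise ConstantFactorError("constant vector has zero range")
    out = -50.0 + 100.0 * (arr - lo) / (hi - lo)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


@dataclass
class RegressionResult:
    """OLS fit of one module eigengene on the (standardized) factors."""

    response: str
    table: pd.DataFrame  # index: factors + Intercept; columns: coefficient, t, p, stars
    r_squared: float
    f_pvalue: float
    n: int

    def coefficient(self, factor: str) -> float:
        return float(self.table.loc[factor, "coefficient"])


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def fit_module_regression(
    eigengene: pd.Series, factors: pd.DataFrame, response_name: str = "eigengene"
) -> RegressionResult:
    """Multiple linear regression of an eigengene on environmental factors.

    Complete cases only; the design must be full rank (prune collinear
    factors first).  Both sides are expected to be pre-standardized (the
    [-50, +50] convention); the function does not rescale.
    """
    shared = [s for s in eigengene.index if s in factors.index]
    y = eigengene.loc[shared].to_numpy(dtype=float)
    X = factors.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[ok], X[ok]
    n, k = X.shape
    if n <= k + 1:
        raise InvalidConfigError("need more complete cases than parameters")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RankDeficientDesignError(
            "design matrix is rank deficient; run drop_collinear_factors first"
        )
    fit = sm.OLS(y, design).fit()
    names = ["Intercept"] + list(factors.columns)
    table = pd.DataFrame(
        {
            "coefficient": fit.params,
            "t": fit.tvalues,
            "p": fit.pvalues,
        },
        index=names,
    )
    table["stars"] = [_stars(p) for p in table["p"]]
    # factors first, intercept last (regression-table layout)
    table = table.reindex(list(factors.columns) + ["Intercept"])
    return RegressionResult(
        response=response_name,
        table=table,
        r_squared=float(fit.rsquared),
        f_pvalue=float(fit.f_pvalue),
        n=int(n),
    )


@dataclass
class BiplotResult:
    """PCA of the module x factor correlation matrix."""

    module_scores: pd.DataFrame  # modules x (PC1, PC2)
    factor_loadings: pd.DataFrame  # factors x (PC1, PC2)
    variance_fractions: np.ndarray


def correlation_pca_biplot(
    cortable: CorrelationTable, impute_missing: bool = False
) -> BiplotResult:
    """PCA biplot computed on the correlation-coefficient matrix.

    Modules are observations, factors variables; columns are centered but
    not rescaled (the cells already share the r scale).  Missing cells abort
    unless ``impute_missing`` replaces them with 0 (with a warning).
    """
    r = cortable.r.copy()
    if r.shape[0] < 3:
        raise InvalidConfigError("biplot needs at least 3 modules")
    if r.isna().any().any():
        if not impute_missing:
            raise InvalidConfigError(
                "missing correlation cells; pass impute_missing=True to zero-fill"
            )
        warnings.warn("missing correlation cells imputed with 0")
        r = r.fillna(0.0)
    x = r.to_numpy(dtype=float)
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = (s**2).sum()
    ncomp = min(2, s.size)
    scores = u[:, :ncomp] * s[:ncomp]
    loadings = vt[:ncomp].T
    fractions = (s[:ncomp] ** 2) / total if total > 0 else np.zeros(ncomp)
    cols = [f"PC{i + 1}" for i in range(ncomp)]
    return BiplotResult(
        module_scores=pd.DataFrame(scores, index=r.index, columns=cols),
        factor_loadings=pd.DataFrame(loadings, index=r.columns, columns=cols),
        variance_fractions=fractions,
    )


def gene_eigengene_crosscorrelation(
    expr: ExpressionMatrix,
    source_module_genes: list[str],
    target_eigengene: pd.Series,
    alpha_levels: tuple[float, ...] = (0.01, 0.001),
    bin_width: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Correlate every source-module gene with another module's eigengene.

    Returns ``(per_gene, counts, histogram)``: per-gene r and p; counts of
    significantly positive/negative genes at each alpha; and fixed-width
    histogram bins of the r values over [-1, 1] for frequency plots.
    """
    y = target_eigengene.reindex(expr.sample_ids).to_numpy(dtype=float)
    x = expr.values.loc[list(source_module_genes)].to_numpy(dtype=float)
    n = y.size
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean()
    denom = np.sqrt((xm**2).sum(axis=1) * (ym**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((xm @ ym) / denom, -1.0, 1.0)
    p = np.array([_pearson_p(v, n) for v in r])
    per_gene = pd.DataFrame(
        {"r": r, "p": p}, index=pd.Index(source_module_genes, name="gene_id")
    )
    rows = []
    for alpha in alpha_levels:
        sig = per_gene["p"] < alpha
        rows.append(
            {
                "alpha": alpha,
                "positive": int((sig & (per_gene["r"] > 0)).sum()),
                "negative": int((sig & (per_gene["r"] < 0)).sum()),
            }
        )
    counts = pd.DataFrame(rows).set_index("alpha")
    nbins = int(round(2.0 / bin_width))
    edges = np.linspace(-1.0, 1.0, nbins + 1)
    hist, _ = np.histogram(per_gene["r"].dropna(), bins=edges)
    histogram = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}
    )
    return per_gene, counts, histogram


def eigengene_correlation(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    """Pearson r between two eigengenes with a two-sided t-test p."""
    shared = [s for s in a.index if s in b.index]
    if len(shared) < 4:
        raise InvalidConfigError("need at least 4 shared samples")
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantFactorError("degenerate (constant) eigengene")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, _pearson_p(r, len(shared))
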