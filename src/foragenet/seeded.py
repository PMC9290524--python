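"""Seeded coexpression module construction.

Instead of unsupervised network clustering, a module can be grown from a
small curated list of marker genes: seeds are the candidates whose profiles
correlate significantly (with the requested sign) with an environmental
factor; the seeds' PC1 sample scores summarize the response; every filtered
gene whose profile correlates with those scores above a threshold joins the
module.  Overlap with an existing module set and eigengene correlations then
quantify whether the seeded module is genuinely new.  This is the procedure
used to probe for a low-nitrate response module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from foragenet.errors import ConstantFactorError, InvalidConfigError
from foragenet.expression import ExpressionMatrix
from foragenet.network import ModuleSet, compute_eigengene

__all__ = [
    "SeedModuleResult",
    "select_seed_genes",
    "seed_scores",
    "extract_seeded_module",
    "overlap_with_modules",
]


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of ``x`` (genes x samples) against ``y``, with
    two-sided p-values from the t distribution with n-2 df."""
    n = y.size
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean()
    denom = np.sqrt((xm**2).sum(axis=1) * (ym**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm @ ym) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), np.nan, np.where(np.isinf(t), 0.0, p))
    return r, p


@dataclass
class SeedModuleResult:
    """Outcome of the seeded-module procedure."""

    seed_genes: list[str]
    seed_pc1: pd.Series
    #: member gene -> Pearson r with the seed PC1 scores
    members: pd.Series
    r_threshold: float
    eigengene: pd.Series | None = None
    #: existing module -> number of members shared with it
    overlap: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    #: existing module -> Pearson r between eigengenes
    eigengene_correlations: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def member_genes(self) -> list[str]:
        return list(self.members.index)


def select_seed_genes(
    expr: ExpressionMatrix,
    candidate_genes: list[str],
    factor: pd.Series,
    alpha: float = 0.05,
    direction: str = "negative",
) -> pd.DataFrame:
    """Seeds = candidates significantly correlated with a factor.

    Pearson r of each candidate against the per-sample factor values, with a
    two-sided p from the t distribution (n-2 df); genes with ``p < alpha``
    and r of the requested sign (``"negative"``, ``"positive"`` or
    ``"both"``) are returned as a DataFrame with columns r, p.
    """
    if not candidate_genes:
        raise InvalidConfigError("candidate gene list is empty")
    fac = factor.reindex(expr.sample_ids).to_numpy(dtype=float)
    ok = np.isfinite(fac)
    if ok.sum() < 4:
        raise InvalidConfigError("factor needs at least 4 non-missing values")
    if np.ptp(fac[ok]) == 0:
        raise ConstantFactorError(f"factor {factor.name!r} is constant")
    x = expr.values.loc[list(candidate_genes)].to_numpy(dtype=float)[:, ok]
    r, p = _pearson_with_p(x, fac[ok])
    table = pd.DataFrame({"r": r, "p": p}, index=pd.Index(candidate_genes, name="gene_id"))
    keep = table["p"] < alpha
    if direction == "negative":
        keep &= table["r"] < 0
    elif direction == "positive":
        keep &= table["r"] > 0
    elif direction != "both":
        raise InvalidConfigError("direction must be negative, positive or both")
    return table.loc[keep]


def seed_scores(expr: ExpressionMatrix, seeds: list[str]) -> pd.Series:
    """PC1 sample scores of the seed genes.

    Identical computation contract as the module eigengene (z-score, SVD,
    unit variance, sign oriented to a positive mean seed correlation).
    """
    scores, _ = compute_eigengene(expr, seeds)
    scores = scores.rename("seed_pc1")
    return scores


def extract_seeded_module(
    expr: ExpressionMatrix,
    seed_pc1: pd.Series,
    r_threshold: float = 0.5,
    seed_genes: list[str] | None = None,
) -> SeedModuleResult:
    """All genes with ``|r| > r_threshold`` against the seed PC1 scores.

    The inequality is strict: a gene at exactly the threshold is excluded.
    """
    if not 0 < r_threshold < 1:
        raise InvalidConfigError("r_threshold must lie in (0, 1)")
    y = seed_pc1.reindex(expr.sample_ids).to_numpy(dtype=float)
    x = expr.values.to_numpy(dtype=float)
    r, _ = _pearson_with_p(x, y)
    keep = np.abs(r) > r_threshold
    members = pd.Series(r[keep], index=expr.values.index[keep], name="r")
    result = SeedModuleResult(
        seed_genes=list(seed_genes or []),
        seed_pc1=seed_pc1,
        members=members,
        r_threshold=r_threshold,
    )
    if len(members) >= 1:
        eig, _ = compute_eigengene(expr, result.member_genes)
        result.eigengene = eig
    return result


def overlap_with_modules(
    result: SeedModuleResult, modules: ModuleSet
) -> tuple[pd.Series, pd.Series]:
    """Shared-member counts and eigengene correlations vs an existing ModuleSet.

    Returns ``(overlap, eigengene_r)``: per existing module, the number of
    seeded-module members it contains, and the Pearson correlation between
    the seeded eigengene and that module's eigengene.  Both are also stored
    on ``result``.
    """
    member_set = set(result.member_genes)
    counts = {}
    for m in modules.module_names:
        counts[m] = len(member_set & set(modules.members(m)))
    overlap = pd.Series(counts, dtype=int).sort_values(ascending=False)
    cors = {}
    if result.eigengene is not None and not modules.eigengenes.empty:
        e = result.eigengene.to_numpy(dtype=float)
        for m in modules.eigengenes.index:
            other = modules.eigengenes.loc[m].to_numpy(dtype=float)
            cors[m] = float(np.corrcoef(e, other)[0, 1])
    eigengene_r = pd.Series(cors, dtype=float)
    result.overlap = overlap
    result.eigengene_correlations = eigengene_r
    return overlap, eigengene_r
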