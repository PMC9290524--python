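"""Module decomposition and functional characterization.

A detected coexpression module is split into submodules by k-means under
correlation distance (implemented as k-means on row-z-scored profiles, for
which squared Euclidean distance is monotone in ``1 - r``), member genes are
projected by PCA for inspection, and GO-term over-representation is tested
per gene set with one-sided Fisher's exact tests and Benjamini-Hochberg
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from foragenet.errors import DegenerateModuleError, InvalidConfigError
from foragenet.expression import ExpressionMatrix, GeneAnnotation

__all__ = [
    "SubmoduleSet",
    "EnrichmentResult",
    "kmeans_submodules",
    "module_pca",
    "go_enrichment",
]


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise DegenerateModuleError("constant gene in module; z-score undefined")
    return (x - mu) / sd


@dataclass
class SubmoduleSet:
    """k-means decomposition of one parent module.

    ``labels`` maps member gene -> submodule index in 1..k; ``centroids`` is
    k x samples on the z-score scale; ``mean_kme`` is the mean correlation of
    each submodule's genes with the parent-module eigengene (when one was
    supplied).
    """

    parent: str
    k: int
    labels: pd.Series
    centroids: np.ndarray
    inertia: float
    mean_kme: dict[int, float] = field(default_factory=dict)


def kmeans_submodules(
    expr: ExpressionMatrix,
    module_genes: list[str],
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 20,
    parent: str = "module",
    parent_eigengene: pd.Series | None = None,
) -> SubmoduleSet:
    """Split a module into ``k`` submodules under correlation distance.

    Rows are z-scored across samples and clustered with k-means (best of
    ``n_restarts`` by within-cluster sum of squares, deterministic under
    ``seed``).  On z-scored rows, ``||z_i - z_j||^2 = 2 n (1 - r_ij)``, so
    the objective is the centered-correlation distance.
    """
    if k < 2:
        raise InvalidConfigError("k must be >= 2")
    if len(module_genes) < k:
        raise InvalidConfigError("module smaller than the requested k")
    z = _zscore_rows(expr.values.loc[list(module_genes)].to_numpy(dtype=float))
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(z)
    # deterministic submodule numbering: by first-member position
    order = sorted(range(k), key=lambda c: int(np.flatnonzero(raw == c)[0]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series(
        [remap[c] for c in raw], index=pd.Index(module_genes, name="gene_id")
    )
    centroids = km.cluster_centers_[order]
    mean_kme: dict[int, float] = {}
    if parent_eigengene is not None:
        eig = parent_eigengene.to_numpy(dtype=float)
        eigz = (eig - eig.mean()) / eig.std()
        r = z @ eigz / z.shape[1]
        for sub in range(1, k + 1):
            mean_kme[sub] = float(r[labels.to_numpy() == sub].mean())
    return SubmoduleSet(
        parent=parent,
        k=k,
        labels=labels,
        centroids=centroids,
        inertia=float(km.inertia_),
        mean_kme=mean_kme,
    )


def module_pca(
    expr: ExpressionMatrix, module_genes: list[str], n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of module member genes (genes as observations).

    Member rows are z-scored across samples, sample dimensions are centered,
    and the genes are projected on the leading principal components.
    Returns (gene scores DataFrame with columns PC1..PCn, variance
    fractions).
    """
    if len(module_genes) < 3:
        raise InvalidConfigError("module PCA needs at least 3 genes")
    sub = expr.values.loc[list(module_genes)]
    if sub.shape[1] < 3:
        raise InvalidConfigError("module PCA needs at least 3 samples")
    z = _zscore_rows(sub.to_numpy(dtype=float))
    centered = z - z.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    total = (s**2).sum()
    n_components = min(n_components, s.size)
    if total == 0:
        # all member profiles identical after standardization: the gene cloud
        # is a single point, every component carries zero variance
        warnings.warn("module has rank 0 after centering; zero scores returned")
        frame = pd.DataFrame(
            np.zeros((len(module_genes), n_components)),
            index=pd.Index(module_genes, name="gene_id"),
            columns=[f"PC{i + 1}" for i in range(n_components)],
        )
        return frame, np.zeros(n_components)
    scores = u[:, :n_components] * s[:n_components]
    fractions = (s[:n_components] ** 2) / total
    frame = pd.DataFrame(
        scores,
        index=pd.Index(module_genes, name="gene_id"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, fractions


def fisher_pvalue(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (over-representation) Fisher's exact test on a 2x2 table.

    Returns (odds ratio, p).  This is the exact hypergeometric upper tail
    P(X >= a) with X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b).
    """
    odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


@dataclass
class EnrichmentResult:
    """One GO term's 2x2 over-representation test.

    ``a`` = in-set annotated, ``b`` = in-set not annotated, ``c`` = out-set
    annotated, ``d`` = out-set not annotated.
    """

    term: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    fdr: float


def go_enrichment(
    genes: list[str] | set[str],
    universe: list[str] | set[str],
    annotation: GeneAnnotation,
    fdr_threshold: float = 0.01,
    return_all: bool = False,
) -> list[EnrichmentResult]:
    """One-sided Fisher's exact GO enrichment with BH correction.

    For every term annotating at least one universe gene, tests whether the
    term is over-represented in ``genes`` relative to the rest of the
    universe.  Terms with BH-adjusted FDR below ``fdr_threshold`` are
    returned sorted by raw p (all tested terms if ``return_all``).
    """
    universe = set(universe)
    genes = set(genes)
    if not universe:
        raise InvalidConfigError("empty gene universe")
    if not genes <= universe:
        raise InvalidConfigError("gene set must be a subset of the universe")
    term_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in annotation.terms.get(g, ()):
            term_genes.setdefault(t, set()).add(g)
    dropped = [t for t, s in term_genes.items() if not s]
    if dropped:
        warnings.warn(f"terms annotating no universe gene skipped: {dropped[:5]}")
    terms = sorted(t for t, s in term_genes.items() if s)
    if not terms:
        return []
    n_in = len(genes)
    n_out = len(universe) - n_in
    results = []
    for t in terms:
        ann = term_genes[t]
        a = len(ann & genes)
        b = n_in - a
        c = len(ann) - a
        d = n_out - c
        odds, p = fisher_pvalue(a, b, c, d)
        results.append(EnrichmentResult(t, a, b, c, d, odds, p, np.nan))
    _, fdrs, _, _ = multipletests([r.p for r in results], method="fdr_bh")
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    results.sort(key=lambda r: (r.p, r.term))
    if return_all:
        return results
    return [r for r in results if r.fdr < fdr_threshold]


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view matching the TSV interface ``term,a,b,c,d,odds_ratio,p,fdr``."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "fdr": r.fdr,
            }
            for r in results
        ]
    )
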