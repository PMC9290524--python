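"""Weighted gene coexpression network construction and module detection.

The workflow follows the canonical weighted-network recipe: an unsigned
adjacency ``a_ij = |cor(x_i, x_j)|**beta`` with the soft power ``beta`` chosen
by a scale-free topology fit, the topological overlap matrix (TOM) as a
neighbourhood-sharing similarity, average-linkage clustering of ``1 - TOM``,
a static height cut with a minimum module size, module eigengenes (PC1 sample
scores of the standardized member expression), eigengene-similarity merging,
and kME connectivity (gene-eigengene correlation).

Deviations from the reference tooling are deliberate and documented in the
package methods note: the tree is cut at a fixed height rather than with the
dynamic hybrid algorithm, and genes left unassigned by the cut can be rescued
by their kME (the analogue of the partitioning-around-medoids stage).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from foragenet.errors import ConstantGeneError, DegenerateModuleError, InvalidConfigError
from foragenet.expression import ExpressionMatrix

__all__ = [
    "SoftThresholdScan",
    "AdjacencyMatrix",
    "TomMatrix",
    "ModuleSet",
    "pick_soft_threshold",
    "adjacency",
    "topological_overlap",
    "cluster_genes",
    "cut_modules",
    "compute_eigengene",
    "merge_modules",
    "module_connectivity",
    "percentile_gene_profile",
    "detect_modules",
    "MODULE_COLOR_NAMES",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"

#: size-ranked module names, echoing the colour-code convention of the
#: reference implementation (largest module first).
MODULE_COLOR_NAMES = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


def _expr_array(expr: ExpressionMatrix) -> np.ndarray:
    return expr.values.to_numpy(dtype=float)


def _check_no_constant_genes(x: np.ndarray, gene_ids: list[str]) -> None:
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [gene_ids[i] for i in bad[:5]]
        raise ConstantGeneError(
            f"{bad.size} genes have zero variance (e.g. {names}); "
            "remove them before network construction"
        )


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return (x - mu) / sd


def _abs_correlation(x: np.ndarray) -> np.ndarray:
    r = np.corrcoef(x)
    np.clip(np.abs(r), 0.0, 1.0, out=r)
    return r


@dataclass
class SoftThresholdScan:
    """Scale-free fit index and mean connectivity per candidate power."""

    powers: list[float]
    fit_r2: list[float]
    mean_connectivity: list[float]
    chosen_power: float
    target_r2: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": self.powers,
                "fit_r2": self.fit_r2,
                "mean_connectivity": self.mean_connectivity,
            }
        )


@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    a: np.ndarray
    power: float


@dataclass
class TomMatrix:
    gene_ids: list[str]
    tom: np.ndarray


@dataclass
class ModuleSet:
    """Gene->module labels with per-module eigengenes and kME connectivity.

    ``eigengenes`` is modules x samples; ``kme`` is genes x modules
    (correlation of every gene with every module eigengene).  Genes not in
    any module carry the reserved label ``"unassigned"``.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)
    kme: pd.DataFrame = field(default_factory=pd.DataFrame)
    explained_variance: dict[str, float] = field(default_factory=dict)

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.labels.unique() if m != UNASSIGNED]

    @property
    def sizes(self) -> pd.Series:
        counts = self.labels[self.labels != UNASSIGNED].value_counts()
        return counts.sort_values(ascending=False)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index of a connectivity vector.

    Genes are binned by connectivity into ``n_bins`` equal-width bins; the
    log10 bin frequency is regressed on the log10 mean connectivity over
    non-empty bins, and the index is ``-sign(slope) * R**2`` (positive when
    the degree distribution decays, as a power law does).  Degenerate inputs
    (all connectivities equal, or fewer than three usable bins) return 0.
    """
    k = np.asarray(k, dtype=float)
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0
    counts, edges = np.histogram(k, bins=n_bins)
    means = np.full(n_bins, np.nan)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            means[b] = k[sel].mean()
    ok = (counts > 0) & np.isfinite(means) & (means > 0)
    if ok.sum() < 3:
        return 0.0
    x = np.log10(means[ok])
    y = np.log10(counts[ok])
    if np.ptp(x) == 0:
        return 0.0
    res = linregress(x, y)
    return float(-np.sign(res.slope) * res.rvalue**2)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers: list[float] | None = None,
    target_r2: float = 0.9,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan soft powers for scale-free topology.

    For each power the whole-network connectivity ``k_i = sum_j |r_ij|**beta``
    is computed and scored with :func:`scale_free_fit`.  The chosen power is
    the smallest one reaching ``target_r2``; if none does, the power with the
    best fit index is returned.
    """
    if powers is None:
        powers = list(range(1, 21))
    x = _expr_array(expr)
    if x.shape[0] < 30:
        raise InvalidConfigError("soft-threshold scan needs at least 30 genes")
    if x.shape[1] < 4:
        raise InvalidConfigError("soft-threshold scan needs at least 4 samples")
    _check_no_constant_genes(x, expr.gene_ids)
    absr = _abs_correlation(x)
    np.fill_diagonal(absr, 0.0)
    fits: list[float] = []
    mean_k: list[float] = []
    for beta in powers:
        k = (absr**beta).sum(axis=1)
        fits.append(scale_free_fit(k, n_bins=n_bins))
        mean_k.append(float(k.mean()))
    chosen = None
    for beta, fit in zip(powers, fits):
        if fit >= target_r2:
            chosen = beta
            break
    if chosen is None:
        chosen = powers[int(np.argmax(fits))]
    return SoftThresholdScan(
        powers=list(powers),
        fit_r2=fits,
        mean_connectivity=mean_k,
        chosen_power=float(chosen),
        target_r2=target_r2,
    )


def adjacency(expr: ExpressionMatrix, power: float) -> AdjacencyMatrix:
    """Unsigned weighted adjacency ``a_ij = |pearson(x_i, x_j)|**power``."""
    if power <= 0:
        raise InvalidConfigError("soft power must be positive")
    x = _expr_array(expr)
    _check_no_constant_genes(x, expr.gene_ids)
    a = _abs_correlation(x) ** power
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(gene_ids=expr.gene_ids, a=a, power=power)


def topological_overlap(adj: AdjacencyMatrix) -> TomMatrix:
    """Unsigned topological overlap matrix.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` where
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{j != i} a_ij``;
    the diagonal is 1.  Cells whose denominator vanishes (isolated gene
    pairs) are defined as 0.
    """
    a = adj.a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # diagonal of `a` is zero, so u != i and u != j are excluded
    num = l + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TomMatrix(gene_ids=list(adj.gene_ids), tom=tom)


def cluster_genes(tom: TomMatrix) -> np.ndarray:
    """Average-linkage hierarchical clustering on dissimilarity 1 - TOM.

    Returns a scipy linkage matrix over the genes in ``tom.gene_ids`` order.
    """
    if len(tom.gene_ids) < 2:
        raise InvalidConfigError("clustering needs at least 2 genes")
    diss = 1.0 - tom.tom
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(np.clip(diss, 0.0, None), checks=False)
    return linkage(condensed, method="average")


def cut_modules(
    dendrogram: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 30,
    cut_height: float = 0.995,
) -> ModuleSet:
    """Static tree cut: branches below ``cut_height`` with at least
    ``min_module_size`` leaves become modules; all other genes are
    ``"unassigned"``.  Modules are named by size rank from the standard
    colour list.
    """
    if min_module_size < 2:
        raise InvalidConfigError("min_module_size must be >= 2")
    flat = fcluster(dendrogram, t=cut_height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=pd.Index(gene_ids, name="gene_id"), dtype=object)
    sizes = pd.Series(flat).value_counts()
    big = sizes[sizes >= min_module_size]
    # deterministic naming: by size desc, ties by first-gene position
    order = sorted(
        big.index,
        key=lambda c: (-big[c], int(np.flatnonzero(flat == c)[0])),
    )
    for rank, cluster_id in enumerate(order):
        name = (
            MODULE_COLOR_NAMES[rank]
            if rank < len(MODULE_COLOR_NAMES)
            else f"module{rank + 1}"
        )
        labels.iloc[np.flatnonzero(flat == cluster_id)] = name
    return ModuleSet(labels=labels)


def compute_eigengene(
    expr: ExpressionMatrix, gene_subset: list[str]
) -> tuple[pd.Series, float]:
    """Module eigengene: PC1 sample scores of the standardized member rows.

    Each member gene is z-scored across samples; the first right singular
    vector of the resulting genes-x-samples matrix gives the sample scores,
    rescaled to unit variance and sign-oriented so that the mean correlation
    with the member genes is positive.  Returns the eigengene Series and the
    explained-variance fraction of PC1.
    """
    if len(gene_subset) < 1:
        raise InvalidConfigError("eigengene needs at least one gene")
    sub = expr.values.loc[list(gene_subset)]
    if sub.shape[1] < 3:
        raise InvalidConfigError("eigengene needs at least 3 samples")
    x = sub.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).all():
        raise DegenerateModuleError("all member genes are constant")
    x = x[sd > 0]
    z = _zscore_rows(x)
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    scores = scores / scores.std()
    if np.mean([np.corrcoef(row, scores)[0, 1] for row in z]) < 0:
        scores = -scores
    explained = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(scores, index=expr.values.columns, name="eigengene"), explained


def _eigengenes_for(
    expr: ExpressionMatrix, labels: pd.Series
) -> tuple[pd.DataFrame, dict[str, float]]:
    modules = [m for m in labels.unique() if m != UNASSIGNED]
    rows, ev = {}, {}
    for m in modules:
        genes = list(labels.index[labels == m])
        eig, frac = compute_eigengene(expr, genes)
        rows[m] = eig
        ev[m] = frac
    eigengenes = pd.DataFrame(rows).T
    if not eigengenes.empty:
        eigengenes = eigengenes[expr.sample_ids]
    return eigengenes, ev


def attach_eigengenes(expr: ExpressionMatrix, modules: ModuleSet) -> ModuleSet:
    """Compute (or refresh) eigengenes and kME for a labelled ModuleSet."""
    eigengenes, ev = _eigengenes_for(expr, modules.labels)
    kme = module_connectivity(expr, eigengenes)
    return ModuleSet(
        labels=modules.labels.copy(),
        eigengenes=eigengenes,
        kme=kme,
        explained_variance=ev,
    )


def merge_modules(
    expr: ExpressionMatrix, modules: ModuleSet, merge_height: float
) -> ModuleSet:
    """Greedily merge modules whose eigengene dissimilarity is below a height.

    While any pair of eigengenes has ``1 - cor < merge_height``, the closest
    pair is merged (the larger module keeps its name) and its eigengene is
    recomputed.  Mirrors construction-time merging at 0.2 followed by a
    coarser pass at 0.3.
    """
    if modules.eigengenes.empty:
        modules = attach_eigengenes(expr, modules)
    labels = modules.labels.copy()
    while True:
        names = [m for m in labels.unique() if m != UNASSIGNED]
        if len(names) < 2:
            break
        eig, _ = _eigengenes_for(expr, labels)
        cors = np.corrcoef(eig.loc[names].to_numpy())
        diss = 1.0 - cors
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_height:
            break
        a, b = names[i], names[j]
        keep, drop = (a, b) if (labels == a).sum() >= (labels == b).sum() else (b, a)
        labels[labels == drop] = keep
    return attach_eigengenes(expr, ModuleSet(labels=labels))


def module_connectivity(
    expr: ExpressionMatrix, eigengenes: pd.DataFrame
) -> pd.DataFrame:
    """kME table: Pearson correlation of every gene with every eigengene."""
    if eigengenes.empty:
        return pd.DataFrame(index=expr.values.index)
    x = _expr_array(expr)
    _check_no_constant_genes(x, expr.gene_ids)
    zg = _zscore_rows(x)
    ze = _zscore_rows(eigengenes.to_numpy(dtype=float))
    kme = zg @ ze.T / x.shape[1]
    return pd.DataFrame(
        np.clip(kme, -1.0, 1.0), index=expr.values.index, columns=eigengenes.index
    )


def rank_by_connectivity(modules: ModuleSet, module: str) -> list[str]:
    """Member genes of ``module`` sorted by own-module kME, highest first.

    kME ties break by gene id (lexicographic).
    """
    members = modules.members(module)
    kme = modules.kme.loc[members, module]
    order = sorted(members, key=lambda g: (-kme[g], g))
    return order


def percentile_gene_profile(
    expr: ExpressionMatrix,
    modules: ModuleSet,
    module: str,
    reference_gene: str,
    percentiles: list[float] = (1, 50, 100),
    sample_groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Expression of connectivity-percentile genes relative to a reference.

    The module members are ranked by own-module kME; the gene at percentile
    ``p`` is the one at rank ``ceil(p/100 * module size)`` (rank 1 = highest
    kME).  The output holds, per sample, the expression ratio of each
    percentile gene to ``reference_gene`` (NaN where the reference is zero),
    plus optional sample grouping keys (e.g. genotype-site combinations).
    """
    members = modules.members(module)
    if reference_gene not in members:
        raise InvalidConfigError("reference gene must belong to the module")
    for p in percentiles:
        if not 1 <= p <= 100:
            raise InvalidConfigError("percentiles must lie in [1, 100]")
    order = rank_by_connectivity(modules, module)
    ref = expr.values.loc[reference_gene]
    out = pd.DataFrame(index=expr.values.columns)
    if sample_groups is not None:
        out["group"] = sample_groups.reindex(out.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        for p in percentiles:
            rank = math.ceil(p / 100 * len(order))
            gene = order[rank - 1]
            ratio = expr.values.loc[gene] / ref.where(ref != 0)
            out[f"p{p:g}:{gene}"] = ratio
    return out


def detect_modules(
    expr: ExpressionMatrix,
    power: float | None = None,
    min_module_size: int = 30,
    cut_height: float = 0.995,
    merge_heights: tuple[float, ...] = (0.2, 0.3),
    kme_assign_threshold: float | None = 0.5,
    target_r2: float = 0.9,
) -> tuple[ModuleSet, SoftThresholdScan | None]:
    """One-step module detection.

    Runs the full chain: soft-threshold scan (unless ``power`` is given),
    adjacency, TOM, average-linkage clustering, static cut, eigengene
    merging at each height in ``merge_heights``, and finally an optional kME
    rescue pass that assigns every gene (including ones the static cut left
    out) to the module of its strongest kME when that kME reaches
    ``kme_assign_threshold``.
    """
    scan = None
    if power is None:
        scan = pick_soft_threshold(expr, target_r2=target_r2)
        power = scan.chosen_power
    adj = adjacency(expr, power)
    tom = topological_overlap(adj)
    tree = cluster_genes(tom)
    modules = cut_modules(tree, tom.gene_ids, min_module_size, cut_height)
    if not modules.module_names:
        warnings.warn("static cut produced no module; all genes unassigned")
        return modules, scan
    modules = attach_eigengenes(expr, modules)
    for h in merge_heights:
        modules = merge_modules(expr, modules, h)
    if kme_assign_threshold is not None:
        labels = modules.labels.copy()
        kme = modules.kme
        best = kme.abs().idxmax(axis=1)
        bestval = kme.abs().max(axis=1)
        reassign = bestval >= kme_assign_threshold
        labels[reassign] = best[reassign]
        labels[~reassign] = UNASSIGNED
        # enforce the minimum size after rescue
        for m, n in labels.value_counts().items():
            if m != UNASSIGNED and n < min_module_size:
                labels[labels == m] = UNASSIGNED
        if (labels != UNASSIGNED).any():
            modules = attach_eigengenes(expr, ModuleSet(labels=labels))
        else:
            modules = ModuleSet(labels=labels)
    return modules, scan
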