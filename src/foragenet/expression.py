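"""Expression preprocessing: TPM normalization, filtering, log transform.

The preprocessing contract is the standard bulk RNA-seq one: raw read counts
together with transcript lengths are converted to transcripts-per-kilobase
million (TPM), genes with mean TPM below a threshold (default 5) are removed,
and the retained matrix is transformed to log2(TPM + 1) before any network
computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from foragenet.errors import InvalidConfigError

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "GeneAnnotation",
    "counts_to_tpm",
    "filter_by_mean_tpm",
    "log_transform",
    "inverse_log_transform",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_go_annotation_tsv",
    "write_go_annotation_tsv",
]


@dataclass
class CountMatrix:
    """Gene-by-sample raw counts plus per-gene transcript lengths (bp).

    ``counts`` is a DataFrame indexed by gene id with sample columns;
    ``lengths`` is a Series aligned to the same gene index.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        self.counts.index = self.counts.index.astype(str)
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.counts.index.has_duplicates:
            raise InvalidConfigError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise InvalidConfigError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidConfigError("negative counts")
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise InvalidConfigError("every gene needs a positive length")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values tagged with their scale.

    ``scale`` is ``"tpm"`` or ``"log2"``; operations check the tag so a
    log-scale matrix is never re-normalized or re-logged by accident.
    """

    values: pd.DataFrame
    scale: str = "tpm"
    #: sample ids whose TPM normalization was undefined (all-zero columns)
    flagged_samples: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneAnnotation:
    """gene -> set of GO term accessions, with an explicit gene universe."""

    terms: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set(self.terms)
        missing = set(self.terms) - self.universe
        if missing:
            raise InvalidConfigError(
                f"{len(missing)} annotated genes missing from the universe"
            )


def counts_to_tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Convert raw counts to TPM.

    TPM_gs = 1e6 * (count_gs / length_kb_g) / sum_g(count_gs / length_kb_g),
    so every sample column sums to 1e6. A sample with all-zero counts has no
    defined normalization; its column is emitted as zeros and the sample id
    is recorded in ``flagged_samples`` with a warning.
    """
    length_kb = counts.lengths.to_numpy(dtype=float) / 1e3
    rate = counts.counts.to_numpy(dtype=float) / length_kb[:, None]
    colsum = rate.sum(axis=0)
    flagged = [s for s, c in zip(counts.sample_ids, colsum) if c == 0]
    if flagged:
        warnings.warn(
            f"samples with all-zero counts, TPM undefined: {flagged}",
            stacklevel=2,
        )
    safe = np.where(colsum == 0, 1.0, colsum)
    tpm = 1e6 * rate / safe
    values = pd.DataFrame(tpm, index=counts.counts.index, columns=counts.counts.columns)
    return ExpressionMatrix(values=values, scale="tpm", flagged_samples=flagged)


def filter_by_mean_tpm(expr: ExpressionMatrix, threshold: float = 5.0) -> ExpressionMatrix:
    """Retain genes whose arithmetic mean TPM across samples is >= threshold.

    The boundary is inclusive: a gene averaging exactly the threshold stays.
    Gene order is preserved.
    """
    if threshold < 0:
        raise InvalidConfigError("mean-TPM threshold must be nonnegative")
    if expr.scale != "tpm":
        raise InvalidConfigError("filter_by_mean_tpm expects a TPM-scale matrix")
    keep = expr.values.mean(axis=1) >= threshold
    return ExpressionMatrix(
        values=expr.values.loc[keep].copy(),
        scale="tpm",
        flagged_samples=list(expr.flagged_samples),
    )


def log_transform(expr: ExpressionMatrix, pseudo: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudo).  The pseudo-count keeps zero TPM finite."""
    if expr.scale != "tpm":
        raise InvalidConfigError("log_transform expects a TPM-scale matrix")
    if pseudo <= 0 and (expr.values.to_numpy() <= 0).any():
        raise InvalidConfigError("pseudo-count must be positive when zeros are present")
    values = np.log2(expr.values + pseudo)
    return ExpressionMatrix(values=values, scale="log2", flagged_samples=list(expr.flagged_samples))


def inverse_log_transform(expr: ExpressionMatrix, pseudo: float = 1.0) -> ExpressionMatrix:
    """Invert :func:`log_transform`: TPM = 2**value - pseudo."""
    if expr.scale != "log2":
        raise InvalidConfigError("inverse_log_transform expects a log2-scale matrix")
    values = np.exp2(expr.values) - pseudo
    return ExpressionMatrix(values=values, scale="tpm", flagged_samples=list(expr.flagged_samples))


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: CountMatrix, path: str | Path) -> None:
    """TSV with columns ``gene_id, length_bp, <sample...>``."""
    out = counts.counts.copy()
    out.insert(0, "length_bp", counts.lengths)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    lengths = df.pop("length_bp")
    return CountMatrix(counts=df, lengths=lengths)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_expression_tsv(path: str | Path, scale: str = "tpm") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df, scale=scale)


def write_go_annotation_tsv(annotation: GeneAnnotation, path: str | Path) -> None:
    """TSV ``gene_id<TAB>GO:NNNNNNN;GO:NNNNNNN`` (one row per annotated gene)."""
    with open(path, "w") as fh:
        for gene in sorted(annotation.universe):
            terms = ";".join(sorted(annotation.terms.get(gene, ())))
            fh.write(f"{gene}\t{terms}\n")


def read_go_annotation_tsv(path: str | Path) -> GeneAnnotation:
    terms: dict[str, set[str]] = {}
    universe: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, _, rest = line.partition("\t")
            universe.add(gene)
            tset = {t for t in rest.split(";") if t}
            if tset:
                terms[gene] = tset
    return GeneAnnotation(terms=terms, universe=universe)
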