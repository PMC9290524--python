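"""Synthetic datasets with planted coexpression structure and known truth.

The generator emulates the study design the pipeline targets: a few hundred
root samples spread along wide soil-nutrient gradients (e.g. nitrate-N from
10.5 to 212 mg/kg, Bray II-P from 5.3 to 494 mg/kg), a handful of gene
modules whose eigengenes are linear responses to those latent factors, a
background of unstructured genes, and mixed plant/fungal rRNA read sets with
per-sample fungal abundance gradients.  Every generated object carries a
ground-truth record so downstream stages can be scored against the planted
structure.

The generative model is a test fixture, not a claim about field data: genes
load on their module eigengene with a planted kME, the latent profile is
mapped through an exponential link to an expected TPM (mean 50, safely above
the mean-TPM >= 5 filter), and counts are Poisson draws at a fixed library
size.  Reads are 75 bp (mirroring single-end 75-base sequencing) with
substitution errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from foragenet.dualrna import (
    FIVE_PRIME_CONSENSUS,
    THREE_PRIME_CONSENSUS,
    ReadSet,
    RrnaReferenceSet,
    write_fasta,
    write_reads_fastq,
)
from foragenet.errors import InvalidConfigError, InvalidReferenceError
from foragenet.expression import (
    CountMatrix,
    GeneAnnotation,
    write_counts_tsv,
    write_go_annotation_tsv,
)

__all__ = [
    "FactorSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_factor_table",
    "generate_expression",
    "generate_go_annotation",
    "generate_rrna_references",
    "generate_rrna_reads",
    "write_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class FactorSpec:
    """One environmental factor: range plus per-module effect weights."""

    name: str
    minimum: float
    maximum: float
    #: effect weight of this factor on each module's eigengene (len n_modules)
    weights: tuple[float, ...]
    log_uniform: bool = False


def _default_factor_specs(n_modules: int) -> tuple[FactorSpec, ...]:
    """Soil/plant-like gradients with distinct module responses.

    The ranges mirror realistic field gradients (nitrate-N 10.5-212 mg/kg,
    Bray II-P 5.3-494 mg/kg, organic matter 1-12%, leaf P 0.5-6 mg/g, pH
    4.5-8).  Each module has one dominant factor plus mild cross-loadings;
    the weight vectors are kept far from (anti-)parallel so that the planted
    eigengenes stay mutually identifiable — for an unsigned network two
    anti-correlated modules would be one and the same, and the ground truth
    would be ill-posed.
    """
    w_no3 = (-0.8, 0.0, 0.0, 0.2, 0.0)
    w_p = (-0.3, -0.8, 0.0, 0.0, 0.0)
    w_om = (0.0, 0.3, 0.8, 0.0, 0.0)
    w_leafp = (0.0, 0.0, 0.0, 0.8, -0.3)
    w_ph = (0.0, 0.0, 0.2, 0.0, 0.8)
    return (
        FactorSpec("NO3_N", 10.5, 212.0, w_no3[:n_modules], log_uniform=True),
        FactorSpec("BrayII_P", 5.3, 494.0, w_p[:n_modules], log_uniform=True),
        FactorSpec("OM", 1.0, 12.0, w_om[:n_modules]),
        FactorSpec("leaf_P", 0.5, 6.0, w_leafp[:n_modules]),
        FactorSpec("pH", 4.5, 8.0, w_ph[:n_modules]),
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults define the reference benchmark: 5 modules x 100 genes plus 500
    background genes over 100 samples, planted kME uniform in [0.6, 0.95],
    eigengene noise sd 0.3.
    """

    n_samples: int = 100
    n_modules: int = 5
    genes_per_module: int = 100
    n_background_genes: int = 500
    kme_range: tuple[float, float] = (0.6, 0.95)
    noise_sd: float = 0.3
    factor_specs: tuple[FactorSpec, ...] | None = None
    gene_length_range: tuple[int, int] = (500, 5000)
    library_size: int = 2_000_000
    mean_tpm: float = 50.0
    overdispersion: float | None = None  # negative-binomial size; None = Poisson
    rrna_error_rate: float = 0.01
    n_otus: int = 20
    reads_per_sample_range: tuple[int, int] = (20_000, 40_000)
    read_length: int = 75
    #: per-sample fungal:plant abundance ratio range (log-uniform)
    fungal_ratio_range: tuple[float, float] = (3e-3, 3e-1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor_specs is None:
            self.factor_specs = _default_factor_specs(self.n_modules)
        lo, hi = self.kme_range
        if not (0 < lo <= hi <= 1):
            raise InvalidConfigError("kme_range must be ordered within (0, 1]")
        if self.n_samples < 3:
            raise InvalidConfigError("need at least 3 samples")
        for name in (
            "n_modules",
            "genes_per_module",
            "n_background_genes",
            "library_size",
            "n_otus",
            "read_length",
        ):
            if getattr(self, name) < 0 or (
                name in ("n_modules", "genes_per_module", "library_size") and getattr(self, name) == 0
            ):
                raise InvalidConfigError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be nonnegative")
        if not 0 <= self.rrna_error_rate <= 0.2:
            raise InvalidConfigError("rrna_error_rate must lie in [0, 0.2]")
        for spec in self.factor_specs:
            if spec.minimum > spec.maximum:
                raise InvalidConfigError(f"factor {spec.name}: min > max")
            if len(spec.weights) != self.n_modules:
                raise InvalidConfigError(
                    f"factor {spec.name}: needs one weight per module"
                )

    def module_names(self) -> list[str]:
        return [f"planted{m + 1}" for m in range(self.n_modules)]

    def sample_names(self) -> list[str]:
        width = len(str(self.n_samples))
        return [f"s{i + 1:0{width}d}" for i in range(self.n_samples)]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    planted_labels: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    planted_kme: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    planted_eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: per-module sd of the raw (pre-standardization) factor response + noise;
    #: converts planted factor weights to coefficients on the eigengene scale
    planted_eigengene_scale: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    planted_factor_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: pre-link latent profiles (kME * eigengene + residual), genes x samples
    planted_latent: pd.DataFrame = field(default_factory=pd.DataFrame)
    planted_otu_abundances: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: per-sample fungal:plant abundance ratio used for the rRNA read mix
    planted_fungal_ratio: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    #: per-module enriched GO term (when an annotation was generated)
    enriched_terms: dict[str, str] = field(default_factory=dict)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # stage offsets keep the per-stage streams independent but reproducible
    return np.random.default_rng((config.seed, stage))


def generate_factor_table(config: SimulationConfig) -> pd.DataFrame:
    """Sample-by-factor table with each factor drawn within its range.

    Uniform by default, log-uniform when the spec says so (soil nutrient
    gradients are closer to log-uniform in the field).
    """
    for spec in config.factor_specs:
        if spec.minimum >= spec.maximum and spec.minimum != spec.maximum:
            raise InvalidConfigError(f"factor {spec.name}: min >= max")
    rng = _rng(config, 1)
    data = {}
    for spec in config.factor_specs:
        if spec.minimum == spec.maximum:
            vals = np.full(config.n_samples, float(spec.minimum))
        elif spec.log_uniform:
            vals = np.exp(
                rng.uniform(
                    np.log(spec.minimum), np.log(spec.maximum), config.n_samples
                )
            )
        else:
            vals = rng.uniform(spec.minimum, spec.maximum, config.n_samples)
        data[spec.name] = vals
    return pd.DataFrame(data, index=pd.Index(config.sample_names(), name="sample_id"))


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def generate_expression(
    config: SimulationConfig, factors: pd.DataFrame
) -> tuple[CountMatrix, SyntheticTruth]:
    """Counts with planted modules driven by the factor table.

    Module eigengene m = standardized(sum_f w_mf * standardized(factor_f) +
    N(0, noise_sd)); gene g of module m has latent profile
    ``kME_g * eigengene_m + sqrt(1 - kME_g^2) * N(0, 1)``; background genes
    are i.i.d. N(0, 1).  Latents map through ``exp`` scaled to a mean TPM of
    ``config.mean_tpm``, and counts are Poisson (optionally negative
    binomial) at the configured library size with per-gene lengths.
    """
    if factors.shape[0] != config.n_samples:
        raise InvalidConfigError("factor table row count != n_samples")
    rng = _rng(config, 2)
    n = config.n_samples
    module_names = config.module_names()
    z_factors = {
        spec.name: _standardize(factors[spec.name].to_numpy(dtype=float))
        if np.ptp(factors[spec.name].to_numpy()) > 0
        else np.zeros(n)
        for spec in config.factor_specs
    }
    eigengenes = np.zeros((config.n_modules, n))
    scales = np.zeros(config.n_modules)
    effects = np.zeros((config.n_modules, len(config.factor_specs)))
    for m in range(config.n_modules):
        signal = np.zeros(n)
        for f, spec in enumerate(config.factor_specs):
            effects[m, f] = spec.weights[m]
            signal = signal + spec.weights[m] * z_factors[spec.name]
        noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
        raw = signal + noise
        if np.ptp(raw) == 0:  # degenerate: no signal, no noise
            raw = rng.normal(0.0, 1.0, n)
        scales[m] = raw.std()
        eigengenes[m] = _standardize(raw)

    gene_ids: list[str] = []
    labels: list[str] = []
    kmes: list[float] = []
    latents = []
    lo, hi = config.kme_range
    for m, mod in enumerate(module_names):
        k = rng.uniform(lo, hi, config.genes_per_module)
        eps = rng.standard_normal((config.genes_per_module, n))
        lat = k[:, None] * eigengenes[m][None, :] + np.sqrt(1 - k[:, None] ** 2) * eps
        latents.append(lat)
        for i in range(config.genes_per_module):
            gene_ids.append(f"{mod}_g{i + 1:03d}")
            labels.append(mod)
            kmes.append(float(k[i]))
    if config.n_background_genes:
        latents.append(rng.standard_normal((config.n_background_genes, n)))
        for i in range(config.n_background_genes):
            gene_ids.append(f"bg_g{i + 1:04d}")
            labels.append("background")
            kmes.append(0.0)
    latent = np.vstack(latents)

    # monotone link latent -> expected TPM with per-gene mean config.mean_tpm
    expo = np.exp(latent)
    tpm_expected = config.mean_tpm * expo / expo.mean(axis=1, keepdims=True)
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, len(gene_ids)
    )
    length_kb = lengths / 1e3
    weight = tpm_expected * length_kb[:, None]
    rate = config.library_size * weight / weight.sum(axis=0, keepdims=True)
    if config.overdispersion is not None:
        size = config.overdispersion
        counts = rng.negative_binomial(size, size / (size + rate))
    else:
        counts = rng.poisson(rate)

    index = pd.Index(gene_ids, name="gene_id")
    count_matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=index, columns=factors.index),
        lengths=pd.Series(lengths, index=index, name="length_bp"),
    )
    truth = SyntheticTruth(
        planted_labels=pd.Series(labels, index=index, name="module"),
        planted_kme=pd.Series(kmes, index=index, name="kme"),
        planted_eigengenes=pd.DataFrame(
            eigengenes, index=module_names, columns=factors.index
        ),
        planted_eigengene_scale=pd.Series(scales, index=module_names),
        planted_factor_effects=pd.DataFrame(
            effects,
            index=module_names,
            columns=[s.name for s in config.factor_specs],
        ),
        planted_latent=pd.DataFrame(latent, index=index, columns=factors.index),
    )
    return count_matrix, truth


def generate_go_annotation(
    config: SimulationConfig,
    truth: SyntheticTruth,
    n_background_terms: int = 30,
    enriched_fraction: float = 0.5,
    background_rate: float = 0.02,
    terms_per_gene: float = 2.0,
) -> GeneAnnotation:
    """Random GO annotation with one planted enriched term per module.

    Background terms are assigned at random (Poisson number of terms per
    gene); each planted module additionally gets a dedicated term annotating
    ``enriched_fraction`` of its genes and ``background_rate`` of all other
    genes.
    """
    rng = _rng(config, 3)
    genes = list(truth.planted_labels.index)
    terms: dict[str, set[str]] = {g: set() for g in genes}
    pool = [f"GO:{7000000 + i:07d}" for i in range(n_background_terms)]
    for g in genes:
        k = rng.poisson(terms_per_gene)
        for t in rng.choice(pool, size=min(k, len(pool)), replace=False):
            terms[g].add(str(t))
    enriched: dict[str, str] = {}
    for m, mod in enumerate(config.module_names()):
        term = f"GO:{8000000 + m:07d}"
        enriched[mod] = term
        members = truth.planted_labels.index[truth.planted_labels == mod]
        for g in members:
            if rng.random() < enriched_fraction:
                terms[g].add(term)
        for g in truth.planted_labels.index[truth.planted_labels != mod]:
            if rng.random() < background_rate:
                terms[g].add(term)
    truth.enriched_terms = enriched
    return GeneAnnotation(terms={g: t for g, t in terms.items() if t}, universe=set(genes))


def generate_rrna_references(
    config: SimulationConfig,
    plant_length: int = 3000,
    otu_length_range: tuple[int, int] = (600, 750),
) -> RrnaReferenceSet:
    """Random rRNA references: one plant LSU-like sequence and ``n_otus``
    fungal OTUs carrying the conserved consensus termini (so trimming has
    something to remove)."""
    rng = _rng(config, 4)
    plant = "".join(
        np.char.decode(rng.choice(_BASES, size=plant_length), "ascii")
    )
    fungal: dict[str, str] = {}
    for i in range(config.n_otus):
        core_len = int(rng.integers(otu_length_range[0], otu_length_range[1] + 1))
        core = "".join(np.char.decode(rng.choice(_BASES, size=core_len), "ascii"))
        fungal[f"OTU{i + 1:03d}"] = FIVE_PRIME_CONSENSUS + core + THREE_PRIME_CONSENSUS
    return RrnaReferenceSet(plant_id="plant_LSU", plant_seq=plant, fungal=fungal)


def generate_rrna_reads(
    config: SimulationConfig,
    references: RrnaReferenceSet,
    n_samples: int | None = None,
    truth: SyntheticTruth | None = None,
    stage_offset: int = 0,
    plant_abundance: float = 1.0,
) -> tuple[ReadSet, SyntheticTruth]:
    """Reads drawn from the references proportional to planted abundances.

    Per sample, the fungal:plant abundance ratio is log-uniform within
    ``config.fungal_ratio_range`` and the fungal share is split across OTUs
    by a Dirichlet draw; a read's source is chosen proportional to abundance
    times reference length (longer molecules yield more fragments), its
    start is uniform, and substitutions are applied at
    ``config.rrna_error_rate``.  Read names encode the true source as
    ``<sample>|<ref>|<i>``.  ``stage_offset`` decorrelates repeated draws
    (e.g. two sequencing "protocols" from the same abundances);
    ``plant_abundance`` sets the host share of the mix (0 = fungal-only).
    """
    rng = _rng(config, 5 + stage_offset)
    n_samples = n_samples if n_samples is not None else config.n_samples
    read_len = config.read_length
    seqs = references.sequences()
    for rid, seq in seqs.items():
        if len(seq) < max(read_len, 150):
            raise InvalidReferenceError(
                f"reference {rid} shorter than {max(read_len, 150)} nt"
            )
    otu_ids = sorted(references.fungal)
    width = len(str(n_samples))
    samples = [f"s{i + 1:0{width}d}" for i in range(n_samples)]
    if truth is not None and not truth.planted_otu_abundances.empty:
        abundances = truth.planted_otu_abundances
        ratios = truth.planted_fungal_ratio
    else:
        lo, hi = config.fungal_ratio_range
        ratios = pd.Series(
            np.exp(rng.uniform(np.log(lo), np.log(hi), n_samples)), index=samples
        )
        comp = rng.dirichlet(np.ones(len(otu_ids)) * 2.0, size=n_samples)
        abundances = pd.DataFrame(
            comp * ratios.to_numpy()[:, None], index=samples, columns=otu_ids
        )
    ref_ids = [references.plant_id, *otu_ids]
    lengths = np.array([len(seqs[r]) for r in ref_ids], dtype=float)
    base_lookup = np.zeros(256, dtype=np.uint8)
    for code, b in enumerate(b"ACGT"):
        base_lookup[b] = code
    ref_codes = {
        r: base_lookup[np.frombuffer(seqs[r].encode(), dtype=np.uint8)]
        for r in ref_ids
    }
    reads: dict[str, list[tuple[str, str]]] = {}
    offsets = np.arange(read_len)
    for s in samples:
        ab = np.array(
            [plant_abundance, *abundances.loc[s, otu_ids].to_numpy(dtype=float)]
        )
        weight = ab * lengths
        if weight.sum() == 0:
            reads[s] = []
            continue
        prob = weight / weight.sum()
        n_reads = int(
            rng.integers(
                config.reads_per_sample_range[0], config.reads_per_sample_range[1] + 1
            )
        )
        sources = rng.choice(len(ref_ids), size=n_reads, p=prob)
        max_start = (lengths[sources] - read_len).astype(np.int64)
        starts = (rng.random(n_reads) * (max_start + 1)).astype(np.int64)
        frags = np.empty((n_reads, read_len), dtype=np.uint8)
        for src in np.unique(sources):
            sel = np.flatnonzero(sources == src)
            frags[sel] = ref_codes[ref_ids[src]][starts[sel, None] + offsets]
        if config.rrna_error_rate > 0:
            mask = rng.random((n_reads, read_len)) < config.rrna_error_rate
            shifts = rng.integers(1, 4, size=int(mask.sum()))
            frags[mask] = (frags[mask] + shifts) % 4
        chars = _BASES[frags]
        reads[s] = [
            (f"{s}|{ref_ids[src]}|{i}", chars[i].tobytes().decode())
            for i, src in enumerate(sources)
        ]
    out_truth = truth if truth is not None else SyntheticTruth()
    out_truth.planted_otu_abundances = abundances
    out_truth.planted_fungal_ratio = ratios
    return ReadSet(reads=reads), out_truth


@dataclass
class SyntheticDataset:
    """A complete generated dataset plus its ground truth."""

    config: SimulationConfig
    factors: pd.DataFrame
    counts: CountMatrix
    annotation: GeneAnnotation
    references: RrnaReferenceSet
    reads: ReadSet
    truth: SyntheticTruth


def generate_dataset(
    config: SimulationConfig, n_rrna_samples: int | None = 20
) -> SyntheticDataset:
    """Run every generator stage under one config/seed.

    ``n_rrna_samples`` defaults to 20, mirroring a design where a subset of
    the expression samples receives dedicated rRNA sequencing; pass None to
    generate reads for every sample.
    """
    factors = generate_factor_table(config)
    counts, truth = generate_expression(config, factors)
    annotation = generate_go_annotation(config, truth)
    references = generate_rrna_references(config)
    reads, truth = generate_rrna_reads(
        config, references, n_samples=n_rrna_samples, truth=truth
    )
    return SyntheticDataset(
        config=config,
        factors=factors,
        counts=counts,
        annotation=annotation,
        references=references,
        reads=reads,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> list[str]:
    """Write every dataset component as plain text; returns the manifest.

    Emits counts TSV, factor CSV, GO annotation TSV, reference FASTA, reads
    FASTQ, and the truth JSON; the manifest lists the files written (also
    saved as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    write_counts_tsv(dataset.counts, out / "counts.tsv")
    files.append("counts.tsv")
    dataset.factors.to_csv(out / "factors.csv", index_label="sample_id", float_format="%.10g")
    files.append("factors.csv")
    write_go_annotation_tsv(dataset.annotation, out / "go_annotation.tsv")
    files.append("go_annotation.tsv")
    write_fasta(dataset.references.sequences(), out / "references.fasta")
    files.append("references.fasta")
    write_reads_fastq(dataset.reads, out / "reads.fastq")
    files.append("reads.fastq")

    truth = dataset.truth
    truth_obj = {
        "planted_labels": truth.planted_labels.to_dict(),
        "planted_kme": truth.planted_kme.to_dict(),
        "planted_eigengenes": {
            m: [float(v) for v in truth.planted_eigengenes.loc[m]]
            for m in truth.planted_eigengenes.index
        },
        "eigengene_samples": list(map(str, truth.planted_eigengenes.columns)),
        "planted_factor_effects": {
            m: truth.planted_factor_effects.loc[m].to_dict()
            for m in truth.planted_factor_effects.index
        },
        "planted_otu_abundances": {
            s: truth.planted_otu_abundances.loc[s].to_dict()
            for s in truth.planted_otu_abundances.index
        },
        "planted_fungal_ratio": truth.planted_fungal_ratio.to_dict(),
        "enriched_terms": truth.enriched_terms,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_obj, fh, indent=1, sort_keys=True)
    files.append("truth.json")

    with open(out / "manifest.json", "w") as fh:
        json.dump({"files": files}, fh, indent=1)
    return files
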