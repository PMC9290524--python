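"""Pipeline orchestration: run every stage from one config, reproducibly.

The config is a flat YAML-serializable mapping; a run writes every stage
artifact into the output directory plus a JSON manifest (config hash, seed,
package version, per-stage row counts) sufficient to reproduce the run
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from foragenet import __version__, dualrna, expression, interplay, network, seeded, structure
from foragenet.errors import ForagenetError, InvalidConfigError

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths."""

    counts_tsv: str = ""
    factors_csv: str = ""
    go_annotation_tsv: str = ""
    references_fasta: str = ""
    reads_fastq: str = ""
    out_dir: str = "results"
    seed: int = 0

    mean_tpm_threshold: float = 5.0
    log_pseudo: float = 1.0

    soft_power: float | None = None
    target_r2: float = 0.9
    min_module_size: int = 30
    cut_height: float = 0.995
    merge_heights: tuple[float, ...] = (0.2, 0.3)
    kme_assign_threshold: float | None = 0.5

    submodule_k: int = 5
    submodule_restarts: int = 20
    module_fdr: float = 0.01
    submodule_fdr: float = 0.05

    seed_candidates: tuple[str, ...] = ()
    seed_factor: str = ""
    seed_alpha: float = 0.05
    seed_direction: str = "negative"
    seed_r_threshold: float = 0.5

    collinearity_cut: float = 0.9
    min_identity: float = 95.0
    min_aln_len: int = 75
    assignment_kmer: int = 15

    def validate(self) -> None:
        if self.min_module_size < 2:
            raise InvalidConfigError("min_module_size must be >= 2")
        if not 0 <= self.mean_tpm_threshold:
            raise InvalidConfigError("mean_tpm_threshold must be nonnegative")
        if self.submodule_k < 2:
            raise InvalidConfigError("submodule_k must be >= 2")
        if not 0 < self.seed_r_threshold < 1:
            raise InvalidConfigError("seed_r_threshold must lie in (0,1)")
        if self.min_identity <= 0 or self.min_aln_len <= 0:
            raise InvalidConfigError("assignment thresholds must be positive")


def save_config(config: PipelineConfig, path: str | Path) -> None:
    data = asdict(config)
    data["merge_heights"] = list(config.merge_heights)
    data["seed_candidates"] = list(config.seed_candidates)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "merge_heights" in data:
        data["merge_heights"] = tuple(data["merge_heights"])
    if "seed_candidates" in data:
        data["seed_candidates"] = tuple(data["seed_candidates"])
    return PipelineConfig(**data)


def _config_hash(config: PipelineConfig) -> str:
    data = asdict(config)
    data.pop("out_dir", None)  # artifact content does not depend on destination
    payload = json.dumps(data, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages in order, writing artifacts and a run manifest.

    Stages: expression preprocessing -> network module detection ->
    submodules + GO enrichment -> seeded module (when seeds configured) ->
    module-environment statistics -> dual-RNA quantification (when reads
    configured).  A stage failure writes a FAILED marker naming the stage
    and re-raises.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }
    save_config(config, out / "config.yaml")
    manifest["outputs"].append("config.yaml")

    stage = "expression"
    try:
        counts = expression.read_counts_tsv(config.counts_tsv)
        tpm = expression.counts_to_tpm(counts)
        filtered = expression.filter_by_mean_tpm(tpm, config.mean_tpm_threshold)
        logexpr = expression.log_transform(filtered, config.log_pseudo)
        expression.write_expression_tsv(logexpr, out / "log2_tpm.tsv")
        manifest["outputs"].append("log2_tpm.tsv")
        manifest["stages"][stage] = {
            "genes_in": counts.counts.shape[0],
            "genes_retained": logexpr.n_genes,
            "samples": logexpr.n_samples,
        }

        stage = "network"
        modules, scan = network.detect_modules(
            logexpr,
            power=config.soft_power,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            merge_heights=config.merge_heights,
            kme_assign_threshold=config.kme_assign_threshold,
            target_r2=config.target_r2,
        )
        modules.labels.to_csv(out / "module_labels.tsv", sep="\t", header=["module"])
        manifest["outputs"].append("module_labels.tsv")
        if not modules.eigengenes.empty:
            modules.eigengenes.to_csv(out / "eigengenes.csv", float_format="%.10g")
            modules.kme.to_csv(out / "kme.tsv", sep="\t", float_format="%.10g")
            manifest["outputs"] += ["eigengenes.csv", "kme.tsv"]
        if scan is not None:
            scan.as_frame().to_csv(out / "soft_threshold_scan.csv", index=False, float_format="%.10g")
            manifest["outputs"].append("soft_threshold_scan.csv")
        manifest["stages"][stage] = {
            "power": scan.chosen_power if scan is not None else config.soft_power,
            "n_modules": len(modules.module_names),
            "module_sizes": {m: int(n) for m, n in modules.sizes.items()},
        }

        stage = "structure"
        annotation = None
        if config.go_annotation_tsv:
            annotation = expression.read_go_annotation_tsv(config.go_annotation_tsv)
        structure_info: dict = {}
        if modules.module_names:
            largest = modules.sizes.index[0]
            sub = structure.kmeans_submodules(
                logexpr,
                modules.members(largest),
                k=min(config.submodule_k, len(modules.members(largest))),
                seed=config.seed,
                n_restarts=config.submodule_restarts,
                parent=largest,
                parent_eigengene=modules.eigengenes.loc[largest],
            )
            sub.labels.to_csv(out / "submodule_labels.tsv", sep="\t", header=["submodule"])
            manifest["outputs"].append("submodule_labels.tsv")
            structure_info["submodules_of"] = largest
            structure_info["k"] = sub.k
            if annotation is not None:
                universe = [g for g in logexpr.gene_ids if g in annotation.universe]
                results = structure.go_enrichment(
                    [g for g in modules.members(largest) if g in annotation.universe],
                    universe,
                    annotation,
                    fdr_threshold=config.module_fdr,
                )
                structure.enrichment_frame(results).to_csv(
                    out / "go_enrichment.tsv", sep="\t", index=False, float_format="%.10g"
                )
                manifest["outputs"].append("go_enrichment.tsv")
                structure_info["enriched_terms"] = len(results)
        manifest["stages"][stage] = structure_info

        stage = "seeded_module"
        factors = pd.read_csv(config.factors_csv, index_col="sample_id")
        if config.seed_candidates and config.seed_factor:
            seeds_table = seeded.select_seed_genes(
                logexpr,
                [g for g in config.seed_candidates if g in logexpr.gene_ids],
                factors[config.seed_factor],
                alpha=config.seed_alpha,
                direction=config.seed_direction,
            )
            info = {"n_seeds": int(len(seeds_table))}
            if len(seeds_table) >= 1:
                pc1 = seeded.seed_scores(logexpr, list(seeds_table.index))
                result = seeded.extract_seeded_module(
                    logexpr, pc1, config.seed_r_threshold, list(seeds_table.index)
                )
                overlap, eig_r = seeded.overlap_with_modules(result, modules)
                members = pd.DataFrame({"r": result.members})
                members["existing_module"] = modules.labels.reindex(members.index)
                members.to_csv(out / "seeded_members.tsv", sep="\t", float_format="%.10g")
                manifest["outputs"].append("seeded_members.tsv")
                info["n_members"] = len(result.members)
                info["overlap"] = {m: int(c) for m, c in overlap.items()}
            manifest["stages"][stage] = info
        else:
            manifest["stages"][stage] = {"skipped": True}

        stage = "env_interplay"
        if modules.module_names:
            cortable = interplay.module_factor_correlations(modules.eigengenes, factors)
            cortable.r.to_csv(out / "module_factor_r.csv", float_format="%.10g")
            manifest["outputs"].append("module_factor_r.csv")
            retained, dropped = interplay.drop_collinear_factors(
                factors, config.collinearity_cut
            ) if factors.shape[1] >= 2 else (list(factors.columns), [])
            std_factors = pd.DataFrame(
                {f: interplay.standardize_minmax(factors[f]) for f in retained}
            )
            reg_info = {}
            rows = []
            for m in modules.eigengenes.index:
                eig = interplay.standardize_minmax(modules.eigengenes.loc[m])
                try:
                    fit = interplay.fit_module_regression(eig, std_factors, m)
                except ForagenetError:
                    continue
                reg_info[m] = fit.r_squared
                t = fit.table.reset_index(names="factor")
                t.insert(0, "module", m)
                rows.append(t)
            if rows:
                pd.concat(rows).to_csv(
                    out / "module_regression.csv", index=False, float_format="%.10g"
                )
                manifest["outputs"].append("module_regression.csv")
            if cortable.r.shape[0] >= 3:
                biplot = interplay.correlation_pca_biplot(cortable, impute_missing=True)
                biplot.module_scores.to_csv(out / "biplot_scores.csv", float_format="%.10g")
                manifest["outputs"].append("biplot_scores.csv")
            manifest["stages"][stage] = {
                "factors_retained": retained,
                "factors_dropped": [d[1] for d in dropped],
                "r_squared": reg_info,
            }
        else:
            manifest["stages"][stage] = {"skipped": True}

        stage = "dualrna"
        if config.references_fasta and config.reads_fastq:
            seqs = dualrna.read_fasta(config.references_fasta)
            plant_id = next(iter(seqs))
            refs = dualrna.RrnaReferenceSet(
                plant_id=plant_id,
                plant_seq=seqs[plant_id],
                fungal={k: v for k, v in seqs.items() if k != plant_id},
            )
            refs = dualrna.trim_reference_consensus(refs)
            reads = dualrna.read_reads_fastq(config.reads_fastq)
            assignment = dualrna.assign_reads(
                reads,
                refs,
                min_identity=config.min_identity,
                min_len=config.min_aln_len,
                kmer=config.assignment_kmer,
            )
            normalized = dualrna.length_normalize_counts(assignment, refs)
            profile = dualrna.fungal_abundance_index(normalized, refs.plant_id)
            abundance = pd.DataFrame(
                {
                    "plant_normalized": profile.plant_normalized,
                    "fungal_per_1e5_plant": profile.fungal_per_1e5_plant,
                    "log_index": profile.log_index,
                }
            )
            abundance.to_csv(out / "fungal_abundance.csv", float_format="%.10g")
            manifest["outputs"].append("fungal_abundance.csv")
            manifest["stages"][stage] = {
                "n_reads": assignment.n_reads_total,
                "n_assigned": assignment.n_assigned,
                "n_samples": len(reads.sample_ids),
            }
        else:
            manifest["stages"][stage] = {"skipped": True}
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
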