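"""End-to-end orchestration of the cell/exosome small-RNA analysis.

Stage order follows the analysis flow: annotation and clusters, biotype
composition, differential expression at mature / cluster / piRNA level,
interindividual variability, pedigree haplotypes, eQTL mapping with its
confounder QC, and NTA profiling.  Every stage writes a TSV under the
output directory and contributes to a JSON summary; a log records the
seed, configuration hash, and stage status.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters as clu
from . import composition as comp
from . import diffexp as de
from . import eqtl as eq
from . import haplotypes as hap
from . import nta as ntamod
from . import simulate as sim
from ._data import CELL, EXOSOME

log = logging.getLogger("exorna")


@dataclass
class PipelineConfig:
    """Paths, thresholds, and stage toggles for one pipeline run."""

    out_dir: str = "exorna_out"
    annotation: str | None = None
    counts: str | None = None
    samples: str | None = None
    biotypes: str | None = None
    genotypes_vcf: str | None = None
    pedigree: str | None = None
    de_fdr: float = 0.01
    eqtl_fdr: float = 0.20
    min_median: float = 10.0
    cluster_gap: int = 10_000
    min_aligned: int = 16
    kmer_k: int = 10
    seed: int = 0
    synthetic: bool = True
    stages: list[str] = field(
        default_factory=lambda: [
            "clusters",
            "composition",
            "diffexp",
            "variability",
            "haplotypes",
            "eqtl",
            "nta",
        ]
    )

    def __post_init__(self):
        if not 0 < self.de_fdr < 1 or not 0 < self.eqtl_fdr < 1:
            raise ValueError("FDR thresholds must be in (0, 1)")
        if self.cluster_gap < 0 or self.min_aligned < 1 or self.kmer_k < 1:
            raise ValueError("invalid threshold configuration")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; return (and write) the summary bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    try:
        _run_stages(config, out, summary)
    except Exception as exc:  # partial outputs are retained on disk
        stage = summary.get("failed_stage", "?")
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary


def _run_stages(config: PipelineConfig, out: Path, summary: dict) -> None:
    if config.synthetic:
        summary["failed_stage"] = "simulate"
        sim_cfg = sim.SimulationConfig(seed=config.seed)
        pedigree, genotypes, annotation, counts, truth = sim.simulate_study(sim_cfg)
        sim.write_gff3(annotation, out / "annotation.gff3")
        sim.write_vcf(genotypes, out / "genotypes.vcf")
        sim.write_pedigree_tsv(pedigree, out / "pedigree.tsv")
        counts.to_tsv(out / "counts.tsv")
        counts.samples.to_csv(out / "samples.tsv", sep="\t")
        sim.write_biotypes_tsv(annotation, out / "biotypes.tsv")
        truth.to_json(out / "truth.json")
        summary["stages"]["simulate"] = "ok"
    else:
        raise NotImplementedError(
            "non-synthetic runs: load counts/annotation via the library API"
        )
    biotypes = annotation.biotypes

    if "clusters" in config.stages:
        summary["failed_stage"] = "clusters"
        cluster_map = clu.build_clusters(annotation, max_gap=config.cluster_gap)
        table = clu.cluster_table(annotation, cluster_map)
        table.to_csv(out / "clusters.tsv", sep="\t")
        summary["stages"]["clusters"] = "ok"
        summary["n_clusters"] = len(cluster_map.clusters)
        summary["n_excluded_matures"] = len(cluster_map.excluded_matures())
    else:
        cluster_map = None

    if "composition" in config.stages:
        summary["failed_stage"] = "composition"
        props = comp.biotype_proportions(counts, biotypes)
        tests = comp.compare_compositions(props, counts.samples)
        props.to_csv(out / "composition.tsv", sep="\t")
        tests.to_csv(out / "composition_tests.tsv", sep="\t")
        summary["stages"]["composition"] = "ok"
        summary["composition_significant_classes"] = sorted(
            tests.index[tests["p_bonferroni"] < 0.05].tolist()
        )

    de_results: dict[str, pd.DataFrame] = {}
    if "diffexp" in config.stages:
        summary["failed_stage"] = "diffexp"
        mirna = [t for t in counts.transcripts if biotypes.get(t) == "miRNA"]
        pirna = [t for t in counts.transcripts if biotypes.get(t) == "piRNA"]
        levels = {"mature": counts.subset_transcripts(mirna)}
        if pirna:
            levels["pirna"] = counts.subset_transcripts(pirna)
        if cluster_map is not None:
            levels["cluster"] = clu.aggregate_cluster_counts(
                counts.subset_transcripts([t for t in mirna if t in cluster_map.mature_cluster]),
                cluster_map,
            )
        for name, cm in levels.items():
            res = de.nb_differential_test(cm)
            res.to_csv(out / f"diffexp_{name}.tsv", sep="\t")
            de_results[name] = res
            summary[f"n_de_{name}"] = int((res["padj"] < config.de_fdr).sum())
            summary[f"n_tested_{name}"] = int(res["pvalue"].notna().sum())
        summary["stages"]["diffexp"] = "ok"

    if "variability" in config.stages:
        summary["failed_stage"] = "variability"
        mirna = [t for t in counts.transcripts if biotypes.get(t) == "miRNA"]
        norm = de.normalized_counts(counts)
        from . import variability as var

        rho = var.spearman_matrix(norm.loc[mirna])
        rho.to_csv(out / "spearman_mirna.tsv", sep="\t")
        linkage, leaves = var.cluster_samples(rho)
        with open(out / "dendrogram_mirna.nwk", "w") as fh:
            fh.write(var.dendrogram_newick(linkage, list(rho.index)))
        comparison = var.compare_within_compartment_variability(rho, counts.samples)
        summary["stages"]["variability"] = "ok"
        summary["mean_within_cell_rho"] = comparison.mean_within_cell
        summary["mean_within_exosome_rho"] = comparison.mean_within_exosome
        summary["variability_wilcoxon_p"] = comparison.pvalue

    blocks = None
    if "haplotypes" in config.stages:
        summary["failed_stage"] = "haplotypes"
        filtered, report = hap.mendelian_filter(genotypes, pedigree)
        report.to_csv(out / "mendelian_report.tsv", sep="\t", index=False)
        phased = hap.phase_parents(filtered, pedigree)
        trans = hap.infer_transmissions(filtered, phased, pedigree)
        blocks = hap.segment_blocks(trans)
        hap.blocks_to_bed(blocks, out / "blocks.bed")
        hap.block_codes_table(blocks).to_csv(out / "block_codes.tsv", sep="\t", index=False)
        summary["stages"]["haplotypes"] = "ok"
        summary["n_markers_dropped"] = int(genotypes.n_markers - filtered.n_markers)
        summary["n_blocks"] = len(blocks)

    if "eqtl" in config.stages and blocks is not None:
        summary["failed_stage"] = "eqtl"
        variant_positions = genotypes.markers[["chrom", "pos"]]
        fits = {}
        for compartment in (CELL, EXOSOME):
            fits[compartment] = eq.map_eqtls(
                counts,
                blocks,
                annotation,
                pedigree,
                compartment,
                variant_positions=variant_positions,
                min_median=config.min_median,
            )
            fits[compartment].to_csv(out / f"eqtl_{compartment}.tsv", sep="\t")
        shared = eq.shared_eqtls(fits[CELL], fits[EXOSOME], fdr=config.eqtl_fdr)
        shared.to_csv(out / "eqtl_shared.tsv", sep="\t")
        summary["stages"]["eqtl"] = "ok"
        summary["n_eqtl_tested_cell"] = len(fits[CELL])
        summary["n_eqtl_tested_exosome"] = len(fits[EXOSOME])
        summary["shared_eqtls"] = sorted(shared.index.tolist())
        try:
            corr = eq.effect_correlation(fits[CELL], fits[EXOSOME])
            summary["eqtl_effect_correlation"] = corr
        except ValueError:
            summary["eqtl_effect_correlation"] = None
        if len(shared):
            verdicts = {}
            for t in shared.index:
                block = next(b for b in blocks if b.block_id == shared.at[t, "block_cell"])
                verdicts[t] = eq.sex_confounding_check(block, pedigree)["pvalue"]
            summary["eqtl_sex_check_p"] = verdicts
        summary["stages"]["eqtl_qc"] = "ok"

    if "nta" in config.stages:
        summary["failed_stage"] = "nta"
        sim_cfg = sim.SimulationConfig(seed=config.seed)
        aln = sim.simulate_hairpin_alignments(sim_cfg)
        sam_path = out / "hairpin_alignments.sam"
        aln.write_sam(sam_path)
        aln.write_fastq(out / "unmapped.fastq")
        extraction = ntamod.extract_ntas(sam_path, min_aligned=config.min_aligned)
        profile = ntamod.nta_frequency_table(extraction)
        pd.Series(profile.percentages, name="percent").rename_axis("nta").to_csv(
            out / "nta_frequencies.tsv", sep="\t"
        )
        summary["stages"]["nta"] = "ok"
        summary["nta_free_percent"] = profile.nta_free_percent

    summary.pop("failed_stage", None)
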