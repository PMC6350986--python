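"""End-to-end pipeline: counts -> site tests -> gene scores -> intersection
-> extreme subset -> enrichment, with a plain-text provenance log.

Every stage writes a TSV under the output directory; a failure in any stage
aborts with the stage name attached.  Outputs are deterministic for a given
configuration (and seed, when the input counts are simulated).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import association, counts_io, cross_collection, enrichment, gene_scores
from .counts_io import CountsTable, GeneModel


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    ``counts_paths`` maps collection label -> counts TSV.  All thresholds
    default to the analysis constants: per-library minimum coverage 15, BH
    alpha 0.01, gene-score cutoff 4.0, top fraction 0.05 for gene scores and
    0.10 for the extreme subset.
    """

    counts_paths: dict[str, str]
    annotation_path: str
    categories_path: str | None = None
    manifest_path: str | None = None
    output_dir: str = "results"
    min_coverage: int = 15
    alpha: float = 0.01
    cutoff: float = 4.0
    top_fraction: float = 0.05
    extreme_fraction: float = 0.10
    df_rule: str = "observed_minus_1"
    neglog10p_cap: float = association.DEFAULT_NEGLOG10P_CAP
    fdr_level: str = "site"
    merges: dict[str, tuple[str, ...]] | None = field(
        default_factory=lambda: dict(enrichment.DEFAULT_MERGES)
    )
    non_coding_genes: tuple[str, ...] = ()
    arm_boundaries: dict[str, int] | None = None
    focal_interval: tuple[str, int, int] | None = None
    make_plots: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("top_fraction", "extreme_fraction", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "merges" in data and data["merges"] is not None:
            data["merges"] = {k: tuple(v) for k, v in data["merges"].items()}
        if "focal_interval" in data and data["focal_interval"] is not None:
            c, s, e = data["focal_interval"]
            data["focal_interval"] = (str(c), int(s), int(e))
        if "non_coding_genes" in data:
            data["non_coding_genes"] = tuple(data["non_coding_genes"])
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class PipelineResult:
    output_dir: Path
    site_results: dict[str, pd.DataFrame]
    gene_tables: dict[str, pd.DataFrame]
    high_sets: dict[str, list[str]]
    common: cross_collection.CommonSet | None
    extreme: cross_collection.ExtremeSet | None
    enrichment_table: pd.DataFrame | None
    log_path: Path


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write all artifacts under ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = ["# poolseq-assoc pipeline log"]
    log.append(
        f"parameters: min_coverage={config.min_coverage} alpha={config.alpha} "
        f"cutoff={config.cutoff} top_fraction={config.top_fraction} "
        f"extreme_fraction={config.extreme_fraction} df_rule={config.df_rule} "
        f"fdr_level={config.fdr_level} seed={config.seed}"
    )
    for label, path in config.counts_paths.items():
        log.append(f"input counts[{label}]: {path} sha256={_sha256(path)}")
    log.append(
        f"input annotation: {config.annotation_path} "
        f"sha256={_sha256(config.annotation_path)}"
    )

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 — re-raise with stage context
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    categories = (
        stage("categories", counts_io.read_category_map, config.categories_path)
        if config.categories_path
        else None
    )
    genes: list[GeneModel] = stage(
        "annotation", counts_io.read_gene_models, config.annotation_path,
        categories,
    )
    manifest = (
        stage("manifest", counts_io.read_manifest, config.manifest_path)
        if config.manifest_path
        else None
    )

    site_results: dict[str, pd.DataFrame] = {}
    gene_tables: dict[str, pd.DataFrame] = {}
    high_sets: dict[str, list[str]] = {}
    scores_by_collection: dict[str, dict[str, float]] = {}
    for label, path in config.counts_paths.items():
        table: CountsTable = stage(f"read[{label}]", CountsTable.read, path,
                                   manifest=manifest)
        table, cov_report = stage(
            f"filter[{label}]", counts_io.filter_sites, table,
            config.min_coverage,
        )
        table, mono_report = stage(
            f"monomorphic[{label}]", counts_io.flag_monomorphic, table
        )
        log.append(
            f"[{label}] sites: input={cov_report.n_input} "
            f"low_coverage={cov_report.n_low_coverage} "
            f"monomorphic={mono_report.n_monomorphic} "
            f"no_data={mono_report.n_no_data} "
            f"tested={mono_report.n_polymorphic}"
        )
        if table.n_sites:
            cov = counts_io.coverage_summary(table)
            log.append(
                f"[{label}] total coverage across replicates: min={cov.min:.0f} "
                f"max={cov.max:.0f} mean={cov.mean:.1f} median={cov.median:.1f}"
            )
        results = stage(
            f"test[{label}]", association.test_sites, table,
            df_rule=config.df_rule, neglog10p_cap=config.neglog10p_cap,
        )
        site_results[label] = results
        results.to_csv(outdir / f"sites_{label}.tsv", sep="\t", index=False,
                       float_format="%.6g")

        assignment, assign_report = stage(
            f"assign[{label}]", gene_scores.assign_sites_to_genes, results, genes
        )
        log.append(
            f"[{label}] site-gene assignment: intergenic="
            f"{assign_report.n_intergenic} multi_gene={assign_report.n_multi_gene}"
        )
        gene_table = stage(
            f"score[{label}]", gene_scores.score_genes, results, genes,
            assignment, config.top_fraction,
        )
        gene_table = stage(
            f"high_set[{label}]", gene_scores.high_association_set, gene_table,
            results, assignment, config.alpha, config.cutoff, config.fdr_level,
        )
        gene_tables[label] = gene_table
        gene_table.to_csv(outdir / f"genes_{label}.tsv", sep="\t", index=False,
                          float_format="%.6g")
        high = gene_table.loc[gene_table["pass_high"], "gene_id"].tolist()
        high_sets[label] = high
        log.append(f"[{label}] high-association genes: {len(high)}")

    common = extreme = enrich_table = None
    if len(config.counts_paths) >= 2:
        scores_by_collection = {
            label: dict(zip(t["gene_id"], t["score"]))
            for label, t in gene_tables.items()
        }
        common = stage(
            "intersect", cross_collection.intersect_collections, high_sets,
            scores_by_collection, config.non_coding_genes,
        )
        log.append(
            f"common genes (all collections): {len(common.common)} "
            f"(non-coding removed: {common.n_removed_non_coding}); "
            f"union={common.union_size}"
        )
        region_rows = [
            ("+".join(sorted(k)), v) for k, v in sorted(
                common.region_counts.items(), key=lambda kv: sorted(kv[0])
            )
        ]
        pd.DataFrame(region_rows, columns=["region", "n_genes"]).to_csv(
            outdir / "venn_regions.tsv", sep="\t", index=False
        )
        pd.DataFrame({"gene_id": common.common}).to_csv(
            outdir / "common_genes.tsv", sep="\t", index=False
        )
        if common.common:
            extreme = stage(
                "extreme", cross_collection.extreme_subset, common,
                config.extreme_fraction,
            )
            log.append(
                "extreme thresholds: "
                + " ".join(f"{k}={v:.3f}" for k, v in extreme.thresholds.items())
                + f"; members={len(extreme.members)}"
            )
            pd.DataFrame({"gene_id": extreme.members}).to_csv(
                outdir / "extreme_genes.tsv", sep="\t", index=False
            )
            summary = stage(
                "positions", cross_collection.positional_summary, common.common,
                genes, config.arm_boundaries, config.focal_interval,
            )
            summary.per_chromosome.rename("n_genes").to_csv(
                outdir / "common_per_chromosome.tsv", sep="\t",
                index_label="chrom",
            )
            if categories is not None:
                enrich_table = stage(
                    "enrich", enrichment.enrich_all, common.common, categories,
                    config.merges,
                )
                enrich_table.to_csv(outdir / "enrichment.tsv", sep="\t",
                                    index=False, float_format="%.6g")
                top = enrich_table.iloc[0]
                log.append(
                    f"most enriched category: {top['category']} "
                    f"({top['k']}/{top['n']}, p={top['p_upper']:.3g})"
                )
    if config.make_plots and common is not None and len(common.common):
        from . import plotting

        stage(
            "plot", plotting.manhattan_plot, gene_tables,
            outdir / "gene_scores_manhattan.png", config.focal_interval,
            config.cutoff,
        )
    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(log) + "\n")
    return PipelineResult(
        outdir, site_results, gene_tables, high_sets, common, extreme,
        enrich_table, log_path,
    )
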