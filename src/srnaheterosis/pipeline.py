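"""End-to-end orchestration: files in, classified tables and a report out.

``run_all`` wires the stages together for a complete trio dataset: miRNA /
siRNA-cluster / gene count matrices, per-sample cytosine reports, the
cluster/gene/TE annotation tracks and a miRNA-target pair table.  Every
intermediate is written as TSV (intervals as BED), one log line per stage
records input/output counts, and a machine-readable JSON summary sits next
to the tables.  The run is deterministic: no stage draws random numbers.

All thresholds live in :class:`RunConfig` with the analysis defaults:
FDR < 0.05 with fold change > 2 for differential expression; RPM > 2 (small
RNA) or FPKM > 0.5 (genes) in at least two samples for the expressed
filter; cytosine coverage >= 5; >= 4 cytosines per region; methylation
difference 0.1/0.1/0.05 for CG/CHG/CHH; D/A cutpoints 0.5 and 2; Met_d/a
cutpoint 0.5; 100-bp bins; 2-kb flanks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression_patterns as ep
from . import genomic_context as gc
from . import integration as it
from . import methylome as me
from .io_formats import (CONTEXTS, SampleSheet, read_bed, read_counts,
                         read_cytosine_report, read_gff3_genes,
                         read_sample_sheet, write_bed, write_tsv)

log = logging.getLogger("srnaheterosis")


@dataclass
class RunConfig:
    """Input paths and every tunable threshold of the pipeline."""

    out_dir: str = "out"
    # inputs (any count matrix may be omitted; its stage is skipped)
    expr_samples: str | None = None
    meth_samples: str | None = None
    mirna_counts: str | None = None
    sirna_counts: str | None = None
    gene_fpkm: str | None = None
    cytosine_reports: dict = field(default_factory=dict)  # sample_id -> path
    clusters_bed: str | None = None
    genes_gff3: str | None = None
    tes_bed: str | None = None
    pairs_tsv: str | None = None
    # thresholds
    fdr: float = 0.05
    lfc: float = 1.0                    # log2 scale: fold change > 2
    rpm_filter: float = 2.0
    rpm_min_samples: int = 2
    fpkm_filter: float = 0.5
    fpkm_min_samples: int = 2
    min_coverage: int = 5
    min_cytosines: int = 4
    diff_thresholds: dict = field(
        default_factory=lambda: dict(me.DIFF_THRESHOLDS))
    da_cut_inner: float = 0.5
    da_cut_outer: float = 2.0
    met_da_cut: float = 0.5
    bin_width: int = 100
    flank: int = 2000
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def check_paths(self) -> None:
        for name in ("expr_samples", "meth_samples", "mirna_counts",
                     "sirna_counts", "gene_fpkm", "clusters_bed",
                     "genes_gff3", "tes_bed", "pairs_tsv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        for sample, p in self.cytosine_reports.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"cytosine report {sample}: {p}")


def _expression_stage(config: RunConfig, counts_path: str, kind: str,
                      sheet: SampleSheet, out: Path, tag: str,
                      threshold: float, min_samples: int) -> dict:
    matrix = read_counts(counts_path, sheet, kind)
    res = ep.run_expression_analysis(matrix, threshold, min_samples,
                                     config.fdr, config.lfc)
    write_tsv(res["calls"], out / f"expression_calls_{tag}.tsv", index=True)
    for name, de in res["de"].items():
        write_tsv(de, out / f"de_{tag}_{name}.tsv", index=True)
    log.info("expression[%s]: %d features in, %d expressed, %d candidates",
             tag, len(matrix.counts), len(res["expressed"]),
             len(res["candidates"]))
    return res


def run_all(config: RunConfig) -> dict:
    """Run every stage the config provides inputs for; returns the report."""
    config.check_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "outputs": []}

    expr_results: dict[str, dict] = {}
    if config.expr_samples:
        sheet = read_sample_sheet(config.expr_samples)
        sheet.require_trio()
        for tag, path, kind, thr, ms in (
                ("mirna", config.mirna_counts, "miRNA",
                 config.rpm_filter, config.rpm_min_samples),
                ("sirna", config.sirna_counts, "sirna_cluster",
                 config.rpm_filter, config.rpm_min_samples),
                ("gene", config.gene_fpkm, "gene",
                 config.fpkm_filter, config.fpkm_min_samples)):
            if path is None:
                continue
            try:
                res = _expression_stage(config, path, kind, sheet, out, tag,
                                        thr, ms)
            except Exception as exc:
                raise RuntimeError(f"stage expression[{tag}] failed: {exc}"
                                   ) from exc
            expr_results[tag] = res
            report["stages"].append({"stage": f"expression_{tag}",
                                     "n_candidates": len(res["candidates"]),
                                     "patterns": res["summary"]})
            report["outputs"].append(f"expression_calls_{tag}.tsv")

    annotations = None
    clusters = genes = tes = None
    if config.clusters_bed and config.genes_gff3:
        clusters = read_bed(config.clusters_bed, "sirna_cluster")
        genes = read_gff3_genes(config.genes_gff3)
        tes = read_bed(config.tes_bed, "TE") if config.tes_bed else []
        annotations = gc.annotate_clusters(clusters, genes, tes, config.flank)
        annot_df = pd.DataFrame(
            [(a.cluster_id, a.category, a.linked_gene_id or "")
             for a in annotations],
            columns=["cluster_id", "category", "linked_gene_id"]
        ).set_index("cluster_id")
        write_tsv(annot_df, out / "cluster_annotation.tsv", index=True)
        dist = gc.category_distribution(annotations)
        report["stages"].append({"stage": "annotation",
                                 "n_clusters": len(annotations),
                                 "category_fractions": dist})
        report["outputs"].append("cluster_annotation.tsv")
        log.info("annotation: %d clusters", len(annotations))

    meth_calls_by_context: dict[str, pd.DataFrame] = {}
    if config.cytosine_reports and config.meth_samples and clusters:
        msheet = read_sample_sheet(config.meth_samples)
        msheet.require_trio()
        calls = {s: read_cytosine_report(p, s)
                 for s, p in config.cytosine_reports.items()}
        pooled = {g: me.pool_replicates(calls, msheet.samples_of(g))
                  for g in ("female", "male", "hybrid")}
        groups_of = {"FvsM": ("female", "male"), "HvsF": ("hybrid", "female"),
                     "HvsM": ("hybrid", "male")}
        meth_summary = {}
        for ctx in CONTEXTS:
            dm = {}
            for cname, (g1, g2) in groups_of.items():
                dm[cname] = me.region_dm_test(
                    calls, clusters, ctx, msheet.samples_of(g1),
                    msheet.samples_of(g2), config.diff_thresholds[ctx],
                    config.min_coverage, config.min_cytosines, config.fdr)
                write_tsv(dm[cname], out / f"dm_{ctx}_{cname}.tsv", index=True)
            cand = me.select_methylation_candidates(dm["FvsM"], dm["HvsF"],
                                                    dm["HvsM"])
            wml = me.region_wml_table(pooled, clusters, ctx,
                                      config.min_coverage)
            mcalls = me.classify_met_da_table(wml.loc[sorted(cand)], ctx)
            meth_calls_by_context[ctx] = mcalls
            write_tsv(mcalls, out / f"methylation_calls_{ctx}.tsv", index=True)
            tally = mcalls["pattern"].value_counts().to_dict()
            meth_summary[ctx] = {p: int(tally.get(p, 0))
                                 for p in me.METH_PATTERNS}
            report["outputs"].append(f"methylation_calls_{ctx}.tsv")
            log.info("methylome[%s]: %d candidates, patterns %s", ctx,
                     len(cand), meth_summary[ctx])
        report["stages"].append({"stage": "methylome",
                                 "patterns_by_context": meth_summary})

    if expr_results.get("sirna") is not None and meth_calls_by_context \
            and annotations is not None:
        groups, grp_report = it.build_pattern_groups(
            expr_results["sirna"]["calls"], meth_calls_by_context, annotations)
        focal = [g for g in groups
                 if (g.expression_superclass, g.context,
                     g.methylation_pattern) in it.FOCAL_COMBOS]
        group_rows = [(g.name, len(g.member_cluster_ids),
                       len(g.associated_gene_ids),
                       ",".join(g.associated_gene_ids)) for g in groups]
        write_tsv(pd.DataFrame(group_rows,
                               columns=["group", "n_clusters", "n_genes",
                                        "gene_ids"]).set_index("group"),
                  out / "pattern_groups.tsv", index=True)
        report["stages"].append({
            "stage": "integration",
            "groups": {g.name: {"clusters": len(g.member_cluster_ids),
                                "genes": len(g.associated_gene_ids)}
                       for g in groups},
            "focal_groups": [g.name for g in focal],
            "excluded": grp_report})
        report["outputs"].append("pattern_groups.tsv")
        if expr_results.get("gene") is not None:
            assoc = it.gene_pattern_enrichment_in_groups(
                focal, expr_results["gene"]["calls"])
            write_tsv(pd.DataFrame(
                [(a.label, a.table[0][0], a.table[0][1], a.table[1][0],
                  a.table[1][1], a.odds_ratio, a.p) for a in assoc],
                columns=["label", "t11", "t10", "t01", "t00", "odds_ratio",
                         "p"]).set_index("label"),
                out / "group_gene_associations.tsv", index=True)
            report["outputs"].append("group_gene_associations.tsv")

    if config.pairs_tsv and expr_results.get("mirna") is not None \
            and expr_results.get("gene") is not None:
        pair_table = pd.read_csv(config.pairs_tsv, sep="\t", comment="#")
        pairs, pair_report = it.opposing_pairs(
            pair_table, expr_results["mirna"]["calls"],
            expr_results["gene"]["calls"])
        pair_df = pd.DataFrame(
            [(p.mirna_id, p.mirna_pattern, p.mirna_da, p.target_gene_id,
              p.gene_pattern, p.gene_da, p.source) for p in pairs],
            columns=["mirna_id", "mirna_pattern", "mirna_da",
                     "target_gene_id", "gene_pattern", "gene_da", "source"])
        write_tsv(pair_df, out / "opposing_pairs.tsv")
        report["stages"].append({"stage": "opposing_pairs",
                                 "n_pairs": len(pairs), **pair_report})
        report["outputs"].append("opposing_pairs.tsv")
        log.info("opposing_pairs: %d retained", len(pairs))

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["outputs"].append("report.json")
    return report
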