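"""Pipeline orchestration and cross-stage summaries.

``run_pipeline`` wires the stages together — differential expression for the
three pairwise comparisons (genes and miRNAs), the mid-parent non-additivity
test, 12-category classification, the miRNA-mRNA anti-correlation network,
optional enrichment — and emits per-stage TSVs plus a single JSON report
whose percentage fields are always recomputable from its own numerator and
denominator fields.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from ._util import pct_half_up
from . import destats, enrichment, network as network_mod, patterns, tables_io
from .destats import DEThresholds, MIRNA_THRESHOLDS, MRNA_THRESHOLDS, PATTERN_THRESHOLDS
from .errors import ConfigurationError, DomainError, PipelineError
from .tables_io import ExpressionTable

logger = logging.getLogger(__name__)

COMPARISONS = ("A-vs-B", "C-vs-A", "C-vs-B")
VENN_REGIONS = ("A_only", "B_only", "C_only", "AB", "AC", "BC", "ABC")


def call_expressed(
    table: ExpressionTable, min_norm: float = 0.0, mode: str = "cpm"
) -> tuple[dict, dict]:
    """Per-library expressed-feature sets and the 7 three-way Venn regions.

    A feature is expressed in a library when its normalized value reaches
    ``min_norm``; the default threshold 0 means "at least one read"
    (normalized value strictly positive).
    """
    if min_norm < 0:
        raise DomainError("expression threshold must be non-negative")
    norm = destats.normalize(table, mode)
    if min_norm == 0:
        member = norm > 0
    else:
        member = norm >= min_norm
    sets = {role: set(table.feature_ids[member[role]]) for role in ("A", "B", "C")}
    a, b, c = sets["A"], sets["B"], sets["C"]
    regions = {
        "A_only": len(a - b - c),
        "B_only": len(b - a - c),
        "C_only": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(a & b & c),
    }
    return sets, regions


def tf_family_summary(
    features,
    tf_table: pd.DataFrame,
    normalized: pd.DataFrame,
) -> pd.DataFrame:
    """Per-TF-family member count and mean expression.

    ``tf_table`` maps gene -> family (annotation layout, term_id = family).
    The mean is total normalized expression over the family's *expressed*
    members divided by their number (per-library values averaged across the
    three libraries first), i.e. total amount over the number of genes
    expressed.
    """
    features = set(features)
    fam = tf_table[tf_table["feature_id"].isin(features)]
    rows = []
    for family, sub in fam.groupby("term_id", sort=True):
        genes = pd.Index(sorted(set(sub["feature_id"]))).intersection(normalized.index)
        values = normalized.loc[genes].mean(axis=1)
        expressed = values[values > 0]
        rows.append(
            {
                "family": family,
                "gene_count": int(len(genes)),
                "expressed_count": int(len(expressed)),
                "mean_expression": float(expressed.mean()) if len(expressed) else 0.0,
            }
        )
    out = pd.DataFrame(rows, columns=["family", "gene_count", "expressed_count", "mean_expression"])
    return out.sort_values("mean_expression", ascending=False, ignore_index=True)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run (all inputs are TSV)."""

    gene_counts: str
    mirna_counts: str | None = None
    #: optional role->size TSV overriding column-sum library sizes (use when
    #: the tables do not contain every mapped read)
    gene_library_sizes: str | None = None
    mirna_library_sizes: str | None = None
    target_pairs: str | None = None
    annotation: str | None = None
    slim_map: str | None = None
    tf_table: str | None = None
    outdir: str = "polyploid_eld_out"
    mode: str = "cpm"
    pseudocount: float = 1.0
    expressed_min_norm: float = 0.0
    mrna_thresholds: DEThresholds = field(default_factory=lambda: MRNA_THRESHOLDS)
    mirna_thresholds: DEThresholds = field(default_factory=lambda: MIRNA_THRESHOLDS)
    pattern_thresholds: DEThresholds = field(default_factory=lambda: PATTERN_THRESHOLDS)
    enrich_alpha: float = 0.05

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        for key in ("mrna_thresholds", "mirna_thresholds", "pattern_thresholds"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = DEThresholds(**raw[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _de_stage(table, thresholds, cfg, prefix, outdir):
    results = {}
    tallies = {}
    for comparison in COMPARISONS:
        res = destats.run_comparison(
            table, comparison, thresholds, cfg.mode, cfg.pseudocount
        )
        res.to_csv(os.path.join(outdir, f"de_{prefix}_{comparison}.tsv"), sep="\t")
        results[comparison] = res
        tallies[comparison] = destats.de_counts(res)
        logger.info(
            "de[%s %s]: %d features -> %d up / %d down",
            prefix, comparison, len(res),
            tallies[comparison]["up"], tallies[comparison]["down"],
        )
    return results, tallies


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the report dict (also written as JSON)."""
    cfg = config
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        gene_sizes = (
            tables_io.read_library_sizes(cfg.gene_library_sizes)
            if cfg.gene_library_sizes
            else None
        )
        genes = tables_io.read_counts(cfg.gene_counts, library_sizes=gene_sizes)
    except Exception as exc:
        raise PipelineError(f"stage read_counts(genes) failed: {exc}") from exc

    # expressed-feature Venn
    name = stage("expressed")
    sets, regions = call_expressed(genes, cfg.expressed_min_norm, cfg.mode)
    report["stages"][name] = {
        "expressed_per_library": {r: len(sets[r]) for r in sets},
        "venn": regions,
        "coexpressed_all_three": regions["ABC"],
    }

    # gene DE
    name = stage("de_genes")
    gene_de, gene_tallies = _de_stage(genes, cfg.mrna_thresholds, cfg, "gene", cfg.outdir)
    de_any = (
        (gene_de["C-vs-A"]["call"] != "ns") | (gene_de["C-vs-B"]["call"] != "ns")
    )
    deg_total = int(de_any.sum())
    report["stages"][name] = {
        "per_comparison": gene_tallies,
        "deg_total_vs_parents": deg_total,
        "deg_share_of_detected": pct_half_up(deg_total, len(genes)),
        "detected_total": len(genes),
    }

    # non-additivity vs MPV
    name = stage("nonadditive")
    nonadd = patterns.nonadditive_test(genes, cfg.mode, cfg.pseudocount)
    nonadd.to_csv(os.path.join(cfg.outdir, "nonadditive_genes.tsv"), sep="\t")
    report["stages"][name] = {
        "total": int(nonadd["nonadditive"].sum()),
        "up": int((nonadd["direction"] == "up").sum()),
        "down": int((nonadd["direction"] == "down").sum()),
        "share_of_detected": pct_half_up(int(nonadd["nonadditive"].sum()), len(genes)),
    }

    # 12-category classification
    name = stage("patterns")
    calls = patterns.pattern_calls(
        genes, cfg.pattern_thresholds, cfg.mode, cfg.pseudocount, nonadditive=nonadd
    )
    calls.to_csv(os.path.join(cfg.outdir, "pattern_calls_genes.tsv"), sep="\t")
    report["stages"][name] = patterns.summarize_patterns(calls, deg_total=deg_total)

    # miRNA stages
    mirna_de = None
    if cfg.mirna_counts:
        name = stage("de_mirnas")
        mirna_sizes = (
            tables_io.read_library_sizes(cfg.mirna_library_sizes)
            if cfg.mirna_library_sizes
            else None
        )
        mirnas = tables_io.read_counts(cfg.mirna_counts, library_sizes=mirna_sizes)
        mirna_de, mirna_tallies = _de_stage(
            mirnas, cfg.mirna_thresholds, cfg, "mirna", cfg.outdir
        )
        report["stages"][name] = {"per_comparison": mirna_tallies}

        name = stage("patterns_mirnas")
        mirna_nonadd = patterns.nonadditive_test(mirnas, cfg.mode, cfg.pseudocount)
        mirna_calls = patterns.pattern_calls(
            mirnas, cfg.pattern_thresholds, cfg.mode, cfg.pseudocount,
            nonadditive=mirna_nonadd,
        )
        mirna_calls.to_csv(
            os.path.join(cfg.outdir, "pattern_calls_mirnas.tsv"), sep="\t"
        )
        mirna_deg_total = int(
            ((mirna_de["C-vs-A"]["call"] != "ns") | (mirna_de["C-vs-B"]["call"] != "ns")).sum()
        )
        report["stages"][name] = patterns.summarize_patterns(
            mirna_calls, deg_total=mirna_deg_total
        )

    # network
    if mirna_de is not None and cfg.target_pairs:
        name = stage("network")
        pairs = tables_io.read_target_pairs(cfg.target_pairs)
        edges_ca = network_mod.related_targets(
            mirna_de["C-vs-A"], gene_de["C-vs-A"], pairs, "C-vs-A"
        )
        edges_cb = network_mod.related_targets(
            mirna_de["C-vs-B"], gene_de["C-vs-B"], pairs, "C-vs-B"
        )
        net = network_mod.merge_networks(edges_ca, edges_cb)
        flags = nonadd["nonadditive"]
        network_mod.export_edgelist(
            net, os.path.join(cfg.outdir, "related_edges.tsv"), flags
        )
        report["stages"][name] = network_mod.network_summary(net, flags)
        report["stages"][name]["skipped_pairs"] = net.attrs.get("skipped_pairs", 0)

    # enrichment
    if cfg.annotation:
        name = stage("enrichment")
        ann = tables_io.read_annotation(cfg.annotation)
        population = set(genes.feature_ids)
        study = set(de_any.index[de_any])
        enr = enrichment.enrich(study, population, ann, cfg.enrich_alpha)
        enr.to_csv(os.path.join(cfg.outdir, "enrichment_degs.tsv"), sep="\t", index=False)
        entry = {
            "deg_terms_tested": len(enr),
            "deg_terms_significant": int(enr["significant"].sum()) if len(enr) else 0,
        }
        add_set = set(nonadd.index[~nonadd["nonadditive"]])
        na_set = set(nonadd.index[nonadd["nonadditive"]])
        if add_set and na_set:
            cmp_df = enrichment.compare_sets_by_term(add_set, na_set, ann, cfg.enrich_alpha)
            cmp_df.to_csv(
                os.path.join(cfg.outdir, "additive_vs_nonadditive_terms.tsv"),
                sep="\t", index=False,
            )
            entry["additive_vs_nonadditive_significant"] = (
                int(cmp_df["significant"].sum()) if len(cmp_df) else 0
            )
        if cfg.slim_map:
            slim = tables_io.read_slim_map(cfg.slim_map)
            tab = enrichment.slim_tabulate(study, slim, ann)
            tab.to_csv(os.path.join(cfg.outdir, "slim_tabulation_degs.tsv"), sep="\t", index=False)
            entry["slim_categories"] = len(tab)
        report["stages"][name] = entry

    # TF families
    if cfg.tf_table:
        name = stage("tf_families")
        tf = tables_io.read_annotation(cfg.tf_table)
        norm = destats.normalize(genes, cfg.mode)
        fam = tf_family_summary(set(de_any.index[de_any]), tf, norm)
        fam.to_csv(os.path.join(cfg.outdir, "tf_family_summary.tsv"), sep="\t", index=False)
        report["stages"][name] = {
            "families": len(fam),
            "top_family": fam.iloc[0]["family"] if len(fam) else None,
            "top_family_mean_expression": (
                float(fam.iloc[0]["mean_expression"]) if len(fam) else None
            ),
        }

    with open(os.path.join(cfg.outdir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
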