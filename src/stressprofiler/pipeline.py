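"""End-to-end orchestration: normalize -> express -> DE -> sets ->
patterns -> cluster -> enrich -> co-express, with TSV artifacts.

Every stage is a pure function of (inputs, config); a run writes each
stage's table plus a JSON summary whose config hash fully determines
all artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .coexpression import annotate_network, coexpression_edges
from .de_calling import Thresholds, call_all_series, de_summary
from .enrichment import fisher_enrich
from .io_core import (CategoryMap, SERIES_ORDER, TISSUES,
                      read_category_map, read_counts, write_table)
from .normalization import cpm, expressed_by_stress, tmm_factors
from .patterns import (foldchange_profile, group_patterns, group_sizes,
                       hcluster)
from .set_analysis import proportion, venn2, venn3

log = logging.getLogger("stressprofiler")


@dataclass
class RunConfig:
    """Paths, thresholds and toggles of one pipeline run."""

    counts: str
    samples: str
    outdir: str
    categories: str | None = None
    expr_threshold: float = 10.0
    over_threshold: float = 30.0
    fc_threshold: float = 3.0
    min_support: int = 2
    trim_m: float = 0.30
    trim_a: float = 0.05
    pseudocount: float = 1.0
    r_threshold: float = 0.9
    coexpression_signed: bool = True
    min_bin_size: int = 2
    alpha: float = 0.05
    enable_enrichment: bool = True
    enable_coexpression: bool = True

    def validate(self) -> None:
        for p in (self.counts, self.samples):
            if not Path(p).is_file():
                raise FileNotFoundError(f"input file not found: {p}")
        if self.enable_enrichment and self.categories is None:
            raise ValueError(
                "enrichment enabled but no categories file given"
            )
        if self.categories is not None and \
                not Path(self.categories).is_file():
            raise FileNotFoundError(
                f"categories file not found: {self.categories}"
            )

    def thresholds(self) -> Thresholds:
        return Thresholds(self.expr_threshold, self.over_threshold,
                          self.fc_threshold, self.min_support)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def venn_tables(de_sets: dict[str, frozenset[str]]) -> pd.DataFrame:
    """All stress-within-tissue venn2 and tissue-within-stress venn3
    partitions as one tidy table."""
    rows = []
    for tissue in TISSUES:
        a = de_sets.get(f"c.{tissue}", frozenset())
        b = de_sets.get(f"d.{tissue}", frozenset())
        part = venn2(a, b, f"c.{tissue}", f"d.{tissue}")
        pct = part.percentages or {}
        for region, size in part.sizes.items():
            rows.append({
                "comparison": f"cold_vs_drought.{tissue}",
                "region": region, "size": size,
                "percent": pct.get(region, float("nan")),
            })
    for prefix, name in (("c", "cold"), ("d", "drought")):
        sets = [de_sets.get(f"{prefix}.{t}", frozenset()) for t in TISSUES]
        part3 = venn3(*sets, labels=tuple(f"{prefix}.{t}" for t in TISSUES))
        total = sum(part3.sizes.values())
        for sig, size in sorted(part3.sizes.items()):
            rows.append({
                "comparison": f"tissues.{name}", "region": sig,
                "size": size,
                "percent": (proportion(size, total, 1)
                            if total else float("nan")),
            })
    return pd.DataFrame(rows,
                        columns=["comparison", "region", "size", "percent"])


def de_table(all_calls) -> pd.DataFrame:
    rows = []
    for key in SERIES_ORDER:
        for gene, call in sorted(all_calls.get(key, {}).items()):
            fcs = {f"fc_t{c.time_index}": c.fc for c in call.candidates}
            rows.append({"gene_id": gene, "series": key,
                         "stress": call.series.stress,
                         "tissue": call.series.tissue,
                         "direction": call.direction.value,
                         "n_support": call.n_support, **fcs})
    return pd.DataFrame(rows, columns=[
        "gene_id", "series", "stress", "tissue", "direction",
        "n_support", "fc_t1", "fc_t2", "fc_t3"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute every enabled stage and write artifacts to outdir.

    Returns the run summary (also written as ``summary.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "config_hash": config.digest(),
                     "config": asdict(config)}

    stage = "normalize"
    try:
        counts = read_counts(config.counts, config.samples)
        factors = tmm_factors(counts, config.trim_m, config.trim_a)
        write_table(
            pd.DataFrame({"sample_id": factors.sample_ids,
                          "factor": factors.factors}),
            outdir / "factors.tsv", sort_by=["sample_id"])

        stage = "express"
        expr = cpm(counts, factors)
        expr.cpm.reset_index().to_csv(outdir / "cpm.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        background = expressed_by_stress(expr, config.expr_threshold)
        summary["n_expressed"] = {k: len(v) for k, v in background.items()}

        stage = "call-DE"
        series_list = counts.condition_series()
        all_calls = call_all_series(expr, series_list, config.thresholds())
        de_counts, de_sets = de_summary(all_calls)
        write_table(de_table(all_calls), outdir / "de_genes.tsv",
                    sort_by=["series", "gene_id"])
        summary["de_counts"] = {k: de_counts.get(k, 0)
                                for k in SERIES_ORDER}

        stage = "venn"
        vtab = venn_tables(de_sets)
        write_table(vtab, outdir / "venn.tsv",
                    sort_by=["comparison", "region"])
        summary["venn"] = vtab.to_dict("records")

        stage = "patterns"
        membership = group_patterns(all_calls)
        sizes = group_sizes(membership)
        write_table(membership, outdir / "pattern_membership.tsv",
                    sort_by=["group_id", "gene_id"])
        sizes.to_csv(outdir / "groups.tsv", sep="\t", index=False)
        summary["n_groups"] = int(len(sizes))
        summary["n_de_genes_total"] = int(len(membership))

        stage = "cluster"
        profile = foldchange_profile(expr, series_list, all_calls,
                                     config.pseudocount)
        profile.reset_index().to_csv(outdir / "heatmap_matrix.tsv",
                                     sep="\t", index=False,
                                     float_format="%.6g")
        if len(profile) >= 2:
            tree = hcluster(profile)
            (outdir / "leaf_order.txt").write_text(
                "\n".join(tree.leaf_order) + "\n")

        categories: CategoryMap | None = None
        if config.categories is not None:
            categories = read_category_map(config.categories)

        if config.enable_enrichment and categories is not None:
            stage = "enrich"
            tables = []
            for stress, bg in background.items():
                de_all = frozenset().union(*[
                    de_sets.get(f"{stress[0]}.{t}", frozenset())
                    for t in TISSUES])
                de_all &= bg
                if not de_all:
                    continue
                tab = fisher_enrich(de_all, bg, categories,
                                    config.min_bin_size, config.alpha)
                tab.insert(0, "de_set", stress)
                tables.append(tab)
            enr = (pd.concat(tables, ignore_index=True) if tables
                   else pd.DataFrame())
            if len(enr):
                enr.to_csv(outdir / "enrichment.tsv", sep="\t",
                           index=False, float_format="%.6g")
                summary["top_enrichment"] = (
                    enr.sort_values(["q", "bin"]).head(5)
                    [["de_set", "bin", "k", "K", "q"]].to_dict("records"))

        if config.enable_coexpression and len(profile) >= 2:
            stage = "coexpress"
            seeds = list(profile.index)
            edges = coexpression_edges(profile, seeds, config.r_threshold,
                                       config.coexpression_signed)
            write_table(edges, outdir / "edges.tsv",
                        sort_by=["gene_a", "gene_b"])
            summary["n_edges"] = int(len(edges))
            if categories is not None:
                write_table(annotate_network(edges, categories),
                            outdir / "nodes.tsv", sort_by=["gene"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log.info("pipeline complete: %s (config %s)", outdir,
             summary["config_hash"])
    return summary
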