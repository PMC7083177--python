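"""End-to-end orchestration: simulate → preprocess → DEG → meta → enrich → network.

A run is driven by one structured YAML config plus a seed and an output
directory. Every stage writes its outputs as deterministic TSV/JSON under
the output directory, so rerunning the same config and seed reproduces
every file byte for byte. Stage functions operate on the on-disk layout,
which lets the CLI expose them individually while ``run_pipeline`` chains
them.

Output layout::

    outdir/
      data/        simulated inputs (matrices, sample sheets, annotation,
                   gene sets, edge table, seed genes, truth)
      processed/   analysis-ready matrices + qc.tsv
      dge/         per-comparison differential-expression tables
      meta/        pooled results, subgroup tables, recurrence, concordance
      enrichment/  ORA table
      network/     module trace, hubs, degree fit
      run_summary.json
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as aio
from .diffexpr import MODERATION_EB, run_diffexpr
from .enrichment import run_enrichment, top_sets
from .meta import (
    build_region_map,
    recurrence_summary,
    run_meta,
    run_subgroup_meta,
    significant_genes,
    subgroup_concordance,
)
from .network import build_ppin, diamond_expand, fit_power_law, select_hubs
from .preprocess import preprocess_study
from .simulate import (
    CohortConfig,
    GeneSetConfig,
    InteractomeConfig,
    generate_cohort,
    generate_gene_sets,
    generate_interactome,
    generate_seed_table,
)
from .types import ExpressionStudy

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    deg_alpha: float = 0.05
    meta_alpha: float = 0.05
    edge_cutoff: float = 0.9
    hub_percentile: float = 95.0
    n_iter: int = 200
    min_reports: int = 2
    seed_p_cutoff: float = 1e-8


@dataclass
class RunConfig:
    """Full run configuration (synthetic mode)."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    network: InteractomeConfig = field(default_factory=InteractomeConfig)
    gene_sets: GeneSetConfig = field(default_factory=GeneSetConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    moderation: str = MODERATION_EB
    outliers_first: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; unknown keys are an error."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    def build(cls, section):
        data = raw.get(section, {}) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown keys in {section!r}: {sorted(unknown)}")
        if "baseline_range" in data:
            data["baseline_range"] = tuple(data["baseline_range"])
        return cls(**data)

    top_known = {"seed", "cohort", "network", "gene_sets", "thresholds", "moderation", "outliers_first"}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        cohort=build(CohortConfig, "cohort"),
        network=build(InteractomeConfig, "network"),
        gene_sets=build(GeneSetConfig, "gene_sets"),
        thresholds=build(Thresholds, "thresholds"),
        moderation=raw.get("moderation", MODERATION_EB),
        outliers_first=bool(raw.get("outliers_first", False)),
    )


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations (empty iff the config is valid)."""
    violations: list[str] = []
    t = config.thresholds
    if not 0 < t.deg_alpha < 1:
        violations.append("thresholds.deg_alpha: must lie in (0, 1)")
    if not 0 < t.meta_alpha < 1:
        violations.append("thresholds.meta_alpha: must lie in (0, 1)")
    if not 0 <= t.edge_cutoff <= 1:
        violations.append("thresholds.edge_cutoff: must lie in [0, 1]")
    if not 0 < t.hub_percentile < 100:
        violations.append("thresholds.hub_percentile: must lie in (0, 100)")
    if t.n_iter < 0:
        violations.append("thresholds.n_iter: must be >= 0")
    if t.min_reports < 2:
        violations.append("thresholds.min_reports: must be >= 2 (a gene must recur)")
    if not 0 < t.seed_p_cutoff <= 1:
        violations.append("thresholds.seed_p_cutoff: must lie in (0, 1]")
    if not isinstance(config.seed, int) or config.seed < 0:
        violations.append("seed: must be a non-negative integer")
    if config.moderation not in ("eb", "none"):
        violations.append("moderation: must be 'eb' or 'none'")
    for section, cfg in (("cohort", config.cohort), ("network", config.network), ("gene_sets", config.gene_sets)):
        try:
            cfg.validate()
        except ValueError as exc:
            violations.append(f"{section}: {exc}")
    n_planted = int(round(config.cohort.frac_up * config.cohort.n_genes)) + int(
        round(config.cohort.frac_down * config.cohort.n_genes)
    )
    if config.network.module_size > max(n_planted, 0):
        violations.append("network.module_size: exceeds the number of planted non-null genes")
    if config.network.n_nodes > config.cohort.n_genes:
        violations.append("network.n_nodes: exceeds the cohort gene universe")
    return violations


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
                raise StageError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _sub_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


@_stage("simulate")
def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    """Generate cohort, gene sets, interactome and seed genes under data/."""
    data = outdir / "data"
    data.mkdir(parents=True, exist_ok=True)
    s_cohort, s_net, s_sets, s_seeds = _sub_seeds(config.seed, 4)

    studies, annotation, truth = generate_cohort(config.cohort, s_cohort)
    meta_rows = []
    for st in studies:
        aio.write_expression_study(st, data / f"{st.study_id}.matrix.tsv", data / f"{st.study_id}.samples.tsv")
        meta_rows.append((st.study_id, st.region, st.platform, st.log_scale))
    pd.DataFrame(meta_rows, columns=["study_id", "region", "platform", "log_scale"]).to_csv(
        data / "studies.tsv", sep="\t", index=False, lineterminator="\n"
    )
    ann = annotation.rename("symbol").reset_index()
    ann.columns = ["probe_id", "symbol"]
    ann.to_csv(data / "annotation.tsv", sep="\t", index=False, lineterminator="\n")

    gene_sets = generate_gene_sets(truth, config.gene_sets, s_sets)
    aio.write_gmt(gene_sets, data / "genesets.gmt")

    # plant the interactome module on true non-null genes so the module is
    # recoverable from the significant meta-genes
    rng = np.random.default_rng(s_net)
    nonnull = sorted(truth.nonnull_genes())
    module_nodes = sorted(rng.choice(nonnull, size=config.network.module_size, replace=False))
    rest_pool = sorted(set(truth.genes) - set(module_nodes))
    n_rest = config.network.n_nodes - config.network.module_size
    rest = sorted(rng.choice(rest_pool, size=n_rest, replace=False))
    nodes = sorted(module_nodes + rest)
    edges, net_truth = generate_interactome(
        config.network, s_net, nodes=nodes, module_nodes=module_nodes
    )
    string_scaled = edges.copy()
    string_scaled["score"] = (string_scaled["score"] * 1000).round(0).astype(int)
    string_scaled.to_csv(data / "edges.tsv", sep="\t", index=False, lineterminator="\n")
    seed_table = generate_seed_table(net_truth, s_seeds)
    seed_table.to_csv(
        data / "seeds.tsv", sep="\t", index=False, float_format="%.6g", lineterminator="\n"
    )

    _write_json(
        {
            "state": truth.state.to_dict(),
            "effect_sizes": truth.effect_sizes,
            "outlier_arrays": truth.outlier_arrays,
            "module": sorted(net_truth.module),
            "seeds": sorted(net_truth.seeds),
        },
        data / "truth.json",
    )
    return {
        "n_studies": len(studies),
        "n_genes": len(truth.genes),
        "n_planted_up": int((truth.state == "up").sum()),
        "n_planted_down": int((truth.state == "down").sum()),
        "n_gene_sets": len(gene_sets),
        "n_edges": len(edges),
        "n_seed_genes": len(seed_table),
    }


def _load_studies(data: Path) -> list[ExpressionStudy]:
    meta = pd.read_csv(data / "studies.tsv", sep="\t")
    studies = []
    for row in meta.itertuples(index=False):
        studies.append(
            aio.read_expression_study(
                data / f"{row.study_id}.matrix.tsv",
                data / f"{row.study_id}.samples.tsv",
                platform=row.platform,
                study_id=row.study_id,
                region=row.region,
                log_scale=bool(row.log_scale),
            )
        )
    return studies


@_stage("preprocess")
def stage_preprocess(config: RunConfig, outdir: Path) -> dict:
    """Normalize, collapse and QC-screen every study into processed/."""
    data = outdir / "data"
    out = outdir / "processed"
    out.mkdir(parents=True, exist_ok=True)
    studies = _load_studies(data)
    annotation = aio.read_annotation(data / "annotation.tsv")
    omitted: dict[str, list[str]] = {}
    qc_rows = []
    for st in studies:
        ready, report = preprocess_study(
            st, annotation=annotation if st.platform == "intensity" else None,
            outliers_first=config.outliers_first,
        )
        aio.write_expression_study(
            ready, out / f"{st.study_id}.matrix.tsv", out / f"{st.study_id}.samples.tsv"
        )
        omitted[st.study_id] = report.omitted
        for array_id, row in report.metrics.iterrows():
            qc_rows.append(
                (st.study_id, array_id, row.get("distance"), row.get("ks"), row.get("ma"),
                 array_id in report.omitted)
            )
    qc = pd.DataFrame(qc_rows, columns=["study_id", "array", "distance", "ks", "ma", "omitted"])
    aio.write_results(qc, out / "qc.tsv", sort_by=["study_id", "array"])
    _write_json({"omitted": omitted}, out / "qc.json")
    return {"arrays_omitted": {k: len(v) for k, v in omitted.items()}}


@_stage("dge")
def stage_dge(config: RunConfig, outdir: Path) -> dict:
    """Differential expression for every processed comparison into dge/."""
    processed = outdir / "processed"
    out = outdir / "dge"
    out.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(outdir / "data" / "studies.tsv", sep="\t")
    degs_per_comparison = {}
    for row in meta.itertuples(index=False):
        study = aio.read_expression_study(
            processed / f"{row.study_id}.matrix.tsv",
            processed / f"{row.study_id}.samples.tsv",
            platform="intensity",  # all processed matrices are log2 symbol-level
            study_id=row.study_id,
            region=row.region,
        )
        result = run_diffexpr(study, moderation=config.moderation, alpha=config.thresholds.deg_alpha)
        table = result.table.reset_index()
        table.insert(0, "comparison_id", row.study_id)
        aio.write_results(table, out / f"{row.study_id}.tsv", sort_by=["p_adj", "symbol"])
        degs_per_comparison[row.study_id] = int(result.table["is_deg"].sum())
    return {"degs_per_comparison": degs_per_comparison}


def _load_dge(outdir: Path):
    from .types import ComparisonResult

    meta = pd.read_csv(outdir / "data" / "studies.tsv", sep="\t")
    comparisons = []
    data = {}
    for row in meta.itertuples(index=False):
        table = pd.read_csv(outdir / "dge" / f"{row.study_id}.tsv", sep="\t").set_index("symbol")
        comparisons.append(ComparisonResult(comparison_id=row.study_id, table=table))
        mat = pd.read_csv(outdir / "processed" / f"{row.study_id}.matrix.tsv", sep="\t", index_col=0)
        sheet = pd.read_csv(outdir / "processed" / f"{row.study_id}.samples.tsv", sep="\t")
        data[row.study_id] = (mat, sheet.set_index("sample_id")["group"])
    return comparisons, data, meta


@_stage("meta")
def stage_meta(config: RunConfig, outdir: Path) -> dict:
    """Global + subgroup meta-analysis into meta/."""
    out = outdir / "meta"
    out.mkdir(parents=True, exist_ok=True)
    comparisons, data, meta_sheet = _load_dge(outdir)
    t = config.thresholds

    table = run_meta(comparisons, data, min_reports=t.min_reports, alpha=t.meta_alpha)
    aio.write_results(table, out / "meta.tsv", sort_by=["p_adj", "symbol"])
    rec = recurrence_summary(comparisons)
    _write_json(rec, out / "recurrence.json")

    region_map = {row.study_id: row.region for row in meta_sheet.itertuples(index=False)}
    from .meta import assign_subgroup

    branch_map = {cid: assign_subgroup(region) for cid, region in region_map.items()}
    sub_tables = run_subgroup_meta(
        comparisons, data, branch_map, min_reports=t.min_reports, alpha=t.meta_alpha
    )
    (out / "subgroups").mkdir(exist_ok=True)
    for label, sub in sub_tables.items():
        aio.write_results(sub, out / "subgroups" / f"{label}.tsv", sort_by=["p_adj", "symbol"])
    concordance = {}
    labels = sorted(sub_tables)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            concordance[f"{la}|{lb}"] = subgroup_concordance(
                sub_tables[la], sub_tables[lb], alpha=t.meta_alpha
            )
    _write_json(concordance, out / "concordance.json")

    sig = significant_genes(table, t.meta_alpha)
    return {
        "recurrence": rec,
        "genes_pooled": int(len(table)),
        "significant_meta_genes": int(len(sig)),
        "significant_up": int((sig["direction"] == "up").sum()),
        "significant_down": int((sig["direction"] == "down").sum()),
        "subgroups": {k: int(len(significant_genes(v, t.meta_alpha))) for k, v in sub_tables.items()},
    }


@_stage("enrich")
def stage_enrich(config: RunConfig, outdir: Path) -> dict:
    """ORA of significant meta-genes against the gene sets into enrichment/."""
    out = outdir / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    t = config.thresholds
    meta_table = pd.read_csv(outdir / "meta" / "meta.tsv", sep="\t")
    gene_sets = aio.read_gmt(outdir / "data" / "genesets.gmt")
    comparisons, _, _ = _load_dge(outdir)
    measured: set[str] = set()
    for comp in comparisons:
        measured |= set(comp.table.index)
    universe = measured & gene_sets.union()
    query = set(significant_genes(meta_table, t.meta_alpha)["symbol"]) & universe
    result = run_enrichment(query, gene_sets, universe, alpha=t.meta_alpha)
    aio.write_results(result, out / "enrichment.tsv", sort_by=["p_adj", "p", "set_id"])
    top = top_sets(result, alpha=t.meta_alpha)
    return {
        "sets_tested": int(len(result)),
        "sets_significant": int((result["p_adj"] < t.meta_alpha).sum()),
        "top_sets": top["set_id"].tolist(),
    }


@_stage("network")
def stage_network(config: RunConfig, outdir: Path) -> dict:
    """PPIN, degree fit, DIAMOnD module and hubs into network/."""
    out = outdir / "network"
    out.mkdir(parents=True, exist_ok=True)
    t = config.thresholds
    meta_table = pd.read_csv(outdir / "meta" / "meta.tsv", sep="\t")
    sig = set(significant_genes(meta_table, t.meta_alpha)["symbol"])
    edges = aio.read_edge_table(outdir / "data" / "edges.tsv", score_scale="string1000")
    graph = build_ppin(edges, members=sig, cutoff=t.edge_cutoff)
    try:
        fit = fit_power_law(graph)
        fit_dict = {"coefficient": fit.coefficient, "exponent": fit.exponent, "r2": fit.r2}
    except ValueError as exc:
        logger.warning("degree fit skipped: %s", exc)
        fit_dict = None
    _write_json(
        {"nodes": graph.number_of_nodes(), "edges": graph.number_of_edges(), "fit": fit_dict},
        out / "degree_fit.json",
    )
    seeds = aio.read_seed_genes(outdir / "data" / "seeds.tsv", p_cutoff=t.seed_p_cutoff)
    module = diamond_expand(graph, seeds, n_iter=t.n_iter)
    aio.write_results(module.additions, out / "module.tsv", sort_by=["iteration"])
    hubs = select_hubs(graph, module, percentile=t.hub_percentile)
    aio.write_results(hubs, out / "hubs.tsv", sort_by=None)
    return {
        "ppin_nodes": graph.number_of_nodes(),
        "ppin_edges": graph.number_of_edges(),
        "degree_fit": fit_dict,
        "seeds_in_graph": int(len(module.seeds)),
        "module_size": int(len(module.members)),
        "hubs": hubs["symbol"].tolist(),
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write ``run_summary.json``.

    Raises :class:`StageError` on stage failure (partial outputs are kept)
    and ``ValueError`` if the config is invalid. The returned summary also
    carries the config echo and internal consistency checks.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "config": config.to_dict()}
    summary["simulate"] = stage_simulate(config, outdir)
    summary["preprocess"] = stage_preprocess(config, outdir)
    summary["dge"] = stage_dge(config, outdir)
    summary["meta"] = stage_meta(config, outdir)
    summary["enrichment"] = stage_enrich(config, outdir)
    summary["network"] = stage_network(config, outdir)

    checks = {
        "pooled_le_recurrent": summary["meta"]["genes_pooled"]
        <= summary["meta"]["recurrence"]["n_recurrent"],
        "significant_le_pooled": summary["meta"]["significant_meta_genes"]
        <= summary["meta"]["genes_pooled"],
        "module_ge_seeds": summary["network"]["module_size"]
        >= summary["network"]["seeds_in_graph"],
    }
    summary["consistency"] = checks
    if not all(checks.values()):
        failed = [k for k, v in checks.items() if not v]
        raise StageError(f"[summary] consistency checks failed: {failed}")
    _write_json(summary, outdir / "run_summary.json")
    return summary
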