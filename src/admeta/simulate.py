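"""Synthetic multi-study cohorts, interactomes, seed genes, and gene sets.

Every generator is a pure function of (config, seed) and returns ground
truth alongside the data, so each downstream stage — normalization, DEG
calling, meta-analysis, enrichment, module detection — can be scored
against the planted signal without downloading anything.

The cohort model: a shared gene universe in which a configured fraction of
genes is planted up- or down-regulated with a common per-study effect size
δ. Intensity (microarray-like) studies draw Gaussian noise around per-gene
baselines on the log2 scale and route through duplicate probes; count
(RNA-seq-like) studies draw negative-binomial counts whose means are
multiplied by exp(±δ) in cases. Optional outlier arrays receive a global
+4σ shift so that the quality-control screen has something to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    CASE,
    CONTROL,
    CohortTruth,
    ExpressionStudy,
    GeneSetCollection,
    NetworkTruth,
    PLATFORM_COUNT,
    PLATFORM_INTENSITY,
)

# region labels cycle over branches of the brain-region hierarchy used by
# the subgroup analysis, so a default cohort spans several subgroups
DEFAULT_REGIONS = (
    "hippocampus",
    "frontal cortex",
    "amygdala",
    "entorhinal cortex",
    "temporal cortex",
    "cerebellum",
    "putamen",
)


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults are the conditions the downstream recovery checks are run
    under: five case–control studies of 10+10 samples over a shared
    universe, 5% of genes planted up and 5% down at δ = 1.5 (log2 units
    for intensity, natural-log fold for counts) with σ = 0.5 intensity
    noise; one in five studies is count-based.
    """

    n_studies: int = 5
    n_genes: int = 2000
    n_case: int = 10
    n_control: int = 10
    frac_up: float = 0.05
    frac_down: float = 0.05
    effect_size: float = 1.5
    sigma: float = 0.5
    platform_mix: float = 0.2  # fraction of count studies
    probe_multiplicity: float = 1.2  # mean probes per gene (intensity)
    frac_unannotated: float = 0.02  # junk probes without a symbol
    n_outlier_arrays: int = 0  # per intensity study
    dispersion: float = 0.1  # NB: var = mu + dispersion * mu^2
    baseline_range: tuple[float, float] = (6.0, 12.0)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_studies < 1:
            raise ValueError("need at least one gene and one study")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >=2 samples per group")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_up + self.frac_down >= 1:
            raise ValueError("frac_up + frac_down must be < 1")
        if self.effect_size < 0 or self.sigma <= 0 or self.dispersion <= 0:
            raise ValueError("effect_size >= 0, sigma > 0, dispersion > 0 required")
        if not 0 <= self.platform_mix <= 1:
            raise ValueError("platform_mix must lie in [0, 1]")
        if self.probe_multiplicity < 1:
            raise ValueError("probe_multiplicity must be >= 1")


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[list[ExpressionStudy], pd.Series, CohortTruth]:
    """Generate a multi-study cohort with known per-gene truth.

    Returns (studies, annotation, truth). Intensity studies are emitted on
    the log2 scale (``log_scale=True``) with a probe-level annotation
    (symbols duplicated across multi-probe genes, junk probes
    unannotated); count studies are gene-indexed integer matrices.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    n_up = int(round(config.frac_up * config.n_genes))
    n_down = int(round(config.frac_down * config.n_genes))
    order = rng.permutation(config.n_genes)
    state = pd.Series("null", index=genes, name="state")
    state.iloc[order[:n_up]] = "up"
    state.iloc[order[n_up : n_up + n_down]] = "down"
    sign = state.map({"up": 1.0, "down": -1.0, "null": 0.0}).to_numpy()

    baseline = rng.uniform(*config.baseline_range, size=config.n_genes)

    # probe map shared across intensity studies
    extra = rng.random(config.n_genes) < (config.probe_multiplicity - 1.0)
    probe_map: dict[str, list[str]] = {}
    probe_rows: list[tuple[str, str, int]] = []  # (probe, symbol, gene index)
    counter = 0
    for gi, g in enumerate(genes):
        n_probes = 2 if extra[gi] else 1
        ids = []
        for _ in range(n_probes):
            pid = f"P{counter:06d}"
            counter += 1
            ids.append(pid)
            probe_rows.append((pid, g, gi))
        probe_map[g] = ids
    n_junk = int(round(config.frac_unannotated * len(probe_rows)))
    junk_probes = [f"P{counter + j:06d}" for j in range(n_junk)]
    annotation = pd.Series(
        [sym for _, sym, _ in probe_rows] + [np.nan] * n_junk,
        index=[pid for pid, _, _ in probe_rows] + junk_probes,
        name="symbol",
    )
    annotation.index.name = "probe_id"

    n_count = int(round(config.platform_mix * config.n_studies))
    studies: list[ExpressionStudy] = []
    effect_sizes: dict[str, float] = {}
    sample_sizes: dict[str, tuple[int, int]] = {}
    outlier_roster: dict[str, list[str]] = {}

    for si in range(config.n_studies):
        study_id = f"S{si:02d}"
        region = DEFAULT_REGIONS[si % len(DEFAULT_REGIONS)]
        is_count = si >= config.n_studies - n_count
        n_s = config.n_case + config.n_control
        samples = [f"{study_id}_{'A' if j < config.n_case else 'C'}{j:03d}" for j in range(n_s)]
        group = pd.Series(
            [CASE] * config.n_case + [CONTROL] * config.n_control, index=samples, name="group"
        )
        is_case = (group == CASE).to_numpy().astype(float)
        delta = config.effect_size
        effect_sizes[study_id] = delta
        sample_sizes[study_id] = (config.n_case, config.n_control)

        if is_count:
            # NB counts: mean = libsize * pi_g * exp(case * (+-delta))
            pi = 2.0 ** baseline
            pi = pi / pi.sum()
            libsize = rng.integers(800_000, 1_200_000, size=n_s).astype(float)
            mu = libsize[None, :] * pi[:, None] * np.exp(
                sign[:, None] * delta * is_case[None, :]
            )
            r = 1.0 / config.dispersion
            p = r / (r + mu)
            counts = rng.negative_binomial(r, p)
            values = pd.DataFrame(counts, index=genes, columns=samples)
            outlier_roster[study_id] = []
            studies.append(
                ExpressionStudy(study_id, region, PLATFORM_COUNT, values, group, log_scale=False)
            )
        else:
            gene_vals = (
                baseline[:, None]
                + sign[:, None] * delta * is_case[None, :]
                + rng.normal(0.0, config.sigma, size=(config.n_genes, n_s))
            )
            # duplicate probes share the gene value with independent noise
            rows = np.empty((len(probe_rows) + n_junk, n_s))
            for ri, (_, _, gi) in enumerate(probe_rows):
                rows[ri] = gene_vals[gi] + rng.normal(0.0, config.sigma, size=n_s) * extra[gi]
            for ji in range(n_junk):
                rows[len(probe_rows) + ji] = rng.normal(
                    np.mean(config.baseline_range), config.sigma, size=n_s
                )
            shifted: list[str] = []
            if config.n_outlier_arrays > 0:
                pick = rng.choice(n_s, size=min(config.n_outlier_arrays, n_s), replace=False)
                rows[:, pick] += 4.0 * config.sigma
                shifted = [samples[j] for j in sorted(pick)]
            outlier_roster[study_id] = shifted
            values = pd.DataFrame(rows, index=list(annotation.index), columns=samples)
            studies.append(
                ExpressionStudy(study_id, region, PLATFORM_INTENSITY, values, group, log_scale=True)
            )

    truth = CohortTruth(
        genes=genes,
        state=state,
        effect_sizes=effect_sizes,
        sample_sizes=sample_sizes,
        outlier_arrays=outlier_roster,
        probe_map=probe_map,
    )
    return studies, annotation, truth


@dataclass
class InteractomeConfig:
    """Scale-free backbone with a planted dense module.

    The backbone is preferential attachment (Barabási–Albert, ``m`` edges
    per new node); every pair inside the planted module is additionally
    connected with ``module_extra_edge_prob``. Edge confidences are drawn
    in [0.9, 1] by default so the confidence filter is a no-op unless
    ``low_scores`` is set.
    """

    n_nodes: int = 500
    attachment_m: int = 2
    module_size: int = 20
    module_extra_edge_prob: float = 0.6
    n_seeds: int = 5
    low_scores: bool = False

    def validate(self) -> None:
        if self.module_size > self.n_nodes:
            raise ValueError("module_size must be <= n_nodes")
        if self.n_seeds > self.module_size:
            raise ValueError("n_seeds must be <= module_size")
        if self.attachment_m < 1 or self.n_nodes <= self.attachment_m:
            raise ValueError("need n_nodes > attachment_m >= 1")
        if not 0 <= self.module_extra_edge_prob <= 1:
            raise ValueError("module_extra_edge_prob must lie in [0, 1]")


def generate_interactome(
    config: InteractomeConfig,
    seed: int,
    nodes: list[str] | None = None,
    module_nodes: list[str] | None = None,
) -> tuple[pd.DataFrame, NetworkTruth]:
    """Generate an edge table and its ground truth.

    ``nodes`` supplies node names (defaults to ``N0000``…); pass
    ``module_nodes`` to plant the module on specific symbols (e.g. true
    DEGs of a cohort).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if nodes is None:
        nodes = [f"N{i:04d}" for i in range(config.n_nodes)]
    if len(nodes) != config.n_nodes:
        raise ValueError("nodes list must have n_nodes entries")

    backbone = nx.barabasi_albert_graph(
        config.n_nodes, config.attachment_m, seed=int(rng.integers(2**31))
    )
    edges = {(min(u, v), max(u, v)) for u, v in backbone.edges()}

    index_of = {name: i for i, name in enumerate(nodes)}
    if module_nodes is None:
        module_idx = sorted(rng.choice(config.n_nodes, size=config.module_size, replace=False))
    else:
        if len(module_nodes) != config.module_size:
            raise ValueError("module_nodes must have module_size entries")
        module_idx = sorted(index_of[n] for n in module_nodes)
    for ai, u in enumerate(module_idx):
        for v in module_idx[ai + 1 :]:
            if rng.random() < config.module_extra_edge_prob:
                edges.add((u, v))

    seeds_idx = sorted(rng.choice(module_idx, size=config.n_seeds, replace=False))

    lo = 0.4 if config.low_scores else 0.9
    ordered = sorted(edges)
    scores = rng.uniform(lo, 1.0, size=len(ordered))
    table = pd.DataFrame(
        {
            "node_a": [min(nodes[u], nodes[v]) for u, v in ordered],
            "node_b": [max(nodes[u], nodes[v]) for u, v in ordered],
            "score": scores,
        }
    ).sort_values(["node_a", "node_b"]).reset_index(drop=True)

    truth = NetworkTruth(
        nodes=list(nodes),
        module={nodes[i] for i in module_idx},
        seeds={nodes[i] for i in seeds_idx},
    )
    return table, truth


def generate_seed_table(truth: NetworkTruth, seed: int) -> pd.DataFrame:
    """Seed-gene table for the planted seeds, at genome-wide significance.

    Association p-values are drawn log-uniformly in [1e-12, 1e-8] so every
    planted seed survives the p ≤ 1e-8 filter.
    """
    rng = np.random.default_rng(seed)
    symbols = sorted(truth.seeds)
    p = 10.0 ** rng.uniform(-12.0, -8.0, size=len(symbols))
    return pd.DataFrame({"symbol": symbols, "association_p": p})


@dataclass
class GeneSetConfig:
    """Gene-set collection with a known enriched subset.

    Enriched sets draw ``enrichment_frac`` of their members from the
    cohort's true non-null genes; the rest of each set, and all remaining
    sets, are uniform draws from the universe.
    """

    n_sets: int = 20
    set_size: int = 50
    n_enriched_sets: int = 5
    enrichment_frac: float = 0.8

    def validate(self) -> None:
        if self.n_enriched_sets > self.n_sets:
            raise ValueError("n_enriched_sets must be <= n_sets")
        if not 0 <= self.enrichment_frac <= 1:
            raise ValueError("enrichment_frac must lie in [0, 1]")
        if self.set_size < 1:
            raise ValueError("set_size must be >= 1")


def generate_gene_sets(truth: CohortTruth, config: GeneSetConfig, seed: int) -> GeneSetCollection:
    """Generate gene sets; enriched set names start with ``ENR``."""
    config.validate()
    if config.set_size > len(truth.genes):
        raise ValueError("set_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    universe = np.array(truth.genes)
    nonnull = np.array(sorted(truth.nonnull_genes()))
    n_signal = int(round(config.enrichment_frac * config.set_size))
    if config.n_enriched_sets > 0 and n_signal > len(nonnull):
        raise ValueError("not enough non-null genes for the requested enrichment")

    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(config.n_sets):
        if i < config.n_enriched_sets:
            signal = rng.choice(nonnull, size=n_signal, replace=False)
            rest_pool = np.setdiff1d(universe, signal)
            rest = rng.choice(rest_pool, size=config.set_size - n_signal, replace=False)
            name = f"ENR{i:03d}"
            desc = "planted enriched set"
            members = frozenset(signal) | frozenset(rest)
        else:
            name = f"BG{i:03d}"
            desc = "background set"
            members = frozenset(rng.choice(universe, size=config.set_size, replace=False))
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)
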