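"""Event-based log-odds-ratio random-effects meta-analysis across studies.

Each comparison contributes, per gene, a 2×2 table of "dysregulation
events": a sample shows an event when its expression lies strictly above
the control-group median for that gene in that comparison. The log odds
ratio of event rates (case vs control) is the study effect θᵢ with
variance vᵢ = 1/a + 1/b + 1/c + 1/d (Haldane–Anscombe +0.5 on every cell
whenever any cell is zero). Effects are pooled under a random-effects
model with the DerSimonian–Laird between-study variance τ²; the pooled
θ̂ = Σw*ᵢθᵢ/Σw*ᵢ with w*ᵢ = 1/(vᵢ + τ²). Genes are admitted when at
least ``min_reports`` comparisons called them a DEG; the sign of θ̂ gives
the pooled dysregulation direction, and BH-adjusted p < 0.05 gives
significance.

The sample-level event rule (median split of the control group) is this
package's operationalization: it is nonparametric and direction-free —
down-regulated genes produce θ < 0 without any special casing.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .types import (
    CASE,
    CONTROL,
    ComparisonResult,
    EventTable2x2,
    ExpressionStudy,
    PooledEffect,
    StudyEffect,
)

logger = logging.getLogger(__name__)

# brain-region branches of the subgroup analysis (cytology-based hierarchy)
SUBGROUP_CEREBELLUM = "cerebellum"
SUBGROUP_PUTAMEN_NA = "putamen_nucleus_accumbens"
SUBGROUP_AMY_HIP = "amygdala_hippocampus"
SUBGROUP_NEOCORTEX = "cerebral_neocortex"
SUBGROUP_OTHER = "other_branch"

_REGION_KEYWORDS = {
    SUBGROUP_CEREBELLUM: ("cerebellum",),
    SUBGROUP_PUTAMEN_NA: ("putamen", "nucleus accumbens", "nucleus_accumbens"),
    SUBGROUP_AMY_HIP: ("amygdala", "hippocampus"),
    SUBGROUP_NEOCORTEX: (
        "cortex",
        "neocortex",
        "gyrus",
        "lobe",
        "cingulate",
        "pole",
        "lobule",
    ),
}


def assign_subgroup(region: str) -> str:
    """Map a free-text brain-region label onto its hierarchy branch."""
    low = region.lower()
    for label, keywords in _REGION_KEYWORDS.items():
        if any(kw in low for kw in keywords):
            return label
    return SUBGROUP_OTHER


def build_region_map(studies: list[ExpressionStudy]) -> dict[str, str]:
    """comparison_id → subgroup branch for a list of studies."""
    return {s.study_id: assign_subgroup(s.region) for s in studies}


def build_event_table(
    matrix: pd.DataFrame, group: pd.Series, symbol: str, comparison_id: str = ""
) -> EventTable2x2:
    """Count dysregulation events for one gene in one comparison.

    An event is expression strictly above the control-group median. Counts
    (a, b) are case events/non-events, (c, d) the control ones; the
    Haldane–Anscombe +0.5 is applied to every cell if any cell is zero.
    """
    if symbol not in matrix.index:
        raise KeyError(f"symbol {symbol!r} absent from matrix")
    group = group.loc[matrix.columns]
    row = matrix.loc[symbol]
    case_vals = row[(group == CASE).to_numpy()].to_numpy(dtype=float)
    ctrl_vals = row[(group == CONTROL).to_numpy()].to_numpy(dtype=float)
    median = float(np.median(ctrl_vals))
    a = float(np.sum(case_vals > median))
    c = float(np.sum(ctrl_vals > median))
    b = float(len(case_vals)) - a
    d = float(len(ctrl_vals)) - c
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return EventTable2x2(comparison_id, symbol, a, b, c, d, corrected)


def log_odds_ratio(table: EventTable2x2) -> StudyEffect:
    """θ = ln(ad/bc), v = 1/a + 1/b + 1/c + 1/d."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) <= 0:
        raise ValueError("zero cell without Haldane-Anscombe correction")
    theta = math.log((a * d) / (b * c))
    v = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return StudyEffect(theta=theta, v=v)


def pool_random_effects(effects: list[StudyEffect]) -> PooledEffect:
    """DerSimonian–Laird random-effects pooling of logOR effects.

    Fixed-effect weights wᵢ = 1/vᵢ give θ_F and the heterogeneity
    Q = Σwᵢ(θᵢ − θ_F)²; τ² = max(0, (Q − (k−1)) / (Σwᵢ − Σwᵢ²/Σwᵢ));
    random-effects weights w*ᵢ = 1/(vᵢ + τ²) give θ̂, SE = (Σw*ᵢ)^−1/2,
    z = θ̂/SE and a two-sided normal p. A single effect passes through
    with τ² = 0.
    """
    if not effects:
        raise ValueError("no effects to pool")
    theta = np.array([e.theta for e in effects])
    v = np.array([e.v for e in effects])
    k = len(effects)
    w = 1.0 / v
    theta_f = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_f) ** 2))
    if k == 1:
        tau2 = 0.0
    else:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    theta_hat = float(np.sum(w_star * theta) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    z = theta_hat / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PooledEffect(theta=theta_hat, tau2=tau2, se=se, z=z, p=p, q=q, k=k)


def _event_counts(matrix: pd.DataFrame, group: pd.Series) -> pd.DataFrame:
    """Vectorized event counts (a, b, c, d) for every gene of a comparison."""
    group = group.loc[matrix.columns]
    case_mask = (group == CASE).to_numpy()
    ctrl = matrix.loc[:, ~case_mask].to_numpy(dtype=float)
    case = matrix.loc[:, case_mask].to_numpy(dtype=float)
    median = np.median(ctrl, axis=1)
    a = (case > median[:, None]).sum(axis=1).astype(float)
    c = (ctrl > median[:, None]).sum(axis=1).astype(float)
    b = case.shape[1] - a
    d = ctrl.shape[1] - c
    out = pd.DataFrame({"a": a, "b": b, "c": c, "d": d}, index=matrix.index)
    zero = out.min(axis=1) == 0
    out.loc[zero] += 0.5
    out["corrected"] = zero
    return out


def run_meta(
    comparisons: list[ComparisonResult],
    data: dict[str, tuple[pd.DataFrame, pd.Series]],
    min_reports: int = 2,
    alpha: float = 0.05,
    use_all_comparisons: bool = False,
) -> pd.DataFrame:
    """Pool every gene reported as a DEG by ≥ ``min_reports`` comparisons.

    ``data`` maps comparison_id to the preprocessed (matrix, group) pair
    the DEG call was made on. By default each gene's event tables come
    from exactly the comparisons that called it a DEG;
    ``use_all_comparisons`` instead pools every comparison measuring the
    gene. Output columns: symbol, k, theta, tau2, se, z, p, p_adj,
    direction, Q; BH is applied across all pooled genes in one batch.
    """
    if min_reports < 2:
        raise ValueError("min_reports must be >= 2 (a gene must recur)")
    deg_calls: dict[str, set[str]] = {}
    measured: dict[str, set[str]] = {}
    for comp in comparisons:
        for sym, _ in comp.deg_set():
            deg_calls.setdefault(sym, set()).add(comp.comparison_id)
        for sym in comp.table.index:
            measured.setdefault(sym, set()).add(comp.comparison_id)
    pooled_genes = sorted(g for g, ids in deg_calls.items() if len(ids) >= min_reports)
    cols = ["symbol", "k", "theta", "tau2", "se", "z", "p", "p_adj", "direction", "Q"]
    if not pooled_genes:
        logger.warning("no gene reported as DEG in >= %d comparisons", min_reports)
        return pd.DataFrame(columns=cols)

    counts = {cid: _event_counts(mat, grp) for cid, (mat, grp) in data.items()}
    rows = []
    for gene in pooled_genes:
        source = measured[gene] if use_all_comparisons else deg_calls[gene]
        effects = []
        for cid in sorted(source):
            tab = counts.get(cid)
            if tab is None or gene not in tab.index:
                continue
            r = tab.loc[gene]
            effects.append(
                log_odds_ratio(
                    EventTable2x2(cid, gene, r["a"], r["b"], r["c"], r["d"], bool(r["corrected"]))
                )
            )
        if not effects:
            continue
        pe = pool_random_effects(effects)
        rows.append(
            (gene, pe.k, pe.theta, pe.tau2, pe.se, pe.z, pe.p,
             np.nan, "up" if pe.theta > 0 else "down", pe.q)
        )
    result = pd.DataFrame(rows, columns=cols)
    result["p_adj"] = bh_adjust(result["p"].to_numpy())
    return result.sort_values(["p_adj", "symbol"], kind="mergesort").reset_index(drop=True)


def significant_genes(meta_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows of a meta-analysis table significant at p_adj < alpha."""
    return meta_table[meta_table["p_adj"] < alpha]


def recurrence_summary(comparisons: list[ComparisonResult]) -> dict:
    """How many distinct DEGs recur in at least two comparisons.

    Returns ``n_unique_degs`` (distinct DEG symbols across all
    comparisons), ``n_recurrent`` (those reported by ≥2 comparisons) and
    ``pct_recurrent`` (their percentage, rounded to 2 decimals).
    """
    if not comparisons:
        raise ValueError("need at least one comparison")
    reports: dict[str, int] = {}
    for comp in comparisons:
        for sym, _ in comp.deg_set():
            reports[sym] = reports.get(sym, 0) + 1
    n_unique = len(reports)
    n_recurrent = sum(1 for n in reports.values() if n >= 2)
    pct = round(100.0 * n_recurrent / n_unique, 2) if n_unique else 0.0
    return {"n_unique_degs": n_unique, "n_recurrent": n_recurrent, "pct_recurrent": pct}


def subgroup_concordance(meta_a: pd.DataFrame, meta_b: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Direction agreement of significant genes shared by two subgroups.

    Returns counts of shared symbols, concordant up, concordant down, and
    discordant pairs; shared = up + down + discordant by construction.
    """
    a = significant_genes(meta_a, alpha).set_index("symbol")["direction"]
    b = significant_genes(meta_b, alpha).set_index("symbol")["direction"]
    shared = a.index.intersection(b.index)
    up = int(((a.loc[shared] == "up") & (b.loc[shared] == "up")).sum())
    down = int(((a.loc[shared] == "down") & (b.loc[shared] == "down")).sum())
    return {
        "n_shared": len(shared),
        "n_concordant_up": up,
        "n_concordant_down": down,
        "n_discordant": len(shared) - up - down,
    }


def run_subgroup_meta(
    comparisons: list[ComparisonResult],
    data: dict[str, tuple[pd.DataFrame, pd.Series]],
    region_map: dict[str, str],
    min_reports: int = 2,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-branch meta-analysis (BH within each subgroup).

    Comparisons mapped to ``other_branch`` are excluded with a warning;
    branches with fewer than two comparisons are skipped.
    """
    unmapped = [c.comparison_id for c in comparisons if c.comparison_id not in region_map]
    if unmapped:
        raise ValueError(f"comparisons missing from region map: {unmapped}")
    groups: dict[str, list[ComparisonResult]] = {}
    for comp in comparisons:
        label = region_map[comp.comparison_id]
        if label == SUBGROUP_OTHER:
            logger.warning("comparison %s in unmapped branch; excluded", comp.comparison_id)
            continue
        groups.setdefault(label, []).append(comp)
    out: dict[str, pd.DataFrame] = {}
    for label in sorted(groups):
        comps = groups[label]
        if len(comps) < 2:
            logger.warning("subgroup %s has <2 comparisons; skipped", label)
            continue
        sub_data = {c.comparison_id: data[c.comparison_id] for c in comps}
        out[label] = run_meta(comps, sub_data, min_reports=min_reports, alpha=alpha)
    return out
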