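"""Two-group differential expression with empirical-Bayes moderation.

Per gene, the effect is the log2 fold change (case − control) tested with
a pooled-variance t statistic. By default the per-gene variances are
shrunk toward a common prior estimated by method of moments on the log
sample variances under a scaled inverse-chi-square prior — the classic
moderated-t construction — which stabilizes small-sample comparisons.
Genes pass to the DEG list when the Benjamini–Hochberg adjusted p-value is
strictly below the significance level (default 0.05).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .types import CASE, CONTROL, ComparisonResult, ExpressionStudy

logger = logging.getLogger(__name__)

MODERATION_EB = "eb"
MODERATION_NONE = "none"


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0²) on {log s²}.

    Models s² ~ s0²·F(df, d0); the mean and variance of log F in terms of
    digamma/trigamma functions give moment equations for d0 and s0². A
    non-positive excess variance yields d0 = inf (all genes share s0²).
    Raises if no finite positive variances are available.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("too few positive variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    mean_e = float(np.mean(e))
    var_e = float(np.var(e, ddof=1))
    excess = var_e - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s02 = float(np.exp(mean_e))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s02 = float(np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderated_t_test(
    matrix: pd.DataFrame,
    group: pd.Series,
    moderation: str = MODERATION_EB,
    comparison_id: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Per-gene two-group test on a log2 symbol × samples matrix.

    logFC = mean(case) − mean(control); the pooled variance (n1+n2−2 df)
    is either used directly (``moderation="none"``) or shrunk toward the
    empirical-Bayes prior, in which case the t statistic has d0 + d_g
    degrees of freedom. Falls back to the plain t when prior estimation
    fails (logged). A gene with zero variance and zero logFC gets p = 1.
    """
    if moderation not in (MODERATION_EB, MODERATION_NONE):
        raise ValueError(f"unknown moderation {moderation!r}")
    group = group.loc[matrix.columns]
    case = matrix.loc[:, (group == CASE).to_numpy()].to_numpy(dtype=float)
    ctrl = matrix.loc[:, (group == CONTROL).to_numpy()].to_numpy(dtype=float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 samples per group")
    logfc = case.mean(axis=1) - ctrl.mean(axis=1)
    dg = n1 + n2 - 2
    s2 = (case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)) / dg

    if moderation == MODERATION_EB:
        try:
            d0, s02 = estimate_variance_prior(s2, dg)
        except ValueError:
            logger.warning("EB prior estimation failed; falling back to plain t")
            moderation = MODERATION_NONE
    if moderation == MODERATION_EB:
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s02)
            df_total = np.inf
        else:
            s2_tilde = (d0 * s02 + dg * s2) / (d0 + dg)
            df_total = d0 + dg
    else:
        s2_tilde = s2
        df_total = float(dg)

    denom = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, logfc / np.where(denom > 0, denom, 1.0), np.where(logfc == 0, 0.0, np.inf * np.sign(logfc)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # degenerate genes: no variance and no difference -> p = 1, not NaN
    degenerate = (denom == 0) & (logfc == 0)
    p = np.where(degenerate, 1.0, p)
    t = np.where(degenerate, 0.0, t)

    p_adj = bh_adjust(p)
    direction = np.where(logfc >= 0, "up", "down")
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "df": float(dg) if np.isinf(df_total) else float(df_total),
            "p": p,
            "p_adj": p_adj,
            "is_deg": p_adj < alpha,
            "direction": direction,
        },
        index=matrix.index.copy(),
    )
    table.index.name = "symbol"
    return ComparisonResult(comparison_id=comparison_id, table=table)


def call_degs(result: ComparisonResult, alpha: float = 0.05) -> set[tuple[str, str]]:
    """DEGs at strict p_adj < alpha, as (symbol, direction) pairs."""
    sub = result.table[result.table["p_adj"] < alpha]
    return set(zip(sub.index, sub["direction"]))


def run_diffexpr(
    study: ExpressionStudy, moderation: str = MODERATION_EB, alpha: float = 0.05
) -> ComparisonResult:
    """Differential expression for a preprocessed (log2, symbol-level) study."""
    return moderated_t_test(
        study.values, study.group, moderation=moderation, comparison_id=study.study_id, alpha=alpha
    )
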