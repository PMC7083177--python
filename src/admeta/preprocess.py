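"""Per-study normalization, probe handling, and outlier-array exclusion.

The microarray path is: background correction → quantile normalization →
log2 transform → probe-to-symbol collapse → three-metric outlier screen.
The count path is log-CPM. Both end in a symbol × samples matrix on the
log2 scale ready for differential testing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionStudy, PLATFORM_COUNT, PLATFORM_INTENSITY, QCReport

logger = logging.getLogger(__name__)

BG_NONE = "none"
BG_MIN_SHIFT = "min_shift"


def background_correct(study: ExpressionStudy, method: str = BG_MIN_SHIFT) -> ExpressionStudy:
    """Background-correct linear-scale intensities.

    ``min_shift`` subtracts each array's 5th percentile and floors the
    result at 1 so the subsequent log2 stays defined; ``none`` is the
    identity.
    """
    if study.platform != PLATFORM_INTENSITY:
        raise ValueError("background correction applies to intensity data only")
    if method == BG_NONE:
        return study
    if method != BG_MIN_SHIFT:
        raise ValueError(f"unknown background-correction method {method!r}")
    vals = study.values
    shifted = vals.sub(vals.quantile(0.05, axis=0), axis=1).clip(lower=1.0)
    return ExpressionStudy(
        study.study_id, study.region, study.platform, shifted, study.group, study.log_scale
    )


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every array onto the common distribution of sorted means.

    After the operation each column's sorted values equal the across-array
    mean of sorted values; ties within an array receive the mean of their
    tied quantile means. A single-column matrix is returned unchanged with
    a warning.
    """
    if matrix.shape[1] < 2:
        logger.warning("quantile normalization skipped: fewer than 2 arrays")
        return matrix.copy()
    if matrix.isna().any().any():
        raise ValueError("quantile normalization requires no missing values")
    arr = matrix.to_numpy(dtype=float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        out[order, j] = mean_sorted
        # ties: average the quantile means assigned within each tie group
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) < len(col):
            sums = np.bincount(inv, weights=out[:, j])
            out[:, j] = sums[inv] / counts[inv]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(study: ExpressionStudy, annotation: pd.Series) -> ExpressionStudy:
    """Collapse a probe-level matrix to unique gene symbols.

    Three steps: rows sharing a probe id are averaged element-wise; probes
    without a symbol are dropped; among probes mapping to the same symbol,
    the probe with the highest mean expression across arrays is kept.
    Expects log2-scale intensities.
    """
    vals = study.values
    if vals.index.duplicated().any():
        vals = vals.groupby(level=0, sort=False).mean()
    symbols = annotation.reindex(vals.index)
    keep = symbols.notna()
    vals = vals[keep.to_numpy()]
    symbols = symbols[keep]
    if vals.empty:
        raise ValueError("no annotated probes remain after collapse")
    means = vals.mean(axis=1)
    best = (
        pd.DataFrame({"symbol": symbols.to_numpy(), "mean": means.to_numpy(), "probe": vals.index})
        .sort_values(["symbol", "mean", "probe"], ascending=[True, False, True])
        .drop_duplicates("symbol", keep="first")
    )
    out = vals.loc[best["probe"]]
    out.index = pd.Index(best["symbol"].to_numpy(), name="symbol")
    out = out.sort_index()
    return ExpressionStudy(
        study.study_id, study.region, study.platform, out, study.group, study.log_scale
    )


def detect_outlier_arrays(matrix: pd.DataFrame) -> QCReport:
    """Flag outlier arrays with three metrics and a Tukey upper fence.

    Metrics per array: mean Euclidean distance to all other arrays;
    Kolmogorov–Smirnov statistic of the array's values against the pooled
    distribution of all arrays; mean absolute deviation from the
    row-median pseudo-reference. An array is an outlier on a metric when
    its value exceeds Q3 + 1.5·IQR across arrays; arrays flagged by at
    least one metric are omitted. With fewer than 4 arrays no exclusion is
    attempted.
    """
    arrays = list(matrix.columns)
    arr = matrix.to_numpy(dtype=float)
    n = arr.shape[1]
    if n < 4:
        logger.warning("outlier detection skipped: fewer than 4 arrays")
        empty = pd.DataFrame(index=arrays, columns=["distance", "ks", "ma"], dtype=float)
        return QCReport(metrics=empty, thresholds=pd.Series(dtype=float), omitted=[])

    # pairwise Euclidean distances between arrays
    gram = arr.T @ arr
    sq = np.diag(gram)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * gram, 0.0)
    dist = np.sqrt(d2)
    mean_dist = dist.sum(axis=0) / (n - 1)

    pooled = np.sort(arr.ravel())
    ks = np.array([stats.ks_2samp(arr[:, j], pooled, method="asymp").statistic for j in range(n)])

    ref = np.median(arr, axis=1)
    ma = np.mean(np.abs(arr - ref[:, None]), axis=0)

    metrics = pd.DataFrame({"distance": mean_dist, "ks": ks, "ma": ma}, index=arrays)
    q1 = metrics.quantile(0.25)
    q3 = metrics.quantile(0.75)
    thresholds = q3 + 1.5 * (q3 - q1)
    flagged = (metrics > thresholds).any(axis=1)
    omitted = [a for a in arrays if flagged[a]]
    return QCReport(metrics=metrics, thresholds=thresholds, omitted=omitted)


def drop_arrays(study: ExpressionStudy, arrays: list[str]) -> ExpressionStudy:
    """Remove the given arrays from a study (keeping ≥1 per group)."""
    keep = [c for c in study.values.columns if c not in set(arrays)]
    return ExpressionStudy(
        study.study_id,
        study.region,
        study.platform,
        study.values[keep],
        study.group.loc[keep],
        study.log_scale,
    )


def log_cpm(study: ExpressionStudy) -> pd.DataFrame:
    """log2 counts-per-million: log2((count + 0.5) / (libsize + 1) × 1e6)."""
    if study.platform != PLATFORM_COUNT:
        raise ValueError("log_cpm applies to count data only")
    counts = study.values.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    cpm = (counts + 0.5) / (lib + 1.0)[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm), index=study.values.index, columns=study.values.columns)


def preprocess_study(
    study: ExpressionStudy,
    annotation: pd.Series | None = None,
    background: str = BG_MIN_SHIFT,
    outliers_first: bool = False,
) -> tuple[ExpressionStudy, QCReport]:
    """Run the full per-study chain; returns the analysis-ready study + QC.

    Intensity default: background correction (linear input only) →
    quantile normalization → log2 → probe collapse → outlier screen on
    the collapsed matrix. ``outliers_first`` instead screens the log2
    matrix *before* normalization — quantile normalization equalizes
    array distributions and therefore erases the global shifts the screen
    is meant to catch. Count: log-CPM (no probe collapse, no array screen
    — RNA-seq read QC is upstream of this pipeline).
    """
    if study.platform == PLATFORM_COUNT:
        # the log-CPM matrix is no longer a count matrix; it re-enters the
        # common path as a derived log2 intensity-like study
        logged = log_cpm(study)
        out = ExpressionStudy(
            study.study_id, study.region, PLATFORM_INTENSITY, logged, study.group, log_scale=True
        )
        empty = pd.DataFrame(index=list(logged.columns), columns=["distance", "ks", "ma"], dtype=float)
        return out, QCReport(metrics=empty, thresholds=pd.Series(dtype=float), omitted=[])

    work = study
    if not work.log_scale:
        work = background_correct(work, method=background)

    report = None
    if outliers_first:
        pre = np.log2(work.values) if not work.log_scale else work.values
        report = detect_outlier_arrays(pre)
        if report.omitted:
            work = drop_arrays(work, report.omitted)

    normalized = quantile_normalize(work.values)
    if not work.log_scale:
        normalized = np.log2(normalized)
    work = ExpressionStudy(
        work.study_id, work.region, work.platform, normalized, work.group, log_scale=True
    )
    if annotation is not None:
        work = collapse_probes(work, annotation)
    if report is None:
        report = detect_outlier_arrays(work.values)
        if report.omitted:
            work = drop_arrays(work, report.omitted)
    return work, report
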