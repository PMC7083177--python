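"""Core domain containers shared across the pipeline stages.

Expression data travel as :class:`ExpressionStudy` objects (a features ×
samples matrix plus a case/control sample sheet); downstream stages exchange
plain :class:`pandas.DataFrame` tables with documented column contracts so
that every intermediate can be written to, and re-read from, TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"
VALID_GROUPS = frozenset({CASE, CONTROL})

PLATFORM_INTENSITY = "intensity"
PLATFORM_COUNT = "count"
VALID_PLATFORMS = frozenset({PLATFORM_INTENSITY, PLATFORM_COUNT})


@dataclass
class ExpressionStudy:
    """One case–control comparison: expression matrix plus sample sheet.

    Parameters
    ----------
    study_id
        Identifier of the comparison (a dataset may contribute several).
    region
        Brain-region label used for subgroup assignment.
    platform
        ``"intensity"`` (microarray-like, Gaussian on the log2 scale) or
        ``"count"`` (RNA-seq-like, non-negative integers).
    values
        Features × samples matrix. Row index holds probe or gene
        identifiers (duplicates allowed pre-collapse), columns are sample
        ids.
    group
        Per-sample label in ``{"case", "control"}``, indexed by sample id.
    log_scale
        For intensity data, whether values are already log2-transformed.
    """

    study_id: str
    region: str
    platform: str
    values: pd.DataFrame
    group: pd.Series
    log_scale: bool = True

    def __post_init__(self) -> None:
        if self.platform not in VALID_PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        cols = list(self.values.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate sample ids in matrix")
        unknown = set(self.group.unique()) - VALID_GROUPS
        if unknown:
            raise ValueError(f"unknown group label: {sorted(unknown)}")
        missing = set(cols) - set(self.group.index)
        if missing or len(self.group) != len(cols):
            raise ValueError("sample sheet does not match matrix columns")
        # harmonize sample order to the matrix column order
        self.group = self.group.loc[cols]
        for label in (CASE, CONTROL):
            if (self.group == label).sum() < 1:
                raise ValueError(f"need at least one {label} sample")
        if self.platform == PLATFORM_COUNT:
            arr = self.values.to_numpy()
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError("counts must be finite and non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("non-integer count on count platform")

    @property
    def case_samples(self) -> list[str]:
        return list(self.group.index[self.group == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.group.index[self.group == CONTROL])

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set id → members, plus descriptions."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def union(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out


@dataclass
class QCReport:
    """Array-quality report from the three-metric outlier screen.

    ``metrics`` has one row per array and one column per metric
    (``distance``, ``ks``, ``ma``); ``thresholds`` holds the Tukey upper
    fence per metric; ``omitted`` lists arrays flagged by at least one
    metric.
    """

    metrics: pd.DataFrame
    thresholds: pd.Series
    omitted: list[str]


@dataclass
class ComparisonResult:
    """Per-comparison differential-expression table.

    ``table`` is indexed by gene symbol with columns ``logFC`` (case −
    control, log2), ``t``, ``df``, ``p``, ``p_adj`` (BH), ``is_deg`` and
    ``direction`` (``up``/``down``).
    """

    comparison_id: str
    table: pd.DataFrame

    def deg_set(self) -> set[tuple[str, str]]:
        sub = self.table[self.table["is_deg"]]
        return set(zip(sub.index, sub["direction"]))


@dataclass
class EventTable2x2:
    """Dysregulation-event contingency table for one gene in one comparison.

    ``a``/``b`` are case events / non-events, ``c``/``d`` the control
    counterparts. ``corrected`` records that the Haldane–Anscombe +0.5 was
    applied to every cell (done whenever any raw cell is zero).
    """

    comparison_id: str
    symbol: str
    a: float
    b: float
    c: float
    d: float
    corrected: bool = False


@dataclass
class StudyEffect:
    """Log odds ratio effect for one comparison: θ, its variance v, w=1/v."""

    theta: float
    v: float

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError("effect variance must be positive")

    @property
    def w(self) -> float:
        return 1.0 / self.v


@dataclass
class PooledEffect:
    """Random-effects pooling result for one gene."""

    theta: float
    tau2: float
    se: float
    z: float
    p: float
    q: float
    k: int


@dataclass
class DegreeFit:
    """Power-law fit of a degree histogram: expected count ≈ C·x^b."""

    coefficient: float
    exponent: float
    r2: float


@dataclass
class DiseaseModule:
    """Seed genes plus the ordered DIAMOnD additions.

    ``additions`` columns: ``symbol``, ``iteration`` (1-based),
    ``connectivity_p``, ``k`` (degree), ``k_s`` (links into the module when
    added).
    """

    seeds: set[str]
    additions: pd.DataFrame

    @property
    def members(self) -> set[str]:
        return self.seeds | set(self.additions["symbol"])


@dataclass
class CohortTruth:
    """Ground truth for a synthetic multi-study cohort."""

    genes: list[str]
    state: pd.Series  # per gene: "up" | "down" | "null"
    effect_sizes: dict[str, float]  # study_id -> delta
    sample_sizes: dict[str, tuple[int, int]]  # study_id -> (n_case, n_control)
    outlier_arrays: dict[str, list[str]]  # study_id -> shifted sample ids
    probe_map: dict[str, list[str]]  # symbol -> probe ids (intensity)

    def nonnull_genes(self) -> set[str]:
        return set(self.state.index[self.state != "null"])


@dataclass
class NetworkTruth:
    """Ground truth for a synthetic interactome with a planted module."""

    nodes: list[str]
    module: set[str]
    seeds: set[str]

    def __post_init__(self) -> None:
        if not self.seeds <= self.module:
            raise ValueError("seeds must lie inside the planted module")
        if not self.module <= set(self.nodes):
            raise ValueError("planted module must lie inside the node set")
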