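"""Readers and writers for every external file the pipeline touches.

The single tabular dialect is TSV (UTF-8, no quoting, ``.`` decimal);
gene sets use standard GMT. All writers are deterministic: fixed column
order, documented row sort, floats at six significant digits — writing the
same table twice yields byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ExpressionStudy, GeneSetCollection, VALID_GROUPS

logger = logging.getLogger(__name__)

SCORE_SCALE_UNIT = "unit"
SCORE_SCALE_STRING1000 = "string1000"


def read_expression_study(
    path_matrix: str | Path,
    path_samples: str | Path,
    platform: str,
    study_id: str | None = None,
    region: str = "",
    log_scale: bool = True,
) -> ExpressionStudy:
    """Load a features × samples TSV matrix plus its sample sheet.

    The matrix TSV has a header row of sample ids and feature ids in the
    first column; the sample sheet has columns ``sample_id`` and ``group``
    with group in ``{case, control}``. Sample order is harmonized to the
    matrix column order.
    """
    matrix = pd.read_csv(path_matrix, sep="\t", index_col=0)
    sheet = pd.read_csv(path_samples, sep="\t", dtype=str)
    if "sample_id" not in sheet.columns or "group" not in sheet.columns:
        raise ValueError("sample sheet needs columns sample_id, group")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    unknown = set(sheet["group"]) - VALID_GROUPS
    if unknown:
        raise ValueError(f"unknown group label: {sorted(unknown)}")
    group = sheet.set_index("sample_id")["group"]
    if set(matrix.columns) != set(group.index):
        raise ValueError("sample sheet does not match matrix columns")
    return ExpressionStudy(
        study_id=study_id or Path(path_matrix).stem,
        region=region,
        platform=platform,
        values=matrix,
        group=group,
        log_scale=log_scale,
    )


def read_annotation(path: str | Path) -> pd.Series:
    """Read a probe → gene-symbol table (columns ``probe_id``, ``symbol``).

    Probe ids must be unique. Empty symbols load as missing (NaN). A probe
    annotated with several symbols (``A /// B`` or ``A|B``) keeps the first
    listed symbol; the event is logged.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "probe_id" not in table.columns or "symbol" not in table.columns:
        raise ValueError("annotation needs columns probe_id, symbol")
    if table["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids in annotation")
    symbols = table.set_index("probe_id")["symbol"]
    multi = symbols.str.contains(r"\s*///\s*|\|", regex=True, na=False)
    if multi.any():
        logger.info("%d probes map to multiple symbols; keeping the first", multi.sum())
        symbols = symbols.str.split(r"\s*///\s*|\|", regex=True).str[0]
    symbols = symbols.replace("", np.nan)
    return symbols


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene TAB gene ...``.

    Genes duplicated within a line are deduplicated; duplicate set names
    are an error; an empty file yields an empty collection.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def read_edge_table(path: str | Path, score_scale: str = SCORE_SCALE_STRING1000) -> pd.DataFrame:
    """Read a STRING-style edge list (columns ``node_a, node_b, score``).

    Scores are normalized to [0, 1] (``string1000`` scores divided by
    1000). Self-loops are dropped; duplicate undirected pairs keep the
    maximum score. The result is sorted by (node_a, node_b) with
    node_a < node_b, so row order of the input does not matter.
    """
    table = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    for col in ("node_a", "node_b", "score"):
        if col not in table.columns:
            raise ValueError(f"edge table needs column {col!r}")
    score = table["score"].astype(float)
    if score_scale == SCORE_SCALE_STRING1000:
        if (score < 0).any() or (score > 1000).any():
            raise ValueError("score outside [0, 1000]")
        score = score / 1000.0
    elif score_scale == SCORE_SCALE_UNIT:
        if (score < 0).any() or (score > 1).any():
            raise ValueError("score outside [0, 1]")
    else:
        raise ValueError(f"unknown score scale {score_scale!r}")
    edges = pd.DataFrame(
        {
            "node_a": np.minimum(table["node_a"], table["node_b"]),
            "node_b": np.maximum(table["node_a"], table["node_b"]),
            "score": score,
        }
    )
    edges = edges[edges["node_a"] != edges["node_b"]]
    edges = (
        edges.groupby(["node_a", "node_b"], as_index=False)["score"]
        .max()
        .sort_values(["node_a", "node_b"])
        .reset_index(drop=True)
    )
    return edges


def read_seed_genes(path: str | Path, p_cutoff: float = 1e-8) -> pd.DataFrame:
    """Read GWAS seed genes (columns ``symbol, association_p``).

    Rows at genome-wide significance (association_p ≤ ``p_cutoff``,
    boundary inclusive) are retained; duplicate symbols collapse to the
    smallest p.
    """
    table = pd.read_csv(path, sep="\t", dtype={"symbol": str})
    for col in ("symbol", "association_p"):
        if col not in table.columns:
            raise ValueError(f"seed table needs column {col!r}")
    p = table["association_p"].astype(float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("association p outside (0, 1]")
    kept = table[p <= p_cutoff]
    if kept.empty:
        logger.warning("no seed genes at p <= %g", p_cutoff)
        return pd.DataFrame(columns=["symbol", "association_p"])
    out = (
        kept.groupby("symbol", as_index=False)["association_p"]
        .min()
        .sort_values(["association_p", "symbol"])
        .reset_index(drop=True)
    )
    return out


def write_results(table: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None) -> None:
    """Write a result table as deterministic TSV.

    Rows are sorted by ``sort_by`` (default: ``p_adj`` then ``symbol``
    where present, else the existing order); floats are rendered at six
    significant digits so repeated writes are byte-identical.
    """
    if table is None:
        raise ValueError("table is None")
    out = table.copy()
    if sort_by is None:
        sort_by = [c for c in ("p_adj", "symbol") if c in out.columns]
    if sort_by:
        out = out.sort_values(sort_by, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def write_expression_study(study: ExpressionStudy, path_matrix: str | Path, path_samples: str | Path) -> None:
    """Write a study back to the matrix + sample-sheet TSV pair."""
    study.values.to_csv(path_matrix, sep="\t", float_format="%.6g", lineterminator="\n")
    sheet = pd.DataFrame({"sample_id": study.group.index, "group": study.group.values})
    sheet.to_csv(path_samples, sep="\t", index=False, lineterminator="\n")


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write gene sets in GMT, sets and members in sorted order."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
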