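"""Merge target-prediction lists and filter differential-expression tables.

Candidate direct targets of a miRNA are obtained by (1) taking the union of
the gene lists returned by several prediction databases, keeping per-gene
provenance, (2) intersecting with the genes detected in an RNA-seq
experiment, and (3) keeping the genes that respond in the direction
de-repression predicts — upregulated in a miRNA loss-of-function mutant —
at an adjusted-p and |log2 fold change| cutoff.  Both filters are strict
inequalities (padj < 0.05, log2FC > 0.5 by default); boundary-equal values
are excluded.

Tables are plain pandas DataFrames with columns ``gene_id``, optional
``gene_name``, ``log2fc``, ``padj`` and optional ``biotype``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from mirkit.errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

_REQUIRED_DE_COLUMNS = ("gene_id", "log2fc", "padj")


@dataclass(frozen=True)
class MergedPredictions:
    """Union of several prediction lists with per-gene source provenance."""

    sources: dict[str, frozenset[str]]  # gene_id -> set of database labels
    n_unique: int
    n_multi_source: int
    n_by_source_count: dict[int, int] = field(default_factory=dict)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self.sources)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.sources


def _normalize_id(gene_id: str) -> str:
    return str(gene_id).strip()


def merge_predictions(lists: Mapping[str, Iterable[str]]) -> MergedPredictions:
    """Union several per-database gene lists, keeping provenance.

    ``lists`` maps a database label to its predicted gene ids.  Gene ids
    are whitespace-trimmed before the union; within one database duplicate
    ids collapse.  The result records, for every gene, which databases
    predicted it, the number of unique genes, and the number predicted by
    two or more databases.  The union size obeys the counting identity
    ``n_unique = Σ|list_i| − (#in exactly 2) − 2·(#in exactly 3)`` for up
    to three databases, which is checked and logged.
    """
    if not lists:
        raise ValidationError("merge_predictions requires at least one list")
    per_gene: dict[str, set[str]] = {}
    sizes = {}
    for label, ids in lists.items():
        deduped = {_normalize_id(g) for g in ids}
        sizes[label] = len(deduped)
        for g in deduped:
            per_gene.setdefault(g, set()).add(label)
    by_count = Counter(len(s) for s in per_gene.values())
    n_unique = len(per_gene)
    expected = sum(sizes.values()) - sum((k - 1) * v for k, v in by_count.items())
    if expected != n_unique:  # pragma: no cover - arithmetic identity
        logger.warning("prediction-merge counting identity violated")
    return MergedPredictions(
        sources={g: frozenset(s) for g, s in per_gene.items()},
        n_unique=n_unique,
        n_multi_source=sum(v for k, v in by_count.items() if k >= 2),
        n_by_source_count=dict(sorted(by_count.items())),
    )


def _check_de_schema(de_table: pd.DataFrame) -> pd.DataFrame:
    for col in _REQUIRED_DE_COLUMNS:
        if col not in de_table.columns:
            raise SchemaError(f"differential-expression table is missing column {col!r}")
    table = de_table.copy()
    for col in ("log2fc", "padj"):
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"column {col!r}: non-numeric value {table[col].iloc[row]!r} "
                f"at row {row + 1}"
            )
        table[col] = numeric
    table["gene_id"] = table["gene_id"].map(_normalize_id)
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].unique()
        raise ValidationError(f"duplicate gene ids in DE table: {', '.join(dupes[:5])}")
    return table


def filter_candidates(
    de_table: pd.DataFrame,
    predictions: MergedPredictions | Iterable[str] | None = None,
    padj_max: float = 0.05,
    min_log2fc: float = 0.5,
    direction: str = "up",
) -> pd.DataFrame:
    """Filter a DE table down to candidate direct targets.

    Keeps genes that are in ``predictions`` (if given), have
    ``padj < padj_max`` (strict) and respond beyond ``min_log2fc`` in the
    requested direction (strict; ``up``, ``down`` or ``both``).  The output
    is sorted by descending ``|log2fc|``, ties broken by ``gene_id``, and
    carries ``sources``/``n_sources`` provenance columns when predictions
    are supplied.
    """
    if padj_max <= 0 or min_log2fc < 0:
        raise ValidationError("padj_max must be > 0 and min_log2fc >= 0")
    if direction not in {"up", "down", "both"}:
        raise ValidationError(f"unknown direction {direction!r}")
    table = _check_de_schema(de_table)

    mask = table["padj"] < padj_max
    if direction == "up":
        mask &= table["log2fc"] > min_log2fc
    elif direction == "down":
        mask &= table["log2fc"] < -min_log2fc
    else:
        mask &= table["log2fc"].abs() > min_log2fc

    source_map: dict[str, frozenset[str]] | None = None
    if predictions is not None:
        if isinstance(predictions, MergedPredictions):
            source_map = predictions.sources
        else:
            source_map = {_normalize_id(g): frozenset(["predicted"]) for g in predictions}
        mask &= table["gene_id"].isin(source_map)

    out = table.loc[mask].copy()
    out["abs_log2fc"] = out["log2fc"].abs()
    out = (
        out.sort_values(["abs_log2fc", "gene_id"], ascending=[False, True])
        .drop(columns="abs_log2fc")
        .reset_index(drop=True)
    )
    if source_map is not None:
        out["sources"] = out["gene_id"].map(
            lambda g: ",".join(sorted(source_map[g]))
        )
        out["n_sources"] = out["gene_id"].map(lambda g: len(source_map[g]))
    return out


def summarize_prediction_overlap(
    de_table: pd.DataFrame,
    predictions: MergedPredictions,
    padj_max: float = 0.05,
) -> dict:
    """Intersect merged predictions with a DE table.

    A predicted gene is *detected* if it appears in the DE table at all and
    *dysregulated* if additionally ``padj < padj_max``.  Prediction ids not
    found in the table are returned (not silently dropped).
    """
    table = _check_de_schema(de_table)
    detected_ids = set(table["gene_id"])
    predicted = set(predictions.gene_ids)
    detected = predicted & detected_ids
    sub = table[table["gene_id"].isin(detected)]
    dys = sub[sub["padj"] < padj_max]
    return {
        "n_predicted": len(predicted),
        "n_detected": len(detected),
        "n_dysregulated": len(dys),
        "n_up": int((dys["log2fc"] > 0).sum()),
        "n_down": int((dys["log2fc"] < 0).sum()),
        "unmatched_ids": sorted(predicted - detected_ids),
    }


def summarize_dysregulation(de_table: pd.DataFrame, padj_max: float = 0.05) -> dict:
    """Count up/down dysregulated genes and the lncRNA breakdown.

    Dysregulated means ``padj < padj_max``.  Genes with a log2fc of exactly
    0 among the dysregulated are counted as neither up nor down and
    reported separately (a well-formed DE table cannot contain them).
    Percentages are rounded to one decimal.
    """
    table = _check_de_schema(de_table)
    dys = table[table["padj"] < padj_max]
    n_dys = len(dys)
    if n_dys == 0:
        logger.warning("no dysregulated rows at padj < %s", padj_max)
        return {
            "n_detected": len(table),
            "n_dysregulated": 0,
            "n_up": 0,
            "n_down": 0,
            "n_zero": 0,
            "pct_down": 0.0,
            "pct_up": 0.0,
            "biotype_breakdown": {},
            "lncRNA": None,
        }
    n_up = int((dys["log2fc"] > 0).sum())
    n_down = int((dys["log2fc"] < 0).sum())
    n_zero = n_dys - n_up - n_down
    if n_zero:
        logger.warning("%d dysregulated rows have log2fc exactly 0", n_zero)

    biotype_breakdown: dict[str, dict] = {}
    lnc_summary = None
    if "biotype" in dys.columns:
        for biotype, grp in dys.groupby("biotype"):
            biotype_breakdown[str(biotype)] = {
                "n": len(grp),
                "n_up": int((grp["log2fc"] > 0).sum()),
                "n_down": int((grp["log2fc"] < 0).sum()),
            }
        lnc = biotype_breakdown.get("lncRNA")
        if lnc and lnc["n"] > 0:
            lnc_summary = {
                **lnc,
                "pct_up": round(100.0 * lnc["n_up"] / lnc["n"], 1),
                "pct_down": round(100.0 * lnc["n_down"] / lnc["n"], 1),
            }
    return {
        "n_detected": len(table),
        "n_dysregulated": n_dys,
        "n_up": n_up,
        "n_down": n_down,
        "n_zero": n_zero,
        "pct_down": round(100.0 * n_down / n_dys, 1),
        "pct_up": round(100.0 * n_up / n_dys, 1),
        "biotype_breakdown": biotype_breakdown,
        "lncRNA": lnc_summary,
    }
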