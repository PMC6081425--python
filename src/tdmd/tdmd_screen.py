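"""Candidate TDMD target screen.

Predicted miRNA:target pairs carrying a 3'-pairing-contribution score
(3C-score, a non-positive TargetScan quantity; more negative = more 3'
complementarity) are classed, filtered by contextual expression, and ranked
by their dynamic range and by their share of the miRNA's 3C-target pool.

Prediction tables are pandas DataFrames with columns
``gene, mirna, site_type, conserved, c3_score`` (see :func:`read_targetscan`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, as_dataframe

logger = logging.getLogger("tdmd")

REQUIRED_COLUMNS = ["gene", "mirna", "site_type", "conserved", "c3_score"]


class ThreeCClass(IntEnum):
    """3C-score class; total order follows decreasing (more negative) score."""

    NONE = 0
    LOW = 1
    MID = 2
    HIGH = 3


@dataclass(frozen=True)
class TargetRecord:
    gene: str
    mirna: str
    site_type: str
    conserved: bool
    c3_score: float

    def __post_init__(self) -> None:
        if self.c3_score > 0:
            raise ValueError("3C-score must be <= 0")


def read_targetscan(path) -> pd.DataFrame:
    """Read a TargetScan-style TSV (gene, miRNA, site type, conserved, 3C-score)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["c3_score"] > 0).any():
        raise ValueError(f"{path}: positive 3C-score encountered")
    return df


def classify_3c(
    c3_score: float,
    entry: float = -0.01,
    low_mid: float = -0.03,
    mid_high: float = -0.05,
) -> ThreeCClass:
    """Class of one 3C-score; boundary values fall in the more negative class."""
    if c3_score > 0:
        raise ValueError("3C-score must be <= 0")
    if c3_score <= mid_high:
        return ThreeCClass.HIGH
    if c3_score <= low_mid:
        return ThreeCClass.MID
    if c3_score <= entry:
        return ThreeCClass.LOW
    return ThreeCClass.NONE


def classify_table(records: pd.DataFrame, **bounds) -> pd.DataFrame:
    """Return a copy of the table with a ``c3_class`` column added."""
    out = records.copy()
    out["c3_class"] = [classify_3c(s, **bounds) for s in out["c3_score"]]
    return out


def filter_expressed(
    records: pd.DataFrame,
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    rpkm_min: float = 1.0,
    cpm_min: float = 10.0,
) -> pd.DataFrame:
    """Keep pairs whose gene reaches >= rpkm_min in at least one condition and
    whose miRNA exceeds cpm_min (strictly). Absent genes/miRNAs count as not
    expressed and are logged."""
    gmax = as_dataframe(gene_expr).max(axis=1)
    mmax = as_dataframe(mirna_expr).max(axis=1)
    absent_g = set(records["gene"]) - set(gmax.index)
    absent_m = set(records["mirna"]) - set(mmax.index)
    if absent_g:
        logger.info("%d genes absent from expression matrix", len(absent_g))
    if absent_m:
        logger.info("%d miRNAs absent from CPM matrix", len(absent_m))
    gene_ok = records["gene"].map(gmax).fillna(0) >= rpkm_min
    mirna_ok = records["mirna"].map(mmax).fillna(0) > cpm_min
    return records[gene_ok & mirna_ok].reset_index(drop=True)


def fraction_3c(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-miRNA percentage of predictions that are 3C-targets, per class.

    The denominator is the miRNA's total predictions (the table must include
    the non-3C predictions, class NONE). Returns the per-miRNA table and the
    aggregate percentage of 3C predictions over the whole pool.
    """
    table = records if "c3_class" in records.columns else classify_table(records)
    rows = []
    for mirna, grp in table.groupby("mirna"):
        n = len(grp)
        if n == 0:
            logger.info("miRNA %s has zero predictions; omitted", mirna)
            continue
        row = {"mirna": mirna, "n_predictions": n}
        for cls in (ThreeCClass.LOW, ThreeCClass.MID, ThreeCClass.HIGH):
            row[f"pct_{cls.name.lower()}"] = 100.0 * (grp["c3_class"] == cls).sum() / n
        row["pct_3c"] = 100.0 * (grp["c3_class"] != ThreeCClass.NONE).sum() / n
        rows.append(row)
    per_mirna = pd.DataFrame(rows)
    aggregate = 100.0 * (table["c3_class"] != ThreeCClass.NONE).sum() / len(table)
    return per_mirna, aggregate


def pool_contribution(
    gene: str,
    mirna: str,
    records: pd.DataFrame,
    gene_expr: ExpressionMatrix,
    class_floor: ThreeCClass = ThreeCClass.LOW,
    condition: str | None = None,
) -> float:
    """Percent contribution of one target to the miRNA's 3C pool.

    100 x RPKM(gene, condition) / sum of RPKM over all the miRNA's
    3C-targets at or above ``class_floor`` in that condition.
    """
    table = records if "c3_class" in records.columns else classify_table(records)
    expr = as_dataframe(gene_expr)
    if condition is None:
        condition = expr.columns[0]
    pool = table[(table["mirna"] == mirna) & (table["c3_class"] >= class_floor)]
    if gene not in set(pool["gene"]):
        raise ValueError(
            f"{gene} is not a 3C-target of {mirna} at class >= {class_floor.name}"
        )
    pool_genes = [g for g in pool["gene"].unique() if g in expr.index]
    denom = expr.loc[pool_genes, condition].sum()
    if denom <= 0:
        raise ZeroDivisionError(
            f"zero total 3C-pool expression for {mirna} in {condition}"
        )
    return 100.0 * expr.loc[gene, condition] / denom


def pool_contribution_table(
    records: pd.DataFrame,
    gene_expr: ExpressionMatrix,
    class_floor: ThreeCClass = ThreeCClass.LOW,
) -> pd.DataFrame:
    """Max pool contribution (over conditions) for every (gene, miRNA) pair."""
    table = records if "c3_class" in records.columns else classify_table(records)
    expr = as_dataframe(gene_expr)
    pool = table[table["c3_class"] >= class_floor]
    out = []
    for mirna, grp in pool.groupby("mirna"):
        genes = [g for g in grp["gene"].unique() if g in expr.index]
        if not genes:
            continue
        sub = expr.loc[genes]
        denom = sub.sum(axis=0)
        valid = denom > 0
        if not valid.any():
            logger.info("zero 3C pool for %s in all conditions", mirna)
            continue
        shares = 100.0 * sub.loc[:, valid].div(denom[valid], axis=1)
        for gene in genes:
            out.append(
                {"gene": gene, "mirna": mirna, "max_pool_pct": shares.loc[gene].max()}
            )
    return pd.DataFrame(out)


def rank_candidates(
    records: pd.DataFrame,
    gene_expr_timecourse: ExpressionMatrix,
    pseudocount: float = 0.1,
    reference: str | None = None,
    pool_class_floor: ThreeCClass = ThreeCClass.LOW,
) -> pd.DataFrame:
    """Rank candidate TDMD pairs by class, pool share and dynamic range.

    For every (gene, miRNA) pair: max log2 FC of the gene between any
    condition and the reference (first column by default; RPKM pseudocount
    bounds fold-changes of transcripts absent at the reference), max pool
    contribution, max RPKM. Sorted by (c3_class, max_pool_pct, max_log2fc)
    descending.
    """
    table = records if "c3_class" in records.columns else classify_table(records)
    expr = as_dataframe(gene_expr_timecourse)
    if expr.shape[1] < 2:
        raise ValueError("time course requires >= 2 conditions")
    if reference is None:
        reference = expr.columns[0]
    lfc = np.log2(expr.add(pseudocount)).sub(
        np.log2(expr[reference] + pseudocount), axis=0
    )
    max_lfc = lfc.max(axis=1)
    max_rpkm = expr.max(axis=1)
    shares = pool_contribution_table(table, gene_expr_timecourse, pool_class_floor)

    # a (gene, miRNA) pair may carry several sites: keep its best class
    pairs = (
        table.groupby(["gene", "mirna"], as_index=False)["c3_class"].max()
    )
    pairs = pairs[pairs["gene"].isin(expr.index)].copy()
    pairs["max_log2fc"] = pairs["gene"].map(max_lfc)
    pairs["max_rpkm"] = pairs["gene"].map(max_rpkm)
    pairs = pairs.merge(shares, on=["gene", "mirna"], how="left")
    pairs["max_pool_pct"] = pairs["max_pool_pct"].fillna(0.0)
    pairs = pairs.sort_values(
        ["c3_class", "max_pool_pct", "max_log2fc", "gene", "mirna"],
        ascending=[False, False, False, True, True],
    ).reset_index(drop=True)
    return pairs
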