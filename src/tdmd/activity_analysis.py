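"""miRNA-activity statistics.

Quantifies changes in miRNA-mediated repression: median log2-fold-change
shifts of target sets against non-targets (Wilcoxon rank-sum), cumulative
distributions, per-miRNA summaries over chimera-derived target sets,
per-miRNA differential expression (Welch's t-test), the two-clone serum DEG
filter, per-cluster target enrichment (chi-square contingency), and the
binned flow-cytometry estimator of sensor repression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("tdmd")


@dataclass(frozen=True)
class TargetSet:
    """A named set of target genes (TargetScan CS/NCS, HITS-CLIP, CLEAR-CLIP,
    seed subclass...), restricted to the expressed-gene universe."""

    name: str
    genes: frozenset

    @classmethod
    def from_iterable(cls, name, genes) -> "TargetSet":
        return cls(name, frozenset(genes))


def target_set_shift(
    reg: pd.DataFrame,
    target_set: TargetSet,
    contrast: str,
) -> tuple[float, float]:
    """Median log2 FC shift of a target set versus non-targets.

    Returns ``(delta_median, wilcoxon_p)`` where delta_median =
    median(targets) - median(non-targets) and p is the two-sided Wilcoxon
    rank-sum p-value.
    """
    values = reg[contrast].dropna()
    in_set = values.index.isin(target_set.genes)
    targets = values[in_set]
    background = values[~in_set]
    if len(targets) == 0:
        raise ValueError(f"target set {target_set.name!r} is empty in this table")
    if len(background) == 0:
        raise ValueError("complement of the target set is empty")
    delta = float(targets.median() - background.median())
    stat = stats.ranksums(targets, background)
    return delta, float(stat.pvalue)


def shift_table(
    reg: pd.DataFrame,
    sets: list[TargetSet],
    contrasts: list[str] | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """delta-median and Wilcoxon p for every set x contrast; optional BH FDR."""
    contrasts = contrasts or list(reg.columns)
    rows = []
    for ts in sets:
        for contrast in contrasts:
            delta, p = target_set_shift(reg, ts, contrast)
            rows.append(
                {"set": ts.name, "contrast": contrast, "delta_median": delta, "p": p}
            )
    out = pd.DataFrame(rows)
    if fdr:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def cdf_table(
    reg: pd.DataFrame,
    sets: list[TargetSet],
    contrast: str,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Empirical CDF point sets per target set, plus the non-target curve."""
    values = reg[contrast].dropna()
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    covered = set()
    for ts in sets:
        sub = values[values.index.isin(ts.genes)]
        if len(sub) == 0:
            logger.info("set %s empty for contrast %s", ts.name, contrast)
            continue
        ecdf = ECDF(sub.to_numpy())
        out[ts.name] = (ecdf.x, ecdf.y)
        covered |= set(sub.index)
    rest = values[~values.index.isin(covered)]
    if len(rest):
        ecdf = ECDF(rest.to_numpy())
        out["non-targets"] = (ecdf.x, ecdf.y)
    return out


def per_mirna_summary(
    reg: pd.DataFrame,
    chimera_sets: dict[str, set],
    contrast: str,
    min_targets: int = 50,
) -> pd.Series:
    """Median log2 FC per miRNA over its expressed targets.

    miRNAs with fewer than ``min_targets`` targets present in the regulation
    table are omitted.
    """
    values = reg[contrast].dropna()
    medians = {}
    for mirna, genes in chimera_sets.items():
        sub = values[values.index.isin(genes)]
        if len(sub) < min_targets:
            continue
        medians[mirna] = float(sub.median())
    return pd.Series(medians, name=contrast).sort_values()


def mirna_differential(
    cpm_wt: pd.DataFrame,
    cpm_ko: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-miRNA log2 FC (KO vs WT of mean log2 CPM) and Welch's t-test p.

    Both matrices are miRNA x replicate CPM tables with matching rows;
    each group needs >= 2 replicates.
    """
    if cpm_wt.shape[1] < 2 or cpm_ko.shape[1] < 2:
        raise ValueError("Welch's t-test requires >= 2 replicates per group")
    common = cpm_wt.index.intersection(cpm_ko.index)
    lw = np.log2(cpm_wt.loc[common] + pseudocount)
    lk = np.log2(cpm_ko.loc[common] + pseudocount)
    t = stats.ttest_ind(lk, lw, axis=1, equal_var=False)
    return pd.DataFrame(
        {
            "log2fc": lk.mean(axis=1) - lw.mean(axis=1),
            "welch_p": t.pvalue,
        },
        index=common,
    )


def serum_deg_filter(
    expr_wt: pd.DataFrame,
    expr_ko1: pd.DataFrame,
    expr_ko2: pd.DataFrame,
    rpkm_min: float = 1.0,
    lfc_min: float = 1.0,
    pseudocount: float = 0.1,
) -> list[str]:
    """Serum-stimulation differential genes, called jointly in two clones.

    A gene qualifies when its maximum RPKM across all three series exceeds
    ``rpkm_min`` and |log2 FC(KO vs WT)| > lfc_min in BOTH mutant clones,
    with the same sign, at one or more shared time points. Time points are
    matched by column label.
    """
    timepoints = [c for c in expr_wt.columns if c in expr_ko1.columns and c in expr_ko2.columns]
    if not timepoints:
        raise ValueError("no shared time points between the three series")
    genes = expr_wt.index.intersection(expr_ko1.index).intersection(expr_ko2.index)
    wt = expr_wt.loc[genes, timepoints]
    ko1 = expr_ko1.loc[genes, timepoints]
    ko2 = expr_ko2.loc[genes, timepoints]
    expressed = (
        pd.concat([wt, ko1, ko2], axis=1).max(axis=1) > rpkm_min
    )
    l1 = np.log2(ko1 + pseudocount) - np.log2(wt + pseudocount)
    l2 = np.log2(ko2 + pseudocount) - np.log2(wt + pseudocount)
    concordant = (
        (l1.abs() > lfc_min) & (l2.abs() > lfc_min) & (np.sign(l1) == np.sign(l2))
    ).any(axis=1)
    return sorted(genes[expressed & concordant])


def cluster_enrichment(
    cluster_assignments: pd.Series,
    target_set: TargetSet | set,
    universe: set | None = None,
) -> pd.DataFrame:
    """Per-cluster 2x2 chi-square contingency test of target enrichment.

    For each cluster the table crosses in-cluster membership with
    target-set membership over the universe (all clustered genes by
    default). Uncorrected Pearson chi-square; clusters with a zero expected
    count are flagged and their p omitted.
    """
    genes = set(universe) if universe is not None else set(cluster_assignments.index)
    targets = target_set.genes if isinstance(target_set, TargetSet) else set(target_set)
    targets = targets & genes
    assign = cluster_assignments[cluster_assignments.index.isin(genes)]
    rows = []
    for cluster in sorted(assign.unique()):
        members = set(assign[assign == cluster].index)
        a = len(members & targets)
        b = len(members) - a
        c = len(targets) - a
        d = len(genes) - a - b - c
        table = np.array([[a, b], [c, d]])
        expected_ok = (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all()
        row = {
            "cluster": cluster,
            "n_genes": len(members),
            "n_targets": a,
            "enrichment": (a / len(members)) / (len(targets) / len(genes))
            if members and targets
            else np.nan,
        }
        if expected_ok:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            row["chi2"], row["p"] = chi2, p
        else:
            row["chi2"], row["p"] = np.nan, np.nan
            logger.warning("cluster %s: zero expected count, p omitted", cluster)
        rows.append(row)
    return pd.DataFrame(rows)


def sensor_repression(
    sensor: pd.DataFrame,
    control: pd.DataFrame,
    n_bins: int = 100,
    bin_size: int = 1000,
) -> tuple[np.ndarray, float]:
    """Binned flow-cytometry estimate of sensor repression fold.

    Both populations carry per-cell ``dngfr`` (transduction co-reporter) and
    ``dgfp`` (miRNA-responsive reporter) intensities. Channels are
    log-transformed; each population is sorted by dNGFR and divided into
    ``n_bins`` equal-count bins of ``bin_size`` cells (shrunk to
    floor(n/n_bins) when events are scarce, with a log entry). The per-bin
    fold is the ratio of geometric-mean dGFP, control over sensor, matched
    by bin rank, so repression > 1; the summary is the mean over bins.
    """
    for name, pop in (("sensor", sensor), ("control", control)):
        if len(pop) == 0:
            raise ValueError(f"{name} population is empty")
        if (pop[["dngfr", "dgfp"]] <= 0).any().any():
            raise ValueError(f"{name}: intensities must be positive")
    n_min = min(len(sensor), len(control))
    size = bin_size
    if n_min < n_bins * bin_size:
        size = n_min // n_bins
        if size == 0:
            raise ValueError("too few events for the requested number of bins")
        logger.info("bin size reduced to %d (only %d events)", size, n_min)

    def bin_means(pop: pd.DataFrame) -> np.ndarray:
        order = np.argsort(pop["dngfr"].to_numpy(), kind="mergesort")
        log_gfp = np.log(pop["dgfp"].to_numpy())[order][: n_bins * size]
        return log_gfp.reshape(n_bins, size).mean(axis=1)

    folds = np.exp(bin_means(control) - bin_means(sensor))
    return folds, float(folds.mean())
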