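"""Expression calling, stress classification, pattern clustering, and qPCR.

A gene counts as expressed in a condition when FPKM strictly exceeds 1
(the protocol's wording; boundary values are logged so the inclusive
convention is recoverable). Under stress, a gene is up-regulated when the
treatment/control ratio exceeds 2-fold and down-regulated below one half;
ratios use a small pseudocount so zero-FPKM controls are well defined.
Expression patterns come from average-linkage hierarchical clustering on
1 - Pearson correlation of log2(FPKM + 1) rows, cut where merge similarity
drops below a 0.5 correlation. qPCR relative expression follows the
2^-ddCt method against a reference gene and calibrator condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

logger = logging.getLogger("genefam")

RATIO_PSEUDOCOUNT = 0.01
LOG_PSEUDOCOUNT = 1.0


# ---------------------------------------------------------------------------
# Expressed / differential calls
# ---------------------------------------------------------------------------

@dataclass
class ExpressionCalls:
    gene_ids: list[str]
    condition_ids: list[str]
    expressed: np.ndarray  # boolean gene x condition
    expressed_any: np.ndarray  # boolean per gene

    def n_expressed_any(self) -> int:
        return int(self.expressed_any.sum())


def call_expressed(matrix: ExpressionMatrix, threshold: float = 1.0) -> ExpressionCalls:
    """Flag FPKM > threshold per condition; expressed_any = any condition."""
    flags = matrix.values > threshold
    boundary = int((matrix.values == threshold).sum())
    if boundary:
        logger.info("call_expressed: %d cells exactly at threshold %g (called not expressed)",
                    boundary, threshold)
    return ExpressionCalls(
        gene_ids=list(matrix.gene_ids),
        condition_ids=list(matrix.condition_ids),
        expressed=flags,
        expressed_any=flags.any(axis=1),
    )


def call_differential(
    treatment_fpkm: float,
    control_fpkm: float,
    fold_up: float = 2.0,
    fold_down: float = 0.5,
    pseudocount: float = RATIO_PSEUDOCOUNT,
) -> str:
    """up / down / unchanged from the treatment:control FPKM ratio.

    Strict inequalities on both bounds ("more than twofold", "less than one
    half"), so a ratio of exactly 2 is unchanged.
    """
    if treatment_fpkm < 0 or control_fpkm < 0:
        raise ValueError("FPKM values cannot be negative")
    ratio = (treatment_fpkm + pseudocount) / (control_fpkm + pseudocount)
    if ratio > fold_up:
        return "up"
    if ratio < fold_down:
        return "down"
    return "unchanged"


def differential_table(
    matrix: ExpressionMatrix,
    condition_pairs: list[tuple[str, str, str]],
    fold_up: float = 2.0,
    fold_down: float = 0.5,
    pseudocount: float = RATIO_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene up/down/unchanged calls for (treatment, control, label) pairs."""
    frame = matrix.to_frame()
    out = {}
    for treatment, control, label in condition_pairs:
        out[label] = [
            call_differential(frame.at[g, treatment], frame.at[g, control],
                              fold_up, fold_down, pseudocount)
            for g in matrix.gene_ids
        ]
    return pd.DataFrame(out, index=matrix.gene_ids)


# ---------------------------------------------------------------------------
# Pattern clustering
# ---------------------------------------------------------------------------

@dataclass
class PatternClusters:
    clusters: dict[int, list[str]]  # cluster id -> gene ids
    merge_heights: list[float]  # linkage criterion value per merge
    labels: dict[str, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cluster_expression_patterns(
    matrix: ExpressionMatrix,
    threshold: float = 0.5,
    pseudocount: float = LOG_PSEUDOCOUNT,
) -> PatternClusters:
    """Average-linkage clustering of log2(FPKM + pseudocount) profiles.

    Distance is 1 - Pearson correlation between rows; the tree is cut where
    merge similarity drops below ``threshold`` correlation (i.e. at
    cophenetic distance 1 - threshold). Zero-variance rows have undefined
    correlation and are assigned singleton clusters with a warning.
    """
    if len(matrix.gene_ids) < 2:
        raise ValueError("need at least 2 genes to cluster")
    data = np.log2(matrix.values + pseudocount)
    variances = data.var(axis=1)
    constant = variances == 0
    usable_idx = np.flatnonzero(~constant)
    clusters: dict[int, list[str]] = {}
    labels: dict[str, int] = {}
    merge_heights: list[float] = []
    next_id = 1
    if constant.any():
        for i in np.flatnonzero(constant):
            gene = matrix.gene_ids[i]
            logger.warning("gene %s has constant profile; assigned its own cluster", gene)
            clusters[next_id] = [gene]
            labels[gene] = next_id
            next_id += 1
    if usable_idx.size == 1:
        gene = matrix.gene_ids[usable_idx[0]]
        clusters[next_id] = [gene]
        labels[gene] = next_id
    elif usable_idx.size >= 2:
        sub = data[usable_idx]
        corr = np.corrcoef(sub)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        linkage = hierarchy.linkage(condensed, method="average")
        merge_heights = [float(h) for h in linkage[:, 2]]
        assignment = hierarchy.fcluster(linkage, t=1.0 - threshold, criterion="distance")
        for local, cluster in enumerate(assignment):
            gene = matrix.gene_ids[usable_idx[local]]
            cid = next_id + int(cluster) - 1
            clusters.setdefault(cid, []).append(gene)
            labels[gene] = cid
    logger.info("expression patterns: %d clusters at correlation threshold %.2f",
                len(clusters), threshold)
    return PatternClusters(clusters=clusters, merge_heights=merge_heights, labels=labels)


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt
# ---------------------------------------------------------------------------

@dataclass
class RelativeExpression:
    gene_id: str
    treatment: str
    delta_ct: list[float]  # replicate dCt values in the treatment
    ddct: float
    fold_change: float  # 2^-ddCt
    dispersion: float  # SD of replicate dCt, propagated across conditions
    p_value: float = math.nan  # two-sided t-test vs the calibrator dCt


def compute_relative_expression(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_condition: str,
) -> dict[str, RelativeExpression]:
    """2^-ddCt relative expression of a gene per condition.

    dCt = Ct(target) - Ct(reference) per replicate; ddCt = mean dCt of the
    condition minus mean dCt of the calibrator; fold change = 2^-ddCt.
    Returns one result per condition (the calibrator maps to fold 1).
    """
    def delta_cts(condition: str) -> list[float]:
        sub = ct_table[ct_table["condition"] == condition]
        target = sub[sub["gene"] == target_gene].set_index("replicate")["Ct"]
        reference = sub[sub["gene"] == reference_gene].set_index("replicate")["Ct"]
        if reference.empty:
            raise ValueError(f"missing reference Ct for {reference_gene!r} in {condition!r}")
        if target.empty:
            raise ValueError(f"missing target Ct for {target_gene!r} in {condition!r}")
        common = target.index.intersection(reference.index)
        if common.empty:
            raise ValueError(f"no shared replicates for {condition!r}")
        return [float(target[r] - reference[r]) for r in common]

    calibrator_dct = delta_cts(calibrator_condition)
    cal_mean = float(np.mean(calibrator_dct))
    cal_var = float(np.var(calibrator_dct, ddof=1)) if len(calibrator_dct) > 1 else 0.0

    results: dict[str, RelativeExpression] = {}
    for condition in ct_table["condition"].unique():
        dct = delta_cts(condition)
        ddct = float(np.mean(dct)) - cal_mean
        var = float(np.var(dct, ddof=1)) if len(dct) > 1 else 0.0
        dispersion = math.sqrt(var / max(len(dct), 1) + cal_var / max(len(calibrator_dct), 1))
        if (condition != calibrator_condition and len(dct) > 1
                and len(calibrator_dct) > 1 and (var > 0 or cal_var > 0)):
            _stat, p_value = stats.ttest_ind(dct, calibrator_dct)
            p_value = float(p_value)
        else:
            p_value = math.nan
        results[condition] = RelativeExpression(
            gene_id=target_gene, treatment=condition, delta_ct=dct,
            ddct=ddct, fold_change=2.0 ** (-ddct), dispersion=dispersion,
            p_value=p_value,
        )
    return results
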