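"""qPCR relative expression by the Livak 2^-ddCt method, with one-way
ANOVA / Tukey HSD group comparison and heatmap-ready log2 matrices.

The workflow: replicate Cq values are averaged within each
(gene, line, temperature, time) cell, the reference-gene Cq is
subtracted (dCt), the calibrator cell's dCt is subtracted (ddCt), and
fold-change is 2^-ddCt.  Replicate-level folds (each replicate's dCt
against the calibrator mean dCt) are retained for the ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ValidationError
from .io import CqTable

GROUP_COLS = CqTable.GROUP_COLS  # line, temperature, time


def ddct_fold(
    cq_target_t: float,
    cq_ref_t: float,
    cq_target_c: float,
    cq_ref_c: float,
) -> float:
    """2^-ddCt fold-change of a treated cell against the calibrator cell."""
    for v in (cq_target_t, cq_ref_t, cq_target_c, cq_ref_c):
        if not math.isfinite(v):
            raise ValidationError("Cq values must be finite")
    ddct = (cq_target_t - cq_ref_t) - (cq_target_c - cq_ref_c)
    return 2.0 ** (-ddct)


@dataclass
class RelativeExpression:
    """Fold-changes per gene x group plus replicate-level folds for ANOVA."""

    summary: pd.DataFrame  # gene_id, line, temperature, time, fold, log2_fold, n
    replicate_folds: pd.DataFrame  # same keys + replicate, fold


def relative_expression(
    cq: CqTable, calibrator_time: float | None = None
) -> RelativeExpression:
    """Per-gene 2^-ddCt folds against each series' calibrator time point.

    The calibrator is the ``calibrator_time`` (default: the table's, i.e.
    0 h) cell of the same gene / line / temperature series, so the
    calibrator cell of every series has fold exactly 1 by construction.
    """
    cal_time = cq.calibrator_time if calibrator_time is None else calibrator_time
    df = cq.data.copy()
    df["dct"] = df["cq_target"] - df["cq_reference"]
    cell_mean = (
        df.groupby(["gene_id", *GROUP_COLS], sort=False)["dct"]
        .agg(["mean", "count"])
        .reset_index()
    )
    cal = cell_mean[cell_mean["time"] == cal_time][
        ["gene_id", "line", "temperature", "mean"]
    ].rename(columns={"mean": "dct_cal"})
    if cal.empty:
        raise ValidationError(f"no calibrator cells at time {cal_time} h")
    merged = cell_mean.merge(cal, on=["gene_id", "line", "temperature"], how="left")
    if merged["dct_cal"].isna().any():
        bad = merged.loc[merged["dct_cal"].isna(), "gene_id"].unique()
        raise ValidationError(
            f"missing calibrator cell for gene(s) {sorted(bad)} at {cal_time} h"
        )
    merged["ddct"] = merged["mean"] - merged["dct_cal"]
    merged["fold"] = 2.0 ** (-merged["ddct"])
    merged["log2_fold"] = -merged["ddct"]
    summary = merged[
        ["gene_id", *GROUP_COLS, "fold", "log2_fold"]
    ].assign(n=merged["count"])

    rep = df.merge(cal, on=["gene_id", "line", "temperature"], how="left")
    rep["fold"] = 2.0 ** (-(rep["dct"] - rep["dct_cal"]))
    replicate_folds = rep[["gene_id", *GROUP_COLS, "replicate", "fold"]]
    return RelativeExpression(summary=summary, replicate_folds=replicate_folds)


# ---------------------------------------------------------------------------
# ANOVA + Tukey


@dataclass
class AnovaResult:
    f_stat: float | None
    p_value: float | None
    df_between: int
    df_within: int
    group_means: dict[str, float]
    letters: dict[str, str]  # compact letter display at alpha
    flagged: str = ""  # reason when F is undefined


def _compact_letters(
    groups: list[str],
    means: dict[str, float],
    significant: set[frozenset[str]],
) -> dict[str, str]:
    """Greedy compact-letter display: groups sharing a letter never differ.

    Groups are processed in descending mean order; each joins every
    existing letter class it does not significantly differ from, opening
    a new class when none admits it.
    """
    order = sorted(groups, key=lambda g: (-means[g], g))
    classes: list[set[str]] = []
    for g in order:
        placed = False
        for cls in classes:
            if all(frozenset((g, other)) not in significant for other in cls):
                cls.add(g)
                placed = True
        if not placed:
            classes.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for idx, cls in enumerate(classes):
        for g in cls:
            letters[g] += alphabet[idx % len(alphabet)]
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def anova_tukey(
    folds: dict[str, list[float]], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA across groups with Tukey HSD letters.

    ``folds`` maps group label -> replicate values.  Requires >= 2 groups
    with >= 2 replicates each.  Zero within-group variance with equal
    means leaves F undefined (flagged), rather than raising.
    """
    if len(folds) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    for g, vals in folds.items():
        if len(vals) < 2:
            raise ValidationError(f"group {g!r} has fewer than two replicates")
    groups = list(folds)
    means = {g: float(np.mean(folds[g])) for g in groups}
    values = [np.asarray(folds[g], dtype=float) for g in groups]
    df_between = len(groups) - 1
    df_within = sum(len(v) for v in values) - len(groups)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in values)
    if ssw == 0:
        if len(set(means.values())) == 1:
            return AnovaResult(
                f_stat=None,
                p_value=None,
                df_between=df_between,
                df_within=df_within,
                group_means=means,
                letters={g: "a" for g in groups},
                flagged="zero within-group variance with equal means",
            )
        # perfectly separated groups: F is infinite, unequal means all differ
        significant = {
            frozenset((a, b))
            for i, a in enumerate(groups)
            for b in groups[i + 1 :]
            if means[a] != means[b]
        }
        return AnovaResult(
            f_stat=math.inf,
            p_value=0.0,
            df_between=df_between,
            df_within=df_within,
            group_means=means,
            letters=_compact_letters(groups, means, significant),
        )
    f, p = stats.f_oneway(*values)
    flat = np.concatenate(values)
    labels = np.concatenate([[g] * len(folds[g]) for g in groups])
    tukey = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    significant = set()
    for (a, b), reject in zip(
        ((r[0], r[1]) for r in tukey.summary().data[1:]), tukey.reject
    ):
        if reject:
            significant.add(frozenset((str(a), str(b))))
    letters = _compact_letters(groups, means, significant)
    return AnovaResult(
        f_stat=float(f),
        p_value=float(p),
        df_between=df_between,
        df_within=df_within,
        group_means=means,
        letters=letters,
    )


# ---------------------------------------------------------------------------
# Heatmap matrix


@dataclass
class HeatmapMatrix:
    matrix: pd.DataFrame  # genes x condition columns, log2 fold
    row_order: list[str]
    imputed: list[tuple[str, str]]  # (gene, column) cells filled with 0


def heatmap_matrix(rel: RelativeExpression, cluster: bool = True) -> HeatmapMatrix:
    """Genes x condition-time matrix of log2 folds, optionally row-clustered.

    Missing cells are imputed as 0 log2-fold and flagged.  Clustering is
    average-linkage on correlation distance; rows with zero variance fall
    back to zero correlation distance against equal rows.  Row order is
    deterministic (scipy leaf order with fixed tie-breaking by index).
    """
    summary = rel.summary
    if summary.empty:
        raise ValidationError("no expression values to arrange")
    col = (
        summary["line"].astype(str)
        + "|"
        + summary["temperature"].astype(str)
        + "C|"
        + summary["time"].astype(str)
        + "h"
    )
    wide = summary.assign(condition=col).pivot_table(
        index="gene_id", columns="condition", values="log2_fold", sort=False
    )
    imputed = [
        (g, c)
        for g in wide.index
        for c in wide.columns
        if pd.isna(wide.loc[g, c])
    ]
    wide = wide.fillna(0.0)
    order = list(wide.index)
    if cluster and len(wide) > 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            dists = pdist(wide.values, metric="correlation")
        dists = np.nan_to_num(dists, nan=0.0)  # constant rows: treat as identical
        link = hierarchy.linkage(dists, method="average")
        leaf_idx = hierarchy.leaves_list(link)
        order = [wide.index[i] for i in leaf_idx]
        wide = wide.loc[order]
    elif cluster and len(wide) == 2:
        order = list(wide.index)
    return HeatmapMatrix(matrix=wide, row_order=order, imputed=imputed)
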