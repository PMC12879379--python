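"""Rank genes by cell-type specificity of expression.

The input is an already-normalized expression matrix (genes x samples) and a
map assigning every sample to the ``target`` cell type (e.g. T cells) or the
``background`` (every other cell type).  Per gene we sum expression over each
sample group, drop genes with weak target-group expression, and rank:

* ``rank_target``  -- aggregate target expression, high to low,
* ``rank_background`` -- aggregate background expression, low to high,
* ``specificity_score`` -- ascending rank of ``rank_target + rank_background``.

Small specificity scores mean high, selective expression in the target cell
type.  Gene sets are then cut from the score distribution: the *top* set lies
more than ``k_top`` SDs below the mean, the *comparator* set lies above the
``mean - k_comp * SD`` threshold (the gap between the two cuts is a deliberate
zone of exclusion), and the *bottom* set is the ``|top|`` genes with the
largest scores.

All ranks use average ("fractional") ranks for ties, which keeps the rank sum
symmetric between tied genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

TARGET = "target"
BACKGROUND = "background"


def validate_expression(values: pd.DataFrame, groups: pd.Series) -> None:
    """Check the expression-matrix invariants; raise ``ValueError`` on breach."""
    if values.empty:
        raise ValueError("expression matrix is empty")
    if not values.index.is_unique:
        raise ValueError("gene ids are not unique")
    if (values.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")
    missing = values.columns.difference(groups.index)
    if len(missing):
        raise ValueError(f"samples without a group label: {list(missing)[:5]}")
    bad = set(groups.loc[values.columns]) - {TARGET, BACKGROUND}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")


def aggregate_expression(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Sum expression per gene over target-group and background-group samples.

    Parameters
    ----------
    values
        Genes x samples matrix of non-negative normalized counts.
    groups
        Series mapping sample id -> ``"target"`` / ``"background"``.

    Returns
    -------
    DataFrame indexed by gene with columns ``agg_target`` and
    ``agg_background``.
    """
    validate_expression(values, groups)
    labels = groups.loc[values.columns]
    tgt = values.loc[:, labels[labels == TARGET].index]
    bkg = values.loc[:, labels[labels == BACKGROUND].index]
    if tgt.shape[1] == 0 or bkg.shape[1] == 0:
        raise ValueError("both sample groups must contain at least one sample")
    return pd.DataFrame(
        {"agg_target": tgt.sum(axis=1), "agg_background": bkg.sum(axis=1)}
    )


def median_filter(agg_target: pd.Series) -> pd.Index:
    """Retain genes whose target aggregate is at or above the pre-filter median.

    The median is computed over *all* genes before any are removed; genes
    exactly at the median are kept.
    """
    if len(agg_target) == 0:
        raise ValueError("no genes to filter")
    med = float(np.median(agg_target.to_numpy()))
    return agg_target.index[agg_target >= med]


def specificity_scores(aggregates: pd.DataFrame) -> pd.DataFrame:
    """Rank genes into a specificity-score table.

    ``aggregates`` must already be median-filtered and carry columns
    ``agg_target`` and ``agg_background``.  Ties receive average ranks.
    """
    if len(aggregates) == 0:
        raise ValueError("empty aggregate table")
    rank_t = rankdata(-aggregates["agg_target"].to_numpy(), method="average")
    rank_b = rankdata(aggregates["agg_background"].to_numpy(), method="average")
    rank_sum = rank_t + rank_b
    score = rankdata(rank_sum, method="average")
    return pd.DataFrame(
        {
            "agg_target": aggregates["agg_target"],
            "agg_background": aggregates["agg_background"],
            "rank_target": rank_t,
            "rank_background": rank_b,
            "rank_sum": rank_sum,
            "specificity_score": score,
        },
        index=aggregates.index,
    )


@dataclass
class GeneSetPartition:
    """Top / comparator / bottom gene sets cut from the score distribution."""

    top: list = field(default_factory=list)
    comparator: list = field(default_factory=list)
    bottom: list = field(default_factory=list)
    mu: float = float("nan")
    sigma: float = float("nan")
    k_top: float = 4.0
    k_comp: float = 3.0


def partition_gene_sets(
    scores: pd.DataFrame,
    k_top: float = 4.0,
    k_comp: float = 3.0,
    score_col: str | None = None,
) -> GeneSetPartition:
    """Cut the specificity-score distribution into gene sets.

    top:        score < mu - k_top * sigma   (strict)
    comparator: score > mu - k_comp * sigma  (strict)
    bottom:     the ``|top|`` genes with the largest scores.

    ``mu`` and ``sigma`` are the mean and population SD of the retained-gene
    scores.  Genes falling between the two thresholds belong to neither set.

    By default the thresholds are computed on the ``rank_sum`` column when it
    is present: the final specificity score is a rank and therefore uniform,
    so mean-minus-k-SD cuts on it could never select a gene, whereas the rank
    sum concentrates around n+1 (its components are anti-correlated for
    abundance-driven genes) and leaves cell-type-specific genes in a long
    left tail that the SD thresholds are designed to catch.
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 genes to partition")
    if score_col is None:
        score_col = "rank_sum" if "rank_sum" in scores.columns else "specificity_score"
    s = scores[score_col]
    mu = float(s.mean())
    sigma = float(s.std(ddof=0))
    top = list(s.index[s < mu - k_top * sigma])
    comparator = list(s.index[s > mu - k_comp * sigma])
    if not top:
        warnings.warn("no gene lies below the top-set threshold; top and bottom are empty")
        bottom: list = []
    else:
        # largest scores first; deterministic tie-break on gene id
        order = sorted(s.index, key=lambda g: (-s[g], str(g)))
        bottom = order[: len(top)]
    return GeneSetPartition(top, comparator, bottom, mu, sigma, k_top, k_comp)


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x samples TSV whose first column holds gene ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_map_tsv(path) -> pd.Series:
    """Read a sample map TSV (sample_id, [cell_type,] group) into a Series."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, -1].to_numpy(), index=df.iloc[:, 0].to_numpy())
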