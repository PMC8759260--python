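"""Cluster the core trans-association matrix and attribute clusters to
naive/activated immune phenotypes.

The core CpG x gene matrix of corrected t statistics (non-significant
entries zeroed) is clustered hierarchically (Euclidean distance,
complete linkage by default) and cut at two clusters on each axis —
the naive-associated and activated-associated blocks.  Sorted-cell
reference profiles are min-max normalized per gene/CpG across cell
types, cluster membership is tested for naive-vs-activated differential
levels (Welch t), and paired naive/activated clock-age differences are
summarized per clock and lineage.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .clocks import AgePrediction, ClockModel, predict_age


@dataclass
class TransHeatmap:
    t_matrix: pd.DataFrame        # core CpG x gene corrected t, zeros where n.s.
    row_labels: pd.Series         # CpG -> 1 or 2
    col_labels: pd.Series         # gene -> 1 or 2
    row_order: list[str]          # dendrogram leaf order
    col_order: list[str]


@dataclass
class DeltaAgeResult:
    table: pd.DataFrame           # clock x lineage rows: median delta, p, n, stars


def cluster_core_set(t_matrix: pd.DataFrame, method: str = "complete") -> TransHeatmap:
    """Two-way hierarchical clustering of the core trans matrix.

    Rows (CpGs) and columns (genes) are clustered independently with
    Euclidean distance and cut at k = 2.  The input must be complete;
    set non-significant entries to 0 beforehand.  An all-constant matrix
    has no valid 2-cluster split and raises.
    """
    if t_matrix.isna().any().any():
        raise ValueError("t matrix must have no missing entries (zero the non-significant)")
    if t_matrix.shape[0] < 2 or t_matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    if float(np.ptp(t_matrix.values)) == 0.0:
        raise ValueError("degenerate matrix: all entries equal, no 2-cluster split")

    def cut(mat: np.ndarray, names) -> tuple[pd.Series, list]:
        link = linkage(mat, method=method, metric="euclidean")
        labels = fcluster(link, t=2, criterion="maxclust")
        order = [names[i] for i in leaves_list(link)]
        return pd.Series(labels, index=names), order

    row_labels, row_order = cut(t_matrix.values, list(t_matrix.index))
    col_labels, col_order = cut(t_matrix.values.T, list(t_matrix.columns))
    return TransHeatmap(t_matrix=t_matrix, row_labels=row_labels,
                        col_labels=col_labels, row_order=row_order,
                        col_order=col_order)


def core_t_matrix(results, core, zero_nonsignificant: bool = True,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Corrected-t matrix restricted to the core set, with entries that
    are not Bonferroni-significant trans associations set to 0 (the
    heatmap's "white")."""
    from .associations import TRANS
    t = results.t_corrected.loc[core.cpgs, core.genes].copy()
    if zero_nonsignificant:
        n_trans = int((results.mask.values == TRANS).sum())
        p = results.p_corrected.loc[core.cpgs, core.genes]
        is_trans = results.mask.loc[core.cpgs, core.genes] == TRANS
        sig = (p * n_trans < alpha) & is_trans
        t = t.where(sig, other=0.0)
    return t


def minmax_normalize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Normalize each gene/CpG profile across cell types to [0, 1]:
    (X - min) / max(X - min).

    ``profiles`` is cell type x feature.  Constant profiles are
    undefined and emitted as NaN (not divided by zero).  Idempotent on
    non-constant profiles.
    """
    if profiles.shape[1] == 0:
        raise ValueError("empty profile")
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 cell types")
    x = profiles.values.astype(float)
    mn = x.min(axis=0, keepdims=True)
    rng = (x - mn).max(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(rng == 0, np.nan, (x - mn) / rng)
    return pd.DataFrame(out, index=profiles.index, columns=profiles.columns)


def differential_group_test(normalized: pd.DataFrame, members: Iterable[str],
                            group_a: Sequence[str], group_b: Sequence[str]
                            ) -> tuple[float, float]:
    """Welch t test of a cluster's median normalized levels between two
    cell-type groups.

    For each member feature, its median over ``group_a`` cell types and
    over ``group_b`` cell types are computed; the two per-member vectors
    are compared with an unequal-variance t test.  Returns (t, p).
    """
    members = [m for m in members if m in normalized.columns]
    if not members:
        raise ValueError("no cluster members present in the profile table")
    if not len(group_a) or not len(group_b):
        raise ValueError("both cell-type groups must be non-empty")
    a = normalized.loc[list(group_a), members].median(axis=0).dropna()
    b = normalized.loc[list(group_b), members].median(axis=0).dropna()
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError("need at least 2 members with defined values per group")
    av, bv = a.loc[common].values, b.loc[common].values
    if np.allclose(av, bv):
        return 0.0, 1.0
    t, p = stats.ttest_ind(av, bv, equal_var=False)
    return float(t), float(p)


def predict_sorted_cell_ages(clocks: Sequence[ClockModel], sorted_beta: pd.DataFrame,
                             max_missing_frac: float = 0.2) -> dict[str, AgePrediction]:
    """Apply each clock to the sorted-cell beta matrix."""
    return {c.name: predict_age(c, sorted_beta, max_missing_frac=max_missing_frac)
            for c in clocks}


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def paired_delta_age(predictions: dict[str, AgePrediction],
                     sample_meta: pd.DataFrame) -> DeltaAgeResult:
    """Median paired (activated - naive) age difference per clock and
    lineage, with a paired t test across donors.

    ``sample_meta`` maps sample -> donor, lineage, phenotype; every
    donor must contribute exactly one naive and one activated sample per
    lineage it appears in.
    """
    rows = []
    for lineage, grp in sample_meta.groupby("lineage"):
        pairs = {}
        for donor, dgrp in grp.groupby("donor"):
            phen = dgrp["phenotype"]
            naive = dgrp.index[phen == "naive"]
            act = dgrp.index[phen == "activated"]
            if len(naive) != 1 or len(act) != 1:
                raise ValueError(
                    f"donor {donor!r} in lineage {lineage!r} lacks a complete naive/activated pair")
            pairs[donor] = (naive[0], act[0])
        if len(pairs) < 2:
            raise ValueError(f"lineage {lineage!r}: need at least 2 donors")
        for name, pred in predictions.items():
            diffs = np.array([pred.predicted[a] - pred.predicted[n]
                              for (n, a) in pairs.values()])
            if np.allclose(diffs.std(ddof=1), 0.0):
                t, p = (np.inf if diffs.mean() != 0 else 0.0), (0.0 if diffs.mean() != 0 else 1.0)
            else:
                t, p = stats.ttest_rel(
                    [pred.predicted[a] for (_, a) in pairs.values()],
                    [pred.predicted[n] for (n, _) in pairs.values()])
                t, p = float(t), float(p)
            rows.append((name, lineage, float(np.median(diffs)), t, p,
                         len(pairs), _stars(p)))
    table = pd.DataFrame(
        rows, columns=["clock", "lineage", "median_delta", "t", "p", "n_donors", "stars"])
    return DeltaAgeResult(table=table)
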