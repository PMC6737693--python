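"""Median-split stratified differential expression.

The bioinformatics stage of the pipeline: filter out low-abundance genes,
split the cohort at the median expression of a marker gene (e.g. ESR1),
call differentially expressed genes between the high and low groups at
fold change > 2 and p < 0.05 (strict inequalities), rank the top up/down
genes, and hierarchically cluster the resulting submatrix for a heatmap
(Euclidean distance, average linkage).

The moderated test shrinks per-gene variances toward a common prior fitted
by method of moments across genes (empirical Bayes), which stabilizes
small-sample variance estimates; a plain Welch t-test is available as the
unmoderated alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "GroupLabels",
    "ClusterResult",
    "filter_low_expression",
    "stratify_by_gene",
    "differential_expression",
    "select_top_degs",
    "cluster_heatmap",
]


def filter_low_expression(matrix: pd.DataFrame, min_mean: float = 2.0) -> pd.DataFrame:
    """Drop genes whose average expression is below ``min_mean`` (log2 units).

    A gene with row mean exactly ``min_mean`` is retained (the exclusion rule
    is a strict ``<``).  Gene order and the sample set are preserved.
    """
    if matrix.empty:
        raise ValueError("matrix is empty")
    kept = matrix.loc[matrix.mean(axis=1) >= min_mean]
    if kept.empty:
        warnings.warn("abundance filter removed every gene", stacklevel=2)
    return kept


@dataclass(frozen=True)
class GroupLabels:
    """Sample-to-group assignment from a marker-gene median split."""

    labels: pd.Series  # sample id -> "high" | "low"
    marker_gene: str
    cutoff_value: float

    @property
    def high(self) -> pd.Index:
        return self.labels.index[self.labels == "high"]

    @property
    def low(self) -> pd.Index:
        return self.labels.index[self.labels == "low"]


def stratify_by_gene(matrix: pd.DataFrame, marker: str) -> GroupLabels:
    """Split samples at the median of the marker gene's expression.

    Samples strictly above the median go to the high group; samples at or
    below it to the low group.  For an odd number of distinct values the
    median sample therefore joins the low group, giving the (N-1)/2 high vs
    (N+1)/2 low split.
    """
    if marker not in matrix.index:
        raise KeyError(f"marker gene {marker!r} not in matrix")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to stratify")
    values = matrix.loc[marker]
    if isinstance(values, pd.DataFrame):
        raise ValueError(f"marker gene {marker!r} is duplicated in the matrix")
    cutoff = float(np.median(values.to_numpy()))
    labels = pd.Series(np.where(values > cutoff, "high", "low"), index=matrix.columns,
                       name="group")
    return GroupLabels(labels=labels, marker_gene=marker, cutoff_value=cutoff)


def _moments_prior(s2: np.ndarray, d: float):
    """Method-of-moments fit of a scaled inverse-chi-square variance prior.

    Models per-gene sample variances as s² | σ² ~ σ²·χ²_d/d with
    σ² ~ s0²·d0/χ²_{d0}. Matching the first two marginal moments of s²
    across genes yields (d0, s0²); a degenerate spread (all variance
    explained by the χ²_d wobble) maps to d0 = ∞, i.e. complete shrinkage.
    """
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1)) if s2.size > 1 else 0.0
    e4 = (v + m**2) / (1.0 + 2.0 / d)  # E[sigma^4]
    c = e4 / m**2 if m > 0 else 1.0
    if c <= 1.0 + 1e-12:
        return np.inf, m
    d0 = (4.0 * c - 2.0) / (c - 1.0)
    s0_sq = m * (d0 - 2.0) / d0
    return d0, s0_sq


def differential_expression(matrix: pd.DataFrame, labels: GroupLabels,
                            fc_threshold: float = 2.0, p_threshold: float = 0.05,
                            moderated: bool = True,
                            fdr_bh: bool = False) -> pd.DataFrame:
    """Per-gene two-group contrast between the high and low strata.

    Returns a table with columns ``mean_high``, ``mean_low``, ``log2fc``
    (= mean_high − mean_low), ``stat``, ``p``, ``direction`` and ``is_deg``.
    A gene is a DEG iff |log2fc| > log2(fc_threshold) and p < p_threshold,
    both strict.  With ``moderated`` the per-gene variances are shrunk toward
    the method-of-moments prior; otherwise a Welch t-test is used.  With
    ``fdr_bh`` the p cutoff is applied to Benjamini–Hochberg adjusted values
    instead (off by default: the calling rule is on raw p).
    """
    high_idx = [matrix.columns.get_loc(c) for c in labels.high]
    low_idx = [matrix.columns.get_loc(c) for c in labels.low]
    n1, n2 = len(high_idx), len(low_idx)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    x = matrix.to_numpy(float)
    xh, xl = x[:, high_idx], x[:, low_idx]
    mean_h, mean_l = xh.mean(axis=1), xl.mean(axis=1)
    lfc = mean_h - mean_l

    if n1 < 2 or n2 < 2:
        # p undefined: every gene flagged not-callable
        stat = np.full(len(lfc), np.nan)
        p = np.full(len(lfc), np.nan)
    elif moderated:
        d = n1 + n2 - 2
        var_h = xh.var(axis=1, ddof=1)
        var_l = xl.var(axis=1, ddof=1)
        s2 = ((n1 - 1) * var_h + (n2 - 1) * var_l) / d
        d0, s0_sq = _moments_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_post = np.inf
        else:
            s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
            df_post = d + d0
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = lfc / se
        p = 2.0 * (stats.norm.sf(np.abs(stat)) if np.isinf(df_post)
                   else stats.t.sf(np.abs(stat), df_post))
    else:
        stat, p = stats.ttest_ind(xh, xl, axis=1, equal_var=False)

    p_eff = p
    if fdr_bh and np.all(np.isfinite(p)):
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        p_eff = np.empty_like(q)
        p_eff[order] = np.minimum(q, 1.0)

    lfc_cut = np.log2(fc_threshold)
    with np.errstate(invalid="ignore"):
        is_deg = (np.abs(lfc) > lfc_cut) & (p_eff < p_threshold)
    is_deg = np.where(np.isnan(p), False, is_deg)
    direction = np.where(~is_deg, "none", np.where(lfc > 0, "up", "down"))

    out = pd.DataFrame(
        {
            "mean_high": mean_h,
            "mean_low": mean_l,
            "log2fc": lfc,
            "stat": stat,
            "p": p,
            "direction": direction,
            "is_deg": is_deg,
        },
        index=matrix.index,
    )
    if fdr_bh:
        out["q"] = p_eff
    return out


def select_top_degs(table: pd.DataFrame, n_up: int = 50, n_down: int = 50) -> list:
    """Top up-regulated genes (descending log2fc) followed by top down-regulated
    genes (ascending log2fc), among called DEGs only.

    If fewer than requested are available, all are returned with a warning.
    """
    up = table[table["is_deg"] & (table["direction"] == "up")]
    down = table[table["is_deg"] & (table["direction"] == "down")]
    up_sel = up.sort_values("log2fc", ascending=False, kind="stable").head(n_up)
    down_sel = down.sort_values("log2fc", ascending=True, kind="stable").head(n_down)
    if len(up_sel) < n_up or len(down_sel) < n_down:
        warnings.warn(
            f"requested top {n_up}/{n_down} DEGs but only {len(up_sel)} up and "
            f"{len(down_sel)} down available", stacklevel=2)
    return list(up_sel.index) + list(down_sel.index)


@dataclass
class ClusterResult:
    """Row/column orderings and merge trees from hierarchical clustering."""

    row_order: np.ndarray
    col_order: np.ndarray
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    distance_metric: str = "euclidean"
    linkage_method: str = "average"


def cluster_heatmap(matrix: pd.DataFrame, genes) -> ClusterResult:
    """Agglomerative clustering of genes (rows) and samples (columns).

    Euclidean distance, average linkage; deterministic for fixed input (ties
    broken by input order, as in the underlying SciPy implementation).
    """
    sub = matrix.loc[list(genes)]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples to cluster")
    x = sub.to_numpy(float)
    row_z = linkage(pdist(x, metric="euclidean"), method="average")
    col_z = linkage(pdist(x.T, metric="euclidean"), method="average")
    return ClusterResult(
        row_order=np.asarray(leaves_list(row_z)),
        col_order=np.asarray(leaves_list(col_z)),
        row_linkage=row_z,
        col_linkage=col_z,
    )
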