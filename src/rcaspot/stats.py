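"""Downstream statistics: log transform, Ward clustering, correlation
panels, fluorescence regression/gating, reference comparison, composition
tables.

Counts are analyzed as log2(dots/cell + 1).  Clustering uses Euclidean
distances with the ward.D2 criterion (squared-distance Lance–Williams
update, merge heights on the distance scale), matching R's
hclust(..., method = "ward.D2").
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .spots import CountsMatrix


def _frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountsMatrix) else counts


def log_transform(counts) -> pd.DataFrame:
    """Elementwise log2(x + 1).  The inverse 2**v − 1 recovers raw counts."""
    df = _frame(counts)
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log2(df.astype(float) + 1.0)


def ward_cluster(
    table: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
) -> tuple[np.ndarray, pd.Series]:
    """Agglomerative Ward clustering of cells (rows).

    Returns the scipy linkage matrix (step, a, b, height, size) and the
    per-cell cluster ids from cutting at ``n_clusters`` or ``height``.
    Heights are on the Euclidean distance scale; the merge criterion is
    the squared-distance Ward update (ward.D2 semantics).
    """
    X = np.asarray(table, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least 2 cells")
    if n_clusters is not None and n_clusters > X.shape[0]:
        raise ValueError("more clusters requested than cells")
    Z = hierarchy.linkage(X, method="ward")
    if n_clusters is not None:
        ids = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    elif height is not None:
        ids = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        ids = np.ones(X.shape[0], dtype=int)
    index = table.index if isinstance(table, pd.DataFrame) else pd.RangeIndex(len(ids))
    return Z, pd.Series(ids, index=index, name="cluster")


def linkage_table(Z: np.ndarray) -> pd.DataFrame:
    """Merge tree as a CSV-ready table: step, a, b, height."""
    return pd.DataFrame(
        {
            "step": np.arange(len(Z)),
            "a": Z[:, 0].astype(int),
            "b": Z[:, 1].astype(int),
            "height": Z[:, 2],
        }
    )


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman ρ (average ranks on ties), unit diagonal.

    Constant columns have undefined rank correlation and are reported as
    NaN, not silently as 0.
    """
    if table.shape[0] < 3:
        raise ValueError("Spearman matrix needs at least 3 cells")
    cols = table.columns
    X = table.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns produce NaN by design
        rho = sps.spearmanr(X).statistic
    if np.isscalar(rho):  # two columns: spearmanr returns a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    const = X.std(axis=0) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    return pd.DataFrame(rho, index=cols, columns=cols)


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.std(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fluorescence_gate(rid: pd.Series, control_rid: pd.Series) -> pd.Series:
    """Positive iff a cell's raw integrated density strictly exceeds the
    maximum observed in the negative-control cells."""
    if len(control_rid) == 0:
        raise ValueError("control set is empty")
    threshold = float(np.max(control_rid))
    return (rid > threshold).rename("positive")


def compare_to_reference(
    mean_log_counts: pd.Series, reference: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Spearman ρ between per-gene mean log2(dots+1) and a reference
    profile (e.g. mean log2(counts+1) of a sequenced cell population),
    over their shared genes.  Also returns the paired table, with the
    Pearson r as a column attribute for completeness."""
    shared = mean_log_counts.index.intersection(reference.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes between panel and reference")
    a = mean_log_counts.loc[shared].astype(float)
    b = reference.loc[shared].astype(float)
    rho = float(sps.spearmanr(a, b).statistic)
    paired = pd.DataFrame({"observed_mean_log2": a, "reference_mean_log2": b})
    paired.attrs["pearson_r"] = float(sps.pearsonr(a, b).statistic)
    return rho, paired


def marker_expression_table(labels: pd.Series, counts) -> pd.DataFrame:
    """Heatmap data: per annotated cell type, the percentage of its cells
    with at least one dot of each gene."""
    df = _frame(counts)
    labels = labels.reindex(df.index)
    if labels.isna().any():
        raise ValueError("every cell in the counts matrix needs a label")
    return (df > 0).groupby(labels).mean() * 100.0


def composition_table(
    labels: pd.Series, regions: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region × type composition, both normalizations of the balloon plot.

    Returns ``(pct_of_type, pct_of_region)``: the first gives, per cell
    type, the percentage found at each region (rows sum to 100 across
    regions); the second gives, per region, the percentage contributed by
    each type including NA (rows sum to 100 across types).
    """
    labels, regions = labels.align(regions, join="inner")
    if labels.isna().any() or regions.isna().any():
        raise ValueError("every cell needs both a label and a region")
    tab = pd.crosstab(labels, regions)
    pct_of_type = tab.div(tab.sum(axis=1), axis=0) * 100.0
    by_region = tab.T
    pct_of_region = by_region.div(by_region.sum(axis=1), axis=0) * 100.0
    return pct_of_type, pct_of_region
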