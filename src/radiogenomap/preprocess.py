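"""Expression preprocessing: count filtering, log transform, k-NN imputation, standardization.

The RNA-seq computational tail implemented here starts from a transcript count
matrix and an FPKM matrix (genes x samples) and produces a complete,
per-gene standardized expression matrix ready for metagene scoring:

1. keep transcripts with >= ``min_count`` reads in >= ``min_fraction`` of samples,
2. log2-transform FPKM, marking zeros as missing,
3. impute missing entries from the 15 nearest gene rows,
4. standardize every gene row to mean 0 / unit variance (ddof=1).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

__all__ = [
    "filter_low_count_transcripts",
    "log_transform",
    "knn_impute",
    "standardize_genes",
]


def filter_low_count_transcripts(
    counts: pd.DataFrame,
    min_count: int = 5,
    min_fraction: float = 0.7,
) -> tuple[pd.DataFrame, list[str]]:
    """Keep transcripts with at least ``min_count`` reads in at least
    ``min_fraction`` of samples.

    The sample threshold is ``ceil(min_fraction * n_samples)`` — strictly
    "at least" the requested fraction. Row order is preserved.

    Returns the filtered count matrix and the list of kept gene ids.
    """
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("count matrix contains negative entries")
    n_samples = counts.shape[1]
    needed = math.ceil(min_fraction * n_samples)
    keep = (values >= min_count).sum(axis=1) >= needed
    filtered = counts.loc[keep]
    return filtered, list(filtered.index)


def log_transform(fpkm: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """log2-transform an FPKM matrix.

    By default zeros become missing (NaN), to be filled by :func:`knn_impute`;
    with ``pseudocount`` set, computes ``log2(x + pseudocount)`` and produces
    no missing values.
    """
    values = fpkm.to_numpy(dtype=float)
    if np.nanmin(values) < 0:
        raise ValueError("FPKM matrix contains negative entries")
    if pseudocount is not None:
        out = np.log2(values + pseudocount)
    else:
        with np.errstate(divide="ignore"):
            out = np.log2(values)
        out[values == 0] = np.nan
    return pd.DataFrame(out, index=fpkm.index, columns=fpkm.columns)


def knn_impute(matrix: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Fill missing entries from the k nearest gene rows.

    Distance between two gene rows is the Euclidean distance over the samples
    observed in both, normalized by the number of shared samples
    (``sqrt(mean of squared differences)``). A missing entry (g, s) becomes the
    inverse-distance-weighted mean — weights ``1/(d + 1e-12)`` — of the values
    at sample s of the k rows nearest to g that are observed at s; when none of
    the k neighbors is observed at s, the row mean of g is used.
    """
    X = matrix.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    missing = np.isnan(X)
    if not missing.any():
        return matrix.copy()
    fully_missing = missing.all(axis=1)
    if fully_missing.any():
        bad = matrix.index[fully_missing][0]
        raise ValueError(f"gene {bad!r} has no observed values; cannot impute")
    if n_genes < k + 1:
        raise ValueError(f"need at least k+1={k + 1} gene rows, got {n_genes}")

    # nan_euclidean scales by sqrt(n_total / n_shared); divide by sqrt(n_total)
    # to get the per-shared-sample normalization.
    dist = nan_euclidean_distances(X) / np.sqrt(n_samples)
    np.fill_diagonal(dist, np.inf)
    dist[np.isnan(dist)] = np.inf  # pairs with no shared samples

    out = X.copy()
    row_means = np.nanmean(X, axis=1)
    for g in np.flatnonzero(missing.any(axis=1)):
        order = np.argsort(dist[g], kind="stable")[:k]
        d = dist[g, order]
        finite = np.isfinite(d)
        order, d = order[finite], d[finite]
        w = 1.0 / (d + 1e-12)
        for s in np.flatnonzero(missing[g]):
            observed = ~np.isnan(X[order, s])
            if observed.any():
                out[g, s] = np.average(X[order[observed], s], weights=w[observed])
            else:
                out[g, s] = row_means[g]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def standardize_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0 and unit variance (ddof=1).

    Constant rows cannot be standardized; they are dropped with a warning
    rather than aborting the run.
    """
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix has missing values; impute before standardizing")
    sd = X.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        dropped = list(matrix.index[constant])
        warnings.warn(f"dropping {len(dropped)} constant gene row(s): {dropped[:5]}...")
        X, sd = X[~constant], sd[~constant]
        index = matrix.index[~constant]
    else:
        index = matrix.index
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(Z, index=index, columns=matrix.columns)
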