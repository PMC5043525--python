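"""Query-driven co-expression search, significance, and cross-platform pooling.

After SVD filtering, every gene is scored by the mean Fisher-transformed
Pearson correlation with the query genes:

    zbar_g = (1 / 2N) * sum_Q ln((1 + rho_gQ) / (1 - rho_gQ))
           = mean_Q atanh(rho_gQ)

The zbar values are robust-standardized by their median and MAD,

    S_g = (zbar_g - median(z)) / (1.4826 * MAD(z)),

and one-sided upper-tail p-values are read off the standard normal
(large positive S_g = enrichment in the queried cell type; under scrambled
sample labels S_g is close to standard normal, so this matches a
permutation test). Platforms are scored independently and pooled with
Stouffer's Z-score method; pooled p-values are FDR-adjusted
(Benjamini-Hochberg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .svd_filter import (
    FilterParams,
    factorize,
    filter_matrix,
    kaiser_rank,
    query_weights,
    standardize_genes,
)

__all__ = [
    "DegenerateDistributionError",
    "PlatformResult",
    "SearchResult",
    "mean_fisher_correlation",
    "robust_standardize",
    "scores_to_pvalues",
    "stouffer_pool",
    "adjust_bh",
    "adjust_holm",
    "search_platform",
    "cellmapper_search",
]

# clamp correlations before atanh so duplicated profiles stay finite
_RHO_CLAMP = 1.0 - 1e-12
_P_FLOOR = np.finfo(float).tiny


class DegenerateDistributionError(ValueError):
    """The zbar distribution has MAD 0 and cannot be robust-standardized."""


@dataclass
class PlatformResult:
    """Per-platform score table plus filter diagnostics.

    ``table`` columns: gene_id, zbar, s, p, fdr, rank (1-based, by
    descending s, ties broken by gene id). Query genes are excluded from
    the table and listed in ``query_report``.
    """

    table: pd.DataFrame
    query_report: pd.DataFrame
    sigma: np.ndarray
    w: np.ndarray
    sigma_filtered: np.ndarray
    retained_rank: int
    zero_variance_genes: list = field(default_factory=list)
    dropped_constant_genes: list = field(default_factory=list)


@dataclass
class SearchResult:
    """Pooled cross-platform result.

    ``pooled`` columns: gene_id, combined_z, combined_p, combined_fdr,
    n_platforms_present, predicted; ordered by (combined_p asc, gene_id asc).
    """

    pooled: pd.DataFrame
    platforms: list
    query_genes: list
    skipped_platforms: list = field(default_factory=list)


def mean_fisher_correlation(
    filtered: np.ndarray | ExpressionMatrix,
    query_rows,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean Fisher z of every gene's correlation with the query genes.

    Pearson correlations are computed across samples of the filtered
    profiles, clamped to +/-(1 - 1e-12), and atanh-averaged over the N
    query genes. Rows with zero variance after filtering get zbar = 0 and
    are flagged (second return value: boolean mask).

    Raises ``ValueError`` with fewer than 3 samples.
    """
    values = filtered.values if isinstance(filtered, ExpressionMatrix) else np.asarray(filtered, float)
    query_rows = np.asarray(query_rows, dtype=int)
    if query_rows.size == 0:
        raise ValueError("need at least one query gene")
    m, n = values.shape
    if n < 3:
        raise ValueError(f"correlation needs at least 3 samples, got {n}")
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero_var = norms <= 1e-12
    safe = np.where(zero_var, 1.0, norms)
    unit = centered / safe[:, None]
    rho = unit @ unit[query_rows].T  # m x N
    rho[zero_var] = 0.0
    rho[:, zero_var[query_rows]] = 0.0
    rho = np.clip(rho, -_RHO_CLAMP, _RHO_CLAMP)
    zbar = np.arctanh(rho).mean(axis=1)
    zbar[zero_var] = 0.0
    return zbar, zero_var


def robust_standardize(zbar: np.ndarray) -> np.ndarray:
    """Standardize scores by their median and scaled MAD.

    S_g = (zbar_g - median) / (1.4826 * MAD), with MAD the unscaled median
    absolute deviation from the median. Raises
    :class:`DegenerateDistributionError` when MAD is 0 and ``ValueError``
    for fewer than 3 scores.
    """
    zbar = np.asarray(zbar, dtype=float)
    if zbar.size < 3:
        raise ValueError("robust standardization needs at least 3 scores")
    med = np.median(zbar)
    mad = np.median(np.abs(zbar - med))
    if mad <= 0.0:
        raise DegenerateDistributionError(
            "MAD of the score distribution is 0; scores cannot be standardized"
        )
    return (zbar - med) / (1.4826 * mad)


def scores_to_pvalues(s: np.ndarray) -> np.ndarray:
    """One-sided upper-tail standard-normal p-values (enrichment only)."""
    p = stats.norm.sf(np.asarray(s, dtype=float))
    return np.clip(p, _P_FLOOR, 1.0)


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def adjust_holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down family-wise error rate adjustment."""
    return multipletests(np.asarray(p, float), method="holm")[1]


def stouffer_pool(platform_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool per-platform one-sided p-values with Stouffer's Z-score method.

    Each table must have columns ``gene_id`` and ``p``. Per platform the
    p-value is converted to a normal quantile z = Phi^-1(1 - p); for each
    gene present on k >= 1 platforms the combined score is sum(z) / sqrt(k).
    Genes absent from a platform simply use fewer terms. Returns a table
    with combined_z, combined_p, combined_fdr and n_platforms_present,
    ordered by (combined_p asc, gene_id asc).

    Raises ``ValueError`` if no platform tables are given.
    """
    if not platform_tables:
        raise ValueError("no platform tables to pool")
    frames = []
    for i, t in enumerate(platform_tables):
        z = stats.norm.isf(np.clip(t["p"].to_numpy(float), _P_FLOOR, 1.0 - 1e-16))
        frames.append(pd.DataFrame({"gene_id": t["gene_id"], "z": z}))
    cat = pd.concat(frames, ignore_index=True)
    grouped = cat.groupby("gene_id", sort=False)["z"]
    combined = grouped.sum() / np.sqrt(grouped.count())
    out = pd.DataFrame({
        "gene_id": combined.index,
        "combined_z": combined.to_numpy(float),
        "n_platforms_present": grouped.count().to_numpy(int),
    })
    out["combined_p"] = np.clip(stats.norm.sf(out["combined_z"]), _P_FLOOR, 1.0)
    out["combined_fdr"] = adjust_bh(out["combined_p"].to_numpy())
    out = out.sort_values(["combined_p", "gene_id"], kind="mergesort").reset_index(drop=True)
    return out


def search_platform(
    matrix: ExpressionMatrix,
    query_genes,
    params: FilterParams | None = None,
    use_filter: bool = True,
) -> PlatformResult:
    """Run the full single-platform pipeline.

    standardize -> SVD -> Kaiser truncation -> query weights -> filtered
    reconstruction -> mean Fisher z -> median/MAD standardization ->
    one-sided normal p -> BH FDR. With ``use_filter=False`` the
    correlations are computed on the standardized but unfiltered matrix
    (a baseline; the significance machinery is unchanged).

    Query genes are excluded from the ranked table (their self-correlation
    is 1) and reported separately with their zbar.
    """
    params = params or FilterParams()
    std, dropped = standardize_genes(matrix)
    query_genes = list(query_genes)
    missing = [g for g in query_genes if g in dropped]
    if missing:
        raise ValueError(f"query genes are constant in this platform: {missing}")
    query_rows = std.row_index(query_genes)  # raises KeyError for absent genes

    fact = factorize(std)
    sigma = fact.sigma.copy()
    weights = query_weights(fact, query_rows, params)
    if params.kaiser:
        L = kaiser_rank(fact, std.n_samples, min_rank=params.min_rank)
    else:
        L = fact.rank
    if use_filter:
        filtered = filter_matrix(fact, weights, L)
    else:
        filtered = std.values

    zbar, zero_var = mean_fisher_correlation(filtered, query_rows)

    is_query = np.zeros(std.n_genes, dtype=bool)
    is_query[query_rows] = True
    table = pd.DataFrame({
        "gene_id": std.gene_ids[~is_query],
        "zbar": zbar[~is_query],
    })
    table["s"] = robust_standardize(table["zbar"].to_numpy())
    table["p"] = scores_to_pvalues(table["s"].to_numpy())
    table["fdr"] = adjust_bh(table["p"].to_numpy())
    order = table.sort_values(["s", "gene_id"], ascending=[False, True],
                              kind="mergesort").index
    table.loc[order, "rank"] = np.arange(1, len(table) + 1)
    table["rank"] = table["rank"].astype(int)
    table = table.sort_values("rank", kind="mergesort").reset_index(drop=True)

    query_report = pd.DataFrame({
        "gene_id": std.gene_ids[is_query],
        "zbar": zbar[is_query],
    })
    return PlatformResult(
        table=table,
        query_report=query_report,
        sigma=sigma,
        w=weights.w,
        sigma_filtered=weights.sigma_filtered,
        retained_rank=L,
        zero_variance_genes=list(std.gene_ids[zero_var & ~is_query]),
        dropped_constant_genes=dropped,
    )


def cellmapper_search(
    datasets: list[ExpressionMatrix],
    query_genes,
    params: FilterParams | None = None,
    fdr_threshold: float = 0.01,
    use_filter: bool = True,
) -> SearchResult:
    """Search one or more platforms and pool the evidence.

    Every query gene must be present in at least one dataset; a platform
    containing none of the query genes is skipped (recorded in
    ``skipped_platforms``). Genes with pooled FDR <= ``fdr_threshold`` are
    flagged ``predicted``. Output order is (combined_p asc, gene_id asc).
    """
    query_genes = list(query_genes)
    if not query_genes:
        raise ValueError("need at least one query gene")
    if not datasets:
        raise ValueError("need at least one dataset")
    present: set = set()
    for d in datasets:
        present.update(set(d.gene_ids) & set(query_genes))
    absent = [g for g in query_genes if g not in present]
    if absent:
        raise ValueError(f"query genes absent from every dataset: {absent}")

    platforms = []
    skipped = []
    for i, d in enumerate(datasets):
        qs = [g for g in query_genes if g in set(d.gene_ids)]
        if not qs:
            skipped.append(i)
            continue
        platforms.append(search_platform(d, qs, params=params, use_filter=use_filter))

    pooled = stouffer_pool([p.table for p in platforms])
    pooled["predicted"] = pooled["combined_fdr"] <= fdr_threshold
    return SearchResult(pooled=pooled, platforms=platforms,
                        query_genes=query_genes, skipped_platforms=skipped)
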