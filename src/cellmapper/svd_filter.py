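"""Query-adaptive SVD filtering of standardized expression matrices.

The filter amplifies expression patterns that separate the query genes
from the rest of the genome and suppresses the rest. The standardized
matrix (each gene mean 0, sd 1 across samples) is factorized as
``X = U diag(sigma) V^T``. Each singular value is rescaled to

    sigma'_k = sigma_k ** alpha * |w_k|,      w_k = sum_q tanh(u_k^q)

where ``u_k^q`` is the loading of query gene q on singular vector k after
standardizing that vector's loadings across all genes (mean 0, sd 1).
The exponent ``alpha`` in [0, 1] compresses the spectrum (1 = no scaling,
0 = all retained vectors weighted equally); ``tanh`` saturates so a single
query gene can contribute at most +/-1 per vector. Vectors on which the
query genes have unremarkable loadings get |w_k| near 0 and are smoothly
silenced. Vectors accounting for less variance than an average single
sample (Kaiser's criterion) are discarded outright, and the filtered
matrix is reconstructed from the surviving spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "FilterParams",
    "SVDFactorization",
    "FilterWeights",
    "standardize_genes",
    "factorize",
    "kaiser_rank",
    "query_weights",
    "filter_matrix",
]

# rows with sample sd below this are flagged as zero-variance
_ZERO_VAR_TOL = 1e-12


@dataclass
class FilterParams:
    """Tunables of the SVD filter.

    alpha : singular-value exponent in [0, 1], default 0.5.
    kaiser : apply Kaiser's variance criterion to truncate the rank.
    min_rank : floor on the retained rank (>= 1 so the filtered matrix is
        never identically zero).
    """

    alpha: float = 0.5
    kaiser: bool = True
    min_rank: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.min_rank < 1:
            raise ValueError("min_rank must be >= 1")


@dataclass
class SVDFactorization:
    """Thin SVD of a standardized matrix: X = U diag(sigma) V^T."""

    U: np.ndarray       # m x r gene loadings
    sigma: np.ndarray   # r singular values, non-increasing
    V: np.ndarray       # n x r sample loadings

    @property
    def rank(self) -> int:
        return len(self.sigma)

    def reconstruct(self, L: int | None = None) -> np.ndarray:
        L = self.rank if L is None else L
        return (self.U[:, :L] * self.sigma[:L]) @ self.V[:, :L].T


@dataclass
class FilterWeights:
    """Per-singular-vector query weights and the filtered spectrum."""

    w: np.ndarray               # w_k = sum_q tanh(standardized loading)
    u_normalized: np.ndarray    # m x r, each column mean 0 / sd 1 across genes
    sigma_filtered: np.ndarray  # sigma_k^alpha * |w_k|
    query_rows: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def standardize_genes(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, list]:
    """Scale each gene to mean 0 and sample standard deviation 1.

    Uses the sample sd (divisor n-1). Zero-variance rows cannot be scaled;
    they are removed and their ids returned. Raises ``ValueError`` if fewer
    than 2 samples or if every row is constant.
    """
    if matrix.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    sd = matrix.values.std(axis=1, ddof=1)
    keep = sd > _ZERO_VAR_TOL
    dropped = list(matrix.gene_ids[~keep])
    if not keep.any():
        raise ValueError("all gene rows have zero variance")
    vals = matrix.values[keep]
    vals = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep, None]
    out = ExpressionMatrix(matrix.gene_ids[keep], matrix.sample_ids.copy(), vals)
    return out, dropped


def factorize(matrix: ExpressionMatrix | np.ndarray) -> SVDFactorization:
    """Thin SVD of a (standardized) matrix.

    Numerical non-convergence in LAPACK surfaces as ``np.linalg.LinAlgError``.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, float)
    U, sigma, Vt = np.linalg.svd(values, full_matrices=False)
    return SVDFactorization(U=U, sigma=sigma, V=Vt.T)


def kaiser_rank(fact: SVDFactorization, n_samples: int, min_rank: int = 1) -> int:
    """Number of singular vectors accounting for more variance than one sample.

    Retains components with ``sigma_k^2 > (sum_j sigma_j^2) / n_samples``
    (strict inequality). At least ``min_rank`` vectors are always kept so
    the downstream reconstruction is never empty — this also covers the
    degenerate all-equal spectrum where no component clears the threshold.
    """
    var = fact.sigma**2
    threshold = var.sum() / n_samples
    L = int((var > threshold).sum())
    return max(L, min_rank)


def query_weights(
    fact: SVDFactorization,
    query_rows,
    params: FilterParams | None = None,
) -> FilterWeights:
    """Compute per-vector query weights w_k and the filtered spectrum.

    Each column of U is standardized across genes (mean 0, sample sd 1)
    before the tanh; ``w_k`` sums the saturated standardized loadings of
    the query genes, and ``sigma_filtered_k = sigma_k**alpha * |w_k|``.
    """
    params = params or FilterParams()
    query_rows = np.asarray(query_rows, dtype=int)
    if query_rows.size == 0:
        raise ValueError("query_rows must be non-empty")
    m = fact.U.shape[0]
    if query_rows.min() < 0 or query_rows.max() >= m:
        raise IndexError(f"query row out of range for matrix with {m} genes")
    mu = fact.U.mean(axis=0)
    sd = fact.U.std(axis=0, ddof=1)
    sd = np.where(sd > _ZERO_VAR_TOL, sd, 1.0)  # constant column: loadings already 0 after centering
    u_norm = (fact.U - mu) / sd
    w = np.tanh(u_norm[query_rows]).sum(axis=0)
    sigma_filtered = fact.sigma**params.alpha * np.abs(w)
    return FilterWeights(w=w, u_normalized=u_norm, sigma_filtered=sigma_filtered,
                         query_rows=query_rows)


def filter_matrix(
    fact: SVDFactorization,
    weights: FilterWeights,
    L: int,
) -> np.ndarray:
    """Reconstruct the filtered matrix U[:, :L] diag(sigma'[:L]) V[:, :L]^T.

    ``L`` is the Kaiser-truncated rank, determined from the ORIGINAL
    spectrum before query weighting.
    """
    if L < 1:
        raise ValueError("retained rank L must be >= 1")
    if L > fact.rank:
        raise ValueError(f"L={L} exceeds factorization rank {fact.rank}")
    return (fact.U[:, :L] * weights.sigma_filtered[:L]) @ fact.V[:, :L].T
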