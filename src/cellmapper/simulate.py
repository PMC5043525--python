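"""Synthetic mixed-tissue expression data with planted cell-type structure.

Heterogeneous samples (whole tissue, biopsies) are modelled as convex
combinations of latent cell-type expression profiles whose proportions
vary from sample to sample — the variation that makes statistical
inference of cell type-enriched genes possible in the first place. The
generator plants disjoint marker-gene sets, one per cell type: each gene
has one background expression level shared across types, and a marker's
profile is raised by a fixed log2 fold change in its own type only, so
markers are exactly the *differentially* expressed genes. Batch structure
(additive per-gene offsets shared by samples of the same batch) emulates
the technical variation of multi-study compendia. The ground truth
(marker assignments, mixing proportions, batch labels) is emitted so
every pipeline stage can be evaluated without external data.

What it emulates: sample-to-sample composition variability (Dirichlet
proportions, allowing rare types), additive measurement noise, and batch
structure. What it does not: probe effects, intensity saturation, or
other platform-specific microarray artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "MixtureDesign",
    "SyntheticTruth",
    "simulate_mixture",
    "simulate_null",
    "default_benchmark_design",
]


@dataclass
class MixtureDesign:
    """Parameters of a planted-marker mixture simulation.

    n_genes, n_samples : matrix dimensions m x n.
    n_cell_types : number of latent cell types K.
    markers_per_type : planted markers per type (disjoint sets;
        K * markers_per_type <= m).
    log2_fold_change : elevation of a marker's expression in its own
        type's profile, in log2 units.
    proportion_prior : length-K Dirichlet concentration vector for the
        per-sample mixing proportions; small relative concentrations give
        rare cell types, and a small total concentration gives highly
        variable composition. None = symmetric with total K.
    noise_sd : sd of additive Gaussian measurement noise (log2 units).
    n_batches, batch_sd : samples are split evenly into batches; each
        batch draws an additive per-gene offset ~ Normal(0, batch_sd)
        shared by its samples.
    background : "shared" (default) gives every gene one background level
        across types, so only planted markers vary between cell types;
        "independent" draws a separate Normal(0, 1) background per gene
        per type, making every gene differentially expressed and marker
        recovery fundamentally ambiguous (a stress-test variant).
    mixing : "log2" mixes profiles directly in log2 space (a documented
        simplification; per-gene standardization downstream makes only the
        co-variation structure matter); "linear" mixes 2**profile
        intensities and returns log2 of the mixture.
    seed : generator seed; every draw is reproducible from it.
    """

    n_genes: int = 2000
    n_samples: int = 200
    n_cell_types: int = 5
    markers_per_type: int = 50
    log2_fold_change: float = 2.0
    proportion_prior: np.ndarray | None = None
    noise_sd: float = 0.5
    n_batches: int = 10
    batch_sd: float = 0.25
    background: str = "shared"
    mixing: str = "log2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        if self.n_cell_types < 1:
            raise ValueError("need at least one cell type")
        if self.markers_per_type < 0:
            raise ValueError("markers_per_type must be >= 0")
        if self.n_cell_types * self.markers_per_type > self.n_genes:
            raise ValueError("marker sets exceed the number of genes")
        if self.noise_sd < 0 or self.batch_sd < 0:
            raise ValueError("noise_sd and batch_sd must be >= 0")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.background not in ("shared", "independent"):
            raise ValueError(f"background must be 'shared' or 'independent', got {self.background!r}")
        if self.mixing not in ("log2", "linear"):
            raise ValueError(f"mixing must be 'log2' or 'linear', got {self.mixing!r}")
        if self.proportion_prior is not None:
            prior = np.asarray(self.proportion_prior, dtype=float)
            if prior.shape != (self.n_cell_types,):
                raise ValueError("proportion_prior must have one entry per cell type")
            if (prior <= 0).any():
                raise ValueError("Dirichlet concentrations must be positive")
            self.proportion_prior = prior


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated matrix.

    markers : gene_id -> cell type label ("type_0", ...) for planted
        markers; genes absent from the dict are background.
    proportions : n_samples x K DataFrame of mixing proportions
        (rows sum to 1).
    batch_labels : per-sample batch index.
    """

    markers: dict
    proportions: pd.DataFrame
    batch_labels: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def markers_of(self, cell_type: str) -> list:
        return [g for g, t in self.markers.items() if t == cell_type]


def default_benchmark_design(seed: int = 1, **overrides) -> MixtureDesign:
    """The standard benchmark: m=2000, n=200, K=5, 50 markers/type, fold
    change 2.0, noise sd 0.5, 10 batches with offset sd 0.25, and a rare
    first cell type with mean mixing proportion 0.05 (remaining types
    share the rest equally).

    The Dirichlet concentration vector equals the mean proportions (total
    concentration 1.0): tissue composition varies strongly from sample to
    sample, with the rare type absent from most samples and occasionally
    substantial — the compendium-like regime the search is meant for.
    """
    k = overrides.get("n_cell_types", 5)
    if "proportion_prior" not in overrides:
        means = np.full(k, (1.0 - 0.05) / (k - 1)) if k > 1 else np.array([1.0])
        if k > 1:
            means[0] = 0.05
        overrides["proportion_prior"] = means  # total concentration 1.0
    return MixtureDesign(seed=seed, **overrides)


def simulate_mixture(design: MixtureDesign) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a mixed-sample expression matrix with planted markers.

    Per-gene background expression is drawn Normal(0, 1); each marker's
    own-type profile is raised by ``log2_fold_change``. Sample expression
    is the proportion-weighted combination of the type profiles plus the
    batch offset and Normal(0, noise_sd) noise. Marker sets occupy the
    first K * markers_per_type gene rows (type 0 first); gene positions
    carry no information for the scoring pipeline, which is
    permutation-invariant in rows.
    """
    rng = np.random.default_rng(design.seed)
    m, n, k = design.n_genes, design.n_samples, design.n_cell_types

    if design.background == "shared":
        profiles = np.tile(rng.standard_normal(m)[:, None], (1, k))
    else:
        profiles = rng.standard_normal((m, k))
    markers: dict = {}
    gene_ids = np.array([f"G{i:05d}" for i in range(m)], dtype=object)
    for t in range(k):
        rows = np.arange(t * design.markers_per_type, (t + 1) * design.markers_per_type)
        profiles[rows, t] += design.log2_fold_change
        for r in rows:
            markers[gene_ids[r]] = f"type_{t}"

    prior = design.proportion_prior if design.proportion_prior is not None else np.ones(k)
    props = rng.dirichlet(prior, size=n)  # n x K

    if design.mixing == "log2":
        values = profiles @ props.T
    else:
        values = np.log2((2.0**profiles) @ props.T)

    batch_labels = np.arange(n) * design.n_batches // n
    if design.n_batches > 1 and design.batch_sd > 0:
        offsets = rng.normal(0.0, design.batch_sd, size=(m, design.n_batches))
        values = values + offsets[:, batch_labels]
    if design.noise_sd > 0:
        values = values + rng.normal(0.0, design.noise_sd, size=(m, n))

    sample_ids = np.array([f"S{j:04d}" for j in range(n)], dtype=object)
    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    truth = SyntheticTruth(
        markers=markers,
        proportions=pd.DataFrame(props, index=sample_ids,
                                 columns=[f"type_{t}" for t in range(k)]),
        batch_labels=batch_labels,
    )
    return matrix, truth


def simulate_null(m: int, n: int, seed: int = 0) -> ExpressionMatrix:
    """An i.i.d. standard-normal matrix — the no-structure null.

    Mirrors scrambling sample labels: no gene shares co-variation with any
    other beyond chance, so query scores should be calibrated null.
    """
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((m, n))
    gene_ids = np.array([f"G{i:05d}" for i in range(m)], dtype=object)
    sample_ids = np.array([f"S{j:04d}" for j in range(n)], dtype=object)
    return ExpressionMatrix(gene_ids, sample_ids, values)
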