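"""Evaluation of ranked gene lists: gold standards, precision-recall, enrichment.

Predictions are evaluated against gold standards of experimentally defined
cell type-enriched genes — genes whose mean expression in purified samples
of the target type exceeds a fold-change threshold over the remaining
samples. Ranking quality is summarized by the area under the
precision-recall curve (AUPR), computed with the interpolation-free
average-precision estimator: the sum of precision at each retrieved
positive divided by the total number of positives. Set-level overlap is
tested with a one-sided Fisher's exact test (hypergeometric tail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "GoldStandard",
    "PRCurve",
    "derive_gold_standard",
    "precision_recall",
    "aupr",
    "enrichment_fisher",
]


@dataclass
class GoldStandard:
    """A positive gene set within a universe, with provenance."""

    positives: set
    universe: set
    label: str = ""

    def __post_init__(self) -> None:
        self.positives = set(self.positives)
        self.universe = set(self.universe)
        if not self.positives:
            raise ValueError("gold standard has no positive genes")
        if not self.positives <= self.universe:
            raise ValueError("positives must be a subset of the universe")


@dataclass
class PRCurve:
    """Precision/recall at every prefix of a ranked list."""

    recall: np.ndarray
    precision: np.ndarray
    n_positives: int


def derive_gold_standard(
    profiles: ExpressionMatrix,
    target_samples,
    fold_threshold: float = 3.0,
    log_scale: bool = True,
    label: str = "",
) -> GoldStandard:
    """Genes at least ``fold_threshold``-fold higher in the target samples.

    With ``log_scale=True`` (log2 input) the rule is applied as a
    difference of means >= log2(fold_threshold); otherwise as a ratio of
    linear-scale means. The comparison is inclusive ("at least"). Raises
    ``ValueError`` if the target or non-target sample set is empty.
    """
    target_samples = set(target_samples)
    is_target = np.array([s in target_samples for s in profiles.sample_ids])
    if not is_target.any():
        raise ValueError("no target samples present in the matrix")
    if is_target.all():
        raise ValueError("no non-target samples to compare against")
    mean_t = profiles.values[:, is_target].mean(axis=1)
    mean_o = profiles.values[:, ~is_target].mean(axis=1)
    if log_scale:
        positive = mean_t - mean_o >= np.log2(fold_threshold)
    else:
        positive = mean_t >= fold_threshold * mean_o
    pos = set(profiles.gene_ids[positive])
    if not pos:
        raise ValueError("no gene passes the fold-change threshold")
    return GoldStandard(pos, set(profiles.gene_ids), label=label)


def precision_recall(ranked_genes, gold: GoldStandard) -> PRCurve:
    """Precision and recall over every prefix of a ranked gene list.

    Genes outside the gold standard's universe are excluded before
    computation. Raises ``ValueError`` on an empty (post-filter) ranking.
    """
    ranked = [g for g in ranked_genes if g in gold.universe]
    if not ranked:
        raise ValueError("empty ranking after restricting to the universe")
    hits = np.array([g in gold.positives for g in ranked])
    tp = np.cumsum(hits)
    k = np.arange(1, len(ranked) + 1)
    n_pos = len(gold.positives)
    return PRCurve(recall=tp / n_pos, precision=tp / k, n_positives=n_pos)


def aupr(curve: PRCurve) -> float:
    """Area under the PR curve, average-precision form.

    Interpolation-free: sum of precision at each rank where a positive is
    retrieved, divided by the total number of positives — equivalently
    sum(delta_recall * precision) over the curve. Positives never
    retrieved contribute zero area.
    """
    delta = np.diff(curve.recall, prepend=0.0)
    return float(np.sum(delta * curve.precision))


def enrichment_fisher(hits, candidates, universe) -> tuple[float, float]:
    """One-sided (greater) Fisher's exact test for overlap of two gene sets.

    The 2x2 table is [[|hits & candidates|, |hits - candidates|],
    [|candidates - hits|, |neither|]]; the p-value is the exact
    hypergeometric upper tail. Returns (odds_ratio, p). Raises
    ``ValueError`` on an empty universe or sets outside it.
    """
    hits, candidates, universe = set(hits), set(candidates), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe or not candidates <= universe:
        raise ValueError("hits and candidates must be subsets of the universe")
    a = len(hits & candidates)
    b = len(hits - candidates)
    c = len(candidates - hits)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)
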