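"""Two-phase prioritization of GWAS candidate genes by cell-type expression.

A GWAS locus typically contains several positional candidate genes of
which only one drives the association. If the relevant cell type is
known — or can be detected — genes selectively expressed in that cell
type are the natural candidates.

Phase 1 detects "priority" cell types: genes within a small window
(default 20 kb) centered on each GWAS SNP form the positional-candidate
set, and each cell type whose top predictions (default top 200) are
enriched for these candidates (one-sided Fisher's exact test, Holm
family-wise adjustment across cell types, adjusted p <= 0.05) is flagged.
Cell types known from the literature can be supplied as additional
priorities.

Phase 2 emphasizes sensitivity: every gene whose interval lies within a
maximum distance (default 250 kb, nearest gene edge to SNP position — a
distance proxy for linkage disequilibrium; no LD panel is consulted) of a
GWAS SNP and is predicted for a priority cell type at FDR <= 0.1 is
reported as a prioritized (SNP, gene, cell type) triple.

Coordinates are 1-based inclusive internally; BED input (0-based
half-open) is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import enrichment_fisher
from .search import adjust_holm

__all__ = [
    "SnpRecord",
    "GeneInterval",
    "read_snps_bed",
    "read_genes_bed",
    "positional_candidates",
    "phase1_priority_cell_types",
    "phase2_select_candidates",
]


@dataclass(frozen=True)
class SnpRecord:
    """A GWAS variant: identifier, chromosome, 1-based position."""

    snp_id: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1")


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic extent, 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    def distance_to(self, snp: SnpRecord) -> float:
        """Nearest-edge distance in bp; 0 if the SNP falls inside; inf across chromosomes."""
        if self.chromosome != snp.chromosome:
            return float("inf")
        if self.start <= snp.position <= self.end:
            return 0.0
        return float(min(abs(snp.position - self.start), abs(snp.position - self.end)))


def read_snps_bed(path) -> list[SnpRecord]:
    """Read SNPs from a 4-column BED-like TSV (chrom, pos0, pos0+1, snp_id)."""
    df = pd.read_csv(Path(path), sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name"], dtype={"chrom": str})
    return [SnpRecord(str(r.name), str(r.chrom), int(r.start) + 1)
            for r in df.itertuples(index=False)]


def read_genes_bed(path) -> list[GeneInterval]:
    """Read gene intervals from BED (chrom, start0, end0, gene_id)."""
    df = pd.read_csv(Path(path), sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name"], dtype={"chrom": str})
    return [GeneInterval(str(r.name), str(r.chrom), int(r.start) + 1, int(r.end))
            for r in df.itertuples(index=False)]


def positional_candidates(
    snps: list[SnpRecord],
    genes: list[GeneInterval],
    window_bp: int = 20_000,
) -> dict:
    """Genes overlapping a window centered on each SNP.

    Gene g is a candidate for SNP s iff g's interval overlaps
    [position - window_bp/2, position + window_bp/2] (inclusive) on the
    same chromosome. Returns snp_id -> set of gene ids. With window 0 only
    genes containing the SNP position qualify.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    half = window_bp / 2.0
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out: dict = {}
    for s in snps:
        lo, hi = s.position - half, s.position + half
        out[s.snp_id] = {
            g.gene_id for g in by_chrom.get(s.chromosome, [])
            if g.end >= lo and g.start <= hi
        }
    return out


def phase1_priority_cell_types(
    celltype_predictions: dict,
    gwas_candidates,
    universe,
    top_n: int = 200,
    alpha: float = 0.05,
) -> tuple[list, pd.DataFrame]:
    """Detect cell types whose top predictions are enriched for GWAS candidates.

    ``celltype_predictions`` maps cell type -> ranked gene list (best
    first). For each cell type the top ``top_n`` genes are tested for
    overlap with ``gwas_candidates`` by a one-sided Fisher's exact test
    over ``universe``; p-values are Holm-adjusted across cell types.
    Returns (priority cell types with adjusted p <= alpha, full table
    sorted by adjusted then raw p).
    """
    gwas_candidates = set(gwas_candidates)
    if not gwas_candidates:
        raise ValueError("empty GWAS candidate set")
    universe = set(universe)
    rows = []
    for ct, ranked in celltype_predictions.items():
        if len(ranked) < top_n:
            raise ValueError(f"cell type {ct!r}: ranked list shorter than top_n={top_n}")
        top = set(ranked[:top_n])
        odds, p = enrichment_fisher(top, gwas_candidates & universe, universe)
        rows.append({"cell_type": ct, "odds_ratio": odds, "p": p})
    table = pd.DataFrame(rows)
    table["p_holm"] = adjust_holm(table["p"].to_numpy())
    table["priority"] = table["p_holm"] <= alpha
    table = table.sort_values(["p_holm", "p", "cell_type"], kind="mergesort").reset_index(drop=True)
    priorities = list(table.loc[table["priority"], "cell_type"])
    return priorities, table


def phase2_select_candidates(
    snps: list[SnpRecord],
    genes: list[GeneInterval],
    pooled_by_cell_type: dict,
    max_distance_bp: int = 250_000,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Select in-locus genes predicted for the priority cell types.

    ``pooled_by_cell_type`` maps each priority cell type to its pooled
    result table (columns ``gene_id`` and ``combined_fdr``). A
    (SNP, gene, cell type) triple is emitted when the gene's interval lies
    within ``max_distance_bp`` of the SNP position (nearest edge,
    inclusive at the boundary) and its FDR for that cell type is <=
    ``fdr_threshold``. Sorted by (snp_id, fdr, gene_id, cell_type).
    """
    if not pooled_by_cell_type:
        raise ValueError("no priority cell types supplied")
    fdr_maps = {
        ct: dict(zip(tab["gene_id"], tab["combined_fdr"]))
        for ct, tab in pooled_by_cell_type.items()
    }
    rows = []
    for s in snps:
        for g in genes:
            dist = g.distance_to(s)
            if dist > max_distance_bp:
                continue
            for ct, fdr_map in fdr_maps.items():
                fdr = fdr_map.get(g.gene_id)
                if fdr is not None and fdr <= fdr_threshold:
                    rows.append({
                        "snp_id": s.snp_id,
                        "gene_id": g.gene_id,
                        "cell_type": ct,
                        "fdr": float(fdr),
                        "distance_bp": int(dist),
                    })
    out = pd.DataFrame(rows, columns=["snp_id", "gene_id", "cell_type", "fdr", "distance_bp"])
    return out.sort_values(["snp_id", "fdr", "gene_id", "cell_type"],
                           kind="mergesort").reset_index(drop=True)
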