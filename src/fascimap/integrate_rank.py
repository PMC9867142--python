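"""Intersect BSA candidate regions with DEGs and rank candidate genes.

The mapping interval from the genome scan typically holds dozens of genes;
the genes that are also differentially expressed between the bulked
phenotypes are the prime candidates, ranked by their abundance in the
focal tissue (candidates expressed below a floor are flagged low).
"""

from __future__ import annotations

from dataclasses import dataclass

from .bsa_scan import CandidateRegion
from .de_expr import ExpressionRecord
from .io_formats import GeneModel

LOW_EXPR_FLOOR = 1.0  # FPKM


@dataclass
class CandidateGene:
    gene_id: str
    region: CandidateRegion
    is_deg: bool = True
    expression_level: float = float("nan")
    low_expression: bool = False


def genes_in_region(
    region: CandidateRegion, gene_models: list[GeneModel]
) -> list[GeneModel]:
    """Genes whose 1-based inclusive span overlaps the region by >= 1 bp."""
    hits = [
        g
        for g in gene_models
        if g.chrom == region.chrom and g.start <= region.end and g.end >= region.start
    ]
    hits.sort(key=lambda g: (g.start, g.gene_id))
    return hits


def intersect_degs(
    region_genes: list[GeneModel],
    deg_list: list[ExpressionRecord],
    region: CandidateRegion,
) -> list[CandidateGene]:
    """Region genes that are DEGs, in genomic order; empty result allowed."""
    deg_ids = {r.gene_id for r in deg_list}
    return [
        CandidateGene(gene_id=g.gene_id, region=region)
        for g in region_genes
        if g.gene_id in deg_ids
    ]


def rank_candidates(
    candidates: list[CandidateGene],
    tissue_fpkm: dict[str, float],
    low_expr_floor: float = LOW_EXPR_FLOOR,
) -> list[CandidateGene]:
    """Sort candidates by focal-tissue abundance, flagging low expression.

    Descending abundance; genes below the floor are flagged
    ``low_expression``.  Ties break lexicographically on gene_id for a
    deterministic order.
    """
    for c in candidates:
        c.expression_level = float(tissue_fpkm.get(c.gene_id, 0.0))
        c.low_expression = c.expression_level < low_expr_floor
    return sorted(candidates, key=lambda c: (-c.expression_level, c.gene_id))
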