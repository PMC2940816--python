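"""SNP-to-gene assignment with strand-aware upstream windows.

Coordinates are 0-based half-open throughout (BED convention).  A SNP
belongs to a gene when it falls in the transcribed interval or within a
fixed window upstream of the transcription start site: 500 bp for scan
reporting, 25 kb for pathway/gene-set analyses.  The TSS is tx_start on the
+ strand and tx_end on the - strand, so the upstream window extends left of
tx_start for + genes and right of tx_end for - genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneModel", "SnpLocus",
    "assign_snps", "nearest_gene", "classify_genic",
    "genes_with_significant",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene-level transcript: 0-based half-open [tx_start, tx_end)."""

    gene_id: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")

    def window(self, upstream_bp: int) -> tuple[int, int]:
        """Half-open assignment interval including the upstream window."""
        if self.strand == "+":
            return max(0, self.tx_start - upstream_bp), self.tx_end
        return self.tx_start, self.tx_end + upstream_bp


@dataclass(frozen=True)
class SnpLocus:
    snp_id: str
    chrom: str
    pos: int  # 0-based

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"{self.snp_id}: position must be >= 0")


def _trees(genes: list[GeneModel], upstream_bp: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo, hi = g.window(upstream_bp)
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)
    return trees


def assign_snps(snps: list[SnpLocus], genes: list[GeneModel],
                upstream_bp: int = 500) -> dict[str, set[str]]:
    """Map each SNP to the set of genes whose window contains it.

    A SNP may hit several overlapping genes; a SNP on a chromosome with no
    genes simply maps to the empty set.
    """
    if upstream_bp < 0:
        raise ValueError("upstream_bp must be >= 0")
    trees = _trees(genes, upstream_bp)
    out: dict[str, set[str]] = {}
    for s in snps:
        tree = trees.get(s.chrom)
        out[s.snp_id] = ({iv.data for iv in tree[s.pos]} if tree is not None
                         else set())
    return out


def nearest_gene(snp: SnpLocus, genes: list[GeneModel]
                 ) -> tuple[str, int] | None:
    """Closest gene on the SNP's chromosome and its distance in bp.

    Distance is 0 inside the transcribed region, otherwise the gap to the
    nearer transcript boundary under half-open coordinates (a SNP at
    tx_end is 1 bp away).  Equidistant genes resolve to the
    lexicographically smaller gene_id.  Returns None when the chromosome
    carries no gene.
    """
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != snp.chrom:
            continue
        if g.tx_start <= snp.pos < g.tx_end:
            d = 0
        elif snp.pos < g.tx_start:
            d = g.tx_start - snp.pos
        else:
            d = snp.pos - (g.tx_end - 1)
        cand = (d, g.gene_id)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    return best[1], best[0]


def classify_genic(snps: list[SnpLocus], genes: list[GeneModel],
                   upstream_bp: int = 0) -> pd.Series:
    """Boolean per SNP: assigned to >= 1 gene under the given window."""
    assignments = assign_snps(snps, genes, upstream_bp)
    out = pd.Series({s.snp_id: bool(assignments[s.snp_id]) for s in snps})
    out.index.name = "snp"
    out.name = "genic"
    return out


def genes_with_significant(assignments: dict[str, set[str]],
                           significant: pd.Series) -> list[str]:
    """Distinct genes carrying at least one significant SNP, sorted."""
    hit: set[str] = set()
    for snp, flag in significant.items():
        if flag:
            hit |= assignments.get(snp, set())
    return sorted(hit)
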