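"""Assign SNPs to genes with strand-aware upstream windows.

Scan reporting uses the transcribed region plus 500 bp upstream of the
TSS; gene-set analyses widen the window to 25 kb.  Coordinates are
0-based half-open (BED).
"""

from helmscan.genemap import GeneModel, SnpLocus, assign_snps, nearest_gene

genes = [
    GeneModel("IL4_like", "chr1", 10_000, 19_000, "+"),
    GeneModel("CTLA4_like", "chr1", 40_000, 47_000, "-"),
]
snps = [
    SnpLocus("rs_genic", "chr1", 12_345),      # inside IL4_like
    SnpLocus("rs_promoter", "chr1", 9_700),    # 300 bp upstream (+ strand)
    SnpLocus("rs_upstream20k", "chr1", 60_000),  # 13 kb past CTLA4_like end
    SnpLocus("rs_far", "chr1", 120_000),
]

for u in (500, 25_000):
    asg = assign_snps(snps, genes, upstream_bp=u)
    hits = {s: sorted(g) for s, g in asg.items() if g}
    print(f"upstream window {u:>6} bp -> {hits}")

print("\nnearest gene and distance (bp):")
for s in snps:
    gene, dist = nearest_gene(s, genes)
    print(f"  {s.snp_id:<14} {gene:<12} {dist}")
print("rs_upstream20k sits upstream of the minus-strand gene's TSS "
      "(its tx_end), so only the 25 kb rule captures it.")
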