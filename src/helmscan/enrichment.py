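"""Gene-set enrichment by SNP-count-matched resampling, and genic chi-square.

A gene's chance of carrying a significant SNP grows with the number of SNPs
typed in it, so an enrichment test must compare the target set against
random gene sets with a *matched SNP-count profile*.  The universe of genes
covered by at least one SNP is split into intervals (24 by default) on the
typed-SNP-count axis; each resample replaces every target gene with a
random gene from the same interval.  Empirical p-values use the
(1 + k) / (1 + R) permutation estimator.

A companion chi-square contrasts the genic/intergenic split of significant
SNPs against one MAF-matched control SNP drawn per hit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneBins", "EnrichmentResult",
    "bin_genes_by_snp_count", "resample_enrichment", "genic_chisq",
]


@dataclass(frozen=True)
class GeneBins:
    """Partition of the gene universe into SNP-count intervals."""

    n_bins: int
    bin_edges: np.ndarray        # ascending count edges, len = n_eff + 1
    gene_bin: pd.Series          # gene_id -> bin index in [0, n_eff)

    @property
    def n_effective(self) -> int:
        return len(self.bin_edges) - 1


@dataclass(frozen=True)
class EnrichmentResult:
    observed_gene_count: int
    observed_snp_count: int
    R: int
    null_gene_counts: np.ndarray
    null_snp_counts: np.ndarray
    p_gene: float
    p_snp: float
    seed: int


def bin_genes_by_snp_count(universe: pd.Series, n_bins: int = 24) -> GeneBins:
    """Quantile-bin genes on typed-SNP count.

    ``universe`` maps gene_id -> SNP count (all counts >= 1).  Edges are the
    count quantiles; duplicate edges (heavy count ties) are merged, so the
    effective number of bins may be below ``n_bins``.  Deterministic given
    the input.
    """
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    counts = universe.astype(int)
    if (counts < 1).any():
        raise ValueError("every universe gene must carry >= 1 SNP")
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    interior = np.quantile(counts.to_numpy(), qs, method="higher")
    edges = np.unique(np.concatenate(
        [[counts.min()], interior, [counts.max() + 1]])).astype(float)
    idx = np.searchsorted(edges, counts.to_numpy(), side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    gene_bin = pd.Series(idx, index=counts.index, name="bin")
    return GeneBins(n_bins=n_bins, bin_edges=edges, gene_bin=gene_bin)


def _empirical_upper(null: np.ndarray, obs: float) -> float:
    return (1.0 + int(np.sum(null >= obs))) / (1.0 + len(null))


def _empirical_two_sided(null: np.ndarray, obs: float) -> float:
    upper = _empirical_upper(null, obs)
    lower = (1.0 + int(np.sum(null <= obs))) / (1.0 + len(null))
    return min(1.0, 2.0 * min(upper, lower))


def resample_enrichment(target, universe: pd.Series, bins: GeneBins,
                        sig_genes, R: int = 10_000, seed: int = 0,
                        with_replacement: bool = False,
                        exclude_target: bool = False) -> EnrichmentResult:
    """Matched-resampling test for enrichment of significant genes.

    Per resample, each target gene is replaced by a random universe gene
    from the same SNP-count bin, without replacement within the resample
    (``with_replacement=True`` relaxes this when a bin is too small).  The
    upper-tail empirical p compares the observed number of target genes
    carrying >= 1 significant SNP against the resampled counts; the SNP
    count uses a two-sided empirical p, since the matched design makes
    either deviation interpretable.

    Target genes stay in the sampling pool by default (a resample may
    redraw them); ``exclude_target`` removes them.
    """
    target = set(target)
    sig_genes = set(sig_genes)
    if not target <= set(universe.index):
        missing = sorted(target - set(universe.index))[:5]
        raise ValueError(f"target genes outside the universe, e.g. {missing}")
    rng = np.random.default_rng(seed)

    gene_bin = bins.gene_bin
    counts = universe.astype(int)
    target_idx = gene_bin.index.isin(target)
    need = gene_bin[target_idx].value_counts().sort_index()

    observed_gene_count = sum(1 for g in target if g in sig_genes)
    observed_snp_count = int(counts[list(target)].sum())

    pool_gene_bin = gene_bin[~gene_bin.index.isin(target)] if exclude_target \
        else gene_bin
    null_gene = np.zeros(R, dtype=np.int64)
    null_snp = np.zeros(R, dtype=np.int64)
    for b, k in need.items():
        pool = pool_gene_bin.index[pool_gene_bin == b]
        if len(pool) == 0 or (not with_replacement and len(pool) < k):
            raise ValueError(
                f"bin {b} holds {len(pool)} genes but {k} draws are needed; "
                "use with_replacement=True")
        pool_sig = np.fromiter((g in sig_genes for g in pool), dtype=bool,
                               count=len(pool))
        pool_cnt = counts[pool].to_numpy()
        if with_replacement:
            draws = rng.integers(0, len(pool), size=(R, k))
        else:
            # k smallest of random keys = uniform draw without replacement
            keys = rng.random((R, len(pool)))
            draws = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null_gene += pool_sig[draws].sum(axis=1)
        null_snp += pool_cnt[draws].sum(axis=1)

    return EnrichmentResult(
        observed_gene_count=observed_gene_count,
        observed_snp_count=observed_snp_count,
        R=R,
        null_gene_counts=null_gene,
        null_snp_counts=null_snp,
        p_gene=_empirical_upper(null_gene, observed_gene_count),
        p_snp=_empirical_two_sided(null_snp, observed_snp_count),
        seed=seed,
    )


def genic_chisq(sig_snps, all_snps, maf: pd.Series, genic: pd.Series,
                maf_window: float = 0.01, seed: int = 0,
                continuity: bool = False
                ) -> tuple[float, float, np.ndarray]:
    """Chi-square for genic enrichment of significant SNPs vs MAF-matched
    controls.

    For every significant SNP one control is drawn uniformly from the
    non-significant SNPs whose MAF lies within ``maf_window`` of it.  The
    2x2 table (significant/control x genic/intergenic) is tested with
    Pearson's chi-square on 1 df, continuity correction off by default.

    Returns (chi2, p, table) with table rows = (significant, control) and
    columns = (genic, intergenic).
    """
    sig = list(sig_snps)
    if not sig:
        raise ValueError("no significant SNPs")
    rng = np.random.default_rng(seed)
    sig_set = set(sig)
    pool = [s for s in all_snps if s not in sig_set]
    pool_maf = maf[pool].to_numpy()
    order = np.argsort(pool_maf)
    pool_sorted = np.asarray(pool, dtype=object)[order]
    maf_sorted = pool_maf[order]

    controls = []
    empty = []
    for s in sig:
        m = maf[s]
        lo = np.searchsorted(maf_sorted, m - maf_window, side="left")
        hi = np.searchsorted(maf_sorted, m + maf_window, side="right")
        if hi <= lo:
            empty.append(s)
            continue
        controls.append(pool_sorted[lo + rng.integers(0, hi - lo)])
    if empty:
        raise ValueError(f"significant SNPs with no MAF-matched control: "
                         f"{empty[:10]}")

    g = genic.astype(bool)
    table = np.array([
        [int(g[sig].sum()), int((~g[sig]).sum())],
        [int(g[controls].sum()), int((~g[controls]).sum())],
    ])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(chi2), float(p), table
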