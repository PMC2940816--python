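"""Matched-resampling enrichment and the genic chi-square: binning,
determinism, empirical-p behaviour, matching and worked chi-square values."""

import numpy as np
import pandas as pd
import pytest

from helmscan import enrichment as enr


def _universe(counts):
    return pd.Series(counts, index=[f"g{i}" for i in range(len(counts))])


class TestBinning:
    def test_one_gene_per_bin(self):
        u = _universe(range(1, 25))
        bins = enr.bin_genes_by_snp_count(u, n_bins=24)
        assert bins.gene_bin.nunique() == 24
        assert bins.gene_bin.value_counts().eq(1).all()

    def test_all_same_count_single_bin(self):
        bins = enr.bin_genes_by_snp_count(_universe([7] * 30), n_bins=24)
        assert bins.n_effective == 1
        assert (bins.gene_bin == 0).all()

    def test_bimodal_counts_split_at_the_gap(self):
        u = _universe([1] * 100 + [50] * 100)
        bins = enr.bin_genes_by_snp_count(u, n_bins=2)
        assert (bins.gene_bin[u == 1] == 0).all()
        assert (bins.gene_bin[u == 50] == 1).all()

    def test_counts_fall_within_their_bin_edges(self):
        rng = np.random.default_rng(0)
        u = _universe(rng.geometric(0.15, 500))
        bins = enr.bin_genes_by_snp_count(u, n_bins=24)
        for g, b in bins.gene_bin.items():
            assert bins.bin_edges[b] <= u[g] < bins.bin_edges[b + 1]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enr.bin_genes_by_snp_count(pd.Series(dtype=int))


class TestResampling:
    def test_target_equals_universe_gives_p_one(self):
        u = _universe([3] * 40)
        bins = enr.bin_genes_by_snp_count(u, 24)
        res = enr.resample_enrichment(list(u.index), u, bins,
                                      sig_genes=["g0", "g1"], R=200, seed=1)
        # every resample is a permutation of the whole universe
        assert (res.null_gene_counts == res.observed_gene_count).all()
        assert res.p_gene == 1.0

    def test_no_significant_genes_gives_p_one(self):
        u = _universe([2] * 100)
        bins = enr.bin_genes_by_snp_count(u, 4)
        res = enr.resample_enrichment(list(u.index[:10]), u, bins,
                                      sig_genes=[], R=100, seed=2)
        assert res.observed_gene_count == 0
        assert (res.null_gene_counts == 0).all()
        assert res.p_gene == 1.0

    def test_same_seed_reproduces_null(self):
        rng = np.random.default_rng(3)
        u = _universe(rng.geometric(0.2, 300))
        bins = enr.bin_genes_by_snp_count(u, 10)
        sig = list(u.index[rng.random(300) < 0.1])
        target = list(u.index[:40])
        a = enr.resample_enrichment(target, u, bins, sig, R=300, seed=9)
        b = enr.resample_enrichment(target, u, bins, sig, R=300, seed=9)
        assert (a.null_gene_counts == b.null_gene_counts).all()
        assert (a.null_snp_counts == b.null_snp_counts).all()
        c = enr.resample_enrichment(target, u, bins, sig, R=300, seed=10)
        assert (a.null_gene_counts != c.null_gene_counts).any()

    def test_bin_matching_preserves_composition(self):
        """Drawn sets have the target's per-bin composition exactly: the
        null SNP totals are bounded by the per-bin count ranges."""
        u = _universe([1] * 50 + [10] * 50)
        bins = enr.bin_genes_by_snp_count(u, 2)
        target = list(u.index[:5]) + list(u.index[50:60])  # 5 low, 10 high
        res = enr.resample_enrichment(target, u, bins, sig_genes=[],
                                      R=200, seed=4)
        # all counts within a bin are equal here, so matching forces the
        # null SNP total to be exactly the observed one
        assert (res.null_snp_counts == res.observed_snp_count).all()

    def test_without_replacement_draws_are_distinct(self):
        u = _universe([4] * 10)
        bins = enr.bin_genes_by_snp_count(u, 1)
        # target of 9 genes in a 10-gene bin: only 10 possible draws each
        # resample; significant = 1 gene -> null count in {0, 1}
        res = enr.resample_enrichment(list(u.index[:9]), u, bins,
                                      sig_genes=["g9"], R=500, seed=5)
        assert set(np.unique(res.null_gene_counts)) <= {0, 1}
        # with 9 of 10 drawn, g9 appears in 90% of resamples
        assert 0.8 < res.null_gene_counts.mean() < 0.97

    def test_exhausted_bin_raises_and_replacement_flag_rescues(self):
        u = _universe([2] * 5)
        bins = enr.bin_genes_by_snp_count(u, 1)
        target = list(u.index)
        with pytest.raises(ValueError, match="with_replacement"):
            enr.resample_enrichment(target, u, bins, [], R=10, seed=6,
                                    exclude_target=True)
        res = enr.resample_enrichment(target, u, bins, [], R=10, seed=6,
                                      with_replacement=True)
        assert res.R == 10

    def test_p_gene_monotone_in_observed_count(self):
        null = np.array([0, 1, 1, 2, 3, 5])
        ps = [enr._empirical_upper(null, k) for k in range(6)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert ps[0] == 1.0


class TestGenicChisq:
    def _inputs(self, n_sig, genic_sig, genic_ctl):
        """One control available per significant SNP, each pair isolated
        in its own MAF window so the draw is deterministic."""
        sig = [f"sig{i}" for i in range(n_sig)]
        ctl = [f"ctl{i}" for i in range(n_sig)]
        maf = pd.Series({**{s: 0.011 * i + 0.005 for i, s in enumerate(sig)},
                         **{c: 0.011 * i + 0.005 for i, c in enumerate(ctl)}})
        genic = pd.Series({**{s: i < genic_sig for i, s in enumerate(sig)},
                           **{c: i < genic_ctl for i, c in enumerate(ctl)}})
        return sig, sig + ctl, maf, genic

    def test_balanced_table_gives_zero_chi2(self):
        sig, snps, maf, genic = self._inputs(40, 20, 20)
        chi2, p, table = enr.genic_chisq(sig, snps, maf, genic,
                                         maf_window=0.005)
        assert table.tolist() == [[20, 20], [20, 20]]
        assert chi2 == 0.0 and p == 1.0

    def test_worked_value_30_10_10_30(self):
        sig, snps, maf, genic = self._inputs(40, 30, 10)
        chi2, p, table = enr.genic_chisq(sig, snps, maf, genic,
                                         maf_window=0.005)
        assert table.tolist() == [[30, 10], [10, 30]]
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(7.7e-6, rel=0.02)

    def test_empty_control_window_names_snps(self):
        maf = pd.Series({"sig0": 0.4, "ctl0": 0.1})
        genic = pd.Series({"sig0": True, "ctl0": False})
        with pytest.raises(ValueError, match="sig0"):
            enr.genic_chisq(["sig0"], ["sig0", "ctl0"], maf, genic,
                            maf_window=0.01)

    def test_null_calibration_rejection_near_nominal(self):
        """Significance independent of genic status: the chi-square
        rejects at roughly its nominal level."""
        rng = np.random.default_rng(8)
        rej = 0
        reps = 150
        for _ in range(reps):
            n = 400
            snps = [f"s{i}" for i in range(n)]
            maf = pd.Series(rng.uniform(0.05, 0.5, n), index=snps)
            genic = pd.Series(rng.random(n) < 0.4, index=snps)
            sig = list(rng.choice(snps, size=60, replace=False))
            try:
                _, p, _ = enr.genic_chisq(sig, snps, maf, genic,
                                          seed=int(rng.integers(2**31)))
            except ValueError:
                continue
            rej += p < 0.05
        assert 0.01 <= rej / reps <= 0.11
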