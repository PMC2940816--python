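"""Genome scan: MAF folding, vectorised tau/p, the two significance gates
and the climate confounder re-test."""

import numpy as np
import pandas as pd
import pytest

from helmscan import kendall
from helmscan import scan as sm
from helmscan.scan import ScanConfig


def _freqs(rows, pops=None):
    rows = np.atleast_2d(np.asarray(rows, float))
    pops = pops or [f"p{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, columns=pops,
                        index=[f"s{i}" for i in range(rows.shape[0])])


def _env(values, pops=None):
    values = np.asarray(values, float)
    pops = pops or [f"p{i}" for i in range(len(values))]
    return pd.Series(values, index=pops)


@pytest.mark.parametrize("row,maf", [
    ((0.2, 0.4, 0.6), pytest.approx(0.4)),
    ((0.9, 0.8, 1.0), pytest.approx(0.1)),   # folding
    ((0.5,), 0.5),                           # upper bound
    ((0.2, np.nan, 0.4), pytest.approx(0.3)),  # missing ignored
])
def test_compute_maf(row, maf):
    assert sm.compute_maf(row) == maf


def test_compute_maf_all_missing_rejected():
    with pytest.raises(ValueError, match="missing"):
        sm.compute_maf([np.nan, np.nan])


class TestScan:
    # 12 populations in 6 countries -> env tied in pairs
    env = _env(np.repeat([1.0, 2, 3, 4, 5, 6], 2),
               pops=[f"p{i}" for i in range(12)])

    def test_monotone_snp_attains_maximum_given_ties(self):
        f = np.linspace(0.1, 0.9, 12)  # strictly increasing with env
        rec = sm.scan(_freqs([f], pops=list(self.env.index)), self.env,
                      ScanConfig(min_n=11))
        # every non-env-tied pair concordant: the tau-b ceiling for a
        # tie-free frequency vector is sqrt((n0 - n2) / n0)
        n0 = 12 * 11 // 2
        n2 = 6  # six countries, one tied pair each
        assert rec["tau"].iloc[0] == pytest.approx(
            np.sqrt((n0 - n2) / n0))
        r = kendall.kendall_tau_b(f, self.env.to_numpy())
        assert rec["tau"].iloc[0] == pytest.approx(r.tau)

    def test_complementary_rows_same_tau_abs_opposite_orientation(self):
        f = np.linspace(0.1, 0.9, 12)
        rec = sm.scan(_freqs([f, 1 - f], pops=list(self.env.index)),
                      self.env, ScanConfig())
        assert rec["tau_abs"].iloc[0] == pytest.approx(rec["tau_abs"].iloc[1])
        assert rec["p"].iloc[0] == pytest.approx(rec["p"].iloc[1])
        assert {"ref", "alt"} == set(rec["orientation"])

    def test_constant_row_degenerate(self):
        rec = sm.scan(_freqs([np.full(12, 0.3)], pops=list(self.env.index)),
                      self.env, ScanConfig())
        assert bool(rec["degenerate"].iloc[0])
        assert rec["p"].iloc[0] == 1.0

    def test_vectorised_path_matches_scalar_kendall(self):
        rng = np.random.default_rng(0)
        F = _freqs(rng.uniform(0, 1, (50, 12)), pops=list(self.env.index))
        rec = sm.scan(F, self.env, ScanConfig())
        y = self.env.to_numpy()
        for i in [0, 17, 49]:
            r = kendall.tau_pvalue_normal(
                kendall.kendall_tau_b(F.iloc[i].to_numpy(), y))
            assert rec["tau"].iloc[i] == pytest.approx(r.tau, abs=1e-12)
            assert rec["p"].iloc[i] == pytest.approx(r.p, abs=1e-12)

    def test_missing_values_pairwise_deletion(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0, 1, 12)
        f_nan = f.copy()
        f_nan[3] = np.nan
        F = _freqs([f_nan], pops=list(self.env.index))
        rec = sm.scan(F, self.env, ScanConfig(min_n=11))
        ok = ~np.isnan(f_nan)
        r = kendall.tau_pvalue_normal(
            kendall.kendall_tau_b(f_nan[ok], self.env.to_numpy()[ok]))
        assert rec["n_used"].iloc[0] == 11
        assert rec["tau"].iloc[0] == pytest.approx(r.tau)

    def test_low_n_flagged_untested(self):
        f = np.full(12, np.nan)
        f[:5] = [0.1, 0.2, 0.3, 0.4, 0.5]
        rec = sm.scan(_freqs([f], pops=list(self.env.index)), self.env,
                      ScanConfig(min_n=11))
        assert not bool(rec["tested"].iloc[0])

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        F = _freqs(rng.uniform(0, 1, (30, 12)), pops=list(self.env.index))
        a = sm.scan(F, self.env, ScanConfig())
        perm_snps = rng.permutation(F.index)
        perm_pops = rng.permutation(F.columns)
        b = sm.scan(F.loc[perm_snps, perm_pops], self.env, ScanConfig())
        pd.testing.assert_frame_equal(a.loc[perm_snps], b,
                                      check_like=True)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sm.scan(_freqs([[0.1, 0.2, 0.3]], pops=["a", "b", "c"]),
                    _env([1, 2, 3], pops=["x", "y", "z"]))


class TestPercentileGate:
    def _records(self, maf, tau_abs):
        n = len(maf)
        return pd.DataFrame({
            "n_used": 12, "tau": tau_abs, "tau_abs": tau_abs,
            "orientation": "ref", "p": 0.5, "maf": maf,
            "degenerate": False, "tested": True,
        }, index=[f"s{i}" for i in range(n)])

    def test_strictly_largest_in_window_passes(self):
        rng = np.random.default_rng(3)
        tau = rng.uniform(0, 0.5, 100)
        tau[17] = 0.99
        rec = sm.maf_matched_percentile(
            self._records(np.full(100, 0.25), tau), ScanConfig())
        assert bool(rec["pass_percentile"].iloc[17])
        assert rec["percentile_rank"].iloc[17] == 1.0

    def test_all_equal_tau_cannot_pass(self):
        rec = sm.maf_matched_percentile(
            self._records(np.full(50, 0.25), np.full(50, 0.3)), ScanConfig())
        assert not rec["pass_percentile"].any()

    def test_singleton_window_cannot_pass(self):
        rec = sm.maf_matched_percentile(
            self._records(np.array([0.05, 0.45]), np.array([0.9, 0.1])),
            ScanConfig())
        assert not rec["pass_percentile"].any()

    def test_window_is_maf_local(self):
        # two well-separated MAF clusters judged independently
        maf = np.concatenate([np.full(20, 0.1), np.full(20, 0.4)])
        tau = np.concatenate([np.linspace(0, 0.2, 20),
                              np.linspace(0.5, 0.9, 20)])
        rec = sm.maf_matched_percentile(self._records(maf, tau), ScanConfig())
        low = rec.iloc[:20]
        high = rec.iloc[20:]
        # top of each cluster passes within its own window
        assert bool(low["pass_percentile"].iloc[19])
        assert bool(high["pass_percentile"].iloc[19])
        # strong-but-not-top high-cluster SNPs fail despite dwarfing the
        # low cluster
        assert not high["pass_percentile"].iloc[:17].any()

    def test_iid_pass_fraction_near_five_percent(self):
        rng = np.random.default_rng(4)
        rec = sm.maf_matched_percentile(
            self._records(np.full(2000, 0.3), rng.uniform(0, 1, 2000)),
            ScanConfig())
        frac = rec["pass_percentile"].mean()
        assert 0.04 <= frac <= 0.06


def test_bonferroni_threshold_values():
    assert sm.bonferroni_threshold(1, 0.05) == 0.05
    assert sm.bonferroni_threshold(100, 0.01) == pytest.approx(1e-4)
    with pytest.raises(ValueError):
        sm.bonferroni_threshold(0, 0.05)


def test_call_significant_is_conjunction_of_gates():
    rec = pd.DataFrame({
        "n_used": 12, "tau": [0.9, 0.9, 0.2],
        "tau_abs": [0.9, 0.9, 0.2], "orientation": "ref",
        "p": [1e-9, 0.5, 1e-9], "maf": 0.3,
        "degenerate": False, "tested": True,
        "percentile_rank": [1.0, 1.0, 0.2],
        "pass_percentile": [True, True, False],
    }, index=["both", "pct_only", "bonf_only"])
    out, summary = sm.call_significant(rec, ScanConfig(alpha=0.05), m=3)
    assert out["significant"].to_dict() == {
        "both": True, "pct_only": False, "bonf_only": False}
    assert summary["n_significant"] == 1


def test_allele_relabelling_leaves_gates_unchanged():
    rng = np.random.default_rng(5)
    env = _env(np.repeat(np.arange(6.0), 2))
    F = _freqs(rng.uniform(0, 1, (200, 12)), pops=list(env.index))
    flip = rng.random(200) < 0.5
    F2 = F.copy()
    F2.iloc[flip] = 1 - F2.iloc[flip]
    a, _ = sm.call_significant(
        sm.maf_matched_percentile(sm.scan(F, env), ScanConfig()))
    b, _ = sm.call_significant(
        sm.maf_matched_percentile(sm.scan(F2, env), ScanConfig()))
    for col in ["tau_abs", "p", "maf", "pass_percentile", "pass_bonferroni",
                "significant"]:
        assert (a[col] == b[col]).all() or \
            np.allclose(a[col].astype(float), b[col].astype(float))


def test_drift_null_p_is_anticonservative():
    """Shared country drift makes per-SNP p stochastically smaller than
    uniform — the documented reason the percentile gate exists."""
    from helmscan.simulate import SimConfig, simulate_dataset
    cfg = SimConfig(n_snps=2000, n_selected=0, seed=11)
    ds = simulate_dataset(cfg)
    rec = sm.scan(ds.freqs, ds.pop_env, ScanConfig())
    p = rec["p"].to_numpy()
    assert (p < 0.05).mean() > 0.10      # far above the nominal 5%
    assert np.median(p) < 0.35


class TestClimateConfound:
    def _setup(self):
        rng = np.random.default_rng(6)
        env = _env(np.repeat(np.arange(1.0, 7), 2))
        F = _freqs(rng.uniform(0, 1, (20, 12)), pops=list(env.index))
        # make 3 SNPs track env tightly
        for i in range(3):
            F.iloc[i] = np.clip(env.to_numpy() / 10.0
                                + rng.normal(0, 0.01, 12), 0, 1)
        return F, env

    def test_identical_climate_reproduces_scan_p(self):
        F, env = self._setup()
        rec = sm.scan(F, env, ScanConfig())
        sig = list(F.index[:3])
        out = sm.climate_confound_check(sig, F, {"same": env}, alpha=0.05)
        for snp in sig:
            assert out.loc[out["snp"] == snp, "p"].iloc[0] == \
                pytest.approx(rec.loc[snp, "p"])

    def test_permuted_climate_rarely_passes(self):
        F, env = self._setup()
        rng = np.random.default_rng(7)
        # permute at the country level, keeping the tie structure
        vals = env.to_numpy().reshape(6, 2)
        perm = rng.permutation(6)
        climate = _env(vals[perm].ravel(), pops=list(env.index))
        out = sm.climate_confound_check(list(F.index[:3]), F,
                                        {"permuted": climate}, alpha=0.05)
        assert not out["pass"].any()

    def test_constant_climate_all_degenerate(self):
        F, env = self._setup()
        climate = _env(np.full(12, 7.0), pops=list(env.index))
        out = sm.climate_confound_check(list(F.index[:3]), F,
                                        {"const": climate}, alpha=0.05)
        assert not out["pass"].any()
        assert (out["p"] == 1.0).all()

    def test_empty_significant_set_rejected(self):
        F, env = self._setup()
        with pytest.raises(ValueError):
            sm.climate_confound_check([], F, {"e": env})
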