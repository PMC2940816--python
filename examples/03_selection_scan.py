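"""Genome scan on a synthetic panel with planted environment-tracking SNPs.

Simulates 10 countries x 5 populations with 5,000 neutral SNPs under
Balding-Nichols drift plus 25 planted SNPs whose frequency follows a
logistic function of the environmental gradient, then applies the
two-gate significance call (Bonferroni + MAF-matched 95th percentile).
"""

from helmscan.scan import ScanConfig, call_significant, \
    maf_matched_percentile, scan
from helmscan.simulate import SimConfig, simulate_dataset

cfg = SimConfig(n_snps=5_000, n_selected=25, seed=11)
ds = simulate_dataset(cfg)
print(f"panel: {ds.freqs.shape[0]} SNPs x {ds.freqs.shape[1]} populations "
      f"in {cfg.n_countries} countries, beta = {cfg.beta}")

sc = ScanConfig()
records = scan(ds.freqs, ds.pop_env, sc)
records = maf_matched_percentile(records, sc)
records, summary = call_significant(records, sc)

print(f"\nBonferroni threshold: {summary['bonferroni_threshold']:.3e}")
print(f"pass Bonferroni:      {summary['n_pass_bonferroni']}")
print(f"pass 95th percentile: {summary['n_pass_percentile']}")
print(f"significant (both):   {summary['n_significant']}")

sel = ds.truth["selected"]
sig = records["significant"]
tp = int((sel & sig).sum())
print(f"\nplanted SNPs recovered: {tp}/{int(sel.sum())} "
      f"(sensitivity {tp / sel.sum():.2f})")
print(f"neutral SNPs called:    {int((~sel & sig).sum())}")
print("Shared country drift inflates neutral correlations, so a scan "
      "hit is a candidate, not proof of selection — the percentile gate "
      "bounds the per-window call rate at 5%, it does not uninflate p.")

top = records[sig].nlargest(3, "tau_abs")
print("\nstrongest hits (snp, |tau|, p, maf):")
for snp, row in top.iterrows():
    print(f"  {snp}  {row['tau_abs']:.3f}  {row['p']:.2e}  "
          f"{row['maf']:.3f}")
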