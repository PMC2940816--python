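"""Stage orchestration: reproducible scan / enrichment runs over files.

Each stage reads the plain-text interchange formats, runs the library, and
writes its outputs together with a JSON manifest recording the input
checksums, the configuration and the seed, so a run can be audited and
reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, asdict, replace
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd

from . import io as hio
from . import enrichment as enr
from . import genemap
from . import pathogen_env as penv
from . import scan as scanmod
from .simulate import SimConfig, simulate_dataset, write_dataset

__all__ = ["RunConfig", "run_simulate", "run_scan", "run_enrich", "run_all"]

log = logging.getLogger("helmscan")


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters for one pipeline run.  Flags beat config files;
    a missing optional stage input simply disables that stage."""

    frequencies: str
    populations: str
    env: str
    out_dir: str
    genes: str | None = None
    snp_loci: str | None = None
    gene_set: str | None = None
    truth: str | None = None
    alpha: float = 0.05
    maf_window: float = 0.01
    percentile: float = 0.95
    min_n: int = 11
    resamples: int = 10_000
    n_bins: int = 24
    with_replacement: bool = False
    exclude_target: bool = False
    upstream_scan: int = 500      # SNP-to-gene rule for scan reporting
    upstream_sets: int = 25_000   # SNP-to-gene rule for gene-set analyses
    seed: int = 0

    def scan_config(self) -> scanmod.ScanConfig:
        return scanmod.ScanConfig(alpha=self.alpha,
                                  maf_window=self.maf_window,
                                  percentile=self.percentile,
                                  min_n=self.min_n)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _manifest(cfg: RunConfig, out_path, stage: str, **extra) -> None:
    inputs = {}
    for name in ("frequencies", "populations", "env", "genes", "snp_loci",
                 "gene_set", "truth"):
        p = getattr(cfg, name)
        if p and Path(p).exists():
            inputs[name] = {"path": str(p), "sha256": _sha256(p)}
    try:
        ver = _pkg_version("helmscan")
    except Exception:
        ver = "unknown"
    hio.write_manifest(out_path, stage=stage, version=ver, seed=cfg.seed,
                       config=asdict(cfg), inputs=inputs, **extra)


def run_simulate(sim_cfg: SimConfig, out_dir) -> dict[str, str]:
    """Generate a synthetic dataset directory (see simulate module)."""
    ds = simulate_dataset(sim_cfg)
    paths = write_dataset(ds, out_dir)
    log.info("simulated %d SNPs (%d selected) for %d populations -> %s",
             len(ds.freqs), int(ds.truth["selected"].sum()),
             ds.freqs.shape[1], out_dir)
    return paths


def run_scan(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Scan + gates; writes scan.tsv and scan_summary.json."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    freqs = hio.read_frequency_matrix(cfg.frequencies)
    pops = hio.read_population_table(cfg.populations)
    env = hio.read_env(cfg.env)
    pop_env = penv.broadcast_to_populations(env, pops)

    sc = cfg.scan_config()
    records = scanmod.scan(freqs, pop_env, sc)
    records = scanmod.maf_matched_percentile(records, sc)
    records, summary = scanmod.call_significant(records, sc)
    log.info("scan: %d SNPs, %d tested, %d pass Bonferroni, %d pass "
             "percentile, %d significant", summary["n_snps"],
             summary["n_tested"], summary["n_pass_bonferroni"],
             summary["n_pass_percentile"], summary["n_significant"])

    nearest = None
    if cfg.genes and cfg.snp_loci:
        genes = hio.read_genes_bed(cfg.genes)
        loci = hio.read_snp_loci(cfg.snp_loci)
        assignments = genemap.assign_snps(loci, genes, cfg.upstream_scan)
        sig_genes = genemap.genes_with_significant(
            assignments, records["significant"])
        summary["n_significant_genes"] = len(sig_genes)
        nearest = {}
        for s in loci:
            ng = genemap.nearest_gene(s, genes)
            if ng is not None:
                nearest[s.snp_id] = ng
        log.info("scan: significant SNPs map to %d distinct genes "
                 "(upstream %d bp)", len(sig_genes), cfg.upstream_scan)

    hio.write_scan_table(records, out / "scan.tsv", nearest=nearest)
    _manifest(cfg, out / "scan_summary.json", "scan", summary=summary)
    return records, summary


def run_enrich(cfg: RunConfig, records: pd.DataFrame | None = None
               ) -> dict:
    """Matched-resampling gene-set enrichment plus the genic chi-square."""
    if not (cfg.genes and cfg.snp_loci and cfg.gene_set):
        raise ValueError("enrichment needs genes, snp_loci and gene_set")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if records is None:
        records, _ = run_scan(cfg)

    genes = hio.read_genes_bed(cfg.genes)
    loci = hio.read_snp_loci(cfg.snp_loci)
    target = hio.read_gene_set(cfg.gene_set)

    assignments = genemap.assign_snps(loci, genes, cfg.upstream_sets)
    counts: dict[str, int] = {}
    for snp, gs in assignments.items():
        for g in gs:
            counts[g] = counts.get(g, 0) + 1
    universe = pd.Series(counts, name="snp_count").sort_index()
    target_in = [g for g in target if g in universe.index]
    sig_genes = genemap.genes_with_significant(
        assignments, records["significant"])

    bins = enr.bin_genes_by_snp_count(universe, cfg.n_bins)
    res = enr.resample_enrichment(
        target_in, universe, bins, sig_genes,
        R=cfg.resamples, seed=cfg.seed,
        with_replacement=cfg.with_replacement,
        exclude_target=cfg.exclude_target)

    genic = genemap.classify_genic(loci, genes, cfg.upstream_scan)
    sig_snps = records.index[records["significant"]].tolist()
    chisq = None
    if sig_snps:
        chi2, p_chi, table = enr.genic_chisq(
            sig_snps, records.index.tolist(), records["maf"], genic,
            maf_window=cfg.maf_window, seed=cfg.seed)
        chisq = {"chi2": chi2, "p": p_chi, "table": table.tolist()}

    report = {
        "target_size": len(target_in),
        "universe_size": int(len(universe)),
        "n_bins_effective": bins.n_effective,
        "observed_gene_count": res.observed_gene_count,
        "observed_snp_count": res.observed_snp_count,
        "R": res.R,
        "p_gene": res.p_gene,
        "p_snp": res.p_snp,
        "genic_chisq": chisq,
    }
    log.info("enrichment: %d/%d target genes significant, p_gene = %.4g, "
             "p_snp = %.4g", res.observed_gene_count, len(target_in),
             res.p_gene, res.p_snp)
    pd.DataFrame({"null_gene_counts": res.null_gene_counts,
                  "null_snp_counts": res.null_snp_counts}).to_csv(
        out / "enrichment_null.tsv", sep="\t", index=False)
    _manifest(cfg, out / "enrichment.json", "enrich", report=report)
    return report


def run_all(cfg: RunConfig) -> dict:
    """Scan, confounder-free significance call, enrichment, and (when a
    truth table is supplied) a truth-vs-called confusion matrix."""
    records, summary = run_scan(cfg)
    report: dict = {"scan": summary}
    if cfg.gene_set:
        report["enrichment"] = run_enrich(cfg, records=records)
    if cfg.truth:
        truth = pd.read_csv(cfg.truth, sep="\t").set_index("snp")
        t = truth["selected"].astype(bool).reindex(records.index)
        s = records["significant"].astype(bool)
        report["confusion"] = {
            "tp": int((t & s).sum()), "fp": int((~t & s).sum()),
            "fn": int((t & ~s).sum()), "tn": int((~t & ~s).sum()),
        }
        cm = report["confusion"]
        log.info("truth: TP=%d FP=%d FN=%d TN=%d", cm["tp"], cm["fp"],
                 cm["fn"], cm["tn"])
    _manifest(cfg, Path(cfg.out_dir) / "report.json", "all", report=report)
    return report
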