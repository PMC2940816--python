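"""Synthetic multi-country SNP panels with known truth.

The generator emulates the structure the scan is built for: a worldwide
panel of populations nested in countries, a country-level environmental
gradient (tied across a country's populations by construction), and SNP
allele frequencies shaped by hierarchical drift, with a small planted
fraction of SNPs whose frequency tracks the environment.

Drift follows the Balding-Nichols model: a SNP with ancestral frequency p0
draws a country frequency from Beta(p0(1-F)/F, (1-p0)(1-F)/F) with
dispersion F_country, and each population frequency from the same law
around its country frequency with F_pop.  Shared country-level draws make
populations of one country correlated, which — combined with the smooth
environmental gradient — inflates neutral |tau| above the independence
null; this is exactly the inflation the MAF-matched percentile gate
corrects for, and the reason the generator exists.

Selected SNPs replace the country frequency by a logistic dose-response
logistic(a + beta * z) in the standardised environment z, with a random
intercept a ~ Uniform(-1, 1), then add population-level drift as usual.

Defaults (10 countries x 5 populations, 20,000 neutral + 50 selected SNPs,
F_country = 0.05, F_pop = 0.01, beta = 8) give a panel of roughly HGDP-like
structure at a desk-scale SNP count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .genemap import GeneModel, SnpLocus, assign_snps

__all__ = [
    "SimConfig", "SyntheticDataset",
    "simulate_neutral_freqs", "simulate_selected_freqs",
    "simulate_annotation", "simulate_dataset", "write_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    n_countries: int = 10
    pops_per_country: int = 5
    n_snps: int = 20_000          # neutral SNPs
    n_selected: int = 50          # planted environment-tracking SNPs
    F_country: float = 0.05
    F_pop: float = 0.01
    beta: float = 8.0
    env_values: tuple[float, ...] | None = None  # default integer gradient
    n_genes: int = 2_000
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    chrom_length: int = 200_000_000
    target_set_size: int = 200
    target_enrichment_odds: float = 1.0
    target_upstream_bp: int = 25_000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.F_country < 1 and 0 < self.F_pop < 1):
            raise ValueError("F parameters must lie in (0, 1)")
        if self.n_selected > self.n_snps + self.n_selected:
            raise ValueError("n_selected exceeds total SNPs")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must be 0 < lo <= hi")
        if self.env_values is not None \
                and len(self.env_values) != self.n_countries:
            raise ValueError("env_values length must equal n_countries")

    def env(self) -> np.ndarray:
        if self.env_values is not None:
            return np.asarray(self.env_values, dtype=float)
        # integer "diversity-like" gradient, one value per country
        return np.arange(1, self.n_countries + 1, dtype=float)


@dataclass
class SyntheticDataset:
    cfg: SimConfig
    pops: pd.DataFrame            # population, country
    env: pd.Series                # country -> value
    freqs: pd.DataFrame           # SNP x population
    truth: pd.DataFrame           # per SNP: selected, p0, slope
    genes: list[GeneModel]
    loci: list[SnpLocus]
    gene_sets: dict[str, list[str]] = field(default_factory=dict)

    @property
    def pop_env(self) -> pd.Series:
        out = self.pops.set_index("population")["country"].map(self.env)
        out.name = self.env.name
        return out.astype(float)


def _balding_nichols(p: np.ndarray, F: float, size, rng) -> np.ndarray:
    c = (1.0 - F) / F
    return rng.beta(np.maximum(p * c, 1e-12),
                    np.maximum((1.0 - p) * c, 1e-12), size=size)


def simulate_neutral_freqs(cfg: SimConfig, rng: np.random.Generator,
                           n_snps: int | None = None) -> np.ndarray:
    """Neutral SNP x population frequencies under two-level drift.

    Ancestral p0 ~ Uniform(0.05, 0.95); country frequencies are
    Balding-Nichols around p0 with F_country; population frequencies are
    Balding-Nichols around their country with F_pop.  Returns an array of
    shape (n_snps, n_countries * pops_per_country); populations are ordered
    country-major.
    """
    m = cfg.n_snps if n_snps is None else n_snps
    nc, k = cfg.n_countries, cfg.pops_per_country
    p0 = rng.uniform(0.05, 0.95, size=m)
    pc = _balding_nichols(p0[:, None], cfg.F_country, (m, nc), rng)
    pp = _balding_nichols(np.repeat(pc, k, axis=1), cfg.F_pop,
                          (m, nc * k), rng)
    return pp


def simulate_selected_freqs(cfg: SimConfig, env: np.ndarray,
                            rng: np.random.Generator,
                            n_snps: int | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Environment-tracking SNP frequencies plus their intercepts.

    Country mean = logistic(a + beta * z(env)), a ~ Uniform(-1, 1), z the
    standardised environment; population frequencies add Balding-Nichols
    noise with F_pop.  With beta = 0 this reduces exactly to the neutral
    model with p0 = logistic(a).
    """
    m = cfg.n_selected if n_snps is None else n_snps
    nc, k = cfg.n_countries, cfg.pops_per_country
    z = (env - env.mean()) / env.std() if env.std() > 0 else env * 0.0
    a = rng.uniform(-1.0, 1.0, size=m)
    logit = a[:, None] + cfg.beta * z[None, :]
    pc = 1.0 / (1.0 + np.exp(-logit))
    pp = _balding_nichols(np.repeat(pc, k, axis=1), cfg.F_pop,
                          (m, nc * k), rng)
    return pp, a


def simulate_annotation(cfg: SimConfig, rng: np.random.Generator,
                        n_snps: int) -> tuple[list[GeneModel],
                                              list[SnpLocus]]:
    """Non-overlapping genes and uniform SNP positions on one chromosome.

    Genes are placed by distributing the free space between them uniformly
    (order statistics of uniform draws); strands are random.
    """
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    total = int(lengths.sum())
    free = cfg.chrom_length - total
    if free < 0:
        raise ValueError(
            f"genes need {total} bp but chromosome is {cfg.chrom_length} bp")
    offsets = np.sort(rng.integers(0, free + 1, size=cfg.n_genes))
    starts = offsets + np.concatenate(([0], np.cumsum(lengths[:-1])))
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    width = len(str(cfg.n_genes))
    genes = [GeneModel(gene_id=f"g{i + 1:0{width}d}", chrom="chr1",
                       tx_start=int(s), tx_end=int(s + L), strand=st)
             for i, (s, L, st) in enumerate(zip(starts, lengths, strands))]
    wsnp = len(str(n_snps))
    pos = rng.integers(0, cfg.chrom_length, size=n_snps)
    loci = [SnpLocus(snp_id=f"snp{i + 1:0{wsnp}d}", chrom="chr1", pos=int(q))
            for i, q in enumerate(pos)]
    return genes, loci


def _weighted_sample_without_replacement(weights: np.ndarray, k: int,
                                         rng) -> np.ndarray:
    # Efraimidis-Spirakis: top-k of u^(1/w)
    u = rng.random(len(weights))
    keys = np.power(u, 1.0 / np.maximum(weights, 1e-300))
    return np.argpartition(-keys, k - 1)[:k] if k > 0 \
        else np.empty(0, dtype=int)


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate the full dataset: panel, environment, frequencies,
    annotation, target gene set and truth labels.

    One seeded generator drives everything, so identical configs produce
    identical datasets.  Selected SNPs are chosen among all loci with odds
    ``target_enrichment_odds : 1`` in favour of loci assignable (under the
    ``target_upstream_bp`` rule) to a target-set gene, which plants the
    enrichment signal the resampling test is meant to recover.
    """
    rng = np.random.default_rng(cfg.seed)
    nc, k = cfg.n_countries, cfg.pops_per_country
    countries = [f"c{i + 1:02d}" for i in range(nc)]
    pops = pd.DataFrame({
        "population": [f"p{c + 1:02d}_{j + 1:02d}"
                       for c in range(nc) for j in range(k)],
        "country": [countries[c] for c in range(nc) for j in range(k)],
    })
    env = pd.Series(cfg.env(), index=pd.Index(countries, name="country"),
                    name="diversity")

    m_total = cfg.n_snps + cfg.n_selected
    genes, loci = simulate_annotation(cfg, rng, m_total)

    gene_ids = [g.gene_id for g in genes]
    target = sorted(rng.choice(gene_ids, size=cfg.target_set_size,
                               replace=False))
    target_set = set(target)

    assignment = assign_snps(loci, genes, upstream_bp=cfg.target_upstream_bp)
    in_target = np.array([bool(assignment[s.snp_id] & target_set)
                          for s in loci])
    weights = np.where(in_target, cfg.target_enrichment_odds, 1.0)
    sel_idx = np.sort(_weighted_sample_without_replacement(
        weights, cfg.n_selected, rng))
    selected = np.zeros(m_total, dtype=bool)
    selected[sel_idx] = True

    freqs = np.empty((m_total, nc * k))
    p0 = np.full(m_total, np.nan)
    slope = np.zeros(m_total)
    neutral_rows = simulate_neutral_freqs(cfg, rng, n_snps=int(
        (~selected).sum()))
    freqs[~selected] = neutral_rows
    if cfg.n_selected > 0:
        sel_rows, a = simulate_selected_freqs(cfg, env.to_numpy(), rng)
        freqs[selected] = sel_rows
        slope[selected] = cfg.beta
        p0[selected] = 1.0 / (1.0 + np.exp(-a))

    snp_ids = [s.snp_id for s in loci]
    freq_df = pd.DataFrame(freqs, index=pd.Index(snp_ids, name="snp"),
                           columns=pops["population"].to_list())
    truth = pd.DataFrame({
        "selected": selected,
        "p0": p0,
        "slope": slope,
    }, index=pd.Index(snp_ids, name="snp"))

    return SyntheticDataset(cfg=cfg, pops=pops, env=env, freqs=freq_df,
                            truth=truth, genes=genes, loci=loci,
                            gene_sets={"target": list(target)})


def write_dataset(ds: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write every interchange file plus a JSON manifest; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "frequencies": out / "frequencies.tsv",
        "populations": out / "populations.tsv",
        "env": out / "env.tsv",
        "genes": out / "genes.bed",
        "snp_loci": out / "snp_loci.tsv",
        "truth": out / "truth.tsv",
    }
    hio.write_frequency_matrix(ds.freqs, paths["frequencies"])
    hio.write_population_table(ds.pops, paths["populations"])
    hio.write_env(ds.env, paths["env"])
    hio.write_genes_bed(ds.genes, paths["genes"])
    hio.write_snp_loci(ds.loci, paths["snp_loci"])
    ds.truth.to_csv(paths["truth"], sep="\t")
    for name, members in ds.gene_sets.items():
        p = out / f"geneset_{name}.txt"
        hio.write_gene_set(members, p)
        paths[f"geneset_{name}"] = p
    hio.write_manifest(out / "manifest.json",
                       config=asdict(ds.cfg), seed=ds.cfg.seed,
                       files={k: str(v.name) for k, v in paths.items()})
    paths["manifest"] = out / "manifest.json"
    return {k: str(v) for k, v in paths.items()}
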