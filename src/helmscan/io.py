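"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are tab-separated with headers; gene models travel as BED6
(0-based half-open); gene sets are one gene_id per line.  The presence
matrix encodes cells as 0 (absent), 1 (present) or R (present but rare /
no prevalence estimate).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genemap import GeneModel, SnpLocus
from .pathogen_env import PresenceMatrix

__all__ = [
    "read_presence_matrix", "write_presence_matrix",
    "read_surveys", "read_env", "write_env",
    "read_population_table", "write_population_table",
    "read_frequency_matrix", "write_frequency_matrix",
    "read_genes_bed", "write_genes_bed",
    "read_snp_loci", "write_snp_loci",
    "read_gene_set", "write_gene_set",
    "write_scan_table", "write_manifest",
    "load_curated_presence",
]


def load_curated_presence() -> "PresenceMatrix":
    """Packaged synthetic curation of helminth transmission.

    A synthetic stand-in for a manually curated species x country
    presence/absence matrix (the original curation source is a proprietary
    epidemiology database): 60 real helminth species/genera across 21
    countries hosting a worldwide population panel, each species
    transmitted in at least one country, with a tropical-skewed richness
    pattern and per-cell rare/no-estimate flags.
    """
    from importlib.resources import files
    path = files("helmscan.data") / "helminth_presence_synthetic.tsv"
    return read_presence_matrix(str(path))


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except Exception as exc:  # name the file in the error
        raise ValueError(f"failed to read {path}: {exc}") from exc


def read_presence_matrix(path) -> PresenceMatrix:
    """Species x country matrix with cells in {0, 1, R}."""
    df = _read_tsv(path, dtype=str).set_index("species")
    cells = df.apply(lambda c: c.str.strip().str.upper())
    valid = cells.isin(["0", "1", "R"])
    if not valid.all().all():
        bad = cells.where(~valid).stack().head(3)
        raise ValueError(f"{path}: invalid presence cells (want 0/1/R): "
                         f"{bad.to_dict()}")
    present = cells.isin(["1", "R"])
    rare = cells == "R"
    present.index = present.index.str.strip()
    present.columns = present.columns.str.strip()
    rare.index = present.index
    rare.columns = present.columns
    return PresenceMatrix(present=present, rare=rare)


def write_presence_matrix(pm: PresenceMatrix, path) -> None:
    cells = pm.present.astype(int).astype(str).where(~pm.rare, "R")
    cells.index.name = "species"
    cells.to_csv(path, sep="\t")


def read_surveys(path) -> pd.DataFrame:
    """Prevalence survey records: country, species, prevalence, hiv."""
    df = _read_tsv(path)
    need = {"country", "species", "prevalence", "hiv"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: survey table needs columns {sorted(need)}")
    df["prevalence"] = df["prevalence"].astype(float)
    df["hiv"] = df["hiv"].map(
        {"1": True, "0": False, 1: True, 0: False, True: True, False: False,
         "T": True, "F": False, "true": True, "false": False})
    if df["hiv"].isna().any():
        raise ValueError(f"{path}: hiv column must be 0/1")
    return df


def read_env(path) -> pd.Series:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: env table needs `country value` columns")
    s = df.set_index(df.columns[0])[df.columns[1]].astype(float)
    s.index.name = "country"
    return s


def write_env(env: pd.Series, path) -> None:
    env.rename("value").rename_axis("country").to_csv(path, sep="\t")


def read_population_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if not {"population", "country"} <= set(df.columns):
        raise ValueError(f"{path}: needs `population country [lat lon]`")
    if df["population"].duplicated().any():
        raise ValueError(f"{path}: duplicate population labels")
    return df


def write_population_table(pops: pd.DataFrame, path) -> None:
    pops.to_csv(path, sep="\t", index=False)


def read_frequency_matrix(path) -> pd.DataFrame:
    df = _read_tsv(path).set_index("snp")
    out = df.astype(float)
    vals = out.to_numpy()
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError(f"{path}: frequencies outside [0, 1]")
    return out


def write_frequency_matrix(freqs: pd.DataFrame, path) -> None:
    # default float repr round-trips float64 exactly
    freqs.rename_axis("snp").to_csv(path, sep="\t")


def read_genes_bed(path) -> list[GeneModel]:
    """BED6: chrom start end gene_id score strand."""
    genes = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise ValueError(f"{path}:{ln}: BED6 needs 6 columns")
        genes.append(GeneModel(gene_id=f[3], chrom=f[0],
                               tx_start=int(f[1]), tx_end=int(f[2]),
                               strand=f[5]))
    return genes


def write_genes_bed(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}"
                     f"\t0\t{g.strand}\n")


def read_snp_loci(path) -> list[SnpLocus]:
    df = _read_tsv(path)
    if not {"snp", "chrom", "pos"} <= set(df.columns):
        raise ValueError(f"{path}: needs `snp chrom pos` columns")
    return [SnpLocus(snp_id=r.snp, chrom=r.chrom, pos=int(r.pos))
            for r in df.itertuples()]


def write_snp_loci(snps: list[SnpLocus], path) -> None:
    pd.DataFrame({"snp": [s.snp_id for s in snps],
                  "chrom": [s.chrom for s in snps],
                  "pos": [s.pos for s in snps]}).to_csv(path, sep="\t",
                                                        index=False)


def read_gene_set(path) -> list[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [ln for ln in lines if ln and not ln.startswith("#")]


def write_gene_set(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_scan_table(records: pd.DataFrame, path,
                     nearest: dict[str, tuple[str, int]] | None = None
                     ) -> None:
    """Scan output TSV: snp tau p maf percentile_rank significant
    [gene distance]."""
    out = records.copy()
    cols = ["tau", "p", "maf", "percentile_rank", "significant"]
    cols = [c for c in cols if c in out.columns]
    out = out[cols]
    if nearest is not None:
        out["gene"] = [nearest.get(s, ("NA", -1))[0] for s in out.index]
        out["distance"] = [nearest.get(s, ("NA", -1))[1] for s in out.index]
    out.rename_axis("snp").to_csv(path, sep="\t", float_format="%.6g")


def write_manifest(path, **fields) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")
    Path(path).write_text(json.dumps(fields, indent=2, sort_keys=True,
                                     default=_default) + "\n")
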