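"""Environmental variables from pathogen occurrence and prevalence tables.

Pathogen (helminth) diversity — the number of parasite species/genera
transmitted in a country — serves as the proxy for pathogen-driven selective
pressure.  This module builds that per-country diversity count from a
curated presence/absence matrix, aggregates prevalence surveys, correlates
group prevalences with diversity, and broadcasts country-level values onto
populations.  Because several populations share a country, the broadcast
deliberately preserves blocks of tied values; climate covariates are
averaged back to the country level for the same reason, so every
correlation in the pipeline sees a comparable tie structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kendall import TauResult, correlate as _correlate

__all__ = [
    "PresenceMatrix",
    "compute_diversity",
    "aggregate_prevalence",
    "group_prevalence",
    "correlate_env",
    "broadcast_to_populations",
    "average_climate",
]


@dataclass(frozen=True)
class PresenceMatrix:
    """Species x country presence/absence with per-cell rarity flags.

    ``present`` and ``rare`` are boolean DataFrames indexed by species with
    countries as columns.  ``rare`` marks infections reported as rare in
    humans or lacking any prevalence estimate; it may only be True where
    ``present`` is True.
    """

    present: pd.DataFrame
    rare: pd.DataFrame

    def __post_init__(self):
        p, r = self.present, self.rare
        if not (p.index.equals(r.index) and p.columns.equals(r.columns)):
            raise ValueError("present and rare must share species/countries")
        if p.index.duplicated().any():
            raise ValueError("duplicate species labels")
        if p.columns.duplicated().any():
            raise ValueError("duplicate country labels")
        if (r & ~p).any().any():
            raise ValueError("rare=True requires present=True")

    @property
    def species_ids(self) -> list[str]:
        return list(self.present.index)

    @property
    def country_ids(self) -> list[str]:
        return list(self.present.columns)


def compute_diversity(presence: PresenceMatrix,
                      common_only: bool = False) -> pd.Series:
    """Per-country count of species recorded as transmitted there.

    Every species present in a country counts once, irrespective of its
    prevalence.  With ``common_only`` the count is restricted to species
    that are *common* (not rare-flagged) in at least one of the countries
    where they occur: species rare everywhere they occur are removed
    globally before counting.
    """
    p = presence.present
    if p.shape[0] == 0:
        raise ValueError("presence matrix has no species")
    if common_only:
        common_somewhere = (p & ~presence.rare).any(axis=1)
        p = p.loc[common_somewhere]
    out = p.sum(axis=0).astype(int)
    out.index.name = "country"
    out.name = "diversity"
    return out


def aggregate_prevalence(surveys: pd.DataFrame) -> pd.Series:
    """Mean prevalence per (country, species) over non-HIV surveys.

    ``surveys`` needs columns ``country, species, prevalence, hiv``.
    Surveys of HIV-seropositive cohorts are excluded first (HIV modulates
    helminth susceptibility); (country, species) pairs left with no survey
    are absent from the output.
    """
    required = {"country", "species", "prevalence", "hiv"}
    missing = required - set(surveys.columns)
    if missing:
        raise ValueError(f"survey table missing columns: {sorted(missing)}")
    if len(surveys) == 0:
        raise ValueError("no survey records")
    prev = surveys["prevalence"].astype(float)
    if ((prev < 0) | (prev > 1)).any():
        bad = surveys.loc[(prev < 0) | (prev > 1)]
        raise ValueError(f"prevalence outside [0, 1] in rows {list(bad.index)}")
    kept = surveys.loc[~surveys["hiv"].astype(bool)]
    out = kept.groupby(["country", "species"], sort=True)["prevalence"].mean()
    out.name = "prevalence"
    return out


def group_prevalence(prev: pd.Series, group_map: dict[str, str],
                     combiner: str = "mean") -> pd.Series:
    """Combine per-species prevalences into per-(country, group) values.

    ``prev`` is indexed by (country, species) as produced by
    :func:`aggregate_prevalence`.  Default combiner is the unweighted mean
    over member species with data; ``max`` and ``sum`` are available.
    Countries with no data for any member species are absent.
    """
    species = prev.index.get_level_values("species")
    unmapped = sorted(set(species) - set(group_map))
    if unmapped:
        raise ValueError(f"species without a group: {unmapped}")
    if combiner not in ("mean", "max", "sum"):
        raise ValueError(f"unknown combiner {combiner!r}")
    df = prev.rename("prevalence").reset_index()
    df["group"] = df["species"].map(group_map)
    out = df.groupby(["country", "group"], sort=True)["prevalence"] \
            .agg(combiner)
    out.name = "prevalence"
    return out


def correlate_env(x: pd.Series, y: pd.Series, min_countries: int = 11
                  ) -> TauResult:
    """Kendall tau-b between two per-country variables.

    Computed over the intersection of countries present in both vectors.
    Fewer than 3 shared countries is an error; fewer than ``min_countries``
    triggers a warning and exact permutation inference (see
    :func:`helmscan.kendall.correlate`).
    """
    shared = x.index.intersection(y.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared countries; need at least 3")
    return _correlate(x.loc[shared].to_numpy(dtype=float),
                      y.loc[shared].to_numpy(dtype=float),
                      min_n_normal=min_countries)


def _check_pop_table(pops: pd.DataFrame) -> pd.Series:
    if "population" in pops.columns:
        pops = pops.set_index("population")
    if pops.index.duplicated().any():
        raise ValueError("duplicate population labels")
    return pops["country"]


def broadcast_to_populations(env: pd.Series, pops: pd.DataFrame) -> pd.Series:
    """Assign each population its country's environmental value.

    Populations sharing a country share one value; this is the source of
    the tie blocks the correlation machinery is built around.
    """
    country_of = _check_pop_table(pops)
    unknown = sorted(set(country_of) - set(env.index))
    if unknown:
        raise ValueError(f"populations map to countries absent from the "
                         f"environment vector: {unknown}")
    out = country_of.map(env).astype(float)
    out.index.name = "population"
    out.name = env.name or "env"
    return out


def average_climate(pop_values: pd.Series, pops: pd.DataFrame) -> pd.Series:
    """Unweighted per-country mean of per-population climate values.

    Climate variables are natively per population (station coordinates);
    averaging them back to countries keeps the tie structure identical to
    the diversity variable across all correlation analyses.
    """
    country_of = _check_pop_table(pops)
    missing = sorted(set(pop_values.index) - set(country_of.index))
    if missing:
        raise ValueError(f"values given for unknown populations: {missing}")
    df = pd.DataFrame({
        "value": pop_values.astype(float),
        "country": country_of.reindex(pop_values.index),
    })
    if df["country"].isna().any():
        raise ValueError("population with unknown country")
    out = df.groupby("country", sort=True)["value"].mean()
    out.name = pop_values.name or "climate"
    return out
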