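"""Reference-database coverage auditing against hierarchical species pools.

A barcode reference database can only assign taxa it contains, so the share
of a local species pool with barcode records bounds what a reanalysis can
recover.  Two complementary proportions are audited per dataset, geographic
scale (basin / country / continent) and taxonomic resolution (species /
genus):

* ``coverage`` — the proportion of pool taxa represented in the reference
  database;
* ``local_assignment_proportion`` — the proportion of taxa in an uncorrected
  ("global") assignment that belong to the local pool.

Genus resolution collapses both sets to genus labels before intersecting: a
genus counts as covered if any congeneric species has a barcode record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd

from .taxonomy import genus_set

Scale = Literal["basin", "country", "continent"]
Resolution = Literal["species", "genus"]

SCALES: tuple[Scale, ...] = ("basin", "country", "continent")
RESOLUTIONS: tuple[Resolution, ...] = ("species", "genus")


class EmptyPoolError(ValueError):
    """Raised when a proportion is undefined because the denominator set is empty."""


@dataclass(frozen=True)
class SpeciesPoolHierarchy:
    """Nested local species pools for one dataset: basin ⊆ country ⊆ continent."""

    basin: frozenset[str]
    country: frozenset[str]
    continent: frozenset[str]
    basin_label: str = ""
    country_label: str = ""
    continent_label: str = ""

    def pool(self, scale: Scale) -> frozenset[str]:
        return getattr(self, scale)

    @property
    def is_nested(self) -> bool:
        return self.basin <= self.country <= self.continent


@dataclass(frozen=True)
class ReferenceDB:
    """Set of taxa with barcode records for one primer's reference database."""

    primer: str
    species: frozenset[str]

    @property
    def genera(self) -> frozenset[str]:
        return genus_set(self.species)

    def __contains__(self, name: str) -> bool:
        return name in self.species


def _at_resolution(names: Iterable[str], resolution: Resolution) -> frozenset[str]:
    names = frozenset(names)
    return genus_set(names) if resolution == "genus" else names


def pool_coverage(pool: Iterable[str], refdb: ReferenceDB,
                  resolution: Resolution = "species") -> float:
    """Proportion of pool taxa represented in the reference database."""
    pool_r = _at_resolution(pool, resolution)
    if not pool_r:
        raise EmptyPoolError("coverage undefined for an empty species pool")
    ref_r = _at_resolution(refdb.species, resolution)
    return len(pool_r & ref_r) / len(pool_r)


def assigned_local_proportion(assigned: Iterable[str], pool: Iterable[str],
                              resolution: Resolution = "species") -> float:
    """Proportion of assigned taxa present in the local pool."""
    assigned_r = _at_resolution(assigned, resolution)
    if not assigned_r:
        raise EmptyPoolError("proportion undefined for an empty assigned set")
    pool_r = _at_resolution(pool, resolution)
    return len(assigned_r & pool_r) / len(assigned_r)


@dataclass(frozen=True)
class CoverageRecord:
    dataset_id: str
    continent: str
    scale: Scale
    resolution: Resolution
    coverage: float | None
    local_assignment_proportion: float | None
    absent: bool = False


def coverage_report(collection) -> pd.DataFrame:
    """Audit every dataset x scale x resolution combination of a collection.

    Datasets missing a pool at some scale yield an explicit record flagged
    ``absent`` rather than being dropped.  Returns a tidy DataFrame with one
    row per combination.
    """
    records: list[CoverageRecord] = []
    for ds in collection.datasets:
        assigned = ds.global_species()
        for scale in SCALES:
            pool = ds.pools.pool(scale)
            for resolution in RESOLUTIONS:
                if not pool:
                    records.append(CoverageRecord(
                        ds.dataset_id, ds.metadata.continent, scale, resolution,
                        None, None, absent=True))
                    continue
                cov = pool_coverage(pool, ds.refdb, resolution)
                lap = (assigned_local_proportion(assigned, pool, resolution)
                       if assigned else None)
                records.append(CoverageRecord(
                    ds.dataset_id, ds.metadata.continent, scale, resolution,
                    cov, lap, absent=False))
    return pd.DataFrame([r.__dict__ for r in records])
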