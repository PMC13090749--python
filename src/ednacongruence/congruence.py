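"""Species-identity congruence between original and reanalyzed assignments.

The comparison unit is one dataset: the species x site read-count table
produced by reanalyzing its raw reads under a common workflow, versus the
species list the original study reported.  After correcting the reanalysis to
the basin-scale local species pool, every species falls into exactly one of
four categories:

1. shared between original and (basin-corrected) reanalysis;
2. unique to the reanalysis;
3. unique to the original but locally recorded at the basin scale
   ("extra local species");
4. unique to the original and not basin-local.

Two overlap proportions summarize a dataset,

    p_sp   = |shared| / |reanalyzed species|
    p_read = reads assigned to shared species / total reanalyzed reads,

and two per-species relative-abundance indices feed the abundance models:
``a_i`` (share of the dataset's total reads) and ``b_i`` (mean within-site
relative abundance).  ``p_read`` equals the sum of ``a_i`` over shared
species, an identity exercised in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .coverage import ReferenceDB


class UndefinedProportionError(ValueError):
    """A proportion whose denominator is empty/zero."""


@dataclass
class ReadTable:
    """Species x site read counts for one dataset.

    ``counts`` has canonical species names as the row index and site ids as
    columns; entries are non-negative integers.
    """

    dataset_id: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            bad = np.argwhere(self.counts.values < 0)[0]
            raise ValueError(
                f"negative read count in dataset {self.dataset_id!r}, species "
                f"{self.counts.index[bad[0]]!r}, site {self.counts.columns[bad[1]]!r}")
        if self.counts.index.has_duplicates:
            raise ValueError(f"duplicate species rows in dataset {self.dataset_id!r}")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]

    @property
    def species(self) -> frozenset[str]:
        present = self.counts.sum(axis=1) > 0
        return frozenset(self.counts.index[present])

    @property
    def total_reads(self) -> int:
        return int(self.counts.values.sum())


@dataclass
class OriginalAssignment:
    """Species reported by the original study (optionally per-site presence)."""

    dataset_id: str
    species: frozenset[str]
    presence: pd.DataFrame | None = None  # species x site, 0/1; optional
    richness_only: bool = False  # original provided only a richness table


@dataclass(frozen=True)
class CategoryPartition:
    """Four-way identity classification; the sets are pairwise disjoint."""

    shared: frozenset[str]
    unique_reanalysis: frozenset[str]
    unique_original_local: frozenset[str]
    unique_original_nonlocal: frozenset[str]

    def sizes(self) -> dict[str, int]:
        return {
            "n_shared": len(self.shared),
            "n_unique_rean": len(self.unique_reanalysis),
            "n_unique_orig_local": len(self.unique_original_local),
            "n_unique_orig_nonlocal": len(self.unique_original_nonlocal),
        }

    @property
    def universe(self) -> frozenset[str]:
        return (self.shared | self.unique_reanalysis
                | self.unique_original_local | self.unique_original_nonlocal)


@dataclass
class CongruenceResult:
    dataset_id: str
    partition: CategoryPartition
    p_sp: float
    p_read: float
    extra_local_with_barcode: int


def correct_to_pool(obj, pool: Iterable[str]):
    """Restrict a species set or :class:`ReadTable` to a local species pool.

    Rows for species outside the pool are dropped entirely (their reads do not
    re-enter any denominator).  An empty result is allowed.
    """
    pool = frozenset(pool)
    if isinstance(obj, ReadTable):
        keep = obj.counts.index.isin(pool)
        return ReadTable(obj.dataset_id, obj.counts.loc[keep])
    return frozenset(obj) & pool


def richness_per_site(table: ReadTable) -> pd.Series:
    """Number of species with positive reads at each site."""
    return (table.counts > 0).sum(axis=0)


def classify_species(original: Iterable[str], reanalyzed_basin: Iterable[str],
                     basin_pool: Iterable[str]) -> CategoryPartition:
    """Partition original ∪ basin-corrected reanalyzed species into 4 categories."""
    original = frozenset(original)
    rean = frozenset(reanalyzed_basin)
    pool = frozenset(basin_pool)
    if not rean <= pool:
        raise ValueError(
            "reanalyzed species must already be basin-corrected: "
            f"{sorted(rean - pool)[:5]} outside the basin pool")
    orig_only = original - rean
    return CategoryPartition(
        shared=original & rean,
        unique_reanalysis=rean - original,
        unique_original_local=orig_only & pool,
        unique_original_nonlocal=orig_only - pool,
    )


def prop_shared_species(partition: CategoryPartition) -> float:
    """p_sp: share of (basin-corrected) reanalyzed species also found originally."""
    n_rean = len(partition.shared) + len(partition.unique_reanalysis)
    if n_rean == 0:
        raise UndefinedProportionError("no reanalyzed species: p_sp undefined")
    return len(partition.shared) / n_rean


def prop_shared_reads(table: ReadTable, shared: Iterable[str]) -> float:
    """p_read: share of reanalyzed reads assigned to shared species."""
    total = table.total_reads
    if total == 0:
        raise UndefinedProportionError("zero total reads: p_read undefined")
    shared = frozenset(shared)
    mask = table.counts.index.isin(shared)
    return float(table.counts.loc[mask].values.sum()) / total


def species_total_relabund(table: ReadTable) -> pd.Series:
    """a_i: per-species share of the dataset's total reads (sums to 1)."""
    totals = table.counts.sum(axis=1).astype(float)
    grand = totals.sum()
    if grand == 0:
        raise UndefinedProportionError("zero grand total: a_i undefined")
    return totals / grand


def species_mean_site_relabund(table: ReadTable) -> pd.Series:
    """b_i: mean within-site relative abundance across sites (sums to 1).

    Sites with zero total reads are excluded and the site count reduced
    accordingly (avoiding 0/0); a table whose sites are all empty is an error.
    """
    site_totals = table.counts.sum(axis=0).astype(float)
    occupied = site_totals > 0
    if not occupied.any():
        raise UndefinedProportionError("all sites empty: b_i undefined")
    sub = table.counts.loc[:, occupied].astype(float)
    props = sub / site_totals[occupied]
    return props.mean(axis=1)


def extra_local_barcode_count(unique_original_local: Iterable[str],
                              refdb: ReferenceDB) -> int:
    """How many extra local (category-3) species have barcode records."""
    return len(frozenset(unique_original_local) & refdb.species)


def congruence_result(dataset, *, scale: str = "basin") -> CongruenceResult | None:
    """Full identity comparison for one dataset at the given pool scale.

    Returns ``None`` for datasets whose original assignment is richness-only
    (no species list), which are excluded from identity comparison but kept in
    richness comparison.
    """
    if dataset.original is None or dataset.original.richness_only:
        return None
    pool = dataset.pools.pool(scale)
    corrected = correct_to_pool(dataset.read_table, pool)
    part = classify_species(dataset.original.species, corrected.species, pool)
    p_sp = prop_shared_species(part) if part.shared | part.unique_reanalysis else float("nan")
    try:
        p_read = prop_shared_reads(corrected, part.shared)
    except UndefinedProportionError:
        p_read = float("nan")
    return CongruenceResult(
        dataset_id=dataset.dataset_id,
        partition=part,
        p_sp=p_sp,
        p_read=p_read,
        extra_local_with_barcode=extra_local_barcode_count(
            part.unique_original_local, dataset.refdb),
    )


def congruence_table(collection, *, scale: str = "basin") -> pd.DataFrame:
    """Per-dataset congruence summaries for a collection (tidy DataFrame)."""
    rows = []
    for ds in collection.datasets:
        res = congruence_result(ds, scale=scale)
        if res is None:
            continue
        row = {"dataset_id": ds.dataset_id,
               "continent": ds.metadata.continent,
               "year": ds.metadata.year,
               "refdb_type": ds.metadata.refdb_type,
               "median_fish_reads": ds.metadata.median_fish_reads,
               **res.partition.sizes(),
               "n_reanalyzed": len(res.partition.shared) + len(res.partition.unique_reanalysis),
               "p_sp": res.p_sp, "p_read": res.p_read,
               "extra_local_with_barcode": res.extra_local_with_barcode}
        rows.append(row)
    return pd.DataFrame(rows)


def abundance_table(collection, *, scale: str = "basin") -> pd.DataFrame:
    """Per-species abundance indices with shared/unique flags, all datasets.

    One row per reanalyzed species per dataset: index values ``a`` and ``b``
    plus the shared flag, used by the abundance mixed models.
    """
    rows = []
    for ds in collection.datasets:
        res = congruence_result(ds, scale=scale)
        if res is None:
            continue
        corrected = correct_to_pool(ds.read_table, ds.pools.pool(scale))
        if corrected.total_reads == 0:
            continue
        a = species_total_relabund(corrected)
        b = species_mean_site_relabund(corrected)
        for sp in sorted(corrected.species):
            rows.append({
                "dataset_id": ds.dataset_id,
                "species": sp,
                "shared": sp in res.partition.shared,
                "refdb_type": ds.metadata.refdb_type,
                "year": ds.metadata.year,
                "a": float(a[sp]),
                "b": float(b[sp]),
            })
    return pd.DataFrame(rows)
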