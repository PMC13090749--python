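"""In-memory containers for a multi-dataset eDNA collection.

A ``Dataset`` bundles everything the analysis stages need for one study x
primer combination: the reanalyzed read table, the original assignment, the
hierarchical species pools, the barcode reference database and metadata.
A ``Collection`` is a list of datasets plus the shared synonym table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .congruence import OriginalAssignment, ReadTable
from .coverage import ReferenceDB, SpeciesPoolHierarchy
from .taxonomy import SynonymTable


@dataclass
class DatasetMetadata:
    dataset_id: str
    continent: str
    year: int
    barcode: str
    refdb_type: str                 # "global" | "custom"
    median_fish_reads: float
    n_sites: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class Dataset:
    dataset_id: str
    read_table: ReadTable
    original: OriginalAssignment | None
    pools: SpeciesPoolHierarchy
    refdb: ReferenceDB
    metadata: DatasetMetadata

    def global_species(self) -> frozenset[str]:
        """Uncorrected ("global") reanalyzed species set."""
        return self.read_table.species


@dataclass
class Collection:
    datasets: list[Dataset]
    synonyms: SynonymTable = field(default_factory=SynonymTable)

    def __post_init__(self) -> None:
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate dataset ids: {dupes}")

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def get(self, dataset_id: str) -> Dataset:
        for d in self.datasets:
            if d.dataset_id == dataset_id:
                return d
        raise KeyError(dataset_id)

    def replace_datasets(self, datasets: Sequence[Dataset]) -> "Collection":
        return Collection(list(datasets), self.synonyms)

    def content_hash(self) -> str:
        """SHA-256 digest of every table and metadata field (determinism checks)."""
        h = hashlib.sha256()
        for d in sorted(self.datasets, key=lambda x: x.dataset_id):
            h.update(d.dataset_id.encode())
            h.update(d.read_table.counts.to_csv().encode())
            if d.original is not None:
                h.update(",".join(sorted(d.original.species)).encode())
                if d.original.presence is not None:
                    h.update(d.original.presence.to_csv().encode())
            for pool in (d.pools.basin, d.pools.country, d.pools.continent):
                h.update(",".join(sorted(pool)).encode())
            h.update(",".join(sorted(d.refdb.species)).encode())
            h.update(json.dumps(d.metadata.as_dict(), sort_keys=True,
                                default=str).encode())
        return h.hexdigest()
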