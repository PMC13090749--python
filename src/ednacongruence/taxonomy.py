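"""Species-name canonicalization for cross-table comparisons.

Every comparison between an original assignment, a reanalyzed read table, a
local species pool and a barcode reference database assumes the tables share a
namespace of canonical Latin binomials.  Source tables in practice mix
synonyms, formatting and case, so all inputs pass through a
:class:`SynonymTable` before any set arithmetic.

Names that cannot be resolved (not in the synonym table and not shaped like a
binomial) are kept under a flagged ``unresolved:`` namespace so that read
totals are conserved while species-level statistics can exclude them.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

UNRESOLVED_PREFIX = "unresolved:"

_WS = re.compile(r"\s+")


def _normalize_raw(raw: str) -> str:
    """Whitespace-collapse, Unicode-NFC, and case-normalize a name string."""
    s = unicodedata.normalize("NFC", raw).strip()
    s = _WS.sub(" ", s)
    if not s:
        return s
    tokens = s.split(" ")
    tokens = [tokens[0].capitalize()] + [t.lower() for t in tokens[1:]]
    return " ".join(tokens)


@dataclass(frozen=True)
class CanonicalName:
    """A canonical taxon label at species or genus rank.

    ``binomial`` has exactly two whitespace-separated tokens at species rank
    ("Genus epithet") and one at genus rank; the first token is capitalized.
    """

    binomial: str
    rank: str = "species"

    def __post_init__(self) -> None:
        ntok = len(self.binomial.split(" "))
        if self.rank == "species" and ntok != 2:
            raise ValueError(f"species-rank name must be a binomial: {self.binomial!r}")
        if self.rank == "genus" and ntok != 1:
            raise ValueError(f"genus-rank name must be a single token: {self.binomial!r}")
        if not self.binomial[:1].isupper():
            raise ValueError(f"canonical names start with a capital: {self.binomial!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.binomial


class SynonymTable:
    """Mapping from variant name strings to canonical binomials.

    Canonical names are fixed points of the mapping and no variant maps to two
    different canonicals (enforced at construction).
    """

    def __init__(self, mapping: Mapping[str, str] | None = None,
                 provenance: Mapping[str, str] | None = None) -> None:
        self._map: dict[str, str] = {}
        self.provenance: dict[str, str] = {}
        if mapping:
            for variant, canonical in mapping.items():
                self.add(variant, canonical,
                         (provenance or {}).get(variant, "unspecified"))

    def add(self, variant: str, canonical: str, provenance: str = "unspecified") -> None:
        v = _normalize_raw(variant)
        c = _normalize_raw(canonical)
        existing = self._map.get(v)
        if existing is not None and existing != c:
            raise ValueError(f"variant {v!r} maps to both {existing!r} and {c!r}")
        self._map[v] = c
        self.provenance[v] = provenance
        # canonical names must be fixed points
        if self._map.get(c, c) != c:
            raise ValueError(f"canonical {c!r} is itself a mapped variant")
        self._map.setdefault(c, c)

    def lookup(self, normalized: str) -> str | None:
        return self._map.get(normalized)

    def variants_of(self, canonical: str) -> list[str]:
        """Non-canonical variant spellings mapping to ``canonical``."""
        c = _normalize_raw(canonical)
        return sorted(v for v, t in self._map.items() if t == c and v != c)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, name: str) -> bool:
        return _normalize_raw(name) in self._map

    @classmethod
    def from_csv(cls, path) -> "SynonymTable":
        """Read a two-column CSV (variant, canonical)."""
        df = pd.read_csv(path)
        cols = list(df.columns[:2])
        return cls(dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str))))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"variant": list(self._map), "canonical": list(self._map.values())}
        ).to_csv(path, index=False)


def standardize_name(raw: str, table: SynonymTable | None = None) -> CanonicalName | None:
    """Normalize and synonym-map a raw name.

    Returns the canonical :class:`CanonicalName`, or ``None`` (the unresolved
    marker) when the name is absent from the table and not itself shaped like
    a binomial or single genus token.  Empty input is an error.
    """
    if not raw or not raw.strip():
        raise ValueError("empty name string")
    s = _normalize_raw(raw)
    if table is not None:
        hit = table.lookup(s)
        if hit is not None:
            s = hit
    ntok = len(s.split(" "))
    ok_shape = (ntok == 2) or (ntok == 1)
    # reject pseudo-names like "Sp. indet." even if two-token
    if any(ch in s for ch in ".?") or not s[:1].isalpha():
        ok_shape = False
    if table is not None and table.lookup(s) is None and not ok_shape:
        return None
    if not ok_shape:
        return None
    return CanonicalName(s, rank="species" if ntok == 2 else "genus")


def genus_of(name: CanonicalName | str) -> CanonicalName:
    """Collapse a species-rank name to its genus; genus input passes through."""
    if isinstance(name, str):
        name = CanonicalName(name, rank="species" if " " in name else "genus")
    if name.rank == "genus":
        return name
    return CanonicalName(name.binomial.split(" ")[0], rank="genus")


def genus_set(names: Iterable[str]) -> frozenset[str]:
    """Genus labels for a collection of canonical species names."""
    return frozenset(n.split(" ")[0] for n in names)


def harmonize_names(names: Iterable[str], synonyms: SynonymTable) -> dict[str, str]:
    """Map each input label to its canonical form (or an ``unresolved:`` label)."""
    out: dict[str, str] = {}
    for raw in names:
        canon = standardize_name(raw, synonyms)
        out[raw] = canon.binomial if canon is not None else UNRESOLVED_PREFIX + _normalize_raw(raw)
    return out


def harmonize_read_table(table: pd.DataFrame, synonyms: SynonymTable) -> pd.DataFrame:
    """Canonicalize row labels of a species x site read table, merging synonyms.

    Rows whose names canonicalize identically are summed; unresolved rows are
    retained under the ``unresolved:`` namespace.  The grand total of reads is
    conserved exactly.
    """
    if table.empty:
        return table.copy()
    mapping = harmonize_names(table.index.astype(str), synonyms)
    out = table.groupby(table.index.map(mapping), sort=True).sum()
    out.index.name = table.index.name
    return out


def harmonize_species_set(names: Iterable[str], synonyms: SynonymTable) -> frozenset[str]:
    """Canonicalized species set, dropping unresolved labels."""
    mapped = harmonize_names(names, synonyms).values()
    return frozenset(n for n in mapped if not n.startswith(UNRESOLVED_PREFIX))


def drop_unresolved(table: pd.DataFrame) -> pd.DataFrame:
    """Remove ``unresolved:`` rows (used before species-level statistics)."""
    keep = ~table.index.astype(str).str.startswith(UNRESOLVED_PREFIX)
    return table.loc[keep]
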