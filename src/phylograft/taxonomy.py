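"""Reference taxonomy: loading, name resolution, lineages and MRCA.

The taxonomy is a parent-pointer forest loaded from a local TSV file with
columns ``taxon_id  parent_id  rank  scientific_name  synonyms`` (synonyms
``|``-separated, possibly empty; the root row has an empty parent_id).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from .errors import (
    AmbiguousNameError,
    FormatError,
    TaxonomyCycleError,
    UnknownTaxonError,
    UnresolvedNameError,
    PhylograftError,
)

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Canonical form used for synonym lookup: trimmed, internal whitespace
    collapsed to single spaces, case-folded."""
    return _WS.sub(" ", name.strip()).casefold()


@dataclass(frozen=True)
class TaxonRecord:
    taxon_id: str
    parent_id: str | None
    scientific_name: str
    rank: str = ""
    synonyms: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.scientific_name:
            raise FormatError(f"taxon {self.taxon_id}: empty scientific_name")
        if self.taxon_id == self.parent_id:
            raise FormatError(f"taxon {self.taxon_id} is its own parent")


@dataclass
class TaxonomyTable:
    records: dict[str, TaxonRecord]
    root_id: str
    synonym_index: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self._validate()
        if not self.synonym_index:
            self._build_synonym_index()

    def _validate(self) -> None:
        for rec in self.records.values():
            if rec.parent_id is None:
                if rec.taxon_id != self.root_id:
                    raise FormatError(
                        f"multiple roots: {rec.taxon_id} and {self.root_id}"
                    )
            elif rec.parent_id not in self.records:
                raise FormatError(
                    f"taxon {rec.taxon_id}: missing parent {rec.parent_id}"
                )
        # acyclicity: walk every parent chain
        for tid in self.records:
            seen = set()
            cur: str | None = tid
            while cur is not None:
                if cur in seen:
                    raise TaxonomyCycleError(f"cycle through taxon {cur}")
                seen.add(cur)
                cur = self.records[cur].parent_id

    def _build_synonym_index(self) -> None:
        idx: dict[str, list[str]] = {}
        for rec in self.records.values():
            for syn in rec.synonyms:
                idx.setdefault(normalize_name(syn), []).append(rec.taxon_id)
        self.synonym_index = idx

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def get(self, taxon_id: str) -> TaxonRecord:
        try:
            return self.records[taxon_id]
        except KeyError:
            raise UnknownTaxonError(taxon_id) from None


def load_taxonomy(path) -> TaxonomyTable:
    """Read a taxonomy TSV file (see module docstring for the dialect)."""
    records: dict[str, TaxonRecord] = {}
    root_id: str | None = None
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("taxon_id"):
            raise FormatError(f"{path}: missing taxonomy header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            tid, pid, rank, name, syns = parts
            if tid in records:
                raise FormatError(f"{path}:{lineno}: duplicate taxon id {tid!r}")
            synonyms = tuple(s for s in syns.split("|") if s)
            rec = TaxonRecord(tid, pid or None, name, rank, synonyms)
            if rec.parent_id is None:
                if root_id is not None:
                    raise FormatError(f"{path}:{lineno}: second root {tid!r}")
                root_id = tid
            records[tid] = rec
    if root_id is None:
        raise FormatError(f"{path}: no root record (empty parent_id)")
    return TaxonomyTable(records=records, root_id=root_id)


def resolve_name(name: str, table: TaxonomyTable) -> TaxonRecord:
    """Resolve a free-text name: exact scientific name, then case-insensitive
    scientific name, then synonyms. Unique winner required at the winning tier."""
    if not name:
        raise PhylograftError("empty query name")
    exact = [r for r in table.records.values() if r.scientific_name == name]
    if len(exact) == 1:
        return exact[0]
    if len(exact) > 1:
        raise AmbiguousNameError(name, exact)
    norm = normalize_name(name)
    ci = [r for r in table.records.values() if normalize_name(r.scientific_name) == norm]
    if len(ci) == 1:
        return ci[0]
    if len(ci) > 1:
        raise AmbiguousNameError(name, ci)
    syn_ids = table.synonym_index.get(norm, [])
    if len(syn_ids) == 1:
        return table.records[syn_ids[0]]
    if len(syn_ids) > 1:
        raise AmbiguousNameError(name, [table.records[t] for t in syn_ids])
    raise UnresolvedNameError(name)


def lineage_of(taxon_id: str, table: TaxonomyTable) -> list[str]:
    """Root-first path of taxon ids ending at ``taxon_id``."""
    rec = table.get(taxon_id)
    path = [rec.taxon_id]
    while rec.parent_id is not None:
        rec = table.get(rec.parent_id)
        path.append(rec.taxon_id)
    return path[::-1]


def search_taxon(ingroup_ids: Iterable[str], table: TaxonomyTable) -> TaxonRecord:
    """The deepest taxon present on every ingroup lineage: the MRCA of all
    ingroup taxa, which on a taxonomy tree is always a named node."""
    ids = list(ingroup_ids)
    if not ids:
        raise PhylograftError("search_taxon requires a nonempty ingroup")
    lineages = [lineage_of(t, table) for t in ids]
    first = lineages[0]
    mrca = None
    for depth, tid in enumerate(first):
        if all(len(lin) > depth and lin[depth] == tid for lin in lineages):
            mrca = tid
        else:
            break
    if mrca is None:
        raise PhylograftError("ingroup spans disconnected roots; no common ancestor")
    return table.get(mrca)


def is_within(taxon_id: str, clade_id: str, table: TaxonomyTable) -> bool:
    """True iff ``clade_id`` lies on the lineage of ``taxon_id`` (a taxon is
    within itself)."""
    table.get(clade_id)  # raise on unknown clade
    return clade_id in lineage_of(taxon_id, table)
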