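"""Core working dataset: aligned matrix, tree I/O, and tree/alignment
reconciliation.

Trees are represented as :class:`dendropy.Tree` objects throughout; support
values travel as internal node labels in newick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO

from .errors import FormatError, ReconcileError, UnknownTaxonError
from .seqs import ungapped_length
from .taxonomy import TaxonomyTable, search_taxon

log = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTURYSWKMBDHVN-?")


class Alignment:
    """Fixed-width matrix of IUPAC DNA rows keyed by tip label."""

    def __init__(self, rows: dict[str, str], locus_name: str = "locus"):
        if not rows:
            raise FormatError("alignment must have at least one row")
        widths = {len(s) for s in rows.values()}
        if len(widths) != 1:
            for label, seq in rows.items():
                if len(seq) != len(next(iter(rows.values()))):
                    raise FormatError(
                        f"row {label!r} has width {len(seq)}, expected uniform width"
                    )
        self.rows: dict[str, str] = dict(rows)
        self.locus_name = locus_name

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def labels(self) -> list[str]:
        return list(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, label: str) -> str:
        return self.rows[label]

    def __contains__(self, label: str) -> bool:
        return label in self.rows

    def __eq__(self, other) -> bool:
        return isinstance(other, Alignment) and self.rows == other.rows

    def subset(self, labels) -> "Alignment":
        return Alignment({l: self.rows[l] for l in labels}, self.locus_name)


def read_alignment(path, locus_name: str | None = None) -> Alignment:
    """Read an aligned FASTA file; sequence case is normalized to upper."""
    rows: dict[str, str] = {}
    width = None
    for rec in SeqIO.parse(str(path), "fasta"):
        label = rec.id
        if label in rows:
            raise FormatError(f"{path}: duplicate label {label!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise FormatError(f"{path}: row {label!r} has invalid characters {sorted(bad)}")
        if width is None:
            width = len(seq)
        elif len(seq) != width:
            raise FormatError(
                f"{path}: row {label!r} has length {len(seq)}, expected {width}"
            )
        rows[label] = seq
    if not rows:
        raise FormatError(f"{path}: no FASTA records")
    return Alignment(rows, locus_name or "locus")


def write_alignment(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for label, seq in alignment.rows.items():
            fh.write(f">{label}\n{seq}\n")


def read_tree(path_or_string, *, from_string: bool = False) -> dendropy.Tree:
    """Read a single newick tree. Internal node labels are kept as support
    labels; quoted labels are allowed."""
    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    try:
        if from_string:
            tree = dendropy.Tree.get(data=path_or_string, **kwargs)
        else:
            tree = dendropy.Tree.get(path=str(path_or_string), **kwargs)
    except Exception as exc:  # dendropy raises assorted parse errors
        raise FormatError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", unquoted_underscores=True,
                                suppress_rooting=True))


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


@dataclass
class OtuMap:
    """tip_label -> (taxon_id, source accession or None)."""

    entries: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def taxon_of(self, label: str) -> str:
        try:
            return self.entries[label][0]
        except KeyError:
            raise UnknownTaxonError(label) from None

    def accession_of(self, label: str) -> str | None:
        return self.entries[label][1]

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def add(self, label: str, taxon_id: str, accession: str | None = None) -> None:
        self.entries[label] = (taxon_id, accession)


def read_otu_map(path) -> OtuMap:
    """TSV: tip_label, taxon_id, accession (accession may be empty)."""
    entries: dict[str, tuple[str, str | None]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise FormatError(f"{path}:{lineno}: expected 2-3 columns")
            label, taxon_id = parts[0], parts[1]
            accession = parts[2] if len(parts) == 3 and parts[2] else None
            if label in entries:
                raise FormatError(f"{path}:{lineno}: duplicate tip label {label!r}")
            entries[label] = (taxon_id, accession)
    return OtuMap(entries)


def write_otu_map(otu_map: OtuMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for label, (tid, acc) in otu_map.entries.items():
            fh.write(f"{label}\t{tid}\t{acc or ''}\n")


@dataclass
class Dataset:
    tree: dendropy.Tree
    alignment: Alignment
    otu_map: OtuMap
    ingroup_labels: set[str]
    search_taxon_id: str
    dropped_labels: list[str] = field(default_factory=list)


def reconcile(
    tree: dendropy.Tree,
    alignment: Alignment,
    otu_map: OtuMap,
    taxonomy: TaxonomyTable,
    ingroup_spec: set[str] | None = None,
) -> Dataset:
    """Intersect tree and alignment; rows absent from the tree are dropped and
    logged. The search taxon is the taxonomy MRCA of the ingroup rows' taxa.

    ``ingroup_spec`` is a set of tip labels; if omitted every tip is ingroup.
    """
    leaves = leaf_labels(tree)
    kept = {l: s for l, s in alignment.rows.items() if l in leaves}
    dropped = [l for l in alignment.rows if l not in leaves]
    for l in dropped:
        log.info("dropping alignment row %r: not a tree leaf", l)
    if not kept:
        raise ReconcileError(
            "tree and alignment share no labels; at least one taxon and its "
            "corresponding sequence are required"
        )
    ingroup = set(ingroup_spec) if ingroup_spec is not None else set(leaves)
    ingroup &= leaves
    ingroup_row_taxa = {
        otu_map.taxon_of(l) for l in kept if l in ingroup and l in otu_map
    }
    if not ingroup_row_taxa:
        raise ReconcileError("no ingroup alignment row maps to a taxon")
    st = search_taxon(sorted(ingroup_row_taxa), taxonomy)
    return Dataset(
        tree=tree,
        alignment=Alignment(kept, alignment.locus_name),
        otu_map=otu_map,
        ingroup_labels=ingroup,
        search_taxon_id=st.taxon_id,
        dropped_labels=dropped,
    )


def mean_ungapped_length(alignment: Alignment) -> float:
    """Arithmetic mean over rows of the count of non-gap, non-missing
    characters (N and other ambiguity codes count as sequence)."""
    return sum(ungapped_length(s) for s in alignment.rows.values()) / len(alignment)
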