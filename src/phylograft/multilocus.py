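"""Merge per-locus pipeline outputs into species-tree-ready inputs: a
concatenated supermatrix (nexus + partition table) and a gene-tree bundle.

Loci are merged on taxon id, never on tip label, since labels differ across
loci. Taxa missing a locus are padded with '?' (missing), distinct from '-'
(indel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .datamodel import Alignment, OtuMap, leaf_labels
from .errors import FormatError, PhylograftError
from .profile_align import ExtendedAlignment
from .seqs import ungap, ungapped_length


@dataclass
class LocusRun:
    locus_name: str
    extended_alignment: ExtendedAlignment
    tree: dendropy.Tree
    otu_map: OtuMap

    def __post_init__(self):
        extra = leaf_labels(self.tree) - set(self.extended_alignment.alignment.rows)
        if extra:
            raise FormatError(f"tree leaves missing from alignment: {sorted(extra)}")


@dataclass
class Supermatrix:
    alignment: Alignment
    partitions: list[tuple[str, int, int]] = field(default_factory=list)  # 1-based incl.

    def __post_init__(self):
        pos = 1
        for name, start, end in self.partitions:
            if start != pos or end < start:
                raise FormatError(f"partition {name!r} does not tile the matrix")
            pos = end + 1
        if pos != self.alignment.width + 1:
            raise FormatError("partitions do not cover the full width")


def select_representatives(run: LocusRun) -> dict[str, tuple[str, str]]:
    """One sequence per taxon: the row with the most non-gap characters; ties
    break on lexicographically smallest accession, then label. Returns
    taxon_id -> (label, ungapped sequence)."""
    best: dict[str, tuple] = {}
    for label, seq in run.extended_alignment.alignment.rows.items():
        if label not in run.otu_map:
            continue
        tid = run.otu_map.taxon_of(label)
        acc = run.otu_map.accession_of(label) or "￿"
        key = (-ungapped_length(seq), acc, label)
        if tid not in best or key < best[tid][0]:
            best[tid] = (key, label, seq)
    return {tid: (label, ungap(seq)) for tid, (_k, label, seq) in sorted(best.items())}


def _representative_rows(run: LocusRun) -> dict[str, str]:
    """Aligned (full-width) row per taxon for the selected representative."""
    reps = select_representatives(run)
    aln = run.extended_alignment.alignment
    return {tid: aln[label] for tid, (label, _seq) in reps.items()}


def concatenate(runs: list[LocusRun]) -> Supermatrix:
    """Concatenate representative rows across loci over the union of taxa;
    taxa absent from a locus get '?' across that partition."""
    names = [r.locus_name for r in runs]
    if len(set(names)) != len(names):
        raise FormatError(f"duplicate locus names: {names}")
    per_locus = [_representative_rows(r) for r in runs]
    taxa = sorted(set().union(*[set(d) for d in per_locus]))
    if not taxa:
        raise PhylograftError("no taxa across runs")
    rows = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for run, rep in zip(runs, per_locus):
        width = run.extended_alignment.alignment.width
        for t in taxa:
            rows[t].append(rep.get(t, "?" * width))
        partitions.append((run.locus_name, pos, pos + width - 1))
        pos += width
    alignment = Alignment({t: "".join(parts) for t, parts in rows.items()}, "supermatrix")
    return Supermatrix(alignment=alignment, partitions=partitions)


def gene_tree_bundle(runs: list[LocusRun], path) -> None:
    """One newick per line, in input order, with tips collapsed to the
    representative per taxon and renamed to taxon_id."""
    lines = []
    for run in runs:
        reps = select_representatives(run)
        keep = {label: tid for tid, (label, _s) in reps.items()}
        for lf in run.tree.leaf_node_iter():
            if lf.taxon.label not in run.otu_map:
                raise PhylograftError(
                    f"tip {lf.taxon.label!r} has no taxon mapping in locus {run.locus_name}"
                )
        tree = run.tree.clone(depth=1)
        drop = [lf.taxon for lf in tree.leaf_node_iter() if lf.taxon.label not in keep]
        if drop:
            tree.prune_taxa(drop)
        for lf in tree.leaf_node_iter():
            lf.taxon.label = keep[lf.taxon.label]
        lines.append(tree.as_string(schema="newick", unquoted_underscores=True,
                                    suppress_rooting=True).strip())
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _nexus_label(label: str) -> str:
    if any(c in label for c in " ()[]{}/\\,;:=*'\"`+<>-"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_nexus(supermatrix: Supermatrix, path) -> None:
    """Sequential nexus DATA block (datatype=dna, missing=?, gap=-) plus a
    sets block with one charset per partition."""
    aln = supermatrix.alignment
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={len(aln)} NCHAR={aln.width};\n")
        fh.write("    FORMAT DATATYPE=DNA MISSING=? GAP=- INTERLEAVE=NO;\n")
        fh.write("    MATRIX\n")
        for label, seq in aln.rows.items():
            fh.write(f"    {_nexus_label(label)}  {seq}\n")
        fh.write("    ;\nEND;\n\nBEGIN SETS;\n")
        for name, start, end in supermatrix.partitions:
            fh.write(f"    CHARSET {_nexus_label(name)} = {start}-{end};\n")
        fh.write("END;\n")


def write_partition_tsv(supermatrix: Supermatrix, path) -> None:
    """RAxML-style partition file: ``DNA, locus = start-end``."""
    with open(path, "w") as fh:
        for name, start, end in supermatrix.partitions:
            fh.write(f"DNA, {name} = {start}-{end}\n")
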