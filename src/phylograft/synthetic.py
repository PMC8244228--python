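"""Synthetic fixture generation: taxonomies, random trees, evolved sequences,
search databases, and the pruned-tip verification experiment.

Everything is deterministic under an integer seed and writes only plain-text
formats, so fixtures are always rebuilt programmatically rather than shipped.
"""

from __future__ import annotations

import json
import math
import os
import random
from dataclasses import dataclass

import dendropy

from .datamodel import (
    Alignment,
    OtuMap,
    read_tree,
    write_alignment,
    write_otu_map,
    write_tree,
)
from .errors import PhylograftError
from .search import SeqDatabase, write_database
from .taxonomy import TaxonomyTable, TaxonRecord

_SYLLABLES = ["ba", "co", "da", "fe", "gi", "ho", "ju", "ka", "lo", "mi",
              "ne", "po", "qua", "ri", "su", "ta", "ve", "xi", "yo", "zu"]


def _make_name(rng: random.Random, n_syll: int = 3) -> str:
    word = "".join(rng.choice(_SYLLABLES) for _ in range(n_syll))
    return word.capitalize()


def generate_taxonomy(n_genera: int, species_per_genus: int, seed: int) -> TaxonomyTable:
    """root -> genera -> species. The last genus is the outgroup genus (its
    name carries the prefix 'Outgrp'). Deterministic under seed."""
    if n_genera < 1 or species_per_genus < 1:
        raise PhylograftError("counts must be positive")
    rng = random.Random(seed)
    records: dict[str, TaxonRecord] = {}
    root = TaxonRecord("tax0000", None, _make_name(rng) + "aceae", "family")
    records[root.taxon_id] = root
    idx = 1
    for g in range(n_genera):
        gname = _make_name(rng)
        if g == n_genera - 1:
            gname = "Outgrp" + gname.lower()
        gid = f"tax{idx:04d}"
        idx += 1
        records[gid] = TaxonRecord(gid, root.taxon_id, gname, "genus")
        for _s in range(species_per_genus):
            sid = f"tax{idx:04d}"
            idx += 1
            sname = f"{gname} {_make_name(rng, 2).lower()}{idx}"
            syns = (f"{gname[0]}. {sname.split(' ', 1)[1]}",) if rng.random() < 0.3 else ()
            records[sid] = TaxonRecord(sid, gid, sname, "species", syns)
    return TaxonomyTable(records=records, root_id=root.taxon_id)


def write_taxonomy(table: TaxonomyTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon_id\tparent_id\trank\tscientific_name\tsynonyms\n")
        for rec in table.records.values():
            fh.write(
                f"{rec.taxon_id}\t{rec.parent_id or ''}\t{rec.rank}\t"
                f"{rec.scientific_name}\t{'|'.join(rec.synonyms)}\n"
            )


def random_tree(labels: list[str], seed: int, mean_branch: float = 0.05) -> dendropy.Tree:
    """Random binary tree: repeatedly join two random clusters; exponential
    branch lengths with the given mean."""
    if len(labels) < 2:
        raise PhylograftError("need at least 2 labels")
    rng = random.Random(seed)
    clusters = [f"{l}:{rng.expovariate(1.0 / mean_branch):.6f}" for l in labels]
    while len(clusters) > 2:
        i, j = sorted(rng.sample(range(len(clusters)), 2), reverse=True)
        a = clusters.pop(i)
        b = clusters.pop(j)
        bl = rng.expovariate(1.0 / mean_branch)
        clusters.append(f"({a},{b}):{bl:.6f}")
    newick = f"({clusters[0]},{clusters[1]});"
    return read_tree(newick, from_string=True)


def evolve_sequences(tree: dendropy.Tree, root_length: int, subs_rate: float, seed: int) -> dict[str, str]:
    """Evolve a uniform-random root sequence along the tree under the
    equal-rates (Jukes-Cantor) chain: per branch each site differs from its
    parent with probability (3/4)(1 - exp(-(4/3) * rate * branch_length)),
    the new base uniform among the other three. This makes the pairwise
    identity saturate at 25% and the JC distance estimator consistent for the
    path length. No indels."""
    rng = random.Random(seed)
    bases = "ACGT"
    root_seq = [rng.choice(bases) for _ in range(root_length)]
    seqs: dict[int, list[str]] = {id(tree.seed_node): root_seq}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = seqs[id(node)]
        else:
            if node.edge.length is None:
                raise PhylograftError("missing branch length during simulation")
            p = 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * subs_rate * node.edge.length))
            parent = seqs[id(node.parent_node)]
            seq = list(parent)
            for i in range(len(seq)):
                if rng.random() < p:
                    seq[i] = rng.choice([b for b in bases if b != seq[i]])
            seqs[id(node)] = seq
        if node.is_leaf():
            out[node.taxon.label] = "".join(seq)
    return out


@dataclass
class VerificationCase:
    """Pruned-tip recovery experiment: an input tree/alignment with 9 ingroup
    tips removed, their sequences placed in the search database (5 of them
    polluted with a contiguous run of 100 'N'), plus out-of-clade decoys."""

    tree: dendropy.Tree
    alignment: Alignment
    otu_map: OtuMap
    taxonomy: TaxonomyTable
    ingroup_labels: set[str]
    pruned_labels: list[str]
    db: SeqDatabase
    n_polluted: int
    expected: dict


# original ungapped lengths of the pruned sequences that receive a 100-N run
POLLUTED_LENGTHS = (450, 470, 480, 490, 500)
N_PRUNED = 9
N_DECOYS = 200
ALIGNED_WIDTH = 600
ROW_LENGTH = 480  # every input alignment row; the mean is therefore exactly 480


def build_verification_case(seed: int = 1) -> VerificationCase:
    """41-tip tree (38 ingroup + 3 outgroup); the input dataset carries 32
    tips after pruning 9 ingroup tips. All 9 pruned sequences go into the
    database together with 200 decoy records from a genus outside the search
    taxon; a contiguous 100-'N' run is inserted into the 5 pruned sequences
    of original ungapped lengths 450/470/480/490/500 (the other 4 keep length
    480)."""
    rng = random.Random(seed)

    # taxonomy: family root; ingroup genus (38 spp), outgroup genus (3 spp),
    # decoy genus (200 spp)
    records: dict[str, TaxonRecord] = {}
    root = TaxonRecord("tax0000", None, "Verifaceae", "family")
    records[root.taxon_id] = root
    genera = {
        "ING": TaxonRecord("gen0001", root.taxon_id, "Veritas", "genus"),
        "OUT": TaxonRecord("gen0002", root.taxon_id, "Outgrpverus", "genus"),
        "DEC": TaxonRecord("gen0003", root.taxon_id, "Decoyia", "genus"),
    }
    records.update({g.taxon_id: g for g in genera.values()})

    def add_species(prefix: str, genus: TaxonRecord, count: int) -> list[TaxonRecord]:
        out = []
        for i in range(count):
            sid = f"{prefix}{i:04d}"
            name = f"{genus.scientific_name} {_make_name(rng, 2).lower()}{i}"
            rec = TaxonRecord(sid, genus.taxon_id, name, "species")
            records[sid] = rec
            out.append(rec)
        return out

    ingroup_sp = add_species("isp", genera["ING"], 38)
    outgroup_sp = add_species("osp", genera["OUT"], 3)
    decoy_sp = add_species("dsp", genera["DEC"], N_DECOYS)
    taxonomy = TaxonomyTable(records=records, root_id=root.taxon_id)

    def tip(rec: TaxonRecord) -> str:
        return rec.scientific_name.replace(" ", "_")

    ingroup_tips = [tip(r) for r in ingroup_sp]
    outgroup_tips = [tip(r) for r in outgroup_sp]

    # full 41-tip tree: ingroup clade sister to outgroup clade
    ing = random_tree(ingroup_tips, seed=rng.randrange(2**31), mean_branch=0.03)
    outg = random_tree(outgroup_tips, seed=rng.randrange(2**31), mean_branch=0.03)
    ing_nwk = ing.as_string(schema="newick", unquoted_underscores=True,
                            suppress_rooting=True).strip().rstrip(";")
    out_nwk = outg.as_string(schema="newick", unquoted_underscores=True,
                             suppress_rooting=True).strip().rstrip(";")
    full_tree = read_tree(f"({ing_nwk}:0.05,{out_nwk}:0.15);", from_string=True)

    leaf_seqs = evolve_sequences(full_tree, ALIGNED_WIDTH, 1.0,
                                 seed=rng.randrange(2**31))

    pruned = sorted(rng.sample(ingroup_tips, N_PRUNED))
    polluted = list(pruned)
    rng.shuffle(polluted)
    polluted = polluted[: len(POLLUTED_LENGTHS)]
    pruned_length = {lbl: 480 for lbl in pruned}
    for lbl, length in zip(polluted, POLLUTED_LENGTHS):
        pruned_length[lbl] = length

    # input tree: prune the 9 tips
    input_tree = full_tree.clone(depth=1)
    input_tree.prune_taxa_with_labels(pruned)

    # input alignment: remaining 32 tips, first 480 bases + trailing gaps
    name_to_id = {tip(r): r.taxon_id for r in ingroup_sp + outgroup_sp}
    rows = {}
    otu = OtuMap()
    for lbl in ingroup_tips + outgroup_tips:
        if lbl in pruned:
            continue
        rows[lbl] = leaf_seqs[lbl][:ROW_LENGTH] + "-" * (ALIGNED_WIDTH - ROW_LENGTH)
        otu.add(lbl, name_to_id[lbl], None)
    alignment = Alignment(rows, "locus1")

    # database: pruned sequences (+100-N runs into the polluted five) + decoys
    db_records = []
    expected_pruned = []
    for i, lbl in enumerate(pruned):
        L = pruned_length[lbl]
        seq = leaf_seqs[lbl][:L]
        is_polluted = lbl in polluted
        if is_polluted:
            mid = L // 2
            seq = seq[:mid] + "N" * 100 + seq[mid:]
        acc = f"ACC{i:04d}"
        tid = name_to_id[lbl]
        db_records.append((acc, tid, seq))
        otu.add(acc, tid, acc)
        expected_pruned.append({
            "label": lbl, "accession": acc, "taxon_id": tid,
            "original_length": L, "polluted": is_polluted,
            "db_length": len(seq),
        })
    for i, rec in enumerate(decoy_sp):
        seq = "".join(rng.choice("ACGT") for _ in range(ROW_LENGTH))
        db_records.append((f"DEC{i:04d}", rec.taxon_id, seq))
    db = SeqDatabase(db_records)

    lo, hi = 0.8 * ROW_LENGTH, 1.2 * ROW_LENGTH
    expected = {
        "mean_ungapped_length": float(ROW_LENGTH),
        "length_window": [lo, hi],
        "pruned": expected_pruned,
        "expected_recovered_taxa": sorted(
            e["taxon_id"] for e in expected_pruned if lo <= e["db_length"] <= hi
        ),
        "expected_length_rejected_accessions": sorted(
            e["accession"] for e in expected_pruned
            if not (lo <= e["db_length"] <= hi)
        ),
        "n_db_records": len(db_records),
        "search_taxon_id": genera["ING"].taxon_id,
    }

    return VerificationCase(
        tree=input_tree,
        alignment=alignment,
        otu_map=otu,
        taxonomy=taxonomy,
        ingroup_labels={l for l in rows if l in set(ingroup_tips)},
        pruned_labels=pruned,
        db=db,
        n_polluted=len(polluted),
        expected=expected,
    )


def write_fixture_dir(case: VerificationCase, outdir) -> None:
    """Write the complete plain-text fixture directory: taxonomy.tsv,
    tree.nwk, alignment.fasta, otu_map.tsv, ingroup.txt, db.fasta and the
    ground-truth manifest expected.json."""
    os.makedirs(outdir, exist_ok=True)
    write_taxonomy(case.taxonomy, os.path.join(outdir, "taxonomy.tsv"))
    write_tree(case.tree, os.path.join(outdir, "tree.nwk"))
    write_alignment(case.alignment, os.path.join(outdir, "alignment.fasta"))
    write_otu_map(case.otu_map, os.path.join(outdir, "otu_map.tsv"))
    write_database(case.db, os.path.join(outdir, "db.fasta"))
    with open(os.path.join(outdir, "ingroup.txt"), "w") as fh:
        for lbl in sorted(case.ingroup_labels):
            fh.write(lbl + "\n")
    with open(os.path.join(outdir, "expected.json"), "w") as fh:
        json.dump(case.expected, fh, indent=2, sort_keys=True)
        fh.write("\n")
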