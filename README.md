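# phylograft

Update a published phylogeny with homologous sequences from a local sequence
database, fully offline:

1. **Reconcile** an input tree (newick) with its single-locus DNA alignment
   (FASTA), a tip→taxon mapping (TSV), and a reference taxonomy (TSV); the
   *search taxon* is the taxonomy MRCA of the ingroup.
2. **Search & filter**: every alignment row is queried once per cycle against
   a local FASTA database (built-in Smith–Waterman backend with a
   Karlin–Altschul-shaped e-value, or external 12-column tabular hits).
   Candidates are excluded if they (1) fall outside the search taxon, (2) have
   an e-value above the cutoff (default 1e-5), (3) fall outside 80%–120% of
   the alignment's mean ungapped length, or (4) duplicate an existing
   same-taxon sequence; at most 5 sequences per taxon are kept (at random),
   and by default a single search cycle is run. Length-excluded candidates
   are listed in `seqlen_mismatch.txt`.
3. **Extend** the alignment by profile alignment against the frozen original
   columns (round-trip exact: stripping inserted columns and new rows
   reproduces the input character-for-character).
4. **Rebuild & compare**: internal Jukes–Cantor + neighbor-joining path with
   column-bootstrap support (default 100 replicates), or an adapter for an
   external RAxML-compatible ML binary; the updated tree is compared to the
   original with unweighted/weighted Robinson–Foulds metrics and per-node
   conflict classification (supported_by / conflicts_with / resolves).

A `multilocus` module merges per-locus runs (keyed by taxon id) into a
nexus supermatrix with partitions and a gene-tree bundle, and a `synthetic`
module generates all fixtures, including a pruned-tip verification
experiment: 9 of 41 tips are pruned into the database, 5 of them polluted
with a contiguous 100-'N' run so that exactly 3 exceed the 120% length
cutoff — the pipeline recovers 6 of 9 tips and reports the 3 others.

## CLI

```sh
# generate the synthetic verification fixture directory
phylograft fixtures --seed 1 -o fixture/

# full pipeline run (INI config; an empty file reproduces all defaults)
phylograft run -c fixture/config.ini

# tree comparison: RF metrics + conflict classification
phylograft compare original.nwk updated.nwk -o comparison.json

# merge per-locus run directories
phylograft multilocus run_locus1/ run_locus2/ -o merged/
```

Config file format (all keys optional; paths are resolved relative to the
config file):

```ini
[paths]
tree = tree.nwk
alignment = alignment.fasta
otu_map = otu_map.tsv
taxonomy = taxonomy.tsv
db = db.fasta
ingroup = ingroup.txt     ; optional, one tip label per line
workdir = work

[run]
seed = 1

[filter]
evalue_cutoff = 0.00001
min_len_prop = 0.8
max_len_prop = 1.2
max_per_taxon = 5
max_cycles = 1

[tree]
backend = internal_nj     ; or external_ml
bootstrap_replicates = 100
```

A run writes `updated_tree.nwk`, `extended_alignment.fasta`,
`seqlen_mismatch.txt`, `audit.jsonl`, `comparison.json` and `run_log.txt`
into the work directory; reruns under the same seed are byte-identical.

## File formats

- taxonomy TSV: `taxon_id  parent_id  rank  scientific_name  synonyms`
  (synonyms `|`-separated; root row has empty parent_id)
- OTU map TSV: `tip_label  taxon_id  accession` (accession may be empty)
- database FASTA headers: `>accession|taxon_id`
- tabular hits: standard 12-column blast-tabular
  (`qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore`)
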