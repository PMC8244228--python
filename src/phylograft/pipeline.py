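"""End-to-end run: reconcile -> search/filter cycles -> profile extension ->
tree rebuild -> comparison, with all artifacts written to a work directory."""

from __future__ import annotations

import configparser
import json
import logging
import os
from dataclasses import dataclass, field

from . import compare as compare_mod
from .datamodel import (
    read_alignment,
    read_otu_map,
    read_tree,
    reconcile,
    write_alignment,
    write_tree,
)
from .errors import ConfigError, UndefinedMetricError, PhylograftError
from .filtering import FilterConfig, run_cycles, write_audit_log, write_seqlen_mismatch
from .profile_align import extend_alignment
from .search import SearchBackendConfig, read_database
from .seqs import ungap
from .taxonomy import load_taxonomy
from .treebuild import TreeBuildConfig, external_ml_adapter, internal_pipeline

log = logging.getLogger(__name__)

ARTIFACTS = (
    "updated_tree.nwk",
    "extended_alignment.fasta",
    "seqlen_mismatch.txt",
    "audit.jsonl",
    "comparison.json",
    "run_log.txt",
)


@dataclass
class RunConfig:
    tree: str = ""
    alignment: str = ""
    otu_map: str = ""
    taxonomy: str = ""
    db: str = ""
    workdir: str = "phylograft_run"
    ingroup: str = ""  # optional file with one tip label per line
    seed: int = 1
    filter: FilterConfig = field(default_factory=FilterConfig)
    search: SearchBackendConfig = field(default_factory=SearchBackendConfig)
    treebuild: TreeBuildConfig = field(default_factory=TreeBuildConfig)

    def validate(self) -> None:
        for name in ("tree", "alignment", "otu_map", "taxonomy", "db"):
            path = getattr(self, name)
            if not path:
                raise ConfigError(f"missing required path: {name}")
            if not os.path.exists(path):
                raise ConfigError(f"{name} path does not exist: {path}")
        if self.ingroup and not os.path.exists(self.ingroup):
            raise ConfigError(f"ingroup path does not exist: {self.ingroup}")


def load_run_config(path) -> RunConfig:
    """INI with sections [paths], [search], [filter], [tree], [run]. An empty
    file reproduces all defaults."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise ConfigError(f"cannot read config file: {path}")
    cfg = RunConfig()
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    if parser.has_section("paths"):
        for key in ("tree", "alignment", "otu_map", "taxonomy", "db", "workdir", "ingroup"):
            if parser.has_option("paths", key):
                setattr(cfg, key, resolve(parser.get("paths", key)))
    if parser.has_option("run", "seed"):
        cfg.seed = parser.getint("run", "seed")
    fkw = {}
    for key, cast in (("evalue_cutoff", float), ("min_len_prop", float),
                      ("max_len_prop", float), ("max_per_taxon", int),
                      ("max_cycles", int)):
        if parser.has_option("filter", key):
            fkw[key] = cast(parser.get("filter", key))
    cfg.filter = FilterConfig(rng_seed=cfg.seed + 1, **fkw)
    skw = {}
    for key, cast in (("match", float), ("mismatch", float), ("gap_open", float),
                      ("gap_extend", float), ("lam", float), ("K", float),
                      ("hit_cap", int), ("seed_k", int), ("min_seed_kmers", int)):
        if parser.has_option("search", key):
            skw[key] = cast(parser.get("search", key))
    cfg.search = SearchBackendConfig(**skw)
    tkw = {}
    if parser.has_option("tree", "backend"):
        tkw["backend"] = parser.get("tree", "backend")
    if parser.has_option("tree", "bootstrap_replicates"):
        tkw["bootstrap_replicates"] = parser.getint("tree", "bootstrap_replicates")
    cfg.treebuild = TreeBuildConfig(rng_seed=cfg.seed + 2, **tkw)
    return cfg


def cmd_run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict and writes
    updated_tree.nwk, extended_alignment.fasta, seqlen_mismatch.txt,
    audit.jsonl, comparison.json and run_log.txt into the work directory."""
    config.validate()
    os.makedirs(config.workdir, exist_ok=True)
    log_lines: list[str] = []

    def say(msg: str) -> None:
        log.info(msg)
        log_lines.append(msg)

    taxonomy = load_taxonomy(config.taxonomy)
    tree = read_tree(config.tree)
    alignment = read_alignment(config.alignment)
    otu_map = read_otu_map(config.otu_map)
    db = read_database(config.db)
    ingroup_spec = None
    if config.ingroup:
        with open(config.ingroup) as fh:
            ingroup_spec = {l.strip() for l in fh if l.strip()}
    say(f"stage reconcile: {len(alignment)} alignment rows, "
        f"{len(list(tree.leaf_node_iter()))} tree leaves")
    dataset = reconcile(tree, alignment, otu_map, taxonomy, ingroup_spec)
    if dataset.dropped_labels:
        say(f"dropped rows (not in tree): {', '.join(dataset.dropped_labels)}")
    say(f"search taxon: {dataset.search_taxon_id} "
        f"({taxonomy.get(dataset.search_taxon_id).scientific_name})")

    say(f"stage search+filter: db of {len(db)} records, "
        f"max {config.filter.max_cycles} cycle(s)")
    kept, reports = run_cycles(dataset, db, taxonomy, config.filter, config.search)
    for report in reports:
        counts: dict[str, int] = {}
        for _h, reason in report.rejected:
            counts[reason] = counts.get(reason, 0) + 1
        breakdown = ", ".join(f"{k}={v}" for k, v in sorted(counts.items()))
        say(f"cycle {report.cycle_index}: kept={len(report.kept)} "
            f"rejected[{breakdown or 'none'}]")
    write_seqlen_mismatch(reports, taxonomy, os.path.join(config.workdir, "seqlen_mismatch.txt"))
    write_audit_log(reports, os.path.join(config.workdir, "audit.jsonl"))

    say(f"stage extend: adding {len(kept)} sequences")
    new_seqs = sorted(
        (h.accession, ungap(h.subject_sequence)) for h in kept
    )
    ext = extend_alignment(dataset.alignment, new_seqs)
    write_alignment(ext.alignment, os.path.join(config.workdir, "extended_alignment.fasta"))
    for hit in kept:
        dataset.otu_map.add(hit.accession, hit.taxon_id, hit.accession)

    say(f"stage treebuild: backend={config.treebuild.backend}, "
        f"{config.treebuild.bootstrap_replicates} bootstrap replicates")
    if config.treebuild.backend == "external_ml":
        config.treebuild.starting_tree = dataset.tree
        updated, _reps = external_ml_adapter(
            ext.alignment, config.treebuild, os.path.join(config.workdir, "ml")
        )
    else:
        updated, _reps = internal_pipeline(ext.alignment, config.treebuild)
    write_tree(updated, os.path.join(config.workdir, "updated_tree.nwk"))

    say("stage compare: original vs updated on shared leaves")
    try:
        summary = compare_mod.comparison_summary(updated, dataset.tree)
    except UndefinedMetricError as exc:
        summary = {"error": str(exc)}
    with open(os.path.join(config.workdir, "comparison.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    result = {
        "n_kept": len(kept),
        "kept_accessions": sorted(h.accession for h in kept),
        "kept_taxa": sorted({h.taxon_id for h in kept}),
        "n_cycles": len(reports),
        "comparison": summary,
        "workdir": config.workdir,
    }
    say(f"done: kept {len(kept)} sequences over {len(reports)} cycle(s)")
    with open(os.path.join(config.workdir, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return result
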