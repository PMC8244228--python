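"""The four candidate-exclusion rules, the per-taxon cap, and the search-cycle
controller, with a complete per-candidate audit trail.

Rules are applied in order; the first failing rule is recorded:

1. OUTSIDE_SEARCH_TAXON - candidate taxon not within the search taxon
2. EVALUE               - e-value above the cutoff
3. LENGTH               - ungapped length outside the proportional window
   around the mean ungapped length of the input alignment (inclusive bounds)
4. DUPLICATE_SAME_TAXON - identical to, or contained in, an existing sequence
   of the same taxon (original alignment rows first, then already-kept
   candidates)

Candidates surviving all rules are capped at ``max_per_taxon`` per taxon,
chosen uniformly at random (OVER_CAP).
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field

from .datamodel import Dataset, mean_ungapped_length
from .errors import ConfigError
from .search import SearchBackendConfig, SearchHit, SeqDatabase, run_search
from .seqs import ungap, ungapped_length
from .taxonomy import TaxonomyTable, is_within
from .errors import UnknownTaxonError

log = logging.getLogger(__name__)

REASONS = ("OUTSIDE_SEARCH_TAXON", "EVALUE", "LENGTH", "DUPLICATE_SAME_TAXON", "OVER_CAP")


@dataclass
class FilterConfig:
    evalue_cutoff: float = 0.00001
    min_len_prop: float = 0.8
    max_len_prop: float = 1.2
    max_per_taxon: int = 5
    max_cycles: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_len_prop < self.max_len_prop):
            raise ConfigError("require 0 < min_len_prop < max_len_prop")
        if self.evalue_cutoff <= 0:
            raise ConfigError("evalue_cutoff must be positive")
        if self.max_per_taxon < 1:
            raise ConfigError("max_per_taxon must be >= 1")
        if self.max_cycles < 1:
            raise ConfigError("max_cycles must be >= 1")


@dataclass
class FilterReport:
    kept: list[SearchHit] = field(default_factory=list)
    rejected: list[tuple[SearchHit, str]] = field(default_factory=list)
    cycle_index: int = 1


@dataclass(frozen=True)
class LengthMismatchRecord:
    accession: str
    taxon_name: str
    ungapped_length: int


def dedupe_by_accession(hits: list[SearchHit]) -> list[SearchHit]:
    """Keep one hit per accession: lowest e-value, then highest score, then
    smallest query label."""
    best: dict[str, SearchHit] = {}
    for h in hits:
        cur = best.get(h.accession)
        if cur is None or (h.evalue, -h.score, h.query_label) < (cur.evalue, -cur.score, cur.query_label):
            best[h.accession] = h
    return sorted(best.values(), key=lambda h: h.accession)


def filter_hits(
    hits: list[SearchHit],
    dataset: Dataset,
    taxonomy: TaxonomyTable,
    config: FilterConfig,
    mean_len: float | None = None,
    extra_existing: list[tuple[str, str]] | None = None,
    cycle_index: int = 1,
) -> FilterReport:
    """Apply rules (1)-(4) then the per-taxon cap.

    ``hits`` should be deduplicated by accession beforehand (see
    :func:`dedupe_by_accession`). ``extra_existing`` supplies additional
    (taxon_id, ungapped sequence) pairs treated like original rows for the
    duplicate rule, used by later search cycles.
    """
    if mean_len is None:
        mean_len = mean_ungapped_length(dataset.alignment)
    lo = config.min_len_prop * mean_len
    hi = config.max_len_prop * mean_len

    # existing sequences per taxon: original alignment rows first, then any
    # sequences kept in earlier cycles
    existing: dict[str, list[str]] = {}
    for label, seq in dataset.alignment.rows.items():
        if label in dataset.otu_map:
            existing.setdefault(dataset.otu_map.taxon_of(label), []).append(ungap(seq))
    for tid, seq in extra_existing or []:
        existing.setdefault(tid, []).append(seq)

    report = FilterReport(cycle_index=cycle_index)
    passed: list[SearchHit] = []
    # canonical processing order: rule (4) outcomes and the cap selection are
    # then independent of the caller's hit ordering
    for hit in sorted(hits, key=lambda h: h.accession):
        reason = None
        try:
            inside = is_within(hit.taxon_id, dataset.search_taxon_id, taxonomy)
        except UnknownTaxonError:
            log.warning("hit %s: unknown taxon %r", hit.accession, hit.taxon_id)
            inside = False
        if not inside:
            reason = "OUTSIDE_SEARCH_TAXON"
        elif hit.evalue > config.evalue_cutoff:
            reason = "EVALUE"
        else:
            ulen = ungapped_length(hit.subject_sequence)
            if not (lo <= ulen <= hi):
                reason = "LENGTH"
            else:
                cand = ungap(hit.subject_sequence)
                for ex in existing.get(hit.taxon_id, []):
                    if cand in ex:
                        reason = "DUPLICATE_SAME_TAXON"
                        break
        if reason is None:
            passed.append(hit)
            existing.setdefault(hit.taxon_id, []).append(ungap(hit.subject_sequence))
        else:
            report.rejected.append((hit, reason))

    rng = random.Random(config.rng_seed)
    kept = cap_per_taxon(passed, config.max_per_taxon, rng)
    kept_accs = {h.accession for h in kept}
    for hit in passed:
        if hit.accession in kept_accs:
            report.kept.append(hit)
        else:
            report.rejected.append((hit, "OVER_CAP"))
    return report


def cap_per_taxon(candidates: list[SearchHit], k: int, rng: random.Random) -> list[SearchHit]:
    """Retain at most ``k`` candidates per taxon, chosen uniformly at random;
    deterministic under a seeded rng. Candidates are grouped and sampled in
    accession order so the result is independent of input ordering."""
    if k < 1:
        raise ConfigError("per-taxon cap must be >= 1")
    by_taxon: dict[str, list[SearchHit]] = {}
    for h in sorted(candidates, key=lambda h: h.accession):
        by_taxon.setdefault(h.taxon_id, []).append(h)
    kept: list[SearchHit] = []
    for tid in sorted(by_taxon):
        group = by_taxon[tid]
        if len(group) <= k:
            kept.extend(group)
        else:
            kept.extend(rng.sample(group, k))
    order = {h.accession: i for i, h in enumerate(candidates)}
    kept.sort(key=lambda h: order.get(h.accession, 0))
    return kept


def run_cycles(
    dataset: Dataset,
    db: SeqDatabase,
    taxonomy: TaxonomyTable,
    filter_config: FilterConfig | None = None,
    search_config: SearchBackendConfig | None = None,
) -> tuple[list[SearchHit], list[FilterReport]]:
    """Iterated search-and-filter. Cycle 1 queries the original alignment
    rows; cycle i>1 queries only sequences newly kept in cycle i-1. Stops when
    a cycle keeps nothing new or ``max_cycles`` is reached. An accession kept
    in an earlier cycle is never re-added."""
    filter_config = filter_config or FilterConfig()
    mean_len = mean_ungapped_length(dataset.alignment)
    all_kept: list[SearchHit] = []
    reports: list[FilterReport] = []
    queries: dict[str, str] | None = None  # None -> original alignment rows
    seen_accessions: set[str] = set()
    for cycle in range(1, filter_config.max_cycles + 1):
        hits = run_search(dataset, db, search_config, queries=queries)
        hits = [h for h in hits if h.accession not in seen_accessions]
        hits = dedupe_by_accession(hits)
        extra = [(h.taxon_id, ungap(h.subject_sequence)) for h in all_kept]
        report = filter_hits(
            hits, dataset, taxonomy, filter_config,
            mean_len=mean_len, extra_existing=extra, cycle_index=cycle,
        )
        reports.append(report)
        if not report.kept:
            break
        all_kept.extend(report.kept)
        seen_accessions.update(h.accession for h in report.kept)
        queries = {h.accession: ungap(h.subject_sequence) for h in report.kept}
    return all_kept, reports


def length_mismatch_records(
    reports: list[FilterReport] | FilterReport, taxonomy: TaxonomyTable
) -> list[LengthMismatchRecord]:
    if isinstance(reports, FilterReport):
        reports = [reports]
    out = []
    for report in reports:
        for hit, reason in report.rejected:
            if reason != "LENGTH":
                continue
            name = (
                taxonomy.get(hit.taxon_id).scientific_name
                if hit.taxon_id in taxonomy
                else hit.taxon_id
            )
            out.append(
                LengthMismatchRecord(hit.accession, name, ungapped_length(hit.subject_sequence))
            )
    out.sort(key=lambda r: r.accession)
    return out


def write_seqlen_mismatch(
    reports: list[FilterReport] | FilterReport, taxonomy: TaxonomyTable, path
) -> None:
    """One tab-separated line per LENGTH-rejected hit: accession, taxon name,
    ungapped length; sorted by accession. An empty file is written when there
    are no length rejections."""
    records = length_mismatch_records(reports, taxonomy)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.accession}\t{rec.taxon_name}\t{rec.ungapped_length}\n")


def write_audit_log(reports: list[FilterReport], path) -> None:
    """JSON-lines audit: one object per hit (accession, reason, cycle)."""
    with open(path, "w", encoding="utf-8") as fh:
        for report in reports:
            entries = [(h.accession, "kept") for h in report.kept]
            entries += [(h.accession, reason) for h, reason in report.rejected]
            for acc, reason in sorted(entries):
                fh.write(json.dumps(
                    {"accession": acc, "reason": reason, "cycle": report.cycle_index},
                    sort_keys=True) + "\n")
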