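"""Candidate discovery: a built-in local-alignment search backend over a local
FASTA database, orientation normalization, and an adapter for external
12-column tabular hit files.

The built-in backend scores with Smith-Waterman (affine gaps, via Biopython's
PairwiseAligner) and converts scores to e-values with a Karlin-Altschul-shaped
model E = K * m * n * exp(-lambda * S), where m is the summed database length
and n the query length. The filter depends on e-values only through a
threshold, so any monotone score->e-value map preserves its semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from Bio import Align, SeqIO

from .datamodel import Dataset
from .errors import FormatError, PhylograftError, SearchError, UnresolvedSubjectError
from .seqs import ORIENTATIONS, reverse_complement, ungap

__all__ = [
    "SeqDatabase",
    "SearchHit",
    "SearchBackendConfig",
    "read_database",
    "builtin_score",
    "orient_candidate",
    "run_search",
    "parse_tabular_hits",
]


@dataclass
class SeqDatabase:
    """Local stand-in for a public sequence database: accession, taxon,
    gap-free DNA sequence."""

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for acc, _tid, seq in self.records:
            if acc in seen:
                raise FormatError(f"duplicate accession {acc!r}")
            seen.add(acc)
            if not seq or "-" in seq or "?" in seq:
                raise FormatError(f"record {acc!r}: sequence must be nonempty and gap-free")

    def __len__(self) -> int:
        return len(self.records)

    def by_accession(self, accession: str) -> tuple[str, str, str]:
        for rec in self.records:
            if rec[0] == accession:
                return rec
        raise UnresolvedSubjectError(f"accession {accession!r} not in database")

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, _, seq in self.records)


def read_database(path) -> SeqDatabase:
    """FASTA with ``>accession|taxon_id`` headers."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "|" not in header:
            raise FormatError(f"{path}: header {header!r} lacks '|taxon_id' suffix")
        acc, tid = header.split("|", 1)
        records.append((acc, tid, str(rec.seq).upper()))
    return SeqDatabase(records)


def write_database(db: SeqDatabase, path) -> None:
    with open(path, "w") as fh:
        for acc, tid, seq in db.records:
            fh.write(f">{acc}|{tid}\n{seq}\n")


@dataclass(frozen=True)
class SearchHit:
    query_label: str
    accession: str
    taxon_id: str
    evalue: float
    score: float
    subject_sequence: str
    orientation: str = "forward"


@dataclass
class SearchBackendConfig:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    lam: float = 0.625
    K: float = 0.41
    db_size_m: int | None = None  # summed db length; filled in by run_search
    hit_cap: int = 100  # best-scoring subjects kept per query
    seed_k: int = 11  # k-mer size of the shared-word prescreen
    min_seed_kmers: int = 1  # 0 disables the prescreen (exhaustive scoring)

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise PhylograftError("require match > 0 > mismatch")
        if self.lam <= 0 or self.K <= 0:
            raise PhylograftError("lambda and K must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = self.match
        al.mismatch_score = self.mismatch
        al.open_gap_score = self.gap_open
        al.extend_gap_score = self.gap_extend
        return al


def _evalue(score: float, m: int, n: int, config: SearchBackendConfig) -> float:
    return config.K * m * n * math.exp(-config.lam * score)


def builtin_score(query: str, subject: str, config: SearchBackendConfig) -> tuple[float, float]:
    """Best local-alignment score and its e-value. Both sequences must be
    gap-free and nonempty."""
    if not query or not subject:
        raise PhylograftError("builtin_score requires nonempty sequences")
    if "-" in query or "-" in subject:
        raise PhylograftError("builtin_score requires ungapped sequences")
    score = float(config.aligner().score(query, subject))
    m = config.db_size_m if config.db_size_m is not None else len(subject)
    return score, _evalue(score, m, len(query), config)


def orient_candidate(
    candidate: str, reference: str, config: SearchBackendConfig
) -> tuple[str, str]:
    """Return the transform of ``candidate`` (forward / reverse-complement /
    reverse / complement) that scores best against ``reference``; ties break
    in that priority order."""
    seq, tag, _, _ = _orient_scored(candidate, reference, config)
    return seq, tag


def _orient_scored(candidate, reference, config):
    best = None
    for tag, fn in ORIENTATIONS:
        seq = fn(candidate)
        score, evalue = builtin_score(reference, seq, config)
        if best is None or score > best[2]:
            best = (seq, tag, score, evalue)
    return best


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def run_search(
    dataset: Dataset,
    db: SeqDatabase,
    config: SearchBackendConfig | None = None,
    queries: dict[str, str] | None = None,
) -> list[SearchHit]:
    """Submit every alignment row (gaps stripped) once against the database.

    ``queries`` overrides the query set (label -> gap-free sequence), used by
    later search cycles that query only newly kept sequences.
    """
    config = config or SearchBackendConfig()
    if not db.records:
        raise PhylograftError("empty database")
    if config.db_size_m is None:
        config = replace(config, db_size_m=db.total_length)
    if queries is None:
        queries = {l: ungap(s) for l, s in dataset.alignment.rows.items()}
    hits: list[SearchHit] = []
    k = config.seed_k
    for label, qseq in queries.items():
        if not qseq:
            raise SearchError(label, "empty ungapped query")
        try:
            q_kmers = _kmers(qseq, k) | _kmers(reverse_complement(qseq), k)
            scored = []
            for acc, tid, sseq in db.records:
                if config.min_seed_kmers > 0:
                    shared = sum(1 for i in range(len(sseq) - k + 1)
                                 if sseq[i : i + k] in q_kmers)
                    if shared < config.min_seed_kmers:
                        continue
                oriented, tag, score, evalue = _orient_scored(sseq, qseq, config)
                scored.append(SearchHit(label, acc, tid, evalue, score, oriented, tag))
            scored.sort(key=lambda h: (-h.score, h.accession))
            hits.extend(scored[: config.hit_cap])
        except PhylograftError:
            raise
        except Exception as exc:
            raise SearchError(label, str(exc)) from exc
    return hits


def parse_tabular_hits(path, db: SeqDatabase, config: SearchBackendConfig | None = None) -> list[SearchHit]:
    """Adapter for standard 12-column blast-tabular output (qseqid sseqid
    pident length mismatch gapopen qstart qend sstart send evalue bitscore).

    Subject sequences and taxa are looked up in ``db`` by accession; a
    reversed subject coordinate range (send < sstart) marks a minus-strand
    match, and the subject sequence is reverse-complemented accordingly.
    """
    hits: list[SearchHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(parts)}"
                )
            qseqid, sseqid = parts[0], parts[1]
            try:
                sstart, send = int(parts[8]), int(parts[9])
                evalue, bitscore = float(parts[10]), float(parts[11])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            acc, tid, seq = db.by_accession(sseqid)
            if send < sstart:
                hits.append(SearchHit(qseqid, acc, tid, evalue, bitscore,
                                      reverse_complement(seq), "reverse-complement"))
            else:
                hits.append(SearchHit(qseqid, acc, tid, evalue, bitscore, seq, "forward"))
    return hits
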