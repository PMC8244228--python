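import json
import random

import pytest

from phylograft.datamodel import Alignment, OtuMap, read_tree, reconcile
from phylograft.errors import ConfigError
from phylograft.filtering import (
    FilterConfig,
    cap_per_taxon,
    dedupe_by_accession,
    filter_hits,
    run_cycles,
    write_audit_log,
    write_seqlen_mismatch,
)
from phylograft.search import SearchBackendConfig, SearchHit, SeqDatabase
from phylograft.taxonomy import TaxonomyTable, TaxonRecord, is_within, lineage_of


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_taxonomy():
    recs = {
        "r": TaxonRecord("r", None, "Rootaceae", "family"),
        "g": TaxonRecord("g", "r", "Veritas", "genus"),
        "out": TaxonRecord("out", "r", "Aliena", "genus"),
    }
    for i in range(8):
        recs[f"s{i}"] = TaxonRecord(f"s{i}", "g", f"Veritas sp{i}", "species")
    for i in range(3):
        recs[f"o{i}"] = TaxonRecord(f"o{i}", "out", f"Aliena sp{i}", "species")
    return TaxonomyTable(records=recs, root_id="r")


def make_dataset(rng, mean_len=100):
    table = make_taxonomy()
    rows = {"a": rand_seq(rng, mean_len), "b": rand_seq(rng, mean_len)}
    tree = read_tree("(a,b,x);", from_string=True)
    otu = OtuMap()
    otu.add("a", "s0")
    otu.add("b", "s1")
    ds = reconcile(tree, Alignment(rows), otu, table, {"a", "b"})
    assert ds.search_taxon_id == "g"
    return ds, table


def hit(accession, taxon_id="s2", evalue=1e-9, length=100, seq=None, rng=None):
    seq = seq or rand_seq(rng or random.Random(hash(accession) % 2**31), length)
    return SearchHit("a", accession, taxon_id, evalue, 100.0, seq)


def test_evalue_rule_default_cutoff():
    rng = random.Random(1)
    ds, table = make_dataset(rng)
    report = filter_hits([hit("A1", evalue=0.001)], ds, table, FilterConfig())
    assert report.rejected[0][1] == "EVALUE"
    report2 = filter_hits([hit("A1", evalue=1e-5)], ds, table, FilterConfig())
    assert [h.accession for h in report2.kept] == ["A1"]


def test_length_rule_boundaries_inclusive():
    rng = random.Random(2)
    ds, table = make_dataset(rng, mean_len=100)
    hits = [hit(f"A{n}", taxon_id=f"s{i + 2}", length=n, rng=rng)
            for i, n in enumerate((79, 80, 120, 121))]
    report = filter_hits(hits, ds, table, FilterConfig(), mean_len=100.0)
    outcome = {h.accession: "kept" for h in report.kept}
    outcome.update({h.accession: r for h, r in report.rejected})
    assert outcome == {"A79": "LENGTH", "A80": "kept", "A120": "kept", "A121": "LENGTH"}


def test_outside_search_taxon_rule():
    rng = random.Random(3)
    ds, table = make_dataset(rng)
    report = filter_hits([hit("A1", taxon_id="o0")], ds, table, FilterConfig())
    assert report.rejected[0][1] == "OUTSIDE_SEARCH_TAXON"


def test_unknown_taxon_routed_outside_not_crash():
    rng = random.Random(4)
    ds, table = make_dataset(rng)
    report = filter_hits([hit("A1", taxon_id="ghost")], ds, table, FilterConfig())
    assert report.rejected[0][1] == "OUTSIDE_SEARCH_TAXON"


def test_duplicate_same_taxon_vs_other_taxon():
    rng = random.Random(5)
    ds, table = make_dataset(rng)
    same = hit("A1", taxon_id="s0", seq=ds.alignment["a"])  # identical, same taxon
    other = hit("A2", taxon_id="s3", seq=ds.alignment["a"])  # identical, other taxon
    report = filter_hits([same, other], ds, table, FilterConfig())
    reasons = {h.accession: r for h, r in report.rejected}
    assert reasons == {"A1": "DUPLICATE_SAME_TAXON"}
    assert [h.accession for h in report.kept] == ["A2"]


def test_duplicate_substring_containment():
    rng = random.Random(6)
    ds, table = make_dataset(rng)
    sub = ds.alignment["a"][10:95]  # 85 chars, within the length window
    report = filter_hits([hit("A1", taxon_id="s0", seq=sub)], ds, table, FilterConfig())
    assert report.rejected[0][1] == "DUPLICATE_SAME_TAXON"
    # same subsequence, different taxon: kept
    report2 = filter_hits([hit("A1", taxon_id="s4", seq=sub)], ds, table, FilterConfig())
    assert len(report2.kept) == 1


def _rule_oracle(hits, ds, table, config, mean_len, existing_by_taxon):
    """Independent straight-line reimplementation of rules (1)-(4)."""
    existing = {k: list(v) for k, v in existing_by_taxon.items()}
    out = {}
    for h in sorted(hits, key=lambda x: x.accession):
        if h.taxon_id not in table.records or \
                ds.search_taxon_id not in lineage_of(h.taxon_id, table):
            out[h.accession] = "OUTSIDE_SEARCH_TAXON"
        elif h.evalue > config.evalue_cutoff:
            out[h.accession] = "EVALUE"
        elif not (config.min_len_prop * mean_len
                  <= sum(c not in "-?" for c in h.subject_sequence)
                  <= config.max_len_prop * mean_len):
            out[h.accession] = "LENGTH"
        elif any(h.subject_sequence in e for e in existing.get(h.taxon_id, [])):
            out[h.accession] = "DUPLICATE_SAME_TAXON"
        else:
            out[h.accession] = "kept"
            existing.setdefault(h.taxon_id, []).append(h.subject_sequence)
    return out


def _random_hits(rng, n):
    hits = []
    for i in range(n):
        taxon = rng.choice(["s0", "s1", "s2", "s3", "o0", "ghost"])
        evalue = 10.0 ** rng.uniform(-12, -2)
        length = rng.randint(60, 140)
        hits.append(hit(f"H{i:04d}", taxon_id=taxon, evalue=evalue,
                        length=length, rng=rng))
    return hits


def test_filter_matches_independent_oracle():
    rng = random.Random(7)
    ds, table = make_dataset(rng)
    hits = _random_hits(rng, 300)
    config = FilterConfig(max_per_taxon=1000)  # disable the cap
    report = filter_hits(hits, ds, table, config, mean_len=100.0)
    got = {h.accession: "kept" for h in report.kept}
    got.update({h.accession: r for h, r in report.rejected})
    existing = {"s0": [ds.alignment["a"]], "s1": [ds.alignment["b"]]}
    assert got == _rule_oracle(hits, ds, table, config, 100.0, existing)


def test_filter_conservation_and_partition():
    rng = random.Random(8)
    ds, table = make_dataset(rng)
    hits = _random_hits(rng, 200)
    report = filter_hits(hits, ds, table, FilterConfig(), mean_len=100.0)
    assert len(report.kept) + len(report.rejected) == len(hits)
    accs = [h.accession for h in report.kept] + [h.accession for h, _ in report.rejected]
    assert sorted(accs) == sorted(h.accession for h in hits)


def test_filter_order_stability():
    rng = random.Random(9)
    ds, table = make_dataset(rng)
    hits = _random_hits(rng, 100)
    r1 = filter_hits(hits, ds, table, FilterConfig(), mean_len=100.0)
    shuffled = list(hits)
    rng.shuffle(shuffled)
    r2 = filter_hits(shuffled, ds, table, FilterConfig(), mean_len=100.0)
    assert {h.accession for h in r1.kept} == {h.accession for h in r2.kept}
    assert dict((h.accession, r) for h, r in r1.rejected) == \
        dict((h.accession, r) for h, r in r2.rejected)


def test_filter_monotonicity_under_tightening():
    rng = random.Random(10)
    ds, table = make_dataset(rng)
    hits = _random_hits(rng, 150)
    # thresholds: compare the pre-cap kept sets (cap disabled), which must
    # shrink under any tightening
    loose = FilterConfig(max_per_taxon=1000)
    base_kept = {h.accession for h in
                 filter_hits(hits, ds, table, loose, mean_len=100.0).kept}
    for cfg in (FilterConfig(evalue_cutoff=1e-8, max_per_taxon=1000),
                FilterConfig(min_len_prop=0.9, max_len_prop=1.1, max_per_taxon=1000)):
        kept = {h.accession for h in
                filter_hits(hits, ds, table, cfg, mean_len=100.0).kept}
        assert kept <= base_kept
    # per-taxon cap: a smaller k never enlarges any taxon's kept count
    for k_small, k_big in ((2, 5), (1, 3)):
        def taxon_counts(k):
            rep = filter_hits(hits, ds, table,
                              FilterConfig(max_per_taxon=k), mean_len=100.0)
            counts = {}
            for h in rep.kept:
                counts[h.taxon_id] = counts.get(h.taxon_id, 0) + 1
            return counts
        small, big = taxon_counts(k_small), taxon_counts(k_big)
        assert sum(small.values()) <= sum(big.values())
        for tid, c in small.items():
            assert c <= max(big.get(tid, 0), k_small)


def test_cap_12_candidates_keep_5():
    rng = random.Random(11)
    ds, table = make_dataset(rng)
    hits = [hit(f"C{i:02d}", taxon_id="s5", rng=rng) for i in range(12)]
    report = filter_hits(hits, ds, table, FilterConfig(rng_seed=4), mean_len=100.0)
    assert len(report.kept) == 5
    assert sum(1 for _, r in report.rejected if r == "OVER_CAP") == 7


def test_cap_under_limit_keeps_all():
    rng = random.Random(12)
    hits = [hit(f"C{i}", rng=rng) for i in range(3)]
    kept = cap_per_taxon(hits, 5, random.Random(0))
    assert kept == hits


def test_cap_rejects_bad_k():
    with pytest.raises(ConfigError):
        cap_per_taxon([], 0, random.Random(0))


def test_cap_deterministic_and_uniform():
    rng = random.Random(13)
    hits = [hit(f"C{i:02d}", rng=rng) for i in range(12)]
    first = [h.accession for h in cap_per_taxon(hits, 5, random.Random(99))]
    again = [h.accession for h in cap_per_taxon(hits, 5, random.Random(99))]
    assert first == again
    counts = {h.accession: 0 for h in hits}
    n_seeds = 1000
    for seed in range(n_seeds):
        for h in cap_per_taxon(hits, 5, random.Random(seed)):
            counts[h.accession] += 1
    for acc, c in counts.items():
        assert abs(c / n_seeds - 5 / 12) < 0.05, acc


def _chain_fixture(rng):
    """db where A is discoverable from the query, B only from A, C only from
    B (sequences built from shared 150 bp segments)."""
    table = make_taxonomy()
    seg = {k: rand_seq(rng, 150) for k in "XYZWV"}
    q = seg["X"] + seg["Y"]
    a = seg["Y"] + seg["Z"]
    b = seg["Z"] + seg["W"]
    c = seg["W"] + seg["V"]
    tree = read_tree("(a,x,y);", from_string=True)
    otu = OtuMap()
    otu.add("a", "s0")
    otu.add("x", "s7")  # second ingroup row so the search taxon is the genus
    ds = reconcile(tree, Alignment({"a": q, "x": rand_seq(rng, 300)}), otu,
                   table, {"a", "x"})
    assert ds.search_taxon_id == "g"
    db = SeqDatabase([("A", "s1", a), ("B", "s2", b), ("C", "s3", c)])
    return ds, db, table


def test_run_cycles_single_cycle_default():
    rng = random.Random(14)
    ds, db, table = _chain_fixture(rng)
    kept, reports = run_cycles(ds, db, table, FilterConfig())
    assert len(reports) == 1
    assert [h.accession for h in kept] == ["A"]


def test_run_cycles_transitive_chain():
    rng = random.Random(15)
    ds, db, table = _chain_fixture(rng)
    kept, reports = run_cycles(ds, db, table, FilterConfig(max_cycles=3))
    by_cycle = {r.cycle_index: sorted(h.accession for h in r.kept) for r in reports}
    assert by_cycle[1] == ["A"]
    assert by_cycle[2] == ["B"]
    assert by_cycle[3] == ["C"]
    assert sorted(h.accession for h in kept) == ["A", "B", "C"]


def test_run_cycles_terminates_without_hits():
    rng = random.Random(16)
    table = make_taxonomy()
    tree = read_tree("(a,x,y);", from_string=True)
    otu = OtuMap()
    otu.add("a", "s0")
    ds = reconcile(tree, Alignment({"a": rand_seq(rng, 100)}), otu, table, {"a"})
    db = SeqDatabase([("R", "s1", rand_seq(rng, 100))])
    kept, reports = run_cycles(ds, db, table, FilterConfig(max_cycles=5))
    assert kept == []
    assert len(reports) == 1


def test_dedupe_by_accession():
    h1 = hit("A1", evalue=1e-9)
    h2 = hit("A1", evalue=1e-12)
    h3 = hit("A2", evalue=1e-7)
    deduped = dedupe_by_accession([h1, h2, h3])
    assert [(h.accession, h.evalue) for h in deduped] == [("A1", 1e-12), ("A2", 1e-7)]


def test_write_seqlen_mismatch_three_lines(tmp_path):
    rng = random.Random(17)
    ds, table = make_dataset(rng)
    hits = [hit(f"L{i}", taxon_id=f"s{i + 2}", length=200 + i, rng=rng)
            for i in range(3)]
    report = filter_hits(hits, ds, table, FilterConfig(), mean_len=100.0)
    path = tmp_path / "seqlen_mismatch.txt"
    write_seqlen_mismatch(report, table, path)
    lines = path.read_text().splitlines()
    assert len(lines) == 3
    parsed = [tuple(l.split("\t")) for l in lines]
    assert parsed == [
        ("L0", "Veritas sp2", "200"),
        ("L1", "Veritas sp3", "201"),
        ("L2", "Veritas sp4", "202"),
    ]


def test_write_seqlen_mismatch_empty(tmp_path):
    rng = random.Random(18)
    ds, table = make_dataset(rng)
    report = filter_hits([], ds, table, FilterConfig())
    path = tmp_path / "seqlen_mismatch.txt"
    write_seqlen_mismatch(report, table, path)
    assert path.read_text() == ""


def test_audit_log_roundtrip(tmp_path):
    rng = random.Random(19)
    ds, table = make_dataset(rng)
    hits = _random_hits(rng, 40)
    report = filter_hits(hits, ds, table, FilterConfig(), mean_len=100.0)
    path = tmp_path / "audit.jsonl"
    write_audit_log([report], path)
    entries = [json.loads(l) for l in path.read_text().splitlines()]
    assert len(entries) == len(hits)
    assert all(e["cycle"] == 1 for e in entries)
    kept_accs = {e["accession"] for e in entries if e["reason"] == "kept"}
    assert kept_accs == {h.accession for h in report.kept}


def test_config_validation():
    with pytest.raises(ConfigError):
        FilterConfig(min_len_prop=1.3)
    with pytest.raises(ConfigError):
        FilterConfig(evalue_cutoff=0)
    with pytest.raises(ConfigError):
        FilterConfig(max_per_taxon=0)
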