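"""Family-curation funnel: filters, collapses, and structural flags."""

import numpy as np
import pandas as pd
import pytest

from oysteriap import curation
from oysteriap.config import CurationConfig
from oysteriap.curation import (apply_collapse_to_counts, collapse_haplotigs,
                                collapse_identical, detect_intronless,
                                detect_tandem_arrays, filter_iap_candidates,
                                flag_retroposition, mine_rcd_annotations)
from oysteriap.io_formats import (DomainHit, GeneModel, SequenceRecord,
                                  TranscriptModel)

AA = "ACDEFGHIKLMNPQRSTVWY"


def hit(pid, src="CDD", acc="cd00022", start=0, end=80):
    return DomainHit(pid, src, acc, "BIR", start, end, 1e-10)


# ---------------------------------------------------------------------------
# Candidate filtering: E-value cutoff plus CDD BIR confirmation

def test_filter_candidates_rules():
    scan = [hit("P1"), hit("P2"), hit("P3", src="PFAM", acc="PF00653")]
    kept = filter_iap_candidates(
        [("P1", 1e-5), ("P2", 0.01), ("P3", 1e-8)], scan)
    assert kept == {"P1"}  # P2 over threshold, P3 lacks a CDD BIR


def test_filter_candidate_absent_from_scan_dropped(caplog):
    with caplog.at_level("WARNING"):
        kept = filter_iap_candidates([("P9", 1e-9)], [hit("P1")])
    assert kept == set()
    assert "P9" in caplog.text


def test_filter_threshold_is_strict():
    kept = filter_iap_candidates([("P1", 0.001)], [hit("P1")])
    assert kept == set()  # E-value must be strictly below 0.001


# ---------------------------------------------------------------------------
# Identical-sequence collapse

def test_collapse_identical_examples():
    recs = [SequenceRecord("B", "", "MKV"), SequenceRecord("A", "", "MKV"),
            SequenceRecord("C", "", "ACD")]
    kept, mapping = collapse_identical(recs)
    assert {r.id for r in kept} == {"A", "C"}
    assert mapping == {"B": "A"}
    all_distinct, identity_map = collapse_identical(
        [SequenceRecord("X", "", "MK"), SequenceRecord("Y", "", "MV")])
    assert identity_map == {} and len(all_distinct) == 2


def test_collapse_identical_matches_hash_set_oracle():
    # 158 transcripts with planted duplicate pairs, as in a curated family
    rng = np.random.default_rng(42)
    base = ["".join(rng.choice(list(AA), 50)) for _ in range(84)]
    seqs = list(base)
    while len(seqs) < 158:
        seqs.append(base[rng.integers(0, len(base))])
    rng.shuffle(seqs)
    recs = [SequenceRecord(f"T{i:03d}", "", s) for i, s in enumerate(seqs)]
    kept, mapping = collapse_identical(recs)
    assert len(kept) == len({r.residues for r in recs})  # hash-set oracle
    assert len(mapping) == len(recs) - len(kept)


def test_collapse_identical_is_idempotent():
    rng = np.random.default_rng(7)
    seqs = ["".join(rng.choice(list(AA), 30)) for _ in range(10)] * 2
    recs = [SequenceRecord(f"P{i}", "", s) for i, s in enumerate(seqs)]
    kept, _ = collapse_identical(recs)
    kept2, mapping2 = collapse_identical(kept)
    assert kept2 == kept and mapping2 == {}


# ---------------------------------------------------------------------------
# Haplotig collapse

def _pair_identity(val):
    return {("P1", "P2"): val, ("P2", "P1"): val}


def test_haplotig_low_coverage_member_removed():
    recs = [SequenceRecord("P1", "", "MKV"), SequenceRecord("P2", "", "MKL")]
    kept, removed = collapse_haplotigs(
        recs, _pair_identity(0.96), {"P1": 10.0, "P2": 30.0})
    assert removed == {"P1": "P2"}
    assert [r.id for r in kept] == ["P2"]


def test_haplotig_below_identity_threshold_kept():
    recs = [SequenceRecord("P1", "", "MKV"), SequenceRecord("P2", "", "MKL")]
    kept, removed = collapse_haplotigs(
        recs, _pair_identity(0.90), {"P1": 10.0, "P2": 30.0})
    assert removed == {} and len(kept) == 2


def test_haplotig_half_coverage_boundary_kept():
    # 20 >= 0.5 * 30: not strictly below half the cluster max
    recs = [SequenceRecord("P1", "", "MKV"), SequenceRecord("P2", "", "MKL")]
    kept, removed = collapse_haplotigs(
        recs, _pair_identity(0.96), {"P1": 20.0, "P2": 30.0})
    assert removed == {} and len(kept) == 2


def test_haplotig_missing_coverage_errors():
    recs = [SequenceRecord("P1", "", "MKV"), SequenceRecord("P2", "", "MKL")]
    with pytest.raises(ValueError, match="coverage"):
        collapse_haplotigs(recs, _pair_identity(0.96), {"P1": 10.0})


def test_haplotig_collapse_is_idempotent():
    recs = [SequenceRecord(f"P{i}", "", s) for i, s in
            enumerate(["MKVA", "MKVC", "MKVD", "WWWW"])]
    ident = {}
    for a in ("P0", "P1", "P2"):
        for b in ("P0", "P1", "P2"):
            if a != b:
                ident[(a, b)] = 0.97
    cov = {"P0": 30.0, "P1": 5.0, "P2": 4.0, "P3": 10.0}
    kept, removed = collapse_haplotigs(recs, ident, cov)
    kept2, removed2 = collapse_haplotigs(kept, ident, cov)
    assert removed2 == {} and kept2 == kept


def test_haplotig_count_reassignment_conserves_totals():
    counts = pd.DataFrame(
        {"s1": [10, 4, 7], "s2": [2, 8, 1]},
        index=["P1", "P2", "P3"])
    merged = apply_collapse_to_counts(counts, {"P2": "P1"})
    assert merged.values.sum() == counts.values.sum()
    assert list(merged.index) == ["P1", "P3"]
    assert merged.loc["P1"].tolist() == [14, 10]


# ---------------------------------------------------------------------------
# Intronless detection

def _gene(gid, exon_counts):
    tms = []
    for i, n in enumerate(exon_counts):
        exons = tuple((j * 200, j * 200 + 100) for j in range(n))
        tms.append(TranscriptModel(f"{gid}.t{i+1}", exons))
    return GeneModel(gid, "chr1", "+", tuple(tms))


def test_detect_intronless_rules():
    genes = [_gene("g1", [1]), _gene("g2", [2]), _gene("g3", [1, 2])]
    assert detect_intronless(genes) == {"g1"}


# ---------------------------------------------------------------------------
# Tandem arrays

def test_three_adjacent_iap_genes_form_one_array():
    order = [("a", 0, 10), ("b", 20, 30), ("c", 40, 50)]
    arrays = detect_tandem_arrays({"a", "b", "c"}, {"chr1": order})
    assert len(set(arrays.values())) == 1 and set(arrays) == {"a", "b", "c"}


def test_too_many_intervening_genes_break_array():
    order = [("a", 0, 10)] + \
        [(f"x{i}", 20 + i * 20, 30 + i * 20) for i in range(5)] + \
        [("b", 200, 210)]
    arrays = detect_tandem_arrays({"a", "b"}, {"chr1": order})
    assert arrays == {}


def test_large_gap_breaks_array():
    order = [("a", 0, 10), ("b", 300_000, 300_010)]
    arrays = detect_tandem_arrays({"a", "b"}, {"chr1": order})
    assert arrays == {}


def _brute_force_arrays(iap_ids, order, cfg):
    """Exhaustive oracle: qualifying relation between consecutive IAP genes,
    then union-find over chains."""
    iap = [(g, s, e) for g, s, e in order if g in iap_ids]
    pos = {g: i for i, (g, _s, _e) in enumerate(order)}
    parent = {g: g for g, _s, _e in iap}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for (g1, _s1, e1), (g2, s2, _e2) in zip(iap, iap[1:]):
        intervening = sum(
            1 for g, _s, _e in order
            if pos[g1] < pos[g] < pos[g2] and g not in iap_ids)
        if intervening <= cfg.tandem_max_intervening and \
                s2 - e1 <= cfg.tandem_max_gap_bp:
            parent[find(g2)] = find(g1)
    groups = {}
    for g, _s, _e in iap:
        groups.setdefault(find(g), set()).add(g)
    return {frozenset(v) for v in groups.values() if len(v) >= 2}


@pytest.mark.parametrize("seed", range(5))
def test_tandem_arrays_match_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    cfg = CurationConfig(tandem_max_gap_bp=5_000)
    pos, order = 0, []
    for i in range(40):
        length = int(rng.integers(500, 2000))
        order.append((f"g{i:02d}", pos, pos + length))
        pos += length + int(rng.integers(100, 8_000))
    iap_ids = {g for g, _s, _e in order if rng.random() < 0.4}
    got = detect_tandem_arrays(iap_ids, {"chr1": order}, cfg)
    got_groups = {}
    for g, a in got.items():
        got_groups.setdefault(a, set()).add(g)
    assert {frozenset(v) for v in got_groups.values()} == \
        _brute_force_arrays(iap_ids, order, cfg)


# ---------------------------------------------------------------------------
# Retroposition flags

def test_flag_retroposition():
    flags = flag_retroposition({
        "g1": [DomainHit("g1", "INTERPRO", "IPR002492", "Tc1", 0, 100, 1e-6)],
        "g2": [DomainHit("g2", "INTERPRO", "IPR000477",
                         "Reverse transcriptase", 0, 100, 1e-6)],
        "g3": [DomainHit("g3", "INTERPRO", "IPR013083", "RING", 0, 50, 1e-6)],
    })
    assert flags["g1"] == frozenset({"transposase_tc1"})
    assert flags["g2"] == frozenset({"reverse_transcriptase"})
    assert flags["g3"] == frozenset()


# ---------------------------------------------------------------------------
# Apoptosis annotation mining

def test_mine_rcd_whole_word_matching():
    catalog = {"caspase 3": ("caspase 3",), "AIF": ("AIF",)}
    products = [
        ("g1", "t1", "caspase 3-like protein"),
        ("g2", "t2", "uncharacterized protein LOC1"),
        ("g3", "t3", "RAIFX domain protein"),   # must not match inside a word
        ("g4", "t4", "AIF homolog"),
    ]
    out = mine_rcd_annotations(products, catalog)
    assert set(out["transcript_id"]) == {"t1", "t4"}
    assert out.loc[out.transcript_id == "t1", "matched_alias"].iloc[0] \
        == "caspase 3"


def test_mine_rcd_empty_catalog_errors():
    with pytest.raises(ValueError, match="empty"):
        mine_rcd_annotations([("g", "t", "x")], {})


def test_mine_rcd_case_insensitive():
    out = mine_rcd_annotations(
        [("g", "t", "Caspase 3, partial")], {"caspase 3": ("caspase 3",)})
    assert len(out) == 1


# ---------------------------------------------------------------------------
# Identity helper

def test_global_identity_exact_and_mutated():
    assert curation.global_identity("MKVLQACDEF", "MKVLQACDEF") == 1.0
    assert 0.85 <= curation.global_identity("MKVLQACDEF", "MKVLQACDEW") <= 0.95
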