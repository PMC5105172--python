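"""Transposon miner: TIR scan, pairing, TSD calls, SRR status, catalog."""

import numpy as np
import pytest

from inil import synthetic_forge as sf
from inil.core_io import GenomeAssembly, GenomicInterval, ScaffoldRecord, revcomp
from inil.synthetic_forge import SRR3, SRR5, TIR3, TIR5
from inil.tpn_miner import (FIVE_PRIME, THREE_PRIME, SrrSeed, TirHit, TirSeed,
                            TpnCatalog, TpnElement, TsdCall, call_tsd,
                            catalog_stats, detect_srr, annotate_gene_context,
                            nominate_elements, pair_tirs, scan_tirs)

from conftest import make_assembly

SEEDS = [TirSeed(FIVE_PRIME, TIR5), TirSeed(THREE_PRIME, TIR3)]
SRRS = [SrrSeed(FIVE_PRIME, SRR5), SrrSeed(THREE_PRIME, SRR3)]


def _bg(rng, n):
    return sf.random_background(rng, n, (0.25,) * 4).tobytes().decode()


# ----------------------------------------------------------- TIR scan ----

def test_scan_exact_hit():
    rng = np.random.default_rng(0)
    seq = _bg(rng, 100) + TIR5 + _bg(rng, 100)
    hits = scan_tirs(make_assembly(s1=seq), SEEDS, 0)
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end, h.end_type, h.strand, h.mismatches) == \
        (100, 128, FIVE_PRIME, "+", 0)


def test_scan_no_hit_and_bad_seed():
    asm = make_assembly(s1="A" * 500)
    assert scan_tirs(asm, [TirSeed(FIVE_PRIME, "C" * 28)], 3) == []
    with pytest.raises(ValueError, match="N"):
        TirSeed(FIVE_PRIME, "ACGTN" + "A" * 23)


def _sliding_window_oracle(seq, seeds, max_mm):
    """Exhaustive windowed Hamming comparison at every offset and strand."""
    from numpy.lib.stride_tricks import sliding_window_view
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    best = {}
    for seed in seeds:
        m = len(seed.seq)
        if arr.size < m:
            continue
        wins = sliding_window_view(arr, m)
        for strand, pat in (("+", seed.seq), ("-", revcomp(seed.seq))):
            p = np.frombuffer(pat.encode(), dtype=np.uint8)
            mm = (wins != p).sum(axis=1)
            for pos in np.nonzero(mm <= max_mm)[0]:
                key = (int(pos), seed.end_type)
                cand = (int(mm[pos]), strand)
                old = best.get(key)
                if (old is None or cand[0] < old[0]
                        or (cand[0] == old[0] and strand == "+")):
                    best[key] = cand
    return {(pos, et, s, k) for (pos, et), (k, s) in best.items()}


def test_scan_matches_sliding_window_oracle():
    rng = np.random.default_rng(7)
    seq = list(_bg(rng, 50_000))
    for k in range(10):
        copy = list(TIR5 if k % 2 == 0 else revcomp(TIR3))
        if k < 2:  # two copies carry 2 substitutions
            for i in rng.choice(28, size=2, replace=False):
                copy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[i]]
        pos = 1_000 + k * 4_500
        seq[pos:pos + 28] = copy
    seq = "".join(seq)
    hits = scan_tirs(make_assembly(s1=seq), SEEDS, 2)
    got = {(h.start, h.end_type, h.strand, h.mismatches) for h in hits}
    assert got == _sliding_window_oracle(seq, SEEDS, 2)
    assert len(hits) == 10


# ------------------------------------------------------------ pairing ----

def _mk_hit(start, end_type, strand, sid="s1", mm=0):
    return TirHit(sid, start, start + 28, end_type, strand, mm)


def test_pair_convergent():
    cands = pair_tirs([_mk_hit(100, FIVE_PRIME, "+"),
                       _mk_hit(1000, THREE_PRIME, "-")], 60, 50_000)
    assert len(cands) == 1
    assert (cands[0].start, cands[0].end, cands[0].orientation) == (100, 1028, "+")


def test_pair_rejects_same_type_and_bad_spans():
    assert pair_tirs([_mk_hit(100, FIVE_PRIME, "+"),
                      _mk_hit(1000, FIVE_PRIME, "+")], 60, 50_000) == []
    with pytest.raises(ValueError):
        pair_tirs([], 100, 100)


def test_pair_matches_all_pairs_oracle():
    rng = np.random.default_rng(5)
    hits = [_mk_hit(int(p),
                    FIVE_PRIME if rng.random() < 0.5 else THREE_PRIME,
                    "+" if rng.random() < 0.5 else "-")
            for p in rng.choice(40_000, size=20, replace=False)]
    got = {(c.start, c.end, c.orientation)
           for c in pair_tirs(hits, 60, 20_000)}
    want = set()
    for lh in hits:
        for rh in hits:
            if lh.scaffold_id != rh.scaffold_id or rh.start <= lh.start:
                continue
            if lh.strand != "+" or rh.strand != "-":
                continue
            if lh.end_type == rh.end_type:
                continue
            span = rh.end - lh.start
            if 60 <= span <= 20_000:
                want.add((lh.start, rh.end,
                          "+" if lh.end_type == FIVE_PRIME else "-"))
    assert got == want


# ---------------------------------------------------------------- TSD ----

def _candidate(asm, start, end):
    lh = TirHit("s1", start, start + 28, FIVE_PRIME, "+", 0)
    rh = TirHit("s1", end - 28, end, THREE_PRIME, "-", 0)
    from inil.tpn_miner import TpnCandidate
    return TpnCandidate("s1", start, end, lh, rh, "+")


def test_tsd_exact_3mer():
    body = "G" * 100
    asm = make_assembly(s1="CCCCC" + "TAA" + body + "TAA" + "CCCCC")
    tsd = call_tsd(asm, _candidate(asm, 8, 108))
    assert tsd == TsdCall(3, "TAA", "TAA", 0)


def test_tsd_prefers_longer_exact():
    body = "G" * 100
    asm = make_assembly(s1="ACGTA" + body + "ACGTA")
    tsd = call_tsd(asm, _candidate(asm, 5, 105))
    assert (tsd.length, tsd.left_seq, tsd.hamming) == (5, "ACGTA", 0)


def test_tsd_rejects_distant_flanks():
    asm = make_assembly(s1="CCAAA" + "G" * 100 + "CCCCC")
    assert call_tsd(asm, _candidate(asm, 5, 105)) is None


# ---------------------------------------------------------------- SRR ----

def _element_assembly(left_block, right_block, interior=3_000, seed=1):
    rng = np.random.default_rng(seed)
    body = TIR5 + left_block + _bg(rng, interior) + right_block + revcomp(TIR3)
    seq = _bg(rng, 300) + "TAT" + body + "TAT" + _bg(rng, 300)
    asm = make_assembly(s1=seq)
    return asm, _candidate(asm, 303, 303 + len(body))


def test_srr_canonical_plus():
    asm, cand = _element_assembly(SRR5 * 3, revcomp(SRR3 * 3))
    assert detect_srr(asm, cand, SRRS) == ("present", "present", "+")


def test_srr_mirrored_minus():
    asm, cand = _element_assembly(SRR5 * 3, revcomp(SRR3 * 3))
    rec = asm["s1"]
    flipped = make_assembly(s1=revcomp(rec.seq))
    L = rec.length
    cand2 = _candidate(flipped, L - cand.end, L - cand.start)
    srr5, srr3, orientation = detect_srr(flipped, cand2, SRRS)
    assert (srr5, srr3, orientation) == ("present", "present", "-")


def test_srr_single_degenerate_copy_is_rearranged():
    asm, cand = _element_assembly(SRR5 * 3, revcomp(SRR3))
    srr5, srr3, _ = detect_srr(asm, cand, SRRS)
    assert (srr5, srr3) == ("present", "rearranged")


# ----------------------------------------------------------- nominate ----

def test_nominate_recovers_forge_truth(forged_default):
    res = forged_default
    catalog = nominate_elements(res.assembly, res.tir_seeds, res.srr_seeds,
                                res.gene_models)
    truth = {(t["scaffold_id"], t["start"], t["end"]): t
             for t in res.truth if t["feature_type"].startswith("tpn_")}
    mined = {(e.scaffold_id, e.start, e.end): e for e in catalog.elements}
    assert mined.keys() == truth.keys()
    for key, t in truth.items():
        el = mined[key]
        assert el.tsd.left_seq == t["payload"]["tsd_left"]
        assert (el.tsd.hamming > 0) == t["payload"]["tsd_mismatch"]
        assert el.orientation == t["strand"]


def test_nominate_no_tsd_no_elements():
    rng = np.random.default_rng(3)
    body = TIR5 + _bg(rng, 500) + revcomp(TIR3)
    # flanks share nothing: poly-C left, poly-G right
    seq = _bg(rng, 100) + "CCCCC" + body + "GGGGG" + _bg(rng, 100)
    cat = nominate_elements(make_assembly(s1=seq), SEEDS, SRRS)
    assert len(cat) == 0


def test_nominate_nested_candidates_tie_break():
    """Two nested spans share a left TIR; greedy selection keeps exactly
    one, the one the documented tie-break chain picks."""
    rng = np.random.default_rng(8)
    inner = _bg(rng, 300)
    outer_tail = _bg(rng, 400)
    body_inner = TIR5 + inner + revcomp(TIR3)
    seq = ("TGA" + body_inner + "TGA" + outer_tail + revcomp(TIR3) + "TGA")
    seq = _bg(rng, 50) + seq + _bg(rng, 50)
    asm = make_assembly(s1=seq)
    hits = scan_tirs(asm, SEEDS, 0)
    cands = [c for c in pair_tirs(hits, 60, 50_000)
             if call_tsd(asm, c) is not None]
    assert len(cands) >= 2          # nested spans both validate
    cat = nominate_elements(asm, SEEDS, SRRS)
    assert len(cat) == 1
    # oracle: enumerate candidates, apply the chain by brute force
    ranked = sorted(
        ((c, call_tsd(asm, c)) for c in cands),
        key=lambda ct: (ct[0].left.mismatches + ct[0].right.mismatches,
                        ct[1].hamming, -ct[0].span, ct[0].start))
    best = ranked[0][0]
    assert (cat.elements[0].start, cat.elements[0].end) == (best.start, best.end)


def test_strand_symmetry(forged_default):
    """Mining the reverse-complemented genome yields the mirror catalog."""
    res = forged_default
    sub = GenomeAssembly([res.assembly.scaffolds[0]])
    fwd = nominate_elements(sub, res.tir_seeds, res.srr_seeds)
    rc = GenomeAssembly([ScaffoldRecord(r.id, revcomp(r.seq)) for r in sub])
    rev = nominate_elements(rc, res.tir_seeds, res.srr_seeds)
    L = sub.scaffolds[0].length
    mirrored = {(L - e.end, L - e.start,
                 "+" if e.orientation == "-" else "-") for e in fwd.elements}
    assert {(e.start, e.end, e.orientation) for e in rev.elements} == mirrored


def test_no_nominations_on_seedless_sequence():
    rng = np.random.default_rng(21)
    asm = make_assembly(s1=_bg(rng, 2_000_000))
    assert len(nominate_elements(asm, SEEDS, SRRS)) == 0


# --------------------------------------------------------- gene context ----

def _catalog_one(start, end):
    tsd = TsdCall(3, "TAA", "TAA", 0)
    return TpnCatalog([TpnElement("s1", start, end, tsd, "+")])


def test_context_priority_and_intergenic():
    features = [
        GenomicInterval("s1", 0, 1000, "+", "exon", {"gene_id": "gA"}),
        GenomicInterval("s1", 1000, 2000, "+", "intron", {"gene_id": "gA"}),
    ]
    # element straddles the exon/intron boundary; midpoint 950 is exonic
    cat = annotate_gene_context(_catalog_one(800, 1100), features)
    assert cat.elements[0].gene_context == "exon"
    assert cat.elements[0].parent_gene == "gA"
    cat = annotate_gene_context(_catalog_one(1200, 1400), features)
    assert cat.elements[0].gene_context == "intron"
    cat = annotate_gene_context(_catalog_one(5000, 5500), features)
    assert cat.elements[0].gene_context == "none"
    assert cat.elements[0].parent_gene is None


def test_forged_gene_context(forged_default):
    res = forged_default
    cat = nominate_elements(res.assembly, res.tir_seeds, res.srr_seeds,
                            res.gene_models)
    want = {(t["scaffold_id"], t["start"]): t["payload"]["gene_context"]
            for t in res.truth
            if t["feature_type"].startswith("tpn_")
            and "gene_context" in t["payload"]}
    got = {(e.scaffold_id, e.start): e.gene_context for e in cat.elements
           if e.gene_context != "none"}
    assert got == want


# ---------------------------------------------------------------- stats ----

def _dummy_element(length, tsd="TAA", hamming=0, srr="present"):
    return TpnElement("s1", 0, length, TsdCall(len(tsd), tsd, tsd, hamming),
                      "+", srr, srr)


def test_stats_lengths():
    cat = TpnCatalog([_dummy_element(100), _dummy_element(300)])
    s = cat.stats
    assert (s["mean_len"], s["min_len"], s["max_len"]) == (200, 100, 300)


def test_stats_at_fraction_counting():
    els = [_dummy_element(100, tsd="TAA") for _ in range(19)]
    els.append(_dummy_element(100, tsd="GCC"))
    assert TpnCatalog(els).stats["tsd_at_fraction"] == pytest.approx(0.95)


def test_stats_empty_catalog():
    s = catalog_stats(TpnCatalog([]))
    assert s["count"] == 0 and s["undefined_ratios"]


def test_stats_recomputable(forged_default):
    res = forged_default
    cat = nominate_elements(res.assembly, res.tir_seeds, res.srr_seeds)
    assert cat.stats == catalog_stats(cat)
    assert cat.stats["count"] == len(cat.elements)
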