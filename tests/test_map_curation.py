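"""Marker filters, chimera detection/splitting, pseudo-chromosome build."""

import numpy as np
import pandas as pd
import pytest

from inil import synthetic_forge as sf
from inil.core_io import (AlignmentHit, GapRun, GenomeAssembly, ScaffoldRecord,
                          find_gap_runs, revcomp)
from inil.map_curation import (LinkageMap, MarkerTable, apply_splits,
                               build_pseudochromosomes,
                               detect_contig_chimeras,
                               detect_scaffold_chimeras, filter_markers,
                               flank_repeat_filter, non_n_total,
                               reconstruct_from_agp, split_contig_three,
                               split_scaffold)

from conftest import make_assembly


def _table(geno: pd.DataFrame, positions=None) -> MarkerTable:
    markers = pd.DataFrame({
        "marker_id": geno.index,
        "scaffold_id": "s1",
        "position": positions if positions is not None
        else range(0, 1000 * len(geno), 1000)})
    return MarkerTable(markers, geno)


# ------------------------------------------------------------- 80/80 filter

def test_filter_drops_sub_threshold_marker():
    n = 100
    geno = pd.DataFrame("AA", index=[f"m{i}" for i in range(3)],
                        columns=[f"s{j}" for j in range(n)])
    geno.iloc[0, :21] = pd.NA        # present in 79% of samples
    out = filter_markers(_table(geno))
    assert list(out.genotypes.index) == ["m1", "m2"]


def test_filter_identity_on_complete_matrix():
    geno = pd.DataFrame("AB", index=[f"m{i}" for i in range(5)],
                        columns=[f"s{j}" for j in range(10)])
    out = filter_markers(_table(geno))
    assert out.genotypes.shape == (5, 10)
    assert out.flags["filter_rounds"][-1] == \
        {"markers_dropped": 0, "samples_dropped": 0}


def _fixed_point_oracle(mat: pd.DataFrame, marker_min, sample_min):
    """Naive loop re-applying both drops until nothing changes."""
    rows, cols = list(mat.index), list(mat.columns)
    while True:
        ok = lambda r: np.mean([mat.loc[r, c] != "NA" for c in cols])
        rows2 = [r for r in rows if np.mean(
            [mat.loc[r, c] != "NA" for c in cols]) >= marker_min]
        cols2 = [c for c in cols if not rows2 or np.mean(
            [mat.loc[r, c] != "NA" for r in rows2]) >= sample_min]
        if rows2 == rows and cols2 == cols:
            return rows, cols
        rows, cols = rows2, cols2


def test_filter_fixed_point_matches_iteration_oracle():
    rng = np.random.default_rng(13)
    mat = pd.DataFrame(
        np.where(rng.random((10, 10)) < 0.25, "NA", "AA"),
        index=[f"m{i}" for i in range(10)],
        columns=[f"s{j}" for j in range(10)])
    out = filter_markers(_table(mat.replace("NA", pd.NA)), 0.8, 0.8)
    rows, cols = _fixed_point_oracle(mat, 0.8, 0.8)
    assert list(out.genotypes.index) == rows
    assert list(out.genotypes.columns) == cols


def test_filter_monotone_in_marker_threshold():
    rng = np.random.default_rng(29)
    mat = pd.DataFrame(
        np.where(rng.random((20, 15)) < 0.3, pd.NA, "BB"),
        index=[f"m{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(15)])
    counts = [filter_markers(_table(mat), mm, 0.8).n_markers
              for mm in (0.5, 0.7, 0.9)]
    assert counts == sorted(counts, reverse=True)


def test_filter_empty_result_flags_not_raises():
    geno = pd.DataFrame(pd.NA, index=["m0"], columns=["s0", "s1"])
    out = filter_markers(_table(geno))
    assert out.flags["empty_after_filter"]


# ------------------------------------------------------ flank repeat filter

def _flank_hit(q, t, length):
    return AlignmentHit(q, 300, 0, min(300, length), t, 0, length, "+",
                        length, length, float(length))


def test_flank_filter_rules():
    geno = pd.DataFrame("AA", index=["m0", "m1", "m2"], columns=["s0"])
    table = _table(geno, positions=[200, 2_000, 5_000])
    asm = make_assembly(s1="A" * 10_000)
    hits = [_flank_hit("m0", "m0", 300),     # self-hit only -> kept
            _flank_hit("m1", "m2", 200),     # long non-self -> m1 dropped
            _flank_hit("m2", "m1", 120)]     # short non-self -> kept
    out = flank_repeat_filter(table, asm, hits, flank=150)
    assert list(out.markers["marker_id"]) == ["m0", "m2"]


def test_flank_clipped_marker_kept_and_flagged():
    geno = pd.DataFrame("AA", index=["m0"], columns=["s0"])
    table = _table(geno, positions=[50])   # flank runs off the left edge
    asm = make_assembly(s1="A" * 10_000)
    out = flank_repeat_filter(table, asm, [], flank=150)
    assert list(out.markers["marker_id"]) == ["m0"]
    assert out.flags["flank_clipped_markers"] == ["m0"]


# --------------------------------------------------- scaffold-level chimeras

def _marker_table(rows):
    df = pd.DataFrame(rows, columns=["marker_id", "scaffold_id", "position",
                                     "lg"])
    geno = pd.DataFrame(index=df["marker_id"])
    return MarkerTable(df, geno)


def test_scaffold_chimera_split_at_gap():
    seq = "A" * 5_000 + "N" * 100 + "C" * 5_000
    asm = make_assembly(s1=seq)
    table = _marker_table([
        ("a1", "s1", 500, 2), ("a2", "s1", 1_500, 2), ("a3", "s1", 2_500, 2),
        ("b1", "s1", 6_000, 7), ("b2", "s1", 7_000, 7)])
    (ev,) = detect_scaffold_chimeras(asm, table, find_gap_runs(asm, 10))
    assert ev.resolution == "split_two"
    assert (ev.junction.start, ev.junction.end) == (5_000, 5_100)
    assert (ev.left_lg, ev.right_lg) == (2, 7)


def test_scaffold_single_lg_no_event():
    asm = make_assembly(s1="A" * 1_000 + "N" * 50 + "C" * 1_000)
    table = _marker_table([("a1", "s1", 100, 1), ("a2", "s1", 1_500, 1)])
    assert detect_scaffold_chimeras(asm, table, find_gap_runs(asm, 10)) == []


def test_alternating_singletons_flagged_only():
    asm = make_assembly(s1="A" * 10_000)
    table = _marker_table([("a1", "s1", 1_000, 2), ("b1", "s1", 2_000, 7),
                           ("a2", "s1", 3_000, 2), ("b2", "s1", 4_000, 7)])
    events = detect_scaffold_chimeras(asm, table, [])
    assert events and all(e.resolution == "flagged_only" for e in events)


def test_junction_is_longest_gap_tie_leftmost():
    seq = ("A" * 1_000 + "N" * 30 + "A" * 1_000 + "N" * 80 + "A" * 1_000
           + "N" * 80 + "C" * 1_000)
    asm = make_assembly(s1=seq)
    table = _marker_table([("a1", "s1", 100, 1), ("a2", "s1", 500, 1),
                           ("b1", "s1", len(seq) - 500, 2),
                           ("b2", "s1", len(seq) - 100, 2)])
    (ev,) = detect_scaffold_chimeras(asm, table, find_gap_runs(asm, 10))
    assert (ev.junction.start, ev.junction.length) == (2_030, 80)


# --------------------------------------------------------------- splitting

def test_split_scaffold_lengths_and_roundtrip():
    seq = "A" * 5_000 + "N" * 100 + "C" * 4_900
    rec = ScaffoldRecord("s1", seq)
    left, right = split_scaffold(rec, GapRun("s1", 5_000, 5_100))
    assert (left.id, left.length) == ("s1_1", 5_000)
    assert (right.id, right.length) == ("s1_2", 4_900)
    assert left.seq + "N" * 100 + right.seq == seq


def test_split_at_edge_rejected():
    rec = ScaffoldRecord("s1", "N" * 20 + "A" * 100)
    with pytest.raises(ValueError, match="edge"):
        split_scaffold(rec, GapRun("s1", 0, 20))


def test_forged_chimera_suite(forged_chimeras):
    res = forged_chimeras
    gaps = find_gap_runs(res.assembly, 10)
    events = detect_scaffold_chimeras(res.assembly, res.markers, gaps)
    splits = {e.target_id: e for e in events if e.resolution == "split_two"}
    truth = {t["scaffold_id"]: t for t in res.truth
             if t["feature_type"] == "chimera_scaffold"}
    assert splits.keys() == truth.keys()
    for sid, ev in splits.items():
        t = truth[sid]
        assert (ev.junction.start, ev.junction.end) == \
            (t["start"], t["start"] + t["payload"]["gap_len"])
    # zero false splits among the clean chromosomes
    assert not any(e.target_id.startswith("chr") for e in splits.values())
    # splitting recovers the exact planted halves and conserves sequence
    before = non_n_total(res.assembly)
    split_asm, provenance = apply_splits(res.assembly, events)
    assert non_n_total(split_asm) == before
    for sid, t in truth.items():
        left, right = provenance[sid]
        assert split_asm[left].length == t["payload"]["left_len"]
        assert split_asm[right].length == t["payload"]["right_len"]


# ---------------------------------------------------- contig-level chimeras

def test_contig_three_part_boundaries():
    rec = ScaffoldRecord("c1", "A" * 100_000)
    table = _marker_table([
        ("a1", "c1", 10_000, 1), ("a2", "c1", 40_000, 1),
        ("b1", "c1", 60_000, 2), ("b2", "c1", 90_000, 2)])
    ev = detect_contig_chimeras(rec, table)
    assert ev.resolution == "split_three"
    assert ev.junction == (40_000, 60_000)
    parts = split_contig_three(rec, ev.junction)
    assert [p.length for p in parts] == [40_000, 20_000, 40_000]


def test_contig_single_lg_none():
    rec = ScaffoldRecord("c1", "A" * 10_000)
    table = _marker_table([("a1", "c1", 1_000, 1), ("a2", "c1", 9_000, 1)])
    assert detect_contig_chimeras(rec, table) is None


def test_contig_interleaved_flagged():
    rec = ScaffoldRecord("c1", "A" * 10_000)
    table = _marker_table([("a1", "c1", 1_000, 1), ("b1", "c1", 2_000, 2),
                           ("a2", "c1", 3_000, 1), ("b2", "c1", 4_000, 2)])
    ev = detect_contig_chimeras(rec, table)
    assert ev.resolution == "flagged_only"


def test_contig_bac_anchor_refines_left_edge():
    rec = ScaffoldRecord("c1", "A" * 100_000)
    table = _marker_table([
        ("a1", "c1", 10_000, 1), ("a2", "c1", 40_000, 1),
        ("b1", "c1", 60_000, 2), ("b2", "c1", 90_000, 2)])
    pair = (AlignmentHit("p/1", 500, 0, 500, "c1", 39_000, 39_500, "+",
                         500, 500, 500.0),
            AlignmentHit("p/2", 500, 0, 500, "c1", 47_500, 48_000, "-",
                         500, 500, 500.0))
    ev = detect_contig_chimeras(rec, table, bac_anchor_hits=[pair])
    assert ev.junction == (48_000, 60_000)


def test_forged_contig_chimeras_middle_contains_junction(forged_chimeras):
    res = forged_chimeras
    truth = {t["scaffold_id"]: t["payload"]["junction_point"]
             for t in res.truth if t["feature_type"] == "chimera_contig"}
    assert truth
    for sid, jp in truth.items():
        ev = detect_contig_chimeras(res.assembly[sid], res.markers)
        assert ev.resolution == "split_three"
        assert ev.junction[0] <= jp < ev.junction[1]


# ------------------------------------------------------- pseudochromosomes

def _map_and_markers(spec):
    """spec: list of (scaffold_id, [(marker, pos, lg, cM), ...])"""
    mrows, lrows = [], []
    for sid, markers in spec:
        for mid, pos, lg, cm in markers:
            mrows.append({"marker_id": mid, "scaffold_id": sid,
                          "position": pos})
            lrows.append({"lg": lg, "marker_id": mid, "cM": cm})
    mdf = pd.DataFrame(mrows)
    ldf = pd.DataFrame(lrows).sort_values(["lg", "cM"]).reset_index(drop=True)
    table = MarkerTable(mdf, pd.DataFrame(index=mdf["marker_id"]))
    return LinkageMap(ldf), table


def test_build_lengths_and_gap_arithmetic():
    asm = make_assembly(sA="A" * 1_000, sB="C" * 2_000, sC="G" * 3_000)
    lmap, table = _map_and_markers([
        ("sA", [("m1", 100, 1, 0.0), ("m2", 900, 1, 5.0)]),
        ("sB", [("m3", 100, 1, 10.0), ("m4", 1_900, 1, 15.0)]),
        ("sC", [("m5", 100, 1, 20.0), ("m6", 2_900, 1, 25.0)])])
    plans, pseudo, agp, stats = build_pseudochromosomes(
        asm, lmap, table, gap_size=100)
    assert pseudo["chr1"].length == 6_000 + 2 * 100
    assert [r["scaffold_id"] for r in plans[0].rows] == ["sA", "sB", "sC"]
    assert stats["anchored_fraction"] == 1.0


def test_build_reverse_orientation():
    asm = make_assembly(sA="ACGT" * 250, sB="C" * 1_000)
    lmap, table = _map_and_markers([
        ("sA", [("m1", 100, 1, 8.0), ("m2", 900, 1, 2.0)]),   # cM decreases
        ("sB", [("m3", 100, 1, 10.0), ("m4", 900, 1, 14.0)])])
    plans, pseudo, agp, _ = build_pseudochromosomes(asm, lmap, table,
                                                    gap_size=10)
    assert plans[0].rows[0]["scaffold_id"] == "sA"
    assert plans[0].rows[0]["orientation"] == "-"
    assert pseudo["chr1"].seq[:1_000] == revcomp(asm["sA"].seq)


def test_build_unoriented_single_marker():
    asm = make_assembly(sA="A" * 500, sB="C" * 500)
    lmap, table = _map_and_markers([
        ("sA", [("m1", 100, 1, 0.0)]),
        ("sB", [("m2", 100, 1, 5.0), ("m3", 400, 1, 9.0)])])
    plans, *_ = build_pseudochromosomes(asm, lmap, table)
    assert plans[0].rows[0]["orientation"] == "unoriented"


def test_build_anchored_fraction_half():
    asm = make_assembly(sA="A" * 1_000, sB="C" * 1_000,
                        sC="G" * 1_000, sD="T" * 1_000)
    lmap, table = _map_and_markers([
        ("sA", [("m1", 100, 1, 0.0), ("m2", 900, 1, 5.0)]),
        ("sB", [("m3", 100, 1, 10.0), ("m4", 900, 1, 15.0)])])
    _, pseudo, _, stats = build_pseudochromosomes(asm, lmap, table)
    assert stats["anchored_fraction"] == 0.5
    assert "sC" in pseudo and "sD" in pseudo    # unanchored pass through


def test_build_rejects_unresolved_chimera():
    asm = make_assembly(sA="A" * 1_000)
    lmap, table = _map_and_markers([
        ("sA", [("m1", 100, 1, 0.0), ("m2", 900, 2, 0.0)])])
    with pytest.raises(ValueError, match="chimera"):
        build_pseudochromosomes(asm, lmap, table)


def test_agp_reconstruction_and_conservation(forged_default, tmp_path):
    res = forged_default
    plans, pseudo, agp, stats = build_pseudochromosomes(
        res.assembly, res.linkage_map, res.markers, gap_size=100)
    rebuilt = reconstruct_from_agp(agp, res.assembly)
    for plan in plans:
        assert rebuilt[plan.chromosome_id].seq == pseudo[plan.chromosome_id].seq
    assert non_n_total(pseudo) == non_n_total(res.assembly)
    # AGP survives a write/load round trip
    from inil.map_curation import load_agp, write_agp
    p = tmp_path / "x.agp"
    write_agp(agp, p)
    assert load_agp(p) == [list(r) for r in agp]
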