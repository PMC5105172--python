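"""Linkage-map-guided assembly curation.

Covers the map-facing half of the curation workflow: the 80/80
marker/sample genotype filter, the 150-bp flank repeat filter, chimera
detection and splitting at scaffold level (split at an intervening N gap)
and contig level (three-way split bracketing the transition), and
pseudo-chromosome construction (order by median cM, orient by marker-order
concordance, join with N spacers, emit AGP v2.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .core_io import (AlignmentHit, GapRun, GenomeAssembly, ScaffoldRecord,
                      revcomp)

MISSING = "NA"
GENOTYPES = {"AA", "AB", "BB"}


@dataclass
class MarkerTable:
    """Marker metadata plus the marker x sample genotype matrix.

    ``markers``: DataFrame with columns marker_id, scaffold_id, position
    (0-based), optionally lg and cM. ``genotypes``: DataFrame indexed by
    marker_id, one column per sample, values in {AA, AB, BB} or NA.
    """

    markers: pd.DataFrame
    genotypes: pd.DataFrame
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.markers["marker_id"].is_unique:
            raise ValueError("marker ids must be unique")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class LinkageMap:
    """Ordered markers per linkage group."""

    table: pd.DataFrame  # columns: lg, marker_id, cM

    def __post_init__(self) -> None:
        if self.table["marker_id"].duplicated().any():
            raise ValueError("a marker may appear in only one linkage group")
        for lg, grp in self.table.groupby("lg"):
            if (grp["cM"].diff().dropna() < 0).any():
                raise ValueError(f"cM not non-decreasing in group {lg}")

    @property
    def groups(self) -> list:
        return list(dict.fromkeys(self.table["lg"]))

    def lg_of(self) -> dict[str, object]:
        return dict(zip(self.table["marker_id"], self.table["lg"]))

    def cm_of(self) -> dict[str, float]:
        return dict(zip(self.table["marker_id"], self.table["cM"]))


@dataclass
class ChimeraEvent:
    target_id: str
    level: str                     # scaffold | contig
    junction: GapRun | tuple[int, int] | None
    left_lg: object
    right_lg: object
    resolution: str                # split_two | split_three | flagged_only


@dataclass
class PseudoChromosomePlan:
    chromosome_id: str
    rows: list[dict]               # scaffold_id, orientation, gap_after
    anchored_length: int = 0


# ---------------------------------------------------------------------------
# Marker filtering
# ---------------------------------------------------------------------------

def filter_markers(table: MarkerTable, marker_min: float = 0.80,
                   sample_min: float = 0.80) -> MarkerTable:
    """Iterate the completeness filter to a fixed point.

    Each round first drops markers genotyped in fewer than ``marker_min``
    of the current samples, then drops samples carrying fewer than
    ``sample_min`` of the surviving markers. Per-round drop counts are
    recorded in ``flags['filter_rounds']``.
    """
    if not (0 < marker_min <= 1 and 0 < sample_min <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    geno = table.genotypes.copy()
    rounds: list[dict] = []
    while True:
        present = geno.notna() & geno.isin(GENOTYPES)
        keep_m = present.mean(axis=1) >= marker_min
        geno2 = geno.loc[keep_m]
        present2 = geno2.notna() & geno2.isin(GENOTYPES)
        if len(geno2):
            keep_s = present2.mean(axis=0) >= sample_min
        else:
            keep_s = pd.Series(True, index=geno2.columns)
        geno3 = geno2.loc[:, keep_s]
        rounds.append({"markers_dropped": int((~keep_m).sum()),
                       "samples_dropped": int((~keep_s).sum())})
        if rounds[-1]["markers_dropped"] == 0 and rounds[-1]["samples_dropped"] == 0:
            break
        geno = geno3
    flags = dict(table.flags)
    flags["filter_rounds"] = rounds
    flags["empty_after_filter"] = geno3.shape[0] == 0 or geno3.shape[1] == 0
    markers = table.markers[table.markers["marker_id"].isin(geno3.index)]
    return MarkerTable(markers.reset_index(drop=True), geno3, flags)


def flank_repeat_filter(table: MarkerTable, assembly: GenomeAssembly,
                        self_alignments: Sequence[AlignmentHit],
                        flank: int = 150) -> MarkerTable:
    """Drop markers whose SNP-flank region aligns elsewhere for > ``flank`` bases.

    ``self_alignments`` is the all-vs-all alignment of the extracted flank
    regions; a hit is non-self when query and target ids differ. Markers
    whose flanks run off their scaffold are clipped, kept, and flagged.
    """
    repetitive: set[str] = set()
    for h in self_alignments:
        if h.query_id != h.target_id and h.align_len > flank:
            repetitive.add(h.query_id)
    clipped = []
    for _, row in table.markers.iterrows():
        if row["scaffold_id"] in assembly:
            L = assembly[row["scaffold_id"]].length
            if row["position"] < flank or row["position"] + flank > L:
                clipped.append(row["marker_id"])
    keep = ~table.markers["marker_id"].isin(repetitive)
    markers = table.markers[keep].reset_index(drop=True)
    flags = dict(table.flags)
    flags["flank_clipped_markers"] = clipped
    flags["flank_repetitive_dropped"] = int((~keep).sum())
    return MarkerTable(markers, table.genotypes.loc[markers["marker_id"]], flags)


def extract_flank_regions(table: MarkerTable, assembly: GenomeAssembly,
                          flank: int = 150) -> dict[str, str]:
    """SNP-flank region (up to 2*flank bases around each marker), clipped
    at scaffold edges; keyed by marker id for the all-vs-all alignment."""
    regions = {}
    for _, row in table.markers.iterrows():
        rec = assembly[row["scaffold_id"]]
        pos = int(row["position"])
        regions[row["marker_id"]] = rec.seq[max(0, pos - flank):
                                            min(rec.length, pos + flank)]
    return regions


# ---------------------------------------------------------------------------
# Chimera detection and splitting
# ---------------------------------------------------------------------------

def _lg_blocks(positions: Sequence[int], lgs: Sequence[object]
               ) -> list[tuple[object, int, int, int]]:
    """Runs of consecutive same-LG markers: (lg, count, first_pos, last_pos)."""
    blocks = []
    for pos, lg in sorted(zip(positions, lgs)):
        if blocks and blocks[-1][0] == lg:
            lg0, n, first, _ = blocks[-1]
            blocks[-1] = (lg0, n + 1, first, pos)
        else:
            blocks.append((lg, 1, pos, pos))
    return blocks


def detect_scaffold_chimeras(assembly: GenomeAssembly,
                             markers: MarkerTable,
                             gap_runs: Sequence[GapRun],
                             min_block: int = 2) -> list[ChimeraEvent]:
    """Call a chimera where two >= min_block marker blocks of different
    linkage groups are separated by an N gap.

    The junction is the longest gap run strictly between the blocks (tie:
    leftmost). Conflicting LG signals without a qualifying block pair and
    gap are reported as ``flagged_only``.
    """
    if min_block < 2:
        raise ValueError("min_block must be >= 2")
    if "lg" not in markers.markers.columns:
        raise ValueError("markers need an 'lg' column")
    gaps_by_scaffold: dict[str, list[GapRun]] = {}
    for g in gap_runs:
        gaps_by_scaffold.setdefault(g.scaffold_id, []).append(g)
    events: list[ChimeraEvent] = []
    df = markers.markers.dropna(subset=["lg"])
    for sid, grp in df.groupby("scaffold_id", sort=False):
        if sid not in assembly:
            continue
        blocks = _lg_blocks(grp["position"].tolist(), grp["lg"].tolist())
        if len({b[0] for b in blocks}) < 2:
            continue
        found_split = False
        for left, right in zip(blocks, blocks[1:]):
            if left[0] == right[0] or left[1] < min_block or right[1] < min_block:
                continue
            between = [g for g in gaps_by_scaffold.get(sid, [])
                       if g.start >= left[3] and g.end <= right[2]]
            if between:
                junction = max(between, key=lambda g: (g.length, -g.start))
                events.append(ChimeraEvent(sid, "scaffold", junction,
                                           left[0], right[0], "split_two"))
                found_split = True
            else:
                events.append(ChimeraEvent(sid, "scaffold", None,
                                           left[0], right[0], "flagged_only"))
                found_split = True
        if not found_split:
            first_lg = blocks[0][0]
            other = next(b[0] for b in blocks if b[0] != first_lg)
            events.append(ChimeraEvent(sid, "scaffold", None, first_lg,
                                       other, "flagged_only"))
    return events


def split_scaffold(scaffold: ScaffoldRecord, junction: GapRun
                   ) -> tuple[ScaffoldRecord, ScaffoldRecord]:
    """Split at an N-gap junction, discarding the gap itself."""
    if junction.start <= 0 or junction.end >= scaffold.length:
        raise ValueError("junction at scaffold edge")
    left = ScaffoldRecord(f"{scaffold.id}_1", scaffold.seq[:junction.start])
    right = ScaffoldRecord(f"{scaffold.id}_2", scaffold.seq[junction.end:])
    return left, right


def detect_contig_chimeras(contig: ScaffoldRecord, markers: MarkerTable,
                           bac_anchor_hits: Sequence[tuple[AlignmentHit,
                                                           AlignmentHit]] = (),
                           min_block: int = 2) -> ChimeraEvent | None:
    """Three-way split plan for a gap-free chimeric contig.

    The left part ends at the last marker of the first LG block (extended
    rightward by a concordant BAC-end pair lying entirely left of the
    second block); the right part starts at the first marker of the
    second block; the middle keeps the (shortened) chimeric junction.
    Interleaved blocks yield ``flagged_only``.
    """
    df = markers.markers
    grp = df[(df["scaffold_id"] == contig.id) & df["lg"].notna()]
    if grp.empty:
        return None
    blocks = _lg_blocks(grp["position"].tolist(), grp["lg"].tolist())
    distinct = list(dict.fromkeys(b[0] for b in blocks))
    if len(distinct) < 2:
        return None
    pair = next(
        ((left, right) for left, right in zip(blocks, blocks[1:])
         if left[0] != right[0] and left[1] >= min_block
         and right[1] >= min_block), None)
    if pair is None:
        # two LGs present but interleaved / sub-threshold blocks only
        return ChimeraEvent(contig.id, "contig", None,
                            distinct[0], distinct[1], "flagged_only")
    first, second = pair
    left_edge, right_edge = first[3], second[2]
    if left_edge >= right_edge:
        return ChimeraEvent(contig.id, "contig", None,
                            first[0], second[0], "flagged_only")
    for h1, h2 in bac_anchor_hits:
        if h1.target_id != contig.id or h2.target_id != contig.id:
            continue
        lo = min(h1.target_start, h2.target_start)
        hi = max(h1.target_end, h2.target_end)
        # concordant pair wholly left of the second block refines the left
        # edge; wholly right of the first block refines the right edge
        if hi < right_edge and hi > left_edge and lo <= left_edge:
            left_edge = hi
        elif lo > left_edge and lo < right_edge and hi >= right_edge:
            right_edge = lo
    return ChimeraEvent(contig.id, "contig", (left_edge, right_edge),
                        first[0], second[0], "split_three")


def split_contig_three(contig: ScaffoldRecord, breakpoints: tuple[int, int]
                       ) -> tuple[ScaffoldRecord, ScaffoldRecord, ScaffoldRecord]:
    """Materialise a split_three plan: left / middle (still chimeric) / right."""
    a, b = breakpoints
    if not (0 < a < b < contig.length):
        raise ValueError("breakpoints must be strictly inside the contig")
    return (ScaffoldRecord(f"{contig.id}_1", contig.seq[:a]),
            ScaffoldRecord(f"{contig.id}_2", contig.seq[a:b]),
            ScaffoldRecord(f"{contig.id}_3", contig.seq[b:]))


def apply_splits(assembly: GenomeAssembly, events: Iterable[ChimeraEvent]
                 ) -> tuple[GenomeAssembly, dict[str, list[str]]]:
    """Apply split_two/split_three events; returns the new assembly and a
    provenance map parent -> children."""
    provenance: dict[str, list[str]] = {}
    replacements: dict[str, list[ScaffoldRecord]] = {}
    for ev in events:
        if ev.resolution == "split_two":
            parent = assembly[ev.target_id]
            children = list(split_scaffold(parent, ev.junction))
        elif ev.resolution == "split_three":
            parent = assembly[ev.target_id]
            children = list(split_contig_three(parent, ev.junction))
        else:
            continue
        replacements[ev.target_id] = children
        provenance[ev.target_id] = [c.id for c in children]
    out: list[ScaffoldRecord] = []
    for rec in assembly:
        out.extend(replacements.get(rec.id, [rec]))
    return GenomeAssembly(out), provenance


# ---------------------------------------------------------------------------
# Pseudo-chromosome construction
# ---------------------------------------------------------------------------

def build_pseudochromosomes(assembly: GenomeAssembly, linkage_map: LinkageMap,
                            markers: MarkerTable, gap_size: int = 100
                            ) -> tuple[list[PseudoChromosomePlan],
                                       GenomeAssembly, list[list], dict]:
    """Order, orient and join anchored scaffolds per linkage group.

    Returns (plans, pseudo-chromosome assembly incl. unanchored scaffolds,
    AGP rows, anchoring stats). Scaffolds are ordered by the median cM of
    their markers; orientation is the sign of the Kendall concordance
    between marker position and cM ("-" scaffolds are reverse-
    complemented); scaffolds with fewer than two informative markers or a
    tied concordance are kept as "+" but flagged unoriented. A scaffold
    whose markers point at two linkage groups is an error — the chimera
    stage must run first.
    """
    lg_of = linkage_map.lg_of()
    cm_of = linkage_map.cm_of()
    df = markers.markers
    df = df[df["marker_id"].isin(lg_of)]
    per_scaffold: dict[str, pd.DataFrame] = {
        sid: grp for sid, grp in df.groupby("scaffold_id") if sid in assembly}

    assignments: dict[str, object] = {}
    for sid, grp in per_scaffold.items():
        lgs = {lg_of[m] for m in grp["marker_id"]}
        if len(lgs) > 1:
            raise ValueError(
                f"scaffold {sid} has markers in linkage groups {sorted(map(str, lgs))}; "
                "resolve chimeras first")
        assignments[sid] = lgs.pop()

    plans: list[PseudoChromosomePlan] = []
    agp_rows: list[list] = []
    out_records: list[ScaffoldRecord] = []
    anchored_len = 0
    for lg in linkage_map.groups:
        members = [sid for sid, g in assignments.items() if g == lg]
        if not members:
            continue
        med = {sid: float(np.median([cm_of[m] for m in
                                     per_scaffold[sid]["marker_id"]]))
               for sid in members}
        members.sort(key=lambda sid: (med[sid], sid))
        rows, parts = [], []
        pos = 0
        part_no = 0
        chrom_id = f"chr{lg}"
        for i, sid in enumerate(members):
            grp = per_scaffold[sid]
            orientation, flagged = _orient(grp, cm_of)
            rec = assembly[sid]
            seq = rec.seq if orientation != "-" else revcomp(rec.seq)
            parts.append(seq)
            gap_after = gap_size if i < len(members) - 1 else 0
            rows.append({"scaffold_id": sid,
                         "orientation": orientation if not flagged else "unoriented",
                         "gap_after": gap_after})
            part_no += 1
            agp_rows.append([chrom_id, pos + 1, pos + rec.length,
                             part_no, "W", sid, 1, rec.length,
                             orientation if orientation == "-" else "+"])
            pos += rec.length
            anchored_len += rec.length
            if gap_after:
                part_no += 1
                agp_rows.append([chrom_id, pos + 1, pos + gap_after,
                                 part_no, "N", gap_after,
                                 "scaffold", "yes", "map"])
                parts.append("N" * gap_after)
                pos += gap_after
        plans.append(PseudoChromosomePlan(
            chrom_id, rows, anchored_length=sum(
                assembly[r["scaffold_id"]].length for r in rows)))
        out_records.append(ScaffoldRecord(chrom_id, "".join(parts)))
    for rec in assembly:
        if rec.id not in assignments:
            out_records.append(rec)
    stats = {
        "anchored_scaffolds": len(assignments),
        "total_scaffolds": len(assembly),
        "anchored_length": anchored_len,
        "total_length": assembly.total_length,
        "anchored_fraction": (anchored_len / assembly.total_length
                              if assembly.total_length else 0.0),
        "n_pseudochromosomes": len(plans),
    }
    return plans, GenomeAssembly(out_records), agp_rows, stats


def _orient(grp: pd.DataFrame, cm_of: Mapping[str, float]) -> tuple[str, bool]:
    pos = grp["position"].to_numpy(dtype=float)
    cm = np.array([cm_of[m] for m in grp["marker_id"]], dtype=float)
    informative = len({(p, c) for p, c in zip(pos, cm)})
    if len(pos) < 2 or informative < 2:
        return "+", True
    tau = kendalltau(pos, cm).statistic
    if np.isnan(tau) or tau == 0:
        return "+", True
    return ("+" if tau > 0 else "-"), False


# ---------------------------------------------------------------------------
# AGP v2.0 I/O and reconstruction
# ---------------------------------------------------------------------------

def write_agp(agp_rows: Sequence[Sequence], path) -> None:
    with open(path, "w") as out:
        out.write("##agp-version\t2.0\n")
        for row in agp_rows:
            out.write("\t".join(map(str, row)) + "\n")


def load_agp(path) -> list[list]:
    rows = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[4] in ("N", "U"):
                rows.append([f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                             int(f[5]), f[6], f[7], f[8]])
            else:
                rows.append([f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                             f[5], int(f[6]), int(f[7]), f[8]])
    return rows


def reconstruct_from_agp(agp_rows: Sequence[Sequence],
                         assembly: GenomeAssembly) -> GenomeAssembly:
    """Rebuild object sequences from AGP rows plus their component scaffolds."""
    objects: dict[str, list[str]] = {}
    for row in agp_rows:
        parts = objects.setdefault(row[0], [])
        if row[4] in ("N", "U"):
            parts.append("N" * int(row[5]))
        else:
            comp = assembly[row[5]]
            seq = comp.seq[int(row[6]) - 1:int(row[7])]
            parts.append(revcomp(seq) if row[8] == "-" else seq)
    return GenomeAssembly(
        [ScaffoldRecord(name, "".join(parts)) for name, parts in objects.items()])


def non_n_total(assembly: GenomeAssembly) -> int:
    """Total non-N bases — the conserved quantity across splits and joins."""
    return sum(rec.length - rec.seq.upper().count("N") for rec in assembly)
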