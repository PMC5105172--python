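"""Tandem-repeat landscape: telomeres, centromeres, rDNA/NOR cataloguing.

Detection is monomer-seeded: given a known repeat unit (the 7-bp telomeric
``AAACCCT``, a ~173-bp centromeric satellite, rDNA component seeds), maximal
tandem arrays are located by approximate matching, merged, and classified.
Period inference for an unknown satellite uses minimum-normalised-Hamming
self-alignment of a window against itself at candidate lags.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_io import AlignmentHit, GenomeAssembly, revcomp, seq_to_array
from .tpn_miner import hamming_scan

RDNA_COMPONENTS = ("18S", "5.8S", "25S")


@dataclass
class TandemArray:
    """A maximal tandem stretch of one monomer; copies may be fractional."""

    scaffold_id: str
    start: int
    end: int
    monomer: str
    identity: float
    strand: str

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def copies(self) -> float:
        return self.span / len(self.monomer)


@dataclass
class TelomereCall:
    scaffold_id: str
    status: str  # both_ends | one_end | internal_only | fully_telomeric | none
    arrays: list[TandemArray] = field(default_factory=list)


@dataclass
class CentromereStretch:
    scaffold_id: str
    start: int
    end: int
    merged_from: int
    monomer_len: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class RdnaUnit:
    scaffold_id: str
    start: int
    end: int
    strand: str
    components: tuple[str, ...]

    @property
    def complete(self) -> bool:
        return self.components == RDNA_COMPONENTS


@dataclass
class FiveSCluster:
    scaffold_id: str
    start: int
    end: int
    n_copies: int


# ---------------------------------------------------------------------------
# Monomer-seeded tandem array detection
# ---------------------------------------------------------------------------

def _extend_periodic(seq: str, start: int, end: int, period: int
                     ) -> tuple[int, int]:
    """Grow [start,end) while the sequence continues its own period exactly."""
    L = len(seq)
    while end < L and seq[end] == seq[end - period]:
        end += 1
    while start > 0 and seq[start - 1] == seq[start - 1 + period]:
        start -= 1
    return start, end


def _arrays_one_strand(rec_id: str, seq: str, arr: np.ndarray, monomer: str,
                       min_copies: int, max_divergence: float, strand: str
                       ) -> list[TandemArray]:
    m = len(monomer)
    max_mm = int(max_divergence * m)
    idx, mism = hamming_scan(arr, monomer, max_mm)
    if idx.size == 0:
        return []
    out: list[TandemArray] = []
    runs: list[list[int]] = [[0]]
    for i in range(1, idx.size):
        # chain matches whose starts advance by about one period; merge
        # runs separated by less than one monomer length
        if idx[i] - idx[runs[-1][-1]] <= 2 * m - 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    for run in runs:
        starts = idx[run]
        core_s, core_e = int(starts[0]), int(starts[-1]) + m
        s, e = _extend_periodic(seq, core_s, core_e, m)
        if e - s < m * min_copies:
            continue
        matched = mism[run]
        identity = 1.0 - float(np.mean(matched)) / m
        out.append(TandemArray(rec_id, s, e, monomer, identity, strand))
    return out


def _merge_adjacent(arrays: list[TandemArray], max_gap: int) -> list[TandemArray]:
    if not arrays:
        return arrays
    arrays = sorted(arrays, key=lambda a: a.start)
    merged = [arrays[0]]
    for a in arrays[1:]:
        last = merged[-1]
        if a.start - last.end < max_gap:
            merged[-1] = TandemArray(
                last.scaffold_id, last.start, max(last.end, a.end),
                last.monomer,
                min(last.identity, a.identity), last.strand)
        else:
            merged.append(a)
    return merged


def find_tandem_arrays(assembly: GenomeAssembly, monomer: str,
                       min_copies: int = 2,
                       max_divergence: float = 0.1) -> list[TandemArray]:
    """Maximal tandem arrays of (rotations of) a monomer on either strand.

    Each detected unit matches the monomer with at most ``max_divergence``
    mismatch fraction; phase/rotation is irrelevant because the matched
    core is extended outward by exact self-periodic comparison, so partial
    units at the edges contribute fractional copies (span / monomer
    length). Runs on the same strand closer than one monomer length are
    merged.
    """
    if len(monomer) < 2:
        raise ValueError("monomer must be at least 2 bases")
    if not (0 <= max_divergence < 0.5):
        raise ValueError("max_divergence must be in [0, 0.5)")
    monomer = monomer.upper()
    out: list[TandemArray] = []
    for rec in assembly:
        seq = rec.seq.upper()
        arr = seq_to_array(seq)
        for strand, unit in (("+", monomer), ("-", revcomp(monomer))):
            found = _arrays_one_strand(rec.id, seq, arr, unit, min_copies,
                                       max_divergence, strand)
            out.extend(_merge_adjacent(found, len(monomer)))
    # a strand-symmetric monomer yields the same span twice; keep "+"
    uniq: dict[tuple[str, int, int], TandemArray] = {}
    for a in out:
        key = (a.scaffold_id, a.start, a.end)
        if key not in uniq or a.strand == "+":
            uniq[key] = a
    return sorted(uniq.values(), key=lambda a: (a.scaffold_id, a.start, a.strand))


# ---------------------------------------------------------------------------
# Telomere classification
# ---------------------------------------------------------------------------

def classify_telomeres(assembly: GenomeAssembly,
                       arrays: Sequence[TandemArray],
                       end_window: int = 10_000,
                       full_cover_fraction: float = 0.95
                       ) -> list[TelomereCall]:
    """Classify each scaffold by where its telomeric arrays sit.

    ``fully_telomeric`` (array coverage >= full_cover_fraction of the
    scaffold) overrides the positional statuses.
    """
    by_scaffold: dict[str, list[TandemArray]] = {}
    for a in arrays:
        by_scaffold.setdefault(a.scaffold_id, []).append(a)
    calls = []
    for rec in assembly:
        sc_arrays = by_scaffold.get(rec.id, [])
        if not sc_arrays:
            calls.append(TelomereCall(rec.id, "none", []))
            continue
        L = rec.length
        covered = sum(a.span for a in sc_arrays)
        left = any(a.start < end_window for a in sc_arrays)
        right = any(a.end > L - end_window for a in sc_arrays)
        if covered / L >= full_cover_fraction:
            status = "fully_telomeric"
        elif left and right:
            status = "both_ends"
        elif left or right:
            status = "one_end"
        else:
            status = "internal_only"
        calls.append(TelomereCall(rec.id, status, sc_arrays))
    return calls


# ---------------------------------------------------------------------------
# Period inference
# ---------------------------------------------------------------------------

def infer_monomer(window: str, max_period: int = 500,
                  max_mismatch_fraction: float = 0.25
                  ) -> tuple[int, str] | None:
    """Dominant tandem period and majority consensus of a window, or None.

    The period is the lag minimising the normalised Hamming distance of
    the window against itself; among lags within 0.01 of the minimum the
    smallest is taken, so the fundamental period wins over its multiples.
    """
    window = window.upper()
    if len(window) < 4 * max_period:
        max_period = max(2, len(window) // 4)
    arr = seq_to_array(window)
    n = arr.size
    fracs = np.ones(max_period + 1)
    for k in range(2, max_period + 1):
        fracs[k] = np.mean(arr[:-k] != arr[k:])
    best = float(fracs[2:].min())
    if best > max_mismatch_fraction:
        return None
    period = int(np.nonzero(fracs[2:] <= best + 0.01)[0][0]) + 2
    cols: list[Counter] = [Counter() for _ in range(period)]
    for i, c in enumerate(window):
        cols[i % period][c] += 1
    consensus = "".join(c.most_common(1)[0][0] for c in cols)
    return period, consensus


# ---------------------------------------------------------------------------
# Centromere candidates
# ---------------------------------------------------------------------------

def find_centromere_candidates(arrays: Sequence[TandemArray],
                               min_stretch: int = 3_000,
                               merge_gap: int = 50_000,
                               monomer_len_range: tuple[int, int] = (160, 190)
                               ) -> tuple[list[CentromereStretch],
                                          dict[str, CentromereStretch]]:
    """Merge >3-kb centromeric-satellite arrays within 50 kb and report the
    longest merged stretch per scaffold/chromosome."""
    lo, hi = monomer_len_range
    eligible = sorted(
        (a for a in arrays
         if lo <= len(a.monomer) <= hi and a.span > min_stretch),
        key=lambda a: (a.scaffold_id, a.start))
    stretches: list[CentromereStretch] = []
    for a in eligible:
        last = stretches[-1] if stretches else None
        if (last is not None and last.scaffold_id == a.scaffold_id
                and a.start - last.end <= merge_gap):
            stretches[-1] = CentromereStretch(
                last.scaffold_id, last.start, max(last.end, a.end),
                last.merged_from + 1, last.monomer_len)
        else:
            stretches.append(CentromereStretch(
                a.scaffold_id, a.start, a.end, 1, len(a.monomer)))
    longest: dict[str, CentromereStretch] = {}
    for st in stretches:
        cur = longest.get(st.scaffold_id)
        if cur is None or st.span > cur.span:
            longest[st.scaffold_id] = st
    return stretches, longest


# ---------------------------------------------------------------------------
# rDNA / NOR units and 5S clusters
# ---------------------------------------------------------------------------

def _component_of(hit: AlignmentHit) -> str:
    return hit.query_id.split("_")[0]


def detect_rdna_units(hits: Iterable[AlignmentHit],
                      unit_spacing: int = 5_000,
                      cluster_gap: int = 50_000
                      ) -> tuple[list[RdnaUnit], list[FiveSCluster]]:
    """Chain 18S->5.8S->25S hits into NOR units; cluster 5S hits.

    Hit component labels are taken from the query id (text before the
    first underscore); anything outside {18S, 5.8S, 25S, 5S} is an error.
    On the minus strand the genomic order of a unit is mirrored
    (25S, 5.8S, 18S by coordinate). Each hit joins at most one unit.
    """
    allowed = set(RDNA_COMPONENTS) | {"5S"}
    by_scaffold: dict[str, list[AlignmentHit]] = {}
    five_s: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        comp = _component_of(h)
        if comp not in allowed:
            raise ValueError(f"unknown rDNA component label {comp!r}")
        if comp == "5S":
            five_s.setdefault(h.target_id, []).append(h)
        else:
            by_scaffold.setdefault(h.target_id, []).append(h)

    units: list[RdnaUnit] = []
    for sid, shits in by_scaffold.items():
        for strand in "+-":
            order = (RDNA_COMPONENTS if strand == "+"
                     else tuple(reversed(RDNA_COMPONENTS)))
            pool = sorted((h for h in shits if h.strand == strand),
                          key=lambda h: h.target_start)
            used = [False] * len(pool)
            for i, h in enumerate(pool):
                if used[i] or _component_of(h) != order[0]:
                    continue
                chain = [i]
                for want in order[1:]:
                    prev = pool[chain[-1]]
                    nxt = next(
                        (j for j in range(chain[-1] + 1, len(pool))
                         if not used[j] and _component_of(pool[j]) == want
                         and 0 <= pool[j].target_start - prev.target_end
                         <= unit_spacing), None)
                    if nxt is None:
                        break
                    chain.append(nxt)
                if len(chain) == 3:
                    for j in chain:
                        used[j] = True
                    units.append(RdnaUnit(
                        sid, pool[chain[0]].target_start,
                        pool[chain[-1]].target_end, strand, RDNA_COMPONENTS))
    units.sort(key=lambda u: (u.scaffold_id, u.start))

    clusters: list[FiveSCluster] = []
    for sid, shits in five_s.items():
        shits = sorted(shits, key=lambda h: h.target_start)
        cur = [shits[0]]
        for h in shits[1:]:
            if h.target_start - cur[-1].target_end <= cluster_gap:
                cur.append(h)
            else:
                clusters.append(FiveSCluster(
                    sid, cur[0].target_start, cur[-1].target_end, len(cur)))
                cur = [h]
        clusters.append(FiveSCluster(
            sid, cur[0].target_start, cur[-1].target_end, len(cur)))
    clusters.sort(key=lambda c: (c.scaffold_id, c.start))
    return units, clusters


def nor_summary(units: Sequence[RdnaUnit],
                clusters: Sequence[FiveSCluster]) -> dict:
    """Per-scaffold NOR unit counts and 5S totals, JSON-ready."""
    per_scaffold: dict[str, int] = {}
    for u in units:
        per_scaffold[u.scaffold_id] = per_scaffold.get(u.scaffold_id, 0) + 1
    return {
        "nor_units_per_scaffold": per_scaffold,
        "n_nor_scaffolds": len(per_scaffold),
        "n_5s_clusters": len(clusters),
        "n_5s_copies": sum(c.n_copies for c in clusters),
        "n_5s_scaffolds": len({c.scaffold_id for c in clusters}),
    }
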