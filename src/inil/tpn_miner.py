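"""CACTA/Tpn1-family transposon mining.

The detection pipeline follows the anatomy of *Tpn1*-family elements:
28-bp terminal inverted repeats (TIRs) at both ends, a 3-5 bp AT-rich
target-site duplication (TSD) immediately flanking the element, and
sub-terminal repetitive regions (SRRs: tandem 122-bp units at the 5' end,
104-bp units at the 3' end) required in cis for transposition.

Stages: ungapped Hamming scan for TIR seeds on both strands -> pairing of
convergent TIR hits into candidate spans -> TSD calling on the flanks ->
greedy overlap resolution -> SRR detection for orientation and activity
classification -> optional gene-context annotation -> catalog statistics.

TIR matching is a deterministic ungapped scan with a mismatch budget
(default 3 of 28) rather than a heuristic seeded aligner: at this seed
length the two are equivalent in practice and the scan is exactly
checkable against a sliding-window oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core_io import (GenomeAssembly, GenomicInterval, revcomp, seq_to_array)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

PUTATIVELY_ACTIVE = "putatively_active"
REARRANGED_INACTIVE = "rearranged_inactive"

SRR_PRESENT = "present"
SRR_ABSENT = "absent"
SRR_REARRANGED = "rearranged"

# gene-context priority when several features contain the element midpoint
_CONTEXT_PRIORITY = {"exon": 3, "five_prime_UTR": 2, "intron": 1}


@dataclass(frozen=True)
class TirSeed:
    """One terminal-inverted-repeat seed sequence (element orientation, 5'->3')."""

    end_type: str
    seq: str

    def __post_init__(self) -> None:
        if self.end_type not in {FIVE_PRIME, THREE_PRIME}:
            raise ValueError(f"bad end_type {self.end_type!r}")
        if "N" in self.seq.upper():
            raise ValueError("TIR seed may not contain N")


@dataclass(frozen=True)
class SrrSeed:
    """One sub-terminal repeat unit (122 bp for the 5' end, 104 bp for the 3')."""

    end_type: str
    seq: str

    @property
    def unit_len(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TirHit:
    scaffold_id: str
    start: int
    end: int
    end_type: str
    strand: str
    mismatches: int


@dataclass(frozen=True)
class TsdCall:
    length: int
    left_seq: str
    right_seq: str
    hamming: int

    @property
    def at_containing(self) -> bool:
        return any(b in "ATat" for b in self.left_seq)


@dataclass
class TpnElement:
    """A nominated element; span is TIR-inclusive, TSD-exclusive."""

    scaffold_id: str
    start: int
    end: int
    tsd: TsdCall
    orientation: str
    srr5_status: str = SRR_ABSENT
    srr3_status: str = SRR_ABSENT
    gene_context: str = "none"
    parent_gene: str | None = None
    tir_mismatches: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def activity_class(self) -> str:
        if self.srr5_status == SRR_PRESENT and self.srr3_status == SRR_PRESENT:
            return PUTATIVELY_ACTIVE
        return REARRANGED_INACTIVE


@dataclass
class TpnConfig:
    """Tunable knobs of the miner, with field defaults."""

    tir_len: int = 28
    max_mismatches: int = 3
    min_span: int = 60
    max_span: int = 50_000
    tsd_lengths: tuple[int, ...] = (3, 4, 5)
    tsd_max_hamming: int = 1
    subterminal_window: int = 600
    min_srr_copies: int = 2
    srr_divergence: float = 0.10


@dataclass
class TpnCatalog:
    elements: list[TpnElement] = field(default_factory=list)

    @property
    def stats(self) -> dict:
        return catalog_stats(self)

    def __len__(self) -> int:
        return len(self.elements)

    def to_intervals(self) -> list[GenomicInterval]:
        out = []
        for i, el in enumerate(self.elements, 1):
            out.append(GenomicInterval(
                el.scaffold_id, el.start, el.end, el.orientation,
                "terminal_inverted_repeat_element",
                {"ID": f"tpn{i:04d}",
                 "tsd": el.tsd.left_seq,
                 "tsd_hamming": str(el.tsd.hamming),
                 "srr5": el.srr5_status, "srr3": el.srr3_status,
                 "activity": el.activity_class,
                 "gene_context": el.gene_context,
                 **({"parent_gene": el.parent_gene} if el.parent_gene else {})}))
        return out


# ---------------------------------------------------------------------------
# Stage 1: TIR scanning
# ---------------------------------------------------------------------------

def hamming_scan(seq_arr: np.ndarray, pattern: str, max_mm: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Offsets (and mismatch counts) where pattern matches with <= max_mm
    substitutions. Vectorised shift-and-accumulate over the byte array."""
    pat = seq_to_array(pattern)
    n, m = seq_arr.size, pat.size
    if n < m:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int32)
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for k in range(m):
        mism += seq_arr[k:n - m + 1 + k] != pat[k]
    idx = np.nonzero(mism <= max_mm)[0]
    return idx, mism[idx]


def scan_tirs(assembly: GenomeAssembly, seeds: Iterable[TirSeed],
              max_mismatches: int = 3) -> list[TirHit]:
    """Every ungapped occurrence of each seed on either strand.

    A reverse-complement match of a seed is reported at its forward
    coordinates with strand "-". Hits sharing (scaffold, position,
    end_type) are deduplicated keeping the fewest mismatches (tie: "+").
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("no TIR seeds given")
    for s in seeds:
        if max_mismatches >= len(s.seq) / 4:
            raise ValueError("max_mismatches must be < seed length / 4")
    best: dict[tuple[str, int, str], TirHit] = {}
    for rec in assembly:
        arr = seq_to_array(rec.seq)
        for seed in seeds:
            m = len(seed.seq)
            for strand, pattern in (("+", seed.seq), ("-", revcomp(seed.seq))):
                idx, mm = hamming_scan(arr, pattern, max_mismatches)
                for pos, k in zip(idx.tolist(), mm.tolist()):
                    key = (rec.id, pos, seed.end_type)
                    hit = TirHit(rec.id, pos, pos + m, seed.end_type, strand, k)
                    old = best.get(key)
                    if (old is None or k < old.mismatches
                            or (k == old.mismatches and strand == "+"
                                and old.strand == "-")):
                        best[key] = hit
    return sorted(best.values(), key=lambda h: (h.scaffold_id, h.start, h.end_type))


# ---------------------------------------------------------------------------
# Stage 2: TIR pairing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TpnCandidate:
    scaffold_id: str
    start: int
    end: int
    left: TirHit
    right: TirHit
    orientation: str

    @property
    def span(self) -> int:
        return self.end - self.start


def pair_tirs(hits: Sequence[TirHit], min_span: int = 60,
              max_span: int = 50_000) -> list[TpnCandidate]:
    """All convergent left/right TIR pairs with span within bounds.

    A "+"-oriented element shows its 5' seed forward on the left and its
    3' seed as a reverse-complement match on the right; a "-"-oriented
    element shows the mirror image. Every eligible ordered pair is
    returned — the TSD filter and overlap resolution decide downstream.
    """
    if min_span >= max_span:
        raise ValueError("min_span must be < max_span")
    by_scaffold: dict[str, list[TirHit]] = {}
    for h in hits:
        by_scaffold.setdefault(h.scaffold_id, []).append(h)
    out: list[TpnCandidate] = []
    for sid, shits in by_scaffold.items():
        shits = sorted(shits, key=lambda h: h.start)
        lefts = [h for h in shits if h.strand == "+"]
        rights = [h for h in shits if h.strand == "-"]
        for lh in lefts:
            want = THREE_PRIME if lh.end_type == FIVE_PRIME else FIVE_PRIME
            orient = "+" if lh.end_type == FIVE_PRIME else "-"
            for rh in rights:
                if rh.end_type != want or rh.start <= lh.start:
                    continue
                span = rh.end - lh.start
                if span < min_span:
                    continue
                if span > max_span:
                    continue
                out.append(TpnCandidate(sid, lh.start, rh.end, lh, rh, orient))
    out.sort(key=lambda c: (c.scaffold_id, c.start, c.end))
    return out


# ---------------------------------------------------------------------------
# Stage 3: TSD calling
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def call_tsd(assembly: GenomeAssembly, candidate: TpnCandidate,
             tsd_lengths: Sequence[int] = (3, 4, 5),
             max_hamming: int = 1) -> TsdCall | None:
    """TSD on the immediate flanks of a candidate span, or None.

    Preference order: exact duplication at the longest allowed length down
    to 3 bp, then a one-mismatch 3-mer. Flanks running off the scaffold
    disqualify only the lengths they truncate.
    """
    rec = assembly[candidate.scaffold_id]
    seq = rec.seq.upper()
    s, e, L = candidate.start, candidate.end, rec.length
    lengths = sorted(tsd_lengths, reverse=True)
    for n in lengths:
        if s - n < 0 or e + n > L:
            continue
        left, right = seq[s - n:s], seq[e:e + n]
        if left == right and "N" not in left:
            return TsdCall(n, left, right, 0)
    n = min(lengths)
    if max_hamming > 0 and s - n >= 0 and e + n <= L:
        left, right = seq[s - n:s], seq[e:e + n]
        d = _hamming(left, right)
        if d <= max_hamming and "N" not in left + right:
            return TsdCall(n, left, right, d)
    return None


# ---------------------------------------------------------------------------
# Stage 4: SRR detection
# ---------------------------------------------------------------------------

def _tandem_count(window_arr: np.ndarray, unit: str, max_mm: int) -> int:
    """Longest chain of unit occurrences spaced within 1.5 unit lengths."""
    idx, _ = hamming_scan(window_arr, unit, max_mm)
    if idx.size == 0:
        return 0
    m = len(unit)
    best = run = 1
    # occurrences at overlapping offsets collapse into one tandem copy
    last = idx[0]
    for pos in idx[1:]:
        gap = pos - last
        if gap < 0.5 * m:
            continue
        if gap <= 1.5 * m:
            run += 1
            best = max(best, run)
        else:
            run = 1
        last = pos
    return best


def detect_srr(assembly: GenomeAssembly, candidate: TpnCandidate,
               srr_seeds: Iterable[SrrSeed],
               subterminal_window: int = 600,
               min_srr_copies: int = 2,
               srr_divergence: float = 0.10) -> tuple[str, str, str]:
    """SRR status at both ends plus the element orientation.

    Orientation is "+" when the 122-bp-type (5') unit sits at the left
    end, "-" when it sits (reverse-complemented) at the right end. A
    status is ``present`` with >= min_srr_copies tandem copies in the
    expected orientation, ``rearranged`` when copies exist but are too few
    or inverted, ``absent`` otherwise.
    """
    seed5 = next(s for s in srr_seeds if s.end_type == FIVE_PRIME)
    seed3 = next(s for s in srr_seeds if s.end_type == THREE_PRIME)
    rec = assembly[candidate.scaffold_id]
    s, e = candidate.start, candidate.end
    w = min(subterminal_window, (e - s) // 2)
    left = seq_to_array(rec.seq[s:s + w])
    right = seq_to_array(rec.seq[e - w:e])

    def counts(arr, seed):
        mm = int(srr_divergence * seed.unit_len)
        fwd = _tandem_count(arr, seed.seq, mm)
        rev = _tandem_count(arr, revcomp(seed.seq), mm)
        return fwd, rev

    l5f, l5r = counts(left, seed5)
    r5f, r5r = counts(right, seed5)
    l3f, l3r = counts(left, seed3)
    r3f, r3r = counts(right, seed3)

    plus_evidence = l5f + r3r
    minus_evidence = r5r + l3f
    orientation = "+" if plus_evidence >= minus_evidence else "-"

    def status(expected: int, inverted: int) -> str:
        if expected >= min_srr_copies:
            return SRR_PRESENT
        if expected + inverted >= 1:
            return SRR_REARRANGED
        return SRR_ABSENT

    if orientation == "+":
        srr5 = status(l5f, l5r)   # 5' end = genomic left, unit forward
        srr3 = status(r3r, r3f)   # 3' end = genomic right, unit revcomp
    else:
        srr5 = status(r5r, r5f)   # 5' end = genomic right
        srr3 = status(l3f, l3r)   # 3' end = genomic left
    return srr5, srr3, orientation


# ---------------------------------------------------------------------------
# Stage 5: nomination (scan -> pair -> TSD -> overlap resolution -> SRR)
# ---------------------------------------------------------------------------

def nominate_elements(assembly: GenomeAssembly,
                      tir_seeds: Iterable[TirSeed],
                      srr_seeds: Iterable[SrrSeed],
                      gene_models: Sequence[GenomicInterval] | None = None,
                      config: TpnConfig | None = None) -> TpnCatalog:
    """Run the full miner and return a catalog of non-overlapping elements.

    Overlapping TSD-validated candidates are resolved greedily: fewest
    total TIR mismatches, then lowest TSD Hamming distance, then longest
    span, then leftmost.
    """
    cfg = config or TpnConfig()
    hits = scan_tirs(assembly, tir_seeds, cfg.max_mismatches)
    candidates = pair_tirs(hits, cfg.min_span, cfg.max_span)
    validated: list[tuple[TpnCandidate, TsdCall]] = []
    for cand in candidates:
        tsd = call_tsd(assembly, cand, cfg.tsd_lengths, cfg.tsd_max_hamming)
        if tsd is not None:
            validated.append((cand, tsd))
    validated.sort(key=lambda ct: (
        ct[0].left.mismatches + ct[0].right.mismatches,
        ct[1].hamming, -ct[0].span, ct[0].scaffold_id, ct[0].start))
    occupied: dict[str, IntervalTree] = {}
    accepted: list[tuple[TpnCandidate, TsdCall]] = []
    for cand, tsd in validated:
        tree = occupied.setdefault(cand.scaffold_id, IntervalTree())
        if tree.overlap(cand.start, cand.end):
            continue
        tree.addi(cand.start, cand.end)
        accepted.append((cand, tsd))
    elements: list[TpnElement] = []
    for cand, tsd in accepted:
        srr5, srr3, orientation = detect_srr(
            assembly, cand, srr_seeds, cfg.subterminal_window,
            cfg.min_srr_copies, cfg.srr_divergence)
        if srr5 == SRR_ABSENT and srr3 == SRR_ABSENT:
            orientation = cand.orientation
        elements.append(TpnElement(
            cand.scaffold_id, cand.start, cand.end, tsd, orientation,
            srr5, srr3,
            tir_mismatches=cand.left.mismatches + cand.right.mismatches))
    elements.sort(key=lambda el: (el.scaffold_id, el.start))
    catalog = TpnCatalog(elements)
    if gene_models is not None:
        annotate_gene_context(catalog, gene_models)
    return catalog


# ---------------------------------------------------------------------------
# Stage 6: gene context
# ---------------------------------------------------------------------------

def annotate_gene_context(catalog: TpnCatalog,
                          gene_models: Sequence[GenomicInterval]) -> TpnCatalog:
    """Assign each element the highest-priority gene feature containing its
    midpoint (exon > five_prime_UTR > intron > none) and the parent gene."""
    trees: dict[str, IntervalTree] = {}
    for iv in gene_models:
        if iv.feature_type in _CONTEXT_PRIORITY:
            trees.setdefault(iv.scaffold_id, IntervalTree()).addi(
                iv.start, iv.end, iv)
    for el in catalog.elements:
        tree = trees.get(el.scaffold_id)
        el.gene_context, el.parent_gene = "none", None
        if tree is None:
            continue
        mid = (el.start + el.end) // 2
        hits = [h.data for h in tree.at(mid)]
        if not hits:
            continue
        top = max(hits, key=lambda iv: _CONTEXT_PRIORITY[iv.feature_type])
        el.gene_context = top.feature_type
        el.parent_gene = top.attributes.get("gene_id",
                                            top.attributes.get("Parent"))
    return catalog


# ---------------------------------------------------------------------------
# Stage 7: statistics
# ---------------------------------------------------------------------------

def catalog_stats(catalog: TpnCatalog) -> dict:
    els = catalog.elements
    n = len(els)
    if n == 0:
        return {"count": 0, "mean_len": None, "min_len": None, "max_len": None,
                "tsd_len_histogram": {}, "tsd_mismatch_count": 0,
                "tsd_at_fraction": None, "rearranged_count": 0,
                "in_gene_count": 0, "undefined_ratios": True}
    lengths = [el.length for el in els]
    hist: dict[int, int] = {}
    for el in els:
        hist[el.tsd.length] = hist.get(el.tsd.length, 0) + 1
    return {
        "count": n,
        "mean_len": float(np.mean(lengths)),
        "min_len": int(min(lengths)),
        "max_len": int(max(lengths)),
        "tsd_len_histogram": hist,
        "tsd_mismatch_count": sum(el.tsd.hamming > 0 for el in els),
        "tsd_at_fraction": sum(el.tsd.at_containing for el in els) / n,
        "rearranged_count": sum(
            el.activity_class == REARRANGED_INACTIVE for el in els),
        "in_gene_count": sum(el.gene_context != "none" for el in els),
        "undefined_ratios": False,
    }


# ---------------------------------------------------------------------------
# Seed FASTA I/O (ids encode end_type, e.g. ">tir_five_prime")
# ---------------------------------------------------------------------------

def load_seeds(path, kind: str = "tir"):
    """Read TIR or SRR seeds from FASTA; record ids must contain
    'five_prime' or 'three_prime'."""
    from Bio import SeqIO
    seeds = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if FIVE_PRIME in rec.id:
            end_type = FIVE_PRIME
        elif THREE_PRIME in rec.id:
            end_type = THREE_PRIME
        else:
            raise ValueError(f"seed id {rec.id!r} does not encode an end type")
        cls = TirSeed if kind == "tir" else SrrSeed
        seeds.append(cls(end_type, str(rec.seq).upper()))
    if not seeds:
        raise ValueError(f"no seeds in {path}")
    return seeds
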