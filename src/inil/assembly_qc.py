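"""Assembly statistics and validation: N50 family, BAC-end paired scoring,
EST coverage summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import AlignmentHit

SAME_SCAFFOLD = "same_scaffold"
CROSS_SCAFFOLD = "cross_scaffold"
UNPAIRED = "unpaired"
UNALIGNED = "unaligned"


@dataclass
class AssemblyStats:
    n_seqs: int
    total: int
    n50: int
    l50: int
    longest: int


@dataclass
class BacPairCall:
    read_pair_id: str
    status: str
    insert_len: int | None = None
    chosen_hits: tuple[AlignmentHit, AlignmentHit] | None = None


def compute_stats(lengths: Sequence[int]) -> AssemblyStats:
    """N50/L50 by descending cumulative length reaching half the total."""
    if not lengths:
        raise ValueError("no sequence lengths")
    if min(lengths) <= 0:
        raise ValueError("lengths must be positive")
    srt = sorted(lengths, reverse=True)
    total = sum(srt)
    half = total / 2
    cum = 0
    for rank, length in enumerate(srt, 1):
        cum += length
        if cum >= half:
            return AssemblyStats(len(srt), total, length, rank, srt[0])
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# BAC-end pairing
# ---------------------------------------------------------------------------

def group_read_pairs(hits: Iterable[AlignmentHit],
                     suffixes: tuple[str, str] = ("/1", "/2")
                     ) -> dict[str, tuple[list[AlignmentHit], list[AlignmentHit]]]:
    """Group hits into (forward-read hits, reverse-read hits) per pair id."""
    pairs: dict[str, tuple[list, list]] = {}
    for h in hits:
        for mate, suf in enumerate(suffixes):
            if h.query_id.endswith(suf):
                pid = h.query_id[:-len(suf)]
                pairs.setdefault(pid, ([], []))[mate].append(h)
                break
        else:
            raise ValueError(f"read id {h.query_id!r} has no mate suffix")
    return pairs


def _inward(h1: AlignmentHit, h2: AlignmentHit) -> bool:
    if h1.strand == h2.strand:
        return False
    fwd, rev = (h1, h2) if h1.strand == "+" else (h2, h1)
    return fwd.target_start <= rev.target_start


def pair_bac_ends(pairs: Mapping[str, tuple[Sequence[AlignmentHit],
                                            Sequence[AlignmentHit]]],
                  max_insert: int = 400_000,
                  min_score: float = 0.0
                  ) -> tuple[list[BacPairCall], dict]:
    """Choose the best paired placement per BAC-end read pair.

    Eligible combinations place both reads on one target, on opposite
    strands, facing inward, with an insert no longer than ``max_insert``;
    the combination with the largest combined score wins (tie: smaller
    insert). Pairs with both reads aligned but no eligible combination are
    ``cross_scaffold`` using each read's best single hit. The summary rate
    uses pairs with both reads aligned as denominator and also reports the
    all-pairs denominator.
    """
    calls: list[BacPairCall] = []
    inserts: list[int] = []
    for pid in sorted(pairs):
        h1s = [h for h in pairs[pid][0] if h.score >= min_score]
        h2s = [h for h in pairs[pid][1] if h.score >= min_score]
        if not h1s and not h2s:
            calls.append(BacPairCall(pid, UNALIGNED))
            continue
        if not h1s or not h2s:
            calls.append(BacPairCall(pid, UNPAIRED))
            continue
        best = None
        for a in h1s:
            for b in h2s:
                if a.target_id != b.target_id or not _inward(a, b):
                    continue
                insert = (max(a.target_end, b.target_end)
                          - min(a.target_start, b.target_start))
                if insert > max_insert:
                    continue
                key = (-(a.score + b.score), insert)
                if best is None or key < best[0]:
                    best = (key, insert, (a, b))
        if best is not None:
            calls.append(BacPairCall(pid, SAME_SCAFFOLD, best[1], best[2]))
            inserts.append(best[1])
        else:
            top1 = max(h1s, key=lambda h: h.score)
            top2 = max(h2s, key=lambda h: h.score)
            calls.append(BacPairCall(pid, CROSS_SCAFFOLD, None, (top1, top2)))
    n_total = len(calls)
    n_both = sum(c.status in (SAME_SCAFFOLD, CROSS_SCAFFOLD) for c in calls)
    n_same = sum(c.status == SAME_SCAFFOLD for c in calls)
    hist, edges = (np.histogram(inserts, bins=20) if inserts
                   else (np.zeros(0, int), np.zeros(0)))
    summary = {
        "n_pairs": n_total,
        "n_both_aligned": n_both,
        "n_same_scaffold": n_same,
        "same_scaffold_rate": n_same / n_both if n_both else None,
        "same_scaffold_rate_all_pairs": n_same / n_total if n_total else None,
        "cross_scaffold_rate": (n_both - n_same) / n_both if n_both else None,
        "insert_mean": float(np.mean(inserts)) if inserts else None,
        "insert_histogram": {"counts": hist.tolist(),
                             "edges": edges.tolist()},
    }
    return calls, summary


# ---------------------------------------------------------------------------
# EST coverage
# ---------------------------------------------------------------------------

def _union_len(spans: list[tuple[int, int]]) -> int:
    spans.sort()
    total, cur_s, cur_e = 0, None, None
    for s, e in spans:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def est_coverage(hits: Iterable[AlignmentHit],
                 query_lens: Mapping[str, int],
                 covered_threshold: float = 0.90) -> dict:
    """Fraction of queries aligned at all, and aligned over >= threshold of
    their length (query-side span union against the best-scoring target)."""
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if h.query_end > query_lens.get(h.query_id, h.query_len):
            raise ValueError(f"hit query span exceeds length of {h.query_id}")
        by_query.setdefault(h.query_id, []).append(h)
    n_all = len(query_lens)
    if n_all == 0:
        raise ValueError("query_lens is empty")
    n_aligned = 0
    n_covered = 0
    coverages: dict[str, float] = {}
    for qid, qlen in query_lens.items():
        qhits = by_query.get(qid, [])
        if not qhits:
            coverages[qid] = 0.0
            continue
        n_aligned += 1
        score_by_target: dict[str, float] = {}
        for h in qhits:
            score_by_target[h.target_id] = score_by_target.get(h.target_id, 0.0) + h.score
        best_target = max(score_by_target, key=lambda t: score_by_target[t])
        spans = [(h.query_start, h.query_end) for h in qhits
                 if h.target_id == best_target]
        cov = _union_len(spans) / qlen
        coverages[qid] = cov
        if cov >= covered_threshold:
            n_covered += 1
    return {
        "n_queries": n_all,
        "aligned_fraction": n_aligned / n_all,
        "well_covered_fraction": n_covered / n_all,
        "coverage_threshold": covered_threshold,
        "per_query_coverage": coverages,
    }
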