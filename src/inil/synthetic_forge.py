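"""Seeded synthetic-genome forge with machine-readable truth.

Generates desk-scale genomes carrying the feature classes the curation
pipeline assumes — CACTA-family elements with 28-bp TIRs, AT-rich 3-bp
TSDs and 122/104-bp sub-terminal repeat blocks; telomeric, centromeric and
rDNA arrays; chimeric scaffolds; an F2 mapping population under the
Haldane map function; BAC-end pair placements — and records the exact
coordinates and payload of every planted feature.

Determinism: one integer-seeded RNG stream per feature class, spawned in a
fixed order from the master seed, so enabling or resizing one feature
class does not perturb the placements of another. All randomness flows
through numpy Generators; no hash-ordering dependence.

Planted elements are spaced so that no two TIRs of different elements can
pair within the miner's span ceiling: each chromosome places its elements
with at least ``max_span`` of clear background between occupied intervals.
This makes the planted truth the unique solution of the mining problem and
is part of the generator's truth-integrity contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (GenomeAssembly, GenomicInterval, ScaffoldRecord,
                      AlignmentHit, revcomp, write_genome, write_gff3,
                      write_bed6, write_blast6)
from .map_curation import LinkageMap, MarkerTable
from .tpn_miner import FIVE_PRIME, THREE_PRIME, SrrSeed, TirSeed

# Canonical seed sequences of the forged element family. The TIRs open with
# the CACTA motif of the superfamily; the SRR units are the 122-bp (5') and
# 104-bp (3') tandem monomers of the element anatomy.
TIR5 = "CACTAATCTTACTTCTACACCGATGGAG"
TIR3 = "CACTACCATAACACCACTGCCAGACCCT"
SRR5 = ("GTTATATGCACAAGTTGCGAGCCGCACTTATAGAGCGCGCCTAGCACTTCGAACGCACTTC"
        "TTTCCTGTGAAGCTACGCTGGTAATGGGTACCGTAATTGGAACACCTCAACGATCAGCTCG")
SRR3 = ("GTACTTTTCGTCACTCGTAGGCACGATCCTAAATAACATACCTGGTCGTCGGCAAGAGTTA"
        "GCGGGCTTCATTGAACGCGTGTGGGAGTTTGAAGGTTTTTAGC")

TELOMERE_MONOMER = "AAACCCT"

# Per-base TSD weights back-solved so that a 3-bp TSD contains at least one
# A or T with probability 1 - (2*0.184)^3 ~ 0.95.
TSD_WEIGHTS = {"A": 0.316, "C": 0.184, "G": 0.184, "T": 0.316}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TpnForgeConfig:
    n_intact: int = 50
    n_rearranged: int = 5
    len_range: tuple[int, int] = (161, 40_619)
    tsd_len: int = 3
    tsd_mismatch_fraction: float = 14 / 339
    n_in_intron: int = 2
    n_in_utr: int = 1


@dataclass
class TelomereForgeConfig:
    monomer: str = TELOMERE_MONOMER
    copies_range: tuple[int, int] = (50, 400)
    n_both_ends: int = 2
    n_one_end: int = 2
    n_fully: int = 1


@dataclass
class CentromereForgeConfig:
    monomer_len: int = 173
    copies_range: tuple[int, int] = (30, 80)
    divergence: float = 0.02
    per_chromosome: bool = True


@dataclass
class RdnaForgeConfig:
    component_lengths: dict = field(default_factory=lambda: {
        "18S": 1800, "5.8S": 160, "25S": 3400, "5S": 120})
    n_units: int = 2
    n_5s: int = 30


@dataclass
class ChimeraForgeConfig:
    n_events: int = 0          # gap-junction (scaffold-level) chimeras
    n_contig_events: int = 0   # gap-free (contig-level) chimeras
    gap_len: int = 100
    source_len: int = 300_000


@dataclass
class F2ForgeConfig:
    n_progeny: int = 200
    marker_spacing: float = 10.0   # cM between adjacent markers
    cm_per_kb: float = 0.2
    missing_rate: float = 0.05


@dataclass
class BacForgeConfig:
    n_pairs: int = 500
    insert_mean: float = 100_000.0
    insert_sd: float = 10_000.0
    read_len: int = 500
    cross_fraction: float = 0.0


@dataclass
class ForgeConfig:
    seed: int = 0
    n_chromosomes: int = 10
    chromosome_len: int = 500_000
    base_composition: tuple[float, ...] = (0.31, 0.19, 0.19, 0.31)
    n_random_genes: int = 10
    tpn: TpnForgeConfig = field(default_factory=TpnForgeConfig)
    telomere: TelomereForgeConfig = field(default_factory=TelomereForgeConfig)
    centromere: CentromereForgeConfig = field(default_factory=CentromereForgeConfig)
    rdna: RdnaForgeConfig = field(default_factory=RdnaForgeConfig)
    chimera: ChimeraForgeConfig = field(default_factory=ChimeraForgeConfig)
    f2: F2ForgeConfig = field(default_factory=F2ForgeConfig)
    bac: BacForgeConfig = field(default_factory=BacForgeConfig)

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        lo, hi = self.tpn.len_range
        if not (60 <= lo < hi <= 50_000):
            raise ValueError("tpn len_range must lie within [60, 50000]")


@dataclass
class ForgeResult:
    config: ForgeConfig
    assembly: GenomeAssembly
    truth: list[dict]
    tir_seeds: list[TirSeed]
    srr_seeds: list[SrrSeed]
    gene_models: list[GenomicInterval]
    markers: MarkerTable
    linkage_map: LinkageMap
    gametes: dict
    bac_hits: list[AlignmentHit]
    bac_truth: list[dict]
    rdna_hits: list[AlignmentHit]

    def truth_of(self, feature_type: str) -> list[dict]:
        return [t for t in self.truth if t["feature_type"] == feature_type]


# ---------------------------------------------------------------------------
# Low-level generators
# ---------------------------------------------------------------------------

def random_background(rng: np.random.Generator, length: int,
                      composition: Sequence[float]) -> np.ndarray:
    """Random sequence as a uint8 byte array under a base composition."""
    return rng.choice(_BASES, size=length, p=np.asarray(composition))


def draw_tsd(rng: np.random.Generator, length: int = 3,
             weights: dict[str, float] | None = None) -> str:
    """One AT-biased target-site duplication."""
    w = weights or TSD_WEIGHTS
    bases = list(w)
    p = np.array([w[b] for b in bases])
    return "".join(rng.choice(bases, size=length, p=p / p.sum()))


def _rand_seq(rng: np.random.Generator, n: int,
              composition=(0.25, 0.25, 0.25, 0.25)) -> str:
    return random_background(rng, n, composition).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Tpn element construction and planting
# ---------------------------------------------------------------------------

#: the shortest element that can carry both SRR blocks plus clear
#: sub-terminal windows; intact draws are clamped here (see docs)
MIN_SRR_ELEMENT_LEN = 1200


def build_element(rng: np.random.Generator, length: int,
                  composition: Sequence[float],
                  rearranged: bool = False,
                  tsd_len: int = 3,
                  tsd_mismatch: bool = False) -> dict:
    """Construct one element: returns body, TSDs, strand and truth payload.

    Body anatomy (+ strand): 5'TIR, >=2 tandem 122-bp SRR units, random
    interior, >=2 tandem 104-bp SRR units (reverse-complemented), 3'TIR as
    the reverse complement of the 3' seed. A rearranged element omits or
    inverts one SRR block. Raises if ``length`` cannot fit the anatomy.
    """
    k5 = int(rng.integers(2, 4))
    k3 = int(rng.integers(2, 4))
    srr5_block = SRR5 * k5
    srr3_block = revcomp(SRR3 * k3)
    mode = "intact"
    if rearranged:
        mode = str(rng.choice(["omit5", "omit3", "invert5", "invert3"]))
        if mode == "omit5":
            srr5_block = ""
        elif mode == "omit3":
            srr3_block = ""
        elif mode == "invert5":
            srr5_block = revcomp(srr5_block)
        else:
            srr3_block = revcomp(srr3_block)
    fixed = len(TIR5) + len(TIR3) + len(srr5_block) + len(srr3_block)
    interior_len = length - fixed
    if interior_len < 0:
        raise ValueError(
            f"element length {length} cannot fit anatomy of {fixed} bases")
    interior = random_background(rng, interior_len, composition).tobytes().decode()
    body = TIR5 + srr5_block + interior + srr3_block + revcomp(TIR3)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        body = revcomp(body)
    tsd = draw_tsd(rng, tsd_len)
    tsd_right = tsd
    if tsd_mismatch:
        i = int(rng.integers(tsd_len))
        others = [b for b in "ACGT" if b != tsd[i]]
        tsd_right = tsd[:i] + str(rng.choice(others)) + tsd[i + 1:]
    return {"body": body, "tsd_left": tsd, "tsd_right": tsd_right,
            "strand": strand, "mode": mode, "srr_copies": (k5, k3)}


def _fix_flank_uniqueness(chrom: np.ndarray, start: int, end: int,
                          tsd_len: int, rng: np.random.Generator) -> None:
    """Redraw background bases just outside the TSDs until no spurious
    exact 4/5-mer duplication flanks the element span."""
    for _ in range(100):
        clash = False
        for n in (5, 4):
            if n <= tsd_len:
                continue
            if start - n < 0 or end + n > chrom.size:
                continue
            left = chrom[start - n:start].tobytes()
            right = chrom[end:end + n].tobytes()
            if left == right:
                clash = True
        if not clash:
            return
        for pos in (start - 5, start - 4, end + 3, end + 4):
            if 0 <= pos < chrom.size and not (start - tsd_len <= pos < end + tsd_len):
                chrom[pos] = rng.choice(_BASES)
    raise RuntimeError("could not make element flanks unique")


def plant_tpn(chromosomes: dict[str, np.ndarray], config: ForgeConfig,
              rng: np.random.Generator,
              occupied: dict[str, list[tuple[int, int]]]) -> list[dict]:
    """Plant intact and rearranged elements with anti-pairing spacing.

    Mutates the chromosome byte arrays in place; returns truth entries.
    Elements on one chromosome are separated by more than the miner's
    span ceiling so planted TIRs cannot cross-pair.
    """
    tcfg = config.tpn
    margin = 50_000 + 200
    lo = max(tcfg.len_range[0], MIN_SRR_ELEMENT_LEN)
    hi = tcfg.len_range[1]
    n_total = tcfg.n_intact + tcfg.n_rearranged
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), n_total)).astype(int)
    kinds = np.array(["intact"] * tcfg.n_intact
                     + ["rearranged"] * tcfg.n_rearranged)
    order = rng.permutation(n_total)
    lengths, kinds = lengths[order], kinds[order]
    n_mismatch = int(round(tcfg.tsd_mismatch_fraction * n_total))
    mismatch_idx = set(rng.choice(n_total, size=n_mismatch, replace=False).tolist())

    chrom_ids = list(chromosomes)
    per_chrom: dict[str, list[int]] = {cid: [] for cid in chrom_ids}
    for i in range(n_total):
        per_chrom[chrom_ids[i % len(chrom_ids)]].append(i)

    truth: list[dict] = []
    for cid, idxs in per_chrom.items():
        if not idxs:
            continue
        chrom = chromosomes[cid]
        L = chrom.size
        lens = [int(lengths[i]) + 2 * tcfg.tsd_len for i in idxs]
        slack = L - sum(lens) - (len(idxs) + 1) * margin
        if slack < 0:
            raise ValueError(
                "features cannot be placed without overlap; reduce counts, "
                "lengths, or increase chromosome_len")
        cuts = np.sort(rng.integers(0, slack + 1, size=len(idxs)))
        pos = 0
        for j, i in enumerate(idxs):
            start_full = margin + int(cuts[j]) + sum(lens[:j]) + j * margin
            el = build_element(rng, int(lengths[i]), config.base_composition,
                               rearranged=(kinds[i] == "rearranged"),
                               tsd_len=tcfg.tsd_len,
                               tsd_mismatch=(i in mismatch_idx))
            full = el["tsd_left"] + el["body"] + el["tsd_right"]
            s = start_full
            e = s + len(full)
            chrom[s:e] = np.frombuffer(full.encode(), dtype=np.uint8)
            body_s = s + tcfg.tsd_len
            body_e = e - tcfg.tsd_len
            _fix_flank_uniqueness(chrom, body_s, body_e, tcfg.tsd_len, rng)
            occupied.setdefault(cid, []).append((s, e))
            truth.append({
                "feature_type": f"tpn_{kinds[i]}",
                "scaffold_id": cid, "start": body_s, "end": body_e,
                "strand": el["strand"],
                "payload": {"tsd_left": el["tsd_left"],
                            "tsd_right": el["tsd_right"],
                            "tsd_mismatch": el["tsd_left"] != el["tsd_right"],
                            "mode": el["mode"],
                            "length": body_e - body_s}})
            pos = e
    truth.sort(key=lambda t: (t["scaffold_id"], t["start"]))
    return truth


# ---------------------------------------------------------------------------
# Tandem arrays: telomeres and centromeres
# ---------------------------------------------------------------------------

def _telomere_array(rng, monomer: str, copies: int) -> str:
    partial = int(rng.integers(0, len(monomer)))
    return monomer * copies + monomer[:partial]


def plant_telomeres(chromosomes: dict[str, np.ndarray],
                    config: ForgeConfig, rng: np.random.Generator,
                    occupied: dict[str, list[tuple[int, int]]]
                    ) -> tuple[list[dict], list[ScaffoldRecord]]:
    """Arrays at chromosome ends (forward at the left end, reverse-
    complemented at the right) plus fully telomeric extra scaffolds."""
    tcfg = config.telomere
    truth: list[dict] = []
    cids = list(chromosomes)
    targets: list[tuple[str, str]] = []
    for cid in cids[:tcfg.n_both_ends]:
        targets += [(cid, "left"), (cid, "right")]
    for cid in cids[tcfg.n_both_ends:tcfg.n_both_ends + tcfg.n_one_end]:
        targets.append((cid, "left" if rng.random() < 0.5 else "right"))
    for cid, side in targets:
        copies = int(rng.integers(*tcfg.copies_range))
        arr = _telomere_array(rng, tcfg.monomer, copies)
        chrom = chromosomes[cid]
        if side == "left":
            s, e = 0, len(arr)
        else:
            arr = revcomp(arr)
            s, e = chrom.size - len(arr), chrom.size
        chrom[s:e] = np.frombuffer(arr.encode(), dtype=np.uint8)
        occupied.setdefault(cid, []).append((s, e))
        truth.append({"feature_type": "telomere", "scaffold_id": cid,
                      "start": s, "end": e,
                      "strand": "+" if side == "left" else "-",
                      "payload": {"copies": len(arr) / len(tcfg.monomer),
                                  "side": side}})
    extras: list[ScaffoldRecord] = []
    for k in range(tcfg.n_fully):
        copies = int(rng.integers(*tcfg.copies_range))
        seq = _telomere_array(rng, tcfg.monomer, copies)
        sid = f"telo_{k + 1}"
        extras.append(ScaffoldRecord(sid, seq))
        truth.append({"feature_type": "telomere", "scaffold_id": sid,
                      "start": 0, "end": len(seq), "strand": "+",
                      "payload": {"copies": len(seq) / len(tcfg.monomer),
                                  "side": "full"}})
    return truth, extras


def _place_free(rng, L: int, span: int,
                occ: list[tuple[int, int]], margin: int = 200,
                tries: int = 400) -> int:
    for _ in range(tries):
        s = int(rng.integers(margin, L - span - margin))
        if all(e2 <= s - margin or s + span + margin <= s2
               for s2, e2 in occ):
            return s
    raise ValueError("features cannot be placed without overlap; "
                     "reduce counts or lengths")


def plant_centromeres(chromosomes: dict[str, np.ndarray],
                      config: ForgeConfig, rng: np.random.Generator,
                      occupied: dict[str, list[tuple[int, int]]]
                      ) -> tuple[list[dict], str]:
    """One diverged satellite array per chromosome; returns truth and the
    genome-wide centromeric monomer."""
    ccfg = config.centromere
    monomer = _rand_seq(rng, ccfg.monomer_len)
    truth: list[dict] = []
    targets = list(chromosomes) if ccfg.per_chromosome else []
    for cid in targets:
        copies = int(rng.integers(*ccfg.copies_range))
        units = [_mutate(rng, monomer, ccfg.divergence) for _ in range(copies)]
        arr = "".join(units)
        chrom = chromosomes[cid]
        s = _place_free(rng, chrom.size, len(arr),
                        occupied.setdefault(cid, []))
        chrom[s:s + len(arr)] = np.frombuffer(arr.encode(), dtype=np.uint8)
        occupied[cid].append((s, s + len(arr)))
        truth.append({"feature_type": "centromere", "scaffold_id": cid,
                      "start": s, "end": s + len(arr), "strand": "+",
                      "payload": {"copies": copies,
                                  "monomer_len": ccfg.monomer_len}})
    return truth, monomer


# ---------------------------------------------------------------------------
# rDNA scaffolds and hit tables
# ---------------------------------------------------------------------------

def plant_rdna(config: ForgeConfig, rng: np.random.Generator
               ) -> tuple[list[ScaffoldRecord], list[AlignmentHit],
                          list[dict], dict[str, str]]:
    """Dedicated NOR and 5S scaffolds plus the component-labelled hit
    table the rDNA detector consumes."""
    rcfg = config.rdna
    comp_seqs = {name: _rand_seq(rng, n)
                 for name, n in rcfg.component_lengths.items()}
    truth: list[dict] = []
    hits: list[AlignmentHit] = []
    scaffolds: list[ScaffoldRecord] = []

    parts: list[str] = [_rand_seq(rng, 1000)]
    pos = 1000
    sid = "nor_1"
    counter = 0
    for u in range(rcfg.n_units):
        unit_start = pos
        for name, spacer in (("18S", 300), ("5.8S", 300), ("25S", 2000)):
            seq = comp_seqs[name]
            counter += 1
            hits.append(AlignmentHit(
                f"{name}_{counter}", len(seq), 0, len(seq), sid,
                pos, pos + len(seq), "+", len(seq), len(seq),
                float(len(seq))))
            parts.append(seq)
            pos += len(seq)
            parts.append(_rand_seq(rng, spacer))
            pos += spacer
        truth.append({"feature_type": "nor_unit", "scaffold_id": sid,
                      "start": unit_start, "end": pos - 2000, "strand": "+",
                      "payload": {"unit_index": u}})
    scaffolds.append(ScaffoldRecord(sid, "".join(parts)))

    if rcfg.n_5s > 0:
        sid5 = "fives_1"
        parts5 = [_rand_seq(rng, 500)]
        pos = 500
        for k in range(rcfg.n_5s):
            seq = comp_seqs["5S"]
            hits.append(AlignmentHit(
                f"5S_{k + 1}", len(seq), 0, len(seq), sid5,
                pos, pos + len(seq), "+", len(seq), len(seq),
                float(len(seq))))
            truth.append({"feature_type": "5S", "scaffold_id": sid5,
                          "start": pos, "end": pos + len(seq), "strand": "+",
                          "payload": {}})
            parts5.append(seq)
            pos += len(seq)
            parts5.append(_rand_seq(rng, 400))
            pos += 400
        scaffolds.append(ScaffoldRecord(sid5, "".join(parts5)))
    return scaffolds, hits, truth, comp_seqs


# ---------------------------------------------------------------------------
# Genes (random plus genes wrapped around planted elements)
# ---------------------------------------------------------------------------

def plant_genes(chromosomes: dict[str, np.ndarray], config: ForgeConfig,
                rng: np.random.Generator,
                occupied: dict[str, list[tuple[int, int]]],
                tpn_truth: list[dict]) -> list[GenomicInterval]:
    """Gene models: random intergenic genes, plus genes whose intron or
    5' UTR contains a planted element (exon features cover coding
    sequence only, so a UTR-resident element is not also exonic)."""
    intervals: list[GenomicInterval] = []
    gi = 0

    def add_gene(cid, gene_start, gene_end, exons, utr=None):
        nonlocal gi
        gi += 1
        gid, mid = f"gene{gi:03d}", f"mRNA{gi:03d}"
        intervals.append(GenomicInterval(cid, gene_start, gene_end, "+",
                                         "gene", {"ID": gid}))
        intervals.append(GenomicInterval(cid, gene_start, gene_end, "+",
                                         "mRNA", {"ID": mid, "Parent": gid,
                                                  "gene_id": gid}))
        for (es, ee) in exons:
            intervals.append(GenomicInterval(
                cid, es, ee, "+", "exon", {"Parent": mid, "gene_id": gid}))
        for (_, le), (rs, _) in zip(exons, exons[1:]):
            if rs > le:
                intervals.append(GenomicInterval(
                    cid, le, rs, "+", "intron",
                    {"Parent": mid, "gene_id": gid}))
        if utr:
            intervals.append(GenomicInterval(
                cid, utr[0], utr[1], "+", "five_prime_UTR",
                {"Parent": mid, "gene_id": gid}))

    intact = [t for t in tpn_truth if t["feature_type"] == "tpn_intact"]
    n_intron = min(config.tpn.n_in_intron, len(intact))
    n_utr = min(config.tpn.n_in_utr, max(0, len(intact) - n_intron))
    for t in intact[:n_intron]:
        cid, s, e = t["scaffold_id"], t["start"], t["end"]
        add_gene(cid, s - 700, e + 700,
                 exons=[(s - 700, s - 200), (e + 200, e + 700)])
        t["payload"]["gene_context"] = "intron"
    for t in intact[n_intron:n_intron + n_utr]:
        cid, s, e = t["scaffold_id"], t["start"], t["end"]
        add_gene(cid, s - 200, e + 900,
                 exons=[(e + 400, e + 900)], utr=(s - 200, e + 200))
        t["payload"]["gene_context"] = "five_prime_UTR"

    for _ in range(config.n_random_genes):
        cid = str(rng.choice(list(chromosomes)))
        L = chromosomes[cid].size
        span = int(rng.integers(2000, 6000))
        try:
            s = _place_free(rng, L, span, occupied.setdefault(cid, []))
        except ValueError:
            continue
        occupied[cid].append((s, s + span))
        n_ex = int(rng.integers(2, 5))
        bounds = np.sort(rng.choice(
            np.arange(s + 100, s + span - 100), size=2 * n_ex - 2,
            replace=False))
        edges = [s] + bounds.tolist() + [s + span]
        exons = [(edges[2 * k], edges[2 * k + 1]) for k in range(n_ex)]
        add_gene(cid, s, s + span, exons)
    return intervals


# ---------------------------------------------------------------------------
# Chimeras
# ---------------------------------------------------------------------------

def make_chimeras(config: ForgeConfig, rng: np.random.Generator,
                  next_lg: int) -> tuple[list[ScaffoldRecord], list[dict],
                                         pd.DataFrame, int]:
    """Chimeric scaffolds from dedicated source-chromosome pairs.

    Each event joins a prefix of one fresh source chromosome to a suffix
    of another (different linkage groups), through an N gap for
    scaffold-level events or seamlessly for contig-level ones. Markers of
    the retained parts are remapped onto chimera coordinates; truth
    records the junction interval and flanking linkage groups.
    """
    ccfg = config.chimera
    fcfg = config.f2
    spacing_bp = int(ccfg.source_len * 0.35), int(ccfg.source_len * 0.65)
    scaffolds: list[ScaffoldRecord] = []
    truth: list[dict] = []
    marker_rows: list[dict] = []
    step_bp = int(fcfg.marker_spacing / fcfg.cm_per_kb * 1000)

    def source(lg):
        seq = random_background(rng, ccfg.source_len,
                                config.base_composition).tobytes().decode()
        positions = list(range(step_bp // 2, ccfg.source_len, step_bp))
        return seq, positions, lg

    events = ([("scaffold", ccfg.gap_len)] * ccfg.n_events
              + [("contig", 0)] * ccfg.n_contig_events)
    for k, (level, gap_len) in enumerate(events, 1):
        lg_a, lg_b = next_lg, next_lg + 1
        next_lg += 2
        seq_a, pos_a, _ = source(lg_a)
        seq_b, pos_b, _ = source(lg_b)
        cut_a = int(rng.integers(*spacing_bp))
        cut_b = int(rng.integers(*spacing_bp))
        while cut_a % step_bp == step_bp // 2:
            cut_a += 13
        sid = f"chimera_{k}"
        seq = seq_a[:cut_a] + "N" * gap_len + seq_b[cut_b:]
        scaffolds.append(ScaffoldRecord(sid, seq))
        truth.append({
            "feature_type": f"chimera_{level}", "scaffold_id": sid,
            "start": cut_a, "end": cut_a + max(gap_len, 1), "strand": ".",
            "payload": {"left_lg": lg_a, "right_lg": lg_b,
                        "gap_len": gap_len,
                        "left_len": cut_a,
                        "right_len": len(seq_b) - cut_b,
                        "junction_point": cut_a + gap_len // 2}})
        for i, p in enumerate(x for x in pos_a if x < cut_a):
            marker_rows.append({"marker_id": f"m{lg_a}_{i + 1}",
                                "scaffold_id": sid, "position": p,
                                "lg": lg_a,
                                "cM": p / 1000 * fcfg.cm_per_kb})
        for i, p in enumerate(x for x in pos_b if x >= cut_b):
            marker_rows.append({"marker_id": f"m{lg_b}_{i + 1}",
                                "scaffold_id": sid,
                                "position": cut_a + gap_len + (p - cut_b),
                                "lg": lg_b,
                                "cM": p / 1000 * fcfg.cm_per_kb})
    return scaffolds, truth, pd.DataFrame(marker_rows), next_lg


# ---------------------------------------------------------------------------
# F2 population under Haldane recombination
# ---------------------------------------------------------------------------

def haldane_r(d_cm: float) -> float:
    """Map distance (cM) to recombination fraction, no interference."""
    return (1.0 - np.exp(-2.0 * d_cm / 100.0)) / 2.0


def simulate_f2(linkage_map: LinkageMap, markers: pd.DataFrame,
                config: F2ForgeConfig, rng: np.random.Generator
                ) -> tuple[MarkerTable, dict]:
    """Genotype an F2 population: two independent gametes per progeny,
    crossovers per marker interval with the Haldane recombination
    fraction, genotypes AA/AB/BB, missing entries at ``missing_rate``.

    Returns the marker table and the underlying gamete matrices (truth)
    keyed by linkage group.
    """
    n = config.n_progeny
    samples = [f"s{i + 1:03d}" for i in range(n)]
    geno_frames = []
    gametes: dict = {}
    for lg in linkage_map.groups:
        sub = linkage_map.table[linkage_map.table["lg"] == lg]
        ids = sub["marker_id"].tolist()
        cm = sub["cM"].to_numpy(dtype=float)
        m = len(ids)
        r = haldane_r(np.diff(cm)) if m > 1 else np.zeros(0)
        gam = np.zeros((2 * n, m), dtype=np.int8)
        gam[:, 0] = rng.integers(0, 2, size=2 * n)
        if m > 1:
            xo = rng.random((2 * n, m - 1)) < r
            gam[:, 1:] = gam[:, [0]] ^ np.cumsum(xo, axis=1) % 2
        gametes[lg] = gam
        dosage = gam[0::2] + gam[1::2]          # n x m in {0,1,2}
        codes = np.array(["AA", "AB", "BB"])
        geno = pd.DataFrame(codes[dosage].T, index=ids, columns=samples)
        miss = rng.random(geno.shape) < config.missing_rate
        geno = geno.mask(miss)
        geno_frames.append(geno)
    genotypes = pd.concat(geno_frames) if geno_frames else pd.DataFrame()
    genotypes = genotypes.reindex(markers["marker_id"])
    return MarkerTable(markers.reset_index(drop=True), genotypes), gametes


# ---------------------------------------------------------------------------
# BAC-end pairs
# ---------------------------------------------------------------------------

def simulate_bac_ends(assembly: GenomeAssembly, config: BacForgeConfig,
                      rng: np.random.Generator
                      ) -> tuple[list[AlignmentHit], list[dict]]:
    """Concordant inward-facing read-pair placements (plus an optional
    cross-scaffold fraction), emitted as alignment hits."""
    rl = config.read_len
    eligible = [r for r in assembly
                if r.length > config.insert_mean + 6 * config.insert_sd + 2 * rl]
    if not eligible:
        raise ValueError("no scaffold long enough for the BAC insert length")
    hits: list[AlignmentHit] = []
    truth: list[dict] = []
    for k in range(config.n_pairs):
        pid = f"bac{k + 1:05d}"
        rec = eligible[int(rng.integers(len(eligible)))]
        insert = 0
        while insert < 2 * rl:
            insert = int(rng.normal(config.insert_mean, config.insert_sd))
        start = int(rng.integers(0, rec.length - insert))
        cross = rng.random() < config.cross_fraction
        h1 = AlignmentHit(f"{pid}/1", rl, 0, rl, rec.id,
                          start, start + rl, "+", rl, rl, float(rl))
        if cross and len(eligible) > 1:
            other = eligible[(eligible.index(rec) + 1) % len(eligible)]
            s2 = int(rng.integers(0, other.length - rl))
            h2 = AlignmentHit(f"{pid}/2", rl, 0, rl, other.id,
                              s2, s2 + rl, "-", rl, rl, float(rl))
            truth.append({"pair_id": pid, "status": "cross_scaffold",
                          "insert": None})
        else:
            h2 = AlignmentHit(f"{pid}/2", rl, 0, rl, rec.id,
                              start + insert - rl, start + insert, "-",
                              rl, rl, float(rl))
            truth.append({"pair_id": pid, "status": "same_scaffold",
                          "insert": insert})
        hits.extend([h1, h2])
    return hits, truth


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def forge_genome(config: ForgeConfig | None = None,
                 out_dir: str | Path | None = None) -> ForgeResult:
    """Generate the full synthetic study: genome, truth, markers, map,
    genotypes, BAC and rDNA hit tables; optionally write everything under
    ``out_dir``. Byte-identical for a fixed config and seed."""
    cfg = config or ForgeConfig()
    ss = np.random.SeedSequence(cfg.seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ["background", "tpn", "telomere", "centromere", "rdna",
         "chimera", "f2", "bac", "genes"], ss.spawn(9))}

    chrom_ids = [f"chr{i + 1:02d}" for i in range(cfg.n_chromosomes)]
    chromosomes = {cid: random_background(streams["background"],
                                          cfg.chromosome_len,
                                          cfg.base_composition)
                   for cid in chrom_ids}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_ids}

    truth: list[dict] = []
    tpn_truth = (plant_tpn(chromosomes, cfg, streams["tpn"], occupied)
                 if cfg.tpn.n_intact + cfg.tpn.n_rearranged > 0 else [])
    telo_truth, telo_extras = plant_telomeres(
        chromosomes, cfg, streams["telomere"], occupied)
    cen_truth, cen_monomer = plant_centromeres(
        chromosomes, cfg, streams["centromere"], occupied)
    rdna_scaffolds, rdna_hits, rdna_truth, _ = (
        plant_rdna(cfg, streams["rdna"])
        if cfg.rdna.n_units + cfg.rdna.n_5s > 0 else ([], [], [], {}))
    gene_models = plant_genes(chromosomes, cfg, streams["genes"],
                              occupied, tpn_truth)
    truth += tpn_truth + telo_truth + cen_truth + rdna_truth

    # markers along each regular chromosome; one linkage group per chromosome
    fcfg = cfg.f2
    step_bp = int(fcfg.marker_spacing / fcfg.cm_per_kb * 1000)
    marker_rows: list[dict] = []
    for lg, cid in enumerate(chrom_ids, 1):
        for i, p in enumerate(range(step_bp // 2, cfg.chromosome_len, step_bp)):
            marker_rows.append({"marker_id": f"m{lg}_{i + 1}",
                                "scaffold_id": cid, "position": p,
                                "lg": lg, "cM": p / 1000 * fcfg.cm_per_kb})
    next_lg = cfg.n_chromosomes + 1
    chim_scaffolds, chim_truth, chim_markers, next_lg = make_chimeras(
        cfg, streams["chimera"], next_lg)
    truth += chim_truth
    marker_df = pd.DataFrame(marker_rows)
    if len(chim_markers):
        marker_df = pd.concat([marker_df, chim_markers], ignore_index=True)

    map_df = (marker_df[["lg", "marker_id", "cM"]]
              .sort_values(["lg", "cM"], kind="stable")
              .reset_index(drop=True))
    linkage_map = LinkageMap(map_df)
    marker_table, gametes = simulate_f2(linkage_map, marker_df,
                                        fcfg, streams["f2"])

    records = [ScaffoldRecord(cid, chromosomes[cid].tobytes().decode())
               for cid in chrom_ids]
    assembly = GenomeAssembly(records + telo_extras + rdna_scaffolds
                              + chim_scaffolds)

    bac_hits, bac_truth = ([], [])
    if cfg.bac.n_pairs > 0:
        bac_hits, bac_truth = simulate_bac_ends(assembly, cfg.bac,
                                                streams["bac"])
    truth.sort(key=lambda t: (t["scaffold_id"], t["start"], t["feature_type"]))

    result = ForgeResult(
        config=cfg, assembly=assembly, truth=truth,
        tir_seeds=[TirSeed(FIVE_PRIME, TIR5), TirSeed(THREE_PRIME, TIR3)],
        srr_seeds=[SrrSeed(FIVE_PRIME, SRR5), SrrSeed(THREE_PRIME, SRR3)],
        gene_models=gene_models, markers=marker_table,
        linkage_map=linkage_map, gametes=gametes,
        bac_hits=bac_hits, bac_truth=bac_truth, rdna_hits=rdna_hits)
    if out_dir is not None:
        write_forge_output(result, out_dir)
    return result


def write_forge_output(result: ForgeResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome(result.assembly, out / "genome.fasta")
    write_bed6([GenomicInterval(t["scaffold_id"], t["start"], t["end"],
                                t["strand"] if t["strand"] in "+-" else ".",
                                t["feature_type"])
                for t in result.truth], out / "truth.bed")
    with open(out / "truth.json", "w") as fh:
        json.dump(result.truth, fh, indent=1, sort_keys=True)
    with open(out / "seeds_tir.fasta", "w") as fh:
        for s in result.tir_seeds:
            fh.write(f">tir_{s.end_type}\n{s.seq}\n")
    with open(out / "seeds_srr.fasta", "w") as fh:
        for s in result.srr_seeds:
            fh.write(f">srr_{s.end_type}\n{s.seq}\n")
    geno = result.markers.genotypes.fillna("NA")
    meta = result.markers.markers.set_index("marker_id")
    pd.concat([meta[["scaffold_id", "position"]], geno], axis=1).to_csv(
        out / "markers.tsv", sep="\t", index_label="marker_id")
    result.linkage_map.table.to_csv(out / "map.tsv", sep="\t", index=False)
    write_blast6(result.bac_hits, out / "bac_hits.tsv")
    write_blast6(result.rdna_hits, out / "rdna_hits.tsv")
    write_gff3(result.gene_models, out / "genes.gff3", source="forge")
    with open(out / "forge_config.json", "w") as fh:
        json.dump(asdict(result.config), fh, indent=1, sort_keys=True)
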