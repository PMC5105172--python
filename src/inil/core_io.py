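"""Domain types and file I/O for the genome-curation pipeline.

Coordinate convention: every in-memory interval is 0-based, half-open
``[start, end)``. The 1-based inclusive convention of GFF3/AGP/BLAST-6
exists only at the file boundary; conversion happens exactly once, in the
readers and writers of this module, and is involutive.

Lowercase (soft-masked) sequence is preserved on load and round-trips
through the writers, but every matching step elsewhere in the package
treats case as irrelevant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTNacgtn")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Uppercased sequence as a uint8 byte array, for vectorised scans."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldRecord:
    """One named assembly sequence over {A,C,G,T,N}, case preserved."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or re.search(r"\s", self.id):
            raise ValueError(f"invalid scaffold id {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


class GenomeAssembly:
    """Ordered collection of scaffolds with unique ids."""

    def __init__(self, scaffolds: Iterable[ScaffoldRecord]):
        self.scaffolds: list[ScaffoldRecord] = list(scaffolds)
        seen: set[str] = set()
        for rec in self.scaffolds:
            if rec.id in seen:
                raise ValueError(f"duplicate scaffold id {rec.id!r}")
            seen.add(rec.id)
        self._by_id = {rec.id: rec for rec in self.scaffolds}

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __iter__(self):
        return iter(self.scaffolds)

    def __getitem__(self, scaffold_id: str) -> ScaffoldRecord:
        return self._by_id[scaffold_id]

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self._by_id

    @property
    def total_length(self) -> int:
        return sum(rec.length for rec in self.scaffolds)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.scaffolds]

    def lengths(self) -> dict[str, int]:
        return {rec.id: rec.length for rec in self.scaffolds}


@dataclass(frozen=True)
class GapRun:
    """A maximal run of Ns inside a scaffold, 0-based half-open."""

    scaffold_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomicInterval:
    """Generic positioned feature (GFF3/BED plumbing)."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "."
    feature_type: str = "region"
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad interval [{self.start},{self.end}) on {self.scaffold_id}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class AlignmentHit:
    """One pairwise alignment, both sides 0-based half-open, target forward."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    target_id: str
    target_start: int
    target_end: int
    strand: str
    matches: int
    align_len: int
    score: float

    def __post_init__(self) -> None:
        if not (self.query_start < self.query_end):
            raise ValueError(f"bad query span for {self.query_id}")
        if not (self.target_start < self.target_end):
            raise ValueError(f"bad target span for {self.query_id}")
        if self.matches > self.align_len:
            raise ValueError(f"matches > align_len for {self.query_id}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_genome(path: str | Path) -> GenomeAssembly:
    """Read a FASTA file of scaffolds.

    Rejects duplicate ids, empty records, and any character outside
    {A,C,G,T,N} (either case), naming the offending id and position.
    """
    path = Path(path)
    scaffolds: list[ScaffoldRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if rec.id in seen:
            raise ValueError(f"duplicate scaffold id {rec.id!r} in {path}")
        seen.add(rec.id)
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        bad = set(seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"illegal character {seq[pos]!r} at position {pos} "
                f"of scaffold {rec.id!r}")
        scaffolds.append(ScaffoldRecord(rec.id, seq))
    if not scaffolds:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeAssembly(scaffolds)


def write_genome(assembly: GenomeAssembly, path: str | Path,
                 line_width: int = 60) -> None:
    """Write scaffolds as FASTA, preserving order and case."""
    records = [SeqRecord(Seq(rec.seq), id=rec.id, description="")
               for rec in assembly]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Gap runs
# ---------------------------------------------------------------------------

_GAP_RE = re.compile(r"[Nn]+")


def find_gap_runs(assembly: GenomeAssembly, min_gap_len: int = 10) -> list[GapRun]:
    """All maximal N runs of length >= min_gap_len, sorted by scaffold then start."""
    if min_gap_len < 1:
        raise ValueError("min_gap_len must be >= 1")
    runs: list[GapRun] = []
    for rec in assembly:
        for m in _GAP_RE.finditer(rec.seq):
            if m.end() - m.start() >= min_gap_len:
                runs.append(GapRun(rec.id, m.start(), m.end()))
    return runs


# ---------------------------------------------------------------------------
# Tabular alignments: PAF and BLAST outfmt 6
# ---------------------------------------------------------------------------

def load_alignments(path: str | Path, dialect: str) -> list[AlignmentHit]:
    """Read PAF or BLAST-6 tabular alignments.

    ``dialect`` must be ``"paf"`` or ``"blast6"``; there is no
    auto-detection. Coordinates are normalised to 0-based half-open on both
    sides; BLAST-6 reversed target coordinates become forward coordinates
    with strand "-".
    """
    if dialect not in {"paf", "blast6"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[AlignmentHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "paf":
                    hits.append(_parse_paf(fields))
                else:
                    hits.append(_parse_blast6(fields))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
    return hits


def _parse_paf(f: Sequence[str]) -> AlignmentHit:
    if len(f) < 12:
        raise ValueError("PAF needs >= 12 columns")
    score = None
    for tag in f[12:]:
        if tag.startswith("AS:i:"):
            score = float(tag[5:])
            break
    matches = int(f[9])
    return AlignmentHit(
        query_id=f[0], query_len=int(f[1]),
        query_start=int(f[2]), query_end=int(f[3]),
        target_id=f[5], target_start=int(f[7]), target_end=int(f[8]),
        strand=f[4], matches=matches, align_len=int(f[10]),
        score=score if score is not None else float(matches))


def _parse_blast6(f: Sequence[str]) -> AlignmentHit:
    if len(f) < 12:
        raise ValueError("BLAST-6 needs 12 columns")
    pident, length = float(f[2]), int(f[3])
    qstart, qend = int(f[6]), int(f[7])
    sstart, send = int(f[8]), int(f[9])
    if sstart <= send:
        strand, ts, te = "+", sstart - 1, send
    else:
        strand, ts, te = "-", send - 1, sstart
    matches = min(length, int(round(pident / 100.0 * length)))
    return AlignmentHit(
        query_id=f[0], query_len=max(qend, qstart),
        query_start=qstart - 1, query_end=qend,
        target_id=f[1], target_start=ts, target_end=te,
        strand=strand, matches=matches, align_len=length,
        score=float(f[11]))


def write_paf(hits: Iterable[AlignmentHit], path: str | Path,
              target_lens: Mapping[str, int] | None = None) -> None:
    """Write hits as PAF; score preserved in the AS:i tag."""
    target_lens = target_lens or {}
    with open(path, "w") as out:
        for h in hits:
            tlen = target_lens.get(h.target_id, h.target_end)
            out.write("\t".join(map(str, [
                h.query_id, h.query_len, h.query_start, h.query_end,
                h.strand, h.target_id, tlen, h.target_start, h.target_end,
                h.matches, h.align_len, 255,
                f"AS:i:{int(h.score)}"])) + "\n")


def write_blast6(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in BLAST outfmt-6 columns (1-based inclusive coordinates)."""
    with open(path, "w") as out:
        for h in hits:
            pident = 100.0 * h.matches / h.align_len if h.align_len else 0.0
            if h.strand == "+":
                ss, se = h.target_start + 1, h.target_end
            else:
                ss, se = h.target_end, h.target_start + 1
            out.write("\t".join(map(str, [
                h.query_id, h.target_id, f"{pident:.2f}", h.align_len,
                h.align_len - h.matches, 0, h.query_start + 1, h.query_end,
                ss, se, "0.0", f"{h.score:g}"])) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def load_gene_models(path: str | Path) -> list[GenomicInterval]:
    """Read gene models from GFF3 and derive introns.

    Returns gene, mRNA, exon, CDS and five_prime_UTR features plus one
    derived ``intron`` per gap between consecutive exons of an mRNA. Every
    exon/UTR/intron interval carries ``Parent`` (its mRNA) and ``gene_id``
    attributes. Raises if an exon falls outside its parent mRNA span.
    """
    db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                            merge_strategy="create_unique")
    out: list[GenomicInterval] = []

    def _iv(feat, ftype=None, extra=None) -> GenomicInterval:
        attrs = {k: v[0] for k, v in feat.attributes.items() if v}
        if extra:
            attrs.update(extra)
        return GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                               feat.strand if feat.strand in "+-" else ".",
                               ftype or feat.featuretype, attrs)

    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        out.append(_iv(gene))
        for mrna in db.children(gene, featuretype="mRNA"):
            mrna_id = mrna.attributes.get("ID", [mrna.id])[0]
            out.append(_iv(mrna, extra={"gene_id": gene_id}))
            exons = sorted(db.children(mrna, featuretype="exon"),
                           key=lambda f: f.start)
            for ex in exons:
                if ex.start < mrna.start or ex.end > mrna.end:
                    raise ValueError(
                        f"exon [{ex.start},{ex.end}] outside mRNA {mrna_id}")
                out.append(_iv(ex, extra={"gene_id": gene_id}))
            for left, right in zip(exons, exons[1:]):
                if right.start - 1 > left.end:
                    out.append(GenomicInterval(
                        mrna.seqid, left.end, right.start - 1,
                        mrna.strand if mrna.strand in "+-" else ".",
                        "intron", {"Parent": mrna_id, "gene_id": gene_id}))
            for feat in db.children(mrna):
                if feat.featuretype in {"CDS", "five_prime_UTR"}:
                    out.append(_iv(feat, extra={"gene_id": gene_id}))
    return out


def write_gff3(intervals: Iterable[GenomicInterval], path: str | Path,
               source: str = "inil") -> None:
    """Write intervals as GFF3 (1-based inclusive at the boundary)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for iv in intervals:
            attrs = ";".join(f"{k}={v}" for k, v in iv.attributes.items()) or "."
            out.write("\t".join(map(str, [
                iv.scaffold_id, source, iv.feature_type,
                iv.start + 1, iv.end, ".", iv.strand, ".", attrs])) + "\n")


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed6(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as out:
        for iv in intervals:
            name = iv.attributes.get("Name", iv.feature_type)
            score = iv.attributes.get("score", "0")
            out.write("\t".join(map(str, [
                iv.scaffold_id, iv.start, iv.end, name, score,
                iv.strand if iv.strand != "." else "+"])) + "\n")


def load_bed6(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]),
                                       f[5] if len(f) > 5 else ".",
                                       f[3] if len(f) > 3 else "region",
                                       {"score": f[4]} if len(f) > 4 else {}))
    return out
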