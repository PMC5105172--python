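# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, the parameters that matter, and what the synthetic
studies do and do not demonstrate.

## Coordinates and sequence handling

All in-memory intervals are 0-based half-open. The 1-based inclusive
conventions of GFF3, AGP and BLAST-6 exist only in the readers/writers of
`core_io`, so the conversion happens exactly once and is involutive.
Soft-masked (lowercase) sequence is preserved on round trips but treated
as ordinary bases in every matching step: none of the in-house rules here
depend on masking state, and making case irrelevant keeps results
independent of which masker produced the input. Alignment dialects (PAF
vs BLAST-6) are always stated explicitly — no auto-detection — for
bit-exact reproducibility. N runs shorter than `min_gap_len = 10` are not
treated as scaffold junctions; single or few-N runs inside contigs are
ordinary ambiguity, not scaffolding joins.

## Transposon mining

The element model: 28-bp TIRs at both ends (the right-hand TIR is the
reverse complement of the 3′ seed), a 3–5-bp TSD duplicated exactly (or
with one mismatch) on both flanks, and SRR blocks — tandem 122-bp units
inside the 5′ TIR, 104-bp units inside the 3′ TIR.

*TIR scan.* Ungapped Hamming matching with `max_mismatches = 3` (of 28)
on both strands, vectorised as a shift-and-accumulate over byte arrays.
A deterministic scan was chosen over a heuristic seeded aligner because
at 28 bp the two find the same hits, and the scan is exactly checkable
against an exhaustive sliding-window oracle (a property the test suite
asserts). A chance hit at this threshold requires ≥ 25/28 identity and
has probability ≈ 10⁻¹³ per offset, so random background produces no
nominations (also asserted, on 2 Mb of seed-free sequence).

*Pairing.* Convergent configurations only — 5′-seed forward hit left of a
3′-seed reverse-complement hit (element on +), or the mirror image
(element on −) — with span in `[min_span, max_span] = [60, 50000]` bp.
The bounds bracket the plausible extremes of two-TIR elements
(a floor just above two TIRs plus a TSD; a ceiling above the longest
family members on record, ~41 kb). All eligible pairs are kept; conflicts
are resolved after TSD validation.

*TSD call.* Flank comparison with preference exact-5 > exact-4 >
exact-3 > one-mismatch-3. This ordering reproduces the family's observed
regime — essentially all 3-bp TSDs, rare longer ones, a small fraction
with a single mismatch — without inflating long TSD calls: a spurious
exact 5-mer flank duplication has probability ≈ 10⁻³ per candidate.

*Overlap resolution.* Greedy, by fewest total TIR mismatches, then
lowest TSD Hamming distance, then longest span, then leftmost. Accepted
elements are pairwise non-overlapping.

*SRR status and activity.* Within a sub-terminal window
(`subterminal_window = 600` bp, clipped to half the span), an end is
`present` with ≥ `min_srr_copies = 2` tandem copies of the
end-appropriate unit (per-unit divergence ≤ 0.10) in the expected
orientation, `rearranged` when copies exist but are too few or inverted,
else `absent`. Orientation is read from which end carries the 122-bp-type
block. An element is `putatively_active` iff both ends are `present`;
anything else is `rearranged_inactive`. The window of 600 bp covers at
least two units of either block while staying clear of element
interiors.

*Gene context.* The feature containing the element midpoint wins, with
priority exon > 5′ UTR > intron. Midpoint containment (rather than full
containment) keeps the call stable for elements that slightly overrun a
feature boundary. Introns are derived from inter-exon gaps at load time;
exon features are assumed to cover coding sequence, with `five_prime_UTR`
features written separately (otherwise a UTR-resident element would
always be shadowed by its containing exon).

*Transposase screening.* Identifying autonomous elements (TnpA/TnpD
homologues) requires a translated protein search; the catalog consumes
such hits as tabular alignments and records them as flags rather than
embedding a translated aligner.

## Repeat landscape

*Monomer-seeded arrays.* Matches of the monomer (Hamming, divergence ≤
`max_divergence`) are chained when their starts advance by about one
period; the matched core is then extended outward while the sequence
continues its own period exactly (`seq[i] == seq[i − m]`). This makes
detection independent of the phase/rotation of the query monomer and
yields fractional copy numbers as span/monomer-length (e.g. ten units of
`AAACCCT` plus a trailing `AAAC` → 74/7 ≈ 10.571 copies), matching the
fractional "repeating units" convention used for telomere reporting.
Edges may extend a base or two beyond a planted array wherever background
coincidentally continues the period; spans are therefore compared to
truth within one monomer length.

*Telomeres.* A scaffold is `both_ends`/`one_end`/`internal_only` by
whether arrays intersect the first/last `end_window = 10000` bp;
`fully_telomeric` (coverage ≥ `full_cover_fraction = 0.95`) overrides.
Both defaults quantify qualitative notions ("at the ends", "completely
covered") that have no canonical values; they are stated in the output.

*Period inference.* The dominant period of a window is the lag in
`[2, max_period]` minimising the normalised Hamming distance of the
window against itself; among lags within 0.01 of the minimum the
smallest is returned, so the fundamental period beats its multiples.
Windows whose best lag still mismatches > 0.25 of positions are called
aperiodic. The consensus is the column-majority base per phase class.

*Centromere candidates.* Arrays with monomer length in 160–190 bp
(a band around the 173-bp satellite) and span > 3 kb are merged when
separated by ≤ 50 kb; the longest merged stretch per chromosome
approximates the centromere position. Merging is idempotent.

*rDNA.* NOR units are strand-consistent 18S → 5.8S → 25S chains
(coordinate-mirrored on the minus strand) with inter-component spacing
≤ 5 kb, each hit used at most once; 5S hits cluster at ≤ 50 kb gaps and
are reported independently of NOR scaffolds. Components come from
seed-sequence alignments labelled in the query id, not from covariance
models, so no external RNA-family database is required.

## Map-guided curation

*80/80 filter.* Drop markers genotyped in < 80 % of current samples,
then samples carrying < 80 % of surviving markers, iterated to a fixed
point. The fixed point makes the result independent of how many times
the two steps are applied (given their stated order); per-round drop
counts are reported.

*Flank repeat filter.* A marker is dropped iff any non-self alignment of
its extracted ±150-bp flank region exceeds 150 aligned bases. Markers
whose flanks run off the scaffold are clipped, kept and flagged.

*Scaffold chimeras.* A split is called where ≥ `min_block = 2`
consecutive markers of one linkage group are followed by ≥ 2 of another
with an N gap strictly between the blocks; the junction is the longest
such gap (tie: leftmost). Two markers per block is the smallest
"stretch" that is not a single mis-mapped marker; conflicting signals
without a qualifying gap are flagged, never split. Splitting discards
the junction Ns and names children `<id>_1`, `<id>_2`; non-N bases are
conserved exactly.

*Contig chimeras.* With no gap at the transition, the contig is cut in
three: the left part ends at the last marker of the first block, the
right part starts at the first marker of the second, and the middle —
which must contain the true junction — stays chimeric but shorter.
Concordant BAC-end pairs lying wholly on one side may tighten (never
override) the marker-defined edges, since paired-end evidence localises
the junction no further than the innermost concordant insert.

*Pseudo-chromosomes.* Within each linkage group, scaffolds are ordered
by the median cM of their markers and oriented by the sign of the
Kendall concordance between marker position and cM; scaffolds with < 2
informative markers or a tied statistic are included unoriented (kept as
+, flagged). Scaffolds join through `gap_size = 100` N spacers (the gap
size is a bookkeeping convention, not an estimate). The AGP v2.0 rows
(`scaffold` gaps, evidence `map`) reconstruct the emitted FASTA
byte-identically. A scaffold whose markers still point at two linkage
groups is an error at this stage — chimera resolution must run first.

## Assembly QC

N50/L50 follow the descending-cumulative-length definition. BAC-end
pairing enumerates hit combinations per read pair; eligible combinations
are same-target, opposite-strand, inward-facing, insert ≤ 400 kb (4× the
expected ~100-kb insert), scored by the sum of the two hits' native
scores (bit score for BLAST-6, `AS` tag or match count for PAF), ties to
the smaller insert. Orientation is constrained because outward-facing
placements cannot arise from an intact clone. Pairs with both reads
aligned but no eligible combination are cross-scaffold. The same-scaffold
rate is reported against both denominators (both-aligned, and all pairs)
since the choice is a reporting convention. EST coverage takes, per
query, the union of query-side spans against the best-scoring target.

## The synthetic forge

One RNG stream per feature class, spawned in fixed order from the master
seed (numpy `SeedSequence`), so resizing one feature class never
perturbs another; output is byte-identical per seed.

What it emulates, and the defaults:

- Background: i.i.d. bases at 62 % AT (A=T=0.31, C=G=0.19), a typical
  plant-genome composition; 10 chromosomes × 500 kb.
- Elements: 50 intact + 5 rearranged, length log-uniform over the family
  range (161–40,619 bp), TSDs of 3 bp drawn with per-base weights
  A=T=0.316, C=G=0.184 — back-solved so P(TSD contains A or T) =
  1 − 0.368³ ≈ 0.95 — and a 14/339 fraction carrying one TSD mismatch.
  Two constraints depart from a literal draw: (i) an element carrying
  both SRR blocks cannot be shorter than its fixed anatomy, so intact
  draws are clamped to ≥ 1,200 bp (the shortest real family members are
  SRR-less degenerates the activity classifier would call inactive
  anyway); (ii) elements on one chromosome are spaced by more than the
  miner's span ceiling, and flanking background is redrawn if it would
  create a spurious exact 4/5-mer duplication around a span. Both are
  truth-integrity guarantees: they make the planted catalog the unique
  correct answer, which is what lets recall/precision be asserted at
  exactly 1.
- Telomeres/centromeres/rDNA: `AAACCCT` arrays (forward at left ends,
  reverse-complemented at right ends, 50–400 copies, plus fully
  telomeric scaffolds); one 173-bp satellite array per chromosome at 2 %
  per-base divergence; dedicated NOR (18S–5.8S–25S) and 5S scaffolds
  with the matching component-labelled hit table.
- Chimeras: fresh source-chromosome pairs joined prefix + N gap + suffix
  (or seamlessly for contig-level events), with markers remapped and the
  junction recorded.
- F2 population: 200 progeny, markers every 10 cM (0.2 cM/kb), two
  independent gametes per progeny with per-interval crossover probability
  `r = (1 − e^(−2d))/2` (Haldane — the standard minimal no-interference
  model for exercising map logic), 5 % missing genotypes.
- BAC ends: 500 inward-facing pairs, insert ~ Normal(100 kb, 10 kb)
  truncated positive, placed uniformly on scaffolds long enough to hold
  them; an optional cross-scaffold fraction.

What the forge does **not** emulate: sequencing error, read-level data,
the real genome's overall repeat content (~63 % repetitive), nested or
fragmented element copies, segregation distortion, or crossover
interference. Passing the planted-truth suites therefore demonstrates
the correctness of the rules on clean signals at desk scale, not
detection power on a real 735-Mb assembly, where diverged and nested
copies make recall a property of the seed set as much as of the
algorithm.

## Problem sizes and determinism

The standard synthetic studies are sized for quick, repeatable runs on a
single CPU: a 5-Mb genome for mining and anchoring, a 20-chromosome
suite with 13 chimeras for curation, 2,000 TSD draws, 400 gametes. All
statistical assertions use 3σ (or slightly wider multi-comparison)
bounds derived from the binomial/CLT sampling error at those sizes.
`scripts/acceptance.py --seed N` reruns everything from scratch; every
reported number is computed at run time.

## Known limitations

- TIR matching is ungapped; an element with an indel inside a TIR is
  found only via the other end's seed variants.
- `detect_srr` reads tandem structure through seed matching, so SRR
  blocks diverged > 10 % per unit from the seeds read as absent.
- The contig-level split places boundaries at marker/anchor positions;
  without dense markers the middle (still-chimeric) part can be large.
- The 5S "cluster" definition (≤ 50 kb gaps) and the NOR spacing cap are
  operational choices; real NOR intergenic spacers vary by species.
- `infer_monomer` assumes one dominant period; interleaved satellites
  return only the strongest.
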