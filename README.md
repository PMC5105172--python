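# inil — genome curation for CACTA/*Tpn1*-rich plant assemblies

`inil` is a toolkit for the bespoke curation computations that turn a draft
plant genome assembly into an annotated, chromosome-scale resource, built
around the biology of *Ipomoea nil* (Japanese morning glory) and its
*Tpn1*-family CACTA transposons — the major spontaneous mutagen of that
species. It is aimed at assembly and repeat-annotation practitioners who
need these steps as reproducible, testable library code rather than
one-off scripts.

It provides five cooperating components:

1. **Transposon mining** (`inil.tpn_miner`). *Tpn1*-family elements are
   bounded by 28-bp terminal inverted repeats (TIRs), flanked by a 3–5-bp
   AT-rich target-site duplication (TSD), and carry sub-terminal
   repetitive regions (SRRs: tandem 122-bp units at the 5′ end, 104-bp
   units at the 3′ end) required *in cis* for transposition. The miner
   scans both strands for TIR seeds with a Hamming budget (≤ 3 of 28),
   pairs convergent hits into candidate spans, validates the TSD on the
   immediate flanks (preference: exact 5 > exact 4 > exact 3 > 3 with one
   mismatch), resolves overlaps greedily, determines orientation and
   activity from the SRR blocks (both present ⇒ putatively active;
   missing/inverted ⇒ rearranged, inactive), and annotates gene context
   (exon / 5′ UTR / intron) from GFF3 gene models.
2. **Repeat landscape** (`inil.repeat_landscape`). Monomer-seeded tandem
   array detection (rotation- and strand-aware, fractional copy numbers
   `span / monomer length`), telomere classification from the `AAACCCT`
   unit, satellite period inference by minimum-normalised-Hamming
   self-alignment (the ~173-bp centromeric monomer), the > 3 kb / 50 kb
   centromere-stretch merge rule, and 18S–5.8S–25S NOR unit chaining plus
   5S cluster counting from component-labelled alignments.
3. **Map-guided curation** (`inil.map_curation`). The 80/80
   marker/sample genotype completeness filter (iterated to a fixed
   point), the 150-bp flank repeat filter, chimera detection where marker
   blocks of two linkage groups are separated by an N gap (split in two
   at the junction) or meet inside a contig (split in three, the middle
   part keeping the shortened junction), and pseudo-chromosome
   construction: order scaffolds by median cM, orient by Kendall
   concordance of position vs cM, join with N spacers, emit AGP v2.0.
4. **Assembly QC** (`inil.assembly_qc`). N50/L50 statistics, BAC-end
   read-pair scoring (best combined-score inward-facing placement,
   same-scaffold rate, insert distribution) and EST coverage summaries.
5. **Synthetic forge** (`inil.synthetic_forge`). A seeded generator that
   emits genomes containing all of the above — planted elements with
   known TSDs and SRR states, telomere/centromere/rDNA arrays, chimeric
   scaffolds, an F2 population genotyped under the Haldane map function
   `r = (1 − e^(−2d))/2`, and BAC-end pairs with ~100-kb inserts —
   together with machine-readable truth for every feature, so each stage
   is testable at desk scale.

## Worked example

Forge a 5-Mb study genome and mine it:

```bash
inil-forge --seed 11 --out-dir forged
inil-tpn --genome forged/genome.fasta \
         --tir-seeds forged/seeds_tir.fasta \
         --srr-seeds forged/seeds_srr.fasta \
         --gene-models forged/genes.gff3 --out-dir tpn_out
cat tpn_out/catalog_stats.json
```

prints

```json
{
 "count": 55,
 "in_gene_count": 3,
 "max_len": 35784,
 "mean_len": 9925.763636363636,
 "min_len": 1212,
 "rearranged_count": 5,
 "tsd_at_fraction": 0.9454545454545454,
 "tsd_len_histogram": {"3": 55},
 "tsd_mismatch_count": 2,
 "undefined_ratios": false
}
```

All 55 planted elements (50 intact + 5 SRR-rearranged) are recovered with
exact spans; the 5 rearranged ones are classified inactive; 3 sit inside
gene features (two introns, one 5′ UTR); 52 of 55 TSDs contain an A or T,
matching the ~95 % AT-containing regime the TSD base weights encode.

The same forge output drives the other commands:

```bash
inil-repeats --genome forged/genome.fasta --rdna-hits forged/rdna_hits.tsv \
             --out-dir rep_out
inil-curate  --genome forged/genome.fasta --markers forged/markers.tsv \
             --linkage-map forged/map.tsv --out-dir cur_out
inil-qc      --genome forged/genome.fasta --bac-hits forged/bac_hits.tsv \
             --out-dir qc_out
```

`cur_out/anchoring_stats.json` reports 10 of 13 scaffolds (99.33 % of the
assembly length) anchored into 10 pseudo-chromosomes — the telomere-only
and rDNA scaffolds carry no markers and pass through unanchored — and
`qc_out/qc_summary.json` shows a 100 % same-scaffold BAC pairing rate with
a mean insert near 100 kb.

With real data, the same functions consume a genome FASTA, GFF3 gene
models, TIR/SRR/rDNA seed FASTAs, a marker × sample genotype TSV, a
linkage-map TSV, and PAF or BLAST-6 tabular alignments produced by your
aligner of choice.

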