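# Methods

## The calling model

A double nucleotide polymorphism (DNP) site is defined by two adjacent
1-based positions and two dinucleotide alleles (reference and
alternative, differing, both over ACGT). The caller treats the two
positions as a single two-base marker and genotypes it per individual
from reads, never from per-position calls:

1. **Windowed pileup with read names.** The pileup covers four bases —
   the two DNP positions plus the directly upstream and downstream
   flanks — and every observation carries its read identifier. Two
   backends exist: a native one over indexed BAMs (pysam/htslib) and a
   parser for the standard mpileup text dialect with the read-name
   column, which doubles as an independent oracle in the test suite.
   Unmapped, secondary, supplementary, duplicate and QC-fail alignments
   are excluded; reads below the mapping-quality floor and bases below
   the base-quality floor are dropped (a dropped base means the read
   does not cover that position).
2. **Read grouping.** Observations are joined by read name into one
   two-base microhaplotype per read. Because a read comes from a single
   chromosome, this is a physical phase measurement, not an inference.
3. **Indel discard.** Any read with an indel annotation at a window
   position it covers — an inserted/deleted segment immediately after a
   position, or a position spanned by a deletion — is discarded and
   counted. Indels from sequencing error near the DNP cause reference
   bias (reads carrying the alternative allele plus an indel tend to
   realign as reference), so the flanks are screened as well as the DNP
   positions themselves. A read's flank check applies only to flank
   positions it actually covers; a read starting exactly at the first
   DNP position is not penalized for lacking an upstream flank, and a
   flank outside the contig is simply absent from the window.
4. **Counting.** Each retained read that covers both positions
   contributes one dinucleotide, classified as reference, alternative
   or *other* (anything else, including N-containing pairs). The full
   tally is reported as `combined_bases`/`combined_counts`.
5. **Likelihoods and assignment.** See below.

## Genotype likelihoods

The model is the standard biallelic diploid per-read mixture used for
single-base genotype likelihoods, with two adaptations for dinucleotide
alleles:

* a read's error probability uses the **arithmetic mean of its two
  phred qualities**: ε = 10^(−(q₁+q₂)/20);
* the mismatch probability is taken as ε itself rather than ε/3 — the
  alternative allele is a dinucleotide, not one of three alternative
  bases, so the 1/3 partition of the single-base model does not apply.

For g ∈ {0,1,2} copies of the alternative allele, a reference-showing
read contributes ((2−g)(1−ε) + gε)/2 and an alternative-showing read the
complementary form; GLg is the sum of log₁₀ factors over informative
reads. GL values are reported raw (not rescaled to a zero maximum).
Useful identities, both enforced by tests: GL1 = m·log₁₀(½) exactly for
m informative reads, and with zero informative reads the empty product
gives (0, 0, 0).

Reads in the *other* class are excluded from the likelihood but drive
the refusal rule: a genotype is withheld when N_Other/(N_ref+N_alt)
exceeds 0.1 (strictly), when N_ref+N_alt = 0, or when the maximum
likelihood is tied (a tie arises only in pathological symmetry; the
caller refuses to guess). The output prints `NA` in all cases; the log
records the reason (`no_informative_reads`, `other_ratio_exceeded`,
`likelihood_tie`, `pileup_error`).

## Overlapping mates

A mate pair is one DNA fragment from one chromosome, so two overlapping
mates must not be double-counted. When both mates report the same base
at a window position they are merged into a single observation at the
higher quality; if they disagree, the whole fragment is dropped. The
rule is applied uniformly at every window position (not only the two
DNP positions) — simpler, deterministic, and a flank disagreement is
itself evidence of a problematic fragment. Consequently the native
pileup backend keeps both mates visible (`ignore_overlaps=False`) and
leaves the resolution to the grouping step.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_baseq` | 13 | phred floor below which a base does not count as coverage (the mpileup convention) |
| `min_mapq` | 0 | mapping-quality floor for reads entering the pileup |
| `max_depth` | 100 000 | pileup depth cap; effectively uncapped so counts are never silently truncated |
| other-ratio threshold | 0.1 | strict upper bound on N_Other/(N_ref+N_alt) for a call |

The quality floors match the defaults of the external mpileup tool;
whether the original pipeline applied any stricter floor is unknown, so
these are declared choices, exposed as CLI options. No BAQ recomputation
is performed (a deliberate non-goal; the oracle tests run the external
tool with BAQ disabled accordingly).

## Output conventions

`full_output_<sample>.txt` columns: chrom, pos1, pos2, ref, alt, N_ref,
N_alt, N_other, combined_bases, combined_counts, GT, GL0, GL1, GL2,
reads_discarded_for_indels, ratio_reads_discarded_for_indels.
`combined_bases` is sorted by descending count then lexicographically;
floats use 6 significant digits; the discard ratio's denominator is the
number of reads covering both DNP positions before the indel discard
(0/0 → 0). The exact column order, headers and float format are this
package's declared conventions — equivalents of, not byte-level clones
of, any other implementation's tables. Sample names come from BAM
basenames; collisions are an error rather than silent suffixing.

Parallelism is per sample; results are assembled in bamlist order, so
output files are byte-identical with and without `--parallel` (a tested
invariant). The caller itself uses no randomness.

## Synthetic data

`synthetic_fixtures` builds complete seeded test worlds: a random
reference FASTA, panels of non-overlapping DNP sites (reference
dinucleotide read from the FASTA, alternative differing at both
positions, consecutive sites ≥ 250 bp apart so 100 bp reads of one site
never touch another site's window), and real coordinate-sorted, indexed
BAMs — the pileup engine is always exercised end to end, never mocked.

Scenario defaults are coverage 20, read length 100, base error rate
10⁻³ with the matching constant phred quality (30), half the reads on
each strand. The heterozygous scenarios draw each read's haplotype with
probability ½; the trans-SNP scenario puts one derived base on each
haplotype; the triallelic scenario mixes ref/alt/third at
0.35/0.35/0.30 so its expected other-ratio (≈0.43) sits firmly above
the 0.1 threshold; the indel scenario plants, per read with probability
`indel_rate`, either a 1-bp insertion immediately after the first DNP
position or a deletion of the upstream flank base, with correct CIGARs.

What the generator does **not** emulate: platform-specific error
profiles (e.g. the homopolymer-indel-rich profile of some sequencers),
mapping ambiguity from repeats, variable per-base qualities within a
read, alignment artifacts around true germline indels, and contaminated
or damaged samples. Passing tests therefore demonstrate correctness of
the counting, filtering and likelihood machinery under clean mapping
assumptions — not robustness to every real-data pathology.

## Problem sizes in the test and acceptance runs

The recovery experiments use 500 simulated sites per genotype class at
coverage 20 and 0.1% base error, batched as one multi-site BAM per
class on a 130 kb contig; discrimination uses 100 trans sites across
coverages 1–50 and 100 cis-heterozygous sites; indel accounting uses 60
sites at 30× with a 0.3 planting rate. These sizes give stable
percentages (recovery ≈ 99.9%) while keeping a full run in the order of
seconds.

## Known limitations

* Only 2-base variants: longer multi-nucleotide variants and general
  microhaplotypes would need a wider window and k-mer alleles (the
  grouping principle generalizes, the current data model does not).
* No CRAM input; no VCF output (bespoke TSVs only).
* The `NA` of a zero-coverage site and the `NA` of an over-threshold
  other-ratio print identically in the tables; the distinction lives
  only in the run log.
* Cohort counters weigh every site equally; no allele-frequency or
  population-structure modelling is attempted.
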