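# Methods

## Coordinate and evidence model

All internal coordinates are 0-based half-open; GFF3/SAM/VCF boundaries are
converted at the I/O layer only, and user-facing junction and variant
positions are printed 1-based. SAM is handled as text (via pysam); the
pipeline starts at alignments, so any upstream aligner can feed it.

An integration event is described by the 1-based last retained host base of
the 5′ flank (`left_junction`), a non-negative flanking deletion, an
orientation and a zygosity. The modified haplotype is
`host[1..L] + construct + host[L+d+1..]`. Two evidence classes identify it
in paired-end DNA data:

1. **Bridging pairs** — one primary mate on a host scaffold, the other on
   the construct. The construct mate is labelled P/C/T by maximal overlap
   with the promoter / cassette / terminator segments; the LB border counts
   toward the promoter side and the RB border toward the terminator side,
   so evidence at either construct end is always attributable to a side.
2. **Chimeric split reads** — a primary host-side record with a soft clip
   whose remainder maps to the construct. A host segment clipped at its
   reference-right (3′) end gives junction = `pos + refspan − 1`; clipped
   at its 5′ end, junction = `pos`. Per side, the modal position across
   supporting reads is reported; ties break toward the larger construct-side
   support, then the smaller coordinate, with a tie flag.

With the last-retained-base convention a clean insertion yields
`pos_T = pos_P + 1`, and the deletion between junctions `p < t` is
`t − p − 1` bases; a negative difference (overlapping junctions) is flagged
`complex` rather than forced into a deletion length. Candidates lacking
chimeric support on one side stay `complex` too — that is the expected
outcome near repeat-dense or misassembled regions, which this package
reports but does not attempt to reconstruct.

**Clustering.** Bridging pairs are grouped per scaffold with a positional
window defaulting to twice a generous maximum insert size (a bridging
pair's host anchor lies within one fragment length of the junction; pass
`2 × max_insert` from `estimate_insert_bounds` for data-driven windows).
The `min_support` exclusion (default 10 pairs) applies to the per-scaffold
P+T total, matching how support is usually reported (per-site totals first,
P/T split second); a per-side threshold can be emulated by filtering the
returned counts.

**Insertion zygosity.** Reads mapping unclipped across the junction
(≥ 10 host bases on both sides) can only come from an unmodified
haplotype. Zero such reads calls a homozygous insertion only when ≥ 10
records overlap a ±50 bp window around the junction — homozygosity is never
inferred from missing data.

## Fusion transcripts

Fusion evidence is read pairs against a transcriptome + cassette reference
with one primary mate on a cassette and one on a host transcript; the host
mate's exon rank comes from its transcript-space position. Reads should be
pre-cropped to a common short length (36 nt default in the CLI pipeline,
via `transform_reads`) so junction-spanning mates still map end-to-end;
genome-space coverage profiling uses full-length reads. The default
minimum fusion support is 3 pairs — the evidence observed in practice is
usually far higher, but no published threshold exists, so the value is
configurable.

Disruption zygosity counts wild-type connections across the insertion
intron k: mate pairs linking exons ≤ k to exons ≥ k+1 and (by default)
single reads crossing the exon-k/k+1 boundary in transcript space; a
strict pairs-only mode (`count_spliced_singles=False`) reproduces the
narrower reading. `hom_disrupted` requires zero wild-type support *and*
≥ 10 informative records near the boundary; `het_disrupted` requires both
evidence classes. Construct-to-site assignment is direct where a disrupted
gene has fusion evidence for one construct, and by elimination (flagged
`inferred_by_elimination`) when exactly one construct and one candidate
remain; contradictory evidence yields a `conflict` flag, never a guess.

## Variant calling and filters

The pileup genotyper is a deliberate simplification of a likelihood-based
caller: per position it tallies bases with BQ ≥ 20 (depth counts all
reads), and emits the plurality non-reference allele when it has ≥ 2
supporting reads and ≥ 20 % of counted bases — enough to suppress isolated
errors without a genotype model. Indels come from I/D CIGAR ops in the
left-aligned anchored-base VCF convention. Because the genotype-likelihood
model is out of scope, raw call counts on real data will differ from a
bcftools-style caller even where filter behavior is identical.

Filter profiles:

| rule | genomic | transcriptomic |
|---|---|---|
| min quality / mean MQ | 20 / 20 | 20 / 20 |
| coverage | 4 … sample max | ≥ 4 |
| MQ0 fraction | ≤ 0.10 | ≤ 0.10 |
| alt reads per strand | ≥ 1 | — |
| alt fraction | — | ≥ 0.9 |
| SNV near indel | — | ≤ 10 nt |
| indel pair | — | ≤ 100 nt |
| SNV cluster | — | 3 in ≤ 10 nt |

Numerical/design choices:

- The transcriptomic dialect's "minimum fraction of 0.1 MQ0 reads" is
  implemented as a **maximum** (≤ 0.10), consistent with the genomic
  dialect; a minimum would select for ambiguous mappings. The literal
  reading is available behind `literal_mq0f_minimum`.
- Positional exclusions are evaluated on the raw candidate set *before*
  per-variant quality rules: artifact clusters should suppress neighbors
  even when some members independently fail other filters. The cascade is
  idempotent and the per-variant rules are order-independent.
- The SNV-cluster rule removes **all** members of a qualifying cluster.
- Consensus-error subtraction is position-level and allele-agnostic
  (any varying position in the self-mapped call set is removed).
- The sample-specific coverage ceiling defaults to `round(1.45 × mean
  depth)` when not supplied — the ratio implied by published ceilings of
  30 at 21× and 26× at 38 — and is always overridable.
- Divergence is SNVs per Mbp of CDS positions with depth ≥ 4; the display
  value is rounded half-to-even to integer precision, full precision is
  retained internally.
- The impact classifier is codon-level and strand-aware (standard code):
  frameshift / stop-gain / stop-loss / start-loss / splice-site (2 intronic
  bases at exon boundaries) → HIGH, missense / in-frame indel → MODERATE,
  synonymous → LOW. A transcript whose CDS length is not a multiple of 3 is
  flagged and its annotations carry a low-confidence marker.

## Expression

Counting is union-mode at fragment level: a fragment counts once for the
single gene whose merged exons its aligned blocks overlap; fragments
touching two genes are discarded as ambiguous; intron-only fragments are
uncounted. Target-region masking drops any fragment overlapping a masked
interval from its gene's count, removing construct-derived reads that
would bias fold changes of the targeted genes. Effective gene length for
FPKM is the merged-exon union length, consistent with union-mode counting.

`TPM_i = (FPKM_i / Σⱼ FPKMⱼ) × 10⁶`, so a gene at FPKM = 1 has
`TPM = 10⁶ / Σⱼ FPKMⱼ`; that value is the per-sample expression threshold.
The DEG caller reproduces only the deterministic gates — mean normalized
count ≥ 10 across all samples, |LFC| ≥ 0.5 on `log2((mean_B + 1)/(mean_A +
1))`, and TPM ≥ threshold in at least one condition — not a
negative-binomial test or LFC shrinkage, which belong to an external
model. Whether the mean filter uses raw or normalized counts is not
specified anywhere; normalized counts are used. Median-of-ratios size
factors follow the standard convention (factor = median over
everywhere-nonzero genes of count / geometric-mean row), under which
identical samples get factors of 1 and a doubled sample has twice the
factor of its partner.

## Gene-set QC and annotation

Exonpart hints are maximal covered segments with their mean coverage
clipped into [20, 300] (`floor_mode="drop"` removes sub-floor segments
instead — the published wording is ambiguous between the two); intron
hints carry the full N-op span with a support count. The 1 % hint-support
rule is per transcript: hint-covered exonic positions / total exonic
length ≥ 0.01 (exonic length is the natural denominator for exonic
evidence). TE overlap is summed over all CDS intervals against the merged
repeat track; the retention boundary is > 10 nt. Peptides shorter than
10 aa are dropped.

The aligned fraction of a homology hit is the maximum total query coverage
achievable by pairwise non-overlapping HSPs, solved exactly by weighted-
interval scheduling with weight = covered length (the definition is about
coverage, not summed bitscore). The annotation cascade walks tiers in
order, takes the best passing hit (E ≤ 10e-10, ≥ 70 aa, ≥ 90 % identity,
aligned-fraction criterion, descriptor not in {uncharacterized, unknown,
hypothetical}), and lets the rest fall through. The printed
aligned-fraction filter is a ceiling (≤ 0.90), which rejects
near-full-length matches and is suspected inverted; the ceiling is the
replication default and a `≥ 0.70` preset is provided, with the comparator
in force recorded in every annotation.

## What the simulator emulates — and does not

The generator produces: random-sequence scaffolds with embedded multi-exon
genes (ATG…stop, GT..AG introns, CDS ≡ exons), labelled repeat intervals;
construct insertions (default constructs reproduce the deposited insert
geometry: LB 73 + promoter 2,700 + cassette 840/1,072 + terminator 850 +
RB 73 nt, i.e. 4,536 nt and 4,768 nt totals); paired-end fragments from a
normal insert distribution truncated to [2 × read length, ∞) (defaults
125 bp reads, 700 ± 50 bp inserts — the spread is a choice, only the peak
and mapper bounds are documented); exact truth alignments with soft-clipped
primary/supplementary chimeric records; spliced RNA fragments proportional
to abundance × length with fusion transcripts; and Poisson-planted SNVs
and short indels with a chosen Ti/Tv. Sequencing errors are substitutions
only; filter-cascade tests inject artifacts explicitly instead.

Not emulated: mapping ambiguity (truth alignments are exact, so MQ0 and
mismapping artifacts must be injected), repeat-mediated misassembly, UTRs
(CDS ≡ exon), positional error/coverage biases, PCR duplicates beyond
simple duplication, and more than two haplotypes. Passing tests therefore
demonstrate the correctness of the *decision rules and arithmetic* under
the stated statistical structure — not robustness to real-world mapping
noise, which depends on the upstream aligner.

## Problem sizes used by the test suite

The acceptance-style tests run 50 insertion scenarios on a 1 Mb host at
30× (junctions, lesions 0–500 bp, and zygosity recovered exactly),
divergence calibration at 10 / 67 / 8,152 SNV per Mbp on a 1 Mbp CDS track
(within 3√rate), Ti/Tv calibration with 50,000 planted SNVs at 1.4
(± 0.05), brute-force equivalence checks for the positional filter rules
(10,000 variants) and the HSP scheduler (1,000 instances ≤ 10 HSPs), and
the TPM identities on random matrices. The full suite runs in under two
minutes on one CPU.

## Known limitations

- The pileup genotyper has no genotype likelihoods; het/hom calls ride on
  allele fractions downstream, not on the caller.
- Junction calling reports the modal coordinate; systematically shifted
  split alignments (e.g. microhomology at the junction) would shift the
  mode, as they would for any split-read caller.
- `complex` lesions are reported, not resolved; rearrangement
  reconstruction is out of scope.
- The DEG gates are decision rules without error control; they are not a
  substitute for a count-model test when replicate structure supports one.
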