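# xenolocus

Characterization of transgene integrations in a host genome from paired-end
sequencing data.

When a transgenic line is produced by T-DNA transformation, the construct
lands at an unpredictable genomic position and may delete flanking host
sequence, disrupt a gene, or splice itself into a fusion transcript driven
by its own promoter. `xenolocus` implements the computational side of a
molecular characterization of such a line:

- **Insertion-site detection** — from alignments against a combined
  host + construct reference, *bridging pairs* (one mate on a host
  scaffold, one on the construct, labelled P/C/T by the promoter /
  cassette / terminator segment they hit) locate candidate scaffolds, and
  *chimeric split reads* (primary + soft-clipped supplementary records)
  place both junctions at base-pair precision. Junction convention:
  the reported coordinate is the last retained host base (1-based), so the
  flanking deletion between a promoter-side junction `p` and a
  terminator-side junction `t` is `|t − p| − 1` bases. Clusters with fewer
  than 10 bridging pairs are excluded.
- **Fusion transcripts and zygosity** — read pairs with one mate on a
  construct cassette and one on a host transcript ("insert mate" / "host
  mate") evidence a fusion RNA; absence of read pairs linking the exons
  flanking the insertion intron, at adequate local depth, indicates both
  alleles are disrupted (homozygosity).
- **Variant filter cascades** — a pileup genotyper plus two named filter
  dialects (`genomic`: coverage window, MQ0 fraction ≤ 0.10, ≥ 1
  alternative read per strand; `transcriptomic`: positional artifact rules
  — SNVs within 10 nt of an indel, indel pairs within 100 nt, 3-SNV
  clusters within 10 nt — and alternative-allele fraction ≥ 0.9),
  consensus-error subtraction, call-set partition, Ti/Tv, and
  CDS-restricted divergence as SNVs per Mbp of positions with ≥ 4×
  coverage.
- **Expression filters** — union-mode fragment counting with target-region
  masking, depth and median-of-ratios normalization, FPKM/TPM with the
  sample-specific expression threshold `10⁶ / Σⱼ FPKMⱼ` (the FPKM→TPM
  conversion at FPKM = 1), and the threshold-based differential-expression
  gates (mean count ≥ 10, |LFC| ≥ threshold, TPM gate).
- **Gene-set QC** — expression hints (exonpart coverage clamped into
  [20, 300], intron hints from spliced reads), retention rules (≥ 1 %
  hint support, ≤ 10 nt CDS–transposon overlap, ≥ 10 aa peptide), the
  twelve standard gene-set metrics, and a tiered homology-annotation
  cascade whose aligned fraction is the maximum query coverage by mutually
  compatible (non-overlapping) HSPs, solved by weighted-interval
  scheduling.
- **A synthetic-data generator** (`xenolocus.simulate`) that produces host
  genomes with multi-exon genes, construct insertions with configurable
  lesion and zygosity, paired-end DNA reads with exact truth alignments
  (including bridging and chimeric evidence), spliced RNA-seq reads with
  fusion transcripts, and variants planted at chosen densities and Ti/Tv
  ratios — so every stage is testable end-to-end with no downloads.

## Worked example

Simulate a homozygous insertion with a 28-base flanking deletion at host
position 25,000 and recover it from the alignments:

```bash
xenolocus simulate --out-prefix demo --scaffold-length 50000 \
    --insert-at 25000 --deleted 28 --depth 20 --seed 3
xenolocus insertion-scan --sam demo.truth.sam \
    --constructs demo.constructs.fasta --out cands.tsv
cat cands.tsv
```

```
scaffold  P   T   junction_P  junction_T  lesion  support  zygosity
scf01     60  51  25000       25029       28      111      hom
```

Reading: 60 promoter-side and 51 terminator-side bridging pairs cluster on
`scf01` (111 ≥ the 10-pair threshold); split reads place the junctions at
25,000 and 25,029, i.e. host bases 25,001–25,028 (28 bases) were deleted by
the integration; no unclipped read spans the junction, so the insertion is
homozygous.

The same arithmetic applied to the published junction pair:

```python
>>> from xenolocus import infer_lesion
>>> infer_lesion(27872, 27901)
28
```

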