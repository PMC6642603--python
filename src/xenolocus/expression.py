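"""Fragment counting, target-region masking, normalization, FPKM/TPM with
the sample-specific TPM expression threshold, and the threshold-based
differential-expression gates.

The differential-expression model here is deliberately the printed decision
rules, not a negative-binomial test: genes with mean normalized count < 10
across replicates and conditions are removed, the log2 fold change (with a
pseudocount) must reach the LFC threshold, and at least one condition must
reach the sample-specific TPM threshold derived from the FPKM->TPM
conversion at FPKM = 1:  threshold = 10^6 / sum_j FPKM_j.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import AlignmentRecord, Interval, TranscriptModel, reference_blocks

__all__ = [
    "CountMatrix",
    "AbundanceTable",
    "DEGResult",
    "count_fragments",
    "mask_target_regions",
    "merged_exon_lengths",
    "normalize",
    "fpkm_tpm",
    "call_degs",
]


@dataclass
class CountMatrix:
    """Per-(gene, sample) fragment counts plus library sizes."""

    counts: pd.DataFrame  # index = gene ids, columns = sample labels
    library_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        for s in self.counts.columns:
            if self.library_sizes.get(s, 0) < self.counts[s].sum():
                raise ValueError(f"library size of {s} below its column sum")


@dataclass
class AbundanceTable:
    fpkm: pd.DataFrame
    tpm: pd.DataFrame
    exonic_length_kb: pd.Series
    tpm_threshold: dict[str, float]


@dataclass
class DEGResult:
    gene_id: str
    mean_count: float
    lfc: float
    passed_mean_filter: bool
    passed_tpm_filter: bool
    called_deg: bool


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _gene_exon_index(models: Sequence[TranscriptModel]) -> dict[str, list[tuple[int, int, str]]]:
    """chrom -> sorted (start, end, gene_id) over merged per-gene exons."""
    per_gene: dict[str, list[Interval]] = defaultdict(list)
    gene_chrom: dict[str, str] = {}
    for m in models:
        per_gene[m.gene_id].extend(m.exons)
        gene_chrom[m.gene_id] = m.chrom
    from .formats import interval_merge

    index: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for gid, exons in per_gene.items():
        for iv in interval_merge(exons):
            index[iv.chrom].append((iv.start, iv.end, gid))
    for chrom in index:
        index[chrom].sort()
    return index


def count_fragments(
    alignments: Iterable[AlignmentRecord],
    models: Sequence[TranscriptModel],
    sample_label: str = "sample",
    target_track: Sequence[Interval] | None = None,
) -> CountMatrix:
    """Union-mode fragment counting: a fragment (all primary records sharing
    a qname) counts once for the single gene whose exons its aligned blocks
    overlap; fragments touching exons of more than one gene are ambiguous
    and discarded; intron-only fragments are uncounted.

    ``target_track`` masks construct-targeted regions: any fragment whose
    alignment overlaps a masked interval is excluded from its gene's count,
    removing the construct-derived reads that would bias fold-change
    estimates for the targeted genes.
    """
    index = _gene_exon_index(models)
    targets = [t for t in (target_track or [])]
    frag_blocks: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    n_records = 0
    for a in alignments:
        if not a.is_primary or a.is_unmapped:
            continue
        n_records += 1
        for bs, be in reference_blocks(a.pos, a.cigar, skip_deletions=True):
            frag_blocks[a.qname].append((a.refname, bs, be))
    gene_counts: dict[str, int] = defaultdict(int)
    n_fragments = 0
    for qname, blocks in frag_blocks.items():
        n_fragments += 1
        genes = set()
        masked = False
        for chrom, bs, be in blocks:
            for ts, te, gid in index.get(chrom, []):
                if ts < be and bs < te:
                    genes.add(gid)
            for t in targets:
                if t.chrom == chrom and t.start < be and bs < t.end:
                    masked = True
        if masked or len(genes) != 1:
            continue
        gene_counts[genes.pop()] += 1
    all_genes = sorted({m.gene_id for m in models})
    counts = pd.DataFrame(
        {sample_label: [gene_counts.get(g, 0) for g in all_genes]}, index=all_genes
    )
    return CountMatrix(counts, {sample_label: n_fragments})


def mask_target_regions(
    alignments: Iterable[AlignmentRecord],
    models: Sequence[TranscriptModel],
    target_track: Sequence[Interval],
    sample_label: str = "sample",
) -> CountMatrix:
    """Recount with construct-targeted intervals masked (fragments
    overlapping a target interval are excluded from their gene's count;
    genes without target intervals are unaffected)."""
    exonic = {iv for m in models for iv in m.exons}
    for t in target_track:
        if not any(e.chrom == t.chrom and e.start <= t.start and t.end <= e.end for e in exonic):
            import warnings

            warnings.warn(f"target interval {t} not inside any exon", stacklevel=2)
    return count_fragments(alignments, models, sample_label, target_track=target_track)


def merged_exon_lengths(models: Sequence[TranscriptModel]) -> pd.Series:
    """Per-gene union-exon length in nt (the effective length for FPKM)."""
    from .formats import interval_merge

    per_gene: dict[str, list[Interval]] = defaultdict(list)
    for m in models:
        per_gene[m.gene_id].extend(m.exons)
    return pd.Series(
        {g: sum(len(iv) for iv in interval_merge(exs)) for g, exs in per_gene.items()}
    ).sort_index()


def combine_samples(matrices: Sequence[CountMatrix]) -> CountMatrix:
    counts = pd.concat([m.counts for m in matrices], axis=1).fillna(0).astype(int)
    sizes: dict[str, int] = {}
    for m in matrices:
        sizes.update(m.library_sizes)
    return CountMatrix(counts, sizes)


# ---------------------------------------------------------------------------
# normalization and abundance
# ---------------------------------------------------------------------------

def normalize(matrix: CountMatrix, method: str = "depth") -> tuple[pd.DataFrame, dict[str, float]]:
    """``depth``: scale each sample by mean library size / library size.
    ``median_of_ratios``: size factor = median over genes of
    count / geometric-mean row (requires >= 1 gene nonzero in all samples).
    Returns (normalized counts, size factors)."""
    counts = matrix.counts.astype(float)
    if method == "depth":
        sizes = pd.Series(matrix.library_sizes, dtype=float)
        factors = sizes / sizes.mean()
    elif method == "median_of_ratios":
        nonzero = counts[(counts > 0).all(axis=1)]
        if nonzero.empty:
            raise ValueError("median_of_ratios requires a gene with nonzero counts in all samples")
        log_gm = np.log(nonzero).mean(axis=1)
        ratios = np.log(nonzero).sub(log_gm, axis=0)
        factors = np.exp(ratios.median(axis=0))
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return counts.div(factors, axis=1), dict(factors)


def fpkm_tpm(matrix: CountMatrix, exonic_lengths: pd.Series) -> AbundanceTable:
    """FPKM = count x 10^9 / (library size x exonic length in nt); TPM via
    TPM_i = (FPKM_i / sum_j FPKM_j) x 10^6.  The sample-specific TPM
    expression threshold is that conversion at FPKM_i = 1:
    threshold = 10^6 / sum_j FPKM_j."""
    lens = exonic_lengths.reindex(matrix.counts.index)
    if (lens <= 0).any() or lens.isna().any():
        raise ValueError("every gene needs a positive exonic length")
    fpkm = pd.DataFrame(index=matrix.counts.index)
    tpm = pd.DataFrame(index=matrix.counts.index)
    thresholds: dict[str, float] = {}
    for s in matrix.counts.columns:
        lib = matrix.library_sizes[s]
        if lib <= 0:
            raise ValueError(f"zero library size for {s}")
        f = matrix.counts[s] * 1e9 / (lib * lens)
        total = f.sum()
        fpkm[s] = f
        tpm[s] = f / total * 1e6 if total > 0 else 0.0
        thresholds[s] = 1e6 / total if total > 0 else float("inf")
    return AbundanceTable(fpkm, tpm, lens / 1000.0, thresholds)


# ---------------------------------------------------------------------------
# DEG gates
# ---------------------------------------------------------------------------

def call_degs(
    normalized: pd.DataFrame,
    abundance: AbundanceTable,
    conditions: Mapping[str, Sequence[str]],
    mean_min: float = 10.0,
    lfc_threshold: float = 0.5,
    pseudocount: float = 1.0,
) -> list[DEGResult]:
    """Threshold-gate differential expression between two conditions.

    ``conditions`` maps the two condition names to their replicate sample
    labels; the LFC is log2((mean_B + pc) / (mean_A + pc)) with condition
    order taken from the mapping (B relative to A, i.e. positive = up in B).
    A gene is a DEG when it passes the mean-count gate (mean over all
    samples >= ``mean_min``), the TPM gate (TPM >= sample-specific threshold
    in at least one condition, any replicate), and |LFC| >= threshold.
    """
    if len(conditions) != 2:
        raise ValueError("exactly two conditions required")
    (name_a, reps_a), (name_b, reps_b) = conditions.items()
    out: list[DEGResult] = []
    for gene in normalized.index:
        row = normalized.loc[gene]
        mean_all = float(row.mean())
        mean_a = float(row[list(reps_a)].mean())
        mean_b = float(row[list(reps_b)].mean())
        lfc = float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))
        passed_mean = mean_all >= mean_min
        passed_tpm = False
        for reps in (reps_a, reps_b):
            if any(
                abundance.tpm.loc[gene, s] >= abundance.tpm_threshold[s] for s in reps
            ):
                passed_tpm = True
                break
        called = passed_mean and passed_tpm and abs(lfc) >= lfc_threshold
        out.append(DEGResult(gene, mean_all, lfc, passed_mean, passed_tpm, called))
    return out
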