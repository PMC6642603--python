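"""Pileup genotyping and the variant filter cascades.

Two filter dialects are provided as named profiles:

``genomic``
    quality >= 20, mean mapping quality >= 20, coverage between 4 and a
    sample-specific maximum, MQ0 fraction <= 0.10, and at least one
    alternative read per strand.

``transcriptomic``
    the per-variant quality/coverage/MQ rules plus positional artifact
    exclusions — SNVs within 10 nt of an indel, both members of an indel
    pair within 100 nt, all members of any 3-SNV cluster spanning <= 10 nt —
    and a minimum alternative-allele fraction of 0.9.

Consensus errors of the reference assembly are removed by subtracting every
varying position of a self-mapped call set (the reference genotype mapped
against its own assembly), position-level and allele-agnostic.

The pileup genotyper is a deliberate simplification of a likelihood-based
caller: it emits the plurality non-reference allele with depth, strand and
mapping-quality annotations, which is exactly the evidence the filter
cascades test.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .formats import AlignmentRecord, Interval, TranscriptModel, VariantRecord, interval_merge

__all__ = [
    "FilterProfile",
    "CallSet",
    "FilterResult",
    "ImpactAnnotation",
    "dedup_primary_unique",
    "pileup_genotype",
    "filter_callset",
    "subtract_selfmap",
    "set_partition",
    "titv_ratio",
    "divergence_snv_per_mbp",
    "snv_rate_per_mbp",
    "classify_impact",
]


@dataclass
class FilterProfile:
    """A named parameter set governing variant retention."""

    name: str
    min_qual: float = 20.0
    min_avg_mq: float = 20.0
    min_cov: int = 4
    max_cov: int | None = None
    max_mq0f: float = 0.10
    min_reads_per_strand: int = 0
    min_alt_fraction: float = 0.0
    snv_indel_distance: int = 0
    indel_pair_distance: int = 0
    snv_cluster_count: int = 0
    snv_cluster_span: int = 0
    # the transcriptomic dialect's printed "minimum fraction of 0.1 reads
    # with 0-mapping quality" reads like a typo for a maximum (a minimum
    # would select for ambiguity); the literal reading is available here
    literal_mq0f_minimum: bool = False

    @classmethod
    def genomic(cls, max_cov: int | None = None) -> "FilterProfile":
        return cls(name="genomic", max_cov=max_cov, min_reads_per_strand=1)

    @classmethod
    def transcriptomic(cls) -> "FilterProfile":
        return cls(
            name="transcriptomic",
            min_alt_fraction=0.9,
            snv_indel_distance=10,
            indel_pair_distance=100,
            snv_cluster_count=3,
            snv_cluster_span=10,
        )

    @classmethod
    def preset(cls, name: str, **kw) -> "FilterProfile":
        if name == "genomic":
            return cls.genomic(**kw)
        if name == "transcriptomic":
            return cls.transcriptomic(**kw)
        raise ValueError(f"unknown profile {name!r}")


def default_max_coverage(mean_depth: float) -> int:
    """Sample-specific coverage ceiling when none is supplied: 1.45x the
    genome-wide mean depth (the published ceilings, 30 at 21x and 38 at 26x,
    sit at that multiple)."""
    return int(round(1.45 * mean_depth))


@dataclass
class CallSet:
    sample_label: str
    variants: list[VariantRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.variants = sorted(self.variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos, ref, alt) in call set")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def snvs(self) -> list[VariantRecord]:
        return [v for v in self.variants if v.vtype == "SNV"]

    @property
    def indels(self) -> list[VariantRecord]:
        return [v for v in self.variants if v.vtype != "SNV"]


# ---------------------------------------------------------------------------
# alignment preprocessing
# ---------------------------------------------------------------------------

@dataclass
class DedupResult:
    alignments: list[AlignmentRecord]
    n_ambiguous: int = 0
    n_duplicates: int = 0
    n_missing_tags: int = 0


def dedup_primary_unique(
    alignments: Iterable[AlignmentRecord],
    min_score_gap: int = 1,
) -> DedupResult:
    """Keep primary, non-supplementary records that map uniquely and are not
    PCR duplicates.

    A read is ambiguous (dropped) when its best secondary alignment is within
    ``min_score_gap`` mismatches of the primary (NM tags; AS as fallback).
    Duplicates share (refname, 5'-clip-adjusted start, strand, mate refname,
    mate start); the record with the highest summed base quality (mapq as
    fallback) is kept.
    """
    by_qname: dict[tuple[str, int], list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        if a.is_unmapped or a.is_supplementary:
            continue
        mate_no = 1 if a.is_read1 or not a.is_paired else 2
        by_qname[(a.qname, mate_no)].append(a)
    kept: list[AlignmentRecord] = []
    n_ambiguous = n_missing = 0
    for recs in by_qname.values():
        primary = next((r for r in recs if not r.is_secondary), None)
        if primary is None:
            continue
        secondaries = [r for r in recs if r.is_secondary]
        if secondaries:
            def mism(r: AlignmentRecord) -> int | None:
                if "NM" in r.tags:
                    return int(r.tags["NM"])
                if "AS" in r.tags:
                    return -int(r.tags["AS"])
                return None
            pm = mism(primary)
            sms = [mism(s) for s in secondaries]
            if pm is None or any(s is None for s in sms):
                n_missing += 1
                continue
            if min(sms) - pm < min_score_gap:
                n_ambiguous += 1
                continue
        kept.append(primary)
    # duplicate marking
    def clip5_start(r: AlignmentRecord) -> int:
        if not r.is_reverse:
            lead = r.cigar[0][1] if r.cigar and r.cigar[0][0] in "SH" else 0
            return r.ref_start - lead
        tail = r.cigar[-1][1] if r.cigar and r.cigar[-1][0] in "SH" else 0
        return r.ref_end + tail

    best: dict[tuple, AlignmentRecord] = {}
    n_dup = 0
    for r in kept:
        key = (r.refname, clip5_start(r), r.is_reverse, r.mate_refname, r.mate_pos,
               1 if r.is_read1 else 2)
        cur = best.get(key)
        if cur is None:
            best[key] = r
        else:
            n_dup += 1
            q_new = sum(r.quals) if r.quals else r.mapq
            q_old = sum(cur.quals) if cur.quals else cur.mapq
            if q_new > q_old:
                best[key] = r
    return DedupResult(list(best.values()), n_ambiguous, n_dup, n_missing)


# ---------------------------------------------------------------------------
# pileup genotyping
# ---------------------------------------------------------------------------

class _Site:
    __slots__ = ("depth", "mq_sum", "mq0", "bases", "indels")

    def __init__(self) -> None:
        self.depth = 0
        self.mq_sum = 0
        self.mq0 = 0
        self.bases: dict[tuple[str, bool], list[int]] = defaultdict(list)  # (base, rev) -> BQs
        self.indels: dict[tuple[str, str], list[bool]] = defaultdict(list)  # (ref,alt)->strands


def pileup_genotype(
    alignments: Iterable[AlignmentRecord],
    reference: Mapping[str, str],
    min_bq: int = 20,
    sample_label: str = "sample",
) -> CallSet:
    """Per-position genotyping: bases below ``min_bq`` are excluded from
    allele counts (not from depth); an SNV is emitted when a non-reference
    base is the plurality alternative; insertions and deletions come from
    I/D CIGAR ops in the anchored-base convention (position = anchor,
    REF and ALT share the anchor base)."""
    sites: dict[tuple[str, int], _Site] = defaultdict(_Site)
    for a in alignments:
        if a.is_unmapped or not a.is_primary or a.is_duplicate:
            continue
        if a.refname not in reference:
            raise ValueError(f"alignment chromosome {a.refname!r} absent from reference")
        ref = reference[a.refname]
        rpos = a.ref_start
        qpos = 0
        default_q = 35
        for op, n in a.cigar:
            if op in "M=X":
                for i in range(n):
                    site = sites[(a.refname, rpos + i)]
                    site.depth += 1
                    site.mq_sum += a.mapq
                    if a.mapq == 0:
                        site.mq0 += 1
                    bq = a.quals[qpos + i] if a.quals else default_q
                    if bq >= min_bq and a.seq != "*":
                        site.bases[(a.seq[qpos + i], a.is_reverse)].append(bq)
                rpos += n
                qpos += n
            elif op == "I":
                if rpos > 0 and a.seq != "*":
                    anchor = ref[rpos - 1]
                    ins = a.seq[qpos : qpos + n]
                    sites[(a.refname, rpos - 1)].indels[(anchor, anchor + ins)].append(a.is_reverse)
                qpos += n
            elif op == "D":
                if rpos > 0:
                    anchor = ref[rpos - 1]
                    deleted = ref[rpos - 1 : rpos + n]
                    sites[(a.refname, rpos - 1)].indels[(deleted, anchor)].append(a.is_reverse)
                rpos += n
            elif op == "N":
                rpos += n
            elif op in "SH":
                if op == "S":
                    qpos += n
            # P consumes nothing
    variants: list[VariantRecord] = []
    for (chrom, pos0), site in sites.items():
        if site.depth == 0:
            continue
        refbase = reference[chrom][pos0]
        mq_mean = site.mq_sum / site.depth
        mq0f = site.mq0 / site.depth
        counted = sum(len(v) for v in site.bases.values())
        # SNV: plurality non-reference base
        alt_tallies: dict[str, int] = defaultdict(int)
        for (base, _rev), bqs in site.bases.items():
            if base != refbase:
                alt_tallies[base] += len(bqs)
        if alt_tallies:
            alt = max(alt_tallies, key=lambda b: (alt_tallies[b], b))
            alt_n = alt_tallies[alt]
            ref_n = sum(len(bqs) for (b, _r), bqs in site.bases.items() if b == refbase)
            if alt_n >= 2 and alt_n >= ref_n_plurality_floor(counted):
                alt_bqs = [q for (b, _r), bqs in site.bases.items() if b == alt for q in bqs]
                variants.append(
                    VariantRecord(
                        chrom=chrom,
                        pos=pos0 + 1,
                        ref=refbase,
                        alt=alt,
                        qual=float(np.mean(alt_bqs)) if alt_bqs else 0.0,
                        depth=site.depth,
                        ref_count=ref_n,
                        alt_count=alt_n,
                        alt_fwd=len(site.bases.get((alt, False), [])),
                        alt_rev=len(site.bases.get((alt, True), [])),
                        mq_mean=mq_mean,
                        mq0_fraction=mq0f,
                    )
                )
        for (ref_al, alt_al), strands in site.indels.items():
            n_alt = len(strands)
            if n_alt < 2:
                continue
            variants.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref=ref_al,
                    alt=alt_al,
                    qual=float(default_indel_qual(n_alt)),
                    depth=site.depth,
                    ref_count=max(site.depth - n_alt, 0),
                    alt_count=n_alt,
                    alt_fwd=sum(1 for s in strands if not s),
                    alt_rev=sum(1 for s in strands if s),
                    mq_mean=mq_mean,
                    mq0_fraction=mq0f,
                )
            )
    # deduplicate identical keys (can arise from overlapping mates)
    uniq: dict[tuple, VariantRecord] = {}
    for v in variants:
        uniq.setdefault(v.key, v)
    return CallSet(sample_label, list(uniq.values()), provenance="pileup_genotype")


def ref_n_plurality_floor(counted: int) -> int:
    """Minimum alternative count to call at a site: at least 20% of counted
    bases, floor 2 — suppresses isolated sequencing errors at high depth."""
    return max(2, int(math.ceil(0.2 * counted)))


def default_indel_qual(support: int) -> float:
    return min(60.0, 10.0 + 5.0 * support)


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    callset: CallSet
    rejected: list[tuple[VariantRecord, str]] = field(default_factory=list)


def _positional_exclusions(variants: Sequence[VariantRecord], profile: FilterProfile) -> dict[tuple, str]:
    """Artifact-neighborhood rules, evaluated on the raw candidate set before
    per-variant filters so that artifact clusters suppress their neighbors
    even when some members independently fail other rules."""
    excluded: dict[tuple, str] = {}
    by_chrom: dict[str, list[VariantRecord]] = defaultdict(list)
    for v in variants:
        by_chrom[v.chrom].append(v)
    for chrom, vs in by_chrom.items():
        vs.sort(key=lambda v: v.pos)
        snvs = [v for v in vs if v.vtype == "SNV"]
        indels = [v for v in vs if v.vtype != "SNV"]
        if profile.snv_indel_distance:
            ipos = [i.pos for i in indels]
            for s in snvs:
                if any(abs(s.pos - p) <= profile.snv_indel_distance for p in ipos):
                    excluded.setdefault(s.key, "snv_near_indel")
        if profile.indel_pair_distance:
            for a, b in zip(indels, indels[1:]):
                if b.pos - a.pos <= profile.indel_pair_distance:
                    excluded.setdefault(a.key, "indel_pair")
                    excluded.setdefault(b.key, "indel_pair")
        if profile.snv_cluster_count >= 2:
            k = profile.snv_cluster_count
            for i in range(len(snvs) - k + 1):
                if snvs[i + k - 1].pos - snvs[i].pos + 1 <= profile.snv_cluster_span:
                    for v in snvs[i : i + k]:
                        excluded.setdefault(v.key, "snv_cluster")
    return excluded


def filter_callset(callset: CallSet, profile: FilterProfile) -> FilterResult:
    """Apply a filter profile; rejected variants are annotated with the
    first rule that removed them (audit trail)."""
    positional = _positional_exclusions(callset.variants, profile)
    kept: list[VariantRecord] = []
    rejected: list[tuple[VariantRecord, str]] = []
    for v in callset.variants:
        rule = positional.get(v.key)
        if rule is None:
            rule = _pervariant_rule(v, profile)
        if rule is None:
            kept.append(v)
        else:
            rejected.append((v, rule))
    return FilterResult(
        CallSet(callset.sample_label, kept, provenance=f"{callset.provenance}|{profile.name}"),
        rejected,
    )


def _pervariant_rule(v: VariantRecord, p: FilterProfile) -> str | None:
    if v.qual < p.min_qual:
        return "min_qual"
    if v.mq_mean < p.min_avg_mq:
        return "min_avg_mq"
    if v.depth < p.min_cov:
        return "min_cov"
    if p.max_cov is not None and v.depth > p.max_cov:
        return "max_cov"
    if p.literal_mq0f_minimum:
        if v.mq0_fraction < p.max_mq0f:
            return "mq0f_literal_minimum"
    elif v.mq0_fraction > p.max_mq0f:
        return "max_mq0f"
    if p.min_reads_per_strand:
        if v.alt_fwd < p.min_reads_per_strand or v.alt_rev < p.min_reads_per_strand:
            return "reads_per_strand"
    if p.min_alt_fraction and v.alt_fraction < p.min_alt_fraction:
        return "alt_fraction"
    return None


def subtract_selfmap(callset: CallSet, selfmap: CallSet) -> CallSet:
    """Remove every variant at a position where the reference genotype varies
    against its own assembly (consensus errors); position-level and
    allele-agnostic."""
    bad = {(v.chrom, v.pos) for v in selfmap.variants}
    kept = [v for v in callset.variants if (v.chrom, v.pos) not in bad]
    return CallSet(callset.sample_label, kept, provenance=f"{callset.provenance}|selfmap_subtracted")


def set_partition(a: CallSet, b: CallSet) -> tuple[list[VariantRecord], list[VariantRecord], list[VariantRecord]]:
    """(shared, unique_a, unique_b) matched on (chrom, pos, ref, alt)."""
    keys_b = {v.key for v in b.variants}
    keys_a = {v.key for v in a.variants}
    shared = [v for v in a.variants if v.key in keys_b]
    unique_a = [v for v in a.variants if v.key not in keys_b]
    unique_b = [v for v in b.variants if v.key not in keys_a]
    return shared, unique_a, unique_b


def titv_ratio(variants: Iterable[VariantRecord] | CallSet) -> float | None:
    """Transitions (A<->G, C<->T) over transversions; None when no
    transversions are present (undefined)."""
    vs = variants.snvs if isinstance(variants, CallSet) else [v for v in variants if v.vtype == "SNV"]
    ti = sum(1 for v in vs if v.is_transition)
    tv = len(vs) - ti
    if tv == 0:
        return None
    return ti / tv


# ---------------------------------------------------------------------------
# CDS-restricted divergence
# ---------------------------------------------------------------------------

def snv_rate_per_mbp(snv_count: int, covered_positions: int) -> int:
    """Display value: SNVs per megabase of covered sequence, rounded
    half-to-even to integer precision."""
    if covered_positions <= 0:
        raise ValueError("no covered positions")
    return round(snv_count / (covered_positions / 1e6))


@dataclass
class DivergenceResult:
    covered_positions: int
    snv_count: int
    snv_per_mbp: int
    snv_per_mbp_exact: float


def divergence_snv_per_mbp(
    callset: CallSet,
    depth_track: Mapping[str, np.ndarray],
    cds_track: Sequence[Interval],
    min_cov: int = 4,
) -> DivergenceResult:
    """Accession divergence as SNVs per Mbp of CDS positions with depth >=
    ``min_cov``; only SNVs at such positions count."""
    merged = interval_merge(cds_track)
    covered = 0
    covered_mask: dict[str, list[Interval]] = defaultdict(list)
    ok: dict[str, np.ndarray] = {}
    for chrom, depth in depth_track.items():
        ok[chrom] = np.asarray(depth) >= min_cov
    for iv in merged:
        if iv.chrom not in ok:
            continue
        covered += int(ok[iv.chrom][iv.start : iv.end].sum())
        covered_mask[iv.chrom].append(iv)
    if covered == 0:
        raise ValueError("zero covered CDS positions")
    n_snv = 0
    for v in callset.snvs:
        mask = ok.get(v.chrom)
        if mask is None or v.pos - 1 >= len(mask) or not mask[v.pos - 1]:
            continue
        if any(iv.contains_point(v.pos - 1) for iv in covered_mask[v.chrom]):
            n_snv += 1
    exact = n_snv / (covered / 1e6)
    return DivergenceResult(covered, n_snv, snv_rate_per_mbp(n_snv, covered), exact)


# ---------------------------------------------------------------------------
# coding-impact classification
# ---------------------------------------------------------------------------

_HIGH = {"frameshift", "stop_gained", "splice_site", "start_lost", "stop_lost"}
_MODERATE = {"missense", "inframe_indel"}


@dataclass
class ImpactAnnotation:
    variant: VariantRecord
    gene_id: str | None
    consequence: str
    impact: str
    low_confidence: bool = False


def _impact_of(consequence: str) -> str:
    if consequence in _HIGH:
        return "HIGH"
    if consequence in _MODERATE:
        return "MODERATE"
    if consequence == "synonymous":
        return "LOW"
    return "MODIFIER"


def classify_impact(
    variant: VariantRecord,
    models: Sequence[TranscriptModel],
    genome: Mapping[str, str],
) -> ImpactAnnotation:
    """Codon-level consequence for CDS SNVs (standard genetic code,
    strand-aware); indels are frameshift when the length change is not a
    multiple of 3, else in-frame; the 2 intronic bases flanking an exon are
    splice sites; everything else is non-coding."""
    pos0 = variant.pos - 1
    for m in models:
        if m.chrom != variant.chrom or not m.cds:
            continue
        # splice-site check: 2 intronic bases at each exon boundary
        for intr in m.introns():
            if intr.start <= pos0 < intr.start + 2 or intr.end - 2 <= pos0 < intr.end:
                return ImpactAnnotation(variant, m.gene_id, "splice_site", "HIGH")
        in_cds = any(c.start <= pos0 < c.end for c in m.cds)
        if not in_cds:
            continue
        low_conf = m.cds_length % 3 != 0
        if variant.vtype != "SNV":
            delta = abs(len(variant.alt) - len(variant.ref))
            cons = "frameshift" if delta % 3 else "inframe_indel"
            return ImpactAnnotation(variant, m.gene_id, cons, _impact_of(cons), low_conf)
        cds_seq = m.cds_sequence(genome)
        # CDS offset of the variant in translation order
        if m.strand != "-":
            off = 0
            for c in m.cds:
                if c.start <= pos0 < c.end:
                    off += pos0 - c.start
                    break
                off += len(c)
            alt_base = variant.alt
        else:
            off = 0
            for c in reversed(m.cds):
                if c.start <= pos0 < c.end:
                    off += c.end - 1 - pos0
                    break
                off += len(c)
            alt_base = str(Seq(variant.alt).complement())
        codon_i = off // 3
        within = off % 3
        codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
        if len(codon) < 3:
            return ImpactAnnotation(variant, m.gene_id, "non_coding", "MODIFIER", True)
        new_codon = codon[:within] + alt_base + codon[within + 1 :]
        aa_old = str(Seq(codon).translate())
        aa_new = str(Seq(new_codon).translate())
        if codon_i == 0 and m.has_start_codon and aa_new != aa_old:
            cons = "start_lost"
        elif aa_old == aa_new:
            cons = "synonymous"
        elif aa_new == "*":
            cons = "stop_gained"
        elif aa_old == "*":
            cons = "stop_lost"
        else:
            cons = "missense"
        return ImpactAnnotation(variant, m.gene_id, cons, _impact_of(cons), low_conf)
    return ImpactAnnotation(variant, None, "non_coding", "MODIFIER")
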