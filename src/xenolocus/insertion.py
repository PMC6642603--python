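"""Transgene integration-site detection from paired-end genomic alignments
against a combined host + construct reference.

Evidence classes
----------------
*Bridging pairs*: one mate on a host scaffold, the other on a construct,
labelled P/C/T by which annotated construct segment (promoter / cassette /
terminator) the construct-mapped mate overlaps most.

*Chimeric (split) reads*: a primary alignment with a soft-clipped remainder
whose other side maps to a construct, localizing a junction at base-pair
precision.  The junction convention is: junction = last retained host base
(1-based), so a clean insertion with no flanking deletion yields
``pos_T = pos_P + 1`` and the deleted-base count between two junctions is
``|pos_T - pos_P| - 1``.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .formats import (
    AlignmentRecord,
    Interval,
    cigar_ref_span,
    reference_blocks,
)
from .simulate import TransgeneSpec

__all__ = [
    "BridgePair",
    "JunctionCall",
    "CandidateInsertion",
    "estimate_insert_bounds",
    "classify_bridging_pairs",
    "cluster_candidates",
    "call_junctions",
    "infer_lesion",
    "call_insertion_zygosity",
    "profile_coverage",
]


@dataclass
class BridgePair:
    qname: str
    host_anchor: Interval
    construct_name: str
    segment: str  # P / C / T


@dataclass
class JunctionCall:
    scaffold: str
    position: int  # 1-based last host base adjacent to the construct
    side: str  # P or T
    support: int
    construct_name: str = ""
    tied: bool = False


@dataclass
class CandidateInsertion:
    scaffold: str
    p_pairs: int = 0
    t_pairs: int = 0
    c_pairs: int = 0
    anchor_span: Interval | None = None
    junction_p: JunctionCall | None = None
    junction_t: JunctionCall | None = None
    lesion: int | str = "complex"  # int = deletion length (0 = none)
    assigned_construct: str | None = None
    assignment_mode: str | None = None  # direct | inferred_by_elimination
    zygosity: str = "undetermined"  # hom | het | undetermined
    wildtype_span_reads: int = 0

    @property
    def total_pairs(self) -> int:
        return self.p_pairs + self.t_pairs + self.c_pairs


# ---------------------------------------------------------------------------

def estimate_insert_bounds(
    alignments: Iterable[AlignmentRecord],
    lower_q: float = 0.001,
    upper_q: float = 0.999,
) -> tuple[int, int]:
    """Quantile bounds of observed template lengths of proper pairs,
    mirroring insert-size estimation from a mapped read subset."""
    tlens = [abs(a.tlen) for a in alignments if a.is_proper and a.tlen > 0 and a.is_primary]
    if not tlens:
        raise ValueError("no proper pairs in sample")
    lo, hi = np.quantile(tlens, [lower_q, upper_q])
    return int(lo), int(hi)


def _primary_pairs(alignments: Iterable[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    pairs: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        if a.is_primary and not a.is_unmapped:
            pairs[a.qname].append(a)
    return pairs


def classify_bridging_pairs(
    alignments: Iterable[AlignmentRecord],
    constructs: Sequence[TransgeneSpec],
) -> list[BridgePair]:
    """Read pairs with one primary mate on a host scaffold and the other on a
    construct; the construct mate is labelled P/C/T by maximal overlap with
    the annotated construct segments."""
    by_name = {c.name: c for c in constructs}
    out: list[BridgePair] = []
    for qname, mates in _primary_pairs(alignments).items():
        if len(mates) != 2:
            continue
        a, b = mates
        a_con, b_con = a.refname in by_name, b.refname in by_name
        if a_con == b_con:
            continue  # both host or both construct
        host, cmate = (b, a) if a_con else (a, b)
        spec = by_name[cmate.refname]
        seg = spec.segment_of(Interval(cmate.refname, cmate.ref_start, max(cmate.ref_end, cmate.ref_start + 1)))
        out.append(
            BridgePair(
                qname=qname,
                host_anchor=Interval(host.refname, host.ref_start, max(host.ref_end, host.ref_start + 1)),
                construct_name=spec.name,
                segment=seg,
            )
        )
    return out


def cluster_candidates(
    bridge_pairs: Sequence[BridgePair],
    min_support: int = 10,
    window: int = 1550,
) -> list[CandidateInsertion]:
    """Group bridging pairs per scaffold within ``window`` of each other's
    host anchors and drop clusters with fewer than ``min_support`` total
    pairs (the published exclusion threshold).

    ``window`` defaults to twice a generous maximum insert size; pass
    ``2 * max_insert`` from :func:`estimate_insert_bounds` when available.
    """
    by_scaffold: dict[str, list[BridgePair]] = defaultdict(list)
    for bp in bridge_pairs:
        by_scaffold[bp.host_anchor.chrom].append(bp)
    out: list[CandidateInsertion] = []
    for scaffold in sorted(by_scaffold):
        pairs = sorted(by_scaffold[scaffold], key=lambda p: p.host_anchor.start)
        cluster: list[BridgePair] = []
        clusters: list[list[BridgePair]] = []
        for bp in pairs:
            if cluster and bp.host_anchor.start - cluster[-1].host_anchor.start > window:
                clusters.append(cluster)
                cluster = []
            cluster.append(bp)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            if len(cl) < min_support:
                continue
            seg_counts = Counter(bp.segment for bp in cl)
            out.append(
                CandidateInsertion(
                    scaffold=scaffold,
                    p_pairs=seg_counts.get("P", 0),
                    t_pairs=seg_counts.get("T", 0),
                    c_pairs=seg_counts.get("C", 0),
                    anchor_span=Interval(
                        scaffold,
                        min(bp.host_anchor.start for bp in cl),
                        max(bp.host_anchor.end for bp in cl),
                    ),
                )
            )
    return out


def _clip_side(rec: AlignmentRecord) -> str | None:
    """'5p' if the record is clipped at its reference-left end, '3p' if at
    its reference-right end; the larger clip wins, None if unclipped."""
    cigar = rec.cigar
    left = cigar[0][1] if cigar and cigar[0][0] in "SH" else 0
    right = cigar[-1][1] if cigar and cigar[-1][0] in "SH" else 0
    if left == right == 0:
        return None
    return "5p" if left >= right else "3p"


def call_junctions(
    chimeric_alignments: Iterable[AlignmentRecord],
    candidate: CandidateInsertion,
    constructs: Sequence[TransgeneSpec],
    flank: int = 2000,
) -> CandidateInsertion:
    """Call the two junctions of a candidate from junction-spanning reads.

    Input records should be primary alignments that have supplementary
    alignments (split reads); the host-side segment's clipped end gives the
    junction: clipped at the 3' (reference-right) end -> junction =
    pos + reference span - 1; clipped at the 5' end -> junction = pos.  The
    side label (P/T) comes from where the clipped remainder maps on the
    construct.  Per side the modal position across reads is reported; ties
    break toward the higher summed construct-side support, then the smaller
    coordinate (flagged).  A side without chimeric support stays absent and
    the lesion is reported ``complex``.
    """
    by_name = {c.name: c for c in constructs}
    recs = list(chimeric_alignments)
    # construct-side pieces per read, used to label the side of host clips
    con_side: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for r in recs:
        if r.refname in by_name and not r.is_secondary:
            con_side[r.qname].append(r)
    votes: dict[str, Counter] = {"P": Counter(), "T": Counter()}
    span = candidate.anchor_span
    for r in recs:
        if r.refname != candidate.scaffold or r.is_secondary or r.is_unmapped:
            continue
        if span is not None and not (
            span.start - flank <= r.ref_start <= span.end + flank
        ):
            continue
        side = _clip_side(r)
        if side is None:
            continue
        partners = con_side.get(r.qname)
        if not partners:
            continue
        seg_votes = Counter()
        for p in partners:
            spec = by_name[p.refname]
            seg = spec.segment_of(
                Interval(p.refname, p.ref_start, max(p.ref_end, p.ref_start + 1))
            )
            seg_votes[seg] += 1
        seg = seg_votes.most_common(1)[0][0]
        if seg == "C":
            continue  # cassette-internal split, not a host junction
        junction = r.pos + cigar_ref_span(r.cigar) - 1 if side == "3p" else r.pos
        votes[seg][junction] += 1
    cand = candidate
    for seg, attr in (("P", "junction_p"), ("T", "junction_t")):
        if not votes[seg]:
            continue
        best = max(votes[seg].items(), key=lambda kv: (kv[1], -kv[0]))
        tied = sum(1 for v in votes[seg].values() if v == best[1]) > 1
        setattr(
            cand,
            attr,
            JunctionCall(
                scaffold=cand.scaffold,
                position=best[0],
                side=seg,
                support=best[1],
                tied=tied,
            ),
        )
    if cand.junction_p and cand.junction_t:
        cand.lesion = infer_lesion(cand.junction_p, cand.junction_t)
    else:
        cand.lesion = "complex"
    return cand


def infer_lesion(junction_p: JunctionCall | int, junction_t: JunctionCall | int) -> int | str:
    """Deleted-base count between the two junctions of one integration.

    With the last-retained-host-base convention the host loses
    ``|pos_T - pos_P| - 1`` bases; 0 means a clean insertion; a negative
    difference (overlapping junctions) is flagged ``complex``.
    """
    p = junction_p.position if isinstance(junction_p, JunctionCall) else junction_p
    t = junction_t.position if isinstance(junction_t, JunctionCall) else junction_t
    if isinstance(junction_p, JunctionCall) and isinstance(junction_t, JunctionCall):
        if junction_p.scaffold != junction_t.scaffold:
            raise ValueError("junctions on different scaffolds")
    deleted = abs(t - p) - 1
    return deleted if deleted >= 0 else "complex"


def call_insertion_zygosity(
    alignments: Iterable[AlignmentRecord],
    candidate: CandidateInsertion,
    min_span: int = 10,
    min_depth: int = 10,
) -> CandidateInsertion:
    """Genomic zygosity of the insertion: reads mapping continuously across
    the junction (unclipped, covering ``min_span`` host bases on both sides)
    can only come from an unmodified haplotype.  Zero such reads at adequate
    local depth -> hom; both insertion and wild-type evidence -> het."""
    if candidate.junction_p is None and candidate.junction_t is None:
        candidate.zygosity = "undetermined"
        return candidate
    jpos = (candidate.junction_p or candidate.junction_t).position  # 1-based
    span_reads = 0
    local_depth = 0
    # depth is assessed over a window around the junction so that flank-only
    # coverage still demonstrates the locus was sequenced
    win_lo, win_hi = jpos - 1 - 50, jpos - 1 + 50
    for a in alignments:
        if a.refname != candidate.scaffold or a.is_secondary or a.is_unmapped:
            continue
        if a.ref_start < win_hi and a.ref_end > win_lo:
            local_depth += 1
            clipped = any(op in "SH" for op, _ in a.cigar)
            if (
                not clipped
                and not a.is_supplementary
                and a.ref_start <= jpos - min_span
                and a.ref_end >= jpos + min_span
            ):
                span_reads += 1
    candidate.wildtype_span_reads = span_reads
    if span_reads == 0:
        candidate.zygosity = "hom" if local_depth >= min_depth else "undetermined"
    else:
        candidate.zygosity = "het"
    return candidate


def profile_coverage(
    alignments: Iterable[AlignmentRecord],
    region: Interval,
    ref_length: int | None = None,
) -> np.ndarray:
    """Per-position depth over ``region`` counting primary, non-duplicate
    records via reference-consuming CIGAR ops (deleted positions count as
    covered; intron skips do not)."""
    if ref_length is not None and region.end > ref_length:
        raise ValueError("region outside reference")
    depth = np.zeros(len(region), dtype=np.int32)
    for a in alignments:
        if a.refname != region.chrom or not a.is_primary or a.is_duplicate or a.is_unmapped:
            continue
        for bs, be in reference_blocks(a.pos, a.cigar):
            lo = max(bs, region.start) - region.start
            hi = min(be, region.end) - region.start
            if lo < hi:
                depth[lo:hi] += 1
    return depth
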