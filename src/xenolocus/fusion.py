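"""Construct-host fusion-transcript detection, per-exon coverage profiling,
disruption-zygosity inference and construct-to-site assignment.

A fusion transcript arises when a strong construct promoter drives
transcription into a disrupted host gene: its RNA is the construct cassette
attached to the normally spliced downstream exons.  Evidence is read pairs
(pre-cropped to a common short length so junction-spanning mates still map
end-to-end) with one mate on a cassette and the other on a host transcript
("insert mate" / "host mate").
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import AlignmentRecord, Interval, TranscriptModel, reference_blocks
from .insertion import CandidateInsertion, profile_coverage

__all__ = [
    "FusionEvidence",
    "ExonCoverageProfile",
    "ZygosityCall",
    "find_fusion_pairs",
    "per_exon_coverage",
    "call_disruption_zygosity",
    "assign_constructs",
]


@dataclass
class FusionEvidence:
    gene_id: str
    transcript_id: str
    construct_name: str
    supporting_pairs: int
    exon_hits: dict[int, int] = field(default_factory=dict)  # 1-based exon rank -> pairs

    def __post_init__(self) -> None:
        if self.exon_hits and sum(self.exon_hits.values()) != self.supporting_pairs:
            raise ValueError("supporting_pairs must equal the sum of exon_hits")


@dataclass
class ExonCoverageProfile:
    transcript_id: str
    per_exon_mean_depth: list[float]
    sample_label: str = ""


@dataclass
class ZygosityCall:
    gene_id: str
    state: str  # hom_disrupted | het_disrupted | intact | undetermined
    wildtype_junction_pairs: int
    fusion_pairs: int
    flank_depth_ok: bool = True


# ---------------------------------------------------------------------------

def find_fusion_pairs(
    alignments: Iterable[AlignmentRecord],
    models: Sequence[TranscriptModel],
    cassette_names: Sequence[str],
) -> list[FusionEvidence]:
    """Read pairs (vs transcriptome + cassette references) with one primary
    mate on a cassette and the other on a host transcript.  The host mate's
    exon (biological rank, from its transcript-space position) is recorded.
    """
    by_tid = {m.transcript_id: m for m in models}
    cset = set(cassette_names)
    clash = cset & set(by_tid)
    if clash:
        raise ValueError(f"cassette names collide with transcript ids: {sorted(clash)}")
    mates: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        if a.is_primary and not a.is_unmapped:
            mates[a.qname].append(a)
    hits: dict[tuple[str, str, str], dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for qname, recs in mates.items():
        if len(recs) != 2:
            continue
        a, b = recs
        a_cas, b_cas = a.refname in cset, b.refname in cset
        if a_cas == b_cas:
            continue
        cas, host = (a, b) if a_cas else (b, a)
        model = by_tid.get(host.refname)
        if model is None:
            continue
        # exon rank of the host mate's midpoint in transcript coordinates
        mid = host.ref_start + max(1, host.ref_end - host.ref_start) // 2
        mid = min(mid, model.exonic_length - 1)
        rank = model.transcript_to_exon_rank(mid)
        hits[(model.gene_id, model.transcript_id, cas.refname)][rank] += 1
    out = []
    for (gid, tid, cas_name), exon_hits in sorted(hits.items()):
        out.append(
            FusionEvidence(
                gene_id=gid,
                transcript_id=tid,
                construct_name=cas_name,
                supporting_pairs=sum(exon_hits.values()),
                exon_hits=dict(sorted(exon_hits.items())),
            )
        )
    return out


def per_exon_coverage(
    alignments: Iterable[AlignmentRecord],
    transcript: TranscriptModel,
    sample_label: str = "",
) -> ExonCoverageProfile:
    """Mean depth per exon (biological order) from spliced genome-space
    alignments, restricted to the exon intervals."""
    if not transcript.exons:
        raise ValueError(f"{transcript.transcript_id} has no exons")
    span = transcript.span
    depth = profile_coverage(alignments, span)
    means = []
    for e in transcript.exons_by_rank():
        means.append(float(np.mean(depth[e.start - span.start : e.end - span.start])))
    return ExonCoverageProfile(transcript.transcript_id, means, sample_label)


def call_disruption_zygosity(
    alignments: Iterable[AlignmentRecord],
    transcript: TranscriptModel,
    insertion_intron_index: int,
    fusion_pairs: int,
    min_fusion_support: int = 3,
    min_flank_depth: int = 10,
    count_spliced_singles: bool = True,
) -> ZygosityCall:
    """Zygosity of a gene disruption from transcriptome-space alignments.

    Wild-type support is evidence connecting exon k and exon k+1 across the
    insertion intron: mate pairs with one mate in exons <= k and the other in
    exons >= k+1, and (unless ``count_spliced_singles`` is off, for strict
    pairs-only replication) single reads whose transcript-space alignment
    crosses the exon k / k+1 boundary.

    ``hom_disrupted`` requires zero wild-type support AND adequate depth on
    the junction-flanking exons, so homozygosity is never called from missing
    data; ``het_disrupted`` needs both evidence classes.
    """
    k = insertion_intron_index
    if not 1 <= k <= transcript.n_exons - 1:
        raise ValueError(f"intron index {k} out of range")
    ranks = transcript.exons_by_rank()
    boundary = sum(len(e) for e in ranks[:k])  # transcript offset of exon k+1 start
    mates: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        if a.refname == transcript.transcript_id and a.is_primary and not a.is_unmapped:
            mates[a.qname].append(a)
    wildtype = 0
    flank_depth = 0
    for qname, recs in mates.items():
        crosses = False
        sides = set()
        for r in recs:
            s, e = r.ref_start, r.ref_end
            if s < boundary <= e - 1:
                if count_spliced_singles:
                    crosses = True
                flank_depth += 1
            elif e <= boundary:
                if e > boundary - 200:
                    flank_depth += 1
                sides.add("up")
            else:
                if s < boundary + 200:
                    flank_depth += 1
                sides.add("down")
        if crosses or {"up", "down"} <= sides:
            wildtype += 1
    flank_ok = flank_depth >= min_flank_depth
    if wildtype == 0 and fusion_pairs >= min_fusion_support:
        state = "hom_disrupted" if flank_ok else "undetermined"
    elif wildtype > 0 and fusion_pairs >= min_fusion_support:
        state = "het_disrupted"
    elif wildtype > 0:
        state = "intact"
    else:
        state = "undetermined"
    return ZygosityCall(
        gene_id=transcript.gene_id,
        state=state,
        wildtype_junction_pairs=wildtype,
        fusion_pairs=fusion_pairs,
        flank_depth_ok=flank_ok,
    )


def assign_constructs(
    candidates: Sequence[CandidateInsertion],
    fusion_evidence: Sequence[FusionEvidence],
    gene_scaffolds: Mapping[str, str],
    construct_names: Sequence[str],
) -> list[CandidateInsertion]:
    """Assign constructs to insertion sites.  A candidate whose scaffold
    hosts a gene with fusion evidence for construct X is assigned X
    (direct); with exactly one construct and one candidate left, the
    remainder is assigned by elimination and flagged.  Contradictory fusion
    evidence (two constructs fused to genes on one scaffold) leaves the
    candidate unassigned with a conflict flag."""
    by_scaffold: dict[str, set[str]] = defaultdict(set)
    for ev in fusion_evidence:
        scaffold = gene_scaffolds.get(ev.gene_id)
        if scaffold is not None:
            by_scaffold[scaffold].add(ev.construct_name)
    for cand in candidates:
        cons = by_scaffold.get(cand.scaffold, set())
        if len(cons) == 1:
            cand.assigned_construct = next(iter(cons))
            cand.assignment_mode = "direct"
        elif len(cons) > 1:
            cand.assigned_construct = None
            cand.assignment_mode = "conflict"
    unassigned = [c for c in candidates if c.assigned_construct is None and c.assignment_mode != "conflict"]
    used = {c.assigned_construct for c in candidates if c.assigned_construct}
    remaining = [n for n in construct_names if n not in used]
    if len(unassigned) == 1 and len(remaining) == 1:
        unassigned[0].assigned_construct = remaining[0]
        unassigned[0].assignment_mode = "inferred_by_elimination"
    return list(candidates)
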