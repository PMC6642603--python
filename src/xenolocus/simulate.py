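"""Synthetic data with the statistical structure the downstream stages assume.

The generator emulates a T-DNA characterization experiment: a multi-scaffold
host genome carrying multi-exon genes, an RNAi construct (left border +
promoter + cassette + terminator + right border) inserted at a chosen host
position with an optional flanking deletion and hom/het zygosity, paired-end
genomic reads against the combined host+construct reference (including
bridging pairs and junction-spanning chimeric reads), spliced RNA-seq reads
including construct-host fusion transcripts, and SNVs/indels planted at a
chosen density and Ti/Tv ratio.

Truth alignments are emitted directly from the simulation coordinates, so
every downstream assertion can be exact; an externally produced SAM can be
substituted anywhere an alignment list is accepted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .formats import (
    AlignmentRecord,
    FastqRead,
    Interval,
    SequenceRecord,
    TranscriptModel,
    VariantRecord,
    FPAIRED,
    FPROPER,
    FREVERSE,
    FMREVERSE,
    FREAD1,
    FREAD2,
    FSUPPLEMENTARY,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGTN", "TGCAN")
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# specs and truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TransgeneSpec:
    """An RNAi construct: LB + promoter + cassette + terminator + RB.

    Intervals are on the construct's own coordinate system (chrom = name).
    """

    name: str
    seq: str
    promoter: Interval
    cassette: Interval
    terminator: Interval

    def __post_init__(self) -> None:
        parts = [self.promoter, self.cassette, self.terminator]
        for iv in parts:
            if iv.end > len(self.seq):
                raise ValueError(f"{self.name}: {iv} outside construct")
        if not (self.promoter.end <= self.cassette.start and self.cassette.end <= self.terminator.start):
            raise ValueError(f"{self.name}: promoter/cassette/terminator must be ordered and disjoint")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def cassette_seq(self) -> str:
        return self.seq[self.cassette.start : self.cassette.end]

    def segment_of(self, iv: Interval) -> str:
        """P/C/T label by maximal overlap of an interval on the construct.

        The LB flank counts toward the promoter side and the RB flank toward
        the terminator side, so evidence near either construct end is always
        attributable to a side."""
        segments = (
            ("P", 0, self.cassette.start),
            ("C", self.cassette.start, self.cassette.end),
            ("T", self.cassette.end, len(self.seq)),
        )
        best, best_ov = "P", -1
        for label, s, e in segments:
            ov = max(0, min(iv.end, e) - max(iv.start, s))
            if ov > best_ov:
                best, best_ov = label, ov
        return best


# component lengths reproducing the exact deposited insert lengths
# (XylT 4,536 nt and FucT 4,768 nt, borders included) together with the
# exact cassette lengths (XylT 840 nt, FucT 1,072 nt)
_LB, _PROMOTER, _TERMINATOR, _RB = 73, 2700, 850, 73
_CASSETTES = {"XylT": 840, "FucT": 1072}


def default_constructs(seed: int = 7) -> list[TransgeneSpec]:
    """The two RNAi constructs (FucT and XylT silencing) with random
    sequence but the deposited component geometry."""
    rng = np.random.default_rng(seed)
    out = []
    for name, cas_len in _CASSETTES.items():
        total = _LB + _PROMOTER + cas_len + _TERMINATOR + _RB
        seq = "".join(np.char.decode(rng.choice(_BASES, size=total), "ascii"))
        p0 = _LB
        c0 = p0 + _PROMOTER
        t0 = c0 + cas_len
        out.append(
            TransgeneSpec(
                name=name,
                seq=seq,
                promoter=Interval(name, p0, c0),
                cassette=Interval(name, c0, t0),
                terminator=Interval(name, t0, t0 + _TERMINATOR),
            )
        )
    return out


@dataclass
class InsertionEvent:
    """Ground truth for one integration: ``left_junction`` is the 1-based
    last retained host base of the 5' flank; the right flank resumes at
    ``left_junction + deleted + 1``."""

    scaffold: str
    left_junction: int
    deleted: int = 0
    orientation: str = "forward"
    zygosity: str = "hom"
    construct: str = ""
    disrupted_gene: str | None = None

    def __post_init__(self) -> None:
        if self.deleted < 0:
            raise ValueError("deleted must be >= 0")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be forward|reverse")
        if self.zygosity not in ("hom", "het"):
            raise ValueError("zygosity must be hom|het")

    @property
    def right_junction(self) -> int:
        """1-based first retained host base of the 3' flank."""
        return self.left_junction + self.deleted + 1


@dataclass
class ReadSimConfig:
    """Sequencing-run parameters.  Defaults mirror a 2x125 paired-end run
    with a 700 bp peak fragment length; fragment lengths are drawn from a
    normal truncated to [2 x read_length, inf)."""

    read_length: int = 125
    insert_mean: float = 700.0
    insert_sd: float = 50.0
    depth: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


@dataclass
class FusionSpec:
    """A construct-cassette to host-transcript fusion: the cassette RNA is
    attached upstream of exons ``first_exon``..end (biological ranks), which
    keep their original splicing."""

    construct_name: str
    cassette_seq: str
    transcript_id: str
    first_exon: int
    abundance: float = 1.0


@dataclass
class TruthSet:
    """Everything the simulator knows, serializable for later comparison."""

    insertions: list[InsertionEvent] = field(default_factory=list)
    planted_variants: list[VariantRecord] = field(default_factory=list)
    transcript_abundances: dict[str, float] = field(default_factory=dict)
    fusion: FusionSpec | None = None

    def to_json(self, path) -> None:
        payload = {
            "insertions": [asdict(e) for e in self.insertions],
            "planted_variants": [asdict(v) for v in self.planted_variants],
            "transcript_abundances": self.transcript_abundances,
            "fusion": asdict(self.fusion) if self.fusion else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            insertions=[InsertionEvent(**e) for e in d["insertions"]],
            planted_variants=[VariantRecord(**v) for v in d["planted_variants"]],
            transcript_abundances=d["transcript_abundances"],
            fusion=FusionSpec(**d["fusion"]) if d["fusion"] else None,
        )


# ---------------------------------------------------------------------------
# host genome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def make_host_genome(
    n_scaffolds: int = 1,
    lengths: Sequence[int] = (100_000,),
    genes_per_scaffold: int = 5,
    gc: float = 0.5,
    seed: int = 0,
    n_repeats: int = 3,
) -> tuple[list[SequenceRecord], list[TranscriptModel], list[Interval]]:
    """Random scaffolds with embedded multi-exon genes and repeat intervals.

    Genes carry ATG start and TAA stop codons and GT..AG intron boundaries;
    every CDS interval coincides with an exon.  Deterministic per seed.
    """
    if len(lengths) != n_scaffolds:
        raise ValueError("lengths must match n_scaffolds")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    models: list[TranscriptModel] = []
    repeats: list[Interval] = []
    gene_no = 0
    for si in range(n_scaffolds):
        length = int(lengths[si])
        if length < 10_000:
            raise ValueError("scaffold lengths must be >= 10 kb")
        name = f"scf{si + 1:02d}"
        arr = _random_seq(rng, length, gc)
        # carve non-overlapping gene loci on a coarse grid
        slot = length // max(genes_per_scaffold, 1)
        for gi in range(genes_per_scaffold):
            gene_no += 1
            n_ex = int(rng.integers(2, 6))
            ex_lens = rng.integers(90, 300, size=n_ex)
            ex_lens[-1] += (3 - int(ex_lens.sum()) % 3) % 3
            in_lens = rng.integers(80, 400, size=n_ex - 1)
            gene_len = int(ex_lens.sum() + in_lens.sum())
            if gene_len + 200 > slot:
                raise ValueError("requested gene does not fit its scaffold slot")
            start = si * 0 + gi * slot + int(rng.integers(50, slot - gene_len - 100))
            strand = "+" if rng.random() < 0.7 else "-"
            exons = []
            pos = start
            for k in range(n_ex):
                exons.append(Interval(name, pos, pos + int(ex_lens[k]), strand))
                if k < n_ex - 1:
                    ilen = int(in_lens[k])
                    # canonical splice dinucleotides in transcription direction
                    if strand == "+":
                        arr[pos + int(ex_lens[k])] = b"G"
                        arr[pos + int(ex_lens[k]) + 1] = b"T"
                        arr[pos + int(ex_lens[k]) + ilen - 2] = b"A"
                        arr[pos + int(ex_lens[k]) + ilen - 1] = b"G"
                    else:
                        arr[pos + int(ex_lens[k])] = b"C"
                        arr[pos + int(ex_lens[k]) + 1] = b"T"
                        arr[pos + int(ex_lens[k]) + ilen - 2] = b"A"
                        arr[pos + int(ex_lens[k]) + ilen - 1] = b"C"
                    pos += int(ex_lens[k]) + ilen
                else:
                    pos += int(ex_lens[k])
            gend = pos
            if strand == "+":
                arr[start : start + 3] = np.frombuffer(b"ATG", dtype="S1")
                arr[gend - 3 : gend] = np.frombuffer(b"TAA", dtype="S1")
            else:
                arr[gend - 3 : gend] = np.frombuffer(b"CAT", dtype="S1")
                arr[start : start + 3] = np.frombuffer(b"TTA", dtype="S1")
            gid = f"g{gene_no:05d}"
            models.append(
                TranscriptModel(
                    gene_id=gid,
                    transcript_id=f"{gid}.t1",
                    strand=strand,
                    exons=exons,
                    cds=list(exons),
                    has_start_codon=True,
                    has_stop_codon=True,
                )
            )
        for _ in range(n_repeats):
            rlen = int(rng.integers(200, 1500))
            rstart = int(rng.integers(0, length - rlen))
            repeats.append(Interval(name, rstart, rstart + rlen))
        records.append(SequenceRecord(name, arr.tobytes().decode("ascii")))
    return records, models, repeats


# ---------------------------------------------------------------------------
# insertion
# ---------------------------------------------------------------------------

# a haplotype scaffold is a list of layout segments mapping haplotype
# coordinates onto the (host + construct) reference:
#   (refname, ref_start, ref_end, strand) with hap length = ref_end - ref_start
Segment = tuple[str, int, int, str]


@dataclass
class Haplotype:
    """One haplotype: per-scaffold sequence plus the piecewise layout onto
    the unmodified host + construct reference."""

    name: str
    seqs: dict[str, str]
    layouts: dict[str, list[Segment]]


def identity_haplotype(name: str, genome: dict[str, str]) -> Haplotype:
    return Haplotype(
        name,
        dict(genome),
        {c: [(c, 0, len(s), "+")] for c, s in genome.items()},
    )


def apply_insertion(
    genome: dict[str, str],
    transgene: TransgeneSpec,
    event: InsertionEvent,
    models: Sequence[TranscriptModel] = (),
) -> tuple[list[Haplotype], InsertionEvent]:
    """Build the carrier haplotype(s): host[1..left_junction] + construct +
    host[left_junction+deleted+1..].  ``het`` keeps one unmodified haplotype.

    If the lesion falls inside an annotated gene the event is flagged with
    the disrupted gene id (an allowed scenario, not an error).
    """
    host = genome[event.scaffold]
    L = event.left_junction
    if L + event.deleted >= len(host):
        raise ValueError("insertion + deletion runs off the scaffold")
    cseq = transgene.seq if event.orientation == "forward" else revcomp(transgene.seq)
    modified = host[:L] + cseq + host[L + event.deleted :]
    strand = "+" if event.orientation == "forward" else "-"
    layout: list[Segment] = []
    if L > 0:
        layout.append((event.scaffold, 0, L, "+"))
    layout.append((transgene.name, 0, len(cseq), strand))
    layout.append((event.scaffold, L + event.deleted, len(host), "+"))
    event.construct = transgene.name
    for m in models:
        if m.chrom == event.scaffold and m.span.start < L + event.deleted and L < m.span.end:
            event.disrupted_gene = m.gene_id
            break
    hap1 = Haplotype("hap1", {**genome, event.scaffold: modified}, {
        **{c: [(c, 0, len(s), "+")] for c, s in genome.items()},
        event.scaffold: layout,
    })
    if event.zygosity == "het":
        return [hap1, identity_haplotype("hap2", genome)], event
    hap2 = Haplotype("hap2", hap1.seqs, hap1.layouts)
    return [hap1, hap2], event


# ---------------------------------------------------------------------------
# paired-end genomic reads
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReads:
    reads1: list[FastqRead]
    reads2: list[FastqRead]
    alignments: list[AlignmentRecord]
    references: dict[str, int]


def _map_to_reference(layout: list[Segment], start: int, end: int) -> list[tuple[str, int, int, str, int]]:
    """Intersect a haplotype range with the layout.  Returns pieces as
    (refname, ref_start, ref_end, strand, offset_in_range)."""
    pieces = []
    hap_off = 0
    for refname, rs, re_, strand in layout:
        seg_len = re_ - rs
        lo = max(start, hap_off)
        hi = min(end, hap_off + seg_len)
        if lo < hi:
            if strand == "+":
                pieces.append((refname, rs + (lo - hap_off), rs + (hi - hap_off), "+", lo - start))
            else:
                pieces.append(
                    (refname, rs + seg_len - (hi - hap_off), rs + seg_len - (lo - hap_off), "-", lo - start)
                )
        hap_off += seg_len
    return pieces


def _mate_records(
    qname: str,
    pieces: Sequence[tuple[str, int, int, str, int]],
    read_len: int,
    reverse: bool,
    readno: int,
    seq: str,
    min_piece: int = 12,
) -> list[AlignmentRecord]:
    """Records for one mate.  A single piece yields one full-M record; a
    junction-spanning read yields a soft-clipped primary on its longest piece
    plus soft-clipped supplementaries on the others.  Pieces shorter than
    ``min_piece`` are treated as unalignable and folded into the clip."""
    usable = [p for p in pieces if p[2] - p[1] >= min_piece]
    if not usable:
        return []
    base_flag = FPAIRED | (FREVERSE if reverse else 0) | (FREAD1 if readno == 1 else FREAD2)
    primary = max(usable, key=lambda p: p[2] - p[1])
    out = []
    for piece in usable:
        refname, rs, re_, pstrand, off = piece
        plen = re_ - rs
        # offset of the piece within the sequenced (stored) read
        soff = off if not reverse else read_len - off - plen
        rec_reverse = reverse ^ (pstrand == "-")
        # stored orientation: SAM stores the read in reference-forward
        # orientation, so the clip side follows the record's strand
        coff = soff if not rec_reverse else read_len - soff - plen
        cigar = []
        if coff:
            cigar.append(("S", coff))
        cigar.append(("M", plen))
        if read_len - coff - plen:
            cigar.append(("S", read_len - coff - plen))
        flag = (base_flag & ~FREVERSE) | (FREVERSE if rec_reverse else 0)
        if piece is not primary:
            flag |= FSUPPLEMENTARY
        # SAM stores SEQ in reference-forward orientation
        stored = revcomp(seq) if rec_reverse else seq
        out.append(
            AlignmentRecord(
                qname=qname,
                flag=flag,
                refname=refname,
                pos=rs + 1,
                mapq=60,
                cigar=cigar,
                seq=stored,
                quals=None,
                tags={"NM": 0, "AS": plen},
            )
        )
    return out


def _inject_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[int(rng.integers(3))]])
    return arr.tobytes().decode()


def simulate_genomic_pairs(
    haplotypes: Sequence[Haplotype],
    references: dict[str, int],
    config: ReadSimConfig,
    emit_fastq: bool = True,
) -> SimulatedReads:
    """Sample paired-end fragments uniformly along each haplotype and emit
    truth alignments against the unmodified host + construct reference.

    Pairs straddling a junction become bridging pairs (mates on different
    references); reads overlapping a junction become chimeric records
    (primary on the longer side, soft-clipped supplementary on the shorter).
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    reads1: list[FastqRead] = []
    reads2: list[FastqRead] = []
    alns: list[AlignmentRecord] = []
    quals = [35] * rl
    pair_no = 0
    f_fwd1 = FPAIRED | FREAD1 | FMREVERSE
    f_fwd2 = FPAIRED | FREAD2 | FMREVERSE
    f_rev1 = FPAIRED | FREAD1 | FREVERSE
    f_rev2 = FPAIRED | FREAD2 | FREVERSE
    for hap in haplotypes:
        for chrom, seq in hap.seqs.items():
            layout = hap.layouts[chrom]
            clen = len(seq)
            # hap-coordinate segment table for the fast single-segment path
            segs: list[tuple[int, int, str, int, str]] = []
            off = 0
            for refname, rs, re_, strand in layout:
                segs.append((off, off + (re_ - rs), refname, rs, strand))
                off += re_ - rs
            n_pairs = int(round(config.depth * clen / (2 * rl) / len(haplotypes)))
            frags = rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)
            frags = np.clip(frags, 2 * rl, None).astype(np.int64)
            frags = np.minimum(frags, clen)
            starts = (rng.random(n_pairs) * (clen - frags + 1)).astype(np.int64)
            flip = rng.random(n_pairs) < 0.5
            m_cigar = [("M", rl)]
            for i in range(n_pairs):
                pair_no += 1
                qname = f"{hap.name}_p{pair_no}"
                fs, fe = int(starts[i]), int(starts[i] + frags[i])
                left_seq = seq[fs : fs + rl]
                right_fwd = seq[fe - rl : fe]
                if config.error_rate:
                    left_seq = _inject_errors(rng, left_seq, config.error_rate)
                    right_fwd = _inject_errors(rng, right_fwd, config.error_rate)
                right_seq = revcomp(right_fwd)
                fl = bool(flip[i])
                # FR library: the left-end mate is always sequenced forward and
                # the right-end mate reverse; flip only swaps the R1/R2 labels
                r1_seq, r2_seq = (right_seq, left_seq) if fl else (left_seq, right_seq)
                # fast path: both mates fully inside single forward segments
                lseg = rseg = None
                for hs, he, refname, rs, strand in segs:
                    if hs <= fs and fs + rl <= he:
                        lseg = (refname, rs + fs - hs) if strand == "+" else None
                    if hs <= fe - rl and fe <= he:
                        rseg = (refname, rs + (fe - rl) - hs) if strand == "+" else None
                if lseg is not None and rseg is not None:
                    lp = AlignmentRecord(
                        qname, f_fwd2 if fl else f_fwd1, lseg[0], lseg[1] + 1, 60,
                        m_cigar, rseg[0], rseg[1] + 1, 0, left_seq, None, {"NM": 0, "AS": rl},
                    )
                    rp = AlignmentRecord(
                        qname, f_rev1 if fl else f_rev2, rseg[0], rseg[1] + 1, 60,
                        m_cigar, lseg[0], lseg[1] + 1, 0, right_fwd, None, {"NM": 0, "AS": rl},
                    )
                    if lseg[0] == rseg[0]:
                        tlen = int(frags[i])
                        lp.flag |= FPROPER
                        rp.flag |= FPROPER
                        lp.tlen, rp.tlen = tlen, -tlen
                    alns.append(lp)
                    alns.append(rp)
                else:
                    left_recs = _mate_records(
                        qname, _map_to_reference(layout, fs, fs + rl), rl,
                        False, 2 if fl else 1, left_seq,
                    )
                    right_recs = _mate_records(
                        qname, _map_to_reference(layout, fe - rl, fe), rl,
                        True, 1 if fl else 2, right_seq,
                    )
                    # mate cross-references from the primaries
                    lp = next((r for r in left_recs if not r.is_supplementary), None)
                    rp = next((r for r in right_recs if not r.is_supplementary), None)
                    for recs, other in ((left_recs, rp), (right_recs, lp)):
                        for r in recs:
                            if other is not None:
                                r.mate_refname = other.refname
                                r.mate_pos = other.pos
                                if other.is_reverse:
                                    r.flag |= FMREVERSE
                    if (
                        lp is not None
                        and rp is not None
                        and lp.refname == rp.refname
                        and len(lp.cigar) == 1
                        and len(rp.cigar) == 1
                    ):
                        tlen = int(frags[i])
                        for r in (lp, rp):
                            r.flag |= FPROPER
                        lp.tlen, rp.tlen = tlen, -tlen
                    alns.extend(left_recs)
                    alns.extend(right_recs)
                if emit_fastq:
                    reads1.append(FastqRead(qname, r1_seq, quals))
                    reads2.append(FastqRead(qname, r2_seq, quals))
    return SimulatedReads(reads1, reads2, alns, dict(references))


# ---------------------------------------------------------------------------
# RNA-seq
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRna:
    reads1: list[FastqRead]
    reads2: list[FastqRead]
    genome_alignments: list[AlignmentRecord]
    transcriptome_alignments: list[AlignmentRecord]
    transcriptome_refs: dict[str, int]
    per_exon_truth: dict[str, list[int]]


def _spliced_record(
    qname: str,
    model: TranscriptModel,
    t_off: int,
    length: int,
    reverse: bool,
    readno: int,
    seq: str,
    clip5: int = 0,
    clip3: int = 0,
) -> AlignmentRecord:
    """Genome-space record for a read whose aligned portion sits at
    transcript offset ``t_off``; ``clip5``/``clip3`` are unaligned read
    bases (transcript-forward orientation, e.g. a cassette-derived prefix
    of a fusion read) emitted as soft clips."""
    # collect genomic blocks ascending
    blocks: list[tuple[int, int]] = []
    off = 0
    for e in model.exons_by_rank():
        elen = len(e)
        lo = max(t_off, off)
        hi = min(t_off + length, off + elen)
        if lo < hi:
            if model.strand != "-":
                blocks.append((e.start + (lo - off), e.start + (hi - off)))
            else:
                blocks.append((e.end - (hi - off), e.end - (lo - off)))
        off += elen
    blocks.sort()
    cigar: list[tuple[str, int]] = []
    # stored SEQ is genome-forward; on minus-strand models the read's 5'
    # clip lands at the record's 3' end
    lead, tail = (clip5, clip3) if model.strand != "-" else (clip3, clip5)
    if lead:
        cigar.append(("S", lead))
    for j, (bs, be) in enumerate(blocks):
        if j:
            cigar.append(("N", bs - blocks[j - 1][1]))
        cigar.append(("M", be - bs))
    if tail:
        cigar.append(("S", tail))
    rec_reverse = reverse ^ (model.strand == "-")
    flag = FPAIRED | (FREAD1 if readno == 1 else FREAD2) | (FREVERSE if rec_reverse else 0)
    return AlignmentRecord(
        qname=qname,
        flag=flag,
        refname=model.chrom,
        pos=blocks[0][0] + 1,
        mapq=60,
        cigar=cigar,
        seq=revcomp(seq) if rec_reverse else seq,
        tags={"NM": 0},
    )


def simulate_rnaseq(
    models: Sequence[TranscriptModel],
    genome: dict[str, str],
    abundances: dict[str, float],
    config: ReadSimConfig,
    fusion: FusionSpec | None = None,
    n_pairs: int | None = None,
) -> SimulatedRna:
    """Sample read pairs from mature transcripts proportional to
    abundance x length; genome-space truth alignments use N ops across
    introns.  A fusion transcript concatenates the cassette sequence with a
    suffix of the host transcript (exons ``first_exon``..end, original
    splicing); its cassette-derived mates map to the cassette reference in
    transcriptome space and are soft-clipped out of genome space.
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    by_id = {m.transcript_id: m for m in models}
    if fusion and fusion.transcript_id not in by_id:
        raise ValueError(f"fusion references unknown transcript {fusion.transcript_id}")
    if fusion:
        host = by_id[fusion.transcript_id]
        if not 1 <= fusion.first_exon <= host.n_exons:
            raise ValueError(f"fusion exon {fusion.first_exon} out of range")

    # source pool: (source_id, mature sequence, weight, model-or-None, t0)
    # where t0 is the transcript offset of the mature suffix for fusions
    pool: list[tuple[str, str, float, TranscriptModel | None, int]] = []
    for tid, ab in abundances.items():
        if ab < 0:
            raise ValueError("abundances must be >= 0")
        if ab == 0:
            continue
        m = by_id[tid]
        pool.append((tid, m.spliced_sequence(genome), ab, m, 0))
    if fusion and fusion.abundance > 0:
        host = by_id[fusion.transcript_id]
        ranks = host.exons_by_rank()
        suffix_start = sum(len(e) for e in ranks[: fusion.first_exon - 1])
        mature = fusion.cassette_seq + host.spliced_sequence(genome)[suffix_start:]
        pool.append((f"fusion:{fusion.construct_name}", mature, fusion.abundance, host, suffix_start))

    weights = np.array([w * len(s) for _, s, w, _, _ in pool], dtype=float)
    if n_pairs is None:
        total_len = sum(len(s) for _, s, _, _, _ in pool)
        n_pairs = int(round(config.depth * total_len / (2 * rl)))
    if not len(pool) or weights.sum() == 0:
        return SimulatedRna([], [], [], [], {}, {})
    weights /= weights.sum()
    choice = rng.choice(len(pool), size=n_pairs, p=weights)

    t_refs = {tid: len(s) for tid, s, _, m, _ in pool if m is None or not tid.startswith("fusion:")}
    for m in models:
        t_refs.setdefault(m.transcript_id, len(m.spliced_sequence(genome)))
    if fusion:
        t_refs[fusion.construct_name] = len(fusion.cassette_seq)

    reads1: list[FastqRead] = []
    reads2: list[FastqRead] = []
    g_alns: list[AlignmentRecord] = []
    t_alns: list[AlignmentRecord] = []
    quals = [35] * rl
    per_exon: dict[str, list[int]] = {
        m.transcript_id: [0] * m.n_exons for m in models
    }
    for i in range(n_pairs):
        sid, mature, _, model, t0 = pool[int(choice[i])]
        is_fusion = sid.startswith("fusion:")
        cas_len = len(fusion.cassette_seq) if is_fusion else 0
        mlen = len(mature)
        frag = int(np.clip(rng.normal(config.insert_mean, config.insert_sd), 2 * rl, mlen))
        if mlen < 2 * rl:
            continue
        fs = int(rng.integers(0, mlen - frag + 1))
        fe = fs + frag
        qname = f"rna_p{i}"
        r1 = mature[fs : fs + rl]
        r2 = revcomp(mature[fe - rl : fe])
        if config.error_rate:
            r1 = _inject_errors(rng, r1, config.error_rate)
            r2 = _inject_errors(rng, r2, config.error_rate)
        reads1.append(FastqRead(qname, r1, quals))
        reads2.append(FastqRead(qname, r2, quals))

        for mate_no, (ms, mseq, mrev) in enumerate(
            (( fs, r1, False), (fe - rl, r2, True)), start=1
        ):
            me = ms + rl
            # transcriptome-space truth
            if not is_fusion:
                flag = FPAIRED | (FREAD1 if mate_no == 1 else FREAD2) | (FREVERSE if mrev else 0)
                t_alns.append(
                    AlignmentRecord(qname, flag, sid, ms + 1, 60, [("M", rl)], seq=mseq)
                )
            else:
                # piece on cassette vs piece on host transcript
                flag = FPAIRED | (FREAD1 if mate_no == 1 else FREAD2) | (FREVERSE if mrev else 0)
                cas_part = max(0, min(me, cas_len) - ms)
                host_part = rl - max(0, cas_part) if me > cas_len else 0
                if cas_part >= host_part and cas_part > 0:
                    cigar = [("M", cas_part)] + ([("S", rl - cas_part)] if rl > cas_part else [])
                    if mrev:
                        cigar = cigar[::-1]
                    t_alns.append(
                        AlignmentRecord(
                            qname, flag, fusion.construct_name, ms + 1, 60, cigar, seq=mseq
                        )
                    )
                elif host_part > 0:
                    hs = max(ms - cas_len, 0)
                    clip = rl - host_part
                    cigar = ([("S", clip)] if clip else []) + [("M", host_part)]
                    if mrev and clip:
                        cigar = cigar[::-1]
                    t_alns.append(
                        AlignmentRecord(
                            qname,
                            flag,
                            fusion.transcript_id,
                            t0 + hs + 1,
                            60,
                            cigar,
                            seq=mseq,
                        )
                    )
            # genome-space truth (host-derived portion only)
            if model is not None:
                if is_fusion:
                    g_lo = max(ms, cas_len)
                    if me - g_lo < 12:
                        continue
                    rec = _spliced_record(
                        qname, model, t0 + g_lo - cas_len, me - g_lo, mrev, mate_no,
                        mseq, clip5=g_lo - ms,
                    )
                else:
                    rec = _spliced_record(qname, model, t0 + ms, rl, mrev, mate_no, mseq)
                g_alns.append(rec)
                # per-exon truth bookkeeping
                lo = t0 + (max(ms, cas_len) - cas_len if is_fusion else ms)
                hi = t0 + (me - cas_len if is_fusion else me)
                off = 0
                for rank, e in enumerate(model.exons_by_rank(), start=1):
                    if lo < off + len(e) and hi > off:
                        per_exon[model.transcript_id][rank - 1] += min(hi, off + len(e)) - max(lo, off)
                    off += len(e)
    # fix mate pointers for transcriptome records (pair by qname)
    prim: dict[tuple[str, int], AlignmentRecord] = {}
    for r in t_alns:
        prim[(r.qname, 1 if r.is_read1 else 2)] = r
    for r in t_alns:
        other = prim.get((r.qname, 2 if r.is_read1 else 1))
        if other is not None:
            r.mate_refname = other.refname
            r.mate_pos = other.pos
            if other.is_reverse:
                r.flag |= FMREVERSE
    return SimulatedRna(reads1, reads2, g_alns, t_alns, t_refs, per_exon)


# ---------------------------------------------------------------------------
# planted variants
# ---------------------------------------------------------------------------

def plant_variants(
    genome: dict[str, str],
    rate_per_mbp: float,
    titv_ratio: float = 2.0,
    region_track: Sequence[Interval] | None = None,
    indel_rate_per_mbp: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], list[VariantRecord]]:
    """Plant SNVs (and optionally short indels) at a Poisson density within
    ``region_track`` (whole genome when None).  Transitions are chosen with
    probability titv/(titv+1).  Returns the mutated genome and the 1-based
    truth records on reference coordinates."""
    if rate_per_mbp < 0 or titv_ratio <= 0:
        raise ValueError("rate >= 0 and titv_ratio > 0 required")
    rng = np.random.default_rng(seed)
    if region_track is None:
        region_track = [Interval(c, 0, len(s)) for c, s in genome.items()]
    regions = [iv for iv in region_track if iv.chrom in genome]
    if not regions and rate_per_mbp > 0:
        raise ValueError("empty region track with positive rate")
    total = sum(len(iv) for iv in regions)
    mbp = total / 1e6
    n_snv = rng.poisson(rate_per_mbp * mbp)
    n_indel = rng.poisson(indel_rate_per_mbp * mbp)
    # flatten region offsets for uniform position draws
    cum = np.cumsum([len(iv) for iv in regions])
    draws = rng.choice(total, size=min(n_snv + n_indel, total), replace=False)
    variants: list[VariantRecord] = []
    mutated = {c: np.frombuffer(s.encode(), dtype="S1").copy() for c, s in genome.items()}
    p_ti = titv_ratio / (titv_ratio + 1.0)
    for k, flat in enumerate(draws):
        ri = int(np.searchsorted(cum, flat, side="right"))
        iv = regions[ri]
        off = int(flat) - (int(cum[ri]) - len(iv))
        pos0 = iv.start + off
        chrom = iv.chrom
        ref = genome[chrom][pos0]
        if ref == "N":
            continue
        if k < n_snv:
            if rng.random() < p_ti:
                alt = TRANSITION[ref]
            else:
                alt = TRANSVERSIONS[ref][int(rng.integers(2))]
            mutated[chrom][pos0] = alt.encode()
            variants.append(
                VariantRecord(chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, qual=60.0)
            )
        else:
            ilen = int(rng.integers(1, 4))
            if rng.random() < 0.5 and pos0 + ilen + 1 < iv.end:  # deletion
                ref_al = genome[chrom][pos0 : pos0 + ilen + 1]
                variants.append(
                    VariantRecord(chrom=chrom, pos=pos0 + 1, ref=ref_al, alt=ref_al[0], qual=60.0)
                )
            else:  # insertion
                ins = "".join(np.char.decode(rng.choice(_BASES, size=ilen), "ascii"))
                variants.append(
                    VariantRecord(chrom=chrom, pos=pos0 + 1, ref=ref, alt=ref + ins, qual=60.0)
                )
    # apply indels right-to-left so earlier coordinates stay valid
    out = {c: a.tobytes().decode() for c, a in mutated.items()}
    indels = sorted(
        (v for v in variants if v.vtype != "SNV"), key=lambda v: (v.chrom, -v.pos)
    )
    for v in indels:
        s = out[v.chrom]
        if v.vtype == "DEL":
            out[v.chrom] = s[: v.pos] + s[v.pos - 1 + len(v.ref) :]
        else:
            out[v.chrom] = s[: v.pos] + v.alt[1:] + s[v.pos :]
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return out, variants
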