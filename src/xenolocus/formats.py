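"""Readers/writers for the standard formats the pipeline touches, plus the
interval and CIGAR primitives shared by every stage.

Conventions
-----------
All internal coordinates are 0-based, half-open.  GFF3, SAM and VCF use
1-based coordinates on disk; the conversion happens here, at the I/O layer,
and nowhere else.  User-facing junction and variant positions are printed
1-based.

SAM is consumed and produced as text (any upstream aligner's output is
acceptable); BAM/CRAM are out of scope.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "FastqRead",
    "Interval",
    "TranscriptModel",
    "AlignmentRecord",
    "VariantRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_gff3",
    "write_gff3",
    "read_sam",
    "write_sam",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "parse_cigar",
    "cigar_to_string",
    "cigar_ref_span",
    "cigar_query_span",
    "reference_blocks",
    "interval_merge",
    "interval_overlap_length",
    "transform_reads",
]

_VALID_BASES = set("ACGTN")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
# reference- and query-consuming CIGAR operations (SAM spec semantics)
REF_OPS = frozenset("MDN=X")
QUERY_OPS = frozenset("MIS=X")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named nucleotide sequence (FASTA record), upper-cased, ACGTN only."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.seq = self.seq.upper()
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in record {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FastqRead:
    """A sequencing read with per-base Phred qualities."""

    id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ValueError(f"read {self.id!r}: {len(self.quals)} quals for {len(self.seq)} bases")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def start1(self) -> int:
        """1-based start (GFF3/SAM/VCF convention)."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """1-based closed end — equal to the half-open end."""
        return self.end

    @classmethod
    def from_1based(cls, chrom: str, start1: int, end1: int, strand: str = ".") -> "Interval":
        return cls(chrom, start1 - 1, end1, strand)

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TranscriptModel:
    """A transcript: ordered exon and CDS intervals under a gene.

    Exons are stored in ascending genomic order regardless of strand; the
    ``exon_rank`` helper returns biological (strand-aware) exon numbers.
    """

    gene_id: str
    transcript_id: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    has_start_codon: bool = False
    has_stop_codon: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(f"{self.transcript_id}: CDS {c} outside every exon")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> Interval:
        """Gene-span interval including introns."""
        return Interval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[Interval]:
        return [
            Interval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    def exons_by_rank(self) -> list[Interval]:
        """Exons in biological order (5'→3' of the transcript)."""
        return self.exons if self.strand != "-" else list(reversed(self.exons))

    def genome_to_transcript(self, gpos: int) -> int | None:
        """Map a 0-based genomic position to a 0-based transcript offset."""
        off = 0
        for e in self.exons_by_rank():
            if e.start <= gpos < e.end:
                return off + (gpos - e.start if self.strand != "-" else e.end - 1 - gpos)
            off += len(e)
        return None

    def transcript_to_exon_rank(self, tpos: int) -> int:
        """1-based exon number containing a 0-based transcript offset."""
        off = 0
        for i, e in enumerate(self.exons_by_rank(), start=1):
            if tpos < off + len(e):
                return i
            off += len(e)
        raise IndexError(f"transcript offset {tpos} beyond {self.transcript_id}")

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.chrom][e.start:e.end] for e in self.exons)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.chrom][c.start:c.end] for c in self.cds)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


# SAM flag bits
FPAIRED, FPROPER, FUNMAP, FMUNMAP = 0x1, 0x2, 0x4, 0x8
FREVERSE, FMREVERSE, FREAD1, FREAD2 = 0x10, 0x20, 0x40, 0x80
FSECONDARY, FQCFAIL, FDUP, FSUPPLEMENTARY = 0x100, 0x200, 0x400, 0x800


@dataclass(slots=True)
class AlignmentRecord:
    """One SAM line.  ``pos``/``mate_pos`` are 1-based leftmost positions
    (0 means unmapped, as in SAM)."""

    qname: str
    flag: int
    refname: str
    pos: int
    mapq: int
    cigar: list[tuple[str, int]]
    mate_refname: str = "*"
    mate_pos: int = 0
    tlen: int = 0
    seq: str = "*"
    quals: list[int] | None = None
    tags: dict[str, int | float | str] = field(default_factory=dict)

    # -- flag accessors -----------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FPAIRED)

    @property
    def is_proper(self) -> bool:
        return bool(self.flag & FPROPER)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FUNMAP)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & FMUNMAP)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FREVERSE)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & FREAD1)

    @property
    def is_read2(self) -> bool:
        return bool(self.flag & FREAD2)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FSECONDARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FDUP)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FSUPPLEMENTARY)

    @property
    def is_primary(self) -> bool:
        return not (self.flag & (FSECONDARY | FSUPPLEMENTARY))

    # -- coordinates --------------------------------------------------------
    @property
    def ref_start(self) -> int:
        """0-based leftmost reference position."""
        return self.pos - 1

    @property
    def ref_end(self) -> int:
        """0-based half-open reference end."""
        return self.pos - 1 + cigar_ref_span(self.cigar)

    def validate(self) -> None:
        if self.pos < 0:
            raise ValueError(f"{self.qname}: negative pos")
        if self.seq != "*":
            qlen = cigar_query_span(self.cigar)
            if qlen and qlen != len(self.seq):
                raise ValueError(
                    f"{self.qname}: CIGAR query span {qlen} != seq length {len(self.seq)}"
                )


@dataclass
class VariantRecord:
    """A called variant with the depth/strand/quality annotations the
    filter cascades test.  ``pos`` is 1-based (VCF convention); indels use
    the anchored-base representation (REF and ALT share their first base)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0
    depth: int = 0
    ref_count: int = 0
    alt_count: int = 0
    alt_fwd: int = 0
    alt_rev: int = 0
    mq_mean: float = 60.0
    mq0_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos} ref == alt")
        if self.ref_count + self.alt_count > self.depth:
            raise ValueError(f"{self.chrom}:{self.pos} allele counts exceed depth")
        if not 0.0 <= self.mq0_fraction <= 1.0:
            raise ValueError("mq0_fraction outside [0, 1]")

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def alt_fraction(self) -> float:
        tot = self.ref_count + self.alt_count
        return self.alt_count / tot if tot else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_transition(self) -> bool:
        return self.vtype == "SNV" and {self.ref, self.alt} in ({"A", "G"}, {"C", "T"})


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream FASTA records; malformed headers raise :class:`ParseError`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}:1: expected '>' header, got {first.strip()!r}")
    for rec in SeqIO.parse(str(path), "fasta"):
        yield SequenceRecord(rec.id, str(rec.seq), rec.description)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.description}" if rec.description else f">{rec.id}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield FastqRead(rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"]))


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = r.quals
            fh.write(rec.format("fastq"))


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> tuple[list[TranscriptModel], dict[str, list[Interval]]]:
    """Parse GFF3 gene models (gene/mRNA/exon/CDS linked by ID/Parent).

    Returns the transcript models plus any non-gene feature tracks (e.g.
    repeats) keyed by feature type.  A CDS falling outside every exon of its
    transcript raises (the model is flagged invalid, not silently kept).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[TranscriptModel] = []
    tracks: dict[str, list[Interval]] = {}
    seen_gene_children = {"mRNA", "exon", "CDS"}
    for mrna in db.features_of_type("mRNA", order_by="start"):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        exons = [
            Interval.from_1based(c.seqid, c.start, c.end, c.strand)
            for c in db.children(mrna, featuretype="exon", order_by="start")
        ]
        cds = [
            Interval.from_1based(c.seqid, c.start, c.end, c.strand)
            for c in db.children(mrna, featuretype="CDS", order_by="start")
        ]
        attrs = mrna.attributes
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
                has_start_codon=attrs.get("has_start", ["false"])[0] == "true",
                has_stop_codon=attrs.get("has_stop", ["false"])[0] == "true",
            )
        )
    for ftype in db.featuretypes():
        if ftype in seen_gene_children or ftype == "gene":
            continue
        tracks[ftype] = [
            Interval.from_1based(f.seqid, f.start, f.end, f.strand if f.strand in "+-" else ".")
            for f in db.features_of_type(ftype, order_by="start")
        ]
    return models, tracks


def write_gff3(
    models: Sequence[TranscriptModel],
    path: str | Path,
    tracks: dict[str, list[Interval]] | None = None,
) -> None:
    """Emit gene/mRNA/exon/CDS rows (plus optional feature tracks)."""
    lines = ["##gff-version 3"]
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    for gene_id, tms in by_gene.items():
        chrom = tms[0].chrom
        strand = tms[0].strand
        gstart = min(t.span.start for t in tms)
        gend = max(t.span.end for t in tms)
        lines.append(
            f"{chrom}\txenolocus\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\tID={gene_id}"
        )
        for t in tms:
            flags = (
                f"has_start={'true' if t.has_start_codon else 'false'};"
                f"has_stop={'true' if t.has_stop_codon else 'false'}"
            )
            lines.append(
                f"{chrom}\txenolocus\tmRNA\t{t.span.start + 1}\t{t.span.end}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id};Parent={gene_id};{flags}"
            )
            for i, e in enumerate(t.exons, start=1):
                lines.append(
                    f"{chrom}\txenolocus\texon\t{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
                )
            for i, c in enumerate(t.cds, start=1):
                lines.append(
                    f"{chrom}\txenolocus\tCDS\t{c.start + 1}\t{c.end}\t.\t{t.strand}\t0\t"
                    f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}"
                )
    if tracks:
        for ftype, ivs in tracks.items():
            for i, iv in enumerate(ivs, start=1):
                lines.append(
                    f"{iv.chrom}\txenolocus\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                    f"ID={ftype}_{i}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _from_pysam(a: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = [("MIDNSHP=X"[code], ln) for code, ln in (a.cigartuples or [])]
    return AlignmentRecord(
        qname=a.query_name,
        flag=a.flag,
        refname=a.reference_name if a.reference_name is not None else "*",
        pos=a.reference_start + 1 if a.reference_start is not None and a.reference_start >= 0 else 0,
        mapq=a.mapping_quality,
        cigar=cigar,
        mate_refname=(a.next_reference_name if a.next_reference_name is not None else "*"),
        mate_pos=a.next_reference_start + 1 if a.next_reference_start >= 0 else 0,
        tlen=a.template_length,
        seq=a.query_sequence if a.query_sequence else "*",
        quals=list(a.query_qualities) if a.query_qualities is not None else None,
        tags=dict(a.get_tags()),
    )


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read SAM text into :class:`AlignmentRecord` objects, preserving input
    order.  All refnames must be declared in ``@SQ`` header lines."""
    with pysam.AlignmentFile(str(path), "r") as fh:
        return [_from_pysam(a) for a in fh]


def write_sam(
    header: dict[str, int],
    records: Iterable[AlignmentRecord],
    path: str | Path,
) -> None:
    """Write SAM text; ``header`` maps refname to reference length."""
    refs = list(header.items())
    hdr = pysam.AlignmentHeader.from_references(
        [name for name, _ in refs], [ln for _, ln in refs]
    )
    tid = {name: i for i, (name, _) in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=hdr) as out:
        for r in records:
            a = pysam.AlignedSegment(hdr)
            a.query_name = r.qname
            a.flag = r.flag
            if r.refname != "*":
                if r.refname not in tid:
                    raise ParseError(f"refname {r.refname!r} absent from header")
                a.reference_id = tid[r.refname]
                a.reference_start = r.pos - 1
            a.mapping_quality = r.mapq
            if r.cigar:
                a.cigarstring = cigar_to_string(r.cigar)
            if r.mate_refname == "=":
                a.next_reference_id = a.reference_id
            elif r.mate_refname != "*":
                a.next_reference_id = tid[r.mate_refname]
            if r.mate_pos:
                a.next_reference_start = r.mate_pos - 1
            a.template_length = r.tlen
            if r.seq != "*":
                a.query_sequence = r.seq
                if r.quals is not None:
                    a.query_qualities = r.quals
            for k, v in r.tags.items():
                a.set_tag(k, v)
            out.write(a)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    ('INFO', 'DP', '1', 'Integer', 'Raw read depth'),
    ('INFO', 'MQ', '1', 'Float', 'Mean mapping quality'),
    ('INFO', 'MQ0F', '1', 'Float', 'Fraction of MQ0 reads'),
    ('FORMAT', 'GT', '1', 'String', 'Genotype'),
    ('FORMAT', 'AD', 'R', 'Integer', 'Allelic depths'),
    ('FORMAT', 'ADF', 'R', 'Integer', 'Allelic depths, forward strand'),
    ('FORMAT', 'ADR', 'R', 'Integer', 'Allelic depths, reverse strand'),
]


def write_vcf(
    variants: Sequence[VariantRecord],
    path: str | Path,
    contigs: dict[str, int],
    sample: str = "SAMPLE",
) -> None:
    hdr = pysam.VariantHeader()
    for name, length in contigs.items():
        hdr.contigs.add(name, length=length)
    for kind, vid, num, vtype, desc in _VCF_HEADER_LINES:
        hdr.add_meta(
            kind,
            items=[("ID", vid), ("Number", num), ("Type", vtype), ("Description", desc)],
        )
    hdr.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=hdr) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
                qual=v.qual,
            )
            rec.info["DP"] = v.depth
            rec.info["MQ"] = v.mq_mean
            rec.info["MQ0F"] = v.mq0_fraction
            smp = rec.samples[sample]
            smp["AD"] = (v.ref_count, v.alt_count)
            ref_fwd = max(0, v.ref_count)  # strand split of REF not tracked; all fwd
            smp["ADF"] = (ref_fwd, v.alt_fwd)
            smp["ADR"] = (0, v.alt_rev)
            out.write(rec)


def read_vcf(path: str | Path) -> list[VariantRecord]:
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as fh:
        sample = list(fh.header.samples)[0] if list(fh.header.samples) else None
        for rec in fh:
            smp = rec.samples[sample] if sample else {}
            ad = smp.get("AD", (0, 0)) or (0, 0)
            adf = smp.get("ADF", (0, 0)) or (0, 0)
            adr = smp.get("ADR", (0, 0)) or (0, 0)
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    qual=rec.qual if rec.qual is not None else 0.0,
                    depth=int(rec.info.get("DP", sum(x or 0 for x in ad))),
                    ref_count=int(ad[0] or 0),
                    alt_count=int(ad[1] or 0),
                    alt_fwd=int(adf[1] or 0),
                    alt_rev=int(adr[1] or 0),
                    mq_mean=float(rec.info.get("MQ", 60.0)),
                    mq0_fraction=float(rec.info.get("MQ0F", 0.0)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Interval]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{ln}: BED needs >= 3 columns")
        strand = parts[5] if len(parts) >= 6 else "."
        out.append(Interval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path, names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# CIGAR arithmetic
# ---------------------------------------------------------------------------

def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    if cigar in ("*", ""):
        return []
    ops = _CIGAR_RE.findall(cigar)
    if sum(len(n) + 1 for n, _ in ops) != len(cigar):
        raise ParseError(f"unparseable CIGAR {cigar!r}")
    return [(op, int(n)) for n, op in ops]


def cigar_to_string(cigar: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar) or "*"


def cigar_ref_span(cigar: Sequence[tuple[str, int]]) -> int:
    """Total length of reference-consuming operations (M, D, N, =, X)."""
    return sum(n for op, n in cigar if op in REF_OPS)


def cigar_query_span(cigar: Sequence[tuple[str, int]]) -> int:
    """Total length of query-consuming operations (M, I, S, =, X)."""
    return sum(n for op, n in cigar if op in QUERY_OPS)


def reference_blocks(pos: int, cigar: Sequence[tuple[str, int]], skip_deletions: bool = False) -> list[tuple[int, int]]:
    """0-based half-open reference blocks covered by an alignment starting at
    1-based ``pos``.  N (intron skips) always split blocks; D splits only when
    ``skip_deletions`` — by default deleted reference positions count as
    covered, matching depth-profile semantics."""
    blocks: list[tuple[int, int]] = []
    ref = pos - 1
    cur_start: int | None = None
    for op, n in cigar:
        if op in "M=X" or (op == "D" and not skip_deletions):
            if cur_start is None:
                cur_start = ref
            ref += n
        elif op in ("N", "D"):
            if cur_start is not None:
                blocks.append((cur_start, ref))
                cur_start = None
            ref += n
        # I, S, H, P consume no reference
    if cur_start is not None:
        blocks.append((cur_start, ref))
    return blocks


# ---------------------------------------------------------------------------
# interval primitives
# ---------------------------------------------------------------------------

def interval_merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Minimal sorted disjoint cover, grouped per chromosome (intervals on
    different chromosomes are never merged)."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: x.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(Interval(chrom, cur_s, cur_e))
    return merged


def interval_overlap_length(a: Interval, track: Iterable[Interval]) -> int:
    """Total bases of ``a`` overlapped by the merged track."""
    return sum(a.overlap_length(t) for t in interval_merge(track))


# ---------------------------------------------------------------------------
# read transforms
# ---------------------------------------------------------------------------

@dataclass
class TransformResult:
    reads: list[FastqRead]
    n_dropped_short: int = 0


def transform_reads(
    reads: Iterable[FastqRead],
    crop_to: int | None = None,
    sample_n: int | None = None,
    seed: int = 0,
) -> TransformResult:
    """Crop reads to their first ``crop_to`` bases and/or subsample to
    ``sample_n`` reads without replacement (seeded, deterministic).

    Reads shorter than ``crop_to`` are dropped, not padded; the drop count is
    reported.  Cropping mirrors the common preprocessing of trimming all reads
    to a shared length before end-to-end mapping; subsampling equalizes
    library sizes across datasets.
    """
    if crop_to is not None and crop_to < 1:
        raise ValueError("crop_to must be >= 1")
    out: list[FastqRead] = []
    dropped = 0
    for r in reads:
        if crop_to is not None:
            if len(r.seq) < crop_to:
                dropped += 1
                continue
            r = FastqRead(r.id, r.seq[:crop_to], r.quals[:crop_to])
        out.append(r)
    if sample_n is not None and sample_n < len(out):
        rng = random.Random(seed)
        idx = sorted(rng.sample(range(len(out)), sample_n))
        out = [out[i] for i in idx]
    return TransformResult(out, dropped)
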