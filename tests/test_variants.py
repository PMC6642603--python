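"""Pileup genotyping, filter cascades, set arithmetic, Ti/Tv, divergence and
coding-impact classification."""

import random

import numpy as np
import pytest
from Bio.Seq import Seq

from xenolocus import simulate as sim
from xenolocus import variants as var
from xenolocus.formats import AlignmentRecord, Interval, VariantRecord, parse_cigar


def _aln(qname, refname, pos, cigar, flag=0x1, seq=None, quals=None, tags=None,
         mate_pos=0):
    cig = parse_cigar(cigar)
    return AlignmentRecord(
        qname, flag, refname, pos, 60, cig,
        mate_refname=refname if mate_pos else "*", mate_pos=mate_pos,
        seq=seq or "*", quals=quals, tags=tags if tags is not None else {"NM": 0},
    )


def _v(pos, ref="A", alt="G", chrom="c", **kw):
    defaults = dict(qual=60.0, depth=30, ref_count=0, alt_count=30, alt_fwd=15,
                    alt_rev=15, mq_mean=50.0, mq0_fraction=0.0)
    defaults.update(kw)
    return VariantRecord(chrom, pos, ref, alt, **defaults)


# ---------------------------------------------------------------------------
# dedup
# ---------------------------------------------------------------------------

class TestDedup:
    def test_ambiguous_mapping_dropped(self):
        alns = [
            _aln("q1", "c", 100, "50M", tags={"NM": 0}),
            _aln("q1", "c", 900, "50M", flag=0x1 | 0x100, tags={"NM": 0}),
        ]
        res = var.dedup_primary_unique(alns)
        assert res.alignments == []
        assert res.n_ambiguous == 1

    def test_unique_mapping_kept(self):
        alns = [
            _aln("q1", "c", 100, "50M", tags={"NM": 0}),
            _aln("q1", "c", 900, "50M", flag=0x1 | 0x100, tags={"NM": 2}),
        ]
        res = var.dedup_primary_unique(alns)
        assert len(res.alignments) == 1

    def test_no_secondary_kept(self):
        res = var.dedup_primary_unique([_aln("q1", "c", 100, "50M")])
        assert len(res.alignments) == 1

    def test_pcr_duplicates_collapse_to_one(self):
        dups = [
            _aln(f"q{i}", "c", 100, "50M", quals=[30 + (i % 3)] * 50, mate_pos=400)
            for i in range(100)
        ]
        res = var.dedup_primary_unique(dups)
        assert len(res.alignments) == 1
        assert res.n_duplicates == 99

    def test_missing_tags_counted(self):
        alns = [
            _aln("q1", "c", 100, "50M", tags={}),
            _aln("q1", "c", 900, "50M", flag=0x1 | 0x100, tags={}),
        ]
        res = var.dedup_primary_unique(alns)
        assert res.n_missing_tags == 1
        assert res.alignments == []


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

class TestPileup:
    REF = {"c": "AAAAAAAAAACCCCCCCCCCGGGGGGGGGGTTTTTTTTTT"}

    def test_matching_reads_give_empty_callset(self):
        alns = [_aln(f"q{i}", "c", 1, "40M", seq=self.REF["c"]) for i in range(10)]
        cs = var.pileup_genotype(alns, self.REF)
        assert len(cs) == 0

    def test_hom_snv_alt_fraction_one(self):
        mutant = self.REF["c"][:5] + "G" + self.REF["c"][6:]
        alns = [_aln(f"q{i}", "c", 1, "40M", seq=mutant) for i in range(30)]
        cs = var.pileup_genotype(alns, self.REF)
        (v,) = cs.variants
        assert (v.pos, v.ref, v.alt) == (6, "A", "G")
        assert v.alt_fraction == 1.0
        assert v.depth == 30

    def test_het_snv_allele_depths(self):
        mutant = self.REF["c"][:5] + "G" + self.REF["c"][6:]
        alns = [
            _aln(f"q{i}", "c", 1, "40M", seq=mutant if i % 2 else self.REF["c"])
            for i in range(30)
        ]
        (v,) = var.pileup_genotype(alns, self.REF).variants
        assert (v.ref_count, v.alt_count) == (15, 15)

    def test_insertion_anchored_base_convention(self):
        # read inserts "TT" after reference position 10 (1-based)
        seq = self.REF["c"][:10] + "TT" + self.REF["c"][10:20]
        alns = [_aln(f"q{i}", "c", 1, "10M2I10M", seq=seq) for i in range(5)]
        vs = var.pileup_genotype(alns, self.REF).variants
        assert [(v.pos, v.ref, v.alt, v.vtype) for v in vs] == [(10, "A", "ATT", "INS")]

    def test_deletion_anchored_base_convention(self):
        seq = self.REF["c"][:10] + self.REF["c"][13:23]
        alns = [_aln(f"q{i}", "c", 1, "10M3D10M", seq=seq) for i in range(5)]
        vs = var.pileup_genotype(alns, self.REF).variants
        assert [(v.pos, v.ref, v.alt, v.vtype) for v in vs] == [(10, "ACCC", "A", "DEL")]

    def test_low_quality_bases_excluded_from_alleles(self):
        mutant = self.REF["c"][:5] + "G" + self.REF["c"][6:]
        alns = [
            _aln(f"q{i}", "c", 1, "40M", seq=mutant, quals=[10] * 40) for i in range(10)
        ]
        assert len(var.pileup_genotype(alns, self.REF, min_bq=20)) == 0

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            var.pileup_genotype([_aln("q", "zz", 1, "10M", seq="A" * 10)], self.REF)

    def test_planted_variants_recovered_from_simulation(self, small_genome):
        mutated, truth = sim.plant_variants(small_genome, 1000, titv_ratio=1.4, seed=42)
        hap = sim.identity_haplotype("h", mutated)
        refs = {c: len(s) for c, s in small_genome.items()}
        reads = sim.simulate_genomic_pairs(
            [hap, hap], refs, sim.ReadSimConfig(depth=30, seed=43), emit_fastq=False
        )
        cs = var.pileup_genotype(reads.alignments, small_genome)
        truth_keys = {v.key for v in truth}
        called_keys = {v.key for v in cs.variants}
        assert truth_keys == called_keys


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

class TestFilterCascade:
    def test_snv_cluster_removed(self):
        cs = var.CallSet("s", [_v(100), _v(104, ref="C", alt="T"), _v(108)])
        res = var.filter_callset(cs, var.FilterProfile.transcriptomic())
        assert len(res.callset) == 0
        assert {r for _, r in res.rejected} == {"snv_cluster"}

    def test_snv_near_indel_removed(self):
        cs = var.CallSet("s", [_v(105), _v(100, ref="AT", alt="A")])
        res = var.filter_callset(cs, var.FilterProfile.transcriptomic())
        rules = {v.key: r for v, r in res.rejected}
        assert rules[("c", 105, "A", "G")] == "snv_near_indel"

    def test_indel_pair_both_removed(self):
        cs = var.CallSet("s", [_v(100, ref="AT", alt="A"), _v(180, ref="G", alt="GA")])
        res = var.filter_callset(cs, var.FilterProfile.transcriptomic())
        assert {r for _, r in res.rejected} == {"indel_pair"}
        assert len(res.callset) == 0

    def test_strand_rule_genomic(self):
        cs = var.CallSet("s", [_v(100, alt_fwd=3, alt_rev=0, alt_count=3, ref_count=27)])
        res = var.filter_callset(cs, var.FilterProfile.genomic())
        assert [r for _, r in res.rejected] == ["reads_per_strand"]

    def test_coverage_window_genomic(self):
        cs = var.CallSet("s", [_v(100, depth=3, alt_count=3), _v(200, depth=40, alt_count=40)])
        res = var.filter_callset(cs, var.FilterProfile.genomic(max_cov=38))
        assert sorted(r for _, r in res.rejected) == ["max_cov", "min_cov"]

    def test_mq0_fraction_ceiling_and_literal_flag(self):
        noisy = _v(100, mq0_fraction=0.25)
        cs = var.CallSet("s", [noisy])
        assert var.filter_callset(cs, var.FilterProfile.genomic()).rejected[0][1] == "max_mq0f"
        literal = var.FilterProfile.transcriptomic()
        literal.literal_mq0f_minimum = True
        clean = var.CallSet("s", [_v(100, mq0_fraction=0.0)])
        assert var.filter_callset(clean, literal).rejected[0][1] == "mq0f_literal_minimum"

    def test_alt_fraction_rule_transcriptomic(self):
        cs = var.CallSet("s", [_v(100, ref_count=10, alt_count=20, alt_fwd=10, alt_rev=10)])
        res = var.filter_callset(cs, var.FilterProfile.transcriptomic())
        assert [r for _, r in res.rejected] == ["alt_fraction"]

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            var.FilterProfile.preset("exotic")

    def test_idempotence(self):
        rng = random.Random(2)
        vs = []
        taken = set()
        for _ in range(300):
            p = rng.randrange(1, 100_000)
            if p in taken:
                continue
            taken.add(p)
            if rng.random() < 0.2:
                vs.append(_v(p, ref="AT", alt="A"))
            else:
                vs.append(_v(p))
        cs = var.CallSet("s", vs)
        prof = var.FilterProfile.transcriptomic()
        once = var.filter_callset(cs, prof).callset
        twice = var.filter_callset(once, prof).callset
        assert [v.key for v in once.variants] == [v.key for v in twice.variants]

    def test_positional_rules_match_bruteforce(self):
        """Neighborhood rules vs an O(n^2) scan on random layouts."""
        rng = random.Random(7)
        prof = var.FilterProfile.transcriptomic()
        for _ in range(200):
            positions = sorted(rng.sample(range(1, 3000), rng.randint(2, 40)))
            vs = [
                _v(p, ref="AT", alt="A") if rng.random() < 0.3 else _v(p)
                for p in positions
            ]
            cs = var.CallSet("s", vs)
            res = var.filter_callset(cs, prof)
            got = {v.key for v, r in res.rejected
                   if r in ("snv_near_indel", "indel_pair", "snv_cluster")}
            expect = set()
            snvs = [v for v in vs if v.vtype == "SNV"]
            indels = [v for v in vs if v.vtype != "SNV"]
            for s in snvs:
                if any(abs(s.pos - i.pos) <= 10 for i in indels):
                    expect.add(s.key)
            for a in indels:
                if any(0 < abs(a.pos - b.pos) <= 100 for b in indels):
                    expect.add(a.key)
            spos = sorted(v.pos for v in snvs)
            for i in range(len(spos)):
                for j in range(i + 2, len(spos)):
                    if spos[j] - spos[i] + 1 <= 10 and j - i == 2:
                        for v in snvs:
                            if spos[i] <= v.pos <= spos[j]:
                                expect.add(v.key)
            assert got == expect


# ---------------------------------------------------------------------------
# set arithmetic
# ---------------------------------------------------------------------------

class TestSetOps:
    def test_selfmap_subtraction_identity_and_positional(self):
        cs = var.CallSet("s", [_v(100), _v(200, ref="C", alt="T")])
        assert len(var.subtract_selfmap(cs, var.CallSet("n", []))) == 2
        # allele-agnostic: a different allele at the same position still removes
        selfmap = var.CallSet("n", [_v(200, ref="C", alt="A")])
        out = var.subtract_selfmap(cs, selfmap)
        assert [v.pos for v in out.variants] == [100]

    def test_consensus_errors_removed_planted_kept(self, small_genome):
        _, consensus = sim.plant_variants(small_genome, 300, seed=60)
        _, real = sim.plant_variants(small_genome, 300, seed=61)
        consensus_keys = {(v.chrom, v.pos) for v in consensus}
        real_only = [v for v in real if (v.chrom, v.pos) not in consensus_keys]
        merged = {v.key: v for v in consensus + real_only}
        cs = var.CallSet("s", list(merged.values()))
        out = var.subtract_selfmap(cs, var.CallSet("n", consensus))
        assert {v.key for v in out.variants} == {v.key for v in real_only}

    def test_identical_sets_have_no_unique_members(self):
        cs = var.CallSet("s", [_v(100), _v(200)])
        shared, ua, ub = var.set_partition(cs, var.CallSet("t", [_v(100), _v(200)]))
        assert len(shared) == 2 and not ua and not ub

    def test_partition_matches_bruteforce_and_conserves(self):
        rng = random.Random(9)
        pos_a = rng.sample(range(1, 50_000), 3000)
        pos_b = rng.sample(range(1, 50_000), 3000)
        a = var.CallSet("a", [_v(p) for p in pos_a])
        b = var.CallSet("b", [_v(p) for p in pos_b])
        shared, ua, ub = var.set_partition(a, b)
        sa, sb = set(pos_a), set(pos_b)
        assert {v.pos for v in shared} == sa & sb
        assert {v.pos for v in ua} == sa - sb
        assert {v.pos for v in ub} == sb - sa
        assert len(ua) + len(shared) == len(a)
        assert len(shared) + len(ua) + len(ub) == len(sa | sb)


class TestTiTv:
    def test_two_ti_one_tv(self):
        vs = [_v(1, "A", "G"), _v(2, "C", "T"), _v(3, "A", "C")]
        assert var.titv_ratio(vs) == 2.0

    def test_degenerate_cases(self):
        assert var.titv_ratio([_v(1, "A", "C")]) == 0.0
        assert var.titv_ratio([_v(1, "A", "G")]) is None


class TestDivergence:
    def test_published_worked_examples(self):
        assert var.snv_rate_per_mbp(65_140, 7_990_760) == 8_152
        assert var.snv_rate_per_mbp(556, 8_630_008) == 64
        assert var.snv_rate_per_mbp(0, 1_000_000) == 0

    def test_min_coverage_gates_numerator_and_denominator(self):
        depth = {"c": np.array([10] * 50 + [1] * 50)}
        cds = [Interval("c", 0, 100)]
        cs = var.CallSet("s", [_v(10), _v(80)])  # second lies below min_cov
        res = var.divergence_snv_per_mbp(cs, depth, cds, min_cov=4)
        assert res.covered_positions == 50
        assert res.snv_count == 1

    def test_zero_covered_positions_raises(self):
        with pytest.raises(ValueError):
            var.divergence_snv_per_mbp(
                var.CallSet("s", []), {"c": np.zeros(10)}, [Interval("c", 0, 10)]
            )


# ---------------------------------------------------------------------------
# impact
# ---------------------------------------------------------------------------

class TestImpact:
    def test_indel_rules(self, small_host):
        _, models, _ = small_host
        m = models[0]
        pos = m.cds[0].start + 4  # inside CDS, 1-based pos below
        frameshift = var.classify_impact(
            _v(pos + 1, ref="AT", alt="A", chrom=m.chrom), [m], {}
        )
        assert (frameshift.consequence, frameshift.impact) == ("frameshift", "HIGH")
        inframe = var.classify_impact(_v(pos + 1, ref="ATTT", alt="A", chrom=m.chrom), [m], {})
        assert (inframe.consequence, inframe.impact) == ("inframe_indel", "MODERATE")

    def test_splice_site_high(self, small_host, small_genome):
        _, models, _ = small_host
        m = next(mm for mm in models if mm.n_exons >= 2)
        intron = m.introns()[0]
        ref = small_genome[m.chrom][intron.start]
        alt = "A" if ref != "A" else "G"
        ann = var.classify_impact(
            _v(intron.start + 1, ref=ref, alt=alt, chrom=m.chrom), [m], small_genome
        )
        assert (ann.consequence, ann.impact) == ("splice_site", "HIGH")

    def test_intergenic_is_non_coding(self, small_host, small_genome):
        _, models, _ = small_host
        ann = var.classify_impact(
            _v(1, ref=small_genome["scf01"][0], alt="N", chrom="scf01"), models, small_genome
        )
        assert ann.impact == "MODIFIER"

    def test_matches_translate_and_compare_oracle(self, small_host, small_genome):
        """Codon-level classification vs whole-protein re-translation on
        random CDS SNVs."""
        _, models, _ = small_host
        rng = random.Random(77)
        n_checked = 0
        mismatches = []
        for _ in range(1000):
            m = rng.choice(models)
            cds_iv = rng.choice(m.cds)
            pos0 = rng.randrange(cds_iv.start, cds_iv.end)
            ref = small_genome[m.chrom][pos0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            ann = var.classify_impact(
                _v(pos0 + 1, ref=ref, alt=alt, chrom=m.chrom), [m], small_genome
            )
            # oracle: mutate the genome, retranslate the whole CDS
            chrom_seq = small_genome[m.chrom]
            mutated = {m.chrom: chrom_seq[:pos0] + alt + chrom_seq[pos0 + 1 :]}
            old_prot = str(Seq(m.cds_sequence(small_genome)).translate())
            new_prot = str(Seq(m.cds_sequence(mutated)).translate())
            if old_prot == new_prot:
                expect = "synonymous"
            else:
                (i, a, b) = next(
                    (i, a, b) for i, (a, b) in enumerate(zip(old_prot, new_prot)) if a != b
                )
                if i == 0 and m.has_start_codon:
                    expect = "start_lost"
                elif b == "*":
                    expect = "stop_gained"
                elif a == "*":
                    expect = "stop_lost"
                else:
                    expect = "missense"
            n_checked += 1
            if ann.consequence != expect:
                mismatches.append((m.transcript_id, pos0, ref, alt, ann.consequence, expect))
        assert not mismatches, mismatches[:5]
        assert n_checked == 1000
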