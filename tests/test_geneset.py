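"""Expression hints, gene-set filtering rules, summary metrics, compatible
HSP coverage and the tiered annotation cascade."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xenolocus import geneset as gs
from xenolocus.formats import AlignmentRecord, Interval, TranscriptModel, parse_cigar


def _aln(qname, refname, pos, cigar, flag=0x1):
    return AlignmentRecord(qname, flag, refname, pos, 60, parse_cigar(cigar))


def _model(gene="g1", tid="g1.t1", chrom="c", exons=((0, 200), (500, 600)),
           cds=None, strand="+", start=True, stop=True):
    ex = [Interval(chrom, s, e, strand) for s, e in exons]
    cd = [Interval(chrom, s, e, strand) for s, e in (cds if cds is not None else exons)]
    return TranscriptModel(gene, tid, strand, ex, cd, start, stop)


class TestHints:
    def test_coverage_clamped_to_ceiling(self):
        alns = [_aln(f"q{i}", "c", 1, "50M") for i in range(500)]
        hints = gs.build_hints(alns)
        (h,) = [h for h in hints if h.kind == "exonpart"]
        assert h.coverage == 300

    def test_floor_clip_vs_drop(self):
        alns = [_aln(f"q{i}", "c", 1, "50M") for i in range(5)]
        (h,) = gs.build_hints(alns)
        assert h.coverage == 20
        assert gs.build_hints(alns, floor_mode="drop") == []

    def test_intron_hint_spans_simulated_intron(self):
        # two-exon spliced reads: 30M 100N 30M starting at various offsets
        alns = [_aln(f"q{i}", "c", 11, "30M100N30M") for i in range(25)]
        hints = gs.build_hints(alns)
        intron_hints = [h for h in hints if h.kind == "intron"]
        assert len(intron_hints) == 1
        h = intron_hints[0]
        assert (h.interval.start, h.interval.end) == (40, 140)
        assert h.coverage == 25

    def test_priority_merge(self):
        a = gs.ExpressionHint("intron", Interval("c", 10, 50), 30, source_priority=1)
        b = gs.ExpressionHint("intron", Interval("c", 10, 50), 99, source_priority=2)
        merged = gs.merge_hint_sources([a], [b])
        assert merged == [b]


class TestFilterGeneSet:
    def _hint_for(self, m, fraction=1.0):
        e = m.exons[0]
        end = e.start + max(1, int(m.exonic_length * fraction))
        return gs.ExpressionHint("exonpart", Interval(e.chrom, e.start, min(end, e.end)), 50)

    def test_no_hint_coverage_drops_model(self):
        m = _model()
        ledger = gs.filter_gene_set([m], [], [])
        assert not ledger.retained
        assert ledger.rejected[0][1] == ["hint_support"]

    def test_te_overlap_boundary_10_vs_11(self):
        m = _model()
        hints = [self._hint_for(m)]
        kept = gs.filter_gene_set([m], hints, [Interval("c", 0, 10)])
        assert kept.retained
        dropped = gs.filter_gene_set([m], hints, [Interval("c", 0, 11)])
        assert dropped.rejected[0][1] == ["te_overlap"]

    def test_short_peptide_dropped(self):
        m = _model(exons=((0, 30),), cds=((0, 30),))  # 9 aa after stop removal
        hints = [self._hint_for(m)]
        ledger = gs.filter_gene_set([m], hints, [])
        assert ledger.rejected[0][1] == ["short_peptide"]
        kept = gs.filter_gene_set([m], hints, [], min_peptide_aa=9)
        assert kept.retained

    def test_planted_failures_recovered_exactly(self):
        """A scaled-down raw prediction set with planted failure modes: the
        rejection ledger reproduces the planted counts rule by rule."""
        rng = random.Random(4)
        models, hints, repeats = [], [], []
        planted = {"hint_support": 0, "te_overlap": 0, "short_peptide": 0, "ok": 0}
        cursor = 0
        for i in range(200):
            gid = f"g{i}"
            exlen = rng.choice([150, 300, 600])
            m = _model(gid, f"{gid}.t1", exons=((cursor, cursor + exlen),))
            fate = rng.choice(["ok", "ok", "hint_support", "te_overlap", "short_peptide"])
            if fate == "short_peptide":
                m = _model(gid, f"{gid}.t1", exons=((cursor, cursor + 30),))
                hints.append(self._hint_for(m))
            elif fate == "hint_support":
                pass  # no hints emitted for this model
            elif fate == "te_overlap":
                hints.append(self._hint_for(m))
                repeats.append(Interval("c", cursor, cursor + 20))
            else:
                hints.append(self._hint_for(m))
            planted[fate] += 1
            models.append(m)
            cursor += exlen + 200
        ledger = gs.filter_gene_set(models, hints, repeats)
        assert len(ledger.retained) == planted["ok"]
        counts = ledger.rule_counts()
        assert counts.get("hint_support", 0) == planted["hint_support"]
        assert counts.get("te_overlap", 0) == planted["te_overlap"]
        assert counts.get("short_peptide", 0) == planted["short_peptide"]
        assert len(ledger.retained) + len(ledger.rejected) == len(models)

    def test_one_percent_boundary(self):
        m = _model(exons=((0, 1000),), cds=((0, 999),))
        just_enough = [gs.ExpressionHint("exonpart", Interval("c", 0, 10), 50)]
        assert gs.filter_gene_set([m], just_enough, []).retained
        too_little = [gs.ExpressionHint("exonpart", Interval("c", 0, 9), 50)]
        assert not gs.filter_gene_set([m], too_little, []).retained


class TestMetrics:
    def test_two_exon_arithmetic(self):
        m = _model(exons=((0, 200), (500, 600)), cds=((0, 200), (500, 600)))
        met = gs.geneset_metrics([m], proteins={"g1.t1": "M" * 99})
        assert met.avg_transcript_length_nt == 300
        assert met.avg_exons_per_transcript == 2
        assert met.avg_intron_length_nt == 300
        assert met.avg_gene_length_nt == 600
        assert met.n_with_start_and_stop == 1
        assert met.avg_protein_length_aa == 99

    def test_single_exon_transcript_contributes_no_intron(self):
        a = _model("g1", "t1", exons=((0, 300),))
        b = _model("g2", "t2", exons=((1000, 1200), (1500, 1700)))
        met = gs.geneset_metrics([a, b])
        assert met.n_single_exon_transcripts == 1
        assert met.avg_intron_length_nt == 300

    def test_multi_isoform_counting(self):
        a = _model("g1", "t1")
        b = _model("g1", "t2", exons=((0, 200),))
        c = _model("g2", "t3")
        met = gs.geneset_metrics([a, b, c])
        assert (met.n_genes, met.n_transcripts, met.n_multi_isoform_genes) == (2, 3, 1)

    def test_simulator_set_matches_closed_form(self, small_host):
        _, models, _ = small_host
        met = gs.geneset_metrics(models)
        assert met.n_transcripts == len(models)
        assert met.avg_exons_per_transcript == pytest.approx(
            sum(m.n_exons for m in models) / len(models)
        )
        introns = [len(i) for m in models for i in m.introns()]
        assert met.avg_intron_length_nt == pytest.approx(sum(introns) / len(introns))

    def test_combination_is_size_weighted(self, small_host):
        _, models, _ = small_host
        half = len(models) // 2
        a, b = models[:half], models[half:]
        ma, mb, mall = (gs.geneset_metrics(x) for x in (a, b, models))
        weighted = (ma.avg_transcript_length_nt * len(a) + mb.avg_transcript_length_nt * len(b)) / len(models)
        assert mall.avg_transcript_length_nt == pytest.approx(weighted)


def _brute_force_mchsp(hsps, qlen):
    best = 0
    for r in range(len(hsps) + 1):
        for combo in itertools.combinations(hsps, r):
            ivs = sorted(combo)
            if any(b[0] < a[1] for a, b in zip(ivs, ivs[1:])):
                continue
            best = max(best, sum(e - s for s, e in ivs))
    return best / qlen


class TestAlignedFraction:
    def test_single_hsp(self):
        assert gs.aligned_fraction_mchsp([(0, 70)], 100) == 0.70

    def test_overlapping_pair_takes_best_single(self):
        assert gs.aligned_fraction_mchsp([(0, 60), (50, 100)], 100) == 0.60

    def test_empty_and_bounds(self):
        assert gs.aligned_fraction_mchsp([], 50) == 0.0
        with pytest.raises(ValueError):
            gs.aligned_fraction_mchsp([(0, 60)], 50)

    @given(
        st.integers(50, 200),
        st.lists(st.tuples(st.integers(0, 180), st.integers(1, 60)), min_size=1, max_size=8),
    )
    @settings(deadline=None, max_examples=150)
    def test_matches_exhaustive_subsets(self, qlen, raw):
        hsps = [(s % qlen, min(s % qlen + ln, qlen)) for s, ln in raw]
        hsps = [(s, e) for s, e in hsps if e > s]
        if not hsps:
            return
        assert gs.aligned_fraction_mchsp(hsps, qlen) == pytest.approx(
            _brute_force_mchsp(hsps, qlen)
        )


class TestAnnotateCascade:
    def _hit(self, q, tier_desc="ribosomal protein L3", ev=1e-50, ident=95.0,
             aln=200, hsps=((0, 200),), qlen_hint=None):
        return gs.HomologyHit(q, "subj", ev, ident, aln, [tuple(h) for h in hsps],
                              subject_description=tier_desc)

    def test_tier1_pass_short_circuits(self):
        qlens = {"q1": 250}
        t1 = [self._hit("q1")]
        t2 = [self._hit("q1", "other protein")]
        ann, un = gs.annotate_cascade(qlens, [t1, t2])
        assert ann["q1"].tier == 1 and un == []

    def test_blacklisted_descriptor_falls_through(self):
        qlens = {"q1": 250}
        t1 = [self._hit("q1", "hypothetical protein")]
        t2 = [self._hit("q1", "kinase")]
        ann, _ = gs.annotate_cascade(qlens, [t1, t2])
        assert ann["q1"].tier == 2

    def test_thresholds_enforced(self):
        qlens = {"q1": 250, "q2": 250, "q3": 250}
        table = [
            self._hit("q1", ev=1e-5),          # fails E-value
            self._hit("q2", aln=50),           # fails alignment length
            self._hit("q3", ident=80.0),       # fails identity
        ]
        ann, un = gs.annotate_cascade(qlens, [table])
        assert ann == {} and un == ["q1", "q2", "q3"]

    def test_aligned_fraction_comparator_presets(self):
        qlens = {"q1": 200}
        full = [self._hit("q1", hsps=[(0, 200)])]
        literal = gs.AnnotationThresholds()  # <= 0.90 rejects full-length
        ann, _ = gs.annotate_cascade(qlens, [full], literal)
        assert ann == {}
        alt = gs.AnnotationThresholds(aligned_fraction_cmp="ge", aligned_fraction_value=0.70)
        ann2, _ = gs.annotate_cascade(qlens, [full], alt)
        assert "q1" in ann2

    def test_planted_tier_matrix(self):
        """A 4-tier fixture with a planned pass matrix: per-tier annotation
        counts match the plan and coverage is monotone in tiers."""
        rng = random.Random(6)
        qlens = {f"q{i}": 300 for i in range(60)}
        plan = {q: rng.choice([1, 2, 3, 4, None]) for q in qlens}
        tiers = [[], [], [], []]
        for q, t in plan.items():
            if t is None:
                continue
            for earlier in range(t - 1):
                tiers[earlier].append(self._hit(q, "uncharacterized protein"))
            tiers[t - 1].append(self._hit(q, "annotated enzyme", hsps=[(0, 200)]))
        ann, un = gs.annotate_cascade(qlens, tiers)
        for q, t in plan.items():
            if t is None:
                assert q in un
            else:
                assert ann[q].tier == t
        # monotone: adding a tier never un-annotates
        ann3, _ = gs.annotate_cascade(qlens, tiers[:3])
        assert set(ann3) <= set(ann)

    def test_empty_tier_list_rejected(self):
        with pytest.raises(ValueError):
            gs.annotate_cascade({"q": 10}, [])
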