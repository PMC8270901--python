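import numpy as np
import pytest

from fulquant.alnfilter import JunctionChain
from fulquant.isoformbuild import (TranscriptModel, apply_locus_rules,
                                   build_loci, collapse_reads,
                                   compute_boundaries, deseq2_export,
                                   detect_genomic_polya,
                                   final_annotation_filter,
                                   filter_transcripts, quantify)
from fulquant.novelty import ReferenceAnnotation


def _chain(introns, strand="+", read_id="r", start=None, end=None,
           full_length=True, sample="s1"):
    introns = tuple(tuple(i) for i in introns)
    if start is None:
        start = introns[0][0] - 100
    if end is None:
        end = introns[-1][1] + 100
    return JunctionChain(read_id, "chr1", strand, introns, start, end,
                        full_length, sample)


def _transcript(introns, strand="+", count=10, fl=1.0, tid="T1", locus="G1",
                start=None, end=None):
    introns = tuple(tuple(i) for i in introns)
    if start is None:
        start = introns[0][0] - 100
    if end is None:
        end = introns[-1][1] + 100
    return TranscriptModel(tid, "chr1", strand, introns, start, end,
                           count, fl, locus_id=locus)


PLAIN = {"chr1": "C" * 100000}  # no polyA tracts, no motifs


class TestCollapse:
    def test_identical_chains_merge(self):
        drafts = collapse_reads([_chain([(200, 300)], read_id=f"r{i}")
                                 for i in range(3)])
        assert len(drafts) == 1 and drafts[0].read_count == 3

    def test_differing_intron_separates(self):
        drafts = collapse_reads([_chain([(200, 300)]),
                                 _chain([(200, 310)])])
        assert len(drafts) == 2

    def test_opposite_strand_separates(self):
        drafts = collapse_reads([_chain([(200, 300)]),
                                 _chain([(200, 300)], strand="-")])
        assert len(drafts) == 2

    def test_full_length_fraction(self):
        drafts = collapse_reads(
            [_chain([(200, 300)], read_id="a", full_length=True),
             _chain([(200, 300)], read_id="b", full_length=False)])
        assert drafts[0].full_length_fraction == 0.5


class TestBoundaries:
    def test_odd_count_median(self):
        members = [_chain([(200, 300)], start=s, end=400)
                   for s in (100, 102, 104)]
        t = _transcript([(200, 300)])
        assert compute_boundaries(t, members)[0] == 102

    def test_even_count_lower_middle(self):
        members = [_chain([(200, 300)], start=s, end=400)
                   for s in (100, 102)]
        t = _transcript([(200, 300)])
        assert compute_boundaries(t, members)[0] == 100

    def test_single_member_uses_own_ends(self):
        members = [_chain([(200, 300)], start=150, end=390)]
        t = _transcript([(200, 300)])
        assert compute_boundaries(t, members) == (150, 390)

    def test_terminal_exons_keep_one_base(self):
        members = [_chain([(200, 300)], start=200, end=300)]
        t = _transcript([(200, 300)])
        start, end = compute_boundaries(t, members)
        assert start < 200 and end > 300


class TestGenomicPolyA:
    def _genome(self, run_at, run_len=12, base="A"):
        seq = list("C" * 2000)
        seq[run_at:run_at + run_len] = base * run_len
        return {"chr1": "".join(seq)}

    def test_run_downstream_of_tes_detected(self):
        t = _transcript([(200, 300)], end=1000)
        assert detect_genomic_polya(self._genome(1002), t)

    def test_no_run_near_tes(self):
        t = _transcript([(200, 300)], end=1000)
        assert not detect_genomic_polya(PLAIN, t)

    def test_short_run_ignored(self):
        t = _transcript([(200, 300)], end=1000)
        assert not detect_genomic_polya(self._genome(1002, run_len=8), t)

    def test_run_beyond_distance_ignored(self):
        t = _transcript([(200, 300)], end=1000)
        assert not detect_genomic_polya(self._genome(1012), t)

    def test_minus_strand_t_run(self):
        # '-' strand TES is the genomic left end; tail is a T tract
        seq = list("C" * 2000)
        seq[489:501] = "T" * 12
        t = _transcript([(600, 700)], strand="-", start=500, end=800)
        assert detect_genomic_polya({"chr1": "".join(seq)}, t)

    def test_tes_outside_chromosome_errors(self):
        t = _transcript([(200, 300)], end=99999999)
        with pytest.raises(ValueError):
            detect_genomic_polya(PLAIN, t)


class TestTranscriptFilters:
    def _draft(self, count=10, fl=0.8, strand="+"):
        t = _transcript([(200, 300)], strand=strand, count=count, fl=fl)
        return t

    @pytest.mark.parametrize("count,passed", [(3, False), (4, True)])
    def test_read_count_strictly_greater_than_three(self, count, passed):
        t = filter_transcripts([self._draft(count=count)], PLAIN)[0]
        assert (t.status == "passed") is passed
        if not passed:
            assert t.status == "filtered:read_count"

    @pytest.mark.parametrize("fl,passed", [(0.40, False), (0.41, True)])
    def test_full_length_strictly_greater_than_forty_percent(self, fl, passed):
        t = filter_transcripts([self._draft(fl=fl)], PLAIN)[0]
        assert (t.status == "passed") is passed

    def test_unknown_strand_filtered(self):
        t = filter_transcripts([self._draft(strand="unknown")], PLAIN)[0]
        assert t.status == "filtered:no_strand"

    def test_statuses_stable_under_input_order(self):
        drafts1 = [self._draft(count=c, fl=f)
                   for c, f in [(3, 0.8), (10, 0.2), (10, 0.9)]]
        drafts2 = list(reversed(
            [self._draft(count=c, fl=f)
             for c, f in [(3, 0.8), (10, 0.2), (10, 0.9)]]))
        s1 = {(t.read_count, t.full_length_fraction): t.status
              for t in filter_transcripts(drafts1, PLAIN)}
        s2 = {(t.read_count, t.full_length_fraction): t.status
              for t in filter_transcripts(drafts2, PLAIN)}
        assert s1 == s2


class TestLoci:
    def test_overlapping_same_strand_one_locus(self):
        a = _transcript([(200, 300)], tid="A")
        b = _transcript([(250, 350)], tid="B")
        a.status = b.status = "passed"
        loci = build_loci([a, b])
        assert len(loci) == 1 and a.locus_id == b.locus_id

    def test_opposite_strand_two_loci(self):
        a = _transcript([(200, 300)], tid="A")
        b = _transcript([(200, 300)], strand="-", tid="B")
        assert len(build_loci([a, b])) == 2

    def test_disjoint_two_loci(self):
        a = _transcript([(200, 300)], tid="A")
        b = _transcript([(5200, 5300)], tid="B")
        assert len(build_loci([a, b])) == 2

    def test_intron_only_overlap_is_not_exonic(self):
        # B sits entirely inside A's intron: no exon overlap, two loci
        a = _transcript([(200, 900)], tid="A")
        b = _transcript([(300, 400)], start=250, end=450, tid="B")
        assert len(build_loci([a, b])) == 2


class TestLocusRules:
    def _locus(self, specs):
        """specs: list of (tid, count, introns, start)."""
        ts = []
        for tid, count, introns, start in specs:
            t = _transcript(introns, count=count, tid=tid, start=start)
            ts.append(t)
        loci = build_loci(ts)
        return loci, ts

    def test_three_percent_at_equality_filtered(self):
        loci, ts = self._locus([
            ("A", 100, [(200, 300), (400, 500)], 100),
            ("B", 3, [(200, 300), (400, 520)], 100),
        ])
        apply_locus_rules(loci, ts, PLAIN, misalignment_check=False)
        assert ts[1].status == "filtered:locus_fraction"
        assert ts[0].status == "passed"

    def test_just_above_three_percent_kept(self):
        loci, ts = self._locus([
            ("A", 100, [(200, 300), (400, 500)], 100),
            ("B", 4, [(200, 300), (400, 520)], 100),
        ])
        apply_locus_rules(loci, ts, PLAIN, misalignment_check=False)
        assert ts[1].status == "passed"

    @pytest.mark.parametrize("count,status", [
        (25, "filtered:truncation"), (26, "passed")])
    def test_truncation_rescue_at_25_percent(self, count, status):
        # B's chain is the 5' -truncated tail of A's; A has count 100
        loci, ts = self._locus([
            ("A", 100, [(200, 300), (400, 500), (600, 700)], 100),
            ("B", count, [(400, 500), (600, 700)], 320),
        ])
        apply_locus_rules(loci, ts, PLAIN, misalignment_check=False)
        assert ts[1].status == status

    def test_truncation_on_minus_strand_uses_genomic_prefix(self):
        a = _transcript([(200, 300), (400, 500), (600, 700)], strand="-",
                        count=100, tid="A", start=100)
        b = _transcript([(200, 300), (400, 500)], strand="-", count=10,
                        tid="B", start=120, end=580)
        loci = build_loci([a, b])
        apply_locus_rules(loci, [a, b], PLAIN, misalignment_check=False)
        assert b.status == "filtered:truncation"

    def test_misalignment_all_private_noncanonical(self):
        # B has one private junction with a non-canonical motif
        seq = list("C" * 100000)
        for s, e in [(200, 300), (400, 500)]:
            seq[s:s + 2] = "GT"
            seq[e - 2:e] = "AG"
        genome = {"chr1": "".join(seq)}
        loci, ts = self._locus([
            ("A", 100, [(200, 300), (400, 500)], 100),
            ("B", 50, [(200, 300), (420, 520)], 100),
        ])
        apply_locus_rules(loci, ts, genome)
        assert ts[1].status == "filtered:misalignment"
        assert ts[0].status == "passed"


class TestFinalAnnotationFilter:
    def _reference(self):
        ref_t = _transcript([(200, 300), (400, 500), (600, 700)], tid="R1")
        return ReferenceAnnotation.from_transcripts([ref_t])

    def test_filtered_known_chain_rescued(self):
        t = _transcript([(200, 300), (400, 500), (600, 700)])
        t.status = "filtered:read_count"
        final = final_annotation_filter([t], self._reference())
        assert t.status == "rescued" and final == [t]

    def test_novel_two_exon_removed(self):
        t = _transcript([(200, 330)])
        final = final_annotation_filter([t], self._reference())
        assert final == [] and t.status == "filtered:two_exon"

    def test_novel_truncation_of_known_removed(self):
        t = _transcript([(400, 500), (600, 700)], start=320)
        final = final_annotation_filter([t], self._reference())
        assert final == [] and t.status == "filtered:known_truncation"

    def test_novel_three_exon_non_subchain_kept(self):
        t = _transcript([(200, 330), (400, 500)])
        final = final_annotation_filter([t], self._reference())
        assert final == [t]


class TestQuantify:
    def test_counts_and_conservation(self):
        t1 = _transcript([(200, 300)], tid="T1", locus="G1")
        t2 = _transcript([(200, 310)], tid="T2", locus="G1")
        chains = ([_chain([(200, 300)], read_id=f"a{i}") for i in range(5)]
                  + [_chain([(200, 310)], read_id=f"b{i}") for i in range(2)]
                  + [_chain([(200, 320)], read_id="c0")])
        counts, gene_counts, unassigned = quantify([t1, t2], {"s1": chains})
        assert counts.loc["T1", "s1"] == 5
        assert counts.loc["T2", "s1"] == 2
        assert gene_counts.loc["G1", "s1"] == 7
        assert int(unassigned["s1"]) == 1
        assert counts["s1"].sum() + unassigned["s1"] == len(chains)

    def test_empty_sample_all_zero(self):
        t1 = _transcript([(200, 300)], tid="T1")
        counts, _, unassigned = quantify([t1], {"s1": []})
        assert counts["s1"].sum() == 0 and unassigned["s1"] == 0

    def test_deseq2_prefilter_strictly_greater_than_ten(self):
        t1 = _transcript([(200, 300)], tid="T1")
        t2 = _transcript([(200, 310)], tid="T2")
        counts, _, _ = quantify(
            [t1, t2],
            {"s1": [_chain([(200, 300)], read_id=f"r{i}") for i in range(10)],
             "s2": [_chain([(200, 310)], read_id=f"q{i}") for i in range(11)]})
        out = deseq2_export(counts)
        assert not out.loc["T1", "pass_prefilter"]  # total 10 is not > 10
        assert out.loc["T2", "pass_prefilter"]
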