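import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fulquant.alnfilter import JunctionChain
from fulquant.isoformbuild import TranscriptModel
from fulquant.novelty import ReferenceAnnotation
from fulquant.stats import (NMDCall, bh_adjust, classify_adjacency,
                            compute_psi, define_constitutive_exons,
                            exon_pair_counts, fisher_exact_2x2, predict_nmd,
                            psi_counts)
from fulquant.stats import test_exon_pairs as run_exon_pair_tests
from fulquant.stats import test_isoform_usage as run_isoform_usage_test

from oracles import bh_stepup, fisher_two_sided


def _transcript(introns, strand="+", tid="T1", start=None, end=None):
    introns = tuple(tuple(i) for i in introns)
    if start is None:
        start = introns[0][0] - 50
    if end is None:
        end = introns[-1][1] + 50
    return TranscriptModel(tid, "chr1", strand, introns, start, end, 10, 1.0)


def _chain(introns, read_id="r", start=None, end=None):
    introns = tuple(tuple(i) for i in introns)
    if start is None:
        start = introns[0][0] - 50
    if end is None:
        end = introns[-1][1] + 50
    return JunctionChain(read_id, "chr1", "+", introns, start, end, True, "s")


class TestConstitutiveExons:
    def test_partition(self):
        # exon (300,400) in all three isoforms; (500,600) only in two
        ts = [
            _transcript([(100, 300), (400, 500), (600, 700)], tid="a"),
            _transcript([(100, 300), (400, 500), (600, 700)], tid="b"),
            _transcript([(100, 300), (400, 700)], tid="c"),
        ]
        constitutive, alternative = define_constitutive_exons(ts)
        assert constitutive == [(300, 400)]
        assert alternative == [(500, 600)]

    def test_single_isoform_no_testable_pairs(self):
        ts = [_transcript([(100, 300), (400, 500)])]
        constitutive, alternative = define_constitutive_exons(ts)
        assert alternative == []

    def test_no_transcripts_rejected(self):
        with pytest.raises(ValueError):
            define_constitutive_exons([])


class TestExonPairCounts:
    def test_presence_absence_cells(self):
        a, b = (200, 300), (500, 600)
        reads = (
            [_chain([(100, 200), (300, 500), (600, 700)], read_id=f"b{i}")
             for i in range(10)]  # both exons
            + [_chain([(100, 700)], read_id=f"n{i}", start=50, end=750)
               for i in range(10)]  # neither exon present, span covers both
        )
        tab = exon_pair_counts("g", a, b, reads)
        assert (tab.n_both, tab.n_a_only, tab.n_b_only, tab.n_neither) \
            == (10, 0, 0, 10)

    def test_uninformative_span_excluded(self):
        a, b = (200, 300), (500, 600)
        # read covers only exon A's locus: not informative for the pair
        short = _chain([(100, 200), (300, 350)], start=80, end=380)
        tab = exon_pair_counts("g", a, b, [short])
        assert (tab.n_both, tab.n_a_only, tab.n_b_only, tab.n_neither) \
            == (0, 0, 0, 0)


class TestFisherExact:
    def test_worked_value(self):
        p, direction = fisher_exact_2x2((10, 0, 0, 10))
        assert p == pytest.approx(2 / 184756, rel=1e-9)
        assert direction == "inclusive"

    def test_symmetry_exclusive(self):
        p, direction = fisher_exact_2x2((0, 10, 10, 0))
        assert p == pytest.approx(2 / 184756, rel=1e-9)
        assert direction == "exclusive"

    def test_balanced_table(self):
        p, direction = fisher_exact_2x2((5, 5, 5, 5))
        assert p == pytest.approx(1.0)
        assert direction == "undefined"

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2((0, 0, 5, 5))

    def test_matches_enumeration_oracle_sample(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = tuple(int(x) for x in rng.integers(0, 13, size=4))
            r1, c1 = t[0] + t[1], t[0] + t[2]
            n = sum(t)
            if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
                continue
            p, _ = fisher_exact_2x2(t)
            assert p == pytest.approx(fisher_two_sided(*t), abs=1e-9)


class TestBHAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.04, 0.03]) == pytest.approx(
            [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == [0.2]

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.05] * 5) == pytest.approx([0.05] * 5)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        adj = np.array(bh_adjust(p))
        assert np.all(adj <= 1.0) and np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 30))).tolist()
            assert bh_adjust(p) == pytest.approx(bh_stepup(p), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        p = rng.random(40)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(expected.tolist())


class TestAdjacency:
    def test_constitutive_between_makes_distal(self):
        assert classify_adjacency((100, 200), (500, 600),
                                  [(300, 400)]) == "distal"

    def test_neighbouring_alternative_adjacent(self):
        assert classify_adjacency((100, 200), (500, 600), []) == "adjacent"

    def test_constitutive_outside_pair_ignored(self):
        assert classify_adjacency((300, 400), (500, 600),
                                  [(100, 200)]) == "adjacent"


def _nmd_case(distance):
    """Genome/transcript where the first stop ends ``distance`` nt upstream
    of the last junction (transcript coordinates)."""
    exons = [(0, 100), (200, 300), (400, 500)]
    # transcript length 300; last junction boundary at transcript coord 200
    stop_last = 199 - distance
    s = stop_last - 2
    a = s % 3  # in-frame start strictly before the stop
    sense = ["C"] * 300
    sense[a:a + 3] = "ATG"
    sense[s:s + 3] = "TAA"
    genome_seq = (
        "".join(sense[0:100]) + "G" * 100 + "".join(sense[100:200])
        + "G" * 100 + "".join(sense[200:300]))
    t = _transcript([(100, 200), (300, 400)], start=0, end=500)
    ref = ReferenceAnnotation()
    ref.start_codons["REF1"] = ("chr1", "+", a, a + 3)
    return t, ref, {"chr1": genome_seq}


class TestPredictNMD:
    @pytest.mark.parametrize("distance,is_nmd", [(56, True), (55, False)])
    def test_55nt_rule_boundary(self, distance, is_nmd):
        t, ref, genome = _nmd_case(distance)
        call = predict_nmd(t, ref, genome)
        assert call.stop_to_last_junction_distance == distance
        assert call.is_nmd is is_nmd

    def test_stop_in_last_exon_not_nmd(self):
        t, ref, genome = _nmd_case(-40)
        call = predict_nmd(t, ref, genome)
        assert not call.is_nmd

    def test_no_contained_start_codon_no_call(self):
        t, ref, genome = _nmd_case(56)
        ref.start_codons = {"REF1": ("chr1", "+", 150, 153)}  # intronic
        call = predict_nmd(t, ref, genome)
        assert not call.is_nmd and call.no_call_reason

    def test_annotation_mismatch_no_call(self):
        t, ref, genome = _nmd_case(56)
        genome = {"chr1": "C" * 700}  # no ATG at the claimed position
        call = predict_nmd(t, ref, genome)
        assert call.no_call_reason == "annotation_mismatch"

    def test_pure_function(self):
        t, ref, genome = _nmd_case(70)
        assert predict_nmd(t, ref, genome) == predict_nmd(t, ref, genome)


class TestPSI:
    @pytest.mark.parametrize("inc,exc,expected", [
        (8, 2, 0.8), (0, 5, 0.0), (0, 0, None)])
    def test_ratio(self, inc, exc, expected):
        assert compute_psi(inc, exc) == expected

    def test_counting_rule(self):
        exon, up, down = (300, 400), (100, 200), (500, 600)
        reads = (
            [_chain([(200, 300), (400, 500)], read_id=f"i{i}",
                    start=50, end=650) for i in range(8)]
            + [_chain([(80, 100), (200, 500), (600, 620)], read_id=f"e{i}",
                      start=50, end=650) for i in range(2)])
        inc, exc = psi_counts(exon, up, down, reads)
        assert (inc, exc) == (8, 2)
        assert compute_psi(inc, exc) == pytest.approx(0.8)

    def test_bounded_when_defined(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            inc, exc = int(rng.integers(0, 50)), int(rng.integers(0, 50))
            psi = compute_psi(inc, exc)
            if psi is not None:
                assert 0.0 <= psi <= 1.0


class TestIsoformUsage:
    def _counts(self, wt, mut):
        return pd.DataFrame({
            "WT": wt, "MUT": mut,
            "locus_id": ["g1"] * len(wt),
        }, index=[f"T{i}" for i in range(len(wt))])

    def test_worked_two_isoform_gene(self):
        out = run_isoform_usage_test(self._counts([50, 50], [90, 10]))
        # both isoforms of a 2-isoform gene give the same 2x2 table
        expected = fisher_two_sided(50, 50, 90, 10)
        assert out["p_value"].tolist() == pytest.approx(
            [expected, expected], abs=1e-12)
        assert expected == pytest.approx(5.549e-10, rel=1e-3)

    def test_identical_proportions_p_one(self):
        out = run_isoform_usage_test(self._counts([50, 50], [25, 25]))
        assert out["p_value"].tolist() == pytest.approx([1.0, 1.0])

    def test_single_isoform_gene_skipped(self):
        out = run_isoform_usage_test(self._counts([50], [90]))
        assert out.empty

    def test_zero_condition_skipped(self):
        out = run_isoform_usage_test(self._counts([50, 50], [0, 0]))
        assert out.empty


def test_exon_pair_pipeline_finds_exclusive_pair():
    """Two mutually exclusive exons across two isoforms give an exclusive
    call with a BH-adjusted p-value."""
    t1 = _transcript([(100, 200), (300, 600)], tid="A", start=50, end=700)
    t2 = _transcript([(100, 400), (500, 600)], tid="B", start=50, end=700)
    reads = ([_chain([(100, 200), (300, 600)], read_id=f"a{i}",
                     start=50, end=700) for i in range(12)]
             + [_chain([(100, 400), (500, 600)], read_id=f"b{i}",
                       start=50, end=700) for i in range(12)])
    tests = run_exon_pair_tests({"g1": [t1, t2]}, {"g1": reads})
    assert len(tests) == 1
    assert tests[0].odds_direction == "exclusive"
    assert tests[0].p_value == pytest.approx(
        fisher_two_sided(0, 12, 12, 0), abs=1e-12)
    assert tests[0].p_adjusted >= tests[0].p_value - 1e-15
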