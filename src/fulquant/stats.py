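"""Downstream isoform statistics.

* Exon co-association: for every pair of alternative exons of a gene, reads
  covering both exon loci are cross-tabulated by presence/absence of each
  exon and tested with a two-sided Fisher exact test; adjusted p-values use
  Benjamini-Hochberg.  Pair direction follows the sample odds ratio:
  inclusive (+) pairs co-occur, exclusive (-) pairs avoid each other.
* NMD prediction: a novel transcript carrying an annotated start codon is
  predicted to be a nonsense-mediated-decay target when its first in-frame
  stop codon lies more than 55 nt upstream of the last exon-exon junction.
* PSI: inclusive reads / (inclusive + exclusive reads) per exon.
* Isoform-usage testing: per-isoform 2x2 Fisher test (isoform vs. the rest
  of its gene, condition A vs. B) on replicate-summed counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .alnfilter import JunctionChain
from .isoformbuild import TranscriptModel
from .novelty import ReferenceAnnotation
from .preprocess import reverse_complement

INCLUSIVE = "inclusive"
EXCLUSIVE = "exclusive"
UNDEFINED = "undefined"

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class ExonPairTable:
    gene_id: str
    exon_a: tuple[int, int]
    exon_b: tuple[int, int]
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    adjacency: str = "adjacent"


@dataclass
class ExonPairTest:
    table: ExonPairTable
    odds_direction: str
    p_value: float
    p_adjusted: float = float("nan")


@dataclass
class NMDCall:
    transcript_id: str
    start_codon_source: Optional[str]
    stop_to_last_junction_distance: Optional[int]
    is_nmd: bool
    no_call_reason: Optional[str] = None


# ---------------------------------------------------------------------------
# exon partition and pair counting

def internal_exons(transcript: TranscriptModel) -> list[tuple[int, int]]:
    """Exons identified by their internal splice-site pair (terminal exons
    excluded because their outer ends are not splice sites)."""
    return transcript.exons[1:-1]


def define_constitutive_exons(
    gene_transcripts: Sequence[TranscriptModel],
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Partition the gene's internal exons into (constitutive, alternative).

    An exon is constitutive iff its splice-site pair appears in every
    transcript of the gene.
    """
    if not gene_transcripts:
        raise ValueError("gene has no transcripts")
    exon_sets = [set(internal_exons(t)) for t in gene_transcripts]
    union = set().union(*exon_sets)
    constitutive = set.intersection(*exon_sets) if exon_sets else set()
    alternative = union - constitutive
    return sorted(constitutive), sorted(alternative)


def _chain_internal_exons(chain: JunctionChain) -> set:
    introns = chain.introns
    return {(introns[i][1], introns[i + 1][0])
            for i in range(len(introns) - 1)}


def exon_pair_counts(
    gene_id: str,
    exon_a: tuple[int, int],
    exon_b: tuple[int, int],
    reads: Iterable[JunctionChain],
) -> ExonPairTable:
    """4-cell presence/absence table for one alternative exon pair.

    Only reads whose aligned span covers both exon loci entirely are
    informative: for them, absence of an exon means it was spliced out, not
    that the read ended early.
    """
    if exon_b < exon_a:
        exon_a, exon_b = exon_b, exon_a
    n = [0, 0, 0, 0]  # both, a only, b only, neither
    for read in reads:
        if read.read_start > exon_a[0] or read.read_end < exon_b[1]:
            continue  # span does not cover both loci
        exons = _chain_internal_exons(read)
        a = exon_a in exons
        b = exon_b in exons
        if a and b:
            n[0] += 1
        elif a:
            n[1] += 1
        elif b:
            n[2] += 1
        else:
            n[3] += 1
    return ExonPairTable(gene_id, exon_a, exon_b, *n)


# ---------------------------------------------------------------------------
# exact test and multiple-testing adjustment

def fisher_exact_2x2(table: Sequence[int]) -> tuple[float, str]:
    """Two-sided Fisher exact test on (n11, n12, n21, n22).

    The p-value sums, over the hypergeometric distribution fixed at the
    observed margins, the probabilities of all tables at most as probable as
    the observed one.  Direction compares the sample odds ratio to 1.
    """
    n11, n12, n21, n22 = (int(x) for x in table)
    if min(n11, n12, n21, n22) < 0:
        raise ValueError("negative cell count")
    row1 = n11 + n12
    col1 = n11 + n21
    total = n11 + n12 + n21 + n22
    if row1 == 0 or col1 == 0 or row1 == total or col1 == total:
        raise ValueError("zero margin: test undefined")
    kmin = max(0, row1 + col1 - total)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(support, total, col1, row1)
    p_obs = pmf[n11 - kmin]
    # relative tolerance guards against floating-point ties
    p = float(np.sum(pmf[pmf <= p_obs * (1 + 1e-7)]))
    p = min(1.0, p)
    cross1 = n11 * n22
    cross2 = n12 * n21
    if cross1 > cross2:
        direction = INCLUSIVE
    elif cross1 < cross2:
        direction = EXCLUSIVE
    else:
        direction = UNDEFINED
    return p, direction


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def classify_adjacency(
    exon_a: tuple[int, int],
    exon_b: tuple[int, int],
    constitutive: Iterable[tuple[int, int]],
) -> str:
    """"distal" iff >= 1 constitutive exon lies strictly between the pair."""
    if exon_b < exon_a:
        exon_a, exon_b = exon_b, exon_a
    for cs, ce in constitutive:
        if cs >= exon_a[1] and ce <= exon_b[0]:
            return "distal"
    return "adjacent"


def test_exon_pairs(
    genes: Dict[str, Sequence[TranscriptModel]],
    reads_by_gene: Dict[str, Sequence[JunctionChain]],
) -> list[ExonPairTest]:
    """Co-association tests for all alternative exon pairs of all genes,
    BH-adjusted across the whole experiment."""
    tests: list[ExonPairTest] = []
    for gene_id in sorted(genes):
        transcripts = genes[gene_id]
        if len(transcripts) < 2:
            continue
        constitutive, alternative = define_constitutive_exons(transcripts)
        reads = list(reads_by_gene.get(gene_id, []))
        for exon_a, exon_b in itertools.combinations(alternative, 2):
            tab = exon_pair_counts(gene_id, exon_a, exon_b, reads)
            tab.adjacency = classify_adjacency(exon_a, exon_b, constitutive)
            try:
                p, direction = fisher_exact_2x2(
                    (tab.n_both, tab.n_a_only, tab.n_b_only, tab.n_neither))
            except ValueError:
                continue  # zero margin or empty table: skipped
            tests.append(ExonPairTest(tab, direction, p))
    adj = bh_adjust([t.p_value for t in tests])
    for t, a in zip(tests, adj):
        t.p_adjusted = a
    return tests


# ---------------------------------------------------------------------------
# NMD prediction

def _transcript_sequence(transcript: TranscriptModel, genome) -> str:
    chrom_seq = genome[transcript.chrom]
    seq = "".join(str(chrom_seq[s:e]) for s, e in transcript.exons).upper()
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq


def _genomic_to_transcript(transcript: TranscriptModel, pos: int
                           ) -> Optional[int]:
    """Transcript coordinate (5'->3') of genomic position ``pos``."""
    offset = 0
    total = sum(e - s for s, e in transcript.exons)
    for s, e in transcript.exons:
        if s <= pos < e:
            t = offset + (pos - s)
            return total - 1 - t if transcript.strand == "-" else t
        offset += e - s
    return None


def predict_nmd(
    transcript: TranscriptModel,
    reference: ReferenceAnnotation,
    genome,
    distance_threshold: int = 55,
) -> NMDCall:
    """55-nt rule: NMD predicted when the first in-frame stop ends more than
    ``distance_threshold`` nt upstream of the last exon-exon junction.

    The reading frame starts at the 5'-most annotated start codon whose
    first base lies on the transcript's exons; transcripts containing no
    annotated start codon are not called.
    """
    tid = transcript.transcript_id
    seq = _transcript_sequence(transcript, genome)
    n_exons = len(transcript.exons)
    if n_exons < 2:
        return NMDCall(tid, None, None, False, "unspliced")

    candidates = []
    for ref_tid, (chrom, strand, cs, ce) in reference.start_codons.items():
        if chrom != transcript.chrom or strand != transcript.strand:
            continue
        first_base = cs if strand != "-" else ce - 1
        tpos = _genomic_to_transcript(transcript, first_base)
        if tpos is not None and tpos + 3 <= len(seq):
            candidates.append((tpos, ref_tid))
    if not candidates:
        return NMDCall(tid, None, None, False, "no_known_start_codon")
    tpos, source = min(candidates)
    if seq[tpos:tpos + 3] != "ATG":
        return NMDCall(tid, source, None, False, "annotation_mismatch")

    stop_last: Optional[int] = None
    for i in range(tpos, len(seq) - 2, 3):
        if seq[i:i + 3] in _STOPS:
            stop_last = i + 2  # transcript coordinate of the stop's last base
            break
    if stop_last is None:
        return NMDCall(tid, source, None, False, "no_stop_codon")

    # transcript coordinate of the 5'-most base after the last junction
    exon_lengths = [e - s for s, e in transcript.exons]
    if transcript.strand == "-":
        exon_lengths = exon_lengths[::-1]
    last_junction = sum(exon_lengths[:-1])
    distance = last_junction - 1 - stop_last
    return NMDCall(tid, source, distance, distance > distance_threshold)


# ---------------------------------------------------------------------------
# PSI

def compute_psi(inclusive_count: int, exclusive_count: int) -> Optional[float]:
    """PSI = inclusive / (inclusive + exclusive); None when both are zero."""
    if inclusive_count < 0 or exclusive_count < 0:
        raise ValueError("counts must be non-negative")
    total = inclusive_count + exclusive_count
    if total == 0:
        return None
    return inclusive_count / total


def psi_counts(
    exon: tuple[int, int],
    upstream: tuple[int, int],
    downstream: tuple[int, int],
    reads: Iterable[JunctionChain],
) -> tuple[int, int]:
    """(inclusive, exclusive) read counts for one cassette exon.

    Inclusive reads contain the exon; exclusive reads contain both the
    upstream and downstream exons but not the exon of interest.
    """
    inc = exc = 0
    for read in reads:
        exons = _chain_internal_exons(read)
        if exon in exons:
            inc += 1
        elif upstream in exons and downstream in exons:
            exc += 1
    return inc, exc


def psi_per_exon(
    gene_transcripts: Sequence[TranscriptModel],
    reads: Sequence[JunctionChain],
) -> list[dict]:
    """PSI of every alternative internal exon of a gene.

    The upstream/downstream exons are the nearest internal exons flanking
    the exon of interest in the gene's exon union.
    """
    constitutive, alternative = define_constitutive_exons(gene_transcripts)
    all_exons = sorted(set(constitutive) | set(alternative))
    rows = []
    for exon in alternative:
        i = all_exons.index(exon)
        if i == 0 or i == len(all_exons) - 1:
            continue
        inc, exc = psi_counts(exon, all_exons[i - 1], all_exons[i + 1], reads)
        rows.append({
            "exon_start": exon[0], "exon_end": exon[1],
            "inclusive": inc, "exclusive": exc,
            "psi": compute_psi(inc, exc),
        })
    return rows


# ---------------------------------------------------------------------------
# isoform usage

def test_isoform_usage(
    gene_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Per-isoform usage test between two conditions.

    ``gene_counts``: rows = isoforms (index transcript_id, with a
    ``locus_id`` column), two numeric columns = replicate-summed counts per
    condition.  Each isoform of a multi-isoform gene is tested with a 2x2
    Fisher test (isoform vs. the other isoforms, condition A vs. B); the
    returned frame carries p and BH-adjusted p.  Single-isoform genes and
    zero-margin tables are skipped.
    """
    cond_cols = [c for c in gene_counts.columns if c != "locus_id"]
    if len(cond_cols) != 2:
        raise ValueError("expected exactly two condition columns")
    a_col, b_col = cond_cols
    rows = []
    for locus, sub in gene_counts.groupby("locus_id"):
        if len(sub) < 2:
            continue
        tot_a = int(sub[a_col].sum())
        tot_b = int(sub[b_col].sum())
        for tid, row in sub.iterrows():
            ia, ib = int(row[a_col]), int(row[b_col])
            table = (ia, tot_a - ia, ib, tot_b - ib)
            try:
                p, direction = fisher_exact_2x2(table)
            except ValueError:
                continue
            rows.append({"transcript_id": tid, "locus_id": locus,
                         a_col: ia, b_col: ib, "p_value": p,
                         "direction": direction})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = bh_adjust(out["p_value"].tolist())
    return out
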