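"""Collapse tagged junction chains into transcript models and quantify them.

Reads sharing the same tag splice-site chain are collapsed into one
transcript isoform.  Terminal exon ends are not trusted base-precisely:
the TSS and TES of a transcript are the medians of its member reads' 5'
and 3' genomic ends.  A cascade of filters then removes reverse-
transcription and alignment artifacts:

transcript-level
    (1) read count > 3; (2) > 40% full-length member reads; (3) the TES is
    more than 10 bp from a genomic polyA tract (internal-priming
    signature); (4) transcript strand is known.
locus-level
    (1) read count > 3% of the most abundant transcript of the locus;
    (2) not a misalignment product (all private junctions non-canonical);
    (3) not a 5' truncation of a higher-count transcript, unless its own
    count exceeds 25% of that transcript's.
annotation-level
    transcripts whose intron chain matches the reference are rescued even
    if filtered earlier; novel transcripts with only 2 exons or whose chain
    is a terminal sub-chain of a known transcript are removed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .alnfilter import CANONICAL_FWD, CANONICAL_REV, JunctionChain

Chain = Tuple[Tuple[int, int], ...]

STATUS_PASSED = "passed"
STATUS_RESCUED = "rescued"


@dataclass
class TranscriptModel:
    transcript_id: str
    chrom: str
    strand: str
    intron_chain: Chain
    start: int  # genomic left end (0-based)
    end: int  # genomic right end (half-open)
    read_count: int
    full_length_fraction: float
    locus_id: str = ""
    status: str = STATUS_PASSED
    members: list = field(default_factory=list, repr=False)

    @property
    def tss(self) -> int:
        return self.start if self.strand != "-" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand != "-" else self.start

    @property
    def exons(self) -> list[tuple[int, int]]:
        bounds = [self.start]
        for s, e in self.intron_chain:
            bounds.extend([s, e])
        bounds.append(self.end)
        return [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]

    @property
    def passed(self) -> bool:
        return self.status in (STATUS_PASSED, STATUS_RESCUED)


@dataclass
class GeneLocus:
    locus_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    transcript_ids: list[str]


def _median_low(values: list[int]) -> int:
    """Median with even counts resolved to the lower middle value."""
    vals = sorted(values)
    return vals[(len(vals) - 1) // 2]


def collapse_reads(tagged_chains: Iterable[JunctionChain]
                   ) -> list[TranscriptModel]:
    """One draft transcript per distinct (chrom, strand, intron chain)."""
    groups: Dict[tuple, list[JunctionChain]] = defaultdict(list)
    for chain in tagged_chains:
        if not chain.introns:
            continue
        groups[(chain.chrom, chain.strand, chain.introns)].append(chain)
    drafts = []
    for i, key in enumerate(sorted(groups, key=lambda k: (k[0], k[1], k[2]))):
        chrom, strand, introns = key
        members = groups[key]
        n_fl = sum(m.is_full_length for m in members)
        draft = TranscriptModel(
            transcript_id=f"FQT{i + 1:06d}",
            chrom=chrom,
            strand=strand,
            intron_chain=introns,
            start=0,
            end=0,
            read_count=len(members),
            full_length_fraction=n_fl / len(members),
            members=members,
        )
        draft.start, draft.end = compute_boundaries(draft, members)
        drafts.append(draft)
    return drafts


def compute_boundaries(transcript: TranscriptModel,
                       members: list[JunctionChain]) -> tuple[int, int]:
    """Median member 5'/3' ends, clipped so terminal exons keep >= 1 bp."""
    start = _median_low([m.read_start for m in members])
    end = _median_low([m.read_end for m in members])
    first_intron_start = transcript.intron_chain[0][0]
    last_intron_end = transcript.intron_chain[-1][1]
    start = min(start, first_intron_start - 1)
    end = max(end, last_intron_end + 1)
    return start, end


def detect_genomic_polya(
    genome,
    transcript: TranscriptModel,
    max_distance: int = 10,
    min_run: int = 10,
    max_mismatch: int = 1,
) -> bool:
    """Internal-priming check: a genomic A tract starting near the TES.

    True when a run of >= ``min_run`` consecutive A (T for '-' strand, read
    in transcription sense) with at most one interior mismatch starts within
    +-``max_distance`` bp of the transcript termination site.
    """
    chrom_seq = genome[transcript.chrom]
    chrom_len = len(chrom_seq)
    tes = transcript.tes
    if tes < 0 or tes > chrom_len:
        raise ValueError(
            f"{transcript.transcript_id}: TES {tes} outside {transcript.chrom}")
    max_span = min_run + max_mismatch + 5
    if transcript.strand == "-":
        # tail extends leftward as T on the forward genome strand
        lo = max(0, tes - max_distance - max_span)
        hi = min(chrom_len, tes + max_distance + 1)
        window = str(chrom_seq[lo:hi]).upper()[::-1]  # read right-to-left
        anchor = hi - 1 - tes  # position of TES in reversed window
        base = "T"
    else:
        lo = max(0, tes - max_distance)
        hi = min(chrom_len, tes + max_distance + max_span)
        window = str(chrom_seq[lo:hi]).upper()
        anchor = tes - lo
        base = "A"
    # any qualifying run whose start is within max_distance of the anchor
    for offset in range(len(window)):
        if abs(offset - anchor) > max_distance:
            continue
        if window[offset:offset + 1] != base:
            continue
        length = mism = 0
        best_len = 0
        for ch in window[offset:]:
            if ch != base:
                mism += 1
                if mism > max_mismatch:
                    break
            length += 1
            if ch == base:
                best_len = length  # runs must end on a matching base
        if best_len >= min_run:
            return True
    return False


def filter_transcripts(
    drafts: list[TranscriptModel],
    genome,
    min_count: int = 3,
    min_full_length_fraction: float = 0.40,
    polya_distance: int = 10,
) -> list[TranscriptModel]:
    """Transcript-level false-positive filters; statuses record the first
    failing rule."""
    for t in drafts:
        if not t.read_count > min_count:
            t.status = "filtered:read_count"
        elif not t.full_length_fraction > min_full_length_fraction:
            t.status = "filtered:full_length_fraction"
        elif detect_genomic_polya(genome, t, max_distance=polya_distance):
            t.status = "filtered:genomic_polya"
        elif t.strand not in ("+", "-"):
            t.status = "filtered:no_strand"
        else:
            t.status = STATUS_PASSED
    return drafts


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_loci(transcripts: list[TranscriptModel]) -> list[GeneLocus]:
    """Single-linkage grouping by exonic overlap (>= 1 bp, same strand).

    Assigns ``locus_id`` on the passed transcripts and returns the loci.
    """
    passed = [t for t in transcripts if t.passed]
    uf = _UnionFind(len(passed))
    by_group: Dict[tuple, list[int]] = defaultdict(list)
    for i, t in enumerate(passed):
        by_group[(t.chrom, t.strand)].append(i)
    for idxs in by_group.values():
        events = []  # (start, end, transcript index) per exon
        for i in idxs:
            for s, e in passed[i].exons:
                events.append((s, e, i))
        events.sort()
        active: list[tuple[int, int]] = []  # (end, idx)
        for s, e, i in events:
            active = [(ae, ai) for ae, ai in active if ae > s]
            for _, ai in active:
                uf.union(i, ai)
            active.append((e, i))
    clusters: Dict[int, list[int]] = defaultdict(list)
    for i in range(len(passed)):
        clusters[uf.find(i)].append(i)
    loci = []
    ordered = sorted(clusters.values(),
                     key=lambda ix: (passed[ix[0]].chrom,
                                     min(passed[i].start for i in ix),
                                     passed[ix[0]].strand))
    for n, idxs in enumerate(ordered):
        locus_id = f"FQG{n + 1:05d}"
        for i in idxs:
            passed[i].locus_id = locus_id
        loci.append(GeneLocus(
            locus_id=locus_id,
            chrom=passed[idxs[0]].chrom,
            strand=passed[idxs[0]].strand,
            span=(min(passed[i].start for i in idxs),
                  max(passed[i].end for i in idxs)),
            transcript_ids=[passed[i].transcript_id for i in idxs],
        ))
    return loci


def _is_5p_truncation(short: TranscriptModel, long: TranscriptModel) -> bool:
    """True when ``short``'s chain is a strict 5'-truncated tail of
    ``long``'s and its 5' end lies inside ``long``'s span."""
    ns, nl = len(short.intron_chain), len(long.intron_chain)
    if ns >= nl:
        return False
    if short.strand == "-":
        if short.intron_chain != long.intron_chain[:ns]:
            return False
        return short.end <= long.end
    if short.intron_chain != long.intron_chain[-ns:]:
        return False
    return short.start >= long.start


def _junction_motif_canonical(genome, chrom: str, strand: str,
                              intron: tuple[int, int]) -> bool:
    seq = genome[chrom]
    d = str(seq[intron[0]:intron[0] + 2]).upper()
    a = str(seq[intron[1] - 2:intron[1]]).upper()
    if strand == "-":
        return (d, a) in CANONICAL_REV
    return (d, a) in CANONICAL_FWD


def apply_locus_rules(
    loci: list[GeneLocus],
    transcripts: list[TranscriptModel],
    genome=None,
    min_fraction_of_max: float = 0.03,
    truncation_rescue_fraction: float = 0.25,
    misalignment_check: bool = True,
) -> list[TranscriptModel]:
    """Within-locus filters: abundance fraction, misalignment, 5' truncation."""
    by_id = {t.transcript_id: t for t in transcripts}
    for locus in loci:
        members = [by_id[tid] for tid in locus.transcript_ids
                   if by_id[tid].passed]
        if not members:
            continue
        max_count = max(t.read_count for t in members)
        # rule 1: strict > 3% of the locus maximum
        for t in members:
            if not t.read_count > min_fraction_of_max * max_count:
                t.status = "filtered:locus_fraction"
        survivors = [t for t in members if t.passed]
        # rule 2: misalignment products — every private junction non-canonical
        if misalignment_check and genome is not None:
            shared: Dict[tuple, int] = defaultdict(int)
            for t in survivors:
                for intron in t.intron_chain:
                    shared[intron] += 1
            for t in survivors:
                private = [i for i in t.intron_chain if shared[i] == 1]
                if private and all(
                    not _junction_motif_canonical(genome, t.chrom, t.strand, i)
                    for i in private
                ):
                    t.status = "filtered:misalignment"
            survivors = [t for t in survivors if t.passed]
        # rule 3: 5' truncation products of higher-count transcripts
        for t in sorted(survivors, key=lambda x: x.read_count):
            for other in survivors:
                if other is t or not other.passed:
                    continue
                if other.read_count <= t.read_count:
                    continue
                if _is_5p_truncation(t, other):
                    if not (t.read_count >
                            truncation_rescue_fraction * other.read_count):
                        t.status = "filtered:truncation"
                        break
    return transcripts


def final_annotation_filter(
    transcripts: list[TranscriptModel],
    reference,
) -> list[TranscriptModel]:
    """Rescue known chains, then drop dubious novel transcripts.

    ``reference`` is a :class:`fulquant.novelty.ReferenceAnnotation`.
    Filtered transcripts whose intron chain matches a reference transcript
    are rescued.  Novel transcripts with exactly 2 exons, or whose chain is
    a strict terminal sub-chain (5' or 3') of a known transcript on the same
    chrom/strand, are removed.  Returns the final (passed) set.
    """
    for t in transcripts:
        known = reference.match_chain(t.chrom, t.strand, t.intron_chain)
        if known is not None:
            if not t.passed:
                t.status = STATUS_RESCUED
            continue
        if not t.passed:
            continue
        if len(t.intron_chain) == 1:  # 2 exons
            t.status = "filtered:two_exon"
        elif reference.is_terminal_subchain(t.chrom, t.strand, t.intron_chain):
            t.status = "filtered:known_truncation"
    return [t for t in transcripts if t.passed]


def quantify(
    final_transcripts: list[TranscriptModel],
    tagged_chains_by_sample: Dict[str, list[JunctionChain]],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-sample transcript and gene (locus) count tables.

    A chain counts toward the single transcript whose intron chain it
    equals; chains matching no final transcript are tallied as unassigned.
    Returns (transcript_counts, gene_counts, unassigned).
    """
    chain_to_tid = {
        (t.chrom, t.strand, t.intron_chain): t.transcript_id
        for t in final_transcripts
    }
    samples = sorted(tagged_chains_by_sample)
    tids = [t.transcript_id for t in final_transcripts]
    counts = pd.DataFrame(0, index=tids, columns=samples, dtype=int)
    unassigned = pd.Series(0, index=samples, dtype=int)
    for sample, chains in tagged_chains_by_sample.items():
        for chain in chains:
            tid = chain_to_tid.get((chain.chrom, chain.strand, chain.introns))
            if tid is None:
                unassigned[sample] += 1
            else:
                counts.loc[tid, sample] += 1
    locus_of = {t.transcript_id: t.locus_id for t in final_transcripts}
    gene_counts = counts.groupby(
        counts.index.map(locus_of)).sum()
    gene_counts.index.name = "locus_id"
    return counts, gene_counts, unassigned


def deseq2_export(transcript_counts: pd.DataFrame,
                  min_total: int = 10) -> pd.DataFrame:
    """Count matrix with the low-count prefilter flag used before
    differential expression testing (>= ``min_total`` reads summed over all
    samples)."""
    out = transcript_counts.copy()
    out["pass_prefilter"] = transcript_counts.sum(axis=1) > min_total
    return out
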