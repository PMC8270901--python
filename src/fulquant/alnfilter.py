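"""Spliced-alignment parsing, identity, rejection rules and junction extraction.

Alignments are consumed from SAM/BAM produced by an external spliced aligner
(minimap2 ``-K500m -secondary=no -a -x splice -splice-flank=yes`` in the
reference configuration, or the exact-placement aligner of the simulator).
An alignment is rejected when any of the following holds:

1. the read has supplementary alignments (chimera signature);
2. soft clipping at either end exceeds 30 bp;
3. an insertion longer than 5 bp lies near a splice junction (CIGAR ``N``);
4. the alignment is unspliced (no ``N`` operation).

All genomic coordinates are 0-based half-open.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

#: N ops shorter than this are treated as deletions, not introns
MIN_INTRON_LENGTH = 20

DROP_SUPPLEMENTARY = "supplementary"
DROP_SOFTCLIP = "softclip"
DROP_JUNCTION_INSERTION = "junction_insertion"
DROP_UNSPLICED = "unspliced"

# splice motifs on the forward genome strand (donor 2-mer, acceptor 2-mer)
_FWD_MOTIFS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}
_REV_MOTIFS = {("CT", "AC"), ("CT", "GC"), ("GT", "AT")}
CANONICAL_FWD = _FWD_MOTIFS
CANONICAL_REV = _REV_MOTIFS


@dataclass
class SplicedAlignment:
    """One read's genomic alignment with the statistics the filters need."""

    read_id: str
    chrom: str
    aln_strand: str  # mapping orientation of the read: '+' or '-'
    aln_start: int
    aln_end: int
    exon_blocks: list[tuple[int, int]]
    soft_clip_5p: int
    soft_clip_3p: int
    cigar_events: list[tuple[str, int]]
    matches: int
    mismatches: int
    insertions: int
    deletions: int
    has_supplementary: bool = False
    ts_tag: Optional[str] = None  # transcript strand relative to alignment
    strand: str = "unknown"  # transcript strand after infer_strand

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exon_blocks[i][1], self.exon_blocks[i + 1][0])
            for i in range(len(self.exon_blocks) - 1)
        ]


@dataclass(frozen=True)
class JunctionChain:
    """A read reduced to its splicing structure."""

    read_id: str
    chrom: str
    strand: str
    introns: tuple[tuple[int, int], ...]
    read_start: int
    read_end: int
    is_full_length: bool = False
    sample: str = ""


def percent_identity(aln: SplicedAlignment) -> float:
    """Matched bases over all aligned columns (matches+mismatches+indels)."""
    total = aln.matches + aln.mismatches + aln.insertions + aln.deletions
    if total == 0:
        raise ValueError(f"{aln.read_id}: alignment has zero aligned bases")
    return aln.matches / total


def _blocks_from_cigar(start: int, cigar: list[tuple[str, int]],
                       min_intron: int = MIN_INTRON_LENGTH
                       ) -> list[tuple[int, int]]:
    """Exon blocks from reference position + CIGAR; short N ops merge as D."""
    blocks: list[tuple[int, int]] = []
    pos = start
    block_start = start
    for op, length in cigar:
        if op in ("M", "=", "X", "D"):
            pos += length
        elif op == "N":
            if length >= min_intron:
                blocks.append((block_start, pos))
                block_start = pos + length
            pos += length
        # I and S consume no reference
    blocks.append((block_start, pos))
    return [b for b in blocks if b[1] > b[0]]


def parse_alignment(rec: pysam.AlignedSegment,
                    supplementary_reads: Optional[set] = None
                    ) -> SplicedAlignment:
    """Build a :class:`SplicedAlignment` from a mapped pysam record."""
    ops = "MIDNSHP=XB"
    cigar = [(ops[op], ln) for op, ln in rec.cigartuples]
    n_m = sum(ln for op, ln in cigar if op in ("M", "=", "X"))
    n_i = sum(ln for op, ln in cigar if op == "I")
    n_d = sum(ln for op, ln in cigar if op == "D")
    try:
        nm = rec.get_tag("NM")
    except KeyError:
        nm = n_i + n_d  # assume no substitutions when NM absent
    mismatches = max(0, nm - n_i - n_d)
    matches = n_m - mismatches
    clip_left = cigar[0][1] if cigar[0][0] == "S" else 0
    clip_right = cigar[-1][1] if cigar[-1][0] == "S" else 0
    rev = rec.is_reverse
    ts = None
    if rec.has_tag("ts"):
        ts = rec.get_tag("ts")
    read_id = rec.query_name
    has_supp = rec.is_supplementary or (
        supplementary_reads is not None and read_id in supplementary_reads
    )
    return SplicedAlignment(
        read_id=read_id,
        chrom=rec.reference_name,
        aln_strand="-" if rev else "+",
        aln_start=rec.reference_start,
        aln_end=rec.reference_end,
        exon_blocks=_blocks_from_cigar(rec.reference_start, cigar),
        soft_clip_5p=clip_right if rev else clip_left,
        soft_clip_3p=clip_left if rev else clip_right,
        cigar_events=cigar,
        matches=matches,
        mismatches=mismatches,
        insertions=n_i,
        deletions=n_d,
        has_supplementary=has_supp,
        ts_tag=ts,
    )


def filter_alignment(
    aln: SplicedAlignment,
    max_softclip: int = 30,
    max_junction_insert: int = 5,
    junction_window: int = 10,
) -> Optional[str]:
    """Apply the four rejection rules; return the first failing reason or None.

    An insertion is "near" a junction when the gap in query coordinates
    between the insertion and the nearest ``N`` boundary is at most
    ``junction_window`` bases.
    """
    if aln.has_supplementary:
        return DROP_SUPPLEMENTARY
    if aln.soft_clip_5p > max_softclip or aln.soft_clip_3p > max_softclip:
        return DROP_SOFTCLIP

    # query positions of junctions and of oversized insertions
    qpos = 0
    junction_q: list[int] = []
    big_inserts: list[tuple[int, int]] = []  # (qstart, qend) of the I op
    for op, length in aln.cigar_events:
        if op in ("M", "=", "X"):
            qpos += length
        elif op == "I":
            if length > max_junction_insert:
                big_inserts.append((qpos, qpos + length))
            qpos += length
        elif op == "S":
            qpos += length
        elif op == "N" and length >= MIN_INTRON_LENGTH:
            junction_q.append(qpos)
        # D and short N consume no query
    for qs, qe in big_inserts:
        for j in junction_q:
            if min(abs(j - qs), abs(j - qe)) <= junction_window:
                return DROP_JUNCTION_INSERTION
    if not junction_q:
        return DROP_UNSPLICED
    return None


def extract_junction_chain(aln: SplicedAlignment) -> JunctionChain:
    """Project the alignment's intron structure to a junction chain."""
    if len(aln.exon_blocks) < 2:
        raise ValueError(f"{aln.read_id}: unspliced alignment has no junctions")
    return JunctionChain(
        read_id=aln.read_id,
        chrom=aln.chrom,
        strand=aln.strand,
        introns=tuple(aln.introns),
        read_start=aln.aln_start,
        read_end=aln.aln_end,
    )


def infer_strand(aln: SplicedAlignment, genome) -> str:
    """Transcript strand from the aligner's ``ts`` tag, else splice-motif vote.

    ``genome`` maps chromosome name to sequence (any object supporting
    ``genome[chrom][start:end]`` returning an upper-case string, e.g. a dict
    or ``pyfaidx.Fasta`` wrapper).
    """
    if aln.ts_tag in ("+", "-"):
        if aln.ts_tag == "+":
            return aln.aln_strand
        return "-" if aln.aln_strand == "+" else "+"
    votes = Counter()
    seq = genome[aln.chrom]
    for start, end in aln.introns:
        d = str(seq[start:start + 2]).upper()
        a = str(seq[end - 2:end]).upper()
        if (d, a) in _FWD_MOTIFS:
            votes["+"] += 1
        elif (d, a) in _REV_MOTIFS:
            votes["-"] += 1
    if not votes:
        return "unknown"
    if len(votes) == 2 and votes["+"] == votes["-"]:
        return "unknown"
    return votes.most_common(1)[0][0]


def filter_bam(
    bam_path,
    genome,
    full_length_flags: Optional[dict] = None,
    max_softclip: int = 30,
    max_junction_insert: int = 5,
    junction_window: int = 10,
    sample: str = "",
    report: Optional[dict] = None,
) -> list[JunctionChain]:
    """Run the whole alignment stage on one SAM/BAM file.

    ``full_length_flags`` maps read_id -> bool from the preprocess stage.
    Returns the kept junction chains; drop reasons accumulate in ``report``.
    """
    if report is None:
        report = {}
    reasons: Counter = Counter()
    chains: list[JunctionChain] = []
    mode = "rb" if str(bam_path).endswith(".bam") else "r"

    with pysam.AlignmentFile(str(bam_path), mode, check_sq=False) as fh:
        records = [r for r in fh if not r.is_unmapped and not r.is_secondary]
    supp_reads = {r.query_name for r in records if r.is_supplementary}

    for rec in records:
        if rec.is_supplementary:
            reasons[DROP_SUPPLEMENTARY] += 1
            continue
        aln = parse_alignment(rec, supplementary_reads=supp_reads)
        reason = filter_alignment(aln, max_softclip, max_junction_insert,
                                  junction_window)
        if reason is not None:
            reasons[reason] += 1
            continue
        aln.strand = infer_strand(aln, genome)
        chain = extract_junction_chain(aln)
        if full_length_flags is not None:
            chain = JunctionChain(
                read_id=chain.read_id, chrom=chain.chrom, strand=chain.strand,
                introns=chain.introns, read_start=chain.read_start,
                read_end=chain.read_end,
                is_full_length=bool(full_length_flags.get(chain.read_id, False)),
                sample=sample,
            )
        else:
            chain = JunctionChain(
                read_id=chain.read_id, chrom=chain.chrom, strand=chain.strand,
                introns=chain.introns, read_start=chain.read_start,
                read_end=chain.read_end, sample=sample,
            )
        chains.append(chain)

    for k, v in reasons.items():
        report[f"drop_{k}"] = report.get(f"drop_{k}", 0) + v
    report["alignments_kept"] = report.get("alignments_kept", 0) + len(chains)
    return chains


def write_chains_tsv(chains: Iterable[JunctionChain], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstrand\tintrons\tread_start\tread_end"
                 "\tfull_length\tsample\n")
        for c in chains:
            intr = ";".join(f"{s}-{e}" for s, e in c.introns)
            fh.write(f"{c.read_id}\t{c.chrom}\t{c.strand}\t{intr}"
                     f"\t{c.read_start}\t{c.read_end}\t{int(c.is_full_length)}"
                     f"\t{c.sample}\n")


def read_chains_tsv(path) -> list[JunctionChain]:
    chains = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, chrom, strand, intr, rs, re_, fl, sample = \
                line.rstrip("\n").split("\t")
            introns = tuple(
                tuple(int(x) for x in part.split("-"))
                for part in intr.split(";") if part
            )
            chains.append(JunctionChain(rid, chrom, strand, introns,
                                        int(rs), int(re_), fl == "1", sample))
    return chains
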