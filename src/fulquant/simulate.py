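"""Synthetic multi-isoform loci and ONT-like full-length cDNA reads.

The generator emulates the structure of a spike-in style benchmark: a small
artificial genome of multi-exon gene loci, each expressing several
alternative isoforms (exon skipping, alternative splice sites, intron
retention) with canonical GT-AG introns, abundances drawn from a log-uniform
ladder spanning up to ~10^6-fold, and reads carrying the artifact classes
the pipeline's filters target:

* base errors (substitution/insertion/deletion) at configurable rates;
* junction wobble — alignment boundaries jittered around the true splice
  sites (normal, sd in bases, rounded);
* 5' truncation — RT drop-off; such reads lack the 5' adapter;
* internal priming — oligo(dT) priming inside the transcript body,
  producing 3'-truncated reads that still look full-length;
* template switching — chimeric concatenation of two molecules, which an
  aligner reports as a primary + supplementary pair.

Reads are emitted already basecalled (FASTQ); an exact-placement aligner
writes the corresponding SAM from provenance so the full pipeline can run
without an external spliced aligner.  All outputs are byte-deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .preprocess import ISPCR_ADAPTER, reverse_complement

Block = Tuple[int, int]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults model a small ONT-like run: 20 multi-isoform loci, a 10^6-fold
    abundance ladder across genes, 5% substitution / 2.5% insertion / 2.5%
    deletion, 1.5-base junction wobble and modest artifact rates.
    """

    seed: int = 0
    n_genes: int = 20
    isoforms_per_gene: tuple[int, int] = (2, 4)
    n_exons: tuple[int, int] = (4, 9)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (80, 400)
    gene_spacing: int = 2000
    abundance_ladder_span: float = 1e6
    isoform_rel_abundance: tuple[float, float] = (0.3, 1.0)
    total_molecules: int = 5000
    min_molecules_per_isoform: int = 0
    substitution_rate: float = 0.05
    insertion_rate: float = 0.025
    deletion_rate: float = 0.025
    junction_wobble_sd: float = 1.5
    rate_truncation_5p: float = 0.1
    truncation_mean: int = 150
    rate_internal_priming: float = 0.05
    rate_template_switch: float = 0.02
    polya_length: tuple[int, int] = (15, 40)
    adapter: str = ISPCR_ADAPTER

    def __post_init__(self):
        for r in (self.substitution_rate, self.insertion_rate,
                  self.deletion_rate, self.rate_truncation_5p,
                  self.rate_internal_priming, self.rate_template_switch):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @classmethod
    def perfect(cls, **overrides) -> "SimConfig":
        """Error- and artifact-free conditions (identity benchmark)."""
        kwargs = dict(
            substitution_rate=0.0, insertion_rate=0.0, deletion_rate=0.0,
            junction_wobble_sd=0.0, rate_truncation_5p=0.0,
            rate_internal_priming=0.0, rate_template_switch=0.0,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class IsoformTruth:
    isoform_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Block]

    @property
    def chain(self) -> tuple[Block, ...]:
        return tuple((self.exons[i][1], self.exons[i + 1][0])
                     for i in range(len(self.exons) - 1))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class TruthSet:
    genome: Dict[str, str]
    isoforms: list[IsoformTruth]
    molecule_counts: Dict[str, int] = field(default_factory=dict)
    start_codons: Dict[str, Block] = field(default_factory=dict)  # per gene

    def isoform(self, isoform_id: str) -> IsoformTruth:
        return next(i for i in self.isoforms if i.isoform_id == isoform_id)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")

    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for iso in self.isoforms:
                attrs = (f'gene_id "{iso.gene_id}"; '
                         f'transcript_id "{iso.isoform_id}";')
                fh.write("\t".join([
                    iso.chrom, "sim", "transcript", str(iso.start + 1),
                    str(iso.end), ".", iso.strand, ".", attrs]) + "\n")
                for s, e in iso.exons:
                    fh.write("\t".join([
                        iso.chrom, "sim", "exon", str(s + 1), str(e), ".",
                        iso.strand, ".", attrs]) + "\n")
                sc = self.start_codons.get(iso.gene_id)
                if sc is not None and any(
                        s <= sc[0] and sc[1] <= e for s, e in iso.exons):
                    fh.write("\t".join([
                        iso.chrom, "sim", "start_codon", str(sc[0] + 1),
                        str(sc[1]), ".", iso.strand, ".", attrs]) + "\n")

    def write_counts(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("isoform_id\tmolecules\n")
            for iso in self.isoforms:
                fh.write(f"{iso.isoform_id}"
                         f"\t{self.molecule_counts.get(iso.isoform_id, 0)}\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _splice_motifs(strand: str) -> tuple[str, str]:
    """Genomic (intron start 2-mer, intron end 2-mer) for canonical GT-AG."""
    return ("GT", "AG") if strand != "-" else ("CT", "AC")


def _is_terminal_subchain(short: tuple, long: tuple) -> bool:
    n = len(short)
    return n < len(long) and (long[:n] == short or long[-n:] == short)


def make_toy_reference(config: SimConfig,
                       rng: Optional[np.random.Generator] = None) -> TruthSet:
    """Random genome + annotation with all novelty-relevant event classes.

    Every gene gets a full-exon base isoform plus variants made by skipping
    an internal exon, shifting an internal splice site, or retaining an
    intron; chains are kept distinct and never a terminal sub-chain of a
    sibling (such isoforms would be indistinguishable from truncation
    artifacts by design of the pipeline's filters).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    genome_parts: list[str] = []
    pos = config.gene_spacing
    genome_parts.append(_random_seq(rng, pos))
    isoforms: list[IsoformTruth] = []
    start_codons: Dict[str, Block] = {}

    for g in range(config.n_genes):
        gene_id = f"SIMG{g + 1:04d}"
        strand = "+" if g % 2 == 0 else "-"
        n_ex = int(rng.integers(config.n_exons[0], config.n_exons[1] + 1))
        exon_lens = rng.integers(config.exon_length[0],
                                 config.exon_length[1] + 1, size=n_ex)
        intron_lens = rng.integers(config.intron_length[0],
                                   config.intron_length[1] + 1, size=n_ex - 1)
        # genomic layout of the gene
        exons: list[Block] = []
        p = pos
        gene_seq = []
        dm, am = _splice_motifs(strand)
        for i in range(n_ex):
            exons.append((p, p + int(exon_lens[i])))
            gene_seq.append(_random_seq(rng, int(exon_lens[i])))
            p += int(exon_lens[i])
            if i < n_ex - 1:
                intron = list(_random_seq(rng, int(intron_lens[i])))
                intron[:2] = dm
                intron[-2:] = am
                gene_seq.append("".join(intron))
                p += int(intron_lens[i])
        seq = list("".join(gene_seq))

        # plant a start codon near the transcription start
        if strand == "+":
            sc_off = exons[0][0] - pos + 9
            seq[sc_off:sc_off + 3] = "ATG"
            start_codons[gene_id] = (exons[0][0] + 9, exons[0][0] + 12)
        else:
            sc_end = exons[-1][1] - pos - 9
            seq[sc_end - 3:sc_end] = "CAT"  # ATG in transcription sense
            start_codons[gene_id] = (exons[-1][1] - 12, exons[-1][1] - 9)

        # isoform structures
        base = IsoformTruth(f"{gene_id}.1", gene_id, chrom, strand,
                            list(exons))
        gene_isoforms = [base]
        n_iso = int(rng.integers(config.isoforms_per_gene[0],
                                 config.isoforms_per_gene[1] + 1))
        attempts = 0
        while len(gene_isoforms) < n_iso and attempts < 50:
            attempts += 1
            event = rng.choice(["ES", "ASS", "IR"])
            new_exons = [list(b) for b in exons]
            if event == "ES" and n_ex >= 4:
                j = int(rng.integers(1, n_ex - 1))  # internal exon
                del new_exons[j]
            elif event == "IR":
                j = int(rng.integers(1, n_ex - 2)) if n_ex > 3 else 1
                merged = [new_exons[j][0], new_exons[j + 1][1]]
                new_exons[j:j + 2] = [merged]
            else:  # ASS: shift an internal donor into its exon
                j = int(rng.integers(1, n_ex - 1))
                delta = int(rng.integers(20, 41))
                if new_exons[j][1] - delta - new_exons[j][0] < 20:
                    continue
                new_exons[j][1] -= delta
                # alternative sites must stay separable at the clustering
                # resolution: keep >= 20 bp from every existing splice site
                used = {b for iso2 in gene_isoforms
                        for intron in iso2.chain for b in intron}
                if any(abs(new_exons[j][1] - u) < 20 for u in used):
                    continue
                # plant the canonical motif at the new intron start
                off = new_exons[j][1] - pos
                seq[off:off + 2] = dm
            cand = IsoformTruth(f"{gene_id}.{len(gene_isoforms) + 1}",
                                gene_id, chrom, strand,
                                [tuple(b) for b in new_exons])
            chains = [iso.chain for iso in gene_isoforms]
            if cand.chain in chains:
                continue
            if any(_is_terminal_subchain(cand.chain, c)
                   or _is_terminal_subchain(c, cand.chain) for c in chains):
                continue
            gene_isoforms.append(cand)
        isoforms.extend(gene_isoforms)

        genome_parts.append("".join(seq))
        spacer = config.gene_spacing
        genome_parts.append(_random_seq(rng, spacer))
        pos = p + spacer

    truth = TruthSet(genome={chrom: "".join(genome_parts)},
                     isoforms=isoforms, start_codons=start_codons)
    _sample_abundances(truth, config, rng)
    return truth


def _sample_abundances(truth: TruthSet, config: SimConfig,
                       rng: np.random.Generator) -> None:
    genes = sorted({iso.gene_id for iso in truth.isoforms})
    log_span = np.log10(config.abundance_ladder_span)
    gene_w = {g: 10.0 ** (rng.uniform(0, log_span)) for g in genes}
    lo, hi = config.isoform_rel_abundance
    weights = np.array([gene_w[iso.gene_id] * rng.uniform(lo, hi)
                        for iso in truth.isoforms])
    probs = weights / weights.sum()
    counts = rng.multinomial(config.total_molecules, probs)
    if config.min_molecules_per_isoform > 0:
        counts = np.maximum(counts, config.min_molecules_per_isoform)
    truth.molecule_counts = {
        iso.isoform_id: int(c) for iso, c in zip(truth.isoforms, counts)
    }


# ---------------------------------------------------------------------------
# read simulation

@dataclass
class SimRead:
    read_id: str
    isoform_id: str
    sequence: str  # as sequenced (adapter + cDNA + polyA, possibly flipped)
    qualities: np.ndarray
    artifacts: list
    flipped: bool
    sense: str = ""  # cDNA portion in transcript sense (what the aligner sees
    # after adapter/polyA trimming)
    segments: list = field(default_factory=list)
    chrom: str = ""
    strand: str = "+"


def _truncate_5p(exons: list[Block], strand: str, n: int
                 ) -> Optional[list[Block]]:
    """Remove the first ``n`` transcript bases (transcript sense)."""
    order = exons if strand == "+" else exons[::-1]
    out = []
    remaining = n
    for s, e in order:
        ln = e - s
        if remaining >= ln:
            remaining -= ln
            continue
        if strand == "+":
            out.append((s + remaining, e))
        else:
            out.append((s, e - remaining))
        remaining = 0
        out.extend([(s2, e2) for s2, e2 in
                    (order[order.index((s, e)) + 1:])])
        break
    if not out:
        return None
    return out if strand == "+" else out[::-1]


def _truncate_3p(exons: list[Block], strand: str, keep: int
                 ) -> Optional[list[Block]]:
    """Keep only the first ``keep`` transcript bases (transcript sense)."""
    order = exons if strand == "+" else exons[::-1]
    out = []
    remaining = keep
    for s, e in order:
        ln = e - s
        if remaining <= 0:
            break
        if remaining >= ln:
            out.append((s, e))
            remaining -= ln
        else:
            if strand == "+":
                out.append((s, s + remaining))
            else:
                out.append((e - remaining, e))
            remaining = 0
    if not out:
        return None
    return out if strand == "+" else out[::-1]


def _wobble_blocks(blocks: list[Block], sd: float,
                   rng: np.random.Generator) -> list[Block]:
    """Jitter internal block boundaries (junction wobble)."""
    if sd <= 0 or len(blocks) < 2:
        return blocks
    out = [list(b) for b in blocks]
    for i in range(len(out) - 1):
        d = int(round(rng.normal(0, sd)))
        a = int(round(rng.normal(0, sd)))
        # clamp: keep blocks >= 5 bp and the intron >= 25 bp
        new_end = out[i][1] + d
        new_start = out[i + 1][0] + a
        if (new_end - out[i][0] >= 5 and new_start + 5 <= out[i + 1][1]
                and new_start - new_end >= 25):
            out[i][1] = new_end
            out[i + 1][0] = new_start
    return [tuple(b) for b in out]


def _apply_errors(seq: str, config: SimConfig, rng: np.random.Generator
                  ) -> tuple[str, list, int]:
    """Base errors on one aligned block.

    Returns (mutated sequence, cigar ops [(op, len)], edit count).  With
    zero indel rates this is a vectorized substitution pass.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    edits = 0
    if config.substitution_rate > 0 and n:
        mask = rng.random(n) < config.substitution_rate
        idx = np.nonzero(mask)[0]
        if idx.size:
            shift = rng.integers(1, 4, size=idx.size)
            lut = np.zeros(256, dtype=np.int64)
            for i, b in enumerate(_BASES):
                lut[b] = i
            base_idx = lut[arr[idx]]
            arr[idx] = _BASES[(base_idx + shift) % 4]
            edits += idx.size
    if config.insertion_rate <= 0 and config.deletion_rate <= 0:
        return arr.tobytes().decode(), [("M", n)] if n else [], edits

    # indel path: per-base op sampling
    out = []
    ops: list[list] = []
    p_ins, p_del = config.insertion_rate, config.deletion_rate
    draws = rng.random(n)
    for i in range(n):
        r = draws[i]
        if r < p_del:
            _push(ops, "D", 1)
            edits += 1
            continue
        if r < p_del + p_ins:
            out.append(chr(rng.choice(_BASES)))
            _push(ops, "I", 1)
            edits += 1
        out.append(chr(arr[i]))
        _push(ops, "M", 1)
    return "".join(out), [tuple(o) for o in ops], edits


def _push(ops: list, op: str, ln: int) -> None:
    if ops and ops[-1][0] == op:
        ops[-1][1] += ln
    else:
        ops.append([op, ln])


def simulate_reads(
    truth: TruthSet,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    fastq_path=None,
    sam_path=None,
    provenance_path=None,
) -> list[SimRead]:
    """Generate reads for every molecule of the truth set.

    When paths are given, FASTQ, exact-placement SAM and provenance TSV are
    written; the in-memory reads are returned either way.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    reads: list[SimRead] = []
    n_read = 0
    iso_ids = [iso.isoform_id for iso in truth.isoforms]
    iso_counts = np.array([truth.molecule_counts.get(i, 0) for i in iso_ids])
    total = iso_counts.sum()
    iso_probs = iso_counts / total if total else None

    for iso in truth.isoforms:
        count = truth.molecule_counts.get(iso.isoform_id, 0)
        for _ in range(count):
            n_read += 1
            read_id = f"read{n_read:07d}"
            artifacts = []
            chrom_seq = truth.genome[iso.chrom]
            strand = iso.strand
            exons = list(iso.exons)
            has_5p_adapter = True

            partner_blocks = None
            if (config.rate_template_switch > 0 and iso_probs is not None
                    and rng.random() < config.rate_template_switch):
                artifacts.append("template_switch")
                partner = truth.isoform(
                    iso_ids[int(rng.choice(len(iso_ids), p=iso_probs))])
                # 5' part of this molecule + 3' part of the partner
                if len(exons) > 1 and len(partner.exons) > 1:
                    cut_a = int(rng.integers(1, len(exons)))
                    cut_b = int(rng.integers(1, len(partner.exons)))
                    if strand == "+":
                        part_a = exons[:cut_a]
                    else:
                        part_a = exons[-cut_a:]
                    if partner.strand == "+":
                        part_b = partner.exons[-cut_b:]
                    else:
                        part_b = partner.exons[:cut_b]
                    exons = part_a
                    partner_blocks = (partner, [tuple(b) for b in part_b])

            if (config.rate_truncation_5p > 0
                    and rng.random() < config.rate_truncation_5p):
                t = int(rng.geometric(1.0 / config.truncation_mean))
                trunc = _truncate_5p(exons, strand, t)
                if trunc is not None and sum(
                        e - s for s, e in trunc) >= 60:
                    exons = trunc
                    artifacts.append("truncation_5p")
                    has_5p_adapter = False

            if (config.rate_internal_priming > 0 and partner_blocks is None
                    and rng.random() < config.rate_internal_priming):
                length = sum(e - s for s, e in exons)
                if length > 150:
                    keep = int(rng.integers(80, length - 40))
                    trunc = _truncate_3p(exons, strand, keep)
                    if trunc is not None:
                        exons = trunc
                        artifacts.append("internal_priming")

            exons = _wobble_blocks(exons, config.junction_wobble_sd, rng)

            segments = []
            cdna_genomic, ops, edits = _blocks_to_read(
                exons, chrom_seq, config, rng)
            part_b_data = None
            if partner_blocks is not None:
                partner, blocks_b = partner_blocks
                blocks_b = _wobble_blocks(blocks_b,
                                          config.junction_wobble_sd, rng)
                part_b_data = (_blocks_to_read(blocks_b, chrom_seq, config,
                                               rng), partner, blocks_b)

            # assemble the read in transcript sense
            sense_a = (cdna_genomic if strand == "+"
                       else reverse_complement(cdna_genomic))
            sense = sense_a
            if part_b_data is not None:
                (seq_b, ops_b, edits_b), partner, blocks_b = part_b_data
                sense_b = (seq_b if partner.strand == "+"
                           else reverse_complement(seq_b))
                sense = sense_a + sense_b
            polya = "A" * int(rng.integers(config.polya_length[0],
                                           config.polya_length[1] + 1))
            adapter5 = config.adapter if has_5p_adapter else ""
            full = adapter5 + sense + polya

            flipped = bool(rng.random() < 0.5)
            emitted = reverse_complement(full) if flipped else full

            # per-base qualities match the configured error rate
            err = (config.substitution_rate + config.insertion_rate
                   + config.deletion_rate)
            target_q = -10 * np.log10(max(err, 1e-3))
            quals = np.clip(
                np.round(rng.normal(target_q, 2.0, size=len(emitted))),
                2, 41).astype(int)

            # segment bookkeeping for the SAM writer; offsets are relative
            # to the trimmed (adapter/polyA-free) cDNA in transcript sense
            seg_a = {
                "blocks": exons, "ops": ops, "edits": edits,
                "sense_offset": 0, "sense_len": len(sense_a),
                "strand": strand,
            }
            segments.append(seg_a)
            if part_b_data is not None:
                (seq_b, ops_b, edits_b), partner, blocks_b = part_b_data
                segments.append({
                    "blocks": blocks_b, "ops": ops_b, "edits": edits_b,
                    "sense_offset": len(sense_a),
                    "sense_len": len(sense) - len(sense_a),
                    "strand": partner.strand,
                })

            reads.append(SimRead(
                read_id=read_id, isoform_id=iso.isoform_id,
                sequence=emitted, qualities=quals, artifacts=artifacts,
                flipped=flipped, sense=sense, segments=segments,
                chrom=iso.chrom, strand=strand,
            ))

    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    if sam_path is not None:
        write_truth_sam(reads, truth, sam_path)
    if provenance_path is not None:
        write_provenance(reads, provenance_path)
    return reads


def _blocks_to_read(blocks, chrom_seq, config, rng):
    """Extract + mutate block sequences; returns (seq, ops, edit count) in
    genomic orientation."""
    parts = []
    ops: list = []
    edits = 0
    for i, (s, e) in enumerate(blocks):
        seq, block_ops, ed = _apply_errors(chrom_seq[s:e], config, rng)
        parts.append(seq)
        for op, ln in block_ops:
            _push(ops, op, ln)
        edits += ed
        if i < len(blocks) - 1:
            _push(ops, "N", blocks[i + 1][0] - e)
    return "".join(parts), [tuple(o) for o in ops], edits


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def write_provenance(reads, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tisoform_id\tartifacts\tflipped\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.isoform_id}"
                     f"\t{','.join(r.artifacts) or '.'}\t{int(r.flipped)}\n")


def write_truth_sam(reads, truth: TruthSet, path) -> None:
    """Exact-placement SAM from provenance (no external aligner needed)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in sorted(truth.genome.items())],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            full_fwd = r.sense  # trimmed read, transcript sense
            for si, seg in enumerate(r.segments):
                a = pysam.AlignedSegment(out.header)
                a.query_name = r.read_id
                strand = seg["strand"]
                is_rev = (strand == "-") != r.flipped
                flag = 16 if is_rev else 0
                if si > 0:
                    flag |= 2048
                a.flag = flag
                a.reference_id = out.header.references.index(r.chrom)
                a.reference_start = seg["blocks"][0][0]
                a.mapping_quality = 60
                # reference-orientation read sequence
                ref_seq = (full_fwd if strand == "+"
                           else reverse_complement(full_fwd))
                n_read = len(full_fwd)
                off, ln = seg["sense_offset"], seg["sense_len"]
                if strand == "+":
                    left_clip, right_clip = off, n_read - off - ln
                else:
                    left_clip = n_read - off - ln
                    right_clip = off
                cigar = []
                if left_clip:
                    cigar.append(("S", left_clip))
                cigar.extend(seg["ops"])
                if right_clip:
                    cigar.append(("S", right_clip))
                opcode = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4}
                a.cigartuples = [(opcode[op], ln_) for op, ln_ in cigar]
                a.query_sequence = ref_seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(ref_seq))
                a.set_tag("NM", seg["edits"])
                a.set_tag("ts", "+" if strand == (
                    "-" if is_rev else "+") else "-", value_type="A")
                out.write(a)


# ---------------------------------------------------------------------------
# evaluation against truth

@dataclass
class EvalResult:
    precision: Optional[float]
    recall: float
    recall_top_half: float
    n_reported: int
    n_true_matched: int
    n_truth_evaluated: int
    boundary_within_20: Optional[float]
    boundary_deviations: list = field(default_factory=list)


def score_against_truth(
    final_transcripts,
    truth: TruthSet,
    min_true_count: int = 0,
    boundary_tolerance: int = 20,
) -> EvalResult:
    """Precision/recall of the reported isoform set at intron-chain level.

    Precision = identified true chains / all reported chains.  Recall is
    computed over truth isoforms with molecule count > ``min_true_count``,
    overall and for the most abundant 50%.  Boundary deviations are |TSS -
    truth| and |TES - truth| of every matched transcript.
    """
    truth_chains = {(i.chrom, i.strand, i.chain): i for i in truth.isoforms}
    matched_ids = set()
    n_match = 0
    devs: list[int] = []
    for t in final_transcripts:
        iso = truth_chains.get((t.chrom, t.strand, t.intron_chain))
        if iso is not None:
            n_match += 1
            matched_ids.add(iso.isoform_id)
            devs.append(abs(t.start - iso.start))
            devs.append(abs(t.end - iso.end))
    n_reported = len(list(final_transcripts))
    precision = n_match / n_reported if n_reported else None

    evaluated = [i for i in truth.isoforms
                 if truth.molecule_counts.get(i.isoform_id, 0) > min_true_count]
    recall = (sum(i.isoform_id in matched_ids for i in evaluated)
              / len(evaluated)) if evaluated else 0.0
    by_abundance = sorted(
        evaluated, key=lambda i: -truth.molecule_counts.get(i.isoform_id, 0))
    top = by_abundance[: max(1, len(by_abundance) // 2)] if by_abundance else []
    recall_top = (sum(i.isoform_id in matched_ids for i in top)
                  / len(top)) if top else 0.0
    within = (sum(d <= boundary_tolerance for d in devs) / len(devs)
              if devs else None)
    return EvalResult(
        precision=precision, recall=recall, recall_top_half=recall_top,
        n_reported=n_reported, n_true_matched=n_match,
        n_truth_evaluated=len(evaluated),
        boundary_within_20=within, boundary_deviations=devs,
    )
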