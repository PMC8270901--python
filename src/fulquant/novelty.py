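"""Comparison of identified transcripts against a reference annotation.

A transcript is *known* when its full ordered intron chain matches a
reference transcript on the same chromosome and strand; terminal-exon end
differences are ignored.  Novel transcripts are classified by the novel
splicing events they carry:

NE  novel exon — an exon whose flanking splice sites are both unannotated
    and which overlaps no reference exon;
IR  intron retention — a transcript exon fully containing a reference
    intron;
ES  exon skipping — a junction joining two annotated sites that skips at
    least one reference exon lying strictly inside it;
ASS alternative splice site — a junction with exactly one end at an
    annotated site of the matching side;
NC  novel combination — every junction individually annotated (or built
    from annotated sites) but the chain matching no reference transcript;
multiple — two or more distinct event types;
ambiguous — too many of the transcript's member junctions could not be
    assigned to tag splice sites (alignment anomalies).
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import gffutils

from .isoformbuild import TranscriptModel

Chain = Tuple[Tuple[int, int], ...]

CATEGORIES = ("NC", "NE", "IR", "ES", "ASS", "multiple", "ambiguous", "none")


@dataclass
class NoveltyCall:
    transcript_id: str
    status: str  # "known" | "novel"
    category: str = "none"
    events: list = field(default_factory=list)  # [(type, (start, end))]
    read_through: bool = False
    matched_reference: Optional[str] = None


class ReferenceAnnotation:
    """Indexed projections of one reference GTF.

    Internally 0-based half-open; the GTF boundary (1-based inclusive) is
    converted on load.
    """

    def __init__(self):
        self.chains: Dict[tuple, str] = {}  # (chrom, strand, chain) -> tid
        self.chain_list: Dict[tuple, list[tuple[Chain, str]]] = defaultdict(list)
        self.junctions: Dict[tuple, Set[tuple]] = defaultdict(set)
        self.donor_sites: Dict[tuple, Set[int]] = defaultdict(set)
        self.acceptor_sites: Dict[tuple, Set[int]] = defaultdict(set)
        self.exons: Dict[tuple, list[tuple[int, int]]] = defaultdict(list)
        self.exon_set: Dict[tuple, Set[tuple]] = defaultdict(set)
        self.gene_spans: Dict[tuple, list[tuple[int, int, str]]] = defaultdict(list)
        self.start_codons: Dict[str, tuple] = {}  # tid -> (chrom, strand, pos)
        self.transcript_exons: Dict[str, list[tuple[int, int]]] = {}
        self.transcript_strand: Dict[str, tuple] = {}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_gtf(cls, path) -> "ReferenceAnnotation":
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
        ref = cls()
        gene_bounds: Dict[tuple, dict] = {}
        for feat in db.all_features():
            chrom, strand = feat.seqid, feat.strand
            start, end = feat.start - 1, feat.end  # to 0-based half-open
            if feat.featuretype == "exon":
                tid = feat.attributes.get("transcript_id", [None])[0]
                ref.transcript_exons.setdefault(tid, []).append((start, end))
                ref.transcript_strand[tid] = (chrom, strand)
                gid = feat.attributes.get("gene_id", [tid])[0]
                key = (chrom, strand, gid)
                b = gene_bounds.setdefault(key, {"lo": start, "hi": end})
                b["lo"] = min(b["lo"], start)
                b["hi"] = max(b["hi"], end)
            elif feat.featuretype == "start_codon":
                tid = feat.attributes.get("transcript_id", [None])[0]
                pos = start if strand != "-" else end  # first base, 5'->3'
                ref.start_codons[tid] = (chrom, strand, start, end)
        for tid, exons in ref.transcript_exons.items():
            exons.sort()
            chrom, strand = ref.transcript_strand[tid]
            ref._index_transcript(tid, chrom, strand, exons)
        for (chrom, strand, gid), b in gene_bounds.items():
            ref.gene_spans[(chrom, strand)].append((b["lo"], b["hi"], gid))
        for key in ref.gene_spans:
            ref.gene_spans[key].sort()
        for key in ref.exons:
            ref.exons[key] = sorted(set(ref.exons[key]))
        return ref

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]
                         ) -> "ReferenceAnnotation":
        """Build a reference from transcript models (used for self-checks)."""
        ref = cls()
        gene_bounds: Dict[tuple, dict] = {}
        for t in transcripts:
            ref.transcript_exons[t.transcript_id] = list(t.exons)
            ref.transcript_strand[t.transcript_id] = (t.chrom, t.strand)
            ref._index_transcript(t.transcript_id, t.chrom, t.strand, t.exons)
            key = (t.chrom, t.strand, t.locus_id or t.transcript_id)
            b = gene_bounds.setdefault(key, {"lo": t.start, "hi": t.end})
            b["lo"] = min(b["lo"], t.start)
            b["hi"] = max(b["hi"], t.end)
        for (chrom, strand, gid), b in gene_bounds.items():
            ref.gene_spans[(chrom, strand)].append((b["lo"], b["hi"], gid))
        for key in ref.gene_spans:
            ref.gene_spans[key].sort()
        for key in ref.exons:
            ref.exons[key] = sorted(set(ref.exons[key]))
        return ref

    def _index_transcript(self, tid, chrom, strand, exons):
        chain = tuple(
            (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
        )
        key = (chrom, strand)
        if chain:
            self.chains[(chrom, strand, chain)] = tid
            self.chain_list[key].append((chain, tid))
        for intron in chain:
            self.junctions[key].add(intron)
            left_side_donor = strand != "-"
            if left_side_donor:
                self.donor_sites[key].add(intron[0])
                self.acceptor_sites[key].add(intron[1])
            else:
                self.acceptor_sites[key].add(intron[0])
                self.donor_sites[key].add(intron[1])
        for ex in exons:
            self.exons[key].append(ex)
            self.exon_set[key].add(ex)

    # -- queries -----------------------------------------------------------
    def match_chain(self, chrom, strand, chain: Chain) -> Optional[str]:
        return self.chains.get((chrom, strand, tuple(chain)))

    def is_terminal_subchain(self, chrom, strand, chain: Chain) -> bool:
        """Is ``chain`` a strict prefix or suffix of a known chain?"""
        chain = tuple(chain)
        n = len(chain)
        for ref_chain, _tid in self.chain_list.get((chrom, strand), []):
            if len(ref_chain) <= n:
                continue
            if ref_chain[:n] == chain or ref_chain[-n:] == chain:
                return True
        return False

    def exons_overlapping(self, chrom, strand, start, end
                          ) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons.get((chrom, strand), []):
            if s >= end:
                break
            if e > start:
                out.append((s, e))
        return out

    def exons_inside(self, chrom, strand, start, end) -> list[tuple[int, int]]:
        """Reference exons strictly inside (start, end)."""
        return [
            (s, e) for s, e in self.exons.get((chrom, strand), [])
            if s > start and e < end
        ]


def match_known(transcript: TranscriptModel,
                reference: ReferenceAnnotation) -> Optional[str]:
    return reference.match_chain(transcript.chrom, transcript.strand,
                                 transcript.intron_chain)


def _junction_sides(strand: str, intron: tuple[int, int]) -> tuple[int, int]:
    """(donor position, acceptor position) of an intron given the strand."""
    if strand == "-":
        return intron[1], intron[0]
    return intron[0], intron[1]


def classify_novel(
    transcript: TranscriptModel,
    reference: ReferenceAnnotation,
    ambiguous_fraction: float = 0.0,
    ambiguity_threshold: float = 0.2,
) -> NoveltyCall:
    """Full novelty call for one transcript (known detection included)."""
    tid = transcript.transcript_id
    matched = match_known(transcript, reference)
    if matched is not None:
        return NoveltyCall(tid, "known", "none", matched_reference=matched)
    if ambiguous_fraction > ambiguity_threshold:
        return NoveltyCall(tid, "novel", "ambiguous")

    key = (transcript.chrom, transcript.strand)
    donors = reference.donor_sites.get(key, set())
    acceptors = reference.acceptor_sites.get(key, set())
    junctions = reference.junctions.get(key, set())

    events: list[tuple[str, tuple[int, int]]] = []
    combination_only = True  # stays True while all junctions use known sites

    for intron in transcript.intron_chain:
        if intron in junctions:
            continue
        d, a = _junction_sides(transcript.strand, intron)
        d_known = d in donors
        a_known = a in acceptors
        if d_known and a_known:
            skipped = reference.exons_inside(transcript.chrom,
                                             transcript.strand, *intron)
            if skipped:
                events.append(("ES", intron))
            # else: a novel pairing of annotated sites -> combination only
        elif d_known or a_known:
            events.append(("ASS", intron))
        else:
            # both sites novel: attributed to a novel exon when one flanks,
            # otherwise counted as novel splice sites
            events.append(("_novel_sites", intron))

    # exon-level events
    exon_list = transcript.exons
    for i, (es, ee) in enumerate(exon_list):
        # intron retention: exon fully contains a reference intron
        for rs, re_ in reference.junctions.get(key, set()):
            if es < rs and re_ < ee:
                events.append(("IR", (es, ee)))
                break
        # novel exon: internal exon, both flanking sites unannotated,
        # overlapping no reference exon
        if 0 < i < len(exon_list) - 1:
            left_known = es in donors or es in acceptors
            right_known = ee in donors or ee in acceptors
            if (not left_known and not right_known
                    and not reference.exons_overlapping(
                        transcript.chrom, transcript.strand, es, ee)):
                events.append(("NE", (es, ee)))
                # the flanking junctions' novelty is explained by the exon
                events = [ev for ev in events
                          if not (ev[0] in ("_novel_sites", "ASS")
                                  and (ev[1][1] == es or ev[1][0] == ee))]

    # leftover double-novel-site junctions count as alternative splice sites
    events = [("ASS", iv) if typ == "_novel_sites" else (typ, iv)
              for typ, iv in events]

    types = sorted({typ for typ, _ in events})
    if not types:
        category = "NC"
    elif len(types) == 1:
        category = types[0]
    else:
        category = "multiple"
    return NoveltyCall(tid, "novel", category, events=events)


def flag_read_through(transcript: TranscriptModel,
                      reference: ReferenceAnnotation) -> bool:
    """True when the transcript's exons overlap >= 2 reference genes on the
    same strand."""
    spans = reference.gene_spans.get((transcript.chrom, transcript.strand), [])
    genes = set()
    for s, e, gid in spans:
        for es, ee in transcript.exons:
            if es < e and ee > s:
                genes.add(gid)
                break
    return len(genes) >= 2


def repeat_overlap(
    exons_by_class: Dict[str, list[tuple[str, int, int]]],
    repeats: Dict[str, list[tuple[int, int]]],
) -> Dict[str, float]:
    """Fraction of exons per class overlapping a repeat interval (>= 1 bp).

    ``exons_by_class`` maps a class label (e.g. "known"/"novel") to
    (chrom, start, end) exons; ``repeats`` maps chrom to sorted intervals.
    """
    fractions = {}
    for label, exons in exons_by_class.items():
        if not exons:
            fractions[label] = float("nan")
            continue
        flagged = 0
        for chrom, s, e in exons:
            ivs = repeats.get(chrom, [])
            i = bisect.bisect_left(ivs, (s, s)) - 1
            hit = False
            for rs, re_ in ivs[max(0, i):]:
                if rs >= e:
                    break
                if re_ > s:
                    hit = True
                    break
            flagged += hit
        fractions[label] = flagged / len(exons)
    return fractions


def read_repeat_bed(path) -> Dict[str, list[tuple[int, int]]]:
    repeats: Dict[str, list[tuple[int, int]]] = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            repeats[parts[0]].append((int(parts[1]), int(parts[2])))
    for chrom in repeats:
        repeats[chrom].sort()
    return dict(repeats)


def classify_all(
    transcripts: list[TranscriptModel],
    reference: ReferenceAnnotation,
    ambiguous_fractions: Optional[Dict[str, float]] = None,
) -> list[NoveltyCall]:
    calls = []
    for t in transcripts:
        af = (ambiguous_fractions or {}).get(t.transcript_id, 0.0)
        call = classify_novel(t, reference, ambiguous_fraction=af)
        call.read_through = flag_read_through(t, reference)
        calls.append(call)
    return calls


def write_novelty_tsv(calls: Iterable[NoveltyCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tstatus\tcategory\tevents\tread_through\n")
        for c in calls:
            ev = ";".join(f"{t}:{iv[0]}-{iv[1]}" for t, iv in c.events)
            fh.write(f"{c.transcript_id}\t{c.status}\t{c.category}\t{ev}"
                     f"\t{int(c.read_through)}\n")
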