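"""Tag splice-site identification by clustering junction-end positions.

Per-read junction ends scatter around the true splice sites because of
basecalling error and alignment wobble.  The donor and acceptor ends of all
introns are histogrammed separately per chromosome and strand, and each
histogram is reduced to a set of *tag splice sites* by an iterative
peak-picking procedure controlled by four constants:

half_window (HFWINSIZE)
    counts are smoothed with a running sum over +-half_window positions;
dist_thresh (DISTHRES)
    cluster radius: positions within this distance of a peak join it;
peak_thresh (PTHRESHOLD)
    a peak must have raw count >= this;
sum_thresh (SUMHOLD)
    a cluster is accepted only when its summed raw count >= this.

All thresholds are inclusive.  The tag position is the observed position
closest to the cluster's raw-count centroid (ties: the higher count, then
the smaller coordinate), so tags always sit on observed positions while the
center estimate stays robust to symmetric per-read wobble.
"""

from __future__ import annotations

import bisect
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

from .alnfilter import JunctionChain

DONOR = "donor"
ACCEPTOR = "acceptor"

SiteKey = Tuple[str, str, str]  # (chrom, strand, side)


@dataclass(frozen=True)
class ClusterParams:
    half_window: int = 5
    dist_thresh: int = 8
    peak_thresh: int = 3
    sum_thresh: int = 5

    def __post_init__(self):
        for name in ("half_window", "dist_thresh", "peak_thresh", "sum_thresh"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SpliceSiteTag:
    chrom: str
    strand: str
    side: str
    position: int
    support: int
    member_positions: list  # [(position, count), ...]


def junction_sides(strand: str) -> tuple[str, str]:
    """(side of intron-left end, side of intron-right end) for a strand.

    On '+' the intron's left boundary is the donor (exon-intron junction) and
    the right boundary the acceptor; on '-' it is the opposite.
    """
    if strand == "-":
        return ACCEPTOR, DONOR
    return DONOR, ACCEPTOR


def collect_junction_ends(chains: Iterable[JunctionChain]
                          ) -> Dict[SiteKey, Counter]:
    """Histogram donor and acceptor intron ends per (chrom, strand, side)."""
    hists: Dict[SiteKey, Counter] = defaultdict(Counter)
    for chain in chains:
        left_side, right_side = junction_sides(chain.strand)
        for start, end in chain.introns:
            hists[(chain.chrom, chain.strand, left_side)][start] += 1
            hists[(chain.chrom, chain.strand, right_side)][end] += 1
    return dict(hists)


def cluster_sites(histogram: Dict[int, int], params: ClusterParams,
                  chrom: str = "", strand: str = "", side: str = ""
                  ) -> list[SpliceSiteTag]:
    """Reduce one position histogram to tag splice sites.

    Iteratively: smooth the remaining raw counts with a running sum over
    +-half_window; pick the position with the highest smoothed count whose
    raw count >= peak_thresh (ties to the smaller coordinate); gather all
    remaining positions within dist_thresh of it; accept the cluster when its
    raw-count sum >= sum_thresh; remove the gathered positions and repeat.
    """
    remaining = {int(p): int(c) for p, c in histogram.items() if c > 0}
    tags: list[SpliceSiteTag] = []
    while remaining:
        positions = sorted(remaining)
        # smoothed count = sum of raw counts within +-half_window
        best_pos = None
        best_smooth = -1
        for p in positions:
            if remaining[p] < params.peak_thresh:
                continue
            lo = bisect.bisect_left(positions, p - params.half_window)
            hi = bisect.bisect_right(positions, p + params.half_window)
            smooth = sum(remaining[q] for q in positions[lo:hi])
            if smooth > best_smooth:
                best_smooth = smooth
                best_pos = p
        if best_pos is None:
            break
        lo = bisect.bisect_left(positions, best_pos - params.dist_thresh)
        hi = bisect.bisect_right(positions, best_pos + params.dist_thresh)
        members = [(q, remaining[q]) for q in positions[lo:hi]]
        total = sum(c for _, c in members)
        if total >= params.sum_thresh:
            # tag position: the observed position closest to the raw-count
            # centroid (ties -> higher count -> smaller coordinate); the
            # centroid is a consistent center estimate under symmetric
            # per-read junction wobble, where the mode is not
            centroid = sum(p * c for p, c in members) / total
            tag_pos = min(
                members,
                key=lambda pc: (abs(pc[0] - centroid), -pc[1], pc[0]),
            )[0]
            tags.append(SpliceSiteTag(chrom, strand, side, tag_pos, total,
                                      members))
        for q, _ in members:
            del remaining[q]
    tags.sort(key=lambda t: t.position)
    return tags


#: canonical half-motifs of the first/last two intron bases on the forward
#: genome strand, by (strand, side of the intron end)
_HALF_MOTIFS = {
    ("+", DONOR): ("start", {"GT", "GC", "AT"}),
    ("+", ACCEPTOR): ("end", {"AG", "AC"}),
    ("-", DONOR): ("end", {"AC", "GC", "AT"}),
    ("-", ACCEPTOR): ("start", {"CT", "GT"}),
}


def refine_tag_positions(tags: Dict[SiteKey, list[SpliceSiteTag]],
                         genome) -> Dict[SiteKey, list[SpliceSiteTag]]:
    """Anchor tag positions on canonical splice motifs where possible.

    For each tag, if a member position carries the canonical half-motif of
    its side (GT../..AG and minor variants, strand-aware), the tag moves to
    the motif-bearing member closest to the cluster centroid.  This mirrors
    how splice-aware aligners anchor junctions and sharpens low-support
    tags whose centroid is off by a base; it uses only the genome sequence,
    never an annotation.
    """
    for (chrom, strand, side), tag_list in tags.items():
        if (strand, side) not in _HALF_MOTIFS:
            continue
        which, motifs = _HALF_MOTIFS[(strand, side)]
        seq = genome[chrom]
        for tag in tag_list:
            total = sum(c for _, c in tag.member_positions)
            centroid = sum(p * c for p, c in tag.member_positions) / total
            candidates = []
            for p, c in tag.member_positions:
                mer = (str(seq[p:p + 2]) if which == "start"
                       else str(seq[p - 2:p])).upper()
                if mer in motifs:
                    candidates.append((p, c))
            if candidates:
                tag.position = min(
                    candidates,
                    key=lambda pc: (abs(pc[0] - centroid), -pc[1], pc[0]),
                )[0]
    return tags


def build_tag_index(chains: Iterable[JunctionChain],
                    params: Optional[ClusterParams] = None,
                    genome=None) -> Dict[SiteKey, list[SpliceSiteTag]]:
    """Cluster every junction-end histogram of a dataset.

    When a genome is supplied, tag positions are motif-refined afterwards
    (see :func:`refine_tag_positions`)."""
    if params is None:
        params = ClusterParams()
    hists = collect_junction_ends(chains)
    index: Dict[SiteKey, list[SpliceSiteTag]] = {}
    for key in sorted(hists):
        chrom, strand, side = key
        index[key] = cluster_sites(hists[key], params, chrom, strand, side)
    if genome is not None:
        index = refine_tag_positions(index, genome)
    return index


def _snap(position: int, tag_positions: list[int], dist_thresh: int
          ) -> Optional[int]:
    """Nearest tag within dist_thresh; equidistant ties -> smaller coord."""
    if not tag_positions:
        return None
    i = bisect.bisect_left(tag_positions, position)
    candidates = []
    if i > 0:
        candidates.append(tag_positions[i - 1])
    if i < len(tag_positions):
        candidates.append(tag_positions[i])
    best = min(candidates, key=lambda t: (abs(t - position), t))
    if abs(best - position) <= dist_thresh:
        return best
    return None


def assign_reads_to_tags(
    chains: Iterable[JunctionChain],
    tags: Dict[SiteKey, list[SpliceSiteTag]],
    params: Optional[ClusterParams] = None,
    report: Optional[dict] = None,
) -> tuple[list[JunctionChain], list[JunctionChain]]:
    """Snap every junction end of every chain onto its nearest tag.

    Returns (tagged_chains, discarded_chains); a chain with any junction end
    farther than dist_thresh from every tag of the matching (chrom, strand,
    side) is discarded.
    """
    if params is None:
        params = ClusterParams()
    pos_index = {key: [t.position for t in tag_list]
                 for key, tag_list in tags.items()}
    tagged: list[JunctionChain] = []
    discarded: list[JunctionChain] = []
    for chain in chains:
        left_side, right_side = junction_sides(chain.strand)
        new_introns = []
        ok = True
        for start, end in chain.introns:
            s = _snap(start, pos_index.get((chain.chrom, chain.strand,
                                            left_side), []),
                      params.dist_thresh)
            e = _snap(end, pos_index.get((chain.chrom, chain.strand,
                                          right_side), []),
                      params.dist_thresh)
            if s is None or e is None or e <= s:
                ok = False
                break
            new_introns.append((s, e))
        if not ok:
            discarded.append(chain)
            continue
        tagged.append(JunctionChain(
            read_id=chain.read_id, chrom=chain.chrom, strand=chain.strand,
            introns=tuple(new_introns), read_start=chain.read_start,
            read_end=chain.read_end, is_full_length=chain.is_full_length,
            sample=chain.sample,
        ))
    if report is not None:
        report["chains_tagged"] = report.get("chains_tagged", 0) + len(tagged)
        report["chains_unassignable"] = (
            report.get("chains_unassignable", 0) + len(discarded))
    return tagged, discarded


def write_tags_bed(tags: Dict[SiteKey, list[SpliceSiteTag]], path) -> None:
    """Tags as 6-column BED (name = side, score = support)."""
    rows = []
    for (chrom, strand, side), tag_list in tags.items():
        for t in tag_list:
            rows.append((chrom, t.position, t.position + 1, side, t.support,
                         strand))
    rows.sort()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
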